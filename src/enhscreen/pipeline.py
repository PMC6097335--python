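"""Convenience orchestration of the standard stage order.

These helpers just chain the library stages with the reference parameter
set; each stage remains individually usable. The TU universe downstream of
filtering is the set of detected TUs (those passing the minimum-coverage
rule), so pairing operates on detected TUs only.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from . import enhancers, expression, screen as screen_mod

__all__ = ["call_induced_elements", "score_screen"]


def call_induced_elements(
    tus: pd.DataFrame,
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    min_reads: float = 20,
    floor: float = 10,
    max_sep: int = 800,
    min_fold: float = 2.0,
    scan_margin: int = 200,
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter -> quantile-normalize -> fold change -> pair -> induction call.

    Returns (RE table with induced flags and scan regions, per-replicate
    log2 fold-change table over detected TUs).
    """
    filtered = expression.filter_min_coverage(counts, min_reads=min_reads)
    norm = expression.quantile_normalize(filtered)
    fc = expression.fold_change(norm, samples, floor=floor)
    detected = tus[tus["tu_id"].isin(fc.index)]
    res = enhancers.pair_bidirectional(detected, max_sep=max_sep)
    res = enhancers.call_induced(res, fc, min_fold=min_fold)
    res = enhancers.add_scan_regions(res, margin=scan_margin, chrom_lengths=chrom_lengths)
    return res, fc


def score_screen(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    library,
    floor: float = 50,
    mean_fc_threshold: float = 1.75,
    threshold_units: str | None = None,
    min_guides_per_re: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """CPM -> floored per-replicate log2 FC -> Z scores -> hit calling.

    Returns (per-guide enrichment table, hit report).
    """
    norm = screen_mod.normalize_cpm(counts)
    fc = screen_mod.guide_fold_changes(norm, samples, floor=floor)
    enr = screen_mod.z_scores(fc)
    report = screen_mod.call_hits(
        enr, library, mean_fc_threshold=mean_fc_threshold,
        threshold_units=threshold_units, min_guides_per_re=min_guides_per_re,
    )
    return enr, report
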