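"""Pooled CRISPR screen scoring: CPM, floored log2 enrichment, Z scores, hits.

Read counts per sgRNA are normalized to 1 M reads per sample, floored at 50
normalized reads (so lowly covered guides cannot produce inflated ratios),
turned into per-replicate log2 enrichment ratios between the induced and
control populations, averaged over replicates, and standardized against the
library-wide mean and SD to a Z score. A guide is a hit when its mean
enrichment exceeds a threshold; an RE-level hit is corroborated when at
least two distinct hit guides target the same regulatory element.

Count tables are DataFrames (rows = guide ids, columns = sample ids) with a
sample table carrying ``condition`` (``induced``/``control``) and
``replicate`` columns, as in :mod:`enhscreen.expression`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .expression import paired_log2_fold_change
from .guides import GuideLibrary

__all__ = ["normalize_cpm", "guide_fold_changes", "z_scores", "call_hits"]


def normalize_cpm(counts: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Scale each sample column to ``scale`` total reads (counts per million)."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    return counts * scale / totals


def guide_fold_changes(
    norm: pd.DataFrame,
    samples: pd.DataFrame,
    floor: float = 50,
) -> pd.DataFrame:
    """Per-replicate log2 enrichment (induced vs control) of normalized counts.

    Normalized counts below ``floor`` (default 50) are raised to the floor
    before the ratio. Replicates are paired by index; an unpaired layout
    raises ValueError.
    """
    return paired_log2_fold_change(norm, samples, floor=floor, pairing="by_index")


def z_scores(fc_table: pd.DataFrame) -> pd.DataFrame:
    """Mean enrichment per guide and its library-wide standard (Z) score.

    Returns the per-replicate columns plus ``mean_fc`` (arithmetic mean of
    the per-replicate log2 FCs) and ``z`` standardized with the library mean
    and sample SD (ddof=1) of ``mean_fc``. A degenerate library (SD = 0)
    yields all-zero Z with a warning; fewer than 2 guides is an error.
    """
    if len(fc_table) < 2:
        raise ValueError("Z scores need at least 2 guides")
    out = fc_table.copy()
    out["mean_fc"] = fc_table.mean(axis=1)
    sd = out["mean_fc"].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("library-wide SD of mean enrichment is 0; all Z set to 0", stacklevel=2)
        out["z"] = 0.0
    else:
        out["z"] = (out["mean_fc"] - out["mean_fc"].mean()) / sd
    return out


def call_hits(
    enrichments: pd.DataFrame,
    library: GuideLibrary | pd.DataFrame,
    mean_fc_threshold: float = 1.75,
    threshold_units: str | None = None,
    min_guides_per_re: int = 2,
) -> dict:
    """Guide-level hits and RE-level corroborated hits.

    ``enrichments`` is the :func:`z_scores` output indexed by guide id;
    ``library`` supplies the guide -> RE mapping (a :class:`GuideLibrary` or
    a DataFrame with ``guide_id``/``re_id`` columns).

    ``threshold_units`` must be given explicitly as ``"log2"`` or
    ``"linear"``: the hit threshold (1.75 by default) is ambiguous between
    a log2 and a linear enrichment fold, and the choice changes the hit set,
    so it is a required analysis decision rather than a default. Guide hits
    have mean enrichment strictly above the threshold; corroborated REs are
    targeted by at least ``min_guides_per_re`` distinct hit guides. Both
    lists are sorted by best Z score.
    """
    if threshold_units not in ("log2", "linear"):
        raise ValueError(
            "threshold_units must be 'log2' or 'linear': the screen hit "
            "threshold is stated as a bare enrichment fold and its scale is "
            "ambiguous, so the caller must choose explicitly"
        )
    guides = library.guides if isinstance(library, GuideLibrary) else library
    mapping = guides.set_index("guide_id")["re_id"]

    mean_enrich = enrichments["mean_fc"]
    if threshold_units == "linear":
        mean_enrich = np.exp2(mean_enrich)
    hits = enrichments[mean_enrich > mean_fc_threshold].sort_values("z", ascending=False)

    guide_hits = [
        {"guide_id": str(g), "mean_fc": float(row["mean_fc"]), "z": float(row["z"])}
        for g, row in hits.iterrows()
    ]

    by_re: dict[str, list[dict]] = {}
    for gh in guide_hits:
        re_id = mapping.get(gh["guide_id"])
        if re_id is None or (isinstance(re_id, float) and np.isnan(re_id)):
            continue
        by_re.setdefault(str(re_id), []).append(gh)
    re_hits = [
        {
            "re_id": re_id,
            "guides": [g["guide_id"] for g in members],
            "best_z": max(g["z"] for g in members),
        }
        for re_id, members in by_re.items()
        if len(members) >= min_guides_per_re
    ]
    re_hits.sort(key=lambda r: -r["best_z"])
    return {
        "guide_hits": guide_hits,
        "re_hits": re_hits,
        "threshold": mean_fc_threshold,
        "threshold_units": threshold_units,
        "min_guides_per_re": min_guides_per_re,
    }
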