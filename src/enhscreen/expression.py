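"""Filtering, normalization and induction fold changes for TU count tables.

The nascent-transcription workflow quantifies each strand-specific
transcriptional unit (TU) in every sample, keeps TUs with minimal coverage,
makes samples comparable by quantile normalization, and expresses induction
as per-replicate log2 fold changes with a floor on expression levels so that
lowly expressed TUs cannot produce inflated ratios.

An expression matrix is a pandas DataFrame (rows = TU ids, columns = sample
ids) accompanied by a sample table (index = sample id) with ``condition``
(``control`` or ``induced``) and ``replicate`` (integer) columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "filter_min_coverage",
    "quantile_normalize",
    "fold_change",
    "paired_log2_fold_change",
]


def filter_min_coverage(matrix: pd.DataFrame, min_reads: float = 20) -> pd.DataFrame:
    """Keep rows covered by at least ``min_reads`` in at least one sample.

    Operates on raw (pre-normalization) counts. Row order is preserved.
    An empty result is permitted (a warning is emitted, not an error).
    """
    kept = matrix[matrix.max(axis=1) >= min_reads]
    if kept.empty and not matrix.empty:
        warnings.warn(
            f"filter_min_coverage(min_reads={min_reads}) removed every row",
            stacklevel=2,
        )
    return kept


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so each carries the identical value multiset.

    Every column is replaced by the per-rank across-column means; within-column
    rank order is preserved. Ties within a column receive the mean of the
    normalized values their ranks span (the common "average" convention).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    arr = matrix.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    rank_means = np.take_along_axis(arr, order, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = rank_means
        # average the assigned values over groups of tied input values
        col = pd.Series(out[:, j])
        out[:, j] = col.groupby(arr[:, j]).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _replicate_pairs(samples: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Return (replicate, induced_sample, control_sample) triples by index."""
    for col in ("condition", "replicate"):
        if col not in samples.columns:
            raise ValueError(f"sample table is missing column '{col}'")
    by = {
        (row.condition, row.replicate): sample
        for sample, row in samples.iterrows()
    }
    reps_ind = sorted(r for c, r in by if c == "induced")
    reps_ctl = sorted(r for c, r in by if c == "control")
    if reps_ind != reps_ctl or not reps_ind:
        raise ValueError(
            "unpaired replicate structure: induced replicates "
            f"{reps_ind} vs control replicates {reps_ctl}"
        )
    return [(r, by[("induced", r)], by[("control", r)]) for r in reps_ind]


def paired_log2_fold_change(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    floor: float,
    pairing: str = "by_index",
) -> pd.DataFrame:
    """log2(max(induced, floor) / max(control, floor)) per replicate.

    The floor is applied to each level before the ratio, never to the ratio
    itself, so the result is finite everywhere. ``pairing='by_index'`` pairs
    induced replicate i with control replicate i; ``pairing='vs_mean'``
    compares each induced replicate against the mean control level.
    """
    pairs = _replicate_pairs(samples)
    if pairing not in ("by_index", "vs_mean"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    ctl_mean = matrix[[c for _, _, c in pairs]].mean(axis=1)
    out = {}
    for rep, ind_s, ctl_s in pairs:
        num = np.maximum(matrix[ind_s].to_numpy(dtype=float), floor)
        ctl = ctl_mean if pairing == "vs_mean" else matrix[ctl_s]
        den = np.maximum(ctl.to_numpy(dtype=float), floor)
        out[rep] = np.log2(num / den)
    return pd.DataFrame(out, index=matrix.index)


def fold_change(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    floor: float = 10,
    pairing: str = "by_index",
) -> pd.DataFrame:
    """Per-replicate log2 induction fold change of a normalized TU matrix.

    Expression levels below ``floor`` (default 10) are raised to the floor
    before the ratio to avoid inflated fold changes for lowly expressed TUs.
    Returns a DataFrame (rows = TU ids, columns = replicate indices).
    """
    return paired_log2_fold_change(matrix, samples, floor=floor, pairing=pairing)
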