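"""Pair divergent TUs into regulatory elements and call induced elements.

Bidirectional transcription is the defining signature of active regulatory
elements (enhancers and promoters): two TUs on opposite strands whose 5'
start sites lie within a short window (800 bp by default) and that
transcribe away from each other. A regulatory element (RE) is called
induced when both of its mates show at least a two-fold expression increase
in every replicate.

TU tables are BED-like DataFrames with columns
``tu_id, chrom, start, end, strand`` (0-based half-open; strand ``+``/``-``).
The 5' start site of a TU is ``start`` on the plus strand and ``end - 1`` on
the minus strand.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["tss", "pair_bidirectional", "call_induced", "scan_region", "add_scan_regions"]

RE_COLUMNS = [
    "re_id", "chrom", "plus_tu", "minus_tu",
    "plus_tss", "minus_tss", "core_start", "core_end", "separation",
]


def tss(tus: pd.DataFrame) -> pd.Series:
    """5' start-site coordinate of each TU (start for +, end-1 for -)."""
    plus = tus["strand"] == "+"
    return pd.Series(
        np.where(plus, tus["start"], tus["end"] - 1),
        index=tus.index,
        name="tss",
    )


def pair_bidirectional(
    tus: pd.DataFrame,
    max_sep: int = 800,
    require_divergent: bool = True,
) -> pd.DataFrame:
    """Pair opposite-strand TUs whose start sites are at most ``max_sep`` apart.

    Pairing is one-to-one and greedy: every TU joins at most one RE, the
    nearest start-site partner wins, and ties are broken by the leftmost
    partner coordinate. With ``require_divergent`` (default) the two TUs must
    transcribe away from each other (minus-strand TSS at or left of the
    plus-strand TSS); convergent opposite-strand pairs are rejected.
    Output rows are ordered by genomic position.
    """
    bad = set(tus["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand value(s): {sorted(bad)}")
    t = tus.copy()
    t["tss"] = tss(t)

    candidates = []
    for chrom, group in t.groupby("chrom", sort=True):
        plus = group[group["strand"] == "+"]
        minus = group[group["strand"] == "-"]
        for _, p in plus.iterrows():
            sep = (minus["tss"] - p["tss"]).abs()
            ok = sep <= max_sep
            if require_divergent:
                ok &= minus["tss"] <= p["tss"]
            for _, m in minus[ok].iterrows():
                s = abs(int(m["tss"]) - int(p["tss"]))
                left = min(int(m["tss"]), int(p["tss"]))
                candidates.append((s, str(chrom), left, p["tu_id"], m["tu_id"],
                                   int(p["tss"]), int(m["tss"])))

    candidates.sort()
    used: set = set()
    rows = []
    for s, chrom, left, ptu, mtu, ptss, mtss in candidates:
        if ptu in used or mtu in used:
            continue
        used.update((ptu, mtu))
        lo, hi = min(ptss, mtss), max(ptss, mtss)
        rows.append((chrom, ptu, mtu, ptss, mtss, lo, hi + 1, s))

    rows.sort(key=lambda r: (r[0], r[5]))
    res = pd.DataFrame(rows, columns=RE_COLUMNS[1:])
    res.insert(0, "re_id", [f"RE{i:05d}" for i in range(len(res))])
    assert res[["plus_tu", "minus_tu"]].to_numpy().ravel().size == len(used)
    return res


def call_induced(
    res: pd.DataFrame,
    fc: pd.DataFrame,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Flag REs whose two mates are induced ``min_fold``-fold in every replicate.

    ``fc`` is the per-replicate log2 fold-change table indexed by TU id.
    The rule is inclusive: log2 FC >= log2(min_fold) for BOTH mates in ALL
    replicates. Raises KeyError naming any RE mate absent from ``fc``.
    """
    threshold = np.log2(min_fold)
    out = res.copy()
    flags = []
    for _, re_row in res.iterrows():
        for mate in (re_row["plus_tu"], re_row["minus_tu"]):
            if mate not in fc.index:
                raise KeyError(f"TU '{mate}' of {re_row['re_id']} missing from fold-change table")
        mates = fc.loc[[re_row["plus_tu"], re_row["minus_tu"]]]
        flags.append(bool((mates.to_numpy() >= threshold).all()))
    out["induced"] = flags
    return out


def scan_region(
    re_row: Mapping,
    margin: int = 200,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """Motif-scan interval of an RE: between the two TSSs plus a margin.

    Returns the half-open interval
    ``[min(tss) - margin, max(tss) + margin + 1)`` (the inclusive outer base
    is part of the scanned region), clipped to chromosome bounds.
    """
    lo = min(int(re_row["plus_tss"]), int(re_row["minus_tss"])) - margin
    hi = max(int(re_row["plus_tss"]), int(re_row["minus_tss"])) + margin + 1
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def add_scan_regions(
    res: pd.DataFrame,
    margin: int = 200,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Attach ``scan_start``/``scan_end`` columns to an RE table."""
    out = res.copy()
    bounds = [
        scan_region(
            row,
            margin=margin,
            chrom_length=None if chrom_lengths is None else chrom_lengths[row["chrom"]],
        )
        for _, row in res.iterrows()
    ]
    out["scan_start"] = [b[0] for b in bounds]
    out["scan_end"] = [b[1] for b in bounds]
    return out
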