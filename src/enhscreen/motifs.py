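"""PWM motif scanning with exact null p-values, flank controls, enrichment.

A position weight matrix (PWM) holds per-position base probabilities for a
transcription-factor binding motif. Windows are scored as log-odds in bits,

    score(w) = sum_i log2( p[ w_i , i ] / bg[ w_i ] ),

and each window score is converted to an exact p-value — the probability
that a random background word scores at least as high — computed by dynamic
programming over the discretized score distribution (granularity 1/1000
bit, i.e. per-position log-odds are rounded to integer milli-bits and the
full null distribution of the integer total is convolved exactly). A window
is reported when its p-value is at or below the threshold (1e-4 by default,
the FIMO default). Both strands are scanned; occurrences must lie fully
inside the scanned region.

Over-representation of a motif in test regions versus flanking control
regions is assessed by a one-sided Fisher's exact test on the 2x2 table of
regions with / without at least one occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from ._util import encode_sequence

__all__ = [
    "PWM",
    "scan_occurrences",
    "extract_controls",
    "fisher_enrichment",
    "motif_enrichment",
]

GRANULARITY = 1000  # integer score units per bit

OCC_COLUMNS = ["motif_id", "re_id", "chrom", "start", "end", "strand", "score", "p_value"]


@dataclass
class PWM:
    """Position weight matrix with background model and pseudocount.

    ``probs`` is a 4 x L array of per-position base probabilities in row
    order A, C, G, T. A small pseudocount mixes each column with the
    background (``p' = (p + pc*bg) / (1 + pc)``) so log-odds stay finite.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PWM must be a 4 x L matrix with L >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-3):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        eff = (self.probs + self.pseudocount * self.background[:, None]) / (1 + self.pseudocount)
        self._eff = eff
        assert np.allclose(eff.sum(axis=0), 1.0, atol=1e-6)
        self._log_odds = np.log2(eff / self.background[:, None])
        self._int_scores = np.rint(self._log_odds * GRANULARITY).astype(np.int64)
        self._distribution_cache: tuple[int, np.ndarray] | None = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.01,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = counts / counts.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        return cls(name=name, probs=probs, background=bg, pseudocount=pseudocount)

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        name: str | None = None,
        dominance: float = 0.94,
        pseudocount: float = 0.01,
    ) -> "PWM":
        """Sharp PWM putting ``dominance`` probability on each consensus base."""
        idx = encode_sequence(consensus.upper())
        if (idx >= 4).any():
            raise ValueError(f"consensus must be unambiguous DNA, got {consensus!r}")
        L = len(consensus)
        probs = np.full((4, L), (1 - dominance) / 3)
        probs[idx, np.arange(L)] = dominance
        return cls(name=name or consensus.upper(), probs=probs, pseudocount=pseudocount)

    # -- basic properties --------------------------------------------------
    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self._eff.argmax(axis=0))

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L float log-odds (bits) after pseudocount."""
        return self._log_odds

    @property
    def int_scores(self) -> np.ndarray:
        """4 x L integer (milli-bit) log-odds actually used for p-values."""
        return self._int_scores

    @property
    def max_score(self) -> float:
        return float(self._log_odds.max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        rc = PWM(
            name=f"{self.name}_rc",
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background.copy(),
            pseudocount=self.pseudocount,
        )
        return rc

    # -- scoring and exact null distribution ------------------------------
    def score(self, window: str) -> float:
        """Float log-odds score of a length-L window (ambiguous bases score 0)."""
        idx = encode_sequence(window.upper())
        if idx.size != self.length:
            raise ValueError(f"window length {idx.size} != motif length {self.length}")
        lo = np.vstack([self._log_odds, np.zeros(self.length)])
        return float(lo[idx, np.arange(self.length)].sum())

    def score_distribution(self) -> tuple[int, np.ndarray]:
        """(min_total, pmf) of the integer score under the background model.

        ``pmf[k]`` is the probability that a background word has integer
        score ``min_total + k``.
        """
        if self._distribution_cache is not None:
            return self._distribution_cache
        ints = self._int_scores
        mins = ints.min(axis=0)
        pmf = np.ones(1)
        for i in range(self.length):
            width = int(ints[:, i].max() - mins[i])
            new = np.zeros(pmf.size + width)
            for b in range(4):
                off = int(ints[b, i] - mins[i])
                new[off:off + pmf.size] += pmf * self.background[b]
            pmf = new
        self._distribution_cache = (int(mins.sum()), pmf)
        return self._distribution_cache

    def survival(self) -> tuple[int, np.ndarray]:
        """(min_total, sf) where sf[k] = P(score >= min_total + k)."""
        min_total, pmf = self.score_distribution()
        return min_total, pmf[::-1].cumsum()[::-1]

    def pvalue(self, int_score: int) -> float:
        """Exact P(background word scores >= int_score), in milli-bits."""
        min_total, sf = self.survival()
        k = int(int_score) - min_total
        if k <= 0:
            return 1.0
        if k >= sf.size:
            return 0.0
        return float(sf[k])

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose exact p-value is <= p_threshold."""
        min_total, sf = self.survival()
        idx = np.searchsorted(-sf, -p_threshold, side="left")
        if idx >= sf.size:
            return min_total + sf.size  # unattainable: no window passes
        return min_total + int(idx)


def _scan_strand(idx: np.ndarray, pwm: PWM, threshold_int: int) -> tuple[np.ndarray, np.ndarray]:
    """Window start offsets and integer scores passing threshold on one matrix."""
    L = pwm.length
    if idx.size < L:
        return np.empty(0, dtype=int), np.empty(0, dtype=np.int64)
    ints = np.vstack([pwm.int_scores, np.zeros(L, dtype=np.int64)])
    windows = sliding_window_view(idx, L)
    scores = ints[windows, np.arange(L)].sum(axis=1)
    hit = np.nonzero(scores >= threshold_int)[0]
    return hit, scores[hit]


def scan_occurrences(
    regions: pd.DataFrame | Iterable,
    genome: Mapping[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Report PWM occurrences on both strands of each region.

    ``regions`` is a DataFrame with columns ``chrom, start, end`` and
    optionally ``re_id``; ``genome`` maps chromosome name to sequence.
    Occurrences are length-L windows lying fully inside the region whose
    exact null p-value is <= ``p_threshold``; overlapping occurrences are
    allowed. Minus-strand windows are scored with the reverse-complement
    matrix (coordinates stay on the top strand). Output order is
    deterministic: by (chrom, start, strand). Regions shorter than the motif
    yield no occurrences.
    """
    if not isinstance(regions, pd.DataFrame):
        regions = pd.DataFrame(list(regions), columns=["chrom", "start", "end"])
    if "re_id" not in regions.columns:
        regions = regions.copy()
        regions["re_id"] = [f"region{i}" for i in range(len(regions))]

    rc = pwm.reverse_complement()
    thr_plus = pwm.score_threshold(p_threshold)
    thr_minus = rc.score_threshold(p_threshold)

    rows = []
    for _, reg in regions.iterrows():
        chrom = reg["chrom"]
        start, end = int(reg["start"]), int(reg["end"])
        seq = genome[chrom][start:end]
        idx = encode_sequence(seq.upper())
        for strand, matrix, thr in (("+", pwm, thr_plus), ("-", rc, thr_minus)):
            offs, ints = _scan_strand(idx, matrix, thr)
            for off, sint in zip(offs, ints):
                window = seq[off:off + pwm.length].upper()
                score = matrix.score(window)
                rows.append((
                    reg["re_id"], chrom, start + int(off), start + int(off) + pwm.length,
                    strand, score, matrix.pvalue(int(sint)),
                ))
    rows.sort(key=lambda r: (r[1], r[2], r[4]))
    occs = pd.DataFrame(rows, columns=OCC_COLUMNS[1:])
    occs.insert(0, "motif_id", [f"M{i:05d}" for i in range(len(occs))])
    return occs


def extract_controls(
    region: tuple[int, int],
    chrom_length: int,
) -> dict[str, tuple[int, int] | None]:
    """Immediately flanking upstream/downstream control intervals.

    Each control abuts the test region and has the same length, clipped at
    chromosome edges (an entirely infeasible flank is returned as ``None``;
    both infeasible raises ValueError).
    """
    start, end = int(region[0]), int(region[1])
    if not (0 <= start < end <= chrom_length):
        raise ValueError(f"region {region} outside chromosome of length {chrom_length}")
    length = end - start
    upstream: tuple[int, int] | None = (max(0, start - length), start)
    downstream: tuple[int, int] | None = (end, min(chrom_length, end + length))
    if upstream[1] - upstream[0] <= 0:
        upstream = None
    if downstream[1] - downstream[0] <= 0:
        downstream = None
    if upstream is None and downstream is None:
        raise ValueError(f"no feasible flank for region {region}")
    return {"upstream": upstream, "downstream": downstream}


def fisher_enrichment(
    n_test_with: int,
    n_test: int,
    n_control_with: int,
    n_control: int,
) -> tuple[float, float]:
    """One-sided Fisher's exact test for motif over-representation.

    The 2x2 table is (test with / test without // control with / control
    without); the alternative is excess in the test set. Returns
    (odds ratio, p-value); the odds ratio is Haldane-corrected (+0.5 per
    cell) whenever any cell is zero.
    """
    if n_test <= 0 or n_control <= 0:
        raise ValueError("test and control sets must be non-empty")
    a, b = n_test_with, n_test - n_test_with
    c, d = n_control_with, n_control - n_control_with
    if min(a, b, c, d) < 0:
        raise ValueError("with-counts exceed set sizes")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if min(a, b, c, d) == 0:
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b * c)
    return float(odds), float(p)


def motif_enrichment(
    test_regions: pd.DataFrame,
    control_regions: pd.DataFrame,
    genome: Mapping[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
) -> tuple[float, float]:
    """Fisher over-representation of a motif in test vs control regions.

    Each set is scanned with :func:`scan_occurrences`; a region counts as
    "with motif" when it contains at least one occurrence.
    """
    def n_with(regions: pd.DataFrame) -> int:
        regs = regions.copy()
        regs["re_id"] = [f"r{i}" for i in range(len(regs))]
        occ = scan_occurrences(regs, genome, pwm, p_threshold)
        return occ["re_id"].nunique()

    if len(test_regions) == 0 or len(control_regions) == 0:
        raise ValueError("test and control region sets must be non-empty")
    return fisher_enrichment(
        n_with(test_regions), len(test_regions),
        n_with(control_regions), len(control_regions),
    )
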