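"""Independent brute-force oracles used by the tests.

These deliberately re-derive each quantity from first principles (exhaustive
enumeration, direct counting) without calling the implementation paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_guides(seq: str, motifs, margin: int = 5, spacer_len: int = 20) -> set:
    """Every (spacer, strand, cut) obtained by testing all PAM x motif pairs."""
    out = set()
    for s, e in motifs:
        for i in range(len(seq) - 2):
            tri = seq[i:i + 3]
            if tri[1] == "G" and tri[2] == "G":
                cut = i - 3
                if s - margin <= cut <= e + margin and i - spacer_len >= 0 and cut >= 0:
                    out.add((seq[i - spacer_len:i], "+", cut))
            if tri[0] == "C" and tri[1] == "C":
                cut = i + 6
                if s - margin <= cut <= e + margin and i + 3 + spacer_len <= len(seq):
                    out.add((rc(seq[i + 3:i + 3 + spacer_len]), "-", cut))
    return out


def enumeration_pvalues(int_matrix: np.ndarray, background: np.ndarray) -> dict[int, float]:
    """Exact P(score >= s) for every attainable integer score, by enumerating
    all 4^L background words (L <= 8 keeps this tractable)."""
    L = int_matrix.shape[1]
    mass: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=L):
        s = int(sum(int_matrix[b, i] for i, b in enumerate(word)))
        p = float(np.prod([background[b] for b in word]))
        mass[s] = mass.get(s, 0.0) + p
    sf = {}
    acc = 0.0
    for s in sorted(mass, reverse=True):
        acc += mass[s]
        sf[s] = acc
    return sf


def brute_force_occurrences(
    seq: str,
    int_plus: np.ndarray,
    int_minus: np.ndarray,
    background: np.ndarray,
    p_threshold: float,
) -> set:
    """(start, end, strand) of all windows with enumeration p <= threshold."""
    L = int_plus.shape[1]
    enc = [("ACGT".find(c) if c in "ACGT" else 4) for c in seq.upper()]
    hits = set()
    for strand, mat in (("+", int_plus), ("-", int_minus)):
        sf = enumeration_pvalues(mat, background)
        padded = np.vstack([mat, np.zeros(L, dtype=mat.dtype)])
        for i in range(len(seq) - L + 1):
            s = int(sum(padded[enc[i + k], k] for k in range(L)))
            # p-value of s: smallest sf entry at a score <= s
            p = min((v for k, v in sf.items() if k <= s), default=1.0)
            if p <= p_threshold:
                hits.add((i, i + L, strand))
    return hits
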