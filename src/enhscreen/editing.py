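"""Per-position mutation profiles of aligned amplicon reads.

After targeting an enhancer with Cas9, the edited locus is PCR-amplified and
sequenced; aligned reads are walked CIGAR operation by operation to count,
at every reference position, how many reads carry a match, a mismatch or a
deletion there, and how many insertions occur at each between-base
coordinate. Only M (alignment match), I (insertion) and D (deletion)
operations are supported — the amplicon use case needs nothing else — and
any other operation is rejected with an explicit error. Insertions are
assigned to the between-base coordinate preceding the inserted bases (SAM
convention). No realignment or indel shifting is performed: the profile
reflects the alignment as given.
"""

from __future__ import annotations

import re as _re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["AlignedRead", "EditProfile", "profile_edits", "edit_fraction"]

_CIGAR_RE = _re.compile(r"(\d+)([A-Z=])")


@dataclass(frozen=True)
class AlignedRead:
    """A read aligned to the amplicon reference (0-based ``ref_start``)."""

    read_id: str
    ref_start: int
    cigar: str
    sequence: str


def parse_cigar(cigar: str, read_id: str = "?") -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) pairs; only M/I/D allowed."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"read '{read_id}': malformed CIGAR {cigar!r}")
    parsed = [(int(n), o) for n, o in ops]
    bad = {o for _, o in parsed} - {"M", "I", "D"}
    if bad:
        raise ValueError(
            f"read '{read_id}': unsupported CIGAR operation(s) {sorted(bad)} "
            "(only M/I/D are accepted)"
        )
    if any(n <= 0 for n, _ in parsed):
        raise ValueError(f"read '{read_id}': zero-length CIGAR operation in {cigar!r}")
    return parsed


@dataclass
class EditProfile:
    """Per-position edit counts over a profiled region.

    ``per_position`` is indexed by reference coordinate with ``match``,
    ``mismatch`` and ``deletion`` columns; ``insertions`` is indexed by the
    between-base coordinates ``region_start..region_end``. ``events`` keeps
    one row per read-level edit (kind, start, end) and ``read_spans`` the
    reference interval covered by each read, which together support
    read-level summaries such as :func:`edit_fraction`.
    """

    region: tuple[int, int]
    per_position: pd.DataFrame
    insertions: pd.Series
    events: pd.DataFrame
    read_spans: pd.DataFrame
    total_reads: int

    def __add__(self, other: "EditProfile") -> "EditProfile":
        if self.region != other.region:
            raise ValueError("profiles cover different regions")
        return EditProfile(
            region=self.region,
            per_position=self.per_position + other.per_position,
            insertions=self.insertions + other.insertions,
            events=pd.concat([self.events, other.events], ignore_index=True),
            read_spans=pd.concat([self.read_spans, other.read_spans], ignore_index=True),
            total_reads=self.total_reads + other.total_reads,
        )


def profile_edits(
    reads: Iterable[AlignedRead] | Sequence,
    reference: str,
    region: tuple[int, int] | None = None,
) -> EditProfile:
    """Count matches, mismatches, deletions and insertions per position.

    Walks each read's CIGAR against ``reference``: M compares bases (an
    ambiguous base counts as mismatch), D increments the deletion count at
    every deleted reference position, I increments the insertion count at
    the preceding between-base coordinate. Counting is restricted to
    ``region`` (default: the whole reference). Alignments running past the
    reference raise an error naming the read.
    """
    if region is None:
        region = (0, len(reference))
    rs, re_ = int(region[0]), int(region[1])
    if not (0 <= rs < re_ <= len(reference)):
        raise ValueError(f"region {region} outside reference of length {len(reference)}")
    ref = reference.upper()
    n = re_ - rs
    match = np.zeros(n, dtype=np.int64)
    mismatch = np.zeros(n, dtype=np.int64)
    deletion = np.zeros(n, dtype=np.int64)
    insertion = np.zeros(n + 1, dtype=np.int64)
    events = []
    spans = []
    total = 0

    for read in reads:
        if not isinstance(read, AlignedRead):
            read = AlignedRead(*read)
        total += 1
        ops = parse_cigar(read.cigar, read.read_id)
        consumed = sum(ln for ln, op in ops if op in ("M", "I"))
        if consumed != len(read.sequence):
            raise ValueError(
                f"read '{read.read_id}': CIGAR consumes {consumed} read bases "
                f"but sequence has {len(read.sequence)}"
            )
        rpos = read.ref_start
        qpos = 0
        seq = read.sequence.upper()
        for ln, op in ops:
            if op == "M":
                if rpos + ln > len(ref):
                    raise ValueError(f"read '{read.read_id}': alignment exceeds reference")
                for k in range(ln):
                    p = rpos + k
                    if rs <= p < re_:
                        base = seq[qpos + k]
                        if base == ref[p]:
                            match[p - rs] += 1
                        else:
                            mismatch[p - rs] += 1
                            events.append((read.read_id, "mismatch", p, p + 1))
                rpos += ln
                qpos += ln
            elif op == "D":
                if rpos + ln > len(ref):
                    raise ValueError(f"read '{read.read_id}': alignment exceeds reference")
                lo, hi = max(rpos, rs), min(rpos + ln, re_)
                if lo < hi:
                    deletion[lo - rs:hi - rs] += 1
                events.append((read.read_id, "deletion", rpos, rpos + ln))
                rpos += ln
            else:  # I
                if rs <= rpos <= re_:
                    insertion[rpos - rs] += 1
                events.append((read.read_id, "insertion", rpos, rpos))
                qpos += ln
        spans.append((read.read_id, read.ref_start, rpos))

    per_position = pd.DataFrame(
        {"match": match, "mismatch": mismatch, "deletion": deletion},
        index=pd.RangeIndex(rs, re_, name="position"),
    )
    return EditProfile(
        region=(rs, re_),
        per_position=per_position,
        insertions=pd.Series(insertion, index=pd.RangeIndex(rs, re_ + 1), name="insertions"),
        events=pd.DataFrame(events, columns=["read_id", "kind", "start", "end"]),
        read_spans=pd.DataFrame(spans, columns=["read_id", "ref_start", "ref_end"]),
        total_reads=total,
    )


def edit_fraction(profile: EditProfile, window: tuple[int, int]) -> float:
    """Fraction of window-covering reads carrying at least one edit there.

    A mismatch touches the window when its position lies inside it; a
    deletion when its reference interval overlaps it; an insertion when its
    between-base coordinate lies at or inside the window edges. Raises if no
    read covers the window.
    """
    ws, we = int(window[0]), int(window[1])
    if not (profile.region[0] <= ws < we <= profile.region[1]):
        raise ValueError(f"window {window} outside profiled region {profile.region}")
    spans = profile.read_spans
    covering = spans[(spans["ref_start"] < we) & (spans["ref_end"] > ws)]
    if covering.empty:
        raise ValueError(f"no read covers window {window}")

    ev = profile.events
    if ev.empty:
        return 0.0
    mm = (ev["kind"] == "mismatch") & (ev["start"] >= ws) & (ev["start"] < we)
    dl = (ev["kind"] == "deletion") & (ev["start"] < we) & (ev["end"] > ws)
    ins = (ev["kind"] == "insertion") & (ev["start"] >= ws) & (ev["start"] <= we)
    edited = set(ev[mm | dl | ins]["read_id"]) & set(covering["read_id"])
    return len(edited) / len(covering)
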