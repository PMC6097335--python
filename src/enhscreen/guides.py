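"""SpCas9 sgRNA design: guides whose predicted cut disrupts a motif.

Geometry (all coordinates 0-based; cut positions are between-base):

* A plus-strand PAM is an ``NGG`` trinucleotide occupying ``[p, p+3)`` on
  the top strand; the 20-nt protospacer is ``[p-20, p)`` and the blunt cut
  falls 3 nt 5' of the PAM, between protospacer positions 17 and 18, i.e.
  at between-base coordinate ``p - 3``.
* A minus-strand PAM reads ``NGG`` on the bottom strand, i.e. ``CCN`` on
  the top strand at ``[p, p+3)``; the protospacer is ``[p+3, p+23)``
  (reverse-complemented) and the cut falls at between-base coordinate
  ``p + 6``.

A guide is designable for a motif occurrence ``[s, e)`` when its cut
coordinate lies in the inclusive window ``[s - margin, e + margin]``
(margin 5 by default): the cut lands within the motif or up to ``margin``
bases from its edges. The signed ``offset`` is 0 when the cut is inside the
motif (between-base coordinates ``s..e``), negative when upstream of the
5' edge and positive when downstream of the 3' edge.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from ._util import revcomp

__all__ = ["find_pams", "cut_site", "designable_guides", "build_library", "GuideLibrary"]

logger = logging.getLogger(__name__)

GUIDE_COLUMNS = [
    "guide_id", "re_id", "motif_id", "chrom", "strand",
    "spacer", "pam", "pam_start", "cut_pos", "offset",
]


def find_pams(sequence: str, offset: int = 0) -> pd.DataFrame:
    """All NGG PAM sites on both strands of ``sequence``.

    Plus-strand sites match ``NGG`` on the given sequence; minus-strand
    sites match ``CCN`` on the given sequence (``NGG`` on the reverse
    strand). ``offset`` shifts reported positions into genome coordinates.
    Returns a DataFrame with ``pam_start`` (start of the 3-mer) and
    ``strand``, ordered by position then strand.
    """
    seq = sequence.upper()
    rows = []
    for i in range(len(seq) - 2):
        if seq[i + 1] == "G" and seq[i + 2] == "G":
            rows.append((offset + i, "+"))
        if seq[i] == "C" and seq[i + 1] == "C":
            rows.append((offset + i, "-"))
    return pd.DataFrame(rows, columns=["pam_start", "strand"])


def cut_site(pam_start: int, strand: str) -> int:
    """Predicted blunt-cut between-base coordinate for a PAM site.

    The cut occurs 3 nt 5' of the PAM on the guide's strand: ``p - 3`` for a
    plus-strand PAM starting at ``p``, ``p + 6`` for a minus-strand PAM.
    """
    if strand == "+":
        return pam_start - 3
    if strand == "-":
        return pam_start + 6
    raise ValueError(f"invalid strand {strand!r}")


def _cut_offset(cut: int, motif_start: int, motif_end: int) -> int:
    """Signed distance from a between-base cut to the nearest motif edge."""
    if cut < motif_start:
        return cut - motif_start
    if cut > motif_end:
        return cut - motif_end
    return 0


def designable_guides(
    occ: Mapping,
    genome: Mapping[str, str],
    margin: int = 5,
    spacer_len: int = 20,
) -> pd.DataFrame:
    """Candidate guides whose cut lies within ``margin`` of a motif occurrence.

    ``occ`` needs ``chrom``, ``start``, ``end`` (and optionally ``motif_id``,
    ``re_id``). Candidates without enough flanking sequence for a full
    spacer are skipped with a logged warning. Inclusive margin on both sides.
    """
    chrom = occ["chrom"]
    seq = genome[chrom]
    s, e = int(occ["start"]), int(occ["end"])
    # PAM starts that could place a cut in [s-margin, e+margin]
    lo = max(0, s - margin - 6)
    hi = min(len(seq), e + margin + 6)
    pams = find_pams(seq[lo:hi], offset=lo)

    rows = []
    for _, pam in pams.iterrows():
        p, strand = int(pam["pam_start"]), pam["strand"]
        cut = cut_site(p, strand)
        if not (s - margin <= cut <= e + margin):
            continue
        if cut < 0 or cut > len(seq):
            continue
        if strand == "+":
            sp_lo, sp_hi = p - spacer_len, p
            if sp_lo < 0 or p + 3 > len(seq):
                logger.warning("skipping PAM at %s:%d:+ — insufficient flank for spacer", chrom, p)
                continue
            spacer = seq[sp_lo:sp_hi].upper()
            pam_seq = seq[p:p + 3].upper()
        else:
            sp_lo, sp_hi = p + 3, p + 3 + spacer_len
            if sp_hi > len(seq) or p < 0:
                logger.warning("skipping PAM at %s:%d:- — insufficient flank for spacer", chrom, p)
                continue
            spacer = revcomp(seq[sp_lo:sp_hi].upper())
            pam_seq = revcomp(seq[p:p + 3].upper())
        rows.append((
            occ.get("re_id", ""), occ.get("motif_id", ""), chrom, strand,
            spacer, pam_seq, p, cut, _cut_offset(cut, s, e),
        ))
    df = pd.DataFrame(rows, columns=GUIDE_COLUMNS[1:])
    df.insert(0, "guide_id", [f"{chrom}:{c}:{st}" for c, st in zip(df["cut_pos"], df["strand"])])
    return df


@dataclass
class GuideLibrary:
    """Designed guide table plus summary statistics and duplicate records."""

    guides: pd.DataFrame
    stats: dict = field(default_factory=dict)
    duplicates: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_library(
    res: pd.DataFrame,
    occs: pd.DataFrame,
    genome: Mapping[str, str],
    margin: int = 5,
    spacer_len: int = 20,
) -> GuideLibrary:
    """Assemble the guide library over all motif occurrences.

    Takes the union of :func:`designable_guides` over occurrences (sorted by
    genomic position for determinism), collapses duplicate spacer sequences
    library-wide (first occurrence kept, cross-references recorded in
    ``duplicates``), and computes summary statistics. A motif or RE is
    "targetable" iff at least one guide survives.
    """
    sort_keys = [c for c in ("chrom", "start", "strand") if c in occs.columns]
    occs_sorted = occs.sort_values(sort_keys, kind="stable")
    all_guides = []
    for _, occ in occs_sorted.iterrows():
        g = designable_guides(occ, genome, margin=margin, spacer_len=spacer_len)
        all_guides.append(g)
    guides = (
        pd.concat(all_guides, ignore_index=True)
        if all_guides else pd.DataFrame(columns=GUIDE_COLUMNS)
    )

    dup_rows = []
    if len(guides):
        seen: dict[str, str] = {}
        keep = []
        for i, row in guides.iterrows():
            if row["spacer"] in seen:
                keep.append(False)
                dup_rows.append((row["spacer"], seen[row["spacer"]],
                                 row["motif_id"], row["re_id"]))
            else:
                seen[row["spacer"]] = f"sg{len(seen):05d}"
                keep.append(True)
        guides = guides[pd.Series(keep, index=guides.index)].reset_index(drop=True)
        guides["guide_id"] = [f"sg{i:05d}" for i in range(len(guides))]
    duplicates = pd.DataFrame(
        dup_rows, columns=["spacer", "kept_guide_id", "dropped_motif_id", "dropped_re_id"]
    )

    per_motif = Counter(guides["motif_id"]) if len(guides) else Counter()
    stats = {
        "n_res_input": int(len(res)),
        "n_motifs_input": int(len(occs)),
        "n_res_targetable": int(guides["re_id"].nunique()) if len(guides) else 0,
        "n_motifs_targetable": int(len(per_motif)),
        "n_guides": int(len(guides)),
        "guides_per_motif": dict(Counter(per_motif.values())),
        "n_duplicate_spacers": int(len(duplicates)),
    }
    return GuideLibrary(guides=guides, stats=stats, duplicates=duplicates)
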