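"""Readers and writers for the pipeline's on-disk formats.

Plain-text formats throughout: FASTA genomes (Bio.SeqIO), BED6 interval
tables, TSV matrices with a header row of sample ids plus a sample-metadata
sidecar, JASPAR/MEME-minimal PWMs (Bio.motifs), SAM alignments (pysam) or a
plain TSV of (read_id, ref_start, cigar, sequence). All genomic coordinates
on disk are 0-based half-open (BED convention).
"""

from __future__ import annotations

import importlib.resources
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .editing import AlignedRead
from .motifs import PWM

__all__ = [
    "read_fasta", "write_fasta",
    "read_tsv", "write_tsv",
    "read_bed6", "write_bed6",
    "read_matrix", "read_samples",
    "load_pwm", "default_ap1_pwm",
    "read_sam_reads", "read_reads_tsv",
]


# -- FASTA ----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a {name: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- TSV tables -----------------------------------------------------------

def read_tsv(
    path: str | Path,
    required: Sequence[str] = (),
    index_col=None,
) -> pd.DataFrame:
    """Read a TSV table, checking required columns (error names file+column)."""
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    for col in required:
        if col not in df.columns and col != df.index.name:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Count/expression matrix: first column is the row id, rest are samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no sample columns")
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    """Sample metadata sidecar (sample_id, condition, replicate)."""
    df = read_tsv(path, required=("sample_id", "condition", "replicate"))
    return df.set_index("sample_id")


# -- BED6 -----------------------------------------------------------------

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6 file from a DataFrame holding the six BED columns."""
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    if df["strand"].isna().any():
        raise ValueError(f"{path}: not a BED6 file (missing strand column)")
    return df


def tus_to_bed6(tus: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": tus["chrom"], "start": tus["start"], "end": tus["end"],
        "name": tus["tu_id"], "score": 0, "strand": tus["strand"],
    })


def bed6_to_tus(bed: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "tu_id": bed["name"], "chrom": bed["chrom"],
        "start": bed["start"], "end": bed["end"], "strand": bed["strand"],
    })


def res_to_bed6(res: pd.DataFrame) -> pd.DataFrame:
    """REs as BED6 over the scan interval; score 1 if induced else 0."""
    start = res["scan_start"] if "scan_start" in res else res["core_start"]
    end = res["scan_end"] if "scan_end" in res else res["core_end"]
    score = res["induced"].astype(int) if "induced" in res else 0
    return pd.DataFrame({
        "chrom": res["chrom"], "start": start, "end": end,
        "name": res["re_id"], "score": score, "strand": ".",
    })


# -- PWM ------------------------------------------------------------------

def _pwm_from_bio_motif(m, pseudocount: float = 0.01) -> PWM:
    counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
    name = m.name or getattr(m, "matrix_id", None) or "motif"
    return PWM.from_counts(str(name), counts, pseudocount=pseudocount)


def load_pwm(path: str | Path, fmt: str | None = None, pseudocount: float = 0.01) -> PWM:
    """Load a PWM from a JASPAR (counts) or MEME-minimal file.

    The format is sniffed when not given: JASPAR files start with '>',
    MEME-minimal files with 'MEME version'.
    """
    text = Path(path).read_text()
    if fmt is None:
        fmt = "jaspar" if text.lstrip().startswith(">") else "minimal"
    if fmt == "jaspar":
        m = bio_motifs.read(StringIO(text), "jaspar")
        return _pwm_from_bio_motif(m, pseudocount)
    if fmt in ("minimal", "meme"):
        parsed = bio_motifs.parse(StringIO(text), "minimal")
        m = parsed[0]
        probs = np.array([list(m.pwm[b]) for b in "ACGT"], dtype=float)
        bg = np.array([m.background[b] for b in "ACGT"], dtype=float)
        return PWM(str(m.name or "motif"), probs, background=bg, pseudocount=pseudocount)
    raise ValueError(f"unknown PWM format {fmt!r}")


def default_ap1_pwm(pseudocount: float = 0.01) -> PWM:
    """The packaged AP-1 PWM (synthetic, consensus-derived; see data file)."""
    ref = importlib.resources.files("enhscreen.data") / "ap1_consensus_synthetic.jaspar"
    with importlib.resources.as_file(ref) as path:
        return load_pwm(path, fmt="jaspar", pseudocount=pseudocount)


# -- aligned reads --------------------------------------------------------

def read_sam_reads(path: str | Path) -> list[AlignedRead]:
    """Aligned reads from a SAM file (mapped reads only)."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.cigarstring is None:
                continue
            reads.append(AlignedRead(
                read_id=aln.query_name,
                ref_start=aln.reference_start,
                cigar=aln.cigarstring,
                sequence=aln.query_sequence or "",
            ))
    return reads


def read_reads_tsv(path: str | Path) -> list[AlignedRead]:
    """Aligned reads from a plain TSV (read_id, ref_start, cigar, sequence)."""
    df = read_tsv(path, required=("read_id", "ref_start", "cigar", "sequence"))
    return [
        AlignedRead(str(r.read_id), int(r.ref_start), str(r.cigar), str(r.sequence))
        for r in df.itertuples()
    ]
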