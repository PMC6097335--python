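"""Synthetic genomes, TU count tables and screen counts with planted truth.

Every downstream stage of the pipeline is testable without any external
download because this module generates its inputs with known ground truth:

* a random genome carrying enhancer loci, each with a divergent TU pair and
  exactly one planted AP-1-consensus motif instance between the two start
  sites; "designable" motifs get an NGG PAM on each strand whose predicted
  cut falls inside the motif, while for non-designable motifs every PAM
  whose cut would land within the margin is ablated by substitution;
* decoy loci (unidirectional TUs, convergent opposite-strand pairs, and
  divergent pairs separated beyond the pairing window) that give the
  enhancer caller a specificity surface;
* negative-binomial TU counts with a planted induction fold at induced
  loci, in paired control/induced replicates;
* multinomial pooled-screen counts with planted guide enrichment.

The negative binomial is parameterized by its mean and the extra-Poisson
(biological) coefficient of variation ``nb_dispersion``:
``var = mu + (nb_dispersion * mu)**2``. All randomness flows from
``SimulationConfig.seed``; the same config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import check_dna, revcomp
from .guides import cut_site, find_pams

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "generate_genome",
    "generate_tu_counts",
    "generate_screen_counts",
    "plant_screen_truth",
    "evaluate_enhancer_calls",
]

CHROM = "chr1"
LOCUS_SLOT = 3000        # bp reserved per planted locus
TU_LENGTH = 1000         # bp per synthetic TU
TSS_HALF_SEPARATION = 150  # bp from locus center to each start site

LOCUS_COLUMNS = [
    "locus_id", "kind", "chrom", "center", "induced",
    "motif_start", "motif_end", "motif_strand", "designable",
    "plus_tu", "minus_tu",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults mirror the experimental setting the pipeline is built for:
    ~4-fold eRNA induction at stress-activated enhancers measured in
    biological duplicates, 62% of motif-bearing elements designable, and a
    4-replicate pooled screen with ~1000x guide coverage and 4-fold
    enrichment of senescence-bypass guides.
    """

    genome_length: int | None = None  # auto: LOCUS_SLOT per planted locus
    n_enhancers: int = 200
    n_induced: int = 20
    motif_consensus: str = "TGACTCA"  # AP-1 / TRE heptamer
    designable_fraction: float = 0.62
    induction_fold: float = 4.0
    nb_dispersion: float = 0.1  # biological CV: var = mu + (cv*mu)^2
    base_mean_reads: float = 200.0
    baseline_log_sd: float = 1.0  # per-TU spread of baseline expression (ln scale)
    n_replicates: int = 2
    n_decoy_unidirectional: int = 40
    n_decoy_convergent: int = 20
    n_decoy_divergent_far: int = 20
    decoy_separation: int = 900  # TSS separation of far divergent decoys
    n_hit_res: int = 3
    n_guides_per_hit: int = 2
    guide_effect_fold: float = 4.0
    n_screen_replicates: int = 4
    reads_per_guide: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_induced > self.n_enhancers:
            raise ValueError("n_induced must not exceed n_enhancers")
        if not 0 <= self.designable_fraction <= 1:
            raise ValueError("designable_fraction must lie in [0, 1]")
        for name in ("induction_fold", "guide_effect_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_enhancers > 0:
            check_dna(self.motif_consensus, "motif_consensus")
            if len(self.motif_consensus) < 4:
                raise ValueError("motif_consensus must be at least 4 bp")
        if self.n_replicates < 1 or self.n_screen_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        needed = LOCUS_SLOT * max(1, self.n_loci)
        if self.genome_length is None:
            self.genome_length = needed
        elif self.genome_length < needed:
            raise ValueError(
                f"genome_length={self.genome_length} cannot place {self.n_loci} "
                f"non-overlapping loci with flanks (needs >= {needed} = "
                f"{LOCUS_SLOT} bp per locus)"
            )

    @property
    def n_loci(self) -> int:
        return (
            self.n_enhancers + self.n_decoy_unidirectional
            + self.n_decoy_convergent + self.n_decoy_divergent_far
        )


@dataclass
class TruthSet:
    """Planted ground truth: locus table and (optionally) enriched guides."""

    loci: pd.DataFrame
    enriched_guides: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["guide_id", "effect_fold"])
    )

    @property
    def enhancer_loci(self) -> pd.DataFrame:
        return self.loci[self.loci["kind"] == "enhancer"]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _designability_margin_cuts(seq: str, s: int, e: int, margin: int) -> int:
    """Number of PAMs whose predicted cut falls within [s-margin, e+margin]."""
    lo = max(0, s - margin - 6)
    hi = min(len(seq), e + margin + 6)
    pams = find_pams(seq[lo:hi], offset=lo)
    n = 0
    for _, pam in pams.iterrows():
        cut = cut_site(int(pam["pam_start"]), pam["strand"])
        if s - margin <= cut <= e + margin:
            n += 1
    return n


def _plant_motif_site(
    seq: bytearray,
    s: int,
    e: int,
    motif: str,
    designable: bool,
    margin: int = 5,
) -> None:
    """Write a motif instance and arrange PAM geometry around it in place.

    Designable sites get one plus-strand PAM (cut at ``e-1``, inside the
    motif) and one minus-strand PAM (cut at ``s+2``); every other NGG/CCN
    whose cut could land within the margin is ablated by substituting the
    second base of the offending GG/CC dinucleotide with T.
    """
    seq[s:e] = motif.encode()
    protected = set(range(s, e))
    if designable:
        # plus-strand PAM 'AGG' at [e+2, e+5): cut = (e+2) - 3 = e - 1
        seq[e + 2] = ord("A")
        seq[e + 3] = ord("G")
        seq[e + 4] = ord("G")
        seq[e + 5] = ord("T")  # block an accidental GG at (e+4, e+5)
        # minus-strand PAM 'CCA' at [s-4, s-1): cut = (s-4) + 6 = s + 2
        seq[s - 5] = ord("T")  # block an accidental CC at (s-5, s-4)
        seq[s - 4] = ord("C")
        seq[s - 3] = ord("C")
        seq[s - 2] = ord("A")
        protected |= set(range(s - 5, s - 1)) | set(range(e + 2, e + 6))

    zone_lo = max(0, s - margin - 9)
    zone_hi = min(len(seq) - 1, e + margin + 8)
    for i in range(zone_lo, zone_hi):
        pair = bytes(seq[i:i + 2])
        if pair in (b"GG", b"CC"):
            if i in protected and i + 1 in protected:
                continue
            target = i + 1 if i + 1 not in protected else i
            seq[target] = ord("T")


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], TruthSet]:
    """Random genome with planted enhancer motifs and decoy loci.

    Background sequence is uniform-random ACGT. Each enhancer locus carries
    exactly one planted motif instance (the consensus or its reverse
    complement, chosen at random) midway between the future TU start sites.
    Planted designability is verified against the PAM/cut geometry after
    construction; a violated constraint raises RuntimeError naming it.
    """
    rng = _rng(config, 0)
    motif = config.motif_consensus.upper()
    L = len(motif)
    seq = bytearray(
        np.frombuffer(b"ACGT", dtype=np.uint8)[
            rng.integers(0, 4, config.genome_length)
        ].tobytes()
    )

    kinds = (
        ["enhancer"] * config.n_enhancers
        + ["unidirectional"] * config.n_decoy_unidirectional
        + ["convergent"] * config.n_decoy_convergent
        + ["far"] * config.n_decoy_divergent_far
    )
    induced_idx = set(
        rng.choice(config.n_enhancers, size=config.n_induced, replace=False).tolist()
    ) if config.n_enhancers else set()
    n_designable = int(round(config.designable_fraction * config.n_enhancers))
    designable_idx = set(
        rng.choice(config.n_enhancers, size=n_designable, replace=False).tolist()
    ) if config.n_enhancers else set()

    rows = []
    enh_counter = 0
    for i, kind in enumerate(kinds):
        center = LOCUS_SLOT * i + LOCUS_SLOT // 2
        locus_id = f"L{i:05d}"
        if kind != "enhancer":
            minus_tu = "" if kind == "unidirectional" else f"TU{i:05d}m"
            rows.append((locus_id, kind, CHROM, center, False,
                         pd.NA, pd.NA, pd.NA, False, f"TU{i:05d}p", minus_tu))
            continue
        s = center - L // 2
        e = s + L
        strand = "+" if rng.random() < 0.5 else "-"
        planted = motif if strand == "+" else revcomp(motif)
        designable = enh_counter in designable_idx
        _plant_motif_site(seq, s, e, planted, designable)
        rows.append((
            locus_id, kind, CHROM, center, enh_counter in induced_idx,
            s, e, strand, designable, f"TU{i:05d}p", f"TU{i:05d}m",
        ))
        enh_counter += 1

    genome = {CHROM: seq.decode()}
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)

    # verify planted designability against the actual PAM/cut geometry
    for _, row in loci[loci["kind"] == "enhancer"].iterrows():
        n_cuts = _designability_margin_cuts(
            genome[CHROM], int(row["motif_start"]), int(row["motif_end"]), margin=5
        )
        if row["designable"] and n_cuts == 0:
            raise RuntimeError(
                f"{row['locus_id']}: designable motif ended up without a PAM "
                "placing a cut within the margin"
            )
        if not row["designable"] and n_cuts > 0:
            raise RuntimeError(
                f"{row['locus_id']}: non-designable motif retains {n_cuts} PAM(s) "
                "with a cut within the margin (ablation failed)"
            )
    return genome, TruthSet(loci=loci)


def _locus_tus(row: pd.Series, decoy_separation: int) -> list[tuple]:
    """TU intervals for one locus: (tu_id, chrom, start, end, strand)."""
    c = int(row["center"])
    kind = row["kind"]
    half = TSS_HALF_SEPARATION
    if kind in ("enhancer",):
        return [
            (row["minus_tu"], row["chrom"], c - half - TU_LENGTH + 1, c - half + 1, "-"),
            (row["plus_tu"], row["chrom"], c + half, c + half + TU_LENGTH, "+"),
        ]
    if kind == "far":
        h = decoy_separation // 2
        return [
            (row["minus_tu"], row["chrom"], c - h - TU_LENGTH + 1, c - h + 1, "-"),
            (row["plus_tu"], row["chrom"], c + h, c + h + TU_LENGTH, "+"),
        ]
    if kind == "convergent":
        # opposite strands, close start sites, transcribing toward each other
        return [
            (row["plus_tu"], row["chrom"], c - half, c - half + TU_LENGTH, "+"),
            (row["minus_tu"], row["chrom"], c + half - TU_LENGTH + 1, c + half + 1, "-"),
        ]
    if kind == "unidirectional":
        return [(row["plus_tu"], row["chrom"], c - TU_LENGTH // 2, c + TU_LENGTH // 2, "+")]
    raise ValueError(f"unknown locus kind {kind!r}")


def _draw_counts(rng: np.random.Generator, means: np.ndarray, cv: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + (cv*mu)^2 (Poisson when cv=0)."""
    if cv <= 0:
        return rng.poisson(means)
    r = 1.0 / cv**2
    p = r / (r + means)
    return rng.negative_binomial(r, p)


def generate_tu_counts(
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TU table, count matrix and sample table for the planted loci.

    Each enhancer locus yields a divergent plus/minus TU pair whose start
    sites are ``2 * TSS_HALF_SEPARATION`` apart; induced loci have both
    mates' negative-binomial means multiplied by ``induction_fold`` in the
    induced-condition samples. Decoy loci contribute unidirectional TUs,
    convergent pairs and over-separated divergent pairs at baseline levels.
    """
    rng = _rng(config, 1)
    tu_rows = []
    induced_tus: set[str] = set()
    for _, row in truth.loci.iterrows():
        tus = _locus_tus(row, config.decoy_separation)
        tu_rows.extend(tus)
        if bool(row["induced"]):
            induced_tus.update(t[0] for t in tus)
    tus = pd.DataFrame(tu_rows, columns=["tu_id", "chrom", "start", "end", "strand"])

    samples = pd.DataFrame(
        [
            (f"{cond}_{r}", cond, r)
            for cond in ("control", "induced")
            for r in range(1, config.n_replicates + 1)
        ],
        columns=["sample_id", "condition", "replicate"],
    ).set_index("sample_id")

    # per-TU baseline spans orders of magnitude, as real nascent-transcription
    # levels do; this is what makes cross-sample quantile normalization safe
    base = config.base_mean_reads * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=len(tus))
    )
    is_induced_tu = tus["tu_id"].isin(induced_tus).to_numpy()
    counts = {}
    for sample_id, meta in samples.iterrows():
        means = base.copy()
        if meta["condition"] == "induced":
            means[is_induced_tu] *= config.induction_fold
        counts[sample_id] = _draw_counts(rng, means, config.nb_dispersion)
    matrix = pd.DataFrame(counts, index=tus["tu_id"])
    return tus, matrix, samples


def plant_screen_truth(
    library,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Choose enriched guides: ``n_guides_per_hit`` guides in each of
    ``n_hit_res`` randomly chosen REs that carry enough guides."""
    guides = getattr(library, "guides", library)
    if len(guides) == 0:
        raise ValueError("cannot plant screen truth in an empty library")
    rng = rng if rng is not None else _rng(config, 3)
    sizes = guides.groupby("re_id").size()
    eligible = sorted(sizes[sizes >= config.n_guides_per_hit].index)
    if len(eligible) < config.n_hit_res:
        raise ValueError(
            f"only {len(eligible)} REs carry >= {config.n_guides_per_hit} guides; "
            f"cannot plant {config.n_hit_res} hit REs"
        )
    chosen = rng.choice(len(eligible), size=config.n_hit_res, replace=False)
    picked = []
    for idx in sorted(chosen.tolist()):
        re_id = eligible[idx]
        members = guides[guides["re_id"] == re_id]["guide_id"].tolist()
        take = rng.choice(len(members), size=config.n_guides_per_hit, replace=False)
        picked.extend(members[i] for i in sorted(take.tolist()))
    return pd.DataFrame(
        {"guide_id": picked, "effect_fold": config.guide_effect_fold}
    )


def generate_screen_counts(
    library,
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial pooled-screen counts with planted guide enrichment.

    Per replicate, a control sample draws counts around equal guide
    representation and the paired induced sample draws with enriched guides'
    probabilities multiplied by their planted effect fold. Total depth is
    ``reads_per_guide * n_guides`` per sample.
    """
    guides = getattr(library, "guides", library)
    if len(guides) == 0:
        raise ValueError("cannot simulate a screen for an empty guide library")
    rng = _rng(config, 2)
    guide_ids = guides["guide_id"].tolist()
    effects = pd.Series(1.0, index=guide_ids)
    for _, row in truth.enriched_guides.iterrows():
        if row["guide_id"] in effects.index:
            effects[row["guide_id"]] = float(row["effect_fold"])

    total = int(round(config.reads_per_guide * len(guide_ids)))
    p_control = np.full(len(guide_ids), 1.0 / len(guide_ids))
    p_induced = effects.to_numpy() / effects.sum()

    counts = {}
    rows = []
    for r in range(1, config.n_screen_replicates + 1):
        counts[f"control_{r}"] = rng.multinomial(total, p_control)
        counts[f"induced_{r}"] = rng.multinomial(total, p_induced)
        rows.append((f"control_{r}", "control", r))
        rows.append((f"induced_{r}", "induced", r))
    samples = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate"])
    samples = samples.set_index("sample_id")
    matrix = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"))
    return matrix[sorted(matrix.columns)], samples


def evaluate_enhancer_calls(
    called_res: pd.DataFrame,
    truth: TruthSet,
) -> tuple[float, float]:
    """(sensitivity, false-discovery rate) of induced-RE calls vs truth.

    An induced call is matched to a planted induced enhancer locus through
    its unordered TU-id pair.
    """
    truth_pairs = {
        frozenset((row["plus_tu"], row["minus_tu"]))
        for _, row in truth.enhancer_loci[truth.enhancer_loci["induced"]].iterrows()
    }
    called = called_res[called_res["induced"]] if "induced" in called_res else called_res
    called_pairs = {
        frozenset((row["plus_tu"], row["minus_tu"])) for _, row in called.iterrows()
    }
    tp = len(called_pairs & truth_pairs)
    sensitivity = tp / len(truth_pairs) if truth_pairs else float("nan")
    fdr = (len(called_pairs) - tp) / len(called_pairs) if called_pairs else 0.0
    return sensitivity, fdr


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with no planted induction (induction_fold = 1)."""
    return replace(config, induction_fold=1.0)
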