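# enhscreen

Discovery of oncogenic-stress-induced enhancers from bidirectional eRNA
signal, design of a CRISPR-Cas9 library that cuts inside their AP-1 binding
motifs, and scoring of a pooled senescence-bypass screen — as a tested,
reusable Python library with a synthetic-data module that plants ground
truth for every stage.

## Who this is for

Functional-genomics groups mapping which regulatory elements a cell needs
to enter oncogene-induced senescence (OIS). Active enhancers transcribe
short eRNAs divergently from two closely spaced start sites; changes in
eRNA output track changes in enhancer activity, so nascent-RNA (GRO-seq)
counts over transcriptional units (TUs) give a genome-wide, quantitative
enhancer readout. Elements activated by oncogenic stress can then be
perturbed in situ: sgRNAs are designed so the Cas9 cut destroys the
transcription-factor motif that drives the element, and guides whose
integration lets cells keep proliferating under oncogenic stress become
enriched in a pooled screen.

## The method

1. **Expression.** TU counts are kept when covered by ≥ 20 reads in at
   least one sample, quantile-normalized across samples, and converted to
   per-replicate log2 fold changes with a floor of 10 on expression levels:
   FC_r = log2(max(I_r, 10) / max(C_r, 10)).
2. **Regulatory elements.** Opposite-strand TUs whose 5′ start sites lie
   ≤ 800 bp apart and that transcribe away from each other form an RE;
   an RE is *induced* when both mates rise ≥ 2-fold in every replicate.
3. **Motifs.** The region between the two start sites ± 200 bp is scanned
   with an AP-1 position weight matrix; a window is an occurrence when its
   exact null p-value (dynamic programming over the discretized log-odds
   score distribution) is ≤ 1e-4. Over-representation versus same-length
   immediate flanks is a one-sided Fisher's exact test.
4. **Guide design.** For every NGG PAM near a motif, the blunt SpCas9 cut
   is placed 3 nt 5′ of the PAM; a guide is kept when the cut falls within
   the motif or ≤ 5 bp from its edges. Duplicate spacers are collapsed
   library-wide.
5. **Screen scoring.** sgRNA counts are normalized to 1 M reads per sample
   and floored at 50; per-replicate log2 enrichment (induced vs control)
   is averaged over replicates and standardized to a library-wide Z score:
   z_g = (m̄_g − μ) / σ. Guide hits exceed a mean-enrichment threshold and
   an RE-level hit is *corroborated* when ≥ 2 distinct hit guides target it.
6. **Editing outcomes.** Aligned amplicon reads are walked CIGAR-op by
   CIGAR-op to count matches, mismatches, deletions per reference position
   and insertions per between-base coordinate.

The `simulate` module generates genomes, TU count tables and screen counts
with planted truth (induced loci, designable motifs, enriched guides), so
every stage is testable end to end without any download.

## Worked example

`examples/` holds one short script per capability. `python
examples/01_call_induced_enhancers.py` simulates 200 divergent enhancer
loci (20 induced 4-fold) plus decoys and runs the calling chain:

```
TUs simulated:        520
REs paired:           199
REs called induced:   20 (planted: 20)
sensitivity / FDR:    1.00 / 0.00
```

All 20 planted induced elements are recovered with no false calls;
decoy TUs (unidirectional, convergent, or 900 bp apart) never pair.
Continuing through motif scanning and guide design
(`examples/02…`, `examples/03…`):

```
motif occurrences:       21 in 20 REs
enrichment:              odds ratio 631.4, one-sided p = 5.51e-14
targetable REs:     12 (60%)
distinct sgRNAs:    26
```

The AP-1 motif concentrates in induced elements rather than their flanks,
and 60% of motif-bearing elements admit a guide whose cut lands within
5 bp of the motif — each typically targeted by 2 guides, one per strand.
`examples/04_score_pooled_screen.py` then recovers all 20 planted enriched
guides above the 1.75 (log2) threshold and flags exactly the 3 elements
carrying two planted guides as corroborated hits.

A thin CLI mirrors the library (`enhscreen simulate | normalize |
call-enhancers | scan-motifs | design-library | simulate-screen |
score-screen | edit-profile`); every stage writes a JSON provenance
sidecar and is byte-reproducible under a fixed seed.

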