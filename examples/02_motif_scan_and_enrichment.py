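"""Scan induced elements for the AP-1 motif and test over-representation.

Each induced RE's scan region (between the two TU start sites, +-200 bp)
is scanned with the packaged AP-1 PWM; windows are reported when their
exact null p-value is <= 1e-4. Flanking sequences of the same length serve
as controls for a one-sided Fisher's exact test.
"""

import pandas as pd

import enhscreen as es
from enhscreen.io import default_ap1_pwm
from enhscreen.motifs import extract_controls, fisher_enrichment
from enhscreen.pipeline import call_induced_elements

config = es.SimulationConfig(seed=3)
genome, truth = es.generate_genome(config)
tus, counts, samples = es.generate_tu_counts(truth, config)
chrom_lengths = {name: len(seq) for name, seq in genome.items()}
res, _ = call_induced_elements(tus, counts, samples, chrom_lengths=chrom_lengths)

induced = res[res["induced"]]
regions = induced.rename(columns={"scan_start": "start", "scan_end": "end"})
regions = regions[["re_id", "chrom", "start", "end"]]

pwm = default_ap1_pwm()
occs = es.scan_occurrences(regions, genome, pwm, p_threshold=1e-4)

controls = []
for _, reg in regions.iterrows():
    flanks = extract_controls((reg["start"], reg["end"]), chrom_lengths[reg["chrom"]])
    for side, iv in flanks.items():
        if iv is not None:
            controls.append({"chrom": reg["chrom"], "start": iv[0], "end": iv[1]})
controls = pd.DataFrame(controls)
ctrl_occs = es.scan_occurrences(controls, genome, pwm, p_threshold=1e-4)

odds, p = fisher_enrichment(
    occs["re_id"].nunique(), len(regions),
    ctrl_occs["re_id"].nunique(), len(controls),
)

print(f"PWM: {pwm.name} (consensus {pwm.consensus}, {pwm.length} bp)")
print(f"induced REs scanned:     {len(regions)}")
print(f"motif occurrences:       {len(occs)} in {occs['re_id'].nunique()} REs")
print(f"control flanks with hit: {ctrl_occs['re_id'].nunique()} / {len(controls)}")
print(f"enrichment:              odds ratio {odds:.1f}, one-sided p = {p:.2e}")
print()
print("A small p-value means AP-1 motif instances concentrate in the induced")
print("elements rather than in their immediate flanks — the signature that")
print("motivates targeting this motif with a CRISPR library.")
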