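"""Design sgRNAs whose predicted Cas9 cut disrupts each AP-1 motif.

For every motif occurrence in an induced element, every NGG PAM (both
strands) is tested: a guide is emitted when the blunt cut 3 nt upstream of
the PAM lands within the motif or up to 5 bp from its edges. Duplicate
spacers are collapsed library-wide.
"""

import enhscreen as es
from enhscreen.io import default_ap1_pwm
from enhscreen.pipeline import call_induced_elements

config = es.SimulationConfig(seed=3)
genome, truth = es.generate_genome(config)
tus, counts, samples = es.generate_tu_counts(truth, config)
res, _ = call_induced_elements(
    tus, counts, samples,
    chrom_lengths={name: len(seq) for name, seq in genome.items()},
)
induced = res[res["induced"]]
regions = induced.rename(columns={"scan_start": "start", "scan_end": "end"})
occs = es.scan_occurrences(
    regions[["re_id", "chrom", "start", "end"]], genome, default_ap1_pwm()
)

library = es.build_library(induced, occs, genome, margin=5, spacer_len=20)

s = library.stats
print(f"input REs:          {s['n_res_input']}")
print(f"motif occurrences:  {s['n_motifs_input']}")
print(f"targetable REs:     {s['n_res_targetable']} "
      f"({100 * s['n_res_targetable'] / max(1, s['n_res_input']):.0f}%)")
print(f"distinct sgRNAs:    {s['n_guides']}")
print(f"guides per motif:   {s['guides_per_motif']}")
print()
print(library.guides.head(4).to_string(index=False))
print()
print("Each guide's cut_pos is the between-base cut coordinate and offset is")
print("its signed distance to the motif edge (0 = cut inside the motif). An")
print("RE is targetable when at least one guide survives; untargetable REs")
print("lack any NGG close enough to place the cut within the 5-bp margin.")
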