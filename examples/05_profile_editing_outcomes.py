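"""Profile Cas9 editing outcomes in amplicon reads around a cut site.

Builds a toy amplicon with reads carrying small deletions/insertions at the
expected cut position (as after targeting an enhancer motif), walks each
CIGAR, and reports per-position mutation counts and the edited fraction in
the motif window.
"""

import enhscreen as es

reference = ("ACGTTGCAAGGTCCATGGAA" "TGACTCA" "GGTACCAGTTCGATCCGGTA")
motif = (20, 27)  # the AP-1 site; Cas9 cut expected inside it

reads = []
for i in range(6):  # unedited reads
    reads.append(es.AlignedRead(f"wt{i}", 0, f"{len(reference)}M", reference))
for i in range(3):  # 2-bp deletion at the cut site
    seq = reference[:22] + reference[24:]
    reads.append(es.AlignedRead(f"del{i}", 0, "22M2D23M", seq))
# 1-bp insertion at the cut site
reads.append(es.AlignedRead("ins0", 0, "22M1I25M", reference[:22] + "T" + reference[22:]))

profile = es.profile_edits(reads, reference)
window = profile.per_position.loc[motif[0]:motif[1] - 1]
print("per-position counts across the motif window:")
print(window.to_string())
print()
print(f"insertions at between-base 22: {int(profile.insertions.loc[22])}")
frac = es.edit_fraction(profile, motif)
print(f"fraction of reads edited within the motif: {frac:.2f}")
print()
print("Deletions are counted at every deleted reference base and insertions")
print("at the between-base coordinate preceding them, so the profile peaks")
print("exactly where Cas9 cut — the readout used to confirm that selected")
print("guides actually disrupt the motif.")
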