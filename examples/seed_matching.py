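"""Extract microRNA seeds and scan a 3'UTR for target sites.

The seed region (nucleotides 2-8 of the mature microRNA) determines the
canonical mRNA target motif: its reverse complement. miR-181's motif
closely resembles the curated binding consensus of the RBP TDP-43, and
miR-340-5p's resembles the U-rich preference of HuR — the kind of shared
sequence preference that puts an RBP and a microRNA on the same stretch
of UTR.
"""

from transinteract import MatureMirna, UtrModel, scan_utr, seed_of, target_motif

for name, mature in [
    ("hsa-miR-181", "AACAUUCAACGCUGUCGGUGAGU"),
    ("hsa-miR-340-5p", "UUAUAAAGCAAUGAGACUGAUU"),
]:
    seed = seed_of(mature)
    motif = target_motif(seed)
    print(f"{name}: mature 5'{mature}3'")
    print(f"  seed (nt 2-8)      5'{seed}3'")
    print(f"  mRNA target motif  5'{motif}3'")

utr = UtrModel("GENE1", "T1", "+", ((0, 40),),
               sequence="ACGCAUGAAUGUCCGGAUACGCUUUAUAGGCAUGAAUGUC")
print("\nScanning a 40-nt UTR for both motifs:")
for mirna_id, mature in [("hsa-miR-181", "AACAUUCAACGCUGUCGGUGAGU"),
                         ("hsa-miR-340-5p", "UUAUAAAGCAAUGAGACUGAUU")]:
    for m in scan_utr(MatureMirna(mirna_id, mature), utr):
        print(f"  {mirna_id} site at [{m.start},{m.end}) = {m.site_motif}")
# Each line is one exact 7-mer seed-complement occurrence; these intervals
# feed the same overlap classification as CLIP-derived RBP sites.
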