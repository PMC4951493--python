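"""Tandem site arrangements and emergent junction motifs.

Two same-orientation 14 bp dyad sites a few base pairs apart create a junction
whose inner arms (GAACA ... TGTTC) can constitute an instance of the
Firmicutes/Actinobacteria LexA motif GAAC-N4-GTTC. The emergent spacer is
gap + 2, so the canonical instance appears at a 2 bp gap only.
"""

from regulonscout import (emergence_spacing, find_tandem_sites, junction_instances,
                          motif_from_consensus, scan_sequence)

site = "TGTTCAGTCGAACA"
promoter = "ATGCATGCAT" + site + "GG" + site + "CCGGAATTGC"

motif = motif_from_consensus("TGTTC-N4-GAACA", 1.9)
hits = scan_sequence(motif, promoter, threshold=0.8 * motif.max_score)
print("site hits at:", [h.position for h in hits])

arrangements = find_tandem_sites(hits, promoter, max_gap=10)
for arr in arrangements:
    print(f"tandem pair: gap={arr.gap}, junction={arr.junction}")
    for inst in junction_instances(arr):
        print(f"  emergent {inst.motif_name} at offset {inst.offset}: {inst.matched}")

print("gaps generating GAAC-N4-GTTC:",
      emergence_spacing("TGTTC-N4-GAACA", "GAAC-N4-GTTC", gaps=range(0, 11)))
# Only gap 2 yields the canonical Firmicutes-type instance; at gaps 0 or 1 the
# emergent spacer shrinks to N2/N3 and the pattern no longer fits.
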