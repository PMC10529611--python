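"""Amplicon designs, coordinate mapping and variant libraries.

Builds the bundled synthetic codon-saturation design, maps a few positions
between amplicon and HGVS c. coordinates, and enumerates the degenerate
(NNN) codon library with consequences.
"""

from collections import Counter

from sgekit.design import enumerate_codon_library, enumerate_snv_library
from sgekit.presets import codon_design

design = codon_design()
print(f"amplicon {design.amplicon_id}: {len(design.reference_seq)} bp, "
      f"exon {design.exon_intervals[0]}, cut at {design.cut_sites[0]}")

# amplicon position 30 is the first exonic base; 18 is 12 nt into the intron
for pos in (30, 18, 50):
    print(f"  amplicon {pos:3d} -> c.{design.map_position(pos)}")

library = [k for aa in (57, 58, 59) for k in enumerate_codon_library(design, aa)]
kinds = Counter(k.hgvs_p.endswith("*") and "nonsense"
                or k.hgvs_p.endswith("=") and "synonymous" or "missense"
                for k in library)
print(f"\ncodon library for residues 57-59: {len(library)} variants {dict(kinds)}")
print("examples:", ", ".join(f"{k.hgvs_c} ({k.hgvs_p})" for k in library[:3]))

snvs = enumerate_snv_library(design, "150-5", "155")
print(f"\nSNV library c.150-5..c.155: {len(snvs)} variants "
      f"(3 per position, intronic flank included)")

# Each variant is identified by its substitution edits alone; the fixed
# synonymous PAM-marker edit is design metadata used to gate counting.
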