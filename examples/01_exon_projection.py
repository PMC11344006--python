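"""Project reference exons onto a haplotype assembly through a PAF alignment.

Builds a small reference gene with two exons, applies a 24-bp insertion
inside the second (VNTR-like) exon to create a synthetic assembly, then
lifts the exons through the constructed CIGAR, splices, translates, and
classifies the ORF.  The projected protein should be exactly 8 aa longer
than the reference protein.
"""

from vntrkit.projection import (
    GeneModel,
    GenomicInterval,
    project_and_translate,
    translate_cds,
)
from vntrkit.synthetic import gen_alignment_fixture

exon1 = "ATGGCTAGT" * 4                # 36 bp, carries the start codon
exon2 = "ACTAGTACTCCT" * 12 + "TAA"    # 147 bp, repeat-rich, carries the stop
intron = "GGGGGGGGGG"
reference = exon1 + intron + exon2
model = GeneModel(
    "toy",
    [
        GenomicInterval("ref", 0, len(exon1)),
        GenomicInterval("ref", len(exon1) + len(intron), len(reference)),
    ],
)

# 24-bp in-frame insertion 30 bp into exon 2
insert_at = len(exon1) + len(intron) + 30
fx = gen_alignment_fixture(reference, model, [(insert_at, "ins", 24)], seed=2)

ref_protein = translate_cds(exon1 + exon2).rstrip("*")
p = project_and_translate(fx.contig_seq, fx.alignment, model)

print(f"reference protein: {len(ref_protein)} aa")
print(f"projected protein: {p.length_aa} aa, status={p.status}")
print(f"exon intervals on assembly: "
      f"{[(iv.start, iv.end) for iv in p.exon_intervals_on_assembly]}")
print(f"length difference: {p.length_aa - len(ref_protein)} aa "
      "(one 24-bp insertion = 8 codons)")
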