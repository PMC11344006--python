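"""Catalog VNTR motifs across a synthetic cohort and cluster usage.

Generates 30 haplotypes from a 10-motif grammar with light mutation,
tiles each tandem-repeat domain into 8-aa motifs, builds the catalog with
occurrence/carrier counts, normalizes the usage matrix, and clusters
haplotypes by UPGMA.  With mutation on, the catalog grows beyond the
grammar (each new motif differs by at most one codon's worth of change).
"""

from vntrkit.motifs import (
    MotifConfig,
    build_catalog,
    normalize,
    position_frequencies,
    segment_vntr,
    st_content,
    upgma_cluster,
    usage_matrix,
)
from vntrkit.synthetic import DomainSpec, GrammarConfig, gen_vntr_cohort

MOTIFS = ("TTSTTSAP", "TTSTTSGP", "TTSATSAP", "TTSTTPAP", "TISTTSAP",
          "TTSTTSVP", "STSTTSAP", "TTSTASAP", "TTSTTSSP", "TTSTTSAA")
CYS = "CDWRCTQLGCDNHKCEWHQGRCCQEC"
cfg = GrammarConfig(
    motif_set=MOTIFS,
    domain_template=(
        DomainSpec("cys", "cysD1", exemplar=CYS),
        DomainSpec("TR", "TR1", motif_count_choices=(10, 15, 20)),
        DomainSpec("cys", "cysD1", exemplar=CYS),
        DomainSpec("TR", "TR2", motif_count_choices=(12, 18)),
    ),
    cohort_size=30,
    seed=11,
    mutation_rate=0.01,
)
cohort = gen_vntr_cohort(cfg)

# re-segment from the emitted domain sequences (not the truth lists)
per_hap = {}
mc = MotifConfig(8)
for hap, arch in cohort.architectures.items():
    per_hap[hap] = [m for kind, _, seq in arch if kind == "TR"
                    for m in segment_vntr(seq, mc).motifs]

catalog = build_catalog(per_hap)
print(f"grammar motifs: {len(MOTIFS)}; observed unique motifs: {len(catalog)}")
print(f"motifs private to one haplotype: {len(catalog.singletons())}")

hap0 = sorted(per_hap)[0]
st, pct = st_content(per_hap[hap0])
print(f"{hap0}: {len(per_hap[hap0])} motifs, S/T count {st} ({pct:.1f}%)")

norm = normalize(usage_matrix(catalog, per_hap), "row+column")
tree = upgma_cluster(norm, axis="rows")
print(f"UPGMA leaf order (first 5): {tree.leaf_order()[:5]}")

pfm = position_frequencies(catalog, "unique")
consensus = "".join(pfm.loc[i].idxmax() for i in range(8))
print(f"catalog consensus motif: {consensus}")
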