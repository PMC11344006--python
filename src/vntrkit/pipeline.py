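"""End-to-end orchestration of the characterization and scan stages.

Two entry points mirror the two halves of the analysis:

* :func:`run_characterize` — synthetic (or supplied) VNTR cohort ->
  protein projection/classification -> domain annotation -> protein
  groups -> motif catalog, usage matrices and UPGMA trees.
* :func:`run_scan` — haplotype matrix -> binned Tajima's D with
  percentile flags and permutation p-values -> Gabriel LD blocks ->
  haplogroup tSNPs.

Each stage writes its outputs under the configured directory together
with a manifest (JSON) listing parameters and SHA-256 digests of every
input and output, so reruns are verifiably identical and ``resume`` can
skip completed stages by digest equality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import domains as dom
from . import io as vio
from . import ld as ldmod
from . import motifs as mot
from . import popgen as pg
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_characterize", "run_scan", "load_config"]

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level",
    "cohort", "motif", "domain_library", "min_identity", "min_group_size",
    "scan", "ld", "haplogroups",
}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    log_level: str = "INFO"
    cohort: dict = field(default_factory=dict)
    motif: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    ld: dict = field(default_factory=dict)
    haplogroups: str | None = None        # labels TSV path
    domain_library: str | None = None     # exemplar FASTA path
    min_identity: float = 0.80
    min_group_size: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate_inputs(self) -> None:
        for p in (self.haplogroups, self.domain_library):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, name: str, params: dict, outputs: list[Path]) -> Path:
    manifest = {
        "stage": name,
        "parameters": params,
        "outputs": {str(p.relative_to(out_dir)): _digest(p) for p in sorted(outputs)},
    }
    path = out_dir / f"manifest_{name}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _stage_done(out_dir: Path, name: str) -> bool:
    path = out_dir / f"manifest_{name}.json"
    if not path.exists():
        return False
    manifest = json.loads(path.read_text())
    for rel, digest in manifest.get("outputs", {}).items():
        p = out_dir / rel
        if not p.exists() or _digest(p) != digest:
            return False
    return True


def run_characterize(
    cfg: PipelineConfig, dry_run: bool = False, resume: bool = False
) -> dict:
    """Cohort generation -> motif catalog/usage/UPGMA -> domains -> groups."""
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    plan = ["cohort", "motifs", "domains", "groups"]
    if dry_run:
        logger.info("dry-run: would execute stages %s", plan)
        return {"plan": plan}
    if resume and out.exists() and all(_stage_done(out, s) for s in plan):
        logger.info("resume: all stage manifests verify, skipping recomputation")
        return {"resumed": True, "plan": plan}
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    # stage: cohort (synthetic grammar cohort with truth)
    template = _default_template(cfg.cohort)
    grammar = syn.GrammarConfig(
        motif_set=tuple(cfg.cohort.get("motif_set", _DEFAULT_MOTIFS)),
        domain_template=template,
        cohort_size=int(cfg.cohort.get("cohort_size", 40)),
        seed=int(cfg.seed),
        mutation_rate=float(cfg.cohort.get("mutation_rate", 0.0)),
    )
    cohort = syn.gen_vntr_cohort(grammar)
    vio.write_fasta(cohort.proteins, out / "proteins.fasta")
    vio.write_fasta(cohort.cds, out / "cds.fasta")
    _write_manifest(out, "cohort",
                    {"cohort_size": grammar.cohort_size, "seed": grammar.seed,
                     "mutation_rate": grammar.mutation_rate},
                    [out / "proteins.fasta", out / "cds.fasta"])
    artifacts["cohort"] = cohort

    # stage: motifs
    catalog = mot.build_catalog(cohort.motif_lists)
    raw = mot.usage_matrix(catalog, cohort.motif_lists)
    mode = cfg.motif.get("normalize", "row+column")
    norm = mot.normalize(raw, mode)
    catalog.to_frame().to_csv(out / "catalog.tsv", sep="\t", index=False)
    norm.values.to_csv(out / "usage_matrix.tsv", sep="\t")
    tree = mot.upgma_cluster(norm, axis="rows")
    (out / "haplotype_tree.nwk").write_text(tree.newick() + "\n")
    pfm = mot.position_frequencies(catalog, cfg.motif.get("pfm_weighting", "unique"))
    pfm.to_csv(out / "pfm.tsv", sep="\t")
    _write_manifest(out, "motifs", {"normalize": mode},
                    [out / "catalog.tsv", out / "usage_matrix.tsv",
                     out / "haplotype_tree.nwk", out / "pfm.tsv"])
    artifacts["catalog"] = catalog
    artifacts["usage"] = norm

    # stage: domains
    if cfg.domain_library:
        library = dom.read_domain_library(cfg.domain_library)
    else:
        library = [(s.label or "cysD1", s.exemplar)
                   for s in template if s.kind == "cys"]
    rows = []
    vectors = {}
    for hap in sorted(cohort.proteins):
        annos = dom.annotate_domains(
            cohort.proteins[hap], library, cfg.min_identity
        )
        counts = [len(d) for d in cohort.per_domain_motifs[hap]]
        vectors[hap] = dom.architecture_vector(annos, counts)
        for a in annos:
            rows.append((hap, a.domain_type, a.start_aa, a.end_aa, round(a.identity, 4)))
    pd.DataFrame(rows, columns=["haplotype", "domain", "start_aa", "end_aa", "identity"]) \
        .to_csv(out / "domains.tsv", sep="\t", index=False)
    _write_manifest(out, "domains", {"min_identity": cfg.min_identity},
                    [out / "domains.tsv"])
    artifacts["vectors"] = vectors

    # stage: groups
    groups = dom.assign_protein_groups(vectors, cfg.min_group_size)
    pd.DataFrame([(g.haplotype_id, g.group_label) for g in groups],
                 columns=["haplotype", "group"]) \
        .to_csv(out / "protein_groups.tsv", sep="\t", index=False)
    _write_manifest(out, "groups", {"min_group_size": cfg.min_group_size},
                    [out / "protein_groups.tsv"])
    artifacts["groups"] = groups
    return artifacts


def run_scan(cfg: PipelineConfig, dry_run: bool = False) -> dict:
    """Haplotype matrix -> Tajima's D bins -> permutation p -> blocks/tSNPs."""
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    plan = ["hapmatrix", "tajima_bins", "blocks", "tsnps"]
    if dry_run:
        logger.info("dry-run: would execute stages %s", plan)
        return {"plan": plan}
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    scan = cfg.scan

    sfs = syn.SFSConfig(
        n_haplotypes=int(scan.get("n_haplotypes", 100)),
        n_sites=int(scan.get("n_sites", 400)),
        region_length_bp=int(scan.get("region_length_bp", 100_000)),
        spectrum=scan.get("spectrum", "neutral"),
        seed=int(cfg.seed),
    )
    matrix = syn.sim_hapmatrix(sfs)
    vio.write_haplotype_tsv(matrix, out / "hapmatrix.tsv")
    _write_manifest(out, "hapmatrix", {"spectrum": sfs.spectrum, "seed": sfs.seed},
                    [out / "hapmatrix.tsv"])
    artifacts["matrix"] = matrix

    bins = pg.bin_scan(
        matrix, sfs.region_length_bp,
        bin_size=int(scan.get("bin_size", 10_000)),
        min_snps=int(scan.get("min_snps", 10)),
    )
    background = syn.sim_hapmatrix(
        syn.SFSConfig(sfs.n_haplotypes, int(scan.get("background_sites", 4000)),
                      int(scan.get("background_sites", 4000)) * 250,
                      seed=int(cfg.seed) + 1, spectrum=sfs.spectrum)
    )
    bg_bins = pg.bin_scan(background, background.site_positions[-1] + 1,
                          bin_size=int(scan.get("bin_size", 10_000)),
                          min_snps=int(scan.get("min_snps", 10)))
    bg_values = [b.tajima.D for b in bg_bins if b.tajima.defined]
    bins = pg.percentile_flags(bins, bg_values)
    null_cfg = pg.PermutationNull(
        tail=scan.get("tail", "lower"),
        n_bins_per_replicate=int(scan.get("bins_per_replicate", min(len(bg_values), 10_000))),
        n_replicates=int(scan.get("replicates", 1000)),
        seed=int(cfg.seed),
    )
    bins, null = pg.permutation_test(bins, bg_values, null_cfg)
    pd.DataFrame(
        [(b.start, b.tajima.D, b.snp_count, "|".join(sorted(b.flags)),
          b.p_empirical, b.p_adjusted) for b in bins],
        columns=["bin_start", "tajimas_d", "n_snps", "flags", "p_empirical", "p_adjusted"],
    ).to_csv(out / "tajima_bins.tsv", sep="\t", index=False)
    _write_manifest(out, "tajima_bins",
                    {"tail": null.tail, "replicates": null.n_replicates},
                    [out / "tajima_bins.tsv"])
    artifacts["bins"] = bins

    ld_cfg = cfg.ld
    filtered, removal = ldmod.filter_sites(
        matrix,
        maf_min=float(ld_cfg.get("maf_min", 0.05)),
        call_rate_min=float(ld_cfg.get("call_rate_min", 0.75)),
        hwe_alpha=ld_cfg.get("hwe_alpha", 1e-3),
    )
    blocks = ldmod.gabriel_blocks(filtered, seed=int(cfg.seed))
    pd.DataFrame(
        [(b.sequence_name, b.start, b.end, b.n_sites, round(b.strong_pair_fraction, 4))
         for b in blocks],
        columns=["chrom", "start", "end", "n_sites", "strong_fraction"],
    ).to_csv(out / "blocks.bed", sep="\t", index=False, header=False)
    _write_manifest(out, "blocks", {"filters": removal}, [out / "blocks.bed"])
    artifacts["blocks"] = blocks

    if cfg.haplogroups:
        labels = vio.read_labels_tsv(cfg.haplogroups)
        target = ld_cfg.get("target_haplogroup") or sorted(set(labels.values()))[0]
        pseudo = ldmod.encode_haplogroup(labels, target, order=matrix.sample_ids)
        window = tuple(ld_cfg.get("window", (0, sfs.region_length_bp)))
        hits = ldmod.discover_tsnps(
            matrix, pseudo, window,
            r2_threshold=float(ld_cfg.get("r2_threshold", 0.85)),
        )
        pd.DataFrame(
            [(h.site_position, round(h.r_squared, 6), h.passes_threshold) for h in hits],
            columns=["position", "r2", "tsnp"],
        ).to_csv(out / "tsnps.tsv", sep="\t", index=False)
        _write_manifest(out, "tsnps", {"target": target}, [out / "tsnps.tsv"])
        artifacts["tsnps"] = hits
    return artifacts


_DEFAULT_MOTIFS = (
    "TTSTTSAP", "TTSTTSGP", "TTSTTSVP", "TTSATSAP", "TTSTTPAP",
    "TTSTASAP", "TISTTSAP", "TTSTTSAA", "STSTTSAP", "TTSTTSSP",
)


def _default_template(cohort_cfg: dict) -> tuple[syn.DomainSpec, ...]:
    if "template" in cohort_cfg:
        return tuple(syn.DomainSpec(**d) for d in cohort_cfg["template"])
    cys = "CDWRCTQLGCDNHKCEWHQGRCCQEC"
    return (
        syn.DomainSpec("cys", "cysD1", exemplar=cys),
        syn.DomainSpec("TR", "TR1", motif_count_choices=(8, 10, 12)),
        syn.DomainSpec("cys", "cysD1", exemplar=cys, copy_choices=(1, 2)),
        syn.DomainSpec("TR", "TR2", motif_count_choices=(15, 20)),
        syn.DomainSpec("cys", "cysD1", exemplar=cys),
    )
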