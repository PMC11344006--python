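"""Synthetic-data generators with exact ground truth.

Everything the pipeline consumes can be generated here with a known answer:
VNTR-bearing gene cohorts built from a motif grammar (domain templates with
copy-number variation and capped per-site substitution), assembly/alignment
fixtures with constructed CIGARs and truth exon projections, and phased SNP
haplotype matrices with controllable site-frequency spectra, planted LD
blocks, and diploid genotypes with a tunable inbreeding coefficient.

Every generator is a pure function of its configuration and seed (one
``numpy.random.default_rng`` per call; no global state), so fixtures are
bit-reproducible and each downstream module can be tested against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .popgen import HaplotypeMatrix
from .projection import AlignmentRecord, GeneModel, GenomicInterval

__all__ = [
    "DomainSpec",
    "GrammarConfig",
    "SFSConfig",
    "VNTRCohort",
    "AlignmentFixture",
    "gen_vntr_cohort",
    "gen_alignment_fixture",
    "sim_hapmatrix",
    "sim_ld_blocks",
    "sim_diploids",
]

# deterministic reverse-translation table: one codon per amino acid
_CODON_OF = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
_STOPS = {"TAA", "TAG", "TGA"}
_NT = "ACGT"


@dataclass(frozen=True)
class DomainSpec:
    """One template slot: a cys-type exemplar or a tandem-repeat domain.

    ``copy_choices`` are the admissible copy numbers of the slot (sampled
    uniformly per haplotype); for TR domains ``motif_count_choices`` are the
    admissible per-domain motif counts.
    """

    kind: str                      # "cys" | "TR"
    label: str = ""
    exemplar: str | None = None    # cys domains
    motif_count_choices: tuple[int, ...] = ()  # TR domains
    copy_choices: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if self.kind not in ("cys", "TR"):
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.kind == "cys" and not self.exemplar:
            raise ValueError("cys domain needs an exemplar sequence")
        if self.kind == "TR" and not self.motif_count_choices:
            raise ValueError("TR domain needs motif_count_choices")


@dataclass(frozen=True)
class GrammarConfig:
    motif_set: tuple[str, ...]
    domain_template: tuple[DomainSpec, ...]
    cohort_size: int
    seed: int
    mutation_rate: float = 0.0   # per-nt substitution rate inside the CDS
    allow_stops: bool = False    # permit nonsense substitutions

    def __post_init__(self) -> None:
        lengths = {len(m) for m in self.motif_set}
        if len(lengths) != 1:
            raise ValueError("motif lengths must be uniform")
        if not 0 <= self.mutation_rate <= 0.2:
            raise ValueError("mutation_rate must be in [0, 0.2]")

    @property
    def motif_len_aa(self) -> int:
        return len(self.motif_set[0])


@dataclass
class VNTRCohort:
    """Generated cohort plus the truth tables that describe it exactly."""

    cds: dict[str, str]
    proteins: dict[str, str]
    # per haplotype: ordered (kind, label, aa_sequence) domain architecture
    architectures: dict[str, list[tuple[str, str, str]]]
    # per haplotype: motif lists pooled over TR domains, and per TR domain
    motif_lists: dict[str, list[str]]
    per_domain_motifs: dict[str, list[list[str]]]
    grammar_motifs: tuple[str, ...]


def _mutate_block(block: str, rate: float, rng, cap: int, allow_stops: bool) -> str:
    """Substitute nucleotides at ``rate``, capped at ``cap`` per block.

    The cap keeps every mutated motif within a provable Hamming budget of
    its grammar source.  Nonsense substitutions (in-frame stops) are
    resampled away unless ``allow_stops``.
    """
    if rate <= 0 or cap == 0:
        return block
    n_sub = min(int(rng.binomial(len(block), rate)), cap)
    if n_sub == 0:
        return block
    seq = list(block)
    sites = rng.choice(len(block), size=n_sub, replace=False)
    for s in sites:
        choices = [c for c in _NT if c != seq[s]]
        for _ in range(20):
            cand = choices[rng.integers(0, 3)]
            old = seq[s]
            seq[s] = cand
            codon_start = (s // 3) * 3
            if allow_stops or "".join(seq[codon_start : codon_start + 3]) not in _STOPS:
                break
            seq[s] = old
    return "".join(seq)


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(cds).translate())


def gen_vntr_cohort(cfg: GrammarConfig) -> VNTRCohort:
    """Sample a cohort of VNTR gene haplotypes from the motif grammar.

    Each haplotype draws domain copy numbers, per-TR-domain motif counts
    and motif sequences from the grammar, reverse-translates with a fixed
    codon table, applies capped per-site substitution, and records its
    exact architecture, motif lists, and sequences.  The CDS carries an
    ATG start and a terminal TAA stop.
    """
    rng = np.random.default_rng(cfg.seed)
    L_nt = 3 * cfg.motif_len_aa
    cap = math.ceil(cfg.mutation_rate * L_nt)
    cohort = VNTRCohort({}, {}, {}, {}, {}, cfg.motif_set)

    for h in range(cfg.cohort_size):
        hap = f"hap{h:03d}"
        cds_parts = ["ATG"]
        arch: list[tuple[str, str, str]] = []
        per_domain: list[list[str]] = []
        tr_index = 0
        for spec in cfg.domain_template:
            copies = int(rng.choice(spec.copy_choices))
            for _ in range(copies):
                if spec.kind == "cys":
                    nt = "".join(_CODON_OF[aa] for aa in spec.exemplar)
                    nt = _mutate_block(
                        nt, cfg.mutation_rate, rng,
                        math.ceil(cfg.mutation_rate * len(nt)), cfg.allow_stops,
                    )
                    cds_parts.append(nt)
                    arch.append(("cys", spec.label or "cys", _translate(nt)))
                else:
                    tr_index += 1
                    count = int(rng.choice(spec.motif_count_choices))
                    motifs_aa = []
                    domain_nt = []
                    for _ in range(count):
                        motif = cfg.motif_set[rng.integers(0, len(cfg.motif_set))]
                        nt = "".join(_CODON_OF[aa] for aa in motif)
                        nt = _mutate_block(nt, cfg.mutation_rate, rng, cap,
                                           cfg.allow_stops)
                        domain_nt.append(nt)
                        motifs_aa.append(_translate(nt))
                    seq_nt = "".join(domain_nt)
                    cds_parts.append(seq_nt)
                    label = spec.label or f"TR{tr_index}"
                    arch.append(("TR", label, _translate(seq_nt)))
                    per_domain.append(motifs_aa)
        cds_parts.append("TAA")
        cds = "".join(cds_parts)
        protein = _translate(cds)
        protein = protein[:-1] if protein.endswith("*") else protein
        cohort.cds[hap] = cds
        cohort.proteins[hap] = protein
        cohort.architectures[hap] = arch
        cohort.per_domain_motifs[hap] = per_domain
        cohort.motif_lists[hap] = [m for dom in per_domain for m in dom]
    return cohort


@dataclass
class AlignmentFixture:
    contig_name: str
    contig_seq: str
    alignment: AlignmentRecord
    paf_line: str
    # per exon: truth assembly interval, or None when fully deleted
    truth_intervals: list[GenomicInterval | None]


def gen_alignment_fixture(
    reference_seq: str,
    model: GeneModel,
    edits: list[tuple[int, str, int]],
    contig_name: str = "asm",
    seed: int = 0,
) -> AlignmentFixture:
    """Apply an edit list to a reference and construct the PAF alignment.

    Edits are (position, "ins"|"del", length) on reference coordinates,
    sorted and non-overlapping; insertions add random bases before the
    reference base at ``position``.  Truth exon intervals are computed by
    direct offset arithmetic (independent of the CIGAR walker), with edges
    falling in deletions snapped inward.
    """
    rng = np.random.default_rng(seed)
    ref_len = len(reference_seq)
    prev_end = 0
    for pos, kind, length in edits:
        if kind not in ("ins", "del"):
            raise ValueError(f"unknown edit kind {kind!r}")
        if length < 1 or pos < prev_end or pos > ref_len:
            raise ValueError("edits must be sorted, non-overlapping, in range")
        prev_end = pos + (length if kind == "del" else 0)
    if prev_end > ref_len:
        raise ValueError("deletion runs past the reference end")

    # build contig + CIGAR
    pieces: list[str] = []
    cigar: list[tuple[int, str]] = []
    cursor = 0
    for pos, kind, length in edits:
        if pos > cursor:
            pieces.append(reference_seq[cursor:pos])
            cigar.append((pos - cursor, "="))
        if kind == "ins":
            pieces.append("".join(_NT[i] for i in rng.integers(0, 4, size=length)))
            cigar.append((length, "I"))
            cursor = pos
        else:
            cigar.append((length, "D"))
            cursor = pos + length
    if cursor < ref_len:
        pieces.append(reference_seq[cursor:])
        cigar.append((ref_len - cursor, "="))
    contig = "".join(pieces)

    aln = AlignmentRecord(
        query_name=contig_name,
        query_len=len(contig),
        query_start=0,
        query_end=len(contig),
        strand="+",
        target_name=model.exons[0].sequence_name if model.exons else "ref",
        target_len=ref_len,
        target_start=0,
        target_end=ref_len,
        mapq=60,
        cigar=cigar,
    )
    aln.validate()
    cg = "".join(f"{n}{op}" for n, op in cigar)
    paf = "\t".join(
        str(x)
        for x in (
            aln.query_name, aln.query_len, aln.query_start, aln.query_end,
            aln.strand, aln.target_name, aln.target_len, aln.target_start,
            aln.target_end, sum(n for n, op in cigar if op == "="),
            sum(n for n, op in cigar), aln.mapq, f"cg:Z:{cg}",
        )
    )

    # truth projection by offset arithmetic
    dels = [(p, l) for p, k, l in edits if k == "del"]
    ins = [(p, l) for p, k, l in edits if k == "ins"]

    def deleted(r: int) -> bool:
        return any(p <= r < p + l for p, l in dels)

    def q_of(r: int) -> int:
        shift = sum(l for p, l in ins if p <= r) - sum(
            min(l, max(0, r - p)) for p, l in dels
        )
        return r + shift

    truth: list[GenomicInterval | None] = []
    for exon in model.exons:
        first = next((r for r in range(exon.start, exon.end) if not deleted(r)), None)
        if first is None:
            truth.append(None)
            continue
        last = next(
            r for r in range(exon.end - 1, exon.start - 1, -1) if not deleted(r)
        )
        truth.append(GenomicInterval(contig_name, q_of(first), q_of(last) + 1, "+"))
    return AlignmentFixture(contig_name, contig, aln, paf, truth)


@dataclass(frozen=True)
class SFSConfig:
    """Site-frequency-spectrum sampler configuration.

    ``neutral`` draws minor(derived)-allele counts i in 1..n-1 with
    P(i) ∝ 1/i (the standard neutral expectation), ``rare_excess`` with
    P(i) ∝ 1/i^2 and ``common_excess`` with P(i) ∝ i/(n-i) (truncated).
    """

    n_haplotypes: int
    n_sites: int
    region_length_bp: int
    seed: int
    spectrum: str = "neutral"
    sequence_name: str = "sim"

    def __post_init__(self) -> None:
        if self.spectrum not in ("neutral", "rare_excess", "common_excess"):
            raise ValueError(f"unknown spectrum {self.spectrum!r}")
        if self.n_sites > self.region_length_bp:
            raise ValueError("n_sites cannot exceed region_length_bp")
        if self.n_haplotypes < 2:
            raise ValueError("need at least two haplotypes")


def spectrum_weights(n: int, spectrum: str) -> np.ndarray:
    i = np.arange(1, n, dtype=float)
    if spectrum == "neutral":
        w = 1.0 / i
    elif spectrum == "rare_excess":
        w = 1.0 / i**2
    else:
        # common excess: increasing weight toward intermediate frequencies,
        # truncated to minor-allele counts (i <= n/2); without the
        # truncation the law would concentrate on nearly fixed alleles,
        # which contribute like rare variants
        w = np.where(i <= n / 2, i / (n - i), 0.0)
    return w / w.sum()


def sim_hapmatrix(cfg: SFSConfig) -> HaplotypeMatrix:
    """Phased haplotype matrix with a controlled site-frequency spectrum.

    Allele counts are drawn i.i.d. per site from the configured spectrum,
    carriers assigned uniformly at random, positions uniform without
    replacement over the region.
    """
    rng = np.random.default_rng(cfg.seed)
    n, S = cfg.n_haplotypes, cfg.n_sites
    w = spectrum_weights(n, cfg.spectrum)
    counts = rng.choice(np.arange(1, n), size=S, p=w)
    A = np.zeros((n, S), dtype=np.int8)
    for s in range(S):
        carriers = rng.choice(n, size=int(counts[s]), replace=False)
        A[carriers, s] = 1
    positions = np.sort(rng.choice(cfg.region_length_bp, size=S, replace=False))
    return HaplotypeMatrix(cfg.sequence_name, positions, A)


def sim_ld_blocks(
    block_layout: list[tuple[int, int]],
    n_haplotypes: int,
    seed: int,
    spacer_sites: int = 3,
    site_spacing_bp: int = 1_000,
    sequence_name: str = "sim",
) -> tuple[HaplotypeMatrix, list[tuple[int, int]]]:
    """Plant perfect-LD blocks separated by independent spacer sites.

    ``block_layout`` lists (site_count, n_distinct_local_haplotypes) per
    block; within a block each haplotype copies one of k local patterns
    (all used, drawn uniformly), so with k <= 3 every within-block pair
    shows |D'| = 1.  ``spacer_sites`` independent Bernoulli(1/2) sites
    separate consecutive blocks and flank the layout.  Returns the matrix
    and the truth blocks as (first_site_index, last_site_index) pairs.
    """
    rng = np.random.default_rng(seed)
    n = n_haplotypes
    columns: list[np.ndarray] = []
    truth: list[tuple[int, int]] = []

    def spacers(k: int) -> None:
        for _ in range(k):
            col = rng.integers(0, 2, size=n).astype(np.int8)
            while col.min() == col.max():
                col = rng.integers(0, 2, size=n).astype(np.int8)
            columns.append(col)

    spacers(spacer_sites)
    for m_sites, k in block_layout:
        if k < 2:
            raise ValueError("need at least two local haplotype patterns")
        while True:
            patterns = rng.integers(0, 2, size=(k, m_sites)).astype(np.int8)
            distinct = len({p.tobytes() for p in patterns}) == k
            polymorphic = np.all(patterns.min(axis=0) != patterns.max(axis=0))
            if distinct and polymorphic:
                break
        while True:
            assign = rng.integers(0, k, size=n)
            if len(set(assign.tolist())) == k:
                break
        start_idx = len(columns)
        block = patterns[assign]  # (n, m_sites)
        columns.extend(block.T)
        truth.append((start_idx, start_idx + m_sites - 1))
        spacers(spacer_sites)

    A = np.column_stack(columns)
    positions = np.arange(A.shape[1], dtype=np.int64) * site_spacing_bp
    return HaplotypeMatrix(sequence_name, positions, A), truth


def sim_diploids(matrix: HaplotypeMatrix, inbreeding_f: float, seed: int) -> np.ndarray:
    """Diploid genotype dosages under an inbreeding coefficient F.

    Per site, with allele-1 frequency p and q = 1 - p, genotype
    probabilities are (q^2 + Fpq, 2pq(1 - F), p^2 + Fpq) for dosages
    (0, 1, 2), clipped to [0, 1] and renormalized; F = -1 with p = 0.5
    gives all heterozygotes, negative F a heterozygote excess.  Individuals
    number n_haplotypes // 2.
    """
    if not -1.0 <= inbreeding_f <= 1.0:
        raise ValueError("inbreeding coefficient must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    N = matrix.n_haplotypes // 2
    if N < 1:
        raise ValueError("need at least two haplotypes to form a diploid")
    A = matrix.alleles
    p = (A == 1).sum(axis=0) / np.maximum((A != -1).sum(axis=0), 1)
    q = 1.0 - p
    F = inbreeding_f
    probs = np.stack(
        [q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q], axis=1
    )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    out = np.empty((N, matrix.n_sites), dtype=np.int8)
    for s in range(matrix.n_sites):
        out[:, s] = rng.choice(3, size=N, p=probs[s])
    return out
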