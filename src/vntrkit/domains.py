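"""Protein domain architecture for mucin-like VNTR proteins.

Secreted gel-forming mucins interleave cysteine-rich (CysD) domains with
serine/threonine-rich tandem-repeat (PTS/VNTR) domains inside one very large
central exon.  This module annotates predicted proteins against a library of
domain exemplars (greedy ungapped matching), summarizes each haplotype as a
copy-number architecture vector, and partitions haplotypes into protein
groups (identical architectures).

The matching is a reproducible formalization of what is usually manual
curation: at each scan position the exemplar with the highest ungapped
identity above a threshold is annotated and the scan resumes after it.
Stretches between exemplar matches are called PTS when their combined
serine+threonine fraction exceeds a floor, otherwise "linker".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "DomainAnnotation",
    "ArchitectureVector",
    "ProteinGroupAssignment",
    "annotate_domains",
    "architecture_vector",
    "assign_protein_groups",
    "read_domain_library",
]

DEFAULT_MIN_IDENTITY = 0.80
DEFAULT_ST_FLOOR = 0.40


@dataclass(frozen=True)
class DomainAnnotation:
    """One annotated stretch [start_aa, end_aa) on a protein.

    For exemplar matches ``identity`` is the ungapped identity to the matched
    exemplar; for inferred PTS/linker stretches it carries the S+T fraction
    of the stretch.
    """

    domain_type: str
    start_aa: int
    end_aa: int
    identity: float

    def __len__(self) -> int:
        return self.end_aa - self.start_aa


@dataclass(frozen=True)
class ArchitectureVector:
    """Copy-number summary of one haplotype's domain architecture."""

    cys_counts: tuple[tuple[str, int], ...]  # sorted (domain_type, count)
    tr_domain_count: int
    per_domain_motif_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.per_domain_motif_counts) != self.tr_domain_count:
            raise ValueError(
                "per_domain_motif_counts must have one entry per TR domain"
            )


@dataclass(frozen=True)
class ProteinGroupAssignment:
    haplotype_id: str
    group_label: str  # P1..Pk or "ungrouped"


def _identity(a: str, b: str) -> float:
    """Ungapped identity of two equal-length strings."""
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _st_fraction(seq: str) -> float:
    return (seq.count("S") + seq.count("T")) / len(seq) if seq else 0.0


def read_domain_library(path) -> list[tuple[str, str]]:
    """Read a domain library FASTA with headers ``>type:<label>``."""
    from Bio import SeqIO

    library = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = rec.id.split(":", 1)[1] if ":" in rec.id else rec.id
        library.append((label, str(rec.seq).upper()))
    return library


def annotate_domains(
    protein: str,
    library: list[tuple[str, str]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    st_floor: float = DEFAULT_ST_FLOOR,
) -> list[DomainAnnotation]:
    """Greedy left-to-right exemplar annotation of a protein sequence.

    At each position the exemplar with the highest ungapped identity
    ``>= min_identity`` is annotated (ties break by library order) and the
    scan resumes after the match.  Unmatched stretches between annotations
    become ``PTS`` if their S+T fraction exceeds ``st_floor``, else
    ``linker``.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    if not library:
        raise ValueError("empty domain library")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")

    matches: list[DomainAnnotation] = []
    pos = 0
    n = len(protein)
    while pos < n:
        best = None
        for label, exemplar in library:
            m = len(exemplar)
            if pos + m > n:
                continue
            ident = _identity(protein[pos : pos + m], exemplar)
            if ident >= min_identity and (best is None or ident > best[0]):
                best = (ident, label, m)
        if best is None:
            pos += 1
            continue
        ident, label, m = best
        matches.append(DomainAnnotation(label, pos, pos + m, ident))
        pos += m

    annotations: list[DomainAnnotation] = []
    prev_end = 0
    for m_ in matches + [None]:
        gap_end = n if m_ is None else m_.start_aa
        if gap_end > prev_end:
            stretch = protein[prev_end:gap_end]
            frac = _st_fraction(stretch)
            kind = "PTS" if frac > st_floor else "linker"
            annotations.append(DomainAnnotation(kind, prev_end, gap_end, frac))
        if m_ is not None:
            annotations.append(m_)
            prev_end = m_.end_aa
    return annotations


def architecture_vector(
    annotations: list[DomainAnnotation],
    motif_counts: list[int],
    tr_types: tuple[str, ...] = ("PTS",),
    tr_prefix: str = "TR",
) -> ArchitectureVector:
    """Summarize annotations as a copy-number vector.

    TR/PTS domains are indexed positionally in protein order (TR1 = first);
    ``motif_counts`` must align one-to-one with them.  Everything that is not
    a TR/PTS domain or a linker counts as a cys-type domain.
    """
    tr = [
        a for a in annotations
        if a.domain_type in tr_types or a.domain_type.startswith(tr_prefix)
    ]
    if len(tr) != len(motif_counts):
        raise ValueError(
            f"{len(tr)} TR domains but {len(motif_counts)} motif counts"
        )
    cys = Counter(
        a.domain_type
        for a in annotations
        if a not in tr and a.domain_type != "linker"
    )
    return ArchitectureVector(
        cys_counts=tuple(sorted(cys.items())),
        tr_domain_count=len(tr),
        per_domain_motif_counts=tuple(motif_counts),
    )


def assign_protein_groups(
    vectors: dict[str, ArchitectureVector],
    min_group_size: int = 2,
) -> list[ProteinGroupAssignment]:
    """Partition haplotypes into protein groups by identical architecture.

    Classes of size >= ``min_group_size`` receive labels P1..Pk ordered by
    descending size then lexicographic smallest member; smaller classes are
    labeled "ungrouped".  ``min_group_size=2`` is the strict policy (a group
    must hold more than one haplotype); ``min_group_size=1`` admits
    singleton groups, which is appropriate for near-invariant loci with
    informative length singletons.
    """
    if not vectors:
        raise ValueError("no architecture vectors supplied")
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")

    classes: dict[ArchitectureVector, list[str]] = {}
    for hap in sorted(vectors):
        classes.setdefault(vectors[hap], []).append(hap)

    eligible = [h for h in classes.values() if len(h) >= min_group_size]
    eligible.sort(key=lambda haps: (-len(haps), min(haps)))
    label_of: dict[str, str] = {}
    for i, haps in enumerate(eligible, start=1):
        for h in haps:
            label_of[h] = f"P{i}"
    return [
        ProteinGroupAssignment(hap, label_of.get(hap, "ungrouped"))
        for hap in sorted(vectors)
    ]
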