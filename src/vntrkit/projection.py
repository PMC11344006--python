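"""Exon projection from a reference onto haplotype assemblies.

Haplotype assemblies are aligned to a reference (e.g. with minimap2, PAF
output with the ``cg:Z`` CIGAR tag).  Reference exon coordinates are lifted
through the alignment onto the assembly contig, the exons are extracted and
spliced in transcript order, translated with the standard genetic code, and
the resulting open reading frame is classified as complete, truncated
(internal stop) or incomplete (unliftable exons / missing start).

Coordinates are 0-based half-open throughout; BED input keeps its native
convention (which is the same), PAF is consumed natively.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "AlignmentRecord",
    "GeneModel",
    "ProteinModel",
    "PafError",
    "LiftoverError",
    "parse_paf",
    "read_paf",
    "read_exon_bed",
    "liftover_interval",
    "select_alignment",
    "project_and_translate",
    "classify_orf",
]

# CIGAR ops: which sequence each op consumes
_QUERY_OPS = frozenset("=XMIS")
_TARGET_OPS = frozenset("=XMDN")
_ALIGNED_OPS = frozenset("=XM")
_CIGAR_RE = re.compile(r"(\d+)([=XMIDNSH])")


class PafError(ValueError):
    """Malformed or self-inconsistent PAF input."""


class LiftoverError(ValueError):
    """Interval cannot be projected through the alignment."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    sequence_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """One assembly-to-reference alignment (a PAF line with its CIGAR)."""

    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    mapq: int
    cigar: list[tuple[int, str]] | None = None

    @property
    def has_cigar(self) -> bool:
        return self.cigar is not None

    def validate(self) -> None:
        """Check CIGAR consumption against the query/target spans."""
        if self.cigar is None:
            return
        q = sum(n for n, op in self.cigar if op in _QUERY_OPS and op != "S")
        t = sum(n for n, op in self.cigar if op in _TARGET_OPS)
        if q != self.query_end - self.query_start:
            raise PafError(
                f"{self.query_name}: CIGAR consumes {q} query bases but the "
                f"query span is {self.query_end - self.query_start}"
            )
        if t != self.target_end - self.target_start:
            raise PafError(
                f"{self.query_name}: CIGAR consumes {t} target bases but the "
                f"target span is {self.target_end - self.target_start}"
            )


@dataclass
class GeneModel:
    """Reference exon structure: non-overlapping exons sorted by start."""

    gene_name: str
    exons: list[GenomicInterval]
    coding_strand: str = "+"

    def __post_init__(self) -> None:
        if self.coding_strand not in ("+", "-"):
            raise ValueError("coding_strand must be '+' or '-'")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("exons must be non-overlapping and sorted")


@dataclass
class ProteinModel:
    """Predicted protein for one haplotype with provenance and ORF status."""

    haplotype_id: str
    protein_sequence: str
    status: str  # complete | truncated | incomplete
    exon_intervals_on_assembly: list[GenomicInterval] = field(default_factory=list)
    notes: str = ""
    raw_translation: str = ""  # internal stops retained as '*', for inspection

    @property
    def length_aa(self) -> int:
        return len(self.protein_sequence)


def _parse_cigar(text: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(text)]
    if "".join(f"{n}{op}" for n, op in ops) != text:
        raise PafError(f"unparseable CIGAR {text!r}")
    return ops


def parse_paf(lines) -> list[AlignmentRecord]:
    """Parse a PAF text stream into validated alignment records.

    Records without a ``cg:Z`` tag are returned with ``cigar=None`` and are
    ineligible for liftover.  Raises :class:`PafError` naming the line number
    on a malformed line or a CIGAR/coordinate contradiction.
    """
    records = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise PafError(f"line {lineno}: expected >=12 PAF fields, got {len(fields)}")
        try:
            rec = AlignmentRecord(
                query_name=fields[0],
                query_len=int(fields[1]),
                query_start=int(fields[2]),
                query_end=int(fields[3]),
                strand=fields[4],
                target_name=fields[5],
                target_len=int(fields[6]),
                target_start=int(fields[7]),
                target_end=int(fields[8]),
                mapq=int(fields[11]),
            )
        except ValueError as exc:
            raise PafError(f"line {lineno}: {exc}") from exc
        if rec.strand not in ("+", "-"):
            raise PafError(f"line {lineno}: invalid strand {rec.strand!r}")
        for tag in fields[12:]:
            if tag.startswith("cg:Z:"):
                rec.cigar = _parse_cigar(tag[5:])
        try:
            rec.validate()
        except PafError as exc:
            raise PafError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def read_paf(path) -> list[AlignmentRecord]:
    with open(path) as fh:
        return parse_paf(fh)


def read_exon_bed(path, gene_name: str = "gene", coding_strand: str = "+") -> GeneModel:
    """Read a BED6 exon model; the name field carries the exon rank."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rank = int(f[3]) if len(f) > 3 and f[3].strip() else len(rows) + 1
            strand = f[5].strip() if len(f) > 5 else "+"
            rows.append((rank, GenomicInterval(f[0], int(f[1]), int(f[2]), strand)))
    rows.sort(key=lambda r: r[1].start)
    return GeneModel(gene_name, [iv for _, iv in rows], coding_strand)


def _target_to_query_walk(aln: AlignmentRecord):
    """Yield (target_pos, query_aln_offset, op_len, op) blocks.

    query offsets are in alignment orientation (0 at query_start for '+',
    0 at query_end-1 moving down for '-'); conversion to forward-strand
    contig coordinates happens in :func:`liftover_interval`.
    """
    t = aln.target_start
    q = 0
    for n, op in aln.cigar:
        yield t, q, n, op
        if op in _TARGET_OPS:
            t += n
        if op in _QUERY_OPS and op != "S":
            q += n


def _aln_offset_to_forward(aln: AlignmentRecord, qa: int) -> int:
    if aln.strand == "+":
        return aln.query_start + qa
    return aln.query_end - 1 - qa


def liftover_interval(aln: AlignmentRecord, ref_iv: GenomicInterval) -> GenomicInterval:
    """Project a reference interval through the alignment onto the assembly.

    Edges that fall inside an assembly deletion snap inward (toward the
    interval interior) to the nearest aligned base; an interval entirely
    inside a deletion raises :class:`LiftoverError`.  Coordinates are
    reported on the forward strand of the assembly contig, with the
    interval's strand set to the alignment strand.
    """
    if aln.cigar is None:
        raise LiftoverError(f"{aln.query_name}: record has no CIGAR")
    if ref_iv.sequence_name != aln.target_name:
        raise LiftoverError(
            f"interval on {ref_iv.sequence_name} but alignment targets {aln.target_name}"
        )
    if ref_iv.start < aln.target_start or ref_iv.end > aln.target_end:
        raise LiftoverError(
            f"interval [{ref_iv.start},{ref_iv.end}) not covered by alignment "
            f"[{aln.target_start},{aln.target_end})"
        )

    first_qa = None  # query offset of first aligned base at/after ref start
    last_qa = None   # query offset of last aligned base before ref end
    snap = 0
    for t0, q0, n, op in _target_to_query_walk(aln):
        if op not in _ALIGNED_OPS:
            continue
        t1 = t0 + n
        lo = max(t0, ref_iv.start)
        hi = min(t1, ref_iv.end)
        if lo >= hi:
            continue
        if first_qa is None:
            first_qa = q0 + (lo - t0)
            snap += lo - ref_iv.start
        last_qa = q0 + (hi - 1 - t0)
    if first_qa is None:
        raise LiftoverError(
            f"interval [{ref_iv.start},{ref_iv.end}) lies entirely within a deletion"
        )
    a = _aln_offset_to_forward(aln, first_qa)
    b = _aln_offset_to_forward(aln, last_qa)
    start, end = (a, b + 1) if a <= b else (b, a + 1)
    return GenomicInterval(aln.query_name, start, end, aln.strand)


def select_alignment(records: list[AlignmentRecord], ref_iv: GenomicInterval) -> AlignmentRecord:
    """Pick the liftover record for a locus among overlapping alignments.

    Longest target overlap wins; ties break by higher mapq, then
    lexicographic query name.
    """
    def overlap(r: AlignmentRecord) -> int:
        if r.target_name != ref_iv.sequence_name:
            return 0
        return max(0, min(r.target_end, ref_iv.end) - max(r.target_start, ref_iv.start))

    eligible = [r for r in records if r.has_cigar and overlap(r) > 0]
    if not eligible:
        raise LiftoverError("no CIGAR-bearing alignment overlaps the locus")
    return min(eligible, key=lambda r: (-overlap(r), -r.mapq, r.query_name))


def translate_cds(cds: str) -> str:
    """Standard-code translation retaining internal stops as ``*``."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def classify_orf(raw_translation: str) -> str:
    """Classify a raw translation (internal stops retained).

    complete: starts with M, exactly one stop and it is terminal;
    truncated: an internal stop occurs; incomplete: otherwise.
    """
    if not raw_translation:
        raise ValueError("empty translation")
    stop = raw_translation.find("*")
    if not raw_translation.startswith("M"):
        return "incomplete"
    if stop == -1:
        return "incomplete"  # no terminal stop codon
    if stop == len(raw_translation) - 1:
        return "complete"
    return "truncated"


def project_and_translate(
    assembly_seq: str,
    aln: AlignmentRecord,
    model: GeneModel,
    haplotype_id: str | None = None,
) -> ProteinModel:
    """Lift all exons, splice, translate and classify the ORF.

    Exons are spliced in transcript order (reverse genomic order when the
    gene is on the reference '-' strand); the extraction strand on the
    assembly combines the coding strand with the alignment strand.
    """
    hap = haplotype_id or aln.query_name
    if len(assembly_seq) != aln.query_len:
        raise ValueError(
            f"{hap}: assembly sequence length {len(assembly_seq)} does not match "
            f"PAF query_len {aln.query_len} for contig {aln.query_name}"
        )
    lifted: list[GenomicInterval] = []
    notes = []
    for rank, exon in enumerate(model.exons, start=1):
        try:
            asm_iv = liftover_interval(aln, exon)
        except LiftoverError as exc:
            return ProteinModel(
                hap, "", "incomplete", lifted, notes=f"exon {rank} unliftable: {exc}"
            )
        if len(asm_iv) != len(exon):
            notes.append(f"exon {rank}: {len(exon)}bp -> {len(asm_iv)}bp")
        lifted.append(asm_iv)

    effective_strand = "+" if model.coding_strand == aln.strand else "-"
    pieces = []
    for iv in lifted:
        seq = assembly_seq[iv.start : iv.end]
        if effective_strand == "-":
            seq = str(Seq(seq).reverse_complement())
        pieces.append(seq)
    if model.coding_strand == "-":
        pieces = pieces[::-1]
    cds = "".join(pieces)
    if not cds:
        raise LiftoverError(f"{hap}: spliced CDS is empty")

    raw = translate_cds(cds)
    status = classify_orf(raw)
    stop = raw.find("*")
    protein = raw[:stop] if stop >= 0 else raw
    return ProteinModel(
        hap, protein, status, lifted, notes="; ".join(notes), raw_translation=raw
    )
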