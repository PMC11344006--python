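"""VNTR motif decomposition, usage matrices, and UPGMA clustering.

Mucin VNTR domains are degenerate tandem arrays of a fixed-size repeat unit
(8 aa / 24 nt for MUC5AC-like repeats, 29 aa / 87 nt for MUC5B-like ones).
Domains are tiled into consecutive fixed-size motifs, the distinct motifs
form a catalog with occurrence and carrier counts, and per-haplotype usage
matrices (raw counts, row-normalized fractions, optionally per-motif
min-max scaled) feed UPGMA clustering of haplotypes and motifs.

Segmentation is exact tiling: a domain is cut into consecutive blocks of
the motif length starting at a phase offset; a trailing block shorter than
the motif length is returned as a remainder and excluded from counts, so
prefix + motifs + remainder always reconstructs the domain byte-exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MotifConfig",
    "MotifCatalog",
    "UsageMatrix",
    "Segmentation",
    "UpgmaNode",
    "segment_vntr",
    "build_catalog",
    "usage_matrix",
    "normalize",
    "upgma_cluster",
    "st_content",
    "position_frequencies",
]


@dataclass(frozen=True)
class MotifConfig:
    """Motif geometry and segmentation phase policy."""

    motif_len_aa: int = 8
    phase_policy: str = "fixed"  # fixed | best-consensus
    consensus_prefix: str = "TTSTTS"

    def __post_init__(self) -> None:
        if self.motif_len_aa < 1:
            raise ValueError("motif_len_aa must be >= 1")
        if self.phase_policy not in ("fixed", "best-consensus"):
            raise ValueError(f"unknown phase policy {self.phase_policy!r}")

    @property
    def motif_len_nt(self) -> int:
        return 3 * self.motif_len_aa


@dataclass
class Segmentation:
    motifs: list[str]
    prefix: str      # skipped leading residues when phase offset > 0
    remainder: str   # trailing block shorter than the motif length
    phase_offset: int

    def reconstruct(self) -> str:
        return self.prefix + "".join(self.motifs) + self.remainder


@dataclass
class MotifCatalog:
    motifs: list[str]
    occurrence_counts: dict[str, int]
    carrier_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.motifs)

    def singletons(self) -> list[str]:
        """Motifs private to a single haplotype."""
        return [m for m in self.motifs if self.carrier_counts[m] == 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif": self.motifs,
                "occurrences": [self.occurrence_counts[m] for m in self.motifs],
                "carriers": [self.carrier_counts[m] for m in self.motifs],
            }
        )


@dataclass
class UsageMatrix:
    values: pd.DataFrame  # rows = haplotypes, columns = motifs
    normalization_state: str = "raw"  # raw | row | row+column


def segment_vntr(domain_seq: str, cfg: MotifConfig) -> Segmentation:
    """Tile a VNTR domain into fixed-size motifs.

    ``fixed`` phase tiles from offset 0; ``best-consensus`` chooses the
    offset in [0, motif_len) maximizing the number of blocks whose first
    six residues equal the consensus prefix (ties -> smallest offset).
    """
    if not domain_seq:
        raise ValueError("empty domain sequence")
    L = cfg.motif_len_aa

    def tile(offset: int) -> list[str]:
        body = domain_seq[offset:]
        return [body[i : i + L] for i in range(0, len(body) - L + 1, L)]

    if cfg.phase_policy == "fixed":
        offset = 0
    else:
        k = len(cfg.consensus_prefix)
        offset = max(
            range(L),
            key=lambda o: (sum(m[:k] == cfg.consensus_prefix for m in tile(o)), -o),
        )
    motifs = tile(offset)
    used = offset + L * len(motifs)
    return Segmentation(
        motifs=motifs,
        prefix=domain_seq[:offset],
        remainder=domain_seq[used:],
        phase_offset=offset,
    )


def build_catalog(per_haplotype_motifs: dict[str, list[str]]) -> MotifCatalog:
    """Collect distinct motifs with cohort occurrence and carrier counts.

    Motif lists may pool several domains of one haplotype; all motifs must
    share one length (a uniform :class:`MotifConfig`).
    """
    lengths = {len(m) for motifs in per_haplotype_motifs.values() for m in motifs}
    if len(lengths) > 1:
        raise ValueError(f"mixed motif lengths {sorted(lengths)}")
    occurrence: Counter = Counter()
    carriers: Counter = Counter()
    for hap in sorted(per_haplotype_motifs):
        motifs = per_haplotype_motifs[hap]
        occurrence.update(motifs)
        carriers.update(set(motifs))
    ordered = sorted(occurrence, key=lambda m: (-occurrence[m], m))
    return MotifCatalog(ordered, dict(occurrence), dict(carriers))


def usage_matrix(
    catalog: MotifCatalog, per_haplotype_motifs: dict[str, list[str]]
) -> UsageMatrix:
    """Raw per-haplotype motif count matrix over the catalog columns."""
    rows = sorted(per_haplotype_motifs)
    known = set(catalog.motifs)
    data = np.zeros((len(rows), len(catalog.motifs)), dtype=float)
    col = {m: j for j, m in enumerate(catalog.motifs)}
    for i, hap in enumerate(rows):
        for m in per_haplotype_motifs[hap]:
            if m not in known:
                raise ValueError(f"motif {m!r} of {hap} not in catalog")
            data[i, col[m]] += 1
    return UsageMatrix(pd.DataFrame(data, index=rows, columns=catalog.motifs), "raw")


def normalize(matrix: UsageMatrix, mode: str = "row") -> UsageMatrix:
    """Normalize a raw usage matrix.

    ``row``: divide each row by its total motif count (accounts for VNTR
    length variation; zero-total rows stay zero).  ``row+column``: then
    min-max scale each column to [0, 1]; constant columns map to 0.
    """
    if mode not in ("row", "row+column"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    vals = matrix.values.to_numpy(dtype=float, copy=True)
    totals = vals.sum(axis=1, keepdims=True)
    np.divide(vals, totals, out=vals, where=totals > 0)
    if mode == "row+column":
        lo = vals.min(axis=0, keepdims=True)
        hi = vals.max(axis=0, keepdims=True)
        span = hi - lo
        with np.errstate(invalid="ignore"):
            vals = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1), 0.0)
    return UsageMatrix(
        pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        mode,
    )


@dataclass
class UpgmaNode:
    """Node of an UPGMA merge tree; height is the ultrametric node height
    (half the average inter-cluster distance at the merge)."""

    height: float
    leaf: str | None = None
    children: tuple["UpgmaNode", "UpgmaNode"] | None = None

    @property
    def n_leaves(self) -> int:
        if self.leaf is not None:
            return 1
        return sum(c.n_leaves for c in self.children)

    def leaf_order(self) -> list[str]:
        """Traversal order: smaller subtree first, ties lexicographic."""
        if self.leaf is not None:
            return [self.leaf]
        a, b = (c.leaf_order() for c in self.children)
        if (len(a), a[0]) > (len(b), b[0]):
            a, b = b, a
        return a + b

    def merge_sequence(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merges as (left leaves, right leaves, height), in chronological
        (nondecreasing-height) order; ties by smallest member label."""
        def collect(node: UpgmaNode) -> list:
            if node.leaf is not None:
                return []
            out = []
            for c in node.children:
                out.extend(collect(c))
            l, r = (frozenset(c.leaf_order()) for c in node.children)
            if min(l) > min(r):
                l, r = r, l
            out.append((l, r, node.height))
            return out

        return sorted(collect(self), key=lambda m: (m[2], min(m[0])))

    def newick(self) -> str:
        def fmt(node: UpgmaNode, parent_h: float) -> str:
            blen = parent_h - node.height
            if node.leaf is not None:
                return f"{node.leaf}:{blen:.6g}"
            a, b = node.children
            order = node.leaf_order()
            first = a if a.leaf_order()[0] == order[0] else b
            second = b if first is a else a
            inner = ",".join(fmt(c, node.height) for c in (first, second))
            return f"({inner}):{blen:.6g}"

        if self.leaf is not None:
            return f"{self.leaf};"
        a, b = self.children
        if a.leaf_order()[0] != self.leaf_order()[0]:
            a, b = b, a
        return f"({fmt(a, self.height)},{fmt(b, self.height)});"


def upgma_cluster(
    matrix: UsageMatrix, axis: str = "rows", metric: str = "euclidean"
) -> UpgmaNode:
    """UPGMA (unweighted average linkage) over matrix rows or columns.

    At each step the closest pair of clusters merges; the new node's height
    is half the unweighted average of all member pairwise distances; the
    distance from the merged cluster to any other is the size-weighted
    (i.e. unweighted over leaf pairs) average.  Deterministic: ties break
    by the lexicographically smallest pair of cluster representatives.
    """
    df = matrix.values if axis == "rows" else matrix.values.T
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    labels = [str(x) for x in df.index]
    if len(labels) < 2:
        raise ValueError("need at least two leaves to cluster")
    X = df.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    D = squareform(pdist(X, metric=metric))

    nodes: dict[str, UpgmaNode] = {lab: UpgmaNode(0.0, leaf=lab) for lab in labels}
    sizes = {lab: 1 for lab in labels}
    dist = {
        (a, b): D[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def d(a: str, b: str) -> float:
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    active = sorted(labels)
    while len(active) > 1:
        best = min(
            ((d(a, b), a, b) for i, a in enumerate(active) for b in active[i + 1 :]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dm, a, b = best
        merged = UpgmaNode(dm / 2.0, children=(nodes[a], nodes[b]))
        key = min(a, b)
        active = [x for x in active if x not in (a, b)]
        for x in active:
            new = (sizes[a] * d(a, x) + sizes[b] * d(b, x)) / (sizes[a] + sizes[b])
            for stale in ((x, a), (a, x), (x, b), (b, x)):
                dist.pop(stale, None)
            dist[(key, x)] = new
        nodes[key] = merged
        sizes[key] = sizes[a] + sizes[b]
        active.append(key)
        active.sort()
    return nodes[active[0]]


def st_content(motifs: list[str]) -> tuple[int, float]:
    """Absolute serine+threonine count and percent S/T over pooled motifs."""
    total = sum(len(m) for m in motifs)
    st = sum(m.count("S") + m.count("T") for m in motifs)
    if total == 0:
        raise ValueError("percent S/T undefined for an empty motif list")
    return st, 100.0 * st / total


def position_frequencies(
    catalog: MotifCatalog, weighting: str = "unique"
) -> pd.DataFrame:
    """Per-position residue frequencies across catalog motifs (PFM).

    ``unique`` counts each distinct motif once; ``occurrence`` weights each
    motif by its cohort occurrence count.  Rows are positions (0-based),
    columns residues; each row sums to 1.
    """
    if weighting not in ("unique", "occurrence"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if not catalog.motifs:
        raise ValueError("empty catalog")
    lengths = {len(m) for m in catalog.motifs}
    if len(lengths) != 1:
        raise ValueError("ragged motif lengths")
    L = lengths.pop()
    counts: list[Counter] = [Counter() for _ in range(L)]
    for m in catalog.motifs:
        w = 1 if weighting == "unique" else catalog.occurrence_counts[m]
        for i, aa in enumerate(m):
            counts[i][aa] += w
    residues = sorted({aa for c in counts for aa in c})
    pfm = pd.DataFrame(0.0, index=range(L), columns=residues)
    for i, c in enumerate(counts):
        tot = sum(c.values())
        for aa, k in c.items():
            pfm.loc[i, aa] = k / tot
    return pfm
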