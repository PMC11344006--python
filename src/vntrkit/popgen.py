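"""Binned Tajima's D selection scan with a permutation null, plus
Hardy-Weinberg and contingency chi-square machinery.

Tajima's D contrasts mean pairwise nucleotide diversity (pi) with the
scaled segregating-site count S/a1; an excess of rare variants drives D
negative (a signature of positive selection or expansion), an excess of
common variants drives it positive (balancing selection).  Genomic bins
(default 10 kbp, >= 10 SNPs) are scored and flagged against an
autosome-wide background by percentile, and an empirical permutation null
of per-replicate tail-percentile cut points yields p-values with
Bonferroni correction over bins x populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import chi2

__all__ = [
    "HaplotypeMatrix",
    "TajimaDResult",
    "BinStat",
    "PermutationNull",
    "HWEResult",
    "tajimas_d",
    "tajima_constants",
    "bin_scan",
    "percentile_flags",
    "permutation_test",
    "hwe_test",
    "contingency_chisq",
    "classify_vntr_lengths",
]

MISSING = -1  # sentinel for a missing allele in int matrices


@dataclass
class HaplotypeMatrix:
    """Phased biallelic matrix: rows = haplotypes, columns = sites.

    ``alleles`` holds 0/1 with ``MISSING`` (-1) for missing calls.
    Positions are 0-based bp offsets, strictly increasing.
    """

    sequence_name: str
    site_positions: np.ndarray  # (S,)
    alleles: np.ndarray         # (n_hap, S) int8
    sample_ids: list[str] = field(default_factory=list)
    population_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[1] != self.site_positions.size:
            raise ValueError("alleles must be (n_haplotypes, n_sites)")
        if self.site_positions.size > 1 and not np.all(np.diff(self.site_positions) > 0):
            raise ValueError("site positions must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def restrict(self, start: int, end: int) -> "HaplotypeMatrix":
        """Sites with position in [start, end)."""
        keep = (self.site_positions >= start) & (self.site_positions < end)
        return HaplotypeMatrix(
            self.sequence_name,
            self.site_positions[keep],
            self.alleles[:, keep],
            list(self.sample_ids),
            list(self.population_labels),
        )

    def subset_haplotypes(self, indices) -> "HaplotypeMatrix":
        """Haplotype subset, e.g. carriers of one haplogroup label."""
        idx = np.asarray(indices)
        return HaplotypeMatrix(
            self.sequence_name,
            self.site_positions.copy(),
            self.alleles[idx],
            [self.sample_ids[i] for i in idx],
            [self.population_labels[i] for i in idx] if self.population_labels else [],
        )


@dataclass(frozen=True)
class TajimaDResult:
    n: int
    S: int
    pi: float
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    D: float | None  # None when undefined (S=0 or vanishing variance)

    @property
    def defined(self) -> bool:
        return self.D is not None


@dataclass
class BinStat:
    sequence_name: str
    start: int
    end: int
    snp_count: int
    tajima: TajimaDResult
    percentile_rank: float | None = None
    flags: frozenset = frozenset()
    p_empirical: float | None = None
    p_adjusted: float | None = None


@dataclass(frozen=True)
class PermutationNull:
    """Null of per-replicate tail-percentile cut points.

    Each replicate samples ``n_bins_per_replicate`` background bin values
    and records its ``percentile_level`` (lower tail) or
    100 - ``percentile_level`` (upper tail) percentile.
    """

    tail: str  # lower | upper
    n_bins_per_replicate: int = 10_000
    n_replicates: int = 10_000
    percentile_level: float = 5.0
    seed: int = 0
    null_values: np.ndarray | None = None
    pooled: bool = False  # alternative reading: pool sampled values instead

    def __post_init__(self) -> None:
        if self.tail not in ("lower", "upper"):
            raise ValueError("tail must be 'lower' or 'upper'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants of Tajima's test statistic for n haplotypes."""
    if n < 2:
        raise ValueError("need at least two haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(
    matrix: HaplotypeMatrix, max_missing_fraction: float = 0.25
) -> TajimaDResult:
    """Tajima's D over all sites of a (region-restricted) matrix.

    pi is the mean over all haplotype pairs of per-site disagreements,
    counted pairwise-complete over non-missing calls; sites with more than
    ``max_missing_fraction`` missing calls are excluded from both S and pi.
    Degenerate cases (S = 0, or n = 2 where the variance constants vanish
    exactly) return ``D = None`` rather than raising.
    """
    n = matrix.n_haplotypes
    if n < 2:
        raise ValueError("need at least two haplotypes")
    A = matrix.alleles
    missing = A == MISSING
    keep = missing.mean(axis=0) <= max_missing_fraction
    A = A[:, keep]
    missing = missing[:, keep]

    obs = ~missing
    ones = np.where(obs, A == 1, False)
    n_obs = obs.sum(axis=0)
    n_one = ones.sum(axis=0)
    seg = (n_one > 0) & (n_one < n_obs) & (n_obs >= 2)
    S = int(seg.sum())

    # pairwise-complete pi: per site, mismatching informative pairs
    # = ones * zeros; averaged over the fixed number of haplotype pairs.
    n_zero = n_obs - n_one
    diffs = (n_one[seg] * n_zero[seg]).astype(float)
    pairs = n * (n - 1) / 2.0
    pi = float(diffs.sum() / pairs)

    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    if S == 0 or var <= 0:
        D = None
    else:
        D = (pi - S / k["a1"]) / math.sqrt(var)
    return TajimaDResult(n=n, S=S, pi=pi, D=D, **k)


def bin_scan(
    matrix: HaplotypeMatrix,
    sequence_length: int,
    bin_size: int = 10_000,
    min_snps: int = 10,
) -> list[BinStat]:
    """Tajima's D in consecutive half-open bins [k*b, (k+1)*b).

    Bins with fewer than ``min_snps`` segregating sites are dropped, after
    the common practice for binned selection scans.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if matrix.n_sites and int(matrix.site_positions[-1]) >= sequence_length:
        raise ValueError("site positions exceed sequence_length")
    out = []
    for start in range(0, sequence_length, bin_size):
        end = min(start + bin_size, sequence_length)
        sub = matrix.restrict(start, end)
        if sub.n_sites == 0:
            continue
        res = tajimas_d(sub)
        if res.S < min_snps:
            continue
        out.append(BinStat(matrix.sequence_name, start, end, res.S, res))
    return out


def _percentile_rank(value: float, background: np.ndarray) -> float:
    return float(np.sum(background < value)) / background.size


def percentile_flags(bins: list[BinStat], background) -> list[BinStat]:
    """Rank each bin's D against a background distribution and flag tails.

    percentile_rank is the fraction of background values strictly below the
    bin's D; flags: bottom5 (< 0.05), bottom10 (< 0.10), top5 (> 0.95),
    top10 (> 0.90).  Bins with undefined D are passed through unranked.
    """
    bg = np.asarray([v for v in background if v is not None and np.isfinite(v)], float)
    if bg.size == 0:
        raise ValueError("empty background")
    out = []
    for b in bins:
        if not b.tajima.defined:
            out.append(b)
            continue
        rank = _percentile_rank(b.tajima.D, bg)
        flags = set()
        if rank < 0.10:
            flags.add("bottom10")
        if rank < 0.05:
            flags.add("bottom5")
        if rank > 0.90:
            flags.add("top10")
        if rank > 0.95:
            flags.add("top5")
        out.append(replace_bin(b, percentile_rank=rank, flags=frozenset(flags)))
    return out


def replace_bin(b: BinStat, **kw) -> BinStat:
    return replace(b, **kw)


def build_permutation_null(background, cfg: PermutationNull) -> PermutationNull:
    """Sample the replicate tail-percentile cut points from the background.

    Sampling is without replacement when the background holds at least
    ``n_bins_per_replicate`` values, else with replacement.  Identical seed
    gives bit-identical null values.
    """
    bg = np.asarray([v for v in background if v is not None and np.isfinite(v)], float)
    if bg.size == 0:
        raise ValueError("empty background")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_bins_per_replicate
    with_replacement = bg.size < m
    q = cfg.percentile_level if cfg.tail == "lower" else 100.0 - cfg.percentile_level
    if cfg.pooled:
        samples = rng.choice(bg, size=(cfg.n_replicates, m), replace=True)
        null = np.sort(samples.ravel())
    else:
        null = np.empty(cfg.n_replicates)
        for r in range(cfg.n_replicates):
            sample = rng.choice(bg, size=m, replace=with_replacement)
            null[r] = np.percentile(sample, q)
    return replace(cfg, null_values=null)


def permutation_test(
    bins: list[BinStat],
    background,
    cfg: PermutationNull,
    n_tests: int | None = None,
) -> tuple[list[BinStat], PermutationNull]:
    """Empirical p-values against the permutation null of cut points.

    For the lower tail, p = (1 + #{cut points <= D}) / (1 + R): small when
    D is more negative than essentially every replicate's lower-percentile
    cut point.  Upper tail mirrors with >=.  p_adjusted is Bonferroni over
    ``n_tests`` (bins x populations; defaults to len(bins)).
    """
    if cfg.null_values is None:
        cfg = build_permutation_null(background, cfg)
    null = np.sort(cfg.null_values)
    R = null.size
    if n_tests is None:
        n_tests = len(bins)
    out = []
    for b in bins:
        if not b.tajima.defined:
            out.append(b)
            continue
        D = b.tajima.D
        if cfg.tail == "lower":
            k = int(np.searchsorted(null, D, side="right"))  # cut points <= D
        else:
            k = R - int(np.searchsorted(null, D, side="left"))  # cut points >= D
        p = (1.0 + k) / (1.0 + R)
        out.append(replace_bin(b, p_empirical=p, p_adjusted=min(1.0, p * n_tests)))
    return out, cfg


@dataclass(frozen=True)
class HWEResult:
    observed: tuple[int, int, int]  # hom_ref, het, hom_alt
    allele_freq: float              # frequency of the "ref" allele
    expected: tuple[float, float, float]
    chi_square: float
    df: int
    p_value: float


def hwe_test(observed: tuple[int, int, int]) -> HWEResult:
    """One-degree chi-square test for departure from Hardy-Weinberg.

    Allele frequency is estimated from the genotype counts; expected counts
    are (p^2 N, 2pq N, q^2 N).  Monomorphic input (one allele absent) has no
    testable expectation and raises ValueError.
    """
    hom_ref, het, hom_alt = (int(x) for x in observed)
    if min(hom_ref, het, hom_alt) < 0:
        raise ValueError("negative genotype count")
    N = hom_ref + het + hom_alt
    if N == 0:
        raise ValueError("no observations")
    p = (2 * hom_ref + het) / (2.0 * N)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise ValueError("monomorphic input: HWE test undefined")
    expected = (p * p * N, 2 * p * q * N, q * q * N)
    x2 = sum((o - e) ** 2 / e for o, e in zip((hom_ref, het, hom_alt), expected))
    return HWEResult((hom_ref, het, hom_alt), p, expected, x2, 1, float(chi2.sf(x2, 1)))


def contingency_chisq(table) -> tuple[float, int, float, bool]:
    """Pearson chi-square on an r x c table, no continuity correction.

    Returns (chi_square, df, p_value, low_expected_warning); the warning is
    True when any expected cell is below 5.  Zero marginals raise.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2 or T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (T < 0).any():
        raise ValueError("negative counts")
    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row/column margin")
    E = np.outer(rows, cols) / T.sum()
    x2 = float(((T - E) ** 2 / E).sum())
    df = (T.shape[0] - 1) * (T.shape[1] - 1)
    return x2, df, float(chi2.sf(x2, df)), bool((E < 5).any())


def classify_vntr_lengths(
    lengths: dict[str, float],
    short_max: float = 1_500,
    long_min: float = 2_000,
    groups: dict[str, str] | None = None,
):
    """Classify VNTR lengths into short/intermediate/long classes.

    short: strictly below ``short_max``; long: strictly above ``long_min``;
    intermediate otherwise (the boundary values themselves are
    intermediate).  With ``groups`` given, returns additionally the
    class x group contingency table and its chi-square enrichment test.
    """
    import pandas as pd

    if any(v <= 0 for v in lengths.values()):
        raise ValueError("lengths must be positive")

    def cls(v: float) -> str:
        if v < short_max:
            return "short"
        if v > long_min:
            return "long"
        return "intermediate"

    classes = {h: cls(v) for h, v in lengths.items()}
    if groups is None:
        return classes
    df = pd.DataFrame(
        {"cls": [classes[h] for h in sorted(lengths)],
         "group": [groups[h] for h in sorted(lengths)]}
    )
    table = pd.crosstab(df["cls"], df["group"])
    # with a single class (or single group) there is nothing to contrast:
    # the enrichment statistic is identically zero
    if table.shape[0] < 2 or table.shape[1] < 2:
        return classes, table, (0.0, 0, 1.0, False)
    return classes, table, contingency_chisq(table.to_numpy())
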