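"""Linkage disequilibrium statistics, Gabriel haplotype blocks, and
haplogroup tag-SNP discovery from phased haplotypes.

D' is Lewontin's normalized LD coefficient (D divided by its maximum
attainable magnitude given the allele frequencies); r^2 the squared allele
correlation.  Blocks follow the Gabriel et al. definition: pairs whose
confidence interval on |D'| indicates "strong LD" (lower bound >= 0.70,
upper >= 0.98) must make up at least 95% of informative pairs, where pairs
with CI upper bound < 0.90 show "strong recombination".  Confidence
intervals come from a nonparametric bootstrap over haplotypes.  Haplogroup
labels are encoded as biallelic pseudo-sites so that tag SNPs (tSNPs) can
be found as the sites whose r^2 with the pseudo-site exceeds a threshold
(strictly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import MISSING, HaplotypeMatrix, hwe_test

__all__ = [
    "LDPairStats",
    "LDBlock",
    "TSNPHit",
    "ld_pair",
    "filter_sites",
    "gabriel_blocks",
    "block_size_percentile",
    "encode_haplogroup",
    "append_pseudo_site",
    "discover_tsnps",
    "haplotypes_to_genotypes",
]

PSEUDO_SITE_POSITION = -1  # sentinel: cannot collide with real (>=0) sites


@dataclass(frozen=True)
class LDPairStats:
    pA: float           # allele-1 frequency at the first site
    pB: float           # allele-1 frequency at the second site
    pAB: float          # joint frequency of the 1/1 gamete
    D_raw: float
    Dmax: float
    D_prime: float
    r_squared: float
    n_informative: int


@dataclass(frozen=True)
class LDBlock:
    sequence_name: str
    start: int                   # bp of first member site
    end: int                     # bp after last member site (half-open)
    member_sites: tuple[int, ...]  # site indices into the filtered matrix
    strong_pair_fraction: float

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        return len(self.member_sites)


@dataclass(frozen=True)
class TSNPHit:
    site_position: int
    r_squared: float
    passes_threshold: bool


def _pair_stats(x: np.ndarray, y: np.ndarray) -> LDPairStats:
    obs = (x != MISSING) & (y != MISSING)
    n = int(obs.sum())
    if n == 0:
        raise ValueError("no informative haplotypes for this pair")
    xi = x[obs].astype(float)
    yi = y[obs].astype(float)
    pA = xi.mean()
    pB = yi.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site: LD undefined")
    pAB = float((xi * yi).mean())
    D = pAB - pA * pB
    if D > 0:
        Dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        Dmax = min(pA * pB, (1 - pA) * (1 - pB))
    Dp = D / Dmax if Dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDPairStats(pA, pB, pAB, D, Dmax, Dp, r2, n)


def ld_pair(matrix: HaplotypeMatrix, i: int, j: int) -> LDPairStats:
    """Pairwise D', r^2 between sites ``i`` and ``j`` (pairwise-complete)."""
    return _pair_stats(matrix.alleles[:, i], matrix.alleles[:, j])


def haplotypes_to_genotypes(matrix: HaplotypeMatrix) -> np.ndarray:
    """Pair consecutive haplotypes (2k, 2k+1) into diploid genotypes.

    Returns an (n_individuals, n_sites) array of alt-allele dosages 0/1/2,
    with MISSING where either haplotype is missing.
    """
    A = matrix.alleles
    if A.shape[0] % 2:
        raise ValueError("odd haplotype count cannot be paired into diploids")
    a, b = A[0::2], A[1::2]
    g = (a + b).astype(np.int8)
    g[(a == MISSING) | (b == MISSING)] = MISSING
    return g


def filter_sites(
    matrix: HaplotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.75,
    hwe_alpha: float | None = 1e-3,
) -> tuple[HaplotypeMatrix, dict[str, int]]:
    """Apply the standard pre-LD site filters.

    Removes sites with minor allele frequency < ``maf_min``, diploid
    genotyping rate < ``call_rate_min``, or Hardy-Weinberg departure at
    ``hwe_alpha`` (skipped when None).  Returns the filtered matrix and the
    per-filter removal counts.
    """
    A = matrix.alleles
    obs = A != MISSING
    n_obs = obs.sum(axis=0)
    n_one = np.where(obs, A == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, n_one / np.maximum(n_obs, 1), 0.0)
    maf = np.minimum(freq, 1 - freq)

    keep = np.ones(matrix.n_sites, dtype=bool)
    log = {"maf": 0, "call_rate": 0, "hwe": 0}

    fail_maf = maf < maf_min
    log["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    g = haplotypes_to_genotypes(matrix) if matrix.n_haplotypes % 2 == 0 else None
    if g is not None:
        call_rate = (g != MISSING).mean(axis=0)
        fail_cr = keep & (call_rate < call_rate_min)
        log["call_rate"] = int(fail_cr.sum())
        keep &= ~fail_cr
        if hwe_alpha is not None:
            for s in np.nonzero(keep)[0]:
                gs = g[:, s]
                gs = gs[gs != MISSING]
                counts = (int((gs == 0).sum()), int((gs == 1).sum()), int((gs == 2).sum()))
                try:
                    if hwe_test(counts).p_value < hwe_alpha:
                        keep[s] = False
                        log["hwe"] += 1
                except ValueError:
                    pass  # monomorphic among called genotypes: not testable
    filtered = HaplotypeMatrix(
        matrix.sequence_name,
        matrix.site_positions[keep],
        matrix.alleles[:, keep],
        list(matrix.sample_ids),
        list(matrix.population_labels),
    )
    return filtered, log


def _bootstrap_abs_dprime_ci(
    X: np.ndarray, n_boot: int, seed: int, q_lo: float = 5.0, q_hi: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI on |D'| for every site pair, vectorized.

    X is a complete (no-missing) 0/1 haplotype matrix.  One index resample
    per replicate is shared across pairs.  Pairs monomorphic in a replicate
    contribute NaN to that replicate and are ignored by the percentile.
    """
    n, m = X.shape
    rng = np.random.default_rng(seed)
    Xf = X.astype(np.float64)
    vals = np.empty((n_boot, m, m))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb = Xf[idx]
        p = Xb.mean(axis=0)
        P11 = (Xb.T @ Xb) / n
        D = P11 - np.outer(p, p)
        pos = np.minimum(np.outer(p, 1 - p), np.outer(1 - p, p))
        neg = np.minimum(np.outer(p, p), np.outer(1 - p, 1 - p))
        Dmax = np.where(D > 0, pos, neg)
        poly = (p > 0) & (p < 1)
        ok = np.outer(poly, poly) & (Dmax > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals[b] = np.where(ok, np.abs(D) / np.where(ok, Dmax, 1.0), np.nan)
    with np.errstate(all="ignore"):
        lo = np.nanpercentile(vals, q_lo, axis=0)
        hi = np.nanpercentile(vals, q_hi, axis=0)
    return lo, hi


def gabriel_blocks(
    matrix: HaplotypeMatrix,
    max_span_bp: int = 200_000,
    n_boot: int = 200,
    seed: int = 0,
    strong_lo: float = 0.70,
    strong_hi: float = 0.98,
    recomb_hi: float = 0.90,
    min_strong_fraction: float = 0.95,
) -> list[LDBlock]:
    """Gabriel-definition haplotype blocks from phased haplotypes.

    A pair is in strong LD when its bootstrap CI on |D'| has lower bound
    >= ``strong_lo`` and upper bound >= ``strong_hi``; it shows strong
    recombination when the upper bound < ``recomb_hi``.  Candidate site
    ranges where strong pairs are >= ``min_strong_fraction`` of informative
    (strong + recombination) pairs are accepted greedily from largest bp
    span to smallest, skipping overlaps.
    """
    m = matrix.n_sites
    if m < 2:
        return []
    pos = matrix.site_positions
    A = matrix.alleles
    if (A == MISSING).any():
        raise ValueError("gabriel_blocks expects a complete (filtered) matrix")
    lo, hi = _bootstrap_abs_dprime_ci(A, n_boot, seed)

    strong = (lo >= strong_lo) & (hi >= strong_hi)
    recomb = hi < recomb_hi
    informative = (strong | recomb) & ~np.isnan(hi)

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if pos[j] - pos[i] > max_span_bp:
                break
            sl = slice(i, j + 1)
            n_inf = int(np.triu(informative[sl, sl], k=1).sum())
            n_str = int(np.triu(strong[sl, sl], k=1).sum())
            if n_inf == 0 or n_str == 0:
                continue
            if n_str / n_inf >= min_strong_fraction:
                candidates.append((int(pos[j] - pos[i] + 1), i, j, n_str / n_inf))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    blocks: list[LDBlock] = []
    taken = np.zeros(m, dtype=bool)
    for span, i, j, frac in candidates:
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        blocks.append(
            LDBlock(
                matrix.sequence_name,
                int(pos[i]),
                int(pos[j]) + 1,
                tuple(range(i, j + 1)),
                frac,
            )
        )
    blocks.sort(key=lambda b: b.start)
    return blocks


def block_size_percentile(block_sizes, query_size: float) -> float:
    """Fraction of background block sizes strictly smaller than the query."""
    bg = np.asarray(list(block_sizes), dtype=float)
    if bg.size == 0:
        raise ValueError("empty background")
    return float(np.sum(bg < query_size)) / bg.size


def encode_haplogroup(labels: dict[str, str], target: str, order=None) -> np.ndarray:
    """Encode a haplogroup as a biallelic pseudo-site column.

    1 for haplotypes labeled ``target``, 0 otherwise; ``order`` fixes the
    haplotype ordering (defaults to sorted label keys).
    """
    if target not in set(labels.values()):
        raise ValueError(f"unknown haplogroup {target!r}")
    if order is None:
        order = sorted(labels)
    missing = [h for h in order if h not in labels]
    if missing:
        raise ValueError(f"unlabeled haplotypes: {missing[:5]}")
    return np.array([1 if labels[h] == target else 0 for h in order], dtype=np.int8)


def append_pseudo_site(matrix: HaplotypeMatrix, column: np.ndarray) -> HaplotypeMatrix:
    """Prepend the pseudo-site at the sentinel position (-1)."""
    return HaplotypeMatrix(
        matrix.sequence_name,
        np.concatenate(([PSEUDO_SITE_POSITION], matrix.site_positions)),
        np.column_stack([column.astype(np.int8), matrix.alleles]),
        list(matrix.sample_ids),
        list(matrix.population_labels),
    )


def discover_tsnps(
    matrix: HaplotypeMatrix,
    pseudo_site: np.ndarray,
    window: tuple[int, int],
    r2_threshold: float = 0.85,
    positions=None,
) -> list[TSNPHit]:
    """Score sites against a haplogroup pseudo-site by r^2.

    Every site whose position falls in the half-open ``window`` (or in the
    explicit ``positions`` list, e.g. externally supplied GWAS risk SNPs)
    is scored; hits require r^2 strictly greater than the threshold.
    Output is sorted by descending r^2 then position.  Sites monomorphic
    among informative haplotypes are skipped (undefined LD).
    """
    if positions is not None:
        wanted = set(int(p) for p in positions)
        idx = [k for k, p in enumerate(matrix.site_positions) if int(p) in wanted]
    else:
        start, end = window
        idx = [
            k for k, p in enumerate(matrix.site_positions) if start <= int(p) < end
        ]
    hits = []
    for k in idx:
        try:
            stats = _pair_stats(matrix.alleles[:, k], pseudo_site)
        except ValueError:
            continue
        hits.append(
            TSNPHit(int(matrix.site_positions[k]), stats.r_squared,
                    stats.r_squared > r2_threshold)
        )
    hits.sort(key=lambda h: (-h.r_squared, h.site_position))
    return hits
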