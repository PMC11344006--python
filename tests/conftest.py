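import numpy as np
import pytest

from vntrkit.popgen import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_hapmatrix(rng, n_hap, n_sites, region=None):
    """Random segregating biallelic matrix (every site polymorphic)."""
    region = region or n_sites * 10
    A = np.zeros((n_hap, n_sites), dtype=np.int8)
    for s in range(n_sites):
        k = int(rng.integers(1, n_hap))
        A[rng.choice(n_hap, size=k, replace=False), s] = 1
    pos = np.sort(rng.choice(region, size=n_sites, replace=False))
    return HaplotypeMatrix("chr", pos, A)


# --- independent oracles (kept deliberately naive) ---------------------------

def brute_tajimas_d(alleles):
    """Direct pairwise-difference Tajima's D; None when undefined."""
    import itertools, math

    n, S_total = alleles.shape
    seg = [
        s for s in range(S_total)
        if len({a for a in alleles[:, s] if a >= 0}) == 2
    ]
    S = len(seg)
    diffs = []
    for i, j in itertools.combinations(range(n), 2):
        d = 0
        for s in seg:
            a, b = alleles[i, s], alleles[j, s]
            if a >= 0 and b >= 0 and a != b:
                d += 1
        diffs.append(d)
    pi = sum(diffs) / len(diffs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if S == 0 or var <= 0:
        return None
    return (pi - S / a1) / math.sqrt(var)


def brute_upgma(labels, D):
    """Naive UPGMA over a full distance matrix.

    Clusters are frozensets; at each step the pair with the smallest mean
    leaf-pair distance merges at half that distance.  Returns the merge
    sequence [(left, right, height)] with left holding the smaller minimum
    label.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    clusters = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for x in clusters:
            for y in clusters:
                if min(x) >= min(y):
                    continue
                d = sum(D[index[a]][index[b]] for a in x for b in y) / (len(x) * len(y))
                key = (d, min(x), min(y))
                if best is None or key < best[0]:
                    best = (key, x, y)
        d, x, y = best[0][0], best[1], best[2]
        merges.append((x, y, d / 2.0))
        clusters = [c for c in clusters if c not in (x, y)] + [x | y]
    return merges
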