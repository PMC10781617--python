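"""Shared simulation designs used by unit and acceptance tests."""
import numpy as np

from paleoturnover.genotypes import GenotypeTable, SiteRecord


def simulate_tree_table(seed, n_sites=5000, n_per=4, flow=0.0, F=0.1):
    """Pseudo-haploid genotypes on the tree (((P1,P2),P3),P4).

    ``flow`` admixes the P2 branch with fraction ``flow`` from P3 after the
    P1/P2 split (introgression), which creates an ABBA excess (negative D
    under the BABA-positive convention).  All sites use a transversion
    allele pair.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, n_sites)

    def drift(p, f):
        s = (1 - f) / f
        return np.clip(rng.beta(p * s, (1 - p) * s), 1e-6, 1 - 1e-6)

    p123 = drift(p0, F)
    p12 = drift(p123, 2 * F)
    p3 = drift(p123, 2 * F)
    p1 = drift(p12, F)
    p2 = drift(p12, F)
    if flow > 0:
        p2 = (1 - flow) * p2 + flow * p3
    ps = [p1, p2, p3, drift(p0, F)]
    cols, groups, samples = [], [], []
    for gi, p in enumerate(ps):
        alleles = rng.random((n_sites, n_per)) < p[:, None]
        cols.append((2 * alleles).astype(np.int8))
        groups.append([f"P{gi + 1}_{k}" for k in range(n_per)])
        samples += groups[-1]
    sites = [
        SiteRecord(str(1 + j // 100), (j % 100) * 50000 + 1, "A", "C", site_id=f"v{j}")
        for j in range(n_sites)
    ]
    return GenotypeTable(samples, sites, np.hstack(cols), np.ones(len(samples), bool)), groups


def peaked_sources(n_sources=3, n_features=9):
    """Well-separated relative sharing profiles (one dominant block each)."""
    S = {}
    for k in range(n_sources):
        v = np.full(n_features, 0.01)
        v[3 * k] = 0.85
        v[3 * k + 1] = 0.10
        v[3 * k + 2] = 0.03
        S[chr(ord("A") + k)] = v / v.sum()
    return S


def grid_weight_targets(sources, noise_sd=0.01, n_targets=20, seed=0):
    """Targets with true weights on a simplex grid plus feature noise."""
    rng = np.random.default_rng(seed)
    names = list(sources)
    S = np.column_stack([sources[n] for n in names])
    grid = [
        (a / 4, b / 4, 1 - a / 4 - b / 4)
        for a in range(5)
        for b in range(5 - a)
    ]
    targets = []
    for i in range(n_targets):
        w = np.array(grid[i % len(grid)], dtype=float)
        y = S @ w + rng.normal(0.0, noise_sd, S.shape[0])
        targets.append((w, np.clip(y, 1e-9, None)))
    return names, targets


def simulate_admixed_haplotypes(seed, g_true=20.0, alpha=0.4, n_hap=200, n_sites=500):
    """Haplotypes from a two-state Markov local-ancestry process whose
    ancestry LD decays as exp(-g * d), then alleles drawn from the local
    source frequency."""
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, 1.0, n_sites))
    pA = rng.uniform(0.1, 0.9, n_sites)
    pB = np.clip(pA + rng.choice([-1, 1], n_sites) * rng.uniform(0.2, 0.5, n_sites), 0.02, 0.98)
    d = np.diff(pos)
    H = np.zeros((n_hap, n_sites), dtype=np.int8)
    for h in range(n_hap):
        x = np.empty(n_sites, bool)
        x[0] = rng.random() < alpha
        for j in range(1, n_sites):
            if rng.random() < np.exp(-g_true * d[j - 1]):
                x[j] = x[j - 1]
            else:
                x[j] = rng.random() < alpha
        p = np.where(x, pA, pB)
        H[h] = rng.random(n_sites) < p
    return H, pos, pA, pB
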