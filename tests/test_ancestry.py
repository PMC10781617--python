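import itertools

import numpy as np
import pytest

from paleoturnover.ancestry import (
    admixture_date,
    d_statistic,
    fit_reference_pca,
    lsq_project,
    mixture_from_matrix,
    nnls_mixture,
)
from paleoturnover.genotypes import MISSING, GenotypeTable, SiteRecord
from paleoturnover.ibd import IBDShareMatrix

from simulators import (
    grid_weight_targets,
    peaked_sources,
    simulate_admixed_haplotypes,
    simulate_tree_table,
)


# ---------------------------------------------------------------------------
# nnls_mixture
# ---------------------------------------------------------------------------

def test_target_equal_to_source():
    A = np.array([0.4, 0.1, 0.5])
    B = np.array([0.1, 0.8, 0.1])
    res = nnls_mixture(A.copy(), {"A": A, "B": B})
    assert res.weights[0] == pytest.approx(1.0, abs=1e-10)
    assert res.weights[1] == pytest.approx(0.0, abs=1e-10)
    assert res.residual_norm == pytest.approx(0.0, abs=1e-10)


def test_equal_mixture_of_orthogonal_sources():
    A = np.array([1.0, 0.0, 0.0, 0.0])
    B = np.array([0.0, 1.0, 0.0, 0.0])
    y = 0.5 * A + 0.5 * B
    res = nnls_mixture(y, {"A": A, "B": B})
    assert np.allclose(res.weights, [0.5, 0.5], atol=1e-12)
    assert res.residual_norm == pytest.approx(0.0, abs=1e-12)


def simplex_grid_search(y, S, step=0.01):
    """Brute-force NNLS-on-the-simplex oracle at fixed resolution."""
    best, best_err = None, np.inf
    grid = np.arange(0.0, 1.0 + 1e-12, step)
    for w1 in grid:
        w2 = 1.0 - w1
        err = np.linalg.norm(S @ np.array([w1, w2]) - y)
        if err < best_err:
            best, best_err = (w1, w2), err
    return np.array(best)


def test_nonnegativity_active_matches_grid_search():
    # y = A - 0.2*B clipped at 0 with B non-overlapping -> w_B should be 0
    A = np.array([0.5, 0.5, 0.0, 0.0])
    B = np.array([0.0, 0.0, 0.6, 0.4])
    y = np.clip(A - 0.2 * B, 0.0, None)
    res = nnls_mixture(y, {"A": A, "B": B})
    S = np.column_stack([A / A.sum(), B / B.sum()])
    oracle = simplex_grid_search(y / y.sum(), S, step=0.01)
    assert res.weights[1] == pytest.approx(0.0, abs=1e-10)
    assert np.allclose(res.weights, oracle, atol=0.01)


def test_all_zero_target_rejected():
    with pytest.raises(ValueError, match="no sharing signal"):
        nnls_mixture(np.zeros(3), {"A": np.ones(3), "B": np.ones(3)})


def test_collinear_sources_warn_but_return():
    A = np.array([0.5, 0.5, 0.0])
    with pytest.warns(UserWarning, match="collinear"):
        res = nnls_mixture(A, {"A": A, "B": 2 * A})
    assert res.weights.sum() == pytest.approx(1.0)


def test_weights_simplex_property():
    rng = np.random.default_rng(0)
    for _ in range(25):
        S = {n: rng.uniform(0, 1, 6) for n in "ABC"}
        y = rng.uniform(0, 1, 6)
        res = nnls_mixture(y, S)
        assert np.all(res.weights >= 0)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_recovery_with_feature_noise():
    """3-source grid-weight truth recovered within +/-0.05 at noise SD 0.01
    (20 seeds)."""
    sources = peaked_sources()
    max_err = 0.0
    for seed in range(20):
        names, targets = grid_weight_targets(sources, noise_sd=0.01, n_targets=20, seed=seed)
        for w_true, y in targets:
            res = nnls_mixture(y, sources)
            max_err = max(max_err, float(np.max(np.abs(res.weights - w_true))))
    assert max_err <= 0.05


def test_mixture_from_matrix_assigns_own_cluster():
    n = 12
    ids = [f"M{i:02d}" for i in range(n)]
    labels = np.repeat([0, 1, 2], 4)
    rate = np.where(labels[:, None] == labels[None, :], 0.02, 0.001)
    np.fill_diagonal(rate, 0.0)
    m = IBDShareMatrix(ids, rate * 3000.0, rate, 3000.0)
    groups = {f"g{k}": [ids[i] for i in range(n) if labels[i] == k] for k in range(3)}
    res = mixture_from_matrix(m, groups, "M00")
    assert res.sources[int(np.argmax(res.weights))] == "g0"
    assert res.weights[0] > 0.9


# ---------------------------------------------------------------------------
# d_statistic
# ---------------------------------------------------------------------------

def haploid_table(patterns, n_blocks=4):
    """One haploid (pseudo-haploid) sample per population; patterns are
    tuples of 0/1 ALT carriage for (P1, P2, P3, P4), repeated across blocks
    so the jackknife is defined."""
    sites = []
    rows = []
    i = 0
    for b in range(n_blocks):
        for pat in patterns:
            sites.append(SiteRecord(str(b + 1), (i % len(patterns)) * 100000 + 1, "A", "C", site_id=f"v{i}"))
            rows.append([2 * x for x in pat])
            i += 1
    dosages = np.array(rows, dtype=np.int8)
    return GenotypeTable(["p1", "p2", "p3", "p4"], sites, dosages, np.array([True] * 4))


GROUPS = (["p1"], ["p2"], ["p3"], ["p4"])


def enumeration_D(patterns, reps):
    """Per-site enumeration oracle for the frequency formula with p in {0,1}."""
    num = den = 0.0
    for pat in patterns * reps:
        p1, p2, p3, p4 = pat
        num += (p1 - p2) * (p3 - p4)
        den += (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4)
    return num / den


def test_pattern_count_oracle():
    # 3 BABA + 1 ABBA per block
    patterns = [(1, 0, 1, 0), (1, 0, 1, 0), (1, 0, 1, 0), (0, 1, 1, 0)]
    g = haploid_table(patterns)
    res = d_statistic(g, GROUPS, block_size=1.0)
    assert res.D == pytest.approx(enumeration_D(patterns, 4))
    assert res.D == pytest.approx((3 - 1) / (3 + 1))  # BABA-excess positive


def test_identical_p1_p2_gives_zero():
    # identical *sample sets* for P1 and P2: numerator is zero per site
    patterns = [(1, 0, 1, 0), (0, 1, 1, 0), (1, 1, 0, 1)]
    g = haploid_table(patterns)
    res = d_statistic(g, (["p1", "p2"], ["p1", "p2"], ["p3"], ["p4"]), block_size=1.0)
    assert res.D == 0.0


def test_sign_flips_under_swaps():
    patterns = [(1, 0, 1, 0), (1, 0, 1, 0), (0, 1, 1, 0)]
    g = haploid_table(patterns)
    d0 = d_statistic(g, GROUPS, block_size=1.0).D
    d_swap12 = d_statistic(g, (["p2"], ["p1"], ["p3"], ["p4"]), block_size=1.0).D
    d_swap34 = d_statistic(g, (["p1"], ["p2"], ["p4"], ["p3"]), block_size=1.0).D
    assert d_swap12 == pytest.approx(-d0)
    assert d_swap34 == pytest.approx(-d0)


def test_invariant_under_allele_relabel():
    patterns = [(1, 0, 1, 0), (1, 0, 1, 0), (0, 1, 1, 0)]
    g = haploid_table(patterns)
    d0 = d_statistic(g, GROUPS, block_size=1.0).D
    flipped = g.dosages.copy()
    flipped[0] = 2 - flipped[0]  # ref/alt flip at site 0 (no missing here)
    g2 = GenotypeTable(g.samples, g.sites, flipped, g.pseudo_haploid)
    d1 = d_statistic(g2, GROUPS, block_size=1.0).D
    assert d1 == pytest.approx(d0)


def test_too_few_blocks_rejected():
    patterns = [(1, 0, 1, 0), (0, 1, 1, 0)]
    g = haploid_table(patterns, n_blocks=2)
    with pytest.raises(ValueError, match="jackknife undefined"):
        d_statistic(g, GROUPS, block_size=1.0)


def test_empty_group_rejected():
    g = haploid_table([(1, 0, 1, 0)])
    with pytest.raises(ValueError, match="empty"):
        d_statistic(g, (["p1"], [], ["p3"], ["p4"]))


def test_null_z_calibration_small():
    zs = []
    for rep in range(30):
        g, groups = simulate_tree_table(seed=rep, n_sites=2000)
        zs.append(d_statistic(g, tuple(groups), block_size=5.0).Z)
    zs = np.array(zs)
    assert np.mean(np.abs(zs) >= 3) < 0.15  # loose at n=30; acceptance runs 200
    assert 0.6 < zs.std() < 1.5


def test_gene_flow_sign():
    # P3 -> P2 flow raises P2/P3 allele sharing (ABBA) -> D negative
    hits = 0
    for rep in range(10):
        g, groups = simulate_tree_table(seed=100 + rep, flow=0.2)
        res = d_statistic(g, tuple(groups), block_size=5.0)
        hits += res.D < 0
    assert hits >= 9


# ---------------------------------------------------------------------------
# lsq_project
# ---------------------------------------------------------------------------

def random_panel(seed=0, n_sites=400, n_samples=20):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_sites)
    labels = np.repeat([0, 1], n_samples // 2)
    shift = np.where(labels[:, None] == 0, -0.15, 0.15)
    freqs = np.clip(p[None, :] + shift, 0.02, 0.98)
    dosages = rng.binomial(2, freqs).T.astype(np.int8)
    sites = [SiteRecord("1", j + 1, "A", "C", site_id=f"s{j}") for j in range(n_sites)]
    ids = [f"R{i:02d}" for i in range(n_samples)]
    return GenotypeTable(ids, sites, dosages)


def test_projection_identity_for_reference_sample():
    g = random_panel()
    ref = fit_reference_pca(g, k=2)
    for i in (0, 7, 15):
        dos = g.dosages[:, i][np.array([s.name in set(ref.site_ids) for s in g.sites])]
        coords = lsq_project(ref, dos)
        assert np.allclose(coords, ref.coords[i], atol=1e-8)


def test_masking_monotonicity():
    g = random_panel(seed=1)
    ref = fit_reference_pca(g, k=2)
    keep = np.array([s.name in set(ref.site_ids) for s in g.sites])
    dos_full = g.dosages[:, 3][keep].astype(np.int8)
    truth = ref.coords[3]
    rng = np.random.default_rng(5)
    errs = []
    for frac in (0.8, 0.5, 0.2):
        dos = dos_full.copy()
        mask = rng.random(len(dos)) < frac
        dos[mask] = MISSING
        coords = lsq_project(ref, dos)
        errs.append(np.linalg.norm(coords - truth))
    assert errs[0] > errs[2]  # error shrinks as masking decreases


def test_projection_with_only_ten_sites():
    g = random_panel(seed=2)
    ref = fit_reference_pca(g, k=2)
    dos = np.full(len(ref.site_ids), MISSING, dtype=np.int8)
    keep_idx = np.arange(10)
    full = g.dosages[:, 4][np.array([s.name in set(ref.site_ids) for s in g.sites])]
    dos[keep_idx] = full[keep_idx]
    coords = lsq_project(ref, dos)
    assert np.all(np.isfinite(coords))


def test_no_overlap_rejected():
    g = random_panel(seed=3)
    ref = fit_reference_pca(g, k=2)
    dos = np.full(len(ref.site_ids), MISSING, dtype=np.int8)
    with pytest.raises(ValueError, match="non-missing"):
        lsq_project(ref, dos)


# ---------------------------------------------------------------------------
# admixture_date
# ---------------------------------------------------------------------------

def test_generation_recovery_within_20pct():
    H, pos, pA, pB = simulate_admixed_haplotypes(seed=7)
    res = admixture_date(H, pos, (pA, pB), bins=np.linspace(0.005, 0.3, 25))
    assert not res.no_date
    assert abs(res.generations - 20.0) / 20.0 <= 0.20


def test_unadmixed_panel_flagged_no_date():
    rng = np.random.default_rng(8)
    n_sites = 300
    pos = np.sort(rng.uniform(0, 1.0, n_sites))
    pA = rng.uniform(0.1, 0.9, n_sites)
    pB = np.clip(pA + 0.3, 0.02, 0.98)
    H = (rng.random((100, n_sites)) < pA).astype(np.int8)  # pure source A
    res = admixture_date(H, pos, (pA, pB), bins=np.linspace(0.005, 0.3, 25))
    assert res.no_date


def test_generation_time_scales_years_only():
    H, pos, pA, pB = simulate_admixed_haplotypes(seed=9)
    bins = np.linspace(0.005, 0.3, 25)
    r1 = admixture_date(H, pos, (pA, pB), bins=bins, generation_time=29.0)
    r2 = admixture_date(H, pos, (pA, pB), bins=bins, generation_time=58.0)
    assert r1.generations == pytest.approx(r2.generations)
    assert r2.years == pytest.approx(2.0 * r1.years)


def test_too_few_bins_rejected():
    H, pos, pA, pB = simulate_admixed_haplotypes(seed=10, n_sites=60)
    with pytest.raises(ValueError, match="non-empty distance bins"):
        admixture_date(H, pos, (pA, pB), bins=np.array([0.0, 0.001, 0.002]))
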