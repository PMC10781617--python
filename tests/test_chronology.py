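import numpy as np
import pytest
from scipy import integrate, stats

from paleoturnover.chronology import (
    CalibrationCurve,
    RadiocarbonDate,
    calibrate,
    combine_dates,
    fit_phase_model,
    marine_fraction,
    read_radiocarbon_csv,
    reservoir_correct,
    trapezoid_logpdf,
    write_radiocarbon_csv,
)
from paleoturnover.synthetic import generate_calibration_curve

from conftest import calibrated_normal


# ---------------------------------------------------------------------------
# marine_fraction / reservoir_correct
# ---------------------------------------------------------------------------

def test_marine_fraction_endpoints():
    assert marine_fraction(-21.0, (-21.0, -12.5)) == 0.0
    assert marine_fraction(-12.5, (-21.0, -12.5)) == 1.0
    assert marine_fraction(-16.75, (-21.0, -12.5)) == pytest.approx(0.5)


def test_marine_fraction_clipped():
    assert marine_fraction(-25.0, (-21.0, -12.5)) == 0.0
    assert marine_fraction(-10.0, (-21.0, -12.5)) == 1.0


def test_marine_fraction_monotone_in_d13c():
    vals = [marine_fraction(x) for x in np.linspace(-24, -10, 50)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_reservoir_flag_thresholds():
    flagged = reservoir_correct(RadiocarbonDate("a", 5000, 30, d13c=-17.5, d15n=12.5))
    assert flagged.reservoir_flag
    terrestrial = reservoir_correct(RadiocarbonDate("b", 5000, 30, d13c=-20.0, d15n=10.0))
    assert not terrestrial.reservoir_flag
    assert terrestrial.c14_age == 5000 and terrestrial.sigma == 30


def test_reservoir_and_rule_requires_both():
    only_c = reservoir_correct(RadiocarbonDate("c", 5000, 30, d13c=-17.0, d15n=11.0))
    only_n = reservoir_correct(RadiocarbonDate("d", 5000, 30, d13c=-19.0, d15n=13.0))
    assert not only_c.reservoir_flag and not only_n.reservoir_flag


def test_reservoir_propagation_arithmetic():
    # f = 0.5 at the endmember midpoint; offset 400 +/- 50
    d = RadiocarbonDate("e", 5000, 30, d13c=-16.75, d15n=13.0)
    out = reservoir_correct(d, endmembers=(-21.0, -12.5), full_marine_offset=(400.0, 50.0))
    assert out.reservoir_age == pytest.approx(200.0)
    assert out.c14_age == pytest.approx(4800.0)
    assert out.sigma == pytest.approx(np.sqrt(30**2 + (0.5 * 50) ** 2))


def test_reservoir_identity_on_unflagged_preserves_everything():
    d = RadiocarbonDate("f", 5000, 30, d13c=-20.5, d15n=9.0, ancestry_class="farmer")
    out = reservoir_correct(d)
    assert out.c14_age == d.c14_age and out.sigma == d.sigma
    assert out.ancestry_class == "farmer"


def test_reservoir_missing_isotopes_rejected():
    with pytest.raises(ValueError, match="isotope"):
        reservoir_correct(RadiocarbonDate("g", 5000, 30))


# ---------------------------------------------------------------------------
# calibrate
# ---------------------------------------------------------------------------

def test_identity_curve_closed_form_normal(identity_curve):
    dens = calibrated_normal(5000, 30, identity_curve)
    assert dens.mean() == pytest.approx(5000.0, abs=1.0)
    assert dens.sd() == pytest.approx(30.0, abs=1.0)
    (lo, hi), = dens.hpd(0.954)
    assert lo == pytest.approx(5000 - 2 * 30, abs=3.0)
    assert hi == pytest.approx(5000 + 2 * 30, abs=3.0)


def test_sigma_to_zero_concentrates(identity_curve):
    dens = calibrated_normal(5000, 1e-7, identity_curve)
    assert dens.pmf.max() > 0.999


def test_mass_conserved_for_many_inputs(identity_curve):
    rng = np.random.default_rng(0)
    for _ in range(20):
        age = rng.uniform(2000, 7000)
        sd = rng.uniform(10, 120)
        dens = calibrated_normal(age, sd, identity_curve)
        assert dens.pmf.sum() == pytest.approx(1.0, abs=1e-9)


def test_age_outside_span_rejected(identity_curve):
    with pytest.raises(ValueError, match="outside"):
        calibrate(RadiocarbonDate("x", 20000, 30), identity_curve)


def test_bimodal_density_from_two_crossing_curve():
    # wiggle crosses 5000 14C BP at two separate calendar ages
    grid = np.arange(4000.0, 6001.0, 1.0)
    mu = 5000.0 + 150.0 * np.sin(2 * np.pi * (grid - 4000.0) / 2000.0)
    curve = CalibrationCurve(grid, mu, np.zeros_like(grid))
    dens = calibrate(RadiocarbonDate("bi", 5100.0, 20.0), curve)
    intervals = dens.hpd(0.954)
    assert len(intervals) >= 2  # disjoint HPD regions
    # numeric integration oracle for the enclosed mass
    total = dens.hpd_mass(0.954)
    assert total == pytest.approx(0.954, abs=0.01)
    # oracle: unnormalized posterior integrated over the HPD region vs grid sum
    post = stats.norm.pdf(5100.0, loc=mu, scale=np.maximum(20.0, 1e-9))
    post /= integrate.trapezoid(post, grid)
    for lo, hi in intervals:
        sel = (grid >= lo) & (grid <= hi)
        grid_mass = dens.pmf[sel].sum()
        oracle_mass = integrate.trapezoid(post[sel], grid[sel])
        assert grid_mass == pytest.approx(oracle_mass, abs=0.01)


# ---------------------------------------------------------------------------
# combine_dates
# ---------------------------------------------------------------------------

def test_combine_identical_pair():
    res = combine_dates([RadiocarbonDate("a", 5000, 30), RadiocarbonDate("b", 5000, 30)])
    assert res.c14_age == pytest.approx(5000.0)
    assert res.sigma == pytest.approx(30 / np.sqrt(2), abs=0.05)
    assert res.chi2_stat == pytest.approx(0.0)
    assert res.passes


def test_combine_inconsistent_pair_fails_chi2():
    res = combine_dates([RadiocarbonDate("a", 5000, 30), RadiocarbonDate("b", 5200, 30)])
    assert res.chi2_stat == pytest.approx(200**2 / (2 * 30**2), rel=1e-9)
    assert res.chi2_critical == pytest.approx(stats.chi2.ppf(0.95, 1))
    assert not res.passes


def test_combine_three_identical():
    res = combine_dates([RadiocarbonDate(str(i), 4800, 45) for i in range(3)])
    assert res.sigma == pytest.approx(45 / np.sqrt(3))


def test_combine_dominant_precision_limit():
    res = combine_dates(
        [RadiocarbonDate("a", 5000, 30), RadiocarbonDate("b", 7777, 3e6)]
    )
    assert res.c14_age == pytest.approx(5000.0, abs=1e-3)
    assert res.sigma == pytest.approx(30.0, abs=1e-4)


def test_combine_single_date_rejected():
    with pytest.raises(ValueError, match="at least two"):
        combine_dates([RadiocarbonDate("a", 5000, 30)])


# ---------------------------------------------------------------------------
# trapezoid prior
# ---------------------------------------------------------------------------

def test_trapezoid_normalizes_and_shapes():
    a, b, c, d = 6000.0, 5800.0, 5200.0, 5000.0
    grid = np.linspace(4900, 6100, 5001)
    dens = np.exp(trapezoid_logpdf(grid, a, b, c, d))
    assert integrate.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)
    h = 1.0 / (0.5 * (a - b) + (b - c) + 0.5 * (c - d))
    assert np.exp(trapezoid_logpdf(5500.0, a, b, c, d)) == pytest.approx(h)
    assert np.exp(trapezoid_logpdf(5900.0, a, b, c, d)) == pytest.approx(0.5 * h)
    assert trapezoid_logpdf(6500.0, a, b, c, d) == -np.inf
    assert trapezoid_logpdf(4990.0, a, b, c, d) == -np.inf


def test_trapezoid_invalid_ordering():
    assert trapezoid_logpdf(5500.0, 5000.0, 6000.0, 5200.0, 5100.0) == -np.inf


# ---------------------------------------------------------------------------
# fit_phase_model
# ---------------------------------------------------------------------------

def two_phase_densities(curve, seed, n_per=20, sigma=40.0, farmer=(5900, 4850), steppe=(4850, 4000)):
    rng = np.random.default_rng(seed)
    dens = []
    for cls, (old, young) in (("farmer", farmer), ("steppe", steppe)):
        for t in rng.uniform(young, old, n_per):
            age = float(t + rng.normal(0, sigma))
            dens.append(
                calibrated_normal(age, sigma, curve, ancestry_class=cls, lab_id=cls, resolution=2.0)
            )
    return dens


@pytest.fixture(scope="module")
def wide_curve():
    return generate_calibration_curve("identity", (7000.0, 3000.0), noise_sd=0.0)


def test_phase_model_recovers_duration(wide_curve):
    dens = two_phase_densities(wide_curve, seed=1, n_per=50, sigma=1.0)
    post = fit_phase_model(dens, (7000, 3000), n_iter=2500, n_burn=1000, n_chains=2, seed=11)
    lo, hi = post.duration_interval(0.95)
    assert lo <= 1050.0 <= hi
    # width shrinks with more data
    dens_small = two_phase_densities(wide_curve, seed=2, n_per=10, sigma=1.0)
    post_small = fit_phase_model(dens_small, (7000, 3000), n_iter=2500, n_burn=1000, n_chains=2, seed=12)
    lo_s, hi_s = post_small.duration_interval(0.95)
    assert (hi - lo) < (hi_s - lo_s)


def test_degenerate_single_point_phase_concentrates(wide_curve):
    dens = [
        calibrated_normal(5900, 0.5, wide_curve, ancestry_class="farmer", resolution=1.0)
        for _ in range(8)
    ] + two_phase_densities(wide_curve, seed=3, n_per=5)[-5:]
    post = fit_phase_model(dens, (7000, 3000), n_iter=3000, n_burn=1500, n_chains=1, seed=5)
    onset = post.onset_draws["farmer"].ravel()
    assert abs(np.median(onset) - 5900.0) < 15.0


def test_same_seed_identical_draws(wide_curve):
    dens = two_phase_densities(wide_curve, seed=4, n_per=5)
    a = fit_phase_model(dens, (7000, 3000), n_iter=600, n_burn=200, n_chains=2, seed=99)
    b = fit_phase_model(dens, (7000, 3000), n_iter=600, n_burn=200, n_chains=2, seed=99)
    assert np.array_equal(a.duration_draws, b.duration_draws)
    c = fit_phase_model(dens, (7000, 3000), n_iter=600, n_burn=200, n_chains=2, seed=100)
    assert not np.array_equal(a.duration_draws, c.duration_draws)


def test_convergence_diagnostics_reported(wide_curve):
    dens = two_phase_densities(wide_curve, seed=6, n_per=20)
    post = fit_phase_model(dens, (7000, 3000), n_iter=2000, n_burn=800, n_chains=2, seed=7)
    assert "duration" in post.rhat
    assert post.rhat["duration"] < 1.05
    assert post.converged


def test_every_draw_satisfies_ordering(wide_curve):
    dens = two_phase_densities(wide_curve, seed=8, n_per=8)
    post = fit_phase_model(dens, (7000, 3000), n_iter=800, n_burn=300, n_chains=1, seed=3)
    for cls in post.classes:
        draws = post.param_draws[cls].reshape(-1, 4)
        assert np.all(draws[:, 0] >= draws[:, 1])
        assert np.all(draws[:, 1] >= draws[:, 2])
        assert np.all(draws[:, 2] >= draws[:, 3])


def test_min_dates_per_class_enforced(wide_curve):
    dens = two_phase_densities(wide_curve, seed=9, n_per=2)
    with pytest.raises(ValueError, match="need >= 3"):
        fit_phase_model(dens, (7000, 3000), n_iter=400, n_burn=100, seed=1)


def test_prior_window_must_cover_dates(wide_curve):
    dens = two_phase_densities(wide_curve, seed=10, n_per=4)
    with pytest.raises(ValueError, match="support"):
        fit_phase_model(dens, (9000, 8000), n_iter=400, n_burn=100, seed=1)


# ---------------------------------------------------------------------------
# curve + dates IO
# ---------------------------------------------------------------------------

def test_curve_14c_roundtrip(tmp_path, identity_curve):
    p = tmp_path / "curve.14c"
    identity_curve.write_14c(p)
    back = CalibrationCurve.read_14c(p)
    assert np.allclose(back.cal_bp, identity_curve.cal_bp)
    assert np.allclose(back.mu, identity_curve.mu, atol=0.01)


def test_radiocarbon_csv_roundtrip(tmp_path):
    dates = [
        RadiocarbonDate("L1", 5000, 30, d13c=-19.5, d15n=11.0, cn_atomic=3.2, ancestry_class="farmer"),
        RadiocarbonDate("L2", 4500, 25),
    ]
    p = tmp_path / "dates.csv"
    write_radiocarbon_csv(dates, p)
    back = read_radiocarbon_csv(p)
    assert back[0].lab_id == "L1" and back[0].ancestry_class == "farmer"
    assert back[1].d13c is None
    assert back[0].d15n == 11.0
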