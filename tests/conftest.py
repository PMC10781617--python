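import numpy as np
import pytest

from paleoturnover.chronology import RadiocarbonDate, calibrate
from paleoturnover.genotypes import GenotypeTable, SiteRecord
from paleoturnover.synthetic import (
    StratumSpec,
    SyntheticScenario,
    generate_calibration_curve,
    generate_cohort,
)


def three_strata(between: float = 3.0, within: float = 60.0):
    return (
        StratumSpec(
            "hg",
            isotope_means=(-16.0, 14.0),
            isotope_sds=(0.6, 0.8),
            sr_mean_sd=(0.7093, 0.0006),
            ibd_rate_within=within,
            ibd_rate_between=between,
        ),
        StratumSpec(
            "farmer",
            isotope_means=(-20.0, 10.0),
            isotope_sds=(0.4, 0.6),
            sr_mean_sd=(0.7098, 0.0010),
            ibd_rate_within=within,
            ibd_rate_between=between,
        ),
        StratumSpec(
            "steppe",
            isotope_means=(-20.0, 10.0),
            isotope_sds=(0.4, 0.6),
            sr_mean_sd=(0.7102, 0.0012),
            ibd_rate_within=within,
            ibd_rate_between=between,
        ),
    )


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(
        n_individuals=36,
        time_window=(7000.0, 3500.0),
        turnover_times=(5900.0, 4850.0),
        strata=three_strata(),
        n_sites=500,
        fst_divergence=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort(scenario):
    return generate_cohort(scenario)


@pytest.fixture(scope="session")
def identity_curve():
    return generate_calibration_curve("identity", (8000.0, 1000.0), noise_sd=0.0)


@pytest.fixture
def toy_genotypes():
    """3 samples x 5 sites with one pseudo-haploid sample and one missing call."""
    sites = [
        SiteRecord("1", 100, "A", "C", maf=0.2, info_score=0.9, site_id="s1"),
        SiteRecord("1", 200, "C", "T", maf=0.05, info_score=0.8, site_id="s2"),
        SiteRecord("2", 100, "G", "T", maf=0.3, info_score=0.4, site_id="s3"),
        SiteRecord("2", 300, "G", "A", maf=0.4, info_score=0.95, site_id="s4"),
        SiteRecord("3", 150, "T", "A", maf=0.1, info_score=0.99, site_id="s5"),
    ]
    dosages = np.array(
        [
            [0, 1, 2],
            [2, -1, 0],
            [1, 2, 0],
            [0, 0, 2],
            [2, 1, 0],
        ],
        dtype=np.int8,
    )
    pseudo = np.array([False, False, True])
    return GenotypeTable(["A", "B", "C"], sites, dosages, pseudo)


def calibrated_normal(mean, sd, curve, ancestry_class="other", lab_id="x", resolution=1.0):
    d = RadiocarbonDate(lab_id, float(mean), float(sd), ancestry_class=ancestry_class)
    return calibrate(d, curve, resolution)
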