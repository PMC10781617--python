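"""Seeded synthetic cohort generator.

Emits a cohort with the statistical structure the downstream analyses
assume: temporally ordered ancestry strata with abrupt turnovers, a
Balding-Nichols genotype model with controllable between-stratum drift,
cluster-structured IBD sharing (Poisson segment counts, exponential
lengths), stratum-specific stable-isotope distributions and radiocarbon
measurements produced by pushing each true calendar date through a supplied
calibration curve plus Gaussian noise.  Truth tables (stratum labels, true
dates) are emitted alongside the data so every stage can be validated
against known ground truth.

Randomness is split into one independent stream per data domain (dates,
genotypes, IBD, isotopes, 14C), all spawned from the master seed, so
perturbing one domain leaves the others byte-identical.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chronology import CalibrationCurve
from .genotypes import GenotypeTable, SiteRecord, write_genotypes

__all__ = [
    "StratumSpec",
    "SyntheticScenario",
    "Cohort",
    "generate_cohort",
    "generate_calibration_curve",
    "write_cohort",
    "scenario_from_dict",
    "load_scenario",
]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class StratumSpec:
    """One ancestry stratum: drifted allele frequencies plus isotope/IBD model."""

    name: str
    isotope_means: tuple[float, float] = (-20.0, 10.0)  # (d13C, d15N) permil
    isotope_sds: tuple[float, float] = (0.5, 0.8)
    sr_mean_sd: tuple[float, float] = (0.7095, 0.0008)
    ibd_rate_within: float = 60.0  # expected total cM shared per within pair
    ibd_rate_between: float = 5.0  # expected total cM shared with other strata
    segment_mean_length: float = 8.0  # cM

    def __post_init__(self):
        if not (self.ibd_rate_within > self.ibd_rate_between >= 0):
            raise ValueError(
                f"{self.name}: require ibd_rate_within > ibd_rate_between >= 0"
            )
        if self.segment_mean_length <= 0:
            raise ValueError(f"{self.name}: segment_mean_length must be positive")


@dataclass(frozen=True)
class SyntheticScenario:
    """Full generative configuration for one synthetic cohort."""

    n_individuals: int
    time_window: tuple[float, float]  # (oldest, youngest) cal BP
    turnover_times: tuple[float, ...]  # strictly decreasing cal BP boundaries
    strata: tuple[StratumSpec, ...]
    genome_map_length: float = 3000.0  # cM
    n_sites: int = 1000
    fst_divergence: float = 0.05
    c14_sigma: float = 30.0
    n_chromosomes: int = 22
    min_reportable_cm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        old, young = self.time_window
        if old <= young:
            raise ValueError("time_window must be (oldest, youngest) with oldest > youngest")
        tt = tuple(float(t) for t in self.turnover_times)
        if any(t2 >= t1 for t1, t2 in zip(tt, tt[1:])):
            raise ValueError("turnover_times must be strictly decreasing in cal BP")
        if any(not (young < t < old) for t in tt):
            raise ValueError("turnover_times must fall inside time_window")
        if len(self.strata) != len(tt) + 1:
            raise ValueError("need exactly len(turnover_times)+1 strata")
        if not (0.0 < self.fst_divergence < 1.0):
            raise ValueError("fst_divergence must be in (0, 1)")
        if any(s.segment_mean_length <= self.min_reportable_cm for s in self.strata):
            raise ValueError("segment_mean_length must exceed min_reportable_cm")
        object.__setattr__(self, "turnover_times", tt)
        object.__setattr__(self, "strata", tuple(self.strata))

    @property
    def boundaries(self) -> list[float]:
        """Occupancy boundaries oldest -> youngest, one interval per stratum."""
        old, young = self.time_window
        return [old, *self.turnover_times, young]


@dataclass
class Cohort:
    scenario: SyntheticScenario
    genotypes: GenotypeTable
    ibd_segments: pd.DataFrame  # sample1, sample2, chrom, start_cM, end_cM, length_cM
    sample_meta: pd.DataFrame
    isotopes: pd.DataFrame
    radiocarbon: pd.DataFrame
    truth: pd.DataFrame  # id, stratum, true_date + one-hot ancestry weights
    curve: CalibrationCurve
    stratum_freqs: np.ndarray  # (n_strata, n_sites) true allele frequencies
    ancestral_freqs: np.ndarray

    def as_tuple(self):
        return (self.genotypes, self.ibd_segments, self.sample_meta, self.isotopes, self.radiocarbon)


def generate_calibration_curve(
    kind: str = "identity",
    window: tuple[float, float] = (8000.0, 1000.0),
    noise_sd: float = 20.0,
    seed: int = 0,
    resolution: float = 10.0,
) -> CalibrationCurve:
    """Stand-in calibration curve on a regular knot grid.

    ``identity``: mu(t) = t with constant curve sigma.  ``wiggled``: mu(t) =
    t plus a smooth seeded perturbation (amplitude ~ 3x noise_sd) so the
    curve is non-trivial but reproducible.  Queries between knots are
    linearly interpolated by :class:`CalibrationCurve`.
    """
    old, young = max(window), min(window)
    if old <= young:
        raise ValueError("window must be non-empty")
    grid = np.arange(young, old + 0.5 * resolution, resolution)
    if kind == "identity":
        mu = grid.copy()
    elif kind == "wiggled":
        rng = np.random.default_rng(seed)
        raw = rng.normal(0.0, 3.0 * max(noise_sd, 1.0), size=len(grid))
        kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
        kernel /= kernel.sum()
        wiggle = np.convolve(raw, kernel, mode="same")
        mu = grid + wiggle
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    sigma = np.full(len(grid), float(noise_sd))
    return CalibrationCurve(grid, mu, sigma)


def _allocate_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n individuals over strata."""
    raw = n * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def generate_cohort(scenario: SyntheticScenario, curve: CalibrationCurve | None = None) -> Cohort:
    """Generate the full synthetic cohort for a validated scenario."""
    if scenario.n_sites < 100:
        raise ValueError("n_sites < 100 gives degenerate downstream analyses")
    if scenario.n_individuals < 4:
        raise ValueError("n_individuals < 4 gives degenerate downstream analyses")

    ss = np.random.SeedSequence(scenario.seed)
    rng_dates, rng_geno, rng_ibd, rng_iso, rng_c14 = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    if curve is None:
        old, young = scenario.time_window
        pad = 0.1 * (old - young) + 200.0
        curve = generate_calibration_curve("identity", (old + pad, max(young - pad, 0.0)), noise_sd=0.0)

    n = scenario.n_individuals
    strata = scenario.strata
    n_strata = len(strata)
    bounds = scenario.boundaries
    durations = np.array([bounds[k] - bounds[k + 1] for k in range(n_strata)])
    counts = _allocate_counts(n, durations)

    ids = [f"SYN{i:04d}" for i in range(n)]
    stratum_idx = np.repeat(np.arange(n_strata), counts)
    true_dates = np.concatenate(
        [
            rng_dates.uniform(bounds[k + 1], bounds[k], size=counts[k])
            for k in range(n_strata)
        ]
    )

    # --- genotypes: Balding-Nichols drift from a shared ancestral frequency ---
    F = scenario.fst_divergence
    p0 = rng_geno.uniform(0.05, 0.95, size=scenario.n_sites)
    shape = (1.0 - F) / F
    stratum_freqs = np.vstack(
        [rng_geno.beta(p0 * shape, (1.0 - p0) * shape) for _ in range(n_strata)]
    )
    stratum_freqs = np.clip(stratum_freqs, 1e-6, 1.0 - 1e-6)
    dosages = rng_geno.binomial(2, stratum_freqs[stratum_idx].T).astype(np.int8)

    chrom_len = scenario.genome_map_length / scenario.n_chromosomes
    site_global_pos = np.linspace(0.0, scenario.genome_map_length, scenario.n_sites, endpoint=False)
    sites = []
    for j, gp in enumerate(site_global_pos):
        ci = min(int(gp // chrom_len), scenario.n_chromosomes - 1)
        local_bp = int((gp - ci * chrom_len) * 1e6) + 1  # nominal 1 cM ~ 1 Mb
        ref, alt = rng_geno.choice(4, size=2, replace=False)
        pooled = dosages[j].mean() / 2.0
        sites.append(
            SiteRecord(
                chrom=str(ci + 1),
                pos=local_bp,
                ref=str(_ALLELES[ref]),
                alt=str(_ALLELES[alt]),
                maf=float(min(pooled, 1.0 - pooled)),
                info_score=1.0,
                site_id=f"snp{j}",
            )
        )
    genotypes = GenotypeTable(ids, sites, dosages)

    # --- IBD segments: Poisson counts, exponential lengths ---
    seg_rows = []
    for i, j in itertools.combinations(range(n), 2):
        si, sj = strata[stratum_idx[i]], strata[stratum_idx[j]]
        if stratum_idx[i] == stratum_idx[j]:
            rate = si.ibd_rate_within
        else:
            rate = 0.5 * (si.ibd_rate_between + sj.ibd_rate_between)
        mean_len = 0.5 * (si.segment_mean_length + sj.segment_mean_length)
        if rate <= 0:
            continue
        n_seg = rng_ibd.poisson(rate / mean_len)
        if n_seg == 0:
            continue
        lengths = rng_ibd.exponential(mean_len, size=n_seg)
        lengths = np.minimum(lengths, scenario.genome_map_length)
        starts = rng_ibd.uniform(0.0, scenario.genome_map_length - lengths)
        for L, start in zip(lengths, starts):
            ci = min(int(start // chrom_len), scenario.n_chromosomes - 1)
            seg_rows.append(
                (
                    ids[i],
                    ids[j],
                    str(ci + 1),
                    start - ci * chrom_len,
                    start - ci * chrom_len + L,
                    L,
                )
            )
    ibd_segments = pd.DataFrame(
        seg_rows, columns=["sample1", "sample2", "chrom", "start_cM", "end_cM", "length_cM"]
    )

    # --- isotopes ---
    iso_rows = []
    for i in range(n):
        s = strata[stratum_idx[i]]
        d13c = rng_iso.normal(s.isotope_means[0], s.isotope_sds[0])
        d15n = rng_iso.normal(s.isotope_means[1], s.isotope_sds[1])
        sr = rng_iso.normal(s.sr_mean_sd[0], s.sr_mean_sd[1])
        cn = float(np.clip(rng_iso.normal(3.25, 0.08), 2.5, 4.0))
        iso_rows.append((ids[i], d13c, d15n, cn, sr))
    isotopes = pd.DataFrame(iso_rows, columns=["id", "d13c", "d15n", "cn_atomic", "sr_ratio"])

    # --- radiocarbon: push true dates through the curve plus noise ---
    mu = curve.mu_at(true_dates)
    c14 = mu + rng_c14.normal(0.0, scenario.c14_sigma, size=n)
    radiocarbon = pd.DataFrame(
        {
            "lab_id": ids,
            "c14_age": c14,
            "sigma": scenario.c14_sigma,
            "d13c": isotopes["d13c"],
            "d15n": isotopes["d15n"],
            "cn_atomic": isotopes["cn_atomic"],
            "ancestry_class": [strata[k].name for k in stratum_idx],
        }
    )

    sample_meta = pd.DataFrame(
        {
            "id": ids,
            "coverage": 1.0,
            "mean_gp": 0.99,
            "contamination": 0.01,
            "date_mid": true_dates,
            "group_label": [strata[k].name for k in stratum_idx],
            "kin": "",
        }
    )

    truth = pd.DataFrame(
        {
            "id": ids,
            "stratum": [strata[k].name for k in stratum_idx],
            "true_date": true_dates,
        }
    )
    for k, s in enumerate(strata):  # abrupt turnovers: one-hot true ancestry
        truth[f"w_{s.name}"] = (stratum_idx == k).astype(float)

    return Cohort(
        scenario=scenario,
        genotypes=genotypes,
        ibd_segments=ibd_segments,
        sample_meta=sample_meta,
        isotopes=isotopes,
        radiocarbon=radiocarbon,
        truth=truth,
        curve=curve,
        stratum_freqs=stratum_freqs,
        ancestral_freqs=p0,
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write every cohort artifact as plain text; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_eigenstrat": str(out / "genotypes"),
        "genotypes_vcf": str(out / "genotypes.vcf"),
        "ibd": str(out / "ibd_segments.tsv"),
        "meta": str(out / "sample_meta.csv"),
        "isotopes": str(out / "isotopes.csv"),
        "radiocarbon": str(out / "radiocarbon.csv"),
        "truth": str(out / "truth.csv"),
        "curve": str(out / "curve.14c"),
    }
    write_genotypes(cohort.genotypes, paths["genotypes_eigenstrat"], "eigenstrat")
    write_genotypes(cohort.genotypes, paths["genotypes_vcf"], "vcf")
    cohort.ibd_segments.to_csv(paths["ibd"], sep="\t", index=False)
    cohort.sample_meta.to_csv(paths["meta"], index=False)
    cohort.isotopes.to_csv(paths["isotopes"], index=False)
    cohort.radiocarbon.to_csv(paths["radiocarbon"], index=False)
    cohort.truth.to_csv(paths["truth"], index=False)
    cohort.curve.write_14c(paths["curve"])
    return paths


def scenario_from_dict(cfg: dict) -> SyntheticScenario:
    strata = tuple(
        StratumSpec(
            name=s["name"],
            isotope_means=tuple(s.get("isotope_means", (-20.0, 10.0))),
            isotope_sds=tuple(s.get("isotope_sds", (0.5, 0.8))),
            sr_mean_sd=tuple(s.get("sr_mean_sd", (0.7095, 0.0008))),
            ibd_rate_within=float(s.get("ibd_rate_within", 60.0)),
            ibd_rate_between=float(s.get("ibd_rate_between", 5.0)),
            segment_mean_length=float(s.get("segment_mean_length", 8.0)),
        )
        for s in cfg["strata"]
    )
    return SyntheticScenario(
        n_individuals=int(cfg["n_individuals"]),
        time_window=tuple(cfg["time_window"]),
        turnover_times=tuple(cfg["turnover_times"]),
        strata=strata,
        genome_map_length=float(cfg.get("genome_map_length", 3000.0)),
        n_sites=int(cfg.get("n_sites", 1000)),
        fst_divergence=float(cfg.get("fst_divergence", 0.05)),
        c14_sigma=float(cfg.get("c14_sigma", 30.0)),
        n_chromosomes=int(cfg.get("n_chromosomes", 22)),
        min_reportable_cm=float(cfg.get("min_reportable_cm", 1.0)),
        seed=int(cfg.get("seed", 0)),
    )


def load_scenario(path) -> SyntheticScenario:
    """Load a scenario from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    return scenario_from_dict(cfg)
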