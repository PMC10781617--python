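# paleoturnover

Multiproxy inference machinery for detecting ancient population turnovers,
built around the analyses used for dense Mesolithic–Neolithic ancient-DNA
transects:

- **`synthetic`** — seeded generator of a full synthetic cohort (temporally
  ordered ancestry strata with abrupt turnovers, Balding–Nichols genotypes,
  cluster-structured IBD segments, stratum-specific stable-isotope
  distributions, radiocarbon measurements pushed through a calibration
  curve) plus truth tables, so every downstream stage is testable without
  external data.
- **`genotypes`** — EIGENSTRAT/VCF genotype IO (diploid and pseudo-haploid
  dosages), site filters (MAF / imputation info score / transversions-only)
  and sample QC (coverage < 0.1×, mean genotype probability < 0.98,
  contamination > 5%, iterative removal of the lower-coverage member of
  close-kin pairs).
- **`ibd`** — pairwise IBD sharing-rate matrices from segment tables,
  deterministic hierarchical community detection (greedy modularity
  agglomeration with lexicographic tie-breaking), and PCA of the
  IBD-sharing covariance matrix.
- **`ancestry`** — supervised ancestry mixtures via non-negative least
  squares on relative IBD-sharing rate vectors; four-population
  D-statistics with a weighted block jackknife; least-squares projection of
  low-coverage samples onto a reference PCA; simplified admixture-LD decay
  dating (exponential fit, age in generations).
- **`chronology`** — radiocarbon calibration on arbitrary curve tables,
  diet-scaled marine reservoir correction (flagged when both δ¹³C ≥ −18.0‰
  and δ¹⁵N ≥ +12.0‰), inverse-variance replicate combination with a χ²
  consistency test, and a two-phase Bayesian model with a trapezoidal phase
  prior (Metropolis-within-Gibbs MCMC) yielding the posterior of the
  inter-onset duration between two ancestry classes.
- **`phenotypes`** — multinomial-logistic pigmentation predictions from
  effect-allele dosages, additive height polygenic scores standardized
  against a reference population, collagen C:N quality control (2.9–3.6),
  marine-diet classification from δ¹³C mixing, and robust (median/MAD) Sr
  mobility outliers.
- **`pipeline` / CLI** — end-to-end orchestration into one chronologically
  sorted multiproxy table and first-appearance (turnover) detection per
  ancestry.

## CLI

Everything is reachable through one entry point:

```bash
paleoturnover simulate --scenario scenario.json --out sim/ --seed 1
paleoturnover qc --meta sim/sample_meta.csv --out qc.csv
paleoturnover ibd-stats --ibd sim/ibd_segments.tsv --ids ids.txt --out rate.csv
paleoturnover cluster --matrix rate.csv --out clusters.tsv
paleoturnover mixture --matrix rate.csv --sources sources.tsv --out mixtures.csv
paleoturnover dstat --geno sim/genotypes --groups groups.tsv --pops P1,P2,P3,P4 --out d.csv
paleoturnover calibrate --dates dates.csv --curve curve.14c --out cal.csv
paleoturnover combine --dates replicates.csv
paleoturnover phase-model --dates dates.csv --curve curve.14c --seed 1 --out phase.json
paleoturnover phenotype --dosages dos.csv --panel panel.tsv --intercepts panel.json --out probs.csv
paleoturnover isotope-qc --isotopes iso.csv --out isoqc.csv
paleoturnover sr-outliers --isotopes iso.csv --out sr.csv
paleoturnover run --config config.json --out run/
```

A minimal scenario file:

```json
{
  "n_individuals": 36,
  "time_window": [7000, 3500],
  "turnover_times": [5900, 4850],
  "strata": [
    {"name": "hg", "isotope_means": [-16, 14], "ibd_rate_within": 60, "ibd_rate_between": 3},
    {"name": "farmer", "isotope_means": [-20, 10], "ibd_rate_within": 60, "ibd_rate_between": 3},
    {"name": "steppe", "isotope_means": [-20, 10], "ibd_rate_within": 60, "ibd_rate_between": 3}
  ],
  "n_sites": 500,
  "seed": 7
}
```

`paleoturnover run` consumes a config JSON/YAML pointing at the metadata,
IBD, isotope, radiocarbon and curve files (see `pipeline.RunConfig`), and
writes `multiproxy.csv`, per-stage artifacts, `turnovers.json`, a structured
log and the echoed config.

## Notes

- The bundled pigmentation panels under `src/paleoturnover/data/` are
  format examples for the prediction machinery; supply a published
  coefficient table (same TSV/JSON layout) for real predictions.
- All stochastic stages take explicit seeds; per-domain RNG streams in the
  simulator mean perturbing one data domain leaves the others bit-identical.
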