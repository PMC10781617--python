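"""End-to-end orchestration: QC -> IBD stats -> clustering -> mixtures ->
chronology -> isotope proxies -> aligned multiproxy table.

Each proxy degrades gracefully: a failing stage logs the problem and leaves
its columns missing rather than aborting the run.  The serialized config is
echoed next to the outputs so a rerun reproduces them bit-for-bit for the
deterministic stages.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, chronology, genotypes, ibd, phenotypes

logger = logging.getLogger("paleoturnover")

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "detect_turnovers"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration (paths + stage parameters + seed)."""

    meta: str
    ibd: str
    isotopes: str | None = None
    radiocarbon: str | None = None
    curve: str | None = None
    source_groups: str | None = None  # two-column TSV: id, population
    map_length: float = 3000.0
    min_segment_cm: float = 1.0
    gain_tol: float = 1e-9
    min_community_size: int = 5
    weight_threshold: float = 0.25
    endmembers: tuple[float, float] = chronology.DEFAULT_ENDMEMBERS
    full_marine_offset: tuple[float, float] = chronology.DEFAULT_MARINE_OFFSET
    run_phase_model: bool = False
    phase_classes: tuple[str, str] = ("farmer", "steppe")
    mcmc_iters: int = 4000
    mcmc_burn: int = 1500
    mcmc_chains: int = 2
    grid_resolution: float = 1.0
    sr_mad_k: float = 3.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("meta", "ibd"):
            if key not in cfg:
                raise ConfigError(f"missing required config key {key!r}")
        out = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()})
        for key in ("meta", "ibd", "isotopes", "radiocarbon", "curve", "source_groups"):
            path = getattr(out, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{key}: input file not found: {path}")
        if not (0.0 < out.weight_threshold):
            raise ConfigError("weight_threshold must be positive")
        if out.map_length <= 0:
            raise ConfigError("map_length must be positive")
        return out

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
        if not isinstance(cfg, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def read_source_groups(path) -> dict:
    """Two-column TSV (id, population) -> {population: [ids...]}."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, population)")
    id_col, pop_col = df.columns[:2]
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row[pop_col]), []).append(str(row[id_col]))
    return groups


def run_pipeline(config: RunConfig, out_dir) -> pd.DataFrame:
    """Execute every available stage and write the multiproxy table.

    Returns the multiproxy DataFrame (one row per QC-retained individual,
    chronologically sorted, oldest first).
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    logger.info("pipeline start; seed=%d", config.seed)

    # --- stage: sample QC ---
    meta = genotypes.read_sample_meta_csv(config.meta)
    retained, exclusions = genotypes.qc_samples(meta)
    pd.DataFrame(exclusions, columns=["id", "reason"]).to_csv(out / "qc_exclusions.csv", index=False)
    logger.info("qc: retained %d / %d samples", len(retained), len(meta))
    meta_by_id = {m.id: m for m in meta}

    table = pd.DataFrame({"id": retained})
    table["qc_status"] = "pass"
    table["date_mid"] = [meta_by_id[i].date_mid for i in retained]

    # --- stage: IBD sharing + clustering ---
    cluster_level1: dict[str, str] = {}
    share = None
    try:
        segs = ibd.read_ibd_tsv(config.ibd)
        segs = segs[segs["sample1"].isin(retained) & segs["sample2"].isin(retained)]
        share = ibd.sharing_matrix(segs, retained, config.map_length, config.min_segment_cm)
        share.to_frame("rate").to_csv(out / "sharing_rate.csv")
        clusters = ibd.detect_communities(
            share, min_size=config.min_community_size, gain_tol=config.gain_tol
        )
        cluster_level1 = clusters.level(0)
        rows = [(i, *clusters.labels[i]) for i in clusters.ids]
        with open(out / "clusters.tsv", "w") as fhh:
            for r in rows:
                fhh.write("\t".join(str(x) for x in r) + "\n")
    except Exception as exc:  # degrade gracefully
        logger.warning("ibd/cluster stage failed: %s", exc)
    table["cluster"] = table["id"].map(cluster_level1)

    # --- stage: supervised NNLS mixtures ---
    source_names: list[str] = []
    if share is not None:
        if config.source_groups:
            groups = read_source_groups(config.source_groups)
            groups = {
                name: [s for s in members if s in set(retained)]
                for name, members in groups.items()
            }
            groups = {name: m for name, m in groups.items() if m}
        else:
            groups = {
                f"cluster_{lab}": members
                for lab, members in ibd.detect_communities(
                    share, min_size=config.min_community_size, gain_tol=config.gain_tol
                ).communities(0).items()
            }
        source_names = list(groups)
        mix_rows = []
        for sid in retained:
            try:
                res = ancestry.mixture_from_matrix(share, groups, sid)
                mix_rows.append({"id": sid, **res.as_dict(), "residual": res.residual_norm})
            except Exception as exc:
                logger.warning("mixture failed for %s: %s", sid, exc)
                mix_rows.append({"id": sid})
        mix = pd.DataFrame(mix_rows)
        mix.to_csv(out / "mixtures.csv", index=False)
        for name in source_names:
            table[f"w_{name}"] = table["id"].map(mix.set_index("id")[name]) if name in mix else np.nan

    # --- stage: chronology ---
    if config.radiocarbon and config.curve:
        try:
            curve = chronology.CalibrationCurve.read_14c(config.curve)
            dates = chronology.read_radiocarbon_csv(config.radiocarbon)
            dates = [d for d in dates if d.lab_id in set(retained)]
            corrected = [
                chronology.reservoir_correct(d, config.endmembers, config.full_marine_offset)
                if d.d13c is not None and d.d15n is not None
                else d
                for d in dates
            ]
            densities = [
                chronology.calibrate(d, curve, config.grid_resolution) for d in corrected
            ]
            cal_mid = {dd.lab_id: dd.mean() for dd in densities}
            table["cal_date_mid"] = table["id"].map(cal_mid)
            table["reservoir_flag"] = table["id"].map(
                {d.lab_id: d.reservoir_flag for d in corrected}
            )
            if config.run_phase_model:
                post = chronology.fit_phase_model(
                    densities,
                    prior_window=(max(dd.cal_bp.max() for dd in densities), 0.0),
                    n_iter=config.mcmc_iters,
                    n_burn=config.mcmc_burn,
                    n_chains=config.mcmc_chains,
                    seed=config.seed,
                    classes=config.phase_classes,
                )
                (out / "phase_model.json").write_text(json.dumps(post.summary(), indent=2))
        except Exception as exc:
            logger.warning("chronology stage failed: %s", exc)

    # --- stage: isotope proxies ---
    if config.isotopes:
        try:
            iso = pd.read_csv(config.isotopes)
            iso = iso[iso["id"].isin(set(retained))]
            recs = [
                phenotypes.IsotopeRecord(
                    id=str(r["id"]),
                    d13c=float(r["d13c"]),
                    d15n=float(r["d15n"]),
                    cn_atomic=float(r["cn_atomic"]),
                    sr_ratio=float(r["sr_ratio"]) if "sr_ratio" in iso.columns and pd.notna(r.get("sr_ratio")) else None,
                )
                for _, r in iso.iterrows()
            ]
            diet = {
                r.id: phenotypes.diet_class(r, config.endmembers) for r in recs
            }
            cn = {r.id: phenotypes.collagen_qc(r)[0] for r in recs}
            table["d13c"] = table["id"].map({r.id: r.d13c for r in recs})
            table["d15n"] = table["id"].map({r.id: r.d15n for r in recs})
            table["marine_fraction"] = table["id"].map({i: d[0] for i, d in diet.items()})
            table["marine_class"] = table["id"].map({i: d[1] for i, d in diet.items()})
            table["collagen_ok"] = table["id"].map(cn)
            try:
                flags = phenotypes.sr_outliers(iso, k=config.sr_mad_k)
                table["sr_outlier"] = table["id"].map(flags.set_index("id")["outlier"])
            except ValueError as exc:
                logger.warning("sr outlier stage skipped: %s", exc)
        except Exception as exc:
            logger.warning("isotope stage failed: %s", exc)

    # --- finalize: chronological sort (oldest first) ---
    sort_col = "cal_date_mid" if "cal_date_mid" in table and table["cal_date_mid"].notna().any() else "date_mid"
    table = table.sort_values([sort_col, "id"], ascending=[False, True]).reset_index(drop=True)
    table.to_csv(out / "multiproxy.csv", index=False)

    summary = {
        "n_retained": len(retained),
        "n_excluded": len(exclusions),
        "sources": source_names,
        "elapsed_s": time.time() - t0,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline done in %.1fs", summary["elapsed_s"])
    logger.removeHandler(fh)
    fh.close()
    return table


def detect_turnovers(
    table: pd.DataFrame,
    weight_threshold: float = 0.25,
    date_col: str | None = None,
) -> list[dict]:
    """First chronological appearance of each ancestry per NNLS weight.

    For every ``w_<ancestry>`` column, returns the oldest individual whose
    weight meets the threshold; date ties report the smaller id.  Ancestries
    with no qualifying individual are omitted (logged).
    """
    weight_cols = [c for c in table.columns if c.startswith("w_")]
    if not weight_cols:
        raise ValueError("no ancestry weight columns (w_*) present")
    if date_col is None:
        date_col = "cal_date_mid" if "cal_date_mid" in table and table["cal_date_mid"].notna().any() else "date_mid"
    out = []
    for col in weight_cols:
        qual = table[table[col] >= weight_threshold]
        if qual.empty:
            logger.info("no individual reaches weight %.2f for %s", weight_threshold, col)
            continue
        oldest = qual[date_col].max()
        ties = qual[qual[date_col] == oldest].sort_values("id")
        if len(ties) > 1:
            logger.info("date tie for %s at %.1f: %s", col, oldest, list(ties["id"]))
        row = ties.iloc[0]
        out.append(
            {
                "ancestry": col[2:],
                "id": row["id"],
                "date": float(oldest),
                "weight": float(row[col]),
            }
        )
    return out
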