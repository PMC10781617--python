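"""Genetic phenotype predictions and diet/mobility isotope proxies.

Pigmentation uses a multinomial-logistic panel (per-category coefficients
against a reference category); height is an additive polygenic score
standardized against a reference population.  Diet proxies classify the
marine protein fraction from collagen d13C, collagen quality is screened on
the atomic C:N window, and Sr mobility outliers are flagged with a robust
median/MAD rule relative to the dataset itself.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chronology import (
    D13C_THRESHOLD,
    D15N_THRESHOLD,
    DEFAULT_ENDMEMBERS,
    marine_fraction,
)

__all__ = [
    "PanelVariant",
    "PhenotypePanel",
    "PGSPanel",
    "IsotopeRecord",
    "PigmentationPrediction",
    "pigmentation_probs",
    "height_pgs",
    "collagen_qc",
    "diet_class",
    "sr_outliers",
    "load_phenotype_panel",
    "load_pgs_panel",
    "default_pigmentation_panel",
]

CN_WINDOW = (2.9, 3.6)  # inclusive atomic C:N collagen-quality window
MAD_CONSISTENCY = 1.4826


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelVariant:
    id: str
    effect_allele: str
    betas: dict  # category -> coefficient


@dataclass(frozen=True)
class PhenotypePanel:
    """Multinomial-logistic coefficient panel.

    ``intercepts`` holds one intercept per non-reference category; the
    reference category receives the residual probability mass.
    """

    variants: tuple
    intercepts: dict
    reference_category: str
    trait: str = ""

    def __post_init__(self):
        cats = set(self.intercepts)
        for v in self.variants:
            if set(v.betas) != cats:
                raise ValueError(
                    f"variant {v.id}: coefficient categories {sorted(v.betas)} != "
                    f"panel categories {sorted(cats)}"
                )

    @property
    def categories(self) -> list[str]:
        return list(self.intercepts) + [self.reference_category]


@dataclass(frozen=True)
class PGSPanel:
    loci: tuple  # of (id, effect_allele, beta)
    trait: str = ""

    def __post_init__(self):
        ids = [l[0] for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate loci in PGS panel")
        if not all(np.isfinite(l[2]) for l in self.loci):
            raise ValueError("non-finite effect size in PGS panel")


@dataclass(frozen=True)
class IsotopeRecord:
    id: str
    d13c: float
    d15n: float
    cn_atomic: float
    sr_ratio: float | None = None

    def __post_init__(self):
        if self.cn_atomic is not None and self.cn_atomic <= 0:
            raise ValueError(f"{self.id}: cn_atomic must be positive")


# ---------------------------------------------------------------------------
# Pigmentation (HIrisPlex-style multinomial logistic)
# ---------------------------------------------------------------------------

@dataclass
class PigmentationPrediction:
    probs: dict  # category -> probability, sums to 1
    n_dropped: int
    low_confidence: bool

    def top(self) -> str:
        return max(self.probs, key=self.probs.get)


def pigmentation_probs(dosages: dict, panel: PhenotypePanel) -> PigmentationPrediction:
    """Category probabilities from effect-allele dosages in [0, 2].

    score_c = intercept_c + sum beta_cv * dosage_v over panel variants;
    p_c = exp(score_c) / (1 + sum exp(score)); the reference category takes
    the residual mass.  Missing dosages (absent or None) drop the variant
    and flag the prediction low-confidence.
    """
    cats = list(panel.intercepts)
    scores = {c: float(panel.intercepts[c]) for c in cats}
    n_dropped = 0
    for v in panel.variants:
        dos = dosages.get(v.id)
        if dos is None:
            n_dropped += 1
            continue
        if not (0.0 <= dos <= 2.0):
            raise ValueError(f"dosage for {v.id} outside [0, 2]: {dos}")
        for c in cats:
            scores[c] += v.betas[c] * dos
    exp_scores = {c: np.exp(s) for c, s in scores.items()}
    denom = 1.0 + sum(exp_scores.values())
    probs = {c: float(e / denom) for c, e in exp_scores.items()}
    probs[panel.reference_category] = float(1.0 / denom)
    return PigmentationPrediction(probs=probs, n_dropped=n_dropped, low_confidence=n_dropped > 0)


def load_phenotype_panel(tsv_path, intercepts_json_path) -> PhenotypePanel:
    """Panel format: TSV (variant, effect_allele, category, beta) + JSON
    {"trait":…, "reference_category":…, "intercepts": {category: value}}."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"variant", "effect_allele", "category", "beta"}
    if not required <= set(df.columns):
        raise ValueError(f"{tsv_path}: expected columns {sorted(required)}")
    meta = json.loads(Path(intercepts_json_path).read_text())
    variants = []
    for (vid, allele), grp in df.groupby(["variant", "effect_allele"], sort=False):
        betas = dict(zip(grp["category"], grp["beta"].astype(float)))
        variants.append(PanelVariant(id=str(vid), effect_allele=str(allele), betas=betas))
    return PhenotypePanel(
        variants=tuple(variants),
        intercepts={k: float(v) for k, v in meta["intercepts"].items()},
        reference_category=str(meta["reference_category"]),
        trait=str(meta.get("trait", "")),
    )


def default_pigmentation_panel(trait: str = "eye") -> PhenotypePanel:
    """Bundled *illustrative* eye/hair panel in the documented format.

    The coefficients are format examples for testing the machinery, not a
    validated forensic panel; replace with a published coefficient table for
    real predictions.
    """
    data_dir = Path(__file__).parent / "data"
    return load_phenotype_panel(
        data_dir / f"example_{trait}_panel.tsv",
        data_dir / f"example_{trait}_intercepts.json",
    )


# ---------------------------------------------------------------------------
# Height polygenic score
# ---------------------------------------------------------------------------

def load_pgs_panel(tsv_path, trait: str = "height") -> PGSPanel:
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"variant", "effect_allele", "beta"}
    if not required <= set(df.columns):
        raise ValueError(f"{tsv_path}: expected columns {sorted(required)}")
    loci = tuple(
        (str(r["variant"]), str(r["effect_allele"]), float(r["beta"])) for _, r in df.iterrows()
    )
    return PGSPanel(loci=loci, trait=trait)


def height_pgs(
    dosages: dict,
    panel: PGSPanel,
    reference_scores: np.ndarray,
    cm_per_sd: float = 1.0,
) -> dict:
    """Additive PGS: sum of beta * dosage over non-missing loci, rescaled by
    panel_size / non_missing so partially-typed samples stay comparable.

    Standardization uses the population moments (ddof=0) of the reference
    score distribution; ``delta_cm`` converts SD units with ``cm_per_sd``.
    Requires >= 50% of panel loci non-missing.
    """
    betas = {vid: beta for vid, _, beta in panel.loci}
    present = [vid for vid in betas if dosages.get(vid) is not None]
    if len(present) < 0.5 * len(betas):
        raise ValueError(
            f"insufficient panel coverage: {len(present)}/{len(betas)} loci non-missing"
        )
    raw = sum(betas[vid] * float(dosages[vid]) for vid in present)
    raw *= len(betas) / len(present)
    ref = np.asarray(reference_scores, dtype=float)
    mu, sd = float(ref.mean()), float(ref.std(ddof=0))
    standardized = (raw - mu) / sd if sd > 0 else 0.0
    return {
        "raw": float(raw),
        "standardized": float(standardized),
        "delta_cm": float(standardized * cm_per_sd),
        "n_loci_used": len(present),
        "n_loci_panel": len(betas),
    }


def pgs_raw_score(dosages: dict, panel: PGSPanel) -> float:
    """Unstandardized PGS for building a reference-score distribution."""
    betas = {vid: beta for vid, _, beta in panel.loci}
    present = [vid for vid in betas if dosages.get(vid) is not None]
    if not present:
        raise ValueError("no panel loci typed")
    raw = sum(betas[vid] * float(dosages[vid]) for vid in present)
    return float(raw * len(betas) / len(present))


# ---------------------------------------------------------------------------
# Diet / collagen / mobility proxies
# ---------------------------------------------------------------------------

def collagen_qc(rec: IsotopeRecord, window: tuple[float, float] = CN_WINDOW) -> tuple[bool, str]:
    """Pass iff the atomic C:N ratio lies in the closed quality window."""
    lo, hi = window
    if lo <= rec.cn_atomic <= hi:
        return True, ""
    return False, f"C:N={rec.cn_atomic:g} outside {lo}-{hi}"


def diet_class(
    rec: IsotopeRecord,
    endmembers: tuple[float, float] = DEFAULT_ENDMEMBERS,
    mixed_bounds: tuple[float, float] = (0.2, 0.5),
) -> tuple[float, str, bool]:
    """(marine_fraction, diet class, reservoir flag) for one individual.

    Classes: terrestrial (f < 0.2), mixed (0.2 <= f <= 0.5),
    marine-dominated (f > 0.5).  The reservoir flag applies the elevated
    d13C/d15N AND rule.
    """
    f = marine_fraction(rec.d13c, endmembers)
    lo, hi = mixed_bounds
    if f < lo:
        cls = "terrestrial"
    elif f <= hi:
        cls = "mixed"
    else:
        cls = "marine-dominated"
    flag = (rec.d13c >= D13C_THRESHOLD) and (rec.d15n >= D15N_THRESHOLD)
    return f, cls, flag


def sr_outliers(records, k: float = 3.0) -> pd.DataFrame:
    """Flag Sr-ratio mobility outliers relative to the dataset itself.

    Robust rule: |sr - median| > k * MAD (scaled by 1.4826).  If the MAD is
    zero the scale falls back to IQR/1.349 with a warning; if that is also
    zero, any value different from the median is flagged.

    ``records`` is an iterable of IsotopeRecord or a DataFrame with columns
    id, sr_ratio.  Returns a DataFrame (id, sr_ratio, robust_z, outlier).
    """
    if isinstance(records, pd.DataFrame):
        df = records[["id", "sr_ratio"]].dropna().copy()
    else:
        df = pd.DataFrame(
            [(r.id, r.sr_ratio) for r in records if r.sr_ratio is not None],
            columns=["id", "sr_ratio"],
        )
    if len(df) < 5:
        raise ValueError("need >= 5 records with sr_ratio")
    x = df["sr_ratio"].to_numpy(dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med))) * MAD_CONSISTENCY
    if mad > 0:
        scale = mad
    else:
        warnings.warn("zero MAD: falling back to IQR scale for Sr outliers", stacklevel=2)
        q1, q3 = np.percentile(x, [25, 75])
        scale = (q3 - q1) / 1.349
    if scale > 0:
        z = (x - med) / scale
        outlier = np.abs(z) > k
    else:
        dev = x != med
        z = np.zeros_like(x)
        z[dev] = np.sign(x[dev] - med) * np.inf
        outlier = dev if np.isfinite(k) else np.zeros(len(x), dtype=bool)
    df["robust_z"] = z
    df["outlier"] = outlier
    return df
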