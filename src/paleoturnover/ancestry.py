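"""Supervised ancestry inference and four-population tests.

* ``nnls_mixture`` — non-negative least squares on *relative* IBD-sharing
  rate vectors (each vector normalized to sum 1), weights renormalized to
  the simplex.
* ``d_statistic`` — frequency-based four-population D with a weighted
  leave-one-block-out jackknife Z score; one code path serves diploid and
  pseudo-haploid dosages.
* ``lsq_project`` — least-squares projection of a possibly-missing sample
  onto reference PCA loadings.
* ``admixture_date`` — simplified admixture-LD decay dating: the weighted
  two-locus covariance statistic is binned by genetic distance and fitted
  with A0 * exp(-lambda * d) + c; lambda is the age in generations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .genotypes import MISSING, GenotypeTable
from .ibd import ClusterAssignment, IBDShareMatrix

__all__ = [
    "MixtureResult",
    "DStatResult",
    "ReferencePCA",
    "AdmixtureDateResult",
    "nnls_mixture",
    "sharing_features",
    "mixture_from_matrix",
    "d_statistic",
    "fit_reference_pca",
    "lsq_project",
    "admixture_date",
]

DEFAULT_GENERATION_TIME = 29.0  # years per generation, configurable


# ---------------------------------------------------------------------------
# NNLS mixture modelling
# ---------------------------------------------------------------------------

@dataclass
class MixtureResult:
    target: str
    sources: list[str]
    weights: np.ndarray  # non-negative, sums to 1
    residual_norm: float
    n_reference_features: int

    def as_dict(self) -> dict:
        return {s: float(w) for s, w in zip(self.sources, self.weights)}


def nnls_mixture(
    target_vector: np.ndarray,
    source_vectors: dict,
    target_id: str = "target",
    cond_warn: float = 1e8,
) -> MixtureResult:
    """Express a target's relative sharing profile as a non-negative mixture
    of source profiles.

    All vectors are first normalized to sum 1 ("relative" rates); weights
    are then renormalized to the simplex.
    """
    names = list(source_vectors)
    if len(names) < 2:
        raise ValueError("need at least two sources")
    y = np.asarray(target_vector, dtype=float)
    S = np.column_stack([np.asarray(source_vectors[nm], dtype=float) for nm in names])
    if len(y) < len(names):
        raise ValueError("feature dimension must be >= number of sources")
    if np.any(y < 0) or np.any(S < 0):
        raise ValueError("sharing-rate vectors must be non-negative")
    if y.sum() <= 0:
        raise ValueError(f"{target_id}: no sharing signal (all-zero target vector)")
    col_sums = S.sum(axis=0)
    if np.any(col_sums <= 0):
        bad = [nm for nm, cs in zip(names, col_sums) if cs <= 0]
        raise ValueError(f"all-zero source vectors: {bad}")
    y = y / y.sum()
    S = S / col_sums
    cond = np.linalg.cond(S)
    if cond > cond_warn:
        warnings.warn(f"{target_id}: nearly collinear sources (cond={cond:.3g})", stacklevel=2)
    w, rnorm = optimize.nnls(S, y)
    if w.sum() <= 0:
        raise ValueError(f"{target_id}: degenerate NNLS solution (all-zero weights)")
    return MixtureResult(
        target=target_id,
        sources=names,
        weights=w / w.sum(),
        residual_norm=float(rnorm),
        n_reference_features=len(y),
    )


def sharing_features(
    m: IBDShareMatrix,
    reference_groups: dict,
    target_id: str,
) -> np.ndarray:
    """Feature vector for a target: mean sharing rate with each reference
    group's members (the target itself excluded from every group)."""
    i = m.index(target_id)
    feats = []
    for members in reference_groups.values():
        idx = [m.index(s) for s in members if s != target_id]
        if not idx:
            raise ValueError(f"reference group empty after excluding {target_id!r}")
        feats.append(float(m.rate[i, idx].mean()))
    return np.array(feats)


def mixture_from_matrix(
    m: IBDShareMatrix,
    reference_groups: dict,
    target_id: str,
    per_individual: bool = False,
) -> MixtureResult:
    """Supervised mixture of a target over labelled reference groups.

    Source vectors default to cluster means (each source's members averaged
    in the same group-feature space); ``per_individual=True`` instead uses
    each group's best-matching member profile stacked per group.
    """
    y = sharing_features(m, reference_groups, target_id)
    sources = {}
    for name, members in reference_groups.items():
        vecs = []
        for s in members:
            if s == target_id:
                continue
            vecs.append(sharing_features(m, reference_groups, s))
        V = np.vstack(vecs)
        sources[name] = V.mean(axis=0) if not per_individual else np.median(V, axis=0)
    return nnls_mixture(y, sources, target_id=target_id)


# ---------------------------------------------------------------------------
# D-statistics
# ---------------------------------------------------------------------------

@dataclass
class DStatResult:
    populations: tuple
    D: float
    Z: float
    stderr: float
    n_sites_used: int
    n_blocks: int
    block_size: float

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.D <= 1.0 + 1e-12):
            raise ValueError("|D| must be <= 1")


def _group_freqs(g: GenotypeTable, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    index = {s: j for j, s in enumerate(g.samples)}
    unknown = [s for s in ids if s not in index]
    if unknown:
        raise ValueError(f"unknown samples in group: {unknown}")
    cols = [index[s] for s in ids]
    dos = g.dosages[:, cols].astype(float)
    obs = dos != MISSING
    count = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, dos, 0.0).sum(axis=1) / (2.0 * count)
    return p, count > 0


def d_statistic(
    g: GenotypeTable,
    groups: tuple,
    block_size: float = 5.0,
    weighted: bool = True,
    genetic_positions: np.ndarray | None = None,
) -> DStatResult:
    """Four-population D with block-jackknife Z.

    D = sum (p1-p2)(p3-p4) / sum (p1+p2-2 p1 p2)(p3+p4-2 p3 p4), with p the
    per-group non-missing ALT frequency; positive D indicates an excess of
    BABA-type sharing between the first and third populations.  Blocks are
    contiguous along the genome: ``block_size`` is interpreted in cM when
    ``genetic_positions`` (one value per site) is given, otherwise in Mb.
    """
    if len(groups) != 4:
        raise ValueError("groups must be (P1, P2, P3, P4)")
    for gi in groups:
        if len(gi) == 0:
            raise ValueError("empty population group")
    freqs = []
    used = np.ones(g.n_sites, dtype=bool)
    for ids in groups:
        p, has = _group_freqs(g, list(ids))
        freqs.append(p)
        used &= has
    if not used.any():
        raise ValueError("no site has a non-missing call in every population")
    p1, p2, p3, p4 = (np.where(used, f, 0.0) for f in freqs)
    num = np.where(used, (p1 - p2) * (p3 - p4), 0.0)
    den = np.where(used, (p1 + p2 - 2 * p1 * p2) * (p3 + p4 - 2 * p3 * p4), 0.0)
    if den.sum() <= 0:
        raise ValueError("zero denominator: no informative sites")

    # contiguous blocks along the genome
    if genetic_positions is not None:
        pos = np.asarray(genetic_positions, dtype=float)
        chroms = np.array([s.chrom for s in g.sites])
    else:
        pos = np.array([s.pos for s in g.sites], dtype=float) / 1e6  # Mb
        chroms = np.array([s.chrom for s in g.sites])
    block_keys = pd.Series(list(zip(chroms, np.floor(pos / block_size).astype(int))))
    block_ids, block_codes = np.unique(block_keys[used].to_numpy(), return_inverse=True)

    codes = np.full(g.n_sites, -1)
    codes[used] = block_codes
    n_blocks = len(block_ids)
    if n_blocks < 3:
        raise ValueError("jackknife undefined: fewer than 3 non-empty blocks")

    num_b = np.zeros(n_blocks)
    den_b = np.zeros(n_blocks)
    m_b = np.zeros(n_blocks)
    sel = codes >= 0
    np.add.at(num_b, codes[sel], num[sel])
    np.add.at(den_b, codes[sel], den[sel])
    np.add.at(m_b, codes[sel], 1.0)

    N, Dn = num_b.sum(), den_b.sum()
    theta = N / Dn
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_minus = (N - num_b) / (Dn - den_b)
    theta_minus = np.where(np.isfinite(theta_minus), theta_minus, theta)

    if not weighted:
        m_b = np.ones(n_blocks)
    M = m_b.sum()
    h = M / m_b
    theta_j = n_blocks * theta - np.sum((1.0 - m_b / M) * theta_minus)
    tau = h * theta - (h - 1.0) * theta_minus
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / n_blocks
    se = float(np.sqrt(var))
    z = float(theta / se) if se > 0 else float("inf") * np.sign(theta) if theta != 0 else 0.0

    return DStatResult(
        populations=tuple(tuple(gi) for gi in groups),
        D=float(np.clip(theta, -1.0, 1.0)),
        Z=z,
        stderr=se,
        n_sites_used=int(used.sum()),
        n_blocks=n_blocks,
        block_size=float(block_size),
    )


# ---------------------------------------------------------------------------
# Least-squares PCA projection
# ---------------------------------------------------------------------------

@dataclass
class ReferencePCA:
    site_ids: list[str]
    freqs: np.ndarray  # reference ALT allele frequency per site
    loadings: np.ndarray  # (n_sites, k), orthonormal columns
    eigenvalues: np.ndarray
    coords: np.ndarray  # (n_ref, k)
    sample_ids: list[str]


def fit_reference_pca(g: GenotypeTable, k: int = 2) -> ReferencePCA:
    """smartpca-style PCA of a reference panel.

    Dosages are centered at 2p and scaled by sqrt(p(1-p)); missing reference
    calls are mean-imputed (zero after centering).  Monomorphic sites are
    dropped.
    """
    if k >= g.n_samples:
        raise ValueError("k must be < number of reference samples")
    dos = g.dosages.astype(float)
    obs = dos != MISSING
    p = g.alt_freqs()
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    dos, obs, p = dos[keep], obs[keep], p[keep]
    scale = np.sqrt(p * (1.0 - p))
    Z = np.where(obs, (dos - 2.0 * p[:, None]) / scale[:, None], 0.0)
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)  # samples x sites
    coords = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    eigenvalues = (S**2) / max(g.n_samples - 1, 1)
    return ReferencePCA(
        site_ids=[s.name for s, m in zip(g.sites, keep) if m],
        freqs=p,
        loadings=loadings,
        eigenvalues=eigenvalues[:k],
        coords=coords,
        sample_ids=list(g.samples),
    )


def lsq_project(ref: ReferencePCA, dosages: np.ndarray, min_overlap: int = 10) -> np.ndarray:
    """Project a possibly-missing dosage vector onto reference loadings.

    ``dosages`` is aligned to ``ref.site_ids`` (MISSING = -1 allowed); the
    least-squares solution uses only non-missing sites.
    """
    dos = np.asarray(dosages, dtype=float)
    if dos.shape[0] != len(ref.site_ids):
        raise ValueError("dosage vector not aligned to reference sites")
    obs = dos != MISSING
    if obs.sum() < min_overlap:
        raise ValueError(f"fewer than {min_overlap} non-missing sites overlap the loadings")
    scale = np.sqrt(ref.freqs * (1.0 - ref.freqs))
    z = (dos[obs] - 2.0 * ref.freqs[obs]) / scale[obs]
    V = ref.loadings[obs]
    coords, *_ = np.linalg.lstsq(V, z, rcond=None)
    return coords


# ---------------------------------------------------------------------------
# Admixture-LD decay dating (simplified)
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureDateResult:
    target: str
    decay_rate: float  # lambda, per Morgan == generations
    generations: float
    years: float
    amplitude: float
    offset: float
    fit_rmse: float
    no_date: bool
    bin_centers: np.ndarray
    statistic: np.ndarray


def admixture_date(
    haplotypes: np.ndarray,
    positions_morgans: np.ndarray,
    source_freqs: tuple,
    bins: np.ndarray | None = None,
    generation_time: float = DEFAULT_GENERATION_TIME,
    target: str = "target",
    min_bins: int = 5,
) -> AdmixtureDateResult:
    """Date a pulse admixture event from weighted two-locus covariance decay.

    ``haplotypes``: (n_haplotypes, n_sites) 0/1 matrix.  ``source_freqs``:
    (p_A, p_B) allele frequencies of the two source populations; the site
    weight is their difference.  The per-bin statistic is
    sum(cov_st * w_s * w_t) / sum((w_s * w_t)^2) over site pairs at genetic
    distance d in the bin, which estimates alpha*(1-alpha)*exp(-g*d) for a
    pulse g generations ago.
    """
    X = np.asarray(haplotypes, dtype=float)
    pos = np.asarray(positions_morgans, dtype=float)
    pA, pB = (np.asarray(p, dtype=float) for p in source_freqs)
    if X.ndim != 2 or X.shape[1] != len(pos):
        raise ValueError("haplotypes must be (n_hap, n_sites) aligned to positions")
    w = pA - pB
    Xc = X - X.mean(axis=0)
    n_hap = X.shape[0]
    C = (Xc.T @ Xc) / max(n_hap - 1, 1)

    iu, ju = np.triu_indices(len(pos), k=1)
    d = np.abs(pos[iu] - pos[ju])
    ww = w[iu] * w[ju]
    cov = C[iu, ju]

    if bins is None:
        d_max = float(np.quantile(d, 0.5))
        bins = np.linspace(0.0, max(d_max, 0.05), 21)
    bins = np.asarray(bins, dtype=float)
    codes = np.digitize(d, bins) - 1
    inside = (codes >= 0) & (codes < len(bins) - 1)
    n_bins = len(bins) - 1
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    np.add.at(num, codes[inside], (cov * ww)[inside])
    np.add.at(den, codes[inside], (ww**2)[inside])
    np.add.at(cnt, codes[inside], 1.0)
    good = (cnt > 0) & (den > 0)
    if good.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} non-empty distance bins, got {int(good.sum())}")
    centers = 0.5 * (bins[:-1] + bins[1:])[good]
    A = num[good] / den[good]

    def model(dd, a0, lam, c0):
        return a0 * np.exp(-lam * dd) + c0

    no_date = False
    try:
        p0 = (max(A[0], 1e-4), 10.0, 0.0)
        popt, _ = optimize.curve_fit(model, centers, A, p0=p0, maxfev=20000)
        a0, lam, c0 = (float(v) for v in popt)
    except (RuntimeError, ValueError):
        a0, lam, c0 = float(A.mean()), 0.0, 0.0
        no_date = True
    resid = A - model(centers, a0, lam, c0)
    rmse = float(np.sqrt(np.mean(resid**2)))
    # no usable date when the decay is absent, or when the exponential
    # explains little beyond a flat profile (signal indistinguishable from
    # bin noise)
    sse_exp = float(np.sum(resid**2))
    sse_const = float(np.sum((A - A.mean()) ** 2))
    if lam <= 0 or a0 <= 0 or (sse_const > 0 and sse_exp > 0.5 * sse_const):
        no_date = True
    return AdmixtureDateResult(
        target=target,
        decay_rate=lam,
        generations=lam,
        years=lam * generation_time,
        amplitude=a0,
        offset=c0,
        fit_rmse=rmse,
        no_date=no_date,
        bin_centers=centers,
        statistic=A,
    )
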