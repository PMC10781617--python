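"""IBD-segment tables -> sharing-rate matrices, community detection and PCA.

The sharing matrix stores, per unordered pair, the summed length (cM) of IBD
segments at or above a minimum reportable length, and the dimensionless rate
(total / analyzable map length).  Clustering is a *deterministic* greedy
modularity agglomeration on the weighted sharing network (ties broken on
lexicographic community labels) recursed within large communities to build
nested levels; PCA is an eigendecomposition of the covariance matrix of the
sharing-rate rows.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IBDShareMatrix",
    "ClusterAssignment",
    "PCAResult",
    "sharing_matrix",
    "detect_communities",
    "ibd_pca",
    "read_ibd_tsv",
    "modularity",
]

IBD_COLUMNS = ["sample1", "sample2", "chrom", "start_cM", "end_cM", "length_cM"]


def read_ibd_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample1", "sample2", "length_cM") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


@dataclass
class IBDShareMatrix:
    """Symmetric total-cM and rate matrices over a fixed id order."""

    ids: list[str]
    total_cm: np.ndarray
    rate: np.ndarray
    map_length: float

    def __post_init__(self):
        n = len(self.ids)
        if self.total_cm.shape != (n, n) or self.rate.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.total_cm, self.total_cm.T):
            raise ValueError("total_cm must be symmetric")
        if np.any(np.diag(self.total_cm) != 0):
            raise ValueError("diagonal must be zero by convention")
        if np.any(self.total_cm > 2.0 * self.map_length + 1e-9):
            raise ValueError("pair total exceeds 2 x map length (sanity bound)")

    def index(self, sample_id: str) -> int:
        return self.ids.index(sample_id)

    def to_frame(self, which: str = "rate") -> pd.DataFrame:
        mat = self.rate if which == "rate" else self.total_cm
        return pd.DataFrame(mat, index=self.ids, columns=self.ids)


def sharing_matrix(
    segments: pd.DataFrame,
    ids: list[str],
    map_length: float,
    min_segment_cm: float = 1.0,
) -> IBDShareMatrix:
    """Accumulate per-pair total IBD sharing from a segment table.

    Segments shorter than ``min_segment_cm`` are ignored; pair orientation
    and row order of the input are irrelevant.
    """
    if map_length <= 0:
        raise ValueError("map_length must be positive")
    index = {s: i for i, s in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate ids")
    n = len(ids)
    total = np.zeros((n, n))
    if len(segments):
        known = segments["sample1"].isin(index) & segments["sample2"].isin(index)
        if not known.all():
            offenders = sorted(
                set(segments.loc[~segments["sample1"].isin(index), "sample1"])
                | set(segments.loc[~segments["sample2"].isin(index), "sample2"])
            )
            raise ValueError(f"segments reference unknown ids: {offenders}")
        keep = segments["length_cM"] >= min_segment_cm
        sub = segments.loc[keep]
        i = sub["sample1"].map(index).to_numpy()
        j = sub["sample2"].map(index).to_numpy()
        L = sub["length_cM"].to_numpy(dtype=float)
        if np.any(L <= 0):
            raise ValueError("segment lengths must be positive")
        np.add.at(total, (i, j), L)
        np.add.at(total, (j, i), L)
        np.fill_diagonal(total, 0.0)
    return IBDShareMatrix(list(ids), total, total / map_length, float(map_length))


# ---------------------------------------------------------------------------
# Community detection: deterministic greedy modularity agglomeration
# ---------------------------------------------------------------------------

def modularity(weights: np.ndarray, labels: np.ndarray) -> float:
    """Weighted-graph Newman modularity of a partition (zero-diagonal W)."""
    w2 = weights.sum()
    if w2 <= 0:
        return 0.0
    deg = weights.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        sel = labels == lab
        q += weights[np.ix_(sel, sel)].sum() / w2 - (deg[sel].sum() / w2) ** 2
    return float(q)


def _greedy_partition(weights: np.ndarray, ids: list[str], gain_tol: float) -> list[list[int]]:
    """Agglomerate singletons by best modularity gain until gain < gain_tol.

    Communities are keyed by their lexicographically smallest member id; the
    merge candidate with the largest gain wins, ties resolved on the sorted
    (key1, key2) pair.  Fully deterministic for a fixed id order.
    """
    n = len(ids)
    w2 = weights.sum()
    comms: dict[str, list[int]] = {ids[i]: [i] for i in range(n)}
    # e[c1][c2]: fraction of total weight between communities; a[c]: degree fraction
    e = {
        ids[i]: {ids[j]: weights[i, j] / w2 for j in range(n) if j != i and weights[i, j] > 0}
        for i in range(n)
    }
    a = {ids[i]: weights[i].sum() / w2 for i in range(n)}

    while len(comms) > 1:
        best = None
        for c1 in sorted(e):
            for c2 in sorted(e[c1]):
                if c2 <= c1:
                    continue
                gain = 2.0 * (e[c1][c2] - a[c1] * a[c2])
                key = (-gain, c1, c2)
                if best is None or key < best[0]:
                    best = (key, c1, c2, gain)
        if best is None or best[3] < gain_tol:
            break
        _, c1, c2, _ = best
        # merge c2 into c1 (c1 is lexicographically smaller -> stays the key)
        comms[c1].extend(comms.pop(c2))
        for nb, w in e.pop(c2).items():
            if nb == c1:
                continue
            e[nb].pop(c2, None)
            e[c1][nb] = e[c1].get(nb, 0.0) + w
            e[nb][c1] = e[c1][nb]
        e[c1].pop(c2, None)
        a[c1] += a.pop(c2)
    return [sorted(members) for _, members in sorted(comms.items())]


@dataclass
class ClusterAssignment:
    """Nested community labels per individual.

    ``labels[id]`` is a tuple, one element per level, e.g. ``("2", "2.1")``;
    deeper levels refine their parent.  ``modularity_by_parent`` maps a
    parent label ("" for the root split) to the modularity of the partition
    found inside it.
    """

    ids: list[str]
    labels: dict
    modularity_by_parent: dict

    @property
    def n_levels(self) -> int:
        return max(len(v) for v in self.labels.values())

    def level(self, k: int = 0) -> dict:
        """id -> label at level k (deepest available label if shallower)."""
        return {i: v[min(k, len(v) - 1)] for i, v in self.labels.items()}

    def communities(self, k: int = 0) -> dict:
        out: dict[str, list[str]] = {}
        for i, lab in self.level(k).items():
            out.setdefault(lab, []).append(i)
        return {lab: sorted(members) for lab, members in sorted(out.items())}


def detect_communities(
    m: IBDShareMatrix,
    min_size: int = 5,
    gain_tol: float = 1e-9,
    max_depth: int = 3,
) -> ClusterAssignment:
    """Hierarchical community detection on the sharing-rate network."""
    n = len(m.ids)
    if n < 2:
        raise ValueError("need at least two individuals")
    labels = {i: [] for i in m.ids}
    mod_by_parent: dict[str, float] = {}

    def recurse(indices: list[int], parent: str, depth: int):
        sub_ids = [m.ids[i] for i in indices]
        W = m.rate[np.ix_(indices, indices)]
        if W.sum() <= 0:
            if parent == "":
                warnings.warn("all-zero sharing matrix: single community", stacklevel=3)
            groups = [list(range(len(indices)))]
        else:
            groups = _greedy_partition(W, sub_ids, gain_tol)
        if len(groups) == 1 and parent != "":
            return  # no further split inside this community
        lab_vec = np.empty(len(indices), dtype=int)
        for g, members in enumerate(groups):
            lab_vec[members] = g
        mod_by_parent[parent] = modularity(W, lab_vec)
        for g, members in enumerate(groups):
            lab = f"{parent}.{g}" if parent else str(g)
            global_members = [indices[k] for k in members]
            for gi in global_members:
                labels[m.ids[gi]].append(lab)
            if depth + 1 < max_depth and len(global_members) >= min_size and len(groups) > 1:
                recurse(global_members, lab, depth + 1)

    recurse(list(range(n)), "", 0)
    return ClusterAssignment(
        ids=list(m.ids),
        labels={i: tuple(v) for i, v in labels.items()},
        modularity_by_parent=mod_by_parent,
    )


# ---------------------------------------------------------------------------
# IBD-covariance PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    ids: list[str]
    coords: np.ndarray  # (n, k), eigenvector * sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all n, non-increasing
    k: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.coords, index=self.ids, columns=cols)


def ibd_pca(m: IBDShareMatrix, k: int = 2) -> PCAResult:
    """Top-k eigendecomposition of the covariance of sharing-rate rows.

    The self-sharing diagonal is replaced by each row's off-diagonal mean
    before computing covariances, to avoid self-sharing artifacts.  Signs
    are fixed so each component's largest-magnitude loading is positive.
    """
    n = len(m.ids)
    if k >= n:
        raise ValueError(f"k must be < number of individuals ({n})")
    R = m.rate.astype(float).copy()
    if n > 1:
        row_mean = R.sum(axis=1) / (n - 1)
        np.fill_diagonal(R, row_mean)
    C = np.cov(R)  # rows of R are the observations' feature vectors
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return PCAResult(list(m.ids), coords, evals, k)
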