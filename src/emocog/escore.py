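"""Composite E-scores from the behavioral feature matrix.

The construction:

1. column-standardize the feature matrix, impute missing cells with the
   column mean (z = 0), and winsorize at |z| <= 2.5 so single outliers do
   not dominate the decompositions;
2. embed the *indices* in 2-D by taking each index's loadings on the first
   two principal components of the participants x indices z-matrix;
3. group the indices by k-means on that plane (k chosen by the inertia
   elbow, or overridden — the study value is 3), with labels canonicalized
   so group 1 is RT-dominated, the last group accuracy-dominated, and the
   emotional-contrast group in between;
4. verify the grouping by leave-one-out cross-validation (refit without one
   index, assign it to the nearest refit center, compare);
5. E-score g = participants' scores on the first principal component of the
   z-scored indices in group g, signed so an anchor index loads positively
   (group 1: overall eFlanker RT; group 2: the pooled emotional-vs-neutral
   RT difference; group 3: overall eFlanker accuracy).

Higher E-score 1 = slower overall; higher E-score 2 = stronger emotional
interference; higher E-score 3 = more accurate responding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .indices import FeatureMatrix

__all__ = [
    "ZMatrix",
    "FeatureEmbedding",
    "FeatureGrouping",
    "EScoreTable",
    "DEFAULT_ANCHORS",
    "winsorized_zscore",
    "embed_features",
    "inertia_curve",
    "choose_k",
    "cluster_features",
    "loo_cluster_stability",
    "compute_escores",
    "derive_escores",
]

Z_CAP = 2.5

DEFAULT_ANCHORS: dict[int, str] = {
    1: "eflanker_rt_overall",
    2: "eflanker_rt_diff_emotional_vs_neutral_target",
    3: "eflanker_acc_overall",
}


@dataclass
class ZMatrix:
    """Standardized, mean-imputed, winsorized feature matrix."""

    values: pd.DataFrame        # capped z-scores, no missing cells
    imputed: pd.DataFrame       # True where a cell was mean-imputed
    col_means: pd.Series
    col_sds: pd.Series
    dropped_columns: list[str] = field(default_factory=list)
    cap: float = Z_CAP


def winsorized_zscore(
    features: FeatureMatrix | pd.DataFrame,
    cap: float = Z_CAP,
    on_constant: str = "raise",
) -> ZMatrix:
    """Column z-scores capped at ``|z| <= cap``; missing cells imputed at 0.

    Standardization uses the mean/SD (ddof=1) over non-missing entries of
    each column; capping is applied after standardization, so applying the
    operation to already-capped data is a no-op.  Zero-variance columns
    either raise (default) or are dropped with a record
    (``on_constant="drop"``, used by the pipeline).
    """
    frame = features.values if isinstance(features, FeatureMatrix) else features
    if len(frame) < 3:
        raise ValueError("need at least 3 rows to standardize")
    if on_constant not in ("raise", "drop"):
        raise ValueError("on_constant must be 'raise' or 'drop'")

    means = frame.mean(axis=0)
    sds = frame.std(axis=0, ddof=1)
    counts = frame.notna().sum(axis=0)
    constant = (sds.fillna(0.0) == 0.0) | (counts < 2)
    if constant.any():
        bad = list(frame.columns[constant])
        if on_constant == "raise":
            raise ValueError(f"zero-variance column(s): {bad}")
        frame = frame.drop(columns=bad)
        means = means.drop(bad)
        sds = sds.drop(bad)
    else:
        bad = []

    z = (frame - means) / sds
    imputed = z.isna()
    z = z.fillna(0.0).clip(lower=-cap, upper=cap)
    return ZMatrix(values=z, imputed=imputed, col_means=means, col_sds=sds,
                   dropped_columns=bad, cap=cap)


@dataclass
class FeatureEmbedding:
    """Each index's coordinates on the first two participant-space PCs."""

    coords: pd.DataFrame                 # index name x [pc1, pc2]
    explained_variance_ratio: np.ndarray


def _signed_components(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|loading| entry of each
    component is positive."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def embed_features(z: ZMatrix) -> FeatureEmbedding:
    """First two principal components of the z-matrix, read as per-index
    loading pairs."""
    X = z.values.to_numpy(float)
    n, p = X.shape
    if min(n - 1, p) < 2:
        raise ValueError("z-matrix rank < 2; cannot extract two components")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(X)
    comp = _signed_components(pca.components_)
    coords = pd.DataFrame(comp.T, index=z.values.columns, columns=["pc1", "pc2"])
    return FeatureEmbedding(coords=coords,
                            explained_variance_ratio=pca.explained_variance_ratio_.copy())


# ---------------------------------------------------------------------------
# grouping


def inertia_curve(
    embedding: FeatureEmbedding,
    k_max: int = 8,
    seed: int = 0,
    restarts: int = 50,
) -> dict[int, float]:
    """Within-cluster sum of squares for k = 1..k_max."""
    X = embedding.coords.to_numpy(float)
    k_max = min(k_max, len(X))
    curve: dict[int, float] = {}
    centroid = X.mean(axis=0)
    curve[1] = float(((X - centroid) ** 2).sum())
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        curve[k] = float(km.inertia_)
    return curve


def choose_k(inertia: Mapping[int, float] | Sequence[float], override: int | None = None) -> int:
    """Elbow rule: the k in 2..K-1 maximizing the inertia second difference
    I(k-1) - 2 I(k) + I(k+1); ties break toward the smallest k."""
    if override is not None:
        return int(override)
    if isinstance(inertia, Mapping):
        ks = sorted(inertia)
        vals = np.array([inertia[k] for k in ks], float)
    else:
        vals = np.asarray(inertia, float)
        ks = list(range(1, len(vals) + 1))
    if len(vals) < 4:
        raise ValueError("need inertia for at least 4 candidate k")
    if np.any(np.diff(vals) > 1e-9 * max(1.0, abs(vals[0]))):
        raise ValueError("inertia must be non-increasing in k")
    second = vals[:-2] - 2 * vals[1:-1] + vals[2:]  # indexed by middle k
    best = int(np.argmax(second))  # first occurrence = smallest k on ties
    return ks[best + 1]


@dataclass
class FeatureGrouping:
    """k-means grouping of the indices, with canonical group numbering."""

    k: int
    labels: pd.Series                 # index name -> group in 1..k
    centers: np.ndarray               # (k, 2), row g-1 = canonical group g
    inertia: dict[int, float]
    chosen_k_note: str = ""
    kinds: pd.Series | None = None

    def members(self, group: int) -> list[str]:
        return list(self.labels.index[self.labels == group])


def _canonical_order(raw_labels: np.ndarray, k: int, kinds: np.ndarray | None,
                     coords: np.ndarray) -> list[int]:
    """Order raw cluster ids so position 0 is RT-dominated and the last
    position accuracy-dominated (fallback: by mean pc1, descending)."""
    keys = []
    for c in range(k):
        members = raw_labels == c
        if kinds is not None and members.any():
            rt_share = float(np.mean(kinds[members] == "rt"))
            acc_share = float(np.mean(kinds[members] == "accuracy"))
            keys.append(rt_share - acc_share)
        else:
            keys.append(float(coords[members, 0].mean()) if members.any() else -np.inf)
    return sorted(range(k), key=lambda c: (-keys[c], c))


def cluster_features(
    embedding: FeatureEmbedding,
    k: int,
    seed: int = 0,
    restarts: int = 50,
    kinds: Mapping[str, str] | pd.Series | None = None,
    inertia: Mapping[int, float] | None = None,
    chosen_k_note: str = "",
) -> FeatureGrouping:
    """k-means (squared Euclidean) on the 2-D embedding, best of ``restarts``
    seeded initializations, with canonicalized group labels."""
    X = embedding.coords.to_numpy(float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of indices ({len(X)})")
    if k == 1:
        raw = np.zeros(len(X), int)
        centers = X.mean(axis=0, keepdims=True)
        inert = float(((X - centers) ** 2).sum())
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        raw = km.labels_
        centers = km.cluster_centers_
        inert = float(km.inertia_)

    kind_arr = None
    kind_series = None
    if kinds is not None:
        kind_series = pd.Series(kinds).reindex(embedding.coords.index)
        kind_arr = kind_series.to_numpy(object)
    order = _canonical_order(raw, k, kind_arr, X)
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=embedding.coords.index,
                       name="group")
    centers = centers[order]
    curve = dict(inertia) if inertia is not None else {}
    curve.setdefault(k, inert)
    return FeatureGrouping(k=k, labels=labels, centers=centers, inertia=curve,
                           chosen_k_note=chosen_k_note, kinds=kind_series)


def _match_labels(ref: np.ndarray, new: np.ndarray, k: int) -> dict[int, int]:
    """Map refit cluster ids to reference group numbers by maximal overlap."""
    overlap = np.zeros((k, k))
    for c in range(k):
        for g in range(1, k + 1):
            overlap[c, g - 1] = np.sum((new == c) & (ref == g))
    rows, cols = linear_sum_assignment(-overlap)
    return {int(c): int(g + 1) for c, g in zip(rows, cols)}


def loo_cluster_stability(
    embedding: FeatureEmbedding,
    grouping: FeatureGrouping,
    seed: int = 0,
    restarts: int = 50,
) -> float:
    """Fraction of indices that keep their group under leave-one-out refits.

    For each index: refit k-means on the remaining indices, align refit
    clusters to the original groups by best label overlap, assign the
    held-out index to the nearest refit center (ties to the lowest group
    number), and compare with its original group.
    """
    k = grouping.k
    X = embedding.coords.to_numpy(float)
    ref = grouping.labels.to_numpy(int)
    if k == 1:
        warnings.warn("loo_cluster_stability with k=1 is trivially 1.0", stacklevel=2)
        return 1.0
    hits = 0
    n = len(X)
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(rest)
        mapping = _match_labels(np.delete(ref, i), km.labels_, k)
        d = ((km.cluster_centers_ - X[i]) ** 2).sum(axis=1)
        groups = np.array([mapping[c] for c in range(k)])
        nearest = groups[d <= d.min() + 1e-12].min()  # tie -> lowest group
        hits += int(nearest == ref[i])
    return hits / n


# ---------------------------------------------------------------------------
# E-scores


@dataclass
class EScoreTable:
    """Per-participant E-scores plus each group's unit-norm loading vector."""

    scores: pd.DataFrame                  # participant x escore1..k
    loadings: dict[int, pd.Series]
    anchors: dict[int, str]
    explained_variance_ratio: dict[int, float]


def _first_pc(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Scores, unit-norm loading vector and variance ratio of the first PC
    of the column-centered matrix X."""
    Xc = X - X.mean(axis=0, keepdims=True)
    if X.shape[1] == 1:
        v = np.ones(1)
        return Xc[:, 0], v, 1.0
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Xc)[:, 0]
    return scores, pca.components_[0].copy(), float(pca.explained_variance_ratio_[0])


def compute_escores(
    z: ZMatrix,
    grouping: FeatureGrouping,
    anchors: Mapping[int, str] | None = None,
) -> EScoreTable:
    """First principal component of each group's z-scored indices.

    Signs are fixed so the group's anchor index loads positively; when the
    anchor is absent from the group (or loads ~0), the largest-|loading|
    index is made positive instead.
    """
    anchors = dict(DEFAULT_ANCHORS if anchors is None else anchors)
    scores = {}
    loadings = {}
    used_anchors = {}
    evr = {}
    for g in range(1, grouping.k + 1):
        cols = [c for c in grouping.members(g) if c in z.values.columns]
        if not cols:
            raise ValueError(f"group {g} has no indices in the z-matrix")
        X = z.values[cols].to_numpy(float)
        s, v, ratio = _first_pc(X)
        load = pd.Series(v, index=cols)
        anchor = anchors.get(g)
        if anchor in cols and abs(load[anchor]) > 1e-12:
            flip = load[anchor] < 0
            used_anchors[g] = anchor
        else:
            top = load.abs().idxmax()
            flip = load[top] < 0
            used_anchors[g] = top
        if flip:
            load = -load
            s = -s
        scores[f"escore{g}"] = s
        loadings[g] = load
        evr[g] = ratio
    table = pd.DataFrame(scores, index=z.values.index)
    return EScoreTable(scores=table, loadings=loadings, anchors=used_anchors,
                       explained_variance_ratio=evr)


def derive_escores(
    features: FeatureMatrix,
    k: int | None = 3,
    k_max: int = 8,
    seed: int = 0,
    restarts: int = 50,
    cap: float = Z_CAP,
    anchors: Mapping[int, str] | None = None,
    compute_stability: bool = True,
    compute_curve: bool = True,
) -> tuple[ZMatrix, FeatureEmbedding, FeatureGrouping, EScoreTable, float | None]:
    """Convenience pipeline: features -> (z, embedding, grouping, scores,
    LOO stability).  ``k=None`` selects k by the inertia elbow."""
    z = winsorized_zscore(features, cap=cap, on_constant="drop")
    embedding = embed_features(z)
    if k is None or compute_curve:
        curve = inertia_curve(embedding, k_max=k_max, seed=seed, restarts=restarts)
    else:
        curve = {}
    if k is None:
        k_used = choose_k(curve)
        note = f"elbow rule on inertia for k=1..{max(curve)}"
    else:
        k_used = int(k)
        note = "override"
    kinds = features.kinds()
    grouping = cluster_features(embedding, k_used, seed=seed, restarts=restarts,
                                kinds=kinds, inertia=curve, chosen_k_note=note)
    table = compute_escores(z, grouping, anchors=anchors)
    stability = (loo_cluster_stability(embedding, grouping, seed=seed,
                                       restarts=restarts)
                 if compute_stability else None)
    return z, embedding, grouping, table, stability
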