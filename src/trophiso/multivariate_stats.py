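"""Distance-based inference: PERMANOVA and canonical analysis of principal
coordinates (CAP).

PERMANOVA partitions the total sum of squared inter-point distances into
among- and within-group components and tests the pseudo-F ratio against a
permutation null (raw-observation permutation).  With Euclidean distances on
a single variable the pseudo-F is algebraically identical to the classical
one-way ANOVA F, which is the primary correctness oracle for this module.

CAP is a constrained ordination: a principal coordinates analysis (Gower
centring + eigendecomposition) followed by a canonical correlation analysis
between the first m PCo axes and the group indicators.  It yields a trace
statistic (sum of squared canonical correlations), a permutation test,
leave-one-out classification and assignment of new samples via the Gower
add-a-point projection.  Here it assigns individual mice to 1000-m
elevational zones from their (lipid-corrected δ¹³C, δ¹⁵N, δ³⁴S) values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, ValidationError

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "PairwiseResult",
    "CapModel",
    "ConfusionTable",
    "euclidean_distances",
    "permanova_oneway",
    "pairwise_permanova",
    "cap_fit",
    "cap_permutation_test",
    "cap_loo",
    "cap_assign",
]

_MAX_PCO_AXES = 20  # cap on m during automatic selection


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with sample ids in row order."""

    data: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(self.ids) != d.shape[0]:
            raise ValidationError("id count does not match matrix size")
        if np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.max(np.abs(d - d.T)) > 1e-12:
            raise ValidationError("distance matrix must be symmetric to 1e-12")
        object.__setattr__(self, "data", d)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        return DistanceMatrix(
            self.data[np.ix_(idx, idx)], tuple(self.ids[i] for i in idx)
        )


def euclidean_distances(
    values: np.ndarray, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Euclidean distances on raw (unstandardised) rows of *values*."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise InputError("values must be a 2-D (samples × variables) array")
    if ids is None:
        ids = [str(i) for i in range(x.shape[0])]
    bad = np.where(~np.isfinite(x).all(axis=1))[0]
    if bad.size:
        raise InputError(
            "missing/non-finite values for sample(s): "
            + ", ".join(str(ids[i]) for i in bad)
        )
    return DistanceMatrix(squareform(pdist(x, metric="euclidean")), tuple(ids))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    df_among: int
    df_within: int
    p_perm: float
    n_perm: int


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    t: float
    p_perm: float
    n_perm: int


def _group_indices(groups: Sequence[str]) -> tuple[list[str], list[np.ndarray]]:
    labels = sorted(set(groups))
    garr = np.asarray(groups)
    return labels, [np.where(garr == lab)[0] for lab in labels]


def _pseudo_f(d2: np.ndarray, idx_groups: list[np.ndarray]) -> float:
    n = d2.shape[0]
    g = len(idx_groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = sum(
        d2[np.ix_(ix, ix)].sum() / (2.0 * ix.size) for ix in idx_groups
    )
    ss_among = ss_total - ss_within
    df_a, df_w = g - 1, n - g
    if ss_within <= 1e-300:
        return 0.0 if abs(ss_among) <= 1e-300 else math.inf
    return (ss_among / df_a) / (ss_within / df_w)


def permanova_oneway(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1), so the smallest attainable
    p-value is 1/(n_perm + 1).
    """
    if len(groups) != D.n:
        raise InputError("group labels must match the distance matrix size")
    if n_perm < 99:
        raise InputError(f"n_perm must be >= 99, got {n_perm}")
    labels, idx_groups = _group_indices(groups)
    if len(labels) < 2:
        raise InputError("PERMANOVA needs at least two groups")
    small = [lab for lab, ix in zip(labels, idx_groups) if ix.size < 2]
    if small:
        raise InputError(f"group(s) of size 1 not allowed: {', '.join(small)}")
    d2 = D.data**2
    f_obs = _pseudo_f(d2, idx_groups)
    sizes = [ix.size for ix in idx_groups]
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    n = D.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        idx_perm = [perm[bounds[k]:bounds[k + 1]] for k in range(len(sizes))]
        if _pseudo_f(d2, idx_perm) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_F=f_obs,
        df_among=len(labels) - 1,
        df_within=n - len(labels),
        p_perm=p,
        n_perm=n_perm,
    )


def pairwise_permanova(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> list[PairwiseResult]:
    """Post hoc two-group tests; t = sqrt(two-group pseudo-F), raw p-values."""
    labels, idx_groups = _group_indices(groups)
    by_label = dict(zip(labels, idx_groups))
    garr = np.asarray(groups)
    rng = np.random.default_rng(seed)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ix = np.concatenate([by_label[a], by_label[b]])
            sub = D.submatrix(ix)
            res = permanova_oneway(
                sub, list(garr[ix]), n_perm=n_perm,
                seed=int(rng.integers(2**31)),
            )
            t = math.sqrt(res.pseudo_F) if math.isfinite(res.pseudo_F) else math.inf
            out.append(PairwiseResult(pair=(a, b), t=t, p_perm=res.p_perm,
                                      n_perm=n_perm))
    return out


# ---------------------------------------------------------------------------
# Principal coordinates (Gower centring) and add-a-point projection

def _pcoa(d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gower-centred eigendecomposition of a squared-distance matrix.

    Returns (eigvals desc, Q orthonormal eigenvectors, diag of the centred
    Gram matrix B), keeping only positive eigenvalues.  Negative eigenvalues
    (absent for Euclidean input) are dropped with a warning.
    """
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    b = a - row - row.T + a.mean()
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-10 if vals.size else 0.0
    if vals.size and vals[-1] < -max(tol, 1e-8):
        warnings.warn(
            "negative PCoA eigenvalues dropped (non-Euclidean distances?)",
            stacklevel=3,
        )
    keep = vals > tol
    if not keep.any():
        raise InputError("degenerate eigen-spectrum: no positive PCoA axes")
    return vals[keep], vecs[:, keep], np.diag(b).copy()


def _project_new(
    eigvals: np.ndarray, Q: np.ndarray, diag_b: np.ndarray, d0: np.ndarray
) -> np.ndarray:
    """Gower add-a-point: coordinates of a new sample, on the same
    orthonormal-axis scale as Q, from its distances *d0* to the training
    samples.  (v_k' g gives λ_k·Q_ik for a training point, so dividing by
    λ_k reproduces the Q entries exactly.)"""
    g = 0.5 * (diag_b - d0**2)
    return (g @ Q) / eigvals


# ---------------------------------------------------------------------------
# CAP

@dataclass(frozen=True)
class CapModel:
    """Fitted CAP: PCoA axes, canonical structure and group centroids.

    ``canonical_coords`` are the ordination coordinates (Q_m·U); internally
    classification uses the same axes rescaled to unit within-group variance,
    which makes nearest-centroid allocation equivalent to classical linear
    discriminant allocation when the distances are Euclidean and m is full
    rank.
    """

    ids: tuple[str, ...]
    groups: tuple[str, ...]
    group_labels: tuple[str, ...]
    eigvals: np.ndarray           # positive PCoA eigenvalues (descending)
    Q: np.ndarray                 # orthonormal PCo axes (n × n_pos)
    diag_b: np.ndarray            # diagonal of the centred Gram matrix
    m: int                        # number of PCo axes used
    sq_canonical_corrs: np.ndarray  # δ², length min(m, g-1)
    trace: float
    U: np.ndarray                 # canonical weights (m × r)
    canonical_coords: np.ndarray  # n × r ordination coordinates
    centroids: np.ndarray         # g × r centroids in classification space
    values: np.ndarray | None = None  # training values for new-sample distances

    @property
    def axis_scale(self) -> np.ndarray:
        return 1.0 / np.sqrt(np.clip(1.0 - self.sq_canonical_corrs, 1e-12, None))


def _canonical(
    Q_m: np.ndarray, groups: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Eigenstructure of Q_m' H Q_m, H the (centred) group-mean projection.

    Because the PCo axes are centred and orthonormal, Q'HQ = Σ_g n_g q̄_g q̄_g'
    and total scatter is the identity, so eigenvalues are the squared
    canonical correlations directly.
    """
    labels, idx_groups = _group_indices(groups)
    m = Q_m.shape[1]
    b = np.zeros((m, m))
    for ix in idx_groups:
        qbar = Q_m[ix].mean(axis=0)
        b += ix.size * np.outer(qbar, qbar)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    r = min(m, len(labels) - 1)
    vals = np.clip(vals[order][:r], 0.0, 1.0)
    return labels, vals, vecs[:, order][:, :r]


def _classification_coords(
    Q_m: np.ndarray, U: np.ndarray, sq_cc: np.ndarray
) -> np.ndarray:
    scale = 1.0 / np.sqrt(np.clip(1.0 - sq_cc, 1e-12, None))
    return (Q_m @ U) * scale


def _nearest_centroid(
    z: np.ndarray, centroids: np.ndarray, labels: Sequence[str]
) -> tuple[str, np.ndarray, bool]:
    """Nearest group centroid; ties broken to the lexicographically first
    label (labels arrive sorted) and flagged."""
    dists = np.linalg.norm(centroids - z, axis=1)
    best = int(np.argmin(dists))
    tol = 1e-9 * max(1.0, float(dists[best]))
    tie = bool(np.sum(dists <= dists[best] + tol) > 1)
    if tie:
        best = int(np.where(dists <= dists[best] + tol)[0][0])
    return labels[best], dists, tie


def _fit_cap(
    D: DistanceMatrix,
    groups: Sequence[str],
    m: int,
    values: np.ndarray | None,
) -> CapModel:
    eigvals, Q, diag_b = _pcoa(D.data)
    m = min(m, Q.shape[1])
    labels, sq_cc, U = _canonical(Q[:, :m], groups)
    coords = Q[:, :m] @ U
    zs = _classification_coords(Q[:, :m], U, sq_cc)
    garr = np.asarray(groups)
    centroids = np.vstack([zs[garr == lab].mean(axis=0) for lab in labels])
    return CapModel(
        ids=D.ids,
        groups=tuple(groups),
        group_labels=tuple(labels),
        eigvals=eigvals,
        Q=Q,
        diag_b=diag_b,
        m=m,
        sq_canonical_corrs=sq_cc,
        trace=float(sq_cc.sum()),
        U=U,
        canonical_coords=coords,
        centroids=centroids,
        values=None if values is None else np.asarray(values, dtype=float),
    )


def _loo_predict(
    D: DistanceMatrix, groups: Sequence[str], m: int
) -> tuple[list[str], list[bool]]:
    """Leave-one-out predictions: refit on n−1, project the held-out sample
    by the add-a-point formula, allocate to the nearest centroid."""
    n = D.n
    garr = np.asarray(groups)
    preds: list[str] = []
    flags: list[bool] = []
    for i in range(n):
        keep = np.delete(np.arange(n), i)
        sub = D.submatrix(keep)
        sub_groups = garr[keep]
        eigvals, Q, diag_b = _pcoa(sub.data)
        m_i = min(m, Q.shape[1])
        labels, sq_cc, U = _canonical(Q[:, :m_i], sub_groups)
        zs = _classification_coords(Q[:, :m_i], U, sq_cc)
        centroids = np.vstack(
            [zs[sub_groups == lab].mean(axis=0) for lab in labels]
        )
        y = _project_new(eigvals, Q, diag_b, D.data[i, keep])
        z_new = (y[:m_i] @ U) / np.sqrt(np.clip(1.0 - sq_cc, 1e-12, None))
        pred, _, tie = _nearest_centroid(z_new, centroids, labels)
        emptied = garr[i] not in labels
        preds.append(pred)
        flags.append(tie or emptied)
        if emptied:
            warnings.warn(
                f"sample {D.ids[i]!r}: its group was emptied by removal; "
                "classified against the remaining groups",
                stacklevel=3,
            )
    return preds, flags


def _loo_success(D: DistanceMatrix, groups: Sequence[str], m: int) -> float:
    preds, _ = _loo_predict(D, groups, m)
    garr = np.asarray(groups)
    return float(np.mean(np.asarray(preds) == garr))


def _choose_m(D: DistanceMatrix, groups: Sequence[str]) -> int:
    """Smallest m maximising leave-one-out classification success."""
    eigvals, Q, _ = _pcoa(D.data)
    g = len(set(groups))
    upper = min(D.n - 2, _MAX_PCO_AXES, Q.shape[1])
    if upper < 1:
        raise InputError("too few samples to choose the number of PCo axes")
    best_m, best_succ = 1, -1.0
    for m in range(1, upper + 1):
        succ = _loo_success(D, groups, m)
        if succ > best_succ + 1e-12:
            best_m, best_succ = m, succ
    return best_m


def cap_fit(
    D: DistanceMatrix,
    groups: Sequence[str],
    m: int | None = None,
    values: np.ndarray | None = None,
) -> CapModel:
    """Fit a CAP model on a distance matrix with group labels.

    If *m* is not given it is chosen in [1, min(n−2, 20)] to maximise
    leave-one-out classification success (smallest m on ties).  Pass the raw
    *values* matrix to enable :func:`cap_assign` on new samples.
    """
    if len(groups) != D.n:
        raise InputError("group labels must match the distance matrix size")
    g = len(set(groups))
    if g < 2:
        raise InputError("CAP needs at least two groups")
    if D.n <= g:
        raise InputError("CAP needs more samples than groups")
    if m is None:
        m = _choose_m(D, groups)
    elif not 1 <= m <= D.n - 1:
        raise InputError(f"m = {m} outside the valid range [1, {D.n - 1}]")
    return _fit_cap(D, groups, m, values)


def cap_permutation_test(
    D: DistanceMatrix,
    groups: Sequence[str],
    m: int | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation test of the CAP trace statistic (labels permuted, same m)."""
    if n_perm < 99:
        raise InputError(f"n_perm must be >= 99, got {n_perm}")
    model = cap_fit(D, groups, m=m)
    Q_m = model.Q[:, : model.m]
    labels, idx_groups = _group_indices(groups)
    sizes = [ix.size for ix in idx_groups]
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(D.n)
        tr = 0.0
        for k in range(len(sizes)):
            ix = perm[bounds[k]:bounds[k + 1]]
            qbar = Q_m[ix].mean(axis=0)
            tr += ix.size * float(qbar @ qbar)
        if tr >= model.trace - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return model.trace, p


@dataclass(frozen=True)
class ConfusionTable:
    """g × g leave-one-out confusion counts (rows true, cols predicted)."""

    labels: tuple[str, ...]
    counts: np.ndarray
    flags: tuple[bool, ...] = ()

    @property
    def row_percent_correct(self) -> np.ndarray:
        diag = np.diag(self.counts).astype(float)
        rowsum = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * diag / rowsum
        return np.round(np.nan_to_num(pct)).astype(int)

    @property
    def overall_percent_correct(self) -> float:
        total = self.counts.sum()
        return float(100.0 * np.trace(self.counts) / total) if total else 0.0

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        df.index.name = "true_bin"
        df["percent_correct"] = self.row_percent_correct
        return df


def cap_loo(
    values: np.ndarray,
    groups: Sequence[str],
    m: int | None = None,
    ids: Sequence[str] | None = None,
) -> ConfusionTable:
    """Leave-one-out cross-classification from raw values."""
    D = euclidean_distances(values, ids=ids)
    if m is None:
        m = _choose_m(D, groups)
    preds, flags = _loo_predict(D, groups, m)
    labels = sorted(set(groups))
    lut = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for true, pred in zip(groups, preds):
        counts[lut[true], lut[pred]] += 1
    return ConfusionTable(labels=tuple(labels), counts=counts, flags=tuple(flags))


def cap_assign(
    model: CapModel, new_values: np.ndarray
) -> tuple[str, np.ndarray, dict[str, float], bool]:
    """Assign a new sample to the nearest group centroid.

    Returns (predicted label, canonical coordinates, centroid distances,
    tie flag).  The new sample need not belong to any training group.
    """
    if model.values is None:
        raise InputError("cap_fit was called without values; cannot project new samples")
    x = np.asarray(new_values, dtype=float).ravel()
    if x.size != model.values.shape[1]:
        raise InputError(
            f"dimension mismatch: model has {model.values.shape[1]} variables, "
            f"new sample has {x.size}"
        )
    d0 = np.linalg.norm(model.values - x, axis=1)
    y = _project_new(model.eigvals, model.Q, model.diag_b, d0)
    coords = y[: model.m] @ model.U
    z = coords * model.axis_scale
    pred, dists, tie = _nearest_centroid(z, model.centroids, model.group_labels)
    return pred, coords, dict(zip(model.group_labels, dists.tolist())), tie
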