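"""Estimation of smooth deformation maps on a regular lattice.

A regular lattice enveloping the organ before deformation is laid over the
landmark data, and the deformed positions of its nodes are estimated by
Bayesian linear-Gaussian regression:

* observation model — each landmark's deformed position is the bilinear
  interpolation of the four (unknown) deformed node positions of its cell,
  plus isotropic Gaussian measurement noise of variance ``sigma2``;
* smoothness prior — a Gaussian penalty ``alpha * ||L d||^2`` on node
  displacements ``d`` (deformed minus reference positions), where ``L``
  stacks the discrete second differences D_xx, sqrt(2)*D_xy, D_yy (the
  discrete thin-plate bending energy).  The null space of this penalty is
  exactly the affine maps, so uniform stretch, rotation and translation are
  never shrunk by smoothing.

The posterior mean of the node positions solves, per coordinate,

    (W'W + alpha*sigma2 * L'L + rho*I) d = W'(x - W*ref),

with a tiny ridge ``rho`` for numerical definiteness at unsupported nodes.
When hyperparameters are not supplied they are chosen by empirical Bayes:
the marginal likelihood is maximized over a 25-point log grid of the
effective smoothing weight ``lambda = alpha*sigma2``, with ``sigma2``
profiled in closed form at each grid point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .exceptions import (
    IdentifiabilityError,
    OutOfDomainError,
    ParameterError,
)
from .geometry import LandmarkPair, Point2
from .io import landmark_arrays

__all__ = [
    "LatticeMap",
    "build_lattice",
    "estimate_map",
    "predict",
    "residual_error",
    "fit_affine",
    "register_embryos",
]

#: ridge on node displacements, for numerical definiteness only
_RHO_POSTERIOR = 1e-10
#: ridge that makes the smoothness prior proper in the evidence computation
_RHO_EVIDENCE = 1e-8
#: empirical-Bayes grid for the effective smoothing weight lambda = alpha*sigma2
_LAMBDA_GRID = np.logspace(-4.0, 5.0, 25)


@dataclass(frozen=True)
class LatticeMap:
    """A regular reference lattice and (optionally) its estimated deformation.

    Node ``(i, j)`` sits at ``origin + (j*spacing, i*spacing)`` before
    deformation; nodes are stored row-major (index ``i*n_cols + j``).
    ``est_nodes`` holds the posterior-mean deformed node positions after
    :func:`estimate_map`.
    """

    origin: tuple[float, float]
    spacing: float
    n_rows: int
    n_cols: int
    est_nodes: Optional[np.ndarray] = None
    hyperparams: Optional[dict] = None
    support_counts: Optional[np.ndarray] = None
    data_hull: Optional[np.ndarray] = None
    folded_cells: tuple = field(default=())

    def __post_init__(self):
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ParameterError("lattice needs at least 2x2 nodes")

    # ---------------------------------------------------------------- nodes
    @property
    def n_nodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def ref_nodes(self) -> np.ndarray:
        """Reference node positions, shape (n_nodes, 2), row-major."""
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        pts = np.stack(
            [
                self.origin[0] + jj.ravel() * self.spacing,
                self.origin[1] + ii.ravel() * self.spacing,
            ],
            axis=1,
        )
        return pts

    @property
    def is_estimated(self) -> bool:
        return self.est_nodes is not None

    # ------------------------------------------------------------- geometry
    def _local(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Cell indices and in-cell coordinates for points, shape (n, 2)."""
        t = (X - np.asarray(self.origin)) / self.spacing
        cj = np.floor(t[:, 0]).astype(int)
        ci = np.floor(t[:, 1]).astype(int)
        # points exactly on the far boundary belong to the last cell
        cj = np.clip(cj, 0, self.n_cols - 2)
        ci = np.clip(ci, 0, self.n_rows - 2)
        u = t[:, 0] - cj
        v = t[:, 1] - ci
        return ci, cj, u, v

    def contains(self, X: np.ndarray, strict: bool = False) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo = np.asarray(self.origin)
        hi = lo + np.array([(self.n_cols - 1), (self.n_rows - 1)]) * self.spacing
        if strict:
            return np.all((X > lo) & (X < hi), axis=1)
        return np.all((X >= lo) & (X <= hi), axis=1)

    def interpolation_weights(self, X: np.ndarray) -> sp.csr_matrix:
        """Sparse (n_points, n_nodes) matrix of bilinear hat weights."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(self.contains(X)):
            raise OutOfDomainError("points outside the lattice")
        ci, cj, u, v = self._local(X)
        n = X.shape[0]
        base = ci * self.n_cols + cj
        cols = np.stack([base, base + 1, base + self.n_cols, base + self.n_cols + 1], axis=1)
        w = np.stack([(1 - u) * (1 - v), u * (1 - v), (1 - u) * v, u * v], axis=1)
        rows = np.repeat(np.arange(n), 4)
        return sp.csr_matrix(
            (w.ravel(), (rows, cols.ravel())), shape=(n, self.n_nodes)
        )

    def cell_centers(self) -> np.ndarray:
        """Reference-frame centers of all cells, shape (n_cells, 2)."""
        xs = self.origin[0] + (np.arange(self.n_cols - 1) + 0.5) * self.spacing
        ys = self.origin[1] + (np.arange(self.n_rows - 1) + 0.5) * self.spacing
        gx, gy = np.meshgrid(xs, ys)
        return np.stack([gx.ravel(), gy.ravel()], axis=1)

    # -------------------------------------------------------- serialization
    def to_json(self, path=None, provenance: Optional[dict] = None) -> str:
        obj = {
            "origin": list(self.origin),
            "spacing": self.spacing,
            "shape": [self.n_rows, self.n_cols],
            "ref_nodes": self.ref_nodes.ravel().tolist(),
            "est_nodes": None
            if self.est_nodes is None
            else np.asarray(self.est_nodes).ravel().tolist(),
            "hyperparams": self.hyperparams,
            "support_counts": None
            if self.support_counts is None
            else self.support_counts.ravel().tolist(),
            "data_hull": None if self.data_hull is None else self.data_hull.tolist(),
            "folded_cells": [list(c) for c in self.folded_cells],
            "provenance": provenance or {},
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source) -> "LatticeMap":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            obj = json.loads(Path(source).read_text())
        else:
            obj = json.loads(source)
        n_rows, n_cols = obj["shape"]
        est = obj.get("est_nodes")
        sc = obj.get("support_counts")
        hull = obj.get("data_hull")
        return LatticeMap(
            origin=tuple(obj["origin"]),
            spacing=float(obj["spacing"]),
            n_rows=n_rows,
            n_cols=n_cols,
            est_nodes=None if est is None else np.asarray(est, float).reshape(-1, 2),
            hyperparams=obj.get("hyperparams"),
            support_counts=None
            if sc is None
            else np.asarray(sc, float).reshape(n_rows - 1, n_cols - 1),
            data_hull=None if hull is None else np.asarray(hull, float),
            folded_cells=tuple(tuple(c) for c in obj.get("folded_cells", [])),
        )


# ------------------------------------------------------------------ lattice
def build_lattice(
    landmarks: Sequence[LandmarkPair],
    spacing: float = 200.0,
    margin_cells: int = 1,
) -> LatticeMap:
    """Axis-aligned regular lattice enveloping all landmark ``X`` positions.

    The grid is aligned to multiples of ``spacing`` and extended by
    ``margin_cells`` cells on every side, so every ``X`` lies strictly inside.
    """
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    if len(landmarks) < 4:
        raise ValueError("need at least 4 landmarks to define a lattice")
    X, _ = landmark_arrays(landmarks)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite landmark coordinates")
    span = X.max(axis=0) - X.min(axis=0)
    if np.any(span <= 0):
        raise IdentifiabilityError("degenerate landmark span (zero extent)")
    lo = np.floor(X.min(axis=0) / spacing) - margin_cells
    hi = np.ceil(X.max(axis=0) / spacing) + margin_cells
    # guarantee strict interiority when data sit exactly on a grid line
    lo = np.where(lo * spacing >= X.min(axis=0), lo - 1, lo)
    hi = np.where(hi * spacing <= X.max(axis=0), hi + 1, hi)
    n_cols = int(hi[0] - lo[0]) + 1
    n_rows = int(hi[1] - lo[1]) + 1
    return LatticeMap(
        origin=(float(lo[0] * spacing), float(lo[1] * spacing)),
        spacing=float(spacing),
        n_rows=n_rows,
        n_cols=n_cols,
    )


# ------------------------------------------------------------------ helpers
def fit_affine(X: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine fit ``x ~ A X + b``; raises for collinear X."""
    X = np.asarray(X, float)
    x = np.asarray(x, float)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    if s[0] <= 0 or s[1] / s[0] < 1e-10:
        raise IdentifiabilityError("landmark X positions are collinear")
    M = np.column_stack([X, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(M, x, rcond=None)
    A = coef[:2].T
    b = coef[2]
    return A, b


def _second_difference_operator(n_rows: int, n_cols: int) -> sp.csr_matrix:
    """Stacked discrete second differences D_xx, sqrt(2)*D_xy, D_yy.

    Acts on a row-major vector of per-node scalars; its null space is exactly
    the lattice restrictions of affine functions.
    """
    def idx(i, j):
        return i * n_cols + j

    rows, cols, vals = [], [], []
    r = 0
    for i in range(n_rows):
        for j in range(1, n_cols - 1):
            cols += [idx(i, j - 1), idx(i, j), idx(i, j + 1)]
            vals += [1.0, -2.0, 1.0]
            rows += [r] * 3
            r += 1
    for j in range(n_cols):
        for i in range(1, n_rows - 1):
            cols += [idx(i - 1, j), idx(i, j), idx(i + 1, j)]
            vals += [1.0, -2.0, 1.0]
            rows += [r] * 3
            r += 1
    s2 = np.sqrt(2.0)
    for i in range(n_rows - 1):
        for j in range(n_cols - 1):
            cols += [idx(i, j), idx(i, j + 1), idx(i + 1, j), idx(i + 1, j + 1)]
            vals += [s2, -s2, -s2, s2]
            rows += [r] * 4
            r += 1
    m = n_rows * n_cols
    return sp.csr_matrix((vals, (rows, cols)), shape=(r, m))


def _merge_duplicates(X: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average deformed positions of exactly repeated reference positions."""
    _, inv, counts = np.unique(X, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return X, x
    warnings.warn(
        "duplicate reference positions found; treating repeated X as "
        "measurement replicates and averaging their deformed positions",
        stacklevel=3,
    )
    k = counts.size
    Xm = np.zeros((k, 2))
    xm = np.zeros((k, 2))
    for g in range(k):
        sel = inv == g
        Xm[g] = X[sel][0]
        xm[g] = x[sel].mean(axis=0)
    return Xm, xm


def _convex_hull(X: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    hull = ConvexHull(X)
    return X[hull.vertices]


# --------------------------------------------------------------- estimation
def _evidence(W, LtL, r, lam, sigma2=None):
    """Marginal log-likelihood of residuals ``r`` (n, 2) at smoothing ``lam``.

    The prior covariance of node displacements is taken proportional to the
    noise variance, ``sigma2 * (lam*L'L + rho*I)^{-1}``, which lets sigma2 be
    profiled in closed form.  Returns (log evidence, profiled or given sigma2).
    """
    n, m = W.shape
    P = (lam * LtL + _RHO_EVIDENCE * sp.identity(m, format="csc")).tocsc()
    A = (P + (W.T @ W)).tocsc()
    luP, luA = splu(P), splu(A)
    # det(I + W P^-1 W') = det(P + W'W)/det(P); r'K^-1 r by Woodbury
    logdetK = float(
        np.sum(np.log(np.abs(luA.U.diagonal())))
        - np.sum(np.log(np.abs(luP.U.diagonal())))
    )
    Wtr = W.T @ r
    sol = luA.solve(Wtr)
    quad = float(
        sum(r[:, c] @ r[:, c] - Wtr[:, c] @ sol[:, c] for c in range(2))
    )
    quad = max(quad, 1e-12)
    n_tot = 2 * n
    if sigma2 is None:
        sigma2 = max(quad / n_tot, 1e-12)
        logev = -0.5 * n_tot * (np.log(2 * np.pi * sigma2) + 1.0) - logdetK
    else:
        logev = (
            -0.5 * n_tot * np.log(2 * np.pi * sigma2)
            - logdetK
            - 0.5 * quad / sigma2
        )
    return logev, sigma2


def _posterior_nodes(W, LtL, ref, r, lam, affine_part):
    """Solve (W'W + lam L'L + rho I) d = W'r, detrended by the affine fit.

    The penalty null space is affine, so splitting off the exact
    least-squares affine displacement keeps the regularized solve on
    small-magnitude residuals (better conditioned); one step of iterative
    refinement polishes the solution.
    """
    m = W.shape[1]
    A_aff, b_aff = affine_part
    d_aff = ref @ A_aff.T + b_aff - ref
    r_resid = r - W @ d_aff
    A = (W.T @ W + lam * LtL + _RHO_POSTERIOR * sp.identity(m)).tocsc()
    lu = splu(A)
    rhs = W.T @ r_resid
    d = lu.solve(rhs)
    d += lu.solve(rhs - A @ d)
    return ref + d_aff + d


def _detF_per_cell(lat: LatticeMap, est: np.ndarray) -> np.ndarray:
    """Jacobian determinant of the bilinear map at every cell center."""
    h = lat.spacing
    y = est.reshape(lat.n_rows, lat.n_cols, 2)
    y00 = y[:-1, :-1]
    y10 = y[:-1, 1:]
    y01 = y[1:, :-1]
    y11 = y[1:, 1:]
    fx = (y10 - y00 + y11 - y01) / (2 * h)  # d phi / d X_pd
    fy = (y01 - y00 + y11 - y10) / (2 * h)  # d phi / d X_ap
    return fx[..., 0] * fy[..., 1] - fx[..., 1] * fy[..., 0]


def estimate_map(
    landmarks: Sequence[LandmarkPair],
    lattice: LatticeMap,
    alpha: Optional[float] = None,
    sigma2: Optional[float] = None,
) -> LatticeMap:
    """Posterior-mean deformed lattice from landmark pairs.

    If ``alpha`` (smoothness weight) and/or ``sigma2`` (observation variance,
    µm²) are omitted they are selected by empirical Bayes (see module
    docstring).  Returns a new :class:`LatticeMap` with ``est_nodes``,
    fitted ``hyperparams``, per-cell data support, the convex hull of the
    landmark ``X`` positions, and any fold-flagged cells filled in.
    """
    if alpha is not None and alpha <= 0:
        raise ParameterError("alpha must be positive")
    if sigma2 is not None and sigma2 <= 0:
        raise ParameterError("sigma2 must be positive")
    if len(landmarks) < 6:
        raise IdentifiabilityError("need at least 6 landmark pairs")
    X, x = landmark_arrays(landmarks)
    X, x = _merge_duplicates(X, x)
    if not np.all(lattice.contains(X, strict=True)):
        raise OutOfDomainError("landmarks must lie strictly inside the lattice")
    affine_part = fit_affine(X, x)  # raises on collinear input

    W = lattice.interpolation_weights(X)
    L = _second_difference_operator(lattice.n_rows, lattice.n_cols)
    LtL = (L.T @ L).tocsr()
    ref = lattice.ref_nodes
    r = x - W @ ref

    if alpha is None:
        best = None
        for lam in _LAMBDA_GRID:
            logev, s2 = _evidence(W, LtL, r, lam, sigma2)
            if best is None or logev > best[0]:
                best = (logev, lam, s2)
        _, lam, s2 = best
        alpha_hat = lam / s2
    else:
        if sigma2 is None:
            # pilot noise estimate from the affine fit, then one refinement
            A0, b0 = affine_part
            res = x - (X @ A0.T + b0)
            s2 = max(float(np.sum(res**2)) / (2 * len(X)), 1e-12)
            for _ in range(2):
                est = _posterior_nodes(W, LtL, ref, r, alpha * s2, affine_part)
                res = x - W @ est
                s2 = max(float(np.sum(res**2)) / (2 * len(X)), 1e-12)
        else:
            s2 = sigma2
        lam = alpha * s2
        alpha_hat = alpha

    est = _posterior_nodes(W, LtL, ref, r, lam, affine_part)

    # per-cell landmark support
    ci, cj, _, _ = lattice._local(X)
    support = np.zeros((lattice.n_rows - 1, lattice.n_cols - 1))
    np.add.at(support, (ci, cj), 1.0)

    dets = _detF_per_cell(lattice, est)
    folded = tuple(map(tuple, np.argwhere(dets <= 0)))
    if folded:
        warnings.warn(f"{len(folded)} lattice cells have det F <= 0 (folded)")

    return replace(
        lattice,
        est_nodes=est,
        hyperparams={"alpha": float(alpha_hat), "sigma2": float(s2), "lambda": float(lam)},
        support_counts=support,
        data_hull=_convex_hull(X),
        folded_cells=folded,
    )


def predict(lattice_map: LatticeMap, X) -> np.ndarray:
    """Evaluate the estimated map at ``X`` by bilinear interpolation.

    ``X`` may be a :class:`Point2`, a length-2 array or an (n, 2) array; the
    result matches the input shape.  Queries outside the lattice raise
    :class:`OutOfDomainError` — no extrapolation is performed.
    """
    if lattice_map.est_nodes is None:
        raise ValueError("map has not been estimated")
    single = False
    if isinstance(X, Point2):
        X = X.as_array()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        single = True
        X = X[None, :]
    inside = lattice_map.contains(X)
    if not np.all(inside):
        raise OutOfDomainError(
            f"{int((~inside).sum())} query points outside the lattice"
        )
    W = lattice_map.interpolation_weights(X)
    out = W @ lattice_map.est_nodes
    return out[0] if single else out


def residual_error(lattice_map: LatticeMap, landmarks: Sequence[LandmarkPair]) -> float:
    """Mean Euclidean distance (µm) between predicted and observed positions."""
    if len(landmarks) == 0:
        raise ValueError("empty landmark list")
    X, x = landmark_arrays(landmarks)
    pred = predict(lattice_map, X)
    return float(np.mean(np.linalg.norm(pred - x, axis=1)))


# ------------------------------------------------------------- registration
def register_embryos(
    landmarks: Sequence[LandmarkPair],
) -> list[LandmarkPair]:
    """Moment-based rigid alignment of embryos to a common frame.

    Fallback for datasets without recorded camera frames: each embryo's
    marker cloud is rotated by the principal-axis angle of its ``X``
    covariance (smallest rotation convention) and translated so the ``X``
    centroids coincide with their cross-embryo mean.  Translation and
    rotation only — size differences are biology, not nuisance.
    """
    by_embryo: dict[str, list[LandmarkPair]] = {}
    for p in landmarks:
        by_embryo.setdefault(p.embryo_id, []).append(p)

    stats = {}
    for e, pairs in by_embryo.items():
        X, _ = landmark_arrays(pairs)
        c = X.mean(axis=0)
        Xc = X - c
        C = Xc.T @ Xc / len(X)
        ang = 0.5 * np.arctan2(2 * C[0, 1], C[0, 0] - C[1, 1])
        # principal angle modulo pi; pick representative nearest zero
        if ang > np.pi / 4:
            ang -= np.pi / 2
        elif ang < -np.pi / 4:
            ang += np.pi / 2
        stats[e] = (c, ang)

    mean_c = np.mean([s[0] for s in stats.values()], axis=0)
    mean_ang = float(np.mean([s[1] for s in stats.values()]))

    out: list[LandmarkPair] = []
    for e, pairs in by_embryo.items():
        c, ang = stats[e]
        th = mean_ang - ang
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for p in pairs:
            Xn = Q @ (p.X.as_array() - c) + mean_c
            xn = Q @ (p.x.as_array() - c) + mean_c
            out.append(
                LandmarkPair(p.embryo_id, p.interval_id, Point2(*Xn), Point2(*xn))
            )
    return out
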