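"""Synthetic study data with known ground truth.

Emulates the dye-injection experiment at its real scale: a paddle-shaped
2-D organ domain (~2000 x 1000 µm), a smooth orientation-preserving
deformation over a 12-h interval built from one of three growth modes
(distally, posteriorly or proximally biased) composed with a global
stretch along the P-D axis, and per-embryo landmark datasets (7-8 embryos,
20-50 markers each) with Gaussian measurement noise and recorded rigid
camera jitter.  The ground-truth map is analytic, so the deformation
gradient, growth-rate and anisotropy fields are available in closed form
for parameter-recovery experiments.

Also provides matched thickness-field pairs (optionally with a controlled
correlation between D-V and area growth) and the camera-frame velocity
demonstration for uniformly growing tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import shapely
from shapely.geometry import Point as ShPoint, Polygon, box

from .exceptions import ParameterError
from .fields import ThicknessField
from .geometry import LandmarkPair, Point2

__all__ = [
    "ScenarioSpec",
    "GroundTruthMap",
    "LandmarkDataset",
    "ThicknessPair",
    "paddle_outline",
    "ground_truth_map",
    "sample_landmarks",
    "unjitter",
    "make_thickness_pair",
    "velocity_frame_demo",
    "VelocityProfile",
]

_MODES = ("distal_biased", "posterior_biased", "proximal_biased", "affine", "custom")


def paddle_outline(length: float = 2000.0, width: float = 1000.0) -> Polygon:
    """Paddle-shaped organ outline: a rectangle capped by a semicircular tip."""
    r = width / 2.0
    body = box(0.0, 0.0, length - r, width)
    cap = ShPoint(length - r, r).buffer(r, quad_segs=24)
    return body.union(cap)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic deformation scenario.

    Defaults are the study conditions: 8 embryos x 30 markers per 12-h
    interval, 20 µm measurement noise, mean area growth 1.4 per interval
    with a 1.5-fold spatial contrast, and 1.3-fold anisotropy aligned with
    the P-D (+x) axis.
    """

    mode: str = "distal_biased"
    domain: Polygon = field(default_factory=paddle_outline)
    base_growth: float = 1.4
    growth_contrast: float = 1.5
    aniso_mag: float = 1.3
    noise_sigma: float = 20.0
    n_embryos: int = 8
    markers_per_embryo: int = 30
    jitter_translation_sd: float = 30.0
    jitter_rotation_sd_deg: float = 2.0
    interval_id: str = "st22-23"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.base_growth <= 0:
            raise ParameterError("base_growth must be positive")
        if self.growth_contrast < 1:
            raise ParameterError("growth_contrast must be >= 1 (degenerate)")
        if self.aniso_mag < 1:
            raise ParameterError("aniso_mag must be >= 1")
        if self.markers_per_embryo < 3:
            raise ParameterError("markers_per_embryo must be >= 3")
        if self.n_embryos < 1:
            raise ParameterError("n_embryos must be >= 1")


# ------------------------------------------------------------ bump functions
def _smoothstep(u, u0, u1):
    """Cosine-tapered ramp: 0 below u0, 1 above u1, C1 everywhere."""
    u = np.asarray(u, dtype=float)
    t = np.clip((u - u0) / (u1 - u0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _smoothstep_integral(u, u0, u1):
    """Antiderivative of :func:`_smoothstep`, zero at u0."""
    u = np.asarray(u, dtype=float)
    t = np.clip((u - u0) / (u1 - u0), 0.0, 1.0)
    ramp = (u1 - u0) * (0.5 * t - np.sin(np.pi * t) / (2.0 * np.pi))
    return ramp + np.maximum(u - u1, 0.0)


class _PlateauProfile:
    """1-D stretch profile p(u) = 1 + (contrast-1) * m(u), m a cosine plateau."""

    def __init__(self, u0: float, u1: float, contrast: float, falling: bool):
        self.u0, self.u1 = u0, u1
        self.c = contrast - 1.0
        self.falling = falling

    def __call__(self, u):
        m = _smoothstep(u, self.u0, self.u1)
        if self.falling:
            m = 1.0 - m
        return 1.0 + self.c * m

    def integral(self, u):
        """Antiderivative anchored at 0."""
        u = np.asarray(u, dtype=float)
        w_int = _smoothstep_integral(u, self.u0, self.u1) - _smoothstep_integral(
            0.0, self.u0, self.u1
        )
        if self.falling:
            return u + self.c * (u - w_int)
        return u + self.c * w_int


class _FlatProfile:
    def __call__(self, u):
        return np.ones_like(np.asarray(u, dtype=float))

    def integral(self, u):
        return np.asarray(u, dtype=float)


def _domain_sample(domain: Polygon, step: float = 25.0) -> np.ndarray:
    """Deterministic dense sample of points inside the domain polygon."""
    xmin, ymin, xmax, ymax = domain.bounds
    xs = np.arange(xmin + step / 2, xmax, step)
    ys = np.arange(ymin + step / 2, ymax, step)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(domain, gx.ravel(), gy.ravel())
    return np.stack([gx.ravel()[inside], gy.ravel()[inside]], axis=1)


# ------------------------------------------------------------------ true map
class GroundTruthMap:
    """Analytic, C1, orientation-preserving deformation map with diagonal F.

    The map is separable, ``phi(x, y) = (phi_x(x), phi_y(y))``: a spatially
    varying stretch along one axis realizes the growth mode, and a uniform
    stretch along +x realizes the P-D anisotropy, so

        F(X) = diag(s_x(x), s_y(y)),  det F = s_x s_y,
        anisotropy = s_x / s_y along (1, 0).

    The stretch profiles are normalized so the area-weighted mean of det F
    over the domain equals ``spec.base_growth``.
    """

    def __init__(self, spec: ScenarioSpec):
        self.spec = spec
        dom = spec.domain
        if not dom.is_valid or dom.area <= 0:
            raise ParameterError("domain must be a valid polygon of positive area")
        xmin, ymin, xmax, ymax = dom.bounds
        self._anchor = np.array([xmin, ymin])
        Lx, Ly = xmax - xmin, ymax - ymin
        kappa, A, G = spec.growth_contrast, spec.aniso_mag, spec.base_growth
        s_perp = np.sqrt(G / A)

        flat = _FlatProfile()
        if spec.mode == "distal_biased":
            px = _PlateauProfile(xmin + 0.45 * Lx, xmin + 0.85 * Lx, kappa, False)
            py = flat
        elif spec.mode == "proximal_biased":
            px = _PlateauProfile(xmin + 0.15 * Lx, xmin + 0.55 * Lx, kappa, True)
            py = flat
        elif spec.mode == "posterior_biased":
            px = flat
            py = _PlateauProfile(ymin + 0.45 * Ly, ymin + 0.85 * Ly, kappa, False)
        else:  # affine / custom default
            px, py = flat, flat

        pts = _domain_sample(dom)
        pbar = float(np.mean(px(pts[:, 0])))
        qbar = float(np.mean(py(pts[:, 1])))
        self._px, self._py = px, py
        # scale factors: s_x = cx * px(x), s_y = cy * py(y)
        self._cx = A * s_perp / pbar
        self._cy = s_perp / qbar

        # orientation and axis-ordering checks over the domain
        sx = self.sx(pts[:, 0])
        sy = self.sy(pts[:, 1])
        if np.any(sx <= 0) or np.any(sy <= 0):
            raise ParameterError("parameters yield det F <= 0 somewhere")
        if np.any(sx < sy):
            raise ParameterError(
                "anisotropy field dips below 1 (s_x < s_y): increase aniso_mag "
                "or decrease growth_contrast"
            )

    # stretch factors --------------------------------------------------
    def sx(self, x):
        return self._cx * self._px(np.asarray(x, dtype=float))

    def sy(self, y):
        return self._cy * self._py(np.asarray(y, dtype=float))

    # map and tensors --------------------------------------------------
    def __call__(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xa = np.atleast_2d(X)
        ax, ay = self._anchor
        out = np.stack(
            [
                ax + self._cx * (self._px.integral(Xa[:, 0]) - self._px.integral(ax)),
                ay + self._cy * (self._py.integral(Xa[:, 1]) - self._py.integral(ay)),
            ],
            axis=1,
        )
        return out[0] if single else out

    def F(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        F = np.zeros((n, 2, 2))
        F[:, 0, 0] = self.sx(X[:, 0])
        F[:, 1, 1] = self.sy(X[:, 1])
        return F

    def det_F(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.sx(X[:, 0]) * self.sy(X[:, 1])

    def aniso_mag_at(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.sx(X[:, 0]) / self.sy(X[:, 1])

    @property
    def aniso_dir(self) -> np.ndarray:
        return np.array([1.0, 0.0])

    def inverse(self, x) -> np.ndarray:
        """Inverse map via dense monotone per-axis interpolation."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        xa = np.atleast_2d(x)
        xmin, ymin, xmax, ymax = self.spec.domain.bounds
        Lx, Ly = xmax - xmin, ymax - ymin
        us = np.linspace(xmin - 0.5 * Lx, xmax + 0.5 * Lx, 4001)
        vs = np.linspace(ymin - 0.5 * Ly, ymax + 0.5 * Ly, 4001)
        fu = self.__call__(np.stack([us, np.full_like(us, ymin)], axis=1))[:, 0]
        fv = self.__call__(np.stack([np.full_like(vs, xmin), vs], axis=1))[:, 1]
        inv = np.stack(
            [np.interp(xa[:, 0], fu, us), np.interp(xa[:, 1], fv, vs)], axis=1
        )
        return inv[0] if single else inv

    # field callables for the simulator ---------------------------------
    def growth_field(self) -> Callable[[np.ndarray], float]:
        return lambda X: float(np.atleast_1d(self.det_F(X))[0])

    def aniso_field(self) -> Callable[[np.ndarray], tuple[float, np.ndarray]]:
        return lambda X: (
            float(np.atleast_1d(self.aniso_mag_at(X))[0]),
            self.aniso_dir,
        )


def ground_truth_map(spec: ScenarioSpec) -> GroundTruthMap:
    """Analytic ground-truth map for a scenario (see :class:`GroundTruthMap`)."""
    return GroundTruthMap(spec)


# ------------------------------------------------------------------ sampling
@dataclass(frozen=True)
class LandmarkDataset:
    """Sampled landmark pairs plus the recorded per-embryo camera frames.

    ``frames[embryo_id] = (theta_rad, t_pd, t_ap)`` is the rigid transform
    that was applied to that embryo's coordinates (rotation about the origin
    then translation), mimicking embryo-to-embryo differences in mounting.
    It is recorded — as it would be known from the limb outline — so the
    pooling step can bring all embryos into the common frame.
    """

    pairs: tuple[LandmarkPair, ...]
    frames: dict[str, tuple[float, float, float]]
    spec: ScenarioSpec

    def __len__(self) -> int:
        return len(self.pairs)


def _sample_in_polygon(domain: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    xmin, ymin, xmax, ymax = domain.bounds
    pts = np.empty((0, 2))
    while len(pts) < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(4 * n, 2))
        ok = shapely.contains_xy(domain, cand[:, 0], cand[:, 1])
        pts = np.vstack([pts, cand[ok]])
    return pts[:n]


def _rigid(theta: float, t: np.ndarray, pts: np.ndarray) -> np.ndarray:
    Q = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return pts @ Q.T + t


def sample_landmarks(
    spec: ScenarioSpec,
    gt_map: Optional[GroundTruthMap] = None,
    jitter: bool = True,
) -> LandmarkDataset:
    """Multi-embryo landmark pairs under a ground-truth map.

    Per embryo: ``markers_per_embryo`` reference positions uniform in the
    domain, deformed positions ``phi*(X)`` plus isotropic Gaussian noise of
    sd ``noise_sigma``; then the embryo's recorded rigid camera jitter is
    applied to both snapshots.  Bit-reproducible given (spec, spec.seed).
    """
    gt = gt_map if gt_map is not None else GroundTruthMap(spec)
    rng = np.random.default_rng(spec.seed)
    pairs: list[LandmarkPair] = []
    frames: dict[str, tuple[float, float, float]] = {}
    for e in range(spec.n_embryos):
        eid = f"embryo{e + 1:02d}"
        X = _sample_in_polygon(spec.domain, spec.markers_per_embryo, rng)
        x = gt(X) + rng.normal(0.0, spec.noise_sigma, size=X.shape)
        if jitter:
            theta = np.deg2rad(rng.normal(0.0, spec.jitter_rotation_sd_deg))
            t = rng.normal(0.0, spec.jitter_translation_sd, size=2)
        else:
            theta, t = 0.0, np.zeros(2)
        frames[eid] = (float(theta), float(t[0]), float(t[1]))
        Xo = _rigid(theta, t, X)
        xo = _rigid(theta, t, x)
        for Xi, xi in zip(Xo, xo):
            pairs.append(
                LandmarkPair(eid, spec.interval_id, Point2(*Xi), Point2(*xi))
            )
    return LandmarkDataset(pairs=tuple(pairs), frames=frames, spec=spec)


def unjitter(dataset: LandmarkDataset) -> list[LandmarkPair]:
    """Undo the recorded camera frames, returning pairs in the common frame.

    This emulates outline-based registration, where the embryo-to-frame
    transform is known from the organ outline rather than estimated from
    the markers themselves.
    """
    out: list[LandmarkPair] = []
    for p in dataset.pairs:
        theta, tx, ty = dataset.frames[p.embryo_id]
        Q = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        t = np.array([tx, ty])
        Xn = Q.T @ (p.X.as_array() - t)
        xn = Q.T @ (p.x.as_array() - t)
        out.append(LandmarkPair(p.embryo_id, p.interval_id, Point2(*Xn), Point2(*xn)))
    return out


# ------------------------------------------------------------------ thickness
@dataclass(frozen=True)
class ThicknessPair:
    """Matched thickness grids before/after deformation plus the true ratio."""

    H: ThicknessField
    h: ThicknessField
    ratio: Callable[[np.ndarray], np.ndarray]


def make_thickness_pair(
    spec: ScenarioSpec,
    gt_map: Optional[GroundTruthMap] = None,
    ratio: float = 1.2,
    target_corr: Optional[float] = None,
    grid_spacing: float = 50.0,
) -> ThicknessPair:
    """Thickness grids ``H`` (before) and ``h`` (after) with known D-V ratio.

    The D-V growth ratio field rho(X) satisfies ``h(phi*(X)) = rho(X) H(X)``
    exactly (up to grid interpolation).  With ``target_corr`` set, rho is
    built from the standardized area-growth pattern and an orthogonalized
    smooth pattern so that the Pearson correlation between D-V growth and
    area growth over the domain is approximately the target.
    """
    gt = gt_map if gt_map is not None else GroundTruthMap(spec)
    dom = spec.domain
    xmin, ymin, xmax, ymax = dom.bounds
    Lx, Ly = xmax - xmin, ymax - ymin

    def H_func(P):
        P = np.atleast_2d(P)
        return (
            220.0
            - 0.03 * (P[:, 0] - xmin)
            + 15.0 * np.cos(np.pi * (P[:, 1] - ymin) / Ly)
        )

    if target_corr is None:
        rho = lambda P: np.full(np.atleast_2d(P).shape[0], float(ratio))
    else:
        t = float(target_corr)
        if not -1.0 <= t <= 1.0:
            raise ParameterError("target_corr must be in [-1, 1]")
        pts = _domain_sample(dom)
        g = gt.det_F(pts)
        g_mu, g_sd = g.mean(), g.std()
        if g_sd == 0:
            raise ParameterError("growth field is constant; cannot target a correlation")

        def g_std(P):
            P = np.atleast_2d(P)
            return (gt.det_F(P) - g_mu) / g_sd

        def psi_raw(P):
            P = np.atleast_2d(P)
            return np.sin(2 * np.pi * (P[:, 0] - xmin) / Lx) * np.cos(
                np.pi * (P[:, 1] - ymin) / Ly
            )

        ps = psi_raw(pts)
        gs = g_std(pts)
        beta = float(np.mean(ps * gs))  # gs has unit variance on the sample
        resid = ps - beta * gs
        r_sd = resid.std()

        def rho(P):
            z = t * g_std(P) + np.sqrt(max(1.0 - t * t, 0.0)) * (
                (psi_raw(P) - beta * g_std(P)) / r_sd
            )
            return float(ratio) * (1.0 + 0.08 * z)

    # reference-frame grid covering the domain with one cell of pad
    pad = grid_spacing
    xs = np.arange(xmin - pad, xmax + pad + grid_spacing, grid_spacing)
    ys = np.arange(ymin - pad, ymax + pad + grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    P_ref = np.stack([gx.ravel(), gy.ravel()], axis=1)
    H_vals = H_func(P_ref).reshape(gy.shape)
    H = ThicknessField(
        origin=(float(xs[0]), float(ys[0])),
        spacing=float(grid_spacing),
        values=H_vals,
        frame="before",
    )

    # deformed-frame grid covering phi*(domain)
    img = gt(P_ref)
    uxmin, uymin = img.min(axis=0) - pad
    uxmax, uymax = img.max(axis=0) + pad
    us = np.arange(uxmin, uxmax + grid_spacing, grid_spacing)
    vs = np.arange(uymin, uymax + grid_spacing, grid_spacing)
    gu, gv = np.meshgrid(us, vs)
    P_def = np.stack([gu.ravel(), gv.ravel()], axis=1)
    P_back = gt.inverse(P_def)
    h_vals = (rho(P_back) * H_func(P_back)).reshape(gv.shape)
    h = ThicknessField(
        origin=(float(us[0]), float(vs[0])),
        spacing=float(grid_spacing),
        values=h_vals,
        frame="after",
    )
    return ThicknessPair(H=H, h=h, ratio=rho)


# ------------------------------------------------------------- velocity demo
@dataclass(frozen=True)
class VelocityProfile:
    """Velocity of material points in uniformly growing 1-D tissue.

    For exponential growth at rate ``k`` (per hour) of a tissue occupying
    ``[0, L0]``, a camera fixed on the anchor point sees ``v(x) = k (x -
    x_anchor)``: zero at the anchor, largest far from it.  The velocity
    *gradient* is ``k`` everywhere — identical in every camera frame.
    """

    k: float
    L0: float
    frame: str
    x_anchor: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.k * (x - self.x_anchor)
        return float(out) if out.ndim == 0 else out

    @property
    def velocity_gradient(self) -> float:
        return self.k


def velocity_frame_demo(k: float, L0: float, frame: str = "left") -> VelocityProfile:
    """Velocity profile seen by a camera fixed at a given tissue point.

    ``frame`` is one of ``left`` (proximal end), ``right`` (distal end) or
    ``center``.  The profiles differ between frames although the underlying
    deformation (uniform growth, gradient ``k``) is identical.
    """
    if k <= 0 or L0 <= 0:
        raise ParameterError("k and L0 must be positive")
    anchors = {"left": 0.0, "right": L0, "center": L0 / 2.0}
    if frame not in anchors:
        raise ParameterError(f"frame must be one of {sorted(anchors)}")
    return VelocityProfile(k=k, L0=L0, frame=frame, x_anchor=anchors[frame])
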