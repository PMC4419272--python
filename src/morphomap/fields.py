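"""Per-cell deformation fields and derived tissue statistics.

Turns an estimated lattice map into one deformation gradient tensor per
lattice cell (evaluated at the cell center from the bilinear shape-function
gradient) and computes the derived quantities used to characterize
morphogenesis: area growth-rate maps, anisotropy maps, dorso-ventral and
volume growth from thickness fields, field correlations, local
treated-vs-control region averages around implanted beads, and the
small-sample affine anisotropy statistic for a handful of markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import pearsonr

from .exceptions import (
    IdentifiabilityError,
    OutOfDomainError,
    ParameterError,
)
from .geometry import LandmarkPair, LocalDeformation, Point2, local_deformation
from .io import landmark_arrays
from .lattice import LatticeMap, fit_affine, predict

__all__ = [
    "ThicknessField",
    "DeformationField",
    "compute_field",
    "dv_growth",
    "volume_growth",
    "field_correlation",
    "region_change",
    "affine_anisotropy",
    "read_thickness",
    "write_thickness",
]


# ------------------------------------------------------------------ thickness
@dataclass(frozen=True)
class ThicknessField:
    """Gridded dorso-ventral thickness (µm) with bilinear interpolation.

    ``values[i, j]`` is the thickness at ``origin + (j*spacing, i*spacing)``;
    NaN marks positions outside the measured support.  ``frame`` says whether
    the grid lives in reference ("before") or deformed ("after") coordinates.
    """

    origin: tuple[float, float]
    spacing: float
    values: np.ndarray
    frame: str = "before"

    def __post_init__(self):
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ParameterError("values must be a 2-D grid")
        if np.any(v[np.isfinite(v)] <= 0):
            raise ParameterError("thickness must be positive where defined")
        if self.frame not in ("before", "after"):
            raise ParameterError("frame must be 'before' or 'after'")
        object.__setattr__(self, "values", v)

    def _interpolator(self) -> RegularGridInterpolator:
        ny, nx = self.values.shape
        ys = self.origin[1] + np.arange(ny) * self.spacing
        xs = self.origin[0] + np.arange(nx) * self.spacing
        return RegularGridInterpolator(
            (ys, xs), self.values, method="linear",
            bounds_error=False, fill_value=np.nan,
        )

    def __call__(self, X) -> np.ndarray:
        """Bilinear thickness at point(s); NaN outside support."""
        if isinstance(X, Point2):
            X = X.as_array()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = self._interpolator()(X[:, ::-1])  # interpolator is (y, x)
        return out if out.size > 1 else float(out[0])


def read_thickness(path, frame: str = "before") -> ThicknessField:
    """Read a thickness TSV: ``#origin_pd``/``#origin_ap``/``#spacing`` header
    lines followed by whitespace-separated matrix rows (NaN = undefined)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, val = line[1:].split(None, 1)
            header[key] = float(val)
        else:
            rows.append([float(t) for t in line.split()])
    for key in ("origin_pd", "origin_ap", "spacing"):
        if key not in header:
            raise ValueError(f"thickness file missing header line #{key}")
    return ThicknessField(
        origin=(header["origin_pd"], header["origin_ap"]),
        spacing=header["spacing"],
        values=np.asarray(rows, dtype=float),
        frame=frame,
    )


def write_thickness(fieldgrid: ThicknessField, path) -> None:
    lines = [
        f"#origin_pd {fieldgrid.origin[0]:.6g}",
        f"#origin_ap {fieldgrid.origin[1]:.6g}",
        f"#spacing {fieldgrid.spacing:.6g}",
    ]
    for row in fieldgrid.values:
        lines.append("\t".join(f"{v:.6g}" for v in row))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- field type
@dataclass(frozen=True)
class DeformationField:
    """Per-cell local deformation over the data-supported part of a lattice.

    ``cells`` holds (row, col) lattice-cell indices, ``centers`` the
    reference-frame cell centers.  Optional per-cell D-V growth and volume
    growth are attached by the thickness workflow; NaN where unavailable.
    """

    interval_id: str
    cells: np.ndarray                      # (n, 2) int
    centers: np.ndarray                    # (n, 2) float, reference frame
    deformations: tuple[LocalDeformation, ...]
    dv_growth: Optional[np.ndarray] = None
    volume_growth: Optional[np.ndarray] = None
    flagged: tuple = field(default=())     # cells where det F <= 0

    @property
    def growth_rate(self) -> np.ndarray:
        return np.array([d.growth_rate for d in self.deformations])

    @property
    def aniso_mag(self) -> np.ndarray:
        return np.array([d.aniso_mag for d in self.deformations])

    @property
    def aniso_angle_deg(self) -> np.ndarray:
        return np.array([d.aniso_angle_deg for d in self.deformations])

    def to_tsv(self, path) -> None:
        recs = []
        for (i, j), c, d in zip(self.cells, self.centers, self.deformations):
            recs.append(
                (
                    int(i), int(j), c[0], c[1],
                    d.F[0, 0], d.F[0, 1], d.F[1, 0], d.F[1, 1],
                    d.growth_rate, d.aniso_mag, d.aniso_angle_deg,
                )
            )
        df = pd.DataFrame(
            recs,
            columns=[
                "cell_i", "cell_j", "center_pd", "center_ap",
                "F11", "F12", "F21", "F22",
                "growth_rate", "aniso_mag", "aniso_angle_deg",
            ],
        )
        if self.dv_growth is not None:
            df["dv_growth"] = self.dv_growth
        if self.volume_growth is not None:
            df["volume_growth"] = self.volume_growth
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- operations
def _cell_tensors(lat: LatticeMap) -> np.ndarray:
    """F at every cell center from the bilinear shape-function gradient."""
    h = lat.spacing
    y = lat.est_nodes.reshape(lat.n_rows, lat.n_cols, 2)
    y00, y10 = y[:-1, :-1], y[:-1, 1:]
    y01, y11 = y[1:, :-1], y[1:, 1:]
    col_pd = (y10 - y00 + y11 - y01) / (2 * h)   # d phi / d X_pd
    col_ap = (y01 - y00 + y11 - y10) / (2 * h)   # d phi / d X_ap
    F = np.stack([col_pd, col_ap], axis=-1)      # (..., 2 comps, 2 cols)
    return F


def compute_field(
    lattice_map: LatticeMap,
    interval_id: str = "",
    supported_only: bool = True,
) -> DeformationField:
    """Per-cell deformation gradients of an estimated map.

    By default only cells whose centers lie inside the convex hull of the
    training landmarks are reported (the estimate is extrapolation outside).
    Cells with ``det F <= 0`` are flagged and excluded from the tensor
    records rather than raising.
    """
    if lattice_map.est_nodes is None:
        raise ValueError("map has not been estimated")
    F = _cell_tensors(lattice_map)
    centers = lattice_map.cell_centers()
    n_ci, n_cj = lattice_map.n_rows - 1, lattice_map.n_cols - 1
    cells = np.stack(
        np.meshgrid(np.arange(n_ci), np.arange(n_cj), indexing="ij"), axis=-1
    ).reshape(-1, 2)
    Fflat = F.reshape(-1, 2, 2)

    keep = np.ones(len(cells), dtype=bool)
    if supported_only and lattice_map.data_hull is not None:
        from shapely.geometry import MultiPoint, Point as ShPoint

        hull = MultiPoint([tuple(p) for p in lattice_map.data_hull]).convex_hull
        keep = np.array([hull.covers(ShPoint(*c)) for c in centers])

    defs: list[LocalDeformation] = []
    rec_cells, rec_centers, flagged = [], [], []
    for k in np.flatnonzero(keep):
        det = float(np.linalg.det(Fflat[k]))
        if det <= 0:
            flagged.append(tuple(cells[k]))
            continue
        defs.append(local_deformation(Fflat[k]))
        rec_cells.append(cells[k])
        rec_centers.append(centers[k])
    return DeformationField(
        interval_id=interval_id,
        cells=np.asarray(rec_cells, dtype=int).reshape(-1, 2),
        centers=np.asarray(rec_centers, dtype=float).reshape(-1, 2),
        deformations=tuple(defs),
        flagged=tuple(flagged),
    )


def dv_growth(
    lattice_map: LatticeMap,
    H: ThicknessField,
    h: ThicknessField,
    X,
) -> float | np.ndarray:
    """Dorso-ventral growth ratio ``h(phi(X)) / H(X)`` at point(s) ``X``.

    ``H`` is thickness before deformation (reference frame), ``h`` after.
    Raises :class:`OutOfDomainError` when a point (or its image) leaves the
    thickness support, or when ``H`` vanishes there.
    """
    single = isinstance(X, Point2) or np.asarray(X, dtype=float).ndim == 1
    if isinstance(X, Point2):
        X = X.as_array()
    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    mapped = predict(lattice_map, Xa)
    before = np.atleast_1d(H(Xa))
    after = np.atleast_1d(h(mapped))
    if np.any(~np.isfinite(before)) or np.any(~np.isfinite(after)):
        raise OutOfDomainError("point outside thickness support")
    if np.any(before <= 0):
        raise OutOfDomainError("H(X) = 0: undefined D-V growth")
    out = after / before
    return float(out[0]) if single else out


def volume_growth(area_growth, dv) -> float | np.ndarray:
    """Volume growth = area growth x D-V growth (both must be positive)."""
    a = np.asarray(area_growth, dtype=float)
    d = np.asarray(dv, dtype=float)
    if np.any(a <= 0) or np.any(d <= 0):
        raise ParameterError("growth ratios must be positive")
    out = a * d
    return float(out) if out.ndim == 0 else out


def attach_dv_growth(
    fieldrec: DeformationField,
    lattice_map: LatticeMap,
    H: ThicknessField,
    h: ThicknessField,
) -> DeformationField:
    """Per-cell D-V and volume growth; cells outside thickness support get NaN."""
    from dataclasses import replace

    n = len(fieldrec.deformations)
    dv = np.full(n, np.nan)
    for k, c in enumerate(fieldrec.centers):
        try:
            dv[k] = dv_growth(lattice_map, H, h, c)
        except OutOfDomainError:
            pass
    vol = np.where(np.isfinite(dv), fieldrec.growth_rate * dv, np.nan)
    return replace(fieldrec, dv_growth=dv, volume_growth=vol)


def field_correlation(f1, f2) -> float:
    """Pearson correlation between two per-cell fields on the same cells.

    Cells where either value is NaN are dropped (no imputation); a constant
    field raises (the correlation is undefined).
    """
    a = np.asarray(f1, dtype=float).ravel()
    b = np.asarray(f2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ParameterError("fields must share the same cells")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ParameterError("need at least 3 cells with full data support")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("constant field: correlation undefined")
    return float(pearsonr(a, b).statistic)


def region_change(
    field_treated: DeformationField,
    field_control: DeformationField,
    center,
    radius: float = 200.0,
) -> tuple[float, float]:
    """Treated-minus-control mean growth rate and anisotropy near a bead.

    Averages per-cell growth rate and anisotropy magnitude over cells whose
    reference-frame centers fall within ``radius`` (µm, default 200) of the
    bead ``center``, separately in each field, and returns the differences
    ``(delta_growth, delta_aniso)``.
    """
    if isinstance(center, Point2):
        center = center.as_array()
    c = np.asarray(center, dtype=float)

    def _mean(f: DeformationField) -> tuple[float, float]:
        d = np.linalg.norm(f.centers - c, axis=1)
        sel = d <= radius
        if not np.any(sel):
            raise OutOfDomainError("no cells within radius of the bead center")
        return float(f.growth_rate[sel].mean()), float(f.aniso_mag[sel].mean())

    g_t, a_t = _mean(field_treated)
    g_c, a_c = _mean(field_control)
    return g_t - g_c, a_t - a_c


def affine_anisotropy(pairs: Sequence[LandmarkPair]) -> float:
    """Anisotropy magnitude of the best-fit affine map through a few markers.

    Used for experiments with only a handful of markers (e.g. four dye
    crystals): the relative positional changes determine a least-squares
    affine map (translation absorbed), whose anisotropy magnitude is
    returned.  Invariant to global rotation/translation of either point set.
    """
    if len(pairs) < 3:
        raise IdentifiabilityError("need at least 3 markers")
    X, x = landmark_arrays(pairs)
    A, _ = fit_affine(X, x)
    from .geometry import anisotropy

    mag, _ = anisotropy(A)
    return mag
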