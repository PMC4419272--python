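"""Cross-validation of estimated deformation maps.

The goodness of an estimated map is evaluated by its predictive performance:
landmarks are split into folds, the map is re-estimated on each training set,
and the held-out deformed positions are predicted.  Errors are reported
separately along the P-D and A-P axes and as Euclidean distances, all in µm.

The default scheme holds out one embryo at a time, matching the pooled
multi-embryo design of the estimation; a seeded k-fold split over markers is
available for single-embryo (e.g. synthetic) data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import OutOfDomainError, ParameterError
from .geometry import LandmarkPair
from .io import landmark_arrays
from .lattice import build_lattice, estimate_map, predict

__all__ = ["PredictionErrorReport", "cross_validate"]


@dataclass(frozen=True)
class FoldResult:
    fold_id: str
    n_train: int
    n_test: int
    n_skipped: int
    err_pd: float
    err_ap: float
    err_euclid: float


@dataclass(frozen=True)
class PredictionErrorReport:
    """Cross-validation prediction errors for one time interval (µm)."""

    interval_id: str
    scheme: str
    n_folds: int
    err_pd: float
    err_ap: float
    err_euclid: float
    median_pd: float
    median_ap: float
    median_euclid: float
    n_predicted: int
    n_skipped: int
    per_fold: tuple[FoldResult, ...] = field(default=())

    def to_json(self, path=None) -> str:
        obj = {
            "interval_id": self.interval_id,
            "scheme": self.scheme,
            "n_folds": self.n_folds,
            "err_pd": self.err_pd,
            "err_ap": self.err_ap,
            "err_euclid": self.err_euclid,
            "median_pd": self.median_pd,
            "median_ap": self.median_ap,
            "median_euclid": self.median_euclid,
            "n_predicted": self.n_predicted,
            "n_skipped": self.n_skipped,
            "per_fold": [vars(f) for f in self.per_fold],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _folds(
    landmarks: Sequence[LandmarkPair],
    scheme: str,
    k: Optional[int],
    seed: int,
) -> list[tuple[str, np.ndarray]]:
    n = len(landmarks)
    if scheme in ("loeo", "leave-one-embryo-out"):
        embryos = sorted({p.embryo_id for p in landmarks})
        if len(embryos) < 2:
            raise ParameterError(
                "leave-one-embryo-out needs at least 2 embryos; use k-fold"
            )
        ids = np.array([p.embryo_id for p in landmarks])
        return [(e, ids == e) for e in embryos]
    if scheme in ("kfold", "k-fold"):
        if k is None or k < 2:
            raise ParameterError("k-fold scheme needs k >= 2")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        parts = np.array_split(perm, k)
        out = []
        for f, part in enumerate(parts):
            mask = np.zeros(n, dtype=bool)
            mask[part] = True
            out.append((f"fold{f}", mask))
        return out
    raise ParameterError(f"unknown scheme {scheme!r}")


def cross_validate(
    landmarks: Sequence[LandmarkPair],
    scheme: str = "loeo",
    k: Optional[int] = None,
    seed: int = 0,
    spacing: float = 200.0,
    margin_cells: int = 1,
    alpha: Optional[float] = None,
    sigma2: Optional[float] = None,
) -> PredictionErrorReport:
    """Fold-wise prediction error of the estimated map.

    For each fold the map is fitted to the training pairs on a lattice built
    from them; held-out points that fall outside that training lattice are
    skipped and counted.  Folds with fewer than 6 training pairs are skipped
    with a warning; if every fold is skipped an error is raised.
    """
    landmarks = list(landmarks)
    interval = landmarks[0].interval_id if landmarks else ""
    abs_pd: list[np.ndarray] = []
    abs_ap: list[np.ndarray] = []
    euclid: list[np.ndarray] = []
    per_fold: list[FoldResult] = []
    n_skipped_total = 0

    for fold_id, test_mask in _folds(landmarks, scheme, k, seed):
        train = [p for p, m in zip(landmarks, test_mask) if not m]
        test = [p for p, m in zip(landmarks, test_mask) if m]
        if len(train) < 6:
            warnings.warn(f"fold {fold_id}: fewer than 6 training pairs, skipped")
            continue
        lat = build_lattice(train, spacing=spacing, margin_cells=margin_cells)
        fitted = estimate_map(train, lat, alpha=alpha, sigma2=sigma2)
        Xt, xt = landmark_arrays(test)
        inside = fitted.contains(Xt)
        n_skip = int((~inside).sum())
        n_skipped_total += n_skip
        if not np.any(inside):
            warnings.warn(f"fold {fold_id}: all held-out points outside lattice")
            continue
        pred = predict(fitted, Xt[inside])
        d = pred - xt[inside]
        abs_pd.append(np.abs(d[:, 0]))
        abs_ap.append(np.abs(d[:, 1]))
        euclid.append(np.linalg.norm(d, axis=1))
        per_fold.append(
            FoldResult(
                fold_id=str(fold_id),
                n_train=len(train),
                n_test=len(test),
                n_skipped=n_skip,
                err_pd=float(np.mean(abs_pd[-1])),
                err_ap=float(np.mean(abs_ap[-1])),
                err_euclid=float(np.mean(euclid[-1])),
            )
        )

    if not per_fold:
        raise OutOfDomainError("all cross-validation folds were skipped")

    pd_all = np.concatenate(abs_pd)
    ap_all = np.concatenate(abs_ap)
    eu_all = np.concatenate(euclid)
    return PredictionErrorReport(
        interval_id=interval,
        scheme=scheme,
        n_folds=len(per_fold),
        err_pd=float(np.mean(pd_all)),
        err_ap=float(np.mean(ap_all)),
        err_euclid=float(np.mean(eu_all)),
        median_pd=float(np.median(pd_all)),
        median_ap=float(np.median(ap_all)),
        median_euclid=float(np.median(eu_all)),
        n_predicted=int(eu_all.size),
        n_skipped=n_skipped_total,
        per_fold=tuple(per_fold),
    )
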