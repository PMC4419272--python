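"""Reading and writing landmark tables.

The on-disk landmark format is a UTF-8 TSV with header
``embryo_id  interval_id  X_pd  X_ap  x_pd  x_ap`` and '.' decimals,
coordinates in micrometres.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import LandmarkPair, Point2

LANDMARK_COLUMNS = ["embryo_id", "interval_id", "X_pd", "X_ap", "x_pd", "x_ap"]


def landmarks_to_frame(pairs: Iterable[LandmarkPair]) -> pd.DataFrame:
    rows = [
        (p.embryo_id, p.interval_id, p.X.pd, p.X.ap, p.x.pd, p.x.ap) for p in pairs
    ]
    return pd.DataFrame(rows, columns=LANDMARK_COLUMNS)


def frame_to_landmarks(df: pd.DataFrame) -> list[LandmarkPair]:
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    return [
        LandmarkPair(
            embryo_id=str(r.embryo_id),
            interval_id=str(r.interval_id),
            X=Point2(float(r.X_pd), float(r.X_ap)),
            x=Point2(float(r.x_pd), float(r.x_ap)),
        )
        for r in df.itertuples(index=False)
    ]


def read_landmarks(path) -> list[LandmarkPair]:
    """Read a landmark TSV file into a list of :class:`LandmarkPair`."""
    df = pd.read_csv(path, sep="\t")
    return frame_to_landmarks(df)


def write_landmarks(pairs: Sequence[LandmarkPair], path) -> None:
    """Write landmark pairs as TSV (see module docstring for the format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    landmarks_to_frame(pairs).to_csv(path, sep="\t", index=False)


def landmark_arrays(pairs: Sequence[LandmarkPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack landmark positions into ``(X, x)`` arrays of shape (n, 2)."""
    X = np.array([[p.X.pd, p.X.ap] for p in pairs], dtype=float)
    x = np.array([[p.x.pd, p.x.ap] for p in pairs], dtype=float)
    return X.reshape(-1, 2), x.reshape(-1, 2)
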