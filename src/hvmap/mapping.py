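"""The Helix Vector Mapping (HVM) coordinates of a paired-EF-hand lobe.

An EF-lobe is placed in an intrinsic coordinate system: the pseudo-two-fold
axis relating its two EF-hands becomes the z-axis and the inter-hand
interface lies in the yz-plane.  Each conformation is then summarised by two
angles measured on the yz-plane:

* ``dE_phi`` — the angle between the E helices and the y-axis (averaged over
  the lobe's two E helices, the second measured after mapping it through the
  two-fold);
* ``dF_delta`` — the signed difference between the two F-helix angles in the
  same convention.

A structure ensemble (NMR models or trajectory frames) maps to a series of
such points, the raw material of the conformational landscape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import axis_angle_of_rotation, fit_helix_axis, kabsch_superpose
from .structures import EFHandDef, EFLobeDef, Model, ResidueRange, StructureEnsemble, select_ca

__all__ = [
    "LobeFrame",
    "HVMPoint",
    "HVMSeries",
    "compute_lobe_frame",
    "projected_angle",
    "hvm_point",
    "map_ensemble",
    "select_window",
    "series_to_frame",
    "write_series_tsv",
    "read_series_tsv",
]

logger = logging.getLogger(__name__)

#: reject lobes whose hand1→hand2 superposition angle falls below this (deg);
#: a well-formed pseudo-two-fold sits near 180°.
TWOFOLD_ANGLE_GATE = 120.0


@dataclass(frozen=True)
class LobeFrame:
    """Intrinsic orthonormal frame of an EF-lobe.

    z is the pseudo-two-fold axis (sign: the mean E-helix direction has a
    positive z-component), x points from the hand-1 toward the hand-2
    centroid (component orthogonal to z), y = z × x, so the inter-hand
    interface lies in the yz-plane.  ``twofold_angle`` is the rotation angle
    of the hand1→hand2 superposition, near 180° for a well-formed lobe.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    twofold_angle: float

    def rotation(self) -> np.ndarray:
        """World→frame rotation matrix (rows are the frame axes)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass(frozen=True)
class HVMPoint:
    dE_phi: float
    dF_delta: float
    frame_index: int = 0
    run_id: str = ""
    lobe: str = ""


@dataclass
class HVMSeries:
    points: list[HVMPoint]
    run_id: str = ""
    lobe: str = ""
    sampling_interval_ps: float | None = None

    def __post_init__(self) -> None:
        idx = [p.frame_index for p in self.points]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def angles(self) -> np.ndarray:
        """(n, 2) array of (dE_phi, dF_delta)."""
        return np.array([[p.dE_phi, p.dF_delta] for p in self.points], float)


def _paired_hand_ca(model: Model, hand: EFHandDef, k: tuple[int, int, int]) -> np.ndarray:
    """Cα of one hand truncated per segment to the paired lengths ``k``.

    Truncation keeps the loop-proximal residues: helix E keeps its
    C-terminal k residues, the loop its first k, helix F its N-terminal k.
    """
    kE, kL, kF = k
    e = select_ca(model, hand.helixE)[len(hand.helixE) - kE:]
    l = select_ca(model, hand.loop)[:kL]
    f = select_ca(model, hand.helixF)[:kF]
    return np.vstack([e, l, f])


def compute_lobe_frame(model: Model, lobe: EFLobeDef) -> LobeFrame:
    """Construct the intrinsic frame of a lobe in one model.

    The z-axis is the rotation axis of the least-squares superposition of
    hand 1 onto hand 2 (Cα paired positionally across helixE+loop+helixF,
    truncated per segment to the shorter hand).  Raises if the superposition
    angle falls below the two-fold sanity gate, which flags a malformed or
    mis-ranged lobe.
    """
    h1, h2 = lobe.hand1, lobe.hand2
    k = tuple(
        min(len(a), len(b))
        for a, b in zip(h1.segments(), h2.segments())
    )
    ca1 = _paired_hand_ca(model, h1, k)
    ca2 = _paired_hand_ca(model, h2, k)
    sup = kabsch_superpose(ca1, ca2)
    axis, angle = axis_angle_of_rotation(sup.rotation)
    if angle < TWOFOLD_ANGLE_GATE:
        raise ValueError(
            f"{lobe.name}: hand1→hand2 rotation angle {angle:.1f}° below the "
            f"two-fold gate ({TWOFOLD_ANGLE_GATE}°); malformed lobe or wrong "
            f"helix ranges"
        )
    e1 = fit_helix_axis(select_ca(model, h1.helixE)).direction
    e2 = fit_helix_axis(select_ca(model, h2.helixE)).direction
    z = axis if float((e1 + e2) @ axis) >= 0 else -axis
    c1, c2 = ca1.mean(axis=0), ca2.mean(axis=0)
    dx = c2 - c1
    x = dx - (dx @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError(f"{lobe.name}: hand centroids coincide along the two-fold axis")
    x = x / nx
    y = np.cross(z, x)
    return LobeFrame(origin=(c1 + c2) / 2.0, x_axis=x, y_axis=y, z_axis=z,
                     twofold_angle=angle)


def projected_angle(vector: np.ndarray, frame: LobeFrame) -> float:
    """Signed angle (degrees) of a vector's yz-projection, from +y toward +z.

    Computed as atan2(v·z, v·y); range (−180, 180].  Raises when the vector
    is parallel to the x-axis (no yz-projection).
    """
    v = np.asarray(vector, dtype=float)
    py = float(v @ frame.y_axis)
    pz = float(v @ frame.z_axis)
    if math.hypot(py, pz) < 1e-9:
        raise ValueError("vector has no yz-projection (parallel to the x-axis)")
    ang = math.degrees(math.atan2(pz, py))
    return 180.0 if ang <= -180.0 else ang


def _twofold_map(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Rotate a vector 180° about the z-axis: v -> 2(v·z)z − v."""
    return 2.0 * float(v @ z) * z - v


def hvm_point(
    model: Model,
    lobe: EFLobeDef,
    frame_index: int = 0,
    run_id: str = "",
) -> HVMPoint:
    """HVM coordinates of one model.

    Hand-2 helix vectors are mapped through the two-fold (rotated 180°
    about z) before projection, so both hands are measured in the hand-1
    convention; ``dE_phi`` is the circular mean of the two E angles and
    ``dF_delta`` the plain difference angle(F1) − angle(mapped F2).
    """
    frame = compute_lobe_frame(model, lobe)
    e1 = fit_helix_axis(select_ca(model, lobe.hand1.helixE)).direction
    f1 = fit_helix_axis(select_ca(model, lobe.hand1.helixF)).direction
    e2 = fit_helix_axis(select_ca(model, lobe.hand2.helixE)).direction
    f2 = fit_helix_axis(select_ca(model, lobe.hand2.helixF)).direction
    z = frame.z_axis
    aE1 = projected_angle(e1, frame)
    aE2 = projected_angle(_twofold_map(e2, z), frame)
    aF1 = projected_angle(f1, frame)
    aF2 = projected_angle(_twofold_map(f2, z), frame)
    # circular mean of the two E angles (robust to the ±180 seam)
    half = ((aE2 - aE1 + 180.0) % 360.0) - 180.0
    dE = aE1 + half / 2.0
    dE = ((dE + 180.0) % 360.0) - 180.0
    if dE == -180.0:
        dE = 180.0
    return HVMPoint(dE_phi=dE, dF_delta=aF1 - aF2,
                    frame_index=frame_index, run_id=run_id, lobe=lobe.name)


def map_ensemble(
    ensemble: StructureEnsemble,
    lobe: EFLobeDef,
    run_id: str = "",
    sampling_interval_ps: float | None = None,
) -> HVMSeries:
    """HVM coordinates for every model of an ensemble, in model order.

    Models failing the two-fold sanity gate are recorded as gaps (their
    frame index is absent) with a logged warning rather than silently
    dropped.  Raises if no model maps successfully.
    """
    run_id = run_id or ensemble.source_id
    points: list[HVMPoint] = []
    for i, model in enumerate(ensemble):
        try:
            points.append(hvm_point(model, lobe, frame_index=i, run_id=run_id))
        except ValueError as exc:
            logger.warning("frame %d of %s skipped: %s", i, run_id, exc)
    if not points:
        raise ValueError(f"no frame of {run_id!r} yielded a valid lobe frame")
    return HVMSeries(points, run_id=run_id, lobe=lobe.name,
                     sampling_interval_ps=sampling_interval_ps)


def select_window(
    series: HVMSeries,
    dE_center: float,
    dE_halfwidth: float,
    dF_center: float,
    dF_halfwidth: float,
) -> list[int]:
    """Frame indices inside a rectangular angle window, boundaries inclusive.

    This is how representative structures are pulled from a landscape
    region, e.g. the overlap window dE = 50 ± 0.5, δdF = 0 ± 0.5.
    """
    if dE_halfwidth <= 0 or dF_halfwidth <= 0:
        raise ValueError("halfwidths must be positive")
    return [
        p.frame_index
        for p in series
        if abs(p.dE_phi - dE_center) <= dE_halfwidth
        and abs(p.dF_delta - dF_center) <= dF_halfwidth
    ]


# ---------------------------------------------------------------------------
# TSV interchange

_COLUMNS = ["run_id", "lobe", "frame_index", "dE_phi", "dF_delta"]


def series_to_frame(series: HVMSeries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_id": [p.run_id for p in series],
            "lobe": [p.lobe for p in series],
            "frame_index": [p.frame_index for p in series],
            "dE_phi": [round(p.dE_phi, 2) for p in series],
            "dF_delta": [round(p.dF_delta, 2) for p in series],
        }
    )


def write_series_tsv(series: HVMSeries, path: str | Path) -> None:
    series_to_frame(series).to_csv(path, sep="\t", index=False)


def read_series_tsv(path: str | Path) -> HVMSeries:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    runs = df["run_id"].unique()
    lobes = df["lobe"].unique()
    if len(runs) != 1 or len(lobes) != 1:
        raise ValueError(f"{path}: expected a single run/lobe, got {runs}/{lobes}")
    points = [
        HVMPoint(
            dE_phi=float(r.dE_phi),
            dF_delta=float(r.dF_delta),
            frame_index=int(r.frame_index),
            run_id=str(r.run_id),
            lobe=str(r.lobe),
        )
        for r in df.itertuples()
    ]
    return HVMSeries(points, run_id=str(runs[0]), lobe=str(lobes[0]))
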