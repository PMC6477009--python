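"""Motor-map metrics: centre of gravity, spline-interpolated
representation area, hand/arm overlap, and asymmetry ratios.

The centre of gravity (CoG) of a muscle representation is the
amplitude-weighted mean of the stimulation-site coordinates that evoked
accepted responses (peak-to-peak MEP >= 50 µV).  Representation area is
measured by interpolating the scattered site amplitudes with a smooth
thin-plate spline onto a fine 2D lattice (sites first projected onto
their principal plane) and counting lattice cells at or above the
response criterion.  Hand/arm overlap is the intersection-over-union of
the two super-threshold footprints, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator, RegularGridInterpolator

from . import config as cfg
from .config import DEFAULTS

MUSCLE_SETS = {"hand": cfg.HAND_MUSCLES, "arm": cfg.ARM_MUSCLES}


class EmptyMapError(ValueError):
    """No accepted responses: the muscle is unmappable in this session."""


@dataclass
class MotorMap:
    """Stimulation sites + response amplitudes for one muscle (or muscle
    group) in one hemisphere of one subject."""

    subject_id: str
    hemisphere: str
    muscle_set: str                 # muscle name, "hand" or "arm"
    points: np.ndarray              # (n, 3) RAS mm
    amplitudes: np.ndarray          # (n,) µV, 0 at no-response sites

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.points.shape[0] != self.amplitudes.size or self.points.shape[0] < 1:
            raise ValueError("points/amplitudes mismatch or empty map")
        if (self.amplitudes < 0).any():
            raise ValueError("amplitudes must be non-negative")


@dataclass
class CoGResult:
    coordinate: np.ndarray          # 3-vector mm
    total_weight: float             # µV (accepted-site amplitude sum)
    n_points: int


@dataclass
class PlaneFrame:
    origin: np.ndarray              # 3-vector mm
    basis: np.ndarray               # (2, 3) orthonormal rows
    residual_rms: float             # out-of-plane RMS of the projected cloud


@dataclass
class AreaResult:
    area: float                     # cm²
    mask: np.ndarray                # 2D boolean super-threshold lattice
    grid_x: np.ndarray              # lattice coordinates along basis[0], mm
    grid_y: np.ndarray              # lattice coordinates along basis[1], mm
    resolution: float               # mm
    plane: Optional[PlaneFrame]
    fallback: bool = False          # True when too few points for the spline


def maps_from_session(session: pd.DataFrame, hemisphere: str,
                      criterion: float = DEFAULTS.response_criterion_uv,
                      ) -> Dict[str, MotorMap]:
    """Build per-muscle and composite hand/arm maps from a session table.

    Composite amplitudes take the per-site maximum across member muscles
    ("any member responded" semantics, matching the overlap definition).
    """
    sub = session[session["hemisphere"] == hemisphere]
    if sub.empty:
        raise ValueError(f"no stimuli for hemisphere {hemisphere!r}")
    sid = str(sub["subject_id"].iloc[0])
    pts = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    amps = {m: np.nan_to_num(sub[f"{m}_amp_uv"].to_numpy(dtype=float))
            for m in cfg.MUSCLES}
    out = {m: MotorMap(sid, hemisphere, m, pts, amps[m]) for m in cfg.MUSCLES}
    for name, members in MUSCLE_SETS.items():
        comp = np.max(np.stack([amps[m] for m in members]), axis=0)
        out[name] = MotorMap(sid, hemisphere, name, pts, comp)
    return out


def compute_cog(m: MotorMap,
                criterion: float = DEFAULTS.response_criterion_uv,
                weighted: bool = True) -> CoGResult:
    """Centre of gravity of the accepted responses.

    ``weighted=True`` (default): amplitude-weighted mean Σaᵢxᵢ/Σaᵢ;
    ``weighted=False``: unweighted centroid of accepted sites.
    """
    keep = m.amplitudes >= criterion
    if not keep.any():
        raise EmptyMapError(
            f"no accepted responses (>= {criterion} µV) for "
            f"{m.muscle_set} {m.hemisphere}")
    pts = m.points[keep]
    a = m.amplitudes[keep]
    if weighted:
        coord = (pts * a[:, None]).sum(axis=0) / a.sum()
    else:
        coord = pts.mean(axis=0)
    return CoGResult(coordinate=coord, total_weight=float(a.sum()),
                     n_points=int(keep.sum()))


def project_to_plane(points: np.ndarray,
                     frame: Optional[PlaneFrame] = None,
                     ) -> Tuple[PlaneFrame, np.ndarray]:
    """Project a 3D site cloud onto its two leading principal axes.

    Returns the plane frame and the 2D in-plane coordinates (distances
    preserved within the plane).  Collinear or degenerate clouds are
    rejected.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if frame is None:
        if pts.shape[0] < 3:
            raise ValueError("need at least 3 points to define a plane")
        origin = pts.mean(axis=0)
        centered = pts - origin
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] <= 1e-9 * max(s[0], 1e-12):
            raise ValueError("degenerate (collinear) site cloud")
        basis = vt[:2]
        resid = centered @ vt[2] if vt.shape[0] > 2 else np.zeros(pts.shape[0])
        frame = PlaneFrame(origin=origin, basis=basis,
                           residual_rms=float(np.sqrt(np.mean(resid ** 2))))
    coords2d = (pts - frame.origin) @ frame.basis.T
    return frame, coords2d


def interpolate_area(m: MotorMap,
                     resolution: float = DEFAULTS.lattice_resolution_mm,
                     criterion: float = DEFAULTS.response_criterion_uv,
                     padding: float = DEFAULTS.lattice_padding_mm,
                     plane: Optional[PlaneFrame] = None,
                     bounds: Optional[Tuple[float, float, float, float]] = None,
                     ) -> AreaResult:
    """Representation area by smooth spline interpolation.

    Site amplitudes (zeros at no-response sites anchor the borders) are
    interpolated with a thin-plate spline onto a ``resolution``-mm 2D
    lattice over the mapped region padded by one grid spacing; the area
    is the count of cells with interpolated amplitude >= criterion times
    the cell area, in cm².  With fewer than 4 accepted sites the spline
    is unreliable, so the area falls back to (accepted sites) × (5 mm)²
    with ``fallback=True``.
    """
    accepted = m.amplitudes >= criterion
    if accepted.sum() < 4:
        area = float(accepted.sum()) * (cfg.DEFAULTS.grid_spacing_mm ** 2) / 100.0
        return AreaResult(area=area, mask=np.zeros((0, 0), dtype=bool),
                          grid_x=np.array([]), grid_y=np.array([]),
                          resolution=resolution, plane=None, fallback=True)

    frame, xy = project_to_plane(m.points, frame=plane)
    if bounds is None:
        x0, y0 = xy.min(axis=0) - padding
        x1, y1 = xy.max(axis=0) + padding
    else:
        x0, x1, y0, y1 = bounds
    gx = np.arange(x0, x1 + resolution / 2, resolution)
    gy = np.arange(y0, y1 + resolution / 2, resolution)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")

    interp = RBFInterpolator(xy, m.amplitudes, kernel="thin_plate_spline")
    vals = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    vals = np.maximum(vals, 0.0)
    mask = vals >= criterion
    area_cm2 = float(mask.sum()) * resolution ** 2 / 100.0
    return AreaResult(area=area_cm2, mask=mask, grid_x=gx, grid_y=gy,
                      resolution=resolution, plane=frame)


def _same_lattice(a: AreaResult, b: AreaResult) -> bool:
    return (a.mask.shape == b.mask.shape
            and a.grid_x.size == b.grid_x.size and b.grid_y.size == a.grid_y.size
            and np.allclose(a.grid_x, b.grid_x) and np.allclose(a.grid_y, b.grid_y))


def overlap_percent(hand: AreaResult, arm: AreaResult) -> float:
    """Relative overlap: area responding in both hand and arm divided by
    the area responding in either, in percent (intersection over union).

    Masks must live on the same plane; a mismatched lattice is re-gridded
    onto the first mask's lattice by nearest-neighbour lookup.
    """
    if hand.fallback or arm.fallback:
        raise ValueError("overlap undefined for fallback (non-spline) areas")
    mask_a = hand.mask
    mask_b = arm.mask
    if not _same_lattice(hand, arm):
        interp = RegularGridInterpolator((arm.grid_x, arm.grid_y),
                                         arm.mask.astype(float),
                                         method="nearest", bounds_error=False,
                                         fill_value=0.0)
        xx, yy = np.meshgrid(hand.grid_x, hand.grid_y, indexing="ij")
        mask_b = interp(np.column_stack([xx.ravel(), yy.ravel()])
                        ).reshape(xx.shape) > 0.5
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        raise ValueError("overlap undefined: empty union of footprints")
    inter = np.logical_and(mask_a, mask_b).sum()
    return 100.0 * float(inter) / float(union)


@dataclass
class RatioMetrics:
    hand_arm: Dict[str, float]      # per hemisphere: hand area / arm area
    left_right: Dict[str, float]    # per muscle set: left / right area
    flags: List[str] = field(default_factory=list)


def ratio_metrics(areas: Dict[Tuple[str, str], float]) -> RatioMetrics:
    """Asymmetry ratios from a {(hemisphere, set): area} mapping.

    Zero (or missing) denominators yield NaN with a flag; such values are
    excluded from group statistics downstream.
    """
    flags: List[str] = []

    def ratio(num_key, den_key):
        num = areas.get(num_key, np.nan)
        den = areas.get(den_key, np.nan)
        if not np.isfinite(den) or den == 0 or not np.isfinite(num):
            flags.append(f"{num_key}/{den_key}")
            return float("nan")
        return float(num / den)

    hand_arm = {h: ratio((h, "hand"), (h, "arm")) for h in ("L", "R")}
    left_right = {s: ratio(("L", s), ("R", s)) for s in ("hand", "arm")}
    return RatioMetrics(hand_arm=hand_arm, left_right=left_right, flags=flags)


def hand_arm_analysis(session: pd.DataFrame, hemisphere: str,
                      resolution: float = DEFAULTS.lattice_resolution_mm,
                      criterion: float = DEFAULTS.response_criterion_uv,
                      ) -> Dict[str, object]:
    """Hand and arm areas plus their overlap for one hemisphere, computed
    on a shared plane and lattice so the masks are directly comparable."""
    maps = maps_from_session(session, hemisphere, criterion)
    hand, arm = maps["hand"], maps["arm"]
    frame, xy = project_to_plane(hand.points)
    pad = DEFAULTS.lattice_padding_mm
    bounds = (xy[:, 0].min() - pad, xy[:, 0].max() + pad,
              xy[:, 1].min() - pad, xy[:, 1].max() + pad)
    hand_area = interpolate_area(hand, resolution, criterion,
                                 plane=frame, bounds=bounds)
    arm_area = interpolate_area(arm, resolution, criterion,
                                plane=frame, bounds=bounds)
    result = {"hand": hand_area, "arm": arm_area, "overlap": np.nan}
    if not (hand_area.fallback or arm_area.fallback):
        try:
            result["overlap"] = overlap_percent(hand_area, arm_area)
        except ValueError:
            pass
    return result


def mask_to_ascii(res: AreaResult) -> str:
    """Plain-text rendering of a super-threshold mask for inspection."""
    if res.mask.size == 0:
        return "(no mask: fallback area)"
    return "\n".join("".join("#" if v else "." for v in row)
                     for row in res.mask.T[::-1])
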