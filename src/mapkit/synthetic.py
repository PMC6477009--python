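"""Synthetic nTMS study generator.

Produces stimulation sessions (stimulus coordinates + per-muscle MEP
amplitudes/latencies), raw EMG sweeps, gray-matter tissue-probability
volumes and whole two-group cohorts with the statistical structure the
downstream analysis assumes.  Every generated artifact retains the latent
parameters that produced it, so each analysis stage can be tested by
parameter recovery.

Model sketch
------------
Each muscle has a cortical "field": a 2D Gaussian amplitude profile of
spread sigma (mm) and asymptote a_max (µV) centred on the cortical
surface, with a site-specific threshold t_rel·rMT.  A stimulus at
in-plane distance d from the centre, at intensity I, yields

    amplitude = a_max · exp(-d²/(2σ²)) · logistic((I − t_rel·rMT)/s) · ε

with s = 0.05·rMT and multiplicative log-normal noise ε.  Amplitudes
below a 20 µV noise floor are set to 0, so the ≥50 µV response criterion
does meaningful work downstream.

Coordinates are right-handed RAS millimetres; x < 0 is the left
hemisphere.  Stimulation grids lie on a plane tangent to a spherical
head model (curvature ignored at this scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import config as cfg
from .config import DEFAULTS
from .emg import EMGTrace
from .morphometry import VolumeImage, ROISpec


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimSite:
    site_id: int
    position: Tuple[float, float, float]   # RAS mm


@dataclass
class MuscleFieldSpec:
    """Latent cortical representation field of one muscle."""
    muscle_name: str
    center: np.ndarray        # 3-vector, RAS mm
    sigma: float              # mm, isotropic in-plane spread
    a_max: float              # µV, asymptotic peak-to-peak amplitude
    t_rel: float = 1.0        # site threshold as fraction of subject rMT

    def __post_init__(self):
        if self.muscle_name not in cfg.MUSCLES:
            raise ValueError(f"unknown muscle {self.muscle_name!r}")
        self.center = np.asarray(self.center, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if not (0.5 < self.t_rel < 1.5):
            raise ValueError("t_rel must lie in (0.5, 1.5)")


@dataclass
class SubjectSpec:
    """Latent per-subject ground truth for one synthetic participant."""
    subject_id: str
    group: str                                 # "AS" | "control"
    rmt: Dict[str, float]                      # %MSO per hemisphere
    sp: Dict[str, float]                       # true silent-period duration, ms
    rest_latency: Dict[str, float]             # ms
    active_latency: Dict[str, float]           # ms
    rest_amp_uv: Dict[str, float]              # µV, hotspot rest amplitude
    fields: Dict[str, List[MuscleFieldSpec]]   # per hemisphere
    affine_to_standard: np.ndarray             # 4x4
    gm_profile: Dict[Tuple[str, str], float]   # (roi_site, hemisphere) -> density
    bbt: Dict[str, float]                      # cubes/min per hand (L/R)
    activity: float                            # min/day

    def __post_init__(self):
        for hemi, v in self.rmt.items():
            if not (20.0 <= v <= 100.0):
                raise ValueError(f"rMT out of range for {hemi}: {v}")
        for hemi, v in self.sp.items():
            if not (30.0 <= v <= 300.0):
                raise ValueError(f"silent period out of range for {hemi}: {v}")
        for k, v in self.gm_profile.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"GM density out of [0,1] for {k}")


@dataclass
class GroupSpec:
    """Cohort recipe: two groups with optional lateralized effects."""
    n_per_group: int = 8
    asymmetry_flags: Dict[str, bool] = field(default_factory=lambda: {
        "arm_area_left": True,       # AS: left > right arm representation area
        "overlap_left": True,        # AS: left > right hand/arm overlap
        "sp_right_shorter": True,    # AS: right-hemisphere shorter silent period
        "active_latency_left": True, # AS: left-hemisphere longer active latency
        "cog_scatter_left": True,    # AS: widened left-hemisphere CoG scatter
    })
    mep_noise_sigma: float = DEFAULTS.mep_lognorm_sigma
    master_seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")


@dataclass
class SubjectData:
    """Everything generated for one subject (inputs to the analysis)."""
    spec: SubjectSpec
    session: Optional[pd.DataFrame] = None         # stimulation-session table
    emg: Optional[dict] = None                     # per-hemisphere trial blocks
    volume: Optional[VolumeImage] = None           # GM tissue-probability map
    rois: Optional[List[ROISpec]] = None


# ---------------------------------------------------------------------------
# Seeding: named substreams of a master seed, order-independent
# ---------------------------------------------------------------------------

def substream(master_seed: int, *names) -> np.random.Generator:
    """Deterministic named RNG substream of ``master_seed``."""
    import zlib
    keys = [int(master_seed)] + [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def tangent_basis(center: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis of the plane tangent to a spherical head
    model at ``center`` (sphere centred at the origin)."""
    n = np.asarray(center, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(n @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    u = ref - (ref @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def make_stimulation_grid(center, extent: float, spacing: float,
                          plane_basis: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                          ) -> List[StimSite]:
    """Regular 2D stimulation lattice embedded in 3D on a plane.

    ``extent`` is the side length covered per axis; with the protocol's
    5 mm line spacing an extent of 20 mm yields a 5x5 grid.
    """
    center = np.asarray(center, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if extent < spacing:
        raise ValueError("extent must be at least one spacing")
    if plane_basis is None:
        u, v = tangent_basis(center)
    else:
        u, v = (np.asarray(b, dtype=float) for b in plane_basis)
        if (abs(np.linalg.norm(u) - 1) > 1e-8 or abs(np.linalg.norm(v) - 1) > 1e-8
                or abs(u @ v) > 1e-8):
            raise ValueError("plane basis must be two orthonormal 3-vectors")
    n = int(np.floor(extent / spacing + 1e-9)) + 1
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    sites = []
    k = 0
    for oy in offsets:
        for ox in offsets:
            pos = center + ox * u + oy * v
            sites.append(StimSite(site_id=k, position=tuple(pos)))
            k += 1
    return sites


def recruitment(intensity: float, threshold: float, scale: float) -> float:
    """Logistic recruitment probability/gain in stimulator intensity."""
    return float(1.0 / (1.0 + np.exp(-(intensity - threshold) / scale)))


def simulate_mep(site, fieldspec: MuscleFieldSpec, intensity: float, rmt: float,
                 rng: Optional[np.random.Generator] = None,
                 subject_latency: float = 21.0,
                 noise_sigma: float = DEFAULTS.mep_lognorm_sigma,
                 latency_jitter: float = DEFAULTS.latency_jitter_ms,
                 noise_floor: float = DEFAULTS.noise_floor_uv,
                 ) -> Tuple[float, float]:
    """Simulated MEP (amplitude µV, latency ms) for one stimulus.

    With ``noise_sigma=0`` and ``latency_jitter=0`` the model is the
    deterministic Gaussian-field × logistic-recruitment surface.
    """
    if not (0.0 <= intensity <= 100.0):
        raise ValueError("intensity must be within [0, 100] %MSO")
    pos = np.asarray(getattr(site, "position", site), dtype=float)
    d = float(np.linalg.norm(pos - fieldspec.center))
    r = recruitment(intensity, fieldspec.t_rel * rmt,
                    DEFAULTS.recruitment_scale_rel * rmt)
    amp = fieldspec.a_max * np.exp(-d ** 2 / (2.0 * fieldspec.sigma ** 2)) * r
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        amp *= float(np.exp(rng.normal(0.0, noise_sigma)))
    if amp < noise_floor:
        return 0.0, float("nan")
    latency = subject_latency
    if latency_jitter > 0:
        if rng is None:
            raise ValueError("rng required when latency_jitter > 0")
        latency += float(rng.normal(0.0, latency_jitter))
    return float(amp), float(latency)


def simulate_emg_trace(mep_amplitude: float, mep_latency: float,
                       sp_duration: float, background_rms: float,
                       fs: float = 3000.0,
                       rng: Optional[np.random.Generator] = None,
                       duration_ms: float = 500.0,
                       stim_ms: float = 100.0,
                       mep_width_ms: float = 15.0,
                       silence_residual: float = 0.02) -> EMGTrace:
    """One synthetic stimulus-locked EMG sweep.

    Structure: tonic Gaussian background of the given RMS, a biphasic MEP
    waveform starting at ``mep_latency`` after the stimulus, a near-silent
    segment of ``sp_duration`` ms after the MEP end, then resumed
    background.  Latent construction parameters are stored in
    ``EMGTrace.ground_truth``.
    """
    if fs < 2000.0:
        raise ValueError("sampling rate must be >= 2000 Hz")
    if sp_duration < 0:
        raise ValueError("silent-period duration must be >= 0")
    n = int(round(duration_ms * fs / 1000.0))
    stim_index = int(round(stim_ms * fs / 1000.0))
    mep_end_ms = stim_ms + mep_latency + mep_width_ms
    if mep_end_ms + sp_duration >= duration_ms:
        raise ValueError("MEP + silent period exceed trace duration")
    if rng is None:
        rng = np.random.default_rng(0)

    t_ms = np.arange(n) / fs * 1000.0
    x = rng.normal(0.0, background_rms, size=n) if background_rms > 0 else np.zeros(n)

    # near-silence after MEP end
    sil0 = mep_end_ms
    sil1 = mep_end_ms + sp_duration
    in_sil = (t_ms >= sil0) & (t_ms < sil1)
    x[in_sil] *= silence_residual

    # biphasic MEP: one full sine cycle under a Hann window, peak-to-peak scaled
    if mep_amplitude > 0:
        m0 = stim_ms + mep_latency
        in_mep = (t_ms >= m0) & (t_ms < m0 + mep_width_ms)
        phase = (t_ms[in_mep] - m0) / mep_width_ms
        w = np.sin(2 * np.pi * phase) * np.sin(np.pi * phase) ** 2
        if w.size and (w.max() - w.min()) > 0:
            w *= mep_amplitude / (w.max() - w.min())
        x[in_mep] += w

    trace = EMGTrace(fs=fs, samples=x, stim_index=stim_index,
                     ground_truth={"mep_amplitude": mep_amplitude,
                                   "mep_latency": mep_latency,
                                   "sp_duration": sp_duration,
                                   "background_rms": background_rms,
                                   "mep_end_ms": mep_latency + mep_width_ms})
    return trace


def simulate_threshold_response(intensity: float, true_t: float, slope_s: float,
                                rng: np.random.Generator) -> bool:
    """Bernoulli response with p = Phi((intensity - true_t)/slope_s)."""
    if slope_s <= 0:
        raise ValueError("slope must be positive")
    p = norm.cdf((intensity - true_t) / slope_s)
    return bool(rng.random() < p)


# canonical synthetic-volume layout -----------------------------------------

VOLUME_SHAPE = (40, 48, 40)


def canonical_rois(shape: Tuple[int, int, int] = VOLUME_SHAPE,
                   extents: Tuple[int, int, int] = DEFAULTS.roi_extents_vox,
                   ) -> List[ROISpec]:
    """Deterministic box-ROI layout (face/hand/leg × motor/sensory × L/R)
    for the canonical synthetic volume.

    Motor boxes sit anterior (smaller y index) to sensory ones; the
    body-part sites run lateral→medial from face to leg, mirrored across
    the midline, mimicking the homunculus at toy scale.
    """
    nx, ny, nz = shape
    midx = nx // 2
    y_motor, y_sensory = ny // 2 - 5, ny // 2 + 5
    z = int(nz * 0.6)
    lat = {"face": int(midx * 0.65), "hand": int(midx * 0.45), "leg": int(midx * 0.2)}
    rois = []
    for part in ("face", "hand", "leg"):
        for kind, y in (("motor", y_motor), ("sensory", y_sensory)):
            for hemi, sign in (("L", -1), ("R", +1)):
                cx = midx + sign * lat[part]
                rois.append(ROISpec(name=f"{part}_{kind}_{hemi}",
                                    center_voxel=(cx, y, z), extents=extents))
    return rois


def simulate_gm_volume(roi_truth: Dict[str, float],
                       shape: Tuple[int, int, int] = VOLUME_SHAPE,
                       voxel_size: float = DEFAULTS.vbm_voxel_mm,
                       noise_sd: float = 0.0,
                       rng: Optional[np.random.Generator] = None,
                       background: float = cfg.ROI_BASE_DENSITY,
                       rois: Optional[List[ROISpec]] = None) -> VolumeImage:
    """Synthetic gray-matter tissue-probability volume: smooth background
    plus box patches at the stated true densities, clipped to [0, 1].

    ``roi_truth`` maps ROI names (see :func:`canonical_rois`) to densities.
    """
    for k, v in roi_truth.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"density out of [0,1] for {k}")
    if rois is None:
        rois = canonical_rois(shape)
    by_name = {r.name: r for r in rois}
    data = np.full(shape, float(background), dtype=float)
    for name, dens in roi_truth.items():
        roi = by_name[name]
        sl = roi.slices(shape)
        data[sl] = dens
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        data = data + rng.normal(0.0, noise_sd, size=shape)
    data = np.clip(data, 0.0, 1.0)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -np.asarray(shape) * voxel_size / 2.0
    return VolumeImage(data=data.astype(np.float32),
                       voxel_size=(voxel_size,) * 3, affine=affine)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _make_fields(rng, hemi: str, group: str, flags: Dict[str, bool]
                 ) -> List[MuscleFieldSpec]:
    """Per-subject muscle fields: hand-knob cluster + medial arm cluster,
    with the lateralized AS effects applied on the left hemisphere."""
    knob = np.asarray(cfg.HAND_KNOB[hemi], dtype=float)
    n = knob / np.linalg.norm(knob)
    # in-plane medial direction: unit x toward the midline, projected onto
    # the tangent plane; second frame vector completes the in-plane basis
    toward_mid = np.array([-np.sign(knob[0]), 0.0, 0.0])
    medial = toward_mid - (toward_mid @ n) * n
    medial /= np.linalg.norm(medial)
    v = np.cross(n, medial)

    scatter = 2.0
    if group == "AS" and hemi == "L" and flags.get("cog_scatter_left", False):
        scatter *= cfg.AS_EFFECTS["cog_scatter_volume_ratio"] ** (1.0 / 3.0)
    jitter = rng.normal(0.0, scatter, size=2)   # common in-plane displacement

    arm_shift = 0.0
    arm_sigma_scale = 1.0
    if group == "AS" and hemi == "L":
        if flags.get("overlap_left", False):
            arm_shift = cfg.AS_EFFECTS["overlap_shift_mm"]
        if flags.get("arm_area_left", False):
            arm_sigma_scale = np.sqrt(cfg.AS_EFFECTS["arm_area_left_scale"])

    fields = []
    for muscle, (du, dv) in {**cfg.HAND_MUSCLE_OFFSETS, **cfg.ARM_MUSCLE_OFFSETS}.items():
        is_arm = muscle in cfg.ARM_MUSCLES
        off_u, off_v = du, dv
        if is_arm and arm_shift:
            off_u -= arm_shift * np.sign(du) if du else arm_shift
        center = (knob + (off_u + jitter[0]) * medial + (off_v + jitter[1]) * v
                  + rng.normal(0.0, 1.0, size=3) * 0.5)
        sigma = rng.uniform(4.5, 6.0) * (arm_sigma_scale if is_arm else 1.0)
        a_max = rng.uniform(400.0, 1200.0)
        t_rel = rng.uniform(0.92, 1.08)
        fields.append(MuscleFieldSpec(muscle_name=muscle, center=center,
                                      sigma=sigma, a_max=a_max, t_rel=t_rel))
    return fields


def make_subject(subject_id: str, group: str, gspec: GroupSpec,
                 rng: np.random.Generator) -> SubjectSpec:
    preset = cfg.GROUP_PRESETS[group]
    flags = gspec.asymmetry_flags

    def draw(entry, lo, hi):
        return {h: _truncated_normal(rng, entry[h][0], entry[h][1], lo, hi)
                for h in ("L", "R")}

    rmt = draw(preset["rmt"], 20.0, 100.0)
    sp_entry = dict(preset["sp"])
    if group == "AS" and not flags.get("sp_right_shorter", True):
        sp_entry["R"] = sp_entry["L"]
    sp = {h: _truncated_normal(rng, sp_entry[h][0], sp_entry[h][1], 30.0, 300.0)
          for h in ("L", "R")}
    rest_lat = draw(preset["rest_lat"], 12.0, 30.0)
    act_entry = dict(preset["active_lat"])
    if group == "AS" and not flags.get("active_latency_left", True):
        act_entry["L"] = act_entry["R"]
    active_lat = {h: _truncated_normal(rng, act_entry[h][0], act_entry[h][1], 12.0, 30.0)
                  for h in ("L", "R")}
    rest_amp = {h: _truncated_normal(rng, preset["rest_amp_mv"][h][0] * 1000.0,
                                     preset["rest_amp_mv"][h][1] * 1000.0,
                                     60.0, 4000.0)
                for h in ("L", "R")}

    fields = {h: _make_fields(rng, h, group, flags) for h in ("L", "R")}

    gm = {}
    for site in cfg.ROI_SITES:
        part_kind = site  # e.g. "face_sensory"
        for hemi in ("L", "R"):
            dens = cfg.ROI_BASE_DENSITY + rng.normal(0.0, cfg.ROI_SUBJECT_SD)
            if group == "AS" and (part_kind, hemi) in cfg.AS_ROI_EFFECTS:
                dens += cfg.AS_ROI_EFFECTS[(part_kind, hemi)]
            gm[(part_kind, hemi)] = float(np.clip(dens, 0.0, 1.0))

    bbt = {h: _truncated_normal(rng, preset["bbt"][h][0], preset["bbt"][h][1],
                                10.0, 120.0) for h in ("L", "R")}
    activity = _truncated_normal(rng, preset["activity"][0], preset["activity"][1],
                                 5.0, 600.0)

    affine = np.eye(4)
    affine[:3, 3] = rng.normal(0.0, 2.0, size=3)  # small native->standard shift

    return SubjectSpec(subject_id=subject_id, group=group, rmt=rmt, sp=sp,
                       rest_latency=rest_lat, active_latency=active_lat,
                       rest_amp_uv=rest_amp, fields=fields,
                       affine_to_standard=affine, gm_profile=gm,
                       bbt=bbt, activity=activity)


def make_session(spec: SubjectSpec, gspec: GroupSpec,
                 rng: np.random.Generator,
                 extent: float = 30.0,
                 spacing: float = DEFAULTS.grid_spacing_mm) -> pd.DataFrame:
    """Stimulation-session table: one stimulus per grid square per
    hemisphere at 110% of the APB rMT, per-muscle amplitude/latency."""
    rows = []
    for hemi in ("L", "R"):
        fields = spec.fields[hemi]
        centroid = np.mean([f.center for f in fields], axis=0)
        sites = make_stimulation_grid(centroid, extent, spacing)
        intensity = min(100.0, DEFAULTS.mapping_intensity_factor * spec.rmt[hemi])
        for site in sites:
            row = {"subject_id": spec.subject_id, "hemisphere": hemi,
                   "site_id": site.site_id,
                   "x_mm": site.position[0], "y_mm": site.position[1],
                   "z_mm": site.position[2], "intensity_pct": intensity}
            for f in fields:
                amp, lat = simulate_mep(site, f, intensity, spec.rmt[hemi],
                                        rng=rng,
                                        subject_latency=spec.rest_latency[hemi],
                                        noise_sigma=gspec.mep_noise_sigma)
                row[f"{f.muscle_name}_amp_uv"] = amp
                row[f"{f.muscle_name}_lat_ms"] = lat if amp > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def make_emg_blocks(spec: SubjectSpec, gspec: GroupSpec,
                    rng: np.random.Generator, fs: float = 3000.0) -> dict:
    """Rest-MEP (11 trials; first elevated) and silent-period (7 trials)
    blocks per hemisphere, with ground truth retained."""
    out = {}
    for hemi in ("L", "R"):
        rest = []
        for i in range(DEFAULTS.n_rest_meps):
            amp = spec.rest_amp_uv[hemi] * float(np.exp(rng.normal(0.0, 0.3)))
            if i == 0:
                amp *= 1.5   # first-trial facilitation
            lat = spec.rest_latency[hemi] + rng.normal(0.0, 0.4)
            rest.append(simulate_emg_trace(amp, lat, 0.0, background_rms=4.0,
                                           fs=fs, rng=rng))
        sps = []
        for _ in range(DEFAULTS.n_silent_periods):
            dur = float(np.clip(spec.sp[hemi] + rng.normal(0.0, 8.0), 30.0, 280.0))
            amp = spec.rest_amp_uv[hemi] * float(np.exp(rng.normal(0.0, 0.3)))
            lat = spec.active_latency[hemi] + rng.normal(0.0, 0.4)
            sps.append(simulate_emg_trace(amp, lat, dur, background_rms=60.0,
                                          fs=fs, rng=rng))
        out[hemi] = {"rest": rest, "silent_period": sps}
    return out


def make_volume(spec: SubjectSpec, rng: np.random.Generator,
                noise_sd: float = 0.03) -> Tuple[VolumeImage, List[ROISpec]]:
    rois = canonical_rois()
    truth = {f"{site}_{hemi}": spec.gm_profile[(site, hemi)]
             for site in cfg.ROI_SITES for hemi in ("L", "R")}
    vol = simulate_gm_volume(truth, noise_sd=noise_sd, rng=rng, rois=rois)
    return vol, rois


def generate_cohort(gspec: GroupSpec,
                    components: Sequence[str] = ("session", "emg", "volume"),
                    ) -> List[SubjectData]:
    """Generate a full two-group cohort, reproducible from ``master_seed``.

    ``components`` selects which heavy artifacts to build ("session",
    "emg", "volume"); subject specs and behavioral scores are always
    generated.
    """
    subjects = []
    for group in ("AS", "control"):
        for i in range(gspec.n_per_group):
            sid = f"{group}{i + 1:02d}"
            rng = substream(gspec.master_seed, "subject", sid)
            spec = make_subject(sid, group, gspec, rng)
            data = SubjectData(spec=spec)
            if "session" in components:
                data.session = make_session(
                    spec, gspec, substream(gspec.master_seed, "session", sid))
            if "emg" in components:
                data.emg = make_emg_blocks(
                    spec, gspec, substream(gspec.master_seed, "emg", sid))
            if "volume" in components:
                data.volume, data.rois = make_volume(
                    spec, substream(gspec.master_seed, "volume", sid))
            subjects.append(data)
    return subjects


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

SESSION_COLUMNS = (["subject_id", "hemisphere", "site_id",
                    "x_mm", "y_mm", "z_mm", "intensity_pct"]
                   + [f"{m}_{k}" for m in cfg.MUSCLES for k in ("amp_uv", "lat_ms")])


def write_session_csv(session: pd.DataFrame, path) -> None:
    session.reindex(columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_session_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_emg_csv(trace: EMGTrace, path) -> None:
    """Per-trial CSV: two header rows (fs_hz, stim_sample), then samples (µV)."""
    with open(path, "w") as fh:
        fh.write(f"fs_hz,{trace.fs}\n")
        fh.write(f"stim_sample,{trace.stim_index}\n")
        for v in trace.samples:
            fh.write(f"{v:.6g}\n")


def read_emg_csv(path) -> EMGTrace:
    with open(path) as fh:
        fs = float(fh.readline().split(",")[1])
        stim = int(fh.readline().split(",")[1])
        samples = np.array([float(line) for line in fh if line.strip()])
    return EMGTrace(fs=fs, samples=samples, stim_index=stim)
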