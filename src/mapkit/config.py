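"""Central configuration: protocol constants and cohort presets.

Every tunable parameter of the pipeline lives here with its protocol
default, so a run can be reproduced from a serialized config alone.
The cohort preset bundles the group-level means/SDs the synthetic
cohorts are drawn from (one preset, versioned by name).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml


@dataclass(frozen=True)
class Defaults:
    """Protocol constants used across the pipeline.

    Units: distances mm, amplitudes µV (MEPs) except where noted,
    intensities %MSO (percent maximum stimulator output), times ms.
    """

    # mapping protocol
    grid_spacing_mm: float = 5.0          # stimulation grid line spacing
    response_criterion_uv: float = 50.0   # MEP acceptance threshold (peak-to-peak)
    mapping_intensity_factor: float = 1.10   # mapping at 110% of APB rMT
    suprathreshold_factor: float = 1.20      # rest/active blocks at 120% rMT
    n_rest_meps: int = 11                 # rest MEP block size (first discarded)
    n_silent_periods: int = 7             # silent-period block size (min+max trimmed)

    # map geometry
    lattice_resolution_mm: float = 0.5    # interpolation lattice cell edge
    lattice_padding_mm: float = 5.0       # pad mapped region by one grid spacing

    # MEP generator model
    noise_floor_uv: float = 20.0          # simulated amplitudes below this -> 0
    recruitment_scale_rel: float = 0.05   # logistic recruitment scale, fraction of rMT
    mep_lognorm_sigma: float = 0.5        # multiplicative log-normal amplitude noise
    latency_jitter_ms: float = 0.5

    # threshold hunting
    hunt_slope_rel: float = 0.07          # assumed psychometric slope, fraction of threshold
    hunt_start_intensity: float = 45.0
    hunt_n_stimuli: int = 20
    hunt_grid: Tuple[float, float, float] = (20.0, 100.0, 0.1)  # lo, hi, step %MSO

    # EMG feature extraction
    mep_search_window_ms: Tuple[float, float] = (10.0, 60.0)
    onset_sd_mult: float = 3.0            # onset = |signal| > mean + k*SD of pre-stim
    sp_smooth_ms: float = 5.0             # moving-average window on rectified EMG
    sp_mep_end_sd_mult: float = 2.0       # MEP-end threshold = pre mean + k*SD (smoothed)
    sp_return_frac: float = 0.5           # return threshold, fraction of pre-stim level
    sp_sustain_ms: float = 5.0            # sustained-return requirement
    sp_tonic_floor_uv: float = 10.0       # minimum tonic background level for a valid trial

    # confidence ellipsoids
    ellipsoid_level: float = 0.90

    # morphometry
    smoothing_fwhm_mm: float = 10.0
    roi_extents_vox: Tuple[int, int, int] = (4, 4, 2)
    vbm_alpha: float = 0.001
    vbm_voxel_mm: float = 1.5

    # statistics
    alpha: float = 0.05
    exact_test_max_n: int = 16            # exact enumeration when combined n <= this

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULTS = Defaults()


# ---------------------------------------------------------------------------
# Cohort preset: group means (SD) for the two study-like groups.
# Scalar measures are (mean, sd) tuples; per-hemisphere where relevant.
# ---------------------------------------------------------------------------

PRESET_NAME = "table1_table2_defaults"

GROUP_PRESETS: Dict[str, dict] = {
    "AS": {
        "rmt": {"L": (56.0, 10.0), "R": (56.0, 16.0)},          # %MSO
        "sp": {"L": (124.0, 30.0), "R": (97.0, 34.0)},          # ms
        "rest_amp_mv": {"L": (0.60, 0.30), "R": (0.54, 0.30)},  # mV (SD narrowed to subject level)
        "rest_lat": {"L": (20.6, 1.1), "R": (20.5, 1.3)},       # ms
        "active_lat": {"L": (19.4, 1.4), "R": (18.3, 1.4)},     # ms; left prolonged
        "bbt": {"L": (54.0, 5.0), "R": (58.0, 7.0)},            # cubes/min
        "activity": (67.0, 26.0),                               # min/day
    },
    "control": {
        "rmt": {"L": (62.0, 16.0), "R": (58.0, 14.0)},
        "sp": {"L": (117.0, 43.0), "R": (115.0, 39.0)},
        "rest_amp_mv": {"L": (0.73, 0.35), "R": (0.59, 0.18)},
        "rest_lat": {"L": (21.0, 1.8), "R": (20.9, 1.7)},
        "active_lat": {"L": (18.3, 2.0), "R": (18.2, 1.8)},
        "bbt": {"L": (64.0, 6.0), "R": (65.0, 5.0)},
        "activity": (115.0, 48.0),
    },
}

# Generator geometry: canonical muscle-field layout (RAS mm, x<0 = left).
# Hand-muscle field centers cluster in a hand-knob-like patch; arm-muscle
# centers sit medial (and slightly superior) to it.
HAND_KNOB = {"L": (-35.0, -22.0, 68.0), "R": (35.0, -22.0, 68.0)}

# offsets within each hemisphere, in the (lateral->medial, posterior->anterior)
# tangent frame used by the generator; mm
HAND_MUSCLE_OFFSETS = {"APB": (0.0, 0.0), "ADM": (3.0, -2.0), "FDI": (-2.5, 2.0)}
ARM_MUSCLE_OFFSETS = {"ECR": (8.0, 0.0), "FCR": (10.5, -2.0), "BB": (9.5, 3.0)}

MUSCLES = ("APB", "ADM", "FDI", "ECR", "FCR", "BB")
HAND_MUSCLES = ("APB", "ADM", "FDI")
ARM_MUSCLES = ("ECR", "FCR", "BB")

# Asymmetry effect sizes toggled by the AS preset flags
AS_EFFECTS = {
    "arm_area_left_scale": 1.4,      # left-hemisphere arm footprint area x1.4
    "overlap_shift_mm": 4.0,         # arm fields moved toward hand fields (left hemisphere)
    "cog_scatter_volume_ratio": 3.0, # left-hemisphere CoG ellipsoid volume x3
}

# ROI layout for the synthetic tissue-probability volumes (voxel indices are
# defined relative to a canonical volume shape; see synthetic.simulate_gm_volume)
ROI_SITES = ("hand_motor", "hand_sensory", "face_motor", "face_sensory",
             "leg_motor", "leg_sensory")

# ROI density presets (true GM density in [0,1]) and AS lateralized effects
ROI_BASE_DENSITY = 0.55
ROI_SUBJECT_SD = 0.03
AS_ROI_EFFECTS = {  # additive shifts applied to the AS group
    ("face_sensory", "L"): -0.06,   # less GM, left face sensory area
    ("leg_motor", "R"): +0.06,      # more GM, right leg motor area
}


def write_config(path, defaults: Defaults = DEFAULTS) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"preset": PRESET_NAME, "defaults": defaults.to_dict()}, fh)


def read_config(path) -> Defaults:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return Defaults(**{k: tuple(v) if isinstance(v, list) else v
                       for k, v in payload["defaults"].items()})
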