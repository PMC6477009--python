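"""End-to-end orchestration: simulate a cohort, extract EMG features,
hunt thresholds, compute map metrics and CoG ellipsoids, extract ROI
densities, and run the group statistics — one reproducible run directory.

All randomness is drawn from named substreams of a single master seed,
so each stage is independently reproducible; the config and seeds are
serialized into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import config as cfg
from .config import DEFAULTS, Defaults
from . import synthetic, emg, threshold, mapping, geometry, morphometry, stats


@dataclass
class RunConfig:
    out_dir: str = "mapkit_run"
    preset: str = "as-vs-control"
    n_per_group: int = 8
    seed: int = 42
    asymmetry: bool = True              # False -> symmetric null generator
    components: Sequence[str] = ("session", "emg", "volume")
    hunt: bool = True                   # simulate per-subject threshold hunts
    defaults: Defaults = field(default_factory=lambda: DEFAULTS)

    def group_spec(self) -> synthetic.GroupSpec:
        flags = {k: self.asymmetry for k in
                 ("arm_area_left", "overlap_left", "sp_right_shorter",
                  "active_latency_left", "cog_scatter_left")}
        return synthetic.GroupSpec(n_per_group=self.n_per_group,
                                   asymmetry_flags=flags,
                                   master_seed=self.seed)


def _round_floats(obj, nd=6):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def analyze_subject(data: synthetic.SubjectData, config: RunConfig,
                    ) -> stats.SubjectRecord:
    """Measure one synthetic subject exactly as the protocol would."""
    spec = data.spec
    rec = stats.SubjectRecord(subject_id=spec.subject_id, group=spec.group)

    for hemi in ("L", "R"):
        # --- threshold (hunted when enabled, else generator truth)
        if config.hunt:
            res = threshold.simulated_hunt(
                spec.rmt[hemi],
                seed=int(synthetic.substream(config.seed, "hunt", spec.subject_id,
                                             hemi).integers(2 ** 31)))
            rec.rmt[hemi] = res.estimate
        else:
            rec.rmt[hemi] = spec.rmt[hemi]

        # --- EMG blocks
        if data.emg is not None:
            block = data.emg[hemi]
            meps = [emg.detect_mep(tr) for tr in block["rest"]]
            amp, lat, _ = emg.summarize_rest_meps(
                [m.amplitude for m in meps], [m.latency for m in meps])
            rec.rest_amp_mv[hemi] = amp / 1000.0
            rec.rest_lat[hemi] = lat
            sp_trials = [emg.silent_period_duration(tr) for tr in block["silent_period"]]
            durations = [r.duration for r in sp_trials if r.valid]
            if len(durations) >= 3:
                rec.sp[hemi] = emg.summarize_silent_periods(durations)
            active_lats = np.array([emg.detect_mep(tr).latency
                                    for tr in block["silent_period"]])
            if np.isfinite(active_lats).any():
                rec.active_lat[hemi] = float(np.nanmean(active_lats))

        # --- motor maps
        if data.session is not None:
            res = mapping.hand_arm_analysis(data.session, hemi)
            rec.area_hand[hemi] = res["hand"].area
            rec.area_arm[hemi] = res["arm"].area
            rec.overlap[hemi] = res["overlap"]

    if data.session is not None:
        areas = {(h, s): {"hand": rec.area_hand, "arm": rec.area_arm}[s].get(h, np.nan)
                 for h in ("L", "R") for s in ("hand", "arm")}
        ratios = mapping.ratio_metrics(areas)
        rec.hand_arm_ratio = ratios.hand_arm
        rec.lr_ratio = ratios.left_right

    if data.volume is not None and data.rois is not None:
        dens = {r.name: morphometry.roi_density(data.volume, r) for r in data.rois}
        motor = [v for k, v in dens.items() if "motor" in k]
        sensory = [v for k, v in dens.items() if "sensory" in k]
        rec.mean_motor_gm = float(np.mean(motor))
        rec.mean_sensory_gm = float(np.mean(sensory))

    rec.bbt = dict(spec.bbt)
    rec.activity = spec.activity
    return rec


def subject_cogs(data: synthetic.SubjectData, normalized: bool = True,
                 ) -> Dict[str, Dict[str, np.ndarray]]:
    """Hand/arm composite CoGs per hemisphere (optionally affine-normalized
    to the standard space)."""
    out: Dict[str, Dict[str, np.ndarray]] = {"hand": {}, "arm": {}}
    for hemi in ("L", "R"):
        maps = mapping.maps_from_session(data.session, hemi)
        for ms in ("hand", "arm"):
            try:
                cog = mapping.compute_cog(maps[ms]).coordinate
            except mapping.EmptyMapError:
                continue
            if normalized:
                cog = geometry.apply_affine(cog, data.spec.affine_to_standard)
            out[ms][hemi] = cog
    return out


def group_ellipsoids(cohort: Sequence[synthetic.SubjectData],
                     level: float = DEFAULTS.ellipsoid_level,
                     ) -> Dict[str, geometry.Ellipsoid]:
    """Per group × muscle-set × hemisphere confidence ellipsoids of the
    normalized CoG clusters (fitted where >= 4 subjects contribute)."""
    clusters: Dict[str, List[np.ndarray]] = {}
    for data in cohort:
        if data.session is None:
            continue
        cogs = subject_cogs(data)
        for ms in ("hand", "arm"):
            for hemi, c in cogs[ms].items():
                clusters.setdefault(f"{data.spec.group}_{ms}_{hemi}", []).append(c)
    out = {}
    for name, pts in clusters.items():
        if len(pts) >= 4:
            try:
                out[name] = geometry.fit_confidence_ellipsoid(np.array(pts), level)
            except ValueError:
                continue
    return out


def run_all(config: RunConfig) -> Path:
    """Run the whole pipeline; returns the run directory.

    Outputs: per-subject metrics (CSV), summary tables (CSV), ellipsoid
    records (JSON), and a manifest with the config hash and seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gspec = config.group_spec()
    cohort = synthetic.generate_cohort(gspec, components=config.components)

    records = [analyze_subject(d, config) for d in cohort]
    metrics = stats.records_to_frame(records)
    metrics.to_csv(out / "subject_metrics.csv", index=False, float_format="%.6g")

    tables = stats.build_summary_tables(records)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")

    ell = {}
    if "session" in config.components:
        fitted = group_ellipsoids(cohort)
        summary = geometry.ellipsoid_summary(fitted) if fitted else {}
        ell = {name: {"center": e.center.tolist(),
                      "axis_lengths_mm": e.axis_lengths.tolist(),
                      "axis_dirs": e.axis_dirs.tolist(),
                      "volume_cm3": e.volume,
                      "orientation": geometry.principal_orientation(e),
                      "n": e.n_points}
               for name, e in fitted.items()}
        with open(out / "ellipsoids.json", "w") as fh:
            json.dump(_round_floats({"ellipsoids": ell, "summary": summary}),
                      fh, indent=1, sort_keys=True)

    cfg_dict = {"preset": config.preset, "n_per_group": config.n_per_group,
                "seed": config.seed, "asymmetry": config.asymmetry,
                "components": list(config.components), "hunt": config.hunt,
                "defaults": config.defaults.to_dict()}
    digest = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config": cfg_dict, "config_sha256": digest,
                "preset_name": cfg.PRESET_NAME,
                "n_subjects": len(records)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(_round_floats(manifest), fh, indent=1, sort_keys=True, default=str)
    return out
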