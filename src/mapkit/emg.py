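"""EMG feature extraction: MEP amplitude/latency, rest-block summaries,
and cortical silent-period duration.

A motor-evoked potential (MEP) is the muscle response to a cortical
stimulus, measured peak-to-peak in µV from stimulus-locked EMG. The
cortical silent period is the pause in tonic EMG that follows an MEP
delivered during voluntary contraction; its duration (MEP end to the
return of background activity) indexes intracortical inhibition.

All detection parameters (onset threshold, smoothing window, return
criterion) are config-exposed; defaults follow common clinical
neurophysiology practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .config import DEFAULTS


@dataclass
class EMGTrace:
    """A single stimulus-locked EMG sweep.

    samples are in µV; ``stim_index`` marks the stimulus sample.
    ``ground_truth`` (optional) carries the latent parameters a synthetic
    trace was built from, enabling parameter-recovery tests.
    """

    fs: float                      # sampling rate, Hz
    samples: np.ndarray            # µV
    stim_index: int
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not (0 <= self.stim_index < self.samples.size):
            raise ValueError("stimulus index outside trace")

    @property
    def pre_window_ms(self) -> float:
        return self.stim_index / self.fs * 1000.0

    def ms_to_samples(self, ms: float) -> int:
        return int(round(ms * self.fs / 1000.0))


@dataclass
class MEPRecord:
    muscle: Optional[str]
    amplitude: float               # µV peak-to-peak
    latency: float                 # ms from stimulus; NaN if no onset found
    accepted: bool


@dataclass
class SilentPeriodResult:
    duration: float                # ms; NaN when invalid
    mep_end: float                 # ms from stimulus
    background_return: float       # ms from stimulus
    valid: bool
    reason: str = ""


def detect_mep(trace: EMGTrace,
               search_window: Tuple[float, float] = DEFAULTS.mep_search_window_ms,
               criterion: float = DEFAULTS.response_criterion_uv,
               muscle: Optional[str] = None,
               onset_sd_mult: float = DEFAULTS.onset_sd_mult) -> MEPRecord:
    """Measure peak-to-peak MEP amplitude and onset latency in a window
    after the stimulus; a response is accepted when amplitude >= criterion.

    Onset latency is the first crossing of |signal| above the pre-stimulus
    mean + ``onset_sd_mult``·SD (threshold-crossing onset, not peak).
    """
    lo, hi = search_window
    if lo >= hi:
        raise ValueError("search window must be increasing")
    i0 = trace.stim_index + trace.ms_to_samples(lo)
    i1 = trace.stim_index + trace.ms_to_samples(hi)
    if i0 < 0 or i1 > trace.samples.size or i0 >= i1:
        raise ValueError("search window outside trace")

    window = trace.samples[i0:i1]
    amplitude = float(window.max() - window.min())

    pre = trace.samples[:trace.stim_index]
    if pre.size:
        thr = float(np.abs(pre).mean() + onset_sd_mult * pre.std())
    else:
        thr = 0.0
    above = np.nonzero(np.abs(window) > thr)[0]
    if above.size and amplitude > 0:
        latency = (i0 + above[0] - trace.stim_index) / trace.fs * 1000.0
    else:
        latency = float("nan")

    return MEPRecord(muscle=muscle, amplitude=amplitude, latency=latency,
                     accepted=amplitude >= criterion)


def summarize_rest_meps(amplitudes: Sequence[float],
                        latencies: Sequence[float],
                        expected_n: int = DEFAULTS.n_rest_meps):
    """Mean amplitude/latency of a rest-MEP block, discarding the first
    trial (its amplitude is systematically elevated).

    Returns ``(mean_amplitude, mean_latency, complete)`` where ``complete``
    is False when fewer than ``expected_n`` trials were supplied (the means
    are then computed on the available trials, still dropping the first).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    latencies = np.asarray(latencies, dtype=float)
    if amplitudes.size != latencies.size:
        raise ValueError("amplitude/latency counts differ")
    if amplitudes.size < 2:
        raise ValueError("need at least 2 trials (first is discarded)")
    complete = amplitudes.size == expected_n
    return (float(np.nanmean(amplitudes[1:])),
            float(np.nanmean(latencies[1:])),
            complete)


def _smoothed_rectified(trace: EMGTrace, smooth_ms: float) -> np.ndarray:
    w = max(1, trace.ms_to_samples(smooth_ms))
    return uniform_filter1d(np.abs(trace.samples), size=w, mode="nearest")


def silent_period_duration(trace: EMGTrace,
                           smooth_ms: float = DEFAULTS.sp_smooth_ms,
                           mep_end_sd_mult: float = DEFAULTS.sp_mep_end_sd_mult,
                           return_frac: float = DEFAULTS.sp_return_frac,
                           sustain_ms: float = DEFAULTS.sp_sustain_ms,
                           tonic_floor_uv: float = DEFAULTS.sp_tonic_floor_uv,
                           mep_window_ms: Tuple[float, float] = (5.0, 80.0),
                           ) -> SilentPeriodResult:
    """Silent-period duration: from the end of the MEP to the return of the
    tonic background EMG, on the moving-average rectified trace.

    Literal zero EMG never occurs with noise, so "absolute silence" is
    operationalized as the smoothed rectified signal staying below a
    fraction of its pre-stimulus level.  MEP end = last sample within the
    MEP window above pre-stimulus mean + k·SD of the smoothed signal;
    background return = first subsequent sample at or above
    ``return_frac``·(pre-stimulus level) sustained for ``sustain_ms``.
    """
    sm = _smoothed_rectified(trace, smooth_ms)
    pre = sm[:trace.stim_index]
    if pre.size < trace.ms_to_samples(20.0):
        return SilentPeriodResult(float("nan"), float("nan"), float("nan"),
                                  False, "insufficient pre-stimulus window")
    pre_mean = float(pre.mean())
    pre_sd = float(pre.std())
    if pre_mean < tonic_floor_uv:
        return SilentPeriodResult(float("nan"), float("nan"), float("nan"),
                                  False, "no tonic background activity")

    i0 = trace.stim_index + trace.ms_to_samples(mep_window_ms[0])
    i1 = min(trace.stim_index + trace.ms_to_samples(mep_window_ms[1]), sm.size)
    mep_thr = pre_mean + mep_end_sd_mult * pre_sd
    above = np.nonzero(sm[i0:i1] > mep_thr)[0]
    if above.size == 0:
        return SilentPeriodResult(float("nan"), float("nan"), float("nan"),
                                  False, "no MEP above threshold")
    mep_end_idx = i0 + above[-1]

    ret_thr = return_frac * pre_mean
    sustain = max(1, trace.ms_to_samples(sustain_ms))
    seg = sm[mep_end_idx + 1:]
    ok = (seg >= ret_thr).astype(int)
    if ok.size >= sustain:
        # first index i with `sustain` consecutive above-threshold samples
        runsum = np.convolve(ok, np.ones(sustain, dtype=int), mode="valid")
        hits = np.nonzero(runsum == sustain)[0]
    else:
        hits = np.array([], dtype=int)
    if hits.size == 0:
        return SilentPeriodResult(float("nan"), float("nan"), float("nan"),
                                  False, "background never returned")
    ret_idx = mep_end_idx + 1 + hits[0]

    to_ms = 1000.0 / trace.fs
    mep_end_ms = (mep_end_idx - trace.stim_index) * to_ms
    ret_ms = (ret_idx - trace.stim_index) * to_ms
    return SilentPeriodResult(ret_ms - mep_end_ms, mep_end_ms, ret_ms, True)


def summarize_silent_periods(durations: Sequence[float],
                             expected_n: int = DEFAULTS.n_silent_periods) -> float:
    """Mean silent-period duration after trimming exactly one minimum and
    one maximum (ties: one instance each)."""
    d = np.asarray([x for x in durations if np.isfinite(x)], dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 valid silent periods to trim and average")
    d = np.sort(d)
    return float(d[1:-1].mean())
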