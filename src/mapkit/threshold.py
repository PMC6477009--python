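"""Maximum-likelihood adaptive resting-motor-threshold (rMT) estimation.

Threshold hunting: the response probability at intensity I is modelled
as Phi((I − t)/s), a cumulative-normal psychometric function of the
stimulator intensity (in %MSO) with threshold t and spread s.  After
each stimulus the likelihood of every candidate threshold on a fine
grid is updated from the response history, and the next stimulus is
delivered at the current maximum-likelihood threshold — the standard
ML-PEST sequential rule.  The spread is tied to the candidate threshold
(s = 0.07·t), the usual assumption of adaptive motor-threshold tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .config import DEFAULTS


@dataclass
class HuntState:
    """Evolving state of one threshold hunt.

    ``anchored`` adds two virtual trials — a non-response at the grid
    floor and a response at the ceiling — to the likelihood.  This keeps
    the early likelihood proper (otherwise a single non-response drives
    the argmax to the boundary) and is the usual regularization in
    ML-PEST threshold tools; it is two pseudo-observations, vanishing in
    influence as real data accumulate.
    """
    history: List[Tuple[float, bool]] = field(default_factory=list)
    slope_rel: float = DEFAULTS.hunt_slope_rel
    grid: Tuple[float, float, float] = DEFAULTS.hunt_grid
    start_intensity: float = DEFAULTS.hunt_start_intensity
    anchored: bool = True
    _ll_cache: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def t_grid(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + step / 2, step)

    def push(self, intensity: float, response: bool) -> None:
        """Append a trial, updating the cached grid log-likelihood."""
        self._loglik_grid()   # ensure cache reflects current history
        self.history.append((float(intensity), bool(response)))
        t = self.t_grid
        self._ll_cache = self._ll_cache + hunt_loglik(
            t, self.slope_rel * t, [(intensity, response)])

    def _loglik_grid(self) -> np.ndarray:
        if self._ll_cache is None:
            t = self.t_grid
            history = list(self.history)
            if self.anchored:
                lo, hi, _ = self.grid
                history += [(lo, False), (hi, True)]
            self._ll_cache = hunt_loglik(t, self.slope_rel * t, history)
        return self._ll_cache

    @property
    def ml_estimate(self) -> float:
        t = self.t_grid
        ll = self._loglik_grid()
        return float(t[int(np.argmax(ll))])   # argmax: ties -> lowest t


def hunt_loglik(t, slope_s, history: Sequence[Tuple[float, bool]]):
    """Log-likelihood of threshold candidate(s) ``t`` given the
    (intensity, response) history: sum of log Phi((I−t)/s) over responses
    and log(1 − Phi((I−t)/s)) over non-responses.  Empty history → 0.
    Vectorized over ``t`` (``slope_s`` may be scalar or match ``t``)."""
    t = np.asarray(t, dtype=float)
    s = np.broadcast_to(np.asarray(slope_s, dtype=float), t.shape)
    if (s <= 0).any():
        raise ValueError("slope must be positive")
    ll = np.zeros_like(t)
    for intensity, response in history:
        z = (intensity - t) / s
        if response:
            ll += norm.logcdf(z)
        else:
            ll += norm.logsf(z)
    return ll if ll.ndim else float(ll)


def next_intensity(state: HuntState) -> float:
    """Next stimulus intensity: the current ML threshold estimate rounded
    to the nearest 1 %MSO and clamped to [20, 100]; a configured start
    intensity before any data."""
    if not state.history:
        return float(state.start_intensity)
    est = state.ml_estimate
    return float(np.clip(round(est), 20.0, 100.0))


@dataclass
class HuntResult:
    estimate: float                      # %MSO, grid resolution
    history: List[Tuple[float, bool]]
    aborted: bool = False


def estimate_rmt(responder: Callable[[float], bool],
                 n_stimuli: int = DEFAULTS.hunt_n_stimuli,
                 state: Optional[HuntState] = None) -> HuntResult:
    """Run an adaptive hunt of ``n_stimuli`` trials against a responder
    callback and return the final ML estimate with the full history.

    A responder exception aborts the hunt; the partial history (and the
    estimate from it) is still returned with ``aborted=True``.
    """
    if n_stimuli < 10:
        raise ValueError("need at least 10 stimuli for a stable estimate")
    if state is None:
        state = HuntState()
    for _ in range(n_stimuli):
        intensity = next_intensity(state)
        try:
            response = bool(responder(intensity))
        except Exception:
            return HuntResult(estimate=state.ml_estimate,
                              history=list(state.history), aborted=True)
        state.push(intensity, response)
    return HuntResult(estimate=state.ml_estimate, history=list(state.history))


def simulated_hunt(true_t: float, n_stimuli: int = DEFAULTS.hunt_n_stimuli,
                   slope_rel: float = DEFAULTS.hunt_slope_rel,
                   seed: int = 0) -> HuntResult:
    """Convenience: hunt against a simulated cumulative-normal responder
    with threshold ``true_t`` and spread ``slope_rel``·``true_t``."""
    from .synthetic import simulate_threshold_response

    rng = np.random.default_rng(seed)
    s = slope_rel * true_t

    def responder(intensity: float) -> bool:
        return simulate_threshold_response(intensity, true_t, s, rng)

    return estimate_rmt(responder, n_stimuli=n_stimuli)
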