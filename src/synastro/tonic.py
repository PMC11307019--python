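"""Tonic GABA current from a drug-induced holding-current shift.

The tonic current carried by extrasynaptic GABA_A receptors is revealed
by blocking them (picrotoxin): the holding current shifts to a new
stable level, and the tonic current is the difference in mean holding
current between one minute after the shift has stabilized and one
minute of pre-drug baseline.  Both windows are fixed at exactly 60 s;
any other length is refused.  Stability of the post-drug window is
assessed with a robust (Theil-Sen) drift estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trace import Trace

WINDOW_S = 60.0
# For a first-order wash-in, the residual transient left in the earliest
# "stable" window biases the estimate by ~24x the slope tolerance (pA),
# independent of shift size, while the wait for stability grows only
# logarithmically in shift/tolerance -- so the default is set small.
DEFAULT_SLOPE_TOL_PA_PER_S = 0.01


@dataclass
class TonicResult:
    pre_mean_pA: float
    post_mean_pA: float
    tonic_current_pA: float
    pre_window: tuple[float, float]
    post_window: tuple[float, float]
    stability_flag: bool


def _window_samples(trace: Trace, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if not np.isclose(t1 - t0, WINDOW_S, atol=1e-6):
        raise ValueError(f"analysis windows must be exactly {WINDOW_S:.0f} s, got {t1 - t0} s")
    if t0 < trace.start_time or t1 > trace.start_time + trace.duration + 1e-9:
        raise ValueError(f"window {window} extends beyond the recording")
    return trace.slice_time(t0, t1)


def robust_drift(samples: np.ndarray, sampling_rate: float, decimate_to_hz: float = 10.0) -> float:
    """Robust drift (pA/s) of a current segment, on a decimated copy.

    Two estimators are combined and the larger-magnitude one returned:
    the Theil-Sen pairwise-median slope (robust to phasic events) and
    the half-window mean difference divided by the half-window span
    (sensitive to the convex tail of an exponential wash-in, which the
    pairwise median systematically understates).  Decimation by block
    averaging keeps the pairwise estimator tractable on multi-kHz data
    without biasing a linear drift.
    """
    step = max(int(sampling_rate / decimate_to_hz), 1)
    n = (samples.size // step) * step
    blocks = samples[:n].reshape(-1, step).mean(axis=1)
    if blocks.size < 4:
        raise ValueError("segment too short for a drift estimate")
    t = np.arange(blocks.size) * (step / sampling_rate)
    ts_slope, _, _, _ = stats.theilslopes(blocks, t)
    half = blocks.size // 2
    span_s = half * step / sampling_rate
    mean_slope = (blocks[half : 2 * half].mean() - blocks[:half].mean()) / span_s
    return float(ts_slope if abs(ts_slope) >= abs(mean_slope) else mean_slope)


def find_stable_post_window(
    trace: Trace,
    drug_onset_s: float,
    slope_tol_pA_per_s: float = DEFAULT_SLOPE_TOL_PA_PER_S,
    window_s: float = WINDOW_S,
    search_step_s: float = 1.0,
) -> tuple[float, float]:
    """Earliest 60-s window after drug onset with drift below tolerance.

    Windows starting at ``drug_onset_s``, stepping by ``search_step_s``,
    are scanned until the magnitude of the robust linear drift drops to
    ``slope_tol_pA_per_s`` or below.

    Raises
    ------
    ValueError
        If no stable window fits inside the recording.
    """
    if window_s != WINDOW_S:
        raise ValueError(f"the post window must be exactly {WINDOW_S:.0f} s")
    end = trace.start_time + trace.duration
    if not trace.start_time <= drug_onset_s < end:
        raise ValueError("drug onset must lie inside the recording")
    if end - drug_onset_s < window_s:
        raise ValueError("less than one window of data after drug onset")
    start = drug_onset_s
    while start + window_s <= end + 1e-9:
        seg = trace.slice_time(start, start + window_s)
        if abs(robust_drift(seg, trace.sampling_rate)) <= slope_tol_pA_per_s:
            return (start, start + window_s)
        start += search_step_s
    raise ValueError(
        f"no 60-s window after t={drug_onset_s} s has |drift| <= "
        f"{slope_tol_pA_per_s} pA/s: baseline never stabilized"
    )


def tonic_current(
    trace: Trace,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    trim_percent: float = 0.0,
) -> TonicResult:
    """Tonic current = post-drug mean minus pre-drug mean (1 min each).

    The sign convention follows the recording: blocking an inhibitory
    tonic conductance shifts the holding current positive, so a genuine
    tonic GABA current yields a positive value.  ``trim_percent``
    optionally applies a symmetric percentile-trimmed mean to both
    windows (to blunt phasic events riding on the holding current).
    """
    if trace.units != "pA":
        raise ValueError("tonic current requires a current (pA) trace")
    if pre_window[1] > post_window[0]:
        raise ValueError("pre and post windows must not overlap")
    pre = _window_samples(trace, pre_window)
    post = _window_samples(trace, post_window)
    if trim_percent > 0:
        frac = trim_percent / 100.0
        pre_mean = float(stats.trim_mean(pre, frac))
        post_mean = float(stats.trim_mean(post, frac))
    else:
        pre_mean = float(np.mean(pre))
        post_mean = float(np.mean(post))
    post_drift = robust_drift(post, trace.sampling_rate)
    return TonicResult(
        pre_mean_pA=pre_mean,
        post_mean_pA=post_mean,
        tonic_current_pA=post_mean - pre_mean,
        pre_window=tuple(pre_window),
        post_window=tuple(post_window),
        stability_flag=abs(post_drift) <= DEFAULT_SLOPE_TOL_PA_PER_S,
    )


def measure_tonic(
    trace: Trace,
    drug_onset_s: float,
    slope_tol_pA_per_s: float = DEFAULT_SLOPE_TOL_PA_PER_S,
    trim_percent: float = 0.0,
) -> TonicResult:
    """Convenience pipeline: last pre-drug minute vs earliest stable
    post-drug minute."""
    pre = (max(drug_onset_s - WINDOW_S, trace.start_time), drug_onset_s)
    if pre[1] - pre[0] < WINDOW_S:
        raise ValueError("need 60 s of pre-drug baseline")
    post = find_stable_post_window(trace, drug_onset_s, slope_tol_pA_per_s)
    return tonic_current(trace, pre, post, trim_percent=trim_percent)
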