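"""Evoked field-potential (fEPSP) slope and long-term potentiation analysis.

The workflow mirrors standard hippocampal slice LTP experiments: evoked
responses are elicited every 20 s (0.05 Hz), each sweep is reduced to the
slope of the linear rising phase of the fEPSP (fit between 10% and 70% of
the peak amplitude), slopes are normalized to the mean of the last 10 min
of baseline, averaged per minute, and summarized over post-induction
windows (conventionally 0-5 min for the immediate potentiation and
55-60 min for its persistence).  The induction protocol modelled here is
a sub-threshold theta-burst: ten bursts of four pulses at 100 Hz,
separated by 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SWEEP_INTERVAL_S = 20.0  # 0.05 Hz evoked stimulation


@dataclass
class Sweep:
    """A single evoked field-potential sweep.

    ``samples`` are in mV on a uniform time base; ``stim_time`` marks the
    stimulus within the sweep (seconds from the first sample), so a
    pre-stimulus segment is available for baseline-offset removal.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_time: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.stim_time < self.samples.size / self.sampling_rate:
            raise ValueError("stim_time must fall inside the sweep")


@dataclass
class SweepSeries:
    """Time-stamped fEPSP slopes around a plasticity-induction event.

    ``times`` are seconds relative to the induction (negative = baseline),
    spaced at the 20-s evoked-stimulation interval; ``labels`` tag each
    sweep ``"baseline"`` or ``"post"``.
    """

    times: np.ndarray
    slopes: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.labels = np.asarray(self.labels)
        if not (self.times.shape == self.slopes.shape == self.labels.shape):
            raise ValueError("times, slopes and labels must have equal length")
        dts = np.diff(self.times)
        if dts.size and not np.all(np.abs(dts - SWEEP_INTERVAL_S) <= 0.5):
            raise ValueError("inter-sweep interval must be 20 +/- 0.5 s")


@dataclass
class ThetaBurstProtocol:
    """Sub-threshold theta-burst stimulation parameters."""

    n_bursts: int = 10
    inter_burst_ms: float = 200.0
    pulses_per_burst: int = 4
    intra_burst_hz: float = 100.0

    @property
    def total_pulses(self) -> int:
        return self.n_bursts * self.pulses_per_burst


@dataclass
class PlasticityResult:
    """Baseline-normalized per-minute fEPSP trajectory.

    ``minutes`` holds the left edge of each 1-min bin relative to the
    induction (0 = first post-induction minute); ``values`` the mean
    normalized slope in each bin.  The mean of the last 10 baseline
    minutes is 1 by construction.
    """

    minutes: np.ndarray
    values: np.ndarray
    baseline_mean_raw: float
    n_sweeps_per_bin: np.ndarray = field(default=None)

    def window_mean(self, lo_min: float, hi_min: float) -> float:
        sel = (self.minutes >= lo_min) & (self.minutes < hi_min)
        if not np.any(sel):
            raise ValueError(f"window [{lo_min}, {hi_min}) min is outside the trajectory")
        return float(np.mean(self.values[sel]))


def fepsp_slope(
    sweep: Sweep,
    blank_ms: float = 1.0,
    search_window_ms: tuple[float, float] = (2.0, 20.0),
    noise_factor: float = 4.0,
) -> float:
    """Slope of the linear rising phase of a fEPSP, in mV/ms.

    The peak (most negative deflection) is located in a post-stimulus
    search window, after blanking the stimulus artifact.  Amplitude is
    measured from the post-artifact local baseline; a straight line is
    fit to the samples between the 10% and 70% amplitude crossings of a
    lightly smoothed copy of the sweep (3-sample moving average), and its
    slope is returned with its sign (negative for the standard
    negative-going fEPSP).

    Raises
    ------
    ValueError
        If no peak rises above ``noise_factor`` times the pre-stimulus
        noise (flagged invalid sweep).
    """
    fs = sweep.sampling_rate
    i_stim = int(round(sweep.stim_time * fs))
    pre = sweep.samples[:i_stim]
    if pre.size < 2:
        raise ValueError("sweep lacks a pre-stimulus segment")
    noise_sd = float(np.std(pre))

    i0 = i_stim + int(round(max(blank_ms, search_window_ms[0]) * 1e-3 * fs))
    i1 = i_stim + int(round(search_window_ms[1] * 1e-3 * fs))
    i1 = min(i1, sweep.samples.size)
    if i1 - i0 < 4:
        raise ValueError("post-stimulus search window too short")

    smooth = np.convolve(sweep.samples, np.ones(3) / 3.0, mode="same")
    seg = smooth[i0:i1]
    # local baseline just after the artifact blank
    base = float(seg[0])
    i_peak = int(np.argmin(seg))
    peak = float(seg[i_peak])
    amp = base - peak  # positive for a negative-going fEPSP
    if amp <= noise_factor * max(noise_sd, 1e-12):
        raise ValueError("no fEPSP peak detected above noise: invalid sweep")

    lo, hi = base - 0.10 * amp, base - 0.70 * amp
    # first crossing of 10% then of 70% on the way down to the peak
    j10 = j70 = None
    for j in range(0, i_peak + 1):
        if j10 is None and seg[j] <= lo:
            j10 = j
        if seg[j] <= hi:
            j70 = j
            break
    if j10 is None or j70 is None or j70 <= j10:
        raise ValueError("could not bracket the 10-70% rising phase")

    idx = np.arange(j10, j70 + 1)
    t_ms = idx / fs * 1e3
    coef = np.polyfit(t_ms, sweep.samples[i0:i1][idx], 1)
    return float(coef[0])


def normalize_series(series: SweepSeries, baseline_minutes: float = 10.0) -> PlasticityResult:
    """Normalize slopes to the late-baseline mean and average per minute.

    The normalizer is the mean slope over the last ``baseline_minutes``
    of baseline sweeps.  Normalized values are then binned into 1-min
    bins aligned to the induction time (sweeps at t in [60*m, 60*(m+1))
    s map to minute ``m``; baseline sweeps to negative minutes).
    """
    is_base = series.labels == "baseline"
    if not np.any(is_base):
        raise ValueError("series contains no baseline sweeps")
    t_base = series.times[is_base]
    cutoff = t_base.max() - (baseline_minutes * 60.0 - SWEEP_INTERVAL_S / 2)
    late_base = series.slopes[is_base & (series.times >= cutoff)]
    need = int(baseline_minutes * 60 / SWEEP_INTERVAL_S)
    if late_base.size < need:
        raise ValueError(
            f"insufficient baseline: need {need} sweeps covering the last "
            f"{baseline_minutes:g} min, found {late_base.size}"
        )
    norm = float(np.mean(late_base))
    if norm == 0:
        raise ValueError("baseline mean slope is zero")
    rel = series.slopes / norm

    minute = np.floor(series.times / 60.0).astype(int)
    uniq = np.unique(minute)
    values = np.array([rel[minute == m].mean() for m in uniq])
    counts = np.array([(minute == m).sum() for m in uniq])
    return PlasticityResult(
        minutes=uniq.astype(float),
        values=values,
        baseline_mean_raw=norm,
        n_sweeps_per_bin=counts,
    )


def window_summary(
    result: PlasticityResult,
    windows: list[tuple[float, float]] = ((0.0, 5.0), (55.0, 60.0)),
) -> dict[tuple[float, float], float]:
    """Mean normalized slope over each requested post-induction window (min)."""
    return {tuple(w): result.window_mean(*w) for w in windows}


def calibrate_stimulus(
    intensities: np.ndarray,
    responses: np.ndarray,
    target: tuple[float, float] = (0.30, 0.40),
    plateau_rtol: float = 0.05,
) -> float:
    """Stimulus intensity evoking 30-40% of the maximal (plateau) response.

    The input-output curve must be monotone increasing with a plateau
    (last two tested intensities within ``plateau_rtol`` of the maximum).
    Returns the smallest tested intensity whose response falls inside the
    target band; if none was sampled inside the band, the intensity at
    the band midpoint is linearly interpolated.
    """
    intensities = np.asarray(intensities, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if intensities.size < 3:
        raise ValueError("need at least 3 input-output samples")
    order = np.argsort(intensities)
    intensities, responses = intensities[order], responses[order]
    rmax = float(np.max(responses))
    if rmax <= 0:
        raise ValueError("non-positive responses: cannot calibrate")
    if np.any(np.abs(responses[-2:] - rmax) > plateau_rtol * rmax):
        raise ValueError("no plateau detected in the input-output curve")
    frac = responses / rmax
    inside = np.where((frac >= target[0]) & (frac <= target[1]))[0]
    if inside.size:
        return float(intensities[inside[0]])
    mid = 0.5 * (target[0] + target[1])
    return float(np.interp(mid, frac, intensities))


def theta_burst_times(protocol: ThetaBurstProtocol | None = None) -> np.ndarray:
    """Pulse times (s) of the theta-burst protocol; first pulse at t=0."""
    p = protocol or ThetaBurstProtocol()
    intra_s = 1.0 / p.intra_burst_hz
    burst_dur = (p.pulses_per_burst - 1) * intra_s
    starts = np.arange(p.n_bursts) * (burst_dur + p.inter_burst_ms * 1e-3)
    times = (starts[:, None] + np.arange(p.pulses_per_burst) * intra_s).ravel()
    return times
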