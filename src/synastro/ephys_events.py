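"""Template-fitting detection of spontaneous/miniature synaptic currents.

A waveform template (built from probe recordings, or directly from
known kinetics) is slid across a voltage-clamp trace; at every offset a
least-squares scale + offset fit is computed and a detection statistic
(fitted scale divided by its standard error) decides whether an event
is present.  Accepted candidates must also clear a minimum amplitude
floor (default 10 pA): events that fit the template but fall between
0 and 10 pA are discarded.  The module also provides per-event kinetics
(10-90% rise time, single-exponential decay tau), per-window event
statistics over the standard 1-min analysis window, resting membrane
potential with spike masking, and the access-resistance stability
criterion (<30% variation) used to gate recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .trace import Trace

DEFAULT_AMPLITUDE_FLOOR_PA = 10.0
DEFAULT_DETECTION_CRITERION = 3.0
DEFAULT_ANALYSIS_WINDOW_S = 60.0


@dataclass
class EventTemplate:
    """Normalized event waveform used by the sliding fit.

    ``waveform`` has peak magnitude 1 and carries the event polarity in
    its sign; ``onset_to_peak_s`` locates the peak within the template
    (also used as the refractory span when resolving overlaps).
    """

    waveform: np.ndarray
    sampling_rate: float
    polarity: int
    n_source_events: int

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        peak = np.max(np.abs(self.waveform))
        if not np.isclose(peak, 1.0, atol=1e-9):
            raise ValueError("template waveform must be normalized to unit peak")
        if self.polarity not in (-1, +1):
            raise ValueError("polarity must be -1 or +1")

    @property
    def duration_ms(self) -> float:
        return self.waveform.size / self.sampling_rate * 1e3

    @property
    def i_peak(self) -> int:
        return int(np.argmax(np.abs(self.waveform)))

    @property
    def onset_to_peak_s(self) -> float:
        return self.i_peak / self.sampling_rate

    @property
    def exclusion_s(self) -> float:
        """Dead time around an accepted detection: onset-to-peak plus the
        span over which the waveform decays to 1/e of its peak.  Within
        this window the detection statistic is dominated by the accepted
        event's own tail, so secondary maxima there are duplicates, not
        new events."""
        tail = np.abs(self.waveform[self.i_peak :])
        below = np.nonzero(tail <= np.exp(-1.0))[0]
        tau_samples = below[0] if below.size else tail.size
        return (self.i_peak + tau_samples) / self.sampling_rate

    @classmethod
    def from_kinetics(cls, kinetics, sampling_rate: float, pre_ms: float = 2.0):
        """Template from known biexponential kinetics (no probe data)."""
        kern = kinetics.kernel(sampling_rate)
        pre = np.zeros(int(round(pre_ms * 1e-3 * sampling_rate)))
        return cls(np.concatenate([pre, kern]), sampling_rate, kinetics.polarity, 0)


@dataclass
class DetectedEvent:
    onset_time: float
    peak_time: float
    amplitude: float  # signed, pA
    rise_time_10_90_ms: float
    decay_tau_ms: float
    fit_score: float

    def __post_init__(self) -> None:
        if self.peak_time < self.onset_time:
            raise ValueError("peak_time must not precede onset_time")


@dataclass
class EventStatistics:
    frequency_hz: float
    mean_amplitude_pA: float | None
    mean_rise_ms: float | None
    mean_decay_ms: float | None
    n_events: int
    window_s: float


@dataclass
class AccessResistanceQC:
    passed: bool
    max_relative_variation: float


# ---------------------------------------------------------------------------
# template construction


def _extract_segments(trace: Trace, peaks: np.ndarray, pre_ms: float, post_ms: float):
    fs = trace.sampling_rate
    npre = int(round(pre_ms * 1e-3 * fs))
    npost = int(round(post_ms * 1e-3 * fs))
    segs = []
    for p in peaks:
        if p - npre < 0 or p + npost > trace.samples.size:
            continue
        seg = trace.samples[p - npre : p + npost].astype(float)
        seg = seg - np.mean(seg[: max(npre // 2, 1)])  # local baseline
        segs.append(seg)
    return segs


def _coarse_candidates(trace: Trace, polarity: int, k_sigma: float, min_sep_s: float):
    y = polarity * trace.samples
    base = np.median(y)
    dev = y - base
    mad = np.median(np.abs(dev - np.median(dev)))
    sigma = 1.4826 * mad if mad > 0 else max(np.std(dev), 1e-12)
    peaks, props = signal.find_peaks(
        dev,
        height=k_sigma * sigma,
        distance=max(int(min_sep_s * trace.sampling_rate), 1),
    )
    order = np.argsort(props["peak_heights"])[::-1]
    return peaks[order]


def build_template(
    probe_traces: list[Trace],
    target_n_events: int = 15,
    polarity: int = -1,
    pre_ms: float = 8.0,
    post_ms: float = 40.0,
    coarse_k_sigma: float = 4.0,
) -> EventTemplate:
    """Build and refine an event template from probe recordings.

    A coarse threshold pass (robust sigma of the polarity-corrected
    signal) collects candidate events across all probe traces; the
    ``target_n_events`` largest (10-20 required) are peak-aligned,
    locally baseline-subtracted, and averaged.  One refinement pass then
    re-detects events with this first-pass template and re-averages.

    Raises
    ------
    ValueError
        If fewer than 10 candidate events are found, naming the
        shortfall.
    """
    if not 10 <= target_n_events <= 20:
        raise ValueError("target_n_events must lie in 10..20")
    if not probe_traces:
        raise ValueError("at least one probe trace is required")
    fs = probe_traces[0].sampling_rate
    min_sep = (pre_ms + post_ms) * 1e-3

    all_segs = []
    for tr in probe_traces:
        if tr.sampling_rate != fs:
            raise ValueError("probe traces must share one sampling rate")
        peaks = _coarse_candidates(tr, polarity, coarse_k_sigma, min_sep)
        all_segs.extend(_extract_segments(tr, peaks, pre_ms, post_ms))
    if len(all_segs) < 10:
        raise ValueError(
            f"only {len(all_segs)} candidate events found across probe traces; "
            f"at least 10 are required to build a template"
        )
    all_segs.sort(key=lambda s: -np.max(np.abs(s)))
    segs = all_segs[:target_n_events]
    avg = np.mean(segs, axis=0)
    wave = avg / np.max(np.abs(avg))
    first = EventTemplate(wave, fs, polarity, len(segs))

    # refinement: one re-detection pass with the first-pass template;
    # the floor at half the median first-pass amplitude keeps tiny
    # tail-remnant fits out of the average
    floor = 0.5 * float(np.median([np.max(np.abs(s)) for s in segs]))
    refined_segs = []
    for tr in probe_traces:
        evs = detect_events(
            tr, first, amplitude_threshold_pA=floor,
            analysis_window_s=tr.duration, _validate_window=False,
        )
        # align on the fitted onset (criterion peak), which is far less
        # noise-sensitive than the raw per-event sample maximum
        peaks = np.array(
            [int(round(e.onset_time * fs)) + first.i_peak
             for e in sorted(evs, key=lambda e: -abs(e.amplitude))]
        )
        refined_segs.extend(_extract_segments(tr, peaks, pre_ms, post_ms))
    if len(refined_segs) >= 10:
        refined_segs.sort(key=lambda s: -np.max(np.abs(s)))
        avg = np.mean(refined_segs[:target_n_events], axis=0)
        wave = avg / np.max(np.abs(avg))
        return EventTemplate(wave, fs, polarity, min(len(refined_segs), target_n_events))
    return first


# ---------------------------------------------------------------------------
# sliding least-squares detection


def _sliding_fit(y: np.ndarray, w: np.ndarray):
    """Per-offset least-squares scale/offset fit of template ``w``.

    Returns (scale, offset, criterion) arrays of length N-L+1 where the
    criterion is scale / SE(scale).
    """
    L = w.size
    N = y.size
    if N < L:
        raise ValueError("trace shorter than template")
    Sw = w.sum()
    Sww = float(w @ w)
    ones = np.ones(L)
    Sy = signal.fftconvolve(y, ones[::-1], mode="valid")
    Syy = signal.fftconvolve(y * y, ones[::-1], mode="valid")
    Swy = signal.fftconvolve(y, w[::-1], mode="valid")
    denom = Sww - Sw * Sw / L
    scale = (Swy - Sw * Sy / L) / denom
    offset = (Sy - scale * Sw) / L
    sse = np.maximum(Syy - offset * Sy - scale * Swy, 0.0)
    sd = np.sqrt(sse / max(L - 2, 1))
    se = np.maximum(sd / np.sqrt(denom), 1e-12)
    return scale, offset, scale / se


def _rise_time_ms(seg: np.ndarray, i_peak: int, fs: float) -> float:
    """10-90% rise time of a positive-going, baseline-subtracted event."""
    peak = seg[i_peak]
    if peak <= 0 or i_peak == 0:
        return float("nan")

    def crossing(level):
        # last upward crossing before the peak: robust to noise blips in
        # the pre-event baseline
        below = np.nonzero(seg[: i_peak + 1] < level)[0]
        if below.size == 0 or below[-1] == i_peak:
            return 0.0
        j = below[-1]
        f = (level - seg[j]) / (seg[j + 1] - seg[j])
        return (j + f) / fs
    t10 = crossing(0.10 * peak)
    t90 = crossing(0.90 * peak)
    return max(t90 - t10, 0.0) * 1e3


def _decay_tau_ms(seg: np.ndarray, i_peak: int, fs: float) -> float:
    """Single-exponential decay tau (log-linear fit, 90% to 10% of peak).

    The fit starts at the 90% crossing after the peak rather than the
    peak itself: immediately after the peak the residual rise component
    of a biexponential event still flattens the waveform and would bias
    the fitted tau upward.
    """
    peak = seg[i_peak]
    tail = seg[i_peak:]
    below = np.nonzero(tail <= 0.10 * peak)[0]
    stop = below[0] if below.size else tail.size
    start_idx = np.nonzero(tail[:stop] <= 0.90 * peak)[0]
    start = start_idx[0] if start_idx.size else 0
    tail = tail[start:stop]
    good = tail > 0
    if good.sum() < 3:
        return float("nan")
    t = np.arange(tail.size)[good] / fs * 1e3
    coef = np.polyfit(t, np.log(tail[good]), 1)
    if coef[0] >= 0:
        return float("nan")
    return float(-1.0 / coef[0])


def detect_events(
    trace: Trace,
    template: EventTemplate,
    amplitude_threshold_pA: float = DEFAULT_AMPLITUDE_FLOOR_PA,
    analysis_window_s: float = DEFAULT_ANALYSIS_WINDOW_S,
    detection_criterion: float = DEFAULT_DETECTION_CRITERION,
    return_audit: bool = False,
    _validate_window: bool = True,
):
    """Detect synaptic events by sliding scaled-template fitting.

    At every offset the template is fit by least squares (scale +
    baseline offset); local maxima of the detection statistic
    (scale / SE(scale)) above ``detection_criterion`` become candidates.
    Candidates whose fitted amplitude magnitude falls below
    ``amplitude_threshold_pA`` are rejected (the 0-10 pA band is
    discarded under the default floor).  Overlapping candidates closer
    than the template's exclusion span (onset-to-peak plus one decay
    constant) are resolved greedily by keeping the better fit score.
    Detections are returned sorted by onset time;
    with ``return_audit=True`` a DataFrame of every candidate and its
    accept/reject outcome is returned alongside.
    """
    if trace.units != "pA":
        raise ValueError(f"event detection requires a current (pA) trace, got {trace.units}")
    if _validate_window and analysis_window_s > trace.duration + 1e-9:
        raise ValueError(
            f"analysis window {analysis_window_s} s exceeds trace duration {trace.duration} s"
        )
    fs = trace.sampling_rate
    n_window = min(int(round(analysis_window_s * fs)), trace.samples.size)
    y = trace.samples[:n_window]
    w = template.waveform
    scale, offset, crit = _sliding_fit(y, w)

    # polarity-positive scale means the candidate matches the template shape
    masked = np.where(scale > 0, crit, 0.0)
    raw_cand, _ = signal.find_peaks(masked, height=detection_criterion)
    # greedy overlap resolution: best fit score wins its exclusion zone
    exclusion = max(int(round(template.exclusion_s * fs)), 1)
    cand = []
    taken = np.zeros(masked.size, dtype=bool)
    for idx in sorted(raw_cand, key=lambda i: -masked[i]):
        if taken[idx]:
            continue
        cand.append(idx)
        lo = max(idx - exclusion, 0)
        taken[lo : idx + exclusion + 1] = True
    cand.sort()

    events = []
    audit = []
    for idx in cand:
        amp_mag = scale[idx]
        amplitude = template.polarity * amp_mag
        accepted = amp_mag >= amplitude_threshold_pA
        record = {
            "onset_time": idx / fs,
            "amplitude_pA": amplitude,
            "fit_score": crit[idx],
            "accepted": bool(accepted),
            "reason": "ok" if accepted else "below_amplitude_floor",
        }
        audit.append(record)
        if not accepted:
            continue
        seg = template.polarity * (y[idx : idx + w.size] - offset[idx])
        i_peak = int(np.argmax(seg))
        events.append(
            DetectedEvent(
                onset_time=idx / fs,
                peak_time=(idx + i_peak) / fs,
                amplitude=amplitude,
                rise_time_10_90_ms=_rise_time_ms(seg, i_peak, fs),
                decay_tau_ms=_decay_tau_ms(seg, i_peak, fs),
                fit_score=float(crit[idx]),
            )
        )
    events.sort(key=lambda e: e.onset_time)
    if return_audit:
        return events, pd.DataFrame(audit)
    return events


def events_to_frame(events: list[DetectedEvent]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in events])


# ---------------------------------------------------------------------------
# summaries and QC


def event_statistics(
    events: list[DetectedEvent],
    analysis_window_s: float = DEFAULT_ANALYSIS_WINDOW_S,
) -> EventStatistics:
    """Frequency and mean amplitude/kinetics over the analysis window.

    An empty event list yields frequency 0 with the means reported as
    absent (None), never as zero.
    """
    if any(e.onset_time > analysis_window_s for e in events):
        raise ValueError("events must lie inside the analysis window")
    n = len(events)
    if n == 0:
        return EventStatistics(0.0, None, None, None, 0, analysis_window_s)
    amps = np.array([e.amplitude for e in events])
    rises = np.array([e.rise_time_10_90_ms for e in events])
    decays = np.array([e.decay_tau_ms for e in events])
    return EventStatistics(
        frequency_hz=n / analysis_window_s,
        mean_amplitude_pA=float(np.mean(amps)),
        mean_rise_ms=float(np.nanmean(rises)) if np.any(np.isfinite(rises)) else None,
        mean_decay_ms=float(np.nanmean(decays)) if np.any(np.isfinite(decays)) else None,
        n_events=n,
        window_s=analysis_window_s,
    )


def resting_membrane_potential(
    trace: Trace,
    window_s: float | None = None,
    spike_excursion_mv: float = 20.0,
) -> float:
    """Mean membrane potential with action-potential excursions masked.

    Samples more than ``spike_excursion_mv`` above the window median
    (spikes) are excluded before averaging.
    """
    if trace.units != "mV":
        raise ValueError(f"resting potential requires a voltage (mV) trace, got {trace.units}")
    y = trace.samples if window_s is None else trace.slice_time(0.0, window_s)
    med = np.median(y)
    keep = y <= med + spike_excursion_mv
    return float(np.mean(y[keep]))


def access_resistance_qc(ra_series_mohm) -> AccessResistanceQC:
    """Stability gate on the series (access) resistance.

    Variation is (max - min) / first value; the recording passes when
    it stays below 30%.
    """
    ra = np.asarray(ra_series_mohm, dtype=float)
    if ra.size < 2:
        raise ValueError("need at least 2 access-resistance measurements")
    if np.any(ra <= 0):
        raise ValueError("access resistance must be positive")
    variation = float((ra.max() - ra.min()) / ra[0])
    return AccessResistanceQC(passed=variation < 0.30, max_relative_variation=variation)
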