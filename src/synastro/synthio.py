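"""Seeded synthetic-data generators with exact ground truth.

Every input modality the analysis pipeline consumes can be generated
here with a known, machine-readable truth record:

* voltage-clamp traces carrying Poisson-timed biexponential synaptic
  events on a noisy holding current (:func:`gen_event_trace`);
* tonic-current recordings with a drug-induced exponential baseline
  shift (:func:`gen_tonic_trace`);
* evoked fEPSP slope series with baseline and decaying/sustained
  potentiation (:func:`gen_fepsp_series`);
* multi-channel astrocyte phantom z-stacks - GFAP tubes along known
  skeletons, DAPI nuclear blobs, Cx43 puncta at inter-cell contacts
  (:func:`gen_astro_stack`);
* two-group behavioral tables with direction-coded emotionality
  effects (:func:`gen_behavior_table`).

All generators are deterministic for a fixed seed, and the returned
:class:`TruthRecord` carries exactly the quantities used to build the
data, so that analysis operations can be validated against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .behavior import ParameterSpec, default_battery, DISTANCE_PARAMETER
from .fepsp import SweepSeries
from .morph import AstroStack, SHOLL_RADII_UM
from .trace import Trace

DEFAULT_SAMPLING_HZ = 10_000.0


# ---------------------------------------------------------------------------
# kernels and truth


@dataclass(frozen=True)
class EventKinetics:
    """Biexponential synaptic-event kinetics.

    The kernel is a difference of exponentials,
    ``k(t) = exp(-t/decay_tau) - exp(-t/rise_tau)``, normalized so its
    peak magnitude is 1 before amplitude scaling; ``polarity`` is -1 for
    inward (downward) currents.  Defaults are a plausible CA1 EPSC
    scale: 1.5 ms rise, 8 ms decay.
    """

    rise_tau_ms: float = 1.5
    decay_tau_ms: float = 8.0
    polarity: int = -1

    def __post_init__(self) -> None:
        if not self.rise_tau_ms > 0:
            raise ValueError("rise_tau_ms must be positive")
        if not self.decay_tau_ms > self.rise_tau_ms:
            raise ValueError("decay_tau_ms must exceed rise_tau_ms")
        if self.polarity not in (-1, +1):
            raise ValueError("polarity must be -1 or +1")

    def kernel(self, sampling_rate: float, duration_ms: float | None = None) -> np.ndarray:
        """Unit-peak biexponential kernel sampled at ``sampling_rate``."""
        if duration_ms is None:
            duration_ms = 8.0 * self.decay_tau_ms
        t = np.arange(0.0, duration_ms * 1e-3, 1.0 / sampling_rate) * 1e3  # ms
        k = np.exp(-t / self.decay_tau_ms) - np.exp(-t / self.rise_tau_ms)
        return self.polarity * k / np.max(np.abs(k))


@dataclass
class TruthRecord:
    """Exact ground truth attached to a generated dataset."""

    event_times_s: np.ndarray | None = None
    event_amplitudes_pA: np.ndarray | None = None  # signed
    kinetics: EventKinetics | None = None
    tonic_shift_pA: float | None = None
    drug_onset_s: float | None = None
    potentiation_factors: np.ndarray | None = None
    cells: list[dict] | None = None
    group_effects: dict | None = None
    seed: int | None = None

    def to_json(self, path) -> None:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, EventKinetics):
                return vars(v) | {
                    "rise_tau_ms": v.rise_tau_ms,
                    "decay_tau_ms": v.decay_tau_ms,
                    "polarity": v.polarity,
                }
            return v

        payload = {}
        for k, v in vars(self).items():
            if v is None:
                continue
            if k == "cells":
                payload[k] = [
                    {kk: conv(vv) for kk, vv in c.items() if kk != "mask"} for c in v
                ]
            else:
                payload[k] = conv(v)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# electrophysiology generators


def gen_event_trace(
    duration_s: float,
    rate_hz: float,
    amp_mean_pA: float,
    amp_sd_pA: float,
    kinetics: EventKinetics | None = None,
    noise_sd_pA: float = 2.0,
    holding_pA: float = -100.0,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_HZ,
) -> tuple[Trace, TruthRecord]:
    """Voltage-clamp trace with Poisson-timed biexponential events.

    Event count ~ Poisson(rate * duration); onsets uniform over the
    recording; amplitude magnitudes ~ Normal(amp_mean, amp_sd), floored
    at 0.5 pA, signed by the kernel polarity.  White Gaussian noise of
    ``noise_sd_pA`` rides on the constant holding current.  The truth
    lists every generated event, including sub-threshold ones.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    if rate_hz < 0:
        raise ValueError("rate_hz must be non-negative")
    if amp_sd_pA < 0 or noise_sd_pA < 0:
        raise ValueError("standard deviations must be non-negative")
    kin = kinetics or EventKinetics()
    rng = np.random.default_rng(seed)

    n_samples = int(round(duration_s * sampling_rate))
    samples = holding_pA + (
        rng.normal(0.0, noise_sd_pA, n_samples) if noise_sd_pA > 0 else 0.0
    )
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 0:
        samples = np.full(n_samples, holding_pA)

    n_events = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, n_events))
    mags = np.maximum(rng.normal(amp_mean_pA, amp_sd_pA, n_events), 0.5)
    kernel = kin.kernel(sampling_rate)
    for t0, mag in zip(onsets, mags):
        i = int(round(t0 * sampling_rate))
        seg = kernel[: n_samples - i]
        samples[i : i + seg.size] += mag * seg

    trace = Trace(samples, sampling_rate, "pA")
    truth = TruthRecord(
        event_times_s=onsets,
        event_amplitudes_pA=kin.polarity * mags,
        kinetics=kin,
        seed=seed,
    )
    return trace, truth


def gen_tonic_trace(
    duration_s: float,
    baseline_pA: float,
    shift_pA: float,
    drug_onset_s: float,
    settle_tau_s: float = 20.0,
    noise_sd_pA: float = 5.0,
    seed: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_HZ,
) -> tuple[Trace, TruthRecord]:
    """Holding-current trace with an exponential drug-induced shift.

    The holding level moves from ``baseline_pA`` toward
    ``baseline_pA + shift_pA`` after ``drug_onset_s`` with time constant
    ``settle_tau_s`` (first-order wash-in), plus white noise.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    if not 0 < drug_onset_s < duration_s:
        raise ValueError("drug_onset_s must fall inside the recording")
    if not settle_tau_s > 0:
        raise ValueError("settle_tau_s must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    level = np.full(n, baseline_pA, dtype=float)
    post = t >= drug_onset_s
    level[post] += shift_pA * (1.0 - np.exp(-(t[post] - drug_onset_s) / settle_tau_s))
    if noise_sd_pA > 0:
        level = level + rng.normal(0.0, noise_sd_pA, n)
    trace = Trace(level, sampling_rate, "pA")
    truth = TruthRecord(tonic_shift_pA=shift_pA, drug_onset_s=drug_onset_s, seed=seed)
    return trace, truth


def gen_fepsp_series(
    n_baseline_sweeps: int,
    n_post_sweeps: int,
    baseline_slope: float = -0.15,
    early_factor: float = 1.5,
    late_factor: float = 1.2,
    decay_tau_min: float = 15.0,
    noise_cv: float = 0.0,
    sweep_interval_s: float = 20.0,
    early_hold_min: float = 5.0,
    settle_by_min: float = 55.0,
    seed: int = 0,
) -> tuple[SweepSeries, TruthRecord]:
    """Evoked fEPSP slope series around a plasticity induction at t=0.

    Baseline sweeps (factor 1) precede the induction at the 20-s evoked
    interval; post-induction sweeps follow a potentiation profile that
    holds ``early_factor`` through the immediate window
    (first ``early_hold_min`` minutes), then relaxes toward
    ``late_factor`` with time constant ``decay_tau_min``, completing the
    transition by ``settle_by_min`` so the late measurement window
    samples the sustained level.  Multiplicative Gaussian noise with
    coefficient of variation ``noise_cv`` models sweep-to-sweep slope
    variability.
    """
    if n_baseline_sweeps < 1 or n_post_sweeps < 1:
        raise ValueError("need at least one baseline and one post sweep")
    if early_factor <= 0 or late_factor <= 0:
        raise ValueError("potentiation factors must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)

    t_base = (np.arange(n_baseline_sweeps) - n_baseline_sweeps) * sweep_interval_s
    t_post = np.arange(n_post_sweeps) * sweep_interval_s
    t_post_min = t_post / 60.0

    def profile(tm: np.ndarray) -> np.ndarray:
        out = np.full(tm.shape, late_factor)
        hold = tm < early_hold_min
        out[hold] = early_factor
        mid = (~hold) & (tm < settle_by_min)
        frac = (1.0 - np.exp(-(tm[mid] - early_hold_min) / decay_tau_min)) / (
            1.0 - np.exp(-(settle_by_min - early_hold_min) / decay_tau_min)
        )
        out[mid] = early_factor + (late_factor - early_factor) * frac
        return out

    factors = np.concatenate([np.ones(n_baseline_sweeps), profile(t_post_min)])
    slopes = baseline_slope * factors
    if noise_cv > 0:
        slopes = slopes * (1.0 + rng.normal(0.0, noise_cv, slopes.size))
    series = SweepSeries(
        times=np.concatenate([t_base, t_post]),
        slopes=slopes,
        labels=np.array(["baseline"] * n_baseline_sweeps + ["post"] * n_post_sweeps),
    )
    truth = TruthRecord(potentiation_factors=factors, seed=seed)
    return series, truth


# ---------------------------------------------------------------------------
# astrocyte phantoms


@dataclass
class CellSpec:
    """Phantom astrocyte: a soma and polyline processes in absolute um.

    Each process is an (n, 3) array of (z, y, x) points starting at the
    soma center; processes sharing a trunk (e.g. a Y-bifurcation) may
    repeat the shared points - duplicated skeleton edges are counted
    once in the truth Sholl profile.
    """

    soma_center_um: tuple[float, float, float]
    processes: list[np.ndarray] = field(default_factory=list)
    soma_radius_um: float = 3.0
    process_radius_um: float = 0.5


def skeleton_edges(cell: CellSpec) -> np.ndarray:
    """Unique skeleton edges of a cell spec, shape (n_edges, 2, 3) in um."""
    seen = set()
    edges = []
    for poly in cell.processes:
        poly = np.asarray(poly, dtype=float)
        for a, b in zip(poly[:-1], poly[1:]):
            key = (tuple(np.round(a, 6)), tuple(np.round(b, 6)))
            if key in seen or (key[1], key[0]) in seen:
                continue
            seen.add(key)
            edges.append((a, b))
    return np.asarray(edges) if edges else np.zeros((0, 2, 3))


def skeleton_sholl(
    edges: np.ndarray,
    center_um: tuple[float, float, float],
    radii_um: np.ndarray = SHOLL_RADII_UM,
) -> np.ndarray:
    """Analytic Sholl counts: sphere crossings of the skeleton edges.

    For each radius the count is the number of intersection points of
    the edge set with the sphere of that radius centered on the nucleus
    centroid - the continuous analog of counting branch crossings.
    """
    c = np.asarray(center_um, dtype=float)
    counts = np.zeros(len(radii_um), dtype=int)
    for p0, p1 in edges:
        d = p1 - p0
        f = p0 - c
        a = float(d @ d)
        if a == 0:
            continue
        b = 2.0 * float(f @ d)
        c0 = float(f @ f)
        for i, r in enumerate(radii_um):
            disc = b * b - 4 * a * (c0 - r * r)
            if disc <= 0:
                continue
            sq = np.sqrt(disc)
            for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 0.0 <= t <= 1.0:
                    counts[i] += 1
    return counts


def _add_capsule(vol, voxel, p0, p1, radius, amp=1.0):
    """Render a soft-edged cylinder (capsule) between two um points."""
    voxel = np.asarray(voxel)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    pad = radius + 2 * voxel.max()
    lo = np.maximum(np.floor((np.minimum(p0, p1) - pad) / voxel).astype(int), 0)
    hi = np.minimum(
        np.ceil((np.maximum(p0, p1) + pad) / voxel).astype(int) + 1, vol.shape
    )
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(l, h) * v for l, h, v in zip(lo, hi, voxel)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    h = voxel.min()
    intensity = amp * np.clip((radius - dist) / h + 0.5, 0.0, 1.0)
    region = tuple(slice(l, hh) for l, hh in zip(lo, hi))
    np.maximum(vol[region], intensity, out=vol[region])


def gen_astro_stack(
    shape_zyx: tuple[int, int, int],
    cells: list[CellSpec],
    voxel_um_zyx: tuple[float, float, float] = (0.25, 0.25, 0.25),
    puncta_density_per_um3: float = 0.002,
    contact_puncta: int = 200,
    noise_sd: float = 0.0,
    gfap_amp: float = 100.0,
    seed: int = 0,
) -> tuple[AstroStack, TruthRecord]:
    """Render phantom astrocytes into a multi-channel z-stack.

    GFAP = soft-edged tubes along each skeleton polyline plus a soma
    sphere; DAPI = Gaussian nuclear blob per soma; Cx43 = puncta
    scattered uniformly plus concentrations at inter-cell contact zones
    (where two cells' rendered masks touch).  The truth carries each
    cell's skeleton edges, analytic Sholl counts, rendered mask, and a
    border-touching flag.  Overlapping somata raise a warning, not an
    error (the downstream splitter is expected to separate them).
    """
    import warnings as _warnings

    voxel = np.asarray(voxel_um_zyx, dtype=float)
    if np.any(voxel <= 0):
        raise ValueError("voxel sizes must be positive")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape_zyx)

    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            dd = np.linalg.norm(
                np.asarray(a.soma_center_um) - np.asarray(b.soma_center_um)
            )
            if dd < a.soma_radius_um + b.soma_radius_um:
                _warnings.warn("overlapping somata in phantom (syncytium)")

    gfap = np.zeros(shape, dtype=float)
    dapi = np.zeros(shape, dtype=float)
    cx43 = np.zeros(shape, dtype=float)
    cell_masks = []
    truth_cells = []
    for cell in cells:
        cv = np.zeros(shape, dtype=float)
        _add_capsule(cv, voxel, cell.soma_center_um, cell.soma_center_um,
                     cell.soma_radius_um, amp=1.0)
        for poly in cell.processes:
            poly = np.asarray(poly, dtype=float)
            for a, b in zip(poly[:-1], poly[1:]):
                _add_capsule(cv, voxel, a, b, cell.process_radius_um, amp=1.0)
        mask = cv >= 0.5
        cell_masks.append(mask)
        np.maximum(gfap, gfap_amp * cv, out=gfap)

        # DAPI nuclear blob
        c_idx = np.asarray(cell.soma_center_um) / voxel
        sigma_vox = (0.6 * cell.soma_radius_um) / voxel
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r2 = (
            ((zz - c_idx[0]) / sigma_vox[0]) ** 2
            + ((yy - c_idx[1]) / sigma_vox[1]) ** 2
            + ((xx - c_idx[2]) / sigma_vox[2]) ** 2
        )
        dapi += gfap_amp * np.exp(-0.5 * r2)

        border = (
            np.any(mask[0]) or np.any(mask[-1])
            or np.any(mask[:, 0]) or np.any(mask[:, -1])
            or np.any(mask[:, :, 0]) or np.any(mask[:, :, -1])
        )
        edges = skeleton_edges(cell)
        truth_cells.append(
            {
                "soma_center_um": tuple(cell.soma_center_um),
                "skeleton_edges_um": edges,
                "sholl_truth": skeleton_sholl(edges, cell.soma_center_um),
                "border_touching": bool(border),
                "mask": mask,
            }
        )

    # Cx43 puncta: background + contact-zone concentration
    n_bg = rng.poisson(puncta_density_per_um3 * np.prod(np.array(shape) * voxel))
    bg_idx = tuple(rng.integers(0, s, n_bg) for s in shape)
    cx43[bg_idx] += 1.0
    from scipy import ndimage as _ndi

    for i in range(len(cell_masks)):
        for j in range(i + 1, len(cell_masks)):
            da = _ndi.binary_dilation(cell_masks[i], iterations=2)
            db = _ndi.binary_dilation(cell_masks[j], iterations=2)
            contact = np.argwhere(da & db)
            if contact.size == 0:
                continue
            pick = contact[rng.integers(0, contact.shape[0], contact_puncta)]
            for p in pick:
                cx43[tuple(p)] += 1.0
    cx43 = _ndi.gaussian_filter(cx43, sigma=0.3 / voxel) * gfap_amp

    if noise_sd > 0:
        gfap = gfap + rng.normal(0.0, noise_sd, shape)
        dapi = dapi + rng.normal(0.0, noise_sd, shape)
        cx43 = cx43 + rng.normal(0.0, noise_sd, shape)

    stack = AstroStack(
        {"gfap": gfap, "dapi": dapi, "cx43": cx43}, tuple(voxel)
    )
    truth = TruthRecord(cells=truth_cells, seed=seed)
    return stack, truth


# ---------------------------------------------------------------------------
# behavior


@dataclass(frozen=True)
class GenParameterSpec:
    """A behavioral parameter plus the control-population moments used
    to simulate it."""

    spec: ParameterSpec
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"{self.spec.parameter_name}: sigma must be positive")


def default_generation_battery() -> list[GenParameterSpec]:
    """Control-population moments for the shipped emotionality battery.

    Magnitudes are plausible for 6-month-old male mice on this battery
    (entries/times in the open field and plus maze, forced-swim
    immobility, grooming, sucrose preference).  Values are generated on
    the final scoring scale, so the generated specs carry no
    distance-normalization flag; the distance-normalization path is
    exercised separately with explicit distances.
    """
    mus = {
        ("open_field", "center_entries"): (30.0, 8.0),
        ("open_field", "center_time_s"): (80.0, 18.0),
        ("elevated_plus_maze", "open_arm_entries"): (6.0, 2.0),
        ("elevated_plus_maze", "open_arm_time_s"): (38.0, 14.0),
        ("forced_swim", "latency_immobility_s"): (52.0, 12.0),
        ("forced_swim", "immobility_time_s"): (48.0, 25.0),
        ("splash", "latency_grooming_s"): (33.0, 10.0),
        ("splash", "grooming_time_s"): (146.0, 30.0),
        ("sucrose_preference", "preference_pct"): (75.0, 8.0),
    }
    out = []
    for s in default_battery():
        mu, sd = mus[(s.test_name, s.parameter_name)]
        out.append(GenParameterSpec(replace(s, normalize_by_distance=False), mu, sd))
    return out


def gen_behavior_table(
    n_per_group: int,
    parameter_specs: list[GenParameterSpec] | None = None,
    group_offsets_sd_units: float | dict = 0.0,
    group_names: tuple[str, str] = ("control", "case"),
    distance_mu_cm: float = 5000.0,
    distance_sd_cm: float = 500.0,
    seed: int = 0,
):
    """Two-group tidy behavioral table with direction-coded effects.

    Control values ~ Normal(mu, sigma) per parameter; case values are
    shifted along the parameter's emotionality direction by
    ``group_offsets_sd_units`` standard deviations (scalar, or a dict
    keyed by ``(test, parameter)``).  Every animal also receives a
    ``travelled_distance`` row (no group effect) so the
    distance-normalization path can run.  Returns a DataFrame with
    columns animal_id, group, test, parameter, value.
    """
    import pandas as pd

    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    specs = parameter_specs if parameter_specs is not None else default_generation_battery()
    rng = np.random.default_rng(seed)

    def offset_for(key):
        if isinstance(group_offsets_sd_units, dict):
            return float(group_offsets_sd_units.get(key, 0.0))
        return float(group_offsets_sd_units)

    rows = []
    effects = {}
    for g, group in enumerate(group_names):
        for k in range(n_per_group):
            animal = f"{group}_{k:03d}"
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "test": "open_field",
                    "parameter": DISTANCE_PARAMETER,
                    "value": rng.normal(distance_mu_cm, distance_sd_cm),
                }
            )
            for gp in specs:
                key = (gp.spec.test_name, gp.spec.parameter_name)
                off = offset_for(key) if g == 1 else 0.0
                mu = gp.mu + gp.spec.direction * off * gp.sigma
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "test": gp.spec.test_name,
                        "parameter": gp.spec.parameter_name,
                        "value": rng.normal(mu, gp.sigma),
                    }
                )
                if g == 1:
                    effects[f"{key[0]}/{key[1]}"] = off
    table = pd.DataFrame(rows)
    table.attrs["truth"] = TruthRecord(group_effects=effects, seed=seed)
    return table
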