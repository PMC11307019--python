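"""Two-level emotionality z-score for rodent behavioral batteries.

Each behavioral parameter is z-normalized against the control group,
z = direction * (X - mu_control) / sd_control, with the direction code
chosen so that a larger score always means more emotionality (more
anxiety-/depression-like behavior).  Parameter z-scores are averaged
within each test into a test score, and test scores are averaged into a
per-animal emotionality z-score, so tests contribute equally regardless
of how many parameters they carry.  Locomotion-confounded parameters
(open-field and elevated-plus-maze counts/times) may be normalized by
the animal's travelled distance before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

DISTANCE_PARAMETER = "travelled_distance"


@dataclass(frozen=True)
class ParameterSpec:
    """Scoring rule for one behavioral parameter.

    ``direction`` is +1 when a higher raw value means more emotionality
    (e.g. immobility time) and -1 when a lower value does (e.g. open-arm
    entries).  ``normalize_by_distance`` divides the raw value by the
    animal's travelled distance before z-scoring.
    """

    test_name: str
    parameter_name: str
    direction: int
    normalize_by_distance: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(
                f"direction for {self.test_name}/{self.parameter_name} must be "
                f"+1 or -1, got {self.direction}"
            )


def default_battery() -> list[ParameterSpec]:
    """Shipped emotionality battery (open field, elevated plus maze,
    forced swim, splash, sucrose preference).

    This is a documented reconstruction of a typical battery for these
    five tests: the direction codes follow the standard interpretation
    of each readout, and the locomotion-confounded open-field and
    plus-maze parameters carry the distance-normalization flag.  Edit or
    replace it to match a given study design.
    """
    return [
        ParameterSpec("open_field", "center_entries", -1, normalize_by_distance=True),
        ParameterSpec("open_field", "center_time_s", -1, normalize_by_distance=True),
        ParameterSpec("elevated_plus_maze", "open_arm_entries", -1, normalize_by_distance=True),
        ParameterSpec("elevated_plus_maze", "open_arm_time_s", -1, normalize_by_distance=True),
        ParameterSpec("forced_swim", "latency_immobility_s", -1),
        ParameterSpec("forced_swim", "immobility_time_s", +1),
        ParameterSpec("splash", "latency_grooming_s", +1),
        ParameterSpec("splash", "grooming_time_s", -1),
        ParameterSpec("sucrose_preference", "preference_pct", -1),
    ]


@dataclass
class EmotionalityScores:
    """Parameter-, test-, and individual-level z-scores.

    ``param_z`` and ``test_z`` are tidy DataFrames; ``emotionality``
    maps animal_id to its final score; ``control_stats`` records the
    control mean/SD used per parameter for audit.
    """

    param_z: pd.DataFrame
    test_z: pd.DataFrame
    emotionality: pd.Series
    control_stats: pd.DataFrame
    group_of: pd.Series = field(default=None)

    def group_mean(self, group: str) -> float:
        ids = self.group_of[self.group_of == group].index
        return float(self.emotionality.loc[self.emotionality.index.isin(ids)].mean())


def param_z(values, control_values, direction: int, parameter: str = "") -> np.ndarray:
    """Direction-coded control-normalized z-score, one per animal.

    z = direction * (X - mu_control) / sd_control, with the control mean
    and sample SD (ddof=1) computed from the control group only.
    """
    values = np.asarray(values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if control_values.size < 2:
        raise ValueError(f"parameter {parameter!r}: need >= 2 control values")
    mu = control_values.mean()
    sd = control_values.std(ddof=1)
    if sd == 0:
        raise ValueError(f"parameter {parameter!r}: control SD is zero")
    return direction * (values - mu) / sd


def distance_normalize(value, travelled_distance):
    """Divide a locomotion-confounded readout by travelled distance."""
    travelled_distance = np.asarray(travelled_distance, dtype=float)
    if np.any(travelled_distance <= 0):
        raise ValueError("travelled distance must be positive")
    return np.asarray(value, dtype=float) / travelled_distance


def emotionality_scores(
    table: pd.DataFrame,
    specs: list[ParameterSpec],
    control_group: str,
) -> EmotionalityScores:
    """Compute the full two-level emotionality score from a tidy table.

    ``table`` columns: animal_id, group, test, parameter, value.  Rows
    with parameter ``travelled_distance`` supply the per-animal distance
    used for flagged parameters.  Missing parameters are excluded from
    the averages (never imputed); an animal with no scored test at all
    is dropped with a warning.
    """
    required = {"animal_id", "group", "test", "parameter", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"behavior table must have columns {sorted(required)}")
    spec_by_key = {(s.test_name, s.parameter_name): s for s in specs}

    dist = (
        table[table["parameter"] == DISTANCE_PARAMETER]
        .set_index("animal_id")["value"]
        .to_dict()
    )
    groups = table.drop_duplicates("animal_id").set_index("animal_id")["group"]

    rows = []
    stats_rows = []
    for (test, parameter), sub in table.groupby(["test", "parameter"]):
        spec = spec_by_key.get((test, parameter))
        if spec is None:
            continue
        sub = sub.drop_duplicates("animal_id")
        vals = sub["value"].to_numpy(dtype=float)
        if spec.normalize_by_distance:
            d = np.array([dist.get(a, np.nan) for a in sub["animal_id"]])
            if np.any(np.isnan(d)):
                raise ValueError(
                    f"{test}/{parameter}: distance normalization requested but "
                    f"'{DISTANCE_PARAMETER}' rows are missing for some animals"
                )
            vals = distance_normalize(vals, d)
        is_ctrl = (sub["group"] == control_group).to_numpy()
        if is_ctrl.sum() < 2:
            raise ValueError(f"{test}/{parameter}: fewer than 2 control animals")
        z = param_z(vals, vals[is_ctrl], spec.direction, parameter=f"{test}/{parameter}")
        stats_rows.append(
            {
                "test": test,
                "parameter": parameter,
                "control_mu": vals[is_ctrl].mean(),
                "control_sd": vals[is_ctrl].std(ddof=1),
                "direction": spec.direction,
            }
        )
        for a, zi in zip(sub["animal_id"], z):
            rows.append({"animal_id": a, "test": test, "parameter": parameter, "z": zi})

    if not rows:
        raise ValueError("no table parameter matched the scoring specs")
    pz = pd.DataFrame(rows)
    tz = (
        pz.groupby(["animal_id", "test"], as_index=False)["z"]
        .mean()
        .rename(columns={"z": "test_z"})
    )
    emo = tz.groupby("animal_id")["test_z"].mean()

    scored = set(emo.index)
    unscored = sorted(set(groups.index) - scored)
    if unscored:
        warnings.warn(f"animals with no scored test excluded: {unscored}")

    return EmotionalityScores(
        param_z=pz,
        test_z=tz,
        emotionality=emo.rename("emotionality_z"),
        control_stats=pd.DataFrame(stats_rows),
        group_of=groups,
    )


def aggregate(pz: pd.DataFrame, specs: list[ParameterSpec]) -> tuple[pd.DataFrame, pd.Series]:
    """Two-level averaging of precomputed parameter z-scores.

    ``pz`` columns: animal_id, test, parameter, z.  Every parameter must
    be mapped to a test in ``specs``.  Returns (test-level scores,
    per-animal emotionality score).
    """
    known = {(s.test_name, s.parameter_name) for s in specs}
    for key in pz[["test", "parameter"]].itertuples(index=False, name=None):
        if key not in known:
            raise ValueError(f"parameter {key} is not mapped to any test in the spec")
    tz = (
        pz.groupby(["animal_id", "test"], as_index=False)["z"]
        .mean()
        .rename(columns={"z": "test_z"})
    )
    emo = tz.groupby("animal_id")["test_z"].mean().rename("emotionality_z")
    return tz, emo
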