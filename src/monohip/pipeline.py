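"""End-to-end processing: raw thigh-IMU signals to hip ROM validity report.

The chain mirrors the single-IMU measurement protocol:

1. zero-phase FIR low-pass of the gyroscope (3.2 Hz cutoff),
2. functional sensor-to-segment calibration (PCA of walking angular
   velocity),
3. per-cycle thigh flexion ROM by strapdown integration (or sensor fusion),
4. per-cycle feature extraction into a feature table,
5. group-cross-validated prediction of hip ROM from the features,
6. Bland-Altman agreement of each predictor against the reference hip ROM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import models as roms
from .calibration import (SegmentCalibration, functional_calibration,
                          kalman_orientation, complementary_orientation,
                          rom_by_fusion, strapdown_cycle_angle)
from .evaluate import (ModelEvaluation, ValidityCriterion, ba_points,
                       bland_altman, check_validity, group_kfold,
                       regression_metrics)
from .features import correlation_filter, extract_features, \
    importance_ranking
from .signals import FilterSpec, TimeSeries, lowpass_zero_phase, \
    segment_cycles, time_normalize
from .simulate import Cohort, IMURecording, TrialData

#: practical filter for the 128 Hz gyroscope stream
DEFAULT_FILTER = FilterSpec(order=50, cutoff=3.2)


def filtered_gyro(imu: IMURecording,
                  filter_spec: FilterSpec | None = DEFAULT_FILTER
                  ) -> TimeSeries:
    ts = imu.gyro_series()
    return lowpass_zero_phase(ts, filter_spec) if filter_spec else ts


def compute_trial_rom(imu: IMURecording, events: np.ndarray,
                      method: str = "strapdown",
                      cal: SegmentCalibration | None = None,
                      filter_spec: FilterSpec | None = DEFAULT_FILTER,
                      reference: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cycle thigh flexion ROM for one trial.

    `method` is 'strapdown', 'complementary', 'kalman' or 'auto'; 'auto'
    runs all three and keeps the one with the lowest MAE against
    `reference` (required in that case). Calibration defaults to functional
    calibration on the filtered gyroscope of this trial.
    """
    gyro = filtered_gyro(imu, filter_spec)
    if cal is None:
        cal = functional_calibration(gyro)

    def _strapdown() -> np.ndarray:
        ml = TimeSeries(gyro.t, gyro.values @ cal.ml_axis, gyro.fs)
        return np.array([strapdown_cycle_angle(c.values, c.fs)[1]
                         for c in segment_cycles(ml, events)])

    def _fused(kind: str) -> np.ndarray:
        if kind == "complementary":
            q = complementary_orientation(gyro, imu.accel_series())
        else:
            q = kalman_orientation(gyro, imu.accel_series())
        out = rom_by_fusion(q, cal, events, method=kind, t0=float(gyro.t[0]))
        return np.array([c.thigh_rom for c in out])

    if method == "auto":
        if reference is None:
            raise ValueError("method='auto' needs a reference thigh ROM")
        candidates = {"strapdown": _strapdown(),
                      "complementary": _fused("complementary"),
                      "kalman": _fused("kalman")}
        from .calibration import select_best_method
        method, _ = select_best_method(candidates, reference)
        roms_arr = candidates[method]
    elif method == "strapdown":
        roms_arr = _strapdown()
    elif method in ("complementary", "kalman"):
        roms_arr = _fused(method)
    else:
        raise ValueError(f"unknown ROM method {method!r}")
    return pd.DataFrame({"cycle_index": np.arange(len(roms_arr)),
                         "thigh_rom": roms_arr, "method": method})


def trial_features(trial: TrialData, method: str = "strapdown",
                   filter_spec: FilterSpec | None = DEFAULT_FILTER
                   ) -> pd.DataFrame:
    """Feature-table rows for every cycle of one trial."""
    gyro = filtered_gyro(trial.imu, filter_spec)
    cal = functional_calibration(gyro)
    rom_df = compute_trial_rom(trial.imu, trial.events, method=method,
                               cal=cal, filter_spec=filter_spec,
                               reference=trial.truth["thigh_rom"].to_numpy())
    ml = TimeSeries(gyro.t, gyro.values @ cal.ml_axis, gyro.fs)
    rows = []
    for cyc, rom in zip(segment_cycles(ml, trial.events),
                        rom_df["thigh_rom"]):
        row = extract_features(
            cyc.values, cyc.fs, thigh_rom=rom,
            leg_length=trial.leg_length, walking_speed=trial.walking_speed,
            group_id=trial.group_id)
        rows.append(row)
    df = pd.DataFrame(rows)
    df["hip_rom_ref"] = trial.truth["hip_rom"].to_numpy()
    df["trial_id"] = trial.trial_id
    df["cycle_index"] = trial.truth["cycle_index"].to_numpy()
    return df


def build_feature_table(cohort: Cohort, method: str = "strapdown",
                        filter_spec: FilterSpec | None = DEFAULT_FILTER
                        ) -> pd.DataFrame:
    """One row per gait cycle across the whole cohort."""
    return pd.concat(
        [trial_features(tr, method, filter_spec) for tr in cohort.trials],
        ignore_index=True)


def build_cycle_tensors(cohort: Cohort,
                        filter_spec: FilterSpec | None = DEFAULT_FILTER
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_cycles, 100, 7) input tensors for the recurrent models.

    Channel 1 is the sagittal thigh angle waveform reconstructed by
    strapdown integration (its range is the measured thigh ROM), channels
    2-4 the tri-axial acceleration and 5-7 the tri-axial angular velocity,
    each time-normalized to 100 points. Returns (tensors, hip ROM
    references, group ids).
    """
    tensors, refs, groups = [], [], []
    for tr in cohort.trials:
        gyro = filtered_gyro(tr.imu, filter_spec)
        cal = functional_calibration(gyro)
        ml = TimeSeries(gyro.t, gyro.values @ cal.ml_axis, gyro.fs)
        acc = tr.imu.accel_series()
        cycles_ml = segment_cycles(ml, tr.events)
        cycles_acc = segment_cycles(acc, tr.events)
        cycles_gyr = segment_cycles(gyro, tr.events)
        for i, (cm, ca, cg) in enumerate(zip(cycles_ml, cycles_acc,
                                             cycles_gyr)):
            angle, _ = strapdown_cycle_angle(cm.values, cm.fs)
            chan = np.column_stack([
                time_normalize(angle),
                time_normalize(ca.values),
                time_normalize(cg.values)])
            tensors.append(chan)
            refs.append(tr.truth["hip_rom"].iloc[i])
            groups.append(tr.group_id)
    return np.stack(tensors), np.array(refs), np.array(groups)


def select_features(table: pd.DataFrame, top_k: int = 3,
                    seed: int = 17) -> list[str]:
    """Two-stage selection: correlation filter, then tree importance."""
    retained = correlation_filter(table)
    ranking = importance_ranking(table, features=retained, seed=seed)
    return ranking["feature"].head(top_k).tolist()


def run_validity_study(cohort_or_table, k: int = 5, seed: int = 0,
                       criterion: ValidityCriterion | None = None,
                       features: list[str] | None = None) -> dict:
    """Cross-validated comparison of the baseline and linear predictors.

    Evaluates, against the reference hip ROM: the raw thigh ROM (agreement
    before any prediction), the naive training-mean predictor, simple
    linear regression on thigh ROM, and multiple linear regression on the
    selected features — each with out-of-fold predictions under
    participant-side group folds.
    """
    crit = criterion or ValidityCriterion()
    table = (cohort_or_table if isinstance(cohort_or_table, pd.DataFrame)
             else build_feature_table(cohort_or_table))
    y = table["hip_rom_ref"].to_numpy(float)
    groups = table["group_id"].to_numpy()
    folds = group_kfold(groups, k=k, seed=seed)
    if features is None:
        features = select_features(table, seed=seed + 17)

    preds = {"thigh_rom_raw": table["thigh_rom"].to_numpy(float)}
    preds["naive"] = roms.train_predict(
        lambda X, yy: roms.NaiveROM(yy).fit(),
        np.zeros((len(y), 1)), y, groups, folds, standardize=False)
    preds["slr"] = roms.train_predict(
        lambda X, yy: roms.LinearROM(yy, X, ["thigh_rom"]).fit(),
        table[["thigh_rom"]].to_numpy(float), y, groups, folds,
        standardize=False)
    preds["mlr"] = roms.train_predict(
        lambda X, yy: roms.LinearROM(yy, X, list(features)).fit(),
        table[list(features)].to_numpy(float), y, groups, folds,
        standardize=False)

    evaluations = []
    for name, p in preds.items():
        agr = bland_altman(p, y)
        evaluations.append(ModelEvaluation(
            name=name, agreement=agr, metrics=regression_metrics(p, y),
            valid=check_validity(agr, crit), ba=ba_points(p, y)))
    return {"table": table, "features": list(features), "folds": folds,
            "predictions": preds, "evaluations": evaluations,
            "criterion": crit}
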