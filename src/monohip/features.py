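"""Per-cycle feature extraction and two-stage feature selection.

Each gait cycle of medio-lateral thigh angular velocity yields seven signal
metrics (mean, skewness, RMS, crest factor, minimum valley, band power,
3 dB power bandwidth); together with the measured thigh ROM, leg length and
walking speed they form one row of the feature table used to predict hip
ROM. Feature selection follows a two-stage scheme: a pairwise Pearson
correlation filter removes redundant features (keeping, within each
correlated pair, the one more correlated with hip ROM), then a single
regression tree ranks the survivors by impurity-reduction importance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

#: the seven per-cycle signal features, in canonical column order
SIGNAL_FEATURES = ("mean", "skewness", "rms", "crest_factor", "min_valley",
                   "band_power", "power_bandwidth")
#: full predictor set of the feature table
ALL_FEATURES = ("thigh_rom", "leg_length", "walking_speed") + SIGNAL_FEATURES

_VAR_EPS = 1e-12


def _power_bandwidth(freqs: np.ndarray, pxx: np.ndarray) -> float:
    """3 dB bandwidth around the periodogram peak, with linear
    interpolation of the half-power crossings; falls back to the band edge
    when the spectrum never drops below half power on a side."""
    k = int(np.argmax(pxx))
    half = pxx[k] / 2.0
    if pxx[k] <= 0.0:
        return 0.0

    def _cross(idx_range) -> float | None:
        prev = k
        for i in idx_range:
            if pxx[i] < half:
                f0, f1 = freqs[i], freqs[prev]
                p0, p1 = pxx[i], pxx[prev]
                if np.isclose(p1, p0):
                    return float(f0)
                return float(f0 + (half - p0) * (f1 - f0) / (p1 - p0))
            prev = i
        return None

    lo = _cross(range(k - 1, -1, -1))
    hi = _cross(range(k + 1, len(pxx)))
    f_lo = freqs[0] if lo is None else lo
    f_hi = freqs[-1] if hi is None else hi
    return float(f_hi - f_lo)


def extract_features(gyro_ml: np.ndarray, fs: float, thigh_rom: float,
                     leg_length: float, walking_speed: float,
                     hip_rom_ref: float = np.nan,
                     group_id: str | None = None) -> dict:
    """One feature-table row from one cycle of medio-lateral angular
    velocity (deg/s).

    Conventions for degenerate cycles: skewness is 0 when the variance
    vanishes, the crest factor is 1 when the RMS vanishes.
    """
    x = np.asarray(gyro_ml, dtype=float)
    if x.size == 0:
        raise ValueError("empty cycle")
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("cycle must be a 1-D series of >= 8 samples")

    rms = float(np.sqrt(np.mean(x ** 2)))
    var = float(np.var(x))
    skew = float(stats.skew(x, bias=False)) if var > _VAR_EPS else 0.0
    crest = float(np.max(np.abs(x)) / rms) if rms > _VAR_EPS else 1.0
    freqs, pxx = sps.periodogram(x, fs=fs, detrend=False)
    band_power = float(np.sum(pxx) * fs / len(x))  # mean power (Parseval)

    return {
        "thigh_rom": float(thigh_rom),
        "leg_length": float(leg_length),
        "walking_speed": float(walking_speed),
        "mean": float(np.mean(x)),
        "skewness": skew,
        "rms": rms,
        "crest_factor": crest,
        "min_valley": float(np.min(x)),
        "band_power": band_power,
        "power_bandwidth": _power_bandwidth(freqs, pxx),
        "hip_rom_ref": float(hip_rom_ref),
        "group_id": group_id,
    }


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson R with the convention that a constant input has R = 0."""
    if np.std(a) < _VAR_EPS or np.std(b) < _VAR_EPS:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def correlation_filter(table: pd.DataFrame, target: str = "hip_rom_ref",
                       threshold: float = 0.5,
                       features: list[str] | None = None) -> list[str]:
    """Redundancy filter: within every feature pair with |R| >= threshold,
    drop the member less correlated with the target.

    Pairs are processed in descending pairwise |R| (ties broken
    lexicographically), which makes the retained set independent of the
    column order of the input table. Constant features have all their
    correlations treated as 0 and are never dropped by the filter.
    """
    feats = list(features) if features is not None else \
        [c for c in ALL_FEATURES if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    y = table[target].to_numpy(float)
    if np.std(y) < _VAR_EPS:
        raise ValueError("target is constant")

    target_r = {f: abs(_safe_corr(table[f].to_numpy(float), y))
                for f in feats}
    pairs = []
    for i, fi in enumerate(sorted(feats)):
        for fj in sorted(feats)[i + 1:]:
            r = abs(_safe_corr(table[fi].to_numpy(float),
                               table[fj].to_numpy(float)))
            if r >= threshold:
                pairs.append((r, fi, fj))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))

    retained = set(feats)
    changed = True
    while changed:
        changed = False
        for _, fi, fj in pairs:
            if fi in retained and fj in retained:
                # drop the member with the weaker target correlation;
                # on an exact tie drop the lexicographically later name
                if (target_r[fi], fj) > (target_r[fj], fi):
                    retained.discard(fj)
                else:
                    retained.discard(fi)
                changed = True
    return [f for f in feats if f in retained]


def importance_ranking(table: pd.DataFrame, target: str = "hip_rom_ref",
                       features: list[str] | None = None,
                       seed: int = 17,
                       min_samples_leaf: int = 20) -> pd.DataFrame:
    """Regression-tree predictor importance.

    A single decision tree is fitted on standardized features; importance is
    the total variance reduction attributed to each feature, normalized to
    sum to one. Deterministic for a fixed seed. The leaf-size floor keeps a
    fully grown tree from attributing residual noise to uninformative
    features on cohort-sized tables.
    """
    feats = list(features) if features is not None else \
        [c for c in ALL_FEATURES if c in table.columns]
    if len(table) < 20:
        raise ValueError("need at least 20 rows for importance ranking")
    y = table[target].to_numpy(float)
    if np.std(y) < _VAR_EPS:
        raise ValueError("target is constant")
    X = StandardScaler().fit_transform(table[feats].to_numpy(float))
    tree = DecisionTreeRegressor(random_state=seed,
                                 min_samples_leaf=min_samples_leaf)
    tree.fit(X, y)
    out = pd.DataFrame({"feature": feats,
                        "importance": tree.feature_importances_})
    return out.sort_values("importance", ascending=False,
                           kind="stable").reset_index(drop=True)
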