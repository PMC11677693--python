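"""Age-acceleration analysis.

The metabolomic age score is detrended against chronologic age with a
cubic smoothing spline (roughness penalty on the second derivative,
smoothing chosen by generalized cross-validation).  Each subject's age
difference is ``age_metabolomic - age_spline``; subjects beyond +/- a
threshold (7 years by default, capturing roughly the 10% tails in the
source cohorts) are classed accelerated or decelerated, and the two tails
are compared characteristic by characteristic with Welch t-tests
(continuous) and chi-squared tests (categorical).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

ACCELERATED = "accelerated"
DECELERATED = "decelerated"
INTERMEDIATE = "intermediate"


@dataclass
class AgeSpline:
    """Smoothing-spline trend of metabolomic age on actual age.

    Calls evaluate the trend at arbitrary ages; outside the training age
    range the trend continues linearly from the boundary slope, keeping
    behavior bounded under extrapolation.
    """

    spline: object
    x_min: float
    x_max: float
    fitted: np.ndarray  # trend at the training ages, in input order

    def __call__(self, ages) -> np.ndarray:
        x = np.asarray(ages, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        out = np.empty_like(x)
        inside = (x >= self.x_min) & (x <= self.x_max)
        out[inside] = self.spline(x[inside])
        for bound in (self.x_min, self.x_max):
            side = x < bound if bound == self.x_min else x > bound
            if side.any():
                slope = float(self.spline(bound, nu=1))
                out[side] = float(self.spline(bound)) + slope * (x[side] - bound)
        return out[0] if scalar else out


def fit_age_spline(age_actual, age_metabolomic) -> AgeSpline:
    """Fit the GCV cubic smoothing spline of metabolomic on actual age.

    Duplicate ages are collapsed to their mean with multiplicity weights
    (the classic smoothing-spline treatment of ties).  Requires at least
    20 points and 4 distinct ages.
    """
    x = np.asarray(age_actual, dtype=float)
    y = np.asarray(age_metabolomic, dtype=float)
    if x.shape != y.shape:
        raise ValueError("age vectors have different lengths")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("ages must be finite")
    if x.size < 20:
        raise ValueError("need at least 20 subjects to fit the age spline")
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    if ux.size < 4:
        raise ValueError("need at least 4 distinct age values")
    ymean = np.bincount(inv, weights=y) / counts
    spl = make_smoothing_spline(ux, ymean, w=counts.astype(float), lam=None)
    model = AgeSpline(spline=spl, x_min=float(ux[0]), x_max=float(ux[-1]),
                      fitted=np.asarray(spl(x), dtype=float))
    return model


def age_acceleration(
    subject_ids: Sequence, age_actual, age_metabolomic,
    threshold: float = 7.0, spline: AgeSpline | None = None,
) -> pd.DataFrame:
    """Build per-subject age-acceleration records.

    Returns a frame with ``age_actual``, ``age_metabolomic``,
    ``age_spline``, ``delta`` (= metabolomic - spline) and ``accel_class``.
    If ``spline`` is given (e.g. fitted on a wider population) it is used
    for detrending; otherwise one is fitted to the provided subjects.
    """
    x = np.asarray(age_actual, dtype=float)
    y = np.asarray(age_metabolomic, dtype=float)
    if spline is None:
        spline = fit_age_spline(x, y)
    trend = spline(x)
    rec = pd.DataFrame({
        "age_actual": x, "age_metabolomic": y,
        "age_spline": trend, "delta": y - trend,
    }, index=pd.Index(subject_ids, name="subject_id"))
    return classify_acceleration(rec, threshold)


def classify_acceleration(records: pd.DataFrame, threshold: float = 7.0,
                          tail_fraction: float | None = None) -> pd.DataFrame:
    """Label records accelerated / decelerated / intermediate.

    Strict inequalities: delta > threshold is accelerated, delta <
    -threshold decelerated, everything else (including the boundary)
    intermediate.  ``tail_fraction`` switches to the symmetric
    quantile-based alternative (e.g. 0.10 for the 10% tails), overriding
    the year threshold.
    """
    if "delta" not in records.columns:
        raise KeyError("records need a 'delta' column")
    if tail_fraction is not None:
        if not 0 < tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        lo = float(records["delta"].quantile(tail_fraction))
        hi = float(records["delta"].quantile(1.0 - tail_fraction))
    else:
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        lo, hi = -float(threshold), float(threshold)
    out = records.copy()
    delta = out["delta"].to_numpy()
    cls = np.where(delta > hi, ACCELERATED,
                   np.where(delta < lo, DECELERATED, INTERMEDIATE))
    out["accel_class"] = cls
    return out


class WelchTResult(NamedTuple):
    statistic: float
    df: float
    p: float


class ChiSquaredResult(NamedTuple):
    statistic: float
    df: int
    p: float
    min_expected: float


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> WelchTResult:
    """Welch two-sample t-test from group summaries (mean, sd, n)."""
    if sd1 <= 0 and sd2 <= 0:
        raise ValueError("zero standard deviation in both groups")
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=False)
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return WelchTResult(float(res.statistic), float(df), float(res.pvalue))


def welch_t(x, y) -> WelchTResult:
    """Welch t-test on raw vectors; equals the summary path on their stats."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t_from_summary(x.mean(), x.std(ddof=1), x.size,
                                y.mean(), y.std(ddof=1), y.size)


def chi_squared_test(contingency, yates: bool | None = None) -> ChiSquaredResult:
    """Pearson chi-squared test on an r x c count table.

    Yates continuity correction defaults to on for 2x2 tables and off
    otherwise; pass ``yates`` to override (2x2 only).  A warning is issued
    when any expected count is below 5.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("contingency must be a 2-D nonnegative count table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is all zeros")
    is_2x2 = table.shape == (2, 2)
    correction = is_2x2 if yates is None else bool(yates) and is_2x2
    stat, p, df, expected = stats.chi2_contingency(table, correction=correction)
    min_exp = float(expected.min())
    if min_exp < 5:
        warnings.warn(
            f"expected count below 5 (min {min_exp:.2f}); chi-squared "
            "approximation may be poor", stacklevel=2)
    return ChiSquaredResult(float(stat), int(df), float(p), min_exp)


def compare_characteristics(
    meta: pd.DataFrame, classes: pd.Series,
    characteristics: dict[str, str],
    group_a: str = ACCELERATED, group_b: str = DECELERATED,
) -> pd.DataFrame:
    """Tabulate accelerated-vs-decelerated differences per characteristic.

    ``characteristics`` maps column name -> "continuous" or "categorical".
    Continuous rows get Welch t-tests and mean (sd) summaries; categorical
    rows get chi-squared tests on the level x group table and n (%)
    summaries.  Missing values are dropped pairwise per row and the count
    recorded.
    """
    classes = classes.reindex(meta.index)
    in_a, in_b = classes == group_a, classes == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each compared class needs at least 2 subjects")
    rows = []
    for name, kind in characteristics.items():
        if name not in meta.columns:
            raise KeyError(f"characteristic {name!r} absent from metadata")
        col = meta[name]
        n_missing = int(col[in_a | in_b].isna().sum())
        a, b = col[in_a].dropna(), col[in_b].dropna()
        if kind == "continuous":
            a, b = a.astype(float), b.astype(float)
            res = welch_t(a, b)
            rows.append({
                "characteristic": name, "type": kind,
                f"summary_{group_a}": f"{a.mean():.3g} ({a.std(ddof=1):.3g})",
                f"summary_{group_b}": f"{b.mean():.3g} ({b.std(ddof=1):.3g})",
                "test": "welch_t", "statistic": res.statistic, "p": res.p,
                "n_missing": n_missing,
            })
        elif kind == "categorical":
            levels = sorted(pd.concat([a, b]).unique(), key=str)
            table = np.array([[int((a == lv).sum()) for lv in levels],
                              [int((b == lv).sum()) for lv in levels]])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = chi_squared_test(table.T)

            def _pct(counts):
                tot = counts.sum()
                return "/".join(f"{c} ({100 * c / tot:.1f}%)" for c in counts)

            rows.append({
                "characteristic": name, "type": kind,
                f"summary_{group_a}": _pct(table[0]),
                f"summary_{group_b}": _pct(table[1]),
                "test": "chi_squared", "statistic": res.statistic, "p": res.p,
                "n_missing": n_missing,
            })
        else:
            raise ValueError(f"unknown characteristic type {kind!r}")
    return pd.DataFrame(rows)
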