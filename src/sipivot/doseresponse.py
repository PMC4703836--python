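"""Dose-response normalization and IC50 estimation from luciferase assays.

Relative activity is the Renilla/firefly luciferase ratio expressed as a
percentage of a non-targeting control (control mean = 100%).  Repression is
modelled with a control-anchored three-parameter logistic,

    RA(c) = 100 - P * c^h / (c^h + IC50^h)

with plateau inhibition P in [0, 100] %, Hill slope h, and IC50 in the
concentration units of the input (nM).  Before fitting, each concentration
is screened for significant repression against the control replicates
(two-sided t-test at alpha = 0.01, reported uncorrected per concentration —
matching per-bar significance calls).  The ND decision itself is a
family-level claim ("no significant repression in any tested range"), so it
gates on Bonferroni-corrected per-concentration tests: ND (IC50 not
determined, zero plateau) when no concentration rejects at alpha divided by
the number of concentrations.  This keeps the family-wise false-signal rate
at ~alpha while costing essentially no power against genuine repression
(replicate assays of real curves reject far below the corrected threshold).  If the
nonlinear fit fails to converge, or lands outside [min(c)/10, 10*max(c)],
an approximate IC50 is read off a regression line of mean activity on
log10(concentration) over the transition region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DoseResponseData",
    "FitResult",
    "ND",
    "sigmoid",
    "normalize_relative_activity",
    "fit_sigmoid",
    "ic50_fallback_regression",
    "relative_imax",
    "DoseResponseModel",
    "DoseResponseResults",
]

#: sentinel for "IC50 not determined"
ND = "ND"

SCREEN_ALPHA = 0.01
HILL_BOUNDS = (0.3, 4.0)


def sigmoid(c, plateau, ic50, hill):
    """Control-anchored repression curve; returns relative activity in %."""
    c = np.asarray(c, dtype=float)
    return 100.0 - plateau * c**hill / (c**hill + ic50**hill)


@dataclass
class DoseResponseData:
    """Replicate relative activities per concentration, plus control replicates.

    ``activities`` maps concentration (nM) -> array of replicate relative
    activities in % (already normalized so that the control mean is 100).
    """

    concentrations: np.ndarray
    activities: dict[float, np.ndarray]
    control_replicates: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(sorted(self.concentrations), dtype=float)
        if self.concentrations.size < 1 or np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(set(self.concentrations.tolist())) != self.concentrations.size:
            raise ValueError("concentrations must be distinct")
        self.activities = {
            float(c): np.asarray(v, dtype=float) for c, v in self.activities.items()
        }
        missing = set(self.concentrations.tolist()) - set(self.activities)
        if missing:
            raise ValueError(f"missing replicate activities for {sorted(missing)}")
        self.control_replicates = np.asarray(self.control_replicates, dtype=float)

    @property
    def mean_activities(self) -> np.ndarray:
        return np.array([self.activities[c].mean() for c in self.concentrations])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponseData":
        """Build from a long table with columns concentration_nM and either
        relative_activity or raw renilla/firefly.  Control rows are flagged
        with concentration 0 (or the label ``NT``)."""
        df = df.copy()
        conc = pd.to_numeric(
            df["concentration_nM"].replace({"NT": 0, "nt": 0}), errors="raise"
        )
        if "relative_activity" not in df.columns:
            if not {"renilla", "firefly"} <= set(df.columns):
                raise ValueError(
                    "need either a relative_activity column or renilla+firefly"
                )
            ctrl_ratio = (
                df.loc[conc == 0, "renilla"] / df.loc[conc == 0, "firefly"]
            ).mean()
            df["relative_activity"] = normalize_relative_activity(
                df["renilla"].to_numpy(), df["firefly"].to_numpy(), ctrl_ratio
            )
        ctrl = df.loc[conc == 0, "relative_activity"].to_numpy(dtype=float)
        if ctrl.size == 0:
            raise ValueError("no control rows (concentration 0 / NT) found")
        doses = sorted(c for c in conc.unique() if c > 0)
        acts = {
            float(c): df.loc[conc == c, "relative_activity"].to_numpy(dtype=float)
            for c in doses
        }
        return cls(np.asarray(doses), acts, ctrl)


@dataclass(frozen=True)
class FitResult:
    """IC50 (nM, or the string ``"ND"``), plateau inhibition %, Hill slope."""

    ic50: float | str
    plateau_inhibition: float
    hill: float
    method: str  # sigmoid_nls | regression_fallback | nd
    per_concentration_significant: tuple[bool, ...] = ()

    @property
    def is_nd(self) -> bool:
        return self.ic50 == ND


def normalize_relative_activity(renilla, firefly, control_ratio_mean):
    """Relative activity in %: 100 * (renilla/firefly) / control mean ratio."""
    renilla = np.asarray(renilla, dtype=float)
    firefly = np.asarray(firefly, dtype=float)
    if np.any(firefly <= 0):
        raise ValueError("firefly readings must be positive")
    if not np.all(np.asarray(control_ratio_mean) > 0):
        raise ValueError("control mean ratio must be positive")
    return 100.0 * (renilla / firefly) / control_ratio_mean


def _screen_pvalues(data: DoseResponseData) -> list[float]:
    """Per-concentration two-sided t-test p-values vs control replicates.

    Repression direction is enforced by the caller; degenerate noiseless
    arms with differing means get p = 0.
    """
    pvals = []
    ctrl = data.control_replicates
    for c in data.concentrations:
        reps = data.activities[float(c)]
        if reps.size < 2 or ctrl.size < 2:
            pvals.append(1.0)
            continue
        if reps.std() == 0 and ctrl.std() == 0:
            pvals.append(0.0 if reps.mean() != ctrl.mean() else 1.0)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(reps, ctrl, equal_var=True)
        pvals.append(float(p) if np.isfinite(p) else 1.0)
    return pvals


def _significance_screen(
    data: DoseResponseData, alpha: float
) -> tuple[tuple[bool, ...], bool]:
    """Per-concentration repression flags and the family-level ND gate.

    Flags use the raw per-concentration alpha (per-bar convention); the ND
    gate requires at least one concentration to reject at the
    Bonferroni-corrected level alpha/m, keeping ND specificity at ~1-alpha.
    Both require the concentration's mean activity below the control mean.
    """
    pvals = _screen_pvalues(data)
    ctrl_mean = data.control_replicates.mean()
    repressed = [
        data.activities[float(c)].mean() < ctrl_mean for c in data.concentrations
    ]
    flags = tuple(
        bool(p < alpha) and rep for p, rep in zip(pvals, repressed)
    )
    m = len(pvals)
    any_corrected = any(
        p < alpha / m and rep for p, rep in zip(pvals, repressed)
    )
    return flags, any_corrected


def ic50_fallback_regression(data: DoseResponseData) -> float | str:
    """Approximate IC50 from the regression line of mean activity on log10(c).

    Uses concentrations whose mean activity lies strictly inside the 20-80%
    band of the observed inhibition range; the IC50 is where the line crosses
    the midpoint between the maximal and minimal observed mean activities.
    Returns ND when fewer than 2 concentrations qualify or the line is flat.
    """
    means = data.mean_activities
    lo, hi = means.min(), means.max()
    span = hi - lo
    if span <= 0:
        return ND
    mask = (means > lo + 0.2 * span) & (means < lo + 0.8 * span)
    if mask.sum() < 2:
        return ND
    x = np.log10(data.concentrations[mask])
    y = means[mask]
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0:
        return ND
    midpoint = (hi + lo) / 2.0
    return float(10.0 ** ((midpoint - intercept) / slope))


def fit_sigmoid(data: DoseResponseData, alpha: float = SCREEN_ALPHA) -> FitResult:
    """Estimate IC50/plateau/Hill, applying the ND rule and the fallback.

    Deterministic: fixed initial values (plateau = 100 - min mean activity,
    IC50 = geometric mean of concentrations, h = 1), no random restarts.
    """
    if data.concentrations.size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    flags, any_significant = _significance_screen(data, alpha)
    if not any_significant:
        return FitResult(ND, 0.0, np.nan, "nd", flags)

    conc = np.concatenate(
        [np.full(data.activities[float(c)].size, c) for c in data.concentrations]
    )
    act = np.concatenate([data.activities[float(c)] for c in data.concentrations])
    means = data.mean_activities
    p0 = [
        float(np.clip(100.0 - means.min(), 1.0, 100.0)),
        float(stats.gmean(data.concentrations)),
        1.0,
    ]
    bounds = (
        [0.0, data.concentrations.min() / 1e6, HILL_BOUNDS[0]],
        [100.0, data.concentrations.max() * 1e6, HILL_BOUNDS[1]],
    )
    lo_ok, hi_ok = data.concentrations.min() / 10.0, data.concentrations.max() * 10.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                sigmoid, conc, act, p0=p0, bounds=bounds, maxfev=10000
            )
        plateau, ic50, hill = map(float, popt)
        if lo_ok <= ic50 <= hi_ok:
            return FitResult(ic50, plateau, hill, "sigmoid_nls", flags)
    except (RuntimeError, ValueError):
        pass
    ic50_fb = ic50_fallback_regression(data)
    if ic50_fb == ND:
        return FitResult(ND, 0.0, np.nan, "nd", flags)
    plateau_fb = float(np.clip(100.0 - means.min(), 0.0, 100.0))
    return FitResult(float(ic50_fb), plateau_fb, np.nan, "regression_fallback", flags)


def relative_imax(fit: FitResult, fit_reference: FitResult) -> float:
    """Maximal inhibition relative to a reference fit, in % (capped at 100).

    The unmodified guide is the usual reference (Imax[WT] = 100%); an ND fit
    has zero plateau, hence 0%.
    """
    if fit_reference.is_nd or fit_reference.plateau_inhibition <= 0:
        raise ValueError("reference fit has no measurable plateau")
    if fit.is_nd:
        return 0.0
    return float(
        min(100.0, 100.0 * fit.plateau_inhibition / fit_reference.plateau_inhibition)
    )


class DoseResponseModel:
    """Dose-response model for one reporter/guide series.

    Examples
    --------
    >>> model = DoseResponseModel.from_frame(table)   # doctest: +SKIP
    >>> res = model.fit()                             # doctest: +SKIP
    >>> res.ic50, res.plateau_inhibition              # doctest: +SKIP
    """

    def __init__(self, data: DoseResponseData, alpha: float = SCREEN_ALPHA) -> None:
        self.data = data
        self.alpha = alpha

    @classmethod
    def from_frame(cls, df: pd.DataFrame, alpha: float = SCREEN_ALPHA):
        return cls(DoseResponseData.from_frame(df), alpha)

    def fit(self) -> "DoseResponseResults":
        return DoseResponseResults(self, fit_sigmoid(self.data, self.alpha))


@dataclass
class DoseResponseResults:
    model: DoseResponseModel
    fit_result: FitResult

    @property
    def ic50(self) -> float | str:
        return self.fit_result.ic50

    @property
    def plateau_inhibition(self) -> float:
        return self.fit_result.plateau_inhibition

    @property
    def hill(self) -> float:
        return self.fit_result.hill

    @property
    def method(self) -> str:
        return self.fit_result.method

    def predict(self, concentrations) -> np.ndarray:
        if self.fit_result.is_nd:
            return np.full(np.asarray(concentrations, dtype=float).shape, 100.0)
        return sigmoid(
            concentrations,
            self.fit_result.plateau_inhibition,
            self.fit_result.ic50,
            1.0 if np.isnan(self.fit_result.hill) else self.fit_result.hill,
        )

    def summary(self) -> pd.DataFrame:
        data = self.model.data
        rows = [
            {
                "concentration_nM": float(c),
                "mean_activity": float(data.activities[float(c)].mean()),
                "sd_activity": float(data.activities[float(c)].std(ddof=1))
                if data.activities[float(c)].size > 1
                else np.nan,
                "significant": flag,
            }
            for c, flag in zip(
                data.concentrations, self.fit_result.per_concentration_significant
            )
        ]
        per_conc = pd.DataFrame(rows)
        per_conc.attrs["ic50_nM"] = self.ic50
        per_conc.attrs["plateau_inhibition_pct"] = self.plateau_inhibition
        per_conc.attrs["hill"] = self.hill
        per_conc.attrs["method"] = self.method
        return per_conc
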