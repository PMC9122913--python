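"""First-order decay fitting for protein chase experiments.

A chase time course (fraction of protein remaining, normalized to t = 0)
under first-order decay follows y(t) = exp(-k t), so ln y is linear in t
with slope -k and half-life ln 2 / k. The default fit is this log-linear
("exponential line equation") regression with the intercept fixed through
ln y(0) = 0; a free-intercept mode and a nonlinear least-squares mode are
available for data whose normalization is uncertain. Confidence intervals
come from a seeded case-resampling bootstrap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["Timecourse", "DecayFit", "DecayComparison", "fit_decay", "compare_decay", "read_timecourse_tsv"]

LN2 = math.log(2.0)


@dataclass
class Timecourse:
    t: np.ndarray  # hours, strictly increasing
    y: np.ndarray  # fraction remaining, > 0
    replicate: str = "r1"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be equal-length 1-D arrays")
        if np.any(self.t < 0):
            raise ValueError("time points must be non-negative")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.y <= 0):
            raise ValueError("fractions remaining must be positive")


@dataclass
class DecayFit:
    k: float  # per hour
    halflife: float  # hours, = ln2 / k (inf when k <= 0)
    ci: tuple[float, float] | None  # bootstrap CI on the half-life, hours
    r2: float
    n_points: int
    growth_flagged: bool = False

    def to_json_dict(self) -> dict:
        return {
            "k_per_hour": self.k,
            "halflife_hours": self.halflife,
            "ci_hours": list(self.ci) if self.ci else None,
            "r2": self.r2,
            "n_points": self.n_points,
            "growth_flagged": self.growth_flagged,
        }


@dataclass
class DecayComparison:
    ratio: float  # halflife_control / halflife_treated
    ci: tuple[float, float] | None
    control: DecayFit
    treated: DecayFit


def _fit_k(t: np.ndarray, logy: np.ndarray, intercept: str) -> float:
    if intercept == "fixed":
        # ln y = -k t through the origin: closed-form least squares
        denom = float(np.sum(t * t))
        if denom == 0.0:
            raise ValueError("need at least one non-zero time point")
        return -float(np.sum(t * logy)) / denom
    slope, _b = np.polyfit(t, logy, 1)
    return -float(slope)


def fit_decay(
    tc: Timecourse,
    intercept: str = "fixed",
    method: str = "loglinear",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DecayFit:
    """Fit y = exp(-k t); return rate, half-life, bootstrap CI and R^2.

    ``intercept="fixed"`` forces the fit through y(0) = 1 (the time course
    must then actually be normalized: y at t = 0 equal to 1 within 1e-6);
    ``"free"`` estimates the intercept. ``method="nls"`` switches to
    nonlinear least squares on the untransformed data. A non-positive rate
    (growth) is flagged and reported with an infinite half-life. The CI is a
    seeded case-resampling bootstrap, computed when >= 4 points are present.
    """
    t, y = tc.t, tc.y
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    if intercept == "fixed" and t[0] == 0.0 and abs(y[0] - 1.0) > 1e-6:
        raise ValueError("fixed-intercept fit requires y(0) = 1 (normalize first)")
    logy = np.log(y)

    if method == "nls":
        if intercept == "fixed":
            popt, _ = curve_fit(lambda tt, k: np.exp(-k * tt), t, y, p0=[0.1])
            k = float(popt[0])
        else:
            popt, _ = curve_fit(lambda tt, k, a: a * np.exp(-k * tt), t, y, p0=[0.1, 1.0])
            k = float(popt[0])
    else:
        k = _fit_k(t, logy, intercept)

    pred = -k * t if intercept == "fixed" else np.polyval(np.polyfit(t, logy, 1), t)
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    growth = k <= 0
    halflife = math.inf if growth else LN2 / k

    ci = None
    if len(t) >= 4 and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(t)
        idx = rng.integers(0, n, size=(n_boot, n))
        hl = np.full(n_boot, np.nan)
        for b in range(n_boot):
            ib = idx[b]  # resample with repetition (repeats re-weight points)
            if len(np.unique(t[ib])) < (1 if intercept == "fixed" else 2) or not np.any(t[ib] > 0):
                continue
            try:
                kb = _fit_k(t[ib], logy[ib], intercept)
            except ValueError:
                continue
            if kb > 0:
                hl[b] = LN2 / kb
        ok = hl[np.isfinite(hl)]
        if len(ok) >= max(10, n_boot // 10):
            a = (1.0 - ci_level) / 2.0
            lo, hi = np.quantile(ok, [a, 1.0 - a])
            if not growth:
                lo, hi = min(lo, halflife), max(hi, halflife)
            ci = (float(lo), float(hi))
    return DecayFit(k=k, halflife=halflife, ci=ci, r2=r2, n_points=len(t), growth_flagged=growth)


def compare_decay(
    control: Timecourse,
    treated: Timecourse,
    intercept: str = "fixed",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> DecayComparison:
    """Half-life ratio control / treated with a seeded bootstrap interval."""
    fc = fit_decay(control, intercept=intercept, n_boot=0)
    ft = fit_decay(treated, intercept=intercept, n_boot=0)
    ratio = fc.halflife / ft.halflife

    ci = None
    if len(control.t) >= 4 and len(treated.t) >= 4 and n_boot > 0:
        rng = np.random.default_rng(seed)
        lc, lt = np.log(control.y), np.log(treated.y)
        nc, nt = len(control.t), len(treated.t)
        ratios = np.full(n_boot, np.nan)
        for b in range(n_boot):
            ic = rng.integers(0, nc, size=nc)
            it = rng.integers(0, nt, size=nt)
            need = 1 if intercept == "fixed" else 2
            if (
                len(np.unique(control.t[ic])) < need
                or len(np.unique(treated.t[it])) < need
                or not np.any(control.t[ic] > 0)
                or not np.any(treated.t[it] > 0)
            ):
                continue
            try:
                kc = _fit_k(control.t[ic], lc[ic], intercept)
                kt = _fit_k(treated.t[it], lt[it], intercept)
            except ValueError:
                continue
            if kc > 0 and kt > 0:
                ratios[b] = kt / kc  # = halflife_c / halflife_t
        ok = ratios[np.isfinite(ratios)]
        if len(ok) >= max(10, n_boot // 10):
            a = (1.0 - ci_level) / 2.0
            lo, hi = np.quantile(ok, [a, 1.0 - a])
            ci = (float(lo), float(hi))
    return DecayComparison(ratio=ratio, ci=ci, control=fc, treated=ft)


def read_timecourse_tsv(path: str) -> list[Timecourse]:
    """Read a TSV with columns t, y[, replicate]; one Timecourse per replicate."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    tcol, ycol = cols.get("t"), cols.get("y")
    if tcol is None or ycol is None:
        raise ValueError("TSV must have columns 't' and 'y'")
    rcol = cols.get("replicate")
    out = []
    if rcol is None:
        out.append(Timecourse(df[tcol].to_numpy(), df[ycol].to_numpy()))
    else:
        for rep, grp in df.groupby(rcol, sort=True):
            out.append(Timecourse(grp[tcol].to_numpy(), grp[ycol].to_numpy(), replicate=str(rep)))
    return out
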