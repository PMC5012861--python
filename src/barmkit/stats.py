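"""Statistical layer: regressions, cluster diagnostic, bootstrap, 2D fits.

Conventions follow the study design throughout: ordinary least squares with
Pearson correlations and two-sided p-values; BARM shifts are analysed pooled
over both flow directions (they form one continuous cluster through zero),
fast-phase shifts are analysed per direction with the mean of the two fits
reported (they form two separated clusters); percentile bootstrap with 400
resampled events and 1000 repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int
    predictor: str
    range_limits: Optional[tuple] = None
    direction_scope: str = "pooled"
    ok: bool = True

    @classmethod
    def no_fit(cls, predictor, direction_scope="pooled", range_limits=None, n=0):
        return cls(
            slope=np.nan, intercept=np.nan, r=np.nan, p=np.nan, n=n,
            predictor=predictor, range_limits=range_limits,
            direction_scope=direction_scope, ok=False,
        )


@dataclass
class PooledSplitComparison:
    slope_difference: float  # pooled slope minus mean of direction-split slopes
    offset_difference: float  # mean |pooled intercept - split intercept| (deg)
    event_class: str
    pooled: RegressionResult = None
    split: dict = None


@dataclass
class BootstrapResult:
    relation: str
    mean_r: float
    ci95: tuple
    reps: int
    sample_size: int


@dataclass
class Regression2DResult:
    a: float  # coefficient on pre-shift slow-phase amplitude
    b: float  # coefficient on pre-shift eye position
    ci95_a: tuple
    ci95_b: tuple
    event_class: str
    model_count: int
    collinear: bool = False


def _extract(measurements, predictor: str):
    """(x, y, direction) arrays from a measurement table or event list."""
    import pandas as pd

    if isinstance(measurements, pd.DataFrame):
        y = measurements["torsional_shift"].to_numpy(dtype=float)
        if predictor == "pre_shift_position":
            col = (
                "pre_blink_torsion"
                if "pre_blink_torsion" in measurements
                else "pre_shift_position"
            )
            x = measurements[col].to_numpy(dtype=float)
        elif predictor == "preceding_slow_amplitude":
            x = measurements["preceding_slow_amplitude"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        d = measurements["flow_direction"].to_numpy()
        return x, y, d
    xs, ys, ds = [], [], []
    for m in measurements:
        y = m.torsional_shift
        if predictor == "pre_shift_position":
            x = (
                m.pre_blink_torsion
                if hasattr(m, "pre_blink_torsion")
                else m.pre_shift_position
            )
        elif predictor == "preceding_slow_amplitude":
            x = m.preceding_slow_amplitude
        else:
            raise ValueError(f"unknown predictor {predictor!r}")
        xs.append(np.nan if x is None else x)
        ys.append(y)
        ds.append(getattr(m, "flow_direction", "none"))
    return np.asarray(xs, float), np.asarray(ys, float), np.asarray(ds)


def _ols(x, y):
    res = sps.linregress(x, y)
    return res.slope, res.intercept, res.rvalue, res.pvalue


def fit_shift_regression(
    measurements,
    predictor: str = "pre_shift_position",
    range_limits: Optional[tuple] = None,
    direction_scope: str = "pooled",
) -> RegressionResult:
    """OLS fit of torsional shift on the chosen predictor.

    ``direction_scope='mean_of_split'`` fits the two flow directions
    separately and reports the mean of their slopes/intercepts (the
    convention used for fast phases); ``'cw'``/``'ccw'`` restrict to one
    direction; ``'pooled'`` fits all events at once (the convention for
    BARMs).  ``range_limits`` restricts the predictor to a closed interval
    before fitting (the constrained-range reanalysis).
    """
    x, y, d = _extract(measurements, predictor)
    ok = np.isfinite(x) & np.isfinite(y)
    if range_limits is not None:
        lo, hi = range_limits
        ok &= (x >= lo) & (x <= hi)
    x, y, d = x[ok], y[ok], d[ok]

    if direction_scope in ("cw", "ccw"):
        sel = d == direction_scope
        if sel.sum() < 3:
            return RegressionResult.no_fit(predictor, direction_scope, range_limits, int(sel.sum()))
        s, i, r, p = _ols(x[sel], y[sel])
        return RegressionResult(s, i, r, p, int(sel.sum()), predictor, range_limits, direction_scope)

    if direction_scope == "mean_of_split":
        fits = []
        n_tot = 0
        for dname in ("cw", "ccw"):
            sel = d == dname
            if sel.sum() < 3:
                return RegressionResult.no_fit(predictor, direction_scope, range_limits, int(sel.sum()))
            fits.append(_ols(x[sel], y[sel]))
            n_tot += int(sel.sum())
        s = float(np.mean([f[0] for f in fits]))
        i = float(np.mean([f[1] for f in fits]))
        r = float(np.mean([f[2] for f in fits]))
        p = float(max(f[3] for f in fits))
        return RegressionResult(s, i, r, p, n_tot, predictor, range_limits, direction_scope)

    if direction_scope != "pooled":
        raise ValueError(f"unknown direction_scope {direction_scope!r}")
    if len(x) < 3:
        return RegressionResult.no_fit(predictor, direction_scope, range_limits, len(x))
    s, i, r, p = _ols(x, y)
    return RegressionResult(s, i, r, p, len(x), predictor, range_limits, direction_scope)


def pooled_vs_split(measurements, predictor: str = "pre_shift_position",
                    event_class: str = "barm") -> PooledSplitComparison:
    """Cluster diagnostic: does pooling the two flow directions change the fit?

    Fits the same events once pooled and once per direction.  BARM shifts
    form one continuous cluster through zero, so pooled and split fits agree
    (small differences); fast-phase shifts form two direction-dependent
    clusters, so the pooled fit differs sharply from the split fits.
    """
    x, y, d = _extract(measurements, predictor)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, d = x[ok], y[ok], d[ok]
    for dname in ("cw", "ccw"):
        if (d == dname).sum() < 3:
            raise ValueError(f"direction {dname!r} missing or underpopulated")
    pooled = _ols(x, y)
    split = {}
    for dname in ("cw", "ccw"):
        sel = d == dname
        split[dname] = _ols(x[sel], y[sel])
    slope_diff = pooled[0] - float(np.mean([split[k][0] for k in split]))
    offset_diff = float(np.mean([abs(pooled[1] - split[k][1]) for k in split]))
    return PooledSplitComparison(
        slope_difference=float(slope_diff),
        offset_difference=offset_diff,
        event_class=event_class,
        pooled=RegressionResult(*pooled, len(x), predictor),
        split={
            k: RegressionResult(*split[k], int((d == k).sum()), predictor, None, k)
            for k in split
        },
    )


def bootstrap_correlations(
    event_pools: dict,
    sample_size: int = 400,
    reps: int = 1000,
    seed: int = 0,
) -> list[BootstrapResult]:
    """Bootstrap the four shift-vs-predictor correlations.

    ``event_pools`` maps a relation name (e.g. ``'barm_vs_position'``) to an
    ``(x, y)`` pair of equal-length arrays.  Each relation is resampled with
    replacement `reps` times at `sample_size` events; the mean Pearson
    correlation and its 95% percentile interval are reported.
    """
    rng = np.random.default_rng(seed)
    out = []
    for relation, (x, y) in event_pools.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) == 0:
            raise ValueError(f"empty pool for relation {relation!r}")
        if len(x) <= sample_size:
            warnings.warn(
                f"pool {relation!r} has {len(x)} <= sample_size={sample_size} events"
            )
        idx = rng.integers(0, len(x), size=(reps, sample_size))
        xs = x[idx]
        ys = y[idx]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        num = (xs * ys).sum(axis=1)
        den = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rs = np.where(den > 0, num / den, np.nan)
        rs = rs[np.isfinite(rs)]
        lo, hi = np.percentile(rs, [2.5, 97.5])
        mean_r = float(np.mean(rs))
        out.append(
            BootstrapResult(
                relation=relation,
                mean_r=mean_r,
                ci95=(float(min(lo, mean_r)), float(max(hi, mean_r))),
                reps=reps,
                sample_size=sample_size,
            )
        )
    return out


def _ols2(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_2d_regression(
    measurements,
    event_class: str = "barm",
    reps: int = 1000,
    seed: int = 0,
    condition_threshold: float = 1e6,
) -> Regression2DResult:
    """Two-predictor fit: shift = a*slow-phase amplitude + b*eye position.

    BARM shifts are fitted with one model pooled over both flow directions;
    fast-phase shifts with two direction-split models whose coefficients are
    averaged.  95% bootstrap intervals are attached per coefficient.
    """
    xs, y, d = _extract(measurements, "pre_shift_position")
    s, _, _ = _extract(measurements, "preceding_slow_amplitude")
    ok = np.isfinite(xs) & np.isfinite(y) & np.isfinite(s)
    xs, y, s, d = xs[ok], y[ok], s[ok], d[ok]

    def one_fit(sel):
        if sel.sum() < 4:
            raise ValueError("need >= 4 measurements per fitted model")
        X = np.column_stack([s[sel], xs[sel], np.ones(sel.sum())])
        collinear = np.linalg.cond(X) > condition_threshold
        beta = _ols2(X, y[sel])
        return beta, collinear, X, y[sel]

    rng = np.random.default_rng(seed)

    def boot(X, yv):
        n = len(yv)
        out = np.empty((reps, 2))
        for k in range(reps):
            idx = rng.integers(0, n, n)
            out[k] = _ols2(X[idx], yv[idx])[:2]
        return out

    if event_class == "barm":
        sel = np.ones(len(y), dtype=bool)
        beta, collinear, X, yv = one_fit(sel)
        bs = boot(X, yv)
        ci_a = tuple(np.percentile(bs[:, 0], [2.5, 97.5]))
        ci_b = tuple(np.percentile(bs[:, 1], [2.5, 97.5]))
        return Regression2DResult(
            a=float(beta[0]), b=float(beta[1]),
            ci95_a=ci_a, ci95_b=ci_b,
            event_class=event_class, model_count=1, collinear=collinear,
        )

    betas, boots, coll = [], [], False
    for dname in ("cw", "ccw"):
        sel = d == dname
        beta, c, X, yv = one_fit(sel)
        betas.append(beta)
        boots.append(boot(X, yv))
        coll |= c
    mean_beta = np.mean(betas, axis=0)
    bs = 0.5 * (boots[0] + boots[1])
    ci_a = tuple(np.percentile(bs[:, 0], [2.5, 97.5]))
    ci_b = tuple(np.percentile(bs[:, 1], [2.5, 97.5]))
    return Regression2DResult(
        a=float(mean_beta[0]), b=float(mean_beta[1]),
        ci95_a=ci_a, ci95_b=ci_b,
        event_class=event_class, model_count=2, collinear=coll,
    )
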