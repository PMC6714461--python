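"""CO2 kinetic trait extraction and population-level trait statistics.

Raw glass-reactor weight-loss series are smoothed with a local quadratic
(loess-style) regression, monotonized, and reduced to the standard trait
panel: CO2max, lag phase (LP), T35/T50/T70 crossing times against an
*expected* maximum (default 125 g/L), and the mean CO2 release rate between
T50 and T70.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FermentationCurve, PhenotypeTable

log = logging.getLogger(__name__)

#: expected total CO2 release used as the T35/T50/T70 denominator (g/L)
DEFAULT_EXPECTED_MAX = 125.0
#: CO2 production rate defining the end of the lag phase (g/L/h)
DEFAULT_RATE_THRESHOLD = 0.05


@dataclass
class KineticTraits:
    """Kinetic trait panel for one fermentation; undefined traits are None."""

    co2max: float
    lp: Optional[float]
    t35: Optional[float]
    t50: Optional[float]
    t70: Optional[float]
    rate50_70: Optional[float]
    expected_max: float = DEFAULT_EXPECTED_MAX

    def __post_init__(self) -> None:
        times = [t for t in (self.lp, self.t35, self.t50, self.t70) if t is not None]
        if any(b < a - 1e-9 for a, b in zip(times, times[1:])):
            raise ValueError(f"trait times must be ordered lp<=t35<=t50<=t70: {times}")
        if self.rate50_70 is not None and self.t50 is not None and self.t70 is not None:
            ident = self.rate50_70 * (self.t70 - self.t50)
            if not math.isclose(ident, 0.2 * self.expected_max, rel_tol=0, abs_tol=1e-6):
                raise ValueError("rate50_70 inconsistent with t70 - t50")

    def as_dict(self) -> dict:
        return {
            "CO2max": self.co2max,
            "LP": self.lp,
            "T35": self.t35,
            "T50": self.t50,
            "T70": self.t70,
            "rate50_70": self.rate50_70,
        }


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def smooth_curve(curve: FermentationCurve, span: float = 0.3) -> FermentationCurve:
    """Loess-style smoothing: tricube-weighted local quadratic fits.

    The fit is evaluated at the input time points and the output is
    monotonized by a running maximum (cumulative CO2 cannot decrease).

    Parameters
    ----------
    span:
        Fraction of points entering each local fit, in (0, 1].
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    t, y = curve.times, curve.co2
    n = len(t)
    if n < 5:
        raise ValueError(f"need >= 5 points to smooth, got {n}")
    k = max(4, int(math.ceil(span * n)))  # local quadratic needs >= 3, keep margin
    k = min(k, n)
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        w = _tricube(d[idx] / h) if h > 0 else np.ones(k)
        # guard against all-zero weights at ties
        if w.sum() <= 0:
            w = np.ones(k)
        x = t[idx] - t[i]
        design = np.column_stack([np.ones(k), x, x * x])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        fitted[i] = coef[0]
    fitted = np.maximum.accumulate(fitted)
    return FermentationCurve(times=t.copy(), co2=fitted, meta=dict(curve.meta))


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> Optional[float]:
    """Linear-interpolated first upward crossing of ``level``; None if never."""
    above = values >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def extract_traits(
    curve: FermentationCurve,
    expected_max: float = DEFAULT_EXPECTED_MAX,
    rate_threshold: float = DEFAULT_RATE_THRESHOLD,
    span: float = 0.3,
    presmoothed: bool = False,
) -> KineticTraits:
    """Extract the kinetic trait panel from a CO2 curve.

    ``CO2max`` is the observed maximum; ``T35/T50/T70`` are first crossings of
    35/50/70% of ``expected_max`` (these denominators deliberately differ);
    ``LP`` is the earliest time the central finite-difference rate of the
    smoothed curve exceeds ``rate_threshold``; ``rate50_70`` is
    ``0.2 * expected_max / (t70 - t50)``. Crossings never reached are returned
    as None and logged.
    """
    if expected_max <= 0:
        raise ValueError("expected_max must be > 0")
    if not presmoothed and np.any(np.diff(curve.co2) < 0):
        log.warning("curve %s not monotone; smoothing internally", curve.meta)
        curve = smooth_curve(curve, span=span)
    t, y = curve.times, curve.co2

    co2max = float(np.max(y))
    rate = np.gradient(y, t)
    lp = _first_crossing(t, rate, rate_threshold)
    t35 = _first_crossing(t, y, 0.35 * expected_max)
    t50 = _first_crossing(t, y, 0.50 * expected_max)
    t70 = _first_crossing(t, y, 0.70 * expected_max)
    for name, val in (("T35", t35), ("T50", t50), ("T70", t70)):
        if val is None:
            log.info("trait %s undefined: crossing never reached (%s)", name, curve.meta)
    rate50_70 = None
    if t50 is not None and t70 is not None and t70 > t50:
        rate50_70 = 0.2 * expected_max / (t70 - t50)
    return KineticTraits(
        co2max=co2max, lp=lp, t35=t35, t50=t50, t70=t70,
        rate50_70=rate50_70, expected_max=expected_max,
    )


def traits_table(curves: list[FermentationCurve], **kwargs) -> pd.DataFrame:
    """Extract traits from many curves; one row per curve, meta columns kept."""
    rows = []
    for curve in curves:
        traits = extract_traits(curve, **kwargs)
        row = dict(curve.meta)
        row.update(traits.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def heritability(
    pheno: PhenotypeTable,
    trait: str,
    control_replicates: dict[str, list[float]],
) -> Optional[float]:
    """Broad-sense heritability (percent) from replicated control genotypes.

    ``h2 = 100 * (s2_progeny - s2_env) / s2_progeny`` where ``s2_env`` is the
    mean within-genotype replicate variance of the controls (parents and
    hybrid) and ``s2_progeny`` the variance of the per-segregant trait means.
    Clamped to [0, 100]; None when the progeny variance is zero.
    """
    controls = {k: np.asarray(v, float) for k, v in control_replicates.items()}
    replicated = {k: v for k, v in controls.items() if len(v) >= 2}
    if len(replicated) < 2:
        raise ValueError("need >= 2 replicated control genotypes")
    means = pheno.trait_means(trait)
    if len(means) < 10:
        raise ValueError(f"need >= 10 progeny, got {len(means)}")
    s2_progeny = float(np.var(means, ddof=1))
    if s2_progeny == 0:
        return None
    s2_env = float(np.mean([np.var(v, ddof=1) for v in replicated.values()]))
    h2 = 100.0 * (s2_progeny - s2_env) / s2_progeny
    return float(np.clip(h2, 0.0, 100.0))


def trait_correlations(
    pheno: PhenotypeTable, alpha: float = 0.001
) -> pd.DataFrame:
    """Pairwise Pearson correlations with Bonferroni-adjusted p-values.

    Returns a long frame (trait_a, trait_b, n, r, p, p_adj, significant) over
    unordered trait pairs including the diagonal; missing values are dropped
    pairwise. Pairs with a zero-variance member get ``r = NaN``.
    """
    wide = pheno.trait_wide()
    traits = list(wide.columns)
    n_tests = len(traits) * (len(traits) - 1) // 2
    rows = []
    for i, ta in enumerate(traits):
        for tb in traits[i:]:
            pair = wide[[ta, tb]].dropna() if ta != tb else wide[[ta]].dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(f"need >= 3 complete observations for {ta}/{tb}")
            if ta == tb:
                r, p = 1.0, 0.0
            else:
                a, b = pair[ta].to_numpy(), pair[tb].to_numpy()
                if np.std(a) == 0 or np.std(b) == 0:
                    r, p = float("nan"), float("nan")
                else:
                    r, p = stats.pearsonr(a, b)
            p_adj = min(1.0, p * max(1, n_tests)) if not math.isnan(p) else float("nan")
            rows.append(
                {
                    "trait_a": ta,
                    "trait_b": tb,
                    "n": n,
                    "r": r,
                    "p": p,
                    "p_adj": p_adj,
                    "significant": bool(p_adj <= alpha) if not math.isnan(p_adj) else False,
                }
            )
    return pd.DataFrame(rows)
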