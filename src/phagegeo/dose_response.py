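"""Four-parameter logistic (4PL) dose-response fitting for paired ±phage assays.

The assay design: host growth (OD600 at the 12 h endpoint, normalized to
no-ion, no-phage controls) is measured across a serial dilution of a single
inorganic salt, with and without lytic phage.  The half-maximal concentration
of the fitted curve is the ion's IC50 (direct toxicity, phage absent) or EC50
(concentration enabling lytic infection, phage present).  Comparing the two,
per ion, classifies the ion's role:

* ``enables_infection`` — EC50 significantly below IC50: the ion permits
  phage killing at concentrations harmless to the host.
* ``protective``        — EC50 significantly above IC50: phage presence
  shields the host from ion toxicity (the trivalent-metal pattern).
* ``toxic_only``        — both curves inhibit, thresholds indistinguishable.
* ``no_inhibition``     — the phage-free curve never inhibits within the
  tested range.

Significance is a disjoint 95% bootstrap percentile interval on the two
half-maximal concentrations (case resampling of wells).

The model, fitted on log10 concentration x = log10(c):

    y(x) = bottom + (top - bottom) / (1 + 10**(hill * (x - log10(half_max))))

with hill > 0.  Inhibition corresponds to top > bottom; a stimulated
(mirrored) response is captured by the same functional form with the roles of
top and bottom exchanged — both orientations are fitted and the lower
residual sum of squares wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateControlError,
    InsufficientDataError,
    InvalidConfigError,
    PairingError,
    SchemaError,
    UnstableFitError,
)

__all__ = [
    "DoseSeries",
    "FourPLFit",
    "ThresholdCall",
    "normalize_responses",
    "fit_4pl",
    "bootstrap_ci",
    "call_threshold",
    "series_from_plate",
    "analyze_plate",
    "fourpl",
    "CLASS_ENABLES",
    "CLASS_PROTECTIVE",
    "CLASS_TOXIC_ONLY",
    "CLASS_NO_INHIBITION",
]

CLASS_ENABLES = "enables_infection"
CLASS_PROTECTIVE = "protective"
CLASS_TOXIC_ONLY = "toxic_only"
CLASS_NO_INHIBITION = "no_inhibition"

#: fitted dynamic range below this fraction of the control response is
#: reported as no inhibition rather than an extrapolated half-max
MIN_DYNAMIC_RANGE = 0.20

_HILL_BOUNDS = (0.2, 10.0)


def fourpl(conc, top: float, bottom: float, half_max: float, hill: float):
    """Evaluate the 4PL curve at concentration(s) ``conc`` (mM)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / half_max) ** hill)


@dataclass
class DoseSeries:
    """One ion x one phage condition: concentration vs normalized response."""

    ion: str
    phage: str
    conc: np.ndarray
    response: np.ndarray
    controls: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.controls = np.asarray(self.controls, dtype=float)
        if self.conc.shape != self.response.shape:
            raise SchemaError("conc and response must have equal length")
        if np.any(self.conc <= 0):
            raise SchemaError("dose series concentrations must be positive; "
                              "zero-ion wells belong in `controls`")
        if not np.all(np.isfinite(self.response)) or np.any(self.response < 0):
            raise SchemaError("responses must be finite and nonnegative")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.conc).size)


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with the half-maximal concentration and its CI.

    ``half_max`` is the IC50 when ``phage == 'none'`` and the EC50 otherwise.
    ``direction`` records whether the response falls ("inhibition") or rises
    ("stimulation") with concentration.  A ``no_inhibition`` sentinel carries
    NaN for ``half_max`` and ``hill``.
    """

    ion: str
    phage: str
    top: float
    bottom: float
    hill: float
    half_max: float
    rss: float
    converged: bool
    direction: str = "inhibition"
    no_inhibition: bool = False
    ci_low: float = math.nan
    ci_high: float = math.nan

    def midpoint_response(self) -> float:
        return 0.5 * (self.top + self.bottom)


@dataclass
class ThresholdCall:
    """Paired ±phage verdict for one ion."""

    ion: str
    ic50_fit: FourPLFit
    ec50_fit: FourPLFit
    shifted: bool
    classification: str


def normalize_responses(raw, control_mean: float) -> np.ndarray:
    """Divide raw responses by the mean of control wells (no ion, no phage)."""
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise DegenerateControlError(
            f"control mean must be positive, got {control_mean!r}"
        )
    return np.asarray(raw, dtype=float) / control_mean


# ---------------------------------------------------------------------------
# fitting internals

_LN10 = math.log(10.0)


def _residual_factory(logc: np.ndarray, y: np.ndarray):
    def resid(theta):
        top, bottom, loghm, hill = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - loghm))) - y

    def jac(theta):
        top, bottom, loghm, hill = theta
        u = 10.0 ** (hill * (logc - loghm))
        denom = (1.0 + u) ** 2
        d_top = 1.0 / (1.0 + u)
        d_bottom = u / (1.0 + u)
        d_loghm = (top - bottom) * hill * _LN10 * u / denom
        d_hill = -(top - bottom) * _LN10 * (logc - loghm) * u / denom
        return np.column_stack([d_top, d_bottom, d_loghm, d_hill])

    return resid, jac


def _midpoint_guess(logc: np.ndarray, y: np.ndarray) -> float:
    """Initial log10(half_max): the concentration bracketing the response
    midpoint of per-concentration means."""
    order = np.argsort(logc)
    lx, ly = logc[order], y[order]
    ux = np.unique(lx)
    means = np.array([ly[lx == v].mean() for v in ux])
    mid = 0.5 * (means.max() + means.min())
    above = means >= mid
    for i in range(len(ux) - 1):
        if above[i] != above[i + 1]:
            return 0.5 * (ux[i] + ux[i + 1])
    return float(np.median(ux))


def _fit_arrays(conc: np.ndarray, y: np.ndarray, starts=None, tol: float = 1e-12):
    """Core least-squares fit; returns (top, bottom, loghm, hill, rss, ok)
    or None when no start converges.

    By default both curve orientations (inhibition and its mirror image) are
    tried and the lower-RSS solution wins; ``starts`` overrides the initial
    parameter vectors (used to warm-start bootstrap refits).
    """
    logc = np.log10(conc)
    lo_hm, hi_hm = logc.min() - 1.0, logc.max() + 1.0
    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-12)
    bounds = (
        [ymin - span, ymin - span, lo_hm, _HILL_BOUNDS[0]],
        [ymax + span, ymax + span, hi_hm, _HILL_BOUNDS[1]],
    )
    if starts is None:
        hm0 = np.clip(_midpoint_guess(logc, y), lo_hm, hi_hm)
        starts = [
            (ymax, ymin, hm0, 1.0),  # inhibition
            (ymin, ymax, hm0, 1.0),  # mirrored (stimulation)
        ]
    resid, jac = _residual_factory(logc, y)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(
                resid,
                jac=jac,
                x0=x0,
                bounds=bounds,
                method="trf",
                xtol=tol,
                ftol=tol,
                gtol=tol,
                max_nfev=400,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[4]:
            top, bottom, loghm, hill = (float(v) for v in res.x)
            best = (top, bottom, loghm, hill, rss, bool(res.success))
    return best


def _control_level(series: DoseSeries) -> float:
    if series.controls.size:
        return float(np.mean(series.controls))
    return 1.0  # responses are normalized; controls map to ~1 by construction


def _sentinel(series: DoseSeries, top: float, bottom: float, rss: float) -> FourPLFit:
    return FourPLFit(
        ion=series.ion,
        phage=series.phage,
        top=top,
        bottom=bottom,
        hill=math.nan,
        half_max=math.nan,
        rss=rss,
        converged=True,
        no_inhibition=True,
    )


def fit_4pl(series: DoseSeries) -> FourPLFit:
    """Least-squares 4PL fit of one dose series on log10 concentration.

    Flat responses, or a fitted dynamic range below
    ``MIN_DYNAMIC_RANGE`` x control level, yield a ``no_inhibition``
    sentinel rather than an extrapolated half-max.  Fewer than 4 distinct
    nonzero concentrations raise :class:`InsufficientDataError`.
    """
    if series.n_distinct < 4:
        raise InsufficientDataError(
            f"{series.ion}/{series.phage}: {series.n_distinct} distinct "
            "concentrations (need >= 4)"
        )
    y = series.response
    level = _control_level(series)
    if np.ptp(y) < 1e-12:
        return _sentinel(series, float(y.max()), float(y.min()), 0.0)
    fitted = _fit_arrays(series.conc, y)
    if fitted is None:
        return _sentinel(series, float(y.max()), float(y.min()), math.nan)
    top, bottom, loghm, hill, rss, ok = fitted
    direction = "inhibition" if top >= bottom else "stimulation"
    hi, lo = max(top, bottom), min(top, bottom)
    if (hi - lo) < MIN_DYNAMIC_RANGE * level:
        return _sentinel(series, hi, lo, rss)
    return FourPLFit(
        ion=series.ion,
        phage=series.phage,
        top=hi,
        bottom=lo,
        hill=hill,
        half_max=10.0**loghm,
        rss=rss,
        converged=ok,
        direction=direction,
    )


def bootstrap_ci(
    series: DoseSeries,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the half-maximal concentration.

    Wells (concentration, response pairs) are resampled with replacement;
    resamples with < 4 distinct concentrations, failed optimizations, or
    no-inhibition refits count as failures, and > 50% failures raise
    :class:`UnstableFitError`.
    """
    if n_boot < 100:
        raise InvalidConfigError("n_boot must be >= 100")
    if not 0 < alpha < 1:
        raise InvalidConfigError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = series.conc.size
    level = _control_level(series)
    # warm-start every refit from the full-data solution (both orientations
    # were already compared there); keeps resampling stable and fast
    full = _fit_arrays(series.conc, series.response)
    warm = None if full is None else [np.array(full[:4])]
    estimates: list[float] = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c, y = series.conc[idx], series.response[idx]
        if np.unique(c).size < 4 or np.ptp(y) < 1e-12:
            failures += 1
            continue
        fitted = _fit_arrays(c, y, starts=warm, tol=1e-9)
        if fitted is None:
            failures += 1
            continue
        top, bottom, loghm, hill, rss, ok = fitted
        if abs(top - bottom) < MIN_DYNAMIC_RANGE * level or not ok:
            failures += 1
            continue
        estimates.append(10.0**loghm)
    if failures > 0.5 * n_boot:
        raise UnstableFitError(
            f"{failures}/{n_boot} bootstrap refits failed for "
            f"{series.ion}/{series.phage}"
        )
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _cis_disjoint(a: FourPLFit, b: FourPLFit) -> bool:
    if any(math.isnan(v) for v in (a.ci_low, a.ci_high, b.ci_low, b.ci_high)):
        return False
    return a.ci_high < b.ci_low or b.ci_high < a.ci_low


def call_threshold(ic_fit: FourPLFit, ec_fit: FourPLFit) -> ThresholdCall:
    """Classify an ion from its paired phage-free (IC50) and phage-present
    (EC50) fits, using the disjoint-CI significance rule."""
    if ic_fit.ion != ec_fit.ion:
        raise PairingError(f"paired fits for {ic_fit.ion!r} vs {ec_fit.ion!r}")
    if ic_fit.no_inhibition:
        return ThresholdCall(ic_fit.ion, ic_fit, ec_fit, False, CLASS_NO_INHIBITION)
    if ec_fit.no_inhibition:
        return ThresholdCall(ic_fit.ion, ic_fit, ec_fit, False, CLASS_TOXIC_ONLY)
    shifted = _cis_disjoint(ic_fit, ec_fit)
    if shifted and ec_fit.half_max < ic_fit.half_max:
        cls = CLASS_ENABLES
    elif shifted:
        cls = CLASS_PROTECTIVE
    else:
        cls = CLASS_TOXIC_ONLY
    return ThresholdCall(ic_fit.ion, ic_fit, ec_fit, shifted, cls)


# ---------------------------------------------------------------------------
# plate-level pipeline

def series_from_plate(
    plate: pd.DataFrame, response_col: str = "od600"
) -> list[DoseSeries]:
    """Split a long-format plate table into normalized dose series.

    Responses are normalized to the zero-concentration control wells of the
    phage-free condition (the culture with no added ion and no phage); if the
    plate has no phage-free controls, each condition's own zero-concentration
    wells are used instead.
    """
    required = {"ion", "conc_mM", "phage", response_col}
    missing = required - set(plate.columns)
    if missing:
        raise SchemaError(f"plate table missing columns: {sorted(missing)}")
    ctrl = plate[plate["conc_mM"] == 0]
    base = ctrl[ctrl["phage"] == "none"]
    series = []
    for (ion, phage), grp in plate[plate["conc_mM"] > 0].groupby(
        ["ion", "phage"], sort=True
    ):
        cond_ctrl = base if len(base) else ctrl[ctrl["phage"] == phage]
        if not len(cond_ctrl):
            raise DegenerateControlError(
                f"no zero-concentration control wells for condition {phage!r}"
            )
        cmean = float(cond_ctrl[response_col].mean())
        series.append(
            DoseSeries(
                ion=str(ion),
                phage=str(phage),
                conc=grp["conc_mM"].to_numpy(float),
                response=normalize_responses(grp[response_col].to_numpy(float), cmean),
                controls=normalize_responses(cond_ctrl[response_col].to_numpy(float), cmean),
            )
        )
    return series


def analyze_plate(
    plate: pd.DataFrame,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    response_col: str = "od600",
    minus_phage: str = "none",
) -> tuple[list[FourPLFit], list[ThresholdCall]]:
    """Fit every (ion, phage) series on a plate and call thresholds per ion.

    Returns all fits (with bootstrap CIs where defined) and one
    :class:`ThresholdCall` per ion that was measured in both the phage-free
    and a phage-present condition.
    """
    rng = np.random.default_rng(seed)
    fits: dict[tuple[str, str], FourPLFit] = {}
    for s in series_from_plate(plate, response_col=response_col):
        fit = fit_4pl(s)
        if not fit.no_inhibition:
            sub = int(rng.integers(0, 2**31 - 1))
            try:
                lo, hi = bootstrap_ci(s, n_boot=n_boot, alpha=alpha, seed=sub)
            except UnstableFitError:
                lo = hi = math.nan
            fit = replace(fit, ci_low=lo, ci_high=hi)
        fits[(s.ion, s.phage)] = fit
    calls = []
    for (ion, phage), ec in sorted(fits.items()):
        if phage == minus_phage:
            continue
        ic = fits.get((ion, minus_phage))
        if ic is not None:
            calls.append(call_threshold(ic, ec))
    return list(fits.values()), calls
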