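"""Batch-culture kinetics: growth rates, specific uptake/excretion fluxes,
yields, and saturation-kinetics fits.

The estimators implement the standard exponential-phase regression recipe
for closed batch cultures:

* the growth rate mu is the slope of ln(biomass) against time over the
  exponential window, pooled across biological replicates;
* the specific flux q of a compound is the slope of its culture
  concentration against biomass/mu, so that ``dC/dt = q X(t)`` integrates
  to a straight line; a positive q is excretion, a negative q uptake;
* confidence intervals come from the regression slope's standard error and
  the t distribution (99% for fluxes and growth, 95% for kinetic fits).

Headspace gas amounts (mmol) are converted to culture concentrations per
liquid volume before the flux regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CultureTimeSeries",
    "FluxEstimate",
    "FluxEstimateSet",
    "KineticFit",
    "BoundedExponentialFit",
    "OdDcwFit",
    "YieldTable",
    "fit_od_dcw",
    "detect_exponential_window",
    "fit_growth_rate",
    "estimate_specific_flux",
    "estimate_fluxes",
    "compute_yields",
    "fit_monod",
    "fit_bounded_exponential",
    "headspace_moles",
    "GAS_CONSTANT",
    "ATM_PA",
]

GAS_CONSTANT = 8.31446261815324  # J mol-1 K-1
ATM_PA = 101325.0  # Pa per standard atmosphere

#: compounds carried by the standard time-series schema; gases are headspace
#: amounts in mmol, acids aqueous concentrations in mM
GAS_COLUMNS = {"ch4": "ch4_mmol", "o2": "o2_mmol", "co2": "co2_mmol"}
ACID_COLUMNS = {"formate": "formate_mM", "acetate": "acetate_mM"}
COMPOUND_COLUMNS = {**GAS_COLUMNS, **ACID_COLUMNS}

#: default OD600 -> gDCW/L conversion factor for the modeled methanotroph
OD_TO_GDCW = 0.26


@dataclass
class CultureTimeSeries:
    """Replicated batch-culture measurements over time.

    ``data`` holds one row per (time, replicate) with columns ``time_h``,
    ``replicate``, a biomass column (``od600`` or ``gdcw_per_l``), headspace
    gas amounts ``ch4_mmol``/``o2_mmol``/``co2_mmol`` and aqueous acid
    concentrations ``formate_mM``/``acetate_mM``.  ``metadata`` carries the
    vessel geometry (liquid/headspace volumes in L), temperature (K),
    pressure (atm), the initial headspace percentages, and — for synthetic
    series — the generator ground truth.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time_h", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"time series lacks required columns {sorted(missing)}")
        if self.biomass_column is None:
            raise ValueError("time series needs an 'od600' or 'gdcw_per_l' column")
        for _, group in self.data.groupby("replicate"):
            t = group["time_h"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError("times must be strictly increasing within a replicate")
        if (self.data[self.biomass_column] < 0).any():
            raise ValueError("biomass must be non-negative")

    # -- accessors ----------------------------------------------------------

    @property
    def biomass_column(self) -> str | None:
        for col in ("gdcw_per_l", "od600"):
            if col in self.data.columns:
                return col
        return None

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.data["time_h"].to_numpy())

    def biomass_gdcw(self, od_factor: float = OD_TO_GDCW) -> np.ndarray:
        """Biomass in gDCW/L for every row, converting OD600 if necessary."""
        col = self.biomass_column
        values = self.data[col].to_numpy(dtype=float)
        return values * od_factor if col == "od600" else values

    def concentration(self, compound: str, od_factor: float = OD_TO_GDCW) -> np.ndarray:
        """Culture concentration of ``compound`` per liquid volume (mM).

        Headspace gas amounts (mmol) are divided by the liquid volume;
        aqueous acids are already mM.
        """
        if compound in GAS_COLUMNS:
            v_liq = self.metadata.get("liquid_volume_l")
            if not v_liq or v_liq <= 0:
                raise ValueError(
                    "liquid_volume_l metadata required to normalize gas amounts"
                )
            return self.data[GAS_COLUMNS[compound]].to_numpy(dtype=float) / v_liq
        if compound in ACID_COLUMNS:
            return self.data[ACID_COLUMNS[compound]].to_numpy(dtype=float)
        raise KeyError(f"unknown compound {compound!r}")

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key}={value}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CultureTimeSeries":
        metadata: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                try:
                    metadata[key.strip()] = float(value)
                except ValueError:
                    metadata[key.strip()] = value
                body_start = i + 1
            else:
                break
        from io import StringIO

        data = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        return cls(data=data, metadata=metadata)


@dataclass
class FluxEstimate:
    """A regression point estimate with its 99% confidence interval."""

    value: float
    ci_lower: float
    ci_upper: float
    stderr: float
    n_points: int

    def covers(self, truth: float) -> bool:
        return self.ci_lower <= truth <= self.ci_upper


@dataclass
class FluxEstimateSet:
    """Exponential-phase growth rate and specific fluxes with 99% CIs.

    ``fluxes`` maps compound names (ch4, o2, co2, formate, acetate) to
    :class:`FluxEstimate`; negative values are uptake, positive excretion.
    """

    growth_rate: FluxEstimate
    fluxes: dict[str, FluxEstimate]
    window: tuple[float, float]

    def to_dict(self) -> dict:
        def enc(e: FluxEstimate) -> dict:
            return {
                "value": e.value,
                "ci99_lower": e.ci_lower,
                "ci99_upper": e.ci_upper,
                "stderr": e.stderr,
                "n": e.n_points,
            }

        return {
            "growth_rate_per_h": enc(self.growth_rate),
            "specific_fluxes_mmol_per_h_per_gDCW": {
                k: enc(v) for k, v in self.fluxes.items()
            },
            "window_h": list(self.window),
        }


@dataclass
class KineticFit:
    """Monod fit: mu = mumax * S / (Km + S), with 95% CIs."""

    mumax: float
    km: float
    mumax_ci95: tuple[float, float]
    km_ci95: tuple[float, float]
    residual_ss: float
    n_points: int


@dataclass
class BoundedExponentialFit:
    """Fit of y = a (1 - exp(-b x)); ``asymptote`` is the plateau a."""

    asymptote: float
    rate: float
    asymptote_ci95: tuple[float, float]
    rate_ci95: tuple[float, float]
    residual_ss: float
    n_points: int


@dataclass
class OdDcwFit:
    """OD600 <-> dry-cell-weight conversion regression."""

    slope: float
    intercept: float
    r2_adjusted: float
    slope_pvalue: float
    through_origin: bool


@dataclass
class YieldTable:
    """Per-compound yields over the whole culture (per mmol CH4 consumed)."""

    compound_yields: dict[str, float]  # mmol mmol-CH4^-1
    biomass_yield: float  # gDCW mmol-CH4^-1
    ch4_consumed_mmol: float


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


def _slope_ci(x: np.ndarray, y: np.ndarray, alpha: float) -> FluxEstimate:
    """Least-squares slope with a t-based confidence interval."""
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = n - 2
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("regression abscissa is constant")
    stderr = math.sqrt(np.sum(resid**2) / dof / sxx) if dof > 0 else float("inf")
    half = stats.t.ppf(1 - alpha / 2, dof) * stderr
    return FluxEstimate(float(slope), float(slope - half), float(slope + half),
                        float(stderr), n)


def fit_od_dcw(
    pairs: Sequence[tuple[float, float]] | np.ndarray, through_origin: bool = True
) -> OdDcwFit:
    """Fit gDCW/L = factor * OD600 (+ intercept unless ``through_origin``).

    Reports the adjusted R2 and the slope p-value so the through-origin and
    free-intercept variants can be compared.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (od600, gdcw_per_l) pairs")
    od, dcw = arr[:, 0], arr[:, 1]
    if np.allclose(od, 0):
        raise ValueError("all OD600 values are zero")
    if np.ptp(od) == 0:
        raise ValueError("OD600 values are all identical; slope is undefined")
    import statsmodels.api as sm

    X = od[:, None] if through_origin else sm.add_constant(od)
    fit = sm.OLS(dcw, X).fit()
    slope = float(fit.params[-1])
    intercept = 0.0 if through_origin else float(fit.params[0])
    return OdDcwFit(
        slope=slope,
        intercept=intercept,
        r2_adjusted=float(fit.rsquared_adj),
        slope_pvalue=float(fit.pvalues[-1]),
        through_origin=through_origin,
    )


def detect_exponential_window(
    series: CultureTimeSeries,
    min_points: int = 4,
    r2_threshold: float = 0.98,
    od_factor: float = OD_TO_GDCW,
) -> tuple[float, float]:
    """Locate the exponential-growth window.

    Scans contiguous windows of the sampled time points and selects the
    longest window with at least ``min_points`` distinct times whose pooled
    ln(biomass)-vs-time regression achieves R2 >= ``r2_threshold`` (ties
    broken by higher R2).  The selected window is then trimmed greedily:
    an endpoint time is dropped while doing so cuts the residual variance
    by a quarter or more, which sheds lag or plateau points that a long
    window can
    otherwise absorb without breaching the threshold.  Raises when no
    window qualifies, in which case a window must be supplied manually to
    the estimators.
    """
    times = series.times
    if len(times) < min_points:
        raise ValueError(f"need at least {min_points} time points")
    t_all = series.data["time_h"].to_numpy(dtype=float)
    x_all = series.biomass_gdcw(od_factor)

    def window_fit(i: int, j: int) -> tuple[float, float] | None:
        """(r2, slope) of the pooled log-linear fit on times[i..j]."""
        mask = (t_all >= times[i]) & (t_all <= times[j])
        x = x_all[mask]
        if (x <= 0).any():
            return None
        t = t_all[mask]
        y = np.log(x)
        slope, intercept = np.polyfit(t, y, 1)
        ss_res = np.sum((y - slope * t - intercept) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return r2, slope

    best: tuple[int, float, int, int] | None = None  # (length, r2, i, j)
    for i in range(len(times)):
        for j in range(i + min_points - 1, len(times)):
            fit = window_fit(i, j)
            if fit is None or fit[1] <= 0:
                continue
            if fit[0] >= r2_threshold:
                key = (j - i, fit[0])
                if best is None or key > (best[0], best[1]):
                    best = (j - i, fit[0], i, j)
    if best is None:
        raise ValueError(
            f"no contiguous window of >= {min_points} points reaches "
            f"R2 >= {r2_threshold}; supply the exponential window manually"
        )
    _, r2, i, j = best
    while j - i + 1 > min_points and (1.0 - r2) > 1e-12:
        candidates = []
        for ii, jj in ((i + 1, j), (i, j - 1), (i + 1, j - 1)):
            if jj - ii + 1 < min_points:
                continue
            fit = window_fit(ii, jj)
            if fit is not None and fit[1] > 0:
                candidates.append((fit[0], ii, jj))
        if not candidates:
            break
        cand_r2, ii, jj = max(candidates)
        if (1.0 - cand_r2) <= 0.75 * (1.0 - r2):
            r2, i, j = cand_r2, ii, jj
        else:
            break
    return (float(times[i]), float(times[j]))


def _window_mask(series: CultureTimeSeries, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    t = series.data["time_h"].to_numpy(dtype=float)
    return (t >= t0) & (t <= t1)


def fit_growth_rate(
    series: CultureTimeSeries,
    window: tuple[float, float],
    od_factor: float = OD_TO_GDCW,
) -> FluxEstimate:
    """Growth rate: slope of ln(biomass) vs time pooled over replicates.

    The 99% CI uses the slope standard error and the t distribution with
    n - 2 degrees of freedom.
    """
    mask = _window_mask(series, window)
    t = series.data["time_h"].to_numpy(dtype=float)[mask]
    x = series.biomass_gdcw(od_factor)[mask]
    if len(t) < 3:
        raise ValueError("growth window must contain at least 3 measurements")
    if (x <= 0).any():
        raise ValueError("non-positive biomass inside the growth window")
    return _slope_ci(t, np.log(x), alpha=0.01)


def estimate_specific_flux(
    series: CultureTimeSeries,
    compound: str,
    mu: float,
    window: tuple[float, float],
    od_factor: float = OD_TO_GDCW,
) -> FluxEstimate:
    """Specific flux of ``compound``: slope of concentration vs biomass/mu.

    Under exponential growth the integrated mass balance is ``C(t) = C0 +
    (q/mu) (X(t) - X0)``, so regressing C on X/mu recovers q directly, in
    mmol h-1 gDCW-1.  Positive q is excretion, negative uptake.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    mask = _window_mask(series, window)
    if mask.sum() < 3:
        raise ValueError("flux window must contain at least 3 measurements")
    x = series.biomass_gdcw(od_factor)[mask] / mu
    c = series.concentration(compound, od_factor)[mask]
    return _slope_ci(x, c, alpha=0.01)


def estimate_fluxes(
    series: CultureTimeSeries,
    window: tuple[float, float] | None = None,
    compounds: Iterable[str] = COMPOUND_COLUMNS,
    od_factor: float = OD_TO_GDCW,
) -> FluxEstimateSet:
    """Growth rate plus specific fluxes for every compound, with 99% CIs."""
    if window is None:
        window = detect_exponential_window(series, od_factor=od_factor)
    mu = fit_growth_rate(series, window, od_factor)
    fluxes = {
        name: estimate_specific_flux(series, name, mu.value, window, od_factor)
        for name in compounds
        if COMPOUND_COLUMNS[name] in series.data.columns
    }
    return FluxEstimateSet(growth_rate=mu, fluxes=fluxes, window=window)


def compute_yields(
    series: CultureTimeSeries, od_factor: float = OD_TO_GDCW
) -> YieldTable:
    """Yields over the full culture period, per mmol of CH4 consumed.

    Compound yields are change in amount per total methane consumed; the
    biomass yield is in gDCW per mmol CH4 using the liquid volume.
    """
    mean = series.data.groupby("time_h").mean(numeric_only=True)
    first, last = mean.iloc[0], mean.iloc[-1]
    d_ch4 = first["ch4_mmol"] - last["ch4_mmol"]
    if d_ch4 <= 0:
        raise ValueError("no methane consumption over the culture period")
    v_liq = series.metadata.get("liquid_volume_l", float("nan"))
    yields: dict[str, float] = {}
    for name, col in COMPOUND_COLUMNS.items():
        if name == "ch4" or col not in mean.columns:
            continue
        delta = last[col] - first[col]
        if col.endswith("_mM"):  # aqueous mM -> mmol via liquid volume
            delta *= v_liq
        yields[name] = float(delta / d_ch4)
    bio_col = series.biomass_column
    x0 = first[bio_col] * (od_factor if bio_col == "od600" else 1.0)
    x1 = last[bio_col] * (od_factor if bio_col == "od600" else 1.0)
    biomass_yield = float((x1 - x0) * v_liq / d_ch4)
    return YieldTable(
        compound_yields=yields,
        biomass_yield=biomass_yield,
        ch4_consumed_mmol=float(d_ch4),
    )


# ---------------------------------------------------------------------------
# nonlinear kinetic fits
# ---------------------------------------------------------------------------


def _curve_ci95(popt, pcov, dof):
    half = stats.t.ppf(0.975, dof) * np.sqrt(np.diag(pcov))
    return [(float(p - h), float(p + h)) for p, h in zip(popt, half)]


def fit_monod(
    growth_rates: Sequence[float], substrate_concentrations: Sequence[float]
) -> KineticFit:
    """Nonlinear least-squares Monod fit mu = mumax S / (Km + S).

    Initialized at mumax0 = max(mu), Km0 = median(S); 95% CIs from the
    parameter covariance and the t distribution.  The fit is invariant to
    the ordering of the input points.
    """
    mu = np.asarray(growth_rates, dtype=float)
    s = np.asarray(substrate_concentrations, dtype=float)
    if mu.shape != s.shape or mu.size < 3:
        raise ValueError("need at least 3 matched (S, mu) pairs")
    if (s <= 0).any():
        raise ValueError("substrate concentrations must be positive")

    def monod(sv, mumax, km):
        return mumax * sv / (km + sv)

    p0 = (float(mu.max()), float(np.median(s)))
    try:
        popt, pcov = optimize.curve_fit(monod, s, mu, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"Monod fit did not converge from p0={p0}: {exc}") from exc
    resid = mu - monod(s, *popt)
    dof = max(mu.size - 2, 1)
    ci = _curve_ci95(popt, pcov, dof)
    return KineticFit(
        mumax=float(popt[0]),
        km=float(popt[1]),
        mumax_ci95=ci[0],
        km_ci95=ci[1],
        residual_ss=float(np.sum(resid**2)),
        n_points=int(mu.size),
    )


def fit_bounded_exponential(
    x: Sequence[float], y: Sequence[float]
) -> BoundedExponentialFit:
    """Fit the bounded exponential y = a (1 - exp(-b x)).

    The asymptote a is the saturation plateau (e.g. the maximal
    oxygen-to-methane uptake flux ratio when fitted against the initial
    headspace ratio).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if (x < 0).any():
        raise ValueError("x must be non-negative")

    def bexp(xv, a, b):
        return a * (1.0 - np.exp(-b * xv))

    xpos = x[x > 0]
    p0 = (float(y.max()) or 1.0, 1.0 / float(np.median(xpos)) if xpos.size else 1.0)
    try:
        popt, pcov = optimize.curve_fit(bexp, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"bounded-exponential fit did not converge from p0={p0}: {exc}"
        ) from exc
    resid = y - bexp(x, *popt)
    dof = max(x.size - 2, 1)
    ci = _curve_ci95(popt, pcov, dof)
    return BoundedExponentialFit(
        asymptote=float(popt[0]),
        rate=float(popt[1]),
        asymptote_ci95=ci[0],
        rate_ci95=ci[1],
        residual_ss=float(np.sum(resid**2)),
        n_points=int(x.size),
    )


def headspace_moles(
    percent_vv: float,
    headspace_volume_l: float,
    temperature_k: float,
    pressure_atm: float = 1.0,
) -> float:
    """Ideal-gas amount (mmol) of a gas at ``percent_vv`` of the headspace.

    n = P V (pct/100) / (R T) with P in Pa, V in m3 and R = 8.31446
    J mol-1 K-1; the result is scaled to mmol.
    """
    if not 0 <= percent_vv <= 100:
        raise ValueError("percent_vv must be in [0, 100]")
    if headspace_volume_l <= 0 or temperature_k <= 0 or pressure_atm <= 0:
        raise ValueError("volume, temperature and pressure must be positive")
    v_m3 = headspace_volume_l * 1e-3
    mol = pressure_atm * ATM_PA * v_m3 * (percent_vv / 100.0) / (GAS_CONSTANT * temperature_k)
    return mol * 1000.0
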