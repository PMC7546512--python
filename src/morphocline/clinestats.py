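"""Correlation of morphology and color with altitude and latitude.

Variables come in two kinds — categorical morphology (ordinal states)
and continuous color (RGB channel means) — and are related to two
environmental axes: altitude in meters (continuous) and latitude
(clumped into discrete collection areas, so treated categorically).
Method dispatch follows the variable types:

====================  ==================  ===========================
variable              vs altitude         vs latitude
====================  ==================  ===========================
categorical, 2-state  point-biserial      Cramér's V
categorical, 3+       ML polyserial       Cramér's V
continuous (RGB)      Pearson             polyserial (ordinal 4-bin)
====================  ==================  ===========================

All coefficients share the range |r| <= 1, so sorted absolute-value
series from different methods can be compared; a series is summarized
by the mean of its absolute coefficients.

Latitude enters the Cramér's V column either as the distinct sampled
latitude values treated as categories (``latitude_mode="categories"``,
the default, which matches the published series for this material) or
binned into the four ordered collection bands
(``latitude_mode="bins"``).  For polyserial against continuous color
the four ordered bins are always used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import norm

__all__ = [
    "EnvironmentVector",
    "bin_latitude",
    "point_biserial",
    "polyserial_ml",
    "cramers_v",
    "CorrelationSeries",
    "correlate_with_environment",
    "compare_series",
    "LinearFit",
    "brightness_altitude_fits",
    "aic_model_compare",
]


@dataclass
class EnvironmentVector:
    """Collection environment of one specimen."""

    specimen_id: str
    altitude: float          # meters
    latitude: float          # decimal degrees, north positive
    latitude_bin: int = -1   # ordinal 0-3; derived when negative

    def __post_init__(self):
        derived = bin_latitude(self.latitude)
        if self.latitude_bin < 0:
            self.latitude_bin = derived
        elif self.latitude_bin != derived:
            raise ValueError(
                f"latitude_bin {self.latitude_bin} inconsistent with "
                f"latitude {self.latitude} (expected {derived})"
            )


def bin_latitude(lat: float) -> int:
    """Four ordered latitude bands: [0] >= 0°, [1] (-10°, 0°), [2] [-15°, -10°], [3] < -15°.

    The published band limits leave (-5°, -10°) formally unassigned; the
    nearest-interval extension folds it into band 1.  No studied
    specimen falls in the gap.
    """
    if not -90 <= lat <= 90:
        raise ValueError(f"latitude out of range: {lat}")
    if lat >= 0:
        return 0
    if lat > -10:
        return 1
    if lat >= -15:
        return 2
    return 3


# --------------------------------------------------------------------------
# coefficients


def _pairwise(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def point_biserial(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of continuous ``x`` with dichotomous ``y`` coded 0/1."""
    x, y = _pairwise(x, y)
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValueError(f"y must have exactly 2 observed values, got {len(levels)}")
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    return float(stats.pointbiserialr((y == levels[1]).astype(int), x)[0])


def polyserial_ml(
    x: Sequence[float],
    y: Sequence[int],
    full: bool = False,
):
    """Maximum-likelihood polyserial correlation of continuous x and ordinal y.

    Models (x, y*) as bivariate normal with y observed by thresholding
    the latent y*.  The log-likelihood

    ``sum_i log phi(z_i) + log[Phi((tau_{y_i} - rho z_i)/sqrt(1-rho^2))
    - Phi((tau_{y_i - 1} - rho z_i)/sqrt(1-rho^2))]``

    is maximized jointly over rho and the thresholds tau, with x
    standardized by its sample mean and (n-1) standard deviation.  The
    optimizer works on atanh(rho) and log threshold spacings, starting
    from the two-step estimate.  Returns rho, or a result dict with
    ``full=True``.
    """
    x, y = _pairwise(x, y)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    cats, ycode = np.unique(y, return_inverse=True)
    if len(cats) < 2:
        raise ValueError("y has a single observed category")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    z = (x - x.mean()) / x.std(ddof=1)
    counts = np.bincount(ycode)
    cum = np.cumsum(counts)[:-1] / n
    tau0 = norm.ppf(cum)
    r = float(np.corrcoef(x, y)[0, 1])
    rho0 = np.sqrt((n - 1) / n) * np.std(y, ddof=1) * r / norm.pdf(tau0).sum()
    rho0 = float(np.clip(rho0, -0.95, 0.95))

    def unpack(p):
        rho = np.tanh(p[0])
        tau = np.concatenate([[p[1]], p[1] + np.cumsum(np.exp(p[2:]))])
        return rho, tau

    def nll(p):
        rho, tau = unpack(p)
        s = np.sqrt(1.0 - rho * rho)
        bounds = np.concatenate([[-np.inf], tau, [np.inf]])
        hi = norm.cdf((bounds[ycode + 1] - rho * z) / s)
        lo = norm.cdf((bounds[ycode] - rho * z) / s)
        pr = hi - lo
        if np.any(pr <= 1e-300):
            return 1e12
        return -float(np.sum(norm.logpdf(z) + np.log(pr)))

    p0 = np.concatenate(
        [[np.arctanh(rho0)], [tau0[0]], np.log(np.maximum(np.diff(tau0), 1e-3))]
    )
    res = optimize.minimize(
        nll, p0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
    )
    if not res.success:
        warnings.warn(f"polyserial optimizer: {res.message}", stacklevel=2)
    rho, tau = unpack(res.x)
    rho = float(rho)
    if full:
        return {
            "rho": rho,
            "thresholds": tau,
            "rho_two_step": rho0,
            "loglik": -res.fun,
            "converged": bool(res.success),
            "n": n,
        }
    return rho


def cramers_v(x: Sequence, y: Sequence, corrected: bool = False) -> float:
    """Cramér's V between two categorical vectors.

    The plain variant is ``sqrt(chi2 / (n * min(r-1, c-1)))``.  With
    ``corrected=True`` the Bergsma bias correction subtracts the
    independence expectation of phi² and shrinks the table dimensions,
    so weak associations in small tables collapse toward 0 instead of
    sitting at their chance level.
    """
    sx = pd.Series(x)
    sy = pd.Series(y)
    keep = sx.notna() & sy.notna()
    tab = pd.crosstab(sx[keep], sy[keep]).to_numpy()
    r, c = tab.shape
    if r < 2 or c < 2:
        raise ValueError("both variables need >= 2 observed categories")
    n = tab.sum()
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    phi2 = chi2 / n
    if not corrected:
        return float(np.sqrt(phi2 / min(r - 1, c - 1)))
    phi2c = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    rc = r - (r - 1) ** 2 / (n - 1)
    cc = c - (c - 1) ** 2 / (n - 1)
    return float(np.sqrt(phi2c / min(rc - 1, cc - 1)))


# --------------------------------------------------------------------------
# series


@dataclass
class SeriesEntry:
    variable_id: str
    method: str
    coefficient: float
    n_used: int


@dataclass
class CorrelationSeries:
    """Per-variable association coefficients against one environmental axis."""

    target: str
    entries: list[SeriesEntry] = field(default_factory=list)

    @property
    def abs_sorted(self) -> np.ndarray:
        vals = np.abs([e.coefficient for e in self.entries if not np.isnan(e.coefficient)])
        return np.sort(vals)[::-1]

    @property
    def average(self) -> float:
        return float(np.mean(self.abs_sorted))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.variable_id, e.method, e.coefficient, e.n_used) for e in self.entries],
            columns=["variable", "method", "coefficient", "n"],
        )


def _env_frame(env) -> pd.DataFrame:
    if isinstance(env, pd.DataFrame):
        df = env.copy()
        if "latitude_bin" not in df:
            df["latitude_bin"] = [bin_latitude(v) for v in df["latitude"]]
        return df
    return pd.DataFrame(
        {
            "specimen_id": [e.specimen_id for e in env],
            "altitude": [e.altitude for e in env],
            "latitude": [e.latitude for e in env],
            "latitude_bin": [e.latitude_bin for e in env],
        }
    )


def correlate_with_environment(
    variables: pd.DataFrame,
    env,
    target: Literal["altitude", "latitude"],
    kinds: dict[str, str] | None = None,
    latitude_mode: Literal["categories", "bins"] = "categories",
) -> CorrelationSeries:
    """Build a correlation series for every variable column against one axis.

    ``variables`` is a specimen-by-variable DataFrame aligned with
    ``env`` (a DataFrame with ``altitude``/``latitude`` columns or a
    sequence of :class:`EnvironmentVector`).  ``kinds`` maps column
    names to ``"categorical"`` or ``"continuous"``; unlisted columns
    default to categorical for integer dtypes and continuous otherwise.
    Missing cells are dropped pairwise per variable.  A variable with
    fewer than 2 observed states yields a NaN coefficient, which is
    excluded from the series average.
    """
    envf = _env_frame(env)
    if len(envf) != len(variables):
        raise ValueError("variables and environment tables differ in length")
    series = CorrelationSeries(target=target)
    for col in variables.columns:
        vals = variables[col]
        kind = (kinds or {}).get(
            col,
            "categorical" if pd.api.types.is_integer_dtype(vals.dropna().convert_dtypes())
            else "continuous",
        )
        try:
            if target == "altitude":
                alt = envf["altitude"].to_numpy(float)
                v = vals.to_numpy(float)
                keep = ~(np.isnan(v) | np.isnan(alt))
                if kind == "categorical":
                    k = len(np.unique(v[keep]))
                    if k == 2:
                        coef = point_biserial(alt, v)
                        method = "point_biserial"
                    else:
                        coef = polyserial_ml(alt, v[keep].astype(int))
                        method = "polyserial"
                else:
                    coef = float(stats.pearsonr(alt[keep], v[keep])[0])
                    method = "pearson"
                n_used = int(keep.sum())
            else:
                if kind == "categorical":
                    lat_cat = (
                        envf["latitude"]
                        if latitude_mode == "categories"
                        else envf["latitude_bin"]
                    )
                    coef = cramers_v(vals, lat_cat, corrected=True)
                    method = "cramers_v"
                    n_used = int(vals.notna().sum())
                else:
                    v = vals.to_numpy(float)
                    lbin = envf["latitude_bin"].to_numpy()
                    keep = ~np.isnan(v)
                    coef = polyserial_ml(v[keep], lbin[keep])
                    method = "polyserial"
                    n_used = int(keep.sum())
        except ValueError:
            coef, method, n_used = float("nan"), "undefined", 0
        series.entries.append(SeriesEntry(str(col), method, coef, n_used))
    return series


def compare_series(a: CorrelationSeries, b: CorrelationSeries):
    """Signed difference of series averages, plus the sorted series.

    The two series are sorted independently (by descending absolute
    coefficient) for plotting; the scalar comparison is
    ``a.average - b.average``.
    """
    return {
        "difference": a.average - b.average,
        "average_a": a.average,
        "average_b": b.average,
        "sorted_a": a.abs_sorted,
        "sorted_b": b.abs_sorted,
    }


# --------------------------------------------------------------------------
# brightness regressions


@dataclass
class LinearFit:
    variable_id: str
    slope: float        # per meter
    intercept: float
    p_value: float      # two-sided t test on the slope
    r_squared: float
    n: int


def brightness_altitude_fits(
    brightness: pd.DataFrame, env, min_n: int = 3
) -> list[LinearFit]:
    """OLS of per-specimen perceived brightness on altitude, per body area.

    ``brightness`` is specimen-by-area (one column per sampled body
    area, values in [0, 1]); rows align with ``env``.  Areas with fewer
    than ``min_n`` complete specimens are skipped with a warning.
    Results are sorted from the most decreasing to the most increasing
    slope.
    """
    envf = _env_frame(env)
    alt = envf["altitude"].to_numpy(float)
    fits = []
    for col in brightness.columns:
        y = brightness[col].to_numpy(float)
        keep = ~(np.isnan(y) | np.isnan(alt))
        if keep.sum() < min_n:
            warnings.warn(f"area {col}: fewer than {min_n} specimens; skipped",
                          stacklevel=2)
            continue
        res = stats.linregress(alt[keep], y[keep])
        fits.append(
            LinearFit(
                variable_id=str(col),
                slope=float(res.slope),
                intercept=float(res.intercept),
                p_value=float(res.pvalue),
                r_squared=float(res.rvalue**2),
                n=int(keep.sum()),
            )
        )
    fits.sort(key=lambda f: f.slope)
    return fits


# --------------------------------------------------------------------------
# linearity screening


def aic_model_compare(
    x: Sequence[float],
    y: Sequence[float],
    models: Sequence[str] = ("linear", "quadratic", "cubic", "exponential"),
) -> list[tuple[str, float]]:
    """Rank curve families for y(x) by Gaussian-likelihood AIC.

    AIC = n ln(RSS/n) + 2k with k the parameter count of each fit;
    models are returned in ascending AIC order (best first).  Used to
    screen whether a relationship is adequately linear before relying
    on Pearson correlation.
    """
    x, y = _pairwise(x, y)
    n = len(x)
    n_params = {"linear": 2, "quadratic": 3, "cubic": 4, "exponential": 3}
    kmax = max(n_params[m] for m in models)
    if n <= kmax + 1:
        raise ValueError(f"need more than {kmax + 1} points")
    out = []
    for m in models:
        if m in ("linear", "quadratic", "cubic"):
            deg = n_params[m] - 1
            coef = np.polyfit(x, y, deg)
            pred = np.polyval(coef, x)
        elif m == "exponential":
            # y = a * exp(b x) + c, fit by least squares
            span = np.ptp(x) or 1.0

            def f(x_, a, b, c):
                return a * np.exp(b * x_) + c

            try:
                p, _ = optimize.curve_fit(
                    f, x, y, p0=[np.ptp(y) or 1.0, 1.0 / span, float(np.min(y))],
                    maxfev=20000,
                )
                pred = f(x, *p)
            except RuntimeError:
                out.append((m, np.inf))
                continue
        else:
            raise ValueError(f"unknown model {m!r}")
        rss = float(np.sum((y - pred) ** 2))
        # floor at numerical precision so exact fits tie and 2k decides
        floor = n * (1e-10 * (float(np.abs(y).mean()) + 1.0)) ** 2
        rss = max(rss, floor)
        out.append((m, n * np.log(rss / n) + 2 * n_params[m]))
    out.sort(key=lambda t: t[1])
    return out
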