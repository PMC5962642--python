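"""Concentration–response modelling and benchmark-concentration statistics.

Max-over-time descriptor summaries are fit to a four-parameter log-logistic
(4PL) model on log concentration,

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e))),

with steepness ``b``, asymptotes ``c`` and ``d``, and inflection ``e``. The
benchmark concentration (BMC) — the point of departure — is the concentration
at which the fitted curve moves ``+0.25`` (or ``-0.25`` for suppressed ICAM1
responses) in absolute scaled response away from its low-concentration
asymptote; it is obtained by inverting the log-logistic in closed form. A
compound is censored when the fitted plateau never departs that far, or when
the crossing falls outside the tested 1–100 × C-max range.

Class-level statistics compare severe vs non-severe DILI compounds: a Welch
two-sample t-test on log10(BMC / C-max), and a nested linear-model ANOVA
asking whether the severity label explains log10 BMC beyond log10 C-max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats


@dataclass(frozen=True)
class CurveFit4PL:
    b: float
    c: float
    d: float
    e: float
    converged: bool
    rss: float
    identifiable: bool = True  # False when responses were flat (b meaningless)

    def predict(self, x):
        return fourpl(np.asarray(x, dtype=float), self.b, self.c, self.d, self.e)


@dataclass(frozen=True)
class BMCResult:
    bmc_xcmax: float  # nan when censored
    delta: float
    baseline: float
    censored: bool
    reason: str = ""

    def bmc_uM(self, cmax_uM: float) -> float:
        return self.bmc_xcmax * cmax_uM


def fourpl(x, b: float, c: float, d: float, e: float):
    """Four-parameter log-logistic response at concentration x (> 0)."""
    x = np.asarray(x, dtype=float)
    return c + (d - c) / (1.0 + np.exp(b * (np.log(x) - math.log(e))))


def fit_4pl(
    conc_xcmax,
    responses,
    response_bounds: tuple = (-1.0, 1.0),
    n_starts: int = 8,
) -> CurveFit4PL:
    """Least-squares 4PL fit with multi-start initialization.

    ``responses`` are replicate-mean max-over-time summaries, one per tested
    concentration. Asymptotes are bounded to the descriptor's range; ``e`` is
    optimized on the log scale and bounded one decade beyond the tested
    concentrations. Flat responses return a degenerate converged fit with
    ``c = d = mean`` flagged non-identifiable.
    """
    x = np.asarray(conc_xcmax, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 4 or np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()) or (x <= 0).any():
        raise ValueError("concentrations must be positive and responses finite")

    span = float(y.max() - y.min())
    if span == 0.0:
        return CurveFit4PL(0.0, y[0], y[0], float(np.median(x)), True, 0.0,
                           identifiable=False)

    lo, hi = response_bounds
    pad = 0.25 * (hi - lo)
    log_e_lo, log_e_hi = math.log(x.min()) - math.log(10), math.log(x.max()) + math.log(10)

    def residuals(theta):
        b, c, d, log_e = theta
        return fourpl(x, b, c, d, math.exp(log_e)) - y

    bounds = ([-20.0, lo - pad, lo - pad, log_e_lo],
              [20.0, hi + pad, hi + pad, log_e_hi])
    order = np.argsort(x)
    y_low, y_high = y[order][0], y[order][-1]  # responses at the conc extremes
    starts = []
    for le in np.linspace(math.log(x.min()), math.log(x.max()), max(n_starts // 4, 2)):
        for bb in (-1.0, -4.0, 1.0, 4.0):
            # b < 0: f(0) = c, f(inf) = d;  b > 0: f(0) = d, f(inf) = c
            c0, d0 = (y_low, y_high) if bb < 0 else (y_high, y_low)
            starts.append([bb, c0, d0, le])

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, bounds[0], bounds[1])
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=bounds,
                xtol=1e-12, ftol=1e-12, gtol=1e-10, max_nfev=400,
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18 * max(span, 1.0) ** 2:  # exact fit; stop searching
            break
    if best is None:
        return CurveFit4PL(math.nan, math.nan, math.nan, math.nan, False, math.inf)
    b, c, d, log_e = best.x
    rss = float(2 * best.cost)
    converged = bool(best.success)
    return CurveFit4PL(float(b), float(c), float(d), float(math.exp(log_e)),
                       converged, rss)


def compute_bmc(
    fit: CurveFit4PL,
    delta: float,
    conc_range: tuple = (1.0, 100.0),
) -> BMCResult:
    """Benchmark concentration from a fitted 4PL curve by closed-form inversion.

    The baseline is the fitted low-concentration asymptote (``c`` for ``b < 0``,
    ``d`` for ``b > 0``); the BMC solves ``f(x) = baseline + delta``. Censored
    when the fit did not converge, the plateau-to-baseline span is smaller than
    ``|delta|``, the departure has the wrong sign, or the crossing lies outside
    the tested concentration range.
    """
    if not fit.converged:
        return BMCResult(math.nan, delta, math.nan, True, "fit did not converge")
    if fit.b < 0:
        baseline, plateau = fit.c, fit.d
    elif fit.b > 0:
        baseline, plateau = fit.d, fit.c
    else:
        return BMCResult(math.nan, delta, fit.c, True, "flat response")
    span = plateau - baseline
    if span * delta <= 0:
        return BMCResult(math.nan, delta, baseline, True,
                         "response moves against the requested direction")
    if abs(span) < abs(delta):
        return BMCResult(math.nan, delta, baseline, True,
                         "plateau departs less than |delta| from baseline")
    # f(x) = baseline + delta  =>  exp(b (ln x - ln e)) = span/delta - 1
    ratio = (fit.d - fit.c) / (baseline + delta - fit.c) - 1.0
    log_x = math.log(fit.e) + math.log(ratio) / fit.b
    bmc = math.exp(log_x)
    if not conc_range[0] <= bmc <= conc_range[1]:
        return BMCResult(math.nan, delta, baseline, True,
                         "crossing outside the tested concentration range")
    return BMCResult(float(bmc), delta, float(baseline), False)


def bmc_grid_search(fit: CurveFit4PL, delta: float, conc_range=(1.0, 100.0),
                    n_grid: int = 10_000) -> float:
    """Brute-force BMC on a log-spaced concentration grid (oracle for the
    closed-form inversion); nan when no grid point crosses."""
    xs = np.geomspace(conc_range[0], conc_range[1], n_grid)
    f = fit.predict(xs)
    baseline = fit.c if fit.b < 0 else fit.d
    crossed = (f - baseline) / delta >= 1.0 if delta != 0 else np.zeros(n_grid, bool)
    if not crossed.any():
        return math.nan
    return float(xs[int(np.argmax(crossed))])


def fit_bmc_table(
    summaries: pd.DataFrame,
    cmax_by_compound: dict[str, float],
    delta_by_reporter: dict[str, tuple] | None = None,
    conc_range: tuple = (1.0, 100.0),
) -> pd.DataFrame:
    """Fit 4PL curves and extract BMCs for a max-over-time summary table.

    ``summaries`` has columns compound, reporter, descriptor, conc_xcmax,
    response (replicate means). For ICAM1 both the +0.25 and −0.25 departures
    are attempted and the more potent (smaller) uncensored BMC is reported as
    the headline, with the direction retained.
    """
    if delta_by_reporter is None:
        delta_by_reporter = {r: (0.25,) for r in ("SRXN1", "CHOP", "P21")}
        delta_by_reporter["ICAM1"] = (0.25, -0.25)
    rows = []
    for (compound, reporter, descriptor), sub in summaries.groupby(
        ["compound", "reporter", "descriptor"]
    ):
        sub = sub.sort_values("conc_xcmax")
        rng = (-1.0, 1.0) if reporter == "ICAM1" else (0.0, 1.0)
        fit = fit_4pl(sub["conc_xcmax"], sub["response"], response_bounds=rng)
        candidates = [
            compute_bmc(fit, delta, conc_range)
            for delta in delta_by_reporter.get(reporter, (0.25,))
        ]
        ok = [r for r in candidates if not r.censored]
        res = min(ok, key=lambda r: r.bmc_xcmax) if ok else candidates[0]
        cmax = cmax_by_compound.get(compound, math.nan)
        rows.append(
            {
                "compound": compound,
                "reporter": reporter,
                "descriptor": descriptor,
                "b": fit.b,
                "c": fit.c,
                "d": fit.d,
                "e": fit.e,
                "converged": fit.converged,
                "bmc_xcmax": res.bmc_xcmax,
                "delta": res.delta,
                "censored": res.censored,
                "censor_reason": res.reason,
                "bmc_uM": res.bmc_xcmax * cmax,
                "bmc_over_cmax": res.bmc_xcmax,
            }
        )
    return pd.DataFrame(rows)


def bmc_class_welch(bmc_over_cmax, severity) -> dict:
    """Welch two-sample t-test on log10(BMC / C-max) between severity classes.

    Censored values (NaN) are excluded; with fewer than 2 uncensored values
    in either class no test is run and NaN statistics are reported.
    """
    vals = np.asarray(bmc_over_cmax, dtype=float)
    sev = np.asarray(severity)
    keep = np.isfinite(vals)
    a = np.log10(vals[keep & (sev == "severe")])
    b = np.log10(vals[keep & (sev == "non_severe")])
    if a.size < 2 or b.size < 2:
        return {"t": math.nan, "p": math.nan, "n_severe": a.size, "n_non_severe": b.size}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "n_severe": a.size, "n_non_severe": b.size}


def bmc_class_lm(bmc_xcmax, cmax_uM, severity) -> dict:
    """Nested-model ANOVA: does severity explain log10 BMC beyond log10 C-max?

    Null model: log10(BMC_uM) ~ 1 + log10(C-max); full model adds the severity
    indicator. Returns the F statistic and p-value of the comparison.
    """
    bmc = np.asarray(bmc_xcmax, dtype=float)
    cmax = np.asarray(cmax_uM, dtype=float)
    sev = np.asarray(severity)
    keep = np.isfinite(bmc) & np.isfinite(cmax)
    bmc, cmax, sev = bmc[keep], cmax[keep], sev[keep]
    if bmc.size < 4:
        raise ValueError("too few uncensored observations for the nested ANOVA")
    is_severe = (sev == "severe").astype(float)
    if is_severe.std() == 0:
        raise ValueError("severity label has zero variance")
    y = np.log10(bmc * cmax)
    x_null = sm.add_constant(np.log10(cmax))
    x_full = np.column_stack([x_null, is_severe])
    fit_null = sm.OLS(y, x_null).fit()
    fit_full = sm.OLS(y, x_full).fit()
    f, p, _ = fit_full.compare_f_test(fit_null)
    return {
        "F": float(f),
        "p": float(p),
        "coef_severity": float(fit_full.params[-1]),
        "n": int(bmc.size),
    }
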