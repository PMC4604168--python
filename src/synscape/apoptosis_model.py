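"""Viability→cPARP dual regression and "unexpectedly apoptotic" calling.

Within one cell line, wells that lose viability generally gain cleaved-PARP
staining; the shape of that relationship differs between lines.  Each line
is therefore fitted with two candidate families on the percent scales,

    exponential:  f(x) = a * exp(-x / tau)
    linear:       f(x) = a * x + tau

where x is viability (% of control) and f(x) the expected cPARP level
(% of control).  The family with the higher Pearson correlation between
fitted and observed values wins (ties and exponential failures fall back to
linear, which has fewer pathologies as tau grows without bound).

Combinations whose cPARP exceeds the line's fitted expectation are called
"unexpectedly apoptotic" with a one-sided two-sample Welch t-test of the
combination's residuals against all other residuals of that line; a focal
group of one falls back to a z-score against the line's residual
distribution.  The test runs on log-scale residuals, log(obs+1) -
log(fit+1), which stabilises the strongly multiplicative well-to-well
variation of cPARP staining.  Calls are labelled by death kinetics: "slow"
when the combination keeps near-normal viability (> 80% of control) while
cPARP rises, "fast" otherwise.  Flagged pairs form a drug network whose node
degree counts the flagged partnerships of each drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .screen_model import ScreenDataset

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDO = 1.0
SLOW_KINETICS_VIABILITY_PCT = 80.0

TAU_BOUNDS = (1e-6, 1e6)

#: background residual spread below which a line is apoptosis-quiet and
#: yields no outlier calls (guards noise-free data, where residuals are
#: numerical fitting error only)
MIN_BACKGROUND_SD = 1e-6


class FitError(RuntimeError):
    """A regression family could not be fitted; carries diagnostics."""


def normalize_cparp(raw_pct, pseudo: float = DEFAULT_PSEUDO):
    """log(raw + pseudo) on the control-normalised percent scale.

    The pseudo-count keeps wells with zero positive nuclei finite.  The
    transform is strictly monotone.
    """
    raw = np.asarray(raw_pct, dtype=float)
    if (raw < 0).any():
        raise ValueError("cPARP percentages must be non-negative")
    out = np.log(raw + pseudo)
    return float(out) if out.ndim == 0 else out


def _pearson(fitted: np.ndarray, observed: np.ndarray) -> float:
    if np.std(fitted) < 1e-12 or np.std(observed) < 1e-12:
        return 0.0
    return float(np.corrcoef(fitted, observed)[0, 1])


def fit_linear(x, y) -> tuple[float, float, float, np.ndarray]:
    """OLS line y = a*x + tau.  Returns (a, tau, pearson_r, residuals)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise FitError(f"linear fit needs >= 2 points, got {x.size}")
    if np.ptp(x) < 1e-12:
        raise FitError("linear fit is rank-deficient: all x identical")
    a, tau = np.polyfit(x, y, 1)
    fitted = a * x + tau
    return float(a), float(tau), _pearson(fitted, y), y - fitted


def _exp_model(x, a, tau):
    return a * np.exp(-x / tau)


def fit_exponential(x, y) -> tuple[float, float, float, np.ndarray]:
    """Least-squares fit of y = a*exp(-x/tau).

    Initialised at a0 = max(y), tau0 = range(x)/2 with bounded tau and a
    few tau restarts; persistent non-convergence raises :class:`FitError`
    so the family is excluded from model selection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise FitError(f"exponential fit needs >= 4 points, got {x.size}")
    if (x < 0).any():
        raise FitError("exponential fit requires non-negative x")
    if np.ptp(y) < 1e-12:
        raise FitError("degenerate input: all y identical")

    a0 = max(float(np.max(y)), 1e-9)
    tau0 = max(float(np.ptp(x)) / 2.0, 10 * TAU_BOUNDS[0])
    best = None
    for scale in (1.0, 0.25, 4.0):
        p0 = (a0, float(np.clip(tau0 * scale, *TAU_BOUNDS)))
        try:
            popt, _ = optimize.curve_fit(
                _exp_model,
                x,
                y,
                p0=p0,
                bounds=([1e-12, TAU_BOUNDS[0]], [np.inf, TAU_BOUNDS[1]]),
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        resid = y - _exp_model(x, *popt)
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("exponential fit did not converge from any start")
    a, tau = best[1]
    fitted = _exp_model(x, a, tau)
    return float(a), float(tau), _pearson(fitted, y), y - fitted


@dataclass
class CparpFit:
    """Selected viability→cPARP fit for one cell line.

    ``residuals`` are raw-scale observed − fitted; ``log_residuals`` are
    log(obs+1) − log(max(fit,0)+1) and drive the outlier test.  ``index``
    aligns both with the measurement rows the fit was computed on.
    """

    line_id: str
    family: str  # "exponential" | "linear"
    a: float
    tau: float
    pearson_r: float
    residuals: np.ndarray
    log_residuals: np.ndarray
    fitted: np.ndarray
    index: pd.Index
    diagnostics: dict = field(default_factory=dict)

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.family == "exponential":
            return _exp_model(x, self.a, self.tau)
        return self.a * x + self.tau


def select_model(
    x, y, line_id: str = "", index: pd.Index | None = None
) -> CparpFit:
    """Fit both families and keep the one with the higher Pearson r.

    Exact ties and exponential failures select the linear family.  Both
    families failing raises :class:`FitError` carrying both diagnostics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if index is None:
        index = pd.RangeIndex(len(x))

    exp_err = lin_err = None
    exp_fit = lin_fit = None
    try:
        exp_fit = fit_exponential(x, y)
    except FitError as e:
        exp_err = str(e)
    try:
        lin_fit = fit_linear(x, y)
    except FitError as e:
        lin_err = str(e)

    if lin_fit is None and exp_fit is None:
        raise FitError(
            f"line {line_id or '?'}: both families failed "
            f"(exponential: {exp_err}; linear: {lin_err})"
        )

    use_exp = (
        exp_fit is not None
        and (lin_fit is None or exp_fit[2] > lin_fit[2])  # strict: ties → linear
    )
    family = "exponential" if use_exp else "linear"
    a, tau, r, resid = exp_fit if use_exp else lin_fit
    fitted = y - resid
    log_resid, log_params = _log_scale_residuals(x, y, family, (a, tau), fitted)
    return CparpFit(
        line_id=line_id,
        family=family,
        a=a,
        tau=tau,
        pearson_r=r,
        residuals=resid,
        log_residuals=log_resid,
        fitted=fitted,
        index=index,
        diagnostics={
            "pearson_exponential": exp_fit[2] if exp_fit else None,
            "pearson_linear": lin_fit[2] if lin_fit else None,
            "exponential_error": exp_err,
            "linear_error": lin_err,
            "log_refit_params": log_params,
        },
    )


def _log_scale_residuals(
    x: np.ndarray,
    y: np.ndarray,
    family: str,
    p0: tuple[float, float],
    fitted_raw: np.ndarray,
) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Residuals on the log scale from a refit of the selected family.

    cPARP well-to-well variation is multiplicative, so the outlier test
    operates on log(obs + pseudo) - log(fit + pseudo).  Refitting the
    already-selected family by least squares on that scale removes the
    small x-dependent bias a raw-scale fit leaves in log residuals (raw
    least squares over-weights high-cPARP wells), which would otherwise
    distort the test's null calibration.  Falls back to residuals about the
    raw fit if the refit fails.
    """
    z = np.log(np.maximum(y, 0.0) + DEFAULT_PSEUDO)

    if family == "exponential":
        def model(x_, a_, tau_):
            return np.log(np.maximum(_exp_model(x_, a_, tau_), 0.0) + DEFAULT_PSEUDO)
    else:
        def model(x_, a_, tau_):
            return np.log(np.maximum(a_ * x_ + tau_, 0.0) + DEFAULT_PSEUDO)

    try:
        popt, _ = optimize.curve_fit(model, x, z, p0=p0, maxfev=20000)
        return z - model(x, *popt), (float(popt[0]), float(popt[1]))
    except (RuntimeError, ValueError):
        return z - np.log(np.maximum(fitted_raw, 0.0) + DEFAULT_PSEUDO), None


def fit_all_lines(dataset: ScreenDataset) -> dict[str, CparpFit]:
    """Dual-regression fit per cell line over all its measurements
    (singles and combinations, both tiers)."""
    fits: dict[str, CparpFit] = {}
    m = dataset.measurements
    for line_id, sub in m.groupby("line_id", sort=True):
        try:
            fits[line_id] = select_model(
                sub["viability_pct"].to_numpy(float),
                sub["cparp_pct"].to_numpy(float),
                line_id=line_id,
                index=sub.index,
            )
        except FitError as e:
            logger.warning("line %s excluded from apoptosis analysis: %s",
                           line_id, e)
    return fits


def classify_kinetics(viability_pct: float) -> str:
    """"slow" death kinetics iff viability stays > 80% of control."""
    return "slow" if viability_pct > SLOW_KINETICS_VIABILITY_PCT else "fast"


def _robust_background(residuals: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based scale of the background residual distribution.

    A robust scale keeps a minority of genuine outliers in the background
    from inflating the spread they are screened against (a single planted
    fraction q at +k SD inflates the classical SD by sqrt(1 + q*k^2)).
    Consistent with the SD under a normal null.
    """
    center = float(np.median(residuals))
    mad = float(np.median(np.abs(residuals - center)))
    return center, 1.4826 * mad


def residual_outlier_test(
    focal: np.ndarray, background: np.ndarray
) -> tuple[float, str]:
    """One-sided elevated-residual test of focal vs background.

    Welch two-sample t-test for focal groups of >= 2; a single focal value
    is z-scored against the background distribution (flagged via the
    returned method string).  Returns (one-sided p, method).
    """
    focal = np.asarray(focal, dtype=float)
    background = np.asarray(background, dtype=float)
    if focal.size == 0:
        raise ValueError("focal subset must be non-empty")
    if focal.size == 1:
        center, scale = _robust_background(background)
        if scale < MIN_BACKGROUND_SD:
            return 1.0, "quiet"
        z = (focal[0] - center) / scale
        return float(stats.norm.sf(z)), "zscore"
    sd = background.std(ddof=1) if background.size > 1 else 0.0
    if sd < MIN_BACKGROUND_SD:
        return 1.0, "quiet"
    t = stats.ttest_ind(focal, background, equal_var=False, alternative="greater")
    return float(t.pvalue), "welch_t"


def call_dataset(
    dataset: ScreenDataset,
    fits: Mapping[str, CparpFit] | None = None,
    alpha: float = DEFAULT_ALPHA,
    adjust: str = "none",
) -> pd.DataFrame:
    """Call unexpectedly apoptotic combinations across the whole screen.

    One row per (pair, line, tier) combination with the one-sided p-value,
    the mean focal log-residual (``excess_cparp``), the optional BH-adjusted
    p (within each cell line), the significance flag and the kinetics label.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    if fits is None:
        fits = fit_all_lines(dataset)

    m = dataset.measurements
    combo = dataset.combination_mask
    rows = []
    for line_id, fit in fits.items():
        sub = m.loc[fit.index]
        resid = pd.Series(fit.log_residuals, index=fit.index)
        is_combo = combo.loc[fit.index]
        n = len(fit.index)
        r_all = resid.to_numpy()
        # robust background for the single-well z path; the focal well's own
        # contribution to a median over hundreds of wells is negligible
        bg_center, bg_scale = _robust_background(r_all)

        for (da, db, tier), grp in sub[is_combo].groupby(
            ["drug_a", "drug_b", "tier"], sort=True
        ):
            focal = resid.loc[grp.index].to_numpy()
            n_f = focal.size
            n_bg = n - n_f
            if n_bg < 3:
                continue
            if bg_scale < MIN_BACKGROUND_SD:
                p, method = 1.0, "quiet"
            elif n_f == 1:
                z = (focal[0] - bg_center) / bg_scale
                p, method = float(stats.norm.sf(z)), "zscore"
            else:
                mask = np.ones(n, dtype=bool)
                mask[fit.index.get_indexer(grp.index)] = False
                t = stats.ttest_ind(
                    focal, r_all[mask], equal_var=False, alternative="greater"
                )
                p, method = float(t.pvalue), "welch_t"
            rows.append(
                {
                    "line_id": line_id,
                    "drug_a": da,
                    "drug_b": db,
                    "tier": tier,
                    "n_focal": n_f,
                    "excess_cparp": float(focal.mean()),
                    "viability_pct": float(grp["viability_pct"].mean()),
                    "p_value": p,
                    "method": method,
                }
            )

    calls = pd.DataFrame(
        rows,
        columns=[
            "line_id",
            "drug_a",
            "drug_b",
            "tier",
            "n_focal",
            "excess_cparp",
            "viability_pct",
            "p_value",
            "method",
        ],
    )
    if calls.empty:
        calls["p_adjusted"] = pd.Series(dtype=float)
        calls["significant"] = pd.Series(dtype=bool)
        calls["kinetics"] = pd.Series(dtype=object)
        return calls

    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        calls["p_adjusted"] = np.nan
        for line_id, grp in calls.groupby("line_id"):
            _, p_adj, _, _ = multipletests(
                grp["p_value"].to_numpy(), method="fdr_bh"
            )
            calls.loc[grp.index, "p_adjusted"] = p_adj
    else:
        calls["p_adjusted"] = calls["p_value"]

    calls["significant"] = (calls["p_adjusted"] < alpha) & (
        calls["excess_cparp"] > 0
    )
    calls["kinetics"] = [
        classify_kinetics(v) for v in calls["viability_pct"]
    ]
    return calls


def excess_apoptosis_rate(calls: pd.DataFrame) -> float:
    """Percent of tested (pair, line, tier) combinations flagged significant."""
    if calls.empty:
        return float("nan")
    return 100.0 * float(calls["significant"].mean())


def build_network(calls: pd.DataFrame) -> nx.Graph:
    """Drug-pair network of significant calls.

    One edge per flagged pair carrying the tiers and kinetics observed and
    the pair's best p-value; node degree equals the number of flagged
    partner pairs of that drug.
    """
    g = nx.Graph()
    if calls.empty:
        return g
    sig = (
        calls[calls["significant"].astype(bool)]
        if "significant" in calls.columns
        else calls
    )
    for (da, db), grp in sig.groupby(["drug_a", "drug_b"]):
        g.add_edge(
            da,
            db,
            tiers=",".join(sorted(set(grp["tier"]))),
            kinetics=",".join(sorted(set(grp["kinetics"]))),
            n_lines=int(grp["line_id"].nunique()),
            min_p=float(grp["p_adjusted"].min()),
        )
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    return g


def write_network(g: nx.Graph, path) -> None:
    """GraphML export of the apoptosis network."""
    nx.write_graphml(g, path)
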