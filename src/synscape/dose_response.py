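"""Sigmoid dose-response fitting, combination index and isobolograms.

Secondary assays of a drug pair follow the classic fixed-ratio design: each
single agent is titrated, and the combination is titrated at a constant
molar ratio.  All three titrations are fitted with the four-parameter
logistic on log-dose,

    v(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill),

with viability as fraction of control, so E_max = 1 - bottom.  The
combination index at affected fraction f is the dose-additivity ratio

    CI(f) = d1/D1 + d2/D2,

where D1, D2 are the single-agent doses reaching f, and d1, d2 the
constituent doses inside the combination reaching f at the fixed ratio
(mutually exclusive form, no cross-term).  CI < 1 indicates synergy, 1
additivity, > 1 antagonism; the isobologram plots (d1/D1, d2/D2) against
the (1,0)-(0,1) additivity line.  A partner drug can improve a curve by a
leftward IC50 shift (potency) or by deepening E_max (efficacy); both modes
are classified from the fitted parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

DEFAULT_EFFECT_LEVELS = (0.5, 0.75, 0.9)
EXTRAPOLATION_FACTOR = 10.0
FLAT_RESPONSE_RANGE = 0.05


class UnreachableEffectError(ValueError):
    """A curve cannot reach the requested affected fraction."""


class LowConfidenceFitError(RuntimeError):
    """A flagged fit cannot support the requested classification."""


@dataclass
class DoseResponseCurve:
    """Four-parameter logistic fit of viability (fraction of control) vs dose."""

    bottom: float
    top: float
    ic50: float
    hill: float
    doses: np.ndarray | None = None
    responses: np.ndarray | None = None
    converged: bool = True
    flags: tuple = ()
    curve_id: str = ""

    @property
    def emax(self) -> float:
        """Maximal effect: 1 - bottom on the viability scale."""
        return 1.0 - self.bottom

    def response(self, dose):
        dose = np.asarray(dose, dtype=float)
        out = self.bottom + (self.top - self.bottom) / (
            1.0 + (dose / self.ic50) ** self.hill
        )
        return float(out) if out.ndim == 0 else out

    def dose_at_effect(self, effect_level: float, check_range: bool = True) -> float:
        """Dose at which the affected fraction reaches ``effect_level``.

        Closed-form logistic inverse at viability v = 1 - effect_level.
        Effect levels outside (bottom, top) raise
        :class:`UnreachableEffectError`; with fitted data attached, doses
        beyond 10x the tested range are refused rather than extrapolated.
        """
        if not 0.0 < effect_level < 1.0:
            raise ValueError("effect_level must be in (0, 1)")
        v = 1.0 - effect_level
        if not (self.bottom < v < self.top):
            raise UnreachableEffectError(
                f"curve {self.curve_id or '?'}: viability {v:.3f} outside "
                f"({self.bottom:.3f}, {self.top:.3f})"
            )
        d = self.ic50 * ((self.top - v) / (v - self.bottom)) ** (1.0 / self.hill)
        if check_range and self.doses is not None and len(self.doses):
            lo = float(np.min(self.doses)) / EXTRAPOLATION_FACTOR
            hi = float(np.max(self.doses)) * EXTRAPOLATION_FACTOR
            if not lo <= d <= hi:
                raise UnreachableEffectError(
                    f"curve {self.curve_id or '?'}: inverted dose {d:.3g} is "
                    f"beyond {EXTRAPOLATION_FACTOR:g}x the tested range"
                )
        return float(d)


def _logistic(logd, bottom, top, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10 ** ((logd - log_ic50) * hill))


def fit_sigmoid(
    doses: Sequence[float], responses: Sequence[float], curve_id: str = ""
) -> DoseResponseCurve:
    """Least-squares 4-parameter logistic fit on log10 dose.

    Designs with < 5 doses or < 2 orders of magnitude of dose range are
    fitted but flagged; flat data is flagged ``flat`` with an undefined
    IC50, never silently accepted.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape or doses.ndim != 1:
        raise ValueError("doses and responses must be matching 1-d arrays")
    if (doses <= 0).any():
        raise ValueError("doses must be positive concentrations")
    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]

    flags = []
    if doses.size < 5:
        flags.append("few_doses")
    if doses.size >= 2 and np.log10(doses.max() / doses.min()) < 2.0:
        flags.append("narrow_range")
    if float(np.ptp(responses)) < FLAT_RESPONSE_RANGE:
        flags.append("flat")
        return DoseResponseCurve(
            bottom=float(responses.mean()),
            top=float(responses.mean()),
            ic50=float("nan"),
            hill=float("nan"),
            doses=doses,
            responses=responses,
            converged=False,
            flags=tuple(flags),
            curve_id=curve_id,
        )

    logd = np.log10(doses)
    mid = (responses.max() + responses.min()) / 2.0
    log_ic50_0 = float(logd[np.argmin(np.abs(responses - mid))])
    p0 = (float(responses.min()), float(responses.max()), log_ic50_0, 1.0)
    lo = [-0.5, 0.0, logd.min() - 2.0, 0.1]
    hi = [1.5, 2.0, logd.max() + 2.0, 10.0]
    converged = True
    try:
        popt, _ = optimize.curve_fit(
            _logistic, logd, responses, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError):
        converged = False
        popt = p0
        flags.append("no_convergence")
    bottom, top, log_ic50, hill = popt
    ic50 = float(10**log_ic50)
    if converged and not (doses.min() <= ic50 <= doses.max()):
        flags.append("extrapolated_ic50")
    return DoseResponseCurve(
        bottom=float(bottom),
        top=float(top),
        ic50=ic50,
        hill=float(hill),
        doses=doses,
        responses=responses,
        converged=converged,
        flags=tuple(flags),
        curve_id=curve_id,
    )


@dataclass
class CIResult:
    """Combination index at one affected fraction for a fixed-ratio combo.

    ``d1``/``d2`` are the constituent doses inside the combination reaching
    the effect, ``big_d1``/``big_d2`` the single-agent doses doing the same;
    ``ci = d1/D1 + d2/D2`` equals 1 under exact dose additivity.
    """

    effect_level: float
    d1: float
    d2: float
    big_d1: float
    big_d2: float

    @property
    def ci(self) -> float:
        return self.d1 / self.big_d1 + self.d2 / self.big_d2


def combination_index(
    curve1: DoseResponseCurve,
    curve2: DoseResponseCurve,
    combo_curve: DoseResponseCurve,
    ratio: tuple[float, float],
    effect_level: float,
) -> CIResult:
    """Chou-Talalay combination index (mutually exclusive form).

    ``combo_curve`` is fitted against total combination dose; ``ratio``
    gives the molar proportions of drugs 1 and 2 in the mixture (any scale,
    normalised internally).  All three curves are inverted in closed form at
    the requested affected fraction; an unreachable effect raises with the
    offending curve named.
    """
    r1, r2 = float(ratio[0]), float(ratio[1])
    if r1 < 0 or r2 < 0 or r1 + r2 <= 0:
        raise ValueError("ratio components must be non-negative and not both zero")
    total = r1 + r2
    r1, r2 = r1 / total, r2 / total

    t = combo_curve.dose_at_effect(effect_level)
    d1, d2 = r1 * t, r2 * t
    # a zero-weight constituent contributes nothing (self-combination limit)
    big_d1 = curve1.dose_at_effect(effect_level) if r1 > 0 else 1.0
    big_d2 = curve2.dose_at_effect(effect_level) if r2 > 0 else 1.0
    return CIResult(
        effect_level=effect_level, d1=d1, d2=d2, big_d1=big_d1, big_d2=big_d2
    )


def average_ci(
    curve1: DoseResponseCurve,
    curve2: DoseResponseCurve,
    combo_curve: DoseResponseCurve,
    ratio: tuple[float, float],
    effect_levels: Sequence[float] = DEFAULT_EFFECT_LEVELS,
) -> tuple[list[CIResult], float]:
    """CI at several effect levels (default ED50/75/90) plus their mean."""
    results = [
        combination_index(curve1, curve2, combo_curve, ratio, e)
        for e in effect_levels
    ]
    return results, float(np.mean([r.ci for r in results]))


def isobologram_points(ci_results: Sequence[CIResult]):
    """Normalised isobologram coordinates plus the additivity line.

    Returns (points, line) where points are (d1/D1, d2/D2) pairs — each
    summing to its CI, below the line for synergy — and line is the
    additivity segment ((1, 0), (0, 1)).
    """
    points = [(r.d1 / r.big_d1, r.d2 / r.big_d2) for r in ci_results]
    return points, ((1.0, 0.0), (0.0, 1.0))


def classify_shift(
    single_curve: DoseResponseCurve,
    curve_with_partner: DoseResponseCurve,
    potency_fold_min: float = 2.0,
    emax_delta_min: float = 0.2,
) -> str:
    """Classify a partner's effect as an IC50 shift vs an E_max boost.

    ``potency_shift``: IC50 drops by >= ``potency_fold_min`` without a
    meaningful E_max change; ``efficacy_boost``: E_max deepens by >=
    ``emax_delta_min``; ``both``/``neither`` accordingly.  Flagged
    (non-converged or flat) fits refuse classification.
    """
    for c in (single_curve, curve_with_partner):
        bad = {"flat", "no_convergence"} & set(c.flags)
        if bad or not c.converged:
            raise LowConfidenceFitError(
                f"curve {c.curve_id or '?'} flagged {sorted(bad) or 'unconverged'}; "
                "classification refused"
            )
    fold = single_curve.ic50 / curve_with_partner.ic50
    emax_delta = curve_with_partner.emax - single_curve.emax
    efficacy = emax_delta >= emax_delta_min
    if fold >= potency_fold_min:
        return "both" if efficacy else (
            "potency_shift" if abs(emax_delta) < emax_delta_min else "neither"
        )
    return "efficacy_boost" if efficacy else "neither"
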