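"""Bliss-independence synergy scoring and hit calling.

Under Bliss independence two non-interacting drugs leave a surviving fraction
equal to the product of their single-agent surviving fractions,

    v_expected = v_a * v_b,

so the synergy score (in percent-of-control points) is

    Bliss = 100 * (v_a * v_b - v_ab),

positive when the combination kills more than expected (synergy), negative
for antagonism.  Viabilities above 1 (growth stimulation) are clipped to 1
when forming the expected value only — Bliss independence is defined on
probabilities — while raw observed values are kept for the score's observed
term.

Hit calling uses a strict threshold on the score (default > 40 points).
Synthetic lethality is the extreme case where neither single agent has a
meaningful effect (both singles > 80% viability) yet the combination drops
below 50%; at dataset level the flag additionally requires the record to be
a synergy hit, so the reported synthetic-lethality rate is the fraction of
synergy hits that are synthetic lethal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .screen_model import ScreenDataset, TIERS

logger = logging.getLogger(__name__)

DEFAULT_SYNERGY_THRESHOLD_PCT = 40.0
DEFAULT_SL_SINGLE_MIN_PCT = 80.0
DEFAULT_SL_COMBO_MAX_PCT = 50.0


def bliss_expected(v_a: float, v_b: float) -> float:
    """Expected surviving fraction of a non-interacting combination.

    Inputs are surviving fractions (>= 0); values above 1 are clipped to 1
    for the expectation, since the Bliss null is a product of probabilities.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if (v_a < 0).any() or (v_b < 0).any():
        raise ValueError("surviving fractions must be non-negative")
    out = np.minimum(v_a, 1.0) * np.minimum(v_b, 1.0)
    return float(out) if out.ndim == 0 else out


def bliss_score(v_a: float, v_b: float, v_ab: float) -> float:
    """Bliss synergy score in percent points: 100*(v_a*v_b - v_ab)."""
    v_ab = np.asarray(v_ab, dtype=float)
    if (v_ab < 0).any():
        raise ValueError("surviving fractions must be non-negative")
    out = 100.0 * (bliss_expected(v_a, v_b) - v_ab)
    return float(out) if np.ndim(out) == 0 else out


def bliss_expected_pct(pct_a, pct_b):
    """Expected combination viability on the percent scale.

    This exact expression is shared with the synthetic-screen generator so
    that a noise-free Bliss-null screen scores identically zero down to the
    last bit.
    """
    return np.minimum(pct_a, 100.0) * np.minimum(pct_b, 100.0) / 100.0


def cparp_bliss_expected_pct(pct_a, pct_b):
    """Bliss-expected combined induction for the cPARP readout.

    cPARP is an induction (not survival) readout; treating the
    control-normalised percent clipped to [0, 100] as a positivity
    probability, independence gives p_a + p_b - p_a*p_b.  Used only for the
    wide-layout display block, never for viability synergy calls.
    """
    a = np.minimum(pct_a, 100.0)
    b = np.minimum(pct_b, 100.0)
    return a + b - a * b / 100.0


def call_synergy_hit(
    bliss_score_pct, threshold_pct: float = DEFAULT_SYNERGY_THRESHOLD_PCT
):
    """True iff the Bliss score strictly exceeds the threshold (default 40)."""
    out = np.asarray(bliss_score_pct, dtype=float) > threshold_pct
    return bool(out) if out.ndim == 0 else out


def call_synthetic_lethal(
    v_a,
    v_b,
    v_ab,
    single_min_pct: float = DEFAULT_SL_SINGLE_MIN_PCT,
    combo_max_pct: float = DEFAULT_SL_COMBO_MAX_PCT,
):
    """Both singles inert (> 80% viability) yet the combination kills (< 50%).

    Comparisons are strict; boundary values are non-hits.  Inputs are
    fractions.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    v_ab = np.asarray(v_ab, dtype=float)
    out = (
        (100.0 * v_a > single_min_pct)
        & (100.0 * v_b > single_min_pct)
        & (100.0 * v_ab < combo_max_pct)
    )
    return bool(out) if out.ndim == 0 else out


def score_dataset(
    dataset: ScreenDataset,
    tiers: Sequence[str] = TIERS,
    threshold_pct: float = DEFAULT_SYNERGY_THRESHOLD_PCT,
    sl_single_min_pct: float = DEFAULT_SL_SINGLE_MIN_PCT,
    sl_combo_max_pct: float = DEFAULT_SL_COMBO_MAX_PCT,
) -> pd.DataFrame:
    """Score every complete (pair, line, tier) combination of a screen.

    Replicates are averaged before scoring.  Returns one row per scored
    combination with columns ``line_id, drug_a, drug_b, tier, v_a, v_b,
    v_ab, bliss_expected, bliss_score, is_synergy_hit, is_synthetic_lethal``.
    Combinations whose single-agent partner rows are missing are excluded
    with a logged count.

    ``is_synthetic_lethal`` here requires the record to also be a synergy
    hit, so that the synthetic-lethality rate is a fraction of synergy hits.
    """
    m = dataset.measurements
    key = ["line_id", "tier"]

    singles = (
        m[dataset.single_mask]
        .groupby(key + ["drug_a"], as_index=False)["viability_pct"]
        .mean()
        .rename(columns={"drug_a": "drug", "viability_pct": "single_pct"})
    )
    combos = (
        m[dataset.combination_mask & m["tier"].isin(list(tiers))]
        .groupby(key + ["drug_a", "drug_b"], as_index=False)["viability_pct"]
        .mean()
        .rename(columns={"viability_pct": "combo_pct"})
    )
    n_before = len(combos)
    combos = combos.merge(
        singles.rename(columns={"drug": "drug_a", "single_pct": "pct_a"}),
        on=key + ["drug_a"],
        how="left",
    ).merge(
        singles.rename(columns={"drug": "drug_b", "single_pct": "pct_b"}),
        on=key + ["drug_b"],
        how="left",
    )
    complete = combos["pct_a"].notna() & combos["pct_b"].notna()
    n_dropped = n_before - int(complete.sum())
    if n_dropped:
        logger.warning(
            "%d combination(s) excluded from synergy scoring (missing "
            "single-agent partner rows)",
            n_dropped,
        )
    combos = combos[complete].reset_index(drop=True)

    pct_a = combos["pct_a"].to_numpy(float)
    pct_b = combos["pct_b"].to_numpy(float)
    pct_ab = combos["combo_pct"].to_numpy(float)
    expected_pct = bliss_expected_pct(pct_a, pct_b)
    score = expected_pct - pct_ab

    out = pd.DataFrame(
        {
            "line_id": combos["line_id"],
            "drug_a": combos["drug_a"],
            "drug_b": combos["drug_b"],
            "tier": combos["tier"],
            "v_a": pct_a / 100.0,
            "v_b": pct_b / 100.0,
            "v_ab": pct_ab / 100.0,
            "bliss_expected": expected_pct / 100.0,
            "bliss_score": score,
        }
    )
    out["is_synergy_hit"] = call_synergy_hit(score, threshold_pct)
    out["is_synthetic_lethal"] = out["is_synergy_hit"] & (
        (pct_a > sl_single_min_pct)
        & (pct_b > sl_single_min_pct)
        & (pct_ab < sl_combo_max_pct)
    )
    return out


@dataclass
class BreadthResult:
    """Per-pair synergy breadth: in how many lines is the pair a hit."""

    per_pair: pd.DataFrame  # drug_a, drug_b, tier, n_lines_synergistic, lines
    histogram: pd.Series  # index: breadth (>=1), values: number of pairs

    def fraction_le(self, k: int) -> float:
        """Fraction of pairs with >= 1 hit whose breadth is <= k."""
        total = int(self.histogram.sum())
        if total == 0:
            return float("nan")
        return float(self.histogram[self.histogram.index <= k].sum()) / total


def synergy_breadth(
    scores: pd.DataFrame,
    threshold_pct: float | None = None,
    tier: str = "standard",
) -> BreadthResult:
    """Count, per pair, the cell lines in which it is a synergy hit.

    Operates on the output of :func:`score_dataset`.  If ``threshold_pct``
    is given the hit flags are recomputed at that threshold, otherwise the
    stored ``is_synergy_hit`` flags are used.  Only the requested tier is
    considered (the screen's breadth histogram is a standard-tier summary by
    default).
    """
    sub = scores[scores["tier"] == tier]
    hit = (
        sub["bliss_score"] > threshold_pct
        if threshold_pct is not None
        else sub["is_synergy_hit"]
    )
    hits = sub[hit]
    if hits.empty:
        per_pair = pd.DataFrame(
            columns=["drug_a", "drug_b", "tier", "n_lines_synergistic", "lines"]
        )
        return BreadthResult(per_pair, pd.Series(dtype=int))
    grouped = hits.groupby(["drug_a", "drug_b"])["line_id"].agg(sorted)
    per_pair = pd.DataFrame(
        {
            "drug_a": [k[0] for k in grouped.index],
            "drug_b": [k[1] for k in grouped.index],
            "tier": tier,
            "n_lines_synergistic": [len(v) for v in grouped],
            "lines": list(grouped),
        }
    )
    histogram = (
        per_pair["n_lines_synergistic"].value_counts().sort_index().astype(int)
    )
    return BreadthResult(per_pair, histogram)


@dataclass
class RateResult:
    """A percentage with its numerator/denominator; undefined when the
    denominator is zero (``defined`` False, ``percent`` NaN)."""

    percent: float
    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0


def synthetic_lethality_rate(scores: pd.DataFrame) -> RateResult:
    """Percent of synergy hits that are synthetic lethal.

    Zero synergy hits yields an undefined (flagged) result, not an error.
    """
    n_hits = int(scores["is_synergy_hit"].sum())
    n_sl = int(scores["is_synthetic_lethal"].sum())
    if n_hits == 0:
        return RateResult(float("nan"), n_sl, 0)
    return RateResult(100.0 * n_sl / n_hits, n_sl, n_hits)


def promiscuity_index(
    scores: pd.DataFrame, threshold_pct: float | None = None
) -> pd.DataFrame:
    """Per-drug sensitizer profile: distinct hit partners and total hits.

    A broadly sensitizing drug (an MDR-inhibitor-like compound) accumulates
    hits with many partners across many lines and ranks first.  Returns a
    DataFrame (drug, n_partners, n_hits) sorted by total hits descending.
    """
    hit = (
        scores["bliss_score"] > threshold_pct
        if threshold_pct is not None
        else scores["is_synergy_hit"]
    )
    hits = scores[hit]
    long = pd.concat(
        [
            hits.rename(columns={"drug_a": "drug", "drug_b": "partner"})[
                ["drug", "partner", "line_id"]
            ],
            hits.rename(columns={"drug_b": "drug", "drug_a": "partner"})[
                ["drug", "partner", "line_id"]
            ],
        ]
    )
    if long.empty:
        return pd.DataFrame(columns=["drug", "n_partners", "n_hits"])
    out = (
        long.groupby("drug")
        .agg(n_partners=("partner", "nunique"), n_hits=("partner", "size"))
        .reset_index()
        .sort_values(["n_hits", "n_partners", "drug"], ascending=[False, False, True])
        .reset_index(drop=True)
    )
    return out


def bliss_matrix(scores: pd.DataFrame, tier: str = "standard") -> pd.DataFrame:
    """Pivot scores into a (pair x line) Bliss matrix for differential tests.

    Rows are labelled ``drug_a|drug_b``; replicate-mean scores at the given
    tier fill the cells.
    """
    sub = scores[scores["tier"] == tier].copy()
    sub["pair"] = sub["drug_a"].astype(str) + "|" + sub["drug_b"].astype(str)
    return sub.pivot_table(index="pair", columns="line_id", values="bliss_score")
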