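"""Headline screen-level summaries combining the synergy and apoptosis stages."""

from __future__ import annotations

from typing import Mapping

from .apoptosis_model import call_dataset, excess_apoptosis_rate
from .screen_model import ScreenDataset
from .synergy_core import (
    score_dataset,
    synergy_breadth,
    synthetic_lethality_rate,
)


def headline_summary(
    dataset: ScreenDataset,
    threshold_pct: float = 40.0,
    breadth_k: int = 3,
    alpha: float = 0.05,
    adjust: str = "bh",
    breadth_tier: str = "standard",
) -> Mapping[str, float]:
    """The three screen-level headline percentages.

    * ``synthetic_lethality_rate_pct`` — synergy hits whose single agents
      were inert (> 80% viability) while the combination fell below 50%.
    * ``breadth_le_k_pct`` — synergistic pairs showing synergy in at most
      ``breadth_k`` cell lines (how private synergies are).
    * ``excess_cparp_rate_pct`` — combinations flagged unexpectedly
      apoptotic relative to the cell line's viability→cPARP fit.
    """
    scores = score_dataset(dataset, threshold_pct=threshold_pct)
    sl = synthetic_lethality_rate(scores)
    breadth = synergy_breadth(scores, tier=breadth_tier)
    calls = call_dataset(dataset, alpha=alpha, adjust=adjust)
    return {
        "synthetic_lethality_rate_pct": sl.percent,
        "n_synergy_hits": sl.denominator,
        f"breadth_le_{breadth_k}_pct": 100.0 * breadth.fraction_le(breadth_k),
        "n_synergistic_pairs": int(breadth.histogram.sum()),
        "excess_cparp_rate_pct": excess_apoptosis_rate(calls),
        "n_combinations_tested": len(calls),
    }
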