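"""Synthetic fixed-ratio combination screens with known ground truth.

The generator emulates the structure of a large two-tier combination
screen — 108 drugs (5,778 unordered pairs), 36 melanoma-like cell lines,
two fixed-ratio concentration tiers and two readouts, i.e. 416,016
combination rows and 832,032 combination data points at full scale — so
every analysis stage can be exercised against planted truth without any
external data.

Model, in order of construction (single seeded RNG, hence byte-identical
datasets per seed):

* Single-agent true viabilities are logit-normal per (drug, line, tier):
  sigmoid(logit(base_tier) + drug effect + line effect).  The standard-tier
  base (0.85) emulates the screen run-in that calibrates doses to > 70%
  mean viability; the low tier sits higher (0.93).
* Null combinations obey Bliss independence exactly on the percent scale,
  sharing the expectation expression with the scorer so a noise-free null
  screen scores identically zero.
* Planted synergies subtract a viability delta in chosen lines; a
  "broad sensitizer" (an MDR-inhibitor-like promiscuous drug) multiplies
  the null kill of every partner in its susceptible lines.
* Measurement noise is additive on the fraction scale (scaled to percent),
  clipped to [0, 120] so mild growth stimulation survives.
* cPARP follows each line's own viability→cPARP relation — exponential
  a*exp(-x/tau) or linear a*x + tau, family 50/50 unless pinned — with
  log-normal multiplicative noise; planted "slow/fast death" outliers
  multiply by exp(shift_sd * noise_sd_cparp).

When the planted-effect lists are left at ``None`` a representative
landscape is auto-planted: ~5% of pairs synergistic with mostly-private
breadth (truncated geometric, P(breadth <= 3) ~ 0.56), one broad
sensitizer, and cPARP outliers in 4% of combination records.  Passing
explicit (possibly empty) lists overrides this; :func:`null_config` gives
the fully null, noise-free configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict


import numpy as np
import pandas as pd

from .screen_model import (
    CellLineEntry,
    DrugEntry,
    ScreenDataset,
    ScreenValidationError,
    canonical_pair,
    pair_count,
)
from .synergy_core import bliss_expected_pct

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedSynergy:
    """A context-specific synergy: the pair's viability drops by ``delta``
    (fraction scale) in the listed lines at the given tier."""

    drug_a: str
    drug_b: str
    lines: tuple
    delta: float
    tier: str = "standard"

    def __post_init__(self):
        if not 0.0 < self.delta <= 1.0:
            raise ScreenValidationError("planted delta must be in (0, 1]")


@dataclass(frozen=True)
class Sensitizer:
    """A promiscuous sensitizer: combination kill of every pair containing
    ``drug_id`` is multiplied by ``factor`` in the susceptible lines."""

    drug_id: str
    lines: tuple
    factor: float = 3.0


@dataclass(frozen=True)
class CparpOutlier:
    """An unexpectedly apoptotic combination: its cPARP is shifted by
    ``shift_sd`` background SDs (log scale) in one line/tier."""

    drug_a: str
    drug_b: str
    line_id: str
    tier: str = "standard"
    shift_sd: float = 4.0


@dataclass(frozen=True)
class CparpRelation:
    """Per-line viability→cPARP relation (family, a, tau)."""

    family: str  # "exponential" | "linear"
    a: float
    tau: float


@dataclass
class SimulationConfig:
    """Study conditions of a simulated screen.

    Defaults reproduce the full screen geometry (108 drugs, 36 lines, two
    tiers, single replicate) with moderate measurement noise.  ``None`` for
    the planted-effect fields requests the representative auto-planted
    landscape described in the module docstring.
    """

    n_drugs: int = 108
    n_lines: int = 36
    tiers: tuple = ("standard", "low")
    replicates: int = 1
    noise_sd_viability: float = 0.05  # fraction scale
    noise_sd_cparp: float = 0.20  # log scale
    base_viability: dict = field(
        default_factory=lambda: {"standard": 0.85, "low": 0.93}
    )
    drug_effect_sd: float = 0.9  # logit scale
    line_effect_sd: float = 0.4  # logit scale
    n_resistant_lines: int = 6
    planted_synergies: list | None = None
    broad_sensitizer: Sensitizer | None | str = "auto"
    cparp_relations: dict | None = None
    planted_cparp_outliers: list | None = None
    auto_synergy_pair_fraction: float = 0.05
    auto_breadth_geom_p: float = 0.24  # P(breadth<=3) ≈ 0.56
    auto_delta_range: tuple = (0.45, 0.7)
    auto_outlier_fraction: float = 0.04
    auto_outlier_shift_sd: float = 4.0
    seed: int = 0


def full_scale_config(**overrides) -> SimulationConfig:
    """Full-scale configuration: 108 drugs, 36 lines, two tiers.

    The resulting dataset has 5,778 pairs, 416,016 combination rows and
    832,032 combination data points.
    """
    return SimulationConfig(**overrides)


def null_config(n_drugs: int = 108, n_lines: int = 36, **overrides) -> SimulationConfig:
    """Noise-free Bliss-null configuration with no planted effects."""
    kw = dict(
        n_drugs=n_drugs,
        n_lines=n_lines,
        noise_sd_viability=0.0,
        noise_sd_cparp=0.0,
        planted_synergies=[],
        broad_sensitizer=None,
        planted_cparp_outliers=[],
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class GroundTruth:
    """Everything planted into a simulated screen, for recovery tests.

    ``realized_bliss`` maps each planted synergy event to the Bliss-score
    drop (percent points) actually imprinted on the noise-free data: a
    planted delta is truncated when the pair's null combination viability
    is already below it (a strong single agent leaves less room to kill).
    """

    planted_synergies: list
    sensitizer: Sensitizer | None
    cparp_outliers: list
    cparp_relations: dict
    single_viability_true: pd.DataFrame  # drug x line x tier true fractions
    realized_bliss: dict = field(default_factory=dict)

    def synergy_events(self) -> set:
        """(drug_a, drug_b, line_id, tier) tuples of every planted synergy."""
        events = set()
        for p in self.planted_synergies:
            for line in p.lines:
                events.add((p.drug_a, p.drug_b, line, p.tier))
        return events

    def detectable_events(self, min_bliss_pct: float) -> set:
        """Planted events whose realized Bliss drop reaches ``min_bliss_pct``."""
        return {
            e for e, drop in self.realized_bliss.items() if drop >= min_bliss_pct
        }


def drug_id(i: int) -> str:
    return f"D{i + 1:03d}"


def line_id(i: int) -> str:
    return f"L{i + 1:02d}"


def _auto_plants(
    config: SimulationConfig,
    rng: np.random.Generator,
    drugs: list,
    lines: list,
    null_pct: np.ndarray,
) -> list:
    """Representative mostly-private synergy landscape.

    ``null_pct`` is the (pair x line) noise-free null combination viability
    at the planting tier; events are placed only where the full delta is
    realizable (null viability >= delta + 5 points), so every auto-planted
    event carries its nominal Bliss drop.
    """
    n_pairs = pair_count(config.n_drugs)
    n_syn = max(1, round(config.auto_synergy_pair_fraction * n_pairs))
    ia, ib = np.triu_indices(config.n_drugs, k=1)
    chosen = rng.choice(n_pairs, size=n_syn, replace=False)
    plants = []
    lo, hi = config.auto_delta_range
    for p in chosen:
        delta = float(rng.uniform(lo, hi))
        feasible = np.flatnonzero(null_pct[p] >= 100.0 * delta + 5.0)
        if feasible.size == 0:
            continue
        breadth = min(
            int(rng.geometric(config.auto_breadth_geom_p)), feasible.size
        )
        which = rng.choice(feasible, size=breadth, replace=False)
        plants.append(
            PlantedSynergy(
                drug_a=drugs[ia[p]],
                drug_b=drugs[ib[p]],
                lines=tuple(lines[i] for i in sorted(which)),
                delta=delta,
                tier="standard",
            )
        )
    return plants


def _draw_cparp_relations(
    config: SimulationConfig, rng: np.random.Generator, lines: list
) -> dict:
    """One relation per line; families 50/50, parameters anchored so the
    control level (x = 100) sits near 100% of control."""
    relations = {}
    for line in lines:
        if rng.random() < 0.5:
            tau = float(rng.uniform(30.0, 60.0))
            a = 100.0 * np.exp(100.0 / tau)  # f(100) = 100
            relations[line] = CparpRelation("exponential", float(a), tau)
        else:
            tau = float(rng.uniform(300.0, 600.0))  # f(0), basal apoptosis
            a = (100.0 - tau) / 100.0  # f(100) = 100
            relations[line] = CparpRelation("linear", float(a), tau)
    return relations


def _relation_values(rel: CparpRelation, x: np.ndarray) -> np.ndarray:
    if rel.family == "exponential":
        out = rel.a * np.exp(-x / rel.tau)
    else:
        out = rel.a * x + rel.tau
    return np.maximum(out, 1.0)


def generate_screen(config: SimulationConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate a screen and its ground truth.  Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n_d, n_l = config.n_drugs, config.n_lines
    tiers = tuple(config.tiers)
    drugs = [drug_id(i) for i in range(n_d)]
    lines = [line_id(i) for i in range(n_l)]
    drug_index = {d: i for i, d in enumerate(drugs)}
    line_index = {l: i for i, l in enumerate(lines)}

    # --- true single-agent viabilities (logit-normal) -------------------
    drug_eff = rng.normal(0.0, config.drug_effect_sd, size=n_d)
    line_eff = rng.normal(0.0, config.line_effect_sd, size=n_l)
    base = np.array(
        [np.log(b / (1 - b)) for b in (config.base_viability[t] for t in tiers)]
    )
    logits = base[:, None, None] + drug_eff[None, :, None] + line_eff[None, None, :]
    s_true = 1.0 / (1.0 + np.exp(-logits))  # (T, D, L) fractions
    s_true_pct = 100.0 * s_true

    # --- resistance groups ----------------------------------------------
    resistant = set(
        rng.choice(n_l, size=min(config.n_resistant_lines, n_l), replace=False)
    )
    line_entries = [
        CellLineEntry(
            line_id=lines[i],
            genotype_tags=frozenset({"BRAF_V600E"}),
            resistance_group="resistant" if i in resistant else "sensitive",
        )
        for i in range(n_l)
    ]
    panel = [
        DrugEntry(drug_id=d, conc_standard=1e-6, conc_low=2.5e-7) for d in drugs
    ]

    # --- planted effects -------------------------------------------------
    sens = config.broad_sensitizer
    if sens == "auto":
        s_drug = drugs[int(rng.integers(n_d))]
        susceptible = rng.choice(n_l, size=n_l // 2, replace=False)
        sens = Sensitizer(
            drug_id=s_drug,
            lines=tuple(lines[i] for i in sorted(susceptible)),
            factor=3.0,
        )
    if sens is not None and sens.drug_id not in drug_index:
        raise ScreenValidationError(f"sensitizer {sens.drug_id!r} not in panel")

    relations = config.cparp_relations
    if relations is None:
        relations = _draw_cparp_relations(config, rng, lines)

    # --- combination true values on the percent scale -------------------
    ia, ib = np.triu_indices(n_d, k=1)
    n_p = ia.size
    # (T, P, L): Bliss-null expectation from the noise-free singles,
    # via the same expression the scorer uses
    combo_pct = bliss_expected_pct(s_true_pct[:, ia, :], s_true_pct[:, ib, :])

    if sens is not None:
        s_i = drug_index[sens.drug_id]
        pair_rows = np.flatnonzero((ia == s_i) | (ib == s_i))
        line_cols = np.array([line_index[l] for l in sens.lines], dtype=int)
        if line_cols.size and pair_rows.size:
            block = combo_pct[:, pair_rows[:, None], line_cols[None, :]]
            kill = np.minimum(100.0, (100.0 - block) * sens.factor)
            combo_pct[:, pair_rows[:, None], line_cols[None, :]] = 100.0 - kill

    tier_index = {t: i for i, t in enumerate(tiers)}
    plants = config.planted_synergies
    if plants is None:
        t_plant = tier_index.get("standard", 0)
        plants = _auto_plants(config, rng, drugs, lines, combo_pct[t_plant])
    for p in plants:
        if p.drug_a not in drug_index or p.drug_b not in drug_index:
            raise ScreenValidationError(
                f"planted pair ({p.drug_a}, {p.drug_b}) not in panel"
            )
        canonical_pair(p.drug_a, p.drug_b)
        for l in p.lines:
            if l not in line_index:
                raise ScreenValidationError(f"planted line {l!r} not in panel")
        if p.tier not in tiers:
            raise ScreenValidationError(f"planted tier {p.tier!r} not simulated")

    pair_row = {}
    for r in range(n_p):
        pair_row[(drugs[ia[r]], drugs[ib[r]])] = r
    realized: dict = {}
    for p in plants:
        r = pair_row[canonical_pair(p.drug_a, p.drug_b)]
        t = tier_index[p.tier]
        for l in p.lines:
            before = combo_pct[t, r, line_index[l]]
            after = max(before - 100.0 * p.delta, 0.0)
            combo_pct[t, r, line_index[l]] = after
            realized[(p.drug_a, p.drug_b, l, p.tier)] = before - after
    combo_pct = np.maximum(combo_pct, 0.0)

    # --- assemble measurement rows --------------------------------------
    reps = config.replicates
    sv = 100.0 * config.noise_sd_viability

    frames = []
    for t, tier in enumerate(tiers):
        for rep in range(1, reps + 1):
            # controls
            frames.append(
                pd.DataFrame(
                    {
                        "line_id": lines,
                        "drug_a": np.nan,
                        "drug_b": np.nan,
                        "tier": tier,
                        "replicate": rep,
                        "viability_pct": 100.0,
                        "cparp_pct": 100.0,
                    }
                )
            )
            # singles
            noise = rng.normal(0.0, 1.0, size=(n_d, n_l)) * sv
            pct = np.clip(s_true_pct[t] + noise, 0.0, 120.0)
            frames.append(
                pd.DataFrame(
                    {
                        "line_id": np.tile(lines, n_d),
                        "drug_a": np.repeat(drugs, n_l),
                        "drug_b": np.nan,
                        "tier": tier,
                        "replicate": rep,
                        "viability_pct": pct.ravel(),
                        "cparp_pct": 0.0,
                    }
                )
            )
            # combinations
            noise = rng.normal(0.0, 1.0, size=(n_p, n_l)) * sv
            pct = np.clip(combo_pct[t] + noise, 0.0, 120.0)
            frames.append(
                pd.DataFrame(
                    {
                        "line_id": np.tile(lines, n_p),
                        "drug_a": np.repeat([drugs[i] for i in ia], n_l),
                        "drug_b": np.repeat([drugs[i] for i in ib], n_l),
                        "tier": tier,
                        "replicate": rep,
                        "viability_pct": pct.ravel(),
                        "cparp_pct": 0.0,
                    }
                )
            )
    m = pd.concat(frames, ignore_index=True)

    # --- cPARP from each line's relation --------------------------------
    outliers = config.planted_cparp_outliers
    auto_outliers = outliers is None

    sc = config.noise_sd_cparp
    line_codes = m["line_id"].map(line_index).to_numpy()
    x = m["viability_pct"].to_numpy(float)
    f = np.empty_like(x)
    for l, rel in relations.items():
        sel = line_codes == line_index[l]
        f[sel] = _relation_values(rel, x[sel])
    eps = rng.normal(0.0, 1.0, size=len(m)) * sc
    shift = np.zeros(len(m))

    combo_rows = m["drug_b"].notna().to_numpy()
    if auto_outliers:
        combo_idx = np.flatnonzero(combo_rows)
        n_out = round(config.auto_outlier_fraction * combo_idx.size)
        chosen = (
            rng.choice(combo_idx, size=n_out, replace=False)
            if n_out
            else np.array([], dtype=int)
        )
        shift[chosen] = config.auto_outlier_shift_sd * sc
        outliers = [
            CparpOutlier(
                drug_a=m.at[i, "drug_a"],
                drug_b=m.at[i, "drug_b"],
                line_id=m.at[i, "line_id"],
                tier=m.at[i, "tier"],
                shift_sd=config.auto_outlier_shift_sd,
            )
            for i in chosen
        ]
    else:
        key = pd.MultiIndex.from_arrays(
            [m["drug_a"], m["drug_b"], m["line_id"], m["tier"]]
        )
        lookup = {}
        for o in outliers:
            a, b = canonical_pair(o.drug_a, o.drug_b)
            lookup[(a, b, o.line_id, o.tier)] = o.shift_sd * sc
        if lookup:
            shift = np.array([lookup.get(k, 0.0) for k in key])

    m["cparp_pct"] = np.where(
        m["drug_a"].isna(),  # controls stay pinned at 100
        m["cparp_pct"],
        f * np.exp(eps + shift),
    )

    dataset = ScreenDataset(panel=panel, lines=line_entries, measurements=m)
    truth = GroundTruth(
        planted_synergies=list(plants),
        sensitizer=sens,
        cparp_outliers=list(outliers),
        cparp_relations=dict(relations),
        single_viability_true=pd.DataFrame(
            {
                "tier": np.repeat(list(tiers), n_d * n_l),
                "drug_id": np.tile(np.repeat(drugs, n_l), len(tiers)),
                "line_id": np.tile(lines, n_d * len(tiers)),
                "viability_true": s_true.ravel(),
            }
        ),
        realized_bliss=realized,
    )
    return dataset, truth


def truth_to_dict(truth: GroundTruth) -> dict:
    """JSON-serialisable ground truth (the true-viability table elided)."""
    return {
        "planted_synergies": [asdict(p) for p in truth.planted_synergies],
        "sensitizer": asdict(truth.sensitizer) if truth.sensitizer else None,
        "cparp_outliers": [asdict(o) for o in truth.cparp_outliers],
        "cparp_relations": {
            k: asdict(v) for k, v in truth.cparp_relations.items()
        },
    }


def generate_differential_matrix(
    n_pairs: int = 107,
    n_group_a: int = 6,
    n_group_b: int = 30,
    n_planted: int = 20,
    shift: float = 30.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list, list]:
    """Synergy matrix for the two-class differential design.

    Rows are combinations (e.g. every partner of one anchor drug), columns
    cell lines: ``n_group_a`` focal (resistant) and ``n_group_b`` others.
    The first ``n_planted`` rows get a ``+shift`` Bliss-point offset in the
    focal columns on top of N(0, noise_sd) noise.  Returns (matrix,
    group_a column names, planted row labels).
    """
    rng = np.random.default_rng(seed)
    n = n_group_a + n_group_b
    x = rng.normal(0.0, noise_sd, size=(n_pairs, n))
    x[:n_planted, :n_group_a] += shift
    cols = [f"L{i + 1:02d}" for i in range(n)]
    rows = [f"pair{i + 1:03d}" for i in range(n_pairs)]
    matrix = pd.DataFrame(x, index=rows, columns=cols)
    return matrix, cols[:n_group_a], rows[:n_planted]
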