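"""Domain types, validation and I/O for fixed-ratio drug combination screens.

A screen measures every unordered pair of drugs from a panel (plus each drug
alone and DMSO controls) across a panel of cell lines, at two fixed-ratio
concentration tiers, with two per-well readouts: cell count ("viability") and
the fraction of cleaved-PARP-positive nuclei ("cparp"), both expressed as
percent of the DMSO control.

Two on-disk layouts are supported:

* **long** — CSV/TSV with one row per (line, drug_a, drug_b-or-blank, tier,
  replicate) and columns ``line_id, drug_a, drug_b, tier, replicate,
  viability_pct, cparp_pct``.  Single-agent rows leave ``drug_b`` blank;
  DMSO control rows leave both drug columns blank.
* **wide** — an XLSX workbook with one block (sheet) per readout and tier,
  rows indexed by combination label and columns by cell line, mirroring the
  usual supplementary-table presentation of such screens.  Pre-computed Bliss
  blocks, when present, are retained for cross-checking only and are never
  substituted for recomputation.

Values above 100% are permitted (growth stimulation); synergy arithmetic
converts to fractions internally (see :mod:`synscape.synergy_core`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIERS = ("standard", "low")
RESISTANCE_GROUPS = ("sensitive", "resistant", "unassigned")

#: canonical column order of the long layout
LONG_COLUMNS = (
    "line_id",
    "drug_a",
    "drug_b",
    "tier",
    "replicate",
    "viability_pct",
    "cparp_pct",
)

#: row label used for DMSO control rows in the wide layout
CONTROL_LABEL = "DMSO"

#: separator between drug ids in wide-layout combination labels
PAIR_SEP = " + "


class SchemaError(ValueError):
    """An input table does not have the required columns."""


class ScreenValidationError(ValueError):
    """A measurement table violates a screen invariant."""


class LayoutError(ValueError):
    """A wide-layout workbook does not have the expected sheet structure."""


@dataclass(frozen=True)
class DrugEntry:
    """One compound of the screening panel.

    ``conc_standard`` and ``conc_low`` are the molar concentrations used at
    the two fixed-ratio tiers; the low tier is strictly below the standard
    tier by definition.
    """

    drug_id: str
    name: str = ""
    target_class: str = ""
    conc_standard: float = 1e-6
    conc_low: float = 1e-7

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ScreenValidationError("drug_id must be a non-empty token")
        if not (self.conc_standard > 0 and self.conc_low > 0):
            raise ScreenValidationError(
                f"drug {self.drug_id}: concentrations must be > 0"
            )
        if not self.conc_low < self.conc_standard:
            raise ScreenValidationError(
                f"drug {self.drug_id}: conc_low must be < conc_standard"
            )


@dataclass(frozen=True)
class CellLineEntry:
    """One cell line of the panel.

    ``genotype_tags`` are free-form tokens such as ``BRAF_V600E`` or
    ``NRAS_mut``; ``resistance_group`` partitions lines for differential
    synergy analysis and must be assigned (non-``unassigned``) before that
    analysis runs.
    """

    line_id: str
    genotype_tags: frozenset = frozenset()
    resistance_group: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.line_id:
            raise ScreenValidationError("line_id must be a non-empty token")
        if self.resistance_group not in RESISTANCE_GROUPS:
            raise ScreenValidationError(
                f"line {self.line_id}: resistance_group must be one of "
                f"{RESISTANCE_GROUPS}, got {self.resistance_group!r}"
            )


def canonical_pair(drug_a: str, drug_b: str) -> tuple[str, str]:
    """Return the unordered pair in canonical (lexicographic) order."""
    if drug_a == drug_b:
        raise ScreenValidationError(f"self-combination {drug_a!r} is not a pair")
    return (drug_a, drug_b) if drug_a < drug_b else (drug_b, drug_a)


def pair_count(n_drugs: int) -> int:
    """Number of unordered two-drug combinations from a panel of ``n_drugs``.

    A 108-drug panel yields 5,778 pairs.
    """
    if n_drugs < 2:
        raise ValueError(f"need at least 2 drugs for a combination, got {n_drugs}")
    return math.comb(n_drugs, 2)


def _canonicalize_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce drug_a < drug_b (lexicographic) wherever both are present."""
    both = df["drug_a"].notna() & df["drug_b"].notna()
    if both.any():
        if (df.loc[both, "drug_a"] == df.loc[both, "drug_b"]).any():
            bad = df.index[both & (df["drug_a"] == df["drug_b"])][0]
            raise ScreenValidationError(f"row {bad}: self-combination is not a pair")
        swap = both & (df["drug_a"] > df["drug_b"])
        if swap.any():
            a = df.loc[swap, "drug_a"].copy()
            df.loc[swap, "drug_a"] = df.loc[swap, "drug_b"]
            df.loc[swap, "drug_b"] = a
    return df


@dataclass
class ScreenDataset:
    """A full screen: drug panel, cell-line panel and the measurement table.

    ``measurements`` holds one row per well-level observation with the
    columns of :data:`LONG_COLUMNS`.  ``extras`` carries auxiliary blocks
    (e.g. Bliss values stored in an imported workbook) that are kept for
    cross-checks but are never used in place of recomputation.
    """

    panel: list[DrugEntry]
    lines: list[CellLineEntry]
    measurements: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in LONG_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise SchemaError(f"measurements missing column(s): {', '.join(missing)}")
        self.measurements = _canonicalize_pairs(
            self.measurements.loc[:, list(LONG_COLUMNS)].reset_index(drop=True)
        )
        self.validate()

    # -- panel helpers -------------------------------------------------
    @property
    def drug_ids(self) -> list[str]:
        return [d.drug_id for d in self.panel]

    @property
    def line_ids(self) -> list[str]:
        return [l.line_id for l in self.lines]

    def drug(self, drug_id: str) -> DrugEntry:
        for d in self.panel:
            if d.drug_id == drug_id:
                return d
        raise KeyError(drug_id)

    # -- masks ---------------------------------------------------------
    @property
    def combination_mask(self) -> pd.Series:
        m = self.measurements
        return m["drug_a"].notna() & m["drug_b"].notna()

    @property
    def single_mask(self) -> pd.Series:
        m = self.measurements
        return m["drug_a"].notna() & m["drug_b"].isna()

    @property
    def control_mask(self) -> pd.Series:
        m = self.measurements
        return m["drug_a"].isna()

    @property
    def n_combination_rows(self) -> int:
        return int(self.combination_mask.sum())

    @property
    def n_combination_datapoints(self) -> int:
        """Combination data points = rows x 2 readouts (viability, cPARP)."""
        return 2 * self.n_combination_rows

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        m = self.measurements
        drugs = set(self.drug_ids)
        lines = set(self.line_ids)
        if len(drugs) != len(self.panel):
            raise ScreenValidationError("drug_id values must be unique within a panel")
        if len(lines) != len(self.lines):
            raise ScreenValidationError("line_id values must be unique")

        unknown_line = ~m["line_id"].isin(lines)
        if unknown_line.any():
            raise ScreenValidationError(
                f"row {m.index[unknown_line][0]}: unknown line_id "
                f"{m.loc[unknown_line, 'line_id'].iloc[0]!r}"
            )
        for col in ("drug_a", "drug_b"):
            bad = m[col].notna() & ~m[col].isin(drugs)
            if bad.any():
                raise ScreenValidationError(
                    f"row {m.index[bad][0]}: unknown drug id "
                    f"{m.loc[bad, col].iloc[0]!r} in {col}"
                )
        bad_tier = ~m["tier"].isin(TIERS)
        if bad_tier.any():
            raise ScreenValidationError(
                f"row {m.index[bad_tier][0]}: tier must be one of {TIERS}"
            )
        for col in ("viability_pct", "cparp_pct"):
            vals = m[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ScreenValidationError(
                    f"row {m.index[~np.isfinite(vals)][0]}: non-finite {col}"
                )
            if (vals < 0).any():
                raise ScreenValidationError(
                    f"row {m.index[vals < 0][0]}: negative {col} "
                    f"({vals[vals < 0][0]:g})"
                )

    def flag_incomplete(self) -> pd.Series:
        """Combination rows whose single-agent partner rows are missing.

        A combination row is complete only if both constituents have a
        single-agent row at the same (line, tier).  Incomplete rows are kept
        in the dataset but excluded from synergy scoring.
        """
        m = self.measurements
        singles = set(
            zip(
                m.loc[self.single_mask, "line_id"],
                m.loc[self.single_mask, "tier"],
                m.loc[self.single_mask, "drug_a"],
            )
        )
        combo = self.combination_mask
        keys_a = zip(m["line_id"], m["tier"], m["drug_a"])
        keys_b = zip(m["line_id"], m["tier"], m["drug_b"])
        has_a = pd.Series([k in singles for k in keys_a], index=m.index)
        has_b = pd.Series([k in singles for k in keys_b], index=m.index)
        return combo & ~(has_a & has_b)


# ---------------------------------------------------------------------------
# panel / line metadata tables
# ---------------------------------------------------------------------------

def read_panel(path: str | Path) -> list[DrugEntry]:
    """Read a drug panel CSV (drug_id, name, target_class, conc_standard, conc_low)."""
    df = pd.read_csv(path)
    if "drug_id" not in df.columns:
        raise SchemaError("panel file missing column: drug_id")
    return read_panel_frame(df)


def read_lines(path: str | Path) -> list[CellLineEntry]:
    """Read a cell-line panel CSV (line_id, genotype_tags, resistance_group)."""
    df = pd.read_csv(path)
    if "line_id" not in df.columns:
        raise SchemaError("cell-line file missing column: line_id")
    return read_lines_frame(df)


def write_panel(panel: Sequence[DrugEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": d.drug_id,
                "name": d.name,
                "target_class": d.target_class,
                "conc_standard": d.conc_standard,
                "conc_low": d.conc_low,
            }
            for d in panel
        ]
    ).to_csv(path, index=False)


def write_lines(lines: Sequence[CellLineEntry], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "line_id": l.line_id,
                "genotype_tags": ";".join(sorted(l.genotype_tags)),
                "resistance_group": l.resistance_group,
            }
            for l in lines
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# long layout
# ---------------------------------------------------------------------------

def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _panel_from_measurements(m: pd.DataFrame) -> list[DrugEntry]:
    ids = sorted(
        set(m["drug_a"].dropna()).union(set(m["drug_b"].dropna()))
    )
    return [DrugEntry(drug_id=i) for i in ids]


def _lines_from_measurements(m: pd.DataFrame) -> list[CellLineEntry]:
    return [CellLineEntry(line_id=i) for i in sorted(set(m["line_id"]))]


def read_long_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    panel: Sequence[DrugEntry] | None = None,
    lines: Sequence[CellLineEntry] | None = None,
) -> ScreenDataset:
    """Read a long-layout CSV/TSV into a validated :class:`ScreenDataset`.

    ``schema`` optionally maps the canonical column names of
    :data:`LONG_COLUMNS` to the names used in the file.  Panel and line
    metadata default to minimal entries inferred from the table.  The count
    of incomplete combination rows (missing single-agent partners) is
    reported via logging; the rows themselves are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_infer_sep(path))
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(LONG_COLUMNS)].copy()
    for col in ("drug_a", "drug_b", "line_id", "tier"):
        df[col] = df[col].astype("object")
        df.loc[df[col].isin(["", "NONE", "None"]), col] = np.nan
    df["replicate"] = df["replicate"].fillna(1).astype(int)
    ds = ScreenDataset(
        panel=list(panel) if panel is not None else _panel_from_measurements(df),
        lines=list(lines) if lines is not None else _lines_from_measurements(df),
        measurements=df,
    )
    incomplete = ds.flag_incomplete()
    if incomplete.any():
        logger.warning(
            "%d combination row(s) lack single-agent partner rows and will be "
            "excluded from synergy scoring",
            int(incomplete.sum()),
        )
    return ds


def write_long_table(dataset: ScreenDataset, path: str | Path) -> None:
    """Write the long layout; ``read_long_table`` round-trips it exactly."""
    path = Path(path)
    dataset.measurements.to_csv(path, sep=_infer_sep(path), index=False)


# ---------------------------------------------------------------------------
# wide (supplementary-table style) layout
# ---------------------------------------------------------------------------

def _row_label(drug_a, drug_b) -> str:
    if pd.isna(drug_a):
        return CONTROL_LABEL
    if pd.isna(drug_b):
        return str(drug_a)
    return f"{drug_a}{PAIR_SEP}{drug_b}"


def _parse_label(label: str) -> tuple:
    if label == CONTROL_LABEL:
        return (np.nan, np.nan)
    if PAIR_SEP in label:
        a, b = label.split(PAIR_SEP)
        return canonical_pair(a.strip(), b.strip())
    return (label, np.nan)


def _wide_block(m: pd.DataFrame, value_col: str, line_ids: Sequence[str]) -> pd.DataFrame:
    labels = [_row_label(a, b) for a, b in zip(m["drug_a"], m["drug_b"])]
    block = (
        m.assign(combination=labels)
        .pivot_table(
            index="combination", columns="line_id", values=value_col, aggfunc="mean"
        )
        .reindex(columns=list(line_ids))
    )
    block.index.name = "combination"
    return block


def write_s3_layout(dataset: ScreenDataset, path: str | Path) -> None:
    """Write the wide XLSX layout.

    Sheets: ``drugs``, ``cell_lines``, and per tier ``cell_count_<tier>``,
    ``cparp_<tier>``, plus computed ``bliss_<tier>`` and
    ``cparp_bliss_<tier>`` blocks for combination rows.  Replicates are
    collapsed to their mean, so the layout round-trips exactly only for
    single-replicate datasets.
    """
    from .synergy_core import bliss_expected_pct, cparp_bliss_expected_pct

    path = Path(path)
    m = dataset.measurements
    line_ids = dataset.line_ids
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        pd.DataFrame(
            [
                {
                    "drug_id": d.drug_id,
                    "name": d.name,
                    "target_class": d.target_class,
                    "conc_standard": d.conc_standard,
                    "conc_low": d.conc_low,
                }
                for d in dataset.panel
            ]
        ).to_excel(xl, sheet_name="drugs", index=False)
        pd.DataFrame(
            [
                {
                    "line_id": l.line_id,
                    "genotype_tags": ";".join(sorted(l.genotype_tags)),
                    "resistance_group": l.resistance_group,
                }
                for l in dataset.lines
            ]
        ).to_excel(xl, sheet_name="cell_lines", index=False)

        for tier in TIERS:
            sub = m[m["tier"] == tier]
            if sub.empty:
                continue
            cc = _wide_block(sub, "viability_pct", line_ids)
            cp = _wide_block(sub, "cparp_pct", line_ids)
            cc.to_excel(xl, sheet_name=f"cell_count_{tier}")
            cp.to_excel(xl, sheet_name=f"cparp_{tier}")

            combo_labels = [
                lab for lab in cc.index
                if PAIR_SEP in str(lab)
            ]
            if combo_labels:
                bliss = pd.DataFrame(index=combo_labels, columns=cc.columns,
                                     dtype=float)
                cbliss = pd.DataFrame(index=combo_labels, columns=cc.columns,
                                      dtype=float)
                for lab in combo_labels:
                    a, b = _parse_label(str(lab))
                    if a not in cc.index or b not in cc.index:
                        continue
                    exp_v = bliss_expected_pct(
                        cc.loc[a].to_numpy(float), cc.loc[b].to_numpy(float)
                    )
                    bliss.loc[lab] = exp_v - cc.loc[lab].to_numpy(float)
                    exp_c = cparp_bliss_expected_pct(
                        cp.loc[a].to_numpy(float), cp.loc[b].to_numpy(float)
                    )
                    cbliss.loc[lab] = cp.loc[lab].to_numpy(float) - exp_c
                bliss.index.name = "combination"
                cbliss.index.name = "combination"
                bliss.to_excel(xl, sheet_name=f"bliss_{tier}")
                cbliss.to_excel(xl, sheet_name=f"cparp_bliss_{tier}")


def read_s3_layout(path: str | Path) -> ScreenDataset:
    """Read a wide-layout workbook back into a :class:`ScreenDataset`.

    Stored Bliss blocks are retained in ``dataset.extras`` and cross-checked
    against recomputation; cells deviating by more than one Bliss point are
    counted in ``extras['bliss_mismatch_count']`` and reported via logging.
    """
    from .synergy_core import bliss_expected_pct

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    book = pd.read_excel(path, sheet_name=None, index_col=None)
    names = set(book)
    cc_sheets = [s for s in names if s.startswith("cell_count_")]
    if not cc_sheets:
        raise LayoutError(
            "unrecognized workbook structure; expected cell_count_<tier> "
            f"sheet(s), found: {sorted(names)}"
        )

    panel = (
        read_panel_frame(book["drugs"]) if "drugs" in names else None
    )
    lines = (
        read_lines_frame(book["cell_lines"]) if "cell_lines" in names else None
    )

    rows = []
    extras: dict = {}
    mismatch = 0
    for sheet in cc_sheets:
        tier = sheet.removeprefix("cell_count_")
        if tier not in TIERS:
            raise LayoutError(f"unknown tier in sheet name {sheet!r}")
        cc = book[sheet].set_index("combination")
        cp_name = f"cparp_{tier}"
        if cp_name not in names:
            raise LayoutError(
                f"missing sheet {cp_name!r}; found: {sorted(names)}"
            )
        cp = book[cp_name].set_index("combination")
        for lab in cc.index:
            a, b = _parse_label(str(lab))
            for line in cc.columns:
                v = cc.at[lab, line]
                c = cp.at[lab, line] if line in cp.columns and lab in cp.index else np.nan
                if pd.isna(v):
                    continue
                rows.append(
                    {
                        "line_id": line,
                        "drug_a": a,
                        "drug_b": b,
                        "tier": tier,
                        "replicate": 1,
                        "viability_pct": float(v),
                        "cparp_pct": float(c) if not pd.isna(c) else 0.0,
                    }
                )
        bl_name = f"bliss_{tier}"
        if bl_name in names:
            stored = book[bl_name].set_index("combination")
            extras[bl_name] = stored
            for lab in stored.index:
                a, b = _parse_label(str(lab))
                if a not in cc.index or b not in cc.index or lab not in cc.index:
                    continue
                exp = bliss_expected_pct(
                    cc.loc[a].to_numpy(float), cc.loc[b].to_numpy(float)
                )
                recomputed = exp - cc.loc[lab].to_numpy(float)
                diff = np.abs(stored.loc[lab].to_numpy(float) - recomputed)
                mismatch += int(np.nansum(diff > 1.0))
        cb_name = f"cparp_bliss_{tier}"
        if cb_name in names:
            extras[cb_name] = book[cb_name].set_index("combination")

    if mismatch:
        logger.warning(
            "stored Bliss values disagree with recomputation (>1 point) in %d "
            "cell(s); recomputed values take precedence",
            mismatch,
        )
    extras["bliss_mismatch_count"] = mismatch

    df = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    return ScreenDataset(
        panel=panel if panel is not None else _panel_from_measurements(df),
        lines=lines if lines is not None else _lines_from_measurements(df),
        measurements=df,
        extras=extras,
    )


def _text(value, default: str = "") -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    return str(value)


def read_panel_frame(df: pd.DataFrame) -> list[DrugEntry]:
    return [
        DrugEntry(
            drug_id=_text(r["drug_id"]),
            name=_text(r.get("name")),
            target_class=_text(r.get("target_class")),
            conc_standard=float(r.get("conc_standard", 1e-6)),
            conc_low=float(r.get("conc_low", 1e-7)),
        )
        for r in df.to_dict("records")
    ]


def read_lines_frame(df: pd.DataFrame) -> list[CellLineEntry]:
    return [
        CellLineEntry(
            line_id=_text(r["line_id"]),
            genotype_tags=frozenset(
                t for t in _text(r.get("genotype_tags")).split(";") if t
            ),
            resistance_group=_text(r.get("resistance_group"), "unassigned")
            or "unassigned",
        )
        for r in df.to_dict("records")
    ]
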