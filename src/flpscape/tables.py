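"""CSV schemas, validated readers, and species/tree reconciliation.

All tabular inputs are plain CSV with documented headers:

* specimens:    species, sex, plumage_class, sexing_method
* colors:       specimen, species, sex, plumage_class, patchNN_R/G/B
* morphometrics: specimen, species, sex, bill_mm, wing_mm
* covariates:   species, flp, chromatism, migratory, dominance,
                body_length, mean_temperature, mean_precipitation,
                temperature_predictability, precipitation_predictability

Readers validate row-by-row, keep the good rows, and report every failure
together rather than stopping at the first.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import dendropy
import pandas as pd

from . import trees
from .errors import InvalidArgumentError

__all__ = ["TableResult", "read_specimens", "read_colors", "read_morphometrics",
           "read_covariates", "reconcile_species"]

SPECIMEN_COLUMNS = ["species", "sex", "plumage_class", "sexing_method"]
MORPHO_COLUMNS = ["specimen", "species", "sex", "bill_mm", "wing_mm"]
COVARIATE_COLUMNS = ["species", "flp", "chromatism", "migratory", "dominance",
                     "body_length", "mean_temperature", "mean_precipitation",
                     "temperature_predictability",
                     "precipitation_predictability"]

SEXES = {"female", "male", "unknown"}
SEXING_METHODS = {"gonad", "unknown", "plumage"}


@dataclasses.dataclass
class TableResult:
    """A validated table plus the rows that failed validation."""

    records: pd.DataFrame
    errors: list[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidArgumentError(
            f"{what} table missing required columns: {missing}")


def read_specimens(path) -> TableResult:
    """Specimen scores; rejects rows with classes outside 1..4 or bad tags."""
    df = pd.read_csv(path)
    _require_columns(df, SPECIMEN_COLUMNS, "specimen")
    errors: list[str] = []
    keep = []
    for i, row in df.iterrows():
        problems = []
        try:
            cls = int(row["plumage_class"])
            if cls not in (1, 2, 3, 4):
                problems.append(f"plumage_class {cls} outside 1..4")
        except (TypeError, ValueError):
            problems.append(f"plumage_class {row['plumage_class']!r} not an integer")
        if row["sex"] not in SEXES:
            problems.append(f"sex {row['sex']!r} not in {sorted(SEXES)}")
        if row["sexing_method"] not in SEXING_METHODS:
            problems.append(
                f"sexing_method {row['sexing_method']!r} not in "
                f"{sorted(SEXING_METHODS)}")
        if problems:
            errors.append(f"row {i}: " + "; ".join(problems))
        else:
            keep.append(i)
    good = df.loc[keep].copy()
    good["plumage_class"] = good["plumage_class"].astype(int)
    return TableResult(good.reset_index(drop=True), errors)


def read_colors(path) -> TableResult:
    """Patch-color table; every patch channel must be finite in [0, 255]."""
    df = pd.read_csv(path)
    _require_columns(df, ["specimen", "species", "sex", "plumage_class"],
                     "color")
    patch_cols = [c for c in df.columns if c.startswith("patch")]
    if not patch_cols:
        raise InvalidArgumentError("color table has no patchNN_R/G/B columns")
    errors: list[str] = []
    keep = []
    for i, row in df.iterrows():
        vals = pd.to_numeric(row[patch_cols], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals > 255).any():
            errors.append(f"row {i}: patch values missing or outside [0, 255]")
        else:
            keep.append(i)
    return TableResult(df.loc[keep].reset_index(drop=True), errors)


def read_morphometrics(path) -> TableResult:
    df = pd.read_csv(path)
    _require_columns(df, MORPHO_COLUMNS, "morphometrics")
    errors: list[str] = []
    keep = []
    for i, row in df.iterrows():
        try:
            bill, wing = float(row["bill_mm"]), float(row["wing_mm"])
            if bill <= 0 or wing <= 0:
                raise ValueError
            keep.append(i)
        except (TypeError, ValueError):
            errors.append(f"row {i}: bill/wing lengths must be positive numbers")
    return TableResult(df.loc[keep].reset_index(drop=True), errors)


def read_covariates(path) -> TableResult:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "flp", "chromatism"], "covariate")
    errors: list[str] = []
    keep = []
    for i, row in df.iterrows():
        problems = []
        if row["flp"] not in (0, 1):
            problems.append(f"flp {row['flp']!r} not 0/1")
        if row["chromatism"] not in ("monochromic", "dichromic", "FLP"):
            problems.append(f"chromatism {row['chromatism']!r} invalid")
        elif (row["flp"] == 1) != (row["chromatism"] == "FLP"):
            problems.append("flp flag inconsistent with chromatism")
        if problems:
            errors.append(f"row {i}: " + "; ".join(problems))
        else:
            keep.append(i)
    return TableResult(df.loc[keep].reset_index(drop=True), errors)


def reconcile_species(table: pd.DataFrame, tree: dendropy.Tree,
                      ) -> dict[str, list[str]]:
    """Cross-check species labels against the tree's tips.

    Returns lists of species present only in the table (excluded from
    phylogenetic stages) and tips present only in the tree.
    """
    table_sp = set(table["species"].unique())
    tips = set(trees.tip_labels(tree))
    return {
        "only_in_table": sorted(table_sp - tips),
        "only_in_tree": sorted(tips - table_sp),
        "shared": sorted(table_sp & tips),
    }
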