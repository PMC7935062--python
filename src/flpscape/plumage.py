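"""Specimen scoring, FLP presence/absence rules, and sensitivity grids.

Museum skins are scored on an ordinal 1–4 scale of male-like
("androchromic") plumage: Class 1 is 0% androchromic, Class 4 is >= 50%.
Classes {1, 2} binarize to the heterochrome morph and {3, 4} to the
androchrome morph.  A species *exhibits* female-limited polymorphism (FLP)
when at least ``presence_min_prop`` of its females are androchromic and
the female score distribution is not unimodal; it *lacks* FLP when at
least ``absence_min_females`` females have been sampled without meeting
the presence rule — with 19 females there is an ~85% chance of sampling at
least one androchrome female if the morph frequency is 10%.  Species
meeting neither rule remain unclassified.  A configurable grid of
threshold combinations supports sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dip import dip_test
from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "ThresholdConfig", "FLPClassification",
    "binarize_plumage_class", "ingest_records", "summarize_species",
    "detection_probability", "required_sample_size",
    "classify_species", "classify_all", "default_sensitivity_grid",
    "build_sensitivity_matrices",
]

VALID_CLASSES = (1, 2, 3, 4)
STATUSES = ("FLP", "no_FLP_dichromic", "monochromic", "unclassified")


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    """Presence/absence thresholds for the FLP decision rule."""

    presence_min_prop: float = 0.10
    androchrome_min_class: int = 3
    absence_min_females: int = 19
    dip_alpha: float = 0.05
    require_bimodality: bool = True
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.presence_min_prop <= 1.0:
            raise InvalidArgumentError("presence_min_prop must be in (0, 1]")
        if self.androchrome_min_class not in (3, 4):
            raise InvalidArgumentError("androchrome_min_class must be 3 or 4")
        if self.absence_min_females < 1:
            raise InvalidArgumentError("absence_min_females must be >= 1")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return (f"p{int(round(self.presence_min_prop * 100)):02d}"
                f"_c{self.androchrome_min_class}"
                f"_a{self.absence_min_females}")


@dataclasses.dataclass(frozen=True)
class FLPClassification:
    species: str
    status: str
    n_females: int
    prop_androchrome: float
    dip_p: float


def binarize_plumage_class(plumage_class: int,
                           androchrome_min_class: int = 3) -> str:
    """Map an ordinal class to the heterochrome/androchrome morph."""
    if plumage_class not in VALID_CLASSES:
        raise InvalidArgumentError(
            f"plumage_class must be in {VALID_CLASSES}, got {plumage_class}")
    return ("androchrome" if plumage_class >= androchrome_min_class
            else "heterochrome")


def ingest_records(records: pd.DataFrame) -> pd.DataFrame:
    """Drop plumage-sexed specimens and validate classes.

    Specimens tagged as sexed by plumage are circular for this analysis
    and are excluded up front.
    """
    bad = ~records["plumage_class"].isin(VALID_CLASSES)
    if bad.any():
        raise InvalidArgumentError(
            f"{int(bad.sum())} records with plumage_class outside 1..4")
    if "sexing_method" in records.columns:
        records = records[records["sexing_method"] != "plumage"]
    return records.reset_index(drop=True)


def summarize_species(records: pd.DataFrame, *,
                      androchrome_min_class: int = 3,
                      with_dip: bool = True, dip_boot: int = 200,
                      seed: int = 0) -> pd.DataFrame:
    """Per-species female score summary.

    Counts are restricted to specimens tagged female (unknown-sex skins are
    excluded).  ``prop_androchrome`` is the fraction of females at or above
    ``androchrome_min_class``; ``dip_p`` is the bootstrap unimodality
    p-value of the female scores (NaN when fewer than 4 females).  Rows are
    ordered by species label.
    """
    records = ingest_records(records)
    females = records[records["sex"] == "female"]
    rows = []
    for sp in sorted(records["species"].unique()):
        scores = females.loc[females["species"] == sp, "plumage_class"]
        n = len(scores)
        counts = [int((scores == c).sum()) for c in VALID_CLASSES]
        prop = (float((scores >= androchrome_min_class).mean())
                if n else float("nan"))
        if with_dip and n >= 4:
            dip_p = dip_test(scores.to_numpy(), n_boot=dip_boot, seed=seed)
        else:
            dip_p = float("nan")
        rows.append((sp, n, *counts, prop, dip_p))
    return pd.DataFrame(rows, columns=[
        "species", "n_females", "n_class1", "n_class2", "n_class3",
        "n_class4", "prop_androchrome", "dip_p"])


def detection_probability(n_females: int, morph_freq: float) -> float:
    """Chance of sampling at least one androchrome female.

    With morph frequency ``f`` in the population, a sample of ``n`` females
    contains at least one androchrome with probability ``1 - (1 - f)^n``
    (e.g. 85% for 18 females at a 10% morph frequency).
    """
    if not 0.0 <= morph_freq <= 1.0:
        raise InvalidArgumentError("morph_freq must be in [0, 1]")
    if n_females < 0:
        raise InvalidArgumentError("n_females must be >= 0")
    return 1.0 - (1.0 - morph_freq) ** n_females


def required_sample_size(morph_freq: float, target_prob: float) -> int:
    """Smallest n with ``detection_probability(n, f) >= target``."""
    if not 0.0 < morph_freq <= 1.0:
        raise InvalidArgumentError("no finite sample detects a 0-frequency morph")
    if not 0.0 < target_prob < 1.0:
        raise InvalidArgumentError("target_prob must be in (0, 1)")
    if morph_freq == 1.0:
        return 1
    n = math.ceil(math.log1p(-target_prob) / math.log1p(-morph_freq))
    while detection_probability(n, morph_freq) < target_prob:  # guard rounding
        n += 1
    while n > 1 and detection_probability(n - 1, morph_freq) >= target_prob:
        n -= 1
    return n


def classify_species(summary_row, dichromatism_flag: str,
                     config: ThresholdConfig = ThresholdConfig(),
                     previously_flp: bool = False) -> FLPClassification:
    """Apply the presence/absence decision rule to one species summary.

    Presence: androchrome proportion >= ``presence_min_prop`` and (unless
    bimodality is not required) dip p-value < ``dip_alpha``.  Absence:
    at least ``absence_min_females`` females sampled, the presence rule not
    met, and no prior literature report of FLP; absent species carry the
    external dichromatism flag.  Everything else is unclassified.
    """
    if dichromatism_flag not in ("dichromic", "monochromic"):
        raise InvalidArgumentError(
            f"dichromatism_flag must be dichromic/monochromic, "
            f"got {dichromatism_flag!r}")
    sp = summary_row["species"]
    n = int(summary_row["n_females"])
    prop = float(summary_row["prop_androchrome"]) if n else 0.0
    dip_p = float(summary_row.get("dip_p", float("nan")))

    presence_candidate = n > 0 and prop >= config.presence_min_prop
    if presence_candidate:
        if not config.require_bimodality:
            return FLPClassification(sp, "FLP", n, prop, dip_p)
        if math.isnan(dip_p):
            # presence proportion met but unimodality untestable
            return FLPClassification(sp, "unclassified", n, prop, dip_p)
        if dip_p < config.dip_alpha:
            return FLPClassification(sp, "FLP", n, prop, dip_p)
    if n >= config.absence_min_females and not previously_flp:
        status = ("monochromic" if dichromatism_flag == "monochromic"
                  else "no_FLP_dichromic")
        return FLPClassification(sp, status, n, prop, dip_p)
    return FLPClassification(sp, "unclassified", n, prop, dip_p)


def classify_all(summaries: pd.DataFrame,
                 dichromatism_flags: Mapping[str, str],
                 config: ThresholdConfig = ThresholdConfig(),
                 previously_flp: Mapping[str, bool] | None = None,
                 ) -> pd.DataFrame:
    """Classify every summarized species; one row per species."""
    previously_flp = previously_flp or {}
    rows = []
    for _, row in summaries.iterrows():
        sp = row["species"]
        flag = dichromatism_flags.get(sp, "dichromic")
        c = classify_species(row, flag, config,
                             previously_flp.get(sp, False))
        rows.append(dataclasses.asdict(c))
    return pd.DataFrame(rows)


def default_sensitivity_grid() -> list[ThresholdConfig]:
    """Eight threshold combinations for sensitivity analysis."""
    grid = []
    for prop, cls, absence in itertools.product((0.05, 0.10), (3, 4),
                                                (10, 19)):
        grid.append(ThresholdConfig(presence_min_prop=prop,
                                    androchrome_min_class=cls,
                                    absence_min_females=absence))
    return grid


def build_sensitivity_matrices(records: pd.DataFrame,
                               dichromatism_flags: Mapping[str, str],
                               config_grid: Iterable[ThresholdConfig] | None = None,
                               *, dip_boot: int = 200, seed: int = 0,
                               ) -> dict[str, pd.DataFrame]:
    """One classification table per threshold configuration.

    Summaries are recomputed per configuration because the androchrome
    class cut changes the presence proportion.  Configuration labels must
    be unique.
    """
    grid = list(config_grid) if config_grid is not None else default_sensitivity_grid()
    if not grid:
        raise InvalidArgumentError("config_grid must be non-empty")
    names = [c.name for c in grid]
    if len(set(names)) != len(names):
        raise InvalidArgumentError(f"duplicate configuration labels: {names}")
    out = {}
    summaries_by_cut: dict[int, pd.DataFrame] = {}
    for cfg in grid:
        cut = cfg.androchrome_min_class
        if cut not in summaries_by_cut:
            summaries_by_cut[cut] = summarize_species(
                records, androchrome_min_class=cut, dip_boot=dip_boot,
                seed=seed)
        out[cfg.name] = classify_all(summaries_by_cut[cut],
                                     dichromatism_flags, cfg)
    return out
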