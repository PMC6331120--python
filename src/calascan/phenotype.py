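"""Halo-rating phenotyping: consolidation, classification, screen summaries.

Colonies spotted on tributyrin (short-chain, clearing halo) or olive-oil/
rhodamine (long-chain, fluorescent halo) plates are rated in triplicate on an
ordinal 0..4 scale (wild type = 3; 0 = no halo, made explicit here).  The
triplicates are consolidated by median, then each clone is classified for
per-substrate activity and for chain-length discrimination.

The verbal selection rule ("strong hydrolysis of one substrate and weak or no
hydrolysis of the other") is made numeric by configurable thresholds:
active iff rating >= 2 (unequivocal halo); strong discrimination iff the
preferred substrate rates >= 3 while the other rates <= 1; weak iff the
preferred rates exactly 2 with the other <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from statistics import median

import pandas as pd

from .reference import round_half_up

__all__ = [
    "SUBSTRATES",
    "RATING_MIN",
    "RATING_MAX",
    "Thresholds",
    "HaloObservation",
    "PhenotypeCall",
    "ScreenSummary",
    "ReplicateDisagreementWarning",
    "consolidate",
    "classify",
    "call_phenotypes",
    "summarize_screen",
    "read_ratings",
    "calls_table",
    "summary_table",
]

SUBSTRATES = ("tributyrin", "olive_oil")
RATING_MIN, RATING_MAX = 0, 4


class ReplicateDisagreementWarning(UserWarning):
    """Triplicate halo ratings span more than one ordinal shade."""


@dataclass(frozen=True)
class Thresholds:
    """Numeric decision thresholds for the ordinal classification rule."""

    active_min: int = 2        # rating at/above which a halo counts as active
    strong_pref_min: int = 3   # preferred-substrate rating for strong discrimination
    weak_pref: int = 2         # preferred-substrate rating for weak discrimination
    other_max: int = 1         # max rating tolerated on the disfavored substrate


@dataclass(frozen=True)
class HaloObservation:
    clone_id: str
    substrate: str
    ratings: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if len(self.ratings) != 3:
            raise ValueError("exactly 3 replicate ratings required")
        for r in self.ratings:
            if not (isinstance(r, int) and RATING_MIN <= r <= RATING_MAX):
                raise ValueError(f"rating {r!r} outside {RATING_MIN}..{RATING_MAX}")


@dataclass(frozen=True)
class PhenotypeCall:
    clone_id: str
    rating_short: int
    rating_long: int
    active_short: bool
    active_long: bool
    discrimination: str   # short | long | none
    strength: str         # strong | weak | n/a


@dataclass(frozen=True)
class ScreenSummary:
    library_id: str
    clones_screened: int
    n_active: int
    pct_active: int
    n_discriminative_short: int
    n_discriminative_long: int


def consolidate(obs: HaloObservation) -> int:
    """Median of the three replicate ratings.

    Replicate disagreement (range > 1 shade) is surfaced as a warning; the
    median is still used.
    """
    if max(obs.ratings) - min(obs.ratings) > 1:
        warnings.warn(
            f"clone {obs.clone_id} / {obs.substrate}: replicate ratings "
            f"{obs.ratings} span more than one shade",
            ReplicateDisagreementWarning, stacklevel=2,
        )
    return int(median(obs.ratings))


def classify(rating_short: int, rating_long: int,
             thresholds: Thresholds = Thresholds(),
             clone_id: str = "") -> PhenotypeCall:
    """Classify consolidated ratings into activity flags and discrimination."""
    for r in (rating_short, rating_long):
        if not RATING_MIN <= r <= RATING_MAX:
            raise ValueError(f"rating {r} outside {RATING_MIN}..{RATING_MAX}")
    t = thresholds
    active_short = rating_short >= t.active_min
    active_long = rating_long >= t.active_min

    discrimination, strength = "none", "n/a"
    pref, other, direction = ((rating_short, rating_long, "short")
                              if rating_short > rating_long
                              else (rating_long, rating_short, "long"))
    if rating_short != rating_long and other <= t.other_max:
        if pref >= t.strong_pref_min:
            discrimination, strength = direction, "strong"
        elif pref == t.weak_pref:
            discrimination, strength = direction, "weak"
    return PhenotypeCall(
        clone_id=clone_id,
        rating_short=rating_short, rating_long=rating_long,
        active_short=active_short, active_long=active_long,
        discrimination=discrimination, strength=strength,
    )


def call_phenotypes(observations: list[HaloObservation],
                    thresholds: Thresholds = Thresholds()) -> list[PhenotypeCall]:
    """Consolidate and classify paired-substrate observations per clone.

    Each clone must appear with both substrates; order in the input is free.
    """
    by_clone: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for obs in observations:
        if obs.clone_id not in by_clone:
            by_clone[obs.clone_id] = {}
            order.append(obs.clone_id)
        by_clone[obs.clone_id][obs.substrate] = consolidate(obs)
    calls = []
    for clone_id in order:
        ratings = by_clone[clone_id]
        missing = set(SUBSTRATES) - set(ratings)
        if missing:
            raise ValueError(f"clone {clone_id} missing substrate(s): {sorted(missing)}")
        calls.append(classify(ratings["tributyrin"], ratings["olive_oil"],
                              thresholds, clone_id=clone_id))
    return calls


def summarize_screen(calls: list[PhenotypeCall], library_id: str) -> ScreenSummary:
    """Count active and discriminative clones; percent active to whole percent."""
    if not calls:
        raise ValueError("summarize_screen requires at least one phenotype call")
    n_active = sum(1 for c in calls if c.active_short or c.active_long)
    return ScreenSummary(
        library_id=library_id,
        clones_screened=len(calls),
        n_active=n_active,
        pct_active=int(round_half_up(100.0 * n_active / len(calls), 0)),
        n_discriminative_short=sum(1 for c in calls if c.discrimination == "short"),
        n_discriminative_long=sum(1 for c in calls if c.discrimination == "long"),
    )


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

def read_ratings(path: str | Path) -> list[HaloObservation]:
    """Read a ratings table (clone_id, substrate, rep1, rep2, rep3; TSV/CSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return [
        HaloObservation(str(row.clone_id), str(row.substrate),
                        (int(row.rep1), int(row.rep2), int(row.rep3)))
        for row in df.itertuples()
    ]


def calls_table(calls: list[PhenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def summary_table(summaries: list[ScreenSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
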