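"""Germination rates, germination timelines, penetrance and association.

Conidia of known concentration are plated on media with different
carbon sources; germination rate per strain and condition is the mean
replicate colony count over the expected colony number (from the
suspension concentration) times 100%.  Penetrance is the fraction of a
strain's conidiophores displaying its majority architectural phenotype.
Phenotype-category association (e.g. communication group vs phenotype)
is assessed by the Pearson chi-square test of independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import PHENOTYPE_ORDER, PhenotypeLabel

__all__ = [
    "GerminationRecord",
    "PenetranceRecord",
    "AssociationResult",
    "expected_colonies",
    "germination_rate",
    "germination_timeline",
    "penetrance",
    "association_test",
]

#: Germination rates above this are reported as-is but flagged: the
#: suspension concentration behind the expected count is only roughly
#: calibrated.
RATE_WARN_THRESHOLD = 120.0


@dataclass(frozen=True)
class GerminationRecord:
    """Replicate colony counts for one strain on one medium condition."""

    strain: str
    phenotype: PhenotypeLabel | None
    carbon_source: str
    concentration: float  # percent w/v
    replicate_colony_counts: tuple[int, ...]
    expected_colonies: float
    first_germination_day: int | None = None

    def __post_init__(self) -> None:
        if len(self.replicate_colony_counts) < 1:
            raise ValueError("at least one replicate count is required")
        if any(c < 0 for c in self.replicate_colony_counts):
            raise ValueError("replicate colony counts must be non-negative")
        if self.expected_colonies <= 0:
            raise ValueError("expected colony count must be > 0")
        if (self.first_germination_day is not None
                and self.first_germination_day < 1):
            raise ValueError("first germination day must be >= 1")

    @property
    def condition(self) -> str:
        return f"{self.carbon_source} {self.concentration:g}%"


@dataclass(frozen=True)
class PenetranceRecord:
    """Majority phenotype and its fraction for one strain."""

    classified_counts: dict[PhenotypeLabel, int]
    majority_phenotype: PhenotypeLabel
    penetrance: float
    strain: str = ""
    fractions: dict[PhenotypeLabel, float] = field(default_factory=dict)


@dataclass(frozen=True)
class AssociationResult:
    """Pearson chi-square test of independence on a contingency table."""

    chisq: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray


def expected_colonies(concentration_cells_per_ml: float,
                      volume_plated_ml: float) -> float:
    """Expected colony count: suspension concentration times volume.

    e.g. 1.00e3 cells/ml plated at 100 ul (0.1 ml) -> 100 colonies.
    """
    if concentration_cells_per_ml <= 0 or volume_plated_ml <= 0:
        raise ValueError("concentration and plated volume must be > 0")
    return concentration_cells_per_ml * volume_plated_ml


def germination_rate(record: GerminationRecord) -> float:
    """Germination rate in percent for one plate-count record.

    ``mean(replicate counts) / expected colonies x 100``.  The rate may
    exceed 100% because the expected count derives from a roughly
    calibrated suspension; values above 120% are reported unchanged but
    trigger a warning.
    """
    rate = (float(np.mean(record.replicate_colony_counts))
            / record.expected_colonies * 100.0)
    if rate > RATE_WARN_THRESHOLD:
        warnings.warn(
            f"germination rate {rate:.1f}% for {record.strain!r} on "
            f"{record.condition!r} exceeds {RATE_WARN_THRESHOLD:g}%; check "
            "the expected colony calibration", RuntimeWarning, stacklevel=2)
    return rate


def germination_timeline(
    records: list[GerminationRecord],
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Pivot first-germination days to strain x condition, flag early strains.

    Returns the pivoted table and, per condition, the strain that
    germinated strictly earlier than every other strain (``None`` when
    no strain did).  Records without a recorded first day are excluded
    with a warning.
    """
    usable = []
    for rec in records:
        if rec.first_germination_day is None:
            warnings.warn(
                f"record for {rec.strain!r} on {rec.condition!r} has no "
                "first germination day; excluded from the timeline",
                RuntimeWarning, stacklevel=2)
        else:
            usable.append(rec)
    if not usable:
        return pd.DataFrame(), {}
    frame = pd.DataFrame({
        "strain": [r.strain for r in usable],
        "condition": [r.condition for r in usable],
        "day": [r.first_germination_day for r in usable],
    })
    table = frame.pivot_table(index="strain", columns="condition",
                              values="day", aggfunc="min")
    early: dict[str, str | None] = {}
    for condition in table.columns:
        days = table[condition].dropna()
        early[condition] = None
        if len(days) >= 2:
            ranked = days.sort_values()
            if ranked.iloc[0] < ranked.iloc[1]:
                early[condition] = str(ranked.index[0])
    return table, early


def penetrance(
    classified_counts: dict[PhenotypeLabel, int],
    strain: str = "",
) -> PenetranceRecord:
    """Majority phenotype and the fraction of conidiophores showing it.

    Ties between phenotypes are broken by the fixed WT < Wrap < Bulky
    order, with a warning.
    """
    counts = {PhenotypeLabel.parse(k) if not isinstance(k, PhenotypeLabel)
              else k: int(v) for k, v in classified_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("classified counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("at least one classified conidiophore is required")
    ordered = [p for p in PHENOTYPE_ORDER if p in counts]
    best = max(ordered, key=lambda p: counts[p])
    top = counts[best]
    if sum(1 for p in ordered if counts[p] == top) > 1:
        warnings.warn(
            f"penetrance tie for {strain or 'strain'}; broken by the fixed "
            "WT < Wrap < Bulky order", RuntimeWarning, stacklevel=2)
    return PenetranceRecord(
        classified_counts=counts,
        majority_phenotype=best,
        penetrance=top / total,
        strain=strain,
        fractions={p: counts[p] / total for p in ordered},
    )


def association_test(observed) -> AssociationResult:
    """Pearson chi-square test of independence on an r x c table.

    Expected counts are the outer product of the margins over the grand
    total; df = (r - 1)(c - 1); no continuity correction.  A warning is
    emitted when any expected cell falls below 5 (the usual validity
    guideline for the chi-squared approximation).
    """
    table = np.asarray(observed, float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("every row and column margin must be positive")
    chisq, p, df, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 5):
        warnings.warn(
            "some expected cells are below 5; the chi-squared approximation "
            "may be inaccurate", RuntimeWarning, stacklevel=2)
    return AssociationResult(
        chisq=float(chisq), df=int(df), p_value=float(p),
        observed=table, expected=np.asarray(expected, float))
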