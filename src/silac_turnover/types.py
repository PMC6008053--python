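"""Record types carried between pipeline stages.

Tabular data (peptide measurements, label counts, complex membership,
puncta counts) travel as validated pandas DataFrames with canonical
column names; the small per-entity results below are dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PEPTIDE_COLUMNS",
    "LABEL_COUNT_COLUMNS",
    "SAMPLE_KEY",
    "LabelPurity",
    "HalfLifeRecord",
    "ComparisonResult",
    "PairedDecayResult",
    "PunctaFit",
]

#: canonical columns of a peptide table
PEPTIDE_COLUMNS = (
    "sequence",
    "protein_group",
    "missed_cleavages",
    "ratio_HL",
    "light_only",
    "timepoint",
    "replicate",
    "injection",
    "condition",
)

#: a sample is one LC-MS injection of one replicate at one timepoint
SAMPLE_KEY = ("condition", "replicate", "injection", "timepoint")

LABEL_COUNT_COLUMNS = SAMPLE_KEY + ("LH_count", "HH_count")


@dataclass(frozen=True)
class LabelPurity:
    """Per-sample heavy-incorporation probability.

    P_H is the probability that a single Arg/Lys residue incorporated into
    a nascent protein is the heavy isotopologue; P_L = 1 - P_H is the
    residual-light probability of the post-switch medium.
    """

    sample: tuple
    LH_count: int
    HH_count: int
    P_H: float

    @property
    def P_L(self) -> float:
        return 1.0 - self.P_H


@dataclass
class HalfLifeRecord:
    """Per-protein first-order decay fit.

    ``censored`` marks proteins decaying too fast for a reliable fit within
    the sampling design; they carry the assignment "<1 day" and no numeric
    rate constant.
    """

    protein_group: str
    n_peptides: int
    n_points: int
    k_per_day: float | None
    se_k: float | None
    r_squared: float | None
    half_life_days: float | None
    censored: bool

    def __post_init__(self):
        if self.censored:
            assert self.k_per_day is None and self.half_life_days is None
        elif self.k_per_day is not None and self.half_life_days is None:
            self.half_life_days = math.log(2.0) / self.k_per_day


@dataclass
class ComparisonResult:
    """Cross-condition turnover verdict for one protein."""

    protein_group: str
    direction: str  # faster_in_A | faster_in_B | inconsistent
    p_values: dict[float, float]  # chase timepoint -> raw p-value
    significant_timepoints: dict[float, bool]  # after Bonferroni
    significant: bool


@dataclass
class PairedDecayResult:
    """Paired peptide-level decay comparison for one protein."""

    protein_group: str
    n_peptides: int
    mean_decay_A: float
    mean_decay_B: float
    p_value: float
    significant: bool


@dataclass
class PunctaFit:
    """Exponential fit to a puncta-per-cell pulse-chase time course."""

    target: str
    chase_days: tuple[float, ...]
    mean_counts: tuple[float, ...]
    n_cells: tuple[int, ...]
    k_per_day: float
    half_life_days: float
    r_squared: float
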