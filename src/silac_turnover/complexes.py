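"""Half-life cohesion of multi-protein complexes.

Tests whether co-members of annotated complexes have more similar
half-lives than randomly sampled proteins: the sample standard deviation
of half-lives is computed within each sufficiently measured complex and
compared, by a two-sided Mann-Whitney test, against SDs of size-matched
random groups drawn from the same half-life population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CohesionReport",
    "complex_sd",
    "random_sd_null",
    "cohesion_test",
    "cohesion_report",
]


@dataclass
class CohesionReport:
    """Cohesion statistics: per-complex SDs, the resampling null and the
    Mann-Whitney comparison."""

    complex_sds: pd.DataFrame  # complex_id, n_measured, sd_days
    null_sds: np.ndarray
    statistic: float
    p_value: float
    #: Spearman correlation of complex size vs SD (diagnostic)
    size_sd_spearman: float


def complex_sd(
    halflives: dict[str, float],
    complexes: pd.DataFrame,
    min_members: int = 5,
    min_measured: int = 3,
) -> pd.DataFrame:
    """Sample SD of half-lives within each sufficiently measured complex.

    ``halflives`` maps protein group to a numeric half-life in days;
    censored proteins carry no numeric value and must not be included.
    Complexes with fewer than ``min_members`` annotated members or fewer
    than ``min_measured`` measured half-lives are dropped.
    """
    if not halflives:
        raise ValueError("half-life map is empty")
    rows = []
    for cid, grp in complexes.groupby("complex_id", sort=True):
        members = grp["protein_group"].unique()
        if len(members) < min_members:
            continue
        values = np.array([halflives[m] for m in members if m in halflives])
        if values.size < min_measured:
            logger.info("complex %s dropped: %d/%d half-lives", cid,
                        values.size, len(members))
            continue
        rows.append((cid, len(members), values.size, float(np.std(values, ddof=1))))
    return pd.DataFrame(
        rows, columns=["complex_id", "n_members", "n_measured", "sd_days"]
    )


def random_sd_null(
    halflives: dict[str, float],
    group_sizes,
    n_rep: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
) -> np.ndarray:
    """Null SD distribution from size-matched random protein groups.

    Each repetition draws, for every tested complex size, a random group of
    that size from the half-life population (without replacement within a
    group by default) and records its sample SD. Deterministic given the
    seed.
    """
    values = np.asarray(list(halflives.values()), dtype=float)
    group_sizes = [int(s) for s in group_sizes]
    if not group_sizes:
        raise ValueError("no group sizes supplied")
    if not with_replacement and max(group_sizes) > values.size:
        raise ValueError(
            f"population ({values.size}) smaller than largest group "
            f"({max(group_sizes)})"
        )
    rng = np.random.default_rng([seed, 67])
    out = np.empty(n_rep * len(group_sizes))
    pos = 0
    for _ in range(n_rep):
        for size in group_sizes:
            draw = rng.choice(values, size=size, replace=with_replacement)
            out[pos] = np.std(draw, ddof=1)
            pos += 1
    return out


def cohesion_test(complex_sds, null_sds) -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of complex SDs against null SDs.

    Degenerate all-tie inputs (every SD identical in both samples) have an
    undefined tie-corrected normal statistic; the test is then saturated at
    U = n1*n2/2 with p = 1.
    """
    complex_sds = np.asarray(complex_sds, dtype=float)
    null_sds = np.asarray(null_sds, dtype=float)
    if complex_sds.size == 0 or null_sds.size == 0:
        raise ValueError("both SD samples must be non-empty")
    pooled = np.concatenate([complex_sds, null_sds])
    if np.all(pooled == pooled[0]):
        return complex_sds.size * null_sds.size / 2.0, 1.0
    u_stat, p = stats.mannwhitneyu(complex_sds, null_sds, alternative="two-sided")
    return float(u_stat), float(p)


def cohesion_report(
    halflives: dict[str, float],
    complexes: pd.DataFrame,
    min_members: int = 5,
    min_measured: int = 3,
    n_rep: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
) -> CohesionReport:
    """Full cohesion analysis: per-complex SDs, resampling null, test."""
    sds = complex_sd(halflives, complexes, min_members, min_measured)
    if sds.empty:
        raise ValueError("no complex passed the membership/measurement thresholds")
    null = random_sd_null(
        halflives, sds["n_measured"].tolist(), n_rep, seed, with_replacement
    )
    statistic, p = cohesion_test(sds["sd_days"].to_numpy(), null)
    if sds["n_members"].nunique() > 1 and sds["sd_days"].nunique() > 1:
        rho = float(stats.spearmanr(sds["n_members"], sds["sd_days"]).statistic)
    else:
        rho = float("nan")
    return CohesionReport(
        complex_sds=sds, null_sds=null, statistic=statistic, p_value=p,
        size_sd_spearman=rho,
    )
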