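"""Per-protein half-life determination from corrected peptide fractions.

Stages, in order: peptide filtering (complete time courses per biological
replicate, t0 mean %old above threshold, protein-group-unique peptides),
replicate merging, Tukey-fence outlier removal per protein and timepoint,
exclusion of profiles without a continuous decay, k-means censoring of
fast-turnover proteins to "<1 day", and a no-intercept least-squares fit of
ln(%old) on time. The regression has no intercept because ln(%old) = -k*t
passes through the origin by construction; the reported R^2 is therefore
the uncentered coefficient of determination. The half-life is ln(2)/k.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .kinetics import compute_old_fractions
from .types import HalfLifeRecord, LabelPurity

logger = logging.getLogger(__name__)

__all__ = [
    "filter_peptides",
    "remove_outliers",
    "check_monotonic_decay",
    "cluster_fast_turnover",
    "fit_halflife",
    "prepare_profiles",
    "run_pipeline",
]


def filter_peptides(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    timepoints=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the peptide-level retention rules within biological replicates.

    Retains, per (condition, replicate), only peptides quantified at every
    design timepoint and whose mean %old at t0 exceeds the threshold
    (default 0.9); peptides mapping to more than one protein group are
    dropped first. Replicates are merged afterwards simply by pooling the
    retained rows. Returns (retained rows, exclusion log).
    """
    config = config or PipelineConfig()
    exclusions = []
    table = table[~table["excluded"]] if "excluded" in table.columns else table
    if timepoints is None:
        timepoints = np.sort(table["timepoint"].unique())
    timepoints = np.asarray(timepoints, dtype=float)

    multi = table["protein_group"].str.contains(";")
    shared = table.groupby("sequence")["protein_group"].transform("nunique") > 1
    nonunique = multi | shared
    for seq in table.loc[nonunique, "sequence"].unique():
        exclusions.append(("peptide", seq, "filter", "not_unique_to_protein_group"))
    table = table[~nonunique]

    key = ["condition", "replicate", "sequence"]
    grouped = table.groupby(key, sort=False)
    coverage = grouped["timepoint"].nunique()
    complete = coverage[coverage == len(timepoints)].index

    t0_mean = (
        table[table["timepoint"] == 0.0].groupby(key, sort=False)["fraction_old"].mean()
    )
    good_t0 = t0_mean[t0_mean > config.t0_min_old].index

    keep_index = complete.intersection(good_t0)
    dropped = coverage.index.difference(keep_index)
    for cond, rep, seq in dropped:
        reason = (
            "incomplete_time_course"
            if (cond, rep, seq) not in complete
            else "t0_mean_below_threshold"
        )
        exclusions.append(("peptide_replicate", f"{cond}/{rep}/{seq}", "filter", reason))

    keep = pd.MultiIndex.from_frame(table[key]).isin(keep_index)
    retained = table[keep].reset_index(drop=True)
    logger.info(
        "filter_peptides: retained %d/%d rows (%d peptide-replicates dropped)",
        len(retained), len(table), len(dropped),
    )
    excl = pd.DataFrame(exclusions, columns=["level", "entity", "stage", "reason"])
    return retained, excl


def remove_outliers(values, tukey_k: float = 1.5) -> np.ndarray:
    """Boolean retention mask under Tukey fences.

    Quartiles use linear interpolation between order statistics; values
    outside [Q1 - k*IQR, Q3 + k*IQR] are flagged for removal. With one
    value, or all values equal, everything is retained.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("remove_outliers requires at least one value")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return (values >= q1 - tukey_k * iqr) & (values <= q3 + tukey_k * iqr)


def _tukey_filter(retained: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    group = retained.groupby(["condition", "protein_group", "timepoint"], sort=False)
    q1 = group["fraction_old"].transform(lambda s: np.percentile(s, 25.0))
    q3 = group["fraction_old"].transform(lambda s: np.percentile(s, 75.0))
    iqr = q3 - q1
    ok = (retained["fraction_old"] >= q1 - config.tukey_k * iqr) & (
        retained["fraction_old"] <= q3 + config.tukey_k * iqr
    )
    logger.info("outlier removal: %d/%d values removed", int((~ok).sum()), len(ok))
    return retained[ok].reset_index(drop=True)


def check_monotonic_decay(means_by_timepoint, tolerance: float = 0.05) -> bool:
    """True iff per-timepoint means never rise by more than ``tolerance``
    between consecutive ordered timepoints."""
    series = pd.Series(means_by_timepoint).sort_index()
    values = series.to_numpy(dtype=float)
    return bool(np.all(values[1:] <= values[:-1] + tolerance))


def cluster_fast_turnover(
    mean_profiles: pd.DataFrame,
    k_clusters: int = 6,
    seed: int = 0,
    censor_day: float = 1.0,
    censor_threshold: float = 0.5,
) -> set[str]:
    """Censor proteins in fast-decay k-means clusters to "<1 day".

    ``mean_profiles`` is proteins x timepoints (mean %old). Proteins in
    clusters whose centroid %old at the censoring day is at or below the
    threshold decay too fast for a reliable exponential fit. With fewer
    profiles than clusters the per-protein rule (mean %old at the censoring
    day <= threshold) is applied directly.
    """
    if mean_profiles.empty:
        return set()
    days = np.asarray(mean_profiles.columns, dtype=float)
    eligible = days >= censor_day
    if not eligible.any():
        raise ValueError(f"no timepoint at or after censor_day={censor_day}")
    day_col = int(np.argmax(eligible))  # first timepoint >= censor_day

    matrix = mean_profiles.to_numpy(dtype=float)
    if len(mean_profiles) < k_clusters:
        fast = matrix[:, day_col] <= censor_threshold
        return set(mean_profiles.index[fast])
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10)
    labels = km.fit_predict(matrix)
    fast_clusters = np.flatnonzero(km.cluster_centers_[:, day_col] <= censor_threshold)
    fast = np.isin(labels, fast_clusters)
    return set(mean_profiles.index[fast])


def fit_halflife(
    t,
    fraction_old,
    protein_group: str = "",
    n_peptides: int = 0,
    include_t0: bool = True,
) -> HalfLifeRecord | None:
    """No-intercept least-squares fit of ln(%old) on time.

    k is the negated slope, with its standard error and the uncentered
    R^2; half-life = ln(2)/k. Returns None when the fitted k is not
    positive (unfittable profile, logged by the caller). Points with
    non-positive fractions never reach the log transform.
    """
    t = np.asarray(t, dtype=float)
    old = np.asarray(fraction_old, dtype=float)
    keep = old > 0
    if not include_t0:
        keep &= t > 0
    t, old = t[keep], old[keep]
    if t.size < 3 or np.all(t == 0):
        return None
    y = np.log(old)
    fit = sm.OLS(y, t[:, None]).fit()
    slope = float(fit.params[0])
    k = -slope
    if k <= 0:
        return None
    se = float(fit.bse[0])
    if not np.isfinite(se):  # perfect fit with zero residual variance
        se = 0.0
    return HalfLifeRecord(
        protein_group=protein_group,
        n_peptides=n_peptides,
        n_points=int(t.size),
        k_per_day=k,
        se_k=se,
        r_squared=float(fit.rsquared),
        half_life_days=math.log(2.0) / k,
        censored=False,
    )


def prepare_profiles(
    table: pd.DataFrame,
    purities: list[LabelPurity],
    config: PipelineConfig | None = None,
    timepoints=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """%old computation, peptide filtering and outlier removal.

    Returns the retained peptide-level rows (the pooled decay profiles all
    downstream statistics draw from) and the exclusion log.
    """
    config = config or PipelineConfig()
    with_old = compute_old_fractions(table, purities, config)
    retained, exclusions = filter_peptides(with_old, config, timepoints)
    retained = _tukey_filter(retained, config)
    return retained, exclusions


def run_pipeline(
    table: pd.DataFrame,
    purities: list[LabelPurity],
    config: PipelineConfig | None = None,
    timepoints=None,
    condition: str | None = None,
) -> tuple[list[HalfLifeRecord], pd.DataFrame]:
    """Full half-life pipeline for one condition.

    Ordering: fraction computation -> filtering -> replicate merge ->
    outlier removal -> monotonic-decay exclusion -> fast-turnover censoring
    -> no-intercept fitting. Every exclusion is logged with its stage and
    reason. ``condition`` restricts a multi-condition table.
    """
    config = (config or PipelineConfig()).validate()
    if condition is not None:
        table = table[table["condition"] == condition]
    if table["condition"].nunique() > 1:
        raise ValueError(
            "run_pipeline operates on one condition; pass condition=..."
        )
    retained, exclusions = prepare_profiles(table, purities, config, timepoints)
    excl_rows = exclusions.values.tolist()

    if retained.empty:
        logger.warning("run_pipeline: no peptides survived filtering")
        return [], pd.DataFrame(
            excl_rows, columns=["level", "entity", "stage", "reason"]
        )

    mean_profiles = retained.pivot_table(
        index="protein_group", columns="timepoint", values="fraction_old",
        aggfunc="mean",
    )

    monotone = mean_profiles.apply(
        lambda row: check_monotonic_decay(row.dropna(), config.monotonic_tolerance),
        axis=1,
    )
    for protein in mean_profiles.index[~monotone]:
        excl_rows.append(("protein", protein, "monotonicity", "non_continuous_decay"))
    mean_profiles = mean_profiles[monotone]

    censored = cluster_fast_turnover(
        mean_profiles.dropna(),
        k_clusters=config.k_clusters,
        seed=config.cluster_seed,
        censor_day=config.censor_day,
        censor_threshold=config.censor_threshold,
    )

    records: list[HalfLifeRecord] = []
    by_protein = retained[retained["protein_group"].isin(mean_profiles.index)].groupby(
        "protein_group", sort=True
    )
    for protein, grp in by_protein:
        n_peptides = grp["sequence"].nunique()
        if protein in censored:
            records.append(
                HalfLifeRecord(
                    protein_group=protein, n_peptides=n_peptides,
                    n_points=len(grp), k_per_day=None, se_k=None,
                    r_squared=None, half_life_days=None, censored=True,
                )
            )
            continue
        record = fit_halflife(
            grp["timepoint"].to_numpy(), grp["fraction_old"].to_numpy(),
            protein_group=protein, n_peptides=n_peptides,
            include_t0=config.include_t0_in_fit,
        )
        if record is None:
            excl_rows.append(("protein", protein, "fit", "nonpositive_rate_constant"))
            continue
        records.append(record)

    logger.info(
        "run_pipeline: %d proteins fitted (%d censored), %d exclusions logged",
        len(records), len(censored), len(excl_rows),
    )
    exclusion_log = pd.DataFrame(
        excl_rows, columns=["level", "entity", "stage", "reason"]
    )
    return records, exclusion_log
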