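"""Cross-condition protein turnover comparisons.

Two procedures are implemented. The culture-type comparison takes the
retained %old values per protein and chase timepoint in two conditions,
keeps only proteins whose per-timepoint means differ in a consistent
direction at every chase timepoint, runs a two-sided t-test per timepoint
(Welch by default), applies a Bonferroni correction over the total number
of tests performed, and calls a protein significant when at least two of
the three chase timepoints stay significant. The paired-design comparison
reduces each peptide to its decay (%old at t0 minus %old at the final
chase day), matches peptides by sequence across conditions, and applies a
paired t-test per protein with Bonferroni correction over proteins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig, SimulationConfig
from .halflife import prepare_profiles
from .kinetics import estimate_purity_table
from .simulate import generate_proteome, simulate_silac_experiment
from .types import ComparisonResult, PairedDecayResult

logger = logging.getLogger(__name__)

__all__ = [
    "compare_culture_turnover",
    "compare_paired_decay",
    "type_one_error_audit",
]


def _value_sets(profiles: pd.DataFrame, chase: np.ndarray) -> dict:
    """protein -> {timepoint -> ndarray of retained %old values}."""
    out: dict[str, dict[float, np.ndarray]] = {}
    sub = profiles[profiles["timepoint"].isin(chase)]
    for (protein, tp), grp in sub.groupby(["protein_group", "timepoint"], sort=False):
        out.setdefault(protein, {})[float(tp)] = grp["fraction_old"].to_numpy()
    return out


def compare_culture_turnover(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = True,
    chase_timepoints=None,
    exclude: set | None = None,
    replicate_means: bool = False,
) -> list[ComparisonResult]:
    """Per-protein turnover comparison between two culture types.

    ``profiles_*`` are retained peptide-level rows (protein_group,
    timepoint, fraction_old, and replicate when ``replicate_means`` is
    used) from :func:`silac_turnover.halflife.prepare_profiles`.
    ``exclude`` removes proteins without a comparable rate (e.g. censored
    "<1 day" in either condition). Only proteins whose mean %old is always
    greater, or always smaller, in A than in B at every chase timepoint
    enter testing; the Bonferroni denominator is the number of tested
    proteins times the number of chase timepoints.
    """
    if replicate_means:
        keys = ["protein_group", "timepoint", "replicate"]
        profiles_a = profiles_a.groupby(keys, as_index=False)["fraction_old"].mean()
        profiles_b = profiles_b.groupby(keys, as_index=False)["fraction_old"].mean()
    if chase_timepoints is None:
        chase_timepoints = np.sort(
            profiles_a.loc[profiles_a["timepoint"] > 0, "timepoint"].unique()
        )
    chase = np.asarray(chase_timepoints, dtype=float)
    sets_a = _value_sets(profiles_a, chase)
    sets_b = _value_sets(profiles_b, chase)
    shared = sorted(set(sets_a) & set(sets_b) - (exclude or set()))
    if not shared:
        logger.warning("compare_culture_turnover: no shared proteins")
        return []

    testable: list[str] = []
    directions: dict[str, str] = {}
    for protein in shared:
        cells_a, cells_b = sets_a[protein], sets_b[protein]
        if any(
            tp not in cells_a or tp not in cells_b
            or cells_a[tp].size < 2 or cells_b[tp].size < 2
            for tp in chase
        ):
            continue
        diffs = np.array([cells_a[tp].mean() - cells_b[tp].mean() for tp in chase])
        if np.all(diffs < 0):
            # lower %old in A at every timepoint = faster decay in A
            directions[protein] = "faster_in_A"
        elif np.all(diffs > 0):
            directions[protein] = "faster_in_B"
        else:
            directions[protein] = "inconsistent"
            continue
        testable.append(protein)

    n_tests = len(testable) * len(chase)
    results: list[ComparisonResult] = []
    for protein in shared:
        direction = directions.get(protein, "inconsistent")
        if protein not in testable:
            results.append(
                ComparisonResult(protein, direction, {}, {}, significant=False)
            )
            continue
        p_values, sig = {}, {}
        for tp in chase:
            _, p = stats.ttest_ind(
                sets_a[protein][tp], sets_b[protein][tp], equal_var=not welch
            )
            p = float(p)
            p_values[float(tp)] = p
            sig[float(tp)] = bool(p * n_tests < alpha)
        n_sig = sum(sig.values())
        results.append(
            ComparisonResult(
                protein_group=protein,
                direction=direction,
                p_values=p_values,
                significant_timepoints=sig,
                significant=n_sig >= 2,
            )
        )
    logger.info(
        "compare_culture_turnover: %d shared, %d tested, %d significant",
        len(shared), len(testable), sum(r.significant for r in results),
    )
    return results


def _peptide_decay(oldfrac: pd.DataFrame, t_final: float) -> pd.DataFrame:
    """Per-peptide decay = mean %old(t0) - mean %old(final chase day)."""
    valid = oldfrac[~oldfrac["excluded"]] if "excluded" in oldfrac.columns else oldfrac
    t0 = (
        valid[valid["timepoint"] == 0.0]
        .groupby(["protein_group", "sequence"])["fraction_old"].mean()
    )
    t_end = (
        valid[valid["timepoint"] == t_final]
        .groupby(["protein_group", "sequence"])["fraction_old"].mean()
    )
    decay = (t0 - t_end).dropna().rename("decay")
    return decay[decay >= 0].reset_index()


def compare_paired_decay(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    t_final: float | None = None,
) -> list[PairedDecayResult]:
    """Paired peptide-level decay comparison for a two-timepoint design.

    Inputs are %old-annotated peptide tables (see
    :func:`silac_turnover.kinetics.compute_old_fractions`) for the two
    conditions. Peptides with a negative decay in either condition are
    removed; proteins need at least two matched peptides. Bonferroni is
    over the number of proteins tested.
    """
    if t_final is None:
        t_final = float(
            max(table_a["timepoint"].max(), table_b["timepoint"].max())
        )
    decay_a = _peptide_decay(table_a, t_final).set_index(
        ["protein_group", "sequence"]
    )["decay"]
    decay_b = _peptide_decay(table_b, t_final).set_index(
        ["protein_group", "sequence"]
    )["decay"]
    matched = pd.concat(
        {"A": decay_a, "B": decay_b}, axis=1, join="inner"
    ).reset_index()

    tested: list[tuple[str, np.ndarray, np.ndarray]] = []
    for protein, grp in matched.groupby("protein_group", sort=True):
        if len(grp) < 2:
            logger.info(
                "compare_paired_decay: %s skipped (<2 matched peptides)", protein
            )
            continue
        tested.append((protein, grp["A"].to_numpy(), grp["B"].to_numpy()))

    n_tests = len(tested)
    results = []
    for protein, a, b in tested:
        if np.allclose(a, b):
            p = 1.0
        else:
            _, p = stats.ttest_rel(a, b)
            p = float(p)
        results.append(
            PairedDecayResult(
                protein_group=protein,
                n_peptides=len(a),
                mean_decay_A=float(a.mean()),
                mean_decay_B=float(b.mean()),
                p_value=p,
                significant=bool(p * n_tests < alpha),
            )
        )
    return results


def type_one_error_audit(
    config: SimulationConfig | None = None,
    pipeline: PipelineConfig | None = None,
    n_sim: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    effect_multiplier: float = 1.0,
) -> dict:
    """Monte-Carlo audit of the culture-type comparison procedure.

    Simulates ``n_sim`` condition pairs sharing a proteome. With
    ``effect_multiplier = 1`` the pair is a matched null and the reported
    family-wise error rate is the fraction of runs with at least one
    significant call; with a real effect the reported power is the mean
    fraction of tested proteins called significant (every protein carries
    the effect). Alpha = 0 yields zero significant calls by construction.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    base = config or SimulationConfig(
        n_proteins=40, peptides_per_protein_mean=4.0, n_injections=1,
        n_complexes=0,
    )
    pipeline = pipeline or PipelineConfig()
    fwer_hits = 0
    power_sum = 0.0
    n_power_runs = 0
    for run in range(n_sim):
        cfg = SimulationConfig(
            **{
                **base.__dict__,
                "condition_multipliers": {"A": 1.0, "B": effect_multiplier},
                "seed": (seed * 100003 + run) % (2**31 - 1),
            }
        )
        proteome = generate_proteome(cfg)
        table, counts, _ = simulate_silac_experiment(proteome, cfg)
        purities = estimate_purity_table(counts, pooled=pipeline.pooled_purity)
        prof_a, _ = prepare_profiles(
            table[table["condition"] == "A"], purities, pipeline
        )
        prof_b, _ = prepare_profiles(
            table[table["condition"] == "B"], purities, pipeline
        )
        results = compare_culture_turnover(
            prof_a, prof_b, alpha=alpha, welch=pipeline.welch
        )
        n_sig = sum(r.significant for r in results)
        if n_sig:
            fwer_hits += 1
        tested = [r for r in results if r.p_values]
        if tested:
            power_sum += n_sig / len(tested)
            n_power_runs += 1
    return {
        "n_sim": n_sim,
        "alpha": alpha,
        "effect_multiplier": effect_multiplier,
        "fwer": fwer_hits / n_sim,
        "power": power_sum / n_power_runs if n_power_runs else float("nan"),
    }
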