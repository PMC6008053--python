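"""Cross-condition turnover comparisons and their error control."""

import numpy as np
import pandas as pd
import pytest

from silac_turnover import (
    SimulationConfig,
    compare_culture_turnover,
    compare_paired_decay,
    prepare_profiles,
    simulate_silac_experiment,
    type_one_error_audit,
)
from conftest import make_oldfrac_rows


def _profiles(values_by_protein_tp, rng=None, jitter=0.0):
    """Long profile frame from {protein: {timepoint: [values]}}."""
    rows = []
    for protein, by_tp in values_by_protein_tp.items():
        for tp, values in by_tp.items():
            for i, value in enumerate(values):
                if jitter:
                    value = value + rng.normal(0, jitter)
                rows.append((protein, f"{protein}PEP{i}K", float(tp),
                             "R1", "I1", value))
    return make_oldfrac_rows(rows)


@pytest.fixture
def effect_pair():
    """Simulated condition pair with a global 1.4x rate-constant effect and
    about 20 retained values per protein and timepoint."""
    import math

    from silac_turnover import TrueProteome

    halflives = np.linspace(2.0, 15.0, 12)
    rates = pd.concat(
        [
            pd.DataFrame(
                {
                    "protein_group": [f"P{i:05d}" for i in range(12)],
                    "condition": cond,
                    "k_true": mult * math.log(2) / halflives,
                    "half_life_true_days": halflives / mult,
                    "complex_id": "",
                }
            )
            for cond, mult in (("A", 1.0), ("B", 1.4))
        ],
        ignore_index=True,
    )
    peptides = pd.DataFrame(
        {
            "protein_group": np.repeat(rates["protein_group"].unique(), 4),
            "sequence": [f"PEP{i}K" for i in range(48)],
            "missed_cleavages": 0,
            "detectability": 1.0,
        }
    )
    proteome = TrueProteome(rates=rates, peptides=peptides)
    cfg = SimulationConfig(
        n_proteins=12, seed=21, ratio_noise_log_sd=0.05, dropout_prob=0.0,
        detectability_range=(1.0, 1.0), n_injections=2,
        missed_cleavage_prob=0.0,
        condition_multipliers={"A": 1.0, "B": 1.4},
    )
    table, _, truth = simulate_silac_experiment(proteome, cfg)
    from silac_turnover import LabelPurity

    purities = [LabelPurity(("A", "R1", "I1", 1.0), 3200, 800, 0.8)]
    prof_a, _ = prepare_profiles(table[table["condition"] == "A"], purities)
    prof_b, _ = prepare_profiles(table[table["condition"] == "B"], purities)
    return prof_a, prof_b


class TestCultureComparison:
    def test_identical_tables_yield_no_significance(self, small_run):
        table, _, _, purities = small_run
        prof, _ = prepare_profiles(table, purities)
        results = compare_culture_turnover(prof, prof)
        assert results and not any(r.significant for r in results)
        assert all(r.direction == "inconsistent" for r in results)

    def test_global_effect_detected_at_every_timepoint(self, effect_pair):
        prof_a, prof_b = effect_pair
        results = compare_culture_turnover(prof_a, prof_b)
        tested = [r for r in results if r.p_values]
        assert tested
        for res in tested:
            assert res.direction == "faster_in_B"
            assert all(res.significant_timepoints.values())
            assert res.significant

    def test_swapping_conditions_flips_directions_only(self, effect_pair):
        prof_a, prof_b = effect_pair
        fwd = {r.protein_group: r for r in compare_culture_turnover(prof_a, prof_b)}
        rev = {r.protein_group: r for r in compare_culture_turnover(prof_b, prof_a)}
        flip = {"faster_in_A": "faster_in_B", "faster_in_B": "faster_in_A",
                "inconsistent": "inconsistent"}
        assert fwd.keys() == rev.keys()
        for protein, res in fwd.items():
            assert rev[protein].direction == flip[res.direction]
            assert rev[protein].significant == res.significant
            for tp, p in res.p_values.items():
                assert rev[protein].p_values[tp] == pytest.approx(p, rel=1e-9)

    def test_inconsistent_direction_not_tested(self, rng):
        base = {
            1.0: [0.9] * 5, 3.0: [0.7] * 5, 7.0: [0.4] * 5,
            0.0: [1.0] * 5,
        }
        prof_a = _profiles({"P1": base}, rng, jitter=0.01)
        flipped = {0.0: base[0.0], 1.0: [0.8] * 5, 3.0: [0.75] * 5,
                   7.0: [0.35] * 5}
        prof_b = _profiles({"P1": flipped}, rng, jitter=0.01)
        results = compare_culture_turnover(prof_a, prof_b)
        assert results[0].direction == "inconsistent"
        assert results[0].p_values == {} and not results[0].significant

    def test_row_order_invariance(self, effect_pair):
        prof_a, prof_b = effect_pair
        shuffled = prof_a.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fwd = compare_culture_turnover(prof_a, prof_b)
        alt = compare_culture_turnover(shuffled, prof_b)
        assert [(r.protein_group, r.significant) for r in fwd] == [
            (r.protein_group, r.significant) for r in alt
        ]


def _paired_tables(rng, n_proteins=8, n_peptides=15, shift_protein=None,
                   shift=0.3):
    """Two-timepoint (0 and 7 d) %old tables for a paired design."""
    rows_a, rows_b = [], []
    for i in range(n_proteins):
        protein = f"P{i}"
        for j in range(n_peptides):
            seq = f"{protein}PEP{j}K"
            decay_a = 0.5 + rng.normal(0, 0.02)
            decay_b = decay_a + rng.normal(0, 0.02)
            if protein == shift_protein:
                decay_b += shift
            rows_a += [(protein, seq, 0.0, "R1", "I1", 1.0),
                       (protein, seq, 7.0, "R1", "I1", 1.0 - decay_a)]
            rows_b += [(protein, seq, 0.0, "R1", "I1", 1.0),
                       (protein, seq, 7.0, "R1", "I1", 1.0 - decay_b)]
    return make_oldfrac_rows(rows_a), make_oldfrac_rows(rows_b)


class TestPairedComparison:
    def test_identical_tables_yield_no_significance(self, rng):
        table_a, _ = _paired_tables(rng)
        results = compare_paired_decay(table_a, table_a.copy())
        assert results and not any(r.significant for r in results)

    def test_negative_decay_peptides_removed(self, rng):
        table_a, table_b = _paired_tables(rng, n_proteins=1, n_peptides=5)
        # one peptide rises instead of decaying in condition A
        rising = table_a["sequence"] == "P0PEP0K"
        table_a.loc[rising & (table_a["timepoint"] == 7.0), "fraction_old"] = 1.2
        results = compare_paired_decay(table_a, table_b)
        assert results[0].n_peptides == 4

    def test_single_shifted_protein_detected(self, rng):
        table_a, table_b = _paired_tables(rng, shift_protein="P3")
        results = {r.protein_group: r for r in
                   compare_paired_decay(table_a, table_b)}
        assert results["P3"].significant
        assert not any(r.significant for p, r in results.items() if p != "P3")

    def test_underpowered_proteins_skipped(self, rng):
        table_a, table_b = _paired_tables(rng, n_proteins=1, n_peptides=15)
        lone = make_oldfrac_rows(
            [("Q1", "QPEPK", 0.0, "R1", "I1", 1.0),
             ("Q1", "QPEPK", 7.0, "R1", "I1", 0.5)]
        )
        table_a = pd.concat([table_a, lone], ignore_index=True)
        table_b = pd.concat([table_b, lone], ignore_index=True)
        results = compare_paired_decay(table_a, table_b)
        assert "Q1" not in {r.protein_group for r in results}


class TestAudit:
    def test_zero_alpha_yields_zero_calls(self):
        out = type_one_error_audit(
            SimulationConfig(n_proteins=10, peptides_per_protein_mean=3.0,
                             n_injections=1, seed=3),
            n_sim=3, alpha=0.0, seed=3,
        )
        assert out["fwer"] == 0.0 and out["power"] == 0.0
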