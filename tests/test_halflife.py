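"""Filtering cascade, outlier fences, censoring and the decay fit."""

import math

import numpy as np
import pandas as pd
import pytest

from silac_turnover import (
    LabelPurity,
    SimulationConfig,
    TrueProteome,
    check_monotonic_decay,
    cluster_fast_turnover,
    filter_peptides,
    fit_halflife,
    generate_proteome,
    remove_outliers,
    run_pipeline,
    simulate_silac_experiment,
)
from conftest import make_oldfrac_rows


class TestFilterPeptides:
    def _base_rows(self):
        rows = []
        for t in (0.0, 1.0, 3.0, 7.0):
            rows.append(("P1", "GOODPEPK", t, "R1", "I1", math.exp(-0.1 * t)))
        return rows

    def test_incomplete_time_course_removed(self):
        rows = self._base_rows()
        rows += [("P2", "PARTIALK", t, "R1", "I1", 0.9) for t in (0.0, 1.0, 3.0)]
        retained, excl = filter_peptides(make_oldfrac_rows(rows))
        assert set(retained["sequence"]) == {"GOODPEPK"}
        assert (excl["reason"] == "incomplete_time_course").sum() == 1

    def test_low_t0_mean_removed(self):
        rows = self._base_rows()
        rows += [("P2", "LOWTZERK", t, "R1", "I1", 0.85 if t == 0 else 0.5)
                 for t in (0.0, 1.0, 3.0, 7.0)]
        retained, excl = filter_peptides(make_oldfrac_rows(rows))
        assert set(retained["sequence"]) == {"GOODPEPK"}
        assert (excl["reason"] == "t0_mean_below_threshold").sum() == 1

    def test_clean_unique_peptide_retained(self):
        retained, excl = filter_peptides(make_oldfrac_rows(self._base_rows()))
        assert len(retained) == 4 and excl.empty

    def test_shared_peptides_dropped(self):
        rows = self._base_rows()
        rows += [("P2;P3", "MULTIMAPK", t, "R1", "I1", 0.95)
                 for t in (0.0, 1.0, 3.0, 7.0)]
        rows += [("P4", "SHAREDK", t, "R1", "I1", 0.95)
                 for t in (0.0, 1.0, 3.0, 7.0)]
        rows += [("P5", "SHAREDK", t, "R2", "I1", 0.95)
                 for t in (0.0, 1.0, 3.0, 7.0)]
        retained, excl = filter_peptides(make_oldfrac_rows(rows))
        assert set(retained["sequence"]) == {"GOODPEPK"}
        assert (excl["reason"] == "not_unique_to_protein_group").sum() == 2


class TestRemoveOutliers:
    def test_low_outlier_flagged(self):
        values = [0.88, 0.90, 0.91, 0.92, 0.20]
        mask = remove_outliers(values)
        assert list(mask) == [True, True, True, True, False]

    def test_identical_values_all_retained(self):
        assert remove_outliers([0.5] * 6).all()

    def test_two_points_never_excluded(self, rng):
        # interpolated quartiles of 2 points give fences spanning both
        for _ in range(50):
            pair = rng.uniform(0, 1, size=2)
            assert remove_outliers(pair).all()

    def test_matches_brute_force_fences(self, rng):
        """Tukey filtering agrees with explicit interpolated-quartile
        fences on random vectors."""
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            values = rng.normal(0.7, 0.2, size=n)
            srt = np.sort(values)
            # linear interpolation between order statistics
            def quantile(q):
                pos = q * (n - 1)
                lo, hi = int(np.floor(pos)), int(np.ceil(pos))
                return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
            q1, q3 = quantile(0.25), quantile(0.75)
            iqr = q3 - q1
            expected = (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)
            assert (remove_outliers(values) == expected).all()


class TestMonotonicDecay:
    @pytest.mark.parametrize(
        "means, tolerance, expected",
        [
            ({0: 1.0, 1: 0.8, 3: 0.6, 7: 0.4}, 0.05, True),
            ({0: 1.0, 1: 0.7, 3: 0.9, 7: 0.5}, 0.05, False),
            ({0: 1.0, 1: 0.80, 3: 0.81, 7: 0.5}, 0.05, True),
        ],
    )
    def test_examples(self, means, tolerance, expected):
        assert check_monotonic_decay(means, tolerance) is expected


class TestClusterCensoring:
    @staticmethod
    def _profiles(halflives):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        rows = {
            f"P{i}": np.exp(-math.log(2) / hl * t)
            for i, hl in enumerate(halflives)
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=t)

    def test_two_separated_populations(self):
        # fast k=1.5/d (t1/2=0.46 d) vs slow k=0.1/d (t1/2=6.9 d)
        fast = [math.log(2) / 1.5] * 20
        slow = [math.log(2) / 0.1] * 20
        profiles = self._profiles(fast + slow)
        censored = cluster_fast_turnover(profiles, k_clusters=6, seed=0)
        assert censored == {f"P{i}" for i in range(20)}

    def test_direct_rule_fallback(self):
        profiles = self._profiles([0.5, 8.0, 10.0])  # fewer than k_clusters
        censored = cluster_fast_turnover(profiles, k_clusters=6, seed=0)
        assert censored == {"P0"}

    def test_slow_protein_not_censored(self):
        profiles = self._profiles([14.0] * 10)
        assert cluster_fast_turnover(profiles, k_clusters=2, seed=0) == set()


class TestFitHalflife:
    def test_noiseless_closed_form(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        rec = fit_halflife(t, np.exp(-0.2 * t), protein_group="P1")
        assert rec.k_per_day == pytest.approx(0.2, abs=1e-12)
        assert rec.half_life_days == pytest.approx(math.log(2) / 0.2, abs=1e-9)
        assert rec.r_squared == pytest.approx(1.0, abs=1e-12)
        assert rec.se_k == pytest.approx(0.0, abs=1e-9)

    def test_halflife_of_one_day_at_k_ln2(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        rec = fit_halflife(t, np.exp(-math.log(2) * t))
        assert rec.half_life_days == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        k_true = 0.128
        t = rng.uniform(0, 7, size=50)
        y = np.exp(-k_true * t + rng.normal(0, 0.1, size=50))
        rec = fit_halflife(t, y)
        oracle = -np.sum(t * np.log(y)) / np.sum(t * t)
        assert rec.k_per_day == pytest.approx(oracle, abs=1e-10)

    def test_order_and_duplication_invariance(self, rng):
        t = np.array([0.0, 1.0, 3.0, 7.0] * 5)
        y = np.exp(-0.3 * t + rng.normal(0, 0.05, t.size))
        rec = fit_halflife(t, y)
        perm = rng.permutation(t.size)
        rec_perm = fit_halflife(t[perm], y[perm])
        assert rec_perm.k_per_day == pytest.approx(rec.k_per_day, abs=1e-12)
        rec_dup = fit_halflife(np.tile(t, 2), np.tile(y, 2))
        assert rec_dup.k_per_day == pytest.approx(rec.k_per_day, abs=1e-12)
        assert rec_dup.se_k < rec.se_k

    def test_halflife_strictly_decreasing_in_k(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        halflives = [
            fit_halflife(t, np.exp(-k * t)).half_life_days
            for k in np.linspace(0.05, 1.0, 12)
        ]
        assert all(a > b for a, b in zip(halflives, halflives[1:]))

    def test_rising_profile_unfittable(self):
        t = np.array([0.0, 1.0, 3.0, 7.0])
        assert fit_halflife(t, np.exp(0.1 * t)) is None


class TestRunPipeline:
    def test_noiseless_full_label_recovery_is_exact(self):
        cfg = SimulationConfig(
            n_proteins=60, seed=8, p_heavy=1.0, ratio_noise_log_sd=0.0,
            dropout_prob=0.0, detectability_range=(1.0, 1.0),
        )
        proteome = generate_proteome(cfg)
        table, counts, truth = simulate_silac_experiment(proteome, cfg)
        from silac_turnover import estimate_purity_table

        records, _ = run_pipeline(table, estimate_purity_table(counts))
        k_map = dict(zip(truth["protein_group"], truth["k_true"]))
        fitted = [r for r in records if not r.censored]
        assert fitted
        for rec in fitted:
            assert rec.k_per_day == pytest.approx(
                k_map[rec.protein_group], abs=1e-9
            )

    def test_all_proteins_failing_t0_filter_yield_empty_output(self):
        rows = []
        for protein in ("P1", "P2"):
            for t in (0.0, 1.0, 3.0, 7.0):
                # t0 mean %old 0.8 <= 0.9 threshold
                rows.append((protein, f"{protein}PEPK", t, "R1", "I1",
                             0.8 * math.exp(-0.1 * t)))
        table = make_oldfrac_rows(rows)
        table["ratio_HL"] = (1 - table["fraction_old"]) / table["fraction_old"]
        table["light_only"] = False
        purity = [LabelPurity(("mixed", "R1", "I1", 1.0), 100, 400, 1.0)]
        records, excl = run_pipeline(
            table.drop(columns=["fraction_old", "excluded", "reason"]), purity
        )
        assert records == []
        assert (excl["reason"] == "t0_mean_below_threshold").sum() == 2

    def test_censoring_assigns_fast_population(self):
        rates = pd.DataFrame(
            {
                "protein_group": [f"F{i}" for i in range(15)]
                + [f"S{i}" for i in range(15)],
                "condition": "mixed",
                "k_true": [1.5] * 15 + [0.1] * 15,
                "complex_id": "",
            }
        )
        rates["half_life_true_days"] = math.log(2) / rates["k_true"]
        rng = np.random.default_rng(0)
        peptides = pd.DataFrame(
            {
                "protein_group": np.repeat(rates["protein_group"].to_numpy(), 3),
                "sequence": [f"PEP{i}K" for i in range(90)],
                "missed_cleavages": 0,
                "detectability": 1.0,
            }
        )
        proteome = TrueProteome(rates=rates, peptides=peptides)
        cfg = SimulationConfig(
            n_proteins=30, seed=1, ratio_noise_log_sd=0.0, dropout_prob=0.0,
            detectability_range=(1.0, 1.0),
        )
        table, _, _ = simulate_silac_experiment(proteome, cfg)
        # fully tryptic peptides produce no label counts; supply the purity
        purity = [LabelPurity(("mixed", "R1", "I1", 1.0), 3200, 800, 0.8)]
        records, _ = run_pipeline(table, purity)
        censored = {r.protein_group for r in records if r.censored}
        assert censored == {f"F{i}" for i in range(15)}
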