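import dataclasses

import numpy as np
import pytest

from crcpanel.diffexpr import differential_expression
from crcpanel.matrix import align_samples
from crcpanel.preprocess import preprocess
from crcpanel.simulate import (
    PanelGene,
    SimulationConfig,
    calibrate_hazards,
    default_panel,
    generate_cohort,
)
from crcpanel.survival import km_fit, km_survival_at


def null_config(seed):
    panel = [dataclasses.replace(g, log2fc=0.0) for g in default_panel()]
    return SimulationConfig(seed=seed, panel=panel)


class TestCalibrateHazards:
    def test_closed_form(self):
        lam = calibrate_hazards([0.52])
        np.testing.assert_allclose(lam, -np.log(0.52) / 60)

    def test_rate_vanishes_as_survival_approaches_one(self):
        assert calibrate_hazards([0.9999])[0] < 1e-5

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.0], [1.2]):
            with pytest.raises(ValueError):
                calibrate_hazards(bad)

    def test_monte_carlo_recovers_target(self):
        """lambda from S(60) = 0.83 at n = 10^4, no censoring: KM at 60
        months lands within 0.01 of the target."""
        rng = np.random.default_rng(7)
        lam = calibrate_hazards([0.83])[0]
        t = rng.exponential(1 / lam, 10_000)
        curve = km_fit(t, np.ones(t.size, bool))
        assert km_survival_at(curve, 60.0) == pytest.approx(0.83, abs=0.01)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(SimulationConfig(seed=11))
        b = generate_cohort(SimulationConfig(seed=11))
        np.testing.assert_array_equal(a.expression.values, b.expression.values)
        assert a.clinical.equals(b.clinical)
        assert a.truth.equals(b.truth)

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(seed=11))
        b = generate_cohort(SimulationConfig(seed=12))
        assert (a.expression.values != b.expression.values).any()

    def test_counts_are_nonnegative_integers(self, default_cohort):
        v = default_cohort.expression.values
        assert (v >= 0).all()
        np.testing.assert_array_equal(v, np.rint(v))

    def test_truth_states_consistent_with_normalized_expression(self, default_cohort):
        """The recorded high-risk states match dichotomizing the normalized
        log2 expression at the configured thresholds."""
        norm = preprocess(default_cohort.expression)
        tum, _ = align_samples(norm, default_cohort.clinical)
        for rule in default_cohort.config.score_config.rules:
            expr = tum.gene_row(rule.transcript_id)
            np.testing.assert_array_equal(
                rule.is_high_risk(expr),
                default_cohort.truth[f"state_{rule.transcript_id}"].to_numpy(),
            )

    def test_configured_fold_changes_recovered(self, default_cohort):
        """Empirical tumour-normal mean log2 difference stays within
        3 sd / sqrt(n) (plus count-rounding slack) of each configured shift."""
        m = default_cohort.expression
        log2 = np.log2(m.values + 1)
        cls = m.class_array
        diff = log2[:, cls == "tumour"].mean(axis=1) - log2[:, cls == "normal"].mean(
            axis=1
        )
        score_ids = set(default_cohort.config.score_config.transcript_ids)
        for gene, d in zip(default_cohort.config.panel, diff):
            if gene.transcript_id in score_ids or gene.is_housekeeping:
                continue
            tol = 3 * gene.noise_sd * np.sqrt(1 / 66 + 1 / 10) + 0.15
            assert abs(d - gene.log2fc) < tol, gene.symbol

    def test_censoring_fraction_matches_expectation(self):
        """Observed censoring at n=1000 within 5 points of the closed-form
        expectation under the admin-79-month + 20% drop-out model."""
        cfg = SimulationConfig(seed=5, n_tumour=1000)
        cohort = generate_cohort(cfg)
        rates = calibrate_hazards(cfg.five_year_targets)
        p = cfg.p_high
        pk = np.array([(1 - p) ** 3, 3 * p * (1 - p) ** 2, 3 * p**2 * (1 - p) + p**3])
        fmax = cfg.followup_max
        # P(censored | rate) = (1-q) e^{-lam*fmax} + q * E_U[ e^{-lam U} ]
        q = cfg.dropout_prob
        pc = (1 - q) * np.exp(-rates * fmax) + q * (1 - np.exp(-rates * fmax)) / (
            rates * fmax
        )
        expected = float(pk @ pc)
        observed = 1.0 - cohort.clinical["os_event"].mean()
        assert abs(observed - expected) < 0.05

    def test_dfs_never_exceeds_os(self, default_cohort):
        cl = default_cohort.clinical
        assert (cl["dfs_time"] <= cl["os_time"] + 1e-9).all()

    def test_invalid_config_lists_fields(self):
        cfg = SimulationConfig(seed=1, p_high=1.5, dropout_prob=-0.1)
        with pytest.raises(ValueError) as exc:
            cfg.validate()
        assert "p_high" in str(exc.value) and "dropout_prob" in str(exc.value)

    def test_negative_binomial_count_model(self):
        cohort = generate_cohort(
            SimulationConfig(seed=2, count_model="negbin", n_tumour=10)
        )
        v = cohort.expression.values
        assert (v >= 0).all()
        np.testing.assert_array_equal(v, np.rint(v))

    def test_panel_composition(self):
        panel = default_panel()
        assert sum(g.is_housekeeping for g in panel) == 3
        assert sum(not g.is_housekeeping for g in panel) == 28
        assert {"GAPDH", "ACTB", "TUBB"} == {
            g.symbol for g in panel if g.is_housekeeping
        }


class TestPipelineRecovery:
    def test_null_panel_keeps_false_discoveries_nominal(self):
        """All log2fc = 0: fraction of transcripts at q < 0.05 stays within
        2 SE of the 5% FDR level across seeds."""
        fracs = []
        for seed in range(60):
            cohort = generate_cohort(null_config(seed))
            de = differential_expression(
                preprocess(cohort.expression), method="welch_t"
            )
            fracs.append(de["significant"].mean())
        mean = float(np.mean(fracs))
        se = float(np.std(fracs) / np.sqrt(len(fracs)))
        assert mean <= 0.05 + 2 * se

    def test_large_shifts_recover_sign_across_seeds(self):
        """Transcripts with |log2fc| >= 2 keep the configured sign of their
        estimated fold change in >= 95% of 100 seeded cohorts."""
        panel = default_panel()
        strong = [
            i
            for i, g in enumerate(panel)
            if abs(g.log2fc) >= 2 and not g.is_housekeeping
        ]
        hits = 0
        total = 0
        for seed in range(100):
            cohort = generate_cohort(SimulationConfig(seed=seed))
            de = differential_expression(preprocess(cohort.expression))
            fc = de["log2fc"].to_numpy()
            for i in strong:
                total += 1
                hits += np.sign(fc[i]) == np.sign(panel[i].log2fc)
        assert hits >= 0.95 * total
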