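"""Fractions reacted, sequence filtering, kinetic fitting, and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from kseqland.kseq_kinetics import (
    MissingQpcrError,
    bootstrap_fit,
    compute_fraction_reacted,
    filter_sequences,
    fit_all,
    fit_kinetics,
)
from kseqland.synthetic_data import kinetic_fraction_reacted

ALPHA, T = 0.479, 90.0
CONC = np.array([1250.0, 250.0, 50.0, 10.0, 2.0] * 3)


class TestFilter:
    def test_filter_rules(self, small_center):
        triple = "TTT" + small_center[3:]
        candidates = [
            small_center,               # center itself: retained
            "T" + small_center[1:],     # single mutant: retained
            small_center[:-1],          # 20-mer: excluded
            small_center[:-1] + "N",    # ambiguous base: excluded
            triple,                     # triple mutant: excluded
        ]
        kept = filter_sequences(candidates, [small_center])
        assert kept == [small_center, "T" + small_center[1:]]

    def test_filter_requires_centers(self):
        with pytest.raises(ValueError):
            filter_sequences(["ACGT"], [])


class TestFractionReacted:
    def _toy(self):
        counts = pd.DataFrame(
            {"input_r1": [400, 999_600], "rx": [100, 999_900]},
            index=["SEQA", "SEQB"],
        )
        metadata = pd.DataFrame(
            {
                "sample_id": ["input_r1", "rx"],
                "role": ["input", "reacted"],
                "substrate": ["", "BWO"],
                "concentration_uM": [np.nan, 250.0],
                "replicate": [1, 1],
            }
        )
        qpcr = pd.DataFrame(
            {
                "sample_id": ["input_r1"] * 3 + ["rx"] * 3,
                "measurement": [1, 2, 3] * 2,
                "total_ng": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
            }
        )
        return counts, metadata, qpcr

    def test_arithmetic_example(self):
        # reacted amount = (100/1e6) * 2.0 ng = 2e-4; input = (400/1e6) * 1 = 4e-4
        counts, metadata, qpcr = self._toy()
        fr, issues = compute_fraction_reacted(counts, metadata, qpcr)
        val = fr.loc[fr["sequence"] == "SEQA", "fraction_reacted"].iloc[0]
        assert val == pytest.approx(0.5, rel=1e-12)
        assert issues.empty

    def test_zero_reacted_reads_gives_zero_fraction(self):
        counts, metadata, qpcr = self._toy()
        counts.loc["SEQA", "rx"] = 0
        fr, _ = compute_fraction_reacted(counts, metadata, qpcr)
        assert fr.loc[fr["sequence"] == "SEQA", "fraction_reacted"].iloc[0] == 0.0

    def test_sequence_absent_from_input_is_dropped(self):
        counts, metadata, qpcr = self._toy()
        counts.loc["SEQA", "input_r1"] = 0
        fr, issues = compute_fraction_reacted(counts, metadata, qpcr)
        assert "SEQA" not in set(fr["sequence"])
        assert (issues["kind"] == "absent_from_input").any()

    def test_zero_read_sample_is_excluded_with_record(self):
        counts, metadata, qpcr = self._toy()
        counts["rx"] = 0
        fr, issues = compute_fraction_reacted(counts, metadata, qpcr)
        assert fr.empty
        assert (issues["kind"] == "zero_read_sample").any()

    def test_missing_qpcr_is_configuration_error(self):
        counts, metadata, qpcr = self._toy()
        with pytest.raises(MissingQpcrError):
            compute_fraction_reacted(counts, metadata, qpcr[qpcr.sample_id != "rx"])

    def test_noiseless_simulation_roundtrip(self, tiny_dataset):
        """Fractions recomputed from a noiseless dataset equal the true
        survival fractions from the kinetic law."""
        ds = tiny_dataset
        fr, _ = compute_fraction_reacted(ds.counts, ds.metadata, ds.qpcr)
        land = ds.landscape
        sub = fr.sample(300, random_state=0)
        expected = kinetic_fraction_reacted(
            land.k.to_numpy()[
                land.k.index.get_indexer(sub["sequence"]),
                land.k.columns.get_indexer(sub["substrate"]),
            ],
            land.A.to_numpy()[
                land.A.index.get_indexer(sub["sequence"]),
                land.A.columns.get_indexer(sub["substrate"]),
            ],
            sub["concentration_uM"].to_numpy(),
            ds.design.alpha,
            ds.design.reaction_time_min,
        )
        assert np.allclose(sub["fraction_reacted"].to_numpy(), expected, rtol=1e-9)


class TestFit:
    def test_noiseless_roundtrip(self):
        F = kinetic_fraction_reacted(100.0, 0.8, CONC, ALPHA, T)
        res = fit_kinetics(CONC, F, ALPHA, T)
        assert res.converged
        assert res.k == pytest.approx(100.0, rel=1e-8)
        assert res.A == pytest.approx(0.8, rel=1e-8)

    def test_all_zero_fractions_report_no_signal(self):
        res = fit_kinetics(CONC, np.zeros_like(CONC), ALPHA, T)
        assert not res.converged
        assert res.kA == 0.0

    def test_saturated_data_flags_unidentifiable_rate(self):
        res = fit_kinetics(CONC, np.full_like(CONC, 0.6), ALPHA, T)
        assert res.A == pytest.approx(0.6, rel=0.05)
        assert not res.converged  # rate ran to a bound

    def test_single_concentration_is_insufficient(self):
        res = fit_kinetics(np.array([250.0, 250.0]), np.array([0.3, 0.31]), ALPHA, T)
        assert not res.converged
        assert "insufficient" in res.message

    def test_kA_invariant_to_concentration_rescaling(self):
        F = kinetic_fraction_reacted(100.0, 0.8, CONC, ALPHA, T)
        res1 = fit_kinetics(CONC, F, ALPHA, T)
        res2 = fit_kinetics(CONC * 10, F, ALPHA, T)
        assert res2.k == pytest.approx(res1.k / 10, rel=1e-6)
        assert res2.kA * 10 == pytest.approx(res1.kA, rel=1e-6)

    def test_alpha_cancels_in_rate_ratio(self):
        """Doubling alpha halves every fitted k, so enhancement ratios are
        unchanged."""
        F = kinetic_fraction_reacted(100.0, 0.8, CONC, ALPHA, T)
        res1 = fit_kinetics(CONC, F, ALPHA, T)
        res2 = fit_kinetics(CONC, F, 2 * ALPHA, T)
        assert res2.k == pytest.approx(res1.k / 2, rel=1e-6)

    def test_first_order_optimality_at_optimum(self):
        rng = np.random.default_rng(5)
        F = kinetic_fraction_reacted(40.0, 0.7, CONC, ALPHA, T) * np.exp(
            rng.normal(0, 0.05, CONC.size)
        )
        res = fit_kinetics(CONC, F, ALPHA, T)
        # residuals orthogonal to the model gradient in k at the optimum
        c = CONC * 1e-6
        g = 1 - np.exp(-res.k * ALPHA * c * T)
        resid = F - res.A * g
        dF_dk = res.A * ALPHA * c * T * np.exp(-res.k * ALPHA * c * T)
        grad_k = resid @ dF_dk
        norm = np.linalg.norm(resid) * np.linalg.norm(dF_dk) + 1e-30
        assert abs(grad_k) / norm < 1e-6
        assert abs(resid @ g) / (np.linalg.norm(resid) * np.linalg.norm(g)) < 1e-6


class TestBootstrap:
    def test_zero_noise_bootstrap_degenerates_to_point_estimate(self):
        F = kinetic_fraction_reacted(100.0, 0.8, CONC, ALPHA, T)
        res = bootstrap_fit(CONC, F, ALPHA, T, n_boot=200, seed=0)
        assert res.kA_median == pytest.approx(res.kA, rel=2e-3)
        assert res.kA_sd < 2e-3 * res.kA

    def test_single_replicate_statistics_equal_that_refit(self):
        rng = np.random.default_rng(1)
        F = kinetic_fraction_reacted(50.0, 0.6, CONC, ALPHA, T) * np.exp(
            rng.normal(0, 0.1, CONC.size)
        )
        res = bootstrap_fit(CONC, F, ALPHA, T, n_boot=1, seed=2)
        assert res.kA_median == res.kA_p2_5 == res.kA_p97_5
        assert res.kA_sd == 0.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        F = kinetic_fraction_reacted(50.0, 0.6, CONC, ALPHA, T) * np.exp(
            rng.normal(0, 0.1, CONC.size)
        )
        a = bootstrap_fit(CONC, F, ALPHA, T, n_boot=100, seed=7)
        b = bootstrap_fit(CONC, F, ALPHA, T, n_boot=100, seed=7)
        assert a.kA_median == b.kA_median and a.kA_sd == b.kA_sd

    def test_interval_covers_truth_for_iid_noise(self):
        """With iid multiplicative noise on the fractions, the 95% pairs
        bootstrap interval should cover true kA close to nominally."""
        rng = np.random.default_rng(4)
        hits, n_sim = 0, 150
        for _ in range(n_sim):
            k, A = 10 ** rng.uniform(0.5, 2.5), rng.uniform(0.4, 0.95)
            F = kinetic_fraction_reacted(k, A, CONC, ALPHA, T) * np.exp(
                rng.normal(0, 0.1, CONC.size)
            )
            res = bootstrap_fit(CONC, F, ALPHA, T, n_boot=300, seed=rng)
            hits += res.kA_p2_5 <= k * A <= res.kA_p97_5
        assert 0.85 <= hits / n_sim <= 0.99


def test_fit_all_shape_and_determinism(tiny_dataset):
    ds = tiny_dataset
    fr, _ = compute_fraction_reacted(ds.counts, ds.metadata, ds.qpcr)
    seqs = list(ds.landscape.sequences[:5])
    fits1 = fit_all(fr, ALPHA, T, n_boot=50, seed=1, sequences=seqs)
    fits2 = fit_all(fr, ALPHA, T, n_boot=50, seed=1, sequences=seqs[:3])
    assert len(fits1) == 5 * len(ds.design.substrates)
    merged = fits1.merge(fits2, on=["sequence", "substrate"], suffixes=("_a", "_b"))
    # per-group seeding: results independent of which other groups are fit
    assert np.allclose(merged["kA_median_a"], merged["kA_median_b"])
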