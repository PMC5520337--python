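"""Simulator contracts: catalogs, planted truth, traces and peak tables."""

import numpy as np
import pandas as pd
import pytest

from spliceshift.pipeline import quantify_peak_table, quantify_traces
from spliceshift.psi import SIRNAS, call_changes, compute_delta_psi
from spliceshift.synthetic import (
    DEFAULT_KD_TABLE,
    SIZE_MAX_BP,
    SIZE_MIN_BP,
    ZERO_NOISE,
    NoiseParams,
    Sample,
    catalog_to_frame,
    frame_to_catalog,
    generate_ase_catalog,
    generate_samples,
    generate_truth,
    simulate_peak_table,
    smn_exon7_fixture,
    synthesize_trace,
)


KD_L1 = pd.DataFrame(
    [("L1", "siRNA1", 0.7), ("L1", "siRNA2", 0.9)],
    columns=["cell_line", "sirna", "kd_fraction"],
)


class TestCatalog:
    def test_smn_fixture_sizes(self):
        ase = smn_exon7_fixture()
        assert (ase.size_exclusion_bp, ase.size_inclusion_bp) == (276, 330)
        assert ase.alt_region_bp == 54  # the alternative exon length

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            generate_ase_catalog(0, seed=1)

    def test_sizes_within_resolvable_window_and_ids_unique(self):
        catalog = generate_ase_catalog(96, seed=5)
        assert len(catalog) == 96
        assert len({a.ase_id for a in catalog}) == 96
        for a in catalog:
            assert SIZE_MIN_BP <= a.size_exclusion_bp < a.size_inclusion_bp <= SIZE_MAX_BP
            assert a.alt_region_bp >= 20

    def test_some_genes_carry_two_events(self):
        catalog = generate_ase_catalog(96, seed=5)
        assert len({a.gene for a in catalog}) == 92

    def test_seed_determinism(self):
        a = catalog_to_frame(generate_ase_catalog(96, seed=7))
        b = catalog_to_frame(generate_ase_catalog(96, seed=7))
        pd.testing.assert_frame_equal(a, b)
        c = catalog_to_frame(generate_ase_catalog(96, seed=8))
        assert not a.equals(c)

    def test_frame_round_trip(self):
        catalog = generate_ase_catalog(10, seed=3)
        assert frame_to_catalog(catalog_to_frame(catalog)) == catalog


class TestTruth:
    def test_all_null_when_prop_null_is_one(self):
        catalog = generate_ase_catalog(30, seed=1)
        truth = generate_truth(catalog, prop_null=1.0, seed=2)
        assert (truth.effects["effect_dpsi"] == 0).all()

    def test_concordant_signs_when_no_discordance_planted(self):
        catalog = generate_ase_catalog(50, seed=1)
        truth = generate_truth(catalog, prop_null=0.3, discordant_rate=0.0, seed=2)
        for r in truth.effects.itertuples(index=False):
            if r.effect_dpsi == 0:
                continue
            signs = {
                np.sign(truth.realized_effect(r.ase_id, r.cell_line, s)) for s in SIRNAS
            }
            assert len(signs) == 1

    def test_direction_conserved_across_cell_lines(self):
        catalog = generate_ase_catalog(50, seed=1)
        truth = generate_truth(catalog, prop_null=0.3, response_rate=0.8, seed=2)
        signs = (
            truth.effects[truth.effects["effect_dpsi"] != 0]
            .groupby("ase_id")["effect_dpsi"]
            .agg(lambda v: len(set(np.sign(v))))
        )
        assert (signs == 1).all()

    def test_null_fraction_within_binomial_bounds(self):
        catalog = generate_ase_catalog(200, seed=9)
        truth = generate_truth(catalog, prop_null=0.7, seed=10)
        n_null = (
            truth.effects.groupby("ase_id")["effect_dpsi"].agg(lambda v: (v == 0).all()).sum()
        )
        # binomial 95% bounds around 0.7 at n = 200
        half_width = 1.96 * np.sqrt(0.7 * 0.3 / 200)
        assert abs(n_null / 200 - 0.7) <= half_width

    def test_stronger_knockdown_never_shows_smaller_shift(self):
        catalog = generate_ase_catalog(40, seed=3)
        truth = generate_truth(catalog, prop_null=0.2, seed=4)
        kd = DEFAULT_KD_TABLE.set_index(["cell_line", "sirna"])["kd_fraction"]
        for r in truth.effects.itertuples(index=False):
            mags = {
                s: abs(truth.realized_effect(r.ase_id, r.cell_line, s)) for s in SIRNAS
            }
            stronger = max(SIRNAS, key=lambda s: kd[(r.cell_line, s)])
            weaker = SIRNAS[0] if stronger == SIRNAS[1] else SIRNAS[1]
            assert mags[stronger] >= mags[weaker]

    def test_stronger_sirna_expresses_full_planted_effect(self):
        catalog = generate_ase_catalog(10, seed=3)
        truth = generate_truth(catalog, prop_null=0.0, discordant_rate=0.0, seed=4)
        kd = DEFAULT_KD_TABLE.set_index(["cell_line", "sirna"])["kd_fraction"]
        for r in truth.effects.itertuples(index=False):
            if r.effect_dpsi == 0:
                continue
            stronger = max(SIRNAS, key=lambda s: kd[(r.cell_line, s)])
            assert truth.realized_effect(r.ase_id, r.cell_line, stronger) == pytest.approx(
                r.effect_dpsi
            )

    def test_malformed_kd_table_rejected(self):
        catalog = generate_ase_catalog(5, seed=1)
        bad = pd.DataFrame(
            [("L1", "siRNA1", 0.5)], columns=["cell_line", "sirna", "kd_fraction"]
        )
        with pytest.raises(ValueError):
            generate_truth(catalog, cell_lines=["L1"], kd_table=bad, seed=1)

    def test_truth_determinism(self):
        catalog = generate_ase_catalog(20, seed=1)
        a = generate_truth(catalog, seed=5).effects
        b = generate_truth(catalog, seed=5).effects
        pd.testing.assert_frame_equal(a, b)


class TestSampleSheet:
    def test_one_mock_per_cell_line_and_day(self):
        samples = generate_samples()
        df = pd.DataFrame([(s.cell_line, s.condition, s.batch_day) for s in samples],
                          columns=["cell_line", "condition", "batch_day"])
        mocks = df[df["condition"] == "mock"].groupby(["cell_line", "batch_day"]).size()
        assert (mocks == 1).all()
        # every knockdown sample has a same-day mock
        for r in df[df["condition"] != "mock"].itertuples(index=False):
            assert (r.cell_line, r.batch_day) in mocks.index

    def test_split_days_give_each_sirna_its_own_mock(self):
        samples = generate_samples(cell_lines=["L1"], split_sirna_days=True)
        days = {s.condition: s.batch_day for s in samples if s.condition != "mock"}
        assert days["siRNA1"] != days["siRNA2"]


class TestTraceSynthesis:
    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(baseline_sd=-1.0)

    @pytest.mark.parametrize("psi_true", [50.0, 80.0])
    def test_zero_noise_round_trip_recovers_psi(self, psi_true):
        ase = smn_exon7_fixture()
        truth = generate_truth([ase], cell_lines=["L1"], kd_table=KD_L1, prop_null=1.0, seed=1)
        truth.effects["baseline_psi"] = psi_true
        truth = type(truth)(effects=truth.effects, kd=truth.kd)
        sample = Sample("L1", "mock", 1)
        trace = synthesize_trace(sample, [ase], truth, ZERO_NOISE, seed=0)
        psi = quantify_traces([(sample, ase, trace)])["psi"].iloc[0]
        assert psi == pytest.approx(psi_true, abs=0.05)

    def test_size_jitter_keeps_called_sizes_within_ten_percent(self):
        # lognormal tail: at sd = 0.03, |log-error| < log(1.1) with p ≈ 0.9985
        ase = smn_exon7_fixture()
        truth = generate_truth([ase], cell_lines=["L1"], kd_table=KD_L1, prop_null=1.0, seed=1)
        noise = NoiseParams(baseline_sd=0.0, size_jitter_sd=0.03, amount_cv=0.0)
        samples = [Sample("L1", "mock", d) for d in range(1000)]
        peaks = simulate_peak_table([ase], truth, samples, noise=noise, seed=42)
        inc = peaks[peaks["amplicon"] == "inclusion"]["called_size_bp"]
        assert len(inc) == 1000
        within = (np.abs(inc - 330.0) <= 33.0).mean()
        assert within >= 0.99

    def test_trace_and_peak_table_paths_agree_at_zero_noise(self, zero_noise_screen):
        catalog, truth, samples, peaks = zero_noise_screen
        sub = catalog[:4]
        rng = np.random.default_rng(0)
        traces = [
            (s, a, synthesize_trace(s, [a], truth, ZERO_NOISE, rng=rng))
            for s in samples[:6]
            for a in sub
        ]
        psi_tr = quantify_traces(traces).set_index(["ase_id", "cell_line", "condition"])["psi"]
        psi_pk = quantify_peak_table(peaks, catalog).set_index(
            ["ase_id", "cell_line", "condition"]
        )["psi"]
        common = psi_tr.index
        np.testing.assert_allclose(psi_tr.loc[common], psi_pk.loc[common], atol=0.05)

    def test_trace_determinism(self):
        ase = smn_exon7_fixture()
        truth = generate_truth([ase], cell_lines=["L1"], kd_table=KD_L1, prop_null=0.0, seed=1)
        sample = Sample("L1", "siRNA1", 1)
        t1 = synthesize_trace(sample, [ase], truth, seed=9)
        t2 = synthesize_trace(sample, [ase], truth, seed=9)
        np.testing.assert_array_equal(t1.signal, t2.signal)


class TestScreenRoundTrip:
    def test_zero_noise_calls_equal_planted_truth(self, zero_noise_screen):
        catalog, truth, samples, peaks = zero_noise_screen
        psi = quantify_peak_table(peaks, catalog)
        calls = call_changes(compute_delta_psi(psi))
        expected = truth.expected_calls()
        merged = calls.merge(expected, on=["ase_id", "cell_line"], suffixes=("", "_t"))
        assert len(merged) == len(catalog) * 5
        assert (merged["changed"] == merged["changed_t"]).all()
        assert (merged["direction"] == merged["direction_t"]).all()

    def test_discordant_events_are_never_called(self):
        catalog = generate_ase_catalog(40, seed=21)
        truth = generate_truth(
            catalog, prop_null=0.0, discordant_rate=1.0, response_rate=1.0, seed=22
        )
        peaks = simulate_peak_table(catalog, truth, generate_samples(), noise=ZERO_NOISE, seed=23)
        calls = call_changes(compute_delta_psi(quantify_peak_table(peaks, catalog)))
        assert not calls["changed"].any()
        assert (calls["reason"] == "discordant").all()
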