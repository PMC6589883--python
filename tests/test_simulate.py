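"""Synthetic-data generators: determinism, calibration, planted structure."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilmfc import electrochem as ec
from soilmfc import simulate


class TestDeterminism:
    def test_voltage_traces_identical(self, config):
        a = simulate.gen_voltage_trace(config, "TC")
        b = simulate.gen_voltage_trace(config, "TC")
        np.testing.assert_array_equal(a.voltage_V, b.voltage_V)

    def test_distinct_reactors_differ(self, config):
        a = simulate.gen_voltage_trace(config, "TC", "TC-1")
        b = simulate.gen_voltage_trace(config, "TC", "TC-2")
        assert not np.array_equal(a.voltage_V, b.voltage_V)

    def test_all_generators_reproducible(self, config):
        p1 = simulate.gen_qpcr_plate(config)
        p2 = simulate.gen_qpcr_plate(config)
        pd.testing.assert_frame_equal(p1.wells, p2.wells)
        c1 = simulate.gen_concentration_table(config)
        c2 = simulate.gen_concentration_table(config)
        pd.testing.assert_frame_equal(c1, c2)
        t1, _ = simulate.gen_community(config)
        t2, _ = simulate.gen_community(config)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_different_seed_differs(self, config):
        other = replace(config, seed=config.seed + 1)
        a = simulate.gen_voltage_trace(config, "TC")
        b = simulate.gen_voltage_trace(other, "TC")
        assert not np.array_equal(a.voltage_V, b.voltage_V)


class TestVoltageTrace:
    def test_zero_before_startup_delay(self, config):
        trace = simulate.gen_voltage_trace(config, "TC")
        before = trace.voltage_V[trace.time_s < 9 * 3600.0]
        np.testing.assert_array_equal(before, 0.0)

    def test_noiseless_summaries_match_profile(self, noiseless_config):
        prof = noiseless_config.current_profiles["SC"]
        m = ec.trace_metrics(simulate.gen_voltage_trace(noiseless_config, "SC"))
        assert m.first_peak_mA_m2 == pytest.approx(prof.first_peak_mA_m2)
        assert m.max_current_density_mA_m2 == pytest.approx(prof.max_mA_m2)
        assert m.startup_time_h == pytest.approx(prof.startup_h, abs=0.5)

    def test_noisy_summaries_within_tolerance(self, config):
        m = ec.trace_metrics(simulate.gen_voltage_trace(config, "TC"))
        assert m.first_peak_mA_m2 == pytest.approx(65.0, abs=10.0)
        assert m.max_current_density_mA_m2 == pytest.approx(136.0, abs=10.0)

    def test_unknown_treatment_rejected(self, config):
        with pytest.raises(KeyError):
            simulate.gen_voltage_trace(config, "XX")


class TestPolarization:
    def test_divider_model_noiseless(self, noiseless_config):
        sw = simulate.gen_polarization(noiseless_config, "CC",
                                       resistances=[1332.0])
        assert sw.voltage_V[0] == pytest.approx(0.18 / 2)

    def test_monotone_in_resistance_when_noiseless(self, noiseless_config):
        sw = simulate.gen_polarization(noiseless_config, "TC")
        order = np.argsort(sw.resistance_ohm)
        assert (np.diff(sw.voltage_V[order]) >= 0).all()

    def test_parameter_recovery_with_noise(self, config):
        sw = simulate.gen_polarization(config, "CC", noise_frac=0.02,
                                       resistances=np.geomspace(10000, 100, 30))
        fit = ec.fit_polarization(sw)
        assert fit.ocv_V == pytest.approx(0.18, rel=0.02)
        assert fit.internal_resistance_ohm == pytest.approx(1332.0, rel=0.05)

    def test_empty_ladder_rejected(self, config):
        with pytest.raises(ValueError):
            simulate.gen_polarization(config, "TC", resistances=[])


class TestAntibioticDecay:
    def test_endpoint_removal_calibration(self, config):
        # decay pinned so the layer-averaged day-58 removal is ~70% for the
        # closed-circuit tetracycline treatment
        residuals = [simulate.gen_antibiotic_decay(config, "TC", l, 58.0)
                     for l in simulate.LAYERS]
        removal = (5.0 - np.mean(residuals)) / 5.0 * 100.0
        assert removal == pytest.approx(70.0, abs=3.0)

    def test_zero_time_returns_spike(self, config):
        assert simulate.gen_antibiotic_decay(config, "SC", "C", 0.0) == 5.0

    def test_zero_rate_constant(self, config):
        cfg = replace(config, target_residuals={("TC", "C"): 5.0})
        assert cfg.decay_rate_per_day("TC", "C") == 0.0
        assert simulate.gen_antibiotic_decay(cfg, "TC", "C", 30.0) == 5.0

    def test_negative_time_rejected(self, config):
        with pytest.raises(ValueError):
            simulate.gen_antibiotic_decay(config, "TC", "C", -1.0)

    def test_monotone_decay(self, config):
        ts = np.linspace(0, 58, 10)
        cs = [simulate.gen_antibiotic_decay(config, "SN", "S", t) for t in ts]
        assert all(a > b for a, b in zip(cs, cs[1:]))


class TestQPCRPlate:
    def test_planted_qc_failures_counted_exactly(self, config):
        from soilmfc import qpcr
        design = replace(config.qpcr, p_multi_peak=0.1, p_bad_efficiency=0.1)
        cfg = replace(config, qpcr=design)
        plate = simulate.gen_qpcr_plate(cfg)
        _, excluded = qpcr.qc_filter(plate.wells, return_report=True)
        assert len(excluded) == plate.n_planted_qc_failures
        assert plate.n_planted_qc_failures > 0

    def test_noiseless_cts_invert_transform(self, noiseless_config):
        truth = pd.DataFrame({"tetG": [1.0, 1000.0], "16S": [1e4, 1e4]},
                             index=["s1", "s2"])
        plate = simulate.gen_qpcr_plate(noiseless_config, truth)
        cts = plate.wells.set_index(["sample", "gene"])["ct"]
        assert cts.loc[("s1", "tetG")].iloc[0] == pytest.approx(31.0)
        assert cts.loc[("s2", "tetG")].iloc[0] == pytest.approx(21.0)

    def test_nonpositive_gamma_rejected(self, config):
        bad = pd.DataFrame({"tetG": [0.0]}, index=["s1"])
        with pytest.raises(ValueError):
            simulate.gen_qpcr_plate(config, bad)


class TestCommunity:
    def test_within_module_rank_correlation_planted(self, config):
        table, truth = simulate.gen_community(config)
        first = truth.modules["module_1"]
        rhos = []
        for i in range(len(first)):
            for j in range(i + 1, len(first)):
                r = stats.spearmanr(table.counts.loc[first[i]],
                                    table.counts.loc[first[j]]).statistic
                rhos.append(r)
        assert np.mean(rhos) == pytest.approx(0.9, abs=0.1)

    def test_between_module_correlation_near_zero(self, config):
        table, truth = simulate.gen_community(config)
        a = truth.modules["module_1"][0]
        b = truth.modules["module_2"][0]
        r = stats.spearmanr(table.counts.loc[a], table.counts.loc[b]).statistic
        assert abs(r) < 0.5

    def test_treatment_fold_change_enriches_planted_taxa(self, config):
        treat, truth = simulate.gen_community(config, "treatment")
        ctrl, _ = simulate.gen_community(config, "control")
        t_mean = treat.counts.mean(axis=1)
        c_mean = ctrl.counts.mean(axis=1)
        enriched = list(truth.enriched)
        assert (t_mean[enriched] > c_mean[enriched]).mean() > 0.8

    def test_unit_fold_change_leaves_distribution_alone(self, config):
        cfg = replace(config,
                      community=replace(config.community,
                                        treatment_fold_change=1.0))
        treat, _ = simulate.gen_community(cfg, "treatment")
        ctrl, _ = simulate.gen_community(cfg, "control")
        # same marginal distribution: medians of log counts comparable
        lt = np.log1p(treat.counts.values).mean()
        lc = np.log1p(ctrl.counts.values).mean()
        assert lt == pytest.approx(lc, rel=0.1)

    def test_invalid_rho_rejected(self, config):
        cfg = replace(config,
                      community=replace(config.community,
                                        within_module_rho=1.0))
        with pytest.raises(ValueError):
            simulate.gen_community(cfg)

    def test_integer_counts(self, config):
        table, _ = simulate.gen_community(config)
        assert np.issubdtype(table.counts.values.dtype, np.integer)


def test_write_all_produces_loadable_inputs(tmp_path, config):
    from soilmfc.community import AbundanceTable
    from soilmfc import qpcr
    paths = simulate.write_all(config, tmp_path)
    traces = ec.read_traces(paths["traces"])
    assert len(traces) == config.n_reactors * len(config.current_profiles)
    sweeps = ec.read_sweeps(paths["sweeps"])
    assert len(sweeps) == 3
    wells = qpcr.read_wells(paths["qpcr_wells"])
    assert set(wells.columns) >= set(qpcr.WELL_COLUMNS)
    table = AbundanceTable.from_tsv(paths["abundance_treatment"])
    assert table.n_taxa == 40
    edges = pd.read_csv(paths["true_edges"], sep="\t")
    assert {"taxon_a", "taxon_b", "rho_true"} <= set(edges.columns)
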