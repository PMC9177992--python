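"""Generative models: tables, reads, and perturbation time courses."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

from cdtaseq import pipeline
from cdtaseq.kinetics import pr_expected
from cdtaseq.mixturemodel import GlobalParams
from cdtaseq.readkit import dedup_umis, umi_stats
from cdtaseq.simulator import (
    GeneKinetics,
    PerturbationScenario,
    SimConfig,
    default_genes,
    make_test_references,
    scenario_library,
    simulate_reads,
    simulate_tables,
    simulate_timecourse,
)


def one_gene_config(delta=math.log(2) / 8.2, pi=1.0, **kw):
    kw.setdefault("seed", 7)
    kw.setdefault("gamma", math.log(2) / 90.0)
    return SimConfig(genes=[GeneKinetics("g", pi, delta)], **kw)


class TestSimulateTables:
    def test_membership_fraction_matches_closed_form(self):
        cfg = one_gene_config(t_label=9.0, t0=1.0, reads_per_gene=50_000)
        table, p_true, n_recent = simulate_tables(cfg)["g"]
        expected = pr_expected(9.0, math.log(2) / 8.2, cfg.gamma, 1.0)
        assert p_true == pytest.approx(expected, rel=1e-12)
        se = math.sqrt(p_true * (1 - p_true) / cfg.reads_per_gene)
        assert abs(n_recent / cfg.reads_per_gene - p_true) < 3 * se
        assert table.total == cfg.reads_per_gene

    def test_saturation_limit(self):
        cfg = one_gene_config(delta=2.0, t_label=60.0, reads_per_gene=5_000)
        _, p_true, n_recent = simulate_tables(cfg)["g"]
        assert p_true > 0.999 and n_recent / 5_000 > 0.99

    def test_xi_equals_eps_indistinguishable(self):
        cfg1 = one_gene_config(seed=3, epsilon=0.02, xi=0.020001, reads_per_gene=20_000)
        table, _, _ = simulate_tables(cfg1)["g"]
        xs, ys, ns = table.cells()
        # pooled conversions follow a single binomial: chi-square GOF on Y|X=x
        x0 = 13
        obs = table.counts[x0, : x0 + 1]
        p = 0.02
        exp = obs.sum() * stats.binom.pmf(np.arange(x0 + 1), x0, p)
        keep = exp > 5
        chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.001

    def test_seed_determinism(self, small_cohort):
        c1 = SimConfig(genes=small_cohort, seed=9, reads_per_gene=500)
        c2 = SimConfig(genes=small_cohort, seed=9, reads_per_gene=500)
        t1 = simulate_tables(c1)
        t2 = simulate_tables(c2)
        for g in t1:
            assert np.array_equal(t1[g][0].counts, t2[g][0].counts)

    def test_fixed_x_mode(self):
        cfg = one_gene_config(x_value=12, reads_per_gene=1_000)
        table, _, _ = simulate_tables(cfg)["g"]
        xs, _, ns = table.cells()
        assert set(xs) == {12} and ns.sum() == 1_000


class TestSimulateReads:
    def test_truth_conservation_and_determinism(self, toy_references, rng):
        host, spike, windows = toy_references
        genes = default_genes(10, rng)
        cfg = SimConfig(genes=genes, seed=5, reads_per_gene=300)
        reads1, truth1 = simulate_reads(cfg, host, spike, windows)
        reads2, truth2 = simulate_reads(cfg, host, spike, windows)
        assert [r.seq for r in reads1] == [r.seq for r in reads2]
        assert truth1.equals(truth2)
        host_reads = [r for r in reads1 if not r.is_spike]
        assert truth1["n_reads"].sum() == len(host_reads)
        per_gene = truth1.set_index("gene")["n_reads"]
        for g in genes:
            assert per_gene[g.gene_id] == 300

    def test_missing_window_errors(self, toy_references):
        host, spike, windows = toy_references
        cfg = SimConfig(genes=[GeneKinetics("nope", 1.0, 0.1)], seed=1)
        with pytest.raises(KeyError):
            simulate_reads(cfg, host, spike, windows)

    def test_zero_conversion_config_recovers_pr_zero(self, toy_references, rng):
        host, spike, windows = toy_references
        genes = default_genes(4, rng)
        # delta tiny and label window ~ lag: essentially no recent molecules
        genes = [GeneKinetics(g.gene_id, g.pi, 1e-6) for g in genes]
        cfg = SimConfig(genes=genes, seed=2, reads_per_gene=2_000, gamma=0.0,
                        t_label=1.0, t0=1.0)
        reads, _ = simulate_reads(cfg, host, spike, windows)
        params = GlobalParams(cfg.epsilon, cfg.xi, cfg.t0, cfg.gamma)
        res = pipeline.quantify_sample(reads, host, windows, params, t_label=9.0)
        assert (res.rates["p_r"].dropna() < 0.02).all()

    def test_planted_duplication_recovered(self, toy_references, rng):
        host, spike, windows = toy_references
        genes = default_genes(10, rng)
        cfg = SimConfig(genes=genes, seed=8, reads_per_gene=1_000, dup_factor=1.3,
                        spike_fraction=0.0)
        reads, truth = simulate_reads(cfg, host, spike, windows)
        records, _ = pipeline.reads_to_records(reads, host)
        stats_ = umi_stats(records)
        assert stats_["mean_reads_per_umi"] == pytest.approx(1.3, abs=0.03)
        deduped = dedup_umis(records)
        assert len(deduped) <= truth["n_molecules"].sum()

    def test_spike_fraction_sweep_linear(self, toy_references, rng):
        host, spike, windows = toy_references
        genes = default_genes(6, rng)
        levels, inv_fracs = [], []
        for frac in (0.01, 0.02, 0.03, 0.04, 0.05):
            cfg = SimConfig(genes=genes, seed=4, reads_per_gene=400,
                            spike_fraction=frac)
            reads, _ = simulate_reads(cfg, host, spike, windows)
            params = GlobalParams(cfg.epsilon, cfg.xi, cfg.t0, cfg.gamma)
            res = pipeline.quantify_sample(reads, host, windows, params, cfg.t_label)
            levels.append(res.sample.relative_level)
            inv_fracs.append((1 - frac) / frac)
        r = np.corrcoef(inv_fracs, levels)[0, 1]
        assert r**2 > 0.99


class TestTimecourse:
    def test_no_perturbation_flat_at_steady_state(self, small_cohort):
        cfg = SimConfig(genes=small_cohort, seed=1)
        trajs = simulate_timecourse(scenario_library("wildtype"), cfg)
        for g in small_cohort:
            tr = trajs[g.gene_id]
            r_ss = g.pi / (g.delta + cfg.gamma)
            assert np.allclose(tr.total, r_ss, rtol=1e-12)
            p_ss = pr_expected(cfg.t_label, g.delta, cfg.gamma, cfg.t0)
            assert np.allclose(tr.p_r, p_ss, rtol=1e-10)

    def test_full_shutdown_growth_and_initial_slope(self):
        pi, delta, gamma = 2.0, 0.1, 0.005
        scen = PerturbationScenario("shutdown", shutdown_factor=1e-9,
                                    adaptation_factor=1.0,
                                    times=np.arange(0.0, 600.0, 1.0))
        cfg = SimConfig(genes=[GeneKinetics("g", pi, delta)], seed=1, gamma=gamma)
        tr = simulate_timecourse(scen, cfg)["g"]
        # grows toward pi/gamma
        assert tr.total[-1] > 0.9 * (pi / gamma) * (1 - math.exp(-gamma * 599))
        slope0 = (tr.total[1] - tr.total[0]) / 1.0
        assert slope0 == pytest.approx(pi * delta / (delta + gamma), rel=0.01)

    def test_nonmonotone_shape_and_ode_oracle(self):
        pi, delta, gamma = 1.5, math.log(2) / 10.0, 0.006
        scen = PerturbationScenario("x", shutdown_factor=0.05,
                                    adaptation_onset=60.0, adaptation_factor=0.5,
                                    times=np.arange(0.0, 241.0, 2.0))
        cfg = SimConfig(genes=[GeneKinetics("g", pi, delta)], seed=1, gamma=gamma)
        tr = simulate_timecourse(scen, cfg)["g"]
        peak_idx = int(np.argmax(tr.total))
        assert 0 < peak_idx < tr.times.size - 1  # accumulation then reversion
        assert tr.total[0] == pytest.approx(pi / (delta + gamma), rel=1e-12)

        def rhs(t, y):
            d = delta * 0.05
            p = pi * (0.5 if t >= 60.0 else 1.0)
            return p - (d + gamma) * y[0]

        sol = solve_ivp(rhs, (0.0, 240.0), [tr.total[0]], t_eval=tr.times,
                        rtol=1e-10, atol=1e-12, max_step=1.0)
        assert np.max(np.abs(sol.y[0] - tr.total) / np.abs(sol.y[0])) < 1e-6

    def test_recent_matches_labeled_ode_oracle(self):
        # labeled molecules from a pulse: production on, same decay
        pi, delta, gamma = 1.0, 0.05, 0.005
        t_label, t0 = 9.0, 1.0
        scen = PerturbationScenario("x", shutdown_factor=0.2,
                                    adaptation_onset=30.0, adaptation_factor=0.5,
                                    times=np.array([0.0, 28.0, 33.0, 36.0, 100.0]))
        cfg = SimConfig(genes=[GeneKinetics("g", pi, delta)], seed=1, gamma=gamma,
                        t_label=t_label, t0=t0)
        tr = simulate_timecourse(scen, cfg)["g"]
        for i, t in enumerate(tr.times):
            a = t - (t_label - t0)

            def rhs(s, y):
                d = delta if s < 0 else delta * 0.2
                p = pi * (0.5 if s >= 30.0 else 1.0)
                return p - (d + gamma) * y[0]

            sol = solve_ivp(rhs, (a, t), [0.0], rtol=1e-11, atol=1e-13, max_step=0.5)
            assert tr.recent[i] == pytest.approx(float(sol.y[0, -1]), rel=1e-6)

    def test_onset_jitter_is_per_gene_and_seeded(self, small_cohort):
        scen = PerturbationScenario("x", shutdown_factor=0.1, adaptation_onset=60.0,
                                    adaptation_factor=0.5, onset_jitter_sd=10.0)
        cfg = SimConfig(genes=small_cohort, seed=12)
        t1 = simulate_timecourse(scen, cfg)
        t2 = simulate_timecourse(scen, cfg)
        g0, g1 = small_cohort[0].gene_id, small_cohort[1].gene_id
        assert np.array_equal(t1[g0].recent, t2[g0].recent)
        # jitter differentiates genes' adaptation timing
        r0 = t1[g0].recent / t1[g0].recent[0]
        r1 = t1[g1].recent / t1[g1].recent[0]
        assert not np.allclose(r0, r1)


class TestScenarioLibrary:
    def test_wildtype_identity(self):
        wt = scenario_library("wildtype")
        assert wt.shutdown_factor == 1.0 and wt.adaptation_factor == 1.0

    def test_unknown_name_lists_presets(self):
        with pytest.raises(KeyError, match="xrn1-like"):
            scenario_library("nonsense")

    def test_onset_ordering(self):
        lib = scenario_library()
        assert (
            lib["not1-like"].adaptation_onset
            < lib["dcp2-like"].adaptation_onset
            < lib["xrn1-like"].adaptation_onset
        )
        assert (
            lib["xrn1-like"].shutdown_factor
            < lib["dcp2-like"].shutdown_factor
            < lib["not1-like"].shutdown_factor
        )

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            PerturbationScenario("bad", shutdown_factor=0.0)
        with pytest.raises(ValueError):
            PerturbationScenario("bad", adaptation_factor=1.5)

    def test_scenario_from_yaml_with_preset_override(self, tmp_path):
        from cdtaseq.simulator import scenario_from_file

        path = tmp_path / "scen.yaml"
        path.write_text(
            "preset: dcp2-like\nadaptation_onset: 40\ntimes: [0, 10, 20, 30, 40, 50]\n"
        )
        scen = scenario_from_file(path)
        assert scen.adaptation_onset == 40
        assert scen.shutdown_factor == scenario_library("dcp2-like").shutdown_factor
        assert scen.times.tolist() == [0, 10, 20, 30, 40, 50]


class TestEndToEndRecovery:
    def test_pipeline_recovers_planted_delta(self, rng):
        genes = default_genes(25, rng)
        host, spike, windows = make_test_references(25, rng)
        cfg = SimConfig(genes=genes, seed=21, reads_per_gene=2_000)
        reads, truth = simulate_reads(cfg, host, spike, windows)
        params = GlobalParams(cfg.epsilon, cfg.xi, cfg.t0, cfg.gamma)
        res = pipeline.quantify_sample(reads, host, windows, params, cfg.t_label)
        df = res.rates.merge(truth, left_on="transcript_id", right_on="gene")
        ok = df[df["censoring"] == "ok"]
        assert len(ok) >= 20
        rel_err = np.abs(ok["delta_x"] - ok["delta_y"]) / ok["delta_y"]
        assert rel_err.median() < 0.10
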