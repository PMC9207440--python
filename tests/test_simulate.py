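import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmq.quantify import compute_fold_change
from rhythmq.simulate import (
    DesignGrid,
    GeneTruth,
    ScenarioConfig,
    generate_dataset,
    generate_random_feeding_schedule,
    study_scenario,
    true_expression,
)

from conftest import make_scenario, replace


class TestDesignGrid:
    def test_default_grid_matches_study_design(self):
        d = DesignGrid()
        assert d.time_labels == ("ZT3", "ZT7", "ZT11", "ZT15", "ZT19", "ZT23", "ZT3b")
        assert d.times_h == (3.0, 7.0, 11.0, 15.0, 19.0, 23.0, 27.0)
        assert d.time_of("ZT3b") == 27.0  # next-day 3 h, phase-equivalent to 3 h
        assert all(d.n_at(g, lbl) == 7 for g, lbl in d.iter_cells())
        assert len(d.groups) == 3
        assert d.light_regime["DD_scheduled"] == "DD"
        assert d.feeding_regime["LD_random"] == "random"

    def test_rejects_small_n_and_bad_times(self):
        with pytest.raises(ValueError, match="n_per_time"):
            DesignGrid(n_per_time=1)
        with pytest.raises(ValueError, match="strictly increasing"):
            DesignGrid(times_h=(3.0, 3.0), time_labels=("a", "b"))
        with pytest.raises(ValueError, match="unique"):
            DesignGrid(times_h=(3.0, 7.0), time_labels=("a", "a"))

    def test_per_cell_n_between_5_and_7(self):
        rng = np.random.default_rng(0)
        base = DesignGrid(groups=("G1",), tissues=("liver",))
        ns = {cell: int(rng.integers(5, 8)) for cell in base.iter_cells()}
        d = replace(base, n_per_time=ns)
        sc = make_scenario([GeneTruth(gene="g", mesor=2.0)])
        sc = replace(sc, design=d)
        df = generate_dataset(sc)
        counts = df[df["gene"] == "g"].groupby("time_label")["sample_id"].nunique()
        for (g, lbl), n in ns.items():
            assert counts[lbl] == n


class TestGeneTruth:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="mesor"):
            GeneTruth(gene="g", mesor=0.0)
        with pytest.raises(ValueError, match="acrophase"):
            GeneTruth(gene="g", mesor=1.0, acrophase_h=24.0)

    def test_trajectory_is_the_stated_sinusoid(self):
        tr = GeneTruth(gene="g", mesor=5.0, amplitude=2.0, acrophase_h=17.5)
        t = np.array([3.0, 7.0, 27.0])
        expected = 5.0 + 2.0 * np.cos(np.pi / 12 * (t - 17.5))
        assert np.allclose(true_expression(tr, t), expected)
        assert tr.is_rhythmic
        assert not GeneTruth(gene="g", mesor=5.0).is_rhythmic


class TestGenerateDataset:
    def test_default_design_emits_seven_labelled_times_seven_fish(self):
        sc = study_scenario(seed=0)
        df = generate_dataset(sc)
        sub = df[(df["gene"] == "per1a") & (df["tissue"] == "hypothalamus")
                 & (df["group"] == "LD_scheduled")]
        assert list(sub["time_label"].unique()) == [
            "ZT3", "ZT7", "ZT11", "ZT15", "ZT19", "ZT23", "ZT3b"]
        assert (sub.groupby("time_label")["sample_id"].nunique() == 7).all()
        # duplicate wells per fish x gene x time
        per_fish = sub.groupby(["sample_id", "time_label"])["replicate"].count()
        assert (per_fish == 2).all()

    def test_determinism_same_config_bytes_identical(self):
        sc = study_scenario(seed=123)
        csv1 = generate_dataset(sc).to_csv(index=False)
        csv2 = generate_dataset(sc).to_csv(index=False)
        assert csv1 == csv2
        assert generate_dataset(study_scenario(seed=124)).to_csv(index=False) != csv1

    def test_null_scenario_flat_means(self):
        sc = make_scenario(
            [GeneTruth(gene="g", mesor=5.0, biological_noise_sd=0.1)],
            output_kind="measurement", noise_scale="additive", seed=4,
        )
        df = generate_dataset(sc)
        assert not sc.genes[0].is_rhythmic
        means = df.groupby("time_label")["value"].mean()
        assert np.ptp(means.to_numpy()) < 0.25  # flat up to sampling noise

    def test_zero_noise_quantification_recovers_sinusoid(self, zero_noise_table):
        """Noise-free Ct data put through 2^-ddCt equal the generating sinusoid
        once rescaled by the (known) expression level of the calibrator cell."""
        df, sc = zero_noise_table
        expr = compute_fold_change(df, sc.reference_gene)
        truth = sc.genes[0]
        cal = expr.attrs["calibrators"][("liver", "per1a")]
        scale = float(true_expression(truth, cal["time_h"]))
        sub = expr[expr["gene"] == "per1a"]
        expected = true_expression(truth, sub["time_h"].to_numpy())
        assert np.allclose(sub["fold"].to_numpy() * scale, expected, rtol=1e-12)
        # the flat gene comes back flat at fold 1
        flat = expr[expr["gene"] == "clock1a"]["fold"]
        assert np.allclose(flat, 1.0, rtol=1e-12)

    def test_reference_gene_time_invariant_in_expectation(self):
        sc = make_scenario(
            [GeneTruth(gene="g", mesor=2.0, amplitude=1.0, acrophase_h=5,
                       biological_noise_sd=0.2)],
            ref_sd=0.15, technical_sd=0.1, seed=9, n_per_time=30,
        )
        df = generate_dataset(sc)
        ref = df[df["gene"] == sc.reference_gene]
        means = ref.groupby("time_label")["ct"].mean()
        assert np.ptp(means.to_numpy()) < 0.15

    def test_scale_equivariance_of_quantified_folds(self, zero_noise_table):
        """Doubling every truth level leaves calibrator-relative folds unchanged."""
        df, sc = zero_noise_table
        doubled = replace(
            sc, genes=[replace(t, mesor=2 * t.mesor, amplitude=2 * t.amplitude)
                       for t in sc.genes]
        )
        f0 = compute_fold_change(df, sc.reference_gene)["fold"]
        f1 = compute_fold_change(generate_dataset(doubled), sc.reference_gene)["fold"]
        assert np.allclose(f0, f1, rtol=1e-12)

    def test_rejects_negative_expected_expression(self):
        sc = make_scenario(
            [GeneTruth(gene="badgene", mesor=1.0, amplitude=2.0, acrophase_h=0.0)]
        )
        with pytest.raises(ValueError, match="badgene"):
            generate_dataset(sc)

    def test_truths_resolve_per_tissue_and_group(self):
        sc = study_scenario(seed=0)
        hyp_dd = sc.truths_for("hypothalamus", "DD_scheduled")
        assert all(t.amplitude == 0.0 for t in hyp_dd)  # fully arrhythmic
        liv_dd = sc.truths_for("liver", "DD_scheduled")
        assert any(t.amplitude > 0 for t in liv_dd)  # liver keeps rhythms

    def test_yaml_round_trip(self, tmp_path):
        sc = study_scenario(seed=5)
        p = tmp_path / "sc.yaml"
        sc.to_yaml(p)
        back = ScenarioConfig.from_yaml(p)
        assert back == sc
        assert generate_dataset(back).equals(generate_dataset(sc))


class TestFeedingSchedule:
    def test_single_day_single_time(self):
        s = generate_random_feeding_schedule(1, seed=0)
        assert s.shape == (1,) and 0 <= s[0] < 24

    def test_deterministic_under_seed(self):
        a = generate_random_feeding_schedule(30, seed=42)
        b = generate_random_feeding_schedule(30, seed=42)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, generate_random_feeding_schedule(30, seed=43))

    def test_one_feeding_in_every_24h_day(self):
        s = generate_random_feeding_schedule(50, seed=1)
        days = np.floor(s / 24.0).astype(int)
        assert np.array_equal(days, np.arange(50))

    def test_times_of_day_uniform(self):
        s = generate_random_feeding_schedule(1000, seed=7)
        stat, _ = stats.kstest(np.mod(s, 24.0) / 24.0, "uniform")
        assert stat < 1.36 / np.sqrt(1000)  # 5% critical value

    def test_rejects_nonpositive_days(self):
        with pytest.raises(ValueError):
            generate_random_feeding_schedule(0, seed=0)
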