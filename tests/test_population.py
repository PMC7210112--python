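"""Optimization, clustering, correlation and the transmission maps."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from grcsim.cell import GrCModel
from grcsim.population import (
    OptimizationConfig,
    classify_subtypes,
    correlate_ifc_gmax,
    ifc_vs_gmax_sweep,
    make_template,
    optimize_conductances,
)
from grcsim.synth import CohortSpec, generate_cohort


class TestClassifySubtypes:
    def test_three_planted_gaussian_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        blobs = []
        for mu in (-80.0, -40.0, 0.0):
            blobs.append(
                pd.DataFrame(
                    {
                        "ifc": rng.normal(mu, 2.0, 20),
                        "f_initial": rng.normal(45.0, 2.0, 20),
                        "subtype": f"blob{mu}",
                    }
                )
            )
        df = pd.concat(blobs, ignore_index=True)
        res = classify_subtypes(df)
        assert res.k == 3
        assert adjusted_rand_score(df.subtype, res.assignments) == 1.0

    def test_single_blob_flagged_degenerate_or_low_k(self):
        df = pd.DataFrame({"ifc": np.full(30, -20.0), "f_initial": np.full(30, 40.0)})
        res = classify_subtypes(df)
        assert res.degenerate and res.k == 1

    def test_synthetic_cohort_selects_three_clusters_with_significant_anova(self):
        """The non-accelerating cells of a cohort emulating the recorded
        proportions split into three statistically distinct clusters."""
        df = generate_cohort(CohortSpec(n_cells=63, seed=2))
        res = classify_subtypes(df)
        non_accel = res.assignments >= 0
        assert int(non_accel.sum()) == 55
        assert res.k == 3
        assert res.anova_p is not None and res.anova_p < 0.05

    def test_planted_labels_recovered_with_high_ari(self):
        df = generate_cohort(CohortSpec(n_cells=63, seed=4))
        res = classify_subtypes(df)
        mask = res.assignments >= 0
        ari = adjusted_rand_score(df.subtype[mask], res.assignments[mask])
        assert ari > 0.9

    def test_accelerating_cells_are_preseparated(self):
        df = generate_cohort(CohortSpec(n_cells=63, seed=0))
        res = classify_subtypes(df)
        accel_mask = (df.subtype == "accelerating").to_numpy()
        assert np.all(res.assignments[accel_mask] == -1)

    def test_invariant_to_feature_column_order(self):
        df = generate_cohort(CohortSpec(n_cells=63, seed=7))
        a = classify_subtypes(df[["ifc", "f_initial"]].assign(subtype=df.subtype))
        b = classify_subtypes(df[["f_initial", "ifc"]].assign(subtype=df.subtype))
        assert a.k == b.k
        assert np.array_equal(a.assignments, b.assignments)


class TestCorrelation:
    def test_collinear_points_have_unit_r_squared(self):
        g = np.linspace(0.01, 0.1, 12)
        df = pd.DataFrame({"Cav2.2@soma": g, "ifc": -5.0 - 900.0 * g})
        slope, r2, p = correlate_ifc_gmax(df)
        assert slope == pytest.approx(-900.0)
        assert r2 == pytest.approx(1.0)

    def test_shuffled_pairing_destroys_correlation(self):
        rng = np.random.default_rng(1)
        g = np.linspace(0.01, 0.1, 200)
        ifc = -5.0 - 900.0 * g
        df = pd.DataFrame({"Cav2.2@soma": g, "ifc": rng.permutation(ifc)})
        _, r2, _ = correlate_ifc_gmax(df)
        assert r2 < 0.05

    def test_zero_variance_gmax_rejected(self):
        df = pd.DataFrame({"Cav2.2@soma": np.full(12, 0.05), "ifc": np.arange(12.0)})
        with pytest.raises(ValueError, match="zero variance"):
            correlate_ifc_gmax(df)

    def test_needs_at_least_ten_models(self):
        df = pd.DataFrame({"Cav2.2@soma": [0.1, 0.2], "ifc": [0.0, -10.0]})
        with pytest.raises(ValueError):
            correlate_ifc_gmax(df)


class TestIFCvsCavSweep:
    def test_adaptation_deepens_with_cav22_density(self):
        """Across a model sweep spanning the Cav2.2 range, IFC@10pA falls
        with the conductance density (negative regression slope) — the
        model's account of why high-Cav cells adapt."""
        sweep = ifc_vs_gmax_sweep(
            n_models=12,
            base_overrides={("KCa1.1", "soma"): 1.0, ("Kv1.1", "soma"): 1.2},
            dt=0.02,
        )
        slope, r2, p = correlate_ifc_gmax(sweep)
        assert slope < 0.0
        assert p < 0.05
        assert sweep.ifc.iloc[0] > sweep.ifc.iloc[-1]


GA_GENES = (
    ("Nav1.6", "soma"),
    ("Kv3.4", "soma"),
    ("Kv2", "soma"),
    ("Cav2.2", "soma"),
    ("KCa1.1", "soma"),
)


@pytest.fixture(scope="module")
def recovery_run():
    base = GrCModel.from_config().with_gmax({("Kv1.1", "soma"): 1.2})
    truth = {("Cav2.2", "soma"): 0.02, ("KCa1.1", "soma"): 0.6}
    template = make_template(base.with_gmax(truth), currents=(10.0,))
    cfg = OptimizationConfig(
        population_size=16,
        n_generations=5,
        template=template,
        template_currents=(10.0,),
        genes=GA_GENES,
        seed=3,
    )
    pop = optimize_conductances(cfg, base_model=base)
    return base, template, cfg, pop


class TestOptimizer:

    def test_best_fitness_non_increasing_across_generations(self, recovery_run):
        _, _, _, pop = recovery_run
        assert all(b <= a + 1e-12 for a, b in zip(pop.history, pop.history[1:]))

    def test_recovers_template_features_within_two_sd(self, recovery_run):
        """Parameter-recovery: the best individual reproduces every feature
        of the self-generated template within 2 feature-SDs."""
        from grcsim.population import _feature_distance

        base, template, cfg, pop = recovery_run
        best_model = base.with_gmax(pop.best())
        feats = make_template(best_model, currents=(10.0,))
        d = _feature_distance(feats, template)
        assert np.all(d < 2.0), d

    def test_deterministic_under_fixed_seed(self, recovery_run):
        base, template, cfg, pop = recovery_run
        pop2 = optimize_conductances(cfg, base_model=base)
        assert np.allclose(pop.table.fitness, pop2.table.fitness)

    def test_collapsed_bounds_give_identical_population(self, tmp_path):
        """With every gene's bounds collapsed to a point the GA has no
        freedom: the final population has zero variance."""
        from grcsim.channels import load_channel_table

        table = load_channel_table()
        # collapse bounds of two soma channels onto their defaults
        import copy

        t2 = copy.deepcopy(table)
        for chan in ("Kv2", "Kv1.5"):
            d = t2.channels[chan]["distribution"]["soma"]
            d["bounds"] = [d["gmax"], d["gmax"]]
        base = GrCModel.from_config(channel_table=t2)
        template = make_template(base, currents=(10.0,))
        cfg = OptimizationConfig(
            population_size=6,
            n_generations=1,
            template=template,
            template_currents=(10.0,),
            genes=(("Kv2", "soma"), ("Kv1.5", "soma")),
            seed=0,
        )
        pop = optimize_conductances(cfg, base_model=base)
        assert pop.table["Kv2@soma"].std() == 0.0
        assert pop.table["Kv1.5@soma"].std() == 0.0

    def test_short_template_leaves_late_adaptation_unconstrained(self, recovery_run):
        """Fitting only the first 500 ms leaves the slow dials free: the
        final population simulated for 2 s spans clearly adapting and
        nearly non-adapting solutions."""
        from grcsim.cell import simulate_current_clamp
        from grcsim.features import spike_train_stats

        base, _, cfg, pop = recovery_run
        good = pop.table[pop.table.fitness < 5.0]
        ifcs = []
        for _, row in good.head(10).iterrows():
            overrides = {g: float(row[f"{g[0]}@{g[1]}"]) for g in cfg.genes}
            st = spike_train_stats(
                simulate_current_clamp(base.with_gmax(overrides), 10.0, 2000.0, dt=0.02)
            )
            if st.delta_f_0_2000 is not None:
                ifcs.append(st.delta_f_0_2000)
        assert min(ifcs) < -30.0
        assert max(ifcs) > -15.0

    def test_missing_template_rejected(self):
        with pytest.raises(ValueError):
            optimize_conductances(OptimizationConfig(template=None))
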