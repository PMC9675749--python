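import numpy as np
import pandas as pd
import pytest

from stftwas.expression_models import (GeneModel, GeneSkipped,
                                       fold_assignment, residualize_traits,
                                       select_models, train_gene_model,
                                       write_model_store)
from stftwas.synthetic_data import _block_sizes, sample_dosages

from conftest import make_panel


class TestResidualize:
    def test_no_covariates_centers_traits(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame({"g1": rng.normal(5, 1, 50)},
                              index=[f"S{i}" for i in range(50)])
        out = residualize_traits(values)
        np.testing.assert_allclose(out["g1"],
                                   values["g1"] - values["g1"].mean())

    def test_trait_equal_to_covariate_is_dropped(self):
        rng = np.random.default_rng(1)
        idx = [f"S{i}" for i in range(50)]
        cov = pd.DataFrame({"c1": rng.normal(0, 1, 50)}, index=idx)
        values = pd.DataFrame({"g1": cov["c1"], "g2": rng.normal(0, 1, 50)},
                              index=idx)
        out = residualize_traits(values, cov)
        assert list(out.columns) == ["g2"]

    def test_projection_recovers_noise_variance(self):
        rng = np.random.default_rng(2)
        n = 500
        idx = [f"S{i}" for i in range(n)]
        cov = pd.DataFrame({"c1": rng.normal(0, 1, n)}, index=idx)
        noise = rng.normal(0, 1, n)
        values = pd.DataFrame({"g": 2.0 * cov["c1"] + noise}, index=idx)
        out = residualize_traits(values, cov)
        assert out["g"].var() == pytest.approx(noise.var(), rel=0.05)
        assert abs(out["g"].mean()) < 1e-10

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(3)
        idx = [f"S{i}" for i in range(30)]
        c1 = rng.normal(0, 1, 30)
        cov = pd.DataFrame({"c1": c1, "c2": 2 * c1}, index=idx)
        values = pd.DataFrame({"g": rng.normal(0, 1, 30)}, index=idx)
        with pytest.raises(ValueError, match="c2"):
            residualize_traits(values, cov)


class TestFoldAssignment:
    def test_balanced_and_order_invariant(self):
        ids = [f"S{i}" for i in range(103)]
        folds = fold_assignment(ids, 10, seed=7)
        counts = np.bincount(folds, minlength=10)
        assert counts.max() - counts.min() <= 1
        perm = np.random.default_rng(0).permutation(103)
        permuted = fold_assignment([ids[i] for i in perm], 10, seed=7)
        np.testing.assert_array_equal(permuted, folds[perm])

    def test_seed_changes_folds(self):
        ids = [f"S{i}" for i in range(50)]
        assert not np.array_equal(fold_assignment(ids, 5, 1),
                                  fold_assignment(ids, 5, 2))


def heritable_panel_and_trait(seed, n=500, m=30, h2=0.4, causal=0):
    rng = np.random.default_rng(seed)
    dos = sample_dosages(n, rng.uniform(0.1, 0.5, m), _block_sizes(m, 3),
                         0.2, rng)
    panel = make_panel(dos)
    g = 0.8 * dos[:, causal]
    s2e = np.var(g) * (1 - h2) / h2
    y = g + rng.normal(0, np.sqrt(s2e), n)
    trait = pd.Series(y - y.mean(), index=panel.samples, name="gene1")
    return panel, trait


class TestTrainGeneModel:
    def test_recovers_single_variant_signal(self):
        panel, trait = heritable_panel_and_trait(0)
        span = ("1", int(panel.variants["pos"].iloc[0]),
                int(panel.variants["pos"].iloc[0]) + 10)
        model = train_gene_model(panel, trait, span,
                                 set(panel.variants["id"]), seed=1)
        assert 0.30 <= model.cv_r2 <= 0.50
        assert "v0000" in model.variant_ids
        w = dict(zip(model.variant_ids, model.weights))
        assert w["v0000"] > 0  # sign matches the simulated effect

    def test_weights_confined_to_prioritized_cis_candidates(self):
        panel, trait = heritable_panel_and_trait(1)
        prioritized = set(panel.variants["id"][:10])
        span = ("1", 1001, 1011)
        model = train_gene_model(panel, trait, span, prioritized,
                                 window_bp=100_000, seed=1)
        from stftwas.expression_models import cis_candidates
        allowed = set(panel.variants["id"][
            cis_candidates(panel, span, prioritized, 100_000)])
        assert set(model.variant_ids) <= allowed

    def test_no_cis_candidates_skips(self):
        panel, trait = heritable_panel_and_trait(2)
        with pytest.raises(GeneSkipped, match="no prioritized cis"):
            train_gene_model(panel, trait, ("2", 1, 10),
                             set(panel.variants["id"]))

    def test_constant_trait_skips(self):
        panel, trait = heritable_panel_and_trait(3)
        trait[:] = 1.0
        with pytest.raises(GeneSkipped, match="variance"):
            train_gene_model(panel, trait, ("1", 1001, 1011),
                             set(panel.variants["id"]))

    def test_deterministic_given_seed(self):
        panel, trait = heritable_panel_and_trait(4)
        span = ("1", 1001, 1011)
        a = train_gene_model(panel, trait, span, set(panel.variants["id"]),
                             seed=9)
        b = train_gene_model(panel, trait, span, set(panel.variants["id"]),
                             seed=9)
        assert a.cv_r2 == b.cv_r2
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_cv_r2_order_invariant(self):
        panel, trait = heritable_panel_and_trait(5, n=200)
        span = ("1", 1001, 1011)
        base = train_gene_model(panel, trait, span,
                                set(panel.variants["id"]), seed=3)
        perm = np.random.default_rng(1).permutation(panel.n_samples)
        panel2 = type(panel)([panel.samples[i] for i in perm],
                             panel.variants, panel.dosages[perm])
        shuffled = train_gene_model(panel2, trait, span,
                                    set(panel.variants["id"]), seed=3)
        assert shuffled.cv_r2 == pytest.approx(base.cv_r2, abs=1e-10)

    def test_null_trait_rarely_passes_filter(self):
        # pure-noise traits must fail the R^2 > 0.01 retention filter in
        # the vast majority of draws
        rng = np.random.default_rng(6)
        dos = sample_dosages(300, rng.uniform(0.1, 0.5, 50),
                             _block_sizes(50, 5), 0.2, rng)
        panel = make_panel(dos)
        span = ("1", 1001, 1011)
        passed = 0
        n_seeds = 60
        for s in range(n_seeds):
            noise = np.random.default_rng(1000 + s).normal(0, 1, 300)
            trait = pd.Series(noise, index=panel.samples, name="g")
            m = train_gene_model(panel, trait, span,
                                 set(panel.variants["id"]), seed=s,
                                 nested=False)
            passed += m.cv_r2 > 0.01
        assert passed <= 0.10 * n_seeds + 2

    def test_extreme_regularization_kills_all_weights(self):
        # monotone shrinkage sanity: a huge penalty empties the model and
        # leaves no predictive ability
        panel, trait = heritable_panel_and_trait(7, n=200)
        span = ("1", 1001, 1011)
        strong = train_gene_model(panel, trait, span,
                                  set(panel.variants["id"]), seed=1,
                                  alpha_override=1e6)
        assert len(strong.variant_ids) == 0
        assert strong.cv_r2 <= 0.0
        mild = train_gene_model(panel, trait, span,
                                set(panel.variants["id"]), seed=1)
        assert mild.cv_r2 > strong.cv_r2

    def test_median_cv_r2_monotone_in_heritability(self):
        medians = []
        for h2 in (0.1, 0.3, 0.6):
            r2s = []
            for s in range(8):
                panel, trait = heritable_panel_and_trait(100 + s, n=300,
                                                         h2=h2)
                m = train_gene_model(panel, trait, ("1", 1001, 1011),
                                     set(panel.variants["id"]), seed=s,
                                     nested=False)
                r2s.append(m.cv_r2)
            medians.append(np.median(r2s))
        assert medians[0] < medians[1] < medians[2]


class TestSelectModels:
    def _model(self, r2):
        return GeneModel("g", ("1", 1, 2), ["v"], np.array([1.0]), r2, 10,
                         0.1)

    def test_strict_threshold(self):
        models = [self._model(r) for r in (0.0, 0.01, 0.0100001, 0.5)]
        kept = select_models(models)
        assert [m.cv_r2 for m in kept] == [0.0100001, 0.5]

    def test_empty_input(self):
        assert select_models([]) == []

    def test_matches_bruteforce_filter(self):
        rng = np.random.default_rng(8)
        r2s = rng.uniform(-0.1, 0.3, 20)
        models = [self._model(r) for r in r2s]
        assert len(select_models(models)) == int((r2s > 0.01).sum())


def test_model_store_round_trip(tmp_path):
    panel, trait = heritable_panel_and_trait(9, n=150)
    model = train_gene_model(panel, trait, ("1", 1001, 1011),
                             set(panel.variants["id"]), seed=2)
    write_model_store([model], panel, tmp_path)
    weights = pd.read_csv(tmp_path / "weights.tsv", sep="\t")
    extra = pd.read_csv(tmp_path / "extra.tsv", sep="\t")
    cov = pd.read_csv(tmp_path / "covariance.tsv", sep="\t")
    assert set(weights["variant_id"]) == set(model.variant_ids)
    assert extra.loc[0, "cv_r2"] == pytest.approx(model.cv_r2)
    # stored covariance matches the training panel
    v0 = model.variant_ids[0]
    j = list(panel.variants["id"]).index(v0)
    expected_var = np.var(panel.dosages[:, j], ddof=1)
    got = cov[(cov["variant_i"] == v0) & (cov["variant_j"] == v0)]
    assert got["cov"].iloc[0] == pytest.approx(expected_var)
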