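import numpy as np
import pytest

from phylotaste.errors import ModelError
from phylotaste.metrics import drug_versatility
from phylotaste.pglmm import (
    DesignData,
    MCMCSettings,
    ModelSpec,
    RandomTerm,
    build_design,
    compute_h2,
    compute_px,
    default_random_terms,
    detect_separation,
    kde_mode,
    sample_posterior,
    summarize,
    ztpoisson_logpmf,
    _sample_truncnorm,
)
from phylotaste.phylo import phylo_correlation


class TestZTPoissonPmf:
    def test_value_at_k1_lam1(self):
        # e^-1 / (1 - e^-1)
        assert np.exp(ztpoisson_logpmf(1, 1.0)) == pytest.approx(
            0.581977, abs=1e-6
        )

    def test_sums_to_one(self):
        total = np.exp(ztpoisson_logpmf(np.arange(1, 51), 2.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_truncation_limit_small_rate(self):
        assert np.exp(ztpoisson_logpmf(1, 1e-10)) == pytest.approx(1.0, abs=1e-9)

    def test_k_zero_is_domain_error(self):
        with pytest.raises(ModelError):
            ztpoisson_logpmf(0, 1.0)
        with pytest.raises(ModelError):
            ztpoisson_logpmf(1, 0.0)


class TestPx:
    def test_one_of_four_crosses(self):
        assert compute_px(np.array([-1.0, 2, 3, 4])).value == 0.25

    def test_symmetric_pair(self):
        assert compute_px(np.array([-1.0, 1.0])).value == 0.5

    def test_no_crossing_records_floor(self):
        r = compute_px(np.array([1.0, 2.0, 3.0]))
        assert r.value == 0.0
        assert r.floor == pytest.approx(1 / 3)

    def test_zero_counts_as_crossing(self):
        assert compute_px(np.array([0.0, 1.0, 1.0, 1.0])).value == 0.25

    def test_doubled_variant(self):
        r = compute_px(np.array([-1.0, 1, 1, 1]))
        assert r.doubled == pytest.approx(0.5)

    def test_needs_two_samples(self):
        with pytest.raises(ModelError):
            compute_px(np.array([1.0]))


class TestH2:
    def test_direct_ratio(self):
        h2, mode = compute_h2(
            np.array([[9.0, 0.5, 0.25]]* 20),
            ["phylo", "plant_part", "panellist"],
            np.full(20, 0.25),
        )
        assert np.allclose(h2, 0.9)
        assert mode == pytest.approx(0.9, abs=0.01)

    def test_zero_phylo_variance(self):
        h2, mode = compute_h2(
            np.array([[0.0, 1.0]] * 20), ["phylo", "x"], np.ones(20)
        )
        assert np.all(h2 == 0)

    def test_requires_phylo_label(self):
        with pytest.raises(ModelError):
            compute_h2(np.ones((5, 1)), ["other"], np.ones(5))


def test_kde_mode_constant_samples():
    assert kde_mode(np.full(50, 3.2)) == pytest.approx(3.2)


@pytest.fixture
def design_dataset(vocab):
    """Hand-built dataset in which every fixed-effect column varies."""
    import pandas as pd
    from conftest import make_trials
    from phylotaste.panel_data import PanelDataset, UseMatrix

    drugs = pd.DataFrame(
        {
            "drug_id": ["d1", "d2"],
            "taxon_name": ["Genus alpha", "Genus beta"],
            "genus": ["Genus", "Genus"],
            "family": ["Fam", "Fam"],
            "plant_part": ["root", "bark"],
        }
    )
    trials = make_trials(
        vocab,
        [
            ("t1", "d1", "p1", 5, {q: 1 for q in vocab.qualities}),
            ("t2", "d1", "p2", 9, {q: 2 for q in vocab.qualities}),
            ("t3", "d2", "p1", 7, {}),
        ],
    )
    uses = UseMatrix(
        indicators=pd.DataFrame(
            [[1, 0], [0, 1]], index=pd.Index(["d1", "d2"], name="drug_id"),
            columns=["u1", "u2"],
        ),
        category_map={"u1": "A", "u2": "B"},
    )
    versa = pd.DataFrame({"drug_id": ["d1", "d2"], "n_categories": [3, 0]})
    return PanelDataset(drugs=drugs, trials=trials, uses=uses, vocab=vocab), versa


class TestBuildDesign:
    def test_row_and_column_counts(self, design_dataset):
        ds, versa = design_dataset
        spec = ModelSpec(fixed_effects="qualities", family="gaussian")
        d = build_design(ds, spec, versa)
        assert d.X.shape == (3, 24)  # intercept + 22 qualities + days
        assert d.x_names[0] == "intercept" and d.x_names[-1] == "days"

    def test_versatility_repeated_within_drug(self, design_dataset):
        ds, versa = design_dataset
        d = build_design(ds, ModelSpec(family="gaussian"), versa)
        np.testing.assert_array_equal(d.y, [3.0, 3.0, 0.0])

    def test_zero_truncation_drops_and_logs(self, design_dataset):
        ds, versa = design_dataset
        spec = ModelSpec(family="zt_poisson", fixed_effects="qualities")
        d = build_design(ds, spec, versa)
        assert d.n_dropped == 1  # d2's single trial (versatility 0)
        assert len(d.y) == 2

    def test_days_is_mean_centred(self, design_dataset):
        ds, versa = design_dataset
        d = build_design(ds, ModelSpec(family="gaussian"), versa)
        assert d.X[:, d.x_names.index("days")].mean() == pytest.approx(0.0)

    def test_use_response(self, design_dataset):
        ds, _ = design_dataset
        spec = ModelSpec(response="use:u1", family="probit",
                         fixed_effects="qualities")
        d = build_design(ds, spec)
        np.testing.assert_array_equal(d.y, [1.0, 1.0, 0.0])

    def test_constant_column_errors_unless_dropped(self, small_sim):
        ds, tree, ranks, truth = small_sim
        spec = ModelSpec(fixed_effects="qualities", family="gaussian")
        with pytest.raises(ModelError, match="constant"):
            build_design(ds, spec, truth.versatility)
        spec2 = ModelSpec(fixed_effects="qualities", family="gaussian",
                          drop_constant=True)
        d = build_design(ds, spec2, truth.versatility)
        assert len(d.dropped_columns) >= 1
        assert d.X.shape[1] == 24 - len(d.dropped_columns)


def test_truncated_normal_respects_sign_constraints(rng):
    mean = rng.normal(0, 3, size=2000)
    positive = rng.random(2000) < 0.5
    draws = _sample_truncnorm(rng, mean, np.ones(2000), positive)
    assert np.all(draws[positive] > 0)
    assert np.all(draws[~positive] <= 0)
    # extreme means stay finite
    far = _sample_truncnorm(
        rng, np.full(10, -40.0), np.ones(10), np.ones(10, bool)
    )
    assert np.all(np.isfinite(far)) and np.all(far > 0)


def _random_design(rng, n, p):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta = rng.normal(0, 1, size=p)
    y = X @ beta + rng.standard_normal(n)
    return X, y


class TestSamplerOracles:
    def test_gaussian_matches_conjugate_closed_form(self, rng):
        """Known-variance gaussian posterior equals the normal closed form."""
        for trial in range(5):
            n = int(rng.integers(20, 51))
            p = int(rng.integers(1, 5))
            X, y = _random_design(rng, n, p)
            d = DesignData(
                y=y, X=X, x_names=[f"b{j}" for j in range(p)], Z=[],
                term_labels=[], term_levels=[], family="gaussian",
            )
            spec = ModelSpec(
                family="gaussian", fix_residual=1.0,
                mcmc=MCMCSettings(iterations=4000, burn_in=500, thin=4,
                                  seed=100 + trial),
            )
            chain = sample_posterior(d, spec)
            V = np.linalg.inv(X.T @ X + np.eye(p) / 1e10)
            mean = V @ X.T @ y
            S = chain.beta.shape[0]
            mcse = chain.beta.std(axis=0) / np.sqrt(S / 5)  # conservative ESS
            assert np.all(np.abs(chain.beta.mean(axis=0) - mean) < 3 * mcse)
            # posterior sd within 15% of the closed form
            np.testing.assert_allclose(
                chain.beta.std(axis=0), np.sqrt(np.diag(V)), rtol=0.15
            )

    def test_probit_intercept_symmetry(self):
        """Balanced 0/1 response centres the probit intercept at zero."""
        y = np.repeat([0.0, 1.0], 250)
        d = DesignData(
            y=y, X=np.ones((500, 1)), x_names=["intercept"], Z=[],
            term_labels=[], term_levels=[], family="probit",
        )
        spec = ModelSpec(
            family="probit", fix_residual=1.0,
            mcmc=MCMCSettings(iterations=4000, burn_in=500, thin=4, seed=7),
        )
        chain = sample_posterior(d, spec)
        mcse = chain.beta[:, 0].std() / np.sqrt(200)
        assert abs(chain.beta[:, 0].mean()) < max(3 * mcse, 0.02)

    def test_ztpoisson_intercept_recovers_rate(self):
        """exp(intercept mode) close to the simulated truncated-Poisson rate."""
        rng = np.random.default_rng(5)
        lam = 3.0
        y = rng.poisson(lam, size=4000)
        y = y[y > 0][:2000].astype(float)
        d = DesignData(
            y=y, X=np.ones((len(y), 1)), x_names=["intercept"], Z=[],
            term_labels=[], term_levels=[], family="zt_poisson",
        )
        spec = ModelSpec(
            family="zt_poisson",
            mcmc=MCMCSettings(iterations=8000, burn_in=2000, thin=10, seed=2),
        )
        chain = sample_posterior(d, spec)
        assert np.exp(kde_mode(chain.beta[:, 0])) == pytest.approx(lam, rel=0.1)
        assert 0.15 < chain.acceptance_rate < 0.55

    def test_seed_determinism(self, small_sim):
        ds, tree, ranks, truth = small_sim
        corr = phylo_correlation(tree, sorted(ds.drugs["taxon_name"].unique()))
        spec = ModelSpec(
            family="zt_poisson", fixed_effects="intensity_complexity",
            random_terms=default_random_terms(corr),
            mcmc=MCMCSettings(iterations=500, burn_in=100, thin=5, seed=9),
        )
        d = build_design(ds, spec, truth.versatility)
        c1 = sample_posterior(d, spec)
        c2 = sample_posterior(d, spec)
        np.testing.assert_array_equal(c1.beta, c2.beta)
        np.testing.assert_array_equal(c1.var_components, c2.var_components)
        np.testing.assert_array_equal(c1.var_resid, c2.var_resid)


class TestSummaries:
    def test_summary_shapes_and_ranges(self, small_sim):
        ds, tree, ranks, truth = small_sim
        corr = phylo_correlation(tree, sorted(ds.drugs["taxon_name"].unique()))
        spec = ModelSpec(
            family="zt_poisson", fixed_effects="intensity_complexity",
            random_terms=default_random_terms(corr),
            mcmc=MCMCSettings(iterations=1000, burn_in=200, thin=10, seed=3),
        )
        d = build_design(ds, spec, truth.versatility)
        summ = summarize(sample_posterior(d, spec), d)
        assert set(summ.coefficients["name"]) == {
            "intercept", "intensity", "complexity", "days"
        }
        assert ((summ.coefficients["px"] >= 0) & (summ.coefficients["px"] <= 1)).all()
        assert summ.h2_samples is not None
        assert 0.0 <= summ.h2_mode <= 1.0

    def test_separation_flag_on_empty_cell(self, vocab):
        # a predictor never non-zero among positive-response rows
        n = 40
        X = np.column_stack([np.ones(n), np.r_[np.zeros(20), np.ones(20)]])
        y = np.r_[np.ones(20), np.zeros(20)]
        d = DesignData(
            y=y, X=X, x_names=["intercept", "smoky"], Z=[],
            term_labels=[], term_levels=[], family="probit",
        )
        assert detect_separation(d) == ["smoky"]

    def test_constant_chain_summary(self):
        from phylotaste.pglmm import PosteriorChain

        chain = PosteriorChain(
            beta=np.full((20, 1), 2.5), beta_names=["b"],
            var_components=np.ones((20, 0)), term_labels=[],
            var_resid=np.ones(20), u_mean={}, acceptance_rate=None,
            seed=0, settings=MCMCSettings(iterations=100, burn_in=0, thin=5,
                                          seed=0),
            family="gaussian",
        )
        summ = summarize(chain)
        row = summ.coefficients.iloc[0]
        assert row["mean"] == row["mode"] == 2.5
        assert row["px"] == 0.0 and row["px_floor"] == pytest.approx(1 / 20)
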