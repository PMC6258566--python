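"""Response probabilities, lapse mixture, and dataset log likelihood."""

import numpy as np
import pandas as pd
import pytest

import psyconf as pc
from psyconf.likelihood import (LapseParams, PreparedTrials, apply_lapses,
                                core_response_probabilities,
                                dataset_log_likelihood, log_posterior,
                                response_probabilities)
from psyconf.params import PriorSpec, param_specs, subject_like_params


def random_trials(rng, n=20, tasks=("A", "B")):
    tids = rng.choice(list(tasks), size=n)
    rel = rng.integers(1, 7, size=n)
    return pd.DataFrame({
        "task": tids,
        "orientation_deg": rng.normal(0, 8, size=n),
        "reliability_level": rel,
        "reliability_value": np.asarray(pc.GABOR_CONTRASTS)[rel - 1],
        "response": rng.integers(1, 9, size=n),
        "chosen_category": rng.integers(1, 3, size=n),
    })


ALL_FAMILIES = ["bayes_ultrastrong", "bayes_strong", "bayes_weak",
                "bayes_weak_dn", "fixed", "lin", "quad",
                "orientation_estimation", "linear_neural",
                "precision_hybrid", "precision_hybrid_dn"]


class TestNormalization:
    @pytest.mark.parametrize("name", ALL_FAMILIES)
    def test_core_probabilities_partition_unity(self, name, rng):
        """Σ_r p(r|s,σ) = 1 for plausible parameter draws."""
        model = pc.get_model(name)
        trials = random_trials(rng, n=20)
        tol = 1e-6 if name in ("orientation_estimation",) else 1e-9
        for _ in range(8):
            pv = subject_like_params(model, rng)
            p = core_response_probabilities(model, pv, trials)
            assert p.shape == (20, 8)
            assert np.all(p >= 0)
            assert np.allclose(p.sum(axis=1), 1.0, atol=tol)

    @pytest.mark.parametrize("name", ["fixed", "quad", "bayes_weak",
                                      "precision_hybrid"])
    def test_partition_holds_across_the_prior_box(self, name, rng):
        """Normalization is structural, not parameter-dependent: random
        draws from the full prior box still sum to 1."""
        model = pc.get_model(name)
        priors = PriorSpec.for_model(model)
        trials = random_trials(rng, n=10)
        for _ in range(50):
            pv = pc.ParamVector(model, priors.sample(rng))
            p = core_response_probabilities(model, pv, trials)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_choice_only_two_vector(self, rng):
        model = pc.get_model("lin_choice")
        pv = subject_like_params(model, rng)
        p = core_response_probabilities(model, pv, random_trials(rng))
        assert p.shape == (20, 2)
        assert np.allclose(p.sum(axis=1), 1.0)


from hypothesis import given, settings
from hypothesis import strategies as st


class TestLapseProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(lam_f=st.floats(0, 0.3), lam_c=st.floats(0, 0.3),
           lam_r=st.floats(0, 0.3), lam1=st.floats(0, 1),
           lam4=st.floats(0, 1), prev=st.integers(0, 8),
           seed=st.integers(0, 10_000))
    def test_mixture_is_a_probability_vector(self, lam_f, lam_c, lam_r,
                                             lam1, lam4, prev, seed):
        """The lapse mixture maps probability vectors to probability
        vectors for every admissible lapse configuration."""
        core = np.random.default_rng(seed).dirichlet(np.ones(8))
        lp = LapseParams(lambda_full=lam_f, lambda_1=lam1, lambda_4=lam4,
                         lambda_conf=lam_c, lambda_repeat=lam_r)
        out = apply_lapses(core, lp, previous_response=prev)
        assert np.all(out >= -1e-15)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestLapses:
    def test_zero_lapses_identity(self, rng):
        core = rng.dirichlet(np.ones(8), size=5)
        out = apply_lapses(core, LapseParams())
        assert np.allclose(out, core)

    def test_repeat_lapse_degenerate(self):
        core = np.full(8, 0.125)
        out = apply_lapses(core, LapseParams(lambda_repeat=1.0),
                           previous_response=3)
        assert out[2] == pytest.approx(1.0)

    def test_full_lapse_uniform_endpoints(self, rng):
        """λ1 = λ4 = 0.25 gives a uniform full-lapse confidence
        distribution; checked against direct enumeration of the mix."""
        core = rng.dirichlet(np.ones(8))
        lp = LapseParams(lambda_full=0.1, lambda_1=0.25, lambda_4=0.25)
        out = apply_lapses(core, lp)
        expect = 0.9 * core + 0.1 * np.full(8, 0.5 * 0.25)
        assert np.allclose(out, expect)

    def test_interpolated_confidence_weights(self):
        lp = LapseParams(lambda_full=0.2, lambda_1=0.6, lambda_4=0.0)
        w = lp.confidence_weights()
        raw = np.array([0.6, 0.4, 0.2, 0.0])
        assert np.allclose(w, raw / raw.sum())

    def test_mixture_normalized_and_positive(self, rng):
        core = rng.dirichlet(np.ones(8), size=30)
        core[0, :4] = 0.0
        core[0] /= core[0].sum()
        lp = LapseParams(lambda_full=0.05, lambda_1=0.3, lambda_4=0.2,
                         lambda_conf=0.04, lambda_repeat=0.03)
        prev = rng.integers(0, 9, size=30)
        out = apply_lapses(core, lp, prev)
        assert np.allclose(out.sum(axis=1), 1.0)
        assert np.all(out > 0)  # full lapse floors every response

    def test_first_trial_repeat_mass_redistributed(self, rng):
        core = rng.dirichlet(np.ones(8))
        lp = LapseParams(lambda_full=0.1, lambda_repeat=0.2)
        out = apply_lapses(core, lp, previous_response=0)
        expect = (0.7 * core + 0.1 * lp.full_lapse_distribution()) / 0.8
        assert np.allclose(out, expect)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            LapseParams(lambda_full=0.5, lambda_conf=0.4, lambda_repeat=0.2)


class TestNesting:
    def test_fixed_lin_quad_equivalence(self, rng, make_params):
        """Fixed ≡ Lin(m=0) ≡ Quad(m=0) trial by trial."""
        model_f, pv_f = make_params("fixed", seed=4)
        ds = pc.generate_dataset([pc.task_a(), pc.task_b()],
                                 pc.SessionStructure(testing_blocks=(1, 30)),
                                 model_f, pv_f, seed=9)
        ll_f = dataset_log_likelihood(model_f, pv_f, ds)
        base = pv_f.natural_dict()
        for name in ("lin", "quad"):
            model = pc.get_model(name)
            vals = dict(base)
            for t in ("A", "B"):
                for j in range(1, 8):
                    vals[f"m{t}_{j}"] = 0.0
            pv = pc.ParamVector.from_dict(model, vals)
            ll = dataset_log_likelihood(model, pv, ds)
            assert abs(ll - ll_f) < 1e-12 * max(1.0, abs(ll_f))

    def test_ultrastrong_embeds_in_weak(self, rng, make_params):
        """Bayes_Ultrastrong parameters re-expressed in Bayes_Weak give an
        identical likelihood."""
        model_u, pv_u = make_params("bayes_ultrastrong", seed=2)
        ds = pc.generate_dataset([pc.task_a(), pc.task_b()],
                                 pc.SessionStructure(testing_blocks=(1, 30)),
                                 model_u, pv_u, seed=3)
        ll_u = dataset_log_likelihood(model_u, pv_u, ds)
        model_w = pc.get_model("bayes_weak")
        vals = {k: v for k, v in pv_u.natural_dict().items()
                if not k.startswith("k_")}
        k = [pv_u.get(f"k_{j}") for j in (1, 2, 3, 4)]
        for j in (1, 2, 3, 4):
            vals[f"kA_{j}"] = k[j - 1]
            vals[f"kB_{j}"] = k[j - 1]
        for j in (5, 6, 7):
            vals[f"kB_{j}"] = 2 * k[3] - k[7 - j]
        pv_w = pc.ParamVector.from_dict(model_w, vals)
        ll_w = dataset_log_likelihood(model_w, pv_w, ds)
        assert ll_w == pytest.approx(ll_u, abs=1e-10)


class TestDatasetLogLikelihood:
    def test_additivity_over_concatenation(self, make_params, rng):
        model, pv = make_params("quad", seed=1, lambda_repeat=0.0)
        t1 = random_trials(rng, 40)
        t2 = random_trials(rng, 25)
        both = pd.concat([t1, t2], ignore_index=True)
        ll = dataset_log_likelihood(model, pv, both)
        assert ll == pytest.approx(
            dataset_log_likelihood(model, pv, t1)
            + dataset_log_likelihood(model, pv, t2), abs=1e-9)

    def test_matches_independent_per_trial_product(self, make_params, rng):
        model, pv = make_params("lin", seed=3, lambda_repeat=0.0)
        trials = random_trials(rng, 100)
        total, pointwise = dataset_log_likelihood(model, pv, trials,
                                                  return_pointwise=True)
        single = [dataset_log_likelihood(model, pv, trials.iloc[[i]]
                                         .reset_index(drop=True))
                  for i in range(len(trials))]
        assert total == pytest.approx(sum(single), abs=1e-10)
        assert np.allclose(pointwise, single)

    def test_trial_order_invariance_without_repeat_lapse(self, make_params, rng):
        model, pv = make_params("fixed", seed=5, lambda_repeat=0.0)
        trials = random_trials(rng, 60)
        perm = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert dataset_log_likelihood(model, pv, trials) == pytest.approx(
            dataset_log_likelihood(model, pv, perm), abs=1e-9)

    def test_repeat_lapse_breaks_order_invariance(self, make_params, rng):
        model, pv = make_params("fixed", seed=5, lambda_repeat=0.25)
        trials = random_trials(rng, 60)
        perm = trials.iloc[::-1].reset_index(drop=True)
        assert dataset_log_likelihood(model, pv, trials) != pytest.approx(
            dataset_log_likelihood(model, pv, perm), abs=1e-6)

    def test_zero_probability_yields_minus_inf_with_diagnostic(self, rng):
        model = pc.get_model("fixed")
        pv = subject_like_params(model, rng)
        vals = pv.natural_dict()
        for j in range(1, 8):
            vals[f"kA_{j}"] = 0.0        # responses 2..7 impossible in Task A
        for lam in ("lambda_full", "lambda_conf", "lambda_repeat"):
            vals[lam] = 0.0
        pv = pc.ParamVector.from_dict(model, vals)
        trials = random_trials(rng, 10, tasks=("A",))
        trials.loc[0, "response"] = 4
        with pytest.warns(RuntimeWarning, match="zero response probability"):
            ll = dataset_log_likelihood(model, pv, trials)
        assert ll == -np.inf

    def test_scope_mismatch_rejected(self, rng):
        model = pc.get_model("quad_taska")
        pv = subject_like_params(model, rng)
        with pytest.raises(ValueError, match="fit scope"):
            dataset_log_likelihood(model, pv, random_trials(rng, 10))


class TestLogPosterior:
    def test_flat_prior_constant_offset(self, make_params, rng):
        model, pv = make_params("fixed", seed=7)
        priors = PriorSpec.for_model(model)
        trials = random_trials(rng, 30)
        pv2 = subject_like_params(model, rng)
        lp1 = log_posterior(model, pv.values, trials, priors)
        lp2 = log_posterior(model, pv2.values, trials, priors)
        ll1 = dataset_log_likelihood(model, pv, trials)
        ll2 = dataset_log_likelihood(model, pv2, trials)
        assert lp1 - lp2 == pytest.approx(ll1 - ll2, abs=1e-9)

    def test_outside_prior_box_minus_inf(self, make_params, rng):
        model, pv = make_params("fixed", seed=7)
        priors = PriorSpec.for_model(model)
        trials = random_trials(rng, 10)
        bad = pv.values.copy()
        bad[0] = priors.low[0] - 1.0
        assert log_posterior(model, bad, trials, priors) == -np.inf
        edge = np.clip(pv.values, priors.low, priors.high)
        assert np.isfinite(log_posterior(model, edge, trials, priors))

    def test_paramvector_validation_names_block(self, rng):
        model = pc.get_model("quad")
        pv = subject_like_params(model, rng)
        bad = pv.values.copy()
        idx = [i for i, p in enumerate(param_specs(model))
               if p.name == "lambda_full"][0]
        bad[idx] = 2.0
        with pytest.raises(ValueError, match="lapse"):
            pc.ParamVector(model, bad).validate()


class TestPreparedTrials:
    def test_prepared_matches_dataframe_path(self, make_params, rng):
        model, pv = make_params("quad", seed=2)
        trials = random_trials(rng, 50)
        prep = PreparedTrials(model, trials)
        a = response_probabilities(model, pv, trials)
        b = response_probabilities(model, pv, prep)
        assert np.array_equal(a, b)
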