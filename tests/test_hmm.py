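"""HMM core: initialisation, decoding vs an exhaustive oracle, EM, BH, I/O."""

import numpy as np
import pytest

import spanpeaks as sp
from spanpeaks.errors import ModelError
from spanpeaks.hmm import NOISE, SIGNAL, ZERO, _log_emission, sample_counts

from conftest import enumerate_posteriors, make_layout, random_model


def cov_from(counts: dict[str, list[int]], bin_size=200) -> sp.BinnedCoverage:
    layout = make_layout(*[(c, len(v) * bin_size) for c, v in counts.items()])
    return sp.BinnedCoverage(
        layout, bin_size, {c: np.asarray(v, dtype=np.int64) for c, v in counts.items()}
    )


class TestInitializeModel:
    def test_quantile_statistics_on_mixture(self, rng):
        # 50% zeros, 45% NB(mean 2), 5% NB(mean 40)
        n = 10_000
        kinds = rng.choice(3, size=n, p=[0.5, 0.45, 0.05])
        counts = np.zeros(n, dtype=np.int64)
        counts[kinds == 1] = rng.negative_binomial(2.0, 2.0 / 4.0, (kinds == 1).sum())
        counts[kinds == 2] = rng.negative_binomial(2.0, 2.0 / 42.0, (kinds == 2).sum())
        model = sp.initialize_model(cov_from({"chr1": counts.tolist()}))
        # direct computation of the stated quantile statistics
        positive = counts[counts > 0]
        med = np.median(positive)
        expected_noise = positive[positive <= med].mean()
        top = np.sort(counts)[-int(np.ceil(0.02 * n)):]
        expected_signal = max(top.mean(), 2 * expected_noise)
        assert model.noise.mean == pytest.approx(expected_noise)
        assert model.signal.mean == pytest.approx(expected_signal)
        assert model.signal.mean >= 2 * model.noise.mean

    def test_constant_counts_force_signal_floor(self):
        model = sp.initialize_model(cov_from({"chr1": [3] * 100}))
        assert model.noise.mean == pytest.approx(3.0)
        assert model.signal.mean == pytest.approx(6.0)  # forced >= 2x noise

    def test_all_zero_errors(self):
        with pytest.raises(ModelError, match="no signal"):
            sp.initialize_model(cov_from({"chr1": [0] * 50}))

    def test_deterministic_defaults(self):
        model = sp.initialize_model(cov_from({"chr1": [0, 1, 2, 5, 40]}))
        assert np.allclose(model.initial, 1 / 3)
        assert np.allclose(np.diag(model.transition), 0.8)
        assert model.transition.sum(axis=1) == pytest.approx([1, 1, 1])


class TestForwardBackward:
    def test_single_zero_bin_prefers_zero_state(self):
        cov = cov_from({"chr1": [0, 1]})
        model = sp.initialize_model(cov)
        post, _ = sp.forward_backward(model, np.array([0]))
        # one step: posterior ~ initial x emission; ZERO emits 0 with prob 1
        assert post[0, SIGNAL] < post[0, ZERO]
        assert post[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_positive_count_kills_zero_state(self, rng):
        model = random_model(rng)
        chain = np.array([0, 3, 0, 1, 7])
        post, _ = sp.forward_backward(model, chain)
        assert np.all(post[chain > 0, ZERO] == 0)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_exhaustive_path_oracle(self, rng):
        for _ in range(30):
            model = random_model(rng)
            T = int(rng.integers(1, 9))
            chain = rng.integers(0, 12, size=T)
            post, ll = sp.forward_backward(model, chain)
            ref_post, ref_ll = enumerate_posteriors(
                model.initial, model.transition, _log_emission(model, chain)
            )
            np.testing.assert_allclose(post, ref_post, atol=1e-10)
            assert ll == pytest.approx(ref_ll, abs=1e-8)

    def test_invalid_params_named(self):
        cov = cov_from({"chr1": [0, 1, 2]})
        model = sp.initialize_model(cov)
        model.signal.mean = float("nan")
        with pytest.raises(ModelError, match="SIGNAL"):
            sp.forward_backward(model, np.array([0, 1, 2]))


class TestBaumWelch:
    def test_recovers_generating_parameters(self):
        truth = sp.SpanModel(
            bin_size=200,
            fragment_size=0,
            initial=np.array([0.4, 0.4, 0.2]),
            transition=np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]]),
            noise=sp.NegBinParams(2.0, 1.5),
            signal=sp.NegBinParams(20.0, 3.0),
        )
        chains = sample_counts(truth, [10_000] * 10, seed=5)
        cov = cov_from({k: v.tolist() for k, v in chains.items()})
        fitted = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=50)
        assert abs(fitted.noise.mean - truth.noise.mean) / truth.noise.mean < 0.15
        assert abs(fitted.signal.mean - truth.signal.mean) / truth.signal.mean < 0.15
        assert np.all(np.abs(np.diag(fitted.transition) - np.diag(truth.transition)) < 0.1)

    def test_single_iteration_contract(self):
        cov = cov_from({"chr1": [0, 1, 0, 4, 9, 0, 2, 30, 28, 0]})
        fitted = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=1)
        assert len(fitted.fit_log) == 2  # init + one EM step

    def test_refit_is_a_fixed_point(self):
        cov = cov_from({"chr1": [0, 1, 0, 4, 9, 0, 2, 30, 28, 0, 1, 1]})
        fitted = sp.baum_welch_fit(sp.initialize_model(cov), cov)
        refit = sp.baum_welch_fit(fitted, cov)
        assert len(refit.fit_log) <= 2
        assert abs(refit.fit_log[-1] - refit.fit_log[0]) <= 1e-6 * abs(refit.fit_log[0])

    def test_monotone_loglik_on_random_data(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 25, size=int(rng.integers(20, 200)))
            if not counts.any():
                counts[0] = 1
            cov = cov_from({"chr1": counts.tolist()})
            fitted = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=15)
            diffs = np.diff(fitted.fit_log)
            assert np.all(diffs >= -1e-6 * np.abs(np.array(fitted.fit_log)[:-1]))

    def test_label_swap_identifiability(self):
        cov = cov_from(
            {"chr1": [0, 1, 2, 0, 1, 25, 30, 22, 0, 1, 2, 1, 28, 31, 0, 2]}
        )
        init = sp.initialize_model(cov)
        swapped = init.copy()
        # exchange the state means and dispersions; fitting must restore ordering
        swapped.noise, swapped.signal = (
            sp.NegBinParams(init.signal.mean, init.signal.dispersion),
            sp.NegBinParams(init.noise.mean, init.noise.dispersion),
        )
        a = sp.baum_welch_fit(init, cov)
        b = sp.baum_welch_fit(swapped, cov)
        assert b.noise.mean < b.signal.mean
        assert b.noise.mean == pytest.approx(a.noise.mean, rel=0.05)
        assert b.signal.mean == pytest.approx(a.signal.mean, rel=0.05)

    def test_shared_parameters_across_chains(self):
        cov = cov_from({"chr1": [0, 5, 9, 0], "chr2": [1, 0, 22, 25]})
        fitted = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=5)
        assert fitted.noise.mean < fitted.signal.mean

    def test_bad_arguments_rejected(self):
        cov = cov_from({"chr1": [0, 1]})
        model = sp.initialize_model(cov)
        with pytest.raises(ValueError, match="max_iter"):
            sp.baum_welch_fit(model, cov, max_iter=0)
        with pytest.raises(ValueError, match="tol"):
            sp.baum_welch_fit(model, cov, tol=0)
        empty = sp.BinnedCoverage(make_layout(), 200, {})
        with pytest.raises(ModelError, match="empty"):
            sp.baum_welch_fit(model, empty)


class TestScores:
    def test_pvalue_is_posterior_error_probability(self):
        cov = cov_from({"chr1": [0, 1, 0, 9, 12, 0, 2, 1]})
        model = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=10)
        scores = sp.compute_scores(model, cov)
        post = scores.posterior["chr1"]
        np.testing.assert_allclose(
            scores.pvalue["chr1"], post[:, ZERO] + post[:, NOISE], atol=1e-12
        )
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_qvalues_adjusted_genome_wide(self):
        cov = cov_from({"chr1": [0, 1, 0, 9], "chr2": [12, 0, 2, 1]})
        model = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=10)
        scores = sp.compute_scores(model, cov)
        flat_p = np.concatenate([scores.pvalue[c] for c in ("chr1", "chr2")])
        flat_q = np.concatenate([scores.qvalue[c] for c in ("chr1", "chr2")])
        np.testing.assert_allclose(flat_q, sp.bh_adjust(flat_p), atol=1e-12)

    def test_unfitted_model_rejected(self):
        cov = cov_from({"chr1": [0, 1, 2]})
        with pytest.raises(ModelError, match="fitted"):
            sp.compute_scores(sp.initialize_model(cov), cov)

    def test_thread_count_does_not_change_scores(self):
        cov = cov_from({"chr1": [0, 1, 0, 9] * 20, "chr2": [12, 0, 2, 1] * 20})
        model = sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=10)
        s1 = sp.compute_scores(model, cov, threads=1)
        s2 = sp.compute_scores(model, cov, threads=3)
        for c in ("chr1", "chr2"):
            np.testing.assert_array_equal(s1.qvalue[c], s2.qvalue[c])


class TestBHAdjust:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            sp.bh_adjust(np.array([0.01, 0.02, 0.04])), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_equal_pvalues_invariant(self):
        np.testing.assert_allclose(sp.bh_adjust(np.array([0.05] * 4)), [0.05] * 4)

    def test_empty(self):
        assert sp.bh_adjust(np.array([])).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sp.bh_adjust(np.array([0.5, 1.5]))

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(sp.bh_adjust(p)[perm], sp.bh_adjust(p[perm]), atol=1e-12)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(sp.bh_adjust(p), ref, atol=1e-12)

    def test_monotone_when_sorted_by_pvalue(self, rng):
        p = rng.uniform(size=200)
        q = sp.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestSerialization:
    def fitted(self):
        cov = cov_from({"chr1": [0, 1, 0, 9, 12, 0, 2, 1]})
        return sp.baum_welch_fit(sp.initialize_model(cov), cov, max_iter=5), cov

    def test_round_trip(self, tmp_path):
        model, _ = self.fitted()
        path = tmp_path / "m.span"
        sp.save_model(model, path)
        back = sp.load_model(path)
        assert back.bin_size == model.bin_size
        assert back.fragment_size == model.fragment_size
        np.testing.assert_allclose(back.initial, model.initial, atol=1e-12)
        np.testing.assert_allclose(back.transition, model.transition, atol=1e-12)
        assert back.noise.mean == pytest.approx(model.noise.mean, abs=1e-12)
        assert back.signal.dispersion == pytest.approx(model.signal.dispersion, abs=1e-12)
        assert back.fit_log == pytest.approx(model.fit_log, abs=1e-12)

    def test_rescore_after_load_identical(self, tmp_path):
        model, cov = self.fitted()
        path = tmp_path / "m.span"
        sp.save_model(model, path)
        s1 = sp.compute_scores(model, cov)
        s2 = sp.compute_scores(sp.load_model(path), cov)
        np.testing.assert_array_equal(s1.qvalue["chr1"], s2.qvalue["chr1"])

    def test_wrong_magic_or_version(self, tmp_path):
        bad = tmp_path / "bad.span"
        bad.write_text('{"format": "something.else", "version": 1}')
        with pytest.raises(ModelError, match="spanpeaks.model"):
            sp.load_model(bad)
        bad.write_text('{"format": "spanpeaks.model", "version": 99}')
        with pytest.raises(ModelError, match="version 99"):
            sp.load_model(bad)
        bad.write_text("not json at all{")
        with pytest.raises(ModelError, match="corrupt"):
            sp.load_model(bad)
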