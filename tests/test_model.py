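"""Core model: genotype spaces, likelihood, posterior, EM, classification."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnsnv import (
    AllelicCount,
    CNAState,
    EMConfig,
    ModelParams,
    classify,
    classify_positions,
    default_hyperparams,
    diploid_baseline,
    fit_em,
    force_state,
    genotype_posterior,
    genotype_space,
    log_likelihood,
    p_snv,
    SimConfig,
    simulate_dataset,
)


def exact_binom_pmf(a: int, n: int, mu: float) -> Fraction:
    """Exact-arithmetic Binomial pmf (independent oracle)."""
    p = Fraction(mu)
    return math.comb(n, a) * p**a * (1 - p) ** (n - a)


def exact_posterior(a, n, mu, pi):
    """Bayes' rule by direct summation in exact arithmetic."""
    weights = [Fraction(p) * exact_binom_pmf(a, n, m) for p, m in zip(pi, mu)]
    total = sum(weights)
    return [w / total for w in weights]


class TestGenotypeSpace:
    @pytest.mark.parametrize(
        "state, genotypes, ref_counts",
        [
            (CNAState.NEUT_LOSS, ("aa", "ab", "bb"), (2, 1, 0)),
            (CNAState.GAIN, ("aaa", "aab", "abb", "bbb"), (3, 2, 1, 0)),
            (
                CNAState.HLAMP,
                ("aaaaa", "aaaab", "aaabb", "aabbb", "abbbb", "bbbbb"),
                (5, 4, 3, 2, 1, 0),
            ),
        ],
    )
    def test_enumeration(self, state, genotypes, ref_counts):
        space = genotype_space(state)
        assert space.genotypes == genotypes
        assert space.ref_counts == ref_counts
        assert len(space) == state.ploidy + 1

    def test_unknown_code_rejected_with_name(self):
        with pytest.raises(ValueError, match="7"):
            CNAState.from_code(7)

    def test_loss_is_not_a_distinct_state(self):
        assert CNAState.from_code(2) is CNAState.NEUT_LOSS
        assert [int(s) for s in CNAState] == [2, 3, 4, 5]


class TestLikelihood:
    def test_simple_values(self):
        assert log_likelihood(1, 2, 0.5) == pytest.approx(math.log(0.5))
        assert log_likelihood(0, 0, 0.5) == 0.0

    def test_matches_exact_oracle_at_deep_position(self):
        # depth/ref-count of a validated deep amplicon position
        expected = math.log(float(exact_binom_pmf(10, 85, 0.8)))
        assert log_likelihood(10, 85, 0.8) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mu", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_mu_outside_open_interval(self, mu):
        with pytest.raises(ValueError):
            log_likelihood(1, 2, mu)

    def test_rejects_count_above_depth(self):
        with pytest.raises(ValueError):
            log_likelihood(5, 3, 0.5)


class TestPosterior:
    def test_uniform_when_components_identical(self):
        params = ModelParams(
            mu={s: np.full(s.ploidy + 1, 0.5) for s in CNAState},
            pi={s: np.full(s.ploidy + 1, 1 / (s.ploidy + 1)) for s in CNAState},
        )
        count = AllelicCount("1", 10, 7, 12, CNAState.GAIN)
        post = genotype_posterior(count, params)
        assert post == pytest.approx(np.full(4, 0.25), abs=1e-12)

    def test_likelihood_domination_with_all_reference_reads(self):
        params = ModelParams(
            mu={CNAState.NEUT_LOSS: np.array([0.99, 0.5, 0.01])},
            pi={CNAState.NEUT_LOSS: np.full(3, 1 / 3)},
        )
        for depth, bound in [(50, 0.99), (500, 0.999999)]:
            count = AllelicCount("1", 1, depth, depth)
            post = genotype_posterior(count, params)
            assert post[0] > bound

    def test_concentrates_on_matching_allele_fraction_at_high_depth(self, hyper):
        # as depth grows with a/N fixed at r/c, the genotype with reference
        # fraction r/c wins regardless of the skewed prior
        params = ModelParams.from_prior(hyper)
        state = CNAState.HLAMP
        n = 10_000
        for k, r in enumerate(genotype_space(state).ref_counts):
            a = round(n * r / state.ploidy)
            post = genotype_posterior(AllelicCount("1", 1, a, n, state), params)
            assert int(np.argmax(post)) == k
            assert post[k] > 0.999

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=2, max_value=5),
        st.randoms(use_true_random=False),
    )
    def test_matches_exact_bayes_oracle(self, depth, code, rnd):
        a = rnd.randint(0, depth)
        state = CNAState(code)
        k = state.ploidy + 1
        mu = np.sort(np.array([rnd.uniform(0.01, 0.99) for _ in range(k)]))[::-1]
        mu += np.arange(k)[::-1] * 1e-6  # ensure strictly decreasing
        raw = np.array([rnd.uniform(0.05, 1.0) for _ in range(k)])
        pi = raw / raw.sum()
        params = ModelParams(mu={state: mu}, pi={state: pi})
        post = genotype_posterior(AllelicCount("1", 1, a, depth, state), params)
        oracle = exact_posterior(a, depth, mu, pi)
        for got, want in zip(post, oracle):
            assert abs(got - float(want)) <= 1e-10 * float(want)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)


class TestPSnv:
    @pytest.mark.parametrize(
        "posterior, state, expected",
        [
            ([1, 0, 0], CNAState.NEUT_LOSS, 0.0),
            ([0.3, 0.5, 0.2], CNAState.NEUT_LOSS, 0.7),
            ([0.2, 0.2, 0.2, 0.2, 0.1, 0.1], CNAState.HLAMP, 0.8),
        ],
    )
    def test_sums_variant_genotypes(self, posterior, state, expected):
        assert p_snv(np.array(posterior), genotype_space(state)) == pytest.approx(
            expected
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p_snv(np.array([0.5, 0.5]), genotype_space(CNAState.HLAMP))


class TestDefaultHyperparams:
    def test_beta_means(self, hyper):
        neut = hyper.mu_means(CNAState.NEUT_LOSS)
        assert neut == pytest.approx([0.99, 0.5, 0.01])
        hlamp = hyper.mu_means(CNAState.HLAMP)
        assert hlamp[1] == pytest.approx(0.99 * 0.8 + 0.01 * 0.2)  # 0.794

    def test_dirichlet_favours_non_variant(self, hyper):
        for state in CNAState:
            d = np.asarray(hyper.delta[state])
            assert d[0] == 1000.0
            assert np.all(d[1:] == 2.0)
            pi = hyper.pi_means(state)
            assert pi[0] > 0.99

    def test_all_strictly_positive_and_lengths_match(self, hyper):
        for state in CNAState:
            k = state.ploidy + 1
            for block in (hyper.delta, hyper.alpha, hyper.beta):
                vec = np.asarray(block[state])
                assert vec.shape == (k,)
                assert np.all(vec > 0)


class TestEM:
    def test_single_position_matches_closed_form_conjugate_update(self, hyper):
        """One M-step on one observation equals the hand-computed MAP update."""
        state = CNAState.NEUT_LOSS
        a, n = 12, 30
        counts = pd.DataFrame(
            {"chrom": ["1"], "pos": [1], "ref_count": [a], "depth": [n],
             "state_code": [int(state)]}
        )
        params, report = fit_em(counts, hyper, EMConfig(max_iter=1))

        mu0 = [Fraction(m) for m in hyper.mu_means(state)]
        pi0 = [Fraction(p) for p in hyper.pi_means(state)]
        weights = [
            p * math.comb(n, a) * m**a * (1 - m) ** (n - a)
            for p, m in zip(pi0, mu0)
        ]
        total = sum(weights)
        resp = [w / total for w in weights]
        delta = [Fraction(d) for d in np.asarray(hyper.delta[state], float)]
        alpha = [Fraction(x) for x in np.asarray(hyper.alpha[state], float)]
        beta = [Fraction(x) for x in np.asarray(hyper.beta[state], float)]
        pi_num = [r + d - 1 for r, d in zip(resp, delta)]
        pi_expected = [x / sum(pi_num) for x in pi_num]
        mu_expected = [
            (r * a + al - 1) / (r * n + al + be - 2)
            for r, al, be in zip(resp, alpha, beta)
        ]
        # the model keeps mu inside [1e-6, 1 - 1e-6]
        lo, hi = Fraction(1, 10**6), 1 - Fraction(1, 10**6)
        mu_expected = [min(max(m, lo), hi) for m in mu_expected]
        assert params.pi[state] == pytest.approx(
            [float(x) for x in pi_expected], rel=1e-12
        )
        assert params.mu[state] == pytest.approx(
            [float(x) for x in mu_expected], rel=1e-12
        )
        assert report.states[state].iterations == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_log_posterior_trace_non_decreasing(self, hyper, seed):
        counts, _ = simulate_dataset(SimConfig(n_per_state=300, seed=seed))
        _, report = fit_em(counts, hyper)
        for state, fit in report.states.items():
            trace = np.asarray(fit.log_posterior_trace)
            assert trace.size >= 2
            assert np.all(np.diff(trace) >= -1e-8), f"trace decreased in {state.name}"

    def test_absent_state_keeps_prior_means_and_is_flagged(self, hyper):
        counts, _ = simulate_dataset(SimConfig(n_per_state=100, seed=3))
        counts = counts[counts["state_code"] != int(CNAState.HLAMP)]
        params, report = fit_em(counts, hyper)
        assert not report.states[CNAState.HLAMP].fitted
        assert params.mu[CNAState.HLAMP] == pytest.approx(
            hyper.mu_means(CNAState.HLAMP)
        )
        assert params.pi[CNAState.HLAMP] == pytest.approx(
            hyper.pi_means(CNAState.HLAMP)
        )

    def test_all_reference_data_leaves_variant_weights_at_prior_only_value(
        self, hyper
    ):
        """With only homozygous-reference positions the responsibility sums for
        variant genotypes vanish and the pi update reduces to its prior term."""
        n_pos = 200
        counts = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, n_pos + 1),
                "ref_count": 50,
                "depth": 50,
                "state_code": int(CNAState.NEUT_LOSS),
            }
        )
        params, _ = fit_em(counts, hyper)
        delta = np.asarray(hyper.delta[CNAState.NEUT_LOSS], float)
        k = delta.size
        prior_only = (delta[1:] - 1.0) / (n_pos + delta.sum() - k)
        assert params.pi[CNAState.NEUT_LOSS][1:] == pytest.approx(
            prior_only, rel=1e-6
        )

    def test_parameter_recovery_from_known_parameters(self, hyper):
        """Data simulated at the prior means is recovered closely by MAP-EM."""
        counts, _ = simulate_dataset(SimConfig(n_per_state=1000, seed=21))
        params, _ = fit_em(counts, hyper)
        for state in CNAState:
            tv = 0.5 * np.abs(params.pi[state] - hyper.pi_means(state)).sum()
            assert tv < 0.05
            # the all-reference component carries ~99% of the data
            assert abs(params.mu[state][0] - hyper.mu_means(state)[0]) < 0.02


class TestClassify:
    def test_threshold_is_inclusive(self, training_params):
        count = AllelicCount("1", 5, 20, 30, CNAState.GAIN)
        call = classify(count, training_params, threshold=0.5)
        exact = call.p_snv
        assert classify(count, training_params, threshold=exact).passed
        above = np.nextafter(exact, 1.0)
        assert not classify(count, training_params, threshold=above).passed

    def test_zero_depth_is_nocall_with_prior_posterior(self, training_params):
        count = AllelicCount("1", 5, 0, 0, CNAState.AMP)
        call = classify(count, training_params)
        assert call.nocall and not call.passed
        expected = training_params.pi[CNAState.AMP]
        assert call.posterior == pytest.approx(expected / expected.sum())

    def test_reference_skewed_variant_called_in_hlamp_but_not_diploid(
        self, training_params
    ):
        """A deep position with 75/85 reference reads (non-reference fraction
        ~0.12) is a confident aaaab/aaabb call under the five-copy state space
        but invisible to the diploid model, whose nearest genotype aa absorbs
        it as sequencing noise."""
        hl = classify(
            AllelicCount("1", 181813423, 75, 85, CNAState.HLAMP), training_params
        )
        assert hl.map_genotype in ("aaaab", "aaabb")
        assert hl.p_snv > 0.77
        dip = classify(
            AllelicCount("1", 181813423, 75, 85, CNAState.NEUT_LOSS), training_params
        )
        assert dip.p_snv < 0.77

    def test_posteriors_normalized_across_call_table(self, small_dataset, fitted):
        counts, _ = small_dataset
        params, _ = fitted
        calls = classify_positions(counts, params)
        sums = np.array([p.sum() for p in calls["posterior"]])
        assert np.all(np.abs(sums - 1.0) < 1e-9)
        assert np.all((calls["p_snv"] >= 0) & (calls["p_snv"] <= 1))

    def test_map_ties_break_toward_reference_rich_genotype(self):
        # identical components make every genotype exactly equiprobable;
        # the reported MAP genotype must be the most reference-rich one
        state = CNAState.NEUT_LOSS
        tied = ModelParams(
            mu={state: np.full(3, 0.5)}, pi={state: np.full(3, 1 / 3)}
        )
        call = classify(AllelicCount("1", 1, 5, 10, state), tied)
        assert call.posterior == pytest.approx(np.full(3, 1 / 3), abs=1e-12)
        assert call.map_genotype == "aa"


class TestDiploidBaseline:
    def test_bit_identical_to_full_model_when_everything_is_neutral(
        self, small_dataset, hyper
    ):
        counts, _ = small_dataset
        forced = force_state(counts, CNAState.NEUT_LOSS)
        params, _ = fit_em(forced, hyper)
        full = classify_positions(forced, params)
        base, base_params, _ = diploid_baseline(counts, hyper)
        for state in CNAState:
            assert np.array_equal(params.mu[state], base_params.mu[state])
            assert np.array_equal(params.pi[state], base_params.pi[state])
        assert np.array_equal(full["p_snv"].to_numpy(), base["p_snv"].to_numpy())
        for a, b in zip(full["posterior"], base["posterior"]):
            assert np.array_equal(a, b)
        assert full["map_genotype"].tolist() == base["map_genotype"].tolist()

    def test_empty_input_gives_empty_output(self, hyper):
        empty = pd.DataFrame(
            columns=["chrom", "pos", "ref_count", "depth", "state_code"]
        ).astype({"pos": int, "ref_count": int, "depth": int, "state_code": int})
        calls, _, report = diploid_baseline(empty, hyper)
        assert len(calls) == 0
        assert not any(fit.fitted for fit in report.states.values())


class TestParamsSerialization:
    def test_roundtrip_is_exact(self, tmp_path, fitted):
        params, _ = fitted
        path = tmp_path / "params.tsv"
        params.to_file(path)
        loaded = ModelParams.from_file(path)
        for state in CNAState:
            assert np.array_equal(params.mu[state], loaded.mu[state])
            assert np.array_equal(params.pi[state], loaded.pi[state])

    def test_missing_genotype_rejected(self, tmp_path, fitted):
        params, _ = fitted
        path = tmp_path / "params.tsv"
        params.to_file(path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="missing"):
            ModelParams.from_file(path)


class TestAllelicCountValidation:
    def test_rejects_count_exceeding_depth(self):
        with pytest.raises(ValueError):
            AllelicCount("1", 100, 5, 3)

    def test_rejects_non_positive_position(self):
        with pytest.raises(ValueError):
            AllelicCount("1", 0, 1, 2)
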