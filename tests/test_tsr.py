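import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from littrends import GenerativeSpec, generate
from littrends.lda import TopicModel
from littrends.preprocess import Tokenized, preprocess
from littrends.synthetic import truth_model
from littrends.tsr import (CRITERIA, METRICS, TsrWeights, benchmarks, combine,
                           distance, intra_criterion, rank_topics,
                           raw_distances, score_raw_table, standardize_range,
                           standardize_total, temporal_tsr)


def spreadsheet_tsr(raw, psi_u=0.5, psi_v=0.5, Psi=(1 / 3, 1 / 3, 1 / 3)):
    """Independent brute-force evaluation of the standardization/combination
    chain, written cell-by-cell the way a spreadsheet would lay it out."""
    K = len(raw)
    out = {"S1": [[0.0] * 3 for _ in range(K)],
           "S2": [[0.0] * 3 for _ in range(K)]}
    for ci in range(3):
        for mi in range(3):
            col = [raw[k][mi][ci] for k in range(K)]
            T = sum(col)
            std1 = [c * (T - c) / T if T > 0 else 0.0 for c in col]
            lo, hi = min(col), max(col)
            std2 = ([(c - lo) / (hi - lo) for c in col]
                    if hi - lo >= 1e-12 else [0.5] * K)
            for k in range(K):
                out["S1"][k][ci] += std1[k] / 3.0
                out["S2"][k][ci] += std2[k] / 3.0
    s_hat = [out["S1"][k][2] * (psi_u * out["S1"][k][0]
                                + psi_v * out["S1"][k][1]) for k in range(K)]
    psi_hat = [Psi[0] * out["S2"][k][0] + Psi[1] * out["S2"][k][1]
               + Psi[2] * out["S2"][k][2] for k in range(K)]
    tsr = [psi_hat[k] * s_hat[k] for k in range(K)]
    return s_hat, psi_hat, tsr


class TestDistance:
    def test_self_distance_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        for m in METRICS:
            assert distance(p, p, m) == pytest.approx(0.0, abs=1e-9)

    def test_kl_hand_value(self):
        p, q = np.array([0.5, 0.5]), np.array([0.75, 0.25])
        # 0.5 ln(0.5/0.75) + 0.5 ln(0.5/0.25) = 0.5 ln(4/3)
        assert distance(p, q, "KL") == pytest.approx(0.143841, abs=1e-6)

    def test_orthogonal_extremes(self):
        p, q = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert distance(p, q, "COS") == pytest.approx(1.0)
        assert distance(p, q, "COR") == pytest.approx(2.0)

    def test_constant_vector_cor_policy(self):
        unif = np.array([0.25] * 4)
        p = np.array([0.7, 0.1, 0.1, 0.1])
        assert distance(p, unif, "COR") == 1.0
        assert distance(unif, unif, "COR") == 1.0

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            distance(np.array([1.0]), np.array([0.5, 0.5]), "KL")
        with pytest.raises(ValueError, match="negative"):
            distance(np.array([-0.5, 1.5]), np.array([0.5, 0.5]), "COS")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_nonnegative_on_random_distributions(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6))
        q = rng.dirichlet(np.ones(6))
        for m in METRICS:
            assert distance(p, q, m) >= 0.0


class TestStandardize:
    @pytest.mark.parametrize("scores,expected", [
        ([1.0, 1.0], [0.5, 0.5]),          # 1*(2-1)/2
        ([3.0, 1.0], [0.75, 0.75]),        # 3*(4-3)/4 and 1*(4-1)/4
        ([5.0], [0.0]),                    # single topic: empty j!=k sum
    ])
    def test_total_printed_mode(self, scores, expected):
        assert standardize_total(np.array(scores)) == pytest.approx(expected)

    def test_total_share_mode(self):
        assert standardize_total(np.array([3.0, 1.0]),
                                 mode="share") == pytest.approx([0.75, 0.25])

    def test_total_all_zero_warns_and_zeroes(self, caplog):
        out = standardize_total(np.zeros(3))
        assert np.array_equal(out, np.zeros(3))

    def test_range_hand_values(self):
        assert standardize_range(np.array([2.0, 4.0, 6.0])) == pytest.approx(
            [0.0, 0.5, 1.0])
        assert standardize_range(np.array([3.0, 3.0])) == pytest.approx(
            [0.5, 0.5])

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_range_bounded(self, scores):
        out = standardize_range(np.array(scores))
        assert (out >= 0.0).all() and (out <= 1.0).all()


class TestIntraCriterion:
    def test_mean_of_metrics(self):
        scores = {"KL": np.array([0.0]), "COR": np.array([0.5]),
                  "COS": np.array([1.0])}
        assert intra_criterion(scores) == pytest.approx([0.5])

    def test_missing_metric_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            intra_criterion({"KL": np.zeros(2), "COR": np.zeros(2)})

    def test_linear_in_inputs(self):
        rng = np.random.default_rng(0)
        scores = {m: rng.random(4) for m in METRICS}
        scaled = {m: 3.0 * v for m, v in scores.items()}
        assert intra_criterion(scaled) == pytest.approx(
            3.0 * intra_criterion(scores))


class TestCombine:
    def test_symbolic_constant_scores(self):
        s, t = 0.6, 0.3
        S1 = np.full((4, 3), s)
        S2 = np.full((4, 3), t)
        s_hat, psi_hat, tsr_vals = combine(S1, S2)
        assert s_hat == pytest.approx([s * s] * 4)
        assert psi_hat == pytest.approx([t] * 4)
        assert tsr_vals == pytest.approx([t * s * s] * 4)

    def test_zero_background_kills_s_hat(self):
        S1 = np.array([[0.9, 0.8, 0.0]])
        S2 = np.full((1, 3), 0.5)
        s_hat, _, tsr_vals = combine(S1, S2)
        assert s_hat[0] == 0.0 and tsr_vals[0] == 0.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            TsrWeights(psi_u=0.7, psi_v=0.5)
        with pytest.raises(ValueError):
            TsrWeights(Psi_u=0.5, Psi_v=0.5, Psi_b=0.5)
        with pytest.raises(ValueError):
            TsrWeights(psi_u=-0.2, psi_v=1.2)


class TestChainOracle:
    def test_matches_spreadsheet_on_fixed_table(self):
        # hand-fixed 3-topic raw distance table (topic x metric x criterion)
        raw = np.array([
            [[1.2, 0.4, 2.0], [0.9, 1.1, 0.3], [0.5, 0.6, 0.7]],
            [[0.1, 1.4, 1.0], [1.9, 0.2, 0.8], [1.5, 0.6, 0.9]],
            [[2.2, 0.9, 0.0], [0.4, 1.2, 1.1], [0.5, 1.6, 0.3]],
        ])
        table = score_raw_table(raw)
        s_hat, psi_hat, tsr_vals = spreadsheet_tsr(raw.tolist())
        assert table.S_hat == pytest.approx(s_hat, abs=1e-9)
        assert table.psi_hat == pytest.approx(psi_hat, abs=1e-9)
        assert table.tsr == pytest.approx(tsr_vals, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_spreadsheet_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random((3, 3, 3)) * 3.0
        table = score_raw_table(raw)
        s_hat, psi_hat, tsr_vals = spreadsheet_tsr(raw.tolist())
        assert table.tsr == pytest.approx(tsr_vals, abs=1e-9)

    def test_rank_is_permutation_ordered_by_tsr(self):
        rng = np.random.default_rng(7)
        raw = rng.random((5, 3, 3))
        table = score_raw_table(raw)
        assert sorted(table.rank) == [1, 2, 3, 4, 5]
        order = np.argsort(table.rank)
        assert (np.diff(table.tsr[order]) <= 1e-15).all()


def _toy_model_and_corpus():
    doc_tokens = [np.array([0, 0, 1]), np.array([1, 2, 2, 2]),
                  np.array([3, 3, 0])]
    tok = Tokenized(doc_tokens=doc_tokens, vocab=list("abcd"),
                    doc_ids=["1", "2", "3"], years=[2014, 2016, 2020])
    rng = np.random.default_rng(0)
    phi = rng.dirichlet(np.ones(4), size=2)
    theta = rng.dirichlet(np.ones(2), size=3)
    model = TopicModel(K=2, alpha=0.1, beta=0.1, phi=phi, theta=theta, z=[],
                       n_kw=np.zeros((2, 4)), n_jk=np.zeros((3, 2)),
                       loglik_trace=np.zeros(1), z_marginal=np.zeros((1, 2)),
                       seed=0)
    return model, tok


class TestBenchmarks:
    def test_uniform_and_background(self):
        model, tok = _toy_model_and_corpus()
        b = benchmarks(model, tok)
        assert np.allclose(b["U"].dist, 0.25)
        assert np.allclose(b["B"].dist, 1.0 / 3)

    def test_vacuous_matches_hand_counts(self):
        model, tok = _toy_model_and_corpus()
        # token counts: a=3, b=2, c=3, d=2 over 10 tokens
        b = benchmarks(model, tok)
        assert b["V"].dist == pytest.approx([0.3, 0.2, 0.3, 0.2])

    def test_point_mass_for_single_word_corpus(self):
        tok = Tokenized(doc_tokens=[np.array([0, 0, 0])], vocab=["w"],
                        doc_ids=["1"], years=[2015])
        model = TopicModel(K=1, alpha=1, beta=1, phi=np.array([[1.0]]),
                           theta=np.array([[1.0]]), z=[],
                           n_kw=np.zeros((1, 1)), n_jk=np.zeros((1, 1)),
                           loglik_trace=np.zeros(1),
                           z_marginal=np.zeros((1, 1)), seed=0)
        assert benchmarks(model, tok)["V"].dist == pytest.approx([1.0])


class TestRankTopics:
    def test_uniform_topic_has_zero_self_distances(self):
        model, tok = _toy_model_and_corpus()
        model.phi = np.vstack([np.full(4, 0.25), model.phi[1]])
        raw = raw_distances(model, tok)
        assert raw[0, 0, 0] == pytest.approx(0.0, abs=1e-9)   # KL to U
        assert raw[0, 2, 0] == pytest.approx(0.0, abs=1e-9)   # COS to U
        assert raw[0, 1, 0] == 1.0                            # COR policy

    def test_topic_permutation_equivariance(self):
        spec = GenerativeSpec(K_true=4, V=80, M=60, seed=3,
                              junk_plants=("uniform",))
        corpus, truth = generate(spec)
        tok = preprocess(corpus, min_df=1, max_df_frac=1.0, phrases=False)
        model = truth_model(truth, tok)
        t1 = rank_topics(model, tok)
        perm = np.array([2, 0, 3, 1])
        model2 = truth_model(truth, tok)
        model2.phi = model2.phi[perm]
        model2.theta = model2.theta[:, perm]
        t2 = rank_topics(model2, tok)
        assert t2.tsr == pytest.approx(t1.tsr[perm], abs=1e-12)
        assert sorted(t1.rank) == sorted(t2.rank)

    def test_planted_junk_ranks_bottom(self):
        spec = GenerativeSpec(K_true=6, V=240, M=300, alpha=0.1, beta=0.02,
                              doc_length_mean=50,
                              junk_plants=("uniform", "vacuous"), seed=0)
        corpus, truth = generate(spec)
        tok = preprocess(corpus, min_df=1, max_df_frac=1.0, phrases=False)
        table = rank_topics(truth_model(truth, tok), tok)
        worst_two = set(np.argsort(table.rank)[-2:])
        assert worst_two == set(truth.junk_ids)

    def test_tsr_finite_nonnegative_and_std_range_bounded(self):
        model, tok = _toy_model_and_corpus()
        table = rank_topics(model, tok)
        assert np.isfinite(table.tsr).all() and (table.tsr >= 0).all()
        assert (table.std_range >= 0).all() and (table.std_range <= 1).all()


class TestTemporalTsr:
    def test_single_period_reduces_to_global(self):
        model, tok = _toy_model_and_corpus()
        tables, traj = temporal_tsr(model, tok, periods=[(2013, 2022)])
        global_table = rank_topics(model, tok)
        only = tables[(2013, 2022)]
        assert only.tsr == pytest.approx(global_table.tsr, abs=1e-12)
        assert np.array_equal(traj["2013-2022"].to_numpy(),
                              global_table.rank)

    def test_default_periods(self):
        from littrends.tsr import DEFAULT_PERIODS

        assert DEFAULT_PERIODS == ((2013, 2015), (2016, 2018), (2019, 2022))

    def test_empty_period_is_error(self):
        model, tok = _toy_model_and_corpus()
        with pytest.raises(ValueError, match="2017-2018"):
            temporal_tsr(model, tok, periods=[(2014, 2016), (2017, 2018)])

    def test_overlapping_periods_rejected(self):
        model, tok = _toy_model_and_corpus()
        with pytest.raises(ValueError, match="overlap"):
            temporal_tsr(model, tok, periods=[(2013, 2016), (2016, 2020)])

    def test_period_prevalence_pulls_topic_toward_background(self):
        # a topic whose documents all land in the last period dominates that
        # period's sub-corpus, so its word row moves toward the period
        # marginal (vacuousness) and its document column toward the
        # background reference: both period-sensitive raw distances shrink
        # and its significance rank number grows from period 1 to period 3
        spec = GenerativeSpec(K_true=4, V=160, M=900, alpha=0.08, beta=0.02,
                              doc_length_mean=50, years=(2013, 2022),
                              year_skew=(0, 1.0), seed=21)
        corpus, truth = generate(spec)
        tok = preprocess(corpus, min_df=1, max_df_frac=1.0, phrases=False)
        model = truth_model(truth, tok)
        years = np.asarray(tok.years)
        early = np.flatnonzero((years >= 2013) & (years <= 2015))
        late = np.flatnonzero((years >= 2019) & (years <= 2022))
        raw_early = raw_distances(model, tok, early)
        raw_late = raw_distances(model, tok, late)
        assert raw_late[0, 0, 1] < raw_early[0, 0, 1]   # KL to W-Vacuous
        tables, traj = temporal_tsr(model, tok)
        assert traj.iloc[0, -1] > traj.iloc[0, 0]
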