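"""Cluster-HMM: reciprocation detection, features, fitting, filtering.

The forward filter is checked against an exhaustive path-enumeration
oracle, and fitting against sequences simulated from a known model.
"""

import itertools

import numpy as np
import pytest

from nudgegame import (
    AllocationEvent,
    FeatureVector,
    MotiveModel,
    detect_reciprocation,
    extract_features,
    fit_motive_model,
    forward_filter,
    predict_reciprocation,
    sample_motive_sequences,
)


def fv(*vals):
    return FeatureVector(*vals)


def brute_force_posterior(model: MotiveModel, obs: list[bool]) -> np.ndarray:
    """Sum over every hidden state path; posterior of the final state."""
    K, T = model.K, len(obs)
    pi = np.full(K, 1.0 / K)
    post = np.zeros(K)
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= model.transitions[a, b]
        for s, o in zip(path, obs):
            p *= model.emissions[s] if o else 1 - model.emissions[s]
        post[path[-1]] += p
    return post / post.sum()


def random_model(rng, K):
    T = rng.random((K, K)) + 0.1
    T /= T.sum(axis=1, keepdims=True)
    return MotiveModel(
        K=K,
        centers=rng.random((K, 5)),
        transitions=T,
        emissions=rng.uniform(0.05, 0.95, K),
    )


class TestDetectReciprocation:
    def test_detect_cases(self, toy_roster):
        cfg, players = toy_roster
        a = next(p for p in players if p.id == "G1H1")
        b = next(p for p in players if p.id == "G2H1")
        c = next(p for p in players if p.id == "G1H2")
        history = [
            AllocationEvent(cfg.game_id, 1, b, a),  # b gives to a at t-1
            AllocationEvent(cfg.game_id, 2, a, b),  # a returns at t
        ]
        assert detect_reciprocation(history, a, round=2, window=1) is True
        history2 = [
            AllocationEvent(cfg.game_id, 1, b, a),
            AllocationEvent(cfg.game_id, 2, a, c),  # a gives elsewhere
        ]
        assert detect_reciprocation(history2, a, round=2, window=1) is False

    def test_no_benefactor_is_undefined_not_false(self, toy_roster):
        cfg, players = toy_roster
        a, c = players[1], players[2]
        history = [AllocationEvent(cfg.game_id, 2, a, c)]
        assert detect_reciprocation(history, a, round=2, window=1) is None

    def test_round_one_is_undefined(self, toy_roster):
        cfg, players = toy_roster
        assert detect_reciprocation([], players[0], round=1) is None

    def test_matches_exhaustive_scan_on_random_histories(self, toy_roster, rng):
        """Oracle: direct scan of a toy history for (benefactor, return)
        pairs, for every player/round/window."""
        cfg, players = toy_roster
        for _ in range(50):
            history = [
                AllocationEvent(
                    cfg.game_id,
                    t,
                    players[rng.integers(8)],
                    players[rng.integers(8)],
                )
                for t in range(1, 7)
                for _k in range(3)
            ]
            for p in players[:4]:
                for t in (2, 4, 6):
                    for window in (1, 2):
                        benefactors = {
                            e.allocator.id
                            for e in history
                            if e.recipient.id == p.id
                            and e.allocator.id != p.id
                            and t - window <= e.round < t
                        }
                        own = [
                            e for e in history if e.round == t and e.allocator.id == p.id
                        ]
                        if not benefactors or not own:
                            expected = None
                        else:
                            expected = own[0].recipient.id in benefactors
                        got = detect_reciprocation(history, p, t, window)
                        if expected is None and own:
                            assert got is None
                        else:
                            assert got == expected


class TestExtractFeatures:
    def test_cold_start_defaults(self, toy_roster):
        cfg, players = toy_roster
        focal_agent = next(p for p in players if p.kind == "agent")
        p = next(p for p in players if p.kind == "human" and p.group == 1)
        f = extract_features([], p, 1, focal_agent, cfg)
        assert f.group_alignment == 1.0
        assert (f.ingroup_tie, f.outgroup_tie) == (0.0, 0.0)
        assert f.allocated is False
        assert f.wealth == 1.0
        assert f.reciprocation_tendency == 0.5

    def test_tie_shares_from_counts(self, toy_roster):
        cfg, players = toy_roster
        focal_agent = next(p for p in players if p.kind == "agent" and p.group == 2)
        p = next(q for q in players if q.kind == "human" and q.group == 1)
        ingroup = [q for q in players if q.group == 1 and q != p]
        outgroup = [q for q in players if q.group == 2]
        history = [
            AllocationEvent(cfg.game_id, 1, p, ingroup[0]),
            AllocationEvent(cfg.game_id, 2, p, ingroup[1]),
            AllocationEvent(cfg.game_id, 3, p, outgroup[0]),
            AllocationEvent(cfg.game_id, 4, p, p),  # self, excluded from ties
        ]
        f = extract_features(history, p, 5, focal_agent, cfg)
        assert f.ingroup_tie == pytest.approx(2 / 3)
        assert f.outgroup_tie == pytest.approx(1 / 3)
        assert f.group_alignment == 0.0

    def test_wealth_is_balance_over_starting_tokens(self, study2_config, toy_roster):
        cfg, players = toy_roster
        import dataclasses

        cfg40 = dataclasses.replace(cfg, starting_tokens=40, rounds=6)
        p = players[1]
        other = players[5]
        # p gives 4 tokens away and receives none: balance 36 of 40
        history = [
            AllocationEvent(cfg40.game_id, t, p, other) for t in range(1, 5)
        ]
        f = extract_features(history, p, 6, players[0], cfg40)
        assert f.wealth == pytest.approx(36 / 40)


class TestFitMotiveModel:
    def test_degenerate_single_cluster(self):
        feats = [[fv(1, 0, 0, 1, 0.5)] * 5]
        labels = [[True, False, True, None, True]]
        model = fit_motive_model(feats, labels, K=1, seed=0)
        assert model.K == 1
        np.testing.assert_allclose(model.transitions, [[1.0]])
        # add-one smoothed mean of 3 true among 4 defined labels
        assert model.emissions[0] == pytest.approx((3 + 1) / (4 + 2))

    def test_k_reduced_to_distinct_points_with_warning(self):
        feats = [[fv(1, 0, 0, 1, 0.5), fv(0, 1, 0, 1, 0.5)] * 3]
        labels = [[True, False] * 3]
        with pytest.warns(UserWarning, match="reducing K"):
            model = fit_motive_model(feats, labels, K=3, seed=0)
        assert model.K == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_motive_model([], [], K=2)

    def test_rows_stochastic_and_emissions_bounded(self, rng):
        truth = random_model(rng, 3)
        feats, obs, _ = sample_motive_sequences(truth, 4, 40, rng)
        model = fit_motive_model(feats, obs, K=3, seed=1)
        np.testing.assert_allclose(model.transitions.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((model.emissions >= 0) & (model.emissions <= 1))

    def test_two_motive_parameter_recovery(self, rng):
        """Well-separated 2-motive generator: emissions and transition
        rows recovered within 0.1."""
        truth = MotiveModel(
            K=2,
            centers=np.array([[0, 1, 0, 1.0, 0.2], [1, 0, 1, 0.5, 0.8]]),
            transitions=np.array([[0.8, 0.2], [0.3, 0.7]]),
            emissions=np.array([0.2, 0.8]),
        )
        feats, obs, _ = sample_motive_sequences(truth, 5, 100, rng)
        model = fit_motive_model(feats, obs, K=2, seed=3)
        order = np.argsort(model.emissions)
        emissions = model.emissions[order]
        transitions = model.transitions[order][:, order]
        assert np.all(np.abs(emissions - truth.emissions) < 0.1)
        assert np.all(np.abs(transitions - truth.transitions) < 0.1)


class TestPredict:
    def test_single_state_returns_its_emission(self):
        model = MotiveModel(
            K=1,
            centers=np.zeros((1, 5)),
            transitions=np.array([[1.0]]),
            emissions=np.array([0.7]),
        )
        assert predict_reciprocation(model, fv(0, 0, 0, 0, 0)) == pytest.approx(0.7)

    def test_two_state_average(self):
        model = MotiveModel(
            K=2,
            centers=np.array([[0.0] * 5, [1.0] * 5]),
            transitions=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emissions=np.array([0.2, 0.8]),
        )
        # features at the first center -> state 0 -> 0.5*0.2 + 0.5*0.8
        assert predict_reciprocation(model, fv(0, 0, 0, 0, 0)) == pytest.approx(0.5)

    def test_non_stochastic_row_rejected(self):
        model = MotiveModel(
            K=2,
            centers=np.zeros((2, 5)),
            transitions=np.array([[0.5, 0.4], [0.5, 0.5]]),
            emissions=np.array([0.2, 0.8]),
        )
        with pytest.raises(ValueError, match="sum to 1"):
            predict_reciprocation(model, fv(0, 0, 0, 0, 0))

    def test_invariant_to_motive_relabeling(self, rng):
        model = random_model(rng, 3)
        perm = np.array([2, 0, 1])
        permuted = MotiveModel(
            K=3,
            centers=model.centers[perm],
            transitions=model.transitions[perm][:, perm],
            emissions=model.emissions[perm],
        )
        for _ in range(20):
            f = fv(*rng.random(5))
            assert predict_reciprocation(model, f) == pytest.approx(
                predict_reciprocation(permuted, f), abs=1e-12
            )


class TestForwardFilter:
    def test_single_state_posterior_is_one(self):
        model = MotiveModel(
            K=1,
            centers=np.zeros((1, 5)),
            transitions=np.array([[1.0]]),
            emissions=np.array([0.7]),
        )
        np.testing.assert_allclose(forward_filter(model, [True, False, True]), [1.0])

    def test_matches_brute_force_enumeration(self, rng):
        """Exact oracle equivalence: K <= 3, sequence length <= 6."""
        for K in (1, 2, 3):
            for length in (1, 2, 4, 6):
                for _ in range(5):
                    model = random_model(rng, K)
                    obs = [bool(b) for b in rng.integers(0, 2, length)]
                    expected = brute_force_posterior(model, obs)
                    got = forward_filter(model, obs)
                    np.testing.assert_allclose(got, expected, atol=1e-10)
                    assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            forward_filter(random_model(rng, 2), [])

    def test_zero_likelihood_yields_uniform_with_warning(self):
        model = MotiveModel(
            K=2,
            centers=np.zeros((2, 5)),
            transitions=np.array([[0.5, 0.5], [0.5, 0.5]]),
            emissions=np.array([1.0, 1.0]),  # False is impossible
        )
        with pytest.warns(UserWarning, match="zero likelihood"):
            post = forward_filter(model, [False])
        np.testing.assert_allclose(post, [0.5, 0.5])


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        model = random_model(rng, 3)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MotiveModel.from_json(path)
        assert back.K == model.K
        np.testing.assert_allclose(back.centers, model.centers)
        np.testing.assert_allclose(back.transitions, model.transitions)
        np.testing.assert_allclose(back.emissions, model.emissions)
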