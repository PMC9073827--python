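"""Value function, probability weighting, decision weights, and prospect values."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from cptgdm import (
    CPTParams,
    decision_weights,
    normalize_values,
    probability_weight,
    prospect_value,
    rank,
    value_function,
)

TOL = 5e-4


def brute_force_pi(probs, values, mu):
    """Independent cumulative-difference enumeration of decision weights."""
    n = len(probs)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    gains = [i for i in order if values[i] >= 0]
    losses = [i for i in order if values[i] < 0]

    def w(q):
        # cumulative sums within fp noise of the endpoints count as exact
        if q <= 1e-12:
            return 0.0
        if q >= 1 - 1e-9:
            return 1.0
        return mu * q + 0.5 * (1 - mu)

    pi = {}
    for j, idx in enumerate(gains):
        head = sum(probs[i] for i in gains[: j + 1])
        prev = sum(probs[i] for i in gains[:j])
        pi[idx] = w(head) - w(prev)
    for j, idx in enumerate(reversed(losses)):
        tail = sum(probs[i] for i in list(reversed(losses))[: j + 1])
        prev = sum(probs[i] for i in list(reversed(losses))[:j])
        pi[idx] = w(tail) - w(prev)
    return np.array([pi[i] for i in range(n)])


class TestValueFunction:
    @pytest.mark.parametrize(
        "z,params,expected",
        [
            (-0.120, CPTParams(lam=2, beta=1), -0.240),  # loss doubled by loss aversion
            (0.0, CPTParams(), 0.0),
            (15.988, CPTParams(alpha=1), 15.988),  # identity on gains at alpha = 1
            (-4.0, CPTParams(lam=2.25, alpha=0.88, beta=0.88), -2.25 * 4.0**0.88),
        ],
    )
    def test_two_piece_power_form(self, z, params, expected):
        assert value_function(z, params) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(0.001, 100, allow_nan=False), st.floats(1, 5))
    def test_loss_aversion_scales_losses(self, z, lam):
        p = CPTParams(alpha=0.8, beta=0.8, lam=lam)
        assert abs(value_function(-z, p)) == pytest.approx(lam * value_function(z, p), rel=1e-9)

    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=6, unique=True))
    def test_strictly_increasing(self, zs):
        p = CPTParams(alpha=0.7, beta=0.9, lam=2.0)
        zs = sorted(zs)
        vals = [value_function(z, p) for z in zs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(beta=1.5), dict(lam=0.5), dict(mu=0)])
    def test_parameter_ranges_enforced(self, bad):
        with pytest.raises(ValueError):
            CPTParams(**bad)


class TestNormalizeValues:
    def test_normalizer_is_max_absolute_valued_payoff(self):
        # C1 column of the packaged example after loss aversion (lam = 2)
        gains = [15.988, 23.488, 35.988]
        losses = [-2 * 7.738, -2 * 5.738, -2 * 3.369]
        values = np.array(gains + losses).reshape(3, 2, 1)
        vtilde, vstar = normalize_values(values)
        assert vstar[0] == pytest.approx(35.988)
        assert np.abs(vtilde).max() == pytest.approx(1.0)

    def test_all_zero_criterion_maps_to_zero(self):
        vtilde, vstar = normalize_values(np.zeros((2, 2, 1)))
        assert vstar[0] == 0.0
        assert np.all(vtilde == 0.0)

    @given(st.floats(0.1, 10))
    def test_scale_invariance_of_ratios(self, c):
        values = np.array([[1.0, -3.0], [2.0, 0.5]]).reshape(2, 2, 1)
        base, _ = normalize_values(values)
        scaled, _ = normalize_values(c * values)
        assert scaled == pytest.approx(base)


class TestProbabilityWeight:
    @pytest.mark.parametrize(
        "p,mu,expected",
        [
            (0.75, 0.6, 0.65),
            (0.3, 0.6, 0.38),
            (1.0, 0.6, 1.0),
            (0.0, 0.6, 0.0),
            (0.4, 1.0, 0.4),  # unit slope leaves probabilities undistorted
        ],
    )
    def test_neo_additive_form(self, p, mu, expected):
        assert probability_weight(p, mu) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0, 1, allow_nan=False), st.floats(0.05, 1.0))
    def test_complementarity(self, p, mu):
        # identity holds wherever 1 - p is representable on the same side of
        # the endpoint discontinuity as p
        assume(p in (0.0, 1.0) or 0.0 < 1.0 - p < 1.0)
        assert probability_weight(p, mu) + probability_weight(1 - p, mu) == pytest.approx(1.0)

    @given(st.floats(0.05, 1.0))
    def test_monotone_on_open_interval(self, mu):
        grid = np.linspace(0.01, 0.99, 25)
        vals = [probability_weight(p, mu) for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ValueError):
            probability_weight(1.2, 0.6)


class TestDecisionWeights:
    @pytest.mark.parametrize(
        "probs,pi_gain,pi_loss",
        [
            ([0.75, 0.25], 0.65, 0.35),
            ([0.8, 0.2], 0.68, 0.32),
            ([0.7, 0.3], 0.62, 0.38),
        ],
    )
    def test_two_outcome_gain_loss_split(self, probs, pi_gain, pi_loss):
        dw = decision_weights(probs, [0.7, -0.4], CPTParams(mu=0.6))
        assert dw.pi == pytest.approx([pi_gain, pi_loss], abs=1e-12)
        assert dw.n_gains == 1

    @given(
        st.lists(st.floats(0.05, 1.0), min_size=2, max_size=5),
        st.data(),
    )
    def test_matches_brute_force_enumeration(self, raw_probs, data):
        probs = np.array(raw_probs) / np.sum(raw_probs)
        values = data.draw(
            st.lists(
                st.floats(-1, 1, allow_nan=False),
                min_size=len(probs),
                max_size=len(probs),
            )
        )
        params = CPTParams(mu=data.draw(st.floats(0.1, 1.0)))
        dw = decision_weights(probs, values, params)
        expected = brute_force_pi(list(probs), values, params.mu)
        assert dw.pi == pytest.approx(expected, abs=1e-12)
        assert dw.pi.sum() == pytest.approx(1.0, abs=1e-9)  # telescoping identity

    def test_zero_values_count_as_gains(self):
        dw = decision_weights([0.5, 0.5], [0.0, -0.2], CPTParams(mu=0.6))
        assert dw.is_gain.tolist() == [True, False]

    def test_rejects_bad_probability_sum(self):
        with pytest.raises(ValueError, match="sum to 1"):
            decision_weights([0.7, 0.2], [0.5, -0.5], CPTParams())

    def test_mu_one_recovers_objective_probabilities(self):
        dw = decision_weights([0.7, 0.3], [0.5, -0.5], CPTParams(mu=1.0))
        assert dw.pi == pytest.approx([0.7, 0.3])


class TestProspectValueAndRank:
    def test_packaged_example_first_alternative(self):
        # combined per-outcome normalized values collapse across criteria here,
        # so the per-criterion aggregation must equal the printed arithmetic
        vt = np.array([[0.725], [-0.613]])
        pv = prospect_value([0.75, 0.25], vt, [1.0], CPTParams(mu=0.6))
        assert pv == pytest.approx(0.725 * 0.65 - 0.613 * 0.35, abs=1e-12)

    def test_single_certain_outcome_returns_normalized_value(self):
        pv = prospect_value([1.0], np.array([[0.42]]), [1.0], CPTParams())
        assert pv == pytest.approx(0.42)

    def test_mixed_sign_across_criteria_partitions_per_attribute(self):
        # outcome 1 is a gain on criterion 1 but a loss on criterion 2
        vt = np.array([[0.5, -0.5], [-0.2, 0.8]])
        params = CPTParams(mu=0.6)
        pv = prospect_value([0.6, 0.4], vt, [0.5, 0.5], params)
        w = lambda p: 0.6 * p + 0.2
        expected = 0.5 * (w(0.6) * 0.5 + w(0.4) * -0.2) + 0.5 * (w(0.4) * 0.8 + w(0.6) * -0.5)
        assert pv == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_attribute_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            prospect_value([1.0], np.array([[0.1]]), [0.7], CPTParams())

    @pytest.mark.parametrize(
        "pvs,expected",
        [
            ([0.257, 0.431, 0.422], [1, 2, 0]),
            ([0.470, 0.581, 0.594], [2, 1, 0]),
            ([0.3, 0.3, 0.1], [0, 1, 2]),  # ties keep input order
        ],
    )
    def test_ranking(self, pvs, expected):
        assert rank(pvs) == expected

    @given(st.floats(0.1, 5), st.integers(0, 2**31 - 1))
    def test_per_criterion_rescaling_leaves_pv_unchanged(self, c, seed):
        # with alpha = beta the valued payoffs scale linearly, so the
        # per-criterion normalization cancels any positive rescaling
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(3, 2, 2))
        probs = rng.dirichlet(np.ones(2))
        params = CPTParams(alpha=1.0, beta=1.0, lam=2.0, mu=0.6)
        vt, _ = normalize_values(values)
        scaled = values.copy()
        scaled[:, :, 0] *= c
        vt_scaled, _ = normalize_values(scaled)
        for i in range(3):
            pv0 = prospect_value(probs, vt[i], [0.5, 0.5], params)
            pv1 = prospect_value(probs, vt_scaled[i], [0.5, 0.5], params)
            assert pv1 == pytest.approx(pv0, abs=1e-9)
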