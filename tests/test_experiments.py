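"""Phenomenology drivers: WA limit, discrepancy sweeps, order effects,
dissonance, certain persuaders, boomerang reports."""

import numpy as np
import pytest

from credence import (
    DiscreteOpinion,
    GaussianParams,
    Grid,
    GridOpinion,
    OpinionValidationError,
    RevisionParams,
    boomerang_revision_report,
    certain_persuader_revision,
    discrepancy_sweep,
    dissonance_scenario,
    find_anchors,
    gaussian_density,
    hellinger,
    monotone_discrepancy_check,
    order_experiment,
    revise,
    revise_density,
    revise_sequence,
    weighted_average_prediction,
)
from credence.experiments import locate_primacy_crossover, params_for

from conftest import random_opinion


def op(*w):
    return DiscreteOpinion.from_weights(np.asarray(w, dtype=float))


def full_rule_anchor_shift(mu_q, eps, sigma_p=1.0, sigma_q=1.0, n=8001):
    gp, gq = GaussianParams(0.0, sigma_p), GaussianParams(mu_q, sigma_q)
    g = Grid(-8.0 * sigma_p, mu_q + 8.0 * sigma_q, n)
    pt = revise_density(gaussian_density(gp, g), gaussian_density(gq, g), params_for(eps))
    return find_anchors(pt).dominant[0]


class TestWeightedAveragePrediction:
    def test_conservatism_limit(self):
        pred = weighted_average_prediction(GaussianParams(0, 1), GaussianParams(1, 1), 1.0)
        assert pred.weight_other == 0.0
        assert pred.predicted_anchor == 0.0
        assert pred.weight_self + pred.weight_other == 1.0

    def test_dispersion_narrows_with_sharper_persuader(self):
        pred = weighted_average_prediction(
            GaussianParams(0, 1.0), GaussianParams(0, 0.5), 0.5
        )
        assert pred.predicted_dispersion_ratio < 1.0
        wide = weighted_average_prediction(GaussianParams(0, 1.0), GaussianParams(0, 2.0), 0.5)
        assert wide.predicted_dispersion_ratio > 1.0

    def test_boomerang_reverses_shift_and_dispersion(self):
        pred = weighted_average_prediction(GaussianParams(0, 1), GaussianParams(1, 1), 1.5)
        assert pred.weight_other < 0  # anchor shifts away from the persuader
        sharper = weighted_average_prediction(
            GaussianParams(0, 1.0), GaussianParams(0, 0.5), 1.5
        )
        assert sharper.predicted_dispersion_ratio > 1.0  # reversed inequality

    @pytest.mark.parametrize("eps", [0.3, 0.5, 0.7])
    def test_first_order_agreement_with_full_rule(self, eps):
        """Relative error of the predicted shift halves (at least) with m."""
        errors = []
        for m in (0.4, 0.2, 0.1):
            pred = weighted_average_prediction(
                GaussianParams(0, 1), GaussianParams(m, 1), eps
            )
            shift = full_rule_anchor_shift(m, eps)
            errors.append(abs(shift - pred.predicted_anchor) / m)
        assert errors[1] < 0.6 * errors[0] + 1e-4
        assert errors[2] < 0.6 * errors[1] + 1e-4

    def test_ratio_tends_to_one(self):
        pred = weighted_average_prediction(GaussianParams(0, 1), GaussianParams(0.05, 1), 0.5)
        shift = full_rule_anchor_shift(0.05, 0.5)
        assert shift / pred.predicted_anchor == pytest.approx(1.0, abs=5e-3)


class TestFindAnchors:
    def test_single_gaussian(self):
        g = Grid(-8, 8, 2001)
        a = find_anchors(gaussian_density(GaussianParams(1.0, 1.0), g))
        assert len(a) == 1
        assert a.dominant[0] == pytest.approx(1.0, abs=1e-3)

    def test_two_component_mixture(self):
        g = Grid(-10, 10, 2001)
        x = g.points
        mix = np.exp(-((x + 3) ** 2) / 2) + 0.6 * np.exp(-((x - 3) ** 2) / 2)
        a = find_anchors(GridOpinion.from_unnormalized(g, mix))
        assert len(a) == 2
        assert a.dominant[0] == pytest.approx(-3.0, abs=1e-2)

    def test_plateau_collapses_to_midpoint(self):
        g = Grid(0.0, 10.0, 101)
        vals = np.ones(101)
        vals[40:61] = 2.0  # flat top between x=4 and x=6
        a = find_anchors(GridOpinion.from_unnormalized(g, vals))
        assert len(a) == 1
        assert a.dominant[0] == pytest.approx(5.0, abs=1e-9)

    def test_min_height_filter(self):
        g = Grid(-10, 10, 2001)
        x = g.points
        mix = np.exp(-((x + 3) ** 2) / 2) + 0.005 * np.exp(-((x - 3) ** 2) / 2)
        assert len(find_anchors(GridOpinion.from_unnormalized(g, mix), 0.01)) == 1


@pytest.fixture(scope="module")
def sweep():
    return discrepancy_sweep(1.0, 1.0, 0.5, np.linspace(0.0, 6.0, 25), n_points=1201)


class TestDiscrepancySweep:

    def test_no_change_at_zero_discrepancy(self, sweep):
        assert sweep.table.h.iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert sweep.table.anchor_shift.iloc[0] == pytest.approx(0.0, abs=1e-2)

    def test_inverted_u(self, sweep):
        h = sweep.table.h.to_numpy()
        imax = int(np.argmax(h))
        assert 0 < imax < len(h) - 1  # interior maximum
        assert np.all(np.diff(h[: imax + 1]) > 0)
        assert np.all(np.diff(h[imax:]) < 0)

    def test_m_star_in_non_commitment_latitude(self, sweep):
        assert 2.0 < sweep.m_star < 3.0  # sigma_p = 1
        assert 2.0 <= sweep.m_star_tv < 3.0

    def test_no_jump_at_moderate_epsilon(self, sweep):
        assert not sweep.anchor_jump

    def test_small_epsilon_anchor_jump_fires(self):
        fired = []
        for eps in (0.1, 0.2, 0.3):
            sw = discrepancy_sweep(1.0, 1.0, eps, np.linspace(0.0, 8.0, 33), n_points=1201)
            fired.append(sw.anchor_jump)
        assert any(fired)

    def test_input_validation(self):
        with pytest.raises(OpinionValidationError):
            discrepancy_sweep(1.0, 1.0, 0.5, np.linspace(0, 1, 5))


class TestMonotoneDiscrepancy:
    def test_monotone_change_for_equal_anchors(self):
        tab = monotone_discrepancy_check(1.0, 0.5, np.linspace(1.0, 3.0, 11))
        assert tab.change_h.iloc[0] == pytest.approx(0.0, abs=1e-6)  # sigma_q = sigma_p
        assert np.all(np.diff(tab.discrepancy_h) > 0)
        assert np.all(np.diff(tab.change_h) > 0)
        # the TV-based change agrees in ordering
        assert np.all(np.diff(tab.change_tv) > 0)


class TestOrderExperiment:
    def test_binary_worked_example(self):
        res = order_experiment(op(0.5, 0.5), (op(1.0, 0.0), op(0.0, 1.0)), 0.5)
        assert res.final_forward.weights == pytest.approx([0.4727, 0.5273], abs=5e-5)
        assert res.verdict == "recency"

    def test_gaussian_symmetric_setup(self):
        res = order_experiment(
            GaussianParams(0.0, 1.0),
            (GaussianParams(1.5, 1.0), GaussianParams(-1.5, 1.0)),
            0.5,
        )
        assert res.verdict == "recency"

    def test_asymmetric_setup_rejected(self):
        with pytest.raises(OpinionValidationError):
            order_experiment(
                GaussianParams(0.0, 1.0),
                (GaussianParams(1.5, 1.0), GaussianParams(-1.0, 1.0)),
                0.5,
            )
        with pytest.raises(OpinionValidationError):
            order_experiment(op(0.4, 0.6), (op(1.0, 0.0), op(0.0, 1.0)), 0.5)

    def test_recency_on_200_randomized_symmetric_setups(self, rng):
        """Outside the boomerang regime the verdict is recency in 100% of
        randomized symmetric setups (discrete palindromic and Gaussian)."""
        for i in range(200):
            eps = float(rng.uniform(0.05, 0.95))
            if i % 2:
                k = int(rng.integers(2, 7))
                half = rng.dirichlet(np.ones(k))
                p = DiscreteOpinion.from_weights(np.concatenate([half, half[::-1]]))
                qw = rng.dirichlet(np.ones(2 * k)) + 1e-6
                q = DiscreteOpinion.from_weights(qw)
                qp = DiscreteOpinion.from_weights(qw[::-1])
                res = order_experiment(p, (q, qp), eps)
            else:
                d = float(rng.uniform(0.3, 3.0))
                sq = float(rng.uniform(0.4, 2.0))
                res = order_experiment(
                    GaussianParams(0.0, 1.0),
                    (GaussianParams(d, sq), GaussianParams(-d, sq)),
                    eps,
                    n_points=801,
                )
            assert res.verdict == "recency"

    def test_multi_exposure_recency(self, rng):
        """Alternating exposure (B,C,B,C) vs its reverse: the final opinion
        leans toward whichever persuader came last."""
        for _ in range(50):
            k = int(rng.integers(2, 6))
            eps = float(rng.uniform(0.1, 0.9))
            half = rng.dirichlet(np.ones(k))
            p = DiscreteOpinion.from_weights(np.concatenate([half, half[::-1]]))
            bw = rng.dirichlet(np.ones(2 * k)) + 1e-6
            b = DiscreteOpinion.from_weights(bw)
            cop = DiscreteOpinion.from_weights(bw[::-1])
            params = RevisionParams(eps)
            fin = revise_sequence(p, [b, cop, b, cop], params)
            assert hellinger(fin, cop) < hellinger(fin, b)

    def test_primacy_crossover_in_boomerang_regime(self):
        eps_star = locate_primacy_crossover(
            op(0.5, 0.5), (op(1.0, 0.0), op(0.0, 1.0)), lo=1.05, hi=3.0
        )
        assert 1.0 < eps_star <= 3.0
        before = order_experiment(op(0.5, 0.5), (op(1.0, 0.0), op(0.0, 1.0)), eps_star - 0.05)
        after = order_experiment(op(0.5, 0.5), (op(1.0, 0.0), op(0.0, 1.0)), eps_star + 0.05)
        assert before.verdict == "recency"
        assert after.verdict == "primacy"

    def test_order_difference_depends_mostly_on_persuaders_near_conservatism(self):
        """Near eps = 1 the leading-order difference between the two orders
        is a function of the persuading opinions only: varying the prior
        changes it only at higher order in (1 - eps)."""
        q = op(0.7, 0.2, 0.1)
        qp = op(0.2, 0.3, 0.5)

        def order_diff(p, eps):
            params = RevisionParams(eps)
            f1 = revise_sequence(p, [q, qp], params).probabilities
            f2 = revise_sequence(p, [qp, q], params).probabilities
            return f1 - f2

        ratios = []
        for eta in (0.2, 0.1, 0.05):
            d1 = order_diff(op(0.3, 0.4, 0.3), 1 - eta)
            d2 = order_diff(op(0.5, 0.2, 0.3), 1 - eta)
            ratios.append(np.linalg.norm(d1 - d2) / np.linalg.norm(d1))
        assert ratios[2] < ratios[1] < ratios[0]
        assert ratios[1] < 0.1


class TestDissonance:
    def test_conservative_agent_keeps_single_peak(self):
        out = dissonance_scenario(GaussianParams(0, 1), GaussianParams(2.0, 0.3), 0.95)
        assert out.classification == "single-peak"

    def test_credulous_agent_dominated_by_new_anchor(self):
        out = dissonance_scenario(GaussianParams(0, 1), GaussianParams(2.0, 0.3), 0.05)
        assert out.classification == "dominated-new"

    def test_archived_witness_is_dissonant(self):
        out = dissonance_scenario(GaussianParams(0, 1), GaussianParams(2.0, 0.3), 0.5)
        assert out.classification == "dissonant"
        (l1, h1), (l2, h2) = out.anchors.anchors[0], out.anchors.anchors[1]
        assert 1 / 3 <= h1 / h2 <= 3
        assert abs(l1 - l2) > 1.0  # widely separated anchors

    def test_narrower_prior_resists_splitting(self):
        out = dissonance_scenario(GaussianParams(0, 0.4), GaussianParams(2.0, 0.3), 0.5)
        assert len(out.anchors) == 1


class TestCertainPersuader:
    def test_uniform_prior_gets_unique_maximum_at_target(self):
        p = op(*([1 / 5] * 5))
        out = certain_persuader_revision(p, 2, 0.5)
        assert int(np.argmax(out.weights)) == 2
        assert np.sum(out.weights == out.weights.max()) == 1

    def test_zero_prior_is_immune(self):
        p = op(0.0, 0.6, 0.4)
        out = certain_persuader_revision(p, 0, 0.3)
        assert np.allclose(out.weights, p.weights, rtol=1e-12, atol=1e-15)

    def test_small_tail_becomes_global_maximum(self):
        p = op(0.01, *([0.99 / 9] * 9))
        out = certain_persuader_revision(p, 0, 0.3)
        assert int(np.argmax(out.weights)) == 0

    def test_epsilon_range_validated(self):
        with pytest.raises(OpinionValidationError):
            certain_persuader_revision(op(0.5, 0.5), 0, 1.0)


class TestBoomerangReport:
    def test_anchor_recoils_and_peak_enhances(self):
        rep = boomerang_revision_report(GaussianParams(0, 1), GaussianParams(1.5, 1), 1.5)
        assert rep.moves_away and rep.anchor_displacement < 0
        assert rep.peak_height_ratio > 1.0
        assert rep.width_ratio < 1.0  # dominant peak narrows

    def test_deep_local_minimum_near_crossing(self):
        rep = boomerang_revision_report(GaussianParams(0, 1), GaussianParams(1.5, 1), 1.5)
        assert rep.x0 is not None and rep.min_depth_frac < 0.05
        assert 0.0 < rep.x0 < 3.0  # near the p-q crossing region
        assert rep.n_peaks >= 2

    def test_equal_anchor_dispersion_reversal(self):
        """Sharper persuader at the same anchor *widens* the opinion when
        epsilon > 1 (reversed inequality), measured as the full dispersion."""
        g = Grid(-15, 15, 6001)
        p = gaussian_density(GaussianParams(0, 1.0), g)
        q = gaussian_density(GaussianParams(0, 0.8), g)
        widened = revise_density(p, q, RevisionParams(1.5, "boomerang"))
        assert widened.std() > 1.0
        narrowed = revise_density(p, q, RevisionParams(0.5))
        assert narrowed.std() < 1.0

    def test_overlap_region_loses_mass_pointwise(self):
        """Where the persuader outweighs the prior (and the pooled measure is
        still positive), the revised density sits strictly below the prior."""
        eps = 1.5
        g = Grid(-10, 10, 4001)
        p = gaussian_density(GaussianParams(0, 1), g)
        q = gaussian_density(GaussianParams(1.5, 1), g)
        pt = revise_density(p, q, RevisionParams(eps, "boomerang"))
        pooled = eps * p.density + (1 - eps) * q.density
        region = (q.density > p.density) & (pooled > 0)
        assert region.sum() > 10
        assert np.all(pt.density[region] < p.density[region])

    def test_requires_boomerang_epsilon(self):
        with pytest.raises(OpinionValidationError):
            boomerang_revision_report(GaussianParams(0, 1), GaussianParams(1, 1), 0.5)
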