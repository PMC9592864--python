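import numpy as np
import pytest
from scipy.stats import norm

from ihcquant.mixtures import (
    CaseCall,
    ClassCounts,
    DegenerateFitError,
    Gmm1D,
    ThresholdPair,
    assign_classes,
    call_case_main_class,
    call_case_r50,
    discordance,
    fit_gmm_em,
    intersect_adjacent,
)
from ihcquant.synthetic import load_study_fixture


def _dense_grid_crossing(model, k1, k2):
    """Independent crossing oracle: sign change on a dense grid between means."""
    lo, hi = model.means[k1], model.means[k2]
    x = np.linspace(lo, hi, 100_001)
    diff = model.component_pdf(k1, x) - model.component_pdf(k2, x)
    idx = np.nonzero(np.diff(np.sign(diff)))[0]
    return x[idx[0]]


class TestFitGmmEm:
    def test_three_component_recovery(self):
        rng = np.random.default_rng(0)
        x = np.concatenate(
            [rng.normal(m, 0.02, 1000) for m in (0.2, 0.5, 0.8)]
        )
        model = fit_gmm_em(x, K=3)
        assert np.allclose(model.means, (0.2, 0.5, 0.8), atol=0.01)
        assert np.allclose(model.weights, 1 / 3, atol=0.03)

    def test_k1_matches_sample_moments(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 2.0, 500)
        model = fit_gmm_em(x, K=1)
        assert model.means[0] == pytest.approx(x.mean(), abs=1e-6)
        assert model.sds[0] == pytest.approx(x.std(), abs=1e-6)

    def test_loglik_monotone_in_iterations(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        # deterministic init: truncating the iteration count replays a prefix
        logliks = [fit_gmm_em(x, K=2, max_iter=k, tol=0.0).loglik for k in range(2, 12)]
        assert all(b >= a - 1e-9 for a, b in zip(logliks, logliks[1:]))

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_gmm_em(np.ones(100), K=2)

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_gmm_em(np.arange(15), K=2)

    def test_weights_sum_to_one_means_sorted(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(m, 0.5, 200) for m in (0, 2, 7)])
        model = fit_gmm_em(x, K=3)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(model.means) > 0).all()

    def test_agrees_with_sklearn_oracle(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.3, 0.03, 800), rng.normal(0.7, 0.04, 1200)])
        ours = fit_gmm_em(x, K=2)
        ref = GaussianMixture(2, covariance_type="full", random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        ref_means = np.sort(ref.means_.ravel())
        assert np.allclose(ours.means, ref_means, atol=0.01)


class TestIntersectAdjacent:
    def _model(self, weights, means, sds):
        return Gmm1D(
            weights=np.asarray(weights, float),
            means=np.asarray(means, float),
            sds=np.asarray(sds, float),
            loglik=0.0,
            n_iter=1,
        )

    def test_symmetric_pair_midpoint(self):
        m = self._model([1 / 3] * 3, [0.0, 1.0, 2.0], [0.1] * 3)
        pair = intersect_adjacent(m)
        assert pair.t1 == pytest.approx(0.5, abs=1e-9)
        assert pair.t2 == pytest.approx(1.5, abs=1e-9)

    def test_equal_variance_closed_form(self):
        # w1 N(x;0,s) = w2 N(x;1,s) crosses at 1/2 + s^2 ln(w1/w2)
        m = self._model([0.7, 0.3, 0.5], [0.0, 1.0, 5.0], [0.1, 0.1, 0.1])
        pair = intersect_adjacent(m)
        assert pair.t1 == pytest.approx(0.5 + 0.01 * np.log(0.7 / 0.3), abs=1e-9)

    def test_ordering_invariant_and_grid_oracle(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(m, 0.05, 700) for m in (0.2, 0.5, 0.85)])
        model = fit_gmm_em(x, K=3)
        pair = intersect_adjacent(model)
        assert model.means[0] < pair.t1 < model.means[1] < pair.t2 < model.means[2]
        assert pair.t1 == pytest.approx(_dense_grid_crossing(model, 0, 1), abs=1e-4)
        assert pair.t2 == pytest.approx(_dense_grid_crossing(model, 1, 2), abs=1e-4)

    def test_requires_three_components(self):
        with pytest.raises(ValueError):
            intersect_adjacent(self._model([0.5, 0.5], [0, 1], [0.1, 0.1]))


class TestAssignClasses:
    def test_all_below_first_threshold(self):
        c = assign_classes(np.full(7, 0.1), ThresholdPair(0.3, 0.6))
        assert (c.n0, c.n1, c.n2) == (7, 0, 0)

    def test_boundary_goes_to_upper_class(self):
        c = assign_classes(np.array([0.3, 0.6]), ThresholdPair(0.3, 0.6))
        assert (c.n0, c.n1, c.n2) == (0, 1, 1)

    def test_uniform_grid_bruteforce(self):
        v = np.linspace(0, 1, 300)
        pair = ThresholdPair(0.31, 0.74)
        c = assign_classes(v, pair)
        assert c.n0 == int(np.sum(v < 0.31))
        assert c.n2 == int(np.sum(v >= 0.74))
        assert c.total == 300


class TestCaseCalls:
    @pytest.mark.parametrize(
        "counts,expected",
        [((198, 770, 0), "high"), ((1204, 162, 0), "low"), ((711, 636, 4), "low")],
    )
    def test_main_class_rule(self, counts, expected):
        assert call_case_main_class(ClassCounts(*counts)) == expected

    @pytest.mark.parametrize(
        "counts,r,expected",
        [
            ((201, 228, 2417), 84.93, "high"),
            ((278, 322, 438), 42.20, "low"),
            ((2, 74, 65), 46.10, "low"),
        ],
    )
    def test_r50_rule(self, counts, r, expected):
        r_pct, label = call_case_r50(ClassCounts(*counts))
        assert r_pct == pytest.approx(r, abs=0.01)
        assert label == expected

    def test_r50_tie_at_exactly_half_is_high(self):
        _, label = call_case_r50(ClassCounts(1, 1, 2))
        assert label == "high"

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            call_case_main_class(ClassCounts(0, 0, 0))


class TestDiscordance:
    def _fixture_calls(self, marker, rule):
        counts = load_study_fixture("table4_counts").df
        expert = load_study_fixture("table4_expert").df
        counts = counts[counts.marker == marker]
        labels = dict(zip(expert[expert.marker == marker].case,
                          expert[expert.marker == marker].expert_label))
        calls = []
        for _, row in counts.iterrows():
            c = ClassCounts(int(row.n0), int(row.n1), int(row.n2))
            label = rule(c)
            if isinstance(label, tuple):
                label = label[1]
            calls.append(CaseCall(row.case, marker, label, labels[row.case]))
        return calls

    def test_bim_four_discordant(self):
        n, table = discordance(self._fixture_calls("Bim", call_case_main_class))
        assert n == 4
        assert sorted(table.case) == ["P26", "P29", "P32", "P35"]

    def test_perk_seven_discordant(self):
        n, _ = discordance(self._fixture_calls("P-ERK", call_case_r50))
        assert n == 7

    def test_no_disagreement_zero(self):
        calls = [CaseCall("P1", "Bim", "high", "high")]
        assert discordance(calls)[0] == 0

    def test_missing_expert_label_raises(self):
        with pytest.raises(ValueError):
            discordance([CaseCall("P1", "Bim", "high", "")])
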