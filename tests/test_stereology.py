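import numpy as np
import pytest

from ihcquant.io import BinaryMask
from ihcquant.stereology import (
    EXCLUDED,
    LABELED,
    UNLABELED,
    CrossGrid,
    EmptyGridError,
    MarkSet,
    calibrate,
    concordance_percent,
    consensus_marks,
    estimate_ratio,
    make_grid,
    quality_factor_ci,
    quality_factor_sens_spec,
    sample_mask_at,
)


def _grid_with(labels1, labels2=None):
    """Build one or two mark sets on a shared synthetic grid."""
    n = len(labels1)
    positions = [(0, i) for i in range(n)]
    grid = CrossGrid(spacing=2, offset=(0, 0), positions=positions, seed=0)
    m1 = MarkSet(grid=grid, labels=dict(zip(positions, labels1)))
    if labels2 is None:
        return m1
    return m1, MarkSet(grid=grid, labels=dict(zip(positions, labels2)))


class TestMakeGrid:
    def test_full_frame_node_count(self, full_roi):
        grid = make_grid(full_roi((100, 100)), spacing=10, seed=4)
        assert len(grid) == 100

    def test_deterministic_per_seed(self, full_roi):
        roi = full_roi((64, 64))
        assert make_grid(roi, 7, seed=5).positions == make_grid(roi, 7, seed=5).positions

    def test_empty_roi_raises(self):
        roi = BinaryMask(np.zeros((32, 32), dtype=bool))
        with pytest.raises(EmptyGridError):
            make_grid(roi, 8, seed=0)

    def test_mean_node_count_unbiased(self):
        # irregular blob of known area: E[nodes] = A / spacing^2
        rng = np.random.default_rng(0)
        from scipy.ndimage import gaussian_filter

        field = gaussian_filter(rng.standard_normal((120, 120)), 12)
        roi = BinaryMask(field > np.quantile(field, 0.65))
        area = roi.values.sum()
        s = 10
        counts = [len(make_grid(roi, s, seed=k)) for k in range(500)]
        mc_se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - area / s**2) <= 3 * mc_se


class TestSampling:
    def test_all_true_all_labeled(self, full_roi):
        roi = full_roi((40, 40))
        grid = make_grid(roi, 8, seed=1)
        marks = sample_mask_at(grid, roi)
        assert all(lab == LABELED for lab in marks.labels.values())

    def test_empty_mask_all_unlabeled(self, full_roi):
        grid = make_grid(full_roi((40, 40)), 8, seed=1)
        marks = sample_mask_at(grid, BinaryMask(np.zeros((40, 40), bool)))
        assert all(lab == UNLABELED for lab in marks.labels.values())

    def test_half_plane_split(self):
        roi = BinaryMask(np.ones((40, 40), bool))
        half = np.zeros((40, 40), bool)
        half[20:] = True
        grid = CrossGrid(
            spacing=10,
            offset=(5, 5),
            positions=[(r, c) for r in range(5, 40, 10) for c in range(5, 40, 10)],
            seed=0,
        )
        marks = sample_mask_at(grid, BinaryMask(half))
        n_lab, n_unlab, _ = marks.counts()
        assert n_lab == n_unlab == 8


class TestEstimateRatio:
    def test_wald_interval(self):
        marks = _grid_with([LABELED] * 50 + [UNLABELED] * 50)
        est = estimate_ratio(marks)
        assert est.p_hat == 0.5 and est.n == 100
        assert est.ci95 == pytest.approx((0.402, 0.598), abs=1e-3)

    def test_zero_hits_clipped(self):
        est = estimate_ratio(_grid_with([UNLABELED] * 10))
        assert est.p_hat == 0.0 and est.ci95[0] == 0.0

    def test_all_excluded_error(self):
        with pytest.raises(ValueError):
            estimate_ratio(_grid_with([EXCLUDED] * 5))


class TestConsensus:
    def test_identical_unchanged(self):
        m1, m2 = _grid_with([LABELED, UNLABELED] * 5, [LABELED, UNLABELED] * 5)
        assert consensus_marks(m1, m2).labels == m1.labels

    def test_full_disagreement_all_excluded(self):
        m1, m2 = _grid_with([LABELED] * 6, [UNLABELED] * 6)
        assert all(v == EXCLUDED for v in consensus_marks(m1, m2).labels.values())

    def test_ten_percent_disagreement_retention(self):
        rng = np.random.default_rng(8)
        l1 = [LABELED if rng.random() < 0.5 else UNLABELED for _ in range(1000)]
        l2 = [
            (UNLABELED if a == LABELED else LABELED) if rng.random() < 0.1 else a
            for a in l1
        ]
        cons = consensus_marks(*_grid_with(l1, l2))
        kept = sum(v != EXCLUDED for v in cons.labels.values())
        assert abs(kept - 900) < 40  # ~binomial(1000, 0.9)


class TestConcordance:
    def test_identical_sets(self):
        m1, m2 = _grid_with([LABELED, UNLABELED] * 4, [LABELED, UNLABELED] * 4)
        lab, unlab, total = concordance_percent(m1, m2)
        assert (lab, unlab, total) == (100.0, 100.0, 8)

    def test_disjoint_labelings(self):
        m1, m2 = _grid_with([LABELED] * 4, [UNLABELED] * 4)
        lab, _, _ = concordance_percent(m1, m2)
        assert lab == 0.0

    def test_constructed_2x2_table(self):
        # a=30 both labeled, b=10 reader1 only, c=10 reader2 only, d=50 both unlabeled
        l1 = [LABELED] * 30 + [LABELED] * 10 + [UNLABELED] * 10 + [UNLABELED] * 50
        l2 = [LABELED] * 30 + [UNLABELED] * 10 + [LABELED] * 10 + [UNLABELED] * 50
        lab, unlab, total = concordance_percent(*_grid_with(l1, l2))
        assert lab == pytest.approx(100.0 * 30 / 50)  # union base: a+b+c
        assert unlab == pytest.approx(100.0 * 50 / 70)
        assert total == 100


class TestQualityFactors:
    @pytest.mark.parametrize(
        "sens,spec,qf",
        [(0.7090, 0.9459, 0.8275), (0.9785, 0.9205, 0.9495)],
    )
    def test_mean_of_sens_spec(self, sens, spec, qf):
        # construct a confusion table realizing the given sens/spec at n=10000
        tp = round(sens * 5000)
        tn = round(spec * 5000)
        ref = [LABELED] * 5000 + [UNLABELED] * 5000
        test = (
            [LABELED] * tp + [UNLABELED] * (5000 - tp)
            + [UNLABELED] * tn + [LABELED] * (5000 - tn)
        )
        out = quality_factor_sens_spec(*_grid_with(ref, test))
        assert out.sensitivity == pytest.approx(sens, abs=1e-4)
        assert out.specificity == pytest.approx(spec, abs=1e-4)
        assert out.qf_sens_spec == pytest.approx(qf, abs=1e-4)

    def test_identical_marksets_perfect(self):
        labs = [LABELED] * 5 + [UNLABELED] * 5
        out = quality_factor_sens_spec(*_grid_with(labs, labs))
        assert out.qf_sens_spec == 1.0

    def test_single_class_reference_undefined(self):
        with pytest.raises(ValueError):
            quality_factor_sens_spec(*_grid_with([LABELED] * 6, [LABELED] * 6))

    def test_ci_overlap(self):
        e = estimate_ratio(_grid_with([LABELED] * 50 + [UNLABELED] * 50))

        class E:
            def __init__(self, lo, hi):
                self.ci95 = (lo, hi)
                self.p_hat, self.n = 0.5, 1

        assert quality_factor_ci(e, e) == 1.0
        assert quality_factor_ci(E(0.1, 0.2), E(0.3, 0.4)) == 0.0
        assert quality_factor_ci(E(0.40, 0.60), E(0.50, 0.70)) == pytest.approx(1 / 3)


class TestCalibrate:
    def test_phantom_shift_grid(self, small_phantom, full_roi):
        from ihcquant.stain import classify_stain, fit_stain_model, ohta_transform

        b = small_phantom
        roi = full_roi(b.rgb.shape)
        ohta = ohta_transform(b.rgb)
        base = fit_stain_model(ohta.I2[roi.values])
        grid = make_grid(roi, spacing=8, seed=2)
        from ihcquant.synthetic import simulate_expert_marks

        marks = simulate_expert_marks(grid, b.true_stain, error_rate=0.0)
        shifts = [-20.0, -10.0, 0.0, 10.0, 20.0]
        best, qf = calibrate(
            lambda s: classify_stain(ohta, base.with_shift(s), roi), shifts, marks
        )
        assert qf >= 0.95

    def test_single_candidate(self, full_roi):
        roi = full_roi((32, 32))
        grid = make_grid(roi, 8, seed=0)
        truth = BinaryMask(np.tri(32, 32, dtype=bool))
        marks = sample_mask_at(grid, truth)
        best, qf = calibrate(lambda p: truth, ["only"], marks)
        assert best == "only" and qf == 1.0

    def test_tie_breaks_to_first(self, full_roi):
        roi = full_roi((32, 32))
        grid = make_grid(roi, 8, seed=0)
        truth = BinaryMask(np.tri(32, 32, dtype=bool))
        marks = sample_mask_at(grid, truth)
        best, _ = calibrate(lambda p: truth, ["first", "second"], marks)
        assert best == "first"

    def test_empty_grid_error(self, full_roi):
        roi = full_roi((32, 32))
        grid = make_grid(roi, 8, seed=0)
        marks = sample_mask_at(grid, BinaryMask(np.tri(32, 32, dtype=bool)))
        with pytest.raises(ValueError):
            calibrate(lambda p: None, [], marks)
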