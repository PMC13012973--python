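"""Agreement statistics against brute-force oracles, worked examples, and
independent library implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from digibone.errors import InvalidInputError, NumericalError
from digibone.fusion import PredictionRecord
from digibone.gp_scale import GPScale, snap_array
from digibone.metrics import (bland_altman, class_agreement, dice, evaluate,
                              mad, r_squared, rmse, weighted_kappa)


class TestMadRmse:
    def test_worked_example(self):
        assert mad([10, 14], [12, 12]) == pytest.approx(2.0)

    def test_identity(self):
        x = np.arange(5.0)
        assert mad(x, x) == 0.0 and rmse(x, x) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            mad([1, 2], [1])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_mad_le_rmse(self, seed):
        rng = np.random.default_rng(seed)
        p, t = rng.normal(size=(2, 20)) * 10
        assert mad(p, t) <= rmse(p, t) + 1e-12


class TestBlandAltman:
    def test_constant_offset(self):
        t = np.arange(10.0)
        bias, lo, hi, flagged = bland_altman(t + 3, t)
        assert bias == pytest.approx(3) and lo == pytest.approx(3)
        assert hi == pytest.approx(3) and flagged == []

    def test_worked_example(self):
        # d = {0,0,0,0,10}: bias 2, sample sd sqrt(20), limits 2 -/+ 2*sqrt(20)
        t = np.zeros(5)
        p = np.array([0, 0, 0, 0, 10.0])
        bias, lo, hi, flagged = bland_altman(p, t)
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(2 - 2 * np.sqrt(20))
        assert hi == pytest.approx(2 + 2 * np.sqrt(20))
        assert flagged == []          # 10 < 10.944..., inside the limits

    def test_flags_invariant_under_common_shift(self):
        rng = np.random.default_rng(1)
        p, t = rng.normal(size=(2, 50))
        _, _, _, f1 = bland_altman(p, t)
        _, _, _, f2 = bland_altman(p + 100, t + 100)
        assert f1 == f2

    def test_needs_two_pairs(self):
        with pytest.raises(InvalidInputError):
            bland_altman([1.0], [1.0])


class TestRSquared:
    def test_perfect_linear_relation(self):
        t = np.arange(10.0)
        assert r_squared(2 * t + 5, t) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(NumericalError):
            r_squared(np.ones(5), np.arange(5.0))

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        p, t = rng.normal(size=(2, 200))
        cov = np.mean((p - p.mean()) * (t - t.mean()))
        want = (cov / (p.std() * t.std())) ** 2
        assert r_squared(p, t) == pytest.approx(want, abs=1e-12)


class TestWeightedKappa:
    scale = GPScale(sex="male", classes=(60, 96, 120))

    def test_perfect_agreement(self):
        a = [60, 96, 120, 96]
        assert weighted_kappa(a, a, self.scale) == pytest.approx(1.0)

    def test_three_class_hand_example(self):
        # a=[c1,c1,c2,c3], b=[c1,c2,c2,c3]; quadratic penalty on indices
        a = [60, 60, 96, 120]
        b = [60, 96, 96, 120]
        obs = np.zeros((3, 3))
        for i, j in zip([0, 0, 1, 2], [0, 1, 1, 2]):
            obs[i, j] += 0.25
        exp = np.outer(obs.sum(1), obs.sum(0))
        pen = (np.subtract.outer(np.arange(3), np.arange(3)) / 2.0) ** 2
        want = 1 - (pen * obs).sum() / (pen * exp).sum()
        assert weighted_kappa(a, b, self.scale) == pytest.approx(want, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        classes = np.asarray(self.scale.classes)
        a = classes[rng.integers(0, 3, 500)]
        b = classes[rng.integers(0, 3, 500)]
        want = cohen_kappa_score(np.searchsorted(classes, a),
                                 np.searchsorted(classes, b),
                                 weights="quadratic")
        assert weighted_kappa(a, b, self.scale) == pytest.approx(want, abs=1e-9)

    def test_independent_shuffle_gives_near_zero(self):
        rng = np.random.default_rng(4)
        classes = np.asarray(self.scale.classes)
        kappas = []
        for _ in range(200):
            a = classes[rng.integers(0, 3, 300)]
            b = a.copy()
            rng.shuffle(b)
            kappas.append(weighted_kappa(a, b, self.scale))
        assert abs(np.mean(kappas)) < 0.02

    def test_label_outside_scale_rejected(self):
        with pytest.raises(InvalidInputError):
            weighted_kappa([60, 97], [60, 96], self.scale)


class TestClassAgreement:
    scale = GPScale(sex="male", classes=(60, 96, 120, 150))

    def test_exact(self):
        a = [60, 96, 120]
        assert class_agreement(a, a, self.scale, k=0) == 100.0

    def test_one_class_shift(self):
        a = [60, 96, 120]
        b = [96, 120, 150]
        assert class_agreement(a, b, self.scale, k=0) == 0.0
        assert class_agreement(a, b, self.scale, k=1) == 100.0

    def test_mixed_pairs_vs_manual_count(self):
        a = [60, 60, 96, 96, 120, 120, 150, 150, 60, 150]
        b = [60, 96, 96, 150, 60, 120, 60, 150, 120, 96]
        idx = {60: 0, 96: 1, 120: 2, 150: 3}
        for k in (0, 1, 2):
            manual = 100 * np.mean(
                [abs(idx[x] - idx[y]) <= k for x, y in zip(a, b)])
            assert class_agreement(a, b, self.scale, k=k) == pytest.approx(manual)


class TestDice:
    def test_identity_disjoint_empty(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((2, 2), bool), np.zeros((2, 2), bool)) == 1.0


class TestEvaluate:
    def test_perfect_predictions(self, male_scale):
        rng = np.random.default_rng(5)
        classes = np.asarray(male_scale.classes)
        y = classes[rng.integers(0, len(classes), 30)]
        recs = [PredictionRecord(id=str(i), sex="male", fh=v, seg_shortbones=v,
                                 seg_carpals=v, seg_wrist=v, y=v)
                for i, v in enumerate(y)]
        rep = evaluate(recs, y.astype(float), male_scale)
        assert rep.mad == 0 and rep.r2 == pytest.approx(1)
        assert rep.kappa == pytest.approx(1) and rep.pct_exact == 100.0

    def test_fields_match_component_metrics(self, male_scale):
        from digibone.synthdata import generate_prediction_table
        recs = generate_prediction_table(200, 0.5, 6, 6, male_scale, seed=1)
        pred = np.array([r.fh for r in recs])
        truth = np.array([r.y for r in recs])
        rep = evaluate(recs, pred, male_scale)
        snapped = snap_array(pred, male_scale)
        assert rep.mad == pytest.approx(mad(pred, truth))
        assert rep.rmse == pytest.approx(rmse(pred, truth))
        assert rep.r2 == pytest.approx(r_squared(pred, truth))
        assert rep.kappa == pytest.approx(weighted_kappa(snapped, truth, male_scale))
        assert rep.pct_within_1 == pytest.approx(
            class_agreement(snapped, truth, male_scale, k=1))
        assert rep.mad <= rep.rmse
        assert rep.loa_low <= rep.bias <= rep.loa_high

    def test_writes_plot_files(self, tmp_path, male_scale):
        from digibone.synthdata import generate_prediction_table
        recs = generate_prediction_table(30, 0.5, 6, 6, male_scale, seed=2)
        pred = np.array([r.fh for r in recs])
        evaluate(recs, pred, male_scale, plots_dir=tmp_path, plot_prefix="fh")
        assert (tmp_path / "fh_correlation.png").exists()
        assert (tmp_path / "fh_bland_altman.png").exists()
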