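import numpy as np
import pytest

from technome.qualification import (
    QualificationTensor,
    combine_q,
    compute_tensor,
    invivo_sign,
    q_insilico,
    q_invitro,
    q_invivo,
    q_orthog,
    select_qualified,
)
from technome.tables import (
    CohortLabels,
    RadiomeMatrix,
    SeriesRecord,
    SeriesTable,
    SurrogateMatrix,
)


def _mats(r, s, sur_names=None):
    n = r.shape[0]
    ids = [f"p{i}" for i in range(n)]
    sur_names = sur_names or [f"s{l}" for l in range(s.shape[1])]
    return (
        RadiomeMatrix(r, ids, [f"f{j}" for j in range(r.shape[1])]),
        SurrogateMatrix(s, ids, sur_names, {x: "cr" for x in sur_names}),
    )


class TestInVivo:
    def test_identical_columns_score_one(self):
        x = np.random.default_rng(0).normal(size=(20, 1))
        radiome, surrogates = _mats(x, x.copy())
        assert q_invivo(radiome, surrogates)[0, 0] == pytest.approx(1.0)

    def test_constant_surrogate_scores_zero(self):
        rng = np.random.default_rng(0)
        radiome, surrogates = _mats(rng.normal(size=(10, 1)), np.full((10, 1), 2.0))
        assert q_invivo(radiome, surrogates)[0, 0] == 0.0

    def test_too_few_rows_raise(self):
        radiome, surrogates = _mats(np.zeros((2, 1)), np.zeros((2, 1)))
        with pytest.raises(ValueError):
            q_invivo(radiome, surrogates)

    def test_null_pairs_rarely_exceed_point_one(self):
        # independent standard normals, n=1000: |rho| ~ 0.032, so < 0.1
        # for the vast majority of pairs
        rng = np.random.default_rng(1)
        radiome, surrogates = _mats(rng.normal(size=(1000, 20)), rng.normal(size=(1000, 50)))
        q = q_invivo(radiome, surrogates)
        assert (q < 0.1).mean() >= 0.99


def _perturbation(base_r, base_s, responses_r, responses_s, families=("gaussian", "rayleigh", "poisson", "gamma")):
    """Build a 4x5+baseline series from per-level response vectors."""
    radiome, surrogates = _mats(base_r, base_s)
    records = [SeriesRecord("baseline", radiome, surrogates, None, 0)]
    for fam in families:
        for level in range(1, 6):
            r = base_r + responses_r(fam, level)[None, :]
            s = base_s + responses_s(fam, level)[None, :]
            rm, sm = _mats(r, s)
            records.append(SeriesRecord(f"{fam}:{level}", rm, sm, fam, level))
    return SeriesTable("perturbation", records)


class TestInSilico:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.base_r = rng.normal(size=(8, 1))
        self.base_s = rng.normal(size=(8, 2))

    def test_perfect_monotone_coresponse_scores_one(self):
        series = _perturbation(
            self.base_r, self.base_s,
            lambda fam, lv: np.array([lv * 0.1]),
            lambda fam, lv: np.array([lv * 0.2, 0.0]),
        )
        sign = np.ones((1, 2))
        q = q_insilico(series, sign)
        assert q[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_unresponsive_surrogate_scores_zero(self):
        series = _perturbation(
            self.base_r, self.base_s,
            lambda fam, lv: np.array([lv * 0.1]),
            lambda fam, lv: np.zeros(2),
        )
        q = q_insilico(series, np.ones((1, 2)))
        assert q[0, 1] == 0.0

    def test_sign_mismatch_is_gated_to_zero(self):
        series = _perturbation(
            self.base_r, self.base_s,
            lambda fam, lv: np.array([lv * 0.1]),
            lambda fam, lv: np.array([-lv * 0.2, 0.0]),
        )
        q = q_insilico(series, np.ones((1, 2)))  # in-vivo sign positive
        assert q[0, 0] == 0.0

    def test_missing_baseline_raises(self):
        records = []
        rm, sm = _mats(self.base_r, self.base_s)
        records.append(SeriesRecord("gaussian:1", rm, sm, "gaussian", 1))
        records.append(SeriesRecord("gaussian:2", rm, sm, "gaussian", 2))
        series = SeriesTable("perturbation", records)
        with pytest.raises(ValueError):
            q_insilico(series, np.ones((1, 2)))


class TestInVitro:
    def _phantom(self, r_vals, s_vals):
        records = []
        for k, (r, s) in enumerate(zip(r_vals, s_vals)):
            rm, sm = _mats(np.atleast_2d(r), np.atleast_2d(s))
            records.append(SeriesRecord(f"protocol_{k}", rm, sm))
        return SeriesTable("phantom", records)

    def test_affine_surrogate_scores_one(self):
        p = np.linspace(-1, 1, 10)
        series = self._phantom(p[:, None], (3 * p + 1)[:, None])
        assert q_invitro(series)[0, 0] == pytest.approx(1.0)

    def test_protocol_independent_surrogate_scores_low(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            p = rng.normal(size=20)
            series = self._phantom(p[:, None], rng.normal(size=20)[:, None])
            hits += q_invitro(series)[0, 0] < 0.5
        assert hits >= 36  # ~95% of null draws

    def test_single_condition_raises(self):
        series = self._phantom([[0.0]], [[0.0]])
        with pytest.raises(ValueError):
            q_invitro(series)


class TestOrthogonality:
    def test_surrogate_equal_to_label_scores_zero(self):
        b = np.array([0, 1] * 10)
        _, surrogates = _mats(np.zeros((20, 1)) + np.arange(20)[:, None], b[:, None].astype(float))
        labels = CohortLabels(b, [f"p{i}" for i in range(20)])
        assert q_orthog(surrogates, labels)[0, 0] == pytest.approx(0.0)

    def test_independent_surrogate_scores_high(self):
        rng = np.random.default_rng(4)
        highs = 0
        for _ in range(30):
            b = rng.integers(0, 2, 1000)
            _, surrogates = _mats(np.zeros((1000, 1)), rng.normal(size=(1000, 1)))
            labels = CohortLabels(b, [f"p{i}" for i in range(1000)])
            highs += q_orthog(surrogates, labels)[0, 0] > 0.9
        assert highs >= 29

    def test_constant_surrogate_scores_one_by_convention(self):
        b = np.array([0, 1] * 5)
        _, surrogates = _mats(np.zeros((10, 1)), np.full((10, 1), 7.0))
        labels = CohortLabels(b, [f"p{i}" for i in range(10)])
        assert q_orthog(surrogates, labels)[0, 0] == 1.0

    def test_single_class_raises(self):
        _, surrogates = _mats(np.zeros((10, 1)), np.random.default_rng(0).normal(size=(10, 1)))
        labels = CohortLabels(np.zeros(10, dtype=int), [f"p{i}" for i in range(10)])
        with pytest.raises(ValueError):
            q_orthog(surrogates, labels)

    def test_complement_identity_with_point_biserial(self):
        rng = np.random.default_rng(5)
        b = rng.integers(0, 2, 200)
        s = 0.5 * b + rng.normal(size=200)
        _, surrogates = _mats(np.zeros((200, 1)), s[:, None])
        labels = CohortLabels(b, [f"p{i}" for i in range(200)])
        pb = np.corrcoef(s, b)[0, 1]
        assert q_orthog(surrogates, labels)[0, 0] + abs(pb) == pytest.approx(1.0, abs=1e-12)


class TestCombineAndSelect:
    def _tensor(self, values):
        scores = {
            crit: np.full((1, 1), val)
            for crit, val in zip(("invivo", "insilico", "invitro", "orthog"), values)
        }
        return QualificationTensor(scores, ["f0"], ["s0"])

    def test_weighted_sum_arithmetic(self):
        tensor = self._tensor((0.9, 0.8, 0.1, 1.0))
        theta = {"invivo": 1.0, "insilico": 0.5, "invitro": 0.0, "orthog": 0.2}
        assert combine_q(tensor, theta)[0, 0] == pytest.approx(1.5)

    def test_uniform_half_scores_sum_to_two(self):
        tensor = self._tensor((0.5, 0.5, 0.5, 0.5))
        theta = dict.fromkeys(("invivo", "insilico", "invitro", "orthog"), 1.0)
        assert combine_q(tensor, theta)[0, 0] == pytest.approx(2.0)

    def test_zero_weights_give_zero_and_empty_sets(self):
        tensor = self._tensor((0.9, 0.9, 0.9, 0.9))
        theta = dict.fromkeys(("invivo", "insilico", "invitro", "orthog"), 0.0)
        Q = combine_q(tensor, theta)
        assert Q[0, 0] == 0.0
        assert select_qualified(Q).all_empty

    def test_negative_weight_raises(self):
        tensor = self._tensor((0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            combine_q(tensor, {"invivo": -1.0})

    def test_selection_is_strictly_above_threshold(self):
        sets = select_qualified(np.array([[1.5, 1.0, 0.99]]), q_min=1.0)
        assert list(sets.sets[0]) == [0]

    def test_monotone_in_theta(self):
        # raising any weight can only grow the qualified sets
        rng = np.random.default_rng(6)
        scores = {c: rng.uniform(size=(3, 8)) for c in ("invivo", "insilico", "invitro", "orthog")}
        tensor = QualificationTensor(scores, ["a", "b", "c"], [f"s{l}" for l in range(8)])
        for _ in range(30):
            theta = {c: rng.uniform(0, 3) for c in scores}
            bumped = dict(theta)
            crit = rng.choice(list(scores))
            bumped[crit] += rng.uniform(0, 2)
            before = select_qualified(combine_q(tensor, theta))
            after = select_qualified(combine_q(tensor, bumped))
            for s_before, s_after in zip(before.sets, after.sets):
                assert set(s_before) <= set(s_after)

    def test_scores_bounded_by_four_at_unit_weights(self):
        rng = np.random.default_rng(7)
        scores = {c: rng.uniform(size=(2, 5)) for c in ("invivo", "insilico", "invitro", "orthog")}
        tensor = QualificationTensor(scores, ["a", "b"], [f"s{l}" for l in range(5)])
        Q = combine_q(tensor, dict.fromkeys(scores, 1.0))
        assert Q.max() <= 4.0


class TestComputeTensor:
    def test_degenerate_columns_zeroed_and_flagged(self, preset_cohort):
        cohort, truth, series = preset_cohort
        sur = cohort.surrogates
        values = sur.values.copy()
        values[:, 0] = 1.0
        from technome.tables import SurrogateMatrix

        flat = SurrogateMatrix(values, sur.patient_ids, sur.surrogate_names, sur.cr_of)
        tensor = compute_tensor(cohort.radiome, flat, labels=cohort.labels, active=("invivo", "orthog"))
        assert not tensor.valid[0]
        assert tensor.get("invivo")[:, 0].max() == 0.0
        assert tensor.get("orthog")[:, 0].max() == 0.0

    def test_genuine_surrogates_outscore_decoys(self, preset_cohort):
        cohort, truth, series = preset_cohort
        tensor = compute_tensor(
            cohort.radiome, cohort.surrogates, labels=cohort.labels,
            perturbation=series["perturbation"], phantom=series["phantom"],
        )
        prod = tensor.get("invivo") * tensor.get("orthog")
        clean = truth.role_indices("clean")
        leak = truth.role_indices("bioleak")
        assert prod[:, clean].mean() - prod[:, leak].mean() >= 0.2

    def test_long_frame_export_shape(self, preset_cohort):
        cohort, truth, series = preset_cohort
        tensor = compute_tensor(cohort.radiome, cohort.surrogates, labels=cohort.labels,
                                active=("invivo", "orthog"))
        df = tensor.to_long_frame()
        assert set(df.columns) == {"feature", "surrogate", "criterion", "score"}
        assert len(df) == 2 * 2 * 84
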