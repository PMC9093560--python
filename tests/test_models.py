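"""Expected-prediction formulas of every model in the zoo."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from newsreason.data_model import FeatureError, Group, ItemClass, Response, Truth
from newsreason.feature_prep import PartisanshipBands, SentimentSelection
from newsreason.models import (
    CRParams,
    CRTimeParams,
    MoodParams,
    MS2RParams,
    PartyParams,
    RecognitionParams,
    SentimentParams,
    VanBavelParams,
    clip_unit,
    predict_baseline,
    predict_cr,
    predict_cr_time,
    predict_item_mean,
    predict_mood,
    predict_ms2r,
    predict_party,
    predict_recognition,
    predict_sentiments,
    predict_van_bavel,
)

from conftest import A, R, build_dataset, make_item, make_participant

BANDS = PartisanshipBands(neutral_halfwidth=0.5, scale=(1.0, 5.0))


def _p(crt=0.5, group=Group.REP, **kw):
    p = make_participant(crt=crt, **kw)
    p.group = group
    return p


class TestClipUnit:
    @pytest.mark.parametrize("x, expected", [(1.2, 1.0), (-0.3, 0.0), (0.5, 0.5)])
    def test_cases(self, x, expected):
        assert clip_unit(x) == expected

    @pytest.mark.parametrize("x", [float("nan"), float("inf")])
    def test_non_finite_rejected(self, x):
        with pytest.raises(ValueError):
            clip_unit(x)

    @given(st.floats(allow_nan=False, allow_infinity=False))
    @settings(deadline=None, max_examples=100)
    def test_always_in_unit_interval(self, x):
        assert 0.0 <= clip_unit(x) <= 1.0


class TestCR:
    @pytest.mark.parametrize("params, crt, truth, expected", [
        ((0.6, 0.2, 0.0, 0.0), 0.5, Truth.REAL, 0.7),
        ((0.0, 0.0, 0.4, -0.4), 0.0, Truth.FAKE, 0.4),
        ((1.1, 0.5, 0.0, 0.0), 1.0, Truth.REAL, 1.0),  # clipped
    ])
    def test_formula(self, params, crt, truth, expected):
        p = CRParams(*params)
        got = predict_cr(make_item(truth=truth), _p(crt=crt), p)
        assert got == pytest.approx(expected)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_crt_for_positive_alpha(self, c1, c2):
        lo, hi = sorted([c1, c2])
        p = CRParams(0.3, 0.5, 0.0, 0.0)
        item = make_item(truth=Truth.REAL)
        assert predict_cr(item, _p(crt=lo), p) <= predict_cr(item, _p(crt=hi), p)


class TestCRTime:
    BASE = CRParams(0.5, 0.0, 0.5, 0.0)

    def _trial(self, reac):
        from newsreason.data_model import Trial
        return Trial("p", "i", Response.ACCEPT, reaction_time=reac, reaction_z=reac)

    def test_zero_alpha_equals_cr(self):
        p = CRTimeParams(self.BASE, 0.0, 0.0)
        item = make_item(truth=Truth.REAL)
        assert predict_cr_time(item, _p(), self._trial(2.0), p) == \
            predict_cr(item, _p(), self.BASE)

    def test_zero_reaction_equals_cr(self):
        p = CRTimeParams(self.BASE, 0.7, 0.7)
        item = make_item(truth=Truth.FAKE)
        assert predict_cr_time(item, _p(), self._trial(0.0), p) == \
            predict_cr(item, _p(), self.BASE)

    def test_additive_arithmetic(self):
        p = CRTimeParams(self.BASE, 0.1, 0.0)
        got = predict_cr_time(make_item(truth=Truth.REAL), _p(), self._trial(2.0), p)
        assert got == pytest.approx(0.7)

    def test_multiplicative_variant(self):
        p = CRTimeParams(self.BASE, 0.5, 0.5)
        got = predict_cr_time(make_item(truth=Truth.REAL), _p(), self._trial(2.0), p,
                              variant="multiplicative")
        assert got == pytest.approx(0.25)


class TestMS2R:
    def test_neutral_item_exactly_half_regardless_of_params(self):
        item = make_item(part=3.0)
        item.item_class = ItemClass.NEUTRAL
        p = MS2RParams(0.9, 0.9, 0.1, 0.1)
        assert predict_ms2r(item, _p(crt=1.0), p) == 0.5

    def test_matched_and_mismatched_branches(self):
        p = MS2RParams(0.5, 0.3, 0.5, -0.3)
        item = make_item(part=4.6)
        item.item_class = ItemClass.REP
        assert predict_ms2r(item, _p(crt=1.0, group=Group.REP), p) == pytest.approx(0.8)
        assert predict_ms2r(item, _p(crt=1.0, group=Group.DEM), p) == pytest.approx(0.2)

    @given(st.floats(0, 1), st.booleans())
    @settings(deadline=None, max_examples=50)
    def test_equal_params_ignore_matching(self, crt, matched):
        """With kappa_C=kappa_N and alpha_C=alpha_N the congruence is irrelevant."""
        p = MS2RParams(0.4, 0.2, 0.4, 0.2)
        item = make_item(part=4.6)
        item.item_class = ItemClass.REP
        group = Group.REP if matched else Group.DEM
        expected = clip_unit(0.4 + 0.2 * crt)
        assert predict_ms2r(item, _p(crt=crt, group=group), p) == pytest.approx(expected)


class TestMood:
    BASE = CRParams(0.5, 0.0, 0.5, 0.0)

    def _mood_p(self, pp, pn):
        return _p(panas_p=pp, panas_n=pn)

    def test_balanced_mood_equals_cr(self):
        p = MoodParams(self.BASE, 0.3, 0.3)
        item = make_item(truth=Truth.REAL)
        for variant in ("SUPPRESSION", "IMPROVEMENT"):
            assert predict_mood(item, self._mood_p(2.0, 2.0), p, variant) == 0.5

    def test_suppression_symmetric_under_swap(self):
        p = MoodParams(self.BASE, 0.1, 0.1)
        item = make_item(truth=Truth.REAL)
        assert predict_mood(item, self._mood_p(3.0, 1.0), p, "SUPPRESSION") == \
            predict_mood(item, self._mood_p(1.0, 3.0), p, "SUPPRESSION")

    def test_signed_vs_absolute_difference(self):
        p = MoodParams(self.BASE, 0.1, 0.1)
        item = make_item(truth=Truth.REAL)
        person = self._mood_p(1.0, 2.0)  # diff = -1
        assert predict_mood(item, person, p, "SUPPRESSION") == pytest.approx(0.6)
        assert predict_mood(item, person, p, "IMPROVEMENT") == pytest.approx(0.4)

    def test_variants_coincide_when_positive_dominates(self):
        p = MoodParams(self.BASE, 0.07, 0.07)
        item = make_item(truth=Truth.FAKE)
        person = self._mood_p(4.0, 1.0)
        assert predict_mood(item, person, p, "SUPPRESSION") == \
            predict_mood(item, person, p, "IMPROVEMENT")

    def test_absent_panas_raises(self):
        p = MoodParams(self.BASE, 0.1, 0.1)
        with pytest.raises(FeatureError):
            predict_mood(make_item(), _p(), p, "SUPPRESSION")


class TestRecognition:
    def test_threshold_fires_above(self):
        p = RecognitionParams(kappa_i=1.5)
        assert predict_recognition(make_item(fam=2.0), _p(), p, "THRESHOLD") == 1.0

    def test_threshold_strict_at_boundary(self):
        p = RecognitionParams(kappa_i=1.5)
        assert predict_recognition(make_item(fam=1.5), _p(), p, "THRESHOLD") == 0.0

    def test_linear_form(self):
        p = RecognitionParams(kappa_i=0.2, alpha_i=0.3)
        assert predict_recognition(make_item(fam=1.0), _p(), p, "LINEAR") == \
            pytest.approx(0.5)

    def test_threshold_is_single_jump_step(self):
        """Non-decreasing in familiarity with exactly one jump at kappa."""
        p = RecognitionParams(kappa_i=2.0)
        fams = np.linspace(1.0, 3.0, 41)
        out = [predict_recognition(make_item(fam=f), _p(), p, "THRESHOLD")
               for f in fams]
        jumps = np.diff(out)
        assert np.all(jumps >= 0)
        assert np.sum(jumps > 0) == 1

    def test_own_group_familiarity_used(self):
        item = make_item(fam_rep=2.5, fam_dem=1.0, fam_mean=1.75)
        p = RecognitionParams(kappa_i=2.0)
        assert predict_recognition(item, _p(group=Group.REP), p, "THRESHOLD") == 1.0
        assert predict_recognition(item, _p(group=Group.DEM), p, "THRESHOLD") == 0.0


class TestSentiments:
    SEL = SentimentSelection(k=2, categories=["a", "b"])

    def test_zero_vector_accepts_boundary_inclusive(self):
        item = make_item(sentiments=np.zeros(2))
        assert predict_sentiments(item, SentimentParams(np.array([1.0, -1.0])),
                                  self.SEL) == 1.0

    def test_negative_sum_rejects(self):
        item = make_item(sentiments=np.array([1.0, 0.0]))
        assert predict_sentiments(item, SentimentParams(np.array([-0.5, 3.0])),
                                  self.SEL) == 0.0

    def test_sign_symmetry_flips_non_boundary(self, rng):
        for _ in range(20):
            s = rng.uniform(0, 1, 2)
            w = rng.normal(size=2)
            if abs(s @ w) < 1e-12:
                continue
            item = make_item(sentiments=s)
            a = predict_sentiments(item, SentimentParams(w), self.SEL)
            b = predict_sentiments(item, SentimentParams(-w), self.SEL)
            assert a != b

    def test_length_mismatch_raises(self):
        item = make_item(sentiments=np.zeros(3))
        with pytest.raises(ValueError):
            predict_sentiments(item, SentimentParams(np.zeros(2)), self.SEL)


class TestParty:
    def test_truth_oracle_at_degenerate_params(self):
        p = PartyParams(1.0, 0.0, 0.0, 0.0)
        assert predict_party(make_item(truth=Truth.REAL), p) == 1.0
        assert predict_party(make_item(truth=Truth.FAKE), p) == 0.0

    def test_linear_form(self):
        p = PartyParams(0.5, 0.1, 0.0, 0.0)
        assert predict_party(make_item(truth=Truth.REAL, part=2.0), p) == \
            pytest.approx(0.7)

    def test_all_zero_params(self):
        p = PartyParams(0.0, 0.0, 0.0, 0.0)
        assert predict_party(make_item(truth=Truth.REAL, part=4.0), p) == 0.0


class TestVanBavel:
    def _vb(self, **kw):
        base = dict(alpha=0, kappa_R=0, beta_R=0, gamma_R=0,
                    kappa_F=0, beta_F=0, gamma_F=0, kappa_p=0)
        base.update(kw)
        return VanBavelParams(**base)

    def test_all_zero(self):
        item = make_item(part=4.6)
        item.item_class = ItemClass.REP
        assert predict_van_bavel(item, _p(), self._vb()) == 0.0

    def test_matched_adds_exactly_kappa_p(self):
        item = make_item(part=4.6, fam=1.0)
        item.item_class = ItemClass.REP
        p = self._vb(kappa_R=0.3, kappa_p=0.25)
        matched = predict_van_bavel(item, _p(group=Group.REP), p)
        unmatched = predict_van_bavel(item, _p(group=Group.DEM), p)
        assert matched - unmatched == pytest.approx(0.25)

    def test_familiarity_term(self):
        item = make_item(part=3.0, fam=1.0, truth=Truth.REAL)
        item.item_class = ItemClass.NEUTRAL
        p = self._vb(alpha=0.5, kappa_R=0.2)
        assert predict_van_bavel(item, _p(), p) == pytest.approx(0.7)


class TestBaselines:
    def test_random_half(self):
        assert predict_baseline(make_item(), "RANDOM") == 0.5

    def test_always_reject_zero(self):
        assert predict_baseline(make_item(), "ALWAYS_REJECT") == 0.0

    def test_correct_categorization(self):
        assert predict_baseline(make_item(truth=Truth.FAKE),
                                "CORRECT_CATEGORIZATION") == 0.0
        assert predict_baseline(make_item(truth=Truth.REAL),
                                "CORRECT_CATEGORIZATION") == 1.0


class TestItemMean:
    def test_leave_one_out_counting(self):
        ps = [make_participant(f"p{k}", conservatism=float(k)) for k in range(5)]
        items = [make_item("i1"), make_item("i2", fam=1.0)]
        responses = [[A, R], [A, R], [A, R], [R, A], [A, A]]
        ds = build_dataset(ps, items, responses)
        # item i1: others of p3 are A,A,A,A -> 1.0; others of p0 are A,A,R,A -> 0.75
        assert predict_item_mean(items[0], ps[3], ds) == 1.0
        assert predict_item_mean(items[0], ps[0], ds) == 0.75

    def test_matches_brute_force_on_random_grid(self, rng):
        ps = [make_participant(f"p{k}", conservatism=float(k % 7)) for k in range(10)]
        items = [make_item(f"i{j}", fam=1.0 + j * 0.1) for j in range(10)]
        responses = [[A if rng.random() < 0.5 else R for _ in items] for _ in ps]
        ds = build_dataset(ps, items, responses)
        for a in range(10):
            for j in range(10):
                others = [responses[b][j] for b in range(10) if b != a]
                expected = sum(r is A for r in others) / len(others)
                assert predict_item_mean(items[j], ps[a], ds) == pytest.approx(expected)


class TestVectorizedAgainstScalar:
    """The vectorized model layer must agree with the scalar formulas."""

    def test_registry_models_stay_in_unit_interval(self, rng):
        from newsreason.synthetic import SyntheticConfig, generate_dataset
        from newsreason.models import make_model, MODEL_REGISTRY
        import newsreason.fft  # noqa: F401

        cfg = SyntheticConfig(n_participants=8, seed=3)
        ds, _ = generate_dataset(cfg)
        for name in ("cr", "ms2r", "recognition", "recognition_linear",
                     "van_bavel", "sentiments", "party"):
            m = make_model(name).bind(ds)
            params = rng.normal(size=m.n_params)
            p = m.predict_vec(params, np.arange(m.table.n_trials))
            assert np.all(p >= 0.0) and np.all(p <= 1.0), name

    def test_van_bavel_vector_matches_scalar(self, rng):
        from newsreason.synthetic import SyntheticConfig, generate_dataset
        from newsreason.models import make_model

        ds, _ = generate_dataset(SyntheticConfig(n_participants=5, seed=9))
        m = make_model("van_bavel").bind(ds)
        params = rng.normal(size=8)
        vp = VanBavelParams(*params)
        vec = m.predict_vec(params, np.arange(m.table.n_trials))
        for k, t in enumerate(ds.trials[:40]):
            item = ds.items[t.item_id]
            person = ds.participants[t.participant_id]
            assert vec[k] == pytest.approx(predict_van_bavel(item, person, vp))
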