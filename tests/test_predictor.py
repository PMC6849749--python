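"""Distribution combination, joint likelihood, and IC profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melexp.ppm import Distribution
from melexp.predictor import (CombinationConfig, Predictor, betting_ic,
                              combine, joint_event_probability, train_ltm)
from melexp.synthetic import CultureSpec, generate_culture
from melexp.viewpoints import ConfigurationError
from conftest import make_melody


def _dist(**mass):
    return Distribution(mass)


class TestCombine:
    def test_identical_inputs_are_a_fixed_point(self):
        d = _dist(a=0.3, b=0.7)
        for scheme in ("arithmetic", "geometric"):
            out = combine([d, d, d], b=2.0, scheme=scheme)
            for s in "ab":
                assert math.isclose(out[s], d[s], abs_tol=1e-12)

    def test_certain_model_dominates_uniform(self):
        sharp = _dist(a=0.98, b=0.01, c=0.01)
        flat = _dist(a=1 / 3, b=1 / 3, c=1 / 3)
        out = combine([sharp, flat], b=1.0)
        kl_sharp = sum(out[s] * math.log2(out[s] / sharp[s]) for s in "abc")
        kl_flat = sum(out[s] * math.log2(out[s] / flat[s]) for s in "abc")
        assert kl_sharp < kl_flat

    def test_two_symbol_hand_computation(self):
        # independent arithmetic for the weighting rule, b = 1:
        # H1 = -(0.9 lg 0.9 + 0.1 lg 0.1), H2 = 1 bit, Hmax = 1 bit
        h1 = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        w1_raw, w2_raw = (h1 / 1.0) ** -1.0, 1.0
        w1 = w1_raw / (w1_raw + w2_raw)
        expected_a = w1 * 0.9 + (1 - w1) * 0.5
        out = combine([_dist(a=0.9, b=0.1), _dist(a=0.5, b=0.5)], b=1.0)
        assert math.isclose(out["a"], expected_a, abs_tol=1e-12)
        assert math.isclose(out["b"], 1 - expected_a, abs_tol=1e-12)

    def test_mismatched_alphabets_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            combine([_dist(a=1.0), _dist(b=1.0)])

    def test_geometric_renormalises(self):
        out = combine([_dist(a=0.9, b=0.1), _dist(a=0.2, b=0.8)],
                      b=2.0, scheme="geometric")
        assert math.isclose(out["a"] + out["b"], 1.0, abs_tol=1e-12)


class TestJointAndBetting:
    def test_joint_probability_is_the_product(self):
        assert joint_event_probability(1.0, 1.0) == 1.0
        assert math.isclose(joint_event_probability(0.5, 0.5), 0.25)
        # 0.25 joint likelihood = 2 bits = 1 + 1
        assert math.isclose(-math.log2(joint_event_probability(0.5, 0.5)), 2.0)

    def test_joint_mean_ic_additivity_of_reported_means(self):
        # additivity holds for the printed per-model means as well
        assert math.isclose(2.44 + 1.49, 3.93)
        assert abs((6.53 + 2.86) - 9.39) <= 0.005 + 1e-12

    def test_zero_probability_rejected(self):
        with pytest.raises(ValueError):
            joint_event_probability(0.0, 0.5)

    @pytest.mark.parametrize("capital,expected", [
        (20.0, 0.0), (10.0, 1.0), (1.0, math.log2(20))])
    def test_betting_capital_to_bits(self, capital, expected):
        assert math.isclose(betting_ic(capital), expected, abs_tol=1e-12)

    def test_betting_requires_positive_capital(self):
        with pytest.raises(ValueError):
            betting_ic(0.0)


class TestProfiles:
    def test_single_event_untrained_is_uniform(self):
        m = make_melody([60], melody_id="one", tonic=60)
        predictor = Predictor(CombinationConfig(
            pitch_viewpoints=("pitch",), onset_viewpoints=(),
            subsystems=("stm",)), pitch_alphabet=range(60, 72))
        prof = predictor.profile(m)
        rec = prof.records["pitch"][0]
        assert math.isclose(rec.p, 1 / 12)
        assert math.isclose(rec.H, math.log2(12))

    def test_repetition_drives_stm_ic_down(self):
        m = make_melody([60] * 6, melody_id="ccccc", tonic=60)
        predictor = Predictor(CombinationConfig(
            pitch_viewpoints=("pitch",), onset_viewpoints=(),
            subsystems=("stm",)), pitch_alphabet=range(55, 66))
        ics = predictor.profile(m).ics("pitch")
        assert all(b < a for a, b in zip(ics[1:], ics[2:]))
        assert ics[-1] < ics[1]

    def test_joint_ic_is_sum_of_attribute_ics(self, small_corpus):
        predictor = train_ltm(small_corpus, CombinationConfig())
        m = small_corpus["a"]
        prof = predictor.profile(m)
        joint = prof.ics("joint")
        split = [p.h + o.h for p, o in zip(prof.records["pitch"],
                                           prof.records["onset"])]
        assert joint == pytest.approx(split, abs=1e-12)
        assert math.isclose(prof.mean_ic("joint"),
                            prof.mean_ic("pitch") + prof.mean_ic("onset"),
                            abs_tol=1e-9)

    def test_sd_config_requires_tonic(self, small_corpus):
        m = make_melody([60, 62, 64], melody_id="untonicked")
        predictor = train_ltm(small_corpus)
        with pytest.raises(ConfigurationError, match="tonic"):
            predictor.profile(m)

    def test_profile_rows_export(self, small_corpus):
        predictor = train_ltm(small_corpus)
        m = small_corpus["b"]
        rows = predictor.profile(m).to_rows(m)
        assert len(rows) == len(m)
        assert {"melody_id", "index", "onset", "pitch", "ic_joint_bits",
                "ic_pitch_bits", "entropy_pitch_bits"} <= set(rows[0])

    def test_serialization_preserves_predictions(self, small_corpus):
        predictor = train_ltm(small_corpus)
        clone = Predictor.from_json(predictor.to_json())
        m = small_corpus["c"]
        assert clone.profile(m).ics("joint") == \
            pytest.approx(predictor.profile(m).ics("joint"), abs=1e-12)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.integers(58, 66), min_size=1, max_size=8),
       st.sampled_from(["arithmetic", "geometric"]),
       st.floats(0.5, 4.0))
def test_profile_records_are_consistent(pitches, scheme, b):
    """Every emitted record normalises, h = −log2 p, and entropy lies in
    [0, log2 |alphabet|]."""
    m = make_melody(pitches, melody_id="prop", tonic=60)
    cfg = CombinationConfig(pitch_viewpoints=("pitch", "sd"),
                            onset_viewpoints=("ioi",),
                            subsystems=("stm",), scheme=scheme, b=b)
    prof = Predictor(cfg, pitch_alphabet=range(55, 70),
                     ioi_alphabet=[12, 24, 48]).profile(m)
    for records in prof.records.values():
        for rec in records:
            total = math.fsum(p for _, p in rec.distribution.items())
            assert math.isclose(total, 1.0, abs_tol=1e-9)
            assert math.isclose(rec.h, -math.log2(rec.p), abs_tol=1e-9)
            assert -1e-9 <= rec.H <= math.log2(len(rec.distribution)) + 1e-9


def test_ltm_mean_ic_approaches_chain_entropy_rate():
    """Trained on a first-order chain, mean IC converges to the source's
    entropy rate (Monte-Carlo check on long synthetic corpora)."""
    transition = ((0.7, 0.2, 0.1),
                  (0.1, 0.8, 0.1),
                  (0.3, 0.3, 0.4))
    spec = CultureSpec(
        name="chain", degrees=(0, 4, 7),
        transition=transition, initial=(1 / 3, 1 / 3, 1 / 3),
        ratios=(__import__("fractions").Fraction(1),),
        ratio_transition=((1.0,),), ratio_initial=(1.0,),
        length_range=(60, 60))
    # stationary distribution and entropy rate of the generator
    t = np.array(transition)
    evals, evecs = np.linalg.eig(t.T)
    pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
    pi /= pi.sum()
    rate = -(pi[:, None] * t * np.log2(t)).sum()

    train = generate_culture(spec, 120, seed=5)
    test = generate_culture(spec, 30, seed=6)
    cfg = CombinationConfig(pitch_viewpoints=("pitch",), onset_viewpoints=(),
                            subsystems=("ltm",), ltm_order_bound=1)
    predictor = Predictor(cfg).train(train)
    mean_ic = np.mean([predictor.mean_ic(m, "pitch") for m in test])
    # smoothing overhead and the unpredictable first note keep mean IC a
    # little above the rate; both shrink as O(1/n)
    assert rate - 0.05 < mean_ic < rate + 0.25
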