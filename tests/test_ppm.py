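"""The variable-order model: counting, smoothing, online updates."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from melexp.ppm import ContextModel, Distribution
from melexp.viewpoints import UNDEFINED


# --------------------------------------------------------------------------
# Independent oracle: the interpolated escape-C recursion written directly
# against raw training data, with no shared code.
# --------------------------------------------------------------------------

def oracle_distribution(sequences, alphabet, context, order_bound=None):
    def ngram_counts(ctx):
        bucket = {}
        k = len(ctx)
        for seq in sequences:
            for i in range(k, len(seq)):
                if tuple(seq[i - k:i]) == tuple(ctx):
                    bucket[seq[i]] = bucket.get(seq[i], 0) + 1
        return bucket

    def rec(ctx):
        if ctx is None:
            return {s: 1.0 / len(alphabet) for s in alphabet}
        lower = rec(tuple(ctx[1:]) if ctx else None)
        bucket = ngram_counts(ctx)
        if not bucket:
            return lower
        n = sum(bucket.values())
        t = len(bucket)
        return {s: bucket.get(s, 0) / (n + t) + t / (n + t) * lower[s]
                for s in alphabet}

    ctx = tuple(context)
    if order_bound is not None:
        ctx = ctx[len(ctx) - min(len(ctx), order_bound):]
    dist = rec(ctx)
    z = sum(dist.values())
    return {s: p / z for s, p in dist.items()}


class TestTraining:
    def test_first_order_counts(self):
        model = ContextModel(order_bound=1).train([["a", "b", "a"]])
        assert model.counts == {(): {"a": 2, "b": 1},
                                ("a",): {"b": 1}, ("b",): {"a": 1}}

    def test_training_twice_doubles_counts(self):
        once = ContextModel(order_bound=2).train([["a", "b", "a"]])
        twice = ContextModel(order_bound=2).train([["a", "b", "a"]] * 2)
        assert twice.counts == {ctx: {s: 2 * n for s, n in bucket.items()}
                                for ctx, bucket in once.counts.items()}

    def test_undefined_positions_skipped(self):
        with_bot = ContextModel(order_bound=2).train([[UNDEFINED, 4, 3]])
        without = ContextModel(order_bound=2).train([[4, 3]])
        assert with_bot.counts == without.counts
        assert UNDEFINED not in with_bot.alphabet


class TestPredict:
    def test_untrained_is_uniform(self):
        model = ContextModel(alphabet="abc", order_bound=2)
        dist = model.predict(("a",))
        assert all(math.isclose(dist[s], 1 / 3) for s in "abc")

    def test_matches_oracle_on_worked_example(self):
        data = [["a", "b", "a", "b", "a"]]
        model = ContextModel(order_bound=2).train(data)
        expected = oracle_distribution(data, model.alphabet, ("b",), 2)
        dist = model.predict(("b",))
        for s in model.alphabet:
            assert math.isclose(dist[s], expected[s], abs_tol=1e-12)

    def test_unseen_prefix_falls_back_to_longest_seen_suffix(self):
        model = ContextModel(order_bound=3).train([["a", "b", "a", "b"]])
        model.declare("x")
        long = model.predict(("x", "b"))
        short = model.predict(("b",))
        for s in model.alphabet:
            assert math.isclose(long[s], short[s], abs_tol=1e-12)

    def test_empty_alphabet_is_an_error(self):
        with pytest.raises(RuntimeError, match="alphabet"):
            ContextModel().predict(())

    def test_restricted_prediction_consistent_with_full(self):
        model = ContextModel(order_bound=2).train([["a", "b", "a", "c"]])
        full = model.predict(("a",))
        restricted = model.predict_over(model.alphabet, ("a",))
        for s in model.alphabet:
            assert math.isclose(full[s], restricted[s], abs_tol=1e-12)


def test_oracle_equivalence_randomised():
    """predict() equals the brute-force recursion for all short contexts
    over random training sets (alphabets of up to 4 symbols)."""
    rng = random.Random(7)
    for trial in range(30):
        alphabet = "abcd"[:rng.randint(2, 4)]
        data = [[rng.choice(alphabet) for _ in range(rng.randint(3, 12))]
                for _ in range(rng.randint(1, 4))]
        bound = rng.choice([1, 2, 3, None])
        model = ContextModel(alphabet=alphabet, order_bound=bound).train(data)
        for length in range(4):
            for ctx in itertools.product(alphabet, repeat=length):
                expected = oracle_distribution(data, model.alphabet, ctx, bound)
                got = model.predict(ctx)
                for s in model.alphabet:
                    assert math.isclose(got[s], expected[s], abs_tol=1e-9), \
                        (trial, ctx, s)


class TestOnline:
    def test_prediction_precedes_update(self):
        stm = ContextModel(alphabet="ab", order_bound=2, mode="online")
        first = stm.predict(())
        assert math.isclose(first["a"], 0.5)
        stm.update_online("a", ())
        assert stm.counts == {(): {"a": 1}}
        assert stm.predict(())["a"] > 0.5

    def test_online_processing_equals_batch_counts(self):
        seq = ["a", "b", "b", "a", "c", "a"]
        stm = ContextModel(order_bound=2, mode="online")
        for i, sym in enumerate(seq):
            stm.update_online(sym, seq[:i])
        batch = ContextModel(order_bound=2).train([seq])
        assert stm.counts == batch.counts

    def test_reset_empties_counts(self):
        stm = ContextModel(order_bound=1, mode="online")
        stm.update_online("a", ())
        stm.reset()
        assert stm.counts == {}

    def test_static_model_rejects_online_update(self):
        with pytest.raises(RuntimeError, match="online"):
            ContextModel(mode="static").update_online("a", ())


@settings(deadline=None, max_examples=60)
@given(st.lists(st.lists(st.sampled_from("abcd"), min_size=1, max_size=10),
                min_size=1, max_size=4),
       st.lists(st.sampled_from("abcd"), max_size=3),
       st.sampled_from([0, 1, 2, 3, None]))
def test_predict_normalises_with_full_support(data, context, bound):
    model = ContextModel(alphabet="abcd", order_bound=bound).train(data)
    dist = model.predict(context)
    assert math.isclose(sum(p for _, p in dist.items()), 1.0, abs_tol=1e-9)
    assert all(p > 0 for _, p in dist.items())
    assert 0.0 <= dist.entropy() <= math.log2(len(model.alphabet)) + 1e-9


@settings(deadline=None, max_examples=40)
@given(st.lists(st.lists(st.sampled_from("abc"), min_size=1, max_size=8),
                min_size=1, max_size=3),
       st.lists(st.sampled_from("abc"), max_size=2),
       st.sampled_from("abc"))
def test_observation_strictly_increases_its_probability(data, context, sym):
    model = ContextModel(alphabet="abc", order_bound=3, mode="online")
    model.train(data)
    before = model.predict(context)[sym]
    model.update_online(sym, context)
    assert model.predict(context)[sym] > before


class TestSerialization:
    def test_json_round_trip(self):
        from fractions import Fraction
        model = ContextModel(order_bound=2).train(
            [[(0, Fraction(1, 2)), (2, Fraction(3, 2)), (0, Fraction(1, 2))]])
        back = ContextModel.from_json(model.to_json())
        assert back.counts == model.counts
        assert back.alphabet == model.alphabet
        assert back.order_bound == model.order_bound

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            ContextModel.from_json('{"format": "other/9"}')


def test_distribution_validates_and_reports():
    d = Distribution({"a": 0.25, "b": 0.75})
    assert math.isclose(d.information_content("a"), 2.0)
    assert math.isclose(d.entropy(), 0.25 * 2 + 0.75 * math.log2(4 / 3))
    assert d.argmax() == "b"
    with pytest.raises(ValueError, match="sums"):
        Distribution({"a": 0.2, "b": 0.2})
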