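"""Variable-order Markov prediction with PPM-style interpolated smoothing.

The model stores n-gram counts up to an order bound and predicts the next
symbol by blending maximum-likelihood estimates of all orders from the
longest matching context suffix down to a uniform floor.  The blend uses
escape method C: at a context with total count N and T distinct observed
continuations,

    p(s) = n(s) / (N + T)  +  T / (N + T) · p_lower(s)

so that every symbol of the alphabet retains strictly positive mass (the
order −1 floor is uniform).  Contexts never seen are skipped, which makes
prediction from an unseen long context identical to prediction from its
longest seen suffix.

Two modes are supported: a static long-term model trained once on a
corpus, and an online short-term model updated incrementally after each
prediction and emptied before every new piece.  The undefined marker ⊥
contributes neither as a context element nor as a predictand.
"""

from __future__ import annotations

import json
import math
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

from .viewpoints import is_defined

Symbol = Hashable


class Distribution:
    """A strictly positive probability mass function over a finite alphabet."""

    __slots__ = ("_mass",)

    def __init__(self, mass: Mapping[Symbol, float]):
        total = math.fsum(mass.values())
        if not mass or not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mass sums to {total}, not 1")
        self._mass = dict(mass)

    def __getitem__(self, symbol: Symbol) -> float:
        return self._mass[symbol]

    def get(self, symbol: Symbol, default: float = 0.0) -> float:
        return self._mass.get(symbol, default)

    def __iter__(self):
        return iter(self._mass)

    def __len__(self) -> int:
        return len(self._mass)

    def items(self):
        return self._mass.items()

    @property
    def alphabet(self) -> tuple:
        return tuple(self._mass)

    def entropy(self) -> float:
        """Shannon entropy in bits: H = −Σ p log₂ p."""
        return -math.fsum(p * math.log2(p) for p in self._mass.values() if p > 0)

    def information_content(self, symbol: Symbol) -> float:
        """Surprisal of ``symbol`` in bits: h = −log₂ p."""
        p = self._mass[symbol]
        if p <= 0:
            raise ValueError(f"zero probability for {symbol!r}")
        return -math.log2(p)

    def argmax(self) -> Symbol:
        return max(self._mass, key=self._mass.__getitem__)

    def __repr__(self) -> str:
        head = ", ".join(f"{s!r}: {p:.4g}" for s, p in list(self._mass.items())[:4])
        more = "" if len(self._mass) <= 4 else ", ..."
        return f"Distribution({{{head}{more}}})"


class ContextModel:
    """Variable-order count store over a growable finite alphabet.

    Parameters
    ----------
    alphabet:
        Symbols to declare up front (e.g. a fixed prediction alphabet such
        as the 37 chromatic pitches from B2 to B5).  Symbols seen in
        training are always added; declared-but-unseen symbols receive
        probability only through the uniform floor.
    order_bound:
        Maximum context length used for counting and prediction; ``None``
        means unbounded.
    mode:
        ``"static"`` for a corpus-trained long-term model, ``"online"``
        for an incrementally updated short-term model.
    """

    def __init__(self, alphabet: Iterable[Symbol] = (),
                 order_bound: int | None = 3,
                 mode: str = "static"):
        if order_bound is not None and order_bound < 0:
            raise ValueError("order_bound must be >= 0 or None")
        if mode not in ("static", "online"):
            raise ValueError(f"mode must be 'static' or 'online', got {mode!r}")
        self.order_bound = order_bound
        self.mode = mode
        self._alphabet: dict[Symbol, None] = {}   # insertion-ordered set
        self.declare(alphabet)
        self.counts: dict[tuple, dict[Symbol, int]] = {}

    # -- alphabet ----------------------------------------------------------

    @property
    def alphabet(self) -> tuple:
        return tuple(self._alphabet)

    def declare(self, symbols: Iterable[Symbol]) -> None:
        """Add symbols to the alphabet without observing them."""
        for s in symbols:
            if not is_defined(s):
                raise ValueError("⊥ cannot be an alphabet symbol")
            self._alphabet.setdefault(s, None)

    # -- training ----------------------------------------------------------

    def train(self, sequences: Iterable[Sequence[Symbol]]) -> "ContextModel":
        """Count (context, next) pairs up to the order bound.

        Positions holding ⊥ are dropped before counting, so they neither
        extend contexts nor act as predictands.  Returns ``self``.
        """
        for seq in sequences:
            run = [s for s in seq if is_defined(s)]
            self.declare(run)
            for i, sym in enumerate(run):
                kmax = i if self.order_bound is None else min(i, self.order_bound)
                for k in range(kmax + 1):
                    ctx = tuple(run[i - k:i])
                    bucket = self.counts.setdefault(ctx, {})
                    bucket[sym] = bucket.get(sym, 0) + 1
        return self

    def update_online(self, observed: Symbol, context: Sequence[Symbol]) -> None:
        """Record one observation after its prediction has been issued.

        Increments the count of ``observed`` after every suffix of
        ``context`` (including the empty context) up to the order bound.
        """
        if self.mode != "online":
            raise RuntimeError("update_online is only valid for online models")
        if not is_defined(observed):
            raise ValueError("cannot observe ⊥")
        ctx = tuple(s for s in context if is_defined(s))
        self.declare((observed,))
        self.declare(ctx)
        kmax = (len(ctx) if self.order_bound is None
                else min(len(ctx), self.order_bound))
        for k in range(kmax + 1):
            bucket = self.counts.setdefault(ctx[len(ctx) - k:], {})
            bucket[observed] = bucket.get(observed, 0) + 1

    def reset(self) -> None:
        """Empty all learned counts (used between pieces for online models)."""
        self.counts = {}

    # -- prediction --------------------------------------------------------

    def predict(self, context: Sequence[Symbol] = ()) -> Distribution:
        """Predictive distribution after ``context`` (⊥ entries ignored)."""
        alpha = self.alphabet
        if not alpha:
            raise RuntimeError("cannot predict over an empty alphabet")
        ctx = tuple(s for s in context if is_defined(s))
        if self.order_bound is not None:
            ctx = ctx[len(ctx) - min(len(ctx), self.order_bound):]
        floor = 1.0 / len(alpha)
        p = {s: floor for s in alpha}
        for k in range(len(ctx) + 1):        # ascending order: 0 .. len(ctx)
            bucket = self.counts.get(ctx[len(ctx) - k:])
            if not bucket:
                continue
            total = sum(bucket.values())
            types = len(bucket)
            esc = types / (total + types)
            p = {s: bucket.get(s, 0) / (total + types) + esc * p[s]
                 for s in alpha}
        norm = math.fsum(p.values())
        return Distribution({s: v / norm for s, v in p.items()})

    def predict_over(self, symbols: Sequence[Symbol],
                     context: Sequence[Symbol] = ()) -> Distribution:
        """Predictive distribution restricted to a given symbol set.

        Used when the prediction alphabet is induced by the current
        context (e.g. the derived symbols that a fixed set of candidate
        pitches would realise).  Counts for symbols outside ``symbols``
        are ignored; the uniform floor ranges over ``symbols`` only.
        """
        alpha = list(dict.fromkeys(symbols))
        if not alpha:
            raise ValueError("empty prediction alphabet")
        ctx = tuple(s for s in context if is_defined(s))
        if self.order_bound is not None:
            ctx = ctx[len(ctx) - min(len(ctx), self.order_bound):]
        floor = 1.0 / len(alpha)
        p = {s: floor for s in alpha}
        keep = set(alpha)
        for k in range(len(ctx) + 1):
            bucket = self.counts.get(ctx[len(ctx) - k:])
            if not bucket:
                continue
            bucket = {s: n for s, n in bucket.items() if s in keep}
            if not bucket:
                continue
            total = sum(bucket.values())
            types = len(bucket)
            esc = types / (total + types)
            p = {s: bucket.get(s, 0) / (total + types) + esc * p[s]
                 for s in alpha}
        norm = math.fsum(p.values())
        return Distribution({s: v / norm for s, v in p.items()})

    def sequence_ics(self, sequence: Sequence[Symbol],
                     online: bool | None = None) -> list[float]:
        """Per-symbol information content of ``sequence`` in bits.

        ⊥ positions are skipped.  With ``online`` true (default for
        online-mode models) each prediction is followed by an update.
        """
        if online is None:
            online = self.mode == "online"
        run = [s for s in sequence if is_defined(s)]
        out = []
        for i, sym in enumerate(run):
            ctx = tuple(run[:i])
            dist = self.predict(ctx)
            out.append(dist.information_content(sym)
                       if sym in dist._mass else math.inf)
            if online:
                self.update_online(sym, ctx)
        return out

    # -- serialization -----------------------------------------------------

    _FORMAT = "melexp.context-model/1"

    def to_json(self) -> str:
        doc = {
            "format": self._FORMAT,
            "order_bound": self.order_bound,
            "mode": self.mode,
            "alphabet": [_encode_symbol(s) for s in self._alphabet],
            "counts": [[ [_encode_symbol(s) for s in ctx],
                         [[_encode_symbol(s), n] for s, n in bucket.items()] ]
                       for ctx, bucket in self.counts.items()],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ContextModel":
        doc = json.loads(text)
        if doc.get("format") != cls._FORMAT:
            raise ValueError(f"unrecognised model format {doc.get('format')!r}")
        model = cls(alphabet=[_decode_symbol(s) for s in doc["alphabet"]],
                    order_bound=doc["order_bound"], mode=doc["mode"])
        for ctx_enc, bucket_enc in doc["counts"]:
            ctx = tuple(_decode_symbol(s) for s in ctx_enc)
            model.counts[ctx] = {_decode_symbol(s): n for s, n in bucket_enc}
        return model


def _encode_symbol(sym):
    if isinstance(sym, bool):
        raise TypeError("boolean symbols unsupported")
    if isinstance(sym, int):
        return ["i", sym]
    if isinstance(sym, str):
        return ["s", sym]
    if isinstance(sym, Fraction):
        return ["f", sym.numerator, sym.denominator]
    if isinstance(sym, tuple):
        return ["t", [_encode_symbol(x) for x in sym]]
    raise TypeError(f"cannot serialise symbol of type {type(sym).__name__}")


def _decode_symbol(enc):
    tag = enc[0]
    if tag == "i":
        return enc[1]
    if tag == "s":
        return enc[1]
    if tag == "f":
        return Fraction(enc[1], enc[2])
    if tag == "t":
        return tuple(_decode_symbol(x) for x in enc[1])
    raise ValueError(f"bad symbol encoding {enc!r}")
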