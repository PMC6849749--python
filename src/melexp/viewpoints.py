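"""Viewpoints: derived symbolic attributes of melodic sequences.

A viewpoint maps a melody onto a sequence of derived symbols, one per
event.  Where the defining function has no value (the first note has no
pitch interval; the first two notes have no ioi ratio) the sequence
carries the distinguished undefined marker ``UNDEFINED`` (⊥).

Supported viewpoints:

========== =========== ====================================================
name       attribute   value at event n
========== =========== ====================================================
pitch      pitch       MIDI note number
pi         pitch       pitch[n] − pitch[n−1] (semitones); ⊥ at n = 0
sd         pitch       (pitch[n] − tonic) mod 12, the chromatic scale degree
onset      onset       onset[n] in ticks
ioi        onset       onset[n] − onset[n−1]; ⊥ at n = 0
ioi-ratio  onset       ioi[n] / ioi[n−1] as an exact reduced ratio; ⊥ for
                       the first two notes
========== =========== ====================================================

Two viewpoints may be linked (``pi ⊗ sd``): the linked value is the pair
of component values where both are defined and ⊥ otherwise.

Prediction works in derived space, so a model's output distribution over
derived symbols must be mapped back onto a basic alphabet of candidate
pitches or iois; :func:`to_basic_distribution` performs this inversion,
splitting the mass of a derived symbol equally among the basic candidates
that realise it and renormalising away mass that falls outside the basic
alphabet's image.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Mapping, Sequence

from .melody_io import Melody


class _Undefined:
    """Singleton undefined marker ⊥."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "⊥"

    def __reduce__(self):
        return (_Undefined, ())


UNDEFINED = _Undefined()


class ConfigurationError(ValueError):
    """A viewpoint was requested without the metadata it needs."""


class UndefinedContextError(ValueError):
    """The context does not determine the viewpoint's inverse mapping."""


def is_defined(value) -> bool:
    return value is not UNDEFINED


@dataclass(frozen=True)
class PredictionContext:
    """The slice of melodic history needed to invert a viewpoint.

    Any field may be ``None`` when the history does not supply it (e.g.
    ``prev_pitch`` before the first note).
    """

    prev_pitch: int | None = None
    prev_onset: int | None = None
    prev_ioi: int | None = None
    tonic: int | None = None

    @classmethod
    def at(cls, melody: Melody, index: int) -> "PredictionContext":
        """Context for predicting event ``index`` of ``melody``."""
        prev_pitch = melody.events[index - 1].pitch if index >= 1 else None
        prev_onset = melody.events[index - 1].onset if index >= 1 else None
        prev_ioi = (melody.events[index - 1].onset - melody.events[index - 2].onset
                    if index >= 2 else None)
        return cls(prev_pitch=prev_pitch, prev_onset=prev_onset,
                   prev_ioi=prev_ioi, tonic=melody.tonic)


class Viewpoint:
    """Base class; concrete viewpoints implement ``derive`` and
    ``candidate_symbol``."""

    name: str
    attribute: str          # 'pitch', 'onset', or 'mixed' for cross links

    def derive(self, melody: Melody) -> tuple:
        raise NotImplementedError

    def candidate_symbol(self, candidate: int, ctx: PredictionContext):
        """Derived symbol the basic ``candidate`` (a pitch, or an ioi for
        temporal viewpoints) would realise in ``ctx``."""
        raise NotImplementedError

    def symbol_key(self, symbol, attribute: str):
        """Projection of a derived symbol used when inverting onto the
        given basic attribute; identity for single-attribute viewpoints."""
        return symbol

    def __repr__(self) -> str:
        return f"<viewpoint {self.name}>"

    def __eq__(self, other) -> bool:
        return isinstance(other, Viewpoint) and self.name == other.name

    def __hash__(self) -> int:
        return hash(self.name)


class _PitchVp(Viewpoint):
    name, attribute = "pitch", "pitch"

    def derive(self, melody):
        return melody.pitches

    def candidate_symbol(self, candidate, ctx):
        return candidate


class _PiVp(Viewpoint):
    name, attribute = "pi", "pitch"

    def derive(self, melody):
        return (UNDEFINED,) + melody.intervals

    def candidate_symbol(self, candidate, ctx):
        if ctx.prev_pitch is None:
            raise UndefinedContextError("pi needs a previous pitch")
        return candidate - ctx.prev_pitch


class _SdVp(Viewpoint):
    name, attribute = "sd", "pitch"

    def derive(self, melody):
        if melody.tonic is None:
            raise ConfigurationError(
                f"melody {melody.id!r}: scale degree requested but no tonic "
                "is annotated")
        return tuple((p - melody.tonic) % 12 for p in melody.pitches)

    def candidate_symbol(self, candidate, ctx):
        if ctx.tonic is None:
            raise UndefinedContextError("sd needs an annotated tonic")
        return (candidate - ctx.tonic) % 12


class _OnsetVp(Viewpoint):
    name, attribute = "onset", "onset"

    def derive(self, melody):
        return melody.onsets

    def candidate_symbol(self, candidate, ctx):
        # temporal candidates are iois; the onset they produce needs history
        if ctx.prev_onset is None:
            raise UndefinedContextError("onset inversion needs a previous onset")
        return ctx.prev_onset + candidate


class _IoiVp(Viewpoint):
    name, attribute = "ioi", "onset"

    def derive(self, melody):
        return (UNDEFINED,) + melody.iois

    def candidate_symbol(self, candidate, ctx):
        return candidate


class _IoiRatioVp(Viewpoint):
    name, attribute = "ioi-ratio", "onset"

    def derive(self, melody):
        iois = melody.iois
        out = [UNDEFINED, UNDEFINED]
        for prev, cur in zip(iois, iois[1:]):
            out.append(Fraction(cur, prev))
        return tuple(out[:len(melody)])

    def candidate_symbol(self, candidate, ctx):
        if ctx.prev_ioi is None or ctx.prev_ioi <= 0:
            raise UndefinedContextError("ioi-ratio needs a previous ioi")
        return Fraction(candidate, ctx.prev_ioi)


class LinkedViewpoint(Viewpoint):
    """Product of two viewpoints; defined only where both components are."""

    def __init__(self, a: Viewpoint, b: Viewpoint):
        if a == b:
            raise ValueError("cannot link a viewpoint with itself")
        self.components = (a, b)
        self.name = f"{a.name} x {b.name}"
        self.attribute = a.attribute if a.attribute == b.attribute else "mixed"

    def derive(self, melody):
        seq_a = self.components[0].derive(melody)
        seq_b = self.components[1].derive(melody)
        return tuple((va, vb) if is_defined(va) and is_defined(vb) else UNDEFINED
                     for va, vb in zip(seq_a, seq_b))

    def candidate_symbol(self, candidate, ctx):
        return tuple(c.candidate_symbol(candidate, ctx) for c in self.components)

    def symbol_key(self, symbol, attribute):
        if self.attribute != "mixed":
            return symbol
        for comp, val in zip(self.components, symbol):
            if comp.attribute == attribute:
                return val
        raise UndefinedContextError(
            f"{self.name} has no component for attribute {attribute!r}")


def link(a: Viewpoint, b: Viewpoint) -> LinkedViewpoint:
    """Link two distinct viewpoints into their product viewpoint."""
    return LinkedViewpoint(a, b)


_BASIC: dict[str, Viewpoint] = {vp.name: vp for vp in
                                (_PitchVp(), _PiVp(), _SdVp(),
                                 _OnsetVp(), _IoiVp(), _IoiRatioVp())}


def get_viewpoint(name: str) -> Viewpoint:
    """Resolve a viewpoint by name; ``"pi x sd"`` (or ``"pi ⊗ sd"``) links."""
    name = name.strip()
    for sep in (" x ", "⊗", " X "):
        if sep in name:
            left, _, right = name.partition(sep)
            return link(get_viewpoint(left), get_viewpoint(right))
    try:
        return _BASIC[name]
    except KeyError:
        raise ValueError(f"unknown viewpoint {name!r}; expected one of "
                         f"{sorted(_BASIC)} or a linked pair 'a x b'") from None


def derive(melody: Melody, spec: Viewpoint | str) -> tuple:
    """Derived-value sequence of ``spec`` over ``melody`` (⊥ where undefined)."""
    vp = get_viewpoint(spec) if isinstance(spec, str) else spec
    return vp.derive(melody)


def defined_subsequence(values: Sequence) -> tuple:
    """Drop ⊥ positions, keeping order (the sequence a model trains on)."""
    return tuple(v for v in values if is_defined(v))


def to_basic_distribution(derived_dist: Mapping[Hashable, float],
                          spec: Viewpoint,
                          ctx: PredictionContext,
                          basic_alphabet: Sequence[int],
                          attribute: str | None = None) -> dict[int, float]:
    """Invert a distribution over derived symbols onto a basic alphabet.

    Each basic candidate maps (given the context) to a unique derived key;
    a derived symbol's probability mass is split equally among the basic
    candidates realising it, and the result is renormalised so that mass
    on derived symbols outside the basic alphabet's image is redistributed.

    Raises :class:`UndefinedContextError` when the context does not
    determine the inversion (e.g. pitch interval before any pitch), and
    :class:`ValueError` when no derived mass lands on the basic alphabet.
    """
    if attribute is None:
        if spec.attribute == "mixed":
            raise ValueError("attribute must be named for a mixed linked "
                             "viewpoint")
        attribute = spec.attribute
    keys = {b: spec.symbol_key(spec.candidate_symbol(b, ctx), attribute)
            if spec.attribute == "mixed" else spec.candidate_symbol(b, ctx)
            for b in basic_alphabet}
    group_size: dict[Hashable, int] = {}
    for k in keys.values():
        group_size[k] = group_size.get(k, 0) + 1
    if spec.attribute == "mixed":
        mass_by_key: dict[Hashable, float] = {}
        for sym, p in derived_dist.items():
            k = spec.symbol_key(sym, attribute)
            mass_by_key[k] = mass_by_key.get(k, 0.0) + p
    else:
        mass_by_key = dict(derived_dist)
    raw = {b: mass_by_key.get(k, 0.0) / group_size[k] for b, k in keys.items()}
    total = sum(raw.values())
    if total <= 0.0:
        raise ValueError("derived distribution places no mass on the basic "
                         "alphabet's image")
    return {b: p / total for b, p in raw.items()}
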