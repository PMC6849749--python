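"""Synthetic corpora with known statistical structure.

Every analysis stage in this package is testable without external data
through three generators, all pure functions of (spec, seed):

* :func:`generate_culture` — melodic corpora sampled from first-order
  Markov chains over scale degrees and over ioi ratios.  The default
  pair of cultures contrasts a pentatonic-flavoured style with a
  diatonic-flavoured one, with different rhythmic-ratio preferences —
  loosely echoing a Chinese/Western folk-song contrast without any claim
  of ethnographic fidelity.
* :func:`generate_metrical_rhythms` — rhythms sampled bar by bar from a
  per-position onset-probability (accent) profile, annotated with the
  true meter and phase.
* :func:`perturb_melody` — controlled rhythm / interval / contour /
  phrase-order / modulation errors for similarity experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np

from .melody_io import Corpus, Event, Melody

_MIN_IOI, _MAX_IOI = 6, 96      # clamp for the ratio chain (ticks)


def _check_stochastic(matrix: np.ndarray, name: str) -> None:
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{name} must be square")
    if (matrix < 0).any() or not np.allclose(matrix.sum(axis=1), 1.0,
                                             atol=1e-9):
        raise ValueError(f"{name} rows must be non-negative and sum to 1")


@dataclass(frozen=True)
class CultureSpec:
    """Generating process for one synthetic musical culture.

    Scale degrees are semitone offsets from the tonic; the melody's
    pitches are ``tonic + degree``.  Rhythm follows a chain over exact
    ioi ratios starting from ``base_ioi`` ticks, clamped to the 6..96
    tick range (the ratio is forced to 1 when a step would leave it).
    """

    name: str
    degrees: tuple[int, ...]
    transition: tuple[tuple[float, ...], ...]
    initial: tuple[float, ...]
    ratios: tuple[Fraction, ...]
    ratio_transition: tuple[tuple[float, ...], ...]
    ratio_initial: tuple[float, ...]
    tonic: int = 60
    base_ioi: int = 24
    length_range: tuple[int, int] = (16, 32)

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        rt = np.asarray(self.ratio_transition, dtype=float)
        _check_stochastic(t, "transition")
        _check_stochastic(rt, "ratio_transition")
        if t.shape[0] != len(self.degrees):
            raise ValueError("transition size must match degree alphabet")
        if rt.shape[0] != len(self.ratios):
            raise ValueError("ratio_transition size must match ratio alphabet")
        for vec, n, name in ((self.initial, len(self.degrees), "initial"),
                             (self.ratio_initial, len(self.ratios),
                              "ratio_initial")):
            v = np.asarray(vec, dtype=float)
            if v.shape != (n,) or (v < 0).any() or not math.isclose(
                    v.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be a length-{n} distribution")


def generate_culture(spec: CultureSpec, n: int, seed: int = 0) -> Corpus:
    """Sample ``n`` melodies from a culture's generating chains."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    transition = np.asarray(spec.transition, dtype=float)
    initial = np.asarray(spec.initial, dtype=float)
    ratio_tr = np.asarray(spec.ratio_transition, dtype=float)
    ratio_init = np.asarray(spec.ratio_initial, dtype=float)
    melodies = []
    for i in range(n):
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        deg_idx = int(rng.choice(len(spec.degrees), p=initial))
        pitches = [spec.tonic + spec.degrees[deg_idx]]
        for _ in range(length - 1):
            deg_idx = int(rng.choice(len(spec.degrees), p=transition[deg_idx]))
            pitches.append(spec.tonic + spec.degrees[deg_idx])
        onsets = [0]
        ioi = spec.base_ioi
        ratio_idx = int(rng.choice(len(spec.ratios), p=ratio_init))
        for k in range(length - 1):
            if k > 0:
                ratio_idx = int(rng.choice(len(spec.ratios),
                                           p=ratio_tr[ratio_idx]))
                nxt = ioi * spec.ratios[ratio_idx]
                if nxt.denominator == 1 and _MIN_IOI <= nxt <= _MAX_IOI:
                    ioi = int(nxt)
            onsets.append(onsets[-1] + ioi)
        events = tuple(Event(onset=o, pitch=p) for o, p in zip(onsets, pitches))
        melodies.append(Melody(id=f"{spec.name}{i:04d}", events=events,
                               tonic=spec.tonic, culture=spec.name))
    return Corpus(melodies=melodies, name=spec.name)


def default_culture_specs() -> tuple[CultureSpec, CultureSpec]:
    """The default well-separated two-culture fixture.

    Culture "penta" moves mostly stepwise around a pentatonic degree set
    and prefers even, occasionally doubled note values; culture "diat"
    uses a seven-degree diatonic set with a leading-tone pull to the
    tonic and prefers dotted/halved ratio patterns.
    """
    penta = CultureSpec(
        name="penta",
        degrees=(0, 2, 4, 7, 9),
        transition=(
            (0.15, 0.45, 0.20, 0.10, 0.10),
            (0.30, 0.15, 0.35, 0.15, 0.05),
            (0.10, 0.35, 0.15, 0.30, 0.10),
            (0.05, 0.15, 0.35, 0.15, 0.30),
            (0.25, 0.05, 0.10, 0.45, 0.15),
        ),
        initial=(0.4, 0.15, 0.15, 0.2, 0.1),
        ratios=(Fraction(1), Fraction(2), Fraction(1, 2)),
        ratio_transition=(
            (0.70, 0.20, 0.10),
            (0.55, 0.05, 0.40),
            (0.55, 0.40, 0.05),
        ),
        ratio_initial=(0.8, 0.1, 0.1),
    )
    diat = CultureSpec(
        name="diat",
        degrees=(0, 2, 4, 5, 7, 9, 11),
        transition=(
            (0.10, 0.30, 0.15, 0.05, 0.15, 0.05, 0.20),
            (0.35, 0.10, 0.30, 0.10, 0.10, 0.03, 0.02),
            (0.15, 0.25, 0.10, 0.30, 0.15, 0.03, 0.02),
            (0.10, 0.05, 0.35, 0.10, 0.30, 0.08, 0.02),
            (0.20, 0.05, 0.15, 0.25, 0.10, 0.20, 0.05),
            (0.05, 0.03, 0.05, 0.10, 0.35, 0.12, 0.30),
            (0.55, 0.03, 0.02, 0.05, 0.10, 0.15, 0.10),
        ),
        initial=(0.35, 0.1, 0.15, 0.05, 0.25, 0.05, 0.05),
        ratios=(Fraction(1), Fraction(1, 2), Fraction(3, 2), Fraction(2)),
        ratio_transition=(
            (0.35, 0.30, 0.25, 0.10),
            (0.30, 0.35, 0.05, 0.30),
            (0.30, 0.45, 0.15, 0.10),
            (0.30, 0.50, 0.15, 0.05),
        ),
        ratio_initial=(0.5, 0.25, 0.2, 0.05),
    )
    return penta, diat


def blend_cultures(a: CultureSpec, b: CultureSpec, t: float,
                   name: str | None = None) -> CultureSpec:
    """Interpolate culture ``a`` toward culture ``b`` over their union
    alphabets (t = 0 reproduces a's statistics; t = 1 reproduces b's).

    Used to dial generator divergence in validation experiments: corpora
    from ``blend_cultures(a, b, t)`` grow harder to tell from culture
    ``a`` as t decreases.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    degrees = tuple(sorted(set(a.degrees) | set(b.degrees)))
    ratios = tuple(sorted(set(a.ratios) | set(b.ratios)))

    def embed(spec: CultureSpec, union: tuple, own: tuple, matrix, init):
        m = np.full((len(union), len(union)), 0.0)
        v = np.zeros(len(union))
        idx = {s: i for i, s in enumerate(union)}
        own_idx = [idx[s] for s in own]
        matrix = np.asarray(matrix, dtype=float)
        init = np.asarray(init, dtype=float)
        for r, ri in enumerate(own_idx):
            for c, ci in enumerate(own_idx):
                m[ri, ci] = matrix[r, c]
        # rows for symbols outside this culture: its initial distribution
        for ri in range(len(union)):
            if ri not in own_idx:
                for c, ci in enumerate(own_idx):
                    m[ri, ci] = init[c]
        for c, ci in enumerate(own_idx):
            v[ci] = init[c]
        return m, v

    ma, va = embed(a, degrees, a.degrees, a.transition, a.initial)
    mb, vb = embed(b, degrees, b.degrees, b.transition, b.initial)
    ra, pa = embed(a, ratios, a.ratios, a.ratio_transition, a.ratio_initial)
    rb, pb = embed(b, ratios, b.ratios, b.ratio_transition, b.ratio_initial)
    mix = lambda x, y: tuple(map(tuple, ((1 - t) * np.asarray(x)
                                         + t * np.asarray(y)).tolist()))
    vmix = lambda x, y: tuple(((1 - t) * np.asarray(x)
                               + t * np.asarray(y)).tolist())
    return CultureSpec(
        name=name or f"{a.name}~{b.name}@{t:g}",
        degrees=degrees, transition=mix(ma, mb), initial=vmix(va, vb),
        ratios=ratios, ratio_transition=mix(ra, rb),
        ratio_initial=vmix(pa, pb),
        tonic=a.tonic, base_ioi=a.base_ioi, length_range=a.length_range)


# ---------------------------------------------------------------------------
# Metrical rhythms
# ---------------------------------------------------------------------------

#: Default accent profiles on a 24-tick (crotchet) grid: strong downbeat,
#: category-specific interior accents.
DEFAULT_ACCENT_PROFILES: dict[str, tuple[float, ...]] = {
    "3/4": (1.0, 0.7, 0.15),
    "4/4": (1.0, 0.15, 0.65, 0.45),
}


def generate_metrical_rhythms(category: str, accent_profile: Sequence[float],
                              n: int, seed: int = 0, bars: int = 8,
                              grid: int = 24, pitch: int = 60) -> Corpus:
    """Sample rhythms from a per-position accent profile.

    The bar period is ``len(accent_profile) * grid`` ticks; each grid
    position of each bar receives an onset with its profile probability.
    The downbeat of the first bar always carries an onset, anchoring the
    phase at zero.  Melodies are annotated with the category as their
    time signature; pitch is a constant placeholder (rhythm-only data).
    """
    if not accent_profile:
        raise ValueError("accent profile must be non-empty")
    if any(not 0.0 <= p <= 1.0 for p in accent_profile):
        raise ValueError("accent probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    profile = list(accent_profile)
    melodies = []
    for i in range(n):
        onsets = []
        for bar in range(bars):
            for j, p in enumerate(profile):
                t = (bar * len(profile) + j) * grid
                if (bar == 0 and j == 0) or rng.random() < p:
                    onsets.append(t)
        if len(onsets) < 2:        # degenerate all-silent draw
            onsets = [0, len(profile) * grid]
        events = tuple(Event(onset=t, pitch=pitch) for t in onsets)
        melodies.append(Melody(id=f"{category.replace('/', '-')}_{i:04d}",
                               events=events, time_signature=category))
    return Corpus(melodies=melodies, name=category)


# ---------------------------------------------------------------------------
# Phrase-structured melodies for segmentation experiments
# ---------------------------------------------------------------------------

#: Pitch sets of the default phrase chains: four distinct registers, each a
#: five-note scale segment cycled near-deterministically within a phrase.
_PHRASE_SETS = ((60, 62, 64, 65, 67), (72, 74, 76, 77, 79),
                (48, 50, 52, 53, 55), (84, 86, 88, 89, 91))


def generate_phrased_melody(seed: int = 0, n_phrases: int = 6,
                            phrase_length: tuple[int, int] = (11, 14),
                            follow: float = 0.97,
                            ioi: int = 24) -> tuple[Melody, list[int]]:
    """A melody of concatenated phrases from distinct Markov chains.

    Each phrase is sampled from one of four chains (never the one used
    for the preceding phrase): a chain walks its own five-pitch set
    cyclically, following the cycle with probability ``follow`` and
    jumping uniformly within the set otherwise.  Within a phrase the
    music is therefore highly predictable to an online learner, while
    the first event of each new phrase — drawn from a different chain in
    a different register — is not.  Returns the melody and the list of
    true boundary positions (the first event index of each non-initial
    phrase), the ground truth for boundary-detection evaluation.
    """
    if n_phrases < 2:
        raise ValueError("need at least two phrases")
    if not 0.0 <= follow <= 1.0:
        raise ValueError("follow must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pitches: list[int] = []
    boundaries: list[int] = []
    prev_chain = None
    for _ in range(n_phrases):
        choices = [i for i in range(len(_PHRASE_SETS)) if i != prev_chain]
        chain = int(rng.choice(choices))
        prev_chain = chain
        pitch_set = _PHRASE_SETS[chain]
        if pitches:
            boundaries.append(len(pitches))
        length = int(rng.integers(phrase_length[0], phrase_length[1] + 1))
        j = int(rng.integers(len(pitch_set)))
        for _ in range(length):
            pitches.append(pitch_set[j])
            j = ((j + 1) % len(pitch_set) if rng.random() < follow
                 else int(rng.integers(len(pitch_set))))
    events = tuple(Event(onset=ioi * i, pitch=p)
                   for i, p in enumerate(pitches))
    return Melody(id=f"phrased{seed:04d}", events=events, tonic=60), boundaries


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

ERROR_TYPES = ("rhythm", "interval", "contour", "phrase-order", "modulation")


def perturb_melody(melody: Melody, error_type: str, magnitude: float,
                   seed: int = 0, cut: int | None = None) -> Melody:
    """Introduce controlled errors of one type into a melody.

    ``magnitude`` is the proportion of editable positions affected (0
    returns the melody unchanged).  Error types: ``rhythm`` doubles or
    halves selected iois; ``interval`` widens selected non-unison
    intervals by a semitone, preserving contour; ``contour`` inverts the
    sign of selected non-unison intervals; ``phrase-order`` swaps the two
    contiguous segments around ``cut`` (seeded interior point when not
    given) — applying the swap twice with complementary cut restores the
    original; ``modulation`` transposes a final segment up two semitones.
    """
    if error_type not in ERROR_TYPES:
        raise ValueError(f"unknown error type {error_type!r}; "
                         f"expected one of {ERROR_TYPES}")
    if not 0.0 <= magnitude <= 1.0:
        raise ValueError("magnitude must lie in [0, 1]")
    if magnitude == 0.0:
        return melody
    if len(melody) < 3:
        raise ValueError("melody too short to perturb")
    rng = np.random.default_rng(seed)
    if error_type == "rhythm":
        iois = list(melody.iois)
        k = max(1, round(magnitude * len(iois)))
        for idx in rng.choice(len(iois), size=min(k, len(iois)),
                              replace=False):
            halved = iois[idx] // 2
            iois[idx] = halved if iois[idx] % 2 == 0 and halved >= _MIN_IOI \
                else iois[idx] * 2
        return _rebuild(melody, melody.pitches, iois)
    if error_type in ("interval", "contour"):
        ivs = list(melody.intervals)
        editable = [i for i, v in enumerate(ivs) if v != 0]
        if not editable:
            raise ValueError("melody has no non-unison intervals to edit")
        k = max(1, round(magnitude * len(editable)))
        for idx in rng.choice(editable, size=min(k, len(editable)),
                              replace=False):
            if error_type == "interval":
                ivs[idx] += 1 if ivs[idx] > 0 else -1   # widen, keep contour
            else:
                ivs[idx] = -ivs[idx]                    # flip contour
        pitches = [melody.pitches[0]]
        for v in ivs:
            pitches.append(pitches[-1] + v)
        return _rebuild(melody, pitches, melody.iois)
    if error_type == "phrase-order":
        if cut is None:
            cut = int(rng.integers(1, len(melody)))
        if not 1 <= cut < len(melody):
            raise ValueError(f"cut {cut} outside 1..{len(melody) - 1}")
        pitches = melody.pitches[cut:] + melody.pitches[:cut]
        iois = list(melody.iois)
        seam = iois[cut - 1]
        iois = iois[cut:] + [seam] + iois[:cut - 1]
        return _rebuild(melody, pitches, iois)
    # modulation: transpose a suffix
    k = max(1, round(magnitude * len(melody)))
    start = len(melody) - k
    pitches = list(melody.pitches)
    for i in range(start, len(pitches)):
        pitches[i] += 2
    return _rebuild(melody, pitches, melody.iois)


def _rebuild(melody: Melody, pitches: Sequence[int],
             iois: Sequence[int]) -> Melody:
    onsets = [melody.events[0].onset]
    for d in iois:
        onsets.append(onsets[-1] + d)
    events = tuple(Event(onset=o, pitch=p) for o, p in zip(onsets, pitches))
    return replace(melody, events=events)
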