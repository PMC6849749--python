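"""Bayesian meter induction from symbolic rhythms.

The metrical interpretation of a rhythm is treated as a hidden variable
with two parts: a metrical category (the time signature, i.e. the bar
period in ticks) and a phase aligning the bar grid to the rhythm.  The
posterior over interpretations after each event combines

* a prior over categories estimated as relative frequencies of notated
  time signatures in a training corpus (phase uniform within category),
* a likelihood of each onset given the interpretation, estimated by a
  variable-order model over (ioi, metrical-position) symbols, where the
  metrical position is the onset modulo the bar period under the
  hypothesis' phase.

Both terms are conditioned on the preceding rhythmic context, so the
posterior can shift dynamically event by event.  Accumulation is done in
the log domain with per-event renormalisation.  The same machinery
yields meter-conditioned temporal prediction: the next-ioi distribution
is the posterior-weighted mixture of the per-hypothesis conditional
predictions, which typically carries lower information content than a
meter-blind ioi model on metrically regular music.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .melody_io import Corpus, Melody, TICKS_PER_CROTCHET
from .ppm import ContextModel, Distribution

logger = logging.getLogger(__name__)

_LOG_FLOOR = -700.0    # exp() underflow guard for dead hypotheses


class DataError(ValueError):
    """Corpus lacks annotations required for meter estimation."""


@dataclass(frozen=True, order=True)
class MeterCategory:
    """A metrical category: time-signature label and bar period in ticks."""

    label: str
    period: int

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("bar period must be positive")


@dataclass(frozen=True, order=True)
class MeterHypothesis:
    """A metrical interpretation: category plus phase offset in ticks."""

    category: MeterCategory
    phase: int

    def __post_init__(self) -> None:
        if not 0 <= self.phase < self.category.period:
            raise ValueError(f"phase {self.phase} outside [0, "
                             f"{self.category.period})")

    def position(self, onset: int) -> int:
        """Metrical position of an onset within the bar."""
        return (onset - self.phase) % self.category.period


def category_from_label(label: str) -> MeterCategory:
    """Bar period of a time signature on the 24-ticks-per-crotchet grid."""
    try:
        num, den = label.split("/")
        period = int(num) * 4 * TICKS_PER_CROTCHET // int(den)
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"cannot parse time signature {label!r}") from exc
    return MeterCategory(label=label, period=period)


class MeterPosterior:
    """Per-event posterior over metrical interpretations."""

    def __init__(self, hypotheses: Sequence[MeterHypothesis],
                 trace: Sequence[Sequence[float]]):
        self.hypotheses = tuple(hypotheses)
        self.trace = [tuple(row) for row in trace]

    def __len__(self) -> int:
        return len(self.trace)

    def at(self, event: int) -> dict[MeterHypothesis, float]:
        return dict(zip(self.hypotheses, self.trace[event]))

    def category_posterior(self, event: int = -1) -> dict[str, float]:
        """Posterior per category (phases summed out) after ``event``."""
        out: dict[str, float] = {}
        for h, p in zip(self.hypotheses, self.trace[event]):
            out[h.category.label] = out.get(h.category.label, 0.0) + p
        return out

    def map_hypothesis(self, event: int = -1) -> MeterHypothesis:
        row = self.trace[event]
        return self.hypotheses[max(range(len(row)), key=row.__getitem__)]


@dataclass
class RhythmModel:
    """Per-category likelihood models over (ioi, metrical position) symbols."""

    categories: dict[str, MeterCategory]
    models: dict[str, ContextModel]
    grid: int
    ioi_alphabet: tuple[int, ...] = ()

    def hypotheses(self, labels: Iterable[str] | None = None
                   ) -> list[MeterHypothesis]:
        labels = list(labels) if labels is not None else sorted(self.categories)
        out = []
        for label in labels:
            cat = self.categories[label]
            for phase in range(0, cat.period, self.grid):
                out.append(MeterHypothesis(category=cat, phase=phase))
        return out


# ---------------------------------------------------------------------------
# Empirical estimation
# ---------------------------------------------------------------------------

def estimate_prior(corpus: Corpus | Iterable[Melody]) -> dict[str, float]:
    """Relative frequency of each notated time signature in the corpus.

    The phase prior is uniform within a category and is applied when
    hypotheses are enumerated, not here.
    """
    melodies = list(corpus)
    if not melodies:
        raise DataError("cannot estimate a meter prior from an empty corpus")
    missing = [m.id for m in melodies if not m.time_signature]
    if missing:
        raise DataError(f"melodies lack time-signature annotations: {missing}")
    counts: dict[str, int] = {}
    for m in melodies:
        counts[m.time_signature] = counts.get(m.time_signature, 0) + 1
    total = len(melodies)
    return {label: n / total for label, n in sorted(counts.items())}


def train_likelihood(corpus: Corpus | Iterable[Melody],
                     order_bound: int | None = 2) -> RhythmModel:
    """Train per-category rhythm models on an annotated corpus.

    Each melody contributes its sequence of (ioi, position-within-bar)
    symbols to its category's model, with positions taken under the
    notated meter at the annotated (zero) phase.  The phase lattice step
    is the smallest ioi observed, for tractability.
    """
    melodies = list(corpus)
    missing = [m.id for m in melodies if not m.time_signature]
    if missing:
        raise DataError(f"melodies lack time-signature annotations: {missing}")
    categories: dict[str, MeterCategory] = {}
    sequences: dict[str, list[list[tuple[int, int]]]] = {}
    all_iois: set[int] = set()
    for m in melodies:
        cat = categories.setdefault(m.time_signature,
                                    category_from_label(m.time_signature))
        seq = [(ioi, onset % cat.period)
               for ioi, onset in zip(m.iois, m.onsets[1:])]
        sequences.setdefault(cat.label, []).append(seq)
        all_iois.update(m.iois)
    models = {}
    for label, cat in categories.items():
        model = ContextModel(order_bound=order_bound, mode="static")
        model.train(sequences.get(label, []))
        models[label] = model
    grid = min(all_iois) if all_iois else TICKS_PER_CROTCHET
    return RhythmModel(categories=categories, models=models, grid=grid,
                       ioi_alphabet=tuple(sorted(all_iois)))


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _event_likelihood(model: ContextModel, hyp: MeterHypothesis,
                      prev_onset: int, ioi: int,
                      context: Sequence[tuple[int, int]],
                      candidates: Sequence[int]) -> tuple[float, Distribution]:
    """P(observed ioi | hypothesis, context) together with the conditional
    next-ioi distribution it came from."""
    symbols = [(d, hyp.position(prev_onset + d)) for d in candidates]
    dist = model.predict_over(symbols, context)
    observed = (ioi, hyp.position(prev_onset + ioi))
    return dist[observed], dist


def infer(onsets: Sequence[int], prior: Mapping[str, float],
          likelihoods: RhythmModel) -> MeterPosterior:
    """Event-by-event posterior over metrical interpretations of a rhythm.

    The posterior after event t is proportional to the category prior
    (uniform over phases within a category) times the product of onset
    likelihoods up to t, renormalised at every event.
    """
    if not onsets:
        raise ValueError("rhythm is empty")
    hyps = likelihoods.hypotheses(prior.keys())
    candidates = _candidate_iois(likelihoods, onsets)
    n_phase = {label: sum(1 for h in hyps if h.category.label == label)
               for label in prior}
    logw = [math.log(max(prior[h.category.label], 1e-300))
            - math.log(n_phase[h.category.label]) for h in hyps]
    contexts: list[list[tuple[int, int]]] = [[] for _ in hyps]
    trace = [_normalise(logw)]
    for prev, onset in zip(onsets, onsets[1:]):
        ioi = onset - prev
        for j, h in enumerate(hyps):
            model = likelihoods.models[h.category.label]
            p, _ = _event_likelihood(model, h, prev, ioi, contexts[j],
                                     candidates)
            if p <= 0.0:
                logger.warning("zero likelihood for %s at onset %d; "
                               "flooring", h, onset)
                logw[j] = _LOG_FLOOR
            else:
                logw[j] += math.log(p)
            contexts[j].append((ioi, h.position(onset)))
        peak = max(logw)
        logw = [max(v - peak, _LOG_FLOOR) for v in logw]
        trace.append(_normalise(logw))
    return MeterPosterior(hyps, trace)


def predict_next_onset(onsets: Sequence[int], posterior: MeterPosterior,
                       likelihoods: RhythmModel,
                       candidates: Sequence[int] | None = None) -> Distribution:
    """Posterior-weighted mixture distribution over the next ioi."""
    if candidates is None:
        candidates = _candidate_iois(likelihoods, onsets)
    prev = onsets[-1]
    weights = posterior.at(-1 if len(posterior) else 0)
    mix = {d: 0.0 for d in candidates}
    for h, w in weights.items():
        if w <= 0.0:
            continue
        model = likelihoods.models[h.category.label]
        context = [(b - a, h.position(b)) for a, b in zip(onsets, onsets[1:])]
        symbols = [(d, h.position(prev + d)) for d in candidates]
        dist = model.predict_over(symbols, context)
        for d, sym in zip(candidates, symbols):
            mix[d] += w * dist[sym]
    total = math.fsum(mix.values())
    return Distribution({d: v / total for d, v in mix.items()})


def classify_meter(onsets: Sequence[int], prior: Mapping[str, float],
                   likelihoods: RhythmModel) -> str:
    """Category with maximal final posterior mass (phases summed out).

    Ties break by higher prior, then by label order.
    """
    posterior = infer(onsets, prior, likelihoods)
    by_cat = posterior.category_posterior(-1)
    return min(by_cat,
               key=lambda lab: (-round(by_cat[lab], 12), -prior[lab], lab))


# ---------------------------------------------------------------------------
# Temporal information content, with and without metrical inference
# ---------------------------------------------------------------------------

def metered_rhythm_ics(onsets: Sequence[int], prior: Mapping[str, float],
                       likelihoods: RhythmModel) -> list[float]:
    """Per-ioi IC (bits) of a rhythm under online metrical inference.

    Each ioi is scored against the mixture of per-hypothesis conditional
    predictions weighted by the posterior available *before* the event,
    after which the posterior is updated — prediction precedes learning.
    """
    if len(onsets) < 2:
        return []
    hyps = likelihoods.hypotheses(prior.keys())
    candidates = _candidate_iois(likelihoods, onsets)
    n_phase = {label: sum(1 for h in hyps if h.category.label == label)
               for label in prior}
    logw = [math.log(max(prior[h.category.label], 1e-300))
            - math.log(n_phase[h.category.label]) for h in hyps]
    contexts: list[list[tuple[int, int]]] = [[] for _ in hyps]
    ics = []
    for prev, onset in zip(onsets, onsets[1:]):
        ioi = onset - prev
        weights = _normalise(logw)
        p_mix = 0.0
        event_ps = []
        for j, h in enumerate(hyps):
            model = likelihoods.models[h.category.label]
            p, _ = _event_likelihood(model, h, prev, ioi, contexts[j],
                                     candidates)
            event_ps.append(p)
            p_mix += weights[j] * p
        ics.append(-math.log2(max(p_mix, 1e-300)))
        for j, (h, p) in enumerate(zip(hyps, event_ps)):
            logw[j] = (logw[j] + math.log(p)) if p > 0 else _LOG_FLOOR
            contexts[j].append((ioi, h.position(onset)))
        peak = max(logw)
        logw = [max(v - peak, _LOG_FLOOR) for v in logw]
    return ics


def train_ioi_model(corpus: Corpus | Iterable[Melody],
                    order_bound: int | None = 2) -> ContextModel:
    """Meter-blind baseline: a variable-order model over raw ioi sequences."""
    model = ContextModel(order_bound=order_bound, mode="static")
    model.train([m.iois for m in corpus])
    return model


def meter_free_rhythm_ics(onsets: Sequence[int], model: ContextModel,
                          candidates: Sequence[int] | None = None
                          ) -> list[float]:
    """Per-ioi IC of a rhythm under the meter-blind ioi model."""
    iois = [b - a for a, b in zip(onsets, onsets[1:])]
    if candidates is None:
        candidates = sorted(set(model.alphabet) | set(iois))
    ics = []
    for i, ioi in enumerate(iois):
        dist = model.predict_over(candidates, tuple(iois[:i]))
        ics.append(dist.information_content(ioi))
    return ics


def _candidate_iois(likelihoods: RhythmModel,
                    onsets: Sequence[int]) -> list[int]:
    observed = {b - a for a, b in zip(onsets, onsets[1:])}
    return sorted(set(likelihoods.ioi_alphabet) | observed)


def _normalise(logw: Sequence[float]) -> list[float]:
    peak = max(logw)
    w = [math.exp(v - peak) for v in logw]
    total = math.fsum(w)
    return [v / total for v in w]
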