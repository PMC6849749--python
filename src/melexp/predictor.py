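"""Combining model predictions and computing information-content profiles.

The predictive system maintains, for each basic attribute (pitch and note
onset), one variable-order model per configured viewpoint, duplicated
across two subsystems: a long-term model (LTM) trained on a corpus, and a
short-term model (STM) learning online within the current piece and
emptied before each new one.  For every event the per-viewpoint derived
predictions are mapped onto the basic alphabet, combined within each
subsystem, then across subsystems, by an entropy-weighted mixture: a
model whose prediction is more certain (lower entropy relative to the
uniform maximum) receives a higher weight,

    w_m = (H(p_m) / H_max) ** (-b),      H_max = log2 |alphabet|,

with the weights normalised to sum to one.  The note's final probability
is the joint likelihood of its pitch and its onset, so joint information
content is the sum of the pitch and onset ICs.

Information content h = −log2 p and entropy H = −Σ p log2 p are reported
in bits; entropy is computed on the post-combination distribution over
the declared basic alphabet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .melody_io import Corpus, Melody
from .ppm import ContextModel, Distribution
from .viewpoints import (PredictionContext, Viewpoint, UndefinedContextError,
                         get_viewpoint, is_defined)

_ENTROPY_FLOOR = 1e-6   # relative entropy below this counts as certainty

ATTRIBUTES = ("pitch", "onset")


@dataclass(frozen=True)
class CombinationConfig:
    """Which viewpoints and subsystems are active, and how to mix them.

    ``b`` is the entropy-weighting exponent (larger values concentrate
    weight on the most certain model); ``scheme`` selects an arithmetic
    (weighted sum) or geometric (weighted product, renormalised) mixture.
    """

    pitch_viewpoints: tuple[str, ...] = ("pi x sd",)
    onset_viewpoints: tuple[str, ...] = ("ioi-ratio",)
    subsystems: tuple[str, ...] = ("ltm", "stm")
    scheme: str = "arithmetic"
    b: float = 2.0
    ltm_order_bound: int | None = 3
    stm_order_bound: int | None = None

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("weighting exponent b must be positive")
        if self.scheme not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown combination scheme {self.scheme!r}")
        if not set(self.subsystems) <= {"ltm", "stm"} or not self.subsystems:
            raise ValueError("subsystems must be a non-empty subset of "
                             "{'ltm', 'stm'}")
        if not self.pitch_viewpoints and not self.onset_viewpoints:
            raise ValueError("at least one viewpoint must be active")
        for name in self.pitch_viewpoints + self.onset_viewpoints:
            get_viewpoint(name)   # validates against the lexicon

    @property
    def attributes(self) -> tuple[str, ...]:
        out = []
        if self.pitch_viewpoints:
            out.append("pitch")
        if self.onset_viewpoints:
            out.append("onset")
        return tuple(out)

    def viewpoints(self, attribute: str) -> tuple[Viewpoint, ...]:
        names = (self.pitch_viewpoints if attribute == "pitch"
                 else self.onset_viewpoints)
        return tuple(get_viewpoint(n) for n in names)


@dataclass(frozen=True)
class PredictionRecord:
    """Per-event prediction outcome for one attribute."""

    index: int
    attribute: str
    observed: object          # realised basic symbol; None when undefined
    p: float                  # probability of the realised symbol
    h: float                  # information content, bits
    H: float                  # entropy of the predictive distribution, bits
    distribution: Distribution | None = None


@dataclass
class Profile:
    """IC/entropy profile of one melody under a configured predictor."""

    melody_id: str
    records: dict[str, list[PredictionRecord]] = field(default_factory=dict)

    def ics(self, attribute: str = "joint") -> list[float]:
        if attribute == "joint":
            per_attr = [self.records[a] for a in self.records]
            return [math.fsum(recs[i].h for recs in per_attr)
                    for i in range(len(per_attr[0]))]
        return [r.h for r in self.records[attribute]]

    def mean_ic(self, attribute: str = "joint") -> float:
        ics = self.ics(attribute)
        return math.fsum(ics) / len(ics)

    def probabilities(self, attribute: str = "joint") -> list[float]:
        if attribute == "joint":
            return [2.0 ** -h for h in self.ics("joint")]
        return [r.p for r in self.records[attribute]]

    def to_rows(self, melody: Melody | None = None) -> list[dict]:
        """Flat per-event rows (melody id, index, onset, pitch, per-attribute
        p/h/H and the joint IC) for CSV export."""
        n = len(next(iter(self.records.values())))
        joint = self.ics("joint")
        rows = []
        for i in range(n):
            row = {"melody_id": self.melody_id, "index": i}
            if melody is not None:
                row["onset"] = melody.events[i].onset
                row["pitch"] = melody.events[i].pitch
            for attr, recs in self.records.items():
                row[f"p_{attr}"] = recs[i].p
                row[f"ic_{attr}_bits"] = recs[i].h
                row[f"entropy_{attr}_bits"] = recs[i].H
            row["ic_joint_bits"] = joint[i]
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# Distribution combination
# ---------------------------------------------------------------------------

def entropy_weights(dists: Sequence[Distribution], b: float) -> list[float]:
    """Relative-entropy weights (H/H_max)^(−b), normalised to sum to 1."""
    n = len(dists[0])
    if any(len(d) != n for d in dists):
        raise ValueError("distributions have mismatched alphabet sizes")
    h_max = math.log2(n) if n > 1 else 1.0
    rel = [max(d.entropy() / h_max, _ENTROPY_FLOOR) for d in dists]
    raw = [r ** (-b) for r in rel]
    total = math.fsum(raw)
    return [w / total for w in raw]


def combine(dists: Sequence[Distribution], b: float = 2.0,
            scheme: str = "arithmetic") -> Distribution:
    """Entropy-weighted mixture of distributions over a common alphabet."""
    if not dists:
        raise ValueError("no distributions to combine")
    alphabet = set(dists[0].alphabet)
    if any(set(d.alphabet) != alphabet for d in dists):
        raise ValueError("distributions must share one alphabet")
    if len(dists) == 1:
        return dists[0]
    weights = entropy_weights(dists, b)
    if scheme == "arithmetic":
        mass = {s: math.fsum(w * d[s] for w, d in zip(weights, dists))
                for s in dists[0].alphabet}
    elif scheme == "geometric":
        logmass = {s: math.fsum(w * math.log(d[s])
                                for w, d in zip(weights, dists))
                   for s in dists[0].alphabet}
        peak = max(logmass.values())
        mass = {s: math.exp(v - peak) for s, v in logmass.items()}
    else:
        raise ValueError(f"unknown combination scheme {scheme!r}")
    total = math.fsum(mass.values())
    return Distribution({s: v / total for s, v in mass.items()})


def joint_event_probability(p_pitch: float, p_onset: float) -> float:
    """Joint likelihood of a note's pitch and onset (their product)."""
    for name, p in (("pitch", p_pitch), ("onset", p_onset)):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} probability {p} outside (0, 1]")
    return p_pitch * p_onset


def betting_ic(S: float, alternatives: int = 20) -> float:
    """Information content implied by mean betting capital S.

    In the betting paradigm a participant splits capital across the
    possible next pitches; a correct prediction multiplies the stake by
    the number of alternatives, Sₙ = 20·p·Sₙ₋₁ for 20 pitches.  The
    equivalent surprisal is log₂(alternatives) − log₂ S bits.
    """
    if S <= 0:
        raise ValueError("capital S must be positive")
    return math.log2(alternatives) - math.log2(S)


# ---------------------------------------------------------------------------
# The predictor proper
# ---------------------------------------------------------------------------

class Predictor:
    """A configured predictive system with trained long-term models.

    Parameters
    ----------
    config:
        Active viewpoints, subsystems and mixture settings.
    pitch_alphabet, ioi_alphabet:
        Candidate sets for the two basic attributes.  When training from
        a corpus they default to the symbols occurring there; a fixed
        alphabet (e.g. the 37 chromatic pitches from B2 to B5) may be
        supplied instead.
    """

    def __init__(self, config: CombinationConfig | None = None,
                 pitch_alphabet: Iterable[int] = (),
                 ioi_alphabet: Iterable[int] = ()):
        self.config = config or CombinationConfig()
        self.pitch_alphabet: tuple[int, ...] = tuple(dict.fromkeys(pitch_alphabet))
        self.ioi_alphabet: tuple[int, ...] = tuple(dict.fromkeys(ioi_alphabet))
        self.ltm: dict[str, ContextModel] = {
            vp.name: ContextModel(order_bound=self.config.ltm_order_bound,
                                  mode="static")
            for attr in ATTRIBUTES for vp in self.config.viewpoints(attr)}

    # -- training ----------------------------------------------------------

    def train(self, corpus: Corpus | Iterable[Melody]) -> "Predictor":
        """Train the long-term models on a corpus; grows basic alphabets
        with the pitches and iois observed there."""
        melodies = list(corpus)
        for attr in self.config.attributes:
            for vp in self.config.viewpoints(attr):
                self.ltm[vp.name].train([vp.derive(m) for m in melodies])
        self.pitch_alphabet = tuple(dict.fromkeys(
            self.pitch_alphabet
            + tuple(p for m in melodies for p in m.pitches)))
        self.ioi_alphabet = tuple(dict.fromkeys(
            self.ioi_alphabet
            + tuple(d for m in melodies for d in m.iois)))
        return self

    # -- profiling ---------------------------------------------------------

    def profile(self, melody: Melody) -> Profile:
        """Predict every event of ``melody`` and return its IC profile.

        Each active attribute yields one record per event.  Events where
        no active viewpoint is invertible (e.g. the very first note under
        an interval-only configuration, or the first onset, which has no
        ioi) fall back to the maximum-ignorance uniform distribution over
        the basic alphabet.  Short-term models start empty and are
        updated online after each event's prediction.
        """
        cfg = self.config
        basic = {
            "pitch": tuple(dict.fromkeys(self.pitch_alphabet + melody.pitches)),
            "onset": tuple(dict.fromkeys(self.ioi_alphabet + melody.iois)),
        }
        derived = {vp.name: vp.derive(melody)
                   for attr in cfg.attributes for vp in cfg.viewpoints(attr)}
        stm: dict[str, ContextModel] = {}
        if "stm" in cfg.subsystems:
            stm = {vp.name: ContextModel(order_bound=cfg.stm_order_bound,
                                         mode="online")
                   for attr in cfg.attributes for vp in cfg.viewpoints(attr)}
        profile = Profile(melody_id=melody.id,
                          records={a: [] for a in cfg.attributes})
        for i in range(len(melody)):
            ctx = PredictionContext.at(melody, i)
            for attr in cfg.attributes:
                alphabet = basic[attr]
                observed = (melody.pitches[i] if attr == "pitch"
                            else (melody.iois[i - 1] if i >= 1 else None))
                per_subsystem: list[Distribution] = []
                for subsystem in cfg.subsystems:
                    models = self.ltm if subsystem == "ltm" else stm
                    per_vp: list[Distribution] = []
                    for vp in cfg.viewpoints(attr):
                        d = self._viewpoint_prediction(
                            models[vp.name], vp, derived[vp.name][:i],
                            ctx, alphabet, attr)
                        if d is not None:
                            per_vp.append(d)
                    if per_vp:
                        per_subsystem.append(
                            combine(per_vp, b=cfg.b, scheme=cfg.scheme))
                if per_subsystem:
                    final = combine(per_subsystem, b=cfg.b, scheme=cfg.scheme)
                else:
                    final = Distribution(
                        {s: 1.0 / len(alphabet) for s in alphabet})
                if observed is None:
                    p = 1.0 / len(alphabet)
                else:
                    p = final[observed]
                profile.records[attr].append(PredictionRecord(
                    index=i, attribute=attr, observed=observed, p=p,
                    h=-math.log2(p), H=final.entropy(), distribution=final))
            # prediction first, then online learning
            for attr in cfg.attributes:
                for vp in cfg.viewpoints(attr):
                    if vp.name in stm and is_defined(derived[vp.name][i]):
                        stm[vp.name].update_online(derived[vp.name][i],
                                                   derived[vp.name][:i])
        return profile

    @staticmethod
    def _viewpoint_prediction(model: ContextModel, vp: Viewpoint,
                              derived_context: Sequence, ctx: PredictionContext,
                              alphabet: Sequence[int], attribute: str
                              ) -> Distribution | None:
        """Basic-attribute distribution from one viewpoint model, or None
        when the viewpoint is not invertible at this position."""
        try:
            keys = [vp.candidate_symbol(b, ctx) for b in alphabet]
        except UndefinedContextError:
            return None
        if vp.attribute == "mixed":
            # marginalise the pair distribution onto the component that
            # carries this attribute, then look candidates up by that key
            keys = [vp.symbol_key(k, attribute) for k in keys]
            if not model.alphabet:   # untrained: nothing to marginalise
                return Distribution({b: 1.0 / len(alphabet) for b in alphabet})
            pair_dist = model.predict(derived_context)
            mass_by_key: dict = {}
            for sym, p in pair_dist.items():
                k = vp.symbol_key(sym, attribute)
                mass_by_key[k] = mass_by_key.get(k, 0.0) + p
            getter = mass_by_key.get
        else:
            derived_dist = model.predict_over(
                list(dict.fromkeys(keys)), derived_context)
            getter = derived_dist.get
        group: dict = {}
        for k in keys:
            group[k] = group.get(k, 0) + 1
        raw = {b: getter(k, 0.0) / group[k] for b, k in zip(alphabet, keys)}
        total = math.fsum(raw.values())
        if total <= 0.0:
            # model's learned pairs lie outside the candidate set entirely
            return Distribution({b: 1.0 / len(alphabet) for b in alphabet})
        return Distribution({b: v / total for b, v in raw.items()})

    def mean_ic(self, melody: Melody, attribute: str = "joint") -> float:
        return self.profile(melody).mean_ic(attribute)

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        import dataclasses
        import json
        doc = {
            "format": "melexp.predictor/1",
            "config": dataclasses.asdict(self.config),
            "pitch_alphabet": list(self.pitch_alphabet),
            "ioi_alphabet": list(self.ioi_alphabet),
            "ltm": {name: model.to_json() for name, model in self.ltm.items()},
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Predictor":
        import json
        doc = json.loads(text)
        if doc.get("format") != "melexp.predictor/1":
            raise ValueError(f"unrecognised predictor format "
                             f"{doc.get('format')!r}")
        cfg = doc["config"]
        for key in ("pitch_viewpoints", "onset_viewpoints", "subsystems"):
            cfg[key] = tuple(cfg[key])
        predictor = cls(config=CombinationConfig(**cfg),
                        pitch_alphabet=doc["pitch_alphabet"],
                        ioi_alphabet=doc["ioi_alphabet"])
        predictor.ltm = {name: ContextModel.from_json(payload)
                         for name, payload in doc["ltm"].items()}
        return predictor


def train_ltm(corpus: Corpus | Iterable[Melody],
              config: CombinationConfig | None = None,
              **alphabets) -> Predictor:
    """Convenience constructor: a predictor with LTMs trained on ``corpus``."""
    return Predictor(config=config, **alphabets).train(corpus)


def ic_profile(melody: Melody, predictor: Predictor) -> Profile:
    """IC/entropy profile of ``melody`` under a trained predictor."""
    return predictor.profile(melody)
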