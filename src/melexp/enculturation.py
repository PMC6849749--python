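"""Two-culture cultural-distance analysis.

A listener enculturated in style A is simulated by a long-term model
trained on corpus A.  For each composition we obtain two mean per-note
information contents: under its own culture's model (via k-fold
cross-validation, so the piece never appears in its own training set)
and under the other culture's model (trained on that culture's full
corpus).  Plotting one against the other, pieces on the line of equality
are equally predictable to both simulated listeners; the perpendicular
distance from that line is a quantitative cultural distance.  Rotating
the plane by 45° gives

    distance   = (ic_other − ic_own) / √2      (signed; positive means
                                                the own-culture model
                                                predicts the piece better)
    complexity = (ic_other + ic_own) / √2      (culture-neutral axis)

A piece is classified into the culture whose model finds it more
predictable (lower mean IC); corpus-level accuracy is the fraction of
pieces with positive cultural distance.  The short-term model is not
used anywhere in this analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .melody_io import Corpus, Melody
from .predictor import CombinationConfig, Predictor

_SQRT2 = math.sqrt(2.0)

#: LTM-only defaults for enculturation simulations.
LTM_ONLY = CombinationConfig(subsystems=("ltm",))

#: Sentinel returned when a piece is exactly equally predictable under
#: both culture models.
UNDECIDED = "undecided"


@dataclass(frozen=True)
class CulturalDistanceResult:
    """45°-rotated coordinates of a piece in the two-model IC plane."""

    ic_own: float
    ic_other: float

    @property
    def distance(self) -> float:
        """Signed cultural distance in bits (perpendicular to x = y)."""
        return (self.ic_other - self.ic_own) / _SQRT2

    @property
    def complexity(self) -> float:
        """Culture-neutral complexity in bits (along x = y)."""
        return (self.ic_other + self.ic_own) / _SQRT2


def cultural_distance(ic_own: float, ic_other: float) -> CulturalDistanceResult:
    """Rotate a (own-model IC, other-model IC) pair into distance and
    complexity coordinates."""
    if not (math.isfinite(ic_own) and math.isfinite(ic_other)):
        raise ValueError("mean ICs must be finite")
    return CulturalDistanceResult(ic_own=ic_own, ic_other=ic_other)


def assign_folds(n: int, folds: int, seed: int) -> list[int]:
    """Deterministic fold labels: a seeded shuffle dealt round-robin."""
    order = np.random.default_rng(seed).permutation(n)
    labels = [0] * n
    for pos, idx in enumerate(order):
        labels[idx] = pos % folds
    return labels


def within_culture_ic(corpus: Corpus, config: CombinationConfig | None = None,
                      folds: int = 10, seed: int = 0,
                      attribute: str = "joint") -> dict[str, float]:
    """Mean IC of each melody under models trained on the rest of its corpus.

    Melodies are dealt into ``folds`` folds by a seeded permutation; each
    fold is predicted by a long-term model trained on the other folds.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(corpus):
        raise ValueError(f"folds={folds} exceeds corpus size {len(corpus)}")
    config = config or LTM_ONLY
    labels = assign_folds(len(corpus), folds, seed)
    melodies = list(corpus)
    out: dict[str, float] = {}
    for fold in range(folds):
        train_set = [m for m, lab in zip(melodies, labels) if lab != fold]
        test_set = [m for m, lab in zip(melodies, labels) if lab == fold]
        if not test_set:
            continue
        model = Predictor(config).train(train_set)
        for m in test_set:
            out[m.id] = model.mean_ic(m, attribute)
    return out


def between_culture_ic(model: Predictor, corpus: Corpus | list[Melody],
                       attribute: str = "joint") -> dict[str, float]:
    """Mean IC of every melody in ``corpus`` under a fixed trained model."""
    return {m.id: model.mean_ic(m, attribute) for m in corpus}


def classify_piece(melody: Melody, model_a: Predictor, model_b: Predictor,
                   label_a: str, label_b: str,
                   attribute: str = "joint") -> str:
    """Label of the culture model that finds the melody more predictable.

    An exact tie returns the ``UNDECIDED`` sentinel.
    """
    ic_a = model_a.mean_ic(melody, attribute)
    ic_b = model_b.mean_ic(melody, attribute)
    if ic_a == ic_b:
        return UNDECIDED
    return label_a if ic_a < ic_b else label_b


@dataclass
class CorpusSummary:
    """Corpus-level outcome of a two-culture comparison."""

    label_a: str
    label_b: str
    accuracy: float                   # fraction of pieces with distance > 0
    mean_distance: float              # mean signed per-piece distance, bits
    mean_complexity: float
    pieces: dict[str, CulturalDistanceResult]   # id -> rotated coordinates
    culture_of: dict[str, str]

    def scatter_rows(self) -> list[dict]:
        """Per-piece rows (ic_own, ic_other, distance, complexity) for the
        two-model IC scatter plot."""
        return [{"melody_id": mid, "culture": self.culture_of[mid],
                 "ic_own": r.ic_own, "ic_other": r.ic_other,
                 "distance": r.distance, "complexity": r.complexity}
                for mid, r in self.pieces.items()]


def corpus_summary(corpus_a: Corpus, corpus_b: Corpus,
                   config: CombinationConfig | None = None,
                   folds: int = 10, seed: int = 0,
                   attribute: str = "joint",
                   label_a: str | None = None,
                   label_b: str | None = None) -> CorpusSummary:
    """Full two-culture analysis of a pair of (deduplicated) corpora.

    Within-culture ICs come from cross-validation; between-culture ICs
    from each culture's full-corpus model applied to the other corpus.
    Accuracy is the fraction of pieces whose own-culture model assigns
    the lower mean IC (positive signed distance); the overall cultural
    distance is the mean of the signed per-piece distances.
    """
    config = config or LTM_ONLY
    label_a = label_a or corpus_a.name or "A"
    label_b = label_b or corpus_b.name or "B"
    own_a = within_culture_ic(corpus_a, config, folds, seed, attribute)
    own_b = within_culture_ic(corpus_b, config, folds, seed + 1, attribute)
    model_a = Predictor(config).train(corpus_a)
    model_b = Predictor(config).train(corpus_b)
    other_a = between_culture_ic(model_b, corpus_a, attribute)
    other_b = between_culture_ic(model_a, corpus_b, attribute)
    pieces: dict[str, CulturalDistanceResult] = {}
    culture_of: dict[str, str] = {}
    for mid in own_a:
        pieces[mid] = cultural_distance(own_a[mid], other_a[mid])
        culture_of[mid] = label_a
    for mid in own_b:
        pieces[mid] = cultural_distance(own_b[mid], other_b[mid])
        culture_of[mid] = label_b
    n = len(pieces)
    accuracy = sum(1 for r in pieces.values() if r.distance > 0) / n
    mean_distance = math.fsum(r.distance for r in pieces.values()) / n
    mean_complexity = math.fsum(r.complexity for r in pieces.values()) / n
    return CorpusSummary(label_a=label_a, label_b=label_b, accuracy=accuracy,
                         mean_distance=mean_distance,
                         mean_complexity=mean_complexity,
                         pieces=pieces, culture_of=culture_of)
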