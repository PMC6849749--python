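"""Compression-distance melodic similarity.

The compression distance from melody x to melody y is the mean per-note
information content of y under a model trained only on x: if y shares
x's statistical structure it compresses well (low IC, high similarity);
if not, the IC approaches the smoothing floor of an ignorant model.  The
measure is asymmetric, so both directions are reported together with
their mean, which is the default ranking key.  Distances are in bits per
note and are not normalised by self-complexity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .melody_io import Corpus, Melody
from .predictor import CombinationConfig, Predictor

#: LTM-only configuration: similarity compares corpus-style structure, so
#: the within-piece short-term learner is off unless explicitly enabled.
DEFAULT_SIMILARITY_CONFIG = CombinationConfig(subsystems=("ltm",))


@dataclass(frozen=True)
class DistanceResult:
    """Directed and symmetrised compression distances, in bits/note."""

    d_xy: float   # mean IC of y under a model trained on x
    d_yx: float   # mean IC of x under a model trained on y
    x_id: str = ""
    y_id: str = ""

    @property
    def symmetric(self) -> float:
        return 0.5 * (self.d_xy + self.d_yx)


def compression_distance(x: Melody, y: Melody,
                         config: CombinationConfig | None = None,
                         attribute: str = "joint") -> DistanceResult:
    """Compression distance between two melodies.

    Trains a predictor on ``x`` alone and averages the IC of ``y``'s
    notes under it (and vice versa).  ``attribute`` selects the joint
    pitch-and-onset likelihood (default) or a single attribute.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValueError("melodies must be non-empty")
    config = config or DEFAULT_SIMILARITY_CONFIG
    d_xy = Predictor(config).train([x]).mean_ic(y, attribute)
    d_yx = Predictor(config).train([y]).mean_ic(x, attribute)
    return DistanceResult(d_xy=d_xy, d_yx=d_yx, x_id=x.id, y_id=y.id)


def rank_candidates(query: Melody, candidates: Corpus | Iterable[Melody],
                    config: CombinationConfig | None = None,
                    attribute: str = "joint") -> list[tuple[str, float]]:
    """Rank candidates by ascending symmetrised distance to the query.

    Ties keep corpus order (Python's sort is stable), so the earlier
    candidate wins a tie.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates to rank")
    scored = [(c.id, compression_distance(query, c, config, attribute).symmetric)
              for c in candidates]
    return sorted(scored, key=lambda item: item[1])
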