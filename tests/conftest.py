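import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from melexp.melody_io import Corpus, Event, Melody


def make_melody(pitches, iois=None, melody_id="m", tonic=None, **meta):
    """Build a melody from pitches and (optionally) iois in ticks."""
    iois = iois or [24] * (len(pitches) - 1)
    onsets = [0]
    for d in iois:
        onsets.append(onsets[-1] + d)
    events = tuple(Event(onset=o, pitch=p) for o, p in zip(onsets, pitches))
    return Melody(id=melody_id, events=events, tonic=tonic, **meta)


@pytest.fixture
def simple_melody():
    """G4 B4 D5 on crotchets, tonic G: the canonical worked example."""
    return make_melody([67, 71, 74], tonic=67, melody_id="gbd")


@pytest.fixture
def small_corpus():
    return Corpus(melodies=[
        make_melody([60, 62, 64, 62, 60], melody_id="a", tonic=60),
        make_melody([60, 64, 67, 64, 60], melody_id="b", tonic=60),
        make_melody([67, 65, 64, 62, 60], melody_id="c", tonic=60),
    ], name="small")
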