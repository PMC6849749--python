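"""Reading, writing and curating symbolic melodies.

Melodies are monophonic sequences of note events, each carrying an onset
time in integer ticks (24 ticks per crotchet) and a chromatic pitch as a
MIDI note number (60 = middle C).  Four input formats are supported:

* ``tabular`` — a two-column CSV dialect with header ``onset,pitch``;
* ``kern``    — a subset of the **kern representation (single spine,
  recip durations, ties, barlines, grace notes);
* ``esac``    — a subset of the EsAC folk-song notation (KEY/MEL fields,
  scale-degree digits with octave and duration modifiers);
* ``midi``    — Standard MIDI Files, format 0 or 1, first note-bearing
  track, onsets rescaled to the 24-tick crotchet grid.

Corpora are directories of tabular melodies indexed by a JSON-lines
manifest that carries per-melody metadata (tonic, time signature,
culture label).  :func:`deduplicate_corpus` implements the conservative
duplicate-removal rule used for cross-cultural corpus preparation: two
melodies count as duplicates when they share the same opening sequence
of melodic pitch intervals, regardless of rhythm.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterator

TICKS_PER_CROTCHET = 24
"""Tick resolution: 24 ticks to a crotchet (quarter note)."""

_TICKS_PER_WHOLE = 4 * TICKS_PER_CROTCHET


class ParseError(ValueError):
    """Raised when a melody source is malformed; names the offending line."""


class UnsupportedContentError(ValueError):
    """Raised for well-formed sources whose content is out of scope
    (e.g. polyphony)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Event:
    """A single note: onset in ticks and pitch as a MIDI note number."""

    onset: int
    pitch: int

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside MIDI range 0..127")
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset}")


@dataclass(frozen=True)
class Melody:
    """A monophonic melody with optional tonal/metrical/cultural metadata.

    ``tonic`` is a MIDI note number giving the tonal centre (its pitch
    class is what matters for scale-degree viewpoints); ``time_signature``
    is a label such as ``"4/4"``; ``culture`` is a free corpus label.
    """

    id: str
    events: tuple[Event, ...]
    tonic: int | None = None
    time_signature: str | None = None
    culture: str | None = None

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError(f"melody {self.id!r} has no events")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError(f"melody {self.id!r}: onsets must strictly increase")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def pitches(self) -> tuple[int, ...]:
        return tuple(e.pitch for e in self.events)

    @property
    def onsets(self) -> tuple[int, ...]:
        return tuple(e.onset for e in self.events)

    @property
    def intervals(self) -> tuple[int, ...]:
        """Successive pitch intervals in semitones (length ``len - 1``)."""
        p = self.pitches
        return tuple(b - a for a, b in zip(p, p[1:]))

    @property
    def iois(self) -> tuple[int, ...]:
        """Inter-onset intervals in ticks (length ``len - 1``)."""
        o = self.onsets
        return tuple(b - a for a, b in zip(o, o[1:]))

    def with_metadata(self, **kwargs) -> "Melody":
        return replace(self, **kwargs)


@dataclass
class Corpus:
    """An ordered collection of melodies with unique ids."""

    melodies: list[Melody] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [m.id for m in self.melodies]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate melody ids in corpus: {dupes}")

    def __iter__(self) -> Iterator[Melody]:
        return iter(self.melodies)

    def __len__(self) -> int:
        return len(self.melodies)

    def __getitem__(self, key: int | str) -> Melody:
        if isinstance(key, str):
            for m in self.melodies:
                if m.id == key:
                    return m
            raise KeyError(key)
        return self.melodies[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.melodies]


# ---------------------------------------------------------------------------
# Tabular format (canonical round-trip format)
# ---------------------------------------------------------------------------

def parse_tabular(text: str, melody_id: str = "melody", **metadata) -> Melody:
    """Parse the ``onset,pitch`` CSV dialect (comma or tab separated)."""
    rows = [ln for ln in text.splitlines() if ln.strip()]
    if not rows:
        raise ParseError("empty tabular source")
    dialect = "\t" if "\t" in rows[0] else ","
    reader = csv.reader(io.StringIO("\n".join(rows)), delimiter=dialect)
    header = next(reader)
    if [h.strip().lower() for h in header[:2]] != ["onset", "pitch"]:
        raise ParseError(f"tabular header must be 'onset,pitch', got {header!r}")
    events = []
    for lineno, row in enumerate(reader, start=2):
        try:
            events.append(Event(onset=int(row[0]), pitch=int(row[1])))
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return Melody(id=melody_id, events=tuple(events), **metadata)


def write_tabular(melody: Melody) -> str:
    lines = ["onset,pitch"]
    lines += [f"{e.onset},{e.pitch}" for e in melody.events]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# **kern subset
# ---------------------------------------------------------------------------

_KERN_STEP = {"c": 0, "d": 2, "e": 4, "f": 5, "g": 7, "a": 9, "b": 11}
_TONIC_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}


def _kern_pitch(token: str, lineno: int) -> int:
    letters = [c for c in token if c.lower() in _KERN_STEP]
    if not letters or len(set(c.lower() for c in letters)) != 1:
        raise ParseError(f"line {lineno}: cannot read kern pitch in {token!r}")
    step = _KERN_STEP[letters[0].lower()]
    if letters[0].islower():           # c = C4, cc = C5, ...
        octave = 3 + len(letters)
    else:                              # C = C3, CC = C2, ...
        octave = 4 - len(letters)
    pitch = 12 * (octave + 1) + step
    pitch += token.count("#") - token.count("-")
    if not 0 <= pitch <= 127:
        raise ParseError(f"line {lineno}: pitch out of range in {token!r}")
    return pitch


def _kern_duration(token: str, lineno: int) -> int:
    digits = "".join(c for c in token if c.isdigit())
    if not digits:
        raise ParseError(f"line {lineno}: missing duration in {token!r}")
    recip = int(digits)
    base = Fraction(_TICKS_PER_WHOLE * 2) if recip == 0 else Fraction(_TICKS_PER_WHOLE, recip)
    dots = token.count(".")
    dur = base * (Fraction(2) - Fraction(1, 2 ** dots))
    if dur.denominator != 1:
        raise ParseError(f"line {lineno}: duration {token!r} not representable "
                         f"on the {TICKS_PER_CROTCHET}-tick crotchet grid")
    return int(dur)


def parse_kern(text: str, melody_id: str = "melody", **metadata) -> Melody:
    """Parse a single-spine **kern melody.

    Handles recip durations with dots, ties (merged into one event),
    rests (advance time only) and grace notes (dropped: they carry no
    independent metrical onset).  Key (``*G:``) and meter (``*M3/4``)
    tandem interpretations populate tonic/time-signature metadata.
    """
    events: list[Event] = []
    time = 0
    spine: int | None = None
    tied = False
    tonic = metadata.pop("tonic", None)
    timesig = metadata.pop("time_signature", None)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if line.startswith("**"):
            kerns = [i for i, c in enumerate(cols) if c == "**kern"]
            if not kerns:
                raise ParseError(f"line {lineno}: no **kern spine declared")
            if len(kerns) > 1:
                raise UnsupportedContentError(
                    f"line {lineno}: {len(kerns)} kern spines; only monophonic "
                    "single-spine input is supported")
            spine = kerns[0]
            continue
        if spine is None:
            raise ParseError(f"line {lineno}: data before **kern declaration")
        token = cols[spine] if spine < len(cols) else "."
        if token.startswith("*"):
            if token.startswith("*M") and "/" in token:
                timesig = token[2:]
            elif token.endswith(":") and len(token) >= 3:
                letter = token[1].upper()
                if letter in _TONIC_PC:
                    t = 60 + _TONIC_PC[letter]
                    t += token.count("#") - token.count("-")
                    tonic = t
            continue
        if token.startswith("=") or token == ".":
            continue
        if "q" in token or "Q" in token:   # grace note: no metrical onset
            continue
        if " " in token.strip():
            raise UnsupportedContentError(
                f"line {lineno}: chord token {token!r}; polyphony unsupported")
        dur = _kern_duration(token, lineno)
        if "r" in token:                   # rest lengthens the gap
            time += dur
            tied = False
            continue
        pitch = _kern_pitch(token, lineno)
        if ("_" in token or "]" in token) and tied:
            if not events or events[-1].pitch != pitch:
                raise ParseError(f"line {lineno}: tie continuation {token!r} "
                                 "does not match previous pitch")
            time += dur
            tied = "]" not in token
            continue
        events.append(Event(onset=time, pitch=pitch))
        time += dur
        tied = "[" in token
    if not events:
        raise ParseError("kern source contains no notes")
    return Melody(id=melody_id, events=tuple(events), tonic=tonic,
                  time_signature=timesig, **metadata)


# ---------------------------------------------------------------------------
# EsAC subset
# ---------------------------------------------------------------------------

_MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)


def parse_esac(text: str, melody_id: str | None = None, **metadata) -> Melody:
    """Parse an EsAC record (KEY and MEL fields).

    KEY carries the signature ``KEY[<id> <unit> <tonic> <timesig>]`` where
    ``unit`` is the base note value as a recip number (``08`` = quaver).
    MEL holds scale-degree digits 1-7 (0 = rest) with ``-``/``+`` octave
    shifts, ``b``/``#`` chromatic alterations, ``_`` duration doubling
    and ``.`` dotting.
    """
    fields: dict[str, str] = {}
    key = None
    for m in _iter_esac_fields(text):
        fields[m[0]] = m[1]
    if "MEL" not in fields:
        raise ParseError("EsAC record has no MEL[] field")
    unit_ticks = TICKS_PER_CROTCHET
    tonic = metadata.pop("tonic", None)
    timesig = metadata.pop("time_signature", None)
    if "KEY" in fields:
        parts = fields["KEY"].split()
        if parts:
            key = parts[0]
        if len(parts) >= 2:
            try:
                unit_ticks = _TICKS_PER_WHOLE // int(parts[1])
            except (ValueError, ZeroDivisionError) as exc:
                raise ParseError(f"KEY[]: bad unit {parts[1]!r}") from exc
        if len(parts) >= 3 and parts[2][0].upper() in _TONIC_PC:
            tonic = 60 + _TONIC_PC[parts[2][0].upper()]
            tonic += parts[2].count("#") - parts[2].count("b")
        if len(parts) >= 4 and "/" in parts[3]:
            timesig = parts[3]
    if tonic is None:
        raise ParseError("EsAC record lacks a tonic (KEY[] third field)")
    if melody_id is None:
        melody_id = fields.get("CUT", key or "esac").strip() or "esac"

    events: list[Event] = []
    time = 0
    i = 0
    mel = fields["MEL"].replace("//", " ")
    while i < len(mel):
        ch = mel[i]
        if ch.isspace():
            i += 1
            continue
        octave = 0
        while i < len(mel) and mel[i] in "+-":
            octave += 1 if mel[i] == "+" else -1
            i += 1
        if i >= len(mel) or not mel[i].isdigit():
            raise ParseError(f"MEL[]: unexpected character {mel[i]!r} at offset {i}")
        degree = int(mel[i])
        i += 1
        alter = 0
        while i < len(mel) and mel[i] in "b#":
            alter += 1 if mel[i] == "#" else -1
            i += 1
        units = 1
        while i < len(mel) and mel[i] == "_":
            units += 1
            i += 1
        dotted = False
        while i < len(mel) and mel[i] == ".":
            dotted = True
            i += 1
        dur = units * unit_ticks
        if dotted:
            dur = dur * 3 // 2
        if degree == 0:                 # pause
            time += dur
            continue
        pitch = tonic + _MAJOR_SCALE[degree - 1] + 12 * octave + alter
        events.append(Event(onset=time, pitch=pitch))
        time += dur
    if not events:
        raise ParseError("EsAC MEL[] contains no notes")
    return Melody(id=melody_id, events=tuple(events), tonic=tonic,
                  time_signature=timesig, **metadata)


def _iter_esac_fields(text: str) -> Iterator[tuple[str, str]]:
    i = 0
    while i < len(text):
        j = text.find("[", i)
        if j < 0:
            return
        name = text[max(text.rfind("\n", 0, j) + 1, 0):j].strip()
        k = text.find("]", j)
        if k < 0:
            raise ParseError(f"unclosed {name}[ field")
        yield name, text[j + 1:k]
        i = k + 1


# ---------------------------------------------------------------------------
# Standard MIDI File subset
# ---------------------------------------------------------------------------

def parse_midi(data: bytes, melody_id: str = "melody", **metadata) -> Melody:
    """Parse a format 0/1 Standard MIDI File; first track containing notes.

    Onsets are rescaled from the file's ticks-per-quarter division to the
    24-tick crotchet grid.  Overlapping or simultaneous notes raise
    :class:`UnsupportedContentError`.
    """
    if len(data) < 14 or data[:4] != b"MThd":
        raise ParseError("byte 0: not a Standard MIDI File (missing MThd)")
    division = int.from_bytes(data[12:14], "big")
    if division & 0x8000:
        raise ParseError("SMPTE time division unsupported")
    if division == 0:
        raise ParseError("zero time division")
    ntrks = int.from_bytes(data[10:12], "big")
    pos = 8 + int.from_bytes(data[4:8], "big")
    for _ in range(ntrks):
        if data[pos:pos + 4] != b"MTrk":
            raise ParseError(f"byte {pos}: expected MTrk chunk")
        length = int.from_bytes(data[pos + 4:pos + 8], "big")
        track = data[pos + 8:pos + 8 + length]
        pos += 8 + length
        onsets = _midi_track_notes(track)
        if onsets:
            events = []
            last_onset = None
            for tick, pitch in onsets:
                scaled = Fraction(tick * TICKS_PER_CROTCHET, division)
                onset = int(round(scaled))
                if last_onset is not None and onset <= last_onset:
                    raise UnsupportedContentError(
                        "simultaneous notes: polyphony unsupported")
                events.append(Event(onset=onset, pitch=pitch))
                last_onset = onset
            return Melody(id=melody_id, events=tuple(events), **metadata)
    raise ParseError("no note events in any track")


def _midi_track_notes(track: bytes) -> list[tuple[int, int]]:
    notes: list[tuple[int, int]] = []
    time = 0
    i = 0
    status = 0
    while i < len(track):
        delta, i = _read_varlen(track, i)
        time += delta
        b = track[i]
        if b & 0x80:
            status = b
            i += 1
        if status == 0xFF:                        # meta event
            i += 1                                # type byte
            length, i = _read_varlen(track, i)
            i += length
            continue
        if status in (0xF0, 0xF7):                # sysex
            length, i = _read_varlen(track, i)
            i += length
            continue
        kind = status & 0xF0
        if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
            d1, d2 = track[i], track[i + 1]
            i += 2
            if kind == 0x90 and d2 > 0:
                notes.append((time, d1))
        elif kind in (0xC0, 0xD0):
            i += 1
        else:
            raise ParseError(f"byte {i}: unexpected MIDI status {status:#x}")
    return notes


def _read_varlen(data: bytes, i: int) -> tuple[int, int]:
    value = 0
    while True:
        if i >= len(data):
            raise ParseError(f"byte {i}: truncated variable-length quantity")
        b = data[i]
        i += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, i


# ---------------------------------------------------------------------------
# Dispatch, corpus manifest I/O, deduplication
# ---------------------------------------------------------------------------

_PARSERS = {
    "tabular": parse_tabular,
    "kern": parse_kern,
    "esac": parse_esac,
    "midi": parse_midi,
}

_SUFFIXES = {".csv": "tabular", ".tsv": "tabular", ".krn": "kern",
             ".kern": "kern", ".esac": "esac", ".sm": "esac",
             ".mid": "midi", ".midi": "midi"}


def parse_melody(source: str | bytes, format: str, melody_id: str = "melody",
                 **metadata) -> Melody:
    """Parse ``source`` in the named format (tabular, kern, esac or midi)."""
    try:
        parser = _PARSERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; "
                         f"expected one of {sorted(_PARSERS)}") from None
    if format == "midi":
        if isinstance(source, str):
            raise ParseError("MIDI input must be bytes")
        return parser(source, melody_id=melody_id, **metadata)
    if isinstance(source, bytes):
        source = source.decode("utf-8")
    return parser(source, melody_id=melody_id, **metadata)


def load_melody(path: str | Path, format: str | None = None, **metadata) -> Melody:
    path = Path(path)
    fmt = format or _SUFFIXES.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from suffix of {path.name!r}")
    raw = path.read_bytes()
    return parse_melody(raw, fmt, melody_id=path.stem, **metadata)


def load_corpus(path: str | Path, name: str | None = None) -> Corpus:
    """Load a corpus from a JSON-lines manifest or a directory of melodies.

    A manifest line looks like ``{"file": "x.csv", "tonic": 67,
    "time_signature": "4/4", "culture": "west"}``; relative paths resolve
    against the manifest location.  A directory is read in sorted order.
    """
    path = Path(path)
    melodies: list[Melody] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _SUFFIXES)
        for p in files:
            melodies.append(load_melody(p))
        return Corpus(melodies=melodies, name=name or path.name)
    base = path.parent
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name} line {lineno}: {exc}") from exc
        meta = {k: rec[k] for k in ("tonic", "time_signature", "culture")
                if rec.get(k) is not None}
        m = load_melody(base / rec["file"], rec.get("format"), **meta)
        if "id" in rec:
            m = m.with_metadata(id=rec["id"])
        melodies.append(m)
    return Corpus(melodies=melodies, name=name or path.stem)


def save_corpus(corpus: Corpus, directory: str | Path) -> Path:
    """Write a corpus as tabular files plus ``manifest.jsonl``; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.jsonl"
    with manifest.open("w") as fh:
        for m in corpus:
            fname = f"{m.id}.csv"
            (directory / fname).write_text(write_tabular(m))
            rec = {"file": fname, "id": m.id, "tonic": m.tonic,
                   "time_signature": m.time_signature, "culture": m.culture}
            fh.write(json.dumps({k: v for k, v in rec.items() if v is not None})
                     + "\n")
    return manifest


def deduplicate_corpus(corpus: Corpus, opening_length: int = 10) -> Corpus:
    """Remove compositions that duplicate an earlier melody's opening.

    Two melodies are duplicates when their first ``opening_length`` pitch
    intervals are identical, regardless of rhythm (transposed copies are
    therefore caught).  Melodies shorter than the opening length are
    compared over their full interval sequence, so a short melody also
    matches any longer one it prefixes.  The first occurrence in corpus
    order survives; the operation is idempotent.
    """
    if opening_length < 1:
        raise ValueError("opening_length must be >= 1")
    kept: list[Melody] = []
    openings: list[tuple[int, ...]] = []
    for m in corpus:
        if len(m) < 2:
            raise ValueError(f"melody {m.id!r} has fewer than 2 events; "
                             "cannot form an interval opening")
        opening = m.intervals[:opening_length]
        dup = any(opening[:len(seen)] == seen[:len(opening)]
                  for seen in openings)
        if not dup:
            kept.append(m)
            openings.append(opening)
    return Corpus(melodies=kept, name=corpus.name)
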