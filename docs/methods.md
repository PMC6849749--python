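# Methods

## The predictive model

`melexp` models a monophonic melody as a sequence of events carrying a
chromatic pitch (MIDI note number) and an onset time on a fixed grid of
24 ticks per crotchet. Prediction operates on *viewpoints* — derived
symbol sequences — rather than on raw events:

| viewpoint  | attribute | value at event n                      | undefined (⊥) at |
|------------|-----------|---------------------------------------|------------------|
| `pitch`    | pitch     | MIDI note number                      | —                |
| `pi`       | pitch     | pitch[n] − pitch[n−1]                 | n = 0            |
| `sd`       | pitch     | (pitch[n] − tonic) mod 12             | — (needs tonic)  |
| `onset`    | onset     | onset in ticks                        | —                |
| `ioi`      | onset     | onset[n] − onset[n−1]                 | n = 0            |
| `ioi-ratio`| onset     | ioi[n]/ioi[n−1], exact reduced ratio  | n ∈ {0, 1}       |

Two viewpoints can be linked (`pi ⊗ sd`); the linked value is the pair
where both components are defined and ⊥ otherwise. ⊥ positions
contribute neither as context symbols nor as prediction targets.

Scale degree is taken mod 12 (chromatic degree, octave-free): the
within-octave examples that motivate the viewpoint do not constrain the
multi-octave case, and the mod-12 reading keeps the derived alphabet
small and octave-invariant. Ioi ratios are exact `Fraction`s, not
floats, so alphabets remain finite and hashable on quantized corpora.

### Variable-order prediction

Each (viewpoint, subsystem) pair owns a `ContextModel`: an n-gram count
store up to an order bound. The predictive distribution after a context
interpolates all orders from the longest stored suffix down to a
uniform order −1 floor using the PPM escape-method-C mixture

    p_k(s) = n(s) / (N + T)  +  T / (N + T) · p_{k−1}(s),

where N is the context's total count and T its number of distinct
continuations; contexts with zero counts pass through transparently, so
an unseen long context predicts exactly as its longest seen suffix.
Escape method C was chosen as the canonical weighted mixture of all
lower orders; it guarantees strictly positive mass on every alphabet
symbol, so information content is always finite.

Defaults: order bound 3 for the long-term model (LTM; trained once on a
corpus) and unbounded for the short-term model (STM; trained online
within the current piece under a strict predict-then-update contract
and emptied before each new piece). Both bounds are configurable.

### From derived symbols to basic predictions

A model predicts derived symbols, but profiles are reported over a
basic alphabet of candidate pitches or iois. For each event the
candidate set induces, through the current context (previous pitch,
previous ioi, tonic), a set of derived symbols; the model's prediction
is computed over exactly that induced set, and a derived symbol's mass
is split equally among the candidates that realise it (relevant for
mod-12 scale degrees over a multi-octave alphabet) before
renormalisation. Basic alphabets default to the symbols observed in
training plus those of the melody under analysis; a fixed alphabet
(e.g. the 37 chromatic pitches from B2 to B5) can be supplied instead.

### Combination

Per-viewpoint distributions are combined within each subsystem, then
across subsystems (LTM with STM), by an entropy-weighted mixture with
weights `w_m ∝ (H(p_m)/H_max)^(−b)`, H_max = log₂|alphabet|: the more
certain a model, the more it is trusted. The same exponent `b` is used
at both stages (nothing in the source analyses distinguishes them);
defaults are the arithmetic scheme and b = 2, both configurable, with a
geometric (renormalised weighted product) scheme available. Relative
entropies are floored at 10⁻⁶ so that a zero-entropy (delta) input
receives finite, dominant weight rather than dividing by zero.

A note's final probability is the joint likelihood of its pitch and its
onset — the product of the two attribute probabilities — so joint IC is
the sum of the attribute ICs by construction. Events at which an
attribute has no invertible viewpoint (the first note under an
interval-only configuration; the first onset, which has no ioi) are
scored at the maximum-ignorance uniform floor over the basic alphabet,
which keeps every event scored and the joint additivity exact.

Information content is reported in bits (base-2 logarithms) throughout,
matching the bits-per-symbol units in which such analyses are reported.

## Derived analyses

**Compression distance.** D(x, y) is the mean per-note joint IC of y
under a predictor trained only on x (LTM only by default). The measure
is asymmetric as defined; both directions and their mean are reported,
and the symmetrised mean is the default ranking key. Distances are in
bits/note and deliberately not normalised by self-complexity — rankings
against a fixed query are unaffected, and the raw scale stays
interpretable.

**Segmentation.** Event n is a phrase boundary iff its IC exceeds the
mean of the previous w events by at least k sample standard deviations
of that window and exceeds the previous event's IC; the boundary marks
the first event of the new group, and its strength is the z-score.
Defaults w = 10, k = 2 (the source description fixes no constants);
windows shorter than w at the start of a piece are used once they hold
at least two events, and the standard deviation is floored at 10⁻⁶.
Raising k can only remove boundaries. Evaluation matches predictions to
annotations within a tolerance, each annotation used at most once, with
the undefined-as-zero convention for empty sets.

**Meter.** The metrical interpretation (time signature category +
phase) is a hidden variable. The category prior is the corpus relative
frequency of notated time signatures; the phase prior is uniform within
a category, on a lattice of multiples of the smallest observed ioi (a
tractability choice). The likelihood of an onset given an
interpretation is a `ContextModel` over (ioi, position-within-bar)
symbols — position = onset modulo bar period under the hypothesis'
phase — which makes both prior and likelihood conditional on the
preceding rhythmic context. Posteriors are accumulated in the log
domain and renormalised per event; dead hypotheses are floored rather
than zeroed. Temporal prediction mixes the per-hypothesis conditional
next-ioi distributions under the current posterior, with prediction
strictly preceding the posterior update. Classification takes the
category with maximal final posterior mass (phases summed out), ties
broken by prior then label order.

**Cultural distance.** Within-culture ICs use k-fold cross-validation
(default 10): melodies are shuffled by a seeded permutation, dealt
round-robin into folds, and each fold is predicted by an LTM trained on
the rest. Between-culture ICs come from the other culture's full-corpus
LTM. The STM is disabled throughout. The 45° rotation gives signed
distance (ic_other − ic_own)/√2 — positive = more predictable under the
own-culture model, the sign convention under which both reference
per-piece distances are positive — and complexity (ic_own +
ic_other)/√2. The corpus-level distance is the mean of *signed*
per-piece distances (the signed and absolute readings coincide only
when every piece is own-model-predictable; the signed one is the
natural average of the rotated coordinate). Accuracy is the fraction of
pieces with positive distance, i.e. minimum-IC classification; an exact
tie yields an `undecided` sentinel rather than a forced label.

Corpus preparation removes duplicates conservatively: two melodies are
duplicates when they share their opening pitch-interval sequence,
rhythm ignored, so transposed copies are caught. The opening length is
a parameter (default 10 intervals; shorter melodies compare over their
full sequence), and the first occurrence in file order survives — the
exact opening length behind the reference procedure is not documented,
so it is exposed rather than hard-coded.

## Synthetic data

The generators are pure functions of (spec, seed) and reproduce
bitwise across runs.

*Two-culture corpora.* Each culture is a first-order Markov chain over
scale degrees (pitch = tonic + degree) plus a chain over ioi ratios
(first ioi 24 ticks; iois clamped to 6..96 ticks, forcing ratio 1 at
the boundary). The default pair contrasts a pentatonic degree set
{0,2,4,7,9} favouring even note values with a diatonic set
{0,2,4,5,7,9,11} with a leading-tone pull and dotted/halved rhythm
preferences — loosely echoing a Chinese/Western folk contrast, with no
claim of ethnographic fidelity. Default 16–32 notes per melody.
`blend_cultures` interpolates the two processes over their union
alphabets to dial divergence in validation experiments.

*Metrical rhythms.* Rhythms are sampled bar by bar from a per-position
onset-probability profile on a 24-tick grid (defaults: 3/4 →
(1.0, 0.7, 0.15); 4/4 → (1.0, 0.15, 0.65, 0.45); 8 bars), downbeat of
the first bar anchored so the true phase is zero.

*Phrase fixtures.* Melodies concatenate 6 phrases of 11–14 notes, each
from one of four near-deterministic cyclic chains in distinct
registers (cycle followed with probability 0.97). Phrases are kept
longer than the default detection window so that one boundary's IC
spike has left the window before the next arrives — the simple
mean/deviation rule is known to mask consecutive peaks closer together
than its window.

*Perturbations.* Rhythm (double/halve selected iois), interval (widen,
contour preserved), contour (flip signs), phrase order (swap two
contiguous segments; applying the complementary cut restores the
original) and modulation (transpose a suffix by two semitones), all
seeded, with magnitude = proportion of editable positions.

What the synthetic data does *not* emulate: real corpora's phrase
repetition structure and motivic development, non-stationarity within
pieces, ornamentation, expressive timing, or the empirical statistics
of any real folk-song collection. Passing tests on these fixtures
demonstrates that each algorithm recovers the structure its own model
class assumes; they say nothing about fit to human listeners or real
corpora, which requires the external corpora the command-line tools
accept.

## Problem sizes and numerical choices

The validation experiments use 200 melodies per culture with 10-fold
cross-validation for the enculturation analysis, 100 test rhythms per
category (trained on 40 each) for meter classification, and 50 seeded
trials for segmentation — sizes at which the seeded Monte-Carlo
variation of every reported statistic is well inside the margins being
asserted. Tie-breaking is deterministic everywhere (corpus order for
equal similarity ranks, prior then label order for equal meter
posteriors, rounded to 12 decimals before comparison to absorb
floating-point jitter). Model serialization is versioned JSON holding
raw counts, so a reloaded model reproduces predictions exactly.

## Known limitations

* No update exclusion or hybrid LTM+ (online-updated long-term model);
  the LTM is static after training.
* Monophonic input only; no voice separation, no harmonic or polyphonic
  modelling.
* No tonic estimation: scale-degree viewpoints need an annotated tonic.
* The **kern/EsAC/MIDI readers are deliberate subsets (single spine,
  core duration/tie/grace syntax, format 0/1 first note track) meant
  for folk-song-style corpora, not full engraving dialects.
* Exact reproduction of published analysis numbers on external corpora
  is configuration-sensitive (order bounds, escape method, alphabet
  closure are not pinned by the source descriptions) and requires those
  corpora; the bundled analyses validate behaviour on synthetic data
  with known ground truth instead.
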