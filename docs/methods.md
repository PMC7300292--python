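# Methods

## Scope and model

`strokenote` treats a creative session as an event-driven system observed
through two digitized channels: a MIDI note/pedal stream for music and a
tablet stroke log for drawing. All analysis rests on one primitive: the
derivation of labeled state intervals that tile the session span
[0, duration] without gap or overlap. Music sessions are `playing` exactly
while ≥ 1 note sounds and `idle` otherwise; art sessions are `erasing`
during eraser-tool strokes, `drawing` during all other strokes and `idle`
otherwise. A fuller hierarchical state formalism (nested or concurrent
states, therapist–client interaction states) is deliberately out of scope:
every metric the package reports is a function of this flat interval
derivation, so the flat form is sufficient and much easier to verify.
"Materials being selected" is not observable in either logged format and is
absorbed into `idle`. The clock starts at the first event of a MIDI file
unless an explicit origin is configured; art logs carry their own clock.
We tile from t = 0, so time before the first event counts as idle.

Adjacent intervals with equal labels are merged and zero-length intervals
dropped. Interval measures are computed by a sweep-line union, verified in
tests against 1 ms brute-force sampling.

## Event model

* Note: onset < offset in seconds, pitch 0–127, intensity (velocity)
  1–127. A velocity-0 note-on is a note-off (MIDI convention); overlapping
  same-pitch notes are matched FIFO per (channel, pitch), which makes
  pairing deterministic. Note duration is the key-press interval only;
  pedal-sustained resonance does not extend it.
* Pedal: CC64 thresholded at value ≥ 64 (the MIDI half-point convention —
  the source material names no threshold); a press is a contiguous hold.
* Tempo: tick→seconds via the file's tempo map; a configurable default
  (120 bpm) applies when the file carries no tempo meta event. SMPTE
  division, aftertouch and pitch-bend are out of scope (the latter two are
  skipped with a warning).
* Stroke: a pen-down→pen-up trace of strictly time-increasing samples with
  normalized pressure ∈ [0, 1]. Canvas coordinates are screen-frame
  (origin top-left, y down). Tool and color tokens come from the
  configured toolset (6 tools incl. eraser) and palette (10 colors);
  eraser strokes carry a color token that color metrics ignore.

The session JSON schema is versioned (`schema_version: 1`) and round-trips
losslessly; the art log exists in a canonical JSONL dialect and an accepted
CSV dialect.

## Metric definitions and conventions

Music:

* Concurrent playing % = 100 × Σ note durations / union playing time;
  undefined (reported absent) with no notes.
* Keyboard denominator for % keys used is 88 (A0–C8); the capture device
  is a piano-style keyboard of unstated size, and 88 is the standard
  full-size assumption.
* Note density is presses per minute of *net playing time* (the
  alternative, per session minute, is a one-line change and deliberately
  not the default).
* Cluster size is the sweep-line concurrency level (overlapping sustains,
  not simultaneous onsets only).
* Octave = floor(pitch/12) − 1, so MIDI 60 = C4. Octave, intensity,
  pitch-class and cluster histograms are duration-weighted and normalized
  to 100%; modal statistics are duration-weighted with ties broken toward
  the lower value. Black-key press share is press-count-weighted (a press
  preference, not a time share).
* Dynamics bands: eight equal 16-value bins of velocity named
  pppp, ppp, pp, p, mf, f, ff, ffff; mf therefore starts at 64, which is
  also the mf guide-line value in the plots.
* Transitions order notes by onset (ties by pitch ascending). Crescendo /
  diminuendo are maximal runs of ≥ 3 onsets with strictly monotone
  intensity; accelerando / ritardando are maximal runs of ≥ 3 strictly
  monotone inter-onset intervals. The run length (3) and strictness are
  package conventions — the phenomena are named in the field without a
  detection rule — and are configurable via `transition_profile(min_run=…)`.

Art:

* Net drawing time is the union of all stroke spans, eraser included;
  erasure % and per-color/per-tool shares all use it as denominator, so
  color shares plus the eraser share partition drawing time exactly.
* Switch rates (color, tool) are per minute of session time — a behavioral
  rate, not a share of drawing time. Color switches skip eraser strokes.
* The (tool, color) crosstab covers non-eraser strokes; eraser time is
  reported once via the erasure share.
* Stroke velocity is arc length over stroke duration; mean drawing
  velocity is total arc length over net drawing time; units are
  canvas-units/s, physical calibration being a metadata concern.
* Amplitude is the bounding-box diagonal (a stated proxy — the underlying
  notion is not defined more precisely in the field).
* Rotation sense is the sign of the shoelace signed area of the closed
  polyline, reported as seen on screen (y-down accounted for); strokes
  whose |area| is below 1% of their bounding-box area are "none", which
  keeps near-straight strokes unclassified.
* Net direction is binned into 8 compass sectors of 45° (N = screen up).
* Canvas grid defaults to 3×3; "boundary" is the outer ring of cells and
  "center" the middle cell(s) (two middle rows/columns for even
  dimensions). Page crossings sum |Δ cell index| over consecutive sample
  pairs per stroke, which makes the count invariant to re-sampling a
  straight segment.
* Mean pressure is dwell-time-weighted (trapezoid weights per sample),
  falling back to a plain mean for zero-extent strokes.

## Group comparison

`one_way_f` computes the classic one-way ANOVA from sums of squares
(numpy), with the p-value from scipy's F distribution; scipy's
`f_oneway`, the two-sample t-test (F ≡ t² for two groups) and pingouin's
η² serve as independent cross-checks in the tests. Observations are
treated as independent — repeated-measure designs are analyzed as if
between-subject, a documented caveat matching how such parameter tables
are typically reported in this literature; note that published df in that
literature do not always match standard (k−1, N−k) accounting, which is
what this package implements. SS components below 1e-12 of SS_total are
treated as zero so identical groups report exactly F = 0, p = 1; zero
within-group variance with unequal means reports F = ∞, p = 0, flagged
`degenerate`. No multiple-testing correction is applied by default; a
Benjamini–Hochberg option (`fdr=True`) is provided. Metrics undefined for
a session (None) drop that session; histogram bins a session never touched
count as 0%.

Superposition is start-aligned (each source shifted so its first onset is
t = 0), not duration-normalized; the merged duration is the maximum source
duration and splitting by source tag recovers the inputs.

## Reports

SVG output is deterministic (fixed `svg.hashsalt`, date metadata
suppressed): identical inputs yield byte-identical files, which the tests
rely on. The heatmap colormap is perceptually uniform ("inferno"), softer
notes rendering colder; guide lines sit at intensity 64 (mf) and pitch 60
(C4). Art superpositions default to 50% opacity. All table numbers are
the metric fields verbatim (percentages rounded to 1 decimal); the
renderer derives nothing itself. Palette RGB values and the colormap are
style-config defaults, not claims of visual identity with any particular
published figure.

## Synthetic sessions

The generator is first-class, tested code, not a fixture. Music: note
onsets are a homogeneous Poisson process (default 60 onsets/min over
120 s); each onset draws a cluster size ({1: 0.7, 2: 0.2, 3: 0.1} by
default), an octave from a discretized normal (center 4, spread 1), a
pitch class black with probability 5/12 (uniform within the chosen class
set), an intensity from a normal (mean 64, sd 15) clipped to 1–127, and an
exponential duration (mean 0.8 s); pedal presses are a sparser Poisson
process (2/min) with exponential holds of mean 4 s, in the seconds-per-
press range reported for real improvisations. Art: stroke starts are
Poisson (12/min), sequentialized so a single pen never draws two strokes
at once; paths are random walks with Gaussian heading increments at a
target speed (150 units/s, exponential lengths of mean 200 units) sampled
at 50 Hz from cells drawn by a bias map over an 800×600 canvas; tools and
colors are weighted draws with a 0.1 eraser probability; pressures are
clipped normals (0.5 ± 0.15). Defaults are meant as plausible session
statistics for a layperson improviser/drawer; where no published value
pins them down they were chosen once and documented here.

What the generator does *not* emulate: rhythmic and phrase structure,
harmony, hand anatomy, figurative drawing content, correlated pressure
profiles. Passing tests therefore validate the measurement pipeline's
correctness and calibration on known structure, not any claim about human
behavior.

`recovery_report` simulates n replicates (seeds spawned deterministically
from the profile seed, kept below 2³¹) and compares estimable parameters —
intensity mean, modal octave, modal cluster, black-key share, erasure
share, color shares, pressure mean — against profile truth. The
acceptance battery checks recovery at 20 replicates × 120 s.

## Numerical choices

* Time is float seconds throughout; interval tiling asserts closure to
  1e-9 s; merged-label tolerance 1e-12 s.
* The 1 ms sampling oracles in the tests are compared at 0.5% relative
  error with small absolute slack for boundary-bin misassignment.
* MIDI writing quantizes to 480 PPQ at 120 bpm (≈ 1 ms resolution);
  round-trip tests allow 2 ms.
* Histogram/modal tie-breaks: lower value wins; float weights compared
  with a 1e-12 guard.

## Known limitations

* Single-pen, single-keyboard capture; overlapping strokes are rejected
  rather than modeled.
* ANOVA assumes independence and homoscedasticity; no mixed-effects or
  repeated-measures support.
* The MIDI reader covers format 0/1 with PPQ division only.
* Art "pattern" analysis is limited to rotation sense and direction
  binning; shape/figurativeness analysis is out of scope.
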