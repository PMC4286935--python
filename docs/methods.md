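# Methods

## The diagram model

A diagram is fully determined by four inputs: a single-bait experiment
(ordered rows `bait,arc_class,prey`), a reference of ordered, named protein
sets, an ordered RGB palette, and the layout options. The pipeline is a pure
function of these: parse → dedupe → map → assign colors → segment layout →
arc geometry → render. There is no randomness anywhere downstream of the
fixture generator, and both renderers are byte-deterministic, so identical
inputs always produce identical files.

### Angular layout

All widths are expressed in *protein units*: one reference entry = 1 unit,
the bait sector = `bait_units`, each of the two white spacers flanking the
bait = `spacer_units`. The unit angle is

    u = 360 / (total entries + bait_units + 2 * spacer_units)

and every sector's width is its unit count times `u`, so the ring tiles to
exactly 360° and set widths are proportional to set sizes. With the default
`spacer_units = 3` a spacer spans exactly three protein slots and serves as
a scale bar. Angles are degrees in the mathematical convention
(counterclockwise positive), normalized to [0°, 360°); the clockwise default
is a sign flip applied while walking the ring, and the SVG backend flips the
y axis once at emission.

An empty protein set yields a zero-width segment (with a warning) rather
than being dropped, so set indices in the geometry always align with the
reference; zero-width segments are skipped at render time.

### Mapping semantics

Prey ids are matched to reference column 2 by exact, case-sensitive string
equality after stripping surrounding whitespace — identifiers such as
UniProt accessions are case-significant and must not be folded. "First
occurrence" for reappearance-OFF mapping means lowest `(set_index,
entry_index)`, i.e. reference-file order, the only ordering the user can see
and control. Two invariants follow directly and are asserted in tests:

* conservation: `|OFF arcs| + |unmatched| = |deduplicated records|`;
* containment: the OFF arc set is a subset of the ON arc set, with equality
  exactly when no mapped prey occurs more than once in the reference.

Exact duplicate experiment rows are collapsed to their first occurrence by
default (duplicate arcs would overdraw invisibly); the removals are
reported and the behavior can be disabled. Rows that differ only in arc
class are distinct interactions, not duplicates. Unmatched preys are
warnings plus a machine-readable report, never errors: a prey list and an
annotation reference legitimately overlap only partially.

### Arc geometry

Arcs are quadratic Béziers whose endpoints sit on the ring's inner edge:
from the bait sector's midpoint to the midpoint of the prey's one-unit slot
(slot midpoints keep every anchor strictly interior to its sector, and
distinct preys within a set get visibly distinct anchors). The control
point is the circle center displaced toward the chord midpoint by the
fraction `arc_tension`; tension 0 (default) sends every arc through the
center, the classic look for "interactions radiate from the bait", while
higher tension flattens crowded diagrams. Arcs whose endpoints are within
10⁻³ degrees of each other cannot form a visible curve; they are flagged
degenerate, warned about, and drawn as a short radial stub (15 % of the
inner radius) so the interaction is still visible.

`ppi` arcs take the color of the set that contains their prey occurrence;
`ivtk` arcs are always black and are ordered after all `ppi` arcs so
substrate relationships draw on top. Overdraw is handled with a default
stroke opacity of 0.8.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `spacer_units` | 3 | protein slots | scale-bar rule |
| `bait_units` | 3 | protein slots | bait sector visually comparable to a spacer; no canonical value exists |
| `radius` | 0.85 | fraction of canvas half-extent | leaves room for labels outside the ring |
| `ring_thickness` | 0.06 | fraction of radius | thin annulus, arcs dominate |
| `bait_center_angle` | 90° | degrees | bait at the top; orientation is a free choice, fixed for reproducibility |
| `clockwise` | true | — | reading order of the sets |
| `arc_tension` | 0 | [0, 1] | arcs through the center |
| `canvas_size` | 800×800 | points | comfortable for slides and print |
| `arc_stroke` | 1.2 | points | legible at default canvas size |

## Synthetic data generator

`proteoring.fixtures.generate_fixture` builds experiment/reference/palette
trios that emulate the *shape* of a filtered AP-MS projection: a handful of
sets of 5–15 proteins (a realistic sub-complex annotation scale), a
controlled fraction of proteins duplicated into a second set (defaults to
20 %, producing the cross-set redundancy reappearance mapping exists for), a
controlled fraction of preys absent from the reference (default 10 %), and
optional exact-duplicate rows. The default experiment size (12 `ppi` + 4
`ivtk` rows) matches the tens-of-interactors scale of a single-kinase
pull-down. Ground-truth ON/OFF/unmatched counts are recorded *while
generating* — every duplication and omission is tracked by independent
bookkeeping — so pipeline tests compare against construction-time truth, not
against the code under test.

What the generator does **not** emulate: identifier noise (isoforms,
obsolete accessions), abundance or score columns (the tool assumes upstream
filtering is done), biologically structured overlap (duplications are
uniform, real complexes share specific cores), or very large references.
Passing tests therefore demonstrate the correctness of parsing, mapping,
layout and rendering logic on well-formed inputs of realistic size — not
robustness to dirty identifier spaces, which exact matching deliberately
refuses to paper over.

## Numerical choices

* Widths are computed as `n_units × u`, never by differencing angles, so the
  tiling identity `Σ widths = 360°` holds to the accumulation error of a
  dozen additions (asserted at 10⁻⁶ degrees; proportionality at 10⁻⁹
  relative).
* Degenerate-arc threshold: 10⁻³ degrees of angular separation.
* Ties and orderings are all inherited from file order; nothing is sorted by
  id, so the user's file order is the single source of ordering truth.
* SVG floats are written at four decimals (a tenth of a milli-point at
  default canvas size); the PDF creation date is pinned and stream
  compression disabled so both backends are byte-reproducible.

## Design choices where the ground truth was open

* **One bait per experiment file.** The layout has exactly one bait sector;
  a file with two distinct bait ids is a hard error rather than a silent
  "first wins".
* **No CSV quoting.** The dialects are plain comma-split; ids or
  descriptions containing commas are rejected rather than guessed at.
* **Spacers as gaps.** White sectors are rendered as background gaps by
  default so diagrams composite onto non-white slides; `fill_spacers`
  restores solid white.
* **SVG is canonical; PDF is drawn, not converted.** Both backends consume
  the same scene, avoiding converter drift; the scene itself serializes to
  JSON so external renderers (or a later re-render with different styling)
  can skip the mapping and layout stages.
* **The bait's own id is mapped like any prey** if it appears in the prey
  column; the bait sector itself is never an arc target — arcs originate
  there.

## Limitations

* No fuzzy or isoform-aware id matching, no id-translation services.
* Single-ring layouts only; no stacked annuli, edge bundling, or
  interactivity.
* No raster export (rasterize the SVG/PDF downstream if needed).
* `compare` renders one diagram per experiment over a shared layout; it does
  not compute overlap statistics — the diagrams are the deliverable.
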