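# proteoring

Circular bait–prey interaction diagrams for affinity-purification mass
spectrometry (AP-MS) experiments.

An AP-MS experiment enriches one tagged or antibody-bound protein (the
*bait*) and identifies everything that co-purifies with it (the *preys*, or
interactors). The standard node-and-edge network pictures of such data are
hard to read for anyone but the specialist, and integrating the experiment
with an orthogonal annotation — say, the functional sub-complexes of the
spliceosome — is awkward. `proteoring` draws the experiment as a circular
diagram instead: annotated *protein sets* occupy colored sectors of an outer
ring, the bait sits in a black sector, and every bait–prey interaction is an
arc from the bait into the prey's slot in its set. Colored arcs mark
protein–protein interactions (`ppi`), black arcs mark in vitro kinase
substrates (`ivtk`). It is aimed at proteomics groups who already have a
filtered, high-confidence prey list and want a publication-quality,
immediately interpretable figure.

## The layout model

Let the reference define sets of sizes `n_1 … n_k`, and let `b` and `s` be
the bait and spacer widths in protein units (both default 3). One protein
occupies one unit, and the unit angle is

```
u = 360° / (Σ nᵢ + b + 2s)
```

The ring is walked from the bait sector (centered at 90°, clockwise by
default): bait → white spacer → set₁ → … → set_k → white spacer. Sector
widths are proportional to protein counts, and each white spacer spans
exactly `s` = 3 protein widths, doubling as a visual scale bar. Each arc is
a quadratic Bézier from the bait sector's midpoint to the midpoint of the
prey's one-unit slot, with its control point at the circle center (a
*tension* option pulls it toward the chord for dense diagrams).

**Reappearance mapping.** A protein may belong to several sets (several
sub-complexes, or several baits' prey lists in a *lenticular* comparison).
With reappearance **on**, every occurrence of a matched prey gets its own
arc — the redundant view that exposes overlap between sets. With
reappearance **off**, only the first occurrence in reference-file order is
drawn — the non-redundant view that shows what is new relative to earlier
sets. Preys absent from the reference are reported, never fatal.

## Input files

Three comma-delimited text files (no quoting; ids must not contain commas):

| file | row format | notes |
|---|---|---|
| experiment | `bait_id,arc_class,prey_id` | `arc_class` ∈ {`ppi`, `ivtk`}; one bait per file |
| reference | `>Set name` header lines, then `desc,protein_id,desc` rows | FASTA-like blocks; the same id may occur in several sets |
| colors | `R,G,B` integers 0–255 | cycled when sets outnumber colors |

## Worked example

`experiment.csv` — SRPK1 with four interactors, one of which (SRSF1,
Q07955) is also an in vitro kinase substrate:

```
SRPK1,ppi,Q07955
SRPK1,ppi,P84103
SRPK1,ppi,Q05519
SRPK1,ivtk,Q07955
SRPK1,ppi,Q13243
```

`reference.csv` — two spliceosomal sub-complexes; note SRSF3 (P84103)
appears in both:

```
>U1 snRNP
serine/arginine-rich splicing factor 1,Q07955,SRSF1
serine/arginine-rich splicing factor 3,P84103,SRSF3
>17S U2
serine/arginine-rich splicing factor 11,Q05519,SRSF11
serine/arginine-rich splicing factor 5,Q13243,SRSF5
splicing factor 3B subunit 1,O75533,SF3B1
serine/arginine-rich splicing factor 3,P84103,SRSF3
```

With `colors.csv` holding two RGB rows:

```
$ proteoring draw experiment.csv reference.csv colors.csv -o srpk1.svg --reappearance on
wrote srpk1.svg (6 arcs, 0 unmatched)

$ proteoring validate experiment.csv reference.csv colors.csv
experiment: bait 'SRPK1', 5 rows (0 duplicate)
reference: 2 sets, 6 entries
colors: 2
mapping: 6 arcs (reappearance on), 0 unmatched preys
```

Five experiment rows become **6** arcs because P84103 occurs in both sets
and reappearance is on; with `--reappearance off` it would be 5. The `ivtk`
row is drawn as a black arc on top of the colored ones. Other subcommands:
`fixture` emits a seeded synthetic trio, `compare` renders several
experiment files against one shared reference with identical sector
geometry (the lenticular comparison), and `render` re-renders a saved
scene-JSON file without recomputing layout.

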