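# Methods

`lsukit` models how the four Arabidopsis thaliana LSU (RESPONSE TO LOW
SULFUR) proteins dimerize through their coiled-coil regions, scores
TAP-MS co-purification data for candidate interaction partners, and ranks
interaction-network hubs enriched in LSU-partner contacts.  This note
records the models, their assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Coiled-coil dimer models

### Template geometry

Dimer models are built on a two-helix parallel template.  The default
template is an ideal two-stranded left-handed coiled coil generated from
the Crick parameterization: each helix axis winds around a common
superhelical z-axis, the two helices 180° apart in superhelical phase, with
backbone and side-chain-anchor atoms placed on a minor helix whose plane is
tilted by the pitch angle so the CA trace is uniform.

Defaults (all configurable):

| parameter | default | unit | rationale |
|---|---|---|---|
| superhelical radius | 4.9 | Å | canonical for two-stranded left-handed coils |
| rise per residue | 1.51 | Å | canonical |
| residues per helix turn | 3.62 | — | canonical α-helix twist |
| superhelical pitch | 150 | Å | canonical |
| slots per helix | 59 | — | the modeled span, residues 7–65 |

With these values the side-chain phase advances ~103°/residue relative to
the rotating inter-helix normal, i.e. near-exact heptad (abcdefg)
periodicity: residues spaced 7 apart point the same way, and a/d-layer side
chains face the partner helix.  A template can instead be loaded from any
two-chain α-helical PDB file; missing CB atoms are reconstructed from
backbone geometry, antiparallel chains are rejected (only parallel dimers
are modeled), and chains of unequal usable length are truncated to the
common length.

### Register scanning and the zipper score

A sequence pair is threaded onto the template over the modeled span
(default residues 7–65; the region predicted coiled-coil in all four LSUs
is 9–39).  Each chain is offset by an integer register shift; residues
pushed past a template end are dropped, no gaps are ever introduced, and a
register leaving fewer than 7 residues on either helix is degenerate and
excluded.  The scan enumerates all combinations of shifts in
[−25, +25] per helix — 51 values each, 2,601 models per pair, about half a
supercoil turn — and every model is scored by the **leucine-zipper contact
count**: the number of leucine side chains (over both chains) whose anchor
point lies within 8.0 Å of a leucine anchor on the opposite chain.

Two operationalizations are this package's own:

* **Contact criterion.** CB–CB distance ≤ 8.0 Å.  CB–CB distances of
  core-packed leucines in two-stranded coiled coils fall well below 8 Å,
  while outward-facing pairs exceed it; the cutoff is a flag
  (`--cutoff`).
* **Counting residues, not pairs.** The score counts leucine side chains
  involved in at least one intermolecular contact, so it is bounded by the
  number of placed leucines and removing a leucine can never raise it.

Best models are all registers attaining the maximal score, ordered by
|Δshift| ascending then lexicographic shifts (deterministic output).  The
set of optimal Δshift = shiftA − shiftB values is reported as the pair's
register-shift series.

The interface score in `interface_energy_proxy` is a deliberately crude
contact-count proxy (−1 per hydrophobic–hydrophobic contact, ±0.5 per
charged contact): free-energy estimates for coiled-coil fragments of this
size are dominated by flanking-residue effects and are not quantitatively
meaningful, so the proxy is used only for qualitative comparisons and is
labeled as such.

### Mutation-effect prediction

`predict_mutation_effect` combines two deterministic terms:

* **zipper_delta** — best zipper score of the mutant minus best zipper
  score of the wild type, each over the full register grid;
* **electro_delta** — intra-helical charge pairs at (i, i±3) and (i, i±4)
  created or removed by the substitution (+1 per like-charge pair created,
  −1 per opposite-charge pair created, with the reverse signs for pairs
  removed).  Like-charge pairs one helix turn apart destabilize a helix;
  opposite-charge pairs stabilize it.

Verdict rule (a design choice of this package, stated in every report):
destabilizing if zipper_delta < 0 or electro_delta > 0; stabilizing if
zipper_delta > 0 or electro_delta < 0; neutral otherwise; the zipper term
dominates when the two disagree.  On LSU1-like homodimers this reproduces
the expected directions: C54A neutral, C54E destabilizing (E51/E54
repulsion), C54R stabilizing (E51/R54 attraction), L60A destabilizing with
a weaker zipper loss when only one chain of an odd–even heterodimer is
mutated.

## TAP-MS specificity scoring

Inputs are a MaxQuant-proteinGroups-style TSV (group id, molecular weight
in kDa, one intensity column per run) and a design TSV mapping runs to
(bait, condition, replicate).  The experimental frame is four TAP-tagged
baits (LSU1–4) × four growth conditions (4 or 10 days, sulfur-sufficient
`nS` or sulfur-deficient `-S`) = 16 datasets, plus a tag-only control line;
three biological replicates for the LSU1 and control lines, two for the
others.  Contaminant/decoy rows (`CON__`/`REV__` prefixes) are dropped.

Per (protein group, bait, condition):

* **abundance** = mean probe intensity / molecular weight (kDa);
* **relative specificity** = log10(median probe / median control), with the
  control median replaced by 1 when the protein is never detected in the
  control (the arbitrary background level);
* **candidate** ⇔ relative specificity strictly > 1 (a 10-fold enrichment
  boundary is *not* a candidate) and detection in ≥ 1 probe replicate.

Per-replicate handling is not fully constrained by the recipe, so this
package takes the following stance: undetected replicates are observed
zeros and enter the median (a protein seen in 1 of 3 probe replicates has
probe median 0 and is never a candidate); only the all-undetected control
case invokes the background = 1 rule; medians are taken within one
(bait, condition) dataset, never pooled across conditions.  Intensities
are used in arbitrary MaxQuant units with no cross-run normalization.
Protein groups that MS cannot resolve (e.g. an LSU2/LSU4 group) are atomic
analysis units, expanded to their member proteins only in reports.
Incidence is the number of datasets (max 16) in which a group is a
candidate; a bait's own protein group in its own line is flagged and
excluded from partner incidence.

## Interactome hub analysis

The network is an undirected simple graph (interaction assays give no
reliable direction; duplicate edges and self-loops are dropped) with two
designated node sets: the four LSU baits and the LSU partners (direct LSU
interactors).  For each connected non-bait node, `degree.LSU` counts its
neighbors inside the partner set, `degree.total` all neighbors, and the
hub statistic is their ratio.  Bait nodes are excluded from candidacy and
from `degree.LSU` (they define the partner set rather than belong to it).

Hub selection and hub ordering use different statistics on purpose:
selection takes the top k (default 9) by ratio after filtering to
`degree.LSU ≥ 10` (the smallest partner degree worth reporting, a flag),
and the selection is then ordered by `degree.LSU` descending for
reporting; `--select-by degree_lsu` ranks purely by partner degree
instead.  All ties break by node id.

## Synthetic data

The generators produce inputs with exactly the statistical structure the
analyses assume, plus ground truth, so every stage is testable without any
download.

* **Sequences** — four 100-residue sequences with leucines exactly at the
  landmark positions of each LSU protein (LSU1/LSU3: 18, 25, 29, 53, 57,
  60, 65, 78, 85; LSU2: 18, 29, 37, 53, 57, 60, 65, 78, 82, 85; LSU4: the
  same minus 85), E at 51 and C at 54 in all four, an initiator M, and a
  helix-favoring background (A/E/K/Q/R) that contains no leucine or other
  hydrophobics; within ±4 of any landmark the background is restricted to
  A/Q so no accidental charge pairs or zipper contacts arise.  A FASTA of
  these sequences (seed 0) ships with the package
  (`lsukit/data/lsu_synthetic.fasta`) and is explicitly synthetic.
* **TAP-MS tables** — 200 background proteins with equal expected
  intensity in probe and control (true ratio 1); 3 planted partners per
  bait whose intensity is multiplied by the fold enrichment (default
  100×) in their bait's probe datasets only; bait LSU groups (with
  LSU2/LSU4 ambiguous) detected only in their own lines; multiplicative
  log-normal noise with sd 0.2 in log10 units (matching the scale of the
  specificity statistic; a typical label-free replicate spread); dropout
  default 0 (0.2 for robustness experiments); molecular weights uniform
  10–150 kDa; base intensities log-uniform 10⁶–10⁸.
* **Networks** — 4 baits, 20 partners (each wired to a random nonempty
  subset of baits), 5 planted hubs attached to each partner with
  probability 0.8 and to each of 200 background nodes with probability
  0.02, and uniform background wiring at 0.02.  Planted hubs therefore
  have expected ratio ≈ 0.8 and expected partner degree 16, comfortably
  above the degree-10 reporting floor, while background nodes essentially
  never reach it.

What the generators deliberately do **not** emulate: correlated
backgrounds across runs, intensity-dependent missingness, shared peptides
beyond the single ambiguous LSU2/LSU4 group, and literature-network degree
distributions.  Passing recovery tests therefore demonstrates correctness
of the statistics and the planted-signal detectability at the stated
settings, not performance on real purifications or curated networks.

## Numerical and degenerate-input choices

* All randomness flows through a single integer seed per simulation
  (`numpy.random.default_rng`); identical seeds give identical outputs,
  byte-for-byte in the tabular exports.
* Degenerate registers carry a −inf sentinel in the score grid and can
  never be selected; an all-degenerate grid is an error, not an empty
  result.
* The relative-specificity sentinel for all-undetected probes is NaN and
  compares false against any threshold.
* Ties everywhere (auto-phase, best-model ordering, hub ranking) break
  deterministically (lowest index / lexicographic / node id).

## Problem sizes used in the recovery studies

The acceptance script and test suite run the register scans at full size
(2,601 models per pair, 16 pairs), the TAP-MS recovery over 20 simulation
seeds (960 planted-partner datasets), and the hub recovery over 50
networks — sizes at which the binomial tails of the planted effects make
the expected recovery essentially 100%.

## Limitations

* The published TAP-MS candidate count (46 protein groups over 16
  datasets) depends on reprocessing the deposited raw mass-spectrometry
  data against a dated proteome database and is not recomputed here; the
  specificity statistics are instead validated on planted synthetic
  tables.
* The full-length LSU sequences are not bundled; only their
  leucine/E51/C54 landmarks are encoded in the synthetic sequences.  The
  ±4 odd–even register-shift preference reported for real odd–even LSU
  heterodimers depends on the complete sequences and the original modeling
  stack, so it is exposed as a qualitative report (the Δshift series per
  pair), not asserted as a test.
* Hub degree values from the curated literature network (e.g. a top hub
  with 33 partner interactions) are only checkable when that interaction
  list is supplied by the user; the bundled networks are synthetic.
* The energy proxy is not a free energy; it must not be compared across
  templates or cutoffs.
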