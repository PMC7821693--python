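# Methods

## Scope and model

`coilmap` analyzes long parallel two-helix coiled-coil domains — the
C-terminal tails of KfrA-type plasmid proteins are the motivating case — at
the level of Cα geometry and sequence register.  The package contains two
halves that check each other:

1. an **analytic generator** that builds Cα-only bundles from an explicit
   Crick parameterization, optionally with planted local distortions, and
2. a **measurement pipeline** that recovers per-layer supercoiling,
   handedness, Crick phase and heptad register from coordinates alone.

Because the generator is exact, every measurement has a known ground truth,
and the package's correctness claims are round-trip claims: planted
parameters and events are recovered within stated tolerances.

## Crick parameterization

Each chain's local helix axis winds around the global bundle (z) axis at
radius R0 with angular frequency ω0 (degrees/residue; negative = left-handed)
while rising h Å/residue.  The Cα sits at radius R1 from the local axis at
the minor-helix phase φ(t) = φ1 + ω1·t (+ any planted jumps), measured **in
the rotating frame** whose zero direction points from the local axis toward
the bundle axis, advancing right-handedly about the local N→C axis direction.

In this frame ω1 = 720/7 °/residue gives an exact 7-residue register repeat;
the lab-frame helix twist is ω1 + ω0 ≈ 99.3°/residue for canonical ω0 =
−3.6, i.e. the familiar 3.62 residues/turn of an α-helix in a left-handed
coiled coil.  Defaults (R0 = 4.9 Å, R1 = 2.26 Å, ω1 = 720/7, ω0 = −3.6,
h = 1.51 Å/residue, chains at 0°/180°) are standard literature values for a
parallel dimer; none are fits to any particular structure, and all are
overridable per residue segment.

### Planted distortions

Distortions are segment overrides on the parameters, so their ground truth is
exact:

- **unwound**: ω0 → 0 over a segment (default 14 residues);
- **right_handed**: ω0 sign-flipped over a segment;
- **stutter** / **stammer**: a single minor-helix phase jump between two
  residues.  The jump sizes follow from the bin arithmetic below: phase
  advances two bins per residue while the register letter advances one, so a
  jump of Δ bins advances the letter by 4Δ (mod 7).  A stutter (register
  advance of 4 at the seam, the classical 4-residue insertion) is a jump of
  −360/7°; a stammer (advance of 3) is +4·360/7°.

## Axis estimation

The local helix axis point for residue i is built from the bisector
construction: m_i = (Cα_{i−1} + Cα_{i+1})/2 − Cα_i points at the local axis
with magnitude R(1 − cos ω̂), where the local twist ω̂ is the angle between
consecutive mid-vectors; the raw axis point is Cα_i + m_i/(1 − cos ω̂).  This
is exact for a straight helix, but for a supercoiled chain the raw points
carry a small periodic error at the lab twist frequency (and its second
harmonic) — worst case ≈ 0.5°/residue in the supercoil trace at ω0 = −5.

The estimator therefore applies two cascaded three-point notch kernels
[1, c, 1]/(c + 2) with c = −2cos ω̂ and c = −2cos 2ω̂.  Each kernel has an
exact transfer-function null at its target frequency; at the (much lower)
superhelical frequency its effect reduces to a ≲0.2% radial scaling, which
leaves angular advance about the bundle axis — the measured quantity —
unchanged.  Worst-case round-trip error after both passes is < 0.07°/residue
for |ω0| ≤ 6.  Each pass costs one residue of support, so axis estimates
exist for residues 4 … n−4; termini are reported as missing, never as zero.

The bundle axis is the per-layer centroid of the chains' axis points (chains
registered index-to-index; an integer register offset is a parameter).  The
**local supercoil** at layer i is the signed angle, about the local bundle
axis direction, between the projections of the chain-axis points of layers i
and i+1 onto the normal plane, averaged over chains.  Handedness uses a
dead-zone ε = 0.5°/residue (measured round-trip noise is < 0.07): |value| ≤ ε
→ "none".

## Crick phase and heptad register

The measured phase of residue i is the signed angle between (axis point →
Cα_i) and (axis point → bundle-axis point) in the plane normal to the local
chain axis; 0° faces the bundle core.  Phases fall into seven 360/7° bins;
the bin [0°, 51.43°) is position a and [308.57°, 360°) is d, so the two
core positions straddle the core direction, and bins follow the phase order
a, e, b, f, c, g, d (bin k ↔ letter 4k mod 7).  The anchor is configurable;
any cyclic rotation relabels positions without creating or destroying
discontinuities.

A **discontinuity** is a transition whose register advance (mod 7) is not 1.
The reported shift is the observed advance normalized to an adjacent step:
4 = stutter, 3 = stammer, anything else (including 0, a repeated letter) =
"other".  Unassigned runs ≤ 3 residues are bridged (expected advance grows
with the gap); longer runs split the register into independent segments with
no event at the seam.  For registers measured from coordinates, one planted
break smears into a short cluster of raw transitions because the axis
estimate is perturbed over ±3 residues; `merge_window=4` combines clusters
into single net events (net shift = Σ(shift−1)+1 mod 7), which recovers
planted shifts exactly and cancels paired glitches.  For prediction-derived
registers the raw (unmerged) events are the right output and are the
default.

The `detect_discontinuities` oracle tests exhaustively enumerate all strings
of length ≤ 5 and sample longer ones; this is complete coverage because each
transition decision depends only on the two flanking assigned residues.

## Ensemble maps and region calls

A map row is one model's (or frame's) chain-averaged supercoil trace; rows
sort best-score-first or by time.  A cell is non-canonical when its
handedness is not left (value > −ε); a column is flagged when ≥ 50%
(`persistence_min`) of its non-missing cells are non-canonical; maximal runs
of ≥ 7 flagged columns (one heptad, `min_len`) become region calls labeled by
terciles of the column range.  Missing cells are excluded from persistence
denominators.  Thresholds are package choices — no published values exist for
them — and are arguments, not constants.  Recovery of planted 50–80-residue
regions present in 80% of 100 models achieves Jaccard ≥ 0.9, with edges
blurred by ±2 residues where the axis estimator spans the segment boundary.

## Property profiles

Residues are grouped by heptad position; per group the package reports count,
mean hydrophobicity (Kyte–Doolittle) and mean residue volume (Zamyatnin, Å³).
Both scales are packaged as plain tables and swappable; they are defaults of
convenience, not claims about which scale any prior analysis used.  The
reference profile is built from user-supplied sequences or from the packaged
**synthetic** reference generator: canonical-register sequences drawn from a
hand-written per-position composition (aliphatic core, charged flanks, polar
solvent face).  It emulates the *shape* of a curated coiled-coil reference
set — core/solvent hydrophobicity contrast, mid-range volumes — but not its
real sequence diversity, so self-consistency tests (zero self-deviation,
alanine-enrichment arithmetic) are meaningful while absolute deviations of
real sequences from this synthetic background are not.

## Family architecture scan

Probability tracks are segmented at p ≥ 0.5 (medium) and p ≥ 0.75 (high)
with gaps ≤ 3 bridged and segments < 14 residues (two heptads) discarded.
A track has the head-tail architecture when a high-confidence segment starts
strictly after the last HTH interval ends; overlapping segments raise a
separate flag rather than being counted.  Non-canonical status runs
discontinuity detection on the predicted register restricted to medium
segments.  Family fractions are exact counts; the non-canonical denominator
is CC-containing tracks.  The synthetic family generator plants all flags
with `round(fraction·denominator)` counts, so summaries recover planted
fractions exactly whenever the products are integers.

## Thermal melts

Melting curves are two-state logistics with additive Gaussian noise —
the simplest model consistent with a single cooperative unfolding
transition.  MRE = θ_mdeg/(10·N·c·l).  Tm is the temperature of the extremum
of the first derivative (centered differences), refined by parabolic
interpolation through the extremum and its neighbors; flat or purely linear
profiles raise an explicit no-transition error.  Savitzky–Golay smoothing
(order 2) is available but off by default — at 2 °C sampling the raw
derivative is well conditioned, and smoothing should be an explicit choice.
Noiseless recovery on the 10–90 °C / 2 °C grid is exact to < 0.1 °C;
with noise at 2% of amplitude, 100-seed recovery within ±2 °C exceeds 95%
(with window-5 smoothing).

## Problem sizes and determinism

Default study sizes mirror the motivating analysis: 251-residue domains,
100-model ensembles, 800-sequence synthetic reference, families of 100–200
tracks, 41-point melt grids.  The test suite and the acceptance script use
these sizes directly except where a smaller instance exercises the identical
code path (20-residue oracle bundles, 10-model determinism runs).  All
randomness flows through explicit `numpy.random.default_rng` seeds; identical
seeds give bit-identical outputs, which the determinism tests assert at the
byte level on written files.

## Known limitations

- Cα-only geometry: no side-chain packing, knobs-into-holes analysis, or
  energetics; register is inferred from phase alone.
- The generator's distortions are idealized (piecewise-constant parameters,
  discrete phase jumps); real folding ensembles blur boundaries further than
  the ±2-residue localization seen here.
- Layer registration assumes in-register parallel chains (an integer offset
  is supported); antiparallel or sheared bundles are out of scope.
- The synthetic reference and synthetic families validate bookkeeping and
  contrasts, not biological composition statistics.
- Axis estimates (and everything downstream) are undefined for the first and
  last three residues of a chain.
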