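# Methods

## Model

A miRNA duplex is the two-stranded Dicer product: the 5p arm and the 3p
arm, typically ~19–24 nt each with 2-nt 3' overhangs at both ends.  Its
secondary structure is predicted with the nearest-neighbour thermodynamic
model as implemented in ViennaRNA (two-strand cofolding); all coordinates
in the package are 1-based over the concatenated `seq5p + seq3p` string
with the `&` separator removed, and `strand_break = len(seq5p)`.

A duplex **end** is formed by both strands.  The 5p end comprises the
first *n* nucleotides of the 5p strand plus the last *n* of the 3p strand;
the 3p end comprises the last *n* of the 5p strand plus the first *n* of
the 3p strand.  Windows cover both strands because forbidding only one
partner of a base pair lets the other partner re-pair elsewhere, which
would not represent an unwound end.  Overhang nucleotides count as window
members: they are terminal nucleotides that happen to be unpaired already,
which is exactly why an already-open end costs nothing to unwind.

The **unwinding energy** of an end at width *n* ∈ {1..4} is

    ΔΔG(end, n) = ΔG(partially unwound) − ΔG(fully wound reference),

with three regimes differing in the reference and in what the rest of the
duplex may do while the window is held open:

* `mfe_pinned` — reference is the unconstrained duplex MFE structure; the
  remainder of the duplex is pinned to it.  ΔΔG ≥ 0 always (the reference
  is the global minimum), and ΔΔG = 0 whenever the window is already
  unpaired in the MFE.
* `hairpin_pinned` — reference is the hairpin-derived duplex structure:
  exactly those base pairs whose both partners lie inside the two arm
  intervals of the precursor hairpin's MFE fold, re-indexed to duplex
  coordinates.  ΔΔG may be negative: a duplex held in its precursor's
  pairing can be energetically favoured to unwind once liberated.
* `ends_only` — no pin; the duplex refolds freely into the constrained
  MFE.  The wound reference is the unconstrained MFE (so values of zero
  again mean "already open"), and by feasible-set inclusion the
  `ends_only` energy never exceeds the `mfe_pinned` energy.

Pinning is expressed as engine hard constraints: matched `()` for every
reference pair (enforced), `x` for every reference-unpaired position.
Unpaired positions are forbidden rather than left free because a free
position would let the engine add pairs absent from the reference, and the
unwinding energy is defined against the fixed reference structure.
Opening a window turns its positions to `x` and releases every pinned pair
with at least one partner inside it — both partners, never one.

### Nearest-neighbour comparison method

The comparison method sums published stacked-pair free energies (ΔG°37)
over the first 1–4 helix steps counted inward from an end, walking the
strand whose 5' terminus forms that end.  An unpaired, bulged or
mismatched position terminates the walk; remaining terms contribute zero.
This mirrors the zero cost of an already-open end, and is the conservative
choice given that the stack table has no parameters for interrupted steps.
The table is read at run time from the engine's Turner 2004 parameter set
at 37 °C (the published nearest-neighbour database values; spot values are
frozen in the test suite against the published numbers).  The 37 °C
parameters are deliberately not rescaled: the point of the comparison is
that this method cannot be evaluated at physiological temperature, whereas
unwinding energies can.

### Twin-drive strand-selection model

    ln(5p/3p) = k · (ΔΔG_5p_end − ΔΔG_3p_end) + N[nt5p] − N[nt3p]

`nt5p`/`nt3p` are the 5'-terminal bases of the two strands.  Positive
ln(5p/3p) predicts 5p dominance; an exact zero is "ambiguous" and scored
incorrect (scoring ties as correct would inflate accuracy).  Prediction is
blind to the annotation: the 5p/3p end energies are used as computed, and
guide/passenger labels enter only at scoring time.

The packaged default constants (`data/twin_drive_constants.yaml`:
k = −0.5 /(kcal/mol); N_U = 2.0, N_A = 1.5, N_G = 0.5, N_C = 0.0) are
package defaults, not fitted values: they encode the established ordering
U > A > G > C and the sign convention that the cheaper-to-unwind end
promotes its strand (hence k < 0 on the unwinding-energy scale).  Users
reproducing a specific published analysis should substitute that
publication's constants via `load_params`.  No refitting to any particular
species is attempted here.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `temperature` | 20 °C | folding temperature; 15/20/25/37 °C is the standard sweep |
| window width *n* | 1..4 | terminal nucleotides forced open per end |
| `terminal_margin` | 4 nt | zone width for terminal-vs-central difference calls |
| `dangle_mode` | engine default | recorded in provenance, never silently changed |
| `k`, `N` | see above | twin-drive constants, provenance-labelled config |

Widths are hard-limited to 4: wider windows on ~21-nt strands start eating
the foldable core (the builder requires n ≤ min(strand length) − 5).
Energies are reported to 2 decimal places in kcal/mol.

Temperature-sweep difference calls use exact dot-bracket equality — the
reproducible analogue of judging "altered structure" by eye — and the
terminal/central split classifies each differing position by whether it
lies within `terminal_margin` of a strand terminus (for hairpins, also
inside an apical loop run of either structure).  The margin is exposed
rather than tuned: published terminal/central splits were made by visual
inspection, and no margin value is claimed to reproduce them exactly.

## Numerical and engine notes

* Engine energies are float32; invariant checks use a 5×10⁻³ kcal/mol
  slack and reports round to 2 decimals.
* Determinism: identical inputs and configuration give bit-identical
  structures and energies; the only global state is the engine parameter
  table, which is re-loaded per call.
* Constraint feasibility is verified on the engine's output (forced-open
  positions must come out unpaired; enforced pairs must be present),
  because the engine "enforces" even non-canonical pins by returning a
  structure rather than failing.  Pinning a non-canonical pair is rejected
  up front.
* ViennaRNA's constraint parser omits (with a warning) enforced pairs that
  span the strand nick at less than 4 nt separation, although such pairs
  are legal in folds and occur in hairpin-derived duplexes (arm positions
  that paired across what used to be the loop).  A fully pinned constraint
  determines a unique structure either way, so when the engine refuses the
  pin the profile falls back to fixed-structure evaluation of that
  structure — the identical quantity, computed directly.
* Degenerate inputs: a duplex region with zero inter-arm pairs projects to
  an all-unpaired duplex (a warning-level situation, not an error); an
  unsatisfiable constraint raises with the miRNA name, end and width.

## Synthetic cohort: what it emulates and what it does not

The generator (`mirunwind.synthetic`) builds duplexes as complementary
cores with 2-nt 3' overhangs, 0–2 planted mismatches and 0–1 bulges placed
≥ 2 columns from the core termini, and hairpins as arm–loop–arm
concatenations; every fixture carries its ground-truth pair map and
feature positions.  Defaults are GC-rich (gc_fraction 0.6) so the planted
helix dominates the folding landscape and engine-dependent tests are
deterministic in practice.

The standard cohort (190 duplexes — the scale of the published *C. elegans*
annotated-duplex set — strand length 22 ± 1 nt, loop 6 nt) additionally
plants thermodynamic end asymmetry: one end gets terminal AU pairs, the
other terminal GC pairs, and the guide label agrees with the weak end in
78% of records, reflecting the field's observation that strand choice
follows duplex end asymmetry for roughly three quarters of miRNAs.  These
are study conditions chosen once, not tuning knobs.

Consequences for interpretation: passing cohort statistics demonstrate the
*machinery* — the sign and significance of the guide/passenger asymmetry,
the regime inequalities, the accuracy bookkeeping — under conditions where
the ground truth is known.  They do not reproduce the published cohort's
exact percentages, because idealised GC-rich duplexes are more stable and
structurally cleaner than real miRNA duplexes: temperature-driven
refolding fractions come out lower, and the planted asymmetry is sharper
than in nature (stratified accuracies are more extreme).  Checks against
the real miRBase cohort require its input files, which are not
redistributed with the package; the acceptance tests state the expected
layout and fail with instructions when the files are absent.

## Problem sizes

The default test suite folds a 12-record cohort plus assorted fixtures
(~10 s); the acceptance script folds the full 190-record cohort across
three regimes, four widths, both ends and two temperatures (~3,000 engine
calls, about half a minute on one CPU).  The exhaustive-enumeration oracle
that cross-checks the constrained MFE is run on 7+7-nt duplexes, where the
full canonical non-crossing structure space is enumerable.

## Known limitations

* No pseudoknots, no partition-function/ensemble quantities, no kinetic
  barrier modelling — ΔΔG is a purely thermodynamic difference.
* The nearest-neighbour module covers Watson–Crick and GU wobble stacks
  only (terminal mismatches, dangles and loop terms live inside the
  folding engine, not in the comparison method).
* isomiR-aware prediction and abundance association are out of scope.
* Arm location requires the mature arms to be exact, unique substrings of
  the precursor; ambiguous placements are an error by design, never a
  silent first match.
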