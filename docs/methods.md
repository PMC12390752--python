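# Methods

This note documents the models behind ddckit: what is simulated, which
parameters matter, the numerical choices, and what the synthetic data do
and do not establish about physical carriers.

## Carrier geometry

A carrier is modelled as a rectangular label lattice: message rows 0..4,
an address row at lattice row −1, five columns, 30 addressable sites in
total.  Each conformation has an (x, y) pitch; defaults are OFF = (6, 6) nm
and ON = (6, 12) nm.  Absolute pitches are configuration, not measurement —
every downstream algorithm (classification tolerances, assignment radii)
is expressed relative to the pitch, and only the constraint
`marker_distance(ON) > marker_distance(OFF)` is enforced at construction.
The two conformation markers default to a dedicated column (col −2) two
rows apart, so their spots never collide with data sites and their
separation doubles on unlocking.

The anti-junction cascade that physically propagates the conformational
change is abstracted to a single per-structure transformation event; the
package does not model junction-level mechanics or free energies.
Partially transformed structures are represented by a row pivot: rows up to
the pivot keep the OFF row pitch, later row gaps take the ON pitch — a
one-dimensional stand-in for a stalled transformation wave.

## Transformation and readout model

Each simulated structure draws:

1. **Category.**  The key class sets the net ON probability `p`:
   `p_admin = 0.76` (polymerase), `p_user = 0.89` (matched strand set),
   `p_spont = 0.14` (no key or mismatched key; mismatched keys show no
   partial cross-talk, consistent with mismatched access collapsing to the
   trigger-free baseline).  Internally an attempt fires with probability
   `p / (1 − p_ic)` and stalls intermediate with probability
   `p_ic = 0.05`, so the ON rate is exactly `p` and the intermediate rate
   is `p·p_ic/(1−p_ic)`.  This parameterisation makes the configured `p`
   identical to the measured ON-conformation yield that the analytic model
   `y_theo = p·qⁿ` consumes; the stall fraction is a free parameter (no
   measured rate exists for it).  It implies an OFF retention of
   `1 − p/(1−p_ic)` (0.853 for the trigger-free default) rather than
   `1 − p`; the two differ by the stalled attempts.
2. **Labelling.**  Every biotin site binds streptavidin independently with
   `q = 0.95`; plain sites emit a false spot with `fp_rate = 0` by default.
   Streptavidin multivalency (one tetravalent label bridging adjacent
   biotins) is not a separate channel: the storage-side codec inserts blank
   columns between character columns where capacity allows, and the wet
   protocol it models uses excess label, so any residual effect is folded
   into `1 − q`.
3. **Localisation.**  Spots are blurred with isotropic Gaussian noise,
   `loc_sigma_nm = 0.5` by default (≈ 8% of the 6 nm pitch).  The readout
   scheme presumes clearly resolved label spots; at this noise the
   probability of a spot straying beyond the assignment radius is ~10⁻⁴.

Randomness: one root seed spawns an independent child stream per
structure, so ensembles are bit-for-bit reproducible and any structure can
be re-simulated alone.

## Decoding

Classification fits the spot cloud against OFF, ON and pivot-indexed
intermediate templates.  Fitting is translation-only (the carriers keep
their rectangular outline through the transformation, so registration is
anchored and needs no rotation search); one median-offset refinement is
applied, clipped to the residual tolerance per axis.  The clip is
load-bearing: templates with equal internal row spacing can otherwise
slide onto one another by a full pitch and become indistinguishable on row
subsets.  The category is the best-fitting template, demoted to UC when
the best residual exceeds `tol = 0.35 × min(pitch)` or when the OFF and ON
fits are within 10% relative residual of each other.  Intermediate wins
only by strictly better fit, so degenerate ties resolve toward the pure
conformations.  Both thresholds are configurable; how image-based counting
separates intermediate from uncertain in practice is not standardised, and
this residual/margin rule is a documented stand-in.

Bit assignment maps each spot to its nearest template site within the same
tolerance (exact ties break toward the lower (row, col) index), sets aside
marker-site spots, and calls a site 1 iff at least one spot lands on it.
CorrInfo is scored strictly: ON conformation *and* every called bit equal
to the ground-truth pattern — the strongest reading of "fully correct
pattern", and the event whose probability `p·qⁿ` models.

## Codec choices

The default scheme uses a 5-bit alphabet (space = 0, A = 1..Z = 26), one
character per column, MSB at the top: 8-bit ASCII cannot fit a four-letter
word in a 5 × 5 array, and the 5-bit reading is the one consistent with
both the array capacity and the ciphertext letter inventory.  An 8-bit
printable-ASCII scheme (3 characters per carrier, words spanning carriers)
is provided as an alternative.  The address-keyed scramble shifts column
`c` cyclically by `(word_index + c) mod 5`; it is invertible, driven only
by the address row, and stored under a rule identifier so other
permutation families can be substituted.  Scrambled columns render as the
character with code 64 + value (0 as a blank), giving letters and
`[ \ ] ^ _` glyphs; codes with no character decode to `?`, so decoding
never fails on noisy data.  When a word is too long for interleaved blank
columns, spacing is dropped with a logged warning rather than rejecting
the word (a `strict` flag restores the hard error).

## Keys and the key space

User-key derivation reads two 16-nt gap regions and seven 15-nt overhang
domains (5-nt toehold + 10-nt primer segment) off the circular scaffold
starting at the design's breakpoint, and returns their reverse
complements.  Matching in sequence mode demands exact complementarity;
abstract-mode keys carry only a design identifier so the simulator and
statistics run without sequences.  Cross-hybridisation between two keys is
scored as the longest common substring between their strand sets — shared
sequence means shared binding target on the other key's carrier — and the
default policy declares keys orthogonal below `k = 8` (an 8-bp unintended
duplex being long enough to nucleate displacement).  Key-space
enumeration shifts the breakpoint in `min_shift` steps
(`floor(length/min_shift)` candidates unfiltered) and, under a policy,
keeps candidates greedily in breakpoint order; maximal-independent-set
selection is out of scope.  The shipped scaffold is a seeded synthetic
stand-in at M13mp18 length (7,249 nt): for key counting and orthogonality
screening only sequence diversity matters, and real FASTA scaffolds load
through the same interface.  DDC-2's breakpoint (3,624) is the first
register past half the scaffold whose key is orthogonal to DDC-1's.

## Statistics

Empirical yields are exact ratios `M/N` with Wilson 95% intervals
(preferred over Wald for the small counts typical of image tallies;
statsmodels implementation).  The biotin-site count `n` in `p·qⁿ` covers
message *and* address 1-bits; the two marker sites are excluded by default
(they are scored as conformation reporters, not data) but can be included.
Condition harnesses decode every simulated field by default, so their
category tallies are observation-side (UC possible) and their CorrInfo is
the decoder's; a tally-only fast path serves large Monte-Carlo estimates.

## Problem sizes and what the tests show

The test suite runs ensembles of 5,000–10,000 structures for statistical
checks (agreement with `p·qⁿ` within three binomial standard errors,
word-yield ordering, the two-user permission matrix) and exhaustive or
brute-force oracles for the discrete machinery (full alphabet, all 32
addresses, all flag combinations of a toy design, quadratic substring
scans, per-spot nearest-site scans).  Synthetic fields emulate localisation
noise, binding dropout and stalled conformations; they do not emulate AFM
artefacts (tip convolution, drift, touching structures), sequence-dependent
transformation kinetics, or partial cross-talk between similar keys.
Passing tests therefore establish internal consistency of codec, model and
decoder at the configured rates — not the physical rates themselves, which
enter only as parameters.

## Known limitations

- The scramble family is a documented stand-in; the printed ciphertext of
  the original demonstration is not reproduced exactly (its mixing rule is
  not public), only the qualitative behaviour (address-keyed, invertible,
  plaintext concealed).  At word index 0 column 0 is a fixed point.
- Intermediate-conformation geometry and rate are free parameters.
- Thermodynamic binding prediction, polymerase kinetics and 3-D mechanics
  are out of scope; orthogonality is a k-mer heuristic, not a ΔG model.
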