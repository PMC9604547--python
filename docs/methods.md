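# Methods

## The model

For a tri-ring Schiff base with two symmetric intramolecular O–H…N
bridges, each physical compound yields two analysis views: the ring
carrying the scanned bridge is *proximal*, the other *distal*. The
proton-transfer energetics of one view are decomposed additively,

EA = EBC + IE-SUB + IE-STER + IE-DIST,
SM = SBC + IS-SUB + IS-STER (+ IS-DIST),

with all quantities in kcal/mol. The decomposition rests on three
assumptions:

1. **Pair symmetry of the classical effect.** Resonance and induction
   through the ring give the same shift for substitution at positions 1
   and 3, and likewise at 2 and 4 (the positions are ring-local labels:
   1 adjacent to the C–N imine linkage, 4 adjacent to the C–O phenol).
   IE-SUB therefore has one value per (substituent, position-pair).
2. **Proximity residual at 1 and 4 only.** Whatever breaks the pair
   symmetry at the bridge-adjacent positions (steric push on the O–H
   group at 4, ring rotation through the N–C contact at 1, secondary
   H-bonding of –NH2) is absorbed into IE-STER, defined only for
   positions 1 and 4.
3. **Weak, separable distal effect.** The distal ring contributes a
   small additive term (|IE-DIST| ≲ 0.5 kcal/mol) independent of the
   proximal pattern.

These assumptions make the fit a sequence of differences rather than a
regression: with Δg(p) the shift of the proximal-mono-substituted
compound (distal ring bare) relative to group g's parent,

* IE-SUB(S, {1,3}) = mean over groups of Δg(3),
* IE-SUB(S, {2,4}) = mean over groups of Δg(2),
* IE-STER(S, 1) = mean of Δg(1) − Δg(3),
* IE-STER(S, 4) = mean of Δg(4) − Δg(2),

identically for the second minimum, and IE-DIST(d) as the mean paired
difference EA(prox, distal d) − EA(prox, distal none). Positions 3 and 2
anchor the classical effect because they carry no steric term; a
substituent missing either anchor record cannot be decomposed and is
reported as unfit rather than guessed.

Groups: the default fit averages **para and meta with equal weight**.
The ortho parent places the two bridges close enough to couple, which
contaminates increments meant to be transferable; it is included only on
explicit request, with a warning. Whether the published table came from
this plain averaging or a global least squares is not decidable from the
fitting rules as stated; averaging is the direct reading and is the
default, and a per-substituent constrained least-squares variant
(`method="lstsq"`, identical on complete noiseless grids) is provided
for comparison.

## Scan profiles and extraction

Profiles are two-column (O–H distance in Å, energy) tables; hartree
input is converted at 1 hartree = 627.509 kcal/mol and every profile is
re-zeroed on its first point, which is taken to be the optimized
molecular form the scan started from. Extraction is purely discrete at
the native 0.05 Å resolution: the barrier is the first interior local
maximum after the start, the PT minimum the first local minimum after
it; EA − SM is always derived, never stored. Numerical details:

* **Plateaus** (exactly equal consecutive energies) count once, at their
  leftmost point. A flat shelf that rises on both ends (EA = SM) is
  reported as a degenerate barrier with difference 0 rather than as "no
  PT minimum".
* **Later structure** (second maxima etc.) is ignored; the physical
  profiles have a single barrier.
* **Reference convention.** Energies stay referenced to the starting
  structure even when the PT form falls below it; SM < 0 is legal,
  flagged `below_reference`, and accompanied by a warning.
  Re-referencing to the global minimum is available as an explicit
  option (`rereference=True`) but never automatic.
* **Refinement.** Optional parabolic refinement (`refine="parabolic"`)
  interpolates the extremum through its two neighbors for off-grid
  apexes; the default stays on-grid to match the data's resolution.

## Synthetic data

The generator replaces the DFT campaign the analysis was designed for.
`generate_dataset` evaluates the additive model literally over a
substitution grid — per group, 12 proximal mono-substitution patterns
(plus the bare parent) × 13 distal patterns — and adds optional i.i.d.
Gaussian noise and explicit pairwise (proximal, distal) interaction
terms that model the known non-additive cases (e.g. the spring-like O/N
repulsion when both bridge-adjacent positions carry –NO2).
`generate_profile` realizes an (EA, SM) pair as a 21-point curve:
a piecewise cubic through (start, 0) → (index 7, EA) → (index 14, SM) →
(index 20, SM + 2.0) with zero slope at the three stationary points, so
each segment is monotone and the extrema sit exactly on grid nodes;
noise never touches the control points, which keeps noiseless round
trips exact and noisy ones gracefully degraded.

Defaults defining the emulated study conditions: scan start 0.95 Å
(a conventional O–H equilibrium placeholder; the true optimized value is
structure-specific), step 0.05 Å, 20 increments; ground-truth increments
from the packaged table; parent parameters EBC = 12.0, SBC = 10.0
kcal/mol for every group — explicitly arbitrary, chosen so EA ≥ SM ≥ 0
holds across the whole grid under the packaged increments; distal
increments, when drawn, bounded by ±0.5 kcal/mol; noise scales 0.05–0.1
kcal/mol (a small fraction of the ~1 kcal/mol proximal spread). An
optional ortho mode inflates distal increments by 1.6× to mimic the
stronger bridge–bridge coupling of that parent; it is off by default.

What the generator does *not* emulate: solvent shifts (a single phase is
generated), anharmonic or asymmetric well shapes beyond the cubic
construction, correlated noise along a scan, conformational flexibility,
and any electronic-structure quantity (charges and distances are only
ever consumed as auxiliary inputs). Passing tests therefore demonstrate
that the analysis machinery is exact and unbiased on additive
double-well data — not that real chemistry is additive; on real data the
approximation report is the instrument that quantifies the deviation.

## Statistics

Spread statistics use the sample (n−1) standard deviation. For a
proximal × distal matrix of one parameter, the proximal spread is the SD
down each column summarized as mean ± SD over columns, the distal spread
the same along rows; slices with fewer than two present values are
excluded with a warning. The "±" is thus the spread of per-slice SDs —
an interpretation choice, recorded here because the estimator and the
meaning of the interval are not fixed by the statistic's name. The
spreads are computed per parameter (EA, SM, difference), never pooled.
Distal-charge correlations are ordinary Pearson r with a least-squares
line, refused below 3 points or at zero variance.

## Problem sizes

The test suite and the acceptance script run entirely on generated
data: grids of 338 records (2 groups × 13 × 13), 21-point profiles, 50
replicates for the spread property, 200 replicates for the noise-bias
check (fitted on the 2 × 13 proximal-mono sub-grid, the only records the
fit consumes), and 100 random double wells for extraction. These sizes
give sampling error comfortably below the asserted bounds (e.g. the
bias check's per-increment standard error is ≤ 0.007 kcal/mol against a
0.02 bound) while keeping the whole suite in seconds.

## Known limitations

* Base parameters are inputs: the package never claims parent EA/SM
  values, and predictions are only as good as the supplied EBC/SBC.
* The model is additive by design; known pairwise exceptions are
  representable in the generator but deliberately not in the predictor.
* Ortho-group bridge coupling has no increment; fits including ortho are
  supported but warned against.
* Extraction assumes the first scan point is the optimized minimum;
  profiles that start off-minimum should be re-referenced explicitly.
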