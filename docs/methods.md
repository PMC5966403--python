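# Methods notes

These notes document the statistical and geometric procedures the
package implements, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
conventions that matter when reproducing results.

## Fluorescence-displacement analytics

**Activity.** A displacement assay reads a dye whose emission rises on
binding the target RNA. With the four control roles A (dye+RNA+
compound), B (dye+compound), C (dye+RNA) and D (dye alone), activity is
100 − 100·(A−B)/(C−D): the compound-background-corrected signal
relative to the RNA-dependent window. Activities are computed per
replicate and then averaged, which is what enables per-compound SEMs
and Welch tests; they are never clamped, so fluorescence enhancers
appear as negative activities and remain visible in the ranked table.

**Assay window guard.** When the RNA adds no dye signal the ratio is
unstable; (C−D) ≤ 0.05·D raises `AssayWindowError` rather than
returning a number. The 5% floor is a guard constant, not a measured
quantity.

**Control pairing.** When a compound's replicate count equals the C/D
control replicate count the ratio is formed replicate-by-replicate.
The default simulated plate instead carries 16 C and 16 D wells (two
dedicated control columns, the common 96-well design) and uses the
plate-mean window for every compound. This matters numerically: with
per-replicate quadruplicate controls, E[1/(C−D)] > 1/E[C−D] biases
mean activity by about −0.4% at 5% noise; averaging 16 control wells
reduces the bias ~16-fold, and binder-free plates then show mean
activity statistically indistinguishable from zero.

**Z′-factor.** The control-based screening-window coefficient
Z′ = 1 − 3(s₊+s₋)/|μ₊−μ₋| with sample SDs. Equal control means raise
an error (the statistic is undefined, not NaN). Z′ ≤ 1 always and is
strictly decreasing in the summed spreads.

**Hit calling.** The procedure is sequential, mirroring screening
practice: the 20% activity cutoff is applied first, and only
cutoff-passing compounds enter two-tailed Welch tests against the
pooled DMSO-control activities, with Bonferroni correction over that
family (`m` = number of cutoff passers by default; any family size can
be passed explicitly). The choice matters: with quadruplicates at 5%
multiplicative noise the Welch statistic has only ≈4–5 Satterthwaite
degrees of freedom, and correcting over the full 304-compound library
leaves ≈80% power at a 40% displacement effect, whereas correcting
over the cutoff-passing family yields ≈91% recovery of binders whose
planted effect exceeds the cutoff at unit precision, and a family-wise
false-positive rate of zero over 1000 binder-free plates. Sensitivity
is defined over binders whose planted displacement exceeds the cutoff,
because a binder below the positivity definition is not recoverable by
the rule regardless of statistics; with effects drawn from N(40,10)%
about 2% of planted binders fall in that category.

**Welch test conventions.** Satterthwaite degrees of freedom; both
groups constant and equal gives p = 1 by convention, constant and
unequal gives p = 0; n < 2 in either group is an error. The
implementation is the textbook formula and is cross-checked against
scipy in the test suite.

**4PL dose–response.** y = bottom + (top−bottom)/(1+(EC50/x)^h),
fitted on log10 concentration by trust-region least squares with
h > 0 enforced, initialised at top = max(y), bottom = min(y), EC50 =
geometric mid-dose, h = 1. The fit must converge on noiseless data to
1e−6 relative (asserted in tests). An EC50 estimate outside the tested
concentration range scaled by [0.1, 10] is not reported — the data do
not constrain it — and a flat response is reported as non-converged.
Standard errors come from the Gauss–Newton covariance
s²·(JᵀJ)⁻¹ when the residual degrees of freedom are positive.

## Splicing quantification

Percent inclusion is 100·inc/(inc+skip) on optionally
background-subtracted band intensities (constant background, floored
at zero); no amplification-bias correction between isoforms is
applied, matching raw densitometry practice. %MIP normalises a
treatment effect by the available headroom,
100·(E7_t − E7_c)/(100 − E7_c); it is undefined at a 100% baseline and
negative when treatment reduces inclusion. Fold changes are 2^−ΔΔCt
and therefore invariant to any global Ct shift.

Probe panels (2AP fluorescence, native-PAGE hairpin fraction, CD band
magnitude) are summarised per variant as Δ% against a designated
reference variant and correlated with exon inclusion by Pearson's r
(the relations of interest are linear on these panels) with a
two-tailed t-based p. A constant signal or constant inclusion raises
an error. CD extrema are located by grid argmax/argmin within the
positive (240–300 nm) and negative (200–235 nm) windows and refined by
three-point parabolic interpolation, so peak shifts are reported at
sub-nm resolution; shifts are antisymmetric under swapping variant and
reference.

## Junction-count differential splicing

A cassette event contributes two inclusion junctions but one skipping
junction, so the summed inclusion count is halved:
PSI = (I/2)/((I/2)+S). This estimator is consistent — under binomial
sampling at depth 200 its mean bias is below 0.01 (measured ≈0.001) —
with a small positive Jensen curvature that vanishes as depth grows.
Samples with zero junction coverage are excluded and logged; events
with no covered sample in a group are dropped with a warning.

ΔPSI = mean PSI(treated) − mean PSI(control) is thresholded on its
absolute value (treatments both promote and reduce inclusion):
|ΔPSI| > 0.4 flags "modified", > 0.65 "strongly affected"; t2 ≥ t1 is
enforced so the strong set is a subset. Gene-level roll-ups count
distinct gene identifiers.

The response classifier contrasts treated-vs-control Welch tests in
the disease (SMA) and wild-type backgrounds at α = 0.05 per test,
without multiplicity correction across the (small) validation panel —
mirroring per-gene qRT-PCR reads; α is configurable. Significant in
SMA only → SMN-recovery-mediated; in both with the same direction →
off-target; in WT only → wt_only; otherwise non-responsive. Under the
null the mislabel rate is bounded by 2α (union of two tests; measured
0.082 at α = 0.05).

Donor windows are 9-mers spanning the splice site (last 3 exonic +
first 6 intronic bases, plus strand, exon first); any equal window
length ≥ the motif length is accepted. A window contains the motif if
some offset matches with at most `max_mismatch` mismatches, with IUPAC
degeneracy allowed in the motif. Enrichment of containing windows
among affected donors is the one-sided hypergeometric upper tail over
the pooled population, which equals brute-force enumeration (verified
exhaustively for pools up to 25 in tests).

## Ensemble geometry

Superposition is the Kabsch SVD solution restricted to proper
rotations by the determinant sign correction, so mirror images are
never matched; near-collinear atom sets (second singular value below
1e−8 of the first) are superposed but flagged degenerate. The RMSD is
symmetric in its arguments to 1e−10 and is cross-checked against an
independent quaternion (Horn) eigenvalue solver to 1e−8 in the tests.

Average pairwise bundle RMSD superposes every unordered model pair
independently on the same atom selection used for the deviation
(all-heavy, stem residues 1–7/13–19, or loop residues 8–12) and
reports mean ± SD over the N(N−1)/2 pairs. Pair-wise and
mean-structure superposition conventions differ by a few hundredths of
an Å on NMR-scale bundles; the pairwise convention is used throughout.

RMSF superposes all frames onto an iteratively refined mean structure
(three passes; the reference converges quickly) and reports the root
mean squared displacement per atom, aggregated per residue as an
unweighted mean over that residue's selected atoms. Fitting the six
rigid degrees of freedom to noise deflates RMSF by roughly
√(1 − 6/(3·n_atoms)) — about 1.3% for the 76-atom hairpin — which is
why pure σ-jitter trajectories recover σ√3 to within 2% rather than
exactly.

Distance observables (terminal opening d(C1′ 1, C1′ 19); loop closure
d(8, 12) in C1′ or centre-of-mass mode) are internal coordinates and
need no superposition. A residue's centre of mass is the mass-weighted
centre of its heavy atoms (full residue by default). Loop-state
classification is a strict threshold on the loop-closure distance:
triloop iff d < threshold, a frame exactly at the threshold counting
as pentaloop. The preferred threshold is the midpoint of the two
reference-state distances when a generator truth is available
(`loop_state_threshold`); otherwise a calibration constant of 7.0 Å
(centre-of-mass mode) is used. Fractions carry Wilson 95% binomial
CIs and are invariant to frame order.

Free-vs-bound terminal-opening shifts are reported with a 95% CI from
a moving-block bootstrap (default block length 50 frames), which
remains valid under short-range frame autocorrelation even though the
bundled generator draws frames independently.

PDB I/O is via gemmi: MODEL/ENDMDL blocks become frames, atom names
are normalised across prime dialects (C1* → C1′), the first alternate
location is kept, hydrogens stay in the roster and are excluded by the
heavy selections, and models whose rosters disagree raise an error
naming the model and atom. Coordinates survive a write/read round trip
to the format's 1e−3 Å precision.

## Synthetic-data generators

All generators draw from one `numpy.random.default_rng(seed)` per
call; identical configuration and seed reproduce identical bytes.
Defaults are the study conditions: 304-compound plates in
quadruplicate with an 18% binder fraction, binder displacement
N(40, 10)% clipped to [0, 100], 2% of compounds autofluorescent
(adding 0.5–1.5× the full signal to their A and B wells, which cancels
in the activity ratio but trips the B-vs-D flag), dye background 200
a.u. and dye+RNA signal 1000 a.u., multiplicative lognormal noise at
CV 5% (plate readers scale with signal); dose series of 8 half-log
doses × 4 replicates around a true EC50 of 16 µM; junction tables of
200 events × 4 samples per group at depth 200 with beta-binomial
intraclass correlation ρ = 0.01 and |ΔPSI| = 0.5 planted in 15% of
events, signed to keep PSI inside [0, 1]. With true PSI p the
inclusion-junction proportion of junction reads is 2p/(1+p), so the
halved-count estimator is centred on p.

The hairpin generator builds an idealised 19-residue stem-loop —
helical rise 2.8 Å, twist 33°/residue, C1′–C1′ pair span 10.4 Å, four
labelled heavy atoms per residue (P, C4′, C1′, base nitrogen) — in two
reference conformations: "pentaloop" (loop residues 8–12 splayed,
loop-closure ≈13 Å, terminus closed at ≈10.4 Å) and "triloop"
(residues 8 and 12 drawn together to ≈5 Å with 9–11 bulged, terminus
opened by 4 Å). Frame states are i.i.d. Bernoulli(p_triloop) with
isotropic Gaussian jitter per axis (default 0.3 Å), so terminal
opening and loop closure are anticorrelated across frames by
construction, and a configurable extra terminal opening emulates a
ligand-bound ensemble. Only the residue-index semantics (terminal
pair 1/19, wobble partners 2/18, loop 8–12 with triloop 9–11) carry
meaning; the helical parameters are a stand-in convention. Pinned
residue identities cover positions 1, 2, 8–12, 15, 18, 19; the rest
default to adenosine and are configurable.

What the generators deliberately do not emulate: plate spatial
artifacts (edge effects), inner-filter corrections, PCR amplification
bias, sequencing-read simulation (junction counts only), Markov dwell
times in the trajectory (the analyses consumed are frame-marginal),
and any physical force field or folding thermodynamics. Passing tests
therefore demonstrate correctness of the estimators and decision rules
under calibrated noise, not robustness to those real-data artifacts.
The probe generator models 2AP intensity only and takes no position on
the chemistry of the labelled position.

## Problem sizes and determinism

The bundled measurements use sizes chosen to make Monte-Carlo
uncertainty small relative to the quantities asserted: 1000
binder-free plates for the family-wise error rate, 400 plates
(~21,000 detectable binders) for sensitivity/precision, 200 dose
refits, 10 junction datasets each for bias and filter operating
characteristics, 10,000 frames for the RMSF expectation and 5000 for
state-fraction recovery. The pipeline fans a single global seed out to
stages by stable SHA-256 hashing of the stage name (31-bit sub-seeds),
so enabling or disabling one stage never changes another's stream, and
rerunning a configuration reproduces every table byte for byte.

## Known limitations

Bonferroni-corrected quadruplicate Welch tests are conservative at
≈4–5 degrees of freedom; compounds with true displacement between the
cutoff and ≈30% are recovered with reduced power. The PSI estimator
assumes the two inclusion junctions are sampled at equal efficiency.
The response classifier treats the two backgrounds as independent
panels and applies no cross-gene multiplicity control. The loop-state
classifier is a single-distance threshold and will blur states whose
distance distributions overlap within the jitter scale. Bundle-RMSD
values depend mildly on the superposition convention; comparisons
against externally reported bundle statistics should allow for that.
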