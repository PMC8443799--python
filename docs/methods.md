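# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coiled-coil geometry

A local helix frame is computed per interior residue from three consecutive
CA atoms: the unit bisector of the angle at CA(i) points at the local helix
axis, and the radius is the least-squares value that makes consecutive axis
points advance parallel to the axis (for an ideal helix this is exact). The
rise is the distance between consecutive axis points and the twist is the
rotation of the CA radial vector about the axis step. Chains are split into
segments at CA–CA gaps above 4.5 Å; collinear stretches yield frames
flagged undefined rather than exceptions; terminal residues carry no frame.

Pairing the two chains' axis points (by equal residue number unless a
register map is given) defines the coiled-coil axis as the midpoint path.
Per position the package reports:

- **coiled-coil radius** (Å): distance from a helix-axis point to the
  midpoint axis. For a dimer this is half the axis–axis separation; it is
  what crystallographic coiled-coil work reports as the "inter-helical
  distance" (canonical dimer values near 4.8–5.0 Å). The axis-to-axis
  distance, twice this, is deliberately not the reported quantity.
- **superhelical phase step** Δφ (deg/residue) and **pitch**
  P = rise·360°/|Δφ| (Å). Where |Δφ| < 0.8°/residue the position is flagged
  not supercoiled and the pitch is the +∞ sentinel; 0.8°/residue
  corresponds to P ≈ 650 Å at a 1.45 Å rise, beyond which "supercoiling" is
  not meaningfully defined on a local window.
- **Crick phase** (deg): azimuth of the CA about the local helix axis,
  measured from the direction pointing away from the coiled-coil axis, so
  the buried orientation is 180°.

Two twist notions coexist and are kept explicit. The lab-frame twist in the
local helix frames equals the true α-helical periodicity (ω1 + ω0 ≈ 98.9°
per residue for a canonical left-handed dimer). The heptad-frame twist of
720/7 ≈ 102.86°/residue — 3.5 residues per turn — is the per-residue Crick
phase step of the profile, because the phase reference co-rotates with the
supercoil. Heptad letters are a pure function of the Crick phase: letters
advance alphabetically with the ideal step of 720/7° and 'a'/'d' are
anchored on the two ideal positions straddling 180° (a at 180° + 720/28°,
d at 180° − 720/28°), which makes a and d the most buried positions.

A heptad starting at position i is **regular** when positions i..i+7 are
consecutive, supercoiled, and the Crick phase drift over the heptad (ideal
advance ≡ 0 mod 360°) is below 15°. The longest run of consecutive regular
starts defines the heptad span; whole heptads inside it are counted.
Summaries over explicit residue windows report arithmetic means and sample
standard deviations of per-residue radius and pitch; near-threshold
positions can make window pitch means heavy-tailed on noisy structures, so
windows should be chosen inside clearly supercoiled spans.

## RDC back-calculation and tensor fitting

A coupling for unit bond vector v is D = vᵀSv with S the symmetric
traceless alignment (Saupe) tensor in Hz — the dipolar prefactor is carried
inside S because fits are Hz against Hz; no gyromagnetic bookkeeping is
attempted. Equivalently D = D_a[(3cos²θ−1) + (3/2)R sin²θ cos 2φ] in the
principal frame, with components ordered |A_zz| ≥ |A_yy| ≥ |A_xx|,
D_a = A_zz/2 and R = 2(A_xx−A_yy)/(3A_zz) ∈ [0, 2/3]. Both code paths are
implemented and tested to agree to 1e-9.

The primary solver is weighted linear least squares over the five
independent Saupe elements — the exact global χ² minimum, deterministic,
with a conditioning check (singular-value ratio < 1e-10 raises, naming
near-collinear vector sets). χ² is σ-weighted by default with a unit-weight
flag, since the original weighting convention is not recoverable. Principal
components and z-y-z Euler angles (degrees, [0,360)×[0,180)×[0,360), the
convention stated in every report because none is standard) come from the
eigen-decomposition. A 5-parameter nonlinear solver (D_a, R, φ, θ, ψ;
Levenberg–Marquardt started from the linear solution) is provided purely as
an independent cross-check; the two agree on χ² to 1e-6 relative on
well-conditioned problems. Q = rms(D_obs−D_calc)/rms(D_obs); all-zero data
fitted by the null tensor define Q = 0 by convention, zero data with
nonzero residuals raise.

Amide N–H vectors use the measured proton when present; otherwise H is
placed in the C(prev)–N–CA plane on the external bisector at 1.02 Å from N
(standard amide geometry; X-ray entries lack hydrogens). Prolines and
chain-initial residues without a preceding carbonyl yield no vector;
skipped residues are logged, never silently dropped.

## Register (offset) scanning

Target residue i is mapped to template position i+k for each offset k in
the scan range (default ±10). Residues with hetNOE < 0.6 are excluded
before fitting; offsets with fewer than five usable pairs are reported as
unusable rows, not dropped. Offsets are ranked by Q. Ties within ΔQ < 0.01
are surfaced as co-optimal, the reported best offset being the smallest
|k|, with an ambiguity flag — register assignment in practice also leans on
sequence alignment, so ambiguity must be visible rather than hidden. The
`offset_consistency` helper checks a scan result against an explicit
alignment and reports which target residues land on template a/d positions
and what fraction of them are hydrophobic (AVLIMFWY).

A structural fact worth knowing: on a *perfectly periodic* coiled coil,
offsets differing by one heptad (7 residues) are exactly degenerate — the
7-residue shift is a rigid rotation of the whole vector set about the
coiled-coil axis, which the tensor refit absorbs. Discrimination between
k and k±7 therefore comes entirely from the template's irregularity (and
from window ends). The synthetic recovery fixture consequently applies
0.3 Å per-atom Gaussian noise to the template — the coordinate-precision
scale of a ~1.9 Å crystal structure — which is the realistic feature that
makes the problem well-posed; at 10% coupling noise on 40-residue windows
the planted offsets {−6, −3, 0, +4} are then recovered essentially always.

## Heteronuclear NOE

hetNOE = I_sat/I_unsat per residue. Errors are the standard deviation of
the ratio over 500 Monte Carlo trials (configurable) in which both heights
are independently perturbed by Gaussian noise of sd equal to the spectral
baseline noise; a flag restricts perturbation to the saturated spectrum
(the original choice is unstated; both-perturbed is the default because
baseline noise affects both spectra). The MC error matches first-order
propagation |r|·σ·sqrt(1/I_sat² + 1/I_unsat²) and scales linearly with the
baseline noise. Flexibility uses a strict ratio < 0.6; a ratio of exactly
0.6 is rigid. Zero unsaturated heights flag the residue undefined and
exclude it from classification. Contiguous flexible runs are reported as
(first, last) residue segments.

## Superposition

Kabsch SVD with the proper-rotation correction (reflections are never
returned; mirrored inputs superpose with nonzero RMSD). Sequence pairing
uses a global BLOSUM62 alignment with affine gaps (open −10, extend −0.5)
over CA-bearing residues; explicit residue-number pairings are accepted for
domain-restricted comparisons. Outlier rejection iterates fit → reject →
refit for up to 5 cycles, rejecting pairs whose deviation exceeds
mean + 2.0·sd of the current deviations. The mean term matters: deviations
are norms, whose mean exceeds twice their sd for pure Gaussian noise, so a
bare k·sd threshold would reject most pairs every cycle and collapse. The
defaults emulate commonly used align tools but exact third-party pair
subsets are not guaranteed, so both parameters are exposed and final pair
counts are always reported.

## Hybrid model assembly

Threading copies template backbone coordinates (through CB) onto the
target numbering at the validated offset. Disordered segments are grown
residue-by-residue (NeRF, ideal bond geometry, trans peptide) with φ drawn
uniformly from [−180°, −50°] and ψ from [80°, 180°], with 20% weight on
ideal polyproline-II (−75°, 145°) — an extended coil library representing
"random extended" conformations. Conformers with any non-bonded heavy-atom
pair below 2.5 Å (residues more than 2 apart) are rejected and resampled;
with an end anchor set, conformers whose final CA misses the anchor
tolerance are rejected first (the cheap test), and exhausting the retry
budget raises with the acceptance rate. This library is deliberately stiff:
over 10–40 residues the mean end-to-end distance grows as ~n^0.78
(persistence-length regime), not the asymptotic self-avoiding-walk n^0.588;
the tests assert the contour-length bound and an exponent in (0.5, 1).

Merging walks a contiguous, non-overlapping segment plan; every seam must
be peptide-continuous (C–N = 1.33 ± 0.2 Å) or the merge fails naming the
seam; per-residue provenance (segment kind) is recorded. Rigid parts are
docked by superposing their first-residue N/CA/C onto the ideal peptide
continuation of the previous segment.

Crosslink compatibility is CA–CA distance ≤ 30 Å for BS³ (the crosslinker
spans 26–30 Å between surface lysines) and ≤ 16 Å for zero-length EDC
pairs — a documented assumption (lysine plus acid side-chain reach and
backbone tolerance), since no span is defined for a zero-length chemistry.
Side chains are not modeled beyond CB, so all distances are CA-based.

The two-conformer workflow (coiled coil 115–232, disordered 233–473,
folded domain 474–645) illustrates domain-proximal and domain-distal
arrangements. Because the extended library essentially never returns a
241-residue linker to within crosslinking range of a ~175 Å coiled coil in
a ten-member ensemble, the proximal conformer is generated with the
sampler's end-anchor facility — four candidates anchored within 30 Å of
the coil's N-terminal CA, ranked by the distance of the domain centroid to
that anchor point — while the distal conformer is the most domain-remote of
ten unanchored draws. This is the package's own selection procedure for
"proximal"; the anchored rejection sampling typically accepts ~1 in 10³
draws.

## Binding quantification

Co-sedimentation: pellet intensities are background-subtracted by the
single required 0 µM lane, negative values clamped to zero with a logged
count, fraction bound = P′/(S+P′), and f = f_max[L]/(K_D+[L]) is fitted by
least squares with covariance-derived standard errors. The default ignores
protein depletion (protein ~4 µM against K_D near 1 µM makes this an
approximation); a depletion-aware quadratic variant sits behind a flag and
the fit report always names the model used.

Anisotropy: r = r_free + (r_bound − r_free)·b with b the exact 1:1
bound-probe fraction from the quadratic equilibrium, computed in the
cancellation-free conjugate form 2·P·L/(s+√(s²−4PL)) so the probe→0 limit
is numerically smooth — probe depletion matters exactly when K_D is
comparable to the probe concentration (the 11 nM / 1 nM regime). A
hyperbolic variant covers the depletion-free limit; the two agree within
0.1% when K_D ≫ probe. Non-monotone titrations and unreached saturation
produce warnings, not errors. Serial-dilution designs (default 2:3 v/v) are
generated by a helper.

Isoelectric points: Henderson–Hasselbalch net charge zeroed by bisection on
pH 0–14 to 0.01 pH. Two pKa tables ship (EMBOSS-style and
Lehninger-style); every report names the table because the result depends
on it. Sequences without ionizable groups raise.

## Synthetic generators

All generators are pure functions of (parameters, seed). The coiled-coil
generator realizes the Crick parameterization: CA atoms on a minor helix
(r1 = 2.26 Å, ω1 = 720/7°/residue, rise 1.51 Å along the coiled-coil axis)
wound on a superhelix (r0 = 4.9 Å, signed pitch −135 Å, i.e. left-handed —
the theoretical pitch arising from the 3.64 vs 3.5 residues/turn mismatch
at this rise); chains sit 180° apart in superhelical phase; the
pitch/ω0/rise consistency relation is enforced. Backbone N, C, O and amide
H atoms are placed from local CA-frame offsets calibrated once against an
ideal straight α-helix grown from (−57°, −47°) dihedrals — adequate for
bond-vector and geometry work, not for chemistry-grade backbone detail.
Distortions are applied after ideal construction: supercoil loss (the
superhelical phase freezes beyond a residue), frayed ranges (residues
removed), a linker range regrown as random coil with the downstream segment
re-docked, and per-atom Gaussian noise.

The compact-domain generator is a synthetic stand-in for a folded domain
where real coordinates are not supplied: a CA trace wound as a spherical
helix (windings ~5.6 Å apart, arc-length sub-stepped so CA–CA ≈ 3.8 Å,
seeded orientation and jitter), reproducing a globular domain's footprint
(radius of gyration ~24 Å at 172 residues) but no fold. RDC, relaxation
and binding simulators evaluate the corresponding forward models and add
seeded Gaussian noise; planted values are recorded so recovery is testable.

What passing tests on these fixtures do **not** show: performance on real
spectra (peak overlap, assignment errors), real disorder (the coil library
is one of many defensible ensembles), real crystallographic error
structure (noise here is isotropic and independent), or biological
correctness of any particular hybrid conformer — the two-conformer output
illustrates reach, it does not rank conformations thermodynamically.

## Problem sizes and runtime choices

The shipped checks use 76–80-residue dimers, 40-residue scan windows with
50–100 replicates per planted offset, 500 Monte Carlo trials for hetNOE
errors, 100 and 25 seeded replicates for the two noisy K_D recoveries, and
a 4-candidate anchored / 10-candidate unanchored conformer pool for the
crosslink comparison — sizes chosen so the full suite and the acceptance
script each complete in well under a minute per stage while keeping every
statistical criterion comfortably powered.

## Known limitations

- Two-stranded parallel coiled coils only; no antiparallel or higher-order
  oligomers, and no sequence-based coiled-coil prediction.
- The register scan fits each helix independently; no joint two-helix fit.
- No dynamic averaging (S²) corrections for RDCs in flexible regions —
  such residues are excluded by the hetNOE gate instead.
- No structure-based (DALI-like) alignment; domain-restricted comparisons
  need a user-supplied pairing when sequences are not alignable.
- Linker ensembles carry no statistical weights and no energies; clash
  rejection is the only physics.
- Crosslink distances are CA–CA with fixed cutoffs; no side-chain
  modeling, no solvent-accessible-surface path lengths.
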