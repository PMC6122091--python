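# Methods

This note documents the models, conventions and numerical choices
behind `ecdkit`, in the order a spectrum flows through the package.

## Stick-to-spectrum convolution

The molar circular dichroism of a set of electronic transitions is
modelled as a sum of energy-normalized Gaussians,

    Δε(E) = 4a Σₙ Rₙ wₙ(E) σₙ(E),
    σₙ(E) = (1/(√(2π) σ)) exp(−(E − Eₙ)² / 2σ²),

with Eₙ the excitation energy (eV), Rₙ the length-gauge rotatory
strength (10⁻⁴⁰ cgs), and σ the exponential half-width (eV).  All
arithmetic is carried out in energy space; the output axis is
converted to wavelength with hc = 1239.841984 eV·nm.

**Prefactor.** `a` is never hard-coded.  It is derived in
`ecdkit.constants` from CODATA-2018 values as

    a = 8π³ N_A / (3·10³ · ln 10 · h c)    (cgs: h in erg s, c in cm/s),

which makes 1/(4a) = 2.2965×10⁻³⁹ — the conversion constant familiar
from standard chiroptical post-processing, Δε(E) = E·R·g(E)/2.296×10⁻³⁹
for R in full cgs units.  The closed form actually evaluated is stored
in `PhysicalConstants.derivation`, so the unit chain is auditable at a
single site.  A unit test asserts the 2% agreement with the literature
constant; by construction the agreement is exact to the printed
precision of that constant.

**Energy weighting.** The weight wₙ multiplying Rₙ is the per-state
excitation energy Eₙ by default, the convention consistent with the
Δε ∝ E·R relation applied stick-by-stick.  Some post-processing codes
instead weight by the incident photon energy E; both conventions agree
at the stick position and differ only within a linewidth, and the
`incident_energy` option selects the alternative explicitly rather
than leaving the choice implicit.

**Defaults.** Output grid 170–400 nm at 0.5 nm (configurable); σ is
mandatory because it is system-dependent (0.3 eV for the Ag⁺-mediated
guanine tetramer, 0.2 eV for B-DNA-like systems).  States with tiny
|R| are kept — pruning is a caller decision, never silent.  Empty
stick spectra convolve to the zero spectrum.

## Ensemble averaging and the confidence band

Member spectra are linearly interpolated onto a common grid — the
intersection of the member spans sampled at the finest member step —
so no extrapolation ever occurs (requesting points outside a member's
span raises a range error).  The ensemble estimate is the pointwise
mean.

The 95% band is a pointwise Student-t interval on the mean,
mean ± t₀.₉₇₅,ₙ₋₁·s/√n, appropriate for the small ensembles (n ≈ 10)
this workflow uses.  A seeded bootstrap-percentile band (2000
resamples) is available as a robustness check; the two can be reported
side by side.  A single-member ensemble degenerates to a zero-width
band with an explicit warning.  The Monte-Carlo calibration
experiment (`ci_coverage_experiment`) measures coverage as the
per-grid-point fraction of replicates whose band covers the true
curve, averaged over points, using iid Gaussian noise around a
broadened two-band reference; with 2000 replicates of 10 members it
sits at 95.0 ± 0.5%.  Snapshot-to-snapshot correlation of real MD
frames is out of scope: the workflow samples sparse, effectively
independent snapshots.

## Peak diagnostics

Peaks are prominence-filtered local extrema (scipy's topographic
prominence), default minimum prominence 1 M⁻¹cm⁻¹ — well below the
bands of interest (tens of M⁻¹cm⁻¹) but above grid-level noise.  A
positive peak must lie above zero and a negative peak below; an
extremum on the wrong side of zero (the sub-zero rise between two
negative bands) is not a band and is not reported.  Positions are
grid-resolution quantities; no sub-grid refinement is applied because
the positions being compared are quoted at ~10 nm granularity.

Calculated and measured peaks are paired by greedy nearest-position
matching without replacement; distance ties break toward the
shorter-wavelength pair so reports are deterministic.  Shift =
calculated − measured (negative = blue-shifted calculation).  The
verdict flag is true iff every matched |shift| is within the
tolerance, default 20 nm.  The positive-feature diagnostic returns
max(0, max Δε) over a window, default 220–240 nm, where spurious
positive shoulders appear in long-range-corrected calculations of
Ag⁺–guanine systems.

## Range-separation parameters

The Coulomb-attenuated exchange partition gives Hartree–Fock exchange
the weight α + β·erf(μ·r₁₂): α at contact, α + β at infinite
separation, with the DFT weight as complement.  μ is in bohr⁻¹, the
convention of the CAM functional definition.  Interpolation paths are
linear in (α, β) at equally spaced fractions with μ held at the start
value; endpoints are reproduced exactly (no floating-point
interpolation at t = 0, 1).  Report tables are 1-indexed to match the
(a)–(e) panel labelling convention of functional-scan figures.

The override stanza encodes each parameter as a 1e-5 integer-scaled
IOp-style field (the granularity of mainstream QC input overrides)
plus a full-precision `! rsh alpha=… beta=… mu=…` comment line; the
decoder reads the comment, so emit/decode round-trips are bit-exact
for arbitrary parameters.

## Structure truncation

Nucleotides (standard residue names, both DNA and RNA spellings,
primed or asterisked sugar-atom names) lose the phosphate and sugar
heavy atoms and their riding hydrogens.  One cut bond per residue is
recorded at the glycosidic link — C1′–N9 for purines, C1′–N1 for
pyrimidines — and the freed nitrogen is capped with a hydrogen placed
along the unit vector toward the removed C1′ at 1.01 Å, a standard
amine N–H length.  The length is configurable; the fixed-length
placement is a declared geometric convention providing the starting
point that a DFT relaxation of cap hydrogens would refine — relaxation
itself is out of scope.  Capping never moves a pre-existing atom, and
stripping is idempotent.  Non-nucleotide species (metal ions, waters)
pass through untouched; a nucleotide lacking its glycosidic nitrogen
is an error rather than a silent skip.

## Synthetic ensembles

The generator emulates the statistical structure of snapshot TDDFT
outputs: bands of states whose energies jitter as iid Gaussians about
a band center and whose rotatory strengths scatter fractionally about
a band mean.  Gaussian jitter is the simplest model of thermal
fluctuation and a modeling choice of this package, not a measured
property of any system.  Defaults: 10 snapshots; two negative bands
centered at 210 and 275 nm (5.90 / 4.51 eV) with four states of mean
R = −60 × 10⁻⁴⁰ cgs each, which broadens (σ = 0.3 eV) to negative
peaks of several tens of M⁻¹cm⁻¹ — the scale seen for Ag⁺-mediated
guanine tetramers; energy jitter s.d. 0.08 eV (~4 nm at 250 nm);
fractional R jitter 0.25.  An optional positive band near 230 nm
emulates the spurious shoulder of long-range-corrected functionals.
One root seed spawns independent per-snapshot streams, so ensembles
are bit-reproducible and individual snapshots do not depend on
ensemble size.

What passing these tests shows: the pipeline recovers planted spectral
structure through broadening, averaging and peak detection, and its
uncertainty band is calibrated under the stated noise model.  What it
does not show: anything about real electronic structure — state
energies and rotatory strengths here are draws from a recipe, with no
exchange-correlation physics, no correlated fluctuations between
states, and iid point noise in pseudo-experiments where real
instruments produce smooth correlated baselines.  Under that iid point
noise the dominant minima of a noisy spectrum wobble by a few nm in
individual realizations (the band bottom is flat relative to the
noise); the stable, tested statement is that the Monte-Carlo mean
drift stays below 2 nm at 5% noise.

## Problem sizes

The test suite and the acceptance script run everything at desk scale
by design: ensembles of 10 snapshots (2000 snapshots only for the
law-of-large-numbers check of the generator), 2000 Monte-Carlo
replicates for band calibration on a 10 nm grid, 100-seed noise
stability, and oracle comparisons over a few dozen random sticks.
These sizes are where the statistical statements stabilize; nothing in
the package depends on larger inputs, and the convolution is vectorized
(states × grid) so multi-hundred-state sticks are routine.

## Known limitations

- Velocity-gauge rotatory strengths, UV–Vis absorption from oscillator
  strengths, and vibronic lineshapes are out of scope.
- The QC-log reader targets the mainstream Gaussian-type dialect; other
  codes enter through the stick-exchange TSV.
- Peak matching is greedy, not globally optimal; for the 2–3 peaks per
  sign typical of these spectra the two coincide.
- Truncation does not perceive bonds: it trusts standard atom and
  residue names, and does not assign protonation states or metal
  coordination.
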