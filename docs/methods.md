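# Methods

`ionslab` models the transport of energetic heavy charged particles (HZE
particles) through homogeneous slabs, at the level of detail needed to
reproduce desk-scale worked numbers in particle therapy and space radiation
dosimetry: stopping and range, charge-changing attenuation, fragment
kinematics, Bragg curves, and LET-based mixed-field dosimetry. This note
records the models, their assumptions, the tunable parameters, and the
places where a genuine design choice had to be made.

## Ionization energy loss

Projectiles are treated as bare nuclei. The mass stopping power is the
uncorrected Bethe formula,

    S = K (Z/A)_mat (Z_p / beta)^2 [ ln(2 m_e c^2 beta^2 gamma^2 / I) - beta^2 ],

with K = 0.307075 MeV cm^2 mol^-1. Density-effect and shell corrections,
effective-charge screening at low velocity, and delta-ray transport are all
deliberately omitted; the formula in this form is accurate to a few percent
from a few MeV/nuc up to relativistic energies, which covers the 10 MeV/nuc
and above region that matters here.

- **Validity floor: 1 MeV/nuc.** Below it the uncorrected formula turns
  unphysical; requests below the floor raise instead of extrapolating. The
  residual range below the floor is booked as a fixed 0.01 g cm^-2 scaled
  by A/Z^2 (the proton-range equivalent at ~1 MeV is of this order; the
  exact value is irrelevant to any quantity the package reports).
- **Mean excitation energies** are the ICRU-standard values: water 75 eV,
  polyethylene 57.4 eV, aluminum 166 eV. These are the dominant systematic
  of the stopping model and are configurable per material.
- **Mass numbers.** Built-in materials carry integer mass numbers (H=1,
  C=12, O=16, Al=27) used both as nucleon counts in the nuclear cross
  section formula and as the g/mol approximation in number densities. The
  bias relative to natural molar masses is below 0.4% everywhere.

Ranges are continuous-slowing-down integrals of 1/S, computed by adaptive
quadrature (relative tolerance 1e-8) for single calls and by a cached
2000-point log-grid trapezoid table (interpolated log-log; converged to
<0.1%) inside the Monte Carlo. Because S depends on the projectile only
through Z_p^2 at fixed energy per nucleon, the A/Z^2 range scaling between
species is exact by construction, e.g. 4He and 1H have identical ranges.

## Charge-changing cross sections

The geometric (overlapping-spheres) model in the Wilson–Townsend form:

    sigma_cc = pi r0^2 (Ap^1/3 + At^1/3 - b - 1/Ap - 1/At)^2,

energy independent, with defaults r0 = 1.26 fm and transparency b = 0.2.
The validated band is roughly 200–1200 MeV/nuc; outside it a warning (not
an error) is emitted once per provider. Known limitations are inherited
deliberately: the model overestimates cross sections on hydrogen targets
(it predicts an 18–19 g cm^-2 mean free path for carbon in polyethylene
where measurements give about 22 g cm^-2) and underestimates the
transparency of 4He. Measured values therefore take precedence when
supplied, through two provider types: a record table keyed by
(projectile, target element), and a per-species mean-free-path override
used to inject published mfp values directly.

The (r0, b) fit is an exhaustive chi-squared grid search — matching the
way these two strongly correlated parameters are usually presented as a
contour map — with errors floored at 10% of the cross section, ties broken
toward small r0 then small b. The default grid steps (0.04 fm in r0, 0.10
in b) were set to roughly twice the one-sigma marginal uncertainties
obtained from a 200-trial fine-grid study of the default synthetic dataset
(30 projectile/target pairs, 10% noise: sd(r0) = 0.019 fm, sd(b) = 0.053,
correlation 0.81). A finer grid would mostly resolve the degeneracy ridge,
not the data.

## Fragment kinematics

Goldhaber statistical widths: each Cartesian momentum component of a
fragment of mass A_f from a projectile of mass A_p is Gaussian with
sigma^2 = sigma0^2 A_f (A_p - A_f)/(A_p - 1), sigma0 = 90 MeV/c by
default. Two width conventions circulate — fragment-total and per-nucleon
— and both are exposed; the familiar worked numbers (38 and 54 MeV/c for
12C -> 4He, a ~1 degree polar width) pair the per-nucleon transverse width
with the fragment-total longitudinal momentum, while the self-consistent
fragment-total pairing gives ~3 degrees. The package computes either; the
discrepancy is a convention choice, not a physics disagreement, and is
left to the caller.

## Branching model

A charge-changing event is reduced to one draw of the *heaviest fragment*
charge from a per-species table, plus light particles conserving charge
and baryon number. The carbon table {B: 0.20, Be: 0.10, Li: 0.10,
He: 0.40, H: 0.20} is anchored to the observed ~20% boron yield per
interaction; other species use a phenomenological rule favoring peripheral
(small charge change) collisions with enhanced He/H yields. Remainder
charge is emitted, by default, as 4He clusters where the nucleon budget
allows with leftover charge as protons ("alpha-clustered" rule; 12C -> 3
alpha is the canonical case), reflecting the helium-dominated light
fragment yields of fragmented light-ion beams; a plain all-protons rule is
available. Leftover nucleons are neutrons: counted and reported per
primary, never transported. Fragments inherit the projectile's velocity at
the vertex, perturbed by Goldhaber draws longitudinally (energy shift) and
transversely (deflection angle, tracked as a scalar lateral offset).

Known limitation: because every fragment retains beam velocity, fragment
fluence downstream of the production point is *not* thinned by the
low-energy, wide-angle component present in full 3-D nuclear-cascade
codes. At the Bragg peak of a 293 MeV/nuc carbon beam this model finds
~15–25% of crossing charged particles to be surviving carbon, versus ~45%
in reference simulations; qualitative composition structure (pure beam at
entrance, H/He-dominated fragment complement, only Z <= 2 far past the
peak) is reproduced.

## Monte Carlo transport and Bragg scoring

1-D transport in areal depth: deterministic slowing along the cached
range-energy tables between nuclear interactions; free paths sampled
exponentially from the species' mean free path (a per-step Bernoulli
scheme with p = step/lambda is available, warning when step > lambda/10).
Fragments are transported recursively. Ionization is scored chamber-style:
at each plane of a regular grid (default 0.05 g cm^-2) the stopping powers
of all crossing charged particles are summed and normalized to the
entrance plane. Particles drifting beyond the 100 mm default scoring
radius through their accumulated deflections are excluded, mirroring the
finite lateral acceptance of real scoring volumes. Planes where a
particle's energy is below the validity floor are not scored (the last
<0.01 g cm^-2 of track).

Range straggling is applied per particle as a Gaussian perturbation of the
stopping depth with sigma = 1.2% of range / sqrt(A) (Bohr-like scaling
from the familiar ~1.2% proton value). This is what gives binned peak
amplitudes their measured scale: a strictly monoenergetic, straggling-free
beam stops at exactly the CSDA range and the single-particle LET
divergence prints through to the binned curve. An optional Gaussian beam
energy spread (default off — beams are simulated monoenergetic) is
provided for studying beamline momentum-spread effects on peak amplitude.

With this default chain, a 200 MeV/nuc carbon beam in polyethylene peaks
at 8.10 g cm^-2 with amplitude ~7-8 (measured: 8.13 g cm^-2, 6.5), and a
600 MeV/nuc oxygen beam stays below unit ionization ratio over ~98% of
depth planes with a peak of ~1.4 — the fragmentation-dominated regime.

## Dosimetry and the shield study

Dose and dose equivalent are fluence-LET sums, D = sum w L x 1.602e-9 Gy
per (keV/um cm^-2) at unit density, H likewise weighted by the ICRP-60
Q(L) (piecewise: 1 below 10 keV/um; 0.32 L - 2.2 to 100; 300/sqrt(L)
above; the middle branch owns L = 100 exactly as published, giving the
documented 29.8 vs 30.0 step). LET is always evaluated in water regardless
of slab material. Charged particles below the 1 MeV/nuc floor are not
scored (the published analyses cut at 10 keV/nuc; the stricter floor
excludes a similarly negligible sliver).

The shield study samples the synthetic GCR field, transports every ion
through the slab (protons vectorized — they cannot charge-change in this
model — heavier species through the full fragmentation chain), and
summarizes the exiting charged field. Species sampling is stratified
(50% abundance-proportional, 50% equal-per-species) with statistical
weights making all estimators unbiased: heavy ions are ~1% of the flux but
carry most of the dose equivalent, and proportional sampling at n = 1e5
would leave the average quality factor at the mercy of ~60 iron draws.
The per-species table reports the closed-form interaction probability, net
attenuation including ranging-out, and the same restricted to incident
energies above 700 MeV/nuc, where feed-down from heavier species makes the
net carbon attenuation visibly smaller than its interaction probability.

A neutron bookkeeping hook reports the neutron yield per primary; no
neutron transport or dose conversion is performed unless the user supplies
conversion coefficients.

## Synthetic GCR spectrum

The flux model is a parametric stand-in for operational GCR models:

    phi(T) ∝ (T + m)^(-2.7) * (T / (T + E0))^2,

per species, normalized to the species abundance. The spectral index 2.7
is the conventional high-energy GCR slope; the modulation parameter E0
(default 600, MV-like) controls the low-energy roll-off — raising it
strictly hardens the spectrum, emulating solar maximum, while leaving the
multi-GeV tail shape untouched. Default abundances: H 0.87, He 0.12, and
1% heavies split C 0.00375, O 0.00345, Mg 0.0011, Si 0.0011, Fe 0.0006.
The split was calibrated once, by direct integration of the analytic
H = sum f L Q(L), so the unshielded average quality factor of the default
field is 6.5 — the middle of the free-space 6–7 band — while keeping the
H+He share at 99% and the dose-equivalent ordering (Fe dominant single
contributor) realistic. What the generator does *not* emulate: solar-cycle
time dependence, isotopic composition, anisotropy, and the detailed
spectral differences between species; conclusions drawn from it are
property-level (bands, orderings, monotonicities), not point predictions.

Problem sizes in the test suite (10^4 primaries for Bragg curves and
survival checks, 10^5 for the shielding study, 100 seeds for fit recovery)
were chosen so that Monte Carlo errors sit comfortably below the tested
tolerances.

## Numerical details

- All randomness flows from `numpy.random.default_rng` seeded explicitly;
  identical configurations are bit-identical.
- Range tables are cached per (Z, A, material name); the log-log
  interpolation error is <0.1% and halving the grid step moves ranges by
  <0.1%.
- Peak finding is argmax with ties broken toward the smallest depth; a
  monotone-decreasing curve is flagged (`no_peak`) rather than rejected.
- Cross-section unit chain: 1 fm^2 = 10 mb, 1 mb = 1e-27 cm^2; LET
  conversion 0.1 keV/um per MeV cm^2 g^-1 at unit density; dose conversion
  1.602e-9 Gy per (keV/um cm^-2).
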