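# Methods

This note documents the models, numerical choices and defaults behind
`gatingspring`, and what the synthetic-data generator does and does not
emulate.

## Tether mechanics

All mechanical elements live in `gatingspring.mechanics` and expose
force→extension, extension→force and compliance at a common tension.

- **Worm-like chain** (DNA handles, unfolded polypeptide): the
  interpolation force law, inextensible (no stretch modulus). The forces
  in these experiments stay below ~20 pN, where enthalpic stretching of
  DNA is a minor correction; adding a stretch modulus is out of scope.
  The entropic energy expression is the exact antiderivative of the force
  law, so energy–force consistency holds to machine precision.
- **Elastic rod** (structured protein): x = x₀ + F/k, defined for F < 0
  (compression) as well; WLC elements reject negative force.
- **Rigid offset** (nanodisc): 5 nm, force-independent below ~7 pN.
- **Parallel bundle**: n identical elements at a common extension share
  the force equally (F/n each); bundle compliance is the member
  compliance divided by n. Heterogeneous bundles are not supported.

Defaults: k_B T = 4.1 pN·nm, 0.365 nm/residue, 0.338 nm/bp (standard
B-DNA rise; the construct's two 2260-bp handles give 1527.8 nm of DNA
contour), P = 40 nm (DNA) and 0.6 nm (polypeptide). All are configurable
through `Constants` and the relevant dataclasses.

Inverses use bisection-secured Brent root finding with relative tolerance
1e−9 and geometric bracket expansion; WLC inversion brackets the
fractional extension in [0, 1).

## Differential pipeline

- **Boxcar filter**: centred moving average, default window 100 ms (the
  analysis convention spans 50–200 ms); edges without full support are
  dropped.
- **Force binning**: uniform 0.2 pN bins over 0.5–20 pN. Each bin stores
  the mean extension, the *population* SD, the sample count and the mean
  measured force of its samples. Fits evaluate models at the per-bin mean
  force, not the geometric centre: near 1 pN the DNA handle compliance is
  tens of nm/pN, so sub-bin differences between how the DNA-only and
  protein–DNA ramps populate a bin otherwise bias the subtraction.
- **Differential subtraction**: protein minus DNA per shared bin, with a
  first-order slope correction that evaluates the DNA extension at the
  protein bins' mean force; then the disordered-tail WLC extension and
  the nanodisc offset are removed. Spreads propagate in quadrature.
- **Pooling**: moment combination across molecules (population SD over
  all samples); across-molecule summary statistics use the sample SD.
- **Stiffness fit**: weighted least squares of x on F over 1–7 pN by
  default (the folded-branch region); weights are per-bin standard
  errors, which strongly down-weight the compliant low-force bins. A
  negative fitted slope is flagged, never clamped. For rip-free
  measurability studies the fit range may extend over the full pulled
  range.
- **Global FEC fit**: simultaneous weighted least squares of the DNA-only
  WLC and the tether model over one or more branches, with P_dna,
  P_chain, x₀, k and per-branch contour gains free (any may be held
  fixed). P_chain trades off against contour gain when only one long
  branch constrains it, so contour-length state assignment fixes P_chain
  at 0.6 nm.
- **Rip detection**: candidate regions where the extension changes by
  half the threshold within the dwell window (default 3 nm / 20 ms); the
  decisive jump is re-measured between medians of windows flanking the
  whole candidate run, which makes the detector robust to the boxcar
  smearing a true step over the filter width. Direction comes from the
  jump sign and pulling phase (positive on pull = unfolding, negative on
  pull = insertion, negative on relaxation = refolding). The threshold
  sits well above the ~0.2 nm post-filter noise floor and below the
  smallest ~5 nm discrete features.
- **State assignment**: residues = round(gain / 0.365), repeats =
  round(residues / 33), round-half-to-even; the canonical intermediates
  I1/I2/I3 match 10/20/29 repeats within ±2 (configurable).
- **Refolding**: a repull is "refolded" when its RMS extension deviation
  from the first pull over 2–6 pN is at most 2 nm — below the smallest
  inter-state extension difference at those forces.

## Force-clamp analysis

The extension histogram (density normalised to unit integral) is fit with
a two-Gaussian mixture by weighted least squares. The mixture objective
has degenerate local minima when the modes overlap, so the fit multistarts
from moment-based initialisations and keeps the lowest reduced χ²; the
result is canonicalised with the high-extension component second. The
open-state occupancy is the high component's mass (not a threshold
crossing), the equilibrium force is the zero crossing of occupancy
log-odds versus clamp force — exact for a two-state system with constant
swing, fitted by a least-squares line through the ladder — and the gating
energy is F_eq × Δx, converted with 1 kcal/mol = 6.9477 pN·nm
(k_B T = 4.1 pN·nm ≈ 0.593 kcal/mol). A per-transition entry point
averages the per-event products instead. The reported swing is the raw
Gaussian-mean separation; no handle-compliance correction is applied by
default.

## Gating model

Each channel state (closed/open × folded/partial) is an elastic rod in
series with a parallel bundle of the four subunits' disordered tails.
The closed-state rod lengths are 20 nm (folded) and 14.5 nm (partially
unfolded); opening adds the 4.6 nm gating swing and the V = 8 k_B T gate
energy. The folded rod stiffness is 1.4 pN/nm. The folded state carries
123 disordered N-terminal residues per subunit; the partial state carries
442 per tethered subunit (123 tail + ~319 from about ten unfolded
repeats) — the published accounting is ambiguous between per-subunit and
per-complex, so this is exposed as configuration.

State energy E = F²/2k + E_u + V satisfies ∂E/∂x = F. Below a state's
zero-force length the chains are slack (zero extension and energy) and
the rod carries linear compression; this keeps the energy surface
continuous so the Boltzmann comparison and midpoint root-solve are
defined on the whole extension axis (only x < 0 is rejected).

The gating force is reported as the occupancy-weighted average tension at
the P = 0.5 extension, with both branch tensions returned so alternative
definitions are checkable. In the chains-removed limit the average
tension at the midpoint is exactly V/swing = 7.13 pN; the full default
model gives ≈ 7.1 pN, consistent with the measured 6.9 pN equilibrium
force within its 0.6 pN spread.

The coupled-spring stiffness is the series combination of the pulled
N-terminal segments (k_N = N · n_AR · k_a / split_N, in parallel) with
all four anchored C-terminal segments (k_C = n_subunits · n_AR · k_a /
split_C): k_T(N) = k_N k_C / (k_N + k_C), which reduces to
29N/(9 + 5N) · k_a for the default 29-repeat, 9/20-split tetramer. It is
computed from the repeat counts, never hard-coded, and equals a
brute-force node-balance reduction of the spring graph. Loading rate uses the half-period convention (rate = 2·f·A·k),
with the 2πfA instantaneous-peak alternative behind a flag; the
Bell–Evans rupture module implements the constant-loading-rate survival,
density, analytic mode and quadrature mean with configurable (k₀, x‡) —
its defaults are placeholders, validated against its own closed forms.

## Synthetic data generator

`gatingspring.simulate` emulates the statistical structure the analysis
assumes, not the instrument physics:

- **Quasi-static pulls**: one trap moves at 10 nm/s; at each separation
  the tension balances the tether in series with two 0.3 pN/nm traps
  (monotone lookup tables, 1200-point force grids, linear interpolation —
  table error < 0.02 nm). There is no Langevin bead dynamics, no
  hydrodynamics and no camera/QPD noise spectrum.
- **Noise**: i.i.d. Gaussian, 2 nm extension / 0.2 pN force per raw
  sample at 1 kHz acquisition (a typical dual-trap rate), reduced ~10×
  by the default boxcar. Real traces have correlated low-frequency drift
  that this model omits, so passing recovery tests bound estimator
  performance under the assumed noise, not under drift.
- **Rips**: fixed-force triggers for deterministic tests, Bell-rate
  hazards (Gillespie over the discrete time grid) for rupture-force
  distributions; each event releases residues into the unfolded chain
  and/or shifts the rod length (negative shifts model insertion drops).
- **Clamp flicker**: an exact-dwell two-state Markov chain whose rates
  k₀·exp(±(F−F_eq)Δx/2k_BT) satisfy detailed balance with the Boltzmann
  occupancy; k₀ = 1 s⁻¹ gives ~120 transitions per 60 s trace at
  equilibrium (no kinetic rates are published; this is a scale choice).
- **Determinism**: every trace takes an explicit `numpy` Generator or
  seed; the canonical cohort spawns independent child streams per trace
  from one root seed, so identical seeds give byte-identical files.

The canonical cohort (`fixture_suite` / `construct_truth`) encodes the
study conditions: wild-type rod 0.7 pN/nm with a 123-residue tail and
5 nm nanodisc, a 12-repeat truncation at 0.26 pN/nm, an isolated ankyrin
domain at 0.12 pN/nm with short termini and no nanodisc, first-rip
triggers at 7.1/5.1/5.5 pN, and a five-point clamp ladder spanning the
6.9 pN equilibrium.

## Problem sizes

Recovery checks use 10 paired molecules per construct (the acceptance
and measurability runs), 60 s clamp traces at 200 Hz, and 5-force clamp
ladders; the measurability grid spans rod stiffnesses 0.1–30 pN/nm with
rip-free tethers fit over the full pulled range. These sizes put every
estimate's sampling error well inside the published spreads.

## Known limitations

- No hidden-Markov segmentation; branch segmentation relies on the jump
  detector, so gradual transitions or dense flicker between rips would
  need manual force-range restriction.
- The inextensible WLC overestimates DNA tension slightly above ~15 pN.
- The mixture-fit occupancy is biased when a clamp sits far from
  equilibrium (one component's mass < ~5%); ladder design should straddle
  the equilibrium force.
- The partial-unfolding state models a single intermediate; the real
  complex shows many.
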