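# Methods

This note records the models, numerical choices and known limitations
behind each analysis stage, in the spirit of a model-documentation
page: what is computed, under which assumptions, and what the synthetic
validation does and does not establish.

## Phase classification

Chains are nodes of a contact graph with an edge whenever the minimum
atom–atom distance between two chains is ≤ the cutoff (default 0.3 nm,
configurable; the hard, inclusive cutoff is part of the definition).
All atoms of a chain participate, including hydrogens; water is
excluded.  Distances use the minimum-image convention in orthorhombic
(three-edge-length) periodic boxes; triclinic cells are out of scope.
The neighbour search is a KD-tree with periodic box support, which is
exactly equivalent to the O(N²) brute force for an inclusive cutoff —
the test suite asserts this equivalence on random periodic systems.
The condensate is the largest connected component with at least
`min_condensate_size` (default 2) chains; size ties break towards the
component containing the lowest chain id, making labels deterministic.
Classification is per frame; no temporal smoothing is applied.  A
separate check (`validate_separation`) verifies that no dispersed
chain is in contact with any condensed chain — true by construction
for labels produced by the clustering, useful against hand-edited
labels.

## H-bond detection and survival autocorrelation

The geometric H-bond criterion (acceptor = amide carbonyl oxygen,
donor = water) defaults to O···H ≤ 2.45 Å, O···O ≤ 3.5 Å and an
O_w–H···O angle ≥ 130°.  All three are configurable and are recorded
in every emitted report, because lifetime statistics are only
comparable under a declared criterion.

`survival_acf` implements the intermittent convention by default: a
bond that breaks and reforms still correlates at long lags, matching
the normalisation ⟨Σ h_ij(t0)²⟩ = ⟨Σ h_ij(t0)⟩ for boolean occupancy.
A strict-continuous variant (`continuous=True`) zeroes a pair's
contribution after its first broken frame.  For each lag the numerator
and denominator average over the origin set {0, stride, …} truncated
so the lagged frame exists, which makes C(0) = 1 exact; with unit
stride the numerator is evaluated by FFT autocorrelation (identical to
the double loop, asserted in tests).  `max_lag` is capped at half the
trajectory length so every lag retains at least half the origins.

Baseline removal subtracts the mean of C over the final 10% of lags
(the equilibrium H-bond population; for a telegraph process the exact
plateau is k_on/(k_on+k_off)) and renormalizes to C(0) = 1.  A
baseline ≥ C(0) means there is no decaying component and is an error.

## Constrained triple-exponential fit

Amplitudes are parametrised by stick-breaking — A₁ = s₁,
A₂ = (1−s₁)s₂, A₃ = (1−s₁)(1−s₂) with s ∈ [0, 1] — so A_n ≥ 0 and
Σ A_n = 1 hold exactly by construction rather than approximately via
penalties.  Time constants are optimised in log space with a
deterministic multistart (descending triples from a log-spaced grid
over the lag window), unweighted residuals on the given lag grid.
The upper τ bound defaults to the sampled window length: a decay
slower than the window is not identifiable and, if left unbounded,
small tail noise can be absorbed into a spurious slow component that
inflates the amplitude-weighted mean.  The shortest component may be
held fixed (`fix_tau3`), the usual treatment of a sub-resolution
librational component.  Components are reported sorted by descending
τ; the covariance of (A, τ) is obtained from the internal-parameter
covariance by the delta method.  The amplitude-weighted mean
τ = Σ A_n τ_n equals the integral of the unit-normalized fit, so for a
degenerate input (e.g. a pure single exponential) the mean lifetime is
recovered even though the amplitude split between components is not
unique.

## Telegraph generator

H-bond occupancy is emulated by a two-state Markov chain with rates
k_on (formation) and k_off (breaking), propagated with *exact*
exponential transition probabilities per step
(P(1→1) = p + (1−p)e^{−k dt}, p = k_on/k, k = k_on + k_off), so the
sampled chain has the exact continuous-time statistics at the frame
times for any dt and the survival ACF is analytically
p + (1−p)e^{−kt}.  A warning fires when dt·k > 0.1: the chain itself
stays exact, but events faster than the frame spacing are invisible to
downstream intermittent/continuous distinctions.  The initial state is
stationary unless overridden.  Seeds are mandatory; generation is
bit-reproducible.

## Joint-Gaussian (Kubo-style) 2D IR generator

Each waiting time's spectrum is a negative ground-state-bleach lobe —
a bivariate Gaussian in (pump, probe) with equal marginal variances
σ² = Δ² + σ_h² and correlation ρ(Tw) = Δ²e^{−Tw/τc}/σ² — plus a
positive excited-state-absorption copy shifted down the probe axis by
the anharmonicity, both scaled by e^{−Tw/T1}.  This is a
phenomenological lineshape, not a third-order response-function
calculation: it is the minimal model for which the CLS has the closed
form CLS(Tw) = ρ(Tw), which is what makes it a ground-truth oracle for
the analysis stage.  Two deliberate idealisations follow: homogeneous
broadening enters as a Gaussian variance term (a true fast-modulation
limit would be Lorentzian), and the lobes are unit-volume (not
unit-peak) so the integrated bleach tracks the population amplitude
alone — correlation-induced narrowing conserves volume, as it must for
a population observable.  Consequently, passing tests establish that
the CLS/NLS/volume estimators are unbiased for Gaussian statistics
with single-exponential frequency memory; they do not probe
non-Gaussian frequency fluctuations, finite pulse effects, coherent
artifacts or phasing errors of real measurements.

## CLS, NLS and relaxation fits

For each pump column in the analysis window (default 1618–1685 cm⁻¹,
configurable) the probe position of the bleach minimum is refined with
a three-point parabolic interpolation (sub-gridpoint precision without
smoothing assumptions).  Columns whose minimum sits on the probe-axis
border or whose depth is below `contrast_fraction` (default 0.1) of
the deepest column — bleach eroded by the overlapping ESA lobe — are
dropped with a warning; at least four usable columns are required.
CLS is the slope of the least-squares line of probe-minimum versus
pump, i.e. d(probe of minimum)/d(pump): 1 when detection follows
excitation perfectly, 0 when memory is lost.  The regression is run in
this direction by definition (the "inverse slope" wording of
slope conventions is axis-dependent; this package's convention is
fixed and logged).  For a joint-Gaussian band with equal pump/probe
widths this slope equals ρ exactly, and the restricted-window test
(sub-interval CLS within 2%) reflects the linearity of the Gaussian
conditional mean.  The nodal line slope interpolates the zero crossing
between the bleach minimum and ESA maximum per column; it matches the
CLS whenever the anharmonic shift well separates the lobes.

CLS(Tw) is summarised by a single-exponential fit CLS₀e^{−Tw/τ}
(a biexponential is deliberately not the default: with few waiting
times the extra parameters are not constrained).  Population
relaxation integrates the negative-signal magnitude over a pump×probe
region (trapezoidal rule) and fits A₀e^{−Tw/τ_VER} + y₀.  A series
that does not decay appreciably over the window (fitted τ much longer
than the span, or τ pinned at its bound) raises a warning and reports
the (large) uncertainty rather than failing.

## Peptide and droplet generators

Backbones are built by natural-extension (NeRF) placement with
standard trans-peptide internal coordinates (N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, ω = 180°), C=O lengths set per residue, and the
carbonyl oxygen placed at dihedral ψ + 180° — which is also how the
exciton builder recovers ψ for the terminal residue without a
successor nitrogen.  Amide hydrogens are attached anti to the
preceding carbonyl oxygen; the N-terminus and prolines carry none.
Requested dihedrals are reproduced to well below 10⁻⁶ degrees
(round-trip asserted), and an α-helical request yields the standard
~1.5 Å rise per residue.

Droplet systems place `n_condensed` template chains sequentially, each
bisected along the packing axis until its minimum distance to its
predecessor equals the contact target (2.5 Å, inside the 3 Å
classification cutoff), then recentre the cluster; dispersed chains
are rejection-sampled with a minimum-image gap ≥ `min_gap` from every
other chain.  Ground-truth labels are the chain-id order.  These are
toy configurations: they validate the exactness of the classifier and
the plumbing of per-phase analysis, not condensate morphology.

## Exciton Hamiltonian

Site frequencies: ω_i = Ω₀ − S(r_i − r₀) with Ω₀ = 1655 cm⁻¹,
r₀ = 1.229 Å, S = 400 cm⁻¹/Å; elongation red-shifts, consistent with
stronger H-bonding to the carbonyl.  The −19 cm⁻¹ proline shift
applies to the amide whose nitrogen belongs to the proline ring, i.e.
the residue preceding a proline.  Nearest-neighbour couplings come
from a (φ, ψ) map with periodic bilinear interpolation, evaluated at
the dihedrals of the residue linking the two carbonyls; the bundled
`synthetic_coupling_map` is an illustrative smooth surface with
realistic few-cm⁻¹ magnitudes, *not* a quantum-chemical
parametrisation — supply a map file for quantitative work.  Remaining
couplings use point transition dipoles displaced 0.868 Å from C along
C=O, tilted 20° towards the peptide-bond nitrogen, prefactor
580 cm⁻¹·Å³ per squared unit dipole; all four TDC parameters are
configurable and logged.  The linear spectrum convolves the stick
spectrum |Σ_i c_ik μ_i|² with unit-area Lorentzians (HWHM 6 cm⁻¹).
Eigenbasis completeness fixes the total stick intensity at Σ_i |μ_i|²
independent of couplings, which the tests assert to 10⁻¹⁰ together
with the Gershgorin bracketing of eigenvalues.  Ensemble spectra are
plain averages over snapshots.

## Pipeline and problem sizes

`run_pipeline` executes classify → per-phase occupancy → ACF →
baseline → constrained fit → mean lifetimes → condensed/dilute ratio,
and emits a JSON report embedding the full resolved configuration,
software version and seeds, so reruns are byte-identical.  The
validation configuration uses 6 condensed + 3 dispersed chains,
600 telegraph pairs per chain, 8000 frames at 0.05 ps spacing and a
10 ps lag window — sizes at which the sampling error of the fitted
mean lifetime is ~2%, comfortably resolving the constructed 40%
condensed/dilute contrast.  When one phase is empty its branch is
reported as absent and no ratio is computed.

## Known limitations

- No MD engine, force field or water model: all dynamical inputs are
  either user-supplied trajectories or the telegraph surrogate.
- No third-order response-function simulation of 2D spectra; the 2D
  generator is a lineshape model (see above).
- Orthorhombic boxes only; inclusive hard cutoffs throughout.
- The bundled dihedral coupling map is synthetic; quantitative exciton
  calculations require a real parametrised map file.
- The H-bond geometric criterion is a convention; reported lifetimes
  shift with it, which is why it is configurable and always logged.
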