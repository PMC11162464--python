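# Methods

## Scope and model

The package treats ultrafast excitation energy transfer (EET) in a stacked
donor/acceptor dimer with a low-lying charge-transfer (CT) state, at two
levels that the literature on such systems uses side by side:

* a **kinetic level** — sequential multiexponential global analysis of
  transient-absorption (TA) maps plus a lifetime decomposition that
  separates conformer populations and reaction channels;
* a **vibronic level** — a linear vibronic coupling (LVC) Hamiltonian for
  three diabatic states (bright donor state `La`, dark `CT`, acceptor
  `Nic*`) propagated as a quantum wavepacket.

Units are fixed package-wide: energies in eV, frequencies in cm⁻¹
(1 cm⁻¹ = 1.239841984×10⁻⁴ eV), time in fs, ħ = 0.6582119569 eV·fs.
Nuclear coordinates are dimensionless mass-frequency-scaled normal
coordinates with the ground-state equilibrium at q = 0; the electronic
ground state is *not* a dynamical state — internal conversion to it enters
only through the kinetics module as a rate.

## LVC Hamiltonian and ablations

`vibronic_model` assembles

H = Σₖ (ω̃ₖ/2)(pₖ²+qₖ²)·𝟙 + Σᵢ|i⟩⟨i|(Eᵢ + Σₖ κᵢₖqₖ) + Σᵢ≠ⱼ|i⟩⟨j|(E⁰ᵢⱼ + Σₖ λᵢⱼₖqₖ)

on a truncated harmonic product basis (q couples ladder levels n↔n±1 with
amplitude √((n+1)/2)). Coupling sign conventions are gauge: flipping the
sign of every coupling into one state is a per-state phase flip that leaves
all observables unchanged, and a property test enforces this. Ablations
(`electronic` → E⁰ᵢⱼ, `interstate_vibronic` → λᵢⱼ, `intrastate_tuning` →
κᵢᵢ, optionally restricted to a mode subset) return modified copies and are
idempotent and mutually commuting.

Default ladder depths follow the common system/bath split (30 levels for
strongly coupled "system" modes, 15 for "bath" modes). The synthetic
fixture uses its own desk-scale depths (below).

## Propagation

`quantum_dynamics.propagate` applies exp(−iHΔt/ħ) to the state vector once
per output step using the Al-Mohy–Higham scaling/Taylor action on the
sparse Hamiltonian (the exponential is never formed). For the reduced
models targeted here this is exact to near machine precision: norm and
energy drift over 200 fs are at the 10⁻¹⁴ level, well inside the 10⁻⁶
invariant the `Trajectory` container enforces. Defaults: t_final = 200 fs,
dt_out = 0.25 fs.

Observables per sample: diabatic populations, the full nuclear-traced
electronic density matrix (coherence magnitudes |ρᵢⱼ| obey
|ρᵢⱼ| ≤ √(PᵢPⱼ)), total energy, norm, and ⟨qₖ⟩ for every mode. The
coherence is defined as the *modulus* of the traced density-matrix
off-diagonal; whether one plots the modulus or the real part is a
convention, and the modulus is adopted because it is basis-phase invariant.

Truncation is the only approximation and is monitored: if the top two
ladder levels of any mode carry more than 1% population, a warning names
the mode. Exact propagation is practical up to roughly six modes at these
depths; larger models are first reduced with `mode_reduction` (Franck–
Condon activity score = max over states/pairs of |κᵢₖ|, |λᵢⱼₖ|; selection is
count-driven with an optional score floor around 0.02 eV, which in practice
separates photoactive from inert modes). Population-transfer "bursts" are
operationalized as local maxima of dP_acceptor/dt on the output grid, with
a 10% prominence filter against grid-scale ripples; for a two-state model
driven through its crossing by one tuning mode the bursts come twice per
vibrational period, so their mean spacing is half the period (10.4 fs at
1600 cm⁻¹) independent of where in the period the crossings fall.

## FED diabatization

`diabatization.fed_diabatize` diagonalizes the excitation-difference matrix
Δx (symmetric by construction here, so eigenvectors are orthogonal);
eigenvalues near +1/−1 tag locally excited states on either fragment, near
0 the CT state. Gauge fixing: columns sorted by descending eigenvalue, sign
chosen so each column's largest-magnitude component is positive. An
eigenvalue farther than 0.2 (configurable) from every target, or a
degenerate Δx spectrum, aborts with an explicit error rather than guessing
a character assignment. The Hamiltonian (and, when given, adiabatic-diagonal
gradient vectors) are rotated by the same orthogonal matrix, yielding
diabatic energies, electronic couplings V, and κ/λ tables; the spectrum is
preserved to 10⁻¹⁰ and round-tripping a rotated planted picture recovers
everything up to sign/order gauge. Hole/electron centroids are inputs (from
per-atom charges); only their distance d_eh is computed. The 0.5 eV rule
(`ct_accessible`) encodes that solvent fluctuations of roughly ±0.5 eV can
only pull a CT state into play if its gas-phase position is within 0.5 eV
of the bright state.

## Kinetics

`irf_exp` is the closed-form exponential ⊗ Gaussian
(σ = FWHM/(2√(2 ln 2))), evaluated piecewise through `erfcx` on the rising
edge and the direct `erfc` form on the decay side so that no regime
overflows; it matches direct quadrature to 10⁻⁶ and reduces to a step
exponential at zero IRF width. Sequential concentration profiles use the
standard chain (Bateman) solution, each term an IRF-convolved exponential;
equal rates are rejected (the solution is singular there).

`global_fit` is a variable projection: lifetimes and time zero (optionally
the IRF width) are the nonlinear parameters optimized by trust-region least
squares (via lmfit), the evolution-associated spectra are solved by linear
least squares at every iteration. Lifetime uncertainties come from the
covariance of the nonlinear stage. Recovery at the measurement scales
(τ = 157/894 fs, 30 fs IRF, −100…1500 fs delays, SNR 50) is better than 1%
bias and 5% RMSE over 20 noise seeds.

The decomposition chain: τ_mix = (1−f)·τ_unfolded + f·τ_folded inverted for
τ_folded, then rate additivity τ_EET = 1/(1/τ_folded − 1/τ_IC). Both are
exact algebra; invalid inputs (non-positive folded lifetime, τ_total >
τ_IC) raise. `mc_uncertainty` propagates independent Gaussian input
uncertainties by resampling (≥1000 draws, seeded), rejecting and counting
draws that make the chain invalid. Note that propagating the measured ±4 fs
lifetime uncertainties through the chain first-order gives σ(τ_folded) ≈ 16
fs — substantially larger than typical quoted uncertainties on the derived
constants, which evidently rest on additional information (e.g. correlated
errors or constraints not contained in the lifetimes alone); the package
therefore treats central values as the reproducible quantities.

## Disorder ensembles

`sample_disorder` shifts the CT vertical energy by Gaussian draws
(default FWHM 1 eV, the scale of solvent-induced CT fluctuation in water)
and multiplies every coupling involving CT by (1 + 0.1·z) with one
standard-normal z per state pair per snapshot — the per-snapshot coupling
variability is not known precisely, so the 10% jitter is a labelled
assumption. Frequencies and non-CT parameters are frozen (rigid solute,
varying solvent). `run_ensemble` propagates each realization independently
(order-invariant), records failures without aborting, sorts snapshots by
the CT–donor gap ΔE at Franck–Condon, and exposes population maps indexed
by ΔE rank (not binned). Pathway classes: `direct` if the CT population
never reaches 0.2, `ct_trapped` if it ends at ≥0.5, else `ct_mediated`.
The model lacks dynamic solvent relaxation, so CT trapping near ΔE ≈ 0 is
expected to be overestimated relative to a polar-solvent experiment.

## Synthetic data and problem sizes

The generator defaults define the study conditions and are fixed:

* Electronic: E_La = 4.7 eV (pump resonance); E_Nic* and E_CT 0.5 eV below.
  The absolute Nic*/CT energies are synthetic placeholders — only their
  offsets matter for the dynamics studied.
* Modes: tuning modes at 1400 and 1600 cm⁻¹ (donor C–C/C–N stretches,
  κ_La = −0.2 eV) and two low-frequency CT↔Nic* coupling modes at 300 and
  500 cm⁻¹ (λ = 0.05 eV); a 100–600 cm⁻¹ band with a few modes is the
  realistic envelope, and two modes keep exact propagation cheap.
* Couplings: V⁰(La,CT) = 0.13 eV — chosen so |V/Δ| ≈ 0.26 at the 0.5 eV
  Franck–Condon gap, the strong-mixing regime; V⁰(CT,Nic*) = 0.10 eV;
  the direct V⁰(La,Nic*) = 0.02 eV is an order of magnitude smaller,
  reflecting the one-electron nature of LE/CT coupling versus the
  two-electron LE/LE exchange.
* TA: τ = 157/894 fs, 30 fs IRF, SNR 50, delays −100…1500 fs in 5 fs
  steps, probe 1.9–3.2 eV (80 points), i.i.d. Gaussian noise scaled to
  peak|ΔA|/SNR.

`make_nadh_basis` supplies the matching desk-scale truncation: 8 ladder
levels on the high-frequency tuning modes and ≈6000/ω̃(cm⁻¹) levels on the
low-frequency modes (20 and 12), sized so the leakage monitor stays silent
over 200 fs. The resulting Hilbert space (≈46k amplitudes) propagates in
well under a minute on one core. Ensemble and property tests use a
two-mode variant (one 1500 cm⁻¹ tuning, one 400 cm⁻¹ coupling mode) where
each 200 fs propagation takes under a second.

What the generators deliberately do *not* emulate: anharmonicity and
Duschinsky rotation, finite-temperature initial conditions, time-dependent
solvent relaxation, coherent-artifact/solvated-electron TA contributions,
and realistic absolute ΔA magnitudes. Tests passing on these fixtures
demonstrate the correctness of the algorithms under the stated model
assumptions, not the accuracy of those assumptions for any particular
molecule.

## Numerical choices

* Propagator accuracy: per-step action computed to near machine precision;
  the `tol` argument is an upper bound the integrator comfortably beats.
* Degenerate inputs (zero gaps, zero couplings) are legal everywhere;
  dynamics reduce to the analytic limits (Rabi oscillation, displaced
  oscillator) that the tests pin to 10⁻⁶.
* Mode-selection ties break by ascending mode index; FED gauge as above;
  lifetimes in fit results are sorted ascending with their spectra.
* Model files carry a schema version and are emitted with 12 significant
  digits; write∘read is identity at that precision.

## Known limitations

* Exact propagation scales exponentially with mode count; beyond ~6 modes
  the reduction step is mandatory, and the package intentionally does not
  implement tensor-tree (multilayer) wavefunctions.
* The FED implementation assumes a symmetric excitation-difference matrix
  (orthogonal eigenvectors) and two fragments.
* The sequential kinetic model requires distinct lifetimes; a parallel
  scheme is not currently exposed.
* Disorder is static: each snapshot's Hamiltonian is time-independent.
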