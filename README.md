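# eetkit

Vibronic wavepacket dynamics and transient-absorption kinetics for
ultrafast excitation energy transfer (EET) in stacked chromophore dimers —
the NADH adenine→nicotinamide transfer being the motivating system.

## Who this is for

Researchers analysing sub-100-fs EET in closely stacked donor/acceptor
aggregates, where the transfer is driven by coherent nuclear motion and may
be gated by a dark charge-transfer (CT) state. The package provides a
desk-scale, fully testable version of the standard computational chain:

1. **Kinetics** — global analysis of pump–probe transient-absorption (TA)
   maps with a sequential multiexponential model convolved with a Gaussian
   instrument response, followed by the lifetime decomposition that isolates
   the EET rate of the folded conformer population.
2. **Vibronic model** — a linear vibronic coupling (LVC) Hamiltonian

   H = Σₖ (ω̃ₖ/2)(pₖ² + qₖ²)·𝟙 + Σᵢ |i⟩⟨i| (Eᵢ + Σₖ κᵢₖ qₖ)
     + Σᵢ≠ⱼ |i⟩⟨j| (E⁰ᵢⱼ + Σₖ λᵢⱼₖ qₖ)

   over diabatic states (Lₐ, CT, Nic\*) and dimensionless normal modes, with
   coupling ablations (zero the E⁰ᵢⱼ, λᵢⱼ, or κᵢᵢ class) as first-class
   operations.
3. **Quantum dynamics** — numerically exact wavepacket propagation on
   reduced mode sets (truncated harmonic product basis, per-step action of
   exp(−iHΔt/ħ)), yielding diabatic populations, electronic coherences
   |ρᵢⱼ(t)| and mode expectation values.
4. **Diabatization** — Fragment Excitation Difference (FED): diagonalizing
   the excitation-difference matrix separates locally excited states
   (eigenvalues ±1) from the CT state (eigenvalue 0) and rotates the
   Hamiltonian and gradients into the diabatic basis.
5. **Mode reduction** — Franck–Condon activity ranking (max of |κ|, |λ| per
   mode), count-driven selection and system/bath tiering.
6. **Ensembles** — Gaussian CT-energy disorder (solvent heterogeneity) with
   coupling jitter, propagated per snapshot and assembled into population
   maps ordered by the CT–donor gap.
7. **Synthetic data** — generators for NADH-like LVC models and TA maps
   with known ground truth, used throughout the test suite.

## Worked example: the EET time constant

The fast TA lifetime of the dimer in water (122 fs) is a population-weighted
mixture of folded (~30%) and unfolded (~70%) conformers; the unfolded decay
equals the bare donor's internal conversion (157 fs). Inverting the mixture
and applying rate additivity k_total = k_IC + k_ET:

```bash
$ eetkit decompose --tau-mix 122 --tau-unfolded 157 --f-folded 0.3 --tau-ic 157
tau_folded = 40.33 fs
tau_EET = 54.28 fs
k_total = 0.0247934 fs^-1 = k_IC (0.00636943) + k_ET (0.018424)
```

The folded conformers decay in ~40 fs; removing the internal-conversion
rate leaves an energy-transfer time of ~54 fs.

The lifetimes themselves come from the global fit. On a synthetic map with
the same scales (τ = 157/894 fs, 30 fs IRF, signal-to-noise 50):

```python
>>> from eetkit import SynthConfig, make_ta_map, global_fit
>>> tamap, truth = make_ta_map(SynthConfig(seed=1, snr=50))
>>> fit = global_fit(tamap, n_components=2)
>>> fit.tau.round(1), fit.tau_stderr.round(2)
(array([156.4, 889.5]), array([0.58, 5.38]))
```

both lifetimes recovered within 1%.

On the dynamics side, `make_nadh_model()` builds the default
donor/CT/acceptor model (CT 0.5 eV below the donor); a 200 fs propagation
from the Franck–Condon point shows the CT doorway filling within ~10 fs and
the acceptor becoming the dominant state well inside 100 fs, with
population-transfer bursts spaced by half the tuning-mode period (~10 fs at
1600 cm⁻¹).

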