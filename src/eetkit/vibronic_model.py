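"""Linear vibronic coupling (LVC) Hamiltonians for donor/CT/acceptor systems.

The model couples a handful of diabatic electronic states (e.g. the bright
``La`` state of the donor, a dark charge-transfer state ``CT`` and the
acceptor state ``Nic*``) through shared harmonic vibrational modes:

    H = sum_k (w_k/2)(p_k^2 + q_k^2) * 1
      + sum_i |i><i| (E_i + sum_k kappa_ik q_k)
      + sum_{i!=j} |i><j| (V0_ij + sum_k lambda_ijk q_k)

with dimensionless normal coordinates q_k, mode quanta w_k (stored in cm^-1,
converted to eV on assembly), per-state vertical energies E_i, intrastate
gradients (tuning) kappa, interstate vibronic couplings lambda and constant
electronic couplings V0, all in eV.  The electronic ground state is not a
dynamical state of the model.

Coupling "ablations" — zeroing a whole class of terms to probe its role in
the dynamics — are first-class operations, mirroring the switch-off
experiments used to dissect energy-transfer mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .units import cm1_to_ev

__all__ = [
    "ModelValidationError",
    "VibronicModel",
    "BasisSpec",
    "ABLATION_CATEGORIES",
    "ablate",
    "decouple_state",
    "build_hamiltonian",
    "electronic_coupling_matrix",
    "mode_q_operator",
]

ABLATION_CATEGORIES = ("electronic", "interstate_vibronic", "intrastate_tuning", "none")


class ModelValidationError(ValueError):
    """Raised when a model or basis violates its invariants.

    ``field`` names the offending quantity.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _as_array(x, shape, name):
    a = np.asarray(x, dtype=float)
    if a.shape != tuple(shape):
        raise ModelValidationError(name, f"expected shape {tuple(shape)}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ModelValidationError(name, "contains non-finite entries")
    return a


@dataclass(frozen=True)
class VibronicModel:
    """Complete LVC Hamiltonian specification.

    Parameters
    ----------
    state_labels
        Unique diabatic labels, e.g. ``("La", "CT", "Nic*")``.
    E
        Diabatic vertical energies at the Franck-Condon point, eV, shape (ns,).
    omega
        Harmonic frequencies, cm^-1, shape (nm,), strictly positive.
    kappa
        Intrastate gradients (tuning), eV per dimensionless coordinate,
        shape (ns, nm).
    lam
        Interstate vibronic couplings, eV, shape (ns, ns, nm); symmetric in
        the state pair with zero diagonal.
    V0
        Constant electronic couplings, eV, shape (ns, ns); symmetric with
        zero diagonal.
    ablation
        Record of ablation categories already applied (metadata only; the
        coupling tables themselves are zeroed by :func:`ablate`).
    """

    state_labels: tuple
    E: np.ndarray
    omega: np.ndarray
    kappa: np.ndarray
    lam: np.ndarray
    V0: np.ndarray
    ablation: tuple = ()

    def __post_init__(self):
        labels = tuple(self.state_labels)
        object.__setattr__(self, "state_labels", labels)
        if len(set(labels)) != len(labels):
            raise ModelValidationError("state_labels", "labels must be unique")
        ns = len(labels)
        E = _as_array(self.E, (ns,), "E")
        omega = _as_array(self.omega, (np.asarray(self.omega).shape[0] if np.ndim(self.omega) else 0,), "omega")
        nm = omega.shape[0]
        if nm and np.any(omega <= 0):
            raise ModelValidationError("omega", "frequencies must be strictly positive")
        kappa = _as_array(self.kappa, (ns, nm), "kappa")
        lam = _as_array(self.lam, (ns, ns, nm), "lam")
        V0 = _as_array(self.V0, (ns, ns), "V0")
        if not np.allclose(V0, V0.T, atol=0.0):
            raise ModelValidationError("V0", "must be symmetric in (i, j)")
        if np.any(np.diag(V0) != 0.0):
            raise ModelValidationError("V0", "diagonal must be zero")
        if not np.allclose(lam, np.swapaxes(lam, 0, 1), atol=0.0):
            raise ModelValidationError("lam", "must be symmetric in (i, j)")
        if np.any(lam[np.arange(ns), np.arange(ns), :] != 0.0):
            raise ModelValidationError("lam", "diagonal must be zero")
        for name, val in (("E", E), ("omega", omega), ("kappa", kappa), ("lam", lam), ("V0", V0)):
            arr = val.copy()
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "ablation", tuple(self.ablation))

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @property
    def n_modes(self) -> int:
        return self.omega.shape[0]

    def state_index(self, label: str) -> int:
        try:
            return self.state_labels.index(label)
        except ValueError:
            raise ModelValidationError(
                "state_labels", f"unknown state {label!r}; have {self.state_labels}"
            ) from None

    @property
    def omega_ev(self) -> np.ndarray:
        """Mode quanta in eV."""
        return cm1_to_ev(self.omega)


@dataclass(frozen=True)
class BasisSpec:
    """Per-mode primitive harmonic-ladder truncation.

    ``levels[k]`` is the number of harmonic-oscillator levels retained for
    mode k (>= 2).  Modes are typically tiered: strongly coupled "system"
    modes get a deep ladder (default 30), weakly coupled "bath" modes a
    shallower one (default 15).
    """

    levels: np.ndarray

    SYSTEM_LEVELS = 30
    BATH_LEVELS = 15

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=int)
        if lv.ndim != 1:
            raise ModelValidationError("levels", "must be a 1-D integer array")
        if lv.size and np.any(lv < 2):
            raise ModelValidationError("levels", "every mode needs >= 2 ladder levels")
        lv = lv.copy()
        lv.setflags(write=False)
        object.__setattr__(self, "levels", lv)

    @classmethod
    def uniform(cls, n_modes: int, levels: int) -> "BasisSpec":
        return cls(np.full(n_modes, levels, dtype=int))

    @classmethod
    def tiered(cls, tiers: Sequence[str], system_levels: int = SYSTEM_LEVELS,
               bath_levels: int = BATH_LEVELS) -> "BasisSpec":
        """Build from per-mode tier labels ("system" or "bath")."""
        sizes = []
        for t in tiers:
            if t == "system":
                sizes.append(system_levels)
            elif t == "bath":
                sizes.append(bath_levels)
            else:
                raise ModelValidationError("tiers", f"unknown tier {t!r}")
        return cls(np.asarray(sizes, dtype=int))

    @property
    def n_modes(self) -> int:
        return self.levels.shape[0]

    @property
    def dim_nuclear(self) -> int:
        return int(np.prod(self.levels, dtype=np.int64)) if self.n_modes else 1

    def check_matches(self, model: VibronicModel) -> None:
        if self.n_modes != model.n_modes:
            raise ModelValidationError(
                "levels",
                f"basis covers {self.n_modes} modes but model has {model.n_modes}",
            )


def ablate(model: VibronicModel, which: str,
           mode_subset: Optional[Sequence[int]] = None) -> VibronicModel:
    """Return a copy of ``model`` with one class of coupling terms zeroed.

    ``which`` selects the class: ``"electronic"`` zeroes the constant
    couplings V0, ``"interstate_vibronic"`` the lambda table,
    ``"intrastate_tuning"`` the kappa table, ``"none"`` returns an identical
    copy.  ``mode_subset`` restricts the zeroing to the listed modes (ignored
    for ``"electronic"``, which has no mode axis).
    """
    if which not in ABLATION_CATEGORIES:
        raise ModelValidationError(
            "which", f"unknown ablation category {which!r}; expected one of {ABLATION_CATEGORIES}"
        )
    if which == "none":
        return replace(model)
    if mode_subset is not None:
        modes = np.asarray(list(mode_subset), dtype=int)
        if modes.size and (modes.min() < 0 or modes.max() >= model.n_modes):
            raise ModelValidationError("mode_subset", "indices outside the model's mode range")
    else:
        modes = None

    kappa, lam, V0 = model.kappa.copy(), model.lam.copy(), model.V0.copy()
    if which == "electronic":
        V0[:] = 0.0
    elif which == "interstate_vibronic":
        if modes is None:
            lam[:] = 0.0
        else:
            lam[:, :, modes] = 0.0
    elif which == "intrastate_tuning":
        if modes is None:
            kappa[:] = 0.0
        else:
            kappa[:, modes] = 0.0
    tag = which if modes is None else f"{which}[{','.join(map(str, modes.tolist()))}]"
    return replace(model, kappa=kappa, lam=lam, V0=V0,
                   ablation=model.ablation + ((tag,) if tag not in model.ablation else ()))


def decouple_state(model: VibronicModel, label: str) -> VibronicModel:
    """Zero every electronic and vibronic coupling into one state.

    Used for the control in which the charge-transfer doorway is switched
    off: with all LE-CT couplings removed the CT population must stay zero.
    """
    s = model.state_index(label)
    V0 = model.V0.copy()
    lam = model.lam.copy()
    V0[s, :] = 0.0
    V0[:, s] = 0.0
    lam[s, :, :] = 0.0
    lam[:, s, :] = 0.0
    return replace(model, V0=V0, lam=lam,
                   ablation=model.ablation + (f"decouple[{label}]",))


def electronic_coupling_matrix(model: VibronicModel, k: int) -> np.ndarray:
    """The electronic matrix W_k multiplying q_k: kappa on the diagonal,
    lambda off the diagonal."""
    W = model.lam[:, :, k].copy()
    W[np.diag_indices(model.n_states)] = model.kappa[:, k]
    return W


def _ladder_q(n: int) -> sp.csr_matrix:
    """Position operator q = (a + a^dagger)/sqrt(2) on an n-level ladder."""
    off = np.sqrt((np.arange(1, n)) / 2.0)
    return sp.diags([off, off], [1, -1], shape=(n, n), format="csr")


def mode_q_operator(basis: BasisSpec, k: int) -> sp.csr_matrix:
    """q_k embedded in the full nuclear product space (no electronic factor)."""
    levels = basis.levels
    op = sp.identity(1, format="csr")
    for j, n in enumerate(levels):
        factor = _ladder_q(n) if j == k else sp.identity(n, format="csr")
        op = sp.kron(op, factor, format="csr")
    return op


def _harmonic_diagonal(model: VibronicModel, basis: BasisSpec) -> np.ndarray:
    """sum_k w_k (n_k + 1/2) over the nuclear product basis, eV."""
    omega_ev = model.omega_ev
    diag = np.zeros(basis.dim_nuclear)
    if model.n_modes == 0:
        return diag
    grids = np.meshgrid(*[np.arange(n) for n in basis.levels], indexing="ij")
    for k, g in enumerate(grids):
        diag += omega_ev[k] * (g.ravel() + 0.5)
    return diag


def build_hamiltonian(model: VibronicModel, basis: BasisSpec) -> sp.csr_matrix:
    """Assemble the LVC Hamiltonian on the electronic (x) nuclear product space.

    Returns a real-symmetric sparse matrix in eV.  The flat index is
    ``nuclear_index * n_states + state``, nuclear occupations in C order.
    Matrix elements follow the harmonic-ladder rules: q_k couples
    occupations n <-> n+1 with amplitude sqrt((n+1)/2).
    """
    basis.check_matches(model)
    ns = model.n_states
    I_el = sp.identity(ns, format="csr")
    H_el = sp.csr_matrix(np.diag(model.E) + model.V0)
    dim_nuc = basis.dim_nuclear

    H = sp.kron(sp.identity(dim_nuc, format="csr"), H_el, format="csr")
    if model.n_modes:
        H = H + sp.kron(sp.diags(_harmonic_diagonal(model, basis)), I_el, format="csr")
        for k in range(model.n_modes):
            W = electronic_coupling_matrix(model, k)
            if np.any(W):
                H = H + sp.kron(mode_q_operator(basis, k), sp.csr_matrix(W), format="csr")
    return H.tocsr()
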