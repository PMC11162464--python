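"""Fragment Excitation Difference (FED) diabatization and CT-state descriptors.

A bichromophoric system carries two locally excited (LE) states — one per
fragment — and a charge-transfer (CT) state.  The excitation-difference
matrix Delta-x, built in the adiabatic basis, measures on which fragment the
excitation sits: diagonalizing it separates the LE states (eigenvalues near
+1 and -1) from the CT state (eigenvalue near 0).  Rotating the adiabatic
electronic Hamiltonian by the same eigenvectors yields the diabatic energies
and the static electronic couplings V; rotating the per-state gradient
vectors yields the intrastate (kappa) and interstate (lambda) coupling
tables that parametrize an LVC model.

Also provided: the coupling/gap mixing ratio |V/Delta|, the electron-hole
centroid distance of a CT state, and the 0.5 eV accessibility rule deciding
whether solvent fluctuations can pull the CT state into play.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FEDInput",
    "FEDResult",
    "ChargeSeparation",
    "DiabatizationError",
    "fed_diabatize",
    "coupling_gap_ratio",
    "eh_distance",
    "ct_accessible",
]

#: Target Delta-x eigenvalues and their diabatic character.
_TARGETS = {1.0: "LE+", -1.0: "LE-", 0.0: "CT"}


class DiabatizationError(ValueError):
    pass


def _sym_array(x, name):
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DiabatizationError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-12):
        raise DiabatizationError(f"{name} must be symmetric")
    if not np.all(np.isfinite(a)):
        raise DiabatizationError(f"{name} contains non-finite entries")
    return a


@dataclass(frozen=True)
class FEDInput:
    """Adiabatic-basis input to the FED transformation.

    ``H_ad``: adiabatic electronic Hamiltonian in eV (diagonal for true
    adiabatic states, but any symmetric matrix is accepted).
    ``delta_x``: excitation-difference matrix (dimensionless, symmetric).
    ``gradients``: optional per-adiabatic-state gradient vectors, eV,
    shape (n_states, n_modes); each mode's gradient is diagonal in the
    adiabatic basis.
    """

    H_ad: np.ndarray
    delta_x: np.ndarray
    gradients: Optional[np.ndarray] = None

    def __post_init__(self):
        H = _sym_array(self.H_ad, "H_ad")
        dx = _sym_array(self.delta_x, "delta_x")
        if H.shape != dx.shape:
            raise DiabatizationError("H_ad and delta_x must share a dimension")
        object.__setattr__(self, "H_ad", H)
        object.__setattr__(self, "delta_x", dx)
        if self.gradients is not None:
            g = np.asarray(self.gradients, dtype=float)
            if g.ndim != 2 or g.shape[0] != H.shape[0]:
                raise DiabatizationError(
                    f"gradients must have shape (n_states, n_modes), got {g.shape}")
            object.__setattr__(self, "gradients", g)


@dataclass(frozen=True)
class FEDResult:
    """Diabatic picture produced by the FED transformation.

    ``U`` is orthogonal; ``H_dia = U.T @ H_ad @ U`` shares the adiabatic
    spectrum.  ``labels[i]`` is "LE+", "LE-" or "CT" according to the
    Delta-x eigenvalue of column i.  If gradients were supplied, ``kappa``
    (n_states, n_modes) and ``lam`` (n_states, n_states, n_modes) hold the
    rotated intrastate and interstate coupling tables.
    """

    U: np.ndarray
    H_dia: np.ndarray
    eigenvalues: np.ndarray
    labels: tuple
    kappa: Optional[np.ndarray] = None
    lam: Optional[np.ndarray] = None

    @property
    def diabatic_energies(self) -> np.ndarray:
        return np.diag(self.H_dia)

    @property
    def couplings(self) -> np.ndarray:
        """Off-diagonal electronic couplings V (eV)."""
        V = self.H_dia.copy()
        V[np.diag_indices_from(V)] = 0.0
        return V

    def ct_eigenvalue(self) -> float:
        """The Delta-x eigenvalue of the state labelled CT."""
        try:
            i = self.labels.index("CT")
        except ValueError:
            raise DiabatizationError("no state was labelled CT") from None
        return float(self.eigenvalues[i])


@dataclass(frozen=True)
class ChargeSeparation:
    """Hole/electron charge centroids (Cartesian, Angstrom) of a CT state."""

    hole: np.ndarray
    electron: np.ndarray

    def __post_init__(self):
        for name in ("hole", "electron"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} centroid must be a finite 3-vector")
            object.__setattr__(self, name, v)

    @property
    def d_eh(self) -> float:
        return eh_distance(self.hole, self.electron)


def fed_diabatize(inp: FEDInput, eigenvalue_tol: float = 0.2) -> FEDResult:
    """Diagonalize Delta-x and rotate the Hamiltonian (and gradients) into
    the diabatic basis.

    Eigenvalues are matched to the targets {+1, -1, 0}; one farther than
    ``eigenvalue_tol`` from every target means the states mix LE and CT
    character and the assignment is refused.  Degenerate Delta-x eigenvalues
    make the eigenvectors arbitrary within the degenerate block and also
    raise.  Gauge fixing: columns ordered by descending eigenvalue, sign set
    so each column's largest-magnitude component is positive.
    """
    dx = inp.delta_x
    evals, evecs = np.linalg.eigh(dx)
    order = np.argsort(-evals)
    evals = evals[order]
    U = evecs[:, order]
    if dx.shape[0] > 1 and np.min(np.abs(np.diff(evals))) < 1e-8:
        raise DiabatizationError(
            "degenerate delta_x eigenvalues: diabatic characters cannot be "
            "separated automatically; disambiguate manually")
    for c in range(U.shape[1]):
        pivot = np.argmax(np.abs(U[:, c]))
        if U[pivot, c] < 0:
            U[:, c] = -U[:, c]

    labels = []
    for ev in evals:
        dists = {t: abs(ev - t) for t in _TARGETS}
        target, d = min(dists.items(), key=lambda kv: kv[1])
        if d > eigenvalue_tol:
            raise DiabatizationError(
                f"ambiguous diabatic character: eigenvalue {ev:.4f} is farther "
                f"than {eigenvalue_tol} from every target in {{+1, -1, 0}}")
        labels.append(_TARGETS[target])

    H_dia = U.T @ inp.H_ad @ U
    kappa = lam = None
    if inp.gradients is not None:
        n, nm = inp.gradients.shape
        kappa = np.empty((n, nm))
        lam = np.empty((n, n, nm))
        for k in range(nm):
            Gk = U.T @ np.diag(inp.gradients[:, k]) @ U
            kappa[:, k] = np.diag(Gk)
            lam[:, :, k] = Gk - np.diag(np.diag(Gk))
    return FEDResult(U, H_dia, evals, tuple(labels), kappa, lam)


def coupling_gap_ratio(V: Sequence[float], gap: Sequence[float]) -> float:
    """Mean electronic-coupling-to-energy-gap ratio |V/Delta| over an
    ensemble of conformations; a value approaching ~0.27 signals strong
    LE/CT wavefunction mixing in the Franck-Condon region."""
    V = np.asarray(V, dtype=float)
    gap = np.asarray(gap, dtype=float)
    if V.shape != gap.shape:
        raise ValueError("V and gap must have equal lengths")
    if np.any(gap == 0.0):
        raise ZeroDivisionError("zero energy gap: |V/Delta| undefined")
    return float(np.mean(np.abs(V / gap)))


def eh_distance(hole_centroid, electron_centroid) -> float:
    """Euclidean distance (Angstrom) between hole and electron centroids."""
    h = np.asarray(hole_centroid, dtype=float)
    e = np.asarray(electron_centroid, dtype=float)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(e))):
        raise ValueError("centroids must be finite")
    return float(np.linalg.norm(h - e))


def ct_accessible(E_CT_gas: float, E_La: float, threshold: float = 0.5) -> bool:
    """Whether solvent fluctuations can bring the CT state into play.

    A gas-phase CT state more than ``threshold`` eV above the bright donor
    state stays out of reach of the solvent-induced energy fluctuations and
    cannot act as a doorway for the transfer.
    """
    if not (np.isfinite(E_CT_gas) and np.isfinite(E_La)):
        raise ValueError("energies must be finite")
    return bool(E_CT_gas - E_La <= threshold)
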