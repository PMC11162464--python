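"""Photoactive-mode ranking, selection and system/bath partition.

Reduced-dimensional wavepacket dynamics needs the vibrational modes that
actually move population: for each mode the activity score is the largest
Franck-Condon gradient or interstate coupling it carries, modes are sorted
by that score, the top ``n_select`` are kept, and the strongest
``n_system`` of those form the "system" tier (deep primitive basis) while
the rest form the "bath" tier (shallow basis).  Discarded modes have
negligible gradients and couplings and do not promote transfer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ModeRanking", "rank_modes", "select_and_partition"]


@dataclass(frozen=True)
class ModeRanking:
    """Per-mode activity scores and (optionally) the selection outcome.

    ``rank`` is the 0-based position in descending-score order (ties broken
    by ascending mode index).  ``tier`` entries are "system", "bath" or
    "discarded"; before selection all modes are "discarded" and ``selected``
    is all-False.
    """

    scores: np.ndarray
    rank: np.ndarray
    selected: np.ndarray
    tier: tuple
    frequencies_cm1: Optional[np.ndarray] = None

    def __post_init__(self):
        n = self.scores.shape[0]
        if sorted(self.rank.tolist()) != list(range(n)):
            raise ValueError("rank must be a permutation of 0..n-1")
        if self.selected.sum() != sum(t != "discarded" for t in self.tier):
            raise ValueError("selected flags inconsistent with tiers")

    @property
    def n_modes(self) -> int:
        return self.scores.shape[0]

    def order(self) -> np.ndarray:
        """Mode indices in descending-score order."""
        return np.argsort(self.rank)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "mode_index": np.arange(self.n_modes),
            "score_eV": self.scores,
            "rank": self.rank,
            "tier": list(self.tier),
        })
        if self.frequencies_cm1 is not None:
            df.insert(1, "frequency_cm1", self.frequencies_cm1)
        return df


def rank_modes(kappa_table: np.ndarray, lambda_table: np.ndarray,
               frequencies_cm1: Optional[np.ndarray] = None) -> ModeRanking:
    """Score every mode by its strongest Franck-Condon activity.

    score(k) = max over states i and pairs (i, j) of {|kappa_ik|, |lambda_ijk|}.
    """
    kappa = np.asarray(kappa_table, dtype=float)
    lam = np.asarray(lambda_table, dtype=float)
    if kappa.ndim != 2 or lam.ndim != 3:
        raise ValueError("kappa_table must be (states, modes); lambda_table (states, states, modes)")
    if kappa.shape[1] != lam.shape[2] or lam.shape[0] != lam.shape[1]:
        raise ValueError(
            f"mismatched mode axes: kappa has {kappa.shape[1]} modes, "
            f"lambda has {lam.shape[2]}")
    scores = np.maximum(np.abs(kappa).max(axis=0), np.abs(lam).max(axis=(0, 1)))
    rank = np.empty(scores.shape[0], dtype=int)
    rank[np.argsort(-scores, kind="stable")] = np.arange(scores.shape[0])
    return ModeRanking(
        scores=scores,
        rank=rank,
        selected=np.zeros(scores.shape[0], dtype=bool),
        tier=tuple("discarded" for _ in scores),
        frequencies_cm1=None if frequencies_cm1 is None
        else np.asarray(frequencies_cm1, dtype=float),
    )


def select_and_partition(ranking: ModeRanking, n_select: int, n_system: int,
                         score_floor: Optional[float] = None) -> ModeRanking:
    """Keep the top ``n_select`` modes; tier the top ``n_system`` as system.

    Selection is count-driven; ``score_floor`` optionally drops selected
    modes whose score falls below it (the typical floor for inactive modes
    is around 0.02 eV).  Ties are broken by ascending mode index.
    """
    n = ranking.n_modes
    if not (0 < n_system <= n_select <= n):
        raise ValueError(
            f"need 0 < n_system <= n_select <= n_modes, got "
            f"n_system={n_system}, n_select={n_select}, n_modes={n}")
    order = ranking.order()
    tier = ["discarded"] * n
    selected = np.zeros(n, dtype=bool)
    for pos, k in enumerate(order[:n_select]):
        if score_floor is not None and ranking.scores[k] < score_floor:
            continue
        selected[k] = True
        tier[k] = "system" if pos < n_system else "bath"
    return ModeRanking(
        scores=ranking.scores,
        rank=ranking.rank,
        selected=selected,
        tier=tuple(tier),
        frequencies_cm1=ranking.frequencies_cm1,
    )
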