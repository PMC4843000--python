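"""Binomial model of shared synaptic input between pairs of granule cells.

Two granule cells sample synapses at random from a common pool of ``n_inf``
potential perforant-path fibres.  If cell A carries ``n_total_a`` synapses and
cell B ``n_total_b``, random sampling implies an expected number of fibres
innervating both cells of

    N_shared = n_total_a * n_total_b / n_inf

with the remainder of each cell's synapses arising from fibres unique to that
cell (independent inputs).  When focal stimulation activates each fibre
independently with probability ``p_eff``, the probability that *both* cells
receive at least one active input (an evoked-EPSC "success" in both cells of a
paired recording) has the closed form

    P_overlap = 1 - (1 - P_both_ind) * (1 - p_eff)**n_shared

where ``P_both_ind`` is the probability that both cells are driven through
their independent fibres alone.  This module implements those relations; the
Monte Carlo fit (:mod:`dentate.fit`) inverts them against paired-recording
overlap curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FiberPool",
    "CellSampling",
    "PairConnectivity",
    "OverlapProbabilities",
    "StimulusDesign",
    "round_half_up",
    "expected_shared",
    "expected_independent",
    "make_pair",
    "p_overlap",
    "p_overlap_value",
    "overlap_curve",
]


def round_half_up(x: float | np.ndarray) -> int | np.ndarray:
    """Round to the nearest integer, ties away from zero upward (0.5 -> 1)."""
    out = np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)
    if np.ndim(x) == 0:
        return int(out)
    return out


@dataclass(frozen=True)
class FiberPool:
    """Pool of potential input fibres available to a projection (N_inf)."""

    n_inf: int

    def __post_init__(self) -> None:
        if self.n_inf < 1:
            raise ValueError(f"n_inf must be >= 1, got {self.n_inf}")


@dataclass(frozen=True)
class CellSampling:
    """Number of functional synapses on one cell (N_total, one fibre each)."""

    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError(f"n_total must be >= 0, got {self.n_total}")


@dataclass(frozen=True)
class PairConnectivity:
    """Integer fibre counts for one recorded pair.

    ``n_shared`` fibres innervate both cells; ``n_ind_a`` / ``n_ind_b`` are
    unique to each cell.
    """

    n_shared: int
    n_ind_a: int
    n_ind_b: int

    def __post_init__(self) -> None:
        for name in ("n_shared", "n_ind_a", "n_ind_b"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def n_total_a(self) -> int:
        return self.n_shared + self.n_ind_a

    @property
    def n_total_b(self) -> int:
        return self.n_shared + self.n_ind_b


@dataclass(frozen=True)
class OverlapProbabilities:
    """Intermediate and final probabilities of the overlap computation."""

    p_not_shared: float
    p_not_ind_a: float
    p_not_ind_b: float
    p_both_ind: float
    p_not_both_ind: float
    p_overlap: float


@dataclass(frozen=True)
class StimulusDesign:
    """Stimulation protocol: minimal activation probability and its multiples.

    ``p_min`` is the fibre-activation probability at the minimal stimulation
    intensity; larger stimuli activate fibres at ``min(1, m * p_min)`` for
    each multiple ``m``.
    """

    p_min: float
    multiples: tuple[float, ...]

    def __init__(self, p_min: float, multiples: Sequence[float]) -> None:
        multiples = tuple(float(m) for m in multiples)
        if not 0.0 < p_min <= 1.0:
            raise ValueError(f"p_min must be in (0, 1], got {p_min}")
        if len(multiples) == 0:
            raise ValueError("multiples must be non-empty")
        if any(m <= 0 for m in multiples):
            raise ValueError("multiples must be positive")
        if any(b <= a for a, b in zip(multiples, multiples[1:])):
            raise ValueError("multiples must be strictly increasing")
        object.__setattr__(self, "p_min", float(p_min))
        object.__setattr__(self, "multiples", multiples)

    def effective_p(self) -> np.ndarray:
        """Per-multiple activation probability, capped at 1."""
        return np.minimum(1.0, np.asarray(self.multiples) * self.p_min)


def expected_shared(n_total_a: int, n_total_b: int, n_inf: int) -> float:
    """Expected number of fibres innervating both cells of a pair.

    Under uniform random sampling of ``n_inf`` fibres, the expected overlap is
    the product of the two sampling densities times the pool size:
    ``n_total_a * n_total_b / n_inf``.  Symmetric in the two cells.
    """
    if n_inf < 1:
        raise ValueError(f"n_inf must be >= 1, got {n_inf}")
    for name, n in (("n_total_a", n_total_a), ("n_total_b", n_total_b)):
        if not 0 <= n <= n_inf:
            raise ValueError(f"{name}={n} must be in [0, n_inf={n_inf}]")
    return n_total_a * n_total_b / n_inf


def expected_independent(n_total: int, n_shared: float) -> float:
    """Number of fibres unique to one cell: ``n_total - n_shared``."""
    if n_shared > n_total:
        raise ValueError(
            f"n_shared={n_shared} cannot exceed n_total={n_total}"
        )
    return n_total - n_shared


def make_pair(n_total_a: int, n_total_b: int, n_inf: int) -> PairConnectivity:
    """Integerized pair connectivity for two cells sampling one fibre pool.

    The expected shared count is rounded half-up; independent counts are the
    per-cell remainders, clamped at zero so a cell never loses fibres to
    rounding.
    """
    shared = round_half_up(expected_shared(n_total_a, n_total_b, n_inf))
    return PairConnectivity(
        n_shared=shared,
        n_ind_a=max(n_total_a - shared, 0),
        n_ind_b=max(n_total_b - shared, 0),
    )


def p_overlap_value(
    n_shared: np.ndarray | int,
    n_ind_a: np.ndarray | int,
    n_ind_b: np.ndarray | int,
    p_eff: np.ndarray | float,
) -> np.ndarray | float:
    """Probability both cells receive >= 1 active fibre (vectorized).

    Broadcasts over all arguments; used in bulk by the Monte Carlo fit.
    """
    p_eff = np.asarray(p_eff, dtype=float)
    if np.any(p_eff < 0) or np.any(p_eff > 1):
        raise ValueError("p_eff must be in [0, 1]")
    q = 1.0 - p_eff
    p_not_shared = q ** np.asarray(n_shared)
    p_both_ind = (1.0 - q ** np.asarray(n_ind_a)) * (1.0 - q ** np.asarray(n_ind_b))
    out = 1.0 - (1.0 - p_both_ind) * p_not_shared
    return out


def p_overlap(pair: PairConnectivity, p_eff: float) -> OverlapProbabilities:
    """Full decomposition of the joint-success probability for one pair."""
    if not 0.0 <= p_eff <= 1.0:
        raise ValueError(f"p_eff must be in [0, 1], got {p_eff}")
    q = 1.0 - p_eff
    p_not_shared = q**pair.n_shared
    p_not_ind_a = q**pair.n_ind_a
    p_not_ind_b = q**pair.n_ind_b
    p_both_ind = (1.0 - p_not_ind_a) * (1.0 - p_not_ind_b)
    p_not_both_ind = 1.0 - p_both_ind
    return OverlapProbabilities(
        p_not_shared=p_not_shared,
        p_not_ind_a=p_not_ind_a,
        p_not_ind_b=p_not_ind_b,
        p_both_ind=p_both_ind,
        p_not_both_ind=p_not_both_ind,
        p_overlap=1.0 - p_not_both_ind * p_not_shared,
    )


def overlap_curve(pair: PairConnectivity, design: StimulusDesign) -> pd.DataFrame:
    """Predicted joint-success probability at each stimulus multiple.

    Returns a frame with columns ``multiple``, ``p_eff``, ``p_overlap`` —
    the serialization contract for predicted overlap curves.
    """
    p_eff = design.effective_p()
    values = p_overlap_value(pair.n_shared, pair.n_ind_a, pair.n_ind_b, p_eff)
    return pd.DataFrame(
        {
            "multiple": list(design.multiples),
            "p_eff": p_eff,
            "p_overlap": np.atleast_1d(values),
        }
    )
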