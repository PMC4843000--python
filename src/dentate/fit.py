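"""Monte Carlo least-squares fit of pair-overlap curves.

The free parameters are the minimal fibre-activation probability ``p_min``
and the mature cell's independent and shared input counts
``(n_ind_mature, n_shared_mature)``.  Candidates are drawn uniformly at
random (p continuous, counts integer), candidates with
``n_ind > max_ind_to_shared * n_shared`` are rejected, and the survivors are
scored by the summed squared error between the closed-form overlap curve and
the measured fraction of simultaneous successes, accumulated over all
supplied datasets (mature-mature, mature-immature, immature-immature pairs).
The immature cell's synapse count is tied to the mature count through a fixed
amplitude ratio (default 0.35), so a single candidate determines all three
pair kinds.

There is no gradient refinement: the binomial overlap relation is fit by pure
random search, and the full ranked candidate table is retained so that the
flatness of the error landscape can be inspected (top-20% summary).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .overlap import (
    PairConnectivity,
    StimulusDesign,
    overlap_curve,
    p_overlap_value,
    round_half_up,
)

__all__ = [
    "PAIR_KINDS",
    "SearchSpace",
    "ModelConstraints",
    "OverlapDataset",
    "FitResult",
    "DerivedConnectivity",
    "SearchResult",
    "squared_error",
    "candidate_to_pairs",
    "run_search",
    "derive_quantities",
    "MonteCarloOverlapFitter",
]

PAIR_KINDS = ("mature_mature", "mature_immature", "immature_immature")

DATASET_COLUMNS = ["pair_kind", "multiple", "fraction_success", "n_trials"]


@dataclass(frozen=True)
class SearchSpace:
    """Uniform sampling ranges for the three free parameters."""

    p_range: tuple[float, float] = (0.001, 0.005)
    n_ind_range: tuple[int, int] = (100, 500)
    n_shared_range: tuple[int, int] = (20, 100)
    n_samples: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_range", "n_ind_range", "n_shared_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high, got ({lo}, {hi})")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class ModelConstraints:
    """Hard constraints linking the immature cell to the mature candidate.

    ``young_ratio`` is the immature/mature synapse-count ratio (measured as a
    constant EPSC-amplitude ratio, default 0.35); ``max_ind_to_shared`` caps
    how many independent inputs a candidate may carry per shared input.
    """

    young_ratio: float = 0.35
    max_ind_to_shared: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.young_ratio <= 1.0:
            raise ValueError(f"young_ratio must be in (0, 1], got {self.young_ratio}")
        if self.max_ind_to_shared <= 0:
            raise ValueError("max_ind_to_shared must be positive")


@dataclass(frozen=True)
class OverlapDataset:
    """Measured (or simulated) simultaneous-success fractions for one pair kind."""

    pair_kind: str
    multiples: tuple[float, ...]
    fraction_success: tuple[float, ...]
    n_trials: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.pair_kind not in PAIR_KINDS:
            raise ValueError(
                f"pair_kind must be one of {PAIR_KINDS}, got {self.pair_kind!r}"
            )
        if not (
            len(self.multiples) == len(self.fraction_success) == len(self.n_trials)
        ):
            raise ValueError("multiples, fraction_success, n_trials lengths differ")
        if len(self.multiples) == 0:
            raise ValueError("dataset has no points")
        if any(b <= a for a, b in zip(self.multiples, self.multiples[1:])):
            raise ValueError("multiples must be strictly increasing")
        if any(not 0.0 <= f <= 1.0 for f in self.fraction_success):
            raise ValueError("fraction_success values must be in [0, 1]")
        if any(k < 1 for k in self.n_trials):
            raise ValueError("n_trials must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_kind": self.pair_kind,
                "multiple": self.multiples,
                "fraction_success": self.fraction_success,
                "n_trials": self.n_trials,
            }
        )

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> list["OverlapDataset"]:
        """Split a tidy frame (columns: pair_kind, multiple, fraction_success,
        n_trials) into one dataset per pair kind."""
        missing = set(DATASET_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"dataset frame missing columns: {sorted(missing)}")
        out = []
        for kind, grp in frame.groupby("pair_kind", sort=False):
            grp = grp.sort_values("multiple")
            out.append(
                OverlapDataset(
                    pair_kind=str(kind),
                    multiples=tuple(float(m) for m in grp["multiple"]),
                    fraction_success=tuple(float(f) for f in grp["fraction_success"]),
                    n_trials=tuple(int(k) for k in grp["n_trials"]),
                )
            )
        return out


@dataclass(frozen=True)
class FitResult:
    """One scored, constraint-satisfying parameter triple."""

    p_min: float
    n_ind_mature: int
    n_shared_mature: int
    error: float
    percentile: float

    @property
    def n_total_mature(self) -> int:
        return self.n_ind_mature + self.n_shared_mature


@dataclass(frozen=True)
class DerivedConnectivity:
    """Connectivity counts implied by a fit: pool size and immature analogues."""

    n_total_mature: int
    n_inf: int
    n_total_young: int
    n_shared_young: int
    n_ind_young: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class SearchResult:
    """Ranked Monte Carlo fits plus the selected best candidate."""

    results: pd.DataFrame  # ranked: p_min, n_ind, n_shared, n_total, error, percentile
    best: FitResult
    summary: pd.DataFrame  # top-20% percentile rows
    n_sampled: int
    n_accepted: int


def squared_error(predicted: pd.DataFrame, observed: OverlapDataset) -> float:
    """Summed squared residual between a predicted curve and measured fractions.

    Both sides are on the 0-1 probability scale; the curves must be evaluated
    at identical stimulus multiples.  Errors from several datasets accumulate
    by plain summation.
    """
    pred_m = np.asarray(predicted["multiple"], dtype=float)
    obs_m = np.asarray(observed.multiples, dtype=float)
    if pred_m.shape != obs_m.shape or not np.allclose(pred_m, obs_m):
        raise ValueError("predicted and observed curves have mismatched multiples")
    resid = np.asarray(predicted["p_overlap"], dtype=float) - np.asarray(
        observed.fraction_success, dtype=float
    )
    return float(np.sum(resid**2))


def candidate_to_pairs(
    p_min: float,
    n_ind_mature: int,
    n_shared_mature: int,
    constraints: ModelConstraints,
    multiples: Sequence[float] = tuple(range(1, 11)),
) -> Mapping[str, tuple[PairConnectivity, StimulusDesign]]:
    """Expand one candidate into the three pair kinds it predicts.

    The mature pair is ``(n_shared, n_ind, n_ind)`` directly; the implied
    fibre pool is ``n_inf = round(n_total^2 / n_shared)`` and the immature
    synapse count is ``round(young_ratio * n_total)``.  Mixed and
    immature-immature pairs follow from random sampling of the same pool.
    """
    if n_shared_mature == 0:
        raise ValueError("n_shared_mature must be positive (fibre pool undefined)")
    design = StimulusDesign(p_min, multiples)
    n_total = n_ind_mature + n_shared_mature
    n_inf = round_half_up(n_total**2 / n_shared_mature)
    n_young = round_half_up(constraints.young_ratio * n_total)
    mature = PairConnectivity(n_shared_mature, n_ind_mature, n_ind_mature)
    shared_mi = round_half_up(n_total * n_young / n_inf)
    mixed = PairConnectivity(
        shared_mi, max(n_total - shared_mi, 0), max(n_young - shared_mi, 0)
    )
    shared_yy = round_half_up(n_young**2 / n_inf)
    young = PairConnectivity(
        shared_yy, max(n_young - shared_yy, 0), max(n_young - shared_yy, 0)
    )
    return {
        "mature_mature": (mature, design),
        "mature_immature": (mixed, design),
        "immature_immature": (young, design),
    }


def derive_quantities(
    fit: FitResult | tuple[int, int], constraints: ModelConstraints | None = None
) -> DerivedConnectivity:
    """Connectivity counts implied by a fitted ``(n_ind, n_shared)`` pair.

    ``n_total = n_ind + n_shared``; the fibre pool follows from inverting the
    sampling-density relation, ``n_inf = round(n_total^2 / n_shared)``; the
    immature counts scale by the amplitude ratio and re-apply the same
    relation against the common pool.
    """
    constraints = constraints or ModelConstraints()
    if isinstance(fit, tuple):
        n_ind, n_shared = fit
    else:
        n_ind, n_shared = fit.n_ind_mature, fit.n_shared_mature
    if n_shared == 0:
        raise ValueError("n_shared must be positive (fibre pool undefined)")
    n_total = n_ind + n_shared
    n_inf = round_half_up(n_total**2 / n_shared)
    n_young = round_half_up(constraints.young_ratio * n_total)
    n_shared_young = round_half_up(n_young**2 / n_inf)
    return DerivedConnectivity(
        n_total_mature=n_total,
        n_inf=n_inf,
        n_total_young=n_young,
        n_shared_young=n_shared_young,
        n_ind_young=n_young - n_shared_young,
    )


def _predicted_fractions(
    p: np.ndarray,
    n_ind: np.ndarray,
    n_shared: np.ndarray,
    dataset: OverlapDataset,
    constraints: ModelConstraints,
) -> np.ndarray:
    """Vectorized overlap prediction, candidates x multiples, for one kind."""
    n_total = n_ind + n_shared
    n_inf = round_half_up(n_total.astype(float) ** 2 / n_shared)
    n_young = round_half_up(constraints.young_ratio * n_total)
    if dataset.pair_kind == "mature_mature":
        ns, na, nb = n_shared, n_ind, n_ind
    elif dataset.pair_kind == "mature_immature":
        ns = round_half_up(n_total.astype(float) * n_young / n_inf)
        na = np.maximum(n_total - ns, 0)
        nb = np.maximum(n_young - ns, 0)
    else:  # immature_immature
        ns = round_half_up(n_young.astype(float) ** 2 / n_inf)
        na = nb = np.maximum(n_young - ns, 0)
    p_eff = np.minimum(1.0, np.outer(p, np.asarray(dataset.multiples, dtype=float)))
    return p_overlap_value(ns[:, None], na[:, None], nb[:, None], p_eff)


def run_search(
    space: SearchSpace,
    datasets: Sequence[OverlapDataset],
    constraints: ModelConstraints | None = None,
) -> SearchResult:
    """Score ``space.n_samples`` random candidates against the datasets.

    Candidates violating ``n_ind <= max_ind_to_shared * n_shared`` are
    discarded before scoring.  Returns every accepted candidate ranked by
    cumulative squared error, the best fit, and a top-20% summary table
    (per-percentile parameter rows).  Deterministic given ``space.seed``.
    """
    constraints = constraints or ModelConstraints()
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    rng = np.random.default_rng(space.seed)
    p = rng.uniform(*space.p_range, size=space.n_samples)
    n_ind = rng.integers(
        space.n_ind_range[0], space.n_ind_range[1], size=space.n_samples, endpoint=True
    )
    n_shared = rng.integers(
        space.n_shared_range[0],
        space.n_shared_range[1],
        size=space.n_samples,
        endpoint=True,
    )
    keep = n_ind <= constraints.max_ind_to_shared * n_shared
    if not np.any(keep):
        raise ValueError(
            "no sampled candidate satisfies n_ind <= "
            f"{constraints.max_ind_to_shared} * n_shared"
        )
    p, n_ind, n_shared = p[keep], n_ind[keep], n_shared[keep]

    error = np.zeros(p.shape[0])
    for ds in datasets:
        pred = _predicted_fractions(p, n_ind, n_shared, ds, constraints)
        obs = np.asarray(ds.fraction_success, dtype=float)
        error += np.sum((pred - obs[None, :]) ** 2, axis=1)

    order = np.argsort(error, kind="stable")
    n_acc = order.size
    results = pd.DataFrame(
        {
            "p_min": p[order],
            "n_ind": n_ind[order],
            "n_shared": n_shared[order],
            "n_total": (n_ind + n_shared)[order],
            "error": error[order],
            "percentile": 100.0 * np.arange(n_acc) / max(n_acc - 1, 1),
        }
    )
    top = results.iloc[0]
    best = FitResult(
        p_min=float(top["p_min"]),
        n_ind_mature=int(top["n_ind"]),
        n_shared_mature=int(top["n_shared"]),
        error=float(top["error"]),
        percentile=0.0,
    )
    summary = _top_fits_summary(results)
    return SearchResult(
        results=results,
        best=best,
        summary=summary,
        n_sampled=space.n_samples,
        n_accepted=n_acc,
    )


def _top_fits_summary(
    results: pd.DataFrame,
    percentiles: Sequence[float] = (0, 1, 2, 5, 10, 15, 20),
) -> pd.DataFrame:
    """Parameter rows at fixed error percentiles within the accepted fits.

    Emulates a progressive sample through the top 20% of random fits: each row
    is the candidate ranked at that percentile of the error distribution.
    """
    n = len(results)
    rows = []
    for q in percentiles:
        idx = min(int(round(q / 100.0 * (n - 1))), n - 1)
        r = results.iloc[idx]
        rows.append(
            {
                "percentile": float(q),
                "p_min": float(r["p_min"]),
                "n_ind": int(r["n_ind"]),
                "n_shared": int(r["n_shared"]),
                "n_total": int(r["n_total"]),
                "error": float(r["error"]),
            }
        )
    return pd.DataFrame(rows)


class MonteCarloOverlapFitter(BaseEstimator):
    """Random-search estimator of pair connectivity from overlap curves.

    Scikit-learn style estimator: hyperparameters are the sampling ranges and
    constraints; :meth:`fit` takes overlap datasets (a list of
    :class:`OverlapDataset` or a tidy frame with columns ``pair_kind,
    multiple, fraction_success, n_trials``) and exposes the selected
    parameters as fitted attributes.

    Parameters
    ----------
    n_samples
        Number of random candidates to draw (default 250,000).
    p_range, n_ind_range, n_shared_range
        Uniform sampling ranges for the minimal activation probability and
        the mature independent / shared input counts.
    young_ratio
        Immature/mature synapse-count ratio tying the immature datasets to
        the mature candidate (default 0.35).
    max_ind_to_shared
        Rejection bound ``n_ind <= max_ind_to_shared * n_shared`` (default 5).
    random_state
        Seed for the candidate draw.

    Attributes
    ----------
    p_min_, n_ind_mature_, n_shared_mature_, error_
        Parameters and cumulative squared error of the best fit.
    best_ : FitResult
    derived_ : DerivedConnectivity
        Pool size and immature counts implied by the best fit.
    search_result_ : SearchResult
        Full ranked candidate table and top-20% summary.
    """

    def __init__(
        self,
        n_samples: int = 250_000,
        p_range: tuple[float, float] = (0.001, 0.005),
        n_ind_range: tuple[int, int] = (100, 500),
        n_shared_range: tuple[int, int] = (20, 100),
        young_ratio: float = 0.35,
        max_ind_to_shared: float = 5.0,
        random_state: int = 0,
    ) -> None:
        self.n_samples = n_samples
        self.p_range = p_range
        self.n_ind_range = n_ind_range
        self.n_shared_range = n_shared_range
        self.young_ratio = young_ratio
        self.max_ind_to_shared = max_ind_to_shared
        self.random_state = random_state

    def _coerce_datasets(self, X) -> list[OverlapDataset]:
        if isinstance(X, pd.DataFrame):
            return OverlapDataset.from_frame(X)
        datasets = list(X)
        if not all(isinstance(d, OverlapDataset) for d in datasets):
            raise TypeError(
                "X must be a tidy DataFrame or a sequence of OverlapDataset"
            )
        return datasets

    def fit(self, X, y=None) -> "MonteCarloOverlapFitter":
        """Run the Monte Carlo search against the supplied overlap datasets."""
        datasets = self._coerce_datasets(X)
        space = SearchSpace(
            p_range=self.p_range,
            n_ind_range=self.n_ind_range,
            n_shared_range=self.n_shared_range,
            n_samples=self.n_samples,
            seed=self.random_state,
        )
        constraints = ModelConstraints(
            young_ratio=self.young_ratio,
            max_ind_to_shared=self.max_ind_to_shared,
        )
        result = run_search(space, datasets, constraints)
        self.search_result_ = result
        self.best_ = result.best
        self.p_min_ = result.best.p_min
        self.n_ind_mature_ = result.best.n_ind_mature
        self.n_shared_mature_ = result.best.n_shared_mature
        self.error_ = result.best.error
        self.derived_ = derive_quantities(result.best, constraints)
        self.constraints_ = constraints
        return self

    def predict(
        self,
        multiples: Sequence[float],
        pair_kind: str = "mature_mature",
    ) -> pd.DataFrame:
        """Predicted overlap curve of the best fit at the given multiples."""
        if not hasattr(self, "best_"):
            raise AttributeError("fit must be called before predict")
        pairs = candidate_to_pairs(
            self.p_min_,
            self.n_ind_mature_,
            self.n_shared_mature_,
            self.constraints_,
            multiples=multiples,
        )
        if pair_kind not in pairs:
            raise ValueError(f"pair_kind must be one of {PAIR_KINDS}")
        pair, design = pairs[pair_kind]
        return overlap_curve(pair, design)

    def score(self, X, y=None) -> float:
        """Negative cumulative squared error of the best fit on ``X``."""
        if not hasattr(self, "best_"):
            raise AttributeError("fit must be called before score")
        total = 0.0
        for ds in self._coerce_datasets(X):
            pred = self.predict(ds.multiples, pair_kind=ds.pair_kind)
            total += squared_error(pred, ds)
        return -total
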