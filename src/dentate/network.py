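"""Feedforward binary-threshold model of the entorhinal-cortex -> dentate circuit.

A population of granule cells (GCs), each labelled mature or immature, is
randomly wired to a smaller entorhinal cortex (EC) population: every GC-EC
edge is an independent Bernoulli draw with an age-specific connection
probability (defaults 219/1296 for mature and 77/1296 for immature cells,
from the fitted slice connectivity).  All synapses have weight 1; there is no
inhibition and no learning.  A GC fires when strictly more than a fixed
fraction (default 20%) of its synaptic inputs are co-active, so sparsely
innervated immature cells reach threshold with fewer active inputs — the
network expression of their higher intrinsic excitability.

Output similarity between random EC input patterns is the normalized dot
product (NDP, cosine similarity) of the binary GC activity vectors.  The
*dynamic range* of a network is the width of the EC-activity interval between
the first level whose mean NDP reaches 0.005 and the first reaching 0.05 —
the range of cortical drive for which outputs stay near-orthogonal.  Sweeps
over the immature fraction quantify how adult neurogenesis changes that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_rng
from .overlap import round_half_up

__all__ = [
    "NetworkConfig",
    "DGNetwork",
    "SweepConfig",
    "SweepResult",
    "build_network",
    "sample_ec_pattern",
    "propagate",
    "ndp",
    "mean_pairwise_ndp",
    "ec_sweep",
    "dynamic_range",
    "neurogenesis_sweep",
    "default_ec_levels",
    "default_ng_levels",
]

# fitted slice-connectivity defaults: synapse counts over the fibre pool
DEFAULT_CONN_MATURE = 219 / 1296
DEFAULT_CONN_IMMATURE = 77 / 1296


def default_ec_levels(step: float = 0.00025) -> tuple[float, ...]:
    """EC activity grid 0.10-0.22 inclusive (481 levels at the default step)."""
    n = int(round((0.22 - 0.10) / step))
    return tuple(np.round(0.10 + step * np.arange(n + 1), 10))


def default_ng_levels() -> tuple[float, ...]:
    """Immature-fraction grid 0-100% in 1% increments (101 levels)."""
    return tuple(np.round(np.arange(101) / 100, 10))


@dataclass(frozen=True)
class NetworkConfig:
    """Construction parameters for one random EC->GC network."""

    n_ec: int = 1300
    n_gc: int = 13000
    frac_immature: float = 0.0
    conn_prob_mature: float = DEFAULT_CONN_MATURE
    conn_prob_immature: float = DEFAULT_CONN_IMMATURE
    threshold_frac: float = 0.20
    fixed_in_degree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ec < 1 or self.n_gc < 1:
            raise ValueError("n_ec and n_gc must be >= 1")
        if not 0.0 <= self.frac_immature <= 1.0:
            raise ValueError("frac_immature must be in [0, 1]")
        for name in ("conn_prob_mature", "conn_prob_immature"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must be in (0, 1)")


@dataclass
class DGNetwork:
    """Realized binary connectivity with maturity labels and firing thresholds."""

    weights: np.ndarray  # bool, (n_gc, n_ec)
    immature: np.ndarray  # bool, (n_gc,)
    threshold_frac: float

    def __post_init__(self) -> None:
        self.in_degree = self.weights.sum(axis=1).astype(np.int64)
        # integer threshold count: active iff active_inputs > threshold_frac * k.
        # Snap near-integer products before flooring so e.g. 0.2 * 15 does not
        # land on 2.9999999999999996 and lower the threshold by one.
        t = self.threshold_frac * self.in_degree
        t = np.where(np.abs(t - np.round(t)) < 1e-9, np.round(t), t)
        self.threshold_count = np.floor(t).astype(np.int64)
        self._weights_f32 = self.weights.astype(np.float32)

    @property
    def n_gc(self) -> int:
        return self.weights.shape[0]

    @property
    def n_ec(self) -> int:
        return self.weights.shape[1]


def build_network(config: NetworkConfig) -> DGNetwork:
    """Draw a random network: independent Bernoulli edges per GC-EC pair.

    The first ``round(frac_immature * n_gc)`` GCs are immature and use the
    immature connection probability.  With ``fixed_in_degree`` every GC of an
    age instead receives exactly ``round(p * n_ec)`` inputs at random
    positions.  Deterministic given ``config.seed``.
    """
    rng = child_rng(config.seed, "build_network")
    n_imm = round_half_up(config.frac_immature * config.n_gc)
    immature = np.zeros(config.n_gc, dtype=bool)
    immature[:n_imm] = True
    probs = np.where(immature, config.conn_prob_immature, config.conn_prob_mature)
    if config.fixed_in_degree:
        weights = np.zeros((config.n_gc, config.n_ec), dtype=bool)
        for age_prob in np.unique(probs):
            rows = np.flatnonzero(probs == age_prob)
            k = round_half_up(age_prob * config.n_ec)
            if k == 0:
                continue
            for i in rows:
                weights[i, rng.choice(config.n_ec, size=k, replace=False)] = True
    else:
        weights = rng.random((config.n_gc, config.n_ec), dtype=np.float32) < probs[
            :, None
        ].astype(np.float32)
    return DGNetwork(
        weights=weights, immature=immature, threshold_frac=config.threshold_frac
    )


def sample_ec_pattern(
    n_ec: int, ec_level: float, rng: int | np.random.Generator
) -> np.ndarray:
    """Binary EC pattern with exactly ``round(ec_level * n_ec)`` active cells."""
    if not 0.0 <= ec_level <= 1.0:
        raise ValueError("ec_level must be in [0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    k = round_half_up(ec_level * n_ec)
    pattern = np.zeros(n_ec, dtype=np.int8)
    if k > 0:
        pattern[rng.choice(n_ec, size=k, replace=False)] = 1
    return pattern


def _sample_ec_patterns(
    n_ec: int, ec_level: float, n_patterns: int, rng: np.random.Generator
) -> np.ndarray:
    """Stack of EC patterns, shape (n_ec, n_patterns), fixed activity mass."""
    out = np.zeros((n_ec, n_patterns), dtype=np.float32)
    k = round_half_up(ec_level * n_ec)
    for j in range(n_patterns):
        if k > 0:
            out[rng.choice(n_ec, size=k, replace=False), j] = 1.0
    return out


def propagate(network: DGNetwork, ec: np.ndarray) -> np.ndarray:
    """Threshold propagation: GC fires iff active inputs > frac * in-degree.

    ``ec`` may be one pattern ``(n_ec,)`` or a stack ``(n_ec, n_patterns)``;
    the output has matching shape over GCs.  The comparison is strict, so a
    GC with in-degree 0 never fires.
    """
    ec = np.asarray(ec)
    if ec.shape[0] != network.n_ec:
        raise ValueError(
            f"EC pattern length {ec.shape[0]} != network n_ec {network.n_ec}"
        )
    single = ec.ndim == 1
    ec2 = ec.reshape(network.n_ec, -1).astype(np.float32)
    counts = network._weights_f32 @ ec2  # exact small-integer arithmetic
    active = counts > (network.threshold_count[:, None].astype(np.float32) + 0.5)
    out = active.astype(np.int8)
    return out[:, 0] if single else out


def ndp(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized dot product (cosine) of two binary activity vectors.

    Defined as 0 when either vector is all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("patterns have mismatched lengths")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def mean_pairwise_ndp(outputs: np.ndarray | Sequence[np.ndarray]) -> float:
    """Mean NDP over all unordered pairs of output patterns.

    ``outputs`` is a list of binary vectors or an array of shape
    ``(n_units, n_patterns)``.  Pairs involving an all-zero output contribute
    0 (they are counted, not dropped).
    """
    A = np.asarray(outputs, dtype=np.float32)
    if A.ndim != 2:
        raise ValueError("outputs must be 2-dimensional")
    if isinstance(outputs, (list, tuple)):
        A = A.T  # list of patterns -> (n_units, n_patterns)
    n_pat = A.shape[1]
    if n_pat < 2:
        raise ValueError("need at least 2 output patterns")
    G = A.T @ A
    norms = np.sqrt(np.diag(G))
    denom = np.outer(norms, norms)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, G / denom, 0.0)
    iu = np.triu_indices(n_pat, k=1)
    return float(C[iu].mean())


@dataclass(frozen=True)
class SweepConfig:
    """Grid specification for EC-activity and neurogenesis sweeps."""

    ec_levels: tuple[float, ...] = field(default_factory=default_ec_levels)
    ng_levels: tuple[float, ...] = field(default_factory=default_ng_levels)
    n_input_sets: int = 100
    n_runs: int = 5
    ndp_low: float = 0.005
    ndp_high: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ec_levels", tuple(float(v) for v in self.ec_levels))
        object.__setattr__(self, "ng_levels", tuple(float(v) for v in self.ng_levels))
        if len(self.ec_levels) == 0:
            raise ValueError("ec_levels is empty")
        if any(b <= a for a, b in zip(self.ec_levels, self.ec_levels[1:])):
            raise ValueError("ec_levels must be strictly increasing")
        if not 0.0 < self.ndp_low < self.ndp_high < 1.0:
            raise ValueError("require 0 < ndp_low < ndp_high < 1")
        if self.n_input_sets < 2:
            raise ValueError("n_input_sets must be >= 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class SweepResult:
    """NDP surface and per-run dynamic ranges of a neurogenesis sweep."""

    ndp: pd.DataFrame  # columns: ng_level, run, ec_level, mean_ndp
    ranges: pd.DataFrame  # columns: ng_level, run, dynamic_range

    def mean_ranges(self) -> pd.DataFrame:
        """Per-NG-level mean/SD of dynamic range over runs."""
        g = self.ranges.groupby("ng_level")["dynamic_range"]
        out = g.agg(["mean", "std"]).reset_index()
        out.columns = ["ng_level", "mean_range", "sd_range"]
        return out

    def summary(self) -> dict:
        """Headline numbers: optimal NG level, max range, range at NG=0, ratio."""
        m = self.mean_ranges()
        i_best = int(m["mean_range"].idxmax())
        best_ng = float(m.loc[i_best, "ng_level"])
        max_range = float(m.loc[i_best, "mean_range"])
        at_zero = m.loc[m["ng_level"] == 0.0, "mean_range"]
        range_ng0 = float(at_zero.iloc[0]) if len(at_zero) else float("nan")
        ratio = max_range / range_ng0 if range_ng0 > 0 else float("inf")
        return {
            "argmax_ng_level": best_ng,
            "max_mean_range": max_range,
            "mean_range_at_ng0": range_ng0,
            "range_ratio_vs_ng0": ratio,
        }


def ec_sweep(
    network: DGNetwork,
    ec_levels: Sequence[float],
    n_input_sets: int,
    rng: int | np.random.Generator,
) -> pd.DataFrame:
    """Mean pairwise output NDP at each EC activity level.

    At each level, ``n_input_sets`` fresh random EC patterns are propagated
    and all unordered output pairs averaged.  Returns columns ``ec_level``,
    ``mean_ndp``, ``silent_fraction`` (share of all-zero outputs).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for level in ec_levels:
        ec = _sample_ec_patterns(network.n_ec, float(level), n_input_sets, rng)
        out = propagate(network, ec)
        silent = float(np.mean(out.sum(axis=0) == 0))
        rows.append(
            {
                "ec_level": float(level),
                "mean_ndp": mean_pairwise_ndp(out),
                "silent_fraction": silent,
            }
        )
    return pd.DataFrame(rows)


def dynamic_range(
    ec_levels: Sequence[float],
    mean_ndp_values: Sequence[float],
    ndp_low: float = 0.005,
    ndp_high: float = 0.05,
) -> float:
    """Width of the EC interval between the NDP_low and NDP_high crossings.

    Scanning levels in increasing order: (first level with NDP >= high) minus
    (first level with NDP >= low).  If the low bound is never reached the
    range is 0; if only the high bound is never reached, the upper end is the
    last level swept.
    """
    levels = np.asarray(ec_levels, dtype=float)
    values = np.asarray(mean_ndp_values, dtype=float)
    if levels.size == 0:
        raise ValueError("empty NDP curve")
    if levels.shape != values.shape:
        raise ValueError("levels and NDP values have mismatched lengths")
    low_hits = np.flatnonzero(values >= ndp_low)
    if low_hits.size == 0:
        return 0.0
    lo = levels[low_hits[0]]
    high_hits = np.flatnonzero(values >= ndp_high)
    hi = levels[high_hits[0]] if high_hits.size else levels[-1]
    return float(hi - lo)


def _sweep_cell(
    base_config: NetworkConfig,
    sweep: SweepConfig,
    ng_level: float,
    run: int,
) -> tuple[pd.DataFrame, float]:
    """One (NG level, run) cell: build a fresh network, sweep EC, score range."""
    cfg = replace(
        base_config,
        frac_immature=float(ng_level),
        seed=int(
            child_rng(sweep.seed, "network", round(ng_level * 1000), run).integers(
                2**31
            )
        ),
    )
    net = build_network(cfg)
    input_rng = child_rng(sweep.seed, "inputs", round(ng_level * 1000), run)
    curve = ec_sweep(net, sweep.ec_levels, sweep.n_input_sets, input_rng)
    dr = dynamic_range(
        curve["ec_level"], curve["mean_ndp"], sweep.ndp_low, sweep.ndp_high
    )
    curve = curve.assign(ng_level=float(ng_level), run=run)
    return curve, dr


def neurogenesis_sweep(
    base_config: NetworkConfig,
    sweep: SweepConfig,
    n_jobs: int = 1,
) -> SweepResult:
    """Dynamic-range surface across immature fractions.

    For every NG level and every run, a fresh network is built (new
    connectivity draw) and swept across the EC grid; the per-run dynamic
    range is recorded.  Each (level, run) cell derives its own child seed
    from ``sweep.seed``, so results are identical regardless of execution
    order or parallelism.
    """
    cells = [(ng, run) for ng in sweep.ng_levels for run in range(sweep.n_runs)]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        outputs = Parallel(n_jobs=n_jobs)(
            delayed(_sweep_cell)(base_config, sweep, ng, run) for ng, run in cells
        )
    else:
        outputs = [_sweep_cell(base_config, sweep, ng, run) for ng, run in cells]
    curves = pd.concat([c for c, _ in outputs], ignore_index=True)
    ranges = pd.DataFrame(
        {
            "ng_level": [ng for ng, _ in cells],
            "run": [run for _, run in cells],
            "dynamic_range": [dr for _, dr in outputs],
        }
    )
    ndp_df = curves[["ng_level", "run", "ec_level", "mean_ndp", "silent_fraction"]]
    return SweepResult(ndp=ndp_df, ranges=ranges)
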