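"""Synthetic paired-recording datasets with the statistics the model assumes.

The experiments this emulates record evoked EPSCs simultaneously from two
granule cells while stepping the stimulus intensity; at each intensity the
fraction of trials with an EPSC in *both* cells ("% simultaneous success",
typically over 20 trials) measures shared innervation.  No raw dataset of this
kind is publicly deposited, so this module is the generative twin of the
closed-form overlap model: per trial, every shared and independent fibre is
active independently with probability ``min(1, m * p_min)``, a cell succeeds
when at least one of its fibres is active, and trial-to-trial variability is
exactly binomial in the trial count.

An EPSC-amplitude proxy (active fibre count x quantal size) supports the
immature/mature amplitude-ratio computation whose expectation equals the
synapse-count ratio (~0.35 for immature vs. mature cells) at every stimulus
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fit import OverlapDataset, PAIR_KINDS
from .overlap import CellSampling, PairConnectivity, StimulusDesign

__all__ = [
    "RecordingDesign",
    "simulate_pair_trials",
    "to_overlap_dataset",
    "amplitude_ratio",
]

TRIAL_COLUMNS = ["multiple", "trial", "success_a", "success_b", "active_a", "active_b"]


@dataclass(frozen=True)
class RecordingDesign:
    """Protocol for a simulated paired recording.

    Parameters
    ----------
    multiples
        Stimulus intensities as multiples of the minimal stimulation.
    n_trials_per_multiple
        Trials recorded at each intensity (experimental default 20).
    p_min
        Fibre activation probability at the minimal stimulation.
    quantal_size
        Amplitude contributed by one active fibre (arbitrary units); only the
        amplitude proxy uses it.
    """

    multiples: tuple[float, ...]
    p_min: float
    n_trials_per_multiple: int = 20
    quantal_size: float = 1.0

    def __post_init__(self) -> None:
        # delegate multiple/p_min validation to StimulusDesign
        object.__setattr__(
            self, "multiples", tuple(float(m) for m in self.multiples)
        )
        StimulusDesign(self.p_min, self.multiples)
        if self.n_trials_per_multiple < 1:
            raise ValueError("n_trials_per_multiple must be >= 1")
        if self.quantal_size <= 0:
            raise ValueError("quantal_size must be positive")

    def stimulus_design(self) -> StimulusDesign:
        return StimulusDesign(self.p_min, self.multiples)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_pair_trials(
    truth: PairConnectivity,
    design: RecordingDesign,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate per-trial paired outcomes under the fibre-activation model.

    Each shared fibre and each independent fibre is active independently with
    probability ``min(1, m * p_min)``; a cell's active-input count is its
    number of active shared plus own independent fibres, and it "succeeds"
    (shows an EPSC) when that count is at least one.

    Returns a tidy frame with columns ``multiple, trial, success_a,
    success_b, active_a, active_b``.  Deterministic given the seed.
    """
    rng = _as_rng(seed)
    p_eff = design.stimulus_design().effective_p()
    n = design.n_trials_per_multiple
    frames = []
    for m, p in zip(design.multiples, p_eff):
        shared = rng.binomial(truth.n_shared, p, size=n)
        ind_a = rng.binomial(truth.n_ind_a, p, size=n)
        ind_b = rng.binomial(truth.n_ind_b, p, size=n)
        active_a = shared + ind_a
        active_b = shared + ind_b
        frames.append(
            pd.DataFrame(
                {
                    "multiple": m,
                    "trial": np.arange(n),
                    "success_a": active_a >= 1,
                    "success_b": active_b >= 1,
                    "active_a": active_a,
                    "active_b": active_b,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def to_overlap_dataset(trials: pd.DataFrame, pair_kind: str) -> OverlapDataset:
    """Collapse trial outcomes to a % simultaneous-success dataset.

    ``fraction_success`` at each multiple is the fraction of trials in which
    both cells succeeded — the fitting target of the overlap model.
    """
    if pair_kind not in PAIR_KINDS:
        raise ValueError(f"pair_kind must be one of {PAIR_KINDS}, got {pair_kind!r}")
    if trials.empty:
        raise ValueError("trials is empty")
    both = trials["success_a"] & trials["success_b"]
    grouped = (
        trials.assign(both=both)
        .groupby("multiple", sort=True)
        .agg(fraction_success=("both", "mean"), n_trials=("both", "size"))
        .reset_index()
    )
    return OverlapDataset(
        pair_kind=pair_kind,
        multiples=tuple(grouped["multiple"]),
        fraction_success=tuple(grouped["fraction_success"]),
        n_trials=tuple(int(k) for k in grouped["n_trials"]),
    )


def amplitude_ratio(
    truth_mature: CellSampling,
    truth_young: CellSampling,
    design: RecordingDesign,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Immature/mature mean EPSC-amplitude ratio at each stimulus multiple.

    The amplitude proxy of a trial is (number of active inputs) x quantal
    size.  Because both cells sample the same activated fibre fraction, the
    expected ratio is ``n_total_young / n_total_mature`` at every multiple —
    the flat amplitude-ratio relation used to constrain the fit.  Multiples
    where the mature mean amplitude is zero yield ``NaN``.
    """
    rng = _as_rng(seed)
    p_eff = design.stimulus_design().effective_p()
    n = design.n_trials_per_multiple
    rows = []
    for m, p in zip(design.multiples, p_eff):
        act_m = rng.binomial(truth_mature.n_total, p, size=n)
        act_y = rng.binomial(truth_young.n_total, p, size=n)
        amp_m = act_m.mean() * design.quantal_size
        amp_y = act_y.mean() * design.quantal_size
        rows.append(
            {
                "multiple": m,
                "ratio": (amp_y / amp_m) if amp_m > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)
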