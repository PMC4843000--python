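"""End-to-end orchestration: simulate/load overlap data -> fit -> networks.

Stages
------
1. ``recordings`` — simulate paired-recording trials for the three pair kinds
   from a ground-truth connectivity (skipped when dataset CSVs are supplied).
2. ``fit``        — Monte Carlo search over (p_min, n_ind, n_shared).
3. ``derive``     — connectivity counts implied by the best fit (pool size,
   immature analogues); skipped stages may be replaced by a best-fit JSON.
4. ``sweep``      — neurogenesis x EC-activity dynamic-range sweep using the
   derived connection probabilities.

All artifacts are CSV/JSON; a run report records the manifest, stage timings
and the headline numbers.  A single master seed drives every stage through
derived child seeds, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import child_rng
from .fit import (
    FitResult,
    ModelConstraints,
    OverlapDataset,
    SearchSpace,
    candidate_to_pairs,
    derive_quantities,
    run_search,
)
from .network import NetworkConfig, SweepConfig, neurogenesis_sweep
from .recordings import RecordingDesign, simulate_pair_trials, to_overlap_dataset

__all__ = ["PipelineConfig", "ConfigError", "RunReport", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised with every validation violation collected, not just the first."""

    def __init__(self, problems: list[str]) -> None:
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth parameters for the synthetic-recordings stage."""

    p_min: float = 0.0039
    n_ind_mature: int = 182
    n_shared_mature: int = 37


@dataclass(frozen=True)
class PipelineConfig:
    truth: TruthConfig = field(default_factory=TruthConfig)
    recording: RecordingDesign = field(
        default_factory=lambda: RecordingDesign(
            multiples=tuple(float(m) for m in range(1, 11)), p_min=0.0039
        )
    )
    search: SearchSpace = field(default_factory=SearchSpace)
    constraints: ModelConstraints = field(default_factory=ModelConstraints)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    seed: int = 0
    n_jobs: int = 1
    data_files: tuple[str, ...] = ()  # measured dataset CSVs; skips simulation
    best_fit_file: str | None = None  # best-fit JSON; skips fitting
    skip_sweep: bool = False


@dataclass
class RunReport:
    config: dict
    timings: dict[str, float]
    manifest: list[str]
    best_fit: dict | None
    derived: dict | None
    sweep_summary: dict | None
    version: str
    python: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)


_SECTION_TYPES = {
    "truth": TruthConfig,
    "recording": RecordingDesign,
    "search": SearchSpace,
    "constraints": ModelConstraints,
    "network": NetworkConfig,
    "sweep": SweepConfig,
}

_TUPLE_FIELDS = {
    ("recording", "multiples"),
    ("search", "p_range"),
    ("search", "n_ind_range"),
    ("search", "n_shared_range"),
    ("sweep", "ec_levels"),
    ("sweep", "ng_levels"),
}


def validate_config(raw: str | Mapping[str, Any] | None) -> PipelineConfig:
    """Parse YAML/JSON text (or a mapping) into a validated PipelineConfig.

    Defaults are the values of the reference analysis (0.35 young/mature
    ratio, 20% firing threshold, 13,000 GC / 1,300 EC, NDP bounds
    0.005/0.05).  All violations across all sections are reported together.
    """
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        return PipelineConfig()
    data = yaml.safe_load(raw) if isinstance(raw, str) else dict(raw)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, Mapping):
        raise ConfigError(["top level must be a mapping of sections"])

    problems: list[str] = []
    kwargs: dict[str, Any] = {}
    known_top = set(_SECTION_TYPES) | {
        "seed",
        "n_jobs",
        "data_files",
        "best_fit_file",
        "skip_sweep",
    }
    for key in data:
        if key not in known_top:
            problems.append(f"unknown section or field: {key!r}")

    for name, cls in _SECTION_TYPES.items():
        section = data.get(name)
        if section is None:
            continue
        if not isinstance(section, Mapping):
            problems.append(f"{name}: must be a mapping")
            continue
        coerced = {}
        valid_fields = set(cls.__dataclass_fields__)
        for k, v in section.items():
            if k not in valid_fields:
                problems.append(f"{name}.{k}: unknown field")
                continue
            if (name, k) in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
                v = tuple(v)
            coerced[k] = v
        try:
            kwargs[name] = cls(**coerced)
        except (ValueError, TypeError) as exc:
            problems.append(f"{name}: {exc}")

    for scalar in ("seed", "n_jobs", "skip_sweep", "best_fit_file"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    if "data_files" in data:
        kwargs["data_files"] = tuple(str(f) for f in data["data_files"])

    if problems:
        raise ConfigError(problems)
    return PipelineConfig(**kwargs)


def _load_datasets(files: tuple[str, ...]) -> list[OverlapDataset]:
    datasets: list[OverlapDataset] = []
    for f in files:
        datasets.extend(OverlapDataset.from_frame(pd.read_csv(f)))
    return datasets


def _simulate_datasets(
    config: PipelineConfig, out: Path, manifest: list[str]
) -> list[OverlapDataset]:
    pairs = candidate_to_pairs(
        config.truth.p_min,
        config.truth.n_ind_mature,
        config.truth.n_shared_mature,
        config.constraints,
        multiples=config.recording.multiples,
    )
    datasets = []
    for kind, (pair, _) in pairs.items():
        rng = child_rng(config.seed, "recordings", kind)
        trials = simulate_pair_trials(pair, config.recording, rng)
        trials_path = out / f"trials_{kind}.csv"
        trials.to_csv(trials_path, index=False)
        manifest.append(trials_path.name)
        ds = to_overlap_dataset(trials, kind)
        datasets.append(ds)
    frame = pd.concat([d.to_frame() for d in datasets], ignore_index=True)
    ds_path = out / "overlap_datasets.csv"
    frame.to_csv(ds_path, index=False)
    manifest.append(ds_path.name)
    return datasets


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute the configured stages and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    timings: dict[str, float] = {}
    best_fit_dict: dict | None = None
    derived_dict: dict | None = None
    sweep_summary: dict | None = None

    # stage 1: datasets ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.data_files:
            datasets = _load_datasets(config.data_files)
        else:
            datasets = _simulate_datasets(config, out, manifest)
    except Exception as exc:
        raise RuntimeError(f"stage 'recordings' failed: {exc}") from exc
    timings["recordings"] = time.perf_counter() - t0

    # stage 2: fit ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.best_fit_file:
            with open(config.best_fit_file) as fh:
                loaded = json.load(fh)
            best = FitResult(
                p_min=loaded["p_min"],
                n_ind_mature=loaded["n_ind_mature"],
                n_shared_mature=loaded["n_shared_mature"],
                error=loaded.get("error", float("nan")),
                percentile=0.0,
            )
        else:
            space = SearchSpace(
                p_range=config.search.p_range,
                n_ind_range=config.search.n_ind_range,
                n_shared_range=config.search.n_shared_range,
                n_samples=config.search.n_samples,
                seed=int(child_rng(config.seed, "fit").integers(2**31)),
            )
            result = run_search(space, datasets, config.constraints)
            best = result.best
            ranked_path = out / "ranked_fits.csv"
            result.results.to_csv(ranked_path, index=False)
            manifest.append(ranked_path.name)
            summary_path = out / "top_fits_summary.csv"
            result.summary.to_csv(summary_path, index=False)
            manifest.append(summary_path.name)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    timings["fit"] = time.perf_counter() - t0

    # stage 3: derived connectivity ---------------------------------------
    t0 = time.perf_counter()
    try:
        derived = derive_quantities(best, config.constraints)
        best_fit_dict = {
            "p_min": best.p_min,
            "n_ind_mature": best.n_ind_mature,
            "n_shared_mature": best.n_shared_mature,
            "error": best.error,
        }
        derived_dict = asdict(derived)
        fit_path = out / "best_fit.json"
        fit_path.write_text(
            json.dumps({**best_fit_dict, "derived": derived_dict}, indent=2)
        )
        manifest.append(fit_path.name)
    except Exception as exc:
        raise RuntimeError(f"stage 'derive' failed: {exc}") from exc
    timings["derive"] = time.perf_counter() - t0

    # stage 4: network sweep ----------------------------------------------
    if not config.skip_sweep:
        t0 = time.perf_counter()
        try:
            net_cfg = NetworkConfig(
                n_ec=config.network.n_ec,
                n_gc=config.network.n_gc,
                frac_immature=0.0,
                conn_prob_mature=derived.n_total_mature / derived.n_inf,
                conn_prob_immature=derived.n_total_young / derived.n_inf,
                threshold_frac=config.network.threshold_frac,
                fixed_in_degree=config.network.fixed_in_degree,
            )
            sweep_cfg = SweepConfig(
                ec_levels=config.sweep.ec_levels,
                ng_levels=config.sweep.ng_levels,
                n_input_sets=config.sweep.n_input_sets,
                n_runs=config.sweep.n_runs,
                ndp_low=config.sweep.ndp_low,
                ndp_high=config.sweep.ndp_high,
                seed=int(child_rng(config.seed, "sweep").integers(2**31)),
            )
            result = neurogenesis_sweep(net_cfg, sweep_cfg, n_jobs=config.n_jobs)
            ndp_path = out / "ndp_surface.csv"
            result.ndp.to_csv(ndp_path, index=False)
            manifest.append(ndp_path.name)
            rng_path = out / "dynamic_ranges.csv"
            result.ranges.to_csv(rng_path, index=False)
            manifest.append(rng_path.name)
            sweep_summary = result.summary()
            summ_path = out / "sweep_summary.json"
            summ_path.write_text(json.dumps(sweep_summary, indent=2, default=float))
            manifest.append(summ_path.name)
        except Exception as exc:
            raise RuntimeError(f"stage 'sweep' failed: {exc}") from exc
        timings["sweep"] = time.perf_counter() - t0

    report = RunReport(
        config=_config_dict(config),
        timings=timings,
        manifest=sorted(manifest),
        best_fit=best_fit_dict,
        derived=derived_dict,
        sweep_summary=sweep_summary,
        version=__version__,
        python=platform.python_version(),
    )
    report_path = out / "run_report.json"
    report.manifest.append(report_path.name)
    report.manifest.sort()
    report_path.write_text(report.to_json())
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else str(o)))
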