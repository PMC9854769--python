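"""End-to-end pipeline runner and the MUSIC-vs-Welch runtime harness.

The benchmark compares the two estimators across trial dimensions of
62 x N (full montage) and 5 x N (lobe-reduced), sample-length buckets of
"below 40k", "40k-45k", "45k-50k" and "50k-55k", median wall-clock seconds
per estimator, and the relative optimization ``100 * (1 - t_music/t_welch)``.
Absolute times are hardware-dependent; only the relative ratio is meaningful
and only its sign is asserted anywhere.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .channel_qc import detect_corrupt_channels, qc_summary
from .emotion_classifier import TrainConfig, cross_validate
from .errors import ConfigError
from .feature_builder import FeatureConfig, build_dataset, extract_features
from .preprocessing import FilterSpec, preprocess_trial
from .synthetic_eeg import SyntheticSpec, simulate_dataset

__all__ = ["BenchReport", "benchmark_estimators", "run_pipeline",
            "DEFAULT_LENGTH_BUCKETS"]

#: (label, representative sample length) pairs for the standard trial-length buckets.
DEFAULT_LENGTH_BUCKETS: tuple[tuple[str, int], ...] = (
    ("below 40k", 38_000),
    ("40k-45k", 42_500),
    ("45k-50k", 47_500),
    ("50k-55k", 52_500),
)


@dataclass
class BenchReport:
    """Per-cell timing results; one row per (dimension, bucket, estimator)."""

    table: pd.DataFrame
    environment: str

    def optimization_table(self) -> pd.DataFrame:
        """Pivot with per-cell optimization % = 100 * (1 - t_music / t_welch)."""
        wide = self.table.pivot_table(
            index=["n_channels", "bucket"], columns="estimator",
            values="seconds", sort=False)
        wide["optimization_pct"] = 100.0 * (1.0 - wide["music"] / wide["welch"])
        return wide.reset_index()


def benchmark_estimators(
    channel_counts: tuple[int, ...] = (62, 5),
    length_buckets: tuple[tuple[str, int], ...] = DEFAULT_LENGTH_BUCKETS,
    reps: int = 3,
    seed: int = 0,
    cfg: FeatureConfig | None = None,
    fs: float = 200.0,
) -> BenchReport:
    """Time MUSIC vs Welch feature extraction on identical inputs.

    Each cell draws one seeded random multichannel signal and times only the
    ``extract_features`` call (monotonic clock, I/O excluded), both
    estimators sharing the same window plan and grid.  The median over
    ``reps`` repetitions is reported.
    """
    if reps < 3:
        raise ConfigError(f"need reps >= 3 for a stable median, got {reps}")
    cfg = cfg or FeatureConfig()
    from .recordings_io import Recording

    rows = []
    for n_ch in channel_counts:
        for bucket, n_samples in length_buckets:
            rng = np.random.default_rng([seed, n_ch, n_samples])
            rec = Recording(
                data=rng.standard_normal((n_ch, n_samples)) * 20.0,
                fs=fs,
                channel_labels=[f"CH{i + 1:02d}" for i in range(n_ch)],
            )
            for estimator in ("welch", "music"):
                times = []
                for _ in range(reps):
                    t0 = time.perf_counter()
                    extract_features(rec, estimator, cfg)
                    times.append(time.perf_counter() - t0)
                rows.append({
                    "n_channels": n_ch, "bucket": bucket, "n_samples": n_samples,
                    "estimator": estimator, "seconds": float(np.median(times)),
                })
    import platform

    return BenchReport(
        table=pd.DataFrame(rows),
        environment=f"{platform.python_version()} / {platform.machine()}",
    )


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Execute simulate -> qc -> preprocess -> features -> train, with artifacts.

    ``config`` keys: ``synthetic`` (SyntheticSpec fields), ``estimator``
    ("music"|"welch"), ``mode`` ("all62"|"lobe_pca"), optional ``qc_threshold_uv``,
    ``features`` (FeatureConfig fields), ``train`` (TrainConfig fields),
    ``n_trials_per_state``.  Returns the evaluation report as a dict and
    writes every intermediate under ``out_dir``.
    """
    for key in ("estimator", "mode"):
        if key not in config:
            raise ConfigError(f"pipeline config missing required key {key!r}")
    estimator = config["estimator"]
    mode = config["mode"]
    if estimator not in ("music", "welch"):
        raise ConfigError(f"unknown estimator {estimator!r}")
    if mode not in ("all62", "lobe_pca"):
        raise ConfigError(f"unknown preprocessing mode {mode!r}")
    os.makedirs(out_dir, exist_ok=True)

    spec = SyntheticSpec(**config.get("synthetic", {}))
    trials = simulate_dataset(spec, n_trials_per_state=config.get("n_trials_per_state", 15))

    threshold = config.get("qc_threshold_uv", 500.0)
    reports = [detect_corrupt_channels(t, threshold) for t in trials]
    summary = qc_summary(reports)
    with open(os.path.join(out_dir, "qc_summary.json"), "w") as fh:
        json.dump(summary.to_json(), fh, indent=2)
    pd.concat([r.to_frame() for r in reports]).to_csv(
        os.path.join(out_dir, "qc_channels.csv"), index=False)

    filters = FilterSpec(**config.get("filters", {}))
    processed = [
        preprocess_trial(t, mode=mode, qc=(r if mode == "lobe_pca" else None),
                         filters=filters)
        for t, r in zip(trials, reports)
    ]

    fcfg_kwargs = dict(config.get("features", {}))
    sub_kwargs = fcfg_kwargs.pop("subspace", {})
    fcfg = FeatureConfig(**fcfg_kwargs)
    if sub_kwargs:
        fcfg = replace(fcfg, subspace=replace(fcfg.subspace, **sub_kwargs))
    tensor = build_dataset(processed, estimator, fcfg)
    tensor.save(os.path.join(out_dir, "features.npz"))
    tensor.manifest().to_csv(os.path.join(out_dir, "features_manifest.csv"), index=False)

    tcfg_kwargs = dict(config.get("train", {}))
    if "hidden_sizes" in tcfg_kwargs:
        tcfg_kwargs["hidden_sizes"] = tuple(tcfg_kwargs["hidden_sizes"])
    tcfg = TrainConfig(**tcfg_kwargs)
    report = cross_validate(tensor, tcfg)
    doc = report.to_json(os.path.join(out_dir, "eval_report.json"))

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump({"config": config, "out_dir": out_dir,
                   "stages": ["simulate", "qc", "preprocess", "features", "train"],
                   "tensor_shape": list(tensor.shape)}, fh, indent=2, default=str)
    return doc
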