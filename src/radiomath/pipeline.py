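"""End-to-end orchestration: simulate, extract, rank, test, decompose.

``run_pipeline`` drives the whole analysis on synthetic data and writes
a reproducible output bundle: cohort table, per-ROI feature table,
per-test ranking and significance tables, per-area importance
breakdowns, and a run manifest (config hash, seeds, normalization
constants, file checksums) sufficient to reproduce every output from
the seed.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .catalog import TEST_KEYS
from .cohort import CohortSpec, default_cohort_spec, generate_cohort, normalize_scores
from .features import extract_all
from .importance import ImportanceBreakdown, family_importance
from .phantom import PhantomSpec, SignalEffect, default_phantom_spec, generate_phantom
from .preprocess import histogram_match
from .rank import RankingConfig, rank_all, scaled_down_config
from .significance import build_noise_distribution, significance_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs besides the seed."""

    tests: list[str] = field(default_factory=lambda: ["mf"])
    n_rois: int = 12
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    roi_radius: float | None = None
    bin_width: float = 25.0
    apply_histogram_match: bool = True
    reference_subject: int = 0  # index of the standardization reference
    noise_replicates: int = 30
    protocol: str = "scaled"  # "scaled" (demo) or "paper" (full 20x100x100)
    signal_plan: list[dict] = field(default_factory=list)
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def ranking_config(self, seed: int) -> RankingConfig:
        if self.protocol == "paper":
            return RankingConfig(seed=seed)
        if self.protocol == "scaled":
            return scaled_down_config(seed=seed)
        raise ValueError(f"unknown protocol profile {self.protocol!r}")

    def phantom_spec(self) -> PhantomSpec:
        plan = [SignalEffect(**e) for e in self.signal_plan]
        return default_phantom_spec(
            n_rois=self.n_rois,
            shape=tuple(self.volume_shape),
            radius=self.roi_radius,
            signal_plan=plan,
            **self.phantom,
        )


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    features: pd.DataFrame
    rankings: dict[str, pd.DataFrame]
    significance: dict[str, pd.DataFrame]
    importance: dict[str, dict[int, ImportanceBreakdown]]
    manifest: dict


def simulate_features(
    config: PipelineConfig, seed: int, cohort_spec: CohortSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a cohort and phantoms and extract the feature table."""
    cohort_spec = cohort_spec or default_cohort_spec(seed=seed)
    cohort_spec.seed = seed
    cohort = generate_cohort(cohort_spec)
    cohort, constants = normalize_scores(cohort)

    spec = config.phantom_spec()
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    volumes = [generate_phantom(row, spec, rng) for _, row in cohort.iterrows()]

    if config.apply_histogram_match:
        reference = volumes[config.reference_subject][0]
        volumes = [
            (histogram_match(img, reference), lab) for img, lab in volumes
        ]

    spacing = np.asarray(spec.spacing, dtype=float)
    tables = [
        extract_all(
            img,
            lab,
            spacing=spacing,
            bin_width=config.bin_width,
            subject_id=row["subject_id"],
        )
        for (img, lab), (_, row) in zip(volumes, cohort.iterrows())
    ]
    features = pd.concat(tables, ignore_index=True)
    return cohort, features, constants


def run_pipeline(
    config: PipelineConfig, seed: int, out_dir=None
) -> PipelineResult:
    """Run simulate → extract → rank → test → importance; write the bundle."""
    t0 = time.time()
    cohort, features, constants = simulate_features(config, seed)
    rank_config = config.ranking_config(seed)

    rankings: dict[str, pd.DataFrame] = {}
    significance: dict[str, pd.DataFrame] = {}
    importance: dict[str, dict[int, ImportanceBreakdown]] = {}
    for test in config.tests:
        if test not in TEST_KEYS:
            raise ValueError(f"unknown test key {test!r}")
        y = cohort[f"{test}_norm"].to_numpy()
        results = rank_all(features, cohort, y, rank_config)
        n_noise_features = int(
            np.median([np.median(r.kept_counts) for r in results])
        )
        noise = build_noise_distribution(
            cohort,
            y,
            rank_config,
            n_features=max(1, n_noise_features),
            n_replicates=config.noise_replicates,
            seed=seed,
        )
        sig = significance_table(results, noise)
        rankings[test] = pd.DataFrame(
            {
                "roi_label": [r.roi_label for r in results],
                "median_mae": [r.median_mae for r in results],
                "baseline_mae": [r.baseline_mae for r in results],
                "improvement_percent": [r.improvement for r in results],
                **{
                    f"partition_mae_{i + 1}": [r.partition_maes[i] for r in results]
                    for i in range(rank_config.n_partitions)
                },
            }
        )
        significance[test] = sig
        importance[test] = {
            r.roi_label: family_importance(r.importances, r.feature_names)
            for r in results
            if sig.set_index("roi_label").loc[r.roi_label, "relevant"]
            or sig.set_index("roi_label").loc[r.roi_label, "significant"]
        }

    manifest = {
        "tool": "radiomath",
        "seed": int(seed),
        "config_hash": io.spec_hash(config),
        "normalization": {t: list(constants[t]) for t in constants},
        "elapsed_seconds": round(time.time() - t0, 2),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    result = PipelineResult(
        cohort=cohort,
        features=features,
        rankings=rankings,
        significance=significance,
        importance=importance,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(result, out_dir)
    return result


def _write_bundle(result: PipelineResult, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h = result.manifest["config_hash"][:16]
    io.write_table(result.cohort, out_dir / "cohort.csv", manifest_hash=h)
    io.write_table(result.features, out_dir / "features.csv", manifest_hash=h)
    files = {"cohort.csv": None, "features.csv": None}
    for test, table in result.rankings.items():
        io.write_table(table, out_dir / f"ranking_{test}.csv", manifest_hash=h)
        files[f"ranking_{test}.csv"] = None
    for test, table in result.significance.items():
        io.write_table(table, out_dir / f"significance_{test}.csv", manifest_hash=h)
        files[f"significance_{test}.csv"] = None
    for test, breakdowns in result.importance.items():
        rows = []
        for label, b in breakdowns.items():
            row = {"roi_label": label, **{f"{k}_percent": v for k, v in b.family_percent.items()}}
            row["flagged_features"] = ";".join(b.flagged_features)
            rows.append(row)
        io.write_table(pd.DataFrame(rows), out_dir / f"importance_{test}.csv", manifest_hash=h)
        files[f"importance_{test}.csv"] = None
    manifest = dict(result.manifest)
    manifest["files"] = {
        name: io.file_checksum(out_dir / name) for name in files
    }
    io.write_manifest(out_dir / "manifest.json", manifest)
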