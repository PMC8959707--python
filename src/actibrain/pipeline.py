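"""End-to-end orchestration: simulate -> preprocess -> features -> models.

Mirrors the two-corpus design of the analysis: the autoencoder is trained on
a large *reference* corpus of activity data (general-population role) and
features are extracted from a smaller *analysis* corpus whose subjects also
have regional volume tables (memory-clinic role).  Every stage writes its
table under the output directory and the run manifest records the counts, so
re-running with the same config and seeds reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import load_atlas, residualize_volumes
from .autoencoder import (
    AutoencoderConfig,
    ae_features,
    build_autoencoder,
    make_split,
    save_model,
    train_autoencoder,
)
from .preprocess import DaySegment, preprocess_records, segments_to_matrix
from .regression import (
    compare_feature_sets,
    export_violin_data,
    fit_all_regions,
    lobe_summary,
    results_frame,
)
from .synthetic import (
    default_truth,
    gen_activity_records,
    gen_subject_traits,
    gen_volume_table,
    write_records,
    write_volume_table,
)
from .timefreq import StftConfig, tf_feature_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Single configuration for a full synthetic run."""

    # synthetic generation
    n_reference_subjects: int = 120
    n_analysis_subjects: int = 40
    days_per_subject: int = 7
    n_traits: int = 3
    missing_run_prob: float = 0.1
    triaxial: bool = False
    volume_noise_sd: float = 1.0
    # preprocessing
    max_missing_run: int = 30
    # feature extraction
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    stft: StftConfig = field(default_factory=StftConfig)
    # modelling
    alpha: float = 0.05
    q: float = 0.05
    feature_sets: tuple[str, ...] = ("dl_tf", "tf_only")
    # bookkeeping
    seed: int = 0
    output_dir: str = "actibrain_run"

    def seeds(self) -> dict[str, int]:
        base = int(self.seed) % (2**31 - 100)
        names = ["ref_traits", "ref_records", "ana_traits", "ana_records",
                 "volumes", "truth", "split"]
        return {name: base + i for i, name in enumerate(names)}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "autoencoder" in raw and isinstance(raw["autoencoder"], dict):
            ae = raw["autoencoder"]
            for key in ("channels", "strides"):
                if key in ae:
                    ae[key] = tuple(ae[key])
            raw["autoencoder"] = AutoencoderConfig(**ae)
        if "stft" in raw and isinstance(raw["stft"], dict):
            raw["stft"] = StftConfig(**raw["stft"])
        if "feature_sets" in raw:
            raw["feature_sets"] = tuple(raw["feature_sets"])
        return cls(**raw)


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict[str, int]
    version: str
    counts: dict[str, int] = field(default_factory=dict)
    status: str = "ok"
    failed_stage: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _group_segments(segments: list[DaySegment]) -> dict[str, list[DaySegment]]:
    grouped: dict[str, list[DaySegment]] = {}
    for seg in segments:
        grouped.setdefault(seg.subject_id, []).append(seg)
    return grouped


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing every intermediate table under output_dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()
    manifest = RunManifest(config_hash=config.config_hash(), seeds=seeds, version=__version__)
    config.to_yaml(out / "config.yaml")
    atlas = load_atlas()
    stage = "simulate"
    try:
        # -- stage 1: simulate the two corpora -----------------------------
        ref_traits = gen_subject_traits(config.n_reference_subjects, config.n_traits, seeds["ref_traits"])
        ref_records = gen_activity_records(
            ref_traits, config.days_per_subject, 1, config.missing_run_prob,
            triaxial=False, seed=seeds["ref_records"],
        )
        ana_traits = gen_subject_traits(config.n_analysis_subjects, config.n_traits, seeds["ana_traits"])
        ana_records = gen_activity_records(
            ana_traits, config.days_per_subject, 1, config.missing_run_prob,
            triaxial=config.triaxial, seed=seeds["ana_records"],
        )
        truth = default_truth(config.n_traits, len(atlas), seeds["truth"], noise_sd=config.volume_noise_sd)
        volumes = gen_volume_table(ana_traits, truth, atlas, seeds["volumes"])
        write_records(ref_records, out / "reference_records.parquet")
        write_records(ana_records, out / "analysis_records.parquet")
        write_volume_table(volumes, out / "volumes.csv")
        truth.to_json(out / "volume_truth.json")
        manifest.counts["reference_days_generated"] = len(ref_records)
        manifest.counts["analysis_days_generated"] = len(ana_records)

        # -- stage 2: preprocess (per-dataset normalization) ----------------
        stage = "preprocess"
        ref_segments, ref_excl = preprocess_records(ref_records, max_missing_run=config.max_missing_run)
        ana_segments, ana_excl = preprocess_records(ana_records, max_missing_run=config.max_missing_run)
        _write_csv(ref_excl, out / "reference_exclusions.csv")
        _write_csv(ana_excl, out / "analysis_exclusions.csv")
        ref_mat, ref_index = segments_to_matrix(ref_segments)
        seg_frame = pd.concat(
            [ref_index, pd.DataFrame(ref_mat, columns=[f"v{i:03d}" for i in range(ref_mat.shape[1])])],
            axis=1,
        )
        seg_frame.to_parquet(out / "reference_segments.parquet", index=False)
        manifest.counts["reference_days_retained"] = len(ref_segments)
        manifest.counts["reference_days_excluded"] = len(ref_excl)
        manifest.counts["analysis_days_retained"] = len(ana_segments)
        manifest.counts["analysis_days_excluded"] = len(ana_excl)

        # -- stage 3: train the autoencoder on the reference corpus ---------
        stage = "train_autoencoder"
        split = make_split(ref_traits.subject_ids, seeds["split"])
        model = build_autoencoder(config.autoencoder)
        train_autoencoder(model, ref_mat, list(ref_index["subject_id"]), split, config.autoencoder)
        save_model(model, out / "autoencoder.npz")

        # -- stage 4: extract features from the analysis corpus -------------
        stage = "extract_features"
        grouped = _group_segments(ana_segments)
        ae_table, skipped = ae_features(model, grouped)
        tf_table = tf_feature_table(grouped, config.stft)
        features = ae_table.join(tf_table, how="inner")
        _write_csv(features, out / "features.csv", index=True)
        manifest.counts["subjects_with_features"] = len(features)
        manifest.counts["subjects_skipped_no_days"] = len(skipped) + (
            config.n_analysis_subjects - len(grouped)
        )

        # -- stage 5: per-region models, summaries, comparisons -------------
        stage = "fit_regions"
        resid = residualize_volumes(volumes, atlas)
        residuals = resid.residuals.loc[features.index]
        results_by_set = {}
        for feature_set in config.feature_sets:
            cols = list(features.columns) if feature_set == "dl_tf" else [
                c for c in features.columns if c.startswith("tf_")
            ]
            results = fit_all_regions(features[cols], residuals, atlas, config.alpha, config.q)
            results_by_set[feature_set] = results
            _write_csv(results_frame(results), out / f"region_results_{feature_set}.csv")
            _write_csv(lobe_summary(results, atlas), out / f"lobe_summary_{feature_set}.csv")
        manifest.counts["regions_modeled"] = len(atlas)
        first = config.feature_sets[0]
        manifest.counts["regions_excluded"] = int(
            sum(r.excluded for r in results_by_set[first])
        )
        if len(config.feature_sets) >= 2:
            a, b = config.feature_sets[:2]
            _write_csv(
                compare_feature_sets(results_by_set[a], results_by_set[b], atlas),
                out / "feature_set_comparison.csv",
            )
            _write_csv(
                export_violin_data(results_by_set[a], results_by_set[b], atlas, (a, b)),
                out / "violin_data.csv",
            )
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.to_json(out / "manifest.json")
        raise
    manifest.to_json(out / "manifest.json")
    return manifest
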