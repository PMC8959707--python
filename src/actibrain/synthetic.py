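"""Synthetic actigraphy and regional-volume data with stored ground truth.

The generator emulates the two data sources the analysis pipeline expects:

* multi-day 1-min activity-count series with circadian structure, near-zero
  nights (the device is removed at bedtime), and optional contiguous daytime
  missing runs;
* a regional gray-matter volume table (116 atlas regions) whose columns are
  linear functions of subject-level latent activity traits plus nuisance
  covariate effects plus Gaussian noise, with the generating coefficients
  stored alongside so that the downstream regression layer can be tested as
  a parameter-recovery problem.

Latent traits are unitless standard-normal subject scores; trait 0 acts as
circadian amplitude (daytime mean count increases with it), trait 1 adds
ultradian (~3 cycles/day) modulation, further traits perturb day-to-day level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "EpochRecord",
    "SyntheticVolumeTruth",
    "gen_subject_traits",
    "gen_activity_records",
    "default_truth",
    "gen_volume_table",
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
    "write_volume_table",
    "read_volume_table",
]

MINUTES_PER_DAY = 1440
#: peak of the circadian bump, minutes after midnight (14:00)
CIRCADIAN_PEAK_MIN = 14 * 60
#: baseline daytime amplitude, device counts/min (ActiGraph-like scale)
BASE_AMPLITUDE = 2000.0
#: multiplicative effect of one SD of trait 0 on the amplitude
AMPLITUDE_LOG_GAIN = 0.4
#: Gamma shape of the multiplicative count noise (mean 1, right-skewed)
GAMMA_SHAPE = 3.0

COVARIATE_COLUMNS = ("age", "sex", "total_intracranial_volume", "education_years")


@dataclass(frozen=True)
class TraitMatrix:
    """Latent subject-level activity traits (n_subjects x n_traits)."""

    subject_ids: list[str]
    traits: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.traits.ndim != 2 or self.traits.shape[0] != len(self.subject_ids):
            raise ValueError("traits must be n_subjects x n_traits")
        if not np.isfinite(self.traits).all():
            raise ValueError("traits must be finite")

    @property
    def n_subjects(self) -> int:
        return self.traits.shape[0]

    @property
    def n_traits(self) -> int:
        return self.traits.shape[1]


@dataclass
class EpochRecord:
    """One subject-day of per-minute activity counts.

    ``counts`` has shape (1440,) for uniaxial data or (1440, 3) for triaxial;
    missing epochs are NaN in ``counts`` and True in ``missing_mask``.
    """

    subject_id: str
    date: str  # ISO calendar date
    counts: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape[0] != MINUTES_PER_DAY:
            raise ValueError(f"expected {MINUTES_PER_DAY} epochs, got {self.counts.shape[0]}")
        if self.missing_mask.shape != self.counts.shape:
            raise ValueError("missing_mask must align with counts")
        present = ~self.missing_mask
        if np.any(self.counts[present] < 0):
            raise ValueError("counts must be non-negative where present")

    @property
    def triaxial(self) -> bool:
        return self.counts.ndim == 2


@dataclass
class SyntheticVolumeTruth:
    """Generating parameters behind a synthetic volume table."""

    coefficients: np.ndarray  # n_traits x n_regions
    covariate_effects: np.ndarray  # 4 x n_regions (age, sex, TIV, education)
    noise_sd: np.ndarray  # per-region, > 0
    intercept: np.ndarray  # per-region

    def __post_init__(self) -> None:
        n_regions = self.coefficients.shape[1]
        if self.covariate_effects.shape != (len(COVARIATE_COLUMNS), n_regions):
            raise ValueError("covariate_effects must be 4 x n_regions")
        if self.noise_sd.shape != (n_regions,) or np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive per region")
        if self.intercept.shape != (n_regions,):
            raise ValueError("intercept must be length n_regions")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients.tolist(),
            "covariate_effects": self.covariate_effects.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "intercept": self.intercept.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticVolumeTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            covariate_effects=np.asarray(payload["covariate_effects"], dtype=float),
            noise_sd=np.asarray(payload["noise_sd"], dtype=float),
            intercept=np.asarray(payload["intercept"], dtype=float),
        )


def gen_subject_traits(n_subjects: int, n_traits: int, seed: int) -> TraitMatrix:
    """Draw independent standard-normal latent traits for each subject."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if n_traits < 1:
        raise ValueError("need at least 1 trait")
    rng = np.random.default_rng(seed)
    traits = rng.standard_normal((n_subjects, n_traits))
    ids = [f"S{i:05d}" for i in range(n_subjects)]
    return TraitMatrix(subject_ids=ids, traits=traits, seed=seed)


def circadian_profile(minutes: np.ndarray | None = None) -> np.ndarray:
    """Baseline expected counts/min: raised cosine peaking at 14:00, clamped at 0.

    Positive roughly 08:00-20:00, zero through the night, so daytime activity
    dominates and the night is quiescent, as in wrist actigraphy of ambulatory
    subjects.
    """
    if minutes is None:
        minutes = np.arange(MINUTES_PER_DAY)
    phase = 2.0 * np.pi * (minutes - CIRCADIAN_PEAK_MIN) / MINUTES_PER_DAY
    return BASE_AMPLITUDE * np.clip(np.cos(phase), 0.0, None)


def gen_activity_records(
    traits: TraitMatrix,
    days_per_subject: int = 7,
    epoch_minutes: int = 1,
    missing_run_prob: float = 0.1,
    triaxial: bool = False,
    noise: bool = True,
    seed: int = 0,
) -> list[EpochRecord]:
    """Simulate per-minute activity-count records for every subject.

    Each subject-day covers 24 h in 1,440 one-minute epochs.  Counts follow the
    circadian baseline scaled by ``exp(gain * trait0)`` with Gamma(mean 1)
    multiplicative noise; trait 1 (if present) adds ultradian modulation and
    trait 2 (if present) perturbs the overall day level.  With probability
    ``missing_run_prob`` a day receives one contiguous daytime missing run of
    uniform random length 5-120 min (device taken off).  Night epochs carry the
    (near-zero) baseline; day-retention decisions downstream never depend on
    them.
    """
    if days_per_subject < 1:
        raise ValueError("days_per_subject must be positive")
    if epoch_minutes != 1:
        raise ValueError("only 1-min epochs are supported (epoch_minutes=1)")
    if not 0.0 <= missing_run_prob <= 1.0:
        raise ValueError("missing_run_prob must be a probability")

    rng = np.random.default_rng(seed)
    base = circadian_profile()
    minutes = np.arange(MINUTES_PER_DAY)
    ultradian = np.sin(2.0 * np.pi * 3.0 * minutes / MINUTES_PER_DAY)
    records: list[EpochRecord] = []
    dates = pd.date_range("2020-01-01", periods=days_per_subject, freq="D")

    for i, sid in enumerate(traits.subject_ids):
        t = traits.traits[i]
        amp = np.exp(AMPLITUDE_LOG_GAIN * t[0])
        mod = np.ones(MINUTES_PER_DAY)
        if traits.n_traits >= 2:
            mod = np.clip(1.0 + 0.3 * t[1] * ultradian, 0.0, None)
        for d in range(days_per_subject):
            level = 1.0
            if traits.n_traits >= 3 and noise:
                level = np.exp(0.1 * t[2] * rng.standard_normal())
            profile = base * amp * mod * level
            if noise:
                counts = profile * rng.gamma(GAMMA_SHAPE, 1.0 / GAMMA_SHAPE, MINUTES_PER_DAY)
            else:
                counts = profile.copy()
            mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
            if rng.random() < missing_run_prob:
                run = int(rng.integers(5, 121))
                start = int(rng.integers(9 * 60, 21 * 60 - run))
                mask[start : start + run] = True
                counts[start : start + run] = np.nan
            if triaxial:
                # split the magnitude over three axes with random positive
                # weights so that sqrt(x^2+y^2+z^2) recovers the 1-axis count
                w = rng.dirichlet(np.ones(3), MINUTES_PER_DAY)
                axes = counts[:, None] * np.sqrt(w)
                mask3 = np.repeat(mask[:, None], 3, axis=1)
                records.append(
                    EpochRecord(sid, dates[d].date().isoformat(), axes, mask3)
                )
            else:
                records.append(
                    EpochRecord(sid, dates[d].date().isoformat(), counts, mask)
                )
    return records


def default_truth(
    n_traits: int,
    n_regions: int = 116,
    seed: int = 0,
    noise_sd: float = 1.0,
    covariate_scale: float = 1.0,
) -> SyntheticVolumeTruth:
    """Random but reproducible generating parameters for a volume table.

    Trait coefficients are N(0, 2^2) (volume units per trait SD); covariate
    effects are small relative to typical rGMV spread; intercepts sit near a
    plausible mean regional volume.
    """
    rng = np.random.default_rng(seed)
    coef = rng.normal(0.0, 2.0, (n_traits, n_regions))
    cov_eff = covariate_scale * np.vstack(
        [
            rng.normal(-0.05, 0.02, n_regions),  # age: atrophy per year
            rng.normal(0.5, 0.3, n_regions),  # sex
            rng.normal(0.004, 0.001, n_regions),  # TIV (per mL)
            rng.normal(0.05, 0.03, n_regions),  # education per year
        ]
    )
    return SyntheticVolumeTruth(
        coefficients=coef,
        covariate_effects=cov_eff,
        noise_sd=np.full(n_regions, float(noise_sd)),
        intercept=rng.normal(50.0, 5.0, n_regions),
    )


def gen_covariates(n_subjects: int, rng: np.random.Generator) -> pd.DataFrame:
    """Covariates resembling an elderly memory-clinic cohort.

    Age ~ N(74.07, 7.05) years, education ~ N(9.14, 4.56) years (clipped at 0),
    sex Bernoulli(0.316) coded 0 female / 1 male, TIV ~ N(1450, 130) mL.
    """
    return pd.DataFrame(
        {
            "age": rng.normal(74.07, 7.05, n_subjects),
            "sex": (rng.random(n_subjects) < 0.316).astype(float),
            "total_intracranial_volume": rng.normal(1450.0, 130.0, n_subjects),
            "education_years": np.clip(rng.normal(9.14, 4.56, n_subjects), 0.0, None),
        }
    )


def gen_volume_table(
    traits: TraitMatrix,
    truth: SyntheticVolumeTruth,
    atlas: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a subjects x regions volume table from traits and stored truth.

    volume = intercept + traits @ coefficients + covariates @ covariate_effects
    + N(0, noise_sd).  Region columns are named by atlas ``region_name``;
    covariates are included as leading columns.
    """
    if truth.coefficients.shape[0] != traits.n_traits:
        raise ValueError("truth coefficients do not match trait count")
    if truth.coefficients.shape[1] != len(atlas):
        raise ValueError("truth shapes do not match atlas region count")
    rng = np.random.default_rng(seed)
    cov = gen_covariates(traits.n_subjects, rng)
    signal = (
        truth.intercept[None, :]
        + traits.traits @ truth.coefficients
        + cov[list(COVARIATE_COLUMNS)].to_numpy() @ truth.covariate_effects
    )
    noise = rng.standard_normal(signal.shape) * truth.noise_sd[None, :]
    volumes = pd.DataFrame(
        signal + noise, columns=list(atlas["region_name"]), index=traits.subject_ids
    )
    out = pd.concat([cov.set_index(pd.Index(traits.subject_ids)), volumes], axis=1)
    out.index.name = "subject_id"
    return out.reset_index()


# ---------------------------------------------------------------------------
# serialization: long-format epoch records and volume tables (CSV / Parquet)

def records_to_frame(records: list[EpochRecord]) -> pd.DataFrame:
    """Long table: subject_id, date, minute, count[_x/_y/_z], missing."""
    frames = []
    for rec in records:
        base = {
            "subject_id": rec.subject_id,
            "date": rec.date,
            "minute": np.arange(MINUTES_PER_DAY),
        }
        if rec.triaxial:
            base.update(
                count_x=rec.counts[:, 0],
                count_y=rec.counts[:, 1],
                count_z=rec.counts[:, 2],
                missing=rec.missing_mask.any(axis=1),
            )
        else:
            base.update(count=rec.counts, missing=rec.missing_mask)
        frames.append(pd.DataFrame(base))
    return pd.concat(frames, ignore_index=True)


def frame_to_records(frame: pd.DataFrame) -> list[EpochRecord]:
    triaxial = "count_x" in frame.columns
    records = []
    for (sid, date), grp in frame.groupby(["subject_id", "date"], sort=True):
        grp = grp.sort_values("minute")
        if len(grp) != MINUTES_PER_DAY:
            raise ValueError(f"{sid} {date}: expected {MINUTES_PER_DAY} rows")
        mask = grp["missing"].to_numpy(dtype=bool)
        if triaxial:
            counts = grp[["count_x", "count_y", "count_z"]].to_numpy(dtype=float)
            mask = np.repeat(mask[:, None], 3, axis=1)
        else:
            counts = grp["count"].to_numpy(dtype=float)
        records.append(EpochRecord(str(sid), str(date), counts, mask))
    return records


def write_records(records: list[EpochRecord], path: str | Path) -> None:
    frame = records_to_frame(records)
    path = Path(path)
    if path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False, float_format="%.10g")


def read_records(path: str | Path) -> list[EpochRecord]:
    path = Path(path)
    if path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path)
    return frame_to_records(frame)


def write_volume_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False, float_format="%.10g")


def read_volume_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)
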