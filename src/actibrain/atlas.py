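"""AAL-116 atlas table with lobe labels, and nuisance residualization of
regional gray-matter volumes.

The packaged table has 116 rows — 90 cerebral regions, 18 cerebellar
hemisphere regions and 8 vermis regions.  Cerebral regions carry one of eight
lobe labels (central 8, frontal 24, insula 2, limbic 14, occipital 14,
parietal 10, subcortical 10, temporal 8); vermis regions are modelled at the
region level but excluded from lobe-level summaries.

Residualization removes the linear effects of age, sex, total intracranial
volume and years of education from each region column by per-region OLS, so
downstream activity-feature models see covariate-adjusted volumes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .synthetic import COVARIATE_COLUMNS

__all__ = ["load_atlas", "residualize_volumes", "ResidualVolumeTable",
           "LOBES", "SUMMARY_LOBES", "ATLAS_SHA256"]

ATLAS_SHA256 = "164c6e59e9332e9eeab730cddbd9784949f733732c5228c850be55234933543f"

LOBES = (
    "central", "cerebellum", "frontal", "insula", "limbic",
    "occipital", "parietal", "subcortical", "temporal", "vermis",
)
#: lobes that enter lobe-level summaries (vermis omitted)
SUMMARY_LOBES = tuple(l for l in LOBES if l != "vermis")


def load_atlas() -> pd.DataFrame:
    """Load the packaged 116-region atlas table, verifying its checksum."""
    ref = resources.files("actibrain.data").joinpath("aal116.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != ATLAS_SHA256:
        raise RuntimeError(f"atlas fixture corrupted (sha256 {digest})")
    atlas = pd.read_csv(ref)
    assert len(atlas) == 116
    return atlas


@dataclass
class ResidualVolumeTable:
    """Covariate-adjusted volumes plus the fitted nuisance coefficients."""

    subject_ids: list[str]
    residuals: pd.DataFrame  # n_subjects x 116, columns = region names
    nuisance_coefficients: pd.DataFrame  # (intercept + 4 covariates) x regions


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {cols}")


def residualize_volumes(table: pd.DataFrame, atlas: pd.DataFrame | None = None) -> ResidualVolumeTable:
    """Regress out age, sex, TIV and education from each region column.

    ``table`` is the subjects x (covariates + 116 regions) frame produced by
    the synthetic generator or read from disk.  Residual columns are exactly
    orthogonal to the covariates (and mean-zero) up to numerical tolerance.
    """
    if len(table) <= 5:
        raise ValueError("need more subjects than covariates + intercept")
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    region_cols = [c for c in table.columns if c not in COVARIATE_COLUMNS and c != "subject_id"]
    if table[region_cols].isna().any().any():
        raise ValueError("missing volumes for included subjects")
    names = ["intercept", *COVARIATE_COLUMNS]
    design = np.column_stack(
        [np.ones(len(table)), table[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)]
    )
    _check_rank(design, names)
    volumes = table[region_cols].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, volumes, rcond=None)
    residuals = volumes - design @ coef
    subject_ids = (
        table["subject_id"].astype(str).tolist()
        if "subject_id" in table.columns
        else [str(i) for i in range(len(table))]
    )
    return ResidualVolumeTable(
        subject_ids=subject_ids,
        residuals=pd.DataFrame(residuals, columns=region_cols, index=subject_ids),
        nuisance_coefficients=pd.DataFrame(coef, index=names, columns=region_cols),
    )
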