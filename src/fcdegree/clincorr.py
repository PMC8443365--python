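"""Clinical association analyses.

Two flavors are provided, both restricted (by convention of the emulated
study) to the patient group:

* cluster-level screening — partial correlations between per-cluster mean
  standardized degree and each clinical score (Y-BOCS total and subscales,
  HAMD, HAMA), controlling for gender, age, illness duration and education,
  Bonferroni-corrected over the full (cluster x variable) family;
* whole-brain maps — per-voxel partial correlation with one score, converted
  to t and passed through the same GRF cluster machinery as the group
  comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .degree import DegreeMap
from .groupstats import (
    StatsConfig,
    _encode_covariates,
    estimate_smoothness,
    grf_cluster_correct,
    stack_maps,
)
from .imaging_io import MaskVolume

DEFAULT_CLINICAL_VARS = (
    "ybocs_total",
    "ybocs_obsession",
    "ybocs_compulsion",
    "hamd",
    "hama",
)
DEFAULT_COVARIATES = ("sex", "age", "illness_duration", "education")


@dataclass
class PartialCorrResult:
    """One partial-correlation test."""

    variable_pair: tuple[str, str]
    r: float
    p_uncorrected: float
    p_bonferroni: float
    n: int
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise DataError(f"partial correlation out of range: {self.r}")


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = y.shape[0]
    x = np.ones((n, 1))
    if covariates is not None and covariates.size:
        x = np.column_stack([x, covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    names: tuple[str, str] = ("x", "y"),
    covariate_names: tuple[str, ...] = (),
    n_tests: int = 1,
) -> PartialCorrResult:
    """Partial Pearson correlation of ``x`` and ``y`` given ``covariates``.

    Both variables are residualized against [intercept, covariates]; the
    correlation of the residuals is tested with
    ``t = r sqrt(df / (1 - r^2))``, ``df = n - n_covariates - 2``. With no
    covariates this reduces exactly to the plain Pearson correlation test.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise DataError("x and y must have the same length")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != x.shape[0]:
            raise DataError("covariate rows must match x/y length")
    n = x.shape[0]
    n_cov = 0 if covariates is None else covariates.shape[1]
    df = n - n_cov - 2
    if df < 1:
        raise DataError(f"insufficient degrees of freedom (n={n}, covariates={n_cov})")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = rx.std(ddof=0), ry.std(ddof=0)
    # residuals that vanish to rounding noise are degenerate
    tol_x = 1e-10 * max(x.std(ddof=0), 1e-300)
    tol_y = 1e-10 * max(y.std(ddof=0), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        raise DataError("constant residuals: partial correlation undefined")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrResult(
        variable_pair=names,
        r=r,
        p_uncorrected=p,
        p_bonferroni=min(1.0, p * n_tests),
        n=n,
        covariates=covariate_names,
    )


def cluster_mean_features(
    maps: list[DegreeMap], label_map: np.ndarray, labels: list[int]
) -> np.ndarray:
    """(n_subjects, n_clusters) table of mean degree inside each cluster."""
    feats = np.empty((len(maps), len(labels)))
    for j, lab in enumerate(labels):
        voxels = label_map == lab
        if not voxels.any():
            raise DataError(f"cluster label {lab} has no voxels")
        for i, m in enumerate(maps):
            vals = m.values[voxels]
            if not np.all(np.isfinite(vals)):
                raise DataError(
                    f"cluster {lab} extends outside subject {m.subject_id!r}'s mask"
                )
            feats[i, j] = vals.mean()
    return feats


def cluster_clinical_screen(
    maps: list[DegreeMap],
    cluster_table: pd.DataFrame,
    label_map: np.ndarray,
    phenotypes: pd.DataFrame,
    clinical_vars: tuple[str, ...] = DEFAULT_CLINICAL_VARS,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """All (cluster, clinical score) partial correlations in the patients.

    The Bonferroni family is the full screen (clusters x variables); every
    test is reported whether or not it is significant. An empty cluster
    table yields an empty result.
    """
    if len(cluster_table) == 0:
        return pd.DataFrame(
            columns=["cluster", "variable", "r", "p_uncorrected", "p_bonferroni", "n"]
        )
    is_patient = phenotypes["group"].astype(str) == "patient"
    pheno_pat = phenotypes.loc[is_patient].reset_index(drop=True)
    maps_pat = [m for m, keep in zip(maps, is_patient) if keep]
    cov = _encode_covariates(pheno_pat, covariates)
    labels = [int(v) for v in cluster_table["label"]]
    feats = cluster_mean_features(maps_pat, label_map, labels)
    n_tests = len(labels) * len(clinical_vars)
    rows = []
    for j, lab in enumerate(labels):
        for var in clinical_vars:
            if var not in pheno_pat.columns:
                raise DataError(f"phenotype table lacks clinical column {var!r}")
            score = pheno_pat[var].astype(float).to_numpy()
            if np.isnan(score).any():
                raise DataError(f"clinical variable {var!r} has missing values")
            res = partial_correlation(
                feats[:, j],
                score,
                cov,
                names=(f"cluster{lab}", var),
                covariate_names=covariates,
                n_tests=n_tests,
            )
            rows.append(
                {
                    "cluster": lab,
                    "variable": var,
                    "r": res.r,
                    "p_uncorrected": res.p_uncorrected,
                    "p_bonferroni": res.p_bonferroni,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def voxelwise_correlation(
    maps: list[DegreeMap],
    score: np.ndarray,
    covariates: np.ndarray | None,
    config: StatsConfig,
    mask: MaskVolume,
    affine: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray]:
    """Whole-brain partial-correlation map with GRF cluster correction.

    Returns ``(r_map, cluster_table, label_map, thresholded_t)``. The score
    and every voxel are residualized against the covariates; the per-voxel
    correlation of residuals is converted to a t statistic with
    ``df = n - n_covariates - 2`` and handed to the same cluster machinery
    as the group comparison.
    """
    score = np.asarray(score, dtype=float).ravel()
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    n = score.shape[0]
    if len(maps) != n:
        raise DataError("one map per score value is required")
    n_cov = 0 if covariates is None else covariates.shape[1]
    df = n - n_cov - 2
    if df < 3:
        raise DataError(f"insufficient df for voxel-wise correlation: {df}")
    if score.std(ddof=0) == 0:
        raise DataError("clinical score is constant across subjects")

    y = stack_maps(maps, mask)  # (n, v)
    rs = _residualize(score, covariates)
    ry = _residualize(y, covariates)
    if rs.std(ddof=0) == 0:
        raise DataError("score residuals are constant given the covariates")
    rs_n = (rs - rs.mean()) / rs.std(ddof=0)
    sy = ry.std(axis=0, ddof=0)
    sy_safe = np.where(sy > 0, sy, 1.0)
    ry_n = (ry - ry.mean(axis=0)) / sy_safe
    r = np.clip((rs_n[:, None] * ry_n).mean(axis=0), -0.999999, 0.999999)
    r = np.where(sy > 0, r, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))

    t_map = np.full(mask.data.shape, np.nan)
    t_map[mask.data] = t
    r_map = np.full(mask.data.shape, np.nan)
    r_map[mask.data] = r
    # residual maps of the full (covariates + score) model drive smoothness
    full_cov = rs[:, None] if covariates is None else np.column_stack([covariates, score])
    res = _residualize(y, full_cov)
    res_maps = np.zeros((n, *mask.data.shape))
    res_maps[:, mask.data] = res
    fwhm = estimate_smoothness(res_maps, mask)
    table, label_map, thresholded = grf_cluster_correct(
        t_map, df, fwhm, mask, config, affine
    )
    return r_map, table, label_map, thresholded
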