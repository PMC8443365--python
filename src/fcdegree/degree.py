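"""Voxel-wise degree centrality (functional connectivity strength) maps.

For every in-mask voxel the Pearson correlation of its time series with every
other in-mask voxel is computed; correlations at or below ``r_threshold``
(default 0.2) are discarded, as are all negative correlations, and the
remaining edges are summarized as

* ``binary`` degree — the number of suprathreshold positive edges, or
* ``weighted`` degree — the sum of suprathreshold positive correlation
  values (the "functional connectivity strength" reading; the default).

The map is then standardized; the default is an in-mask z-score
(mean 0, sd 1), and ``fisher_then_sum`` instead applies the Fisher
r-to-z transform (atanh) to every retained correlation before summation and
z-scores the result.

The correlation matrix is never materialized: rows are streamed in blocks,
so memory is O(block x n_voxels) rather than O(n_voxels^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, DataError
from .imaging_io import BoldRun, MaskVolume

_MODES = ("binary", "weighted")
_STANDARDIZE = ("zscore", "fisher_then_sum", "none")

#: correlations are clipped to this magnitude before atanh so that duplicated
#: series (r = 1 exactly) keep a finite Fisher value
_FISHER_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class DegreeConfig:
    """Degree-map settings.

    ``r_threshold`` removes weak edges (strict inequality: r must exceed the
    threshold). Negative correlations are always set to zero. ``mode``
    selects counting vs. summation of the retained edges.
    """

    r_threshold: float = 0.2
    mode: str = "weighted"
    standardize: str = "zscore"

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_threshold < 1.0):
            raise ConfigurationError("r_threshold must be in [0, 1)")
        if self.mode not in _MODES:
            raise ConfigurationError(f"mode must be one of {_MODES}")
        if self.standardize not in _STANDARDIZE:
            raise ConfigurationError(f"standardize must be one of {_STANDARDIZE}")


@dataclass
class DegreeMap:
    """Per-voxel degree values (NaN outside the mask) plus provenance."""

    values: np.ndarray
    config: DegreeConfig
    subject_id: str = ""
    n_mask_voxels: int = 0

    def in_mask_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


def _standardized_series(run: BoldRun, mask: MaskVolume) -> tuple[np.ndarray, np.ndarray]:
    """In-mask series scaled to zero mean / unit norm; flags zero-variance voxels."""
    mask.check_matches(run)
    x = run.data[mask.data]  # (n_vox, t)
    if x.shape[0] < 2:
        raise DataError("degree needs at least 2 in-mask voxels")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} in-mask voxel(s) have zero variance; "
            "their degree is set to 0",
            stacklevel=3,
        )
        norms = np.where(degenerate, 1.0, norms)
    return xc / norms[:, None], degenerate


def degree_map(
    run: BoldRun,
    mask: MaskVolume,
    config: DegreeConfig = DegreeConfig(),
    block_size: int = 2048,
) -> DegreeMap:
    """Compute the degree map of one preprocessed run.

    Correlation rows are streamed ``block_size`` voxels at a time. Voxels
    with zero temporal variance have no defined correlation and receive
    degree 0 (with a warning).
    """
    xn, degenerate = _standardized_series(run, mask)
    n_vox = xn.shape[0]
    thr = config.r_threshold
    fisher = config.standardize == "fisher_then_sum"
    raw = np.zeros(n_vox)
    idx = np.arange(n_vox)
    for start in range(0, n_vox, block_size):
        stop = min(start + block_size, n_vox)
        r = xn[start:stop] @ xn.T  # (block, n_vox)
        # exclude self-connections
        r[idx[start:stop] - start, idx[start:stop]] = 0.0
        if fisher:
            keep = r > thr
            z = np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))
            raw[start:stop] = np.where(keep, z, 0.0).sum(axis=1)
        else:
            # shift-and-clip trick: after r -> max(r - thr, 0), nonzeros mark
            # strictly suprathreshold edges and their sum is
            # (weighted degree) - thr * (binary degree)
            np.subtract(r, thr, out=r)
            np.clip(r, 0.0, None, out=r)
            counts = (r > 0).sum(axis=1)
            if config.mode == "binary":
                raw[start:stop] = counts
            else:
                raw[start:stop] = r.sum(axis=1) + thr * counts
    raw[degenerate] = 0.0

    values = np.full(mask.data.shape, np.nan)
    values[mask.data] = raw
    dmap = DegreeMap(
        values=values,
        config=config,
        subject_id=run.subject_id,
        n_mask_voxels=n_vox,
    )
    if config.standardize in ("zscore", "fisher_then_sum"):
        dmap = _zscore_map(dmap)
    return dmap


def _zscore_map(dmap: DegreeMap) -> DegreeMap:
    values = dmap.values.copy()
    in_mask = np.isfinite(values)
    x = values[in_mask]
    if x.size < 2:
        raise DataError("z-scoring needs at least 2 in-mask voxels")
    sd = x.std(ddof=0)
    if sd == 0:
        raise DataError("cannot z-score a map with zero in-mask variance")
    values[in_mask] = (x - x.mean()) / sd
    return DegreeMap(
        values=values,
        config=dmap.config,
        subject_id=dmap.subject_id,
        n_mask_voxels=dmap.n_mask_voxels,
    )


def standardize_map(
    dmap: DegreeMap,
    method: str = "zscore",
    run: BoldRun | None = None,
    mask: MaskVolume | None = None,
) -> DegreeMap:
    """Standardize a degree map.

    ``zscore`` rescales the existing values to in-mask mean 0 / sd 1 (and is
    idempotent). ``fisher_then_sum`` is a recompute path — every retained
    correlation is atanh-transformed before summation — and therefore needs
    the originating ``run`` and ``mask``. ``none`` returns the map unchanged
    apart from the recorded method.
    """
    if method == "none":
        return replace_config(dmap, standardize="none")
    if method == "zscore":
        out = _zscore_map(dmap)
        return replace_config(out, standardize="zscore")
    if method == "fisher_then_sum":
        if run is None or mask is None:
            raise ConfigurationError(
                "fisher_then_sum recomputes from the time series; pass run and mask"
            )
        cfg = replace(dmap.config, standardize="fisher_then_sum", mode="weighted")
        return degree_map(run, mask, cfg)
    raise ConfigurationError(f"unknown standardization method {method!r}")


def replace_config(dmap: DegreeMap, **kwargs) -> DegreeMap:
    return DegreeMap(
        values=dmap.values,
        config=replace(dmap.config, **kwargs),
        subject_id=dmap.subject_id,
        n_mask_voxels=dmap.n_mask_voxels,
    )
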