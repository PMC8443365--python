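"""Post-acquisition preprocessing chain for resting-state BOLD runs.

The stages run in a fixed order that mirrors standard degree-centrality
pipelines:

    drop initial volumes -> spatial smoothing -> linear detrend + band-pass
    -> nuisance regression -> framewise-displacement scrubbing

``preprocess_run`` enforces this order; the individual stages are also
exported for unit-level use.

Notes on the individual stages
------------------------------
* Smoothing is a Gaussian kernel of the configured FWHM (mm), converted to a
  per-axis sigma using the voxel sizes from the affine; boundaries use
  "reflect" handling, which conserves the image sum.
* The band-pass is a frequency-domain mask with a raised-cosine taper of
  half-width ``taper_hz`` around each band edge, applied after removing the
  least-squares linear trend.
* The nuisance design is Friston-24 motion expansion (parameters, squares,
  one-volume lags, lagged squares) plus white-matter and CSF series, plus the
  global mean series when global-signal regression is enabled. An intercept
  is always included.
* FD follows the Power formulation: sum of absolute frame-to-frame changes of
  the three translations plus 50 mm times the absolute rotation changes.
* Scrubbing removes every volume whose FD exceeds the threshold together
  with a window of neighbors (default 1 preceding, 2 subsequent), by
  deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DataError
from .imaging_io import BoldRun, MaskVolume

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))
FD_SPHERE_RADIUS_MM = 50.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain (defaults follow common practice for
    degree-centrality studies: drop 10 of 240 volumes, 4 mm FWHM smoothing,
    0.01-0.08 Hz band, FD scrub threshold 0.2 with a 1-before/2-after
    window, exclusion at 2 mm translation or 2 deg rotation)."""

    n_drop: int = 10
    fwhm_mm: float = 4.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    taper_hz: float = 0.002
    use_gsr: bool = False
    fd_threshold: float = 0.2
    scrub_before: int = 1
    scrub_after: int = 2
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    exclusion_rule: str = "or"

    def __post_init__(self) -> None:
        if self.n_drop < 0:
            raise ConfigurationError("n_drop must be >= 0")
        if self.fwhm_mm < 0:
            raise ConfigurationError("fwhm_mm must be >= 0")
        if not (0 <= self.band_low_hz < self.band_high_hz):
            raise ConfigurationError("band must satisfy 0 <= low < high")
        if self.fd_threshold <= 0:
            raise ConfigurationError("fd_threshold must be > 0")
        if self.scrub_before < 0 or self.scrub_after < 0:
            raise ConfigurationError("scrub window sizes must be >= 0")
        if self.exclusion_rule not in ("or", "and"):
            raise ConfigurationError("exclusion_rule must be 'or' or 'and'")


@dataclass
class NuisanceDesign:
    """Per-volume nuisance regressors (24 motion + wm + csf [+ global])."""

    columns: np.ndarray
    labels: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.labels):
            raise DataError("design column count does not match labels")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def drop_initial(run: BoldRun, n_drop: int) -> BoldRun:
    """Remove the first ``n_drop`` volumes (magnetization-equilibration discard)."""
    if n_drop < 0:
        raise ConfigurationError("n_drop must be >= 0")
    if n_drop >= run.n_volumes:
        raise DataError(
            f"n_drop={n_drop} would leave no volumes (run has {run.n_volumes})"
        )
    if n_drop == 0:
        return run
    return BoldRun(
        data=run.data[..., n_drop:],
        tr_seconds=run.tr_seconds,
        affine=run.affine,
        subject_id=run.subject_id,
    )


def smooth_gaussian(run: BoldRun, fwhm_mm: float) -> BoldRun:
    """Smooth every volume with an isotropic Gaussian kernel of ``fwhm_mm``."""
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return run
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / run.voxel_sizes()
    smoothed = ndimage.gaussian_filter(
        run.data, sigma=(*sigma_vox, 0.0), mode="reflect", truncate=6.0
    )
    return BoldRun(
        data=smoothed,
        tr_seconds=run.tr_seconds,
        affine=run.affine,
        subject_id=run.subject_id,
    )


def detrend_and_bandpass(
    series: np.ndarray,
    tr_seconds: float,
    band: tuple[float, float] = (0.01, 0.08),
    taper_hz: float = 0.002,
) -> np.ndarray:
    """Remove the linear trend, then band-pass filter along the last axis.

    The filter is an ideal frequency-domain mask with raised-cosine edges of
    half-width ``taper_hz``; a band edge at or above Nyquist is rejected.
    """
    series = np.asarray(series, dtype=np.float64)
    n_t = series.shape[-1]
    if n_t < 8:
        raise DataError(f"need at least 8 time points, got {n_t}")
    low, high = band
    nyquist = 0.5 / tr_seconds
    if not (0 <= low < high < nyquist):
        raise ConfigurationError(
            f"band {band} outside (0, Nyquist={nyquist:.4g}) for TR {tr_seconds}"
        )
    # least-squares removal of intercept + linear trend along the last axis
    t_axis = np.arange(n_t) - (n_t - 1) / 2.0
    t_axis /= np.sqrt((t_axis**2).sum())
    mean = series.mean(axis=-1, keepdims=True)
    slope = series @ t_axis
    detrended = series - mean - slope[..., None] * t_axis
    freqs = np.fft.rfftfreq(n_t, d=tr_seconds)
    weight = np.ones_like(freqs)
    if taper_hz > 0:
        lo_ramp = np.clip((freqs - (low - taper_hz)) / (2 * taper_hz), 0.0, 1.0)
        hi_ramp = np.clip(((high + taper_hz) - freqs) / (2 * taper_hz), 0.0, 1.0)
        weight = 0.5 * (1 - np.cos(np.pi * lo_ramp)) * 0.5 * (1 - np.cos(np.pi * hi_ramp))
    else:
        weight = ((freqs >= low) & (freqs <= high)).astype(float)
    weight[freqs < max(low - taper_hz, 0.0)] = 0.0
    weight[freqs > high + taper_hz] = 0.0
    spec = np.fft.rfft(detrended, axis=-1)
    return np.fft.irfft(spec * weight, n=n_t, axis=-1)


def friston24(motion: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body parameters into the 24-regressor motion model.

    Columns are, for each parameter ``p``: ``[p, p^2, p_{t-1}, p_{t-1}^2]``;
    the lagged rows start with a zero at t=0.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError(f"motion must be (t, 6), got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise DataError("motion series needs at least 2 rows")
    lag = np.vstack([np.zeros((1, 6)), motion[:-1]])
    blocks = [motion, motion**2, lag, lag**2]
    return np.hstack(blocks)


def build_nuisance_design(
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    global_signal: np.ndarray | None = None,
    source: str = "",
) -> NuisanceDesign:
    """Assemble the nuisance design: Friston-24 + wm + csf (+ global)."""
    f24 = friston24(motion)
    cols = [f24, np.asarray(wm, float)[:, None], np.asarray(csf, float)[:, None]]
    labels = (
        [f"motion{j}" for j in range(6)]
        + [f"motion{j}_sq" for j in range(6)]
        + [f"motion{j}_lag" for j in range(6)]
        + [f"motion{j}_lag_sq" for j in range(6)]
        + ["wm", "csf"]
    )
    if global_signal is not None:
        cols.append(np.asarray(global_signal, float)[:, None])
        labels.append("global")
    columns = np.hstack(cols)
    if columns.shape[0] != f24.shape[0]:
        raise DataError("nuisance series length mismatch")
    return NuisanceDesign(columns=columns, labels=labels, source=source)


def _check_design_rank(design: np.ndarray, labels: list[str]) -> None:
    centered = design - design.mean(axis=0)
    norms = np.linalg.norm(centered, axis=0)
    scale = np.where(norms > 0, norms, 1.0)
    _, r = np.linalg.qr(centered / scale)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        names = [labels[i] for i in np.flatnonzero(bad)]
        raise DataError(f"rank-deficient nuisance design; collinear columns: {names}")


def regress_nuisance(run: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Project out the nuisance design (plus intercept) from every voxel."""
    x = design.columns
    if x.shape[0] != run.n_volumes:
        raise DataError(
            f"design has {x.shape[0]} rows but run has {run.n_volumes} volumes"
        )
    _check_design_rank(x, design.labels)
    xc = np.column_stack([np.ones(x.shape[0]), x])
    shape = run.data.shape
    y = run.data.reshape(-1, shape[3]).T  # (t, voxels)
    q, r = np.linalg.qr(xc)
    beta = np.linalg.solve(r, q.T @ y)
    residuals = (y - xc @ beta).T.reshape(shape)
    return BoldRun(
        data=residuals,
        tr_seconds=run.tr_seconds,
        affine=run.affine,
        subject_id=run.subject_id,
    )


def compute_fd(
    motion: np.ndarray, sphere_radius_mm: float = FD_SPHERE_RADIUS_MM
) -> np.ndarray:
    """Per-volume framewise displacement (Power): FD_0 = 0,
    FD_t = sum |d translation_i| + radius * sum |d rotation_j| (rotations in
    radians)."""
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError(f"motion must be (t, 6), got shape {motion.shape}")
    if motion.shape[0] < 2:
        raise DataError("need at least 2 volumes to compute FD")
    delta = np.abs(np.diff(motion, axis=0))
    fd = delta[:, :3].sum(axis=1) + sphere_radius_mm * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_indices(
    fd_series: np.ndarray, fd_threshold: float, before: int = 1, after: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Indices removed/retained by FD scrubbing (windows clipped at the ends)."""
    fd_series = np.asarray(fd_series, dtype=np.float64)
    n_t = fd_series.shape[0]
    removed = np.zeros(n_t, dtype=bool)
    for t in np.flatnonzero(fd_series > fd_threshold):
        removed[max(0, t - before): min(n_t, t + after + 1)] = True
    return np.flatnonzero(removed), np.flatnonzero(~removed)


def scrub(
    run: BoldRun,
    fd_series: np.ndarray,
    fd_threshold: float = 0.2,
    before: int = 1,
    after: int = 2,
) -> tuple[BoldRun, np.ndarray, int]:
    """Delete high-FD volumes and their neighbor windows.

    Returns ``(scrubbed_run, retained_indices, n_scrubbed)``. A run in which
    every volume is flagged is unusable and raises.
    """
    fd_series = np.asarray(fd_series, dtype=np.float64)
    if fd_series.shape[0] != run.n_volumes:
        raise DataError(
            f"FD length {fd_series.shape[0]} != run volumes {run.n_volumes}"
        )
    removed, retained = scrub_indices(fd_series, fd_threshold, before, after)
    if retained.size < 2:
        raise DataError(
            f"subject {run.subject_id!r}: scrubbing removed "
            f"{removed.size}/{run.n_volumes} volumes; run unusable"
        )
    if removed.size == 0:
        return run, retained, 0
    out = BoldRun(
        data=run.data[..., retained],
        tr_seconds=run.tr_seconds,
        affine=run.affine,
        subject_id=run.subject_id,
    )
    return out, retained, int(removed.size)


def motion_exclusion_check(
    motion: np.ndarray,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
    rule: str = "or",
) -> tuple[bool, np.ndarray]:
    """Screen a subject's motion against the exclusion limits.

    Returns ``(passed, offending_volume_indices)``. With ``rule="or"`` a
    subject fails if either any |translation| exceeds the mm limit or any
    |rotation| (converted to degrees) exceeds the degree limit; with
    ``rule="and"`` both must be violated.
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DataError(f"motion must be (t, 6), got shape {motion.shape}")
    trans_bad = (np.abs(motion[:, :3]) > max_translation_mm).any(axis=1)
    rot_bad = (np.abs(np.rad2deg(motion[:, 3:])) > max_rotation_deg).any(axis=1)
    if rule == "or":
        failed = trans_bad.any() or rot_bad.any()
        offending = np.flatnonzero(trans_bad | rot_bad)
    elif rule == "and":
        failed = trans_bad.any() and rot_bad.any()
        offending = np.flatnonzero(trans_bad | rot_bad) if failed else np.array([], int)
    else:
        raise ConfigurationError("rule must be 'or' or 'and'")
    return (not failed), offending


# ---------------------------------------------------------------------------
# Orchestrated chain
# ---------------------------------------------------------------------------


def preprocess_run(
    run: BoldRun,
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
    config: PreprocessConfig,
    mask: MaskVolume | None = None,
) -> tuple[BoldRun, dict]:
    """Run the full chain in the fixed order and report QC.

    ``motion``, ``wm`` and ``csf`` cover the acquired volumes; the initial
    ``n_drop`` rows are discarded alongside the dropped volumes. Returns the
    preprocessed run and a QC dict (fd_mean, n_scrubbed, retained indices,
    exclusion flag and offending volumes).
    """
    motion = np.asarray(motion, dtype=np.float64)
    if motion.shape[0] != run.n_volumes:
        raise DataError(
            f"motion rows ({motion.shape[0]}) != run volumes ({run.n_volumes})"
        )
    wm = np.asarray(wm, dtype=np.float64)
    csf = np.asarray(csf, dtype=np.float64)

    run = drop_initial(run, config.n_drop)
    motion = motion[config.n_drop:]
    wm = wm[config.n_drop:]
    csf = csf[config.n_drop:]

    passed, offending = motion_exclusion_check(
        motion,
        config.max_translation_mm,
        config.max_rotation_deg,
        config.exclusion_rule,
    )

    run = smooth_gaussian(run, config.fwhm_mm)

    filtered = detrend_and_bandpass(
        run.data.reshape(-1, run.n_volumes),
        run.tr_seconds,
        (config.band_low_hz, config.band_high_hz),
        config.taper_hz,
    ).reshape(run.data.shape)
    run = BoldRun(filtered, run.tr_seconds, run.affine, run.subject_id)

    global_signal = None
    if config.use_gsr:
        if mask is not None:
            mask.check_matches(run)
            global_signal = run.data[mask.data].mean(axis=0)
        else:
            global_signal = run.data.reshape(-1, run.n_volumes).mean(axis=0)
    design = build_nuisance_design(
        motion, wm, csf, global_signal, source=f"subject {run.subject_id}"
    )
    run = regress_nuisance(run, design)

    fd = compute_fd(motion)
    run, retained, n_scrubbed = scrub(
        run, fd, config.fd_threshold, config.scrub_before, config.scrub_after
    )

    qc = {
        "subject_id": run.subject_id,
        "fd_mean": float(fd.mean()),
        "fd_max": float(fd.max()),
        "n_scrubbed": n_scrubbed,
        "n_retained": int(retained.size),
        "retained_indices": retained.tolist(),
        "motion_exclusion_passed": bool(passed),
        "offending_volumes": offending.tolist(),
    }
    return run, qc
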