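"""Synthetic two-group resting-state fMRI cohorts with known ground truth.

The generator emulates the kind of cohort used in voxel-wise degree
(functional-connectivity-strength) case-control studies: two groups of 4-D
BOLD runs on a common grid, rigid-body motion traces, designated white-matter
and CSF nuisance series, and a phenotype table whose clinical scores follow
the group summary statistics of a medication-free OCD sample versus matched
healthy controls.

Signal model
------------
A small number of latent "network" signals, band-limited to the resting-state
band (0.01-0.08 Hz), are linearly mixed into voxels:

* an ordinary voxel belongs to one network ``k`` and follows
  ``sqrt(rho) * s_k + sqrt(1 - rho) * noise_sd * eta`` with
  ``rho = base_coupling``, so two voxels of the same network correlate at
  about ``rho`` (for ``noise_sd = 1``);
* a block of *hub* voxels couples to every network with total coupling
  ``rho_hub = base_coupling (+ effect_strength if the subject is a patient)``,
  split evenly across networks. Hubs therefore correlate with all networks
  and carry a higher degree, and the patient/control contrast of hub degree
  is controlled by ``effect_strength`` (0 gives a null cohort in which the
  two groups are exchangeable in distribution).

On top of the neural signal each voxel receives a linear drift, a
motion-correlated artifact (random spatial weights times the motion
parameters) and a small coupling to the wm/csf nuisance series. Motion is a
6-parameter random walk with occasional step-like spikes of 0.5-2 mm so that
framewise-displacement scrubbing has work to do.

Everything is a pure function of ``(config, seed)``: identical inputs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

import yaml

from .errors import ConfigurationError, DataError
from .imaging_io import (
    BoldRun,
    MaskVolume,
    SubjectRecord,
    write_bold,
    write_motion,
    write_nuisance,
    write_phenotypes,
    write_volume,
)

#: Group summary statistics of the emulated cohort (mean, sd per group) and
#: instrument bounds used to truncate the sampling distributions.
PHENOTYPE_DISTRIBUTIONS = {
    #                (patient mean, sd), (control mean, sd), (low, high)
    "age": ((27.28, 8.16), (27.18, 8.33), (16.0, 50.0)),
    "education": ((13.40, 2.87), (13.74, 3.03), (0.0, 25.0)),
    "ybocs_total": ((24.90, 5.73), (1.13, 0.88), (0.0, 40.0)),
    "ybocs_obsession": ((12.85, 4.25), (0.37, 0.49), (0.0, 20.0)),
    "ybocs_compulsion": ((12.05, 4.62), (0.74, 0.72), (0.0, 20.0)),
    "hamd": ((8.05, 4.40), (1.45, 0.95), (0.0, 52.0)),
    "hama": ((10.83, 6.55), (1.16, 1.00), (0.0, 56.0)),
}

#: Eligibility bounds applied to patients (screening criteria of the emulated
#: study): Y-BOCS total > 16 and HAMD < 18.
PATIENT_YBOCS_MIN = 16.0
PATIENT_HAMD_MAX = 18.0

#: Illness duration (months) is sampled log-normal, matched by moments to
#: 66.68 +/- 75.54.
ILLNESS_DURATION_MEAN = 66.68
ILLNESS_DURATION_SD = 75.54

#: Fraction of male patients / controls (27/40 and 25/38).
MALE_FRACTION = {"patient": 27 / 40, "control": 25 / 38}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults state the emulated acquisition (TR 2 s, 240 volumes) and cohort
    (40 patients / 38 controls) at a 12x12x12 desk-scale grid with 3 mm
    voxels. ``effect_strength = 0`` produces a null cohort.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    n_patients: int = 40
    n_controls: int = 38
    n_networks: int = 6
    n_hub_voxels: int = 27
    effect_strength: float = 0.25
    base_coupling: float = 0.04
    noise_sd: float = 1.0
    noise_smooth_fwhm_vox: float = 2.0
    motion_sd: float = 0.01
    spike_prob: float = 0.02
    drift_amplitude: float = 1.0
    motion_artifact_amplitude: float = 0.1
    nuisance_amplitude: float = 0.2
    voxel_size_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ConfigurationError(f"invalid grid_shape {self.grid_shape}")
        for name in ("n_timepoints", "n_patients", "n_controls", "n_networks",
                     "n_hub_voxels"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 <= self.base_coupling < 1.0):
            raise ConfigurationError("base_coupling must be in [0, 1)")
        if self.effect_strength < 0:
            raise ConfigurationError("effect_strength must be >= 0")
        if self.base_coupling + self.effect_strength >= 1.0:
            raise ConfigurationError("base_coupling + effect_strength must be < 1")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ConfigurationError("spike_prob must be a probability")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


def gray_matter_mask(config: SimulationConfig) -> MaskVolume:
    """Whole-grid mask minus a 1-voxel border (the stand-in gray-matter mask)."""
    mask = np.zeros(config.grid_shape, dtype=bool)
    if min(config.grid_shape) >= 3:
        mask[1:-1, 1:-1, 1:-1] = True
    else:
        mask[:] = True
    return MaskVolume(data=mask, affine=config.affine)


def hub_voxel_mask(config: SimulationConfig) -> np.ndarray:
    """Ground-truth boolean mask of the implanted hub block (grid-centered)."""
    side = int(np.ceil(config.n_hub_voxels ** (1.0 / 3.0)))
    shape = config.grid_shape
    if any(side > s for s in shape):
        raise ConfigurationError("n_hub_voxels does not fit inside the grid")
    start = [max(1, (s - side) // 2) for s in shape]
    coords = [
        (i, j, k)
        for i in range(start[0], start[0] + side)
        for j in range(start[1], start[1] + side)
        for k in range(start[2], start[2] + side)
    ][: config.n_hub_voxels]
    mask = np.zeros(shape, dtype=bool)
    for c in coords:
        mask[c] = True
    return mask


def _network_assignment(config: SimulationConfig) -> np.ndarray:
    """Assign every grid voxel to one network, balanced and spatially
    distributed.

    Resting-state networks are distributed, not contiguous blocks; a
    contiguous assignment would give each network's sampling fluctuation a
    contiguous footprint in every subject's degree map, i.e. long-range
    common modes that no local-smoothness cluster correction can calibrate.
    The assignment is a deterministic function of the config seed and is
    shared by all subjects of a cohort (network topography plays the role of
    anatomy).
    """
    n_vox = int(np.prod(config.grid_shape))
    balanced = np.arange(n_vox) % config.n_networks
    rng = np.random.default_rng([config.seed, 777])
    return rng.permutation(balanced).reshape(config.grid_shape)


def _bandlimited_signals(
    n_signals: int, n_t: int, tr: float, rng: np.random.Generator,
    low: float = 0.01, high: float = 0.08,
) -> np.ndarray:
    """Unit-variance signals with spectral support restricted to [low, high] Hz."""
    white = rng.standard_normal((n_signals, n_t))
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(white, axis=1)
    spec[:, ~keep] = 0.0
    sig = np.fft.irfft(spec, n=n_t, axis=1)
    sd = sig.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def _simulate_motion(
    n_t: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """6-parameter random walk (mm, radians) with persistent translation spikes."""
    steps = np.empty((n_t, 6))
    steps[:, :3] = rng.normal(0.0, config.motion_sd, size=(n_t, 3))
    # rotations walk ~100x slower so their FD share is comparable after the
    # 50 mm sphere-radius scaling
    steps[:, 3:] = rng.normal(0.0, config.motion_sd / 100.0, size=(n_t, 3))
    steps[0] = 0.0
    spikes = rng.random(n_t) < config.spike_prob
    spikes[0] = False
    for t in np.flatnonzero(spikes):
        axis = rng.integers(0, 3)
        jump = rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
        steps[t, axis] += jump
    return np.cumsum(steps, axis=0)


def simulate_subject(
    config: SimulationConfig, group: str, subject_seed: int
) -> tuple[BoldRun, np.ndarray, dict[str, np.ndarray]]:
    """Generate one subject's BOLD run, motion trace and nuisance series.

    Returns ``(run, motion, nuisance)`` where ``motion`` is an
    ``(n_timepoints, 6)`` array (translations mm, rotations radians) and
    ``nuisance`` maps ``"wm"``/``"csf"`` to per-volume series.
    """
    if group not in ("patient", "control"):
        raise DataError(f"unknown group {group!r}")
    rng = np.random.default_rng([config.seed, int(subject_seed),
                                 0 if group == "control" else 1])
    shape = config.grid_shape
    n_vox = int(np.prod(shape))
    n_t = config.n_timepoints

    networks = _bandlimited_signals(config.n_networks, n_t, config.tr_seconds, rng)
    assignment = _network_assignment(config).reshape(n_vox)
    hub = hub_voxel_mask(config).reshape(n_vox)

    rho = config.base_coupling
    rho_hub = rho + (config.effect_strength if group == "patient" else 0.0)

    # neural signal: network share + white noise share
    mix = np.zeros((n_vox, config.n_networks))
    mix[np.arange(n_vox), assignment] = np.sqrt(rho)
    mix[hub, :] = np.sqrt(rho_hub / config.n_networks)
    noise_scale = np.where(hub, np.sqrt(1.0 - rho_hub), np.sqrt(1.0 - rho))
    signal = mix @ networks
    # voxel noise carries an intrinsic spatial correlation (real BOLD noise is
    # spatially smooth); periodic smoothing keeps the field stationary and the
    # field is renormalized to unit variance
    noise = rng.standard_normal((*shape, n_t))
    if config.noise_smooth_fwhm_vox > 0:
        sigma_n = config.noise_smooth_fwhm_vox / np.sqrt(8.0 * np.log(2.0))
        noise = ndimage.gaussian_filter(
            noise, sigma=(sigma_n, sigma_n, sigma_n, 0.0), mode="wrap"
        )
        noise /= noise.std()
    signal += (noise_scale * config.noise_sd)[:, None] * noise.reshape(n_vox, n_t)

    # linear drift, per-voxel slope
    ramp = np.linspace(-1.0, 1.0, n_t)
    signal += (
        config.drift_amplitude * rng.standard_normal(n_vox)[:, None] * ramp[None, :]
    )

    # motion trace + motion-correlated artifact
    motion = _simulate_motion(n_t, config, rng)
    mstd = motion.std(axis=0, ddof=0)
    mstd[mstd == 0] = 1.0
    motion_z = (motion - motion.mean(axis=0)) / mstd
    weights = config.motion_artifact_amplitude * rng.standard_normal((n_vox, 6))
    signal += weights @ motion_z.T

    # designated wm / csf nuisance series, mixed weakly into every voxel
    wm, csf = _bandlimited_signals(2, n_t, config.tr_seconds, rng, low=0.0, high=0.1)
    nw = config.nuisance_amplitude * rng.standard_normal((n_vox, 2))
    signal += nw @ np.vstack([wm, csf])

    data = 1000.0 + 50.0 * signal.reshape(*shape, n_t)
    run = BoldRun(
        data=data,
        tr_seconds=config.tr_seconds,
        affine=config.affine,
        subject_id=f"{group[0]}{subject_seed:03d}",
    )
    return run, motion, {"wm": wm, "csf": csf}


def _truncnorm(
    mean: float, sd: float, low: float, high: float, rng: np.random.Generator
) -> float:
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_phenotype(
    group: str, subject_id: str, rng: np.random.Generator
) -> SubjectRecord:
    """Draw one phenotype row from the group distributions.

    Patient draws respect the eligibility screen (Y-BOCS total > 16,
    HAMD < 18); controls are drawn around the control means. Illness duration
    (patients only) is log-normal matched by moments to 66.68 +/- 75.54
    months.
    """
    col = 0 if group == "patient" else 1
    values: dict[str, float] = {}
    for name, (pat, ctl, bounds) in PHENOTYPE_DISTRIBUTIONS.items():
        mean, sd = (pat, ctl)[col]
        low, high = bounds
        if group == "patient" and name == "ybocs_total":
            low = max(low, PATIENT_YBOCS_MIN + 1e-9)
        if group == "patient" and name == "hamd":
            high = min(high, PATIENT_HAMD_MAX - 1e-9)
        values[name] = _truncnorm(mean, sd, low, high, rng)
    if group == "patient":
        sigma2 = np.log(1.0 + (ILLNESS_DURATION_SD / ILLNESS_DURATION_MEAN) ** 2)
        mu = np.log(ILLNESS_DURATION_MEAN) - sigma2 / 2.0
        duration = float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
    else:
        duration = None
    sex = "male" if rng.random() < MALE_FRACTION[group] else "female"
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=values["age"],
        sex=sex,
        education=values["education"],
        illness_duration=duration,
        ybocs_total=values["ybocs_total"],
        ybocs_obsession=values["ybocs_obsession"],
        ybocs_compulsion=values["ybocs_compulsion"],
        hamd=values["hamd"],
        hama=values["hama"],
    )


def simulate_cohort(config: SimulationConfig, output_dir: str | Path) -> Path:
    """Write a full synthetic cohort to ``output_dir``.

    Creates per subject ``sub-<id>_bold.nii.gz``, ``sub-<id>_motion.txt`` and
    ``sub-<id>_nuisance.tsv``, plus ``phenotypes.csv``, the gray-matter mask,
    the ground-truth hub mask and a ``manifest.yaml`` recording the config.
    Returns the manifest path.
    """
    output_dir = Path(output_dir)
    try:
        output_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {output_dir}: {exc}") from exc

    records: list[SubjectRecord] = []
    subject_seed = 0
    for group, count in (("patient", config.n_patients), ("control", config.n_controls)):
        for _ in range(count):
            subject_seed += 1
            sid = f"{'P' if group == 'patient' else 'C'}{subject_seed:03d}"
            run, motion, nuis = simulate_subject(config, group, subject_seed)
            bold_path = write_bold(run, output_dir / f"sub-{sid}_bold.nii.gz")
            motion_path = write_motion(motion, output_dir / f"sub-{sid}_motion.txt")
            nuis_path = write_nuisance(
                nuis["wm"], nuis["csf"], output_dir / f"sub-{sid}_nuisance.tsv"
            )
            pheno_rng = np.random.default_rng(
                [config.seed, subject_seed, 1000 + (group == "patient")]
            )
            rec = sample_phenotype(group, sid, pheno_rng)
            rec.bold_path = str(bold_path)
            rec.motion_path = str(motion_path)
            rec.nuisance_path = str(nuis_path)
            records.append(rec)

    pheno_path = write_phenotypes(records, output_dir / "phenotypes.csv")
    mask = gray_matter_mask(config)
    mask_path = write_volume(mask.data, mask.affine, output_dir / "gm_mask.nii.gz")
    hub_path = write_volume(
        hub_voxel_mask(config), config.affine, output_dir / "hub_truth.nii.gz"
    )
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_subjects": len(records),
        "phenotypes": pheno_path.name,
        "gm_mask": mask_path.name,
        "hub_truth": hub_path.name,
        "subjects": [r.subject_id for r in records],
    }
    manifest_path = output_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    cfg = dict(manifest["config"])
    cfg["grid_shape"] = tuple(cfg["grid_shape"])
    manifest["config"] = SimulationConfig(**cfg)
    return manifest


def null_config(config: SimulationConfig) -> SimulationConfig:
    """The same cohort with the group effect switched off."""
    return replace(config, effect_strength=0.0)
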