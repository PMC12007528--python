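"""2D digital slice phantoms with millisecond-scale functional dynamics.

The phantom is a labelled 2D grid with per-compartment relaxation parameters.
Each voxel's instantaneous signal is the steady-state SPGRE baseline

    s0 = pd * sin(alpha) * Mss * exp(-TE/T2*)

modulated multiplicatively by (i) a phenomenological percent-change boxcar or
half-sine response time-locked to the stimulus (the candidate DIANA contrast
is injected, not modelled biophysically), (ii) a slow global scanner drift,
(iii) global low-frequency physiological oscillations, with additive thermal
noise and per-trial 2D rigid motion on top.  Everything is deterministic
given the model seeds, so simulated experiments are bit-reproducible.

Two presets ship with the package: ``brain_slice`` (WM/GM/CSF bands with a
calcarine-like target ROI plus gray- and white-matter control ROIs, the
gray-matter control matched in voxel count to the target) and ``tubes``
(centrifuge-tube stability phantom with distinct T1 compartments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bloch import SequenceParams, TissueParams, steady_state_signal

__all__ = [
    "DigitalPhantom",
    "ResponseModel",
    "DriftModel",
    "NoiseModel",
    "MotionModel",
    "make_default_phantom",
    "baseline_image",
    "voxel_timeseries",
    "trial_images",
]

# 7 T tissue parameters (ms); pd relative to CSF
BRAIN_COMPARTMENTS = {
    1: TissueParams(t1_ms=1200.0, t2s_ms=26.0, pd=0.65),  # white matter
    2: TissueParams(t1_ms=2000.0, t2s_ms=28.0, pd=0.80),  # gray matter
    3: TissueParams(t1_ms=4300.0, t2s_ms=60.0, pd=1.00),  # CSF
}

# MnCl2-doped tubes: increasing concentration shortens T1 and T2*
TUBE_COMPARTMENTS = {
    1: TissueParams(t1_ms=400.0, t2s_ms=20.0, pd=1.0),
    2: TissueParams(t1_ms=900.0, t2s_ms=35.0, pd=1.0),
    3: TissueParams(t1_ms=1800.0, t2s_ms=50.0, pd=1.0),
}


@dataclass
class DigitalPhantom:
    """Label map plus per-compartment tissue parameters and named ROI masks.

    ``grid`` holds integer compartment labels (0 = air, zero signal); every
    nonzero label must have an entry in ``compartments``.  ``rois`` maps ROI
    names to boolean masks on the same grid.
    """

    grid: np.ndarray
    compartments: dict[int, TissueParams]
    rois: dict[str, np.ndarray] = field(default_factory=dict)
    preset: str = "custom"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise ValueError("phantom grid must be 2D")
        labels = set(np.unique(self.grid)) - {0}
        missing = labels - set(self.compartments)
        if missing:
            raise ValueError(f"labels without compartment parameters: {missing}")
        for name, mask in self.rois.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.grid.shape:
                raise ValueError(f"ROI {name!r} shape mismatch")
            self.rois[name] = mask

    @property
    def matrix_size(self) -> int:
        return self.grid.shape[0]


@dataclass
class ResponseModel:
    """Phenomenological stimulus-locked percent-change response.

    The response multiplies the baseline of active voxels by
    ``1 + amplitude_pct/100 * shape(t)`` for trial phase t in
    ``[onset_ms, onset_ms + duration_ms)``; ``shape`` is ``"boxcar"``
    (constant 1) or ``"half_sine"``.  ``amplitude_pct = 0`` produces null
    data.  ``active_roi`` names the phantom ROI carrying the response.
    """

    onset_ms: float = 75.0
    duration_ms: float = 150.0
    amplitude_pct: float = 0.05
    shape: str = "boxcar"
    active_roi: str = "target_v1"

    def __post_init__(self) -> None:
        if self.onset_ms < 0:
            raise ValueError("onset_ms must be >= 0")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be > 0")
        if self.shape not in ("boxcar", "half_sine"):
            raise ValueError(f"unknown response shape {self.shape!r}")

    def factor(self, t_phase_ms: np.ndarray) -> np.ndarray:
        """Multiplicative response factor at trial phase ``t_phase_ms``."""
        t = np.asarray(t_phase_ms, dtype=float)
        u = (t - self.onset_ms) / self.duration_ms
        inside = (u >= 0) & (u < 1)
        if self.shape == "boxcar":
            shape = inside.astype(float)
        else:
            shape = np.where(inside, np.sin(np.pi * np.clip(u, 0, 1)), 0.0)
        return 1.0 + self.amplitude_pct / 100.0 * shape


@dataclass
class DriftModel:
    """Global multiplicative linear scanner drift.

    Signal at absolute time t (s) is scaled by
    ``1 + rate_pct_per_min/100 * (t - t0_s)/60`` in every voxel.
    """

    rate_pct_per_min: float = 0.0
    t0_s: float = 0.0

    def factor(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        return 1.0 + self.rate_pct_per_min / 100.0 * (t - self.t0_s) / 60.0


@dataclass
class NoiseModel:
    """Thermal plus low-frequency physiological noise.

    ``thermal_sigma_pct`` is the white-noise standard deviation as a percent
    of the mean nonzero-compartment baseline; the noise field is spatially
    uniform and independent per sample.  ``physio_components`` is a list of
    ``(frequency_hz, amplitude_pct, phase_rad)`` global multiplicative
    sinusoids (defaults emulate respiration at 0.3 Hz and cardiac pulsation
    at 1.0 Hz; convenience placeholders, not measured spectra).  All draws
    derive from ``seed``.
    """

    thermal_sigma_pct: float = 0.0
    physio_components: list[tuple[float, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thermal_sigma_pct < 0:
            raise ValueError("thermal_sigma_pct must be >= 0")
        for f, _, _ in self.physio_components:
            if f < 0:
                raise ValueError("physio frequencies must be >= 0")

    @classmethod
    def default_physio(cls, thermal_sigma_pct: float = 0.0, seed: int = 0):
        return cls(
            thermal_sigma_pct=thermal_sigma_pct,
            physio_components=[(0.3, 0.05, 0.0), (1.0, 0.05, np.pi / 3)],
            seed=seed,
        )

    def physio_factor(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        f = np.ones_like(t)
        for freq, amp_pct, phase in self.physio_components:
            f = f + amp_pct / 100.0 * np.sin(2 * np.pi * freq * t + phase)
        return f

    def rng_for(self, stream_key: tuple[int, ...]) -> np.random.Generator:
        """Independent, reproducible generator for one (run, trial) stream."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), *map(int, stream_key)])
        )


@dataclass
class MotionModel:
    """Per-trial 2D rigid motion: explicit list or seeded random walk.

    ``mode="none"`` is the identity; ``mode="list"`` takes explicit
    ``(dx_px, dy_px, theta_deg)`` triples per trial; ``mode="random_walk"``
    accumulates independent Gaussian steps of standard deviation
    ``step_px`` / ``step_deg`` per trial, deterministically from ``seed``.
    """

    mode: str = "none"
    transforms: list[tuple[float, float, float]] = field(default_factory=list)
    step_px: float = 0.0
    step_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "list", "random_walk"):
            raise ValueError(f"unknown motion mode {self.mode!r}")

    def params_for_trials(self, n_trials: int) -> np.ndarray:
        """(n_trials, 3) array of (dx_px, dy_px, theta_deg) per trial."""
        if self.mode == "none":
            return np.zeros((n_trials, 3))
        if self.mode == "list":
            if len(self.transforms) < n_trials:
                raise ValueError("not enough explicit motion transforms")
            return np.asarray(self.transforms[:n_trials], dtype=float)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 74]))
        steps = rng.normal(
            0.0, [self.step_px, self.step_px, self.step_deg], size=(n_trials, 3)
        )
        return np.cumsum(steps, axis=0)


def _disk(n: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def make_default_phantom(matrix_size: int = 96, preset: str = "brain_slice") -> DigitalPhantom:
    """Deterministic factory for the built-in phantom presets.

    ``brain_slice``: concentric WM core / GM ring / CSF rim with three ROIs —
    ``target_v1`` (posterior GM wedge, standing in for calcarine cortex),
    ``control_gm`` (anterior GM, voxel count matched exactly to the target to
    equate statistical power) and ``control_wm``.  ``tubes``: three disks with
    distinct T1 (``tube_1``..``tube_3`` plus their union ``tubes``).

    Geometry scales with ``matrix_size`` (>= 16) so the same presets serve
    both protocol-size (96/192) and scaled-down simulations.
    """
    n = int(matrix_size)
    if n < 16:
        raise ValueError("matrix_size must be >= 16")
    c = (n - 1) / 2.0

    if preset == "brain_slice":
        grid = np.zeros((n, n), dtype=int)
        grid[_disk(n, c, c, 0.46 * n)] = 3  # CSF rim
        grid[_disk(n, c, c, 0.41 * n)] = 2  # GM ring
        grid[_disk(n, c, c, 0.30 * n)] = 1  # WM core
        yy, xx = np.mgrid[0:n, 0:n]
        gm = grid == 2
        wm = grid == 1
        # posterior (large-y) medial wedge of GM
        target = gm & (yy >= 0.72 * n) & (np.abs(xx - c) <= 0.15 * n)
        if not target.any():
            raise ValueError("matrix too small for target ROI")
        n_t = int(target.sum())
        # anterior GM, matched voxel count (deterministic raster order)
        cand = np.flatnonzero((gm & (yy <= 0.30 * n)).ravel())
        if cand.size < n_t:
            raise ValueError("not enough anterior GM for matched control ROI")
        control_gm = np.zeros(n * n, dtype=bool)
        control_gm[cand[:n_t]] = True
        control_gm = control_gm.reshape(n, n)
        cand_wm = np.flatnonzero((wm & (yy <= c)).ravel())
        control_wm = np.zeros(n * n, dtype=bool)
        control_wm[cand_wm[: min(n_t, cand_wm.size)]] = True
        control_wm = control_wm.reshape(n, n)
        rois = {
            "target_v1": target,
            "control_gm": control_gm,
            "control_wm": control_wm,
        }
        return DigitalPhantom(grid, dict(BRAIN_COMPARTMENTS), rois, preset=preset)

    if preset == "tubes":
        grid = np.zeros((n, n), dtype=int)
        r = 0.13 * n
        centers = [
            (0.32 * n, 0.34 * n),
            (0.68 * n, 0.34 * n),
            (0.50 * n, 0.68 * n),
        ]
        rois: dict[str, np.ndarray] = {}
        for label, (cx, cy) in enumerate(centers, start=1):
            mask = _disk(n, cx, cy, r)
            grid[mask] = label
            rois[f"tube_{label}"] = mask
        rois["tubes"] = grid > 0
        return DigitalPhantom(grid, dict(TUBE_COMPARTMENTS), rois, preset=preset)

    raise ValueError(f"unknown phantom preset {preset!r}")


def baseline_image(phantom: DigitalPhantom, seq: SequenceParams) -> np.ndarray:
    """Steady-state SPGRE magnitude image of the phantom (float, 2D)."""
    img = np.zeros(phantom.grid.shape, dtype=float)
    for label, tissue in phantom.compartments.items():
        img[phantom.grid == label] = steady_state_signal(seq, tissue)
    return img


def thermal_sigma_abs(phantom: DigitalPhantom, seq: SequenceParams, noise: NoiseModel) -> float:
    """Absolute thermal noise standard deviation implied by the model."""
    base = baseline_image(phantom, seq)
    obj = base[phantom.grid > 0]
    ref = float(obj.mean()) if obj.size else 0.0
    return noise.thermal_sigma_pct / 100.0 * ref


def thermal_pct_for_target_tsnr(
    phantom: DigitalPhantom,
    seq: SequenceParams,
    roi: str,
    target_tsnr: float,
) -> float:
    """Thermal noise level (percent) giving a chosen per-voxel tSNR in ``roi``.

    Accounts for the fact that after assembling k-space from independently
    noisy samples and taking the image magnitude, only the real quadrature of
    the complex voxel noise perturbs the magnitude, so the effective
    per-voxel standard deviation is ``sigma/sqrt(2)``.
    """
    base = baseline_image(phantom, seq)
    obj = base[phantom.grid > 0]
    roi_mean = float(base[phantom.rois[roi]].mean())
    ref = float(obj.mean())
    return 100.0 * np.sqrt(2.0) * roi_mean / (target_tsnr * ref)


def trial_images(
    phantom: DigitalPhantom,
    seq: SequenceParams,
    t_abs_s: np.ndarray,
    t_phase_ms: np.ndarray,
    response: ResponseModel | None = None,
    drift: DriftModel | None = None,
    noise: NoiseModel | None = None,
    motion_params: tuple[float, float, float] | None = None,
    stream_key: tuple[int, ...] = (0,),
) -> np.ndarray:
    """Instantaneous voxel images at the sample times of one trial.

    Returns a ``(len(t_abs_s), N, N)`` stack: the (possibly rigidly moved)
    baseline, response-modulated in active voxels at the given trial phases,
    scaled by drift and physiological factors at the absolute times, plus
    thermal noise drawn from the trial's seeded stream.
    """
    t_abs = np.asarray(t_abs_s, dtype=float)
    t_phase = np.asarray(t_phase_ms, dtype=float)
    if t_abs.shape != t_phase.shape:
        raise ValueError("t_abs_s and t_phase_ms must have the same shape")

    base = baseline_image(phantom, seq)
    if response is not None and response.amplitude_pct != 0.0:
        active = phantom.rois[response.active_roi]
        base_active = np.where(active, base, 0.0)
    else:
        base_active = None

    if motion_params is not None and np.any(np.asarray(motion_params) != 0):
        from .recon import RigidTransform2D, apply_rigid2d

        t = RigidTransform2D(*motion_params)
        base = apply_rigid2d(base, t)
        if base_active is not None:
            base_active = apply_rigid2d(base_active, t)

    k = t_abs.size
    stack = np.broadcast_to(base, (k,) + base.shape).copy()
    if base_active is not None:
        rf = response.factor(t_phase) - 1.0
        stack += rf[:, None, None] * base_active

    factor = np.ones(k)
    if drift is not None:
        factor = factor * drift.factor(t_abs)
    if noise is not None and noise.physio_components:
        factor = factor * noise.physio_factor(t_abs)
    stack *= factor[:, None, None]

    if noise is not None and noise.thermal_sigma_pct > 0:
        sigma = thermal_sigma_abs(phantom, seq, noise)
        rng = noise.rng_for(stream_key)
        stack += rng.normal(0.0, sigma, size=stack.shape)
    return stack


def voxel_timeseries(
    phantom: DigitalPhantom,
    seq: SequenceParams,
    trial_timepoints_m: int,
    trial_index: int = 0,
    response: ResponseModel | None = None,
    drift: DriftModel | None = None,
    noise: NoiseModel | None = None,
    motion: MotionModel | None = None,
    run_start_s: float = 0.0,
    run_key: int = 0,
) -> np.ndarray:
    """Per-voxel signal at each of the M time points of one trial.

    Convenience wrapper over :func:`trial_images` with the DIANA timing
    convention: the trial starts at ``run_start_s + trial_index * M * TR``,
    sample m occurs ``m * TR`` after the stimulus onset (trial phase 0).
    """
    m_idx = np.arange(int(trial_timepoints_m))
    tr_s = seq.tr_ms / 1000.0
    t_phase = m_idx * seq.tr_ms
    t_abs = run_start_s + (trial_index * trial_timepoints_m + m_idx) * tr_s
    motion_params = None
    if motion is not None and motion.mode != "none":
        motion_params = tuple(motion.params_for_trials(trial_index + 1)[trial_index])
    return trial_images(
        phantom,
        seq,
        t_abs,
        t_phase,
        response=response,
        drift=drift,
        noise=noise,
        motion_params=motion_params,
        stream_key=(run_key, trial_index),
    )
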