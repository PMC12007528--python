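"""Acquisition schedules and k-space sampling for DIANA and conventional SPGRE.

A conventional single-slice SPGRE run acquires the N phase-encode lines of
each image consecutively, so the k-space centre is revisited every N * TR and
slow scanner drift shows up as a ramp across sequential images.  The DIANA
scheme swaps the phase and measurement loops: each trial (one stimulus + ISI
cycle of M = (stim + ISI)/TR time points) repeatedly samples a single line,
and N trials fill the N lines of an M-image time series.  The centre line is
then revisited only every N * M * TR, turning drift into an inter-run step.

``simulate_acquisition`` samples either schedule from the digital phantom: at
every excitation the instantaneous voxel image is evaluated (response, drift,
noise and per-trial rigid motion included), Fourier transformed, and the
scheduled phase-encode line is stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bloch import SequenceParams
from .phantom import (
    DigitalPhantom,
    DriftModel,
    MotionModel,
    NoiseModel,
    ResponseModel,
    trial_images,
)

__all__ = [
    "Paradigm",
    "PARADIGM_PRESETS",
    "get_paradigm",
    "AcquisitionSchedule",
    "KSpaceSeries",
    "diana_schedule",
    "spgre_schedule",
    "simulate_acquisition",
    "run_duration_s",
    "scan_duration_s",
    "spgre_discard_count",
    "trial_timepoints",
    "DEFAULT_SEQUENCE",
]

#: Protocol sequence parameters: TR 5 ms, TE 2.4 ms, FA 4 deg, 50 deg cycling.
DEFAULT_SEQUENCE = SequenceParams(tr_ms=5.0, te_ms=2.4, fa_deg=4.0)


def trial_timepoints(stim_ms: float, isi_ms: float, tr_ms: float) -> int:
    """Number of time points per trial, M = (stimulus + ISI) / TR.

    The trial length must be an integer multiple of TR.
    """
    total = stim_ms + isi_ms
    m = total / tr_ms
    if abs(m - round(m)) > 1e-9:
        raise ValueError(
            f"trial duration {total} ms is not divisible by TR {tr_ms} ms"
        )
    return int(round(m))


def run_duration_s(n_lines: int, trial_timepoints_m: int, tr_ms: float) -> float:
    """Duration of one fully sampled run: N * M * TR, in seconds."""
    if n_lines < 1 or trial_timepoints_m < 1 or tr_ms <= 0:
        raise ValueError("N, M and TR must be positive")
    return n_lines * trial_timepoints_m * tr_ms / 1000.0


def scan_duration_s(
    n_runs: int, n_dummy: int, n_lines: int, trial_timepoints_m: int, tr_ms: float
) -> float:
    """Duration of one scan: dummy period plus ``n_runs`` back-to-back runs."""
    if n_runs < 0 or n_dummy < 0:
        raise ValueError("n_runs and n_dummy must be >= 0")
    return n_dummy * tr_ms / 1000.0 + n_runs * run_duration_s(
        n_lines, trial_timepoints_m, tr_ms
    )


def spgre_discard_count(n_settle_trs: int, n_lines: int) -> int:
    """Initial SPGRE images to discard so that >= ``n_settle_trs`` TRs have
    elapsed: ``ceil(n_settle_trs / N)``."""
    if n_settle_trs < 0 or n_lines < 1:
        raise ValueError("invalid settle/line counts")
    return math.ceil(n_settle_trs / n_lines)


@dataclass(frozen=True)
class Paradigm:
    """Stimulation paradigm plus matrix/protocol bookkeeping (one Table row
    of the visual-protocol presets)."""

    name: str
    stim_ms: float
    isi_ms: float
    n_runs_per_scan: int
    n_scans: int
    matrix_n: int
    tr_ms: float = 5.0
    resolution: str = "2x2x5mm"
    stimulus_type: str = "noise"

    def __post_init__(self) -> None:
        trial_timepoints(self.stim_ms, self.isi_ms, self.tr_ms)  # validates

    @property
    def trial_timepoints_m(self) -> int:
        return trial_timepoints(self.stim_ms, self.isi_ms, self.tr_ms)

    @property
    def trial_duration_ms(self) -> float:
        return self.stim_ms + self.isi_ms

    def run_duration_s(self) -> float:
        return run_duration_s(self.matrix_n, self.trial_timepoints_m, self.tr_ms)


PARADIGM_PRESETS: dict[str, Paradigm] = {
    "paradigm_I": Paradigm("paradigm_I", 50, 550, 11, 3, 96, stimulus_type="noise"),
    "paradigm_II": Paradigm("paradigm_II", 200, 500, 10, 3, 96, stimulus_type="noise"),
    "paradigm_III": Paradigm("paradigm_III", 100, 600, 11, 3, 96, stimulus_type="noise"),
    "paradigm_IV": Paradigm(
        "paradigm_IV", 100, 600, 11, 4, 96, stimulus_type="naturalistic"
    ),
    "paradigm_V": Paradigm(
        "paradigm_V",
        100,
        600,
        11,
        4,
        192,
        resolution="1x1x5mm",
        stimulus_type="naturalistic",
    ),
}


def get_paradigm(name: str) -> Paradigm:
    try:
        return PARADIGM_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown paradigm preset {name!r}; available: {sorted(PARADIGM_PRESETS)}"
        ) from None


@dataclass
class AcquisitionSchedule:
    """Ordered excitation events of one run.

    Each event is a (phase_line, time_point, trial_index, absolute_time_s)
    tuple stored columnwise.  ``mode`` is ``"diana"`` (trial-major: all M
    time points of one line consecutively) or ``"spgre"`` (image-major: all N
    lines of one image consecutively).  Dummy excitations occupy the
    ``n_dummy * TR`` interval before the first event.
    """

    mode: str
    n_lines: int
    n_timepoints: int
    tr_ms: float
    n_dummy: int
    start_time_s: float
    phase_line: np.ndarray
    time_point: np.ndarray
    trial_index: np.ndarray
    absolute_time_s: np.ndarray

    @property
    def n_events(self) -> int:
        return self.phase_line.size

    @property
    def first_event_time_s(self) -> float:
        return self.start_time_s + self.n_dummy * self.tr_ms / 1000.0

    def center_line_times(self) -> np.ndarray:
        """Absolute times at which the centre phase-encode line is sampled."""
        return self.absolute_time_s[self.phase_line == self.n_lines // 2]


def _line_order(n: int, order: str) -> np.ndarray:
    if order == "sequential":
        return np.arange(n)
    if order == "centric":
        # centre line first, then alternating outwards
        centre = n // 2
        offsets = np.empty(n, dtype=int)
        offsets[0] = 0
        k = np.arange(1, n)
        alt = np.where(k % 2 == 1, (k + 1) // 2, -(k // 2))
        offsets[1:] = alt
        lines = centre + offsets
        lines[lines < 0] += n
        lines[lines >= n] -= n
        return lines
    raise ValueError(f"unknown line order {order!r}")


def diana_schedule(
    n_lines: int,
    trial_timepoints_m: int,
    n_dummy: int = 0,
    tr_ms: float = 5.0,
    start_time_s: float = 0.0,
    line_order: str = "sequential",
) -> AcquisitionSchedule:
    """Loop-swapped schedule: trial k samples one line at all M time points.

    Produces ``N * M`` events after the dummy period; absolute times increase
    strictly by TR.  All M centre-line events fall inside a single trial, so
    consecutive centre-line passes in successive runs are ``N * M * TR``
    apart.
    """
    n, m = int(n_lines), int(trial_timepoints_m)
    if n < 1 or m < 1:
        raise ValueError("N and M must be >= 1")
    lines = _line_order(n, line_order)
    trial = np.repeat(np.arange(n), m)
    phase_line = np.repeat(lines, m)
    time_point = np.tile(np.arange(m), n)
    event = np.arange(n * m)
    t_abs = start_time_s + (n_dummy + event) * tr_ms / 1000.0
    return AcquisitionSchedule(
        mode="diana",
        n_lines=n,
        n_timepoints=m,
        tr_ms=tr_ms,
        n_dummy=int(n_dummy),
        start_time_s=start_time_s,
        phase_line=phase_line,
        time_point=time_point,
        trial_index=trial,
        absolute_time_s=t_abs,
    )


def spgre_schedule(
    n_lines: int,
    n_images: int,
    n_dummy: int = 0,
    tr_ms: float = 5.0,
    start_time_s: float = 0.0,
    line_order: str = "sequential",
) -> AcquisitionSchedule:
    """Conventional schedule: image i acquires all N lines consecutively.

    The centre line is passed once per image, every ``N * TR``.
    ``trial_index`` doubles as the image index (motion is per image).
    """
    n, ni = int(n_lines), int(n_images)
    if n < 1 or ni < 1:
        raise ValueError("N and n_images must be >= 1")
    lines = _line_order(n, line_order)
    phase_line = np.tile(lines, ni)
    time_point = np.repeat(np.arange(ni), n)
    event = np.arange(n * ni)
    t_abs = start_time_s + (n_dummy + event) * tr_ms / 1000.0
    return AcquisitionSchedule(
        mode="spgre",
        n_lines=n,
        n_timepoints=ni,
        tr_ms=tr_ms,
        n_dummy=int(n_dummy),
        start_time_s=start_time_s,
        phase_line=phase_line,
        time_point=time_point,
        trial_index=time_point.copy(),
        absolute_time_s=t_abs,
    )


@dataclass
class KSpaceSeries:
    """Complex k-space samples indexed (time_point, phase_line, readout).

    ``filled`` marks which (time_point, line) pairs have been acquired; a
    series is fully sampled when every pair is filled exactly once.
    """

    data: np.ndarray
    schedule: AcquisitionSchedule
    filled: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_lines(self) -> int:
        return self.data.shape[1]

    @property
    def fully_sampled(self) -> bool:
        return bool(self.filled.all())

    def copy(self) -> "KSpaceSeries":
        return KSpaceSeries(self.data.copy(), self.schedule, self.filled.copy())


def simulate_acquisition(
    phantom: DigitalPhantom,
    seq: SequenceParams,
    schedule: AcquisitionSchedule,
    response: ResponseModel | None = None,
    drift: DriftModel | None = None,
    noise: NoiseModel | None = None,
    motion: MotionModel | None = None,
    trial_duration_ms: float | None = None,
    run_key: tuple[int, ...] | int = 0,
) -> KSpaceSeries:
    """Sample k-space from the phantom along an acquisition schedule.

    For every event the instantaneous image at the event's absolute time is
    built (per-trial rigid motion, stimulus-locked response at the event's
    trial phase, drift/physio scaling, thermal noise), the 2D DFT is taken
    and the scheduled phase-encode row is stored.  Deterministic given the
    model seeds and ``run_key`` (which namespaces the noise streams of this
    run).

    ``trial_duration_ms`` anchors the stimulus phase; it defaults to
    ``M * TR`` for DIANA schedules and is required when injecting a response
    into an SPGRE schedule.
    """
    n = phantom.matrix_size
    if schedule.n_lines != n:
        raise ValueError(
            f"schedule has {schedule.n_lines} lines but phantom matrix is {n}"
        )
    if trial_duration_ms is None:
        if schedule.mode == "diana":
            trial_duration_ms = schedule.n_timepoints * schedule.tr_ms
        elif response is not None:
            raise ValueError("trial_duration_ms required for SPGRE with a response")

    key = (run_key,) if isinstance(run_key, (int, np.integer)) else tuple(run_key)
    data = np.zeros((schedule.n_timepoints, n, n), dtype=complex)
    filled = np.zeros((schedule.n_timepoints, n), dtype=bool)

    trials = np.unique(schedule.trial_index)
    motion_params = None
    if motion is not None and motion.mode != "none":
        motion_params = motion.params_for_trials(int(trials.max()) + 1)

    anchor_ms = schedule.first_event_time_s * 1000.0
    for trial in trials:
        sel = schedule.trial_index == trial
        t_abs = schedule.absolute_time_s[sel]
        if trial_duration_ms is not None:
            # round away float jitter so boxcar edges fall on exact sample times
            t_phase = np.round(
                (t_abs * 1000.0 - anchor_ms) % trial_duration_ms, 6
            )
            t_phase[t_phase >= trial_duration_ms] -= trial_duration_ms
        else:
            t_phase = np.zeros_like(t_abs)
        stack = trial_images(
            phantom,
            seq,
            t_abs,
            t_phase,
            response=response,
            drift=drift,
            noise=noise,
            motion_params=None
            if motion_params is None
            else tuple(motion_params[int(trial)]),
            stream_key=(*key, int(trial)),
        )
        rows = np.fft.fft2(stack, axes=(-2, -1))
        lines = schedule.phase_line[sel]
        tps = schedule.time_point[sel]
        data[tps, lines, :] = rows[np.arange(rows.shape[0]), lines, :]
        filled[tps, lines] = True
    return KSpaceSeries(data=data, schedule=schedule, filled=filled)
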