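"""Offline reconstruction and 2D rigid motion correction.

Reconstruction is a per-time-point inverse 2D DFT of the fully sampled
k-space followed by the magnitude, with optional 16-bit linear quantization
(the offline dynamic range used for the in-vivo data; off by default since it
is a fidelity stressor, not required for correctness).

Motion correction registers every image of a run to a reference image (by
convention the temporal mean of a designated run) with a 2D rigid transform.
The solver is a phase-correlation translation initializer refined by a local
least-squares search over (dx, dy, theta); the accuracy contract is sub-0.1
pixel / 0.1 degree recovery of known transforms on noise-free images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .acquisition import KSpaceSeries

__all__ = [
    "ImageSeries",
    "RigidTransform2D",
    "UndersampledKSpaceError",
    "reconstruct",
    "apply_rigid2d",
    "estimate_rigid2d",
    "motion_correct",
]


class UndersampledKSpaceError(ValueError):
    """Raised when reconstruction is attempted on missing phase lines."""


@dataclass
class ImageSeries:
    """Magnitude image time series of one run."""

    data: np.ndarray  # (n_timepoints, N, N), non-negative
    tr_ms: float = 5.0
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 5.0)
    run_index: int = 0
    scan_index: int = 0
    quantized: bool = False

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def run_mean(self) -> np.ndarray:
        return self.data.mean(axis=0)


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: translation (pixels) and CCW rotation (deg).

    ``ok`` flags whether an estimate converged; it does not enter the
    geometry.  Identity is ``(0, 0, 0)``.
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    theta_deg: float = 0.0
    ok: bool = True

    def inverse(self) -> "RigidTransform2D":
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        # inverse of p -> R p + t is p -> R^-1 (p - t)
        dx = -(c * self.dx_px - s * self.dy_px)
        dy = -(s * self.dx_px + c * self.dy_px)
        return RigidTransform2D(dx, dy, -self.theta_deg, ok=self.ok)

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        th = np.deg2rad(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        dx = c * other.dx_px + s * other.dy_px + self.dx_px
        dy = -s * other.dx_px + c * other.dy_px + self.dy_px
        return RigidTransform2D(
            dx, dy, self.theta_deg + other.theta_deg, ok=self.ok and other.ok
        )

    @property
    def params(self) -> np.ndarray:
        return np.array([self.dx_px, self.dy_px, self.theta_deg])


def apply_rigid2d(
    image: np.ndarray, transform: RigidTransform2D, order: int = 3
) -> np.ndarray:
    """Move an image by a rigid transform (rotation about the image centre,
    then translation), with spline interpolation and zero-filled edges."""
    th = np.deg2rad(transform.theta_deg)
    c, s = np.cos(th), np.sin(th)
    centre = (np.asarray(image.shape) - 1) / 2.0
    t = np.array([transform.dy_px, transform.dx_px])  # (row, col)
    # output(p) = input(Rinv (p - c - t) + c)
    rinv = np.array([[c, s], [-s, c]])  # rotation by -theta in (row, col)
    offset = centre - rinv @ (centre + t)
    return ndimage.affine_transform(
        image, rinv, offset=offset, order=order, mode="constant", cval=0.0
    )


def estimate_rigid2d(
    moving: np.ndarray,
    reference: np.ndarray,
    margin_px: int = 5,
) -> RigidTransform2D:
    """Estimate the rigid transform aligning ``moving`` to ``reference``.

    Minimizes the sum of squared intensity differences between the warped
    moving image and the reference, evaluated away from the image borders
    (``margin_px``) so the zero-filled edge band introduced by resampling
    does not bias the fit.  Translation is initialized by subpixel phase
    correlation; a Powell search then refines (dx, dy, theta) jointly.
    Degenerate (constant) inputs return the identity flagged ``ok=False``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must have the same shape")
    if moving.std() == 0 or reference.std() == 0:
        return RigidTransform2D(ok=False)

    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=50, normalization=None
    )
    x0 = np.array([shift[1], shift[0], 0.0])
    m = margin_px
    core = (slice(m, -m), slice(m, -m)) if m > 0 else (slice(None), slice(None))

    def cost(p: np.ndarray) -> float:
        warped = apply_rigid2d(moving, RigidTransform2D(p[0], p[1], p[2]))
        return float(np.sum((warped[core] - reference[core]) ** 2))

    res = optimize.minimize(
        cost,
        x0,
        method="Powell",
        options={"xtol": 1e-5, "ftol": 1e-12, "maxiter": 400},
    )
    dx, dy, th = res.x
    return RigidTransform2D(float(dx), float(dy), float(th), ok=bool(res.success))


def reconstruct(
    kspace: KSpaceSeries,
    quantize_16bit: bool = False,
    tr_ms: float | None = None,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 5.0),
    run_index: int = 0,
    scan_index: int = 0,
) -> ImageSeries:
    """Inverse-DFT magnitude reconstruction of a fully sampled k-space run.

    ``quantize_16bit`` linearly maps the run onto the 16-bit integer range
    (scale = run maximum) and back, emulating a 16-bit offline dynamic range.
    """
    if not kspace.fully_sampled:
        missing = int((~kspace.filled).sum())
        raise UndersampledKSpaceError(
            f"k-space is undersampled: {missing} (time point, line) pairs missing"
        )
    img = np.abs(np.fft.ifft2(kspace.data, axes=(-2, -1)))
    if quantize_16bit:
        scale = img.max()
        if scale > 0:
            img = np.round(img / scale * 65535.0) / 65535.0 * scale
    return ImageSeries(
        data=img,
        tr_ms=kspace.schedule.tr_ms if tr_ms is None else tr_ms,
        voxel_size_mm=voxel_size_mm,
        run_index=run_index,
        scan_index=scan_index,
        quantized=quantize_16bit,
    )


def motion_correct(
    series: ImageSeries,
    reference: np.ndarray | None = None,
) -> tuple[ImageSeries, pd.DataFrame]:
    """Register every image of a run to a reference and resample.

    ``reference`` defaults to the run's own temporal mean (the protocol
    builds it by averaging one designated run; pass that mean explicitly to
    correct other runs against it).  Returns the corrected series and a
    table of per-time-point transforms with an ``ok`` column; estimation
    failures are flagged, never silently dropped (the frame is left
    uncorrected).
    """
    if reference is None:
        reference = series.run_mean()
    corrected = np.empty_like(series.data)
    rows = []
    for t in range(series.n_timepoints):
        tf = estimate_rigid2d(series.data[t], reference)
        if tf.ok:
            corrected[t] = apply_rigid2d(series.data[t], tf)
        else:
            corrected[t] = series.data[t]
        rows.append(
            {
                "time_point": t,
                "dx_px": tf.dx_px,
                "dy_px": tf.dy_px,
                "theta_deg": tf.theta_deg,
                "ok": tf.ok,
            }
        )
    out = ImageSeries(
        data=np.clip(corrected, 0.0, None),
        tr_ms=series.tr_ms,
        voxel_size_mm=series.voxel_size_mm,
        run_index=series.run_index,
        scan_index=series.scan_index,
        quantized=series.quantized,
    )
    return out, pd.DataFrame(rows)
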