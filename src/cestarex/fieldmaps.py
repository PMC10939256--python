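"""Per-voxel B0, B1 and T1 field mapping.

B0 is located from the minimum of the low-power WASSR dip, B1 from the
double-angle signal ratio, and T1 from a two-parameter saturation-recovery
fit to a variable-TR series.  Voxels failing any fit are removed from the
common analysis mask (intersection semantics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import least_squares

from .pools import ZSpectrum

T1_BOUNDS = (0.05, 10.0)  # s


class OutOfRangeError(ValueError):
    """Estimated quantity fell on the boundary of the sampled range."""


class CorrectionFailedError(RuntimeError):
    """B0 correction left no valid samples."""


@dataclass
class FieldMaps:
    """Per-voxel B0 shift (ppm), B1 ratio (actual/nominal) and T1 (s)."""

    b0_shift: np.ndarray
    b1_ratio: np.ndarray
    t1: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        m = self.mask.astype(bool)
        if np.any(self.b1_ratio[m] <= 0):
            raise ValueError("b1_ratio must be positive inside the mask")
        if np.any(self.t1[m] <= 0):
            raise ValueError("t1 must be positive inside the mask")


def estimate_b0_wassr(wassr: ZSpectrum, grid_step: float = 0.001) -> float:
    """Water-frequency shift from the minimum of the WASSR dip.

    A cubic spline is fitted to the sampled spectrum and evaluated on a fine
    (default 0.001 ppm) grid; the argmin is the per-voxel B0 shift in ppm.

    Raises
    ------
    OutOfRangeError
        If the minimum lies at the boundary of the sampled range — the true
        dip is then outside the sweep and the voxel should be masked out.
    """
    spec = wassr.sorted()
    if len(spec) < 9:
        raise ValueError("WASSR needs at least 9 offsets spanning the dip")
    spline = CubicSpline(spec.offsets, spec.z)
    fine = np.arange(spec.offsets[0], spec.offsets[-1] + grid_step / 2, grid_step)
    shift = float(fine[np.argmin(spline(fine))])
    edge = max(grid_step, (spec.offsets[1] - spec.offsets[0]) / 2)
    if shift <= spec.offsets[0] + edge or shift >= spec.offsets[-1] - edge:
        raise OutOfRangeError(
            f"WASSR minimum at {shift:.3f} ppm lies at the sampled boundary"
        )
    return shift


def apply_b0_shift(zspec: ZSpectrum, b0_shift: float) -> ZSpectrum:
    """Resample a Z-spectrum onto its nominal offsets given a B0 shift.

    The voxel's true saturation offset was ``nominal + b0_shift``; monotone
    cubic (PCHIP) interpolation of the measured spectrum at the shifted
    positions recenters it.  Offsets falling outside the sampled range are
    returned as NaN (missing), never extrapolated.
    """
    if b0_shift == 0.0:
        return ZSpectrum(zspec.offsets.copy(), zspec.z.copy())
    spec = zspec.sorted()
    interp = PchipInterpolator(spec.offsets, spec.z, extrapolate=False)
    target = zspec.offsets + b0_shift
    z = interp(target)
    if np.all(np.isnan(z)):
        raise CorrectionFailedError(
            f"B0 shift {b0_shift} ppm moved all offsets out of range"
        )
    return ZSpectrum(zspec.offsets.copy(), z)


def estimate_b1_double_angle(
    img_alpha, img_2alpha, nominal_alpha_deg: float = 30.0
):
    """B1 transmit ratio from a double-angle image pair.

    With signals S1 ∝ sin(θ) and S2 ∝ sin(2θ) = 2 sin(θ) cos(θ), the actual
    flip is θ = arccos(S2 / (2·S1)); the returned ratio is θ divided by the
    nominal flip angle.  The arccos argument is clamped to [−1, 1]; clamped
    voxels are flagged low-confidence, voxels with S1 ≤ 0 are masked.

    Returns
    -------
    b1_ratio : ndarray
    valid : boolean ndarray (S1 > 0)
    flagged : boolean ndarray (argument clamped)
    """
    s1 = np.asarray(img_alpha, dtype=float)
    s2 = np.asarray(img_2alpha, dtype=float)
    valid = s1 > 0
    ratio_arg = np.full_like(s1, np.nan)
    np.divide(s2, 2.0 * s1, out=ratio_arg, where=valid)
    flagged = valid & (np.abs(ratio_arg) > 1)
    theta = np.arccos(np.clip(ratio_arg, -1.0, 1.0))
    b1_ratio = np.where(valid, theta / np.deg2rad(nominal_alpha_deg), np.nan)
    return b1_ratio, valid, flagged


@dataclass
class T1FitResults:
    """Saturation-recovery fit output: T1 (s), S0, residual norm, QC flag."""

    t1: float
    s0: float
    residual: float
    converged: bool
    at_bound: bool

    @property
    def flagged(self) -> bool:
        return self.at_bound or not self.converged

    def summary(self) -> str:
        return (
            f"Saturation-recovery T1 fit\n"
            f"  T1        {self.t1:.4f} s\n"
            f"  S0        {self.s0:.4f}\n"
            f"  residual  {self.residual:.3e}\n"
            f"  flagged   {self.flagged}"
        )


class SaturationRecoveryT1Model:
    """Two-parameter saturation-recovery model S(TR) = S0·(1 − exp(−TR/T1)).

    TE decay is constant across the TR series and is absorbed into S0.

    Parameters
    ----------
    signals : array-like
        Non-negative signal intensities, one per TR.
    tr_list : array-like
        Repetition times in seconds, at least 3 distinct values.
    """

    def __init__(self, signals, tr_list):
        self.signals = np.asarray(signals, dtype=float)
        self.tr = np.asarray(tr_list, dtype=float)
        if self.signals.shape != self.tr.shape:
            raise ValueError("signals and tr_list must have equal length")
        if len(np.unique(self.tr)) < 3:
            raise ValueError("need at least 3 distinct TRs")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")

    @staticmethod
    def model(tr, s0, t1):
        return s0 * (1.0 - np.exp(-tr / t1))

    def fit(self) -> T1FitResults:
        smax = float(self.signals.max())
        if smax <= 0:
            return T1FitResults(T1_BOUNDS[0], 0.0, 0.0, False, True)
        s0_init = smax
        t1_init = 1.5

        def resid(p):
            return self.model(self.tr, p[0], p[1]) - self.signals

        sol = least_squares(
            resid,
            x0=[s0_init, t1_init],
            bounds=([1e-12, T1_BOUNDS[0]], [np.inf, T1_BOUNDS[1]]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
        )
        t1 = float(sol.x[1])
        tol = 1e-9
        at_bound = t1 <= T1_BOUNDS[0] + tol or t1 >= T1_BOUNDS[1] - tol
        return T1FitResults(
            t1=t1,
            s0=float(sol.x[0]),
            residual=float(np.linalg.norm(sol.fun)),
            converged=bool(sol.success),
            at_bound=at_bound,
        )


def fit_t1_variable_tr(signals, tr_list) -> T1FitResults:
    """Convenience wrapper: fit one voxel's variable-TR series."""
    return SaturationRecoveryT1Model(signals, tr_list).fit()
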