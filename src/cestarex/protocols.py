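"""Shipped acquisition protocols.

Two CEST saturation protocols (a high-power glutamate-weighted one and a
low-power creatine-weighted one with a piecewise asymmetric offset list), a
WASSR B0-mapping sweep, a double-angle B1 pair and a variable-TR T1 series.
All offsets in ppm, times in s, B1 in μT.
"""

from __future__ import annotations

import numpy as np

from .pools import SaturationProtocol


def _arange_inclusive(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def simulation_offsets() -> np.ndarray:
    """Dense symmetric grid for numerical experiments: −8…8 ppm, 0.08 steps."""
    return _arange_inclusive(-8.0, 8.0, 0.08)


def glu_offsets(n: int = 57) -> np.ndarray:
    """Glutamate-protocol offsets: n uniformly spaced over [−8, 8] ppm.

    The acquisition used 57 offsets over that range; the exact spacing is
    not enumerated, so a uniform grid is the default.
    """
    return np.linspace(-8.0, 8.0, n)


def cr_offsets() -> np.ndarray:
    """Creatine-protocol piecewise asymmetric offsets.

    Enumerating the five printed intervals (−8…0 by 0.25, 0.05…2.75 by 0.1,
    2.8…4.3 by 0.125, 4.4…6 by 0.2, 6.5…8 by 0.5) yields 87 offsets.
    """
    parts = [
        _arange_inclusive(-8.0, 0.0, 0.25),
        _arange_inclusive(0.05, 2.75, 0.1),
        _arange_inclusive(2.8, 4.3, 0.125),
        _arange_inclusive(4.4, 6.0, 0.2),
        _arange_inclusive(6.5, 8.0, 0.5),
    ]
    return np.concatenate(parts)


def wassr_offsets() -> np.ndarray:
    """WASSR sweep: 81 offsets, −1…1 ppm with 0.025 ppm increment."""
    return _arange_inclusive(-1.0, 1.0, 0.025)


def glu_protocol(**overrides) -> SaturationProtocol:
    """High-power protocol: B1 = 5.9 μT, 1000 ms saturation."""
    kw = dict(b1_amp=5.9, t_sat=1.0, tr=5.0, offsets=tuple(glu_offsets()))
    kw.update(overrides)
    return SaturationProtocol(**kw)


def cr_protocol(**overrides) -> SaturationProtocol:
    """Low-power protocol: B1 = 1.47 μT, 3500 ms saturation."""
    kw = dict(b1_amp=1.47, t_sat=3.5, tr=5.0, offsets=tuple(cr_offsets()))
    kw.update(overrides)
    return SaturationProtocol(**kw)


def wassr_protocol(**overrides) -> SaturationProtocol:
    """WASSR B0-mapping protocol: B1 = 0.05 μT, 1000 ms saturation."""
    kw = dict(b1_amp=0.05, t_sat=1.0, tr=5.0, offsets=tuple(wassr_offsets()))
    kw.update(overrides)
    return SaturationProtocol(**kw)


def simulation_protocol(**overrides) -> SaturationProtocol:
    """Protocol for the numerical experiments: TR = 8 s, dense offset grid."""
    kw = dict(
        b1_amp=5.9, t_sat=1.0, tr=8.0, offsets=tuple(simulation_offsets())
    )
    kw.update(overrides)
    return SaturationProtocol(**kw)


#: variable-TR series for saturation-recovery T1 mapping (s)
VTR_TR_LIST = (0.25, 0.5, 1.0, 1.5, 2.0, 3.5, 5.0, 8.0)

#: double-angle nominal flip angles (degrees)
DOUBLE_ANGLE_DEG = (30.0, 60.0)

#: default B1 sweep for the numerical contrast experiments
SWEEP_B1_GRID = tuple(np.arange(0.5, 8.6, 1.0))       # 0.5 … 8.5 μT
SWEEP_TSAT_GRID = tuple(np.arange(0.5, 6.2, 0.8))     # 0.5 … 6.1 s
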