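"""Synthetic studies: image-domain phantoms and group-structured ROI tables.

The phantom stands in for the animal acquisitions: a single 2D slice with an
elliptical "brain" containing a hippocampus-like ROI blob, per-class proton
pool systems, smooth B0 (ppm) and B1 (multiplicative ratio) inhomogeneity
fields, and Rician magnitude noise.  From it, :func:`simulate_study`
produces every raw series the processing pipeline consumes: the two CEST
saturation stacks, the WASSR sweep, the double-angle image pair, and the
variable-TR T1 series.

The ROI-table generator draws per-animal Gaussian measures for two groups
(WT and ARTE10 transgenic) with configurable means/SDs; the shipped effect
sizes emulate the reported group differences (e.g. a d ≈ −1.3 glutamate
deficit at n = 10 per group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import protocols as proto
from .bmc import simulate_zvalue
from .pools import PoolSystem, SaturationProtocol, default_pool_system
from .stats import ROITable

#: cache quantization for the per-voxel field values (ppm / ratio units);
#: well below the WASSR and double-angle estimation precision
B0_QUANT = 0.002
B1_QUANT = 0.005


def rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Magnitude of a complex Gaussian perturbation of a real signal."""
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    re = s + rng.normal(0.0, sigma, s.shape)
    im = rng.normal(0.0, sigma, s.shape)
    return np.hypot(re, im)


def _gaussian_blob(shape, center, width, amplitude):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = ((yy - center[0]) / width) ** 2 + ((xx - center[1]) / width) ** 2
    return amplitude * np.exp(-r2)


@dataclass
class PhantomSpec:
    """Declarative phantom description; identical seed ⇒ identical phantom."""

    shape: tuple[int, int] = (16, 16)
    b0_amplitude_ppm: float = 0.2      # peak of the smooth B0 field, |.| <= 0.4
    b1_amplitude: float = 0.1          # B1 ratio spans 1 ± this, within 0.8-1.2
    noise_sigma: float = 0.0           # Rician scale relative to the ref signal
    mt_mode: str = "symmetric_0ppm"
    glu_fraction_scale: float = 1.0    # hippocampus-class Glu pool multiplier
    cr_fraction_scale: float = 1.0     # hippocampus-class Cr pool multiplier
    include_pools: tuple | None = None  # non-water solute pools; None = all
    seed: int = 0

    def __post_init__(self):
        if abs(self.b0_amplitude_ppm) > 0.4:
            raise ValueError("B0 field amplitude must stay within ±0.4 ppm")
        if not (0 <= self.b1_amplitude <= 0.2):
            raise ValueError("B1 field must stay within ratio 0.8–1.2")


BACKGROUND, PARENCHYMA, HIPPOCAMPUS = 0, 1, 2


@dataclass
class Phantom:
    """Labeled phantom: class map, field maps and per-class pool systems."""

    class_map: np.ndarray
    t1_map: np.ndarray
    b0_map: np.ndarray
    b1_map: np.ndarray
    systems: dict[int, PoolSystem]
    spec: PhantomSpec

    @property
    def brain_mask(self) -> np.ndarray:
        return self.class_map != BACKGROUND

    @property
    def roi_mask(self) -> np.ndarray:
        return self.class_map == HIPPOCAMPUS


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the deterministic labeled phantom for a spec."""
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ellipse = ((yy - cy) / (0.45 * ny)) ** 2 + ((xx - cx) / (0.45 * nx)) ** 2 <= 1.0
    blob = ((yy - cy - 0.12 * ny) ** 2 + (xx - cx - 0.12 * nx) ** 2) <= (0.18 * nx) ** 2
    class_map = np.zeros(spec.shape, dtype=int)
    class_map[ellipse] = PARENCHYMA
    class_map[ellipse & blob] = HIPPOCAMPUS
    if not class_map.any():
        raise ValueError("phantom grid too small: no voxel assigned")

    base = default_pool_system(mt_mode=spec.mt_mode, include=spec.include_pools)
    hip = base
    if spec.glu_fraction_scale != 1.0:
        hip = hip.with_fraction(
            "glutamate_amine",
            base.pool_named("glutamate_amine").fraction * spec.glu_fraction_scale,
        )
    if spec.cr_fraction_scale != 1.0:
        hip = hip.with_fraction(
            "cr_guanidinium",
            base.pool_named("cr_guanidinium").fraction * spec.cr_fraction_scale,
        )
    systems = {PARENCHYMA: base, HIPPOCAMPUS: hip}

    t1_map = np.zeros(spec.shape)
    for cls, system in systems.items():
        t1_map[class_map == cls] = system.water.t1

    # smooth deterministic inhomogeneity fields
    b0_map = _gaussian_blob(
        spec.shape, (0.35 * ny, 0.6 * nx), 0.5 * nx, spec.b0_amplitude_ppm
    )
    b1_map = 1.0 + _gaussian_blob(
        spec.shape, (0.6 * ny, 0.35 * nx), 0.6 * nx, spec.b1_amplitude
    ) - 0.5 * spec.b1_amplitude
    b0_map[~ellipse] = 0.0
    b1_map[~ellipse] = 1.0
    return Phantom(class_map, t1_map, b0_map, b1_map, systems, spec)


@dataclass
class StudyData:
    """All raw series produced for one synthetic animal."""

    cest_stacks: dict          # name -> {"stack","ref","offsets","protocol"}
    wassr: dict                # {"stack","offsets","protocol"}
    double_angle: dict         # {"img_alpha","img_2alpha","alpha_deg"}
    vtr: dict                  # {"stack","tr_list"}
    phantom: Phantom
    seed: int


class _ZCache:
    """Quantized per-(system, B1, shifted-offset) Z-value cache."""

    def __init__(self):
        self._store = {}

    def z(self, system_key, system, protocol, offset, b0, b1_ratio):
        # water resonates at +b0 ppm: nominal offset o saturates at o - b0
        off_eff = offset - round(b0 / B0_QUANT) * B0_QUANT
        b1_eff = round(b1_ratio / B1_QUANT) * B1_QUANT
        key = (system_key, protocol.b1_amp, protocol.t_sat, b1_eff, off_eff)
        if key not in self._store:
            self._store[key] = simulate_zvalue(
                system, protocol.with_b1_scale(b1_eff), off_eff
            )
        return self._store[key]


def _simulate_stack(phantom: Phantom, protocol: SaturationProtocol, cache: _ZCache):
    """Per-voxel saturated signals: Z · ref, with every nominal offset seen
    relative to the voxel's shifted water frequency (+b0 ppm) and B1 scaled
    by the voxel's ratio."""
    ny, nx = phantom.class_map.shape
    offsets = np.asarray(protocol.offsets)
    stack = np.zeros((ny, nx, offsets.size))
    ref = phantom.brain_mask.astype(float)  # unit reference signal in tissue
    for iy in range(ny):
        for ix in range(nx):
            cls = phantom.class_map[iy, ix]
            if cls == BACKGROUND:
                continue
            system = phantom.systems[cls]
            b0 = phantom.b0_map[iy, ix]
            b1 = phantom.b1_map[iy, ix]
            for k, off in enumerate(offsets):
                stack[iy, ix, k] = cache.z(cls, system, protocol, off, b0, b1)
    return stack * ref[..., None], ref


def simulate_study(
    phantom: Phantom,
    protocols: dict | None = None,
    seed: int | None = None,
) -> StudyData:
    """Simulate every acquisition of the emulated protocol set.

    ``protocols`` may override any of the keys ``glu``, ``cr``, ``wassr``
    (SaturationProtocol), ``alpha_deg`` (float) and ``tr_list`` (sequence).
    Rician noise of scale ``spec.noise_sigma`` (relative to the unit
    reference signal) is applied to every magnitude image.
    """
    spec = phantom.spec
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p = {
        "glu": proto.glu_protocol(),
        "cr": proto.cr_protocol(),
        "wassr": proto.wassr_protocol(),
        "alpha_deg": proto.DOUBLE_ANGLE_DEG[0],
        "tr_list": proto.VTR_TR_LIST,
    }
    if protocols:
        p.update(protocols)
    cache = _ZCache()
    sigma = spec.noise_sigma

    cest_stacks = {}
    for name in ("glu", "cr"):
        stack, ref = _simulate_stack(phantom, p[name], cache)
        cest_stacks[name] = {
            "stack": rician_noise(stack, sigma, rng),
            "ref": rician_noise(ref, sigma, rng),
            "offsets": np.asarray(p[name].offsets),
            "protocol": p[name],
        }

    wassr_stack, wassr_ref = _simulate_stack(phantom, p["wassr"], cache)
    wassr = {
        "stack": rician_noise(wassr_stack, sigma, rng),
        "ref": rician_noise(wassr_ref, sigma, rng),
        "offsets": np.asarray(p["wassr"].offsets),
        "protocol": p["wassr"],
    }

    alpha = np.deg2rad(p["alpha_deg"])
    m0 = phantom.brain_mask.astype(float)
    img_a = m0 * np.sin(alpha * phantom.b1_map)
    img_2a = m0 * np.sin(2.0 * alpha * phantom.b1_map)
    double_angle = {
        "img_alpha": rician_noise(img_a, sigma, rng),
        "img_2alpha": rician_noise(img_2a, sigma, rng),
        "alpha_deg": p["alpha_deg"],
    }

    tr = np.asarray(p["tr_list"], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rec = 1.0 - np.exp(-tr[None, None, :] / phantom.t1_map[..., None])
    rec = np.where(phantom.brain_mask[..., None], rec, 0.0)
    vtr = {
        "stack": rician_noise(rec, sigma, rng),
        "tr_list": tr,
    }
    return StudyData(cest_stacks, wassr, double_angle, vtr, phantom, seed)


@dataclass
class EffectsSpec:
    """Group means/SDs per measure for the synthetic ROI tables.

    The defaults reconstruct the reported right-hippocampus group structure:
    WT − ARTE10 mean differences of 0.06 / 0.01 / 0.01 s⁻¹ for Glu/PCr/Cr
    AREX with Cohen's d of −1.31 / −1.78 / −1.08, and a +35 ms qT1 shift
    (d = 0.59), at n = 10 animals per group.
    """

    measures: dict = field(
        default_factory=lambda: {
            "AREX_Glu": {"wt_mean": 0.30, "arte10_mean": 0.24, "sd": 0.06 / 1.31},
            "AREX_PCr": {"wt_mean": 0.10, "arte10_mean": 0.09, "sd": 0.01 / 1.78},
            "AREX_Cr": {"wt_mean": 0.12, "arte10_mean": 0.11, "sd": 0.01 / 1.08},
            "qT1_ms": {"wt_mean": 1800.0, "arte10_mean": 1835.37, "sd": 35.37 / 0.59},
        }
    )
    covariates: dict = field(
        default_factory=lambda: {
            "roi_volume": {"mean": 2.0, "sd": 0.15},
            "water_linewidth_hz": {"mean": 14.0, "sd": 1.5},
        }
    )
    n_per_group: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        for name, m in self.measures.items():
            if m["sd"] <= 0:
                raise ValueError(f"{name}: sd must be positive")


def make_roi_table(effects: EffectsSpec) -> ROITable:
    """Draw a two-group per-animal ROI table; deterministic given the seed."""
    rng = np.random.default_rng(effects.seed)
    n = effects.n_per_group
    rows = []
    for gi, group in enumerate(("WT", "ARTE10")):
        for a in range(n):
            row = {"animal_id": f"{group}_{a:02d}", "group": group}
            for name, m in effects.measures.items():
                mean = m["wt_mean"] if group == "WT" else m["arte10_mean"]
                row[name] = rng.normal(mean, m["sd"])
            for name, c in effects.covariates.items():
                row[name] = rng.normal(c["mean"], c["sd"])
            rows.append(row)
    return ROITable(pd.DataFrame(rows))
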