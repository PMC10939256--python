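"""Proton-pool and saturation-protocol domain types.

A CEST experiment saturates labile solute protons with a long CW RF pulse
and reads out the resulting loss of bulk-water longitudinal magnetization
as a Z-spectrum, Z(Δω) = S(Δω)/S0.  The exchanging species are described
here as :class:`Pool` objects (chemical shift, proton fraction, exchange
rate, relaxation times) collected into a :class:`PoolSystem`, and the RF
irradiation as a :class:`SaturationProtocol`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 267.52218744e6

#: default static field of the emulated scanner, tesla
DEFAULT_B0 = 9.4


class InvalidParameterError(ValueError):
    """A pool or protocol parameter violates its physical constraints."""


@dataclass(frozen=True)
class Pool:
    """One exchanging proton pool.

    Parameters
    ----------
    name : str
        Label, e.g. ``"glutamate_amine"``.
    delta_ppm : float
        Chemical-shift offset from water (ppm, positive = downfield).
    fraction : float
        Relative proton fraction (water = 1).
    k_exch : float
        Solute→water exchange rate (s^-1); the reverse rate is
        ``fraction * k_exch`` by mass balance.
    t1, t2 : float
        Longitudinal / transverse relaxation times (s).
    lineshape : str
        Only ``"lorentzian"`` is supported: every pool, including the
        semisolid MT pool, evolves with full 3-component dynamics.
    """

    name: str
    delta_ppm: float
    fraction: float
    k_exch: float
    t1: float
    t2: float
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise InvalidParameterError(f"pool {self.name}: fraction < 0")
        if self.k_exch < 0:
            raise InvalidParameterError(f"pool {self.name}: k_exch < 0")
        if self.t1 <= 0 or self.t2 <= 0:
            raise InvalidParameterError(
                f"pool {self.name}: relaxation times must be positive "
                f"(t1={self.t1}, t2={self.t2})"
            )
        if self.lineshape != "lorentzian":
            raise InvalidParameterError(
                f"pool {self.name}: unsupported lineshape {self.lineshape!r}"
            )


# mt_mode values and the MT-pool centre they imply
MT_MODES = {"symmetric_0ppm": 0.0, "asymmetric_minus2p3ppm": -2.3, "none": None}


@dataclass(frozen=True)
class PoolSystem:
    """An ordered collection of pools, water first.

    ``mt_mode`` declares whether a semisolid magnetization-transfer pool is
    present and where it sits (0 ppm symmetric or −2.3 ppm asymmetric); it
    must be consistent with the pool list.
    """

    pools: tuple[Pool, ...]
    mt_mode: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pools", tuple(self.pools))
        if not self.pools:
            raise InvalidParameterError("PoolSystem needs at least a water pool")
        water = self.pools[0]
        if water.delta_ppm != 0.0 or water.fraction != 1.0:
            raise InvalidParameterError(
                "first pool must be water (delta_ppm=0, fraction=1)"
            )
        if self.mt_mode not in MT_MODES:
            raise InvalidParameterError(f"unknown mt_mode {self.mt_mode!r}")
        mt_pools = [p for p in self.pools if p.name.startswith("mt")]
        if len(mt_pools) > 1:
            raise InvalidParameterError("at most one semisolid MT pool")
        expected = MT_MODES[self.mt_mode]
        if expected is None:
            if mt_pools:
                raise InvalidParameterError("mt_mode='none' but an MT pool is present")
        else:
            if not mt_pools:
                raise InvalidParameterError(
                    f"mt_mode={self.mt_mode!r} requires an MT pool"
                )
            if abs(mt_pools[0].delta_ppm - expected) > 1e-9:
                raise InvalidParameterError(
                    f"MT pool at {mt_pools[0].delta_ppm} ppm inconsistent with "
                    f"mt_mode={self.mt_mode!r} (expected {expected} ppm)"
                )

    @property
    def water(self) -> Pool:
        return self.pools[0]

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def pool_named(self, name: str) -> Pool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(f"no pool named {name!r}")

    def without_pool(self, name: str) -> "PoolSystem":
        """Return a copy with the named (non-water) pool removed."""
        target = self.pool_named(name)
        if target is self.water:
            raise InvalidParameterError("cannot remove the water pool")
        mt_mode = self.mt_mode
        if name.startswith("mt"):
            mt_mode = "none"
        return PoolSystem(
            tuple(p for p in self.pools if p.name != name), mt_mode=mt_mode
        )

    def with_fraction(self, name: str, fraction: float) -> "PoolSystem":
        """Return a copy with the named pool's fraction replaced."""
        if name == self.water.name:
            raise InvalidParameterError("cannot rescale the water pool")
        pools = tuple(
            replace(p, fraction=fraction) if p.name == name else p
            for p in self.pools
        )
        return PoolSystem(pools, mt_mode=self.mt_mode)


@dataclass(frozen=True)
class SaturationProtocol:
    """Continuous-wave block-pulse saturation settings.

    Attributes
    ----------
    b1_amp : float
        Saturation amplitude (μT).
    t_sat : float
        Saturation duration (s).
    tr : float
        Repetition time (s); must satisfy ``t_sat <= tr``.
    offsets : tuple of float
        Saturation offsets (ppm); may be asymmetric and non-uniform.
    ref_offset : float
        Reference (effectively unsaturated) offset, ppm.
    b0 : float
        Static field (T).
    gamma : float
        Gyromagnetic ratio (rad s^-1 T^-1).
    """

    b1_amp: float
    t_sat: float
    tr: float
    offsets: tuple[float, ...]
    ref_offset: float = -300.0
    b0: float = DEFAULT_B0
    gamma: float = GAMMA_PROTON

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", tuple(float(o) for o in self.offsets))
        if self.b1_amp < 0:
            raise InvalidParameterError("b1_amp must be >= 0")
        if not (0 < self.t_sat <= self.tr):
            raise InvalidParameterError("need 0 < t_sat <= tr")
        if not np.all(np.isfinite(self.offsets)):
            raise InvalidParameterError("offsets must be finite")

    def ppm_to_radps(self, ppm) -> np.ndarray | float:
        """Convert a ppm offset to rad/s: ω = Δω_ppm · 1e−6 · γ · B0."""
        return np.asarray(ppm, dtype=float) * 1e-6 * self.gamma * self.b0

    @property
    def omega1(self) -> float:
        """Saturation field strength ω1 = γ·B1 in rad/s."""
        return self.gamma * self.b1_amp * 1e-6

    def with_b1_scale(self, scale: float) -> "SaturationProtocol":
        return replace(self, b1_amp=self.b1_amp * scale)


@dataclass
class ZSpectrum:
    """Normalized water signal versus saturation offset."""

    offsets: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.offsets.shape != self.z.shape:
            raise ValueError("offsets and z must have the same length")
        finite = self.z[np.isfinite(self.z)]
        if finite.size and (finite.min() < -0.1 or finite.max() > 1.2):
            warnings.warn(
                "Z values outside [-0.1, 1.2]; check normalization",
                stacklevel=2,
            )

    @classmethod
    def unchecked(cls, offsets, z) -> "ZSpectrum":
        """Build without the normalized-range soft check (for derived
        quantities such as inverse-difference spectra or fitted baselines
        that legitimately leave [−0.1, 1.2])."""
        obj = cls.__new__(cls)
        obj.offsets = np.asarray(offsets, dtype=float)
        obj.z = np.asarray(z, dtype=float)
        if obj.offsets.shape != obj.z.shape:
            raise ValueError("offsets and z must have the same length")
        return obj

    def __len__(self) -> int:
        return len(self.offsets)

    def sorted(self) -> "ZSpectrum":
        order = np.argsort(self.offsets)
        return ZSpectrum.unchecked(self.offsets[order], self.z[order])

    def plot(self, ax=None, **kwargs):
        """Plot Z against offset with the conventional reversed ppm axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.offsets, self.z, **kwargs)
        ax.set_xlabel("offset (ppm)")
        ax.set_ylabel("Z")
        if not ax.xaxis_inverted():
            ax.invert_xaxis()
        return ax


def _pool_from_dict(d: dict) -> Pool:
    return Pool(
        name=d["name"],
        delta_ppm=float(d["delta_ppm"]),
        fraction=float(d["fraction"]),
        k_exch=float(d["k_exch"]),
        t1=float(d["t1"]),
        t2=float(d["t2"]),
        lineshape=d.get("lineshape", "lorentzian"),
    )


def load_pool_library(path=None) -> dict[str, Pool]:
    """Load the editable YAML pool library (defaults ship with the package).

    The shipped values are working defaults for 9.4 T brain tissue, not
    measured ground truth; override them via a user YAML of the same shape.
    """
    if path is None:
        text = (
            resources.files("cestarex").joinpath("data/pools.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {d["name"]: _pool_from_dict(d) for d in raw["pools"]}


def default_pool_system(
    mt_mode: str = "symmetric_0ppm",
    include: Sequence[str] | None = None,
    library: dict[str, Pool] | None = None,
) -> PoolSystem:
    """Assemble a PoolSystem from the pool library.

    By default all solute pools are included together with the MT variant
    selected by ``mt_mode`` — the full multi-pool brain model used for the
    numerical experiments.
    """
    lib = library if library is not None else load_pool_library()
    mt_name = {
        "symmetric_0ppm": "mt_symmetric",
        "asymmetric_minus2p3ppm": "mt_asymmetric",
        "none": None,
    }[mt_mode]
    if include is None:
        include = [
            n for n in lib if n != "water" and not n.startswith("mt")
        ]
    pools = [lib["water"]]
    pools += [lib[n] for n in include]
    if mt_name is not None:
        pools.append(lib[mt_name])
    return PoolSystem(tuple(pools), mt_mode=mt_mode)
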