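"""Readers/writers and configuration.

Image stacks travel as NIfTI volumes with a JSON sidecar of the same
basename carrying the offset list (ppm), protocol parameters, units and
provenance (seed, config hash).  ROI tables and spectra are CSV; pipeline
configuration is YAML validated against a small schema, with the shipped
Lorentzian bounds and pool library filling any absent field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .lorentzian import DEFAULT_EXCLUSION_WINDOWS, load_lorentzian_defaults
from .pools import load_pool_library


class FormatError(ValueError):
    """A file pair violates the stack format contract."""


@dataclass
class StackBundle:
    """Image stack (grid × offsets) plus its JSON sidecar."""

    stack: np.ndarray
    sidecar: dict

    def __post_init__(self):
        n_img = self.stack.shape[-1]
        offs = self.sidecar.get("offsets_ppm")
        if offs is not None and len(offs) != n_img:
            raise FormatError(
                f"stack has {n_img} volumes but sidecar lists {len(offs)} offsets"
            )

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(self.sidecar["offsets_ppm"], dtype=float)


def _sidecar_path(path: Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_stack(path, stack: np.ndarray, sidecar: dict) -> StackBundle:
    """Write a NIfTI stack and its JSON sidecar (lossless round-trip)."""
    bundle = StackBundle(np.asarray(stack, dtype=float), dict(sidecar))
    img = nib.Nifti1Image(bundle.stack, affine=np.eye(4))
    nib.save(img, str(path))
    with open(_sidecar_path(Path(path)), "w") as fh:
        json.dump(bundle.sidecar, fh, indent=1, sort_keys=True)
    return bundle


def read_stack(path) -> StackBundle:
    """Read a NIfTI stack + sidecar; offsets must be in ppm (Hz values are
    converted when the sidecar carries the static field)."""
    p = Path(path)
    side = _sidecar_path(p)
    if not p.exists():
        raise FormatError(f"missing stack file {p}")
    if not side.exists():
        raise FormatError(f"missing sidecar {side} for stack {p}")
    stack = np.asarray(nib.load(str(p)).get_fdata())
    with open(side) as fh:
        sidecar = json.load(fh)
    units = sidecar.get("offset_units", "ppm")
    if units == "hz":
        b0 = sidecar.get("b0_tesla")
        if b0 is None:
            raise FormatError(
                "offsets are in Hz but the sidecar lacks b0_tesla; "
                "cannot convert to ppm"
            )
        from .pools import GAMMA_PROTON

        hz_per_ppm = GAMMA_PROTON * b0 * 1e-6 / (2 * np.pi)
        sidecar["offsets_ppm"] = [
            o / hz_per_ppm for o in sidecar.pop("offsets_hz")
        ]
        sidecar["offset_units"] = "ppm"
    elif units != "ppm":
        raise FormatError(f"unsupported offset units {units!r}")
    return StackBundle(stack, sidecar)


def write_map(path, array: np.ndarray, meta: dict | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=float), affine=np.eye(4))
    nib.save(img, str(path))
    if meta is not None:
        with open(_sidecar_path(Path(path)), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


# ---------------------------------------------------------------------------
# configuration

_SCHEMA_KEYS = {
    "pool_library",         # path to a pools.yaml-shaped file
    "lorentzian",           # overrides of components/models
    "exclusion_windows",    # [[lo, hi], ...] ppm
    "z_clip",
    "b1_clamp",
    "seed",
    "protocols",            # {"glu": {...}, "cr": {...}, "wassr": {...}}
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with shipped defaults filled in."""

    lorentzian: dict
    pool_library: dict
    exclusion_windows: tuple
    z_clip: float
    b1_clamp: tuple
    seed: int
    protocols: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @property
    def hash(self) -> str:
        text = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.hash, "seed": self.seed}


def _merge_lorentzian(defaults: dict, overrides: dict) -> dict:
    merged = {
        "components": {k: {p: dict(t) for p, t in v.items()}
                       for k, v in defaults["components"].items()},
        "models": {k: list(v) for k, v in defaults["models"].items()},
    }
    for comp, params in overrides.get("components", {}).items():
        for pname, triplet in params.items():
            merged["components"].setdefault(comp, {}).setdefault(pname, {}).update(
                triplet
            )
            t = merged["components"][comp][pname]
            if not (t["lb"] <= t["sv"] <= t["ub"]):
                raise ValueError(
                    f"invalid bounds for {comp}.{pname}: need lb <= sv <= ub, got {t}"
                )
    for label, comps in overrides.get("models", {}).items():
        merged["models"][label] = list(comps)
    return merged


def load_config(path=None) -> PipelineConfig:
    """Load and validate a YAML config; absent fields take shipped defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _SCHEMA_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    lorentzian = _merge_lorentzian(
        load_lorentzian_defaults(), raw.get("lorentzian", {})
    )
    pool_library = load_pool_library(raw.get("pool_library"))
    windows = tuple(
        tuple(w) for w in raw.get("exclusion_windows", DEFAULT_EXCLUSION_WINDOWS)
    )
    for lo, hi in windows:
        if lo >= hi:
            raise ValueError(f"exclusion window [{lo}, {hi}] has lb >= ub")
    return PipelineConfig(
        lorentzian=lorentzian,
        pool_library=pool_library,
        exclusion_windows=windows,
        z_clip=float(raw.get("z_clip", 1e-6)),
        b1_clamp=tuple(raw.get("b1_clamp", (0.5, 1.5))),
        seed=int(raw.get("seed", 0)),
        protocols=raw.get("protocols", {}),
        raw=raw,
    )


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.raw, fh)
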