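"""Cube preprocessing: spectral subset, log transform, per-channel
standardization, spatial resize, and association-tracked augmentation.

The chain runs in a fixed order::

    raw -> select_channels -> log_transform -> normalize -> resize_spatial
        -> (training only) augment

Channel selection keeps every ``step``-th channel of the 1-based inclusive
window ``[first_channel, last_channel]`` — with the defaults (470, 820, 5)
a 1002-channel transmittance cube becomes a 71-channel cube.  The log10
transform compresses the huge dynamic range of transmittance counts (raw
values run from 0 to tens of thousands, with specular hot spots far above
the informative range).  Standardization is per image, per wavelength
channel: each channel is shifted to zero mean and scaled to unit variance.
Augmentation produces the five deterministic spatial transforms (vertical
flip, horizontal flip, 90/180/270-degree rotations); together with the
original that expands a training set exactly six-fold, every variant
sharing the parent's augmentation group and hence its label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize as _skimage_resize

from .hypercube_io import (
    HyperCube,
    SampleManifest,
    Stage,
    ValidationError,
    load_cube,
    write_cube,
)

__all__ = [
    "PreprocessConfig",
    "select_channels",
    "log_transform",
    "normalize",
    "resize_spatial",
    "augment",
    "preprocess_cube",
    "preprocess_dataset",
    "AUGMENTATIONS",
]

_VAR_FLOOR = 1e-12

# name -> spatial transform acting on axes (0, 1) of an (H, W, C) array
AUGMENTATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "vflip": lambda a: a[::-1, :, :],
    "hflip": lambda a: a[:, ::-1, :],
    "rot90": lambda a: np.rot90(a, 1, axes=(0, 1)),
    "rot180": lambda a: np.rot90(a, 2, axes=(0, 1)),
    "rot270": lambda a: np.rot90(a, 3, axes=(0, 1)),
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing constants.

    ``first_channel``/``last_channel`` are 1-based inclusive spectral window
    bounds; ``step`` is the subsampling stride within it.  ``target_size``
    is the output spatial side length in pixels.  ``log_floor`` is the
    positive clip applied before log10 so the transform is total on counts
    that include zeros.
    """

    first_channel: int = 470
    last_channel: int = 820
    step: int = 5
    target_size: int = 32
    log_floor: float = 1.0
    augmentations: tuple[str, ...] = ("vflip", "hflip", "rot90", "rot180", "rot270")

    def __post_init__(self) -> None:
        if not 1 <= self.first_channel <= self.last_channel:
            raise ValidationError(
                f"need 1 <= first_channel <= last_channel, got "
                f"({self.first_channel}, {self.last_channel})"
            )
        if self.step < 1:
            raise ValidationError(f"step must be >= 1, got {self.step}")
        if self.target_size < 1:
            raise ValidationError(f"target_size must be >= 1, got {self.target_size}")
        if not self.log_floor > 0:
            raise ValidationError(f"log_floor must be > 0, got {self.log_floor}")
        unknown = [a for a in self.augmentations if a not in AUGMENTATIONS]
        if unknown:
            raise ValidationError(f"unknown augmentation(s) {unknown}")

    @property
    def n_selected(self) -> int:
        """Channel count after selection: floor((last-first)/step) + 1."""
        return (self.last_channel - self.first_channel) // self.step + 1

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessConfig":
        """Read a key=value config file (unknown keys rejected)."""
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "augmentations":
                kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
            elif key in ("first_channel", "last_channel", "step", "target_size"):
                kwargs[key] = int(val)
            elif key == "log_floor":
                kwargs[key] = float(val)
            else:
                raise ValidationError(f"unknown preprocessing config key '{key}'")
        return cls(**kwargs)


def _require_stage(cube: HyperCube, stage: Stage, op: str) -> None:
    if cube.stage != stage:
        raise ValidationError(
            f"{op}: cube '{cube.sample_id}' is at stage {cube.stage.name}, "
            f"expected {stage.name}"
        )


def select_channels(cube: HyperCube, cfg: PreprocessConfig) -> HyperCube:
    """Keep channels first, first+step, ... <= last (1-based inclusive)."""
    _require_stage(cube, Stage.RAW, "select_channels")
    if cfg.last_channel > cube.n_channels:
        raise IndexError(
            f"last_channel {cfg.last_channel} exceeds cube channel count "
            f"{cube.n_channels}"
        )
    idx = np.arange(cfg.first_channel - 1, cfg.last_channel, cfg.step)
    wl = None if cube.wavelengths is None else cube.wavelengths[idx]
    return cube.advance(cube.pixels[:, :, idx], Stage.CHANNEL_SELECTED, wavelengths=wl)


def log_transform(cube: HyperCube, cfg: PreprocessConfig = PreprocessConfig()) -> HyperCube:
    """log10 of each pixel, clipped below at ``log_floor`` so zeros map to 0."""
    _require_stage(cube, Stage.CHANNEL_SELECTED, "log_transform")
    out = np.log10(np.maximum(cube.pixels, np.float32(cfg.log_floor)))
    return cube.advance(out.astype(np.float32), Stage.LOG)


def normalize(cube: HyperCube) -> HyperCube:
    """Per-channel standardization of this image: zero mean, unit variance.

    Statistics are taken over the spatial pixels of each wavelength channel
    of this cube alone.  Channels with variance below 1e-12 (constant
    channels) map to all zeros.
    """
    _require_stage(cube, Stage.LOG, "normalize")
    x = cube.pixels.astype(np.float64)
    mean = x.mean(axis=(0, 1), keepdims=True)
    var = x.var(axis=(0, 1), keepdims=True)
    out = np.where(var < _VAR_FLOOR, 0.0, (x - mean) / np.sqrt(np.maximum(var, _VAR_FLOOR)))
    return cube.advance(out.astype(np.float32), Stage.NORMALIZED)


def resize_spatial(cube: HyperCube, cfg: PreprocessConfig) -> HyperCube:
    """Bilinear resize of the spatial axes to target_size x target_size.

    Interpolation is applied independently per channel, with anti-aliasing
    off so the operation is a pure interpolation (constants are preserved;
    an identity resize leaves values unchanged).
    """
    _require_stage(cube, Stage.NORMALIZED, "resize_spatial")
    t = cfg.target_size
    if (cube.height, cube.width) == (t, t):
        out = cube.pixels.copy()
    else:
        out = _skimage_resize(
            cube.pixels,
            (t, t, cube.n_channels),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return cube.advance(out.astype(np.float32), Stage.RESIZED)


def augment(cube: HyperCube, cfg: PreprocessConfig = PreprocessConfig()) -> list[HyperCube]:
    """The original cube plus its five deterministic spatial transforms.

    All six share the input's group id; each variant gets a distinct sample
    id derived from the original's.  Requires a square spatial shape (the
    rotations would otherwise change it).
    """
    _require_stage(cube, Stage.RESIZED, "augment")
    if cube.height != cube.width:
        raise ValidationError(
            f"augment: cube '{cube.sample_id}' spatial shape "
            f"{cube.height}x{cube.width} is not square"
        )
    out = [cube]
    for name in cfg.augmentations:
        out.append(
            HyperCube(
                pixels=np.ascontiguousarray(AUGMENTATIONS[name](cube.pixels)),
                sample_id=f"{cube.sample_id}.{name}",
                stage=cube.stage,
                wavelengths=cube.wavelengths,
                group_id=cube.group_id,
            )
        )
    return out


def preprocess_cube(cube: HyperCube, cfg: PreprocessConfig) -> HyperCube:
    """Full single-cube chain: select -> log -> normalize -> resize."""
    return resize_spatial(normalize(log_transform(select_channels(cube, cfg), cfg)), cfg)


def preprocess_dataset(
    manifest: SampleManifest,
    cfg: PreprocessConfig,
    out_dir: str | Path,
    augment_train: bool = True,
) -> SampleManifest:
    """Preprocess every sample of a manifest; augment the training split only.

    Processed cubes are written in the array-directory layout under
    ``out_dir``; the returned manifest (also saved as ``manifest.csv``)
    lists one row per output cube, augmented variants carrying the parent's
    group id and label.  Any per-sample failure aborts with the sample id
    named.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for r in manifest.frame.itertuples():
        sid = str(r.sample_id)
        try:
            cube = load_cube(r.file_path)
            cube.group_id = str(r.group_id)
            done = preprocess_cube(cube, cfg)
            variants = augment(done, cfg) if (augment_train and r.split == "train") else [done]
            for v in variants:
                path = write_cube(v, out_dir / v.sample_id.replace(".", "_"), format="array_dir")
                rows.append(
                    {
                        "sample_id": v.sample_id,
                        "file_path": str(path),
                        "label": r.label,
                        "split": r.split,
                        "group_id": str(r.group_id),
                    }
                )
        except Exception as exc:
            raise ValidationError(f"preprocessing failed for sample '{sid}': {exc}") from exc
    out = SampleManifest.from_rows(rows)
    out.save(out_dir / "manifest.csv")
    return out
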