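"""Hyperspectral cube containers and on-disk I/O.

A :class:`HyperCube` is one sample's ``height x width x channels`` array of
nonnegative transmittance intensities (or their transformed values further
down the preprocessing chain), tagged with a processing stage, a sample id
and an augmentation-group id.  Cubes are stored either as ENVI header +
binary pairs — the de-facto standard container for hyperspectral imagery —
or as a plain array directory (``pixels.npy`` + JSON sidecar), which is the
internal fixture format.

A :class:`SampleManifest` is the tabular registry of a dataset: one row per
sample with its file path, optional ground-truth class label, train/test
split and augmentation group.  Augmented variants of a sample share its
group id and therefore, by construction, its label.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "UnsupportedFormatError",
    "UnlabeledSampleError",
    "Stage",
    "HyperCube",
    "SampleManifest",
    "read_envi",
    "read_array_dir",
    "load_cube",
    "write_cube",
    "load_manifest",
]


class ValidationError(ValueError):
    """An input violates a documented contract."""


class FormatError(ValueError):
    """An on-disk file is missing, truncated or malformed."""


class UnsupportedFormatError(FormatError):
    """A file is recognisably ENVI but uses an unsupported variant."""


class UnlabeledSampleError(LookupError):
    """A label was requested for a sample that carries none."""


class Stage(IntEnum):
    """Position of a cube along the preprocessing chain (forward-only)."""

    RAW = 0
    CHANNEL_SELECTED = 1
    LOG = 2
    NORMALIZED = 3
    RESIZED = 4


@dataclass
class HyperCube:
    """One sample's 3-D intensity array plus identifying metadata.

    Parameters
    ----------
    pixels:
        ``(height, width, channels)`` array; stored as float32.
    sample_id:
        Opaque identifier, unique within a dataset.
    stage:
        Preprocessing stage tag; transitions only move forward.
    wavelengths:
        Optional per-channel wavelengths in nm, ascending with channel index.
    group_id:
        Augmentation-group identifier; defaults to ``sample_id`` (a group of
        one before augmentation).
    """

    pixels: np.ndarray
    sample_id: str
    stage: Stage = Stage.RAW
    wavelengths: np.ndarray | None = None
    group_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise ValidationError(
                f"cube '{self.sample_id}': pixels must have exactly 3 axes "
                f"(H, W, C), got shape {self.pixels.shape}"
            )
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
            if self.wavelengths.shape != (self.pixels.shape[2],):
                raise ValidationError(
                    f"cube '{self.sample_id}': wavelength list length "
                    f"{self.wavelengths.size} != channel count {self.pixels.shape[2]}"
                )
        if self.group_id is None:
            self.group_id = self.sample_id
        self.stage = Stage(self.stage)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def advance(
        self,
        pixels: np.ndarray,
        stage: Stage,
        wavelengths: np.ndarray | None = None,
        sample_id: str | None = None,
    ) -> "HyperCube":
        """Return a copy at a later stage; refuses to move backwards."""
        if Stage(stage) <= self.stage:
            raise ValidationError(
                f"cube '{self.sample_id}': stage may only advance "
                f"({self.stage.name} -> {Stage(stage).name})"
            )
        return HyperCube(
            pixels=pixels,
            sample_id=self.sample_id if sample_id is None else sample_id,
            stage=Stage(stage),
            wavelengths=self.wavelengths if wavelengths is None else wavelengths,
            group_id=self.group_id,
        )


# ---------------------------------------------------------------------------
# ENVI header + binary pairs
# ---------------------------------------------------------------------------

# ENVI "data type" codes -> numpy dtypes (unsupported codes rejected).
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
    15: np.uint64,
}
_DTYPE_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str, path: Path) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError(f"{path}: missing ENVI magic line")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # key = value, where value may be a {...} block spanning lines
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1] if val.endswith("}") else val[1:]
        fields[key] = val.strip()
    return fields


def _header_path(path: Path) -> Path:
    if path.suffix.lower() == ".hdr":
        return path
    cand = path.with_suffix(path.suffix + ".hdr")
    if cand.exists():
        return cand
    return path.with_suffix(".hdr")


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI header+binary pair into a raw-stage :class:`HyperCube`.

    ``path`` may name the ``.hdr`` file, the data file, or their common base.
    BSQ, BIL and BIP interleaves are supported; the wavelength block, when
    present, populates the cube's wavelength axis.
    """
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FormatError(f"{path}: no ENVI header found (looked for {hdr})")
    fields = _parse_envi_header(hdr.read_text(), hdr)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dcode = int(fields["data type"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{hdr}: missing or malformed required header field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").strip().lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise UnsupportedFormatError(f"{hdr}: unsupported interleave '{interleave}'")
    if dcode not in _ENVI_DTYPES:
        raise UnsupportedFormatError(f"{hdr}: unsupported data type code {dcode}")
    dtype = np.dtype(_ENVI_DTYPES[dcode])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    offset = int(fields.get("header offset", "0"))

    base = hdr.with_suffix("")
    candidates = [base, base.with_suffix(".img"), base.with_suffix(".dat"), base.with_suffix(".raw")]
    if path != hdr and path.exists():
        candidates.insert(0, path)
    data_file = next((c for c in candidates if c.exists() and c != hdr), None)
    if data_file is None:
        raise FormatError(f"{hdr}: no companion data file found")

    expected = samples * lines * bands
    raw = np.fromfile(data_file, dtype=dtype, count=expected, offset=offset)
    if raw.size < expected:
        raise FormatError(
            f"{data_file}: truncated payload ({raw.size} values, header promises {expected})"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)

    wavelengths = None
    if "wavelength" in fields:
        wl = [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
        if len(wl) == bands:
            wavelengths = np.asarray(wl)
    stage = Stage[fields["stage"].upper()] if "stage" in fields else Stage.RAW
    return HyperCube(
        pixels=cube,
        sample_id=fields.get("sample id", base.name),
        stage=stage,
        wavelengths=wavelengths,
        group_id=fields.get("group id"),
    )


def _write_envi(cube: HyperCube, path: Path) -> Path:
    hdr = path if path.suffix.lower() == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    data_file = hdr.with_suffix(".img")
    lines, samples, bands = cube.pixels.shape
    parts = [
        "ENVI",
        "description = {alcube hyperspectral cube}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[np.dtype(np.float32)]}",
        "interleave = bsq",
        "byte order = 0",
        f"sample id = {cube.sample_id}",
        f"group id = {cube.group_id}",
        f"stage = {cube.stage.name.lower()}",
    ]
    if cube.wavelengths is not None:
        wl = ", ".join(repr(float(w)) for w in cube.wavelengths)
        parts.append("wavelength units = Nanometers")
        parts.append("wavelength = {" + wl + "}")
    hdr.write_text("\n".join(parts) + "\n")
    # BSQ: band-major layout
    cube.pixels.astype("<f4").transpose(2, 0, 1).tofile(data_file)
    return hdr


def _write_array_dir(cube: HyperCube, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "pixels.npy", cube.pixels.astype(np.float32))
    meta = {
        "sample_id": cube.sample_id,
        "group_id": cube.group_id,
        "stage": cube.stage.name.lower(),
        "wavelengths": None if cube.wavelengths is None else [float(w) for w in cube.wavelengths],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def write_cube(cube: HyperCube, path: str | Path, format: str = "envi") -> Path:
    """Write a cube as ``envi`` (.hdr + .img, float32 BSQ) or ``array_dir``."""
    if cube.n_channels < 1 or cube.height < 1 or cube.width < 1:
        raise ValidationError(
            f"cube '{cube.sample_id}': degenerate shape {cube.pixels.shape} cannot be written"
        )
    path = Path(path)
    try:
        if format == "envi":
            return _write_envi(cube, path)
        if format == "array_dir":
            return _write_array_dir(cube, path)
    except OSError as exc:
        raise OSError(f"cannot write cube '{cube.sample_id}' to {path}: {exc}") from exc
    raise ValidationError(f"unknown cube format '{format}' (expected 'envi' or 'array_dir')")


def read_array_dir(path: str | Path) -> HyperCube:
    """Read a cube from the array-directory layout (pixels.npy + meta.json)."""
    path = Path(path)
    pix_file = path / "pixels.npy"
    meta_file = path / "meta.json"
    if not pix_file.exists() or not meta_file.exists():
        raise FormatError(f"{path}: not an array directory (pixels.npy + meta.json required)")
    meta = json.loads(meta_file.read_text())
    wl = meta.get("wavelengths")
    return HyperCube(
        pixels=np.load(pix_file),
        sample_id=meta["sample_id"],
        stage=Stage[meta.get("stage", "raw").upper()],
        wavelengths=None if wl is None else np.asarray(wl),
        group_id=meta.get("group_id"),
    )


def load_cube(path: str | Path) -> HyperCube:
    """Dispatch on layout: directory -> array_dir, otherwise ENVI."""
    path = Path(path)
    if path.is_dir():
        return read_array_dir(path)
    return read_envi(path)


# ---------------------------------------------------------------------------
# Sample manifests
# ---------------------------------------------------------------------------

_SPLITS = ("train", "test")
_REQUIRED = ("sample_id", "file_path", "split")


@dataclass
class SampleManifest:
    """Ordered registry of samples: id, path, optional label, split, group.

    Wraps a :class:`pandas.DataFrame` with columns ``sample_id``,
    ``file_path``, ``label`` (nullable integer), ``split`` and ``group_id``.
    Row order is preserved from construction and defines the canonical
    sample order used for deterministic tie-breaking downstream.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in _REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"manifest is missing required column '{col}'")
        if "label" not in df.columns:
            df["label"] = pd.array([pd.NA] * len(df), dtype="Int64")
        else:
            df["label"] = pd.array(
                [pd.NA if pd.isna(v) else int(v) for v in df["label"]], dtype="Int64"
            )
        if "group_id" not in df.columns:
            df["group_id"] = df["sample_id"]
        else:
            df["group_id"] = df["group_id"].fillna(df["sample_id"])
        df["sample_id"] = df["sample_id"].astype(str)
        df["group_id"] = df["group_id"].astype(str)
        df["split"] = df["split"].astype(str)

        dupes = df["sample_id"][df["sample_id"].duplicated()]
        if len(dupes):
            raise ValidationError(f"duplicate sample_id '{dupes.iloc[0]}' in manifest")
        bad_split = df["split"][~df["split"].isin(_SPLITS)]
        if len(bad_split):
            raise ValidationError(
                f"unknown split token '{bad_split.iloc[0]}' (expected one of {_SPLITS})"
            )
        # every augmentation group carries at most one label
        labeled = df.dropna(subset=["label"])
        per_group = labeled.groupby("group_id")["label"].nunique()
        conflicted = per_group[per_group > 1]
        if len(conflicted):
            raise ValidationError(
                f"group '{conflicted.index[0]}' carries conflicting labels"
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def ids(self, split: str | None = None) -> list[str]:
        df = self.frame if split is None else self.frame[self.frame["split"] == split]
        return df["sample_id"].tolist()

    def split_sizes(self) -> tuple[int, int]:
        return (
            int((self.frame["split"] == "train").sum()),
            int((self.frame["split"] == "test").sum()),
        )

    def _row(self, sample_id: str) -> pd.Series:
        rows = self.frame[self.frame["sample_id"] == sample_id]
        if rows.empty:
            raise KeyError(f"unknown sample_id '{sample_id}'")
        return rows.iloc[0]

    def path_of(self, sample_id: str) -> Path:
        return Path(self._row(sample_id)["file_path"])

    def group_of(self, sample_id: str) -> str:
        return str(self._row(sample_id)["group_id"])

    def has_label(self, sample_id: str) -> bool:
        return not pd.isna(self._row(sample_id)["label"])

    def label_of(self, sample_id: str) -> int:
        val = self._row(sample_id)["label"]
        if pd.isna(val):
            raise UnlabeledSampleError(f"sample '{sample_id}' carries no label")
        return int(val)

    def labels(self, split: str | None = None) -> dict[str, int]:
        df = self.frame if split is None else self.frame[self.frame["split"] == split]
        return {
            str(r.sample_id): int(r.label)
            for r in df.dropna(subset=["label"]).itertuples()
        }

    def n_classes(self) -> int:
        labeled = self.frame["label"].dropna()
        if labeled.empty:
            raise UnlabeledSampleError("manifest carries no labels")
        return int(labeled.max()) + 1

    def groups(self, split: str | None = None) -> dict[str, list[str]]:
        """group_id -> ordered member sample ids."""
        df = self.frame if split is None else self.frame[self.frame["split"] == split]
        out: dict[str, list[str]] = {}
        for r in df.itertuples():
            out.setdefault(str(r.group_id), []).append(str(r.sample_id))
        return out

    def n_groups(self, split: str | None = None) -> int:
        return len(self.groups(split))

    def subset(self, ids: Iterable[str]) -> "SampleManifest":
        wanted = set(ids)
        return SampleManifest(self.frame[self.frame["sample_id"].isin(wanted)].copy())

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_rows(cls, rows: Sequence[dict]) -> "SampleManifest":
        return cls(pd.DataFrame(list(rows)))


def load_manifest(path: str | Path) -> SampleManifest:
    """Load a CSV manifest; deterministic and order-preserving."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest file not found: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "file_path": str, "split": str})
    return SampleManifest(df)
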