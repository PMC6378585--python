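"""Movie and localization-table I/O.

Movies are TIFF / OME-TIFF time series of uint16 camera counts (ADU), one
page per frame, frames numbered 1..n_frames.  Camera metadata (pixel size,
photon conversion, dark baseline) comes from a YAML/JSON sidecar written next
to the movie, with the OME ``PhysicalSizeX`` attribute as a fallback for the
pixel size; an explicit :class:`CameraModel` override always wins.

Localization tables use the ThunderSTORM CSV dialect: quoted headers such as
``"x [nm]"``, positions in nanometres, intensities in photons.  Floats are
written as their shortest representation with at most 6 significant digits so
that writing the same table twice yields byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import json
import uuid
import xml.etree.ElementTree as _ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import (
    BoundsError,
    FormatError,
    MergeError,
    MetadataError,
    ParseError,
    SchemaError,
)

# ---------------------------------------------------------------------------
# camera + movie handle


@dataclass(frozen=True)
class CameraModel:
    """Camera conversion parameters.

    pixel_size_nm
        Sample-plane size of one camera pixel, nm.
    photons_per_adu
        Photons per digital count; counts are converted to photons as
        ``(ADU - baseline_adu) * photons_per_adu``.
    baseline_adu
        Dark offset of the camera in counts.
    """

    pixel_size_nm: float
    photons_per_adu: float
    baseline_adu: float = 0.0

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise MetadataError("pixel_size_nm must be > 0")
        if not self.photons_per_adu > 0:
            raise MetadataError("photons_per_adu must be > 0")
        if self.baseline_adu < 0:
            raise MetadataError("baseline_adu must be >= 0")

    def adu_to_photons(self, adu: np.ndarray) -> np.ndarray:
        """Convert raw counts to photons, clipped below at zero."""
        phot = (np.asarray(adu, dtype=float) - self.baseline_adu) * self.photons_per_adu
        return np.clip(phot, 0.0, None)


@dataclass(frozen=True)
class MovieHandle:
    """Lazily readable frame stack; frames are addressed 1..n_frames."""

    path: str
    n_frames: int
    height: int
    width: int
    camera: CameraModel

    frame_index_base: int = 1

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise FormatError(f"movie has no frames: {self.path}")
        if self.height < 8 or self.width < 8:
            raise FormatError(
                f"movie frames too small ({self.height}x{self.width}); need >= 8 px"
            )


def _sidecar_paths(path: Path) -> list[Path]:
    name = path.name
    for suf in (".ome.tiff", ".ome.tif", ".tiff", ".tif"):
        if name.lower().endswith(suf):
            name = name[: -len(suf)]
            break
    base = path.parent / name
    return [base.with_name(base.name + ".camera.yaml"),
            base.with_name(base.name + ".camera.json")]


def _read_sidecar(path: Path) -> Optional[dict]:
    for cand in _sidecar_paths(path):
        if cand.exists():
            text = cand.read_text()
            if cand.suffix == ".json":
                return json.loads(text)
            return yaml.safe_load(text)
    return None


def _pixel_size_from_ome(desc: str) -> Optional[float]:
    """Extract PhysicalSizeX (converted to nm) from an OME-XML description."""
    try:
        root = _ET.fromstring(desc)
    except _ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            value = elem.get("PhysicalSizeX")
            if value is None:
                return None
            unit = elem.get("PhysicalSizeXUnit", "µm")
            scale = {"nm": 1.0, "µm": 1e3, "um": 1e3, "mm": 1e6}.get(unit)
            if scale is None:
                return None
            return float(value) * scale
    return None


def open_movie(path, camera_override: Optional[CameraModel] = None) -> MovieHandle:
    """Open a TIFF/OME-TIFF time series and resolve its camera metadata.

    Metadata precedence: ``camera_override`` > sidecar ``<stem>.camera.yaml``
    (or ``.json``) > OME ``PhysicalSizeX`` (pixel size only).  Raises
    :class:`MetadataError` naming the first missing key when the camera model
    cannot be completed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such movie file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            n_frames = len(tf.pages)
            first = tf.pages[0]
            shape = first.shape
            if len(shape) != 2:
                raise FormatError(
                    f"expected single-channel 2D frames, got page shape {shape}"
                )
            height, width = int(shape[0]), int(shape[1])
            desc = first.description or ""
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise FormatError(f"cannot read {path} as a TIFF time series: {exc}") from exc

    if camera_override is not None:
        camera = camera_override
    else:
        values: dict = {}
        ome_px = _pixel_size_from_ome(desc)
        if ome_px is not None:
            values["pixel_size_nm"] = ome_px
        sidecar = _read_sidecar(path)
        if sidecar:
            values.update({k: sidecar[k] for k in
                           ("pixel_size_nm", "photons_per_adu", "baseline_adu")
                           if k in sidecar})
        for key in ("pixel_size_nm", "photons_per_adu", "baseline_adu"):
            if key not in values:
                raise MetadataError(
                    f"camera metadata key '{key}' missing for {path.name}; "
                    "provide a sidecar camera file or a camera_override"
                )
        camera = CameraModel(**values)
    return MovieHandle(path=str(path), n_frames=n_frames,
                       height=height, width=width, camera=camera)


def read_frames(handle: MovieHandle, start: int = 1, stride: int = 1
                ) -> Iterator[tuple[int, np.ndarray]]:
    """Yield ``(frame_number, pixels)`` for frames start, start+stride, ...

    Frames are read lazily one page at a time; pixel values are raw counts.
    """
    if stride < 1:
        raise BoundsError(f"stride must be >= 1, got {stride}")
    if not 1 <= start <= handle.n_frames:
        raise BoundsError(
            f"start frame {start} outside 1..{handle.n_frames}")
    with tifffile.TiffFile(handle.path) as tf:
        for f in range(start, handle.n_frames + 1, stride):
            yield f, tf.pages[f - 1].asarray()


def write_movie(path, stack: np.ndarray, camera: CameraModel,
                seed: int = 0) -> Path:
    """Write a uint16 frame stack as an OME-TIFF plus a camera sidecar.

    The embedded OME-XML (SizeT, PhysicalSizeX/Y) is built here with a UUID
    derived from ``seed`` so identical data produce byte-identical files.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.dtype != np.uint16:
        raise FormatError(f"movie stacks must be uint16, got {stack.dtype}")
    n, h, w = stack.shape
    px_nm = float(camera.pixel_size_nm)
    uid = uuid.uuid5(uuid.NAMESPACE_URL, f"parastorm-movie-{seed}-{n}-{h}-{w}")
    xml = (
        '<?xml version="1.0" encoding="UTF-8"?>'
        '<OME xmlns="http://www.openmicroscopy.org/Schemas/OME/2016-06" '
        f'UUID="urn:uuid:{uid}">'
        '<Image ID="Image:0"><Pixels ID="Pixels:0" DimensionOrder="XYCZT" '
        f'Type="uint16" SizeX="{w}" SizeY="{h}" SizeC="1" SizeZ="1" SizeT="{n}" '
        f'PhysicalSizeX="{px_nm}" PhysicalSizeXUnit="nm" '
        f'PhysicalSizeY="{px_nm}" PhysicalSizeYUnit="nm">'
        '<TiffData/></Pixels></Image></OME>'
    )
    tifffile.imwrite(str(path), stack, photometric="minisblack",
                     description=xml, metadata=None)
    sidecar = _sidecar_paths(path)[0]
    sidecar.write_text(yaml.safe_dump(
        {"pixel_size_nm": float(camera.pixel_size_nm),
         "photons_per_adu": float(camera.photons_per_adu),
         "baseline_adu": float(camera.baseline_adu)},
        sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# localization tables

# internal column name -> CSV header
_BASE_COLUMNS = {
    "id": "id",
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "intensity_photons": "intensity [photon]",
    "offset_photons": "offset [photon]",
    "bkgstd_photons": "bkgstd [photon]",
    "uncertainty_xy_nm": "uncertainty_xy [nm]",
}
_Z_COLUMNS = {
    "z_nm": "z [nm]",
    "sigma1_nm": "sigma1 [nm]",
    "sigma2_nm": "sigma2 [nm]",
    "uncertainty_z_nm": "uncertainty_z [nm]",
}
COLUMNS_2D = list(_BASE_COLUMNS)
COLUMNS_3D = list(_BASE_COLUMNS) + list(_Z_COLUMNS)
_HEADER_TO_COLUMN = {v: k for k, v in {**_BASE_COLUMNS, **_Z_COLUMNS}.items()}
_INT_COLUMNS = ("id", "frame")


def format_float(x: float) -> str:
    """Shortest decimal representation with <= 6 significant digits."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return np.format_float_positional(float(x), precision=6, unique=True,
                                      fractional=False, trim="-")


@dataclass
class LocalizationTable:
    """Ordered emitter localizations with processing provenance.

    ``df`` holds one row per localization with the canonical columns
    (:data:`COLUMNS_2D`, plus z columns when ``dim == 3``); ``provenance``
    is an append-only list of human-readable processing-step descriptions.
    """

    df: pd.DataFrame
    dim: int = 2
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise SchemaError(f"dim must be 2 or 3, got {self.dim}")
        cols = COLUMNS_3D if self.dim == 3 else COLUMNS_2D
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise SchemaError(f"table missing columns: {missing}")
        self.df = self.df.loc[:, cols].reset_index(drop=True)
        if len(self.df):
            ids = self.df["id"].to_numpy()
            if len(np.unique(ids)) != len(ids):
                raise SchemaError("localization ids are not unique")

    # -- construction helpers ------------------------------------------------
    @classmethod
    def empty(cls, dim: int = 2) -> "LocalizationTable":
        cols = COLUMNS_3D if dim == 3 else COLUMNS_2D
        return cls(pd.DataFrame({c: pd.Series(dtype=float) for c in cols}), dim)

    @classmethod
    def from_records(cls, records: Sequence[dict], dim: int = 2,
                     provenance: Optional[list[str]] = None) -> "LocalizationTable":
        cols = COLUMNS_3D if dim == 3 else COLUMNS_2D
        if not records:
            tab = cls.empty(dim)
            tab.provenance = list(provenance or [])
            return tab
        df = pd.DataFrame(list(records))
        for c in cols:
            if c not in df.columns:
                df[c] = np.nan
        return cls(df, dim, list(provenance or []))

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "LocalizationTable":
        return LocalizationTable(self.df.copy(), self.dim, list(self.provenance))

    def with_df(self, df: pd.DataFrame, note: Optional[str] = None
                ) -> "LocalizationTable":
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return LocalizationTable(df.reset_index(drop=True), self.dim, prov)

    def reassign_ids(self) -> "LocalizationTable":
        df = self.df.copy()
        df["id"] = np.arange(1, len(df) + 1, dtype=float)
        return LocalizationTable(df, self.dim, list(self.provenance))


def write_table(table: LocalizationTable, path) -> Path:
    """Write a table as ThunderSTORM-dialect CSV (deterministic bytes)."""
    path = Path(path)
    cols = COLUMNS_3D if table.dim == 3 else COLUMNS_2D
    headers = [(_BASE_COLUMNS | _Z_COLUMNS)[c] for c in cols]
    lines = [",".join(f'"{h}"' for h in headers)]
    df = table.df
    for row in df.itertuples(index=False):
        cells = []
        for c, v in zip(cols, row):
            if c in _INT_COLUMNS:
                cells.append("" if pd.isna(v) else str(int(v)))
            else:
                cells.append(format_float(v))
        lines.append(",".join(cells))
    try:
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise FormatError(f"cannot write table to {path}: {exc}") from exc
    return path


def read_table(path) -> LocalizationTable:
    """Read a ThunderSTORM-dialect CSV; dim inferred from a z column."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                          skip_blank_lines=True)
    except Exception as exc:
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc
    headers = [h.strip() for h in raw.columns]
    unknown = [h for h in headers if h not in _HEADER_TO_COLUMN]
    if unknown:
        raise SchemaError(f"unknown column(s) in {path.name}: {unknown}")
    raw.columns = [_HEADER_TO_COLUMN[h] for h in headers]
    dim = 3 if "z_nm" in raw.columns else 2
    cols = COLUMNS_3D if dim == 3 else COLUMNS_2D
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) in {path.name}: "
                          f"{[(_BASE_COLUMNS | _Z_COLUMNS)[c] for c in missing]}")
    data = {}
    for c in cols:
        col = raw[c].str.strip()
        empty = col == ""
        parsed = pd.to_numeric(col.mask(empty), errors="coerce")
        bad = parsed.isna() & ~empty
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        # noqa: E702 - keep error close to detection
            raise ParseError(
                f"non-numeric value {col[bad].iloc[0]!r} in column "
                f"'{(_BASE_COLUMNS | _Z_COLUMNS)[c]}' at line {row} of {path.name}")
        data[c] = parsed.astype(float)
    return LocalizationTable(pd.DataFrame(data), dim)


def concat_tables(tables: Sequence[LocalizationTable]) -> LocalizationTable:
    """Concatenate tables of equal dim, preserving input order (no sort)."""
    if not tables:
        raise MergeError("no tables to concatenate")
    dims = {t.dim for t in tables}
    if len(dims) != 1:
        raise MergeError(f"cannot concatenate tables of mixed dim {sorted(dims)}")
    dim = dims.pop()
    frames = [t.df for t in tables if len(t.df)]
    df = (pd.concat(frames, ignore_index=True) if frames
          else LocalizationTable.empty(dim).df)
    df = df.copy()
    df["id"] = np.arange(1, len(df) + 1, dtype=float)
    prov: list[str] = []
    for t in tables:
        prov.extend(t.provenance)
    return LocalizationTable(df, dim, prov)


# ---------------------------------------------------------------------------
# run log


class RunLog:
    """Human-readable run log: one timestamped line per processing step."""

    def __init__(self, path=None) -> None:
        self.path = Path(path) if path is not None else None
        self.lines: list[str] = []
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)

    def log(self, message: str) -> str:
        stamp = _dt.datetime.now(_dt.timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        line = f"{stamp}  {message}"
        self.lines.append(line)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")
        return line

    def extend_from(self, other_path) -> None:
        """Concatenate another log file into this one (merge step)."""
        text = Path(other_path).read_text(encoding="utf-8")
        self.lines.extend(text.splitlines())
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(text if text.endswith("\n") or not text else text + "\n")
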