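"""Experiment-folder crawling, image loading, and results export.

An experiment is a single parent folder with one subfolder per culture well,
each named ``{embryo}_{treatment}_{rep}`` (delimiter-separated; configurable),
holding one grayscale TIFF/PNG quarter-field per explant.  Crawling yields one
:class:`Micrograph` per image in deterministic (lexicographic) order, with the
well metadata parsed from the folder name and the explant id from the file
stem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DEFAULT_PIXEL_SCALE_UM",
    "ExplantMeta",
    "Micrograph",
    "load_image",
    "crawl_experiment",
    "export_results",
]

#: default microns per pixel of the acquisition system this pipeline targets.
DEFAULT_PIXEL_SCALE_UM = 3.87

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}
_SUPPORTED_DTYPES = (np.uint8, np.uint16)


@dataclass(frozen=True)
class ExplantMeta:
    """Provenance of one explant image within the experiment hierarchy."""

    embryo_id: str
    treatment: str
    rep: str
    explant_id: str
    source_path: str = ""


@dataclass
class Micrograph:
    """Single-channel quarter-field image plus physical scale and metadata."""

    pixels: np.ndarray
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM
    meta: ExplantMeta | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError(f"pixels must be 2D and at least 2x2, got shape {self.pixels.shape}")
        if not self.pixel_scale_um > 0:
            raise ValueError(f"pixel_scale_um must be > 0, got {self.pixel_scale_um!r}")


def load_image(path: str | Path, channel: int = 0) -> np.ndarray:
    """Load a TIFF or PNG micrograph as a 2D 8/16-bit intensity array.

    Multi-channel images are reduced by selecting ``channel`` along the last
    (colour) axis; the default keeps the first channel.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _IMAGE_SUFFIXES:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"zero-size image file: {path}")
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # corrupt/truncated file
        raise ValueError(f"could not read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if not 0 <= channel < arr.shape[-1]:
            raise ValueError(f"channel {channel} out of range for {path} with shape {arr.shape}")
        arr = arr[..., channel]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D single-channel image in {path}, got shape {arr.shape}")
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}; expected 8- or 16-bit unsigned")
    return arr


def _parse_well_name(name: str, naming_pattern: str) -> dict[str, str]:
    """Map a well folder name onto the fields of ``naming_pattern``.

    The pattern is a delimiter-joined sequence of ``{field}`` placeholders,
    e.g. the default ``{embryo}_{treatment}_{rep}``; the folder name is split
    on the same delimiter.  A treatment name containing the delimiter cannot
    be represented — rename the folder or change the pattern.
    """
    fields = [p.strip("{}") for p in naming_pattern.split("_")]
    if any(not f for f in fields):
        raise ValueError(f"invalid naming_pattern {naming_pattern!r}")
    parts = name.split("_")
    if len(parts) != len(fields) or any(not p for p in parts):
        raise ValueError(
            f"well folder {name!r} does not match naming pattern {naming_pattern!r}"
        )
    return dict(zip(fields, parts))


def crawl_experiment(
    experiment_folder: str | Path,
    naming_pattern: str = "{embryo}_{treatment}_{rep}",
    *,
    channel: int = 0,
    pixel_scale_um: float = DEFAULT_PIXEL_SCALE_UM,
    strict: bool = False,
    progress: bool = False,
) -> list[Micrograph]:
    """Load every explant image under an experiment folder.

    First-level subfolders are wells; their names must match
    ``naming_pattern``.  Deeper nesting is ignored with a warning.  Images are
    returned in lexicographic path order so repeated runs are deterministic.
    With ``strict=False`` unreadable images are skipped with a warning so one
    corrupt file does not abort a batch; ``strict=True`` raises instead.
    ``progress=True`` prints an ascending image count while crawling.
    """
    root = Path(experiment_folder)
    if not root.is_dir():
        raise FileNotFoundError(f"experiment folder not found: {root}")
    micrographs: list[Micrograph] = []
    count = 0
    wells = sorted(p for p in root.iterdir() if p.is_dir())
    if not wells:
        warnings.warn(f"experiment folder {root} contains no well subfolders")
    for well_dir in wells:
        parsed = _parse_well_name(well_dir.name, naming_pattern)
        embryo = parsed.get("embryo", "")
        treatment = parsed.get("treatment", "")
        rep = parsed.get("rep", "")
        if not embryo or not treatment:
            raise ValueError(f"well folder {well_dir.name!r} yields empty embryo or treatment")
        if any(p.is_dir() for p in well_dir.iterdir()):
            warnings.warn(f"ignoring nested folders inside well {well_dir.name!r}")
        files = sorted(p for p in well_dir.iterdir()
                       if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            warnings.warn(f"well folder {well_dir.name!r} contains no images; skipped")
            continue
        for f in files:
            try:
                pixels = load_image(f, channel=channel)
            except (ValueError, FileNotFoundError):
                if strict:
                    raise
                warnings.warn(f"skipping unreadable image {f}")
                continue
            meta = ExplantMeta(
                embryo_id=embryo,
                treatment=treatment,
                rep=rep,
                explant_id=f.stem,
                source_path=str(f),
            )
            micrographs.append(Micrograph(pixels=pixels, pixel_scale_um=pixel_scale_um, meta=meta))
            count += 1
            if progress:
                print(count)
    if not micrographs:
        warnings.warn(f"no images found under {root}")
    return micrographs


_RESULT_COLUMNS = [
    "embryo_id", "treatment", "rep", "explant_id",
    "bin_start_um", "bin_end_um", "density", "is_well_mean",
]


def export_results(table, out_path: str | Path, *, wide: bool = False) -> Path:
    """Write the experiment results table as a UTF-8 CSV.

    ``table`` is an :class:`~axoquant.stats.ExperimentTable` or an equivalent
    tidy DataFrame with columns ``embryo_id, treatment, rep, explant_id,
    bin_start_um, bin_end_um, density, is_well_mean``; per-well mean rows carry
    ``explant_id == "WELL_MEAN"``.  Densities are written at full float
    precision so a re-read reproduces them exactly.  ``wide=True`` instead
    pivots bins into columns (one row per explant/well-mean) for spreadsheet
    use.
    """
    data = getattr(table, "data", table)
    if data is None or len(data) == 0:
        raise ValueError("cannot export an empty results table")
    data = pd.DataFrame(data)[_RESULT_COLUMNS]
    out_path = Path(out_path)
    if wide:
        widedf = data.pivot_table(
            index=["embryo_id", "treatment", "rep", "explant_id", "is_well_mean"],
            columns="bin_start_um", values="density", observed=True,
        ).reset_index()
        widedf.columns = [
            c if isinstance(c, str) else f"density_{c:g}um" for c in widedf.columns
        ]
        widedf.to_csv(out_path, index=False, encoding="utf-8")
    else:
        data.to_csv(out_path, index=False, encoding="utf-8", float_format="%.17g")
    return out_path
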