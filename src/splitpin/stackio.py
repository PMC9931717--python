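"""Reading and writing image stacks, result maps and sidecar reports.

Input stacks are plain multi-page grayscale TIFFs (8/16/32-bit integer
or 32-bit float), pages ordered by decreasing pinhole size; pinhole
sizes and pixel size are user-supplied because standard TIFF tags do not
record them. Output maps are written as 32-bit float single-page TIFFs
alongside a JSON sidecar holding every parameter actually used plus the
input hash, so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

from .decompose import DecompositionResult
from .errors import (
    InconsistentStackError,
    SplitPinError,
    TooFewFramesError,
    UnsupportedFormatError,
)
from .quics import QuicsReport
from .stack import PinholeStack

__all__ = ["StackMetadata", "load_stack", "save_stack", "save_outputs"]


@dataclass(frozen=True)
class StackMetadata:
    """Provenance of a loaded stack, recorded verbatim in output sidecars."""

    source_path: str
    n_frames: int
    dtype: str
    pinhole_sizes: tuple[float, ...] | None
    pixel_size: float | None
    reversed_flag: bool
    sha256: str


def _file_sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def load_stack(
    path: str | Path | list[str | Path],
    pinhole_sizes: tuple[float, ...] | None = None,
    pixel_size: float | None = None,
    reverse: bool = False,
) -> tuple[PinholeStack, StackMetadata]:
    """Load a multi-page TIFF (or several single/multi-page TIFFs) as a stack.

    Pages are taken in file order — largest pinhole first by convention;
    pass ``reverse=True`` if the acquisition ran the other way. With a
    list of paths the pages of each file are concatenated in the given
    order (some acquisition software exports one file per pinhole).

    Raises
    ------
    TooFewFramesError
        Fewer than 2 pages in total.
    UnsupportedFormatError
        RGB / multi-sample pages.
    InconsistentStackError
        Page shapes differ.
    """
    paths = [Path(p) for p in (path if isinstance(path, list) else [path])]
    pages: list[np.ndarray] = []
    for p in paths:
        with tifffile.TiffFile(p) as tif:
            for page in tif.pages:
                arr = np.asarray(page.asarray())
                if arr.ndim != 2:
                    raise UnsupportedFormatError(
                        f"{p}: only grayscale pages are supported, got a page "
                        f"of shape {arr.shape}"
                    )
                pages.append(arr)

    if len(pages) < 2:
        raise TooFewFramesError(
            f"stack has {len(pages)} page(s); at least 2 frames at different "
            "pinhole sizes are required"
        )
    shape0 = pages[0].shape
    if any(pg.shape != shape0 for pg in pages):
        raise InconsistentStackError(
            f"pages have differing shapes: {sorted({pg.shape for pg in pages})}"
        )

    frames = np.stack([pg.astype(np.float64) for pg in pages])
    if reverse:
        frames = frames[::-1].copy()

    stack = PinholeStack(
        frames=frames,
        pinhole_sizes=tuple(pinhole_sizes) if pinhole_sizes else (),
        pixel_size=pixel_size,
    )
    meta = StackMetadata(
        source_path=";".join(str(p) for p in paths),
        n_frames=stack.n_frames,
        dtype=str(pages[0].dtype),
        pinhole_sizes=tuple(pinhole_sizes) if pinhole_sizes else None,
        pixel_size=pixel_size,
        reversed_flag=reverse,
        sha256=";".join(_file_sha256(p) for p in paths),
    )
    return stack, meta


def save_stack(stack: PinholeStack, path: str | Path, dtype=np.float32) -> Path:
    """Write a stack as a multi-page TIFF (one page per pinhole size)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(dtype))
    return path


def save_outputs(
    result: DecompositionResult,
    out_dir: str | Path,
    report: QuicsReport | None = None,
    metadata: StackMetadata | None = None,
) -> dict[str, str]:
    """Write the four result maps, the JSON sidecar and optional QuICS files.

    Returns a manifest mapping artifact names to the paths written. The
    sidecar records the decomposition parameters actually used (estimated
    endpoints included), the software version, and the input provenance.
    """
    from . import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SplitPinError(f"cannot create output directory {out_dir}: {exc}")

    maps = {
        "split_pin": result.split_pin,
        "out_of_focus": result.out_of_focus,
        "modulation": result.phasor.modulation,
        "f_in": result.f_in,
    }
    manifest: dict[str, str] = {}
    for name, arr in maps.items():
        p = out_dir / f"{name}.tif"
        try:
            tifffile.imwrite(p, arr.astype(np.float32))
        except OSError as exc:
            raise SplitPinError(f"failed to write {p}: {exc}")
        manifest[name] = str(p)

    params = result.params_used
    sidecar = {
        "software": "splitpin",
        "version": __version__,
        "params": {
            "m_in": params.m_in,
            "m_out": params.m_out,
            "k_l": params.k_l,
            "j0": params.j0,
            "intensity_threshold": params.intensity_threshold,
            "percentiles": list(params.percentiles),
        },
        "out_of_range_fraction": result.out_of_range_fraction,
        "input": asdict(metadata) if metadata else None,
    }
    sidecar_path = out_dir / "splitpin_run.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    manifest["sidecar"] = str(sidecar_path)

    if report is not None:
        report_path = out_dir / "quics_report.json"
        report_path.write_text(json.dumps(report.as_dict(), indent=2))
        manifest["quics_report"] = str(report_path)
        acf_path = out_dir / "quics_acf.csv"
        with open(acf_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["lag_px", "G", "G_fit"])
            fit = report.fit
            for lag, g in zip(report.acf.lags, report.acf.values):
                g_fit = fit.amplitude * np.exp(-(float(lag) ** 2) / fit.width**2) + fit.offset
                writer.writerow([int(lag), f"{g:.8g}", f"{g_fit:.8g}"])
        manifest["quics_acf"] = str(acf_path)

    return manifest
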