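"""TIFF z-stack input/output and run logging.

Stacks are multi-page grayscale TIFFs; page order is z, rows are y, columns
x.  Values are converted to 32-bit float internally regardless of the file
encoding.  When writing 16-bit output the volume is rescaled by
s = 65535 / max so it fits the integer range, and s is recorded in the run
log: downstream quantification (e.g. un-scaling dot intensities) needs it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import tifffile

from .deconv import VolumeImage

__all__ = ["RunLog", "read_stack", "write_stack", "write_log"]


@dataclass
class RunLog:
    """Everything needed to reproduce a run: parameters, provenance,
    per-iteration objective values and the u16 rescale factor."""

    parameters: dict = field(default_factory=dict)
    psf_provenance: str = ""
    per_iteration: list[float] = field(default_factory=list)
    rescale_factor: float = 1.0
    timestamps: dict = field(default_factory=dict)

    def stamp(self, event: str) -> None:
        self.timestamps[event] = datetime.now(timezone.utc).isoformat()


def read_stack(path: str | Path, voxel: tuple[float, float, float] = (130.0, 130.0, 130.0)) -> VolumeImage:
    """Read a multi-page grayscale TIFF as a float32 volume (z, y, x).

    Voxel sizes come from the caller/CLI; a single page yields nz = 1.
    RGB or otherwise non-grayscale files are rejected with a format error.
    """
    try:
        with tifffile.TiffFile(str(path)) as tif:
            series = tif.series[0]
            if "S" in series.axes or series.axes.endswith(("3", "4")):
                raise ValueError(
                    f"{path}: RGB/multi-sample TIFF is not a grayscale z-stack"
                )
            data = series.asarray()
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale z-stack, got array of shape {data.shape}"
        )
    return VolumeImage(data.astype(np.float32), voxel=voxel)


def write_stack(
    img: VolumeImage,
    path: str | Path,
    encoding: str = "f32",
    preserve_values: bool = True,
    log: RunLog | None = None,
) -> RunLog:
    """Write a volume as TIFF; returns the run log with the rescale factor.

    ``f32`` writes the float data verbatim.  ``u16`` writes
    round(img * s) with s = 65535 / max(img); with ``preserve_values`` and
    max <= 65535 no rescaling is applied (s = 1).
    """
    if not np.all(np.isfinite(img.data)):
        raise ValueError("refusing to write non-finite voxel values")
    log = log or RunLog()
    if encoding == "f32":
        tifffile.imwrite(str(path), img.data.astype(np.float32), photometric="minisblack")
        log.rescale_factor = 1.0
    elif encoding == "u16":
        peak = float(img.data.max())
        if preserve_values and peak <= 65535.0:
            s = 1.0
        else:
            s = 65535.0 / peak if peak > 0 else 1.0
        out = np.round(img.data.astype(np.float64) * s)
        tifffile.imwrite(
            str(path), np.clip(out, 0, 65535).astype(np.uint16), photometric="minisblack"
        )
        log.rescale_factor = s
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    log.parameters.setdefault("encoding", encoding)
    log.stamp("written")
    return log


def write_log(log: RunLog, path: str | Path) -> None:
    """Write the run log as readable key/value text with a JSON tail."""
    lines = [f"rescale_factor = {log.rescale_factor!r}"]
    lines += [f"{k} = {v!r}" for k, v in sorted(log.parameters.items())]
    if log.psf_provenance:
        lines.append(f"psf = {log.psf_provenance}")
    for k, v in sorted(log.timestamps.items()):
        lines.append(f"time.{k} = {v}")
    if log.per_iteration:
        lines.append("iteration\tobjective")
        lines += [f"{i + 1}\t{v:.8g}" for i, v in enumerate(log.per_iteration)]
    payload = {
        "parameters": log.parameters,
        "psf_provenance": log.psf_provenance,
        "rescale_factor": log.rescale_factor,
        "timestamps": log.timestamps,
    }
    text = "\n".join(lines) + "\n# json: " + json.dumps(payload) + "\n"
    Path(path).write_text(text)
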