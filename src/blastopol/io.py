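"""TIFF / CSV / YAML input and output.

Image stacks are stored as plain multi-page TIFF with axes T x Z x Y x X
(16-bit); tables are UTF-8 comma-separated CSV with a mandatory header row
and a leading comment line carrying the config hash and seed so that every
output is traceable to the run that produced it.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

__all__ = ["ImageStack", "read_stack", "write_stack", "write_table", "read_table"]


@dataclass
class ImageStack:
    """Calibrated in-memory stack with optional label companions."""

    data: np.ndarray              # (t, z, y, x)
    pixel_size_um: float
    z_step_um: float
    frame_interval_min: float
    labels: np.ndarray | None = None
    nuclei: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def read_stack(
    path: str | Path,
    *,
    axes: str = "TZYX",
    pixel_size_um: float = 1.0,
    z_step_um: float = 1.0,
    frame_interval_min: float = 1.0,
) -> ImageStack:
    """Read a TIFF stack and normalize axes to (t, z, y, x).

    ``axes`` declares the on-disk order; a 3-D file with ``axes='TYX'`` is
    promoted with a singleton z-dimension.  2-D images are rejected.
    """
    arr = tifffile.imread(str(path))
    axes = axes.upper()
    if arr.ndim != len(axes):
        raise FormatError(
            f"{path}: {arr.ndim}-D data does not match declared axes {axes!r} "
            f"(expected {len(axes)}-D)"
        )
    if arr.ndim == 2:
        raise FormatError(f"{path}: plain 2-D image; a T x Z x Y x X stack is required")
    if sorted(axes) not in (sorted("TZYX"), sorted("TYX")):
        raise FormatError(f"unsupported axes {axes!r}; expected TZYX or TYX")
    order = [axes.index(a) for a in ("TZYX" if len(axes) == 4 else "TYX")]
    arr = np.transpose(arr, order)
    if arr.ndim == 3:
        arr = arr[:, None]
    return ImageStack(
        data=arr,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        frame_interval_min=frame_interval_min,
    )


def write_stack(path: str | Path, data: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(data), metadata={"axes": "TZYX"})


def write_table(df: pd.DataFrame, path: str | Path, *, config_hash: str = "", seed=None) -> None:
    """Write a CSV with a provenance comment line, byte-reproducibly."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# blastopol config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
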