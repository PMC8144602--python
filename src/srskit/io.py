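"""File formats: multi-page TIFF stacks, axis sidecars, and provenance.

Stacks are plain multi-page 32-bit float TIFFs, page ``k`` holding spectral
channel ``k`` (ImageJ-compatible plane order, no compression).  The spectral
axis travels in a sidecar CSV ``<stem>.axis.csv`` with columns
``channel,raman_shift_cm1`` so that any TIFF reader can still open the data.
Outputs written through :func:`write_stack` may carry a ``<stem>.meta.json``
provenance sidecar (stage name, seed, config hash).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .delayline import SpectralAxis
from .simulate import HyperspectralStack

__all__ = [
    "StackFormatError",
    "axis_sidecar_path",
    "write_axis_csv",
    "read_axis_csv",
    "write_stack",
    "read_stack",
    "write_metadata",
]


class StackFormatError(ValueError):
    """Raised for malformed stack files."""


def axis_sidecar_path(stack_path) -> Path:
    p = Path(stack_path)
    return p.with_suffix("").with_suffix(".axis.csv") if p.suffix else p.with_suffix(".axis.csv")


def write_axis_csv(axis: SpectralAxis, path) -> None:
    pd.DataFrame(
        {"channel": np.arange(len(axis)), "raman_shift_cm1": axis.wavenumbers}
    ).to_csv(path, index=False)


def read_axis_csv(path) -> SpectralAxis:
    df = pd.read_csv(path)
    if "raman_shift_cm1" not in df.columns:
        raise StackFormatError("axis CSV must have a 'raman_shift_cm1' column")
    return SpectralAxis(df["raman_shift_cm1"].to_numpy(float))


def write_stack(
    stack: HyperspectralStack,
    path,
    metadata: dict | None = None,
) -> None:
    """Write a stack as an uncompressed multi-page float32 TIFF plus sidecars."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), photometric="minisblack")
    write_axis_csv(stack.axis, axis_sidecar_path(path))
    if metadata is not None:
        write_metadata(path, metadata)


def read_stack(path, expected_channels: int | None = None) -> HyperspectralStack:
    """Read a multi-page TIFF stack; restore its axis from the sidecar CSV.

    Without a sidecar the axis falls back to channel indices (with a
    warning).  Pages of inconsistent shape or a channel-count mismatch with
    ``expected_channels`` raise :class:`StackFormatError`.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise StackFormatError(f"cannot read {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackFormatError(
            f"{path}: expected pages of identical 2-D shape, got array of rank {data.ndim}"
        )
    if expected_channels is not None and data.shape[0] != expected_channels:
        raise StackFormatError(
            f"{path}: {data.shape[0]} pages but {expected_channels} channels declared"
        )
    sidecar = axis_sidecar_path(path)
    if sidecar.exists():
        axis = read_axis_csv(sidecar)
        if len(axis) != data.shape[0]:
            raise StackFormatError(
                f"{path}: sidecar axis has {len(axis)} channels, stack has {data.shape[0]}"
            )
    else:
        warnings.warn(
            f"{path}: no axis sidecar found; using channel indices", stacklevel=2
        )
        axis = SpectralAxis(np.arange(data.shape[0], dtype=float))
    return HyperspectralStack(data=data.astype(np.float32), axis=axis)


def write_metadata(output_path, metadata: dict) -> None:
    """Write the provenance sidecar ``<stem>.meta.json`` next to an output."""
    p = Path(output_path)
    meta_path = p.with_suffix("").with_suffix(".meta.json")
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True))
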