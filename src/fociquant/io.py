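"""TIFF input/output and z-plane selection.

Stacks are stored on disk as multi-page TIFF in ``(z, channel, y, x)``
order (single planes as ``(channel, y, x)``); in memory they are always
normalized to 4-D. Quantification runs on one plane: the z-slice with the
largest total nuclear area, the standard "central plane of the nucleus"
convention for confocal stacks.
"""
from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import tifffile

from .exceptions import ChannelRoleError, EmptyFieldError, FociquantError
from .types import ChannelStack


def save_stack(path: str | Path, stack: ChannelStack) -> None:
    """Write a stack as TIFF; single-plane stacks drop the z axis on disk."""
    pixels = stack.pixels
    if pixels.shape[0] == 1:
        pixels = pixels[0]
    tifffile.imwrite(str(path), pixels, photometric="minisblack")


def load_stack(path: str | Path, roles: dict[str, int]) -> ChannelStack:
    """Read a TIFF into a :class:`ChannelStack` with the given role map.

    2-D files are treated as one channel, 3-D as ``(channel, y, x)`` and 4-D
    as ``(z, channel, y, x)``. Raises :class:`ChannelRoleError` naming the
    offending role when an index is out of range.
    """
    try:
        pixels = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise FociquantError(f"cannot read TIFF {path}: {exc}") from exc
    if pixels.ndim == 2:
        pixels = pixels[np.newaxis, np.newaxis]
    elif pixels.ndim == 3:
        pixels = pixels[np.newaxis]
    elif pixels.ndim != 4:
        raise FociquantError(f"{path}: unsupported TIFF dimensionality {pixels.ndim}")
    n_channels = pixels.shape[1]
    for role, idx in roles.items():
        if not 0 <= idx < n_channels:
            raise ChannelRoleError(
                f"{path}: role {role!r} maps to channel {idx}, "
                f"but the file has {n_channels} channels")
    return ChannelStack(pixels, dict(roles))


def central_plane(stack: ChannelStack,
                  nuclei_per_slice: Callable[[np.ndarray], np.ndarray]) -> int:
    """Index of the z-slice with the largest total nuclear area.

    ``nuclei_per_slice`` is a nucleus-segmentation procedure mapping a DNA
    image to a label mask (e.g. :func:`fociquant.segmentation.segment_nuclei`).
    Ties break toward the lower index. Raises :class:`EmptyFieldError` when
    no slice contains a nucleus.
    """
    areas = np.empty(stack.n_z, dtype=np.int64)
    for z in range(stack.n_z):
        labels = nuclei_per_slice(stack.channel("dna", z=z))
        areas[z] = int(np.count_nonzero(labels))
    if areas.max() == 0:
        raise EmptyFieldError("no nucleus detected in any z-slice")
    return int(np.argmax(areas))
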