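"""Core in-memory containers.

Conventions used throughout the package:

* pixel arrays are indexed ``[y, x]`` (row-major, 0-based);
* multi-channel stacks are ``[z, channel, y, x]`` with ``z == 1`` for single
  planes;
* label masks are integer images where 0 is background and each positive
  label is one object; labels are stable join keys and are never recycled
  after filtering.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ChannelRoleError

#: Channel roles the pipeline understands. ``dna`` (DAPI), ``f_actin``
#: (phalloidin) and ``ha`` (tagged transfected protein) are required for the
#: core analysis; the rest are optional markers.
KNOWN_ROLES = ("dna", "f_actin", "ha", "polii", "edu", "wip", "cortactin")


@dataclass
class ChannelStack:
    """A multi-channel fluorescence image, optionally z-stacked.

    Parameters
    ----------
    pixels
        Array of shape ``(z, channel, y, x)`` with nonnegative intensities.
    roles
        Mapping from role name (e.g. ``"dna"``) to channel index.
    pixel_size
        Optional lateral pixel size in micrometres (metadata only).
    """

    pixels: np.ndarray
    roles: dict[str, int] = field(default_factory=dict)
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3:  # (channel, y, x) -> single plane
            self.pixels = self.pixels[np.newaxis]
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must have shape (z, channel, y, x); got {self.pixels.shape}"
            )
        n_channels = self.pixels.shape[1]
        for role, idx in self.roles.items():
            if not 0 <= idx < n_channels:
                raise ChannelRoleError(
                    f"role {role!r} maps to channel {idx}, but the stack has "
                    f"{n_channels} channels"
                )
        if np.issubdtype(self.pixels.dtype, np.floating) and np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, role: str, z: int = 0) -> np.ndarray:
        """Return one channel plane as float64, addressed by role name."""
        if role not in self.roles:
            raise ChannelRoleError(f"stack has no channel for role {role!r}; "
                                   f"available roles: {sorted(self.roles)}")
        return np.asarray(self.pixels[z, self.roles[role]], dtype=np.float64)

    def plane(self, z: int) -> "ChannelStack":
        """Return a single z-plane as a new stack (z dimension kept, length 1)."""
        return ChannelStack(self.pixels[z:z + 1], dict(self.roles), self.pixel_size)
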