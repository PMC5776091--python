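"""In-memory time-lapse stacks and OME-TIFF round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """A (frame, channel, row, column) intensity stack with physical metadata.

    Intensities are arbitrary units (nonnegative floats); ``pixel_size`` is
    micrometers per pixel and ``frame_interval`` is seconds between frames
    (uniform spacing).
    """

    data: np.ndarray                      # (T, C, H, W) float32
    pixel_size: float                     # um / px
    frame_interval: float                 # s
    channels: List[str] = field(default_factory=lambda: ["phase", "mcherry"])

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4-D (frame, channel, row, col)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if self.data.shape[1] < 2:
            raise ValueError("a stack needs at least 2 channels")
        if self.data.min() < 0:
            raise ValueError("stack intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        """(T, H, W) view of one named channel."""
        return self.data[:, self.channels.index(name)]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    # ------------------------------------------------------------------
    def to_tiff(self, path) -> None:
        """Write as OME-TIFF with channel names and physical pixel size."""
        tifffile.imwrite(
            str(path),
            self.data,
            ome=True,
            metadata={
                "axes": "TCYX",
                "Channel": {"Name": list(self.channels)},
                "PhysicalSizeX": self.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size,
                "PhysicalSizeYUnit": "µm",
                "TimeIncrement": self.frame_interval,
                "TimeIncrementUnit": "s",
            },
        )

    @classmethod
    def from_tiff(cls, path) -> "ImageStack":
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            meta = tf.ome_metadata
        import xml.etree.ElementTree as ET

        pixel_size = 0.1
        frame_interval = 60.0
        channels = None
        if meta:
            root = ET.fromstring(meta)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                if px.get("PhysicalSizeX"):
                    pixel_size = float(px.get("PhysicalSizeX"))
                if px.get("TimeIncrement"):
                    frame_interval = float(px.get("TimeIncrement"))
                names = [c.get("Name") for c in px.findall("ome:Channel", ns)]
                if names and all(n for n in names):
                    channels = names
        if data.ndim == 3:  # single-channel fallback
            data = data[:, None]
        if channels is None or len(channels) != data.shape[1]:
            channels = [f"ch{i}" for i in range(data.shape[1])]
        return cls(
            data=np.clip(data.astype(np.float32), 0, None),
            pixel_size=pixel_size,
            frame_interval=frame_interval,
            channels=channels,
        )
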