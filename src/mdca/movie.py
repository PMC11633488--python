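"""In-memory container and disk I/O for two-photon fluorescence movies.

A movie is a T x H x W stack of fluorescence counts with a frame rate and a
pixel size. The nominal acquisition geometry is a 512 x 512 pixel frame over
a 420 um x 420 um field of view at 10 Hz, giving 0.8203125 um per pixel;
smaller test movies keep the same pixel size unless told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: um per pixel of the nominal 420 um field imaged at 512 px.
DEFAULT_PIXEL_SIZE_UM = 420.0 / 512.0


@dataclass
class CalciumMovie:
    """Fluorescence stack with acquisition metadata.

    Parameters
    ----------
    data:
        Array of shape (T, H, W), fluorescence counts (a.u.). Stored as
        float32 internally so that preprocessing does not overflow integer
        camera counts.
    frame_rate_hz:
        Acquisition rate; the time of frame ``t`` is ``t / frame_rate_hz``.
    pixel_size_um:
        Side length of one pixel in micrometres.
    """

    data: np.ndarray
    frame_rate_hz: float = 10.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"movie data must be T x H x W, got shape {arr.shape}")
        if arr.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.data = arr.astype(np.float32, copy=False)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def with_data(self, data: np.ndarray) -> "CalciumMovie":
        """Return a copy of the metadata wrapped around new pixel data."""
        return replace(self, data=data)


def write_movie_tiff(path, movie: CalciumMovie) -> None:
    """Write a movie as an ImageJ-compatible 16-bit multi-page TIFF.

    Counts are clipped to the uint16 range; ImageJ metadata records the
    frame rate so the stack reloads with its time axis.
    """
    data = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        metadata={"axes": "TYX", "finterval": 1.0 / movie.frame_rate_hz},
    )


def read_movie_tiff(path, frame_rate_hz: float = 10.0,
                    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> CalciumMovie:
    """Load a multi-page TIFF stack as a :class:`CalciumMovie`."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return CalciumMovie(data=np.asarray(data, dtype=np.float32),
                        frame_rate_hz=frame_rate_hz, pixel_size_um=pixel_size_um)
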