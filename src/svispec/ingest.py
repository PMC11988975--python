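"""Reading and preparing video acquisitions.

An acquisition is an ordered stack of RGB frames recorded while the phone
screen sweeps through a colour gradient. Sources are directories of still
frames (PNG/JPG, lexicographic filename order = frame order); a decoded
video can be passed through the same contract as an in-memory stack.
Channel order is normalised to R,G,B at read time regardless of codec.

Typical preparation: read, truncate to a common frame count (videos of the
same nominal duration decode to 177-179 frames), then crop the fixed
region of interest at the centre of the field of view.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "FrameSequence",
    "ROISpec",
    "FrameFormatError",
    "InsufficientFramesError",
    "read_frame_dir",
    "write_frame_dir",
    "truncate_frames",
    "crop_roi",
]

DEFAULT_FRAME_COUNT = 177
DEFAULT_ROI_SIZE = 120

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


class FrameFormatError(ValueError):
    """Frames are missing, non-image, or inconsistently shaped."""


class InsufficientFramesError(ValueError):
    """Fewer frames available than the requested target count."""


@dataclass
class FrameSequence:
    """Ordered stack of H×W×3 colour frames (uint8, R,G,B) from one acquisition."""

    frames: np.ndarray  # (F, H, W, 3) uint8
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise FrameFormatError(
                f"expected (F, H, W, 3) colour frames, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            if self.frames.min() < 0 or self.frames.max() > 255:
                raise FrameFormatError("channel values must lie in [0, 255]")
            self.frames = self.frames.astype(np.uint8)

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass(frozen=True)
class ROISpec:
    """Fixed rectangular region of interest, offsets in pixels from the top-left."""

    top: int
    left: int
    height: int = DEFAULT_ROI_SIZE
    width: int = DEFAULT_ROI_SIZE

    @classmethod
    def centered(
        cls, frame_height: int, frame_width: int,
        height: int = DEFAULT_ROI_SIZE, width: int = DEFAULT_ROI_SIZE,
    ) -> "ROISpec":
        """ROI of the given size centred in the frame (offsets rounded down)."""
        if height > frame_height or width > frame_width:
            raise ValueError(
                f"ROI {height}x{width} does not fit in frame {frame_height}x{frame_width}"
            )
        return cls(top=(frame_height - height) // 2, left=(frame_width - width) // 2,
                   height=height, width=width)


def read_frame_dir(path: str | os.PathLike) -> FrameSequence:
    """Read all still images in *path* as one acquisition.

    Lexicographic filename order defines frame order. All frames must share
    one shape; pixel data are returned in R,G,B channel order.
    """
    names = sorted(
        n for n in os.listdir(path)
        if os.path.splitext(n)[1].lower() in _IMAGE_EXTENSIONS
    )
    if not names:
        raise FrameFormatError(f"no decodable frames found in {path!r}")
    frames = []
    shape = None
    for name in names:
        with Image.open(os.path.join(path, name)) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.uint8)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FrameFormatError(
                f"frame {name!r} has shape {arr.shape}, expected {shape}"
            )
        frames.append(arr)
    return FrameSequence(frames=np.stack(frames), source_id=os.path.basename(os.fspath(path)))


def write_frame_dir(seq: FrameSequence, path: str | os.PathLike) -> None:
    """Write frames as zero-padded ``frame_000.png`` ... (lossless PNG)."""
    os.makedirs(path, exist_ok=True)
    pad = max(3, len(str(seq.frame_count - 1)))
    for i in range(seq.frame_count):
        Image.fromarray(seq.frames[i]).save(
            os.path.join(path, f"frame_{i:0{pad}d}.png")
        )


def truncate_frames(seq: FrameSequence, target: int = DEFAULT_FRAME_COUNT) -> FrameSequence:
    """Keep exactly the first *target* frames so all acquisitions align."""
    if target < 1:
        raise ValueError(f"target frame count must be >= 1, got {target}")
    if seq.frame_count < target:
        raise InsufficientFramesError(
            f"{seq.source_id or 'sequence'}: has {seq.frame_count} frames, "
            f"needs {target} ({target - seq.frame_count} short)"
        )
    return FrameSequence(frames=seq.frames[:target].copy(), source_id=seq.source_id)


def crop_roi(seq: FrameSequence, roi: ROISpec | None = None) -> FrameSequence:
    """Replace every frame by its region of interest.

    With ``roi=None`` the default centred 120×120 window is used, matching
    the fixed acquisition geometry (sample parallel to the screen at a
    fixed standoff, so the sample always occupies the frame centre).
    """
    if roi is None:
        roi = ROISpec.centered(seq.height, seq.width)
    if roi.top < 0 or roi.top + roi.height > seq.height:
        raise ValueError(
            f"ROI rows [{roi.top}, {roi.top + roi.height}) outside frame height {seq.height}"
        )
    if roi.left < 0 or roi.left + roi.width > seq.width:
        raise ValueError(
            f"ROI cols [{roi.left}, {roi.left + roi.width}) outside frame width {seq.width}"
        )
    sub = seq.frames[:, roi.top:roi.top + roi.height, roi.left:roi.left + roi.width, :]
    return FrameSequence(frames=sub.copy(), source_id=seq.source_id)
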