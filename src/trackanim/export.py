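"""Frame-sequence and video export.

Frames are rendered deterministically, watermarked in the upper-right
corner, and written as zero-padded PNGs; encoding the sequence into an
H.264 MP4 is delegated to a narrow encoder adapter (input: PNG paths +
fps, output: video file). When no encoder is available the frames are
still written and an explicit :class:`EncoderUnavailableError` names the
missing dependency — so the PNG pipeline works everywhere and video is a
bonus where ffmpeg exists.

Videos are named ``<title>_<n>.mp4`` in the export folder, with *n* the
auto-incremented recording number; with ``store_frames`` the per-frame
PNGs persist under ``<out_dir>/temp``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Callable, Sequence

from PIL import Image, ImageDraw

from .render import FrameContext, _font, render_frame

__all__ = [
    "EncoderUnavailableError",
    "export_animation",
    "watermark",
    "ffmpeg_encoder",
]

WATERMARK_TEXT = "rendered with trackanim"
_WATERMARK_INSET_PX = 8

#: An encoder turns a PNG sequence plus fps into a video file.
Encoder = Callable[[Sequence[Path], float, Path], None]


class EncoderUnavailableError(RuntimeError):
    """No video encoder is importable; frames were still written."""

    def __init__(self, encoder_name: str, frame_paths: list[Path]):
        self.encoder_name = encoder_name
        self.frame_paths = frame_paths
        super().__init__(
            f"video encoder unavailable (missing {encoder_name}); "
            f"{len(frame_paths)} PNG frames were written"
        )


def watermark(frame: Image.Image) -> Image.Image:
    """Composite the semi-transparent watermark into the upper-right corner."""
    overlay = Image.new("RGBA", frame.size, (0, 0, 0, 0))
    draw = ImageDraw.Draw(overlay)
    font = _font(12)
    width = draw.textlength(WATERMARK_TEXT, font=font)
    x = frame.size[0] - _WATERMARK_INSET_PX - width
    draw.text((x, _WATERMARK_INSET_PX), WATERMARK_TEXT, font=font, fill=(255, 255, 255, 160))
    draw.text((x + 1, _WATERMARK_INSET_PX + 1), WATERMARK_TEXT, font=font, fill=(0, 0, 0, 110))
    return Image.alpha_composite(frame, overlay)


def ffmpeg_encoder(frame_paths: Sequence[Path], fps: float, out_path: Path) -> None:
    """Default adapter: H.264 MP4 via imageio's ffmpeg plugin.

    Raises ImportError when the ffmpeg backend (imageio-ffmpeg) is not
    installed.
    """
    import imageio.v2 as iio

    writer = iio.get_writer(str(out_path), format="FFMPEG", fps=fps, codec="libx264")
    try:
        for path in frame_paths:
            writer.append_data(iio.imread(str(path)))
    finally:
        writer.close()


def _next_recording_number(out_dir: Path, title: str) -> int:
    pattern = re.compile(re.escape(title) + r"_(\d+)\.mp4$")
    numbers = [
        int(m.group(1)) for p in out_dir.glob(f"{title}_*.mp4") if (m := pattern.match(p.name))
    ]
    return max(numbers, default=0) + 1


def export_animation(
    contexts: Sequence[FrameContext],
    fps: float,
    out_dir: str | Path,
    title: str,
    store_frames: bool = False,
    encoder: Encoder | None = ffmpeg_encoder,
) -> tuple[Path | None, list[Path]]:
    """Render, watermark and export a frame sequence, then encode a video.

    Returns ``(video_path, frame_paths)``. PNGs are written under
    ``<out_dir>/temp``; without ``store_frames`` they are removed again
    after a successful encode. ``encoder=None`` skips encoding (frames
    only, video path ``None``).
    If the configured encoder's backend is missing, frames are kept and
    :class:`EncoderUnavailableError` is raised.
    """
    if not contexts:
        raise ValueError("need at least one frame context")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # frames always go to <out_dir>/temp so they survive an encoder failure;
    # without store_frames they are removed again after a successful encode
    frames_dir = out_dir / "temp"
    frames_dir.mkdir(exist_ok=True)

    width = max(4, len(str(len(contexts))))
    frame_paths: list[Path] = []
    for i, ctx in enumerate(contexts):
        frame = watermark(render_frame(ctx))
        path = frames_dir / f"frame_{i:0{width}d}.png"
        frame.save(path, format="PNG")
        frame_paths.append(path)

    if encoder is None:
        return None, frame_paths

    number = _next_recording_number(out_dir, title)
    video_path = out_dir / f"{title}_{number}.mp4"
    try:
        encoder(frame_paths, fps, video_path)
    except ImportError as exc:
        raise EncoderUnavailableError(
            getattr(exc, "name", None) or "imageio-ffmpeg", frame_paths
        ) from exc
    if not store_frames:
        for path in frame_paths:
            path.unlink()
        if not any(frames_dir.iterdir()):
            frames_dir.rmdir()
        frame_paths = []
    return video_path, frame_paths
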