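"""Minimal uncompressed AVI container support.

Writes and reads RIFF/AVI files holding raw 24-bit BGR frames
(``biCompression = BI_RGB``), the plainest AVI flavour there is; the files
play in VLC/ffplay and round-trip losslessly, which the pipeline relies on
for its synthetic ground truth. Only this single flavour is supported:
one video stream, no audio, no compression.

Frame rate is stored exactly as the ``dwRate/dwScale`` rational of the
stream header.
"""

from __future__ import annotations

import struct
from fractions import Fraction
from pathlib import Path

import numpy as np

from .errors import FormatError

_AVIF_HASINDEX = 0x10


def _pad_width(width: int) -> int:
    """Bytes per BGR row, padded to a 4-byte boundary (BMP convention)."""
    return (width * 3 + 3) & ~3


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (N, H, W, 3 uint8, RGB order) as uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[3] != 3 or frames.dtype != np.uint8:
        raise FormatError("frames must be (N, H, W, 3) uint8")
    if fps <= 0:
        raise FormatError("fps must be positive")
    n, height, width, _ = frames.shape
    rate = Fraction(fps).limit_denominator(65535)
    row_bytes = _pad_width(width)
    frame_bytes = row_bytes * height

    # BGR, bottom-up rows, padded — the BI_RGB layout.
    pad = row_bytes - width * 3
    raw = frames[:, ::-1, :, ::-1]
    if pad:
        buf = np.zeros((n, height, row_bytes), dtype=np.uint8)
        buf[:, :, : width * 3] = raw.reshape(n, height, width * 3)
    else:
        buf = np.ascontiguousarray(raw).reshape(n, height, row_bytes)

    avih = struct.pack(
        "<14I",
        int(round(1_000_000 * rate.denominator / rate.numerator)),  # usec/frame
        frame_bytes * max(1, int(round(float(rate)))),  # max bytes/sec
        0,
        _AVIF_HASINDEX,
        n,
        0,
        1,  # one stream
        frame_bytes,
        width,
        height,
        0, 0, 0, 0,
    )
    strh = (
        b"vids" + b"DIB " + struct.pack(
            "<10I4h",
            0, 0, 0,
            rate.denominator,  # dwScale
            rate.numerator,    # dwRate
            0, n, frame_bytes, 0xFFFFFFFF, 0,
            0, 0, width, height,
        )
    )
    strf = struct.pack(
        "<I2i2H2I2i2I",
        40, width, height, 1, 24, 0, frame_bytes, 0, 0, 0, 0,
    )

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        data = fourcc + struct.pack("<I", len(payload)) + payload
        if len(payload) % 2:
            data += b"\x00"
        return data

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"".join(
        chunk(b"00db", buf[i].tobytes()) for i in range(n)
    )
    movi = lst(b"movi", movi_payload)

    # idx1: offsets are relative to the start of the 'movi' fourcc data.
    idx_entries = []
    offset = 4
    for _ in range(n):
        idx_entries.append(struct.pack("<4s3I", b"00db", 0x10, offset, frame_bytes))
        offset += 8 + frame_bytes + (frame_bytes % 2)
    idx1 = chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def _iter_chunks(data: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = data[pos : pos + 4]
        (size,) = struct.unpack_from("<I", data, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns ``(frames RGB uint8, fps)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = path.read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise FormatError(f"{path} is not an AVI (RIFF) file")

    fps: float | None = None
    width = height = None
    bitcount = compression = None
    frames_raw: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal fps, width, height, bitcount, compression
        for fourcc, off, size in _iter_chunks(data, start, end):
            if fourcc == b"LIST":
                walk(off + 4, off + size)
            elif fourcc == b"strh" and size >= 48:
                if data[off : off + 4] == b"vids":
                    scale, rate = struct.unpack_from("<2I", data, off + 20)
                    if scale and rate:
                        fps = rate / scale
            elif fourcc == b"strf" and size >= 40 and width is None:
                (_, w, h, _, bc, comp) = struct.unpack_from("<I2i2HI", data, off)
                width, height, bitcount, compression = w, abs(h), bc, comp
            elif fourcc in (b"00db", b"00dc"):
                frames_raw.append(data[off : off + size])

    walk(12, len(data))
    if width is None or fps is None:
        raise FormatError(f"{path}: missing AVI stream headers")
    if compression != 0 or bitcount != 24:
        raise FormatError(
            f"{path}: only uncompressed 24-bit AVI is supported "
            f"(got biCompression={compression}, biBitCount={bitcount})"
        )
    row_bytes = _pad_width(width)
    out = np.empty((len(frames_raw), height, width, 3), dtype=np.uint8)
    for i, blob in enumerate(frames_raw):
        if len(blob) < row_bytes * height:
            raise FormatError(f"{path}: truncated frame {i}")
        arr = np.frombuffer(blob, dtype=np.uint8, count=row_bytes * height)
        arr = arr.reshape(height, row_bytes)[:, : width * 3].reshape(height, width, 3)
        out[i] = arr[::-1, :, ::-1]  # bottom-up BGR -> top-down RGB
    return out, float(fps)
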