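"""Reading and writing of pattern rasters (PGM / PNG / CSV).

Grayscale 8-bit images map linearly to concentrations in [0, 1]
(pixel / 255).  PGM is written as plain-text P2 by default (P5 binary
optional); PNG goes through Pillow.  CSV matrices hold float values
directly and round-trip without quantization.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = [
    "write_pgm", "read_pgm", "write_png", "read_png",
    "write_csv", "read_csv", "read_pattern", "write_pattern",
    "quantize8", "dequantize8",
]


def quantize8(values: np.ndarray) -> np.ndarray:
    """[0,1] floats -> uint8 levels (round-half-away from zero via rint)."""
    v = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    return np.rint(v * 255.0).astype(np.uint8)


def dequantize8(levels: np.ndarray) -> np.ndarray:
    return np.asarray(levels, dtype=float) / 255.0


def write_pgm(path, values: np.ndarray, binary: bool = False) -> None:
    levels = quantize8(values)
    h, w = levels.shape
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode())
            fh.write(levels.tobytes())
        return
    lines = [f"P2", f"{w} {h}", "255"]
    for row in levels:
        lines.append(" ".join(str(int(x)) for x in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_tokens(fh):
    for raw in fh:
        line = raw.split(b"#", 1)[0] if isinstance(raw, bytes) else raw.split("#", 1)[0]
        if isinstance(line, bytes):
            line = line.decode()
        yield from line.split()


def read_pgm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic == b"P2":
            tokens = list(_read_tokens(fh))
            w, h, maxval = int(tokens[0]), int(tokens[1]), int(tokens[2])
            data = np.array(tokens[3:3 + w * h], dtype=float).reshape(h, w)
        elif magic == b"P5":
            dims = []
            while len(dims) < 3:
                line = fh.readline().split(b"#", 1)[0]
                dims.extend(int(t) for t in line.split())
            w, h, maxval = dims
            data = np.frombuffer(fh.read(w * h), dtype=np.uint8).astype(float)
            data = data.reshape(h, w)
        else:
            raise ValueError(f"not a PGM file (magic {magic!r})")
    return data / maxval


def write_png(path, values: np.ndarray) -> None:
    Image.fromarray(quantize8(values), mode="L").save(path)


def read_png(path) -> np.ndarray:
    img = Image.open(path).convert("L")
    return dequantize8(np.asarray(img))


def write_csv(path, values: np.ndarray) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter=",", fmt="%.17g")


def read_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def read_pattern(path) -> np.ndarray:
    """Dispatch on file extension (.pgm / .png / .csv)."""
    p = str(path).lower()
    if p.endswith(".pgm"):
        return read_pgm(path)
    if p.endswith(".png"):
        return read_png(path)
    if p.endswith(".csv"):
        return read_csv(path)
    raise ValueError(f"unsupported pattern format: {path}")


def write_pattern(path, values: np.ndarray) -> None:
    p = str(path).lower()
    if p.endswith(".pgm"):
        write_pgm(path, values)
    elif p.endswith(".png"):
        write_png(path, values)
    elif p.endswith(".csv"):
        write_csv(path, values)
    else:
        raise ValueError(f"unsupported pattern format: {path}")
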