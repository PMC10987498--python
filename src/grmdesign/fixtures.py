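"""Programmatic target patterns: geometric shapes, periodic patterns,
gradients, embedded glyphs, and a synthetic gap-gene-like multi-channel
fixture.

All patterns are generated deterministically from a :class:`ShapeSpec`,
so every experiment runs without downloading image assets.  Glyphs are
rendered from small embedded bitmaps (not fonts) for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .fitness import TargetPattern
from .simulator import DomainGrid, build_gradient

__all__ = ["ShapeSpec", "render_target", "gapgene_fixture", "SHAPES",
           "GLYPHS", "gapgene_template"]

SHAPES = (
    "square", "circle", "triangle", "diamond", "stripes",
    "checkerboard", "linear_gradient", "glyph",
)

# 7x7 bitmaps; scaled to the domain with nearest-neighbour sampling.
GLYPHS: Mapping[str, tuple[str, ...]] = {
    "plus": (
        "0001000",
        "0001000",
        "0001000",
        "1111111",
        "0001000",
        "0001000",
        "0001000",
    ),
    "T": (
        "1111111",
        "1111111",
        "0001000",
        "0001000",
        "0001000",
        "0001000",
        "0001000",
    ),
    "L": (
        "1100000",
        "1100000",
        "1100000",
        "1100000",
        "1100000",
        "1111111",
        "1111111",
    ),
}


@dataclass(frozen=True)
class ShapeSpec:
    """Geometry of one target channel.

    ``center`` is the (i, j) cell of the shape center (defaults to the
    domain center); ``size`` is the side length / diameter in cells.
    ``foreground`` and ``background`` are the expression levels in
    [0, 1].  Shape-specific extras: ``count`` (stripes), ``tile``
    (checkerboard), ``axis`` ("horizontal"/"vertical" for stripes and
    gradients), ``glyph`` (bitmap name).
    """

    shape: str
    width: int = 64
    height: int = 64
    center: tuple[int, int] | None = None
    size: int = 32
    foreground: float = 1.0
    background: float = 0.0
    count: int = 3
    tile: int = 8
    axis: str = "horizontal"
    glyph: str = "plus"

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        for lvl in (self.foreground, self.background):
            if not 0.0 <= lvl <= 1.0:
                raise ValueError("levels must lie in [0, 1]")

    @property
    def grid(self) -> DomainGrid:
        return DomainGrid(width=self.width, height=self.height)


def _center(spec: ShapeSpec) -> tuple[int, int]:
    if spec.center is not None:
        return spec.center
    return (spec.width // 2, spec.height // 2)


def _check_bounds(spec: ShapeSpec, i0: float, i1: float, j0: float, j1: float):
    if i0 < 0 or j0 < 0 or i1 > spec.width or j1 > spec.height:
        raise ValueError(
            f"{spec.shape} of size {spec.size} at {_center(spec)} does not "
            f"fit the {spec.width}x{spec.height} domain"
        )


def _mesh(spec: ShapeSpec):
    j, i = np.mgrid[0:spec.height, 0:spec.width]
    return i, j


def render_target(spec: ShapeSpec) -> TargetPattern:
    """Rasterize one shape as a single-channel target pattern."""
    i, j = _mesh(spec)
    ci, cj = _center(spec)
    s = spec.size

    if spec.shape == "square":
        i0, j0 = ci - s // 2, cj - s // 2
        _check_bounds(spec, i0, i0 + s, j0, j0 + s)
        mask = (i >= i0) & (i < i0 + s) & (j >= j0) & (j < j0 + s)
    elif spec.shape == "circle":
        r = s / 2.0
        if s > 0:
            _check_bounds(spec, ci - r, ci + r + 1, cj - r, cj + r + 1)
        mask = (i - ci) ** 2 + (j - cj) ** 2 <= r * r if s > 0 else np.zeros_like(i, bool)
    elif spec.shape == "diamond":
        r = s // 2
        _check_bounds(spec, ci - r, ci + r + 1, cj - r, cj + r + 1)
        mask = np.abs(i - ci) + np.abs(j - cj) <= r
    elif spec.shape == "triangle":
        # isoceles, apex up, inscribed in an s x s box centered at (ci, cj)
        j0, j1 = cj - s // 2, cj + s // 2
        _check_bounds(spec, ci - s // 2, ci + s // 2 + 1, j0, j1 + 1)
        frac = np.clip((j - j0) / max(s, 1), 0, 1)   # 0 at apex row
        half = frac * (s / 2.0)
        mask = (j >= j0) & (j <= j1) & (np.abs(i - ci) <= half)
    elif spec.shape == "stripes":
        period = max(spec.width, 1) / max(spec.count, 1) if spec.axis == "vertical" \
            else max(spec.height, 1) / max(spec.count, 1)
        coord = i if spec.axis == "vertical" else j
        mask = (coord // period).astype(int) % 2 == 0
    elif spec.shape == "checkerboard":
        t = max(spec.tile, 1)
        mask = ((i // t) + (j // t)) % 2 == 0
    elif spec.shape == "linear_gradient":
        coord, extent = (i, spec.width) if spec.axis == "horizontal" else (j, spec.height)
        ramp = coord / max(extent - 1, 1)
        values = spec.background + (spec.foreground - spec.background) * ramp
        return TargetPattern([values])
    elif spec.shape == "glyph":
        if spec.glyph not in GLYPHS:
            raise ValueError(f"unknown glyph {spec.glyph!r}")
        bitmap = np.array(
            [[c == "1" for c in row] for row in GLYPHS[spec.glyph]], dtype=bool
        )
        gh, gw = bitmap.shape
        src_j = (j * gh) // spec.height
        src_i = (i * gw) // spec.width
        mask = bitmap[src_j, src_i]
    else:  # pragma: no cover - guarded by ShapeSpec
        raise ValueError(spec.shape)

    values = np.where(mask, spec.foreground, spec.background).astype(float)
    return TargetPattern([values])


# -- gap-gene-like fixture -----------------------------------------------

GAP_GENES = ("Gt", "Hb", "Kni", "Kr")


def gapgene_template(decay_base: float = 0.93):
    """Anti-parallel input backbone (Bcd from the anterior/left, Cad from
    the posterior/right) with the four gap genes as reporters."""
    from .evolution import NetworkTemplate
    from .grm import GeneSpec

    inputs = (
        GeneSpec("Bcd", "input", orientation="from_left",
                 gradient_decay=decay_base),
        GeneSpec("Cad", "input", orientation="from_right",
                 gradient_decay=decay_base),
    )
    return NetworkTemplate(inputs=inputs, reporter_names=GAP_GENES)


def gapgene_fixture(
    width: int = 58, height: int = 29, decay_base: float = 0.93
) -> tuple[dict[str, np.ndarray], TargetPattern]:
    """Synthetic gap-gene-like fixture (labelled synthetic: it emulates
    only the qualitative anterior-posterior banded layout, not measured
    concentrations).

    Returns the two anti-parallel exponential input fields (Bcd, Cad)
    and a four-channel target whose channels are smooth bumps centered
    at distinct positions along the anterior-posterior (x) axis, so the
    channels are mutually exclusive at their band centers.
    """
    grid = DomainGrid(width=width, height=height)
    inputs = {
        "Bcd": build_gradient(grid, "from_left", decay_base),
        "Cad": build_gradient(grid, "from_right", decay_base),
    }
    x = np.arange(width, dtype=float)
    # band peaks snapped to grid columns so each channel reaches 1 exactly
    centers = [round(mu * (width - 1)) for mu in (0.2, 0.4, 0.6, 0.8)]
    sigma = 0.08 * (width - 1)
    channels = []
    for mu in centers:
        band = np.exp(-((x - mu) / sigma) ** 2)
        band[band < 1e-3] = 0.0
        channels.append(np.tile(band, (height, 1)))
    return inputs, TargetPattern(channels, names=list(GAP_GENES))
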