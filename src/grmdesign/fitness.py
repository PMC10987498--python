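"""Blur-tolerant fitness error between developed and target patterns.

A developed reporter pattern D and a target T (both w x h, target values
in [0, 1]) are each blurred with a k x k box kernel, then compared per
cell with a concentration tolerance band alpha:

    error = mean over cells of ln(1 + (|blur(D) - blur(T)| - alpha)+)
            + (Delta - beta)+

where Delta is the reporter's maximum concentration change at the last
simulation step (penalizing non-equilibrium patterns) and (x)+ is the
positive part.  A mechanism whose blurred pattern sits within alpha of
the blurred target everywhere and whose dynamics have settled below beta
scores exactly zero.  Multi-channel targets sum per-channel errors.

Blur normalization: the default ("area") divides by the number of
in-domain kernel cells, so constants are preserved and a larger kernel
is genuinely more forgiving.  The "literal" variant divides the plain
zero-padded convolution by k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["ErrorParams", "TargetPattern", "box_blur", "pattern_error",
           "error_components", "score_simulation"]


@dataclass(frozen=True)
class ErrorParams:
    """Tolerance parameters of the fitness error.

    kernel_size : odd box-blur width in cells (k)
    conc_tol    : concentration tolerance band alpha in [0, 1)
    eq_tol      : equilibrium penalty threshold beta (concentration/time)
    blur_normalization : "area" (default) or "literal"
    """

    kernel_size: int = 5
    conc_tol: float = 0.1
    eq_tol: float = 1e-3
    blur_normalization: str = "area"

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be an odd positive integer")
        if not 0.0 <= self.conc_tol < 1.0:
            raise ValueError("conc_tol must be in [0, 1)")
        if self.eq_tol <= 0:
            raise ValueError("eq_tol must be positive")
        if self.blur_normalization not in ("area", "literal"):
            raise ValueError("blur_normalization must be 'area' or 'literal'")


@dataclass
class TargetPattern:
    """One or more grayscale channels in [0, 1], all of one shape."""

    channels: list[np.ndarray]
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.channels = [np.asarray(c, dtype=float) for c in self.channels]
        if not self.channels:
            raise ValueError("target needs at least one channel")
        shape = self.channels[0].shape
        for c in self.channels:
            if c.shape != shape:
                raise ValueError("target channels differ in shape")
            if np.any(c < 0) or np.any(c > 1):
                raise ValueError("target values must lie in [0, 1]")
        if not self.names:
            self.names = [f"channel{i}" for i in range(len(self.channels))]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape


def box_blur(channel: np.ndarray, kernel_size: int,
             normalization: str = "area") -> np.ndarray:
    """Box-blur one channel with a kernel_size x kernel_size kernel."""
    channel = np.asarray(channel, dtype=float)
    k = kernel_size
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel size must be an odd positive integer")
    if k > min(channel.shape):
        raise ValueError("kernel larger than the domain")
    if k == 1:
        return channel.copy()
    # uniform_filter(...,'constant') is the zero-padded box sum / k^2
    summed = ndimage.uniform_filter(channel, size=k, mode="constant", cval=0.0) * (k * k)
    if normalization == "area":
        counts = ndimage.uniform_filter(
            np.ones_like(channel), size=k, mode="constant", cval=0.0
        ) * (k * k)
        return summed / counts
    if normalization == "literal":
        return summed / k
    raise ValueError(f"unknown normalization {normalization!r}")


# Target patterns are fixed across the thousands of evaluations of a
# design run; memoize their blur (keyed by content digest).
_BLUR_CACHE: dict[tuple, np.ndarray] = {}
_BLUR_CACHE_MAX = 64


def _blur_target(tgt: np.ndarray, params: ErrorParams) -> np.ndarray:
    key = (hash(tgt.tobytes()), tgt.shape, params.kernel_size,
           params.blur_normalization)
    hit = _BLUR_CACHE.get(key)
    if hit is None:
        if len(_BLUR_CACHE) >= _BLUR_CACHE_MAX:
            _BLUR_CACHE.clear()
        hit = box_blur(tgt, params.kernel_size, params.blur_normalization)
        _BLUR_CACHE[key] = hit
    return hit


def _channel_error(dev, tgt, delta, params: ErrorParams) -> tuple[float, float]:
    dev = np.asarray(dev, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    if dev.shape != tgt.shape:
        raise ValueError(
            f"developed {dev.shape} and target {tgt.shape} shapes differ"
        )
    bd = box_blur(dev, params.kernel_size, params.blur_normalization)
    bt = _blur_target(tgt, params)
    excess = np.abs(bd - bt)
    excess -= params.conc_tol
    np.maximum(excess, 0.0, out=excess)
    conc = float(np.mean(np.log1p(excess)))
    eq = max(float(delta) - params.eq_tol, 0.0)
    return conc, eq


def _as_channel_lists(developed, target, delta):
    if isinstance(target, TargetPattern):
        tgts = target.channels
    elif isinstance(target, np.ndarray) or not isinstance(target, Sequence):
        tgts = [np.asarray(target)]
    else:
        tgts = [np.asarray(t) for t in target]
    if isinstance(developed, np.ndarray) or not isinstance(developed, Sequence):
        devs = [np.asarray(developed)]
    else:
        devs = [np.asarray(d) for d in developed]
    deltas = [float(d) for d in np.atleast_1d(np.asarray(delta, dtype=float))]
    if len(devs) != len(tgts):
        raise ValueError("developed/target channel counts differ")
    if len(deltas) == 1 and len(devs) > 1:
        deltas = deltas * len(devs)
    if len(deltas) != len(devs):
        raise ValueError("one equilibrium delta needed per channel")
    return devs, tgts, deltas


def pattern_error(developed, target, delta, params: ErrorParams | None = None) -> float:
    """Fitness error of developed pattern(s) against target pattern(s).

    ``developed`` and ``target`` are single channels or sequences of
    channels (or a :class:`TargetPattern`); ``delta`` gives the last-step
    equilibrium measure per channel.  Multi-channel errors are summed.
    """
    conc, eq = error_components(developed, target, delta, params)
    return conc + eq


def error_components(developed, target, delta,
                     params: ErrorParams | None = None) -> tuple[float, float]:
    """(concentration term, equilibrium penalty), summed over channels."""
    params = params or ErrorParams()
    devs, tgts, deltas = _as_channel_lists(developed, target, delta)
    conc_total = 0.0
    eq_total = 0.0
    for dev, tgt, dlt in zip(devs, tgts, deltas):
        if dlt < 0:
            raise ValueError("equilibrium delta must be >= 0")
        conc, eq = _channel_error(dev, tgt, dlt, params)
        conc_total += conc
        eq_total += eq
    return conc_total, eq_total


def score_simulation(result, grm, target: TargetPattern,
                     params: ErrorParams | None = None) -> float:
    """Score a :class:`~grmdesign.simulator.SimulationResult` against a
    target using the GRM's reporter -> channel bindings."""
    params = params or ErrorParams()
    if not grm.reporter_bindings:
        raise ValueError("GRM has no reporter bindings")
    # when the simulation tracked every non-input gene (strict
    # equilibrium mode), the slowest gene bounds each channel's delta
    reporters = set(grm.reporter_bindings)
    extra = max(
        (d for name, d in result.delta.items() if name not in reporters),
        default=0.0,
    )
    devs, tgts, deltas = [], [], []
    for reporter, channel in sorted(grm.reporter_bindings.items(),
                                    key=lambda kv: kv[1]):
        devs.append(result.fields[reporter])
        tgts.append(target.channels[channel])
        deltas.append(max(result.delta.get(reporter, 0.0), extra))
    return pattern_error(devs, tgts, deltas, params)
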