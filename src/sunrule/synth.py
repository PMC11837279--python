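"""Planted-rule synthetic benchmark tables.

Feature channels are uniform on heterogeneous raw scales (gas-sensor-like
hundreds vs. temperature-like tens), optionally correlated through a
shared per-row latent factor but with *exactly uniform marginals* (the
mixed value is pushed through its own CDF), so interval coverage has a
closed form when the correlation weight is zero.  A row is positive when
a planted conjunction of normalized intervals covers it, with optional
background leakage and i.i.d. label flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import FeatureTable
from .rule_engine import IntervalRule

__all__ = ["GeneratorSpec", "GeneratorConfigError", "generate", "make_null", "planted_coverage"]


class GeneratorConfigError(ValueError):
    """The requested generator configuration is unsatisfiable."""


def _default_scales(d: int) -> list[tuple[float, float]]:
    # two raw-unit families whose spreads differ by >= 10x
    return [(20.0, 25.0) if j % 3 == 2 else (50.0, 900.0) for j in range(d)]


@dataclass
class GeneratorSpec:
    """Configuration for one synthetic table.

    ``planted`` maps channel index -> (lower, upper) in normalized [0, 1]
    coordinates.  ``base_rate`` is the probability an uncovered row is
    positive anyway; ``label_noise`` flips each final label independently.
    ``class_ratio``, when set, is a target positive fraction reached by
    rescaling the planted interval widths about their centres.
    """

    n: int = 400
    d: int = 6
    planted: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.3, 0.6), 4: (0.2, 0.7)}
    )
    channel_scales: list[tuple[float, float]] | None = None
    base_rate: float = 0.0
    label_noise: float = 0.0
    class_ratio: float | None = None
    correlation: float = 0.3
    positive_label: str = "P"
    negative_label: str = "N"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise GeneratorConfigError("n must be >= 10")
        if self.d < 1:
            raise GeneratorConfigError("d must be >= 1")
        if not 0.0 <= self.label_noise < 0.5:
            raise GeneratorConfigError("label_noise must lie in [0, 0.5)")
        if not 0.0 <= self.base_rate < 1.0:
            raise GeneratorConfigError("base_rate must lie in [0, 1)")
        if not 0.0 <= self.correlation < 1.0:
            raise GeneratorConfigError("correlation must lie in [0, 1)")
        if not self.planted:
            raise GeneratorConfigError("at least one planted interval required")
        for j, (lo, hi) in self.planted.items():
            if not 0 <= j < self.d:
                raise GeneratorConfigError(f"planted channel index {j} out of range")
            if not (0.0 <= lo < hi <= 1.0) or hi - lo > 1.0:
                raise GeneratorConfigError(f"planted interval {lo, hi} must satisfy 0 <= lo < hi <= 1")
        if self.channel_scales is not None and len(self.channel_scales) != self.d:
            raise GeneratorConfigError("need one (offset, spread) pair per channel")

    @property
    def scales(self) -> list[tuple[float, float]]:
        return self.channel_scales if self.channel_scales is not None else _default_scales(self.d)

    @property
    def channels(self) -> list[str]:
        return [f"CH{j + 1}" for j in range(self.d)]


def _mixture_cdf(v: np.ndarray, w: float) -> np.ndarray:
    """CDF of ``(1-w) U + w Z`` (two independent uniforms), evaluated at v.

    Pushing the mixed value through this makes marginals exactly uniform
    while preserving the shared-factor correlation across channels.
    """
    a, b = max(1.0 - w, w), min(1.0 - w, w)
    if b == 0.0:
        return v
    out = np.empty_like(v)
    low = v < b
    mid = (v >= b) & (v < a)
    high = v >= a
    out[low] = v[low] ** 2 / (2 * a * b)
    out[mid] = (2 * v[mid] - b) / (2 * a)
    out[high] = 1.0 - (1.0 - v[high]) ** 2 / (2 * a * b)
    return np.clip(out, 0.0, 1.0)


def _draw_uniform_matrix(rng: np.random.Generator, n: int, d: int, w: float) -> np.ndarray:
    e = rng.uniform(size=(n, d))
    if w == 0.0:
        return e
    z = rng.uniform(size=(n, 1))
    return _mixture_cdf((1.0 - w) * e + w * z, w)


def _covered(u: np.ndarray, planted: dict[int, tuple[float, float]]) -> np.ndarray:
    mask = np.ones(u.shape[0], dtype=bool)
    for j, (lo, hi) in planted.items():
        mask &= (u[:, j] >= lo) & (u[:, j] <= hi)
    return mask


def _scaled_planted(
    planted: dict[int, tuple[float, float]], s: float
) -> dict[int, tuple[float, float]]:
    out = {}
    for j, (lo, hi) in planted.items():
        c, h = (lo + hi) / 2.0, (hi - lo) / 2.0 * s
        out[j] = (max(c - h, 0.0), min(c + h, 1.0))
    return out


def _positive_probability(
    spec: GeneratorSpec, planted: dict[int, tuple[float, float]], m: int = 100_000
) -> float:
    """Monte-Carlo P(label == positive) under the generative law."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))
    u = _draw_uniform_matrix(rng, m, spec.d, spec.correlation)
    q = float(np.mean(_covered(u, planted)))
    q = q + spec.base_rate * (1.0 - q)
    return q * (1.0 - spec.label_noise) + (1.0 - q) * spec.label_noise


def _tune_planted(spec: GeneratorSpec) -> dict[int, tuple[float, float]]:
    """Bisection on a width-scaling factor to hit ``class_ratio``."""
    target = spec.class_ratio
    assert target is not None
    lo_s, hi_s = 1e-6, 1.0
    # grow the upper scale until the target is bracketed or every interval
    # saturates at [0, 1] (coverage cannot grow further)
    for _ in range(60):
        scaled = _scaled_planted(spec.planted, hi_s)
        saturated = all((lo, hi) == (0.0, 1.0) for lo, hi in scaled.values())
        if saturated or _positive_probability(spec, scaled) >= target:
            break
        hi_s *= 1.5
    p_lo = _positive_probability(spec, _scaled_planted(spec.planted, lo_s))
    p_hi = _positive_probability(spec, _scaled_planted(spec.planted, hi_s))
    if not (p_lo - 0.02 <= target <= p_hi + 0.02):
        raise GeneratorConfigError(
            f"class_ratio {target} unreachable (achievable range ~[{p_lo:.3f}, {p_hi:.3f}])"
        )
    for _ in range(40):
        mid = 0.5 * (lo_s + hi_s)
        if _positive_probability(spec, _scaled_planted(spec.planted, mid)) < target:
            lo_s = mid
        else:
            hi_s = mid
    return _scaled_planted(spec.planted, 0.5 * (lo_s + hi_s))


def planted_coverage(spec: GeneratorSpec) -> float:
    """Exact coverage probability for uncorrelated channels (product of
    widths); Monte-Carlo estimate otherwise."""
    if spec.correlation == 0.0:
        out = 1.0
        for lo, hi in spec.planted.values():
            out *= hi - lo
        return out
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0FFEE]))
    u = _draw_uniform_matrix(rng, 200_000, spec.d, spec.correlation)
    return float(np.mean(_covered(u, spec.planted)))


def generate(spec: GeneratorSpec) -> tuple[FeatureTable, IntervalRule]:
    """Draw one table and return it with the ground-truth rule in raw units."""
    planted = _tune_planted(spec) if spec.class_ratio is not None else dict(spec.planted)
    rng = np.random.default_rng(spec.seed)
    u = _draw_uniform_matrix(rng, spec.n, spec.d, spec.correlation)
    covered = _covered(u, planted)
    positive = covered.copy()
    if spec.base_rate > 0.0:
        leak = rng.uniform(size=spec.n) < spec.base_rate
        positive |= ~covered & leak
    if spec.label_noise > 0.0:
        flips = rng.uniform(size=spec.n) < spec.label_noise
        positive ^= flips
    labels = np.where(positive, spec.positive_label, spec.negative_label).astype(object)

    scales = spec.scales
    values = np.empty_like(u)
    for j, (offset, spread) in enumerate(scales):
        values[:, j] = offset + spread * u[:, j]
    table = FeatureTable(values, spec.channels, labels)

    truth = IntervalRule.make(
        spec.positive_label,
        [
            (spec.channels[j], scales[j][0] + scales[j][1] * lo, scales[j][0] + scales[j][1] * hi)
            for j, (lo, hi) in sorted(planted.items())
        ],
    )
    return table, truth


def make_null(spec: GeneratorSpec, positive_fraction: float | None = None) -> FeatureTable:
    """Same feature law, labels drawn independently of the features."""
    frac = positive_fraction if positive_fraction is not None else (spec.class_ratio or 0.5)
    if not 0.0 < frac < 1.0:
        raise GeneratorConfigError("positive fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    u = _draw_uniform_matrix(rng, spec.n, spec.d, spec.correlation)
    labels = np.where(
        rng.uniform(size=spec.n) < frac, spec.positive_label, spec.negative_label
    ).astype(object)
    values = np.empty_like(u)
    for j, (offset, spread) in enumerate(spec.scales):
        values[:, j] = offset + spread * u[:, j]
    return FeatureTable(values, spec.channels, labels)
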