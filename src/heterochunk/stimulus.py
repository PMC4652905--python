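"""Synthetic perceptual input: bar patterns, presentation schedules, pixel noise.

The perceptual layer is driven by a fixed set of non-overlapping binary pixel
patterns (the canonical demonstration uses 24 horizontal bars of 6 pixels each
on a 144-pixel canvas).  A schedule maps simulated time to the input vector
``s(t)``: during the presentation phase each pattern is held for a fixed item
duration with a noise realization drawn once per presentation; outside the
schedule the input is zero (recall is input-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternSet",
    "StimulusSequence",
    "generate_bar_patterns",
    "apply_pixel_noise",
    "normalize_input",
    "make_schedule",
    "RawSchedule",
]


class CapacityError(ValueError):
    """Raised when disjoint high-pixel sets cannot be allocated."""


@dataclass
class PatternSet:
    """A set of non-overlapping pixel patterns.

    Attributes
    ----------
    patterns : (n_patterns, M) array of nonnegative pixel intensities.
    high_mask : list of index arrays, the high-intensity pixels per pattern.
    """

    patterns: np.ndarray
    high_mask: list
    M: int
    n_patterns: int

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.shape != (self.n_patterns, self.M):
            raise ValueError(
                f"patterns shape {self.patterns.shape} != ({self.n_patterns}, {self.M})"
            )
        if np.any(self.patterns < 0):
            raise ValueError("pattern intensities must be nonnegative")
        seen = set()
        for idx in self.high_mask:
            s = set(int(i) for i in idx)
            if seen & s:
                raise ValueError("high-intensity pixel sets overlap across patterns")
            seen |= s

    def to_csv(self, path):
        """One row per pattern, comma-separated intensities."""
        np.savetxt(path, self.patterns, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path):
        patterns = np.atleast_2d(np.loadtxt(path, delimiter=","))
        high = [np.flatnonzero(p > p.min()) for p in patterns]
        return cls(patterns, high, patterns.shape[1], patterns.shape[0])

    def to_pgm(self, path, rows=None):
        """Write the pattern set as a plain-text PGM image (patterns stacked)."""
        img = self.patterns
        lo, hi = img.min(), img.max()
        scale = 255.0 / (hi - lo) if hi > lo else 0.0
        pix = np.round((img - lo) * scale).astype(int)
        with open(path, "w") as fh:
            fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n255\n")
            for row in pix:
                fh.write(" ".join(str(v) for v in row) + "\n")


def generate_bar_patterns(
    M: int,
    n_patterns: int,
    pixels_high: int,
    low_value: float = 0.0,
    high_value: float = 1.0,
    seed=None,
) -> PatternSet:
    """Generate ``n_patterns`` patterns with disjoint high-pixel sets.

    When ``M`` is divisible by ``n_patterns`` and ``pixels_high = M /
    n_patterns`` the patterns tile the canvas as contiguous horizontal bars;
    otherwise disjoint high sets are drawn at random.

    Raises
    ------
    CapacityError
        If ``n_patterns * pixels_high > M`` (disjointness impossible).
    """
    if n_patterns * pixels_high > M:
        raise CapacityError(
            f"cannot place {n_patterns} disjoint sets of {pixels_high} pixels in {M}"
        )
    if not high_value > low_value >= 0:
        raise ValueError("requires high_value > low_value >= 0")
    tiles = M % n_patterns == 0 and pixels_high == M // n_patterns
    if tiles:
        order = np.arange(M)
    else:
        order = np.random.default_rng(seed).permutation(M)
    patterns = np.full((n_patterns, M), low_value, dtype=float)
    high_mask = []
    for p in range(n_patterns):
        idx = np.sort(order[p * pixels_high : (p + 1) * pixels_high])
        patterns[p, idx] = high_value
        high_mask.append(idx)
    return PatternSet(patterns, high_mask, M, n_patterns)


def apply_pixel_noise(pattern: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Add independent rectified-Gaussian noise ``max(0, N(0, sigma^2))`` per pixel.

    The draw is made once per call; the caller holds it fixed for the duration
    of one sequence-element presentation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    pattern = np.asarray(pattern, dtype=float)
    if sigma == 0:
        return pattern.copy()
    noise = np.maximum(0.0, rng.normal(0.0, sigma, size=pattern.shape))
    return pattern + noise


def normalize_input(pattern: np.ndarray, C: float) -> np.ndarray:
    """Scale a pattern so its entries sum to ``C`` (feedforward-inhibition
    normalization), preserving proportions."""
    pattern = np.asarray(pattern, dtype=float)
    total = pattern.sum()
    if C <= 0:
        raise ValueError("C must be positive")
    if total <= 0:
        raise ValueError("cannot normalize an all-zero pattern")
    return pattern * (C / total)


@dataclass
class StimulusSequence:
    """A presentation schedule: repeated loops over a fixed pattern order.

    ``s(t)`` is the normalized, noise-corrupted input vector at simulated time
    ``t``; beyond the last presentation it is the zero vector (recall has no
    input).  Each presentation of an element draws one fixed noise
    realization.
    """

    pattern_set: PatternSet
    order: np.ndarray
    n_presentations: int
    item_duration: float
    noise_sigma: float = 0.0
    C: float = 2.0
    seed: int = 0
    noise_before_normalize: bool = False
    _items: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.order = np.asarray(self.order, dtype=int)
        n = self.pattern_set.n_patterns
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must contain each pattern index exactly once")
        if self.item_duration <= 0 or self.n_presentations < 1:
            raise ValueError("item_duration > 0 and n_presentations >= 1 required")
        self._build()

    def _build(self):
        """Materialize every presented item (loop-major, element-minor)."""
        rng = np.random.default_rng(self.seed)
        pats = self.pattern_set.patterns
        items = np.empty(
            (self.n_presentations * len(self.order), self.pattern_set.M), dtype=float
        )
        k = 0
        for _ in range(self.n_presentations):
            for p in self.order:
                raw = pats[p]
                if self.noise_before_normalize:
                    raw = apply_pixel_noise(raw, self.noise_sigma, rng)
                    item = normalize_input(raw, self.C)
                else:
                    item = normalize_input(raw, self.C)
                    item = apply_pixel_noise(item, self.noise_sigma, rng)
                items[k] = item
                k += 1
        self._items = items

    @property
    def n_items(self) -> int:
        return self._items.shape[0]

    @property
    def total_duration(self) -> float:
        return self.n_items * self.item_duration

    @property
    def items(self) -> np.ndarray:
        """(n_items, M) array of presented input vectors, in order."""
        return self._items

    def item_index(self, t: float) -> int:
        """Index of the presented item covering time ``t`` (-1 outside)."""
        if t < 0 or t >= self.total_duration:
            return -1
        return int(t // self.item_duration)

    def s(self, t: float) -> np.ndarray:
        """Input vector at simulated time ``t``."""
        i = self.item_index(t)
        if i < 0:
            return np.zeros(self.pattern_set.M)
        return self._items[i].copy()

    def presented_order(self) -> np.ndarray:
        """Pattern index of every presented item, in order."""
        return np.tile(self.order, self.n_presentations)


@dataclass
class RawSchedule:
    """A bare item stream: each row of ``items`` held for ``item_duration``.

    Minimal schedule interface used e.g. for the recall cue (a single
    pattern held for one item duration).
    """

    items: np.ndarray
    item_duration: float

    def __post_init__(self):
        self.items = np.atleast_2d(np.asarray(self.items, dtype=float))

    @property
    def total_duration(self) -> float:
        return self.items.shape[0] * self.item_duration


def make_schedule(
    pattern_set: PatternSet,
    order,
    n_presentations: int,
    item_duration: float,
    noise_sigma: float = 0.0,
    C: float = 2.0,
    seed: int = 0,
    noise_before_normalize: bool = False,
) -> StimulusSequence:
    """Build a deterministic :class:`StimulusSequence` (see its docstring)."""
    return StimulusSequence(
        pattern_set,
        np.asarray(order, dtype=int),
        n_presentations,
        item_duration,
        noise_sigma,
        C,
        seed,
        noise_before_normalize,
    )
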