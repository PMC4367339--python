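"""Synthetic sensory-panel and mixture-design simulator.

Emulates the experimental setting behind the mixture model so every stage of
the pipeline can be exercised without human assessors: a panel of raters
scoring odor intensity on the OIRS half-step grid with additive Gaussian
noise, and a 24-sample binary-mixture design spanning mixing proportions
0.1–0.9 and three measured-OI bands below the 7.0 ceiling.

What it emulates — and what it does not: ratings are independent across
assessors and samples, noise is Gaussian before grid rounding, and there is
no assessor identity, fatigue or hedonic effect. Passing recovery tests on
this generator demonstrates the estimators, not the behaviour of real panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .core import (
    HALF_STEP,
    SCALE_MAX,
    SCALE_MIN,
    InvalidInputError,
    Odorant,
)
from .mixture_model import BinaryMixtureSample, QuadraticMixtureModel
from .core import ComponentExposure

__all__ = [
    "InfeasibleDesignError",
    "PanelConfig",
    "DesignSpec",
    "PanelRating",
    "PrecisionResult",
    "simulate_panel_rating",
    "generate_mixture_dataset",
    "precision_experiment",
]

#: Measured-OI band edges shared with :func:`odorblend.core.oi_level`.
_BANDS = {"low": (1.0, 2.5), "middle": (2.5, 4.5), "high": (4.5, 7.0)}

_SCALE_MIDPOINT = 0.5 * (SCALE_MIN + SCALE_MAX)


class InfeasibleDesignError(ValueError):
    """A requested OI band cannot be realised under the design ceiling."""


@dataclass(frozen=True)
class PanelConfig:
    """Sensory-panel parameters.

    rating_sd is the per-assessor Gaussian noise before half-step rounding,
    in OIRS units; 0.2 keeps ~95% of 8-assessor panel means within the ±0.4
    fluctuation envelope observed in repeated evaluations. ``rating_sd_fn``
    optionally makes the sd depend on the true OI (rating precision improves
    at higher intensities).
    """

    n_assessors: int = 8
    rating_sd: float = 0.2
    seed: Optional[int] = None
    scale_bounds: Tuple[float, float] = (SCALE_MIN, SCALE_MAX)
    rating_sd_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.n_assessors < 1:
            raise InvalidInputError(f"n_assessors must be ≥ 1, got {self.n_assessors}")
        if self.rating_sd < 0:
            raise InvalidInputError(f"rating_sd must be ≥ 0, got {self.rating_sd}")

    def sd_for(self, true_oi: float) -> float:
        return self.rating_sd_fn(true_oi) if self.rating_sd_fn is not None else self.rating_sd

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class DesignSpec:
    """The binary-mixture sampling design.

    Defaults reproduce the reference design: 24 samples per mixture pair,
    mixing proportions within [0.1, 0.9], true OI below 7.0, allocated 8/8/8
    to the low/middle/high measured-OI bands.
    """

    n_samples: int = 24
    ratio_range: Tuple[float, float] = (0.1, 0.9)
    oi_ceiling: float = 7.0
    level_allocation: Dict[str, int] = field(
        default_factory=lambda: {"low": 8, "middle": 8, "high": 8}
    )

    def __post_init__(self) -> None:
        lo, hi = self.ratio_range
        if not (0.0 < lo < hi < 1.0):
            raise InvalidInputError(f"ratio_range must sit inside (0, 1), got {self.ratio_range}")
        if not (self.oi_ceiling <= SCALE_MAX):
            raise InvalidInputError(f"oi_ceiling must be ≤ {SCALE_MAX}, got {self.oi_ceiling}")
        unknown = set(self.level_allocation) - set(_BANDS)
        if unknown:
            raise InvalidInputError(f"unknown OI bands in allocation: {sorted(unknown)}")
        if sum(self.level_allocation.values()) != self.n_samples:
            raise InvalidInputError(
                f"level allocation {self.level_allocation} does not sum to "
                f"n_samples = {self.n_samples}"
            )


class PanelRating(NamedTuple):
    """Per-assessor half-step ratings and their mean (the measured OI)."""

    ratings: np.ndarray
    mean: float


def _snap_to_grid(values: np.ndarray, bounds: Tuple[float, float]) -> np.ndarray:
    """Round to the nearest half step; ties round away from the nearer scale
    bound (e.g. 3.25 → 3.5 but 5.25 → 5.0), then clamp to the scale."""
    k = np.asarray(values, dtype=float) / HALF_STEP
    lower = np.floor(k)
    frac = k - lower
    tie = np.abs(frac - 0.5) <= 1e-9
    nearest = np.where(frac > 0.5, lower + 1, lower)
    tie_up = values < _SCALE_MIDPOINT  # away from the nearer (lower) bound
    snapped = np.where(tie, np.where(tie_up, lower + 1, lower), nearest) * HALF_STEP
    return np.clip(snapped, bounds[0], bounds[1])


def simulate_panel_rating(
    true_oi: float,
    config: PanelConfig = PanelConfig(),
    rng: Optional[np.random.Generator] = None,
) -> PanelRating:
    """One panel evaluation of one odor sample.

    Each assessor's rating is the true OI plus Gaussian noise, rounded to the
    half-step grid and clamped to the scale; the panel mean is the measured
    OI. Deterministic for a fixed ``config.seed`` (or an explicit ``rng``).
    """
    if not (SCALE_MIN <= true_oi <= SCALE_MAX):
        raise InvalidInputError(f"true OI {true_oi} outside [{SCALE_MIN}, {SCALE_MAX}]")
    rng = config.rng() if rng is None else rng
    sd = config.sd_for(true_oi)
    raw = true_oi + rng.normal(0.0, sd, size=config.n_assessors)
    ratings = _snap_to_grid(raw, config.scale_bounds)
    return PanelRating(ratings=ratings, mean=float(ratings.mean()))


def generate_mixture_dataset(
    pair: Tuple[Odorant, Odorant],
    truth: QuadraticMixtureModel,
    design: DesignSpec = DesignSpec(),
    config: PanelConfig = PanelConfig(),
    rng: Optional[np.random.Generator] = None,
) -> List[BinaryMixtureSample]:
    """Simulate one binary-mixture experiment under a known mixture curve.

    For each sample a target true OI is drawn inside its allocated band
    (below the ceiling) and a mixing proportion inside the design range; the
    total lnOAV that realises the target under the truth curve is split into
    the two components, converted back to concentrations through the
    odorants' thresholds, and a simulated panel supplies the measured OI.
    All randomness flows from a single generator (``config.seed``).
    """
    odorant_a, odorant_b = pair
    rng = config.rng() if rng is None else rng
    lo_x, hi_x = design.ratio_range

    samples: List[BinaryMixtureSample] = []
    idx = 0
    for band in ("low", "middle", "high"):
        count = design.level_allocation.get(band, 0)
        if count == 0:
            continue
        band_lo, band_hi = _BANDS[band]
        band_hi = min(band_hi, design.oi_ceiling)
        if not (band_lo < band_hi):
            raise InfeasibleDesignError(
                f"band {band!r} [{_BANDS[band][0]}, {_BANDS[band][1]}) is empty "
                f"under the OI ceiling {design.oi_ceiling}"
            )
        true_ois = rng.uniform(band_lo, band_hi, size=count)
        xs = rng.uniform(lo_x, hi_x, size=count)
        for true_oi, x in zip(true_ois, xs):
            f_x = float(truth.f(x))
            if not (f_x > 0):
                raise InfeasibleDesignError(
                    f"truth curve non-positive at x = {x:.3g}; cannot realise band {band!r}"
                )
            total = true_oi / f_x
            rating = simulate_panel_rating(float(true_oi), config, rng=rng)
            samples.append(
                BinaryMixtureSample(
                    component_a=ComponentExposure.from_ln_oav(odorant_a, x * total),
                    component_b=ComponentExposure.from_ln_oav(odorant_b, (1.0 - x) * total),
                    measured_oi=rating.mean,
                    mixture_id=f"sim-{idx:02d}",
                )
            )
            idx += 1
    return samples


@dataclass(frozen=True)
class PrecisionResult:
    """Repeated-evaluation deviations: panel means minus their per-sample average."""

    true_oi: Tuple[float, ...]
    panel_means: np.ndarray  # (n_samples, n_repeats)
    deviations: np.ndarray   # (n_samples, n_repeats), row-centered

    def n_outside(self, envelope: float = 0.4) -> int:
        """Number of repeat evaluations deviating more than ±envelope."""
        return int(np.sum(np.abs(self.deviations) > envelope))


def precision_experiment(
    true_oi_set: Sequence[float],
    n_repeats: int = 10,
    config: PanelConfig = PanelConfig(),
    rng: Optional[np.random.Generator] = None,
) -> PrecisionResult:
    """Repeat-evaluation study of panel precision.

    Each sample is rated ``n_repeats`` times by a fresh simulated panel; the
    deviation series is each panel mean minus the sample's across-repeat
    average (so each row sums to zero by construction). The count outside
    the ±0.4 envelope summarizes rating fluctuation.
    """
    if n_repeats < 2:
        raise InvalidInputError(f"n_repeats must be ≥ 2, got {n_repeats}")
    rng = config.rng() if rng is None else rng
    means = np.empty((len(true_oi_set), n_repeats), dtype=float)
    for i, oi in enumerate(true_oi_set):
        for j in range(n_repeats):
            means[i, j] = simulate_panel_rating(float(oi), config, rng=rng).mean
    deviations = means - means.mean(axis=1, keepdims=True)
    return PrecisionResult(
        true_oi=tuple(float(v) for v in true_oi_set),
        panel_means=means,
        deviations=deviations,
    )
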