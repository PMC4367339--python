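"""Tangent-intercept model of binary odor interaction.

A binary mixture sample is reduced to a point (x, OI_m): x is the mixing
proportion of component *a* in lnOAV terms, OI_m the measured intensity per
total lnOAV unit,

    OI_m = OI / (lnOAV_a + lnOAV_b),        x = lnOAV_a / (lnOAV_a + lnOAV_b).

A quadratic y = f(x) is fitted to these points. By analogy with the
tangent-intercept method for partial molar volumes, the tangent to f at a
sample's x intersects the vertical axes x = 1 and x = 0 at the *partial*
odor intensities of the two components,

    OI_a,m = (1 − x)·f′(x) + f(x),          OI_b,m = −x·f′(x) + f(x),

the marginal OI each lnOAV unit of that component contributes. Mixture OI is
then predicted by the summation rule

    OI = OI_a,m · lnOAV_a + OI_b,m · lnOAV_b,

which is algebraically identical to (lnOAV_a + lnOAV_b)·f(x); both routes are
computed and cross-checked. A pooled "extended" curve fitted across several
aldehyde pairs ships as packaged constants for prediction without a panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import ComponentExposure, InvalidInputError, oi_level
from .individual_response import DegenerateDesignError

__all__ = [
    "MissingMeasurementError",
    "SubThresholdComponentError",
    "InvalidPointError",
    "OutOfDomainError",
    "ExtrapolationWarning",
    "BinaryMixtureSample",
    "NormalizedPoint",
    "QuadraticMixtureModel",
    "PartialIntensities",
    "PredictionRecord",
    "EvaluationSummary",
    "EXTENDED_COEFFICIENTS",
    "normalize",
    "fit_mixture_curve",
    "extended_model",
    "partial_intensities",
    "predict_oi",
    "evaluate_predictions",
    "stratify_by_level",
    "round_half_away",
    "report_round_oi",
]

logger = logging.getLogger(__name__)

#: Design range of the mixing proportion; fits and worked examples stay inside.
DESIGN_X_RANGE = (0.1, 0.9)

#: Pooled extended-curve coefficients (a2, a1, a0) for binary aldehyde
#: mixtures, on the (x, OI_m) plane.
EXTENDED_COEFFICIENTS = (2.20, -2.20, 1.32)


class MissingMeasurementError(ValueError):
    """The operation needs a panel-measured OI that the sample lacks."""


class SubThresholdComponentError(ValueError):
    """A component sits at or below its odor threshold (lnOAV ≤ 0)."""


class InvalidPointError(ValueError):
    """A normalized point lies outside the unit mixing-proportion interval."""


class OutOfDomainError(ValueError):
    """Mixing proportion outside the open interval (0, 1)."""


class ExtrapolationWarning(UserWarning):
    """Mixing proportion outside the calibrated design range [0.1, 0.9]."""


# ---------------------------------------------------------------------------
# rounding conventions for reported values
# ---------------------------------------------------------------------------

def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (the convention of the source
    tables, as opposed to banker's rounding)."""
    quantum = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP)
    return float(d)


def report_round_oi(value: float) -> float:
    """Round a predicted OI to report precision (1 decimal) in two stages.

    Values are taken to 2 decimals first and then to 1, ties away from zero.
    This is how the published per-sample predictions were produced — e.g. a
    prediction of 1.5495 is reported as 1.6, not 1.5 — and it is required to
    reproduce the published mean predictive coefficients.
    """
    return round_half_away(round_half_away(value, 2), 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryMixtureSample:
    """One odor-bag sample of a two-odorant mixture.

    Both components must be supra-threshold (lnOAV > 0); the model's
    normalization weights are otherwise undefined.
    """

    component_a: ComponentExposure
    component_b: ComponentExposure
    measured_oi: Optional[float] = None
    mixture_id: Optional[str] = None

    def __post_init__(self) -> None:
        for label, comp in (("a", self.component_a), ("b", self.component_b)):
            if comp.ln_oav <= 0:
                raise SubThresholdComponentError(
                    f"component {label} ({comp.odorant.name!r}) is at or below "
                    f"threshold: lnOAV = {comp.ln_oav:.4g}"
                )

    @property
    def ln_oav_a(self) -> float:
        return self.component_a.ln_oav

    @property
    def ln_oav_b(self) -> float:
        return self.component_b.ln_oav

    @property
    def total_ln_oav(self) -> float:
        return self.ln_oav_a + self.ln_oav_b

    @property
    def mixing_proportion(self) -> float:
        return self.ln_oav_a / self.total_ln_oav

    def swapped(self) -> "BinaryMixtureSample":
        """The same sample with component roles exchanged (x → 1 − x)."""
        return replace(self, component_a=self.component_b, component_b=self.component_a)


@dataclass(frozen=True)
class NormalizedPoint:
    """A sample in the mixture-curve coordinate system (x, OI_m)."""

    x: float
    oi_m: float


@dataclass(frozen=True)
class PartialIntensities:
    """Tangent intercepts at x = 1 and x = 0: per-lnOAV-unit contributions.

    Either value may be negative (hypo-additive interaction); the convex
    identity x·oi_a_m + (1 − x)·oi_b_m = f(x) holds by construction.
    """

    oi_a_m: float
    oi_b_m: float
    x: float


@dataclass
class PredictionRecord:
    """A predicted mixture OI with the inputs and decomposition behind it."""

    ln_oav_a: float
    ln_oav_b: float
    partials: PartialIntensities
    oi_pre: float
    oi_mea: Optional[float] = None
    predictive_coefficient: Optional[float] = None


@dataclass(frozen=True)
class QuadraticMixtureModel:
    """Fitted mixture curve y = a2·x² + a1·x + a0 with its fit metadata.

    ``xtx_inv`` is the inverse normal matrix of the (x², x, 1) design —
    together with ``residual_sd`` and ``n_points`` it is sufficient to
    evaluate pointwise mean-response confidence bands and coefficient
    intervals. Literature-fixed models (packaged constants) carry no
    residual information and cannot produce bands.
    """

    a2: float
    a1: float
    a0: float
    n_points: int = 0
    residual_sd: Optional[float] = None
    confidence_level: float = 0.90
    provenance: str = "fitted"
    xtx_inv: Optional[Tuple[Tuple[float, ...], ...]] = None

    @property
    def coefficients(self) -> Tuple[float, float, float]:
        return (self.a2, self.a1, self.a0)

    def f(self, x: float):
        """Curve value OI_m at mixing proportion x."""
        return (self.a2 * x + self.a1) * x + self.a0

    def derivative(self, x: float):
        """Slope f′(x) of the mixture curve."""
        return 2.0 * self.a2 * x + self.a1

    __call__ = f

    @property
    def symmetry_axis(self) -> float:
        """x where f′ vanishes (the curve's vertex)."""
        if self.a2 == 0:
            raise ZeroDivisionError("degenerate (linear) curve has no vertex")
        return -self.a1 / (2.0 * self.a2)

    def _require_band_info(self) -> None:
        if self.xtx_inv is None or self.residual_sd is None or self.n_points < 4:
            raise ValueError(
                f"model with provenance {self.provenance!r} carries no residual "
                "information; confidence bands are unavailable"
            )

    def confidence_band(self, x, level: Optional[float] = None):
        """Pointwise mean-response confidence band (lo, hi) at x.

        Student-t with n − 3 degrees of freedom at ``level`` (defaults to the
        level stored on the model, normally 0.90).
        """
        self._require_band_info()
        level = self.confidence_level if level is None else level
        x = np.asarray(x, dtype=float)
        v = np.stack([x**2, x, np.ones_like(x)])
        a_inv = np.asarray(self.xtx_inv)
        se = self.residual_sd * np.sqrt(np.einsum("i...,ij,j...->...", v, a_inv, v))
        t = stats.t.ppf(0.5 + level / 2.0, self.n_points - 3)
        yhat = self.f(x)
        return yhat - t * se, yhat + t * se

    def coefficient_standard_errors(self) -> Tuple[float, float, float]:
        self._require_band_info()
        a_inv = np.asarray(self.xtx_inv)
        return tuple(float(self.residual_sd * np.sqrt(a_inv[i, i])) for i in range(3))

    def coefficient_intervals(
        self, level: Optional[float] = None
    ) -> Tuple[Tuple[float, float], ...]:
        """Per-coefficient t confidence intervals ((a2−, a2+), (a1±), (a0±))."""
        self._require_band_info()
        level = self.confidence_level if level is None else level
        t = stats.t.ppf(0.5 + level / 2.0, self.n_points - 3)
        ses = self.coefficient_standard_errors()
        return tuple(
            (c - t * se, c + t * se) for c, se in zip(self.coefficients, ses)
        )

    def swapped(self) -> "QuadraticMixtureModel":
        """The same curve viewed from component b's axis (x ↦ 1 − x).

        Coefficients map to (a2, −2·a2 − a1, a2 + a1 + a0); band information
        is dropped because the design summaries are axis-specific.
        """
        return QuadraticMixtureModel(
            a2=self.a2,
            a1=-2.0 * self.a2 - self.a1,
            a0=self.a2 + self.a1 + self.a0,
            n_points=self.n_points,
            residual_sd=self.residual_sd,
            confidence_level=self.confidence_level,
            provenance=self.provenance,
            xtx_inv=None,
        )


@dataclass(frozen=True)
class EvaluationSummary:
    """Mean predictive coefficient and the per-record ratios behind it."""

    mean_predictive_coefficient: float
    ratios: Tuple[float, ...]
    n_used: int
    n_excluded: int
    rounding: str


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize(sample: BinaryMixtureSample) -> NormalizedPoint:
    """Map a measured sample to the (x, OI_m) plane of the mixture curve."""
    if sample.measured_oi is None:
        raise MissingMeasurementError(
            f"sample {sample.mixture_id!r} has no measured OI; cannot normalize"
        )
    total = sample.total_ln_oav
    return NormalizedPoint(x=sample.ln_oav_a / total, oi_m=sample.measured_oi / total)


def fit_mixture_curve(
    points: Iterable[NormalizedPoint],
    confidence_level: float = 0.90,
) -> QuadraticMixtureModel:
    """Unweighted least-squares quadratic through normalized mixture points.

    Requires at least 4 points with at least 3 distinct x values (the rank
    condition of the quadratic design). Stores the inverse normal matrix and
    residual sd (n − 3 denominator) so confidence bands can be evaluated.
    """
    pts = list(points)
    xs = np.array([p.x for p in pts], dtype=float)
    ys = np.array([p.oi_m for p in pts], dtype=float)
    if not (0.0 < confidence_level < 1.0):
        raise InvalidInputError(f"confidence_level must be in (0, 1), got {confidence_level}")
    bad = (xs < 0.0) | (xs > 1.0) | ~np.isfinite(xs) | ~np.isfinite(ys)
    if bad.any():
        raise InvalidPointError(
            f"{int(bad.sum())} point(s) with x outside [0, 1] or non-finite values"
        )
    if len(pts) < 4:
        raise DegenerateDesignError(f"need ≥ 4 points to fit a quadratic, got {len(pts)}")
    if len(np.unique(xs)) < 3:
        raise DegenerateDesignError("need ≥ 3 distinct mixing proportions")

    design = np.column_stack([xs**2, xs, np.ones_like(xs)])
    coef, *_ = np.linalg.lstsq(design, ys, rcond=None)
    n = len(pts)
    resid = ys - design @ coef
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 3))) if n > 3 else 0.0
    xtx_inv = np.linalg.inv(design.T @ design)
    return QuadraticMixtureModel(
        a2=float(coef[0]),
        a1=float(coef[1]),
        a0=float(coef[2]),
        n_points=n,
        residual_sd=residual_sd,
        confidence_level=confidence_level,
        provenance="fitted",
        xtx_inv=tuple(tuple(float(v) for v in row) for row in xtx_inv),
    )


def extended_model() -> QuadraticMixtureModel:
    """The packaged extended mixture curve for binary aldehyde mixtures.

    y = 2.20·x² − 2.20·x + 1.32, pooled over propionaldehyde, n-valeraldehyde
    and n-heptaldehyde pairs; symmetric about x = 0.5. Literature-fixed: no
    residual information, so no confidence bands.
    """
    a2, a1, a0 = EXTENDED_COEFFICIENTS
    return QuadraticMixtureModel(a2=a2, a1=a1, a0=a0, provenance="literature-fixed")


def partial_intensities(model: QuadraticMixtureModel, x: float) -> PartialIntensities:
    """Tangent-intercept decomposition of the mixture curve at proportion x.

    The tangent to f at (x, f(x)) is evaluated at x = 1 (component a's axis)
    and x = 0 (component b's); the intercepts are the partial OI per lnOAV
    unit of each component. Warns outside the design range [0.1, 0.9].
    """
    x = float(x)
    if not (0.0 < x < 1.0):
        raise OutOfDomainError(f"mixing proportion must be in (0, 1), got {x}")
    if not (DESIGN_X_RANGE[0] <= x <= DESIGN_X_RANGE[1]):
        warnings.warn(
            f"mixing proportion {x:.3g} outside the design range "
            f"[{DESIGN_X_RANGE[0]}, {DESIGN_X_RANGE[1]}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    y, slope = model.f(x), model.derivative(x)
    return PartialIntensities(
        oi_a_m=(1.0 - x) * slope + y,
        oi_b_m=-x * slope + y,
        x=x,
    )


def predict_oi(
    model: QuadraticMixtureModel,
    ln_oav_a: float,
    ln_oav_b: float,
    oi_mea: Optional[float] = None,
) -> PredictionRecord:
    """Predict the joint OI of a binary mixture from its component lnOAVs.

    Computes x, the tangent-intercept partials, and the summation-rule OI;
    the equivalent direct evaluation (lnOAV_a + lnOAV_b)·f(x) is computed as
    a cross-check and must agree to 1e-9.
    """
    if ln_oav_a <= 0 or ln_oav_b <= 0:
        raise SubThresholdComponentError(
            f"both components must be supra-threshold; got lnOAVs "
            f"({ln_oav_a}, {ln_oav_b})"
        )
    total = ln_oav_a + ln_oav_b
    x = ln_oav_a / total
    parts = partial_intensities(model, x)
    oi_pre = parts.oi_a_m * ln_oav_a + parts.oi_b_m * ln_oav_b
    direct = total * model.f(x)
    if abs(oi_pre - direct) > 1e-9 * max(1.0, abs(direct)):
        raise AssertionError(
            f"tangent-summation route ({oi_pre}) disagrees with direct curve "
            f"evaluation ({direct}); numerical inconsistency"
        )
    return PredictionRecord(
        ln_oav_a=float(ln_oav_a),
        ln_oav_b=float(ln_oav_b),
        partials=parts,
        oi_pre=float(oi_pre),
        oi_mea=oi_mea,
    )


def predict_sample(model: QuadraticMixtureModel, sample: BinaryMixtureSample) -> PredictionRecord:
    """Convenience wrapper: predict from a sample's exposures."""
    return predict_oi(model, sample.ln_oav_a, sample.ln_oav_b, oi_mea=sample.measured_oi)


_ROUNDERS = {
    "report": report_round_oi,
    "decimal1": lambda v: round_half_away(v, 1),
    "none": lambda v: v,
}


def evaluate_predictions(
    records: Sequence[PredictionRecord],
    rounding: str = "report",
) -> EvaluationSummary:
    """Predictive coefficients OI_pre/OI_mea and their arithmetic mean.

    ``rounding`` controls the precision at which predictions enter the
    ratios: ``"report"`` (default) applies the published report convention
    (:func:`report_round_oi`), ``"decimal1"`` plain 1-decimal rounding,
    ``"none"`` full precision. Records without a positive measured OI are
    excluded with a logged warning; their ``predictive_coefficient`` stays
    None.
    """
    try:
        rounder = _ROUNDERS[rounding]
    except KeyError:
        raise InvalidInputError(
            f"unknown rounding mode {rounding!r}; expected one of {sorted(_ROUNDERS)}"
        ) from None
    ratios: List[float] = []
    n_excluded = 0
    for i, rec in enumerate(records):
        if rec.oi_mea is None or not (rec.oi_mea > 0):
            logger.warning(
                "excluded-record: record %d has missing or non-positive "
                "measured OI (%r); skipped from evaluation", i, rec.oi_mea,
            )
            n_excluded += 1
            continue
        ratio = rounder(rec.oi_pre) / rec.oi_mea
        rec.predictive_coefficient = ratio
        ratios.append(ratio)
    if not ratios:
        raise MissingMeasurementError("no records with measured OI to evaluate")
    return EvaluationSummary(
        mean_predictive_coefficient=float(np.mean(ratios)),
        ratios=tuple(ratios),
        n_used=len(ratios),
        n_excluded=n_excluded,
        rounding=rounding,
    )


def stratify_by_level(
    samples: Iterable[BinaryMixtureSample],
) -> Dict[str, List[BinaryMixtureSample]]:
    """Group samples into the low / middle / high measured-OI bands.

    Used to check that mixture curves fitted per concentration band agree —
    the interaction depends on the mixing ratio, not the intensity level.
    """
    groups: Dict[str, List[BinaryMixtureSample]] = {"low": [], "middle": [], "high": []}
    for sample in samples:
        if sample.measured_oi is None:
            raise MissingMeasurementError(
                f"sample {sample.mixture_id!r} has no measured OI; cannot stratify"
            )
        groups[oi_level(sample.measured_oi)].append(sample)
    return groups
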