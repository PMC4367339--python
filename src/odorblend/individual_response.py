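"""Linear OI–lnOAV response of single odorants.

Perceived odor intensity of an individual odorant rises linearly with the
natural log of its odor activity value over the working range of the OIRS
scale. The fitted line is the ground truth the panel simulator builds on and
a sanity check for mixture inputs; pooling points from several odorants into
one fit is the caller's choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .core import SCALE_MAX, SCALE_MIN

__all__ = [
    "DegenerateDesignError",
    "LinearResponseModel",
    "IndividualPrediction",
    "fit_linear_response",
    "predict_individual_oi",
]


class DegenerateDesignError(ValueError):
    """The design has too little spread in lnOAV to identify the line."""


@dataclass(frozen=True)
class LinearResponseModel:
    """OLS line OI = slope·lnOAV + intercept for an individual odorant.

    slope is in OIRS units per lnOAV unit; residual_sd uses the n−2
    denominator (0.0 when n == 2 or the fit is exact).
    """

    slope: float
    intercept: float
    n_points: int
    residual_sd: float

    def predict(self, ln_oav: float) -> float:
        return self.slope * ln_oav + self.intercept

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LinearResponseModel":
        return cls(**json.loads(text))


class IndividualPrediction(NamedTuple):
    """Predicted OI plus a scale flag (None, 'below-scale' or 'above-scale')."""

    oi: float
    flag: Optional[str]


def fit_linear_response(
    points: Iterable[Tuple[float, float]],
) -> LinearResponseModel:
    """Ordinary least-squares fit of measured OI against lnOAV.

    Parameters
    ----------
    points:
        (lnOAV, measured OI) pairs, at least two with distinct lnOAV.
        Points may come from one odorant or be pooled across several.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise DegenerateDesignError("need at least 2 (lnOAV, OI) points")
    x, y = pts[:, 0], pts[:, 1]
    if not np.all(np.isfinite(pts)):
        raise DegenerateDesignError("non-finite values in input points")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all lnOAV values identical; slope not identifiable")

    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    n = len(x)
    resid = y - (slope * x + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return LinearResponseModel(float(slope), float(intercept), n, residual_sd)


def predict_individual_oi(model: LinearResponseModel, ln_oav: float) -> IndividualPrediction:
    """Predicted OI for one odorant at one lnOAV, with an out-of-scale flag.

    The value itself is never clamped; callers decide how to treat
    predictions outside the OIRS range [1, 8].
    """
    if not np.isfinite(ln_oav):
        raise ValueError(f"ln_oav must be finite, got {ln_oav}")
    oi = model.predict(float(ln_oav))
    flag = None
    if oi < SCALE_MIN:
        flag = "below-scale"
    elif oi > SCALE_MAX:
        flag = "above-scale"
    return IndividualPrediction(oi, flag)
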