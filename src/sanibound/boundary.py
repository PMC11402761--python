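"""Sanitary-boundary inversion of a fitted GWQI model.

The fitted forward model

    GWQI = b0 + b_tr * Tr + b_depth * Wdepth + b_lpw * Lpw

is solved algebraically for the well-to-latrine distance Lpw at a
nominal index value GWQI* (default 25, guaranteeing very good water):

    Lpw = a_tr * Tr + a_depth * Wdepth + a_gwqi * GWQI* + a0

with a_tr = -b_tr/b_lpw, a_depth = -b_depth/b_lpw, a_gwqi = 1/b_lpw and
a0 = -b0/b_lpw.  Inversion always uses full-precision coefficients so
that substituting the boundary back into the forward model returns the
nominal index exactly; the published 3-decimal equation is reproduced
by :meth:`BoundaryModel.rounded_equation`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .assoc_stats import RegressionFit
from .well_data import WellDataError, WellTable

__all__ = ["BoundaryModel", "invert_model", "eval_boundary", "boundary_for_wells"]

log = logging.getLogger(__name__)

#: canonical forward-term column names
TR = "transmissivity_m2day"
DEPTH = "depth_m"
LPW = "dist_latrine_m"


@dataclass(frozen=True)
class BoundaryModel:
    """Inverted sanitary-boundary equation.

    Carries the forward coefficients at full precision; the inverse
    coefficients are derived properties.  ``clip`` controls whether
    negative raw boundaries (physically meaningless distances) are
    clipped to 0 during evaluation.
    """

    intercept: float
    beta_tr: float
    beta_depth: float
    beta_lpw: float
    nominal_gwqi: float = 25.0
    clip: bool = True

    def __post_init__(self):
        if self.beta_lpw == 0:
            raise WellDataError(
                "cannot invert: latrine-distance coefficient is zero"
            )

    # -- inverse coefficients -------------------------------------------------
    @property
    def a_tr(self) -> float:
        return -self.beta_tr / self.beta_lpw

    @property
    def a_depth(self) -> float:
        return -self.beta_depth / self.beta_lpw

    @property
    def a_gwqi(self) -> float:
        return 1.0 / self.beta_lpw

    @property
    def a0(self) -> float:
        return -self.intercept / self.beta_lpw

    @property
    def constant_at_nominal(self) -> float:
        """a0 + a_gwqi * GWQI*, the constant of the final boundary equation."""
        return self.a0 + self.a_gwqi * self.nominal_gwqi

    def rounded_equation(self, ndigits: int = 3) -> dict[str, float]:
        """Display-precision inverse equation, as printed.

        Coefficients are rounded first and the nominal constant is then
        computed from the rounded values, matching how the published
        final equation was derived from the rounded intermediate one.
        """
        a_tr = round(self.a_tr, ndigits)
        a_depth = round(self.a_depth, ndigits)
        a_gwqi = round(self.a_gwqi, ndigits)
        a0 = round(self.a0, ndigits)
        return {
            "a_tr": a_tr,
            "a_depth": a_depth,
            "a_gwqi": a_gwqi,
            "a0": a0,
            "constant_at_nominal": round(a0 + a_gwqi * self.nominal_gwqi, ndigits),
        }

    # -- persistence ----------------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "beta_tr": self.beta_tr,
                    "beta_depth": self.beta_depth,
                    "beta_lpw": self.beta_lpw,
                    "nominal_gwqi": self.nominal_gwqi,
                    "clip": self.clip,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "BoundaryModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def invert_model(fit: RegressionFit, nominal_gwqi: float = 25.0,
                 clip: bool = True) -> BoundaryModel:
    """Invert a fitted GWQI model into a :class:`BoundaryModel`.

    The fit must contain a latrine-distance term with a nonzero
    coefficient; transmissivity and depth terms default to 0 when the
    stepwise selection dropped them.
    """
    if LPW not in fit.predictors:
        raise WellDataError(f"fit lacks the latrine-distance term {LPW!r}")
    extra = [t for t in fit.predictors if t not in (TR, DEPTH, LPW)]
    if extra:
        raise WellDataError(
            f"fit contains terms outside the boundary equation: {extra}"
        )
    b_lpw = fit.coefficients[LPW]
    if b_lpw == 0:
        raise WellDataError("latrine-distance coefficient is zero")
    return BoundaryModel(
        intercept=fit.intercept,
        beta_tr=fit.coefficients.get(TR, 0.0),
        beta_depth=fit.coefficients.get(DEPTH, 0.0),
        beta_lpw=b_lpw,
        nominal_gwqi=nominal_gwqi,
        clip=clip,
    )


def eval_boundary(model: BoundaryModel, tr, depth, clip: bool | None = None):
    """Evaluate the sanitary distance (m) at given transmissivity/depth.

    Accepts scalars or arrays.  Negative raw values are clipped to 0
    when clipping is enabled (model default), and clip events are
    logged.  NaN inputs propagate.
    """
    tr = np.asarray(tr, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(tr[~np.isnan(tr)] < 0) or np.any(depth[~np.isnan(depth)] < 0):
        raise WellDataError("transmissivity and depth must be non-negative")
    raw = model.a_tr * tr + model.a_depth * depth + model.constant_at_nominal
    do_clip = model.clip if clip is None else clip
    if do_clip:
        n_neg = int(np.sum(raw < 0))
        if n_neg:
            log.info("eval_boundary: clipped %d negative boundary value(s) to 0",
                     n_neg)
        raw = np.maximum(raw, 0.0)
    return raw if raw.ndim else float(raw)


def boundary_for_wells(model: BoundaryModel, wells: WellTable) -> WellTable:
    """Append a per-well ``boundary_m`` column; log min/max/mean."""
    wells.require_columns([TR, DEPTH])
    out = wells.copy()
    tr = out.frame[TR].to_numpy(dtype=float)
    depth = out.frame[DEPTH].to_numpy(dtype=float)
    missing = np.isnan(tr) | np.isnan(depth)
    if missing.any():
        raise WellDataError(
            f"wells missing Tr or depth at rows {list(np.nonzero(missing)[0])}"
        )
    out.frame["boundary_m"] = eval_boundary(model, tr, depth)
    b = out.frame["boundary_m"]
    log.info("boundary_for_wells: n=%d min=%.1f max=%.1f mean=%.1f m",
             len(b), b.min(), b.max(), b.mean())
    return out
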