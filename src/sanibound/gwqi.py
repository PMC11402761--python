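"""Weighted-arithmetic Groundwater Quality Index (GWQI).

The index summarizes a multi-parameter chemistry sample against
guideline standards:

    Wi  = wi / sum(wj)            (relative weight)
    qi  = 100 * Ci / Si           (quality rating)
    SIi = Wi * qi                 (sub-index)
    GWQI = sum_i SIi

Lower is better: [0, 50) excellent, [50, 100) good, [100, 200) poor,
[200, 300) very poor, [300, inf) unsuitable for consumption.  The
published class bounds are strict inequalities that leave the edge
values unassigned; this implementation closes each interval on the
left so the partition is total and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .well_data import (
    ChemistrySample,
    GuidelineTable,
    WellDataError,
    WellTable,
)

__all__ = [
    "CLASS_LABELS",
    "CLASS_EDGES",
    "IndexResult",
    "relative_weights",
    "compute_gwqi",
    "classify_gwqi",
    "batch_gwqi",
]

log = logging.getLogger(__name__)

CLASS_LABELS = ("excellent", "good", "poor", "very poor", "unsuitable")
CLASS_EDGES = (50.0, 100.0, 200.0, 300.0)


@dataclass(frozen=True)
class IndexResult:
    """Per-parameter breakdown and total index for one sample."""

    ratings: dict[str, float]      # qi
    sub_indices: dict[str, float]  # SIi = Wi * qi
    value: float                   # GWQI = sum(SIi)
    label: str


def relative_weights(raw_weights: Mapping[str, float]) -> dict[str, float]:
    """Normalize raw weights wi to relative weights Wi = wi / sum(wj).

    The output sums to 1 (within 1e-12).  Raises on an empty mapping or
    any non-positive weight.
    """
    if not raw_weights:
        raise WellDataError("relative_weights: empty weight mapping")
    bad = {k: v for k, v in raw_weights.items() if not v > 0}
    if bad:
        raise WellDataError(f"relative_weights: non-positive weights {bad}")
    total = float(sum(raw_weights.values()))
    return {k: v / total for k, v in raw_weights.items()}


def classify_gwqi(value: float) -> str:
    """Map a GWQI value to its quality class label."""
    if value < 0 or not np.isfinite(value):
        raise WellDataError(f"GWQI must be finite and >= 0, got {value}")
    idx = int(np.searchsorted(CLASS_EDGES, value, side="right"))
    return CLASS_LABELS[idx]


def compute_gwqi(
    sample: ChemistrySample,
    guidelines: GuidelineTable,
    renormalize: bool = False,
) -> IndexResult:
    """Compute the GWQI of one chemistry sample.

    Parameters present in the sample must exist in the guideline table;
    parameters absent from the sample simply do not contribute (the sum
    runs over available parameters and the weights are NOT renormalized
    to the subset — a warning lists what is missing).

    ``renormalize`` divides all relative weights by their table-wide sum
    (the printed weights sum to 1.0036, not 1).
    """
    weights = guidelines.relative_weights
    if renormalize:
        s = guidelines.weight_sum
        weights = {k: w / s for k, w in weights.items()}
    standards = guidelines.standards

    unknown = [p for p in sample if p not in standards]
    if unknown:
        raise KeyError(
            f"sample parameters not in guideline table: {sorted(unknown)}"
        )
    missing = [p for p in guidelines.parameters if p not in sample.concentrations]
    if missing:
        log.warning(
            "GWQI computed over %d/%d parameters; missing: %s",
            len(sample.concentrations), len(guidelines), missing,
        )

    ratings: dict[str, float] = {}
    sub: dict[str, float] = {}
    for p, ci in sample.items():
        if ci < 0:
            raise WellDataError(f"negative concentration for {p!r}: {ci}")
        qi = 100.0 * ci / standards[p]
        ratings[p] = qi
        sub[p] = weights[p] * qi
    value = float(sum(sub.values()))
    return IndexResult(ratings=ratings, sub_indices=sub, value=value,
                       label=classify_gwqi(value))


def batch_gwqi(
    wells: WellTable,
    guidelines: GuidelineTable,
    renormalize: bool = False,
) -> WellTable:
    """Fill the measured-GWQI column of a well table.

    Wells carrying a precomputed ``gwqi_actual`` pass through unchanged;
    wells with chemistry columns get the index computed; wells with
    neither are skipped with a warning.  A summary (n, min, max, mean,
    class proportions) is logged.
    """
    out = wells.copy()
    chem_cols = [c for c in wells.chemistry_parameters]
    skipped = []
    if "gwqi_actual" not in out.frame.columns:
        out.frame["gwqi_actual"] = np.nan
    for idx, row in out.frame.iterrows():
        if not np.isnan(row["gwqi_actual"]):
            continue
        conc = {c: row[c] for c in chem_cols if not np.isnan(row[c])}
        if not conc:
            skipped.append(idx)
            continue
        res = compute_gwqi(ChemistrySample(conc), guidelines, renormalize)
        out.frame.loc[idx, "gwqi_actual"] = res.value
    if skipped:
        log.warning(
            "batch_gwqi: %d wells lack both chemistry and GWQI; skipped rows %s",
            len(skipped), skipped,
        )
    vals = out.frame["gwqi_actual"].dropna().to_numpy()
    if len(vals):
        # model-space GWQI (regression noise) may dip below 0; such values
        # have no quality class and are excluded from the class tally
        labels = [classify_gwqi(v) for v in vals if v >= 0]
        props = {
            lab: labels.count(lab) / len(labels)
            for lab in CLASS_LABELS
            if lab in labels
        }
        log.info(
            "batch_gwqi: n=%d min=%.3f max=%.3f mean=%.3f classes=%s",
            len(vals), vals.min(), vals.max(), vals.mean(), props,
        )
    else:
        log.info("batch_gwqi: summary of zero wells")
    return out
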