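"""Well-field data model and I/O.

A *well table* is the package's central container: one row per hand-dug
well, with coordinates in decimal degrees, hydrogeological covariates
(elevation, depth, aquifer transmissivity, distance to the nearest pit
latrine, well age) and, optionally, either raw chemistry concentrations
or a precomputed groundwater quality index (GWQI).

Packaged fixtures transcribe the published guideline standards/weights,
the 28-well validation table, the six-variable correlation matrix and
the fitted GWQI regression, all at their printed precision.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellDataError",
    "SchemaError",
    "RowError",
    "GuidelineEntry",
    "GuidelineTable",
    "ChemistrySample",
    "WellRecord",
    "WellTable",
    "WELL_COLUMNS",
    "read_wells",
    "write_wells",
    "load_fixture",
    "FIXTURE_NAMES",
]

#: canonical well-table columns, in CSV order
WELL_COLUMNS = (
    "no",
    "lon",
    "lat",
    "gwqi_actual",
    "elevation_m",
    "dist_latrine_m",
    "depth_m",
    "transmissivity_m2day",
    "age_yr",
    "gwqi_predicted",
)

#: columns that must be present in any well CSV
MANDATORY_COLUMNS = ("no", "lon", "lat")

#: numeric validity constraints: column -> (lower bound, strict)
_BOUNDS = {
    "depth_m": (0.0, True),
    "transmissivity_m2day": (0.0, True),
    "dist_latrine_m": (0.0, False),
    "age_yr": (0.0, False),
}


class WellDataError(ValueError):
    """Base class for well-data problems."""


class SchemaError(WellDataError):
    """A mandatory column is missing or mis-typed."""


class RowError(WellDataError):
    """One or more rows violate a value constraint; carries row indices."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = tuple(rows)


@dataclass(frozen=True)
class GuidelineEntry:
    """One water-quality parameter: guideline standard and weights.

    ``standard`` is the permissible concentration Si (mg/l except EC in
    uS/cm and pH, which is unitless); ``relative_weight`` is the
    normalized weight Wi used in the index.
    """

    parameter: str
    unit: str
    standard: float
    raw_weight: float | None = None
    relative_weight: float | None = None

    def __post_init__(self):
        if not self.standard > 0:
            raise WellDataError(
                f"guideline standard for {self.parameter!r} must be > 0, "
                f"got {self.standard}"
            )
        if self.relative_weight is not None and not (
            0.0 <= self.relative_weight <= 1.0
        ):
            raise WellDataError(
                f"relative weight for {self.parameter!r} outside [0, 1]: "
                f"{self.relative_weight}"
            )


@dataclass(frozen=True)
class GuidelineTable:
    """Ordered collection of :class:`GuidelineEntry` with unique names."""

    entries: tuple[GuidelineEntry, ...]

    def __post_init__(self):
        names = [e.parameter for e in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise WellDataError(f"duplicate guideline parameters: {dupes}")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(e.parameter for e in self.entries)

    @property
    def standards(self) -> dict[str, float]:
        return {e.parameter: e.standard for e in self.entries}

    @property
    def relative_weights(self) -> dict[str, float]:
        return {
            e.parameter: e.relative_weight
            for e in self.entries
            if e.relative_weight is not None
        }

    @property
    def weight_sum(self) -> float:
        return float(sum(self.relative_weights.values()))

    def __getitem__(self, parameter: str) -> GuidelineEntry:
        for e in self.entries:
            if e.parameter == parameter:
                return e
        raise KeyError(parameter)

    def __len__(self) -> int:
        return len(self.entries)

    def with_standard(self, parameter: str, standard: float) -> "GuidelineTable":
        """Return a copy with one parameter's standard replaced.

        Used e.g. to move the pH denominator off the default upper
        guideline bound of 8.5.
        """
        if parameter not in self.parameters:
            raise KeyError(parameter)
        return GuidelineTable(
            tuple(
                replace(e, standard=standard) if e.parameter == parameter else e
                for e in self.entries
            )
        )

    def renormalized(self) -> "GuidelineTable":
        """Return a copy whose relative weights sum to exactly 1."""
        s = self.weight_sum
        if s <= 0:
            raise WellDataError("cannot renormalize: weight sum is not positive")
        return GuidelineTable(
            tuple(
                replace(e, relative_weight=e.relative_weight / s)
                if e.relative_weight is not None
                else e
                for e in self.entries
            )
        )

    @classmethod
    def from_csv(cls, path) -> "GuidelineTable":
        df = pd.read_csv(path, comment="#")
        missing = {"parameter", "unit", "standard", "relative_weight"} - set(
            df.columns
        )
        if missing:
            raise SchemaError(f"guideline CSV missing columns: {sorted(missing)}")
        entries = []
        for _, row in df.iterrows():
            raw = row.get("raw_weight")
            entries.append(
                GuidelineEntry(
                    parameter=str(row["parameter"]),
                    unit="" if pd.isna(row["unit"]) else str(row["unit"]),
                    standard=float(row["standard"]),
                    raw_weight=None if pd.isna(raw) else float(raw),
                    relative_weight=float(row["relative_weight"]),
                )
            )
        return cls(tuple(entries))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "parameter": self.parameters,
                "unit": [e.unit for e in self.entries],
                "standard": [e.standard for e in self.entries],
                "raw_weight": [e.raw_weight for e in self.entries],
                "relative_weight": [e.relative_weight for e in self.entries],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ChemistrySample:
    """Concentrations Ci keyed by guideline parameter name (pH unitless)."""

    concentrations: Mapping[str, float]

    def __post_init__(self):
        bad = {k: v for k, v in self.concentrations.items() if v < 0}
        if bad:
            raise WellDataError(f"negative concentrations: {bad}")

    def __getitem__(self, parameter: str) -> float:
        return self.concentrations[parameter]

    def __iter__(self):
        return iter(self.concentrations)

    def items(self):
        return self.concentrations.items()


@dataclass
class WellRecord:
    """One well's covariates, plus optional chemistry and index values."""

    well_id: str
    lon: float
    lat: float
    elevation_m: float | None = None
    dist_latrine_m: float | None = None
    depth_m: float | None = None
    transmissivity_m2day: float | None = None
    age_yr: float | None = None
    gwqi_actual: float | None = None
    gwqi_predicted: float | None = None
    chemistry: ChemistrySample | None = None

    def __post_init__(self):
        for name, strict in (("depth_m", True), ("transmissivity_m2day", True)):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise WellDataError(f"{name} must be > 0, got {v}")
        for name in ("dist_latrine_m", "age_yr"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise WellDataError(f"{name} must be >= 0, got {v}")


@dataclass
class WellTable:
    """An ordered well collection backed by a :class:`pandas.DataFrame`.

    Columns beyond :data:`WELL_COLUMNS` (and the projected ``x_m``/``y_m``)
    are interpreted as chemistry concentrations keyed by guideline
    parameter name.
    """

    frame: pd.DataFrame
    provenance: str = "user"  # fixture | user | synthetic

    def __post_init__(self):
        if "no" in self.frame.columns:
            ids = self.frame["no"].astype(str)
            if ids.duplicated().any():
                dupes = sorted(ids[ids.duplicated()].unique())
                raise WellDataError(f"duplicate well ids: {dupes}")
            self.frame = self.frame.assign(no=ids)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chemistry_parameters(self) -> tuple[str, ...]:
        extra = [
            c
            for c in self.frame.columns
            if c not in WELL_COLUMNS and c not in ("x_m", "y_m", "boundary_m")
        ]
        return tuple(extra)

    def require_columns(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise SchemaError(f"well table missing columns: {missing}")

    def copy(self) -> "WellTable":
        return WellTable(self.frame.copy(), self.provenance)

    def records(self) -> list[WellRecord]:
        chem_cols = self.chemistry_parameters
        out = []
        for _, row in self.frame.iterrows():
            def opt(col):
                v = row.get(col)
                return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

            chem = {
                c: float(row[c]) for c in chem_cols if not pd.isna(row.get(c))
            }
            out.append(
                WellRecord(
                    well_id=str(row["no"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    elevation_m=opt("elevation_m"),
                    dist_latrine_m=opt("dist_latrine_m"),
                    depth_m=opt("depth_m"),
                    transmissivity_m2day=opt("transmissivity_m2day"),
                    age_yr=opt("age_yr"),
                    gwqi_actual=opt("gwqi_actual"),
                    gwqi_predicted=opt("gwqi_predicted"),
                    chemistry=ChemistrySample(chem) if chem else None,
                )
            )
        return out

    @classmethod
    def from_records(
        cls, records: Sequence[WellRecord], provenance: str = "user"
    ) -> "WellTable":
        chem_params: list[str] = []
        for r in records:
            if r.chemistry is not None:
                for p in r.chemistry:
                    if p not in chem_params:
                        chem_params.append(p)
        rows = []
        for r in records:
            row = {
                "no": r.well_id,
                "lon": r.lon,
                "lat": r.lat,
                "gwqi_actual": r.gwqi_actual,
                "elevation_m": r.elevation_m,
                "dist_latrine_m": r.dist_latrine_m,
                "depth_m": r.depth_m,
                "transmissivity_m2day": r.transmissivity_m2day,
                "age_yr": r.age_yr,
                "gwqi_predicted": r.gwqi_predicted,
            }
            for p in chem_params:
                row[p] = (
                    r.chemistry.concentrations.get(p, np.nan)
                    if r.chemistry is not None
                    else np.nan
                )
            rows.append(row)
        cols = list(WELL_COLUMNS) + chem_params
        frame = pd.DataFrame(rows, columns=cols)
        for c in cols:
            if c != "no":
                frame[c] = pd.to_numeric(frame[c])
        return cls(frame, provenance)


def _validate_frame(df: pd.DataFrame) -> None:
    problems = []
    rows: list[int] = []
    for col, (lo, strict) in _BOUNDS.items():
        if col not in df.columns:
            continue
        vals = df[col]
        bad = (vals <= lo) if strict else (vals < lo)
        bad &= vals.notna()
        if bad.any():
            idx = list(df.index[bad])
            op = ">" if strict else ">="
            problems.append(f"{col} must be {op} {lo} (rows {idx})")
            rows.extend(idx)
    if problems:
        raise RowError("; ".join(problems), sorted(set(rows)))


def read_wells(path, schema: Mapping[str, str] | None = None,
               provenance: str = "user") -> WellTable:
    """Read a well CSV into a :class:`WellTable`.

    Parameters
    ----------
    path:
        CSV file with a header row, "." decimal separator, UTF-8.
    schema:
        optional mapping from file column names to canonical names
        (see :data:`WELL_COLUMNS`); unmapped columns are kept as-is.
    provenance:
        tag recorded on the returned table.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    RowError
        if a cell fails to parse as a number or violates a bound; the
        message names the offending rows and columns.
    """
    df = pd.read_csv(path, comment="#", dtype={"no": str})
    if schema:
        df = df.rename(columns=dict(schema))
        if "no" in df.columns:
            df["no"] = df["no"].astype(str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    numeric_cols = [c for c in df.columns if c != "no"]
    for col in numeric_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = list(df.index[coerced.isna() & df[col].notna()])
            raise RowError(
                f"non-numeric value(s) in column {col!r} at rows {bad}", bad
            ) from None
    _validate_frame(df)
    return WellTable(df, provenance)


def write_wells(table: WellTable, path) -> None:
    """Write a :class:`WellTable` as CSV; optional fields become empty cells."""
    table.frame.to_csv(path, index=False)


FIXTURE_NAMES = ("guidelines", "validation_wells", "correlations", "regression")


def _fixture_path(name: str):
    return importlib.resources.files("sanibound.data").joinpath(f"{name}.csv")


def load_fixture(name: str):
    """Load a packaged fixture by name.

    ``guidelines``
        the 11-parameter :class:`GuidelineTable` (printed relative
        weights verbatim; their sum is 1.0036).
    ``validation_wells``
        the 28-well :class:`WellTable` used for regression validation.
    ``correlations``
        the published six-variable correlation matrix, as a
        :class:`sanibound.assoc_stats.CorrelationMatrix` (no p-values).
    ``regression``
        the published stepwise GWQI fit, as a
        :class:`sanibound.assoc_stats.RegressionFit` (R² = 0.796).
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    p = _fixture_path(name)
    if name == "guidelines":
        return GuidelineTable.from_csv(p)
    if name == "validation_wells":
        return read_wells(p, provenance="fixture")
    if name == "correlations":
        from .assoc_stats import CorrelationMatrix

        df = pd.read_csv(p, index_col=0)
        return CorrelationMatrix(
            variables=tuple(df.columns),
            r=df.to_numpy(dtype=float),
            p=np.full(df.shape, np.nan),
            n=np.full(df.shape, 112, dtype=int),
        )
    # regression
    from .assoc_stats import RegressionFit

    df = pd.read_csv(p, comment="#")
    with open(p, "r", encoding="utf-8") as fh:
        first = fh.readline()
    r2 = float(first.split("r_squared=")[1]) if "r_squared=" in first else np.nan
    terms = dict(zip(df["term"], df["coefficient"]))
    se = dict(zip(df["term"], df["se"]))
    t = dict(zip(df["term"], df["t"]))
    pv = dict(zip(df["term"], df["p"]))
    predictors = tuple(x for x in df["term"] if x != "intercept")
    return RegressionFit(
        response="gwqi_actual",
        predictors=predictors,
        intercept=float(terms["intercept"]),
        coefficients={k: float(terms[k]) for k in predictors},
        se={k: float(se[k]) for k in se},
        t={k: float(t[k]) for k in t},
        p={k: float(pv[k]) for k in pv},
        r_squared=r2,
        resid_std=np.nan,
        n=90,
        trace=(),
    )
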