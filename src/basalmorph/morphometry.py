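"""Core morphometric quantities for basal-cell karyometry.

A case is summarised by four primary size measurements taken from traced
cell and nucleus outlines — cell area (CA, µm²), cell perimeter (CP, µm),
nuclear area (NA, µm²) and nuclear perimeter (NP, µm) — from which three
derived, dimensionless descriptors are computed:

* form perimeter (form PE), ``4·c·A/P²`` with circle constant ``c``:
  a circularity score that is 1 for a perfect circle and decreases as the
  outline becomes more irregular;
* contour index (CI), ``P/√A``: 2√π ≈ 3.5449 for a circle, increasing
  with indentations or convolutions of the outline;
* nuclear–cytoplasmic ratio (N:C), ``NA/(CA − NA)``: the nuclear area
  relative to the remaining cytoplasmic area.

Form PE and CI are algebraically linked — ``CI² · form_pe = 4c`` — so they
carry the same shape information on different scales.  The circle constant
defaults to π; the classical school-book approximation 22/7 is provided for
compatibility with older image-analysis software.  Every downstream group
statistic is invariant under this choice because it rescales form PE by a
global positive factor.

Measured data can violate the isoperimetric bound (form PE > 1) because
area and perimeter are estimated by different discrete procedures; such
values are legitimate and are passed through with a warning, never clipped.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CIRCLE_PI",
    "CIRCLE_22_7",
    "GROUPS",
    "MorphometryError",
    "DomainError",
    "InsufficientDataError",
    "MeasurementRecord",
    "ShapeDescriptors",
    "GroupSummary",
    "form_pe",
    "contour_index",
    "nc_ratio",
    "derive_descriptors",
    "summarize",
    "summarize_values",
    "read_measurements",
    "write_measurements",
    "load_reference_cohort",
    "DESCRIPTOR_VARIABLES",
    "MEASURED_VARIABLES",
]

#: Exact circle constant (default).
CIRCLE_PI: float = math.pi
#: Historical rational approximation used by some legacy analyzers.
CIRCLE_22_7: float = 22.0 / 7.0

#: Controlled vocabulary for the diagnostic group label.
GROUPS: tuple[str, ...] = ("normal", "leukoplakia", "scc")

MEASURED_VARIABLES: tuple[str, ...] = (
    "cell_area",
    "cell_perimeter",
    "nuclear_area",
    "nuclear_perimeter",
)
DESCRIPTOR_VARIABLES: tuple[str, ...] = (
    "cellular_form_pe",
    "nuclear_form_pe",
    "cellular_ci",
    "nuclear_ci",
    "nc_ratio",
)


class MorphometryError(ValueError):
    """Base class for morphometry pipeline errors."""


class DomainError(MorphometryError):
    """An input value lies outside the mathematical domain of an operation."""


class InsufficientDataError(MorphometryError):
    """Too few observations to compute the requested quantity."""


def _require_positive(value: float, name: str) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise DomainError(f"{name} must be strictly positive and finite, got {value!r}")


def form_pe(area: float, perimeter: float, circle_constant: float = CIRCLE_PI) -> float:
    """Circularity score ``4·c·area/perimeter²`` (1 for a circle, c = π).

    Parameters
    ----------
    area : float
        Enclosed area, µm² (or any unit; the score is scale invariant).
    perimeter : float
        Outline length in the matching linear unit.
    circle_constant : float
        π by default; pass :data:`CIRCLE_22_7` to mimic legacy software.

    Values above 1 are possible for measured data (independent area and
    perimeter estimators) and are returned unchanged with a warning.
    """
    _require_positive(area, "area")
    _require_positive(perimeter, "perimeter")
    score = 4.0 * circle_constant * area / (perimeter * perimeter)
    if score > 1.0 + 1e-12:
        warnings.warn(
            f"form PE {score:.4f} exceeds the isoperimetric bound of 1; "
            "keeping the value as measured",
            stacklevel=2,
        )
    return score


def contour_index(area: float, perimeter: float) -> float:
    """Boundary irregularity ``perimeter/√area``; 2√π ≈ 3.5449 for a circle."""
    _require_positive(area, "area")
    _require_positive(perimeter, "perimeter")
    return perimeter / math.sqrt(area)


def nc_ratio(nuclear_area: float, cell_area: float) -> float:
    """Nuclear–cytoplasmic ratio ``NA/(CA − NA)``.

    Raises
    ------
    DomainError
        If either area is non-positive or the nucleus is not strictly
        smaller than the cell (zero or negative cytoplasm).
    """
    _require_positive(nuclear_area, "nuclear_area")
    _require_positive(cell_area, "cell_area")
    if nuclear_area >= cell_area:
        raise DomainError(
            f"implausible record: nuclear_area ({nuclear_area}) must be "
            f"strictly smaller than cell_area ({cell_area})"
        )
    return nuclear_area / (cell_area - nuclear_area)


@dataclass(frozen=True)
class MeasurementRecord:
    """One case's four primary size measurements plus its diagnostic group.

    Invariants (checked on construction): all four measurements strictly
    positive, the nucleus strictly inside the cell (NA < CA), and the group
    one of :data:`GROUPS`.
    """

    case_id: str
    group: str
    cell_area: float
    cell_perimeter: float
    nuclear_area: float
    nuclear_perimeter: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DomainError(
                f"case {self.case_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        for name in MEASURED_VARIABLES:
            _require_positive(getattr(self, name), f"case {self.case_id!r}: {name}")
        if not self.nuclear_area < self.cell_area:
            raise DomainError(
                f"case {self.case_id!r}: nuclear_area ({self.nuclear_area}) "
                f"must be smaller than cell_area ({self.cell_area})"
            )


@dataclass(frozen=True)
class ShapeDescriptors:
    """Derived per-case descriptors: form PE and CI per compartment, N:C."""

    cellular_form_pe: float
    nuclear_form_pe: float
    cellular_ci: float
    nuclear_ci: float
    nc_ratio: float


def derive_descriptors(
    record: MeasurementRecord, circle_constant: float = CIRCLE_PI
) -> ShapeDescriptors:
    """Compute all five shape/ratio descriptors for one measurement record.

    Deterministic and side-effect free; domain errors are re-raised with
    the offending case id attached.
    """
    try:
        return ShapeDescriptors(
            cellular_form_pe=form_pe(record.cell_area, record.cell_perimeter, circle_constant),
            nuclear_form_pe=form_pe(record.nuclear_area, record.nuclear_perimeter, circle_constant),
            cellular_ci=contour_index(record.cell_area, record.cell_perimeter),
            nuclear_ci=contour_index(record.nuclear_area, record.nuclear_perimeter),
            nc_ratio=nc_ratio(record.nuclear_area, record.cell_area),
        )
    except DomainError as exc:
        raise DomainError(f"case {record.case_id!r}: {exc}") from exc


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics for one variable within one diagnostic group.

    ``sem = sd/√n``; the 95% confidence interval for the mean uses the
    Student-t quantile with ``n − 1`` degrees of freedom.
    """

    group: str
    variable: str
    n: int
    mean: float
    sd: float
    sem: float
    ci95_low: float
    ci95_high: float


def summarize_values(values: Sequence[float], group: str, variable: str) -> GroupSummary:
    """Mean, sample SD (n−1), SEM and t-based 95% CI for one group/variable."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 observations for {group}/{variable}, got {arr.size}"
        )
    n = int(arr.size)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    sem = sd / math.sqrt(n)
    tq = float(_sps.t.ppf(0.975, n - 1))
    return GroupSummary(
        group=group,
        variable=variable,
        n=n,
        mean=mean,
        sd=sd,
        sem=sem,
        ci95_low=mean - tq * sem,
        ci95_high=mean + tq * sem,
    )


def variable_values(
    records: Iterable[MeasurementRecord],
    variable: str,
    circle_constant: float = CIRCLE_PI,
) -> np.ndarray:
    """Extract a measured column or compute a derived descriptor column."""
    records = list(records)
    if variable in MEASURED_VARIABLES:
        return np.array([getattr(r, variable) for r in records], dtype=float)
    if variable in DESCRIPTOR_VARIABLES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # form PE > 1 already reported at load
            return np.array(
                [getattr(derive_descriptors(r, circle_constant), variable) for r in records],
                dtype=float,
            )
    raise LookupError(
        f"unknown variable {variable!r}; expected one of "
        f"{MEASURED_VARIABLES + DESCRIPTOR_VARIABLES}"
    )


def summarize(
    records: Iterable[MeasurementRecord],
    group: str,
    variable: str,
    circle_constant: float = CIRCLE_PI,
) -> GroupSummary:
    """Descriptive statistics of one (group, variable) cell of the cohort.

    ``variable`` may be a primary measurement (``cell_area`` …) or a derived
    descriptor (``nuclear_form_pe`` …).
    """
    if group not in GROUPS:
        raise LookupError(f"unknown group {group!r}; expected one of {GROUPS}")
    members = [r for r in records if r.group == group]
    values = variable_values(members, variable, circle_constant)
    return summarize_values(values, group, variable)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_CSV_HEADER = [
    "case_id",
    "group",
    "cell_area",
    "cell_perimeter",
    "nuclear_area",
    "nuclear_perimeter",
]


def read_measurements(path) -> list[MeasurementRecord]:
    """Read a measurement table CSV, validating every row.

    Rows violating record invariants are rejected; a single error listing
    every offending row (1-based data row numbers) is raised, rather than
    silently dropping them.
    """
    records: list[MeasurementRecord] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != _CSV_HEADER:
            raise MorphometryError(
                f"unexpected CSV header {reader.fieldnames!r}; expected {_CSV_HEADER!r}"
            )
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    MeasurementRecord(
                        case_id=row["case_id"],
                        group=row["group"],
                        cell_area=float(row["cell_area"]),
                        cell_perimeter=float(row["cell_perimeter"]),
                        nuclear_area=float(row["nuclear_area"]),
                        nuclear_perimeter=float(row["nuclear_perimeter"]),
                    )
                )
            except (MorphometryError, KeyError, TypeError) as exc:
                problems.append(f"row {i}: {exc}")
            except ValueError as exc:  # float() parse failure
                problems.append(f"row {i}: {exc}")
    if problems:
        raise MorphometryError(
            "rejected {0} row(s):\n  {1}".format(len(problems), "\n  ".join(problems))
        )
    return records


def _fmt(x: float) -> str:
    # shortest round-trip representation, so load → save is byte stable
    return repr(float(x))


def write_measurements(records: Iterable[MeasurementRecord], path) -> None:
    """Write records in the standard CSV dialect (UTF-8, decimal point)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        handle.write(",".join(_CSV_HEADER) + "\n")
        for r in records:
            handle.write(
                f"{r.case_id},{r.group},{_fmt(r.cell_area)},{_fmt(r.cell_perimeter)},"
                f"{_fmt(r.nuclear_area)},{_fmt(r.nuclear_perimeter)}\n"
            )


def load_reference_cohort() -> list[MeasurementRecord]:
    """Load the packaged 70-case reference cohort.

    10 normal buccal mucosa, 30 leukoplakia and 30 well-differentiated oral
    squamous-cell-carcinoma cases; per-case mean basal-cell measurements in
    µm/µm², rows in the published order (leukoplakia, SCC, normal).
    """
    ref = resources.files("basalmorph").joinpath("data/reference_cohort.csv")
    with resources.as_file(ref) as path:
        return read_measurements(path)
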