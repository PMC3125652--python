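"""Synthetic basal-cell histology: label masks and measurement tables.

The generator emulates the statistical structure the analysis assumes —
three diagnostic groups (normal buccal mucosa, leukoplakia,
well-differentiated SCC) whose per-case cell and nuclear sizes, nuclear
fractions and boundary irregularity follow group-specific distributions —
without attempting photorealism.  Two output routes share one parameter
set:

* :func:`generate_tabular` draws per-case measurement records directly
  (fast; used for statistics testing), and
* :func:`generate_dataset` renders non-overlapping star-convex cells with
  nested nuclei into label-mask rasters field by field, together with a
  ground-truth table of the true polygon areas/perimeters, so the whole
  imaging path can be validated end to end.

Cell geometry is a star-convex radial perturbation: the boundary radius is
``R·(1 + irregularity · Σ_k w_k cos(kθ + φ_k))`` over a fixed band of
harmonics with random phases.  One knob — ``irregularity`` — therefore
moves shapes along the circularity axis: 0 gives a circle (form PE → 1),
larger values give indented outlines with lower form PE and higher contour
index.  Because the harmonic amplitudes are fixed given the knob (only the
phases are random), the resulting form PE is essentially a deterministic,
invertible function of the knob, computed by :func:`form_pe_of_irregularity`
and inverted by :func:`irregularity_for_form_pe`.

All randomness flows through an explicit ``numpy.random.Generator``; there
is no global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skimage import draw as skdraw

from . import morphometry as mm
from .imaging import Calibration, FieldFiles, LabelMaskPair, write_field
from .morphometry import DomainError, MeasurementRecord, MorphometryError

__all__ = [
    "GroupParams",
    "SyntheticSpec",
    "TruncationReport",
    "SyntheticDataset",
    "CapacityError",
    "form_pe_of_irregularity",
    "irregularity_for_form_pe",
    "render_cell",
    "generate_tabular",
    "generate_dataset",
    "default_spec",
]


class CapacityError(MorphometryError):
    """A field raster is too small to place the requested cells."""


# Harmonic band of the radial perturbation: wavenumbers and relative
# weights (∝ 1/k, normalised to unit RMS so `irregularity` is the RMS
# relative radius deviation).
_HARMONICS = np.array([2, 3, 4, 5, 6])
_WEIGHTS = (1.0 / _HARMONICS) / np.sqrt(np.sum((1.0 / _HARMONICS) ** 2) / 2.0)
_REFERENCE_PHASES = 2.399963 * _HARMONICS  # fixed, spread phases for calibration
_MAX_IRREGULARITY = 0.45  # knob ceiling; radii are bounded below anyway


def _radial_profile(theta: np.ndarray, irregularity: float, phases: np.ndarray) -> np.ndarray:
    eps = irregularity * np.sum(
        _WEIGHTS[:, None] * np.cos(_HARMONICS[:, None] * theta[None, :] + phases[:, None]),
        axis=0,
    )
    # bound the excursions so indentations stay wider than a raster pixel
    return np.clip(1.0 + eps, 0.35, 1.9)


def _polygon(radius_profile: np.ndarray, theta: np.ndarray) -> np.ndarray:
    ring = np.column_stack(
        [radius_profile * np.sin(theta), radius_profile * np.cos(theta)]
    )
    return np.vstack([ring, ring[:1]])


def _shoelace(poly: np.ndarray) -> float:
    r, c = poly[:, 0], poly[:, 1]
    return float(abs(0.5 * np.sum(r[:-1] * c[1:] - r[1:] * c[:-1])))


def _perimeter(poly: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(poly, axis=0), axis=1)))


def form_pe_of_irregularity(irregularity: float, n_vertices: int = 720) -> float:
    """Form PE of the canonical shape at a given irregularity knob.

    Deterministic (reference phases); monotonically decreasing in the knob.
    """
    if irregularity < 0:
        raise DomainError(f"irregularity must be >= 0, got {irregularity}")
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    poly = _polygon(_radial_profile(theta, irregularity, _REFERENCE_PHASES), theta)
    return 4.0 * math.pi * _shoelace(poly) / _perimeter(poly) ** 2


def irregularity_for_form_pe(target_form_pe: float) -> float:
    """Invert :func:`form_pe_of_irregularity`.

    Targets at or above the circle value map to 0 (measured data may exceed
    the isoperimetric bound; geometry cannot); targets below the most
    irregular achievable shape map to the knob's upper limit.
    """
    lo, hi = 0.0, _MAX_IRREGULARITY
    f_lo, f_hi = form_pe_of_irregularity(lo), form_pe_of_irregularity(hi)
    if target_form_pe >= f_lo:
        return 0.0
    if target_form_pe <= f_hi:
        return hi
    return float(brentq(lambda a: form_pe_of_irregularity(a) - target_form_pe, lo, hi))


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one diagnostic group.

    Areas are per-case means in µm²; ``nucleus_fraction`` is NA/CA;
    irregularity knobs are RMS relative radius deviations (dimensionless,
    0 = circle) for the cell and nucleus outlines.
    """

    group: str
    n_cases: int
    cell_area_mean: float
    cell_area_sd: float
    nuclear_area_mean: float
    nuclear_area_sd: float
    nucleus_fraction_mean: float
    nucleus_fraction_sd: float
    cell_irregularity: float
    nuclear_irregularity: float

    def __post_init__(self) -> None:
        if self.group not in mm.GROUPS:
            raise DomainError(f"unknown group {self.group!r}")
        if self.n_cases < 1:
            raise DomainError("n_cases must be positive")
        for name in (
            "cell_area_mean",
            "cell_area_sd",
            "nuclear_area_mean",
            "nuclear_area_sd",
            "nucleus_fraction_sd",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if not 0.0 < self.nucleus_fraction_mean < 1.0:
            raise DomainError("nucleus_fraction_mean must lie in (0, 1)")
        for name in ("cell_irregularity", "nuclear_irregularity"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a synthetic dataset.

    ``fields_per_case`` and ``cells_per_field`` are inclusive (min, max)
    ranges drawn uniformly per case/field; defaults follow the acquisition
    protocol the generator emulates (5–10 fields, 5–7 basal cells each).
    ``cell_cv`` is the within-case coefficient of variation of per-cell
    area; ``form_pe_cv`` the case-to-case CV of the form-PE level.
    """

    groups: tuple[GroupParams, ...]
    fields_per_case: tuple[int, int] = (5, 10)
    cells_per_field: tuple[int, int] = (5, 7)
    raster_shape: tuple[int, int] = (512, 512)
    microns_per_pixel: float = 0.25
    cell_cv: float = 0.10
    form_pe_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise DomainError("spec needs at least one group")
        for rng_pair, name in ((self.fields_per_case, "fields_per_case"),
                               (self.cells_per_field, "cells_per_field")):
            lo, hi = rng_pair
            if not (1 <= lo <= hi):
                raise DomainError(f"{name} must satisfy 1 <= min <= max, got {rng_pair}")
        if self.microns_per_pixel <= 0:
            raise DomainError("microns_per_pixel must be positive")
        # largest plausible cell must fit well inside the raster
        biggest = max(g.cell_area_mean + 4 * g.cell_area_sd for g in self.groups)
        radius_px = math.sqrt(biggest / math.pi) * 1.6 / self.microns_per_pixel
        if min(self.raster_shape) < 4 * radius_px:
            raise DomainError(
                f"raster {self.raster_shape} too small for cells of ~{biggest:.0f} µm²"
            )

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.microns_per_pixel)


@dataclass(frozen=True)
class TruncationReport:
    """Bookkeeping of redraws forced by positivity / NA < CA truncation."""

    n_draws: int
    n_rejected: int

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / max(self.n_draws, 1)


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Spec whose group parameters equal the packaged reference cohort's
    empirical group means/SDs (10 normal, 30 leukoplakia, 30 SCC cases).

    Irregularity knobs are set by inverting each group's mean form PE, so a
    rendered dataset reproduces the cohort's shape-descriptor levels as far
    as geometry allows (measured form PE above 1 maps to a circle).
    """
    records = mm.load_reference_cohort()
    params = []
    for group in mm.GROUPS:
        members = [r for r in records if r.group == group]
        ca = np.array([r.cell_area for r in members])
        na = np.array([r.nuclear_area for r in members])
        frac = na / ca
        cfpe = mm.variable_values(members, "cellular_form_pe")
        nfpe = mm.variable_values(members, "nuclear_form_pe")
        params.append(
            GroupParams(
                group=group,
                n_cases=len(members),
                cell_area_mean=float(ca.mean()),
                cell_area_sd=float(ca.std(ddof=1)),
                nuclear_area_mean=float(na.mean()),
                nuclear_area_sd=float(na.std(ddof=1)),
                nucleus_fraction_mean=float(frac.mean()),
                nucleus_fraction_sd=float(frac.std(ddof=1)),
                cell_irregularity=irregularity_for_form_pe(float(cfpe.mean())),
                nuclear_irregularity=irregularity_for_form_pe(float(nfpe.mean())),
            )
        )
    return SyntheticSpec(groups=tuple(params), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def render_cell(
    target_area: float,
    irregularity: float,
    nucleus_fraction: float,
    rng: np.random.Generator,
    nuclear_irregularity: Optional[float] = None,
    n_vertices: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """One cell/nucleus polygon pair, centred at the origin, in µm.

    The cell polygon is star-convex about the origin with area rescaled
    analytically to ``target_area``; the nucleus is a second star-convex
    polygon strictly inside it with area ≈ ``nucleus_fraction`` of the
    cell's.  Returns ``(cell, nucleus)`` as closed (N+1, 2) vertex arrays.
    """
    if not target_area > 0:
        raise DomainError(f"target_area must be positive, got {target_area}")
    if not 0.0 < nucleus_fraction < 1.0:
        raise DomainError(f"nucleus_fraction must lie in (0, 1), got {nucleus_fraction}")
    if nuclear_irregularity is None:
        nuclear_irregularity = irregularity
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)

    cell_r = _radial_profile(theta, irregularity, rng.uniform(0, 2 * np.pi, len(_HARMONICS)))
    cell = _polygon(cell_r, theta)
    cell *= math.sqrt(target_area / _shoelace(cell))
    cell_r = cell_r * math.sqrt(target_area / _shoelace(_polygon(cell_r, theta)))

    nuc_r = _radial_profile(
        theta, nuclear_irregularity, rng.uniform(0, 2 * np.pi, len(_HARMONICS))
    )
    target_na = nucleus_fraction * target_area
    cap = 0.90 * cell_r  # pointwise radial margin guarantees containment
    for _ in range(60):
        area = _shoelace(_polygon(nuc_r, theta))
        nuc_r = np.minimum(nuc_r * math.sqrt(target_na / area), cap)
        if abs(_shoelace(_polygon(nuc_r, theta)) - target_na) / target_na < 1e-6:
            break
    return cell, _polygon(nuc_r, theta)


# ---------------------------------------------------------------------------
# Tabular route
# ---------------------------------------------------------------------------


def _draw_case_sizes(
    g: GroupParams, rng: np.random.Generator, counter: list[int]
) -> tuple[float, float]:
    """Draw (CA, NA) from the group's normals, truncated to 0 < NA < CA."""
    for _ in range(1000):
        counter[0] += 1
        ca = rng.normal(g.cell_area_mean, g.cell_area_sd)
        na = rng.normal(g.nuclear_area_mean, g.nuclear_area_sd)
        if ca > 0 and na > 0 and na < ca:
            return float(ca), float(na)
        counter[1] += 1
    raise DomainError(f"group {g.group}: truncation rejected 1000 consecutive draws")


def generate_tabular(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    with_report: bool = False,
):
    """Draw per-case measurement records directly from the group models.

    CA and NA come from the group normal distributions (truncated to
    positivity and NA < CA); CP and NP are back-computed from the group's
    form-PE level (via the irregularity knob) jittered case to case by
    ``form_pe_cv``.  Deterministic given ``spec.seed`` (or an explicit rng).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counter = [0, 0]  # draws, rejections
    records: list[MeasurementRecord] = []
    for g in spec.groups:
        fpe_cell_level = form_pe_of_irregularity(g.cell_irregularity)
        fpe_nuc_level = form_pe_of_irregularity(g.nuclear_irregularity)
        for i in range(g.n_cases):
            ca, na = _draw_case_sizes(g, rng, counter)
            fpe_c = max(fpe_cell_level * (1.0 + rng.normal(0.0, spec.form_pe_cv)), 0.05)
            fpe_n = max(fpe_nuc_level * (1.0 + rng.normal(0.0, spec.form_pe_cv)), 0.05)
            records.append(
                MeasurementRecord(
                    case_id=f"syn-{g.group}-{i + 1:03d}",
                    group=g.group,
                    cell_area=ca,
                    cell_perimeter=math.sqrt(4.0 * math.pi * ca / fpe_c),
                    nuclear_area=na,
                    nuclear_perimeter=math.sqrt(4.0 * math.pi * na / fpe_n),
                )
            )
    report = TruncationReport(n_draws=counter[0], n_rejected=counter[1])
    return (records, report) if with_report else records


# ---------------------------------------------------------------------------
# Imaging route
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory rendered dataset: mask fields plus ground-truth polygons."""

    spec: SyntheticSpec
    fields: list[FieldFiles] = field(repr=False)
    ground_truth: pd.DataFrame = field(repr=False)


def _place_centres(
    radii_px: list[float], shape: tuple[int, int], rng: np.random.Generator, context: str
) -> list[tuple[float, float]]:
    centres: list[tuple[float, float]] = []
    for i, r in enumerate(radii_px):
        margin = r + 3.0
        if 2 * margin >= min(shape):
            raise CapacityError(f"{context}: object radius {r:.0f} px exceeds raster")
        for _ in range(400):
            cand = (
                rng.uniform(margin, shape[0] - 1 - margin),
                rng.uniform(margin, shape[1] - 1 - margin),
            )
            if all(
                math.hypot(cand[0] - c[0], cand[1] - c[1]) > r + radii_px[j] + 3.0
                for j, c in enumerate(centres)
            ):
                centres.append(cand)
                break
        else:
            raise CapacityError(
                f"{context}: could not place object {i + 1}/{len(radii_px)} "
                f"in a {shape} raster after 400 attempts"
            )
    return centres


def generate_dataset(
    spec: SyntheticSpec,
    out_dir=None,
    rng: Optional[np.random.Generator] = None,
) -> SyntheticDataset:
    """Render label-mask fields plus a ground-truth measurement table.

    Per case: a case-level cell area and nucleus fraction are drawn from
    the group model, then each field receives 5–7 cells whose areas jitter
    around the case level by ``cell_cv``.  Cells are placed without overlap
    or border contact; the ground truth records each placed polygon's true
    shoelace area and length in µm.  Deterministic given ``spec.seed``.

    If ``out_dir`` is given, masks (16-bit TIFF), sidecar JSONs,
    ``ground_truth.csv`` and a ``manifest.json`` with the full spec are
    written there.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mpp = spec.microns_per_pixel
    cal = spec.calibration
    fields_out: list[FieldFiles] = []
    gt_rows: list[dict] = []
    counter = [0, 0]
    for g in spec.groups:
        for i in range(g.n_cases):
            case_id = f"syn-{g.group}-{i + 1:03d}"
            case_ca, case_na = _draw_case_sizes(g, rng, counter)
            frac = float(
                np.clip(
                    rng.normal(g.nucleus_fraction_mean, g.nucleus_fraction_sd), 0.05, 0.85
                )
            )
            n_fields = int(rng.integers(spec.fields_per_case[0], spec.fields_per_case[1] + 1))
            for fi in range(n_fields):
                n_cells = int(
                    rng.integers(spec.cells_per_field[0], spec.cells_per_field[1] + 1)
                )
                polys = []
                for _ in range(n_cells):
                    area = case_ca * max(1.0 + rng.normal(0.0, spec.cell_cv), 0.2)
                    polys.append(
                        render_cell(
                            area,
                            g.cell_irregularity,
                            frac,
                            rng,
                            nuclear_irregularity=g.nuclear_irregularity,
                        )
                    )
                radii_px = [np.linalg.norm(cell, axis=1).max() / mpp for cell, _ in polys]
                centres = _place_centres(
                    radii_px, spec.raster_shape, rng, f"case {case_id} field {fi}"
                )
                cell_mask = np.zeros(spec.raster_shape, dtype=np.uint16)
                nuc_mask = np.zeros(spec.raster_shape, dtype=np.uint16)
                for lab, ((cell, nuc), ctr) in enumerate(zip(polys, centres), start=1):
                    for poly, target in ((cell, cell_mask), (nuc, nuc_mask)):
                        px = poly / mpp + np.asarray(ctr)
                        rr, cc = skdraw.polygon(px[:, 0], px[:, 1], spec.raster_shape)
                        target[rr, cc] = lab
                    gt_rows.append(
                        {
                            "case_id": case_id,
                            "group": g.group,
                            "field_index": fi,
                            "label": lab,
                            "cell_area": _shoelace(cell),
                            "cell_perimeter": _perimeter(cell),
                            "nuclear_area": _shoelace(nuc),
                            "nuclear_perimeter": _perimeter(nuc),
                        }
                    )
                pair = LabelMaskPair(
                    cell_mask=cell_mask, nucleus_mask=nuc_mask, calibration=cal
                )
                fields_out.append(
                    FieldFiles(case_id=case_id, group=g.group, field_index=fi, pair=pair)
                )
    ground_truth = pd.DataFrame(gt_rows)
    dataset = SyntheticDataset(spec=spec, fields=fields_out, ground_truth=ground_truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for ff in fields_out:
            write_field(out_dir, ff.case_id, ff.group, ff.field_index, ff.pair)
        ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, float_format="%.6f")
        manifest = {"spec": asdict(spec), "seed": spec.seed}
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return dataset
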