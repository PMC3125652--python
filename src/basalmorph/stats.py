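"""Inferential statistics for the three-group morphometry comparison.

Implements the classical toolkit applied to per-case records: fixed-effects
one-way ANOVA with the full sum-of-squares decomposition, the pooled-
variance two-sample Student t (the design's degrees of freedom, 38 for
30-vs-10 and 58 for 30-vs-30, force the pooled rather than Welch form),
the Mann–Whitney U test under the large-sample normal approximation with
tie-corrected variance, and the Kruskal–Wallis H test with tie correction.

Statistics are computed on per-case records (one row per case), never on
per-cell measurements.  p-values come from the corresponding reference
distributions in :mod:`scipy.stats`; everything else is computed here so
the implementation can be cross-checked against independent library
routines in the test suite.

Notes on conventions
--------------------
* t statistics are reported as magnitudes with two-sided p-values.
* The Mann–Whitney Z uses no continuity correction by default (set
  ``continuity=True`` for the corrected variant); the tie correction
  subtracts ``Σ(τ³ − τ)/((N)(N − 1))`` from the variance factor.
* A "Cytoplasm" comparison in this pipeline's area reports means the
  whole-cell area, not cell minus nucleus — recomputation shows the
  published per-case data reproduce the reference t values only on
  whole-cell area (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import morphometry as mm
from .morphometry import (
    CIRCLE_PI,
    GroupSummary,
    InsufficientDataError,
    MeasurementRecord,
    MorphometryError,
)

__all__ = [
    "AnovaTable",
    "TestResult",
    "DegenerateDataError",
    "one_way_anova",
    "t_test_pooled",
    "mann_whitney",
    "kruskal_wallis",
    "run_full_comparison",
    "ComparisonReport",
    "write_report",
    "format_p",
]

#: Variables analysed by the full comparison, in report order.
ANALYSIS_VARIABLES: tuple[str, ...] = (
    "nuclear_area",
    "cell_area",
    "nuclear_form_pe",
    "cellular_form_pe",
    "nuclear_ci",
    "cellular_ci",
    "nc_ratio",
)

#: Pairwise comparisons in report order (matches the published layout).
PAIRS: tuple[tuple[str, str], ...] = (
    ("leukoplakia", "normal"),
    ("scc", "normal"),
    ("leukoplakia", "scc"),
)


class DegenerateDataError(MorphometryError):
    """The data admit no variance, so the test statistic is undefined."""


class ConfigurationError(MorphometryError):
    """The comparison cannot be set up from the provided records."""


@dataclass(frozen=True)
class AnovaTable:
    """Fixed-effects one-way ANOVA decomposition.

    Invariants: ``between_ss + within_ss = total_ss``,
    ``df_between + df_within = df_total``, ``ms = ss/df`` and
    ``f_ratio = ms_between/ms_within``.
    """

    between_ss: float
    within_ss: float
    total_ss: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_ratio: float
    p_value: float


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test outcome (statistic, df where defined, p)."""

    test: str
    comparison: str
    statistic: float
    p_value: float
    df: Optional[float] = None
    alternative: str = "two-sided"
    details: dict = field(default_factory=dict)


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def one_way_anova(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None
) -> AnovaTable:
    """Fixed-effects one-way ANOVA across ``k ≥ 2`` groups.

    The p-value is the upper tail of F(df_between, df_within).
    """
    arrs = _as_groups(groups)
    if len(arrs) < 2:
        raise InsufficientDataError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrs):
        raise InsufficientDataError("every ANOVA group needs at least two observations")
    allv = np.concatenate(arrs)
    grand = allv.mean()
    between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrs))
    within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b = len(arrs) - 1
    df_w = len(allv) - len(arrs)
    if within <= 0:
        raise DegenerateDataError("zero within-group variance; F ratio undefined")
    ms_b = between / df_b
    ms_w = within / df_w
    f_ratio = ms_b / ms_w
    return AnovaTable(
        between_ss=between,
        within_ss=within,
        total_ss=between + within,
        df_between=df_b,
        df_within=df_w,
        df_total=df_b + df_w,
        ms_between=ms_b,
        ms_within=ms_w,
        f_ratio=f_ratio,
        p_value=float(_sps.f.sf(f_ratio, df_b, df_w)),
    )


def t_test_pooled(a: Sequence[float], b: Sequence[float], comparison: str = "") -> TestResult:
    """Pooled-variance two-sample Student t, df = n₁ + n₂ − 2, two-sided.

    The statistic is reported as a magnitude.
    """
    x, y = np.asarray(a, float), np.asarray(b, float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each sample needs at least two observations")
    df = len(x) + len(y) - 2
    pooled = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if pooled <= 0:
        raise DegenerateDataError("zero pooled variance; t undefined")
    t = (x.mean() - y.mean()) / math.sqrt(pooled * (1 / len(x) + 1 / len(y)))
    return TestResult(
        test="t_pooled",
        comparison=comparison,
        statistic=abs(float(t)),
        df=df,
        p_value=float(2.0 * _sps.t.sf(abs(t), df)),
        details={"t_signed": float(t)},
    )


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney(
    a: Sequence[float], b: Sequence[float], comparison: str = "", continuity: bool = False
) -> TestResult:
    """Mann–Whitney U with normal approximation and tie-corrected variance.

    ``U`` counts pairs won by the first sample (plus half-ties).  The
    reported statistic is |Z|; ``details`` carries U and the signed Z.  No
    continuity correction is applied unless requested.
    """
    x, y = np.asarray(a, float), np.asarray(b, float)
    if len(x) < 1 or len(y) < 1:
        raise InsufficientDataError("each sample needs at least one observation")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = _sps.rankdata(np.concatenate([x, y]))
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(np.concatenate([x, y])) / (n * (n - 1)))
    if var <= 0:
        raise DegenerateDataError("all observations tied; Mann-Whitney Z undefined")
    delta = u - mu
    if continuity and delta != 0:
        delta -= 0.5 * math.copysign(1.0, delta)
    z = delta / math.sqrt(var)
    return TestResult(
        test="mann_whitney",
        comparison=comparison,
        statistic=abs(z),
        p_value=float(2.0 * _sps.norm.sf(abs(z))),
        details={"U": u, "z_signed": z, "continuity": continuity},
    )


def kruskal_wallis(
    groups: Sequence[Sequence[float]], comparison: str = ""
) -> TestResult:
    """Kruskal–Wallis H with tie correction; p from χ²(k − 1)."""
    arrs = _as_groups(groups)
    if len(arrs) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs at least two groups")
    allv = np.concatenate(arrs)
    n = len(allv)
    if n < len(arrs) + 1:
        raise InsufficientDataError("too few observations for Kruskal-Wallis")
    ranks = _sps.rankdata(allv)
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum() ** 2 / len(r) for r in np.split(ranks, np.cumsum([len(a) for a in arrs]))[:-1]
    ) - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(allv) / (n**3 - n)
    if correction <= 0:
        raise DegenerateDataError("all observations identical; H undefined")
    h /= correction
    df = len(arrs) - 1
    return TestResult(
        test="kruskal_wallis",
        comparison=comparison,
        statistic=float(h),
        df=df,
        p_value=float(_sps.chi2.sf(h, df)),
    )


def format_p(p: float) -> str:
    """Render a p-value the way the reference reports print it."""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


# ---------------------------------------------------------------------------
# Full comparison bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonReport:
    """All tables of the three-group comparison for every variable."""

    summaries: list[GroupSummary]
    anova: dict[str, AnovaTable]
    t_tests: dict[str, list[TestResult]]
    mann_whitney: dict[str, list[TestResult]]
    kruskal: dict[str, TestResult]
    alpha: float = 0.05

    def significant(self, result) -> bool:
        return result.p_value <= self.alpha


def run_full_comparison(
    records: Iterable[MeasurementRecord],
    circle_constant: float = CIRCLE_PI,
    alpha: float = 0.05,
    continuity: bool = False,
) -> ComparisonReport:
    """Group summaries, ANOVA, pairwise pooled t, pairwise Mann–Whitney and
    Kruskal–Wallis for every analysis variable.

    Requires all three diagnostic groups to be present.
    """
    records = list(records)
    present = sorted({r.group for r in records})
    missing = [g for g in mm.GROUPS if g not in present]
    if missing:
        raise ConfigurationError(
            f"missing diagnostic group(s) {missing}; present: {present}"
        )
    by_group = {g: [r for r in records if r.group == g] for g in mm.GROUPS}
    values = {
        (g, v): mm.variable_values(by_group[g], v, circle_constant)
        for g, v in itertools.product(mm.GROUPS, ANALYSIS_VARIABLES)
    }

    summaries = [
        mm.summarize(records, g, v, circle_constant)
        for v in mm.MEASURED_VARIABLES + mm.DESCRIPTOR_VARIABLES
        for g in mm.GROUPS
    ]

    anova: dict[str, AnovaTable] = {}
    t_tests: dict[str, list[TestResult]] = {}
    mw: dict[str, list[TestResult]] = {}
    kw: dict[str, TestResult] = {}
    for v in ANALYSIS_VARIABLES:
        grouped = [values[(g, v)] for g in mm.GROUPS]
        anova[v] = one_way_anova(grouped)
        t_tests[v] = [
            t_test_pooled(values[(a, v)], values[(b, v)], comparison=f"{a} vs {b}")
            for a, b in PAIRS
        ]
        mw[v] = [
            mann_whitney(
                values[(a, v)], values[(b, v)], comparison=f"{a} vs {b}", continuity=continuity
            )
            for a, b in PAIRS
        ]
        kw[v] = kruskal_wallis(grouped, comparison="all groups")
    return ComparisonReport(
        summaries=summaries, anova=anova, t_tests=t_tests, mann_whitney=mw, kruskal=kw, alpha=alpha
    )


def _anova_frame(report: ComparisonReport, variables: Sequence[str]) -> pd.DataFrame:
    rows = []
    for v in variables:
        a = report.anova[v]
        rows += [
            {
                "variable": v,
                "source_of_variation": "between_groups",
                "sum_of_squares": a.between_ss,
                "df": a.df_between,
                "mean_square": a.ms_between,
                "f_ratio": a.f_ratio,
                "p_value": format_p(a.p_value),
            },
            {
                "variable": v,
                "source_of_variation": "within_groups",
                "sum_of_squares": a.within_ss,
                "df": a.df_within,
                "mean_square": a.ms_within,
                "f_ratio": "",
                "p_value": "",
            },
            {
                "variable": v,
                "source_of_variation": "total",
                "sum_of_squares": a.total_ss,
                "df": a.df_total,
                "mean_square": "",
                "f_ratio": "",
                "p_value": "",
            },
        ]
    return pd.DataFrame(rows)


def _result_dict(r: TestResult) -> dict:
    d = {
        "test": r.test,
        "comparison": r.comparison,
        "statistic": r.statistic,
        "df": r.df,
        "p_value": r.p_value,
        "alternative": r.alternative,
    }
    d.update({k: v for k, v in r.details.items()})
    return d


def write_report(report: ComparisonReport, out_dir) -> None:
    """Serialise the bundle: one CSV per table plus a full-precision JSON.

    CSV layouts mirror the published tables: descriptive summaries, the
    area ANOVAs, the area t-tests, the form-PE / contour-index / N:C
    ANOVAs, and the rank tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(s) for s in report.summaries]).to_csv(
        out / "summaries.csv", index=False
    )
    _anova_frame(report, ["nuclear_area", "cell_area"]).to_csv(
        out / "anova_areas.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "variable": v,
                "comparison": t.comparison,
                "t_value": t.statistic,
                "df": int(t.df),
                "p_value": format_p(t.p_value),
            }
            for v in ("nuclear_area", "cell_area")
            for t in report.t_tests[v]
        ]
    ).to_csv(out / "ttests_areas.csv", index=False)
    _anova_frame(report, ["nuclear_form_pe", "cellular_form_pe"]).to_csv(
        out / "anova_form_pe.csv", index=False
    )
    _anova_frame(report, ["nuclear_ci", "cellular_ci"]).to_csv(
        out / "anova_contour_index.csv", index=False
    )
    _anova_frame(report, ["nc_ratio"]).to_csv(out / "anova_nc_ratio.csv", index=False)
    rank_rows = []
    for v in ANALYSIS_VARIABLES:
        for r in report.mann_whitney[v]:
            rank_rows.append(
                {
                    "variable": v,
                    "test": r.test,
                    "comparison": r.comparison,
                    "statistic": r.statistic,
                    "df": "",
                    "p_value": format_p(r.p_value),
                }
            )
        k = report.kruskal[v]
        rank_rows.append(
            {
                "variable": v,
                "test": k.test,
                "comparison": k.comparison,
                "statistic": k.statistic,
                "df": int(k.df),
                "p_value": format_p(k.p_value),
            }
        )
    pd.DataFrame(rank_rows).to_csv(out / "rank_tests.csv", index=False)

    doc = {
        "alpha": report.alpha,
        "summaries": [vars(s) for s in report.summaries],
        "anova": {
            v: {k: getattr(a, k) for k in vars(a)} for v, a in report.anova.items()
        },
        "t_tests": {v: [_result_dict(t) for t in ts] for v, ts in report.t_tests.items()},
        "mann_whitney": {
            v: [_result_dict(t) for t in ts] for v, ts in report.mann_whitney.items()
        },
        "kruskal_wallis": {v: _result_dict(k) for v, k in report.kruskal.items()},
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
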