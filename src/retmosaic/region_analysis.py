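"""Equator/midline partitioning and p+OC enrichment via repeated G-tests.

Each retina is split into dorsal and ventral halves at the equator (a
mirror line lying between two ommatidial rows) and, independently, into
anterior and posterior halves at the centre-most dorso-ventral column.
Enrichment of pale (p+OC) ommatidia in a half is expressed as the
deviation of that half's p+OC percentage from the whole-retina
percentage, and tested with G-tests of the region x type (p+OC vs y)
table.  Replicate retinas of one (strain, sex) group are combined with
the repeated-G decomposition:

    G_total   = sum of the individual G statistics        (df = k)
    G_pooled  = G of the element-wise summed table        (df = 1)
    G_het     = G_total - G_pooled                        (df = k - 1)

so that heterogeneity among replicates can be screened before reading
the pooled test.  DRA and UNKNOWN ommatidia never enter region tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .mosaic_model import (
    DRA,
    P_OC,
    RetinalMosaicMap,
    TypeCounts,
    UNKNOWN,
    UndefinedValueError,
    Y,
    count_types,
    percent_p_oc,
)

Axis = Literal["dorsoventral", "anteroposterior"]

DV_LABELS = ("dorsal", "ventral")
AP_LABELS = ("anterior", "posterior", "midline")


class ConfigurationError(ValueError):
    """A map lacks the annotation required for the requested partition."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero marginal; the G-test is undefined."""


@dataclass
class RegionPartition:
    """Per-ommatidium region labels for one partition axis.

    Dorso-ventral labels are exhaustive (every ommatidium is dorsal or
    ventral); for the antero-posterior axis, ommatidia on the midline
    column are labelled ``midline`` and excluded from both halves.
    """

    axis: Axis
    labels: np.ndarray  # one label per ommatidium, aligned with the map

    def regions(self) -> tuple[str, ...]:
        return DV_LABELS if self.axis == "dorsoventral" else AP_LABELS[:2]


@dataclass(frozen=True)
class GTestResult:
    """A single G statistic with its degrees of freedom and p-value."""

    g: float
    df: int
    p: float


@dataclass
class RepeatedGTestResult:
    """Individual / pooled / heterogeneity / total G decomposition."""

    individual: list[GTestResult]
    pooled: GTestResult
    heterogeneity: GTestResult
    total: GTestResult

    @property
    def heterogeneity_significant(self) -> bool:
        """Flag raised when replicates disagree (p < 0.05); read the
        pooled test with caution in that case."""
        return self.heterogeneity.p < 0.05


def partition(mosaic: RetinalMosaicMap, axis: Axis) -> RegionPartition:
    """Label every ommatidium by its side of the equator or midline."""
    if axis == "dorsoventral":
        if mosaic.equator_boundary is None:  # pragma: no cover - enforced upstream
            raise ConfigurationError("map has no equator_boundary annotation")
        eq = mosaic.equator_boundary
        labels = np.array(
            ["dorsal" if o.row > eq else "ventral" for o in mosaic.ommatidia]
        )
    elif axis == "anteroposterior":
        if mosaic.midline_col is None:  # pragma: no cover
            raise ConfigurationError("map has no midline_col annotation")
        mid = mosaic.midline_col
        labels = np.array(
            [
                "anterior" if o.col < mid else ("posterior" if o.col > mid else "midline")
                for o in mosaic.ommatidia
            ]
        )
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return RegionPartition(axis=axis, labels=labels)


def region_type_counts(
    mosaic: RetinalMosaicMap, part: RegionPartition, region: str
) -> tuple[int, int]:
    """(n_p_oc, n_y) within one region; DRA/UNKNOWN excluded."""
    types = mosaic.types()
    in_region = part.labels == region
    n_p = int(np.sum(in_region & (types == P_OC)))
    n_y = int(np.sum(in_region & (types == Y)))
    return n_p, n_y


def region_table(
    mosaic: RetinalMosaicMap, part: RegionPartition
) -> np.ndarray:
    """2x2 table: rows = the two halves, cols = (p+OC, y)."""
    rows = [region_type_counts(mosaic, part, r) for r in part.regions()]
    return np.array(rows, dtype=int)


def region_enrichment(
    mosaic: RetinalMosaicMap,
    part: RegionPartition,
    region: str | None = None,
) -> float | dict[str, float]:
    """Deviation of a region's p+OC percentage from the whole retina's.

    The whole-retina reference is the p+OC percentage over all non-DRA,
    typed ommatidia of the map, so dorso-ventral and antero-posterior
    deviations of the same retina share one reference.  With
    ``region=None`` a dict over both halves is returned.
    """
    whole = percent_p_oc(count_types(mosaic))

    def one(r: str) -> float:
        n_p, n_y = region_type_counts(mosaic, part, r)
        if n_p + n_y == 0:
            raise UndefinedValueError(f"region {r!r} holds no typed ommatidia")
        return 100.0 * n_p / (n_p + n_y) - whole

    if region is not None:
        return one(region)
    return {r: one(r) for r in part.regions()}


def _g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """2 * sum O ln(O/E); zero observed cells contribute 0."""
    o = observed.astype(float).ravel()
    e = expected.astype(float).ravel()
    mask = o > 0
    return float(2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask])))


def g_test_2x2(
    table: np.ndarray | Sequence[Sequence[int]],
    williams: bool = False,
    expected_ratio: float | None = None,
) -> GTestResult:
    """G-test of a 2x2 region x type table.

    By default expectations come from the table's own row and column
    marginals (independence / intrinsic hypothesis, df = 1).  With
    ``expected_ratio`` set (a p+OC proportion in (0,1)), each row is
    instead tested against that fixed extrinsic ratio (df = 1 per row,
    2 total) -- a sensitivity variant for when the reference proportion
    comes from outside the table.  ``williams=True`` applies the
    Williams small-sample correction to the independence G.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if expected_ratio is None:
        if (row == 0).any() or (col == 0).any():
            raise DegenerateTableError("zero marginal in 2x2 table")
        expected = np.outer(row, col) / n
        g = _g_statistic(t, expected)
        df = 1
        if williams:
            q = 1.0 + ((n / row).sum() - 1.0) * ((n / col).sum() - 1.0) / (6.0 * n)
            g /= q
    else:
        if not (0.0 < expected_ratio < 1.0):
            raise ValueError("expected_ratio must be in (0,1)")
        if (row == 0).any():
            raise DegenerateTableError("empty region row in 2x2 table")
        expected = np.column_stack(
            [row * expected_ratio, row * (1.0 - expected_ratio)]
        )
        g = _g_statistic(t, expected)
        df = 2
    p = float(stats.chi2.sf(g, df)) if g > 0 else 1.0
    return GTestResult(g=g, df=df, p=p)


def repeated_g_test(
    tables: Sequence[np.ndarray],
    williams: bool = False,
    table_ids: Sequence | None = None,
) -> RepeatedGTestResult:
    """Repeated G-tests over replicate retinas of one (strain, sex) group.

    Each table is one retina's region x type 2x2 table.  Degenerate
    tables abort with an error naming the offending replicates (by
    ``table_ids`` if given, else by position).
    """
    if len(tables) < 2:
        raise ValueError("repeated G-test needs at least 2 tables")
    ids = list(table_ids) if table_ids is not None else list(range(len(tables)))
    bad = []
    arrs = []
    for i, t in zip(ids, tables):
        t = np.asarray(t, dtype=float)
        arrs.append(t)
        if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
            bad.append(i)
    if bad:
        raise DegenerateTableError(f"degenerate table(s) for retina id(s) {bad}")
    individual = [g_test_2x2(t, williams=williams) for t in arrs]
    k = len(arrs)
    pooled = g_test_2x2(np.sum(arrs, axis=0), williams=williams)
    g_total = float(sum(r.g for r in individual))
    total = GTestResult(g=g_total, df=k, p=float(stats.chi2.sf(g_total, k)))
    g_het = g_total - pooled.g
    het = GTestResult(
        g=g_het, df=k - 1, p=float(stats.chi2.sf(max(g_het, 0.0), k - 1))
    )
    return RepeatedGTestResult(
        individual=individual, pooled=pooled, heterogeneity=het, total=total
    )
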