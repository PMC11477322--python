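"""Cross-species and cross-gene codon-usage comparisons.

Covers the pooled-gene RSCU table, high/low-frequency codon classification
and the two-gene intersection, the ENC-ranked expression grouping with
delta-RSCU optimal-codon calling, and parity-rule-2 (PR2) coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import GeneticCode, standard_code
from .indices import (
    CodonCounts,
    RscuTable,
    SilentSiteComposition,
    count_codons,
    rscu,
)
from .io import CdsSet


@dataclass(frozen=True)
class CodonSetComparison:
    """High- (RSCU > 1) and low-frequency (RSCU < 1) codon sets of two
    usage tables and their intersections. A codon at exactly 1 belongs to
    neither set."""

    high_a: frozenset[str]
    high_b: frozenset[str]
    low_a: frozenset[str]
    low_b: frozenset[str]

    @property
    def shared_high(self) -> frozenset[str]:
        return self.high_a & self.high_b

    @property
    def shared_low(self) -> frozenset[str]:
        return self.low_a & self.low_b


@dataclass(frozen=True)
class DeltaRscuResult:
    """Optimal-codon call from ENC-ranked expression groups.

    delta maps each codon to mean(high-group RSCU) - mean(low-group RSCU);
    a codon is optimal when delta >= threshold, its high-group mean exceeds
    1 and its low-group mean is below 1.
    """

    high_group: tuple[str, ...]
    low_group: tuple[str, ...]
    rscu_high: RscuTable
    rscu_low: RscuTable
    delta: Mapping[str, float]
    optimal_codons: tuple[str, ...]
    threshold: float


@dataclass(frozen=True)
class Pr2Point:
    """PR2 plane coordinates for one species: x = A3/(A3+T3),
    y = G3/(G3+C3), both undefined (NaN) on a zero denominator."""

    species: str
    x: float
    y: float

    CENTER = (0.5, 0.5)

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.x) or math.isnan(self.y))


def pooled_rscu(cds_set: CdsSet, code: GeneticCode | None = None) -> RscuTable:
    """RSCU of the codon counts summed across every species in the set."""
    code = code or standard_code()
    pooled = CodonCounts.pooled(
        (count_codons(r, code) for r in cds_set), source=f"pooled/{cds_set.gene}"
    )
    return rscu(pooled, code, scope="pooled_gene")


def frequency_classes(
    table: RscuTable, precision: int | None = None
) -> tuple[frozenset[str], frozenset[str]]:
    """Split codons into high (RSCU > 1) and low (RSCU < 1) sets.

    ``precision`` rounds values (half-even) before comparison, for
    reproducing classifications made from printed tables.
    """
    high, low = set(), set()
    for codon, v in table.values.items():
        if math.isnan(v):
            continue
        if precision is not None:
            v = round(v, precision)
        if v > 1:
            high.add(codon)
        elif v < 1:
            low.add(codon)
    return frozenset(high), frozenset(low)


def shared_codons(
    a: RscuTable, b: RscuTable, precision: int | None = None
) -> CodonSetComparison:
    """High/low sets of two usage tables and their intersections."""
    high_a, low_a = frequency_classes(a, precision)
    high_b, low_b = frequency_classes(b, precision)
    return CodonSetComparison(high_a=high_a, high_b=high_b, low_a=low_a, low_b=low_b)


def rank_expression_groups(
    indices: pd.DataFrame, g: int = 5
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """ENC-ranked expression groups of size g: (high_expression, low_expression).

    Species are sorted by Nc descending (ties broken by label); the first g
    (largest ENC, weakest bias) form the low-expression group and the last g
    (smallest ENC, strongest bias) the high-expression group.
    """
    nc = indices["Nc"].dropna()
    if 2 * g > len(nc):
        raise ValueError(f"need at least {2 * g} species with defined Nc, have {len(nc)}")
    order = sorted(nc.index, key=lambda s: (-nc[s], s))
    low = tuple(order[:g])
    high = tuple(order[-g:][::-1])
    return high, low


def group_mean_rscu(tables: Mapping[str, RscuTable], members: Sequence[str]) -> RscuTable:
    """Arithmetic mean of per-species RSCU over the group members.

    Codons undefined for a species (absent family) are skipped in that
    codon's mean; family sums need not equal the family size for this scope.
    """
    missing = [s for s in members if s not in tables]
    if missing:
        raise KeyError(f"no per-species RSCU for: {', '.join(missing)}")
    codons = list(next(iter(tables.values())).values)
    values = {}
    for c in codons:
        vals = [tables[s].values[c] for s in members]
        vals = [v for v in vals if not math.isnan(v)]
        values[c] = float(np.mean(vals)) if vals else math.nan
    return RscuTable(scope="group_mean", values=values)


def delta_rscu(
    per_species_rscu: Mapping[str, RscuTable],
    high: Sequence[str],
    low: Sequence[str],
    threshold: float = 0.08,
) -> DeltaRscuResult:
    """Call optimal codons from the high/low expression-group RSCU means."""
    rscu_high = group_mean_rscu(per_species_rscu, high)
    rscu_low = group_mean_rscu(per_species_rscu, low)
    delta = {
        c: rscu_high.values[c] - rscu_low.values[c] for c in rscu_high.values
    }
    optimal = tuple(
        c
        for c in sorted(delta)
        if not math.isnan(delta[c])
        and delta[c] >= threshold
        and rscu_high.values[c] > 1
        and rscu_low.values[c] < 1
    )
    return DeltaRscuResult(
        high_group=tuple(high),
        low_group=tuple(low),
        rscu_high=rscu_high,
        rscu_low=rscu_low,
        delta=delta,
        optimal_codons=optimal,
        threshold=threshold,
    )


def pr2_coordinates(
    compositions: Mapping[str, SilentSiteComposition] | pd.DataFrame,
) -> list[Pr2Point]:
    """PR2 points per species.

    Accepts either silent-site compositions or an index table with
    T3s/C3s/A3s/G3s columns (fractions or percentages; the coordinates are
    ratios, so the scale cancels).
    """
    points = []
    if isinstance(compositions, pd.DataFrame):
        items = (
            (sp, row["A3s"], row["T3s"], row["G3s"], row["C3s"])
            for sp, row in compositions.iterrows()
        )
    else:
        items = (
            (sp, c.a3s, c.t3s, c.g3s, c.c3s) for sp, c in compositions.items()
        )
    for sp, a3, t3, g3, c3 in items:
        x = a3 / (a3 + t3) if (a3 + t3) > 0 else math.nan
        y = g3 / (g3 + c3) if (g3 + c3) > 0 else math.nan
        points.append(Pr2Point(species=sp, x=float(x), y=float(y)))
    return points


def pr2_summary(points: Sequence[Pr2Point]) -> dict:
    """Mean coordinates and quadrant occupancy around the (0.5, 0.5) center."""
    defined = [p for p in points if p.defined]
    if not defined:
        raise ValueError("no defined PR2 points")
    xs = np.array([p.x for p in defined])
    ys = np.array([p.y for p in defined])
    on_boundary = (xs == 0.5) | (ys == 0.5)
    quadrants = {
        "A_rich_G_rich": int(np.sum((xs > 0.5) & (ys > 0.5))),
        "A_rich_C_rich": int(np.sum((xs > 0.5) & (ys < 0.5))),
        "T_rich_G_rich": int(np.sum((xs < 0.5) & (ys > 0.5))),
        "T_rich_C_rich": int(np.sum((xs < 0.5) & (ys < 0.5))),
    }
    return {
        "mean_x": float(xs.mean()),
        "mean_y": float(ys.mean()),
        "n_defined": len(defined),
        "n_boundary": int(on_boundary.sum()),
        "quadrant_counts": quadrants,
    }
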