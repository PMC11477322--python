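"""Per-sequence codon-usage indices.

The battery computed here mirrors the classic CodonW column set: silent-site
base composition (T3s/C3s/A3s/G3s, GC3s), overall GC, the effective number of
codons (ENC; Wright's estimator), the codon adaptation index (CAI; Sharp &
Li's geometric mean of relative adaptiveness weights), the codon bias index
(CBI; Bennetzen & Hall), the frequency of optimal codons (Fop), protein mean
hydropathy (Gravy; Kyte-Doolittle) and aromaticity (Aromo), plus the codon
counts L_sym and L_aa.

Conventions shared by every statistic: a single terminal stop codon never
enters any count; Met (AUG) and Trp (UGG) carry no synonymous choice and are
excluded from RSCU, CAI, CBI/Fop and silent-site composition; six-fold amino
acids (Leu, Ser, Arg) are treated as single six-codon families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.SeqUtils import ProtParamData

from .genetics import GeneticCode, SINGLE_CODON_AA, standard_code
from .io import CdsRecord, CdsSet, sense_codons, translate

INDEX_COLUMNS = [
    "T3s", "C3s", "A3s", "G3s", "CAI", "CBI", "Fop",
    "Nc", "GC3s", "GC", "L_sym", "L_aa", "Gravy", "Aromo",
]

AROMATIC = frozenset("FYW")


class IndexError_(ValueError):
    """Raised when an index is undefined for the given input."""


@dataclass(frozen=True)
class CodonCounts:
    """Occurrence counts over the sense codons for one sequence or a pool."""

    counts: Mapping[str, int]
    source: str = "unknown"

    @property
    def total_codons(self) -> int:
        return int(sum(self.counts.values()))

    def get(self, codon: str) -> int:
        return int(self.counts.get(codon, 0))

    def family_total(self, family: Iterable[str]) -> int:
        return sum(self.get(c) for c in family)

    @classmethod
    def pooled(cls, many: Iterable["CodonCounts"], source: str = "pooled") -> "CodonCounts":
        acc: dict[str, int] = {}
        for cc in many:
            for codon, n in cc.counts.items():
                acc[codon] = acc.get(codon, 0) + int(n)
        return cls(counts=acc, source=source)


@dataclass(frozen=True)
class RscuTable:
    """RSCU values over the degenerate sense codons (59 under table 1).

    ``scope`` is ``per_sequence``, ``pooled_gene`` or ``group_mean``; only the
    first two satisfy the family-sum identity (sum of RSCU over a family
    equals the family size). Families absent from the input have undefined
    RSCU, stored as NaN.
    """

    scope: str
    values: Mapping[str, float]
    counts: Mapping[str, int] | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.values), name="rscu")


@dataclass(frozen=True)
class SilentSiteComposition:
    """Third-position base fractions over silent sites, plus overall GC.

    Silent sites are third positions of codons whose amino acid has at least
    two synonyms (AUG, UGG and stops excluded). All four fractions share that
    denominator, so they sum to one; GC3s = C3s + G3s. ``gc`` is the G+C
    fraction over every position of all counted codons.
    """

    t3s: float
    c3s: float
    a3s: float
    g3s: float
    gc: float
    n_silent_sites: int

    @property
    def gc3s(self) -> float:
        return self.c3s + self.g3s


@dataclass(frozen=True)
class EncBreakdown:
    """Wright's ENC with the per-fold-class mean homozygosities behind it."""

    f_bar: Mapping[int, float]
    n_families_observed: Mapping[int, int]
    nc: float


@dataclass(frozen=True)
class CaiReference:
    """Relative adaptiveness weights w for CAI.

    Within every synonymous family the most-used reference codon has w = 1;
    AUG and UGG have w = 1 by convention but never enter the geometric mean.
    Reference codons unobserved in the source data are floored at
    ``zero_floor`` rather than given w = 0, so CAI stays finite.
    """

    weights: Mapping[str, float]
    provenance: str = "custom"
    zero_floor: float = 0.01

    @classmethod
    def from_counts(
        cls,
        counts: CodonCounts,
        code: GeneticCode | None = None,
        provenance: str = "derived_from_counts",
        zero_floor: float = 0.01,
    ) -> "CaiReference":
        code = code or standard_code()
        weights: dict[str, float] = {}
        for aa, family in code.families.items():
            if aa in SINGLE_CODON_AA:
                weights[family[0]] = 1.0
                continue
            fam_counts = [counts.get(c) for c in family]
            top = max(fam_counts)
            if top == 0:
                # family absent from the reference: uninformative, all w = 1
                for c in family:
                    weights[c] = 1.0
                continue
            for c, n in zip(family, fam_counts):
                weights[c] = max(n / top, zero_floor)
        return cls(weights=weights, provenance=provenance, zero_floor=zero_floor)

    @classmethod
    def from_weights(
        cls, weights: Mapping[str, float], provenance: str = "custom"
    ) -> "CaiReference":
        return cls(weights=dict(weights), provenance=provenance)


# ---------------------------------------------------------------------------
# elementary counts
# ---------------------------------------------------------------------------

def count_codons(record: CdsRecord, code: GeneticCode | None = None) -> CodonCounts:
    """Count sense codons of a validated record (terminal stop excluded)."""
    code = code or standard_code()
    codons = sense_codons(record, code)
    if not codons:
        raise IndexError_(f"no codons: {record.species}")
    counts: dict[str, int] = {}
    for codon in codons:
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, source=f"{record.species}/{record.gene}")


def rscu(counts: CodonCounts, code: GeneticCode | None = None,
         scope: str = "per_sequence") -> RscuTable:
    """Relative synonymous codon usage: observed over uniform-expected counts.

    For codon i of an amino acid with Ni synonyms observed G_ij times,
    RSCU = Ni * G_ij / sum_j G_ij. Families with zero observations yield NaN
    (undefined, not zero). Only degenerate families are reported.
    """
    code = code or standard_code()
    values: dict[str, float] = {}
    out_counts: dict[str, int] = {}
    for aa, family in code.degenerate_families.items():
        ni = len(family)
        tot = counts.family_total(family)
        for c in family:
            out_counts[c] = counts.get(c)
            values[c] = ni * counts.get(c) / tot if tot > 0 else math.nan
    return RscuTable(scope=scope, values=values, counts=out_counts)


def silent_composition(
    record: CdsRecord, code: GeneticCode | None = None
) -> SilentSiteComposition:
    """Third-position composition over silent sites, and overall GC."""
    code = code or standard_code()
    codons = sense_codons(record, code)
    silent = [c for c in codons if code.codon_to_aa[c] not in SINGLE_CODON_AA]
    if not silent:
        raise IndexError_(f"zero silent sites: {record.species}")
    n = len(silent)
    third = [c[2] for c in silent]
    gc_all = sum(b in "GC" for codon in codons for b in codon) / (3 * len(codons))
    return SilentSiteComposition(
        t3s=third.count("U") / n,
        c3s=third.count("C") / n,
        a3s=third.count("A") / n,
        g3s=third.count("G") / n,
        gc=gc_all,
        n_silent_sites=n,
    )


# ---------------------------------------------------------------------------
# ENC (Wright)
# ---------------------------------------------------------------------------

def enc_wright(counts: CodonCounts, code: GeneticCode | None = None) -> EncBreakdown:
    """Wright's effective number of codons.

    Per family with n >= 2 observations the codon homozygosity is
    F = (n * sum p_i^2 - 1) / (n - 1); F-bar_k averages F over observed
    families of fold class k, and Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6. An
    unobserved three-fold class (Ile absent) is substituted by the mean of
    the two- and four-fold estimates; any other missing class makes the
    estimate undefined. Nc is clamped to [20, 61].
    """
    code = code or standard_code()
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.degenerate_families.items():
        k = len(family)
        n = counts.family_total(family)
        if n < 2:
            continue  # F undefined at n <= 1 (estimator divides by n - 1)
        p2 = sum((counts.get(c) / n) ** 2 for c in family)
        f = (n * p2 - 1) / (n - 1)
        if f > 0:
            per_class[k].append(f)
    f_bar = {k: float(np.mean(v)) for k, v in per_class.items() if v}
    n_obs = {k: len(v) for k, v in per_class.items()}
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
    class_counts = {2: 9, 3: 1, 4: 5, 6: 3}
    if any(k not in f_bar for k in class_counts):
        missing = sorted(k for k in class_counts if k not in f_bar)
        raise IndexError_(f"enc_undefined: no observed fold class {missing}")
    nc = 2.0 + sum(m / f_bar[k] for k, m in class_counts.items())
    return EncBreakdown(f_bar=f_bar, n_families_observed=n_obs,
                        nc=float(min(61.0, max(20.0, nc))))


# ---------------------------------------------------------------------------
# CAI / CBI / Fop
# ---------------------------------------------------------------------------

def cai_sharp_li(counts: CodonCounts, ref: CaiReference,
                 code: GeneticCode | None = None) -> float:
    """CAI: geometric mean of reference weights over the counted codons.

    AUG and UGG are excluded; weights are floored at the reference's
    ``zero_floor`` so the mean is finite.
    """
    code = code or standard_code()
    log_sum = 0.0
    n = 0
    for aa, family in code.degenerate_families.items():
        for c in family:
            k = counts.get(c)
            if k:
                w = max(ref.weights.get(c, 1.0), ref.zero_floor)
                log_sum += k * math.log(w)
                n += k
    if n == 0:
        raise IndexError_("CAI undefined: no degenerate codons counted")
    return math.exp(log_sum / n)


def optimal_codons_by_frequency(
    counts: CodonCounts, code: GeneticCode | None = None
) -> frozenset[str]:
    """One optimal codon per degenerate family: the most frequent (ties by
    codon alphabetical order, deterministic)."""
    code = code or standard_code()
    chosen = []
    for aa, family in code.degenerate_families.items():
        chosen.append(max(family, key=lambda c: (counts.get(c), [-ord(x) for x in c])))
    return frozenset(chosen)


def _optimal_split(counts: CodonCounts, optimal_set: frozenset[str],
                   code: GeneticCode) -> tuple[float, float, float]:
    n_opt = n_tot = n_rand = 0.0
    for aa, family in code.degenerate_families.items():
        fam_n = counts.family_total(family)
        if fam_n == 0:
            continue
        n_tot += fam_n
        n_rand += fam_n / len(family)
        n_opt += sum(counts.get(c) for c in family if c in optimal_set)
    return n_opt, n_tot, n_rand


def cbi(counts: CodonCounts, optimal_set: frozenset[str],
        code: GeneticCode | None = None) -> float:
    """Bennetzen-Hall codon bias index, clamped to [-1, 1].

    CBI = (N_opt - N_rand) / (N_tot - N_rand) with N_rand the expectation
    under uniform synonymous usage; NaN when the denominator vanishes.
    """
    code = code or standard_code()
    n_opt, n_tot, n_rand = _optimal_split(counts, optimal_set, code)
    if n_tot == 0:
        raise IndexError_("CBI undefined: no degenerate codons counted")
    if n_tot == n_rand:
        return math.nan
    return float(min(1.0, max(-1.0, (n_opt - n_rand) / (n_tot - n_rand))))


def fop(counts: CodonCounts, optimal_set: frozenset[str],
        code: GeneticCode | None = None) -> float:
    """Frequency of optimal codons over all degenerate-family codons."""
    code = code or standard_code()
    n_opt, n_tot, _ = _optimal_split(counts, optimal_set, code)
    if n_tot == 0:
        raise IndexError_("Fop undefined: no degenerate codons counted")
    return n_opt / n_tot


# ---------------------------------------------------------------------------
# protein-level indices
# ---------------------------------------------------------------------------

def gravy(protein: str) -> float:
    """Mean Kyte-Doolittle hydropathy of the protein (stop stripped)."""
    protein = protein.rstrip("*")
    if not protein:
        raise IndexError_("gravy undefined for empty protein")
    return sum(ProtParamData.kd[aa] for aa in protein) / len(protein)


def aromo(protein: str) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp)."""
    protein = protein.rstrip("*")
    if not protein:
        raise IndexError_("aromo undefined for empty protein")
    return sum(aa in AROMATIC for aa in protein) / len(protein)


# ---------------------------------------------------------------------------
# the per-species summary table
# ---------------------------------------------------------------------------

def derive_default_cai_reference(
    cds_set: CdsSet, code: GeneticCode | None = None, n_top: int = 5
) -> CaiReference:
    """Weights from the pooled counts of the ``n_top`` lowest-ENC species.

    Low ENC marks the most codon-biased (proxy: most highly expressed)
    sequences in the set, following the ENC-ranked expression grouping used
    for the delta-RSCU analysis.
    """
    code = code or standard_code()
    per_species = {r.species: count_codons(r, code) for r in cds_set}
    encs = {}
    for sp, cc in per_species.items():
        try:
            encs[sp] = enc_wright(cc, code).nc
        except IndexError_:
            continue
    chosen = sorted(encs, key=lambda s: (encs[s], s))[: min(n_top, len(encs))]
    pooled = CodonCounts.pooled((per_species[s] for s in chosen), source="high_group")
    return CaiReference.from_counts(
        pooled, code, provenance="derived_from_high_group"
    )


def summarize_indices(
    cds_set: CdsSet,
    ref: CaiReference | None = None,
    code: GeneticCode | None = None,
    optimal_set: frozenset[str] | None = None,
) -> pd.DataFrame:
    """One row of the 14 indices per species, in input order.

    Composition columns (T3s, C3s, A3s, G3s, GC3s, GC) are reported as
    percentages to match the conventional table layout; the remaining
    indices are unit-free. Species whose indices cannot be computed appear
    with NaN values. When ``ref`` or ``optimal_set`` is omitted they are
    derived from the set itself (pooled high-expression group weights; most
    frequent codon per family of the pooled counts).
    """
    code = code or standard_code()
    if ref is None:
        ref = derive_default_cai_reference(cds_set, code)
    if optimal_set is None:
        pooled = CodonCounts.pooled(
            (count_codons(r, code) for r in cds_set), source="pooled"
        )
        optimal_set = optimal_codons_by_frequency(pooled, code)
    rows = []
    for record in cds_set:
        try:
            cc = count_codons(record, code)
            comp = silent_composition(record, code)
            protein = translate(record, code).rstrip("*")
            n_sym = sum(
                cc.family_total(f) for f in code.degenerate_families.values()
            )
            row = {
                "T3s": 100 * comp.t3s,
                "C3s": 100 * comp.c3s,
                "A3s": 100 * comp.a3s,
                "G3s": 100 * comp.g3s,
                "CAI": cai_sharp_li(cc, ref, code),
                "CBI": cbi(cc, optimal_set, code),
                "Fop": fop(cc, optimal_set, code),
                "Nc": enc_wright(cc, code).nc,
                "GC3s": 100 * comp.gc3s,
                "GC": 100 * comp.gc,
                "L_sym": n_sym,
                "L_aa": cc.total_codons,
                "Gravy": gravy(protein),
                "Aromo": aromo(protein),
            }
        except IndexError_:
            row = {c: math.nan for c in INDEX_COLUMNS}
        rows.append(pd.Series(row, name=record.species))
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


def format_indices_table(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation layer: percent columns at 2 dp, indices at 3 dp
    (round-half-even, matching printed-table comparisons)."""
    out = table.copy()
    for col in ("T3s", "C3s", "A3s", "G3s", "GC3s", "GC"):
        out[col] = out[col].round(2)
    for col in ("CAI", "CBI", "Fop", "Nc", "Gravy", "Aromo"):
        out[col] = out[col].round(3)
    return out
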