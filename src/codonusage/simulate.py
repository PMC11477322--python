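"""Synthetic CDS sets with known codon-usage structure.

The generator draws amino acids i.i.d. from a frequency vector and, within
each synonymous family, picks codons from a softmax over a single GC3-bias
parameter beta: p(codon) proportional to exp(beta) for G/C-ending codons and
exp(0) otherwise. beta = 0 gives uniform synonymous usage (expected RSCU = 1
everywhere, ENC near 61); large beta saturates toward G/C-only usage. An
optional clade structure adds per-clade beta offsets, planting a recoverable
phylogenetic signal. Closed-form expected RSCU and GC3s accompany every
sample, so pipeline estimates can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genetics import GeneticCode, SINGLE_CODON_AA, rna_to_dna, standard_code
from .io import CdsRecord, CdsSet


def default_aa_freqs(code: GeneticCode | None = None) -> dict[str, float]:
    """Uniform over the 18 degenerate amino acids, Met and Trp at 0.02 each.

    Guarantees every fold class is observed in long sequences, so ENC is
    always defined.
    """
    code = code or standard_code()
    degenerate = [aa for aa in code.families if aa not in SINGLE_CODON_AA]
    freqs = {aa: 0.96 / len(degenerate) for aa in degenerate}
    freqs.update({aa: 0.02 for aa in SINGLE_CODON_AA})
    return freqs


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic CDS set.

    beta is the GC3-bias strength (log-odds per codon of a G/C-ending
    choice within a family); clade offsets shift beta per species group.
    """

    n_species: int = 24
    length_codons: int = 500
    beta: float = 1.0
    aa_freqs: Mapping[str, float] | None = None
    clades: Mapping[str, str] | None = None  # species -> clade label
    clade_beta_offsets: Mapping[str, float] = field(default_factory=dict)
    gene: str = "geneA"
    seed: int = 0

    def validate(self, code: GeneticCode) -> None:
        problems = []
        if self.n_species < 1:
            problems.append("n_species must be >= 1")
        if self.length_codons < 10:
            problems.append("length_codons must be >= 10")
        freqs = self.resolved_aa_freqs(code)
        if abs(sum(freqs.values()) - 1.0) > 1e-9:
            problems.append("aa_freqs must sum to 1")
        if any(aa not in code.families for aa in freqs):
            problems.append("aa_freqs contains unknown amino acids")
        if self.clades is not None:
            unknown = set(self.clade_beta_offsets) - set(self.clades.values())
            if unknown:
                problems.append(f"offsets for unknown clades: {sorted(unknown)}")
        if problems:
            raise ValueError("; ".join(problems))

    def resolved_aa_freqs(self, code: GeneticCode) -> dict[str, float]:
        if self.aa_freqs is None:
            return default_aa_freqs(code)
        total = sum(self.aa_freqs.values())
        return {aa: f / total for aa, f in self.aa_freqs.items()}

    def species_names(self) -> list[str]:
        if self.clades is not None:
            return list(self.clades)
        return [f"species_{i + 1:02d}" for i in range(self.n_species)]

    def species_beta(self, species: str) -> float:
        if self.clades is None:
            return self.beta
        clade = self.clades[species]
        return self.beta + self.clade_beta_offsets.get(clade, 0.0)


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations under the generative model."""

    expected_rscu: Mapping[str, float]
    expected_gc3s: float
    beta: float
    spec: SyntheticSpec


def family_codon_probs(
    family: tuple[str, ...], beta: float, code: GeneticCode
) -> np.ndarray:
    """Softmax codon probabilities within one synonymous family."""
    logits = np.array([beta if code.is_gc_ending(c) else 0.0 for c in family])
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def expected_rscu(
    spec: SyntheticSpec, code: GeneticCode | None = None, beta: float | None = None
) -> GroundTruth:
    """Expected RSCU per codon and expected GC3s under the softmax model.

    Within a family of size Ni, expected RSCU = Ni * p(codon); expected GC3s
    averages each family's G/C-ending probability mass, weighted by the
    amino-acid frequencies restricted to degenerate families.
    """
    code = code or standard_code()
    spec.validate(code)
    b = spec.beta if beta is None else beta
    freqs = spec.resolved_aa_freqs(code)
    exp_rscu: dict[str, float] = {}
    gc_mass = 0.0
    weight_sum = 0.0
    for aa, family in code.degenerate_families.items():
        p = family_codon_probs(family, b, code)
        for c, pc in zip(family, p):
            exp_rscu[c] = len(family) * float(pc)
        w = freqs.get(aa, 0.0)
        weight_sum += w
        gc_mass += w * sum(
            pc for c, pc in zip(family, p) if code.is_gc_ending(c)
        )
    return GroundTruth(
        expected_rscu=exp_rscu,
        expected_gc3s=gc_mass / weight_sum,
        beta=b,
        spec=spec,
    )


def sample_cds_set(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[CdsSet, GroundTruth]:
    """Draw one CDS per species; deterministic under the spec's seed.

    Each body codon is an amino acid from ``aa_freqs`` and a codon from the
    family softmax at that species' beta; an ATG start is prepended and a
    TAA stop appended.
    """
    code = code or standard_code()
    spec.validate(code)
    rng = np.random.default_rng(spec.seed)
    freqs = spec.resolved_aa_freqs(code)
    aas = list(freqs)
    aa_p = np.array([freqs[a] for a in aas])
    records = []
    for species in spec.species_names():
        b = spec.species_beta(species)
        draws = rng.choice(len(aas), size=spec.length_codons, p=aa_p)
        codons = np.empty(spec.length_codons, dtype=object)
        for ai in range(len(aas)):
            positions = np.nonzero(draws == ai)[0]
            if positions.size == 0:
                continue
            family = code.families[aas[ai]]
            p = family_codon_probs(family, b, code)
            picks = rng.choice(len(family), size=positions.size, p=p)
            codons[positions] = [family[k] for k in picks]
        seq = "ATG" + "".join(rna_to_dna(c) for c in codons) + "TAA"
        records.append(CdsRecord(species=species, gene=spec.gene, sequence=seq))
    return CdsSet(gene=spec.gene, records=tuple(records)), expected_rscu(spec, code)


def two_clade_spec(
    n_species: int = 24,
    length_codons: int = 500,
    beta: float = 1.0,
    offset: float = 2.0,
    gene: str = "geneA",
    seed: int = 0,
) -> SyntheticSpec:
    """Convenience: two equal clades at beta +/- offset."""
    clades = {
        f"species_{i + 1:02d}": ("cladeA" if i < n_species // 2 else "cladeB")
        for i in range(n_species)
    }
    return SyntheticSpec(
        n_species=n_species,
        length_codons=length_codons,
        beta=beta,
        clades=clades,
        clade_beta_offsets={"cladeA": offset, "cladeB": -offset},
        gene=gene,
        seed=seed,
    )
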