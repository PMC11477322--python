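"""Genetic code tables and codon bookkeeping.

Everything downstream (RSCU, ENC, CAI, silent-site composition) is driven by a
:class:`GeneticCode` object built from an NCBI translation table via Biopython.
Codons are stored and compared in the RNA alphabet (``UUC`` rather than
``TTC``); sequence storage elsewhere is DNA, with the mapping applied at the
reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

RNA_BASES = "ACGU"

#: Amino acids whose synonymous family has a single member under the standard
#: code; they carry no synonymous-choice information and are excluded from
#: RSCU, CAI, Fop/CBI and silent-site statistics.
SINGLE_CODON_AA = frozenset({"M", "W"})


def dna_to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with synonymous-family structure.

    Attributes
    ----------
    table_id : int
        NCBI translation table identifier (1 = standard).
    codon_to_aa : dict
        RNA codon -> one-letter amino acid, over the sense codons.
    stop_codons : frozenset
        RNA stop codons.
    families : dict
        Amino acid -> tuple of RNA codons, in a stable (alphabetical) order.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(repr=False)

    @classmethod
    def from_ncbi_table(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_rna_by_id[table_id]
        codon_to_aa = dict(sorted(table.forward_table.items()))
        fams: dict[str, list[str]] = {}
        for codon, aa in codon_to_aa.items():
            fams.setdefault(aa, []).append(codon)
        families = {aa: tuple(sorted(cs)) for aa, cs in sorted(fams.items())}
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            stop_codons=frozenset(table.stop_codons),
            families=families,
        )

    # -- derived views -------------------------------------------------

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(self.codon_to_aa)

    @property
    def degenerate_families(self) -> dict[str, tuple[str, ...]]:
        """Families with at least two synonymous codons."""
        return {aa: cs for aa, cs in self.families.items() if len(cs) >= 2}

    @property
    def degenerate_codons(self) -> tuple[str, ...]:
        """The codons reported by RSCU-style tables (59 under table 1)."""
        return tuple(
            c for cs in self.degenerate_families.values() for c in cs
        )

    def fold_class(self, aa: str) -> int:
        """Family size (degeneracy) of an amino acid: 1, 2, 3, 4 or 6."""
        return len(self.families[aa])

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    def translate_codon(self, codon: str) -> str:
        if codon in self.stop_codons:
            return "*"
        return self.codon_to_aa[codon]

    def is_gc_ending(self, codon: str) -> bool:
        return codon[2] in "GC"


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI table 1), cached."""
    return GeneticCode.from_ncbi_table(1)
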