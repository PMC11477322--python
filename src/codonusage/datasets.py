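"""Bundled reference tables for the DDR1 / EHF two-gene study.

Four small TSVs transcribe the published per-species index tables and pooled
codon-usage tables for the DDR1 receptor gene and the EHF transcription
factor across 24 mammalian species. They let every printed-number check run
without sequence downloads; the sequences themselves are not bundled (no
accessions are available), so analyses needing raw CDS use the synthetic
generator instead.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .indices import RscuTable

_GENES = ("ddr1", "ehf")


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("codonusage") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_species_indices(gene: str) -> pd.DataFrame:
    """Per-species codon index table (24 rows; composition in percent).

    Columns: T3s, C3s, A3s, G3s, CAI, CBI, Fop, Nc, GC3s, GC, Gravy, Aromo.
    """
    if gene.lower() not in _GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {_GENES}")
    return _read(f"{gene.lower()}_species_indices.tsv").set_index("species")


def load_pooled_codon_usage(gene: str) -> pd.DataFrame:
    """Pooled 24-species codon table: amino_acid, codon, count, rscu
    (59 degenerate sense codons, RNA alphabet)."""
    if gene.lower() not in _GENES:
        raise ValueError(f"unknown gene {gene!r}; expected one of {_GENES}")
    return _read(f"{gene.lower()}_pooled_codon_usage.tsv")


def pooled_usage_as_rscu_table(gene: str, use_printed_rscu: bool = True) -> RscuTable:
    """The pooled codon table as an RscuTable.

    ``use_printed_rscu=True`` takes the published RSCU column verbatim;
    ``False`` recomputes RSCU from the published counts.
    """
    df = load_pooled_codon_usage(gene)
    counts = dict(zip(df["codon"], df["count"].astype(int)))
    if use_printed_rscu:
        values = dict(zip(df["codon"], df["rscu"].astype(float)))
    else:
        values = {}
        for _, grp in df.groupby("amino_acid"):
            tot = grp["count"].sum()
            for _, row in grp.iterrows():
                values[row["codon"]] = len(grp) * row["count"] / tot
    return RscuTable(scope="pooled_gene", values=values, counts=counts)
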