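"""Reading, validating and writing CDS sets.

A CDS here is one in-frame protein-coding nucleotide sequence tied to a
species label. Validation enforces the frame (length divisible by three), an
unambiguous A/C/G/T alphabet, and the absence of internal stop codons; a
single terminal stop is either trimmed before counting (``trim_stop``, the
default, matching common CodonW usage) or retained on the record but excluded
from every downstream statistic (``strict``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GeneticCode, dna_to_rna, standard_code

ValidationPolicy = Literal["strict", "trim_stop", "skip"]

_DNA_RE = re.compile(r"^[ACGT]*$")


class CdsValidationError(ValueError):
    """A CDS record violating an invariant; carries a machine-readable reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence for one species.

    ``sequence`` is stored as uppercase DNA; codons are reported in RNA.
    """

    species: str
    gene: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        """In-frame codons in the RNA alphabet."""
        rna = dna_to_rna(self.sequence)
        return [rna[i : i + 3] for i in range(0, len(rna), 3)]


@dataclass(frozen=True)
class CdsSet:
    """One gene's CDS across species, in stable input order."""

    gene: str
    records: tuple[CdsRecord, ...]

    def __post_init__(self):
        labels = [r.species for r in self.records]
        dupes = {s for s in labels if labels.count(s) > 1}
        if dupes:
            raise CdsValidationError(
                "duplicate_species", ", ".join(sorted(dupes))
            )

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _check_frame_and_alphabet(record: CdsRecord) -> None:
    if record.length_nt == 0:
        raise CdsValidationError("empty_sequence", record.species)
    if record.length_nt % 3 != 0:
        raise CdsValidationError(
            "length_not_multiple_of_3",
            f"{record.species}: {record.length_nt} nt",
        )
    if not _DNA_RE.match(record.sequence):
        raise CdsValidationError("ambiguous_base", record.species)


def validate_cds(
    record: CdsRecord,
    policy: ValidationPolicy = "trim_stop",
    code: GeneticCode | None = None,
) -> CdsRecord:
    """Validate a parsed record; returns the (possibly trimmed) record.

    Raises :class:`CdsValidationError` with reason codes ``empty_sequence``,
    ``length_not_multiple_of_3``, ``ambiguous_base``, ``internal_stop`` or
    ``no_codons``. Under ``trim_stop`` a single terminal stop codon is
    removed; under ``strict`` it is retained (downstream counting drops it);
    ``skip`` is handled by the set-level readers, which drop failing records.
    """
    code = code or standard_code()
    _check_frame_and_alphabet(record)
    codons = record.codons()
    for i, codon in enumerate(codons[:-1]):
        if codon in code.stop_codons:
            raise CdsValidationError(
                "internal_stop", f"{record.species}: codon {i + 1}"
            )
    if policy == "trim_stop" and codons and codons[-1] in code.stop_codons:
        record = replace(record, sequence=record.sequence[:-3])
        if record.length_nt == 0:
            raise CdsValidationError("no_codons", record.species)
    return record


def sense_codons(record: CdsRecord, code: GeneticCode | None = None) -> list[str]:
    """Codons entering statistics: a terminal stop, if present, is dropped."""
    code = code or standard_code()
    codons = record.codons()
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    return codons


def translate(record: CdsRecord, code: GeneticCode | None = None) -> str:
    """Translate the record codon-by-codon; stops render as ``*``."""
    code = code or standard_code()
    if record.length_nt % 3 != 0:
        raise CdsValidationError(
            "length_not_multiple_of_3", f"{record.species}: {record.length_nt} nt"
        )
    return "".join(code.translate_codon(c) for c in record.codons())


def _species_from_header(header: str, header_regex: str | None) -> str:
    if header_regex is not None:
        m = re.search(header_regex, header)
        if not m:
            raise CdsValidationError("header_unparseable", header)
        return m.group(1) if m.groups() else m.group(0)
    return header.split()[0]


def read_cds_fasta(
    path: str | Path,
    gene: str,
    policy: ValidationPolicy = "trim_stop",
    header_regex: str | None = None,
    code: GeneticCode | None = None,
) -> CdsSet:
    """Read a multi-FASTA of one CDS per species into a validated CdsSet.

    The species label is the first whitespace-delimited header token unless
    ``header_regex`` is given (its first group, or the whole match, is used).
    Lowercase input and ``U`` bases are normalized on read. Under
    ``policy='skip'`` failing records are silently dropped; otherwise the
    first failure raises.
    """
    path = Path(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise CdsValidationError("empty_file", str(path))
    records = []
    for sr in raw:
        species = _species_from_header(sr.description, header_regex)
        seq = str(sr.seq).upper().replace("U", "T")
        rec = CdsRecord(species=species, gene=gene, sequence=seq)
        if policy == "skip":
            try:
                records.append(validate_cds(rec, "trim_stop", code))
            except CdsValidationError:
                continue
        else:
            records.append(validate_cds(rec, policy, code))
    if not records:
        raise CdsValidationError("empty_file", f"no valid records in {path}")
    return CdsSet(gene=gene, records=tuple(records))


def write_cds_fasta(cds_set: CdsSet, path: str | Path) -> Path:
    """Write a CdsSet back to FASTA (species label as header)."""
    path = Path(path)
    out = [
        SeqRecord(Seq(r.sequence), id=r.species.replace(" ", "_"), description="")
        for r in cds_set
    ]
    SeqIO.write(out, str(path), "fasta")
    return path


def validation_report(
    records: Iterable[CdsRecord],
    policy: ValidationPolicy = "trim_stop",
    code: GeneticCode | None = None,
) -> list[dict]:
    """Per-record validation status rows (species, gene, status, reason)."""
    rows = []
    for rec in records:
        try:
            validate_cds(rec, policy if policy != "skip" else "trim_stop", code)
            rows.append(
                {"species": rec.species, "gene": rec.gene, "status": "ok", "reason": ""}
            )
        except CdsValidationError as exc:
            rows.append(
                {
                    "species": rec.species,
                    "gene": rec.gene,
                    "status": "rejected",
                    "reason": exc.reason,
                }
            )
    return rows
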