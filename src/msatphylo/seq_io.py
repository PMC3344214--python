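"""Readers and writers for FASTA, Newick, and locus-configuration files.

FASTA headers carry three fields, ``<species>|<locus>|<alleleID>`` (the
delimiter is configurable).  All sequences are stored uppercase, in cloned
(forward-primer) orientation; the pipeline never reverse-complements.
Unaligned records must be gap-free; aligned FASTA may contain ``-`` and
IUPAC ambiguity letters.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_letters

if TYPE_CHECKING:  # pragma: no cover
    from .distphylo import PhyloTree

#: Characters permitted in aligned sequences (IUPAC nucleotide codes + gap).
ALIGNED_ALPHABET = frozenset(ambiguous_dna_letters.upper()) | {"-"}
#: Characters permitted in unaligned (raw) sequences.
UNALIGNED_ALPHABET = frozenset(ambiguous_dna_letters.upper())

FASTA_WRAP = 70


class FastaParseError(ValueError):
    """Raised for malformed FASTA headers, duplicate IDs, or empty/bad sequences."""


class LocusConfigError(ValueError):
    """Raised for malformed locus-configuration files or invalid motifs."""


@dataclass(frozen=True)
class SequenceRecord:
    """One cloned allele sequence with its species code and locus name."""

    id: str
    species: str
    locus: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("record id must be nonempty")
        if not self.sequence:
            raise FastaParseError(f"record {self.id!r}: sequence must be nonempty")

    @property
    def header(self) -> str:
        return f"{self.species}|{self.locus}|{self.id}"


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus settings: repeat motif and major-region seed threshold.

    ``note`` records the strand-orientation annotation of the cloned
    sequences; it is metadata only and never triggers reverse-complementing.
    """

    name: str
    motif: str
    min_seed_units: int = 3
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) != 2:
            raise LocusConfigError(f"locus {self.name!r}: motif must be 2 nt, got {self.motif!r}")
        if self.motif[0] == self.motif[1]:
            raise LocusConfigError(f"locus {self.name!r}: motif must not be a homopolymer")
        if set(self.motif) - set("ACGT"):
            raise LocusConfigError(f"locus {self.name!r}: motif must be over ACGT")
        if self.min_seed_units < 1:
            raise LocusConfigError(f"locus {self.name!r}: min_seed_units must be positive")


def read_fasta(
    path: str | Path,
    delimiter: str = "|",
    aligned: bool = False,
) -> list[SequenceRecord]:
    """Read FASTA records with ``species<delim>locus<delim>alleleID`` headers.

    Sequences are uppercased; CRLF endings and wrapped lines are accepted.
    Raises :class:`FastaParseError` for malformed headers, duplicate allele
    IDs within a file, empty sequences, or (when ``aligned=False``) gaps.
    """
    alphabet = ALIGNED_ALPHABET if aligned else UNALIGNED_ALPHABET
    records: list[SequenceRecord] = []
    seen_ids: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description.strip()
        parts = header.split(delimiter)
        if len(parts) != 3 or not all(parts):
            raise FastaParseError(
                f"{path}: record {i} header {header!r} does not match "
                f"'species{delimiter}locus{delimiter}alleleID'"
            )
        species, locus, allele_id = (p.strip() for p in parts)
        seq = str(rec.seq).upper().strip()
        if not seq:
            raise FastaParseError(f"{path}: record {i} ({allele_id!r}) has an empty sequence")
        bad = set(seq) - alphabet
        if bad:
            raise FastaParseError(
                f"{path}: record {i} ({allele_id!r}) contains invalid characters {sorted(bad)}"
            )
        if allele_id in seen_ids:
            raise FastaParseError(f"{path}: duplicate record id {allele_id!r}")
        seen_ids.add(allele_id)
        records.append(SequenceRecord(id=allele_id, species=species, locus=locus, sequence=seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    delimiter: str = "|",
    wrap: int = FASTA_WRAP,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = delimiter.join((rec.species, rec.locus, rec.id))
            fh.write(f">{header}\n")
            for start in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[start : start + wrap] + "\n")


def read_locus_config(path: str | Path) -> dict[str, LocusConfig]:
    """Read a key-value locus configuration file.

    One locus per non-comment line::

        AJ-1  motif=TG  min_seed_units=3  note=forward

    Only ``motif`` is mandatory.  Loci are returned in file order.
    """
    configs: dict[str, LocusConfig] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            name, kv = tokens[0], tokens[1:]
            fields: dict[str, str] = {}
            for tok in kv:
                if "=" not in tok:
                    raise LocusConfigError(f"{path}:{lineno}: expected key=value, got {tok!r}")
                key, val = tok.split("=", 1)
                fields[key] = val
            if "motif" not in fields:
                raise LocusConfigError(f"{path}:{lineno}: locus {name!r} is missing motif=")
            if name in configs:
                raise LocusConfigError(f"{path}:{lineno}: duplicate locus {name!r}")
            configs[name] = LocusConfig(
                name=name,
                motif=fields["motif"].upper(),
                min_seed_units=int(fields.get("min_seed_units", 3)),
                note=fields.get("note", ""),
            )
    return configs


def write_locus_config(configs: Mapping[str, LocusConfig], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cfg in configs.values():
            line = f"{cfg.name}  motif={cfg.motif}  min_seed_units={cfg.min_seed_units}"
            if cfg.note:
                line += f"  note={cfg.note}"
            fh.write(line + "\n")


def write_newick(tree: "PhyloTree", path: str | Path, decimals: int = 3) -> None:
    """Write a tree as Newick with bootstrap supports as internal-node labels.

    Branch lengths are rounded to ``decimals`` places.  NaN branch lengths
    are rejected.
    """
    for length in tree.branch_lengths():
        if math.isnan(length):
            raise ValueError("tree contains a NaN branch length")
    with open(path, "w") as fh:
        fh.write(tree.to_newick(decimals=decimals) + "\n")


def write_text_atomic(text: str, path: str | Path) -> None:
    """Write ``text`` to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)
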