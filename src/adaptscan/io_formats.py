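"""Readers and writers for the formats the pipeline touches.

FASTA (plain and aligned), Newick trees, OrthoFinder-style orthogroup
tables, and TSV count/report tables.  All readers validate strictly and
every validation error names the offending record or row: silent
acceptance of malformed upstream output is how wrong biology gets
published.

The gap character is fixed to ``-``; ``.`` and ``?`` are rejected because
MAFFT emits ``-`` and other dialects appearing in an input signal an
upstream problem.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .codons import STOP_CODONS

GAP = "-"
REJECTED_GAPS = (".", "?")

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXJUO*")
NUCLEOTIDE_ALPHABET = set("ACGTUN")


class FormatError(ValueError):
    """A file violated the format contract; the message names the culprit."""


class ConfigurationError(ValueError):
    """A request was inconsistent with the data (e.g. unknown species)."""


@dataclass(frozen=True)
class SeqRecord:
    """A single sequence with its FASTA header."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """An aligned set of equal-length rows over a declared alphabet.

    ``alphabet`` is one of ``protein``, ``codon``, ``nucleotide``.  Codon
    alignments must have a column count divisible by 3 and contain no
    internal stop codon in any fully ungapped triplet.
    """

    records: list[SeqRecord]
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "codon", "nucleotide"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.records:
            raise FormatError("alignment has no records")
        length = len(self.records[0].seq)
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate sequence ID in alignment: {rec.id!r}")
            seen.add(rec.id)
            if len(rec.seq) != length:
                raise FormatError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec.seq)}, expected {length}"
                )
            _check_gap_dialect(rec)
        if self.alphabet == "codon":
            if length % 3:
                raise FormatError(
                    f"codon alignment length {length} is not a multiple of 3"
                )
            for rec in self.records:
                _check_codon_row(rec)

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, rec_id: str) -> str:
        for rec in self.records:
            if rec.id == rec_id:
                return rec.seq
        raise KeyError(rec_id)

    def column(self, i: int) -> str:
        return "".join(rec.seq[i] for rec in self.records)

    def rename(self, mapping: Mapping[str, str]) -> "Alignment":
        """Return a copy with row IDs translated through ``mapping``."""
        return Alignment(
            [
                SeqRecord(mapping.get(r.id, r.id), r.seq, r.description)
                for r in self.records
            ],
            self.alphabet,
        )


def _check_gap_dialect(rec: SeqRecord) -> None:
    for bad in REJECTED_GAPS:
        if bad in rec.seq:
            raise FormatError(
                f"record {rec.id!r} uses gap character {bad!r}; only '-' is accepted"
            )


def _check_codon_row(rec: SeqRecord) -> None:
    for s in range(len(rec.seq) // 3):
        codon = rec.seq[3 * s : 3 * s + 3].upper()
        if codon == GAP * 3:
            continue
        if GAP in codon:
            raise FormatError(
                f"record {rec.id!r}: codon {s + 1} ({codon}) mixes gaps and bases"
            )
        if codon in STOP_CODONS:
            raise FormatError(
                f"record {rec.id!r}: internal stop codon {codon} at codon {s + 1}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike | io.TextIOBase) -> list[SeqRecord]:
    """Read a FASTA file into records, enforcing unique IDs and non-empty rows."""
    handle = open(path) if not isinstance(path, io.TextIOBase) else path
    try:
        records: list[SeqRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence ID: {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            if not seq:
                raise FormatError(f"record {rec.id!r} has an empty sequence")
            desc = rec.description[len(rec.id) :].strip()
            records.append(SeqRecord(rec.id, seq, desc))
        if not records:
            raise FormatError("no FASTA records found")
        return records
    finally:
        if handle is not path:
            handle.close()


def write_fasta(
    records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_alignment(path: str | os.PathLike, alphabet: str) -> Alignment:
    """Read an aligned FASTA file and validate it as an Alignment."""
    return Alignment(read_fasta(path), alphabet)


def write_alignment(aln: Alignment, path: str | os.PathLike) -> None:
    write_fasta(aln.records, path)


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a tree, rejecting duplicate tip labels.

    Absent branch lengths stay ``None`` (absent is not zero: operations
    that need lengths raise rather than inventing them).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            raise FormatError(f"duplicate tip labels in tree: {exc}") from exc
        raise FormatError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise FormatError(f"duplicate tip labels in tree: {sorted(dupes)}")
    return tree


def read_newick_file(path: str | os.PathLike) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree; branch lengths keep 10 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    ).strip()


def write_newick_file(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Orthogroup tables (OrthoFinder Orthogroups.tsv dialect)


@dataclass
class OrthogroupTable:
    """Orthogroup ID -> species -> gene-ID list, in file row order."""

    species: list[str]
    rows: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.rows.items())

    def __len__(self) -> int:
        return len(self.rows)


def read_orthogroup_table(
    path: str | os.PathLike, species: Sequence[str]
) -> OrthogroupTable:
    """Read an OrthoFinder-style Orthogroups.tsv restricted to ``species``.

    Gene lists are comma+space separated; an empty cell means the species
    has no gene in that orthogroup.
    """
    if not species:
        raise ConfigurationError("species panel is empty")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    header = list(df.columns[1:])
    missing = [sp for sp in species if sp not in header]
    if missing:
        raise ConfigurationError(
            f"requested species missing from orthogroup table header: {missing}"
        )
    table = OrthogroupTable(species=list(species))
    og_col = df.columns[0]
    seen: set[str] = set()
    for _, row in df.iterrows():
        og = row[og_col]
        if og in seen:
            raise FormatError(f"duplicate orthogroup ID: {og!r}")
        seen.add(og)
        per_species: dict[str, list[str]] = {}
        for sp in species:
            cell = row[sp].strip()
            genes = [g.strip() for g in cell.split(",") if g.strip()] if cell else []
            if len(genes) != len(set(genes)):
                raise FormatError(
                    f"duplicate gene IDs in orthogroup {og!r}, species {sp!r}"
                )
            per_species[sp] = genes
        table.rows[og] = per_species
    return table


def write_orthogroup_table(table: OrthogroupTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og, per_species in table.rows.items():
            cells = [", ".join(per_species[sp]) for sp in table.species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# TSV tables with provenance header


def write_tsv(
    df: pd.DataFrame, path: str | os.PathLike, meta: Mapping[str, object] | None = None
) -> None:
    """Write a report TSV with a single commented provenance line."""
    from . import __version__

    items = {"adaptscan": __version__}
    if meta:
        items.update(meta)
    header = "# " + " ".join(f"{k}={v}" for k, v in items.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_family_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a family-by-species count table (first column = family ID)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.values < 0).any():
        bad = df.index[(df.values < 0).any(axis=1)][0]
        raise FormatError(f"negative count in family {bad!r}")
    if df.index.duplicated().any():
        bad = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate family ID: {bad!r}")
    return df.astype(int)
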