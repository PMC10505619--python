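"""Orthogroup filtering and per-orthogroup input assembly.

The analysis set is the orthogroups that contain at least one protein
from every species in the configured panel.  Where a species contributes
several isoforms, the longest is retained (ties broken by the
lexicographically smallest gene ID, for determinism).  Codon alignments
are obtained by back-translating the protein alignment with each gene's
CDS, so the nucleotide alignment is exactly column-compatible with the
protein one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from .codons import translate_codon
from .io_formats import (
    Alignment,
    ConfigurationError,
    GAP,
    OrthogroupTable,
    SeqRecord,
)

STOP_SUFFIXES = ("TAA", "TAG", "TGA")


class BackTranslationError(ValueError):
    """CDS and protein row disagree; the message names gene and position."""


@dataclass
class AnalysisOrthogroup:
    """One orthogroup ready for the three signature analyses."""

    id: str
    genes: dict[str, str]  # species -> chosen gene ID
    protein_alignment: Alignment  # rows keyed by species
    codon_alignment: Alignment  # rows keyed by species
    tree: dendropy.Tree  # tips = species


def filter_complete(table: OrthogroupTable, species: Sequence[str]) -> list[str]:
    """IDs of orthogroups with >=1 gene in every species of the panel.

    Row order of the input table is preserved.
    """
    if not species:
        raise ConfigurationError("species panel is empty")
    kept = []
    for og, per_species in table:
        if all(len(per_species.get(sp, [])) >= 1 for sp in species):
            kept.append(og)
    return kept


def select_longest_isoform(candidates: Sequence[SeqRecord]) -> str:
    """Gene ID of the longest candidate; ties -> smallest ID."""
    if not candidates:
        raise ValueError("no candidate isoforms")
    best = min(candidates, key=lambda r: (-len(r.seq), r.id))
    return best.id


def strip_terminal_stop(cds: str) -> str:
    """Remove one trailing stop codon from a CDS if present."""
    if len(cds) >= 3 and cds[-3:].upper() in STOP_SUFFIXES:
        return cds[:-3]
    return cds


def backtranslate(
    protein_aln: Alignment, cds: Mapping[str, SeqRecord]
) -> Alignment:
    """Thread each CDS through its aligned protein row.

    Every amino acid becomes its codon and every protein gap becomes
    ``---``, so the codon alignment has exactly 3x the protein columns.
    One terminal stop codon on a CDS is tolerated and stripped.
    """
    rows = []
    for rec in protein_aln.records:
        if rec.id not in cds:
            raise BackTranslationError(f"no CDS provided for {rec.id!r}")
        nt = strip_terminal_stop(cds[rec.id].seq.upper())
        protein = rec.seq
        ungapped = protein.replace(GAP, "")
        if len(nt) != 3 * len(ungapped):
            raise BackTranslationError(
                f"gene {rec.id!r}: CDS length {len(nt)} != 3 x "
                f"{len(ungapped)} ungapped residues"
            )
        out = []
        k = 0  # residue index into the ungapped protein
        for aa in protein:
            if aa == GAP:
                out.append(GAP * 3)
                continue
            codon = nt[3 * k : 3 * k + 3]
            try:
                coded = translate_codon(codon)
            except KeyError as exc:
                raise BackTranslationError(
                    f"gene {rec.id!r}: unreadable codon {codon!r} at residue {k + 1}"
                ) from exc
            if coded != aa.upper():
                raise BackTranslationError(
                    f"gene {rec.id!r}: codon {codon} translates to {coded}, "
                    f"protein has {aa} at residue {k + 1}"
                )
            out.append(codon)
            k += 1
        rows.append(SeqRecord(rec.id, "".join(out), rec.description))
    return Alignment(rows, "codon")


def choose_genes(
    per_species: Mapping[str, Sequence[str]],
    proteins: Mapping[str, SeqRecord],
) -> dict[str, str]:
    """Pick one gene per species by the longest-isoform rule."""
    chosen = {}
    for sp, genes in per_species.items():
        candidates = [proteins[g] for g in genes]
        chosen[sp] = select_longest_isoform(candidates)
    return chosen


def relabel_tree_to_species(
    tree: dendropy.Tree, gene_to_species: Mapping[str, str]
) -> dendropy.Tree:
    """Rename gene-ID tips to species names when a tree comes per-gene."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if labels & set(gene_to_species):
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label in gene_to_species:
                leaf.taxon.label = gene_to_species[leaf.taxon.label]
    return tree
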