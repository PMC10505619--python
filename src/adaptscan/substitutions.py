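"""Focal-species-unique amino acid substitutions.

A hit is an alignment column where every background species carries one
identical, non-gap residue and the focal species carries a different
non-gap residue.  Columns within a configurable window (default 10) of
any gap in any row are masked out: alignment quality near indels is too
poor to trust single-column inferences.

Functional impact is annotated either by a substitution-matrix proxy
(BLOSUM62 score of background->focal < 0 => deleterious) or from an
imported table of SIFT predictions (deleterious when the prediction says
so or the score is <= 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io_formats import Alignment, ConfigurationError, GAP

logger = logging.getLogger(__name__)

SIFT_SCORE_THRESHOLD = 0.05


@dataclass
class GapMask:
    """Per-column allow/exclude flags with the window that produced them."""

    allowed: np.ndarray  # bool per column
    window: int

    def __len__(self) -> int:
        return len(self.allowed)


@dataclass
class SubstitutionHit:
    orthogroup_id: str
    column: int  # 0-based internally; reports add 1
    focal_residue: str
    background_residue: str
    impact_score: float | None = None
    deleterious: bool | None = None
    source: str = "proxy"


def gap_mask(aln: Alignment, window: int = 10) -> GapMask:
    """Exclude every column within ``window`` of any column containing a gap."""
    if window < 0:
        raise ValueError("window must be >= 0")
    n = aln.length
    has_gap = np.zeros(n, dtype=bool)
    for rec in aln.records:
        has_gap |= np.frombuffer(rec.seq.encode(), dtype=np.uint8) == ord(GAP)
    allowed = np.ones(n, dtype=bool)
    for g in np.nonzero(has_gap)[0]:
        lo = max(0, g - window)
        hi = min(n, g + window + 1)
        allowed[lo:hi] = False
    return GapMask(allowed=allowed, window=window)


def scan_unique_substitutions(
    aln: Alignment,
    focal: str,
    mask: GapMask | None = None,
    min_background: int = 2,
    orthogroup_id: str = "",
) -> list[SubstitutionHit]:
    """Columns where all background rows agree and the focal row differs.

    Background identity is strict: any disagreement or gap among the
    background rows disqualifies the column, as does a focal gap (a
    deletion is not a substitution).
    """
    if focal not in aln.ids:
        raise ConfigurationError(f"focal species {focal!r} not a row of the alignment")
    if mask is None:
        mask = gap_mask(aln)
    if len(mask) != aln.length:
        raise ValueError("mask length does not match alignment columns")
    background = [r.seq for r in aln.records if r.id != focal]
    if len(background) < min_background:
        raise ConfigurationError(
            f"need >= {min_background} background rows, got {len(background)}"
        )
    focal_seq = aln.row(focal)
    hits: list[SubstitutionHit] = []
    for c in np.nonzero(mask.allowed)[0]:
        ref = background[0][c]
        if ref == GAP:
            continue
        if any(row[c] != ref for row in background[1:]):
            continue
        f = focal_seq[c]
        if f == GAP or f == ref:
            continue
        hits.append(
            SubstitutionHit(
                orthogroup_id=orthogroup_id,
                column=int(c),
                focal_residue=f,
                background_residue=ref,
            )
        )
    return hits


@dataclass
class SiftTable:
    """Imported SIFT predictions keyed by (gene, 1-based position)."""

    rows: dict[tuple[str, int], tuple[str, float]] = field(default_factory=dict)
    skipped: int = 0

    @classmethod
    def from_tsv(cls, path) -> "SiftTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"gene", "position", "prediction", "score"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"SIFT table missing columns: {sorted(missing)}")
        table = cls()
        for _, row in df.iterrows():
            table.rows[(str(row["gene"]), int(row["position"]))] = (
                str(row["prediction"]),
                float(row["score"]),
            )
        return table


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def score_impact(
    hits: list[SubstitutionHit],
    matrix=_BLOSUM62,
    sift: SiftTable | None = None,
    focal_gene: str | None = None,
) -> list[SubstitutionHit]:
    """Annotate hits in place with an impact score and deleterious flag.

    Proxy mode scores the background->focal exchange with the matrix;
    a negative score marks an exchange rarer than chance between related
    proteins, taken as functionally impactful.  When a SIFT table covers
    a hit (by focal gene and 1-based column), the imported prediction
    wins and ``source`` records it.
    """
    for hit in hits:
        imported = None
        if sift is not None and focal_gene is not None:
            imported = sift.rows.get((focal_gene, hit.column + 1))
        if imported is not None:
            prediction, score = imported
            hit.impact_score = score
            hit.deleterious = (
                prediction.upper() == "DELETERIOUS" or score <= SIFT_SCORE_THRESHOLD
            )
            hit.source = "imported"
        else:
            try:
                score = float(matrix[hit.background_residue, hit.focal_residue])
            except (KeyError, IndexError):
                logger.warning(
                    "no matrix entry for %s->%s; hit left unannotated",
                    hit.background_residue,
                    hit.focal_residue,
                )
                continue
            hit.impact_score = score
            hit.deleterious = score < 0
            hit.source = "proxy"
    return hits
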