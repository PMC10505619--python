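"""Combine the three signature calls into MSA gene reports.

A gene shows "multiple signatures of adaptive evolution" (MSA) when at
least two of the three per-orthogroup flags are set: elevated
root-to-tip divergence of the focal lineage, a focal-unique amino acid
substitution with predicted functional impact, and branch-site positive
selection (FDR-corrected).  An orthogroup absent from one analysis
simply counts as unflagged there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .divergence import DivergenceResult
from .selection import BranchSiteFit
from .substitutions import SubstitutionHit


@dataclass
class MsaGeneReport:
    orthogroup_id: str
    focal_gene: str
    high_divergence: bool
    unique_substitution: bool
    positively_selected: bool
    msa: bool
    qvalue: float | None = None
    n_hits: int = 0
    n_deleterious_hits: int = 0
    divergence_ratio: float | None = None  # focal / max(background) root-to-tip

    def recompute_msa(self) -> bool:
        return (
            int(self.high_divergence)
            + int(self.unique_substitution)
            + int(self.positively_selected)
        ) >= 2


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(ids) != len(set(ids)):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValueError(f"duplicate orthogroup IDs in {what}: {dupes}")


def combine_signatures(
    divergence: Sequence[DivergenceResult],
    substitutions: Mapping[str, Sequence[SubstitutionHit]],
    selection: Sequence[BranchSiteFit],
    require_impact: bool = True,
    focal_genes: Mapping[str, str] | None = None,
) -> list[MsaGeneReport]:
    """One report row per orthogroup seen by any analysis, ID-sorted.

    ``require_impact`` keeps the substitution signature conditional on a
    deleterious (functional-impact) call; switching it off counts any
    focal-unique substitution.
    """
    _check_unique([d.orthogroup_id for d in divergence], "divergence results")
    _check_unique(list(substitutions.keys()), "substitution results")
    _check_unique([s.orthogroup_id for s in selection], "selection results")
    div_by_og = {d.orthogroup_id: d for d in divergence}
    sel_by_og = {s.orthogroup_id: s for s in selection}
    all_ogs = sorted(set(div_by_og) | set(substitutions) | set(sel_by_og))
    reports = []
    for og in all_ogs:
        div = div_by_og.get(og)
        hits = list(substitutions.get(og, []))
        sel = sel_by_og.get(og)
        high_div = bool(div.high_divergence) if div else False
        n_del = sum(1 for h in hits if h.deleterious)
        uniq = (n_del >= 1) if require_impact else (len(hits) >= 1)
        pos_sel = bool(sel.positively_selected) if sel else False
        ratio = None
        if div:
            others = [
                v for sp, v in div.distances.items() if sp != div.focal
            ]
            top = max(others) if others else 0.0
            ratio = div.distances[div.focal] / top if top > 0 else float("inf")
        report = MsaGeneReport(
            orthogroup_id=og,
            focal_gene=(focal_genes or {}).get(og, ""),
            high_divergence=high_div,
            unique_substitution=bool(uniq),
            positively_selected=pos_sel,
            msa=False,
            qvalue=sel.qvalue if sel else None,
            n_hits=len(hits),
            n_deleterious_hits=n_del,
            divergence_ratio=ratio,
        )
        report.msa = report.recompute_msa()
        reports.append(report)
    return reports


REPORT_COLUMNS = [
    "orthogroup",
    "focal_gene",
    "high_divergence",
    "unique_substitution",
    "positively_selected",
    "msa",
    "qvalue",
    "n_hits",
    "n_deleterious_hits",
    "divergence_ratio",
]


def reports_to_frame(reports: Sequence[MsaGeneReport]) -> pd.DataFrame:
    rows = [
        {
            "orthogroup": r.orthogroup_id,
            "focal_gene": r.focal_gene,
            "high_divergence": r.high_divergence,
            "unique_substitution": r.unique_substitution,
            "positively_selected": r.positively_selected,
            "msa": r.msa,
            "qvalue": r.qvalue,
            "n_hits": r.n_hits,
            "n_deleterious_hits": r.n_deleterious_hits,
            "divergence_ratio": r.divergence_ratio,
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
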