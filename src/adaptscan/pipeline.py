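"""Configuration-driven orchestration of all analysis stages.

Stages: orthogroups -> (divergence | substitutions | selection) ->
families -> combine.  Each stage writes one TSV into the output
directory; a rerun skips any stage whose output already exists under the
same configuration hash, so deleting a single stage file and rerunning
reproduces identical downstream output.  All thresholds live in the
config file; there are no hidden constants.
"""

from __future__ import annotations

import concurrent.futures
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .divergence import call_high_divergence, root_to_tip, root_tree
from .gene_families import analyze_families
from .io_formats import (
    Alignment,
    ConfigurationError,
    read_alignment,
    read_family_counts,
    read_fasta,
    read_newick_file,
    read_orthogroup_table,
    read_tsv,
    write_tsv,
)
from .orthogroups import (
    backtranslate,
    choose_genes,
    filter_complete,
    relabel_tree_to_species,
)
from .selection import branch_site_test, finalize_selection
from .substitutions import SiftTable, gap_mask, scan_unique_substitutions, score_impact

logger = logging.getLogger(__name__)

ALL_STAGES = ("divergence", "substitutions", "selection", "families", "combine")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    species: list[str]
    focal: str
    orthogroup_table: str
    protein_dir: str
    cds_dir: str
    alignment_dir: str
    tree_dir: str
    out_dir: str
    family_counts: str | None = None
    ultrametric_tree: str | None = None
    sift_file: str | None = None
    # thresholds (defaults follow the published analysis where it states
    # them; the rest are package decisions documented in the methods note)
    fdr_threshold: float = 0.05
    beb_threshold: float = 0.95
    gap_window: int = 10
    copy_cap: int = 100
    high_threshold: int = 10
    divergence_rule: str = "strict_max"
    zscore_k: float = 2.0
    rooting: str = "midpoint"
    outgroup: str | None = None
    min_background: int = 2
    require_impact: bool = True
    lrt_convention: str = "chi2_1"
    branch_mode: str = "scale"
    n_starts: int = 3
    two_lambda: bool = True
    high_rule: str = "family_size"
    seed: int = 0
    threads: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    def __post_init__(self) -> None:
        if self.focal not in self.species:
            raise ConfigurationError(
                f"focal species {self.focal!r} not in the species panel"
            )
        if not (0 < self.fdr_threshold < 1):
            raise ConfigurationError("fdr_threshold must be in (0, 1)")
        if not (0 < self.beb_threshold < 1):
            raise ConfigurationError("beb_threshold must be in (0, 1)")
        if self.gap_window < 0:
            raise ConfigurationError("gap_window must be >= 0")
        if self.copy_cap < 1 or self.high_threshold < 0:
            raise ConfigurationError("family thresholds out of range")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class LoadedOrthogroup:
    id: str
    genes: dict[str, str]
    protein_alignment: Alignment  # rows = species
    codon_alignment: Alignment  # rows = species
    tree: "object"  # dendropy.Tree, tips = species


class StageError(RuntimeError):
    def __init__(self, stage: str, orthogroup: str, cause: Exception):
        super().__init__(
            f"stage {stage!r} failed on orthogroup {orthogroup!r}: {cause}"
        )
        self.stage = stage
        self.orthogroup = orthogroup


# ---------------------------------------------------------------------------
# Input assembly


def load_orthogroups(config: PipelineConfig) -> list[LoadedOrthogroup]:
    """Filter the orthogroup table and assemble per-orthogroup inputs."""
    table = read_orthogroup_table(config.orthogroup_table, config.species)
    complete = filter_complete(table, config.species)
    logger.info("%d/%d orthogroups complete for the panel", len(complete), len(table))
    out = []
    for og in complete:
        try:
            proteins = {
                r.id: r for r in read_fasta(Path(config.protein_dir) / f"{og}.faa")
            }
            cds = {r.id: r for r in read_fasta(Path(config.cds_dir) / f"{og}.fna")}
            genes = choose_genes(table.rows[og], proteins)
            gene_to_species = {g: sp for sp, g in genes.items()}
            aln = read_alignment(
                Path(config.alignment_dir) / f"{og}.protein.fasta", "protein"
            )
            missing = set(genes.values()) - set(aln.ids)
            if missing:
                raise ConfigurationError(
                    f"alignment lacks chosen genes: {sorted(missing)}"
                )
            codon = backtranslate(aln, cds).rename(gene_to_species)
            protein_sp = aln.rename(gene_to_species)
            tree = read_newick_file(Path(config.tree_dir) / f"{og}.nwk")
            relabel_tree_to_species(tree, gene_to_species)
            out.append(
                LoadedOrthogroup(
                    id=og,
                    genes=genes,
                    protein_alignment=protein_sp,
                    codon_alignment=codon,
                    tree=tree,
                )
            )
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise StageError("orthogroups", og, exc) from exc
    return out


# ---------------------------------------------------------------------------
# Stages


def run_divergence(ogs, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for og in ogs:
        try:
            tree = root_tree(
                og.tree, method=config.rooting, outgroup=config.outgroup
            )
            dists = root_to_tip(tree)
            res = call_high_divergence(
                dists,
                config.focal,
                rule=config.divergence_rule,
                k=config.zscore_k,
                orthogroup_id=og.id,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("divergence", og.id, exc) from exc
        others = [v for sp, v in dists.items() if sp != config.focal]
        rows.append(
            {
                "orthogroup": og.id,
                "focal_distance": dists[config.focal],
                "max_background": max(others),
                "mean_background": float(np.mean(others)),
                "high_divergence": res.high_divergence,
                "rule": res.rule,
            }
        )
    return pd.DataFrame(rows)


def run_substitutions(ogs, config: PipelineConfig) -> pd.DataFrame:
    sift = SiftTable.from_tsv(config.sift_file) if config.sift_file else None
    rows = []
    for og in ogs:
        try:
            mask = gap_mask(og.protein_alignment, window=config.gap_window)
            hits = scan_unique_substitutions(
                og.protein_alignment,
                config.focal,
                mask=mask,
                min_background=config.min_background,
                orthogroup_id=og.id,
            )
            score_impact(hits, sift=sift, focal_gene=og.genes[config.focal])
        except Exception as exc:  # noqa: BLE001
            raise StageError("substitutions", og.id, exc) from exc
        rows.append(
            {
                "orthogroup": og.id,
                "n_hits": len(hits),
                "n_deleterious": sum(1 for h in hits if h.deleterious),
                "columns": ";".join(str(h.column + 1) for h in hits),
                "deleterious_columns": ";".join(
                    str(h.column + 1) for h in hits if h.deleterious
                ),
            }
        )
    return pd.DataFrame(rows)


def _selection_one(args):
    og, config = args
    try:
        return branch_site_test(
            og.codon_alignment,
            og.tree,
            config.focal,
            orthogroup_id=og.id,
            n_starts=config.n_starts,
            seed=config.seed,
            branch_mode=config.branch_mode,
            lrt_convention=config.lrt_convention,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("selection", og.id, exc) from exc


def run_selection(ogs, config: PipelineConfig) -> pd.DataFrame:
    """Branch-site tests for all orthogroups, then FDR across them.

    Orthogroup-level parallelism: each orthogroup is independent and
    seeded identically regardless of worker count, so results do not
    depend on ``threads``.
    """
    jobs = [(og, config) for og in ogs]
    if config.threads > 1:
        with concurrent.futures.ThreadPoolExecutor(config.threads) as pool:
            fits = list(pool.map(_selection_one, jobs))
    else:
        fits = [_selection_one(j) for j in jobs]
    finalize_selection(
        fits,
        fdr_threshold=config.fdr_threshold,
        beb_threshold=config.beb_threshold,
    )
    rows = []
    for f in fits:
        rows.append(
            {
                "orthogroup": f.orthogroup_id,
                "lnL_null": f.lnL_null,
                "lnL_alt": f.lnL_alt,
                "stat": f.stat,
                "pvalue": f.pvalue,
                "qvalue": f.qvalue,
                "positively_selected": bool(f.positively_selected),
                "selected_sites": ";".join(str(s) for s in f.selected_sites),
                "converged": f.converged,
                "kappa": f.params_alt.kappa,
                "omega2": f.params_alt.omega2,
            }
        )
    return pd.DataFrame(rows)


def run_families(config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    counts = read_family_counts(config.family_counts)
    counts = counts[config.species]
    tree = read_newick_file(config.ultrametric_tree)
    tree.is_rooted = True
    model, results = analyze_families(
        counts,
        tree,
        config.focal,
        copy_cap=config.copy_cap,
        high_threshold=config.high_threshold,
        two_lambda=config.two_lambda,
        high_rule=config.high_rule,
    )
    rows = [
        {
            "family": r.family_id,
            "focal_count": r.focal_count,
            "parent_count": r.parent_count,
            "delta": r.delta,
            "direction": r.direction,
            "highly_changed": r.highly_changed,
        }
        for r in results
    ]
    summary = {
        "lambda_background": model.lambdas[0],
        "lambda_focal": model.lambdas.get(1, model.lambdas[0]),
        "n_expanded": sum(r.direction == "expanded" for r in results),
        "n_contracted": sum(r.direction == "contracted" for r in results),
        "n_highly_changed": sum(r.highly_changed for r in results),
    }
    return pd.DataFrame(rows), summary


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages, caching per-stage TSV outputs.

    Returns a map of stage name to output path.  A stage is skipped when
    its output file already exists and the run manifest carries the same
    config hash (resume semantics).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest_path = out / "manifest.json"
    cached_hash = None
    if manifest_path.exists():
        with open(manifest_path) as fh:
            cached_hash = json.load(fh).get("config_hash")
    resume = cached_hash == chash
    meta = {"config_hash": chash, "seed": config.seed}
    paths: dict[str, Path] = {}

    def stage_path(name: str) -> Path:
        return out / f"{name}.tsv"

    def needs(name: str) -> bool:
        return name in config.stages and not (resume and stage_path(name).exists())

    failed_marker = out / "FAILED"

    def guarded(stage: str, fn):
        # on error: keep partial outputs, drop a FAILED marker, re-raise
        try:
            result = fn()
        except Exception:
            failed_marker.write_text(stage + "\n")
            raise
        if failed_marker.exists():
            failed_marker.unlink()
        return result

    ogs = None
    analysis_stages = {"divergence", "substitutions", "selection", "combine"}
    if any(needs(s) for s in analysis_stages & set(config.stages)):
        ogs = guarded("orthogroups", lambda: load_orthogroups(config))

    if "divergence" in config.stages:
        if needs("divergence"):
            guarded(
                "divergence",
                lambda: write_tsv(
                    run_divergence(ogs, config), stage_path("divergence"), meta
                ),
            )
        paths["divergence"] = stage_path("divergence")
    if "substitutions" in config.stages:
        if needs("substitutions"):
            guarded(
                "substitutions",
                lambda: write_tsv(
                    run_substitutions(ogs, config), stage_path("substitutions"), meta
                ),
            )
        paths["substitutions"] = stage_path("substitutions")
    if "selection" in config.stages:
        if needs("selection"):
            guarded(
                "selection",
                lambda: write_tsv(
                    run_selection(ogs, config), stage_path("selection"), meta
                ),
            )
        paths["selection"] = stage_path("selection")
    if "families" in config.stages and config.family_counts:
        if needs("families"):
            fam_df, summary = guarded("families", lambda: run_families(config))
            write_tsv(fam_df, stage_path("families"), {**meta, **summary})
        paths["families"] = stage_path("families")
    if "combine" in config.stages:
        if needs("combine"):
            report = guarded("combine", lambda: combine_from_stage_outputs(
                stage_path("divergence"),
                stage_path("substitutions"),
                stage_path("selection"),
                require_impact=config.require_impact,
                focal_genes={og.id: og.genes[config.focal] for og in (ogs or [])},
            ))
            write_tsv(report, stage_path("msa_report"), meta)
        paths["combine"] = stage_path("msa_report")

    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "version": __version__,
                "config_hash": chash,
                "seed": config.seed,
                "stages": list(paths),
            },
            fh,
            indent=2,
        )
    return paths


def combine_from_stage_outputs(
    divergence_tsv: Path,
    substitutions_tsv: Path,
    selection_tsv: Path,
    require_impact: bool = True,
    focal_genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rebuild the MSA report from the cached per-stage TSVs.

    Works from files rather than in-memory objects so the combine stage
    can rerun without repeating the expensive analyses.
    """
    div = read_tsv(divergence_tsv) if divergence_tsv.exists() else pd.DataFrame()
    sub = (
        read_tsv(substitutions_tsv) if substitutions_tsv.exists() else pd.DataFrame()
    )
    sel = read_tsv(selection_tsv) if selection_tsv.exists() else pd.DataFrame()
    for name, df in (("divergence", div), ("substitutions", sub), ("selection", sel)):
        if len(df) and df["orthogroup"].duplicated().any():
            raise ValueError(f"duplicate orthogroup IDs in {name} stage output")
    ogs = sorted(
        set(div.get("orthogroup", []))
        | set(sub.get("orthogroup", []))
        | set(sel.get("orthogroup", []))
    )
    div_i = div.set_index("orthogroup") if len(div) else pd.DataFrame()
    sub_i = sub.set_index("orthogroup") if len(sub) else pd.DataFrame()
    sel_i = sel.set_index("orthogroup") if len(sel) else pd.DataFrame()
    rows = []
    for og in ogs:
        high_div = bool(div_i["high_divergence"].get(og, False)) if len(div_i) else False
        n_hits = int(sub_i["n_hits"].get(og, 0)) if len(sub_i) else 0
        n_del = int(sub_i["n_deleterious"].get(og, 0)) if len(sub_i) else 0
        uniq = (n_del >= 1) if require_impact else (n_hits >= 1)
        pos = bool(sel_i["positively_selected"].get(og, False)) if len(sel_i) else False
        q = sel_i["qvalue"].get(og) if len(sel_i) else None
        ratio = None
        if len(div_i) and og in div_i.index:
            top = float(div_i.loc[og, "max_background"])
            ratio = float(div_i.loc[og, "focal_distance"]) / top if top > 0 else None
        rows.append(
            {
                "orthogroup": og,
                "focal_gene": (focal_genes or {}).get(og, ""),
                "high_divergence": high_div,
                "unique_substitution": uniq,
                "positively_selected": pos,
                "msa": (int(high_div) + int(uniq) + int(pos)) >= 2,
                "qvalue": q,
                "n_hits": n_hits,
                "n_deleterious_hits": n_del,
                "divergence_ratio": ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
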