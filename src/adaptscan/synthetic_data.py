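"""Generators for every input the pipeline consumes, with ground truth.

The generators stand in for the real inputs (proteomes, MAFFT
alignments, ML gene trees, MCL family counts) so that every stage is
testable offline against a known answer.  They deliberately avoid the
analyzers' numerical shortcuts wherever that would make a check
self-confirming: the family simulator is event-driven (exact jump
process) while the analyzer uses the closed-form transition
probability, and the codon simulator draws states through the matrix
exponential rather than through the pruning code.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .codons import SENSE_CODONS
from .gene_families import bd_alpha, compile_ultrametric
from .io_formats import (
    Alignment,
    OrthogroupTable,
    SeqRecord,
    write_alignment,
    write_fasta,
    write_newick_file,
    write_orthogroup_table,
    write_tsv,
)
from .selection import (
    CodonModelParams,
    codon_rate_matrix,
    substitution_rate,
    transition_matrix,
)
from .substitutions import gap_mask

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Trees


def simulate_tree(
    n_taxa: int,
    seed: int,
    focal: str | None = None,
    scale: float = 1.0,
    mean_branch: float = 0.1,
    labels: list[str] | None = None,
    ultrametric: bool = False,
    depth: float | None = None,
    shape: str = "join",
) -> dendropy.Tree:
    """Random binary tree with Exp(mean) branch lengths.

    ``shape='join'`` builds the topology by sequential random joins;
    ``shape='coalescent'`` draws a Kingman coalescent (clock-like by
    construction, with realistically short terminal branches).  The
    focal terminal branch is multiplied by ``scale`` (planted elevated
    divergence).  With ``ultrametric`` every tip edge is extended so all
    tips are equidistant from the root, and ``depth`` rescales the tree
    to that root-to-tip height.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if scale <= 0:
        raise ValueError("scale factor must be positive")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"S{i:02d}" for i in range(1, n_taxa + 1)]
        if focal is not None:
            labels[-1] = focal
    if len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    if focal is not None and focal not in labels:
        raise ValueError(f"focal label {focal!r} not among tip labels")

    def draw() -> float:
        return float(rng.exponential(mean_branch))

    if shape == "join":
        frags = []
        for lab in labels:
            length = draw()
            if focal is not None and lab == focal:
                length *= scale
            frags.append(f"{lab}:{length:.10g}")
        while len(frags) > 2:
            i, j = sorted(rng.choice(len(frags), size=2, replace=False))
            b = frags.pop(j)
            a = frags.pop(i)
            frags.append(f"({a},{b}):{draw():.10g}")
        newick = f"({frags[0]},{frags[1]});"
    elif shape == "coalescent":
        # heights of nodes above the present; waiting times Exp with the
        # usual k-choose-2 coalescence rate
        lineages = [(lab, 0.0) for lab in labels]
        height = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            height += float(rng.exponential(2.0 / (k * (k - 1))))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            (b, hb) = lineages.pop(j)
            (a, ha) = lineages.pop(i)
            merged = f"({a}:{height - ha:.10g},{b}:{height - hb:.10g})"
            lineages.append((merged, height))
        newick = lineages[0][0] + ";"
    else:
        raise ValueError(f"unknown tree shape {shape!r}")
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    if shape == "coalescent":
        if depth is not None:
            depths = {}
            for node in tree.preorder_node_iter():
                parent_d = depths.get(id(node.parent_node), 0.0)
                depths[id(node)] = parent_d + (node.edge.length or 0.0)
            dmax = max(depths[id(l)] for l in tree.leaf_node_iter())
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= depth / dmax
        if focal is not None and scale != 1.0:
            leaf = tree.find_node_with_taxon_label(focal)
            leaf.edge.length *= scale
        tree.is_rooted = True
        return tree
    tree.is_rooted = True
    if ultrametric:
        depths = {}
        for node in tree.preorder_node_iter():
            parent_d = depths.get(id(node.parent_node), 0.0)
            depths[id(node)] = parent_d + (node.edge.length or 0.0)
        dmax = max(depths[id(l)] for l in tree.leaf_node_iter())
        for leaf in tree.leaf_node_iter():
            leaf.edge.length += dmax - depths[id(leaf)]
        if depth is not None:
            factor = depth / dmax
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= factor
    return tree


def jitter_tree(
    base: dendropy.Tree,
    seed: int,
    focal: str | None = None,
    focal_scale: float = 1.0,
    edge_sd: float = 0.25,
    rate_sd: float = 0.3,
) -> dendropy.Tree:
    """Per-gene tree: shared topology, lognormal rate variation per edge.

    Orthogroup trees in real data share the species topology but differ
    in rate: this applies a global lognormal gene-rate factor plus
    independent lognormal jitter per edge, then multiplies the focal
    terminal branch by ``focal_scale``.
    """
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree.get(
        data=base.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
    )
    gene_rate = float(np.exp(rng.normal(0.0, rate_sd)))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= gene_rate * float(np.exp(rng.normal(0.0, edge_sd)))
    if focal is not None and focal_scale != 1.0:
        leaf = tree.find_node_with_taxon_label(focal)
        if leaf is None:
            raise ValueError(f"focal label {focal!r} not in tree")
        leaf.edge.length *= focal_scale
    return tree


# ---------------------------------------------------------------------------
# Codon alignments


def _sample_rows(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P[parents], axis=1)
    u = rng.random(len(parents)) * cum[:, -1]
    return np.minimum(
        (cum < u[:, None]).sum(axis=1), P.shape[1] - 1
    )


def simulate_codon_alignment(
    tree: dendropy.Tree,
    params: CodonModelParams,
    n_codons: int,
    seed: int,
    foreground: str | None = None,
    pi: np.ndarray | None = None,
) -> tuple[Alignment, np.ndarray]:
    """Evolve codons along a tree under the branch-site mixture.

    Site classes are drawn from the model proportions; the root codon
    comes from pi (uniform over the 61 sense codons by default); each
    branch applies the matrix exponential of the class- and
    branch-appropriate rate matrix.  Branch lengths are expected
    substitutions per codon site under the background mixture, matching
    the analysis-side scaling.  Returns the alignment and the true class
    of every site.
    """
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    props = params.proportions
    props = props / props.sum()
    classes = rng.choice(4, size=n_codons, p=props)
    bgw = params.background_omegas
    fgw = params.foreground_omegas
    Qs = {w: codon_rate_matrix(params.kappa, w, pi) for w in set(bgw) | set(fgw)}
    r = float(sum(props[k] * substitution_rate(Qs[bgw[k]], pi) for k in range(4)))
    states = {id(tree.seed_node): rng.choice(len(pi), size=n_codons, p=pi)}
    rows: list[SeqRecord] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            current = states[id(node)]
        else:
            if node.edge.length is None:
                raise ValueError("simulation tree has an edge without length")
            t = node.edge.length / r
            is_fg = (
                node.is_leaf()
                and foreground is not None
                and node.taxon.label == foreground
            )
            ws = fgw if is_fg else bgw
            parent = states[id(node.parent_node)]
            current = np.empty(n_codons, dtype=np.int64)
            Pcache = {w: transition_matrix(Qs[w], t) for w in set(ws)}
            for k in range(4):
                sites = classes == k
                if sites.any():
                    current[sites] = _sample_rows(
                        Pcache[ws[k]], parent[sites], rng
                    )
            states[id(node)] = current
        if node.is_leaf():
            seq = "".join(SENSE_CODONS[i] for i in current)
            rows.append(SeqRecord(node.taxon.label, seq))
    return Alignment(rows, "codon"), classes


# ---------------------------------------------------------------------------
# Protein alignments with planted substitutions


def simulate_protein_alignment(
    n_rows: int,
    n_cols: int,
    planted: list[tuple[int, str, str]] = (),
    gaps: list[tuple[int, int, list[int]]] = (),
    seed: int = 0,
    noise: float = 0.05,
    window: int = 10,
    ids: list[str] | None = None,
) -> tuple[Alignment, list[int]]:
    """Protein alignment fixture with planted focal-unique columns.

    Row 0 is the focal row.  Non-planted columns carry a random
    consensus residue; each background row deviates with probability
    ``noise`` (the focal row never does, so only planted columns can be
    hits).  ``planted`` holds (0-based column, focal residue,
    background residue); ``gaps`` holds (start, length, row indices)
    blocks of ``-``.  Returns the alignment and the ground-truth hit
    columns: the planted columns that survive the width-``window`` gap
    mask.
    """
    rng = np.random.default_rng(seed)
    if ids is None:
        ids = ["FOCAL"] + [f"S{i:02d}" for i in range(1, n_rows)]
    cols = [p[0] for p in planted]
    if len(cols) != len(set(cols)):
        raise ValueError("planted columns must be disjoint")
    aa = np.array(list(AMINO_ACIDS))
    consensus = rng.choice(len(aa), size=n_cols)
    grid = np.tile(aa[consensus], (n_rows, 1))
    flip = rng.random((n_rows, n_cols)) < noise
    flip[0] = False  # focal row stays on consensus
    if n_rows > 2:
        # keep at least one background row on consensus per column, so
        # noise can never fabricate an unplanted uniform-background hit
        all_background_flipped = flip[1:].all(axis=0)
        flip[1, all_background_flipped] = False
    offsets = rng.integers(1, len(aa), size=(n_rows, n_cols))
    flipped = aa[(consensus[None, :] + offsets) % len(aa)]
    grid = np.where(flip, flipped, grid)
    for col, focal_res, bg_res in planted:
        if focal_res == bg_res:
            raise ValueError(f"planted column {col}: focal equals background")
        grid[0, col] = focal_res
        grid[1:, col] = bg_res
    for start, length, row_idx in gaps:
        for r in row_idx:
            grid[r, start : start + length] = "-"
    records = [SeqRecord(ids[r], "".join(grid[r])) for r in range(n_rows)]
    aln = Alignment(records, "protein")
    mask = gap_mask(aln, window=window)
    truth = sorted(c for c, _, _ in planted if mask.allowed[c])
    return aln, truth


# ---------------------------------------------------------------------------
# Gene-family counts


def _evolve_counts(
    n: np.ndarray, lam: float, duration: float, rng
) -> np.ndarray:
    """Exact event-driven linear birth-death step for a vector of families."""
    bd_alpha(lam, duration)  # validates the alpha < 1/2 regime
    n = n.astype(np.int64).copy()
    t_rem = np.full(n.shape, duration)
    while True:
        rate = 2.0 * lam * n
        active = rate > 0
        if not active.any():
            break
        dt = np.full(n.shape, np.inf)
        dt[active] = rng.exponential(1.0 / rate[active])
        event = dt < t_rem
        if not event.any():
            break
        births = rng.random(n.shape) < 0.5
        n[event & births] += 1
        n[event & ~births] -= 1
        t_rem[event] -= dt[event]
        t_rem[~event] = 0.0
    return n


def simulate_bd_branch(
    i: int, lam: float, t: float, n_replicates: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo draws of the child count from i parent copies."""
    rng = np.random.default_rng(seed)
    start = np.full(n_replicates, i, dtype=np.int64)
    return _evolve_counts(start, lam, t, rng)


def simulate_family_counts(
    tree: dendropy.Tree,
    lam: float | dict[int, float],
    n_families: int,
    seed: int,
    focal: str | None = None,
    root_p: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Family counts evolved along an ultrametric tree, with true history.

    ``lam`` is a single rate or a {0: background, 1: focal-branch} map
    (the two-lambda generative setting).  Root sizes are geometric
    (success probability ``root_p``), conditioned >= 1 by construction.
    Returns (tip count table, internal-node state table); internal node
    names match :func:`adaptscan.gene_families.compile_ultrametric`.
    """
    lambdas = lam if isinstance(lam, dict) else {0: lam, 1: lam}
    ct = compile_ultrametric(tree, focal)
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {
        ct.root: rng.geometric(root_p, size=n_families).astype(np.int64)
    }
    for node, children in reversed(ct.postorder):
        for child, eidx in children:
            lam_c = lambdas[int(ct.edge_class[eidx])]
            states[child] = _evolve_counts(
                states[node], lam_c, ct.edge_duration[eidx], rng
            )
    fam_ids = [f"F{i + 1:04d}" for i in range(n_families)]
    tips = pd.DataFrame(
        {sp: states[i] for i, sp in ct.tip_species.items()}, index=fam_ids
    )
    internals = pd.DataFrame(
        {
            ct.node_labels[i]: states[i]
            for i in states
            if i not in ct.tip_species
        },
        index=fam_ids,
    )
    tips.index.name = "family"
    internals.index.name = "family"
    return tips, internals


# ---------------------------------------------------------------------------
# Full planted cohort


@dataclass
class CohortSpec:
    """Study conditions for the default synthetic cohort.

    Shapes mirror the real analysis at desk scale: a 19-species panel
    with one focal lineage, 100-codon orthogroup alignments, and a
    two-rate gene-family process on a 120-My-deep ultrametric species
    tree.  ``n_msa_planted`` orthogroups carry two planted signatures
    (elevated focal divergence and deleterious focal-unique
    substitutions); all other orthogroups evolve under the neutral
    branch-site null.
    """

    seed: int = 42
    n_taxa: int = 19
    focal: str = "FOCAL"
    n_orthogroups: int = 50
    n_incomplete: int = 5
    n_codons: int = 100
    n_msa_planted: int = 3
    focal_scale: float = 6.0
    kappa: float = 2.0
    omega0: float = 0.1
    p0: float = 0.80
    p1: float = 0.15
    planted_subs: int = 3
    tree_height: float = 0.5  # root-to-tip height, substitutions/codon site
    edge_rate_sd: float = 0.25  # per-edge lognormal rate jitter (sdlog)
    gene_rate_sd: float = 0.3  # per-gene lognormal rate factor (sdlog)
    divergence_margin: float = 1.2  # planted focal root-to-tip vs max background
    gap_block_ogs: int = 5
    n_families: int = 200
    lambda_background: float = 0.002  # events/gene/My
    lambda_focal: float = 0.004
    tree_depth: float = 120.0


# planted substitution: Gly background -> Trp focal (BLOSUM62 score -2)
_PLANT_BG_CODON = "GGG"
_PLANT_FG_CODON = "TGG"


def _ensure_focal_most_divergent(
    tree: dendropy.Tree, focal: str, margin: float
) -> None:
    """Extend the focal terminal branch until the planted elevated
    divergence holds with the requested margin over every other tip.

    Planting a signature means making its condition true by
    construction; the focal-branch scale factor alone cannot guarantee
    it on every jitter draw.
    """
    depths: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        parent = depths.get(id(node.parent_node), 0.0)
        depths[id(node)] = parent + (node.edge.length or 0.0)
    focal_leaf = tree.find_node_with_taxon_label(focal)
    others = max(
        depths[id(l)] for l in tree.leaf_node_iter() if l is not focal_leaf
    )
    want = margin * others
    if depths[id(focal_leaf)] < want:
        focal_leaf.edge.length += want - depths[id(focal_leaf)]


def simulate_cohort(outdir: str | Path, spec: CohortSpec | None = None) -> Path:
    """Write a complete fixture directory for the whole pipeline.

    Layout: ``orthogroups.tsv``, ``proteins/``, ``cds/``,
    ``alignments/``, ``trees/``, ``species_tree_ultrametric.nwk``,
    ``family_counts.tsv``, ``family_truth.tsv``, ``ground_truth.tsv``
    and ``simulation.json`` (the full spec, seed included).
    """
    spec = spec or CohortSpec()
    out = Path(outdir)
    for sub in ("proteins", "cds", "alignments", "trees"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    species = [f"S{i:02d}" for i in range(1, spec.n_taxa)] + [spec.focal]
    null_params = CodonModelParams(
        kappa=spec.kappa,
        omega0=spec.omega0,
        omega2=1.0,
        p0=spec.p0,
        p1=spec.p1,
    )
    table = OrthogroupTable(species=list(species))
    truth_rows = []
    planted_ogs = [f"OG{i + 1:04d}" for i in range(spec.n_msa_planted)]
    # clock-like base topology (a species tree) so per-gene rate jitter,
    # not tree shape, controls which tip is most divergent
    base_tree = simulate_tree(
        spec.n_taxa,
        seed=spec.seed + 7,
        focal=spec.focal,
        labels=list(species),
        shape="coalescent",
        depth=spec.tree_height,
    )
    # put the focal species on the shortest terminal branch (a label
    # swap, valid by coalescent exchangeability): like the real focal
    # lineage, it has close relatives in the panel, so elevated focal
    # divergence in a null orthogroup is rare rather than a 1-in-n_taxa
    # coin flip
    leaves = list(base_tree.leaf_node_iter())
    shortest = min(leaves, key=lambda l: l.edge.length)
    focal_leaf = next(l for l in leaves if l.taxon.label == spec.focal)
    shortest.taxon.label, focal_leaf.taxon.label = (
        focal_leaf.taxon.label,
        shortest.taxon.label,
    )
    for i in range(spec.n_orthogroups):
        og = f"OG{i + 1:04d}"
        planted = og in planted_ogs
        og_seed = int(rng.integers(0, 2**31 - 1))
        tree = jitter_tree(
            base_tree,
            seed=og_seed,
            focal=spec.focal,
            focal_scale=spec.focal_scale if planted else 1.0,
            edge_sd=spec.edge_rate_sd,
            rate_sd=spec.gene_rate_sd,
        )
        if planted:
            _ensure_focal_most_divergent(tree, spec.focal, spec.divergence_margin)
        aln, _ = simulate_codon_alignment(
            tree, null_params, spec.n_codons, seed=og_seed + 1
        )
        planted_cols: list[int] = []
        if planted:
            cols = rng.choice(
                np.arange(12, spec.n_codons - 12), spec.planted_subs, replace=False
            )
            planted_cols = sorted(int(c) for c in cols)
            new_rows = []
            for rec in aln.records:
                seq = list(rec.seq)
                codon = (
                    _PLANT_FG_CODON if rec.id == spec.focal else _PLANT_BG_CODON
                )
                for c in planted_cols:
                    seq[3 * c : 3 * c + 3] = codon
                new_rows.append(SeqRecord(rec.id, "".join(seq)))
            aln = Alignment(new_rows, "codon")
        genes = {sp: f"{og}_{sp}" for sp in species}
        # one species carries a shorter decoy isoform to exercise the
        # longest-isoform rule
        decoy_sp = species[int(rng.integers(0, len(species) - 1))]
        gap_og = (not planted) and i >= spec.n_orthogroups - spec.gap_block_ogs
        proteins, cds_records, aligned = [], [], []
        for rec in aln.records:
            gid = genes[rec.id]
            codon_row = rec.seq
            if gap_og and rec.id == decoy_sp:
                # delete a codon block from this gene: gaps in the
                # alignment, consistent with its CDS
                start = int(rng.integers(5, spec.n_codons - 10))
                width = 3
                codon_row = (
                    codon_row[: 3 * start]
                    + "-" * (3 * width)
                    + codon_row[3 * (start + width) :]
                )
            nt = codon_row.replace("-", "")
            protein = str(Seq(nt).translate())
            proteins.append(SeqRecord(gid, protein))
            cds_records.append(SeqRecord(gid, nt + "TAA"))
            prot_aligned = "".join(
                "-"
                if codon_row[3 * k] == "-"
                else protein[len(codon_row[: 3 * k].replace("-", "")) // 3]
                for k in range(spec.n_codons)
            )
            aligned.append(SeqRecord(gid, prot_aligned))
            if rec.id == decoy_sp:
                short = protein[: max(10, len(protein) // 2)]
                decoy_id = f"{gid}_short"
                proteins.append(SeqRecord(decoy_id, short))
                cds_records.append(
                    SeqRecord(decoy_id, nt[: 3 * len(short)] + "TAA")
                )
        table.rows[og] = {
            sp: [genes[sp]] + ([f"{genes[sp]}_short"] if sp == decoy_sp else [])
            for sp in species
        }
        write_fasta(proteins, out / "proteins" / f"{og}.faa")
        write_fasta(cds_records, out / "cds" / f"{og}.fna")
        write_alignment(
            Alignment(aligned, "protein"), out / "alignments" / f"{og}.protein.fasta"
        )
        write_newick_file(tree, out / "trees" / f"{og}.nwk")
        truth_rows.append(
            {
                "orthogroup": og,
                "divergence_planted": planted,
                "substitution_planted": planted,
                "planted_columns": ";".join(str(c + 1) for c in planted_cols),
                "msa_expected": planted,
            }
        )
    # incomplete orthogroups: rows only, dropped by the completeness filter
    for i in range(spec.n_incomplete):
        og = f"OG{spec.n_orthogroups + i + 1:04d}"
        missing = species[int(rng.integers(0, len(species)))]
        table.rows[og] = {
            sp: [] if sp == missing else [f"{og}_{sp}"] for sp in species
        }
    write_orthogroup_table(table, out / "orthogroups.tsv")

    sp_tree = simulate_tree(
        spec.n_taxa,
        seed=spec.seed + 101,
        focal=spec.focal,
        labels=list(species),
        ultrametric=True,
        depth=spec.tree_depth,
        mean_branch=spec.tree_depth / 4,
    )
    write_newick_file(sp_tree, out / "species_tree_ultrametric.nwk")
    counts, internals = simulate_family_counts(
        sp_tree,
        {0: spec.lambda_background, 1: spec.lambda_focal},
        spec.n_families,
        seed=spec.seed + 202,
        focal=spec.focal,
    )
    counts.reset_index().to_csv(out / "family_counts.tsv", sep="\t", index=False)
    internals.reset_index().to_csv(out / "family_truth.tsv", sep="\t", index=False)
    write_tsv(
        pd.DataFrame(truth_rows), out / "ground_truth.tsv", {"seed": spec.seed}
    )
    with open(out / "simulation.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return out
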