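"""Synthetic post-duplication genomes with full ground truth.

Every pillar starts fully duplicated (state U) at the root of the species
tree and evolves by exact stochastic (Gillespie) simulation of the
six-state loss model down every branch, so the truth table carries exact
per-branch event histories, not just endpoint states.  Per genome, the
assignment of subgenomes to physical tracks flips between adjacent
pillars with probability theta; each flip breaks both physical contigs,
mirroring how rearrangements sever double-conserved synteny.

Synthetic gene ids follow the grammar ``<genome>_p<pillar>_s<subgenome>``
(e.g. ``sp03_p00017_s2``) so truth joins never need a lookup table; the
outgroup carries one anchor gene ``anc<pillar>`` per pillar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dcs_pipeline import AncestralOrder, Pillar, track_links
from .io_formats import (
    EXPRESSION_CLUSTERS,
    AnnotationTables,
    GenomeGeneOrder,
    HomologyRecord,
    PhyloTree,
    ValidationError,
)
from .wgd_model import STATES, U, F, C1, C2, S1, S2, WGDModelSpec, build_rate_matrix

logger = logging.getLogger("wgdloss.sim")

__all__ = [
    "SimulatedDataset",
    "TruthTable",
    "AnnotationEffectConfig",
    "two_clade_tree",
    "simulate_dataset",
    "replicate_from_template",
    "simulate_annotations",
]


def two_clade_tree(
    n_leaves: int = 8, branch_length: float = 0.3, root_branch: float = 0.3
) -> PhyloTree:
    """Species tree used by default: an explicit root branch from the
    duplication to the first speciation, which splits a two-leaf clade
    from a ladder holding the remaining leaves.  All branch lengths equal
    ``branch_length`` except the root branch."""
    if n_leaves < 2:
        raise ValidationError("need at least two leaves")
    names = [f"sp{i + 1:02d}" for i in range(n_leaves)]
    b = f":{branch_length:g}"
    cladeA = f"({names[0]}{b},{names[1]}{b})"
    rest = names[2:]
    if not rest:
        inner = cladeA
    else:
        ladder = rest[-1] + b
        for nm in reversed(rest[:-1]):
            ladder = f"({nm}{b},{ladder}){b}"
        inner = f"({cladeA}{b},{ladder})"
    newick = f"({inner}:{root_branch:g});"
    return PhyloTree.from_newick(newick)


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Exact simulation record.

    ``bits`` is (n_pillars, n_genomes) over the sorted genome order: bit 0
    means the genome's track 1 holds the subgenome-1 gene at that pillar.
    ``leaf_states`` holds the model state reached at each leaf.
    ``events`` lists every state transition with its branch (tree node),
    pillar and time along the branch.  ``flip_junctions`` maps genome to
    the junction indices (left pillar position) where the tracking
    flipped.
    """

    genome_order: list[str]
    bits: np.ndarray
    leaf_states: pd.DataFrame
    node_states: dict[int, np.ndarray]
    events: pd.DataFrame
    flip_junctions: dict[str, np.ndarray]

    def branch_loss_counts(self) -> pd.DataFrame:
        """True per-branch counts of entries into S1 and S2."""
        ev = self.events
        rows = []
        for node, sub in ev.groupby("node"):
            rows.append(
                {
                    "node": node,
                    "entries_S1": int((sub["to_state"] == "S1").sum()),
                    "entries_S2": int((sub["to_state"] == "S2").sum()),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    """A simulated outgroup + polyploid genomes with truth attached."""

    outgroup: GenomeGeneOrder
    genomes: dict[str, GenomeGeneOrder]
    pillars: list[Pillar]
    order: AncestralOrder
    homologs: dict[str, list[HomologyRecord]]
    truth: TruthTable
    tree: PhyloTree
    spec: WGDModelSpec
    theta: float
    contig_lengths: list[int]


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------


def _evolve_branch(
    states: np.ndarray,
    b: float,
    Q: np.ndarray,
    rng: np.random.Generator,
    node: int,
    events: list[tuple[int, int, float, int, int]],
) -> np.ndarray:
    """Gillespie simulation of one branch for all pillars at once.

    Only a bounded number of rounds is ever needed because F, S1 and S2
    are absorbing and U can pass through at most one converging state.
    """
    rates = -np.diag(Q)
    cur = states.copy()
    t = np.zeros(len(cur))
    while True:
        active = (rates[cur] > 0) & (t < b)
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        r = rates[cur[idx]]
        t[idx] += rng.exponential(1.0 / r)
        moved = idx[t[idx] <= b]
        # snapshot before mutating so a pillar moves at most once per round
        moved_states = cur[moved].copy()
        for s in np.unique(moved_states):
            sel = moved[moved_states == s]
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            dest = rng.choice(6, size=len(sel), p=probs)
            for p, d in zip(sel, dest):
                events.append((node, int(p), float(t[p]), int(s), int(d)))
            cur[sel] = dest
    return cur


def _simulate_states(
    tree: PhyloTree, Q: np.ndarray, n_pillars: int, rng: np.random.Generator
) -> tuple[dict[int, np.ndarray], list[tuple[int, int, float, int, int]]]:
    node_states: dict[int, np.ndarray] = {
        tree.root: np.full(n_pillars, U, dtype=np.int64)
    }
    events: list[tuple[int, int, float, int, int]] = []
    for node in reversed(tree.postorder):
        node = int(node)
        if node == tree.root:
            continue
        parent = int(tree.parent[node])
        node_states[node] = _evolve_branch(
            node_states[parent], float(tree.branch_length[node]), Q, rng, node, events
        )
    return node_states, events


def _contig_of_pillar(contig_lengths: Sequence[int]) -> np.ndarray:
    return np.repeat(np.arange(len(contig_lengths)), contig_lengths)


def simulate_dataset(
    spec: WGDModelSpec,
    tree: PhyloTree,
    theta: float,
    contig_lengths: Sequence[int],
    seed: int = 0,
    extra_boundaries: Mapping[str, Sequence[int]] | None = None,
    outgroup_id: str = "outgroup",
    build_genomes: bool = True,
) -> SimulatedDataset:
    """Simulate a pillar dataset under the loss model and tracking flips.

    ``contig_lengths`` partitions the pillars into ancestral contigs.
    ``extra_boundaries`` optionally forces additional per-genome contig
    breaks at given junction indices (used to replay a template's synteny
    scaffold).  Returns genomes, pillars with slot assignments, an
    identity ancestral order and the full truth table.  With
    ``build_genomes=False`` only the pillars and truth are produced (the
    gene-order files do not enter the likelihood), which speeds up large
    replicate loops.
    """
    if not (0.0 <= theta <= 0.5):
        raise ValidationError(f"theta must lie in [0, 0.5], got {theta}")
    contig_lengths = [int(x) for x in contig_lengths]
    if not contig_lengths or any(x <= 0 for x in contig_lengths):
        raise ValidationError("contig_lengths must be positive and non-empty")
    n_pillars = int(sum(contig_lengths))
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(spec)
    node_states, events = _simulate_states(tree, Q, n_pillars, rng)

    genome_order = sorted(tree.leaf_names.values())
    leaf_of = {name: node for node, name in tree.leaf_names.items()}
    anc_contig = _contig_of_pillar(contig_lengths)

    # tracking bits per genome: uniform start, flip with prob theta
    bits = np.zeros((n_pillars, len(genome_order)), dtype=np.int8)
    flip_junctions: dict[str, np.ndarray] = {}
    for g, gid in enumerate(genome_order):
        start = int(rng.integers(2))
        flips = rng.random(n_pillars - 1) < theta
        bits[:, g] = (start + np.concatenate([[0], np.cumsum(flips)])) % 2
        flip_junctions[gid] = np.nonzero(flips)[0]

    # anchors and outgroup genome
    anchors = [f"anc{i:05d}" for i in range(n_pillars)]
    out_contigs: dict[str, list[str]] = {}
    for c in range(len(contig_lengths)):
        sel = np.nonzero(anc_contig == c)[0]
        out_contigs[f"{outgroup_id}_c{c}"] = [anchors[i] for i in sel]
    outgroup = GenomeGeneOrder(genome_id=outgroup_id, contigs=out_contigs)

    # per-genome gene orders and pillar slots
    extra = {k: set(int(j) for j in v) for k, v in (extra_boundaries or {}).items()}
    pillar_slots: list[dict[str, list[str | None]]] = [
        {} for _ in range(n_pillars)
    ]
    genomes: dict[str, GenomeGeneOrder] = {}
    homologs: dict[str, list[HomologyRecord]] = {}
    for g, gid in enumerate(genome_order):
        states = node_states[leaf_of[gid]]
        contigs: dict[str, list[str]] = {}
        counter = 0
        tracks: tuple[list[str], list[str]] = ([], [])
        recs: list[HomologyRecord] = []

        def close_tracks():
            nonlocal counter, tracks
            for tr in tracks:
                if tr:
                    contigs[f"{gid}_c{counter}"] = list(tr)
                    counter += 1
            tracks = ([], [])

        forced = extra.get(gid, set())
        for i in range(n_pillars):
            if build_genomes and i > 0:
                new_contig = anc_contig[i] != anc_contig[i - 1]
                flipped = bits[i, g] != bits[i - 1, g]
                if new_contig or flipped or (i - 1) in forced:
                    close_tracks()
            surv = {U: (1, 2), F: (1, 2), C1: (1, 2), C2: (1, 2), S1: (1,), S2: (2,)}[
                int(states[i])
            ]
            pair: list[str | None] = [None, None]
            for s in surv:
                gene = f"{gid}_p{i:05d}_s{s}"
                track = (s - 1) if bits[i, g] == 0 else (2 - s)
                pair[track] = gene
                if build_genomes:
                    tracks[track].append(gene)
                    recs.append(
                        HomologyRecord(
                            query_gene=gene,
                            subject_gene=anchors[i],
                            evalue=1e-50,
                            pct_identity=80.0,
                            aln_len_fraction=0.9,
                            ka=0.2,
                        )
                    )
            pillar_slots[i][gid] = pair
        if build_genomes:
            close_tracks()
            genomes[gid] = GenomeGeneOrder(genome_id=gid, contigs=contigs)
            homologs[gid] = recs

    pillars = [
        Pillar(
            anchor=anchors[i],
            slots=pillar_slots[i],
            candidates={
                gid: {g for g in pillar_slots[i][gid] if g is not None}
                for gid in genome_order
            },
        )
        for i in range(n_pillars)
    ]
    order = AncestralOrder(permutation=np.arange(n_pillars))

    leaf_states = pd.DataFrame(
        {gid: [STATES[s] for s in node_states[leaf_of[gid]]] for gid in genome_order}
    )
    events_df = pd.DataFrame(
        events, columns=["node", "pillar", "time", "from_idx", "to_idx"]
    )
    events_df["from_state"] = [STATES[i] for i in events_df["from_idx"]]
    events_df["to_state"] = [STATES[i] for i in events_df["to_idx"]]
    truth = TruthTable(
        genome_order=genome_order,
        bits=bits,
        leaf_states=leaf_states,
        node_states=node_states,
        events=events_df,
        flip_junctions=flip_junctions,
    )
    return SimulatedDataset(
        outgroup=outgroup,
        genomes=genomes,
        pillars=pillars,
        order=order,
        homologs=homologs,
        truth=truth,
        tree=tree,
        spec=spec,
        theta=theta,
        contig_lengths=contig_lengths,
    )


def template_break_junctions(dataset: SimulatedDataset) -> dict[str, list[int]]:
    """Junctions (left pillar position) with a synteny break, per genome."""
    out: dict[str, list[int]] = {}
    perm = dataset.order.permutation
    for gid, genome in dataset.genomes.items():
        broken: set[int] = set()
        for track in (1, 2):
            for jl, _, _, _, ok in track_links(perm, dataset.pillars, genome, track):
                if not ok:
                    broken.add(jl)
        out[gid] = sorted(broken)
    return out


def replicate_from_template(
    template: SimulatedDataset,
    spec: WGDModelSpec,
    theta: float,
    seed: int = 0,
    build_genomes: bool = True,
) -> SimulatedDataset:
    """Re-simulate losses and flips on a template's synteny scaffold.

    The replicate re-uses the template's pillar count, ancestral contigs
    and per-genome break positions: at junctions where the template shows
    a break, the replicate's contigs also end there (the left contig
    absorbs any re-introduced duplicates), while fresh losses and
    theta-flips add their own breaks.
    """
    have_genomes = bool(template.genomes)
    if have_genomes and set(template.genomes) != set(template.truth.genome_order):
        raise ValidationError("template genomes and truth table disagree")
    boundaries = (
        template_break_junctions(template) if (build_genomes and have_genomes) else {}
    )
    return simulate_dataset(
        spec,
        template.tree,
        theta,
        template.contig_lengths,
        seed=seed,
        extra_boundaries=boundaries,
        build_genomes=build_genomes,
    )


# ---------------------------------------------------------------------------
# synthetic annotations
# ---------------------------------------------------------------------------

_DEFAULT_STAGES = (
    ("zygote", 0.0),
    ("cleavage", 0.75),
    ("blastula", 2.25),
    ("gastrula", 5.25),
    ("segmentation", 10.33),
    ("pharyngula", 24.0),
    ("hatching", 48.0),
    ("larval", 72.0),
)

_DEFAULT_CURRENCY = tuple(f"currency{i:02d}" for i in range(13))


@dataclass
class AnnotationEffectConfig:
    """Planted effect sizes for the synthetic annotation generator.

    Defaults mirror the contrasts the downstream tests measure in real
    data: ohnolog-vs-singleton expression-cluster membership rates follow
    the observed zebrafish proportions (maternal 0.03 vs 0.04, pre-MBT
    0.11 vs 0.17, zygotic 0.06 vs 0.05), essentiality rates 0.062 vs
    0.145 among phenotyped genes, and a reaction network of 150 reactions
    over 60 ordinary plus 13 currency metabolites.
    ``ohnolog_degree_exponent`` > 0 makes ohnolog products prefer
    high-degree reactions (0 plants no network effect).
    """

    cluster_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ohnolog": {"maternal": 0.03, "pre-MBT": 0.11, "zygotic": 0.06},
            "singleton": {"maternal": 0.04, "pre-MBT": 0.17, "zygotic": 0.05},
        }
    )
    stage_weights: dict[str, Sequence[float]] | None = None
    phenotyped_prob: float = 0.5
    essential_prob: dict[str, float] = field(
        default_factory=lambda: {"ohnolog": 0.062, "singleton": 0.145}
    )
    anatomy_locations: tuple[str, ...] = (
        "brain",
        "retina",
        "heart",
        "somite",
        "epidermis",
    )
    anatomy_prob: dict[str, float] = field(
        default_factory=lambda: {"ohnolog": 0.3, "singleton": 0.3}
    )
    n_reactions: int = 150
    n_metabolites: int = 60
    metabolites_per_reaction: int = 3
    currency_metabolites: tuple[str, ...] = _DEFAULT_CURRENCY
    currency_prob: float = 0.3
    reactions_per_gene: float = 1.5
    mapped_prob: float = 0.7
    ohnolog_degree_exponent: float = 0.0

    def __post_init__(self) -> None:
        for probs in self.cluster_probs.values():
            for cl, p in probs.items():
                if cl not in EXPRESSION_CLUSTERS:
                    raise ValidationError(f"unknown cluster {cl!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(f"cluster probability {p} outside [0,1]")
        for p in list(self.essential_prob.values()) + [
            self.phenotyped_prob,
            self.currency_prob,
            self.mapped_prob,
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0,1]")


def simulate_annotations(
    gene_sets: Mapping[str, Sequence[str]],
    effect_cfg: AnnotationEffectConfig | None = None,
    seed: int = 0,
) -> AnnotationTables:
    """Generate annotation tables with known planted effects.

    ``gene_sets`` maps set labels (``ohnolog``, ``singleton``; other
    labels fall back to singleton rates) to gene id lists.  Produces
    expression clusters, first-expression stages, anatomy, phenotype
    classes and a random reaction-metabolite network with gene mappings.
    """
    cfg = effect_cfg or AnnotationEffectConfig()
    rng = np.random.default_rng(seed)

    cluster_rows: list[tuple[str, str]] = []
    stage_rows: list[tuple[str, str, float]] = []
    anatomy_rows: list[tuple[str, str]] = []
    pheno_rows: list[tuple[str, str]] = []
    stage_names = [s for s, _ in _DEFAULT_STAGES]
    stage_hours = {s: h for s, h in _DEFAULT_STAGES}

    all_genes: list[tuple[str, str]] = []
    for label, genes in gene_sets.items():
        for g in genes:
            all_genes.append((label, g))

    for label, gene in all_genes:
        key = label if label in cfg.cluster_probs else "singleton"
        probs = cfg.cluster_probs.get(key, {})
        for cluster in EXPRESSION_CLUSTERS:
            if rng.random() < probs.get(cluster, 0.0):
                cluster_rows.append((gene, cluster))
                break
        weights = None
        if cfg.stage_weights is not None:
            weights = np.asarray(
                cfg.stage_weights.get(key, cfg.stage_weights.get("singleton")),
                dtype=float,
            )
        if weights is None:
            weights = np.ones(len(stage_names))
        weights = weights / weights.sum()
        st = stage_names[int(rng.choice(len(stage_names), p=weights))]
        stage_rows.append((gene, st, stage_hours[st]))
        if rng.random() < cfg.anatomy_prob.get(key, 0.3):
            loc = cfg.anatomy_locations[int(rng.integers(len(cfg.anatomy_locations)))]
            anatomy_rows.append((gene, loc))
        if rng.random() < cfg.phenotyped_prob:
            essential = rng.random() < cfg.essential_prob.get(key, 0.1)
            pheno_rows.append((gene, "lethal" if essential else "viable"))

    # reaction-metabolite bipartite graph
    ordinary = [f"met{i:03d}" for i in range(cfg.n_metabolites)]
    reactions = [f"rxn{i:04d}" for i in range(cfg.n_reactions)]
    rxn_mets: list[list[str]] = []
    for _ in reactions:
        mets = list(
            rng.choice(ordinary, size=min(cfg.metabolites_per_reaction, len(ordinary)),
                       replace=False)
        )
        if cfg.currency_metabolites and rng.random() < cfg.currency_prob:
            mets.append(
                cfg.currency_metabolites[
                    int(rng.integers(len(cfg.currency_metabolites)))
                ]
            )
        rxn_mets.append(mets)

    # degree of each reaction in the shared-metabolite graph (for planted
    # ohnolog preference)
    met_members: dict[str, list[int]] = {}
    for i, mets in enumerate(rxn_mets):
        for m in mets:
            if m not in cfg.currency_metabolites:
                met_members.setdefault(m, []).append(i)
    degree = np.zeros(len(reactions))
    for members in met_members.values():
        for i in members:
            degree[i] += len(members) - 1

    rxn_genes: list[list[str]] = [[] for _ in reactions]
    uniform = np.ones(len(reactions)) / len(reactions)
    biased = (1.0 + degree) ** cfg.ohnolog_degree_exponent
    biased = biased / biased.sum()
    for label, gene in all_genes:
        if rng.random() >= cfg.mapped_prob:
            continue
        k = 1 + rng.poisson(max(cfg.reactions_per_gene - 1.0, 0.0))
        key = label if label in cfg.essential_prob else "singleton"
        p = biased if key == "ohnolog" else uniform
        chosen = rng.choice(len(reactions), size=min(k, len(reactions)),
                            replace=False, p=p)
        for i in chosen:
            rxn_genes[int(i)].append(gene)

    reactions_df = pd.DataFrame(
        {
            "reaction": reactions,
            "metabolites": [";".join(m) for m in rxn_mets],
            "genes": [";".join(g) for g in rxn_genes],
        }
    )
    return AnnotationTables(
        first_stage=pd.DataFrame(stage_rows, columns=["gene", "stage", "hours"]),
        clusters=pd.DataFrame(cluster_rows, columns=["gene", "cluster"]),
        anatomy=pd.DataFrame(anatomy_rows, columns=["gene", "location"]),
        phenotypes=pd.DataFrame(pheno_rows, columns=["gene", "phenotype_class"]),
        reactions=reactions_df,
        currency_metabolites=list(cfg.currency_metabolites),
    )
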