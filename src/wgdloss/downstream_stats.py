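"""Gene-set contrasts and metabolic-network position statistics.

Proportion contrasts (expression clusters, first-expression stages,
anatomy, essentiality) use a 2x2 chi-square with the Yates continuity
correction and Benjamini-Hochberg control over families of tests.  The
metabolic network has biochemical reactions as nodes, an edge whenever
two reactions share a non-currency metabolite, and gene-level statistics
averaged over the reactions a gene's product catalyses; significance of
ohnolog-vs-singleton differences comes from a label randomisation in
which every ohnolog pair is first merged into a single entity so the
pairing structure is preserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    EXPRESSION_CLUSTERS,
    AnnotationTables,
    ValidationError,
)

logger = logging.getLogger("wgdloss.stats")

__all__ = [
    "GeneSet",
    "MetabolicNetwork",
    "yates_chisq_2x2",
    "bh_fdr",
    "cluster_contrast",
    "stage_profile",
    "anatomy_contrast",
    "build_network",
    "network_stats",
    "network_randomization_test",
    "essentiality_contrast",
    "ESSENTIAL_LABELS",
]

ESSENTIAL_LABELS = frozenset({"lethal", "dead", "inviable"})


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    """A named set of genes, optionally with ohnolog pairing.

    For ohnolog sets every member has exactly one partner recorded in
    ``partners``; singleton and loss sets carry no pairing.
    """

    name: str
    members: set[str] = field(default_factory=set)
    partners: dict[str, str] = field(default_factory=dict)

    def add(self, gene: str) -> None:
        self.members.add(gene)

    def add_pair(self, a: str, b: str) -> None:
        self.members.update((a, b))
        self.partners[a] = b
        self.partners[b] = a

    def pairs(self) -> list[tuple[str, str]]:
        seen: set[str] = set()
        out: list[tuple[str, str]] = []
        for a, b in self.partners.items():
            if a not in seen and b not in seen:
                out.append(tuple(sorted((a, b))))
                seen.update((a, b))
        return sorted(out)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


# ---------------------------------------------------------------------------
# chi-square and FDR
# ---------------------------------------------------------------------------


def yates_chisq_2x2(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> tuple[float, float]:
    """Continuity-corrected chi-square on a 2x2 proportion table.

    Tests equality of the proportions ``k1/n1`` and ``k2/n2``.  Each
    |O - E| is reduced by 0.5 (floored at 0) before squaring.  A zero
    margin makes the test undefined; the statistic is then 0 and p = 1,
    with a warning.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValidationError(
            f"invalid 2x2 counts ({k1}/{n1}, {k2}/{n2})"
        )
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn("degenerate 2x2 table (zero margin); p set to 1")
        return 0.0, 1.0
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# expression contrasts
# ---------------------------------------------------------------------------


def cluster_contrast(
    cluster_table: pd.DataFrame,
    set_a: GeneSet,
    set_b: GeneSet,
    correction: bool = True,
) -> pd.DataFrame:
    """Per-cluster membership contrast between two gene sets.

    For each expression cluster, the proportion of each set's genes
    observed in the cluster is compared with a Yates 2x2 chi-square.
    Genes outside ``set_a | set_b`` are ignored.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValidationError("both gene sets must be non-empty")
    in_cluster: dict[str, set[str]] = {c: set() for c in EXPRESSION_CLUSTERS}
    for _, row in cluster_table.iterrows():
        if row["cluster"] not in in_cluster:
            raise ValidationError(f"unknown cluster {row['cluster']!r}")
        in_cluster[row["cluster"]].add(row["gene"])
    n1, n2 = len(set_a), len(set_b)
    rows = []
    for cluster in EXPRESSION_CLUSTERS:
        k1 = len(in_cluster[cluster] & set_a.members)
        k2 = len(in_cluster[cluster] & set_b.members)
        stat, p = yates_chisq_2x2(k1, n1, k2, n2, correction=correction)
        rows.append(
            {
                "cluster": cluster,
                "set_a": set_a.name,
                "set_b": set_b.name,
                "k_a": k1,
                "n_a": n1,
                "prop_a": k1 / n1,
                "k_b": k2,
                "n_b": n2,
                "prop_b": k2 / n2,
                "chi2": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def stage_profile(
    first_stage_table: pd.DataFrame,
    ohno: GeneSet,
    sing: GeneSet,
    exclude_zygote: bool = False,
    zygote_stage: str = "zygote",
    correction: bool = True,
) -> pd.DataFrame:
    """Per-stage proportion of genes that retain an ohnolog partner.

    Stages are ordered by hours post-fertilisation.  Each stage's genes
    are tested (Yates 2x2) against all other analysed genes for the
    fraction falling in ``ohno`` rather than ``sing``, with a
    Benjamini-Hochberg correction across stages.  ``exclude_zygote``
    drops genes first expressed in the zygote stage, removing the strong
    early-expression bias before later-stage comparisons.  The same
    machinery serves the root-versus-tip loss-timing profile by passing
    those sets as ``ohno``/``sing``.
    """
    tab = first_stage_table.copy()
    known = ohno.members | sing.members
    tab = tab[tab["gene"].isin(known)]
    if exclude_zygote:
        tab = tab[tab["stage"] != zygote_stage]
    if len(tab) == 0:
        raise ValidationError("no analysable genes in the stage table")
    tab = tab.assign(in_first=tab["gene"].isin(ohno.members))
    n_all = len(tab)
    k_all = int(tab["in_first"].sum())
    rows = []
    stage_order = (
        tab[["stage", "hours"]].drop_duplicates().sort_values("hours")
    )
    for _, srow in stage_order.iterrows():
        sub = tab[tab["stage"] == srow["stage"]]
        k1, n1 = int(sub["in_first"].sum()), len(sub)
        k2, n2 = k_all - k1, n_all - n1
        if n2 == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = yates_chisq_2x2(k1, n1, k2, n2, correction=correction)
        rows.append(
            {
                "stage": srow["stage"],
                "hours": srow["hours"],
                "k_with_partner": k1,
                "n_stage": n1,
                "prop_with_partner": k1 / n1,
                "overall_prop": k_all / n_all,
                "chi2": stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"])
    return out


def anatomy_contrast(
    anatomy_table: pd.DataFrame,
    set_a: GeneSet,
    set_b: GeneSet,
    exclude_genes: Iterable[str] = (),
    correction: bool = True,
) -> pd.DataFrame:
    """Per-location expression contrast between two gene sets.

    For each anatomical location (or each (stage, location) cell when a
    ``stage`` column is present) the proportion of each set's genes
    expressed there is compared by a Yates 2x2 chi-square, with a
    Benjamini-Hochberg correction across all cells.  ``exclude_genes``
    removes genes (typically zygote-expressed ones) from both sets
    before testing.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValidationError("both gene sets must be non-empty")
    excluded = set(exclude_genes)
    members_a = set_a.members - excluded
    members_b = set_b.members - excluded
    if not members_a or not members_b:
        raise ValidationError("exclusion emptied a gene set")
    keys = ["location"] if "stage" not in anatomy_table.columns else [
        "stage", "location"
    ]
    tab = anatomy_table[~anatomy_table["gene"].isin(excluded)]
    rows = []
    n1, n2 = len(members_a), len(members_b)
    for key_vals, sub in tab.groupby(keys):
        genes = set(sub["gene"])
        k1 = len(genes & members_a)
        k2 = len(genes & members_b)
        stat, p = yates_chisq_2x2(k1, n1, k2, n2, correction=correction)
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update(
            {
                "k_a": k1, "n_a": n1, "prop_a": k1 / n1,
                "k_b": k2, "n_b": n2, "prop_b": k2 / n2,
                "chi2": stat, "p": p,
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = bh_fdr(out["p"])
    return out


def essentiality_contrast(
    phenotype_table: pd.DataFrame,
    ohno: GeneSet,
    sing: GeneSet,
    essential_labels: Iterable[str] = ESSENTIAL_LABELS,
    correction: bool = True,
) -> pd.DataFrame:
    """Essential-gene proportion among phenotyped ohnologs vs singletons.

    Only genes with a phenotype record enter the denominators; a gene is
    essential when any of its phenotype classes is in
    ``essential_labels``.
    """
    labels = {s.lower() for s in essential_labels}
    tab = phenotype_table.assign(
        essential=phenotype_table["phenotype_class"].str.lower().isin(labels)
    )
    ess_by_gene = tab.groupby("gene")["essential"].any()
    rows = []
    for gs in (ohno, sing):
        phenotyped = [g for g in gs.members if g in ess_by_gene.index]
        if not phenotyped:
            raise ValidationError(f"no phenotyped genes in set {gs.name!r}")
        k = int(ess_by_gene.loc[phenotyped].sum())
        rows.append((gs.name, k, len(phenotyped)))
    (name1, k1, n1), (name2, k2, n2) = rows
    stat, p = yates_chisq_2x2(k1, n1, k2, n2, correction=correction)
    return pd.DataFrame(
        [
            {
                "set_a": name1,
                "k_a": k1,
                "n_a": n1,
                "prop_a": k1 / n1,
                "set_b": name2,
                "k_b": k2,
                "n_b": n2,
                "prop_b": k2 / n2,
                "chi2": stat,
                "p": p,
            }
        ]
    )


# ---------------------------------------------------------------------------
# metabolic network
# ---------------------------------------------------------------------------


@dataclass
class MetabolicNetwork:
    """Reaction-node network with gene-to-reaction mapping.

    Nodes are reactions; an undirected edge joins two reactions sharing
    at least one non-currency metabolite.  Currency metabolites induce no
    edges and self-edges are never created.
    """

    graph: nx.Graph
    gene_to_reactions: dict[str, set[str]]
    currency_metabolites: list[str]


def build_network(
    reaction_table: pd.DataFrame, currency_list: Iterable[str] = ()
) -> MetabolicNetwork:
    """Build the shared-metabolite reaction network.

    ``reaction_table`` columns: reaction, metabolites (';'-joined),
    genes (';'-joined, may be empty).
    """
    currency = {str(m) for m in currency_list}
    graph = nx.Graph()
    met_members: dict[str, list[str]] = {}
    gene_to_reactions: dict[str, set[str]] = {}
    for _, row in reaction_table.iterrows():
        rxn = row["reaction"]
        graph.add_node(rxn)
        mets = [m for m in str(row["metabolites"]).split(";") if m]
        for m in mets:
            if m not in currency:
                met_members.setdefault(m, []).append(rxn)
        genes = [] if pd.isna(row.get("genes")) else str(row["genes"]).split(";")
        for g in genes:
            if g:
                gene_to_reactions.setdefault(g, set()).add(rxn)
    for members in met_members.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a != b:
                    graph.add_edge(a, b)
    return MetabolicNetwork(
        graph=graph,
        gene_to_reactions=gene_to_reactions,
        currency_metabolites=sorted(currency),
    )


def _shortest_path_counts(graph: nx.Graph) -> dict[str, float]:
    """Number of shortest paths passing through each node.

    For node v this sums, over unordered pairs (s, t) with s, t != v and
    d(s,v) + d(v,t) = d(s,t), the number of distinct shortest s-t paths
    through v (sigma_s(v) * sigma_v(t)).  It is betweenness accounting in
    raw path counts rather than pair fractions.
    """
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for s in nodes:
        si = index[s]
        # BFS with shortest-path counting (Brandes forward pass)
        dist = {s: 0}
        sigma = {s: 1.0}
        queue = [s]
        while queue:
            v = queue.pop(0)
            for w in graph.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        for v, d in dist.items():
            D[si, index[v]] = d
            S[si, index[v]] = sigma[v]
    counts: dict[str, float] = {}
    for v in nodes:
        vi = index[v]
        through = np.outer(S[:, vi], S[vi, :])
        on_path = (D[:, vi][:, None] + D[vi, :][None, :]) == D
        valid = on_path & np.isfinite(D)
        valid[vi, :] = False
        valid[:, vi] = False
        total = float(through[valid].sum()) / 2.0  # unordered pairs
        counts[v] = total
    return counts


def network_stats(
    net: MetabolicNetwork,
    gene_set: GeneSet,
    merge_pairs: bool = True,
) -> pd.DataFrame:
    """Degree, clustering and shortest-path-count means per gene entity.

    A gene's value for each statistic is the mean over the reaction nodes
    it maps to; unmapped genes are excluded (logged).  When the set
    carries ohnolog pairs and ``merge_pairs`` is set, each pair is merged
    into one entity mapped to the union of the two genes' reactions
    before averaging, preserving the duplication structure.
    """
    node_stats = node_statistics(net)
    entities = _entities(net, gene_set, merge_pairs)
    if not entities:
        raise ValidationError(
            f"no genes of set {gene_set.name!r} map to network reactions"
        )
    rows = []
    for name, rxns in entities:
        sub = node_stats.loc[sorted(rxns)]
        rows.append(
            {
                "entity": name,
                "n_reactions": len(rxns),
                "degree": sub["degree"].mean(),
                "clustering": sub["clustering"].mean(),
                "shortest_path_count": sub["shortest_path_count"].mean(),
            }
        )
    return pd.DataFrame(rows)


def node_statistics(net: MetabolicNetwork) -> pd.DataFrame:
    """Per-reaction degree, clustering coefficient and raw path count."""
    graph = net.graph
    degree = dict(graph.degree())
    clustering = nx.clustering(graph)
    paths = _shortest_path_counts(graph)
    return pd.DataFrame(
        {
            "degree": pd.Series(degree, dtype=float),
            "clustering": pd.Series(clustering, dtype=float),
            "shortest_path_count": pd.Series(paths, dtype=float),
        }
    ).sort_index()


def _entities(
    net: MetabolicNetwork, gene_set: GeneSet, merge_pairs: bool
) -> list[tuple[str, set[str]]]:
    """Mapped entities of a set: merged ohnolog pairs, then lone genes."""
    mapped = net.gene_to_reactions
    entities: list[tuple[str, set[str]]] = []
    used: set[str] = set()
    n_unmapped = 0
    if merge_pairs:
        for a, b in gene_set.pairs():
            rxns = mapped.get(a, set()) | mapped.get(b, set())
            used.update((a, b))
            if rxns:
                entities.append((f"{a}+{b}", set(rxns)))
            else:
                n_unmapped += 1
    for g in sorted(gene_set.members - used):
        rxns = mapped.get(g, set())
        if rxns:
            entities.append((g, set(rxns)))
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info(
            "network entities (%s): %d unmapped entities excluded",
            gene_set.name,
            n_unmapped,
        )
    return entities


def network_randomization_test(
    net: MetabolicNetwork,
    ohno: GeneSet,
    sing: GeneSet,
    statistic: str = "degree",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Merged-pair label randomisation for one network statistic.

    Ohnolog pairs are merged into single entities (union of reaction
    assignments), then the ohnolog/singleton labels are permuted over all
    entities with node assignments held fixed.  Two-sided on the absolute
    difference of means, with an add-one Monte-Carlo p-value.

    Returns ``(mean_ohno, mean_sing, p)``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    if statistic not in ("degree", "clustering", "shortest_path_count"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    node_stats = node_statistics(net)
    values: list[float] = []
    labels: list[int] = []
    for is_ohno, gs in ((1, ohno), (0, sing)):
        for _, rxns in _entities(net, gs, merge_pairs=bool(is_ohno)):
            values.append(float(node_stats.loc[sorted(rxns), statistic].mean()))
            labels.append(is_ohno)
    values_arr = np.asarray(values)
    labels_arr = np.asarray(labels, dtype=bool)
    n_ohno = int(labels_arr.sum())
    if n_ohno == 0 or n_ohno == len(labels_arr):
        raise ValidationError("need both ohnolog and singleton entities")
    mean_o = float(values_arr[labels_arr].mean())
    mean_s = float(values_arr[~labels_arr].mean())
    observed = abs(mean_o - mean_s)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(values_arr))
        sel = np.zeros(len(values_arr), dtype=bool)
        sel[perm[:n_ohno]] = True
        diff = abs(values_arr[sel].mean() - values_arr[~sel].mean())
        if diff >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return mean_o, mean_s, float(p)
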