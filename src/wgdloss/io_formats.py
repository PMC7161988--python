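"""Readers and writers for the files the pipeline touches.

All tabular files are tab-delimited UTF-8 with a header row; lines starting
with ``#`` are comments.  Gene coordinates are positional ranks within a
contig (1-based on disk, 0-based in memory).  Strand, if present, is read
and ignored: none of the downstream computations use orientation.

Trees are Newick.  The root of a species tree represents the duplication
event itself; a unifurcating root is allowed (its single edge is the shared
"root branch" from the duplication to the first speciation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("wgdloss.io")

__all__ = [
    "GenomeGeneOrder",
    "HomologyRecord",
    "PhyloTree",
    "AnnotationTables",
    "read_gene_orders",
    "read_all_gene_orders",
    "write_gene_orders",
    "read_homology_table",
    "write_homology_table",
    "read_tree",
    "write_synteny_relationships",
    "read_annotation_tables",
    "write_annotation_tables",
]


class ParseError(ValueError):
    """A malformed input file (reported with the offending line number)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# gene orders
# ---------------------------------------------------------------------------


@dataclass
class GenomeGeneOrder:
    """Ordered gene content of one genome.

    ``contigs`` maps contig name to the ordered list of gene ids on it.
    Gene ids must be unique within the genome and every contig non-empty.
    """

    genome_id: str
    contigs: dict[str, list[str]]
    _index: dict[str, tuple[str, int]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self._index = {}
        for contig, genes in self.contigs.items():
            if not genes:
                raise ValidationError(
                    f"genome {self.genome_id!r}: contig {contig!r} is empty"
                )
            for pos, g in enumerate(genes):
                if g in self._index:
                    raise ValidationError(
                        f"genome {self.genome_id!r}: duplicate gene id {g!r}"
                    )
                self._index[g] = (contig, pos)

    @property
    def n_genes(self) -> int:
        return len(self._index)

    def location(self, gene: str) -> tuple[str, int]:
        """(contig, 0-based position) of ``gene``; KeyError if absent."""
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def genes(self) -> Iterable[str]:
        return self._index.keys()

    def are_neighbors(self, a: str, b: str) -> bool:
        """True when the two genes are adjacent on the same contig.

        Orientation-blind and symmetric.
        """
        ca, pa = self._index[a]
        cb, pb = self._index[b]
        return ca == cb and abs(pa - pb) == 1


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_all_gene_orders(path: str | Path) -> dict[str, GenomeGeneOrder]:
    """Read a gene-order table that may hold several genomes.

    Expected header: ``genome  contig  position  gene`` (extra columns such
    as ``strand`` are ignored).  Within each (genome, contig), rows are
    sorted by position.
    """
    rows: list[tuple[str, str, int, str]] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if header is None:
            header = [p.strip().lower() for p in parts]
            for col in ("genome", "contig", "position", "gene"):
                if col not in header:
                    raise ParseError(
                        f"{path}: line {lineno}: missing column {col!r}"
                    )
            idx = {c: header.index(c) for c in ("genome", "contig", "position", "gene")}
            continue
        if len(parts) < len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
        try:
            pos = int(parts[idx["position"]])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: position is not an integer"
            ) from exc
        rows.append(
            (parts[idx["genome"]], parts[idx["contig"]], pos, parts[idx["gene"]])
        )
    if header is None:
        raise ParseError(f"{path}: empty file")

    out: dict[str, GenomeGeneOrder] = {}
    df = pd.DataFrame(rows, columns=["genome", "contig", "position", "gene"])
    for genome, sub in df.groupby("genome", sort=False):
        contigs: dict[str, list[str]] = {}
        for contig, csub in sub.groupby("contig", sort=False):
            contigs[contig] = list(csub.sort_values("position")["gene"])
        out[genome] = GenomeGeneOrder(genome_id=genome, contigs=contigs)
    logger.info("read %d gene-order rows (%d genomes) from %s", len(rows), len(out), path)
    return out


def read_gene_orders(path: str | Path) -> GenomeGeneOrder:
    """Read a gene-order file containing exactly one genome."""
    orders = read_all_gene_orders(path)
    if len(orders) != 1:
        raise ValidationError(
            f"{path}: expected one genome, found {sorted(orders)}"
        )
    return next(iter(orders.values()))


def write_gene_orders(
    genomes: GenomeGeneOrder | Sequence[GenomeGeneOrder], path: str | Path
) -> None:
    if isinstance(genomes, GenomeGeneOrder):
        genomes = [genomes]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("genome\tcontig\tposition\tgene\n")
        for gord in genomes:
            for contig, genes in gord.contigs.items():
                for pos, g in enumerate(genes, start=1):
                    fh.write(f"{gord.genome_id}\t{contig}\t{pos}\t{g}\n")


# ---------------------------------------------------------------------------
# homology table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyRecord:
    """One homolog hit between a polyploid gene and an outgroup gene.

    ``evalue`` is the BLAST expectation value, ``pct_identity`` the percent
    amino-acid identity in [0, 100], ``aln_len_fraction`` the alignment
    length divided by the mean length of the two genes, and ``ka`` the
    nonsynonymous divergence.  All must be finite and non-negative.
    """

    query_gene: str
    subject_gene: str
    evalue: float
    pct_identity: float
    aln_len_fraction: float
    ka: float

    def __post_init__(self) -> None:
        for name in ("evalue", "pct_identity", "aln_len_fraction", "ka"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValidationError(
                    f"homolog {self.query_gene}/{self.subject_gene}: "
                    f"{name}={v!r} must be finite and non-negative"
                )
        if self.pct_identity > 100:
            raise ValidationError(
                f"homolog {self.query_gene}/{self.subject_gene}: "
                f"pct_identity {self.pct_identity} > 100"
            )


_HOMOLOGY_COLS = [
    "query_gene",
    "subject_gene",
    "evalue",
    "pct_identity",
    "aln_len_fraction",
    "ka",
]


def read_homology_table(path: str | Path) -> list[HomologyRecord]:
    records: list[HomologyRecord] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if header is None:
            header = [p.strip() for p in parts]
            missing = [c for c in _HOMOLOGY_COLS if c not in header]
            if missing:
                raise ParseError(f"{path}: line {lineno}: missing columns {missing}")
            idx = {c: header.index(c) for c in _HOMOLOGY_COLS}
            continue
        if len(parts) < len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
        try:
            rec = HomologyRecord(
                query_gene=parts[idx["query_gene"]],
                subject_gene=parts[idx["subject_gene"]],
                evalue=float(parts[idx["evalue"]]),
                pct_identity=float(parts[idx["pct_identity"]]),
                aln_len_fraction=float(parts[idx["aln_len_fraction"]]),
                ka=float(parts[idx["ka"]]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        records.append(rec)
    if header is None:
        raise ParseError(f"{path}: empty file")
    return records


def write_homology_table(records: Iterable[HomologyRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_HOMOLOGY_COLS) + "\n")
        for r in records:
            fh.write(
                f"{r.query_gene}\t{r.subject_gene}\t{r.evalue:.6g}\t"
                f"{r.pct_identity:.6g}\t{r.aln_len_fraction:.6g}\t{r.ka:.6g}\n"
            )


# ---------------------------------------------------------------------------
# phylogenetic tree
# ---------------------------------------------------------------------------


class PhyloTree:
    """A rooted tree with branch lengths, in array form for fast pruning.

    The root is the duplication event.  Branch lengths are in units of the
    base duplicate-loss rate (the model's "alpha * t"): a length of 0.3
    means an expected 0.3 losses per retained duplicate through the less
    fractionated subgenome's base rate.

    Nodes are indexed 0..n_nodes-1 in a postorder; ``parent[i]`` is the
    parent index (-1 for the root) and ``branch_length[i]`` the length of
    the edge above node ``i`` (0 for the root).  Leaves carry names.
    """

    def __init__(
        self,
        parent: np.ndarray,
        branch_length: np.ndarray,
        leaf_names: dict[int, str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=float)
        self.leaf_names = dict(leaf_names)
        n = len(self.parent)
        if (self.parent == -1).sum() != 1:
            raise ValidationError("tree must have exactly one root")
        if not np.all(np.isfinite(self.branch_length)):
            raise ValidationError("all branch lengths must be finite")
        if np.any(self.branch_length < 0):
            raise ValidationError("branch lengths must be >= 0")
        self.root = int(np.where(self.parent == -1)[0][0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        for i in range(n):
            if not self.children[i] and i not in self.leaf_names:
                raise ValidationError(f"leaf node {i} has no name")
        # postorder check / recompute
        self.postorder = self._compute_postorder()

    def _compute_postorder(self) -> np.ndarray:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, require_lengths: bool = True, default_length: float = 0.1
    ) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ParseError(f"could not parse Newick tree: {exc}") from exc
        return cls.from_dendropy(
            dtree, require_lengths=require_lengths, default_length=default_length
        )

    @classmethod
    def from_dendropy(
        cls,
        dtree: dendropy.Tree,
        require_lengths: bool = True,
        default_length: float = 0.1,
    ) -> "PhyloTree":
        nodes = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        blen = np.zeros(len(nodes))
        leaf_names: dict[int, str] = {}
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    if require_lengths:
                        raise ValidationError(
                            "tree has a branch without a length; lengths are "
                            "required unless the tree only seeds an optimisation"
                        )
                    blen[i] = default_length
                else:
                    blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValidationError("leaf without a name")
                leaf_names[i] = nd.taxon.label.replace(" ", "_")
        return cls(parent, blen, leaf_names)

    # -- views --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def n_branches(self) -> int:
        """Number of edges (every node except the root subtends one)."""
        return self.n_nodes - 1

    @property
    def leaf_labels(self) -> list[str]:
        return [self.leaf_names[i] for i in sorted(self.leaf_names)]

    def leaf_index(self) -> dict[str, int]:
        return {name: i for i, name in self.leaf_names.items()}

    def with_branch_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        t = PhyloTree(self.parent.copy(), np.asarray(lengths, float), self.leaf_names)
        return t

    def branch_labels(self) -> list[str]:
        """Human-readable label for the edge above each non-root node."""
        labels = {}
        for i in range(self.n_nodes):
            if i in self.leaf_names:
                labels[i] = self.leaf_names[i]
        # internal nodes: join sorted descendant leaf names
        for i in self.postorder:
            if i not in labels:
                desc = sorted(
                    labels[c].split("+")[0] for c in self.children[i]
                )
                labels[i] = "+".join(
                    sorted(set().union(*(set(labels[c].split("+")) for c in self.children[i])))
                )
        return [labels[i] for i in range(self.n_nodes)]

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self.children[i]:
                s = self.leaf_names[i]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[i]) + ")"
            if self.parent[i] >= 0:
                s += f":{self.branch_length[i]:.6g}"
            return s

        return rec(self.root) + ";"


def read_tree(path: str | Path, require_lengths: bool = True) -> PhyloTree:
    """Read a rooted Newick tree whose leaves are genome ids."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return PhyloTree.from_newick(text, require_lengths=require_lengths)


# ---------------------------------------------------------------------------
# synteny relationships (S1-dataset style)
# ---------------------------------------------------------------------------


def write_synteny_relationships(order, pillars, genomes, path: str | Path) -> None:
    """Write per-genome synteny symbols for every adjacent pillar pair.

    One record per adjacent pillar pair per genome.  The symbol is ``<->``
    when both tracks are syntenic across the junction, ``|`` when exactly
    one track is broken and ``X`` when both are.  A track's link spanning a
    run of empty slots is attributed to the first junction it crosses, so
    the weighted count (``|`` = 1, ``X`` = 2) equals the genome's
    breakpoint count under the same order.
    """
    from .dcs_pipeline import track_links  # local import to avoid a cycle

    if isinstance(genomes, GenomeGeneOrder):
        genomes = [genomes]
    perm = np.asarray(order.permutation if hasattr(order, "permutation") else order)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "genome\tleft_anchor\tright_anchor\ttrack1_left\ttrack1_right\t"
            "track2_left\ttrack2_right\tsymbol\n"
        )
        for genome in genomes:
            broken = {1: set(), 2: set()}
            link_genes: dict[tuple[int, int], tuple[str, str]] = {}
            for track in (1, 2):
                for i_left, i_right, g_left, g_right, ok in track_links(
                    perm, pillars, genome, track
                ):
                    link_genes[(i_left, track)] = (g_left, g_right)
                    if not ok:
                        broken[track].add(i_left)
            for j in range(len(perm) - 1):
                left = pillars[perm[j]].anchor
                right = pillars[perm[j + 1]].anchor
                n_broken = (j in broken[1]) + (j in broken[2])
                symbol = {0: "<->", 1: "|", 2: "X"}[n_broken]
                cells = []
                for track in (1, 2):
                    pair = link_genes.get((j, track), ("", ""))
                    cells.extend(pair)
                fh.write(
                    f"{genome.genome_id}\t{left}\t{right}\t"
                    + "\t".join(cells)
                    + f"\t{symbol}\n"
                )


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

EXPRESSION_CLUSTERS = ("maternal", "pre-MBT", "zygotic")


@dataclass
class AnnotationTables:
    """Per-gene annotations and the metabolic reaction table.

    ``first_stage``: gene, stage, hours (first observed expression).
    ``clusters``: gene, cluster in {maternal, pre-MBT, zygotic}.
    ``anatomy``: gene, location (one row per observed location).
    ``phenotypes``: gene, phenotype_class.
    ``reactions``: reaction, metabolites (';'-joined), genes (';'-joined).
    ``currency_metabolites``: ubiquitous compounds excluded from network
    edges; may be empty.
    """

    first_stage: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "stage", "hours"])
    )
    clusters: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "cluster"])
    )
    anatomy: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "location"])
    )
    phenotypes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "phenotype_class"])
    )
    reactions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reaction", "metabolites", "genes"])
    )
    currency_metabolites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.clusters):
            bad = set(self.clusters["cluster"]) - set(EXPRESSION_CLUSTERS)
            if bad:
                raise ValidationError(f"unknown expression clusters: {sorted(bad)}")


_TABLE_FILES = {
    "first_stage": "first_stage.tsv",
    "clusters": "clusters.tsv",
    "anatomy": "anatomy.tsv",
    "phenotypes": "phenotypes.tsv",
    "reactions": "reactions.tsv",
}


def write_annotation_tables(tables: AnnotationTables, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        getattr(tables, attr).to_csv(directory / fname, sep="\t", index=False)
    with open(directory / "currency_metabolites.txt", "w", encoding="utf-8") as fh:
        for m in tables.currency_metabolites:
            fh.write(m + "\n")


def read_annotation_tables(directory: str | Path) -> AnnotationTables:
    directory = Path(directory)
    kwargs = {}
    for attr, fname in _TABLE_FILES.items():
        p = directory / fname
        if p.exists():
            kwargs[attr] = pd.read_csv(p, sep="\t", comment="#")
    currency_path = directory / "currency_metabolites.txt"
    currency: list[str] = []
    if currency_path.exists():
        with open(currency_path, encoding="utf-8") as fh:
            currency = [ln.strip() for ln in fh if ln.strip()]
    return AnnotationTables(currency_metabolites=currency, **kwargs)
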