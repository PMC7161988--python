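"""Pillar construction and ancestral gene-order optimisation.

A *pillar* is one ancestral pre-duplication locus: it is anchored by an
outgroup gene and holds up to two homolog slots per polyploid genome (the
two post-duplication tracks).  The ancestral order of pillars is unknown in
rearranged genomes and is sought by simulated annealing, scoring candidate
orders by the synteny they induce: a track's consecutive filled slots
should hold genes that are chromosomal neighbours.

The synteny score ``s`` of an order counts, over pillars and tracks, the
pairs (slot gene at position i, next filled slot gene on the same track at
position i + j, smallest j >= 1) that are adjacent on the same contig.
Breakpoints are the complementary count, so score + breakpoints equals the
number of evaluable track links.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .io_formats import GenomeGeneOrder, HomologyRecord, ValidationError

logger = logging.getLogger("wgdloss.dcs")

__all__ = [
    "Pillar",
    "AncestralOrder",
    "HomologyThresholds",
    "AnnealConfig",
    "filter_homologs",
    "build_pillars",
    "synteny_score",
    "count_breakpoints",
    "track_links",
    "optimize_order",
    "merge_and_retain",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Pillar:
    """One ancestral locus: an outgroup anchor plus per-genome slots.

    ``slots[genome]`` is a two-element list; each element is a gene id or
    None.  Slot index is the track (0-based internally, track 1/2 in
    reports).  ``candidates[genome]`` holds all surviving homologs of the
    anchor in that genome; every filled slot gene must be a candidate.
    """

    anchor: str
    slots: dict[str, list[str | None]] = field(default_factory=dict)
    candidates: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genome, pair in self.slots.items():
            if len(pair) != 2:
                raise ValidationError(
                    f"pillar {self.anchor}: genome {genome} needs exactly 2 slots"
                )
            cand = self.candidates.get(genome, set())
            for g in pair:
                if g is not None and cand and g not in cand:
                    raise ValidationError(
                        f"pillar {self.anchor}: slot gene {g} of {genome} "
                        "is not in the candidate set"
                    )

    def copy_state(self, genome: str) -> Literal["duplicated", "single", "absent"]:
        pair = self.slots.get(genome, [None, None])
        n = sum(g is not None for g in pair)
        return ("absent", "single", "duplicated")[n]

    def filled_slot(self, genome: str) -> int | None:
        """0-based track of the surviving gene for a single-copy genome."""
        pair = self.slots.get(genome, [None, None])
        for k, g in enumerate(pair):
            if g is not None:
                return k
        return None

    def genes(self, genome: str) -> list[str]:
        return [g for g in self.slots.get(genome, [None, None]) if g is not None]


@dataclass
class AncestralOrder:
    """A permutation of pillar indices with its per-genome synteny scores."""

    permutation: np.ndarray
    scores: dict[str, int] = field(default_factory=dict)
    breakpoints: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=np.int64)
        n = len(self.permutation)
        if sorted(self.permutation.tolist()) != list(range(n)):
            raise ValidationError("order must be a permutation of 0..n-1")

    @property
    def n_pillars(self) -> int:
        return len(self.permutation)

    def total_breakpoints(self) -> int:
        return int(sum(self.breakpoints.values()))

    def evaluate(
        self, pillars: Sequence[Pillar], genomes: Iterable[GenomeGeneOrder]
    ) -> "AncestralOrder":
        for genome in genomes:
            self.scores[genome.genome_id] = synteny_score(self, pillars, genome)
            self.breakpoints[genome.genome_id] = count_breakpoints(
                self, pillars, genome
            )
        return self


# ---------------------------------------------------------------------------
# homolog filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyThresholds:
    """Homology acceptance thresholds.

    A hit is kept iff E-value <= max_evalue, percent identity is strictly
    above min_pct_identity, the alignment covers at least
    min_aln_len_fraction of the genes' mean length, and the nonsynonymous
    divergence is strictly below max_ka.
    """

    max_evalue: float = 1e-8
    min_pct_identity: float = 60.0
    min_aln_len_fraction: float = 0.65
    max_ka: float = 0.6


def filter_homologs(
    records: Iterable[HomologyRecord],
    thresholds: HomologyThresholds | None = None,
) -> list[HomologyRecord]:
    """Apply the four homology criteria; log per-criterion rejections."""
    thr = thresholds or HomologyThresholds()
    kept: list[HomologyRecord] = []
    rejected = {"evalue": 0, "pct_identity": 0, "aln_len_fraction": 0, "ka": 0}
    for rec in records:
        ok = True
        if rec.evalue > thr.max_evalue:
            rejected["evalue"] += 1
            ok = False
        if rec.pct_identity <= thr.min_pct_identity:
            rejected["pct_identity"] += 1
            ok = False
        if rec.aln_len_fraction < thr.min_aln_len_fraction:
            rejected["aln_len_fraction"] += 1
            ok = False
        if rec.ka >= thr.max_ka:
            rejected["ka"] += 1
            ok = False
        if ok:
            kept.append(rec)
    logger.info(
        "filter_homologs: kept %d, rejections by criterion %s", len(kept), rejected
    )
    return kept


# ---------------------------------------------------------------------------
# synteny scoring
# ---------------------------------------------------------------------------


def track_links(
    permutation: np.ndarray,
    pillars: Sequence[Pillar],
    genome: GenomeGeneOrder,
    track: int,
) -> Iterator[tuple[int, int, str, str, bool]]:
    """Iterate the track's links under an order.

    For each pair of consecutive *filled* slots on ``track`` (1 or 2),
    yields ``(junction, right_pos, left_gene, right_gene, intact)`` where
    ``junction`` is the order position of the left pillar (the first
    junction the link crosses, to which any break is attributed) and
    ``intact`` is True when the two genes are contig-adjacent.
    """
    k = track - 1
    prev_pos: int | None = None
    prev_gene: str | None = None
    for pos, pil_idx in enumerate(permutation):
        g = pillars[pil_idx].slots.get(genome.genome_id, [None, None])[k]
        if g is None:
            continue
        if prev_gene is not None:
            yield prev_pos, pos, prev_gene, g, genome.are_neighbors(prev_gene, g)
        prev_pos, prev_gene = pos, g


def _perm_of(order: AncestralOrder | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(order, AncestralOrder):
        return order.permutation
    return np.asarray(order, dtype=np.int64)


def synteny_score(
    order: AncestralOrder | Sequence[int],
    pillars: Sequence[Pillar],
    genome: GenomeGeneOrder,
) -> int:
    """Number of intact track links of ``genome`` under the order."""
    perm = _perm_of(order)
    return sum(
        1
        for track in (1, 2)
        for *_, ok in track_links(perm, pillars, genome, track)
        if ok
    )


def count_breakpoints(
    order: AncestralOrder | Sequence[int],
    pillars: Sequence[Pillar],
    genome: GenomeGeneOrder,
) -> int:
    """Number of broken track links (complement of the synteny score)."""
    perm = _perm_of(order)
    return sum(
        1
        for track in (1, 2)
        for *_, ok in track_links(perm, pillars, genome, track)
        if not ok
    )


# ---------------------------------------------------------------------------
# fast numeric view used by the annealer
# ---------------------------------------------------------------------------


class _GenomeView:
    """Integer-coded slot genes and gene coordinates for one genome."""

    def __init__(self, pillars: Sequence[Pillar], genome: GenomeGeneOrder):
        self.genome_id = genome.genome_id
        n = len(pillars)
        gene_ids: dict[str, int] = {}
        contig_ids: dict[str, int] = {}
        contig: list[int] = []
        pos: list[int] = []

        def encode(g: str) -> int:
            if g not in gene_ids:
                c, p = genome.location(g)
                gene_ids[g] = len(gene_ids)
                contig.append(contig_ids.setdefault(c, len(contig_ids)))
                pos.append(p)
            return gene_ids[g]

        self.track_gene = np.full((2, n), -1, dtype=np.int64)
        for i, pillar in enumerate(pillars):
            pair = pillar.slots.get(genome.genome_id, [None, None])
            for k, g in enumerate(pair):
                if g is not None:
                    self.track_gene[k, i] = encode(g)
        self.contig = np.asarray(contig, dtype=np.int64)
        self.pos = np.asarray(pos, dtype=np.int64)

    def breaks_and_junctions(
        self, perm: np.ndarray, want_junctions: bool = False
    ) -> tuple[int, np.ndarray | None]:
        """Breakpoint count and (optionally) the set of broken junctions."""
        total = 0
        broken: list[np.ndarray] = []
        for k in (0, 1):
            seq = self.track_gene[k][perm]
            filled = np.nonzero(seq >= 0)[0]
            if len(filled) < 2:
                continue
            genes = seq[filled]
            ok = (self.contig[genes[:-1]] == self.contig[genes[1:]]) & (
                np.abs(self.pos[genes[:-1]] - self.pos[genes[1:]]) == 1
            )
            total += int((~ok).sum())
            if want_junctions:
                broken.append(filled[:-1][~ok])
        if want_junctions:
            junc = (
                np.unique(np.concatenate(broken)) if broken else np.empty(0, np.int64)
            )
            return total, junc
        return total, None


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------


@dataclass
class AnnealConfig:
    """Simulated-annealing schedule.

    Geometric cooling (T <- cooling * T) with ``steps_per_temp`` proposals
    per temperature (default 100 * n_pillars).  Proposals are an equal mix
    of pillar swaps, single-pillar reinsertions and segment reversals.
    The search stops when no proposal has been accepted for
    ``stop_stale`` consecutive temperatures or T falls below ``t_min``.
    ``phase1_temps`` applies only to the global-break strategy: the number
    of temperature levels spent on the zero-break-adjacency objective
    before switching to total-break minimisation.
    """

    t_initial: float = 2.0
    cooling: float = 0.95
    steps_per_temp: int | None = None
    t_min: float = 1e-3
    stop_stale: int = 3
    phase1_temps: int = 10


Strategy = Literal["naive", "greedy", "global_break", "restricted"]


def _propose(perm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(perm)
    new = perm.copy()
    move = rng.integers(3)
    if move == 0:  # swap two pillars
        i, j = rng.integers(n, size=2)
        new[i], new[j] = new[j], new[i]
    elif move == 1:  # remove one pillar and reinsert elsewhere
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        v = new[i]
        new = np.delete(new, i)
        new = np.insert(new, j if j < len(new) else len(new), v)
    else:  # reverse a segment
        i, j = sorted(rng.integers(n + 1, size=2))
        new[i:j] = new[i:j][::-1]
    return new


def _total_breaks(views: list[_GenomeView], perm: np.ndarray) -> int:
    return sum(v.breaks_and_junctions(perm)[0] for v in views)


def _neg_zero_break_junctions(views: list[_GenomeView], perm: np.ndarray) -> int:
    """Negated count of junctions with no break in any genome."""
    broken: np.ndarray | None = None
    for v in views:
        _, junc = v.breaks_and_junctions(perm, want_junctions=True)
        broken = junc if broken is None else np.union1d(broken, junc)
    n_broken = 0 if broken is None else len(broken)
    return -((len(perm) - 1) - n_broken)


def _greedy_initial_order(
    pillars: Sequence[Pillar], genomes: Sequence[GenomeGeneOrder]
) -> np.ndarray:
    """Chain pillars by shared gene adjacency, most-connected first."""
    n = len(pillars)
    adj: dict[int, dict[int, int]] = {i: {} for i in range(n)}
    # gene -> (pillar, genome) index for adjacency lookup
    for genome in genomes:
        where: dict[str, int] = {}
        for i, p in enumerate(pillars):
            for g in p.genes(genome.genome_id):
                where[g] = i
        for g, i in where.items():
            c, pos = genome.location(g)
            contig_genes = genome.contigs[c]
            for q in (pos - 1, pos + 1):
                if 0 <= q < len(contig_genes):
                    j = where.get(contig_genes[q])
                    if j is not None and j != i:
                        adj[i][j] = adj[i].get(j, 0) + 1
    weight = {i: sum(d.values()) for i, d in adj.items()}
    order_seed = sorted(range(n), key=lambda i: (-weight[i], i))
    used = np.zeros(n, dtype=bool)
    chain: list[int] = []
    for start in order_seed:
        if used[start]:
            continue
        used[start] = True
        chain.append(start)
        cur = start
        while True:
            nxt = None
            best = 0
            for j, w in sorted(adj[cur].items()):
                if not used[j] and w > best:
                    best, nxt = w, j
            if nxt is None:
                break
            used[nxt] = True
            chain.append(nxt)
            cur = nxt
    return np.asarray(chain, dtype=np.int64)


def optimize_order(
    pillars: Sequence[Pillar],
    genomes: Sequence[GenomeGeneOrder],
    strategy: Strategy = "naive",
    anneal_cfg: AnnealConfig | None = None,
    seed: int = 0,
    restricted_pair: tuple[str, str] | None = None,
    initial: AncestralOrder | Sequence[int] | None = None,
) -> AncestralOrder:
    """Search for an ancestral pillar order by simulated annealing.

    Strategies:

    * ``naive`` — minimise the total breakpoint count over all genomes,
      starting from the given (or identity, i.e. outgroup) order.
    * ``greedy`` — same objective, but initialised by a greedy chaining of
      pillars that share many gene adjacencies.
    * ``global_break`` — first maximise the number of pillar junctions
      with no break in any genome, then switch to total-break
      minimisation.
    * ``restricted`` — minimise breaks counted only in ``restricted_pair``.

    Always returns the best order visited (never worse than the
    initialisation under the active final objective).
    """
    cfg = anneal_cfg or AnnealConfig()
    rng = np.random.default_rng(seed)
    n = len(pillars)
    if n == 0:
        raise ValidationError("no pillars to order")
    if strategy not in ("naive", "greedy", "global_break", "restricted"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    if strategy == "restricted":
        if restricted_pair is None:
            raise ValidationError("restricted strategy needs restricted_pair")
        obj_genomes = [g for g in genomes if g.genome_id in restricted_pair]
        if len(obj_genomes) != len(restricted_pair):
            raise ValidationError(
                f"restricted_pair {restricted_pair} not all present"
            )
    else:
        obj_genomes = list(genomes)
    views = [_GenomeView(pillars, g) for g in obj_genomes]

    if initial is not None:
        perm = _perm_of(initial).copy()
    elif strategy == "greedy":
        perm = _greedy_initial_order(pillars, genomes)
    else:
        perm = np.arange(n, dtype=np.int64)

    steps = cfg.steps_per_temp or 100 * n
    phase1 = cfg.phase1_temps if strategy == "global_break" else 0

    def objective(p: np.ndarray, phase1_active: bool) -> float:
        if phase1_active:
            return _neg_zero_break_junctions(views, p)
        return _total_breaks(views, p)

    t = cfg.t_initial
    temp_level = 0
    cur = perm
    cur_obj = objective(cur, phase1 > 0)
    best = cur.copy()
    best_obj = objective(cur, False)
    stale = 0
    while t > cfg.t_min and stale < cfg.stop_stale:
        phase1_active = temp_level < phase1
        accepted = False
        cur_obj = objective(cur, phase1_active)
        for _ in range(steps):
            cand = _propose(cur, rng)
            cand_obj = objective(cand, phase1_active)
            delta = cand_obj - cur_obj
            if delta <= 0 or rng.random() < math.exp(-delta / t):
                if delta != 0:
                    accepted = True
                cur, cur_obj = cand, cand_obj
                final_obj = objective(cand, False) if phase1_active else cand_obj
                if final_obj < best_obj:
                    best, best_obj = cand.copy(), final_obj
            if best_obj == 0:
                break
        stale = 0 if accepted else stale + 1
        t *= cfg.cooling
        temp_level += 1
        if best_obj == 0:
            break

    order = AncestralOrder(permutation=best)
    order.evaluate(pillars, genomes)
    logger.info(
        "optimize_order(%s): %d pillars, best total breaks %d",
        strategy,
        n,
        order.total_breakpoints(),
    )
    return order


# ---------------------------------------------------------------------------
# pillar construction
# ---------------------------------------------------------------------------


def _reference_anchor_order(reference: GenomeGeneOrder) -> list[str]:
    out: list[str] = []
    for genes in reference.contigs.values():
        out.extend(genes)
    return out


def build_pillars(
    reference: GenomeGeneOrder,
    homologs: Sequence[HomologyRecord],
    polyploid: GenomeGeneOrder,
    max_sweeps: int = 4,
) -> list[Pillar]:
    """Assign the polyploid genome's homologs to pillar slots.

    One pillar is created per outgroup gene with at least one surviving
    homolog, in outgroup gene order.  Each polyploid gene fills at most one
    slot; where an anchor has more than two candidates, the two kept are
    those maximising syntenic support (adjacency to the genes assigned to
    neighbouring pillars), refined by hill-climbing sweeps on the synteny
    score under the outgroup order.  Ties break toward the
    lexicographically smallest gene id.
    """
    candidates: dict[str, list[str]] = {}
    for rec in homologs:
        if rec.subject_gene not in reference:
            raise ValidationError(
                f"homolog subject {rec.subject_gene!r} not in reference genome"
            )
        if rec.query_gene not in polyploid:
            raise ValidationError(
                f"homolog query {rec.query_gene!r} not in polyploid genome"
            )
        candidates.setdefault(rec.subject_gene, [])
        if rec.query_gene not in candidates[rec.subject_gene]:
            candidates[rec.subject_gene].append(rec.query_gene)

    anchors = [a for a in _reference_anchor_order(reference) if a in candidates]
    for a in anchors:
        candidates[a] = sorted(candidates[a])
    anchor_pos = {a: i for i, a in enumerate(anchors)}

    # --- initial assignment by local adjacency support
    def support(anchor: str, gene: str) -> int:
        i = anchor_pos[anchor]
        s = 0
        for j in (i - 1, i + 1):
            if 0 <= j < len(anchors):
                for g2 in candidates[anchors[j]]:
                    if g2 != gene and polyploid.are_neighbors(gene, g2):
                        s += 1
        return s

    assigned: dict[str, list[str]] = {}
    claimed: dict[str, tuple[str, int]] = {}  # gene -> (anchor, support)
    for a in anchors:
        ranked = sorted(candidates[a], key=lambda g: (-support(a, g), g))
        chosen: list[str] = []
        for g in ranked:
            if len(chosen) == 2:
                break
            sup = support(a, g)
            prev = claimed.get(g)
            if prev is None or sup > prev[1]:
                if prev is not None:
                    assigned[prev[0]].remove(g)
                claimed[g] = (a, sup)
                chosen.append(g)
        assigned[a] = chosen

    # --- hill-climbing refinement on the synteny score (outgroup order)
    def make_pillars(assignment: dict[str, list[str]]) -> list[Pillar]:
        pillars = [
            Pillar(
                anchor=a,
                slots={polyploid.genome_id: _slot_pair(assignment[a])},
                candidates={polyploid.genome_id: set(candidates[a])},
            )
            for a in anchors
        ]
        _assign_tracks(pillars, polyploid)
        return pillars

    def _slot_pair(genes: list[str]) -> list[str | None]:
        pair: list[str | None] = [None, None]
        for k, g in enumerate(sorted(genes)[:2]):
            pair[k] = g
        return pair

    perm = np.arange(len(anchors))
    best_pillars = make_pillars(assigned)
    best_score = synteny_score(perm, best_pillars, polyploid)
    import itertools

    for _ in range(max_sweeps):
        improved = False
        for a in anchors:
            free = [
                g
                for g in candidates[a]
                if g not in claimed or claimed[g][0] == a
            ]
            if len(free) <= len(assigned[a]):
                continue
            current = tuple(sorted(assigned[a]))
            options = set()
            for r in (1, 2):
                for combo in itertools.combinations(free, min(r, len(free))):
                    options.add(tuple(sorted(combo)))
            for opt in sorted(options):
                if opt == current:
                    continue
                trial = dict(assigned)
                trial[a] = list(opt)
                trial_pillars = make_pillars(trial)
                sc = synteny_score(perm, trial_pillars, polyploid)
                if sc > best_score or (
                    sc == best_score
                    and len(opt) > len(current)
                ):
                    assigned = trial
                    for g in current:
                        claimed.pop(g, None)
                    for g in opt:
                        claimed[g] = (a, 0)
                    best_score = sc
                    best_pillars = trial_pillars
                    improved = True
                    break
        if not improved:
            break

    logger.info(
        "build_pillars(%s): %d pillars, synteny score %d",
        polyploid.genome_id,
        len(best_pillars),
        best_score,
    )
    return best_pillars


def _assign_tracks(pillars: Sequence[Pillar], genome: GenomeGeneOrder) -> None:
    """Place slot genes on tracks so each track chains along contigs.

    Sweeps the pillars in order, keeping the last placed gene per track;
    a gene goes to the track whose last gene is its contig neighbour
    (or, failing that, shares its contig).  Ties put the lexicographically
    smaller gene on track 1.
    """
    gid = genome.genome_id
    last: list[str | None] = [None, None]

    def affinity(g: str, k: int) -> int:
        if last[k] is None:
            return 0
        if genome.are_neighbors(g, last[k]):
            return 2
        if genome.location(g)[0] == genome.location(last[k])[0]:
            return 1
        return 0

    for pillar in pillars:
        genes = pillar.genes(gid)
        if not genes:
            continue
        if len(genes) == 2:
            a, b = sorted(genes)
            straight = affinity(a, 0) + affinity(b, 1)
            crossed = affinity(a, 1) + affinity(b, 0)
            if crossed > straight:
                pillar.slots[gid] = [b, a]
            else:
                pillar.slots[gid] = [a, b]
            last[0], last[1] = pillar.slots[gid][0], pillar.slots[gid][1]
        else:
            g = genes[0]
            k = 0 if affinity(g, 0) >= affinity(g, 1) else 1
            pair: list[str | None] = [None, None]
            pair[k] = g
            pillar.slots[gid] = pair
            last[k] = g


# ---------------------------------------------------------------------------
# merging per-genome pillar sets
# ---------------------------------------------------------------------------


def merge_and_retain(
    per_genome_pillars: dict[str, Sequence[Pillar]],
    genomes: dict[str, GenomeGeneOrder],
    anchors: Sequence[str] | None = None,
) -> list[Pillar]:
    """Merge per-genome pillar sets on their shared outgroup anchors.

    A merged pillar is retained only if (a) every genome contributes at
    least one assigned homolog and (b) every assigned homolog has at least
    one intact syntenic neighbour under the anchor order.  Dropped pillars
    are logged with the reason.
    """
    by_anchor: dict[str, dict[str, Pillar]] = {}
    for gid, pillars in per_genome_pillars.items():
        for p in pillars:
            by_anchor.setdefault(p.anchor, {})[gid] = p
    if anchors is None:
        seen: list[str] = []
        for pillars in per_genome_pillars.values():
            for p in pillars:
                if p.anchor not in seen:
                    seen.append(p.anchor)
        anchors = seen

    all_gids = sorted(per_genome_pillars)
    merged: list[Pillar] = []
    kept_anchors: list[str] = []
    dropped = {"missing_genome": 0, "no_syntenic_neighbor": 0}
    for anchor in anchors:
        contrib = by_anchor.get(anchor, {})
        if any(
            gid not in contrib or not contrib[gid].genes(gid) for gid in all_gids
        ):
            dropped["missing_genome"] += 1
            continue
        merged.append(
            Pillar(
                anchor=anchor,
                slots={gid: list(contrib[gid].slots[gid]) for gid in all_gids},
                candidates={
                    gid: set(contrib[gid].candidates.get(gid, set()))
                    for gid in all_gids
                },
            )
        )
        kept_anchors.append(anchor)

    # syntenic-neighbour requirement, evaluated on the merged order
    perm = np.arange(len(merged))
    bad: set[int] = set()
    for gid in all_gids:
        genome = genomes[gid]
        has_neighbor: dict[tuple[int, str], bool] = {}
        for track in (1, 2):
            for jl, jr, gl, gr, ok in track_links(perm, merged, genome, track):
                for pos, g in ((jl, gl), (jr, gr)):
                    key = (pos, g)
                    has_neighbor[key] = has_neighbor.get(key, False) or ok
        for i, pillar in enumerate(merged):
            for g in pillar.genes(gid):
                if not has_neighbor.get((i, g), False):
                    bad.add(i)
    for i in sorted(bad, reverse=True):
        logger.info(
            "merge_and_retain: dropping pillar %s (homolog without syntenic "
            "neighbour)",
            merged[i].anchor,
        )
        dropped["no_syntenic_neighbor"] += 1
        del merged[i]
    logger.info(
        "merge_and_retain: kept %d pillars, dropped %s", len(merged), dropped
    )
    return merged
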