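"""Cis-anchored Bayesian causal network reconstruction.

Expression (and optionally copy-number / promoter-methylation) profiles are
discretized into three states, genes whose expression associates with their
own CNV or methylation are anchored by parentless cis root nodes, candidate
regulators are restricted by mutual information (sparse candidate search),
and DAG structures are searched by many independent Metropolis–Hastings
chains. Edges present in more than a consensus fraction of the per-chain
best structures form the consensus network, whose remaining directed cycles
are broken at their weakest link.

Scoring uses the decomposable BDeu multinomial-Dirichlet marginal
likelihood, so adding an edge u -> v changes only v's family term. Cis root
nodes enter their own gene's family as permanent extra parents, which makes
p(X -> Y | D) and p(Y -> X | D) inequivalent and lets the search orient
edges between cis-anchored genes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteMatrix",
    "CisMap",
    "StructureSample",
    "ConsensusNetwork",
    "discretize",
    "cis_map_from_flags",
    "detect_cis_regulation",
    "candidate_regulators",
    "FamilyScorer",
    "score_structure",
    "mcmc_chain",
    "consensus_network",
    "break_cycles",
    "reconstruct_network",
]

STATE_NAMES = ("low", "normal", "high")


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscreteMatrix:
    """Genes x samples matrix of ordinal states (0=low, 1=normal, 2=high)."""

    states: pd.DataFrame  # int states per gene/sample
    cutpoints: dict[str, np.ndarray]  # gene -> increasing cut values
    n_states: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def samples(self) -> list[str]:
        return list(self.states.columns)


def _kmeans_1d(x: np.ndarray, k: int, n_iter: int = 100) -> np.ndarray:
    """Deterministic 1-D Lloyd's k-means with quantile initialization.

    Returns the sorted cluster centers.
    """
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    while len(centers) < k:  # quantile collisions: spread by epsilon
        centers = np.sort(np.append(centers, centers[-1] + 1e-9))
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == j].mean() if np.any(assign == j)
                        else centers[j] for j in range(k)])
        new.sort()
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def discretize(values: pd.DataFrame, k: int = 3) -> DiscreteMatrix:
    """Discretize each gene into ``k`` ordered states via 1-D k-means.

    Clusters are ordered by center (low/normal/high for k=3); cutpoints are
    the midpoints between adjacent centers. Genes with fewer distinct values
    than ``k`` get fewer states; constant genes collapse to the single state
    "normal" with a warning.
    """
    states = {}
    cutpoints: dict[str, np.ndarray] = {}
    n_states: dict[str, int] = {}
    n_constant = 0
    for gene, row in values.iterrows():
        x = row.to_numpy(float)
        distinct = np.unique(x)
        if distinct.size == 1:
            states[gene] = np.ones(len(x), dtype=np.int8)
            cutpoints[gene] = np.array([])
            n_states[gene] = 1
            n_constant += 1
            continue
        kk = min(k, distinct.size)
        centers = _kmeans_1d(x, kk)
        cuts = (centers[:-1] + centers[1:]) / 2.0
        states[gene] = np.digitize(x, cuts).astype(np.int8)
        cutpoints[gene] = cuts
        n_states[gene] = kk
    if n_constant:
        warnings.warn(f"{n_constant} constant genes discretized to the "
                      "single state 'normal'")
    df = pd.DataFrame(states, index=values.columns).T
    df = df.loc[values.index]
    return DiscreteMatrix(states=df, cutpoints=cutpoints, n_states=n_states)


# ---------------------------------------------------------------------------
# cis regulation
# ---------------------------------------------------------------------------

@dataclass
class CisMap:
    """Per-gene cis-regulation flags at the configured FDR threshold."""

    table: pd.DataFrame  # columns: has_cis_cnv, has_cis_methyl, q_cnv, q_methyl
    fdr: float

    def cis_genes(self) -> list[str]:
        mask = self.table["has_cis_cnv"] | self.table["has_cis_methyl"]
        return list(self.table.index[mask])

    def flags(self, gene: str) -> tuple[bool, bool]:
        if gene not in self.table.index:
            return (False, False)
        row = self.table.loc[gene]
        return (bool(row["has_cis_cnv"]), bool(row["has_cis_methyl"]))


def _slope_test_q(expr: pd.DataFrame, feature: pd.DataFrame,
                  samples: list[str]) -> pd.Series:
    """BH q-values for the per-gene regression-slope test of expression on
    the gene's own cis feature (equivalent to the Pearson correlation test)."""
    genes = [g for g in expr.index if g in feature.index]
    x = expr.loc[genes, samples].to_numpy(float)
    z = feature.loc[genes, samples].to_numpy(float)
    n = len(samples)
    xc = x - x.mean(axis=1, keepdims=True)
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (zc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xc * zc).sum(axis=1) / denom, 0.0)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
    from scipy import stats as sps
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    return pd.Series(bh_fdr(p), index=genes)


def cis_map_from_flags(genes, cnv_genes=(), methyl_genes=(),
                       fdr: float = 0.01) -> "CisMap":
    """Build a CisMap directly from known cis-gene lists (e.g. synthetic
    ground truth or user-supplied priors)."""
    cnv_genes, methyl_genes = set(cnv_genes), set(methyl_genes)
    table = pd.DataFrame({
        "has_cis_cnv": [g in cnv_genes for g in genes],
        "has_cis_methyl": [g in methyl_genes for g in genes],
        "q_cnv": np.nan, "q_methyl": np.nan,
    }, index=list(genes))
    return CisMap(table=table, fdr=fdr)


def detect_cis_regulation(expr: pd.DataFrame, cnv: pd.DataFrame | None = None,
                          methyl: pd.DataFrame | None = None,
                          fdr: float = 0.01) -> CisMap:
    """Flag genes whose expression associates with their own CNV/methylation.

    Association is a linear-regression slope test of expression on the
    gene-matched cis feature across shared samples; BH correction is applied
    across genes separately per data type, and a gene is flagged when
    q < ``fdr``.
    """
    out = pd.DataFrame({
        "has_cis_cnv": False, "has_cis_methyl": False,
        "q_cnv": np.nan, "q_methyl": np.nan,
    }, index=expr.index)
    for name, feat in (("cnv", cnv), ("methyl", methyl)):
        if feat is None:
            continue
        samples = [s for s in expr.columns if s in feat.columns]
        if not samples:
            raise ValueError(f"no shared samples between expression and {name}")
        q = _slope_test_q(expr, feat, samples)
        out.loc[q.index, f"q_{name}"] = q
        out.loc[q.index[q < fdr], f"has_cis_{name}"] = True
    return CisMap(table=out, fdr=fdr)


# ---------------------------------------------------------------------------
# sparse candidate regulators
# ---------------------------------------------------------------------------

def _pairwise_mi(states: np.ndarray) -> np.ndarray:
    """Plug-in mutual information (nats) between all row pairs of an
    integer state matrix."""
    g, n = states.shape
    nmax = int(states.max()) + 1
    mi = np.zeros((g, g))
    # marginal entropies
    ent = np.empty(g)
    for i in range(g):
        c = np.bincount(states[i], minlength=nmax) / n
        c = c[c > 0]
        ent[i] = -(c * np.log(c)).sum()
    for i in range(g):
        mi[i, i] = ent[i]
        for j in range(i + 1, g):
            joint = np.bincount(states[i] * nmax + states[j],
                                minlength=nmax * nmax) / n
            joint = joint[joint > 0]
            hj = -(joint * np.log(joint)).sum()
            mi[i, j] = mi[j, i] = max(ent[i] + ent[j] - hj, 0.0)
    return mi


def candidate_regulators(disc: DiscreteMatrix,
                         exclude_fraction: float = 0.2) -> dict[str, list[str]]:
    """Allowed parents per gene after mutual-information pruning.

    For each target gene the other genes are ranked by MI with the target
    (descending, ties broken by gene-identifier order) and the lowest
    ``exclude_fraction`` is dropped; the kept count is
    ``floor((n_genes - 1) * (1 - exclude_fraction))``.
    """
    genes = disc.genes
    g = len(genes)
    if g < 3:
        raise ValueError("need at least 3 genes")
    mi = _pairwise_mi(disc.states.to_numpy().astype(np.int64))
    n_keep = int(np.floor((g - 1) * (1.0 - exclude_fraction)))
    out: dict[str, list[str]] = {}
    for ti, target in enumerate(genes):
        others = [(float(-mi[ti, j]), genes[j]) for j in range(g) if j != ti]
        others.sort()  # ascending -MI = descending MI; ties by gene id
        out[target] = [name for _, name in others[:n_keep]]
    return out


# ---------------------------------------------------------------------------
# structure scoring (BDeu)
# ---------------------------------------------------------------------------

def _cis_node(kind: str, gene: str) -> str:
    return f"{kind}:{gene}"


class FamilyScorer:
    """Cached BDeu family scores over discrete gene + cis variables.

    The log marginal likelihood of node v with parent set P is the
    multinomial-Dirichlet closed form with equivalent sample size ``ess``
    spread uniformly over the parent configurations, plus a structure prior
    of ``-parent_penalty`` per (gene) parent. Cis root nodes of a gene are
    implicit permanent parents of that gene and carry no penalty.
    """

    def __init__(self, disc: DiscreteMatrix, cis: CisMap | None = None,
                 cis_states: dict[str, np.ndarray] | None = None,
                 ess: float = 1.0, parent_penalty: float = 1.0):
        from scipy.special import gammaln
        self._gammaln = gammaln
        self.ess = float(ess)
        self.parent_penalty = float(parent_penalty)
        self.states: dict[str, np.ndarray] = {
            g: disc.states.loc[g].to_numpy().astype(np.int64)
            for g in disc.genes
        }
        self.arity: dict[str, int] = {
            g: max(disc.n_states.get(g, int(self.states[g].max()) + 1), 1)
            for g in disc.genes
        }
        self.genes = list(disc.genes)
        self.cis_parents: dict[str, list[str]] = {g: [] for g in self.genes}
        if cis is not None and cis_states:
            for g in self.genes:
                has_cnv, has_meth = cis.flags(g)
                for kind, flag in (("cnv", has_cnv), ("methyl", has_meth)):
                    node = _cis_node(kind, g)
                    if flag and node in cis_states:
                        self.states[node] = np.asarray(cis_states[node],
                                                       dtype=np.int64)
                        self.arity[node] = max(int(self.states[node].max()) + 1,
                                               1)
                        self.cis_parents[g].append(node)
        self._cache: dict[tuple, float] = {}

    def family_score(self, child: str, parents: tuple[str, ...]) -> float:
        """BDeu log score of ``child`` given gene parents ``parents`` (the
        child's cis anchors are added automatically)."""
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        all_parents = list(parents) + self.cis_parents[child]
        x = self.states[child]
        r = self.arity[child]
        n = x.shape[0]
        if all_parents:
            q = 1
            idx = np.zeros(n, dtype=np.int64)
            for p in all_parents:
                idx = idx * self.arity[p] + self.states[p]
                q *= self.arity[p]
        else:
            q = 1
            idx = np.zeros(n, dtype=np.int64)
        counts = np.bincount(idx * r + x, minlength=q * r).reshape(q, r)
        nij = counts.sum(axis=1)
        a_ijk = self.ess / (q * r)
        a_ij = self.ess / q
        gln = self._gammaln
        score = float(
            np.sum(gln(a_ij) - gln(a_ij + nij))
            + np.sum(gln(a_ijk + counts) - gln(a_ijk))
        )
        score -= self.parent_penalty * len(parents)
        self._cache[key] = score
        return score

    def total_score(self, parent_sets: dict[str, tuple[str, ...]]) -> float:
        return sum(self.family_score(g, parent_sets[g]) for g in self.genes)


@dataclass
class StructureSample:
    """A single chain's best DAG (gene edges plus cis anchor edges)."""

    graph: nx.DiGraph
    log_score: float
    seed: int | None = None

    def gene_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self.graph.edges
                if ":" not in u and ":" not in v]


def _parents_to_graph(parent_sets: dict[str, tuple[str, ...]],
                      scorer: FamilyScorer) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(scorer.genes)
    for child, parents in parent_sets.items():
        for p in parents:
            g.add_edge(p, child)
        for cn in scorer.cis_parents[child]:
            g.add_edge(cn, child, cis=True)
    return g


def score_structure(graph: nx.DiGraph, disc: DiscreteMatrix,
                    cis: CisMap | None = None,
                    cis_states: dict[str, np.ndarray] | None = None,
                    ess: float = 1.0, parent_penalty: float = 1.0) -> float:
    """Log posterior score of a DAG over the gene variables.

    The score decomposes over node families (BDeu marginal likelihood plus a
    per-parent penalty); cyclic graphs are rejected.
    """
    gene_nodes = [n for n in graph.nodes if ":" not in n]
    sub = graph.subgraph(gene_nodes)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("graph contains a directed cycle")
    scorer = FamilyScorer(disc, cis, cis_states, ess=ess,
                          parent_penalty=parent_penalty)
    parent_sets = {
        g: tuple(sorted(p for p in sub.predecessors(g))) if g in sub else ()
        for g in scorer.genes
    }
    return scorer.total_score(parent_sets)


# ---------------------------------------------------------------------------
# MCMC structure search
# ---------------------------------------------------------------------------

def _reachable(children: dict[str, set[str]], start: str, goal: str) -> bool:
    """DFS: is ``goal`` reachable from ``start`` through gene edges?"""
    stack = [start]
    seen = {start}
    while stack:
        u = stack.pop()
        if u == goal:
            return True
        for w in children[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def mcmc_chain(disc: DiscreteMatrix, cis: CisMap | None = None,
               candidates: dict[str, list[str]] | None = None,
               seed: int = 0, n_steps: int = 2000,
               cis_states: dict[str, np.ndarray] | None = None,
               max_parents: int = 3, ess: float = 1.0,
               parent_penalty: float = 1.0,
               scorer: FamilyScorer | None = None) -> StructureSample:
    """One Metropolis–Hastings chain over DAG structures.

    Proposals add, delete, or reverse a single edge, restricted to the
    candidate parent sets and a ``max_parents`` cap; cis root nodes are
    permanent parents and never proposed. The chain starts from the empty
    gene graph and returns the highest-scoring structure visited (the
    chain's candidate structure).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if scorer is None:
        scorer = FamilyScorer(disc, cis, cis_states, ess=ess,
                              parent_penalty=parent_penalty)
    genes = scorer.genes
    if candidates is None:
        candidates = {g: [h for h in genes if h != g] for g in genes}
    cand_sets = {g: set(candidates.get(g, ())) - {g} for g in genes}
    pairs = [(u, v) for v in genes for u in sorted(cand_sets[v])]
    if not pairs:
        raise ValueError("no candidate edges")

    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {g: set() for g in genes}
    children: dict[str, set[str]] = {g: set() for g in genes}
    fam = {g: scorer.family_score(g, ()) for g in genes}
    score = sum(fam.values())
    best_score = score
    best_parents = {g: frozenset() for g in genes}

    pair_idx = rng.integers(0, len(pairs), size=n_steps)
    coins = rng.random(n_steps)
    accepts = rng.random(n_steps)

    for step in range(n_steps):
        u, v = pairs[pair_idx[step]]
        if u in parents[v]:
            do_reverse = (coins[step] < 0.5 and v in cand_sets[u]
                          and len(parents[u]) < max_parents)
            if do_reverse:
                # v -> u legal unless u still reaches v by another path
                parents[v].discard(u)
                children[u].discard(v)
                if _reachable(children, u, v):
                    parents[v].add(u)
                    children[u].add(v)
                    continue
                new_fam_v = scorer.family_score(v, tuple(sorted(parents[v])))
                pu = tuple(sorted(parents[u] | {v}))
                new_fam_u = scorer.family_score(u, pu)
                delta = (new_fam_v - fam[v]) + (new_fam_u - fam[u])
                if delta >= 0 or accepts[step] < np.exp(delta):
                    parents[u].add(v)
                    children[v].add(u)
                    fam[v], fam[u] = new_fam_v, new_fam_u
                    score += delta
                else:
                    parents[v].add(u)
                    children[u].add(v)
            else:  # delete
                pv = tuple(sorted(parents[v] - {u}))
                new_fam_v = scorer.family_score(v, pv)
                delta = new_fam_v - fam[v]
                if delta >= 0 or accepts[step] < np.exp(delta):
                    parents[v].discard(u)
                    children[u].discard(v)
                    fam[v] = new_fam_v
                    score += delta
        else:  # add u -> v
            if len(parents[v]) >= max_parents:
                continue
            if _reachable(children, v, u):
                continue  # would create a cycle
            pv = tuple(sorted(parents[v] | {u}))
            new_fam_v = scorer.family_score(v, pv)
            delta = new_fam_v - fam[v]
            if delta >= 0 or accepts[step] < np.exp(delta):
                parents[v].add(u)
                children[u].add(v)
                fam[v] = new_fam_v
                score += delta
        if score > best_score:
            best_score = score
            best_parents = {g: frozenset(parents[g]) for g in genes}

    parent_sets = {g: tuple(sorted(best_parents[g])) for g in genes}
    graph = _parents_to_graph(parent_sets, scorer)
    return StructureSample(graph=graph, log_score=best_score, seed=seed)


# ---------------------------------------------------------------------------
# consensus and cycle removal
# ---------------------------------------------------------------------------

@dataclass
class ConsensusNetwork:
    """Directed consensus graph; edge attribute ``frequency`` in (0, 1]."""

    graph: nx.DiGraph
    threshold: float
    root_nodes: list[str] = field(default_factory=list)  # cis anchors
    removed_edges: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def gene_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if ":" not in n]

    def edges_frame(self) -> pd.DataFrame:
        rows = [(u, v, d["frequency"])
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["parent", "child", "frequency"])

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)


def consensus_network(samples: list[StructureSample],
                      threshold: float = 0.3) -> ConsensusNetwork:
    """Edges occurring in strictly more than ``threshold`` of the per-chain
    best structures, annotated with their frequency."""
    if len(samples) < 2:
        raise ValueError("need at least 2 structures for a consensus")
    counts: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    for s in samples:
        nodes.update(s.graph.nodes)
        for e in s.graph.edges:
            counts[e] = counts.get(e, 0) + 1
    m = len(samples)
    g = nx.DiGraph()
    g.add_nodes_from(n for n in nodes if ":" not in n)
    for (u, v), c in sorted(counts.items()):
        freq = c / m
        if freq > threshold:
            g.add_edge(u, v, frequency=freq)
    roots = sorted(n for n in g.nodes if ":" in n)
    return ConsensusNetwork(graph=g, threshold=threshold, root_nodes=roots)


def _find_cycle_sorted(g: nx.DiGraph) -> list[tuple[str, str]] | None:
    """Deterministic directed-cycle search: iterative DFS from the
    lexicographically smallest node with sorted successor order."""
    color: dict[str, int] = {}
    parent_edge: dict[str, tuple[str, str]] = {}
    for start in sorted(g.nodes):
        if color.get(start):
            continue
        stack = [(start, iter(sorted(g.successors(start))))]
        color[start] = 1  # gray
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if color.get(nxt, 0) == 0:
                    color[nxt] = 1
                    parent_edge[nxt] = (node, nxt)
                    stack.append((nxt, iter(sorted(g.successors(nxt)))))
                    advanced = True
                    break
                if color.get(nxt) == 1:  # back edge: cycle found
                    cycle = [(node, nxt)]
                    cur = node
                    while cur != nxt:
                        e = parent_edge[cur]
                        cycle.append(e)
                        cur = e[0]
                    cycle.reverse()
                    return cycle
            if not advanced:
                color[node] = 2
                stack.pop()
    return None


def break_cycles(net: ConsensusNetwork) -> ConsensusNetwork:
    """Remove directed cycles by deleting each cycle's weakest link.

    Cycles are located by depth-first search from the lexicographically
    smallest node; within a cycle the minimum-frequency edge is deleted
    (frequency ties broken by the lexicographically smallest edge). Deleted
    edges are recorded on the returned network.
    """
    g = net.graph.copy()
    removed: list[tuple[str, str, float]] = list(net.removed_edges)
    while True:
        cycle = _find_cycle_sorted(g)
        if cycle is None:
            break
        u, v = min(cycle, key=lambda e: (g.edges[e]["frequency"], e))
        removed.append((u, v, float(g.edges[(u, v)]["frequency"])))
        logger.info("break_cycles: removed %s -> %s (frequency %.3f)",
                    u, v, removed[-1][2])
        g.remove_edge(u, v)
    return ConsensusNetwork(graph=g, threshold=net.threshold,
                            root_nodes=net.root_nodes, removed_edges=removed)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def reconstruct_network(dataset, n_chains: int = 1000, n_steps: int = 2000,
                        seed: int = 0, threshold: float = 0.3,
                        cis_fdr: float = 0.01, exclude_fraction: float = 0.2,
                        max_parents: int = 3, ess: float = 1.0,
                        parent_penalty: float = 1.0,
                        use_cis: bool = True) -> ConsensusNetwork:
    """Full reconstruction pipeline on an :class:`~invnet.io.OmicsDataset`.

    Discretizes expression, detects cis regulation (when CNV/methylation are
    available; otherwise runs without cis anchors with a warning), prunes
    candidate regulators by mutual information, runs ``n_chains``
    independent chains seeded ``seed + chain_index``, forms the consensus
    network at ``threshold``, and breaks any remaining cycles.
    """
    expr = dataset.expression
    disc = discretize(expr)

    cis = None
    cis_states: dict[str, np.ndarray] = {}
    have_cis = use_cis and (dataset.cnv is not None
                            or dataset.methylation is not None)
    if have_cis:
        cis = detect_cis_regulation(expr, dataset.cnv, dataset.methylation,
                                    fdr=cis_fdr)
        for kind, feat in (("cnv", dataset.cnv),
                           ("methyl", dataset.methylation)):
            if feat is None:
                continue
            flagged = [g for g in cis.table.index
                       if cis.table.loc[g, f"has_cis_{kind}"]
                       and g in feat.index]
            if flagged:
                fd = discretize(feat.loc[flagged, expr.columns])
                for g in flagged:
                    cis_states[_cis_node(kind, g)] = (
                        fd.states.loc[g].to_numpy().astype(np.int64))
    else:
        if use_cis:
            warnings.warn("no CNV/methylation provided: reconstructing "
                          "without cis anchors")

    candidates = candidate_regulators(disc, exclude_fraction=exclude_fraction)
    scorer = FamilyScorer(disc, cis, cis_states, ess=ess,
                          parent_penalty=parent_penalty)
    samples = [
        mcmc_chain(disc, cis, candidates, seed=seed + i, n_steps=n_steps,
                   cis_states=cis_states, max_parents=max_parents,
                   scorer=scorer)
        for i in range(n_chains)
    ]
    net = consensus_network(samples, threshold=threshold)
    return break_cycles(net)
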