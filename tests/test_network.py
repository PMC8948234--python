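"""Discretization, cis detection, BDeu scoring, MCMC search, consensus."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from invnet.network import (ConsensusNetwork, FamilyScorer, break_cycles,
                            candidate_regulators, cis_map_from_flags,
                            consensus_network, detect_cis_regulation,
                            discretize, mcmc_chain, reconstruct_network,
                            score_structure)
from invnet.io import OmicsDataset
from invnet.simulate import generate_dag_data


def _chain_dag():
    g = nx.DiGraph()
    g.add_edges_from([("V00", "V01"), ("V01", "V02")])
    return g


def all_three_node_dags(nodes):
    """All 25 DAGs on three labeled nodes (enumeration oracle)."""
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    dags = []
    for r in range(len(pairs) + 1):
        for combo in itertools.combinations(pairs, r):
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(combo)
            if nx.is_directed_acyclic_graph(g):
                dags.append(g)
    assert len([d for d in dags]) <= 25
    return dags


class TestDiscretize:
    def test_three_clumps_recovered(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 0.2, 30), rng.normal(5, 0.2, 30),
                  rng.normal(10, 0.2, 30)]
        expr = pd.DataFrame([x], index=["g"],
                            columns=[f"s{i}" for i in range(90)])
        disc = discretize(expr)
        states = disc.states.loc["g"].to_numpy()
        assert (states[:30] == 0).all()
        assert (states[30:60] == 1).all()
        assert (states[60:] == 2).all()

    def test_cutpoints_near_midpoints(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.r_[rng.normal(0, 0.3, 40), rng.normal(4, 0.3, 40),
                      rng.normal(8, 0.3, 40)]
            expr = pd.DataFrame([x], index=["g"],
                                columns=[f"s{i}" for i in range(120)])
            cuts = discretize(expr).cutpoints["g"]
            assert cuts == pytest.approx([2.0, 6.0], abs=0.2)

    def test_constant_gene_single_state(self):
        expr = pd.DataFrame([[3.0] * 6], index=["g"],
                            columns=[f"s{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="constant"):
            disc = discretize(expr)
        assert disc.n_states["g"] == 1
        assert (disc.states.loc["g"] == 1).all()


class TestCisDetection:
    def _data(self, rng, n_genes=200, n=100, planted=50, slope=0.8):
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(n)]
        cnv = pd.DataFrame(rng.normal(0, 1, (n_genes, n)), index=genes,
                           columns=samples)
        expr = pd.DataFrame(rng.normal(0, 0.5, (n_genes, n)), index=genes,
                            columns=samples)
        expr.iloc[:planted] += slope * cnv.iloc[:planted]
        return expr, cnv, genes[:planted]

    def test_planted_cis_recovered(self):
        rng = np.random.default_rng(0)
        expr, cnv, planted = self._data(rng)
        cm = detect_cis_regulation(expr, cnv=cnv)
        flagged = set(cm.cis_genes())
        assert len(flagged & set(planted)) >= 45
        assert len(flagged - set(planted)) <= 2

    def test_shuffled_cnv_yields_no_flags(self):
        rng = np.random.default_rng(1)
        expr, cnv, _ = self._data(rng, planted=0, n_genes=500)
        cm = detect_cis_regulation(expr, cnv=cnv)
        assert len(cm.cis_genes()) <= 2

    def test_no_shared_samples_rejected(self):
        rng = np.random.default_rng(2)
        expr, cnv, _ = self._data(rng, n_genes=5)
        cnv.columns = [f"x{i}" for i in range(cnv.shape[1])]
        with pytest.raises(ValueError, match="shared samples"):
            detect_cis_regulation(expr, cnv=cnv)


class TestCandidateRegulators:
    def test_rounding_rule_ten_genes(self):
        disc, _, _ = generate_dag_data(10, 50, seed=0, edge_prob=0.2)
        cands = candidate_regulators(disc, exclude_fraction=0.2)
        # floor(9 * 0.8) = 7 candidates per target
        assert all(len(v) == 7 for v in cands.values())
        assert all(t not in v for t, v in cands.items())

    def test_identical_gene_always_retained(self):
        disc, _, _ = generate_dag_data(10, 50, seed=1, edge_prob=0.2)
        twin = disc.states.loc["V00"].copy()
        disc.states.loc["V09"] = twin  # V09 == V00, maximal MI
        cands = candidate_regulators(disc, exclude_fraction=0.5)
        assert "V09" in cands["V00"]
        assert "V00" in cands["V09"]

    def test_zero_exclusion_keeps_everything(self):
        disc, _, _ = generate_dag_data(6, 40, seed=2, edge_prob=0.2)
        cands = candidate_regulators(disc, exclude_fraction=0.0)
        assert all(len(v) == 5 for v in cands.values())


class TestScoreStructure:
    def test_adding_edge_changes_only_child_family(self):
        disc, _, _ = generate_dag_data(4, 100, seed=0, edge_prob=0.4)
        scorer = FamilyScorer(disc)
        genes = disc.genes
        empty = {g: () for g in genes}
        with_edge = dict(empty)
        with_edge[genes[1]] = (genes[0],)
        delta_total = scorer.total_score(with_edge) - scorer.total_score(empty)
        delta_family = (scorer.family_score(genes[1], (genes[0],))
                        - scorer.family_score(genes[1], ()))
        assert delta_total == pytest.approx(delta_family)

    def test_dependent_pair_prefers_edge(self):
        wins = 0
        for seed in range(100):
            dag = nx.DiGraph()
            dag.add_edges_from([("V00", "V01")])
            disc, _, _ = generate_dag_data(2, 50, seed=seed, dag=dag,
                                           strength=0.85)
            g_edge = nx.DiGraph()
            g_edge.add_nodes_from(["V00", "V01"])
            g_edge.add_edge("V00", "V01")
            g_empty = nx.DiGraph()
            g_empty.add_nodes_from(["V00", "V01"])
            if score_structure(g_edge, disc) > score_structure(g_empty, disc):
                wins += 1
        assert wins >= 95

    def test_degenerate_all_normal_data_finite(self):
        states = pd.DataFrame(np.ones((3, 20), dtype=np.int8),
                              index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(20)])
        from invnet.network import DiscreteMatrix
        disc = DiscreteMatrix(states=states, cutpoints={},
                              n_states={g: 3 for g in "abc"})
        g = nx.DiGraph()
        g.add_nodes_from("abc")
        g.add_edge("a", "b")
        assert np.isfinite(score_structure(g, disc))

    def test_cyclic_graph_rejected(self):
        disc, _, _ = generate_dag_data(3, 30, seed=3)
        g = nx.DiGraph()
        g.add_edges_from([("V00", "V01"), ("V01", "V00")])
        with pytest.raises(ValueError, match="cycle"):
            score_structure(g, disc)


class TestMCMC:
    def test_seed_determinism(self):
        disc, _, _ = generate_dag_data(6, 100, seed=0, edge_prob=0.3)
        a = mcmc_chain(disc, seed=42, n_steps=500)
        b = mcmc_chain(disc, seed=42, n_steps=500)
        assert set(a.graph.edges) == set(b.graph.edges)
        assert a.log_score == b.log_score

    def test_chain_skeleton_recovered(self):
        disc, _, _ = generate_dag_data(3, 500, seed=3, dag=_chain_dag(),
                                       strength=0.9)
        hits = 0
        for s in range(20):
            samp = mcmc_chain(disc, seed=s, n_steps=500)
            skel = {frozenset(e) for e in samp.gene_edges()}
            if {frozenset({"V00", "V01"}), frozenset({"V01", "V02"})} <= skel:
                hits += 1
        assert hits >= 19

    def test_cis_root_orients_edges(self):
        correct = total = 0
        for s in range(10):
            disc, cst, tr = generate_dag_data(3, 400, seed=100 + s,
                                              dag=_chain_dag(),
                                              strength=0.85,
                                              cis_fraction=0.4)
            cm = cis_map_from_flags(disc.genes, cnv_genes=list(tr.cis_nodes))
            samp = mcmc_chain(disc, cis=cm, cis_states=cst, seed=s,
                              n_steps=500)
            edges = set(samp.gene_edges())
            for u, v in tr.dag.edges:
                if (u, v) in edges:
                    correct += 1
                    total += 1
                elif (v, u) in edges:
                    total += 1
        assert total > 0 and correct / total > 0.5

    def test_structures_always_acyclic(self):
        disc, _, _ = generate_dag_data(8, 150, seed=7, edge_prob=0.3)
        for s in range(5):
            samp = mcmc_chain(disc, seed=s, n_steps=800)
            genes_only = samp.graph.subgraph(
                [n for n in samp.graph if ":" not in n])
            assert nx.is_directed_acyclic_graph(genes_only)


def _struct(edges, nodes=("a", "b", "c")):
    from invnet.network import StructureSample
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return StructureSample(graph=g, log_score=0.0)


class TestConsensus:
    def test_identical_structures_frequency_one(self):
        samples = [_struct([("a", "b")]) for _ in range(5)]
        net = consensus_network(samples)
        assert net.graph.edges[("a", "b")]["frequency"] == 1.0

    def test_threshold_is_strict(self):
        samples = [_struct([("a", "b")])] * 3 + [_struct([])] * 7
        net = consensus_network(samples, threshold=0.3)
        assert ("a", "b") not in net.graph.edges

    def test_frequencies_match_hand_count(self):
        samples = [_struct([("a", "b"), ("b", "c")]),
                   _struct([("a", "b")]),
                   _struct([("a", "b"), ("a", "c")]),
                   _struct([("b", "c")]),
                   _struct([("a", "b"), ("b", "c")])]
        net = consensus_network(samples, threshold=0.0)
        assert net.graph.edges[("a", "b")]["frequency"] == pytest.approx(0.8)
        assert net.graph.edges[("b", "c")]["frequency"] == pytest.approx(0.6)
        assert net.graph.edges[("a", "c")]["frequency"] == pytest.approx(0.2)

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(0)
        samples = []
        for _ in range(10):
            edges = [(u, v) for (u, v) in
                     [("a", "b"), ("b", "c"), ("a", "c")]
                     if rng.random() < 0.5]
            samples.append(_struct(edges))
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7):
            net = consensus_network(samples, threshold=thr)
            edges = set(net.graph.edges)
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestBreakCycles:
    def _net(self, edges_with_freq):
        g = nx.DiGraph()
        for u, v, f in edges_with_freq:
            g.add_edge(u, v, frequency=f)
        return ConsensusNetwork(graph=g, threshold=0.3)

    def test_acyclic_input_unchanged(self):
        net = self._net([("a", "b", 0.9), ("b", "c", 0.5)])
        out = break_cycles(net)
        assert set(out.graph.edges) == {("a", "b"), ("b", "c")}
        assert not out.removed_edges

    def test_weakest_link_removed_from_three_cycle(self):
        net = self._net([("a", "b", 0.9), ("b", "c", 0.8), ("c", "a", 0.4)])
        out = break_cycles(net)
        assert out.removed_edges == [("c", "a", 0.4)]
        assert out.is_acyclic()

    def test_output_topologically_sortable(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(12)]
        g = nx.DiGraph()
        for _ in range(30):
            u, v = rng.choice(nodes, 2, replace=False)
            g.add_edge(u, v, frequency=float(rng.uniform(0.3, 1.0)))
        out = break_cycles(ConsensusNetwork(graph=g, threshold=0.3))
        list(nx.topological_sort(out.graph))  # raises if cyclic
        assert out.is_acyclic()


class TestReconstruction:
    def test_dag_recovery_f1(self):
        disc, cst, tr = generate_dag_data(20, 300, seed=11, edge_prob=0.12,
                                          strength=0.85, cis_fraction=0.3)
        # run through the orchestrator with continuous renderings
        values = disc.states.astype(float) * 2.0
        rng = np.random.default_rng(0)
        values += rng.normal(0, 0.25, values.shape)
        cnv_rows = {}
        for v, node in tr.cis_nodes.items():
            cnv_rows[v] = cst[node].astype(float) \
                + rng.normal(0, 0.2, len(cst[node]))
        cnv = pd.DataFrame(cnv_rows).T
        cnv.columns = values.columns
        ds = OmicsDataset(expression=values, cnv=cnv)
        net = reconstruct_network(ds, n_chains=50, n_steps=2000, seed=5)
        pred = {(u, v) for u, v in net.graph.edges
                if ":" not in u and ":" not in v}
        true = set(tr.dag.edges)
        tp = len(pred & true)
        prec = tp / len(pred) if pred else 0.0
        rec = tp / len(true)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert f1 >= 0.6
        assert net.is_acyclic()

    def test_deterministic_given_seed(self):
        disc, _, tr = generate_dag_data(8, 150, seed=2, edge_prob=0.25)
        values = disc.states.astype(float)
        ds = OmicsDataset(expression=values)
        with pytest.warns(UserWarning, match="cis"):
            a = reconstruct_network(ds, n_chains=10, n_steps=300, seed=3)
        with pytest.warns(UserWarning, match="cis"):
            b = reconstruct_network(ds, n_chains=10, n_steps=300, seed=3)
        assert set(a.graph.edges) == set(b.graph.edges)
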