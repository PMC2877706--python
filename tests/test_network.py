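import numpy as np
import pytest

from paleoabc.network import (build_network, build_temporal_network,
                              network_from_alignment, parsimony_limit,
                              parsimony_probability, write_dot, write_graphml)
from paleoabc.seqdata import collapse_haplotypes

from conftest import make_alignment


def mc_parsimony_probability(j, L, n_sims=1_000_000, seed=0):
    """Monte-Carlo oracle for the probability-of-parsimony model.

    Simulates the same per-site model independently of the closed form:
    substitution counts are Poisson with the Jukes-Cantor plug-in
    intensity, each hit moves to one of the three other bases, and a
    difference is parsimonious when its site took exactly one hit.
    """
    p = j / L
    theta = -0.75 * np.log1p(-4 * p / 3)
    rng = np.random.default_rng(seed)
    hits = rng.poisson(theta, n_sims)
    state = np.zeros(n_sims, dtype=np.int64)
    active = hits.copy()
    while (active > 0).any():
        m = active > 0
        step = rng.integers(1, 4, m.sum())
        state[m] = (state[m] + step) % 4
        active[m] -= 1
    changed = state != 0
    p_single = (hits[changed] == 1).mean()
    return p_single ** j


def test_parsimony_probability_matches_mc_oracle():
    for j in (5, 10, 11):
        closed = parsimony_probability(j, 708)
        mc = mc_parsimony_probability(j, 708)
        assert closed == pytest.approx(mc, abs=0.01)


def test_parsimony_limit_cross_route():
    """The integer limit agrees between closed form and the MC oracle."""
    limit = parsimony_limit(708, 0.95)
    assert mc_parsimony_probability(limit, 708) > 0.95
    assert mc_parsimony_probability(limit + 1, 708) < 0.95


def test_parsimony_limit_monotone_in_length():
    limits = [parsimony_limit(L, 0.95) for L in (50, 100, 300, 708, 1500)]
    assert limits == sorted(limits)


def test_parsimony_limit_low_confidence_connects_everything():
    assert parsimony_limit(100, 1e-300) == 100


def test_parsimony_limit_override_and_validation():
    assert parsimony_limit(708, 0.95, override=5) == 5
    with pytest.raises(ValueError):
        parsimony_limit(708, 1.5)
    with pytest.raises(ValueError):
        parsimony_limit(0, 0.95)


def _table(seqs, layer="m"):
    return collapse_haplotypes(make_alignment({(layer, 0.0): seqs}))


def test_single_haplotype_network():
    net = build_network(_table(["AAAA"] * 3), limit=5)
    assert net.graph.number_of_nodes() == 1
    assert net.n_components == 1


def test_two_haplotypes_one_step():
    net = build_network(_table(["AAAA", "AAAT"]), limit=5)
    assert net.graph.number_of_edges() == 1
    assert net.steps_between(0, 1) == 1


def test_chain_without_shortcut():
    # A-B one step, B-C one step, A-C two steps: parsimony keeps the chain
    net = build_network(_table(["AAAA", "AAAT", "AATT"]), limit=5)
    assert not net.graph.has_edge(0, 2)
    assert net.steps_between(0, 2) == 2
    assert net.n_components == 1


def test_multi_step_edge_inserts_intermediates():
    net = build_network(_table(["AAAAAA", "AATTTA"]), limit=5)
    inter = [n for n, d in net.graph.nodes(data=True)
             if d["kind"] == "intermediate"]
    assert len(inter) == 2          # three steps -> two unsampled nodes
    assert net.steps_between(0, 1) == 3


def test_beyond_limit_stays_disconnected():
    net = build_network(_table(["AAAAAA", "TTTTTA"]), limit=3)
    assert net.n_components == 2


def test_components_monotone_in_limit(rng):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 12)]) for _ in range(8)]
    table = _table(seqs)
    comp = [build_network(table, limit).n_components for limit in range(0, 13)]
    assert comp == sorted(comp, reverse=True)
    assert comp[-1] >= 1


def test_network_invariant_under_input_permutation(rng):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 2, 10)]) for _ in range(12)]
    t1 = _table(seqs)
    perm = list(rng.permutation(len(seqs)))
    t2 = _table([seqs[i] for i in perm])
    n1 = build_network(t1, 10)
    n2 = build_network(t2, 10)
    assert n1.n_components == n2.n_components
    # same set of connected haplotype sequence groups
    def comps(net, table):
        return sorted(sorted(table.haplotypes[n] for n in comp
                             if isinstance(n, int))
                      for comp in net.components())
    assert comps(n1, t1) == comps(n2, t2)


def test_every_haplotype_in_exactly_one_component(rng):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 10)]) for _ in range(10)]
    table = _table(seqs)
    net = build_network(table, 4)
    seen = [n for comp in net.components() for n in comp if isinstance(n, int)]
    assert sorted(seen) == list(range(table.k))


def test_temporal_identity_links_single_haplotype():
    tables = {lab: _table(["AAAA"] * 3, lab)
              for lab in ("25200", "15200", "11500", "modern")}
    lay = build_temporal_network(tables, limit=5)
    assert sum(n.graph.number_of_nodes() for n in lay.networks.values()) == 4
    assert len(lay.links) == 3


def test_temporal_no_link_for_private_haplotype():
    tables = {"old": _table(["AAAA", "GGGG"], "old"),
              "new": _table(["AAAA"], "new")}
    lay = build_temporal_network(tables, limit=5)
    assert lay.links == [("old", 0, "new", 0)]
    # the private haplotype appears in the near-match side table instead
    assert len(lay.near_matches) == 1
    assert lay.near_matches[0][4] == 4


def test_temporal_fixture_layer_counts(temporal_haplotype_fixture, tmp_path):
    """The built fixture reproduces the 10/7/7/3 haplotype trajectory."""
    aln = make_alignment(temporal_haplotype_fixture)
    lay = network_from_alignment(aln)
    assert list(lay.layer_haplotype_counts().values()) == [10, 7, 7, 3]
    assert lay.layers == ["25200", "15200", "11500", "modern"]
    # the two major haplotypes thread through every adjacent layer pair
    for la, lb in zip(lay.layers, lay.layers[1:]):
        linked = {(a, b) for (xa, a, xb, b) in lay.links
                  if (xa, xb) == (la, lb)}
        assert {(0, 0), (1, 1)} <= linked
    write_graphml(lay, tmp_path / "net.graphml")
    write_dot(lay, tmp_path / "net.dot")
    assert (tmp_path / "net.graphml").stat().st_size > 0
    assert "--" in (tmp_path / "net.dot").read_text()
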