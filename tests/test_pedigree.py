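"""Purdy parsing, pedigree assembly, NRM construction, ancestry shares."""

import numpy as np
import pytest

from germeval.pedigree import (
    PedigreeCycleError,
    PurdyParseError,
    build_pedigree,
    format_purdy,
    nrm,
    nrm_recursive,
    parse_purdy,
    pct_ancestry,
)
from conftest import random_pedigree
from hypothesis import given, settings
from hypothesis import strategies as st
from germeval.pedigree import cross as cross_node, leaf as leaf_node


def tree_shape(t):
    if t.is_leaf:
        return t.name
    return (tree_shape(t.left), tree_shape(t.right))


@pytest.mark.parametrize(
    "s, shape",
    [
        ("A/B", ("A", "B")),
        ("A/B//C", (("A", "B"), "C")),
        ("A/3/B/C//D", ("A", (("B", "C"), "D"))),
        ("A/B/C", (("A", "B"), "C")),           # equal order: rightmost split
        ("A/B//C/D", (("A", "B"), ("C", "D"))),
        ("A*2/B", ("A", ("A", "B"))),           # doses of A backcross on the left
        ("A/B*2", (("A", "B"), "B")),
        ("A*3/B", ("A", ("A", ("A", "B")))),
        ("W1 /  W2", ("W1", "W2")),
    ],
)
def test_parse_purdy_shapes(s, shape):
    assert tree_shape(parse_purdy(s)) == shape


@pytest.mark.parametrize("bad", ["", "A/", "/B", "A//", "A/B//", "A*0/B", "A*2", "*2/B"])
def test_parse_purdy_rejects_malformed(bad):
    with pytest.raises(PurdyParseError):
        parse_purdy(bad)


def test_purdy_round_trip(rng):
    """format -> parse recovers the tree for random cross structures."""
    names = [f"P{i}" for i in range(8)]
    for _ in range(50):
        import germeval.pedigree as pm

        def grow(depth):
            if depth == 0 or rng.random() < 0.4:
                return pm.leaf(names[int(rng.integers(len(names)))])
            return pm.cross(grow(depth - 1), grow(depth - 1))

        t = grow(3)
        if t.is_leaf:
            continue
        assert tree_shape(parse_purdy(format_purdy(t))) == tree_shape(t)


def test_build_pedigree_simple_and_nested():
    ped = build_pedigree([("X", "A/B")])
    assert len(ped) == 3
    assert ped.parents("X") == ("A", "B")
    assert ped.parents("A") == (None, None)

    ped = build_pedigree([("X", "A/B//C")])
    assert len(ped) == 5  # A, B, C, the A/B cross node, X
    synth = [g for g in ped.genotypes if g.startswith("#")]
    assert len(synth) == 1
    assert ped.parents("X") == (synth[0], "C")


def test_build_pedigree_order_invariance(rng):
    entries = [("F1", (None, None)), ("F2", (None, None)), ("F3", (None, None)),
               ("C1", "F1/F2"), ("C2", "F1/F2//F3"), ("C3", "C1/C2")]
    ped1 = build_pedigree(entries)
    for _ in range(5):
        shuffled = [entries[i] for i in rng.permutation(len(entries))]
        ped2 = build_pedigree(shuffled)
        assert ped2.genotypes == ped1.genotypes
        assert ped2.df["parent1"].tolist() == ped1.df["parent1"].tolist()


def test_build_pedigree_cycle_error():
    with pytest.raises(PedigreeCycleError):
        build_pedigree([("A", ("B", None)), ("B", ("A", None))])


def test_unparseable_purdy_becomes_founder():
    ped = build_pedigree([("X", "A/*bad*//")])
    assert ped.parents("X") == (None, None)


def test_nrm_textbook_values():
    # two founders: identity
    ped = build_pedigree([("A", (None, None)), ("B", (None, None))])
    A = nrm(ped)
    assert np.allclose(A.to_numpy(), np.eye(2))
    # full sibs from unrelated founders: a = 0.5, diagonals 1
    ped = build_pedigree([("S1", "A/B"), ("S2", "A/B")])
    A = nrm(ped)
    assert A.loc["S1", "S2"] == 0.5
    assert A.loc["S1", "S1"] == 1.0
    # selfed offspring of a founder: diagonal 1.5
    ped = build_pedigree([("P", (None, None)), ("S", ("P", "P"))])
    A = nrm(ped)
    assert A.loc["S", "S"] == 1.5
    assert A.loc["P", "S"] == 1.0  # 0.5 * (a_PP + a_PP)


def test_nrm_recursive_oracle_values():
    ped = build_pedigree([("A", (None, None)), ("B", (None, None)), ("X", ("A", "B"))])
    assert nrm_recursive(ped, "A", "B") == 0.0
    assert nrm_recursive(ped, "A", "X") == 0.5
    with pytest.raises(KeyError):
        nrm_recursive(ped, "A", "nope")


@pytest.mark.parametrize("seed", range(8))
def test_nrm_matches_recursive_oracle(seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n_members=40, selfing=True)
    A = nrm(ped).to_numpy()
    gs = ped.genotypes
    for _ in range(60):
        i, j = rng.integers(len(gs), size=2)
        assert abs(A[i, j] - nrm_recursive(ped, gs[i], gs[j])) < 1e-12


@pytest.mark.parametrize("seed", range(6))
def test_nrm_invariants(seed):
    """Symmetric, PSD, diagonal in [1, 2], entries in [0, 2]."""
    rng = np.random.default_rng(100 + seed)
    A = nrm(random_pedigree(rng, n_members=60, selfing=True)).to_numpy()
    assert np.allclose(A, A.T)
    assert np.linalg.eigvalsh(A).min() > -1e-8
    d = np.diag(A)
    assert np.all((d >= 1.0) & (d <= 2.0))
    assert A.min() >= 0.0 and A.max() <= 2.0


def test_pct_ancestry_trivial():
    ped = build_pedigree(
        [("F1", (None, None)), ("F2", (None, None)), ("X", ("F1", "F2"))],
        sources={"F1": "program", "F2": "local", "X": "local"},
    )
    assert pct_ancestry(ped, "F1", {"program"}) == 1.0
    assert pct_ancestry(ped, "X", {"program"}) == 0.5
    assert pct_ancestry(ped, "X", {"nothing"}) == 0.0
    with pytest.raises(KeyError):
        pct_ancestry(ped, "nope", {"program"})


def _gene_drop(ped, g, tags, rng, n_drops):
    """Monte-Carlo oracle: follow one random gene lineage upward per drop."""
    hits = 0
    for _ in range(n_drops):
        node = g
        while True:
            if ped.source(node) in tags:
                hits += 1
                break
            p1, p2 = ped.parents(node)
            pick = p1 if rng.random() < 0.5 else p2
            if pick is None:
                break
            node = pick
    return hits / n_drops


def test_pct_ancestry_matches_gene_dropping(rng):
    entries = [("F1", (None, None)), ("F2", (None, None)), ("F3", (None, None)),
               ("F4", (None, None)),
               ("C1", ("F1", "F2")), ("C2", ("F3", "F4")),
               ("C3", ("C1", "F3")), ("X", ("C3", "C2"))]
    sources = {"F1": "prog", "F3": "prog"}
    ped = build_pedigree(entries, sources=sources, default_source="local")
    n = 100_000
    for g in ("C1", "C3", "X"):
        expected = pct_ancestry(ped, g, {"prog"})
        mc = _gene_drop(ped, g, {"prog"}, rng, n)
        se = np.sqrt(max(expected * (1 - expected), 1e-6) / n)
        assert abs(mc - expected) < 3 * se + 1e-9


def test_pct_ancestry_monotone_in_tags(rng):
    ped = random_pedigree(np.random.default_rng(7), n_members=30)
    gs = ped.genotypes
    base_tags = {"nothing"}
    for anc in gs[:5]:
        with_tag = {"nothing"}
        ped.df.loc[ped.index(anc), "source"] = "tagged"
        ped.__post_init__()
        for g in gs:
            before = pct_ancestry(ped, g, base_tags)
            after = pct_ancestry(ped, g, {"nothing", "tagged"})
            assert after >= before - 1e-12
        ped.df.loc[ped.index(anc), "source"] = ""
        ped.__post_init__()


# -- property tests -----------------------------------------------------------

names_st = st.sampled_from([f"P{i}" for i in range(6)])
trees_st = st.recursive(
    names_st.map(leaf_node),
    lambda kids: st.tuples(kids, kids).map(lambda lr: cross_node(*lr)),
    max_leaves=8,
)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(trees_st)
def test_purdy_round_trip_property(tree):
    """Any cross tree survives format -> parse unchanged (shape equality)."""
    if tree.is_leaf:
        assert parse_purdy(format_purdy(tree)).name == tree.name
    else:
        assert tree_shape(parse_purdy(format_purdy(tree))) == tree_shape(tree)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=5, max_value=40))
def test_nrm_psd_property(seed, n_members):
    """Random pedigrees always give a symmetric PSD A with diagonal in [1, 2]."""
    rng = np.random.default_rng(seed)
    A = nrm(random_pedigree(rng, n_members=n_members, selfing=True)).to_numpy()
    assert np.allclose(A, A.T)
    assert np.linalg.eigvalsh(A).min() > -1e-8
    assert np.all((np.diag(A) >= 1.0) & (np.diag(A) <= 2.0))
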