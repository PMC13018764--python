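from __future__ import annotations

import math

import numpy as np
import pytest

from phenocompare import (
    ancestor_path_length,
    compute_ic,
    lin_similarity,
    load_obo,
    mica,
    resolve_term,
)
from phenocompare.errors import CycleError, OntologyError, UnknownTermError

from conftest import random_dag_obo
from oracles import brute_closure, brute_lin, brute_min_path

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000539
name: refraction
is_a: HP:0000001

[Term]
id: HP:0000545
name: myopia
is_a: HP:0000539

[Term]
id: HP:0025573
name: mild myopia
is_a: HP:0000545
"""


@pytest.fixture()
def chain(tmp_path):
    p = tmp_path / "chain.obo"
    p.write_text(CHAIN_OBO)
    return load_obo(p)


class TestLoadObo:
    def test_myopia_chain_parentage(self, chain):
        assert "HP:0000539" in chain.terms["HP:0000545"].parent_ids
        assert "HP:0000545" in chain.terms["HP:0025573"].parent_ids

    def test_single_root_file(self, tmp_path):
        p = tmp_path / "root.obo"
        p.write_text("[Term]\nid: HP:0000001\nname: root\n")
        g = load_obo(p)
        assert g.descendant_count["HP:0000001"] == 1
        assert g.ic["HP:0000001"] == 0.0

    def test_cycle_is_fatal(self, tmp_path):
        p = tmp_path / "cycle.obo"
        p.write_text(
            "[Term]\nid: HP:0000001\nname: r\n\n"
            "[Term]\nid: HP:0000002\nname: a\nis_a: HP:0000001\nis_a: HP:0000003\n\n"
            "[Term]\nid: HP:0000003\nname: b\nis_a: HP:0000002\n"
        )
        with pytest.raises(CycleError) as exc:
            load_obo(p)
        assert exc.value.edges

    def test_unknown_is_a_target_fatal(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text(
            "[Term]\nid: HP:0000001\nname: r\n\n"
            "[Term]\nid: HP:0000002\nname: a\nis_a: HP:0099999\n"
        )
        with pytest.raises(OntologyError, match="HP:0099999"):
            load_obo(p)

    def test_missing_root_fatal(self, tmp_path):
        p = tmp_path / "two_roots.obo"
        p.write_text(
            "[Term]\nid: HP:0000001\nname: r1\n\n[Term]\nid: HP:0000002\nname: r2\n"
        )
        with pytest.raises(OntologyError, match="ambiguous"):
            load_obo(p)

    def test_fixture_descendant_count_matches_file(self, graph):
        # 57 non-obsolete stanzas in the bundled file
        assert graph.descendant_count[graph.root_id] == len(graph.terms) == 57

    @pytest.mark.parametrize("seed", range(5))
    def test_closure_matches_bruteforce_on_random_dags(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        p = tmp_path / f"dag{seed}.obo"
        p.write_text(random_dag_obo(rng, n))
        g = load_obo(p)
        parents = {t: set(term.parent_ids) for t, term in g.terms.items()}
        expected = brute_closure(parents)
        assert {t: set(c) for t, c in g.ancestor_closure.items()} == expected


class TestResolveTerm:
    def test_primary_identity(self, graph):
        assert resolve_term(graph, "HP:0000545") == "HP:0000545"

    def test_alt_id_alias(self, graph):
        assert resolve_term(graph, "HP:9999991") == "HP:0000545"

    def test_obsolete_replacement(self, graph):
        assert resolve_term(graph, "HP:0008012") == "HP:0000545"

    def test_unknown_raises(self, graph):
        with pytest.raises(UnknownTermError):
            resolve_term(graph, "HP:7777777")


class TestAncestorPathLength:
    def test_direct_child(self, graph):
        assert ancestor_path_length(graph, "HP:0000545", "HP:0025573") == 1

    def test_grandparent(self, graph):
        assert ancestor_path_length(graph, "HP:0000539", "HP:0025573") == 2

    def test_unrelated_terms(self, graph):
        assert ancestor_path_length(graph, "HP:0000639", "HP:0025573") is None

    def test_self_distance_zero(self, graph):
        assert ancestor_path_length(graph, "HP:0000545", "HP:0000545") == 0

    def test_symmetric_in_arguments(self, graph):
        assert ancestor_path_length(graph, "HP:0025573", "HP:0000539") == 2

    def test_multi_parent_takes_minimum(self, graph):
        # Ataxia has a direct edge to its grandparent-through-movement
        assert ancestor_path_length(graph, "HP:0012638", "HP:0001251") == 1

    def test_unknown_raises(self, graph):
        with pytest.raises(UnknownTermError):
            ancestor_path_length(graph, "HP:0000545", "HP:7777777")

    def test_absent_iff_not_in_closure(self, graph):
        terms = sorted(graph.terms)[:20]
        for a in terms:
            for b in terms:
                d = ancestor_path_length(graph, a, b)
                related = a == b or a in graph.ancestor_closure[b] or b in graph.ancestor_closure[a]
                assert (d is None) == (not related)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_min_path(self, tmp_path, seed):
        rng = np.random.default_rng(100 + seed)
        p = tmp_path / "dag.obo"
        p.write_text(random_dag_obo(rng, 25))
        g = load_obo(p)
        parents = {t: set(term.parent_ids) for t, term in g.terms.items()}
        ids = sorted(g.terms)
        for a in ids:
            for b in ids:
                got = ancestor_path_length(g, a, b)
                if a in g.ancestor_closure[b]:
                    assert got == brute_min_path(parents, a, b)
                elif b in g.ancestor_closure[a]:
                    assert got == brute_min_path(parents, b, a)
                elif a != b:
                    assert got is None


class TestInformationContent:
    def test_root_zero_both_modes(self, chain):
        assert chain.ic["HP:0000001"] == 0.0
        compute_ic(chain, mode="corpus", corpus=["HP:0025573", "HP:0000545"])
        assert chain.ic["HP:0000001"] == 0.0

    def test_linear_chain_leaf_ic(self, chain):
        assert chain.ic["HP:0025573"] == pytest.approx(-math.log(1 / 4))

    def test_corpus_all_on_one_leaf(self, chain):
        compute_ic(chain, mode="corpus", corpus=["HP:0025573"] * 7)
        for t in ("HP:0025573", "HP:0000545", "HP:0000539", "HP:0000001"):
            assert chain.ic[t] == pytest.approx(0.0)

    def test_corpus_unknown_terms_dropped_with_count(self, chain):
        compute_ic(chain, mode="corpus", corpus=["HP:0025573", "HP:7777777"])
        assert chain.ic_dropped == 1

    @pytest.mark.parametrize("mode", ["intrinsic", "corpus"])
    def test_monotone_along_edges(self, graph, mode):
        if mode == "corpus":
            corpus = [t for t in sorted(graph.terms)] * 2
            compute_ic(graph, mode="corpus", corpus=corpus)
        else:
            compute_ic(graph, mode="intrinsic")
        for tid, term in graph.terms.items():
            for p in term.parent_ids:
                assert graph.ic[tid] >= graph.ic[p] - 1e-12
        compute_ic(graph, mode="intrinsic")  # restore session fixture state


class TestLinSimilarity:
    def test_identity_is_one(self, graph):
        assert lin_similarity(graph, "HP:0025573", "HP:0025573") == 1.0

    def test_root_children_zero(self, graph):
        assert lin_similarity(graph, "HP:0000478", "HP:0000707") == 0.0

    def test_symmetry_and_bounds_exhaustive(self, graph):
        ids = sorted(graph.terms)
        for a in ids:
            for b in ids:
                s = lin_similarity(graph, a, b)
                assert 0.0 <= s <= 1.0
                assert s == lin_similarity(graph, b, a)
                if a == b:
                    assert s == 1.0

    def test_matches_handrolled_formula(self, graph):
        a, b = "HP:0025573", "HP:0000540"  # mild myopia vs hypermetropia
        m = mica(graph, a, b)
        assert m == "HP:0000539"
        expected = 2 * graph.ic[m] / (graph.ic[a] + graph.ic[b])
        assert lin_similarity(graph, a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_oracle_random_dag(self, tmp_path, seed):
        rng = np.random.default_rng(200 + seed)
        p = tmp_path / "dag.obo"
        p.write_text(random_dag_obo(rng, 20))
        g = load_obo(p)
        parents = {t: set(term.parent_ids) for t, term in g.terms.items()}
        ids = sorted(g.terms)
        for a in ids:
            for b in ids:
                assert lin_similarity(g, a, b) == pytest.approx(
                    brute_lin(parents, g.ic, a, b)
                )

    def test_unknown_raises(self, graph):
        with pytest.raises(UnknownTermError):
            lin_similarity(graph, "HP:0000545", "HP:7777777")
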