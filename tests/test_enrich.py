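"""Fisher over-representation, significance filters, GO-Slim rollup."""

from collections import Counter
from math import comb

import numpy as np
import pandas as pd
import pytest

from protasca.cluster import CladeAssignment
from protasca.enrich import (
    Background,
    apply_significance_filters,
    build_background,
    enrich_clades,
    fisher_enrichment,
    rollup_to_slim,
)
from protasca.io import ProtascaError, read_ontology

from conftest import write_annotations


def make_background(protein_terms):
    counts = Counter()
    for terms in protein_terms.values():
        counts.update(terms)
    return Background(proteins=frozenset(protein_terms),
                      term_counts=counts,
                      protein_terms={p: frozenset(t)
                                     for p, t in protein_terms.items()})


def hypergeom_tail_exact(k, N, K, n):
    """Upper-tail P[X >= k] summed from exact binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i)
               for i in range(k, min(K, n) + 1)) / total


class TestBackground:
    def test_unannotated_proteins_excluded(self, tmp_path, small_obo):
        ann = write_annotations(tmp_path, {f"p{i}": ["GO:0000004"]
                                           for i in range(7)})
        gm = read_ontology(small_obo, ann)
        detected = {f"p{i}" for i in range(10)}  # 3 lack annotations
        bg = build_background(gm, detected)
        assert bg.size == 7

    def test_shared_ancestor_counted_per_protein(self, tmp_path, small_obo):
        ann = write_annotations(tmp_path, {"p1": ["GO:0000004"],
                                           "p2": ["GO:0000004"],
                                           "p3": ["GO:0000004"]})
        gm = read_ontology(small_obo, ann)
        bg = build_background(gm, {"p1", "p2", "p3"})
        assert bg.term_counts["GO:0000001"] == 3  # propagated root

    def test_aspect_restriction(self, tmp_path, small_obo):
        ann = write_annotations(tmp_path, {"p1": ["GO:0000004", "GO:0000008"],
                                           "p2": ["GO:0000008"]})
        gm = read_ontology(small_obo, ann)
        bg = build_background(gm, {"p1", "p2"}, aspect="biological_process")
        assert bg.size == 1  # only p1 has a BP term

    def test_counts_match_brute_force_set_intersections(self, rng, tmp_path,
                                                        small_obo):
        universe = ["GO:0000002", "GO:0000003", "GO:0000004", "GO:0000005"]
        mapping = {f"p{i}": list(rng.choice(universe,
                                            size=rng.integers(1, 3),
                                            replace=False))
                   for i in range(25)}
        gm = read_ontology(small_obo, write_annotations(tmp_path, mapping))
        bg = build_background(gm, set(mapping))
        for term in bg.term_counts:
            brute = sum(1 for p in mapping if term in gm.annotations[p])
            assert bg.term_counts[term] == brute

    def test_empty_detected_rejected(self, tmp_path, small_obo):
        gm = read_ontology(small_obo,
                           write_annotations(tmp_path, {"p1": ["GO:0000004"]}))
        with pytest.raises(ProtascaError):
            build_background(gm, set())


class TestFisher:
    def test_matches_exact_hypergeometric_tail(self, rng):
        """Random 2x2 tables with margins <= 200 against an exact
        combinatorial tail sum, to 1e-12."""
        for _ in range(200):
            N = int(rng.integers(10, 201))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            terms = {}
            with_term = [f"p{i}" for i in range(K)]
            without = [f"p{i}" for i in range(K, N)]
            for p in with_term:
                terms[p] = {"T"}
            for p in without:
                terms[p] = {"other"}
            bg = make_background(terms)
            clade = set(rng.choice(sorted(bg.proteins), size=n,
                                   replace=False))
            p_val = fisher_enrichment(clade, bg, "T")
            k = len([p for p in clade if p in set(with_term)])
            assert p_val == pytest.approx(hypergeom_tail_exact(k, N, K, n),
                                          rel=1e-12, abs=1e-12)

    def test_clade_equals_background_p_one(self):
        bg = make_background({"a": {"T"}, "b": {"T"}, "c": {"other"}})
        assert fisher_enrichment({"a", "b", "c"}, bg, "T") == pytest.approx(1.0)

    def test_zero_count_in_clade_large_p(self):
        bg = make_background({**{f"p{i}": {"T"} for i in range(10)},
                              **{f"q{i}": {"other"} for i in range(90)}})
        clade = {f"q{i}" for i in range(10)}
        assert fisher_enrichment(clade, bg, "T") >= 0.5

    def test_worked_tail_example(self):
        """5 of 10 clade proteins carry a term present 10 times among 100."""
        bg = make_background({**{f"p{i}": {"T"} for i in range(10)},
                              **{f"q{i}": {"other"} for i in range(90)}})
        clade = {f"p{i}" for i in range(5)} | {f"q{i}" for i in range(5)}
        expected = hypergeom_tail_exact(5, 100, 10, 10)
        assert fisher_enrichment(clade, bg, "T") == pytest.approx(expected,
                                                                  rel=1e-12)

    def test_term_absent_from_background(self):
        bg = make_background({"a": {"T"}})
        with pytest.raises(ProtascaError, match="absent"):
            fisher_enrichment({"a"}, bg, "missing")

    def test_random_clade_calibration(self, rng):
        """Under random clade assignment ~5% of (term, clade) pairs fall
        below 0.05; margins are large so attainable levels are dense."""
        N, n = 2000, 200
        term_sizes = {f"T{j}": int(K)
                      for j, K in enumerate(rng.integers(100, 800, size=30))}
        protein_terms = {f"p{i}": set() for i in range(N)}
        ids = np.array(sorted(protein_terms))
        for term, K in term_sizes.items():
            for p in rng.choice(ids, size=K, replace=False):
                protein_terms[p].add(term)
        for p in protein_terms:  # everyone annotated somewhere
            protein_terms[p].add("rootish")
        bg = make_background(protein_terms)
        hits = 0
        total = 0
        for _ in range(40):
            clade = set(rng.choice(ids, size=n, replace=False))
            for term in term_sizes:
                total += 1
                hits += fisher_enrichment(clade, bg, term) < 0.05
        assert 0.03 <= hits / total <= 0.07


class TestFilters:
    def make_table(self, rows):
        return pd.DataFrame(rows)

    def test_count_and_alpha_filters(self):
        table = self.make_table([
            {"clade": 1, "term": "a", "p_value": 0.03,
             "count_in_background": 4},
            {"clade": 1, "term": "b", "p_value": 0.05,
             "count_in_background": 50},
            {"clade": 1, "term": "c", "p_value": 0.049,
             "count_in_background": 5},
        ])
        kept = apply_significance_filters(table)
        assert list(kept["term"]) == ["c"]  # a: low count; b: p not < 0.05

    def test_hand_filtered_fixture(self, rng):
        rows = [{"clade": 1, "term": f"t{i}",
                 "p_value": float(rng.random()),
                 "count_in_background": int(rng.integers(1, 20))}
                for i in range(20)]
        table = self.make_table(rows)
        kept = apply_significance_filters(table, alpha=0.2,
                                          min_background_count=8)
        expected = {r["term"] for r in rows
                    if r["p_value"] < 0.2 and r["count_in_background"] >= 8}
        assert set(kept["term"]) == expected

    def test_bh_mode_is_more_conservative(self, rng):
        rows = [{"clade": 1, "term": f"t{i}",
                 "p_value": float(rng.random() * 0.2),
                 "count_in_background": 10} for i in range(30)]
        table = self.make_table(rows)
        plain = apply_significance_filters(table)
        bh = apply_significance_filters(table, correction="bh")
        assert set(bh["term"]) <= set(plain["term"])


class TestSlimRollup:
    def test_slim_member_maps_to_itself(self, tmp_path, small_obo):
        gm = read_ontology(small_obo,
                           write_annotations(tmp_path, {"p": ["GO:0000004"]}))
        out = rollup_to_slim(["GO:0000002"], gm,
                             slim_subset=frozenset({"GO:0000002"}))
        assert out["GO:0000002"] == {"GO:0000002"}

    def test_two_incomparable_slim_ancestors_both_kept(self, tmp_path,
                                                       small_obo):
        gm = read_ontology(small_obo,
                           write_annotations(tmp_path, {"p": ["GO:0000005"]}))
        slim = frozenset({"GO:0000002", "GO:0000003"})
        out = rollup_to_slim(["GO:0000005"], gm, slim_subset=slim)
        assert out["GO:0000005"] == slim

    def test_general_ancestor_dropped_when_specific_present(self, tmp_path,
                                                            small_obo):
        gm = read_ontology(small_obo,
                           write_annotations(tmp_path, {"p": ["GO:0000004"]}))
        slim = frozenset({"GO:0000001", "GO:0000002"})
        out = rollup_to_slim(["GO:0000004"], gm, slim_subset=slim)
        assert out["GO:0000004"] == {"GO:0000002"}  # root is less specific

    def test_unmapped_bucket(self, tmp_path, small_obo):
        gm = read_ontology(small_obo,
                           write_annotations(tmp_path, {"p": ["GO:0000008"]}))
        out = rollup_to_slim(["GO:0000008"], gm,
                             slim_subset=frozenset({"GO:0000002"}))
        assert out["GO:0000008"] == {"unmapped"}

    def test_matches_brute_force_minimal_ancestors(self, rng, tmp_path):
        """Random DAG: rollup equals an explicit minimal-ancestor search."""
        n = 25
        terms = [f"GO:{i:07d}" for i in range(1, n + 1)]
        parents = {terms[0]: []}
        blocks = ["format-version: 1.2", "",
                  f"[Term]\nid: {terms[0]}\nname: root\n"]
        for i in range(1, n):
            ps = [terms[j] for j in
                  rng.choice(i, size=min(int(rng.integers(1, 3)), i),
                             replace=False)]
            parents[terms[i]] = ps
            blocks.append("\n".join(
                [f"[Term]", f"id: {terms[i]}", f"name: t{i}"]
                + [f"is_a: {p}" for p in ps]) + "\n")
        obo = tmp_path / "rand.obo"
        obo.write_text("\n".join(blocks))
        gm = read_ontology(obo, write_annotations(tmp_path,
                                                  {"p": [terms[-1]]}))

        def ancestors(t):
            seen = set()
            stack = [t]
            while stack:
                for p in parents[stack.pop()]:
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
            return seen

        slim = frozenset(rng.choice(terms[:-1], size=8, replace=False))
        out = rollup_to_slim(list(terms), gm, slim_subset=slim)
        for t in terms:
            if t in slim:
                assert out[t] == {t}
                continue
            cands = ancestors(t) & slim
            if not cands:
                assert out[t] == {"unmapped"}
                continue
            minimal = {c for c in cands
                       if not any(c in ancestors(o) for o in cands if o != c)}
            assert out[t] == minimal
        # rollup never increases the number of distinct mapped terms
        mapped = set().union(*out.values()) - {"unmapped"}
        assert len(mapped) <= len(set(terms))


def test_enrich_clades_end_to_end(tmp_path, small_obo, rng):
    mapping = {f"p{i}": ["GO:0000004"] for i in range(10)}
    mapping.update({f"q{i}": ["GO:0000003"] for i in range(30)})
    gm = read_ontology(small_obo, write_annotations(tmp_path, mapping))
    bg = build_background(gm, set(mapping))
    labels = pd.Series([1] * 10 + [2] * 30,
                       index=pd.Index(sorted(mapping,
                                             key=lambda s: (s[0], int(s[1:])))))
    clades = CladeAssignment(linkage=np.empty((0, 4)),
                             protein_ids=list(labels.index), cut_height=None,
                             labels=labels, n_clades=2)
    table = enrich_clades(clades, bg)
    # clade 1 is exactly the GO:0000004 carriers: strong over-representation
    row = table[(table["clade"] == 1) & (table["term"] == "GO:0000004")]
    assert row["count_in_clade"].iloc[0] == 10
    assert row["p_value"].iloc[0] < 1e-6
    assert row["significant"].iloc[0]
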