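"""Clade-wise GO term over-representation with a Fisher exact test.

For each (clade, term) pair a 2x2 table is formed over the background set —
all detected proteins carrying at least one GO annotation — and the
one-sided (over-representation) Fisher exact p-value computed; this equals
the hypergeometric upper tail

    p = P[K >= k]  with  K ~ Hypergeom(N = |background|,
                                       K_pop = term count in background,
                                       n = |clade|).

Terms are kept when p < alpha (strict) and the term occurs at least
``min_background_count`` times in the background; no multiple-testing
correction is applied by default because clade tests over a GO DAG are not
independent (an optional Benjamini-Hochberg mode exists). Significant terms
can be rolled up to their minimal ancestors within a GO-Slim subset.

Annotations are used after true-path propagation (see
:func:`protasca.io.read_ontology`); the classic per-term Fisher test is
implemented, without topGO-style parent-child decorrelation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .cluster import CladeAssignment
from .io import GoAnnotationMap, ProtascaError


@dataclass
class Background:
    """Annotated detected proteins, their term sets, and per-term counts."""

    proteins: frozenset[str]
    term_counts: Counter
    protein_terms: dict[str, frozenset[str]]

    @property
    def size(self) -> int:
        return len(self.proteins)


def build_background(annotations: GoAnnotationMap,
                     detected: set[str] | frozenset[str],
                     aspect: str | None = None) -> Background:
    """Background = detected proteins with >=1 (propagated) GO annotation.

    ``aspect`` optionally restricts terms to one GO namespace
    (``biological_process``, ``molecular_function``, ``cellular_component``).
    """
    if not detected:
        raise ProtascaError("empty detected-protein set")
    kept: dict[str, frozenset[str]] = {}
    for pid in detected:
        terms = annotations.annotations.get(pid, frozenset())
        if aspect is not None:
            terms = frozenset(t for t in terms
                              if annotations.namespace(t) == aspect)
        if terms:
            kept[pid] = terms
    if not kept:
        raise ProtascaError("no detected protein carries a GO annotation")
    counts: Counter = Counter()
    for terms in kept.values():
        counts.update(terms)
    return Background(proteins=frozenset(kept), term_counts=counts,
                      protein_terms=kept)


def fisher_enrichment(clade: set[str] | frozenset[str],
                      background: Background, term: str) -> float:
    """One-sided Fisher exact p for over-representation of ``term`` in ``clade``.

    The clade must be a subset of the background. Computed as the
    hypergeometric upper tail, which is exactly the one-sided Fisher p for
    the 2x2 table [in-clade with/without term; out-of-clade with/without].
    """
    clade = frozenset(clade)
    if not clade <= background.proteins:
        extra = sorted(clade - background.proteins)[:5]
        raise ProtascaError(f"clade proteins outside background: {extra} ...")
    if term not in background.term_counts:
        raise ProtascaError(f"term {term!r} absent from background")
    k = sum(1 for p in clade if term in background.protein_terms[p])
    N = background.size
    K = background.term_counts[term]
    n = len(clade)
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_clades(clades: CladeAssignment, background: Background,
                  alpha: float = 0.05,
                  min_background_count: int = 5) -> pd.DataFrame:
    """Fisher test of every background term against every clade.

    Clade membership is intersected with the background (proteins without
    annotations cannot contribute). Returns one row per (clade, term) with
    counts, p-value and the significance flag
    ``p < alpha AND background count >= min_background_count``.
    """
    protein_terms = background.protein_terms
    rows = []
    for clade in sorted(clades.labels.unique()):
        members = frozenset(clades.members(clade)) & background.proteins
        if not members:
            continue
        clade_counts: Counter = Counter()
        for p in members:
            clade_counts.update(protein_terms[p])
        n = len(members)
        for term, K in background.term_counts.items():
            k = clade_counts.get(term, 0)
            p_val = float(hypergeom.sf(k - 1, background.size, K, n))
            rows.append({
                "clade": clade,
                "term": term,
                "count_in_clade": k,
                "clade_size_annotated": n,
                "count_in_background": K,
                "background_size": background.size,
                "p_value": p_val,
                "significant": (p_val < alpha) and (K >= min_background_count),
            })
    return pd.DataFrame(rows)


def apply_significance_filters(table: pd.DataFrame, alpha: float = 0.05,
                               min_background_count: int = 5,
                               correction: str | None = None) -> pd.DataFrame:
    """Keep terms with p < alpha (strict) and background count >= threshold.

    ``correction="bh"`` switches the p column to Benjamini-Hochberg adjusted
    values (per clade) before filtering; default is no correction.
    """
    t = table.copy()
    pcol = "p_value"
    if correction == "bh":
        from scipy.stats import false_discovery_control

        t["p_adjusted"] = (t.groupby("clade")["p_value"]
                           .transform(lambda p: false_discovery_control(p, method="bh")))
        pcol = "p_adjusted"
    elif correction is not None:
        raise ProtascaError(f"unknown correction {correction!r}")
    keep = (t[pcol] < alpha) & (t["count_in_background"] >= min_background_count)
    return t.loc[keep].reset_index(drop=True)


def rollup_to_slim(terms: list[str] | pd.Series,
                   annotations: GoAnnotationMap,
                   slim_subset: frozenset[str] | None = None) -> dict[str, frozenset[str]]:
    """Map each term to its minimal ancestors within a GO-Slim subset.

    A term already in the slim maps to itself. Otherwise its slim ancestors
    are collected and only the minimal (most specific) ones kept: a slim
    ancestor is dropped when another kept slim ancestor is its descendant.
    Terms with no slim ancestor map to ``frozenset({"unmapped"})``.
    """
    slim = slim_subset if slim_subset is not None else annotations.slim_subset
    if not slim:
        raise ProtascaError("empty GO-Slim subset")
    out: dict[str, frozenset[str]] = {}
    for term in terms:
        if term in out:
            continue
        if term in slim:
            out[term] = frozenset({term})
            continue
        candidates = annotations.ancestors(term) & slim
        if not candidates:
            out[term] = frozenset({"unmapped"})
            continue
        minimal = {c for c in candidates
                   if not any(c in annotations.ancestors(other)
                              for other in candidates if other != c)}
        out[term] = frozenset(minimal)
    return out


def slim_count_matrix(filtered: pd.DataFrame,
                      annotations: GoAnnotationMap,
                      slim_subset: frozenset[str] | None = None) -> pd.DataFrame:
    """Clade x slim-term count matrix of significant terms (heatmap input)."""
    mapping = rollup_to_slim(list(filtered["term"].unique()), annotations,
                             slim_subset)
    counts: Counter = Counter()
    for _, row in filtered.iterrows():
        for slim_term in mapping[row["term"]]:
            counts[(row["clade"], slim_term)] += 1
    if not counts:
        return pd.DataFrame()
    df = pd.Series(counts).unstack(fill_value=0)
    df.index.name = "clade"
    return df
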