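"""GO-term enrichment of a protein set via Fisher's exact test.

Annotations are closed under ``is_a`` propagation (annotating a term
implies all of its ancestors), terms are restricted to the first four
levels of each ontology namespace (level = shortest ``is_a`` path from
the namespace root, roots at level 0), and one-sided Fisher exact
p-values are Bonferroni-corrected per namespace over the terms actually
tested.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import fisher_exact

NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

__all__ = [
    "OntologyGraph",
    "load_ontology",
    "load_gaf",
    "propagate_annotations",
    "fisher_term",
    "enrich",
]


@dataclass
class OntologyGraph:
    """An ``is_a`` ontology DAG with per-term levels.

    ``graph`` holds child -> parent ``is_a`` edges; ``levels`` maps each
    term to the length of its shortest ``is_a`` path from the namespace
    root (roots are level 0).
    """

    graph: nx.DiGraph
    names: dict[str, str]
    namespaces: dict[str, str]  # term -> MF | BP | CC
    levels: dict[str, int]
    roots: dict[str, str]  # namespace -> root term

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus everything reachable along ``is_a``."""
        return {term} | nx.descendants(self.graph, term)


def load_ontology(obo_text: str) -> OntologyGraph:
    """Parse OBO 1.2 text into an :class:`OntologyGraph`.

    Only ``is_a`` edges are used; obsolete terms are dropped by the
    reader.  Raises ``ValueError`` on a cyclic graph, a namespace with
    several roots, or a term that cannot reach its namespace root.
    """
    multi = obonet.read_obo(io.StringIO(obo_text))
    g = nx.DiGraph()
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for node, data in multi.nodes(data=True):
        ns = data.get("namespace")
        if ns not in NAMESPACES:
            continue
        g.add_node(node)
        names[node] = data.get("name", node)
        namespaces[node] = NAMESPACES[ns]
    for u, v, key in multi.edges(keys=True):
        if key == "is_a" and u in namespaces and v in namespaces:
            g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology is_a graph contains a cycle")

    roots: dict[str, str] = {}
    for node in g.nodes:
        if g.out_degree(node) == 0:
            ns = namespaces[node]
            if ns in roots:
                raise ValueError(f"namespace {ns} has multiple roots "
                                 f"({roots[ns]}, {node})")
            roots[ns] = node

    levels: dict[str, int] = {}
    rg = g.reverse(copy=False)
    for ns, root in roots.items():
        for node, depth in nx.single_source_shortest_path_length(rg, root).items():
            levels[node] = depth
    unreachable = set(g.nodes) - set(levels)
    if unreachable:
        raise ValueError(f"terms cannot reach their namespace root: "
                         f"{sorted(unreachable)[:5]}")
    return OntologyGraph(g, names, namespaces, levels, roots)


def load_gaf(gaf_text: str) -> dict[str, set[str]]:
    """Protein -> GO-term sets from GAF 2.x text.

    Uses object id (column 2) and GO id (column 5); rows qualified with
    NOT are dropped.
    """
    from Bio.UniProt import GOA

    annotations: dict[str, set[str]] = {}
    for rec in GOA.gafiterator(io.StringIO(gaf_text)):
        quals = rec.get("Qualifier") or []
        if any("NOT" in q for q in quals):
            continue
        annotations.setdefault(rec["DB_Object_ID"], set()).add(rec["GO_ID"])
    return annotations


def propagate_annotations(annotations: dict[str, set[str]],
                          ontology: OntologyGraph) -> dict[str, set[str]]:
    """Close each protein's term set under ``is_a`` ancestor propagation.

    Terms absent from the ontology are dropped.
    """
    @lru_cache(maxsize=None)
    def anc(term: str) -> frozenset:
        return frozenset(ontology.ancestors(term))

    closed = {}
    for pid, terms in annotations.items():
        s: set[str] = set()
        for t in terms:
            if t in ontology.namespaces:
                s |= anc(t)
        closed[pid] = s
    return closed


def fisher_term(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p-value for a 2x2 table.

    ``a``: target proteins with the term, ``b``: target without,
    ``c``: background-only with, ``d``: background-only without.  The
    p-value is the hypergeometric tail P(X >= a) at fixed margins.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    return float(fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrich(
    target_ids,
    background_ids,
    annotations: dict[str, set[str]],
    ontology: OntologyGraph,
    max_level: int = 4,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-exact term enrichment of a target set within a background.

    Tests every term with level in 1..``max_level`` annotating at least
    one target protein; Bonferroni m is the number of terms tested in the
    same namespace.  A term is enriched when the corrected p-value is
    below ``alpha``.  Results are sorted by namespace, then p-value.

    Raises ``ValueError`` when the target is empty or not contained in
    the background.
    """
    target = set(target_ids)
    background = set(background_ids)
    if not target:
        raise ValueError("empty target set")
    if not target <= background:
        raise ValueError("target set must be a subset of the background")

    closed = propagate_annotations(annotations, ontology)
    term_proteins: dict[str, set[str]] = {}
    for pid in background:
        for t in closed.get(pid, ()):
            term_proteins.setdefault(t, set()).add(pid)

    candidates = [
        t for t, prots in term_proteins.items()
        if 1 <= ontology.levels[t] <= max_level and prots & target
    ]
    m_by_ns: dict[str, int] = {}
    for t in candidates:
        ns = ontology.namespaces[t]
        m_by_ns[ns] = m_by_ns.get(ns, 0) + 1

    n_t, n_b = len(target), len(background)
    rows = []
    for t in candidates:
        prots = term_proteins[t]
        a = len(prots & target)
        b = n_t - a
        c = len(prots) - a
        d = (n_b - n_t) - c
        p = fisher_term(a, b, c, d)
        m = m_by_ns[ontology.namespaces[t]]
        p_bonf = min(1.0, p * m)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        fold = (a / n_t) / ((a + c) / n_b)
        rows.append({
            "term": t,
            "name": ontology.names[t],
            "namespace": ontology.namespaces[t],
            "level": ontology.levels[t],
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds,
            "fold": fold,
            "p": p,
            "p_bonferroni": p_bonf,
            "m_tests": m,
            "enriched": p_bonf < alpha,
        })
    df = pd.DataFrame(rows, columns=["term", "name", "namespace", "level",
                                     "a", "b", "c", "d", "odds_ratio", "fold",
                                     "p", "p_bonferroni", "m_tests", "enriched"])
    if len(df):
        df = df.sort_values(["namespace", "p"], kind="stable").reset_index(drop=True)
    return df
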