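"""Brute-force oracles shared by the unit and acceptance suites.

These deliberately re-derive each quantity by exhaustive enumeration so they
stay independent of the package's implementations.
"""
import itertools
import math

import networkx as nx


def brute_mcc(g, v):
    """Sum of (|C|-1)! over maximal cliques containing v, by subset enumeration."""
    nodes = list(g.nodes())
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    return sum(math.factorial(len(c) - 1) for c in maximal if v in c)


def brute_mnc_dmnc(g, v, eps=1.7):
    """(MNC, DMNC) by explicit neighborhood-component search."""
    nb = set(g[v])
    if not nb:
        return 0, 0.0
    sub = g.subgraph(nb)
    comps = list(nx.connected_components(sub))
    best = max(comps, key=lambda c: (len(c), sub.subgraph(c).number_of_edges()))
    e = sub.subgraph(best).number_of_edges()
    return len(best), e / len(best) ** eps


def brute_auc(scores, labels):
    """Concordant-pair AUC with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))
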