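"""Residue interaction network and closeness centrality.

Nodes are the Calpha atoms of protein residues; two residues interact
directly when their Calpha–Calpha distance is below 6 A (strict). Closeness
of a node u is (n-1) / sum of shortest-path distances from u, computed with
NetworkX; for disconnected graphs the Wasserman–Faust component-size scaling
applies, which reduces to the plain formula on connected graphs.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

__all__ = ["build_network", "closeness", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 6.0  # A


def build_network(cplx, threshold=DEFAULT_THRESHOLD, chains=None):
    """Residue interaction network over the protein chains of a complex.

    By default every protein (partner 1) chain contributes nodes; pass
    ``chains`` to restrict the network (e.g. to the mutated chain only).
    Residues lacking a Calpha are excluded with a warning.
    """
    residues = []
    for r in cplx.residues:
        if r.kind != "amino-acid":
            continue
        if chains is not None and r.chain not in chains:
            continue
        if r.atom("CA") is None:
            warnings.warn(f"residue {r.key} lacks CA; excluded from network")
            continue
        residues.append(r)
    g = nx.Graph()
    g.add_nodes_from(r.key for r in residues)
    coords = np.array([r.atom("CA").coords for r in residues])
    if len(residues) > 1:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        ii, jj = np.nonzero(np.triu(d < threshold, k=1))
        g.add_edges_from((residues[i].key, residues[j].key)
                         for i, j in zip(ii, jj))
    return g


def closeness(g, node):
    """Closeness centrality of ``node``: (n-1)/sum of shortest-path
    distances, Wasserman–Faust scaled on disconnected graphs; isolated
    nodes score 0 by convention."""
    if node not in g:
        raise KeyError(f"node {node} not in network")
    return nx.closeness_centrality(g, u=node, wf_improved=True)
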