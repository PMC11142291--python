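"""Biochemical/structural metabolite network assembly and export.

Nodes are metabolites passing an exploratory display rule — any-window
group-effect p below alpha (unadjusted, by design) or a large overall
effect size (|Hedge's g| above a floor). Edges connect biochemically
related metabolites (curated reactant pairs), structurally similar ones
(Tanimoto fingerprint similarity at or above a threshold), and optional
manually curated pairs. Each node carries its effect size, significance per
window, direction, and the letter code of the window with the largest
significant effect (A: 0-15 ... G: 60-120). Graphs export as SIF or
GraphML for Cytoscape-style tools; rendering is out of scope.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .auc import WINDOW_LETTERS
from .data import fingerprint_from_hex


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto (Jaccard) similarity |a & b| / |a | b| of two bit vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("Tanimoto undefined for two all-zero fingerprints")
    return float(np.logical_and(a, b).sum() / union)


def build_network(
    window_results: pd.DataFrame,
    annotations: pd.DataFrame,
    kegg_pairs: pd.DataFrame | None = None,
    manual_edges: pd.DataFrame | None = None,
    tanimoto_min: float = 0.7,
    g_floor: float = 0.8,
    alpha: float = 0.05,
    exclude_classes: tuple[str, ...] = (),
    overall_window: str = "0-120",
) -> nx.Graph:
    """Assemble the metabolite graph from per-window statistics.

    ``window_results``: long table (metabolite, window, pvalue, g).
    ``annotations``: indexed by metabolite with ``chem_class`` and
    ``fingerprint`` (hex) columns. A metabolite without a fingerprint joins
    only through reactant-pair or manual edges. ``exclude_classes`` drops
    whole classes from the exported view (e.g. the very dense glyceride
    clusters) without affecting the statistics.
    """
    g_all = window_results.pivot(index="metabolite", columns="window", values="g")
    p_all = window_results.pivot(index="metabolite", columns="window", values="pvalue")

    G = nx.Graph()
    for m in g_all.index:
        gs, ps = g_all.loc[m], p_all.loc[m]
        include = bool((ps < alpha).any()) or bool((gs.abs() > g_floor).any())
        if not include:
            continue
        cls = annotations["chem_class"].get(m, "") if "chem_class" in annotations else ""
        if cls in exclude_classes:
            continue
        sig = ps[ps < alpha]
        letter = ""
        if len(sig):
            best = gs.loc[sig.index].abs().idxmax()
            letter = WINDOW_LETTERS.get(best, "")
        overall_g = (
            float(gs[overall_window])
            if overall_window in gs and np.isfinite(gs[overall_window])
            else float(gs.loc[gs.abs().idxmax()])
        )
        G.add_node(
            m,
            chem_class=str(cls),
            g=overall_g,
            direction="higher" if overall_g > 0 else "lower",
            window_letter=letter,
            min_p=float(ps.min()),
        )

    nodes = list(G.nodes)
    fps = {}
    for m in nodes:
        hexfp = annotations["fingerprint"].get(m) if "fingerprint" in annotations else None
        if isinstance(hexfp, str) and hexfp:
            fps[m] = fingerprint_from_hex(hexfp, n_bits=len(hexfp) * 4)
        else:
            warnings.warn(f"{m}: no fingerprint; structural edges skipped")
    for a, b in itertools.combinations(nodes, 2):
        if a in fps and b in fps and len(fps[a]) == len(fps[b]):
            sim = tanimoto(fps[a], fps[b])
            if sim >= tanimoto_min:
                G.add_edge(a, b, edge_type="tanimoto", similarity=round(sim, 6))
    if kegg_pairs is not None:
        for _, row in kegg_pairs.iterrows():
            a, b = row["metabolite_a"], row["metabolite_b"]
            if a != b and G.has_node(a) and G.has_node(b) and not G.has_edge(a, b):
                G.add_edge(a, b, edge_type="kegg_rpair")
    if manual_edges is not None:
        for _, row in manual_edges.iterrows():
            a, b = row["metabolite_a"], row["metabolite_b"]
            if a != b and G.has_node(a) and G.has_node(b) and not G.has_edge(a, b):
                G.add_edge(a, b, edge_type="manual")
    return G


def export_graph(G: nx.Graph, path, fmt: str = "graphml") -> Path:
    """Write the graph as SIF (``source <type> target`` rows) or GraphML."""
    path = Path(path)
    if fmt == "sif":
        lines = [
            f"{a}\t{d.get('edge_type', 'link')}\t{b}" for a, b, d in G.edges(data=True)
        ]
        isolated = [n for n in G.nodes if G.degree(n) == 0]
        lines += [str(n) for n in isolated]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown export format: {fmt!r} (use 'sif' or 'graphml')")
    return path


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(Path(path))
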