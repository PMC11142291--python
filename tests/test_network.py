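"""Network assembly: similarity, inclusion rule, letters, export round-trip."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ogttmet.data import fingerprint_from_hex, fingerprint_to_hex
from ogttmet.network import build_network, export_graph, read_graphml, tanimoto


class TestTanimoto:
    def test_identity_disjoint_and_hand_case(self):
        a = np.array([1, 1, 0, 0], dtype=bool)
        b = np.array([1, 0, 1, 0], dtype=bool)
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, ~a) == 0.0
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.random(32) < 0.4, rng.random(32) < 0.4
            if not (a | b).any():
                continue
            assert tanimoto(a, b) == tanimoto(b, a)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto([1, 0], [1, 0, 1])
        with pytest.raises(ValueError, match="all-zero"):
            tanimoto([0, 0], [0, 0])


def test_fingerprint_hex_roundtrip():
    rng = np.random.default_rng(1)
    bits = rng.random(64) < 0.5
    assert (fingerprint_from_hex(fingerprint_to_hex(bits), 64) == bits).all()


def window_results(rows):
    return pd.DataFrame(rows, columns=["metabolite", "window", "pvalue", "g"])


def annotations(fps: dict[str, str], classes: dict[str, str] | None = None):
    classes = classes or {}
    return pd.DataFrame(
        {
            "chem_class": pd.Series({m: classes.get(m, "x") for m in fps}),
            "fingerprint": pd.Series(fps),
        }
    )


class TestBuildNetwork:
    def test_inclusion_rule_exact_disjunction(self):
        res = window_results(
            [
                ("sig", "0-120", 0.01, 0.2),     # p rule
                ("big", "0-120", 0.50, 0.9),     # |g| rule
                ("neither", "0-120", 0.50, 0.2),
            ]
        )
        ann = annotations({m: "ff00ff00" for m in ("sig", "big", "neither")})
        G = build_network(res, ann)
        assert set(G.nodes) == {"sig", "big"}

    def test_empty_when_nothing_passes(self):
        res = window_results([("a", "0-120", 0.9, 0.1)])
        G = build_network(res, annotations({"a": "ff"}))
        assert len(G) == 0

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"m{k}", "0-120", rng.random(), rng.normal(0, 0.6)) for k in range(30)
        ]
        res = window_results(rows)
        ann = annotations({f"m{k}": "0f0f" for k in range(30)})
        strict = set(build_network(res, ann, alpha=0.03, g_floor=1.0).nodes)
        loose = set(build_network(res, ann, alpha=0.10, g_floor=0.5).nodes)
        assert strict <= loose

    def test_window_letter_largest_significant_effect(self):
        res = window_results(
            [
                ("m", "0-15", 0.01, 0.4),
                ("m", "0-120", 0.02, 0.9),
                ("m", "60-120", 0.30, 1.5),  # biggest |g| but not significant
            ]
        )
        G = build_network(res, annotations({"m": "ff"}))
        assert G.nodes["m"]["window_letter"] == "D"  # 0-120 wins among significant
        assert G.nodes["m"]["g"] == pytest.approx(0.9)

    def test_tanimoto_and_kegg_edges(self):
        fp_a = fingerprint_to_hex(np.array([1] * 12 + [0] * 4, dtype=bool))
        fp_b = fingerprint_to_hex(np.array([1] * 10 + [0] * 6, dtype=bool))
        fp_c = fingerprint_to_hex(np.array([0] * 12 + [1] * 4, dtype=bool))
        res = window_results(
            [("a", "0-120", 0.01, 1.0), ("b", "0-120", 0.01, 1.0),
             ("c", "0-120", 0.01, 1.0)]
        )
        ann = annotations({"a": fp_a, "b": fp_b, "c": fp_c})
        pairs = pd.DataFrame({"metabolite_a": ["a"], "metabolite_b": ["c"]})
        G = build_network(res, ann, kegg_pairs=pairs, tanimoto_min=0.7)
        assert G.edges["a", "b"]["edge_type"] == "tanimoto"
        assert G.edges["a", "b"]["similarity"] == pytest.approx(10 / 12, abs=1e-6)
        assert G.edges["a", "c"]["edge_type"] == "kegg_rpair"
        assert not G.has_edge("b", "c")

    def test_class_exclusion_toggle(self):
        res = window_results(
            [("tg", "0-120", 0.01, 1.0), ("aa", "0-120", 0.01, 1.0)]
        )
        ann = annotations(
            {"tg": "ff", "aa": "0f"}, classes={"tg": "triglycerides", "aa": "amino"}
        )
        G = build_network(res, ann, exclude_classes=("triglycerides",))
        assert set(G.nodes) == {"aa"}

    def test_planted_class_connected_component(self, small_cohort):
        from ogttmet.auc import build_auc_table
        from ogttmet.univariate import group_effects_all_windows

        _, ds, truth = small_cohort
        feats = build_auc_table(ds, log10=True)
        stats = group_effects_all_windows(feats)
        G = build_network(stats, ds.annotations, ds.kegg_pairs)
        comps = list(nx.connected_components(G))
        planted = set(truth.enriched_members)
        best = max(comps, key=lambda c: len(c & planted))
        assert len(best & planted) >= 5


class TestExport:
    def test_empty_graph_valid(self, tmp_path):
        G = nx.Graph()
        p = export_graph(G, tmp_path / "empty.sif", "sif")
        assert p.read_text() == ""
        p2 = export_graph(G, tmp_path / "empty.graphml", "graphml")
        assert len(read_graphml(p2)) == 0

    def test_three_node_path_two_sif_rows(self, tmp_path):
        G = nx.Graph()
        G.add_edge("a", "b", edge_type="tanimoto")
        G.add_edge("b", "c", edge_type="kegg_rpair")
        p = export_graph(G, tmp_path / "path.sif", "sif")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 2
        assert all(len(l.split("\t")) == 3 for l in lines)

    def test_graphml_roundtrip_equality(self, tmp_path):
        rng = np.random.default_rng(3)
        G = nx.Graph()
        for k in range(50):
            G.add_node(f"n{k}", g=float(rng.normal()), window_letter="D",
                       chem_class="x", direction="higher", min_p=0.5)
        for a, b in itertools.combinations(range(50), 2):
            if rng.random() < 0.05:
                G.add_edge(f"n{a}", f"n{b}", edge_type="tanimoto",
                           similarity=float(round(rng.random(), 6)))
        p = export_graph(G, tmp_path / "g.graphml", "graphml")
        H = read_graphml(p)
        assert set(H.nodes) == set(G.nodes)
        assert {frozenset(e) for e in H.edges} == {frozenset(e) for e in G.edges}
        for n in G.nodes:
            assert H.nodes[n]["g"] == pytest.approx(G.nodes[n]["g"])

    def test_unknown_format_errors(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_graph(nx.Graph(), tmp_path / "x", "dot")
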