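"""Modified cosine scoring and molecular-network construction."""

import numpy as np
import networkx as nx
import pytest
from helpers import brute_force_cosine, random_spectrum

from conjnet.feature_io import Spectrum
from conjnet.spectral_network import (
    CosineParams,
    build_network,
    decorate_nodes,
    export_graph,
    modified_cosine,
)


def spec(fid, peaks, precursor=500.0):
    return Spectrum(feature_id=fid, precursor_mz=precursor, peaks=np.asarray(peaks, float))


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        for k in range(10):
            s = random_spectrum(rng, n_peaks=8, feature_id=f"s{k}")
            score, n = modified_cosine(s, s, CosineParams(min_matched_peaks=1))
            assert score == pytest.approx(1.0, abs=1e-9)
            assert n == len(s)

    def test_disjoint_spectra_score_zero(self):
        a = spec("a", [[100.0, 50.0], [200.0, 50.0]], precursor=300.0)
        b = spec("b", [[150.0, 50.0], [250.0, 50.0]], precursor=300.0)
        assert modified_cosine(a, b, CosineParams(min_matched_peaks=1)) == (0.0, 0)

    def test_min_matched_peaks_gates_score(self):
        a = spec("a", [[100.0, 50.0], [200.0, 50.0], [300.0, 50.0]])
        score, n = modified_cosine(a, a, CosineParams(min_matched_peaks=4))
        assert score == 0.0 and n == 3

    def test_precursor_shift_matches_offset_fragments(self):
        # analogue pair: all fragments offset by the precursor difference
        a = spec("a", [[100.0, 50.0], [150.0, 80.0], [220.0, 30.0], [300.0, 10.0]], precursor=400.0)
        b = spec("b", [[110.0, 50.0], [160.0, 80.0], [230.0, 30.0], [310.0, 10.0]], precursor=410.0)
        score, n = modified_cosine(a, b, CosineParams(min_matched_peaks=1))
        assert score == pytest.approx(1.0, abs=1e-9)
        assert n == 4
        plain = CosineParams(min_matched_peaks=1, allow_precursor_shift=False)
        assert modified_cosine(a, b, plain)[0] == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        params = CosineParams(min_matched_peaks=1)
        for _ in range(30):
            a = random_spectrum(rng, feature_id="a")
            b = random_spectrum(rng, feature_id="b", mz_range=(50.0, 200.0))
            ab, _ = modified_cosine(a, b, params)
            ba, _ = modified_cosine(b, a, params)
            assert ab == pytest.approx(ba, abs=1e-12)

    def test_optimal_matching_equals_brute_force(self):
        rng = np.random.default_rng(2)
        params = CosineParams(min_matched_peaks=1)
        for _ in range(40):
            a = random_spectrum(rng, feature_id="a", mz_range=(50.0, 120.0))
            b = random_spectrum(rng, feature_id="b", mz_range=(50.0, 120.0))
            score, _ = modified_cosine(a, b, params)
            assert score == pytest.approx(brute_force_cosine(a, b, params), abs=1e-9)

    def test_greedy_never_beats_optimal(self):
        rng = np.random.default_rng(3)
        optimal = CosineParams(min_matched_peaks=1)
        greedy = CosineParams(min_matched_peaks=1, matching="greedy")
        for _ in range(50):
            a = random_spectrum(rng, feature_id="a", mz_range=(50.0, 100.0))
            b = random_spectrum(rng, feature_id="b", mz_range=(50.0, 100.0))
            assert modified_cosine(a, b, greedy)[0] <= modified_cosine(a, b, optimal)[0] + 1e-12


class TestAgainstMatchms:
    def test_plain_cosine_matches_reference_implementation(self):
        """Conflict-free spectra: our plain cosine equals matchms CosineGreedy."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(4)
        params = CosineParams(
            fragment_tolerance=0.02, min_matched_peaks=1,
            allow_precursor_shift=False, intensity_power=1.0,
        )
        ref = CosineGreedy(tolerance=0.02, mz_power=0.0, intensity_power=1.0)
        grid = np.arange(100.0, 400.0, 10.0)
        for _ in range(20):
            def pick(fid):
                sel = grid[rng.random(len(grid)) < 0.4]
                if len(sel) == 0:
                    sel = grid[:1]
                mz = np.sort(sel + rng.uniform(-0.005, 0.005, len(sel)))
                return mz, rng.uniform(1.0, 100.0, len(sel))

            mza, ia = pick("a")
            mzb, ib = pick("b")
            ours, n_ours = modified_cosine(
                Spectrum("a", 500.0, np.column_stack([mza, ia])),
                Spectrum("b", 500.0, np.column_stack([mzb, ib])),
                params,
            )
            theirs = ref.pair(
                matchms.Spectrum(mz=mza, intensities=ia, metadata={"precursor_mz": 500.0},
                                 metadata_harmonization=False),
                matchms.Spectrum(mz=mzb, intensities=ib, metadata={"precursor_mz": 500.0},
                                 metadata_harmonization=False),
            )
            assert ours == pytest.approx(float(theirs["score"]), abs=1e-6)
            assert n_ours == int(theirs["matches"])


class TestBuildNetwork:
    def test_identical_spectra_form_one_clique(self):
        peaks = [[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]]
        spectra = [spec(f"s{i}", peaks) for i in range(3)]
        net = build_network(spectra, CosineParams())
        assert len(net.components) == 1
        assert net.graph.number_of_edges() == 3

    def test_threshold_one_with_distinct_spectra_gives_singletons(self):
        rng = np.random.default_rng(5)
        spectra = [random_spectrum(rng, n_peaks=6, feature_id=f"s{i}") for i in range(6)]
        net = build_network(spectra, CosineParams(score_threshold=1.0))
        assert net.graph.number_of_edges() == 0
        assert len(net.components) == 6

    def test_polarities_never_mixed(self):
        peaks = [[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]]
        spectra = [spec("p", peaks), spec("n", peaks)]
        net = build_network(spectra, CosineParams(), polarities={"p": 1, "n": -1})
        assert net.graph.number_of_edges() == 0

    def test_generator_families_form_pure_components(self, paper_like, paper_like_network):
        from conjnet.synthdata import truth_score

        report = truth_score(paper_like.truth, network=paper_like_network)
        assert report["network"]["family_purity"] == 1.0

    def test_raising_threshold_only_refines_components(self, paper_like):
        pols = paper_like.polarities()
        low = build_network(paper_like.spectra, CosineParams(score_threshold=0.7), pols)
        high = build_network(paper_like.spectra, CosineParams(score_threshold=0.85), pols)
        low_of = {fid: comp for comp in low.components for fid in comp}
        for comp in high.components:
            assert len({low_of[fid] for fid in comp}) == 1


class TestDecorateAndExport:
    def test_fold_change_attributes(self):
        peaks = [[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]]
        net = build_network([spec(f"s{i}", peaks) for i in range(3)], CosineParams())
        decorate_nodes(net, fold_changes={"s0": 0.0, "s1": 2.0})
        assert net.graph.nodes["s0"]["log2fc"] == 0.0
        assert net.graph.nodes["s1"]["log2fc"] == 2.0
        assert "log2fc" not in net.graph.nodes["s2"]  # missing stays absent

    def test_graphml_round_trip(self, tmp_path):
        peaks = [[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]]
        net = build_network([spec(f"s{i}", peaks) for i in range(3)], CosineParams())
        export_graph(net, tmp_path / "net.graphml")
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_nodes() == 3
        for u, v, d in net.graph.edges(data=True):
            assert float(back.edges[u, v]["score"]) == pytest.approx(d["score"], abs=1e-6)

    def test_empty_network_is_valid_graphml(self, tmp_path):
        from conjnet.spectral_network import MolecularNetwork

        export_graph(MolecularNetwork(nx.Graph()), tmp_path / "empty.graphml")
        assert nx.read_graphml(tmp_path / "empty.graphml").number_of_nodes() == 0

    def test_edgelist_export(self, tmp_path):
        import pandas as pd

        peaks = [[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]]
        net = build_network([spec(f"s{i}", peaks) for i in range(3)], CosineParams())
        export_graph(net, tmp_path / "net.csv", fmt="edgelist")
        assert len(pd.read_csv(tmp_path / "net.csv")) == 3
        assert len(pd.read_csv(tmp_path / "net.csv.nodes.csv")) == 3
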