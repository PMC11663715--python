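"""The annotation cascade: mass/RT search, MS2 matching, propagation, screen."""

import numpy as np
import pytest
from helpers import mini_table

from conjnet.annotate import (
    Annotation,
    MassRtLibraryEntry,
    SpectralLibraryEntry,
    annotate_cascade,
    match_mass_rt,
    match_spectral_library,
    propagate_categories,
    screen_conjugates,
    verification_hook,
)
from conjnet.chemmass import build_conjugate_library, parse_formula
from conjnet.feature_io import Spectrum
from conjnet.spectral_network import CosineParams, build_network


def one_feature(mz, rt=8.3, polarity=-1, fid="f1"):
    return mini_table([{"id": fid, "polarity": polarity, "mz": mz, "rt": rt, "s1": 1.0}])


class TestMatchMassRt:
    def test_match_within_tolerances(self):
        lib = [MassRtLibraryEntry("Glu-conj", "N-acyl amino acids", 392.2079, rt=8.3)]
        anns = match_mass_rt(one_feature(392.2080), lib)
        assert len(anns) == 1
        assert anns[0].label == "Glu-conj" and anns[0].level == 1

    def test_rt_gate_blocks_mass_match(self):
        lib = [MassRtLibraryEntry("Glu-conj", "N-acyl amino acids", 392.2079, rt=8.8)]
        assert match_mass_rt(one_feature(392.2079, rt=8.3), lib) == []

    def test_exact_mass_only_entry_is_level_two(self):
        lib = [MassRtLibraryEntry("Glu-conj", "N-acyl amino acids", 392.2079)]
        anns = match_mass_rt(one_feature(392.2079, rt=3.0), lib)
        assert anns[0].level == 2

    def test_nearest_entry_wins(self):
        lib = [
            MassRtLibraryEntry("far", "x", 392.2079 + 0.003),
            MassRtLibraryEntry("near", "x", 392.2079 - 0.002),
        ]
        anns = match_mass_rt(one_feature(392.2079), lib)
        assert anns[0].label == "near"

    def test_ppm_window_widens_for_heavy_ions(self):
        # at m/z 1000, 10 ppm = 0.01 Da > 0.005 Da absolute
        lib = [MassRtLibraryEntry("heavy", "x", 1000.0)]
        assert match_mass_rt(one_feature(1000.008), lib)
        assert not match_mass_rt(one_feature(1000.012), lib)


class TestMatchSpectralLibrary:
    peaks = np.array([[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]])

    def _entry(self, name="ref", category="oxylipins"):
        return SpectralLibraryEntry(
            id="lib1", name=name, category=category,
            spectrum=Spectrum("lib1", 400.0, self.peaks),
        )

    def test_identical_spectrum_annotated(self):
        query = Spectrum("q", 400.0, self.peaks)
        anns = match_spectral_library([query], [self._entry()])
        assert anns[0].label == "ref" and anns[0].level == 2
        assert anns[0].evidence["score"] == pytest.approx(1.0, abs=1e-9)

    def test_three_shared_peaks_rejected(self):
        query = Spectrum("q", 400.0, self.peaks[:3])
        assert match_spectral_library([query], [self._entry()]) == []


class TestPropagateCategories:
    @staticmethod
    def _net(groups):
        """Build a network of identical-spectrum cliques, one per group."""
        spectra = []
        for g, ids in enumerate(groups):
            peaks = np.array(
                [[100.0 + 17 * g + 13 * k, 50.0] for k in range(4)]
            )
            spectra.extend(Spectrum(fid, 400.0 + 50 * g, peaks) for fid in ids)
        return build_network(spectra, CosineParams())

    @staticmethod
    def _seed(fid, category, score=0.9):
        return Annotation(fid, category, category, 2, {"score": score})

    def test_single_seed_fills_component(self):
        net = self._net([["A", "B", "C"]])
        anns = propagate_categories(net, [self._seed("A", "oxylipins")])
        assert {a.feature_id: a.category for a in anns} == {"B": "oxylipins", "C": "oxylipins"}
        assert all(a.level == 3 for a in anns)

    def test_majority_wins_and_conflict_flagged(self):
        net = self._net([["A", "B", "C", "D"]])
        seeds = [
            self._seed("A", "flavonoids"),
            self._seed("B", "flavonoids"),
            self._seed("C", "terpenoids"),
        ]
        anns = propagate_categories(net, seeds)
        assert len(anns) == 1
        assert anns[0].category == "flavonoids"
        assert anns[0].evidence["conflict"] is True
        assert anns[0].evidence["seed_categories"] == {"flavonoids": 2, "terpenoids": 1}

    def test_tie_broken_by_strongest_seed(self):
        net = self._net([["A", "B", "C"]])
        seeds = [self._seed("A", "flavonoids", 0.95), self._seed("B", "terpenoids", 0.85)]
        anns = propagate_categories(net, seeds)
        assert anns[0].category == "flavonoids"

    def test_unseeded_component_stays_unannotated(self):
        net = self._net([["A", "B"], ["X"]])
        anns = propagate_categories(net, [self._seed("A", "oxylipins")])
        assert {a.feature_id for a in anns} == {"B"}

    def test_idempotent(self):
        net = self._net([["A", "B", "C"]])
        seeds = [self._seed("A", "oxylipins")]
        first = propagate_categories(net, seeds)
        second = propagate_categories(net, seeds + first)
        assert second == []
        again = propagate_categories(net, seeds)
        assert [(a.feature_id, a.category, a.level) for a in again] == [
            (a.feature_id, a.category, a.level) for a in first
        ]


class TestScreenConjugates:
    lib = build_conjugate_library({"dn-iso-OPDA": parse_formula("C16H24O3")})

    def test_found_mass_matches_glu_conjugate(self):
        anns = screen_conjugates(one_feature(392.2068), self.lib)
        assert anns[0].label == "putative dn-iso-OPDA-Glu"
        assert anns[0].evidence["delta_ppm"] == pytest.approx(2.8, abs=0.2)

    def test_distant_mass_not_matched(self):
        assert screen_conjugates(one_feature(392.30), self.lib) == []

    def test_wrong_polarity_not_matched(self):
        assert screen_conjugates(one_feature(392.2068, polarity=1), self.lib) == []

    def test_leu_ile_reported_jointly(self):
        leu = next(e for e in self.lib if e.amino_acid == "Leu")
        anns = screen_conjugates(one_feature(leu.mz["[M-H]-"]), self.lib)
        assert len(anns) == 1
        assert anns[0].label == "putative dn-iso-OPDA-Ile/Leu"
        assert anns[0].evidence["ambiguous_amino_acids"] == ["Ile", "Leu"]


class TestCascade:
    def test_level_one_never_overwritten(self):
        peaks = np.array([[100.0, 50.0], [150.0, 60.0], [200.0, 70.0], [250.0, 80.0]])
        table = one_feature(392.2079, rt=8.3, fid="f1")
        spectra = [Spectrum("f1", 392.2079, peaks)]
        masslib = [MassRtLibraryEntry("standard", "oxylipins", 392.2079, rt=8.3)]
        speclib = [SpectralLibraryEntry("L", "ms2-hit", "flavonoids", Spectrum("L", 392.2079, peaks))]
        net = build_network(spectra, CosineParams())
        result = annotate_cascade(table, spectra, masslib, speclib, net)
        assert result["f1"].label == "standard" and result["f1"].level == 1
        assert result["f1"].evidence["superseded"][0]["label"] == "ms2-hit"

    def test_cascade_recovers_generator_categories(self, paper_like, paper_like_network):
        from conjnet.synthdata import truth_libraries, truth_score

        masslib, speclib = truth_libraries(paper_like)
        result = annotate_cascade(
            paper_like.table, paper_like.spectra, masslib, speclib, paper_like_network
        )
        report = truth_score(paper_like.truth, annotations=result)
        assert report["annotation"]["category_accuracy"] >= 0.95

    def test_verification_hook_flags_propagated(self):
        anns = {
            "a": Annotation("a", "x", "x", 1, {}),
            "b": Annotation("b", "x", "x", 3, {"step": "network_propagation"}),
        }
        assert verification_hook(anns) == ["b"]
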