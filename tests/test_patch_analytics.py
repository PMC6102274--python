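"""Patch descriptors: hydrophobicity, SASA, similarity, binning."""

import numpy as np
import pytest

from ppikit.contacts import Patch, build_interfaces, extract_patches
from ppikit.fixtures import FixtureSpec, make_structure
from ppikit.patch_analytics import (
    HYDROPHOBICITY_BINS, RESIDUE_BINS, SASA_BINS, SIMILARITY_BINS,
    HydrophobicityScale, bin_distribution, chain_sasa, classify_dimer,
    hydrophobicity_score, patch_sasa, patch_similarity, sequence_identity_pct,
    shrake_rupley, summarize_patch,
)
from ppikit.structure_io import parse_pdb


def dimer_model(residues_a, residues_b, seed=0, atoms_per_chain=None):
    n = max(len(residues_a), len(residues_b))
    spec = FixtureSpec(
        seed=seed, n_chains=2,
        atoms_per_chain=atoms_per_chain or 4 * n,
        residue_names=(tuple(residues_a), tuple(residues_b)),
        jitter=0.0,
    )
    text, _ = make_structure(spec)
    model = parse_pdb(text)
    interface = build_interfaces(model)[0]
    return model, interface


class TestHydrophobicity:
    def test_scale_endpoints_are_ile_and_asp(self):
        scale = HydrophobicityScale.hessa()
        scores = scale.score_by_residue
        assert min(scores, key=scores.get) == "I"
        assert max(scores, key=scores.get) == "D"
        assert scores["I"] == pytest.approx(-0.60)
        assert scores["D"] == pytest.approx(3.49)

    @pytest.mark.parametrize("resname,expected", [("ASP", 3.49), ("ILE", -0.60)])
    def test_single_residue_patch(self, resname, expected):
        model, interface = dimer_model([resname], ["GLY"])
        patch = extract_patches(interface)[0]
        assert patch.residue_count == 1
        score = hydrophobicity_score(patch, model.chain("A"))
        assert score == pytest.approx(expected)

    def test_two_residue_patch_sums_endpoints(self):
        model, interface = dimer_model(["ILE", "ASP"], ["GLY", "GLY"])
        patch = extract_patches(interface)[0]
        assert patch.residue_count == 2
        score = hydrophobicity_score(patch, model.chain("A"))
        assert score == pytest.approx(-0.60 + 3.49)

    def test_empty_patch_scores_zero(self):
        model, _ = dimer_model(["ALA"], ["GLY"])
        empty = Patch(chain_id="A", interacting_atoms=[])
        assert hydrophobicity_score(empty, model.chain("A")) == 0.0


class TestSasa:
    def test_isolated_atom_matches_the_analytic_sphere(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.70]), n_points=960)[0]
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.015)

    def test_disjoint_spheres_are_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        areas = shrake_rupley(coords, np.array([1.70, 1.70]), n_points=960)
        assert areas[1] == pytest.approx(areas[0])
        single = shrake_rupley(coords[:1], np.array([1.70]), n_points=960)[0]
        assert areas.sum() == pytest.approx(2 * single)

    def test_caged_atom_is_buried(self):
        # 12 neighbours at 2.5 Å (icosahedron vertices) occlude the centre
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array([[0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
                          [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
                          [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1]])
        verts = 2.5 * verts / np.linalg.norm(verts[0])
        coords = np.vstack([[0.0, 0.0, 0.0], verts])
        areas = shrake_rupley(coords, np.full(13, 1.70), n_points=2000)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_point_count_floor(self):
        with pytest.raises(ValueError, match="n_points"):
            shrake_rupley(np.zeros((1, 3)), np.array([1.7]), n_points=50)

    def test_doubling_points_changes_patch_sasa_by_under_one_percent(self):
        model, interface = dimer_model(
            ["ALA", "SER", "THR", "VAL"], ["GLY", "GLY", "GLY", "GLY"], seed=5)
        patch = extract_patches(interface)[0]
        coarse = patch_sasa(patch, model.chain("A"), n_points=960)
        fine = patch_sasa(patch, model.chain("A"), n_points=1920)
        assert abs(fine - coarse) / fine < 0.01

    def test_patch_sasa_bounded_by_chain_sasa(self):
        model, interface = dimer_model(
            ["ALA", "SER", "THR", "VAL"], ["GLY", "GLY", "GLY", "GLY"], seed=6)
        patch = extract_patches(interface)[0]
        chain = model.chain("A")
        whole = sum(chain_sasa(chain).values())
        assert 0 < patch_sasa(patch, chain) <= whole + 1e-9

    def test_delta_sasa_is_positive_and_below_isolated(self):
        model, interface = dimer_model(
            ["ALA", "SER", "THR", "VAL"], ["LEU", "LYS", "GLU", "PHE"], seed=7)
        patch = extract_patches(interface)[0]
        chain, partner = model.chain("A"), model.chain("B")
        isolated = patch_sasa(patch, chain)
        buried = patch_sasa(patch, chain, delta=True, partner=partner)
        assert 0 < buried <= isolated

    def test_agrees_with_biotite_shrake_rupley(self):
        """Independent oracle: biotite's Shrake-Rupley on the same coordinates
        and radii should agree to within discretization error."""
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(13)
        coords = rng.uniform(0, 8, (20, 3))
        atoms = biotite_struc.AtomArray(20)
        atoms.coord = coords.astype(np.float32)
        atoms.chain_id[:] = "A"
        atoms.res_id[:] = np.arange(20) + 1
        atoms.res_name[:] = "GLY"
        atoms.atom_name[:] = "CA"
        atoms.element[:] = "C"
        theirs = biotite_struc.sasa(
            atoms, probe_radius=1.4, point_number=1000,
            vdw_radii="Single", ignore_ions=False).sum()
        ours = shrake_rupley(coords, np.full(20, 1.70), n_points=1000).sum()
        assert ours == pytest.approx(theirs, rel=0.03)


class TestSimilarity:
    def test_identical_sequences_score_100(self):
        assert sequence_identity_pct("ACDEFG", "ACDEFG") == pytest.approx(100.0)

    def test_disjoint_alphabets_score_0(self):
        assert sequence_identity_pct("AAAA", "WWWW") == pytest.approx(0.0)

    def test_single_substitution_in_ten(self):
        assert sequence_identity_pct("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(90.0)

    def test_symmetry(self):
        a, b = "ACDEFGHIKLMNP", "ACDEFGHIKVMNP"
        assert sequence_identity_pct(a, b) == pytest.approx(sequence_identity_pct(b, a))

    def test_patch_similarity_uses_whole_observed_chains(self):
        model, _ = dimer_model(["ALA", "GLY", "SER"], ["ALA", "GLY", "SER"], seed=8)
        sim = patch_similarity(model.chain("A"), model.chain("B"))
        assert sim == pytest.approx(100.0)


class TestClassifyAndBins:
    @pytest.mark.parametrize("similarity,expected_class,expected_bin", [
        (100.0, "homologous", "75-100"),
        (75.0, "homologous", "75-100"),
        (74.9, "heterologous", "50-75"),
        (10.0, "heterologous", "0-25"),
    ])
    def test_dimer_classification_boundaries(self, similarity, expected_class,
                                             expected_bin):
        label, bin_label = classify_dimer(similarity)
        assert (label, bin_label) == (expected_class, expected_bin)

    def test_residue_bins_quartet(self):
        dist = bin_distribution([3, 7, 25, 45], RESIDUE_BINS)
        assert {k: v for k, v in dist.items() if v[0]} == {
            "1-5": (1, 25.0), "6-20": (1, 25.0),
            "21-40": (1, 25.0), "41-60": (1, 25.0)}

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError, match="no patches"):
            bin_distribution([], RESIDUE_BINS)

    @pytest.mark.parametrize("spec,lo,hi", [
        (RESIDUE_BINS, 1, 310), (SASA_BINS, 0, 17000),
        (HYDROPHOBICITY_BINS, -5, 120), (SIMILARITY_BINS, 0, 100)])
    def test_bins_conserve_counts_against_direct_tally(self, spec, lo, hi):
        rng = np.random.default_rng(17)
        if spec is RESIDUE_BINS:  # residue counts are integers
            values = rng.integers(lo, hi + 1, 100)
        else:
            values = rng.uniform(lo, hi, 100)
        dist = bin_distribution(values, spec)
        assert sum(c for c, _ in dist.values()) == 100
        assert sum(p for _, p in dist.values()) == pytest.approx(100.0, abs=0.01)
        # independent tally for one bin of each spec
        label = spec.labels[0]
        direct = sum(1 for v in values if spec.bin_of(v) == label)
        assert dist[label][0] == direct

    def test_summarize_patch_combines_all_descriptors(self):
        model, interface = dimer_model(
            ["ALA", "SER", "THR"], ["ALA", "SER", "THR"], seed=9)
        summary = summarize_patch(interface, 0, model.chain("A"), model.chain("B"))
        patch = extract_patches(interface)[0]
        assert summary.residue_count == patch.residue_count
        assert summary.similarity_to_partner == pytest.approx(100.0)
        assert summary.sasa > 0
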