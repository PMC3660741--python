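import numpy as np
import pytest

from symanchor.core_structures import (Atom, Residue, Structure,
                                       apply_transform, make_cn_group)
from symanchor.interface_analysis import (MutantCyclePair, align_pair,
                                          contact_map, detect_axis,
                                          lysine_scan_rotamer, map_restraints,
                                          superpose_homolog)
from symanchor.sequences import (AGTX2_SEQUENCE, CHIMERA_PORE,
                                 CHIMERA_PORE_FIRST, CTX_SEQUENCE,
                                 SHAKER_PORE, SHAKER_PORE_FIRST,
                                 cysteine_positions)
from symanchor.synthetic_data import (ChannelSpec, ToxinSpec,
                                      default_true_pose, gen_c4_channel,
                                      gen_toxin)


class TestDetectAxis:
    def test_exact_tetramer_recovers_construction_axis(self, channel):
        structure, group_true, _ = channel
        group, residual = detect_axis(structure)
        assert residual < 1e-9
        cosang = abs(float(group.axis_direction @ group_true.axis_direction))
        assert cosang == pytest.approx(1.0, abs=1e-9)
        # recovered axis passes through the true axis (z axis through origin)
        assert group_true.axis_distance(group.axis_point) < 1e-6

    def test_noisy_tetramer_axis_within_tolerance(self):
        structure, group_true, _ = gen_c4_channel(ChannelSpec(noise_sd=0.3), seed=5)
        group, residual = detect_axis(structure)
        assert residual < 1.0
        cosang = abs(float(group.axis_direction @ group_true.axis_direction))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 1.0

    def test_tilted_and_shifted_tetramer(self, channel):
        from scipy.spatial.transform import Rotation
        structure, group_true, _ = channel
        t = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        from symanchor.core_structures import RigidTransform
        move = RigidTransform(t, np.array([10.0, -4.0, 7.0]))
        moved = apply_transform(structure, move)
        group, residual = detect_axis(moved)
        assert residual < 1e-6
        true_dir = t @ group_true.axis_direction
        assert abs(float(group.axis_direction @ true_dir)) == pytest.approx(1.0, abs=1e-8)

    def test_wrong_chain_count_rejected(self, toxin):
        with pytest.raises(ValueError, match="expected 4 chains"):
            detect_axis(toxin)

    def test_asymmetric_tetramer_rejected(self, channel):
        structure = channel[0].copy()
        xyz = structure.coords()
        rng = np.random.default_rng(0)
        structure.set_coords(xyz + rng.normal(0, 3.0, xyz.shape))
        with pytest.raises(ValueError):
            detect_axis(structure)


def _complex_for_contacts():
    channel, group, _ = gen_c4_channel(ChannelSpec(), seed=0)
    spec = ToxinSpec()
    toxin = gen_toxin(spec, seed=0)
    posed = apply_transform(toxin, default_true_pose(ChannelSpec(), spec))
    return posed, channel, group


class TestContactMap:
    def test_contacts_are_within_cutoff_and_deduplicated(self):
        ligand, receptor, _ = _complex_for_contacts()
        contacts = contact_map(ligand, receptor, max_distance=6.0)
        assert contacts, "pose at the pore mouth must make interface contacts"
        seen = set()
        for c in contacts:
            assert c.min_distance <= 6.0
            key = (c.ligand_residue, c.receptor_residue)
            assert key not in seen
            seen.add(key)

    def test_min_distance_matches_brute_force(self):
        ligand, receptor, _ = _complex_for_contacts()
        contacts = contact_map(ligand, receptor, max_distance=6.0)
        c = min(contacts, key=lambda c: c.min_distance)
        lres = ligand.residue(*c.ligand_residue[:2])
        rres = receptor.residue(*c.receptor_residue[:2])
        d = min(np.linalg.norm(a.xyz - b.xyz)
                for a in lres.atoms for b in rres.atoms)
        assert c.min_distance == pytest.approx(d, abs=1e-9)

    def test_same_residue_number_appears_once_per_subunit(self):
        ligand, receptor, _ = _complex_for_contacts()
        contacts = contact_map(ligand, receptor, max_distance=8.0)
        per_subunit = {}
        for c in contacts:
            key = (c.ligand_residue, c.receptor_residue[1])
            per_subunit.setdefault(key, set()).add(c.subunit_index)
        # at least one toxin residue touches the same channel residue on
        # more than one subunit ("of another subunit" relationships survive)
        assert any(len(s) > 1 for s in per_subunit.values())

    def test_categories_follow_chemistry(self):
        lys = Structure([Residue("T", 27, "LYS",
                                 [Atom("NZ", "N", np.array([0.0, 0.0, 3.0]))])])
        asp = Structure([Residue("A", 375, "ASP",
                                 [Atom("OD1", "O", np.array([0.0, 0.0, 0.0]))])])
        (c,) = contact_map(lys, asp)
        assert c.category == "hbond"
        # same pair beyond hbond range but within electrostatic range
        asp_far = Structure([Residue("A", 375, "ASP",
                                     [Atom("OD1", "O", np.array([0.0, 0.0, -2.0]))])])
        (c2,) = contact_map(lys, asp_far)
        assert c2.min_distance == pytest.approx(5.0)
        assert c2.category == "electrostatic"
        ala = Structure([Residue("A", 1, "ALA",
                                 [Atom("CB", "C", np.array([0.0, 0.0, 0.0]))])])
        (c3,) = contact_map(lys, ala)
        assert c3.category == "packing"

    def test_empty_structures_rejected(self):
        s = Structure([Residue("A", 1, "ALA", [Atom("CA", "C", np.zeros(3))])])
        with pytest.raises(ValueError):
            contact_map(Structure([]), s)


class TestAlignment:
    def test_pore_sequences_map_anchor_residues(self):
        mapping = align_pair(SHAKER_PORE, CHIMERA_PORE,
                             SHAKER_PORE_FIRST, CHIMERA_PORE_FIRST,
                             "Shaker", "chimera")
        assert mapping.map(449) == 377
        assert mapping.map(425) == 353
        assert mapping.map(445) == 373
        assert not mapping.gaps  # pore regions align without gaps

    def test_constant_offset_between_pore_numberings(self):
        mapping = align_pair(SHAKER_PORE, CHIMERA_PORE,
                             SHAKER_PORE_FIRST, CHIMERA_PORE_FIRST)
        offsets = {t - s for s, t in mapping.aligned_pairs}
        assert offsets == {CHIMERA_PORE_FIRST - SHAKER_PORE_FIRST}

    def test_identity_alignment_is_identity_mapping(self):
        mapping = align_pair(CTX_SEQUENCE, CTX_SEQUENCE)
        assert mapping.aligned_pairs == [(i, i) for i in range(1, 38)]

    def test_gap_is_recorded(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = a[:8] + a[11:]  # internal 3-residue deletion
        mapping = align_pair(a, b, name_a="full", name_b="deleted")
        gap_residues = {n for name, n in mapping.gaps if name == "full"}
        assert len(gap_residues) == 3

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_pair("ACDX", "ACDE")
        with pytest.raises(ValueError, match="empty"):
            align_pair("", "ACDE")

    def test_unmapped_residue_raises_keyerror(self):
        mapping = align_pair(SHAKER_PORE, CHIMERA_PORE,
                             SHAKER_PORE_FIRST, CHIMERA_PORE_FIRST)
        with pytest.raises(KeyError):
            mapping.map(9999)


class TestMapRestraints:
    def test_distances_are_minimum_over_subunits(self):
        ligand, receptor, _ = _complex_for_contacts()
        mapping = align_pair(SHAKER_PORE, CHIMERA_PORE,
                             SHAKER_PORE_FIRST, CHIMERA_PORE_FIRST)
        pairs = [MutantCyclePair(27, 449), MutantCyclePair(25, 425)]
        out = map_restraints(pairs, mapping, ligand, receptor)
        assert out[0].channel_residue_mapped == 377
        assert out[1].channel_residue_mapped == 353
        for p in out:
            assert p.error is None
            lig_xyz = [a.xyz for r in ligand.residues
                       if r.seq_number == p.toxin_residue for a in r.atoms]
            best = min(np.linalg.norm(a - b.xyz)
                       for a in lig_xyz for r in receptor.residues
                       if r.seq_number == p.channel_residue_mapped
                       for b in r.atoms)
            assert p.min_distance == pytest.approx(best, abs=1e-9)

    def test_unmapped_residue_recorded_and_processing_continues(self):
        ligand, receptor, _ = _complex_for_contacts()
        mapping = align_pair(SHAKER_PORE, CHIMERA_PORE,
                             SHAKER_PORE_FIRST, CHIMERA_PORE_FIRST)
        pairs = [MutantCyclePair(27, 9999), MutantCyclePair(27, 449)]
        out = map_restraints(pairs, mapping, ligand, receptor)
        assert out[0].error == "unmapped" and out[0].min_distance is None
        assert out[1].error is None and out[1].min_distance is not None


class TestLysineScan:
    def _backbone_residue(self):
        return Structure([Residue("A", 10, "ALA", [
            Atom("N", "N", np.array([0.0, 1.45, 0.0])),
            Atom("CA", "C", np.array([0.0, 0.0, 0.0])),
            Atom("C", "C", np.array([1.42, -0.55, 0.0])),
        ])])

    def test_chain_geometry_has_correct_bond_lengths(self):
        rec = self._backbone_residue()
        ca = rec.residue("A", 10).atom("CA").xyz
        # a probe far along the all-trans extension direction forces the
        # extended rotamer, whose NZ sits ~6.3 A from CA
        probe_dir = np.array([-2.45, -4.44, -3.80])
        extended = lysine_scan_rotamer(rec, "A", 10, ca + 10 * probe_dir)
        assert 5.5 < np.linalg.norm(extended["nz"] - ca) < 7.0
        # whatever rotamer wins, NZ stays within the side chain's reach
        best = lysine_scan_rotamer(rec, "A", 10, [0.0, 0.0, 8.0])
        assert 2.0 < np.linalg.norm(best["nz"] - ca) < 7.0

    def test_picks_rotamer_closest_to_probe(self):
        rec = self._backbone_residue()
        probe = np.array([0.0, -3.0, 5.0])
        best = lysine_scan_rotamer(rec, "A", 10, probe)
        # brute-force over the same library cannot do better
        assert 0 <= best["rotamer_index"] < 27
        assert best["distance"] >= 0
        far = lysine_scan_rotamer(rec, "A", 10, [100.0, 0.0, 0.0])
        assert far["distance"] > best["distance"]

    def test_implausibly_close_probe_flagged(self):
        rec = self._backbone_residue()
        best = lysine_scan_rotamer(rec, "A", 10, [0.0, 0.0, 8.0])
        again = lysine_scan_rotamer(rec, "A", 10, best["nz"])
        assert again["implausible"]
        assert not best["implausible"] or best["distance"] < 1.5

    def test_missing_backbone_rejected(self, toxin):
        with pytest.raises(ValueError, match="backbone"):
            lysine_scan_rotamer(toxin, "T", 27, [0, 0, 0])


class TestSuperposeHomolog:
    def test_scaffold_superposition_places_homolog(self):
        ctx = gen_toxin(ToxinSpec(), seed=0)
        homolog = gen_toxin(ToxinSpec(sequence=AGTX2_SEQUENCE), seed=3)
        scaffold_ctx = cysteine_positions(CTX_SEQUENCE) + [27]
        # use the same residue numbers on the synthetic homolog body (its CA
        # shell is jittered, not re-threaded, so the numbers exist)
        res, moved = superpose_homolog(homolog, ctx, scaffold_ctx, scaffold_ctx)
        assert res.n_points == 7
        assert res.rmsd < 2.0  # jittered copies of the same scaffold
        np.testing.assert_allclose(
            moved.residue("T", 27).atom("CA").xyz,
            res.transform.apply(homolog.residue("T", 27).atom("CA").xyz))

    def test_scaffold_length_mismatch_rejected(self):
        ctx = gen_toxin(ToxinSpec(), seed=0)
        with pytest.raises(ValueError, match="differ in length"):
            superpose_homolog(ctx, ctx, [7, 13], [7])

    def test_missing_scaffold_atoms_listed(self):
        ctx = gen_toxin(ToxinSpec(), seed=0)
        with pytest.raises(ValueError, match="999"):
            superpose_homolog(ctx, ctx, [7, 13, 999], [7, 13, 17])
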