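"""Duplex model analysis, rebuilding, groove widths, side chains, PDB I/O."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ahyflex import (
    AnnotatedDuplex,
    Modification,
    analyze_structure,
    analyze_trajectory,
    groove_widths,
    ideal_bdna_parameters,
    read_pdb,
    rebuild_duplex,
    side_chain_extension,
    write_pdb,
)
from ahyflex.refgeom import AHY_CHAIN, STANDARD_BASES, build_side_chain
from ahyflex.structure import (
    DuplexModel,
    DuplexTrajectory,
    ParameterTrajectory,
    StructureError,
)

from conftest import random_plausible_parameters


def step_array(analysis) -> np.ndarray:
    return np.array([p.as_array() for p in analysis.step])


def intra_array(analysis) -> np.ndarray:
    return np.array([p.as_array() for p in analysis.intra])


class TestRoundTrip:
    def test_ideal_bdna_recovered_exactly(self, duplex_c):
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        res = analyze_structure(model)
        assert np.abs(step_array(res) - [0, 0, 3.4, 0, 0, 36.0]).max() < 1e-6
        assert np.abs(intra_array(res)).max() < 1e-6

    def test_random_plausible_parameters_round_trip(self, duplex_ahycx4):
        rng = np.random.default_rng(11)
        for _ in range(25):
            intra, step = random_plausible_parameters(rng, 25)
            model = rebuild_duplex(duplex_ahycx4, intra, step)
            res = analyze_structure(model)
            assert np.abs(step_array(res) - np.array([p.as_array() for p in step])).max() < 1e-6
            assert np.abs(intra_array(res) - np.array([p.as_array() for p in intra])).max() < 1e-6

    def test_rigid_motion_invariance(self, duplex_c):
        rng = np.random.default_rng(4)
        intra, step = random_plausible_parameters(rng, 10)
        duplex = AnnotatedDuplex(duplex_c.top_strand[:10])
        model = rebuild_duplex(duplex, intra, step)
        base = analyze_structure(model)
        for seed in range(5):
            rot = Rotation.random(random_state=seed).as_matrix()
            moved = model.transformed(rot, rng.normal(size=3) * 50)
            res = analyze_structure(moved)
            assert np.abs(step_array(res) - step_array(base)).max() < 1e-9
            assert np.abs(intra_array(res) - intra_array(base)).max() < 1e-9

    def test_strand_flip_symmetry(self):
        """Reading the duplex from the opposite strand negates shift and tilt
        and preserves slide, rise, roll and twist."""
        rng = np.random.default_rng(5)
        length = 12
        seq = "".join(rng.choice(list("ACGT"), length))
        duplex = AnnotatedDuplex(seq)
        intra, step = random_plausible_parameters(rng, length)
        model = rebuild_duplex(duplex, intra, step)
        flipped = DuplexModel(
            AnnotatedDuplex(duplex.bottom_strand), model.names,
            np.where(model.chains == "A", "B", "A").astype(object),
            model.resids, model.elements, model.sidechain_site, model.coords)
        res = analyze_structure(model)
        res_f = analyze_structure(flipped)
        signs = np.array([-1, 1, 1, -1, 1, 1])
        for i in range(length - 1):
            assert np.abs(res_f.step[length - 2 - i].as_array()
                          - signs * res.step[i].as_array()).max() < 1e-8

    def test_single_base_pair(self):
        duplex = AnnotatedDuplex("G")
        model = rebuild_duplex(duplex, *ideal_bdna_parameters(1))
        res = analyze_structure(model)
        assert res.step == []
        assert len(res.intra) == 1
        assert np.abs(res.intra[0].as_array()).max() < 1e-9

    def test_parameter_length_mismatch(self, duplex_c):
        intra, step = ideal_bdna_parameters(24)
        with pytest.raises(StructureError, match="expected 25"):
            rebuild_duplex(duplex_c, intra, step)


class TestGrooveWidths:
    def test_ideal_bdna_major_groove_near_canonical(self, duplex_c):
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        profile = groove_widths(model)
        interior = profile.major[~np.isnan(profile.major)]
        assert len(interior) > 10
        assert np.abs(interior - 11.7).max() < 2.0
        minor = profile.minor[~np.isnan(profile.minor)]
        assert np.abs(minor - 5.7).max() < 2.0

    def test_direct_pp_distance_oracle(self, duplex_c):
        """Spot-check one width against a direct P-P distance computation."""
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        p_top = model.residue_atoms("A", 10)["P"]
        p_bot = model.residue_atoms("B", 25 + 1 - 6)["P"]  # bp 10 - 4 = 6
        profile = groove_widths(model)
        assert profile.major[9] == pytest.approx(np.linalg.norm(p_top - p_bot) - 5.8)

    def test_short_duplex_all_undefined_with_warning(self):
        duplex = AnnotatedDuplex("ACGT")
        model = rebuild_duplex(duplex, *ideal_bdna_parameters(4))
        with pytest.warns(UserWarning, match="too short"):
            profile = groove_widths(model)
        assert np.isnan(profile.major).all()
        assert np.isnan(profile.minor).all()

    def test_missing_phosphate_propagates_exactly(self, duplex_c):
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        keep = ~((model.chains == "A") & (model.resids == 10) & (model.names == "P"))
        pruned = DuplexModel(duplex_c, model.names[keep], model.chains[keep],
                             model.resids[keep], model.elements[keep],
                             model.sidechain_site[keep], model.coords[keep])
        full = groove_widths(model)
        part = groove_widths(pruned)
        # only widths anchored at P(strand I, bp 10) change status
        assert np.isnan(part.major[9]) and not np.isnan(full.major[9])
        assert np.isnan(part.minor[9]) and not np.isnan(full.minor[9])
        other = np.arange(25) != 9
        assert np.array_equal(np.isnan(part.major[other]), np.isnan(full.major[other]))
        assert np.array_equal(np.isnan(part.minor[other]), np.isnan(full.minor[other]))


class TestSideChain:
    def test_ahy_extension_within_reported_bound(self):
        assert side_chain_extension("ahy") <= 12.0
        assert side_chain_extension("ahy") > 8.0  # a ~12-bond chain, not collapsed

    def test_methyl_extension_is_one_bond(self):
        assert side_chain_extension("m") == pytest.approx(1.53, abs=1e-9)

    def test_vector_sum_oracle(self):
        """Hand-assembled planar zigzag + exact circle maximisation."""
        deg = math.radians
        # planar chain in the xy plane: direction angles per bond, turning by
        # (180 - bond angle) with alternating sense at sp3 centres
        bonds = [1.53, 1.47, 1.20, 1.47, 1.53, 1.53, 1.47, 1.24, 1.13]
        angles = [109.47, 180.0, 180.0, 109.47, 109.47, 109.47, 115.0, 180.0]
        theta = 0.0
        sense = 1.0
        pts = [np.zeros(2)]
        for k, b in enumerate(bonds):
            pts.append(pts[-1] + b * np.array([math.cos(theta), math.sin(theta)]))
            if k < len(angles):
                turn = 180.0 - angles[k]
                if turn:
                    theta += sense * deg(turn)
                    sense = -sense
        pts = np.array([[x, y, 0.0] for x, y in pts])
        c5, tip = pts[0], pts[-1]
        # free rotation about the linear alkyne segment (atoms 2..4 collinear)
        axis_pt = pts[4]
        u = pts[4] - pts[3]
        u = u / np.linalg.norm(u)
        best = 0.0
        for phi in np.linspace(0, 2 * math.pi, 200_001):
            rot = Rotation.from_rotvec(phi * u).as_matrix()
            cand = rot @ (tip - axis_pt) + axis_pt
            best = max(best, np.linalg.norm(cand - c5))
        assert side_chain_extension("ahy") == pytest.approx(best, abs=1e-6)

    def test_unsupported_code(self):
        with pytest.raises(ValueError, match="unsupported"):
            side_chain_extension("xyz")

    def test_chain_bond_lengths(self):
        chain = build_side_chain("ahy")
        pts = [np.array(STANDARD_BASES["C"]["C5"])] + [chain[n] for n, *_ in AHY_CHAIN]
        lengths = [np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])]
        expected = [spec[1] for spec in AHY_CHAIN]
        assert np.abs(np.array(lengths) - expected).max() < 1e-9


class TestTrajectory:
    def test_identical_frames_give_identical_rows(self, duplex_c):
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        traj = analyze_trajectory([model, model, model])
        assert traj.n_frames == 3
        assert np.array_equal(traj.step[0], traj.step[1])
        assert np.array_equal(traj.step[1], traj.step[2])

    def test_frame_count_preserved(self, duplex_c):
        rng = np.random.default_rng(8)
        models = [rebuild_duplex(duplex_c, *random_plausible_parameters(rng, 25))
                  for _ in range(5)]
        traj = analyze_trajectory(models)
        assert traj.n_frames == 5
        assert traj.n_steps == 24
        assert traj.n_bp == 25

    def test_divergent_atom_count_names_frame(self, duplex_c):
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        short = DuplexModel(duplex_c, model.names[:-1], model.chains[:-1],
                            model.resids[:-1], model.elements[:-1],
                            model.sidechain_site[:-1], model.coords[:-1])
        with pytest.raises(StructureError, match="frame 1"):
            analyze_trajectory([model, short])


class TestPdbIO:
    def test_multi_model_round_trip(self, duplex_ahycx4, tmp_path):
        rng = np.random.default_rng(13)
        models = [rebuild_duplex(duplex_ahycx4, *random_plausible_parameters(rng, 25))
                  for _ in range(3)]
        path = tmp_path / "traj.pdb"
        write_pdb(models, path)
        traj = read_pdb(path)
        assert traj.n_frames == 3
        assert traj.duplex.top_strand == duplex_ahycx4.top_strand
        assert traj.duplex.modifications == duplex_ahycx4.modifications
        # PDB coordinates are written to 3 decimals
        assert np.abs(traj.coords[0] - models[0].coords).max() < 1e-3

    def test_analysis_survives_pdb_precision(self, duplex_c, tmp_path):
        model = rebuild_duplex(duplex_c, *ideal_bdna_parameters(25))
        path = tmp_path / "ideal.pdb"
        write_pdb(model, path)
        res = analyze_structure(read_pdb(path).frame(0))
        assert np.abs(step_array(res) - [0, 0, 3.4, 0, 0, 36.0]).max() < 0.05

    def test_corrupt_pdb_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("not a pdb at all\n")
        with pytest.raises(StructureError):
            read_pdb(path)


def test_parameter_csv_round_trip(tmp_path, duplex_c):
    rng = np.random.default_rng(21)
    traj = ParameterTrajectory(rng.normal(size=(7, 24, 6)), rng.normal(size=(7, 25, 6)))
    traj.write_csv(tmp_path / "step.csv", tmp_path / "bp.csv")
    back = ParameterTrajectory.read_csv(tmp_path / "step.csv", tmp_path / "bp.csv")
    assert np.abs(back.step - traj.step).max() < 1e-12
    assert np.abs(back.intra - traj.intra).max() < 1e-12
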