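"""RDF binning/normalization, peak location, hydrogen-bond occupancy."""

import numpy as np
import pytest

from siechit.atoms import MolecularSystem, SelectionError, Trajectory, select
from siechit.rdf import RDFProfile, hbond_occupancy, radial_distribution, rdf_peak
from siechit.synthetic import ToyComplexSpec, build_toy_complex, generate_trajectory
from conftest import make_atom


def pair_trajectory(distances):
    """Two-atom trajectory with the A-B distance prescribed per frame."""
    atoms = [
        make_atom(name="A1", pos=(0, 0, 0), residue=("A", "REC", 1)),
        make_atom(name="B1", pos=(1, 0, 0), residue=("B", "LIG", 2)),
    ]
    system = MolecularSystem(atoms)
    frames = [np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]]) for d in distances]
    traj = Trajectory(system, frames)
    return traj, select(system, "chain A"), select(system, "chain B")


class TestRadialDistribution:
    def test_fixed_distance_lands_in_peak_bin(self):
        traj, a, b = pair_trajectory([2.75] * 20)
        prof = radial_distribution(traj, a, b, bin_width=0.05, r_max=8.0)
        peak = rdf_peak(prof)
        lo = prof.bin_edges[np.argmax(prof.g)]
        assert lo <= 2.75 < lo + 0.05
        assert abs(peak - 2.75) <= 0.05

    def test_raw_counts_match_brute_force(self, toy_trajectory, toy_complex):
        a = select(toy_complex, "resid 440 and name OD1 OD2")
        b = select(toy_complex, "resname NAG and name N2")
        r_max = 8.0
        prof = radial_distribution(toy_trajectory, a, b, bin_width=0.1, r_max=r_max)
        expected = 0
        for frame in toy_trajectory.frames:
            for i in a.indices:
                for j in b.indices:
                    if np.linalg.norm(frame[i] - frame[j]) < r_max:
                        expected += 1
        assert prof.raw_counts.sum() == expected

    def test_counts_conserved_under_bin_refinement(self, toy_trajectory, toy_complex):
        a = select(toy_complex, "resid 440 and name OD1 OD2")
        b = select(toy_complex, "resname NAG and name N2")
        coarse = radial_distribution(toy_trajectory, a, b, bin_width=0.2, r_max=8.0)
        fine = radial_distribution(toy_trajectory, a, b, bin_width=0.05, r_max=8.0)
        assert coarse.raw_counts.sum() == fine.raw_counts.sum()

    def test_invariant_under_per_frame_rigid_motion(self, toy_trajectory, toy_complex):
        a = select(toy_complex, "resid 440 and name OD1 OD2")
        b = select(toy_complex, "resname NAG and name N2")
        ref = radial_distribution(toy_trajectory, a, b)
        t = np.deg2rad(25)
        rot = np.array(
            [[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]]
        )
        moved = Trajectory(
            toy_complex,
            [f @ rot.T + np.array([5.0, -1.0, 2.0]) for f in toy_trajectory.frames],
        )
        out = radial_distribution(moved, a, b)
        np.testing.assert_allclose(out.raw_counts, ref.raw_counts)
        np.testing.assert_allclose(out.g, ref.g, atol=1e-9)

    def test_ideal_gas_gives_unit_g(self):
        """Uniform points in a periodic box: self-RDF ~ 1 well below the
        box length."""
        rng = np.random.default_rng(123)
        n, box = 5000, 40.0
        pts = rng.uniform(0, box, size=(n, 3))
        atoms = [
            make_atom(name=f"P{i}", pos=pts[i], residue=("A", "GAS", i + 1))
            for i in range(n)
        ]
        system = MolecularSystem(atoms)
        traj = Trajectory(system, [pts])
        sel = select(system, "chain A")
        prof = radial_distribution(
            traj, sel, sel, bin_width=0.25, r_max=6.0,
            box=np.full(3, box),
        )
        inner = prof.g[(prof.bin_centers > 2.0) & (prof.bin_centers < 6.0)]
        assert np.all(np.abs(inner - 1.0) < 0.05)

    def test_counts_only_mode_integrates_to_one(self, toy_trajectory, toy_complex):
        a = select(toy_complex, "resid 440 and name OD1 OD2")
        b = select(toy_complex, "resname NAG and name N2")
        prof = radial_distribution(
            toy_trajectory, a, b, bin_width=0.1, normalization="counts-only"
        )
        assert prof.g.sum() * 0.1 == pytest.approx(1.0)

    def test_partial_overlap_rejected(self, toy_complex):
        a = select(toy_complex, "resname NAG")
        b = select(toy_complex, "resname NAG and name N2")
        traj = Trajectory(toy_complex, [toy_complex.coords])
        with pytest.raises(SelectionError, match="overlap"):
            radial_distribution(traj, a, b)


class TestRdfPeak:
    def test_single_nonzero_bin(self):
        edges = np.arange(0, 8.05, 0.1)
        g = np.zeros(len(edges) - 1)
        g[27] = 5.0  # bin [2.7, 2.8)
        prof = RDFProfile(edges, g, g.copy(), 1, 1, "shell-volume")
        assert rdf_peak(prof) == pytest.approx(2.75)

    def test_tie_breaks_toward_smaller_r(self):
        edges = np.arange(0, 8.05, 0.5)
        g = np.zeros(len(edges) - 1)
        g[4] = g[6] = 3.0  # bins [2.0,2.5) and [3.0,3.5)
        prof = RDFProfile(edges, g, g.copy(), 1, 1, "shell-volume")
        assert rdf_peak(prof) == pytest.approx(2.25)

    def test_all_zero_profile_errors(self):
        edges = np.arange(0, 1.05, 0.1)
        g = np.zeros(len(edges) - 1)
        prof = RDFProfile(edges, g, g.copy(), 1, 1, "shell-volume")
        with pytest.raises(ValueError, match="peak"):
            rdf_peak(prof)

    def test_gaussian_distance_mode_recovered(self):
        rng = np.random.default_rng(42)
        traj, a, b = pair_trajectory(rng.normal(3.25, 0.1, size=2000))
        prof = radial_distribution(traj, a, b, bin_width=0.05, r_max=8.0)
        assert abs(rdf_peak(prof) - 3.25) <= 0.05


class TestHbondOccupancy:
    def test_always_bonded(self):
        traj, a, b = pair_trajectory([2.8] * 30)
        hb = hbond_occupancy(traj, a, b, cutoff=3.0)
        assert hb.occupancy == 1.0
        np.testing.assert_allclose(hb.min_distance, 2.8)

    def test_never_bonded(self):
        traj, a, b = pair_trajectory([3.5] * 30)
        assert hbond_occupancy(traj, a, b, cutoff=3.0).occupancy == 0.0

    def test_designed_probability_recovered(self):
        """Binomial sampling check at the construction probability."""
        rng = np.random.default_rng(77)
        # P(d <= 3.0) = 0.7 by construction
        d = np.where(rng.uniform(size=5000) < 0.7, 2.8, 3.4)
        traj, a, b = pair_trajectory(d)
        hb = hbond_occupancy(traj, a, b, cutoff=3.0)
        assert abs(hb.occupancy - 0.7) < 0.03

    def test_monotone_in_cutoff(self, toy_trajectory, toy_complex):
        donors = select(toy_complex, "resname NAG and name N2")
        acceptors = select(toy_complex, "resid 440 and name OD1 OD2")
        occ = [
            hbond_occupancy(toy_trajectory, donors, acceptors, cutoff=c).occupancy
            for c in (2.0, 2.6, 2.9, 3.2, 4.0)
        ]
        assert occ == sorted(occ)
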