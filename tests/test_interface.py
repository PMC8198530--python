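"""Inter-chain contact maps: distances, binning, typing, diffs, hotspots."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trimertrace.errors import ValidationError
from trimertrace import interface
from trimertrace.structure_io import Frame
from trimertrace.synthetic import TrimerGeometrySpec, generate_trimer_ensemble


def _two_chain_frame(coords_x, coords_y, names_x=None, names_y=None,
                     atoms=None):
    """Frame with chains X and Y; ``atoms`` optionally adds per-residue atom lists."""
    coords_x = np.asarray(coords_x, dtype=float)
    coords_y = np.asarray(coords_y, dtype=float)
    nx_, ny_ = len(coords_x), len(coords_y)
    frame = Frame(
        index=0,
        chain_ids=np.array(["X"] * nx_ + ["Y"] * ny_, dtype="U4"),
        res_ids=np.concatenate([np.arange(1, nx_ + 1), np.arange(1, ny_ + 1)]),
        res_names=np.array(
            (names_x or ["ALA"] * nx_) + (names_y or ["ALA"] * ny_), dtype="U3"
        ),
        ca_coords=np.concatenate([coords_x, coords_y]),
    )
    if atoms is not None:
        coords, res_idx, names = [], [], []
        for i, atom_list in enumerate(atoms):
            for name, xyz in atom_list:
                coords.append(xyz)
                res_idx.append(i)
                names.append(name)
        frame.atom_coords = np.asarray(coords, dtype=float)
        frame.atom_res_index = np.asarray(res_idx, dtype=int)
        frame.atom_names = np.array(names, dtype="U6")
    return frame


class TestDistanceMap:
    def test_single_pair_ca_distance(self):
        frame = _two_chain_frame([[0, 0, 0]], [[6.5, 0, 0]])
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        assert cmap.shape == (1, 1)
        assert cmap.distances[0, 0] == pytest.approx(6.5)

    def test_transpose_symmetry(self, planted_ensemble):
        ensemble, _ = planted_ensemble
        frame = ensemble.frames[0]
        m_ac = interface.interchain_distance_map(frame, "A", "C")
        m_ca = interface.interchain_distance_map(frame, "C", "A")
        assert np.allclose(m_ac.distances, m_ca.distances.T)

    def test_all_atom_uses_sidechain_minimum(self):
        atoms = [
            [("CA", [0.0, 0, 0]), ("CB", [2.0, 0, 0]), ("CG", [5.1, 0, 0])],
            [("CA", [9.0, 0, 0])],
        ]
        frame = _two_chain_frame([[0, 0, 0]], [[9.0, 0, 0]], atoms=atoms)
        all_atom = interface.interchain_distance_map(frame, "X", "Y", mode="all_atom")
        ca_only = interface.interchain_distance_map(frame, "X", "Y", mode="ca_only")
        assert all_atom.distances[0, 0] == pytest.approx(3.9)
        assert ca_only.distances[0, 0] == pytest.approx(9.0)

    def test_all_atom_without_atoms_rejected(self):
        frame = _two_chain_frame([[0, 0, 0]], [[9.0, 0, 0]])
        with pytest.raises(ValidationError):
            interface.interchain_distance_map(frame, "X", "Y", mode="all_atom")

    def test_unknown_chain_rejected(self):
        frame = _two_chain_frame([[0, 0, 0]], [[9.0, 0, 0]])
        with pytest.raises(ValidationError):
            interface.interchain_distance_map(frame, "X", "Z")


class TestBinning:
    @pytest.mark.parametrize(
        "distance, expected",
        [(6.9, 1), (7.0, 1), (7.1, 2), (10.0, 2), (12.0, 3), (16.0, 4), (16.5, 0)],
    )
    def test_nested_distance_classes(self, distance, expected):
        frame = _two_chain_frame([[0, 0, 0]], [[distance, 0, 0]])
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        assert interface.bin_contact_map(cmap)[0, 0] == expected

    @given(st.floats(0.5, 30.0))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_binning_pure_function_of_distance(self, d):
        frame = _two_chain_frame([[0, 0, 0]], [[d, 0, 0]])
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        k = interface.bin_contact_map(cmap)[0, 0]
        edges = (0.0,) + cmap.bin_edges
        if d > edges[-1]:
            assert k == 0
        else:
            assert edges[k - 1] < d <= edges[k]


class TestContactTypes:
    @pytest.mark.parametrize(
        "pair, expected",
        [
            (("LEU", "ILE"), "hydrophobic"),
            (("LYS", "GLU"), "hydrophilic"),
            (("LEU", "LYS"), "mixed"),
        ],
    )
    def test_typing_rule(self, pair, expected):
        frame = _two_chain_frame(
            [[0, 0, 0]], [[5.0, 0, 0]], names_x=[pair[0]], names_y=[pair[1]]
        )
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        summary = interface.classify_contact_types(cmap)
        assert getattr(summary, expected) == 1
        assert summary.total == 1

    def test_unknown_residue_counted_hydrophilic(self, caplog):
        frame = _two_chain_frame(
            [[0, 0, 0]], [[5.0, 0, 0]], names_x=["XXX"], names_y=["SER"]
        )
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        with caplog.at_level("WARNING"):
            summary = interface.classify_contact_types(cmap)
        assert summary.hydrophilic == 1


class TestDiff:
    def _map_at(self, distances):
        frame = _two_chain_frame(
            [[0, 0, 0]], [[d, 0, 0] for d in distances]
        )
        return interface.interchain_distance_map(frame, "X", "Y")

    def test_identical_maps_empty_diff(self):
        m = self._map_at([5.0, 9.0])
        diff = interface.diff_contact_maps(m, m)
        assert diff.gained == set() and diff.lost == set()

    def test_tightened_entry_is_gained(self):
        a = self._map_at([8.0])
        b = self._map_at([6.0])
        diff = interface.diff_contact_maps(a, b, threshold_bin=1)
        assert diff.gained == {(1, 1)} and diff.lost == set()

    def test_antisymmetric_under_swap(self):
        a = self._map_at([5.0, 9.0, 6.0, 20.0])
        b = self._map_at([9.0, 5.0, 6.5, 4.0])
        fwd = interface.diff_contact_maps(a, b)
        rev = interface.diff_contact_maps(b, a)
        assert fwd.gained == rev.lost and fwd.lost == rev.gained

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            interface.diff_contact_maps(self._map_at([5.0]), self._map_at([5.0, 6.0]))


class TestHotspots:
    def test_confined_contacts_dominate_top_segment(self):
        rng = np.random.default_rng(0)
        coords_x = [[1000.0 + 10 * i, 0, 0] for i in range(40)]
        coords_y = [[2000.0, 0, 0]]
        frame = _two_chain_frame(coords_x, coords_y)
        # put residues 20..30 of X within 7 A of Y's residue
        for i in range(19, 30):
            frame.ca_coords[i] = [2000.0 + rng.uniform(-3, 3), 0, 0]
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        top = interface.interface_hotspots(cmap, window=11)[0]
        assert top.start_res == 20 and top.end_res == 30
        assert top.contact_count == 11

    def test_uniform_contacts_no_sharp_hotspot(self):
        """Under spatially uniform contacts the top window stays within 2x of
        the mean window count (50 seeds)."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            tight = rng.random((60, 60)) < 0.3
            d = np.where(tight, 5.0, 30.0)
            cmap = interface.ContactMap(
                chain_pair=("X", "Y"),
                distances=d,
                res_ids_x=np.arange(1, 61),
                res_ids_y=np.arange(1, 61),
                res_names_x=np.array(["ALA"] * 60),
                res_names_y=np.array(["ALA"] * 60),
                mode="ca_only",
            )
            per_res = tight.sum(axis=1)
            window = 10
            mean_count = per_res.sum() * window / 60
            top = interface.interface_hotspots(cmap, window=window)[0]
            assert top.contact_count <= 2 * mean_count

    def test_empty_map_no_hotspots(self):
        frame = _two_chain_frame([[0, 0, 0], [4, 0, 0]], [[500.0, 0, 0]])
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        assert interface.interface_hotspots(cmap, window=2) == []

    def test_window_larger_than_chain_rejected(self):
        frame = _two_chain_frame([[0, 0, 0]], [[5.0, 0, 0]])
        cmap = interface.interchain_distance_map(frame, "X", "Y")
        with pytest.raises(ValidationError):
            interface.interface_hotspots(cmap, window=2)


def test_planted_pair_has_most_tight_contacts():
    """Approaching pair (A,C) carries strictly more class-1 contacts than the
    other interfaces across independent noise-free geometries."""
    for seed in range(10):
        spec = TrimerGeometrySpec(
            n_frames=1, approach_delta=-6.0, noise_sigma=0.0, seed=seed
        )
        ensemble, _ = generate_trimer_ensemble(spec)
        frame = ensemble.frames[0]

        def tight(a, b):
            cmap = interface.interchain_distance_map(frame, a, b)
            return int((interface.bin_contact_map(cmap) == 1).sum())

        assert tight("A", "C") > tight("A", "B")
        assert tight("A", "C") > tight("B", "C")
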