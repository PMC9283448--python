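"""Direction-set geometry, subsampling and I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hippodti.schemes import (
    AcquisitionScheme,
    DirectionSet,
    _energy_and_grad,
    angular_distance,
    generate_electrostatic_set,
    min_angle_report,
    neighbor_count,
    read_directions,
    subsample_directions,
    write_directions,
)

EX = np.array([1.0, 0.0, 0.0])
EY = np.array([0.0, 1.0, 0.0])
EZ = np.array([0.0, 0.0, 1.0])


def _unit(v):
    return v / np.linalg.norm(v)


unit_vectors = st.builds(
    lambda x, y, z: _unit(np.array([x, y, z])),
    *[st.floats(-1, 1).filter(lambda t: abs(t) > 1e-3)] * 3,
)


class TestAngularDistance:
    @pytest.mark.parametrize(
        "u,v,expected",
        [(EX, EX, 0.0), (EX, -EX, 0.0), (EX, EY, 90.0), (EY, EZ, 90.0)],
    )
    def test_reference_angles(self, u, v, expected):
        assert angular_distance(u, v) == pytest.approx(expected, abs=1e-9)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError, match="unit-norm"):
            angular_distance(np.array([2.0, 0, 0]), EX)

    @given(unit_vectors, unit_vectors)
    def test_symmetry_and_antipodal_invariance(self, u, v):
        d = angular_distance(u, v)
        assert 0.0 <= d <= 90.0
        assert d == pytest.approx(angular_distance(v, u), abs=1e-9)
        assert d == pytest.approx(angular_distance(-u, v), abs=1e-9)


class TestNeighborCount:
    def _cone_set(self):
        tilt = np.deg2rad(10.0)
        return DirectionSet(
            np.array([EX, [np.cos(tilt), np.sin(tilt), 0.0], EY]), 1000.0
        )

    def test_orthogonal_axes_have_no_close_neighbors(self):
        s = DirectionSet(np.array([EX, EY, EZ]), 1000.0)
        for i in range(3):
            assert neighbor_count(s, i, threshold=30.0) == 0

    def test_ten_degree_neighbor_detected(self):
        assert neighbor_count(self._cone_set(), 0, threshold=30.0) == 1

    def test_strict_inequality_at_threshold(self):
        # the orthogonal pair sits exactly at 90°, excluded by the strict <
        s = self._cone_set()
        assert neighbor_count(s, 0, threshold=90.0) == 1

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            neighbor_count(self._cone_set(), 5)


def _toy_cone_five():
    """Three vectors within a 15° cone around +x, plus the y and z axes."""
    a = np.deg2rad(12.0)
    cone = np.array(
        [
            EX,
            [np.cos(a), np.sin(a), 0.0],
            [np.cos(a), 0.0, np.sin(a)],
        ]
    )
    return DirectionSet(np.vstack([cone, EY, EZ]), 2700.0)


class TestSubsample:
    def test_identity_when_target_is_full(self):
        s = _toy_cone_five()
        out = subsample_directions(s, 5)
        assert np.array_equal(out.vectors, s.vectors)

    def test_cone_satellites_removed_first(self):
        s = _toy_cone_five()
        out = subsample_directions(s, 3)
        # greedy loop removes the crowded cone members, keeping one survivor
        assert len(out) == 3
        assert any(np.array_equal(v, EY) for v in out.vectors)
        assert any(np.array_equal(v, EZ) for v in out.vectors)
        survivors_x = [v for v in out.vectors if abs(v[0]) > 0.9]
        assert len(survivors_x) == 1

    def test_subset_is_bitwise_exact(self, shell_pair):
        _, s43 = shell_pair
        out = subsample_directions(s43, 22)
        rows = {tuple(v) for v in s43.vectors}
        assert all(tuple(v) in rows for v in out.vectors)

    def test_relative_order_preserved(self, shell_pair):
        _, s43 = shell_pair
        out = subsample_directions(s43, 12)
        idx = [
            int(np.flatnonzero((s43.vectors == v).all(axis=1))[0]) for v in out.vectors
        ]
        assert idx == sorted(idx)

    def test_min_angle_monotone_along_removal(self, shell_pair):
        """Each survivor's nearest-neighbour angle can only grow as crowded
        vectors are removed; consequently the mean minimum angle rises across
        the reconstructed set sizes 43 -> 22 -> 12."""
        _, s43 = shell_pair
        per_vec = min_angle_report(s43).per_vector_min_angle
        checkpoint_means = {43: min_angle_report(s43).mean_min_angle}
        prev_vec = {tuple(v): a for v, a in zip(s43.vectors, per_vec)}
        s = s43
        for n in range(42, 11, -1):
            s = subsample_directions(s, n)
            rep = min_angle_report(s)
            if n in (22, 12):
                checkpoint_means[n] = rep.mean_min_angle
            for v, a in zip(s.vectors, rep.per_vector_min_angle):
                assert a >= prev_vec[tuple(v)] - 1e-12
            prev_vec = {tuple(v): a for v, a in zip(s.vectors, rep.per_vector_min_angle)}
        assert checkpoint_means[43] <= checkpoint_means[22] <= checkpoint_means[12]

    def test_matches_brute_force_single_removal(self):
        """Independent brute-force of one greedy step on random small sets."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 11))
            vecs = rng.standard_normal((n, 3))
            vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
            try:
                s = DirectionSet(vecs, 1000.0)
            except ValueError:
                continue  # rare near-duplicate draw
            out = subsample_directions(s, n - 1)
            removed = [
                i
                for i in range(n)
                if not any(np.array_equal(vecs[i], v) for v in out.vectors)
            ]
            assert len(removed) == 1
            # brute force: neighbour counts, then smallest nearest-neighbour
            # angle, then lowest index
            def angle(i, j):
                return np.degrees(np.arccos(min(1.0, abs(vecs[i] @ vecs[j]))))

            counts = [
                sum(1 for j in range(n) if j != i and angle(i, j) < 30.0)
                for i in range(n)
            ]
            nn = [min(angle(i, j) for j in range(n) if j != i) for i in range(n)]
            cmax = max(counts)
            cand = [i for i in range(n) if counts[i] == cmax]
            best_nn = min(nn[i] for i in cand)
            cand = [i for i in cand if nn[i] == best_nn]
            assert removed[0] == cand[0]

    def test_bad_target(self, shell_pair):
        _, s43 = shell_pair
        with pytest.raises(ValueError):
            subsample_directions(s43, 0)
        with pytest.raises(ValueError):
            subsample_directions(s43, 44)


class TestMinAngleReport:
    def test_orthogonal_axes(self):
        rep = min_angle_report(DirectionSet(np.array([EX, EY, EZ]), 1000.0))
        assert rep.per_vector_min_angle == pytest.approx([90, 90, 90])
        assert rep.mean_min_angle == pytest.approx(90.0)
        assert rep.sd_min_angle == pytest.approx(0.0)

    def test_icosahedral_axes(self):
        # 6 axes of the icosahedron: nearest-neighbour angle arccos(1/sqrt 5)
        phi = (1 + np.sqrt(5)) / 2
        raw = np.array(
            [[0, 1, phi], [0, -1, phi], [1, phi, 0], [-1, phi, 0], [phi, 0, 1], [phi, 0, -1]]
        )
        raw = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        rep = min_angle_report(DirectionSet(raw, 2700.0))
        expected = np.degrees(np.arccos(1 / np.sqrt(5)))
        assert rep.per_vector_min_angle == pytest.approx([expected] * 6, abs=1e-9)

    def test_mean_sd_consistent_with_list(self, shell_pair):
        _, s43 = shell_pair
        rep = min_angle_report(s43)
        assert rep.mean_min_angle == pytest.approx(rep.per_vector_min_angle.mean(), abs=1e-9)
        assert rep.sd_min_angle == pytest.approx(rep.per_vector_min_angle.std(ddof=1), abs=1e-9)

    def test_requires_two_vectors(self):
        with pytest.raises(ValueError):
            min_angle_report(DirectionSet(EX[None, :], 1000.0))


class TestElectrostatic:
    def test_three_directions_are_orthogonal(self):
        s = generate_electrostatic_set(3, seed=5)
        rep = min_angle_report(s)
        assert rep.per_vector_min_angle == pytest.approx([90.0] * 3, abs=1e-4)

    def test_six_directions_are_icosahedral(self):
        s = generate_electrostatic_set(6, seed=5)
        rep = min_angle_report(s)
        expected = np.degrees(np.arccos(1 / np.sqrt(5)))
        assert rep.per_vector_min_angle == pytest.approx([expected] * 6, abs=0.5)

    def test_energy_descends_from_random_start(self):
        rng = np.random.default_rng(9)
        start = rng.standard_normal((10, 3))
        start /= np.linalg.norm(start, axis=1, keepdims=True)
        e_start, _ = _energy_and_grad([start])
        s = generate_electrostatic_set(10, seed=9)
        e_end, _ = _energy_and_grad([s.vectors])
        assert e_end <= e_start

    def test_deterministic_given_seed(self):
        a = generate_electrostatic_set(12, seed=3)
        b = generate_electrostatic_set(12, seed=3)
        assert np.array_equal(a.vectors, b.vectors)

    def test_rejects_tiny_n(self):
        with pytest.raises(ValueError):
            generate_electrostatic_set(2, seed=0)


class TestIO:
    def test_round_trip(self, tmp_path, shell_pair):
        s22, s43 = shell_pair
        write_directions([s22, s43], tmp_path / "d.bvec", tmp_path / "d.bval", n_b0=2)
        shells, n_b0 = read_directions(tmp_path / "d.bvec", tmp_path / "d.bval")
        assert n_b0 == 2
        assert len(shells) == 2
        for orig, rt in zip((s22, s43), shells):
            assert rt.bvalue == orig.bvalue
            assert np.allclose(rt.vectors, orig.vectors, atol=1e-10)

    def test_two_row_bvec_rejected(self, tmp_path):
        (tmp_path / "bad.bvec").write_text("1 0\n0 1\n")
        (tmp_path / "bad.bval").write_text("1000 1000\n")
        with pytest.raises(ValueError, match="3 rows"):
            read_directions(tmp_path / "bad.bvec", tmp_path / "bad.bval")

    def test_column_mismatch_rejected(self, tmp_path):
        (tmp_path / "m.bvec").write_text("1 0 0\n0 1 0\n0 0 1\n")
        (tmp_path / "m.bval").write_text("1000 1000\n")
        with pytest.raises(ValueError, match="columns"):
            read_directions(tmp_path / "m.bvec", tmp_path / "m.bval")

    def test_mixed_b0_and_shell_columns(self, tmp_path):
        # hand-written 5-column file: two b=0 columns plus three b=1000
        (tmp_path / "x.bvec").write_text("0 1 0 0 0\n0 0 1 0 0\n0 0 0 1 0\n")
        (tmp_path / "x.bval").write_text("0 1000 1000 1000 0\n")
        shells, n_b0 = read_directions(tmp_path / "x.bvec", tmp_path / "x.bval")
        assert n_b0 == 2
        assert len(shells) == 1
        assert shells[0].ndir == 3
        assert shells[0].bvalue == 1000.0


class TestDirectionSetValidation:
    def test_rejects_duplicate_vectors(self):
        with pytest.raises(ValueError, match="identical or antipodal"):
            DirectionSet(np.array([EX, EX]), 1000.0)

    def test_rejects_antipodal_pair(self):
        with pytest.raises(ValueError, match="identical or antipodal"):
            DirectionSet(np.array([EX, -EX]), 1000.0)

    def test_rejects_nonpositive_b(self):
        with pytest.raises(ValueError, match="bvalue"):
            DirectionSet(np.array([EX, EY]), 0.0)


class TestAcquisitionScheme:
    def test_from_shells_and_shell_split(self, shell_pair):
        s22, s43 = shell_pair
        scheme = AcquisitionScheme.from_shells([s22, s43], n_b0_per_shell=2)
        assert len(scheme) == 69
        assert scheme.n_b0 == 4
        shells = scheme.shells()
        assert [s.ndir for s in shells] == [22, 43]
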