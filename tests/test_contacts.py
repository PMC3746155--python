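"""Contact detection, fingerprint profiles and their correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lipidprint as lp
from lipidprint.contacts import ContactParams, frame_contacts, window_slice
from lipidprint.core_io import Trajectory

from conftest import (
    brute_force_contacts,
    contact_dict,
    make_annotated,
    random_annotated,
)


class TestFrameContacts:
    def test_boundary_inside_and_outside(self):
        params = ContactParams(cutoff=6.0)
        inside = make_annotated([[0, 0, 0]], [[5.9, 0, 0]], ["tail"])
        cs = frame_contacts(inside, params)
        assert len(cs.pairs) == 1
        assert cs.pairs[0].segment == "tail"
        assert cs.pairs[0].distance == pytest.approx(5.9)
        outside = make_annotated([[0, 0, 0]], [[6.1, 0, 0]], ["tail"])
        assert frame_contacts(outside, params).pairs == []

    def test_minimum_image_wraps(self):
        box = np.array([100.0, 100.0, 100.0])
        frame = make_annotated([[0.5, 50, 50]], [[99.5, 50, 50]],
                               ["phosphate"], box=box)
        cs = frame_contacts(frame, ContactParams(cutoff=6.0, use_pbc=True))
        assert len(cs.pairs) == 1
        assert cs.pairs[0].distance == pytest.approx(1.0)
        # identical to the all-pairs oracle
        assert contact_dict(cs) == brute_force_contacts(
            frame, ContactParams(cutoff=6.0, use_pbc=True))

    def test_pbc_without_box_is_an_error(self):
        frame = make_annotated([[0, 0, 0]], [[5, 0, 0]], ["tail"])
        with pytest.raises(ValueError, match="box"):
            frame_contacts(frame, ContactParams(cutoff=6.0, use_pbc=True))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), pbc=st.booleans())
    def test_spatial_index_equals_brute_force(self, seed, pbc):
        rng = np.random.default_rng(seed)
        frame = random_annotated(rng, n_max=150)
        params = ContactParams(cutoff=float(rng.uniform(2, 8)), use_pbc=pbc)
        assert contact_dict(frame_contacts(frame, params)) == \
            brute_force_contacts(frame, params)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cutoff_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        frame = random_annotated(rng, n_max=150)
        small = contact_dict(frame_contacts(frame, ContactParams(cutoff=4.0)))
        large = contact_dict(frame_contacts(frame, ContactParams(cutoff=7.0)))
        assert set(small) <= set(large)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(42)
        frame = random_annotated(rng, n_max=120, with_box=False)
        params = ContactParams(cutoff=6.0)
        ref = {k: round(v, 9) for k, v in
               contact_dict(frame_contacts(frame, params)).items()}
        # joint rotation + translation of protein and lipids
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = frame.copy()
        moved.coordinates = frame.coordinates @ R.T + np.array([5.0, -3.0, 11.0])
        moved = make_annotated(
            moved.coordinates[frame.roles == "protein"],
            moved.coordinates[frame.roles == "lipid"],
            list(frame.segments[frame.roles == "lipid"]),
            lip_mols=[m - 1 for m in frame.molecule_ids[frame.roles == "lipid"]])
        got = {k: round(v, 9) for k, v in
               contact_dict(frame_contacts(moved, params)).items()}
        assert got == ref


class TestContactProfile:
    def _toggle_trajectory(self, pattern):
        """One protein particle at the origin; the lipid is within 6 Å on
        frames where pattern is 1 and far away otherwise."""
        frames = []
        for on in pattern:
            lip = [[4.0, 0, 0]] if on else [[30.0, 0, 0]]
            frames.append(make_annotated([[0, 0, 0]], lip, ["phosphate"]))
        return Trajectory(frames=frames)

    def test_always_in_contact_is_one(self, martini):
        traj = self._toggle_trajectory([1] * 10)
        prof = lp.contact_profile(traj, martini, ContactParams())
        assert prof.data.loc["A:1", "headgroup_fraction"] == 1.0
        assert prof.n_frames_analyzed == 8  # default window drops 20%

    def test_window_excludes_early_frames(self, martini):
        # contact only in the first 2 of 10 frames: outside [0.2, 1.0]
        traj = self._toggle_trajectory([1, 1] + [0] * 8)
        prof = lp.contact_profile(traj, martini, ContactParams())
        assert prof.data.loc["A:1", "headgroup_fraction"] == 0.0

    def test_deterministic_fraction_matches_pattern(self, martini):
        pattern = ([1] * 6 + [0] * 4) * 10   # 60 of 100 frames
        traj = self._toggle_trajectory(pattern)
        prof = lp.contact_profile(traj, martini,
                                  ContactParams(analysis_window=(0.0, 1.0)))
        assert prof.data.loc["A:1", "phosphate"] == pytest.approx(0.60)

    def test_headgroup_at_least_each_constituent(self, martini, small_run):
        _, traj, _ = small_run
        prof = lp.contact_profile(traj, martini,
                                  ContactParams(analysis_window=(0.0, 1.0)))
        for seg in ("head_terminal", "phosphate", "glycerol"):
            assert (prof.data["headgroup_fraction"] >= prof.data[seg] - 1e-12).all()

    def test_site_occupancy_recovered_exactly(self, martini, small_run):
        """The residue nearest a site sees the site's empirical occupancy
        (the generator's ground truth), bar contacts from neighboring sites."""
        _, traj, truth = small_run
        prof = lp.contact_profile(traj, martini,
                                  ContactParams(analysis_window=(0.0, 1.0)))
        emp = truth.occupancy.mean(axis=0)
        hg = prof.data["headgroup_fraction"]
        for k, res in enumerate(truth.site_nearest_residue):
            assert hg.loc[res] >= emp[k] - 1e-12

    def test_empty_window_is_an_error(self):
        with pytest.raises(ValueError):
            window_slice(10, (0.98, 0.99))


class TestCrystalProfile:
    def test_single_lipid_indicator(self, martini):
        frame = make_annotated([[0, 0, 0], [20, 0, 0]], [[3.5, 0, 0]],
                               ["head_terminal"], resolution="atomistic")
        prof = lp.crystal_contact_profile(frame, ContactParams())
        assert prof.is_binary
        assert prof.data.loc["A:1", "headgroup_fraction"] == 1.0
        assert prof.data.loc["A:2", "headgroup_fraction"] == 0.0

    def test_translation_beyond_cutoff_zeroes_profile(self, martini):
        frame = make_annotated([[0, 0, 0]], [[3.5, 0, 0]], ["head_terminal"],
                               resolution="atomistic")
        shifted = frame.copy()
        shifted.coordinates = frame.coordinates.copy()
        shifted.coordinates[1, 2] += 10.0
        shifted = make_annotated(shifted.coordinates[:1],
                                 shifted.coordinates[1:], ["head_terminal"],
                                 resolution="atomistic")
        prof = lp.crystal_contact_profile(shifted, ContactParams())
        assert (prof.data["headgroup_fraction"] == 0).all()

    def test_requires_lipids(self):
        frame = make_annotated([[0, 0, 0]], [], [])
        with pytest.raises(ValueError, match="lipid"):
            lp.crystal_contact_profile(frame, ContactParams())


class TestInteractingLipidCount:
    def test_phosphate_within_cutoff_counts(self, martini):
        frame = make_annotated(
            [[0, 0, 0]],
            [[5.0, 0, 0], [7.0, 0, 0], [0, 5.5, 0]],
            ["phosphate"] * 3, lip_mols=[0, 1, 2])
        traj = Trajectory(frames=[frame])
        counts, mean = lp.interacting_lipid_count(
            traj, martini, ContactParams(cutoff=6.0, analysis_window=(0.0, 1.0)))
        assert counts.tolist() == [2]
        assert mean == 2.0

    def test_generator_annulus_counted_exactly(self, martini):
        from lipidprint.synthetic_data import (AnnulusSpec, SyntheticParams,
                                               generate)
        params = SyntheticParams(n_frames=20, seed=9,
                                 annulus=AnnulusSpec(n_sites=20, p_occ=1.0))
        traj, _ = generate(params)
        counts, mean = lp.interacting_lipid_count(
            traj, martini, ContactParams(analysis_window=(0.0, 1.0)))
        assert mean == 20.0


class TestCorrelation:
    def test_identity_and_antisymmetry(self):
        prof = _profile_from_vector([0.1, 0.5, 0.9, 0.3])
        assert lp.correlate_profiles(prof, prof).r == pytest.approx(1.0)
        up = _profile_from_vector([1.0, 2 / 3, 1 / 3])
        down = _profile_from_vector([1 / 3, 2 / 3, 1.0])
        assert lp.correlate_profiles(up, down).r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        a = np.array([0.2, 0.8, 0.4, 0.6])
        b = np.array([0.1, 0.9, 0.2, 0.5])
        # independent oracle: covariance over product of standard deviations
        expect = (np.mean((a - a.mean()) * (b - b.mean()))
                  / (a.std() * b.std()))
        got = lp.correlate_profiles(_profile_from_vector(a),
                                    _profile_from_vector(b)).r
        assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_flagged_not_nan_surprise(self):
        flat = _profile_from_vector([0.5, 0.5, 0.5])
        other = _profile_from_vector([0.1, 0.2, 0.3])
        res = lp.correlate_profiles(flat, other)
        assert res.undefined and np.isnan(res.r)

    def test_too_few_shared_residues(self):
        a = _profile_from_vector([0.1, 0.2])
        b = _profile_from_vector([0.3, 0.4])
        with pytest.raises(ValueError, match="shared"):
            lp.correlate_profiles(a, b)

    def test_nonshared_residues_dropped(self):
        a = _profile_from_vector([0.1, 0.2, 0.3, 0.4])
        b = _profile_from_vector([0.1, 0.25, 0.28, 0.4, 0.9])
        res = lp.correlate_profiles(a, b)
        assert res.n_shared == 4
        assert res.n_dropped == 1

    def test_affine_rescaling_invariance(self):
        a = _profile_from_vector([0.1, 0.4, 0.2, 0.8])
        scaled = _profile_from_vector(
            (np.array([0.1, 0.4, 0.2, 0.8]) * 0.5 + 0.1))
        assert lp.correlate_profiles(a, scaled).r == pytest.approx(1.0)

    def test_matrix_mirrors_pairwise_calls(self):
        rng = np.random.default_rng(3)
        profs = [_profile_from_vector(rng.uniform(0, 1, 8), tag=f"p{i}")
                 for i in range(3)]
        m = lp.correlation_matrix(profs)
        assert np.allclose(np.diag(m.values), 1.0)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                channel = "headgroup" if i < j else "tail"
                assert m.iloc[i, j] == pytest.approx(
                    lp.correlate_profiles(profs[i], profs[j], channel).r)

    def test_mixed_scale_flagged(self, martini):
        sim = _profile_from_vector([0.1, 0.6, 0.3, 0.9])
        cry = _profile_from_vector([0.0, 1.0, 0.0, 1.0])
        cry.is_binary = True
        assert lp.correlate_profiles(sim, cry).mixed_scale


def _profile_from_vector(values, tag="test"):
    """ContactProfile carrying the vector in both channels; longer vectors
    exercise key alignment (keys are A:1, A:2, ...)."""
    import pandas as pd
    from lipidprint.contacts import ContactProfile
    values = np.asarray(values, dtype=float)
    n = len(values)
    keys = [f"A:{i + 1}" for i in range(n)]
    df = pd.DataFrame({
        "chain": "A", "resseq": range(1, n + 1), "icode": "",
        "resname": "LEU",
        "head_terminal": values, "phosphate": values, "glycerol": values,
        "tail": values,
        "headgroup_fraction": values, "tail_fraction": values,
    }, index=pd.Index(keys, name="residue"))
    return ContactProfile(df, n_frames_analyzed=10, source_tag=tag)
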