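import copy
import math

import numpy as np
import pytest

from coilreg import ccgeom, synthetic
from coilreg.ccgeom import (assign_heptads, coiled_coil_profile,
                            heptad_letter_from_phase, local_helix_frames,
                            summarize_window, wrap_angle)
from coilreg.structure_io import Atom, Residue
from coilreg.synthetic import CrickParameters, DistortionSpec
from conftest import random_rotation

OMEGA1 = 720.0 / 7.0


def _frames(structure, chain="A"):
    return local_helix_frames(structure.chain(chain))


def _defined(frames):
    return [f for f in frames if f.defined]


class TestLocalHelixFrames:
    def test_straight_helix_parameters(self):
        """For an undistorted helix the frame recovers the construction
        radius, rise and twist."""
        st = synthetic.generate_coiled_coil(
            CrickParameters(omega0=0.0, pitch=math.inf, n_res=30))
        for f in _defined(_frames(st)):
            assert f.local_helix_radius == pytest.approx(2.26, abs=0.05)
            assert f.local_rise == pytest.approx(1.51, abs=0.02)
            assert f.local_twist == pytest.approx(OMEGA1, abs=1.0)

    def test_supercoiled_lab_frame_twist(self, ideal_dimer):
        """On a supercoiled helix the lab-frame twist is omega1 + omega0
        (the true alpha-helical periodicity, ~98.9 deg/residue)."""
        params = CrickParameters()
        twists = [f.local_twist for f in _defined(_frames(ideal_dimer))]
        assert np.mean(twists) == pytest.approx(params.omega1 + params.omega0,
                                                abs=1.0)

    def test_collinear_trace_flagged_not_raised(self):
        ca = [Residue(i, "ALA", [Atom("CA", "C", np.array([0.0, 0.0, 3.8 * i]))])
              for i in range(6)]
        frames = local_helix_frames(ca)
        assert frames and all(not f.defined for f in frames)

    def test_chain_break_splits_segments(self, ideal_dimer):
        chain = copy.deepcopy(ideal_dimer.chain("A"))
        for r in chain[40:]:
            for a in r.atoms:
                a.coords = a.coords + np.array([0.0, 0.0, 50.0])
        frames = _defined(local_helix_frames(chain))
        nums = [f.residue_number for f in frames]
        # residues flanking the break lose their frames, the rest survive
        assert 40 not in nums and 41 not in nums
        assert 38 in nums and 43 in nums

    def test_terminal_residues_carry_no_frame(self, ideal_dimer):
        nums = {f.residue_number for f in _frames(ideal_dimer)}
        chain_nums = [r.number for r in ideal_dimer.chain("A")]
        assert chain_nums[0] not in nums and chain_nums[-1] not in nums


class TestCoiledCoilProfile:
    def test_generator_roundtrip_default(self, ideal_profile):
        params = CrickParameters()
        interior = ideal_profile.cc_radius[3:-3]
        assert np.mean(interior) == pytest.approx(params.r0, rel=0.02)
        pitch = ideal_profile.cc_pitch[np.isfinite(ideal_profile.cc_pitch)]
        assert np.mean(pitch) == pytest.approx(abs(params.pitch), rel=0.05)

    @pytest.mark.parametrize("r0", [3.5, 4.9, 6.5])
    @pytest.mark.parametrize("pitch", [100.0, 175.0, 250.0])
    def test_generator_roundtrip_grid(self, r0, pitch):
        """Measured radius and pitch match generator values within 2%
        across the physical parameter range."""
        st = synthetic.generate_coiled_coil(
            CrickParameters(r0=r0, pitch=-pitch, n_res=60))
        prof = coiled_coil_profile(_frames(st, "A"), _frames(st, "B"))
        assert np.mean(prof.cc_radius[3:-3]) == pytest.approx(r0, rel=0.02)
        vals = prof.cc_pitch[np.isfinite(prof.cc_pitch)][3:-3]
        assert np.mean(vals) == pytest.approx(pitch, rel=0.02)

    def test_parallel_straight_helices_limit(self):
        """No supercoil: phase advance ~0, pitch sentinel +inf, radius is
        half the axis-axis separation."""
        st = synthetic.generate_coiled_coil(
            CrickParameters(omega0=0.0, pitch=math.inf, n_res=30))
        prof = coiled_coil_profile(_frames(st, "A"), _frames(st, "B"))
        assert not prof.supercoiled.any()
        assert np.all(np.isinf(prof.cc_pitch))
        assert np.nanmean(np.abs(prof.delta_phase)) < ccgeom.SUPERCOIL_PHASE_MIN
        assert np.mean(prof.cc_radius) == pytest.approx(4.9, abs=0.1)

    def test_rigid_motion_invariance(self, ideal_dimer, ideal_profile, rng):
        rot = random_rotation(rng)
        shift = rng.standard_normal(3) * 20
        moved = copy.deepcopy(ideal_dimer)
        for cid in moved.chain_ids():
            for r in moved.chain(cid):
                for a in r.atoms:
                    a.coords = rot @ a.coords + shift
        prof = coiled_coil_profile(_frames(moved, "A"), _frames(moved, "B"))
        assert np.allclose(prof.cc_radius, ideal_profile.cc_radius, atol=1e-9)
        fin = np.isfinite(ideal_profile.cc_pitch)
        assert np.allclose(prof.cc_pitch[fin], ideal_profile.cc_pitch[fin],
                           atol=1e-6)
        assert np.allclose(wrap_angle(prof.crick_phase -
                                      ideal_profile.crick_phase), 0, atol=1e-6)

    def test_too_few_pairs_raises(self, ideal_dimer):
        fa = _frames(ideal_dimer)[:5]
        fb = _frames(ideal_dimer, "B")[:5]
        with pytest.raises(ccgeom.InsufficientDataError):
            coiled_coil_profile(fa, fb)

    def test_crick_phase_step_is_heptad_twist(self, ideal_profile):
        """Rotating-frame twist: Crick phase advances 720/7 deg/residue."""
        steps = wrap_angle(np.diff(ideal_profile.crick_phase))
        assert np.nanmean(np.abs(steps)) == pytest.approx(OMEGA1, abs=0.5)


class TestHeptads:
    def test_letters_cycle_and_count(self, ideal_profile):
        """76-residue chains expose 70+ interior positions: ten regular
        heptads with letters cycling abcdefg."""
        profile = copy.deepcopy(ideal_profile)
        summary = assign_heptads(profile)
        assert summary.n_regular_heptads == 10
        letters = profile.heptad_letters
        order = "abcdefg"
        for prev, cur in zip(letters, letters[1:]):
            assert order[(order.index(prev) + 1) % 7] == cur

    def test_supercoil_loss_truncates_span(self):
        k = 40
        st = synthetic.generate_coiled_coil(
            CrickParameters(n_res=76), DistortionSpec(supercoil_loss_after=k))
        prof = coiled_coil_profile(_frames(st, "A"), _frames(st, "B"))
        summary = assign_heptads(prof)
        assert summary.heptad_span is not None
        assert abs(summary.heptad_span[1] - k) <= 7

    def test_no_supercoiled_run_gives_zero(self):
        st = synthetic.generate_coiled_coil(
            CrickParameters(omega0=0.0, pitch=math.inf, n_res=30))
        prof = coiled_coil_profile(_frames(st, "A"), _frames(st, "B"))
        assert assign_heptads(prof).n_regular_heptads == 0

    def test_letter_is_pure_function_of_phase(self):
        """Advancing the phase by one ideal residue step advances the
        letter by one position in the a-g cycle."""
        order = "abcdefg"
        # keep sample phases off the exact bin boundaries, where the letter
        # legitimately flips
        for phase in np.linspace(0, 360, 29) + 5.0:
            a = heptad_letter_from_phase(phase)
            b = heptad_letter_from_phase((phase + OMEGA1) % 360)
            assert order[(order.index(a) + 1) % 7] == b

    def test_buried_positions_are_a_and_d(self):
        for phase, letter in ((180 + OMEGA1 / 4, "a"), (180 - OMEGA1 / 4, "d")):
            assert heptad_letter_from_phase(phase) == letter

    def test_ad_positions_closest_to_partner(self, ideal_dimer, ideal_profile):
        """Exhaustive check: a/d CA atoms are the most buried (closest to
        the partner chain)."""
        profile = copy.deepcopy(ideal_profile)
        assign_heptads(profile)
        ca_b = np.array([r.coords("CA") for r in ideal_dimer.chain("B")])
        dists = {}
        for num, letter in zip(profile.residue_numbers, profile.heptad_letters):
            ca = ideal_dimer.residue("A", int(num)).coords("CA")
            d = float(np.min(np.linalg.norm(ca_b - ca, axis=1)))
            dists.setdefault(letter, []).append(d)
        means = {k: np.mean(v) for k, v in dists.items()}
        core = {means["a"], means["d"]}
        others = [means[k] for k in "bcefg"]
        assert max(core) < min(others)


def test_summarize_window(ideal_profile):
    params = CrickParameters()
    s = summarize_window(ideal_profile, 20, 55)
    assert s.mean_radius == pytest.approx(params.r0, rel=0.02)
    assert s.mean_pitch == pytest.approx(abs(params.pitch), rel=0.02)
    assert s.sd_radius >= 0 and s.sd_pitch >= 0
    with pytest.raises(ccgeom.InsufficientDataError):
        summarize_window(ideal_profile, 500, 600)
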