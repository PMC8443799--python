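import numpy as np
import pytest

from coilreg import assembly, synthetic
from coilreg.assembly import (MergeError, SamplingFailure, Segment,
                              SegmentPlan, assemble_hybrid, count_clashes,
                              crosslink_check, dock_onto_continuation,
                              grow_backbone, merge_models, sample_linker,
                              thread_backbone)
from coilreg.structure_io import Structure


@pytest.fixture(scope="module")
def template():
    st = synthetic.generate_coiled_coil(synthetic.CrickParameters(n_res=40))
    return Structure(chains={"A": st.chain("A")})


class TestThreadBackbone:
    def test_zero_offset_copies_template(self, template):
        seq = {r.number: "A" for r in template.chain("A")}
        model = thread_backbone(template, "A", 0, seq)
        for num in seq:
            src = template.residue("A", num)
            dst = model.residue("A", num)
            assert np.allclose(dst.coords("CA"), src.coords("CA"))

    def test_offset_shifts_source(self, template):
        seq = {i: "L" for i in range(10, 30)}
        model = thread_backbone(template, "A", -3, seq)
        for i in seq:
            assert np.allclose(model.residue("A", i).coords("CA"),
                               template.residue("A", i - 3).coords("CA"))
            assert model.residue("A", i).name == "LEU"

    def test_template_gap_raises(self, template):
        seq = {i: "A" for i in range(35, 50)}   # template ends at 40
        with pytest.raises(MergeError) as err:
            thread_backbone(template, "A", 0, seq)
        assert "41" in str(err.value)


class TestSampleLinker:
    def test_single_residue_trivial(self):
        ens = sample_linker("G", n=1, seed=0)
        assert ens.n_conformers == 1
        assert ens.end_to_end[0] == 0.0

    def test_contour_bound_and_stiff_scaling(self):
        """End-to-end never exceeds the contour length; mean growth is
        between ideal-coil (0.5) and rod (1.0) scaling over 10/20/40."""
        means = []
        for n in (10, 20, 40):
            ens = sample_linker("G" * n, n=40, seed=11)
            assert np.all(ens.end_to_end < 3.8 * n)
            means.append(ens.end_to_end.mean())
        exponent = np.polyfit(np.log([10, 20, 40]), np.log(means), 1)[0]
        assert 0.5 < exponent < 1.0

    def test_seed_bitwise_reproducible(self):
        a = sample_linker("G" * 15, n=3, seed=5)
        b = sample_linker("G" * 15, n=3, seed=5)
        for ca, cb in zip(a.conformers, b.conformers):
            for ra, rb in zip(ca.chain("A"), cb.chain("A")):
                for x, y in zip(ra.atoms, rb.atoms):
                    assert np.array_equal(x.coords, y.coords)

    def test_accepted_conformers_clash_free(self):
        ens = sample_linker("G" * 25, n=10, seed=2)
        for conf in ens.conformers:
            coords = np.array([[a.coords for a in r.atoms]
                               for r in conf.chain("A")])
            assert count_clashes(coords) == 0

    def test_anchor_filters_conformers(self):
        free = sample_linker("G" * 12, n=30, seed=3)
        target = free.conformers[0].chain("A")[-1].coords("CA")
        anchored = sample_linker("G" * 12, n=5, seed=4, end_anchor=target,
                                 end_tolerance=12.0,
                                 max_retries_per_conformer=5000)
        for conf in anchored.conformers:
            end = conf.chain("A")[-1].coords("CA")
            assert np.linalg.norm(end - target) <= 12.0
        assert anchored.acceptance_rate <= 1.0

    def test_impossible_anchor_fails_with_rate(self):
        with pytest.raises(SamplingFailure) as err:
            sample_linker("G" * 10, n=1, seed=0,
                          end_anchor=np.array([500.0, 0, 0]),
                          end_tolerance=1.0, max_retries_per_conformer=50)
        assert "acceptance rate" in str(err.value)

    def test_backbone_geometry(self):
        ens = sample_linker("G" * 20, n=2, seed=9)
        for conf in ens.conformers:
            chain = conf.chain("A")
            for a, b in zip(chain, chain[1:]):
                ca_ca = np.linalg.norm(b.coords("CA") - a.coords("CA"))
                assert ca_ca == pytest.approx(3.8, abs=0.2)
                c_n = np.linalg.norm(b.coords("N") - a.coords("C"))
                assert c_n == pytest.approx(1.33, abs=0.05)


class TestMerge:
    def _plan_and_parts(self, seed=0):
        st = synthetic.generate_coiled_coil(synthetic.CrickParameters(n_res=20))
        coil = Structure(chains={"A": st.chain("A")})
        plan = SegmentPlan([Segment("template-threaded", 1, 20),
                            Segment("random-extended", 21, 30),
                            Segment("rigid-domain", 31, 50)])
        domain = synthetic.generate_compact_domain(20, seed=seed,
                                                   start_number=31)
        return plan, coil, domain

    def test_single_segment_plan_identity(self, template):
        plan = SegmentPlan([Segment("template-threaded", 1, 40)])
        merged, prov = merge_models(plan, {(1, 40): template})
        assert merged.n_residues() == 40
        assert set(prov.values()) == {"template-threaded"}

    def test_three_segment_merge_continuous(self):
        plan, coil, domain = self._plan_and_parts()
        models = assemble_hybrid(plan, sources={(1, 20): coil, (31, 50): domain},
                                 sequences={(21, 30): "G" * 10},
                                 n_conformers=2, seed=4)
        for model, prov in models:
            nums = [r.number for r in model.chain("A")]
            assert nums == list(range(1, 51))
            for seam in (21, 31):   # segment junctions are peptide-continuous
                c_prev = model.residue("A", seam - 1).coords("C")
                n_next = model.residue("A", seam).coords("N")
                d = np.linalg.norm(n_next - c_prev)
                assert abs(d - 1.33) <= assembly.PEPTIDE_BOND_TOL
            assert prov[25] == "random-extended" and prov[40] == "rigid-domain"

    def test_seam_violation_raises(self, template):
        plan = SegmentPlan([Segment("template-threaded", 1, 20),
                            Segment("rigid-domain", 21, 40)])
        part2_res = [r for r in template.chain("A") if r.number > 20]
        # un-docked second part: seam is discontinuous after displacement
        for r in part2_res:
            for a in r.atoms:
                a.coords = a.coords + 25.0
        with pytest.raises(MergeError) as err:
            merge_models(plan, {(1, 20): template,
                                (21, 40): Structure(chains={"A": part2_res})})
        assert "seam" in str(err.value)

    def test_non_contiguous_plan_rejected(self):
        with pytest.raises(MergeError):
            SegmentPlan([Segment("rigid-domain", 1, 10),
                         Segment("rigid-domain", 12, 20)])

    def test_dock_produces_ideal_seam(self, template):
        domain = synthetic.generate_compact_domain(15, seed=1, start_number=41)
        docked = dock_onto_continuation(template.chain("A")[-1], domain)
        c = template.chain("A")[-1].coords("C")
        n = docked.chain("A")[0].coords("N")
        assert np.linalg.norm(n - c) == pytest.approx(1.329, abs=0.05)

    def test_ensembles_seed_reproducible(self):
        plan, coil, domain = self._plan_and_parts()
        m1 = assemble_hybrid(plan, {(1, 20): coil, (31, 50): domain},
                             {(21, 30): "G" * 10}, n_conformers=1, seed=8)
        m2 = assemble_hybrid(plan, {(1, 20): coil, (31, 50): domain},
                             {(21, 30): "G" * 10}, n_conformers=1, seed=8)
        for (a, _), (b, _) in zip(m1, m2):
            for ra, rb in zip(a.chain("A"), b.chain("A")):
                assert np.array_equal(ra.coords("CA"), rb.coords("CA"))


class TestCrosslinkCheck:
    def test_adjacent_residues_compatible_both_chemistries(self, template):
        for chem in ("BS3", "EDC"):
            res = crosslink_check(template, [(10, 11)], chem)
            assert res.distances[0] == pytest.approx(3.8, abs=0.3)
            assert res.compatible[0]

    def test_exact_threshold(self):
        from coilreg.structure_io import Atom, Residue
        r1 = Residue(1, "LYS", [Atom("CA", "C", np.zeros(3))])
        r2 = Residue(2, "LYS", [Atom("CA", "C", np.array([35.0, 0, 0]))])
        r3 = Residue(3, "LYS", [Atom("CA", "C", np.array([0, 29.0, 0]))])
        st = Structure(chains={"A": [r1, r2, r3]})
        res = crosslink_check(st, [(1, 2), (1, 3)], "BS3")
        assert list(res.compatible) == [False, True]

    def test_missing_residue_unassessable(self, template):
        res = crosslink_check(template, [(10, 999)], "BS3")
        assert not res.assessable[0]
        assert np.isnan(res.distances[0])
        assert np.isnan(res.fraction_compatible) or res.fraction_compatible == 0

    def test_unknown_chemistry(self, template):
        with pytest.raises(ValueError):
            crosslink_check(template, [(1, 2)], "DSSO")
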