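"""Dihedral primitive, torsions, pseudotorsions and pucker analysis."""

import math

import numpy as np
import pytest
from Bio.PDB.vectors import Vector, calc_dihedral

from rnakit.fixtures import HelixSpec, make_helix_chain, pseudorotation_torsions
from rnakit.geometry import (
    annotate_chain,
    backbone_torsions,
    dihedral,
    place_atom,
    pseudotorsions,
    pucker_label,
    sugar_pucker,
)
from rnakit.structure_io import RnaChain


def reference_dihedral(p1, p2, p3, p4) -> float:
    """Independent oracle: Biopython's vector-algebra implementation."""
    rad = calc_dihedral(Vector(*p1), Vector(*p2), Vector(*p3), Vector(*p4))
    return math.degrees(rad) % 360.0


class TestDihedral:
    def test_trans_zigzag_is_180(self):
        pts = [(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)]
        assert dihedral(*pts) == pytest.approx(180.0, abs=1e-12)

    @pytest.mark.parametrize("angle", [30.0, 90.0, 275.0])
    def test_constructed_angle_recovered(self, angle):
        a, b, c = np.array([1.0, 1.0, 0.0]), np.zeros(3), np.array([0.0, 0.0, 1.5])
        d = place_atom(a, b, c, 1.4, 111.0, angle)
        assert dihedral(a, b, c, d) == pytest.approx(angle, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        for _ in range(100):
            pts = rng.normal(size=(4, 3)) * 3.0
            base = dihedral(*pts)
            rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
            shift = rng.normal(size=3) * 10.0
            moved = rot.apply(pts) + shift
            delta = abs((dihedral(*moved) - base + 180.0) % 360.0 - 180.0)
            assert delta <= 1e-9

    def test_matches_independent_oracle(self, rng):
        for _ in range(2000):
            pts = rng.normal(size=(4, 3)) * 2.0
            mine = dihedral(*pts)
            if math.isnan(mine):
                continue
            ref = reference_dihedral(*pts)
            assert abs((mine - ref + 180.0) % 360.0 - 180.0) <= 1e-9

    def test_degenerate_geometry_is_nan(self):
        collinear = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)]
        assert math.isnan(dihedral(*collinear))
        coincident = [(0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)]
        assert math.isnan(dihedral(*coincident))


class TestBackboneTorsions:
    def test_five_prime_terminus_alpha_undefined_only(self):
        # P present on residue 1 so only the missing O3'(i-1) matters
        chain = make_helix_chain(
            HelixSpec(4, "ACGU"), include_5p_phosphate=True
        )
        first = backbone_torsions(chain, 1)
        assert math.isnan(first["alpha"])
        for name in ("beta", "gamma", "delta", "epsilon", "zeta", "chi"):
            assert not math.isnan(first[name]), name

    def test_three_prime_terminus(self, helix_chain):
        last = backbone_torsions(helix_chain, len(helix_chain))
        assert math.isnan(last["epsilon"]) and math.isnan(last["zeta"])
        assert not math.isnan(last["delta"])

    def test_interior_residues_identical_by_helix_periodicity(self, helix_chain):
        rows = [backbone_torsions(helix_chain, i) for i in (3, 4, 5)]
        for name in ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi"):
            vals = [r[name] for r in rows]
            assert max(vals) - min(vals) <= 1e-6, name

    @pytest.mark.parametrize(
        "chi,expected", [(0.0, "syn"), (45.0, "syn"), (300.0, "syn"), (200.0, "anti"), (120.0, "anti")]
    )
    def test_syn_anti_window(self, chi, expected):
        chain = make_helix_chain(HelixSpec(2, "AG", chi_deg=chi))
        bt = backbone_torsions(chain, 2)
        assert abs((bt["chi"] - chi + 180.0) % 360.0 - 180.0) <= 1e-6
        assert bt["chi_class"] == expected


class TestPseudotorsions:
    def test_length_two_boundary(self):
        chain = make_helix_chain(HelixSpec(2, "AC"), include_5p_phosphate=True)
        first = pseudotorsions(chain, 1)
        second = pseudotorsions(chain, 2)
        assert math.isnan(first["eta"])  # needs C4'(i-1)
        assert math.isnan(second["theta"])  # needs P(i+1)

    def test_interior_identical(self, helix_chain):
        vals = [pseudotorsions(helix_chain, i) for i in (3, 4, 5)]
        for name in ("eta", "theta", "eta_prime", "theta_prime"):
            defined = [v[name] for v in vals if not math.isnan(v[name])]
            if len(defined) > 1:
                assert max(defined) - min(defined) <= 1e-6, name

    def test_prime_equals_unprimed_when_c1_copied_onto_c4(self, helix_chain):
        import copy

        chain = copy.deepcopy(helix_chain)
        for res in chain.residues:
            res.atoms["C1'"] = res.atoms["C4'"].copy()
        for i in (3, 4):
            pt = pseudotorsions(chain, i)
            assert pt["eta_prime"] == pt["eta"]
            assert pt["theta_prime"] == pt["theta"]


class TestSugarPucker:
    @pytest.mark.parametrize(
        "phase,amp,label",
        [(18.0, 40.0, "C3'-endo"), (162.0, 38.0, "C2'-endo"), (90.0, 40.0, "O4'-endo")],
    )
    def test_forward_inverse(self, phase, amp, label):
        nus = pseudorotation_torsions(phase, amp)
        p, a, lab = sugar_pucker(*nus)
        assert p == pytest.approx(phase, abs=1e-9)
        assert a == pytest.approx(amp, abs=1e-9)
        assert lab == label

    def test_planar_ring(self):
        p, a, lab = sugar_pucker(0.0, 0.0, 0.0, 0.0, 0.0)
        assert a == 0.0 and lab is None

    def test_nu2_near_zero_quadrant(self):
        # P = 90: nu2 = nu_max * cos(90) = 0; atan2 must still resolve it
        nus = pseudorotation_torsions(90.0, 35.0)
        p, a, _ = sugar_pucker(*nus)
        assert p == pytest.approx(90.0, abs=1e-9)
        assert a == pytest.approx(35.0, abs=1e-9)

    def test_bin_edges(self):
        assert pucker_label(0.0) == "C3'-endo"
        assert pucker_label(35.999) == "C3'-endo"
        assert pucker_label(36.0) == "C4'-exo"
        assert pucker_label(324.0) == "C2'-exo"


class TestAnnotateChain:
    def test_single_residue_chain(self):
        chain = make_helix_chain(HelixSpec(1, "A"), include_5p_phosphate=True)
        (desc,) = annotate_chain(chain)
        for name in ("alpha", "epsilon", "zeta", "eta", "theta"):
            assert math.isnan(getattr(desc, name)), name
        assert not math.isnan(desc.phase)
        assert desc.pucker_label == "C3'-endo"

    def test_unresolved_neighbor_propagates(self):
        chain = make_helix_chain(
            HelixSpec(4, "ACGU"), unresolved={2}, include_5p_phosphate=True
        )
        descs = annotate_chain(chain)
        assert math.isnan(descs[0].epsilon) and math.isnan(descs[0].zeta)
        assert math.isnan(descs[2].alpha) and math.isnan(descs[2].eta)
        assert all(math.isnan(getattr(descs[1], n)) for n in ("phase", "chi", "eta"))
        assert descs[1].pucker_label is None

    def test_undefined_count_matches_closed_form(self, helix_chain):
        # fully resolved chain, no 5' P: undefined angles come only from the
        # termini (alpha/beta/eta at residue 1 via the missing P and C4'(0);
        # epsilon/zeta/theta-family at residue L via the missing residue L+1)
        descs = annotate_chain(helix_chain)
        undefined = {
            (d.index, name)
            for d in descs
            for name in (
                "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi",
                "eta", "theta", "eta_prime", "theta_prime", "eta_pprime",
                "theta_pprime",
            )
            if math.isnan(getattr(d, name))
        }
        L = len(helix_chain)
        expected = {
            (1, "alpha"), (1, "beta"),
            # both pseudotorsion anchors of residue 1 are incomplete: eta
            # needs C4'(0) and theta needs the absent 5'-terminal P(1)
            (1, "eta"), (1, "eta_prime"), (1, "eta_pprime"),
            (1, "theta"), (1, "theta_prime"), (1, "theta_pprime"),
            (L, "epsilon"), (L, "zeta"),
            # eta(L) needs P(L+1) just as theta(L) does
            (L, "eta"), (L, "eta_prime"), (L, "eta_pprime"),
            (L, "theta"), (L, "theta_prime"), (L, "theta_pprime"),
        }
        assert undefined == expected

    def test_rigid_motion_invariance_of_all_descriptors(self, helix_chain, rng):
        import copy

        from scipy.spatial.transform import Rotation

        base = annotate_chain(helix_chain)
        rot = Rotation.random(random_state=np.random.RandomState(4))
        shift = rng.normal(size=3) * 20.0
        moved = copy.deepcopy(helix_chain)
        for res in moved.residues:
            for name in res.atoms:
                res.atoms[name] = rot.apply(res.atoms[name]) + shift
        for d0, d1 in zip(base, annotate_chain(moved)):
            for field, v0 in d0.defined_angles().items():
                v1 = getattr(d1, field)
                assert abs((v1 - v0 + 180.0) % 360.0 - 180.0) <= 1e-9, field
            assert d0.pucker_label == d1.pucker_label
            assert d0.chi_class == d1.chi_class
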