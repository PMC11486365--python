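import math

import numpy as np
import pytest

from tango.chain_builder import TorsionPrescription, build_chain, random_prescription
from tango.torsion_core import (
    AngleKind,
    chain_torsions,
    classify_glycosidic,
    dihedral,
    pseudorotation,
    pucker_name,
    residue_torsions,
    wrap_half,
)

BACKBONE_CHI = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


@pytest.mark.parametrize(
    "d,expected",
    [((1, 1, 0), 0.0), ((-1, 1, 0), 180.0), ((0, 1, 1), 90.0), ((0, 1, -1), -90.0)],
)
def test_dihedral_sign_convention(d, expected):
    got = dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), d)
    assert got == pytest.approx(expected, abs=1e-12)


def test_dihedral_degenerate_inputs_are_nan():
    assert math.isnan(dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)))  # collinear
    assert math.isnan(dihedral((1, 0, 0), (0, 0, 0), (0, 0, 0), (0, 1, 1)))  # b == c
    assert math.isnan(dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (0, float("nan"), 1)))


def test_terminus_rules():
    torsions = chain_torsions(build_chain(TorsionPrescription.uniform("GCGC")).chains[0])
    first, last = torsions[0], torsions[-1]
    for kind in (AngleKind.alpha, AngleKind.eta, AngleKind.eta_prime):
        assert not first.defined(kind)
    for kind in (AngleKind.beta, AngleKind.gamma, AngleKind.delta,
                 AngleKind.epsilon, AngleKind.zeta, AngleKind.chi):
        assert first.defined(kind)
    for kind in (AngleKind.epsilon, AngleKind.zeta, AngleKind.theta,
                 AngleKind.theta_prime, AngleKind.eta, AngleKind.eta_prime):
        assert not last.defined(kind)


def test_breaks_suppress_inter_residue_angles():
    chain = build_chain(TorsionPrescription.uniform("GCGC")).chains[0]
    chain.breaks = {1}  # break between residues 2 and 3
    torsions = chain_torsions(chain)
    assert not torsions[2].defined(AngleKind.alpha)
    assert not torsions[1].defined(AngleKind.epsilon)
    assert not torsions[1].defined(AngleKind.zeta)
    assert not torsions[1].defined(AngleKind.theta)
    assert not torsions[2].defined(AngleKind.eta)
    assert torsions[2].defined(AngleKind.beta)


def test_prescribed_gamma_recovered():
    p = TorsionPrescription.uniform("GCG", gamma=54.0)
    got = residue_torsions(build_chain(p).chains[0], 1).get(AngleKind.gamma)
    assert got == pytest.approx(54.0, abs=1e-6)


def test_unknown_base_class_gives_undefined_chi():
    chain = build_chain(TorsionPrescription.uniform("G")).chains[0]
    for name in ("N9", "C4", "C8"):
        del chain.residues[0].atoms[name]
    t = chain_torsions(chain)[0]
    assert chain.residues[0].base_class == "unknown"
    assert not t.defined(AngleKind.chi)
    assert t.glycosidic == "undefined"


def _cosine_nus(p_deg, tau=40.0):
    return [tau * math.cos(math.radians(p_deg + 144.0 * (j - 2))) for j in range(5)]


def test_pseudorotation_recovers_cosine_model_phase():
    for p_true in range(0, 360, 18):
        for tau in (35.0, 40.0, 45.0):
            p, _ = pseudorotation(_cosine_nus(p_true, tau))
            assert abs(wrap_half(p - p_true)) < 1e-9


def test_pseudorotation_quadrants_and_anchors():
    p0, name0 = pseudorotation(_cosine_nus(0.0))
    assert p0 == pytest.approx(0.0, abs=1e-9) and name0 == "C2'-exo-C3'-endo"
    p90, name90 = pseudorotation(_cosine_nus(90.0))  # nu2 = 0: quadrant case
    assert p90 == pytest.approx(90.0, abs=1e-9) and name90 == "O4'-endo"
    p270, name270 = pseudorotation(_cosine_nus(270.0))
    assert p270 == pytest.approx(270.0, abs=1e-9) and name270 == "O4'-exo"


def test_pseudorotation_sign_flip_shifts_phase_by_180():
    for p_true in (10.0, 100.0, 200.0, 300.0):
        nus = _cosine_nus(p_true)
        p_fwd, _ = pseudorotation(nus)
        p_rev, _ = pseudorotation([-v for v in nus])
        assert abs(wrap_half(p_rev - p_fwd - 180.0)) < 1e-9


def test_pseudorotation_undefined_cases():
    p, name = pseudorotation([float("nan"), 1, 2, 3, 4])
    assert math.isnan(p) and name is None
    p, name = pseudorotation([0.0, 0.0, 0.0, 0.0, 0.0])  # flat ring
    assert math.isnan(p) and name is None


def test_pucker_wheel_alternates_envelope_and_twist():
    for sector in range(20):
        name = pucker_name(sector * 18.0)
        if sector % 2:
            assert "-endo" in name or "-exo" in name
            assert name.count("-") == 1  # envelope: single conformer name
        else:
            assert name.count("-") == 3  # twist: two conformer names joined


def test_pseudorotation_stable_under_small_nu_noise(rng):
    for p_true in range(0, 360, 45):
        nus = np.array(_cosine_nus(p_true))
        for _ in range(20):
            noisy = nus + rng.uniform(-0.5, 0.5, size=5)
            p, _ = pseudorotation(noisy)
            assert abs(wrap_half(p - p_true)) < 2.0


@pytest.mark.parametrize(
    "chi,expected",
    [(60.0, "syn"), (90.0, "syn"), (-90.0, "anti"), (180.0, "anti"),
     (-170.0, "anti"), (float("nan"), "undefined")],
)
def test_classify_glycosidic(chi, expected):
    assert classify_glycosidic(chi) == expected


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _transform_chain(chain, matrix, shift):
    import copy

    moved = copy.deepcopy(chain)
    for res in moved.residues:
        for atom in res.atoms.values():
            atom.position[:] = matrix @ atom.position + shift
    return moved


def test_rigid_motion_invariance_and_mirror_antisymmetry(rng):
    p = random_prescription(5, rng)
    chain = build_chain(p).chains[0]
    ref = chain_torsions(chain)
    rot = _random_rotation(rng)
    shift = rng.uniform(-30, 30, size=3)
    moved = chain_torsions(_transform_chain(chain, rot, shift))
    mirrored = chain_torsions(_transform_chain(chain, -np.eye(3), np.zeros(3)))
    for i in range(len(chain)):
        for kind in AngleKind:
            if kind is AngleKind.pseudorotation:
                continue
            a = ref[i].get(kind)
            if not np.isfinite(a):
                assert not moved[i].defined(kind)
                continue
            assert abs(wrap_half(moved[i].get(kind) - a)) < 1e-6
            assert abs(wrap_half(mirrored[i].get(kind) + a)) < 1e-6
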