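"""Tuning maps, environment-induced shifts and the gap report."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flavotune.constants import K_COULOMB_EV, kt_ev
from flavotune.estm import (
    StateDeltaCharges,
    TuningMap,
    estm_map,
    gap_report,
    gap_shift,
    read_delta_charges,
    shift_from_environment,
    write_delta_charges,
)
from flavotune.potential_field import ChargeSet, potential_at
from flavotune.structures_io import Atom, LabeledMolecule
from flavotune.surface import SurfaceCloud, generate_surface
from flavotune.synthetic import make_environment


def _single_atom_mol(r=1.7):
    a = Atom(serial=1, name="C", element="C", residue_name="LIG", residue_id=1,
             chain="A", position=np.zeros(3), charge=0.0, vdw_radius=r)
    return LabeledMolecule(atoms=[a])


def test_delta_charges_must_sum_to_zero():
    with pytest.raises(ValueError, match="sum to 0"):
        StateDeltaCharges(state="bad", delta_q=np.array([0.1, 0.0]))


def test_zero_delta_set_gives_zero_map(toy_flavin, cloud_k2):
    dq = StateDeltaCharges(state="null", delta_q=np.zeros(toy_flavin.n_atoms))
    m = estm_map(toy_flavin, dq, cloud=cloud_k2)
    np.testing.assert_array_equal(m.shifts, 0.0)


def test_single_pair_closed_form():
    """One atom with Δq = +0.1 e probed at 2×1.7 Å: k_C·0.1·0.1/3.4 eV."""
    mol = _single_atom_mol(r=1.7)
    # a one-atom "molecule" cannot have a zero-sum nontrivial set; bypass the
    # charge-conservation guard to isolate the Coulomb kernel
    dq = StateDeltaCharges.__new__(StateDeltaCharges)
    dq.state = "probe-kernel"
    dq.delta_q = np.array([0.1])
    m = estm_map(mol, dq, probe=0.1, scale=2.0, density=1.0)
    expected = K_COULOMB_EV * 0.1 * 0.1 / 3.4
    np.testing.assert_allclose(m.shifts, expected, rtol=1e-9)
    assert expected == pytest.approx(0.04235, abs=2e-5)


def test_probe_sign_flip_negates_shifts(toy_flavin, delta_s1, cloud_k2):
    plus = estm_map(toy_flavin, delta_s1, probe=0.1, cloud=cloud_k2)
    minus = estm_map(toy_flavin, delta_s1, probe=-0.1, cloud=cloud_k2)
    np.testing.assert_allclose(minus.shifts, -plus.shifts, atol=1e-9)


def test_linearity_in_probe_and_delta(toy_flavin, delta_s1, cloud_k2):
    base = estm_map(toy_flavin, delta_s1, probe=0.1, cloud=cloud_k2)
    double_probe = estm_map(toy_flavin, delta_s1, probe=0.2, cloud=cloud_k2)
    np.testing.assert_allclose(double_probe.shifts, 2 * base.shifts, atol=1e-9)
    scaled = StateDeltaCharges(state="x3", delta_q=3 * delta_s1.delta_q)
    triple_dq = estm_map(toy_flavin, scaled, probe=0.1, cloud=cloud_k2)
    np.testing.assert_allclose(triple_dq.shifts, 3 * base.shifts, atol=1e-9)


def test_probe_zero_and_length_mismatch_errors(toy_flavin, delta_s1):
    with pytest.raises(ValueError, match="nonzero"):
        estm_map(toy_flavin, delta_s1, probe=0.0)
    short = StateDeltaCharges(state="short", delta_q=np.zeros(3))
    with pytest.raises(ValueError, match="entries"):
        estm_map(toy_flavin, short)


def test_uniform_potential_shifts_nothing(toy_flavin, delta_s1):
    phi = np.full(toy_flavin.n_atoms, 3.7)
    assert shift_from_environment(toy_flavin, delta_s1, phi) == pytest.approx(0.0, abs=1e-12)


def test_single_site_shift_closed_form(toy_flavin):
    """φ = +1 kT/e at N5 only, Δq(N5) = −0.05 e → ΔE = −0.05·kT(eV)."""
    dq_vals = np.zeros(toy_flavin.n_atoms)
    n5 = toy_flavin.site_index("N5")
    dq_vals[n5] = -0.05
    dq_vals[(n5 + 1) % toy_flavin.n_atoms] = 0.05  # zero-sum compensation
    dq = StateDeltaCharges(state="t", delta_q=dq_vals)
    phi = np.zeros(toy_flavin.n_atoms)
    phi[n5] = 1.0
    de = shift_from_environment(toy_flavin, dq, phi)
    assert de == pytest.approx(-0.05 * kt_ev(298.15), rel=1e-12)
    assert de == pytest.approx(-0.001285, abs=2e-6)


def test_lov1_environment_red_shifts_singlet(toy_flavin, delta_s1):
    env = make_environment("LOV1_like", toy_flavin)
    phi = potential_at(toy_flavin.positions, env)
    assert shift_from_environment(toy_flavin, delta_s1, phi) < 0


def test_gap_shift_signs_and_antisymmetry(toy_flavin, delta_s1, delta_tn):
    zero = gap_shift(toy_flavin, delta_s1, delta_tn, np.zeros(toy_flavin.n_atoms))
    assert zero == 0.0
    pos = make_environment("LOV1_like", toy_flavin)
    neg = ChargeSet(pos.positions, -pos.charges)
    phi_pos = potential_at(toy_flavin.positions, pos)
    phi_neg = potential_at(toy_flavin.positions, neg)
    g_pos = gap_shift(toy_flavin, delta_s1, delta_tn, phi_pos)
    g_neg = gap_shift(toy_flavin, delta_s1, delta_tn, phi_neg)
    assert g_pos > 0 and g_neg < 0
    assert g_neg == pytest.approx(-g_pos, rel=1e-9)


def test_gap_shift_matches_brute_force_sum(toy_flavin, delta_s1, delta_tn):
    env = make_environment("LOV1_like", toy_flavin)
    phi = potential_at(toy_flavin.positions, env)
    brute = sum(
        p * (dt - ds) * kt_ev(298.15)
        for p, ds, dt in zip(phi, delta_s1.delta_q, delta_tn.delta_q)
    )
    assert gap_shift(toy_flavin, delta_s1, delta_tn, phi) == pytest.approx(brute, rel=1e-12)


def test_estm_epm_bilinear_consistency(toy_flavin, delta_s1, cloud_k2):
    """A single point charge q at surface point p: environment-shift route
    equals (q/probe)×map-shift route to 1e−9 — both are the same bilinear form."""
    m = estm_map(toy_flavin, delta_s1, probe=0.1, cloud=cloud_k2)
    for i, q in ((3, 0.37), (101, -0.8)):
        env = ChargeSet(cloud_k2.points[i][None, :], np.array([q]))
        phi = potential_at(toy_flavin.positions, env)
        lhs = shift_from_environment(toy_flavin, delta_s1, phi)
        rhs = (q / 0.1) * m.shifts[i]
        assert lhs == pytest.approx(rhs, abs=1e-9)


def _map_with(cloud, state, shifts):
    vals = np.zeros(cloud.n_points)
    vals[: len(shifts)] = shifts
    return TuningMap(cloud=cloud, state=state, shifts=vals, probe_charge=0.1)


def test_gap_report_printed_arithmetic(cloud_k2):
    """Extrema −0.031 / +0.040 eV combine to a 0.071 eV tuning capacity."""
    s1 = _map_with(cloud_k2, "S1_pipi", [-0.031, -0.01])
    tn = _map_with(cloud_k2, "Tn_npi", [0.040, 0.02])
    gr = gap_report(s1, tn)
    assert gr.combined_capacity == pytest.approx(0.071, abs=1e-12)
    assert not gr.degenerate


def test_gap_report_all_zero_is_degenerate(cloud_k2):
    gr = gap_report(
        _map_with(cloud_k2, "S1", [0.0]), _map_with(cloud_k2, "Tn", [0.0])
    )
    assert gr.combined_capacity == 0.0
    assert gr.degenerate


def test_gap_report_matches_exhaustive_scan(toy_flavin, delta_s1, delta_tn, cloud_k2):
    m1 = estm_map(toy_flavin, delta_s1, cloud=cloud_k2)
    mt = estm_map(toy_flavin, delta_tn, cloud=cloud_k2)
    gr = gap_report(m1, mt)
    red = min(float(s) for s in m1.shifts)  # independent python-loop scan
    blue = max(float(s) for s in mt.shifts)
    assert gr.max_redshift_S1 == pytest.approx(red, abs=1e-15)
    assert gr.max_blueshift_Tn == pytest.approx(blue, abs=1e-15)
    assert gr.combined_capacity == pytest.approx(abs(red) + blue, abs=1e-15)


def test_gap_report_mismatched_clouds_error(toy_flavin, delta_s1):
    c1 = generate_surface(toy_flavin, scale=2.0, density=0.5)
    c2 = generate_surface(toy_flavin, scale=1.5, density=0.5)
    m1 = estm_map(toy_flavin, delta_s1, cloud=c1)
    m2 = estm_map(toy_flavin, delta_s1, cloud=c2)
    with pytest.raises(ValueError, match="share"):
        gap_report(m1, m2)


def test_sign_structure_below_n5_c4_face(toy_flavin, delta_s1, delta_tn):
    """A +0.1e probe below the N5/C4 face red-shifts S1 and blue-shifts Tn."""
    n5 = toy_flavin.atoms[toy_flavin.site_index("N5")].position
    c4 = toy_flavin.atoms[toy_flavin.site_index("C4")].position
    below = ((n5 + c4) / 2 + np.array([0, 0, -3.4]))[None, :]
    mol = toy_flavin
    cloud = SurfaceCloud(points=below, parent=np.array([mol.site_index("N5")]),
                         scale=2.0, source=mol, density=1.0)
    s1 = estm_map(mol, delta_s1, probe=0.1, cloud=cloud)
    tn = estm_map(mol, delta_tn, probe=0.1, cloud=cloud)
    assert s1.shifts[0] < 0
    assert tn.shifts[0] > 0


def test_delta_charge_file_round_trip(tmp_path, toy_flavin, delta_s1):
    p = tmp_path / "dq.txt"
    write_delta_charges(delta_s1, toy_flavin, p)
    back = read_delta_charges(p, toy_flavin, state="S1_pipi")
    np.testing.assert_allclose(back.delta_q, delta_s1.delta_q, atol=1e-6)


@given(st.integers(0, 2**31 - 1))
def test_random_delta_sets_antisymmetric_under_probe_flip(seed):
    rng = np.random.default_rng(seed)
    from flavotune.synthetic import make_toy_flavin

    mol = make_toy_flavin()
    dq_vals = rng.uniform(-0.1, 0.1, mol.n_atoms)
    dq_vals -= dq_vals.mean()
    dq = StateDeltaCharges(state="rand", delta_q=dq_vals)
    cloud = generate_surface(mol, scale=2.0, density=0.3)
    plus = estm_map(mol, dq, probe=0.1, cloud=cloud)
    minus = estm_map(mol, dq, probe=-0.1, cloud=cloud)
    np.testing.assert_allclose(minus.shifts, -plus.shifts, atol=1e-9)
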