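"""Solver verification: patch tests, closed-form bars, return mapping."""

import numpy as np
import pytest

from femfall import MaterialLaw, MaterialState, block_mesh, patch_test, return_map, run_analysis


def _bar_bcs(mesh):
    """Uniaxial z-compression BCs on a block mesh: bottom/top z prescribed,
    lateral contraction free, rigid modes pinned."""
    nodes = mesh.nodes
    zmax = nodes[:, 2].max()
    bot = np.where(nodes[:, 2] < 1e-9)[0]
    top = np.where(nodes[:, 2] > zmax - 1e-9)[0]
    fixed = [3 * n + 2 for n in bot] + [3 * n + 2 for n in top]
    vals = [0.0] * len(bot) + [-1.0] * len(top)
    origin = bot[np.argmin(np.abs(nodes[bot, 0]) + np.abs(nodes[bot, 1]))]
    on_x = [n for n in bot if nodes[n, 0] > nodes[origin, 0] + 1e-9
            and abs(nodes[n, 1] - nodes[origin, 1]) < 1e-9][0]
    fixed += [3 * origin, 3 * origin + 1, 3 * on_x + 1]
    vals += [0.0, 0.0, 0.0]
    return np.array(fixed), np.array(vals), top


@pytest.mark.parametrize("grad", [
    np.array([[1e-4, 0, 0], [0, 0, 0], [0, 0, 0]]),          # uniaxial
    np.array([[0, 1e-4, 0], [0, 0, 0], [0, 0, 0]]),          # simple shear
    np.array([[0, 1e-4, 0], [-1e-4, 0, 0], [0, 0, 0]]),      # small rotation
])
def test_patch_test_affine_fields(law, grad):
    assert patch_test(law, grad=grad, tol=1e-10)


def test_elastic_bar_closed_form(law):
    mesh = block_mesh((1, 1, 1), element_size=3.0, bvtv=0.8)
    fixed, vals, top = _bar_bcs(mesh)
    E = law.stiffness_of(0.8) * 1000.0  # MPa
    L = A = None
    u_t = 0.003 * 3.0  # 0.3% strain: elastic
    h = run_analysis(mesh, law, u_t, n_increments=2, prescribed=(fixed, vals),
                     reaction_dofs=3 * np.asarray(top) + 2)
    F_expected = E * 9.0 * u_t / 3.0
    assert h.reaction[-1] == pytest.approx(F_expected, rel=1e-3)


def test_perfectly_plastic_plateau(law):
    law0 = MaterialLaw(damage_rate=0.0)
    mesh = block_mesh((1, 1, 1), element_size=3.0, bvtv=0.8)
    fixed, vals, top = _bar_bcs(mesh)
    h = run_analysis(mesh, law0, 3.0 * 0.02, n_increments=15, tol=1e-8,
                     prescribed=(fixed, vals),
                     reaction_dofs=3 * np.asarray(top) + 2)
    _, sc = law0.yield_stresses_of(0.8)
    assert h.converged
    assert h.reaction[-1] == pytest.approx(sc * 9.0, rel=1e-6)
    assert h.reaction[-2] == pytest.approx(sc * 9.0, rel=1e-6)


def test_damage_reduces_post_yield_force(law):
    mesh = block_mesh((1, 1, 1), element_size=3.0, bvtv=0.8)
    fixed, vals, top = _bar_bcs(mesh)
    args = dict(n_increments=15, prescribed=(fixed, vals),
                reaction_dofs=3 * np.asarray(top) + 2)
    h0 = run_analysis(mesh, MaterialLaw(damage_rate=0.0), 3.0 * 0.02, **args)
    hd = run_analysis(mesh, MaterialLaw(damage_rate=5.0), 3.0 * 0.02, **args)
    assert hd.reaction[-1] < h0.reaction[-1]
    assert hd.state.damage.max() > 0


# --- pointwise return mapping ---------------------------------------------

def test_return_map_elastic_branch(law):
    state = MaterialState.zeros(1)
    state.damage[:] = 0.25
    eps = np.zeros((1, 6))
    eps[0, 0] = 0.002  # below tensile yield strain
    nominal, new, info = return_map(eps, state, law, 0.8)
    C = law.elastic_matrix(law.stiffness_of(0.8))
    np.testing.assert_allclose(nominal[0], 0.75 * (C @ eps[0]), rtol=1e-12)
    assert new.kappa[0] == 0.0


def test_return_map_uniaxial_stress_plateaus(law):
    """Monotonic uniaxial-stress tension: the effective axial stress plateaus
    at the tensile yield stress (perfect plasticity on effective stress).
    Lateral strains are relaxed each step so the lateral stresses vanish."""
    from scipy.optimize import brentq
    law0 = MaterialLaw(damage_rate=0.0)
    bvtv = 0.6
    st_, _ = law0.yield_stresses_of(bvtv)
    state = MaterialState.zeros(1)
    axial = []
    for e in np.linspace(0, 0.03, 30)[1:]:
        committed = state

        def lateral_stress(el):
            eps = np.zeros((1, 6))
            eps[0, 0] = e
            eps[0, 1] = eps[0, 2] = el
            _, _, info = return_map(eps, committed, law0, bvtv)
            return info["eff"][0, 1]

        el = brentq(lateral_stress, -0.05, 0.02, xtol=1e-12)
        eps = np.zeros((1, 6))
        eps[0, 0] = e
        eps[0, 1] = eps[0, 2] = el
        _, state, info = return_map(eps, committed, law0, bvtv)
        axial.append(info["eff"][0, 0])
        assert abs(info["eff"][0, 1]) < 1e-6 and abs(info["eff"][0, 2]) < 1e-6
    assert axial[-1] == pytest.approx(st_, rel=1e-6)
    assert axial[-5] == pytest.approx(st_, rel=1e-6)
    assert state.kappa[0] > 0


def test_return_map_unloading_slope_is_damaged_elastic(law):
    bvtv = 0.6
    state = MaterialState.zeros(1)
    eps = np.zeros((1, 6))
    eps[0, 0] = 0.02
    _, state, _ = return_map(eps, state, law, bvtv)
    state.damage = np.asarray(law.damage_of(state.kappa))  # commit damage
    D = float(state.damage[0])
    assert D > 0
    s1, _, _ = return_map(eps, state, law, bvtv)
    eps2 = eps.copy()
    eps2[0, 0] -= 0.001  # partial unload: elastic
    s2, new2, _ = return_map(eps2, state, law, bvtv)
    assert new2.kappa[0] == state.kappa[0]
    C = law.elastic_matrix(law.stiffness_of(bvtv))
    expected = (1 - D) * (C @ (eps[0] - eps2[0]))
    np.testing.assert_allclose(s1[0] - s2[0], expected, rtol=1e-9)


def test_kappa_monotone_under_cyclic_strain(law):
    state = MaterialState.zeros(1)
    kappas = []
    for e in [0.0, 0.01, 0.005, 0.015, 0.002, 0.02]:
        eps = np.zeros((1, 6))
        eps[0, 0] = e
        _, state, _ = return_map(eps, state, law, 0.5)
        kappas.append(float(state.kappa[0]))
    assert all(b >= a - 1e-15 for a, b in zip(kappas, kappas[1:]))


# --- structural properties on the reduced phantom --------------------------

@pytest.fixture(scope="module")
def small_history(small_model, law):
    from femfall import criterion_displacement
    u_star = criterion_displacement(small_model)
    return run_analysis(small_model, law, u_star, n_increments=8), u_star


def test_equilibrium_balance(small_history):
    hist, _ = small_history
    assert hist.converged
    assert hist.balance_error < 0.005


def test_increment_refinement_changes_strength_little(small_model, law, small_history):
    from femfall import strength_from_history
    hist8, u_star = small_history
    hist16 = run_analysis(small_model, law, u_star, n_increments=16)
    s8 = strength_from_history(hist8, u_star)
    s16 = strength_from_history(hist16, u_star)
    assert abs(s8 - s16) / s16 < 0.02


def test_density_scaling_increases_strength(small_model, law, small_history):
    from femfall import strength_from_history
    hist, u_star = small_history
    mesh12 = small_model.scale_density(1.2).with_bvtv_from(law)
    hist12 = run_analysis(mesh12, law, u_star, n_increments=8)
    assert strength_from_history(hist12, u_star) > strength_from_history(hist, u_star)


def test_history_contract(small_history):
    hist, _ = small_history
    assert np.all(np.diff(hist.displacement) > 0)
    assert np.all(np.isfinite(hist.reaction))
    assert all(d["converged"] for d in hist.diagnostics if d["converged"])
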