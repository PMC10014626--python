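"""Displacement-driven quasi-static nonlinear FE solution.

Small-strain kinematics on the voxel hexahedral mesh: 2x2x2 Gauss-integrated
C3D8 bricks, elastic-perfectly-plastic bone with closest-point return mapping
onto the quadric yield surface, isotropic damage driven by cumulative plastic
strain, and a Newton-Raphson loop per displacement increment (relative
residual tolerance 1e-4) with sparse direct linear solves.

The driving node is tied vertically to the head-cap top surface; the recorded
reaction force is the sum of vertical internal forces over that surface,
which equals the reaction at the driving node of the rigid vertical coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg, splu

from .femodel import FEMesh
from .material import MaterialLaw, MaterialState

__all__ = ["SolutionHistory", "return_map", "run_analysis", "patch_test",
           "block_mesh"]

_GAUSS = np.array([[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1)
                   for sx in (-1, 1)]) / np.sqrt(3.0)
_CORNER_NAT = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]])
_KAPPA_W = np.array([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])  # engineering -> tensor norm


def _b_matrices(h: float) -> tuple[np.ndarray, float]:
    """B matrices (8 Gauss points, 6x24) and integration weight detJ*w for a
    cube element of edge h (trilinear shape functions)."""
    B = np.zeros((8, 6, 24))
    for g, xi in enumerate(_GAUSS):
        for a in range(8):
            na = _CORNER_NAT[a]
            dN = np.array([
                na[0] * (1 + xi[1] * na[1]) * (1 + xi[2] * na[2]),
                na[1] * (1 + xi[0] * na[0]) * (1 + xi[2] * na[2]),
                na[2] * (1 + xi[0] * na[0]) * (1 + xi[1] * na[1]),
            ]) / 8.0 * (2.0 / h)
            c = 3 * a
            B[g, 0, c + 0] = dN[0]
            B[g, 1, c + 1] = dN[1]
            B[g, 2, c + 2] = dN[2]
            B[g, 3, c + 0] = dN[1]
            B[g, 3, c + 1] = dN[0]
            B[g, 4, c + 0] = dN[2]
            B[g, 4, c + 2] = dN[0]
            B[g, 5, c + 1] = dN[2]
            B[g, 5, c + 2] = dN[1]
    return B, (h / 2.0) ** 3


@dataclass
class SolutionHistory:
    """Per-increment displacement/force record plus final material state."""

    displacement: np.ndarray          # mm, driving-node displacement magnitude
    reaction: np.ndarray              # N at the driving node
    state: MaterialState
    converged: bool
    diagnostics: list = field(default_factory=list)
    balance_error: float = 0.0        # relative vertical equilibrium error

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"displacement_mm": self.displacement,
                             "reaction_N": self.reaction})


# ---------------------------------------------------------------------------
# constitutive update

def _quadric_coeffs(law: MaterialLaw, bvtv: np.ndarray):
    """(A (n,6,6), chi (n,)) of the quadric criterion per point."""
    st, sc = law.yield_stresses_of(np.clip(bvtv, 1e-6, 1.0))
    st, sc = np.atleast_1d(st), np.atleast_1d(sc)
    q = 0.5 * (1.0 / st + 1.0 / sc)
    chi = 0.5 * (1.0 / st - 1.0 / sc)
    f_hyd = law.interaction * q * q
    f_dev = 1.5 * (q * q - f_hyd)  # so that (2/3) f_dev + f_hyd = q^2
    dg = np.diag([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    mm = np.zeros((6, 6))
    mm[:3, :3] = 1.0
    A = (f_dev[:, None, None] * (dg - mm / 3.0)[None]
         + f_hyd[:, None, None] * mm[None])
    return A, chi


def _grad_and_f(s, A, chi):
    As = np.einsum("nij,nj->ni", A, s)
    sq = np.sqrt(np.maximum(np.einsum("ni,ni->n", s, As), 1e-30))
    grad = As / sq[:, None]
    grad[:, :3] += chi[:, None]
    f = sq + chi * s[:, :3].sum(1) - 1.0
    return grad, f, As, sq


def _project_to_surface(s_tr, A, chi, C, tol=1e-10, max_newton=50):
    """Vectorised closest-point projection onto f = 0.

    Returns (effective stress, plastic multiplier, converged flags).
    """
    npts = len(s_tr)
    s = s_tr.copy()
    dl = np.zeros(npts)
    scale = np.maximum(np.linalg.norm(s_tr, axis=1), 1.0)
    active = np.ones(npts, bool)
    for _ in range(max_newton):
        grad, f, As, sq = _grad_and_f(s, A, chi)
        Cg = np.einsum("nij,nj->ni", C, grad)
        R1 = s - s_tr + dl[:, None] * Cg
        err = np.maximum(np.abs(R1).max(axis=1) / scale, np.abs(f))
        active = err > tol
        if not active.any():
            break
        ia = np.where(active)[0]
        H = (A[ia] / sq[ia, None, None]
             - np.einsum("ni,nj->nij", As[ia], As[ia]) / sq[ia, None, None] ** 3)
        J = np.zeros((len(ia), 7, 7))
        J[:, :6, :6] = np.eye(6)[None] + dl[ia, None, None] * np.einsum(
            "nij,njk->nik", C[ia], H)
        J[:, :6, 6] = Cg[ia]
        J[:, 6, :6] = grad[ia]
        R = np.concatenate([R1[ia], f[ia, None]], axis=1)
        try:
            delta = np.linalg.solve(J, R[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        s[ia] -= delta[:, :6]
        dl[ia] -= delta[:, 6]
        np.maximum(dl, 0.0, out=dl)
    return s, dl, ~active


def return_map(trial_strain, state: MaterialState, law: MaterialLaw, bvtv,
               f_tol: float = 1e-9, _depth: int = 0):
    """Stress update for an array of integration points.

    ``trial_strain``: (n, 6) total strain (engineering Voigt); ``state`` the
    committed history (not modified); ``bvtv``: scalar or (n,).

    Returns ``(nominal_stress, new_state, info)`` where ``info`` carries the
    effective stresses, elastic moduli and plastic data needed for the
    algorithmic tangent.
    """
    eps = np.atleast_2d(np.asarray(trial_strain, float))
    n = len(eps)
    v = np.broadcast_to(np.asarray(bvtv, float), (n,)).astype(float)
    new = state.copy()

    E = np.asarray(law.stiffness_of(np.clip(v, 0.0, 1.0)), float)
    floor = v < 0.01
    if floor.any():  # near-void elements keep a tiny elastic stiffness
        E = np.where(floor, 1e-4 * law.stiffness_of(0.01), E)
    C = law.elastic_matrix(E)

    s_tr = np.einsum("nij,nj->ni", C, eps - new.plastic_strain)
    eff = s_tr.copy()

    yieldable = ~floor
    plastic = np.zeros(n, bool)
    A = chi = None
    if yieldable.any():
        A, chi = _quadric_coeffs(law, v)
        _, f_trial, _, _ = _grad_and_f(s_tr, A, chi)
        plastic = yieldable & (f_trial > f_tol)

    dl_full = np.zeros(n)
    apex = np.zeros(n, bool)
    if plastic.any():
        idx = np.where(plastic)[0]
        s, dl, ok = _project_to_surface(s_tr[idx], A[idx], chi[idx], C[idx])
        if not ok.all():
            # apex return: near-hydrostatic tensile trial states have no
            # regular projection on the cone; return them to the vertex
            bad = np.where(~ok)[0]
            chib = chi[idx[bad]]
            if np.any(chib <= 1e-12):
                raise RuntimeError("return mapping failed away from the apex")
            s_apex = np.zeros((len(bad), 6))
            s_apex[:, :3] = (1.0 / (3.0 * chib))[:, None]
            s[bad] = s_apex
            dl[bad] = 0.0
            apex[idx[bad]] = True
            # plastic strain increment carries the full elastic correction
            dsig = s_tr[idx[bad]] - s_apex
            deps_apex = np.linalg.solve(C[idx[bad]], dsig[:, :, None])[:, :, 0]
            new.plastic_strain[idx[bad]] = (state.plastic_strain[idx[bad]]
                                            + deps_apex)
            new.kappa[idx[bad]] = state.kappa[idx[bad]] + np.sqrt(
                np.einsum("nj,j,nj->n", deps_apex, _KAPPA_W, deps_apex))
        good = ok
        gsel = idx[good]
        grad, _, _, _ = _grad_and_f(s[good], A[gsel], chi[gsel])
        deps_p = dl[good, None] * grad
        new.plastic_strain[gsel] = state.plastic_strain[gsel] + deps_p
        dkappa = np.sqrt(np.einsum("nj,j,nj->n", deps_p, _KAPPA_W, deps_p))
        new.kappa[gsel] = state.kappa[gsel] + dkappa
        eff[idx] = s
        dl_full[idx] = dl

    new.damage = np.asarray(law.damage_of(new.kappa))
    # staggered damage: within an increment the nominal stress uses the
    # committed damage; the updated damage takes effect once committed
    d_frozen = np.broadcast_to(np.asarray(state.damage, float), (n,))
    nominal = (1.0 - d_frozen)[:, None] * eff
    info = {"eff": eff, "E": E, "C": C, "plastic": plastic, "A": A, "chi": chi,
            "dl": dl_full, "damage_frozen": d_frozen, "apex": apex}
    return nominal, new, info


def _algorithmic_tangent(info, damage):
    """Per-point 6x6 tangent moduli: damaged elastic for elastic points,
    consistent elastoplastic (damage derivative neglected) for plastic ones."""
    C = info["C"]
    Cout = (1.0 - damage)[:, None, None] * C
    pl = info["plastic"]
    if pl is None or not pl.any():
        return Cout
    idx = np.where(pl)[0]
    s = info["eff"][idx]
    A, chi = info["A"][idx], info["chi"][idx]
    dl = info["dl"][idx]
    Cp = C[idx]
    _, _, As, sq = _grad_and_f(s, A, chi)
    grad = As / sq[:, None]
    grad[:, :3] += chi[:, None]
    H = (A / sq[:, None, None]
         - np.einsum("ni,nj->nij", As, As) / sq[:, None, None] ** 3)
    M = np.eye(6)[None] + dl[:, None, None] * np.einsum("nij,njk->nik", Cp, H)
    MC = np.linalg.solve(M, Cp)
    Mg = np.einsum("nij,nj->ni", MC, grad)
    denom = np.maximum(np.einsum("ni,ni->n", grad, Mg), 1e-30)
    Ct = MC - np.einsum("ni,nj->nij", Mg, Mg) / denom[:, None, None]
    Cout[idx] = (1.0 - damage[idx])[:, None, None] * Ct
    # apex points: the return maps every nearby trial state to the vertex, so
    # the consistent tangent is (nearly) zero; a tiny elastic fraction keeps
    # the global matrix definite
    ap = info.get("apex")
    if ap is not None and ap.any():
        Cout[ap] = 1e-3 * (1.0 - damage[ap])[:, None, None] * C[ap]
    return Cout


# ---------------------------------------------------------------------------
# assembled system

class _System:
    """Voxel-FE assembly with shared element geometry."""

    def __init__(self, mesh: FEMesh, law: MaterialLaw):
        self.mesh = mesh
        self.law = law
        self.B, self.w = _b_matrices(mesh.element_size)
        ne = mesh.n_elements
        self.conn_dofs = (3 * mesh.elements[:, :, None]
                          + np.arange(3)[None, None, :]).reshape(ne, 24)
        self.rows = np.repeat(self.conn_dofs, 24, axis=1).ravel()
        self.cols = np.tile(self.conn_dofs, (1, 24)).ravel()
        self.ndof = 3 * mesh.n_nodes
        self.bone_idx = np.where(mesh.is_bone)[0]
        self.gp_bvtv = np.repeat(mesh.bvtv[self.bone_idx], 8)
        self.C_emb = law.elastic_matrix(mesh.embedding_modulus_gpa)

    def n_gauss_points(self) -> int:
        return len(self.bone_idx) * 8

    def strains(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.conn_dofs]                       # (ne, 24)
        return np.einsum("gik,nk->ngi", self.B, ue)  # (ne, 8, 6)

    def internal_force(self, u, committed: MaterialState):
        mesh = self.mesh
        eps = self.strains(u)
        ne = mesh.n_elements
        stress = np.zeros((ne, 8, 6))
        emb = ~mesh.is_bone
        if emb.any():
            stress[emb] = np.einsum("ij,ngj->ngi", self.C_emb, eps[emb])
        bi = self.bone_idx
        nominal, trial_state, info = return_map(
            eps[bi].reshape(-1, 6), committed, self.law, self.gp_bvtv)
        stress[bi] = nominal.reshape(len(bi), 8, 6)
        fe = np.einsum("gik,ngi->nk", self.B, stress) * self.w
        f = np.bincount(self.conn_dofs.ravel(), weights=fe.ravel(),
                        minlength=self.ndof)
        return f, trial_state, info

    def tangent_matrix(self, trial_state: MaterialState, info):
        mesh = self.mesh
        ne = mesh.n_elements
        Cgp = np.zeros((ne, 8, 6, 6))
        emb = ~mesh.is_bone
        if emb.any():
            Cgp[emb] = self.C_emb
        Ct = _algorithmic_tangent(info, info["damage_frozen"])
        Cgp[self.bone_idx] = Ct.reshape(len(self.bone_idx), 8, 6, 6)
        Ke = np.einsum("gik,ngij,gjl->nkl", self.B, Cgp, self.B,
                       optimize=True) * self.w
        K = coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                       shape=(self.ndof, self.ndof)).tocsc()
        return K


def _sidefall_bcs(mesh: FEMesh):
    """(dof ids, values at unit driving displacement)."""
    fixed, vals = [], []
    for nid in mesh.node_sets["distal_fixed"]:
        for d in range(3):
            fixed.append(3 * nid + d)
            vals.append(0.0)
    for nid in mesh.node_sets["gt_cap_base"]:
        fixed.append(3 * nid + 2)
        vals.append(0.0)
    for nid in mesh.node_sets["head_cap_top"]:
        fixed.append(3 * nid + 2)
        vals.append(-1.0)
    dn = mesh.driving_node
    fixed += [3 * dn, 3 * dn + 1, 3 * dn + 2]
    vals += [0.0, 0.0, -1.0]
    fixed = np.asarray(fixed)
    vals = np.asarray(vals)
    uniq, pos = np.unique(fixed, return_index=True)
    return uniq, vals[pos]


def run_analysis(mesh: FEMesh, law: MaterialLaw, target_displacement: float,
                 n_increments: int = 20, tol: float = 1e-4,
                 max_newton_iter: int = 60, prescribed=None,
                 reaction_dofs=None) -> SolutionHistory:
    """Quasi-static displacement-driven analysis.

    Applies the side-fall boundary conditions (or a custom ``prescribed``
    pair of dof ids and unit-factor values) in equal increments, iterating
    Newton-Raphson with the algorithmic tangent until the residual on the
    free dofs falls below ``tol`` relative to the total constrained force.
    Returns the full force-displacement history; a diverged increment flags
    the run as failed with the partial history preserved.
    """
    if target_displacement <= 0:
        raise ValueError("target displacement must be positive")
    sys_ = _System(mesh, law)
    if prescribed is None:
        fixed_dofs, unit_vals = _sidefall_bcs(mesh)
    else:
        fixed_dofs = np.asarray(prescribed[0])
        unit_vals = np.asarray(prescribed[1])
    if reaction_dofs is None:
        reaction_dofs = 3 * np.asarray(mesh.node_sets["head_cap_top"]) + 2
    reaction_dofs = np.asarray(reaction_dofs)
    free = np.setdiff1d(np.arange(sys_.ndof), fixed_dofs)

    committed = MaterialState.zeros(sys_.n_gauss_points())
    u = np.zeros(sys_.ndof)
    disp_hist, force_hist = [0.0], [0.0]
    diags = []
    converged_all = True
    balance = 0.0
    f_int = np.zeros(sys_.ndof)

    # Newton directions are computed on the CURRENT consistent tangent via
    # preconditioned CG, with a (possibly stale) sparse factorisation as the
    # preconditioner: the factorisation dominates the cost at this problem
    # size, so it is refreshed only when CG stops converging quickly
    lu_cache = {"lu": None}

    def factorize(Kff):
        lu_cache["lu"] = splu(Kff, permc_spec="MMD_AT_PLUS_A",
                              diag_pivot_thresh=0.0,
                              options=dict(SymmetricMode=True))

    def refactorize(trial, info):
        Kff = sys_.tangent_matrix(trial, info)[np.ix_(free, free)].tocsc()
        factorize(Kff)

    # force scale for the relative residual: fixed within an increment and
    # carried over from the previously converged state, because the raw sum
    # of constrained forces swings by orders of magnitude between Newton
    # iterates and would destabilise both the convergence test and the line
    # search
    ref_cache = {"ref": None}

    def newton_solve(u_start, lam, require_balance=False):
        """Modified Newton with backtracking line search at fixed load factor.

        ``require_balance`` additionally drives the signed vertical residual
        sum to a fraction of the reaction (global force balance); it is used
        on the final increment, where the strength is read and the balance
        is reported.  Returns (ok, u, f_int, trial_state, iterations,
        residual)."""
        uu = u_start.copy()
        uu[fixed_dofs] = unit_vals * lam * target_displacement

        f_i, trial, info = sys_.internal_force(uu, committed)
        if ref_cache["ref"] is None:
            ref_cache["ref"] = max(float(np.abs(f_i[fixed_dofs]).sum()), 1.0)
        ref = ref_cache["ref"]

        def residual(f):
            r_max = float(np.abs(f[free]).max()) / ref
            if not require_balance:
                return r_max
            fz = float(f[free][free % 3 == 2].sum())
            react = max(abs(float(f[reaction_dofs].sum())), 1e-2 * ref)
            return max(r_max, 0.04 * abs(fz) / react)

        rel = residual(f_i)
        refactors = 0
        for it in range(max_newton_iter):
            if rel < tol:
                ref_cache["ref"] = max(float(np.abs(f_i[fixed_dofs]).sum()), 1.0)
                return True, uu, f_i, trial, it, rel
            if lu_cache["lu"] is None:
                refactorize(trial, info)
            du = lu_cache["lu"].solve(-f_i[free])
            # backtracking: accept the longest step that reduces the residual
            step = 1.0
            for _ in range(5):
                u_try = uu.copy()
                u_try[free] += step * du
                f_t, trial_t, info_t = sys_.internal_force(u_try, committed)
                rel_t = residual(f_t)
                if rel_t < rel or step <= 1.0 / 16:
                    break
                step *= 0.5
            uu, f_i, trial, info, rel = u_try, f_t, trial_t, info_t, rel_t
            # stalling with a stale operator: refresh the consistent tangent
            if rel >= tol and it >= 6 * (refactors + 1) and refactors < 4:
                refactorize(trial, info)
                refactors += 1
        return rel < tol, uu, f_i, trial, max_newton_iter, rel

    step0 = 1.0 / n_increments
    min_step = step0 / 8.0
    lam = 0.0
    step = step0
    inc = 0
    while lam < 1.0 - 1e-12:
        lam_try = min(lam + step, 1.0)
        ok, u_new, f_new, trial_state, its, rel = newton_solve(
            u, lam_try, require_balance=lam_try >= 1.0 - 1e-12)
        diags.append({"increment": inc + 1, "lambda": lam_try,
                      "iterations": its, "residual": rel, "converged": ok})
        inc += 1
        if not ok:
            if step / 2.0 >= min_step - 1e-15:
                step /= 2.0  # cutback and retry from the committed state
                continue
            converged_all = False
            break
        u, f_int = u_new, f_new
        committed = trial_state.copy()
        lam = lam_try
        disp_hist.append(lam * target_displacement)
        force_hist.append(float(-f_int[reaction_dofs].sum()))
        support = np.setdiff1d(fixed_dofs, reaction_dofs)
        z_support = support[support % 3 == 2]
        fz_r = float(f_int[reaction_dofs].sum())
        fz_s = float(f_int[z_support].sum())
        balance = abs(fz_r + fz_s) / max(abs(fz_r), 1e-9)
        if its <= 6 and step < step0:
            step = min(step * 2.0, step0)

    return SolutionHistory(displacement=np.asarray(disp_hist),
                           reaction=np.asarray(force_hist),
                           state=committed, converged=converged_all,
                           diagnostics=diags, balance_error=float(balance))


# ---------------------------------------------------------------------------
# verification helpers

def block_mesh(shape=(1, 1, 1), element_size: float = 3.0, bvtv: float = 0.5,
               bmd: float | None = None, law: MaterialLaw | None = None) -> FEMesh:
    """Rectangular all-bone block mesh for solver verification."""
    law = law or MaterialLaw()
    from .femodel import _CORNER
    nx, ny, nz = shape
    cells = np.argwhere(np.ones(shape, bool))
    corner_ids = cells[:, None, :] + _CORNER[None, :, :]
    flat = np.ravel_multi_index(corner_ids.reshape(-1, 3).T,
                                (nx + 1, ny + 1, nz + 1))
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 8)
    node_ijk = np.column_stack(np.unravel_index(uniq, (nx + 1, ny + 1, nz + 1)))
    nodes = node_ijk * float(element_size)
    ne = len(elements)
    bmd_val = bmd if bmd is not None else bvtv * law.rho_ref
    return FEMesh(nodes=nodes, elements=elements,
                  bvtv=np.full(ne, float(bvtv)), bmd=np.full(ne, float(bmd_val)),
                  is_bone=np.ones(ne, bool),
                  node_sets={"distal_fixed": np.array([], int),
                             "gt_cap_base": np.array([], int),
                             "head_cap_top": np.array([], int)},
                  driving_node=len(nodes) - 1, head_gt_distance=1.0,
                  element_size=float(element_size),
                  grid_origin=np.zeros(3), element_index=cells,
                  grid_shape=tuple(shape))


def patch_test(law: MaterialLaw | None = None, grad: np.ndarray | None = None,
               tol: float = 1e-10) -> bool:
    """Affine-displacement patch test on a 3x3x3 block.

    Prescribes u = G x on all boundary nodes, solves the interior, and checks
    that every Gauss point carries the uniform strain sym(G).
    """
    law = law or MaterialLaw()
    mesh = block_mesh((3, 3, 3), element_size=2.0, bvtv=0.5, law=law)
    if grad is None:
        grad = np.array([[1e-4, 0, 0], [0, 0, 0], [0, 0, 0]])
    G = np.asarray(grad, float)
    sys_ = _System(mesh, law)
    nodes = mesh.nodes
    lo, hi = nodes.min(axis=0), nodes.max(axis=0)
    on_bnd = np.any((np.abs(nodes - lo) < 1e-9) | (np.abs(nodes - hi) < 1e-9),
                    axis=1)
    bnd = np.where(on_bnd)[0]
    fixed = (3 * bnd[:, None] + np.arange(3)[None]).ravel()
    vals = (nodes[bnd] @ G.T).ravel()
    free = np.setdiff1d(np.arange(sys_.ndof), fixed)

    committed = MaterialState.zeros(sys_.n_gauss_points())
    u = np.zeros(sys_.ndof)
    u[fixed] = vals
    f_int, trial, info = sys_.internal_force(u, committed)
    K = sys_.tangent_matrix(trial, info)
    lu = splu(K[np.ix_(free, free)].tocsc())
    u[free] = lu.solve(-f_int[free])

    eps = sys_.strains(u)
    sym = 0.5 * (G + G.T)
    expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                         2 * sym[0, 1], 2 * sym[0, 2], 2 * sym[1, 2]])
    err = np.abs(eps - expected).max()
    return bool(err < max(tol, tol * np.abs(expected).max()))
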