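"""Finite-volume discretization and steady-state solution of the coupled
reaction-diffusion-transport system.

Each grid point is a finite-volume element; one discrete mass-balance
equation per point and species.  Steady states are found by implicit
pseudo-time stepping with a growing step: every step solves the nonlinear
balance by Picard iteration (reaction sources, carrier fluxes and recycling
exchanges are lagged to the previous iterate; diffusion, first-order losses
and carrier/boundary loss terms are implicit), and each resulting symmetric
positive-definite linear system is solved by the preconditioned
conjugate-gradient method.  Default tolerances are 1e-5 for the nonlinear
(Picard) iteration and 1e-10 for the linear solves; the results are
insensitive to further tightening (checked by the test suite).

The same right-hand side is exposed through an explicit time integrator
(:meth:`Simulator.integrate`), which serves as an independent cross-check
of the implicit path on small fixtures.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import network
from .geometry import RootMap, interfaces
from .params import KineticParameters
from .state import (
    CYTOSOLIC, GRID_SPECIES, HORMONES, MEMBRANE_SPECIES, SpeciesState,
)
from .transport import (
    FluxLedger, carrier_activity, pin_allowed_faces, shoot_boundary_fluxes,
)

# Species solved by a linear system each Picard sweep.  The inactive
# receptor pools (ra, re, ctr) are recovered from the conserved pair totals
# after their active forms are solved implicitly.
SOLVE_ORDER = (
    "auxin", "et", "ck",
    "ras", "res", "ctrs", "x",
    "plsm", "plsp", "pinm", "pinp_cyt", "aux1m", "aux1p_cyt",
)

RECEPTOR_PAIRS = {"ras": "ra", "res": "re", "ctrs": "ctr"}

# full update list for the explicit integrator (pairs handled explicitly)
EXPLICIT_ORDER = SOLVE_ORDER + ("ra", "re", "ctr")


@dataclass
class SolverSettings:
    nonlinear_tol: float = 1e-5
    linear_tol: float = 1e-10
    max_picard_iters: int = 80
    max_linear_iters: int = 500
    dt0: float = 5.0
    dt_growth: float = 1.5
    dt_max: float = 2000.0
    max_steps: int = 600
    steady_tol: float = 1e-9        # relative rate of change, 1/s
    preconditioner: str = "lu"      # "lu", "ilu" or "jacobi"
    hormone0: float = 0.1
    species0: float = 0.01
    conc_floor: float = 1e-6        # uM scale below which a pool counts as empty
    snap_tol: float = 1e-13         # concentrations below this snap to zero

    def __post_init__(self):
        if self.nonlinear_tol <= 0 or self.linear_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.preconditioner not in ("jacobi", "ilu", "lu"):
            raise ValueError(f"unknown preconditioner {self.preconditioner!r}")


@dataclass
class SteadyStateResult:
    state: SpeciesState
    ledger: FluxLedger
    converged: bool
    n_steps: int
    n_picard: int
    n_linear: int
    residuals: dict                 # species -> relative rate of change (1/s)
    elapsed: float
    settings: SolverSettings

    @property
    def max_residual(self) -> float:
        return max(self.residuals.values())


class ConvergenceError(RuntimeError):
    pass


class Simulator:
    """Assembles and solves the crosstalk system on one root map."""

    def __init__(self, rmap: RootMap, params: KineticParameters,
                 settings: SolverSettings | None = None):
        self.rmap = rmap
        self.params = params
        self.settings = settings or SolverSettings()
        self.faces = interfaces(rmap)
        self.h = rmap.spacing
        nr, nc = rmap.dims
        self.n = nr * nc

        self.cyt_flat = rmap.cytosol_mask.ravel()
        self.ck_synth_flat = self._ck_synth_mask().ravel()

        f = self.faces
        self.pin_faces = pin_allowed_faces(rmap, f)
        # per-cell bookkeeping for recycling
        self.cell_of_cyt = rmap.cell_id.ravel()[self.cyt_flat]
        self.n_cyt_per_cell = np.bincount(self.cell_of_cyt,
                                          minlength=rmap.n_cells)
        self.n_pinface_per_cell = np.bincount(
            f.mem_cell[self.pin_faces], minlength=rmap.n_cells)
        self.n_face_per_cell = np.bincount(f.mem_cell, minlength=rmap.n_cells)

        self._build_operators()
        self._boundary_indices()

    # ------------------------------------------------------------------
    # assembly
    # ------------------------------------------------------------------
    def _ck_synth_mask(self) -> np.ndarray:
        ok = np.isin(self.rmap.cell_type,
                     list(network.CK_SYNTHESIS_TYPES))
        sel = np.flatnonzero(ok)
        return np.isin(self.rmap.cell_id, sel) & self.rmap.cytosol_mask

    def _laplacian(self, a, b, w) -> sp.csr_matrix:
        """Stiffness matrix sum_f w (e_a - e_b)(e_a - e_b)^T, flat indices."""
        n = self.n
        if a.size == 0:
            return sp.csr_matrix((n, n))
        rows = np.concatenate([a, b, a, b])
        cols = np.concatenate([a, b, b, a])
        w = np.broadcast_to(w, a.shape).astype(float)
        vals = np.concatenate([w, w, -w, -w])
        return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))

    def _build_operators(self) -> None:
        p, h, f = self.params, self.h, self.faces
        inv_h2 = 1.0 / h ** 2
        L_cyt = self._laplacian(f.cyt_a, f.cyt_b, inv_h2)
        L_wall = self._laplacian(f.wall_a, f.wall_b, inv_h2)
        L_mem = self._laplacian(f.mem_cyt, f.mem_wall, 1.0 / h)

        D_cyto = {
            "plsm": p.D_mrna, "pinm": p.D_mrna, "aux1m": p.D_mrna,
            "plsp": p.D_protein, "pinp_cyt": p.D_protein,
            "aux1p_cyt": p.D_protein,
            "ra": p.D_receptor, "ras": p.D_receptor,
            "re": p.D_receptor, "res": p.D_receptor,
            "ctr": p.D_receptor, "ctrs": p.D_receptor,
            "x": p.D_x,
        }
        ops = {
            "auxin": p.D_auxin * L_cyt + p.D_auxin_wall * L_wall
                     + p.P_auxin_passive * L_mem,
            "et": p.D_et * L_cyt + p.D_et_wall * L_wall + p.P_et_mem * L_mem,
            "ck": p.D_ck * L_cyt + p.D_ck_wall * L_wall + p.P_ck_mem * L_mem,
        }
        for name, D in D_cyto.items():
            ops[name] = D * L_cyt
        self.ops = {}
        for name, L in ops.items():
            L = sp.csr_matrix(L)
            L.sort_indices()
            self.ops[name] = L

    def _boundary_indices(self) -> None:
        rmap = self.rmap
        nc = rmap.dims[1]
        top = rmap.shoot_row
        self.bnd_influx = top * nc + rmap.shoot_influx_cols
        self.bnd_efflux = top * nc + rmap.shoot_efflux_cols
        self.bnd_gas = top * nc + rmap.shoot_gas_cols
        # shootward membrane faces whose wall point is a shoot efflux point
        f = self.faces
        self._efflux_face_of_point = np.full(self.bnd_efflux.size, -1)
        wall_to_face = {int(w): i for i, w in enumerate(f.mem_wall)
                        if f.mem_orientation[i] == 1}
        for j, wpt in enumerate(self.bnd_efflux):
            self._efflux_face_of_point[j] = wall_to_face.get(int(wpt), -1)

    # ------------------------------------------------------------------
    # couplings evaluated at a Picard iterate
    # ------------------------------------------------------------------
    def _couplings(self, c: dict, mem: dict) -> dict:
        p, h, f = self.params, self.h, self.faces
        alpha = (p.P_aux1 / h) * carrier_activity(
            mem["aux1p_mem"], p.aux1_mem_ref, p.carrier_cap)
        beta = np.where(
            self.pin_faces,
            (p.P_pin / h) * carrier_activity(
                mem["pinp_mem"], p.pin_mem_ref, p.carrier_cap),
            0.0,
        )
        a_wall_face = c["auxin"][f.mem_wall]
        k_endo_pin = p.k_pin_endo / (1.0 + a_wall_face / p.K_endo_aux)
        x_near = c["x"][self.bnd_influx - self.rmap.dims[1]]
        influx = (p.k_influx_shoot / h) / (1.0 + x_near / p.K_x_influx)
        pin_scale = np.ones(self.bnd_efflux.size)
        ok = self._efflux_face_of_point >= 0
        pin_scale[ok] = carrier_activity(
            mem["pinp_mem"][self._efflux_face_of_point[ok]],
            p.pin_mem_ref, p.carrier_cap)
        return {
            "alpha": alpha, "beta": beta, "k_endo_pin": k_endo_pin,
            "influx": influx,
            "efflux_coef": (p.k_efflux_shoot / h) * pin_scale,
        }

    # ------------------------------------------------------------------
    # one implicit pseudo-time step
    # ------------------------------------------------------------------
    def assemble_species_system(self, name: str, c: dict, mem: dict,
                                cpl: dict, prod: dict, loss: dict,
                                c_old: dict, dt: float, totals: dict):
        """(A, b) of the discrete mass balance of one species at one Picard
        iterate: (1/dt + loss) c + L c + carrier terms = c_old/dt + production.

        Diffusion, first-order losses, receptor inter-conversion, carrier
        crossing and boundary losses are implicit; reaction sources, carrier
        abundances and recycling returns are lagged to the iterate.  All
        systems are symmetric positive definite except auxin, whose
        carrier-crossing terms are one-directional.
        """
        p, h, f = self.params, self.h, self.faces
        L = self.ops[name]
        diag_extra = np.full(self.n, 1.0 / dt)
        rhs = c_old[name] / dt
        cyt = self.cyt_flat

        if name in RECEPTOR_PAIRS:
            # active form with the inactive pool substituted from the total
            T = totals[RECEPTOR_PAIRS[name]]
            if name == "ras":
                act = p.k_ra_on * c["auxin"]
                deact = p.k_ra_off
            elif name == "res":
                act = p.k_re_off + p.k_re_pls * c["plsp"]
                deact = p.k_re_et * c["et"]
            else:
                act = p.k_ctr_on * c["res"]
                deact = p.k_ctr_off
            rhs = rhs + np.where(cyt, act * T, 0.0)
            diag_extra = diag_extra + np.where(cyt, act + deact, 0.0)
        elif name in prod:
            pr = np.asarray(prod[name], float)
            rhs = rhs + np.where(cyt, pr, 0.0)
            lo = np.broadcast_to(np.asarray(loss[name], float), (self.n,))
            diag_extra = diag_extra + np.where(cyt, lo, 0.0)

        extra = None
        if name == "auxin":
            rhs = rhs.copy()
            rhs[self.bnd_influx] += cpl["influx"]
            diag_extra[self.bnd_efflux] += cpl["efflux_coef"]
            extra = self._carrier_matrix(cpl)
        elif name == "et":
            rhs = rhs.copy()
            diag_extra[self.bnd_gas] += p.P_et_shoot / h
            rhs[self.bnd_gas] += (p.P_et_shoot / h) * p.et_shoot
        elif name == "ck":
            rhs = rhs.copy()
            diag_extra[self.bnd_gas] += p.P_ck_shoot / h
            rhs[self.bnd_gas] += (p.P_ck_shoot / h) * p.ck_shoot
        elif name == "pinp_cyt":
            rhs = rhs + self._endo_return(mem["pinp_mem"], cpl["k_endo_pin"],
                                          self.n_pinface_per_cell,
                                          pin=True)
            diag_extra = diag_extra + np.where(
                self._exo_enabled(self.n_pinface_per_cell),
                p.k_pin_exo, 0.0)
        elif name == "aux1p_cyt":
            rhs = rhs + self._endo_return(
                mem["aux1p_mem"],
                np.full(f.n_membrane, p.k_aux1_endo),
                self.n_face_per_cell, pin=False)
            diag_extra = diag_extra + np.where(
                self._exo_enabled(self.n_face_per_cell),
                p.k_aux1_exo, 0.0)

        A = (L + sp.diags(diag_extra)).tocsr()
        if extra is not None:
            A = (A + extra).tocsr()
        return A, rhs

    def _carrier_matrix(self, cpl) -> sp.csr_matrix:
        """Implicit carrier-crossing operator for auxin: AUX1 influx removes
        alpha*c_wall from the wall and adds it to the cytosol; PIN efflux
        removes beta*c_cyt from the cytosol and adds it to the wall."""
        f = self.faces
        a, b = cpl["alpha"], cpl["beta"]
        rows = np.concatenate([f.mem_wall, f.mem_cyt, f.mem_cyt, f.mem_wall])
        cols = np.concatenate([f.mem_wall, f.mem_wall, f.mem_cyt, f.mem_cyt])
        vals = np.concatenate([a, -a, b, -b])
        return sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n)))

    def _exo_enabled(self, n_faces_per_cell) -> np.ndarray:
        """Cytosol-point mask where exocytosis has somewhere to go."""
        out = np.zeros(self.n, dtype=bool)
        cells_ok = n_faces_per_cell > 0
        cyt_idx = np.flatnonzero(self.cyt_flat)
        out[cyt_idx] = cells_ok[self.cell_of_cyt]
        return out

    def _endo_return(self, mem_pool, k_endo, n_faces_per_cell, pin) -> np.ndarray:
        """Endocytosed protein returned uniformly to each cell's cytosol."""
        f = self.faces
        sel = self.pin_faces if pin else slice(None)
        per_cell = np.bincount(
            f.mem_cell[sel],
            weights=(k_endo * mem_pool)[sel],
            minlength=self.rmap.n_cells)
        share = np.zeros(self.rmap.n_cells)
        ok = self.n_cyt_per_cell > 0
        share[ok] = per_cell[ok] / self.n_cyt_per_cell[ok]
        out = np.zeros(self.n)
        cyt_idx = np.flatnonzero(self.cyt_flat)
        out[cyt_idx] = share[self.cell_of_cyt]
        return out

    def _exo_share(self, c_pool, k_exo, n_faces_per_cell, pin) -> np.ndarray:
        """Exocytosed protein delivered uniformly to each cell's faces."""
        f = self.faces
        cyt_idx = np.flatnonzero(self.cyt_flat)
        per_cell = np.bincount(self.cell_of_cyt,
                               weights=k_exo * c_pool[cyt_idx],
                               minlength=self.rmap.n_cells)
        share = np.zeros(self.rmap.n_cells)
        ok = n_faces_per_cell > 0
        share[ok] = per_cell[ok] / n_faces_per_cell[ok]
        out = share[f.mem_cell]
        if pin:
            out = np.where(self.pin_faces, out, 0.0)
        return out

    def _make_preconditioner(self, A) -> spla.LinearOperator:
        kind = self.settings.preconditioner
        if kind == "jacobi":
            d = A.diagonal()
            return spla.LinearOperator(A.shape, matvec=lambda v: v / d)
        if kind == "ilu":
            fac = spla.spilu(sp.csc_matrix(A), drop_tol=1e-6, fill_factor=15)
        else:
            fac = spla.splu(sp.csc_matrix(A))
        return spla.LinearOperator(A.shape, matvec=fac.solve)

    def _solve_linear(self, A, b, x0, counters, symmetric=True,
                      M=None) -> np.ndarray:
        """Krylov solve to the configured linear tolerance.

        With the Jacobi preconditioner this is plain PCG on the symmetric
        systems (BiCGStab for auxin, whose carrier terms are one-sided).
        With a factorization preconditioner - which is built once per
        pseudo-time step and reused over Picard sweeps, so it is incomplete
        with respect to the current matrix - BiCGStab is used throughout,
        since the lagged preconditioner is not symmetric in the
        CG-required sense.
        """
        st = self.settings
        if M is None:
            M = self._make_preconditioner(A)
        it = [0]

        def cb(_):
            it[0] += 1

        nb = np.linalg.norm(b)
        if nb == 0.0:
            return np.zeros_like(b)
        if np.linalg.norm(b - A @ x0) <= st.linear_tol * nb:
            return x0.copy()   # warm start already solves the system
        use_cg = symmetric and st.preconditioner == "jacobi"
        solver = spla.cg if use_cg else spla.bicgstab
        x, info = solver(A, b, x0=x0, rtol=st.linear_tol, atol=0.0,
                         maxiter=st.max_linear_iters, M=M, callback=cb)
        counters["linear"] += it[0]
        if info != 0:
            if np.linalg.norm(b - A @ x) <= 10 * st.linear_tol * nb:
                return x       # Krylov breakdown after reaching the tolerance
            raise ConvergenceError(f"linear solve failed (info={info})")
        return x

    def step(self, c: dict, mem: dict, dt: float, counters: dict):
        """One implicit pseudo-time step with Picard iteration.  Returns the
        new (c, mem) dictionaries."""
        st = self.settings
        p, f = self.params, self.faces
        c_old = {k: v for k, v in c.items()}
        mem_old = {k: v.copy() for k, v in mem.items()}
        c_it = {k: v.copy() for k, v in c.items()}
        mem_it = {k: v.copy() for k, v in mem.items()}

        # conserved receptor-pair totals obey pure intracellular diffusion,
        # independent of every other species: solve once per step
        totals = {}
        for act, inact in RECEPTOR_PAIRS.items():
            T_old = c_old[act] + c_old[inact]
            A = (self.ops[act] + sp.diags(np.full(self.n, 1.0 / dt))).tocsr()
            totals[inact] = self._solve_linear(A, T_old / dt, T_old, counters)

        precs: dict = {}
        for sweep in range(st.max_picard_iters):
            cpl = self._couplings(c_it, mem_it)
            prod, loss = network.production_and_loss(
                c_it, p, self.ck_synth_flat)
            c_new = dict(c_it)
            for name in SOLVE_ORDER:
                A, b = self.assemble_species_system(
                    name, c_new, mem_it, cpl, prod, loss, c_old, dt, totals)
                if name not in precs:
                    # the matrix changes only mildly between sweeps (lagged
                    # coefficients); one preconditioner per step suffices
                    precs[name] = self._make_preconditioner(A)
                c_new[name] = np.maximum(
                    self._solve_linear(A, b, c_it[name], counters,
                                       symmetric=(name != "auxin"),
                                       M=precs[name]), 0.0)
                if name in RECEPTOR_PAIRS:
                    pair = RECEPTOR_PAIRS[name]
                    c_new[pair] = np.maximum(totals[pair] - c_new[name], 0.0)
            mem_new = {}
            exo_pin = self._exo_share(c_new["pinp_cyt"], p.k_pin_exo,
                                      self.n_pinface_per_cell, pin=True)
            denom = 1.0 / dt + p.d_pinp + cpl["k_endo_pin"]
            mem_new["pinp_mem"] = np.maximum(
                (mem_old["pinp_mem"] / dt + exo_pin) / denom, 0.0)
            exo_aux1 = self._exo_share(c_new["aux1p_cyt"], p.k_aux1_exo,
                                       self.n_face_per_cell, pin=False)
            denom = 1.0 / dt + p.d_aux1p + p.k_aux1_endo
            mem_new["aux1p_mem"] = np.maximum(
                (mem_old["aux1p_mem"] / dt + exo_aux1) / denom, 0.0)

            rel = _max_rel_change(c_it, c_new, mem_it, mem_new,
                                  floor=st.conc_floor)
            c_it, mem_it = c_new, mem_new
            counters["picard"] += 1
            if rel < st.nonlinear_tol:
                break
        else:
            raise ConvergenceError(
                f"Picard iteration did not reach {st.nonlinear_tol} "
                f"in {st.max_picard_iters} sweeps (last update {rel:.2e})")
        snap = st.snap_tol
        for k, v in c_it.items():
            v[v < snap] = 0.0
        for k, v in mem_it.items():
            v[v < snap] = 0.0
        return c_it, mem_it

    # ------------------------------------------------------------------
    # public drivers
    # ------------------------------------------------------------------
    def initial_state(self) -> SpeciesState:
        return SpeciesState.initial(
            self.rmap, self.params, faces=self.faces,
            hormone0=self.settings.hormone0, species0=self.settings.species0)

    def steady_state(self, init: SpeciesState | None = None) -> SteadyStateResult:
        """March the implicit scheme to stationarity with a growing step."""
        st = self.settings
        t0 = time.perf_counter()
        state = (init or self.initial_state()).copy()
        c = {k: state.grid[k].ravel().astype(float) for k in GRID_SPECIES}
        mem = {k: state.mem[k].astype(float) for k in MEMBRANE_SPECIES}

        counters = {"picard": 0, "linear": 0}
        dt = st.dt0
        converged = False
        residuals = {}
        n_steps = 0
        for n_steps in range(1, st.max_steps + 1):
            c_prev = {k: v.copy() for k, v in c.items()}
            mem_prev = {k: v.copy() for k, v in mem.items()}
            try:
                c, mem = self.step(c, mem, dt, counters)
            except ConvergenceError:
                if dt <= st.dt0 * 1.0001:
                    raise
                dt = max(st.dt0, dt / 4.0)  # retry from the previous state
                c, mem = c_prev, mem_prev
                continue
            residuals = _rates_of_change(c_prev, c, mem_prev, mem, dt,
                                         floor=st.conc_floor)
            if max(residuals.values()) < st.steady_tol:
                converged = True
                break
            dt = min(dt * st.dt_growth, st.dt_max)

        for k in GRID_SPECIES:
            state.grid[k] = c[k].reshape(self.rmap.dims)
        for k in MEMBRANE_SPECIES:
            state.mem[k] = mem[k]
        ledger = shoot_boundary_fluxes(state, self.params, self.rmap,
                                       self.faces, self.pin_faces)
        return SteadyStateResult(
            state=state, ledger=ledger, converged=converged,
            n_steps=n_steps, n_picard=counters["picard"],
            n_linear=counters["linear"], residuals=residuals,
            elapsed=time.perf_counter() - t0, settings=st,
        )

    # ------------------------------------------------------------------
    # explicit right-hand side and integrator (verification path)
    # ------------------------------------------------------------------
    def rates(self, c: dict, mem: dict) -> tuple:
        """Explicit dc/dt of every pool at a state (flat arrays)."""
        p, h, f = self.params, self.h, self.faces
        cpl = self._couplings(c, mem)
        prod, loss = network.production_and_loss(c, p, self.ck_synth_flat)
        dc = {}
        for name in EXPLICIT_ORDER:
            rate = -self.ops[name].dot(c[name])
            pr = np.where(self.cyt_flat, np.asarray(prod[name], float), 0.0)
            lo = np.where(self.cyt_flat,
                          np.broadcast_to(np.asarray(loss[name], float),
                                          (self.n,)), 0.0)
            rate += pr - lo * c[name]
            dc[name] = rate
        # auxin carriers and boundary
        a = c["auxin"]
        take_in = cpl["alpha"] * a[f.mem_wall]
        push_out = cpl["beta"] * a[f.mem_cyt]
        np.add.at(dc["auxin"], f.mem_cyt, take_in - push_out)
        np.add.at(dc["auxin"], f.mem_wall, push_out - take_in)
        dc["auxin"][self.bnd_influx] += cpl["influx"]
        dc["auxin"][self.bnd_efflux] -= cpl["efflux_coef"] * a[self.bnd_efflux]
        dc["et"][self.bnd_gas] += (p.P_et_shoot / h) * (p.et_shoot - c["et"][self.bnd_gas])
        dc["ck"][self.bnd_gas] += (p.P_ck_shoot / h) * (p.ck_shoot - c["ck"][self.bnd_gas])
        # recycling
        endo_pin = cpl["k_endo_pin"] * mem["pinp_mem"]
        dc["pinp_cyt"] += self._endo_return(mem["pinp_mem"], cpl["k_endo_pin"],
                                            self.n_pinface_per_cell, pin=True)
        dc["pinp_cyt"] -= np.where(self._exo_enabled(self.n_pinface_per_cell),
                                   p.k_pin_exo, 0.0) * c["pinp_cyt"]
        dmem = {}
        exo_pin = self._exo_share(c["pinp_cyt"], p.k_pin_exo,
                                  self.n_pinface_per_cell, pin=True)
        dmem["pinp_mem"] = exo_pin - endo_pin - p.d_pinp * mem["pinp_mem"]
        dc["aux1p_cyt"] += self._endo_return(
            mem["aux1p_mem"], np.full(f.n_membrane, p.k_aux1_endo),
            self.n_face_per_cell, pin=False)
        dc["aux1p_cyt"] -= np.where(self._exo_enabled(self.n_face_per_cell),
                                    p.k_aux1_exo, 0.0) * c["aux1p_cyt"]
        exo_aux1 = self._exo_share(c["aux1p_cyt"], p.k_aux1_exo,
                                   self.n_face_per_cell, pin=False)
        dmem["aux1p_mem"] = (exo_aux1 - p.k_aux1_endo * mem["aux1p_mem"]
                             - p.d_aux1p * mem["aux1p_mem"])
        return dc, dmem

    def integrate(self, state: SpeciesState, t_end: float, dt: float,
                  record_every: int = 0):
        """Explicit (forward-Euler) time integration.  ``t_end=0`` returns
        the state unchanged.  Returns (final state, trajectory) where the
        trajectory is a list of (t, SpeciesState) if ``record_every`` > 0.
        """
        if t_end < 0:
            raise ValueError("t_end must be nonnegative")
        state = state.copy()
        if t_end == 0:
            return state, []
        c = {k: state.grid[k].ravel().astype(float) for k in GRID_SPECIES}
        mem = {k: state.mem[k].astype(float) for k in MEMBRANE_SPECIES}
        n_steps = int(np.ceil(t_end / dt))
        dt = t_end / n_steps
        traj = []
        for i in range(n_steps):
            dc, dmem = self.rates(c, mem)
            for k in EXPLICIT_ORDER:
                c[k] = np.maximum(c[k] + dt * dc[k], 0.0)
            for k in MEMBRANE_SPECIES:
                mem[k] = np.maximum(mem[k] + dt * dmem[k], 0.0)
            bad = [k for k in EXPLICIT_ORDER if not np.all(np.isfinite(c[k]))]
            if bad:
                raise ConvergenceError(
                    f"explicit step diverged for {bad}; reduce dt")
            if record_every and (i + 1) % record_every == 0:
                snap = state.copy()
                for k in GRID_SPECIES:
                    snap.grid[k] = c[k].reshape(self.rmap.dims)
                for k in MEMBRANE_SPECIES:
                    snap.mem[k] = mem[k].copy()
                traj.append(((i + 1) * dt, snap))
        for k in GRID_SPECIES:
            state.grid[k] = c[k].reshape(self.rmap.dims)
        for k in MEMBRANE_SPECIES:
            state.mem[k] = mem[k]
        return state, traj




def _max_rel_change(c_a, c_b, mem_a, mem_b, floor=1e-6) -> float:
    rel = 0.0
    for k in c_a:
        scale = max(np.max(np.abs(c_b[k])), floor)
        rel = max(rel, np.max(np.abs(c_b[k] - c_a[k])) / scale)
    for k in mem_a:
        if mem_a[k].size:
            scale = max(np.max(np.abs(mem_b[k])), floor)
            rel = max(rel, np.max(np.abs(mem_b[k] - mem_a[k])) / scale)
    return rel


def _rates_of_change(c_a, c_b, mem_a, mem_b, dt, floor=1e-6) -> dict:
    out = {}
    for k in c_a:
        scale = max(np.max(np.abs(c_b[k])), floor)
        out[k] = float(np.max(np.abs(c_b[k] - c_a[k])) / (dt * scale))
    for k in mem_a:
        if mem_a[k].size:
            scale = max(np.max(np.abs(mem_b[k])), floor)
            out[k] = float(np.max(np.abs(mem_b[k] - mem_a[k])) / (dt * scale))
    return out
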