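"""Coupled capillary blood flow and interstitial fluid flow.

Blood flow in the discrete capillary graph is Poiseuille flow with a
transmural Starling leak; the interstitium is a Darcy porous medium whose
pressure obeys

    −κ∇²P_i = ϕ_B − ϕ_L
    ϕ_B = L_p (S/V) (P_B − P_i − σ_s(π_B − π_i))
    ϕ_L = L_pL (S/V)_L (P_i − P_L)        (healthy tissue only)

on a conservative finite-volume grid with harmonic-mean conductivities at
tissue interfaces and a Dirichlet far-field pressure on the outer boundary.
The two problems exchange the vascular pressure field P_B and the local
interstitial pressure seen by each vessel segment, iterated to a fixed
point with under-relaxation.

Tumor tissue has no functional lymphatics (its lymphatic filtration
coefficient is zero), which together with its higher wall conductivity
produces the characteristic elevated interstitial fluid pressure plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SimulationGrid, TissueMap, VascularNetwork, \
    rasterize_network, traverse_cells
from .params import MMHG_PA, NORMAL, TUMOR, ParameterSet

ALL_SIDES = ("left", "right", "bottom", "top")


def _tissue_field(tissue: TissueMap, normal_value: float,
                  tumor_value: float) -> np.ndarray:
    out = np.full(tissue.tumor_mask.shape, normal_value, dtype=float)
    out[tissue.tumor_mask] = tumor_value
    return out


def tissue_coefficient(tissue: TissueMap, params: ParameterSet,
                       name: str) -> np.ndarray:
    """Per-cell field of a tissue parameter (e.g. ``kappa``, ``L_p``)."""
    return _tissue_field(tissue,
                         getattr(params.tissue[NORMAL], name),
                         getattr(params.tissue[TUMOR], name))


def osmotic_offset(tissue: TissueMap, params: ParameterSet) -> np.ndarray:
    """σ_s(π_B − π_i) per cell, Pa."""
    vals = {}
    for t in (NORMAL, TUMOR):
        p = params.tissue[t]
        vals[t] = p.sigma_s * (p.pi_B - p.pi_i)
    return _tissue_field(tissue, vals[NORMAL], vals[TUMOR])


# --------------------------------------------------------------------------
# Network flow
# --------------------------------------------------------------------------

class NetworkFlowModel:
    """Linear Poiseuille network with distributed Starling leak.

    Interior node balance: Σ_j g_ij (p_i − p_j) = −Σ_seg leak share, where a
    segment's leak L_p·2πr·l·(p̄_seg − P_i,local − σ_s(π_B−π_i)) (p̄ the mean
    of its end pressures) is split half to each end node.  Boundary nodes
    hold prescribed pressures.  The matrix is constant; only the local
    interstitial pressure enters the right-hand side, so repeated solves
    during coupling reuse one LU factorization.
    """

    def __init__(self, network: VascularNetwork, params: ParameterSet,
                 grid: SimulationGrid | None = None,
                 tissue: TissueMap | None = None, leak: bool = True):
        network.validate(grid)
        self.network = network
        self.params = params
        self.grid = grid
        self.leak = leak
        n = network.n_nodes
        mu = params.vessel.mu_blood
        lengths = network.segment_lengths()
        radii = np.array([r for _, _, r in network.segments])
        self.conductance = np.pi * radii**4 / (8.0 * mu * lengths)

        # per-segment tissue properties at the segment midpoint
        if grid is not None and tissue is not None:
            mids = np.array([(network.positions[a] + network.positions[b]) / 2
                             for a, b, _ in network.segments])
            ii = np.clip(((mids[:, 0] - grid.origin[0]) / grid.dx).astype(int),
                         0, grid.nx - 1)
            jj = np.clip(((mids[:, 1] - grid.origin[1]) / grid.dy).astype(int),
                         0, grid.ny - 1)
            in_tumor = tissue.tumor_mask[jj, ii]
        else:
            in_tumor = np.zeros(len(network.segments), dtype=bool)
        tis = [params.tissue[TUMOR if t else NORMAL] for t in in_tumor]
        self.seg_Lw = np.array(
            [p.L_p * 2.0 * np.pi * r * l
             for p, (_, _, r), l in zip(tis, network.segments, lengths)]
        ) if leak else np.zeros(len(lengths))
        self.seg_osmotic = np.array(
            [p.sigma_s * (p.pi_B - p.pi_i) for p in tis])

        if grid is not None:
            self.traversals = [traverse_cells(grid, network.positions[a],
                                              network.positions[b])
                               for a, b, _ in network.segments]
        else:
            self.traversals = None

        rows, cols, vals = [], [], []
        bset = set(network.boundary_pressures)
        for k, (a, b, _) in enumerate(network.segments):
            g = self.conductance[k]
            Lw = self.seg_Lw[k]
            for i, j in ((a, b), (b, a)):
                if i in bset:
                    continue
                rows += [i, i]
                cols += [i, j]
                vals += [g + Lw / 4.0, -g + Lw / 4.0]
        for i in bset:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
        # isolated interior nodes would make the system singular; the
        # validate() call above guarantees each component is anchored
        M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        self._lu = spla.splu(M)
        self._bset = bset

    def segment_local_pressure(self, P_i: np.ndarray | None) -> np.ndarray:
        """Length-weighted mean interstitial pressure under each segment."""
        if P_i is None or self.traversals is None:
            return np.zeros(len(self.network.segments))
        out = np.zeros(len(self.network.segments))
        for k, (ii, jj, ll) in enumerate(self.traversals):
            tot = ll.sum()
            out[k] = float((P_i[jj, ii] * ll).sum() / tot) if tot > 0 else 0.0
        return out

    def solve(self, P_i: np.ndarray | None = None):
        """Return (node pressures Pa, segment flows m³/s, leak m³/s)."""
        n = self.network.n_nodes
        rhs = np.zeros(n)
        p_local = self.segment_local_pressure(P_i)
        p_eff = p_local + self.seg_osmotic
        for k, (a, b, _) in enumerate(self.network.segments):
            share = self.seg_Lw[k] / 2.0 * p_eff[k]
            for i in (a, b):
                if i not in self._bset:
                    rhs[i] += share
        for i, p in self.network.boundary_pressures.items():
            rhs[i] = p
        p = self._lu.solve(rhs)
        a_idx = np.array([a for a, _, _ in self.network.segments])
        b_idx = np.array([b for _, b, _ in self.network.segments])
        q = self.conductance * (p[a_idx] - p[b_idx])
        leak = self.seg_Lw * ((p[a_idx] + p[b_idx]) / 2.0 - p_eff)
        return p, q, leak


def solve_network_flow(network: VascularNetwork, params: ParameterSet,
                       P_i: np.ndarray | None = None,
                       grid: SimulationGrid | None = None,
                       tissue: TissueMap | None = None, leak: bool = True):
    """One-shot network solve; see :class:`NetworkFlowModel`."""
    model = NetworkFlowModel(network, params, grid=grid, tissue=tissue,
                             leak=leak)
    p, q, _ = model.solve(P_i)
    return p, q


# --------------------------------------------------------------------------
# Interstitial pressure
# --------------------------------------------------------------------------

class InterstitialModel:
    """Finite-volume Darcy solver with Starling source and lymphatic sink."""

    def __init__(self, grid: SimulationGrid, tissue: TissueMap,
                 sv: np.ndarray, params: ParameterSet,
                 boundary_value: float = 0.0,
                 dirichlet_sides: tuple[str, ...] = ALL_SIDES):
        self.grid = grid
        self.tissue = tissue
        self.sv = sv
        self.params = params
        self.boundary_value = boundary_value
        self.dirichlet_sides = dirichlet_sides

        nx, ny = grid.nx, grid.ny
        kappa = tissue_coefficient(tissue, params, "kappa")
        self.kappa = kappa
        self.a_coeff = tissue_coefficient(tissue, params, "L_p") * sv
        lymph = tissue_coefficient(tissue, params, "lymph_filtration")
        lymph[tissue.tumor_mask] = params.tissue[TUMOR].lymph_filtration
        self.lymph = lymph
        self.P_L = _tissue_field(tissue, params.tissue[NORMAL].P_L,
                                 params.tissue[TUMOR].P_L)
        self.osmotic = osmotic_offset(tissue, params)

        N = nx * ny
        idx = np.arange(N).reshape(ny, nx)
        diag = self.a_coeff.ravel() + self.lymph.ravel()
        rows, cols, vals = [list(idx.ravel())], [list(idx.ravel())], [diag]

        def add_internal(axis: int, spacing: float):
            if axis == 0:     # x-faces between (j,i-1),(j,i)
                ka, kb = kappa[:, :-1], kappa[:, 1:]
                ia, ib = idx[:, :-1], idx[:, 1:]
            else:             # y-faces
                ka, kb = kappa[:-1, :], kappa[1:, :]
                ia, ib = idx[:-1, :], idx[1:, :]
            kh = 2.0 * ka * kb / (ka + kb)
            t = (kh / spacing**2).ravel()
            ia, ib = ia.ravel(), ib.ravel()
            rows.extend([ia, ib, ia, ib])
            cols.extend([ia, ib, ib, ia])
            vals.extend([t, t, -t, -t])

        add_internal(0, grid.dx)
        add_internal(1, grid.dy)

        self._bc_coeff = np.zeros((ny, nx))
        sides = {
            "left": (idx[:, 0], kappa[:, 0], grid.dx),
            "right": (idx[:, -1], kappa[:, -1], grid.dx),
            "bottom": (idx[0, :], kappa[0, :], grid.dy),
            "top": (idx[-1, :], kappa[-1, :], grid.dy),
        }
        for name in dirichlet_sides:
            cells, kap, h = sides[name]
            t = 2.0 * kap / h**2
            rows.append(cells)
            cols.append(cells)
            vals.append(t)
            np.add.at(self._bc_coeff, np.unravel_index(cells, (ny, nx)), t)

        rows = np.concatenate([np.asarray(r).ravel() for r in rows])
        cols = np.concatenate([np.asarray(c).ravel() for c in cols])
        vals = np.concatenate([np.asarray(v).ravel() for v in vals])
        M = sp.coo_matrix((vals, (rows, cols)), shape=(N, N)).tocsc()
        self._lu = spla.splu(M)

    def solve(self, P_B: np.ndarray) -> np.ndarray:
        """Solve for P_i given gridded vascular pressure P_B (Pa)."""
        p_eff = P_B - self.osmotic
        rhs = (self.a_coeff * p_eff + self.lymph * self.P_L
               + self._bc_coeff * self.boundary_value)
        return self._lu.solve(rhs.ravel()).reshape(self.grid.ny, self.grid.nx)

    def face_velocities(self, P_i: np.ndarray):
        """Darcy velocities on cell faces: (u: ny×(nx+1), v: (ny+1)×nx)."""
        g, k = self.grid, self.kappa
        u = np.zeros((g.ny, g.nx + 1))
        v = np.zeros((g.ny + 1, g.nx))
        kh_x = 2.0 * k[:, :-1] * k[:, 1:] / (k[:, :-1] + k[:, 1:])
        kh_y = 2.0 * k[:-1, :] * k[1:, :] / (k[:-1, :] + k[1:, :])
        u[:, 1:-1] = -kh_x * (P_i[:, 1:] - P_i[:, :-1]) / g.dx
        v[1:-1, :] = -kh_y * (P_i[1:, :] - P_i[:-1, :]) / g.dy
        pb = self.boundary_value
        if "left" in self.dirichlet_sides:
            u[:, 0] = -k[:, 0] * (P_i[:, 0] - pb) / (0.5 * g.dx)
        if "right" in self.dirichlet_sides:
            u[:, -1] = -k[:, -1] * (pb - P_i[:, -1]) / (0.5 * g.dx)
        if "bottom" in self.dirichlet_sides:
            v[0, :] = -k[0, :] * (P_i[0, :] - pb) / (0.5 * g.dy)
        if "top" in self.dirichlet_sides:
            v[-1, :] = -k[-1, :] * (pb - P_i[-1, :]) / (0.5 * g.dy)
        return u, v


def solve_interstitial_pressure(grid: SimulationGrid, tissue: TissueMap,
                                sv: np.ndarray, P_B: np.ndarray,
                                params: ParameterSet,
                                boundary_value: float = 0.0,
                                dirichlet_sides: tuple[str, ...] = ALL_SIDES
                                ) -> np.ndarray:
    """One-shot interstitial pressure solve; see :class:`InterstitialModel`."""
    model = InterstitialModel(grid, tissue, sv, params,
                              boundary_value=boundary_value,
                              dirichlet_sides=dirichlet_sides)
    return model.solve(P_B)


def interstitial_velocity(grid: SimulationGrid, P_i: np.ndarray,
                          kappa: np.ndarray) -> np.ndarray:
    """Cell-centered Darcy velocity v = −κ∇P_i, shape (ny, nx, 2)."""
    v = np.zeros(P_i.shape + (2,))
    v[:, :, 0] = -kappa * np.gradient(P_i, grid.dx, axis=1)
    v[:, :, 1] = -kappa * np.gradient(P_i, grid.dy, axis=0)
    return v


# --------------------------------------------------------------------------
# Coupling
# --------------------------------------------------------------------------

@dataclass
class FlowSolution:
    """Converged vascular + interstitial flow state."""

    grid: SimulationGrid
    tissue: TissueMap
    node_pressure: np.ndarray      # Pa per network node
    segment_flow: np.ndarray       # m³/s per segment
    P_i: np.ndarray                # Pa, (ny, nx)
    v_i: np.ndarray                # m/s, (ny, nx, 2) cell centers
    u_face: np.ndarray             # m/s, (ny, nx+1)
    v_face: np.ndarray             # m/s, (ny+1, nx)
    phi_B: np.ndarray              # 1/s filtration rate
    phi_L: np.ndarray              # 1/s lymphatic drainage
    P_B: np.ndarray                # Pa gridded vascular pressure (0 off-vessel)
    sv: np.ndarray                 # 1/m vascular surface density
    iterations: int
    residual: float                # Pa
    converged: bool

    def boundary_outflow(self) -> float:
        """Net Darcy outflow through the outer boundary, m²/s per depth."""
        g = self.grid
        return float(
            (self.u_face[:, -1] - self.u_face[:, 0]).sum() * g.dy
            + (self.v_face[-1, :] - self.v_face[0, :]).sum() * g.dx
        )

    def fluid_balance(self) -> dict[str, float]:
        """Integrated ϕ_B, ϕ_L and boundary outflow (m²/s per unit depth)."""
        area = self.grid.cell_area
        src = float(self.phi_B.sum() * area)
        sink = float(self.phi_L.sum() * area)
        out = self.boundary_outflow()
        scale = max(abs(src), abs(sink) + abs(out), 1e-300)
        return {"filtration": src, "lymph": sink, "boundary_outflow": out,
                "relative_imbalance": abs(src - sink - out) / scale}


def map_vascular_pressure(model: NetworkFlowModel, node_pressure: np.ndarray,
                          grid: SimulationGrid) -> np.ndarray:
    """Project segment mean pressures onto grid cells (length-weighted)."""
    num = np.zeros((grid.ny, grid.nx))
    den = np.zeros((grid.ny, grid.nx))
    for k, (a, b, _) in enumerate(model.network.segments):
        pbar = 0.5 * (node_pressure[a] + node_pressure[b])
        ii, jj, ll = model.traversals[k]
        np.add.at(num, (jj, ii), pbar * ll)
        np.add.at(den, (jj, ii), ll)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return out


def couple_perfusion(network: VascularNetwork, grid: SimulationGrid,
                     tissue: TissueMap, params: ParameterSet,
                     sv: np.ndarray | None = None,
                     tol: float = 1e-3 * MMHG_PA, max_iter: int = 200,
                     relax: float = 0.5, boundary_value: float = 0.0,
                     dirichlet_sides: tuple[str, ...] = ALL_SIDES
                     ) -> FlowSolution:
    """Fixed-point coupling of network and interstitial flow.

    Alternates the network solve (using the current interstitial pressure
    under each segment) with the interstitial solve (using the current
    gridded vascular pressure), under-relaxing P_i until the max change
    drops below ``tol`` (Pa).  Raises ``RuntimeError`` on non-convergence.
    """
    if sv is None:
        sv = rasterize_network(network, grid)
    net_model = NetworkFlowModel(network, params, grid=grid, tissue=tissue)
    int_model = InterstitialModel(grid, tissue, sv, params,
                                  boundary_value=boundary_value,
                                  dirichlet_sides=dirichlet_sides)
    P_i = np.zeros((grid.ny, grid.nx))
    residual = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        node_p, seg_q, _ = net_model.solve(P_i)
        P_B = map_vascular_pressure(net_model, node_p, grid)
        P_new = int_model.solve(P_B)
        residual = float(np.abs(P_new - P_i).max())
        P_i = P_i + relax * (P_new - P_i)
        if residual < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"perfusion coupling did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} Pa)")

    node_p, seg_q, _ = net_model.solve(P_i)
    P_B = map_vascular_pressure(net_model, node_p, grid)
    phi_B = np.where(sv > 0,
                     int_model.a_coeff * (P_B - int_model.osmotic - P_i), 0.0)
    phi_L = int_model.lymph * (P_i - int_model.P_L)
    u, v = int_model.face_velocities(P_i)
    v_c = interstitial_velocity(grid, P_i, int_model.kappa)
    return FlowSolution(grid=grid, tissue=tissue, node_pressure=node_p,
                        segment_flow=seg_q, P_i=P_i, v_i=v_c, u_face=u,
                        v_face=v, phi_B=phi_B, phi_L=phi_L, P_B=P_B, sv=sv,
                        iterations=it, residual=residual, converged=True)
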