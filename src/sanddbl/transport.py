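"""Single-grain flow and reactive O2/N2 transport.

A circular sand grain (radius ``r``, default 145 µm) sits in slowly flowing
pore water. A 5 µm reactive rim on the grain surface carries alternating net
O2-consuming and net O2-producing microbial colonies. The model solves

* stationary Stokes flow (``0 = -grad p + mu lap u``, ``div u = 0``) with
  no-slip on the grain and a uniform stream ``U`` imposed on an outer circle
  (8 grain radii by default), via the closed-form bounded-Stokes
  streamfunction ``psi = U a g(r/a) sin(theta)`` with
  ``g = A rho^3 + B rho ln rho + C rho + D / rho``;
* stationary advection-diffusion-reaction for O2 and N2 on a polar
  finite-volume grid whose radial faces resolve the rim exactly. Face
  advective fluxes are streamfunction differences, hence discretely
  divergence-free, so steady-state mass balance closes to solver precision.

Colony kinetics: the surface rate follows a shifted sinusoid along the grain
perimeter, thresholded so that each of the ``a`` (default 4) colony pairs has
a 76 µm consumer arc (minimum -955 mmol O2 L^-1 h^-1) and a 38 µm producer
arc (maximum +514 mmol O2 L^-1 h^-1) on the default 290 µm grain, with bare
surface in between. O2 consumption is Michaelis-Menten limited,
``f_O2 = C/(K_m + C)`` with K_m = 0.1 µmol L^-1. Denitrification produces N2
at 1/10 of the potential O2 consumption magnitude, gated by the O2
inhibition ``f_N = C_inh/(C_inh + C_O2)`` (C_inh = 0.1 µmol L^-1): N2 is
released where colonies turn anoxic.

All concentrations are carried in mol m^-3 internally (1 µmol L^-1 =
1e-3 mol m^-3); rates in mol m^-3 s^-1 (1 mmol L^-1 h^-1 = 1/3.6e3 mol m^-3 s^-1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "GrainModelConfig",
    "FlowField",
    "FieldSolution",
    "MicroenvSummary",
    "build_grid",
    "solve_flow",
    "surface_reaction_field",
    "solve_solutes",
    "summarize",
    "run_ensemble",
]

MMOL_L_H_TO_MOL_M3_S = 1.0 / 3.6e3  # 1 mmol L^-1 h^-1 = 1 mol m^-3 h^-1
UMOL_L_TO_MOL_M3 = 1.0e-3


class SolverError(RuntimeError):
    """Raised when the nonlinear transport iteration fails to converge."""


@dataclass
class GrainModelConfig:
    """Physical constants, geometry and numerics for the single-grain model.

    Lengths in µm, rates in mmol L^-1 h^-1, concentrations in µmol L^-1,
    velocities in µm s^-1 — matching the units the quantities are usually
    reported in; conversion to SI happens inside the solver.
    """

    grain_radius_um: float = 145.0
    rim_thickness_um: float = 5.0
    colony_pairs: int = 4
    consumer_arc_um: float = 76.0
    producer_arc_um: float = 38.0
    r_c_min_mmol_L_h: float = -955.0
    r_c_max_mmol_L_h: float = 514.0
    k_m_umol_L: float = 0.1
    c_inh_umol_L: float = 0.1
    n_to_o2_ratio: float = 0.1
    d_o2_m2_s: float = 1.1e-9
    d_n2_m2_s: float = 2.1e-9
    dynamic_viscosity_pa_s: float = 1.22e-3
    inflow_velocity_um_s: float = 100.0
    inflow_o2_umol_L: float = 50.0
    production_on: bool = True
    # numerics / geometry
    outer_radius_factor: float = 16.0
    n_theta: int = 192
    n_radial: int = 96
    rim_cells: int = 4
    anoxia_threshold_umol_L: float = 1.0
    extrusion_depth_um: float = 290.0
    rim_diffusivity_factor: float = 1.0
    max_picard_iterations: int = 200
    nonlinear_tolerance: float = 1.0e-8
    # testing hook: axisymmetric uniform rim consumption instead of colonies
    uniform_consumption_mmol_L_h: float | None = None

    def __post_init__(self) -> None:
        if not self.grain_radius_um > self.rim_thickness_um > 0:
            raise ValueError("need grain radius > rim thickness > 0")
        if self.k_m_umol_L <= 0 or self.c_inh_umol_L <= 0:
            raise ValueError("K_m and C_inh must be positive")
        if self.r_c_min_mmol_L_h > 0 or self.r_c_max_mmol_L_h < 0:
            raise ValueError("R_c_min must be <= 0 and R_c_max >= 0")
        if self.inflow_velocity_um_s < 0 or self.inflow_o2_umol_L < 0:
            raise ValueError("inflow velocity and O2 must be non-negative")
        if self.rim_cells < 2:
            raise ValueError("the rim must be resolved by at least 2 cells")
        if self.outer_radius_factor <= 1:
            raise ValueError("outer radius must exceed the grain radius")
        period_um = 2 * np.pi * self.grain_radius_um / self.colony_pairs
        if self.consumer_arc_um + self.producer_arc_um > period_um:
            raise ValueError("colony arcs exceed one sinusoid period")

    @property
    def grain_radius_m(self) -> float:
        return self.grain_radius_um * 1e-6

    @property
    def outer_radius_m(self) -> float:
        return self.outer_radius_factor * self.grain_radius_m


@dataclass
class PolarGrid:
    """Annular finite-volume grid: rim-aligned radial faces, uniform angles."""

    r_faces: np.ndarray      # (Nr+1,) m
    theta_faces: np.ndarray  # (Nt+1,) rad, theta_faces[0]=0, [-1]=2 pi
    rim_cells: int

    def __post_init__(self) -> None:
        self.r_centers = 0.5 * (self.r_faces[1:] + self.r_faces[:-1])
        self.dr = np.diff(self.r_faces)
        self.theta_centers = 0.5 * (self.theta_faces[1:] + self.theta_faces[:-1])
        self.dtheta = float(self.theta_faces[1] - self.theta_faces[0])
        # 2D cell areas (m^2): r dr dtheta
        self.volumes = np.outer(self.r_centers * self.dr,
                                np.full(self.n_theta, self.dtheta))

    @property
    def n_radial(self) -> int:
        return self.r_centers.size

    @property
    def n_theta(self) -> int:
        return self.theta_centers.size


def _geometric_ratio(dr0: float, length: float, n: int) -> float:
    """Growth factor g with sum_{i=1..n} dr0 g^i = length."""
    from scipy.optimize import brentq

    def h(g):
        if abs(g - 1.0) < 1e-12:
            return dr0 * n - length
        return dr0 * g * (g**n - 1.0) / (g - 1.0) - length

    if h(1.0) >= 0:
        return 1.0
    return brentq(h, 1.0 + 1e-12, 2.0, xtol=1e-14)


def build_grid(config: GrainModelConfig) -> PolarGrid:
    """Polar grid from the grain surface to the outer circle.

    The rim (first ``rim_cells`` cells) is meshed uniformly so its outer edge
    coincides with a radial face; beyond it the spacing grows geometrically.
    """
    a = config.grain_radius_m
    b = config.outer_radius_m
    rim = config.rim_thickness_um * 1e-6
    nc = config.rim_cells
    n_out = config.n_radial - nc
    if n_out < 4:
        raise ValueError("n_radial leaves too few cells outside the rim")
    dr0 = rim / nc
    g = _geometric_ratio(dr0, b - a - rim, n_out)
    steps = np.concatenate([np.full(nc, dr0), dr0 * g ** np.arange(1, n_out + 1)])
    r_faces = a + np.concatenate([[0.0], np.cumsum(steps)])
    r_faces[-1] = b
    theta_faces = np.linspace(0.0, 2 * np.pi, config.n_theta + 1)
    return PolarGrid(r_faces=r_faces, theta_faces=theta_faces, rim_cells=nc)


@dataclass
class FlowField:
    """Bounded-Stokes flow past the grain: psi = U a g(r/a) sin(theta)."""

    U: float                 # m/s
    a: float                 # grain radius, m
    b: float                 # outer radius, m
    coeffs: np.ndarray       # (4,) for g = A rho^3 + B rho ln rho + C rho + D/rho
    mu: float = 1.22e-3      # Pa s

    def _g(self, rho: np.ndarray) -> np.ndarray:
        A, B, C, D = self.coeffs
        return A * rho**3 + B * rho * np.log(rho) + C * rho + D / rho

    def _gprime(self, rho: np.ndarray) -> np.ndarray:
        A, B, C, D = self.coeffs
        return 3 * A * rho**2 + B * (np.log(rho) + 1.0) + C - D / rho**2

    def psi(self, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Streamfunction (m^2 s^-1 per unit depth)."""
        return self.U * self.a * self._g(np.asarray(r) / self.a) * np.sin(theta)

    def velocity(self, r: np.ndarray, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(u_r, u_theta) in m s^-1."""
        rho = np.asarray(r) / self.a
        u_r = self.U * self._g(rho) / rho * np.cos(theta)
        u_t = -self.U * self._gprime(rho) * np.sin(theta)
        return u_r, u_t

    def pressure(self, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Pressure field (Pa), defined up to an additive constant."""
        rho = np.asarray(r) / self.a
        A, B, _, _ = self.coeffs
        return self.mu * self.U / self.a * (8.0 * A * rho + 2.0 * B / rho) * np.cos(theta)


def solve_flow(config: GrainModelConfig) -> FlowField:
    """Stationary Stokes flow: no-slip on the grain, uniform stream outside.

    The streamfunction ansatz reduces the Stokes system to four linear
    conditions on g(rho): g(1) = g'(1) = 0 (no slip) and g(beta) = beta,
    g'(beta) = 1 (uniform stream U at the outer circle, the far-field /
    inflow-outflow boundary). The returned field is exactly divergence-free.
    """
    beta = config.outer_radius_factor
    rows = []
    rhs = []
    for rho, fval, dval in ((1.0, 0.0, 0.0), (beta, beta, 1.0)):
        rows.append([rho**3, rho * np.log(rho), rho, 1.0 / rho])
        rhs.append(fval)
        rows.append([3 * rho**2, np.log(rho) + 1.0, 1.0, -1.0 / rho**2])
        rhs.append(dval)
    coeffs = np.linalg.solve(np.array(rows), np.array(rhs))
    return FlowField(
        U=config.inflow_velocity_um_s * 1e-6,
        a=config.grain_radius_m,
        b=config.outer_radius_m,
        coeffs=coeffs,
        mu=config.dynamic_viscosity_pa_s,
    )


def _arc_thresholds(config: GrainModelConfig) -> tuple[float, float]:
    """Sinusoid thresholds reproducing the consumer/producer arc lengths.

    With x = a*theta + phase, producers occupy {sin x > s_p} and consumers
    {sin x < s_c}; the thresholds are set from the arc fractions of one
    period (sin x > s on a fraction p of a period iff s = cos(pi p))."""
    period_um = 2 * np.pi * config.grain_radius_um / config.colony_pairs
    p = config.producer_arc_um / period_um
    q = config.consumer_arc_um / period_um
    s_p = np.cos(np.pi * p)
    s_c = -np.cos(np.pi * q)
    return s_c, s_p


def _phase(config: GrainModelConfig) -> float:
    # place a consumer-arc centre at the inflow-facing point theta = pi
    return -np.pi / 2.0 - config.colony_pairs * np.pi


def surface_reaction_field(
    config: GrainModelConfig, r_m: np.ndarray | float, theta: np.ndarray | float
) -> np.ndarray:
    """Colony O2 rate R_c (mol m^-3 s^-1) at points (r, theta); 0 off the rim.

    Negative over consumer arcs (minimum R_c_min at arc centres), positive
    over producer arcs (maximum R_c_max), zero on bare surface and outside
    the 5 µm rim. The Michaelis-Menten O2 limitation is applied at solve
    time, not here.
    """
    r_m = np.asarray(r_m, dtype=float)
    theta = np.asarray(theta, dtype=float)
    a_rad = config.grain_radius_m
    rim_out = a_rad + config.rim_thickness_um * 1e-6
    in_rim = (r_m >= a_rad - 1e-15) & (r_m <= rim_out + 1e-15)

    if config.uniform_consumption_mmol_L_h is not None:
        rc = np.full(np.broadcast(r_m, theta).shape,
                     config.uniform_consumption_mmol_L_h * MMOL_L_H_TO_MOL_M3_S)
        return np.where(in_rim, rc, 0.0)

    s_c, s_p = _arc_thresholds(config)
    x = np.sin(config.colony_pairs * theta + _phase(config))
    rc = np.zeros(np.broadcast(x, r_m).shape)
    consumer = x < s_c
    producer = x > s_p
    # shape in (0, 1], peaking at the arc centre
    w_c = (s_c - x) / (s_c + 1.0)
    w_p = (x - s_p) / (1.0 - s_p)
    rc = np.where(consumer, config.r_c_min_mmol_L_h * MMOL_L_H_TO_MOL_M3_S * w_c, rc)
    rc = np.where(producer, config.r_c_max_mmol_L_h * MMOL_L_H_TO_MOL_M3_S * w_p, rc)
    return np.where(in_rim, rc, 0.0)


def consumer_colony_index(
    config: GrainModelConfig, theta: np.ndarray
) -> np.ndarray:
    """Index (0..colony_pairs-1) of the consumer colony at each angle, -1 off-arc."""
    s_c, _ = _arc_thresholds(config)
    x = config.colony_pairs * np.asarray(theta) + _phase(config)
    idx = np.floor(x / (2 * np.pi)).astype(int) % config.colony_pairs
    return np.where(np.sin(x) < s_c, idx, -1)


@dataclass
class FieldSolution:
    """Converged fields on the polar grid (radial x angular cell centres)."""

    grid: PolarGrid
    flow: FlowField
    u_r: np.ndarray
    u_theta: np.ndarray
    pressure: np.ndarray
    c_o2: np.ndarray            # mol m^-3
    c_n2: np.ndarray            # mol m^-3 (excess over background)
    reaction_o2: np.ndarray     # nominal R_c, mol m^-3 s^-1
    source_n2: np.ndarray       # mol m^-3 s^-1
    residuals: dict = field(default_factory=dict)

    @property
    def c_o2_umol_L(self) -> np.ndarray:
        return self.c_o2 / UMOL_L_TO_MOL_M3


def _face_fluxes(flow: FlowField, grid: PolarGrid) -> tuple[np.ndarray, np.ndarray]:
    """Discretely divergence-free face volume fluxes from psi differences.

    Returns (Fr, Gt): Fr[i, j] is the outward volumetric flux (m^2 s^-1 per
    unit depth) through the radial face at r_faces[i] of angular cell j;
    Gt[i, j] the +theta flux through the angular face at theta_faces[j] of
    radial cell i.
    """
    rf = grid.r_faces
    tf = grid.theta_faces
    psi_corner = flow.psi(rf[:, None], tf[None, :])  # (Nr+1, Nt+1)
    Fr = psi_corner[:, 1:] - psi_corner[:, :-1]
    Gt = -(psi_corner[1:, :-1] - psi_corner[:-1, :-1])
    return Fr, Gt


def divergence_norm(flow: FlowField, grid: PolarGrid) -> float:
    """Max discrete cell divergence, normalised by U * r (0 for exact fluxes)."""
    Fr, Gt = _face_fluxes(flow, grid)
    div = (Fr[1:, :] - Fr[:-1, :]
           + np.roll(Gt, -1, axis=1) - Gt)
    scale = max(abs(flow.U) * flow.a, 1e-300)
    return float(np.max(np.abs(div)) / scale)


def _assemble(
    grid: PolarGrid,
    Fr: np.ndarray,
    Gt: np.ndarray,
    diff_cell: np.ndarray,
    c_boundary: float,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Upwind/central finite-volume transport operator A0 C = b0 on the annulus.

    Returns the linear advection-diffusion operator (with outer-boundary
    closures) and the boundary right-hand side; reactive terms are added by
    the nonlinear driver.
    """
    Nr, Nt = grid.n_radial, grid.n_theta
    N = Nr * Nt
    rc, rf, dr, dth = grid.r_centers, grid.r_faces, grid.dr, grid.dtheta

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(N)

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64).ravel())
        cols.append(np.asarray(c, dtype=np.int64).ravel())
        vals.append(np.asarray(v, dtype=float).ravel())

    jj = np.arange(Nt)

    # radial interior faces
    for i in range(1, Nr):
        F = Fr[i, :]
        dharm = 2.0 / (1.0 / diff_cell[i - 1, :] + 1.0 / diff_cell[i, :])
        d = dharm * rf[i] * dth / (rc[i] - rc[i - 1])
        Fp, Fm = np.maximum(F, 0.0), np.minimum(F, 0.0)
        n1 = (i - 1) * Nt + jj
        n2 = i * Nt + jj
        add(n1, n1, Fp + d); add(n1, n2, Fm - d)
        add(n2, n1, -Fp - d); add(n2, n2, -Fm + d)

    # angular faces (periodic)
    for j in range(Nt):
        jm = (j - 1) % Nt
        ii = np.arange(Nr)
        G = Gt[:, j]
        dharm = 2.0 / (1.0 / diff_cell[:, jm] + 1.0 / diff_cell[:, j])
        d = dharm * dr / (rc * dth)
        Gp, Gm = np.maximum(G, 0.0), np.minimum(G, 0.0)
        n1 = ii * Nt + jm
        n2 = ii * Nt + j
        add(n1, n1, Gp + d); add(n1, n2, Gm - d)
        add(n2, n1, -Gp - d); add(n2, n2, -Gm + d)

    # outer boundary: Dirichlet on inflow faces, advective outflow otherwise
    F = Fr[Nr, :]
    n = (Nr - 1) * Nt + jj
    d_b = diff_cell[Nr - 1, :] * rf[Nr] * dth / (rf[Nr] - rc[Nr - 1])
    inflow = F <= 0.0
    add(n[~inflow], n[~inflow], F[~inflow])
    add(n[inflow], n[inflow], d_b[inflow])
    b[n[inflow]] += (-F[inflow] + d_b[inflow]) * c_boundary
    # inner boundary (grain surface): no flux -- nothing to add

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    return A, b


def solve_solutes(
    config: GrainModelConfig,
    flow: FlowField | None = None,
    grid: PolarGrid | None = None,
) -> FieldSolution:
    """Coupled stationary O2 / N2 fields around the grain.

    O2: sink = |R_c^-| * C/(K_m + C) in consumer rim cells (implicit Picard
    linearisation, which preserves positivity), source = R_c^+ in producer
    cells when production is on; Dirichlet C0 on the inflow half of the outer
    circle. N2 (excess over background): source = |R_c^-| * n_to_o2_ratio *
    f_N(C_O2), Dirichlet 0 at inflow. Iterates to a relative nonlinear
    residual <= ``config.nonlinear_tolerance``.
    """
    if grid is None:
        grid = build_grid(config)
    if flow is None:
        flow = solve_flow(config)
    Fr, Gt = _face_fluxes(flow, grid)

    Nr, Nt = grid.n_radial, grid.n_theta
    rr = np.broadcast_to(grid.r_centers[:, None], (Nr, Nt))
    tt = np.broadcast_to(grid.theta_centers[None, :], (Nr, Nt))
    rc_field = surface_reaction_field(config, rr, tt)
    sink = np.maximum(-rc_field, 0.0)                        # mol m^-3 s^-1
    prod = np.maximum(rc_field, 0.0) if config.production_on else np.zeros_like(rc_field)

    diff_o2 = np.full((Nr, Nt), config.d_o2_m2_s)
    diff_o2[:grid.rim_cells, :] *= config.rim_diffusivity_factor
    km = config.k_m_umol_L * UMOL_L_TO_MOL_M3
    c0 = config.inflow_o2_umol_L * UMOL_L_TO_MOL_M3

    A0, b0 = _assemble(grid, Fr, Gt, diff_o2, c0)
    vol = grid.volumes.ravel()
    sink_v = sink.ravel() * vol
    b = b0 + (prod * grid.volumes).ravel()
    b_norm = max(float(np.linalg.norm(b)), 1e-300)

    def residual(cv: np.ndarray) -> np.ndarray:
        return A0 @ cv + sink_v * cv / (km + cv) - b

    cv = np.full(Nr * Nt, c0)
    res_rel = np.inf
    for it in range(config.max_picard_iterations):
        res_rel = float(np.linalg.norm(residual(cv)) / b_norm)
        if res_rel <= config.nonlinear_tolerance:
            break
        if it < 5:
            # Picard: implicit sink linearisation, unconditionally positive
            A = A0 + sp.diags(sink_v / (km + cv))
            cv = spla.spsolve(A.tocsc(), b)
        else:
            # Newton on the Michaelis-Menten diagonal
            J = A0 + sp.diags(sink_v * km / (km + cv) ** 2)
            cv = cv - spla.spsolve(J.tocsc(), residual(cv))
        cv = np.maximum(cv, 0.0)
    if res_rel > config.nonlinear_tolerance:
        raise SolverError(
            f"O2 iteration did not converge (relative residual {res_rel:.2e})"
        )
    c = cv.reshape(Nr, Nt)

    # N2: linear solve, source gated by O2 inhibition
    cinh = config.c_inh_umol_L * UMOL_L_TO_MOL_M3
    f_n = cinh / (cinh + c)
    src_n2 = sink * config.n_to_o2_ratio * f_n
    diff_n2 = np.full((Nr, Nt), config.d_n2_m2_s)
    diff_n2[:grid.rim_cells, :] *= config.rim_diffusivity_factor
    A_n, b0_n = _assemble(grid, Fr, Gt, diff_n2, 0.0)
    b_n = b0_n + (src_n2 * grid.volumes).ravel()
    c_n2 = spla.spsolve(A_n.tocsc(), b_n).reshape(Nr, Nt)
    res_n2 = float(np.linalg.norm(A_n @ c_n2.ravel() - b_n)
                   / max(np.linalg.norm(b_n), 1e-300))
    c_n2 = np.maximum(c_n2, 0.0)

    u_r, u_t = flow.velocity(rr, tt)
    return FieldSolution(
        grid=grid,
        flow=flow,
        u_r=u_r,
        u_theta=u_t,
        pressure=flow.pressure(rr, tt),
        c_o2=c,
        c_n2=c_n2,
        reaction_o2=rc_field,
        source_n2=src_n2,
        residuals={"o2_relative": res_rel, "n2_relative": res_n2},
    )


def mass_balance_error(config: GrainModelConfig, sol: FieldSolution,
                       species: str = "o2") -> float:
    """Relative steady-state closure |boundary influx - net reaction| for a species."""
    grid, flow = sol.grid, sol.flow
    Fr, _ = _face_fluxes(flow, grid)
    Nr = grid.n_radial
    rf, rc, dth = grid.r_faces, grid.r_centers, grid.dtheta

    km = config.k_m_umol_L * UMOL_L_TO_MOL_M3
    if species == "o2":
        c = sol.c_o2
        cb = config.inflow_o2_umol_L * UMOL_L_TO_MOL_M3
        diff = np.full_like(c, config.d_o2_m2_s)
        diff[:grid.rim_cells, :] *= config.rim_diffusivity_factor
        sink = np.maximum(-sol.reaction_o2, 0.0) * c / (km + c)
        prod = (np.maximum(sol.reaction_o2, 0.0)
                if config.production_on else np.zeros_like(c))
        net_reaction = float(np.sum((sink - prod) * grid.volumes))
    elif species == "n2":
        c = sol.c_n2
        cb = 0.0
        diff = np.full_like(c, config.d_n2_m2_s)
        diff[:grid.rim_cells, :] *= config.rim_diffusivity_factor
        net_reaction = -float(np.sum(sol.source_n2 * grid.volumes))
    else:
        raise ValueError(species)

    F = Fr[Nr, :]
    c_edge = c[Nr - 1, :]
    influx = 0.0
    for j in range(grid.n_theta):
        if F[j] <= 0.0:
            d_b = diff[Nr - 1, j] * rf[Nr] * dth / (rf[Nr] - rc[Nr - 1])
            influx += -F[j] * cb + d_b * (cb - c_edge[j])
        else:
            influx += -F[j] * c_edge[j]
    scale = max(abs(net_reaction), abs(influx), 1e-300)
    return abs(influx - net_reaction) / scale


@dataclass
class MicroenvSummary:
    """Anoxia and N2-production summary of one converged run."""

    anoxic_rim_volume_fraction: float
    anoxic_colony_count: int
    colony_anoxic_fractions: np.ndarray      # per consumer colony
    n2_per_colony_nmol_d: np.ndarray
    n2_per_grain_nmol_d: float
    o2_boundary_influx_mol_h: float
    mass_balance_o2: float
    mass_balance_n2: float


def summarize(config: GrainModelConfig, sol: FieldSolution) -> MicroenvSummary:
    """Anoxic consumer-rim fraction, anoxic colony count and N2 production.

    A consumer colony counts as anoxic when more than half of its rim area is
    below the anoxia threshold. The 2D N2 source integral is extruded by
    ``extrusion_depth_um`` (default one median grain diameter) to report
    nmol N per colony and per grain per day.
    """
    grid = sol.grid
    thr = config.anoxia_threshold_umol_L * UMOL_L_TO_MOL_M3
    rim = np.zeros_like(sol.c_o2, dtype=bool)
    rim[:grid.rim_cells, :] = True
    consumer = rim & (sol.reaction_o2 < 0.0)

    vol = grid.volumes
    total = float(np.sum(vol[consumer]))
    anoxic = consumer & (sol.c_o2 < thr)
    frac = float(np.sum(vol[anoxic]) / total) if total > 0 else 0.0

    a = config.colony_pairs
    tt = np.broadcast_to(grid.theta_centers[None, :], sol.c_o2.shape)
    cidx = consumer_colony_index(config, tt)
    cidx = np.where(consumer, cidx, -1)
    colony_frac = np.zeros(a)
    n2_colony = np.zeros(a)
    extr = config.extrusion_depth_um * 1e-6
    for k in range(a):
        mask = cidx == k
        vk = float(np.sum(vol[mask]))
        if vk > 0:
            colony_frac[k] = float(np.sum(vol[mask & (sol.c_o2 < thr)]) / vk)
        # mol m^-1 s^-1 integrated over the 2D section, then extruded
        n2_colony[k] = float(np.sum(sol.source_n2[mask] * vol[mask])) * extr
    n2_colony *= 86400.0 * 1e9  # mol/s -> nmol/d

    mb_o2 = mass_balance_error(config, sol, "o2")
    mb_n2 = mass_balance_error(config, sol, "n2")

    # O2 influx across the outer boundary, mol per hour (per extruded grain)
    influx = -mass_balance_influx(config, sol)
    return MicroenvSummary(
        anoxic_rim_volume_fraction=frac,
        anoxic_colony_count=int(np.sum(colony_frac > 0.5)),
        colony_anoxic_fractions=colony_frac,
        n2_per_colony_nmol_d=n2_colony,
        n2_per_grain_nmol_d=float(np.sum(n2_colony)),
        o2_boundary_influx_mol_h=influx * 3600.0 * extr,
        mass_balance_o2=mb_o2,
        mass_balance_n2=mb_n2,
    )


def mass_balance_influx(config: GrainModelConfig, sol: FieldSolution) -> float:
    """Net O2 flux out of the domain across the outer circle (mol m^-1 s^-1)."""
    grid = sol.grid
    Fr, _ = _face_fluxes(sol.flow, grid)
    Nr = grid.n_radial
    rf, rc, dth = grid.r_faces, grid.r_centers, grid.dtheta
    cb = config.inflow_o2_umol_L * UMOL_L_TO_MOL_M3
    diff = config.d_o2_m2_s
    out = 0.0
    for j in range(grid.n_theta):
        F = Fr[Nr, j]
        if F <= 0.0:
            d_b = diff * rf[Nr] * dth / (rf[Nr] - rc[Nr - 1])
            out -= -F * cb + d_b * (cb - sol.c_o2[Nr - 1, j])
        else:
            out += F * sol.c_o2[Nr - 1, j]
    return out


def run_ensemble(
    config: GrainModelConfig,
    velocities_um_s: np.ndarray,
    o2_values_umol_L: np.ndarray,
    production_on: bool = True,
) -> pd.DataFrame:
    """Solve the grain model over a (U, C0) grid and tabulate summaries.

    Returns one row per run with the anoxic consumer-rim fraction, the
    fraction of colonies turned anoxic, per-grain N2 production and the
    Sand_DBL inputs; failed runs are recorded with ``converged = False``
    rather than dropped.
    """
    from . import scaling

    rows = []
    for u in np.atleast_1d(velocities_um_s):
        for c0 in np.atleast_1d(o2_values_umol_L):
            cfg = dataclasses.replace(
                config,
                inflow_velocity_um_s=float(u),
                inflow_o2_umol_L=float(c0),
                production_on=production_on,
            )
            row = {
                "u_um_s": float(u),
                "c0_umol_L": float(c0),
                "production_on": production_on,
            }
            try:
                sol = solve_solutes(cfg)
                summ = summarize(cfg, sol)
                delta = scaling.dbl_thickness(
                    cfg.grain_radius_m, u * 1e-6, d_m2_s=cfg.d_o2_m2_s
                )
                r_o2 = abs(cfg.r_c_min_mmol_L_h) * MMOL_L_H_TO_MOL_M3_S
                sand = (
                    scaling.sanddbl(delta, cfg.d_o2_m2_s, r_o2,
                                    c0 * UMOL_L_TO_MOL_M3)
                    if c0 > 0 else np.inf
                )
                row.update(
                    anoxic_fraction=summ.anoxic_rim_volume_fraction,
                    colony_anoxic_fraction=summ.anoxic_colony_count / cfg.colony_pairs,
                    n2_per_grain_nmol_d=summ.n2_per_grain_nmol_d,
                    dbl_thickness_m=delta,
                    sanddbl=sand,
                    mass_balance_o2=summ.mass_balance_o2,
                    mass_balance_n2=summ.mass_balance_n2,
                    converged=True,
                )
            except (SolverError, np.linalg.LinAlgError) as exc:  # pragma: no cover
                row.update(converged=False, error=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
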