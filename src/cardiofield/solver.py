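"""Finite-element bidomain solver coupled to the torso volume conductor.

The heart carries the parabolic-elliptic bidomain system (normalized
membrane, beta*Cm = 1 by default):

    chi * dVm/dt = div(sigma_i grad(Vm + Ve)) - chi * (Iion - Istim)
    0            = div((sigma_i + sigma_e) grad Ve) + div(sigma_i grad Vm)

and the torso the Laplace equation div(sigma_b grad V) = 0. The heart and
torso share mesh nodes, so the continuity condition V = Ve on the interface
holds by construction; intracellular no-flux on the heart boundary and
insulation on the torso outer surface are natural boundary conditions of the
weak form, and the ground probe carries a homogeneous Dirichlet condition.

Time stepping is a first-order split: a pointwise backward-Euler reaction
update (see ionic.NodalKinetics), an implicit diffusion solve for Vm, and a
direct elliptic solve for the extracellular/torso potential. The
``fully_coupled`` scheme iterates the diffusion/elliptic pair to a fixed
point within each step, mirroring a fully implicit solve.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem, geometry
from .geometry import SAN, TORSO, HeartTorsoMesh
from .ionic import NodalKinetics, RegionParameterSet

log = logging.getLogger("cardiofield")

__all__ = [
    "SolverConfig",
    "StimulusEvent",
    "SimulationState",
    "SimulationResult",
    "SolverError",
    "assemble",
    "apply_boundary_conditions",
    "stimulus_current",
    "step",
    "run",
    "standard_protocol",
    "bar_conduction_velocity",
]


class SolverError(RuntimeError):
    def __init__(self, msg, partial_result=None):
        super().__init__(msg)
        self.partial_result = partial_result


@dataclass(frozen=True)
class SolverConfig:
    """Time-integration and volume-conductor settings (SI units)."""

    dt: float = 1e-3
    t_end: float = 0.6
    sigma_b: float = 0.2  # torso conductivity, S/m
    beta: float = 1.0  # surface-to-volume ratio (normalized form: beta*Cm = 1)
    cm: float = 1.0
    scheme: str = "semi_implicit"  # or "fully_coupled"
    sample_interval: float | None = None  # defaults to dt
    linear_tol: float = 1e-8
    coupling_tol: float = 1e-9
    coupling_maxit: int = 40
    san_rest: float = -0.06  # initial intracellular potential at the SAN (V)
    other_rest: float = -0.085  # initial Vi elsewhere (V)
    store_ve: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma_b <= 0:
            raise ValueError("sigma_b must be positive")
        if self.scheme not in ("semi_implicit", "fully_coupled"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def chi(self) -> float:
        return self.beta * self.cm


@dataclass(frozen=True)
class StimulusEvent:
    """Localized spherical transmembrane stimulus.

    ``amplitude`` is a volumetric rate density in the normalized membrane
    units (V/s added to dVm/dt inside the sphere). Use ``from_total_current``
    to convert a total injected current given an explicit beta*Cm.
    """

    center: tuple
    start: float
    duration: float = 2e-3
    radius: float = 3e-3
    amplitude: float = 200.0

    def __post_init__(self):
        if self.duration <= 0 or self.radius <= 0:
            raise ValueError("stimulus duration and radius must be positive")

    @classmethod
    def from_total_current(cls, center, start, total_current_A, beta_cm,
                           radius=3e-3, duration=2e-3):
        vol = 4.0 / 3.0 * np.pi * radius**3
        return cls(tuple(center), start, duration, radius,
                   amplitude=total_current_A / (vol * beta_cm))

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


@dataclass
class SimulationState:
    """Nodal fields: Vm/v on heart nodes, phi (= Ve on heart, V on torso)."""

    Vm: np.ndarray
    v: np.ndarray
    phi: np.ndarray
    t: float = 0.0


@dataclass
class Operators:
    mesh: HeartTorsoMesh
    params: RegionParameterSet
    cfg: SolverConfig
    heart_nodes: np.ndarray  # global indices, sorted
    Ki: sp.csr_matrix  # intracellular stiffness, heart-local numbering
    A_ell: sp.csr_matrix  # elliptic operator, global numbering (pre-BC)
    M: np.ndarray  # lumped heart mass vector (heart-local)
    kinetics: NodalKinetics
    node_labels: np.ndarray  # per mesh node
    ground_node: int | None = None
    lu_ell: object = None
    lu_par: object = None
    stim_cache: dict = field(default_factory=dict)

    @property
    def constrained(self) -> bool:
        return self.lu_ell is not None


def assemble(mesh: HeartTorsoMesh, params: RegionParameterSet,
             cfg: SolverConfig) -> Operators:
    """Assemble bidomain stiffness/mass operators with regional conductivities."""
    hm = mesh.heart_tet_mask()
    heart_tets = mesh.tets[hm]
    heart_labels = mesh.labels[hm]
    heart_nodes = np.unique(heart_tets)
    glob2heart = -np.ones(mesh.n_nodes, dtype=np.int64)
    glob2heart[heart_nodes] = np.arange(len(heart_nodes))

    sig_i = np.empty(len(heart_tets))
    sig_ie = np.empty(len(heart_tets))
    for lb in np.unique(heart_labels):
        if lb not in params.params:
            raise SolverError(f"missing parameters for subdomain {geometry.LABEL_NAMES[lb]}")
        p = params.params[lb]
        m = heart_labels == lb
        sig_i[m] = p.sigma_i
        sig_ie[m] = p.sigma_i + p.sigma_e

    local_tets = glob2heart[heart_tets]
    Ki = fem.stiffness_matrix(mesh.nodes[heart_nodes], local_tets, sig_i,
                              n_nodes=len(heart_nodes))
    M = fem.lumped_mass(mesh.nodes[heart_nodes], local_tets,
                        n_nodes=len(heart_nodes))

    A_ell = fem.stiffness_matrix(mesh.nodes, heart_tets, sig_ie,
                                 n_nodes=mesh.n_nodes)
    tm = mesh.labels == TORSO
    if tm.any():
        torso_tets = mesh.tets[tm]
        A_ell = A_ell + fem.stiffness_matrix(
            mesh.nodes, torso_tets, np.full(tm.sum(), cfg.sigma_b),
            n_nodes=mesh.n_nodes)

    node_labels = mesh.node_labels()
    kin = NodalKinetics(node_labels[heart_nodes], params)
    return Operators(mesh, params, cfg, heart_nodes, Ki.tocsr(), A_ell.tocsr(),
                     M, kin, node_labels)


def apply_boundary_conditions(ops: Operators, mesh: HeartTorsoMesh | None = None,
                              ground_node: int | None = None) -> Operators:
    """Impose the ground Dirichlet condition and factorize the linear systems.

    The ground defaults to the RL electrode node on an embedded mesh, or to
    node 0 on a heart-only mesh (the extracellular reference is arbitrary).
    """
    mesh = mesh or ops.mesh
    if ground_node is None:
        if mesh.has_torso:
            layout = geometry.place_electrodes(mesh)
            ground_node = layout.ground_node
        else:
            ground_node = 0
    outer = mesh.outer_nodes()
    if mesh.has_torso and ground_node not in outer:
        raise SolverError("ground node must lie on the torso outer surface")

    A = ops.A_ell.tolil(copy=True)
    A.rows[ground_node] = [ground_node]
    A.data[ground_node] = [1.0]
    A = A.tocsr().T.tolil()  # symmetric elimination (ground value is zero)
    A.rows[ground_node] = [ground_node]
    A.data[ground_node] = [1.0]
    A = A.tocsr().T.tocsc()

    cfg = ops.cfg
    Apar = sp.diags(ops.M * cfg.chi / cfg.dt) + ops.Ki
    ops.ground_node = int(ground_node)
    t0 = _time.perf_counter()
    ops.lu_ell = spla.splu(A)
    ops.lu_par = spla.splu(Apar.tocsc())
    log.info("factorized systems (%d elliptic / %d parabolic dof) in %.1fs",
             A.shape[0], Apar.shape[0], _time.perf_counter() - t0)
    return ops


def stimulus_current(protocol, t: float, mesh: HeartTorsoMesh,
                     ops: Operators | None = None) -> np.ndarray:
    """Nodal stimulus rate density (V/s) on heart nodes at time t.

    The support of each event is the set of heart nodes inside its sphere
    while start <= t < start + duration. An event whose sphere contains no
    heart node is logged and ignored.
    """
    if ops is not None:
        heart_nodes = ops.heart_nodes
        cache = ops.stim_cache
    else:
        hm = mesh.heart_tet_mask()
        heart_nodes = np.unique(mesh.tets[hm])
        cache = {}
    out = np.zeros(len(heart_nodes))
    pts = mesh.nodes[heart_nodes]
    for ev in protocol:
        if not ev.active(t):
            continue
        key = (tuple(ev.center), ev.radius)
        if key not in cache:
            d2 = np.einsum("ij,ij->i", pts - np.asarray(ev.center),
                           pts - np.asarray(ev.center))
            idx = np.flatnonzero(d2 <= ev.radius**2)
            if idx.size == 0:
                log.warning("stimulus at %s r=%.1fmm contains no heart node; skipped",
                            ev.center, ev.radius * 1e3)
            cache[key] = idx
        out[cache[key]] += ev.amplitude
    return out


def step(state: SimulationState, ops: Operators, protocol, cfg: SolverConfig | None = None
         ) -> SimulationState:
    """Advance one time step with the configured scheme."""
    cfg = cfg or ops.cfg
    if not ops.constrained:
        raise SolverError("apply_boundary_conditions must be called before stepping")
    dt = cfg.dt
    hn = ops.heart_nodes
    stim = stimulus_current(protocol, state.t, ops.mesh, ops)

    Vm_r, v_new = ops.kinetics.reaction_step(state.Vm, state.v, dt, stim=stim)

    chi = cfg.chi
    phi = state.phi
    Vm_new = state.Vm
    n_iter = 1 if cfg.scheme == "semi_implicit" else cfg.coupling_maxit
    for it in range(n_iter):
        rhs = (chi / dt) * ops.M * Vm_r - ops.Ki @ phi[hn]
        Vm_prev = Vm_new
        Vm_new = ops.lu_par.solve(rhs)
        rhs_g = np.zeros(ops.mesh.n_nodes)
        rhs_g[hn] = -(ops.Ki @ Vm_new)
        rhs_g[ops.ground_node] = 0.0
        phi = ops.lu_ell.solve(rhs_g)
        if cfg.scheme == "semi_implicit":
            break
        dv = np.max(np.abs(Vm_new - Vm_prev))
        if dv < cfg.coupling_tol * max(1.0, np.max(np.abs(Vm_new))):
            break
    else:
        raise SolverError(
            f"fully_coupled fixed point did not converge at t={state.t:.4f}s "
            f"(residual {dv:.3e})")
    if not (np.all(np.isfinite(Vm_new)) and np.all(np.isfinite(phi))):
        raise SolverError(f"non-finite field at t={state.t + dt:.4f}s")
    return SimulationState(Vm_new, v_new, phi, state.t + dt)


@dataclass
class SimulationResult:
    """Sampled nodal fields plus reproducibility metadata.

    Vm and Ve are stored per heart node, the torso potential per outer-surface
    node; all snapshots are float32 to keep long runs memory-friendly.
    """

    times: np.ndarray
    heart_nodes: np.ndarray
    outer_nodes: np.ndarray
    Vm: np.ndarray  # (ns, nh)
    Ve: np.ndarray | None  # (ns, nh)
    V_outer: np.ndarray  # (ns, no)
    v_final: np.ndarray
    mesh: HeartTorsoMesh
    cfg: SolverConfig
    metadata: dict
    partial: bool = False

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def node_trace(self, node: int) -> np.ndarray:
        """Torso/extracellular potential trace at a global mesh node."""
        j = np.flatnonzero(self.outer_nodes == node)
        if j.size:
            return self.V_outer[:, j[0]].astype(float)
        j = np.flatnonzero(self.heart_nodes == node)
        if j.size and self.Ve is not None:
            return self.Ve[:, j[0]].astype(float)
        raise KeyError(f"node {node} was not sampled")

    def vm_trace(self, node: int) -> np.ndarray:
        j = np.flatnonzero(self.heart_nodes == node)
        if not j.size:
            raise KeyError(f"node {node} is not a heart node")
        return self.Vm[:, j[0]].astype(float)

    def nearest_heart_node(self, point) -> int:
        pts = self.mesh.nodes[self.heart_nodes]
        return int(self.heart_nodes[np.argmin(
            np.linalg.norm(pts - np.asarray(point), axis=1))])

    def snapshot_index(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))


def initial_state(ops: Operators, cfg: SolverConfig) -> SimulationState:
    """Published initial conditions: Vi = -60 mV at the SAN, -85 mV elsewhere,
    all extracellular potentials and recovery variables zero (so Vm = Vi)."""
    labs = ops.node_labels[ops.heart_nodes]
    Vm = np.full(len(ops.heart_nodes), cfg.other_rest)
    Vm[labs == SAN] = cfg.san_rest
    v = np.zeros_like(Vm)
    phi = np.zeros(ops.mesh.n_nodes)
    return SimulationState(Vm, v, phi, 0.0)


def run(mesh: HeartTorsoMesh, params: RegionParameterSet, protocol=(),
        cfg: SolverConfig | None = None, ground_node: int | None = None,
        ops: Operators | None = None, init: SimulationState | None = None
        ) -> SimulationResult:
    """Full time loop from 0 to t_end with periodic field sampling."""
    cfg = cfg or SolverConfig()
    if ops is None:
        ops = assemble(mesh, params, cfg)
        apply_boundary_conditions(ops, mesh, ground_node)
    state = init or initial_state(ops, cfg)

    every = max(1, int(round((cfg.sample_interval or cfg.dt) / cfg.dt)))
    n_steps = int(round(cfg.t_end / cfg.dt))
    outer = mesh.outer_nodes()
    times, Vm_s, Ve_s, Vo_s = [], [], [], []

    def snap(s):
        times.append(s.t)
        Vm_s.append(s.Vm.astype(np.float32))
        if cfg.store_ve:
            Ve_s.append(s.phi[ops.heart_nodes].astype(np.float32))
        Vo_s.append(s.phi[outer].astype(np.float32))

    snap(state)
    t0 = _time.perf_counter()
    partial = False
    err = None
    for i in range(n_steps):
        try:
            state = step(state, ops, protocol, cfg)
        except SolverError as exc:
            partial = True
            err = exc
            log.error("stepping aborted at t=%.4fs: %s", state.t, exc)
            break
        if (i + 1) % every == 0:
            snap(state)
        if (i + 1) % max(1, n_steps // 10) == 0:
            log.info("t=%.3fs (%d/%d steps, %.1fs elapsed)", state.t, i + 1,
                     n_steps, _time.perf_counter() - t0)

    result = SimulationResult(
        times=np.asarray(times),
        heart_nodes=ops.heart_nodes,
        outer_nodes=outer,
        Vm=np.asarray(Vm_s),
        Ve=np.asarray(Ve_s) if cfg.store_ve else None,
        V_outer=np.asarray(Vo_s),
        v_final=state.v,
        mesh=mesh,
        cfg=cfg,
        metadata={
            "mesh_hash": mesh.content_hash(),
            "model_id": params.model_id,
            "scheme": cfg.scheme,
            "dt": cfg.dt,
            "t_end": cfg.t_end,
            "ground_node": ops.ground_node,
            "protocol": [
                {"center": list(map(float, ev.center)), "start": ev.start,
                 "duration": ev.duration, "radius": ev.radius,
                 "amplitude": ev.amplitude}
                for ev in protocol
            ],
        },
        partial=partial,
    )
    if partial:
        raise SolverError(str(err), partial_result=result)
    return result


# ---------------------------------------------------------------------------
# Protocol helpers and cable surrogate
# ---------------------------------------------------------------------------

def standard_protocol(mesh: HeartTorsoMesh, amplitude: float = 200.0,
                      radius: float | None = None) -> list:
    """The three-stimulus sequence bridging isolated chambers.

    Spherical stimuli at the sinoatrial-node site (t = 2 ms), the Bachmann's
    bundle site on the left atrium (t = 28 ms) and the atrioventricular-node
    site feeding the ventricular conduction tree (t = 150 ms), each lasting
    2 ms. Sphere radii default to a couple of mesh spacings so every event
    covers mesh nodes.
    """
    cfg = mesh.config or geometry.GeometryConfig()
    if radius is None:
        radius = max(4e-3, 2.0 * cfg.h_heart)
    san = np.asarray(cfg.san_center)
    bb = np.asarray(cfg.bb_center)
    # the "AVN" stimulus feeds the ventricular conduction tree where the
    # bundle bar meets the septal Purkinje shell (endocardial takeover site)
    avn = np.array([cfg.avn_center_xy[0], cfg.avn_center_xy[1],
                    0.5 * (cfg.bnl_z[0] + cfg.bnl_z[1])])
    centers = [san, bb, avn]
    if mesh.has_torso:
        R = geometry._rotation_matrix(cfg.rotation_deg)
        centers = [c @ R.T + np.asarray(cfg.heart_offset) for c in centers]
    starts = (2e-3, 28e-3, 150e-3)
    return [StimulusEvent(tuple(c), s, 2e-3, radius, amplitude)
            for c, s in zip(centers, starts)]


def bar_conduction_velocity(params, sigma_scale: float = 1.0,
                            length: float = 40e-3, width: float = 3e-3,
                            h: float = 1e-3, dt: float = 0.25e-3,
                            threshold: float = -0.02,
                            scheme: str = "semi_implicit") -> float:
    """Planar-wave conduction velocity (m/s) on a thin-bar mesh.

    Stimulates one end and times the threshold crossings at 35% and 75% of
    the bar length -- the cable-theory surrogate used to verify that velocity
    scales with the square root of conductivity.
    """
    from .geometry import VENTRICLES, build_bar_mesh

    mesh = build_bar_mesh(length, width, h)
    p = params.scaled_conductivity([VENTRICLES], sigma_scale)
    cfg = SolverConfig(dt=dt, t_end=0.12, scheme=scheme, store_ve=False)
    ev = StimulusEvent((0.0, width / 2, width / 2), start=1e-3, duration=2e-3,
                       radius=2.5 * h, amplitude=300.0)
    res = run(mesh, p, [ev], cfg)
    xa, xb = 0.35 * length, 0.75 * length
    na = res.nearest_heart_node((xa, width / 2, width / 2))
    nb = res.nearest_heart_node((xb, width / 2, width / 2))
    ta = _first_crossing(res.times, res.vm_trace(na), threshold)
    tb = _first_crossing(res.times, res.vm_trace(nb), threshold)
    if ta is None or tb is None or tb <= ta:
        raise SolverError("wave did not traverse the bar")
    xa_real = res.mesh.nodes[na, 0]
    xb_real = res.mesh.nodes[nb, 0]
    return float((xb_real - xa_real) / (tb - ta))


def _first_crossing(times, trace, threshold):
    idx = np.flatnonzero(np.asarray(trace) >= threshold)
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = trace[i - 1], trace[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))
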