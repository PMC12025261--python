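"""Modified FitzHugh-Nagumo membrane kinetics and the regional parameter registry.

Two variants are used: a self-oscillating form for the sinoatrial node
(pacemaker) and the Rogers-McCulloch form for all other cardiac tissue,
whose recovery current is multiplied by (Vm - B) to suppress the
nonphysiological hyperpolarization of the original FHN model.

With u = (Vm - B)/A the ionic current and recovery dynamics are

    Iion = k*c1*(Vm - B)*(a - u)*(1 - u) + k*c2*v          (SAN variant)
    Iion = k*c1*(Vm - B)*(a - u)*(1 - u) + k*c2*v*(Vm - B) (Rogers-McCulloch)
    dv/dt = k*e*(u - d*v - b)

where A (V) scales the action-potential amplitude, B (V) is the resting
potential, k (1/s) the time scale, e the action-potential duration control,
and a, b, c1, c2, d shape parameters. The membrane equation used by the
tissue solver is the normalized form dVm/dt = -Iion + diffusion.

Three published regional parameter sets ("Model 1", "Model 2", "Model 3")
are built in; Model 3 is the set whose simulated 12-lead ECG morphology is
closest to clinical recordings and is the default elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (ATRIA, AVN, BNL, HIS, LABEL_NAMES, NAME_TO_LABEL, PKJ,
                       SAN, VENTRICLES)

SAN_OSCILLATOR = "SAN_OSCILLATOR"
ROGERS_MCCULLOCH = "ROGERS_MCCULLOCH"

HEART_SUBDOMAIN_ORDER = (SAN, ATRIA, AVN, HIS, BNL, PKJ, VENTRICLES)


class IonicError(ValueError):
    pass


@dataclass(frozen=True)
class FHNParams:
    """Per-subdomain membrane and conductivity parameters (SI units).

    A and B are in volts, k in 1/s, sigma_i / sigma_e in S/m; the remaining
    shape parameters are dimensionless.
    """

    a: float
    b: float
    c1: float
    c2: float
    d: float
    e: float
    A: float
    B: float
    k: float
    sigma_i: float
    sigma_e: float
    variant: str = ROGERS_MCCULLOCH

    def __post_init__(self):
        if self.A <= 0 or self.k <= 0:
            raise IonicError("A and k must be positive")
        if self.sigma_i <= 0 or self.sigma_e <= 0:
            raise IonicError("conductivities must be positive")
        if self.variant not in (SAN_OSCILLATOR, ROGERS_MCCULLOCH):
            raise IonicError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class CellState:
    Vm: float
    v: float


def _unpack(state):
    if hasattr(state, "Vm"):
        return np.asarray(state.Vm, float), np.asarray(state.v, float)
    Vm, v = state
    return np.asarray(Vm, float), np.asarray(v, float)


def iion(state, p: FHNParams):
    """Ionic current (V/s in the normalized membrane equation)."""
    Vm, v = _unpack(state)
    u = (Vm - p.B) / p.A
    cubic = p.k * p.c1 * (Vm - p.B) * (p.a - u) * (1.0 - u)
    if p.variant == SAN_OSCILLATOR:
        return cubic + p.k * p.c2 * v
    return cubic + p.k * p.c2 * v * (Vm - p.B)


def dvdt(state, p: FHNParams):
    """Recovery-variable rate dv/dt = k*e*((Vm-B)/A - d*v - b)."""
    Vm, v = _unpack(state)
    u = (Vm - p.B) / p.A
    return p.k * p.e * (u - p.d * v - p.b)


def integrate_single_cell(p: FHNParams, initial: CellState, duration_s: float,
                          dt_s: float, stimulus=None):
    """Space-clamped integration of dVm/dt = -Iion (+ stimulus), dv/dt as above.

    Uses classical RK4 at fixed dt; raises on non-finite states. ``stimulus``
    is an optional callable t -> V/s added to dVm/dt. Returns (t, Vm, v).
    """
    n = int(round(duration_s / dt_s))
    t = np.arange(n + 1) * dt_s
    Vm = np.empty(n + 1)
    v = np.empty(n + 1)
    Vm[0], v[0] = initial.Vm, initial.v
    stim = stimulus or (lambda _t: 0.0)

    def rhs(ti, y):
        s = CellState(y[0], y[1])
        return np.array([-iion(s, p) + stim(ti), dvdt(s, p)])

    y = np.array([initial.Vm, initial.v], dtype=float)
    for i in range(n):
        ti = t[i]
        k1 = rhs(ti, y)
        k2 = rhs(ti + dt_s / 2, y + dt_s / 2 * k1)
        k3 = rhs(ti + dt_s / 2, y + dt_s / 2 * k2)
        k4 = rhs(ti + dt_s, y + dt_s * k3)
        y = y + dt_s / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IonicError(f"non-finite state at t={t[i+1]:.6f}s: {y}")
        Vm[i + 1], v[i + 1] = y
    return t, Vm, v


# ---------------------------------------------------------------------------
# Parameter registry (regional values per published model)
# ---------------------------------------------------------------------------

_MV = 1e-3
_MS_PER_M = 1e-3  # mS/m -> S/m

# Stored literally as published (A, B in mV; sigma in mS/m; converted below).
# Columns: a, b, c1, c2, d, e, A_mV, B_mV, k, sigma_e_mSm, sigma_i_mSm
_TABLE = {
    "Model1": {
        "SAN": (-0.60, -0.30, 1000.0, 1.0, 0.0, 0.0660, 33.0, -22.0, 1000.0, 0.5, 0.5),
        "ATRIA": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0132, 140.0, -85.0, 1000.0, 8.0, 8.0),
        "AVN": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0132, 140.0, -85.0, 1000.0, 0.5, 0.5),
        "HIS": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0050, 140.0, -85.0, 1000.0, 10.0, 10.0),
        "BNL": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0022, 140.0, -85.0, 1000.0, 15.0, 15.0),
        "PKJ": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0047, 140.0, -85.0, 1000.0, 35.0, 35.0),
        "VENTRICLES": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0060, 140.0, -85.0, 1000.0, 8.0, 8.0),
    },
    "Model2": {
        "SAN": (-1.0, -0.29e-3, 1.9, 1e-3, 0.0, 0.060, 35.0, -30.0, 1000.0, 0.5, 0.5),
        "ATRIA": (0.13, 0.0, 2.6, 1.0, 1.0, 0.010, 140.0, -85.0, 1000.0, 8.0, 8.0),
        "AVN": (0.13, 0.0, 2.6, 1.0, 1.0, 0.010, 140.0, -85.0, 1000.0, 0.5, 0.5),
        "HIS": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0045, 140.0, -85.0, 1000.0, 10.0, 10.0),
        "BNL": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0028, 140.0, -85.0, 1000.0, 15.0, 15.0),
        "PKJ": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0043, 140.0, -85.0, 1000.0, 35.0, 35.0),
        "VENTRICLES": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0050, 140.0, -85.0, 1000.0, 8.0, 8.0),
    },
    "Model3": {
        "SAN": (-1.0, -0.29e-3, 1.9, 1e-3, 0.0, 0.035, 35.0, -30.0, 1000.0, 0.5, 0.5),
        "ATRIA": (0.13, 0.0, 2.6, 1.0, 1.0, 0.020, 140.0, -85.0, 1000.0, 4.0, 4.0),
        "AVN": (0.13, 0.0, 2.6, 1.0, 1.0, 0.010, 140.0, -85.0, 1000.0, 0.5, 0.5),
        "HIS": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0045, 140.0, -85.0, 1000.0, 10.0, 10.0),
        "BNL": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0028, 140.0, -85.0, 1000.0, 15.0, 15.0),
        "PKJ": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0043, 140.0, -85.0, 1000.0, 35.0, 35.0),
        "VENTRICLES": (0.13, 0.0, 2.6, 1.0, 1.0, 0.0050, 140.0, -85.0, 1000.0, 4.0, 4.0),
    },
}

MODEL_IDS = tuple(_TABLE)


@dataclass(frozen=True)
class RegionParameterSet:
    """Subdomain-label -> FHNParams mapping for one regional model."""

    model_id: str
    params: dict  # int label -> FHNParams

    def __post_init__(self):
        missing = [LABEL_NAMES[lb] for lb in HEART_SUBDOMAIN_ORDER if lb not in self.params]
        if missing:
            raise IonicError(f"missing parameters for subdomains: {missing}")

    def __getitem__(self, label: int) -> FHNParams:
        return self.params[label]

    def scaled_conductivity(self, labels, factor: float) -> "RegionParameterSet":
        """New set with sigma_i and sigma_e of the given subdomains scaled."""
        if factor <= 0:
            raise IonicError("conductivity scale factor must be positive")
        new = dict(self.params)
        for lb in labels:
            p = new[lb]
            new[lb] = replace(p, sigma_i=p.sigma_i * factor, sigma_e=p.sigma_e * factor)
        return RegionParameterSet(self.model_id, new)

    def to_dict(self) -> dict:
        out = {}
        for lb in HEART_SUBDOMAIN_ORDER:
            p = self.params[lb]
            out[LABEL_NAMES[lb]] = {
                "a": p.a, "b": p.b, "c1": p.c1, "c2": p.c2, "d": p.d, "e": p.e,
                "A_V": p.A, "B_V": p.B, "k_per_s": p.k,
                "sigma_i_S_per_m": p.sigma_i, "sigma_e_S_per_m": p.sigma_e,
                "variant": p.variant,
            }
        return {"model_id": self.model_id, "subdomains": out}


def get_model(model) -> RegionParameterSet:
    """Built-in regional parameter set; accepts 1/2/3 or 'Model3'."""
    if isinstance(model, int):
        model = f"Model{model}"
    if model not in _TABLE:
        raise IonicError(f"unknown parameter model {model!r} (use 1, 2 or 3)")
    params = {}
    for name, row in _TABLE[model].items():
        a, b, c1, c2, d, e, A_mV, B_mV, k, se, si = row
        lb = NAME_TO_LABEL[name]
        params[lb] = FHNParams(
            a=a, b=b, c1=c1, c2=c2, d=d, e=e,
            A=A_mV * _MV, B=B_mV * _MV, k=k,
            sigma_i=si * _MS_PER_M, sigma_e=se * _MS_PER_M,
            variant=SAN_OSCILLATOR if name == "SAN" else ROGERS_MCCULLOCH,
        )
    return RegionParameterSet(model, params)


def raw_table() -> dict:
    """The registry exactly as published (mV / mS units, no conversion)."""
    return {m: {s: tuple(r) for s, r in rows.items()} for m, rows in _TABLE.items()}


# ---------------------------------------------------------------------------
# Vectorized nodal reaction update used by the tissue solver
# ---------------------------------------------------------------------------

class NodalKinetics:
    """Per-node parameter arrays + implicit reaction step for the PDE solver.

    The reaction half-step solves the backward-Euler system

        Vm' = Vm - dt*Iion(Vm', v') + dt*s
        v'  = v + dt*g(Vm', v')

    per node. v' is linear in Vm', so elimination leaves a scalar (quartic)
    equation per node solved by damped Newton. This stays stable for the very
    stiff SAN row of Model 1 (k*c1 = 1e6 1/s) where explicit substepping at
    dt = 1 ms is hopeless.
    """

    FIELDS = ("a", "b", "c1", "c2", "d", "e", "A", "B", "k")

    def __init__(self, node_labels: np.ndarray, params: RegionParameterSet):
        labs = np.asarray(node_labels)
        self.n = len(labs)
        arrays = {f: np.zeros(self.n) for f in self.FIELDS}
        self.is_san = np.zeros(self.n, dtype=bool)
        present = np.unique(labs)
        for lb in present:
            if lb not in params.params:
                raise IonicError(f"no parameters for node subdomain {lb}")
            p = params.params[lb]
            m = labs == lb
            for f in self.FIELDS:
                arrays[f][m] = getattr(p, f)
            if p.variant == SAN_OSCILLATOR:
                self.is_san[m] = True
        for f, arr in arrays.items():
            setattr(self, f, arr)

    def iion(self, Vm: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = (Vm - self.B) / self.A
        cubic = self.k * self.c1 * (Vm - self.B) * (self.a - u) * (1.0 - u)
        rec = self.k * self.c2 * v
        return cubic + np.where(self.is_san, rec, rec * (Vm - self.B))

    def dvdt(self, Vm: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = (Vm - self.B) / self.A
        return self.k * self.e * (u - self.d * v - self.b)

    def _residual_and_slope(self, Vp, Vn, vn, dt, s):
        ke = self.k * self.e
        den = 1.0 + dt * ke * self.d
        vp = (vn + dt * ke * ((Vp - self.B) / self.A - self.b)) / den
        dvp_dV = dt * ke / (self.A * den)
        u = (Vp - self.B) / self.A
        cub = self.k * self.c1 * (Vp - self.B) * (self.a - u) * (1.0 - u)
        dcub = self.k * self.c1 * (
            (self.a - u) * (1.0 - u)
            - (Vp - self.B) / self.A * (1.0 - u)
            - (Vp - self.B) / self.A * (self.a - u)
        )
        kc2 = self.k * self.c2
        rec = np.where(self.is_san, kc2 * vp, kc2 * vp * (Vp - self.B))
        drec = np.where(
            self.is_san,
            kc2 * dvp_dV,
            kc2 * (dvp_dV * (Vp - self.B) + vp),
        )
        F = Vp - Vn + dt * (cub + rec) - dt * s
        dF = 1.0 + dt * (dcub + drec)
        return F, dF, vp

    def reaction_step(self, Vm, v, dt, stim=None, tol=1e-12, maxit=60,
                      _depth=0):
        """Backward-Euler reaction update; returns (Vm', v').

        Nodes whose damped Newton iteration does not converge (the
        backward-Euler cubic can have multiple roots at large dt) are
        recomputed with two half steps, recursively.
        """
        s = np.zeros_like(Vm) if stim is None else stim
        Vp = Vm.copy()
        scale = np.maximum(self.A, 1e-3)
        converged = np.zeros(Vp.shape, dtype=bool)
        for it in range(maxit):
            F, dF, vp = self._residual_and_slope(Vp, Vm, v, dt, s)
            dF = np.where(np.abs(dF) < 1e-12, 1e-12, dF)
            step = F / dF
            # damp steps to a fraction of the amplitude scale for robustness
            step = np.clip(step, -0.5 * scale, 0.5 * scale)
            Vp = Vp - step
            converged = np.abs(step) / scale < tol
            if converged.all():
                break
        _, _, vp = self._residual_and_slope(Vp, Vm, v, dt, s)
        bad = ~converged | ~np.isfinite(Vp) | ~np.isfinite(vp)
        if bad.any():
            if _depth >= 10:
                raise IonicError("reaction Newton failed to converge")
            sub = _Subset(self, bad)
            Vh, vh = sub.reaction_step(Vm[bad], v[bad], dt / 2, s[bad],
                                       tol, maxit, _depth + 1)
            Vh, vh = sub.reaction_step(Vh, vh, dt / 2, s[bad],
                                       tol, maxit, _depth + 1)
            Vp[bad], vp[bad] = Vh, vh
        if not (np.all(np.isfinite(Vp)) and np.all(np.isfinite(vp))):
            raise IonicError("non-finite state after reaction step")
        return Vp, vp


class _Subset:
    """View of a NodalKinetics restricted to a node mask (fallback path)."""

    def __init__(self, kin: "NodalKinetics", mask):
        for f in NodalKinetics.FIELDS:
            setattr(self, f, getattr(kin, f)[mask])
        self.is_san = kin.is_san[mask]
        self.n = int(mask.sum())

    _residual_and_slope = NodalKinetics._residual_and_slope
    reaction_step = NodalKinetics.reaction_step
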