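"""Derivation of the standard 12-lead ECG, BSPMs and waveform features.

Electrode potentials are sampled from the torso field at the ten probe
nodes. Limb leads follow the Einthoven/Goldberger definitions

    I = VL - VR,  II = VF - VR,  III = VF - VL,
    aVR = (2VR - VL - VF)/2,  aVL = (2VL - VR - VF)/2,  aVF = (2VF - VR - VL)/2

and the precordial leads are referenced to the Wilson central terminal
VCT = (VL + VR + VF)/3. P/QRS/T features are located by windowed extremum
search keyed to the stimulus protocol; chamber depolarization/repolarization
completion times are defined by a nodal Vm threshold crossed by >= 95% of
the chamber's nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ATRIA, VENTRICLES, ElectrodeLayout, HeartTorsoMesh
from .solver import SimulationResult

LIMB = ("RA", "LA", "RL", "LL")
PRECORDIAL = ("V1", "V2", "V3", "V4", "V5", "V6")
LEADS = ("I", "II", "III", "aVR", "aVL", "aVF") + PRECORDIAL

DEPOL_THRESHOLD = -0.02  # V; Vm above this counts as depolarized
COMPLETION_FRACTION = 0.95


class ECGError(ValueError):
    pass


def sample_electrodes(result: SimulationResult, layout: ElectrodeLayout) -> pd.DataFrame:
    """Per-probe potential traces (columns RA..V6, index = time in s)."""
    data = {}
    for name in layout.names:
        data[name] = result.node_trace(layout.node_ids[name])
    df = pd.DataFrame(data, index=pd.Index(result.times, name="time"))
    return df


def limb_leads(VR, VL, VF) -> dict:
    """Einthoven and Goldberger-augmented leads from the limb potentials."""
    VR, VL, VF = (np.asarray(x, float) for x in (VR, VL, VF))
    if not (VR.shape == VL.shape == VF.shape):
        raise ECGError("limb traces must have equal length")
    return {
        "I": VL - VR,
        "II": VF - VR,
        "III": VF - VL,
        "aVR": (2 * VR - VL - VF) / 2,
        "aVL": (2 * VL - VR - VF) / 2,
        "aVF": (2 * VF - VR - VL) / 2,
    }


def wilson_central_terminal(VR, VL, VF) -> np.ndarray:
    return (np.asarray(VL, float) + np.asarray(VR, float) + np.asarray(VF, float)) / 3.0


def precordial_leads(chest: dict, VR, VL, VF) -> dict:
    """V1..V6 leads: chest electrode minus the Wilson central terminal."""
    vct = wilson_central_terminal(VR, VL, VF)
    out = {}
    for name in PRECORDIAL:
        trace = np.asarray(chest[name], float)
        if trace.shape != vct.shape:
            raise ECGError("precordial traces must match limb trace length")
        out[name] = trace - vct
    return out


@dataclass
class ECGTraces:
    """Time axis, raw electrode potentials and the 12 derived leads (V)."""

    time: np.ndarray
    electrodes: pd.DataFrame
    leads: pd.DataFrame
    vct: np.ndarray

    def lead(self, name: str) -> np.ndarray:
        return self.leads[name].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = self.leads.copy()
        df.insert(0, "time", self.time)
        return df


def twelve_lead(result: SimulationResult, layout: ElectrodeLayout) -> ECGTraces:
    """Full 12-lead ECG from a simulation (VR=RA, VL=LA, VF=LL probes)."""
    el = sample_electrodes(result, layout)
    VR, VL, VF = el["RA"].to_numpy(), el["LA"].to_numpy(), el["LL"].to_numpy()
    leads = limb_leads(VR, VL, VF)
    leads.update(precordial_leads({n: el[n].to_numpy() for n in PRECORDIAL}, VR, VL, VF))
    ldf = pd.DataFrame(leads, index=el.index)[list(LEADS)]
    return ECGTraces(result.times.copy(), el, ldf, wilson_central_terminal(VR, VL, VF))


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class WaveFeatures:
    """P/QRS/T morphology plus chamber activation/recovery completion times.

    Amplitudes are baseline-corrected signed extrema (V) on the designated
    lead; times in seconds. Absent waves are None, never fabricated.
    """

    lead: str = "II"
    p_amplitude: float | None = None
    p_time: float | None = None
    p_duration: float | None = None
    qrs_amplitude: float | None = None
    qrs_time: float | None = None
    qrs_duration: float | None = None
    t_amplitude: float | None = None
    t_time: float | None = None
    t_duration: float | None = None
    atrial_depol_completion: float | None = None
    atrial_repol_completion: float | None = None
    ventricular_depol_completion: float | None = None
    ventricular_repol_completion: float | None = None
    threshold: float = DEPOL_THRESHOLD
    extra: dict = field(default_factory=dict)

    @property
    def t_polarity(self):
        if self.t_amplitude is None:
            return None
        return 1 if self.t_amplitude > 0 else -1

    @property
    def qrs_polarity(self):
        if self.qrs_amplitude is None:
            return None
        return 1 if self.qrs_amplitude > 0 else -1

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "lead", "p_amplitude", "p_time", "p_duration",
            "qrs_amplitude", "qrs_time", "qrs_duration",
            "t_amplitude", "t_time", "t_duration",
            "atrial_depol_completion", "atrial_repol_completion",
            "ventricular_depol_completion", "ventricular_repol_completion",
            "threshold")}
        d["t_polarity"] = self.t_polarity
        d["qrs_polarity"] = self.qrs_polarity
        return d


def detect_wave(time, signal, window, baseline=0.0, min_amplitude=0.0,
                width_fraction=0.1, exclude=None):
    """Signed extremum of (signal - baseline) inside [t0, t1).

    Returns (amplitude, peak_time, duration) or None when the window holds no
    deflection above ``min_amplitude``. The duration is the contiguous span
    around the peak where the deflection stays above ``width_fraction`` of
    the peak value. ``exclude`` is an optional list of (t0, t1) intervals
    (e.g. stimulus pulse artifacts) removed from the peak search.
    """
    time = np.asarray(time, float)
    x = np.asarray(signal, float) - baseline
    t0, t1 = window
    m = (time >= t0) & (time < t1)
    for a, b in exclude or ():
        m &= ~((time >= a) & (time <= b))
    if not m.any():
        return None
    idx = np.flatnonzero(m)
    seg = x[idx]
    i = int(np.argmax(np.abs(seg)))
    amp = float(seg[i])
    if abs(amp) <= min_amplitude:
        return None
    peak_t = float(time[idx[i]])
    lvl = width_fraction * abs(amp)
    above = np.sign(amp) * seg >= lvl
    lo = i
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i
    while hi < len(seg) - 1 and above[hi + 1]:
        hi += 1
    duration = float(time[idx[hi]] - time[idx[lo]])
    return amp, peak_t, duration


def chamber_completion_times(result: SimulationResult,
                             threshold: float = DEPOL_THRESHOLD,
                             fraction: float = COMPLETION_FRACTION) -> dict:
    """Depolarization/repolarization completion per chamber.

    Depolarization completion: first time >= ``fraction`` of the chamber's
    nodes have crossed ``threshold`` at least once (the activation wavefront
    has reached them); repolarization completion: first subsequent time the
    same fraction is simultaneously back below threshold. Chambers are the
    working-myocardium subdomains (ATRIA, VENTRICLES).
    """
    labs = result.mesh.node_labels()[result.heart_nodes]
    out = {}
    for name, lb in (("atrial", ATRIA), ("ventricular", VENTRICLES)):
        m = labs == lb
        if not m.any():
            out[f"{name}_depol_completion"] = None
            out[f"{name}_repol_completion"] = None
            continue
        activated = np.maximum.accumulate(result.Vm[:, m] > threshold, axis=0)
        frac_above = activated.mean(axis=1)
        dep = np.flatnonzero(frac_above >= fraction)
        if dep.size == 0:
            out[f"{name}_depol_completion"] = None
            out[f"{name}_repol_completion"] = None
            continue
        t_dep = float(result.times[dep[0]])
        out[f"{name}_depol_completion"] = t_dep
        frac_below = ((result.Vm[:, m] <= threshold).mean(axis=1) >= fraction)
        rep = np.flatnonzero(frac_below & (np.arange(len(result.times)) > dep[0]))
        out[f"{name}_repol_completion"] = (
            float(result.times[rep[0]]) if rep.size else None)
    return out


def default_windows(result: SimulationResult, protocol=(), pad: float = 6e-3) -> dict:
    """P/QRS/T search windows keyed to the stimulus protocol.

    The P window opens shortly after the first (atrial) stimulus and closes
    when atrial depolarization completes (this keeps the atrial
    repolarization deflection out of the P search); the QRS window follows
    the ventricular stimulus until shortly after ventricular depolarization
    completes; the T window covers the remainder. ``pad`` skips the stimulus
    pulse artifact. Without a protocol, windows are derived from the chamber
    threshold crossings.
    """
    t_end = float(result.times[-1])
    if protocol:
        ct = chamber_completion_times(result)
        starts = sorted(ev.start + ev.duration for ev in protocol)
        t_p = starts[0] + pad
        t_v = max(ev.start for ev in protocol)
        p_end = t_v
        if ct["atrial_depol_completion"] is not None:
            p_end = min(t_v, ct["atrial_depol_completion"] + 0.010)
        qrs0 = t_v + pad + 2e-3
        qrs1 = min(qrs0 + 0.12, t_end)
        if ct["ventricular_depol_completion"] is not None:
            qrs1 = min(max(qrs0 + 0.05,
                           ct["ventricular_depol_completion"] + 0.020), t_end)
        return {"P": (t_p, p_end), "QRS": (qrs0, qrs1), "T": (qrs1, t_end)}
    labs = result.mesh.node_labels()[result.heart_nodes]
    times = result.times
    a = (result.Vm[:, labs == ATRIA] > DEPOL_THRESHOLD).mean(axis=1)
    vfr = (result.Vm[:, labs == VENTRICLES] > DEPOL_THRESHOLD).mean(axis=1)
    ia = np.flatnonzero(a > 0.02)
    iv = np.flatnonzero(vfr > 0.02)
    if ia.size == 0 or iv.size == 0:
        return {"P": (0.0, t_end), "QRS": (t_end, t_end), "T": (t_end, t_end)}
    t_p0 = float(times[ia[0]])
    t_v0 = float(times[iv[0]])
    iv_done = np.flatnonzero(vfr >= COMPLETION_FRACTION)
    qrs1 = float(times[iv_done[0]]) + 0.03 if iv_done.size else min(t_v0 + 0.12, t_end)
    return {"P": (t_p0, t_v0), "QRS": (t_v0, qrs1), "T": (qrs1, t_end)}


def extract_wave_features(traces: ECGTraces, result: SimulationResult | None = None,
                          mesh: HeartTorsoMesh | None = None, protocol=(),
                          lead: str = "II", windows: dict | None = None,
                          threshold: float = DEPOL_THRESHOLD,
                          min_amplitude_fraction: float = 1e-3) -> WaveFeatures:
    """Locate P/QRS/T on one lead and append chamber completion times.

    The trace is baseline-corrected by the pre-P quiescent mean. Waves whose
    window holds no deflection above ``min_amplitude_fraction`` times the
    trace's overall range are reported absent.
    """
    if windows is None:
        if result is None:
            raise ECGError("either explicit windows or a simulation result is needed")
        windows = default_windows(result, protocol)
    x = traces.lead(lead)
    t = traces.time
    # stimulus pulses show up as sharp artifacts on the leads; keep them out
    # of both the baseline estimate and the peak search
    exclude = [(ev.start - 1e-3, ev.start + ev.duration + 3e-3) for ev in protocol]
    # quiescent segment: before the first stimulus (nothing is active
    # earlier), otherwise before the P window
    if protocol:
        t_quiet = min(ev.start for ev in protocol)
    else:
        t_quiet = windows["P"][0]
    pre_mask = t < t_quiet
    for a, b in exclude:
        pre_mask &= ~((t >= a) & (t <= b))
    pre = x[pre_mask]
    baseline = float(pre.mean()) if pre.size else 0.0
    rng = float(np.ptp(x))
    min_amp = min_amplitude_fraction * rng if rng > 0 else np.inf
    feats = WaveFeatures(lead=lead, threshold=threshold)
    for wname, (akey, tkey, dkey) in {
        "P": ("p_amplitude", "p_time", "p_duration"),
        "QRS": ("qrs_amplitude", "qrs_time", "qrs_duration"),
        "T": ("t_amplitude", "t_time", "t_duration"),
    }.items():
        hit = detect_wave(t, x, windows[wname], baseline, min_amp, exclude=exclude)
        if hit is not None:
            amp, pt, dur = hit
            setattr(feats, akey, amp)
            setattr(feats, tkey, pt)
            setattr(feats, dkey, dur)
    if result is not None:
        ct = chamber_completion_times(result, threshold)
        feats.atrial_depol_completion = ct["atrial_depol_completion"]
        feats.atrial_repol_completion = ct["atrial_repol_completion"]
        feats.ventricular_depol_completion = ct["ventricular_depol_completion"]
        feats.ventricular_repol_completion = ct["ventricular_repol_completion"]
    feats.extra["windows"] = {k: tuple(v) for k, v in windows.items()}
    feats.extra["baseline"] = baseline
    return feats


# ---------------------------------------------------------------------------
# Surface maps
# ---------------------------------------------------------------------------

@dataclass
class BSPMSnapshot:
    """Body-surface potential distribution at one sampled instant."""

    time: float
    requested_time: float
    nodes: np.ndarray  # outer-surface node indices
    potentials: np.ndarray  # V
    max_node: int
    min_node: int
    max_position: np.ndarray
    min_position: np.ndarray


def bspm(result: SimulationResult, t: float) -> BSPMSnapshot:
    """Torso-surface potential map at the snapshot nearest to t."""
    i = result.snapshot_index(t)
    pot = result.V_outer[i].astype(float)
    imax, imin = int(np.argmax(pot)), int(np.argmin(pot))
    nodes = result.outer_nodes
    return BSPMSnapshot(
        time=float(result.times[i]), requested_time=float(t),
        nodes=nodes, potentials=pot,
        max_node=int(nodes[imax]), min_node=int(nodes[imin]),
        max_position=result.mesh.nodes[nodes[imax]].copy(),
        min_position=result.mesh.nodes[nodes[imin]].copy(),
    )


def epicardial_map(result: SimulationResult, t: float):
    """Extracellular potential on the heart surface at the nearest snapshot.

    Returns (time, node_indices, potentials). On an embedded mesh the heart
    surface is the heart-torso interface; on a heart-only mesh the outer
    boundary of the heart itself.
    """
    if result.Ve is None:
        raise ECGError("run was executed without storing extracellular fields")
    mesh = result.mesh
    if mesh.has_torso:
        faces, _, _ = mesh.interface_facets()
    else:
        faces, _ = mesh.outer_facets()
    surf = np.unique(faces)
    i = result.snapshot_index(t)
    pos = {n: j for j, n in enumerate(result.heart_nodes)}
    sel = np.array([pos[n] for n in surf if n in pos], dtype=int)
    nodes = np.array([n for n in surf if n in pos], dtype=int)
    return float(result.times[i]), nodes, result.Ve[i, sel].astype(float)
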