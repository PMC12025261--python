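"""Lead derivation, waveform feature extraction and surface maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cardiofield as cf
from cardiofield import ecg
from cardiofield import geometry as G
from cardiofield import solver


def test_limb_leads_direct_arithmetic():
    out = ecg.limb_leads([0.0], [1.0], [2.0])
    assert out["I"][0] == 1.0
    assert out["II"][0] == 2.0
    assert out["III"][0] == 1.0
    assert out["aVR"][0] == -1.5
    assert out["aVL"][0] == 0.0
    assert out["aVF"][0] == 1.5


def test_equal_limb_potentials_give_zero_leads():
    out = ecg.limb_leads([0.3, 0.3], [0.3, 0.3], [0.3, 0.3])
    for k, v in out.items():
        assert np.all(v == 0.0), k


@given(st.lists(st.tuples(*[st.floats(-1, 1, allow_nan=False)] * 3),
                min_size=1, max_size=20))
@settings(deadline=None, max_examples=50)
def test_einthoven_and_goldberger_closures(samples):
    VR, VL, VF = (np.array(x) for x in zip(*samples))
    out = ecg.limb_leads(VR, VL, VF)
    assert np.max(np.abs(out["I"] + out["III"] - out["II"])) <= 1e-12
    assert np.max(np.abs(out["aVR"] + out["aVL"] + out["aVF"])) <= 1e-12


def test_lead_reconstruction_is_linear(rng):
    x = rng.normal(size=(3, 50))
    y = rng.normal(size=(3, 50))
    a, b = 2.5, -1.25
    lx = ecg.limb_leads(*x)
    ly = ecg.limb_leads(*y)
    lz = ecg.limb_leads(*(a * x + b * y))
    for k in lx:
        assert np.allclose(lz[k], a * lx[k] + b * ly[k], atol=1e-12)


def test_precordial_leads_reference_wilson_terminal():
    chest = {f"V{i}": np.full(4, 3.0) for i in range(1, 7)}
    out = ecg.precordial_leads(chest, np.full(4, 3.0), np.full(4, 3.0),
                               np.full(4, 3.0))
    for k, v in out.items():
        assert np.all(v == 0.0)
    # VCT = 0 passes electrodes through unchanged
    out = ecg.precordial_leads(chest, np.zeros(4), np.zeros(4), np.zeros(4))
    for k, v in out.items():
        assert np.all(v == 3.0)


def test_mismatched_trace_lengths_rejected():
    with pytest.raises(ecg.ECGError):
        ecg.limb_leads([0.0, 1.0], [0.0], [0.0])


# -- electrode sampling -----------------------------------------------------

def test_ground_probe_trace_is_identically_zero(protocol_run):
    el = ecg.sample_electrodes(protocol_run["result"], protocol_run["layout"])
    assert np.all(el["RL"].to_numpy() == 0.0)


def test_probe_trace_equals_field_at_probe_node(protocol_run):
    res = protocol_run["result"]
    layout = protocol_run["layout"]
    el = ecg.sample_electrodes(res, layout)
    n = layout.node_ids["V3"]
    j = np.flatnonzero(res.outer_nodes == n)[0]
    assert np.array_equal(el["V3"].to_numpy(), res.V_outer[:, j].astype(float))


def test_twelve_lead_identities_on_simulation(protocol_run):
    tr = ecg.twelve_lead(protocol_run["result"], protocol_run["layout"])
    L = tr.leads
    assert np.max(np.abs(L["I"] + L["III"] - L["II"])) <= 1e-12
    assert np.max(np.abs(L["aVR"] + L["aVL"] + L["aVF"])) <= 1e-12
    assert np.allclose(tr.vct, (tr.electrodes["RA"] + tr.electrodes["LA"]
                                + tr.electrodes["LL"]) / 3.0)


# -- feature extraction -----------------------------------------------------

def _gaussian_traces():
    t = np.arange(0.0, 0.6, 1e-3)
    centers = (0.08, 0.22, 0.42)
    amps = (2e-5, 8e-5, -3e-5)
    # compactly supported bumps (truncated at 4 sigma) so the pre-P baseline
    # is exactly zero and the peak heights are recovered exactly
    x = sum(a * np.exp(-0.5 * ((t - c) / 0.012) ** 2) * (np.abs(t - c) < 0.048)
            for a, c in zip(amps, centers))
    import pandas as pd
    leads = pd.DataFrame({k: x for k in ecg.LEADS})
    return ecg.ECGTraces(t, leads.copy(), leads, np.zeros_like(t)), centers, amps


def test_constructed_waves_recovered_exactly():
    """Three Gaussian bumps with known centers/heights: windowed extremum
    search recovers centers within one sample and heights exactly."""
    traces, centers, amps = _gaussian_traces()
    windows = {"P": (0.02, 0.15), "QRS": (0.15, 0.32), "T": (0.32, 0.58)}
    f = ecg.extract_wave_features(traces, windows=windows)
    assert f.p_time == pytest.approx(centers[0], abs=1.0001e-3)
    assert f.qrs_time == pytest.approx(centers[1], abs=1.0001e-3)
    assert f.t_time == pytest.approx(centers[2], abs=1.0001e-3)
    assert f.p_amplitude == pytest.approx(amps[0], rel=1e-9)
    assert f.qrs_amplitude == pytest.approx(amps[1], rel=1e-9)
    assert f.t_amplitude == pytest.approx(amps[2], rel=1e-9)
    assert f.t_polarity == -1 and f.qrs_polarity == 1


def test_feature_extraction_is_shift_equivariant():
    traces, centers, _ = _gaussian_traces()
    w = {"P": (0.02, 0.15), "QRS": (0.15, 0.32), "T": (0.32, 0.58)}
    f0 = ecg.extract_wave_features(traces, windows=w)
    delta = 0.05
    t2 = traces.time.copy()
    import pandas as pd
    x = traces.leads["II"].to_numpy()
    shifted = np.interp(t2 - delta, t2, x, left=0.0, right=0.0)
    leads2 = pd.DataFrame({k: shifted for k in ecg.LEADS})
    tr2 = ecg.ECGTraces(t2, leads2.copy(), leads2, np.zeros_like(t2))
    w2 = {k: (a + delta, b + delta) for k, (a, b) in w.items()}
    f1 = ecg.extract_wave_features(tr2, windows=w2)
    assert f1.p_time == pytest.approx(f0.p_time + delta, abs=1.1e-3)
    assert f1.qrs_time == pytest.approx(f0.qrs_time + delta, abs=1.1e-3)
    assert f1.t_time == pytest.approx(f0.t_time + delta, abs=1.1e-3)


def test_quiescent_run_reports_all_features_absent(model3):
    bar = cf.build_bar_mesh(10e-3, 2e-3, 1.5e-3)
    cfg = solver.SolverConfig(t_end=0.05)
    res = solver.run(bar, model3, [], cfg)
    import pandas as pd
    t = res.times
    flat = pd.DataFrame({k: np.zeros_like(t) for k in ecg.LEADS})
    traces = ecg.ECGTraces(t, flat.copy(), flat, np.zeros_like(t))
    f = ecg.extract_wave_features(
        traces, windows={"P": (0.0, 0.02), "QRS": (0.02, 0.04), "T": (0.04, 0.05)})
    assert f.p_amplitude is None
    assert f.qrs_amplitude is None
    assert f.t_amplitude is None


def test_protocol_run_waves_and_t_polarity(protocol_run):
    """Full-cycle run: P/QRS/T all detected; with endocardium-to-epicardium
    repolarization the T wave opposes the dominant QRS deflection."""
    res = protocol_run["result"]
    tr = ecg.twelve_lead(res, protocol_run["layout"])
    f = ecg.extract_wave_features(tr, res, protocol=protocol_run["protocol"])
    assert f.p_amplitude is not None
    assert f.qrs_amplitude is not None
    assert f.t_amplitude is not None
    assert f.p_duration >= 0 and f.qrs_duration >= 0
    assert f.qrs_polarity * f.t_polarity == -1
    assert f.atrial_depol_completion < f.atrial_repol_completion
    assert f.ventricular_depol_completion < f.ventricular_repol_completion


# -- surface maps -----------------------------------------------------------

def test_bspm_nearest_snapshot_and_extrema(protocol_run):
    res = protocol_run["result"]
    snap = ecg.bspm(res, 0.2004)
    assert snap.time == pytest.approx(0.200, abs=1e-9)
    assert snap.requested_time == 0.2004
    assert snap.potentials.max() == res.V_outer[res.snapshot_index(0.2)].max()
    assert snap.max_node in res.outer_nodes
    assert snap.potentials.shape == res.outer_nodes.shape


def test_r_peak_bspm_is_dipolar_across_torso(protocol_run):
    """At the R peak the surface map is dipolar: a positive and a negative
    extremum on opposite sides of the cardiac source, separated by at least
    the heart's own size."""
    res = protocol_run["result"]
    tr = ecg.twelve_lead(res, protocol_run["layout"])
    f = ecg.extract_wave_features(tr, res, protocol=protocol_run["protocol"])
    snap = ecg.bspm(res, f.qrs_time)
    sep = np.linalg.norm(snap.max_position - snap.min_position)
    assert snap.potentials.max() > 0 > snap.potentials.min()
    assert sep > 0.08  # dipole poles straddle the ~10 cm heart


def test_epicardial_map_covers_interface(protocol_run):
    res = protocol_run["result"]
    t, nodes, pot = ecg.epicardial_map(res, 0.2)
    faces, _, _ = res.mesh.interface_facets()
    assert set(nodes.tolist()) <= set(np.unique(faces).tolist())
    assert len(pot) == len(nodes)
    assert np.all(np.isfinite(pot))
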