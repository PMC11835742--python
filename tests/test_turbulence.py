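"""Oracle and property tests for the model-free turbulence measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuroturb as nt
from neuroturb.geometry import ParcelGeometry
from neuroturb.turbulence import (
    LocalOrderField,
    PhaseField,
    ScaleSet,
    _fit_power_decay,
)

TR = 2.0


def _phase_field(rng, n=30, t=50):
    return PhaseField(
        phases=rng.uniform(-np.pi, np.pi, (n, t)), tr=TR, n_trimmed=0
    )


def _random_geom(rng, n=30):
    return ParcelGeometry.from_coords(rng.uniform(-60, 60, (n, 3)))


# ---------------------------------------------------------------------------
# bandpass / phases
# ---------------------------------------------------------------------------

def _ls_amplitude(series, t, f0):
    """Least-squares sinusoid amplitude at frequency f0 (frequency-response oracle)."""
    X = np.column_stack([np.cos(2 * np.pi * f0 * t), np.sin(2 * np.pi * f0 * t)])
    coef, *_ = np.linalg.lstsq(X, series, rcond=None)
    return float(np.hypot(*coef))


def test_bandpass_passband_amplitude_preserved():
    t = np.arange(300) * TR
    sig = np.cos(2 * np.pi * 0.03 * t)
    filt = nt.bandpass(nt.BoldTimeseries(data=np.vstack([sig, sig]), tr=TR))
    win = slice(60, 240)  # away from filtfilt edge transients
    amp = _ls_amplitude(filt.data[0, win], t[win], 0.03)
    assert abs(amp - 1.0) < 0.01


def test_bandpass_stopband_attenuated():
    t = np.arange(300) * TR
    sig = np.cos(2 * np.pi * 0.2 * t)
    filt = nt.bandpass(nt.BoldTimeseries(data=np.vstack([sig, sig]), tr=TR))
    amp = _ls_amplitude(filt.data[0, 60:240], t[60:240], 0.2)
    assert amp < 0.2


def test_bandpass_removes_constant():
    filt = nt.bandpass(nt.BoldTimeseries(data=np.full((3, 200), 7.0), tr=TR))
    assert np.abs(filt.data).max() < 1e-10


def test_bandpass_rejects_band_outside_nyquist():
    bold = nt.BoldTimeseries(data=np.random.default_rng(0).normal(size=(2, 100)), tr=TR)
    with pytest.raises(ValueError, match="Nyquist"):
        nt.bandpass(bold, 0.01, 0.3)  # Nyquist is 0.25 Hz at TR = 2 s


def test_phases_advance_matches_tone_frequency():
    t = np.arange(300) * TR
    sig = np.cos(2 * np.pi * 0.03 * t)
    filt = nt.bandpass(nt.BoldTimeseries(data=np.vstack([sig, sig]), tr=TR))
    ph = nt.phases(filt, n_trim=10)
    step = np.mod(np.diff(ph.phases[0]) + np.pi, 2 * np.pi) - np.pi
    mid = step[90:190]
    expected = 2 * np.pi * 0.03 * TR
    assert abs(mid.mean() - expected) / expected < 0.05


def test_phases_identical_rows_and_sign_flip():
    rng = np.random.default_rng(1)
    t = np.arange(200) * TR
    sig = np.sin(2 * np.pi * 0.02 * t) + 0.3 * np.sin(2 * np.pi * 0.05 * t + 1.0)
    bold = nt.BoldTimeseries(data=np.vstack([sig, sig, -sig]), tr=TR)
    ph = nt.phases(nt.bandpass(bold), n_trim=10)
    assert np.array_equal(ph.phases[0], ph.phases[1])
    offset = np.mod(ph.phases[2] - ph.phases[0], 2 * np.pi)
    assert np.allclose(offset, np.pi, atol=1e-6)


def test_phases_too_short_after_trim():
    bold = nt.BoldTimeseries(data=np.random.default_rng(0).normal(size=(2, 21)), tr=TR)
    with pytest.raises(ValueError, match="trim"):
        nt.phases(bold, n_trim=10)


# ---------------------------------------------------------------------------
# local order parameter
# ---------------------------------------------------------------------------

def _local_order_bruteforce(phases, dist, lam):
    """Literal double-loop implementation of the local Kuramoto order parameter."""
    n, t = phases.shape
    R = np.zeros((n, t))
    for j in range(n):
        for ti in range(t):
            num = 0j
            den = 0.0
            for k in range(n):
                w = np.exp(-lam * dist[j, k])
                num += w * np.exp(1j * phases[k, ti])
                den += w
            R[j, ti] = abs(num / den)
    return R


def test_local_order_matches_bruteforce():
    rng = np.random.default_rng(7)
    geom = _random_geom(rng, 30)
    ph = _phase_field(rng, 30, 20)
    for lam in (0.01, 0.1):
        fld = nt.local_order(ph, geom, lam)
        brute = _local_order_bruteforce(ph.phases, geom.dist, lam)
        assert np.abs(fld.R - brute).max() < 1e-12


def test_local_order_perfect_synchrony_gives_one():
    rng = np.random.default_rng(3)
    geom = _random_geom(rng, 10)
    ph = PhaseField(phases=np.full((10, 5), 0.7), tr=TR, n_trimmed=0)
    fld = nt.local_order(ph, geom, 0.05)
    assert np.allclose(fld.R, 1.0, atol=1e-12)


def test_local_order_two_node_closed_form():
    lam = 0.1
    d12 = np.log(2.0) / lam  # weight w12 = 0.5
    coords = np.array([[0.0, 0.0, 0.0], [d12, 0.0, 0.0]])
    geom = ParcelGeometry.from_coords(coords)
    ph = PhaseField(phases=np.array([[0.0], [np.pi]]), tr=TR, n_trimmed=0)
    fld = nt.local_order(ph, geom, lam)
    assert abs(fld.R[0, 0] - 1.0 / 3.0) < 1e-12


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10_000), lam=st.floats(1e-3, 5.0))
def test_local_order_bounded(seed, lam):
    rng = np.random.default_rng(seed)
    geom = _random_geom(rng, 15)
    fld = nt.local_order(_phase_field(rng, 15, 10), geom, lam)
    assert fld.R.min() >= 0.0
    assert fld.R.max() <= 1.0


def test_local_order_large_lam_self_dominates():
    rng = np.random.default_rng(11)
    geom = _random_geom(rng, 25)
    fld = nt.local_order(_phase_field(rng, 25, 30), geom, lam=10.0)
    assert fld.R.mean() > 0.99


def test_local_order_small_lam_reduces_to_global():
    rng = np.random.default_rng(12)
    geom = _random_geom(rng, 25)
    ph = _phase_field(rng, 25, 30)
    fld = nt.local_order(ph, geom, lam=1e-8)
    r_global = np.abs(np.mean(np.exp(1j * ph.phases), axis=0))
    assert np.abs(fld.R - r_global[None, :]).max() < 1e-6


def test_local_order_rejects_nonpositive_scale():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        nt.local_order(_phase_field(rng, 10, 5), _random_geom(rng, 10), 0.0)


# ---------------------------------------------------------------------------
# scalar measures
# ---------------------------------------------------------------------------

def test_turbulence_is_pooled_sample_sd():
    rng = np.random.default_rng(4)
    R = rng.uniform(0, 1, (20, 30))
    fld = LocalOrderField(lam=0.05, R=R, theta=np.zeros_like(R))
    flat = R.ravel()
    oracle = np.sqrt(np.sum((flat - flat.mean()) ** 2) / (flat.size - 1))
    assert abs(nt.turbulence_amplitude(fld) - oracle) < 1e-12


def test_turbulence_hand_computed():
    R = np.array([[0.0, 1.0], [0.0, 1.0]])
    fld = LocalOrderField(lam=0.05, R=R, theta=np.zeros_like(R))
    assert abs(nt.turbulence_amplitude(fld) - np.sqrt(1.0 / 3.0)) < 1e-12


def test_turbulence_constant_is_zero():
    R = np.full((5, 8), 0.4)
    fld = LocalOrderField(lam=0.05, R=R, theta=np.zeros_like(R))
    assert nt.turbulence_amplitude(fld) == 0.0


def test_node_metastability_rowwise_oracle_and_pooled_difference():
    rng = np.random.default_rng(5)
    R = rng.uniform(0, 1, (10, 40))
    R[3] = 0.25  # one region constant in time
    fld = LocalOrderField(lam=0.05, R=R, theta=np.zeros_like(R))
    meta = nt.node_metastability(fld)
    oracle = np.array(
        [np.sqrt(np.sum((row - row.mean()) ** 2) / (len(row) - 1)) for row in R]
    )
    assert np.abs(meta - oracle).max() < 1e-12
    assert meta[3] == 0.0
    # pooled SD over all entries is not the mean of per-row SDs in general
    assert abs(meta.mean() - nt.turbulence_amplitude(fld)) > 1e-6


def test_cascade_flow_shifted_copy_is_one():
    rng = np.random.default_rng(6)
    base = rng.uniform(0, 1, (12, 41))
    f_fine = LocalOrderField(lam=0.03, R=base[:, :-1], theta=np.zeros((12, 40)))
    f_coarse = LocalOrderField(lam=0.01, R=base[:, 1:], theta=np.zeros((12, 40)))
    # coarse field at t+1 equals fine field at t by construction after the shift
    shifted = LocalOrderField(lam=0.01, R=np.roll(f_fine.R, 1, axis=1), theta=f_fine.theta)
    assert abs(nt.cascade_flow(f_fine, shifted) - 1.0) < 1e-12


def test_cascade_flow_independent_fields_near_zero():
    rng = np.random.default_rng(8)
    a = LocalOrderField(lam=0.03, R=rng.uniform(0, 1, (100, 120)), theta=np.zeros((100, 120)))
    b = LocalOrderField(lam=0.01, R=rng.uniform(0, 1, (100, 120)), theta=np.zeros((100, 120)))
    assert abs(nt.cascade_flow(a, b)) < 0.1


def test_cascade_flow_matches_flat_correlation_oracle():
    rng = np.random.default_rng(9)
    a = LocalOrderField(lam=0.03, R=rng.uniform(0, 1, (15, 25)), theta=np.zeros((15, 25)))
    b = LocalOrderField(lam=0.01, R=rng.uniform(0, 1, (15, 25)), theta=np.zeros((15, 25)))
    x = a.R[:, :-1].ravel()
    y = b.R[:, 1:].ravel()
    oracle = (
        np.sum((x - x.mean()) * (y - y.mean()))
        / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    )
    assert abs(nt.cascade_flow(a, b) - oracle) < 1e-12


def test_cascade_flow_zero_variance_raises():
    a = LocalOrderField(lam=0.03, R=np.full((4, 10), 0.5), theta=np.zeros((4, 10)))
    b = LocalOrderField(lam=0.01, R=np.random.default_rng(0).uniform(0, 1, (4, 10)),
                        theta=np.zeros((4, 10)))
    with pytest.raises(ValueError, match="zero variance"):
        nt.cascade_flow(a, b)


def test_information_cascade_mean_and_failures():
    assert nt.information_cascade({(0.03, 0.01): 0.4}) == 0.4
    assert nt.information_cascade({(0.03, 0.01): 1.0, (0.06, 0.03): -1.0}) == 0.0
    rng = np.random.default_rng(10)
    flows = {(i, i + 1): v for i, v in enumerate(rng.uniform(-1, 1, 10))}
    assert abs(nt.information_cascade(flows) - np.mean(list(flows.values()))) < 1e-15
    with pytest.raises(ValueError):
        nt.information_cascade({})


# ---------------------------------------------------------------------------
# information transfer
# ---------------------------------------------------------------------------

def test_power_decay_fit_recovers_planted_exponent():
    r = np.linspace(11, 74, 30)
    c = r ** (-0.8)
    assert abs(_fit_power_decay(r, c) - 0.8) < 1e-9


def test_information_transfer_shared_timecourse_gives_zero():
    rng = np.random.default_rng(13)
    geom = _random_geom(rng, 25)
    row = rng.uniform(0.2, 0.8, 60)
    fld = LocalOrderField(lam=0.01, R=np.tile(row, (25, 1)), theta=np.zeros((25, 60)))
    assert abs(nt.information_transfer(fld, geom)) < 1e-9


def test_information_transfer_matches_loop_oracle(geom20):
    rng = np.random.default_rng(14)
    n = 20
    R = rng.uniform(0, 1, (n, 50))
    fld = LocalOrderField(lam=0.01, R=R, theta=np.zeros((n, 50)))
    stat = nt.information_transfer(fld, geom20, fit_range=(10.0, 75.0), bin_mm=2.0)

    # independent implementation: explicit loops + closed-form OLS
    cors, dists = [], []
    for i in range(n):
        for j in range(i + 1, n):
            x, y = R[i], R[j]
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            cors.append(num / den)
            dists.append(geom20.dist[i, j])
    cors, dists = np.asarray(cors), np.asarray(dists)
    centers, means = [], []
    lo = 10.0
    while lo < 75.0:
        m = (dists >= lo) & (dists < lo + 2.0)
        if m.any():
            centers.append(lo + 1.0)
            means.append(cors[m].mean())
        lo += 2.0
    centers, means = np.asarray(centers), np.asarray(means)
    keep = means > 0
    lx, ly = np.log(centers[keep]), np.log(means[keep])
    slope = (np.sum((lx - lx.mean()) * (ly - ly.mean()))
             / np.sum((lx - lx.mean()) ** 2))
    assert abs(stat - (-slope)) < 1e-9


def test_information_transfer_insufficient_bins_fails(geom20):
    rng = np.random.default_rng(15)
    R = rng.uniform(0, 1, (20, 30))
    fld = LocalOrderField(lam=0.01, R=R, theta=np.zeros((20, 30)))
    with pytest.raises(ValueError, match="bins"):
        nt.information_transfer(fld, geom20, fit_range=(10.0, 14.0))


# ---------------------------------------------------------------------------
# full profile
# ---------------------------------------------------------------------------

def test_profile_cascade_is_mean_of_flows(subject_profile):
    flows = list(subject_profile.cascade_flow.values())
    assert abs(subject_profile.information_cascade - np.mean(flows)) < 1e-12


def test_profile_reports_default_scales(subject_profile):
    for lam in (0.01, 0.03, 0.06):
        assert subject_profile.at_scale(subject_profile.turbulence, lam) >= 0


def test_profile_relabeling_invariance(subject_bold, geom60):
    scales = ScaleSet((0.01, 0.06, 0.12))
    prof = nt.compute_profile(subject_bold, geom60, scales)
    rng = np.random.default_rng(21)
    order = rng.permutation(geom60.n_regions)
    bold_p = nt.BoldTimeseries(data=subject_bold.data[order], tr=subject_bold.tr)
    prof_p = nt.compute_profile(bold_p, geom60.permuted(order), scales)
    for lam in scales.lambdas:
        assert abs(prof.at_scale(prof.turbulence, lam)
                   - prof_p.at_scale(prof_p.turbulence, lam)) < 1e-12
        assert abs(prof.at_scale(prof.information_transfer, lam)
                   - prof_p.at_scale(prof_p.information_transfer, lam)) < 1e-10
        meta = prof.at_scale(prof.node_metastability, lam)
        meta_p = prof_p.at_scale(prof_p.node_metastability, lam)
        assert np.abs(meta[order] - meta_p).max() < 1e-12
    assert abs(prof.information_cascade - prof_p.information_cascade) < 1e-12


def test_fully_synchronized_subject_has_zero_turbulence(geom20):
    # identical series in every region -> identical phases -> R = 1 everywhere
    t = np.arange(200) * TR
    sig = np.sin(2 * np.pi * 0.02 * t) + 0.5 * np.cos(2 * np.pi * 0.04 * t)
    bold = nt.BoldTimeseries(data=np.tile(sig, (20, 1)), tr=TR)
    ph = nt.phases(nt.bandpass(bold), n_trim=10)
    fld = nt.local_order(ph, geom20, 0.05)
    # R is 1 everywhere up to floating-point rounding of the kernel sums
    assert np.allclose(fld.R, 1.0, atol=1e-12)
    assert nt.turbulence_amplitude(fld) < 1e-14


def test_scaleset_validation():
    with pytest.raises(ValueError):
        ScaleSet((0.01, 0.01, 0.03))
    with pytest.raises(ValueError):
        ScaleSet((0.0, 0.01))
    pairs = ScaleSet((0.01, 0.03, 0.06)).adjacent_pairs()
    assert pairs == [(0.06, 0.03), (0.03, 0.01)]
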