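"""R2* relaxometry, field initialization, IDEAL water-fat fitting, masking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import curve_fit

from liversep import (AcquisitionParams, EchoSeries, arlo_r2star,
                      compute_pdff, ideal_fit, initial_field, liver_mask)
from liversep.signal_fitting import EmptyMaskError, FatWaterResult


def _series(acq, signal_fn):
    """4D echo series from a per-voxel signal function of (x, y, z, t)."""
    te = acq.echo_times_array
    data = np.zeros((4, 4, 4, len(te)), complex)
    for idx in np.ndindex(4, 4, 4):
        data[idx] = signal_fn(*idx, te)
    return EchoSeries(data=data, acq=acq)


def test_arlo_zero_on_constant_magnitude(acq):
    s = _series(acq, lambda x, y, z, t: np.ones_like(t) + 0j)
    assert np.allclose(arlo_r2star(s), 0.0)


@pytest.mark.parametrize("r2s_true", [15.0, 50.0, 100.0, 200.0, 300.0])
def test_arlo_within_one_percent_of_nlsq(acq, r2s_true):
    """ARLO matches a nonlinear least-squares mono-exponential fit to <1%
    on noiseless decays over the working R2* range."""
    te = acq.echo_times_array
    s = _series(acq, lambda x, y, z, t: 2.0 * np.exp(-r2s_true * t) + 0j)
    est = arlo_r2star(s)[0, 0, 0]

    popt, _ = curve_fit(lambda t, a, r: a * np.exp(-r * t),
                        te, 2.0 * np.exp(-r2s_true * te), p0=[1.0, 50.0])
    oracle = popt[1]
    assert est == pytest.approx(oracle, rel=0.01)
    assert est == pytest.approx(r2s_true, rel=0.01)


def test_arlo_rejects_unequal_spacing():
    acq = AcquisitionParams(echo_times=(0.002, 0.004, 0.009, 0.012))
    s = _series(acq, lambda x, y, z, t: np.exp(-50 * t) + 0j)
    with pytest.raises(ValueError, match="equally spaced"):
        arlo_r2star(s)


def test_arlo_needs_three_echoes():
    with pytest.raises(ValueError):
        AcquisitionParams(echo_times=(0.002, 0.004))


def test_initial_field_zero_phase(acq):
    s = _series(acq, lambda x, y, z, t: np.exp(-30 * t) + 0j)
    f = initial_field(s, mask=np.ones((4, 4, 4), bool))
    assert np.allclose(f, 0.0, atol=1e-9)


def test_initial_field_recovers_water_frequency(acq):
    """A noiseless water voxel at f = 30 Hz is recovered within 0.1 Hz."""
    s = _series(acq, lambda x, y, z, t:
                np.exp(-40 * t) * np.exp(-2j * np.pi * 30.0 * t))
    f = initial_field(s, mask=np.ones((4, 4, 4), bool))
    assert np.allclose(f, 30.0, atol=0.1)


def test_initial_field_unwraps_alias_wrap(acq):
    """A field ramp spanning more than 1/dTE (one full alias wrap) is
    recovered within 1 Hz RMS by the spatial unwrapper."""
    shape = (32, 8, 8)
    ramp = np.linspace(0.0, 420.0, shape[0])[:, None, None] * np.ones(shape)
    te = acq.echo_times_array
    data = np.exp(-30 * te[None, None, None, :]) * \
        np.exp(-2j * np.pi * ramp[..., None] * te[None, None, None, :])
    s = EchoSeries(data=data, acq=acq)
    f = initial_field(s, mask=np.ones(shape, bool))
    err = f - ramp
    err -= np.round(np.mean(err) * acq.delta_te) / acq.delta_te  # global branch
    assert np.sqrt(np.mean(err**2)) < 1.0


def test_initial_field_rejects_zero_input(acq):
    s = EchoSeries(data=np.zeros((4, 4, 4, acq.n_echoes), complex), acq=acq)
    with pytest.raises(ValueError):
        initial_field(s)


def _ideal_oracle(sig, te, nu, r2s, f_grid):
    """Dense 1-D field grid with exact per-f linear (W, F) solves."""
    best = (np.inf, None)
    for f in f_grid:
        e = np.exp(-r2s * te) * np.exp(-2j * np.pi * f * te)
        b = np.stack([e, e * np.exp(-2j * np.pi * nu * te)], axis=1)
        coef, res, *_ = np.linalg.lstsq(b, sig, rcond=None)
        r = np.sum(np.abs(sig - b @ coef) ** 2)
        if r < best[0]:
            best = (r, (np.abs(coef[0]), np.abs(coef[1]), f))
    return best[1]


def test_ideal_water_only(acq):
    s = _series(acq, lambda x, y, z, t:
                np.exp(-40 * t) * np.exp(-2j * np.pi * 12.0 * t))
    fw = ideal_fit(s, f0=np.full((4, 4, 4), 10.0), r2s=np.full((4, 4, 4), 40.0))
    assert np.allclose(fw.fat, 0.0, atol=1e-3)
    assert np.allclose(fw.pdff, 0.0, atol=1e-3)
    assert np.allclose(fw.field, 12.0, atol=0.02)


def test_ideal_fat_only(acq):
    nu = acq.fat_shift_hz
    s = _series(acq, lambda x, y, z, t:
                0.8 * np.exp(-40 * t) * np.exp(-2j * np.pi * nu * t))
    fw = ideal_fit(s, f0=np.zeros((4, 4, 4)), r2s=np.full((4, 4, 4), 40.0))
    assert np.allclose(fw.pdff, 1.0, atol=1e-6)


def test_ideal_matches_grid_search_oracle(acq):
    """Mixed voxel W=0.7, F=0.3, f=30 Hz: recovery within 1e-3 a.u. and
    0.1 Hz, cross-checked against an exhaustive field-grid oracle."""
    nu = acq.fat_shift_hz
    te = acq.echo_times_array
    r2s_true = 60.0

    def sig_fn(x, y, z, t):
        return (0.7 + 0.3 * np.exp(-2j * np.pi * nu * t)) * \
            np.exp(-r2s_true * t) * np.exp(-2j * np.pi * 30.0 * t)

    s = _series(acq, sig_fn)
    fw = ideal_fit(s, f0=np.full((4, 4, 4), 25.0),
                   r2s=np.full((4, 4, 4), r2s_true))
    w_o, f_o, field_o = _ideal_oracle(sig_fn(0, 0, 0, te), te, nu, r2s_true,
                                      np.arange(20.0, 40.0, 0.02))
    assert fw.water[0, 0, 0] == pytest.approx(w_o, abs=1e-3)
    assert fw.fat[0, 0, 0] == pytest.approx(f_o, abs=1e-3)
    assert fw.field[0, 0, 0] == pytest.approx(field_o, abs=0.1)
    assert fw.water[0, 0, 0] == pytest.approx(0.7, abs=1e-3)
    assert fw.fat[0, 0, 0] == pytest.approx(0.3, abs=1e-3)
    assert fw.field[0, 0, 0] == pytest.approx(30.0, abs=0.1)
    assert fw.converged.all()


def test_ideal_residual_not_increased(acq):
    """The damped field refinement never leaves a voxel with a larger
    residual than the initialization."""
    nu = acq.fat_shift_hz
    te = acq.echo_times_array
    rng = np.random.default_rng(0)
    shape = (6, 6, 1)
    f_true = rng.uniform(-60, 60, shape)
    ff = rng.uniform(0, 0.4, shape)
    data = ((1 - ff)[..., None] + ff[..., None] *
            np.exp(-2j * np.pi * nu * te)) * \
        np.exp(-50 * te) * np.exp(-2j * np.pi * f_true[..., None] * te)
    s = EchoSeries(data=data, acq=acq)
    f0 = np.zeros(shape)
    r2s = np.full(shape, 50.0)

    def resid(field):
        e = np.exp(-r2s[..., None] * te) * \
            np.exp(-2j * np.pi * field[..., None] * te)
        b2 = e * np.exp(-2j * np.pi * nu * te)
        out = np.zeros(shape)
        for idx in np.ndindex(*shape):
            bmat = np.stack([e[idx], b2[idx]], axis=1)
            coef, *_ = np.linalg.lstsq(bmat, data[idx], rcond=None)
            out[idx] = np.sum(np.abs(data[idx] - bmat @ coef) ** 2)
        return out

    fw = ideal_fit(s, f0=f0, r2s=r2s)
    assert (resid(fw.field) <= resid(f0) + 1e-10).all()


def _fw(w, f):
    shape = np.shape(w)
    z = np.zeros(shape)
    return FatWaterResult(water=np.asarray(w, float), fat=np.asarray(f, float),
                          field=z, r2s=z, pdff=z, converged=z.astype(bool))


def test_pdff_cases():
    assert compute_pdff(_fw([[1.0]], [[0.0]]))[0, 0] == 0.0
    assert compute_pdff(_fw([[0.0]], [[0.0]]))[0, 0] == 0.0
    assert compute_pdff(_fw([[0.5]], [[0.5]]))[0, 0] == 0.5


@settings(max_examples=50, deadline=None)
@given(st.floats(0.01, 10.0), st.floats(0.0, 10.0), st.floats(0.01, 100.0))
def test_pdff_invariant_under_joint_rescale(w, f, c):
    a = compute_pdff(_fw([[w]], [[f]]))[0, 0]
    b = compute_pdff(_fw([[w * c]], [[f * c]]))[0, 0]
    assert a == pytest.approx(b, abs=1e-12)


def test_liver_mask_threshold_and_erosion():
    r2s = np.zeros((14, 14, 14))
    r2s[2:12, 2:12, 2:12] = 20.0
    m = liver_mask(r2s, threshold=15.0, erosion_radius=1)
    assert m.sum() == 8**3          # one layer eroded from a 10^3 cube
    assert m[3:11, 3:11, 3:11].all()


def test_liver_mask_empty_names_stage():
    with pytest.raises(EmptyMaskError, match="threshold"):
        liver_mask(np.full((8, 8, 8), 10.0))


def test_liver_mask_exclusions_and_largest_component():
    r2s = np.zeros((20, 10, 10))
    r2s[1:9, 1:9, 1:9] = 30.0       # big blob
    r2s[12:16, 2:6, 2:6] = 30.0     # small blob
    m = liver_mask(r2s, erosion_radius=1)
    assert m[2:8, 2:8, 2:8].any() and not m[12:16].any()
    excl = np.zeros_like(r2s, bool)
    excl[:10] = True
    m2 = liver_mask(r2s, erosion_radius=1, exclusions=excl)
    assert not m2[:10].any() and m2[13:15, 3:5, 3:5].any()
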