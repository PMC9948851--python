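"""ROI pipeline: erosion, registration, statistics, verification analytics."""

import numpy as np
import pandas as pd
import pytest

from conftest import erosion_oracle
from ddcqa import AcquisitionSettings, erode_roi, register_template, simulate_volume
from ddcqa.errors import InsufficientDataError, RegistrationError
from ddcqa.roi import (
    build_background_mask,
    build_rod_masks,
    disc_footprint,
    drift_summary,
    energy_response,
    fit_linearity,
    measure_contrasts,
    rod_statistics,
    RegressionResult,
)
from ddcqa.simulate import CTVolume


def _random_blob_mask(rng, shape=(40, 40)):
    from scipy.ndimage import gaussian_filter
    field = gaussian_filter(rng.normal(size=shape), 3.0)
    mask = field > np.quantile(field, 0.7)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


# -- erosion ---------------------------------------------------------------

def test_disc_footprint_5px_shape():
    fp = disc_footprint(5)
    assert fp.shape == (5, 5)
    # offsets whose centre is within 2.5 px: full rows except the 4 corners
    assert fp.sum() == 21
    assert not fp[0, 0] and not fp[0, 4] and not fp[4, 0] and not fp[4, 4]


def test_erosion_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        mask = _random_blob_mask(rng)
        np.testing.assert_array_equal(erode_roi(mask, 5), erosion_oracle(mask, 5))


def test_erosion_of_filled_disc():
    yy, xx = np.mgrid[-15:16, -15:16]
    disc10 = yy * yy + xx * xx <= 10 * 10
    eroded = erode_roi(disc10, 5)
    np.testing.assert_array_equal(eroded, erosion_oracle(disc10, 5))
    # the eroded disc keeps everything the triangle inequality guarantees
    assert np.all(eroded[yy * yy + xx * xx <= 7.5 ** 2])
    assert eroded.sum() < disc10.sum()


def test_erosion_is_anti_extensive():
    rng = np.random.default_rng(1)
    for _ in range(50):
        mask = _random_blob_mask(rng)
        assert not np.any(erode_roi(mask, 5) & ~mask)


def test_erosion_of_thin_mask_is_empty():
    mask = np.zeros((20, 20), dtype=bool)
    mask[10, 2:18] = True  # 1 px thin line
    assert not erode_roi(mask, 5).any()
    with pytest.raises(ValueError):
        erode_roi(np.zeros((5, 5), dtype=bool))


# -- registration ----------------------------------------------------------

def test_registration_recovers_known_pose(layout):
    settings = AcquisitionSettings(noise_sigma_ref_hu=2.0, psf_fwhm_mm=0.0,
                                   n_slices=1)
    volume, _ = simulate_volume(layout, settings, seed=7,
                                rotation_deg=17.3, shift_mm=(2.0, -3.0))
    tf = register_template(volume, layout)
    assert abs(tf.rotation_deg - 17.3) < 0.5
    assert tf.shift_mm[0] == pytest.approx(2.0, abs=0.5)
    assert tf.shift_mm[1] == pytest.approx(-3.0, abs=0.5)


def test_registration_identity(clean_sim):
    volume, truth = clean_sim
    tf = register_template(volume, truth.layout)
    assert abs(tf.rotation_deg) < 0.5
    assert abs(tf.shift_mm[0]) < 0.5 and abs(tf.shift_mm[1]) < 0.5


def test_registration_fails_on_pure_noise(layout):
    settings = AcquisitionSettings(n_slices=1)
    rng = np.random.default_rng(0)
    noise = CTVolume(rng.normal(60.0, 10.0, size=(1, 192, 192)),
                     (2.0, 0.5, 0.5), settings)
    with pytest.raises(RegistrationError):
        register_template(noise, layout)


# -- statistics ------------------------------------------------------------

def test_constant_image_statistics(clean_sim):
    volume, truth = clean_sim
    const = CTVolume(np.full_like(volume.voxels, 42.0), volume.spacing_mm,
                     volume.settings)
    rod_stats, bg = rod_statistics(const, truth.layout, truth.transform)
    for st in rod_stats + [bg]:
        if st.unmeasurable:
            continue
        assert st.mean == st.median == st.min == st.max == 42.0
        assert st.sd == 0.0


def test_large_erosion_flags_unmeasurable(clean_sim):
    volume, truth = clean_sim
    rod_stats, bg = rod_statistics(volume, truth.layout, truth.transform,
                                   erosion_diameter_px=15)
    small = [st for st, rod in zip(rod_stats, truth.layout.rods)
             if rod.spec.diameter_mm == 3]
    assert all(st.unmeasurable for st in small)
    assert all(np.isnan(st.mean) for st in small)


def test_noise_free_contrast_recovery_is_exact(clean_sim):
    volume, truth = clean_sim
    tf = register_template(volume, truth.layout)
    rod_stats, bg = rod_statistics(volume, truth.layout, tf)
    measurements = measure_contrasts(truth.layout, rod_stats, bg,
                                     volume.settings)
    for m, rendered in zip(measurements, truth.rendered_contrast_hu):
        assert m.measured_contrast_hu == pytest.approx(rendered, abs=1e-9)


def test_measured_contrast_within_sampling_bound(clean_sim):
    """Rod-minus-background means stay inside 3 sigma sqrt(1/Nr + 1/Nb)."""
    volume, truth = clean_sim
    sigma = 8.0
    rod_masks = [m & True for m in build_rod_masks(truth.layout, truth.transform,
                                                   volume.voxels.shape[1:])]
    eroded = [erode_roi(m, 5) for m in rod_masks]
    bg = erode_roi(build_background_mask(truth.layout, truth.transform,
                                         volume.voxels.shape[1:]), 5)
    clean = volume.voxels[0]
    rng = np.random.default_rng(123)
    n_rep, hits, total = 100, 0, 0
    for _ in range(n_rep):
        noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
        bg_mean = noisy[bg].mean()
        for mask, rendered in zip(eroded, truth.rendered_contrast_hu):
            if not mask.any():
                continue
            err = (noisy[mask].mean() - bg_mean) - rendered
            bound = 3 * sigma * np.sqrt(1.0 / mask.sum() + 1.0 / bg.sum())
            total += 1
            hits += abs(err) <= bound
    assert hits / total >= 0.98


# -- verification analytics ------------------------------------------------

def _measurement_frame(slope=1.0, intercept=0.0, noise=None, seed=0, kv=120,
                       module_type="native", date="2021-01-01"):
    rng = np.random.default_rng(seed)
    rows = []
    for d in (3, 4, 5, 6, 8, 9):
        for t in (16, 32, 48, 64, 80):
            y = slope * t + intercept
            if noise:
                y += rng.normal(0.0, noise)
            rows.append({"diameter_mm": d, "target_contrast_hu": t,
                         "measured_contrast_hu": y, "module_type": module_type,
                         "kv": kv, "date": date})
    return pd.DataFrame(rows)


def test_linearity_identity_and_affine():
    perfect = fit_linearity(_measurement_frame())
    for res in perfect.values():
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    affine = fit_linearity(_measurement_frame(slope=0.8, intercept=2.0))
    for res in affine.values():
        assert res.slope == pytest.approx(0.8, abs=1e-12)
        assert res.intercept == pytest.approx(2.0, abs=1e-9)


def test_linearity_matches_normal_equations_oracle():
    frame = _measurement_frame(slope=0.9, intercept=1.5, noise=3.0, seed=4)
    fits = fit_linearity(frame)
    for d, grp in frame.groupby("diameter_mm"):
        x = grp["target_contrast_hu"].to_numpy(float)
        y = grp["measured_contrast_hu"].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert fits[float(d)].intercept == pytest.approx(coef[0], abs=1e-9)
        assert fits[float(d)].slope == pytest.approx(coef[1], abs=1e-9)


def test_linearity_insufficient_targets_raises():
    frame = _measurement_frame()
    with pytest.raises(InsufficientDataError):
        fit_linearity(frame[frame["target_contrast_hu"] == 48])


def test_regression_result_rejects_bad_r2():
    with pytest.raises(ValueError):
        RegressionResult(slope=1.0, intercept=0.0, r_squared=1.5, n=10)


def test_drift_summary_constant_and_alternating():
    frames = [_measurement_frame(date=f"2021-0{m}-01") for m in (1, 2, 3)]
    const = pd.concat(frames)
    out = drift_summary(const)
    assert np.allclose(out["sd_of_means"], 0.0)
    # alternating +-1 around the target over four dates
    alt = []
    for i, m in enumerate((1, 2, 3, 4)):
        f = _measurement_frame(date=f"2021-0{m}-01")
        f["measured_contrast_hu"] += 1.0 if i % 2 == 0 else -1.0
        alt.append(f)
    out = drift_summary(pd.concat(alt))
    for t in (16, 32, 48, 64, 80):
        sel = out[out["target_contrast_hu"] == t]
        assert sel["grand_mean"].iloc[0] == pytest.approx(t)


def test_drift_summary_matches_direct_recomputation():
    rng = np.random.default_rng(9)
    frames = []
    for m in (1, 2, 3):
        f = _measurement_frame(noise=2.0, seed=m, date=f"2021-0{m}-01")
        frames.append(f)
    df = pd.concat(frames)
    out = drift_summary(df)
    for t in (16, 80):
        means = [df[(df.date == d) & (df.target_contrast_hu == t)]
                 ["measured_contrast_hu"].mean() for d in sorted(df.date.unique())]
        sel = out[out["target_contrast_hu"] == t]
        assert sel["grand_mean"].iloc[0] == pytest.approx(np.mean(means))
        assert sel["sd_of_means"].iloc[0] == pytest.approx(np.std(means, ddof=1))


def test_drift_needs_two_dates():
    with pytest.raises(InsufficientDataError):
        drift_summary(_measurement_frame())


def test_energy_response_native_equal_iodine_ordered():
    resp = {80: 1.3, 100: 1.15, 120: 1.0}
    frames = []
    for kv, f in resp.items():
        frames.append(_measurement_frame(slope=f, kv=kv,
                                         module_type="contrast_agent"))
        frames.append(_measurement_frame(slope=1.0, kv=kv, module_type="native"))
    table = energy_response(pd.concat(frames))
    native = table[table.module_type == "native"]
    assert np.allclose(native["slope"], native["slope"].iloc[0], atol=1e-6)
    iodine = table[table.module_type == "contrast_agent"].set_index("kv")
    assert iodine.loc[80, "slope"] / iodine.loc[120, "slope"] == pytest.approx(1.3, rel=1e-9)
    assert list(iodine["slope"].sort_index(ascending=True)) == sorted(
        iodine["slope"], reverse=True)


def test_energy_response_needs_two_kv():
    with pytest.raises(InsufficientDataError):
        energy_response(_measurement_frame())
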