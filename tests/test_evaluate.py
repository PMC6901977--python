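"""Evaluation metrics: hand values, brute-force oracles, report structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mr2sct as m
from mr2sct.evaluate import REPORT_COLUMNS
from mr2sct.phantom import LABEL_CODES


def sweep_otsu_threshold(values, bins=256):
    """Exhaustive threshold sweep maximizing between-class variance."""
    hist, edges = np.histogram(values, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    for k in range(bins - 1):
        w0, w1 = hist[:k + 1].sum(), hist[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k + 1] * centers[:k + 1]).sum() / w0
        m1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, centers[k]
    return best_t


# ----------------------------------------------------------------- masks


def between_class_variance(vals, thr, bins=256):
    """Between-class variance of the 256-bin histogram split at ``thr``
    (the objective the threshold search maximizes)."""
    hist, edges = np.histogram(vals, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    lo = centers <= thr
    w0, w1 = hist[lo].sum(), hist[~lo].sum()
    if w0 == 0 or w1 == 0:
        return -np.inf
    m0 = (hist[lo] * centers[lo]).sum() / w0
    m1 = (hist[~lo] * centers[~lo]).sum() / w1
    return w0 * w1 * (m0 - m1) ** 2


def test_otsu_matches_bruteforce_sweep():
    """The implemented threshold achieves the sweep's maximal between-class
    variance; partitions may differ only at near-tie splits, i.e. on pixels
    lying between the two thresholds."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        vals = np.concatenate([rng.normal(-1000, 30, 600),
                               rng.normal(40, 60, 400)])
        img = vals.reshape(40, 25)
        fg = m.otsu_foreground(img)
        t_oracle = sweep_otsu_threshold(vals)
        oracle = img > t_oracle
        mismatch = fg ^ oracle
        if mismatch.any():
            from skimage.filters import threshold_otsu
            t_impl = threshold_otsu(img)
            lo, hi = sorted([t_impl, t_oracle])
            assert np.all((img[mismatch] > lo) & (img[mismatch] <= hi))
            assert (between_class_variance(vals, t_impl)
                    >= 0.9999 * between_class_variance(vals, t_oracle))


def test_otsu_two_delta_histogram_threshold_between_modes():
    img = np.repeat([-1000.0, 0.0], 50).reshape(10, 10)
    fg = m.otsu_foreground(img)
    assert np.array_equal(fg, img == 0.0)  # threshold strictly between modes


def test_body_mask_noise_free_equals_painted_head(clean_pair,
                                                  head_ellipse_mask):
    mask = m.body_mask(clean_pair.ct)
    assert np.array_equal(mask, head_ellipse_mask)


def test_body_mask_fills_internal_air_cavity(clean_pair):
    cavity = (clean_pair.labels == LABEL_CODES["air"])
    mask = m.body_mask(clean_pair.ct)
    internal_air = cavity & mask
    assert internal_air.sum() > 0  # sinus cavity is inside the body outline


def test_body_mask_all_air_errors():
    rng = np.random.default_rng(1)
    img = rng.normal(-1000, 20, (64, 64))
    with pytest.raises(ValueError):
        m.body_mask(img)
    with pytest.raises(ValueError):
        m.body_mask(np.full((64, 64), -1000.0))


def test_split_tissues_matches_painted_bone(clean_pair):
    body = m.body_mask(clean_pair.ct)
    regions = m.split_tissues(clean_pair.ct, body)
    assert np.array_equal(regions.bone,
                          clean_pair.labels == LABEL_CODES["bone"])
    # partition property
    assert (regions.bone | regions.soft).sum() == body.sum()
    assert not (regions.bone & regions.soft).any()


def test_split_tissues_threshold_limit(clean_pair):
    body = m.body_mask(clean_pair.ct)
    regions = m.split_tissues(clean_pair.ct, body, threshold=-2000.0)
    assert np.array_equal(regions.bone, body)
    assert regions.soft.sum() == 0


# ---------------------------------------------------------------- metrics


def test_mae_me_hand_values():
    ct = np.array([[100.0, 200.0, -50.0]])
    sct = np.array([[110.0, 190.0, -50.0]])
    full = np.ones_like(ct, bool)
    assert m.mae(ct, sct, full) == pytest.approx(20.0 / 3.0)
    assert m.me(ct, ct + 10.0, full) == pytest.approx(-10.0)
    assert m.mae(ct, ct, full) == 0.0
    # antisymmetric errors: ME cancels, MAE does not
    err = np.array([[25.0, -25.0]])
    base = np.zeros_like(err)
    assert m.me(base, err, np.ones_like(err, bool)) == 0.0
    assert m.mae(base, err, np.ones_like(err, bool)) == 25.0


def test_metrics_match_double_loop_oracle():
    rng = np.random.default_rng(5)
    ct = rng.normal(0, 500, (64, 64))
    sct = rng.normal(0, 500, (64, 64))
    mask = rng.random((64, 64)) > 0.3
    s_abs = s_sig = n = 0.0
    for i in range(64):
        for j in range(64):
            if mask[i, j]:
                d = ct[i, j] - sct[i, j]
                s_abs += abs(d)
                s_sig += d
                n += 1
    assert m.mae(ct, sct, mask) == pytest.approx(s_abs / n, rel=1e-13)
    assert m.me(ct, sct, mask) == pytest.approx(s_sig / n, abs=1e-10)


def test_empty_mask_rejected():
    img = np.zeros((4, 4))
    with pytest.raises(ValueError):
        m.mae(img, img, np.zeros((4, 4), bool))
    with pytest.raises(ValueError):
        m.me(img, img, np.zeros((4, 4), bool))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_mae_dominates_absolute_me(seed):
    rng = np.random.default_rng(seed)
    ct = rng.normal(0, 300, (8, 8))
    sct = ct + rng.normal(0, 100, (8, 8))
    mask = np.ones((8, 8), bool)
    assert m.mae(ct, sct, mask) >= abs(m.me(ct, sct, mask)) - 1e-9


def test_difference_map_consistency(noisy_pair):
    sct = noisy_pair.ct.with_data(noisy_pair.ct.data + 50.0)
    dm = m.difference_map(noisy_pair.ct, sct)
    np.testing.assert_allclose(dm.data, 50.0, atol=1e-9)
    single = noisy_pair.ct.with_data(noisy_pair.ct.data.copy())
    single.data[10, 10] += 50.0
    dm2 = m.difference_map(noisy_pair.ct, single)
    assert dm2.data[10, 10] == pytest.approx(50.0)
    assert dm2.data.sum() == pytest.approx(50.0)
    body = m.body_mask(noisy_pair.ct)
    assert dm.data[body].mean() == pytest.approx(
        m.mae(noisy_pair.ct, sct, body))


def test_laplace_noise_calibration():
    """MAE against a Laplace(0, b)-corrupted copy estimates b (the mean
    absolute deviation of the Laplace distribution)."""
    pair = m.generate_pair(m.head_phantom_spec(128, seed=1))
    rng = np.random.default_rng(0)
    b = 100.0
    noisy = pair.ct.with_data(pair.ct.data
                              + rng.laplace(0.0, b, pair.ct.shape))
    body = m.body_mask(pair.ct)
    assert m.mae(pair.ct, noisy, body) == pytest.approx(b, abs=3.0)


# ----------------------------------------------------------------- report


def test_cohort_report_structure_and_arithmetic(template):
    pairs = m.cohort(template, 10, seed=2)
    rng = np.random.default_rng(3)
    subjects = [(p.ct, p.ct.with_data(p.ct.data + rng.normal(0, 40, p.ct.shape)))
                for p in pairs]
    report = m.cohort_report(subjects)
    assert list(report.per_subject.columns) == REPORT_COLUMNS
    assert len(report.per_subject) == 10
    # cohort mean equals hand-averaged per-subject values
    manual = report.per_subject["mae_overall"].to_numpy().mean()
    assert report.mean["mae_overall"] == pytest.approx(manual)
    sd_manual = report.per_subject["mae_overall"].to_numpy().std(ddof=0)
    assert report.sd["mae_overall"] == pytest.approx(sd_manual)
    for _, row in report.per_subject.iterrows():
        for region in ("soft", "bone", "overall"):
            assert row[f"mae_{region}"] >= abs(row[f"me_{region}"])


def test_single_subject_sd_is_zero(noisy_pair):
    report = m.cohort_report([(noisy_pair.ct, noisy_pair.ct)])
    assert (report.sd == 0).all()


def test_report_csv_roundtrip(tmp_path, noisy_pair):
    report = m.cohort_report([(noisy_pair.ct, noisy_pair.ct)])
    report.to_csv(tmp_path / "report.csv")
    import pandas as pd
    back = pd.read_csv(tmp_path / "report.csv", index_col=0)
    assert list(back.columns) == REPORT_COLUMNS
    assert "mean" in back.index and "sd" in back.index
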