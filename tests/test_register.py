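"""Registration: MI oracles, warp algebra, bending energy, recovery."""

import numpy as np
import pytest

import mr2sct as m
from mr2sct.register import (BSplineField, CompositeTransform,
                             joint_histogram, register_bspline)


def loop_mi_nearest(a, b, bins):
    """Double-loop hard-binned joint-histogram MI oracle (nats)."""
    def binned(v):
        v = v.ravel()
        u = (v - v.min()) / (v.max() - v.min()) * (bins - 1e-9)
        return np.floor(u).astype(int)
    ia, ib = binned(a), binned(b)
    h = np.zeros((bins, bins))
    for x, y in zip(ia, ib):
        h[x, y] += 1
    p = h / h.sum()
    pa, pb = p.sum(1), p.sum(0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (pa[i] * pb[j]))
    return mi


# --------------------------------------------------------------------- MI


def test_self_mi_equals_marginal_entropy():
    rng = np.random.default_rng(0)
    img = rng.normal(size=(32, 32))
    mi = m.mattes_mi(img, img, bins=16, kernel="nearest")
    ent = m.histogram_entropy(img, bins=16, kernel="nearest")
    assert mi == pytest.approx(ent, rel=1e-12)


def test_mi_matches_loop_oracle_and_shuffled_is_near_zero():
    rng = np.random.default_rng(1)
    img = rng.normal(size=(24, 24))
    shuffled = rng.permutation(img.ravel()).reshape(img.shape)
    mine = m.mattes_mi(img, shuffled, bins=12, kernel="nearest")
    oracle = loop_mi_nearest(img, shuffled, 12)
    assert mine == pytest.approx(oracle, rel=1e-10)
    assert mine < 0.15 * m.histogram_entropy(img, bins=12, kernel="nearest")
    aligned = m.mattes_mi(img, img, bins=12, kernel="nearest")
    assert aligned > 5 * mine


def test_mi_symmetry_parzen(noisy_pair):
    a, b = noisy_pair.ct.data, noisy_pair.mr.data
    assert m.mattes_mi(a, b) == pytest.approx(m.mattes_mi(b, a), abs=1e-9)


def test_mi_errors():
    img = np.random.default_rng(0).normal(size=(16, 16))
    with pytest.raises(ValueError):
        m.mattes_mi(img, img, bins=4)
    with pytest.raises(ValueError):
        m.mattes_mi(img, img, mask=np.zeros((16, 16), bool))
    with pytest.raises(ValueError):
        m.mattes_mi(np.ones((16, 16)), img)


def test_mi_peaks_at_true_alignment(clean_pair):
    """Grid sweep over translations: MI is maximal at zero shift."""
    ct, mr = clean_pair.ct.data, clean_pair.mr.data
    scores = {}
    for tx in range(-6, 7, 2):
        for ty in range(-6, 7, 2):
            w = m.warp(mr, m.RigidTransform2D(0.0, (tx, ty)))
            scores[(tx, ty)] = m.mattes_mi(ct, w)
    assert max(scores, key=scores.get) == (0, 0)


# ------------------------------------------------------------------- warp


def test_warp_identity_is_bit_identical(noisy_pair):
    out = m.warp(noisy_pair.mr, m.RigidTransform2D.identity())
    assert np.array_equal(out.data, noisy_pair.mr.data)


def test_warp_90_degrees_matches_index_permutation():
    rng = np.random.default_rng(2)
    img = rng.normal(size=(33, 33))
    out = m.warp(img, m.RigidTransform2D(90.0, (0.0, 0.0)))
    np.testing.assert_allclose(out, np.rot90(img), atol=1e-9)


def test_warp_inverse_consistency():
    from scipy.ndimage import gaussian_filter
    rng = np.random.default_rng(3)
    img = gaussian_filter(rng.normal(size=(64, 64)), 4)
    t = m.RigidTransform2D(7.0, (3.0, -2.0))
    back = m.warp(m.warp(img, t), t.inverse())
    interior = np.s_[12:-12, 12:-12]
    assert np.abs(back[interior] - img[interior]).max() < 0.05 * np.ptp(img)


def test_rigid_transform_algebra():
    t = m.RigidTransform2D(13.0, (4.0, -9.0))
    comp = t.compose(t.inverse())
    assert comp.rotation == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(comp.translation, (0, 0), atol=1e-12)


def test_warp_fill_values(noisy_pair):
    big = m.RigidTransform2D(0.0, (1000.0, 0.0))
    ct_out = m.warp(noisy_pair.ct, big)
    mr_out = m.warp(noisy_pair.mr, big)
    assert np.all(ct_out.data == m.AIR_HU)
    assert np.all(mr_out.data == 0.0)


# ---------------------------------------------------------------- rigid


def test_rigid_identity_recovery(noisy_pair):
    # moving = fixed: near-exact identity
    res = m.register_rigid(noisy_pair.ct, noisy_pair.ct)
    assert abs(res.transform.rotation) < 0.1
    assert np.abs(res.transform.translation).max() < 0.1
    assert not res.low_confidence
    # multimodal co-registered pair: identity within registration accuracy
    pair = m.generate_pair(m.head_phantom_spec(128, seed=11))
    res2 = m.register_rigid(pair.ct, pair.mr)
    assert abs(res2.transform.rotation) < 1.0
    assert np.abs(res2.transform.translation).max() < 1.0


def test_rigid_known_misalignment_recovery():
    true = m.RigidTransform2D(5.0, (10.0, -7.0))
    pair = m.generate_pair(m.head_phantom_spec(128, seed=2, misalignment=true))
    res = m.register_rigid(pair.ct, pair.mr)
    inv = pair.true_misalignment.inverse()
    assert abs(res.transform.rotation - inv.rotation) < 1.0
    err = np.subtract(res.transform.translation, inv.translation)
    assert np.abs(err).max() < 1.0


def test_rigid_on_pure_noise_is_low_confidence():
    rng = np.random.default_rng(4)
    a = rng.normal(size=(64, 64))
    b = rng.normal(size=(64, 64))
    res = m.register_rigid(a, b, coarse_search=False)
    assert res.low_confidence


def test_rigid_cross_check_against_simpleitk():
    """Independent oracle: an established MI registration package recovers
    the same transform on the same pair."""
    import SimpleITK as sitk
    true = m.RigidTransform2D(4.0, (6.0, -5.0))
    pair = m.generate_pair(m.head_phantom_spec(128, seed=9, misalignment=true))
    fixed = sitk.GetImageFromArray(pair.ct.data.astype(np.float32))
    moving = sitk.GetImageFromArray(pair.mr.data.astype(np.float32))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-3, numberOfIterations=300)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler2DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY), inPlace=False)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2, 1, 0])
    out = reg.Execute(fixed, moving)
    if out.GetName() == "CompositeTransform":
        out = sitk.CompositeTransform(out).GetNthTransform(0)
    euler = sitk.Euler2DTransform(out)
    mine = m.register_rigid(pair.ct, pair.mr).transform
    assert abs(np.degrees(euler.GetAngle()) - mine.rotation) < 1.0
    assert np.abs(np.subtract(euler.GetTranslation(),
                              mine.translation)).max() < 1.5


def test_asgd_optimizer_refines_small_offset():
    true = m.RigidTransform2D(0.0, (2.0, -1.0))
    pair = m.generate_pair(m.head_phantom_spec(64, seed=6, misalignment=true))
    res = m.register_rigid(pair.ct, pair.mr, levels=1, method="asgd",
                           coarse_search=False, max_iter=60, seed=0)
    err = np.subtract(res.transform.translation,
                      pair.true_misalignment.inverse().translation)
    assert np.abs(err).max() < 1.0


# ---------------------------------------------------- bending / B-spline


def test_bending_energy_null_space():
    field = BSplineField.zeros((64, 64), 16)
    assert m.bending_energy(field, (64, 64)) == 0.0
    ny, nx = field.displacements.shape[:2]
    rows = np.arange(ny) * 16.0
    cols = np.arange(nx) * 16.0
    aff = np.zeros((ny, nx, 2))
    aff[:, :, 0] = 0.01 * cols[None, :] + 0.02 * rows[:, None] + 3.0
    aff[:, :, 1] = -0.03 * cols[None, :] + 1.0
    assert m.bending_energy(BSplineField(16, aff), (64, 64)) < 1e-20


def test_bending_energy_bump_matches_finite_differences():
    """Single control-point bump: the analytic spline integrand agrees with
    dense finite differences of the interpolated field (interior window)."""
    ny = nx = 5
    cp = np.zeros((ny, nx, 2))
    cp[2, 2, 0] = 2.0
    field = BSplineField(16, cp)
    u = field.dense((65, 65))[:, :, 0]
    uy, ux = np.gradient(u)
    uyy, _ = np.gradient(uy)
    uxy, uxx = np.gradient(ux)
    win = np.s_[2:-2, 2:-2]
    fd = np.sum(uxx[win] ** 2 + 2 * uxy[win] ** 2 + uyy[win] ** 2)
    sx, _ = field._splines()
    rows = np.arange(65.0)[2:-2]
    cols = np.arange(65.0)[2:-2]
    analytic = np.sum(sx(rows, cols, dx=0, dy=2) ** 2
                      + 2 * sx(rows, cols, dx=1, dy=1) ** 2
                      + sx(rows, cols, dx=2, dy=0) ** 2)
    assert analytic == pytest.approx(fd, rel=0.05)
    assert m.bending_energy(field, (65, 65)) >= analytic


def test_bspline_requires_init_and_sane_grid(noisy_pair):
    with pytest.raises(ValueError):
        register_bspline(noisy_pair.ct, noisy_pair.mr, None, 16)
    with pytest.raises(ValueError):
        register_bspline(noisy_pair.ct, noisy_pair.mr,
                         m.RigidTransform2D.identity(), 2)


def test_bspline_identity_stays_near_zero(noisy_pair):
    res = register_bspline(noisy_pair.ct, noisy_pair.mr,
                           m.RigidTransform2D.identity(), 16,
                           penalty_weight=1e-3, max_iter=25)
    assert np.abs(res.transform.field.displacements).max() < 1.0


def test_bspline_huge_penalty_degenerates_to_rigid_init(noisy_pair):
    res = register_bspline(noisy_pair.ct, noisy_pair.mr,
                           m.RigidTransform2D.identity(), 16,
                           penalty_weight=1e3, max_iter=25)
    dense = res.transform.field.dense(noisy_pair.ct.shape)
    assert np.sqrt((dense ** 2).sum(-1)).mean() < 0.5


def test_bspline_recovers_known_smooth_warp():
    pair = m.generate_pair(m.head_phantom_spec(64, seed=3))
    f0 = BSplineField.zeros((64, 64), 16)
    ny, nx = f0.displacements.shape[:2]
    rng = np.random.default_rng(0)
    cp = np.zeros((ny, nx, 2))
    cp[1:-1, 1:-1] = rng.uniform(-2.5, 2.5, size=(ny - 2, nx - 2, 2))
    true_field = BSplineField(16, cp)
    warped = m.warp(pair.mr, true_field)
    res = register_bspline(pair.ct, warped, m.RigidTransform2D.identity(), 16,
                           penalty_weight=1e-5, max_iter=60)
    assert isinstance(res.transform, CompositeTransform)
    rec = res.transform.field.dense((64, 64))
    true_dense = true_field.dense((64, 64))
    # the recovered field approximates the inverse (negated) warp
    err = np.sqrt(((rec + true_dense) ** 2).sum(-1))
    assert err.mean() < 1.0


def test_joint_histogram_normalized(noisy_pair):
    h = joint_histogram(noisy_pair.ct.data, noisy_pair.mr.data)
    assert h.sum() == pytest.approx(1.0)
    assert (h >= 0).all()
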