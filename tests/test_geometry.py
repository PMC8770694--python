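"""Superimposition, missing-landmark estimation and scalar shape traits."""

import numpy as np
import pytest

from craniomorph import (
    centroid_size, gpa, procrustes_distance, estimate_missing_tps,
    symmetric_subset, facial_length, template_cranium,
)
from craniomorph.geometry import MissingLandmarkError, distance_matrix
from conftest import make_config


def random_similarity(rng):
    A = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(A)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    scale = rng.uniform(0.2, 5.0)
    shift = rng.uniform(-100, 100, 3)
    return lambda X: scale * X @ q.T + shift


# --- centroid size ---------------------------------------------------------


def test_centroid_size_unit_tetrahedron():
    # hand computation: centroid (1/4,1/4,1/4); summed squared distances
    # 0.1875 + 3 * 0.6875 = 2.25, root 1.5
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    assert centroid_size(make_config(coords)) == pytest.approx(1.5)


@pytest.mark.parametrize("factor", [0.5, 2.0, 17.3])
def test_centroid_size_scales_linearly(factor):
    rng = np.random.default_rng(1)
    coords = rng.normal(size=(10, 3))
    assert centroid_size(coords * factor) == pytest.approx(factor * centroid_size(coords))


def test_centroid_size_degenerate_flagged():
    coords = np.ones((5, 3))
    with pytest.warns(UserWarning, match="degenerate"):
        assert centroid_size(coords) == 0.0


def test_centroid_size_requires_complete_config():
    cfg = make_config(np.random.default_rng(0).normal(size=(5, 3)), missing=[2])
    with pytest.raises(MissingLandmarkError):
        centroid_size(cfg)


# --- GPA -------------------------------------------------------------------


def test_gpa_identical_configs_have_zero_procrustes_distance():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(12, 3)) * 40
    transforms = [random_similarity(rng) for _ in range(4)]
    X = np.stack([base] + [t(base) for t in transforms])
    ali = gpa(X)
    D = distance_matrix(ali)
    assert np.abs(D).max() < 1e-9


def test_gpa_residual_ss_non_increasing():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 8, 3)) + np.arange(8)[None, :, None]
    ali = gpa(X)
    ss = np.array(ali.ss_history)
    assert np.all(np.diff(ss) <= 1e-12)


def test_gpa_matches_brute_force_rotation_search_on_planar_triangles():
    # 2D triangles embedded in z=0; the oracle grids over an in-plane
    # rotation angle plus an optional out-of-plane half-turn per specimen
    rng = np.random.default_rng(4)
    tris = []
    for _ in range(3):
        t = np.zeros((3, 3))
        t[:, :2] = rng.normal(size=(3, 2))
        tris.append(t)
    X = np.stack(tris)
    Xc = X - X.mean(axis=1, keepdims=True)
    Xc = Xc / np.sqrt((Xc ** 2).sum(axis=(1, 2)))[:, None, None]

    def rot(theta, flip):
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        if flip:  # half-turn about the x-axis: in-plane reflection, det +1
            R = R @ np.diag([1.0, -1.0, -1.0])
        return R

    def total_ss(params):
        rotated = np.stack([
            Xc[i] @ rot(theta, flip).T
            for i, (theta, flip) in enumerate(params)
        ])
        mean = rotated.mean(axis=0)
        return ((rotated - mean) ** 2).sum()

    grid = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    best, best_params = np.inf, None
    for f2 in (0, 1):
        for f3 in (0, 1):
            for t2 in grid:
                for t3 in grid:
                    ss = total_ss([(0.0, 0), (t2, f2), (t3, f3)])
                    if ss < best:
                        best, best_params = ss, [(0.0, 0), (t2, f2), (t3, f3)]
    # refine around the coarse optimum
    (_, _), (t2, f2), (t3, f3) = best_params
    fine = np.linspace(-0.12, 0.12, 81)
    for d2 in fine:
        for d3 in fine:
            ss = total_ss([(0.0, 0), (t2 + d2, f2), (t3 + d3, f3)])
            best = min(best, ss)

    ali = gpa(X)
    gpa_ss = ((ali.aligned - ali.aligned.mean(axis=0)) ** 2).sum()
    assert gpa_ss == pytest.approx(best, abs=1e-3)
    assert gpa_ss <= best + 1e-9


def test_gpa_invariant_to_input_similarity_transforms():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(8, 15, 3)) * 30
    D0 = distance_matrix(gpa(X))
    for trial in range(5):
        Xt = np.stack([random_similarity(rng)(x) for x in X])
        Dt = distance_matrix(gpa(Xt))
        assert np.abs(Dt - D0).max() < 1e-8


def test_log_centroid_size_ignores_rotation_translation():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(5, 10, 3)) * 25
    ali = gpa(X)
    rigid = []
    for x in X:
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rigid.append(x @ q.T + rng.uniform(-9, 9, 3))
    ali2 = gpa(np.stack(rigid))
    np.testing.assert_allclose(ali2.log_centroid_size, ali.log_centroid_size, atol=1e-9)


# --- Procrustes distance ---------------------------------------------------


def test_procrustes_distance_metric_properties():
    rng = np.random.default_rng(7)
    shapes = rng.normal(size=(100, 9))
    for _ in range(100):
        i, j, k = rng.integers(0, 100, 3)
        dij = procrustes_distance(shapes[i], shapes[j])
        dji = procrustes_distance(shapes[j], shapes[i])
        assert dij == pytest.approx(dji)
        assert dij <= procrustes_distance(shapes[i], shapes[k]) + \
            procrustes_distance(shapes[k], shapes[j]) + 1e-12
    assert procrustes_distance(shapes[0], shapes[0]) == 0.0
    with pytest.raises(ValueError, match="mismatch"):
        procrustes_distance(shapes[0], shapes[0][:6])


# --- thin-plate-spline missing-landmark estimation -------------------------


def test_tps_recovers_affine_transform_exactly():
    template, _, _ = template_cranium()
    affine = template @ np.array([[1.1, 0.2, 0.0], [-0.1, 0.9, 0.05], [0.0, 0.1, 1.2]]) + 5.0
    target = make_config(affine, missing=[10, 30])
    reference = make_config(template, specimen_id="ref")
    est = estimate_missing_tps(target, [reference])
    assert est.is_complete
    assert est.estimated_landmarks == [11, 31]
    np.testing.assert_allclose(est.coords, affine, atol=1e-8)


def test_tps_recovery_error_tracks_noise_level():
    rng = np.random.default_rng(8)
    template, _, _ = template_cranium()
    sigma = 0.5  # mm
    truth = template + rng.normal(0, sigma, template.shape)
    target = make_config(truth, missing=[25])
    est = estimate_missing_tps(target, [make_config(template, specimen_id="ref")])
    err = np.linalg.norm(est.coords[25] - truth[25])
    assert err < 10 * sigma


def test_tps_needs_at_least_four_anchors():
    template, _, _ = template_cranium()
    target = make_config(template.copy(), missing=list(range(3, 53)))
    with pytest.raises(ValueError, match="4 observed"):
        estimate_missing_tps(target, [make_config(template, specimen_id="ref")])


def test_tps_rejects_coplanar_anchors():
    coords = np.zeros((6, 3))
    coords[:, :2] = np.random.default_rng(9).normal(size=(6, 2))
    target = make_config(coords, missing=[5])
    ref = make_config(coords.copy(), specimen_id="ref")
    ref.coords[5] = [0, 0, 1]
    with pytest.raises(ValueError, match="coplanar"):
        estimate_missing_tps(target, [ref])


# --- symmetric subset and facial length ------------------------------------


def test_symmetric_subset_drops_left_side():
    template, labels, _ = template_cranium()
    cfg = make_config(template)
    cfg.landmark_labels = labels
    sub = symmetric_subset(cfg)
    assert sub.n_landmarks == 31
    assert not any(lab.endswith("_L") for lab in sub.landmark_labels)
    # retained labels keep their order
    kept = [lab for lab in labels if not lab.endswith("_L")]
    assert sub.landmark_labels == kept
    np.testing.assert_array_equal(sub.coords[0], cfg.coords[0])


def test_symmetric_subset_requires_53_landmarks():
    with pytest.raises(ValueError, match="k=53"):
        symmetric_subset(make_config(np.random.default_rng(0).normal(size=(10, 3))))


def test_facial_length_constructed_ratio_and_scale_invariance():
    coords = np.zeros((53, 3))
    rng = np.random.default_rng(10)
    coords[:] = rng.normal(size=(53, 3))
    coords[4] = [0, 0, 0]     # landmark 5
    coords[12] = [30, 0, 0]   # landmark 13
    coords[51] = [0, 60, 0]   # landmark 52
    cfg = make_config(coords)
    assert facial_length(cfg) == pytest.approx(0.5)
    assert facial_length(make_config(coords * 3)) == pytest.approx(0.5)


def test_facial_length_requires_its_landmarks():
    coords = np.random.default_rng(11).normal(size=(53, 3))
    cfg = make_config(coords, missing=[12])  # 1-based landmark 13
    with pytest.raises(MissingLandmarkError, match="13"):
        facial_length(cfg)
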