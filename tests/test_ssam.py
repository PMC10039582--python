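import numpy as np
import pytest
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from femrec import phantom as ph
from femrec import ssam
from femrec.image import VolumeImage
from femrec.mesh import MeshError, SurfaceDistance, TetMesh
from femrec.transforms import RigidTransform, rotation_about_axis


# ---------------------------------------------------------------------------
# rigid ICP
# ---------------------------------------------------------------------------

def test_icp_identity(coarse_phantom):
    mesh, _ = coarse_phantom
    tf, aligned = ssam.rigid_align(mesh, mesh)
    assert tf.rotation_angle() < 1e-9
    assert np.linalg.norm(tf.translation) < 1e-9
    np.testing.assert_allclose(aligned.vertices, mesh.vertices, atol=1e-9)


def test_icp_recovers_known_transform(coarse_phantom):
    mesh, _ = coarse_phantom
    true = RigidTransform(rotation_about_axis([0, 0, 1], 10.0), [5.0, 0.0, 0.0])
    moved = mesh.transformed(true)
    tf, aligned = ssam.rigid_align(moved, mesh)
    err = tf.compose(true)
    assert err.rotation_angle() < 0.1
    assert np.linalg.norm(err.apply(mesh.vertices) - mesh.vertices).max() < 0.1


def test_icp_noise_bound(coarse_phantom, rng):
    mesh, _ = coarse_phantom
    noisy = mesh.copy()
    idx = rng.choice(noisy.n_vertices, size=noisy.n_vertices // 5, replace=False)
    noise = rng.normal(scale=0.5 / np.sqrt(3), size=(len(idx), 3))
    noisy.vertices[idx] += noise
    _tf, aligned = ssam.rigid_align(noisy, mesh)
    d, _ = cKDTree(mesh.vertices).query(aligned.vertices)
    rms = np.sqrt((d**2).mean())
    assert rms <= 0.5  # bounded by the injected noise scale


def test_icp_empty_mesh_error(coarse_phantom):
    mesh, _ = coarse_phantom
    empty = mesh.copy()
    empty.vertices = np.zeros((0, 3))
    empty.triangles = np.zeros((0, 3), dtype=int)
    with pytest.raises(MeshError):
        ssam.rigid_align(empty, mesh)


# ---------------------------------------------------------------------------
# FFD correspondence
# ---------------------------------------------------------------------------

def test_ffd_identity(coarse_phantom):
    mesh, _ = coarse_phantom
    out, report = ssam.correspond_ffd(mesh, mesh, grid=(4,), iterations=2)
    assert report["final_mean_distance"] < 1e-6
    np.testing.assert_allclose(out.vertices, mesh.vertices, atol=1e-3)


def test_ffd_scaled_target(coarse_phantom):
    mesh, _ = coarse_phantom
    target = mesh.copy()
    target.vertices = target.vertices * 1.05
    out, report = ssam.correspond_ffd(mesh, target)
    assert SurfaceDistance(target)(out.vertices).mean() < 0.5
    # monotone across refinement levels
    dists = report["level_mean_distance"]
    assert all(b <= a + 1e-12 for a, b in zip(dists, dists[1:]))


def test_ffd_phantom_pair_known_correspondence():
    ref, _ = ph.generate_phantom(ph.PhantomParams(), 0)
    p2 = ph.PhantomParams(shaft_radius=15.5, condyle_offset=20.5, condyle_width=78)
    tgt, _ = ph.generate_phantom(p2, 0)
    out, _report = ssam.correspond_ffd(ref, tgt)
    err = np.linalg.norm(out.vertices - tgt.vertices, axis=1)
    assert err.mean() < 2.0  # generator correspondence is exact by construction


def test_ffd_disjoint_boxes_error(coarse_phantom):
    mesh, _ = coarse_phantom
    far = mesh.copy()
    far.vertices = far.vertices + 10000.0
    with pytest.raises(MeshError, match="overlap"):
        ssam.correspond_ffd(mesh, far)


# ---------------------------------------------------------------------------
# Laplace tet morph
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def convex_tets(rng):
    pts = rng.uniform(-1, 1, size=(250, 3))
    tm = TetMesh(pts, Delaunay(pts).simplices, ConvexHull(pts).simplices)
    return tm.orient_positive()


def test_morph_zero_displacement(convex_tets):
    b = convex_tets.boundary_nodes()
    out, info = ssam.morph_tet_mesh(convex_tets, np.zeros((len(b), 3)))
    np.testing.assert_allclose(out.nodes, convex_tets.nodes, atol=1e-10)
    assert info["inverted_fraction"] == 0.0


def test_morph_uniform_translation(convex_tets):
    b = convex_tets.boundary_nodes()
    t = np.array([3.0, -2.0, 1.0])
    out, _ = ssam.morph_tet_mesh(convex_tets, np.tile(t, (len(b), 1)))
    np.testing.assert_allclose(out.nodes, convex_tets.nodes + t, atol=1e-9)


def test_morph_affine_exact(convex_tets):
    a = np.array([[1.1, 0.2, 0.0], [0.0, 0.9, 0.1], [0.05, 0.0, 1.2]])
    t = np.array([1.0, 2.0, 3.0])
    b = convex_tets.boundary_nodes()
    disp = convex_tets.nodes[b] @ a.T + t - convex_tets.nodes[b]
    out, _ = ssam.morph_tet_mesh(convex_tets, disp)
    expected = convex_tets.nodes @ a.T + t
    assert np.abs(out.nodes - expected).max() < 1e-8


def test_morph_shape_mismatch(convex_tets):
    with pytest.raises(MeshError, match="boundary_displacement"):
        ssam.morph_tet_mesh(convex_tets, np.zeros((3, 3)))


def test_morph_phantom_boundary_exact(corresponded_tets, small_population):
    ref = ph.phantom_tet_mesh(small_population[0].params, 0)
    disp = small_population[1].mesh.vertices - small_population[0].mesh.vertices
    out, info = ssam.morph_tet_mesh(ref, disp[ref.boundary_nodes()])
    np.testing.assert_allclose(
        out.nodes[: len(disp)], small_population[1].mesh.vertices, atol=1e-9
    )
    assert info["inverted_fraction"] < 0.02


# ---------------------------------------------------------------------------
# appearance mapping
# ---------------------------------------------------------------------------

def test_map_appearance_constant_volume(convex_tets):
    vol = VolumeImage(np.full((30, 30, 30), 321.0), [0.1] * 3, [-1.5] * 3)
    out = ssam.map_appearance(convex_tets, vol)
    np.testing.assert_allclose(out.cell_hu, 321.0)


def test_map_appearance_exact_voxel():
    nodes = np.array([[0, 0, 0], [0.2, 0, 0], [0, 0.2, 0], [0, 0, 0.2]], dtype=float)
    # centroid at (0.05, 0.05, 0.05) == center of voxel (1,1,1) for spacing 0.05 origin 0
    tm = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.zeros((0, 3), int)).orient_positive()
    data = np.zeros((8, 8, 8), dtype=np.float32)
    data[1, 1, 1] = 77.0
    vol = VolumeImage(data, [0.05] * 3, [0.0] * 3)
    out = ssam.map_appearance(tm, vol)
    assert out.cell_hu[0] == 77.0


def test_map_appearance_out_of_bounds(convex_tets):
    vol = VolumeImage(np.zeros((4, 4, 4)), [0.1] * 3, [100.0] * 3)
    with pytest.raises(Exception, match="outside"):
        ssam.map_appearance(convex_tets, vol)


def test_map_appearance_phantom_labels(corresponded_tets, small_population):
    """Cortical/medullary cells match the analytic phantom geometry."""
    tm = corresponded_tets[0]
    params = small_population[0].params
    labels = ph.classify_points(tm.centroids(), params)
    spacing = float(small_population[0].volume.spacing[0])
    # only judge cells clearly away from the cortex/canal interface
    sweep = ph._Sweep(params)
    depth = ph._Classifier(sweep).depth(tm.centroids())
    clear = (np.abs(depth - params.cortical_thickness) > spacing) & (depth > spacing / 2)
    expected = np.where(labels == 1, params.cortical_hu, params.medullary_hu)
    ok = np.isclose(tm.cell_hu[clear], expected[clear], atol=0.5).mean()
    assert ok >= 0.95


# ---------------------------------------------------------------------------
# PCA model
# ---------------------------------------------------------------------------

def _const_hu(tm, value):
    out = tm.copy()
    out.cell_hu = np.full(len(tm.tets), float(value))
    return out


def test_two_identical_specimens():
    tm = ph.phantom_tet_mesh(ph.PhantomParams(), 0)
    model = ssam.build_ssam([_const_hu(tm, 100), _const_hu(tm, 100)])
    assert model.n_modes == 0 or np.all(model.eigenvalues < 1e-12)
    np.testing.assert_allclose(model.mean_shape, tm.nodes.reshape(-1))


def test_two_distinct_specimens_single_mode():
    a = _const_hu(ph.phantom_tet_mesh(ph.PhantomParams(), 0), 100)
    b = _const_hu(ph.phantom_tet_mesh(ph.PhantomParams(bone_length=460), 0), 150)
    model = ssam.build_ssam([a, b])
    assert model.n_modes == 1
    # closed form: single mode proportional to the (scaled) difference vector
    diff_shape = (b.nodes - a.nodes).reshape(-1)
    diff_app = (b.cell_hu - a.cell_hu) * model.appearance_scale
    diff = np.concatenate([diff_shape, diff_app])
    diff /= np.linalg.norm(diff)
    dot = abs(model.modes[0] @ diff)
    assert dot == pytest.approx(1.0, abs=1e-9)
    # eigenvalue equals the squared distance to the mean
    assert model.eigenvalues[0] == pytest.approx(np.sum(
        (np.concatenate([a.nodes.reshape(-1), a.cell_hu * model.appearance_scale])
         - np.concatenate([model.mean_shape, model.mean_appearance * model.appearance_scale]))**2
    ) * 2.0 / 1.0, rel=1e-9)


def test_length_only_population_first_mode():
    tets = [
        _const_hu(ph.phantom_tet_mesh(ph.PhantomParams(bone_length=el), 0), 100)
        for el in np.linspace(400, 460, 10)
    ]
    model = ssam.build_ssam(tets, use_appearance=False)
    explained = model.eigenvalues[0] / model.eigenvalues.sum()
    assert explained > 0.95
    weights = np.array([ssam.project_weights(model, t)[0] for t in tets])
    lengths = np.linspace(400, 460, 10)
    corr = abs(np.corrcoef(weights, lengths)[0, 1])
    assert corr > 0.99


def test_training_reconstruction(corresponded_tets, small_model):
    for tm in corresponded_tets:
        b = ssam.project_weights(small_model, tm)
        nodes, hu = small_model.instantiate_arrays(b)
        assert np.abs(nodes - tm.nodes).max() < 1e-6
        assert np.abs(hu - tm.cell_hu).max() < 1e-6


def test_mode_orthonormality(small_model):
    gram = small_model.modes @ small_model.modes.T
    assert np.abs(gram - np.eye(small_model.n_modes)).max() < 1e-8


def test_eigenvalues_descending_nonnegative(small_model):
    ev = small_model.eigenvalues
    assert (ev >= 0).all()
    assert (np.diff(ev) <= 1e-9).all()
    assert small_model.n_modes <= small_model.n_specimens - 1


def test_compactness_monotone(small_model):
    cum = np.cumsum(small_model.eigenvalues) / small_model.eigenvalues.sum()
    assert (np.diff(cum) >= -1e-12).all()


def test_instantiate_mean(small_model):
    surf, tm = ssam.instantiate(small_model, np.zeros(1))
    np.testing.assert_allclose(tm.nodes.reshape(-1), small_model.mean_shape)
    np.testing.assert_allclose(tm.cell_hu, small_model.mean_appearance)


def test_instantiate_symmetry(small_model):
    plus, _ = ssam.instantiate(small_model, np.array([2.0]))
    minus, _ = ssam.instantiate(small_model, np.array([-2.0]))
    mean, _ = ssam.instantiate(small_model, np.array([0.0]))
    np.testing.assert_allclose(
        plus.vertices + minus.vertices, 2 * mean.vertices, atol=1e-8
    )


def test_instantiate_too_many_weights(small_model):
    with pytest.raises(ValueError, match="modes"):
        small_model.instantiate_arrays(np.zeros(small_model.n_modes + 1))


def test_specificity_watertight(small_model, rng):
    from femrec.mesh import check_no_self_intersection

    for _ in range(3):
        b = rng.uniform(-3, 3, size=min(4, small_model.n_modes))
        surf, _ = ssam.instantiate(small_model, b)
        assert surf.is_watertight()
        assert check_no_self_intersection(surf, n_samples=120)


def test_topology_mismatch_error(corresponded_tets):
    other = ph.phantom_tet_mesh(ph.PhantomParams(), 1)
    other.cell_hu = np.zeros(len(other.tets))
    with pytest.raises(MeshError, match="topology"):
        ssam.build_ssam([corresponded_tets[0], other])


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------

def test_loo_rank_bound():
    tets = [
        _const_hu(ph.phantom_tet_mesh(ph.PhantomParams(bone_length=el), 0), 100)
        for el in (410.0, 430.0, 450.0)
    ]
    model, held = ssam.leave_one_out(tets, 0)
    assert model.n_specimens == 2
    assert (model.eigenvalues > 1e-10).sum() <= 1
    assert held is tets[0]


def test_loo_partition(corresponded_tets):
    model, held = ssam.leave_one_out(corresponded_tets, 3)
    assert model.n_specimens == len(corresponded_tets) - 1
    assert held is corresponded_tets[3]


def test_loo_residual_positive(corresponded_tets):
    model, held = ssam.leave_one_out(corresponded_tets, 0)
    b = ssam.project_weights(model, held)
    nodes, _ = model.instantiate_arrays(b)
    loo_err = np.abs(nodes - held.nodes).max()
    assert loo_err > 1e-3  # generic population: held-out not in the span


def test_loo_index_error(corresponded_tets):
    with pytest.raises(IndexError):
        ssam.leave_one_out(corresponded_tets, 99)
    with pytest.raises(ValueError):
        ssam.leave_one_out(corresponded_tets[:2], 0)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def test_hdf5_roundtrip(tmp_path, small_model):
    path = tmp_path / "model.h5"
    small_model.save(path)
    back = ssam.SSAM.load(path)
    np.testing.assert_allclose(back.mean_shape, small_model.mean_shape)
    np.testing.assert_allclose(back.modes, small_model.modes)
    np.testing.assert_allclose(back.eigenvalues, small_model.eigenvalues)
    np.testing.assert_array_equal(back.tets, small_model.tets)
    assert back.appearance_flag == small_model.appearance_flag
    assert back.appearance_scale == pytest.approx(small_model.appearance_scale)
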