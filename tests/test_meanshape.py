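"""Mean-shape pipeline: iso-surfaces, remeshing, Procrustes,
correspondence, voxelization, and population coherence."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

import trimesh as _trimesh

from saseg.meanshape import (
    LandmarkedShapeSet,
    MeanShapeBuilder,
    compute_mean_shape,
    establish_correspondence,
    extract_surface,
    procrustes_align,
    remesh,
    voxelize,
)
from saseg.metrics import dice_score
from saseg.volio import BinaryMask, TriMesh


def make_trimesh(tm):
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# --- extract_surface -------------------------------------------------------

def test_cube_surface_bounding_box():
    data = np.zeros((14, 14, 14), np.uint8)
    data[2:12, 2:12, 2:12] = 1  # 10 voxels per side at 1 mm
    mesh = extract_surface(BinaryMask(data, (1, 1, 1)))
    extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    np.testing.assert_allclose(extent, 10.0, atol=1.0)


def test_sphere_surface_area(sphere_mask):
    mesh = extract_surface(sphere_mask)
    area = mesh.to_trimesh().area
    assert area == pytest.approx(4 * np.pi * 64, rel=0.10)


def test_empty_mask_has_no_surface():
    with pytest.raises(ValueError):
        extract_surface(BinaryMask(np.zeros((4, 4, 4), np.uint8), (1, 1, 1)))


# --- remesh ----------------------------------------------------------------

@pytest.fixture()
def sphere_mesh_10mm():
    shape = (30, 30, 30)
    c = np.asarray(shape) / 2 - 0.5
    idx = np.indices(shape)
    r2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
    mask = BinaryMask((r2 < (10 / 0.8) ** 2).astype(np.uint8), (0.8, 0.8, 0.8))
    return extract_surface(mask)


def test_remesh_median_edge_in_band(sphere_mesh_10mm):
    out = remesh(sphere_mesh_10mm, 1.0)
    edges = out.to_trimesh().edges_unique_length
    assert 0.5 <= np.median(edges) <= 1.5


def test_remesh_preserves_volume(sphere_mesh_10mm):
    v_in = sphere_mesh_10mm.to_trimesh().volume
    v_out = remesh(sphere_mesh_10mm, 1.0).to_trimesh().volume
    assert abs(v_out - v_in) / v_in < 0.05


def test_remesh_near_idempotent(sphere_mesh_10mm):
    once = remesh(sphere_mesh_10mm, 1.0)
    twice = remesh(once, 1.0)
    change = abs(len(twice.vertices) - len(once.vertices)) / len(once.vertices)
    assert change < 0.5


def test_remesh_rejects_nonpositive_edge(sphere_mesh_10mm):
    with pytest.raises(ValueError):
        remesh(sphere_mesh_10mm, 0.0)


# --- generalized Procrustes ------------------------------------------------

def test_gpa_removes_similarity_transforms(rng):
    base = rng.normal(size=(30, 3))
    shapes = []
    for i in range(6):
        R = Rotation.random(random_state=i).as_matrix()
        s = float(rng.uniform(0.5, 2.0))
        t = rng.normal(size=3) * 20
        shapes.append(base @ R.T * s + t)
    aligned, _ = procrustes_align(LandmarkedShapeSet(np.stack(shapes)))
    for i in range(1, 6):
        rmsd = np.sqrt(((aligned.landmarks[i] - aligned.landmarks[0]) ** 2).mean())
        assert rmsd < 1e-6


def test_gpa_matches_closed_form_pairwise_procrustes(rng):
    # two planar triangles embedded in 3D: the optimal rotation aligning
    # one to the other is the closed-form SVD solution
    a = np.array([[0, 0, 0], [4, 0, 0], [0, 2, 0], [1.0, 1.0, 0]])
    R_true = Rotation.from_euler("xyz", [0.3, -0.5, 1.0]).as_matrix()
    b = a @ R_true.T
    aligned, _ = procrustes_align(LandmarkedShapeSet(np.stack([a, b])))
    # closed-form check on the centred/normalized pair
    an = (a - a.mean(0)) / np.linalg.norm(a - a.mean(0))
    bn = (b - b.mean(0)) / np.linalg.norm(b - b.mean(0))
    R_opt, _ = orthogonal_procrustes(bn, an)
    np.testing.assert_allclose(bn @ R_opt, an, atol=1e-12)
    # the GPA result superimposes the two shapes as well as the closed form
    gpa_resid = np.linalg.norm(aligned.landmarks[0] - aligned.landmarks[1])
    cf_resid = np.linalg.norm(bn @ R_opt - an)
    assert gpa_resid <= cf_resid + 1e-9


def test_gpa_idempotent(rng):
    base = rng.normal(size=(20, 3))
    shapes = np.stack([base + 0.05 * rng.normal(size=(20, 3)) for _ in range(4)])
    aligned, _ = procrustes_align(LandmarkedShapeSet(shapes))
    again, _ = procrustes_align(LandmarkedShapeSet(aligned.landmarks))
    rmsd = np.sqrt(((aligned.landmarks - again.landmarks) ** 2).mean())
    assert rmsd < 1e-6


def test_gpa_rejects_degenerate_shape():
    flat = np.zeros((2, 5, 3))
    flat[1] = np.random.default_rng(0).normal(size=(5, 3))
    with pytest.raises(ValueError, match="degenerate"):
        procrustes_align(LandmarkedShapeSet(flat))


def test_mean_shape_order_invariance(rng):
    shapes = rng.normal(size=(5, 12, 3))
    aligned, _ = procrustes_align(LandmarkedShapeSet(shapes))
    perm = aligned.landmarks[::-1].copy()
    m1 = aligned.landmarks.mean(axis=0)
    m2 = perm.mean(axis=0)
    np.testing.assert_allclose(m1, m2, atol=1e-12)


# --- correspondence --------------------------------------------------------

@pytest.fixture(scope="module")
def icosphere():
    sp = _trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return TriMesh(np.asarray(sp.vertices), np.asarray(sp.faces))


def test_correspondence_identity(icosphere):
    corr = establish_correspondence(icosphere, icosphere)
    np.testing.assert_allclose(corr, icosphere.vertices, atol=1e-6)


def test_correspondence_translation_equivariance(icosphere):
    shifted = TriMesh(icosphere.vertices + np.array([5.0, -3.0, 2.0]), icosphere.faces)
    corr = establish_correspondence(icosphere, shifted)
    np.testing.assert_allclose(corr, shifted.vertices, atol=1e-5)


def test_correspondence_under_radial_noise(icosphere):
    rng = np.random.default_rng(1)
    amp = 0.02  # 2% radial noise
    radii = 1.0 + amp * rng.normal(size=len(icosphere.vertices))
    target = TriMesh(icosphere.vertices * radii[:, None], icosphere.faces)
    corr = establish_correspondence(icosphere, target)
    err = np.linalg.norm(corr - target.vertices, axis=1).mean()
    assert err < 2 * amp * 10.0


# --- mean + voxelization ---------------------------------------------------

def test_mean_of_reflected_pair_is_midplane(rng):
    base = rng.normal(size=(10, 3))
    base -= base.mean(axis=0)
    reflected = base.copy()
    reflected[:, 2] *= -1
    mean = np.stack([base, reflected]).mean(axis=0)
    np.testing.assert_allclose(mean[:, 2], 0.0, atol=1e-12)
    np.testing.assert_allclose(mean[:, :2], base[:, :2], atol=1e-12)


def test_compute_mean_of_identical_shapes(icosphere):
    lms = np.stack([icosphere.vertices] * 3)
    aligned, _ = procrustes_align(LandmarkedShapeSet(lms))
    model = compute_mean_shape(aligned, icosphere.faces, scale_mm=40.0, voxel_spacing=1.0)
    assert not model.voxelized.is_empty()
    # mean of identical shapes is the shape itself (up to similarity)
    unit = aligned.landmarks[0]
    np.testing.assert_allclose(aligned.landmarks.mean(axis=0), unit, atol=1e-9)


def test_voxelize_cube_volume():
    box = _trimesh.creation.box(extents=(10, 10, 10))
    box.apply_translation([7, 7, 7])
    vox = voxelize(make_trimesh(box), (1, 1, 1), (15, 15, 15))
    assert int(vox.data.sum()) == pytest.approx(1000, rel=0.10)


def test_voxelize_sphere_volume_and_convergence():
    sp = _trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    sp.apply_translation([7, 7, 7])
    mesh = make_trimesh(sp)
    expect = (4 / 3) * np.pi * 125
    coarse = voxelize(mesh, (1.0, 1.0, 1.0), (15, 15, 15))
    fine = voxelize(mesh, (0.5, 0.5, 0.5), (29, 29, 29))
    vol_fine = fine.data.sum() * 0.125
    vol_coarse = coarse.data.sum() * 1.0
    assert vol_fine == pytest.approx(expect, rel=0.05)
    # refinement converges towards the mesh volume
    assert abs(vol_fine - sp.volume) <= abs(vol_coarse - sp.volume)


def test_voxelize_rejects_open_mesh():
    tri = TriMesh(np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]]))
    with pytest.raises(ValueError, match="watertight"):
        voxelize(tri, (1, 1, 1), (4, 4, 4))


def test_surface_voxel_roundtrip_dice(sphere_mask):
    mesh = extract_surface(sphere_mask)
    vox = voxelize(mesh, sphere_mask.spacing, sphere_mask.data.shape)
    assert dice_score(vox, sphere_mask) > 0.98


# --- pipeline --------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_builder(request):
    from saseg.phantomgen import PhantomParams, make_population

    masks = make_population(6, PhantomParams(), seed=7)
    return MeanShapeBuilder(target_edge_mm=1.5).fit(masks), masks


def test_pipeline_population_coherence(fitted_builder):
    """The mean model, mapped back into each input's pose, overlaps every
    training shape with Dice > 0.7."""
    builder, masks = fitted_builder
    faces = builder.model_.mean_mesh.faces
    unit = builder.landmarks_.landmarks.mean(axis=0)
    unit = unit - unit.mean(axis=0)
    unit /= np.linalg.norm(unit)
    for i, m in enumerate(masks):
        pts = builder.transforms_[i].inverse(unit)
        vox = voxelize(TriMesh(pts, faces), m.spacing, m.data.shape)
        assert dice_score(vox, m) > 0.7


def test_pipeline_provenance(fitted_builder):
    builder, masks = fitted_builder
    prov = builder.model_.provenance
    assert prov["n"] == len(masks)
    assert prov["l"] >= 4
    assert not builder.model_.voxelized.is_empty()


def test_pipeline_needs_two_masks(phantom_population):
    with pytest.raises(ValueError, match="2"):
        MeanShapeBuilder().fit(phantom_population[:1])


def test_pipeline_invariant_to_input_pretransform(rng):
    """GPA invariance at pipeline level: a rotated/shifted copy of every
    mask yields the same aligned landmark geometry (RMSD < 1e-6 after
    superimposing the two means)."""
    base = rng.normal(size=(40, 3))
    shapes = np.stack([base + 0.1 * rng.normal(size=(40, 3)) for _ in range(4)])
    aligned1, _ = procrustes_align(LandmarkedShapeSet(shapes))
    pre = []
    for i, s in enumerate(shapes):
        R = Rotation.random(random_state=100 + i).as_matrix()
        pre.append(s @ R.T * float(rng.uniform(0.5, 2)) + rng.normal(size=3) * 15)
    aligned2, _ = procrustes_align(LandmarkedShapeSet(np.stack(pre)))
    m1 = aligned1.landmarks.mean(axis=0)
    m2 = aligned2.landmarks.mean(axis=0)
    R_fix, _ = orthogonal_procrustes(m2, m1)
    rmsd = np.sqrt(((m2 @ R_fix - m1) ** 2).mean())
    assert rmsd < 1e-6
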