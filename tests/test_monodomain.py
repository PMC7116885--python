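import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from fibroclefts import (
    FibrosisNetwork,
    make_grid_2d,
    make_slab_3d,
    split_mesh,
)
from fibroclefts.monodomain import (
    CHI,
    CM,
    ActivationMap,
    ConductivityField,
    StimulusSpec,
    assemble_operators,
    detect_activation_times,
    lge_conductivity_bands,
    measure_cv,
    run_monodomain,
)

MM2_TO_CM2 = 0.01
MM3_TO_CM3 = 0.001


def _fence_grid(n=12, edge=0.5):
    """Grid split by a complete horizontal no-flux fence at mid-height."""
    mesh = make_grid_2d(n, edge)

    def vid(i, j):
        return j * (n + 1) + i

    row = n // 2
    network = FibrosisNetwork(
        {tuple(sorted((vid(i, row), vid(i + 1, row)))) for i in range(n)}
    )
    return split_mesh(mesh, network).mesh, row * edge


@pytest.mark.parametrize(
    "mesh, scale",
    [
        (make_grid_2d(6, 0.5), MM2_TO_CM2),
        (make_slab_3d((3.0, 2.0, 2.0), 1.0), MM3_TO_CM3),
    ],
    ids=["triangles", "tetrahedra"],
)
def test_operator_structure(mesh, scale):
    mass, K = assemble_operators(mesh, ConductivityField(3.0, 0.5))
    # no-flux (pure Neumann) stiffness annihilates constants
    assert np.abs(K @ np.ones(mesh.n_vertices)).max() < 1e-10
    assert np.isclose(mass.sum(), mesh.measures().sum() * scale)
    assert np.all(mass > 0)
    # symmetric positive semi-definite
    assert abs(K - K.T).max() < 1e-12
    x = np.random.default_rng(0).standard_normal(mesh.n_vertices)
    assert x @ (K @ x) >= -1e-10


def test_anisotropy_requires_orientation():
    mesh = make_grid_2d(3, 1.0)
    mesh.orientation = None
    with pytest.raises(ValueError):
        assemble_operators(mesh, ConductivityField(3.0, 0.5))
    # isotropic works without triads
    assemble_operators(mesh, ConductivityField.isotropic(1.0))


def test_nonpositive_conductivity_rejected():
    mesh = make_grid_2d(3, 1.0)
    with pytest.raises(ValueError):
        assemble_operators(mesh, ConductivityField(-1.0, 1.0))


@pytest.mark.parametrize(
    "i_star, expected",
    [
        (0.0, (1.0, 0.75)),   # band edge: lowest band
        (0.10, (1.0, 0.75)),
        (0.30, (1.0, 0.5)),
        (0.60, (0.75, 0.5)),
        (0.80, (0.5, 0.5)),
        (1.0, (0.5, 0.5)),
    ],
)
def test_lge_conductivity_bands(i_star, expected):
    assert lge_conductivity_bands(i_star) == expected


def test_lge_bands_reject_out_of_range():
    with pytest.raises(ValueError):
        lge_conductivity_bands(1.2)


def test_split_fence_blocks_diffusion():
    mesh, row_y = _fence_grid()
    mass, K = assemble_operators(mesh, ConductivityField.isotropic(1.0))
    below = mesh.centroids()[:, 1] < row_y
    vmask = np.zeros(mesh.n_vertices, bool)
    vmask[np.unique(mesh.elements[below])] = True
    v = np.where(vmask, 0.0, 1.0)
    # energy coupling across the fence vanishes for side-constant fields
    assert abs(v @ (K @ (1.0 - v))) < 1e-12
    dt = 0.02
    A = sp.csc_matrix(sp.diags(mass) + dt / (CHI * CM) * K)
    lu = spla.splu(A)
    u = v.copy()
    for _ in range(2500):  # 50 ms of pure diffusion
        u = lu.solve(mass * u)
    assert np.abs(u - v).max() < 1e-10  # both plateaus preserved exactly


def test_no_stimulus_stays_at_rest(tt_model):
    mesh = make_grid_2d(4, 0.5)
    res = run_monodomain(
        mesh, ConductivityField.isotropic(1.0), [], 500.0, tt_model
    )
    assert len(res.activation) == 0
    from fibroclefts.cells import resting_state

    v_rest = resting_state(tt_model)[0, 0]
    assert np.abs(res.state[0] - v_rest).max() < 0.1


def test_planar_wave_activation_is_linear_in_distance(ms_model):
    mesh = make_grid_2d(16, 0.5)
    x = mesh.vertices[:, 0]
    stim = StimulusSpec(mask=x <= 0.51, strength=500.0, duration=2.0)
    res = run_monodomain(
        mesh, ConductivityField.isotropic(1.0), [stim], 40.0, ms_model
    )
    at = res.activation.first_crossing()
    window = (x > 2.0) & (x < 6.0)
    assert np.isfinite(at[window]).all()
    slope, intercept = np.polyfit(x[window], at[window], 1)
    resid = at[window] - (slope * x[window] + intercept)
    assert np.abs(resid).max() < 1.0  # ms deviation from a constant-CV wave
    cv = measure_cv(at, mesh.vertices, 0, window)
    assert cv > 0


def test_cv_scales_with_sqrt_conductivity(ms_model):
    mesh = make_grid_2d(16, 0.5)
    x = mesh.vertices[:, 0]
    stim = StimulusSpec(mask=x <= 0.51, strength=500.0, duration=2.0)
    window = (x > 2.0) & (x < 6.0)
    cvs = []
    for sigma in (0.5, 2.0):
        res = run_monodomain(
            mesh, ConductivityField.isotropic(sigma), [stim], 60.0, ms_model
        )
        cvs.append(measure_cv(res.activation.first_crossing(),
                              mesh.vertices, 0, window))
    assert cvs[1] / cvs[0] == pytest.approx(2.0, rel=0.15)


def test_stimulus_in_enclosed_region_cannot_escape(ms_model):
    slab = make_slab_3d((4.0, 4.0, 4.0), 1.0)
    inside_el = np.all(
        np.abs(slab.centroids() - 2.0) < 1.0, axis=1
    )
    faces = {}
    import itertools

    for e in np.where(inside_el)[0]:
        for c in itertools.combinations(
            sorted(int(v) for v in slab.elements[e]), 3
        ):
            faces[c] = faces.get(c, 0) + 1
    from fibroclefts.mesh import build_adjacency

    adjacency = build_adjacency(slab)
    boundary_faces = set()
    for fk, count in faces.items():
        if count == 1:  # surface of the enclosed block
            owners = adjacency.face_to_elements[fk]
            if len(owners) == 2:
                boundary_faces.add(fk)
    network = FibrosisNetwork(boundary_faces)
    split = split_mesh(slab, network)
    stim = StimulusSpec(site=(2.0, 2.0, 2.0), radius=0.9, strength=800.0,
                        duration=2.0)
    res = run_monodomain(
        split.mesh, ConductivityField.isotropic(1.0), [stim], 60.0, ms_model
    )
    at = res.activation.first_crossing()
    outside_v = np.zeros(split.mesh.n_vertices, bool)
    outside_v[np.unique(split.mesh.elements[~inside_el])] = True
    inside_only = ~outside_v
    assert np.isfinite(at[inside_only]).any()  # the enclosure does activate
    assert not np.isfinite(at[outside_v]).any()  # nothing leaks out


def test_detect_activation_times_interpolates():
    times = np.arange(0.0, 20.0, 1.0)
    vm = np.where(times < 11, -80.0, 30.0)
    t = detect_activation_times(vm, times)
    assert 10.0 < t < 11.0
    assert np.isnan(detect_activation_times(np.full(20, -80.0), times))
    falling = np.where(times < 11, 30.0, -80.0)
    # the initial sample is already above threshold: no upward crossing
    assert np.isnan(detect_activation_times(falling, times))


def test_measure_cv_on_synthetic_slope():
    coords = np.column_stack([np.linspace(0, 10, 30), np.zeros(30), np.zeros(30)])
    at = coords[:, 0] / 0.84  # 0.84 mm/ms
    assert measure_cv(at, coords, 0) == pytest.approx(84.0, rel=1e-6)
    with pytest.raises(ValueError, match="fewer than 3"):
        measure_cv(np.full(30, np.nan), coords, 0)
    with pytest.raises(ValueError, match="advance"):
        measure_cv(-at, coords, 0)


def test_cg_and_lu_solvers_agree(ms_model):
    mesh = make_grid_2d(8, 0.5)
    stim = StimulusSpec(site=(2.0, 2.0, 0.0), radius=0.8, strength=500.0,
                        duration=2.0)
    kw = dict(duration=20.0, model=ms_model)
    cond = ConductivityField.isotropic(1.0)
    res_lu = run_monodomain(mesh, cond, [stim], solver="lu", **kw)
    res_cg = run_monodomain(mesh, cond, [stim], solver="cg", **kw)
    assert np.abs(res_lu.state[0] - res_cg.state[0]).max() < 1e-3


def test_run_monodomain_validates_inputs(ms_model):
    mesh = make_grid_2d(4, 0.5)
    cond = ConductivityField.isotropic(1.0)
    with pytest.raises(ValueError):
        run_monodomain(mesh, cond, [], -1.0, ms_model)
    with pytest.raises(ValueError):
        run_monodomain(mesh, cond, [], 10.0, ms_model, dt=1.0)
    with pytest.raises(ValueError):
        run_monodomain(mesh, cond, [], 10.0, ms_model,
                       initial_state=np.zeros((2, 3)))


def test_activation_map_windows():
    amap = ActivationMap(5)
    amap.add(np.array([0, 1, 2]), np.array([5.0, 15.0, 25.0]))
    amap.add(np.array([0]), np.array([40.0]))
    first = amap.first_crossing()
    assert first[0] == 5.0 and np.isnan(first[3])
    late = amap.first_crossing(30.0, 50.0)
    assert late[0] == 40.0 and np.isnan(late[1])
    mask = np.array([True, False, False, False, False])
    assert amap.any_in(mask, 30.0, 50.0)
    assert not amap.any_in(mask, 6.0, 39.0)
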