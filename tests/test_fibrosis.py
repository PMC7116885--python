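import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibroclefts import (
    FibrosisNetwork,
    build_adjacency,
    density_sweep,
    face_probability,
    normalize_intensity,
    probability_map,
    sample_network,
    synthetic_lge_fixture,
    tag_lge,
)
from fibroclefts.fibrosis import ProbabilityMap, read_network, write_network


@pytest.mark.parametrize(
    "i, expected",
    [(1.0, 0.0), (3.0, 1.0), (2.0, 0.5), (0.0, 0.0), (5.0, 1.0)],
)
def test_normalize_intensity_values(i, expected):
    assert normalize_intensity(i, 1.0, 3.0) == pytest.approx(expected)


def test_normalize_intensity_requires_ordered_levels():
    with pytest.raises(ValueError):
        normalize_intensity(1.0, 2.0, 2.0)


@pytest.mark.parametrize(
    "i_star, theta, rho, expected",
    [
        (1.0, np.pi / 2, 1.0, 0.0),   # face lying within a sheet: never split
        (1.0, 0.0, 1.0, 1.0),
        (0.5, 0.0, 0.5, 0.25),
        (0.5, np.pi, 0.5, 0.25),      # flipped normal, same cleft
    ],
)
def test_face_probability_values(i_star, theta, rho, expected):
    assert face_probability(i_star, theta, rho) == pytest.approx(expected, abs=1e-12)


def test_face_probability_rejects_out_of_range():
    with pytest.raises(ValueError):
        face_probability(1.5, 0.0, 0.5)
    with pytest.raises(ValueError):
        face_probability(0.5, 0.0, 1.5)


@settings(deadline=None, max_examples=200)
@given(
    i_star=st.floats(0.0, 1.0),
    theta=st.floats(-np.pi, np.pi),
    rho=st.floats(0.0, 1.0),
)
def test_face_probability_bounded_and_sign_symmetric(i_star, theta, rho):
    p = face_probability(i_star, theta, rho)
    assert 0.0 <= p <= rho + 1e-12
    assert p == pytest.approx(face_probability(i_star, -theta, rho), abs=1e-12)


def test_probability_map_confined_to_lge_interior(lge_slab):
    slab, intensity = lge_slab
    adjacency = build_adjacency(slab)
    pmap = probability_map(slab, intensity, 0.8, adjacency)
    assert pmap.p, "the enhancement zone must contain interior faces"
    boundary = {
        f for f, e in adjacency.face_to_elements.items() if len(e) == 1
    }
    for fk, p in pmap.p.items():
        assert 0.0 <= p <= 0.8 + 1e-12
        assert fk not in boundary
        e1, e2 = adjacency.face_to_elements[fk]
        assert slab.region_tag[e1] == 1 and slab.region_tag[e2] == 1


def test_sampling_degenerate_probabilities(lge_slab):
    slab, intensity = lge_slab
    pmap = probability_map(slab, intensity, 0.8)
    zero = ProbabilityMap({f: 0.0 for f in pmap.p}, rho_max=0.0)
    assert len(sample_network(zero, 1)) == 0
    one = ProbabilityMap({f: 1.0 for f in pmap.p}, rho_max=1.0)
    assert sample_network(one, 1).faces == set(pmap.p)


def test_sampling_matches_binomial_expectation():
    faces = {(i, i + 1): 0.3 for i in range(12000)}
    pmap = ProbabilityMap(faces, rho_max=1.0)
    frac = len(sample_network(pmap, 123)) / len(faces)
    sigma = np.sqrt(0.3 * 0.7 / len(faces))
    assert abs(frac - 0.3) < 3 * sigma


def test_sampling_deterministic_per_seed(lge_slab):
    slab, intensity = lge_slab
    pmap = probability_map(slab, intensity, 0.6)
    assert sample_network(pmap, 9).faces == sample_network(pmap, 9).faces
    assert sample_network(pmap, 9).faces != sample_network(pmap, 10).faces


def test_expected_size_monotone_in_density(lge_slab):
    slab, intensity = lge_slab
    means = []
    for rho in (0.2, 0.5, 0.9):
        pmap = probability_map(slab, intensity, rho)
        sizes = [len(sample_network(pmap, s)) for s in range(10)]
        means.append(np.mean(sizes))
    assert means[0] <= means[1] <= means[2]


def test_density_sweep_produces_151_models(lge_slab):
    slab, intensity = lge_slab
    networks = density_sweep(slab, intensity, base_seed=5)
    assert len(networks) == 151
    assert len(networks[-1]) == 0  # fibrosis-free control
    again = density_sweep(slab, intensity, base_seed=5)
    assert all(a.faces == b.faces for a, b in zip(networks, again))


def test_density_sweep_minimal_case(lge_slab):
    slab, intensity = lge_slab
    networks = density_sweep(slab, intensity, densities=[1.0], n_realizations=1)
    assert len(networks) == 2
    with pytest.raises(ValueError):
        density_sweep(slab, intensity, densities=[0.0])


def test_network_round_trip(tmp_path, lge_slab):
    slab, intensity = lge_slab
    pmap = probability_map(slab, intensity, 0.7)
    network = sample_network(pmap, 3)
    path = tmp_path / "net.txt"
    write_network(path, network)
    back = read_network(path)
    assert back.faces == network.faces
    assert back.seed == 3
    assert back.rho_max == pytest.approx(0.7)


def test_synthetic_lge_profile(lge_slab):
    slab, intensity = lge_slab
    r = np.linalg.norm(slab.centroids() - [2.0, 2.0, 1.0], axis=1)
    i_star = intensity.normalized()
    assert np.all(i_star[r > 2.5] == 0.0)
    assert i_star[np.argmin(r)] > 0.8
    again = synthetic_lge_fixture(slab, (2.0, 2.0, 1.0), 2.5, seed=0, noise=0.3)
    twice = synthetic_lge_fixture(slab, (2.0, 2.0, 1.0), 2.5, seed=0, noise=0.3)
    assert np.array_equal(again.value, twice.value)
    assert np.array_equal(slab.region_tag == 1, intensity.value > intensity.i_ref)
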