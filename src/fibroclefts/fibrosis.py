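"""Stochastic interstitial-fibrosis network generation.

Interstitial fibrosis forms thin collagenous clefts between myocyte sheets.
On an image-informed mesh it is modelled by marking interior faces as
no-flux clefts.  Each interior face inside the enhanced (LGE) region gets a
probability

    p = rho_max * |cos(theta)| * I*

where ``I* = clamp((I - I_ref) / (I_max - I_ref), 0, 1)`` is the normalized
image intensity, ``theta`` the angle between the face normal and the local
myocardial sheet-normal direction (clefts preferentially align with the
sheet planes), and ``rho_max`` a global density parameter in [0, 1].  A
network realization samples each face independently with probability p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import AdjacencyIndex, Mesh, build_adjacency, face_key

__all__ = [
    "IntensityField",
    "ProbabilityMap",
    "FibrosisNetwork",
    "normalize_intensity",
    "face_probability",
    "probability_map",
    "sample_network",
    "density_sweep",
    "write_network",
    "read_network",
    "tag_lge",
]


@dataclass
class IntensityField:
    """Per-element scalar image intensity with reference and maximum levels.

    ``i_ref`` is the mean intensity of non-enhanced tissue and ``i_max`` the
    image maximum; intensities at or below ``i_ref`` normalize to 0.
    """

    value: np.ndarray
    i_ref: float
    i_max: float

    def __post_init__(self):
        self.value = np.asarray(self.value, dtype=float)
        if not self.i_max > self.i_ref:
            raise ValueError("i_max must exceed i_ref")

    def normalized(self) -> np.ndarray:
        """Normalized intensity per element, clamped to [0, 1]."""
        return normalize_intensity(self.value, self.i_ref, self.i_max)


def normalize_intensity(i, i_ref: float, i_max: float):
    """Normalized fibrosis intensity ``(I - I_ref)/(I_max - I_ref)`` in [0, 1].

    Accepts scalars or arrays; values are clamped so that anything at or
    below the reference maps to 0 and anything at or above the maximum to 1.
    """
    if not i_max > i_ref:
        raise ValueError("i_max must exceed i_ref")
    out = (np.asarray(i, dtype=float) - i_ref) / (i_max - i_ref)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def face_probability(i_star: float, theta: float, rho_max: float) -> float:
    """Probability of one face being fibrotic: ``rho_max * |cos theta| * I*``.

    The absolute value resolves the sign ambiguity of face normals — a face
    and its flipped normal describe the same geometric cleft.  ``theta`` is
    the angle (radians) between the face normal and the local sheet normal,
    so faces lying within a myocardial sheet (theta = pi/2) are never split.
    """
    if not 0.0 <= i_star <= 1.0:
        raise ValueError(f"i_star must be in [0, 1], got {i_star}")
    if not 0.0 <= rho_max <= 1.0:
        raise ValueError(f"rho_max must be in [0, 1], got {rho_max}")
    return rho_max * abs(np.cos(theta)) * i_star


@dataclass
class ProbabilityMap:
    """Fibrosis probability per interior face of the LGE region.

    ``p`` maps face keys to probabilities in [0, rho_max]; ``theta`` stores
    the face-normal-to-sheet-normal angle used for each face.
    """

    p: dict = field(default_factory=dict)
    theta: dict = field(default_factory=dict)
    rho_max: float = 0.0


@dataclass
class FibrosisNetwork:
    """A realization of the cleft network: a set of interior face keys."""

    faces: set = field(default_factory=set)
    seed: int | None = None
    rho_max: float = 0.0

    def __len__(self):
        return len(self.faces)

    def __contains__(self, face):
        return face_key(face) in self.faces


def probability_map(
    mesh: Mesh,
    intensity: IntensityField,
    rho_max: float,
    adjacency: AdjacencyIndex | None = None,
) -> ProbabilityMap:
    """Build the per-face fibrosis probability map for a mesh.

    A face belongs to the LGE region when both adjacent elements carry
    region tag 1.  Its normalized intensity is the mean of the two adjacent
    elements' values, and its sheet normal the (normalized) average of the
    two adjacent triads' sheet normals; boundary faces never enter the map.
    """
    if not 0.0 <= rho_max <= 1.0:
        raise ValueError("rho_max must be in [0, 1]")
    if mesh.orientation is None:
        raise ValueError("mesh needs orientation triads for face probabilities")
    adjacency = adjacency or build_adjacency(mesh)
    i_star = intensity.normalized()
    pmap = ProbabilityMap(rho_max=rho_max)
    for fk in adjacency.interior_faces():
        e1, e2 = adjacency.face_to_elements[fk]
        if mesh.region_tag[e1] != 1 or mesh.region_tag[e2] != 1:
            continue
        sheet_normal = mesh.orientation[e1, 2] + mesh.orientation[e2, 2]
        nrm = np.linalg.norm(sheet_normal)
        if nrm < 1e-12:  # adjacent sheet normals exactly opposed
            sheet_normal = mesh.orientation[e1, 2]
        else:
            sheet_normal = sheet_normal / nrm
        cos_t = abs(float(mesh.face_normal(fk) @ sheet_normal))
        theta = float(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        fi = 0.5 * (i_star[e1] + i_star[e2])
        pmap.p[fk] = face_probability(float(fi), theta, rho_max)
        pmap.theta[fk] = theta
    return pmap


def sample_network(pmap: ProbabilityMap, seed: int) -> FibrosisNetwork:
    """Sample one fibrosis-network realization from a probability map.

    Each face is included independently when a uniform [0, 1) draw falls
    strictly below its probability; the draw order is the sorted face-key
    order, so realizations are reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    faces = sorted(pmap.p)
    if not faces:
        return FibrosisNetwork(set(), seed, pmap.rho_max)
    u = rng.random(len(faces))
    p = np.array([pmap.p[f] for f in faces])
    chosen = {f for f, ui, pi in zip(faces, u, p) if ui < pi}
    return FibrosisNetwork(chosen, seed, pmap.rho_max)


def density_sweep(
    mesh: Mesh,
    intensity: IntensityField,
    densities=tuple(np.round(np.arange(0.1, 1.01, 0.1), 10)),
    n_realizations: int = 15,
    base_seed: int = 0,
) -> list[FibrosisNetwork]:
    """Sample the full density-by-realization grid of network models.

    For each density ``rho_max`` the map is rebuilt and ``n_realizations``
    networks are drawn with seeds ``base_seed + 1000*density_index +
    realization_index``.  An empty control network (``rho_max = 0``) is
    appended last.  The default sweep (10 densities x 15 realizations plus
    the control) yields 151 models.
    """
    densities = list(densities)
    if any(not 0.0 < d <= 1.0 for d in densities):
        raise ValueError("densities must lie in (0, 1]")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    adjacency = build_adjacency(mesh)
    networks = []
    for di, rho in enumerate(densities):
        pmap = probability_map(mesh, intensity, rho, adjacency)
        for ri in range(n_realizations):
            seed = base_seed + 1000 * di + ri
            networks.append(sample_network(pmap, seed))
    networks.append(FibrosisNetwork(set(), None, 0.0))  # fibrosis-free control
    return networks


def tag_lge(mesh: Mesh, intensity: IntensityField) -> None:
    """Set region tag 1 on every element whose intensity exceeds ``i_ref``."""
    mesh.region_tag = np.where(intensity.value > intensity.i_ref, 1, 0).astype(
        np.int64
    )


def write_network(path, network: FibrosisNetwork) -> None:
    """Write a network as sorted face keys, one per line, with a header."""
    with open(path, "w") as fh:
        fh.write(f"# rho_max={network.rho_max} seed={network.seed}\n")
        for fk in sorted(network.faces):
            fh.write(" ".join(str(v) for v in fk) + "\n")


def read_network(path) -> FibrosisNetwork:
    rho_max, seed = 0.0, None
    faces = set()
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "rho_max":
                        rho_max = float(v)
                    elif k == "seed" and v != "None":
                        seed = int(v)
                continue
            faces.add(face_key(ln.split()))
    return FibrosisNetwork(faces, seed, rho_max)
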