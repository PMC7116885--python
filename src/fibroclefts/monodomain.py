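"""Finite-element monodomain solver on (split) simplex meshes.

The transmembrane potential v (mV) obeys

    chi * Cm * dv/dt = div(sigma grad v) - chi * Cm * (I_ion - I_stim)

with surface-to-volume ratio chi = 1400 /cm, membrane capacitance
Cm = 1 uF/cm^2, conductivity tensor sigma (mS/cm) built per element from
the fibre/sheet orientation triad, and ionic current density I_ion (pA/pF)
from an :class:`~fibroclefts.cells.IonicModel`.  Spatial discretization is
piecewise-linear finite elements with a lumped mass matrix; natural
(no-flux) boundary conditions hold on every boundary face, which is exactly
what makes split fibrotic faces insulating.  Time integration is Godunov
operator splitting: a reaction step at the ionic model's ODE step followed
by an implicit-Euler diffusion solve.  The diffusion system matrix is
constant, so it is factorized once (default) or solved by preconditioned
conjugate gradients.

Activation times are recorded online as the first upward crossing of 0 mV,
linearly interpolated between solver steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .cells import IonicModel, NumericalInstabilityError
from .mesh import Mesh

__all__ = [
    "CHI",
    "CM",
    "ConductivityField",
    "StimulusSpec",
    "ActivationMap",
    "SimulationResult",
    "lge_conductivity_bands",
    "assemble_operators",
    "run_monodomain",
    "detect_activation_times",
    "measure_cv",
    "tune_conductivity",
]

CHI = 1400.0  # surface-to-volume ratio, 1/cm
CM = 1.0      # membrane capacitance, uF/cm^2
_MM_TO_CM = 0.1


@dataclass
class ConductivityField:
    """Per-element transversely isotropic conductivity (mS/cm).

    ``sigma_l`` (along the fibre) and ``sigma_t`` (across it) may be scalars
    or per-element arrays; the tensor for element e is

        sigma_t[e] * I + (sigma_l[e] - sigma_t[e]) * f f^T

    with f the element fibre direction.  Meshes without orientation triads
    get the isotropic tensor ``sigma_t * I`` (set sigma_l = sigma_t).
    """

    sigma_l: np.ndarray | float
    sigma_t: np.ndarray | float

    def tensors(self, mesh: Mesh) -> np.ndarray:
        m = mesh.n_elements
        sl = np.broadcast_to(np.asarray(self.sigma_l, float), (m,))
        st = np.broadcast_to(np.asarray(self.sigma_t, float), (m,))
        if np.any(sl <= 0) or np.any(st <= 0):
            raise ValueError("conductivities must be positive")
        eye = np.broadcast_to(np.eye(3), (m, 3, 3))
        if mesh.orientation is None:
            if not np.allclose(sl, st):
                raise ValueError("anisotropy requires orientation triads")
            return st[:, None, None] * eye
        f = mesh.orientation[:, 0]
        ff = np.einsum("ei,ej->eij", f, f)
        return st[:, None, None] * eye + (sl - st)[:, None, None] * ff

    @classmethod
    def isotropic(cls, sigma: float) -> "ConductivityField":
        return cls(sigma, sigma)


def lge_conductivity_bands(i_star: float) -> tuple[float, float]:
    """Conduction-velocity scale factors (fibre, transverse) for one element.

    Enhanced tissue slows conduction in intensity bands of normalized LGE
    signal: 0-25 % and 25-50 % above the reference reduce the transverse
    velocity by 25 % and 50 % with normal fibre velocity; 50-75 % and
    75-100 % additionally reduce the fibre velocity by 25 % and 50 % (with
    the transverse reduction held at 50 %).  Bands are half-open [lo, hi),
    so exactly 0 falls in the lowest band; the scales multiply the CV
    *targets* to which conductivities are subsequently tuned.
    """
    if not 0.0 <= i_star <= 1.0:
        raise ValueError("normalized intensity must be in [0, 1]")
    if i_star < 0.25:
        return 1.0, 0.75
    if i_star < 0.5:
        return 1.0, 0.5
    if i_star < 0.75:
        return 0.75, 0.5
    return 0.5, 0.5


def assemble_operators(mesh: Mesh, conductivity: ConductivityField):
    """Lumped mass vector and anisotropic stiffness matrix (P1 elements).

    Coordinates are converted from mm to cm so that with sigma in mS/cm the
    product K v is in uA (3D) and chi*Cm*M dv/dt matches.  The stiffness
    matrix has zero row sums (pure Neumann), so constant fields are in its
    nullspace.  Raises on non-positive element tensors.
    """
    coords = mesh.vertices * _MM_TO_CM
    elems = mesh.elements
    meas = mesh.measures() * (_MM_TO_CM ** mesh.dim)
    tensors = conductivity.tensors(mesh)
    nv = mesh.n_vertices
    d = mesh.dim
    x = coords[elems]  # (m, d+1, 3)
    if d == 2:
        J = np.stack([x[:, 1, :2] - x[:, 0, :2], x[:, 2, :2] - x[:, 0, :2]], axis=2)
        sigma = tensors[:, :2, :2]
    else:
        J = np.stack(
            [x[:, k, :] - x[:, 0, :] for k in (1, 2, 3)], axis=2
        )
        sigma = tensors
    det = np.linalg.det(J)
    if np.any(np.abs(det) < 1e-20):
        raise ValueError(f"degenerate element {int(np.argmin(np.abs(det)))}")
    Jinv = np.linalg.inv(J)
    # gradients of barycentric coordinates: rows of Jinv give grad(l_1..l_d);
    # grad(l_0) closes the partition of unity
    grads = np.empty((len(elems), d + 1, d))
    grads[:, 1:, :] = Jinv
    grads[:, 0, :] = -Jinv.sum(axis=1)
    ke = np.einsum("eid,edc,ejc,e->eij", grads, sigma, grads, np.abs(meas))
    rows = np.repeat(elems, d + 1, axis=1).ravel()
    cols = np.tile(elems, (1, d + 1)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(nv, nv)).tocsr()
    mass = np.zeros(nv)
    np.add.at(mass, elems.ravel(), np.repeat(np.abs(meas) / (d + 1), d + 1))
    return mass, K


@dataclass
class StimulusSpec:
    """Transmembrane stimulus: a ball (disc in 2D) or explicit vertex mask.

    ``strength`` is in uA/cm^2 and ``duration`` in ms; ``onsets`` lists the
    start times of identical pulses.  The standard protocol stimulus is
    500 uA/cm^2 for 2 ms in a 1 mm-radius region.
    """

    site: np.ndarray | None = None
    radius: float = 1.0  # mm
    strength: float = 500.0
    duration: float = 2.0
    onsets: tuple = (0.0,)
    mask: np.ndarray | None = None

    def vertex_mask(self, mesh: Mesh) -> np.ndarray:
        if self.mask is not None:
            return np.asarray(self.mask, bool)
        site = np.asarray(self.site, float)
        if site.shape == (2,):
            site = np.append(site, 0.0)
        d = np.linalg.norm(mesh.vertices - site, axis=1)
        m = d <= self.radius
        if not m.any():  # never lose the stimulus on coarse meshes
            m[np.argmin(d)] = True
        return m


class ActivationMap:
    """Per-vertex activation events (upward 0 mV crossings), in ms.

    Events accumulate during a simulation; queries slice by time window so
    multi-beat protocols can attribute activations to beats.  Vertices that
    never activate report NaN.
    """

    def __init__(self, n_vertices: int):
        self.n_vertices = n_vertices
        self._vertices: list[np.ndarray] = []
        self._times: list[np.ndarray] = []

    def add(self, vertices: np.ndarray, times: np.ndarray) -> None:
        self._vertices.append(np.asarray(vertices))
        self._times.append(np.asarray(times))

    @property
    def vertices(self) -> np.ndarray:
        return (
            np.concatenate(self._vertices) if self._vertices else np.empty(0, int)
        )

    @property
    def times(self) -> np.ndarray:
        return (
            np.concatenate(self._times) if self._times else np.empty(0)
        )

    def __len__(self):
        return len(self.times)

    def first_crossing(self, t0: float = -np.inf, t1: float = np.inf) -> np.ndarray:
        """First activation time per vertex within [t0, t1); NaN if none."""
        out = np.full(self.n_vertices, np.nan)
        t, v = self.times, self.vertices
        sel = (t >= t0) & (t < t1)
        np.fmin.at(out, v[sel], t[sel])
        return out

    def any_in(self, mask: np.ndarray, t0: float, t1: float) -> bool:
        """True if any vertex of ``mask`` activates within [t0, t1)."""
        t, v = self.times, self.vertices
        sel = (t >= t0) & (t < t1)
        return bool(np.any(mask[v[sel]]))

    def merged_with(self, other: "ActivationMap") -> "ActivationMap":
        out = ActivationMap(self.n_vertices)
        out._vertices = self._vertices + other._vertices
        out._times = self._times + other._times
        return out


@dataclass
class SimulationResult:
    activation: ActivationMap
    state: np.ndarray
    t_end: float
    trace_times: np.ndarray = None
    traces: np.ndarray = None  # (n_recorded, n_samples)
    record_vertices: np.ndarray = None


def run_monodomain(
    mesh: Mesh,
    conductivity: ConductivityField,
    stimuli,
    duration: float,
    model: IonicModel,
    dt: float | None = None,
    initial_state: np.ndarray | None = None,
    t0: float = 0.0,
    activation: ActivationMap | None = None,
    record_vertices=None,
    record_interval: float = 1.0,
    solver: str = "lu",
    rtol: float = 1e-8,
    stop_when=None,
    operators=None,
) -> SimulationResult:
    """Integrate the monodomain equations for ``duration`` ms.

    ``stimuli`` is a sequence of :class:`StimulusSpec`.  ``initial_state``
    continues a previous simulation (the array is copied); ``activation``
    lets multi-beat protocols accumulate crossings in one map; ``stop_when``
    is an optional ``f(t, vm, activation) -> bool`` polled every millisecond
    for early termination.  Precomputed ``operators`` (mass, stiffness) can
    be passed to avoid reassembly across protocol beats.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = model.dt_ode if dt is None else dt
    if dt > model.dt_ode + 1e-12:
        raise ValueError("dt must not exceed the ionic model's ODE step")
    mass, K = operators if operators is not None else assemble_operators(
        mesh, conductivity
    )
    nv = mesh.n_vertices
    c = dt / (CHI * CM)
    A = sp.csc_matrix(sp.diags(mass) + c * K)
    if solver == "lu":
        lu = spla.splu(A)
        solve = lu.solve
    elif solver == "cg":
        ilu_pre = sp.diags(1.0 / A.diagonal())

        def solve(rhs, _x0=[None]):
            x, info = spla.cg(A, rhs, x0=_x0[0], rtol=rtol, atol=0.0, M=ilu_pre)
            if info != 0:
                raise RuntimeError(f"CG failed to converge (info={info})")
            _x0[0] = x
            return x
    else:
        raise ValueError("solver must be 'lu' or 'cg'")

    if initial_state is None:
        from .cells import resting_state

        state = np.repeat(resting_state(model), nv, axis=1)
    else:
        state = np.array(initial_state, dtype=float, order="C")
        if state.shape != (model.state_dim, nv):
            raise ValueError("initial_state has the wrong shape")

    schedule = []
    for stim in stimuli:
        mask = stim.vertex_mask(mesh)
        idx = np.where(mask)[0]
        for onset in stim.onsets:
            schedule.append((float(onset), float(onset + stim.duration),
                             idx, float(stim.strength)))

    if activation is None:
        activation = ActivationMap(nv)
    rec_idx = None
    trace_times, traces = [], []
    if record_vertices is not None:
        rec_idx = np.asarray(record_vertices, int)

    n_steps = max(1, int(round(duration / dt)))
    check_every = max(1, int(round(1.0 / dt)))
    istim = np.zeros(nv)
    active_key = None
    v_prev = state[0].copy()
    for k in range(n_steps):
        t = t0 + k * dt
        key = tuple(
            i for i, (on, off, _, _) in enumerate(schedule) if on <= t < off
        )
        if key != active_key:
            istim[:] = 0.0
            for i in key:
                _, _, idx, strength = schedule[i]
                istim[idx] += strength
            active_key = key
        model.step(state, istim, dt)
        state[0] = solve(mass * state[0])
        v = state[0]
        crossed = (v_prev < 0.0) & (v >= 0.0)
        if crossed.any():
            w = np.where(crossed)[0]
            frac = -v_prev[w] / (v[w] - v_prev[w])
            activation.add(w, t + dt * frac)
        v_prev[:] = v
        if k % check_every == 0:
            if not np.all(np.isfinite(v)):
                raise NumericalInstabilityError(
                    f"non-finite membrane potential at t={t + dt:.3f} ms"
                )
            if rec_idx is not None:
                trace_times.append(t + dt)
                traces.append(v[rec_idx].copy())
            if stop_when is not None and stop_when(t + dt, v, activation):
                break

    return SimulationResult(
        activation,
        state,
        t0 + (k + 1) * dt,
        np.asarray(trace_times) if rec_idx is not None else None,
        np.asarray(traces).T if rec_idx is not None else None,
        rec_idx,
    )


def detect_activation_times(vm: np.ndarray, times: np.ndarray,
                            threshold: float = 0.0) -> float:
    """First upward threshold crossing of a sampled trace, or NaN.

    Linear interpolation between samples; a trace that only crosses
    downward (or never crosses) returns the NaN sentinel.
    """
    vm = np.asarray(vm, float)
    times = np.asarray(times, float)
    below = vm[:-1] < threshold
    above = vm[1:] >= threshold
    hits = np.where(below & above)[0]
    if len(hits) == 0:
        return float("nan")
    i = hits[0]
    frac = (threshold - vm[i]) / (vm[i + 1] - vm[i])
    return float(times[i] + frac * (times[i + 1] - times[i]))


def measure_cv(
    activation_times: np.ndarray,
    coords: np.ndarray,
    axis,
    window_mask: np.ndarray | None = None,
) -> float:
    """Planar-wave conduction velocity (cm/s) by regression.

    Fits activation time against distance along ``axis`` (unit vector or
    axis index) over the vertices of ``window_mask`` with finite activation
    and inverts the slope.  Requires at least 3 activated sample points and
    a positive slope (a wave actually travelling along the axis).
    """
    coords = np.asarray(coords, float)
    if np.isscalar(axis):
        direction = np.zeros(3)
        direction[int(axis)] = 1.0
    else:
        direction = np.asarray(axis, float)
        direction = direction / np.linalg.norm(direction)
    x = coords @ direction  # mm
    t = np.asarray(activation_times, float)
    sel = np.isfinite(t)
    if window_mask is not None:
        sel &= np.asarray(window_mask, bool)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 activated vertices in the window")
    slope = np.polyfit(x[sel], t[sel], 1)[0]  # ms/mm
    if slope <= 0:
        raise ValueError("activation does not advance along the axis")
    return 100.0 / slope  # mm/ms -> cm/s


_TUNE_CACHE: dict = {}


def _strand_mesh(edge_length: float, dim: int, direction: str):
    from .generators import make_grid_2d, make_slab_3d

    if dim == 2:
        n = max(8, int(round(9.5 / edge_length)))
        mesh = make_grid_2d(n, edge_length)
        return mesh, n * edge_length
    length = 12.0
    width = max(2 * edge_length, 0.8)
    if direction == "transverse":
        def rule(centroids):
            triad = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, -1.0]])
            # propagation along x is across these y-aligned fibres
            t = np.broadcast_to(triad, (len(centroids), 3, 3)).copy()
            return t
    else:
        rule = None
    mesh = make_slab_3d((length, width, width), edge_length, rule)
    return mesh, length


def tune_conductivity(
    target_cv: float,
    direction: str = "fibre",
    edge_length: float = 0.4,
    model: IonicModel | None = None,
    dim: int = 3,
    tol: float = 0.01,
    max_iter: int = 25,
) -> float:
    """Conductivity (mS/cm) reproducing ``target_cv`` (cm/s) on a strand.

    Runs planar-wave simulations on a strand mesh of the requested edge
    length, measuring velocity by regression of activation time on distance
    in the central half of the strand, and iterates the conductivity with
    the diffusion scaling law (CV proportional to sqrt(sigma), refined by
    re-measurement) until the measured velocity is within ``tol`` (relative)
    of the target.  The numerically measured CV depends on the mesh
    resolution, which is why each (target, resolution, model) pair is tuned
    and cached separately.
    """
    if target_cv <= 0:
        raise ValueError("target_cv must be positive")
    model = model or _default_model()
    key = (round(target_cv, 6), direction, round(edge_length, 6), dim, model.name)
    if key in _TUNE_CACHE:
        return _TUNE_CACHE[key]
    mesh, length = _strand_mesh(edge_length, dim, direction)
    sigma = 3.0 * (target_cv / 84.0) ** 2
    history = []
    for it in range(max_iter):
        cv = _measure_strand_cv(mesh, length, sigma, model, target_cv)
        if cv is None:  # propagation failure: conductivity far too low
            sigma *= 4.0
            history.append((sigma, None))
            continue
        history.append((sigma, cv))
        if abs(cv - target_cv) <= tol * target_cv:
            _TUNE_CACHE[key] = sigma
            return sigma
        sigma *= (target_cv / cv) ** 2
    raise RuntimeError(
        f"conductivity tuning did not converge in {max_iter} iterations; "
        f"history={history}"
    )


def _default_model():
    from .cells import TenTusscher2006Epi

    return TenTusscher2006Epi()


def _measure_strand_cv(mesh, length, sigma, model, target_cv):
    """One strand simulation; returns measured CV or None on block."""
    cond = ConductivityField(sigma, sigma)
    x = mesh.vertices[:, 0]
    stim_mask = x <= x.min() + 0.08 * length
    stim = StimulusSpec(mask=stim_mask, strength=500.0, duration=2.0, onsets=(0.0,))
    far = x >= x.max() - 0.05 * length

    def reached_far(t, vm, act):
        return act.any_in(far, 0.0, t + 1.0)

    horizon = length / (0.2 * target_cv / 100.0) + 20.0  # generous, early-stopped
    res = run_monodomain(
        mesh, cond, [stim], horizon, model, stop_when=reached_far
    )
    at = res.activation.first_crossing()
    window = (x >= 0.3 * length) & (x <= 0.8 * length)
    if np.isfinite(at[window]).sum() < 3:
        return None
    try:
        return measure_cv(at, mesh.vertices, 0, window)
    except ValueError:
        return None
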