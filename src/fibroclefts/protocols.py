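"""Experiment drivers: pacing protocols, ERP search and reentry detection.

Three protocols exercise a fibrosis model:

* the transient-block test — two stimuli at a 340 ms coupling interval on
  the 2D cross test meshes, classifying whether each wave crosses the
  fibrotic row (the premature wave is blocked by a tight cleft topology but
  leaks through a leaky one);
* the transmural-activation-time (TAT) sequence — three 600 ms
  preconditioning beats followed by 350 ms and 270 ms extrastimuli, timing
  the wave from an endocardial pacing site to the opposite surface;
* simulated programmed electrical stimulation (PES) — three 600 ms beats,
  then up to three extrastimuli delivered at the local effective refractory
  period found by binary search, each followed by an 800 ms observation
  window in which late activity near the pacing site flags a reentry.

A *new wave* after a probe stimulus is any activation within 4.2 cm of the
stimulus site 110-120 ms after stimulus onset; a *reentry* is any
activation within 1 cm of the site later than 300 ms after the beat.
Distances are Euclidean from the stimulus-site centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cells import IonicModel, TenTusscher2006Epi, resting_state
from .mesh import Mesh
from .monodomain import (
    ActivationMap,
    ConductivityField,
    StimulusSpec,
    assemble_operators,
    run_monodomain,
    tune_conductivity,
)

__all__ = [
    "PESOutcome",
    "TATRecord",
    "BracketError",
    "CalibrationError",
    "detect_new_wave",
    "detect_reentry",
    "erp_binary_search",
    "run_pes",
    "run_tat_protocol",
    "run_block_experiment",
]

NEW_WAVE_RADIUS = 42.0   # mm (4.2 cm) around the stimulus site
NEW_WAVE_WINDOW = (110.0, 120.0)  # ms after stimulus onset
REENTRY_RADIUS = 10.0    # mm (1 cm)
REENTRY_AFTER = 300.0    # ms after the beat
OBSERVE_MS = 800.0       # post-beat observation horizon


class BracketError(RuntimeError):
    """The ERP search bounds do not bracket the refractory threshold."""


class CalibrationError(RuntimeError):
    """A protocol prerequisite (capture, first-wave crossing) failed."""


@dataclass
class PESOutcome:
    """Result of simulated programmed electrical stimulation."""

    erp_bracket: tuple | None
    beats_delivered: int
    reentry: bool
    reentry_beat: int | None = None
    brackets: list = field(default_factory=list)


@dataclass
class TATRecord:
    """Transmural activation times for the final beats of the TAT sequence."""

    tat: list
    coupling_intervals: list
    onsets: list


def _site_mask(coords: np.ndarray, site, radius: float) -> np.ndarray:
    site = np.asarray(site, float)
    if site.shape == (2,):
        site = np.append(site, 0.0)
    return np.linalg.norm(coords - site, axis=1) <= radius


def detect_new_wave(activation: ActivationMap, coords: np.ndarray, stim_site,
                    stim_time: float, radius: float = NEW_WAVE_RADIUS,
                    window=NEW_WAVE_WINDOW) -> bool:
    """True when a probe stimulus captured and launched a propagating wave.

    Captured beats show activations within ``radius`` mm of the stimulus
    site inside ``window`` (ms after stimulus onset); fully refractory
    tissue shows none.  The defaults (4.2 cm, 110-120 ms) assume a
    ventricle-scale domain where a captured wave is still travelling at
    110 ms; scale the window down with the domain.
    """
    mask = _site_mask(coords, stim_site, radius)
    return activation.any_in(mask, stim_time + window[0], stim_time + window[1])


def detect_reentry(activation: ActivationMap, coords: np.ndarray, stim_site,
                   stim_time: float, radius: float = REENTRY_RADIUS,
                   after: float = REENTRY_AFTER) -> bool:
    """True when tissue near the stimulus site re-activates late.

    Any activation within ``radius`` mm of the site later than ``after`` ms
    after the beat means the primary wave has been followed by
    re-excitation; defaults are 1 cm and 300 ms.
    """
    mask = _site_mask(coords, stim_site, radius)
    return activation.any_in(mask, stim_time + after, np.inf)


def erp_binary_search(runner, bounds=(200.0, 450.0), resolution: float = 10.0):
    """Bracket the effective refractory period by bisection.

    ``runner(ci) -> bool`` reports whether a stimulus at coupling interval
    ``ci`` (ms) captures.  The search starts from ``bounds`` and narrows to
    two consecutive intervals (spaced ``resolution``) such that the longer
    captures and the shorter does not; returns ``(failing_ci,
    capturing_ci)``.

    Raises
    ------
    BracketError
        If the lower bound already captures or the upper bound fails.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if not runner(hi):
        raise BracketError(f"no capture at the upper bound CI={hi} ms")
    if runner(lo):
        raise BracketError(f"capture at the lower bound CI={lo} ms")
    while hi - lo > resolution + 1e-9:
        mid = round((lo + hi) / 2.0 / resolution) * resolution
        if mid <= lo:
            mid = lo + resolution
        elif mid >= hi:
            mid = hi - resolution
        if runner(mid):
            hi = mid
        else:
            lo = mid
    return lo, hi


def run_pes(
    mesh: Mesh,
    conductivity: ConductivityField,
    pacing_site,
    model: IonicModel | None = None,
    n_precondition: int = 3,
    s1_interval: float = 600.0,
    max_extra: int = 3,
    erp_bounds=(200.0, 450.0),
    erp_resolution: float = 10.0,
    observe_ms: float = OBSERVE_MS,
    stim_strength: float = 500.0,
    stim_duration: float = 2.0,
    stim_radius: float = 1.0,
    new_wave_window=NEW_WAVE_WINDOW,
    new_wave_radius: float = NEW_WAVE_RADIUS,
    reentry_after: float = REENTRY_AFTER,
) -> PESOutcome:
    """Simulated programmed electrical stimulation.

    Delivers ``n_precondition`` beats at ``s1_interval``, then up to
    ``max_extra`` extrastimuli.  Each extrastimulus is timed at the
    capturing end of the ERP bracket found by binary search from the current
    tissue state (each probe branches off a checkpoint taken at the minimum
    coupling interval after the previous beat).  After each delivered
    extrastimulus ``observe_ms`` of activity is simulated and checked for
    reentry; the protocol stops at the first reentry.
    """
    if observe_ms < reentry_after + 100.0:
        raise ValueError(
            "observation horizon too short to detect reentry "
            f"(need > {reentry_after + 100.0} ms)"
        )
    model = model or TenTusscher2006Epi()
    operators = assemble_operators(mesh, conductivity)
    coords = mesh.vertices
    nv = mesh.n_vertices
    state = np.repeat(resting_state(model), nv, axis=1)
    activation = ActivationMap(nv)
    stim = StimulusSpec(site=pacing_site, radius=stim_radius,
                        strength=stim_strength, duration=stim_duration)

    def advance(state, t0, duration, onsets, act):
        s = StimulusSpec(site=pacing_site, radius=stim_radius,
                         strength=stim_strength, duration=stim_duration,
                         onsets=tuple(onsets))
        return run_monodomain(
            mesh, conductivity, [s], duration, model, initial_state=state,
            t0=t0, activation=act, operators=operators,
        )

    lo_ci = float(erp_bounds[0])
    t = 0.0
    for b in range(n_precondition - 1):
        res = advance(state, t, s1_interval, (t,), activation)
        state, t = res.state, res.t_end
    prev_onset = t
    # deliver the last preconditioning beat but advance only to the minimum
    # coupling interval: that state is the branch point for the ERP search
    res = advance(state, t, lo_ci, (t,), activation)
    state, t = res.state, res.t_end

    outcome = PESOutcome(None, 0, False)
    for extra in range(max_extra):
        checkpoint, t_chk = state, t  # exactly prev_onset + lo_ci

        def probe(ci):
            onset = prev_onset + ci
            dur = (onset - t_chk) + new_wave_window[1] + 2.0
            branch = ActivationMap(nv)
            advance(checkpoint, t_chk, dur, (onset,), branch)
            return detect_new_wave(branch, coords, pacing_site, onset,
                                   new_wave_radius, new_wave_window)

        bracket = erp_binary_search(probe, erp_bounds, erp_resolution)
        outcome.brackets.append(bracket)
        outcome.erp_bracket = bracket
        ci = bracket[1]  # deliver at the capturing interval
        onset = prev_onset + ci
        # deliver the extrastimulus and pause lo_ci after it (the next
        # branch point), then watch the rest of the observation window
        res = advance(checkpoint, t_chk, (onset - t_chk) + lo_ci, (onset,),
                      activation)
        state, t = res.state, res.t_end
        advance(state, t, observe_ms - lo_ci, (), activation)
        outcome.beats_delivered += 1
        if detect_reentry(activation, coords, pacing_site, onset,
                          after=reentry_after):
            outcome.reentry = True
            outcome.reentry_beat = extra
            return outcome
        prev_onset = onset
    return outcome


def run_tat_protocol(
    mesh: Mesh,
    conductivity: ConductivityField,
    pacing_site,
    measurement_site,
    model: IonicModel | None = None,
    coupling_intervals=(600.0, 600.0, 600.0, 350.0, 270.0),
    n_measured: int = 3,
    tail_ms: float = 300.0,
    stim_strength: float = 500.0,
    stim_duration: float = 2.0,
    stim_radius: float = 1.0,
) -> TATRecord:
    """Transmural-activation-time pacing sequence.

    Delivers the beat sequence (default 3 x 600 ms, 350 ms, 270 ms), then
    measures, for the final ``n_measured`` beats, the delay from stimulus
    onset to the first activation of the vertex nearest
    ``measurement_site`` (on the surface opposite the pacing site).  Beats
    whose wave never reaches the site record a NaN sentinel with a warning.
    """
    model = model or TenTusscher2006Epi()
    onsets = np.concatenate([[0.0], np.cumsum(coupling_intervals[1:])])
    site = np.asarray(measurement_site, float)
    if site.shape == (2,):
        site = np.append(site, 0.0)
    vertex = int(np.argmin(np.linalg.norm(mesh.vertices - site, axis=1)))
    stim = StimulusSpec(site=pacing_site, radius=stim_radius,
                        strength=stim_strength, duration=stim_duration,
                        onsets=tuple(onsets))
    duration = float(onsets[-1]) + tail_ms
    res = run_monodomain(mesh, conductivity, [stim], duration, model)
    windows = list(onsets) + [duration]
    tat = []
    for i in range(len(onsets) - n_measured, len(onsets)):
        first = res.activation.first_crossing(windows[i], windows[i + 1])
        value = first[vertex] - onsets[i]
        if not np.isfinite(value):
            warnings.warn(
                f"measurement site never activated for the beat at "
                f"{onsets[i]:.0f} ms"
            )
        tat.append(float(value))
    return TATRecord(
        tat, list(coupling_intervals[-n_measured:]), list(onsets[-n_measured:])
    )


def run_block_experiment(
    topology: str = "tight",
    ci: float = 340.0,
    target_cv: float = 17.0,
    model: IonicModel | None = None,
    crossing_window: float = 300.0,
    n_boxes: int = 38,
    box_edge: float = 0.25,
):
    """Transient-block test on the 2D cross meshes.

    Builds the requested topology of the cross test case, splits it, tunes
    the isotropic conductivity to the target effective conduction velocity,
    stimulates twice (at 0 and ``ci`` ms) halfway across the bottom edge and
    classifies each wave as having *crossed* the fibrotic row (at least one
    activation two element rows above it within ``crossing_window`` ms of
    the stimulus) or been *blocked*.

    The first wave must cross — it travels through fully recovered tissue —
    otherwise a :class:`CalibrationError` is raised.
    """
    from .generators import make_cross_testcase
    from .split import split_mesh

    model = model or TenTusscher2006Epi()
    mesh, network, expected = make_cross_testcase(
        topology, n_boxes=n_boxes, box_edge=box_edge
    )
    split = split_mesh(mesh, network, assignment=expected["assignment"])
    smesh = split.mesh
    sigma = tune_conductivity(
        target_cv, "isotropic", box_edge, model, dim=2
    )
    cond = ConductivityField.isotropic(sigma)
    width = n_boxes * box_edge
    stim = StimulusSpec(site=(width / 2.0, 0.0, 0.0), radius=1.0,
                        strength=500.0, duration=2.0, onsets=(0.0, ci))
    duration = ci + crossing_window + 20.0
    res = run_monodomain(smesh, cond, [stim], duration, model)
    above = smesh.vertices[:, 1] >= expected["row_y"] + 2 * box_edge

    def classify(t_stim):
        crossed = res.activation.any_in(above, t_stim, t_stim + crossing_window)
        return "crossed" if crossed else "blocked"

    waves = {"wave1": classify(0.0), "wave2": classify(ci)}
    if waves["wave1"] != "crossed":
        raise CalibrationError(
            "the first wave failed to cross the fibrotic row; conduction "
            "velocity or refractoriness is mistuned"
        )
    return {
        "topology": topology,
        "waves": waves,
        "sigma": sigma,
        "result": res,
        "mesh": smesh,
        "expected": expected,
    }
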