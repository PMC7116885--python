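"""Membrane kinetics: ionic models behind a pluggable interface.

The default model is the ten Tusscher–Panfilov 2006 human ventricular
action potential (epicardial parameter set), integrated with Rush–Larsen
updates for the twelve gating variables and forward Euler for the membrane
potential, intracellular concentrations and the ryanodine-receptor state,
at a 20 microsecond step.  A two-variable threshold-and-recovery model
(Mitchell–Schaeffer) is provided for fast protocol property tests.

State vectors are (state_dim, n) float64 arrays so that one model instance
serves a whole tissue simulation; row 0 is always the transmembrane
potential in mV.  Stimulus currents are positive-depolarizing, in uA/cm^2
(equivalently pA/pF at 1 uF/cm^2 membrane capacitance).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "IonicModel",
    "TenTusscher2006Epi",
    "MitchellSchaeffer",
    "get_model",
    "resting_state",
    "cell_step",
    "save_state",
    "load_state",
    "NumericalInstabilityError",
]


class NumericalInstabilityError(RuntimeError):
    """State became non-finite during integration."""


# ---------------------------------------------------------------------------
# ten Tusscher & Panfilov 2006, epicardial variant
# ---------------------------------------------------------------------------

# state layout
_V, _M, _H, _J, _XR1, _XR2, _XS, _R, _S, _D, _F, _F2, _FCASS = range(13)
_CAI, _CASR, _CASS, _NAI, _KI, _RBAR = range(13, 19)


@njit(cache=True)
def _tt2006_step(S, istim, dt):  # pragma: no cover - exercised via wrapper
    Rgas = 8314.472
    T = 310.0
    F = 96485.3415
    RTONF = Rgas * T / F
    Cm = 0.185
    Vc = 0.016404
    Vsr = 0.001094
    Vss = 0.00005468
    inverseVcF2 = 1.0 / (2.0 * Vc * F)
    inverseVcF = 1.0 / (Vc * F)
    inversevssF2 = 1.0 / (2.0 * Vss * F)
    Ko = 5.4
    Cao = 2.0
    Nao = 140.0
    pKNa = 0.03
    GNa = 14.838
    GK1 = 5.405
    GKr = 0.153
    GKs = 0.392   # epicardial
    Gto = 0.294   # epicardial
    GCaL = 3.98e-5
    GbNa = 0.00029
    GbCa = 0.000592
    GpCa = 0.1238
    KpCa = 0.0005
    GpK = 0.0146
    PNaK = 2.724
    KmK = 1.0
    KmNa = 40.0
    kNaCa = 1000.0
    Ksat = 0.1
    alpha_naca = 2.5
    gamma = 0.35
    KmCa = 1.38
    KmNai = 87.5
    Vmaxup = 0.006375
    Kup = 0.00025
    Vrel = 0.102
    Vleak = 0.00036
    Vxfer = 0.0038
    k1p = 0.15
    k2p = 0.045
    k3 = 0.060
    k4 = 0.005
    EC = 1.5
    maxsr = 2.5
    minsr = 1.0
    Bufc = 0.2
    Kbufc = 0.001
    Bufsr = 10.0
    Kbufsr = 0.3
    Bufss = 0.4
    Kbufss = 0.00025
    sqrtko = math.sqrt(Ko / 5.4)

    n = S.shape[1]
    for i in range(n):
        V = S[_V, i]
        m = S[_M, i]
        h = S[_H, i]
        j = S[_J, i]
        xr1 = S[_XR1, i]
        xr2 = S[_XR2, i]
        xs = S[_XS, i]
        r = S[_R, i]
        s = S[_S, i]
        d = S[_D, i]
        f = S[_F, i]
        f2 = S[_F2, i]
        fcass = S[_FCASS, i]
        Cai = S[_CAI, i]
        CaSR = S[_CASR, i]
        CaSS = S[_CASS, i]
        Nai = S[_NAI, i]
        Ki = S[_KI, i]
        Rbar = S[_RBAR, i]
        Istim = -istim[i]  # model convention: depolarizing stimulus < 0

        EK = RTONF * math.log(Ko / Ki)
        ENa = RTONF * math.log(Nao / Nai)
        EKs = RTONF * math.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
        ECa = 0.5 * RTONF * math.log(Cao / Cai)

        # fast sodium
        INa = GNa * m * m * m * h * j * (V - ENa)
        # L-type calcium (singularity at V = 15 handled by Taylor limit)
        x = 2.0 * (V - 15.0) / RTONF
        if abs(x) < 1e-7:
            ICaL = GCaL * d * f * f2 * fcass * 2.0 * F * (0.25 * CaSS - Cao)
        else:
            ex = math.exp(x)
            ICaL = (
                GCaL * d * f * f2 * fcass * 4.0 * (V - 15.0)
                * (F * F / (Rgas * T)) * (0.25 * CaSS * ex - Cao) / (ex - 1.0)
            )
        Ito = Gto * r * s * (V - EK)
        IKr = GKr * sqrtko * xr1 * xr2 * (V - EK)
        IKs = GKs * xs * xs * (V - EKs)
        ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - EK - 200.0)))
        bk1 = (
            3.0 * math.exp(0.0002 * (V - EK + 100.0))
            + math.exp(0.1 * (V - EK - 10.0))
        ) / (1.0 + math.exp(-0.5 * (V - EK)))
        IK1 = GK1 * sqrtko * ak1 / (ak1 + bk1) * (V - EK)
        e_g = math.exp(gamma * V / RTONF)
        e_g1 = math.exp((gamma - 1.0) * V / RTONF)
        INaCa = (
            kNaCa
            * (e_g * Nai ** 3 * Cao - e_g1 * Nao ** 3 * Cai * alpha_naca)
            / (
                (KmNai ** 3 + Nao ** 3)
                * (KmCa + Cao)
                * (1.0 + Ksat * e_g1)
            )
        )
        INaK = (
            PNaK * Ko * Nai
            / ((Ko + KmK) * (Nai + KmNa))
            / (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
               + 0.0353 * math.exp(-V / RTONF))
        )
        IpCa = GpCa * Cai / (KpCa + Cai)
        IpK = GpK * (V - EK) / (1.0 + math.exp((25.0 - V) / 5.98))
        IbNa = GbNa * (V - ENa)
        IbCa = GbCa * (V - ECa)

        Iion = (IKr + IKs + IK1 + Ito + INa + IbNa + ICaL + IbCa
                + INaK + INaCa + IpCa + IpK)

        # calcium subsystem
        kcasr = maxsr - (maxsr - minsr) / (1.0 + (EC / CaSR) ** 2)
        k1 = k1p / kcasr
        k2 = k2p * kcasr
        dRbar = k4 * (1.0 - Rbar) - k2 * CaSS * Rbar
        Rbar = Rbar + dt * dRbar
        O = k1 * CaSS * CaSS * Rbar / (k3 + k1 * CaSS * CaSS)
        Irel = Vrel * O * (CaSR - CaSS)
        Ileak = Vleak * (CaSR - Cai)
        Iup = Vmaxup / (1.0 + (Kup / Cai) ** 2)
        Ixfer = Vxfer * (CaSS - Cai)

        # analytic instantaneous buffering (quadratic solve, as in the
        # published integration scheme)
        CaCSQN = Bufsr * CaSR / (CaSR + Kbufsr)
        dCaSR = dt * (Iup - Irel - Ileak)
        bjsr = Bufsr - CaCSQN - dCaSR - CaSR + Kbufsr
        cjsr = Kbufsr * (CaCSQN + dCaSR + CaSR)
        CaSR = (math.sqrt(bjsr * bjsr + 4.0 * cjsr) - bjsr) / 2.0

        CaSSBuf = Bufss * CaSS / (CaSS + Kbufss)
        dCaSS = dt * (
            -Ixfer * (Vc / Vss)
            + Irel * (Vsr / Vss)
            + (-ICaL * inversevssF2 * Cm)
        )
        bcss = Bufss - CaSSBuf - dCaSS - CaSS + Kbufss
        ccss = Kbufss * (CaSSBuf + dCaSS + CaSS)
        CaSS = (math.sqrt(bcss * bcss + 4.0 * ccss) - bcss) / 2.0

        CaBuf = Bufc * Cai / (Cai + Kbufc)
        dCai = dt * (
            -(IbCa + IpCa - 2.0 * INaCa) * inverseVcF2 * Cm
            - (Iup - Ileak) * (Vsr / Vc)
            + Ixfer
        )
        bc = Bufc - CaBuf - dCai - Cai + Kbufc
        cc = Kbufc * (CaBuf + dCai + Cai)
        Cai = (math.sqrt(bc * bc + 4.0 * cc) - bc) / 2.0

        Nai = Nai + dt * (-(INa + IbNa + 3.0 * INaK + 3.0 * INaCa)
                          * inverseVcF * Cm)
        Ki = Ki + dt * (-(Istim + IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK)
                        * inverseVcF * Cm)

        # Rush-Larsen gate updates
        minf = 1.0 / ((1.0 + math.exp((-56.86 - V) / 9.03)) ** 2)
        am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
        bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (
            1.0 + math.exp((V - 50.0) / 200.0)
        )
        taum = am * bm
        hinf = 1.0 / ((1.0 + math.exp((V + 71.55) / 7.43)) ** 2)
        if V < -40.0:
            ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
            bh = 2.7 * math.exp(0.079 * V) + 310000.0 * math.exp(0.3485 * V)
        else:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        tauh = 1.0 / (ah + bh)
        jinf = hinf
        if V < -40.0:
            aj = (
                (-25428.0 * math.exp(0.2444 * V)
                 - 6.948e-6 * math.exp(-0.04391 * V))
                * (V + 37.78)
                / (1.0 + math.exp(0.311 * (V + 79.23)))
            )
            bj = 0.02424 * math.exp(-0.01052 * V) / (
                1.0 + math.exp(-0.1378 * (V + 40.14))
            )
        else:
            aj = 0.0
            bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
        tauj = 1.0 / (aj + bj)
        xr1inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
        axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
        tauxr1 = axr1 * bxr1
        xr2inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
        tauxr2 = axr2 * bxr2
        xsinf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
        axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
        tauxs = axs * bxs + 80.0
        rinf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
        taur = 9.5 * math.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
        sinf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        taus = (
            85.0 * math.exp(-(V + 45.0) ** 2 / 320.0)
            + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0))
            + 3.0
        )
        dinf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
        ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
        gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
        taud = ad * bd + gd
        finf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
        tauf = (
            1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
            + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0))
            + 20.0
        )
        f2inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
        tauf2 = (
            562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
            + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
            + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0))
        )
        fcassinf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
        taufcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0

        S[_M, i] = minf + (m - minf) * math.exp(-dt / taum)
        S[_H, i] = hinf + (h - hinf) * math.exp(-dt / tauh)
        S[_J, i] = jinf + (j - jinf) * math.exp(-dt / tauj)
        S[_XR1, i] = xr1inf + (xr1 - xr1inf) * math.exp(-dt / tauxr1)
        S[_XR2, i] = xr2inf + (xr2 - xr2inf) * math.exp(-dt / tauxr2)
        S[_XS, i] = xsinf + (xs - xsinf) * math.exp(-dt / tauxs)
        S[_R, i] = rinf + (r - rinf) * math.exp(-dt / taur)
        S[_S, i] = sinf + (s - sinf) * math.exp(-dt / taus)
        S[_D, i] = dinf + (d - dinf) * math.exp(-dt / taud)
        S[_F, i] = finf + (f - finf) * math.exp(-dt / tauf)
        S[_F2, i] = f2inf + (f2 - f2inf) * math.exp(-dt / tauf2)
        S[_FCASS, i] = fcassinf + (fcass - fcassinf) * math.exp(-dt / taufcass)

        S[_V, i] = V - dt * (Iion + Istim)
        S[_CAI, i] = Cai
        S[_CASR, i] = CaSR
        S[_CASS, i] = CaSS
        S[_NAI, i] = Nai
        S[_KI, i] = Ki
        S[_RBAR, i] = Rbar


@njit(cache=True)
def _ms_step(S, istim, dt, tau_in, tau_out, tau_open, tau_close, u_gate,
             v_rest, v_amp, stim_scale):  # pragma: no cover
    n = S.shape[1]
    for i in range(n):
        u = (S[0, i] - v_rest) / v_amp
        h = S[1, i]
        du = (h * u * u * (1.0 - u) / tau_in - u / tau_out
              + stim_scale * istim[i])
        u = u + dt * du
        if u < u_gate:
            h = h + dt * (1.0 - h) / tau_open
        else:
            h = h - dt * h / tau_close
        S[0, i] = v_rest + v_amp * u
        S[1, i] = h


class IonicModel:
    """Interface shared by all membrane models.

    Subclasses define ``name``, ``state_dim``, ``dt_ode`` (the largest
    stable reaction step in ms) and implement :meth:`initial_state` and
    :meth:`step`.  Row 0 of the state is the transmembrane potential (mV).
    """

    name: str = ""
    state_dim: int = 0
    dt_ode: float = 0.0

    def initial_state(self, n: int) -> np.ndarray:
        raise NotImplementedError

    def step(self, state: np.ndarray, i_stim: np.ndarray, dt: float) -> None:
        raise NotImplementedError


class TenTusscher2006Epi(IonicModel):
    """ten Tusscher-Panfilov 2006 epicardial human ventricular myocyte."""

    name = "tt2006epi"
    state_dim = 19
    dt_ode = 0.02  # ms

    #: published initial conditions (quiescent myocyte)
    INITIAL = np.array(
        [
            -86.2,    # V (mV)
            0.0,      # m
            0.75,     # h
            0.75,     # j
            0.0,      # xr1
            1.0,      # xr2
            0.0,      # xs
            0.0,      # r
            1.0,      # s
            0.0,      # d
            1.0,      # f
            1.0,      # f2
            1.0,      # fcass
            0.00007,  # Cai (mM)
            1.3,      # CaSR (mM)
            0.00007,  # CaSS (mM)
            7.67,     # Nai (mM)
            138.3,    # Ki (mM)
            1.0,      # Rbar
        ]
    )

    def initial_state(self, n: int) -> np.ndarray:
        return np.repeat(self.INITIAL[:, None], n, axis=1)

    def step(self, state, i_stim, dt):
        _tt2006_step(state, i_stim, dt)


class MitchellSchaeffer(IonicModel):
    """Two-variable threshold-and-recovery membrane model.

    Fast surrogate with a genuine refractory period and rate-dependent
    action-potential duration, used for protocol-level property tests.  The
    activation variable u is mapped to mV as ``V = -80 + 100 u`` so that
    activation detection (0 mV upstroke crossing) works unchanged.  The
    analytic rest point is (V, h) = (-80, 1).
    """

    name = "mitchell-schaeffer"
    state_dim = 2
    dt_ode = 0.1  # ms

    def __init__(self, tau_in=0.3, tau_out=6.0, tau_open=100.0,
                 tau_close=120.0, u_gate=0.13, stim_scale=4e-4):
        self.tau_in = tau_in
        self.tau_out = tau_out
        self.tau_open = tau_open
        self.tau_close = tau_close
        self.u_gate = u_gate
        self.stim_scale = stim_scale  # (du/dt) per uA/cm^2
        self.v_rest = -80.0
        self.v_amp = 100.0

    def initial_state(self, n: int) -> np.ndarray:
        state = np.zeros((2, n))
        state[0] = self.v_rest
        state[1] = 1.0
        return state

    def step(self, state, i_stim, dt):
        _ms_step(state, i_stim, dt, self.tau_in, self.tau_out, self.tau_open,
                 self.tau_close, self.u_gate, self.v_rest, self.v_amp,
                 self.stim_scale)


_MODELS = {
    TenTusscher2006Epi.name: TenTusscher2006Epi,
    MitchellSchaeffer.name: MitchellSchaeffer,
}


def get_model(name: str) -> IonicModel:
    """Instantiate an ionic model by name."""
    try:
        return _MODELS[name]()
    except KeyError:
        raise ValueError(
            f"unknown ionic model {name!r}; available: {sorted(_MODELS)}"
        )


def cell_step(state, i_stim, dt, model: IonicModel) -> np.ndarray:
    """Advance the membrane state by one reaction step (in place).

    ``dt`` must not exceed the model's ``dt_ode``.  Raises
    :class:`NumericalInstabilityError` if any state variable leaves the
    finite range, naming the first offending variable index.
    """
    if dt > model.dt_ode + 1e-12:
        raise ValueError(
            f"dt={dt} ms exceeds the model ODE step {model.dt_ode} ms"
        )
    i_stim = np.broadcast_to(
        np.asarray(i_stim, dtype=float), (state.shape[1],)
    ).copy()
    model.step(state, i_stim, dt)
    if not np.all(np.isfinite(state)):
        bad = np.argwhere(~np.isfinite(state))[0]
        raise NumericalInstabilityError(
            f"non-finite state variable {int(bad[0])} at node {int(bad[1])}"
        )
    return state


def save_state(path, state: np.ndarray, model: IonicModel) -> None:
    """Write a membrane state to a tabular text checkpoint.

    One column per node, one row per state variable, with a header naming
    the model so the checkpoint can be validated on load.
    """
    np.savetxt(path, state, header=f"model={model.name} dim={state.shape[0]}")


def load_state(path, model: IonicModel) -> np.ndarray:
    """Read a checkpoint written by :func:`save_state`."""
    with open(path) as fh:
        header = fh.readline()
    if f"model={model.name}" not in header:
        raise ValueError(f"checkpoint was not written by model {model.name!r}")
    state = np.loadtxt(path, ndmin=2)
    if state.shape[0] != model.state_dim:
        raise ValueError("checkpoint state dimension mismatch")
    return state


_REST_CACHE: dict = {}


def resting_state(model: IonicModel, settle_ms: float = 10000.0) -> np.ndarray:
    """Quiescent state: published initial conditions relaxed to rest.

    The model is integrated stimulus-free for ``settle_ms`` milliseconds at
    its own ODE step and the result cached per (model, settle time); the
    returned array is a fresh (state_dim, 1) copy.
    """
    key = (model.name, float(settle_ms))
    if key not in _REST_CACHE:
        state = model.initial_state(1)
        zero = np.zeros(1)
        n_steps = int(round(settle_ms / model.dt_ode))
        for _ in range(n_steps):
            model.step(state, zero, model.dt_ode)
        if not np.all(np.isfinite(state)):
            raise NumericalInstabilityError("relaxation diverged")
        _REST_CACHE[key] = state
    return _REST_CACHE[key].copy()
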