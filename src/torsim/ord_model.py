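"""O'Hara-Rudy dynamic (ORd) human endocardial ventricular action-potential model.

Deterministic ODE implementation of the ORd 2011 endocardial cell with
per-channel conductance scaling hooks (for population-of-models variability)
and per-channel block multipliers (for pore-block drug action), plus paced
simulation returning the analyzed beat on a uniform grid.

Two integrators are provided:

``lsoda`` / ``bdf``
    scipy adaptive stiff solvers honoring relative/absolute tolerances
    1e-5 / 1e-7 (defaults). LSODA switches to BDF in stiff regions and is
    the reference solver.
``rl``
    a compiled adaptive hybrid integrator (exponential Rush-Larsen update
    for the 31 gate-like states, forward Euler for voltage and
    concentrations, step size controlled by the voltage increment). It is
    the workhorse for population-scale drug trials and is validated against
    the LSODA path in the test suite.

Both are seed-free and bitwise deterministic for identical inputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields

import numpy as np
from numba import njit

__all__ = [
    "CHANNELS",
    "STATE_NAMES",
    "CURRENT_NAMES",
    "ConductanceScaling",
    "PacingProtocol",
    "APTrace",
    "SimulationError",
    "initial_state",
    "derivatives",
    "compute_currents",
    "simulate",
    "write_trace_csv",
    "write_population_bundle",
]

# ---------------------------------------------------------------------------
# Names and ordering
# ---------------------------------------------------------------------------

#: The nine scalable currents, in the fixed order used throughout the package.
CHANNELS = ("INa", "INaL", "Ito", "IKr", "IKs", "IK1", "ICaL", "INaK", "INaCa")

#: Channels a pore-block drug can act on (conductance reduction).
BLOCKABLE_CHANNELS = ("INa", "INaL", "Ito", "IKr", "IKs", "IK1", "ICaL")

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)

N_STATES = len(STATE_NAMES)

# gate-like states: first-order relaxation dy/dt = (y_inf - y)/tau,
# updated exponentially by the hybrid integrator
_GATE_LO, _GATE_HI = 9, 40  # indices [9, 40) are gates; 40 is CaMKt

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "IKb", "INab", "ICab", "IpCa",
)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


class SimulationError(RuntimeError):
    """Raised when the integrator fails (NaN state, runaway voltage, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConductanceScaling:
    """Nine dimensionless multipliers on the ORd maximal conductances.

    The identity scaling (all 1.0) reproduces the baseline published model.
    All factors must be finite and >= 0.
    """

    scale_INa: float = 1.0
    scale_INaL: float = 1.0
    scale_Ito: float = 1.0
    scale_IKr: float = 1.0
    scale_IKs: float = 1.0
    scale_IK1: float = 1.0
    scale_ICaL: float = 1.0
    scale_INaK: float = 1.0
    scale_INaCa: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {val}")

    def as_array(self) -> np.ndarray:
        """Factors as a float64 array in ``CHANNELS`` order."""
        return np.array([getattr(self, "scale_" + c) for c in CHANNELS])

    @classmethod
    def from_array(cls, arr) -> "ConductanceScaling":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError("expected exactly nine scale factors")
        return cls(**{"scale_" + c: float(v) for c, v in zip(CHANNELS, arr)})

    @classmethod
    def identity(cls) -> "ConductanceScaling":
        return cls()


@dataclass(frozen=True)
class PacingProtocol:
    """Pacing protocol: 1 Hz for 150 beats by default, last beat analyzed."""

    cycle_length: float = 1000.0     # ms
    n_beats: int = 150
    stimulus_amplitude: float = -80.0  # uA/uF
    stimulus_duration: float = 0.5     # ms
    analyzed_beat: int | None = None   # 1-based; None = last

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        beat = self.analyzed_beat
        if beat is not None and not (1 <= beat <= self.n_beats):
            raise ValueError("analyzed_beat must be in [1, n_beats]")
        if not (0 < self.stimulus_duration < self.cycle_length):
            raise ValueError("stimulus_duration must lie within the cycle")

    @property
    def analyzed(self) -> int:
        return self.n_beats if self.analyzed_beat is None else self.analyzed_beat


@dataclass
class APTrace:
    """One analyzed beat: uniform time grid (ms from stimulus onset), voltage
    (mV), optional per-current series, and run metadata (including the
    pre-stimulus state of the analyzed beat)."""

    time: np.ndarray
    voltage: np.ndarray
    currents: dict[str, np.ndarray] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape or self.time.size < 2:
            raise ValueError("time and voltage must have equal length >= 2")
        dt = np.diff(self.time)
        if not np.all(dt > 0):
            raise ValueError("time must be strictly increasing")
        if np.max(dt) > 1.0 + 1e-9:
            raise ValueError("trace grid spacing must be <= 1 ms")

    @property
    def cycle_length(self) -> float:
        return float(self.metadata.get("cycle_length", self.time[-1]))


# ---------------------------------------------------------------------------
# ORd 2011 endocardial right-hand side (compiled)
# ---------------------------------------------------------------------------

# physical constants and cell geometry
_R, _T, _F = 8314.0, 310.0, 96485.0
_NAO, _CAO, _KO = 140.0, 1.8, 5.4
_L, _RAD = 0.01, 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL


@njit(cache=True)
def _ghk_flux(x, ci, co, gamma):
    # vffrt*(ci*exp(x) - gamma*co)/(exp(x)-1) with vffrt = F*x/z written in
    # terms of x = z*v*F/(R*T); caller multiplies by F/z via x
    gco = gamma * co
    if abs(x) < 1e-7:
        return _F * ((ci - gco) + x * (ci + gco) / 2.0)
    ex = math.exp(x)
    return _F * x * (ci * ex - gco) / (ex - 1.0)


@njit(cache=True)
def _ord_core(y, mult, ist, dy, ginf, gtau, cur):
    """Evaluate the ORd endocardial model at state ``y``.

    Writes the full derivative vector into ``dy``, steady-state/time-constant
    pairs for the gate-like states into ``ginf``/``gtau`` (so an exponential
    integrator can reuse them), and the membrane currents into ``cur``.

    ``mult`` holds the nine effective conductance multipliers (population
    scale x drug block) in CHANNELS order; ``ist`` is the stimulus current.
    """
    v = y[0]
    nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
    cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]
    m = y[9]; hf = y[10]; hs = y[11]; j = y[12]; hsp = y[13]; jp = y[14]
    mL = y[15]; hL = y[16]; hLp = y[17]
    a = y[18]; iF = y[19]; iS = y[20]; ap = y[21]; iFp = y[22]; iSp = y[23]
    d = y[24]; ff = y[25]; fs = y[26]; fcaf = y[27]; fcas = y[28]
    jca = y[29]; nca = y[30]; ffp = y[31]; fcafp = y[32]
    xrf = y[33]; xrs = y[34]; xs1 = y[35]; xs2 = y[36]; xk1 = y[37]
    Jrelnp = y[38]; Jrelp = y[39]; CaMKt = y[40]

    # CaMK
    KmCaMK = 0.15
    CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = 0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt
    fCaMK = 1.0 / (1.0 + KmCaMK / CaMKa)

    # reversal potentials
    rtf = _R * _T / _F
    ENa = rtf * math.log(_NAO / nai)
    EK = rtf * math.log(_KO / ki)
    PKNa = 0.01833
    EKs = rtf * math.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))
    vfrt = v / rtf

    # INa (fast sodium; original ORd formulation — see the ina_formulation
    # hook in simulate() for swapping in an alternative)
    mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                + 8.552 * math.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                 + 6.149 * math.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * math.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * math.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    GNa = 75.0 * mult[0]
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fCaMK) * h * j + fCaMK * hp * jp)
    ginf[9] = mss; gtau[9] = tm
    ginf[10] = hss; gtau[10] = thf
    ginf[11] = hss; gtau[11] = ths
    ginf[12] = jss; gtau[12] = tj
    ginf[13] = hssp; gtau[13] = thsp
    ginf[14] = jss; gtau[14] = tjp

    # INaL (late sodium)
    mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = 0.0075 * mult[1]
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fCaMK) * hL + fCaMK * hLp)
    ginf[15] = mLss; gtau[15] = tmL
    ginf[16] = hLss; gtau[16] = thL
    ginf[17] = hLssp; gtau[17] = thLp

    # Ito (transient outward potassium)
    ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * math.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * math.exp((v + 114.1) / 8.079))
    AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_to = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02 * mult[2]
    Ito = Gto * (v - EK) * ((1.0 - fCaMK) * a * i_to + fCaMK * ap * ip)
    ginf[18] = ass; gtau[18] = ta
    ginf[19] = iss; gtau[19] = tiF
    ginf[20] = iss; gtau[20] = tiS
    ginf[21] = assp; gtau[21] = ta
    ginf[22] = iss; gtau[22] = tiFp
    ginf[23] = iss; gtau[23] = tiSp

    # ICaL / ICaNa / ICaK (L-type calcium channel)
    dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * math.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * math.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                         + 0.04 * math.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                           + 0.00012 * math.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0
    tffp = 2.5 * tff
    fp = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # nca relaxes to anca*k2n/km2n with time constant 1/km2n
    ginf[24] = dss; gtau[24] = td
    ginf[25] = fss; gtau[25] = tff
    ginf[26] = fss; gtau[26] = tfs
    ginf[27] = fcass; gtau[27] = tfcaf
    ginf[28] = fcass; gtau[28] = tfcas
    ginf[29] = fcass; gtau[29] = tjca
    ginf[30] = anca * k2n / km2n; gtau[30] = 1.0 / km2n
    ginf[31] = fss; gtau[31] = tffp
    ginf[32] = fcass; gtau[32] = tfcafp
    # GHK driving-force terms (x = z*v*F/RT; _ghk_flux supplies F*x*(...))
    PhiCaL = 2.0 * _ghk_flux(2.0 * vfrt, cass, 0.341 * _CAO, 1.0)
    PhiCaNa = _ghk_flux(vfrt, 0.75 * nass, 0.75 * _NAO, 1.0)
    PhiCaK = _ghk_flux(vfrt, 0.75 * kss, 0.75 * _KO, 1.0)
    PCa = 0.0001 * mult[6]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
    gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaL = (1.0 - fCaMK) * PCa * PhiCaL * gate_np + fCaMK * PCap * PhiCaL * gate_p
    ICaNa = (1.0 - fCaMK) * PCaNa * PhiCaNa * gate_np + fCaMK * PCaNap * PhiCaNa * gate_p
    ICaK = (1.0 - fCaMK) * PCaK * PhiCaK * gate_np + fCaMK * PCaKp * PhiCaK * gate_p

    # IKr (rapid delayed rectifier, hERG)
    xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
           / (1.0 + math.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * mult[3]
    IKr = GKr * math.sqrt(_KO / 5.4) * xr * rkr * (v - EK)
    ginf[33] = xrss; gtau[33] = txrf
    ginf[34] = xrss; gtau[34] = txrs

    # IKs (slow delayed rectifier)
    xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                          + 0.001292 * math.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                  + 0.0193 * math.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * mult[4]
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)
    ginf[35] = xs1ss; gtau[35] = txs1
    ginf[36] = xs2ss; gtau[36] = txs2

    # IK1 (inward rectifier)
    xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * _KO + 144.59)
                                  / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                    + math.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    GK1 = 0.1908 * mult[5]
    IK1 = GK1 * math.sqrt(_KO) * rk1 * xk1 * (v - EK)
    ginf[37] = xk1ss; gtau[37] = txk1

    # INaCa (sodium-calcium exchanger), myoplasmic and subspace components
    kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
    kasymm = 12.5; wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
    kcaon = 1.5e6; kcaoff = 5.0e3
    qna = 0.5224; qca = 0.1670
    hca = math.exp(qca * vfrt)
    hna = math.exp(qna * vfrt)
    Gncx = 0.0008 * mult[8]
    KmCaAct = 150.0e-6

    # myoplasmic
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    sx = x1 + x2 + x3 + x4
    E1 = x1 / sx; E2 = x2 / sx; E3 = x3 / sx; E4 = x4 / sx
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # subspace
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    sx = x1 + x2 + x3 + x4
    E1 = x1 / sx; E2 = x2 / sx; E3 = x3 / sx; E4 = x4 / sx
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # INaK (sodium-potassium pump)
    k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
    k3p = 1899.0; k3m = 79300.0; k4p = 639.0; k4m = 40.0
    Knai0 = 9.073; Knao0 = 27.78; delta = -0.1550
    Knai = Knai0 * math.exp(delta * vfrt / 3.0)
    Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5; Kko = 0.3582
    MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
    H = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (_NAO / Knao) ** 3
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    a3 = (k3p * (_KO / Kko) ** 2
          / ((1.0 + _NAO / Knao) ** 3 + (1.0 + _KO / Kko) ** 2 - 1.0))
    b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
    a4 = k4p * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2
          / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    sx = x1 + x2 + x3 + x4
    E1 = x1 / sx; E2 = x2 / sx; E3 = x3 / sx; E4 = x4 / sx
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0 * mult[7]
    INaK = Pnak * (JnakNa + JnakK)

    # background and pump currents
    xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
    IKb = 0.003 * xkb * (v - EK)
    INab = 3.75e-10 * _ghk_flux(vfrt, nai, _NAO, 1.0)
    ICab = 2.5e-8 * 2.0 * _ghk_flux(2.0 * vfrt, cai, 0.341 * _CAO, 1.0)
    IpCa = 0.0005 * cai / (0.0005 + cai)

    # diffusion fluxes between subspace and myoplasm
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # SR calcium release (RyR), CaMK-split
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    ginf[38] = Jrel_inf; gtau[38] = tau_rel
    ginf[39] = Jrel_infp; gtau[39] = tau_relp
    Jrel = (1.0 - fCaMK) * Jrelnp + fCaMK * Jrelp

    # SERCA uptake and NSR->JSR translocation
    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fCaMK) * Jupnp + fCaMK * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # membrane potential
    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + ist)
    dy[0] = -Itot

    # intracellular concentrations (with instantaneous buffering)
    dy[1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
             * _ACAP / (_F * _VMYO) + JdiffNa * _VSS / _VMYO)
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dy[3] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK)
             * _ACAP / (_F * _VMYO) + JdiffK * _VSS / _VMYO)
    dy[4] = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    cmdnmax = 0.05; kmcmdn = 0.00238
    trpnmax = 0.07; kmtrpn = 0.0005
    BSRmax = 0.047; KmBSR = 0.00087
    BSLmax = 1.124; KmBSL = 0.0087
    csqnmax = 10.0; kmcsqn = 0.8
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
                    - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                     + Jrel * _VJSR / _VSS - Jdiff)
    dy[7] = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)

    # gate derivatives from the (inf, tau) pairs
    for g in range(_GATE_LO, _GATE_HI):
        dy[g] = (ginf[g] - y[g]) / gtau[g]

    cur[0] = INa
    cur[1] = INaL
    cur[2] = Ito
    cur[3] = ICaL
    cur[4] = ICaNa
    cur[5] = ICaK
    cur[6] = IKr
    cur[7] = IKs
    cur[8] = IK1
    cur[9] = INaCa_i
    cur[10] = INaCa_ss
    cur[11] = INaK
    cur[12] = IKb
    cur[13] = INab
    cur[14] = ICab
    cur[15] = IpCa


@njit(cache=True)
def _rhs(y, mult, ist):
    dy = np.empty(N_STATES)
    ginf = np.empty(N_STATES)
    gtau = np.empty(N_STATES)
    cur = np.empty(16)
    _ord_core(y, mult, ist, dy, ginf, gtau, cur)
    return dy


@njit(cache=True)
def _fd_jacobian(y, mult, ist):
    """Forward-difference Jacobian of the RHS (used by the scipy solvers)."""
    n = N_STATES
    f0 = _rhs(y, mult, ist)
    jac = np.empty((n, n))
    yp = y.copy()
    for k in range(n):
        h = 1e-8 * max(abs(y[k]), 1e-4)
        yp[k] = y[k] + h
        fk = _rhs(yp, mult, ist)
        yp[k] = y[k]
        for r in range(n):
            jac[r, k] = (fk[r] - f0[r]) / h
    return jac


@njit(cache=True)
def _integrate_rl(y, mult, cl, n_beats, stim_amp, stim_dur,
                  dt_min, dt_max, dv_max, record_beat):
    """Paced integration with the adaptive hybrid (Rush-Larsen) stepper.

    Returns (status, t_rec, y_rec, n_rec, y_prestim) where status is 0 on
    success and 1 on a non-finite/runaway state. The recorded beat's adaptive
    samples are in t_rec[:n_rec] (ms from that beat's stimulus onset) with
    states in y_rec[:n_rec].
    """
    dy = np.empty(N_STATES)
    ginf = np.empty(N_STATES)
    gtau = np.empty(N_STATES)
    cur = np.empty(16)
    max_rec = int(2.0 * cl / dt_min) + 64
    t_rec = np.empty(max_rec)
    y_rec = np.empty((max_rec, N_STATES))
    n_rec = 0
    y_prestim = y.copy()

    for beat in range(1, n_beats + 1):
        rec = beat == record_beat
        if rec:
            y_prestim = y.copy()
            t_rec[0] = 0.0
            y_rec[0] = y
            n_rec = 1
        t = 0.0
        while t < cl - 1e-9:
            ist = stim_amp if t < stim_dur - 1e-12 else 0.0
            _ord_core(y, mult, ist, dy, ginf, gtau, cur)
            adv = abs(dy[0])
            dt = dv_max / adv if adv > 1e-12 else dt_max
            if dt > dt_max:
                dt = dt_max
            if dt < dt_min:
                dt = dt_min
            # do not step across the stimulus edge or the cycle end
            if t < stim_dur and t + dt > stim_dur:
                dt = stim_dur - t
            if t + dt > cl:
                dt = cl - t
            # voltage, concentrations, CaMKt: forward Euler
            y[0] += dt * dy[0]
            for k in range(1, _GATE_LO):
                y[k] += dt * dy[k]
            y[40] += dt * dy[40]
            # gates: exponential update toward steady state
            for g in range(_GATE_LO, _GATE_HI):
                y[g] = ginf[g] + (y[g] - ginf[g]) * math.exp(-dt / gtau[g])
            t += dt
            if not math.isfinite(y[0]) or y[0] > 200.0 or y[0] < -200.0:
                return 1, t_rec, y_rec, n_rec, y_prestim
            if rec:
                if n_rec >= max_rec:
                    return 1, t_rec, y_rec, n_rec, y_prestim
                t_rec[n_rec] = t
                y_rec[n_rec] = y
                n_rec += 1
    return 0, t_rec, y_rec, n_rec, y_prestim


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

# published ORd resting initial conditions (endocardial)
_Y0 = np.array([
    -87.5,      # v
    7.0,        # nai
    7.0,        # nass
    145.0,      # ki
    145.0,      # kss
    1.0e-4,     # cai
    1.0e-4,     # cass
    1.2,        # cansr
    1.2,        # cajsr
    0.0, 1.0, 1.0, 1.0, 1.0, 1.0,          # m hf hs j hsp jp
    0.0, 1.0, 1.0,                          # mL hL hLp
    0.0, 1.0, 1.0, 0.0, 1.0, 1.0,           # a iF iS ap iFp iSp
    0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0,      # d ff fs fcaf fcas jca nca
    1.0, 1.0,                               # ffp fcafp
    0.0, 0.0, 0.0, 0.0, 1.0,                # xrf xrs xs1 xs2 xk1
    0.0, 0.0, 0.0,                          # Jrelnp Jrelp CaMKt
])


def initial_state() -> np.ndarray:
    """Published ORd endocardial resting initial conditions (copy)."""
    return _Y0.copy()


def _effective_multipliers(scaling: ConductanceScaling,
                           block_multipliers: dict[str, float] | None) -> np.ndarray:
    mult = scaling.as_array()
    if block_multipliers:
        for name, b in block_multipliers.items():
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}; expected one of {CHANNELS}")
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"block multiplier for {name} must be in [0,1], got {b}")
            mult[CHANNELS.index(name)] *= b
    return mult


def derivatives(state, scaling: ConductanceScaling | None = None,
                t: float = 0.0, stimulus_current: float = 0.0) -> np.ndarray:
    """Time-derivatives of the full ORd state vector (autonomous in ``t``).

    Each of the nine scaled currents equals its baseline formulation
    multiplied by the corresponding factor in ``scaling``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} entries")
    bad = np.where(~np.isfinite(state))[0]
    if bad.size:
        raise ValueError(f"non-finite state variable {STATE_NAMES[bad[0]]!r}")
    if scaling is None:
        scaling = ConductanceScaling.identity()
    return _rhs(state, scaling.as_array(), stimulus_current)


def compute_currents(state, scaling: ConductanceScaling | None = None,
                     block_multipliers: dict[str, float] | None = None,
                     stimulus_current: float = 0.0) -> dict[str, float]:
    """Membrane currents (uA/uF) at a state, keyed by ``CURRENT_NAMES``."""
    state = np.asarray(state, dtype=float)
    if scaling is None:
        scaling = ConductanceScaling.identity()
    mult = _effective_multipliers(scaling, block_multipliers)
    dy = np.empty(N_STATES)
    ginf = np.empty(N_STATES)
    gtau = np.empty(N_STATES)
    cur = np.empty(16)
    _ord_core(state, mult, stimulus_current, dy, ginf, gtau, cur)
    return dict(zip(CURRENT_NAMES, cur.tolist()))


#: resampled output grid spacing for analyzed beats, ms
OUTPUT_DT = 0.5

#: adaptive hybrid integrator controls: step bounds (ms) and per-step
#: voltage increment target (mV); validated against the LSODA path
RL_DT_MIN = 0.004
RL_DT_MAX = 0.25
RL_DV_MAX = 0.1


def _simulate_scipy(y0, mult, protocol, method, rtol, atol):
    from scipy.integrate import solve_ivp

    dy = np.empty(N_STATES)
    ginf = np.empty(N_STATES)
    gtau = np.empty(N_STATES)
    cur = np.empty(16)

    def make_f(ist):
        def f(t, y):
            _ord_core(y, mult, ist, dy, ginf, gtau, cur)
            return dy.copy()
        return f

    def make_jac(ist):
        def jac(t, y):
            return _fd_jacobian(y, mult, ist)
        return jac

    cl = protocol.cycle_length
    sd = protocol.stimulus_duration
    scipy_method = {"lsoda": "LSODA", "bdf": "BDF"}[method]
    y = y0.copy()
    analyzed = protocol.analyzed
    t_keep = None
    y_keep = None
    y_prestim = None
    for beat in range(1, protocol.n_beats + 1):
        rec = beat == analyzed
        if rec:
            y_prestim = y.copy()
        segs = []
        for (t0, t1, ist) in ((0.0, sd, protocol.stimulus_amplitude),
                              (sd, cl, 0.0)):
            t_eval = None
            if rec:
                n = int(round((t1 - t0) / OUTPUT_DT))
                t_eval = np.linspace(t0, t1, max(n, 1) + 1)
            sol = solve_ivp(make_f(ist), (t0, t1), y, method=scipy_method,
                            jac=make_jac(ist), rtol=rtol, atol=atol,
                            t_eval=t_eval, max_step=np.inf)
            if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
                raise SimulationError(f"solver failed in beat {beat}: {sol.message}")
            y = sol.y[:, -1].copy()
            if rec:
                segs.append((sol.t, sol.y))
        if rec:
            t_keep = np.concatenate([segs[0][0], segs[1][0][1:]])
            y_keep = np.concatenate([segs[0][1], segs[1][1][:, 1:]], axis=1).T
    return t_keep, y_keep, y_prestim


def simulate(scaling: ConductanceScaling | None = None,
             block_multipliers: dict[str, float] | None = None,
             protocol: PacingProtocol | None = None,
             solver: str = "lsoda",
             rtol: float = 1e-5,
             atol: float = 1e-7,
             record_currents: bool = False,
             ina_formulation: str = "ord",
             metadata: dict | None = None) -> APTrace:
    """Pace the scaled/blocked ORd cell and return the analyzed beat.

    Drug block composes multiplicatively with the population scaling. The
    analyzed beat (the last one by default) is resampled to a uniform
    ``OUTPUT_DT`` grid spanning [0, cycle_length] from its stimulus onset;
    the pre-stimulus state is stored in the trace metadata.

    ``solver``: ``"lsoda"`` (default; adaptive, BDF in stiff regions,
    honoring ``rtol``/``atol``), ``"bdf"`` (scipy BDF, same tolerances) or
    ``"rl"`` (fast compiled hybrid integrator).

    ``ina_formulation`` is the swap point for alternative fast-sodium
    formulations; only the original ORd INa (``"ord"``) ships.
    """
    if scaling is None:
        scaling = ConductanceScaling.identity()
    if protocol is None:
        protocol = PacingProtocol()
    if ina_formulation != "ord":
        raise ValueError(
            f"unknown INa formulation {ina_formulation!r}; only 'ord' is available")
    if solver not in ("lsoda", "bdf", "rl"):
        raise ValueError(f"unknown solver {solver!r}")
    mult = _effective_multipliers(scaling, block_multipliers)
    meta = dict(metadata or {})

    y0 = initial_state()
    if solver == "rl":
        status, t_rec, y_rec, n_rec, y_prestim = _integrate_rl(
            y0, mult, protocol.cycle_length, protocol.n_beats,
            protocol.stimulus_amplitude, protocol.stimulus_duration,
            RL_DT_MIN, RL_DT_MAX, RL_DV_MAX, protocol.analyzed)
        if status != 0 or n_rec < 2:
            raise SimulationError(
                "integration diverged (non-finite or runaway voltage) "
                f"[model={meta.get('model_id')}, drug={meta.get('drug')}, "
                f"concentration={meta.get('concentration')}]")
        t_src = t_rec[:n_rec]
        y_src = y_rec[:n_rec]
    else:
        try:
            t_src, y_src, y_prestim = _simulate_scipy(
                y0, mult, protocol, solver, rtol, atol)
        except SimulationError as exc:
            raise SimulationError(
                f"{exc} [model={meta.get('model_id')}, drug={meta.get('drug')}, "
                f"concentration={meta.get('concentration')}]") from exc

    n_out = int(round(protocol.cycle_length / OUTPUT_DT)) + 1
    t_grid = np.linspace(0.0, protocol.cycle_length, n_out)
    y_grid = np.empty((n_out, N_STATES))
    for k in range(N_STATES):
        y_grid[:, k] = np.interp(t_grid, t_src, y_src[:, k])
    if not np.all(np.isfinite(y_grid)):
        raise SimulationError(
            f"non-finite trace [model={meta.get('model_id')}, "
            f"drug={meta.get('drug')}, concentration={meta.get('concentration')}]")

    currents = None
    if record_currents:
        dy = np.empty(N_STATES)
        ginf = np.empty(N_STATES)
        gtau = np.empty(N_STATES)
        cur = np.empty(16)
        series = np.empty((n_out, 16))
        for s in range(n_out):
            _ord_core(y_grid[s], mult, 0.0, dy, ginf, gtau, cur)
            series[s] = cur
        currents = {name: series[:, k].copy()
                    for k, name in enumerate(CURRENT_NAMES)}

    meta.update(
        cycle_length=protocol.cycle_length,
        n_beats=protocol.n_beats,
        analyzed_beat=protocol.analyzed,
        stimulus_amplitude=protocol.stimulus_amplitude,
        stimulus_duration=protocol.stimulus_duration,
        solver=solver,
        scaling={("scale_" + c): float(s) for c, s in zip(CHANNELS, scaling.as_array())},
        block_multipliers={k: float(v) for k, v in (block_multipliers or {}).items()},
        prestimulus_state=y_prestim.copy(),
    )
    return APTrace(time=t_grid, voltage=y_grid[:, 0], currents=currents,
                   metadata=meta)


# ---------------------------------------------------------------------------
# Trace export
# ---------------------------------------------------------------------------


def write_trace_csv(trace: APTrace, path) -> None:
    """Write one trace as CSV (time_ms, voltage_mV[, currents]) with a JSON
    metadata sidecar next to it."""
    import pandas as pd

    cols = {"time_ms": trace.time, "voltage_mV": trace.voltage}
    if trace.currents:
        for name, series in trace.currents.items():
            cols[name] = series
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {}
    for k, v in trace.metadata.items():
        meta[k] = v.tolist() if isinstance(v, np.ndarray) else v
    sidecar = str(path) + ".meta.json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def write_population_bundle(traces: dict[str, APTrace], path) -> None:
    """Compact binary bundle (npz) of many traces for a whole-population run."""
    arrays = {}
    for key, tr in traces.items():
        arrays[f"{key}__time"] = tr.time
        arrays[f"{key}__voltage"] = tr.voltage
    np.savez_compressed(path, **arrays)
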