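"""O'Hara-Rudy (ORd) human ventricular ionic model.

Implements the published dynamic ORd formulation (41 state variables:
membrane potential, ionic concentrations in myoplasm and subspace,
SR calcium, gating variables, CaMK trapping) with the epicardial,
mid-myocardial and endocardial parameter variants, and hooks for
conductance-block drug scaling of g_Na, g_Kr and the PCa permeability
group (I_CaL, I_CaNa, I_CaK).

The model is evaluated by a single numba kernel shared by two steppers:
a fixed-step hybrid integrator (Rush-Larsen exponential update for every
gate-like variable, forward update for potential and concentrations) and
an adaptive scipy ``solve_ivp`` path used as an independent numerical
cross-check. The kernel is vectorised over "nodes" so the same code
drives one cell or a whole tissue grid with per-node cell types.

State layout (index: name):
  0 v, 1 nai, 2 nass, 3 ki, 4 kss, 5 cai, 6 cass, 7 cansr, 8 cajsr,
  9 m, 10 hf, 11 hs, 12 j, 13 hsp, 14 jp, 15 mL, 16 hL, 17 hLp,
  18 a, 19 iF, 20 iS, 21 ap, 22 iFp, 23 iSp, 24 d, 25 ff, 26 fs,
  27 fcaf, 28 fcas, 29 jca, 30 nca, 31 ffp, 32 fcafp, 33 xrf, 34 xrs,
  35 xs1, 36 xs2, 37 xk1, 38 Jrelnp, 39 Jrelp, 40 CaMKt
Indices 9..39 relax exponentially toward a voltage/state-dependent
steady state and are advanced with the Rush-Larsen scheme.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 41
GATE_LO, GATE_HI = 9, 40  # half-open: states [9, 40) are Rush-Larsen updated
N_GATES = GATE_HI - GATE_LO

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp", "d", "ff", "fs",
    "fcaf", "fcas", "jca", "nca", "ffp", "fcafp", "xrf", "xrs",
    "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)

CELL_TYPES = ("endocardial", "epicardial", "mid_myocardial")
ENDO, EPI, MID = 0, 1, 2
_CT_CODE = {"endocardial": ENDO, "epicardial": EPI, "mid_myocardial": MID}


def cell_type_code(cell_type) -> int:
    """Map a cell-type name (or code) to the integer kernel code."""
    if isinstance(cell_type, str):
        try:
            return _CT_CODE[cell_type]
        except KeyError:
            raise ValueError(
                f"unknown cell type {cell_type!r}; expected one of {CELL_TYPES}"
            ) from None
    code = int(cell_type)
    if code not in (ENDO, EPI, MID):
        raise ValueError(f"cell-type code must be 0, 1 or 2, got {code}")
    return code


# Published steady-state values of the endocardial cell at 1 Hz pacing;
# used as the generic starting point (every protocol pre-paces anyway).
_Y0 = np.array([
    -87.5, 7.268, 7.268, 144.65, 144.65, 8.6e-5, 8.49e-5, 1.619, 1.571,
    0.0074621, 0.692591, 0.692574, 0.692477, 0.448501, 0.692413,
    0.000194015, 0.496116, 0.265885,
    0.00101185, 0.999542, 0.589579, 0.000515567, 0.999542, 0.641861,
    2.43015e-9, 1.0, 0.910671, 1.0, 0.99982, 0.999977,
    0.00267171, 1.0, 1.0, 8.26608e-6, 0.453268,
    0.270492, 0.0001963, 0.996801, 2.53943e-5, 3.17262e-7, 0.0124065,
])


def initial_state(cell_type="endocardial", n_nodes: int | None = None) -> np.ndarray:
    """Return a fresh state vector (or ``(n_nodes, 41)`` array)."""
    cell_type_code(cell_type)  # validation only; initials shared across types
    if n_nodes is None:
        return _Y0.copy()
    return np.tile(_Y0, (int(n_nodes), 1))


@njit(cache=True)
def _ord_kernel(y, celltype, scale_na, scale_kr, scale_ca, i_app,
                dy, gss, gtau):  # pragma: no cover - exercised via wrappers
    """Evaluate the ORd model for every node.

    Fills ``dy`` (full time derivative, 1/ms), and ``gss``/``gtau`` with
    the steady state and time constant of states 9..39 for Rush-Larsen
    updates. ``i_app`` is the applied stimulus per node in pA/pF
    (negative = depolarising, added to the total membrane current).
    """
    nao = 140.0
    cao = 1.8
    ko = 5.4
    R = 8314.0
    T = 310.0
    F = 96485.0
    L = 0.01
    rad = 0.0011
    vcell = 1000.0 * 3.14 * rad * rad * L
    Ageo = 2.0 * 3.14 * rad * rad + 2.0 * 3.14 * rad * L
    Acap = 2.0 * Ageo
    vmyo = 0.68 * vcell
    vnsr = 0.0552 * vcell
    vjsr = 0.0048 * vcell
    vss = 0.02 * vcell

    n = y.shape[0]
    for ii in range(n):
        ct = celltype[ii]
        v = y[ii, 0]
        nai = y[ii, 1]
        nass = y[ii, 2]
        ki = y[ii, 3]
        kss = y[ii, 4]
        cai = y[ii, 5]
        cass = y[ii, 6]
        cansr = y[ii, 7]
        cajsr = y[ii, 8]
        m = y[ii, 9]
        hf = y[ii, 10]
        hs = y[ii, 11]
        jg = y[ii, 12]
        hsp = y[ii, 13]
        jp = y[ii, 14]
        mL = y[ii, 15]
        hL = y[ii, 16]
        hLp = y[ii, 17]
        a = y[ii, 18]
        iF = y[ii, 19]
        iS = y[ii, 20]
        ap = y[ii, 21]
        iFp = y[ii, 22]
        iSp = y[ii, 23]
        d = y[ii, 24]
        ff = y[ii, 25]
        fs = y[ii, 26]
        fcaf = y[ii, 27]
        fcas = y[ii, 28]
        jca = y[ii, 29]
        nca = y[ii, 30]
        ffp = y[ii, 31]
        fcafp = y[ii, 32]
        xrf = y[ii, 33]
        xrs = y[ii, 34]
        xs1 = y[ii, 35]
        xs2 = y[ii, 36]
        xk1 = y[ii, 37]
        Jrelnp = y[ii, 38]
        Jrelp = y[ii, 39]
        CaMKt = y[ii, 40]

        # CaMK
        KmCaMK = 0.15
        aCaMK = 0.05
        bCaMK = 0.00068
        CaMKo = 0.05
        KmCaM = 0.0015
        CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
        CaMKa = CaMKb + CaMKt
        dCaMKt = aCaMK * CaMKb * (CaMKb + CaMKt) - bCaMK * CaMKt
        fphos = 1.0 / (1.0 + KmCaMK / CaMKa)

        ENa = (R * T / F) * math.log(nao / nai)
        EK = (R * T / F) * math.log(ko / ki)
        PKNa = 0.01833
        EKs = (R * T / F) * math.log((ko + PKNa * nao) / (ki + PKNa * nai))
        vffrt = v * F * F / (R * T)
        vfrt = v * F / (R * T)

        # INa (fast)
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
        GNa = 75.0 * scale_na
        INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fphos) * h * jg + fphos * hp * jp)

        # INaL
        mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
        tmL = tm
        hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
        thL = 200.0
        hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
        thLp = 3.0 * thL
        GNaL = 0.0075
        if ct == 1:
            GNaL *= 0.6
        INaL = GNaL * (v - ENa) * mL * ((1.0 - fphos) * hL + fphos * hLp)

        # Ito
        ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
        ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                       + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
        iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
        if ct == 1:
            delta_epi = 1.0 - 0.95 / (1.0 + math.exp((v + 70.0) / 5.0))
        else:
            delta_epi = 1.0
        tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                             + 0.08004 * math.exp((v + 50.0) / 16.59))
        tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                             + 1.780e-8 * math.exp((v + 114.1) / 8.079))
        tiF *= delta_epi
        tiS *= delta_epi
        AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
        AiS = 1.0 - AiF
        i_gate = AiF * iF + AiS * iS
        assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
        dti_develop = 1.354 + 1e-4 / (math.exp((v - 167.4) / 15.89)
                                      + math.exp(-(v - 12.23) / 0.2154))
        dti_recover = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
        tiFp = dti_develop * dti_recover * tiF
        tiSp = dti_develop * dti_recover * tiS
        ip_gate = AiF * iFp + AiS * iSp
        Gto = 0.02
        if ct == 1 or ct == 2:
            Gto *= 4.0
        Ito = Gto * (v - EK) * ((1.0 - fphos) * a * i_gate + fphos * ap * ip_gate)

        # ICaL / ICaNa / ICaK
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
        # nca relaxes toward anca*k2n/km2n with time constant 1/km2n
        if vfrt * vfrt < 1e-12:
            # v -> 0 limit of the GHK flux factors
            PhiCaL = 2.0 * F * (cass - 0.341 * cao)
            PhiCaNa = 0.75 * F * (nass - nao)
            PhiCaK = 0.75 * F * (kss - ko)
        else:
            e2v = math.exp(2.0 * vfrt)
            e1v = math.exp(vfrt)
            PhiCaL = 4.0 * vffrt * (cass * e2v - 0.341 * cao) / (e2v - 1.0)
            PhiCaNa = vffrt * (0.75 * nass * e1v - 0.75 * nao) / (e1v - 1.0)
            PhiCaK = vffrt * (0.75 * kss * e1v - 0.75 * ko) / (e1v - 1.0)
        PCa = 0.0001 * scale_ca
        if ct == 1:
            PCa *= 1.2
        elif ct == 2:
            PCa *= 2.5
        PCap = 1.1 * PCa
        PCaNa = 0.00125 * PCa
        PCaK = 3.574e-4 * PCa
        PCaNap = 0.00125 * PCap
        PCaKp = 3.574e-4 * PCap
        gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
        gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
        ICaL = (1.0 - fphos) * PCa * PhiCaL * gate_np + fphos * PCap * PhiCaL * gate_p
        ICaNa = (1.0 - fphos) * PCaNa * PhiCaNa * gate_np + fphos * PCaNap * PhiCaNa * gate_p
        ICaK = (1.0 - fphos) * PCaK * PhiCaK * gate_np + fphos * PCaKp * PhiCaK * gate_p

        # IKr
        xrss = 1.0 / (1.0 + math.exp(-(v + 8.337) / 6.789))
        txrf = 12.98 + 1.0 / (0.3652 * math.exp((v - 31.66) / 3.869)
                              + 4.123e-5 * math.exp(-(v - 47.78) / 20.38))
        txrs = 1.865 + 1.0 / (0.06629 * math.exp((v - 34.70) / 7.355)
                              + 1.128e-5 * math.exp(-(v - 29.74) / 25.94))
        Axrf = 1.0 / (1.0 + math.exp((v + 54.81) / 38.21))
        Axrs = 1.0 - Axrf
        xr = Axrf * xrf + Axrs * xrs
        rkr = (1.0 / (1.0 + math.exp((v + 55.0) / 75.0))
               * 1.0 / (1.0 + math.exp((v - 10.0) / 30.0)))
        GKr = 0.046 * scale_kr
        if ct == 1:
            GKr *= 1.3
        elif ct == 2:
            GKr *= 0.8
        IKr = GKr * math.sqrt(ko / 5.4) * xr * rkr * (v - EK)

        # IKs
        xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
        txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                              + 0.001292 * math.exp(-(v + 210.0) / 230.0))
        xs2ss = xs1ss
        txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                      + 0.0193 * math.exp(-(v + 66.54) / 31.0))
        KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
        GKs = 0.0034
        if ct == 1:
            GKs *= 1.4
        IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

        # IK1
        xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * ko + 144.59)
                                      / (1.5692 * ko + 3.8115)))
        txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                        + math.exp((v + 236.8) / 69.33))
        rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * ko) / 9.493))
        GK1 = 0.1908
        if ct == 1:
            GK1 *= 1.2
        elif ct == 2:
            GK1 *= 1.3
        IK1 = GK1 * math.sqrt(ko) * rk1 * xk1 * (v - EK)

        # INaCa (myoplasmic and subspace components)
        kna1 = 15.0
        kna2 = 5.0
        kna3 = 88.12
        kasymm = 12.5
        wna = 6.0e4
        wca = 6.0e4
        wnaca = 5.0e3
        kcaon = 1.5e6
        kcaoff = 5.0e3
        qna = 0.5224
        qca = 0.1670
        hca = math.exp(qca * vfrt)
        hna = math.exp(qna * vfrt)
        Gncx = 0.0008
        if ct == 1:
            Gncx *= 1.1
        elif ct == 2:
            Gncx *= 1.4
        KmCaAct = 150.0e-6
        zca = 2.0
        zna = 1.0

        # myoplasmic
        h1 = 1.0 + nai / kna3 * (1.0 + hna)
        h2 = (nai * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
        h5 = nai * nai / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + nao / kna3 * (1.0 + 1.0 / hna)
        h8 = nao / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = kasymm + 1.0 + nao / kna1 * (1.0 + nao / kna2)
        h11 = nao * nao / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * cao * kcaon
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
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

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
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

        # INaK
        k1p = 949.5
        k1m = 182.4
        k2p = 687.2
        k2m = 39.4
        k3p_ = 1899.0
        k3m = 79300.0
        k4p_ = 639.0
        k4m = 40.0
        Knai0 = 9.073
        Knao0 = 27.78
        delta = -0.1550
        Knai = Knai0 * math.exp(delta * vfrt / 3.0)
        Knao = Knao0 * math.exp((1.0 - delta) * vfrt / 3.0)
        Kki = 0.5
        Kko = 0.3582
        MgADP = 0.05
        MgATP = 9.8
        Kmgatp = 1.698e-7
        H = 1.0e-7
        eP = 4.2
        Khp = 1.698e-7
        Knap = 224.0
        Kxkur = 292.0
        P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
        a1 = (k1p * (nai / Knai) ** 3
              / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
        b1 = k1m * MgADP
        a2 = k2p
        b2 = (k2m * (nao / Knao) ** 3
              / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0))
        a3 = (k3p_ * (ko / Kko) ** 2
              / ((1.0 + nao / Knao) ** 3 + (1.0 + ko / Kko) ** 2 - 1.0))
        b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
        a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
        b4 = (k4m * (ki / Kki) ** 2
              / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
        x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
        x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
        x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
        x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        zk = 1.0
        JnakNa = 3.0 * (E1 * a3 - E2 * b3)
        JnakK = 2.0 * (E4 * b1 - E3 * a1)
        Pnak = 30.0
        if ct == 1:
            Pnak *= 0.9
        elif ct == 2:
            Pnak *= 0.7
        INaK = Pnak * (zna * JnakNa + zk * JnakK)

        # background / pump currents
        xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
        GKb = 0.003
        if ct == 1:
            GKb *= 0.6
        IKb = GKb * xkb * (v - EK)
        if vfrt * vfrt < 1e-12:
            INab = 3.75e-10 * F * (nai - nao)
            ICab = 2.5e-8 * 2.0 * F * (cai - 0.341 * cao)
        else:
            e1v = math.exp(vfrt)
            e2v = math.exp(2.0 * vfrt)
            INab = 3.75e-10 * vffrt * (nai * e1v - nao) / (e1v - 1.0)
            ICab = 2.5e-8 * 4.0 * vffrt * (cai * e2v - 0.341 * cao) / (e2v - 1.0)
        IpCa = 0.0005 * cai / (0.0005 + cai)

        # diffusion fluxes between subspace and myoplasm
        JdiffNa = (nass - nai) / 2.0
        JdiffK = (kss - ki) / 2.0
        Jdiff = (cass - cai) / 0.2

        # SR release
        bt = 4.75
        a_rel = 0.5 * bt
        Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        if ct == 2:
            Jrel_inf *= 1.7
        tau_rel = bt / (1.0 + 0.0123 / cajsr)
        if tau_rel < 0.001:
            tau_rel = 0.001
        btp = 1.25 * bt
        a_relp = 0.5 * btp
        Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        if ct == 2:
            Jrel_infp *= 1.7
        tau_relp = btp / (1.0 + 0.0123 / cajsr)
        if tau_relp < 0.001:
            tau_relp = 0.001
        Jrel = (1.0 - fphos) * Jrelnp + fphos * Jrelp

        # SR uptake
        Jupnp = 0.004375 * cai / (cai + 0.00092)
        Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
        if ct == 1:
            Jupnp *= 1.3
            Jupp *= 1.3
        Jleak = 0.0039375 * cansr / 15.0
        Jup = (1.0 - fphos) * Jupnp + fphos * Jupp - Jleak
        Jtr = (cansr - cajsr) / 100.0

        # buffers
        cmdnmax = 0.05
        if ct == 2:
            cmdnmax *= 1.3
        kmcmdn = 0.00238
        trpnmax = 0.07
        kmtrpn = 0.0005
        BSRmax = 0.047
        KmBSR = 0.00087
        BSLmax = 1.124
        KmBSL = 0.0087
        csqnmax = 10.0
        kmcsqn = 0.8

        Ist = i_app[ii]
        Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
                + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + Ist)

        dy[ii, 0] = -Itot
        dy[ii, 1] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
                     * Acap / (F * vmyo) + JdiffNa * vss / vmyo)
        dy[ii, 2] = -(ICaNa + 3.0 * INaCa_ss) * Acap / (F * vss) - JdiffNa
        dy[ii, 3] = (-(Ito + IKr + IKs + IK1 + IKb + Ist - 2.0 * INaK)
                     * Acap / (F * vmyo) + JdiffK * vss / vmyo)
        dy[ii, 4] = -ICaK * Acap / (F * vss) - JdiffK
        Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                      + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
        dy[ii, 5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * Acap / (2.0 * F * vmyo)
                            - Jup * vnsr / vmyo + Jdiff * vss / vmyo)
        Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                       + BSLmax * KmBSL / (KmBSL + cass) ** 2)
        dy[ii, 6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * Acap / (2.0 * F * vss)
                             + Jrel * vjsr / vss - Jdiff)
        dy[ii, 7] = Jup - Jtr * vjsr / vnsr
        Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
        dy[ii, 8] = Bcajsr * (Jtr - Jrel)
        dy[ii, 40] = dCaMKt

        # gate-like states: steady state + time constant
        g = GATE_LO
        gss[ii, 9 - g] = mss
        gtau[ii, 9 - g] = tm
        gss[ii, 10 - g] = hss
        gtau[ii, 10 - g] = thf
        gss[ii, 11 - g] = hss
        gtau[ii, 11 - g] = ths
        gss[ii, 12 - g] = jss
        gtau[ii, 12 - g] = tj
        gss[ii, 13 - g] = hssp
        gtau[ii, 13 - g] = thsp
        gss[ii, 14 - g] = jss
        gtau[ii, 14 - g] = tjp
        gss[ii, 15 - g] = mLss
        gtau[ii, 15 - g] = tmL
        gss[ii, 16 - g] = hLss
        gtau[ii, 16 - g] = thL
        gss[ii, 17 - g] = hLssp
        gtau[ii, 17 - g] = thLp
        gss[ii, 18 - g] = ass
        gtau[ii, 18 - g] = ta
        gss[ii, 19 - g] = iss
        gtau[ii, 19 - g] = tiF
        gss[ii, 20 - g] = iss
        gtau[ii, 20 - g] = tiS
        gss[ii, 21 - g] = assp
        gtau[ii, 21 - g] = ta
        gss[ii, 22 - g] = iss
        gtau[ii, 22 - g] = tiFp
        gss[ii, 23 - g] = iss
        gtau[ii, 23 - g] = tiSp
        gss[ii, 24 - g] = dss
        gtau[ii, 24 - g] = td
        gss[ii, 25 - g] = fss
        gtau[ii, 25 - g] = tff
        gss[ii, 26 - g] = fss
        gtau[ii, 26 - g] = tfs
        gss[ii, 27 - g] = fcass
        gtau[ii, 27 - g] = tfcaf
        gss[ii, 28 - g] = fcass
        gtau[ii, 28 - g] = tfcas
        gss[ii, 29 - g] = fcass
        gtau[ii, 29 - g] = tjca
        gss[ii, 30 - g] = anca * k2n / km2n
        gtau[ii, 30 - g] = 1.0 / km2n
        gss[ii, 31 - g] = fss
        gtau[ii, 31 - g] = tffp
        gss[ii, 32 - g] = fcass
        gtau[ii, 32 - g] = tfcafp
        gss[ii, 33 - g] = xrss
        gtau[ii, 33 - g] = txrf
        gss[ii, 34 - g] = xrss
        gtau[ii, 34 - g] = txrs
        gss[ii, 35 - g] = xs1ss
        gtau[ii, 35 - g] = txs1
        gss[ii, 36 - g] = xs2ss
        gtau[ii, 36 - g] = txs2
        gss[ii, 37 - g] = xk1ss
        gtau[ii, 37 - g] = txk1
        gss[ii, 38 - g] = Jrel_inf
        gtau[ii, 38 - g] = tau_rel
        gss[ii, 39 - g] = Jrel_infp
        gtau[ii, 39 - g] = tau_relp

        for k in range(N_GATES):
            dy[ii, GATE_LO + k] = (gss[ii, k] - y[ii, GATE_LO + k]) / gtau[ii, k]


@njit(cache=True)
def rush_larsen_step(y, celltype, scale_na, scale_kr, scale_ca, i_app, dt,
                     dy, gss, gtau):  # pragma: no cover - exercised via wrappers
    """Advance all nodes by one fixed step dt (ms), in place.

    Gate-like states use the exponential Rush-Larsen update; potential,
    concentrations and CaMKt use a forward update.
    """
    _ord_kernel(y, celltype, scale_na, scale_kr, scale_ca, i_app, dy, gss, gtau)
    n = y.shape[0]
    for ii in range(n):
        for k in range(GATE_LO):
            y[ii, k] += dt * dy[ii, k]
        y[ii, 40] += dt * dy[ii, 40]
        for k in range(N_GATES):
            j = GATE_LO + k
            y[ii, j] = gss[ii, k] + (y[ii, j] - gss[ii, k]) * math.exp(-dt / gtau[ii, k])


def ord_derivative(state: np.ndarray, t: float, scales=(1.0, 1.0, 1.0),
                   cell_type="endocardial", pacing: float = 0.0) -> np.ndarray:
    """Time derivative of a single-cell state (1/ms units).

    ``scales`` is (scale_na, scale_kr, scale_ca); ``pacing`` is the applied
    stimulus in pA/pF (negative depolarises).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} entries")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state at t={t}: {y}")
    sna, skr, sca = scales
    y2 = y[None, :].copy()
    ct = np.zeros(1, dtype=np.int8)
    ct[0] = cell_type_code(cell_type)
    dy = np.empty_like(y2)
    gss = np.empty((1, N_GATES))
    gtau = np.empty((1, N_GATES))
    _ord_kernel(y2, ct, float(sna), float(skr), float(sca),
                np.array([float(pacing)]), dy, gss, gtau)
    return dy[0]
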