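"""Numba kernels: fixture-model right-hand side and an adaptive Dormand-Prince
integrator with dense (Hermite) output on a uniform grid.

The fixture cell models are reduced Hodgkin-Huxley-style ventricular /
pacemaker formulations in which every one of the 13 canonical ion-transport
pathways enters as a separable maximal-rate factor.  State vector:

    y = [V (mV), h (Na inactivation), xr (Kr activation),
         f (L-type Ca inactivation), Cai (uM), CaSR (uM),
         yf (pacemaker-current activation)]

Parameter vector layout (see model_core.PARAM_ORDER):

    0..12  the 13 transport maximal rates, canonical order
    13..15 Nao, Cao, Ko (mM)
    16..17 Nai, Ki (mM, held fixed -- no slow intracellular Na/K drift)
    18..19 Gf (pacemaker "funny" conductance, 0 for the paced fixture), Ef (mV)

Kinetic shape constants (gate midpoints, slopes, time constants) are fixed
inside the kernel; they are part of the chosen fixture equations, not tunable
model parameters.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NSTATE = 7
RTF = 26.712  # mV, RT/F at 37 C


@njit(cache=True)
def fixture_rhs(t, y, p, istim, dy):
    """Evaluate state derivatives in place; returns dV/dt for convenience."""
    V = y[0]
    h = y[1]
    xr = y[2]
    f = y[3]
    cai = y[4]
    casr = y[5]
    yf = y[6]

    if cai < 1e-6:
        cai = 1e-6
    if casr < 1e-3:
        casr = 1e-3

    nao = p[13]
    cao = p[14]
    ko = p[15]
    nai = p[16]
    ki = p[17]

    ena = RTF * math.log(nao / nai)
    ek = RTF * math.log(ko / ki)
    cai_mm = cai * 1e-3
    eca = 0.5 * RTF * math.log(cao / cai_mm)

    # --- fast Na+ current (instantaneous activation, single inactivation gate)
    m = 1.0 / (1.0 + math.exp(-(V + 38.0) / 6.0))
    ina = p[0] * m * m * m * h * (V - ena)
    hinf = 1.0 / (1.0 + math.exp((V + 68.0) / 5.5))
    tauh = 1.0 + 15.0 / (1.0 + math.exp((V + 55.0) / 7.0))

    # --- inward rectifier
    x1 = 1.0 / (1.0 + math.exp((V - ek - 15.0) / 10.0))
    ik1 = p[1] * x1 * (V - ek)

    # --- rapid delayed rectifier (gated activation, instantaneous rectification)
    rkr = 1.0 / (1.0 + math.exp((V + 15.0) / 22.0))
    ikr = p[2] * xr * rkr * (V - ek)
    xrinf = 1.0 / (1.0 + math.exp(-(V + 20.0) / 7.0))
    tauxr = 150.0 + 400.0 * math.exp(-((V + 35.0) / 25.0) ** 2)

    # --- slow delayed rectifier, transient outward (quasi-steady activation)
    xsinf = 1.0 / (1.0 + math.exp(-(V - 5.0) / 14.0))
    iks = p[3] * xsinf * (V - ek)
    rto = 1.0 / (1.0 + math.exp(-(V - 10.0) / 9.0))
    ito = p[4] * rto * (V - ek)

    # --- L-type Ca2+ current with Ca-dependent inactivation
    d = 1.0 / (1.0 + math.exp(-(V + 25.0) / 8.0))
    fca = 1.0 / (1.0 + (cai / 1.5) ** 2)
    scao = 2.0 * cao / (cao + 1.8)
    ical = p[5] * d * f * fca * (V - 80.0) * scao
    finf = 1.0 / (1.0 + math.exp((V + 30.0) / 4.5))
    tauf = 40.0 + 400.0 * math.exp(-((V + 30.0) / 30.0) ** 2)

    # --- Na+/Ca2+ exchanger (reduced Luo-Rudy form)
    e1 = math.exp(0.35 * V / RTF)
    e2 = math.exp(-0.65 * V / RTF)
    num = nai * nai * nai * cao * e1 - nao * nao * nao * cai_mm * e2
    den = (60.0 ** 3 + nao ** 3) * (1.38 + cao) * (1.0 + 0.1 * e2)
    incx = p[6] * num / den

    # --- Na+/K+ pump
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RTF) + 0.0353 * math.exp(-V / RTF))
    inak = p[7] * fnak * (ko / (ko + 1.5)) * (nai / (nai + 10.0))

    # --- sarcolemmal Ca pump, backgrounds
    ipca = p[8] * cai / (cai + 0.5)
    ibna = p[9] * (V - ena)
    ibca = p[10] * (V - eca)

    # --- pacemaker ("funny") current: slow activation gate gives the
    # diastolic-depolarization hysteresis; paced fixture has Gf = 0
    yfinf = 1.0 / (1.0 + math.exp((V + 64.0) / 4.0))
    i_f = p[18] * yf * (V - p[19])

    # --- SR Ca handling (fluxes in uM/ms, per cytosolic volume)
    jrel = p[11] * d * f * (casr - cai)
    jup = p[12] * cai * cai / (cai * cai + 0.25 * 0.25)
    jleak = 2.0e-5 * (casr - cai)

    itot = ina + ik1 + ikr + iks + ito + ical + incx + inak + ipca + ibna + ibca + i_f

    dy[0] = -itot + istim
    dy[1] = (hinf - h) / tauh
    dy[2] = (xrinf - xr) / tauxr
    dy[3] = (finf - f) / tauf
    # current -> flux conversion: 5 uM per (uA/uF)*ms, effective (buffered) volume
    dy[4] = -5.0e-3 * (ical + ibca + ipca - 2.0 * incx) * 1.0 + (jrel + jleak - jup)
    dy[5] = 15.0 * (jup - jleak - jrel)
    tauyf = 150.0 + 1350.0 * yfinf  # slow activation, fast deactivation
    dy[6] = (yfinf - yf) / tauyf
    return dy[0]


# Dormand-Prince 5(4) coefficients
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def _segment(p, y, t0, t1, istim, rtol, atol, t_out, v_out, ca_out, i_next, k1):
    """Integrate one constant-stimulus segment [t0, t1], writing dense output.

    Returns (ok, i_next). k1 holds the RHS at the current state on entry and
    exit (FSAL).
    """
    n = NSTATE
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    ytmp = np.empty(n)
    ynew = np.empty(n)
    yerr = np.empty(n)

    t = t0
    dt = min(0.05, t1 - t0)
    fixture_rhs(t, y, p, istim, k1)
    nout = t_out.shape[0]

    while t < t1 - 1e-12:
        if dt < 1e-10:
            return False, i_next
        if t + dt > t1:
            dt = t1 - t

        for i in range(n):
            ytmp[i] = y[i] + dt * _A21 * k1[i]
        fixture_rhs(t, ytmp, p, istim, k2)
        for i in range(n):
            ytmp[i] = y[i] + dt * (_A31 * k1[i] + _A32 * k2[i])
        fixture_rhs(t, ytmp, p, istim, k3)
        for i in range(n):
            ytmp[i] = y[i] + dt * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        fixture_rhs(t, ytmp, p, istim, k4)
        for i in range(n):
            ytmp[i] = y[i] + dt * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        fixture_rhs(t, ytmp, p, istim, k5)
        for i in range(n):
            ytmp[i] = y[i] + dt * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i] + _A64 * k4[i] + _A65 * k5[i]
            )
        fixture_rhs(t, ytmp, p, istim, k6)
        for i in range(n):
            ynew[i] = y[i] + dt * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i]
            )
        fixture_rhs(t + dt, ynew, p, istim, k7)

        errnorm = 0.0
        for i in range(n):
            yerr[i] = dt * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = yerr[i] / sc
            errnorm += e * e
        errnorm = math.sqrt(errnorm / n)

        if errnorm <= 1.0 or dt <= 1e-9:
            # accept; dense output via cubic Hermite on [t, t+dt]
            while i_next < nout and t_out[i_next] <= t + dt + 1e-12:
                s = (t_out[i_next] - t) / dt
                h00 = (1.0 + 2.0 * s) * (1.0 - s) * (1.0 - s)
                h10 = s * (1.0 - s) * (1.0 - s)
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                v_out[i_next] = h00 * y[0] + h10 * dt * k1[0] + h01 * ynew[0] + h11 * dt * k7[0]
                ca_out[i_next] = h00 * y[4] + h10 * dt * k1[4] + h01 * ynew[4] + h11 * dt * k7[4]
                i_next += 1
            t = t + dt
            for i in range(n):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            if errnorm == 0.0:
                fac = 5.0
            else:
                fac = min(5.0, max(0.2, 0.9 * errnorm ** -0.2))
            dt = dt * fac
        else:
            dt = dt * max(0.2, 0.9 * errnorm ** -0.2)
    return True, i_next


@njit(cache=True)
def integrate_fixture(p, y0, t_end, stim_starts, stim_dur, stim_amp, dt_out, rtol, atol):
    """Integrate the fixture model over [0, t_end] ms.

    stim_starts: sorted stimulus onset times (empty array = no stimulus).
    Returns (t_out, v_out, ca_out, y_final, ok).
    """
    nout = int(round(t_end / dt_out)) + 1
    t_out = np.empty(nout)
    for i in range(nout):
        t_out[i] = i * dt_out
    v_out = np.empty(nout)
    ca_out = np.empty(nout)

    y = y0.copy()
    k1 = np.empty(NSTATE)

    # build segment boundaries: stimulus on/off edges + t_end
    nseg = 2 * stim_starts.shape[0] + 1
    edges = np.empty(nseg + 1)
    edges[0] = 0.0
    j = 1
    for i in range(stim_starts.shape[0]):
        s = stim_starts[i]
        if s >= t_end:
            break
        edges[j] = s
        edges[j + 1] = min(s + stim_dur, t_end)
        j += 2
    edges[j] = t_end
    nedge = j + 1

    i_next = 0
    ok = True
    for seg in range(nedge - 1):
        a = edges[seg]
        b = edges[seg + 1]
        if b - a < 1e-9:
            continue
        # stimulus active on [start, start+dur) segments, i.e. odd segments
        amp = 0.0
        for i in range(stim_starts.shape[0]):
            if stim_starts[i] <= a + 1e-9 and a < stim_starts[i] + stim_dur - 1e-9:
                amp = stim_amp
                break
        ok, i_next = _segment(p, y, a, b, amp, rtol, atol, t_out, v_out, ca_out, i_next, k1)
        if not ok:
            break
    # fill any trailing samples (failed runs)
    while i_next < nout:
        v_out[i_next] = y[0]
        ca_out[i_next] = y[4]
        i_next += 1
    return t_out, v_out, ca_out, y, ok
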