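"""Numba fixed-step exponential-Euler kernel for current-clamp integration.

The neuron is flattened into plain float/int arrays (one row per channel;
up to two parallel activation and two parallel inactivation components per
channel).  Voltage uses a semi-implicit update — conductances evaluated at
the current state, the voltage solved implicitly against them — which is
unconditionally stable for passive dynamics; gates relax exactly for the
voltage frozen over one substep.  Units: mV, ms, pA, nS, pF.
"""

import numpy as np
from numba import njit

MAX_COMPONENTS = 2


@njit(cache=True)
def _tau_eval(tau_row, V):
    # tau_row = (tau_min, tau_max_or_-1, V_peak, width)
    if tau_row[1] < 0.0:
        return tau_row[0]
    z = (V - tau_row[2]) / tau_row[3]
    return tau_row[0] + (tau_row[1] - tau_row[0]) * np.exp(-z * z)


@njit(cache=True)
def integrate_cc(
    stim,          # (n, ncomp) pA, zero-order hold per sample
    bias,          # (ncomp,) pA
    substeps,      # int
    dt_ms,         # substep, ms
    V,             # (ncomp,) initial, modified in place
    C_pF,          # (ncomp,)
    gc_nS,         # float coupling
    comp,          # (nch,) int compartment index
    g,             # (nch,) nS
    E,             # (nch,) mV
    p,             # (nch,) int activation exponent
    na, aVh, ak, atau, afrac,   # activation: (nch,), (nch,2), (nch,2), (nch,2,4), (nch,2)
    nh, hVh, hk, htau, hfrac,   # inactivation, same shapes
    a_state, h_state,           # (nch,2) gate states, modified in place
    v_out,         # (n, ncomp) output
):
    n = stim.shape[0]
    ncomp = V.shape[0]
    nch = g.shape[0]
    G = np.zeros(ncomp)
    S = np.zeros(ncomp)
    Vnew = np.zeros(ncomp)
    # constant-tau gates relax with a fixed per-substep factor: hoist it
    a_decay = np.full((nch, 2), -1.0)
    h_decay = np.full((nch, 2), -1.0)
    for ich in range(nch):
        for j in range(na[ich]):
            if atau[ich, j, 1] < 0.0:
                a_decay[ich, j] = 1.0 - np.exp(-dt_ms / atau[ich, j, 0])
        for j in range(nh[ich]):
            if htau[ich, j, 1] < 0.0:
                h_decay[ich, j] = 1.0 - np.exp(-dt_ms / htau[ich, j, 0])
    for i in range(n):
        for c in range(ncomp):
            v_out[i, c] = V[c]
        for _ in range(substeps):
            # gate relaxation (exact for frozen V)
            for ich in range(nch):
                Vc = V[comp[ich]]
                for j in range(na[ich]):
                    xinf = 1.0 / (1.0 + np.exp(-(Vc - aVh[ich, j]) / ak[ich, j]))
                    if a_decay[ich, j] >= 0.0:
                        dec = a_decay[ich, j]
                    else:
                        tau = _tau_eval(atau[ich, j], Vc)
                        dec = 1.0 - np.exp(-dt_ms / tau)
                    a_state[ich, j] += (xinf - a_state[ich, j]) * dec
                for j in range(nh[ich]):
                    xinf = 1.0 / (1.0 + np.exp(-(Vc - hVh[ich, j]) / hk[ich, j]))
                    if h_decay[ich, j] >= 0.0:
                        dec = h_decay[ich, j]
                    else:
                        tau = _tau_eval(htau[ich, j], Vc)
                        dec = 1.0 - np.exp(-dt_ms / tau)
                    h_state[ich, j] += (xinf - h_state[ich, j]) * dec
            # conductance totals
            for c in range(ncomp):
                G[c] = 0.0
                S[c] = 0.0
            for ich in range(nch):
                if na[ich] == 0:
                    A = 1.0
                elif na[ich] == 1:
                    A = a_state[ich, 0]
                    for _k in range(p[ich] - 1):
                        A *= a_state[ich, 0]
                else:
                    A = afrac[ich, 0] * a_state[ich, 0] + afrac[ich, 1] * a_state[ich, 1]
                if nh[ich] == 0:
                    H = 1.0
                elif nh[ich] == 1:
                    H = h_state[ich, 0]
                else:
                    H = hfrac[ich, 0] * h_state[ich, 0] + hfrac[ich, 1] * h_state[ich, 1]
                go = g[ich] * A * H
                c = comp[ich]
                G[c] += go
                S[c] += go * E[ich]
            # semi-implicit voltage update
            for c in range(ncomp):
                dtC = dt_ms / C_pF[c]
                if ncomp == 2:
                    other = 1 - c
                    denom = 1.0 + dtC * (G[c] + gc_nS)
                    Vnew[c] = (
                        V[c] + dtC * (S[c] + stim[i, c] + bias[c] + gc_nS * V[other])
                    ) / denom
                else:
                    denom = 1.0 + dtC * G[c]
                    Vnew[c] = (V[c] + dtC * (S[c] + stim[i, c] + bias[c])) / denom
            for c in range(ncomp):
                V[c] = Vnew[c]
                if np.abs(V[c]) > 200.0:
                    return i
    return -1
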