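"""Numba-compiled fixed-step RK4 integrators for the coupled-column model.

The kernels are deliberately free of ``fastmath`` so that floating-point
evaluation order is fixed: the decoupling contract (a double column with
K1 = K2 = 0 reproduces two isolated single columns bit-identically) relies
on ``x + 0.0 == x`` not being reassociated away.
"""

import numpy as np
from numba import njit

__all__ = ["rk4_double_column", "rk4_single_column"]


@njit(cache=True)
def _sigm(v, e0, v0, r):
    # 2*e0 * logistic(r*(v - v0)); overflow-safe for large |v|
    x = r * (v - v0)
    if x >= 0.0:
        return 2.0 * e0 / (1.0 + np.exp(-x))
    z = np.exp(x)
    return 2.0 * e0 * z / (1.0 + z)


@njit(cache=True)
def rk4_double_column(params, p, pp, dt, c1, c2, n_burn):
    """Integrate a batch of coupled double columns driven by shared inputs.

    params : (Q, 4) array of (C1, C2, K1, K2)
    p, pp  : (n,) drive of column 1 / column 2, held constant over each step
    c1, c2 : (8,) physiological constants (A, B, a, b, e0, v0, r, a_d) per column
    n_burn : leading samples integrated but not returned

    Returns (u, ok): u is (Q, 2, n - n_burn) pyramidal potentials, ok is a
    (Q,) boolean mask, False where the trajectory left the finite range.

    State layout per column: [y0, y1, y2, y6, y3, y4, y5, y7] where (y0,y3)
    is the excitatory-feedback PSP block, (y1,y4) the input block, (y2,y5)
    the inhibitory block and (y6,y7) the inter-column delay block.
    """
    Q = params.shape[0]
    n = p.shape[0]
    u = np.empty((Q, 2, n - n_burn))
    ok = np.ones(Q, np.bool_)
    A1, B1, a1, b1, e01, v01, r1, ad1 = c1[0], c1[1], c1[2], c1[3], c1[4], c1[5], c1[6], c1[7]
    A2, B2, a2, b2, e02, v02, r2, ad2 = c2[0], c2[1], c2[2], c2[3], c2[4], c2[5], c2[6], c2[7]
    yq = np.empty(16)
    ytmp = np.empty(16)
    k = np.empty(16)
    acc = np.empty(16)
    for q in range(Q):
        C1 = params[q, 0]
        C2 = params[q, 1]
        K1 = params[q, 2]
        K2 = params[q, 3]
        # intra-column synapse counts derived from the column's global C
        e11, e21, i11, i21 = C1, 0.8 * C1, 0.25 * C1, 0.25 * C1
        e12, e22, i12, i22 = C2, 0.8 * C2, 0.25 * C2, 0.25 * C2
        for i in range(16):
            yq[i] = 0.0
        for t in range(n):
            pv = p[t]
            ppv = pp[t]
            for st in range(4):
                if st == 0:
                    for i in range(16):
                        ytmp[i] = yq[i]
                elif st == 3:
                    for i in range(16):
                        ytmp[i] = yq[i] + dt * k[i]
                else:
                    for i in range(16):
                        ytmp[i] = yq[i] + 0.5 * dt * k[i]
                s_pyr1 = _sigm(ytmp[1] - ytmp[2], e01, v01, r1)
                s_exc1 = _sigm(e11 * ytmp[0], e01, v01, r1)
                s_inh1 = _sigm(i11 * ytmp[0], e01, v01, r1)
                s_pyr2 = _sigm(ytmp[9] - ytmp[10], e02, v02, r2)
                s_exc2 = _sigm(e12 * ytmp[8], e02, v02, r2)
                s_inh2 = _sigm(i12 * ytmp[8], e02, v02, r2)
                # column 1; K2 couples the delayed pyramidal output of column 2
                k[0] = ytmp[4]
                k[4] = A1 * a1 * s_pyr1 - 2.0 * a1 * ytmp[4] - a1 * a1 * ytmp[0]
                k[1] = ytmp[5]
                k[5] = A1 * a1 * (pv + e21 * s_exc1 + K2 * ytmp[11]) - 2.0 * a1 * ytmp[5] - a1 * a1 * ytmp[1]
                k[2] = ytmp[6]
                k[6] = B1 * b1 * (i21 * s_inh1) - 2.0 * b1 * ytmp[6] - b1 * b1 * ytmp[2]
                k[3] = ytmp[7]
                k[7] = A1 * ad1 * s_pyr1 - 2.0 * ad1 * ytmp[7] - ad1 * ad1 * ytmp[3]
                # column 2; K1 couples the delayed pyramidal output of column 1
                k[8] = ytmp[12]
                k[12] = A2 * a2 * s_pyr2 - 2.0 * a2 * ytmp[12] - a2 * a2 * ytmp[8]
                k[9] = ytmp[13]
                k[13] = A2 * a2 * (ppv + e22 * s_exc2 + K1 * ytmp[3]) - 2.0 * a2 * ytmp[13] - a2 * a2 * ytmp[9]
                k[10] = ytmp[14]
                k[14] = B2 * b2 * (i22 * s_inh2) - 2.0 * b2 * ytmp[14] - b2 * b2 * ytmp[10]
                k[11] = ytmp[15]
                k[15] = A2 * ad2 * s_pyr2 - 2.0 * ad2 * ytmp[15] - ad2 * ad2 * ytmp[11]
                if st == 0:
                    for i in range(16):
                        acc[i] = k[i]
                elif st == 3:
                    for i in range(16):
                        acc[i] += k[i]
                else:
                    for i in range(16):
                        acc[i] += 2.0 * k[i]
            for i in range(16):
                yq[i] = yq[i] + (dt / 6.0) * acc[i]
            if t >= n_burn:
                u[q, 0, t - n_burn] = yq[1] - yq[2]
                u[q, 1, t - n_burn] = yq[9] - yq[10]
        for i in range(16):
            if not (np.abs(yq[i]) < 1e12):  # catches inf and NaN
                ok[q] = False
    return u, ok


@njit(cache=True)
def rk4_single_column(C, p, dt, c1, n_burn):
    """Integrate one isolated column (6 states); same discretisation as the
    double-column kernel so that the decoupled comparison is exact."""
    n = p.shape[0]
    A1, B1, a1, b1, e01, v01, r1 = c1[0], c1[1], c1[2], c1[3], c1[4], c1[5], c1[6]
    e11, e21, i11, i21 = C, 0.8 * C, 0.25 * C, 0.25 * C
    u = np.empty(n - n_burn)
    yq = np.zeros(6)
    ytmp = np.empty(6)
    k = np.empty(6)
    acc = np.empty(6)
    ok = True
    for t in range(n):
        pv = p[t]
        for st in range(4):
            if st == 0:
                for i in range(6):
                    ytmp[i] = yq[i]
            elif st == 3:
                for i in range(6):
                    ytmp[i] = yq[i] + dt * k[i]
            else:
                for i in range(6):
                    ytmp[i] = yq[i] + 0.5 * dt * k[i]
            s_pyr = _sigm(ytmp[1] - ytmp[2], e01, v01, r1)
            s_exc = _sigm(e11 * ytmp[0], e01, v01, r1)
            s_inh = _sigm(i11 * ytmp[0], e01, v01, r1)
            k[0] = ytmp[3]
            k[3] = A1 * a1 * s_pyr - 2.0 * a1 * ytmp[3] - a1 * a1 * ytmp[0]
            k[1] = ytmp[4]
            k[4] = A1 * a1 * (pv + e21 * s_exc + 0.0 * 0.0) - 2.0 * a1 * ytmp[4] - a1 * a1 * ytmp[1]
            k[2] = ytmp[5]
            k[5] = B1 * b1 * (i21 * s_inh) - 2.0 * b1 * ytmp[5] - b1 * b1 * ytmp[2]
            if st == 0:
                for i in range(6):
                    acc[i] = k[i]
            elif st == 3:
                for i in range(6):
                    acc[i] += k[i]
            else:
                for i in range(6):
                    acc[i] += 2.0 * k[i]
        for i in range(6):
            yq[i] = yq[i] + (dt / 6.0) * acc[i]
        if t >= n_burn:
            u[t - n_burn] = yq[1] - yq[2]
    for i in range(6):
        if not (np.abs(yq[i]) < 1e12):
            ok = False
    return u, ok
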