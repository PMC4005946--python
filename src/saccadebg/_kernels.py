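"""Fused numerical kernel for the per-millisecond map updates.

The model's seven retinotopic sheets (SCs, SCi, collicular thalamus, motor,
FEF input/output, FEF thalamus) are updated elementwise from the previous
step's values.  Doing this through one jit-compiled pass keeps the hot loop
memory-bound instead of dispatch-bound.  The formulas here mirror, exactly,
the modular implementations in :mod:`saccadebg.loops` and
:mod:`saccadebg.colliculus`; the test-suite asserts the two paths agree to
floating-point accuracy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fused_map_step"]


@njit(cache=True)
def fused_map_step(scs, sci, th_sc, motor,
                   fef_in, fef_out, th_fef,
                   retina, fefvis, v4_out, dmap,
                   vec_x, vec_y,
                   gate_sc, gate_sci, gate_fef, trn_sc, trn_fef, sat, opn, gpi_rest,
                   p):
    """One synchronous update of all map structures (flattened arrays).

    ``p`` packs the gain parameters (see model for layout).  Returns
    (motor_sum, burst_x, burst_y, th_sc_prev copy is NOT returned --
    learning reads th_sc before calling).
    """
    (dt, tau, tau_scs, tau_motor,
     w_scs_sci, w_fef_sci, w_v4_sci, w_sci_in, w_bgamp,
     w_sciout_th, w_gpi_th_sc, w_trn_th_sc, i_th_sc,
     w_bginhib, w_sat_mot, w_opn_mot,
     w_fefin_fefout, w_th_fefout, w_fefout_th, w_gpi_th_fef,
     w_trn_th_fef, i_th_fef, w_sat_stop, tau_fef) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19],
        p[20], p[21], p[22], p[23])

    sat_fac = 1.0 - w_sat_mot * sat
    if sat_fac < 0.0:
        sat_fac = 0.0
    opn_term = w_opn_mot * opn + w_sat_stop * sat * sat
    k1 = dt / tau
    k_fef = dt / tau_fef
    k_scs = dt / tau_scs
    k_mot = dt / tau_motor

    motor_sum = 0.0
    bx = 0.0
    by = 0.0
    th_sc_max = 0.0
    th_fef_max = 0.0
    fef_in_max = 0.0
    n = scs.shape[0]
    for i in range(n):
        scs_p = scs[i]
        sci_p = sci[i]
        th_sc_p = th_sc[i]
        mot_p = motor[i]
        fin_p = fef_in[i]
        fout_p = fef_out[i]
        th_f_p = th_fef[i]
        d = dmap[i]

        # superficial colliculus: delayed retina, saccade-gated
        x = scs_p + k_scs * (retina[i] * gate_sc - scs_p)
        scs[i] = min(max(x, 0.0), 1.0)

        # deep colliculus: weighted afferents x BG amplification x gate
        aff = (w_scs_sci * scs_p + w_fef_sci * fout_p
               + w_v4_sci * v4_out[i])
        amp = w_sci_in + w_bgamp * d
        x = sci_p + k1 * (aff * amp * gate_sci - sci_p)
        sci[i] = min(max(x, 0.0), 1.0)

        # collicular thalamus
        dth = (sci_p * (w_sciout_th + w_gpi_th_sc * d)
               - w_trn_th_sc * trn_sc + i_th_sc)
        x = th_sc_p + k1 * (dth - th_sc_p)
        x = min(max(x, 0.0), 1.0)
        th_sc[i] = x
        if x > th_sc_max:
            th_sc_max = x

        # motor map: multiplicative SNr and Sat gating, OPN veto
        snr = gpi_rest * (1.0 - d)
        dmot = sci_p * (1.0 - w_bginhib * snr) * sat_fac - opn_term
        x = mot_p + k_mot * (dmot - mot_p)
        x = min(max(x, 0.0), 1.0)
        motor[i] = x
        motor_sum += x
        bx += x * vec_x[i]
        by += x * vec_y[i]

        # FEF input and output maps
        x = fin_p + k_fef * (fefvis[i] * gate_fef - fin_p)
        x = min(max(x, 0.0), 1.0)
        fef_in[i] = x
        if x > fef_in_max:
            fef_in_max = x
        dout = w_fefin_fefout * fin_p * gate_fef + w_th_fefout * th_f_p
        x = fout_p + k_fef * (dout - fout_p)
        fef_out[i] = min(max(x, 0.0), 1.0)

        # FEF thalamus
        dthf = (fout_p * (w_fefout_th + w_gpi_th_fef * d)
                - w_trn_th_fef * trn_fef + i_th_fef)
        x = th_f_p + k_fef * (dthf - th_f_p)
        x = min(max(x, 0.0), 1.0)
        th_fef[i] = x
        if x > th_fef_max:
            th_fef_max = x

    return motor_sum, bx, by, th_sc_max, th_fef_max, fef_in_max
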