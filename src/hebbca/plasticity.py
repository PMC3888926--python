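"""Discretised Hebbian LTP/LTD rule for excitatory synapses.

The rule follows the Artola-Broecher-Singer scheme with two fixed
efficacy steps: a synapse from cell x to cell y is potentiated by
``delta_w`` when the presynaptic output is at least ``theta_pre`` and the
postsynaptic potential is at least ``theta_plus``; it is depressed by
``delta_w`` when the presynaptic side is active but the postsynaptic
potential sits in the LTD band [``theta_minus``, ``theta_plus``)
(homosynaptic LTD), or when the presynaptic side is inactive while the
postsynaptic potential is at or above ``theta_plus`` (heterosynaptic
LTD).  Otherwise the weight is unchanged.  Weights are clipped to
[0, w_max]; saturation at the ceiling is what stabilises mature cell
assemblies.
"""

from __future__ import annotations

import numpy as np

from .config import PlasticityParams


def hebbian_update(w, O_pre, V_post, params: PlasticityParams):
    """Apply one step of the LTP/LTD rule to weight(s) ``w``.

    Accepts scalars or broadcastable arrays; returns the new weight(s),
    clipped to ``[0, params.w_max]``.  The postsynaptic variable is the
    membrane potential, not the output.
    """
    w = np.asarray(w, dtype=float)
    O_pre = np.asarray(O_pre, dtype=float)
    V_post = np.asarray(V_post, dtype=float)
    pre_on = O_pre >= params.theta_pre
    post_hi = V_post >= params.theta_plus
    post_mid = (V_post >= params.theta_minus) & ~post_hi
    ltp = pre_on & post_hi
    ltd = (pre_on & post_mid) | (~pre_on & post_hi)
    delta = params.delta_w * (ltp.astype(float) - ltd.astype(float))
    return np.clip(w + delta, 0.0, params.w_max)


def apply_plasticity_edges(
    w_data: np.ndarray,
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    O_exc: np.ndarray,
    V_exc: np.ndarray,
    params: PlasticityParams,
) -> None:
    """In-place Hebbian update of every excitatory->excitatory edge.

    ``w_data`` is the weight array aligned with ``(pre_idx, post_idx)``
    (within- and between-area links alike; inhibitory wiring is never
    touched).  Uses the current presynaptic outputs and postsynaptic
    membrane potentials.
    """
    if not params.enabled:
        return
    # cheap global gate: LTP needs an active presynaptic cell, both LTD
    # branches need either an active presynaptic cell in the LTD band or a
    # depolarised postsynaptic cell -- if no cell fires above theta_pre
    # and none is depolarised past theta_plus, no weight can change.
    if O_exc.max() < params.theta_pre and V_exc.max() < params.theta_plus:
        return
    o = O_exc[pre_idx]
    v = V_exc[post_idx]
    pre_on = o >= params.theta_pre
    post_hi = v >= params.theta_plus
    ltp = pre_on & post_hi
    ltd = (pre_on & (v >= params.theta_minus) & ~post_hi) | (~pre_on & post_hi)
    w_data += params.delta_w * ltp
    w_data -= params.delta_w * ltd
    np.clip(w_data, 0.0, params.w_max, out=w_data)
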