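"""Numba-compiled inner loops for the cortical branching model.

The automaton state is encoded per node in a single int8 ``phase``:

* 0            quiescent (eligible for activation)
* 1            active this time step
* k >= 2       refractory with k - 1 steps remaining

One update t -> t+1 proceeds as: (i) collect nodes active at t, (ii) decay
phases (active -> refractory(tau_r), refractory counts down, the last
refractory step returns to quiescent), (iii) driven transmission from the
collected active set along out-edges, (iv) spontaneous activation of still
quiescent nodes with probability p_s.  A node active at t therefore cannot
be active again before t + tau_r + 1.  Transmission uses ``rand() <= P_ij``
with edge draws consumed in ascending source-node order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_counts", "run_raster", "seeded_avalanche_sizes"]


@njit(cache=False)
def _step_inplace(phase, prev_active, n_prev, out_ptr, out_tgt, out_w, p_s, tau_r):
    n = phase.shape[0]
    # decay: active -> refractory, refractory counts down
    for i in range(n):
        p = phase[i]
        if p == 1:
            phase[i] = tau_r + 1 if tau_r > 0 else 0
        elif p == 2:
            phase[i] = 0
        elif p > 2:
            phase[i] = p - 1
    # driven transmission from nodes active at t
    n_new = 0
    for a in range(n_prev):
        i = prev_active[a]
        for e in range(out_ptr[i], out_ptr[i + 1]):
            j = out_tgt[e]
            if phase[j] == 0 and np.random.random() <= out_w[e]:
                phase[j] = 1
                n_new += 1
    # spontaneous activation of remaining quiescent nodes
    if p_s > 0.0:
        for j in range(n):
            if phase[j] == 0 and np.random.random() <= p_s:
                phase[j] = 1
                n_new += 1
    return n_new


@njit(cache=False)
def run_counts(out_ptr, out_tgt, out_w, n_nodes, p_s, tau_r, n_steps, seed, init_phase):
    """Run the automaton, returning the per-step number of active nodes.

    ``init_phase`` is the phase vector at t=0 (modified in place so chunked
    runs can resume).  The returned array has length ``n_steps`` and entry t
    is the active count at step t+1.
    """
    np.random.seed(seed)
    phase = init_phase
    counts = np.zeros(n_steps, dtype=np.int32)
    active = np.empty(n_nodes, dtype=np.int32)
    for t in range(n_steps):
        n_act = 0
        for i in range(n_nodes):
            if phase[i] == 1:
                active[n_act] = i
                n_act += 1
        counts[t] = _step_inplace(
            phase, active, n_act, out_ptr, out_tgt, out_w, p_s, tau_r
        )
    return counts


@njit(cache=False)
def run_raster(out_ptr, out_tgt, out_w, n_nodes, p_s, tau_r, n_steps, seed, init_phase):
    """Like :func:`run_counts` but records the full binary node x time raster."""
    np.random.seed(seed)
    phase = init_phase
    raster = np.zeros((n_nodes, n_steps), dtype=np.uint8)
    active = np.empty(n_nodes, dtype=np.int32)
    for t in range(n_steps):
        n_act = 0
        for i in range(n_nodes):
            if phase[i] == 1:
                active[n_act] = i
                n_act += 1
        _step_inplace(phase, active, n_act, out_ptr, out_tgt, out_w, p_s, tau_r)
        for i in range(n_nodes):
            if phase[i] == 1:
                raster[i, t] = 1
    return raster


@njit(cache=False)
def seeded_avalanche_sizes(
    out_ptr, out_tgt, out_w, n_nodes, tau_r, n_avalanches, max_steps, seed
):
    """Sizes of avalanches seeded from single random nodes with p_s = 0.

    Each trial activates one uniformly chosen node in an otherwise quiescent
    network and runs until activity dies out (or ``max_steps``).  Returns the
    total number of activations per trial, the branching-process total
    progeny.
    """
    np.random.seed(seed)
    sizes = np.empty(n_avalanches, dtype=np.int64)
    phase = np.zeros(n_nodes, dtype=np.int8)
    active = np.empty(n_nodes, dtype=np.int32)
    for trial in range(n_avalanches):
        for i in range(n_nodes):
            phase[i] = 0
        seed_node = np.random.randint(0, n_nodes)
        phase[seed_node] = 1
        size = 1
        for _ in range(max_steps):
            n_act = 0
            for i in range(n_nodes):
                if phase[i] == 1:
                    active[n_act] = i
                    n_act += 1
            if n_act == 0:
                break
            size += _step_inplace(
                phase, active, n_act, out_ptr, out_tgt, out_w, 0.0, tau_r
            )
        sizes[trial] = size
    return sizes
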