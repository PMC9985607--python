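"""Exact stochastic simulation (Gillespie direct method) of the network.

The stochastic process is the exact counterpart of the deterministic
mass-action model: unimolecular propensity ``k * a``, heterodimer
propensity ``(k / (V * N_A)) * a_i * a_j`` and homodimer propensity
``(2k / (V * N_A)) * a * (a - 1) / 2`` — the pair-counting form whose
large-copy-number limit reproduces the deterministic channel rate
``k * [A]**2`` with consumption ``2k * [A]**2``.  Conservation of target
and enzyme units is exact at every event because state changes are the
integer stoichiometries.

The inner loop is a numba kernel; copy numbers up to ~1e5 per trajectory
are practical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .network import AVOGADRO, RateParams, ReactionNetwork, TimeCourse, initial_state


@njit(cache=True)
def _ssa_kernel(state0, t_grid, kinds, ri, rj, c, stoich, seed):  # pragma: no cover
    np.random.seed(seed)
    n_rxn = len(kinds)
    n_t = len(t_grid)
    n_sp = len(state0)
    out = np.zeros((n_t, n_sp), dtype=np.int64)
    state = state0.copy()
    t = 0.0
    rec = 0
    props = np.zeros(n_rxn)
    while rec < n_t:
        total = 0.0
        for q in range(n_rxn):
            if kinds[q] == 0:
                p = c[q] * state[ri[q]]
            elif kinds[q] == 1:
                p = c[q] * state[ri[q]] * state[rj[q]]
            else:
                a = state[ri[q]]
                p = c[q] * a * (a - 1) / 2.0
            props[q] = p
            total += p
        if total <= 0.0:
            t = np.inf
        else:
            t += -np.log(np.random.random()) / total
        while rec < n_t and t_grid[rec] <= t:
            out[rec] = state
            rec += 1
        if rec >= n_t:
            break
        u = np.random.random() * total
        acc = 0.0
        q = 0
        for k in range(n_rxn):
            acc += props[k]
            if u <= acc:
                q = k
                break
        for s in range(n_sp):
            state[s] += stoich[q, s]
    return out


def simulate_stochastic(network: ReactionNetwork, params: RateParams,
                        c0: float, volume_L: float | None = None,
                        n_copies: int | None = None,
                        t_grid: np.ndarray | None = None,
                        t_max: float | None = None,
                        seed: int = 0) -> TimeCourse:
    """One exact-SSA trajectory, reported on ``t_grid`` (hours).

    Provide either ``volume_L`` (copy number derived from ``c0``) or
    ``n_copies`` (volume derived).  The returned concentrations are copy
    numbers divided by ``volume_L * N_A`` so the trajectory is directly
    comparable to the deterministic solution.
    """
    if (volume_L is None) == (n_copies is None):
        raise ValueError("give exactly one of volume_L or n_copies")
    if n_copies is not None:
        if n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        volume_L = n_copies / (AVOGADRO * c0)
    else:
        n_copies = int(round(c0 * volume_L * AVOGADRO))
        if n_copies < 1:
            raise ValueError("volume too small: fewer than one copy")
    if t_grid is None:
        if t_max is None:
            raise ValueError("give t_grid or t_max")
        t_grid = np.linspace(0.0, t_max, 51)
    t_grid = np.asarray(t_grid, dtype=float)

    y0 = initial_state(network, params, c0)
    scale = volume_L * AVOGADRO
    state0 = np.round(y0 * scale).astype(np.int64)

    kinds = np.empty(len(network.reactions), dtype=np.int8)
    ri = np.empty(len(network.reactions), dtype=np.int64)
    rj = np.empty(len(network.reactions), dtype=np.int64)
    c = np.empty(len(network.reactions))
    for q, rx in enumerate(network.reactions):
        ri[q], rj[q] = rx.ri, max(rx.rj, 0)
        if rx.kind == "uni":
            kinds[q], c[q] = 0, rx.k
        elif rx.kind == "bi":
            kinds[q], c[q] = 1, rx.k / scale
        else:  # homo: c = 2k/(V*NA), applied to a(a-1)/2 pairs
            kinds[q], c[q] = 2, 2.0 * rx.k / scale
    if network.reactions:
        stoich = np.stack([rx.stoich for rx in network.reactions]).astype(np.int64)
        counts = _ssa_kernel(state0, t_grid, kinds, ri, rj, c, stoich,
                             np.uint32(seed & 0x7FFFFFFF))
    else:  # no active channels: the state is constant for all t
        counts = np.tile(state0, (len(t_grid), 1))
    tc = TimeCourse(times=t_grid, species=network.species,
                    conc=counts.T / scale, c0=c0, params=params,
                    provenance="ssa", seed=seed, network=network)
    tc.meta["counts"] = counts.T          # integer copy numbers (exact)
    tc.meta["n_copies"] = n_copies
    tc.meta["volume_L"] = volume_L
    return tc


def mean_trajectories(network: ReactionNetwork, params: RateParams, c0: float,
                      n_copies: int, t_grid: np.ndarray, n_traj: int,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error over ``n_traj`` SSA trajectories.

    Returns arrays of shape (n_species, n_times).
    """
    acc = None
    acc2 = None
    for k in range(n_traj):
        tc = simulate_stochastic(network, params, c0, n_copies=n_copies,
                                 t_grid=t_grid, seed=seed + k)
        x = tc.conc
        acc = x.copy() if acc is None else acc + x
        acc2 = x ** 2 if acc2 is None else acc2 + x ** 2
    mean = acc / n_traj
    var = np.clip(acc2 / n_traj - mean ** 2, 0.0, None)
    se = np.sqrt(var / n_traj)
    return mean, se
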