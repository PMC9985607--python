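"""Mass-action model of the autocyclase reaction network.

The network tracks, for each number of target units n = 1..N:

* ``An`` — active autocyclase with n fused target units (a tandem
  autocyclase for n > 1), one sortase body attached;
* ``Tn`` — the thioester (acyl-enzyme) intermediate of ``An``
  (mechanistic mode only);
* ``Cn`` — the head-to-tail cyclic product with n target units;
* ``Ln`` — the hydrolysed linear product;
* ``E``  — free (released) sortase;
* ``Ainact`` — starting material whose enzyme is misfolded/inactive;
* ``leakU`` — target units lost to truncation (absorb policy only).

Lumped mode collapses recognition, acylation and nucleophilic attack into
three competing channels:

    An -> Cn + E            k_uni   (unimolecular cyclisation, 1/h)
    An + Am -> A(n+m) + E   k_bi    (tandem formation, 1/(M*h))
    An -> Ln + E            k_hyd   (hydrolysis, 1/h)

The homodimer channel An + An proceeds at rate ``k_bi*[An]**2`` per event
(one event consumes two An), so d[An]/dt receives ``-2*k_bi*[An]**2``.
Mechanistic mode inserts the explicit intermediate: An -> Tn (k_act),
Tn -> Cn + E (k_cyc), Tn + Am -> A(n+m) + E (k_poly), Tn -> Ln + E
(k_hyd), optionally Tn -> An (k_rev).

Every reaction conserves target units and enzyme units; the only
exception is the ``absorb`` truncation policy, whose over-cap events
route surplus target units into the explicit ``leakU`` pool so that the
conservation ledger still closes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class RateParams:
    """Kinetic constants of the reaction network.

    Lumped constants (``k_uni``, ``k_bi``, ``k_hyd``) parameterise the
    default three-channel competition; mechanistic constants (``k_act``,
    ``k_cyc``, ``k_poly``, ``k_rev``) are used only in mechanistic mode.
    ``f_inactive`` is the fraction of starting material that never reacts.
    ``km_M`` is the Michaelis constant of the sortase for its recognition
    site, consumed by the tethering model.  ``ring_scale`` optionally
    multiplies the cyclisation rate of order-n rings (default 1 for all n).
    """

    mode: str = "lumped"
    k_uni: float = 0.01          # 1/h
    k_bi: float = 130.0          # 1/(M h)
    k_hyd: float = 0.0           # 1/h
    k_act: float = 1.0           # 1/h
    k_cyc: float = 1.0           # 1/h
    k_poly: float = 1e4          # 1/(M h)
    k_rev: float = 0.0           # 1/h
    f_inactive: float = 0.0
    km_M: float | None = None
    ring_scale: tuple[tuple[int, float], ...] = ()

    def __post_init__(self):
        if self.mode not in ("lumped", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("k_uni", "k_bi", "k_hyd", "k_act", "k_cyc", "k_poly", "k_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.f_inactive < 1:
            raise ValueError("f_inactive must be in [0, 1)")

    def ring_multiplier(self, n: int) -> float:
        return dict(self.ring_scale).get(n, 1.0)


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel.

    ``kind`` is ``uni`` (rate k*[i]), ``bi`` (k*[i]*[j], i != j) or
    ``homo`` (channel rate k*[i]**2, each event consuming two i).
    ``stoich`` is the integer species-change vector per event.
    """

    name: str
    kind: str
    k: float
    ri: int
    rj: int
    stoich: np.ndarray


@dataclass(frozen=True)
class ReactionNetwork:
    max_order: int
    mode: str
    truncation_policy: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    target_units: np.ndarray      # target units carried by one copy of each species
    enzyme_units: np.ndarray

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def stoich_matrix(self) -> np.ndarray:
        if not self.reactions:
            return np.zeros((len(self.species), 0))
        return np.stack([r.stoich for r in self.reactions], axis=1)


def build_network(max_order: int, params: RateParams,
                  truncation_policy: str = "drop") -> ReactionNetwork:
    """Enumerate species and reactions up to the truncation order.

    Under ``policy="drop"`` any channel whose product would exceed the
    truncation order is removed from the network (no leak occurs); under
    ``policy="absorb"`` the product is routed to the order-N species and
    the surplus target units are booked into the ``leakU`` pool.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if truncation_policy not in ("drop", "absorb"):
        raise ValueError(f"unknown truncation policy {truncation_policy!r}")
    N = max_order
    mech = params.mode == "mechanistic"

    species: list[str] = [f"A{n}" for n in range(1, N + 1)]
    if mech:
        species += [f"T{n}" for n in range(1, N + 1)]
    species += [f"C{n}" for n in range(1, N + 1)]
    species += [f"L{n}" for n in range(1, N + 1)]
    species += ["E", "Ainact", "leakU"]
    idx = {s: i for i, s in enumerate(species)}
    n_sp = len(species)

    tunits = np.zeros(n_sp)
    eunits = np.zeros(n_sp)
    for n in range(1, N + 1):
        tunits[idx[f"A{n}"]] = n
        eunits[idx[f"A{n}"]] = 1
        if mech:
            tunits[idx[f"T{n}"]] = n
            eunits[idx[f"T{n}"]] = 1
        tunits[idx[f"C{n}"]] = n
        tunits[idx[f"L{n}"]] = n
    eunits[idx["E"]] = 1
    tunits[idx["Ainact"]] = 1
    eunits[idx["Ainact"]] = 1
    tunits[idx["leakU"]] = 1  # leak pool is booked directly in target units

    def vec(**changes: int) -> np.ndarray:
        s = np.zeros(n_sp, dtype=np.int64)
        for sp, d in changes.items():
            s[idx[sp]] += d
        return s

    rxns: list[Reaction] = []

    def add(name, kind, k, ri, rj, stoich):
        if k > 0:
            rxns.append(Reaction(name, kind, k, ri, rj, stoich))

    for n in range(1, N + 1):
        donor = f"T{n}" if mech else f"A{n}"
        k_cyc = (params.k_cyc if mech else params.k_uni) * params.ring_multiplier(n)
        add(f"{donor}->C{n}+E", "uni", k_cyc, idx[donor], -1,
            vec(**{donor: -1, f"C{n}": +1, "E": +1}))
        add(f"{donor}->L{n}+E", "uni", params.k_hyd, idx[donor], -1,
            vec(**{donor: -1, f"L{n}": +1, "E": +1}))
        if mech:
            add(f"A{n}->T{n}", "uni", params.k_act, idx[f"A{n}"], -1,
                vec(**{f"A{n}": -1, f"T{n}": +1}))
            add(f"T{n}->A{n}", "uni", params.k_rev, idx[f"T{n}"], -1,
                vec(**{f"T{n}": -1, f"A{n}": +1}))

    def product_stoich(n, m) -> np.ndarray | None:
        """Product-side stoichiometry for an order n+m adduct, or None to drop."""
        if n + m <= N:
            return vec(**{f"A{n + m}": +1, "E": +1})
        if truncation_policy == "drop":
            return None
        s = vec(**{f"A{N}": +1, "E": +1})
        s[idx["leakU"]] += n + m - N
        return s

    if mech:
        for n in range(1, N + 1):
            for m in range(1, N + 1):
                prod = product_stoich(n, m)
                if prod is None:
                    continue
                s = prod + vec(**{f"T{n}": -1, f"A{m}": -1})
                add(f"T{n}+A{m}->", "bi", params.k_poly,
                    idx[f"T{n}"], idx[f"A{m}"], s)
    else:
        for n in range(1, N + 1):
            for m in range(n, N + 1):
                prod = product_stoich(n, m)
                if prod is None:
                    continue
                if n == m:
                    s = prod + vec(**{f"A{n}": -2})
                    add(f"2A{n}->", "homo", params.k_bi, idx[f"A{n}"], -1, s)
                else:
                    s = prod + vec(**{f"A{n}": -1, f"A{m}": -1})
                    add(f"A{n}+A{m}->", "bi", params.k_bi,
                        idx[f"A{n}"], idx[f"A{m}"], s)

    return ReactionNetwork(
        max_order=N, mode=params.mode, truncation_policy=truncation_policy,
        species=tuple(species), reactions=tuple(rxns),
        target_units=tunits, enzyme_units=eunits,
    )


@dataclass
class TimeCourse:
    """Species concentrations (M) over time (h) for one run."""

    times: np.ndarray
    species: tuple[str, ...]
    conc: np.ndarray               # shape (n_species, n_times)
    c0: float
    params: RateParams
    provenance: str                # ode | ssa | synthetic
    seed: int | None = None
    network: ReactionNetwork | None = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, species_name: str) -> np.ndarray:
        return self.conc[self.species.index(species_name)]

    def conservation_errors(self) -> dict[str, float]:
        """Max relative drift of the target-unit and enzyme-unit ledgers."""
        if self.network is None:
            raise ValueError("time course carries no network")
        t_tot = self.network.target_units @ self.conc
        e_tot = self.network.enzyme_units @ self.conc
        return {
            "target_units": float(np.max(np.abs(t_tot - self.c0)) / self.c0),
            "enzyme_units": float(np.max(np.abs(e_tot - self.c0)) / self.c0),
        }

    def leak_fraction(self) -> float:
        """Fraction of target units in the truncation-leak pool at t_end."""
        if self.network is None or "leakU" not in self.species:
            return 0.0
        return float(self["leakU"][-1] / self.c0)

    def to_frame(self, replicate: int = 0):
        """Tidy DataFrame in the shared time-course CSV dialect."""
        import pandas as pd

        rows = []
        for i, sp in enumerate(self.species):
            for j, t in enumerate(self.times):
                rows.append((float(t), sp, float(self.conc[i, j]),
                             replicate, self.provenance))
        return pd.DataFrame(
            rows, columns=["time_h", "species", "conc_M", "replicate", "provenance"])


class SimulationError(RuntimeError):
    pass


def initial_state(network: ReactionNetwork, params: RateParams, c0: float) -> np.ndarray:
    if c0 <= 0:
        raise ValueError("C0 must be > 0")
    y0 = np.zeros(len(network.species))
    y0[network.index["A1"]] = c0 * (1.0 - params.f_inactive)
    y0[network.index["Ainact"]] = c0 * params.f_inactive
    return y0


def _rates(network: ReactionNetwork, y: np.ndarray) -> np.ndarray:
    r = np.empty(len(network.reactions))
    for q, rx in enumerate(network.reactions):
        if rx.kind == "uni":
            r[q] = rx.k * y[rx.ri]
        elif rx.kind == "bi":
            r[q] = rx.k * y[rx.ri] * y[rx.rj]
        else:  # homo
            r[q] = rx.k * y[rx.ri] * y[rx.ri]
    return r


def simulate_deterministic(network: ReactionNetwork, params: RateParams,
                           c0: float, t_grid: np.ndarray,
                           rtol: float = 1e-8, atol: float = 1e-14,
                           conservation_tol: float = 1e-6) -> TimeCourse:
    """Integrate the mass-action ODEs of the network on ``t_grid`` (hours).

    Uses a stiff-capable integrator (LSODA) at rtol 1e-8 / atol 1e-14 M.
    Raises :class:`SimulationError` on solver failure or if either
    conservation ledger drifts by more than ``conservation_tol`` relative.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with >= 2 points")
    y0 = initial_state(network, params, c0)
    S = network.stoich_matrix().astype(float)

    def rhs(_t, y):
        return S @ _rates(network, y)

    t0 = 0.0 if t_grid[0] > 0 else t_grid[0]
    sol = solve_ivp(rhs, (t0, t_grid[-1]), y0, t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"ODE integration failed: {sol.message}")
    conc = np.clip(sol.y, 0.0, None)
    tc = TimeCourse(times=t_grid, species=network.species, conc=conc,
                    c0=c0, params=params, provenance="ode", network=network)
    errs = tc.conservation_errors()
    if max(errs.values()) > conservation_tol:
        raise SimulationError(f"conservation violated beyond tolerance: {errs}")
    tc.meta["conservation"] = errs
    tc.meta["leak_fraction"] = tc.leak_fraction()
    return tc


def run_to_completion(network: ReactionNetwork, params: RateParams, c0: float,
                      unreacted_tol: float = 1e-4, t_max: float = 1e6,
                      n_points: int = 400) -> TimeCourse:
    """Integrate until the unreacted active pool falls below ``unreacted_tol``
    (as a fraction of C0), doubling the horizon as needed up to ``t_max``."""
    rate_floor = params.k_uni + params.k_hyd if params.mode == "lumped" \
        else min(params.k_act, params.k_cyc + params.k_hyd)
    if rate_floor <= 0:
        raise SimulationError("network has no first-order drain; cannot complete")
    t_end = 10.0 / rate_floor
    while True:
        t_grid = np.concatenate([[0.0], np.geomspace(t_end / 1e4, t_end, n_points)])
        tc = simulate_deterministic(network, params, c0, t_grid)
        active = [s for s in network.species if s[0] in "AT" and s != "Ainact"]
        pool = sum(network.target_units[network.index[s]] * tc[s][-1] for s in active)
        if pool / c0 <= unreacted_tol:
            return tc
        t_end *= 4
        if t_end > t_max:
            raise SimulationError("t_max reached before completion")


def product_fractions(tc: TimeCourse, unreacted_threshold: float | None = None
                      ) -> dict[str, float]:
    """Final split of C0 (in target units) over product classes.

    Returns fractions ``monomer_cyclic``, ``oligomer_cyclic``,
    ``hydrolysed``, ``unreacted`` (plus ``leak``); they sum to one up to
    the truncation leak.
    """
    if tc.network is None or tc.conc.size == 0:
        raise ValueError("empty time course or missing network")
    net = tc.network
    y = tc.conc[:, -1]
    idx = net.index
    mono = y[idx["C1"]] / tc.c0
    olig = sum(n * y[idx[f"C{n}"]] for n in range(2, net.max_order + 1)) / tc.c0
    hyd = sum(n * y[idx[f"L{n}"]] for n in range(1, net.max_order + 1)) / tc.c0
    unre = (sum(net.target_units[i] * y[i]
                for i, s in enumerate(net.species) if s[0] in "AT")
            ) / tc.c0
    leak = y[idx["leakU"]] / tc.c0
    if unreacted_threshold is not None:
        active = unre - y[idx["Ainact"]] / tc.c0
        if active > unreacted_threshold:
            raise ValueError(
                f"run not near completion: active fraction {active:.3g} > "
                f"{unreacted_threshold}")
    return {"monomer_cyclic": float(mono), "oligomer_cyclic": float(olig),
            "hydrolysed": float(hyd), "unreacted": float(unre),
            "leak": float(leak)}


def crossover_concentration(params: RateParams) -> float:
    """C* = k_uni / k_bi — the concentration at which the bimolecular
    channel rate equals the unimolecular one (lumped mode)."""
    if params.k_bi <= 0:
        return float("inf")
    return params.k_uni / params.k_bi
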