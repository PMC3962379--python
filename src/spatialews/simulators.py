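"""Stochastic spatial simulators of ecosystems approaching a tipping point.

Three classic model families generate the package's test data, each a
different route to an abrupt vegetation collapse and a different spatial
signature:

1. **Local positive feedback** (:func:`simulate_local_feedback`) — a
   lattice of coupled biomass/water cells.  Biomass grows logistically at
   a water-limited rate and is lost to saturating grazing; biomass and
   water diffuse between von Neumann neighbours; multiplicative noise
   forces the biomass field.  As rainfall drops below a threshold the
   whole lattice collapses nearly synchronously to a bare state.  Spatial
   structure is weak (no patchiness) — the data set for the generic
   indicators alone.

2. **Facilitation cellular automaton** (:func:`simulate_facilitation_ca`)
   — cells are vegetated (+), empty (0) or degraded (-).  Colonisation of
   empty cells mixes global and local seed supply; degraded cells
   regenerate at a rate boosted by vegetated neighbours (the local
   facilitation).  Clustered, scale-free patchiness emerges; increasing
   environmental harshness (decreasing establishment probability b) drives
   the vegetation to extinction.

3. **Scale-dependent feedback PDE model** (:func:`simulate_turing_pde`) —
   three coupled fields (plant biomass P, soil water W, surface water O).
   Vegetation enhances infiltration, concentrating water under patches and
   depleting it at distance: short-range activation with long-range
   inhibition, producing Turing patterns.  Decreasing rainfall moves the
   pattern through gaps -> labyrinth -> spots before desertification.

All simulators run on periodic lattices, are deterministic under a fixed
seed, and emit one snapshot per driver value after a relaxation period,
carrying the state across driver values (a slow ramp along the gradient).
Driver values are ordered *toward* the transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numba
import numpy as np

from .grid import GradientSequence, SpatialGrid

__all__ = [
    "SimConfig",
    "SimulationError",
    "simulate",
    "simulate_local_feedback",
    "simulate_facilitation_ca",
    "simulate_turing_pde",
    "LOCAL_FEEDBACK_DRIVERS",
    "FACILITATION_DRIVERS",
    "TURING_DRIVERS",
]


class SimulationError(RuntimeError):
    """Numerical instability or invalid parameterisation during a run."""


def _laplacian(x: np.ndarray) -> np.ndarray:
    """5-point Laplacian on a periodic lattice, dx = 1."""
    return (
        np.roll(x, 1, 0) + np.roll(x, -1, 0) + np.roll(x, 1, 1) + np.roll(x, -1, 1)
        - 4.0 * x
    )


def _neighbor_fraction(mask: np.ndarray) -> np.ndarray:
    """Fraction of the 4 von Neumann neighbours (periodic) that are True."""
    m = mask.astype(float)
    return (
        np.roll(m, 1, 0) + np.roll(m, -1, 0) + np.roll(m, 1, 1) + np.roll(m, -1, 1)
    ) / 4.0


# ---------------------------------------------------------------------------
# data set 1: local positive feedback lattice
# ---------------------------------------------------------------------------

#: Default rainfall gradient, denser near the collapse threshold.
LOCAL_FEEDBACK_DRIVERS: tuple[float, ...] = (
    1.2, 0.9, 0.72, 0.60, 0.53, 0.48, 0.45, 0.43, 0.415, 0.40,
)


def simulate_local_feedback(
    grid_size: int = 100,
    driver_values: Sequence[float] | None = None,
    seed: int | None = None,
    dt: float = 0.1,
    burn_in: float = 200.0,
    relax: float = 100.0,
    noise: float = 0.15,
    noise_kind: str = "additive",
    growth: float = 1.0,
    capacity: float = 10.0,
    grazing: float = 1.5,
    half_sat_water: float = 1.0,
    water_loss: float = 0.2,
    uptake: float = 0.05,
    diff_biomass: float = 0.2,
    diff_water: float = 0.2,
) -> GradientSequence:
    """Biomass-water lattice with logistic growth and saturating grazing.

    Per cell, with ``r(W) = growth * W / (W + half_sat_water)``::

        dB/dt = r(W) * B * (1 - B/capacity) - grazing * B/(B + 1)
                + diff_biomass * lap(B) + noise term
        dW/dt = rain - water_loss * W - uptake * B * W + diff_water * lap(W)

    The stochastic forcing on the biomass field is additive
    (``noise * xi``) by default or multiplicative (``noise * B * xi``)
    with ``noise_kind='multiplicative'``; additive forcing keeps the
    fluctuation source constant along the gradient so that the rising
    spatial variance reflects the slowing recovery alone.

    The saturating grazing term gives a fold bifurcation: as rainfall (the
    driver) falls, the water-limited growth rate can no longer sustain the
    vegetated branch and the lattice collapses to a near-bare state.
    Driver values must decrease (drying) toward the transition.
    """
    if driver_values is None:
        driver_values = LOCAL_FEEDBACK_DRIVERS
    driver_values = tuple(float(v) for v in driver_values)
    rng = np.random.default_rng(seed)
    shape = (grid_size, grid_size)
    b = capacity * 0.8 + 0.1 * rng.standard_normal(shape)
    w = np.full(shape, driver_values[0] / water_loss) + 0.1 * rng.standard_normal(shape)
    b = np.clip(b, 0.0, None)
    w = np.clip(w, 0.0, None)
    snapshots = []
    sdt = np.sqrt(dt)
    mult = noise_kind == "multiplicative"
    for k, rain in enumerate(driver_values):
        t_total = burn_in if k == 0 else relax
        n_steps = int(round(t_total / dt))
        for step in range(n_steps):
            xi = rng.standard_normal(shape)
            ok = _local_feedback_step(
                b, w, xi, rain, dt, sdt, noise, mult, growth, capacity,
                grazing, half_sat_water, water_loss, uptake, diff_biomass,
                diff_water,
            )
            if not ok:
                raise SimulationError(
                    f"non-finite state at driver {rain}, step {step}; "
                    "reduce dt or noise"
                )
        snapshots.append(
            SpatialGrid(
                b.copy(), value_kind="continuous", boundary="periodic",
                label=f"local_feedback rain={rain:g}",
            )
        )
    return GradientSequence(
        snapshots=tuple(snapshots), stress=driver_values, direction="toward_transition"
    )


@numba.njit(cache=False)
def _local_feedback_step(
    b, w, xi, rain, dt, sdt, noise, mult, growth, capacity, grazing,
    half_sat_water, water_loss, uptake, diff_biomass, diff_water,
):  # pragma: no cover - exercised through simulate_local_feedback
    """One Euler-Maruyama step of the biomass-water lattice, in place.

    Returns False when the state went non-finite (caller raises)."""
    ny, nx = b.shape
    nb = np.empty_like(b)
    nw = np.empty_like(w)
    for i in range(ny):
        iu = i - 1 if i > 0 else ny - 1
        idn = i + 1 if i < ny - 1 else 0
        for j in range(nx):
            jl = j - 1 if j > 0 else nx - 1
            jr = j + 1 if j < nx - 1 else 0
            bc = b[i, j]
            wc = w[i, j]
            lap_b = b[iu, j] + b[idn, j] + b[i, jl] + b[i, jr] - 4.0 * bc
            lap_w = w[iu, j] + w[idn, j] + w[i, jl] + w[i, jr] - 4.0 * wc
            rw = growth * wc / (wc + half_sat_water)
            db = (
                rw * bc * (1.0 - bc / capacity)
                - grazing * bc / (bc + 1.0)
                + diff_biomass * lap_b
            )
            dw = rain - water_loss * wc - uptake * bc * wc + diff_water * lap_w
            amp = noise * bc if mult else noise
            vb = bc + dt * db + amp * sdt * xi[i, j]
            vw = wc + dt * dw
            if not (vb == vb and vw == vw):
                return False
            nb[i, j] = vb if vb > 0.0 else 0.0
            nw[i, j] = vw if vw > 0.0 else 0.0
    b[:, :] = nb
    w[:, :] = nw
    return True



# ---------------------------------------------------------------------------
# data set 2: three-state facilitation cellular automaton
# ---------------------------------------------------------------------------

#: Default establishment-probability gradient (decreasing b = harsher).
FACILITATION_DRIVERS: tuple[float, ...] = (
    0.90, 0.80, 0.70, 0.62, 0.55, 0.50, 0.45, 0.41, 0.37, 0.33,
)

#: integer codes of the three cell states
VEGETATED, EMPTY, DEGRADED = 1, 0, -1


def simulate_facilitation_ca(
    grid_size: int = 100,
    driver_values: Sequence[float] | None = None,
    seed: int | None = None,
    burn_in: int = 400,
    relax: int = 200,
    delta: float = 0.1,
    c: float = 0.3,
    mortality: float = 0.1,
    degradation: float = 0.1,
    regeneration: float = 0.0001,
    facilitation: float = 0.9,
    scheme: Literal["synchronous", "asynchronous"] = "synchronous",
    return_states: bool = False,
) -> GradientSequence | tuple[GradientSequence, list[np.ndarray]]:
    """Three-state stochastic cellular automaton with local facilitation.

    Each cell is vegetated (+), empty (o) or degraded (-).  Per-step
    transition probabilities, with ``rho`` the global vegetated fraction
    and ``q`` the local vegetated fraction among the 4 neighbours::

        empty    -> vegetated : [delta*rho + (1-delta)*q] * max(b - c*rho, 0)
        vegetated -> empty    : mortality
        empty    -> degraded  : degradation
        degraded -> empty     : regeneration + facilitation * q

    The driver ``b`` is the establishment probability under no
    competition; decreasing b is increasing environmental harshness.  The
    facilitation term (regeneration boosted by vegetated neighbours) is
    what clusters vegetation; with ``facilitation=0`` and fully global
    dispersal (``delta=1``) the model has no local interactions at all and
    its occupancy pattern is spatially random.

    Snapshots are {0,1} occupancy grids (vegetated vs not); with
    ``return_states`` the raw three-state lattices (codes +1/0/-1) are
    also returned.
    """
    if driver_values is None:
        driver_values = FACILITATION_DRIVERS
    driver_values = tuple(float(v) for v in driver_values)
    for p, nm in ((mortality, "mortality"), (degradation, "degradation"),
                  (regeneration, "regeneration")):
        if not 0.0 <= p <= 1.0:
            raise SimulationError(f"{nm} must be a probability, got {p}")
    if regeneration + facilitation > 1.0:
        raise SimulationError(
            "regeneration + facilitation exceeds 1: degraded->empty would not "
            "be a probability"
        )
    rng = np.random.default_rng(seed)
    shape = (grid_size, grid_size)
    state = rng.choice(
        np.array([VEGETATED, EMPTY, DEGRADED]), size=shape, p=[0.5, 0.3, 0.2]
    )
    snapshots = []
    raw_states = []
    for k, b in enumerate(driver_values):
        n_steps = burn_in if k == 0 else relax
        for _ in range(n_steps):
            state = _ca_step(
                state, b, delta, c, mortality, degradation, regeneration,
                facilitation, rng, scheme,
            )
        occ = (state == VEGETATED).astype(float)
        snapshots.append(
            SpatialGrid(
                occ, value_kind="discrete_occupancy", boundary="periodic",
                label=f"facilitation_ca b={b:g}",
            )
        )
        if return_states:
            raw_states.append(state.copy())
    seq = GradientSequence(
        snapshots=tuple(snapshots), stress=driver_values, direction="toward_transition"
    )
    return (seq, raw_states) if return_states else seq


def _ca_step(
    state: np.ndarray,
    b: float,
    delta: float,
    c: float,
    mortality: float,
    degradation: float,
    regeneration: float,
    facilitation: float,
    rng: np.random.Generator,
    scheme: str,
) -> np.ndarray:
    veg = state == VEGETATED
    rho = veg.mean()
    q = _neighbor_fraction(veg)
    p_col = (delta * rho + (1.0 - delta) * q) * max(b - c * rho, 0.0)
    p_reg = regeneration + facilitation * q
    if np.any(p_col + degradation > 1.0) or np.any(p_reg > 1.0):
        raise SimulationError(
            "a transition probability exceeded 1; reduce b, degradation or "
            "facilitation"
        )
    if scheme == "synchronous":
        u = rng.random(state.shape)
        new = state.copy()
        empty = state == EMPTY
        degr = state == DEGRADED
        new[veg & (u < mortality)] = EMPTY
        new[empty & (u < p_col)] = VEGETATED
        new[empty & (u >= p_col) & (u < p_col + degradation)] = DEGRADED
        new[degr & (u < p_reg)] = EMPTY
        return new
    # asynchronous: N random single-cell updates per step
    n = state.size
    new = state.copy()
    rows = rng.integers(0, state.shape[0], n)
    cols = rng.integers(0, state.shape[1], n)
    us = rng.random(n)
    for i, j, u in zip(rows, cols, us):
        s = new[i, j]
        veg_n = 0.25 * sum(
            new[(i + di) % state.shape[0], (j + dj) % state.shape[1]] == VEGETATED
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
        )
        rho_now = np.mean(new == VEGETATED)
        if s == VEGETATED and u < mortality:
            new[i, j] = EMPTY
        elif s == EMPTY:
            pc = (delta * rho_now + (1 - delta) * veg_n) * max(b - c * rho_now, 0.0)
            if u < pc:
                new[i, j] = VEGETATED
            elif u < pc + degradation:
                new[i, j] = DEGRADED
        elif s == DEGRADED and u < regeneration + facilitation * veg_n:
            new[i, j] = EMPTY
    return new


# ---------------------------------------------------------------------------
# data set 3: scale-dependent feedback (Turing) PDE model
# ---------------------------------------------------------------------------

#: Default rainfall gradient (mm/day), decreasing toward desertification.
TURING_DRIVERS: tuple[float, ...] = (
    1.24, 1.20, 1.16, 1.12, 1.08, 1.04, 1.00, 0.96, 0.92, 0.88,
)


def simulate_turing_pde(
    grid_size: int = 100,
    driver_values: Sequence[float] | None = None,
    seed: int | None = None,
    dx: float = 2.5,
    dt: float | None = None,
    burn_in: float = 300.0,
    relax: float = 150.0,
    noise: float = 0.01,
    noise_interval: float = 0.1,
    conversion: float = 10.0,
    uptake_max: float = 0.05,
    half_sat_soil: float = 5.0,
    mortality: float = 0.25,
    infiltration_max: float = 0.2,
    half_sat_infil: float = 5.0,
    bare_infiltration: float = 0.2,
    soil_water_loss: float = 0.2,
    diff_plant: float = 0.1,
    diff_soil_water: float = 0.1,
    diff_surface_water: float = 100.0,
) -> GradientSequence:
    """Three-PDE scale-dependent feedback model of patterned vegetation.

    Fields: plant biomass P, soil water W, surface water O, on a periodic
    lattice with spacing ``dx`` (metres)::

        dP/dt = conversion * g(W) * P - mortality * P + diff_plant * lap P
        dW/dt = I(P) * O - g(W) * P - soil_water_loss * W + diff_soil_water * lap W
        dO/dt = rain - I(P) * O + diff_surface_water * lap O

        g(W) = uptake_max * W / (W + half_sat_soil)
        I(P) = infiltration_max * (P + half_sat_infil * bare_infiltration)
                                 / (P + half_sat_infil)

    Vegetation raises the infiltration rate I, so surface water converges
    under patches (short-range activation) and is depleted between them
    (long-range inhibition through the fast surface-water diffusion) — a
    Turing instability.  Along a decreasing-rainfall gradient the pattern
    passes through gaps, labyrinths and spots before collapsing to desert.

    The explicit-Euler time step is chosen automatically from the
    diffusion stability bound ``dt <= dx^2 / (4 * max D)`` (safety factor
    0.8) unless given; a given ``dt`` violating the bound is rejected
    before integration starts.
    """
    if driver_values is None:
        driver_values = TURING_DRIVERS
    driver_values = tuple(float(v) for v in driver_values)
    dmax = max(diff_plant, diff_soil_water, diff_surface_water)
    cfl = dx * dx / (4.0 * dmax)
    if dt is None:
        dt = 0.8 * cfl
    elif dt > cfl:
        raise SimulationError(
            f"dt={dt} violates the diffusion stability bound {cfl:.4g} "
            f"for dx={dx}"
        )
    rng = np.random.default_rng(seed)
    shape = (grid_size, grid_size)
    rain0 = driver_values[0]
    # homogeneous vegetated equilibrium at the initial rainfall, perturbed
    gstar = mortality / conversion
    w_eq = gstar * half_sat_soil / max(uptake_max - gstar, 1e-9)
    p_eq = max((rain0 - soil_water_loss * w_eq) / gstar, 1.0)
    p = np.clip(p_eq + 0.2 * p_eq * rng.standard_normal(shape), 0.1, None)
    w = np.full(shape, w_eq, dtype=float)
    o = np.full(shape, rain0 / infiltration_max, dtype=float)
    # noise is applied between blocks of deterministic steps, at intervals
    # of noise_interval days, with the amplitude scaled accordingly
    block = max(int(round(noise_interval / dt)), 1)
    amp = noise * np.sqrt(block * dt)
    snapshots = []
    for k, rain in enumerate(driver_values):
        t_total = burn_in if k == 0 else relax
        n_steps = int(round(t_total / dt))
        done = 0
        while done < n_steps:
            nsub = min(block, n_steps - done)
            status = _pde_block(
                p, w, o, nsub, dt, 1.0 / (dx * dx), rain,
                conversion, uptake_max, half_sat_soil, mortality,
                infiltration_max, half_sat_infil, bare_infiltration,
                soil_water_loss, diff_plant, diff_soil_water,
                diff_surface_water,
            )
            if status != 0:
                raise SimulationError(
                    f"instability at rain={rain}, step {done}: negative or "
                    "non-finite state; reduce dt"
                )
            done += nsub
            if noise > 0.0:
                p += amp * rng.standard_normal(shape)
                np.clip(p, 0.0, None, out=p)
        snapshots.append(
            SpatialGrid(
                p.copy(), value_kind="continuous", boundary="periodic",
                label=f"turing_pde rain={rain:g}",
            )
        )
    return GradientSequence(
        snapshots=tuple(snapshots), stress=driver_values, direction="toward_transition"
    )


@numba.njit(cache=False)
def _pde_block(
    p, w, o, n_steps, dt, inv_dx2, rain,
    conversion, uptake_max, half_sat_soil, mortality,
    infiltration_max, half_sat_infil, bare_infiltration,
    soil_water_loss, diff_plant, diff_soil_water, diff_surface_water,
):  # pragma: no cover - exercised through simulate_turing_pde
    """Advance the three fields n_steps explicit-Euler steps in place.

    Returns 0 on success, 1 when a state variable went negative beyond
    tolerance or non-finite (caller raises)."""
    ny, nx = p.shape
    np_new = np.empty_like(p)
    nw_new = np.empty_like(w)
    no_new = np.empty_like(o)
    for _ in range(n_steps):
        for i in range(ny):
            iu = i - 1 if i > 0 else ny - 1
            idn = i + 1 if i < ny - 1 else 0
            for j in range(nx):
                jl = j - 1 if j > 0 else nx - 1
                jr = j + 1 if j < nx - 1 else 0
                pc = p[i, j]
                wc = w[i, j]
                oc = o[i, j]
                lap_p = p[iu, j] + p[idn, j] + p[i, jl] + p[i, jr] - 4.0 * pc
                lap_w = w[iu, j] + w[idn, j] + w[i, jl] + w[i, jr] - 4.0 * wc
                lap_o = o[iu, j] + o[idn, j] + o[i, jl] + o[i, jr] - 4.0 * oc
                g = uptake_max * wc / (wc + half_sat_soil)
                infil = (
                    infiltration_max
                    * (pc + half_sat_infil * bare_infiltration)
                    / (pc + half_sat_infil)
                )
                np_new[i, j] = pc + dt * (
                    conversion * g * pc - mortality * pc
                    + diff_plant * lap_p * inv_dx2
                )
                nw_new[i, j] = wc + dt * (
                    infil * oc - g * pc - soil_water_loss * wc
                    + diff_soil_water * lap_w * inv_dx2
                )
                no_new[i, j] = oc + dt * (
                    rain - infil * oc + diff_surface_water * lap_o * inv_dx2
                )
        for i in range(ny):
            for j in range(nx):
                vp = np_new[i, j]
                vw = nw_new[i, j]
                vo = no_new[i, j]
                if not (vp == vp and vw == vw and vo == vo):
                    return 1
                if vp < -0.1 or vw < -0.1 or vo < -0.1:
                    return 1
                p[i, j] = vp if vp > 0.0 else 0.0
                w[i, j] = vw if vw > 0.0 else 0.0
                o[i, j] = vo if vo > 0.0 else 0.0
    return 0


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

Model = Literal["local_feedback", "facilitation_ca", "turing_pde"]


@dataclass(frozen=True)
class SimConfig:
    """Declarative configuration for any of the three simulators."""

    model: Model
    grid_size: int = 100
    driver_values: tuple[float, ...] | None = None
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.driver_values is not None:
            dv = np.asarray(self.driver_values, float)
            diffs = np.diff(dv)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError("driver_values must be strictly monotone")


_MODELS = {
    "local_feedback": simulate_local_feedback,
    "facilitation_ca": simulate_facilitation_ca,
    "turing_pde": simulate_turing_pde,
}


def simulate(config: SimConfig) -> GradientSequence:
    """Run the simulator named in the configuration."""
    fn = _MODELS[config.model]
    return fn(
        grid_size=config.grid_size,
        driver_values=config.driver_values,
        seed=config.seed,
        **config.params,
    )
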