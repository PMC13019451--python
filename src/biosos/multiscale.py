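"""Aggregate-culture simulator: the system-of-systems coupling layer.

Couples the three sub-models per operator-splitting step (default 0.5 h):

1. advance the aggregate size distribution one step (coalescence +
   Gompertz growth, the growth rate tied to the metabolic model's mu at
   bulk conditions);
2. pick a small set of quadrature size classes conserving total count and
   mass, and solve the steady intra-aggregate reaction-diffusion profile
   of each class against the current bulk medium (quasi-steady transport:
   profiles equilibrate fast relative to bulk dynamics);
3. update the bulk medium balances with the number-weighted per-aggregate
   uptake of every class, and advance a representative intracellular cell
   state at bulk conditions;
4. apply feeding events as instantaneous concentration resets.

Viable cell density is the intra-aggregate cell density times the total
aggregate volume per mL (an exposed conversion factor calibrates dissociated
counts against this integral).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .diffusion import (
    DEFAULT_DIFFUSIVITIES,
    DiffusionParams,
    aggregate_uptake,
    network_sink,
    solve_profile,
)
from .network import CultureCondition, NetworkModel, Trajectory
from .pbm import (
    GrowthParams,
    KernelParams,
    NumberDensity,
    default_grid,
    diameters_to_density,
    simulate_pbm,
)

__all__ = [
    "simulate_aggregate_culture",
    "select_quadrature_classes",
    "seed_density",
    "AggregateResult",
]

#: um^3 -> mL
UM3_TO_ML = 1e-12


def seed_density(
    initial_vcd: float,
    cell_density: float,
    mean_diameter: float = 100.0,
    cv: float = 0.3,
    n_samples: int = 4000,
    seed: int = 0,
    grid=None,
) -> NumberDensity:
    """Day-0 seeding distribution: lognormal in diameter.

    The aggregate count per mL is set so the total aggregate volume times
    the intra-aggregate cell density matches ``initial_vcd``.
    """
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1 + cv**2))
    mu = np.log(mean_diameter) - sigma**2 / 2
    d = rng.lognormal(mu, sigma, n_samples)
    nd = diameters_to_density(d, grid if grid is not None else default_grid())
    cells_per_ml = nd.total_mass() * UM3_TO_ML * cell_density
    scale = initial_vcd / cells_per_ml
    return NumberDensity(nd.grid, nd.values * scale, nd.time)


def select_quadrature_classes(density: NumberDensity, n_classes: int = 7):
    """Representative (sizes, weights) conserving total count and mass.

    Bins are grouped into contiguous count quantiles; each group is
    represented by its mass-weighted mean size with its total count as
    weight, so both moments of the density are reproduced exactly.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    counts = density.counts
    piv = density.grid.pivots
    total = counts.sum()
    if total <= 0:
        raise ValueError("degenerate density: no aggregates")
    occupied = np.nonzero(counts > 0)[0]
    if len(occupied) <= n_classes:
        sizes = piv[occupied]
        weights = counts[occupied]
        return sizes, weights
    cum = np.cumsum(counts) / total
    edges = np.searchsorted(cum, np.linspace(0, 1, n_classes + 1)[1:-1], side="left")
    groups = np.split(np.arange(len(counts)), np.unique(edges))
    sizes, weights = [], []
    for g in groups:
        w = counts[g].sum()
        if w <= 0:
            continue
        sizes.append((counts[g] * piv[g]).sum() / w)
        weights.append(w)
    return np.asarray(sizes), np.asarray(weights)


@dataclass
class AggregateResult:
    bulk: Trajectory
    densities: list
    fields: dict  # class size -> ConcentrationField at the final step


def simulate_aggregate_culture(
    model: NetworkModel,
    kernel: KernelParams | None,
    growth: GrowthParams | None,
    diffusion: DiffusionParams,
    condition: CultureCondition,
    times: Sequence[float],
    initial_density: NumberDensity | None = None,
    n_classes: int = 7,
    dt: float = 0.5,
    feed_times: Sequence[float] = (),
    feed_concentrations: Mapping[str, float] | None = None,
    profile_nodes: int = 30,
    vcd_conversion: float = 1.0,
) -> AggregateResult:
    """Simulate a 3D aggregate culture on the requested output times.

    ``growth.alpha_g`` is the within-aggregate Gompertz rate at unhindered
    growth; at each step it is scaled by mu(bulk)/mu_max, tying aggregate
    expansion to the metabolic state.  ``feed_times`` apply
    ``feed_concentrations`` (defaults to the condition's initial medium) as
    instantaneous resets.  Returns the bulk trajectory, the density at each
    output time, and the final per-class radial profiles.
    """
    condition.validate()
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    ck = model.compiled()
    species = [s for s in model.ext_ids if s in diffusion.diffusivities]
    if initial_density is None:
        initial_density = seed_density(condition.initial_vcd, diffusion.cell_density)
    density = initial_density
    grid = density.grid

    ext = condition.medium(model.ext_ids).astype(float)
    ext_index = {s: k for k, s in enumerate(model.ext_ids)}
    s_int = np.array(
        [model.initial_intracellular.get(s, 0.0) for s in model.int_ids]
    )
    int_index = {s: k for k, s in enumerate(model.int_ids)}
    S_int = ck.S[ck.int_rows, :]

    feed = dict(condition.initial_concentrations)
    if feed_concentrations is not None:
        feed = dict(feed_concentrations)
    feed_left = sorted(feed_times)

    def mu_now():
        full = np.empty(len(model.species_ids))
        full[ck.ext_rows] = ext
        full[ck.int_rows] = s_int
        return float(ck.growth_rate(full))

    def vcd_now(dens):
        return dens.total_mass() * UM3_TO_ML * diffusion.cell_density * vcd_conversion

    def record(t):
        full = np.empty(len(model.species_ids))
        full[ck.ext_rows] = ext
        full[ck.int_rows] = s_int
        vf, vr = ck.fluxes_split(full, condition.oxygen_at(t))
        return (t, vcd_now(density), ext.copy(), s_int.copy(), vf - vr, vf, vr)

    t_now = float(times[0])
    out_rows = [record(t_now)]
    out_densities = [density]
    last_fields: dict = {}

    t_end = float(times[-1])
    next_out = 1
    while t_now < t_end - 1e-9:
        h = min(dt, t_end - t_now)
        if next_out < len(times):
            h = min(h, times[next_out] - t_now)
        if feed_left and t_now < feed_left[0] <= t_now + h + 1e-12:
            h = max(feed_left[0] - t_now, 1e-6)

        # (1) size-distribution step
        mu = mu_now()
        if kernel is not None or (growth is not None and growth.alpha_g > 0):
            g_eff = None
            if growth is not None and growth.alpha_g > 0 and mu > 0:
                g_eff = GrowthParams(
                    alpha_g=growth.alpha_g * mu / model.growth.mu_max,
                    m_max=growth.m_max,
                )
            density = simulate_pbm(density, kernel, g_eff, [0.0, h], dt=h)[-1]

        # (2) quadrature classes and steady radial profiles
        sizes, weights = select_quadrature_classes(density, n_classes)
        int_state = dict(zip(model.int_ids, s_int))
        sink = network_sink(
            model, int_state, diffusion, species,
            oxygen_level=condition.oxygen_at(t_now),
        )
        bulk_map = {s: max(ext[ext_index[s]], 0.0) for s in species}
        dC = np.zeros(len(species))
        last_fields = {}
        for x_cls, w_cls in zip(sizes, weights):
            R = (3.0 * x_cls / (4.0 * np.pi)) ** (1.0 / 3.0)
            try:
                fld = solve_profile(
                    R, bulk_map, sink, diffusion,
                    species=species, n_nodes=profile_nodes,
                )
            except RuntimeError as exc:
                raise RuntimeError(
                    f"reaction-diffusion stage failed for class size "
                    f"{x_cls:.3g} um^3 at t={t_now:.2f} h: {exc}"
                ) from exc
            uptake = aggregate_uptake(fld, diffusion)
            last_fields[float(x_cls)] = fld
            for k, s in enumerate(species):
                # mmol/h per aggregate * aggregates/mL -> mM/h
                dC[k] -= uptake[s] * w_cls * 1e3

        # (3) bulk update + representative intracellular state
        for k, s in enumerate(species):
            ext[ext_index[s]] = max(ext[ext_index[s]] + dC[k] * h, 0.0)

        def int_rhs(t, y):
            full = np.empty(len(model.species_ids))
            full[ck.ext_rows] = ext
            full[ck.int_rows] = y
            return S_int @ ck.fluxes(full, condition.oxygen_at(t_now))

        sol = solve_ivp(
            int_rhs, (0.0, h), s_int, method="LSODA", rtol=1e-6, atol=1e-9
        )
        if not sol.success:
            raise RuntimeError(
                f"intracellular stage failed at t={t_now:.2f} h: {sol.message}"
            )
        s_int = np.maximum(sol.y[:, -1], 0.0)

        t_now += h
        # (4) feeding resets
        if feed_left and abs(t_now - feed_left[0]) < 1e-9:
            for s, val in feed.items():
                if s in ext_index:
                    ext[ext_index[s]] = val
            feed_left.pop(0)

        if next_out < len(times) and t_now >= times[next_out] - 1e-9:
            out_rows.append(record(times[next_out]))
            out_densities.append(
                NumberDensity(density.grid, density.values.copy(), times[next_out])
            )
            next_out += 1

    tt = np.array([r[0] for r in out_rows])
    bulk = Trajectory(
        times=tt,
        vcd=np.array([r[1] for r in out_rows]),
        ext_ids=list(model.ext_ids),
        extracellular=np.array([r[2] for r in out_rows]),
        int_ids=list(model.int_ids),
        intracellular=np.array([r[3] for r in out_rows]),
        reaction_ids=list(model.reaction_ids),
        fluxes=np.array([r[4] for r in out_rows]),
        fluxes_forward=np.array([r[5] for r in out_rows]),
        fluxes_reverse=np.array([r[6] for r in out_rows]),
    )
    return AggregateResult(bulk=bulk, densities=out_densities, fields=last_fields)
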