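"""Intra-aggregate reaction-diffusion: radial nutrient/metabolite profiles.

Aggregates are treated as spheres with radial symmetry.  Each transported
metabolite i obeys

    dc_i/dt = (D_i / r^2) d/dr (r^2 dc_i/dr) - rho_i(c)

on r in [0, R], with the symmetry condition dc/dr = 0 at the center and a
Dirichlet boundary c(R) = bulk (no external film resistance by default; a
film-transfer Robin condition is available via ``film_h``).  The volumetric
sink rho_i couples to the single-cell network: per-cell exchange fluxes
evaluated at the local extracellular concentrations times the intra-
aggregate cell density (constant through the sphere).

Units: lengths um, concentrations mM, time h, diffusivities declared in
um^2/s (converted internally), volumetric sink mM/h.  Discretization is
finite volumes with the singular r=0 cell handled by the zero-area inner
face; steady profiles come from a damped Newton iteration on the
method-of-lines residual with an analytically tridiagonal diffusion block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .network import NetworkModel

__all__ = [
    "RadialGrid",
    "DiffusionParams",
    "ConcentrationField",
    "solve_profile",
    "aggregate_uptake",
    "effectiveness_factor",
    "network_sink",
    "DEFAULT_DIFFUSIVITIES",
]

SECONDS_PER_HOUR = 3600.0
#: um^3 * mM -> mmol  (1 L = 1e15 um^3)
UM3_MM_TO_MMOL = 1e-15

#: effective diffusivities in aggregate tissue, um^2/s
DEFAULT_DIFFUSIVITIES = {
    "EGLC": 300.0,
    "ELAC": 500.0,
    "EPYR": 500.0,
    "EGLN": 300.0,
    "EGLU": 300.0,
    "EALA": 400.0,
    "ENH4": 800.0,
    "ESER": 400.0,
    "EVAL": 350.0,
    "ELEU": 330.0,
    "EILE": 330.0,
    "EPRO": 350.0,
}


@dataclass
class RadialGrid:
    """Uniform radial nodes 0 = r_0 < ... < r_{n-1} = R (um)."""

    radii: np.ndarray

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        if self.radii[0] != 0.0:
            raise ValueError("first node must sit at the aggregate center")
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")

    @classmethod
    def uniform(cls, R: float, n_nodes: int = 60) -> "RadialGrid":
        if R <= 0:
            raise ValueError("aggregate radius must be positive")
        return cls(np.linspace(0.0, R, n_nodes))

    @property
    def R(self) -> float:
        return float(self.radii[-1])

    @property
    def n(self) -> int:
        return len(self.radii)


@dataclass
class DiffusionParams:
    """Per-metabolite effective diffusivities and intra-aggregate density."""

    diffusivities: dict = field(default_factory=lambda: dict(DEFAULT_DIFFUSIVITIES))
    cell_density: float = 2.5e8  # cells per mL of aggregate volume

    def __post_init__(self):
        for met, d in self.diffusivities.items():
            if d <= 0:
                raise ValueError(f"non-positive diffusivity for {met}")
        if self.cell_density <= 0:
            raise ValueError("cell density must be positive")

    def d_per_hour(self, met: str) -> float:
        return self.diffusivities[met] * SECONDS_PER_HOUR


@dataclass
class ConcentrationField:
    """Radial concentration profiles c_i(r) inside one aggregate class."""

    grid: RadialGrid
    species: list
    values: np.ndarray  # (n_species, n_nodes), mM
    time: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species), self.grid.n):
            raise ValueError("field shape must be (n_species, n_nodes)")
        if np.any(self.values < -1e-9):
            raise ValueError("negative concentration in field")

    def profile(self, met: str) -> np.ndarray:
        return self.values[self.species.index(met)]


def network_sink(
    model: NetworkModel,
    intracellular: Mapping[str, float],
    params: DiffusionParams,
    species: Sequence[str],
    oxygen_level: float = 1.0,
) -> Callable:
    """Volumetric consumption closure from the single-cell network.

    Returns ``sink(c)`` mapping local extracellular concentrations
    (n_species, n_nodes) to volumetric consumption rates (mM/h, positive
    = consumed), with the intracellular state held fixed (quasi-steady
    cells responding to their local microenvironment).
    """
    ck = model.compiled()
    base = np.zeros(len(model.species_ids))
    for s, val in intracellular.items():
        base[model.species_index[s]] = val
    rows = np.array([model.species_index[s] for s in species])
    S_sub = ck.S[rows, :]
    # mmol/1e9 cells/h * cells/mL -> mM/h
    factor = params.cell_density * 1e-6

    def sink(c: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(c)
        full = np.repeat(base[:, None], c.shape[1], axis=1)
        full[rows, :] = np.maximum(c, 0.0)
        v = ck.fluxes(full, oxygen_level)
        return -(S_sub @ v) * factor

    return sink


def _fv_operator(grid: RadialGrid):
    r = grid.radii
    h = np.diff(r)
    faces = 0.5 * (r[:-1] + r[1:])
    area = 4.0 * np.pi * faces**2
    rf = np.concatenate(([0.0], faces, [r[-1]]))
    vol = 4.0 * np.pi * (rf[1:] ** 3 - rf[:-1] ** 3) / 3.0
    return h, area, vol


def solve_profile(
    R: float,
    bulk: Mapping[str, float],
    sink: Callable,
    params: DiffusionParams,
    mode: str = "steady",
    n_nodes: int = 60,
    species: Sequence[str] | None = None,
    t_end: float = 1.0,
    film_h: Mapping[str, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> ConcentrationField:
    """Solve the radial transport-consumption problem for one aggregate.

    ``sink(c)`` returns volumetric consumption (mM/h) for the stacked
    species; ``mode="steady"`` solves the fixed point of the
    method-of-lines system by damped Newton, ``mode="transient"``
    integrates it to ``t_end`` hours from a uniform-bulk start.
    ``film_h`` (um/h per species) switches the outer boundary to a Robin
    film-transfer condition.
    """
    if species is None:
        species = list(bulk.keys())
    species = list(species)
    cb = np.array([bulk[s] for s in species], dtype=float)
    grid = RadialGrid.uniform(R, n_nodes)
    n = grid.n
    h, area, vol = _fv_operator(grid)
    D = np.array([params.d_per_hour(s) for s in species])
    ns = len(species)

    def rates(c):
        out = np.asarray(sink(c), dtype=float)
        if out.shape != c.shape:
            raise ValueError("sink must return one rate per species per node")
        return out

    def rhs_full(c):
        """Time derivative on all nodes; boundary node handled per BC."""
        flux = D[:, None] * (c[:, 1:] - c[:, :-1]) / h  # at faces
        div = np.zeros_like(c)
        div[:, :-1] += area * flux / vol[:-1]
        div[:, 1:] -= area * flux / vol[1:]
        out = div - rates(c)
        if film_h is None:
            out[:, -1] = 0.0  # Dirichlet: c_R fixed at bulk
        else:
            hh = np.array([film_h[s] for s in species])
            out[:, -1] += hh * 4.0 * np.pi * grid.R**2 * (cb - c[:, -1]) / vol[-1]
        return out

    c0 = np.repeat(cb[:, None], n, axis=1)

    if mode == "transient":
        sol = solve_ivp(
            lambda t, y: rhs_full(y.reshape(ns, n)).ravel(),
            (0.0, t_end),
            c0.ravel(),
            method="BDF",
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"transient diffusion solve failed: {sol.message}")
        c = sol.y[:, -1].reshape(ns, n)
        return ConcentrationField(grid, species, np.maximum(c, 0.0), time=t_end)
    if mode != "steady":
        raise ValueError("mode must be 'steady' or 'transient'")

    # ---- damped Newton on the interior residual -----------------------
    m = n if film_h is not None else n - 1  # unknown nodes per species

    def residual(c):
        return rhs_full(c)[:, :m]

    def jacobian(c):
        # diffusion: tridiagonal per species (analytic)
        rows, cols, vals = [], [], []

        def idx(s, j):
            return s * m + j

        for s in range(ns):
            for j in range(m):
                diag = 0.0
                if j > 0:
                    w = D[s] * area[j - 1] / (h[j - 1] * vol[j])
                    rows.append(idx(s, j)); cols.append(idx(s, j - 1)); vals.append(w)
                    diag -= w
                if j < n - 1:
                    w = D[s] * area[j] / (h[j] * vol[j])
                    if j + 1 < m:
                        rows.append(idx(s, j)); cols.append(idx(s, j + 1)); vals.append(w)
                    diag -= w
                if film_h is not None and j == n - 1:
                    diag -= list(film_h.values())[s] * 4.0 * np.pi * grid.R**2 / vol[-1]
                rows.append(idx(s, j)); cols.append(idx(s, j)); vals.append(diag)
        # sink: finite-difference coupling, diagonal in node
        base_rate = rates(c)
        eps = 1e-7
        for sp_k in range(ns):
            cp = c.copy()
            step = eps * max(1.0, np.abs(c[sp_k]).max())
            cp[sp_k, :] += step
            drate = (rates(cp) - base_rate) / step
            for s in range(ns):
                for j in range(m):
                    rows.append(idx(s, j)); cols.append(idx(sp_k, j))
                    vals.append(-drate[s, j])
        J = sp.coo_matrix((vals, (rows, cols)), shape=(ns * m, ns * m))
        return J.tocsr()

    c = c0.copy()
    scale = max(np.abs(rates(c0)).max(), 1e-12)
    # roundoff floor of the discrete diffusion operator (mM/h)
    eps = np.finfo(float).eps
    floor = 1e4 * eps * 3.0 * D.max() / h.min() ** 2 * max(cb.max(), 1.0)
    target = max(tol * max(scale, 1.0), floor)
    for _ in range(max_iter):
        norm = np.abs(residual(c)).max()
        if norm <= target:
            break
        J = jacobian(c)
        delta = spla.spsolve(J, -residual(c).ravel()).reshape(ns, m)
        lam = 1.0
        cur = norm
        for _ in range(25):
            trial = c.copy()
            trial[:, :m] = np.maximum(c[:, :m] + lam * delta, 0.0)
            if np.abs(residual(trial)).max() < cur:
                c = trial
                break
            lam *= 0.5
        else:
            if cur <= 10 * floor:
                break  # at the operator's roundoff floor
            raise RuntimeError(
                f"steady diffusion solve stalled: residual max {cur:.3e}"
            )
    else:
        raise RuntimeError(
            f"steady diffusion solve did not converge: residual max "
            f"{np.abs(residual(c)).max():.3e}"
        )
    return ConcentrationField(grid, species, np.maximum(c, 0.0))


def aggregate_uptake(
    field: ConcentrationField, params: DiffusionParams
) -> dict:
    """Molar uptake per aggregate (mmol/h) from the surface flux.

    uptake_i = 4 pi R^2 D_i dc_i/dr |_R, positive when the aggregate
    consumes species i; equals the volume-integrated sink at steady state.
    """
    r = field.grid.radii
    hh = r[-1] - r[-2]
    out = {}
    for k, s in enumerate(field.species):
        c = field.values[k]
        grad = (3 * c[-1] - 4 * c[-2] + c[-3]) / (2 * hh)
        D = params.d_per_hour(s)
        out[s] = 4 * np.pi * field.grid.R**2 * D * grad * UM3_MM_TO_MMOL
    return out


def effectiveness_factor(
    field: ConcentrationField,
    sink: Callable,
    params: DiffusionParams,
    species: str | None = None,
) -> float | dict:
    """Ratio of actual volume-integrated uptake to uptake at uniform bulk.

    Quantifies how diffusion limitation lowers per-cell consumption inside
    an aggregate; tends to 1 as R -> 0.
    """
    _, _, vol = _fv_operator(field.grid)
    actual = np.asarray(sink(field.values), dtype=float) @ vol
    bulk_c = np.repeat(field.values[:, -1][:, None], field.grid.n, axis=1)
    ideal = np.asarray(sink(bulk_c), dtype=float) @ vol
    out = {}
    for k, s in enumerate(field.species):
        if abs(ideal[k]) < 1e-30:
            out[s] = np.nan if species != s else None
            if species == s:
                raise ZeroDivisionError(f"bulk-rate denominator is zero for {s}")
            continue
        out[s] = float(actual[k] / ideal[k])
    if species is not None:
        if out[species] is None or np.isnan(out[species]):
            raise ZeroDivisionError(f"bulk-rate denominator is zero for {species}")
        return out[species]
    return out
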