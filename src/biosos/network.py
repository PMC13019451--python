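"""Single-cell kinetic metabolic-redox network for iPSC monolayer culture.

The model couples a lumped central-carbon network (glycolysis, TCA cycle,
anaplerosis, amino-acid exchange) to explicit redox cofactor bookkeeping
(NAD+/NADH, FAD/FADH2) and a biomass-linked growth rate.
Three regulatory elements modulate the kinetics:

* R0 - lactate inhibition of glucose uptake, ``Ki/(Ki + ELAC)`` on the
  lumped glycolysis step;
* R1 - extracellular-pyruvate inhibition of lactate dehydrogenase,
  ``Ki/(Ki + EPYR)`` on the forward LDH term, with NADH/NAD ratio factors
  on both directions;
* R2 - extracellular-pyruvate inhibition of net glutamine consumption.

Oxygen is an environmental scalar in [0, 1] (fraction of normoxia) that
multiplies the two oxidative-phosphorylation steps through a saturation
factor ``O2/(Km_O2 + O2)``; no dissolved-oxygen state variable is carried.

Units: extracellular concentrations mM; intracellular pools
mmol per 1e9 cells; fluxes mmol per 1e9 cells per h; VCD cells/mL.
The conversion ``dC_ext/dt = q * X * 1e-6`` (mM/h) follows from these.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "MetaboliteSpec",
    "RateLaw",
    "Reaction",
    "GrowthRate",
    "NetworkModel",
    "CultureCondition",
    "Trajectory",
    "NetworkValidationError",
    "load_network",
    "save_network",
    "default_network",
    "ldh_flux",
    "glns_flux",
    "evaluate_all_fluxes",
    "simulate_monolayer",
    "redox_ratio",
    "specific_rate",
    "apply_perturbation",
    "DEFAULT_MEDIUM",
]

# Conversion from (mmol/1e9 cells/h) * (cells/mL) to mM/h.
VCD_FLUX_TO_MM_PER_H = 1.0e-6

# Cofactor pairs whose coefficients must cancel in every reaction.
COFACTOR_PAIRS = (("NAD", "NADH"), ("FAD", "FADH2"))

_EPS = 1e-12


class NetworkValidationError(ValueError):
    """Raised when a network definition violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetaboliteSpec:
    """One chemical species of the network.

    Extracellular species follow the 'E' prefix convention (EGLC, ELAC, ...);
    ``carbon_count`` of zero is allowed only for cofactors and ammonium.
    """

    id: str
    compartment: str  # "extracellular" | "intracellular"
    carbon_count: int = 0
    is_cofactor: bool = False


@dataclass
class RateLaw:
    """Multiplicative saturation/inhibition/ratio kinetics.

    Net flux is ``vf - vr`` with

    ``vf = vmax_f * prod S/(Km+S) * prod Ki/(Ki+I) * prod (A/B)/(Km+A/B)``

    over the forward factor lists, and analogously for the reverse factors.
    """

    vmax_f: float
    vmax_r: float = 0.0
    saturation_factors: list = field(default_factory=list)  # (met, Km)
    inhibition_factors: list = field(default_factory=list)  # (met, Ki)
    ratio_factors: list = field(default_factory=list)  # ((num, den), Km)
    rev_saturation_factors: list = field(default_factory=list)
    rev_inhibition_factors: list = field(default_factory=list)
    rev_ratio_factors: list = field(default_factory=list)

    def validate(self, known: set[str], where: str = "") -> None:
        if self.vmax_f < 0 or self.vmax_r < 0:
            raise NetworkValidationError(f"{where}: negative vmax")
        for lst, kind in (
            (self.saturation_factors, "Km"),
            (self.inhibition_factors, "Ki"),
            (self.rev_saturation_factors, "Km"),
            (self.rev_inhibition_factors, "Ki"),
        ):
            for met, k in lst:
                if k <= 0:
                    raise NetworkValidationError(f"{where}: {kind} <= 0 for {met}")
                if met not in known:
                    raise NetworkValidationError(f"{where}: unknown metabolite {met!r}")
        for lst in (self.ratio_factors, self.rev_ratio_factors):
            for (num, den), k in lst:
                if k <= 0:
                    raise NetworkValidationError(f"{where}: ratio Km <= 0")
                for met in (num, den):
                    if met not in known:
                        raise NetworkValidationError(
                            f"{where}: unknown metabolite {met!r}"
                        )


@dataclass
class Reaction:
    """A stoichiometric reaction with its rate law and optional atom map.

    ``atom_map`` is a list of variants; each variant is a mapping with keys
    ``weight``, ``reactants`` ([(met, letters)]) and ``products``.  Letters
    shared between a reactant and a product denote carbon transfer.
    """

    id: str
    stoichiometry: dict[str, float]
    rate_law: RateLaw
    atom_map: list | None = None
    tag: str = "other"
    oxygen_sensitive: bool = False


@dataclass
class GrowthRate:
    """Biomass-associated specific growth rate mu(s).

    ``mu = mu_max * prod_j S_j/(Km_j + S_j)`` over the Monod dependencies.
    """

    mu_max: float
    monod: list = field(default_factory=list)  # (met, Km)


@dataclass
class NetworkModel:
    metabolites: list[MetaboliteSpec]
    reactions: list[Reaction]
    biomass: dict[str, float]  # demand per unit biomass (consumed > 0)
    growth: GrowthRate
    initial_intracellular: dict[str, float] = field(default_factory=dict)
    km_o2: float = 0.02  # half-saturation of the oxygen factor on OXPHOS

    # -- indexing helpers ---------------------------------------------------
    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self.species_ids = [m.id for m in self.metabolites]
        self.species_index = {s: i for i, s in enumerate(self.species_ids)}
        self.ext_ids = [m.id for m in self.metabolites if m.compartment == "extracellular"]
        self.int_ids = [m.id for m in self.metabolites if m.compartment == "intracellular"]
        self.reaction_ids = [r.id for r in self.reactions]
        self._compiled = None

    def metabolite(self, mid: str) -> MetaboliteSpec:
        return self.metabolites[self.species_index[mid]]

    @property
    def biomass_reaction(self) -> Reaction:
        for r in self.reactions:
            if r.tag == "biomass":
                return r
        raise NetworkValidationError("no biomass reaction")

    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.species_ids), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, c in r.stoichiometry.items():
                S[self.species_index[met], j] = c
        return S

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate metabolite ids")
        known = set(ids)
        for m in self.metabolites:
            if m.compartment not in ("extracellular", "intracellular"):
                raise NetworkValidationError(f"{m.id}: bad compartment")
            if m.carbon_count < 0:
                raise NetworkValidationError(f"{m.id}: negative carbon count")
            if (
                m.carbon_count == 0
                and not m.is_cofactor
                and m.id not in ("NH4", "ENH4")
            ):
                raise NetworkValidationError(
                    f"{m.id}: zero carbon count on a non-cofactor species"
                )
        if not self.reactions:
            raise NetworkValidationError("no biomass reaction (empty reaction list)")
        n_bio = sum(1 for r in self.reactions if r.tag == "biomass")
        if n_bio != 1:
            raise NetworkValidationError(
                "no biomass reaction" if n_bio == 0 else "multiple biomass reactions"
            )
        carbon = {m.id: m.carbon_count for m in self.metabolites}
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in known:
                    raise NetworkValidationError(
                        f"reaction {r.id}: unknown metabolite {met!r}"
                    )
            r.rate_law.validate(known, where=f"reaction {r.id}")
            if r.tag == "biomass":
                continue  # biomass carbon is a sink by construction
            balance = sum(
                c * carbon[met]
                for met, c in r.stoichiometry.items()
                if not self.metabolite(met).is_cofactor
            )
            if abs(balance) > 1e-9:
                raise NetworkValidationError(
                    f"reaction {r.id}: carbon unbalanced by {balance:+g}"
                )
            for a, b in COFACTOR_PAIRS:
                ca = r.stoichiometry.get(a, 0.0)
                cb = r.stoichiometry.get(b, 0.0)
                if abs(ca + cb) > 1e-9:
                    raise NetworkValidationError(
                        f"reaction {r.id}: cofactor pair {a}/{b} not conserved"
                    )
        for met, d in self.biomass.items():
            if met not in known:
                raise NetworkValidationError(f"biomass: unknown metabolite {met!r}")
        for met, _ in self.growth.monod:
            if met not in known:
                raise NetworkValidationError(f"growth: unknown metabolite {met!r}")

    # -- compiled kinetics --------------------------------------------------
    def compiled(self) -> "_CompiledKinetics":
        if self._compiled is None:
            self._compiled = _CompiledKinetics(self)
        return self._compiled


class _CompiledKinetics:
    """Flat index arrays for vectorized flux evaluation.

    Evaluation broadcasts over a trailing axis, so a state of shape
    (n_species,) or (n_species, m) yields fluxes (n_rxn,) or (n_rxn, m).
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        idx = model.species_index
        n_rxn = len(model.reactions)
        self.n_rxn = n_rxn
        self.vmax_f = np.array([r.rate_law.vmax_f for r in model.reactions])
        self.vmax_r = np.array([r.rate_law.vmax_r for r in model.reactions])
        self.oxy = np.array([r.oxygen_sensitive for r in model.reactions])
        self.bio_j = next(
            j for j, r in enumerate(model.reactions) if r.tag == "biomass"
        )

        def flat(getter):
            rx, sp, kk = [], [], []
            for j, r in enumerate(model.reactions):
                for met, k in getter(r.rate_law):
                    rx.append(j)
                    sp.append(idx[met])
                    kk.append(k)
            return np.array(rx, dtype=int), np.array(sp, dtype=int), np.array(kk)

        def flat_ratio(getter):
            rx, num, den, kk = [], [], [], []
            for j, r in enumerate(model.reactions):
                for (a, b), k in getter(r.rate_law):
                    rx.append(j)
                    num.append(idx[a])
                    den.append(idx[b])
                    kk.append(k)
            return (
                np.array(rx, dtype=int),
                np.array(num, dtype=int),
                np.array(den, dtype=int),
                np.array(kk),
            )

        self.sat_f = flat(lambda rl: rl.saturation_factors)
        self.inh_f = flat(lambda rl: rl.inhibition_factors)
        self.rat_f = flat_ratio(lambda rl: rl.ratio_factors)
        self.sat_r = flat(lambda rl: rl.rev_saturation_factors)
        self.inh_r = flat(lambda rl: rl.rev_inhibition_factors)
        self.rat_r = flat_ratio(lambda rl: rl.rev_ratio_factors)

        def groups(rx):
            """reduceat segment starts + target reaction per segment."""
            if len(rx) == 0:
                return np.array([], dtype=int), np.array([], dtype=int)
            starts = np.concatenate(([0], np.nonzero(np.diff(rx))[0] + 1))
            return starts, rx[starts]

        self.sat_f_g = groups(self.sat_f[0])
        self.inh_f_g = groups(self.inh_f[0])
        self.rat_f_g = groups(self.rat_f[0])
        self.sat_r_g = groups(self.sat_r[0])
        self.inh_r_g = groups(self.inh_r[0])
        self.rat_r_g = groups(self.rat_r[0])

        self.mu_max = model.growth.mu_max
        self.monod_sp = np.array([idx[m] for m, _ in model.growth.monod], dtype=int)
        self.monod_km = np.array([k for _, k in model.growth.monod])

        self.S = model.stoichiometric_matrix()
        self.ext_rows = np.array([idx[s] for s in model.ext_ids], dtype=int)
        self.int_rows = np.array([idx[s] for s in model.int_ids], dtype=int)

    def growth_rate(self, s: np.ndarray):
        mu = self.mu_max * np.ones(s.shape[1:]) if s.ndim > 1 else self.mu_max
        if len(self.monod_sp):
            c = np.maximum(s[self.monod_sp], 0.0)
            km = self.monod_km.reshape((-1,) + (1,) * (s.ndim - 1))
            mu = mu * np.prod(c / (km + c), axis=0)
        return mu

    def fluxes_split(self, s: np.ndarray, oxygen_level: float = 1.0):
        """Gross forward and reverse fluxes at state ``s`` (clipped at 0)."""
        s = np.asarray(s, dtype=float)
        c = np.maximum(s, 0.0)
        tail = s.shape[1:]

        if not tail:
            vf = self.vmax_f.copy()
            vr = self.vmax_r.copy()

            def apply(v, sat, inh, rat, sat_g, inh_g, rat_g):
                rx, sp, kk = sat
                if len(rx):
                    f = c[sp] / (kk + c[sp])
                    starts, tgt = sat_g
                    v[tgt] *= np.multiply.reduceat(f, starts)
                rx, sp, kk = inh
                if len(rx):
                    f = kk / (kk + c[sp])
                    starts, tgt = inh_g
                    v[tgt] *= np.multiply.reduceat(f, starts)
                rx, num, den, kk = rat
                if len(rx):
                    ratio = c[num] / np.maximum(c[den], _EPS)
                    f = ratio / (kk + ratio)
                    starts, tgt = rat_g
                    v[tgt] *= np.multiply.reduceat(f, starts)

            apply(vf, self.sat_f, self.inh_f, self.rat_f,
                  self.sat_f_g, self.inh_f_g, self.rat_f_g)
            apply(vr, self.sat_r, self.inh_r, self.rat_r,
                  self.sat_r_g, self.inh_r_g, self.rat_r_g)
        else:
            vf = np.broadcast_to(
                self.vmax_f.reshape((-1,) + (1,) * len(tail)), (self.n_rxn,) + tail
            ).copy()
            vr = np.broadcast_to(
                self.vmax_r.reshape((-1,) + (1,) * len(tail)), (self.n_rxn,) + tail
            ).copy()

            def apply(v, sat, inh, rat):
                rx, sp, kk = sat
                if len(rx):
                    kk = kk.reshape((-1,) + (1,) * len(tail))
                    np.multiply.at(v, rx, c[sp] / (kk + c[sp]))
                rx, sp, kk = inh
                if len(rx):
                    kk = kk.reshape((-1,) + (1,) * len(tail))
                    np.multiply.at(v, rx, kk / (kk + c[sp]))
                rx, num, den, kk = rat
                if len(rx):
                    kk = kk.reshape((-1,) + (1,) * len(tail))
                    ratio = c[num] / np.maximum(c[den], _EPS)
                    np.multiply.at(v, rx, ratio / (kk + ratio))

            apply(vf, self.sat_f, self.inh_f, self.rat_f)
            apply(vr, self.sat_r, self.inh_r, self.rat_r)
        if oxygen_level != 1.0 or True:
            o2f = oxygen_level / (self.model.km_o2 + oxygen_level) if oxygen_level > 0 else 0.0
            o2n = 1.0 / (self.model.km_o2 + 1.0)
            vf[self.oxy] *= o2f / o2n
            vr[self.oxy] *= o2f / o2n
        mu = self.growth_rate(s)
        # biomass drain shuts off as any precursor pool nears exhaustion
        vf[self.bio_j] = mu * vf[self.bio_j]
        vr[self.bio_j] = 0.0
        return vf, vr

    def fluxes(self, s, oxygen_level: float = 1.0):
        vf, vr = self.fluxes_split(s, oxygen_level)
        return vf - vr


# ---------------------------------------------------------------------------
# Culture condition and trajectory containers
# ---------------------------------------------------------------------------

#: Background E8-like medium for species not set by a condition table (mM).
DEFAULT_MEDIUM = {
    "EGLC": 17.0,
    "EGLN": 2.0,
    "ELAC": 0.0,
    "EPYR": 0.0,
    "EGLU": 0.1,
    "EALA": 0.1,
    "ENH4": 0.0,
    "ESER": 0.4,
    "EVAL": 0.45,
    "ELEU": 0.5,
    "EILE": 0.45,
    "EPRO": 0.35,
}


@dataclass
class CultureCondition:
    """Initial state and environment of one culture run."""

    initial_concentrations: dict[str, float]
    initial_vcd: float
    duration_h: float = 48.0
    oxygen_level: float = 1.0
    oxygen_schedule: list | None = None  # [(t_start, level)], overrides scalar
    tracer: object | None = None
    label: str = ""

    def validate(self) -> None:
        for met, c in self.initial_concentrations.items():
            if c < 0:
                raise ValueError(f"negative initial concentration for {met}")
        if not 0.0 <= self.oxygen_level <= 1.0:
            raise ValueError("oxygen_level must lie in [0, 1]")
        if self.initial_vcd < 0:
            raise ValueError("negative initial VCD")

    def oxygen_at(self, t: float) -> float:
        if not self.oxygen_schedule:
            return self.oxygen_level
        level = self.oxygen_schedule[0][1]
        for t0, lv in self.oxygen_schedule:
            if t >= t0 - 1e-12:
                level = lv
        return level

    def medium(self, ext_ids: Sequence[str]) -> np.ndarray:
        base = dict(DEFAULT_MEDIUM)
        base.update(self.initial_concentrations)
        return np.array([base.get(s, 0.0) for s in ext_ids])


@dataclass
class Trajectory:
    """Time-resolved culture state: VCD, concentrations, pools, fluxes."""

    times: np.ndarray
    vcd: np.ndarray
    ext_ids: list[str]
    extracellular: np.ndarray  # (nt, n_ext) mM
    int_ids: list[str]
    intracellular: np.ndarray  # (nt, n_int) mmol/1e9 cells
    reaction_ids: list[str]
    fluxes: np.ndarray  # (nt, n_rxn) net, mmol/1e9 cells/h
    fluxes_forward: np.ndarray | None = None
    fluxes_reverse: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def conc(self, species: str) -> np.ndarray:
        if species in self.ext_ids:
            return self.extracellular[:, self.ext_ids.index(species)]
        if species in self.int_ids:
            return self.intracellular[:, self.int_ids.index(species)]
        raise KeyError(species)

    def state_at(self, t: float) -> dict[str, float]:
        out: dict[str, float] = {}
        for ids, mat in ((self.ext_ids, self.extracellular), (self.int_ids, self.intracellular)):
            for k, s in enumerate(ids):
                out[s] = float(np.interp(t, self.times, mat[:, k]))
        return out

    def flux_interpolators(self):
        """(times, forward, reverse) arrays for label propagation."""
        vf = self.fluxes_forward
        vr = self.fluxes_reverse
        if vf is None:
            vf = np.maximum(self.fluxes, 0.0)
            vr = np.maximum(-self.fluxes, 0.0)
        return self.times, vf, vr


# ---------------------------------------------------------------------------
# Rate-law closures printed in the model description
# ---------------------------------------------------------------------------


def ldh_flux(state: Mapping[str, float], params: RateLaw) -> float:
    """Net lactate dehydrogenase flux with pyruvate inhibition (R1).

    ``v = vmax_f * PYR/(Km+PYR) * (NADH/NAD)/(Km+NADH/NAD) * Ki/(Ki+EPYR)
    - vmax_r * LAC/(Km+LAC) * (NAD/NADH)/(Km+NAD/NADH)``
    """
    if state.get("NAD", 0.0) <= 0.0 or state.get("NADH", 0.0) <= 0.0:
        raise ValueError("LDH ratio terms undefined: NAD and NADH must be > 0")
    return _eval_rate_law(state, params)


def glns_flux(state: Mapping[str, float], params: RateLaw) -> float:
    """Net glutamine consumption flux with pyruvate inhibition (R2).

    ``v = vmax_f * GLN/(Km+GLN) * Ki/(Ki+EPYR)
    - vmax_r * GLU/(Km+GLU) * NH4/(Km+NH4)``
    """
    for met in ("GLN", "GLU", "NH4", "EPYR"):
        if state.get(met, 0.0) < 0.0:
            raise ValueError(f"negative concentration for {met}")
    return _eval_rate_law(state, params)


def _eval_rate_law(state: Mapping[str, float], rl: RateLaw) -> float:
    def product(sats, inhs, rats):
        p = 1.0
        for met, km in sats:
            c = state[met]
            p *= c / (km + c)
        for met, ki in inhs:
            p *= ki / (ki + state[met])
        for (a, b), km in rats:
            r = state[a] / max(state[b], _EPS)
            p *= r / (km + r)
        return p

    vf = rl.vmax_f * product(
        rl.saturation_factors, rl.inhibition_factors, rl.ratio_factors
    )
    vr = rl.vmax_r * product(
        rl.rev_saturation_factors, rl.rev_inhibition_factors, rl.rev_ratio_factors
    )
    return vf - vr


def evaluate_all_fluxes(
    model: NetworkModel,
    state: Mapping[str, float] | np.ndarray,
    oxygen_level: float = 1.0,
) -> dict[str, float] | np.ndarray:
    """Net flux of every reaction at the given state.

    ``state`` may be a mapping (returns a dict) or a full state vector in
    model species order (returns an array; a trailing axis broadcasts).
    """
    ck = model.compiled()
    if isinstance(state, Mapping):
        missing = [s for s in model.species_ids if s not in state]
        if missing:
            raise KeyError(f"state missing species: {missing}")
        vec = np.array([state[s] for s in model.species_ids])
        v = ck.fluxes(vec, oxygen_level)
        return dict(zip(model.reaction_ids, v))
    return ck.fluxes(np.asarray(state, dtype=float), oxygen_level)


def redox_ratio(state: Mapping[str, float], modality: str = "enzymatic") -> float:
    """Cofactor redox ratio in [0, 1].

    enzymatic: NAD+/(NAD+ + NADH); optical: FAD/(FAD + NAD(P)H), with NADH
    standing in for NAD(P)H since the model has no NADPH pool.
    """
    if modality == "enzymatic":
        a, b = state["NAD"], state["NADH"]
    elif modality == "optical":
        a, b = state["FAD"], state["NADH"]
    else:
        raise ValueError(f"unknown modality {modality!r}")
    if a + b <= 0:
        raise ValueError("redox ratio undefined: both cofactors are zero")
    return float(a / (a + b))


# ---------------------------------------------------------------------------
# Monolayer simulation
# ---------------------------------------------------------------------------


def simulate_monolayer(
    model: NetworkModel,
    condition: CultureCondition,
    times: Sequence[float],
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the homogeneous (monolayer) culture ODEs.

    ``dX/dt = mu(s) X``, ``dC_ext/dt = q_ext(s) X * 1e-6`` and
    ``ds_int/dt = S_int v`` with a stiff implicit solver.  The oxygen
    schedule, if present, splits the integration at its breakpoints.
    """
    condition.validate()
    times = np.asarray(times, dtype=float)
    if times[0] < 0 or times[-1] > condition.duration_h + 1e-9:
        raise ValueError("requested times outside the condition duration")
    ck = model.compiled()
    n_ext, n_int = len(model.ext_ids), len(model.int_ids)
    ext0 = condition.medium(model.ext_ids)
    int0 = np.array(
        [model.initial_intracellular.get(s, 0.0) for s in model.int_ids]
    )
    y0 = np.concatenate(([condition.initial_vcd], ext0, int0))

    S_ext = ck.S[ck.ext_rows, :]
    S_int = ck.S[ck.int_rows, :]

    def rhs(t, y, o2):
        X = max(y[0], 0.0)
        full = np.empty(len(model.species_ids))
        full[ck.ext_rows] = y[1 : 1 + n_ext]
        full[ck.int_rows] = y[1 + n_ext :]
        v = ck.fluxes(full, o2)
        dX = ck.growth_rate(full) * X
        dC = S_ext @ v * X * VCD_FLUX_TO_MM_PER_H
        ds = S_int @ v
        return np.concatenate(([dX], dC, ds))

    # breakpoints from the oxygen schedule
    breaks = [0.0, float(times[-1])]
    if condition.oxygen_schedule:
        breaks += [t for t, _ in condition.oxygen_schedule if 0 < t < times[-1]]
    breaks = sorted(set(breaks))

    t_out: list[np.ndarray] = []
    y_out: list[np.ndarray] = []
    y = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        o2 = condition.oxygen_at(0.5 * (a + b))
        seg = times[(times >= a - 1e-12) & (times <= b + 1e-12)]
        seg_eval = np.unique(np.concatenate((seg, [a, b])))
        sol = solve_ivp(
            rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=seg_eval,
            args=(o2,),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"monolayer ODE solver failed at t={sol.t[-1] if len(sol.t) else a}: "
                f"{sol.message}; last state {sol.y[:, -1] if sol.y.size else y}"
            )
        keep = np.isin(sol.t, seg)
        t_out.append(sol.t[keep])
        y_out.append(sol.y[:, keep])
        y = sol.y[:, -1]

    tt = np.concatenate(t_out)
    yy = np.concatenate(y_out, axis=1)
    order = np.argsort(tt)
    # drop duplicates at segment boundaries
    tt = tt[order]
    yy = yy[:, order]
    uniq = np.concatenate(([True], np.diff(tt) > 1e-12))
    tt, yy = tt[uniq], yy[:, uniq]

    if np.min(yy[1:, :]) < -100 * atol:
        raise RuntimeError(
            f"negative concentration beyond tolerance: min={np.min(yy[1:, :]):g}"
        )

    nt = len(tt)
    vflux = np.empty((nt, ck.n_rxn))
    vff = np.empty((nt, ck.n_rxn))
    vfr = np.empty((nt, ck.n_rxn))
    for k in range(nt):
        full = np.empty(len(model.species_ids))
        full[ck.ext_rows] = yy[1 : 1 + n_ext, k]
        full[ck.int_rows] = yy[1 + n_ext :, k]
        f, r = ck.fluxes_split(full, condition.oxygen_at(tt[k]))
        vff[k], vfr[k] = f, r
        vflux[k] = f - r
    return Trajectory(
        times=tt,
        vcd=yy[0],
        ext_ids=list(model.ext_ids),
        extracellular=yy[1 : 1 + n_ext].T,
        int_ids=list(model.int_ids),
        intracellular=yy[1 + n_ext :].T,
        reaction_ids=list(model.reaction_ids),
        fluxes=vflux,
        fluxes_forward=vff,
        fluxes_reverse=vfr,
    )


def specific_rate(trajectory: Trajectory, species: str) -> float:
    """Cell-specific consumption rate over the whole trajectory window.

    Uses the log-mean VCD integral standard in batch-culture analysis:
    ``q = -dC / (1e-6 * int X dt)`` with the integral taken piecewise under
    an exponential-growth assumption between sampling points.  Consumption
    (falling concentration) yields a positive rate.
    """
    t = trajectory.times
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time axis")
    X = trajectory.vcd
    if np.any(X <= 0):
        raise ValueError("VCD must stay positive over the window")
    C = trajectory.conc(species)
    integral = 0.0
    for k in range(len(t) - 1):
        x1, x2, dt = X[k], X[k + 1], t[k + 1] - t[k]
        if abs(x2 - x1) < 1e-9 * max(x1, x2):
            integral += x1 * dt
        else:
            integral += (x2 - x1) / math.log(x2 / x1) * dt
    return float(-(C[-1] - C[0]) / (integral * VCD_FLUX_TO_MM_PER_H))


def apply_perturbation(
    condition: CultureCondition,
    kind: str,
    schedule: tuple[float, float] | None = None,
) -> CultureCondition:
    """Return a condition modified for a redox-perturbation experiment.

    ``glucose_starvation`` zeroes initial glucose; ``hypoxia`` sets the
    oxygen level to 0 over ``schedule = (t_on, t_off)`` and restores it.
    """
    out = copy.deepcopy(condition)
    if kind == "normal":
        return out
    if kind == "glucose_starvation":
        out.initial_concentrations = dict(out.initial_concentrations)
        out.initial_concentrations["EGLC"] = 0.0
        return out
    if kind == "hypoxia":
        t_on, t_off = schedule if schedule is not None else (0.0, out.duration_h)
        if not (0 <= t_on < t_off <= out.duration_h + 1e-9):
            raise ValueError("hypoxia schedule outside the condition duration")
        base = out.oxygen_level
        out.oxygen_schedule = [(0.0, base), (t_on, 0.0), (t_off, base)]
        return out
    raise ValueError(f"unknown perturbation kind {kind!r}")


# ---------------------------------------------------------------------------
# Default 29-reaction network
# ---------------------------------------------------------------------------


def _met(mid, comp, c=0, cof=False):
    return {"id": mid, "compartment": comp, "carbon_count": c, "is_cofactor": cof}


def default_network_config() -> dict:
    """Configuration dict for the shipped 29-reaction iPSC network.

    The reaction list follows the published network topology (lumped
    glycolysis, reversible LDH with R1, TCA cycle with FADH2 at succinate
    dehydrogenase, reversible glutaminolysis with R2, transaminases,
    oxidative phosphorylation at P/O 2.5 and 1.5, amino-acid transport and
    one biomass reaction); the kinetic parameter values are non-canonical
    defaults at literature scale, fit only to the synthetic study.
    """
    mets = [
        # extracellular (E prefix)
        _met("EGLC", "extracellular", 6),
        _met("ELAC", "extracellular", 3),
        _met("EPYR", "extracellular", 3),
        _met("EGLN", "extracellular", 5),
        _met("EGLU", "extracellular", 5),
        _met("EALA", "extracellular", 3),
        _met("ENH4", "extracellular", 0),
        _met("ESER", "extracellular", 3),
        _met("EVAL", "extracellular", 5),
        _met("ELEU", "extracellular", 6),
        _met("EILE", "extracellular", 6),
        _met("EPRO", "extracellular", 5),
        # intracellular carbon pools
        _met("PYR", "intracellular", 3),
        _met("LAC", "intracellular", 3),
        _met("ACCOA", "intracellular", 2),
        _met("CIT", "intracellular", 6),
        _met("AKG", "intracellular", 5),
        _met("SUC", "intracellular", 4),
        _met("FUM", "intracellular", 4),
        _met("MAL", "intracellular", 4),
        _met("OAA", "intracellular", 4),
        _met("GLN", "intracellular", 5),
        _met("GLU", "intracellular", 5),
        _met("ALA", "intracellular", 3),
        _met("ASP", "intracellular", 4),
        _met("ASN", "intracellular", 4),
        _met("SER", "intracellular", 3),
        _met("VAL", "intracellular", 5),
        _met("LEU", "intracellular", 6),
        _met("ILE", "intracellular", 6),
        _met("PRO", "intracellular", 5),
        _met("NH4", "intracellular", 0),
        _met("CO2", "intracellular", 1),
        # cofactors
        _met("NAD", "intracellular", 0, True),
        _met("NADH", "intracellular", 0, True),
        _met("FAD", "intracellular", 0, True),
        _met("FADH2", "intracellular", 0, True),
    ]

    def rxn(rid, stoich, rate, tag="other", atom_map=None, oxy=False):
        d = {"id": rid, "stoichiometry": stoich, "rate_law": rate, "tag": tag}
        if atom_map:
            d["atom_map"] = atom_map
        if oxy:
            d["oxygen_sensitive"] = True
        return d

    def amap(reactants, products, weight=1.0):
        return {"weight": weight, "reactants": reactants, "products": products}

    rxns = [
        # Lumped glycolysis doubles as the glucose-uptake step; R0 lactate
        # inhibition acts here (same algebraic family as R1/R2).
        rxn(
            "GLYC",
            {"EGLC": -1, "NAD": -2, "PYR": 2, "NADH": 2},
            {
                "vmax_f": 0.4,
                "saturation_factors": [["EGLC", 0.5], ["NAD", 0.02]],
                "inhibition_factors": [["ELAC", 35.0], ["PYR", 0.3]],
            },
            tag="glycolysis",
            atom_map=[amap([["EGLC", "abcdef"]], [["PYR", "cba"], ["PYR", "def"]])],
        ),
        rxn(
            "LDH",
            {"PYR": -1, "NADH": -1, "LAC": 1, "NAD": 1},
            {
                "vmax_f": 4.0,
                "vmax_r": 0.2,
                "saturation_factors": [["PYR", 0.25]],
                "ratio_factors": [[["NADH", "NAD"], 0.15]],
                "inhibition_factors": [["EPYR", 2.0]],
                "rev_saturation_factors": [["LAC", 1.5]],
                "rev_ratio_factors": [[["NAD", "NADH"], 3.0]],
            },
            tag="redox",
            atom_map=[amap([["PYR", "abc"]], [["LAC", "abc"]])],
        ),
        rxn(
            "PDH",
            {"PYR": -1, "NAD": -1, "ACCOA": 1, "CO2": 1, "NADH": 1},
            {
                "vmax_f": 0.22,
                "saturation_factors": [["PYR", 0.3], ["NAD", 0.05]],
            },
            tag="TCA",
            atom_map=[amap([["PYR", "abc"]], [["CO2", "a"], ["ACCOA", "bc"]])],
        ),
        rxn(
            "PC",
            {"PYR": -1, "CO2": -1, "OAA": 1},
            {
                "vmax_f": 0.05,
                "saturation_factors": [["PYR", 0.3], ["CO2", 0.5]],
            },
            tag="anaplerosis",
            atom_map=[amap([["PYR", "abc"], ["CO2", "d"]], [["OAA", "abcd"]])],
        ),
        rxn(
            "CS",
            {"ACCOA": -1, "OAA": -1, "CIT": 1},
            {
                "vmax_f": 0.22,
                "saturation_factors": [["ACCOA", 0.05], ["OAA", 0.05]],
            },
            tag="TCA",
            atom_map=[amap([["ACCOA", "ab"], ["OAA", "cdef"]], [["CIT", "abcdef"]])],
        ),
        rxn(
            "IDH",
            {"CIT": -1, "NAD": -1, "AKG": 1, "CO2": 1, "NADH": 1},
            {
                "vmax_f": 0.22,
                "saturation_factors": [["CIT", 0.3], ["NAD", 0.05]],
            },
            tag="TCA",
            atom_map=[amap([["CIT", "abcdef"]], [["AKG", "abcde"], ["CO2", "f"]])],
        ),
        rxn(
            "AKGDH",
            {"AKG": -1, "NAD": -1, "SUC": 1, "CO2": 1, "NADH": 1},
            {
                "vmax_f": 0.25,
                "saturation_factors": [["AKG", 0.3], ["NAD", 0.05]],
            },
            tag="TCA",
            atom_map=[amap([["AKG", "abcde"]], [["CO2", "a"], ["SUC", "bcde"]])],
        ),
        rxn(
            "SDH",
            {"SUC": -1, "FAD": -1, "FUM": 1, "FADH2": 1},
            {
                "vmax_f": 0.25,
                "saturation_factors": [["SUC", 0.2], ["FAD", 0.01]],
            },
            tag="TCA",
            atom_map=[amap([["SUC", "abcd"]], [["FUM", "abcd"]])],
        ),
        # fumarate is symmetric: 50/50 scrambling on consumption
        rxn(
            "FUMASE",
            {"FUM": -1, "MAL": 1},
            {
                "vmax_f": 0.3,
                "vmax_r": 0.03,
                "saturation_factors": [["FUM", 0.15]],
                "rev_saturation_factors": [["MAL", 0.3]],
            },
            tag="TCA",
            atom_map=[
                amap([["FUM", "abcd"]], [["MAL", "abcd"]], 0.5),
                amap([["FUM", "abcd"]], [["MAL", "dcba"]], 0.5),
            ],
        ),
        rxn(
            "MDH",
            {"MAL": -1, "NAD": -1, "OAA": 1, "NADH": 1},
            {
                "vmax_f": 0.3,
                "vmax_r": 0.03,
                "saturation_factors": [["MAL", 0.3]],
                "ratio_factors": [[["NAD", "NADH"], 1.0]],
                "rev_saturation_factors": [["OAA", 0.05]],
                "rev_ratio_factors": [[["NADH", "NAD"], 0.3]],
            },
            tag="TCA",
            atom_map=[amap([["MAL", "abcd"]], [["OAA", "abcd"]])],
        ),
        # R2 pyruvate inhibition on the forward glutaminolysis term
        rxn(
            "GLNS",
            {"GLN": -1, "GLU": 1, "NH4": 1},
            {
                "vmax_f": 0.15,
                "vmax_r": 0.02,
                "saturation_factors": [["GLN", 1.0]],
                "inhibition_factors": [["EPYR", 2.0]],
                "rev_saturation_factors": [["GLU", 4.0], ["NH4", 1.0]],
            },
            tag="anaplerosis",
            atom_map=[amap([["GLN", "abcde"]], [["GLU", "abcde"]])],
        ),
        rxn(
            "GDH",
            {"GLU": -1, "NAD": -1, "AKG": 1, "NH4": 1, "NADH": 1},
            {
                "vmax_f": 0.08,
                "saturation_factors": [["GLU", 4.0], ["NAD", 0.05]],
            },
            tag="anaplerosis",
            atom_map=[amap([["GLU", "abcde"]], [["AKG", "abcde"]])],
        ),
        rxn(
            "ALT",
            {"PYR": -1, "GLU": -1, "ALA": 1, "AKG": 1},
            {
                "vmax_f": 0.1,
                "vmax_r": 0.01,
                "saturation_factors": [["PYR", 0.3], ["GLU", 4.0]],
                "rev_saturation_factors": [["ALA", 1.0], ["AKG", 0.3]],
            },
            tag="anaplerosis",
            atom_map=[
                amap(
                    [["PYR", "abc"], ["GLU", "defgh"]],
                    [["ALA", "abc"], ["AKG", "defgh"]],
                )
            ],
        ),
        rxn(
            "AST",
            {"OAA": -1, "GLU": -1, "ASP": 1, "AKG": 1},
            {
                "vmax_f": 0.06,
                "vmax_r": 0.01,
                "saturation_factors": [["OAA", 0.05], ["GLU", 4.0]],
                "rev_saturation_factors": [["ASP", 1.0], ["AKG", 0.3]],
            },
            tag="anaplerosis",
            atom_map=[
                amap(
                    [["OAA", "abcd"], ["GLU", "efghi"]],
                    [["ASP", "abcd"], ["AKG", "efghi"]],
                )
            ],
        ),
        rxn(
            "ASNS",
            {"ASP": -1, "NH4": -1, "ASN": 1},
            {
                "vmax_f": 0.02,
                "saturation_factors": [["ASP", 1.0], ["NH4", 0.5]],
            },
            tag="anaplerosis",
            atom_map=[amap([["ASP", "abcd"]], [["ASN", "abcd"]])],
        ),
        rxn(
            "OXPHOS_NADH",
            {"NADH": -1, "NAD": 1},
            {
                "vmax_f": 1.0,
                "saturation_factors": [["NADH", 0.1]],
            },
            tag="redox",
            oxy=True,
        ),
        rxn(
            "OXPHOS_FADH2",
            {"FADH2": -1, "FAD": 1},
            {
                "vmax_f": 0.4,
                "saturation_factors": [["FADH2", 0.005]],
            },
            tag="redox",
            oxy=True,
        ),
        # transporters (forward = physiological net direction)
        rxn(
            "LACT",
            {"LAC": -1, "ELAC": 1},
            {
                "vmax_f": 1.8,
                "vmax_r": 0.05,
                "saturation_factors": [["LAC", 1.0]],
                "rev_saturation_factors": [["ELAC", 5.0]],
            },
            tag="transport",
            atom_map=[amap([["LAC", "abc"]], [["ELAC", "abc"]])],
        ),
        rxn(
            "PYRT",
            {"EPYR": -1, "PYR": 1},
            {
                "vmax_f": 0.25,
                "vmax_r": 0.05,
                "saturation_factors": [["EPYR", 0.5]],
                "rev_saturation_factors": [["PYR", 0.5]],
            },
            tag="transport",
            atom_map=[amap([["EPYR", "abc"]], [["PYR", "abc"]])],
        ),
        rxn(
            "GLNT",
            {"EGLN": -1, "GLN": 1},
            {
                "vmax_f": 0.11,
                "vmax_r": 0.02,
                "saturation_factors": [["EGLN", 0.5]],
                "rev_saturation_factors": [["GLN", 2.0]],
            },
            tag="transport",
            atom_map=[amap([["EGLN", "abcde"]], [["GLN", "abcde"]])],
        ),
        rxn(
            "GLUT",
            {"GLU": -1, "EGLU": 1},
            {
                "vmax_f": 0.03,
                "vmax_r": 0.01,
                "saturation_factors": [["GLU", 4.0]],
                "rev_saturation_factors": [["EGLU", 1.0]],
            },
            tag="transport",
            atom_map=[amap([["GLU", "abcde"]], [["EGLU", "abcde"]])],
        ),
        rxn(
            "ALAT",
            {"ALA": -1, "EALA": 1},
            {
                "vmax_f": 0.12,
                "vmax_r": 0.02,
                "saturation_factors": [["ALA", 1.0]],
                "rev_saturation_factors": [["EALA", 2.0]],
            },
            tag="transport",
            atom_map=[amap([["ALA", "abc"]], [["EALA", "abc"]])],
        ),
        rxn(
            "NH4T",
            {"NH4": -1, "ENH4": 1},
            {
                "vmax_f": 0.25,
                "vmax_r": 0.01,
                "saturation_factors": [["NH4", 0.5]],
                "rev_saturation_factors": [["ENH4", 2.0]],
            },
            tag="transport",
        ),
        rxn(
            "SERT",
            {"ESER": -1, "SER": 1},
            {
                "vmax_f": 0.02,
                "vmax_r": 0.01,
                "saturation_factors": [["ESER", 0.2]],
                "rev_saturation_factors": [["SER", 1.0]],
            },
            tag="transport",
            atom_map=[amap([["ESER", "abc"]], [["SER", "abc"]])],
        ),
        rxn(
            "VALT",
            {"EVAL": -1, "VAL": 1},
            {
                "vmax_f": 0.018,
                "vmax_r": 0.01,
                "saturation_factors": [["EVAL", 0.3]],
                "rev_saturation_factors": [["VAL", 1.0]],
            },
            tag="transport",
            atom_map=[amap([["EVAL", "abcde"]], [["VAL", "abcde"]])],
        ),
        rxn(
            "LEUT",
            {"ELEU": -1, "LEU": 1},
            {
                "vmax_f": 0.025,
                "vmax_r": 0.012,
                "saturation_factors": [["ELEU", 0.3]],
                "rev_saturation_factors": [["LEU", 1.0]],
            },
            tag="transport",
            atom_map=[amap([["ELEU", "abcdef"]], [["LEU", "abcdef"]])],
        ),
        rxn(
            "ILET",
            {"EILE": -1, "ILE": 1},
            {
                "vmax_f": 0.018,
                "vmax_r": 0.01,
                "saturation_factors": [["EILE", 0.3]],
                "rev_saturation_factors": [["ILE", 1.0]],
            },
            tag="transport",
            atom_map=[amap([["EILE", "abcdef"]], [["ILE", "abcdef"]])],
        ),
        rxn(
            "PROT",
            {"EPRO": -1, "PRO": 1},
            {
                "vmax_f": 0.015,
                "vmax_r": 0.01,
                "saturation_factors": [["EPRO", 0.3]],
                "rev_saturation_factors": [["PRO", 1.0]],
            },
            tag="transport",
            atom_map=[amap([["EPRO", "abcde"]], [["PRO", "abcde"]])],
        ),
    ]

    biomass = {
        "PYR": 1.2,
        "ACCOA": 0.6,
        "GLN": 0.35,
        "GLU": 0.3,
        "ALA": 0.15,
        "ASP": 0.25,
        "ASN": 0.08,
        "SER": 0.3,
        "VAL": 0.25,
        "LEU": 0.35,
        "ILE": 0.25,
        "PRO": 0.2,
    }
    bio_stoich = {met: -d for met, d in biomass.items()}
    avail = [[met, 0.005] for met in biomass]
    rxns.append(
        rxn(
            "BIOMASS",
            bio_stoich,
            {"vmax_f": 1.0, "saturation_factors": avail},
            tag="biomass",
        )
    )

    return {
        "metabolites": mets,
        "reactions": rxns,
        "biomass": biomass,
        "growth": {
            "mu_max": 0.036,
            "monod": [["EGLC", 0.3], ["EGLN", 0.1]],
        },
        "initial_intracellular": {
            "PYR": 0.15,
            "LAC": 1.0,
            "ACCOA": 0.05,
            "CIT": 0.3,
            "AKG": 0.2,
            "SUC": 0.1,
            "FUM": 0.05,
            "MAL": 0.2,
            "OAA": 0.05,
            "GLN": 2.0,
            "GLU": 4.0,
            "ALA": 1.0,
            "ASP": 1.0,
            "ASN": 0.2,
            "SER": 0.5,
            "VAL": 0.3,
            "LEU": 0.3,
            "ILE": 0.3,
            "PRO": 0.3,
            "NH4": 0.5,
            "CO2": 1.0,
            "NAD": 0.7,
            "NADH": 0.3,
            "FAD": 0.09,
            "FADH2": 0.01,
        },
        "km_o2": 0.02,
    }


def load_network(config: dict | str | None = None) -> NetworkModel:
    """Build and validate a NetworkModel from a config dict or YAML path.

    With no argument, returns the shipped 29-reaction default network.
    """
    if config is None:
        config = default_network_config()
    elif isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    mets = [MetaboliteSpec(**m) for m in config["metabolites"]]
    rxns = []
    for r in config["reactions"]:
        rl = RateLaw(
            vmax_f=r["rate_law"].get("vmax_f", 0.0),
            vmax_r=r["rate_law"].get("vmax_r", 0.0),
            saturation_factors=[tuple(x) for x in r["rate_law"].get("saturation_factors", [])],
            inhibition_factors=[tuple(x) for x in r["rate_law"].get("inhibition_factors", [])],
            ratio_factors=[(tuple(p), k) for p, k in r["rate_law"].get("ratio_factors", [])],
            rev_saturation_factors=[tuple(x) for x in r["rate_law"].get("rev_saturation_factors", [])],
            rev_inhibition_factors=[tuple(x) for x in r["rate_law"].get("rev_inhibition_factors", [])],
            rev_ratio_factors=[(tuple(p), k) for p, k in r["rate_law"].get("rev_ratio_factors", [])],
        )
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry=dict(r["stoichiometry"]),
                rate_law=rl,
                atom_map=r.get("atom_map"),
                tag=r.get("tag", "other"),
                oxygen_sensitive=r.get("oxygen_sensitive", False),
            )
        )
    growth = GrowthRate(
        mu_max=config["growth"]["mu_max"],
        monod=[tuple(x) for x in config["growth"].get("monod", [])],
    )
    model = NetworkModel(
        metabolites=mets,
        reactions=rxns,
        biomass=dict(config.get("biomass", {})),
        growth=growth,
        initial_intracellular=dict(config.get("initial_intracellular", {})),
        km_o2=config.get("km_o2", 0.02),
    )
    model.validate()
    return model


def default_network() -> NetworkModel:
    return load_network(None)


def save_network(model: NetworkModel, path: str) -> None:
    """Serialize a NetworkModel back to the YAML config schema."""
    cfg = {
        "metabolites": [
            {
                "id": m.id,
                "compartment": m.compartment,
                "carbon_count": m.carbon_count,
                "is_cofactor": m.is_cofactor,
            }
            for m in model.metabolites
        ],
        "reactions": [],
        "biomass": dict(model.biomass),
        "growth": {
            "mu_max": model.growth.mu_max,
            "monod": [list(x) for x in model.growth.monod],
        },
        "initial_intracellular": dict(model.initial_intracellular),
        "km_o2": model.km_o2,
    }
    for r in model.reactions:
        rl = r.rate_law
        rld = {"vmax_f": rl.vmax_f, "vmax_r": rl.vmax_r}
        for key in (
            "saturation_factors",
            "inhibition_factors",
            "rev_saturation_factors",
            "rev_inhibition_factors",
        ):
            val = getattr(rl, key)
            if val:
                rld[key] = [[m, float(k)] for m, k in val]
        for key in ("ratio_factors", "rev_ratio_factors"):
            val = getattr(rl, key)
            if val:
                rld[key] = [[list(p), float(k)] for p, k in val]
        rd = {
            "id": r.id,
            "stoichiometry": {m: float(c) for m, c in r.stoichiometry.items()},
            "rate_law": rld,
            "tag": r.tag,
        }
        if r.atom_map:
            rd["atom_map"] = r.atom_map
        if r.oxygen_sensitive:
            rd["oxygen_sensitive"] = True
        cfg["reactions"].append(rd)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
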