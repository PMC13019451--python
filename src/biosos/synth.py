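"""Synthetic study-shaped data generators.

Every stage of the pipeline is testable without experimental downloads:
these generators produce monolayer time-course datasets under the eight
glucose/lactate/pyruvate conditions, aggregate diameter samples whose
day-by-day statistics emulate the observed five-day evolution (mean
diameter ~265 um on day 1 rising to ~481 um on day 5 with growing spread),
dual-modality redox ratio series, and tracer MID tables.

All generators are pure functions of their parameters and a seed.  Noise
models: multiplicative Gaussian (fixed CV) for concentrations and cell
densities, additive clipped Gaussian for ratios in [0, 1], and a
simplex-preserving Dirichlet perturbation for MID vectors.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .calibrate import Dataset
from .labeling import LabelingSystem, MIDVector, simulate_mids
from .network import (
    CultureCondition,
    NetworkModel,
    Trajectory,
    default_network,
    redox_ratio,
    simulate_monolayer,
)

__all__ = [
    "generate_monolayer_dataset",
    "generate_condition_suite",
    "generate_aggregate_sizes",
    "generate_redox_series",
    "generate_mid_dataset",
    "TABLE1_CONDITIONS",
    "AGGREGATE_SIZE_STATS",
]

#: condition-table values for the two monolayer studies
TABLE1_CONDITIONS = {
    "historic": {
        "glucose": {"LG": 5.6, "HG": 18.3},
        "lactate": {"LL": 0.0, "HL": 20.0},
        "glutamine": 2.7,
        "pyruvate": 0.41,
        "initial_vcd": 3.2e4,
        "replicates": 6,
        "times": (12.0, 24.0, 36.0, 48.0),
    },
    "pyruvate": {
        "glucose": {"LG": 10.4, "HG": 33.6},
        "lactate": {"LL": 0.0, "HL": 38.0},
        "glutamine": 4.69,
        "pyruvate": 4.4,
        "initial_vcd": 4.8e4,
        "replicates": 2,
        "times": (24.0, 48.0),
    },
}

#: per-day diameter statistics the aggregate-size generator emulates:
#: means interpolate the observed day-1 -> day-5 trajectory
#: (265.4 -> 481.4 um) and the coefficient of variation grows with day.
AGGREGATE_SIZE_STATS = {
    day: {
        "mean": 265.4 + (481.4 - 265.4) * (day - 1) / 4.0,
        "cv": 0.15 + 0.0375 * (day - 1),
    }
    for day in (1, 2, 3, 4, 5)
}

SUITE_VARIABLES = ["VCD", "EGLC", "ELAC", "EPYR", "EGLN", "EGLU", "EALA", "ENH4"]


def generate_monolayer_dataset(
    model: NetworkModel,
    condition: CultureCondition,
    replicates: int,
    noise_cv: float,
    seed: int,
    times: Sequence[float] = (12.0, 24.0, 36.0, 48.0),
    variables: Sequence[str] = SUITE_VARIABLES,
) -> Dataset:
    """Simulated measurements with multiplicative Gaussian noise.

    Each replicate is the model output times (1 + noise_cv * N(0,1)),
    clipped at zero; ``noise_cv = 0`` reproduces the model exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    condition.validate()
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    traj = simulate_monolayer(model, condition, np.concatenate(([0.0], times)))
    keep = np.isin(traj.times, times)
    clean = np.empty((len(times), len(variables)))
    for i, var in enumerate(variables):
        col = traj.vcd if var == "VCD" else traj.conc(var)
        clean[:, i] = col[keep]
    noise = rng.standard_normal((replicates, *clean.shape))
    values = np.maximum(clean[None] * (1.0 + noise_cv * noise), 0.0)
    return Dataset(
        label=condition.label or "synthetic",
        condition=condition,
        times=times,
        variables=list(variables),
        values=values,
    )


def suite_condition(study: str, code: str) -> CultureCondition:
    """Build one of the eight monolayer study conditions (e.g. 'HGLL')."""
    spec = TABLE1_CONDITIONS[study]
    glc = spec["glucose"][code[:2]]
    lac = spec["lactate"][code[2:]]
    return CultureCondition(
        initial_concentrations={
            "EGLC": glc,
            "ELAC": lac,
            "EGLN": spec["glutamine"],
            "EPYR": spec["pyruvate"],
        },
        initial_vcd=spec["initial_vcd"],
        duration_h=48.0,
        label=f"{study}-{code}",
    )


def generate_condition_suite(
    seed: int,
    model: NetworkModel | None = None,
    noise_cv: float = 0.05,
) -> list:
    """The eight-condition monolayer suite (4 historic + 4 pyruvate).

    Initial concentrations, seeding densities, replicate counts and
    measurement schedules follow the study's condition table; noise is
    multiplicative with the given CV.
    """
    if model is None:
        model = default_network()
    out = []
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=8)
    k = 0
    for study in ("historic", "pyruvate"):
        spec = TABLE1_CONDITIONS[study]
        for code in ("HGLL", "HGHL", "LGHL", "LGLL"):
            out.append(
                generate_monolayer_dataset(
                    model,
                    suite_condition(study, code),
                    replicates=spec["replicates"],
                    noise_cv=noise_cv,
                    seed=int(sub[k]),
                    times=spec["times"],
                )
            )
            k += 1
    return out


def generate_aggregate_sizes(day: int, n_samples: int, seed: int) -> np.ndarray:
    """Lognormal aggregate diameters (um) for one culture day (1-5)."""
    if day not in AGGREGATE_SIZE_STATS:
        raise ValueError("day must be in 1..5")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    stats = AGGREGATE_SIZE_STATS[day]
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + stats["cv"] ** 2))
    mu = np.log(stats["mean"]) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, n_samples)


def generate_redox_series(
    modality: str,
    trajectory: Trajectory,
    noise_sd: float,
    seed: int,
    times: Sequence[float] | None = None,
) -> np.ndarray:
    """Redox-ratio time series with additive Gaussian noise clipped to [0,1]."""
    rng = np.random.default_rng(seed)
    if times is None:
        times = trajectory.times
    vals = np.array(
        [redox_ratio(trajectory.state_at(t), modality) for t in times]
    )
    noisy = vals + noise_sd * rng.standard_normal(len(vals))
    return np.clip(noisy, 0.0, 1.0)


def generate_mid_dataset(
    system: LabelingSystem,
    source,
    at_time: float,
    noise_sd: float,
    seed: int,
) -> list:
    """Noisy tracer MIDs: Dirichlet perturbation preserving the simplex.

    The Dirichlet concentration is set so the expectation equals the
    simulated MID exactly (unbiased) with per-channel spread on the order
    of ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    clean = simulate_mids(system, source, at_time)
    if noise_sd <= 0:
        return clean
    out = []
    conc = 1.0 / noise_sd**2
    for mid in clean:
        alpha = np.maximum(mid.fractions, 1e-9) * conc
        out.append(MIDVector(mid.metabolite, rng.dirichlet(alpha)))
    return out
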