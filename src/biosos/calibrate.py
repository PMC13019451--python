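"""Parameter estimation objectives and evaluation metrics.

Implements the study's calibration machinery: the mean-squared-error
objective averaged over datasets, state variables and time points,

    MSE = (1/(K I)) sum_k sum_i (1/T_k) sum_t (y_{i,t}^{(k)} - yhat_{i,t}^{(k)})^2,

the KL-divergence objective for size-distribution fitting (day 1-3 windows),
mean absolute percentage error (MAPE), a bounded multi-start local
optimizer, and a leave-one-out cross-validation harness over culture
conditions.

Because the literal MSE mixes units (mM against cells/mL), each variable is
by default normalized by its per-dataset maximum absolute measurement
before squaring (``normalize=False`` reproduces the literal objective, in
which cell density dominates by roughly 1e4).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .network import (
    CultureCondition,
    NetworkModel,
    Trajectory,
    default_network_config,
    load_network,
    simulate_monolayer,
)
from .pbm import KernelParams, GrowthParams, NumberDensity, simulate_pbm

__all__ = [
    "Dataset",
    "FitResult",
    "mse_loss",
    "kl_loss",
    "mape",
    "fit_parameters",
    "loocv",
    "fit_pbm",
    "predict_dataset",
    "apply_params",
    "make_residual_fn",
]

#: measurement schedules used by the monolayer studies (h)
STUDY_TIME_SETS = (
    (12.0, 24.0, 36.0, 48.0),
    (24.0, 48.0),
    (24.0, 48.0, 72.0),
    (24.0, 48.0, 72.0, 96.0, 120.0),
)


@dataclass
class Dataset:
    """Replicated time-course measurements for one culture condition."""

    label: str
    condition: CultureCondition
    times: np.ndarray  # h
    variables: list  # e.g. ["VCD", "EGLC", ...]
    values: np.ndarray  # (n_replicates, n_times, n_variables)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (
            len(self.times),
            len(self.variables),
        ):
            raise ValueError("values must be (replicates, times, variables)")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one replicate")
        tset = tuple(self.times)
        if not any(set(tset) <= set(s) for s in STUDY_TIME_SETS):
            raise ValueError(
                f"measurement times {tset} match no study schedule"
            )

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class FitResult:
    params: dict
    bounds: dict
    objective: float
    trace: list
    seed: int
    n_starts: int

    def __post_init__(self):
        if not np.isfinite(self.objective):
            raise ValueError("objective must be finite")
        for k, v in self.params.items():
            lo, hi = self.bounds[k]
            if not lo - 1e-12 <= v <= hi + 1e-12:
                raise ValueError(f"estimate for {k} outside its bounds")


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def mse_loss(
    predictions: Sequence[Mapping[str, np.ndarray]],
    datasets: Sequence[Dataset],
    normalize: bool = True,
) -> float:
    """Mean squared error averaged over datasets, variables and times.

    ``predictions[k][var]`` must align with ``datasets[k].times``; replicate
    measurements enter through their mean.  Missing variables or
    mismatched lengths raise.
    """
    if len(predictions) != len(datasets):
        raise ValueError("one prediction set per dataset required")
    K = len(datasets)
    total = 0.0
    n_var = None
    for pred, ds in zip(predictions, datasets):
        y = ds.mean()  # (T, I)
        T, I = y.shape
        if n_var is None:
            n_var = I
        elif I != n_var:
            raise ValueError("datasets measure differing variable sets")
        acc = 0.0
        for i, var in enumerate(ds.variables):
            if var not in pred:
                raise KeyError(f"prediction missing variable {var!r}")
            yhat = np.asarray(pred[var], dtype=float)
            if yhat.shape != (T,):
                raise ValueError(
                    f"prediction for {var} misaligned with measurement times"
                )
            r = y[:, i] - yhat
            if normalize:
                scale = np.abs(y[:, i]).max()
                if scale > 0:
                    r = r / scale
            acc += float(r @ r) / T
        total += acc
    return total / (K * n_var)


def kl_loss(
    observed: Sequence[NumberDensity],
    predicted: Sequence[NumberDensity],
    eps: float = 1e-12,
) -> float:
    """Summed KL divergence between per-time-point size distributions.

    Both densities are normalized per time point; ``eps`` smoothing is
    added to both sides and renormalized to avoid log(0).
    """
    if len(observed) != len(predicted) or not observed:
        raise ValueError("need matching non-empty density lists")
    total = 0.0
    for obs, pred in zip(observed, predicted):
        if obs.grid.n_bins != pred.grid.n_bins or not np.allclose(
            obs.grid.edges, pred.grid.edges
        ):
            raise ValueError("observed and predicted densities on different grids")
        p = obs.counts
        q = pred.counts
        if p.sum() <= 0 or q.sum() <= 0:
            raise ValueError("empty distribution in KL loss")
        p = p + eps
        q = q + eps
        p = p / p.sum()
        q = q / q.sum()
        total += float(np.sum(p * np.log(p / q)))
    return total


def mape(
    predictions: Mapping[str, np.ndarray],
    measurements: Mapping[str, np.ndarray],
) -> dict:
    """Per-variable mean absolute percentage error, 100*mean(|y-yhat|/|y|).

    Zero measurements are excluded with a warning (percentage errors blow
    up at near-zero concentrations).
    """
    out = {}
    for var, y in measurements.items():
        if var not in predictions:
            raise KeyError(f"prediction missing variable {var!r}")
        y = np.asarray(y, dtype=float)
        yhat = np.asarray(predictions[var], dtype=float)
        if y.shape != yhat.shape:
            raise ValueError(f"misaligned series for {var}")
        nz = y != 0
        if not nz.all():
            warnings.warn(
                f"{var}: excluded {int((~nz).sum())} zero measurements from MAPE"
            )
        if not nz.any():
            out[var] = np.nan
            continue
        out[var] = float(100.0 * np.mean(np.abs(y[nz] - yhat[nz]) / np.abs(y[nz])))
    return out


# ---------------------------------------------------------------------------
# model/parameter plumbing
# ---------------------------------------------------------------------------


def apply_params(config: dict, params: Mapping[str, float]) -> dict:
    """Return a config copy with ``{"RXN:vmax_f": v, "growth:mu_max": v}`` set."""
    cfg = copy.deepcopy(config)
    rxn_by_id = {r["id"]: r for r in cfg["reactions"]}
    for key, val in params.items():
        target, attr = key.split(":")
        if target == "growth":
            cfg["growth"][attr] = float(val)
        elif target in rxn_by_id:
            rxn_by_id[target]["rate_law"][attr] = float(val)
        else:
            raise KeyError(f"unknown parameter target {target!r}")
    return cfg


def predict_dataset(model: NetworkModel, dataset: Dataset) -> dict:
    """Simulate the dataset's condition and extract its variables."""
    times = np.concatenate(([0.0], dataset.times))
    traj = simulate_monolayer(model, dataset.condition, times)
    keep = np.isin(traj.times, dataset.times)
    out = {}
    for var in dataset.variables:
        if var == "VCD":
            out[var] = traj.vcd[keep]
        else:
            out[var] = traj.conc(var)[keep]
    return out


def make_residual_fn(
    base_config: dict,
    datasets: Sequence[Dataset],
    names: Sequence[str],
    normalize: bool = True,
) -> Callable:
    """Residual vector (for least-squares fitting) over all datasets.

    Residuals carry the same per-variable normalization and 1/sqrt(T K I)
    weights as ``mse_loss`` so that ||residual||^2 equals the loss.
    """
    names = list(names)
    means = [ds.mean() for ds in datasets]
    K = len(datasets)
    I = len(datasets[0].variables)

    def residuals(x: np.ndarray) -> np.ndarray:
        cfg = apply_params(base_config, dict(zip(names, x)))
        model = load_network(cfg)
        res = []
        for ds, y in zip(datasets, means):
            T = len(ds.times)
            try:
                pred = predict_dataset(model, ds)
            except RuntimeError:
                return np.full(sum(y.size for y in means), 1e6)
            for i, var in enumerate(ds.variables):
                r = y[:, i] - pred[var]
                if normalize:
                    scale = np.abs(y[:, i]).max()
                    if scale > 0:
                        r = r / scale
                res.append(r / np.sqrt(T * K * I))
        return np.concatenate(res)

    return residuals


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_parameters(
    objective: Callable,
    bounds: Mapping[str, tuple],
    seed: int,
    n_starts: int = 6,
    include_center: bool = True,
    max_nfev: int = 80,
    log_scale: bool = False,
    diff_step: float = 1e-3,
) -> FitResult:
    """Bounded multi-start local optimization, deterministic per seed.

    ``objective(x)`` may return a scalar loss (minimized with L-BFGS-B) or
    a residual vector (minimized with trust-region least squares; the
    reported objective is then the sum of squares).  Starts are Latin-
    hypercube points in the bounds, optionally plus the box center.
    ``log_scale`` optimizes in log10 of the (positive) parameters, which
    conditions rate-constant fits much better; ``diff_step`` keeps the
    finite-difference Jacobian step well above ODE-solver noise.
    """
    names = list(bounds.keys())
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("bounds must be finite")
    if log_scale:
        if np.any(lo <= 0):
            raise ValueError("log-scale fitting requires positive bounds")
        t_lo, t_hi = np.log10(lo), np.log10(hi)
        to_x = lambda z: 10.0 ** np.asarray(z)
    else:
        t_lo, t_hi = lo, hi
        to_x = np.asarray
    fun_t = lambda z: objective(to_x(z))

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    n_lhs = max(n_starts - int(include_center), 0)
    starts = []
    if include_center:
        starts.append(0.5 * (t_lo + t_hi))
    if n_lhs:
        starts.extend(t_lo + sampler.random(n_lhs) * (t_hi - t_lo))

    probe = np.asarray(fun_t(starts[0]), dtype=float)
    vector_mode = probe.ndim == 1 and probe.size > 1

    trace = []
    best = None
    failures = []
    for s_idx, z0 in enumerate(starts):
        try:
            if vector_mode:
                sol = optimize.least_squares(
                    fun_t, z0, bounds=(t_lo, t_hi), max_nfev=max_nfev,
                    xtol=1e-10, ftol=1e-10, diff_step=diff_step,
                )
                fun = float(sol.cost * 2.0)  # sum of squares
                z = sol.z if hasattr(sol, "z") else sol.x
            else:
                sol = optimize.minimize(
                    fun_t, z0, method="L-BFGS-B",
                    bounds=list(zip(t_lo, t_hi)),
                    options={
                        "maxfun": max_nfev * max(len(names), 1),
                        "eps": diff_step,
                    },
                )
                fun = float(sol.fun)
                z = sol.x
        except Exception as exc:  # noqa: BLE001 - recorded per start
            failures.append((s_idx, repr(exc)))
            continue
        x = to_x(z)
        trace.append({"start": s_idx, "x0": list(map(float, to_x(z0))),
                      "x": list(map(float, x)), "objective": fun})
        if best is None or fun < best[0]:
            best = (fun, np.clip(x, lo, hi))
    if best is None:
        raise RuntimeError(f"all optimizer starts failed: {failures}")
    return FitResult(
        params=dict(zip(names, map(float, best[1]))),
        bounds=dict(bounds),
        objective=best[0],
        trace=trace,
        seed=seed,
        n_starts=len(starts),
    )


def loocv(
    datasets: Sequence[Dataset],
    bounds: Mapping[str, tuple],
    seed: int,
    base_config: dict | None = None,
    n_starts: int = 1,
    normalize: bool = True,
) -> list:
    """Leave-one-condition-out cross-validation of the monolayer model.

    For each dataset: fit the free parameters on the remaining conditions,
    predict the held-out condition, and report its MSE and per-variable
    MAPE.  Fit failures are recorded and the fold flagged.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets for cross-validation")
    if base_config is None:
        base_config = default_network_config()
    rows = []
    for k, held in enumerate(datasets):
        train = [d for j, d in enumerate(datasets) if j != k]
        row = {"label": held.label, "fold": k, "failed": False}
        try:
            resid = make_residual_fn(base_config, train, list(bounds), normalize)
            fit = fit_parameters(
                lambda x: resid(x), bounds, seed=seed + k,
                n_starts=n_starts, log_scale=True,
            )
            model = load_network(apply_params(base_config, fit.params))
            pred = predict_dataset(model, held)
            meas = {
                var: held.mean()[:, i] for i, var in enumerate(held.variables)
            }
            row["params"] = fit.params
            row["mse"] = mse_loss([pred], [held], normalize=normalize)
            row["mape"] = mape(pred, meas)
        except (RuntimeError, ValueError) as exc:
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    return rows


def fit_pbm(
    observed: Sequence[NumberDensity],
    initial: NumberDensity,
    seed: int,
    growth: GrowthParams | None = None,
    bounds: Mapping[str, tuple] | None = None,
    n_starts: int = 4,
    dt: float = 2.0,
) -> FitResult:
    """Fit aggregation-kernel parameters to observed size distributions.

    Minimizes the summed KL divergence between observed densities (their
    ``time`` fields set, typically days 1-3) and PBM predictions started
    from ``initial``.  Growth parameters are held fixed if given.
    """
    if bounds is None:
        bounds = {
            "log10_k": (-13.0, -9.0),
            "k1": (0.0, 3.0),
            "log10_alpha_g": (-3.0, -1.5),
        }
    times = [initial.time] + [nd.time for nd in observed]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("observed densities must follow the initial density in time")

    def objective(x):
        p = dict(zip(bounds.keys(), x))
        kern = KernelParams(k=10.0 ** p["log10_k"], k1=p.get("k1", 0.0), a=5e7)
        grow = growth
        if "log10_alpha_g" in p:
            grow = GrowthParams(
                alpha_g=10.0 ** p["log10_alpha_g"],
                m_max=growth.m_max if growth else 2.7e8,
            )
        try:
            pred = simulate_pbm(initial, kern, grow, times, dt=dt)[1:]
        except RuntimeError:
            return 1e6
        return kl_loss(list(observed), pred)

    return fit_parameters(objective, bounds, seed=seed, n_starts=n_starts)
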