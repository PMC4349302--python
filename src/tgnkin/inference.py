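"""Priors, likelihood and MAP estimation for model calibration.

Measurements are modeled as the deterministic ODE solution perturbed by
additive independent Gaussian noise with the per-record standard deviations
reported in the dataset.  Relative (band-intensity) time courses carry an
unknown multiplicative gain per course which is profiled in closed form
before the residuals are evaluated, so no extra dimensions are sampled.

All parameters are sampled on the log10 scale under a normalized log-uniform
(box) prior.  Simulation failures at pathological parameter combinations map
to a log-likelihood of ``-inf`` rather than raising, so samplers and
optimizers reject such points gracefully.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from . import _ode
from .models import KineticModel
from .protocols import Protocol, canonical_observable, profile_scale

__all__ = ["PriorSpec", "TemperedTarget", "log_prior", "log_likelihood",
           "log_tempered", "multistart_map", "default_prior_box",
           "GaussianLikelihood", "validate_dataset", "DATASET_COLUMNS"]

DATASET_COLUMNS = ("experiment_id", "protocol_id", "observable", "mode",
                   "time_h", "value", "sd")

_LOG2PI = float(np.log(2.0 * np.pi))


def validate_dataset(data: pd.DataFrame,
                     protocols: dict[str, Protocol] | None = None) -> pd.DataFrame:
    """Check the tabular measurement dataset against its contract."""
    missing = set(DATASET_COLUMNS) - set(data.columns)
    if missing:
        raise ValueError(f"dataset is missing columns {sorted(missing)}")
    if not (data["sd"] > 0).all():
        raise ValueError("every record needs a positive standard deviation")
    for obs in data["observable"].unique():
        canonical_observable(obs)
    if protocols is not None:
        unknown = set(data["protocol_id"].unique()) - set(protocols)
        if unknown:
            raise ValueError(f"records reference unknown protocols {sorted(unknown)}")
    return data


@dataclass(frozen=True)
class PriorSpec:
    """Independent log10-uniform box prior: name -> (lo, hi)."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: need lo < hi, got [{lo}, {hi}]")

    def arrays(self, parameter_names) -> tuple[np.ndarray, np.ndarray]:
        missing = set(parameter_names) - set(self.bounds)
        if missing:
            raise ValueError(f"prior missing parameters {sorted(missing)}")
        lo = np.array([self.bounds[n][0] for n in parameter_names])
        hi = np.array([self.bounds[n][1] for n in parameter_names])
        return lo, hi

    def to_json_dict(self) -> dict:
        return {k: [float(lo), float(hi)] for k, (lo, hi) in self.bounds.items()}

    @classmethod
    def from_json_dict(cls, doc: dict) -> "PriorSpec":
        return cls({k: (float(v[0]), float(v[1])) for k, v in doc.items()})


def log_prior(params_log10: np.ndarray, prior: PriorSpec,
              parameter_names=None) -> float:
    """Normalized log density of the log10-uniform box prior."""
    names = parameter_names if parameter_names is not None else list(prior.bounds)
    lo, hi = prior.arrays(names)
    x = np.asarray(params_log10, dtype=float)
    if x.shape != lo.shape:
        raise ValueError(f"expected {lo.size} parameters, got {x.size}")
    if np.any(x < lo) or np.any(x > hi):
        return -np.inf
    return float(-np.sum(np.log(hi - lo)))


class GaussianLikelihood:
    """Preprocessed likelihood evaluator for one (model, dataset, protocols).

    The constructor compiles the dataset into per-protocol integration plans
    (segment boundaries, constant input vectors, evaluation times) and
    per-record index maps so that a single evaluation is one relaxation to
    the endogenous steady state plus one jitted integrator call per protocol
    segment.
    """

    def __init__(self, model: KineticModel, dataset: pd.DataFrame,
                 protocols: dict[str, Protocol], rtol: float = 1e-8,
                 atol: float = 0.1, max_steps: int = 3_000):
        self.model = model
        self.rtol, self.atol, self.max_steps = rtol, atol, max_steps
        self.n_failed = 0
        data = validate_dataset(dataset, protocols).reset_index(drop=True)
        data = data.assign(observable=data["observable"].map(canonical_observable))
        self._values = data["value"].to_numpy(dtype=float)
        self._sds = data["sd"].to_numpy(dtype=float)
        self._const = float(np.sum(-0.5 * (_LOG2PI + 2.0 * np.log(self._sds))))

        species = list(model.species_names)
        from .protocols import OBSERVABLES
        vcol = 0 if model.variant == "A" else 1

        self._plans = []
        for pid, rows in data.groupby("protocol_id", sort=True):
            proto = protocols[pid]
            times = np.unique(rows["time_h"].to_numpy(dtype=float))
            switches = [t for t in proto.inputs.switch_times()
                        if 0.0 < t < proto.horizon]
            bounds = np.unique(np.concatenate(
                [[0.0], np.array(switches, float), [max(proto.horizon, times.max())]]))
            segments = []
            for t0, t1 in zip(bounds[:-1], bounds[1:]):
                u = proto.inputs.at(0.5 * (t0 + t1))
                mask = (times > t0 + 1e-12) & (times <= t1 + 1e-12)
                segments.append((t0, t1, u, times[mask],
                                 np.nonzero(mask)[0]))
            groups = []
            for (obs, mode, eid), g in rows.groupby(
                    ["observable", "mode", "experiment_id"], sort=True):
                cols = np.array([species.index(s)
                                 for s in OBSERVABLES[obs][vcol]])
                tidx = np.searchsorted(times, g["time_h"].to_numpy(dtype=float))
                groups.append((cols, tidx, g.index.to_numpy(), mode == "relative"))
            self._plans.append((times, segments, groups))

    def predict(self, theta_log10: np.ndarray) -> np.ndarray | None:
        """Model predictions aligned with the dataset rows (gains profiled);
        None when the simulation fails."""
        model = self.model
        theta = np.zeros(27)
        lin = 10.0 ** np.asarray(theta_log10, dtype=float)
        if lin.size != model.n_parameters:
            raise ValueError(f"expected {model.n_parameters} parameters")
        theta[: lin.size] = lin
        vid = model._variant_id
        slowest = min(theta[23], theta[24], theta[25])
        t_relax = min(10.0 / slowest, 1e5)
        pkd = theta[18] / theta[23]
        pi4k = theta[19] / theta[24]
        cert = theta[20] / theta[25]
        x0 = np.array([0.9 * pkd, 0.1 * pkd, 0.9 * pi4k, 0.1 * pi4k,
                       cert / 3, cert / 3, cert / 3])
        x0, status = _ode.relax_to_equilibrium(vid, x0, theta, np.zeros(4),
                                               t_relax, self.rtol, self.atol,
                                               self.max_steps)
        if status != _ode.OK:
            return None
        preds = np.empty_like(self._values)
        for times, segments, groups in self._plans:
            states = np.empty((len(times), 7))
            if times.size and times[0] <= 1e-12:
                states[0] = x0
            x = x0
            for t0, t1, u, t_eval, idx in segments:
                out, x, status = _ode.integrate_segment(
                    vid, x, theta, u, t0, t1, t_eval, self.rtol, self.atol,
                    self.max_steps)
                if status != _ode.OK:
                    return None
                if idx.size:
                    states[idx] = out
            for cols, tidx, rows_idx, relative in groups:
                m = states[np.ix_(tidx, cols)].sum(axis=1)
                if relative:
                    m = m * profile_scale(m, self._values[rows_idx],
                                          self._sds[rows_idx])
                preds[rows_idx] = m
        return preds

    def __call__(self, theta_log10: np.ndarray) -> float:
        preds = self.predict(theta_log10)
        if preds is None or not np.all(np.isfinite(preds)):
            self.n_failed += 1
            return -np.inf
        resid = (self._values - preds) / self._sds
        return self._const - 0.5 * float(np.sum(resid * resid))


def log_likelihood(params_log10, dataset, model, protocols) -> float:
    """Gaussian log-likelihood of the dataset at one log10 parameter vector.

    Convenience wrapper; performance-critical code should construct one
    :class:`GaussianLikelihood` and reuse it.
    """
    if isinstance(protocols, (list, tuple)):
        protocols = {p.pid: p for p in protocols}
    return GaussianLikelihood(model, dataset, protocols)(params_log10)


@dataclass(frozen=True)
class TemperedTarget:
    """Posterior tempered by an inverse temperature beta in [0, 1]."""

    likelihood: GaussianLikelihood
    prior: PriorSpec
    beta: float

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    def __call__(self, params_log10) -> float:
        return log_tempered(params_log10, self)


def log_tempered(params_log10, target: TemperedTarget) -> float:
    """log prior + beta * log likelihood (beta = 0 recovers the prior).

    At beta = 0 the likelihood still defines the trace used for
    thermodynamic integration but does not shape the target; the convention
    ``0 * (-inf) = 0`` applies so prior-only chains never see NaN.
    """
    lp = log_prior(params_log10, target.prior,
                   target.likelihood.model.parameter_names)
    if not np.isfinite(lp):
        return -np.inf
    if target.beta == 0.0:
        return lp
    ll = target.likelihood(params_log10)
    return lp + target.beta * ll


def default_prior_box(model: KineticModel, center_log10,
                      half_width: float = 3.0) -> PriorSpec:
    """Log-uniform box centered on the best available estimate.

    Each parameter gets ``center +/- half_width`` decades, except that
    degradation rates are confined to protein half-lives of 1-100 h and
    synthesis rates to ranges keeping steady-state totals between 1e3 and
    1e9 molecules/cell.
    """
    center = np.asarray(center_log10, dtype=float)
    if center.shape != (model.n_parameters,):
        raise ValueError(f"center must have {model.n_parameters} entries")
    d_lo, d_hi = np.log10(np.log(2) / 100.0), np.log10(np.log(2) / 1.0)
    s_lo, s_hi = 3.0 + d_lo, 9.0 + d_hi
    bounds = {}
    for name, c in zip(model.parameter_names, center):
        lo, hi = c - half_width, c + half_width
        if name.startswith("d_"):
            lo, hi = max(lo, d_lo), min(hi, d_hi)
        elif name.startswith("s_"):
            lo, hi = max(lo, s_lo), min(hi, s_hi)
        if not lo < hi:  # center far outside the physical band: use the band
            lo, hi = (d_lo, d_hi) if name.startswith("d_") else (s_lo, s_hi)
        bounds[name] = (lo, hi)
    return PriorSpec(bounds)


def initial_search_box(model: KineticModel) -> PriorSpec:
    """Broad physically motivated log10 box used to seed multistart MAP.

    Ranges reflect order-of-magnitude knowledge only: first-order rates span
    milli-per-hour to fast (1e-3..1e2 /h), maximal rates and half-saturation
    constants span the molecule scales of the network, degradation rates
    correspond to protein half-lives of 1-100 h, and synthesis rates keep
    steady-state totals between 1e3 and 1e9 molecules/cell.
    """
    d_lo, d_hi = np.log10(np.log(2) / 100.0), np.log10(np.log(2) / 1.0)
    bounds = {}
    for name in model.parameter_names:
        if name.startswith("d_"):
            bounds[name] = (d_lo, d_hi)
        elif name.startswith("s_"):
            bounds[name] = (3.0 + d_lo, 9.0 + d_hi)
        elif name.startswith("vmax"):
            bounds[name] = (3.0, 8.0)
        elif name == "k_phos_free":
            bounds[name] = (-9.0, -3.0)
        elif name == "k_inh":
            bounds[name] = (-1.0, 3.0)
        elif name.startswith("K"):
            bounds[name] = (2.0, 8.0)
        else:  # first-order rate constants
            bounds[name] = (-3.0, 2.0)
    return PriorSpec(bounds)


def multistart_map(model: KineticModel, dataset, prior: PriorSpec, n_starts: int,
                   seed: int, protocols=None, maxiter: int = 200,
                   likelihood: GaussianLikelihood | None = None):
    """Repeated bounded local maximization of the log posterior.

    Starts are log-uniform draws from the prior box; L-BFGS-B with numerical
    gradients does the local work.  Returns the list of
    ``(params_log10, log_posterior)`` sorted best-first; deterministic given
    the seed.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if likelihood is None:
        if isinstance(protocols, (list, tuple)):
            protocols = {p.pid: p for p in protocols}
        likelihood = GaussianLikelihood(model, dataset, protocols)
    lo, hi = prior.arrays(model.parameter_names)
    lp_inside = float(-np.sum(np.log(hi - lo)))
    rng = np.random.default_rng(seed)

    def negpost(x):
        ll = likelihood(x)
        if not np.isfinite(ll):
            return 1e12
        return -(lp_inside + ll)

    # redraw until each start is simulatable: a gradient-free plateau of
    # failed simulations would pin the optimizer to its starting point
    starts = []
    for _ in range(n_starts):
        for _ in range(50):
            x0 = lo + (hi - lo) * rng.random(lo.size)
            if negpost(x0) < 1e11:
                break
        starts.append(x0)

    results, failures = [], []
    for x0 in starts:
        try:
            res = scipy.optimize.minimize(
                negpost, x0, method="L-BFGS-B",
                bounds=list(zip(lo, hi)), options={"maxiter": maxiter})
            results.append((np.asarray(res.x), -float(res.fun)))
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(repr(exc))
    if not results:
        raise RuntimeError("all optimization starts failed: " + "; ".join(failures))
    results.sort(key=lambda t: -t[1])
    return results
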