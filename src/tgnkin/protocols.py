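"""Perturbation protocols: piecewise ODE integration and blot observables.

A protocol describes when each experimental input switches on (ectopic
expression from transfection, PDBu addition, kb-NB142-70 addition) and which
observables are read out at which times.  Integration restarts at every input
switch so the discontinuity never crosses a step.  The initial state of every
protocol is the endogenous steady state (all inputs zero): cells are
unperturbed before transfection.

Observables mirror the western-blot readouts: ``y4`` phospho-PKD (pS910,
maps to PKDpDAG), ``y5`` phospho-PI4KIIIbeta (pS294, maps to PI4Kp), ``y6``
phospho-CERT (pS132, maps to CERTpER in variant A / CERTp in variant B), and
the per-protein totals.  Relative (band-intensity) readouts carry an unknown
per-time-course gain which is profiled in closed form against the paired
measurements under the Gaussian noise model:

    s = sum(x_i d_i / sigma_i^2) / sum(x_i^2 / sigma_i^2),  clipped at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _ode
from .models import InputSignal, KineticModel, steady_state

__all__ = ["Protocol", "ObservationSpec", "Trajectory", "simulate", "observe",
           "profile_scale", "OBSERVABLES", "protocols_to_json",
           "protocols_from_json"]

#: observable id -> (species to sum in variant A, in variant B)
OBSERVABLES = {
    "pPKD": (("PKDpDAG",), ("PKDpDAG",)),
    "pPI4K": (("PI4Kp",), ("PI4Kp",)),
    "pCERT": (("CERTpER",), ("CERTp",)),
    "PKD_total": (("PKD", "PKDpDAG"), ("PKD", "PKDpDAG")),
    "PI4K_total": (("PI4K", "PI4Kp"), ("PI4K", "PI4Kp")),
    "CERT_total": (("CERTpER", "CERTaER", "CERTaTGN"),
                   ("CERTp", "CERTa", "CERTaERTGN")),
}
#: aliases used in the text: y4/y5/y6 are the relative phospho readouts
ALIASES = {"y4": "pPKD", "y5": "pPI4K", "y6": "pCERT"}


def canonical_observable(obs_id: str) -> str:
    obs = ALIASES.get(obs_id, obs_id)
    if obs not in OBSERVABLES:
        raise ValueError(f"unknown observable {obs_id!r}")
    return obs


@dataclass(frozen=True)
class ObservationSpec:
    """What to read out: observable id, 'absolute' or 'relative' mode, times."""

    observable: str
    mode: str
    times: tuple[float, ...]

    def __post_init__(self):
        canonical_observable(self.observable)
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"mode must be absolute|relative, got {self.mode!r}")
        if any(t < 0 for t in self.times):
            raise ValueError("observation times must be nonnegative")


@dataclass(frozen=True)
class Protocol:
    """Input schedule plus observation requests over a fixed horizon (hours)."""

    pid: str
    inputs: InputSignal
    observations: tuple[ObservationSpec, ...]
    horizon: float

    def __post_init__(self):
        for spec in self.observations:
            if any(t > self.horizon + 1e-9 for t in spec.times):
                raise ValueError(
                    f"protocol {self.pid}: observation beyond horizon")

    def observation_times(self) -> np.ndarray:
        times = sorted({t for spec in self.observations for t in spec.times})
        return np.array(times)


@dataclass(frozen=True)
class Trajectory:
    """Dense-at-requested-times solution of one protocol."""

    t: np.ndarray
    states: np.ndarray  # (len(t), 7)
    species_names: tuple[str, ...]
    variant: str

    def series(self, obs_id: str, times=None) -> np.ndarray:
        """Observable series (molecules/cell) at ``times`` (default: full grid)."""
        obs = canonical_observable(obs_id)
        cols = OBSERVABLES[obs][0 if self.variant == "A" else 1]
        idx = [self.species_names.index(c) for c in cols]
        y = self.states[:, idx].sum(axis=1)
        if times is None:
            return y
        pos = np.searchsorted(self.t, np.asarray(times, dtype=float))
        ok = (pos < len(self.t)) & np.isclose(
            self.t[np.minimum(pos, len(self.t) - 1)], times, rtol=0, atol=1e-9)
        if not np.all(ok):
            raise ValueError("requested times are not on the trajectory grid")
        return y[pos]


def simulate(model: KineticModel, params, protocol: Protocol,
             rtol: float = 1e-8, atol: float = 1e-3,
             x0: np.ndarray | None = None, max_steps: int = 100_000) -> Trajectory:
    """Integrate ``model`` through ``protocol`` from the endogenous steady state.

    Piecewise integration restarted at every input switch; the returned grid
    contains 0, the horizon, all switch times and all observation times.
    Raises RuntimeError with the failure time if the integrator gives up.
    """
    theta = model.params_array(params)
    if x0 is None:
        x0 = steady_state(model, params, InputSignal.none())
    switches = [t for t in protocol.inputs.switch_times()
                if 0.0 < t < protocol.horizon]
    grid = np.unique(np.concatenate([
        [0.0, protocol.horizon], np.array(switches, dtype=float),
        protocol.observation_times()]))
    bounds = np.unique(np.concatenate([[0.0, protocol.horizon],
                                       np.array(switches, dtype=float)]))
    states = np.empty((len(grid), 7))
    states[0] = x0
    x = np.asarray(x0, dtype=float).copy()
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        u = protocol.inputs.at(0.5 * (t0 + t1))
        mask = (grid > t0 + 1e-12) & (grid <= t1 + 1e-12)
        t_eval = grid[mask]
        out, x, status = _ode.integrate_segment(
            model._variant_id, x, theta, u, t0, t1, t_eval, rtol, atol, max_steps)
        if status != _ode.OK:
            raise RuntimeError(
                f"integration of protocol {protocol.pid} failed near t={t1} h "
                f"(status {status}); last state {x}")
        states[mask] = out
    return Trajectory(grid, states, model.species_names, model.variant)


def profile_scale(x: np.ndarray, d: np.ndarray, sd: np.ndarray) -> float:
    """Closed-form weighted-least-squares gain of a relative time course.

    Zero when the model series is identically zero; clipped at zero because a
    blot signal cannot invert.
    """
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    sd = np.asarray(sd, dtype=float)
    denom = float(np.sum(x * x / sd ** 2))
    if denom == 0.0:
        return 0.0
    return max(0.0, float(np.sum(x * d / sd ** 2)) / denom)


def observe(trajectory: Trajectory, spec: ObservationSpec,
            data: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Predicted observable series for one observation request.

    Absolute mode returns molecules/cell.  Relative mode returns ``s * x(t)``
    with the gain ``s`` profiled against the paired measurements
    ``data = (values, sds)``; relative mode without paired data is an error
    because the gain is undefined.
    """
    x = trajectory.series(spec.observable, spec.times)
    if spec.mode == "absolute":
        return x
    if data is None:
        raise ValueError("relative mode requires paired data to profile the gain")
    values, sds = data
    return profile_scale(x, values, sds) * x


def protocols_to_json(protocols: list[Protocol]) -> str:
    docs = []
    for p in protocols:
        docs.append({
            "id": p.pid,
            "inputs": [{"u": f"u{i+1}", "t_on_h": t, "level": lv}
                       for i, (t, lv) in enumerate(zip(p.inputs.t_on,
                                                       p.inputs.level))
                       if np.isfinite(t)],
            "observations": [{"observable": s.observable, "mode": s.mode,
                              "times_h": list(s.times)}
                             for s in p.observations],
            "horizon_h": p.horizon,
        })
    return json.dumps(docs, indent=1)


def protocols_from_json(text: str) -> list[Protocol]:
    out = []
    for doc in json.loads(text):
        kw = {rec["u"]: (rec["t_on_h"], rec["level"]) for rec in doc["inputs"]}
        out.append(Protocol(
            doc["id"], InputSignal.steps(**kw),
            tuple(ObservationSpec(s["observable"], s["mode"],
                                  tuple(s["times_h"]))
                  for s in doc["observations"]),
            doc["horizon_h"]))
    return out
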