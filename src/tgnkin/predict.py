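"""Posterior predictions: the endogenous operating state and its perturbations.

``endogenous_distributions`` pushes a posterior parameter sample through the
unperturbed model (all inputs zero): per draw it computes the steady state,
every reaction flux (molecules/hour), and the operating point of each
regulated reaction — the flux expressed as a fraction of its maximal rate
``vmax``, i.e. ``E/(KE+E) * S/(KS+S)``.  Operating points far below 1 mean
the regulation is unsaturated and hence responsive to changes in its
regulator.  Summaries report the expectation and the [0.5, 99.5] percentile
band (99% central mass).

``perturbation_response`` quantifies the mutual influence of PKD activity
and ceramide transfer at steady state:

* ``feedback_knockout`` — the transfer-dependent PKD activation channel is
  removed (vmax_cer = 0) and the relative change of active PKD is reported;
* ``transfer_up_10`` — the transfer rate constant k10 is scaled so the
  steady-state transfer flux J rises by exactly the requested magnitude
  (default 10%), reporting the relative change of active PKD;
* ``pkd_up_10`` — the basal activation rate is scaled so steady-state active
  PKD rises by the magnitude, reporting the relative change of J.

The 1-D multiplier searches use monotone bracketing root-finding to a 1e-6
relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .models import InputSignal, KineticModel, reaction_fluxes, steady_state, \
    transfer_flux

__all__ = ["EndogenousPrediction", "PerturbationScenario",
           "endogenous_distributions", "perturbation_response"]

REGULATED = ("R1", "R3", "R5", "PKD_act_cer")
_VMAX_OF = {"R1": "vmax1", "R3": "vmax3", "R5": "vmax5",
            "PKD_act_cer": "vmax_cer"}


@dataclass(frozen=True)
class QuantitySummary:
    expectation: float
    lower: float   # 0.5 percentile
    upper: float   # 99.5 percentile


@dataclass(frozen=True)
class EndogenousPrediction:
    species_names: tuple[str, ...]
    states: np.ndarray          # (n_kept, 7) molecules/cell
    fluxes: dict[str, np.ndarray]          # reaction id -> (n_kept,) molecules/h
    operating_points: dict[str, np.ndarray]  # regulated reaction -> fraction
    transfer: np.ndarray        # (n_kept,) J molecules/h
    n_dropped: int

    def summary(self) -> dict[str, QuantitySummary]:
        out = {}

        def add(name, draws):
            lo, hi = np.percentile(draws, [0.5, 99.5])
            out[name] = QuantitySummary(float(np.mean(draws)), float(lo),
                                        float(hi))

        for i, sp in enumerate(self.species_names):
            add(f"state:{sp}", self.states[:, i])
        for rid, v in self.fluxes.items():
            add(f"flux:{rid}", v)
        for rid, v in self.operating_points.items():
            add(f"op:{rid}", v)
        add("transfer_flux", self.transfer)
        return out


@dataclass(frozen=True)
class PerturbationScenario:
    kind: str
    magnitude: float = 0.10

    def __post_init__(self):
        if self.kind not in ("feedback_knockout", "transfer_up_10", "pkd_up_10"):
            raise ValueError(f"unknown scenario {self.kind!r}")
        if self.magnitude <= -1.0:
            raise ValueError("magnitude must exceed -1")


def _draws_to_linear(model: KineticModel, sample: np.ndarray) -> np.ndarray:
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    if sample.shape[1] != model.n_parameters:
        raise ValueError(
            f"sample must have {model.n_parameters} columns (log10 scale)")
    return 10.0 ** sample


def endogenous_distributions(model: KineticModel, posterior_sample,
                             max_dropped_frac: float = 0.10,
                             strict: bool = False) -> EndogenousPrediction:
    """Steady-state, flux and operating-point distributions at zero inputs.

    Draws whose steady state does not converge are dropped and counted; more
    than ``max_dropped_frac`` dropped draws raises when ``strict`` is set.
    """
    lin = _draws_to_linear(model, posterior_sample)
    if lin.shape[0] == 0:
        raise ValueError("posterior sample is empty")
    u0 = InputSignal.none()
    states, flux_rows, trans, kept = [], [], [], []
    n_dropped = 0
    for i, theta in enumerate(lin):
        p = model.params_dict(theta)
        try:
            x = steady_state(model, p, u0)
        except RuntimeError:
            n_dropped += 1
            continue
        kept.append(i)
        states.append(x)
        flux_rows.append(reaction_fluxes(model, x, p))
        trans.append(transfer_flux(model, x, p))
    if not states:
        raise RuntimeError("every posterior draw failed to reach a steady state")
    frac = n_dropped / lin.shape[0]
    if frac > max_dropped_frac:
        msg = (f"{n_dropped}/{lin.shape[0]} draws dropped "
               f"({100 * frac:.1f}% > {100 * max_dropped_frac:.0f}%)")
        if strict:
            raise RuntimeError(msg)
        import warnings
        warnings.warn(msg)
    states = np.asarray(states)
    kept = np.asarray(kept, dtype=int)
    fluxes = {rid: np.array([row[rid] for row in flux_rows])
              for rid in flux_rows[0]}
    # operating point = flux / vmax, vmax taken from the same kept draws
    ops = {}
    for rid in REGULATED:
        vmax = lin[kept, model.parameter_names.index(_VMAX_OF[rid])]
        ops[rid] = fluxes[rid] / vmax
    return EndogenousPrediction(
        species_names=model.species_names, states=states, fluxes=fluxes,
        operating_points=ops, transfer=np.asarray(trans), n_dropped=n_dropped)


def _response_for_draw(model: KineticModel, theta: np.ndarray,
                       scenario: PerturbationScenario,
                       rel_tol: float = 1e-6) -> float:
    """Relative change (%) of the scenario's readout for one linear draw."""
    p0 = model.params_dict(theta)
    u0 = InputSignal.none()
    x0 = steady_state(model, p0, u0)
    pkd0 = x0[model.species_names.index("PKDpDAG")]
    j0 = transfer_flux(model, x0, p0)

    if scenario.kind == "feedback_knockout":
        p = dict(p0)
        if p["vmax_cer"] == 0.0:
            return 0.0
        p["vmax_cer"] = 1e-300  # parameters must stay positive; flux is nil
        x = steady_state(model, p, u0)
        pkd = x[model.species_names.index("PKDpDAG")]
        return 100.0 * (pkd - pkd0) / pkd0

    if scenario.magnitude == 0.0:
        return 0.0

    pkd_idx = model.species_names.index("PKDpDAG")
    if scenario.kind == "transfer_up_10":
        knob = "k10"
        target_fn = lambda x, p: transfer_flux(model, x, p)
        target0 = j0
    else:  # pkd_up_10
        knob = "k_act"
        target_fn = lambda x, p: x[pkd_idx]
        target0 = pkd0

    goal = target0 * (1.0 + scenario.magnitude)

    def excess(lam):
        p = dict(p0)
        p[knob] = p0[knob] * lam
        x = steady_state(model, p, u0)
        return target_fn(x, p) - goal

    lo, hi = 1.0, 1.0 + 2.0 * abs(scenario.magnitude) + 0.5
    if scenario.magnitude < 0:
        lo, hi = 1e-3, 1.0
    for _ in range(40):
        if excess(hi) > 0:
            break
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("could not bracket the perturbation multiplier")
    lam = scipy.optimize.brentq(excess, lo, hi, rtol=rel_tol)
    p = dict(p0)
    p[knob] = p0[knob] * lam
    x = steady_state(model, p, u0)
    if scenario.kind == "transfer_up_10":
        new = x[model.species_names.index("PKDpDAG")]
        return 100.0 * (new - pkd0) / pkd0
    new_j = transfer_flux(model, x, p)
    return 100.0 * (new_j - j0) / j0


def perturbation_response(model: KineticModel, posterior_sample,
                          scenario: PerturbationScenario) -> dict:
    """Per-draw distribution of the relative steady-state response (%).

    Returns ``{"draws": array, "expectation": float, "n_dropped": int}``;
    draws whose root-finding fails are dropped and counted.
    """
    lin = _draws_to_linear(model, posterior_sample)
    out, n_dropped = [], 0
    for theta in lin:
        try:
            out.append(_response_for_draw(model, theta, scenario))
        except RuntimeError:
            n_dropped += 1
    if not out:
        raise RuntimeError("all draws failed in the perturbation analysis")
    draws = np.asarray(out)
    return {"draws": draws, "expectation": float(draws.mean()),
            "n_dropped": n_dropped}
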