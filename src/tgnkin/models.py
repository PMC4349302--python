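"""Kinetic ODE models of PKD, PI4KIIIbeta and CERT at the trans-Golgi network.

Two competing model variants encode the two proposed mechanisms of
CERT-mediated ceramide transfer between the ER and the TGN:

* **Variant A** ("shuttle"): CERT stays ER-associated and cycles through a
  phosphorylation-controlled shuttle (CERTaTGN -> CERTpER -> CERTaER ->
  CERTaTGN).  PKD-driven CERT phosphorylation together with
  transfer-dependent PKD activation forms an overall *positive* feedback.
* **Variant B** ("neck-swinging"): only a double-membrane-bound form
  (CERTaERTGN) transfers ceramide; PKD phosphorylation interrupts transfer,
  an overall *negative* feedback.

Both variants have 7 state variables (molecules/cell).  Variant A has 26 rate
parameters, variant B 27 (the extra one, ``k_phos_free``, is PKD-dependent
phosphorylation of free cytosolic CERT).  Regulated reactions follow a
bounded Michaelis-Menten-like law ``v = vmax * E/(KE+E) * S/(KS+S)`` whose
flux never exceeds ``vmax``; the CERT-transfer->PKD activation channel is
regulated by the transfer flux J itself, ``v = vmax_cer * J/(K_cer+J)``.

Experimental inputs (all step functions with values in [0, 1]):
``u1`` PDBu activation of PKD, ``u2`` kb-NB142-70 inhibition of PKD,
``u3``/``u4`` ectopic expression (plasmid-driven synthesis) of PI4KIIIbeta /
CERT.  The inhibitor scales the PKDpDAG-catalyzed vmax terms, the basal and
PDBu activation channels (and ``k_phos_free`` in B) by ``1/(1 + k_inh*u2)``.

Units: molecules/cell for amounts, hours for time; first-order rates 1/h,
synthesis rates and vmax molecules/(cell*h), half-saturation constants
molecules/cell (molecules/h for ``K_cer``, whose regulator is a flux).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.optimize

from . import _ode

__all__ = [
    "KineticModel",
    "ReactionSpec",
    "InputSignal",
    "build_model",
    "rhs",
    "reaction_fluxes",
    "transfer_flux",
    "steady_state",
    "model_to_json",
    "model_from_json",
]

SPECIES_A = ("PKD", "PKDpDAG", "PI4K", "PI4Kp", "CERTpER", "CERTaER", "CERTaTGN")
SPECIES_B = ("PKD", "PKDpDAG", "PI4K", "PI4Kp", "CERTp", "CERTa", "CERTaERTGN")

PARAMS_A = (
    "vmax1", "K1E", "K1S", "kdp_PI4K",
    "vmax3", "K3E", "K3S", "k9",
    "vmax5", "K5E", "K5S", "k10",
    "k_act", "vmax_cer", "K_cer", "k_pdbu", "k_deact", "k_inh",
    "s_PKD", "s_PI4K", "s_CERT", "s_ect_PI4K", "s_ect_CERT",
    "d_PKD", "d_PI4K", "d_CERT",
)
PARAMS_B = PARAMS_A + ("k_phos_free",)


@dataclass(frozen=True)
class InputSignal:
    """Piecewise-constant experimental inputs u1-u4.

    Each input is a step: zero before its switch-on time, ``level`` after.
    """

    t_on: tuple[float, float, float, float] = (np.inf, np.inf, np.inf, np.inf)
    level: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        for lv in self.level:
            if not 0.0 <= lv <= 1.0:
                raise ValueError(f"input levels must lie in [0, 1], got {lv}")

    @classmethod
    def none(cls) -> "InputSignal":
        return cls()

    @classmethod
    def steps(cls, **kw: tuple[float, float]) -> "InputSignal":
        """Build from keyword steps, e.g. ``steps(u3=(0.0, 1.0), u1=(24.0, 1.0))``."""
        t_on = [np.inf] * 4
        level = [0.0] * 4
        for name, (t, lv) in kw.items():
            if name not in ("u1", "u2", "u3", "u4"):
                raise ValueError(f"unknown input {name!r}")
            i = int(name[1]) - 1
            t_on[i] = float(t)
            level[i] = float(lv)
        return cls(tuple(t_on), tuple(level))

    def at(self, t: float) -> np.ndarray:
        """Input vector [u1..u4] at time t (hours)."""
        return np.array([lv if t >= t0 else 0.0
                         for t0, lv in zip(self.t_on, self.level)])

    def switch_times(self) -> list[float]:
        return sorted({t for t in self.t_on if np.isfinite(t)})

    def is_constant(self) -> bool:
        return len(self.switch_times()) == 0 or all(
            t <= 0.0 for t in self.switch_times())


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: substrate -> product with a named rate law.

    ``kind`` is ``mass_action`` (flux = k * [substrate], or k * [regulator] *
    [substrate] when a regulator is given) or ``regulated_mm`` (bounded
    Michaelis-Menten-like, flux <= vmax) or ``constant`` (synthesis).
    ``substrate``/``product`` are species names or None (None product means a
    pure output/degradation flux; None substrate means synthesis).  The flux
    function receives (state dict, params dict, u vector) and returns
    molecules/h.
    """

    rid: str
    kind: str
    substrate: str | None
    product: str | None
    regulator: str | None
    parameters: tuple[str, ...]
    flux: Callable[[dict, dict, np.ndarray], float] = field(compare=False)


@dataclass(frozen=True)
class KineticModel:
    variant: str
    species_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    reaction_specs: tuple[ReactionSpec, ...]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def _variant_id(self) -> int:
        return _ode.VARIANT_A if self.variant == "A" else _ode.VARIANT_B

    def params_array(self, params: dict | np.ndarray) -> np.ndarray:
        """Canonical length-27 linear-scale parameter array for the kernels."""
        theta = np.zeros(27)
        if isinstance(params, dict):
            missing = set(self.parameter_names) - set(params)
            if missing:
                raise ValueError(f"missing parameters: {sorted(missing)}")
            vec = np.array([float(params[name]) for name in self.parameter_names])
        else:
            vec = np.asarray(params, dtype=float)
            if vec.shape != (self.n_parameters,):
                raise ValueError(
                    f"expected {self.n_parameters} parameters, got {vec.shape}")
        if np.any(vec <= 0) or not np.all(np.isfinite(vec)):
            raise ValueError("all parameters must be positive and finite")
        theta[: vec.size] = vec
        return theta

    def params_dict(self, vec: np.ndarray) -> dict[str, float]:
        return dict(zip(self.parameter_names, np.asarray(vec, dtype=float)))


def _mm(E, KE, S, KS, vmax):
    return vmax * E / (KE + E) * S / (KS + S)


def _reactions_common(variant: str) -> list[ReactionSpec]:
    """Reactions shared between the variants (PKD and PI4K subsystems)."""
    cert_transfer = "CERTaTGN" if variant == "A" else "CERTaERTGN"

    def g(p, u):
        return 1.0 / (1.0 + p["k_inh"] * u[1])

    return [
        ReactionSpec("R1", "regulated_mm", "PI4K", "PI4Kp", "PKDpDAG",
                     ("vmax1", "K1E", "K1S", "k_inh"),
                     lambda x, p, u: g(p, u) * _mm(x["PKDpDAG"], p["K1E"],
                                                   x["PI4K"], p["K1S"], p["vmax1"])),
        ReactionSpec("PI4K_dephos", "mass_action", "PI4Kp", "PI4K", None,
                     ("kdp_PI4K",),
                     lambda x, p, u: p["kdp_PI4K"] * x["PI4Kp"]),
        ReactionSpec("PKD_act_basal", "mass_action", "PKD", "PKDpDAG", None,
                     ("k_act", "k_inh"),
                     lambda x, p, u: g(p, u) * p["k_act"] * x["PKD"]),
        ReactionSpec("PKD_act_cer", "regulated_mm", "PKD", "PKDpDAG", "J",
                     ("vmax_cer", "K_cer", "k10"),
                     lambda x, p, u: p["vmax_cer"]
                     * (p["k10"] * x[cert_transfer])
                     / (p["K_cer"] + p["k10"] * x[cert_transfer])),
        ReactionSpec("PKD_act_pdbu", "mass_action", "PKD", "PKDpDAG", None,
                     ("k_pdbu", "k_inh"),
                     lambda x, p, u: g(p, u) * u[0] * p["k_pdbu"] * x["PKD"]),
        ReactionSpec("PKD_deact", "mass_action", "PKDpDAG", "PKD", None,
                     ("k_deact",),
                     lambda x, p, u: p["k_deact"] * x["PKDpDAG"]),
        # R10 is a pure output flux: ceramide is delivered but the carrier
        # itself stays in the transfer-engaged pool, so no state change.
        ReactionSpec("R10", "mass_action", None, None, cert_transfer,
                     ("k10",),
                     lambda x, p, u: p["k10"] * x[cert_transfer]),
        ReactionSpec("syn_PKD", "constant", None, "PKD", None, ("s_PKD",),
                     lambda x, p, u: p["s_PKD"]),
        ReactionSpec("syn_PI4K", "constant", None, "PI4K", None, ("s_PI4K",),
                     lambda x, p, u: p["s_PI4K"]),
        ReactionSpec("ect_PI4K", "constant", None, "PI4K", None, ("s_ect_PI4K",),
                     lambda x, p, u: u[2] * p["s_ect_PI4K"]),
    ]


def _degradation(protein: str, rate: str, forms: Sequence[str]) -> list[ReactionSpec]:
    return [
        ReactionSpec(f"deg_{form}", "mass_action", form, None, None, (rate,),
                     (lambda x, p, u, f=form, r=rate: p[r] * x[f]))
        for form in forms
    ]


def build_model(variant: str) -> KineticModel:
    """Construct the fully wired kinetic model for variant ``"A"`` or ``"B"``."""
    if variant not in ("A", "B"):
        raise ValueError(f"unknown model variant {variant!r}; expected 'A' or 'B'")

    def g(p, u):
        return 1.0 / (1.0 + p["k_inh"] * u[1])

    reactions = _reactions_common(variant)
    if variant == "A":
        species = SPECIES_A
        names = PARAMS_A
        reactions += [
            ReactionSpec("R3", "regulated_mm", "CERTaTGN", "CERTpER", "PKDpDAG",
                         ("vmax3", "K3E", "K3S", "k_inh"),
                         lambda x, p, u: g(p, u) * _mm(x["PKDpDAG"], p["K3E"],
                                                       x["CERTaTGN"], p["K3S"],
                                                       p["vmax3"])),
            ReactionSpec("R9", "mass_action", "CERTpER", "CERTaER", None, ("k9",),
                         lambda x, p, u: p["k9"] * x["CERTpER"]),
            ReactionSpec("R5", "regulated_mm", "CERTaER", "CERTaTGN", "PI4Kp",
                         ("vmax5", "K5E", "K5S"),
                         lambda x, p, u: _mm(x["PI4Kp"], p["K5E"],
                                             x["CERTaER"], p["K5S"], p["vmax5"])),
            ReactionSpec("syn_CERT", "constant", None, "CERTaER", None, ("s_CERT",),
                         lambda x, p, u: p["s_CERT"]),
            ReactionSpec("ect_CERT", "constant", None, "CERTaER", None,
                         ("s_ect_CERT",),
                         lambda x, p, u: u[3] * p["s_ect_CERT"]),
        ]
        cert_forms = ("CERTpER", "CERTaER", "CERTaTGN")
    else:
        species = SPECIES_B
        names = PARAMS_B
        reactions += [
            ReactionSpec("R3", "regulated_mm", "CERTaERTGN", "CERTp", "PKDpDAG",
                         ("vmax3", "K3E", "K3S", "k_inh"),
                         lambda x, p, u: g(p, u) * _mm(x["PKDpDAG"], p["K3E"],
                                                       x["CERTaERTGN"], p["K3S"],
                                                       p["vmax3"])),
            ReactionSpec("R9", "mass_action", "CERTp", "CERTa", None, ("k9",),
                         lambda x, p, u: p["k9"] * x["CERTp"]),
            ReactionSpec("R5", "regulated_mm", "CERTa", "CERTaERTGN", "PI4Kp",
                         ("vmax5", "K5E", "K5S"),
                         lambda x, p, u: _mm(x["PI4Kp"], p["K5E"],
                                             x["CERTa"], p["K5S"], p["vmax5"])),
            ReactionSpec("CERT_phos_free", "mass_action", "CERTa", "CERTp",
                         "PKDpDAG", ("k_phos_free", "k_inh"),
                         lambda x, p, u: g(p, u) * p["k_phos_free"]
                         * x["PKDpDAG"] * x["CERTa"]),
            ReactionSpec("syn_CERT", "constant", None, "CERTa", None, ("s_CERT",),
                         lambda x, p, u: p["s_CERT"]),
            ReactionSpec("ect_CERT", "constant", None, "CERTa", None,
                         ("s_ect_CERT",),
                         lambda x, p, u: u[3] * p["s_ect_CERT"]),
        ]
        cert_forms = ("CERTp", "CERTa", "CERTaERTGN")

    reactions += _degradation("PKD", "d_PKD", ("PKD", "PKDpDAG"))
    reactions += _degradation("PI4K", "d_PI4K", ("PI4K", "PI4Kp"))
    reactions += _degradation("CERT", "d_CERT", cert_forms)

    model = KineticModel(variant, species, names, tuple(reactions))
    used = set()
    for r in reactions:
        used.update(r.parameters)
    assert used == set(names), sorted(set(names) ^ used)
    return model


def _check_state(model: KineticModel, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise ValueError(f"state must have {model.n_species} entries")
    if not np.all(np.isfinite(state)):
        raise ValueError("state must be finite")
    if np.any(state < 0):
        raise ValueError("state amounts must be nonnegative")
    return state


def reaction_fluxes(model: KineticModel, state, params, inputs=None,
                    t: float = 0.0) -> dict[str, float]:
    """Per-reaction fluxes (molecules/h) at one state.

    All fluxes are nonnegative for nonnegative states, and every regulated
    reaction's flux is bounded by its vmax by construction of the rate law.
    """
    state = _check_state(model, state)
    x = dict(zip(model.species_names, state))
    p = model.params_dict(model.params_array(params)[: model.n_parameters]) \
        if not isinstance(params, dict) else dict(params)
    u = inputs.at(t) if isinstance(inputs, InputSignal) else (
        np.zeros(4) if inputs is None else np.asarray(inputs, dtype=float))
    fluxes = {}
    for r in model.reaction_specs:
        v = float(r.flux(x, p, u))
        if not np.isfinite(v):
            raise ArithmeticError(f"non-finite flux in reaction {r.rid}")
        fluxes[r.rid] = v
    return fluxes


def rhs(model: KineticModel, state, t, params, inputs=None) -> np.ndarray:
    """ODE right-hand side, molecules/(cell*h).

    Assembled as the stoichiometry-weighted sum of the per-reaction fluxes,
    so it agrees with :func:`reaction_fluxes` by construction; the fast
    integrator kernel is validated against this function in the tests.
    """
    fluxes = reaction_fluxes(model, state, params, inputs, t)
    idx = {name: i for i, name in enumerate(model.species_names)}
    dx = np.zeros(model.n_species)
    for r in model.reaction_specs:
        v = fluxes[r.rid]
        if r.substrate is not None:
            dx[idx[r.substrate]] -= v
        if r.product is not None:
            dx[idx[r.product]] += v
    return dx


def transfer_flux(model: KineticModel, state, params) -> float:
    """Ceramide transfer flux J = k10 * [transfer-engaged CERT], molecules/h."""
    state = _check_state(model, state)
    p = params if isinstance(params, dict) else model.params_dict(
        model.params_array(params)[: model.n_parameters])
    species = "CERTaTGN" if model.variant == "A" else "CERTaERTGN"
    return float(p["k10"]) * float(state[model.species_names.index(species)])


def _initial_guess(theta: np.ndarray) -> np.ndarray:
    """Turnover-balance guess: totals s/d, split heuristically across forms."""
    pkd = theta[18] / theta[23]
    pi4k = theta[19] / theta[24]
    cert = theta[20] / theta[25]
    return np.array([0.9 * pkd, 0.1 * pkd, 0.9 * pi4k, 0.1 * pi4k,
                     cert / 3, cert / 3, cert / 3])


def steady_state(model: KineticModel, params, inputs=None, tol_ss: float = 1e-6,
                 t_relax: float | None = None, polish: bool = True) -> np.ndarray:
    """Equilibrium state under constant inputs.

    Long relaxation integration (ten times the slowest turnover timescale by
    default) followed by a Newton polish; the result satisfies
    ``max|rhs| <= tol_ss`` (molecules/(cell*h)) and is nonnegative.
    """
    if inputs is None:
        inputs = InputSignal.none()
    if isinstance(inputs, InputSignal):
        if not inputs.is_constant():
            raise ValueError("steady_state requires constant inputs")
        u = inputs.at(0.0)
    else:
        u = np.asarray(inputs, dtype=float)
    theta = model.params_array(params)
    if t_relax is None:
        slowest = min(theta[23], theta[24], theta[25])
        t_relax = min(10.0 / slowest, 1e5)
    x0 = _initial_guess(theta)
    x, status = _ode.relax_to_equilibrium(model._variant_id, x0, theta, u,
                                          t_relax, 1e-10, 1e-4, 2_000_000)
    if status != _ode.OK:
        raise RuntimeError(f"relaxation integration failed (status {status})")

    def f(z):
        return _ode.rhs_kernel(model._variant_id, z, theta, u)

    if polish:
        sol = scipy.optimize.root(f, x, method="hybr")
        cand = np.asarray(sol.x)
        # tolerate roundoff-scale negatives relative to the state's magnitude
        if sol.success and np.all(cand >= -1e-9 * (1.0 + np.max(np.abs(cand)))):
            x = np.clip(cand, 0.0, None)
    resid = float(np.max(np.abs(f(x))))
    scale = float(np.max(np.abs(theta[18:23])))  # largest synthesis flux
    if resid > max(tol_ss, 1e-12 * scale):
        raise RuntimeError(
            f"steady state did not converge: residual {resid:.3e} "
            f"exceeds tolerance {tol_ss:.3e}")
    return x


def model_to_json(model: KineticModel) -> str:
    """Serialize the model structure (not parameter values) for provenance."""
    return json.dumps({
        "variant": model.variant,
        "species": list(model.species_names),
        "parameters": list(model.parameter_names),
        "reactions": [
            {"id": r.rid, "kind": r.kind, "substrate": r.substrate,
             "product": r.product, "regulator": r.regulator,
             "parameters": list(r.parameters)}
            for r in model.reaction_specs
        ],
    }, indent=1)


def model_from_json(text: str) -> KineticModel:
    """Rebuild a model from its JSON export, verifying structural identity."""
    doc = json.loads(text)
    model = build_model(doc["variant"])
    if (list(model.species_names) != doc["species"]
            or list(model.parameter_names) != doc["parameters"]):
        raise ValueError("serialized model structure does not match this build")
    return model
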