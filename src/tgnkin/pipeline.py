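"""Pipeline stages binding the library together, with provenance manifests.

Each stage reads only declared inputs and writes its outputs plus a JSON
manifest recording input hashes, the seed and the settings, so every
downstream number is traceable to a seed and a configuration.  Re-running a
stage with an identical configuration reproduces identical outputs.

Stages:  ``synth`` (generate a synthetic dataset), ``fit`` (multistart MAP
and the prior box centered on it), ``sample`` (parallel-tempering MCMC),
``evidence`` (thermodynamic integration and the Bayes factor; needs chains
for both variants), ``predict`` / ``perturb`` (posterior predictions),
``quantify`` (absolute quantification from a standards table), and ``all``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import (GaussianLikelihood, PriorSpec, default_prior_box,
                        initial_search_box, log_prior, multistart_map,
                        validate_dataset)
from .models import build_model
from .predict import PerturbationScenario, endogenous_distributions, \
    perturbation_response
from .protocols import protocols_from_json, protocols_to_json
from .ptmcmc import Ladder, gelman_rubin, load_chains, pt_sample, save_chains, \
    subsample_posterior
from .evidence import bayes_factor, estimate_evidence
from .quantify import endogenous_abundance, fit_standard_curve, inverse_predict
from .synth import NoiseSpec, dataset_to_csv, default_protocols, \
    generate_dataset, ground_truth

__all__ = ["RunConfig", "SamplerSettings", "run_pipeline", "STAGES"]

STAGES = ("synth", "fit", "sample", "evidence", "predict", "perturb",
          "quantify", "all")


@dataclass
class SamplerSettings:
    levels: int = 4
    ladder_exponent: float = 5.0
    iterations: int = 20_000
    runs: int = 3
    burn_in: float = 0.5
    step_frac: float = 0.08      # initial proposal scale, fraction of prior width
    prior_half_width: float = 3.0  # decades around the MAP estimate
    n_starts: int = 6            # multistart MAP starts
    map_maxiter: int = 60
    posterior_draws: int = 200   # subsample size for predictions


@dataclass
class RunConfig:
    out_dir: str
    variant: str = "A"
    seed: int = 0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    noise: NoiseSpec | None = None
    exclude_protocols: tuple[str, ...] = ("E5",)  # validation data held out
    quantify_inputs: dict | None = None
    tol_ss: float = 1e-6

    def __post_init__(self):
        if self.variant not in ("A", "B"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if isinstance(self.sampler, dict):
            self.sampler = SamplerSettings(**self.sampler)
        if isinstance(self.noise, dict):
            self.noise = NoiseSpec(**self.noise)

    @property
    def out(self) -> Path:
        return Path(self.out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, inputs: list[Path],
                    outputs: list[Path], settings: dict):
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": cfg.seed,
        "settings": settings,
        "inputs": {p.name: _sha256(p) for p in sorted(inputs)},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = cfg.out / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path.name}; run the '{producer}' stage first")
    return path


def _load_tabular(cfg: RunConfig):
    data = validate_dataset(pd.read_csv(_require(cfg.out / "dataset.csv", "synth")))
    protos = {p.pid: p for p in protocols_from_json(
        _require(cfg.out / "protocols.json", "synth").read_text())}
    keep = ~data["protocol_id"].isin(cfg.exclude_protocols)
    return data[keep].reset_index(drop=True), protos


def _stage_synth(cfg: RunConfig) -> list[Path]:
    noise = cfg.noise or NoiseSpec(seed=cfg.seed)
    protos = default_protocols()
    params = ground_truth(cfg.variant)
    data, truth = generate_dataset(cfg.variant, params, protos, noise)
    cfg.out.mkdir(parents=True, exist_ok=True)
    out_csv = cfg.out / "dataset.csv"
    dataset_to_csv(data, out_csv)
    out_proto = cfg.out / "protocols.json"
    out_proto.write_text(protocols_to_json(protos))
    out_truth = cfg.out / "groundtruth.json"
    out_truth.write_text(json.dumps(truth, indent=1, sort_keys=True))
    _write_manifest(cfg, "synth", [], [out_csv, out_proto, out_truth],
                    {"variant": cfg.variant, "noise": asdict(noise)})
    return [out_csv, out_proto, out_truth]


def _stage_fit(cfg: RunConfig) -> list[Path]:
    model = build_model(cfg.variant)
    data, protos = _load_tabular(cfg)
    box = initial_search_box(model)
    ranked = multistart_map(model, data, box, cfg.sampler.n_starts,
                            seed=cfg.seed, protocols=protos,
                            maxiter=cfg.sampler.map_maxiter)
    best, best_lp = ranked[0]
    prior = default_prior_box(model, best,
                              half_width=cfg.sampler.prior_half_width)
    out_map = cfg.out / f"map_{cfg.variant}.json"
    out_map.write_text(json.dumps({
        "variant": cfg.variant,
        "ranked": [{"log_posterior": lp,
                    "params_log10": dict(zip(model.parameter_names, map(float, x)))}
                   for x, lp in ranked]}, indent=1, sort_keys=True))
    out_prior = cfg.out / f"prior_{cfg.variant}.json"
    out_prior.write_text(json.dumps(prior.to_json_dict(), indent=1,
                                    sort_keys=True))
    _write_manifest(cfg, f"fit_{cfg.variant}",
                    [cfg.out / "dataset.csv", cfg.out / "protocols.json"],
                    [out_map, out_prior],
                    {"n_starts": cfg.sampler.n_starts,
                     "maxiter": cfg.sampler.map_maxiter})
    return [out_map, out_prior]


def _chains_digest(runs) -> str:
    h = hashlib.sha256()
    for r in runs:
        h.update(np.ascontiguousarray(r.samples).tobytes())
        h.update(np.ascontiguousarray(r.log_like).tobytes())
    return h.hexdigest()


def _stage_sample(cfg: RunConfig) -> list[Path]:
    model = build_model(cfg.variant)
    data, protos = _load_tabular(cfg)
    prior_path = _require(cfg.out / f"prior_{cfg.variant}.json", "fit")
    prior = PriorSpec.from_json_dict(json.loads(prior_path.read_text()))
    map_path = _require(cfg.out / f"map_{cfg.variant}.json", "fit")
    best = json.loads(map_path.read_text())["ranked"][0]["params_log10"]
    init = np.array([best[n] for n in model.parameter_names])
    lik = GaussianLikelihood(model, data, protos)
    lo, hi = prior.arrays(model.parameter_names)
    s = cfg.sampler
    runs = pt_sample(
        lambda x: log_prior(x, prior, model.parameter_names), lik,
        Ladder.power_law(s.levels, s.ladder_exponent), s.iterations,
        n_runs=s.runs, seed=cfg.seed, init=init,
        step_scale=s.step_frac * (hi - lo), burn_in=s.burn_in,
        prior_sampler=lambda rng: lo + (hi - lo) * rng.random(lo.size))
    out_chains = cfg.out / f"chains_{cfg.variant}.npz"
    diag = gelman_rubin(runs, burn_in=s.burn_in) if s.runs > 1 else None
    save_chains(out_chains, runs, extra_meta={
        "variant": cfg.variant, "chains_digest": _chains_digest(runs),
        "rhat_max": (float(np.nanmax(diag.rhat)) if diag is not None else None)})
    _write_manifest(cfg, f"sample_{cfg.variant}",
                    [cfg.out / "dataset.csv", prior_path, map_path],
                    [out_chains.with_suffix(".json")],
                    {"sampler": asdict(s), "chains_digest": _chains_digest(runs)})
    return [out_chains]


def _stage_evidence(cfg: RunConfig) -> list[Path]:
    for v in ("A", "B"):
        path = cfg.out / f"chains_{v}.npz"
        if not path.exists():
            raise FileNotFoundError(
                f"evidence needs chains for both variants; missing {path.name} "
                f"(run 'sample' with variant {v})")
    estimates = {}
    for v in ("A", "B"):
        runs = load_chains(cfg.out / f"chains_{v}.npz")
        estimates[v] = estimate_evidence(runs, v, burn_in=cfg.sampler.burn_in)
    bf = bayes_factor(estimates["A"], estimates["B"])
    out = cfg.out / "evidence.json"
    out.write_text(json.dumps({
        "log_z": {v: {"value": e.log_z, "se": e.se,
                      "per_run": list(e.per_run_log_z)}
                  for v, e in estimates.items()},
        "two_log_k_AB": bf.two_log_k, "se": bf.se, "category": bf.category},
        indent=1, sort_keys=True))
    _write_manifest(cfg, "evidence",
                    [cfg.out / "chains_A.json", cfg.out / "chains_B.json"],
                    [out], {"burn_in": cfg.sampler.burn_in})
    return [out]


def _posterior_subsample(cfg: RunConfig):
    runs = load_chains(_require(cfg.out / f"chains_{cfg.variant}.npz", "sample"))
    n = min(cfg.sampler.posterior_draws,
            sum(r.posterior_draws(cfg.sampler.burn_in).shape[0] for r in runs))
    return subsample_posterior(runs, n, seed=cfg.seed,
                               burn_in=cfg.sampler.burn_in)


def _stage_predict(cfg: RunConfig) -> list[Path]:
    model = build_model(cfg.variant)
    sample = _posterior_subsample(cfg)
    pred = endogenous_distributions(model, sample)
    out = cfg.out / f"predictions_{cfg.variant}.json"
    out.write_text(json.dumps(
        {"variant": cfg.variant, "n_draws": int(pred.states.shape[0]),
         "n_dropped": pred.n_dropped,
         "summaries": {k: asdict(v) for k, v in pred.summary().items()}},
        indent=1, sort_keys=True))
    _write_manifest(cfg, f"predict_{cfg.variant}",
                    [cfg.out / f"chains_{cfg.variant}.json"], [out],
                    {"posterior_draws": cfg.sampler.posterior_draws})
    return [out]


def _stage_perturb(cfg: RunConfig) -> list[Path]:
    model = build_model(cfg.variant)
    sample = _posterior_subsample(cfg)
    report = {}
    for kind in ("feedback_knockout", "transfer_up_10", "pkd_up_10"):
        res = perturbation_response(model, sample, PerturbationScenario(kind))
        d = res["draws"]
        report[kind] = {
            "expectation_pct": res["expectation"],
            "band_pct": [float(np.percentile(d, 0.5)),
                         float(np.percentile(d, 99.5))],
            "n_dropped": res["n_dropped"]}
    out = cfg.out / f"perturbation_{cfg.variant}.json"
    out.write_text(json.dumps(report, indent=1, sort_keys=True))
    _write_manifest(cfg, f"perturb_{cfg.variant}",
                    [cfg.out / f"chains_{cfg.variant}.json"], [out],
                    {"posterior_draws": cfg.sampler.posterior_draws})
    return [out]


def _stage_quantify(cfg: RunConfig) -> list[Path]:
    if not cfg.quantify_inputs:
        raise ValueError("quantify stage needs cfg.quantify_inputs "
                         "(standards_csv, intensity, ratio_endo_to_ectopic, "
                         "n_cells, optional cv_inputs)")
    q = cfg.quantify_inputs
    standards = pd.read_csv(q["standards_csv"])
    curve = fit_standard_curve(standards[["molecules", "intensity"]].to_numpy())
    inv = inverse_predict(curve, q["intensity"])
    cv_inv = inv.se / inv.molecules if inv.valid else np.nan
    est = endogenous_abundance(q["ratio_endo_to_ectopic"], inv.molecules,
                               q["n_cells"],
                               cvs=tuple(q.get("cv_inputs", (cv_inv, 0.0))))
    cfg.out.mkdir(parents=True, exist_ok=True)
    out = cfg.out / "abundance.json"
    out.write_text(json.dumps({
        "standard_curve": {"slope": curve.slope, "intercept": curve.intercept,
                           "residual_sd": curve.residual_sd, "n": curve.n},
        "ectopic_molecules": inv.molecules, "ectopic_se": inv.se,
        "molecules_per_cell": est.molecules_per_cell, "cv": est.cv},
        indent=1, sort_keys=True))
    _write_manifest(cfg, "quantify", [Path(q["standards_csv"])], [out],
                    {k: v for k, v in q.items() if k != "standards_csv"})
    return [out]


def run_pipeline(config: RunConfig, stage: str = "all") -> list[Path]:
    """Run one pipeline stage (or ``all``); returns the produced paths."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    dispatch = {
        "synth": _stage_synth, "fit": _stage_fit, "sample": _stage_sample,
        "evidence": _stage_evidence, "predict": _stage_predict,
        "perturb": _stage_perturb, "quantify": _stage_quantify,
    }
    if stage != "all":
        return dispatch[stage](config)
    out: list[Path] = []
    out += _stage_synth(config)
    for variant in ("A", "B"):
        sub = RunConfig(out_dir=config.out_dir, variant=variant,
                        seed=config.seed, sampler=config.sampler,
                        noise=config.noise,
                        exclude_protocols=config.exclude_protocols)
        out += _stage_fit(sub)
        out += _stage_sample(sub)
    out += _stage_evidence(config)
    out += _stage_predict(config)
    out += _stage_perturb(config)
    return out
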