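"""Synthetic datasets with the statistical structure of the real experiments.

The generator emulates the calibration study design:

* **E1** — absolute quantification of endogenous PKD, PI4KIIIbeta and CERT
  totals at rest (all inputs zero), replicated, with coefficients of
  variation in the 25-40% range typical of blot-based absolute counts;
* **E2** — 24 h ectopic expression of PI4KIIIbeta (u3), absolute
  PI4KIIIbeta total at 24 h, then PDBu activation of PKD (u1) with relative
  phospho-PKD and phospho-PI4KIIIbeta time courses within the next hour;
* **E3** — 24 h ectopic expression of CERT (u4) with absolute CERT totals at
  8/16/24 h, then kb-NB142-70 inhibition of PKD (u2) with relative
  phospho-PKD and phospho-CERT courses over three hours;
* **E4a/E4b** — refinement measurements: early PKD activation during
  ectopic PI4KIIIbeta expression, and the long-time phospho-PKD course up
  to six hours after PDBu;
* **E5** — the validation point: phospho-PI4KIIIbeta at 25.25 h after
  ectopic expression from 0 h and PKD inhibition at 24 h.

Absolute replicates are drawn from a normal with SD = CV * mean, truncated
at zero (the recorded SD stays the pre-truncation value, keeping the
Gaussian likelihood consistent); relative courses get additive noise with
SD equal to a fraction of the course maximum.  Identical seeds give
byte-identical CSV output.

The shipped ground-truth parameterizations (one per variant) are fixture
choices tuned so endogenous totals sit near the measured magnitudes
(PI4KIIIbeta ~2e6, PKD and CERT ~5e5 molecules/cell) with most PKD and
PI4KIIIbeta unphosphorylated at rest; they are documented in
``data/groundtruth_A.json`` / ``_B.json``.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .inference import DATASET_COLUMNS
from .models import InputSignal, build_model
from .protocols import ObservationSpec, Protocol, protocols_to_json, simulate

__all__ = ["NoiseSpec", "default_protocols", "generate_dataset",
           "ground_truth", "dataset_to_csv"]


@dataclass(frozen=True)
class NoiseSpec:
    cv_absolute: float = 0.30
    rel_sd_frac: float = 0.10
    replicates: int = 3
    seed: int = 0
    allow_out_of_band_cv: bool = False

    def __post_init__(self):
        if not self.allow_out_of_band_cv and not 0.25 <= self.cv_absolute <= 0.40:
            raise ValueError(
                "cv_absolute outside the observed 0.25-0.40 band; "
                "set allow_out_of_band_cv=True to override")
        if self.rel_sd_frac < 0 or self.replicates < 1:
            raise ValueError("invalid noise specification")


def default_protocols(pdbu_refinement_horizon: float = 6.0) -> list[Protocol]:
    """The calibration/refinement/validation protocol set described above."""
    t24 = 24.0
    e2_times = tuple(t24 + dt for dt in (0.0, 1 / 6, 1 / 3, 1 / 2, 1.0))
    e3_times = tuple(t24 + dt for dt in (0.0, 1.0, 2.0, 3.0))
    e4b_times = tuple(t24 + dt for dt in (2.0, 4.0, pdbu_refinement_horizon))
    return [
        Protocol("E1", InputSignal.none(),
                 (ObservationSpec("PKD_total", "absolute", (0.0,)),
                  ObservationSpec("PI4K_total", "absolute", (0.0,)),
                  ObservationSpec("CERT_total", "absolute", (0.0,))),
                 horizon=0.0),
        Protocol("E2", InputSignal.steps(u3=(0.0, 1.0), u1=(t24, 1.0)),
                 (ObservationSpec("PI4K_total", "absolute", (t24,)),
                  ObservationSpec("pPKD", "relative", e2_times),
                  ObservationSpec("pPI4K", "relative", e2_times)),
                 horizon=25.0),
        Protocol("E3", InputSignal.steps(u4=(0.0, 1.0), u2=(t24, 1.0)),
                 (ObservationSpec("CERT_total", "absolute", (8.0, 16.0, t24)),
                  ObservationSpec("pPKD", "relative", e3_times),
                  ObservationSpec("pCERT", "relative", e3_times)),
                 horizon=27.0),
        Protocol("E4a", InputSignal.steps(u3=(0.0, 1.0)),
                 (ObservationSpec("pPKD", "relative", (1.0, 2.0, 4.0)),),
                 horizon=4.0),
        Protocol("E4b", InputSignal.steps(u3=(0.0, 1.0), u1=(t24, 1.0)),
                 (ObservationSpec("pPKD", "relative", e4b_times),),
                 horizon=t24 + pdbu_refinement_horizon),
        Protocol("E5", InputSignal.steps(u3=(0.0, 1.0), u2=(t24, 1.0)),
                 (ObservationSpec("pPI4K", "relative", (25.25,)),),
                 horizon=25.25),
    ]


def ground_truth(variant: str) -> dict[str, float]:
    """Documented ground-truth parameter values shipped with the package."""
    if variant not in ("A", "B"):
        raise ValueError(f"unknown variant {variant!r}")
    ref = importlib.resources.files("tgnkin.data") / f"groundtruth_{variant}.json"
    doc = json.loads(ref.read_text())
    return {k: float(v) for k, v in doc["parameters"].items()}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0.0:
            return v
    return 0.0  # pragma: no cover - mean >> sd in practice


def generate_dataset(variant: str, params, protocols=None,
                     noise: NoiseSpec | None = None
                     ) -> tuple[pd.DataFrame, dict]:
    """Simulate every protocol noise-free and overlay measurement noise.

    Returns the dataset (one row per measurement record) and a ground-truth
    document holding the generating parameters, the noise specification, the
    protocol schedule and the noise-free observables.
    """
    noise = noise or NoiseSpec()
    protocols = protocols if protocols is not None else default_protocols()
    model = build_model(variant)
    rng = np.random.default_rng(noise.seed)
    rows = []
    noise_free: dict[str, dict] = {}
    for proto in protocols:
        try:
            traj = simulate(model, params, proto)
        except RuntimeError as exc:
            raise RuntimeError(
                f"simulation of protocol {proto.pid} failed: {exc}") from exc
        nf_proto = noise_free.setdefault(proto.pid, {})
        for spec in proto.observations:
            m = traj.series(spec.observable, spec.times)
            nf_proto[spec.observable] = {"mode": spec.mode,
                                         "times_h": list(spec.times),
                                         "values": [float(v) for v in m]}
            if spec.mode == "absolute":
                for t, mt in zip(spec.times, m):
                    sd = noise.cv_absolute * mt
                    for _ in range(noise.replicates):
                        value = _truncated_normal(rng, mt, sd) if sd > 0 else mt
                        rows.append((proto.pid, proto.pid, spec.observable,
                                     "absolute", t, value, sd))
            else:
                sd = noise.rel_sd_frac * float(np.max(m))
                if noise.rel_sd_frac > 0 and sd <= 0:
                    raise RuntimeError(
                        f"flat zero course for {spec.observable} in {proto.pid}")
                for t, mt in zip(spec.times, m):
                    value = mt + rng.normal(0.0, sd) if sd > 0 else mt
                    rows.append((proto.pid, proto.pid, spec.observable,
                                 "relative", t, value, sd))
    data = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    truth = {
        "variant": variant,
        "parameters": {k: float(v) for k, v in (
            params.items() if isinstance(params, dict)
            else zip(model.parameter_names, params))},
        "noise": asdict(noise),
        "protocols": json.loads(protocols_to_json(list(protocols))),
        "noise_free": noise_free,
    }
    return data, truth


def dataset_to_csv(data: pd.DataFrame, path) -> None:
    """Write the dataset deterministically (fixed float formatting)."""
    data.to_csv(path, index=False, float_format="%.10g")
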