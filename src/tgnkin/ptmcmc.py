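"""Parallel-tempering Metropolis sampler with swap moves and diagnostics.

The sampler runs a Gaussian random-walk Metropolis chain in log10 parameter
space at every inverse temperature of a ladder, and attempts one randomly
chosen adjacent-pair state swap per iteration with acceptance probability
``min(1, exp((beta_i - beta_j) * (logL_j - logL_i)))``.  Proposal step sizes
are adapted toward a 20-30% acceptance rate during burn-in and frozen
afterwards, preserving the stationary distribution.  Everything is
deterministic given the seed.

The default ladder follows the power-law schedule ``beta_i = (i/(L-1))^5``,
which concentrates levels near beta = 0 where the thermodynamic-integration
integrand varies fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Ladder", "ChainSet", "ChainDiagnostics", "pt_sample",
           "gelman_rubin", "subsample_posterior", "save_chains", "load_chains"]


@dataclass(frozen=True)
class Ladder:
    """Strictly increasing inverse temperatures from exactly 0 to exactly 1."""

    betas: tuple[float, ...]

    def __post_init__(self):
        b = np.asarray(self.betas, dtype=float)
        if b.size < 1:
            raise ValueError("ladder must have at least one level")
        if b.size > 1:
            if b[0] != 0.0 or b[-1] != 1.0:
                raise ValueError("ladder endpoints must be exactly 0 and 1")
            if np.any(np.diff(b) <= 0):
                raise ValueError("ladder must be strictly increasing")
        elif b[0] != 1.0:
            raise ValueError("a single-level ladder must be [1.0]")

    @classmethod
    def power_law(cls, n_levels: int = 10, exponent: float = 5.0) -> "Ladder":
        if n_levels == 1:
            return cls((1.0,))
        i = np.arange(n_levels, dtype=float)
        return cls(tuple((i / (n_levels - 1)) ** exponent))

    def __len__(self):
        return len(self.betas)

    def array(self) -> np.ndarray:
        return np.asarray(self.betas, dtype=float)


@dataclass
class ChainSet:
    """One PT run: per-level sample arrays, traces and acceptance metadata."""

    betas: np.ndarray            # (L,)
    samples: np.ndarray          # (L, n_iter, d), log10 scale
    log_like: np.ndarray         # (L, n_iter)
    accept_rate: np.ndarray      # (L,)
    swap_accept_rate: np.ndarray  # (L-1,)
    step_sizes: np.ndarray       # (L,) final (frozen) proposal scales
    seed: int
    run_id: int
    n_failed: int = 0            # likelihood evaluations returning NaN/-inf

    @property
    def n_iter(self) -> int:
        return self.samples.shape[1]

    def posterior_draws(self, burn_in: float = 0.5) -> np.ndarray:
        """Post-burn-in draws of the beta = 1 chain."""
        start = int(self.n_iter * burn_in)
        return self.samples[-1, start:, :]

    def mean_log_like(self, burn_in: float = 0.5) -> np.ndarray:
        """Per-level posterior-mean log-likelihood (finite draws only).

        A level whose post-burn-in trace is entirely non-finite (a hot chain
        parked in a non-simulatable region) falls back to the finite values
        of its full trace.
        """
        start = int(self.n_iter * burn_in)
        out = np.empty(len(self.betas))
        for i in range(len(self.betas)):
            trace = self.log_like[i, start:]
            finite = trace[np.isfinite(trace)]
            if finite.size == 0:
                finite = self.log_like[i][np.isfinite(self.log_like[i])]
            if finite.size == 0:
                raise RuntimeError(
                    f"no finite log-likelihood values at beta={self.betas[i]}")
            out[i] = finite.mean()
        return out


@dataclass(frozen=True)
class ChainDiagnostics:
    """Potential scale reduction across independent runs."""

    rhat: np.ndarray
    passed: bool
    degenerate: np.ndarray  # per-parameter zero-within-variance flag


def pt_sample(log_prior_fn, log_like_fn, ladder: Ladder, n_iter: int, *,
              n_runs: int = 1, seed: int = 0, init, step_scale,
              burn_in: float = 0.5, target_accept: float = 0.25,
              adapt_interval: int = 50, prior_sampler=None) -> list[ChainSet]:
    """Run ``n_runs`` independent parallel-tempering samplers.

    ``init`` is the common starting point (d,) or a callable ``rng -> (d,)``
    drawn independently per run and level; ``step_scale`` is the initial
    per-parameter proposal scale (scalar or (d,)).  Targets returning NaN
    are treated as -inf and counted in ``n_failed``.

    ``prior_sampler`` (optional, ``rng -> (d,)``) must draw exactly from the
    prior; when given, the beta = 0 level uses it as an independence
    proposal — its target *is* the prior, so such moves renew the hottest
    chain with uncorrelated draws and feed fresh states up the ladder.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    betas = ladder.array()
    L = betas.size
    runs = []
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    for run_id, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)

        def draw_init():
            return np.asarray(init(rng) if callable(init) else init, dtype=float)

        x = np.stack([draw_init() for _ in range(L)])
        d = x.shape[1]
        scale = np.broadcast_to(np.asarray(step_scale, dtype=float), (d,)).copy()
        # per-level, per-parameter proposal scales; during burn-in they are
        # re-estimated from the chain's own coordinate spread (diagonal
        # adaptive Metropolis), the global multiplier tunes acceptance
        scale_lev = np.tile(scale, (L, 1))
        log_step = np.zeros(L)  # per-level multiplier on `scale_lev`, log units
        n_failed = 0

        def eval_target(xi):
            nonlocal n_failed
            lp = log_prior_fn(xi)
            if not np.isfinite(lp):
                return -np.inf, -np.inf
            ll = log_like_fn(xi)
            if np.isnan(ll):
                n_failed += 1
                ll = -np.inf
            return lp, ll

        lp = np.empty(L)
        ll = np.empty(L)
        for i in range(L):
            lp[i], ll[i] = eval_target(x[i])

        samples = np.empty((L, n_iter, d))
        ll_trace = np.empty((L, n_iter))
        acc = np.zeros(L)
        acc_batch = np.zeros(L)
        swap_att = np.zeros(max(L - 1, 1))
        swap_acc = np.zeros(max(L - 1, 1))
        n_burn = int(n_iter * burn_in)

        def tempered(i):
            if betas[i] == 0.0 or not np.isfinite(ll[i]):
                return lp[i] + (0.0 if betas[i] == 0.0 else -np.inf)
            return lp[i] + betas[i] * ll[i]

        for it in range(n_iter):
            for i in range(L):
                if betas[i] == 0.0 and prior_sampler is not None:
                    # independence move from the prior itself (q = target)
                    prop = np.asarray(prior_sampler(rng), dtype=float)
                else:
                    prop = x[i] + np.exp(log_step[i]) * scale_lev[i] \
                        * rng.standard_normal(d)
                lp_p, ll_p = eval_target(prop)
                if betas[i] == 0.0:
                    if prior_sampler is not None:
                        # exact prior draws: proposal density cancels the
                        # target, acceptance is 1 for any valid draw
                        log_alpha = 0.0 if np.isfinite(lp_p) else -np.inf
                    else:
                        log_alpha = lp_p - lp[i]
                else:
                    cur = tempered(i)
                    new = (lp_p + betas[i] * ll_p) if np.isfinite(ll_p) else -np.inf
                    log_alpha = new - cur
                if log_alpha >= 0.0 or np.log(rng.random()) < log_alpha:
                    x[i], lp[i], ll[i] = prop, lp_p, ll_p
                    acc[i] += 1
                    acc_batch[i] += 1
            if L > 1:
                i = int(rng.integers(L - 1))
                j = i + 1
                swap_att[i] += 1
                dll = ll[j] - ll[i]
                if not np.isfinite(dll):
                    dll = -np.inf if (np.isfinite(ll[i]) and not np.isfinite(ll[j])) \
                        else (np.inf if np.isfinite(ll[j]) else 0.0)
                log_alpha = (betas[i] - betas[j]) * dll
                if log_alpha >= 0.0 or np.log(rng.random()) < log_alpha:
                    swap_acc[i] += 1
                    x[[i, j]] = x[[j, i]]
                    lp[[i, j]] = lp[[j, i]]
                    ll[[i, j]] = ll[[j, i]]
            samples[:, it, :] = x
            ll_trace[:, it] = ll
            if it < n_burn and (it + 1) % adapt_interval == 0:
                rate = acc_batch / adapt_interval
                log_step += np.clip(rate - target_accept, -0.5, 0.5)
                # cap the multiplier: unbounded growth (e.g. at beta = 0,
                # where every in-box proposal is accepted) would freeze the
                # chain after burn-in
                np.clip(log_step, -4.0, 1.5, out=log_step)
                acc_batch[:] = 0.0
                # diagonal adaptation toward the chain's own spread (classic
                # 2.38/sqrt(d) scaling), bounded against collapse or blow-up,
                # frozen with everything else after burn-in
                w0 = max(0, it + 1 - 8 * adapt_interval)
                if it + 1 - w0 >= 2 * adapt_interval:
                    sd = samples[:, w0:it + 1, :].std(axis=1)
                    good = sd > 0
                    target_sc = 2.38 / np.sqrt(d) * sd
                    blended = 0.5 * scale_lev + 0.5 * target_sc
                    lo_b, hi_b = 0.05 * scale, 20.0 * scale
                    scale_lev[good] = np.clip(blended, lo_b, hi_b)[good]

        runs.append(ChainSet(
            betas=betas.copy(), samples=samples, log_like=ll_trace,
            accept_rate=acc / n_iter,
            swap_accept_rate=(swap_acc / np.maximum(swap_att, 1))[: max(L - 1, 0)],
            step_sizes=np.exp(log_step), seed=seed, run_id=run_id,
            n_failed=n_failed))
    return runs


def gelman_rubin(runs: list[ChainSet], beta_index: int = -1,
                 burn_in: float = 0.5, threshold: float = 1.1) -> ChainDiagnostics:
    """Potential scale reduction R-hat across independent runs.

    ``R = sqrt(((N-1)/N * W + B/N) / W)`` with W the mean within-run variance
    and B/N the variance of the run means.  Zero within-run variance yields
    R-hat = +inf with a degenerate-chain flag.
    """
    if len(runs) < 2:
        raise ValueError("need at least two independent runs")
    start = int(runs[0].n_iter * burn_in)
    draws = np.stack([r.samples[beta_index, start:, :] for r in runs])  # (M,N,d)
    if any(r.n_iter != runs[0].n_iter for r in runs):
        raise ValueError("runs must have equal iteration counts")
    N = draws.shape[1]
    W = draws.var(axis=1, ddof=1).mean(axis=0)
    B_over_N = draws.mean(axis=1).var(axis=0, ddof=1)
    degenerate = W == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(((N - 1) / N * W + B_over_N) / W)
    rhat = np.where(degenerate, np.inf, rhat)
    passed = bool(np.all(rhat[~degenerate] < threshold)) and not degenerate.any()
    return ChainDiagnostics(rhat=rhat, passed=passed, degenerate=degenerate)


def subsample_posterior(chains, n_out: int, seed: int,
                        burn_in: float = 0.5, thin: int = 1) -> np.ndarray:
    """Representative posterior subsample from the beta = 1 chain(s).

    Burn-in is discarded, draws are thinned uniformly and pooled across runs,
    then ``n_out`` draws are taken without replacement (all of them, in
    order, when ``n_out`` equals the retained count).  Deterministic given
    the seed.
    """
    if isinstance(chains, ChainSet):
        chains = [chains]
    pool = np.concatenate([c.posterior_draws(burn_in)[::thin] for c in chains])
    if n_out > pool.shape[0]:
        raise ValueError(
            f"requested {n_out} draws but only {pool.shape[0]} are available")
    if n_out == pool.shape[0]:
        return pool.copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool.shape[0], size=n_out, replace=False))
    return pool[idx]


def save_chains(path, runs: list[ChainSet], extra_meta: dict | None = None):
    """Persist runs as compressed arrays with a JSON sidecar."""
    path = Path(path)
    arrays = {}
    meta = {"n_runs": len(runs), "betas": list(map(float, runs[0].betas)),
            "seed": runs[0].seed}
    if extra_meta:
        meta.update(extra_meta)
    for r in runs:
        arrays[f"samples_{r.run_id}"] = r.samples
        arrays[f"log_like_{r.run_id}"] = r.log_like
        arrays[f"accept_{r.run_id}"] = r.accept_rate
        arrays[f"swap_{r.run_id}"] = r.swap_accept_rate
        arrays[f"steps_{r.run_id}"] = r.step_sizes
        meta[f"n_failed_{r.run_id}"] = int(r.n_failed)
    np.savez_compressed(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))


def load_chains(path) -> list[ChainSet]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path)
    runs = []
    for run_id in range(meta["n_runs"]):
        runs.append(ChainSet(
            betas=np.asarray(meta["betas"], dtype=float),
            samples=data[f"samples_{run_id}"],
            log_like=data[f"log_like_{run_id}"],
            accept_rate=data[f"accept_{run_id}"],
            swap_accept_rate=data[f"swap_{run_id}"],
            step_sizes=data[f"steps_{run_id}"],
            seed=meta["seed"], run_id=run_id,
            n_failed=meta.get(f"n_failed_{run_id}", 0)))
    return runs
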