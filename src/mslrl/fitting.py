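"""Per-run maximum-likelihood estimation of the RLDDM and model selection.

The likelihood of a run multiplies, over response trials, the Wiener
first-passage density of the observed (rt, choice) given the trial's
drift rate from the forward Rescorla-Wagner pass.  Omitted trials and
trials excluded from RT analyses (rt < 200 ms or beyond 3 within-run SD)
contribute no likelihood term but still drive the value updates -
learning happened on them regardless of measurement quality.

Each model/run is fitted independently by seeded differential evolution
(a population-based global optimizer; the population members play the
role of parallel restarts) with an L-BFGS-B polish, inside fixed bounds:
learning rates in [0, 1], drift weight in [0, 20], boundary in [0.3, 5],
non-decision time in [0.1, min observed RT - 0.01].  The starting point
z = 0.5 and initial values V = 0.5 are never free.  Variants are
compared per run by BIC = k ln N - 2 logL with N the number of trials in
the likelihood; ties go to the model with fewer parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import differential_evolution

from mslrl.analysis import rt_inclusion_mask
from mslrl.ddm import DDMParams, LIKELIHOOD_FLOOR, SERIES_ERR, _wfpt, response_likelihood
from mslrl.rl_models import MODELS, RLParams, run_model
from mslrl.simulate import BehaviouralRecord, simulate_run
from mslrl.task_design import TrialSequence, default_config, generate_run

DEFAULT_BOUNDS = {
    "eta": (0.0, 1.0),
    "vmod": (0.0, 20.0),
    "a": (0.3, 5.0),
    "tau_lo": 0.1,
}


@dataclass
class FitResult:
    """Outcome of fitting one model variant to one run."""

    model: str
    variant: str
    params: dict[str, float]
    logL: float
    n_params: int
    n_trials_used: int
    bic: float
    converged: bool
    n_restarts: int
    seed: int | None = None

    def as_row(self) -> dict:
        return {
            "model": self.model,
            "variant": self.variant,
            "logL": self.logL,
            "n_params": self.n_params,
            "n_trials_used": self.n_trials_used,
            "bic": self.bic,
            "converged": self.converged,
            **self.params,
        }


@dataclass
class RunData:
    """Run packed into flat arrays for the fast likelihood core."""

    variant: str
    n_pairs: int
    left_idx: np.ndarray      # DC: pair index of the left option
    right_idx: np.ndarray     # DC: pair index of the right option
    pres_idx: np.ndarray      # MR: pair index of the presented pair
    choice: np.ndarray        # 1 upper (left/match), 0 lower, -1 omission
    reward: np.ndarray        # delivered feedback 1/0, -1 neutral
    rt: np.ndarray
    include: np.ndarray       # bool: trial contributes a likelihood term
    overlap: np.ndarray       # MR: (n_pairs, k) indices of overlapping pairs


def pack_run(seq: TrialSequence, behaviour: BehaviouralRecord) -> RunData:
    if len(behaviour) != len(seq):
        raise ValueError("behaviour and sequence lengths differ")
    cfg = seq.config
    n = len(seq)
    nv = cfg.n_visual
    n_pairs = cfg.n_audio_tactile * nv
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)
    pres = np.zeros(n, dtype=np.int64)
    choice = np.full(n, -1, dtype=np.int64)
    reward = np.full(n, -1, dtype=np.int64)
    rts = np.asarray(behaviour.rts, dtype=float)
    for i, (tr, resp, out) in enumerate(
        zip(seq, behaviour.responses, behaviour.outcomes)
    ):
        s = tr.sound_index
        if cfg.variant == "discriminative_choice":
            left[i] = s * nv + tr.visual_left
            right[i] = s * nv + tr.visual_right
            if resp is not None:
                choice[i] = 1 if resp == "left" else 0
        else:
            pres[i] = s * nv + tr.visual
            if resp is not None:
                choice[i] = 1 if resp == "match" else 0
        if out is not None:
            reward[i] = out
    include = rt_inclusion_mask(rts)
    if cfg.variant == "match_recognition":
        rows = []
        for p in range(n_pairs):
            s, v = divmod(p, nv)
            rows.append(
                [q for q in range(n_pairs)
                 if q != p and (q // nv == s or q % nv == v)]
            )
        overlap = np.array(rows, dtype=np.int64)
    else:
        overlap = np.zeros((0, 0), dtype=np.int64)
    return RunData(
        variant=cfg.variant, n_pairs=n_pairs, left_idx=left, right_idx=right,
        pres_idx=pres, choice=choice, reward=reward, rt=rts,
        include=include, overlap=overlap,
    )


@njit(cache=True)
def _nll_dc(
    cp, cn, op, on, vmod, a, tau, use_transfer,
    left_idx, right_idx, choice, reward, rt, include, n_pairs,
):
    eps = 1e-6
    V = np.full(n_pairs, 0.5)
    nll = 0.0
    for i in range(left_idx.size):
        vl = min(max(V[left_idx[i]], eps), 1.0 - eps)
        vr = min(max(V[right_idx[i]], eps), 1.0 - eps)
        num = vl * (1.0 - vr)
        nc = num / (num + vr * (1.0 - vl))
        drift = (2.0 * nc - 1.0) * vmod
        if include[i]:
            t = rt[i] - tau
            if t <= 0.0:
                dens = 1e-10
            elif choice[i] == 1:  # upper boundary = left response
                dens = _wfpt(t, -drift, a, 0.5, 1e-10)
            else:
                dens = _wfpt(t, drift, a, 0.5, 1e-10)
            nll -= math.log(max(dens, 1e-10))
        if choice[i] >= 0 and reward[i] >= 0:
            R = float(reward[i])
            if choice[i] == 1:
                ci, oi = left_idx[i], right_idx[i]
            else:
                ci, oi = right_idx[i], left_idx[i]
            eta_c = cp if reward[i] == 1 else cn
            V[ci] += eta_c * (R - V[ci])
            if use_transfer:
                eta_o = op if reward[i] == 1 else on
                V[oi] += eta_o * ((1.0 - R) - V[oi])
    return nll


@njit(cache=True)
def _nll_mr(
    cp, cn, eo, vmod, a, tau, use_transfer,
    pres_idx, choice, reward, rt, include, n_pairs, overlap,
):
    V = np.full(n_pairs, 0.5)
    nll = 0.0
    for i in range(pres_idx.size):
        p = pres_idx[i]
        drift = (2.0 * V[p] - 1.0) * vmod
        if include[i]:
            t = rt[i] - tau
            if t <= 0.0:
                dens = 1e-10
            elif choice[i] == 1:  # upper boundary = "match" response
                dens = _wfpt(t, -drift, a, 0.5, 1e-10)
            else:
                dens = _wfpt(t, drift, a, 0.5, 1e-10)
            nll -= math.log(max(dens, 1e-10))
        if choice[i] >= 0 and reward[i] >= 0:
            r_prime = 1.0 if choice[i] == reward[i] else 0.0
            eta_c = cp if reward[i] == 1 else cn
            V[p] += eta_c * (r_prime - V[p])
            if use_transfer and reward[i] == 1:
                for j in range(overlap.shape[1]):
                    q = overlap[p, j]
                    V[q] += eo * ((1.0 - r_prime) - V[q])
    return nll


def _theta_names(model: str, variant: str) -> list[str]:
    if model == "simple":
        rates = ["eta_c"]
    elif model == "simple_asym":
        rates = ["eta_c_pos", "eta_c_neg"]
    elif model == "transfer":
        rates = ["eta_c", "eta_o"]
    elif model == "transfer_asym":
        if variant == "discriminative_choice":
            rates = ["eta_c_pos", "eta_c_neg", "eta_o_pos", "eta_o_neg"]
        else:
            rates = ["eta_c_pos", "eta_c_neg", "eta_o"]
    else:
        raise ValueError(f"unknown model {model!r}")
    return rates + ["vmod", "a", "tau"]


def _theta_to_params(theta: np.ndarray, model: str, variant: str):
    names = _theta_names(model, variant)
    d = dict(zip(names, (float(x) for x in theta)))
    rl = RLParams(
        model=model,
        eta_c=d.get("eta_c", 0.0),
        eta_c_pos=d.get("eta_c_pos", d.get("eta_c", 0.0)),
        eta_c_neg=d.get("eta_c_neg", d.get("eta_c", 0.0)),
        eta_o=d.get("eta_o", 0.0),
        eta_o_pos=d.get("eta_o_pos", d.get("eta_o", 0.0)),
        eta_o_neg=d.get("eta_o_neg", d.get("eta_o", 0.0)),
    )
    return rl, d["vmod"], d["a"], d["tau"], d


def _nll_packed(theta: np.ndarray, data: RunData, model: str) -> float:
    rl, vmod, a, tau, _ = _theta_to_params(theta, model, data.variant)
    cp, cn, op, on = rl.effective_rates()
    use_transfer = model in ("transfer", "transfer_asym")
    if data.variant == "discriminative_choice":
        return _nll_dc(
            cp, cn, op, on, vmod, a, tau, use_transfer,
            data.left_idx, data.right_idx, data.choice, data.reward,
            data.rt, data.include, data.n_pairs,
        )
    eo = op  # MR transfer fires only after positive feedback
    return _nll_mr(
        cp, cn, eo, vmod, a, tau, use_transfer,
        data.pres_idx, data.choice, data.reward, data.rt, data.include,
        data.n_pairs, data.overlap,
    )


def negative_log_likelihood(
    seq: TrialSequence,
    behaviour: BehaviouralRecord,
    rl: RLParams,
    ddm: DDMParams,
    vmod: float,
    fast: bool = True,
) -> float:
    """Negative log-likelihood (nats) of a run under one RLDDM variant.

    ``fast=True`` uses the compiled forward/likelihood core; ``fast=False``
    composes the pure forward pass (:func:`mslrl.rl_models.run_model`)
    with :func:`mslrl.ddm.response_likelihood` trial by trial - the two
    routes agree to numerical precision.
    """
    if not np.isfinite([vmod, ddm.a, ddm.tau]).all():
        return np.inf
    if fast:
        data = pack_run(seq, behaviour)
        names = _theta_names(rl.model, seq.config.variant)
        cp, cn, op, on = rl.effective_rates()
        lookup = {
            "eta_c": rl.eta_c, "eta_c_pos": cp, "eta_c_neg": cn,
            "eta_o": rl.eta_o, "eta_o_pos": op, "eta_o_neg": on,
            "vmod": vmod, "a": ddm.a, "tau": ddm.tau,
        }
        theta = np.array([lookup[n] for n in names])
        return float(_nll_packed(theta, data, rl.model))
    traces = run_model(seq, behaviour, rl, vmod)
    include = rt_inclusion_mask(np.asarray(behaviour.rts, dtype=float))
    nll = 0.0
    for i, tr in enumerate(seq):
        if not include[i]:
            continue
        resp = behaviour.responses[i]
        upper = resp in ("left", "match")
        lik = response_likelihood(
            float(behaviour.rts[i]), 1 if upper else 0,
            float(traces["drift"].iloc[i]), ddm.a, ddm.tau, ddm.z,
        )
        nll -= math.log(lik)
    return nll


def bic(logL: float, n_params: int, n_trials: int) -> float:
    """Bayesian information criterion, k ln N - 2 logL."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return n_params * math.log(n_trials) - 2.0 * logL


def fit_run(
    seq: TrialSequence,
    behaviour: BehaviouralRecord,
    model: str = "simple",
    bounds: dict | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    maxiter: int = 60,
) -> FitResult:
    """Fit one RLDDM variant to one run by seeded global optimization."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    variant = seq.config.variant
    data = pack_run(seq, behaviour)
    n_used = int(data.include.sum())
    if n_used == 0:
        raise ValueError("no trials usable in the likelihood")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    min_rt = float(np.nanmin(np.where(data.include, data.rt, np.nan)))
    tau_hi = max(min_rt - 0.01, b["tau_lo"] + 0.01)
    names = _theta_names(model, variant)
    box = []
    for name in names:
        if name.startswith("eta"):
            box.append(b["eta"])
        elif name == "vmod":
            box.append(b["vmod"])
        elif name == "a":
            box.append(b["a"])
        else:
            box.append((b["tau_lo"], tau_hi))

    def objective(theta):
        val = _nll_packed(theta, data, model)
        return val if np.isfinite(val) else 1e12

    result = differential_evolution(
        objective,
        bounds=box,
        seed=seed,
        popsize=max(8, n_restarts),
        maxiter=maxiter,
        tol=1e-6,
        init="sobol",
        polish=True,
    )
    theta = np.clip(result.x, [lo for lo, _ in box], [hi for _, hi in box])
    logL = -float(_nll_packed(theta, data, model))
    _, _, _, _, params = _theta_to_params(theta, model, variant)
    k = len(names)
    return FitResult(
        model=model,
        variant=variant,
        params=params,
        logL=logL,
        n_params=k,
        n_trials_used=n_used,
        bic=bic(logL, k, n_used),
        converged=bool(result.success),
        n_restarts=n_restarts,
        seed=seed,
    )


def fit_all_models(
    seq: TrialSequence,
    behaviour: BehaviouralRecord,
    models: tuple[str, ...] = MODELS,
    seed: int = 0,
    **kwargs,
) -> dict[str, FitResult]:
    return {m: fit_run(seq, behaviour, model=m, seed=seed, **kwargs) for m in models}


def select_model(fits: dict[str, FitResult]) -> FitResult:
    """Lowest-BIC fit; ties broken toward the model with fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits.values(), key=lambda f: (f.bic, f.n_params))


def selection_counts(selected: list[FitResult]) -> pd.Series:
    """Count of runs per selected model (shaped like a model-count table)."""
    counts = pd.Series(0, index=list(MODELS), dtype=int)
    for f in selected:
        counts[f.model] += 1
    return counts


@dataclass
class RecoveryReport:
    """Parameter-recovery summary: per-replicate values and aggregates."""

    table: pd.DataFrame          # columns true_<p>, fit_<p> per replicate
    correlations: dict[str, float]
    bias: dict[str, float]
    rmse: dict[str, float]
    confusion: pd.DataFrame | None = None


def _concatenated_sequence(variant: str, n_runs: int, seed: int) -> TrialSequence:
    """``n_runs`` generated runs concatenated into one long learning session."""
    ss = np.random.SeedSequence(seed)
    cfg = default_config(variant)
    trials = []
    for child in ss.spawn(n_runs):
        sub = generate_run(cfg, int(child.generate_state(1)[0] % (2**31)))
        trials.extend(sub.trials)
    for i, tr in enumerate(trials):
        tr.index = i
    return TrialSequence(config=cfg, trials=trials, seed=seed)


def parameter_recovery(
    variant: str = "match_recognition",
    model: str = "simple",
    n_reps: int = 50,
    n_runs_per_fit: int = 10,
    seed: int = 0,
    population: dict[str, tuple[float, float]] | None = None,
    fit_kwargs: dict | None = None,
) -> RecoveryReport:
    """Simulate-and-refit study of parameter recoverability.

    Each replicate draws true parameters from the (truncated normal)
    population, simulates ``n_runs_per_fit`` concatenated runs (420
    trials for match recognition at the default 10), refits the
    generating model, and compares.  Reports per-parameter Pearson
    correlation, mean bias (fit - true) and RMSE.
    """
    from mslrl.simulate import DEFAULT_POPULATIONS, draw_parameters

    pop = population or DEFAULT_POPULATIONS[(variant, "child", "audio_visual")]
    rng = np.random.default_rng(seed)
    fit_kwargs = fit_kwargs or {}
    rows = []
    for rep in range(n_reps):
        true = draw_parameters(pop, rng)
        seq = _concatenated_sequence(
            variant, n_runs_per_fit, int(rng.integers(0, 2**31 - 1))
        )
        rl = RLParams(model=model, eta_c=true["eta"],
                      eta_c_pos=true["eta"], eta_c_neg=true["eta"],
                      eta_o=true["eta"], eta_o_pos=true["eta"],
                      eta_o_neg=true["eta"])
        rec = simulate_run(
            seq, rl, DDMParams(a=true["a"], tau=true["tau"]), true["vmod"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fit = fit_run(
            seq, rec, model=model, seed=int(rng.integers(0, 2**31 - 1)),
            **fit_kwargs,
        )
        row = {"rep": rep}
        mapping = {"eta": "eta_c" if model == "simple" else "eta_c_pos",
                   "vmod": "vmod", "a": "a", "tau": "tau"}
        for p, fitted_name in mapping.items():
            row[f"true_{p}"] = true[p]
            row[f"fit_{p}"] = fit.params[fitted_name]
        rows.append(row)
    table = pd.DataFrame(rows)
    corr, bias_, rmse_ = {}, {}, {}
    for p in ("eta", "vmod", "a", "tau"):
        t, f = table[f"true_{p}"], table[f"fit_{p}"]
        corr[p] = float(np.corrcoef(t, f)[0, 1]) if len(table) > 2 else np.nan
        bias_[p] = float((f - t).mean())
        rmse_[p] = float(np.sqrt(((f - t) ** 2).mean()))
    return RecoveryReport(table=table, correlations=corr, bias=bias_, rmse=rmse_)


def model_recovery(
    variant: str = "match_recognition",
    generating_model: str = "simple",
    n_reps: int = 50,
    n_runs_per_fit: int = 10,
    seed: int = 0,
    models: tuple[str, ...] = MODELS,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Confusion counts: which variant BIC selects on data of known origin."""
    from mslrl.simulate import DEFAULT_POPULATIONS, draw_parameters

    pop = DEFAULT_POPULATIONS[(variant, "child", "audio_visual")]
    rng = np.random.default_rng(seed)
    fit_kwargs = fit_kwargs or {}
    counts = pd.Series(0, index=list(models), dtype=int)
    for _ in range(n_reps):
        true = draw_parameters(pop, rng)
        seq = _concatenated_sequence(
            variant, n_runs_per_fit, int(rng.integers(0, 2**31 - 1))
        )
        rl = RLParams(model=generating_model, eta_c=true["eta"],
                      eta_c_pos=true["eta"], eta_c_neg=true["eta"],
                      eta_o=true["eta"], eta_o_pos=true["eta"],
                      eta_o_neg=true["eta"])
        rec = simulate_run(
            seq, rl, DDMParams(a=true["a"], tau=true["tau"]), true["vmod"],
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fits = fit_all_models(
            seq, rec, models=models, seed=int(rng.integers(0, 2**31 - 1)),
            **fit_kwargs,
        )
        counts[select_model(fits).model] += 1
    out = counts.to_frame(name="selected")
    out.index.name = "model"
    out["generating_model"] = generating_model
    return out
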