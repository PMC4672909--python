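"""Per-observer maximum-likelihood fitting of causal-inference models.

The response likelihood has no closed form, so each candidate parameter
set is scored by Monte Carlo: simulate the generative observer for every
stimulus condition, bin the simulated responses on a 1-degree grid over
[-45, +45] (a joint auditory x visual histogram for bisensory
conditions), add 0.5 pseudo-counts per bin so no observed response has
zero probability, and sum the log probability of each observed trial's
bin.  The pseudo-count is defined at a reference simulation count and
scales proportionally with the actual count, so the smoothed prediction
is the same uniform mixture at any simulation size.  Two variance-
reduction devices keep the objective smooth at modest simulation counts:
the sensory samples are scrambled-Sobol quasi-random draws (cached, so
the objective is deterministic and all models share the same draws), and
the probability-matching decision is marginalized analytically rather
than sampled.  Simulation counts are rounded up to a power of two, as
the Sobol stratification requires.

Optimization is derivative-free (the binned Monte-Carlo objective is
piecewise constant in tiny neighborhoods): a data-driven moment start
plus Latin-hypercube multistarts, each refined by Powell line search in
an unconstrained reparameterization (logit for ``p_common`` and other
box-bounded parameters, log-scaled logit for SDs).  ``fit_models``
additionally warm-starts richer models from the best nested fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc

from . import _kernels
from .core_model import (
    N_BINS,
    ObserverParams,
    _posterior_mean_and_logevidence,
    bin_index,
    build_priors,
    quantize_response,
)
from .model_zoo import ModelSpec

__all__ = [
    "FitOptions",
    "FitResult",
    "bic",
    "response_log_likelihood",
    "fit_model",
    "fit_models",
    "pseudo_r2",
    "r2_pooled",
    "smart_start",
    "build_condition_stats",
]

logger = logging.getLogger(__name__)

_JOINT_BINS = N_BINS * N_BINS

#: reference simulation count at which ``smoothing`` equals pseudo-counts
#: per bin; at other n_sim the pseudo-count scales proportionally so the
#: smoothed distribution is the same uniform mixture regardless of n_sim
REF_N_SIM = 10000


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian Information Criterion, -2 log L + k ln n (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * log_likelihood + k * math.log(n)


# --------------------------------------------------------------------------
# sufficient statistics: the likelihood depends on the data only through
# per-condition histograms of the (binned) responses
# --------------------------------------------------------------------------


@dataclass
class _ConditionStats:
    sA_bi: np.ndarray
    sV_bi: np.ndarray
    n_bi: np.ndarray
    idx_bi: np.ndarray  # global joint-bin indices (cond * 8100 + bin), one per unique bin
    cnt_bi: np.ndarray
    s_uA: np.ndarray
    n_uA: np.ndarray
    idx_uA: np.ndarray
    cnt_uA: np.ndarray
    s_uV: np.ndarray
    n_uV: np.ndarray
    idx_uV: np.ndarray
    cnt_uV: np.ndarray
    n_total: int


def _compress(global_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, cnt = np.unique(global_idx, return_counts=True)
    return uniq, cnt.astype(float)


def build_condition_stats(trials: pd.DataFrame) -> _ConditionStats:
    """Reduce a trial table to per-condition binned response counts."""
    sA = trials["s_A"].to_numpy(float)
    sV = trials["s_V"].to_numpy(float)
    rA = trials["r_A"].to_numpy(float)
    rV = trials["r_V"].to_numpy(float)
    has_A, has_V = ~np.isnan(sA), ~np.isnan(sV)
    if not np.array_equal(has_A, ~np.isnan(rA)) or not np.array_equal(has_V, ~np.isnan(rV)):
        raise ValueError("responses must be present exactly where stimuli are present")
    out_of_range = np.nansum(np.abs(np.concatenate([rA[has_A], rV[has_V]])) > 45.0)
    if out_of_range:
        logger.warning(
            "%d response(s) outside the [-45, 45] scoring range were assigned to edge bins",
            out_of_range,
        )

    bi = has_A & has_V
    keys_bi = sorted({(a, v) for a, v in zip(sA[bi], sV[bi])})
    sA_bi = np.array([k[0] for k in keys_bi])
    sV_bi = np.array([k[1] for k in keys_bi])
    gidx, nb = [], []
    for row, (a, v) in enumerate(keys_bi):
        m = bi & (sA == a) & (sV == v)
        nb.append(int(m.sum()))
        joint = bin_index(rA[m]) * N_BINS + bin_index(rV[m])
        gidx.append(row * _JOINT_BINS + joint)
    idx_bi, cnt_bi = _compress(np.concatenate(gidx) if gidx else np.array([], int))

    def _uni(mask, s_col, r_col):
        keys = sorted(set(s_col[mask]))
        s = np.array(keys)
        gi, nn = [], []
        for row, loc in enumerate(keys):
            m = mask & (s_col == loc)
            nn.append(int(m.sum()))
            gi.append(row * N_BINS + bin_index(r_col[m]))
        idx, cnt = _compress(np.concatenate(gi) if gi else np.array([], int))
        return s, np.array(nn, float), idx, cnt

    s_uA, n_uA, idx_uA, cnt_uA = _uni(has_A & ~has_V, sA, rA)
    s_uV, n_uV, idx_uV, cnt_uV = _uni(has_V & ~has_A, sV, rV)
    return _ConditionStats(
        sA_bi=sA_bi,
        sV_bi=sV_bi,
        n_bi=np.array(nb, float),
        idx_bi=idx_bi,
        cnt_bi=cnt_bi,
        s_uA=s_uA,
        n_uA=n_uA,
        idx_uA=idx_uA,
        cnt_uA=cnt_uA,
        s_uV=s_uV,
        n_uV=n_uV,
        idx_uV=idx_uV,
        cnt_uV=cnt_uV,
        n_total=int(len(trials)),
    )


# --------------------------------------------------------------------------
# batched generative simulation (all conditions at once)
# --------------------------------------------------------------------------


def _pow2_at_least(n: int) -> int:
    return 1 << max(0, (int(n) - 1).bit_length())


_DRAW_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _standard_draws(seed: int, n_eff: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached scrambled-Sobol standard-normal pairs (z_A, z_V).

    Quasi-random stratification sharply reduces the Monte-Carlo error of
    the binned histograms at a given simulation count; the scramble seed
    makes the sequence deterministic, giving common random numbers across
    optimizer evaluations and across models.
    """
    from scipy.special import ndtri

    key = (int(seed), int(n_eff))
    if key not in _DRAW_CACHE:
        eng = qmc.Sobol(d=2, scramble=True, seed=int(seed))
        u = np.clip(eng.random_base2(int(math.log2(n_eff))), 1e-12, 1.0 - 1e-12)
        _DRAW_CACHE[key] = (ndtri(u[:, 0]), ndtri(u[:, 1]))
        if len(_DRAW_CACHE) > 32:
            _DRAW_CACHE.pop(next(iter(_DRAW_CACHE)))
    return _DRAW_CACHE[key]


#: set False to force the pure-numpy reference path (used in tests)
USE_NUMBA = _kernels.HAVE_NUMBA


def _sim_counts(stats: _ConditionStats, op: ObserverParams, n_eff: int, seed: int):
    """Predicted bin weights for every condition from ``n_eff`` simulated samples.

    The probability-matching draw is marginalized analytically: each
    simulated sample contributes weight p(C=1|x) to its fused joint bin
    and 1 - p(C=1|x) to its segregated joint bin, which has the same
    expectation as sampling the decision but far lower variance.
    """
    if USE_NUMBA:
        return _sim_counts_numba(stats, op, n_eff, seed)
    return _sim_counts_numpy(stats, op, n_eff, seed)


def _sim_counts_numba(stats: _ConditionStats, op: ObserverParams, n_eff: int, seed: int):
    """Fused-kernel variant of :func:`_sim_counts_numpy` (same results)."""
    priors = build_priors(op)
    prior_V, prior_A, prior_C1 = priors
    z_A, z_V = _standard_draws(seed, n_eff)
    sbar = math.sqrt(1.0 / (1.0 / op.sigma_A**2 + 1.0 / op.sigma_V**2))
    projV = _kernels.project_prior(_kernels.pack_prior(prior_V), op.sigma_V)
    projA = _kernels.project_prior(_kernels.pack_prior(prior_A), op.sigma_A)
    proj1 = _kernels.project_prior(_kernels.pack_prior(prior_C1), sbar)
    counts = {}
    C = len(stats.sA_bi)
    if C:
        muA = stats.sA_bi * (1.0 + op.dx_A)
        muV = stats.sV_bi * (1.0 + op.dx_V)
        sdV = op.sigma_V + op.dsigma_V * np.abs(stats.sV_bi) / 6.5
        sim = np.zeros(C * _JOINT_BINS)
        _kernels.bisensory_bin_weights(
            muA,
            float(op.sigma_A),
            muV,
            sdV,
            z_A,
            z_V,
            float(op.p_common),
            float(op.sigma_A),
            float(op.sigma_V),
            *projV,
            *projA,
            *proj1,
            sim,
        )
        counts["bi"] = sim
    for tag, s, sigma, dx, dsig, proj, z in (
        ("uA", stats.s_uA, op.sigma_A, op.dx_A, 0.0, projA, z_A),
        ("uV", stats.s_uV, op.sigma_V, op.dx_V, op.dsigma_V, projV, z_V),
    ):
        Cu = len(s)
        if not Cu:
            continue
        mu = s * (1.0 + dx)
        sd = sigma + dsig * np.abs(s) / 6.5
        sim = np.zeros(Cu * N_BINS)
        _kernels.unisensory_bin_counts(mu, sd, z, *proj, sim)
        counts[tag] = sim
    return counts


def _sim_counts_numpy(stats: _ConditionStats, op: ObserverParams, n_eff: int, seed: int):
    """Vectorized reference implementation of the condition simulator."""
    from .core_model import _combine_cues

    priors = build_priors(op)
    prior_V, prior_A, prior_C1 = priors
    z_A, z_V = _standard_draws(seed, n_eff)
    counts = {}
    C = len(stats.sA_bi)
    if C:
        muA = stats.sA_bi * (1.0 + op.dx_A)
        muV = stats.sV_bi * (1.0 + op.dx_V)
        sdV = op.sigma_V + op.dsigma_V * np.abs(stats.sV_bi) / 6.5
        xA = muA[:, None] + op.sigma_A * z_A[None, :]
        xV = muV[:, None] + sdV[:, None] * z_V[None, :]
        seg_A, lev_A = _posterior_mean_and_logevidence(xA, op.sigma_A, prior_A)
        seg_V, lev_V = _posterior_mean_and_logevidence(xV, op.sigma_V, prior_V)
        xbar, sbar, lpair = _combine_cues(xA, xV, op.sigma_A, op.sigma_V)
        fus, lev_1 = _posterior_mean_and_logevidence(xbar, sbar, prior_C1)
        pc = op.p_common
        if pc >= 1.0:
            p1 = np.ones_like(xbar)
        elif pc <= 0.0:
            p1 = np.zeros_like(xbar)
        else:
            logit_p1 = (
                math.log(pc) - math.log1p(-pc) + lpair + lev_1 - lev_A - lev_V
            )
            p1 = 1.0 / (1.0 + np.exp(-np.clip(logit_p1, -700, 700)))
        off = np.arange(C)[:, None] * _JOINT_BINS
        j_seg = bin_index(quantize_response(seg_A)) * N_BINS + bin_index(quantize_response(seg_V)) + off
        fb = bin_index(quantize_response(fus))
        j_fus = fb * N_BINS + fb + off
        sim = np.bincount(j_seg.ravel(), weights=(1.0 - p1).ravel(), minlength=C * _JOINT_BINS)
        sim += np.bincount(j_fus.ravel(), weights=p1.ravel(), minlength=C * _JOINT_BINS)
        counts["bi"] = sim
    for tag, s, sigma, dx, dsig, prior, z in (
        ("uA", stats.s_uA, op.sigma_A, op.dx_A, 0.0, prior_A, z_A),
        ("uV", stats.s_uV, op.sigma_V, op.dx_V, op.dsigma_V, prior_V, z_V),
    ):
        Cu = len(s)
        if not Cu:
            continue
        mu = s * (1.0 + dx)
        sd = sigma + dsig * np.abs(s) / 6.5
        x = mu[:, None] + sd[:, None] * z[None, :]
        r, _ = _posterior_mean_and_logevidence(x, sigma, prior)
        gi = bin_index(quantize_response(r)) + np.arange(Cu)[:, None] * N_BINS
        counts[tag] = np.bincount(gi.ravel(), minlength=Cu * N_BINS).astype(float)
    return counts


def _ll_from_stats(
    stats: _ConditionStats,
    op: ObserverParams,
    n_sim: int,
    seed: int,
    smoothing: float = 0.5,
) -> float:
    n_eff = _pow2_at_least(n_sim)
    counts = _sim_counts(stats, op, n_eff, seed)
    alpha = smoothing * n_eff / REF_N_SIM
    ll = 0.0
    for tag, idx, cnt, n_cond, nbins in (
        ("bi", stats.idx_bi, stats.cnt_bi, stats.n_bi, _JOINT_BINS),
        ("uA", stats.idx_uA, stats.cnt_uA, stats.n_uA, N_BINS),
        ("uV", stats.idx_uV, stats.cnt_uV, stats.n_uV, N_BINS),
    ):
        if tag not in counts or idx.size == 0:
            continue
        sim = counts[tag]
        ll += float(cnt @ np.log(sim[idx] + alpha))
        ll -= float(n_cond.sum()) * math.log(n_eff + alpha * nbins)
    return ll


def response_log_likelihood(
    trials: pd.DataFrame,
    params,
    spec: Optional[ModelSpec] = None,
    n_sim: int = 10000,
    seed: int = 0,
    smoothing: float = 0.5,
) -> float:
    """Monte-Carlo log likelihood of a trial table under one parameter set.

    ``params`` may be an :class:`ObserverParams` or a mapping of free
    values for ``spec``.  Repeated calls with equal seeds are bit-identical
    (common random numbers), and the value depends on the trials only
    through per-condition response histograms, so trial order is
    irrelevant.
    """
    if isinstance(params, ObserverParams):
        op = params
    elif spec is not None:
        op = spec.to_observer_params(params)
    else:
        op = ObserverParams.from_dict(dict(params))
    return _ll_from_stats(build_condition_stats(trials), op, n_sim, seed, smoothing)


# --------------------------------------------------------------------------
# parameter transforms: optimize in an unconstrained space
# --------------------------------------------------------------------------


def _is_sd(name: str) -> bool:
    return name.startswith("sigma") or name == "dsigma_V"


def _to_z(name: str, value: float, lo: float, hi: float) -> float:
    if _is_sd(name) and lo > 0:
        f = (math.log(value) - math.log(lo)) / (math.log(hi) - math.log(lo))
    else:
        f = (value - lo) / (hi - lo)
    return float(logit(np.clip(f, 1e-9, 1 - 1e-9)))


def _from_z(name: str, z: float, lo: float, hi: float) -> float:
    f = float(expit(z))
    if _is_sd(name) and lo > 0:
        return math.exp(math.log(lo) + f * (math.log(hi) - math.log(lo)))
    return lo + f * (hi - lo)


def _vec_from_named(spec: ModelSpec, named: Mapping[str, float]) -> np.ndarray:
    return np.array(
        [_to_z(p, named[p], *spec.bounds[p]) for p in spec.free_params]
    )


def _named_from_vec(spec: ModelSpec, z: np.ndarray) -> dict[str, float]:
    return {
        p: _from_z(p, zi, *spec.bounds[p]) for p, zi in zip(spec.free_params, z)
    }


# --------------------------------------------------------------------------
# data-driven starting point
# --------------------------------------------------------------------------


def smart_start(trials: pd.DataFrame, spec: ModelSpec) -> dict[str, float]:
    """Moment-based initial guess from simple summaries of the trial table.

    Unisensory regression slopes seed the likelihood gain biases, residual
    SDs seed the likelihood SDs, and the fraction of near-coincident
    bisensory responses seeds the binding prior.  Prior parameters start
    at generic mid-range values; their basin is broad.
    """
    sA = trials["s_A"].to_numpy(float)
    sV = trials["s_V"].to_numpy(float)
    rA = trials["r_A"].to_numpy(float)
    rV = trials["r_V"].to_numpy(float)
    uni_A = ~np.isnan(sA) & np.isnan(sV)
    uni_V = ~np.isnan(sV) & np.isnan(sA)
    bi = ~np.isnan(sA) & ~np.isnan(sV)

    def _slope_sd(s, r):
        locs = np.unique(s)
        if locs.size < 2:
            return 1.0, 3.0, 0.0, 3.0
        means = np.array([r[s == l].mean() for l in locs])
        sds = np.array([r[s == l].std(ddof=1) for l in locs])
        slope = float(np.polyfit(locs, means, 1)[0])
        ecc = np.abs(locs) / 6.5
        if np.ptp(ecc) > 0:
            dsig, sd0 = np.polyfit(ecc, sds, 1)
        else:
            dsig, sd0 = 0.0, float(sds.mean())
        return slope, max(float(sd0), 0.3), max(float(dsig), 0.0), float(sds.mean())

    slope_A, _, _, sdA = _slope_sd(sA[uni_A], rA[uni_A])
    slope_V, sdV, dsigV, _ = _slope_sd(sV[uni_V], rV[uni_V])
    congruent = bi & (sA == sV)
    if congruent.sum() > 0:
        frac_close = float(np.mean(np.abs(rA[congruent] - rV[congruent]) <= 2.0))
    else:
        frac_close = 0.5

    guesses = {
        "p_common": frac_close,
        "sigma_V": sdV,
        "sigma_A": sdA,
        "dx_V": slope_V - 1.0,
        "dx_A": slope_A - 1.0,
        "dsigma_V": dsigV,
        "sigma_P": 20.0,
        "x_P": 0.0,
        "sigma_VP": 12.0,
        "x_VP": 0.0,
        "sigma_AP": 15.0,
        "x_AP": 8.0,
    }
    start = {}
    for p in spec.free_params:
        lo, hi = spec.bounds[p]
        width = hi - lo
        start[p] = float(np.clip(guesses[p], lo + 0.02 * width, hi - 0.02 * width))
    return start


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the multistart Monte-Carlo maximum-likelihood search."""

    n_starts: int = 20
    n_sim_search: int = 2000
    n_sim_final: int = 10000
    maxfev: Optional[int] = None  # per start; default 120 * k
    seed: int = 0
    smoothing: float = 0.5
    polish: bool = True
    polish_maxfev: int = 60
    compute_r2: bool = True


@dataclass
class FitResult:
    """Outcome of fitting one model to one observer's trials."""

    model: str
    params: dict[str, float]
    log_likelihood: float
    bic: float
    pseudo_r2: Optional[float]
    n_trials: int
    n_sim: int
    seed: int
    n_starts: int
    start_objectives: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "model": self.model,
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "pseudo_r2": self.pseudo_r2,
            "n_trials": self.n_trials,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }
        row.update(self.params)
        return row


#: parent -> child embeddings used to warm-start richer models from the
#: best fit of a nested (or structurally close) model; missing parameters
#: get neutral values (no bias, near-flat prior)
_NEUTRAL_FILL = {
    "dx_V": 0.0,
    "dx_A": 0.0,
    "dsigma_V": 0.0,
    "sigma_P": 180.0,
    "x_P": 0.0,
    "sigma_VP": 180.0,
    "x_VP": 0.0,
    "sigma_AP": 180.0,
    "x_AP": 0.0,
}

_WARM_START_PARENTS = {
    "M6_likelihood_var": ["M5_likelihood"],
    "M8_hybrid": ["M6_likelihood_var", "M4_original"],
    "M7_priors": ["M4_original"],
    "M9_priors_meta": ["M7_priors", "M4_original"],
}

_PRIOR_SDS = ("sigma_P", "sigma_VP", "sigma_AP")


def _embed_params(parent_params: Mapping[str, float], child: ModelSpec) -> dict[str, float]:
    """Express a fitted parent model inside a richer model's parameter space.

    Replacing the proper uniform prior (density 1/(2h)) with a wide
    Gaussian (peak density 1/(sigma_P sqrt(2 pi))) shifts the
    common-vs-independent evidence ratio by a constant, so the binding
    prior is translated on the logit scale to leave p(C=1|x) unchanged.
    """
    out = {}
    parent_flat = not any(k in parent_params for k in _PRIOR_SDS)
    for p in child.free_params:
        if p in parent_params:
            out[p] = float(parent_params[p])
        elif p == "sigma_VP" and "sigma_P" in parent_params:
            out[p] = float(parent_params["sigma_P"])
        elif p == "sigma_AP" and "sigma_P" in parent_params:
            out[p] = float(parent_params["sigma_P"])
        else:
            out[p] = _NEUTRAL_FILL[p]
        lo, hi = child.bounds[p]
        width = hi - lo
        out[p] = float(np.clip(out[p], lo + 0.02 * width, hi - 0.02 * width))
    if parent_flat and "sigma_P" in out and "p_common" in out:
        h = 45.0
        offset = math.log(2.0 * h) - math.log(out["sigma_P"] * math.sqrt(2.0 * math.pi))
        pc = min(max(out["p_common"], 1e-6), 1.0 - 1e-6)
        out["p_common"] = float(
            np.clip(expit(logit(pc) + offset), 0.02, 0.98)
        )
    return out


def fit_models(
    trials: pd.DataFrame,
    names: Sequence[str],
    options: Optional[FitOptions] = None,
) -> dict[str, FitResult]:
    """Fit several model variants to one observer, warm-starting up the
    nesting chain (each richer model starts from the best nested fit as
    well as its own data-driven start), which keeps the fitted log
    likelihoods consistent with model nesting."""
    from .model_zoo import build_model

    specs = sorted((build_model(n) for n in names), key=lambda s: s.k)
    results: dict[str, FitResult] = {}
    for spec in specs:
        extra = [
            _embed_params(results[p].params, spec)
            for p in _WARM_START_PARENTS.get(spec.name, [])
            if p in results
        ]
        results[spec.name] = fit_model(trials, spec, options, extra_starts=extra)
    return results


def fit_model(
    trials: pd.DataFrame,
    spec: ModelSpec,
    options: Optional[FitOptions] = None,
    extra_starts: Sequence[Mapping[str, float]] = (),
) -> FitResult:
    """Maximum-likelihood fit of one model variant to one observer.

    Runs Powell search from a moment-based start plus Latin-hypercube
    multistarts at ``n_sim_search`` simulations per condition, keeps the
    best, optionally polishes it, and reports the log likelihood (and BIC,
    and pooled pseudo-R-squared) re-evaluated at ``n_sim_final``.
    Deterministic given ``options.seed``.
    """
    opts = options or FitOptions()
    stats = build_condition_stats(trials)
    k = spec.k
    maxfev = opts.maxfev if opts.maxfev is not None else 120 * k

    def objective(z):
        if not np.all(np.isfinite(z)):
            return 1e12
        op = spec.to_observer_params(_named_from_vec(spec, z))
        val = -_ll_from_stats(stats, op, opts.n_sim_search, opts.seed, opts.smoothing)
        return val if math.isfinite(val) else 1e12

    starts = [_vec_from_named(spec, smart_start(trials, spec))]
    starts += [_vec_from_named(spec, dict(s)) for s in extra_starts]
    if opts.n_starts > 1:
        sampler = qmc.LatinHypercube(d=k, seed=opts.seed + 1)
        unit = sampler.random(opts.n_starts - 1)
        for row in unit:
            named = {}
            for p, u in zip(spec.free_params, row):
                lo, hi = spec.bounds[p]
                named[p] = _from_z(p, logit(0.08 + 0.84 * u), lo, hi)
            starts.append(_vec_from_named(spec, named))

    best_z, best_obj, traces = None, np.inf, []
    for z0 in starts:
        res = minimize(
            objective,
            z0,
            method="Powell",
            options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-4},
        )
        traces.append(float(res.fun))
        if res.fun < best_obj:
            best_obj, best_z = float(res.fun), res.x
    if best_z is None or not np.isfinite(best_obj):
        raise RuntimeError(f"all {len(starts)} optimizer starts failed for {spec.name}")
    if opts.polish and opts.n_sim_final != opts.n_sim_search:
        def polish_objective(z):
            if not np.all(np.isfinite(z)):
                return 1e12
            op = spec.to_observer_params(_named_from_vec(spec, z))
            val = -_ll_from_stats(stats, op, opts.n_sim_final, opts.seed, opts.smoothing)
            return val if math.isfinite(val) else 1e12

        res = minimize(
            polish_objective,
            best_z,
            method="Powell",
            options={"maxfev": opts.polish_maxfev, "xtol": 1e-3, "ftol": 1e-4},
        )
        if res.fun < polish_objective(best_z):
            best_z = res.x

    named = _named_from_vec(spec, best_z)
    op = spec.to_observer_params(named)
    ll = _ll_from_stats(stats, op, opts.n_sim_final, opts.seed, opts.smoothing)
    r2 = (
        _pseudo_r2_from_stats(stats, op, opts.n_sim_final, opts.seed, opts.smoothing)
        if opts.compute_r2
        else None
    )
    return FitResult(
        model=spec.name,
        params=named,
        log_likelihood=ll,
        bic=bic(ll, k, stats.n_total),
        pseudo_r2=r2,
        n_trials=stats.n_total,
        n_sim=_pow2_at_least(opts.n_sim_final),
        seed=opts.seed,
        n_starts=len(starts),
        start_objectives=traces,
    )


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------


def r2_pooled(pred: np.ndarray, emp: np.ndarray) -> float:
    """1 - SSE/SST between predicted and empirical bin probabilities, floored at 0.

    Equals 1.0 when the prediction reproduces the empirical frequencies
    exactly, and ~0 when it explains no more than the grand mean does.
    """
    pred = np.asarray(pred, float).ravel()
    emp = np.asarray(emp, float).ravel()
    sst = float(np.sum((emp - emp.mean()) ** 2))
    if sst <= 0:
        logger.warning("degenerate empirical distribution (zero variance); pseudo-R2 set to 0")
        return 0.0
    sse = float(np.sum((emp - pred) ** 2))
    return max(0.0, 1.0 - sse / sst)


def _pseudo_r2_from_stats(
    stats: _ConditionStats,
    op: ObserverParams,
    n_sim: int,
    seed: int,
    smoothing: float,
) -> float:
    n_eff = _pow2_at_least(n_sim)
    counts = _sim_counts(stats, op, n_eff, seed)
    alpha = smoothing * n_eff / REF_N_SIM
    pred_cells, emp_cells = [], []
    for tag, idx, cnt, n_cond, nbins in (
        ("bi", stats.idx_bi, stats.cnt_bi, stats.n_bi, _JOINT_BINS),
        ("uA", stats.idx_uA, stats.cnt_uA, stats.n_uA, N_BINS),
        ("uV", stats.idx_uV, stats.cnt_uV, stats.n_uV, N_BINS),
    ):
        if tag not in counts:
            continue
        C = len(n_cond)
        pred = (counts[tag] + alpha) / (n_eff + alpha * nbins)
        emp = np.zeros(C * nbins)
        emp[idx] = cnt
        emp = emp.reshape(C, nbins) / n_cond[:, None]
        pred_cells.append(pred.ravel())
        emp_cells.append(emp.ravel())
    return r2_pooled(np.concatenate(pred_cells), np.concatenate(emp_cells))


def pseudo_r2(
    trials: pd.DataFrame,
    params,
    spec: Optional[ModelSpec] = None,
    n_sim: int = 10000,
    seed: int = 0,
    smoothing: float = 0.5,
) -> float:
    """Pooled variance-explained between predicted bin probabilities and
    empirical bin frequencies, floored at 0 (1 = prediction matches the
    empirical histograms exactly)."""
    if isinstance(params, ObserverParams):
        op = params
    elif spec is not None:
        op = spec.to_observer_params(params)
    else:
        op = ObserverParams.from_dict(dict(params))
    return _pseudo_r2_from_stats(build_condition_stats(trials), op, n_sim, seed, smoothing)
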