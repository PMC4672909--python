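"""Probabilistic core of the causal-inference observer.

An observer localizes brief auditory and/or visual events in azimuth.
Internal measurements ``x_A``, ``x_V`` are noisy draws from sensory
likelihoods that may be *biased*: their mean is shifted by a gain that
grows linearly with stimulus eccentricity, and the visual likelihood SD
may widen with eccentricity.  The observer combines measurements with
spatial priors (a metamodal central Gaussian, a visual central Gaussian,
and/or a mirrored-pair peripheral auditory prior), infers whether the two
cues share a common cause (C=1) or not (C=2), and reports posterior-mean
location estimates, selecting the fused vs. segregated estimate by
probability matching on the common-cause posterior.

Conventions: degrees azimuth, negative = left of straight ahead, 0 =
fixation.  Speakers in the modeled experiment sit at -13, -6.5, 0, +6.5,
+13 degrees (6.5-degree steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "SPEAKER_LOCATIONS",
    "SPEAKER_STEP",
    "StimulusCondition",
    "SensorySample",
    "LikelihoodSpec",
    "PriorSpec",
    "product_prior",
    "CausalPosterior",
    "EstimatePair",
    "ObserverParams",
    "ResponseDistribution",
    "effective_likelihood",
    "sample_sensory",
    "conditional_estimate",
    "fused_estimate",
    "evidence_common",
    "evidence_independent",
    "posterior_common_cause",
    "decide_and_estimate",
    "predict_response_distribution",
    "build_priors",
    "quantize_response",
]

SPEAKER_LOCATIONS = (-13.0, -6.5, 0.0, 6.5, 13.0)
SPEAKER_STEP = 6.5  # degrees between adjacent speakers; unit of eccentricity scaling

#: response histogram: 1-degree bins spanning [-45, +45]
BIN_LO, BIN_HI, N_BINS = -45.0, 45.0, 90
#: half width of the projection screen; responses are clipped here
SCREEN_HALFWIDTH = 64.9

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusCondition:
    """Latent source locations for one trial; ``None`` marks an absent modality."""

    s_A: Optional[float] = None
    s_V: Optional[float] = None

    def __post_init__(self) -> None:
        if self.s_A is None and self.s_V is None:
            raise ValueError("at least one of s_A, s_V must be present")

    @property
    def bisensory(self) -> bool:
        return self.s_A is not None and self.s_V is not None


@dataclass(frozen=True)
class SensorySample:
    """Internal measurements for one trial (``None`` = modality absent)."""

    x_A: Optional[float] = None
    x_V: Optional[float] = None


@dataclass(frozen=True)
class LikelihoodSpec:
    """One modality's sensory representation.

    Parameters
    ----------
    sigma0
        Baseline likelihood SD at fixation, degrees (> 0).
    delta_mu
        Dimensionless gain bias: the likelihood is centered at
        ``s * (1 + delta_mu)``, so negative values compress measurements
        toward the center and positive values expand them outward.
    delta_sigma
        Degrees of SD added per 6.5-degree step of eccentricity;
        ``sigma(s) = sigma0 + delta_sigma * |s| / 6.5``.
    """

    sigma0: float
    delta_mu: float = 0.0
    delta_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        if self.delta_sigma < 0:
            raise ValueError("delta_sigma must be non-negative")


@dataclass(frozen=True)
class PriorSpec:
    """A spatial prior over source location.

    ``kind='flat'`` is a proper uniform on ``[-support_halfwidth, +support_halfwidth]``;
    ``kind='gaussian'`` a Normal(mean, sigma); ``kind='mirrored_pair'`` an
    equal-weight mixture of Normal(-mean, sigma) and Normal(+mean, sigma)
    (``mean`` >= 0 is the half-separation).  ``kind='mixture'`` is the
    general Gaussian-mixture form produced by taking products of priors.
    """

    kind: str = "flat"
    mean: float = 0.0
    sigma: float = 1.0
    support_halfwidth: float = 45.0
    weights: Optional[tuple] = None
    means: Optional[tuple] = None
    sigmas: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "gaussian", "mirrored_pair", "mixture"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind in ("gaussian", "mirrored_pair") and not self.sigma > 0:
            raise ValueError("prior sigma must be positive")
        if self.kind == "mirrored_pair" and self.mean < 0:
            raise ValueError("mirrored_pair half-separation must be >= 0")
        if self.kind == "flat" and not self.support_halfwidth > 0:
            raise ValueError("flat prior needs positive support halfwidth")

    # -- helpers ----------------------------------------------------------

    @property
    def is_flat(self) -> bool:
        return self.kind == "flat"

    def components(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Gaussian-mixture representation (weights, means, sds)."""
        if self.kind == "gaussian":
            return (np.array([1.0]), np.array([self.mean]), np.array([self.sigma]))
        if self.kind == "mirrored_pair":
            return (
                np.array([0.5, 0.5]),
                np.array([-self.mean, self.mean]),
                np.array([self.sigma, self.sigma]),
            )
        if self.kind == "mixture":
            return (
                np.asarray(self.weights, float),
                np.asarray(self.means, float),
                np.asarray(self.sigmas, float),
            )
        raise ValueError("flat prior has no mixture components")

    def density(self, s: np.ndarray) -> np.ndarray:
        """Prior density evaluated pointwise (used by quadrature cross-checks)."""
        s = np.asarray(s, float)
        if self.is_flat:
            h = self.support_halfwidth
            c = 1.0 / (2.0 * h)
            # half weight exactly at the jump: makes trapezoid quadrature
            # against this density exact for the constant part
            return np.where(np.abs(s) < h, c, np.where(np.abs(s) == h, c / 2.0, 0.0))
        w, m, t = self.components()
        out = np.zeros_like(s)
        for wk, mk, tk in zip(w, m, t):
            out += wk * np.exp(-0.5 * ((s - mk) / tk) ** 2) / (tk * math.sqrt(2 * math.pi))
        return out


def product_prior(priors: Sequence[PriorSpec]) -> PriorSpec:
    """Normalized product of priors (the effective prior when several apply).

    Flat factors are constant on their support and drop out of the
    normalized product when any non-flat factor is present.  The product of
    Gaussian mixtures is again a Gaussian mixture with pairwise-product
    components weighted by the cross-evidence of the component pair.
    """
    nonflat = [p for p in priors if not p.is_flat]
    if not nonflat:
        flats = [p for p in priors if p.is_flat]
        if not flats:
            raise ValueError("empty prior list")
        return flats[0]
    result = nonflat[0]
    for p in nonflat[1:]:
        w1, m1, t1 = result.components()
        w2, m2, t2 = p.components()
        W = (w1[:, None] * w2[None, :]).ravel()
        v1 = t1[:, None] ** 2
        v2 = t2[None, :] ** 2
        vsum = v1 + v2
        # weight of each cross component: evidence of the two means meeting
        cross = np.exp(-0.5 * (m1[:, None] - m2[None, :]) ** 2 / vsum) / np.sqrt(
            2 * math.pi * vsum
        )
        W = W * cross.ravel()
        m = ((m1[:, None] * v2 + m2[None, :] * v1) / vsum).ravel()
        t = np.sqrt((v1 * v2) / vsum).ravel()
        W = W / W.sum()
        result = PriorSpec(
            kind="mixture", weights=tuple(W), means=tuple(m), sigmas=tuple(t)
        )
    return result


@dataclass(frozen=True)
class CausalPosterior:
    """Posterior over the causal structure; p(C=2|x) = 1 - p_common."""

    p_common: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_common <= 1.0):
            raise ValueError("p_common must lie in [0, 1]")

    @property
    def p_independent(self) -> float:
        return 1.0 - self.p_common


@dataclass(frozen=True)
class EstimatePair:
    """Reported location estimates; present exactly where the stimulus was."""

    s_hat_A: Optional[float] = None
    s_hat_V: Optional[float] = None
    inferred_common: bool = False


# --------------------------------------------------------------------------
# observer parameters: one named bundle covering every model variant
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverParams:
    """Full parameter set of the causal-inference observer.

    A prior SD of ``None`` switches the corresponding prior mechanism off;
    with every mechanism off the observer falls back to the flat prior.
    """

    p_common: float
    sigma_V: float
    sigma_A: float
    dx_V: float = 0.0
    dx_A: float = 0.0
    dsigma_V: float = 0.0
    sigma_P: Optional[float] = None  # metamodal central Gaussian prior
    x_P: float = 0.0
    sigma_VP: Optional[float] = None  # visual central Gaussian prior
    x_VP: float = 0.0
    sigma_AP: Optional[float] = None  # auditory mirrored-pair prior
    x_AP: float = 0.0
    flat_halfwidth: float = 45.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_common <= 1.0):
            raise ValueError("p_common must lie in [0, 1]")
        for name in ("sigma_V", "sigma_A"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.dsigma_V < 0:
            raise ValueError("dsigma_V must be non-negative")

    @classmethod
    def from_dict(cls, values: dict) -> "ObserverParams":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**values)

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }

    @property
    def visual_likelihood(self) -> LikelihoodSpec:
        return LikelihoodSpec(self.sigma_V, self.dx_V, self.dsigma_V)

    @property
    def auditory_likelihood(self) -> LikelihoodSpec:
        # only the visual likelihood SD scales with eccentricity
        return LikelihoodSpec(self.sigma_A, self.dx_A, 0.0)


def build_priors(params: ObserverParams) -> tuple[PriorSpec, PriorSpec, PriorSpec]:
    """Assemble the (visual C=2, auditory C=2, common C=1) priors.

    Each modality's segregated posterior uses its own prior times the
    metamodal prior where present; the common-cause posterior uses the
    normalized product of all active priors.  Observers with no prior
    mechanism use a proper uniform over ``[-flat_halfwidth, +flat_halfwidth]``.
    """
    flat = PriorSpec(kind="flat", support_halfwidth=params.flat_halfwidth)
    meta = (
        PriorSpec(kind="gaussian", mean=params.x_P, sigma=params.sigma_P)
        if params.sigma_P is not None
        else None
    )
    vis = (
        PriorSpec(kind="gaussian", mean=params.x_VP, sigma=params.sigma_VP)
        if params.sigma_VP is not None
        else None
    )
    aud = (
        PriorSpec(kind="mirrored_pair", mean=params.x_AP, sigma=params.sigma_AP)
        if params.sigma_AP is not None
        else None
    )
    vis_factors = [p for p in (vis, meta) if p is not None]
    aud_factors = [p for p in (aud, meta) if p is not None]
    all_factors = [p for p in (vis, aud, meta) if p is not None]
    prior_V = product_prior(vis_factors) if vis_factors else flat
    prior_A = product_prior(aud_factors) if aud_factors else flat
    prior_C1 = product_prior(all_factors) if all_factors else flat
    return prior_V, prior_A, prior_C1


# --------------------------------------------------------------------------
# closed-form posterior means and evidences (vectorized over x)
# --------------------------------------------------------------------------


def _norm_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def _posterior_mean_and_logevidence(x, sigma, prior: PriorSpec):
    """Mean of p(s|x) and log of the single-cue evidence ∫ N(x|s,σ) p(s) ds.

    ``x`` may be an array of any shape; ``sigma`` broadcasts against it.
    For the flat prior both quantities follow the truncated-normal closed
    form; for Gaussian mixtures they follow conjugate-Gaussian algebra with
    a log-sum-exp over components.
    """
    x = np.asarray(x, float)
    sigma = np.asarray(sigma, float)
    if prior.is_flat:
        h = prior.support_halfwidth
        alpha = (-h - x) / sigma
        beta = (h - x) / sigma
        z = ndtr(beta) - ndtr(alpha)
        z = np.maximum(z, 1e-300)
        phi_a = np.exp(-0.5 * alpha**2) / math.sqrt(2 * math.pi)
        phi_b = np.exp(-0.5 * beta**2) / math.sqrt(2 * math.pi)
        mean = x + sigma * (phi_a - phi_b) / z
        log_ev = np.log(z) - math.log(2.0 * h)
        return mean, log_ev
    w, m, t = prior.components()
    if len(w) == 1:
        # single-Gaussian prior: plain conjugate update, no mixture bookkeeping
        var, tvar = sigma**2, float(t[0]) ** 2
        pred_sd = math.sqrt(float(var) + tvar) if np.ndim(var) == 0 else np.sqrt(var + tvar)
        log_ev = _norm_logpdf(x - float(m[0]), pred_sd)
        mean = (x * tvar + float(m[0]) * var) / (var + tvar)
        return mean, log_ev
    shape = (len(w),) + (1,) * x.ndim
    w = w.reshape(shape)
    m = m.reshape(shape)
    t = t.reshape(shape)
    var = sigma**2
    tvar = t**2
    pred_sd = np.sqrt(var + tvar)
    comp_logev = np.log(w) + _norm_logpdf(x - m, pred_sd)  # (K, ...)
    top = comp_logev.max(axis=0)
    rel = np.exp(comp_logev - top)
    denom = rel.sum(axis=0)
    log_ev = top + np.log(denom)
    comp_mean = (x * tvar + m * var) / (var + tvar)
    mean = (rel * comp_mean).sum(axis=0) / denom
    return mean, log_ev


# --------------------------------------------------------------------------
# spec operations (scalar-friendly; all accept arrays too)
# --------------------------------------------------------------------------


def effective_likelihood(s_true: float, spec: LikelihoodSpec) -> tuple[float, float]:
    """Mean and SD of the sensory likelihood for a stimulus at ``s_true``.

    The mean is ``s_true * (1 + delta_mu)`` (a gain bias, symmetric about
    the center) and the SD grows by ``delta_sigma`` per 6.5-degree step of
    eccentricity.
    """
    mu = s_true * (1.0 + spec.delta_mu)
    sigma = spec.sigma0 + spec.delta_sigma * abs(s_true) / SPEAKER_STEP
    if not sigma > 0:
        raise ValueError(f"effective sigma must be positive, got {sigma}")
    return float(mu), float(sigma)


def sample_sensory(
    cond: StimulusCondition,
    vis: LikelihoodSpec,
    aud: LikelihoodSpec,
    rng: np.random.Generator,
) -> SensorySample:
    """Draw one internal measurement per present modality."""
    x_A = x_V = None
    if cond.s_A is not None:
        mu, sd = effective_likelihood(cond.s_A, aud)
        x_A = float(rng.normal(mu, sd))
    if cond.s_V is not None:
        mu, sd = effective_likelihood(cond.s_V, vis)
        x_V = float(rng.normal(mu, sd))
    return SensorySample(x_A=x_A, x_V=x_V)


def conditional_estimate(x: float, sigma: float, prior: PriorSpec) -> float:
    """Posterior-mean location from a single cue: mean of p(s|x) ∝ N(x|s,σ) p(s)."""
    if not np.all(np.asarray(sigma) > 0):
        raise ValueError("sigma must be positive")
    mean, _ = _posterior_mean_and_logevidence(x, sigma, prior)
    return float(mean) if np.ndim(mean) == 0 else mean


def _combine_cues(x_A, x_V, sigma_A, sigma_V):
    """Product of the two cue likelihoods as one Gaussian in s.

    Returns the precision-weighted mean, its SD, and the log of the pair
    factor N(x_A - x_V | 0, sqrt(sigma_A^2 + sigma_V^2)).
    """
    prec = 1.0 / np.square(sigma_A) + 1.0 / np.square(sigma_V)
    xbar = (np.asarray(x_A) / np.square(sigma_A) + np.asarray(x_V) / np.square(sigma_V)) / prec
    sbar = np.sqrt(1.0 / prec)
    pair_sd = np.sqrt(np.square(sigma_A) + np.square(sigma_V))
    log_pair = _norm_logpdf(np.asarray(x_A) - np.asarray(x_V), pair_sd)
    return xbar, sbar, log_pair


def fused_estimate(
    x: SensorySample,
    vis_sigma: float,
    aud_sigma: float,
    priors: Sequence[PriorSpec],
) -> float:
    """Posterior-mean location under a common cause, pooling both cues.

    The single latent source is scored by both likelihoods and the product
    of all active priors.
    """
    if x.x_A is None or x.x_V is None:
        raise ValueError("fused estimate requires both modalities present")
    prior = product_prior(list(priors))
    xbar, sbar, _ = _combine_cues(x.x_A, x.x_V, aud_sigma, vis_sigma)
    mean, _ = _posterior_mean_and_logevidence(xbar, sbar, prior)
    return float(mean)


def evidence_common(
    x: SensorySample,
    vis_sigma: float,
    aud_sigma: float,
    priors: Sequence[PriorSpec],
) -> float:
    """p(x_A, x_V | C=1): both cues explained by one source, prior-integrated."""
    if x.x_A is None or x.x_V is None:
        raise ValueError("common-cause evidence requires both modalities")
    prior = product_prior(list(priors))
    xbar, sbar, log_pair = _combine_cues(x.x_A, x.x_V, aud_sigma, vis_sigma)
    _, log_ev = _posterior_mean_and_logevidence(xbar, sbar, prior)
    return float(np.exp(log_pair + log_ev))


def evidence_independent(
    x: SensorySample,
    vis_sigma: float,
    aud_sigma: float,
    prior_A: PriorSpec,
    prior_V: PriorSpec,
) -> float:
    """p(x_A, x_V | C=2): each cue explained by its own source and prior."""
    if x.x_A is None or x.x_V is None:
        raise ValueError("independent-cause evidence requires both modalities")
    _, log_ev_A = _posterior_mean_and_logevidence(x.x_A, aud_sigma, prior_A)
    _, log_ev_V = _posterior_mean_and_logevidence(x.x_V, vis_sigma, prior_V)
    return float(np.exp(log_ev_A + log_ev_V))


def posterior_common_cause(x: SensorySample, params: ObserverParams) -> CausalPosterior:
    """p(C=1 | x_A, x_V) combining both evidences with the binding prior P_c."""
    if x.x_A is None or x.x_V is None:
        raise ValueError("causal posterior requires both modalities")
    pc = params.p_common
    if pc == 1.0:
        return CausalPosterior(1.0)
    if pc == 0.0:
        return CausalPosterior(0.0)
    prior_V, prior_A, prior_C1 = build_priors(params)
    # at decision time the observer only knows x, not the stimulus, so the
    # baseline (eccentricity-independent) likelihood SDs apply
    e1 = evidence_common(x, params.sigma_V, params.sigma_A, [prior_C1])
    e2 = evidence_independent(x, params.sigma_V, params.sigma_A, prior_A, prior_V)
    denom = e1 * pc + e2 * (1.0 - pc)
    if denom <= 0.0:
        raise FloatingPointError("both causal-structure evidences vanished")
    return CausalPosterior(e1 * pc / denom)


def decide_and_estimate(
    x: SensorySample,
    params: ObserverParams,
    rng: np.random.Generator,
) -> EstimatePair:
    """Probability-matching readout.

    One uniform draw xi per trial is shared between modalities: if
    p(C=1|x) > xi both modalities report the fused estimate, otherwise each
    reports its own segregated estimate.  A unisensory sample bypasses
    causal inference entirely.
    """
    prior_V, prior_A, prior_C1 = build_priors(params)
    if x.x_A is None or x.x_V is None:
        if x.x_A is not None:
            return EstimatePair(
                s_hat_A=conditional_estimate(x.x_A, params.sigma_A, prior_A),
                inferred_common=False,
            )
        return EstimatePair(
            s_hat_V=conditional_estimate(x.x_V, params.sigma_V, prior_V),
            inferred_common=False,
        )
    post = posterior_common_cause(x, params)
    xi = float(rng.uniform())
    if post.p_common > xi:
        fused = fused_estimate(x, params.sigma_V, params.sigma_A, [prior_C1])
        return EstimatePair(s_hat_A=fused, s_hat_V=fused, inferred_common=True)
    return EstimatePair(
        s_hat_A=conditional_estimate(x.x_A, params.sigma_A, prior_A),
        s_hat_V=conditional_estimate(x.x_V, params.sigma_V, prior_V),
        inferred_common=False,
    )


# --------------------------------------------------------------------------
# vectorized generative kernel
# --------------------------------------------------------------------------


def simulate_condition_responses(
    cond: StimulusCondition,
    params: ObserverParams,
    n: int,
    rng: np.random.Generator,
    priors: Optional[tuple[PriorSpec, PriorSpec, PriorSpec]] = None,
):
    """Simulate ``n`` independent trials of one condition.

    Returns ``(r_A, r_V, fused)`` arrays; absent modalities give ``None``.
    Responses are raw posterior means (no rounding or clipping).  Draw
    order is fixed (x_A, then x_V, then xi) so equal seeds reproduce
    trials exactly.
    """
    if priors is None:
        priors = build_priors(params)
    prior_V, prior_A, prior_C1 = priors
    if not cond.bisensory:
        if cond.s_A is not None:
            mu, sd = effective_likelihood(cond.s_A, params.auditory_likelihood)
            x = mu + sd * rng.standard_normal(n)
            r, _ = _posterior_mean_and_logevidence(x, params.sigma_A, prior_A)
            return r, None, None
        mu, sd = effective_likelihood(cond.s_V, params.visual_likelihood)
        x = mu + sd * rng.standard_normal(n)
        r, _ = _posterior_mean_and_logevidence(x, params.sigma_V, prior_V)
        return None, r, None
    mu_A, sd_A = effective_likelihood(cond.s_A, params.auditory_likelihood)
    mu_V, sd_V = effective_likelihood(cond.s_V, params.visual_likelihood)
    x_A = mu_A + sd_A * rng.standard_normal(n)
    x_V = mu_V + sd_V * rng.standard_normal(n)
    xi = rng.random(n)
    r_A, r_V, fused = _bisensory_estimates(x_A, x_V, xi, params, priors)
    return r_A, r_V, fused


def _bisensory_estimates(x_A, x_V, xi, params: ObserverParams, priors):
    """Vectorized causal-inference readout for arrays of bisensory samples."""
    prior_V, prior_A, prior_C1 = priors
    seg_A, log_ev_A = _posterior_mean_and_logevidence(x_A, params.sigma_A, prior_A)
    seg_V, log_ev_V = _posterior_mean_and_logevidence(x_V, params.sigma_V, prior_V)
    xbar, sbar, log_pair = _combine_cues(x_A, x_V, params.sigma_A, params.sigma_V)
    fus, log_ev_1 = _posterior_mean_and_logevidence(xbar, sbar, prior_C1)
    pc = params.p_common
    if pc >= 1.0:
        p1 = np.ones_like(np.asarray(xbar))
    elif pc <= 0.0:
        p1 = np.zeros_like(np.asarray(xbar))
    else:
        logit = (
            math.log(pc)
            - math.log1p(-pc)
            + (log_pair + log_ev_1)
            - (log_ev_A + log_ev_V)
        )
        p1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
    fused_mask = p1 > xi
    r_A = np.where(fused_mask, fus, seg_A)
    r_V = np.where(fused_mask, fus, seg_V)
    return r_A, r_V, fused_mask


def quantize_response(r: np.ndarray) -> np.ndarray:
    """Round to the 0.1-degree response resolution and clip at the screen edge."""
    return np.clip(np.round(np.asarray(r, float) * 10.0) / 10.0, -SCREEN_HALFWIDTH, SCREEN_HALFWIDTH)


def bin_index(r: np.ndarray) -> np.ndarray:
    """Map responses to 1-degree histogram bins on [-45, 45]; out-of-range responses land in the edge bins."""
    idx = np.floor(np.asarray(r, float) - BIN_LO).astype(np.int64)
    return np.clip(idx, 0, N_BINS - 1)


@dataclass
class ResponseDistribution:
    """Binned predicted response distribution for one stimulus condition.

    ``probs`` is a normalized 1-D histogram (length 90) for unisensory
    conditions, or a joint 2-D histogram (90 x 90, indexed [auditory bin,
    visual bin]) for bisensory conditions.
    """

    probs: np.ndarray
    condition: StimulusCondition
    n_sim: int
    smoothing: float = 0.5
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(BIN_LO, BIN_HI + 1.0, 1.0)
    )

    @property
    def bisensory(self) -> bool:
        return self.probs.ndim == 2

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges[:-1] + 0.5

    def mean(self) -> tuple[Optional[float], Optional[float]]:
        """(auditory, visual) mean of the binned distribution."""
        c = self.bin_centers
        if self.bisensory:
            return (
                float(self.probs.sum(axis=1) @ c),
                float(self.probs.sum(axis=0) @ c),
            )
        if self.condition.s_A is not None:
            return float(self.probs @ c), None
        return None, float(self.probs @ c)

    def prob_of_response(self, r_A: Optional[float], r_V: Optional[float]) -> float:
        if self.bisensory:
            return float(self.probs[bin_index(r_A), bin_index(r_V)])
        r = r_A if self.condition.s_A is not None else r_V
        return float(self.probs[bin_index(r)])


def predict_response_distribution(
    cond: StimulusCondition,
    params: ObserverParams,
    n_sim: int = 10000,
    rng: Optional[np.random.Generator] = None,
    smoothing: float = 0.5,
) -> ResponseDistribution:
    """Monte-Carlo predicted response distribution for one condition.

    Simulates ``n_sim`` trials end-to-end (sensory sampling, causal
    inference, probability matching), quantizes responses to the
    0.1-degree device resolution, bins on the 1-degree grid, adds
    ``smoothing`` pseudo-counts per bin, and normalizes.  The smoothing
    guarantees that no observable response has zero predicted probability.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    r_A, r_V, _ = simulate_condition_responses(cond, params, n_sim, rng)
    if cond.bisensory:
        idx = bin_index(quantize_response(r_A)) * N_BINS + bin_index(quantize_response(r_V))
        counts = np.bincount(idx, minlength=N_BINS * N_BINS).astype(float)
        counts = counts.reshape(N_BINS, N_BINS)
    else:
        r = r_A if r_A is not None else r_V
        counts = np.bincount(bin_index(quantize_response(r)), minlength=N_BINS).astype(float)
    counts += smoothing
    probs = counts / counts.sum()
    return ResponseDistribution(probs=probs, condition=cond, n_sim=n_sim, smoothing=smoothing)
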