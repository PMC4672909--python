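"""Synthetic sessions and observers for the audiovisual localization task.

The modeled experiment presents brief flashes and noise bursts from five
azimuths (-13, -6.5, 0, +6.5, +13 degrees): 5 auditory-only conditions,
5 visual-only conditions, and the 5 x 5 bisensory grid — 35 conditions,
15 trials each, 525 trials per observer, in pseudorandom order.  Because
no per-trial dataset is deposited for the original cohort, this module
generates populations of simulated observers whose responses follow the
causal-inference process, for use in parameter-recovery and
model-selection studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core_model import (
    SCREEN_HALFWIDTH,
    SPEAKER_LOCATIONS,
    ObserverParams,
    StimulusCondition,
    build_priors,
    simulate_condition_responses,
)
from .model_zoo import ModelSpec, build_model

__all__ = [
    "SessionDesign",
    "PopulationSpec",
    "DEFAULT_M8_PARAMS",
    "DEFAULT_M4_PARAMS",
    "DEFAULT_PARAM_SDS",
    "make_session",
    "simulate_observer",
    "simulate_population",
]

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["subject", "trial_index", "s_A", "s_V", "r_A", "r_V"]

#: illustrative generating parameters for demo cohorts: central visual bias,
#: peripheral auditory bias, eccentricity-scaled visual noise, weak central
#: prior.  The central prior shrinks auditory responses by a factor
#: sigma_P^2 / (sigma_P^2 + sigma_A^2) ~ 0.9, so a *net* peripheral auditory
#: bias requires dx_A > sigma_A^2 / sigma_P^2 ~ 0.12; dx_A = 0.25 leaves a
#: ~1.5-degree outward group bias at +-13 degrees, comparable to the
#: magnitude of the central visual bias, as observed behaviorally.
DEFAULT_M8_PARAMS: Mapping[str, float] = {
    "p_common": 0.55,
    "sigma_V": 2.2,
    "sigma_A": 8.5,
    "dx_V": -0.12,
    "dx_A": 0.25,
    "dsigma_V": 0.6,
    "sigma_P": 25.0,
    "x_P": 0.0,
}

#: baseline-model analogue (no bias mechanisms)
DEFAULT_M4_PARAMS: Mapping[str, float] = {
    "p_common": 0.55,
    "sigma_V": 2.2,
    "sigma_A": 8.5,
    "sigma_P": 25.0,
}

#: between-observer SDs for population draws (truncated to model bounds)
DEFAULT_PARAM_SDS: Mapping[str, float] = {
    "p_common": 0.10,
    "sigma_V": 0.40,
    "sigma_A": 1.50,
    "dx_V": 0.04,
    "dx_A": 0.04,
    "dsigma_V": 0.20,
    "sigma_P": 3.0,
    "x_P": 1.0,
    "sigma_VP": 2.0,
    "x_VP": 1.0,
    "sigma_AP": 2.0,
    "x_AP": 2.0,
}


@dataclass(frozen=True)
class SessionDesign:
    """One observer's session: which conditions, how many repeats, what order."""

    locations: tuple[float, ...] = SPEAKER_LOCATIONS
    n_reps: int = 15
    include_unisensory_auditory: bool = True
    include_unisensory_visual: bool = True
    include_bisensory: bool = True
    shuffle_seed: int = 0

    def conditions(self) -> list[StimulusCondition]:
        if not self.locations:
            raise ValueError("location list must not be empty")
        conds: list[StimulusCondition] = []
        if self.include_unisensory_auditory:
            conds += [StimulusCondition(s_A=float(s)) for s in self.locations]
        if self.include_unisensory_visual:
            conds += [StimulusCondition(s_V=float(s)) for s in self.locations]
        if self.include_bisensory:
            conds += [
                StimulusCondition(s_A=float(a), s_V=float(v))
                for a in self.locations
                for v in self.locations
            ]
        if not conds:
            raise ValueError("design includes no condition type")
        return conds


@dataclass(frozen=True)
class PopulationSpec:
    """A cohort of simulated observers drawn around a generating parameter set."""

    n_subjects: int
    generating_model: str = "M8_hybrid"
    param_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_M8_PARAMS))
    param_sds: Mapping[str, float] = field(default_factory=dict)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def make_session(design: SessionDesign) -> pd.DataFrame:
    """Expand a design into an ordered trial list (seeded uniform shuffle).

    Returns a frame with columns ``trial_index``, ``s_A``, ``s_V`` (NaN for
    an absent modality); each condition appears exactly ``n_reps`` times.
    """
    conds = design.conditions()
    s_A = np.array([np.nan if c.s_A is None else c.s_A for c in conds])
    s_V = np.array([np.nan if c.s_V is None else c.s_V for c in conds])
    order = np.repeat(np.arange(len(conds)), design.n_reps)
    rng = np.random.default_rng(design.shuffle_seed)
    rng.shuffle(order)
    return pd.DataFrame(
        {
            "trial_index": np.arange(order.size),
            "s_A": s_A[order],
            "s_V": s_V[order],
        }
    )


def _as_observer_params(params, spec: Optional[ModelSpec]) -> ObserverParams:
    if isinstance(params, ObserverParams):
        return params
    if spec is not None:
        return spec.to_observer_params(params)
    return ObserverParams.from_dict(dict(params))


def simulate_observer(
    params,
    session: pd.DataFrame,
    rng: np.random.Generator,
    spec: Optional[ModelSpec] = None,
    subject: str = "S001",
) -> pd.DataFrame:
    """Simulate one observer's responses for every trial of a session.

    Each trial runs the full generative pass (sensory sampling, causal
    inference, probability matching); responses are rounded to the
    0.1-degree device resolution and clipped at the screen edge
    (clip events are logged).  Trials of the same condition are simulated
    in one vectorized batch, grouped deterministically, so a given
    ``rng`` state reproduces the trial table exactly.
    """
    op = _as_observer_params(params, spec)
    priors = build_priors(op)
    r_A = np.full(len(session), np.nan)
    r_V = np.full(len(session), np.nan)
    s_A_col = session["s_A"].to_numpy(float)
    s_V_col = session["s_V"].to_numpy(float)
    # deterministic condition order: sort by (s_A, s_V) with absent-modality
    # conditions last; absent values are encoded as None (NaN keys would
    # break set deduplication and make the order process-dependent)
    pairs = {
        (None if np.isnan(a) else float(a), None if np.isnan(v) else float(v))
        for a, v in zip(s_A_col, s_V_col)
    }
    keys = sorted(
        pairs,
        key=lambda t: (
            t[0] is None,
            t[0] if t[0] is not None else 0.0,
            t[1] is None,
            t[1] if t[1] is not None else 0.0,
        ),
    )
    n_clipped = 0
    for a, v in keys:
        mask = (
            (np.isnan(s_A_col) if a is None else (s_A_col == a))
            & (np.isnan(s_V_col) if v is None else (s_V_col == v))
        )
        n = int(mask.sum())
        cond = StimulusCondition(s_A=a, s_V=v)
        ra, rv, _ = simulate_condition_responses(cond, op, n, rng, priors=priors)
        for raw, col in ((ra, r_A), (rv, r_V)):
            if raw is None:
                continue
            n_clipped += int(np.sum(np.abs(raw) > SCREEN_HALFWIDTH))
            col[mask] = np.clip(
                np.round(np.asarray(raw) * 10.0) / 10.0,
                -SCREEN_HALFWIDTH,
                SCREEN_HALFWIDTH,
            )
    if n_clipped:
        logger.info("subject %s: clipped %d response(s) at the screen edge", subject, n_clipped)
    out = session.copy()
    out.insert(0, "subject", subject)
    out["r_A"] = r_A
    out["r_V"] = r_V
    return out[TRIAL_COLUMNS]


def draw_population_params(pop: PopulationSpec) -> pd.DataFrame:
    """Independent per-subject parameter draws, truncated-normal within bounds."""
    spec = build_model(pop.generating_model)
    missing = set(spec.free_params) - set(pop.param_means)
    if missing:
        raise ValueError(f"param_means missing {sorted(missing)} for {spec.name}")
    sds = dict(DEFAULT_PARAM_SDS)
    sds.update(pop.param_sds)
    rng = np.random.default_rng(np.random.SeedSequence([pop.master_seed, 1]))
    rows = {}
    for p in spec.free_params:
        lo, hi = spec.bounds[p]
        mu, sd = float(pop.param_means[p]), float(sds[p])
        if sd <= 0:
            rows[p] = np.full(pop.n_subjects, mu)
        else:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            rows[p] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=pop.n_subjects, random_state=rng)
    truth = pd.DataFrame(rows)
    truth.insert(0, "subject", [f"S{i + 1:03d}" for i in range(pop.n_subjects)])
    truth.insert(1, "model", spec.name)
    return truth


def simulate_population(
    pop: PopulationSpec,
    design: Optional[SessionDesign] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort: returns (trial table, ground-truth parameter table).

    Every observer gets an independent session shuffle and noise stream,
    all derived from ``master_seed``, so regenerating with the same spec
    reproduces both tables exactly.
    """
    if design is None:
        design = SessionDesign()
    spec = build_model(pop.generating_model)
    truth = draw_population_params(pop)
    ss = np.random.SeedSequence([pop.master_seed, 2])
    children = ss.spawn(pop.n_subjects)
    frames = []
    for i, row in truth.iterrows():
        values = {p: row[p] for p in spec.free_params}
        subj_design = SessionDesign(
            locations=design.locations,
            n_reps=design.n_reps,
            include_unisensory_auditory=design.include_unisensory_auditory,
            include_unisensory_visual=design.include_unisensory_visual,
            include_bisensory=design.include_bisensory,
            shuffle_seed=int(children[i].generate_state(1)[0] % (2**31)),
        )
        session = make_session(subj_design)
        rng = np.random.default_rng(children[i])
        frames.append(
            simulate_observer(values, session, rng, spec=spec, subject=row["subject"])
        )
    trials = pd.concat(frames, ignore_index=True)
    return trials, truth
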