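"""Synthetic-respondent simulation for the dual-probe task.

The generative model mirrors the task's rationale: each participant carries
a latent attentional bias theta in (0, 1) — the probability of attending
the negative locus at any probe moment — and a latent identification
ability delta in (0, 1] — the probability of seeing a briefly flashed
probe at all. On each presentation the attended locus is Bernoulli(theta)
(negative), an identification occurs with probability delta, and an
identified probe is always the one at the attended locus. The observed
bias index is then an unbiased but noisy estimate of theta, with binomial
measurement error theta*(1-theta)/(delta*n_trials) on average.

That error decomposition drives calibration: given an observed cohort SD
of the index, the latent SD is obtained by subtracting the mean binomial
error variance (``calibrate_from_descriptives``). Trait anxiety is drawn
jointly Gaussian with theta at a latent correlation; state-anxiety
elevation is linear in standardized theta. Defaults reproduce a cohort of
154 respondents with index mean 0.48 and SD 0.13, identification rate
0.9326 (SD 0.0471), trait anxiety 46.29 (SD 10.43), and a state-anxiety
change score near mean 4.83, SD 12.03.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from . import design, scoring
from .design import OUTER_KEYS
from .scoring import ParticipantSession, TrialRecord

__all__ = [
    "CalibrationError",
    "SimulationConfig",
    "SimulatedCohort",
    "calibrate_from_descriptives",
    "disattenuate_correlation",
    "simulate_latents",
    "simulate_outcome_arrays",
    "simulate_cohort",
    "recovery_experiment",
]


class CalibrationError(ValueError):
    """Observed descriptives incompatible with the latent-trait decomposition."""


class SimulationConfig(BaseModel):
    """Cohort-level generative parameters, calibrated to printed descriptives."""

    n_participants: int = Field(default=154, ge=2)
    n_videos: int = 24
    probes_per_video: int = 10
    mu_theta: float = Field(default=0.48, gt=0.0, lt=1.0)
    sigma_theta: float = Field(default=0.1256, ge=0.0)  # see calibrate_from_descriptives
    mu_delta: float = Field(default=0.9326, gt=0.0, le=1.0)
    sigma_delta: float = Field(default=0.0471, ge=0.0)
    rho_latent: float = Field(default=0.207, ge=-1.0, le=1.0)  # disattenuated r = .20
    trait_mean: float = 46.29
    trait_sd: float = 10.43
    trait_bounds: tuple[int, int] = (20, 80)
    baseline_mean: float = 35.0
    baseline_sd: float = 12.0
    elevation_mean: float = 4.83
    elevation_slope: float = 2.5  # per SD of latent bias
    elevation_sd: float = 11.3  # between-person residual
    block_sd: float = 8.0  # within-person block-to-block noise
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.trait_bounds
        if not 20 <= lo < hi <= 80:
            raise ValueError("trait bounds must satisfy 20 <= lo < hi <= 80")
        return self

    @property
    def n_trials(self) -> int:
        return self.n_videos * self.probes_per_video


@dataclass
class SimulatedCohort:
    sessions: list[ParticipantSession]
    truth: pd.DataFrame  # participant_id, theta, delta, trait, elevation
    config: SimulationConfig


def calibrate_from_descriptives(
    observed_sd: float = 0.13,
    observed_mean: float = 0.48,
    id_rate: float = 0.9326,
    n_trials: int = 240,
) -> float:
    """Latent bias SD implied by an observed index SD.

    The observed index variance decomposes into latent variance plus mean
    binomial error variance observed_mean*(1-observed_mean)/(id_rate*n_trials);
    the latent SD is the square root of the difference.
    """
    if not 0.0 < observed_mean < 1.0:
        raise CalibrationError("observed mean must lie in (0, 1)")
    if not 0.0 < id_rate <= 1.0 or n_trials < 1 or observed_sd < 0:
        raise CalibrationError("invalid calibration inputs")
    error_var = observed_mean * (1.0 - observed_mean) / (id_rate * n_trials)
    latent_var = observed_sd**2 - error_var
    if latent_var < 0:
        raise CalibrationError(
            f"observed variance {observed_sd**2:.5f} is below the binomial "
            f"error floor {error_var:.5f}"
        )
    return float(np.sqrt(latent_var))


def disattenuate_correlation(r_observed: float, reliability: float) -> float:
    """Latent correlation that would produce ``r_observed`` after attenuation.

    Attenuation by measurement error in the index alone:
    r_observed = rho_latent * sqrt(reliability).
    """
    if not 0.0 < reliability <= 1.0:
        raise CalibrationError("reliability must lie in (0, 1]")
    rho = r_observed / np.sqrt(reliability)
    if abs(rho) > 1.0:
        raise CalibrationError("disattenuated correlation exceeds 1 in magnitude")
    return float(rho)


def simulate_latents(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (theta, delta, trait) for every participant.

    (theta, trait) are jointly Gaussian with correlation rho_latent before
    truncation; draws with theta outside (0, 1) or trait outside the score
    bounds are rejected pairwise. Trait scores are discretized to the
    integer sum scale. delta is truncated normal on (0, 1].
    """
    n = config.n_participants
    cov = np.array([[1.0, config.rho_latent], [config.rho_latent, 1.0]])
    theta = np.empty(n)
    trait = np.empty(n)
    lo, hi = config.trait_bounds
    filled = 0
    while filled < n:
        z = rng.multivariate_normal(np.zeros(2), cov, size=n - filled)
        th = config.mu_theta + config.sigma_theta * z[:, 0]
        tr = np.rint(config.trait_mean + config.trait_sd * z[:, 1])
        ok = (th > 0) & (th < 1) & (tr >= lo) & (tr <= hi)
        k = int(ok.sum())
        theta[filled : filled + k] = th[ok]
        trait[filled : filled + k] = tr[ok]
        filled += k
    if config.sigma_delta == 0:
        delta = np.full(n, config.mu_delta)
    else:
        a = (0.0 - config.mu_delta) / config.sigma_delta
        b = (1.0 - config.mu_delta) / config.sigma_delta
        delta = stats.truncnorm.rvs(
            a, b, loc=config.mu_delta, scale=config.sigma_delta, size=n, random_state=rng
        )
    return theta, delta, trait


def simulate_outcome_arrays(
    config: SimulationConfig, rng: np.random.Generator, theta: np.ndarray, delta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized trial outcomes: (neg, ident) 0/1 arrays, persons x trials.

    ``ident[i, j]`` marks an identification; ``neg[i, j]`` marks an
    identification at the negative locus (the attended one).
    """
    shape = (len(theta), config.n_trials)
    attended_neg = rng.random(shape) < theta[:, None]
    ident = (rng.random(shape) < delta[:, None]).astype(np.int8)
    neg = (attended_neg & (ident == 1)).astype(np.int8)
    return neg, ident


def _stai_t_items(trait: int, rng: np.random.Generator) -> list[int]:
    """Raw 20-item responses whose keyed sum equals ``trait`` exactly."""
    scored = np.ones(20, dtype=int)
    remaining = int(trait) - 20
    while remaining > 0:
        room = np.flatnonzero(scored < 4)
        j = rng.choice(room)
        add = min(int(rng.integers(1, 4)), 4 - scored[j], remaining)
        scored[j] += add
        remaining -= add
    return [
        int(5 - v) if j in scoring.STAI_T_REVERSE_ITEMS else int(v)
        for j, v in enumerate(scored)
    ]


def _stai_s6_items(target: float, rng: np.random.Generator) -> list[float]:
    """Six raw items whose keyed mean equals ``target`` up to boundary clipping."""
    jitter = rng.normal(0.0, 5.0, size=6)
    jitter -= jitter.mean()
    keyed = np.clip(target + jitter, 0.0, 100.0)
    return [
        float(100.0 - v) if j in scoring.STAI_S6_ABSENT_ITEMS else float(v)
        for j, v in enumerate(keyed)
    ]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full cohort of trial logs, questionnaires, and ground truth."""
    root = np.random.SeedSequence(config.seed)
    rng_latent, rng_trials, rng_quest, rng_plan = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    theta, delta, trait = simulate_latents(config, rng_latent)
    neg, ident = simulate_outcome_arrays(config, rng_trials, theta, delta)

    z_theta = (
        (theta - config.mu_theta) / config.sigma_theta
        if config.sigma_theta > 0
        else np.zeros_like(theta)
    )
    elevation = (
        config.elevation_mean
        + config.elevation_slope * z_theta
        + rng_quest.normal(0.0, config.elevation_sd, size=len(theta))
    )

    specs = design.build_stimulus_set(seed=rng_plan)
    sessions = []
    for i in range(config.n_participants):
        pid = f"sim{i + 1:04d}"
        ordered = design.generate_session_order(specs, rng_plan)
        trials = []
        for v, spec in enumerate(ordered):
            neg_left = spec.initial_left_valence == "negative"
            for p in range(config.probes_per_video):
                j = v * config.probes_per_video + p
                left_id, right_id = rng_trials.choice(OUTER_KEYS, size=2, replace=False)
                locus = "left" if neg_left else "right"
                response = None
                if ident[i, j]:
                    neg_id = left_id if neg_left else right_id
                    ben_id = right_id if neg_left else left_id
                    response = int(neg_id if neg[i, j] else ben_id)
                trials.append(
                    TrialRecord(
                        participant_id=pid,
                        video_id=spec.video_id,
                        presentation_index=j + 1,
                        negative_locus=locus,
                        left_identity=int(left_id),
                        right_identity=int(right_id),
                        response_identity=response,
                    )
                )
                neg_left = not neg_left  # heads swap between probe arrangements

        baseline = float(np.clip(rng_quest.normal(config.baseline_mean, config.baseline_sd), 0, 100))
        posts = [
            _stai_s6_items(
                float(np.clip(baseline + elevation[i] + rng_quest.normal(0, config.block_sd), 0, 100)),
                rng_quest,
            )
            for _ in range(6)
        ]
        sessions.append(
            ParticipantSession(
                participant_id=pid,
                trials=trials,
                stai_t_items=_stai_t_items(int(trait[i]), rng_quest),
                stai_s6_baseline=_stai_s6_items(baseline, rng_quest),
                stai_s6_post_blocks=posts,
            )
        )

    truth = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in sessions],
            "theta": theta,
            "delta": delta,
            "trait": trait.astype(int),
            "elevation": elevation,
        }
    )
    return SimulatedCohort(sessions=sessions, truth=truth, config=config)


def recovery_experiment(
    config: SimulationConfig, n_replicates: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Parameter-recovery sweep: how well the index recovers the latent bias.

    Per replicate: simulate a cohort, score it, and report the correlation
    between the index and the true latent bias over retained participants,
    the mean bias of the index as an estimator, and KR-20.
    """
    from . import psychometrics

    rows = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for r in range(n_replicates):
        cfg = config.model_copy(update={"seed": int(child_seeds[r])})
        cohort = simulate_cohort(cfg)
        results = {
            s.participant_id: scoring.score_session(s, n_trials=cfg.n_trials)
            for s in cohort.sessions
        }
        truth = cohort.truth.set_index("participant_id")
        retained_ids = [pid for pid, res in results.items() if res.retained]
        idx = np.array([results[p].ab_index for p in retained_ids])
        th = truth.loc[retained_ids, "theta"].to_numpy()
        retained_sessions = [s for s in cohort.sessions if results[s.participant_id].retained]
        matrix = psychometrics.build_item_matrix(retained_sessions, cfg.n_trials)
        if len(idx) >= 3 and np.std(th) > 0:
            corr = float(np.corrcoef(idx, th)[0, 1])
        else:
            corr = float("nan")  # degenerate: no latent variance to recover
        rows.append(
            {
                "replicate": r,
                "seed": int(child_seeds[r]),
                "n_retained": len(retained_ids),
                "corr_index_theta": corr,
                "mean_bias": float(np.mean(idx - th)),
                "kr20": psychometrics.kr20(matrix),
            }
        )
    return pd.DataFrame(rows)
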