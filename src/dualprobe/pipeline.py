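"""End-to-end analysis pipeline: score -> exclude -> reliability ->
correlation -> mediation, emitting one structured report.

The report mirrors the order of a validation analysis of the task:
identification-rate exclusions and descriptives first, then internal
consistency of the bias index, then the index's association with trait
anxiety, then the mediation of trait anxiety's effect on state-anxiety
elevation through the index. Every numeric field traces to exactly one
scoring or psychometrics operation, and (inputs, seed) fully determine
the output.
"""

from __future__ import annotations

import numpy as np

from . import psychometrics, scoring
from .scoring import DataError, ParticipantSession

__all__ = ["run_pipeline"]

MIN_COHORT = 10


def run_pipeline(
    sessions: list[ParticipantSession],
    threshold: float = scoring.DEFAULT_THRESHOLD,
    n_permutations: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    n_trials: int = scoring.TRIALS_PER_SESSION,
) -> dict:
    """Run the full validation analysis on a cohort of sessions."""
    if len(sessions) < MIN_COHORT:
        raise DataError(
            f"pipeline stage 'score': cohort of {len(sessions)} is below the "
            f"minimum of {MIN_COHORT}"
        )

    results = [scoring.score_session(s, threshold, n_trials) for s in sessions]
    retained_res, excluded_res = scoring.apply_exclusions(results)
    retained_ids = {r.participant_id for r in retained_res}
    retained = [s for s in sessions if s.participant_id in retained_ids]
    if len(retained) < MIN_COHORT:
        raise DataError(
            f"pipeline stage 'exclude': only {len(retained)} retained participants"
        )

    indices = np.array([r.ab_index for r in retained_res], dtype=float)
    rates = np.array([r.identification_rate for r in retained_res], dtype=float)

    rel = psychometrics.reliability_report(retained, n_permutations, seed, n_trials)

    report: dict = {
        "n_total": len(sessions),
        "n_excluded": len(excluded_res),
        "n_retained": len(retained_res),
        "threshold": threshold,
        "seed": seed,
        "descriptives": {
            "index_mean": float(indices.mean()),
            "index_sd": float(indices.std(ddof=1)),
            "index_min": float(indices.min()),
            "index_max": float(indices.max()),
            "identification_rate_mean": float(rates.mean()),
            "identification_rate_sd": float(rates.std(ddof=1)),
        },
        "reliability": {
            "kr20": rel.kr20,
            "oddeven_sb": rel.oddeven_sb,
            "perm_mean": rel.perm_mean,
            "perm_ci": list(rel.perm_ci),
            "n_permutations": rel.n_permutations,
        },
    }

    have_quest = all(
        s.stai_t_items is not None
        and s.stai_s6_baseline is not None
        and s.stai_s6_post_blocks is not None
        for s in retained
    )
    if have_quest:
        trait = np.array([scoring.score_stai_t(s.stai_t_items) for s in retained], float)
        changes = []
        for s in retained:
            base = scoring.score_stai_s6(s.stai_s6_baseline)
            posts = [scoring.score_stai_s6(p) for p in s.stai_s6_post_blocks]
            changes.append(scoring.state_change(base, posts).change)
        change = np.array(changes, float)

        corr = psychometrics.pearson_with_test(indices, trait)
        med = psychometrics.mediate(trait, indices, change, n_boot=n_boot, seed=seed)
        report["trait_correlation"] = {
            "r": corr.r,
            "df": corr.df,
            "p": corr.p,
            "d": corr.d,
        }
        report["state_change"] = {
            "mean": float(change.mean()),
            "sd": float(change.std(ddof=1)),
        }
        report["mediation"] = {
            "a": med.a.coef,
            "b": med.b.coef,
            "c": med.c.coef,
            "c_prime": med.c_prime.coef,
            "indirect": med.indirect,
            "ci": list(med.ci),
            "n_boot": med.n_boot,
            "p_a": med.a.p,
            "p_b": med.b.p,
            "p_c": med.c.p,
            "p_c_prime": med.c_prime.p,
        }
    return report
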