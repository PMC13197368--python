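"""Reliability and inferential statistics for the bias index.

Internal consistency of the trial-level index is assessed three ways:

* KR-20 on the persons x presentations binary matrix (1 = negative-locus
  identification, 0 = benign-locus identification, missing = unidentified),
  with missing entries mean-imputed to the item proportion p_j;
* the classical odd/even split-half with Spearman-Brown correction;
* a permutation split-half: each participant's presentation slots are
  randomly partitioned into equal halves, the index is computed per half,
  the halves are correlated across participants and Spearman-Brown
  corrected, and the procedure is repeated (default 10,000 permutations)
  to yield a mean estimate with a percentile interval.

Also provided: Cronbach's alpha (population-variance convention, so it
coincides with KR-20 on dichotomous data), Pearson correlation with the
t-test and the Cohen's-d equivalent d = 2r / sqrt(1 - r^2), and a simple
mediation model (predictor -> mediator -> outcome) with standardized OLS
paths and a bias-corrected bootstrap CI for the indirect effect a*b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .scoring import BiasResult, ParticipantSession, PresentationOutcome, classify_presentation

__all__ = [
    "EstimationError",
    "BinaryItemMatrix",
    "ReliabilityReport",
    "CorrelationResult",
    "MediationPath",
    "MediationResult",
    "outcome_arrays",
    "build_item_matrix",
    "kr20",
    "cronbach_alpha",
    "spearman_brown",
    "split_half_oddeven",
    "split_half_permutation",
    "reliability_report",
    "pearson_with_test",
    "r_to_d",
    "mediate",
]


class EstimationError(ValueError):
    """A coefficient is undefined for the given data (e.g. zero variance)."""


@dataclass(frozen=True)
class BinaryItemMatrix:
    """Persons x items grid with entries in {1, 0, NaN}."""

    data: np.ndarray  # float array, NaN = missing
    participant_ids: tuple[str, ...]

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def row_means(self) -> np.ndarray:
        """Per-person mean over non-missing entries (equals the bias index)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.data, axis=1)


@dataclass(frozen=True)
class ReliabilityReport:
    kr20: float
    oddeven_sb: float
    perm_mean: float
    perm_ci: tuple[float, float]
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float
    d: float  # Cohen's-d equivalent of r
    n: int


@dataclass(frozen=True)
class MediationPath:
    coef: float  # standardized regression coefficient
    se: float
    p: float


@dataclass(frozen=True)
class MediationResult:
    a: MediationPath  # predictor -> mediator
    b: MediationPath  # mediator -> outcome (predictor partialled)
    c: MediationPath  # total effect
    c_prime: MediationPath  # direct effect
    indirect: float  # a * b
    ci: tuple[float, float]  # bias-corrected bootstrap 95% CI
    n_boot: int
    seed: int
    n: int


# ---------------------------------------------------------------------------
# item matrix


def outcome_arrays(
    sessions: list[ParticipantSession], n_trials: int = 240
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-session 0/1 arrays over presentation slots.

    Returns ``(neg, ident, ids)`` where ``neg[i, j]`` is 1 if participant
    i's presentation j was a negative-locus identification and ``ident``
    marks any identification. Rows follow chronological presentation order.
    """
    neg = np.zeros((len(sessions), n_trials), dtype=np.int8)
    ident = np.zeros((len(sessions), n_trials), dtype=np.int8)
    ids = []
    for i, s in enumerate(sessions):
        trials = s.sorted_trials()
        if len(trials) != n_trials:
            raise EstimationError(
                f"{s.participant_id}: expected {n_trials} trials, got {len(trials)}"
            )
        for j, t in enumerate(trials):
            out = classify_presentation(t)
            if out is PresentationOutcome.NEG_CORRECT:
                neg[i, j] = 1
                ident[i, j] = 1
            elif out is PresentationOutcome.BEN_CORRECT:
                ident[i, j] = 1
        ids.append(s.participant_id)
    return neg, ident, ids


def build_item_matrix(
    sessions: list[ParticipantSession], n_trials: int = 240
) -> BinaryItemMatrix:
    """Binary item matrix over the same trials that define the bias index."""
    neg, ident, ids = outcome_arrays(sessions, n_trials)
    data = neg.astype(float)
    data[ident == 0] = np.nan
    return BinaryItemMatrix(data=data, participant_ids=tuple(ids))


# ---------------------------------------------------------------------------
# internal consistency


def kr20(matrix: BinaryItemMatrix | np.ndarray) -> float:
    """Kuder-Richardson 20 with mean imputation of missing entries.

    Item proportions p_j are computed over observed entries; missing entries
    are then imputed to p_j for the total-score variance. Variances use the
    population convention (divide by n), under which KR-20 equals Cronbach's
    alpha exactly on complete dichotomous data.
    """
    data = matrix.data if isinstance(matrix, BinaryItemMatrix) else np.asarray(matrix, float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise EstimationError("KR-20 requires at least 2 persons and 2 items")
    observed = ~np.isnan(data)
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        bad = int((n_obs == 0).sum())
        warnings.warn(f"dropping {bad} items with no observed responses")
        keep = n_obs > 0
        data, observed = data[:, keep], observed[:, keep]
        k = data.shape[1]
        if k < 2:
            raise EstimationError("fewer than 2 items with observed responses")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(data, axis=0)
    q = 1.0 - p
    imputed = np.where(observed, data, p[None, :])
    total = imputed.sum(axis=1)
    var_total = total.var()  # population convention
    if var_total <= 0:
        raise EstimationError("zero total-score variance; KR-20 undefined")
    return float((k / (k - 1)) * (1.0 - (p * q).sum() / var_total))


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for a complete persons x items matrix (population variances)."""
    data = np.asarray(items, dtype=float)
    if np.isnan(data).any():
        raise EstimationError("alpha requires a complete matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise EstimationError("alpha requires at least 2 persons and 2 items")
    item_vars = data.var(axis=0)
    total_var = data.sum(axis=1).var()
    if total_var <= 0:
        raise EstimationError("zero total-score variance; alpha undefined")
    return float((k / (k - 1)) * (1.0 - item_vars.sum() / total_var))


def spearman_brown(r_half: float) -> float:
    """Step up a half-length correlation to full length: 2r / (1 + r)."""
    if r_half <= -1.0:
        raise EstimationError("Spearman-Brown undefined at r = -1")
    return 2.0 * r_half / (1.0 + r_half)


def _half_indices(
    neg: np.ndarray, ident: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Bias indices on the masked and complementary halves (NaN if a half is empty)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(mask, neg, 0).sum(axis=1) / np.where(mask, ident, 0).sum(axis=1)
        b = np.where(~mask, neg, 0).sum(axis=1) / np.where(~mask, ident, 0).sum(axis=1)
    return a, b


def _corr_valid(a: np.ndarray, b: np.ndarray) -> float:
    valid = ~(np.isnan(a) | np.isnan(b))
    dropped = int((~valid).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} participants with an empty half")
    a, b = a[valid], b[valid]
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        raise EstimationError("split-half correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def split_half_oddeven(sessions: list[ParticipantSession], n_trials: int = 240) -> float:
    """Spearman-Brown-corrected odd/even split-half reliability of the index.

    Per participant the index is computed separately over odd- and
    even-numbered presentations (identified trials only within each half);
    the two halves are correlated across participants and stepped up.
    """
    neg, ident, _ = outcome_arrays(sessions, n_trials)
    odd = (np.arange(n_trials) % 2) == 0  # 1-based odd presentation numbers
    a, b = _half_indices(neg, ident, odd[None, :].repeat(len(sessions), axis=0))
    return spearman_brown(_corr_valid(a, b))


def split_half_permutation(
    sessions: list[ParticipantSession],
    n_permutations: int = 10_000,
    seed: int = 0,
    n_trials: int = 240,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Permutation split-half reliability of the bias index.

    For each permutation, every participant's presentation slots are
    independently partitioned into two random halves of ``n_trials // 2``;
    per-half indices are correlated across participants and Spearman-Brown
    corrected. Returns the mean, the (2.5th, 97.5th) percentile interval,
    and the full distribution of corrected coefficients.
    """
    neg, ident, _ = outcome_arrays(sessions, n_trials)
    rng = np.random.default_rng(seed)
    half = n_trials // 2
    estimates = np.empty(n_permutations)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for p in range(n_permutations):
            # random equal split per participant: rank a uniform draw per slot
            order = np.argsort(rng.random(neg.shape), axis=1)
            mask = order < half
            a, b = _half_indices(neg, ident, mask)
            estimates[p] = spearman_brown(_corr_valid(a, b))
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(estimates.mean()), (float(lo), float(hi)), estimates


def reliability_report(
    sessions: list[ParticipantSession],
    n_permutations: int = 10_000,
    seed: int = 0,
    n_trials: int = 240,
) -> ReliabilityReport:
    """All three internal-consistency estimates on one retained cohort."""
    matrix = build_item_matrix(sessions, n_trials)
    perm_mean, perm_ci, _ = split_half_permutation(sessions, n_permutations, seed, n_trials)
    return ReliabilityReport(
        kr20=kr20(matrix),
        oddeven_sb=split_half_oddeven(sessions, n_trials),
        perm_mean=perm_mean,
        perm_ci=perm_ci,
        n_permutations=n_permutations,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# correlation and mediation


def r_to_d(r: float) -> float:
    """Cohen's-d equivalent of a Pearson correlation: d = 2r / sqrt(1 - r^2)."""
    if not -1.0 < r < 1.0:
        raise EstimationError("conversion requires |r| < 1")
    return 2.0 * r / float(np.sqrt(1.0 - r * r))


def pearson_with_test(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with the two-sided t-test and the d equivalent."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EstimationError("x and y must be paired 1-d arrays")
    n = len(x)
    if n < 3:
        raise EstimationError("correlation requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise EstimationError("correlation undefined with zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, df=n - 2, p=float(res.pvalue), d=r_to_d(r), n=n)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise EstimationError("zero variance; standardization undefined")
    return (v - v.mean()) / sd


def _ols_path(y: np.ndarray, X: np.ndarray, col: int) -> MediationPath:
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return MediationPath(
        coef=float(fit.params[col + 1]),
        se=float(fit.bse[col + 1]),
        p=float(fit.pvalues[col + 1]),
    )


def _boot_indirect(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized indirect effect a*b per bootstrap resample (vectorized).

    With all three variables standardized within the resample, the paths
    reduce to correlations: a = r_xm, b = (r_my - r_xm * r_xy) / (1 - r_xm^2).
    Rows of the inputs are resamples.
    """

    def corr(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        num = (uc * vc).sum(axis=1)
        den = np.sqrt((uc**2).sum(axis=1) * (vc**2).sum(axis=1))
        return num / den

    r_xm = corr(x, m)
    r_xy = corr(x, y)
    r_my = corr(m, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (r_my - r_xm * r_xy) / (1.0 - r_xm**2)
    return r_xm * b


def mediate(
    predictor: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MediationResult:
    """Simple mediation with standardized paths and a bias-corrected bootstrap CI.

    All variables are z-standardized; OLS fits mediator ~ predictor (path a),
    outcome ~ predictor + mediator (paths c' and b), and outcome ~ predictor
    (total effect c). The indirect effect is a*b, and c = c' + a*b holds as
    an OLS identity. The CI resamples cases with replacement, recomputes the
    standardized indirect effect per resample, and shifts the percentile
    endpoints by the bias term z0 = Phi^-1(fraction of resamples below the
    point estimate): endpoints at Phi(2*z0 +/- 1.96).
    """
    x = np.asarray(predictor, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(x)
    if not (len(m) == len(y) == n):
        raise EstimationError("predictor, mediator, outcome must be equal length")
    if n < 10:
        raise EstimationError("mediation requires n >= 10")
    xz, mz, yz = _standardize(x), _standardize(m), _standardize(y)
    if abs(float(np.corrcoef(xz, mz)[0, 1])) >= 1.0 - 1e-12:
        raise EstimationError("predictor and mediator are collinear; paths undefined")

    path_a = _ols_path(mz, xz[:, None], 0)
    X2 = np.column_stack([xz, mz])
    path_c_prime = _ols_path(yz, X2, 0)
    path_b = _ols_path(yz, X2, 1)
    path_c = _ols_path(yz, xz[:, None], 0)
    indirect = path_a.coef * path_b.coef

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _boot_indirect(x[idx], m[idx], y[idx])
    boot = boot[np.isfinite(boot)]
    if len(boot) == 0:
        raise EstimationError("all bootstrap resamples degenerate")
    frac_below = np.mean(boot < indirect)
    frac_below = min(max(frac_below, 1.0 / (len(boot) + 1)), 1.0 - 1.0 / (len(boot) + 1))
    z0 = stats.norm.ppf(frac_below)
    zc = stats.norm.ppf(0.975)
    lo_p, hi_p = stats.norm.cdf(2 * z0 - zc), stats.norm.cdf(2 * z0 + zc)
    lo, hi = np.percentile(boot, [100 * lo_p, 100 * hi_p])

    return MediationResult(
        a=path_a,
        b=path_b,
        c=path_c,
        c_prime=path_c_prime,
        indirect=float(indirect),
        ci=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        n=n,
    )
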