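"""Inferential layer for the repeated cross-sectional analysis.

Three estimators, all with the implementation period as the only
predictor:

* **Firth bias-reduced logistic regression** on per-period "high in"
  counts.  The likelihood is penalised by the Jeffreys prior,
  ``l(b) + 0.5 * log det I(b)``, which keeps the estimates finite even
  under complete separation (a period with 0 or all products flagged).
  For the saturated one-factor design used here the fitted proportion of
  a period with ``k`` successes out of ``n`` is exactly
  ``(k + 1/2) / (n + 1)``, which the test suite checks against a numeric
  maximiser.

* **Pairwise estimated-marginal-mean contrasts** on the response
  (proportion) scale, with delta-method standard errors from the
  penalised fit's information matrix and two-sided Wald p-values,
  unadjusted by default.

* **Cochran-Armitage trend test** for a linear trend in proportions over
  ordered periods, equally spaced scores 0..G-1 by default, no
  continuity correction.  Its squared statistic equals the score test
  for logistic regression on the scores.

* **Quantile "regression" with a saturated categorical predictor**: the
  check-loss minimiser per period is a within-period sample quantile;
  when the minimiser is an interval the lower endpoint is returned (the
  vertex an LP solver reports).  Inference for period-versus-baseline
  quantile differences is by seeded within-period bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .errors import DegenerateTrendError, EstimationError, ValidationError
from .types import PERIODS

__all__ = [
    "PeriodCountTable",
    "FirthFit",
    "ContrastResult",
    "TrendResult",
    "QuartileSummary",
    "firth_logistic_fit",
    "emm_pairwise_contrasts",
    "cochran_armitage_trend",
    "sample_quantile_lower",
    "quantile_fit",
    "quantile_inference",
]


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodCountTable:
    """Per-period successes/totals, the unit of every proportion analysis."""

    periods: tuple
    k: tuple
    n: tuple

    def __post_init__(self):
        if len(self.periods) < 1:
            raise ValidationError("need at least 1 period")
        if not (len(self.periods) == len(self.k) == len(self.n)):
            raise ValidationError("periods, k and n must have equal length")
        for period, k, n in zip(self.periods, self.k, self.n):
            if n < 0 or not 0 <= k <= n:
                raise ValidationError(f"period {period}: need 0 <= k <= n, got k={k}, n={n}")

    @classmethod
    def from_counts(cls, counts: Sequence[tuple], periods=None) -> "PeriodCountTable":
        """Build from ``[(k, n), ...]`` in period order (defaults T0..)."""
        if periods is None:
            periods = PERIODS[: len(counts)]
        k, n = zip(*counts)
        return cls(tuple(periods), tuple(int(x) for x in k), tuple(int(x) for x in n))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PeriodCountTable":
        """Build from a table with columns ``period``, ``k``, ``n``."""
        frame = frame.sort_values(
            "period", key=lambda s: s.map({p: i for i, p in enumerate(PERIODS)}).fillna(len(PERIODS))
        )
        return cls(
            tuple(frame["period"]), tuple(int(v) for v in frame["k"]), tuple(int(v) for v in frame["n"])
        )

    @classmethod
    def from_csv(cls, path) -> "PeriodCountTable":
        return cls.from_frame(pd.read_csv(path))

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray(self.k, float) / np.asarray(self.n, float)


def _design(n_groups: int) -> np.ndarray:
    """Intercept + indicator coding for periods 2..G (full rank, saturated)."""
    X = np.zeros((n_groups, n_groups))
    X[:, 0] = 1.0
    for g in range(1, n_groups):
        X[g, g] = 1.0
    return X


# ---------------------------------------------------------------------------
# Firth logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FirthFit:
    """Result of a Jeffreys-penalised logistic fit on grouped counts."""

    periods: tuple
    beta: np.ndarray            # logit-scale coefficients (intercept + indicators)
    cov: np.ndarray             # inverse information at the optimum
    X: np.ndarray               # design matrix (one row per period)
    loglik_penalized: float
    n_iter: int
    converged: bool

    @property
    def fitted_proportions(self) -> np.ndarray:
        """Estimated marginal mean (fitted proportion) per period."""
        return expit(self.X @ self.beta)


def _penalized_loglik(beta, X, k, n):
    eta = X @ beta
    p = expit(eta)
    eps = 1e-300
    ll = float(np.sum(k * np.log(p + eps) + (n - k) * np.log(1 - p + eps)))
    W = n * p * (1 - p)
    sign, logdet = np.linalg.slogdet(X.T @ (W[:, None] * X))
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic_fit(
    counts: PeriodCountTable, *, tol: float = 1e-8, max_iter: int = 100
) -> FirthFit:
    """Fit the one-factor Firth-penalised logistic model to grouped counts.

    Newton iterations on the bias-adjusted score
    ``U*(b) = X'(k - n p + h (1/2 - p))`` where ``h`` are the hat values
    of the weighted design, with step-halving whenever a step would
    decrease the penalised log-likelihood.  Convergence is declared when
    ``max |U*| < tol``.
    """
    k = np.asarray(counts.k, float)
    n = np.asarray(counts.n, float)
    if np.any(n <= 0):
        raise ValidationError("every period must have n > 0")
    G = len(counts.periods)
    X = _design(G)

    # start at the (penalised-friendly) empirical logits
    p0 = (k + 0.5) / (n + 1.0)
    beta = np.linalg.solve(X, np.log(p0 / (1 - p0)))

    trace = []
    pll = _penalized_loglik(beta, X, k, n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        W = n * p * (1 - p)
        XtWX = X.T @ (W[:, None] * X)
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise EstimationError("singular information matrix", trace) from exc
        # hat values of the weighted design
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * W
        U_star = X.T @ (k - n * p + h * (0.5 - p))
        trace.append((it, float(np.max(np.abs(U_star))), pll))
        if np.max(np.abs(U_star)) < tol:
            converged = True
            break
        delta = XtWX_inv @ U_star
        # step-halving on penalised-likelihood decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            cand_pll = _penalized_loglik(cand, X, k, n)
            if cand_pll >= pll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        pll = _penalized_loglik(beta, X, k, n)
    if not converged:
        raise EstimationError(
            f"Firth fit did not converge in {max_iter} iterations", trace
        )
    p = expit(X @ beta)
    W = n * p * (1 - p)
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    return FirthFit(
        periods=counts.periods,
        beta=beta,
        cov=cov,
        X=X,
        loglik_penalized=pll,
        n_iter=it,
        converged=True,
    )


@dataclass(frozen=True)
class ContrastResult:
    """Pairwise difference of fitted proportions, percentage points."""

    period_a: str
    period_b: str
    difference_pp: float     # 100 * (p_b - p_a)
    se_pp: float
    z: float
    p_value: float


def emm_pairwise_contrasts(
    fit: FirthFit, counts: Optional[PeriodCountTable] = None, *, adjust: str = "none"
) -> list:
    """All ordered pairwise contrasts of fitted proportions.

    The contrast for ``(a, b)`` is ``100 * (p_b - p_a)`` percentage
    points with a delta-method standard error; p-values are two-sided
    Wald and unadjusted unless ``adjust="bonferroni"``.
    """
    if not fit.converged:
        raise EstimationError("cannot contrast an unconverged fit")
    if len(fit.periods) < 2:
        raise ValidationError("need at least 2 periods to contrast")
    if adjust not in ("none", "bonferroni"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    p = fit.fitted_proportions
    # gradient of each fitted proportion w.r.t. beta
    grads = (p * (1 - p))[:, None] * fit.X
    results = []
    n_pairs = len(fit.periods) * (len(fit.periods) - 1) // 2
    for a in range(len(fit.periods)):
        for b in range(len(fit.periods)):
            if a == b:
                continue
            g = grads[b] - grads[a]
            var = float(g @ fit.cov @ g)
            if var <= 0:
                raise EstimationError("singular covariance in contrast")
            se = math.sqrt(var)
            diff = float(p[b] - p[a])
            z = diff / se
            pval = 2.0 * sps.norm.sf(abs(z))
            if adjust == "bonferroni":
                pval = min(1.0, pval * n_pairs)
            results.append(
                ContrastResult(
                    period_a=fit.periods[a],
                    period_b=fit.periods[b],
                    difference_pp=100.0 * diff,
                    se_pp=100.0 * se,
                    z=z,
                    p_value=float(pval),
                )
            )
    return results


def contrast_for(contrasts, period_a: str, period_b: str) -> ContrastResult:
    """Pick one pair out of :func:`emm_pairwise_contrasts` output."""
    for c in contrasts:
        if c.period_a == period_a and c.period_b == period_b:
            return c
    raise KeyError((period_a, period_b))


# ---------------------------------------------------------------------------
# Cochran-Armitage trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    scores: tuple
    z: float
    p_value: float


def cochran_armitage_trend(
    counts: PeriodCountTable, scores: Optional[Sequence[float]] = None
) -> TrendResult:
    """Standardised linear-trend statistic over ordered binomial groups.

    ``Z = sum s_g (k_g - n_g pbar) / sqrt(pbar (1-pbar) (sum n_g s_g^2 -
    (sum n_g s_g)^2 / N))`` with ``pbar`` the pooled proportion, and a
    two-sided normal p-value.  Raises when the pooled proportion is 0 or
    1 (no variation to test).
    """
    G = len(counts.periods)
    if G < 3:
        raise ValidationError("need at least 3 periods for a meaningful trend")
    if scores is None:
        scores = tuple(float(i) for i in range(G))
    scores = tuple(float(s) for s in scores)
    if len(scores) != G:
        raise ValidationError("need exactly one score per period")
    k = np.asarray(counts.k, float)
    n = np.asarray(counts.n, float)
    s = np.asarray(scores, float)
    N = n.sum()
    pbar = k.sum() / N
    if pbar <= 0.0 or pbar >= 1.0:
        raise DegenerateTrendError("pooled proportion is 0 or 1; trend undefined")
    num = float(np.sum(s * (k - n * pbar)))
    var = pbar * (1 - pbar) * (float(np.sum(n * s**2)) - float(np.sum(n * s)) ** 2 / N)
    if var <= 0:
        raise DegenerateTrendError("zero trend variance (constant scores?)")
    z = num / math.sqrt(var)
    return TrendResult(scores=scores, z=float(z), p_value=float(2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# quantiles
# ---------------------------------------------------------------------------

def sample_quantile_lower(values: np.ndarray, tau: float) -> float:
    """Check-loss-minimising sample quantile, lower endpoint on ties.

    For ``m`` observations the minimiser of ``sum rho_tau(y - q)`` is the
    order statistic ``y_(ceil(m tau))`` when ``m tau`` is not an integer
    and the interval ``[y_(m tau), y_(m tau + 1)]`` when it is; this
    returns the interval's lower endpoint.
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"tau must be in (0, 1), got {tau}")
    y = np.sort(np.asarray(values, float))
    m = len(y)
    if m == 0:
        raise ValidationError("cannot take the quantile of an empty sample")
    j = tau * m
    j_round = round(j)
    if abs(j - j_round) < 1e-9 * max(1.0, m) and j_round >= 1:
        idx = int(j_round) - 1
    else:
        idx = int(math.ceil(j)) - 1
    return float(y[min(max(idx, 0), m - 1)])


DEFAULT_TAUS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class QuartileSummary:
    """Per-period quantiles of one nutrient (optionally with p-values).

    ``quantiles[i, j]`` is the fitted tau_j quantile in period i;
    ``p_values`` (same shape) holds bootstrap p-values against the
    baseline period, NaN in the baseline row.
    """

    periods: tuple
    taus: tuple
    quantiles: np.ndarray
    p_values: Optional[np.ndarray] = None
    group: Optional[str] = None
    nutrient: Optional[str] = None
    baseline: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, period in enumerate(self.periods):
            row = {"group": self.group, "nutrient": self.nutrient, "period": period}
            for j, tau in enumerate(self.taus):
                row[f"q{int(round(tau * 100))}"] = self.quantiles[i, j]
                if self.p_values is not None:
                    row[f"p_q{int(round(tau * 100))}"] = self.p_values[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def _split_by_period(values, periods):
    values = np.asarray(values, float)
    periods = np.asarray(periods)
    if len(values) != len(periods):
        raise ValidationError("values and periods must align")
    if len(values) and not np.all(np.isfinite(values)):
        raise ValidationError("values must be finite")
    order = {p: i for i, p in enumerate(PERIODS)}
    labels = sorted(set(periods.tolist()), key=lambda p: (order.get(p, len(PERIODS)), p))
    if not labels:
        raise ValidationError("no observations")
    groups = {p: values[periods == p] for p in labels}
    for p, v in groups.items():
        if len(v) == 0:
            raise ValidationError(f"period {p} has no observations")
    return labels, groups


def quantile_fit(values, periods, taus: Sequence[float] = DEFAULT_TAUS) -> QuartileSummary:
    """Fit per-period quantiles with period as the sole (saturated) predictor.

    Because the design is saturated, minimising the pooled check loss
    separates by period and each fitted value is a within-period sample
    quantile under the lower-endpoint convention.
    """
    labels, groups = _split_by_period(values, periods)
    taus = tuple(float(t) for t in taus)
    q = np.array([[sample_quantile_lower(groups[p], t) for t in taus] for p in labels])
    return QuartileSummary(periods=tuple(labels), taus=taus, quantiles=q)


def quantile_inference(
    values,
    periods,
    taus: Sequence[float] = DEFAULT_TAUS,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    baseline: Optional[str] = None,
) -> QuartileSummary:
    """Bootstrap p-values for period-versus-baseline quantile differences.

    Within-period resampling (``n_boot`` replicates, seeded) gives the
    bootstrap standard error of each difference of fitted quantiles; the
    p-value is two-sided normal on ``difference / se``.  Deterministic
    given the seed.  A degenerate bootstrap (zero spread) yields p = 1
    when the observed difference is 0 and p = 0 otherwise.
    """
    if n_boot < 200:
        raise ValidationError(f"n_boot must be >= 200, got {n_boot}")
    fit = quantile_fit(values, periods, taus)
    labels = fit.periods
    if baseline is None:
        baseline = labels[0]
    if baseline not in labels:
        raise ValidationError(f"baseline {baseline!r} not among periods {labels}")
    _, groups = _split_by_period(values, periods)
    rng = np.random.default_rng(seed)
    base_idx = labels.index(baseline)

    def boot_quantiles(sample: np.ndarray) -> np.ndarray:
        """(n_boot, n_taus) bootstrap quantiles under the same convention."""
        m = len(sample)
        draws = rng.integers(0, m, size=(n_boot, m))
        boot = np.sort(sample[draws], axis=1)
        cols = []
        for t in fit.taus:
            j = t * m
            j_round = round(j)
            if abs(j - j_round) < 1e-9 * max(1.0, m) and j_round >= 1:
                idx = int(j_round) - 1
            else:
                idx = int(math.ceil(j)) - 1
            cols.append(boot[:, min(max(idx, 0), m - 1)])
        return np.column_stack(cols)

    pvals = np.full_like(fit.quantiles, np.nan)
    for i, period in enumerate(labels):
        if i == base_idx:
            continue
        qb_base = boot_quantiles(groups[baseline])
        qb_per = boot_quantiles(groups[period])
        diffs = qb_per - qb_base
        se = diffs.std(axis=0, ddof=1)
        observed = fit.quantiles[i] - fit.quantiles[base_idx]
        for j in range(len(fit.taus)):
            if se[j] == 0.0:
                pvals[i, j] = 1.0 if observed[j] == 0.0 else 0.0
            else:
                pvals[i, j] = 2.0 * sps.norm.sf(abs(observed[j] / se[j]))
    return QuartileSummary(
        periods=labels,
        taus=fit.taus,
        quantiles=fit.quantiles,
        p_values=pvals,
        baseline=baseline,
    )
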