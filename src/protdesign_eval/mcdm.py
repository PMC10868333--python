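"""Multi-criteria ranking of design methods: weighted TOPSIS with CRITIC
objective and fuzzy-AHP subjective weights.

Pipeline
--------
1. ``orient_and_transform`` — turn every cost indicator into a benefit one
   (max-minus for linear costs, reciprocal for RMSD) after imputing the at
   most one missing cell per column.
2. ``zscore_standardize`` — remove dimension (sample standard deviation).
3. ``critic_weights`` — objective weights from column variability times
   accumulated conflict, the variability measured on min-max normalized
   columns so indicators with a wide relative spread count more.
4. ``fahp_weights`` — subjective weights from a triangular-fuzzy pairwise
   comparison matrix (geometric-mean aggregation, centroid defuzzification),
   or an explicit weight row in bypass mode.
5. ``combine_weights`` — convex combination, default 50:50.
6. ``topsis_score`` — relative closeness Ci = D⁻/(D⁺ + D⁻) to the ideal
   worst/best solutions; dense ranks by descending Ci.

:class:`TopsisEvaluator` wraps the chain as a scikit-learn style estimator;
:func:`evaluate` and :func:`sensitivity_sweep` are thin functional entry
points over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .errors import (
    ConfigError,
    DegenerateInputError,
    DimensionMismatchError,
    DomainError,
    InputTooSmallError,
    InvariantViolationError,
)
from .io import IndicatorTable

MISSING_POLICIES = ("worst-impute", "best-impute", "mean-impute", "drop-column")

#: Random consistency index for crisp pairwise-comparison matrices of
#: order 1..10 (Saaty).
RANDOM_INDEX = [0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49]


# ---------------------------------------------------------------------------
# weight containers
# ---------------------------------------------------------------------------

@dataclass
class WeightVector:
    """Nonnegative per-indicator weights summing to one."""

    indicator_names: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.indicator_names) != self.weights.size:
            raise DimensionMismatchError(
                "weight vector length does not match its indicator names"
            )
        if np.any(self.weights < 0):
            raise InvariantViolationError("weights must be nonnegative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise InvariantViolationError(
                f"weights must sum to 1 (got {total:.12g}); "
                "use WeightVector.normalized to renormalize"
            )

    @classmethod
    def normalized(cls, indicator_names, weights) -> "WeightVector":
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise InvariantViolationError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise DegenerateInputError("weights sum to zero")
        return cls(list(indicator_names), w / total)

    @classmethod
    def from_mapping(cls, mapping, indicator_names) -> "WeightVector":
        missing = [n for n in indicator_names if n not in mapping]
        if missing:
            raise DimensionMismatchError(
                f"weights missing for indicators {missing}"
            )
        return cls.normalized(indicator_names,
                              [mapping[n] for n in indicator_names])

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.indicator_names)


@dataclass
class EvaluationResult:
    """Per-method relative closeness and dense rank (1 = best)."""

    method_names: list[str]
    ci: np.ndarray
    ranks: np.ndarray
    has_ties: bool = False

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Ci": self.ci, "Rank": self.ranks},
                            index=self.method_names)

    def rank_of(self, method: str) -> int:
        return int(self.ranks[self.method_names.index(method)])

    def ci_of(self, method: str) -> float:
        return float(self.ci[self.method_names.index(method)])


@dataclass
class RankTrajectory:
    """Per-method ranks across a grid of subjective-weight proportions."""

    lambdas: np.ndarray
    ranks: pd.DataFrame  # methods × lambda grid
    ci: pd.DataFrame


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def orient_and_transform(table: IndicatorTable,
                         missing_policy: str = "worst-impute") -> pd.DataFrame:
    """Impute missing cells and convert every column to benefit orientation.

    Cost-linear columns map x → max(column) − x, cost-reciprocal columns
    map x → 1/x (all values must be positive), benefit columns pass
    through.  Missing values are imputed from the observed values of their
    column *before* transformation: the worst observed value under
    ``worst-impute`` (default), the best under ``best-impute``, the mean
    under ``mean-impute``; ``drop-column`` removes the column entirely.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(f"unknown missing policy {missing_policy!r}")
    df = table.data.astype(float).copy()
    for col in list(df.columns):
        orient = table.orientation[col]
        observed = df[col].dropna()
        if observed.empty:
            raise InputTooSmallError(f"indicator {col!r}: all values missing")
        if len(observed) < 2:
            raise InputTooSmallError(
                f"indicator {col!r}: fewer than 2 observed values"
            )
        if df[col].isna().any():
            if missing_policy == "drop-column":
                df = df.drop(columns=col)
                continue
            if missing_policy == "mean-impute":
                fill = observed.mean()
            else:
                want_worst = missing_policy == "worst-impute"
                if orient == "benefit":
                    fill = observed.min() if want_worst else observed.max()
                else:  # larger raw value is worse for both cost flavours
                    fill = observed.max() if want_worst else observed.min()
            df[col] = df[col].fillna(fill)
        if orient == "cost-linear":
            df[col] = df[col].max() - df[col]
        elif orient == "cost-reciprocal":
            if (df[col] <= 0).any():
                raise DomainError(
                    f"indicator {col!r}: reciprocal transform requires "
                    "positive values"
                )
            df[col] = 1.0 / df[col]
    return df


def zscore_standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-score with sample standard deviation (n−1)."""
    sd = matrix.std(ddof=1)
    constant = sd[~(sd > 0)].index.tolist()
    if constant:
        raise DegenerateInputError(
            f"constant indicator column(s): {constant}"
        )
    return (matrix - matrix.mean()) / sd


# ---------------------------------------------------------------------------
# objective weights (CRITIC)
# ---------------------------------------------------------------------------

def critic_weights(matrix: pd.DataFrame) -> WeightVector:
    """CRITIC objective weights from a benefit-oriented matrix.

    Information content of indicator j is σ_j · Σ_k (1 − r_jk), with σ_j
    the sample standard deviation of the min-max normalized column and
    r_jk the Pearson correlation between columns (scale-free, so it can be
    computed on the oriented columns directly).  The self term r_jj
    contributes exactly zero.  Weights are the normalized contents.
    """
    if matrix.shape[1] < 2:
        raise InputTooSmallError("CRITIC requires at least 2 indicators")
    if matrix.shape[0] < 3:
        raise InputTooSmallError("CRITIC requires at least 3 methods")
    rng = matrix.max() - matrix.min()
    if (rng <= 0).any():
        bad = rng[rng <= 0].index.tolist()
        raise DegenerateInputError(f"constant indicator column(s): {bad}")
    normalized = (matrix - matrix.min()) / rng
    sigma = normalized.std(ddof=1)
    corr = matrix.corr(method="pearson")
    if corr.isna().any().any():
        raise DegenerateInputError("undefined correlation between indicators")
    conflict = (1.0 - corr).sum(axis=1)
    content = sigma * conflict
    return WeightVector.normalized(list(matrix.columns), content.to_numpy())


# ---------------------------------------------------------------------------
# subjective weights (fuzzy AHP)
# ---------------------------------------------------------------------------

@dataclass
class FuzzyJudgmentMatrix:
    """n×n reciprocal matrix of triangular fuzzy numbers (l, m, u).

    ``values`` has shape (n, n, 3).  The diagonal is (1,1,1) and
    a_ji = (1/u_ij, 1/m_ij, 1/l_ij).
    """

    indicator_names: list[str]
    values: np.ndarray
    _rtol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.indicator_names)
        if self.values.shape != (n, n, 3):
            raise DimensionMismatchError(
                f"judgment matrix must have shape ({n}, {n}, 3)"
            )
        l, m, u = self.values[..., 0], self.values[..., 1], self.values[..., 2]
        if np.any(l <= 0):
            raise InvariantViolationError("fuzzy numbers must be positive")
        if np.any(l > m + 1e-12) or np.any(m > u + 1e-12):
            raise InvariantViolationError("triangular numbers need l ≤ m ≤ u")
        if not np.allclose(self.values[np.arange(n), np.arange(n)], 1.0):
            raise InvariantViolationError("diagonal must be (1, 1, 1)")
        expected = np.stack([1.0 / u.T, 1.0 / m.T, 1.0 / l.T], axis=-1)
        if not np.allclose(self.values, expected, rtol=self._rtol):
            raise InvariantViolationError(
                "matrix is not reciprocal: a_ji must equal (1/u, 1/m, 1/l)"
            )

    @classmethod
    def from_crisp(cls, indicator_names, matrix) -> "FuzzyJudgmentMatrix":
        """Promote a crisp pairwise matrix to degenerate TFNs (m, m, m)."""
        m = np.asarray(matrix, dtype=float)
        return cls(list(indicator_names), np.stack([m, m, m], axis=-1))

    @classmethod
    def from_config(cls, config: dict) -> "FuzzyJudgmentMatrix":
        names = config["indicator_names"]
        vals = np.asarray(config["values"], dtype=float)
        if vals.ndim == 2:
            return cls.from_crisp(names, vals)
        return cls(list(names), vals)

    @property
    def middle(self) -> np.ndarray:
        return self.values[..., 1]


def consistency_ratio(crisp: np.ndarray) -> float:
    """Saaty consistency ratio of a crisp positive reciprocal matrix."""
    n = crisp.shape[0]
    if n <= 2:
        return 0.0
    eigvals = np.linalg.eigvals(crisp)
    lam_max = float(np.max(eigvals.real))
    ci = (lam_max - n) / (n - 1)
    if n - 1 >= len(RANDOM_INDEX):
        ri = RANDOM_INDEX[-1]
    else:
        ri = RANDOM_INDEX[n - 1]
    return ci / ri


def fahp_weights(judgment: FuzzyJudgmentMatrix,
                 cr_threshold: float = 0.1) -> tuple[WeightVector, float]:
    """Fuzzy-AHP weights and the consistency ratio of the middle matrix.

    Rows are aggregated by the component-wise geometric mean; the fuzzy
    weight of row i is its aggregate divided by the column-sum aggregate
    (with the order-reversing fuzzy reciprocal); defuzzification is the
    centroid (l+m+u)/3, then normalization.  A consistency ratio at or
    above *cr_threshold* emits a warning, not an error.
    """
    vals = judgment.values
    n = vals.shape[0]
    row_gm = np.exp(np.log(vals).mean(axis=1))  # (n, 3), still l ≤ m ≤ u
    totals = row_gm.sum(axis=0)  # (Σl, Σm, Σu)
    fuzzy_w = np.stack([
        row_gm[:, 0] / totals[2],
        row_gm[:, 1] / totals[1],
        row_gm[:, 2] / totals[0],
    ], axis=-1)
    crisp = fuzzy_w.mean(axis=1)  # centroid defuzzification
    weights = WeightVector.normalized(judgment.indicator_names, crisp)
    cr = consistency_ratio(judgment.middle)
    if cr >= cr_threshold:
        import warnings

        warnings.warn(
            f"judgment matrix consistency ratio {cr:.3f} ≥ {cr_threshold}",
            stacklevel=2,
        )
    return weights, cr


def combine_weights(w_objective: WeightVector, w_subjective: WeightVector,
                    lambda_subjective: float = 0.5) -> WeightVector:
    """w = λ·w_subjective + (1−λ)·w_objective, renormalized defensively."""
    if list(w_objective.indicator_names) != list(w_subjective.indicator_names):
        raise DimensionMismatchError(
            "objective and subjective weights use different indicator sets"
        )
    if not 0.0 <= lambda_subjective <= 1.0:
        raise ConfigError("lambda_subjective must lie in [0, 1]")
    combined = (lambda_subjective * w_subjective.weights
                + (1.0 - lambda_subjective) * w_objective.weights)
    return WeightVector.normalized(w_objective.indicator_names, combined)


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------

def topsis_score(standardized: pd.DataFrame,
                 weights: WeightVector) -> EvaluationResult:
    """Relative closeness to the ideal solutions, with dense ranks.

    v_ij = w_j·z_ij; the ideal best (worst) solution is the column-wise
    max (min) of v; D± are Euclidean distances and Ci = D⁻/(D⁺ + D⁻).
    """
    if list(standardized.columns) != list(weights.indicator_names):
        raise DimensionMismatchError(
            "standardized matrix and weights use different indicator sets"
        )
    v = standardized.to_numpy() * weights.weights
    best = v.max(axis=0)
    worst = v.min(axis=0)
    d_plus = np.linalg.norm(v - best, axis=1)
    d_minus = np.linalg.norm(v - worst, axis=1)
    denom = d_plus + d_minus
    if np.any(denom == 0):
        raise DegenerateInputError(
            "a method coincides with both ideal solutions "
            "(all indicators constant)"
        )
    ci = d_minus / denom
    ranks = _dense_ranks_desc(ci)
    has_ties = len(np.unique(np.round(ci, 12))) < ci.size
    return EvaluationResult(list(standardized.index), ci, ranks, has_ties)


def _dense_ranks_desc(ci: np.ndarray) -> np.ndarray:
    """Dense ranking of descending values; ties share the smaller rank."""
    s = pd.Series(ci)
    return s.rank(method="dense", ascending=False).astype(int).to_numpy()


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class TopsisEvaluator(BaseEstimator):
    """CRITIC + fuzzy-AHP weighted TOPSIS ranking, sklearn style.

    Parameters
    ----------
    subjective_weights:
        Mapping of indicator name to subjective weight (bypass mode, used
        to inject a published weight row), or None to derive weights from
        *judgment_matrix*.
    judgment_matrix:
        :class:`FuzzyJudgmentMatrix` (or a config dict for one).  Exactly
        one of *subjective_weights* / *judgment_matrix* must be given.
    lambda_subjective:
        Proportion of the subjective weight in the combination, default 0.5.
    missing_policy:
        How the at most one missing cell per column is handled, see
        :func:`orient_and_transform`.

    Attributes (after :meth:`fit`)
    ------------------------------
    objective_weights_, subjective_weights_, combined_weights_ :
        :class:`WeightVector`
    consistency_ratio_ : float or None (None in bypass mode)
    result_ : :class:`EvaluationResult`
    ci_, ranks_ : ndarray views of the result
    """

    def __init__(self, subjective_weights=None, judgment_matrix=None,
                 lambda_subjective: float = 0.5,
                 missing_policy: str = "worst-impute"):
        self.subjective_weights = subjective_weights
        self.judgment_matrix = judgment_matrix
        self.lambda_subjective = lambda_subjective
        self.missing_policy = missing_policy

    def fit(self, X: IndicatorTable, y=None) -> "TopsisEvaluator":
        if not isinstance(X, IndicatorTable):
            raise ConfigError(
                "TopsisEvaluator.fit expects an IndicatorTable "
                "(use IndicatorTable(data=df, orientation=...))"
            )
        if X.data.shape[0] < 2:
            raise DegenerateInputError(
                "ranking needs at least two methods"
            )
        if (self.subjective_weights is None) == (self.judgment_matrix is None):
            raise ConfigError(
                "provide exactly one of subjective_weights or judgment_matrix"
            )
        try:
            oriented = orient_and_transform(X, self.missing_policy)
            standardized = zscore_standardize(oriented)
            w1 = critic_weights(oriented)
        except Exception as exc:
            raise type(exc)(f"[preprocess/critic] {exc}") from exc
        names = list(oriented.columns)
        if self.subjective_weights is not None:
            w2 = (self.subjective_weights
                  if isinstance(self.subjective_weights, WeightVector)
                  else WeightVector.from_mapping(self.subjective_weights,
                                                 names))
            if list(w2.indicator_names) != names:
                raise DimensionMismatchError(
                    "[fahp] subjective weights do not match table indicators"
                )
            cr = None
        else:
            jm = (self.judgment_matrix
                  if isinstance(self.judgment_matrix, FuzzyJudgmentMatrix)
                  else FuzzyJudgmentMatrix.from_config(self.judgment_matrix))
            if list(jm.indicator_names) != names:
                raise DimensionMismatchError(
                    "[fahp] judgment matrix does not match table indicators"
                )
            w2, cr = fahp_weights(jm)
        combined = combine_weights(w1, w2, self.lambda_subjective)
        result = topsis_score(standardized, combined)

        self.oriented_ = oriented
        self.standardized_ = standardized
        self.objective_weights_ = w1
        self.subjective_weights_ = w2
        self.combined_weights_ = combined
        self.consistency_ratio_ = cr
        self.result_ = result
        self.ci_ = result.ci
        self.ranks_ = result.ranks
        return self

    def fit_predict(self, X: IndicatorTable, y=None) -> np.ndarray:
        """Fit and return the dense ranks (1 = best)."""
        return self.fit(X).ranks_

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise NotFittedError("TopsisEvaluator is not fitted yet")

    @property
    def weights_frame_(self) -> pd.DataFrame:
        self._check_fitted()
        return pd.DataFrame(
            {
                "AHP weight": self.subjective_weights_.series,
                "CRITIC weight": self.objective_weights_.series,
                "Final weight": self.combined_weights_.series,
            }
        ).T


# ---------------------------------------------------------------------------
# functional front ends
# ---------------------------------------------------------------------------

def evaluate(table: IndicatorTable, subjective_weights=None,
             judgment_matrix=None, lambda_subjective: float = 0.5,
             missing_policy: str = "worst-impute",
             ) -> tuple[EvaluationResult, dict[str, WeightVector]]:
    """Run the full pipeline; returns the result and all three weight rows."""
    est = TopsisEvaluator(
        subjective_weights=subjective_weights,
        judgment_matrix=judgment_matrix,
        lambda_subjective=lambda_subjective,
        missing_policy=missing_policy,
    ).fit(table)
    weights = {
        "objective": est.objective_weights_,
        "subjective": est.subjective_weights_,
        "combined": est.combined_weights_,
    }
    return est.result_, weights


def sensitivity_sweep(table: IndicatorTable, subjective_weights=None,
                      judgment_matrix=None, grid=None,
                      missing_policy: str = "worst-impute") -> RankTrajectory:
    """Rank trajectory over a grid of subjective-weight proportions λ.

    The CRITIC weights are data-determined and independent of λ, so they
    are computed once; the grid must lie in [0, 1] and contain 0.5 so the
    default evaluation appears in the trajectory.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    grid = np.asarray(sorted(float(g) for g in grid))
    if grid.size == 0 or grid.min() < 0 or grid.max() > 1:
        raise ConfigError("sensitivity grid must lie in [0, 1]")
    if not np.any(np.isclose(grid, 0.5)):
        raise ConfigError("sensitivity grid must contain λ = 0.5")

    base = TopsisEvaluator(
        subjective_weights=subjective_weights,
        judgment_matrix=judgment_matrix,
        lambda_subjective=0.5,
        missing_policy=missing_policy,
    ).fit(table)
    w1, w2 = base.objective_weights_, base.subjective_weights_
    ranks, cis = {}, {}
    for lam in grid:
        w = combine_weights(w1, w2, float(lam))
        res = topsis_score(base.standardized_, w)
        ranks[lam] = res.ranks
        cis[lam] = res.ci
    methods = base.result_.method_names
    return RankTrajectory(
        lambdas=grid,
        ranks=pd.DataFrame(ranks, index=methods),
        ci=pd.DataFrame(cis, index=methods),
    )
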