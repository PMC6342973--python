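"""Group and aging statistics for entropy and capacity measures.

Implements the study workflow around the entropy pipeline:

* a label-permutation null for comparing the volume entropy of two group
  networks, where each group network is rebuilt from the pooled per-subject
  measurement columns under every permuted labelling;
* per-feature (edge or node capacity) Wilcoxon rank-sum comparisons with
  Benjamini-Hochberg false-discovery-rate control;
* ordinary-least-squares age-association models, linear and quadratic (the
  quadratic fit also reports the vertex age, the extremum of the fitted
  parabola).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .entropy import solve_volume_entropy
from .graph import WeightedNetwork
from .kernel import network_from_measurements

__all__ = [
    "PermutationEntropyResult",
    "permutation_entropy_test",
    "capacity_group_test",
    "AgeAssociation",
    "age_association",
]


@dataclass(frozen=True)
class PermutationEntropyResult:
    """Permutation-null comparison of two group volume entropies.

    ``p_lower_A`` is the probability, under relabelling, of a group-A
    entropy at or below the observed one (add-one estimator); ``p_upper_A``
    the symmetric upper tail, and likewise for B.  ``p_difference`` is the
    two-sided p-value for the observed entropy difference A - B.
    """

    observed_A: float
    observed_B: float
    null_A: np.ndarray
    null_B: np.ndarray
    p_lower_A: float
    p_upper_A: float
    p_lower_B: float
    p_upper_B: float
    p_difference: float
    n_perm: int
    low_permutation_warning: bool


def permutation_entropy_test(
    measurements_A: np.ndarray,
    measurements_B: np.ndarray,
    n_perm: int = 5000,
    seed: int | None = None,
    network_builder: Callable[[np.ndarray], WeightedNetwork] | None = None,
    kernel_k: int = 10,
) -> PermutationEntropyResult:
    """Permutation test for the volume entropy of two group networks.

    Each group is summarized by one network built from its ``p x n_g``
    measurement matrix (columns = subjects or time points).  Every
    permutation reshuffles the pooled columns into two pseudo-groups of the
    original sizes, rebuilds both networks and re-solves the entropy,
    giving a null distribution for each group and for the difference.

    Parameters
    ----------
    measurements_A, measurements_B
        ``p x nA`` and ``p x nB`` matrices over the same ``p`` nodes.
    n_perm
        Number of label permutations (must be >= 1; below 100 the add-one
        p-values are coarse and a warning flag is set).
    seed
        Seeds the permutation stream.
    network_builder
        Maps a ``p x n`` array to a :class:`WeightedNetwork`; defaults to
        the correlation-kernel pipeline with ``k = kernel_k``.
    """
    A = np.asarray(measurements_A, dtype=float)
    B = np.asarray(measurements_B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("measurement matrices must be 2-D with matching rows")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    low = n_perm < 100
    if low:
        warnings.warn("n_perm < 100 gives very coarse permutation p-values")

    if network_builder is None:
        def network_builder(X: np.ndarray) -> WeightedNetwork:
            return network_from_measurements(X, k=kernel_k)

    hint: dict[str, float | None] = {"h": None}

    def entropy_of(X: np.ndarray) -> float:
        net = network_builder(X)
        res = solve_volume_entropy(
            net, bracket_hint=hint["h"], compute_stationary=False
        )
        hint["h"] = res.h_vol if res.h_vol > 0 else None
        return res.h_vol

    obs_A = entropy_of(A)
    obs_B = entropy_of(B)

    pooled = np.concatenate([A, B], axis=1)
    nA, nB = A.shape[1], B.shape[1]
    rng = np.random.default_rng(seed)
    null_A = np.empty(n_perm)
    null_B = np.empty(n_perm)
    for j in range(n_perm):
        perm = rng.permutation(nA + nB)
        null_A[j] = entropy_of(pooled[:, perm[:nA]])
        null_B[j] = entropy_of(pooled[:, perm[nA:]])

    def add_one(count: int) -> float:
        return (1.0 + count) / (1.0 + n_perm)

    diff_obs = obs_A - obs_B
    diff_null = null_A - null_B
    return PermutationEntropyResult(
        observed_A=obs_A,
        observed_B=obs_B,
        null_A=null_A,
        null_B=null_B,
        p_lower_A=add_one(int(np.sum(null_A <= obs_A))),
        p_upper_A=add_one(int(np.sum(null_A >= obs_A))),
        p_lower_B=add_one(int(np.sum(null_B <= obs_B))),
        p_upper_B=add_one(int(np.sum(null_B >= obs_B))),
        p_difference=add_one(int(np.sum(np.abs(diff_null) >= abs(diff_obs)))),
        n_perm=n_perm,
        low_permutation_warning=low,
    )


def capacity_group_test(
    capacities_A: np.ndarray | pd.DataFrame,
    capacities_B: np.ndarray | pd.DataFrame,
    alpha: float = 0.05,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum test with Benjamini-Hochberg control.

    Rows are subjects, columns are features (node capacities, or flattened
    edge-capacity entries); both groups must share the same feature order.
    Returns a DataFrame with the rank-sum statistic, raw ``p``, BH ``q``
    and the significance mask at ``alpha``.  With identical all-tied
    samples the midrank statistic is 0 and ``p = 1``.
    """
    if isinstance(capacities_A, pd.DataFrame) or isinstance(capacities_B, pd.DataFrame):
        fa = list(getattr(capacities_A, "columns", []))
        fb = list(getattr(capacities_B, "columns", []))
        if fa and fb and fa != fb:
            raise ValueError("feature orderings of the two groups differ")
        feature_names = feature_names or (fa or fb)
        capacities_A = np.asarray(capacities_A, dtype=float)
        capacities_B = np.asarray(capacities_B, dtype=float)
    A = np.atleast_2d(np.asarray(capacities_A, dtype=float))
    B = np.atleast_2d(np.asarray(capacities_B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature counts differ: {A.shape[1]} vs {B.shape[1]} "
            "(check that node orderings match)"
        )
    m = A.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(m)]
    stats = np.empty(m)
    pvals = np.empty(m)
    for j in range(m):
        s, pv = ranksums(A[:, j], B[:, j])
        stats[j] = s
        pvals[j] = pv
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "feature": list(feature_names),
            "statistic": stats,
            "p": pvals,
            "q": qvals,
            "significant": reject,
        }
    )


@dataclass(frozen=True)
class AgeAssociation:
    """OLS fit of a subject-level measure against age.

    For the quadratic model, ``vertex_age = -b / (2a)`` locates the
    extremum of the fitted parabola (the age of minimum capacity for a
    U-shaped relation); it is None for the linear model.
    """

    model: str
    coefficients: dict
    p_values: dict
    vertex_age: float | None
    r_squared: float
    n: int

    @property
    def slope(self) -> float:
        return self.coefficients["age"]

    @property
    def curvature(self) -> float | None:
        return self.coefficients.get("age_sq")


def age_association(
    values: np.ndarray,
    ages: np.ndarray,
    model: str = "linear",
) -> AgeAssociation:
    """Fit ``values ~ age`` (linear) or ``values ~ age + age^2`` (quadratic).

    Requires at least 10 subjects and a non-constant age vector.  Reports
    two-sided coefficient p-values from the OLS t-statistics.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValueError("values and ages must be equal-length 1-D arrays")
    if len(values) < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(ages) == 0:
        raise ValueError("age is constant: no association estimable")
    if model not in ("linear", "quadratic"):
        raise ValueError("model must be 'linear' or 'quadratic'")
    cols = {"age": ages}
    if model == "quadratic":
        cols["age_sq"] = ages**2
    exog = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(values, exog).fit()
    coeffs = dict(fit.params)
    pvals = dict(fit.pvalues)
    vertex = None
    if model == "quadratic" and coeffs["age_sq"] != 0:
        vertex = -coeffs["age"] / (2.0 * coeffs["age_sq"])
    return AgeAssociation(
        model=model,
        coefficients=coeffs,
        p_values=pvals,
        vertex_age=vertex,
        r_squared=float(fit.rsquared),
        n=len(values),
    )
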