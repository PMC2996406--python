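"""Per-transcript differential-expression testing.

Three routes to an ecotype test are provided:

* :func:`nested_anova` — the parametric three-way nested ANOVA for the
  balanced ecotype x transect design with biological replicates nested in
  the interaction and technical replicates as residual.  Fixed effects
  (ecotype, transect, interaction) are tested against the nested-replicate
  mean square — the standard convention when the nested factor is random —
  and the nested replicate against the technical residual.
* :func:`permutation_anova` — a randomization one-way ANOVA on
  technical-replicate-averaged values, robust to non-normality and
  heteroscedasticity.
* :func:`f_from_summary` — the equal-n two-group F statistic recovered from
  printed per-group means and standard errors, F = (m1 - m2)^2 / (se1^2 + se2^2).

Multiple testing across transcripts is corrected with the sequential
goodness-of-fit (SGoF) procedure: the observed count of p-values at or below
the nominal level is compared with its binomial expectation and the excess
smallest p-values are declared significant one at a time while the binomial
metatest stays significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix

__all__ = [
    "nested_anova",
    "permutation_anova",
    "f_from_summary",
    "sgof",
    "PermutationResult",
    "SgofResult",
]

#: Sentinel p-value reported when a zero denominator makes F infinite.
P_BELOW_MACHINE = float(np.finfo(float).tiny)


def _f_p(ss_num, df_num, ss_den, df_den):
    """Elementwise F and p with explicit degenerate handling.

    Zero denominator with a positive numerator yields F = inf and the
    below-machine p sentinel; 0/0 yields NaN (test undefined, flagged).
    """
    ms_num = ss_num / df_num
    ms_den = ss_den / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_num / ms_den
    f = np.where((ms_den == 0) & (ms_num > 0), np.inf, f)
    f = np.where((ms_den == 0) & (ms_num == 0), np.nan, f)
    p = np.full_like(ms_num, np.nan, dtype=float)
    finite = np.isfinite(f)
    p[finite] = stats.f.sf(f[finite], df_num, df_den)
    p[np.isinf(f)] = P_BELOW_MACHINE
    # p is a tail probability: clip the zero that sf returns for enormous F
    p[finite & (p < P_BELOW_MACHINE) & ~np.isnan(p)] = P_BELOW_MACHINE
    return f, p


def nested_anova(matrix: ExpressionMatrix, fill_absent: float = 50.0) -> pd.DataFrame:
    """Three-way nested ANOVA per transcript on a balanced design.

    The design must be fully crossed and balanced: 2 (or more) ecotypes x
    transects, ``r`` biological replicates per cell, ``t`` technical
    replicates per biological replicate.  Remaining absent cells (peak below
    the detection floor in every technical run) are filled with
    ``fill_absent`` — the detection-limit value, consistent with the
    partial-detection imputation rule.

    Returns one row per transcript with sums of squares, F statistics and
    p-values for ecotype, transect, interaction and nested replicate, plus
    per-ecotype means and standard errors of the technical-replicate-averaged
    intensities.
    """
    meta = matrix.samples
    for col in ("ecotype", "transect", "biological_replicate", "technical_replicate"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata lacks column {col!r}")
    ecotypes = sorted(meta["ecotype"].unique())
    transects = sorted(meta["transect"].unique())
    a, b = len(ecotypes), len(transects)
    if a < 2 or b < 2:
        raise ValueError("need at least two ecotypes and two transects")

    # order runs into a dense (a, b, r, t) grid, erroring on imbalance
    cell_bios = {}
    for (e, tr), sub in meta.groupby(["ecotype", "transect"]):
        cell_bios[(e, tr)] = sorted(sub["biological_replicate"].unique())
    r_sizes = {len(v) for v in cell_bios.values()}
    if len(cell_bios) != a * b or len(r_sizes) != 1:
        raise ValueError("unbalanced design: unequal biological replicates per cell")
    r = r_sizes.pop()
    t_sizes = set(meta.groupby("biological_replicate").size())
    if len(t_sizes) != 1:
        raise ValueError("unbalanced design: unequal technical replicates per pool")
    t = t_sizes.pop()

    cols = []
    for e in ecotypes:
        for tr in transects:
            for bio in cell_bios[(e, tr)]:
                sub = meta[meta["biological_replicate"] == bio]
                cols.extend(list(sub.sort_values("technical_replicate").index))
    n_tr = matrix.n_transcripts
    x = matrix.intensity[cols].to_numpy(dtype=float).reshape(n_tr, a, b, r, t)
    x = np.where(np.isnan(x), fill_absent, x)

    grand = x.mean(axis=(1, 2, 3, 4), keepdims=True)
    m_e = x.mean(axis=(2, 3, 4), keepdims=True)
    m_t = x.mean(axis=(1, 3, 4), keepdims=True)
    m_et = x.mean(axis=(3, 4), keepdims=True)
    m_rep = x.mean(axis=4, keepdims=True)

    ss_e = (b * r * t) * ((m_e - grand) ** 2).sum(axis=(1, 2, 3, 4))
    ss_t = (a * r * t) * ((m_t - grand) ** 2).sum(axis=(1, 2, 3, 4))
    ss_et = (r * t) * ((m_et - m_e - m_t + grand) ** 2).sum(axis=(1, 2, 3, 4))
    ss_rep = t * ((m_rep - m_et) ** 2).sum(axis=(1, 2, 3, 4))
    ss_res = ((x - m_rep) ** 2).sum(axis=(1, 2, 3, 4))
    ss_total = ((x - grand) ** 2).sum(axis=(1, 2, 3, 4))

    df_e, df_t = a - 1, b - 1
    df_et = (a - 1) * (b - 1)
    df_rep = a * b * (r - 1)
    df_res = a * b * r * (t - 1)

    f_e, p_e = _f_p(ss_e, df_e, ss_rep, df_rep)
    f_t, p_t = _f_p(ss_t, df_t, ss_rep, df_rep)
    f_et, p_et = _f_p(ss_et, df_et, ss_rep, df_rep)
    f_rep, p_rep = _f_p(ss_rep, df_rep, ss_res, df_res)

    out = pd.DataFrame(
        {
            "f_ecotype": f_e,
            "p_ecotype": p_e,
            "f_transect": f_t,
            "p_transect": p_t,
            "f_interaction": f_et,
            "p_interaction": p_et,
            "f_nested": f_rep,
            "p_nested": p_rep,
            "ss_ecotype": ss_e,
            "ss_transect": ss_t,
            "ss_interaction": ss_et,
            "ss_nested": ss_rep,
            "ss_residual": ss_res,
            "ss_total": ss_total,
        },
        index=matrix.intensity.index,
    )
    # per-ecotype summaries over the b*r technical-replicate-averaged pools
    pools = x.mean(axis=4).reshape(n_tr, a, b * r)
    for i, e in enumerate(ecotypes):
        out[f"mean_{e}"] = pools[:, i, :].mean(axis=1)
        out[f"se_{e}"] = pools[:, i, :].std(axis=1, ddof=1) / np.sqrt(b * r)
    out.index.name = "transcript_id"
    return out


@dataclass
class PermutationResult:
    """Outcome of a randomization one-way ANOVA."""

    f_observed: float
    p_perm: float
    n_permutations: int
    seed: int | None = None
    group_means: dict[str, float] = field(default_factory=dict)


def _oneway_f(values: np.ndarray, masks: list[np.ndarray]) -> float:
    grand = values.mean()
    n = len(values)
    k = len(masks)
    ssb = sum(m.sum() * (values[m].mean() - grand) ** 2 for m in masks)
    sst = ((values - grand) ** 2).sum()
    ssw = sst - ssb
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def permutation_anova(
    values,
    group_labels,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Randomization one-way ANOVA.

    ``values`` are per-biological-replicate intensities (technical replicates
    already averaged) and ``group_labels`` the ecotype of each.  The null
    distribution is built by permuting values against labels; the p-value
    uses the add-one estimator (1 + #{F_perm >= F_obs}) / (B + 1) with ties
    counted as exceeding (inclusive), so it is valid and never zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    groups = sorted(set(labels.tolist()))
    masks = [labels == g for g in groups]
    if len(groups) < 2 or any(m.sum() < 2 for m in masks):
        raise ValueError("need >= 2 groups with >= 2 values each")

    f_obs = _oneway_f(values, masks)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permuted(
        np.broadcast_to(values, (n_permutations, len(values))).copy(), axis=1
    )
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    ssb = np.zeros(n_permutations)
    for m in masks:
        ssb += m.sum() * (perm[:, m].mean(axis=1) - grand) ** 2
    ssw = sst - ssb
    k, n = len(groups), len(values)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ssb / (k - 1)) / (ssw / (n - k))
    f_perm = np.where(ssw <= 0, np.where(ssb > 0, np.inf, 0.0), f_perm)
    p = float((1 + np.sum(f_perm >= f_obs)) / (n_permutations + 1))
    return PermutationResult(
        f_observed=f_obs,
        p_perm=p,
        n_permutations=n_permutations,
        seed=seed if isinstance(seed, int) else None,
        group_means={g: float(values[m].mean()) for g, m in zip(groups, masks)},
    )


def f_from_summary(mean_1: float, se_1: float, mean_2: float, se_2: float) -> float:
    """Equal-n two-group one-way ANOVA F from group means and standard errors.

    For two groups of equal size the pooled-variance one-way F equals
    (m1 - m2)^2 / (se1^2 + se2^2) exactly.  With both standard errors zero
    the statistic is undefined and NaN is returned (flagged).
    """
    denom = se_1**2 + se_2**2
    if denom == 0:
        return float("nan")
    return float((mean_1 - mean_2) ** 2 / denom)


@dataclass
class SgofResult:
    """Outcome of the sequential goodness-of-fit multitest correction."""

    n_tests: int
    n_below_gamma: int
    gamma: float
    n_declared: int
    declared_ids: list


def sgof(p_values, gamma: float = 0.05, method: str = "binomial") -> SgofResult:
    """Sequential goodness-of-fit multiple-testing correction.

    Let R be the number of p-values at or below ``gamma`` among the n tests.
    The metatest asks whether R exceeds its expectation under the global
    null, R ~ Binomial(n, gamma).  While the one-sided metatest on the
    current count is significant at ``gamma``, one additional smallest
    p-value is declared significant and the count is decremented; n is held
    fixed across iterations.  ``method`` selects the exact binomial metatest
    (default, conservative for small n) or the asymptotic G-test used by
    some implementations.
    """
    if isinstance(p_values, pd.Series):
        ids = list(p_values.index)
        p = p_values.to_numpy(dtype=float)
    else:
        p = np.asarray(p_values, dtype=float)
        ids = list(range(len(p)))
    if len(p) == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = len(p)
    r = int(np.sum(p <= gamma))

    def meta_significant(count: int) -> bool:
        if count == 0:
            return False
        if method == "binomial":
            return stats.binom.sf(count - 1, n, gamma) <= gamma
        if method == "gtest":
            if count <= n * gamma:
                return False
            obs = np.array([count, n - count])
            exp = np.array([n * gamma, n * (1 - gamma)])
            g = 2.0 * np.sum(special.xlogy(obs, obs / exp))
            return stats.chi2.sf(g, df=1) <= gamma
        raise ValueError(f"unknown SGoF method {method!r}")

    declared = 0
    while declared < r and meta_significant(r - declared):
        declared += 1
    order = np.argsort(p, kind="stable")
    declared_ids = [ids[i] for i in order[:declared]]
    return SgofResult(
        n_tests=n,
        n_below_gamma=r,
        gamma=gamma,
        n_declared=declared,
        declared_ids=declared_ids,
    )
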