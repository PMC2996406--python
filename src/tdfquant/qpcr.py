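"""Reference-gene stability analysis and target-gene quantification.

Implements the geNorm statistics from first principles: quantification-cycle
values are transformed to relative quantities RQ = E^(Cq_min - Cq) (per-gene
minimum-Cq anchor, so each gene's maximum RQ is 1 — the anchor cancels in
every ratio-based statistic), gene stability is measured as

    M_j = mean over k != j of V_jk,
    V_jk = sd over samples of log2(RQ_j / RQ_k)    (n-1 denominator),

and the least stable gene (highest M) is excluded stepwise until two genes
remain; those two cannot be resolved by ratio-based statistics and are
reported as an unordered final pair.  Normalization factors NF_n are
per-sample geometric means of the n most stable genes' relative quantities;
the pairwise variation V_n/n+1 = sd(log2(NF_n / NF_n+1)) decides how many
reference genes are needed (threshold 0.15).  A gene with M >= 1.5 on the
full panel is flagged unsuitable for normalization.

The target gene is normalized qBase-style, NRQ_s = RQ_target,s / NF_s with
NF the geometric mean of the chosen references, and compared between
ecotypes with the randomization one-way ANOVA from
:mod:`tdfquant.anova`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import PermutationResult, permutation_anova
from .io import CqTable

__all__ = [
    "RqMatrix",
    "StabilityReport",
    "NormalizedExpression",
    "QpcrDeResult",
    "cq_to_rq",
    "pairwise_variation",
    "stability_m",
    "genorm_ranking",
    "nf_pairwise_variation",
    "normalize_target",
    "qpcr_de",
    "technical_reproducibility",
]

M_UNSUITABLE = 1.5
V_THRESHOLD = 0.15


@dataclass
class RqMatrix:
    """Genes x samples relative quantities (all > 0 where observed)."""

    rq: pd.DataFrame
    efficiency: pd.Series
    anchor_cq: pd.Series  # per-gene minimum Cq used as anchor
    ecotype: pd.Series | None = None


@dataclass
class StabilityReport:
    """Stepwise geNorm stability analysis of a reference-gene panel."""

    exclusion_order: list[str]  # least stable first
    m_steps: list[dict[str, float]]  # per-step M values of the remaining set
    final_pair: tuple[str, str]  # unordered: ranks tied
    stability_order: list[str]  # most stable first (final pair first, tied)
    unsuitable: list[str] = field(default_factory=list)  # full-panel M >= 1.5
    v_series: dict[str, float] = field(default_factory=dict)  # "V2/3" -> value
    recommended_n: int | None = None
    threshold_m: float = M_UNSUITABLE
    threshold_v: float = V_THRESHOLD


def cq_to_rq(cq: CqTable) -> RqMatrix:
    """Transform Cq values to relative quantities, RQ = E^(min Cq - Cq).

    The per-gene minimum observed Cq anchors the transform (max RQ = 1).
    Missing Cq values stay missing; downstream statistics use
    pairwise-complete samples.
    """
    anchor = cq.cq.min(axis=1, skipna=True)
    if cq.n_missing:
        warnings.warn(
            f"{cq.n_missing} missing Cq value(s); affected samples are used "
            "pairwise-complete downstream",
            stacklevel=2,
        )
    delta = anchor.to_numpy()[:, None] - cq.cq.to_numpy(dtype=float)
    rq = pd.DataFrame(
        np.power(cq.efficiency.to_numpy()[:, None], delta),
        index=cq.cq.index,
        columns=cq.cq.columns,
    )
    return RqMatrix(
        rq=rq,
        efficiency=cq.efficiency.copy(),
        anchor_cq=anchor,
        ecotype=None if cq.ecotype is None else cq.ecotype.copy(),
    )


def pairwise_variation(rq_j, rq_k) -> float:
    """geNorm pairwise variation V_jk: sd of log2 expression ratios."""
    a = pd.Series(rq_j).astype(float)
    b = pd.Series(rq_k).astype(float)
    mask = a.notna() & b.notna()
    if mask.sum() < 2:
        raise ValueError("pairwise variation needs at least 2 shared samples")
    if (a[mask] <= 0).any() or (b[mask] <= 0).any():
        raise ValueError("relative quantities must be positive")
    ratios = np.log2(a[mask].to_numpy() / b[mask].to_numpy())
    return float(np.std(ratios, ddof=1))


def stability_m(rq: RqMatrix | pd.DataFrame, gene_set=None) -> pd.Series:
    """Per-gene stability M: mean pairwise variation against the other genes."""
    frame = rq.rq if isinstance(rq, RqMatrix) else rq
    genes = list(frame.index if gene_set is None else gene_set)
    if len(genes) < 2:
        raise ValueError("stability M needs at least two genes")
    m = {}
    for g in genes:
        m[g] = float(
            np.mean([pairwise_variation(frame.loc[g], frame.loc[k]) for k in genes if k != g])
        )
    return pd.Series(m, name="M")


def genorm_ranking(rq: RqMatrix | pd.DataFrame) -> StabilityReport:
    """Rank reference genes by stepwise exclusion of the least stable gene.

    Exactly G - 2 exclusions are performed; the last two genes cannot be
    resolved (their M values are identical by construction) and are reported
    as an unordered final pair.  Ties in the highest M are broken by gene
    name for determinism.
    """
    frame = rq.rq if isinstance(rq, RqMatrix) else rq
    genes = list(frame.index)
    if len(genes) < 2:
        raise ValueError("need at least two reference genes")
    m_full = stability_m(frame, genes)
    unsuitable = sorted(m_full[m_full >= M_UNSUITABLE].index)
    exclusion: list[str] = []
    steps: list[dict[str, float]] = []
    current = list(genes)
    while True:
        m = stability_m(frame, current)
        steps.append({g: float(m[g]) for g in current})
        if len(current) == 2:
            break
        worst = max(current, key=lambda g: (m[g], g))
        exclusion.append(worst)
        current.remove(worst)
    final_pair = tuple(sorted(current))
    return StabilityReport(
        exclusion_order=exclusion,
        m_steps=steps,
        final_pair=final_pair,  # type: ignore[arg-type]
        stability_order=[*final_pair, *reversed(exclusion)],
        unsuitable=unsuitable,
    )


def _geometric_mean(frame: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean over genes; NaN where any gene is missing."""
    return np.exp2(np.log2(frame.astype(float)).mean(axis=0, skipna=False))


def nf_pairwise_variation(
    rq: RqMatrix | pd.DataFrame, ranking: StabilityReport
) -> StabilityReport:
    """Pairwise variation V_n/n+1 between sequential normalization factors.

    NF_n is the per-sample geometric mean of the n most stable genes'
    relative quantities; V_n/n+1 = sd over samples of log2(NF_n / NF_n+1),
    computed on samples where all n+1 genes are observed.  The recommended
    reference count is the smallest n with V_n/n+1 below 0.15; when no V
    meets the threshold all genes are recommended, with a warning.
    """
    frame = rq.rq if isinstance(rq, RqMatrix) else rq
    order = ranking.stability_order
    g = len(order)
    if g < 3:
        raise ValueError("V series needs at least three ranked genes")
    v_series: dict[str, float] = {}
    recommended = None
    for n in range(2, g):
        nf_n = _geometric_mean(frame.loc[order[:n]])
        nf_n1 = _geometric_mean(frame.loc[order[: n + 1]])
        mask = nf_n.notna() & nf_n1.notna()
        if mask.sum() < 2:
            raise ValueError("V_n/n+1 needs at least 2 complete samples")
        ratios = np.log2(nf_n[mask].to_numpy() / nf_n1[mask].to_numpy())
        v = float(np.std(ratios, ddof=1))
        v_series[f"V{n}/{n + 1}"] = v
        if recommended is None and v < ranking.threshold_v:
            recommended = n
    if recommended is None:
        recommended = g
        warnings.warn(
            f"no V_n/n+1 below {ranking.threshold_v}; using all {g} reference genes",
            stacklevel=2,
        )
    ranking.v_series = v_series
    ranking.recommended_n = recommended
    return ranking


@dataclass
class NormalizedExpression:
    """Per-sample normalized relative quantity of the target gene."""

    nrq: pd.Series
    reference_genes: list[str]
    ecotype: pd.Series | None = None


def normalize_target(rq_target, rq_refs, ecotype=None) -> NormalizedExpression:
    """qBase-style normalization: NRQ_s = RQ_target,s / geomean_refs(RQ_ref,s)."""
    target = pd.Series(rq_target).astype(float)
    refs = rq_refs.rq if isinstance(rq_refs, RqMatrix) else pd.DataFrame(rq_refs)
    if refs.shape[0] == 0:
        raise ValueError("reference set is empty")
    refs = refs[target.index]
    if (refs.to_numpy(dtype=float) <= 0).any():
        raise ValueError("reference relative quantities must be positive")
    nf = _geometric_mean(refs)
    nrq = target / nf
    return NormalizedExpression(
        nrq=nrq,
        reference_genes=list(refs.index),
        ecotype=None if ecotype is None else pd.Series(ecotype)[target.index],
    )


@dataclass
class QpcrDeResult:
    """Ecotype comparison of normalized target-gene expression."""

    permutation: PermutationResult
    higher_in: str
    geometric_means: dict[str, float]
    ratio: float  # geometric-mean NRQ ratio, second group / first group


def qpcr_de(
    norm: NormalizedExpression,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> QpcrDeResult:
    """Randomization one-way ANOVA of normalized expression between ecotypes."""
    if norm.ecotype is None:
        raise ValueError("normalized expression carries no ecotype labels")
    values = norm.nrq.to_numpy(dtype=float)
    labels = norm.ecotype.to_numpy()
    perm = permutation_anova(values, labels, n_permutations=n_permutations, seed=seed)
    groups = sorted(set(labels.tolist()))
    gm = {
        g: float(np.exp2(np.log2(values[labels == g]).mean())) for g in groups
    }
    higher = max(gm, key=lambda g: gm[g])
    ratio = gm[groups[1]] / gm[groups[0]] if len(groups) == 2 else float("nan")
    return QpcrDeResult(
        permutation=perm, higher_in=higher, geometric_means=gm, ratio=ratio
    )


@dataclass
class ReproducibilityResult:
    r: float
    p_perm: float
    n_samples: int
    n_permutations: int


def technical_reproducibility(
    cq_day1: CqTable,
    cq_day2: CqTable,
    gene: str,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> ReproducibilityResult:
    """Between-day reproducibility of raw Cq values for one gene.

    Pearson correlation between the two runs over shared samples, with a
    randomization p-value obtained by permuting one run's values (add-one
    estimator, one-sided on positive correlation).
    """
    x = cq_day1.cq.loc[gene]
    y = cq_day2.cq.loc[gene]
    shared = [s for s in x.index if s in y.index]
    xv = x[shared].to_numpy(dtype=float)
    yv = y[shared].to_numpy(dtype=float)
    mask = ~np.isnan(xv) & ~np.isnan(yv)
    if mask.sum() < 3:
        raise ValueError("need at least 3 shared samples")
    xv, yv = xv[mask], yv[mask]
    r = float(stats.pearsonr(xv, yv).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if np.corrcoef(xv, rng.permutation(yv))[0, 1] >= r:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return ReproducibilityResult(
        r=r, p_perm=float(p), n_samples=int(mask.sum()), n_permutations=n_permutations
    )
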