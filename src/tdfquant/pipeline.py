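"""End-to-end convenience wrappers over the module-level operations."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import anova, peaks, qpcr
from .io import CqTable, PeakRecord, SampleMeta
from .matrix import ExpressionMatrix


@dataclass
class AflpAnalysis:
    """Everything the fingerprint pipeline produces, in order of derivation."""

    matrix_runs: ExpressionMatrix  # normalized, shared transcripts, per run
    matrix_pools: ExpressionMatrix  # technical replicates imputed + averaged
    reproducibility: peaks.ReproducibilityReport
    anova: pd.DataFrame
    permutation: pd.DataFrame  # per-transcript randomization ANOVA
    sgof: anova.SgofResult
    n_peaks_raw: int
    n_peaks_filtered: int
    n_transcripts_binned: int


def analyze_aflp(
    peak_records: list[PeakRecord],
    samples: list[SampleMeta],
    min_rfu: float = 50.0,
    size_min: float = 75.0,
    size_max: float = 500.0,
    bin_tolerance: float = 2.0,
    presence_fraction: float = 0.90,
    floor: float = 50.0,
    n_permutations: int = 10000,
    gamma: float = 0.05,
    seed: int | None = None,
) -> AflpAnalysis:
    """Run the full fingerprint analysis: filter, bin, normalize, select
    shared transcripts, score reproducibility, nested ANOVA, randomization
    ANOVA on pool averages, and SGoF correction of the ecotype p-values."""
    filtered = peaks.filter_peaks(peak_records, min_rfu, size_min, size_max)
    binned = peaks.bin_peaks(filtered, samples, tolerance=bin_tolerance)
    normalized = peaks.normalize_sum_of_signal(binned)
    shared = peaks.select_shared_transcripts(normalized, presence_fraction)
    repro = peaks.reproducibility(shared)
    pools = peaks.impute_and_average_technical(shared, floor=floor)
    nested = anova.nested_anova(shared, fill_absent=floor)

    import numpy as np

    rng = np.random.default_rng(seed)
    labels = pools.samples["ecotype"].to_numpy()
    rows = []
    for tid in pools.intensity.index:
        vals = pools.intensity.loc[tid].to_numpy(dtype=float)
        vals = np.where(np.isnan(vals), floor, vals)
        res = anova.permutation_anova(vals, labels, n_permutations=n_permutations, seed=rng)
        rows.append({"transcript_id": tid, "f_perm": res.f_observed, "p_perm": res.p_perm})
    perm = pd.DataFrame(rows).set_index("transcript_id")
    corrected = anova.sgof(nested["p_ecotype"], gamma=gamma)
    return AflpAnalysis(
        matrix_runs=shared,
        matrix_pools=pools,
        reproducibility=repro,
        anova=nested,
        permutation=perm,
        sgof=corrected,
        n_peaks_raw=len(peak_records),
        n_peaks_filtered=len(filtered),
        n_transcripts_binned=binned.n_transcripts,
    )


@dataclass
class QpcrAnalysis:
    stability: qpcr.StabilityReport
    normalized: qpcr.NormalizedExpression
    de: qpcr.QpcrDeResult


def analyze_qpcr(
    cq: CqTable,
    goi: str,
    references: list[str] | None = None,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> QpcrAnalysis:
    """Reference-gene validation plus target-gene ecotype comparison.

    When ``references`` is None the panel (all genes except ``goi``) is
    ranked with geNorm and the recommended number of most stable genes is
    used for normalization.
    """
    panel = [g for g in cq.genes if g != goi]
    rq = qpcr.cq_to_rq(cq)
    panel_rq = rq.rq.loc[panel]
    report = qpcr.genorm_ranking(panel_rq)
    if len(panel) >= 3:
        report = qpcr.nf_pairwise_variation(panel_rq, report)
    if references is None:
        n = report.recommended_n or 2
        references = report.stability_order[:n]
    norm = qpcr.normalize_target(
        rq.rq.loc[goi], rq.rq.loc[references], ecotype=rq.ecotype
    )
    de = qpcr.qpcr_de(norm, n_permutations=n_permutations, seed=seed)
    return QpcrAnalysis(stability=report, normalized=norm, de=de)
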