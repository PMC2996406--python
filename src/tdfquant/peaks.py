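"""From raw electropherogram peaks to a normalized expression matrix.

Implements the fingerprint-processing chain: detection-floor and sizing-range
filtering, +/-2 bp fragment binning into transcripts, sum-of-signal
normalization, the shared-presence cut-off, technical-replicate imputation
and averaging, and the presence/absence and quantitative reproducibility
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PeakRecord, SampleMeta, samples_frame
from .matrix import ExpressionMatrix

__all__ = [
    "filter_peaks",
    "bin_peaks",
    "normalize_sum_of_signal",
    "select_shared_transcripts",
    "impute_and_average_technical",
    "simple_matching",
    "reproducibility",
    "ReproducibilityReport",
]


def filter_peaks(
    peaks: list[PeakRecord],
    min_rfu: float = 50.0,
    size_min: float = 75.0,
    size_max: float = 500.0,
) -> list[PeakRecord]:
    """Keep peaks with height >= ``min_rfu`` and size in [size_min, size_max].

    Both bounds are inclusive; a 49.9 RFU peak is background noise, a 50.0
    RFU peak at 75.0 bp is a valid fragment.
    """
    return [
        p
        for p in peaks
        if p.height >= min_rfu and size_min <= p.size <= size_max
    ]


def _bin_sizes(sorted_sizes: np.ndarray, tolerance: float) -> np.ndarray:
    """Single-linkage chain binning: a new bin starts wherever the gap
    between consecutive sorted sizes exceeds ``tolerance``."""
    if len(sorted_sizes) == 0:
        return np.empty(0, dtype=int)
    gaps = np.diff(sorted_sizes)
    return np.concatenate([[0], np.cumsum(gaps > tolerance)])


def bin_peaks(
    peaks: list[PeakRecord],
    samples: list[SampleMeta],
    tolerance: float = 2.0,
) -> ExpressionMatrix:
    """Bin peak sizes into transcripts, independently per primer combination.

    Peaks from different runs within +/-``tolerance`` bp of each other (by
    single-linkage chaining over the sorted sizes) are treated as the same
    transcript-derived fragment; within one run, peaks collapsing into the
    same bin keep the taller height.  The representative size of a bin is the
    median of its member sizes.  The result is order-independent: peaks are
    canonically sorted before binning.
    """
    meta = samples_frame(samples)
    known = set(meta.index)
    for p in peaks:
        if p.sample_id not in known:
            raise ValueError(f"peak sample {p.sample_id!r} not in the sample sheet")

    by_combo: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_combo.setdefault(p.primer_combo, []).append(p)

    records = []  # (transcript_id, primer_combo, rep_size)
    cells: dict[tuple[str, str], float] = {}
    used_ids: dict[str, int] = {}
    for combo in sorted(by_combo):
        plist = sorted(by_combo[combo], key=lambda p: (p.size, p.sample_id, -p.height))
        sizes = np.array([p.size for p in plist])
        bins = _bin_sizes(sizes, tolerance)
        for b in range(bins.max() + 1 if len(bins) else 0):
            members = [p for p, lab in zip(plist, bins) if lab == b]
            rep = float(np.median([p.size for p in members]))
            tid = f"{combo}@{rep:.2f}"
            k = used_ids.get(tid, 0)
            used_ids[tid] = k + 1
            if k:  # two bins share the same median size label
                tid = f"{tid}.{k}"
            records.append((tid, combo, rep))
            for p in members:
                key = (tid, p.sample_id)
                if key not in cells or p.height > cells[key]:
                    cells[key] = p.height

    tids = [r[0] for r in records]

    intensity = pd.DataFrame(np.nan, index=tids, columns=list(meta.index))
    for (tid, sid), h in cells.items():
        intensity.at[tid, sid] = h
    transcripts = pd.DataFrame(
        {"primer_combo": [r[1] for r in records], "size": [r[2] for r in records]},
        index=tids,
    )
    order = transcripts.sort_values(["primer_combo", "size"]).index
    return ExpressionMatrix(
        intensity=intensity.loc[order],
        samples=meta,
        transcripts=transcripts.loc[order],
    )


def normalize_sum_of_signal(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Sum-of-signal normalization against the grand mean total.

    Each run's intensities are rescaled so its total signal equals the grand
    mean of per-run totals.  The normalization target is an arbitrary
    positive constant as far as downstream F statistics are concerned (they
    are invariant to a common rescaling); the grand mean keeps values on the
    familiar RFU scale and conserves the grand total signal.
    """
    totals = matrix.intensity.sum(axis=0, skipna=True)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total signal")
    target = totals.mean()
    scaled = matrix.intensity * (target / totals)
    return ExpressionMatrix(scaled, matrix.samples.copy(), matrix.transcripts.copy())


def select_shared_transcripts(
    matrix: ExpressionMatrix, min_fraction: float = 0.90
) -> ExpressionMatrix:
    """Keep transcripts present in at least ``ceil(min_fraction * n_runs)``
    sample runs, counting biological and technical replicates together."""
    need = math.ceil(min_fraction * matrix.n_samples)
    counts = matrix.presence.sum(axis=1)
    keep = counts[counts >= need].index
    return matrix.subset_transcripts(keep)


def impute_and_average_technical(
    matrix: ExpressionMatrix,
    floor: float = 50.0,
    expected_tech: int | None = 2,
) -> ExpressionMatrix:
    """Collapse technical replicates into one column per biological replicate.

    Per biological replicate and transcript: if the peak is present in every
    technical run, take the mean; if present in some but not all, substitute
    the detection-floor value for the missing runs and take the mean; if
    absent everywhere, the transcript stays absent for that replicate (no
    imputation — the floor substitution only covers the partially-detected
    case).

    ``expected_tech`` enforces the number of technical replicates per
    biological replicate (None disables the check).
    """
    meta = matrix.samples
    if "technical_replicate" not in meta.columns:
        raise ValueError("matrix already collapsed: no technical_replicate column")
    groups = meta.groupby("biological_replicate", sort=False)
    bio_ids, columns = [], []
    for bio_id, sub in groups:
        if expected_tech is not None and len(sub) != expected_tech:
            raise ValueError(
                f"biological replicate {bio_id!r} has {len(sub)} technical "
                f"replicates, expected {expected_tech}"
            )
        bio_ids.append(bio_id)
        columns.append(list(sub.index))

    vals = matrix.intensity.to_numpy(dtype=float)
    out = np.full((vals.shape[0], len(bio_ids)), np.nan)
    col_index = {c: i for i, c in enumerate(matrix.intensity.columns)}
    for j, cols in enumerate(columns):
        block = vals[:, [col_index[c] for c in cols]]
        any_present = ~np.all(np.isnan(block), axis=1)
        filled = np.where(np.isnan(block), floor, block)
        out[any_present, j] = filled[any_present].mean(axis=1)

    new_samples = (
        meta.drop(columns=["technical_replicate"])
        .groupby("biological_replicate", sort=False)
        .first()
        .loc[bio_ids]
    )
    new_samples.index.name = "sample_id"
    intensity = pd.DataFrame(out, index=matrix.intensity.index, columns=bio_ids)
    return ExpressionMatrix(intensity, new_samples, matrix.transcripts.copy())


def simple_matching(profile_a, profile_b) -> float:
    """Simple-matching coefficient of two presence/absence profiles:
    (both present + both absent) / length.  Symmetric, in [0, 1]."""
    a = np.asarray(profile_a, dtype=bool)
    b = np.asarray(profile_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("profiles must be equal-length non-empty vectors")
    return float((a == b).mean())


@dataclass
class ReproducibilityReport:
    """Mean technical-replicate agreement across all replicate pairs."""

    per_pair: pd.DataFrame  # index = biological replicate id
    simple_matching_mean: float
    pearson_mean: float
    n_pairs: int


def reproducibility(
    matrix: ExpressionMatrix,
    n_permutations: int = 0,
    seed: int | None = None,
) -> ReproducibilityReport:
    """Technical-replicate reproducibility of a fingerprint matrix.

    For every pair of technical runs of the same biological replicate the
    simple-matching coefficient is computed on the presence profiles and the
    Pearson correlation on the intensities of jointly present transcripts
    (absent is not zero in fingerprint data, so absent cells are excluded).
    Pairs with fewer than three jointly present transcripts get a NaN Pearson
    value and are excluded from the mean.  With ``n_permutations`` > 0 a
    randomization p-value for each pair's Pearson coefficient is added
    (permuting one profile, add-one estimator).
    """
    meta = matrix.samples
    if "technical_replicate" not in meta.columns:
        raise ValueError("matrix has no technical replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for bio_id, sub in meta.groupby("biological_replicate", sort=False):
        if len(sub) != 2:
            continue
        s1, s2 = list(sub.index)
        x = matrix.intensity[s1].to_numpy(dtype=float)
        y = matrix.intensity[s2].to_numpy(dtype=float)
        px, py = ~np.isnan(x), ~np.isnan(y)
        sm = simple_matching(px, py)
        joint = px & py
        r = np.nan
        p_perm = np.nan
        if joint.sum() >= 3:
            xj, yj = x[joint], y[joint]
            if np.ptp(xj) == 0 or np.ptp(yj) == 0:
                r = np.nan  # constant profile: correlation undefined
            else:
                r = float(stats.pearsonr(xj, yj).statistic)
                if n_permutations > 0:
                    null = np.empty(n_permutations)
                    for k in range(n_permutations):
                        null[k] = np.corrcoef(xj, rng.permutation(yj))[0, 1]
                    p_perm = (1 + np.sum(null >= r)) / (n_permutations + 1)
        rows.append(
            {
                "biological_replicate": bio_id,
                "simple_matching": sm,
                "pearson": r,
                "n_joint": int(joint.sum()),
                "p_perm": p_perm,
            }
        )
    if not rows:
        raise ValueError("no technical-replicate pairs in the sample metadata")
    per_pair = pd.DataFrame(rows).set_index("biological_replicate")
    return ReproducibilityReport(
        per_pair=per_pair,
        simple_matching_mean=float(per_pair["simple_matching"].mean()),
        pearson_mean=float(per_pair["pearson"].mean(skipna=True)),
        n_pairs=len(per_pair),
    )
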