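"""Synthetic AFLP fingerprints and qPCR Cq tables with known ground truth.

The AFLP generator emulates the two-ecotype shore-transect design: 2 ecotypes
(RB upper shore, SU lower shore) x 2 transects x 8 pooled biological
replicates x 2 technical replicates, with ~100 transcript-derived fragments
per primer combination in the 75-500 bp sizing window and a 50 RFU detection
floor.  Peak heights follow a log-normal intensity model

    log2(RFU) = baseline_t + effect_t * 1[SU] + b_bio + eps_tech,

with b ~ N(0, sd_bio^2) shared by the two technical runs of a pool and
eps ~ N(0, sd_tech^2) per run.  A peak whose realized height falls below the
detection floor is absent from the table (hard truncation, not clipping),
mirroring how sub-threshold peaks are treated as absent in fingerprint data.

Default variance components (sd_bio = 0.6, sd_tech = 0.5, log2 units) are
calibrated so that 2-4x ecotype effects are reliably detectable with 16
pools per ecotype and that pools cluster by ecotype — the regime the
fingerprint analysis assumes.  They imply a per-pool coefficient of
variation near 0.5 and technical-replicate Pearson correlations around
0.85-0.9, somewhat cleaner than the noisiest published fingerprint data.
Differential transcripts get a 2-4x fold change (|log2 FC| ~ 1.5), with 3 of
4 up-regulated in SU, matching the typically reported direction ratio.

The qPCR generator inverts the relative-quantity transform:

    Cq_gs = a_g - (log2 Q_s + f_gs + goi effect) / log2(E) + N(0, cq_noise_sd^2)

where Q_s is a per-sample loading factor common to all genes (it cancels in
every within-sample gene ratio) and f_gs gene-specific instability noise —
small for engineered-stable reference genes, large for unstable ones.

Randomness uses a documented stream-splitting scheme: one ``SeedSequence``
per simulation is split into a truth stream (baselines, effect assignment,
fragment sizes) and one stream per biological replicate, from which
per-run technical streams are drawn.  Output is therefore reproducible and
independent of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqTable, PeakRecord, SampleMeta

__all__ = [
    "AflpSimConfig",
    "QpcrSimConfig",
    "SimTruth",
    "simulate_aflp",
    "simulate_cq",
    "match_truth_transcripts",
]


@dataclass
class SimTruth:
    """Ground truth of a simulation, for parameter-recovery testing."""

    de_transcripts: dict[str, float] = field(default_factory=dict)  # id -> log2 effect (SU-RB)
    stable_gene_ids: list[str] = field(default_factory=list)
    goi_true_fold_change: float = 1.0


@dataclass
class AflpSimConfig:
    """Configuration of the AFLP fingerprint generator.

    All noise terms are log2-scale standard deviations; ``detection_floor``
    is in RFU and ``size_jitter_sd`` in bp.
    """

    n_transcripts: int = 99
    frac_de: float = 12 / 99
    log2_fold_change: float = 1.5
    frac_up_in_su: float = 0.75
    sd_bio: float = 0.6
    sd_tech: float = 0.5
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.5
    size_jitter_sd: float = 0.15
    detection_floor: float = 50.0
    size_min: float = 75.0
    size_max: float = 500.0
    n_primer_combos: int = 1
    ecotypes: tuple[str, str] = ("RB", "SU")
    n_transects: int = 2
    n_bio_per_cell: int = 8
    n_tech: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.sd_bio < 0 or self.sd_tech < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be positive")
        if self.n_transcripts < 1:
            raise ValueError("need at least one transcript")
        n_samples = len(self.ecotypes) * self.n_transects * self.n_bio_per_cell * self.n_tech
        if n_samples < 2:
            raise ValueError("design must contain at least 2 sample runs")


@dataclass
class QpcrSimConfig:
    """Configuration of the Cq-table generator (noise sds in log2 units,
    cq_noise_sd in cycles)."""

    n_ref_stable: int = 4
    n_ref_unstable: int = 2
    ref_stable_sd: float = 0.05
    ref_unstable_sd: float = 0.5
    goi_log2_fold_change: float = 1.0
    cq_noise_sd: float = 0.2
    loading_sd_log2: float = 0.5
    n_bio_per_ecotype: int = 9
    efficiency: float = 2.0
    ecotypes: tuple[str, str] = ("RB", "SU")
    goi_name: str = "GOI"
    seed: int = 0

    def validate(self) -> None:
        if self.n_ref_stable + self.n_ref_unstable < 2:
            raise ValueError("need at least two reference genes")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be non-negative")
        if self.n_bio_per_ecotype < 2:
            raise ValueError("need at least 2 biological replicates per ecotype")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")


def _true_sizes(n: int, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Well-separated true fragment sizes (>= 4 bp apart) so that binning at
    +/-2 bp cannot merge distinct transcripts."""
    grid = np.arange(lo + 2.0, hi - 2.0, 4.0)
    if n > len(grid):
        raise ValueError(
            f"cannot place {n} transcripts >=4 bp apart in [{lo}, {hi}]"
        )
    return np.sort(rng.choice(grid, size=n, replace=False))


def simulate_aflp(
    config: AflpSimConfig,
) -> tuple[list[PeakRecord], list[SampleMeta], SimTruth]:
    """Simulate peak tables for the full replicate design.

    Returns peak records (only peaks at or above the detection floor),
    sample metadata, and the ground truth (identifiers and signed log2
    effects of the truly differential transcripts).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_bio_total = len(config.ecotypes) * config.n_transects * config.n_bio_per_cell
    truth_ss, *bio_ss = root.spawn(1 + n_bio_total)
    truth_rng = np.random.default_rng(truth_ss)

    n = config.n_transcripts
    combos = [f"pc{i + 1:02d}" for i in range(config.n_primer_combos)]
    combo_of = np.array([i % config.n_primer_combos for i in range(n)])
    sizes_per_combo = {
        c: _true_sizes(int((combo_of == i).sum()), config.size_min, config.size_max, truth_rng)
        for i, c in enumerate(combos)
    }
    true_size = np.empty(n)
    primer = np.empty(n, dtype=object)
    for i, c in enumerate(combos):
        idx = np.where(combo_of == i)[0]
        true_size[idx] = sizes_per_combo[c]
        primer[idx] = c
    tids = [f"{primer[i]}@{true_size[i]:.1f}" for i in range(n)]

    baseline = truth_rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    n_de = int(round(config.frac_de * n))
    de_idx = truth_rng.choice(n, size=n_de, replace=False)
    signs = np.where(truth_rng.random(n_de) < config.frac_up_in_su, 1.0, -1.0)
    effects = np.zeros(n)
    effects[de_idx] = signs * config.log2_fold_change
    truth = SimTruth(
        de_transcripts={tids[i]: float(effects[i]) for i in sorted(de_idx)},
    )

    peaks: list[PeakRecord] = []
    samples: list[SampleMeta] = []
    bio_counter = 0
    for ecotype in config.ecotypes:
        is_su = ecotype == config.ecotypes[1]
        for transect in range(1, config.n_transects + 1):
            for bio in range(1, config.n_bio_per_cell + 1):
                bio_id = f"{ecotype}{transect}b{bio}"
                bio_rng = np.random.default_rng(bio_ss[bio_counter])
                bio_counter += 1
                b = bio_rng.normal(0.0, config.sd_bio, size=n) if config.sd_bio else np.zeros(n)
                for tech in range(1, config.n_tech + 1):
                    sid = f"{bio_id}t{tech}"
                    samples.append(
                        SampleMeta(
                            sample_id=sid,
                            ecotype=ecotype,
                            transect=str(transect),
                            biological_replicate=bio_id,
                            technical_replicate=str(tech),
                        )
                    )
                    eps = (
                        bio_rng.normal(0.0, config.sd_tech, size=n)
                        if config.sd_tech
                        else np.zeros(n)
                    )
                    log2h = baseline + effects * float(is_su) + b + eps
                    height = np.exp2(log2h)
                    jitter = (
                        bio_rng.normal(0.0, config.size_jitter_sd, size=n)
                        if config.size_jitter_sd
                        else np.zeros(n)
                    )
                    size = true_size + jitter
                    detected = height >= config.detection_floor
                    for i in np.where(detected)[0]:
                        peaks.append(
                            PeakRecord(
                                sample_id=sid,
                                primer_combo=str(primer[i]),
                                size=float(size[i]),
                                height=float(height[i]),
                            )
                        )
    return peaks, samples, truth


def match_truth_transcripts(matrix, truth: SimTruth, tolerance: float = 2.0) -> dict[str, str]:
    """Map simulated-truth transcript ids to binned matrix transcript ids.

    Truth ids encode the primer combination and the true fragment size
    (``pc01@85.0``); binned ids carry the median observed size, which differs
    by the sizing jitter.  A truth transcript matches the matrix transcript
    of the same primer combination whose representative size is nearest and
    within ``tolerance`` bp.  Unmatched truth ids (transcript filtered out)
    are omitted.
    """
    mapping: dict[str, str] = {}
    info = matrix.transcripts
    for truth_id in truth.de_transcripts:
        combo, size_s = truth_id.rsplit("@", 1)
        size = float(size_s)
        cand = info[info["primer_combo"] == combo]
        if cand.empty:
            continue
        diffs = (cand["size"] - size).abs()
        best = diffs.idxmin()
        if diffs[best] <= tolerance:
            mapping[truth_id] = best
    return mapping


def simulate_cq(config: QpcrSimConfig) -> tuple[CqTable, SimTruth]:
    """Simulate a reference-panel + target-gene Cq table.

    Gene order: stable references, unstable references, then the gene of
    interest (``config.goi_name``).  Sample ids are ``<ecotype>_<k>``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    truth_ss, noise_ss = root.spawn(2)
    truth_rng = np.random.default_rng(truth_ss)
    rng = np.random.default_rng(noise_ss)

    stable = [f"REFS{i + 1}" for i in range(config.n_ref_stable)]
    unstable = [f"REFU{i + 1}" for i in range(config.n_ref_unstable)]
    genes = stable + unstable + [config.goi_name]
    n_genes = len(genes)
    samples = [
        f"{eco}_{k + 1}"
        for eco in config.ecotypes
        for k in range(config.n_bio_per_ecotype)
    ]
    n_samples = len(samples)
    is_su = np.array([s.startswith(config.ecotypes[1]) for s in samples], dtype=float)

    a = truth_rng.uniform(18.0, 26.0, size=n_genes)  # per-gene base Cq
    log2_q = (
        rng.normal(0.0, config.loading_sd_log2, size=n_samples)
        if config.loading_sd_log2
        else np.zeros(n_samples)
    )
    f_sd = np.array(
        [config.ref_stable_sd] * len(stable)
        + [config.ref_unstable_sd] * len(unstable)
        + [0.0]
    )
    f = rng.normal(0.0, 1.0, size=(n_genes, n_samples)) * f_sd[:, None]
    effect = np.zeros((n_genes, n_samples))
    effect[-1] = config.goi_log2_fold_change * is_su
    log2_e = np.log2(config.efficiency)
    noise = (
        rng.normal(0.0, config.cq_noise_sd, size=(n_genes, n_samples))
        if config.cq_noise_sd
        else np.zeros((n_genes, n_samples))
    )
    cq = a[:, None] - (log2_q[None, :] + f + effect) / log2_e + noise

    table = CqTable(
        cq=pd.DataFrame(cq, index=genes, columns=samples),
        efficiency=pd.Series(config.efficiency, index=genes),
        ecotype=pd.Series(
            [config.ecotypes[1] if s else config.ecotypes[0] for s in is_su],
            index=samples,
        ),
    )
    truth = SimTruth(
        stable_gene_ids=stable,
        goi_true_fold_change=float(2.0 ** config.goi_log2_fold_change),
    )
    return table, truth
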