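"""Readers and writers for peak tables, sample sheets, Cq tables and results.

All downstream modules consume only the typed objects defined here (plus
:class:`~tdfquant.matrix.ExpressionMatrix`).  Input tables are plain CSV/TSV
with canonical headers; a small aliasing map accepts the most common
GeneMapper-style export column names.  Missing values must be encoded as an
empty cell or ``NA`` — nothing else is recognised, to avoid locale ambiguity.

Writers are deterministic: identical inputs produce byte-identical files
(stable key ordering, fixed float formatting).  TSV floats are written with
12 significant digits so that read/write round-trips are lossless to better
than 1e-9 relative; JSON keeps full ``repr`` precision.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "PeakRecord",
    "SampleMeta",
    "CqTable",
    "TableFormatError",
    "TableParseError",
    "read_peak_table",
    "read_sample_sheet",
    "read_cq_table",
    "read_expression_matrix",
    "write_results",
    "design_summary",
    "samples_frame",
]

MISSING_TOKENS = {"", "NA"}

#: Accepted aliases for the canonical peak-table headers.
PEAK_COLUMN_ALIASES = {
    "sample": "sample_id",
    "sample file": "sample_id",
    "sample file name": "sample_id",
    "sample_file": "sample_id",
    "marker": "primer_combo",
    "panel": "primer_combo",
    "primer_combination": "primer_combo",
    "primer combination": "primer_combo",
    "size_bp": "size",
    "fragment_size": "size",
    "peak_height": "height",
    "height_rfu": "height",
    "rfu": "height",
}


class TableFormatError(ValueError):
    """A table is structurally wrong (missing column, duplicate id, ...)."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


@dataclass(frozen=True)
class PeakRecord:
    """One detected electropherogram peak.

    ``size`` is the called fragment length in base pairs (fractional values
    allowed — capillary sizing is sub-bp) and ``height`` the fluorescence
    signal in RFU.
    """

    sample_id: str
    primer_combo: str
    size: float
    height: float

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"peak size must be positive, got {self.size}")
        if self.height < 0:
            raise ValueError(f"peak height must be non-negative, got {self.height}")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one electrophoresis run (= one technical replicate)."""

    sample_id: str
    ecotype: str
    transect: str
    biological_replicate: str
    technical_replicate: str


@dataclass
class CqTable:
    """Genes x samples quantification-cycle values.

    ``cq`` is indexed by gene with one column per sample; NaN flags a missing
    (non-amplified or discarded) reaction.  ``efficiency`` holds the per-gene
    amplification efficiency E with the theoretical-maximum default of 2.0
    (perfect doubling per cycle); values must satisfy 1 < E <= 2.
    ``ecotype`` optionally labels each sample column.
    """

    cq: pd.DataFrame
    efficiency: pd.Series = None  # type: ignore[assignment]
    ecotype: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.efficiency is None:
            self.efficiency = pd.Series(2.0, index=self.cq.index)
        self.efficiency = self.efficiency.reindex(self.cq.index)
        bad = self.efficiency[(self.efficiency <= 1.0) | (self.efficiency > 2.0)]
        if len(bad):
            raise ValueError(
                f"amplification efficiency must be in (1, 2]; offending genes: "
                f"{', '.join(map(str, bad.index))}"
            )
        vals = self.cq.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("Cq values must be finite where observed")

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq.columns)

    @property
    def n_missing(self) -> int:
        return int(self.cq.isna().to_numpy().sum())


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_float(token: str, column: str, row: int):
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise TableParseError(
            f"row {row}: cannot parse {column}={token!r} as a number"
        ) from None


def read_peak_table(path) -> list[PeakRecord]:
    """Read a GeneMapper-style peak list (CSV/TSV).

    Required columns (canonical names or an alias from
    :data:`PEAK_COLUMN_ALIASES`): ``sample_id``, ``primer_combo``, ``size``,
    ``height``.  Row order is preserved; no row is silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df.columns = [PEAK_COLUMN_ALIASES.get(c.strip().lower(), c.strip()) for c in df.columns]
    for col in ("sample_id", "primer_combo", "size", "height"):
        if col not in df.columns:
            raise TableFormatError(f"peak table {path} is missing column {col!r}")
    records: list[PeakRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        size = _parse_float(getattr(row, "size"), "size", i)
        height = _parse_float(getattr(row, "height"), "height", i)
        if size is None or height is None:
            raise TableParseError(f"row {i}: size/height may not be missing in a peak table")
        records.append(
            PeakRecord(
                sample_id=str(getattr(row, "sample_id")).strip(),
                primer_combo=str(getattr(row, "primer_combo")).strip(),
                size=size,
                height=height,
            )
        )
    return records


def read_sample_sheet(path, ecotypes=("RB", "SU")) -> list[SampleMeta]:
    """Read and validate the sample sheet (TSV/CSV).

    Columns: ``sample_id``, ``ecotype``, ``transect``,
    ``biological_replicate``, ``technical_replicate``.  Duplicate sample ids
    and ecotype labels outside ``ecotypes`` are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    required = [
        "sample_id",
        "ecotype",
        "transect",
        "biological_replicate",
        "technical_replicate",
    ]
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"sample sheet {path} is missing column {col!r}")
    ids = df["sample_id"].str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise TableFormatError(f"duplicate sample_id in sample sheet: {dup.iloc[0]!r}")
    bad = df.loc[~df["ecotype"].str.strip().isin(ecotypes), "ecotype"]
    if len(bad):
        raise TableFormatError(
            f"ecotype {bad.iloc[0]!r} not in allowed set {set(ecotypes)}"
        )
    samples = [
        SampleMeta(
            sample_id=r.sample_id.strip(),
            ecotype=r.ecotype.strip(),
            transect=r.transect.strip(),
            biological_replicate=r.biological_replicate.strip(),
            technical_replicate=r.technical_replicate.strip(),
        )
        for r in df.itertuples(index=False)
    ]
    design_summary(samples)  # validates replicate structure
    return samples


def samples_frame(samples: list[SampleMeta]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample id."""
    df = pd.DataFrame([dataclasses.asdict(s) for s in samples]).set_index("sample_id")
    return df


def design_summary(samples: list[SampleMeta]) -> dict:
    """Summarise (and validate) the replicate design of a sample sheet.

    Returns cell counts (ecotype x transect), biological replicates per cell
    and technical replicates per biological replicate, and flags single-group
    sheets.  Raises on duplicate (biological, technical) replicate pairs or a
    biological replicate spanning more than one design cell.
    """
    pairs = [(s.biological_replicate, s.technical_replicate) for s in samples]
    if len(set(pairs)) != len(pairs):
        raise TableFormatError("duplicate (biological_replicate, technical_replicate) pair")
    cell_of: dict[str, tuple[str, str]] = {}
    for s in samples:
        cell = (s.ecotype, s.transect)
        if cell_of.setdefault(s.biological_replicate, cell) != cell:
            raise TableFormatError(
                f"biological replicate {s.biological_replicate!r} appears in more "
                "than one (ecotype, transect) cell"
            )
    cells: dict[tuple[str, str], set] = {}
    tech_per_bio: dict[str, int] = {}
    for s in samples:
        cells.setdefault((s.ecotype, s.transect), set()).add(s.biological_replicate)
        tech_per_bio[s.biological_replicate] = tech_per_bio.get(s.biological_replicate, 0) + 1
    ecotypes = sorted({s.ecotype for s in samples})
    return {
        "n_samples": len(samples),
        "ecotypes": ecotypes,
        "transects": sorted({s.transect for s in samples}),
        "cells": {f"{e}/{t}": len(b) for (e, t), b in sorted(cells.items())},
        "bio_per_cell": sorted({len(b) for b in cells.values()}),
        "tech_per_bio": sorted(set(tech_per_bio.values())),
        "single_group": len(ecotypes) < 2,
    }


def read_cq_table(path, default_efficiency: float = 2.0) -> CqTable:
    """Read a genes x samples Cq table (CSV; first column = gene name).

    An optional ``efficiency`` column carries per-gene amplification
    efficiencies; genes without one get ``default_efficiency``.  Blank or
    ``NA`` cells are flagged missing (NaN).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"Cq table {path} is not rectangular: {exc}") from None
    eff = None
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "efficiency" in cols:
        eff_raw = df.pop("efficiency")
        eff = pd.Series(
            [
                _parse_float(v, "efficiency", i + 2)
                for i, v in enumerate(eff_raw)
            ],
            index=df.index,
            dtype=float,
        ).fillna(default_efficiency)
    cq = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for i, gene in enumerate(df.index):
        for col in df.columns:
            val = _parse_float(df.at[gene, col], f"Cq[{gene},{col}]", i + 2)
            cq.at[gene, col] = np.nan if val is None else val
    if eff is None:
        eff = pd.Series(default_efficiency, index=cq.index)
    return CqTable(cq=cq, efficiency=eff)


# ---------------------------------------------------------------------------
# writers

_TSV_FLOAT = "%.12g"


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float) and math.isnan(v):
        return "NA"
    if isinstance(v, float):
        return _TSV_FLOAT % v
    return str(v)


def _matrix_to_tsv(m: ExpressionMatrix, path: Path) -> None:
    cols = ["transcript_id", "primer_combo", "size", *m.samples.index]
    lines = ["\t".join(cols)]
    for tid in m.intensity.index:
        pc = m.transcripts.at[tid, "primer_combo"] if "primer_combo" in m.transcripts else "NA"
        size = m.transcripts.at[tid, "size"] if "size" in m.transcripts else float("nan")
        row = [str(tid), str(pc), _fmt(float(size))]
        row += [_fmt(float(v) if pd.notna(v) else float("nan")) for v in m.intensity.loc[tid]]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_expression_matrix(path, samples: list[SampleMeta] | pd.DataFrame) -> ExpressionMatrix:
    """Read a matrix TSV written by :func:`write_results` back into memory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    meta = samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)
    transcripts = df[["primer_combo", "size"]].copy()
    intensity = df.drop(columns=["primer_combo", "size"]).astype(float)
    intensity = intensity[list(meta.index)]
    return ExpressionMatrix(intensity=intensity, samples=meta, transcripts=transcripts)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        out = obj.reset_index()
        return [
            {k: _jsonable(v) for k, v in rec.items()}
            for rec in out.to_dict(orient="records")
        ]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_results(result, path, format: str = "json") -> None:
    """Serialise a result object deterministically.

    ``format`` is one of ``tsv`` (matrices/DataFrames), ``json`` (any result)
    or ``newick`` (dendrograms only).
    """
    path = Path(path)
    if format == "newick":
        to_newick = getattr(result, "to_newick", None)
        if to_newick is None:
            raise TypeError("newick output is only available for dendrograms")
        path.write_text(to_newick() + "\n")
        return
    if format == "tsv":
        if isinstance(result, ExpressionMatrix):
            _matrix_to_tsv(result, path)
            return
        if isinstance(result, pd.DataFrame):
            result.to_csv(path, sep="\t", float_format=_TSV_FLOAT, na_rep="NA")
            return
        raise TypeError(f"cannot write {type(result).__name__} as TSV")
    if format == "json":
        payload = _jsonable(result)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")
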