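"""Reading, filtering and histogramming per-read poly(A)-tail tables.

The raw unit of measurement is one nanopore direct-RNA read with a
tail-length estimate in adenosines and a caller QC tag, in the tab-separated
dialect emitted by the nanopolish ``polya`` subprogram (columns ``readname``,
``contig``, ``polya_length``, ``qc_tag``).  Everything downstream works on
integer-binned tail-length distributions and on library-size-normalized
per-transcript abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QC_VOCABULARY",
    "DEFAULT_COLUMNS",
    "TailTable",
    "TailDistribution",
    "AbundanceTable",
    "TailFormatError",
    "read_polya_table",
    "build_distribution",
    "merge_replicates",
    "normalize_abundance",
    "distribution_to_frame",
]

#: Closed QC vocabulary; anything else maps to "other".
QC_VOCABULARY = frozenset({"PASS", "FAIL", "SUFFCLIP", "ADAPTER", "NOREGION", "other"})

#: Column mapping for the nanopolish-polya dialect:
#: logical name -> column header in the file.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "read_id": "readname",
    "transcript_id": "contig",
    "tail_length": "polya_length",
    "qc_tag": "qc_tag",
}


class TailFormatError(ValueError):
    """Raised for malformed tail tables (missing columns, unparsable rows)."""


def _canonical_qc(tag: str) -> str:
    tag = str(tag)
    return tag if tag in QC_VOCABULARY else "other"


@dataclass
class TailTable:
    """Per-read tail-length calls for one sample.

    ``records`` holds columns read_id, transcript_id, tail_length (float,
    adenosines, >= 0) and qc_tag (canonicalized); row order is preserved
    from the source file.
    """

    records: pd.DataFrame
    sample_id: str = ""
    time_min: float = 0.0

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")

    def __len__(self) -> int:
        return len(self.records)

    def lengths(self, transcript_id: str | None = None) -> np.ndarray:
        """Tail lengths, optionally restricted to one transcript."""
        df = self.records
        if transcript_id is not None:
            df = df[df["transcript_id"] == transcript_id]
        return df["tail_length"].to_numpy(dtype=float)

    def counts_by_transcript(self) -> pd.Series:
        return self.records.groupby("transcript_id").size()


def read_polya_table(
    path: str | Path,
    qc_policy: Iterable[str] | None = ("PASS",),
    columns: Mapping[str, str] = DEFAULT_COLUMNS,
    sample_id: str | None = None,
    time_min: float = 0.0,
) -> TailTable:
    """Read a nanopolish-polya style TSV (plain or gzip).

    Only records whose canonical QC tag is in ``qc_policy`` are kept
    (default: PASS only; ``None`` keeps everything).  Raises
    :class:`TailFormatError` naming the missing column, or the 0-based data
    row index of an unparsable tail length.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise TailFormatError(f"missing required column(s): {', '.join(missing)}")
    out = pd.DataFrame(
        {
            "read_id": df[columns["read_id"]].astype(str),
            "transcript_id": df[columns["transcript_id"]].astype(str),
            "qc_tag": df[columns["qc_tag"]].map(_canonical_qc),
        }
    )
    lengths = pd.to_numeric(df[columns["tail_length"]], errors="coerce")
    bad = np.flatnonzero(lengths.isna().to_numpy())
    if bad.size:
        raise TailFormatError(
            f"unparsable tail length at data row {int(bad[0])} "
            f"(value {df[columns['tail_length']].iloc[int(bad[0])]!r})"
        )
    out["tail_length"] = lengths.to_numpy(dtype=float).clip(min=0.0)
    if qc_policy is not None:
        keep = set(qc_policy)
        out = out[out["qc_tag"].isin(keep)].reset_index(drop=True)
    return TailTable(out, sample_id=sample_id or path.stem, time_min=time_min)


@dataclass
class TailDistribution:
    """Integer-binned tail-length histogram with normalized density.

    Support is 0..n_max adenosines.  Invariants: counts sum to n_reads,
    density sums to 1 when n_reads > 0.
    """

    counts: np.ndarray
    label: str = ""
    time_min: float = 0.0
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ValueError("counts must be a 1-D array over support 0..n_max")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.support = np.arange(len(self.counts))

    @property
    def n_max(self) -> int:
        return len(self.counts) - 1

    @property
    def n_reads(self) -> int:
        return int(round(self.counts.sum()))

    @property
    def density(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        """Tail length at cumulative density q (linear interpolation)."""
        c = np.cumsum(self.density)
        return np.interp(q, c, self.support.astype(float))


def build_distribution(
    table: TailTable | Sequence[float] | np.ndarray,
    n_max: int = 250,
    round_mode: str = "nearest",
    label: str = "",
    time_min: float | None = None,
    allow_empty: bool = False,
    transcript_id: str | None = None,
) -> TailDistribution:
    """Histogram tail lengths at 1-adenosine resolution.

    Lengths are rounded to the nearest integer (half-up) and clamped to
    [0, n_max].  ``table`` may be a :class:`TailTable` or a plain sequence
    of lengths.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if isinstance(table, TailTable):
        lengths = table.lengths(transcript_id)
        if time_min is None:
            time_min = table.time_min
        if not label:
            label = transcript_id or table.sample_id
    else:
        lengths = np.asarray(table, dtype=float)
    if time_min is None:
        time_min = 0.0
    if lengths.size == 0 and not allow_empty:
        raise ValueError("no reads")
    if round_mode == "nearest":
        binned = np.floor(lengths + 0.5)  # half-up
    elif round_mode == "floor":
        binned = np.floor(lengths)
    else:
        raise ValueError(f"unknown round_mode {round_mode!r}")
    binned = np.clip(binned, 0, n_max).astype(int)
    counts = np.bincount(binned, minlength=n_max + 1).astype(float)
    return TailDistribution(counts, label=label, time_min=float(time_min))


def merge_replicates(distributions: Sequence[TailDistribution]) -> TailDistribution:
    """Sum counts across replicate histograms of the same group/timepoint."""
    if not distributions:
        raise ValueError("nothing to merge")
    first = distributions[0]
    for d in distributions[1:]:
        if d.label != first.label:
            raise ValueError(f"label mismatch: {d.label!r} vs {first.label!r}")
        if abs(d.time_min - first.time_min) > 1e-6:
            raise ValueError("time_min mismatch between replicates")
        if d.n_max != first.n_max:
            raise ValueError("support mismatch between replicates")
    counts = np.sum([d.counts for d in distributions], axis=0)
    return TailDistribution(counts, label=first.label, time_min=first.time_min)


@dataclass
class AbundanceTable:
    """Per-transcript raw counts and library-size-normalized levels."""

    raw: pd.Series
    normalized: pd.Series
    sample_id: str = ""
    time_min: float = 0.0


def normalize_abundance(
    tables: Mapping[str, pd.Series],
    excluded_ids: Iterable[str] = ("ENO2",),
    na_substitute: float = 0.01,
    scale: float = 1e6,
    time_min: Mapping[str, float] | None = None,
    reference_sample: str | None = None,
) -> dict[str, AbundanceTable]:
    """Library-size normalization of per-transcript read counts.

    Excluded transcripts (spike-in-contaminated ones such as ENO2) are
    removed before the library size is computed; transcripts absent from a
    sample but present in any other get ``na_substitute`` raw counts; each
    sample is scaled to counts per ``scale`` (per million by default).

    With ``reference_sample`` set, every sample is scaled by that one
    sample's library size instead of its own.  Per-sample scaling removes
    between-sample depth differences but also removes any real change in
    pool size; when depth is proportional to input material (as in a
    chase where the whole pool decays), scaling against the reference
    library preserves the absolute dynamics.
    """
    excluded = set(excluded_ids)
    cleaned: dict[str, pd.Series] = {}
    for sid, counts in tables.items():
        s = pd.Series(counts, dtype=float)
        s = s[~s.index.isin(excluded)]
        cleaned[sid] = s
    if reference_sample is not None and reference_sample not in cleaned:
        raise ValueError(f"reference sample {reference_sample!r} not among tables")
    all_ids = sorted(set().union(*[set(s.index) for s in cleaned.values()]))
    ref_library = None
    if reference_sample is not None:
        ref_library = float(
            cleaned[reference_sample].reindex(all_ids).fillna(na_substitute).sum()
        )
        if ref_library <= 0:
            raise ValueError(f"all-zero library in sample {reference_sample!r}")
    out: dict[str, AbundanceTable] = {}
    for sid, s in cleaned.items():
        raw = s.reindex(all_ids).fillna(na_substitute)
        library = ref_library if ref_library is not None else raw.sum()
        if library <= 0:
            raise ValueError(f"all-zero library in sample {sid!r}")
        t = time_min.get(sid, 0.0) if time_min else 0.0
        out[sid] = AbundanceTable(raw, raw / library * scale, sample_id=sid, time_min=t)
    return out


def distribution_to_frame(dist: TailDistribution) -> pd.DataFrame:
    """Long-format table (label, time_min, tail_length, count, density)."""
    return pd.DataFrame(
        {
            "label": dist.label,
            "time_min": dist.time_min,
            "tail_length": dist.support,
            "count": dist.counts.astype(int),
            "density": dist.density,
        }
    )
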