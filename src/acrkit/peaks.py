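"""Peak I/O, stage consensus ACRs, stage partition and genome coverage.

A stage's consensus accessible-chromatin regions (ACRs) are the maximal
intervals covered by at least one peak in *every* replicate of the stage
("shared by all samples, then merged").  Stage-specific peaks have no
>= 1 bp overlap with any other stage's consensus set; common peaks are
the reference stage's peaks overlapped by all other stages.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import ChromSizes

__all__ = [
    "PeakSet",
    "StagePartition",
    "read_peaks",
    "write_peaks",
    "consensus_peaks",
    "stage_partition",
    "genome_coverage",
    "chrom_peak_counts",
]

PEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "pscore", "qscore", "summit",
]

_DIALECT_NCOLS = {"bed3": 3, "bed6": 6, "narrowpeak": 10}


class PeakSet:
    """A sorted set of peaks with narrowPeak attributes.

    Backed by a DataFrame with columns ``chrom, start, end, name, score,
    strand, signal, pscore, qscore, summit``; sorted by (chrom, start,
    end), peak names unique within the set.
    """

    def __init__(self, df: pd.DataFrame, label: str = ""):
        df = df.copy()
        for col, default in (
            ("name", None), ("score", 0), ("strand", "."),
            ("signal", 0.0), ("pscore", 0.0), ("qscore", 0.0), ("summit", -1),
        ):
            if col not in df:
                df[col] = default
        df = df[PEAK_COLUMNS]
        bad = df.index[~(df["start"] < df["end"])]
        if len(bad):
            raise ValueError(f"peak with start >= end at row {bad[0]}")
        if (df["start"] < 0).any():
            raise ValueError("negative peak coordinate")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        df["name"] = df["name"].astype(object)
        missing = df["name"].isna()
        if missing.any():
            prefix = label or "peak"
            df.loc[missing, "name"] = [f"{prefix}_{i}" for i in df.index[missing]]
        if df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate peak id {dup!r} in set {label!r}")
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df
        self.label = label

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    @property
    def ids(self) -> list[str]:
        return list(self.df["name"])

    @property
    def total_bp(self) -> int:
        """Total merged (union) base pairs covered."""
        return sum(
            int((e - s).sum())
            for s, e in (
                _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
                for _, sub in self.df.groupby("chrom", sort=False)
            )
        )

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in self.df.groupby("chrom", sort=True)
        }

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int]],
        label: str = "",
        ids: Sequence[str] | None = None,
    ) -> "PeakSet":
        rows = list(intervals)
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        if ids is not None:
            df["name"] = list(ids)
        return cls(df, label=label)


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    keep_s, keep_e = [int(starts[0])], [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s > keep_e[-1]:
            keep_s.append(int(s))
            keep_e.append(int(e))
        elif e > keep_e[-1]:
            keep_e[-1] = int(e)
    return np.array(keep_s, dtype=np.int64), np.array(keep_e, dtype=np.int64)


def read_peaks(path: str | os.PathLike, dialect: str = "narrowpeak", label: str = "") -> PeakSet:
    """Read BED3 / BED6 / narrowPeak; malformed lines rejected by number."""
    dialect = dialect.lower()
    if dialect not in _DIALECT_NCOLS:
        raise ValueError(f"unknown dialect {dialect!r}; use bed3, bed6 or narrowpeak")
    ncols = _DIALECT_NCOLS[dialect]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} columns for {dialect}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            row = {"chrom": fields[0], "start": start, "end": end}
            if ncols >= 6:
                row["name"] = fields[3]
                row["score"] = float(fields[4]) if fields[4] != "." else 0
                row["strand"] = fields[5]
            if ncols == 10:
                row["signal"] = float(fields[6])
                row["pscore"] = float(fields[7])
                row["qscore"] = float(fields[8])
                row["summit"] = int(fields[9])
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand",
                                     "signal", "pscore", "qscore", "summit"])
    if not rows:
        df = pd.DataFrame(columns=PEAK_COLUMNS)
    return PeakSet(df, label=label or os.path.splitext(os.path.basename(str(path)))[0])


def write_peaks(peaks: PeakSet, path: str | os.PathLike, dialect: str = "narrowpeak") -> None:
    dialect = dialect.lower()
    df = peaks.df.copy()
    if dialect == "bed3":
        out = df[["chrom", "start", "end"]]
    elif dialect == "bed6":
        out = df[["chrom", "start", "end", "name", "score", "strand"]]
    elif dialect == "narrowpeak":
        out = df[PEAK_COLUMNS]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", header=False, index=False)


def consensus_peaks(
    replicate_sets: Sequence[PeakSet],
    mode: str = "intersection",
    min_length: int = 1,
    label: str = "consensus",
) -> PeakSet:
    """Consensus ACRs across replicates of one stage.

    ``mode="intersection"`` (default): maximal intervals covered by at
    least one peak in every replicate, merged into contiguous runs.
    ``mode="union"``: merged envelope of all replicate peaks.
    """
    if len(replicate_sets) == 0:
        raise ValueError("consensus requires at least one replicate peak set")
    if len(replicate_sets) == 1:
        warnings.warn("single replicate: consensus is the replicate itself")
    k = len(replicate_sets)
    chroms = sorted({c for ps in replicate_sets for c in ps.df["chrom"].unique()})
    rows = []
    for chrom in chroms:
        events = []  # (pos, delta)
        present = 0
        for ps in replicate_sets:
            sub = ps.df[ps.df["chrom"] == chrom]
            if sub.empty:
                continue
            present += 1
            s, e = _merge(sub["start"].to_numpy(), sub["end"].to_numpy())
            events.append((s, e))
        if mode == "intersection" and present < k:
            continue
        if not events:
            continue
        starts = np.concatenate([s for s, _ in events])
        ends = np.concatenate([e for _, e in events])
        pos = np.concatenate([starts, ends])
        delta = np.concatenate([np.ones(len(starts), dtype=np.int64),
                                -np.ones(len(ends), dtype=np.int64)])
        order = np.lexsort((-delta, pos))  # starts before ends at equal pos
        pos, delta = pos[order], delta[order]
        cov = np.cumsum(delta)
        need = k if mode == "intersection" else 1
        # segment [pos[i], pos[i+1]) has coverage cov[i]; keep segments at
        # coverage >= need and merge contiguous runs
        seg_s, seg_e, seg_cov = pos[:-1], pos[1:], cov[:-1]
        mask = (seg_cov >= need) & (seg_e > seg_s)
        for s, e in zip(seg_s[mask], seg_e[mask]):
            if rows and rows[-1][0] == chrom and rows[-1][2] == s:
                rows[-1] = (chrom, rows[-1][1], int(e))
            else:
                rows.append((chrom, int(s), int(e)))
    rows = [(c, s, e) for c, s, e in rows if e - s >= min_length]
    ids = [f"{label}_{i + 1}" for i in range(len(rows))]
    return PeakSet.from_intervals(rows, label=label, ids=ids)


@dataclass
class StagePartition:
    """Stage-specific peak sets plus the common set (reference coords)."""

    specific: dict[str, PeakSet]
    common: PeakSet
    reference_stage: str

    def counts(self) -> pd.DataFrame:
        rows = [{"category": f"{stage}_specific", "count": len(ps)}
                for stage, ps in self.specific.items()]
        rows.append({"category": "common", "count": len(self.common)})
        return pd.DataFrame(rows)


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, other: dict[str, tuple[np.ndarray, np.ndarray]], chrom: str
) -> np.ndarray:
    """True for each query interval overlapping (>= 1 bp) the other set."""
    if chrom not in other:
        return np.zeros(len(starts), dtype=bool)
    os_, oe_ = _merge(*other[chrom])
    # overlap iff some merged interval has start < q_end and end > q_start
    idx = np.searchsorted(os_, ends, side="left") - 1
    ok = idx >= 0
    res = np.zeros(len(starts), dtype=bool)
    res[ok] = oe_[idx[ok]] > starts[ok]
    return res


def stage_partition(
    stage_consensus: Mapping[str, PeakSet],
    reference_stage: str | None = None,
) -> StagePartition:
    """Partition stage consensus sets into stage-specific and common peaks.

    A stage's peak is *specific* iff it overlaps (>= 1 bp) no peak of any
    other stage.  *Common* peaks are the reference stage's peaks (default:
    the first stage given) overlapped by every other stage, giving one
    peak universe for differential peak-intensity testing.
    """
    stages = list(stage_consensus)
    if len(stages) < 2:
        raise ValueError("stage partition requires at least 2 stages")
    if reference_stage is None:
        reference_stage = stages[0]
    if reference_stage not in stage_consensus:
        raise ValueError(f"unknown reference stage {reference_stage!r}")
    by_chrom = {s: stage_consensus[s].by_chrom() for s in stages}
    specific: dict[str, PeakSet] = {}
    for stage in stages:
        df = stage_consensus[stage].df
        keep = np.ones(len(df), dtype=bool)
        for chrom, sub in df.groupby("chrom", sort=False):
            s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
            hit = np.zeros(len(sub), dtype=bool)
            for other in stages:
                if other == stage:
                    continue
                hit |= _overlaps_any(s, e, by_chrom[other], chrom)
            keep[sub.index] = ~hit
        specific[stage] = PeakSet(df[keep], label=f"{stage}_specific")
    ref_df = stage_consensus[reference_stage].df
    keep = np.ones(len(ref_df), dtype=bool)
    for chrom, sub in ref_df.groupby("chrom", sort=False):
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        in_all = np.ones(len(sub), dtype=bool)
        for other in stages:
            if other == reference_stage:
                continue
            in_all &= _overlaps_any(s, e, by_chrom[other], chrom)
        keep[sub.index] = in_all
    common = PeakSet(ref_df[keep], label="common")
    return StagePartition(specific=specific, common=common, reference_stage=reference_stage)


def genome_coverage(peak_set: PeakSet, chrom_sizes: ChromSizes) -> float:
    """Fraction of the genome covered by the merged peak set, in [0, 1]."""
    total = chrom_sizes.total_length
    if total <= 0:
        raise ValueError("empty genome")
    for chrom, sub in peak_set.df.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        if int(sub["end"].max()) > chrom_sizes[chrom]:
            raise ValueError(f"peak beyond end of chromosome {chrom!r}")
    return peak_set.total_bp / total


def chrom_peak_counts(peak_set: PeakSet, chrom_sizes: ChromSizes | None = None) -> pd.Series:
    """Peak counts per chromosome; zero rows included when sizes given."""
    counts = peak_set.df["chrom"].value_counts()
    if chrom_sizes is not None:
        counts = counts.reindex(list(chrom_sizes), fill_value=0)
    return counts.sort_index().astype(int).rename("n_peaks")
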