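"""Gene models, promoter/TTS windows and feature classification.

Reads gene annotation (GTF) into strand-aware gene records, derives
promoter and transcription-termination windows around the TSS/TES, and
classifies genomic intervals into the mutually exclusive feature classes
``promoter > tts > exon > intron > intergenic`` by the position of the
interval midpoint.  Promoter peaks additionally carry a *proximal
promoter* flag (midpoint within -1 kb .. +100 bp of a TSS).

Coordinates are 0-based half-open throughout; GTF (1-based closed) is
converted on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "GeneModel",
    "GeneModelSet",
    "FeatureClass",
    "FeatureLabel",
    "WindowsConfig",
    "GenomeAnnotator",
    "read_chrom_sizes",
    "read_gene_models",
    "promoter_window",
    "tts_window",
    "classify_interval",
    "annotate_peaks",
    "feature_class_summary",
    "midpoint",
]


class FeatureLabel(str, Enum):
    """The five mutually exclusive genomic feature classes."""

    PROMOTER = "promoter"
    TTS = "tts"
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: classification priority, highest first
CLASS_PRIORITY: tuple[FeatureLabel, ...] = (
    FeatureLabel.PROMOTER,
    FeatureLabel.TTS,
    FeatureLabel.EXON,
    FeatureLabel.INTRON,
    FeatureLabel.INTERGENIC,
)


@dataclass(frozen=True)
class FeatureClass:
    """A feature label plus the proximal-promoter sub-flag.

    ``proximal_promoter`` is only meaningful when ``value`` is
    ``FeatureLabel.PROMOTER``.
    """

    value: FeatureLabel
    proximal_promoter: bool = False


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp); names unique, lengths positive."""

    def __init__(self, entries: Mapping[str, int]):
        entries = dict(entries)
        for name, length in entries.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._entries = {str(k): int(v) for k, v in entries.items()}

    def __getitem__(self, key: str) -> int:
        return self._entries[key]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def total_length(self) -> int:
        return sum(self._entries.values())

    def to_series(self) -> pd.Series:
        return pd.Series(self._entries, name="length")

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for name, length in self._entries.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | os.PathLike) -> ChromSizes:
    """Read a two-column ``chrom.sizes`` TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise ValueError(f"duplicate chromosome name {dup!r} in {path}")
    return ChromSizes(dict(zip(df["chrom"], df["length"])))


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; strand '+', '-' or '.' (unstranded)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """start + floor(length / 2)."""
        return self.start + (self.end - self.start) // 2


def midpoint(start: int, end: int) -> int:
    """Midpoint convention used everywhere: start + floor(length/2)."""
    return start + (end - start) // 2


@dataclass(frozen=True)
class GeneModel:
    """One gene: interval, strand-aware TSS/TES and exon union."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    exonic_length: int = field(default=0)

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene interval")
        if self.exonic_length == 0:
            object.__setattr__(self, "exonic_length", _union_length(self.exons))

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        """Strand-aware 3' end (0-based position)."""
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start


def _union_length(intervals: Sequence[GenomicInterval]) -> int:
    ivs = sorted((iv.start, iv.end) for iv in intervals)
    total, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


class GeneModelSet:
    """A collection of gene models plus the chromosome sizes in force."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: ChromSizes):
        genes = list(genes)
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate gene_id {dup!r}")
        for g in genes:
            if g.interval.chrom not in chrom_sizes:
                raise ValueError(
                    f"gene {g.gene_id}: unknown chromosome {g.interval.chrom!r}"
                )
            if g.interval.end > chrom_sizes[g.interval.chrom]:
                raise ValueError(f"gene {g.gene_id}: extends past end of chromosome")
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self.chrom_sizes = chrom_sizes

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def exonic_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.exonic_length for g in self}, name="exonic_length")


def read_gene_models(gtf_path: str | os.PathLike, chrom_sizes: ChromSizes) -> GeneModelSet:
    """Read a GTF into a :class:`GeneModelSet`.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    A record on a chromosome absent from ``chrom_sizes`` is rejected, as
    is any gene_id with no exon features.  One TSS per gene record: the
    gene line's strand-aware 5' end.
    """
    text = open(gtf_path).read()
    if not text.strip():
        return GeneModelSet([], chrom_sizes)
    db = gffutils.create_db(
        text,
        ":memory:",
        from_string=True,
        force=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    gene_lines: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "exon"):
            continue
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is None:
            raise ValueError(f"{feat.featuretype} record without gene_id at {feat.seqid}:{feat.start}")
        if feat.seqid not in chrom_sizes:
            raise ValueError(
                f"record for gene {gid!r} on unknown chromosome {feat.seqid!r}"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.featuretype == "gene":
            gene_lines[gid] = iv
        else:
            exons.setdefault(gid, []).append(iv)
    genes = []
    for gid in sorted(set(gene_lines) | set(exons)):
        if gid not in exons:
            raise ValueError(f"gene {gid!r} has no exon features")
        exs = tuple(sorted(exons[gid], key=lambda e: (e.start, e.end)))
        if gid in gene_lines:
            span = gene_lines[gid]
        else:
            span = GenomicInterval(
                exs[0].chrom, min(e.start for e in exs), max(e.end for e in exs), exs[0].strand
            )
        exs = tuple(
            GenomicInterval(e.chrom, e.start, e.end, span.strand) for e in exs
        )
        genes.append(GeneModel(gid, span, exs))
    return GeneModelSet(genes, chrom_sizes)


@dataclass(frozen=True)
class WindowsConfig:
    """Window definitions (bp, strand-aware) used in classification.

    Promoter: TSS - upstream .. TSS + downstream (inclusive).
    Proximal promoter: same construction with its own bounds.
    TTS window: TES - tts_upstream .. TES + tts_downstream (inclusive),
    where "upstream" is into the gene body.
    """

    promoter_upstream: int = 2000
    promoter_downstream: int = 100
    proximal_upstream: int = 1000
    proximal_downstream: int = 100
    tts_upstream: int = 100
    tts_downstream: int = 1000


DEFAULT_WINDOWS = WindowsConfig()


def _anchored_window(
    pos: int, strand: str, upstream: int, downstream: int, chrom: str, chrom_len: int | None
) -> GenomicInterval | None:
    """Inclusive strand-aware window around an anchor position, clipped."""
    if strand == "-":
        start, end = pos - downstream, pos + upstream + 1
    else:
        start, end = pos - upstream, pos + downstream + 1
    start = max(start, 0)
    if chrom_len is not None:
        end = min(end, chrom_len)
    if start >= end:
        return None
    return GenomicInterval(chrom, start, end, strand)


def promoter_window(
    gene: GeneModel,
    upstream_bp: int = 2000,
    downstream_bp: int = 100,
    chrom_sizes: ChromSizes | None = None,
) -> GenomicInterval | None:
    """Strand-aware promoter window TSS-upstream .. TSS+downstream (inclusive).

    Clipped to chromosome bounds when ``chrom_sizes`` is given; returns
    ``None`` if the window falls entirely off-chromosome.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be >= 0")
    chrom = gene.interval.chrom
    chrom_len = chrom_sizes[chrom] if chrom_sizes is not None else None
    return _anchored_window(
        gene.tss, gene.interval.strand, upstream_bp, downstream_bp, chrom, chrom_len
    )


def tts_window(
    gene: GeneModel,
    upstream_bp: int = 100,
    downstream_bp: int = 1000,
    chrom_sizes: ChromSizes | None = None,
) -> GenomicInterval | None:
    """Strand-aware window around the TES (upstream = into the gene body)."""
    chrom = gene.interval.chrom
    chrom_len = chrom_sizes[chrom] if chrom_sizes is not None else None
    return _anchored_window(
        gene.tes, gene.interval.strand, upstream_bp, downstream_bp, chrom, chrom_len
    )


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into disjoint sorted runs."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s > out_e[-1]:
            out_s.append(s)
            out_e.append(e)
        elif e > out_e[-1]:
            out_e[-1] = e
    return np.asarray(out_s), np.asarray(out_e)


class _PointIndex:
    """Membership queries for points against merged intervals, per chrom."""

    def __init__(self, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.by_chrom = by_chrom

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "_PointIndex":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        by_chrom = {}
        for chrom, pairs in grouped.items():
            s = np.array([p[0] for p in pairs], dtype=np.int64)
            e = np.array([p[1] for p in pairs], dtype=np.int64)
            by_chrom[chrom] = _merge_arrays(s, e)
        return cls(by_chrom)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self.by_chrom:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = self.by_chrom[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < ends[idx[ok]]
        return res


class GenomeAnnotator:
    """Precomputed classification and nearest-TSS index over a gene set.

    Built once per (GeneModelSet, WindowsConfig); classification of a
    position is then an O(log n) lookup, vectorised over positions.
    """

    def __init__(self, models: GeneModelSet, windows: WindowsConfig = DEFAULT_WINDOWS):
        self.models = models
        self.windows = windows
        cs = models.chrom_sizes
        prom, prox, tts, exon, body = [], [], [], [], []
        for g in models:
            w = promoter_window(g, windows.promoter_upstream, windows.promoter_downstream, cs)
            if w is not None:
                prom.append(w)
            w = promoter_window(g, windows.proximal_upstream, windows.proximal_downstream, cs)
            if w is not None:
                prox.append(w)
            w = tts_window(g, windows.tts_upstream, windows.tts_downstream, cs)
            if w is not None:
                tts.append(w)
            exon.extend(g.exons)
            body.append(g.interval)
        self._promoter = _PointIndex.from_intervals(prom)
        self._proximal = _PointIndex.from_intervals(prox)
        self._tts = _PointIndex.from_intervals(tts)
        self._exon = _PointIndex.from_intervals(exon)
        self._body = _PointIndex.from_intervals(body)
        # nearest-TSS index: per chromosome, TSS positions sorted with the
        # lexicographically smallest gene_id kept per duplicated position
        self._tss_index: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
        per_chrom: dict[str, list[tuple[int, str, str]]] = {}
        for g in models:
            per_chrom.setdefault(g.interval.chrom, []).append(
                (g.tss, g.gene_id, g.interval.strand)
            )
        for chrom, recs in per_chrom.items():
            recs.sort()  # (pos, gene_id) -> smallest id first within a position
            dedup: list[tuple[int, str, str]] = []
            for pos, gid, strand in recs:
                if dedup and dedup[-1][0] == pos:
                    continue
                dedup.append((pos, gid, strand))
            self._tss_index[chrom] = (
                np.array([r[0] for r in dedup], dtype=np.int64),
                [r[1] for r in dedup],
                [r[2] for r in dedup],
            )

    # -- classification ------------------------------------------------
    def classify_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Class codes (index into CLASS_PRIORITY) for genomic positions."""
        positions = np.asarray(positions, dtype=np.int64)
        code = np.full(len(positions), CLASS_PRIORITY.index(FeatureLabel.INTERGENIC), dtype=np.int8)
        masks = [
            (FeatureLabel.PROMOTER, self._promoter),
            (FeatureLabel.TTS, self._tts),
            (FeatureLabel.EXON, self._exon),
            (FeatureLabel.INTRON, self._body),
        ]
        unassigned = np.ones(len(positions), dtype=bool)
        for label, index in masks:
            hit = unassigned & index.contains(chrom, positions)
            code[hit] = CLASS_PRIORITY.index(label)
            unassigned &= ~hit
        return code

    def proximal_flags(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        return self._proximal.contains(chrom, positions)

    def nearest_tss(self, chrom: str, positions: np.ndarray) -> tuple[list[str | None], np.ndarray]:
        """Nearest gene by |position - TSS| with lexicographic tie-break.

        Returns gene ids (None where the chromosome has no genes) and the
        signed distance in gene orientation (negative = upstream).
        """
        positions = np.asarray(positions, dtype=np.int64)
        n = len(positions)
        if chrom not in self._tss_index:
            return [None] * n, np.full(n, np.nan)
        tss_pos, gene_ids, strands = self._tss_index[chrom]
        right = np.searchsorted(tss_pos, positions, side="left")
        ids: list[str | None] = []
        dists = np.empty(n, dtype=float)
        for i, p in enumerate(positions):
            cands = []
            if right[i] > 0:
                cands.append(right[i] - 1)
            if right[i] < len(tss_pos):
                cands.append(right[i])
            best = min(cands, key=lambda j: (abs(int(tss_pos[j]) - int(p)), gene_ids[j]))
            ids.append(gene_ids[best])
            raw = int(p) - int(tss_pos[best])
            dists[i] = raw if strands[best] == "+" else -raw
        return ids, dists


def classify_interval(
    interval: GenomicInterval,
    models: GeneModelSet | GenomeAnnotator,
    windows: WindowsConfig = DEFAULT_WINDOWS,
) -> FeatureClass:
    """Classify an interval by its midpoint with the fixed class priority."""
    ann = models if isinstance(models, GenomeAnnotator) else GenomeAnnotator(models, windows)
    if interval.chrom not in ann.models.chrom_sizes:
        raise ValueError(f"unknown chromosome {interval.chrom!r}")
    pos = np.array([interval.midpoint])
    code = ann.classify_positions(interval.chrom, pos)[0]
    label = CLASS_PRIORITY[code]
    proximal = bool(ann.proximal_flags(interval.chrom, pos)[0]) if label == FeatureLabel.PROMOTER else False
    return FeatureClass(label, proximal)


def annotate_peaks(
    peaks,
    models: GeneModelSet | GenomeAnnotator,
    windows: WindowsConfig = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Annotate a peak set with feature class, nearest gene and TSS distance.

    Returns a DataFrame with one row per peak: chrom, start, end, peak_id,
    length, midpoint, feature_class, proximal_promoter, nearest_gene,
    tss_distance (signed, gene orientation, negative = upstream).
    """
    from .peaks import PeakSet  # local import to avoid a cycle

    ann = models if isinstance(models, GenomeAnnotator) else GenomeAnnotator(models, windows)
    df = peaks.df if isinstance(peaks, PeakSet) else pd.DataFrame(peaks)
    if df.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "peak_id", "length", "midpoint",
                "feature_class", "proximal_promoter", "nearest_gene", "tss_distance",
            ]
        )
    out = df[["chrom", "start", "end"]].copy()
    out["peak_id"] = df["name"].values if "name" in df else df.index.astype(str)
    out["length"] = out["end"] - out["start"]
    out["midpoint"] = out["start"] + out["length"] // 2
    classes = np.empty(len(out), dtype=object)
    proximal = np.zeros(len(out), dtype=bool)
    nearest = np.empty(len(out), dtype=object)
    dist = np.full(len(out), np.nan)
    for chrom, sub in out.groupby("chrom", sort=False):
        pos = sub["midpoint"].to_numpy()
        codes = ann.classify_positions(chrom, pos)
        labels = [CLASS_PRIORITY[c].value for c in codes]
        classes[sub.index] = labels
        prox = ann.proximal_flags(chrom, pos)
        is_prom = codes == CLASS_PRIORITY.index(FeatureLabel.PROMOTER)
        proximal[sub.index] = prox & is_prom
        ids, d = ann.nearest_tss(chrom, pos)
        nearest[sub.index] = ids
        dist[sub.index] = d
    out = out.reset_index(drop=True)
    out["feature_class"] = classes
    out["proximal_promoter"] = proximal
    out["nearest_gene"] = nearest
    out["tss_distance"] = dist
    return out


def feature_class_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per feature class (rows sum to 100%)."""
    labels = [fl.value for fl in CLASS_PRIORITY]
    counts = annotated["feature_class"].value_counts().reindex(labels, fill_value=0)
    total = counts.sum()
    pct = counts / total * 100.0 if total else counts.astype(float)
    return pd.DataFrame({"count": counts, "percent": pct})


def write_annotated_peaks(annotated: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write annotation as BED6+ (class, proximal flag, gene, distance)."""
    cols = annotated.copy()
    cols["score"] = 0
    cols["strand"] = "."
    bed = cols[
        ["chrom", "start", "end", "peak_id", "score", "strand",
         "feature_class", "proximal_promoter", "nearest_gene", "tss_distance"]
    ]
    bed.to_csv(path, sep="\t", header=False, index=False)
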