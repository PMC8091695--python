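"""Promoter-ACR / expression integration.

Joins accessible-chromatin regions in proximal promoter windows to the
genes they regulate: ACR-count distribution, length-rank grouping
(top / middle / bottom thirds with a deterministic tie rule), FPKM
binning and group-by-bin proportion tables, per-gene intensity vs
expression correlation, k-means clustering of temporal expression
profiles, and hypergeometric gene-set overlap tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-exported for callers)

from .genome_model import (
    DEFAULT_WINDOWS,
    GeneModelSet,
    WindowsConfig,
    promoter_window,
)

__all__ = [
    "PromoterAcrMap",
    "LengthGroupAssignment",
    "OverlapTest",
    "ClusterAssignment",
    "EXPRESSION_BINS",
    "map_promoter_acrs",
    "assign_length_groups",
    "bin_expression",
    "group_bin_table",
    "intensity_expression_correlation",
    "cluster_degs",
    "overlap_significance",
]

#: FPKM bin edges: [0,2), [2,5), [5,10), [10,30), [30, inf)
EXPRESSION_BINS = (0.0, 2.0, 5.0, 10.0, 30.0, np.inf)
BIN_LABELS = ("B1", "B2", "B3", "B4", "B5")

GROUPS = ("bottom", "middle", "top")


@dataclass
class PromoterAcrMap:
    """gene_id -> ACRs (id, length) whose midpoint lies in the gene's
    proximal promoter window."""

    genes: dict[str, list[tuple[str, int]]]

    def count_distribution(self) -> pd.Series:
        """Number of genes with exactly one vs more than one promoter ACR."""
        counts = pd.Series({g: len(v) for g, v in self.genes.items()})
        return pd.Series(
            {"one_acr": int((counts == 1).sum()), "multi_acr": int((counts > 1).sum())}
        )

    def lengths(self, statistic: str = "single") -> pd.Series:
        """Per-gene length statistic over its promoter ACRs.

        ``single`` uses genes with exactly one ACR; ``max`` / ``total``
        use genes with more than one ACR (maximum / summed length).
        """
        if statistic == "single":
            items = {g: v[0][1] for g, v in self.genes.items() if len(v) == 1}
        elif statistic == "max":
            items = {g: max(l for _, l in v) for g, v in self.genes.items() if len(v) > 1}
        elif statistic == "total":
            items = {g: sum(l for _, l in v) for g, v in self.genes.items() if len(v) > 1}
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        return pd.Series(items, dtype=np.int64, name=f"{statistic}_length")


def map_promoter_acrs(
    annotated_peaks: pd.DataFrame,
    models: GeneModelSet,
    windows: WindowsConfig = DEFAULT_WINDOWS,
) -> PromoterAcrMap:
    """Map genes to the ACRs in their proximal promoter window.

    A peak belongs to a gene iff its midpoint lies within the gene's
    proximal window (TSS - proximal_upstream .. TSS + proximal_downstream,
    strand-aware).  A midpoint inside several genes' windows is assigned
    to the gene with the nearest TSS (ties to the smaller gene_id).
    """
    cs = models.chrom_sizes
    windows_by_chrom: dict[str, list[tuple[int, int, int, str]]] = {}
    for g in models:
        w = promoter_window(g, windows.proximal_upstream, windows.proximal_downstream, cs)
        if w is None:
            continue
        windows_by_chrom.setdefault(g.interval.chrom, []).append(
            (w.start, w.end, g.tss, g.gene_id)
        )
    genes: dict[str, list[tuple[str, int]]] = {}
    for row in annotated_peaks.itertuples():
        cands = [
            (abs(row.midpoint - tss), gid)
            for (s, e, tss, gid) in windows_by_chrom.get(row.chrom, [])
            if s <= row.midpoint < e
        ]
        if not cands:
            continue
        _, gid = min(cands)
        genes.setdefault(gid, []).append((row.peak_id, int(row.length)))
    return PromoterAcrMap(genes={g: genes[g] for g in sorted(genes)})


@dataclass
class LengthGroupAssignment:
    """gene_id -> {bottom, middle, top} by ACR-length rank."""

    groups: pd.Series
    statistic_used: str

    def sizes(self) -> dict[str, int]:
        vc = self.groups.value_counts()
        return {g: int(vc.get(g, 0)) for g in GROUPS}


def assign_length_groups(
    gene_lengths: Mapping[str, int] | pd.Series, statistic: str = "single"
) -> LengthGroupAssignment:
    """Split genes into three equal groups by ACR length.

    Genes are sorted by length (ascending: bottom = shortest third) and
    cut into near-equal thirds.  A run of equal lengths straddling a cut
    cannot be split "easily": the whole run moves to the side that
    initially held the majority of it; an exact 50/50 run goes to the
    lower group.  The partition is total and deterministic.
    """
    lengths = pd.Series(dict(gene_lengths) if not isinstance(gene_lengths, pd.Series) else gene_lengths)
    n = len(lengths)
    if n < 3:
        raise ValueError("length grouping requires at least 3 genes")
    # ascending by (length, gene_id): deterministic order within ties
    order = lengths.iloc[np.lexsort((lengths.index.to_numpy(), lengths.to_numpy()))]
    vals = order.to_numpy()
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]  # bottom, middle, top
    group = np.repeat(np.arange(3), sizes)
    for g in (0, 1):
        upper = np.flatnonzero(group > g)
        if len(upper) == 0 or len(upper) == n:
            continue
        cut = upper[0]
        if cut == 0 or vals[cut - 1] != vals[cut]:
            continue
        run = np.flatnonzero(vals == vals[cut])
        lower_count = int((group[run] <= g).sum())
        upper_count = len(run) - lower_count
        target = group[cut - 1] if lower_count >= upper_count else group[cut]
        group[run] = target
    labels = pd.Series([GROUPS[i] for i in group], index=order.index, name="length_group")
    return LengthGroupAssignment(groups=labels.sort_index(), statistic_used=statistic)


def bin_expression(mean_fpkm: pd.Series) -> pd.Series:
    """Assign genes to the five FPKM bins [0,2), [2,5), [5,10), [10,30), >=30."""
    vals = pd.Series(mean_fpkm, dtype=float)
    if (vals < 0).any():
        bad = vals.index[vals < 0][0]
        raise ValueError(f"negative FPKM for gene {bad!r}")
    binned = pd.cut(vals, bins=EXPRESSION_BINS, labels=BIN_LABELS, right=False, include_lowest=True)
    return binned.rename("expression_bin")


def group_bin_table(groups: pd.Series, bins: pd.Series) -> pd.DataFrame:
    """Row-percentage table of expression bins per length group."""
    joined = pd.concat([pd.Series(groups, name="group"), pd.Series(bins, name="bin")], axis=1)
    if joined.isna().any().any():
        raise ValueError("every gene needs both a group and a bin")
    table = pd.crosstab(joined["group"], joined["bin"], dropna=False)
    table = table.reindex(index=list(GROUPS), columns=list(BIN_LABELS), fill_value=0).fillna(0).astype(int)
    row_tot = table.sum(axis=1)
    empty = row_tot[row_tot == 0].index.tolist()
    if empty:
        warnings.warn(f"empty length group(s): {empty}")
    pct = table.div(row_tot.replace(0, np.nan), axis=0).fillna(0.0) * 100.0
    return pct


def intensity_expression_correlation(
    peak_counts_norm: pd.DataFrame,
    fpkm: pd.DataFrame,
    dpi_gene_map: Mapping[str, str],
) -> pd.Series:
    """Pearson r across samples between a gene's DPI-peak intensity and
    its expression; NaN where either vector has zero variance."""
    common_cols = [c for c in peak_counts_norm.columns if c in fpkm.columns]
    if len(common_cols) != len(peak_counts_norm.columns) or len(common_cols) != len(fpkm.columns):
        raise ValueError("intensity and expression matrices must share the same samples")
    out = {}
    for gene, peak in dpi_gene_map.items():
        x = peak_counts_norm.loc[peak, common_cols].to_numpy(dtype=float)
        y = fpkm.loc[gene, common_cols].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[gene] = np.nan
            continue
        out[gene] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, name="r", dtype=float)


@dataclass
class ClusterAssignment:
    """gene_id -> cluster label (1..k, numbered by descending size)."""

    labels: pd.Series
    profiles: pd.DataFrame  # cluster x stage mean z-score profile

    @property
    def k(self) -> int:
        return self.profiles.shape[0]


def cluster_degs(
    fpkm_of_degs: pd.DataFrame,
    stage_map: pd.Series | Mapping[str, str],
    k: int = 6,
    seed: int | np.random.Generator = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """k-means clustering of per-gene temporal expression profiles.

    Expression is z-scored per gene across all samples, averaged within
    stage, and clustered on the resulting stage profiles.  Cluster labels
    are renumbered by descending cluster size for determinism.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(fpkm_of_degs) < k:
        raise ValueError(f"need at least k={k} genes, got {len(fpkm_of_degs)}")
    stage_map = pd.Series(stage_map)
    mat = fpkm_of_degs.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (mat - mean) / sd, 0.0)
    zdf = pd.DataFrame(z, index=fpkm_of_degs.index, columns=fpkm_of_degs.columns)
    stages = []
    for s in stage_map.loc[list(fpkm_of_degs.columns)]:
        if s not in stages:
            stages.append(s)
    prof = pd.DataFrame(
        {s: zdf[stage_map.index[stage_map == s].intersection(zdf.columns)].mean(axis=1)
         for s in stages}
    )
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(0, 2**31 - 1))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(prof.to_numpy())
    # renumber by descending size, ties by original label
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lab: (-sizes[lab], lab))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=prof.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, columns=stages)
    centers.index = pd.Index([remap[i] for i in range(k)], name="cluster")
    return ClusterAssignment(labels=labels, profiles=centers.sort_index())


@dataclass(frozen=True)
class OverlapTest:
    """Upper-tail hypergeometric test of a two-set overlap."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    p: float


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """P(overlap >= observed) when set_b is drawn at random from universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise ValueError("set_a is not contained in the universe")
    if not b <= u:
        raise ValueError("set_b is not contained in the universe")
    ov = len(a & b)
    p = float(stats.hypergeom.sf(ov - 1, len(u), len(a), len(b)))
    return OverlapTest(
        set_a_size=len(a), set_b_size=len(b), universe_size=len(u), overlap=ov,
        p=min(max(p, np.nextafter(0, 1)), 1.0),
    )
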