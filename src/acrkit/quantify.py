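"""Count normalisation, FPKM, and negative-binomial differential testing.

One differential engine serves both assays: differential peak intensity
(DPI) on ATAC read counts in peaks and differential gene expression
(DEG) on exonic read counts, at the shared thresholds adjusted
p < 0.05 and |log2 fold change| > 1.

The test is a per-feature negative-binomial Wald test on median-of-ratios
normalised counts with a moment estimate of the NB dispersion (no
shrinkage), Benjamini-Hochberg correction over the tested features, and
a Student-t reference distribution with the within-group degrees of
freedom — the small-sample analogue of the large-sample normal Wald test.
"""

from __future__ import annotations

import os
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "fpkm",
    "filter_expressed",
    "size_factors",
    "nb_differential",
    "significance_summary",
    "SignificanceSummary",
]


class CountMatrix:
    """Features x samples non-negative integer counts with sample metadata.

    ``samples`` is a DataFrame indexed by sample_id with at least columns
    ``stage`` and ``replicate``; an optional ``library_size`` column
    (total mapped fragments) is used by :func:`fpkm` when present.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame):
        counts = counts.copy()
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative entries in count matrix")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        samples = samples.copy()
        if "sample_id" in samples.columns:
            samples = samples.set_index("sample_id")
        missing = set(counts.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        self.counts = counts
        self.samples = samples.loc[list(counts.columns)]

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples["stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def stage_columns(self, stage: str) -> list[str]:
        cols = list(self.samples.index[self.samples["stage"] == stage])
        if not cols:
            raise ValueError(f"no samples for stage {stage!r}")
        return cols

    @classmethod
    def read(cls, counts_tsv: str | os.PathLike, samples_tsv: str | os.PathLike) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        samples = pd.read_csv(samples_tsv, sep="\t")
        return cls(counts, samples)

    def write(self, counts_tsv: str | os.PathLike, samples_tsv: str | os.PathLike) -> None:
        self.counts.to_csv(counts_tsv, sep="\t")
        self.samples.reset_index().rename(columns={"index": "sample_id"}).to_csv(
            samples_tsv, sep="\t", index=False
        )


def fpkm(
    counts: CountMatrix | pd.DataFrame,
    exonic_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped fragments.

    fpkm = count * 1e9 / (length_bp * library_size).  Library sizes
    default to the sample-sheet ``library_size`` column when available,
    else to per-sample column sums.
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        if library_sizes is None and "library_size" in counts.samples.columns:
            library_sizes = counts.samples["library_size"]
    else:
        mat = counts
    if library_sizes is None:
        library_sizes = mat.sum(axis=0)
    library_sizes = library_sizes.astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    missing = mat.index.difference(exonic_lengths.index)
    if len(missing):
        raise ValueError(f"no exonic length for feature {missing[0]!r}")
    lengths = exonic_lengths.loc[mat.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    return mat.div(lengths, axis=0).div(library_sizes.loc[mat.columns], axis=1) * 1e9


def filter_expressed(
    expr: pd.DataFrame,
    stage_map: pd.Series | dict,
    min_fpkm: float = 1.0,
    min_samples: int = 3,
) -> pd.Index:
    """Genes with FPKM strictly greater than ``min_fpkm`` in at least
    ``min_samples`` samples of at least one stage."""
    stage_map = pd.Series(stage_map)
    keep = pd.Series(False, index=expr.index)
    for stage in stage_map.unique():
        cols = stage_map.index[stage_map == stage]
        keep |= (expr[cols] > min_fpkm).sum(axis=1) >= min_samples
    return expr.index[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Features with a zero count in any sample are excluded from the
    reference; if none remain, falls back to library-size ratios with a
    warning.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    positive = (mat > 0).all(axis=1)
    if positive.sum() == 0:
        warnings.warn("no feature with nonzero counts in all samples; "
                      "falling back to library-size factors")
        factors = mat.sum(axis=0)
    else:
        logs = np.log(mat[positive])
        log_geomean = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_differential(
    counts: CountMatrix,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    min_dispersion: float = 1e-8,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial Wald test for ``contrast = (stage_b, stage_a)``.

    Positive log2 fold change means higher in ``stage_b`` ("B vs A").
    Returns one row per tested feature (all-zero features are excluded
    from testing and from the BH denominator) with columns base_mean,
    log2fc, se, p, padj and direction (up / down / ns).
    """
    stage_b, stage_a = contrast
    cols_b = counts.stage_columns(stage_b)
    cols_a = counts.stage_columns(stage_a)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both stages need >= 2 replicates")
    sub = counts.counts[cols_a + cols_b]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    tested = norm.index[(sub.sum(axis=1) > 0)]
    norm = norm.loc[tested]
    a = norm[cols_a].to_numpy(dtype=float)
    b = norm[cols_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()
    # pooled within-group variance -> moment estimate of NB dispersion
    s2 = ((a.var(axis=1, ddof=1) * (n_a - 1)) + (b.var(axis=1, ddof=1) * (n_b - 1))) / (
        n_a + n_b - 2
    )
    mu_bar = (mu_a * n_a + mu_b * n_b) / (n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu_bar > 0, (s2 - mu_bar) / np.square(mu_bar), min_dispersion)
    disp = np.maximum(disp, min_dispersion)

    log2fc = np.log2((mu_b + pseudocount) / (mu_a + pseudocount))
    # delta-method variance of log2 group means under NB(mu, disp)
    var_a = (mu_a + disp * mu_a**2) / n_a
    var_b = (mu_b + disp * mu_b**2) / n_b
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_a / (np.square(mu_a + pseudocount) * ln2sq)
        + var_b / (np.square(mu_b + pseudocount) * ln2sq)
    )
    se = np.where(se > 0, se, np.inf)
    wald = log2fc / se
    df = n_a + n_b - 2
    p = np.clip(2.0 * stats.t.sf(np.abs(wald), df=df), np.nextafter(0, 1), 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        (padj < alpha) & (log2fc > lfc_min),
        "up",
        np.where((padj < alpha) & (log2fc < -lfc_min), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "direction": direction,
        },
        index=pd.Index(tested, name="feature_id"),
    )


class SignificanceSummary(NamedTuple):
    down: int
    up: int
    total: int


def significance_summary(
    records: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0
) -> SignificanceSummary:
    """Count down- and up-regulated features at the shared thresholds."""
    sig = records["padj"] < alpha
    down = int((sig & (records["log2fc"] < -lfc_min)).sum())
    up = int((sig & (records["log2fc"] > lfc_min)).sum())
    return SignificanceSummary(down=down, up=up, total=down + up)
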