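"""Permutation fold enrichment of peaks in genomic feature classes.

Fold enrichment is observed class counts divided by the mean class
counts of length-matched random region sets: each permutation draws, for
every real peak, one random region of the same length, on a chromosome
sampled with probability proportional to its length (genome-uniform
placement), start uniform over the valid range.  Also provides the
chromosome-length normalisation (normalised chromatin length =
total peaks x chrom length / total genome length), its Pearson
correlation with per-chromosome peak counts, and the one-way
ANOVA + Tukey HSD comparison of peak lengths across feature classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genome_model import (
    CLASS_PRIORITY,
    ChromSizes,
    GeneModelSet,
    GenomeAnnotator,
    WindowsConfig,
    DEFAULT_WINDOWS,
)
from .peaks import PeakSet

__all__ = [
    "EnrichmentResult",
    "UndefinedCorrelationError",
    "sample_random_regions",
    "fold_enrichment",
    "normalized_chrom_lengths",
    "chrom_correlation",
    "region_length_comparison",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


def _chrom_arrays(chrom_sizes: ChromSizes) -> tuple[list[str], np.ndarray]:
    names = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in names], dtype=np.int64)
    return names, lengths


def _sample_positions(
    lengths: np.ndarray,
    chrom_names: list[str],
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
    chrom_weighting: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised draw of (chrom index, start) for length-matched regions."""
    n = len(lengths)
    max_len = int(lengths.max()) if n else 0
    if max_len > int(chrom_lengths.max(initial=0)):
        raise ValueError(f"region length {max_len} exceeds every chromosome")
    chrom_idx = np.empty(n, dtype=np.int64)
    if (lengths <= chrom_lengths.min()).all():
        # fast path: every chromosome is eligible for every length
        p = (
            chrom_lengths / chrom_lengths.sum()
            if chrom_weighting == "length"
            else np.full(len(chrom_lengths), 1 / len(chrom_lengths))
        )
        chrom_idx[:] = rng.choice(len(chrom_lengths), size=n, p=p)
    else:
        for i, ln in enumerate(lengths):
            elig = np.flatnonzero(chrom_lengths >= ln)
            w = chrom_lengths[elig].astype(float) if chrom_weighting == "length" else None
            p = w / w.sum() if w is not None else None
            chrom_idx[i] = rng.choice(elig, p=p)
    span = chrom_lengths[chrom_idx] - lengths  # start uniform on [0, span]
    starts = np.floor(rng.random(n) * (span + 1)).astype(np.int64)
    return chrom_idx, starts


def sample_random_regions(
    lengths,
    chrom_sizes: ChromSizes,
    rng: np.random.Generator,
    chrom_weighting: str = "length",
) -> PeakSet:
    """Length-matched random regions; may overlap one another."""
    lengths = np.asarray(lengths, dtype=np.int64)
    names, chrom_lengths = _chrom_arrays(chrom_sizes)
    chrom_idx, starts = _sample_positions(lengths, names, chrom_lengths, rng, chrom_weighting)
    rows = [
        (names[ci], int(s), int(s + ln))
        for ci, s, ln in zip(chrom_idx, starts, lengths)
    ]
    ids = [f"random_{i + 1}" for i in range(len(rows))]
    return PeakSet.from_intervals(rows, label="random", ids=ids)


@dataclass
class EnrichmentResult:
    """Observed vs permutation-expected peak counts per feature class."""

    table: pd.DataFrame  # index: feature class; columns: observed, expected, sd, fold
    n_perm: int

    def __repr__(self) -> str:  # pragma: no cover
        return f"EnrichmentResult(n_perm={self.n_perm})\n{self.table}"


def fold_enrichment(
    peaks: PeakSet,
    models: GeneModelSet | GenomeAnnotator,
    chrom_sizes: ChromSizes,
    n_perm: int = 5000,
    rng: np.random.Generator | None = None,
    windows: WindowsConfig = DEFAULT_WINDOWS,
    chrom_weighting: str = "length",
    chunk_size: int = 2_000_000,
) -> EnrichmentResult:
    """Permutation fold enrichment of peaks across feature classes.

    observed: class counts of the real peaks (midpoint classification);
    expected: mean class counts over ``n_perm`` length-matched random
    sets; fold = observed / expected (NaN where expected is 0).  ``sd``
    is the standard deviation of the per-permutation counts, so the
    standard error of ``expected`` is ``sd / sqrt(n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    ann = models if isinstance(models, GenomeAnnotator) else GenomeAnnotator(models, windows)
    labels = [fl.value for fl in CLASS_PRIORITY]
    n_cls = len(labels)

    df = peaks.df
    lengths = (df["end"] - df["start"]).to_numpy()
    mids = (df["start"] + (df["end"] - df["start"]) // 2).to_numpy()
    observed = np.zeros(n_cls, dtype=np.int64)
    for chrom, sub in df.groupby("chrom", sort=False):
        codes = ann.classify_positions(chrom, mids[sub.index.to_numpy()])
        observed += np.bincount(codes, minlength=n_cls)

    names, chrom_lengths = _chrom_arrays(chrom_sizes)
    n = len(lengths)
    perm_counts = np.zeros((n_perm, n_cls), dtype=np.int64)
    perms_per_chunk = max(1, chunk_size // max(n, 1)) if n else n_perm
    done = 0
    while done < n_perm:
        block = min(perms_per_chunk, n_perm - done)
        ln = np.tile(lengths, block)
        chrom_idx, starts = _sample_positions(ln, names, chrom_lengths, rng, chrom_weighting)
        mids_r = starts + ln // 2
        codes = np.empty(len(ln), dtype=np.int8)
        for ci in np.unique(chrom_idx):
            sel = chrom_idx == ci
            codes[sel] = ann.classify_positions(names[ci], mids_r[sel])
        perm_id = np.repeat(np.arange(block), 0) if n == 0 else np.repeat(np.arange(block), n)
        flat = np.bincount(perm_id * n_cls + codes, minlength=block * n_cls)
        perm_counts[done:done + block] = flat.reshape(block, n_cls)
        done += block
    expected = perm_counts.mean(axis=0)
    sd = perm_counts.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n_cls)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(expected > 0, observed / expected, np.nan)
    table = pd.DataFrame(
        {"observed": observed, "expected": expected, "sd": sd, "fold": fold},
        index=pd.Index(labels, name="feature_class"),
    )
    return EnrichmentResult(table=table, n_perm=n_perm)


def normalized_chrom_lengths(chrom_sizes: ChromSizes, total_peaks: int) -> pd.Series:
    """Normalised chromatin length per chromosome.

    total peak number x chrom length / total genome length; the values
    sum to the total peak number.
    """
    if total_peaks < 0:
        raise ValueError("total_peaks must be >= 0")
    if len(chrom_sizes) == 0:
        raise ValueError("empty genome")
    lengths = chrom_sizes.to_series().astype(float)
    return (total_peaks * lengths / lengths.sum()).rename("normalized_length")


def chrom_correlation(normalized_lengths: pd.Series, peak_counts: pd.Series) -> tuple[float, float]:
    """Pearson r (and r^2) between normalised lengths and peak counts."""
    joined = pd.concat(
        [normalized_lengths.rename("x"), peak_counts.rename("y")], axis=1, join="inner"
    ).dropna()
    if len(joined) < 3:
        raise ValueError("correlation requires at least 3 chromosomes")
    if joined["x"].nunique() == 1 or joined["y"].nunique() == 1:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(stats.pearsonr(joined["x"], joined["y"]).statistic)
    return r, r * r


@dataclass
class LengthComparison:
    """One-way ANOVA over peak lengths by class, with Tukey HSD letters."""

    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]  # class -> letter group(s); shared letter = not distinct


def _letter_display(groups: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display from the non-significance graph.

    Maximal cliques of the "not significantly different" graph each get a
    letter; a group's label is the sorted concatenation of its letters.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from((tuple(p) for p in nonsig_pairs if len(p) == 2))
    cliques = sorted(nx.find_cliques(g), key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {grp: [] for grp in groups}
    for i, clique in enumerate(cliques):
        for grp in clique:
            letters[grp].append(alphabet[i % len(alphabet)])
    return {grp: "".join(sorted(ls)) for grp, ls in letters.items()}


def region_length_comparison(
    annotated_peaks: pd.DataFrame, alpha: float = 0.05
) -> LengthComparison:
    """Compare peak lengths across feature classes (ANOVA + Tukey HSD).

    Classes with fewer than 2 peaks are excluded with a warning.  The
    letter grouping marks classes sharing a letter as not significantly
    different at ``alpha``.
    """
    df = annotated_peaks[["feature_class", "length"]].copy()
    sizes = df["feature_class"].value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"excluding classes with < 2 peaks: {small}")
        df = df[~df["feature_class"].isin(small)]
    groups = sorted(df["feature_class"].unique())
    if len(groups) < 2:
        raise ValueError("length comparison requires >= 2 classes with >= 2 peaks")
    samples = [df.loc[df["feature_class"] == g, "length"].to_numpy(float) for g in groups]
    f_stat, p = stats.f_oneway(*samples)
    res = pairwise_tukeyhsd(df["length"].to_numpy(float), df["feature_class"].to_numpy(), alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    tukey = tukey.rename(columns={"p-adj": "p_adj"})
    tukey["p_adj"] = res.pvalues  # full precision, not the rounded summary
    tukey["reject"] = res.reject
    nonsig = {
        frozenset((row.group1, row.group2))
        for row in tukey.itertuples()
        if not row.reject
    }
    letters = _letter_display(groups, nonsig)
    return LengthComparison(
        anova_f=float(f_stat), anova_p=float(p), tukey=tukey, letters=letters
    )
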