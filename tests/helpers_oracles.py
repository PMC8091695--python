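"""Independent brute-force oracles used by the test suite.

These label every genomic position explicitly (per-base painting) or
enumerate outcomes directly, and are deliberately independent of the
interval-arithmetic implementations they check.
"""

from __future__ import annotations

import numpy as np

# class codes matching acrkit.genome_model.CLASS_PRIORITY
PROMOTER, TTS, EXON, INTRON, INTERGENIC = 0, 1, 2, 3, 4


def paint_feature_classes(models, windows, chrom: str, chrom_len: int) -> np.ndarray:
    """Per-base feature-class labels by painting in increasing priority."""
    label = np.full(chrom_len, INTERGENIC, dtype=np.int8)

    def paint(mask_start, mask_end, code):
        s, e = max(mask_start, 0), min(mask_end, chrom_len)
        if s < e:
            label[s:e] = code

    genes = [g for g in models if g.interval.chrom == chrom]
    for g in genes:  # gene bodies (introns by default)
        paint(g.interval.start, g.interval.end, INTRON)
    for g in genes:
        for ex in g.exons:
            paint(ex.start, ex.end, EXON)
    for g in genes:  # tts windows
        if g.interval.strand == "+":
            paint(g.tes - windows.tts_upstream, g.tes + windows.tts_downstream + 1, TTS)
        else:
            paint(g.tes - windows.tts_downstream, g.tes + windows.tts_upstream + 1, TTS)
    for g in genes:  # promoter windows win over everything
        if g.interval.strand == "+":
            paint(g.tss - windows.promoter_upstream, g.tss + windows.promoter_downstream + 1, PROMOTER)
        else:
            paint(g.tss - windows.promoter_downstream, g.tss + windows.promoter_upstream + 1, PROMOTER)
    return label


def paint_proximal(models, windows, chrom: str, chrom_len: int) -> np.ndarray:
    mask = np.zeros(chrom_len, dtype=bool)
    for g in models:
        if g.interval.chrom != chrom:
            continue
        if g.interval.strand == "+":
            s, e = g.tss - windows.proximal_upstream, g.tss + windows.proximal_downstream + 1
        else:
            s, e = g.tss - windows.proximal_downstream, g.tss + windows.proximal_upstream + 1
        mask[max(s, 0):min(e, chrom_len)] = True
    return mask


def coverage_mask(intervals, chrom_len: int) -> np.ndarray:
    """Boolean per-base coverage of a list of (start, end) intervals."""
    mask = np.zeros(chrom_len, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def consensus_oracle(replicate_intervals, chrom_len: int) -> list[tuple[int, int]]:
    """Maximal runs covered in every replicate (per-base AND)."""
    mask = np.ones(chrom_len, dtype=bool)
    for intervals in replicate_intervals:
        mask &= coverage_mask(intervals, chrom_len)
    return mask_to_intervals(mask)


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def overlaps_mask(start: int, end: int, mask: np.ndarray) -> bool:
    return bool(mask[start:end].any())


def hypergeom_upper_tail_exact(universe: int, k_a: int, k_b: int, overlap: int) -> float:
    """P(|A ∩ B| >= overlap) by direct combinatorial enumeration."""
    from math import comb

    total = comb(universe, k_b)
    acc = 0
    for ov in range(overlap, min(k_a, k_b) + 1):
        acc += comb(k_a, ov) * comb(universe - k_a, k_b - ov)
    return acc / total


def naive_pwm_hits(seq: str, log_odds: np.ndarray, threshold: float) -> list[int]:
    """All-positions, both-strand PWM scan by explicit loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    w = log_odds.shape[0]
    hits = []
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        if any(b not in base_idx for b in window):
            continue
        fwd = sum(log_odds[j, base_idx[b]] for j, b in enumerate(window))
        rc = "".join(comp[b] for b in reversed(window))
        rev = sum(log_odds[j, base_idx[b]] for j, b in enumerate(rc))
        if fwd >= threshold or rev >= threshold:
            hits.append(i)
    return hits


def tukey_p_manual(samples: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Pairwise Tukey HSD p-values from the studentized-range distribution."""
    from scipy.stats import studentized_range

    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df = n_total - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se = np.sqrt(mse / 2 * (1 / ni + 1 / nj))
            q = abs(samples[i].mean() - samples[j].mean()) / se
            out[(i, j)] = float(studentized_range.sf(q, k, df))
    return out
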