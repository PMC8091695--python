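"""PWM motif scanning and enrichment in peak-centered windows.

Sequences are taken from a 2 x halfwidth window around each peak center
(default halfwidth 100 bp, i.e. -100 .. +100 relative to the center).
Motifs are position-weight matrices scanned by log-odds score on both
strands; a sequence counts as a hit when at least one window position
scores at or above the motif threshold.  Enrichment of hit frequency in
target vs background sequences uses an upper-tail hypergeometric test on
the pooled 2x2 table, flagged at p < 0.01 by default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy import stats

from .genome_model import ChromSizes, GenomicInterval
from .peaks import PeakSet

__all__ = [
    "PWM",
    "MotifEnrichment",
    "read_meme",
    "write_meme",
    "centered_windows",
    "extract_sequences",
    "pwm_scan",
    "motif_enrichment",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position-weight matrix with log-odds scoring.

    ``matrix`` is width x 4 base probabilities (columns A, C, G, T, rows
    summing to 1).  A pseudocount is added to the probabilities before
    taking log-odds against the background.  The default score threshold
    is ``threshold_fraction`` of the maximum achievable log-odds score.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3
    threshold_fraction: float = 0.8
    threshold: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")
        probs = self.matrix + self.pseudocount
        probs /= probs.sum(axis=1, keepdims=True)
        self.log_odds = np.log2(probs / np.asarray(self.background, dtype=float))
        self.max_score = float(self.log_odds.max(axis=1).sum())
        if self.threshold is None:
            self.threshold = self.threshold_fraction * self.max_score

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> np.ndarray:
        """Log-odds matrix for the reverse-complement strand."""
        return self.log_odds[::-1, ::-1]


def read_meme(path: str | os.PathLike) -> list[PWM]:
    """Read PWMs from a MEME (minimal) format motif file."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in _BASES] for i in range(m.length)])
        bg = np.array([m.background.get(b, 0.25) for b in _BASES]) if m.background else np.full(4, 0.25)
        out.append(PWM(motif_id=m.name or m.base_id, matrix=mat, background=bg))
    return out


def write_meme(pwms: list[PWM], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n")
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def centered_windows(
    peaks: PeakSet, halfwidth: int = 100, chrom_sizes: ChromSizes | None = None
) -> list[GenomicInterval]:
    """Windows of midpoint +- halfwidth around each peak center.

    Length is 2 x halfwidth when unclipped; clipped to chromosome bounds
    when sizes are given.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    out = []
    for row in peaks:
        mid = row.start + (row.end - row.start) // 2
        start = max(mid - halfwidth, 0)
        end = mid + halfwidth
        if chrom_sizes is not None:
            end = min(end, chrom_sizes[row.chrom])
        out.append(GenomicInterval(row.chrom, start, end))
    return out


def extract_sequences(
    intervals: list[GenomicInterval], fasta_path: str | os.PathLike
) -> list[str]:
    """Uppercase sequences for the intervals, in order."""
    if not intervals:
        return []
    fa = Fasta(str(fasta_path))
    seqs = []
    for iv in intervals:
        if iv.chrom not in fa:
            raise ValueError(f"chromosome {iv.chrom!r} not in FASTA")
        if iv.end > len(fa[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence length"
            )
        seqs.append(str(fa[iv.chrom][iv.start:iv.end]).upper())
    return seqs


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(len(arr), 4, dtype=np.int8)  # 4 = N / other
    for base, i in _CODE.items():
        code[arr == ord(base)] = i
    return code


def _window_scores(code: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; NaN where the window contains N."""
    w = lo.shape[0]
    n_win = len(code) - w + 1
    if n_win <= 0:
        return np.empty(0)
    idx = np.arange(n_win)[:, None] + np.arange(w)[None, :]
    win = code[idx]  # n_win x w
    valid = (win < 4).all(axis=1)
    safe = np.where(win < 4, win, 0)
    scores = lo[np.arange(w)[None, :], safe].sum(axis=1)
    scores[~valid] = np.nan
    return scores


def pwm_scan(sequence: str, pwm: PWM, threshold: float | None = None) -> np.ndarray:
    """Positions (window starts, forward coordinates) where the log-odds
    score meets the threshold on either strand; N windows are skipped."""
    thr = pwm.threshold if threshold is None else threshold
    code = _encode(sequence)
    fwd = _window_scores(code, pwm.log_odds)
    rev = _window_scores(code, pwm.reverse_complement())
    with np.errstate(invalid="ignore"):
        hits = (fwd >= thr) | (rev >= thr)
    return np.flatnonzero(hits)


@dataclass(frozen=True)
class MotifEnrichment:
    motif_id: str
    target_with_hit: int
    target_total: int
    background_with_hit: int
    background_total: int
    p: float
    flagged: bool


def motif_enrichment(
    target_seqs: list[str],
    background_seqs: list[str],
    pwms: list[PWM],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-motif hit-frequency enrichment of targets over background.

    A sequence is a hit when it contains >= 1 scoring position.  p is the
    upper tail of the hypergeometric distribution on the pooled 2x2
    (target + background sequences as the urn).
    """
    if not pwms:
        return pd.DataFrame(
            columns=["motif_id", "target_with_hit", "target_total",
                     "background_with_hit", "background_total", "p", "flagged"]
        )
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sequence sets must be non-empty")
    rows = []
    for pwm in pwms:
        t_hit = sum(1 for s in target_seqs if len(pwm_scan(s, pwm)) > 0)
        b_hit = sum(1 for s in background_seqs if len(pwm_scan(s, pwm)) > 0)
        n_t, n_b = len(target_seqs), len(background_seqs)
        p = float(stats.hypergeom.sf(t_hit - 1, n_t + n_b, t_hit + b_hit, n_t))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            MotifEnrichment(
                motif_id=pwm.motif_id,
                target_with_hit=t_hit,
                target_total=n_t,
                background_with_hit=b_hit,
                background_total=n_b,
                p=p,
                flagged=p < alpha,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
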