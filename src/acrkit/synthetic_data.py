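"""Seeded synthetic study generator with planted ground truth.

Emulates a three-stage, four-replicate ATAC-seq + RNA-seq design on a
small genome: reproducible replicate peak calls around stage truth
peaks (common across stages or stage-specific, preferentially placed in
proximal promoter windows), negative-binomial read counts with planted
log2 fold changes on a subset of common peaks, gene expression following
six temporal archetype profiles, and a motif written into a fraction of
stage-specific peak windows.  Everything derives from one seed; the same
seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_model import ChromSizes
from .motifs import PWM, write_meme
from .quantify import CountMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticBundle", "generate", "plant_counts"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: six temporal archetypes (stage-level expression multipliers) echoing
#: late induction, monotone rise, monotone fall, early fall, mid peak and
#: a mid trough
DEFAULT_ARCHETYPES: tuple[tuple[float, float, float], ...] = (
    (1.0, 1.0, 8.0),
    (1.0, 3.0, 9.0),
    (9.0, 3.0, 1.0),
    (8.0, 1.0, 1.0),
    (1.0, 8.0, 2.0),
    (8.0, 1.0, 4.0),
)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic bundle."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 900_000,
            "chr2": 750_000,
            "chr3": 600_000,
            "chr4": 450_000,
            "chr5": 300_000,
        }
    )
    n_genes: int = 300
    stages: tuple[str, ...] = ("S1", "S2", "S3")
    replicates_per_stage: int = 4
    n_common_peaks: int = 400
    n_stage_specific: tuple[int, ...] = (40, 80, 160)
    promoter_peak_fraction: float = 0.30
    multi_acr_fraction: float = 0.08  # promoter peaks re-using an already-hit gene
    peak_length_range: tuple[int, int] = (200, 800)
    replicate_reproducibility: float = 0.9
    end_jitter_bp: int = 20
    n_noise_peaks_per_replicate: int = 25
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    dpi_fraction: float = 0.15
    planted_log2fc: float = 2.0
    n_deg_genes: int = 180
    cluster_archetypes: tuple[tuple[float, float, float], ...] = DEFAULT_ARCHETYPES
    low_expression_fraction: float = 0.10
    library_size: float = 2e7
    motif_plant_rate: float = 0.5
    motif_consensus: str = "TGACGTCATC"
    motif_target_stage: str | None = None  # default: last stage
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.replicate_reproducibility <= 1):
            raise ValueError("replicate_reproducibility must be in [0, 1]")
        if not (0 <= self.promoter_peak_fraction <= 1):
            raise ValueError("promoter_peak_fraction must be in [0, 1]")
        if len(self.n_stage_specific) != len(self.stages):
            raise ValueError("n_stage_specific must have one entry per stage")
        if any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")


@dataclass
class SyntheticTruth:
    """Planted parameters the pipeline is tested against."""

    peaks: dict[str, dict]              # peak_id -> chrom/start/end/kind/stage/gene_id
    stage_specific: dict[str, list[str]]
    common: list[str]
    dpi: dict[str, dict]                # planted peak_id -> multipliers + per-contrast lfc
    null_common: list[str]
    peak_base_mean: dict[str, float]
    gene_clusters: dict[str, int]
    deg_ids: list[str]
    low_expression_ids: list[str]
    gene_fpkm: dict[str, list[float]]   # gene_id -> per-stage target FPKM
    exonic_lengths: dict[str, int]
    promoter_map: dict[str, list[str]]  # gene_id -> promoter peak ids
    motif_planted_peaks: list[str]
    motif_target_stage: str
    motif_id: str

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticBundle:
    """File paths of an emitted bundle plus the in-memory truth."""

    outdir: Path
    chrom_sizes: Path
    fasta: Path
    gtf: Path
    replicate_peaks: dict[str, list[Path]]  # stage -> per-replicate narrowPeak
    peak_counts: Path
    gene_counts: Path
    samples: Path
    meme: Path
    truth_json: Path
    truth: SyntheticTruth
    config: SyntheticConfig


class _Occupancy:
    """Non-overlap bookkeeping for placed intervals, with a margin."""

    def __init__(self, chrom_lengths: dict[str, int], margin: int):
        self.lengths = chrom_lengths
        self.margin = margin
        self.intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        if start < 0 or end > self.lengths[chrom]:
            return False
        m = self.margin
        return all(e + m <= start or end + m <= s for s, e in self.intervals[chrom])

    def add(self, chrom: str, start: int, end: int) -> None:
        self.intervals[chrom].append((start, end))


def _place_genes(config: SyntheticConfig, rng: np.random.Generator):
    """Non-overlapping gene models, count per chromosome ~ length."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    raw = config.n_genes * lengths / lengths.sum()
    per_chrom = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - per_chrom))[: config.n_genes - per_chrom.sum()]:
        per_chrom[i] += 1
    genes = []
    gid = 0
    margin = 3000  # room for promoter windows and flanks
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        glens = rng.integers(2000, 6001, size=n)
        free = config.chrom_lengths[chrom] - 2 * margin - int(glens.sum()) - (n - 1) * 1000
        if free < 0:
            raise ValueError(
                f"infeasible config: {n} genes do not fit on {chrom}"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        extra = np.diff(np.concatenate([[0], cuts]))
        pos = margin
        for j in range(n):
            pos += int(extra[j])
            start = pos
            end = start + int(glens[j])
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            # odd segments are introns: 2*n_exons - 1 random segments
            w = rng.random(2 * n_exons - 1) + 0.2
            seg = np.floor((end - start) * w / w.sum()).astype(int)
            seg = np.maximum(seg, 20)
            seg[-1] = (end - start) - int(seg[:-1].sum())
            bounds = start + np.concatenate([[0], np.cumsum(seg)])
            exons = [
                (int(bounds[k]), int(bounds[k + 1])) for k in range(0, 2 * n_exons - 1, 2)
            ]
            gid += 1
            genes.append(
                {
                    "gene_id": f"G{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "exons": exons,
                    "tss": start if strand == "+" else end - 1,
                }
            )
            pos = end + 1000
    return genes


def _write_gtf(genes: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g["gene_id"]}"; transcript_id "{g["gene_id"]}.t1";'
            fh.write(
                f'{g["chrom"]}\tacrkit_sim\tgene\t{g["start"] + 1}\t{g["end"]}\t.\t{g["strand"]}\t.\t{attrs}\n'
            )
            for s, e in g["exons"]:
                fh.write(
                    f'{g["chrom"]}\tacrkit_sim\texon\t{s + 1}\t{e}\t.\t{g["strand"]}\t.\t{attrs}\n'
                )


def _proximal_windows(genes: list[dict]) -> dict[str, list[tuple[int, int, int, str]]]:
    """Per-chromosome (start, end, tss, gene_id) proximal windows (-1 kb .. +100)."""
    out: dict[str, list[tuple[int, int, int, str]]] = {}
    for g in genes:
        if g["strand"] == "+":
            s, e = g["tss"] - 1000, g["tss"] + 101
        else:
            s, e = g["tss"] - 100, g["tss"] + 1001
        out.setdefault(g["chrom"], []).append((s, e, g["tss"], g["gene_id"]))
    return out


def _place_peak_in_promoter(
    gene: dict,
    length: int,
    occ: _Occupancy,
    prox: dict[str, list[tuple[int, int, int, str]]],
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Place a peak whose midpoint maps unambiguously to the gene's
    proximal promoter window (nearest-TSS rule, lexicographic ties)."""
    for _ in range(20):
        # midpoint offset upstream of the TSS, within -800 .. +80
        off = int(rng.integers(-800, 81))
        mid = gene["tss"] + (off if gene["strand"] == "+" else -off)
        start = mid - length // 2
        end = start + length
        if not occ.is_free(gene["chrom"], start, end):
            continue
        containing = [
            (abs(mid - tss), gid)
            for (s, e, tss, gid) in prox.get(gene["chrom"], [])
            if s <= mid < e
        ]
        if containing and min(containing)[1] == gene["gene_id"]:
            return start, end
    return None


def _place_peak_anywhere(
    chrom_lengths: dict[str, int],
    genic_flanks: dict[str, list[tuple[int, int]]],
    length: int,
    occ: _Occupancy,
    rng: np.random.Generator,
    avoid_genic: bool = True,
) -> tuple[str, int, int] | None:
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(200):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(0, chrom_lengths[chrom] - length + 1))
        end = start + length
        if avoid_genic and any(
            s < end and start < e for s, e in genic_flanks.get(chrom, [])
        ):
            continue
        if occ.is_free(chrom, start, end):
            return chrom, start, end
    return None


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion <= 1e-12:
        out[pos] = rng.poisson(mu[pos])
        return out
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu[pos] * dispersion)
    out[pos] = rng.poisson(lam)
    return out


def plant_counts(
    truth: SyntheticTruth, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[CountMatrix, CountMatrix, dict[str, np.ndarray]]:
    """Draw the peak and gene count matrices from the planted means.

    Peak counts follow NB(base_mean x stage multiplier, dispersion) for
    the common-peak universe; gene counts follow the per-stage FPKM
    targets converted through exonic length and library size.  Returns
    (peak counts, gene counts, exonic lengths/library sizes side info).
    """
    stages = list(config.stages)
    reps = config.replicates_per_stage
    sample_ids = [f"{s}_rep{r + 1}" for s in stages for r in range(reps)]
    stage_of = np.repeat(np.arange(len(stages)), reps)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "stage": [stages[i] for i in stage_of],
            "replicate": [r + 1 for _ in stages for r in range(reps)],
        }
    )

    peak_ids = list(truth.common)
    mult = np.ones((len(peak_ids), len(stages)))
    for i, pid in enumerate(peak_ids):
        if pid in truth.dpi:
            mult[i] = np.asarray(truth.dpi[pid]["multipliers"], dtype=float)
    base = np.array([truth.peak_base_mean[p] for p in peak_ids])
    mu_peaks = base[:, None] * mult[:, stage_of]
    peak_counts = _nb_draw(mu_peaks, config.nb_dispersion, rng)
    peak_cm = CountMatrix(
        pd.DataFrame(peak_counts, index=pd.Index(peak_ids, name="peak_id"), columns=sample_ids),
        samples,
    )

    gene_ids = sorted(truth.gene_fpkm)
    fpkm_targets = np.array([truth.gene_fpkm[g] for g in gene_ids])  # genes x stages
    exlen = np.array([truth.exonic_lengths[g] for g in gene_ids], dtype=float)
    lib = config.library_size * np.exp(rng.normal(0.0, 0.05, size=len(sample_ids)))
    side = {"library_sizes": lib}
    samples_g = samples.copy()
    samples_g["library_size"] = lib
    mu_genes = fpkm_targets[:, stage_of] * exlen[:, None] * lib[None, :] / 1e9
    gene_counts = _nb_draw(mu_genes, config.nb_dispersion, rng)
    gene_cm = CountMatrix(
        pd.DataFrame(gene_counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        samples_g,
    )
    return peak_cm, gene_cm, side


def generate(config: SyntheticConfig, outdir: str | os.PathLike) -> SyntheticBundle:
    """Emit the full synthetic bundle into ``outdir`` and return paths + truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stages = list(config.stages)
    chrom_lengths = dict(config.chrom_lengths)

    # --- genome scaffold and genes ------------------------------------
    cs = ChromSizes(chrom_lengths)
    cs_path = outdir / "chrom.sizes"
    cs.write(cs_path)
    genes = _place_genes(config, rng)
    gtf_path = outdir / "genes.gtf"
    _write_gtf(genes, gtf_path)
    genic_flanks: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        genic_flanks.setdefault(g["chrom"], []).append((g["start"] - 2000, g["end"] + 2000))

    # --- truth peak placement -----------------------------------------
    jitter = config.end_jitter_bp
    occ = _Occupancy(chrom_lengths, margin=2 * jitter + 10)
    prox_windows = _proximal_windows(genes)
    free_genes = list(genes)
    rng.shuffle(free_genes)
    peaks: dict[str, dict] = {}
    promoter_map: dict[str, list[str]] = {}

    gene_by_id = {g["gene_id"]: g for g in genes}

    def place_block(n: int, kind: str, stage: str | None, prefix: str) -> list[str]:
        ids = []
        block_genes: list[str] = []
        n_prom = int(round(config.promoter_peak_fraction * n))
        for i in range(n):
            length = int(rng.integers(*config.peak_length_range))
            pid = f"{prefix}_{i + 1:04d}"
            placed = None
            gene_id = None
            if i < n_prom:
                # occasionally give an already-hit gene a second, shorter
                # promoter ACR (multi-ACR genes, a minority of the map)
                if block_genes and rng.random() < config.multi_acr_fraction:
                    cand = block_genes[int(rng.integers(len(block_genes)))]
                    short = int(rng.integers(150, 351))
                    spot = _place_peak_in_promoter(
                        gene_by_id[cand], short, occ, prox_windows, rng
                    )
                    if spot is not None:
                        placed = (gene_by_id[cand]["chrom"], *spot)
                        gene_id = cand
                        length = short
                while placed is None and free_genes:
                    gene = free_genes.pop()
                    spot = _place_peak_in_promoter(gene, length, occ, prox_windows, rng)
                    if spot is not None:
                        placed = (gene["chrom"], *spot)
                        gene_id = gene["gene_id"]
                        block_genes.append(gene_id)
                        break
            if placed is None:
                placed = _place_peak_anywhere(
                    chrom_lengths, genic_flanks, length, occ, rng, avoid_genic=True
                )
            if placed is None:
                raise ValueError("infeasible config: cannot place all peaks without overlap")
            chrom, s, e = placed
            occ.add(chrom, s, e)
            peaks[pid] = {
                "chrom": chrom, "start": int(s), "end": int(e),
                "kind": kind, "stage": stage, "gene_id": gene_id,
            }
            if gene_id is not None:
                promoter_map.setdefault(gene_id, []).append(pid)
            ids.append(pid)
        return ids

    common_ids = place_block(config.n_common_peaks, "common", None, "common")
    stage_specific = {
        stage: place_block(n, "specific", stage, f"{stage}_spec")
        for stage, n in zip(stages, config.n_stage_specific)
    }

    # --- planted DPI on common peaks ----------------------------------
    f = 2.0 ** config.planted_log2fc
    patterns = [(1.0, 1.0, f), (f, f, 1.0), (1.0, f, 1.0)]
    n_dpi = int(round(config.dpi_fraction * len(common_ids)))
    dpi_ids = list(rng.choice(common_ids, size=n_dpi, replace=False))
    dpi: dict[str, dict] = {}
    for i, pid in enumerate(sorted(dpi_ids)):
        mult = list(patterns[i % len(patterns)])
        lfc = {
            f"{stages[b]}_vs_{stages[a]}": float(np.log2(mult[b] / mult[a]))
            for a in range(len(stages))
            for b in range(a + 1, len(stages))
        }
        dpi[pid] = {"multipliers": mult, "lfc": lfc}
    null_common = [p for p in common_ids if p not in dpi]
    base_mean = {
        pid: float(np.exp(rng.normal(np.log(config.nb_mean), 0.4))) for pid in common_ids
    }

    # --- gene expression truth ----------------------------------------
    gene_ids = [g["gene_id"] for g in genes]
    exonic_len = {
        g["gene_id"]: sum(e - s for s, e in g["exons"]) for g in genes
    }
    promoter_genes = set(promoter_map)
    non_promoter = [g for g in gene_ids if g not in promoter_genes]
    rng.shuffle(non_promoter)
    n_low = int(round(config.low_expression_fraction * len(gene_ids)))
    low_ids = sorted(non_promoter[:n_low])
    deg_pool = [g for g in gene_ids if g not in set(low_ids)]
    rng.shuffle(deg_pool)
    deg_ids = sorted(deg_pool[: config.n_deg_genes])
    gene_clusters = {g: (i % len(config.cluster_archetypes)) + 1 for i, g in enumerate(deg_ids)}

    common_peak_len = {pid: peaks[pid]["end"] - peaks[pid]["start"] for pid in common_ids}
    gene_fpkm: dict[str, list[float]] = {}
    for g in gene_ids:
        if g in gene_clusters:
            arch = config.cluster_archetypes[gene_clusters[g] - 1]
            base = float(np.exp(rng.normal(np.log(5.0), 0.4)))
            prof = [base * a for a in arch]
        elif g in set(low_ids):
            prof = [0.3] * len(stages)
        elif g in promoter_genes:
            # expression tied to promoter ACR length: long ACR -> high FPKM
            plen = max(common_peak_len.get(p, 300) for p in promoter_map[g])
            base = float(np.exp(np.log(plen / 25.0) + rng.normal(0.0, 0.5)))
            prof = [base] * len(stages)
        else:
            prof = [float(np.exp(rng.normal(np.log(8.0), 1.0)))] * len(stages)
        gene_fpkm[g] = [float(v) for v in prof]

    # --- motif planting -----------------------------------------------
    target_stage = config.motif_target_stage or stages[-1]
    motif_id = "SYN_MOTIF_1"
    consensus = config.motif_consensus.upper()
    target_ids = stage_specific[target_stage]
    planted = sorted(
        pid for pid in target_ids if rng.random() < config.motif_plant_rate
    )

    truth = SyntheticTruth(
        peaks=peaks,
        stage_specific=stage_specific,
        common=common_ids,
        dpi=dpi,
        null_common=null_common,
        peak_base_mean=base_mean,
        gene_clusters=gene_clusters,
        deg_ids=deg_ids,
        low_expression_ids=low_ids,
        gene_fpkm=gene_fpkm,
        exonic_lengths={g: int(v) for g, v in sorted(exonic_len.items())},
        promoter_map={g: sorted(v) for g, v in sorted(promoter_map.items())},
        motif_planted_peaks=planted,
        motif_target_stage=target_stage,
        motif_id=motif_id,
    )

    # --- genome FASTA (motifs written in before output) ---------------
    fasta_path = outdir / "genome.fa"
    seqs = {
        chrom: _BASES[rng.integers(0, 4, size=length)].copy()
        for chrom, length in chrom_lengths.items()
    }
    cons_arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for pid in planted:
        rec = peaks[pid]
        mid = rec["start"] + (rec["end"] - rec["start"]) // 2
        s = mid - len(consensus) // 2
        seqs[rec["chrom"]][s:s + len(consensus)] = cons_arr
    with open(fasta_path, "w") as fh:
        for chrom in chrom_lengths:
            fh.write(f">{chrom}\n")
            seq = seqs[chrom].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    # --- MEME motif file ----------------------------------------------
    mat = np.full((len(consensus), 4), 0.04)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 0.88
    meme_path = outdir / "motifs.meme"
    write_meme([PWM(motif_id=motif_id, matrix=mat)], meme_path)

    # --- replicate narrowPeak files ------------------------------------
    peaks_dir = outdir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    replicate_paths: dict[str, list[Path]] = {}
    p_rep = config.replicate_reproducibility
    for stage in stages:
        stage_truth = [peaks[pid] | {"pid": pid} for pid in common_ids + stage_specific[stage]]
        stage_truth.sort(key=lambda r: (r["chrom"], r["start"]))
        replicate_paths[stage] = []
        for r in range(config.replicates_per_stage):
            path = peaks_dir / f"{stage}_rep{r + 1}.narrowPeak"
            rows = []
            for rec in stage_truth:
                if p_rep < 1.0 and rng.random() > p_rep:
                    continue
                js = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                je = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
                s = max(rec["start"] + js, 0)
                e = min(max(rec["end"] + je, s + 50), chrom_lengths[rec["chrom"]])
                rows.append((rec["chrom"], s, e, f'{rec["pid"]}.{stage}.r{r + 1}'))
            for i in range(config.n_noise_peaks_per_replicate):
                length = int(rng.integers(*config.peak_length_range))
                spot = _place_peak_anywhere(
                    chrom_lengths, genic_flanks, length, occ, rng, avoid_genic=False
                )
                if spot is None:
                    break
                chrom, s, e = spot
                occ.add(chrom, s, e)  # keep replicate noise disjoint
                rows.append((chrom, s, e, f"noise.{stage}.r{r + 1}.{i + 1}"))
            rows.sort()
            with open(path, "w") as fh:
                for chrom, s, e, name in rows:
                    signal = float(np.round(np.exp(rng.normal(2.0, 0.5)), 4))
                    fh.write(
                        f"{chrom}\t{s}\t{e}\t{name}\t0\t.\t{signal}\t5.0\t3.0\t{(e - s) // 2}\n"
                    )
            replicate_paths[stage].append(path)

    # --- count matrices -----------------------------------------------
    peak_cm, gene_cm, _side = plant_counts(truth, config, rng)
    peak_counts_path = outdir / "peak_counts.tsv"
    gene_counts_path = outdir / "gene_counts.tsv"
    samples_path = outdir / "samples.tsv"
    peak_cm.counts.to_csv(peak_counts_path, sep="\t")
    gene_cm.counts.to_csv(gene_counts_path, sep="\t")
    gene_cm.samples.reset_index(names="sample_id").to_csv(samples_path, sep="\t", index=False)

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    return SyntheticBundle(
        outdir=outdir,
        chrom_sizes=cs_path,
        fasta=fasta_path,
        gtf=gtf_path,
        replicate_peaks=replicate_paths,
        peak_counts=peak_counts_path,
        gene_counts=gene_counts_path,
        samples=samples_path,
        meme=meme_path,
        truth_json=truth_path,
        truth=truth,
        config=config,
    )
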