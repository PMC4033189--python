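"""Synthetic GRO-seq fixtures with planted, recoverable ground truth.

The generator emulates the four-condition design of the analysis — two
genotypes (wild-type and knockout for the activating TF) each under
treatment and vehicle — as strand-specific 50-bp read sets on a synthetic
chromosome, plus seven noisy ChIP peak experiments over a shared set of
true binding sites.

Planted structure, per gene: a lognormal baseline expression; a
multiplicative fold change applied only in the treated wild-type condition
for a chosen fraction of genes; a promoter/body density ratio (pausing);
and an antisense/sense upstream ratio (divergent transcription).  Library-
level biological noise is gamma-distributed per gene and sample so counts
are negative-binomial with variance mu + alpha*mu^2, matching the
differential caller's model.  A fixed fraction of each library is uniform
background.  Active enhancer sites emit reads on both strands within the
site footprint; sites planted near target genes can be active at a higher
rate than distal ones, mimicking pre-activated enhancers.

Each sample contains exactly ``reads_per_sample`` reads: expected read
weights for every source (gene sub-components, enhancer strands,
background) are perturbed by the gamma noise and the library is drawn as a
single multinomial, so per-source counts are negative-binomial to an
excellent approximation while library size stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    ReadSet,
    StrandedInterval,
    read_annotation,
    read_bed,
    write_annotation,
    write_bed,
)

CONDITIONS = ("wt_control", "wt_nutlin", "ko_control", "ko_nutlin")
TREATED_CONDITION = "wt_nutlin"

__all__ = ["SimConfig", "SimTruth", "SimDataset", "simulate_dataset",
           "write_fixture", "read_fixture", "CONDITIONS", "TREATED_CONDITION"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults give the documented standard fixture."""

    seed: int = 0
    n_genes: int = 500
    genome_length: int = 50_000_000
    gene_length_range: tuple[int, int] = (2_000, 20_000)
    n_samples_per_condition: int = 2
    reads_per_sample: int = 1_000_000
    background_fraction: float = 0.03
    induced_fraction: float = 0.10
    induced_fold: float = 6.0
    dispersion: float = 0.05
    pausing_ratio_range: tuple[float, float] = (1.0, 40.0)
    divergence_ratio_range: tuple[float, float] = (0.05, 2.0)
    n_sites: int = 200
    site_active_fraction: float = 0.3
    erna_reads_per_active_site: float = 100.0
    n_peak_experiments: int = 7
    peak_dropout: float = 0.15
    false_peak_rate: float = 20.0
    read_length: int = 50
    n_chromosomes: int = 1
    site_width: int = 600
    site_near_target_fraction: float = 0.2
    near_target_active_fraction: float = 0.8
    min_gene_gap: int = 3_000

    def validate(self) -> None:
        for name in (
            "background_fraction", "induced_fraction", "site_active_fraction",
            "peak_dropout", "site_near_target_fraction",
            "near_target_active_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.induced_fold <= 0:
            raise ValueError("induced_fold must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("n_genes", "n_sites", "n_peak_experiments",
                     "reads_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground-truth ledger the recovery tests score against."""

    gene_truth: pd.DataFrame   # baseline, fold per condition, pausing, divergence
    site_truth: pd.DataFrame   # location, near_target, active, per-strand rate
    peak_truth: pd.DataFrame   # experiment x site emission flags


@dataclass
class SimDataset:
    annotation: list[GeneModel]
    samples: dict[str, ReadSet]          # sample name -> reads
    conditions: dict[str, str]           # sample name -> condition label
    peaks: list[list[StrandedInterval]]  # one peak list per ChIP experiment
    truth: SimTruth
    config: SimConfig


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Place genes on one chromosome, non-overlapping with a minimum gap."""
    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    margin = 2_000  # room for promoter/divergence windows at the chrom edges
    needed = int(lengths.sum()) + (cfg.n_genes + 1) * cfg.min_gene_gap + 2 * margin
    if needed > cfg.genome_length:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small to place "
            f"{cfg.n_genes} genes without overlap (need >= {needed})"
        )
    slack = cfg.genome_length - 2 * margin - int(lengths.sum()) \
        - (cfg.n_genes + 1) * cfg.min_gene_gap
    # distribute remaining slack over the n_genes+1 inter-gene gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=cfg.n_genes))
    extra = np.diff(np.concatenate(([0], cuts, [slack])))
    genes = []
    pos = margin
    for i in range(cfg.n_genes):
        pos += cfg.min_gene_gap + int(extra[i])
        start = pos
        end = start + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene{i:04d}", StrandedInterval("chrS", start, end, strand))
        )
        pos = end
    return genes


def _place_sites(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    induced: np.ndarray,
) -> pd.DataFrame:
    """Choose enhancer-site footprints in intergenic space.

    A configurable fraction is deliberately planted 5-20 kb from an induced
    (target) gene; the rest land uniformly in intergenic gaps, yielding a
    mixture of distal and gene-proximal sites.
    """
    margin = 2_000  # clear of promoter-divergence read spill at gene edges
    spans = sorted((g.interval.start, g.interval.end) for g in genes)
    gaps = []
    prev = 0
    for s, e in spans:
        if s - prev > cfg.site_width + 2 * margin:
            gaps.append((prev + margin, s - margin))
        prev = e
    if cfg.genome_length - prev > cfg.site_width + 2 * margin:
        gaps.append((prev + margin, cfg.genome_length - margin))
    gap_lens = np.array([e - s - cfg.site_width for s, e in gaps], dtype=float)
    gap_p = gap_lens / gap_lens.sum()

    target_idx = np.flatnonzero(induced)
    rows = []
    for i in range(cfg.n_sites):
        near_target = bool(
            len(target_idx) and rng.random() < cfg.site_near_target_fraction
        )
        placed = False
        if near_target:
            for _ in range(50):  # rejection-sample a clean slot near a target
                g = genes[int(rng.choice(target_idx))]
                offset = int(rng.integers(5_000, 20_000))
                if rng.random() < 0.5:
                    start = g.interval.end + offset
                else:
                    start = g.interval.start - offset - cfg.site_width
                end = start + cfg.site_width
                if start < 1_000 or end > cfg.genome_length - 1_000:
                    continue
                if any(s < end and start < e for s, e in spans):
                    continue
                placed = True
                break
        if not placed:
            near_target = False
            gi = int(rng.choice(len(gaps), p=gap_p))
            start = int(rng.integers(gaps[gi][0], gaps[gi][1] - cfg.site_width))
            end = start + cfg.site_width
        active_p = (
            cfg.near_target_active_fraction if near_target
            else cfg.site_active_fraction
        )
        active = bool(rng.random() < active_p)
        rows.append((f"site{i:04d}", "chrS", start, end, near_target, active,
                     cfg.erna_reads_per_active_site if active else 0.0))
    return pd.DataFrame(
        rows,
        columns=["site", "chrom", "start", "end", "near_target", "active",
                 "strand_rate"],
    ).set_index("site")


def _sample_reads(
    cfg: SimConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    gene_truth: pd.DataFrame,
    site_truth: pd.DataFrame,
    condition: str,
) -> ReadSet:
    """Draw one library of exactly ``reads_per_sample`` reads."""
    rl = cfg.read_length
    # --- expected-read weights per source category -------------------------
    cat_region: list[tuple[int, int, str]] = []   # (lo, hi, strand) for starts
    weights: list[float] = []
    fold_col = f"fold_{condition}"
    for g, (_, row) in zip(genes, gene_truth.iterrows()):
        mu = row["baseline"] * row[fold_col]
        r = row["pausing_ratio"]
        d = row["divergence_ratio"]
        L = g.length
        tss = g.tss
        w_prom = 500.0 * r
        w_rest = float(L - 400)
        w_anti = d * (400.0 * r + 600.0)
        wsum = w_prom + w_rest + w_anti
        anti_strand = "-" if g.strand == "+" else "+"
        if g.strand == "+":
            prom = (tss - 100, tss + 400 - rl, "+")
            rest = (tss + 400, g.interval.end - rl, "+")
            anti = (tss - 1000, tss - rl, anti_strand)
        else:
            prom = (tss - 400 + 1, tss + 100 + 1 - rl, "-")
            rest = (g.interval.start, tss - 400 + 1 - rl, "-")
            anti = (tss + 1, tss + 1000 + 1 - rl, anti_strand)
        for region, w in ((prom, w_prom), (rest, w_rest), (anti, w_anti)):
            cat_region.append(region)
            weights.append(mu * w / wsum)
    n_gene_cats = len(weights)
    for _, row in site_truth.iterrows():
        for strand in ("+", "-"):
            cat_region.append((int(row["start"]), int(row["end"]) - rl, strand))
            weights.append(float(row["strand_rate"]))
    weights = np.asarray(weights, dtype=float)
    # gamma noise on gene components only: one factor per gene per sample,
    # shared by its three components so the planted ratios are undisturbed
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        factors = rng.gamma(shape, cfg.dispersion, size=len(genes))
        weights[:n_gene_cats] *= np.repeat(factors, 3)
    # background weight set so its expected share is exactly the configured
    # fraction of the library, whatever the signal total
    f = cfg.background_fraction
    w_bg = f / (1.0 - f) * weights.sum() if f < 1 else weights.sum() * 1e9
    all_w = np.concatenate([weights, [w_bg]])
    counts = rng.multinomial(cfg.reads_per_sample, all_w / all_w.sum())

    # --- materialise read start positions ---------------------------------
    starts_parts: list[np.ndarray] = []
    strands_parts: list[np.ndarray] = []
    for (lo, hi, strand), k in zip(cat_region, counts[:-1]):
        if k == 0:
            continue
        hi_eff = max(hi, lo + 1)
        st = rng.integers(lo, hi_eff, size=k)
        starts_parts.append(st)
        strands_parts.append(np.full(k, strand, dtype="<U1"))
    k_bg = counts[-1]
    if k_bg:
        st = rng.integers(0, cfg.genome_length - rl, size=k_bg)
        starts_parts.append(st)
        strands_parts.append(
            np.where(rng.random(k_bg) < 0.5, "+", "-").astype("<U1")
        )
    starts = (np.concatenate(starts_parts) if starts_parts
              else np.empty(0, dtype=np.int64))
    strands = (np.concatenate(strands_parts) if strands_parts
               else np.empty(0, dtype="<U1"))
    starts = np.clip(starts, 0, cfg.genome_length - rl).astype(np.int64)
    return ReadSet.from_arrays(
        "chrS", starts, starts + rl, strands,
        total_mapped=cfg.reads_per_sample,
        genome_length=cfg.genome_length,
    )


def _sample_peaks(
    cfg: SimConfig, rng: np.random.Generator, site_truth: pd.DataFrame
) -> tuple[list[list[StrandedInterval]], pd.DataFrame]:
    """Seven (by default) noisy peak experiments over the true sites."""
    peak_sets = []
    emitted_rows = []
    for e in range(cfg.n_peak_experiments):
        peaks = []
        for site, row in site_truth.iterrows():
            keep = rng.random() >= cfg.peak_dropout
            emitted_rows.append((e, site, keep))
            if not keep:
                continue
            jitter_s = int(rng.integers(-50, 51))
            jitter_e = int(rng.integers(-50, 51))
            s = max(0, int(row["start"]) + jitter_s)
            t = min(cfg.genome_length, int(row["end"]) + jitter_e)
            if t - s < 50:
                t = s + 50
            peaks.append(StrandedInterval("chrS", s, t))
        n_false = rng.poisson(cfg.false_peak_rate)
        for _ in range(n_false):
            s = int(rng.integers(0, cfg.genome_length - cfg.site_width))
            peaks.append(StrandedInterval("chrS", s, s + cfg.site_width))
        peak_sets.append(sorted(peaks, key=lambda p: (p.start, p.end)))
    peak_truth = pd.DataFrame(
        emitted_rows, columns=["experiment", "site", "emitted"]
    )
    return peak_sets, peak_truth


def simulate_dataset(config: SimConfig | None = None) -> SimDataset:
    """Generate the full synthetic dataset; identical seed, identical output."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _place_genes(cfg, rng)
    n_induced = int(round(cfg.induced_fraction * cfg.n_genes))
    induced = np.zeros(cfg.n_genes, dtype=bool)
    induced[rng.choice(cfg.n_genes, size=n_induced, replace=False)] = True

    lo_p, hi_p = cfg.pausing_ratio_range
    lo_d, hi_d = cfg.divergence_ratio_range
    gene_truth = pd.DataFrame(
        {
            "gene": [g.name for g in genes],
            "baseline": np.exp(rng.normal(0.0, 1.0, cfg.n_genes)),
            "induced": induced,
            "pausing_ratio": np.exp(
                rng.uniform(np.log(lo_p), np.log(hi_p), cfg.n_genes)
            ),
            "divergence_ratio": np.exp(
                rng.uniform(np.log(lo_d), np.log(hi_d), cfg.n_genes)
            ),
        }
    ).set_index("gene")
    for cond in CONDITIONS:
        gene_truth[f"fold_{cond}"] = np.where(
            induced & (cond == TREATED_CONDITION), cfg.induced_fold, 1.0
        )

    site_truth = _place_sites(cfg, rng, genes, induced)
    # put baselines in expected-read units: genes share the control library
    # left over after background and the enhancer budget, so
    # erna_reads_per_active_site really is a per-strand mean read count
    erna_budget = 2.0 * site_truth["strand_rate"].sum()
    gene_budget = max(
        cfg.reads_per_sample * (1.0 - cfg.background_fraction) - erna_budget, 0.0
    )
    if gene_truth["baseline"].sum() > 0:
        gene_truth["baseline"] *= gene_budget / gene_truth["baseline"].sum()
    samples: dict[str, ReadSet] = {}
    conditions: dict[str, str] = {}
    for cond in CONDITIONS:
        for rep in range(cfg.n_samples_per_condition):
            name = f"{cond}_r{rep + 1}"
            samples[name] = _sample_reads(
                cfg, rng, genes, gene_truth, site_truth, cond
            )
            conditions[name] = cond
    peak_sets, peak_truth = _sample_peaks(cfg, rng, site_truth)
    return SimDataset(
        annotation=genes,
        samples=samples,
        conditions=conditions,
        peaks=peak_sets,
        truth=SimTruth(gene_truth, site_truth, peak_truth),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Fixture round trip
# ---------------------------------------------------------------------------

def write_fixture(dataset: SimDataset, directory: str | Path) -> None:
    """Write annotation, per-sample read BEDs, peak BEDs and truth tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_annotation(dataset.annotation, d / "annotation.tsv")
    sample_rows = []
    for name, rs in dataset.samples.items():
        df = rs.to_frame()
        df.insert(3, "name", ".")
        df.insert(4, "score", 0)
        df.to_csv(d / f"reads_{name}.bed", sep="\t", header=False, index=False)
        sample_rows.append(
            (name, dataset.conditions[name], rs.total_mapped, rs.genome_length)
        )
    pd.DataFrame(
        sample_rows, columns=["sample", "condition", "total_mapped", "genome_length"]
    ).to_csv(d / "samples.tsv", sep="\t", index=False)
    (d / "peaks").mkdir(exist_ok=True)
    for i, peaks in enumerate(dataset.peaks):
        write_bed(peaks, d / "peaks" / f"experiment_{i}.bed")
    dataset.truth.gene_truth.to_csv(d / "gene_truth.tsv", sep="\t")
    dataset.truth.site_truth.to_csv(d / "site_truth.tsv", sep="\t")
    dataset.truth.peak_truth.to_csv(d / "peak_truth.tsv", sep="\t", index=False)
    (d / "config.json").write_text(json.dumps(asdict(dataset.config), indent=1))


def read_fixture(directory: str | Path) -> SimDataset:
    """Reload a fixture written by :func:`write_fixture`."""
    d = Path(directory)
    cfg_dict = json.loads((d / "config.json").read_text())
    for key in ("gene_length_range", "pausing_ratio_range", "divergence_ratio_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    cfg = SimConfig(**cfg_dict)
    annotation = read_annotation(d / "annotation.tsv")
    meta = pd.read_csv(d / "samples.tsv", sep="\t")
    samples = {}
    conditions = {}
    for row in meta.itertuples(index=False):
        samples[row.sample] = ReadSet.from_bed(
            d / f"reads_{row.sample}.bed",
            total_mapped=int(row.total_mapped),
            genome_length=int(row.genome_length),
        )
        conditions[row.sample] = row.condition
    peaks = []
    for i in range(cfg.n_peak_experiments):
        peaks.append(read_bed(d / "peaks" / f"experiment_{i}.bed"))
    truth = SimTruth(
        gene_truth=pd.read_csv(d / "gene_truth.tsv", sep="\t", index_col="gene"),
        site_truth=pd.read_csv(d / "site_truth.tsv", sep="\t", index_col="site"),
        peak_truth=pd.read_csv(d / "peak_truth.tsv", sep="\t"),
    )
    return SimDataset(annotation, samples, conditions, peaks, truth, cfg)
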