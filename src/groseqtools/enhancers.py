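"""Consensus TF-binding sites and enhancer-RNA (eRNA) analysis.

Peak sets from several ChIP experiments are pooled, union-merged, and each
merged footprint is kept when enough experiments support it (default 5 of
7).  Each retained site is duplicated onto both strands ("stranded sites");
a stranded copy overlapping an annotated gene on the same strand is
discarded so genic transcription cannot masquerade as eRNA.  Surviving
copies are quantified per sample (counts, fpkm) and called active against
the uniform Poisson background; a site is active when either strand is
(bidirectional eRNA transcription means one detectable strand suffices).
Sites are categorised by edge-to-edge distance to annotated genes: distal
(> 25 kb from every gene), proximal to a target gene, or proximal to a
non-target gene, with target genes taking precedence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneModel, ReadSet, StrandedInterval, merge_intervals
from .quantify import fpkm, poisson_activity

DEFAULT_MIN_SUPPORT = 5
DEFAULT_RADIUS = 25_000

__all__ = [
    "SiteRecord",
    "StrandedSite",
    "consensus_sites",
    "stranded_sites",
    "categorize_sites",
    "erna_quantify",
    "tss_distance_histogram",
]


@dataclass
class SiteRecord:
    """A merged binding-site footprint with experiment support and category."""

    site: StrandedInterval
    support: int
    category: str | None = None              # distal / proximal_target / proximal_non_target
    distance_to_nearest_gene: float = math.nan
    distance_to_nearest_target: float = math.nan


@dataclass(frozen=True)
class StrandedSite:
    """One strand-assigned copy of a site footprint."""

    site_index: int
    interval: StrandedInterval


def consensus_sites(
    peak_sets: list[list[StrandedInterval]],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[SiteRecord]:
    """Merge peaks from all experiments; keep sites seen in >= min_support.

    An experiment supports a merged site iff at least one of its peaks
    overlaps the footprint by >= 1 bp.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    if min_support > len(peak_sets):
        raise ValueError("min_support exceeds the number of peak sets")
    pooled = [p for peaks in peak_sets for p in peaks]
    if not pooled:
        return []
    merged = merge_intervals(pooled, bookended=True)
    # sorted merged footprints per chromosome for binary-search support lookup
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for idx, m in enumerate(merged):
        by_chrom.setdefault(m.chrom, ([], [], []))  # type: ignore[arg-type]
    tmp: dict[str, list[tuple[int, int, int]]] = {}
    for idx, m in enumerate(merged):
        tmp.setdefault(m.chrom, []).append((m.start, m.end, idx))
    lookup = {
        chrom: (
            np.array([t[0] for t in rows]),
            np.array([t[1] for t in rows]),
            [t[2] for t in rows],
        )
        for chrom, rows in tmp.items()
    }
    support = np.zeros(len(merged), dtype=int)
    for peaks in peak_sets:
        seen: set[int] = set()
        for p in peaks:
            if p.chrom not in lookup:
                continue
            starts, ends, idxs = lookup[p.chrom]
            # merged footprints are disjoint and sorted; a peak overlaps the
            # footprints whose start < p.end and end > p.start
            lo = int(np.searchsorted(ends, p.start, side="right"))
            hi = int(np.searchsorted(starts, p.end, side="left"))
            for j in range(lo, hi):
                seen.add(idxs[j])
        for j in seen:
            support[j] += 1
    return [
        SiteRecord(site=m, support=int(support[i]))
        for i, m in enumerate(merged)
        if support[i] >= min_support
    ]


def stranded_sites(
    sites: list[SiteRecord],
    annotation: list[GeneModel],
) -> tuple[list[StrandedSite], int]:
    """Two strand-assigned copies per site, minus genic same-strand copies.

    Returns (surviving stranded records, count before filtering). A copy is
    dropped iff it overlaps (>= 1 bp) any gene on its own strand; the
    unstranded footprint in ``sites`` is untouched either way.
    """
    # sorted gene spans per (chrom, strand) for fast overlap queries
    gene_idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in annotation:
        tmp.setdefault((g.chrom, g.strand), []).append(
            (g.interval.start, g.interval.end)
        )
    for key, spans in tmp.items():
        spans.sort()
        starts = np.array([s for s, _ in spans])
        # running max of ends supports overlap queries on sorted-by-start spans
        ends = np.maximum.accumulate(np.array([e for _, e in spans]))
        gene_idx[key] = (starts, ends)

    def overlaps_gene(iv: StrandedInterval) -> bool:
        key = (iv.chrom, iv.strand)
        if key not in gene_idx:
            return False
        starts, max_ends = gene_idx[key]
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return hi > 0 and max_ends[hi - 1] > iv.start

    out: list[StrandedSite] = []
    n_before = 2 * len(sites)
    for i, rec in enumerate(sites):
        for strand in ("+", "-"):
            iv = StrandedInterval(rec.site.chrom, rec.site.start, rec.site.end, strand)
            if not overlaps_gene(iv):
                out.append(StrandedSite(site_index=i, interval=iv))
    return out, n_before


def categorize_sites(
    sites: list[SiteRecord],
    annotation: list[GeneModel],
    targets: set[str],
    radius: int = DEFAULT_RADIUS,
) -> list[SiteRecord]:
    """Assign distal / proximal_target / proximal_non_target in place.

    Distances are edge-to-edge between the site footprint and the gene span
    (0 when overlapping).  A site within ``radius`` of both a target and a
    non-target gene is proximal_target (targets take precedence).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not annotation:
        import warnings

        warnings.warn("empty annotation: all sites categorised distal")
        for rec in sites:
            rec.category = "distal"
            rec.distance_to_nearest_gene = math.inf
            rec.distance_to_nearest_target = math.inf
        return sites
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for rec in sites:
        d_gene = math.inf
        d_target = math.inf
        for g in by_chrom.get(rec.site.chrom, []):
            d = rec.site.distance_to(g.interval)
            d_gene = min(d_gene, d)
            if g.name in targets:
                d_target = min(d_target, d)
        rec.distance_to_nearest_gene = d_gene
        rec.distance_to_nearest_target = d_target
        if d_gene > radius:
            rec.category = "distal"
        elif d_target <= radius:
            rec.category = "proximal_target"
        else:
            rec.category = "proximal_non_target"
    return sites


def erna_quantify(
    records: list[StrandedSite],
    samples: dict[str, ReadSet],
    background_fraction: float = 0.03,
    alpha: float = 0.01,
    comparisons: dict[str, tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Counts, fpkm and Poisson activity for every stranded record x sample.

    Returns (record_table, site_table, fold_changes):

    * record_table — one row per stranded record per sample with count,
      fpkm, background rate, p-value and the active flag;
    * site_table — per site footprint per sample, active = OR over that
      site's surviving stranded records;
    * fold_changes — per named comparison (sample_A, sample_B), fpkm
      fold change B/A over the records with > 0 reads in both samples.
    """
    rows = []
    for ridx, rec in enumerate(records):
        iv = rec.interval
        for sample, rs in samples.items():
            n = rs.count(iv, strand_specific=True)
            call = poisson_activity(
                iv, n, rs, background_fraction=background_fraction, alpha=alpha
            )
            rows.append(
                (
                    ridx,
                    rec.site_index,
                    iv.chrom,
                    iv.start,
                    iv.end,
                    iv.strand,
                    sample,
                    n,
                    fpkm(n, iv.length, rs.total_mapped),
                    call.background_rate,
                    call.p_value,
                    call.active,
                )
            )
    record_table = pd.DataFrame(
        rows,
        columns=[
            "record", "site", "chrom", "start", "end", "strand", "sample",
            "count", "fpkm", "lambda", "p_value", "active",
        ],
    )
    if record_table.empty:
        return record_table, pd.DataFrame(), {}
    site_table = (
        record_table.groupby(["site", "sample"])
        .agg(active=("active", "any"), n_strands=("record", "count"))
        .reset_index()
    )
    fold_changes: dict[str, pd.DataFrame] = {}
    for name, (sample_a, sample_b) in (comparisons or {}).items():
        wide = record_table.pivot(index="record", columns="sample", values="fpkm")
        cnt = record_table.pivot(index="record", columns="sample", values="count")
        ok = (cnt[sample_a] > 0) & (cnt[sample_b] > 0)
        fc = (wide.loc[ok, sample_b] / wide.loc[ok, sample_a]).rename("fold_change")
        fold_changes[name] = fc.to_frame()
    return record_table, site_table, fold_changes


def tss_distance_histogram(
    genes: list[GeneModel],
    sites: list[SiteRecord],
    inner_halfspan: int = 25_000,
    inner_bin: int = 1_000,
    outer_bins: int = 10,
    outer_bin: int = 5_000,
) -> pd.DataFrame:
    """Histogram of signed distance from each gene's TSS to its nearest site.

    Signed distance = site midpoint - TSS, negated for minus-strand genes so
    positive always means downstream of the TSS.  Inner 1-kb bins span
    +/- 25 kb, flanked by ten 5-kb bins on each side out to +/- 75 kb;
    genes whose nearest site is beyond that are dropped.
    """
    if not sites:
        raise ValueError("sites must be non-empty")
    mids: dict[str, np.ndarray] = {}
    for s in sites:
        mids.setdefault(s.site.chrom, [])  # type: ignore[arg-type]
    tmp: dict[str, list[float]] = {}
    for s in sites:
        tmp.setdefault(s.site.chrom, []).append((s.site.start + s.site.end) / 2.0)
    mids = {c: np.sort(np.array(v)) for c, v in tmp.items()}
    dists = []
    for g in genes:
        if g.chrom not in mids:
            continue
        m = mids[g.chrom]
        tss = g.tss
        j = np.searchsorted(m, tss)
        cands = m[max(0, j - 1): j + 1]
        nearest = cands[np.argmin(np.abs(cands - tss))]
        signed = nearest - tss
        if g.strand == "-":
            signed = -signed
        dists.append(signed)
    span = inner_halfspan + outer_bins * outer_bin
    edges = np.concatenate(
        [
            -span + outer_bin * np.arange(outer_bins),
            np.arange(-inner_halfspan, inner_halfspan, inner_bin),
            inner_halfspan + outer_bin * np.arange(outer_bins + 1),
        ]
    ).astype(float)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
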