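"""RNAPII pausing index and promoter-divergence index.

Pausing index: ratio of promoter read density (reads/bp over -100..+400) to
gene-body density (TSS+1kb to the annotation end).  High values mark
promoter-proximal polymerase pausing.  Significance of promoter enrichment
comes from a one-sided Fisher's exact test on reads vs remaining bp in each
window.

Divergence index: antisense reads in the 1 kb upstream of the TSS divided
by sense reads in the 1 kb downstream, quantifying divergent (unproductive)
transcription relative to productive elongation.  High values sort the most
divergent promoters first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel, ReadSet, StrandedInterval
from .quantify import make_windows

__all__ = [
    "PausingResult",
    "DivergenceResult",
    "pausing_index",
    "divergence_index",
    "pausing_table",
    "divergence_table",
]


@dataclass(frozen=True)
class PausingResult:
    promoter_density: float
    body_density: float
    pausing_index: float  # NaN when undefined (body count 0)
    p_value: float        # one-sided promoter-enrichment Fisher p; NaN if table invalid
    defined: bool


@dataclass(frozen=True)
class DivergenceResult:
    sense_count: int
    antisense_count: int
    divergence_index: float  # antisense/sense; NaN when sense == 0
    defined: bool
    ranked: bool             # meets the minimum total-read floor


def pausing_index(
    promoter_count: int,
    promoter_length: int,
    body_count: int,
    body_length: int,
) -> PausingResult:
    """Density ratio PI = (promoter/bp) / (body/bp) with Fisher enrichment p.

    The 2x2 table is [[promoter reads, promoter bp without a read start],
    [body reads, body bp ditto]], tested one-sided for promoter excess.
    When a window holds more reads than bp the table is invalid and the
    p-value is NaN (the PI itself is still reported).
    """
    if promoter_count < 0 or body_count < 0:
        raise ValueError("counts must be non-negative")
    if promoter_length <= 0 or body_length <= 0:
        raise ValueError("window lengths must be positive")
    pdens = promoter_count / promoter_length
    bdens = body_count / body_length
    if body_count == 0:
        return PausingResult(pdens, 0.0, float("nan"), float("nan"), False)
    pi = pdens / bdens
    if promoter_count > promoter_length or body_count > body_length:
        pval = float("nan")
    else:
        table = [
            [promoter_count, promoter_length - promoter_count],
            [body_count, body_length - body_count],
        ]
        pval = float(stats.fisher_exact(table, alternative="greater")[1])
    return PausingResult(pdens, bdens, pi, pval, True)


def divergence_index(
    gene: GeneModel,
    reads: ReadSet,
    window: int = 1000,
    min_reads: int = 10,
) -> DivergenceResult:
    """DI = antisense reads upstream of the TSS / sense reads downstream.

    Sense window: [TSS, TSS+window) on the gene strand; antisense window:
    [TSS-window, TSS) on the opposite strand; both reflected for minus-
    strand genes.  Genes with fewer than ``min_reads`` total reads in the
    two windows are flagged as unrankable.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    tss = gene.tss
    chrom = gene.chrom
    anti_strand = "-" if gene.strand == "+" else "+"
    if gene.strand == "+":
        sense_iv = StrandedInterval(chrom, tss, tss + window, "+")
        anti_iv = StrandedInterval(chrom, max(0, tss - window), tss, "-")
    else:
        sense_iv = StrandedInterval(chrom, max(0, tss - window + 1), tss + 1, "-")
        anti_iv = StrandedInterval(chrom, tss + 1, tss + 1 + window, "+")
    assert anti_iv.strand == anti_strand
    sense = reads.count(sense_iv, strand_specific=True)
    anti = reads.count(anti_iv, strand_specific=True)
    ranked = sense + anti >= min_reads
    if sense == 0:
        return DivergenceResult(sense, anti, float("nan"), False, ranked)
    return DivergenceResult(sense, anti, anti / sense, True, ranked)


def pausing_table(genes: list[GeneModel], reads: ReadSet) -> pd.DataFrame:
    """Per-gene pausing indices from strand-specific window counts."""
    rows = []
    for g in genes:
        w = make_windows(g)
        if w is None:
            continue
        prom, body = w
        pc = reads.count(prom)
        bc = reads.count(body)
        r = pausing_index(pc, prom.length, bc, body.length)
        rows.append(
            (g.name, pc, bc, r.promoter_density, r.body_density,
             r.pausing_index, r.p_value, r.defined)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "promoter_count", "body_count", "promoter_density",
            "body_density", "pausing_index", "p_value", "defined",
        ],
    ).set_index("gene")


def divergence_table(
    genes: list[GeneModel],
    reads: ReadSet,
    window: int = 1000,
    min_reads: int = 10,
) -> pd.DataFrame:
    rows = []
    for g in genes:
        r = divergence_index(g, reads, window=window, min_reads=min_reads)
        rows.append(
            (g.name, r.sense_count, r.antisense_count, r.divergence_index,
             r.defined, r.ranked)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "sense_count", "antisense_count", "divergence_index",
                 "defined", "ranked"],
    ).set_index("gene")
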