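"""Gene-set overlap statistics and basal-transcription classification.

Overlap of two gene sets drawn from a common universe is tested with the
upper-tail hypergeometric probability P(X >= k); computation is done in
log space so extreme enrichments (p far below 1e-300) remain representable
via their log10.  Basal classification compares per-gene basal fpkm between
two genotypes and splits genes into basally activated (ratio above an upper
fold threshold), basally repressed (below the reciprocal threshold), or
neutral.  Binding-proximity enrichment asks whether a gene set harbors a
TF binding site within a radius more often than the universe does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel
from .enhancers import SiteRecord

__all__ = [
    "ContingencyOverlap",
    "hypergeometric_overlap",
    "basal_classification",
    "binding_enrichment",
]


@dataclass(frozen=True)
class ContingencyOverlap:
    universe: int
    set_size: int
    draw_size: int
    overlap: int
    p_value: float       # may underflow to 0.0 for extreme overlaps
    log10_p: float       # always finite for k <= min(K, n)


def hypergeometric_overlap(
    universe: int, set_size: int, draw_size: int, overlap: int
) -> ContingencyOverlap:
    """Upper-tail hypergeometric overlap test, exact and log-space.

    Models ``overlap`` successes when ``draw_size`` genes are drawn without
    replacement from a universe containing ``set_size`` marked genes;
    p = P(X >= overlap).
    """
    n_, k_, d_, o_ = universe, set_size, draw_size, overlap
    if not (0 <= o_ <= min(k_, d_) <= n_ and k_ <= n_ and d_ <= n_):
        raise ValueError(
            f"invalid contingency: N={n_}, K={k_}, n={d_}, k={o_}"
        )
    if o_ == 0:
        return ContingencyOverlap(n_, k_, d_, o_, 1.0, 0.0)
    logp = float(stats.hypergeom.logsf(o_ - 1, n_, k_, d_))
    return ContingencyOverlap(
        n_, k_, d_, o_, float(np.exp(logp)), logp / math.log(10.0)
    )


def basal_classification(
    fpkm_a: pd.Series,
    fpkm_b: pd.Series,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Classify genes by basal fpkm ratio between genotypes A and B.

    R = (fpkm_A + eps) / (fpkm_B + eps); class is ``basally_activated``
    when R > up_threshold, ``basally_repressed`` when R < down_threshold,
    else ``neutral``.  The pseudocount stabilises ratios of
    barely-transcribed genes.
    """
    if not (up_threshold > 1 > down_threshold > 0):
        raise ValueError("need up_threshold > 1 > down_threshold > 0")
    idx = fpkm_a.index.intersection(fpkm_b.index)
    a = fpkm_a.loc[idx].astype(float)
    b = fpkm_b.loc[idx].astype(float)
    ratio = (a + pseudocount) / (b + pseudocount)
    cls = pd.Series("neutral", index=idx)
    cls[ratio > up_threshold] = "basally_activated"
    cls[ratio < down_threshold] = "basally_repressed"
    return pd.DataFrame({"ratio": ratio, "basal_class": cls})


def binding_enrichment(
    gene_set: Iterable[str],
    annotation: Sequence[GeneModel],
    sites: Sequence[SiteRecord],
    radius: int = 25_000,
    universe: Iterable[str] | None = None,
) -> dict:
    """Fraction of a gene set harboring a binding site within ``radius``.

    A gene harbors a site iff any site footprint lies within ``radius`` bp
    of the gene span (edge-to-edge, 0 when overlapping).  The enrichment p
    is the upper-tail hypergeometric probability of observing at least the
    seen overlap when drawing ``|gene_set|`` genes from the universe.
    """
    gene_set = set(gene_set)
    universe_set = set(universe) if universe is not None else {
        g.name for g in annotation
    }
    if not universe_set:
        raise ValueError("universe must be non-empty")
    if not gene_set <= universe_set:
        raise ValueError("gene_set must be a subset of the universe")
    by_chrom: dict[str, list[SiteRecord]] = {}
    for s in sites:
        by_chrom.setdefault(s.site.chrom, []).append(s)

    def harbors(g: GeneModel) -> bool:
        for s in by_chrom.get(g.chrom, []):
            if g.interval.distance_to(s.site) <= radius:
                return True
        return False

    harboring = {g.name for g in annotation if g.name in universe_set and harbors(g)}
    k_univ = len(harboring)
    k_set = len(gene_set & harboring)
    res = hypergeometric_overlap(
        len(universe_set), k_univ, len(gene_set), k_set
    )
    return {
        "fraction": k_set / len(gene_set) if gene_set else float("nan"),
        "k": k_set,
        "n": len(gene_set),
        "K": k_univ,
        "N": len(universe_set),
        "p_value": res.p_value,
        "log10_p": res.log10_p,
    }
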