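"""Hypergeometric ontology-term enrichment of hit sets.

For a term annotating K of the N screened strains, the probability of seeing
at least k annotated strains among n hits by chance is the upper tail of the
hypergeometric distribution, P(X >= k).  Fold enrichment is the term's
frequency in the hit set relative to its frequency in the screened
background, (k/n) / (K/N).  Only enrichment (upper tail) is tested, and raw
P-values are tiered at 0.05 / 0.01 / 0.001; Benjamini-Hochberg adjustment
is available but off by default.

Annotations are a flat user-supplied term -> strain map; ontology-graph
propagation must be done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["EnrichmentResult", "significance_tier", "hypergeom_enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_hits: int      # annotated strains among the hits
    n_hits: int      # hit-set size
    K_bg: int        # annotated strains in the background
    N_bg: int        # background size
    fold: float      # (k/n) / (K/N)
    p_hyper: float   # upper-tail P(X >= k)
    tier: str        # "", "*", "**" or "***"


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def hypergeom_enrich(
    hits,
    background,
    annotation,
    min_K: int = 2,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every term against the background.

    Parameters
    ----------
    hits, background
        Strain-id sets with ``hits`` a subset of ``background``.
    annotation
        Mapping term -> set of strain ids (as from
        :func:`phscreen.plate_io.read_annotation`).  Annotations outside the
        background are ignored; terms with fewer than ``min_K`` background
        members are skipped.
    fdr
        When true, Benjamini-Hochberg adjusted P-values replace ``p_hyper``
        for the significance tiers (the raw value is still reported).

    Results are sorted by ascending P-value, ties by term name.
    """
    hits = set(hits)
    background = set(background)
    if not annotation:
        raise ValidationError("annotation map is empty")
    stray = hits - background
    if stray:
        shown = ", ".join(sorted(stray)[:5])
        raise ValidationError(
            f"{len(stray)} hit strain(s) missing from the background: {shown}"
        )
    n = len(hits)
    N = len(background)
    if n == 0 or N == 0:
        raise ValidationError("hits and background must be non-empty")
    results = []
    for term in sorted(annotation):
        members = annotation[term] & background
        K = len(members)
        if K < min_K:
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        results.append(EnrichmentResult(
            term=term, k_hits=k, n_hits=n, K_bg=K, N_bg=N,
            fold=fold, p_hyper=p, tier=significance_tier(p),
        ))
    results.sort(key=lambda r: (r.p_hyper, r.term))
    if fdr and results:
        adj = stats.false_discovery_control([r.p_hyper for r in results])
        results = [
            EnrichmentResult(
                term=r.term, k_hits=r.k_hits, n_hits=r.n_hits, K_bg=r.K_bg,
                N_bg=r.N_bg, fold=r.fold, p_hyper=r.p_hyper,
                tier=significance_tier(float(q)),
            )
            for r, q in zip(results, adj)
        ]
    return results
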