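"""Co-occupancy of APC peaks with other transcription-factor peak sets.

Public TF ChIP-seq peak lists (typically two replicates per factor) are
first consolidated to replicate-shared peaks, then overlap with the APC
peak set is scored: an APC peak overlaps a TF peak when the two peak
centers are no more than 400 bp apart (the rule used for cross-dataset
comparison; replicate intersection within one experiment uses the strict
< comparator instead). Enrichment over chance is expressed as fold
overrepresentation against a binned-genome null — the genome treated as
``universe`` disjoint slots — with an upper-tail hypergeometric p-value.

The null universe is not uniquely defined by the screening procedure this
reproduces; the default is floor(effective genome size / 400) with a
2.7-Gb human effective size, and a seeded within-chromosome peak-shuffling
permutation null is available as a cross-check.
"""
from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import Peak, _greedy_match

log = logging.getLogger(__name__)

HUMAN_EFFECTIVE_GENOME = 2_700_000_000
DEFAULT_BIN = 400
DEFAULT_UNIVERSE = HUMAN_EFFECTIVE_GENOME // DEFAULT_BIN


def _center(peak: Peak, use_summit: bool = False) -> int:
    return peak.summit if use_summit else peak.center


@dataclass(frozen=True)
class OverlapStat:
    """Observed vs expected co-occupancy of a query peak set with one TF."""

    tf_name: str
    n_query: int
    n_ref: int
    n_overlap: int
    universe: int
    expected: float
    fold: float
    p_hyper: float


def consolidate_tf_replicates(
    rep_lists: Sequence[Sequence[Peak]],
    max_center_dist: int = 400,
    use_summit: bool = False,
) -> list[Peak]:
    """Peaks shared between all replicate lists of one factor.

    Pairwise center-distance intersection (<= max_center_dist) is applied
    left-to-right over the input lists; representatives come from the
    first list. For a heterodimeric factor assayed through two subunits
    (e.g. AP-1 via JUND and FOSL1), pass all four replicate lists.
    """
    if len(rep_lists) < 2:
        raise ValueError("need at least 2 replicate lists to consolidate")
    current = list(rep_lists[0])
    for k, other in enumerate(rep_lists[1:], start=2):
        pairs = _greedy_match(current, other, key=lambda p: _center(p, use_summit),
                              max_dist=max_center_dist, strict=False)
        current = [a for a, _ in pairs]
        log.info("consolidation step %d: %d shared peaks", k, len(current))
    return current


def overlap_mask(
    query: Sequence[Peak],
    ref: Sequence[Peak],
    max_center_dist: int = 400,
    use_summit: bool = False,
) -> list[bool]:
    """Per-query-peak flag: is there >= 1 same-chromosome ref peak whose
    center lies no more than ``max_center_dist`` bp from the query center?"""
    if max_center_dist < 0:
        raise ValueError("max_center_dist must be non-negative")
    by_chrom: dict[str, list[int]] = {}
    for p in ref:
        by_chrom.setdefault(p.chrom, []).append(_center(p, use_summit))
    for lst in by_chrom.values():
        lst.sort()
    mask = []
    for p in query:
        centers = by_chrom.get(p.chrom)
        if not centers:
            mask.append(False)
            continue
        c = _center(p, use_summit)
        mask.append(bisect_left(centers, c - max_center_dist)
                    < bisect_right(centers, c + max_center_dist))
    return mask


def count_overlaps(
    query: Sequence[Peak],
    ref: Sequence[Peak],
    max_center_dist: int = 400,
    use_summit: bool = False,
) -> int:
    """Number of query peaks with >= 1 same-chromosome ref peak whose center
    lies no more than ``max_center_dist`` bp from the query center. Each
    query peak is counted at most once."""
    return int(sum(overlap_mask(query, ref, max_center_dist=max_center_dist,
                                use_summit=use_summit)))


def enrichment(
    n_query: int,
    n_ref: int,
    n_overlap: int,
    universe: int = DEFAULT_UNIVERSE,
    tf_name: str = "",
) -> OverlapStat:
    """Fold overrepresentation and hypergeometric significance of an
    observed overlap count.

    expected = n_query * n_ref / universe; fold = n_overlap / expected
    (0 when expected is 0); p = P(X >= n_overlap) for X hypergeometric
    with population ``universe``, ``n_ref`` successes and ``n_query``
    draws (scipy survival function, computed stably in log space
    internally).
    """
    if universe < max(n_query, n_ref):
        raise ValueError(f"universe {universe} smaller than a peak set ({n_query}, {n_ref})")
    if min(n_query, n_ref, n_overlap) < 0:
        raise ValueError("counts must be non-negative")
    if n_overlap > min(n_query, n_ref):
        raise ValueError(f"impossible overlap count {n_overlap} > min({n_query}, {n_ref})")
    expected = n_query * n_ref / universe
    fold = (n_overlap / expected) if expected > 0 else 0.0
    p = float(hypergeom.sf(n_overlap - 1, universe, n_ref, n_query))
    return OverlapStat(tf_name=tf_name, n_query=n_query, n_ref=n_ref, n_overlap=n_overlap,
                       universe=universe, expected=expected, fold=fold, p_hyper=p)


def overlap_enrichment(
    query: Sequence[Peak],
    ref: Sequence[Peak],
    universe: int = DEFAULT_UNIVERSE,
    max_center_dist: int = 400,
    tf_name: str = "",
    use_summit: bool = False,
) -> OverlapStat:
    """Count overlaps between two peak sets and score the enrichment."""
    n = count_overlaps(query, ref, max_center_dist=max_center_dist, use_summit=use_summit)
    return enrichment(len(query), len(ref), n, universe=universe, tf_name=tf_name)


def stratified_enrichment(
    query_subsets: Mapping[str, Sequence[Peak]],
    tf_sets: Mapping[str, Sequence[Peak]],
    universe: int = DEFAULT_UNIVERSE,
    max_center_dist: int = 400,
    use_summit: bool = False,
) -> pd.DataFrame:
    """One enrichment row per (query subset, TF) cell.

    Subsets are typically APC peaks linked to up- vs down-regulated genes.
    Empty subsets yield a row with n_query 0 and fold/p marked undefined
    (NaN / 1.0).
    """
    rows = []
    for subset_name, subset in query_subsets.items():
        for tf_name, tf_peaks in tf_sets.items():
            if len(subset) == 0:
                rows.append(dict(subset=subset_name, tf=tf_name, n_query=0,
                                 n_ref=len(tf_peaks), n_overlap=0, universe=universe,
                                 expected=0.0, fold=np.nan, p_hyper=1.0))
                continue
            st = overlap_enrichment(subset, tf_peaks, universe=universe,
                                    max_center_dist=max_center_dist,
                                    tf_name=tf_name, use_summit=use_summit)
            rows.append(dict(subset=subset_name, tf=tf_name, n_query=st.n_query,
                             n_ref=st.n_ref, n_overlap=st.n_overlap, universe=universe,
                             expected=st.expected, fold=st.fold, p_hyper=st.p_hyper))
    return pd.DataFrame(rows)


def shuffle_peaks(peaks: Sequence[Peak], chrom_sizes: Mapping[str, int], rng: np.random.Generator) -> list[Peak]:
    """Random repositioning of peaks within their chromosome, widths preserved."""
    out = []
    for p in peaks:
        size = chrom_sizes[p.chrom]
        w = p.width
        start = int(rng.integers(0, max(1, size - w)))
        off = p.summit - p.start
        out.append(Peak(chrom=p.chrom, start=start, end=start + w, summit=start + off,
                        score=p.score, neg_log10_p=p.neg_log10_p, source_id=p.source_id))
    return out


def permutation_overlap_null(
    query: Sequence[Peak],
    ref: Sequence[Peak],
    chrom_sizes: Mapping[str, int],
    n_perm: int = 100,
    max_center_dist: int = 400,
    seed: int = 0,
) -> dict:
    """Peak-shuffling null for the overlap count: an independent cross-check
    of the binned hypergeometric model. Returns the observed count, the
    mean shuffled count, and an add-one empirical upper-tail p."""
    rng = np.random.default_rng(seed)
    observed = count_overlaps(query, ref, max_center_dist=max_center_dist)
    null = np.array([
        count_overlaps(shuffle_peaks(query, chrom_sizes, rng), ref, max_center_dist=max_center_dist)
        for _ in range(n_perm)
    ])
    p_emp = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return {"observed": observed, "null_mean": float(null.mean()), "p_empirical": p_emp,
            "n_perm": n_perm}


def write_enrichment_table(stats: Sequence[OverlapStat], path) -> None:
    with open(path, "w") as fh:
        fh.write("tf\tn_ref\tn_query\tn_overlap\texpected\tfold\tp_hyper\n")
        for s in stats:
            fh.write(f"{s.tf_name}\t{s.n_ref}\t{s.n_query}\t{s.n_overlap}\t"
                     f"{s.expected:.4g}\t{s.fold:.4g}\t{s.p_hyper:.4g}\n")
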