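"""Genomic-interval data model and core ChIP-seq peak operations.

This module provides the data types used throughout the screen — called
peaks with summits, minimal gene models with first-intron structure, and
peak-to-gene links — together with the operations that start the screen:

* reading peak lists from narrowPeak / BED files,
* one-to-one matching of replicate peak lists by summit distance
  (a peak is reproducible when its summit lies within a fixed distance,
  by default 400 bp, of a summit in the other replicate),
* Pearson correlation of log-scale peak scores between matched replicates,
* nearest-TSS assignment of peaks to genes, and
* classification of a peak's position relative to its gene (within the
  10-kb upstream window of the TSS, inside the first intron, or elsewhere).

Coordinates are 0-based half-open throughout, matching BED/narrowPeak.
"""
from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq interval with its summit and significance.

    ``summit`` is the absolute genomic position of the point of highest
    enrichment; ``score`` is the peak caller's score (log scale in plots);
    ``neg_log10_p`` is the enrichment significance as -log10(p);
    ``fdr_pct`` is an optional peak-level FDR in percent.
    """

    chrom: str
    start: int
    end: int
    summit: int
    score: float = 0.0
    neg_log10_p: float = 0.0
    fdr_pct: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if not self.start <= self.summit < self.end:
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} outside interval"
            )
        if self.neg_log10_p < 0:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: neg_log10_p < 0")

    @property
    def center(self) -> int:
        """Interval midpoint (floor); used for center-based overlap rules."""
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start

    def label(self) -> str:
        return self.source_id or f"{self.chrom}:{self.start}-{self.end}"


class RegionClass(str, Enum):
    """Location of a peak summit relative to its assigned gene."""

    PROMOTER_PROXIMAL = "promoter-proximal"
    UPSTREAM_10KB = "within-10kb-upstream"
    FIRST_INTRON = "first-intron"
    OTHER = "other"


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: TSS, strand, span and first intron.

    ``span`` and ``first_intron`` are 0-based half-open intervals. The TSS
    sits on the strand-appropriate end of the span (start for +, end-1
    for -). ``first_intron`` is absent for intronless genes.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int
    span: tuple[int, int]
    first_intron: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        s, e = self.span
        if not s < e:
            raise ValueError(f"gene {self.gene_id}: empty span")
        expected_tss = s if self.strand == "+" else e - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} not on the {self.strand}-strand end of span {self.span}"
            )
        if self.first_intron is not None:
            i0, i1 = self.first_intron
            if not (s <= i0 < i1 <= e):
                raise ValueError(f"gene {self.gene_id}: first intron {self.first_intron} not inside span")


@dataclass(frozen=True)
class PeakGeneLink:
    """A peak assigned to the gene with the nearest TSS.

    ``signed_tss_distance`` is summit minus TSS in gene-strand orientation:
    negative values are upstream of the TSS. ``gene`` is None when the
    peak's chromosome is absent from the annotation.
    """

    peak: Peak
    gene: Optional[GeneModel]
    signed_tss_distance: Optional[int]
    region_class: RegionClass

    @property
    def is_assigned(self) -> bool:
        return self.gene is not None


# ---------------------------------------------------------------------------
# file ingestion
# ---------------------------------------------------------------------------

def strip_chr_prefix(name: str) -> str:
    """Normalize chromosome names by dropping a leading 'chr' (logged by callers)."""
    return name[3:] if name.lower().startswith("chr") and len(name) > 3 else name


def read_peaks(
    path,
    format: str = "narrowPeak",
    chrom_normalizer: Optional[Callable[[str], str]] = None,
) -> list[Peak]:
    """Read a peak list from a narrowPeak (ENCODE BED6+4) or BED file.

    narrowPeak: summit = start + point-source offset (column 10); an offset
    of -1 falls back to the interval midpoint. Column 5 is the score and
    column 8 the -log10 p-value. Plain BED (3-6 columns): summit = floor
    midpoint, score from column 5 when present.
    """
    fmt = format.lower()
    if fmt not in ("narrowpeak", "bed"):
        raise ValueError(f"unknown peak format {format!r}; expected 'narrowPeak' or 'BED'")
    peaks: list[Peak] = []
    normalized = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                if fmt == "narrowpeak":
                    if len(fields) < 10:
                        raise ValueError("narrowPeak requires 10 columns")
                    offset = int(fields[9])
                    summit = start + offset if offset >= 0 else (start + end) // 2
                    score = float(fields[4])
                    neg_log10_p = float(fields[7])
                    name = fields[3]
                else:
                    summit = (start + end) // 2
                    score = float(fields[4]) if len(fields) > 4 else 0.0
                    neg_log10_p = 0.0
                    name = fields[3] if len(fields) > 3 else ""
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed {format} record at line {lineno}: {exc}") from None
            if chrom_normalizer is not None:
                new = chrom_normalizer(chrom)
                normalized = normalized or new != chrom
                chrom = new
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, summit=summit,
                     score=score, neg_log10_p=neg_log10_p, source_id=name)
            )
    if not peaks:
        log.warning("%s: no peak records found (empty file)", path)
    if normalized:
        log.info("%s: chromosome names normalized on ingest", path)
    return peaks


def write_peaks_narrowpeak(peaks: Sequence[Peak], path) -> None:
    """Write peaks in ENCODE narrowPeak layout (summit as column-10 offset)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.source_id or f"peak_{i}"
            fh.write(
                "\t".join(
                    [p.chrom, str(p.start), str(p.end), name, f"{p.score:.6g}", ".",
                     f"{p.score:.6g}", f"{p.neg_log10_p:.6g}", "-1", str(p.summit - p.start)]
                ) + "\n"
            )


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.source_id or f"peak_{i}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.score:.6g}\t.\n")


# ---------------------------------------------------------------------------
# GTF annotation (exon features only; the dialect the generator emits)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_genes_gtf(path, chrom_normalizer: Optional[Callable[[str], str]] = None) -> list[GeneModel]:
    """Build gene models from the exon features of a GTF file.

    The TSS is derived from the strand; the first intron (in transcription
    order) is the gap between the first two exons. GTF 1-based inclusive
    coordinates are converted to 0-based half-open on ingest.
    """
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF record at line {lineno}")
            if fields[2] != "exon":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
            if chrom_normalizer is not None:
                chrom = chrom_normalizer(chrom)
            attrs = _parse_gtf_attributes(fields[8])
            gid = attrs.get("gene_id", "")
            rec = exons.setdefault(gid, {"chrom": chrom, "strand": strand,
                                         "symbol": attrs.get("gene_name", gid), "exons": []})
            rec["exons"].append((start, end))
    genes: list[GeneModel] = []
    for gid, rec in exons.items():
        ex = sorted(rec["exons"])
        span = (ex[0][0], ex[-1][1])
        strand = rec["strand"]
        tss = span[0] if strand == "+" else span[1] - 1
        first_intron = None
        if len(ex) > 1:
            if strand == "+":
                first_intron = (ex[0][1], ex[1][0])
            else:
                first_intron = (ex[-2][1], ex[-1][0])
        genes.append(GeneModel(gene_id=gid, symbol=rec["symbol"], chrom=rec["chrom"],
                               strand=strand, tss=tss, span=span, first_intron=first_intron))
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    if not genes:
        log.warning("%s: no exon features found", path)
    return genes


def write_genes_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as GTF exon features (two exons flanking the first intron)."""
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            if g.first_intron is None:
                exons = [(s, e)]
            else:
                i0, i1 = g.first_intron
                exons = [(s, i0), (i1, e)]
            for n, (x0, x1) in enumerate(exons, start=1):
                attrs = (f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; '
                         f'gene_name "{g.symbol}"; exon_number "{n}";')
                fh.write("\t".join([g.chrom, "apcscreen", "exon", str(x0 + 1), str(x1),
                                    ".", g.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# replicate intersection
# ---------------------------------------------------------------------------

def _greedy_match(
    a: Sequence[Peak],
    b: Sequence[Peak],
    key: Callable[[Peak], int],
    max_dist: int,
    strict: bool,
) -> list[tuple[Peak, Peak]]:
    """Greedy nearest-first one-to-one matching of peaks by a positional key.

    Candidate pairs on the same chromosome with key distance < max_dist
    (strict) or <= max_dist (non-strict) are taken in ascending distance
    order, ties broken by the lower coordinate first (the sort key
    (distance, min position, max position) is symmetric in the two inputs,
    so swapping the lists yields the same pair set).
    """
    if max_dist < 0:
        raise ValueError(f"max distance must be non-negative, got {max_dist}")
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for j, p in enumerate(b):
        by_chrom_b.setdefault(p.chrom, []).append((key(p), j))
    for lst in by_chrom_b.values():
        lst.sort()
    candidates: list[tuple[int, int, int, int, int]] = []
    for i, p in enumerate(a):
        lst = by_chrom_b.get(p.chrom)
        if not lst:
            continue
        ka = key(p)
        positions = [x[0] for x in lst]
        lo = bisect_left(positions, ka - max_dist)
        hi = bisect_right(positions, ka + max_dist)
        for kb, j in lst[lo:hi]:
            d = abs(ka - kb)
            if (d < max_dist) if strict else (d <= max_dist):
                candidates.append((d, min(ka, kb), max(ka, kb), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for d, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((a[i], b[j]))
    pairs.sort(key=lambda ab: (ab[0].chrom, key(ab[0]), key(ab[1])))
    return pairs


def intersect_replicates(
    a: Sequence[Peak],
    b: Sequence[Peak],
    max_summit_dist: int = 400,
    strict: bool = True,
) -> list[tuple[Peak, Peak]]:
    """Match replicate peak lists one-to-one by summit distance.

    Two peaks on the same chromosome overlap when their summits are
    separated by less than ``max_summit_dist`` (default 400 bp, the median
    peak width in typical peak-calling output); ``strict=False`` switches
    the comparator to <=, the rule used for cross-factor center matching.
    Each peak participates in at most one pair; matching is greedy by
    ascending summit distance. The first element of each pair (the
    replicate-a peak) is the representative interval.
    """
    return _greedy_match(a, b, key=lambda p: p.summit, max_dist=max_summit_dist, strict=strict)


def shared_peaks(pairs: Sequence[tuple[Peak, Peak]]) -> list[Peak]:
    """Representative (replicate-a) peaks of a matched-pair list."""
    return [pa for pa, _ in pairs]


def peak_score_correlation(pairs: Sequence[tuple[Peak, Peak]]) -> float:
    """Pearson correlation of log10 peak scores across matched replicate pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs for a correlation")
    for pa, pb in pairs:
        for p in (pa, pb):
            if p.score <= 0:
                raise ValueError(f"peak {p.label()} has non-positive score {p.score}; cannot log-transform")
    x = np.log10([pa.score for pa, _ in pairs])
    y = np.log10([pb.score for _, pb in pairs])
    return float(np.corrcoef(x, y)[0, 1])


def write_pairs_table(pairs: Sequence[tuple[Peak, Peak]], path) -> None:
    header = ["chrom", "start_1", "end_1", "summit_1", "score_1",
              "start_2", "end_2", "summit_2", "score_2", "summit_distance"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for pa, pb in pairs:
            fh.write("\t".join(map(str, [pa.chrom, pa.start, pa.end, pa.summit, pa.score,
                                         pb.start, pb.end, pb.summit, pb.score,
                                         abs(pa.summit - pb.summit)])) + "\n")


# ---------------------------------------------------------------------------
# peak-to-gene assignment
# ---------------------------------------------------------------------------

def _signed_distance(summit: int, gene: GeneModel) -> int:
    # Negative = upstream of the TSS in gene-strand orientation.
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def _classify(summit: int, gene: Optional[GeneModel], signed: Optional[int], upstream_window: int) -> RegionClass:
    if gene is None or signed is None:
        return RegionClass.OTHER
    if gene.first_intron is not None:
        i0, i1 = gene.first_intron
        if i0 <= summit < i1:
            return RegionClass.FIRST_INTRON
    upstream = -signed
    if 0 < upstream <= upstream_window:
        return RegionClass.UPSTREAM_10KB
    return RegionClass.OTHER


def classify_location(link: PeakGeneLink, upstream_window: int = 10_000) -> RegionClass:
    """Classify a linked peak as within-10kb-upstream, first-intron, or other.

    The upstream class applies when the summit is 1..upstream_window bp
    upstream of the TSS in gene-strand orientation (inclusive boundary);
    a summit inside the first intron takes precedence.
    """
    return _classify(link.peak.summit, link.gene, link.signed_tss_distance, upstream_window)


def assign_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: Optional[int] = None,
    upstream_window: int = 10_000,
) -> list[PeakGeneLink]:
    """Link each peak to the gene with the nearest TSS on its chromosome.

    Equidistant TSS ties go to the lower coordinate, then lexicographic
    gene_id. There is no distance cap unless ``max_distance`` is given.
    Peaks on chromosomes absent from the annotation yield an unassigned
    link (gene None) with a warning.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    by_chrom: dict[str, list[tuple[int, str, GeneModel]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g))
    for lst in by_chrom.values():
        lst.sort(key=lambda t: (t[0], t[1]))
    links: list[PeakGeneLink] = []
    n_unassigned = 0
    for p in peaks:
        lst = by_chrom.get(p.chrom)
        if not lst:
            n_unassigned += 1
            links.append(PeakGeneLink(peak=p, gene=None, signed_tss_distance=None,
                                      region_class=RegionClass.OTHER))
            continue
        positions = [t[0] for t in lst]
        i = bisect_left(positions, p.summit)
        best_d = None
        for idx in (i - 1, i):
            if 0 <= idx < len(lst):
                d = abs(p.summit - positions[idx])
                if best_d is None or d < best_d:
                    best_d = d
        assert best_d is not None
        if max_distance is not None and best_d > max_distance:
            n_unassigned += 1
            links.append(PeakGeneLink(peak=p, gene=None, signed_tss_distance=None,
                                      region_class=RegionClass.OTHER))
            continue
        # all genes at exactly best_d (duplicate TSSs included); tie-break
        # by (tss, gene_id) which the per-position sort already provides
        ties: list[tuple[int, str, GeneModel]] = []
        for target in (p.summit - best_d, p.summit + best_d):
            lo = bisect_left(positions, target)
            hi = bisect_right(positions, target)
            ties.extend(lst[lo:hi])
        ties.sort(key=lambda t: (t[0], t[1]))
        gene = ties[0][2]
        signed = _signed_distance(p.summit, gene)
        links.append(PeakGeneLink(peak=p, gene=gene, signed_tss_distance=signed,
                                  region_class=_classify(p.summit, gene, signed, upstream_window)))
    if n_unassigned:
        log.warning("%d peaks could not be assigned to a gene", n_unassigned)
    return links


def write_links_table(links: Sequence[PeakGeneLink], path) -> None:
    header = ["chrom", "start", "end", "summit", "score", "neg_log10_p",
              "gene_id", "symbol", "strand", "signed_tss_distance", "region_class"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for ln in links:
            p = ln.peak
            if ln.gene is None:
                gid = sym = strand = UNASSIGNED
                dist = "NA"
            else:
                gid, sym, strand = ln.gene.gene_id, ln.gene.symbol, ln.gene.strand
                dist = str(ln.signed_tss_distance)
            fh.write("\t".join(map(str, [p.chrom, p.start, p.end, p.summit, p.score,
                                         p.neg_log10_p, gid, sym, strand, dist,
                                         ln.region_class.value])) + "\n")


# ---------------------------------------------------------------------------
# genome sequence access
# ---------------------------------------------------------------------------

def open_genome(path):
    """Open an indexed FASTA for random access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path))


def fetch_sequence(genome: Mapping, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] as an upper-case string, truncating at
    chromosome bounds with a warning."""
    ref = genome[chrom]
    n = len(ref)
    s, e = max(0, start), min(n, end)
    if (s, e) != (start, end):
        log.warning("interval %s:%d-%d truncated to chromosome bounds", chrom, start, end)
    if e <= s:
        return ""
    return str(ref[s:e]).upper()
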