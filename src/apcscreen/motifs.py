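"""IUPAC consensus motif scanning over peak sequences.

Implements degenerate-consensus matching (both strands, overlapping hits)
for the transcription-factor motifs screened for in APC-associated
regions — AP-1 (TGASTCA), TCF7L2 (WWCAAAG), SP1 (KGGGCGGRRY), USF1/2
(CACGTG), NRF1 (GCGCRYGCGC) and EGR-1 (GCGKGGGCG) — plus per-peak
prevalence statistics and the most-significant-subset selection used to
contrast all peaks against the top-N most enriched peaks.

Presence (>= 1 hit anywhere in the scanned window), not hit count, drives
prevalence. ``N`` bases in the genome never match, so assembly gaps cannot
inflate prevalence.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

from .intervals import Peak, fetch_sequence

log = logging.getLogger(__name__)

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_VALID_SEQ = re.compile(r"[ACGTN]*\Z")


def reverse_complement_iupac(pattern: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus pattern, e.g. AP-1 = TGASTCA."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        bad = [c for c in self.iupac.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"motif {self.name!r}: invalid IUPAC code(s) {bad}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


DEFAULT_MOTIFS: list[MotifPattern] = [
    MotifPattern("AP-1", "TGASTCA"),
    MotifPattern("TCF7L2", "WWCAAAG"),
    MotifPattern("SP1", "KGGGCGGRRY"),
    MotifPattern("USF1/2", "CACGTG"),
    MotifPattern("NRF1", "GCGCRYGCGC"),
    MotifPattern("EGR-1", "GCGKGGGCG"),
]


def read_motifs(path) -> list[MotifPattern]:
    """Read a two-column (name TAB iupac) motif file; '#' lines are comments."""
    motifs = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: expected 'name<TAB>iupac' at line {lineno}")
            motifs.append(MotifPattern(parts[0], parts[1]))
    return motifs


def write_motifs(motifs: Sequence[MotifPattern], path) -> None:
    with open(path, "w") as fh:
        fh.write("# name\tiupac\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.iupac}\n")


class MotifHit(NamedTuple):
    position: int
    strand: str


def _compiled(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported; classes contain
    # only ACGT, so sequence N never matches (conservative)
    body = "".join("[" + IUPAC[c] + "]" for c in pattern)
    return re.compile(r"(?=" + body + r")")


def scan_sequence(seq: str, motif: MotifPattern, both_strands: bool = True) -> list[MotifHit]:
    """All positions where the motif (or its reverse complement) matches.

    Matching is case-insensitive over {A,C,G,T,N}; any other character is
    an error. Minus-strand hits are reported at the position of the
    leftmost base of the match on the given (plus-strand) sequence.
    """
    s = seq.upper()
    if not _VALID_SEQ.match(s):
        bad = sorted(set(s) - set("ACGTN"))
        raise ValueError(f"invalid sequence character(s) {bad}; expected A/C/G/T/N")
    hits = [MotifHit(m.start(), "+") for m in _compiled(motif.iupac).finditer(s)]
    if both_strands:
        rc = reverse_complement_iupac(motif.iupac)
        hits += [MotifHit(m.start(), "-") for m in _compiled(rc).finditer(s)]
    hits.sort()
    return hits


@dataclass(frozen=True)
class MotifPrevalence:
    """Fraction of peaks containing >= 1 match to a motif."""

    motif: MotifPattern
    n_peaks: int
    n_with_hit: int

    @property
    def pct(self) -> float:
        return 100.0 * self.n_with_hit / self.n_peaks if self.n_peaks else 0.0


def peak_sequence(genome: Mapping, peak: Peak, flank: Optional[int] = None) -> str:
    """Sequence scanned for a peak: the full peak extent by default, or
    summit +/- ``flank`` bp when a fixed window is requested."""
    if flank is None:
        return fetch_sequence(genome, peak.chrom, peak.start, peak.end)
    return fetch_sequence(genome, peak.chrom, peak.summit - flank, peak.summit + flank)


def motif_prevalence(
    peaks: Sequence[Peak],
    genome: Mapping,
    motifs: Sequence[MotifPattern],
    flank: Optional[int] = None,
    both_strands: bool = True,
) -> list[MotifPrevalence]:
    """Per-motif prevalence across a peak set (a peak counts once per motif
    regardless of hit multiplicity)."""
    seqs = [peak_sequence(genome, p, flank) for p in peaks]
    out = []
    for m in motifs:
        n_hit = sum(1 for s in seqs if scan_sequence(s, m, both_strands=both_strands))
        out.append(MotifPrevalence(motif=m, n_peaks=len(peaks), n_with_hit=n_hit))
    return out


def top_n_by_significance(peaks: Sequence[Peak], n: int = 500) -> list[Peak]:
    """The n most significant peaks (highest -log10 p; ties by descending
    score, then ascending coordinate). All peaks are returned when fewer
    than n are supplied."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    ranked = sorted(peaks, key=lambda p: (-p.neg_log10_p, -p.score, p.chrom, p.start))
    return ranked[:n]


def write_prevalence_table(rows: Sequence[MotifPrevalence], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tiupac\tn_peaks\tn_with_hit\tpct\n")
        for r in rows:
            fh.write(f"{r.motif.name}\t{r.motif.iupac}\t{r.n_peaks}\t{r.n_with_hit}\t{r.pct:.1f}\n")
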