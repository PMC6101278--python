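"""Seeded generators for every input the screen consumes, with ground truth.

The generators emulate the study's data shapes at desk scale: a small
random genome, a two-exon gene annotation, two replicate APC peak lists
with jittered summits and optional replicate dropout, motif instances
written into peak sequences at controlled prevalences, public-style TF
peak sets with controlled overlap, a Cuffdiff-style human knockdown DE
table, per-sample adenoma expression matrices for two mouse tumor models,
and a dual-luciferase reporter plate with planted condition effects.

Every generator is a pure function of its seed and parameters. One global
seed fans out to per-generator child seeds via a keyed blake2s hash
(``child_seed``), so each fixture component is individually reproducible.

Planted quantities are exact by construction: motif-carrier counts are
exact because accidental IUPAC matches inside peak windows are scrubbed
by point mutation before planting, and TF-overlap counts are exact
because background TF peaks are rejection-sampled away from APC peak
centers.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cascade import ScreenConfig, ScreenInputs
from .expression import DERecord, build_adenoma_panels, write_cuffdiff
from .intervals import GeneModel, Peak, write_genes_gtf, write_peaks_narrowpeak
from .motifs import DEFAULT_MOTIFS, IUPAC, MotifPattern, scan_sequence, write_motifs
from .reporter import ReporterWell, write_plate
from .tf_overlap import consolidate_tf_replicates

log = logging.getLogger(__name__)

_BASES = "ACGT"


def child_seed(seed: int, label: str) -> int:
    """Deterministic per-component seed derived from (seed, label)."""
    digest = hashlib.blake2s(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, label))


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def make_genome(seed: int, n_chrom: int = 2, chrom_len: int = 1_000_000) -> dict[str, str]:
    """Uniform-random A/C/G/T genome, deterministic per seed."""
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10 kb")
    rng = np.random.default_rng(seed)
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(n_chrom):
        codes = rng.integers(0, 4, size=chrom_len)
        genome[f"chr{i + 1}"] = lookup[codes].tobytes().decode("ascii")
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = str(genome[chrom])
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def make_annotation(
    seed: int,
    chrom_sizes: Mapping[str, int],
    n_genes: int = 200,
    exon1_len: int = 200,
    exon2_len: int = 500,
    intron_len: tuple[int, int] = (1_000, 3_000),
    edge_margin: int = 2_000,
) -> list[GeneModel]:
    """Strand-balanced, non-overlapping two-exon gene models.

    Every gene has an exon1-intron1-exon2 structure in transcription
    order; placement is rejection-sampled, raising if the genome cannot
    hold the requested number of genes.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    strands = np.array(["+", "-"])[np.tile([0, 1], (n_genes + 1) // 2)[:n_genes]]
    strands = strands[rng.permutation(n_genes)]
    genes: list[GeneModel] = []
    for i in range(n_genes):
        ilen = int(rng.integers(intron_len[0], intron_len[1] + 1))
        glen = exon1_len + ilen + exon2_len
        for attempt in range(2_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            size = chrom_sizes[chrom]
            if size - glen - 2 * edge_margin <= 0:
                continue
            start = int(rng.integers(edge_margin, size - glen - edge_margin))
            end = start + glen
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise ValueError(f"could not place {n_genes} genes; use a longer genome")
        strand = str(strands[i])
        if strand == "+":
            tss = start
            first_intron = (start + exon1_len, start + exon1_len + ilen)
        else:
            tss = end - 1
            first_intron = (end - exon1_len - ilen, end - exon1_len)
        genes.append(GeneModel(gene_id=f"G{i:04d}", symbol=f"GENE{i:04d}", chrom=chrom,
                               strand=strand, tss=tss, span=(start, end),
                               first_intron=first_intron))
    genes.sort(key=lambda g: (g.chrom, g.span[0]))
    return genes


# ---------------------------------------------------------------------------
# peak planting
# ---------------------------------------------------------------------------

@dataclass
class PeakTruth:
    index: int
    chrom: str
    summit: int
    width: int
    shared: bool
    only_rep: Optional[int]
    top: bool
    motifs: tuple[str, ...]


@dataclass
class PlantedPeaks:
    genome: dict[str, str]
    rep1: list[Peak]
    rep2: list[Peak]
    truth: list[PeakTruth]
    motif_carriers: dict[str, list[int]]
    top_ids: list[int]

    @property
    def n_shared(self) -> int:
        return sum(1 for t in self.truth if t.shared)


def _concrete_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][int(rng.integers(0, len(IUPAC[c])))] for c in pattern)


def _scrub_region(chrom_seq: bytearray, start: int, end: int,
                  motifs: Sequence[MotifPattern],
                  protected: Sequence[tuple[int, int]],
                  rng: np.random.Generator) -> None:
    """Point-mutate away any motif match inside [start, end) that does not
    start inside a protected (planted) span. Bounded loop; raises if the
    region cannot be cleaned without touching protected spans."""
    for _ in range(100):
        window = chrom_seq[start:end].decode("ascii")
        dirty = []
        for m in motifs:
            for hit in scan_sequence(window, m):
                s_abs = start + hit.position
                e_abs = s_abs + len(m)
                if any(ps <= s_abs and e_abs <= pe for ps, pe in protected):
                    continue
                dirty.append((s_abs, e_abs))
        if not dirty:
            return
        for s_abs, e_abs in dirty:
            mutable = [i for i in range(s_abs, e_abs)
                       if not any(ps <= i < pe for ps, pe in protected)]
            if not mutable:
                raise RuntimeError("stray motif match fully inside planted spans")
            i = mutable[len(mutable) // 2]
            current = chr(chrom_seq[i])
            chrom_seq[i] = ord(_BASES[(_BASES.index(current) + 1 + int(rng.integers(0, 3))) % 4])
    raise RuntimeError("could not scrub region of accidental motif matches")


def plant_peaks(
    seed: int,
    genome: Mapping[str, str],
    n_peaks: int = 300,
    anchors: Optional[Sequence[tuple[str, int]]] = None,
    anchor_motifs: Optional[Mapping[int, Sequence[MotifPattern]]] = None,
    width_range: tuple[int, int] = (300, 700),
    replicate_jitter_sd: float = 20.0,
    dropout: float = 0.1,
    motif_plan: Optional[Mapping[MotifPattern, tuple[float, float]]] = None,
    top_frac: float = 0.15,
    min_separation: int = 1_500,
    exclusion_zones: Optional[Sequence[tuple[str, int, int]]] = None,
    protect_anchors: bool = True,
) -> PlantedPeaks:
    """Plant peaks into a genome copy and emit two jittered replicate lists.

    ``anchors`` fixes the summit positions of the first len(anchors)
    peaks (these never drop out when ``protect_anchors``); the rest are
    placed at random with ``min_separation`` between summits and outside
    ``exclusion_zones``. ``motif_plan`` maps a motif to the (fraction of
    top-significance peaks, fraction of remaining peaks) that carry a
    planted instance — exact counts by construction, with accidental
    matches scrubbed. ``dropout`` is the exact fraction of eligible peaks
    present in only one replicate. Enrichment significances are drawn so
    that a ``top_frac`` subset is the most significant.
    """
    rng = np.random.default_rng(seed)
    anchors = list(anchors or [])
    if len(anchors) > n_peaks:
        raise ValueError("more anchors than peaks")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    max_w = width_range[1]
    motif_plan = dict(motif_plan or {})
    anchor_motifs = {int(k): list(v) for k, v in (anchor_motifs or {}).items()}
    all_motifs = list({m.name: m for m in
                       list(motif_plan) + [m for ms in anchor_motifs.values() for m in ms]}.values())
    for m in all_motifs:
        if len(m) > width_range[0] // 2:
            raise ValueError(f"motif {m.name} too long for the peak width range")

    chroms = list(genome)
    sizes = {c: len(genome[c]) for c in chroms}
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    positions: list[tuple[str, int]] = list(anchors)
    occupied: dict[str, list[int]] = {c: [] for c in chroms}
    for c, s in anchors:
        occupied[c].append(s)
    zones = list(exclusion_zones or [])
    margin = max_w // 2 + 100
    for _ in range(n_peaks - len(anchors)):
        for attempt in range(5_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            pos = int(rng.integers(margin, sizes[chrom] - margin))
            if any(abs(pos - q) < min_separation for q in occupied[chrom]):
                continue
            if any(zc == chrom and zs <= pos < ze for zc, zs, ze in zones):
                continue
            positions.append((chrom, pos))
            occupied[chrom].append(pos)
            break
        else:
            raise ValueError("could not place peaks; relax separation or enlarge genome")

    n = n_peaks
    widths = rng.integers(width_range[0], width_range[1] + 1, size=n)
    widths = (widths // 2) * 2  # even widths keep the summit centered

    # significance: a designated top fraction is the most significant
    n_top = max(1, round(top_frac * n))
    top_ids = sorted(int(i) for i in rng.choice(n, size=n_top, replace=False))
    top_set = set(top_ids)
    neg_log10_p = np.where(np.isin(np.arange(n), top_ids),
                           rng.uniform(12.0, 30.0, size=n),
                           rng.uniform(5.0, 10.0, size=n))
    score1 = neg_log10_p * rng.uniform(8.0, 12.0, size=n)
    score2 = score1 * np.exp2(rng.normal(0.0, 0.15, size=n))

    # motif carriers: exact counts per plan, plus forced anchor motifs
    per_peak_motifs: dict[int, list[MotifPattern]] = {i: [] for i in range(n)}
    for i, ms in anchor_motifs.items():
        per_peak_motifs[i].extend(ms)
    rest_ids = [i for i in range(n) if i not in top_set]
    for motif, (frac_top, frac_rest) in motif_plan.items():
        k_top = round(frac_top * len(top_ids))
        k_rest = round(frac_rest * len(rest_ids))
        chosen = ([top_ids[int(j)] for j in rng.choice(len(top_ids), size=k_top, replace=False)]
                  + [rest_ids[int(j)] for j in rng.choice(len(rest_ids), size=k_rest, replace=False)])
        for i in chosen:
            if all(m.name != motif.name for m in per_peak_motifs[i]):
                per_peak_motifs[i].append(motif)

    # mutate a genome copy: scrub accidental matches, then write instances
    mutable = {c: bytearray(genome[c], "ascii") for c in chroms}
    planted_spans: dict[int, list[tuple[int, int]]] = {}
    if all_motifs:
        for i in range(n):
            chrom, s = positions[i]
            w = int(widths[i])
            # replicate jitter is clipped to width/4, so the scanned extent
            # stays within summit +/- 3w/4; scrub the whole reachable window
            half = 3 * w // 4 + 12
            lo, hi = max(0, s - half), min(sizes[chrom], s + half)
            spans: list[tuple[int, int]] = []
            offset = s - sum(len(m) for m in per_peak_motifs[i]) // 2 - len(per_peak_motifs[i])
            for m in per_peak_motifs[i]:
                for attempt in range(20):
                    inst = _concrete_instance(m.iupac, rng)
                    mutable[chrom][offset:offset + len(m)] = inst.encode("ascii")
                    try:
                        _scrub_region(mutable[chrom], lo, hi, all_motifs,
                                      spans + [(offset, offset + len(m))], rng)
                    except RuntimeError:
                        continue
                    spans.append((offset, offset + len(m)))
                    offset += len(m) + 2
                    break
                else:
                    raise RuntimeError(f"could not plant motif {m.name} in peak {i}")
            if not per_peak_motifs[i]:
                _scrub_region(mutable[chrom], lo, hi, all_motifs, [], rng)
            planted_spans[i] = spans
    edited = {c: mutable[c].decode("ascii") for c in chroms}

    # replicate membership: exact dropout among eligible (non-anchor) peaks
    eligible = list(range(len(anchors), n)) if protect_anchors else list(range(n))
    n_drop = round(dropout * len(eligible))
    drop_ids = sorted(int(eligible[j]) for j in rng.choice(len(eligible), size=n_drop, replace=False))
    only_rep = {i: (1 if k % 2 == 0 else 2) for k, i in enumerate(drop_ids)}

    def make_rep(rep: int) -> list[Peak]:
        peaks = []
        for i in range(n):
            if i in only_rep and only_rep[i] != rep:
                continue
            chrom, s = positions[i]
            w = int(widths[i])
            jitter = int(np.clip(round(rng.normal(0.0, replicate_jitter_sd)), -(w // 4), w // 4))
            summit = int(np.clip(s + jitter, 1, sizes[chrom] - 2))
            start = max(0, summit - w // 2)
            end = min(sizes[chrom], start + w)
            score = float(score1[i] if rep == 1 else score2[i])
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit,
                              score=score, neg_log10_p=float(neg_log10_p[i]),
                              source_id=f"apc_{i}_r{rep}"))
        peaks.sort(key=lambda p: (p.chrom, p.start))
        return peaks

    rep1, rep2 = make_rep(1), make_rep(2)
    truth = [PeakTruth(index=i, chrom=positions[i][0], summit=positions[i][1],
                       width=int(widths[i]), shared=i not in only_rep,
                       only_rep=only_rep.get(i), top=i in top_set,
                       motifs=tuple(m.name for m in per_peak_motifs[i]))
             for i in range(n)]
    carriers = {m.name: sorted(i for i in range(n) if any(x.name == m.name for x in per_peak_motifs[i]))
                for m in all_motifs}
    return PlantedPeaks(genome=edited, rep1=rep1, rep2=rep2, truth=truth,
                        motif_carriers=carriers, top_ids=top_ids)


# ---------------------------------------------------------------------------
# TF peak sets
# ---------------------------------------------------------------------------

@dataclass
class TFPlan:
    overlap_ids: tuple[int, ...]        # APC peak indices to co-occupy
    n_background: int = 50
    n_replicates: int = 2
    center_offset_max: int = 120
    replicate_jitter: int = 30
    width_range: tuple[int, int] = (200, 600)


def plant_tf_peaks(
    seed: int,
    apc_truth: Sequence[PeakTruth],
    chrom_sizes: Mapping[str, int],
    plans: Mapping[str, TFPlan],
    apc_margin: int = 1_000,
) -> tuple[dict[str, list[list[Peak]]], dict[str, list[int]]]:
    """Replicate TF peak lists co-occupying chosen APC peaks.

    Overlapping TF peaks are centered within ``center_offset_max`` bp of
    the APC summit; background TF peaks are rejection-sampled at least
    ``apc_margin`` bp from every APC summit, so planted overlap counts
    are exact under the 400-bp center rule.
    """
    rng = np.random.default_rng(seed)
    apc_positions: dict[str, list[int]] = {}
    for t in apc_truth:
        apc_positions.setdefault(t.chrom, []).append(t.summit)
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    tf_sets: dict[str, list[list[Peak]]] = {}
    truth: dict[str, list[int]] = {}
    for tf_name, plan in plans.items():
        centers: list[tuple[str, int]] = []
        for i in plan.overlap_ids:
            t = apc_truth[i]
            off = int(rng.integers(-plan.center_offset_max, plan.center_offset_max + 1))
            centers.append((t.chrom, t.summit + off))
        for _ in range(plan.n_background):
            for attempt in range(5_000):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                pos = int(rng.integers(1_000, chrom_sizes[chrom] - 1_000))
                if any(abs(pos - s) < apc_margin for s in apc_positions.get(chrom, [])):
                    continue
                if any(c == chrom and abs(pos - x) < apc_margin for c, x in centers):
                    continue
                centers.append((chrom, pos))
                break
            else:
                raise ValueError("could not place background TF peaks")
        reps = []
        for r in range(plan.n_replicates):
            peaks = []
            for k, (chrom, c) in enumerate(centers):
                w = int(rng.integers(plan.width_range[0], plan.width_range[1] + 1)) // 2 * 2
                jit = int(rng.integers(-plan.replicate_jitter, plan.replicate_jitter + 1))
                center = int(np.clip(c + jit, w // 2, chrom_sizes[chrom] - w // 2 - 1))
                start = center - w // 2
                peaks.append(Peak(chrom=chrom, start=start, end=start + w,
                                  summit=center, score=float(rng.uniform(50, 500)),
                                  neg_log10_p=float(rng.uniform(5, 20)),
                                  source_id=f"{tf_name}_{k}_r{r + 1}"))
            peaks.sort(key=lambda p: (p.chrom, p.start))
            reps.append(peaks)
        tf_sets[tf_name] = reps
        truth[tf_name] = sorted(plan.overlap_ids)
    return tf_sets, truth


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionData:
    human_de: list[DERecord]
    expr_a: pd.DataFrame
    manifest_a: dict[str, str]
    expr_b: pd.DataFrame
    manifest_b: dict[str, str]
    concordant: dict[str, str]          # human symbol -> direction
    extra_de: dict[str, str]            # human-DE but mouse-null


def mouse_symbol(human_symbol: str) -> str:
    return human_symbol.capitalize()


def make_expression(
    seed: int,
    symbols: Sequence[str],
    concordant: Mapping[str, str],
    extra_de: Optional[Mapping[str, str]] = None,
    samples_per_model: int = 3,
    controls_per_model: int = 3,
    mouse_effect: float = 2.5,
    noise_sd: float = 0.3,
    q_sig_range: tuple[float, float] = (1e-4, 0.01),
) -> ExpressionData:
    """Human DE table plus two mouse adenoma matrices with planted truth.

    ``concordant`` genes are significant in the human table (q below
    threshold) and change ``mouse_effect``-fold in the same direction in
    both mouse models, with Gaussian noise of ``noise_sd`` on the log2
    scale (0 gives exact effects); ``extra_de`` genes are human-DE only;
    all other genes are null everywhere.
    """
    rng = np.random.default_rng(seed)
    extra_de = dict(extra_de or {})
    planted = {**dict(concordant), **extra_de}
    bad = [g for g in planted if g not in set(symbols)]
    if bad:
        raise ValueError(f"planted genes absent from the symbol list: {bad[:5]}")
    records = []
    for sym in symbols:
        base = float(2 ** rng.normal(5.0, 1.5))
        if sym in planted:
            sign = 1.0 if planted[sym] == "up" else -1.0
            lfc = sign * float(rng.uniform(1.0, 3.0))
            q = float(rng.uniform(*q_sig_range))
            p = q * float(rng.uniform(0.05, 0.5))
        else:
            lfc = float(rng.normal(0.0, 0.2))
            p = float(rng.uniform(0.05, 1.0))
            q = float(rng.uniform(0.06, 1.0))
        records.append(DERecord(gene=sym, fpkm_control=base, fpkm_knockdown=base * 2 ** lfc,
                                log2fc=lfc, p=p, q=q))

    def model_matrix(label: str) -> tuple[pd.DataFrame, dict[str, str]]:
        tumor_cols = [f"{label}_tumor_{j + 1}" for j in range(samples_per_model)]
        ctrl_cols = [f"{label}_ctrl_{j + 1}" for j in range(controls_per_model)]
        data = {}
        base = 2 ** rng.normal(6.0, 1.0, size=len(symbols))
        for j, col in enumerate(ctrl_cols):
            data[col] = base * 2 ** rng.normal(0.0, noise_sd, size=len(symbols))
        effect = np.ones(len(symbols))
        for i, sym in enumerate(symbols):
            if sym in concordant:
                effect[i] = mouse_effect if concordant[sym] == "up" else 1.0 / mouse_effect
        for col in tumor_cols:
            data[col] = base * effect * 2 ** rng.normal(0.0, noise_sd, size=len(symbols))
        df = pd.DataFrame(data, index=[mouse_symbol(s) for s in symbols])
        df.index.name = "gene"
        manifest = {**{c: "tumor" for c in tumor_cols}, **{c: "control" for c in ctrl_cols}}
        return df, manifest

    expr_a, manifest_a = model_matrix("aomdss")
    expr_b, manifest_b = model_matrix("apcmin")
    return ExpressionData(human_de=records, expr_a=expr_a, manifest_a=manifest_a,
                          expr_b=expr_b, manifest_b=manifest_b,
                          concordant=dict(concordant), extra_de=extra_de)


# ---------------------------------------------------------------------------
# reporter plates
# ---------------------------------------------------------------------------

DEFAULT_BASE_ACTIVITY = {
    "empty-vector": 1.0,
    "TOPFLASH": 6.0,
    "FOPFLASH": 1.2,
    "PHLDB2-intron1": 4.0,
    "MALL-intron1": 3.0,
}

DEFAULT_REPORTER_EFFECTS = {
    ("TOPFLASH", "siAPC"): 2.0,
    ("TOPFLASH", "siCTNNB1"): 0.5,
    ("PHLDB2-intron1", "siAPC"): 1.8,
    ("PHLDB2-intron1", "siCTNNB1"): 0.6,
    ("MALL-intron1", "siAPC"): 0.5,
    ("MALL-intron1", "siCTNNB1"): 1.6,
}


@dataclass
class ReporterData:
    wells: list[ReporterWell]
    effects: dict[tuple[str, str], float]
    base_activity: dict[str, float]


def make_reporter(
    seed: int,
    base_activity: Optional[Mapping[str, float]] = None,
    effects: Optional[Mapping[tuple[str, str], float]] = None,
    conditions: Sequence[str] = ("scrambled", "siAPC", "siCTNNB1"),
    n_replicates: int = 3,
    noise_cv: float = 0.05,
) -> ReporterData:
    """Reporter wells for every construct x condition x replicate.

    ``effects[(construct, condition)]`` multiplies the construct's
    scrambled-condition activity (default 1); the empty-vector construct
    always has effect 1, anchoring the normalization. Noise is
    multiplicative log-normal with coefficient of variation ``noise_cv``
    (0 gives exact planted effects); each replicate carries its own
    plate-scale factor, which empty-vector normalization removes.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    base_activity = dict(base_activity or DEFAULT_BASE_ACTIVITY)
    if "empty-vector" not in base_activity:
        raise ValueError("base_activity must include the 'empty-vector' construct")
    effects = dict(effects if effects is not None else DEFAULT_REPORTER_EFFECTS)
    sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0

    wells = []
    for rep in range(1, n_replicates + 1):
        renilla_base = 1_000.0 * float(rng.uniform(0.8, 1.25))
        plate_scale = float(rng.uniform(0.7, 1.4))
        for cond in conditions:
            for construct, base in base_activity.items():
                effect = 1.0 if cond == "scrambled" else effects.get((construct, cond), 1.0)
                renilla = renilla_base * noise()
                firefly = renilla * plate_scale * base * effect * noise()
                wells.append(ReporterWell(construct=construct, condition=cond,
                                          replicate_id=rep, firefly=firefly, renilla=renilla))
    full_effects = {(c, cond): (1.0 if cond == "scrambled"
                                else effects.get((c, cond), 1.0))
                    for c in base_activity for cond in conditions}
    return ReporterData(wells=wells, effects=full_effects, base_activity=base_activity)


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------

PRESETS = {
    "default": dict(n_chrom=2, chrom_len=1_000_000, n_genes=200, n_peaks=300,
                    n_up=8, n_down=4, n_region_decoys=6, n_mouse_decoys=8, n_de_only=10,
                    expression_noise_sd=0.0, reporter_noise_cv=0.05,
                    jitter_sd=20.0, dropout=0.1),
    "tiny": dict(n_chrom=2, chrom_len=150_000, n_genes=24, n_peaks=40,
                 n_up=3, n_down=2, n_region_decoys=2, n_mouse_decoys=2, n_de_only=3,
                 expression_noise_sd=0.0, reporter_noise_cv=0.05,
                 jitter_sd=15.0, dropout=0.1),
}

FIXTURE_MOTIF_PLAN = {
    DEFAULT_MOTIFS[0]: (0.50, 0.20),    # AP-1: denser among top peaks
    DEFAULT_MOTIFS[1]: (0.60, 0.25),    # TCF7L2
}


@dataclass
class FixtureTruth:
    seed: int
    preset: str
    candidates: dict[str, str]
    region_decoys: dict[str, str]
    mouse_decoys: dict[str, str]
    de_only: dict[str, str]
    anchor_table: list[dict]
    tf_overlap_ids: dict[str, list[int]]
    motif_carriers: dict[str, list[int]]
    top_ids: list[int]
    n_peaks: int
    n_shared: int
    reporter_effects: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


@dataclass
class Fixture:
    seed: int
    preset: str
    genome: dict[str, str]
    genes: list[GeneModel]
    planted: PlantedPeaks
    tf_replicates: dict[str, list[list[Peak]]]
    expression: ExpressionData
    reporter: ReporterData
    truth: FixtureTruth
    config: ScreenConfig

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def consolidated_tf_sets(self, max_center_dist: int = 400) -> dict[str, list[Peak]]:
        return {name: consolidate_tf_replicates(reps, max_center_dist=max_center_dist)
                for name, reps in self.tf_replicates.items()}

    def screen_inputs(self, with_genome: bool = True, with_tf: bool = True) -> ScreenInputs:
        panels = build_adenoma_panels(self.expression.expr_a, self.expression.manifest_a,
                                      self.expression.expr_b, self.expression.manifest_b)
        return ScreenInputs(
            peaks_rep1=self.planted.rep1, peaks_rep2=self.planted.rep2,
            genes=self.genes, human_de=self.expression.human_de, panels=panels,
            genome=self.genome if with_genome else None,
            motifs=list(FIXTURE_MOTIF_PLAN) if with_genome else None,
            tf_sets=self.consolidated_tf_sets(self.config.tf_center_dist) if with_tf else None,
        )

    def write(self, outdir, force: bool = False) -> Path:
        out = Path(outdir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_genes_gtf(self.genes, out / "genes.gtf")
        write_peaks_narrowpeak(self.planted.rep1, out / "apc_rep1.narrowPeak")
        write_peaks_narrowpeak(self.planted.rep2, out / "apc_rep2.narrowPeak")
        tf_paths: dict[str, list[str]] = {}
        for name, reps in self.tf_replicates.items():
            safe = name.replace("/", "-")
            tf_paths[name] = []
            for r, peaks in enumerate(reps, start=1):
                fname = f"tf_{safe}_rep{r}.narrowPeak"
                write_peaks_narrowpeak(peaks, out / fname)
                tf_paths[name].append(fname)
        write_cuffdiff(self.expression.human_de, out / "human_de.tsv")
        for label, expr, manifest in (("a", self.expression.expr_a, self.expression.manifest_a),
                                      ("b", self.expression.expr_b, self.expression.manifest_b)):
            expr.to_csv(out / f"mouse_model_{label}.tsv", sep="\t")
            with open(out / f"mouse_manifest_{label}.tsv", "w") as fh:
                fh.write("sample\tgroup\n")
                for s, g in manifest.items():
                    fh.write(f"{s}\t{g}\n")
        write_plate(self.reporter.wells, out / "reporter_plate.tsv")
        write_motifs(list(FIXTURE_MOTIF_PLAN), out / "motifs.tsv")
        self.truth.to_json(out / "truth.json")
        config = {
            "inputs": {
                "rep1": "apc_rep1.narrowPeak",
                "rep2": "apc_rep2.narrowPeak",
                "annotation": "genes.gtf",
                "human_de": "human_de.tsv",
                "genome": "genome.fa",
                "motifs": "motifs.tsv",
                "mouse": {
                    "model_a": {"matrix": "mouse_model_a.tsv", "manifest": "mouse_manifest_a.tsv"},
                    "model_b": {"matrix": "mouse_model_b.tsv", "manifest": "mouse_manifest_b.tsv"},
                },
                "tf_sets": tf_paths,
            },
            "thresholds": {"universe": self.config.universe},
            "output_dir": "screen_out",
        }
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
        return out


def _nearest_gene(genes: Sequence[GeneModel], chrom: str, pos: int) -> Optional[GeneModel]:
    """Brute-force unique nearest-TSS gene; None on a tie."""
    best: Optional[GeneModel] = None
    best_d = None
    tie = False
    for g in genes:
        if g.chrom != chrom:
            continue
        d = abs(pos - g.tss)
        if best_d is None or d < best_d:
            best, best_d, tie = g, d, False
        elif d == best_d:
            tie = True
    return None if tie else best


def _pick_anchor(gene: GeneModel, genes: Sequence[GeneModel], kind: str) -> Optional[tuple[str, int]]:
    """A verified summit position for ``gene``: assigned to it by nearest
    TSS and located in the requested region kind."""
    if kind == "upstream":
        sign = -1 if gene.strand == "+" else 1
        options = [gene.tss + sign * off for off in (5_000, 3_000, 2_000, 1_000)]
    elif kind == "intron":
        assert gene.first_intron is not None
        i0, i1 = gene.first_intron
        options = [(i0 + i1) // 2]
    elif kind == "exon2":
        i0, i1 = gene.first_intron  # type: ignore[misc]
        s, e = gene.span
        exon2 = (i1, e) if gene.strand == "+" else (s, i0)
        options = [(exon2[0] + exon2[1]) // 2]
    else:
        raise ValueError(kind)
    for pos in options:
        if _nearest_gene(genes, gene.chrom, pos) is gene:
            return (gene.chrom, pos)
    return None


def make_fixture(seed: int, preset: str = "default") -> Fixture:
    """Build the complete in-memory fixture with recorded ground truth.

    Planted gene roles: fully-passing candidates (with regulatory-region
    peaks, human DE calls and mouse concordance), region decoys (pass
    everything except the regulatory-location filter), mouse decoys
    (human-DE with a peak, discordant in mice), and DE-only genes without
    peaks. Background peaks avoid the regulatory windows of region-decoy
    genes so the planted candidate set is exactly recoverable.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    genome = make_genome(child_seed(seed, "genome"), n_chrom=p["n_chrom"], chrom_len=p["chrom_len"])
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    genes = make_annotation(child_seed(seed, "genes"), chrom_sizes, n_genes=p["n_genes"])

    rng = rng_for(seed, "roles")
    order = [genes[int(i)] for i in rng.permutation(len(genes))]
    ap1, tcf = DEFAULT_MOTIFS[0], DEFAULT_MOTIFS[1]

    candidates: dict[str, str] = {}
    region_decoys: dict[str, str] = {}
    mouse_decoys: dict[str, str] = {}
    de_only: dict[str, str] = {}
    anchors: list[tuple[str, int]] = []
    anchor_motifs: dict[int, list[MotifPattern]] = {}
    anchor_table: list[dict] = []

    def add_anchor(gene: GeneModel, kind: str, role: str, motifs: Sequence[MotifPattern]) -> bool:
        pos = _pick_anchor(gene, genes, kind)
        if pos is None:
            return False
        # scrub windows of two planted peaks must never overlap
        if any(c == pos[0] and abs(s - pos[1]) < 1_100 for c, s in anchors):
            return False
        idx = len(anchors)
        anchors.append(pos)
        if motifs:
            anchor_motifs[idx] = list(motifs)
        anchor_table.append(dict(anchor=idx, gene=gene.symbol, role=role, kind=kind,
                                 chrom=pos[0], summit=pos[1]))
        return True

    n_cand = p["n_up"] + p["n_down"]
    quotas = [("candidate", n_cand), ("region_decoy", p["n_region_decoys"]),
              ("mouse_decoy", p["n_mouse_decoys"]), ("de_only", p["n_de_only"])]
    it = iter(order)
    for role, quota in quotas:
        filled = 0
        while filled < quota:
            gene = next(it, None)
            if gene is None:
                raise ValueError("not enough placeable genes for the requested fixture roles")
            if role == "candidate":
                primary = "upstream" if filled % 2 == 0 else "intron"
                secondary = "intron" if primary == "upstream" else "upstream"
                pos1 = _pick_anchor(gene, genes, primary)
                pos2 = _pick_anchor(gene, genes, secondary)
                if pos1 is None or pos2 is None or abs(pos1[1] - pos2[1]) < 1_100:
                    continue
                if not add_anchor(gene, primary, role, [tcf]):
                    continue
                if not add_anchor(gene, secondary, role, [ap1]):
                    # roll back the primary anchor so the gene is skipped cleanly
                    anchors.pop()
                    anchor_motifs.pop(len(anchors), None)
                    anchor_table.pop()
                    continue
                candidates[gene.symbol] = "up" if filled < p["n_up"] else "down"
            elif role == "region_decoy":
                if not add_anchor(gene, "exon2", role, []):
                    continue
                region_decoys[gene.symbol] = "up" if filled % 2 == 0 else "down"
            elif role == "mouse_decoy":
                if not add_anchor(gene, "upstream", role, []):
                    continue
                mouse_decoys[gene.symbol] = "up" if filled % 2 == 0 else "down"
            else:  # de_only: no peak anchor
                de_only[gene.symbol] = "up" if filled % 2 == 0 else "down"
            filled += 1

    # background peaks must stay clear of region-decoy regulatory windows,
    # otherwise an accidental nearby peak would promote a decoy to candidate
    zones = [(g.chrom, g.span[0] - 11_000, g.span[1] + 11_000)
             for g in genes if g.symbol in region_decoys]

    planted = plant_peaks(
        child_seed(seed, "peaks"), genome, n_peaks=p["n_peaks"], anchors=anchors,
        anchor_motifs=anchor_motifs, replicate_jitter_sd=p["jitter_sd"],
        dropout=p["dropout"], motif_plan=FIXTURE_MOTIF_PLAN,
        exclusion_zones=zones, protect_anchors=True,
    )

    # TF co-occupancy: TCF7L2 at every candidate anchor, AP-1 mostly at
    # up-candidate anchors (mirrors the stronger overlap near genes that
    # increase after APC loss), SP1 background only
    up_anchor_ids = [row["anchor"] for row in anchor_table
                     if row["role"] == "candidate" and candidates[row["gene"]] == "up"]
    down_anchor_ids = [row["anchor"] for row in anchor_table
                       if row["role"] == "candidate" and candidates[row["gene"]] == "down"]
    tf_rng = rng_for(seed, "tfplan")
    n_down_ap1 = max(1, len(down_anchor_ids) // 3)
    ap1_down = sorted(int(down_anchor_ids[j]) for j in
                      tf_rng.choice(len(down_anchor_ids), size=n_down_ap1, replace=False))
    n_bg = max(10, p["n_peaks"] // 6)
    plans = {
        "TCF7L2": TFPlan(overlap_ids=tuple(up_anchor_ids + down_anchor_ids), n_background=n_bg),
        "AP-1": TFPlan(overlap_ids=tuple(up_anchor_ids + ap1_down), n_background=n_bg,
                       n_replicates=4),
        "SP1": TFPlan(overlap_ids=(), n_background=n_bg),
    }
    tf_replicates, tf_truth = plant_tf_peaks(child_seed(seed, "tf"), planted.truth,
                                             chrom_sizes, plans)

    expression = make_expression(
        child_seed(seed, "expr"), [g.symbol for g in genes],
        concordant={**candidates, **region_decoys},
        extra_de={**mouse_decoys, **de_only},
        noise_sd=p["expression_noise_sd"],
    )
    reporter = make_reporter(child_seed(seed, "reporter"), noise_cv=p["reporter_noise_cv"])

    config = ScreenConfig(universe=sum(chrom_sizes.values()) // 400)
    truth = FixtureTruth(
        seed=seed, preset=preset, candidates=candidates, region_decoys=region_decoys,
        mouse_decoys=mouse_decoys, de_only=de_only, anchor_table=anchor_table,
        tf_overlap_ids=tf_truth, motif_carriers=planted.motif_carriers,
        top_ids=planted.top_ids, n_peaks=p["n_peaks"], n_shared=planted.n_shared,
        reporter_effects={f"{c}|{cond}": v for (c, cond), v in reporter.effects.items()},
    )
    return Fixture(seed=seed, preset=preset, genome=planted.genome, genes=genes,
                   planted=planted, tf_replicates=tf_replicates, expression=expression,
                   reporter=reporter, truth=truth, config=config)
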