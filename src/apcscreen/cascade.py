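"""Orchestration of the full target-gene screen.

The screen narrows candidate genes through successive stages:

1. replicate intersection — peaks reproducible between the two APC
   ChIP-seq replicates (summits < 400 bp apart);
2. gene assignment — each shared peak linked to the gene with the
   nearest TSS;
3. human differential expression — peak-linked genes whose transcripts
   change after APC knockdown (q < 0.05), with the direction of change
   asserted here;
4. mouse concordance — genes changed >= 1.5-fold in the human direction
   in adenomas of both mouse tumor models (one-sample t-test, FDR cutoff);
5. regulatory-element location — genes with at least one linked peak
   within 10 kb upstream of the TSS or inside the first intron.

A gene is a final candidate iff it passes every enabled stage. The
report also carries motif/TF presence flags per candidate, stratified
TF-overlap enrichment for peaks linked to up- vs down-regulated genes,
and gene-level co-occurrence tables in which neighboring peaks assigned
to the same gene are grouped together (flag union per gene).
"""
from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .expression import (AdenomaPanel, DERecord, build_adenoma_panels, filter_human_de,
                         map_orthologs, mouse_concordance, read_cuffdiff,
                         read_expression_matrix, read_sample_manifest)
from .intervals import (GeneModel, Peak, PeakGeneLink, RegionClass, assign_to_genes,
                        classify_location, intersect_replicates, open_genome,
                        peak_score_correlation, read_genes_gtf, read_peaks, shared_peaks,
                        write_links_table, write_pairs_table)
from .motifs import MotifPattern, peak_sequence, read_motifs, scan_sequence
from .tf_overlap import (DEFAULT_UNIVERSE, consolidate_tf_replicates, overlap_mask,
                         stratified_enrichment)

log = logging.getLogger(__name__)

REGULATORY_CLASSES = (RegionClass.UPSTREAM_10KB, RegionClass.FIRST_INTRON)


@dataclass
class ScreenConfig:
    """All screen thresholds in one place (defaults are the study values)."""

    max_summit_dist: int = 400
    summit_strict: bool = True          # "less than 400-bp" for replicate intersection
    tf_center_dist: int = 400           # "no more than 400-bp" for TF comparison
    q_max: float = 0.05
    min_fold: float = 1.5
    mouse_fdr_max: float = 0.1
    upstream_window: int = 10_000
    top_n: int = 500
    universe: int = DEFAULT_UNIVERSE
    assignment_max_distance: Optional[int] = None
    mouse_pooled_ttest: bool = True
    fdr_mode: str = "literal"
    enable_human_stage: bool = True
    enable_mouse_stage: bool = True
    enable_region_stage: bool = True
    seed: int = 0                       # permutation null only

    def validate(self) -> None:
        positive = dict(max_summit_dist=self.max_summit_dist, tf_center_dist=self.tf_center_dist,
                        q_max=self.q_max, min_fold=self.min_fold, mouse_fdr_max=self.mouse_fdr_max,
                        upstream_window=self.upstream_window, top_n=self.top_n,
                        universe=self.universe)
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")
        if self.min_fold <= 1.0:
            raise ValueError("min_fold must exceed 1")
        if self.fdr_mode not in ("literal", "step-up"):
            raise ValueError(f"unknown fdr_mode {self.fdr_mode!r}")


@dataclass
class ScreenInputs:
    """In-memory inputs for one screen run (see run_screen_from_config for
    the file-based entry point)."""

    peaks_rep1: Sequence[Peak]
    peaks_rep2: Sequence[Peak]
    genes: Sequence[GeneModel]
    human_de: Sequence[DERecord]
    panels: Optional[Sequence[AdenomaPanel]] = None
    genome: Optional[Mapping] = None
    motifs: Optional[Sequence[MotifPattern]] = None
    tf_sets: Optional[Mapping[str, Sequence[Peak]]] = None


@dataclass
class CandidateGene:
    """A peak-linked gene with its per-stage verdicts and binding-site flags."""

    gene: str
    direction: Optional[str]
    linked_peaks: list[PeakGeneLink]
    stage_flags: dict[str, bool]
    motif_flags: dict[str, bool] = field(default_factory=dict)
    tf_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def is_final(self) -> bool:
        return all(self.stage_flags.values())


@dataclass
class ScreenReport:
    stage_counts: "OrderedDict[str, int]"
    candidates: list[CandidateGene]
    pairs: list[tuple[Peak, Peak]]
    links: list[PeakGeneLink]
    score_correlation: Optional[float]
    gene_table: pd.DataFrame
    mouse_table: Optional[pd.DataFrame] = None
    enrichment_table: Optional[pd.DataFrame] = None
    cooccurrence_table: Optional[pd.DataFrame] = None

    @property
    def final_candidates(self) -> list[CandidateGene]:
        return [c for c in self.candidates if c.is_final]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "stage_counts.tsv", "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in self.stage_counts.items():
                fh.write(f"{stage}\t{count}\n")
        write_pairs_table(self.pairs, out / "shared_peaks.tsv")
        write_links_table(self.links, out / "peak_gene_links.tsv")
        self.gene_table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
        final = self.gene_table[self.gene_table["final_candidate"]]
        final.to_csv(out / "candidates.tsv", sep="\t", index=False)
        if self.mouse_table is not None:
            self.mouse_table.to_csv(out / "mouse_concordance.tsv", sep="\t", index=False)
        if self.enrichment_table is not None:
            self.enrichment_table.to_csv(out / "tf_enrichment.tsv", sep="\t", index=False)
        if self.cooccurrence_table is not None:
            self.cooccurrence_table.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)


def cooccurrence_by_gene(
    links: Sequence[PeakGeneLink],
    peak_flags: Mapping[Peak, frozenset],
    gene_direction: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Gene-level co-occurrence of binding-site flags.

    Neighboring peaks assigned to the same gene are grouped together and
    their flags unioned, then genes are tabulated by flag combination
    (e.g. 'AP-1+TCF7L2', 'TCF7L2', 'neither'), stratified by the gene's
    expression direction when supplied.
    """
    per_gene: dict[str, set] = {}
    for ln in links:
        if ln.gene is None:
            continue
        per_gene.setdefault(ln.gene.symbol, set()).update(peak_flags.get(ln.peak, frozenset()))
    counts: dict[tuple[str, str], int] = {}
    for sym, flags in per_gene.items():
        combo = "+".join(sorted(flags)) if flags else "neither"
        direction = (gene_direction or {}).get(sym, "all")
        counts[(direction, combo)] = counts.get((direction, combo), 0) + 1
    rows = [dict(direction=d, combination=c, n_genes=n)
            for (d, c), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["direction", "combination", "n_genes"])


def _peak_flag_map(
    peaks: Sequence[Peak],
    genome: Optional[Mapping],
    motifs: Optional[Sequence[MotifPattern]],
    tf_sets: Optional[Mapping[str, Sequence[Peak]]],
    tf_center_dist: int,
) -> tuple[dict[Peak, frozenset], list[str]]:
    flags: dict[Peak, set] = {p: set() for p in peaks}
    universe: list[str] = []
    if genome is not None and motifs:
        for m in motifs:
            universe.append(f"motif:{m.name}")
            for p in peaks:
                if scan_sequence(peak_sequence(genome, p), m):
                    flags[p].add(f"motif:{m.name}")
    if tf_sets:
        for tf_name, tf_peaks in tf_sets.items():
            universe.append(f"tf:{tf_name}")
            mask = overlap_mask(peaks, tf_peaks, max_center_dist=tf_center_dist)
            for p, hit in zip(peaks, mask):
                if hit:
                    flags[p].add(f"tf:{tf_name}")
    return {p: frozenset(s) for p, s in flags.items()}, universe


def run_screen(inputs: ScreenInputs, config: Optional[ScreenConfig] = None) -> ScreenReport:
    """Execute the full screen deterministically and return its report.

    Empty stage inputs produce a zero-count report with a prominent
    warning rather than an error.
    """
    cfg = config or ScreenConfig()
    cfg.validate()
    counts: "OrderedDict[str, int]" = OrderedDict()

    # stage 1: replicate intersection
    pairs = intersect_replicates(inputs.peaks_rep1, inputs.peaks_rep2,
                                 max_summit_dist=cfg.max_summit_dist, strict=cfg.summit_strict)
    shared = shared_peaks(pairs)
    counts["replicate_shared_peak_pairs"] = len(pairs)
    if not pairs:
        log.warning("SCREEN: no replicate-shared peaks; all downstream counts are zero")
    correlation = None
    if len(pairs) >= 2 and all(pa.score > 0 and pb.score > 0 for pa, pb in pairs):
        correlation = peak_score_correlation(pairs)
        log.info("stage 1: %d shared peak pairs (log-score Pearson r = %.4f)",
                 len(pairs), correlation)

    # stage 2: nearest-TSS gene assignment
    links = assign_to_genes(shared, inputs.genes, max_distance=cfg.assignment_max_distance,
                            upstream_window=cfg.upstream_window)
    links_by_gene: dict[str, list[PeakGeneLink]] = {}
    for ln in links:
        if ln.gene is not None:
            links_by_gene.setdefault(ln.gene.symbol, []).append(ln)
    counts["genes_with_shared_peaks"] = len(links_by_gene)
    log.info("stage 2: %d genes with >= 1 shared peak", len(links_by_gene))

    # stage 3: human differential expression
    direction: dict[str, Optional[str]] = {}
    if cfg.enable_human_stage:
        up, down = filter_human_de(inputs.human_de, q_max=cfg.q_max)
        de_dir = {r.gene: "up" for r in up}
        de_dir.update({r.gene: "down" for r in down})
        de_by_lower = {g.lower(): d for g, d in de_dir.items()}
        surviving3 = []
        for sym in links_by_gene:
            d = de_by_lower.get(sym.lower())
            if d is not None:
                direction[sym] = d
                surviving3.append(sym)
    else:
        surviving3 = list(links_by_gene)
        direction = {sym: None for sym in surviving3}
    counts["human_de_concordant_genes"] = len(surviving3)
    n_up3 = sum(1 for s in surviving3 if direction.get(s) == "up")
    log.info("stage 3: %d peak-linked genes altered in human cells (%d up, %d down)",
             len(surviving3), n_up3, len(surviving3) - n_up3)

    # stage 4: mouse adenoma concordance
    mouse_df = None
    if cfg.enable_mouse_stage:
        surviving4 = []
        if inputs.panels:
            panel_by_gene = {p.gene: p for p in inputs.panels}
            pairs_hm, _ = map_orthologs(surviving3, list(panel_by_gene))
            h2m = dict(pairs_hm)
            hdir_mouse = {}
            for h, m in h2m.items():
                d = direction.get(h)
                if d is None:  # human stage disabled: take direction from mouse means
                    panel = panel_by_gene[m]
                    d = "up" if panel.mean_fold_a * panel.mean_fold_b >= 1.0 else "down"
                    d = "up" if (panel.mean_fold_a > 1 and panel.mean_fold_b > 1) else (
                        "down" if (panel.mean_fold_a < 1 and panel.mean_fold_b < 1) else d)
                hdir_mouse[m] = d
            tested = [panel_by_gene[m] for m in h2m.values()]
            mouse_df = mouse_concordance(tested, hdir_mouse, min_fold=cfg.min_fold,
                                         fdr_max=cfg.mouse_fdr_max, pooled=cfg.mouse_pooled_ttest,
                                         fdr_mode=cfg.fdr_mode)
            passed_mouse = set(mouse_df.loc[mouse_df["passed"], "gene"]) if not mouse_df.empty else set()
            surviving4 = [h for h in surviving3 if h2m.get(h) in passed_mouse]
        else:
            log.warning("SCREEN: mouse stage enabled but no adenoma panels supplied; "
                        "no genes pass the concordance filter")
    else:
        surviving4 = list(surviving3)
    counts["mouse_concordant_genes"] = len(surviving4)
    log.info("stage 4: %d genes concordant in both mouse adenoma models", len(surviving4))

    # stage 5: regulatory-element location (gene passes if ANY linked peak
    # lies within 10 kb upstream of the TSS or inside the first intron)
    def has_regulatory_peak(sym: str) -> bool:
        return any(classify_location(ln, cfg.upstream_window) in REGULATORY_CLASSES
                   for ln in links_by_gene[sym])

    if cfg.enable_region_stage:
        surviving5 = [s for s in surviving4 if has_regulatory_peak(s)]
    else:
        surviving5 = list(surviving4)
    counts["regulatory_element_genes"] = len(surviving5)
    n_up5 = sum(1 for s in surviving5 if direction.get(s) == "up")
    log.info("stage 5: %d final candidates (%d increased, %d decreased)",
             len(surviving5), n_up5, len(surviving5) - n_up5)

    # candidate assembly with motif / TF flags
    flag_map, _ = _peak_flag_map(shared, inputs.genome, inputs.motifs, inputs.tf_sets,
                                 cfg.tf_center_dist)
    set3, set4, set5 = set(surviving3), set(surviving4), set(surviving5)
    candidates: list[CandidateGene] = []
    rows = []
    for sym in sorted(links_by_gene):
        glinks = links_by_gene[sym]
        stage_flags = OrderedDict(shared_peak=True)
        if cfg.enable_human_stage:
            stage_flags["human_de"] = sym in set3
        if cfg.enable_mouse_stage:
            stage_flags["mouse_concordant"] = sym in set4
        if cfg.enable_region_stage:
            stage_flags["regulatory_element"] = has_regulatory_peak(sym)
        union_flags: set = set()
        for ln in glinks:
            union_flags.update(flag_map.get(ln.peak, frozenset()))
        motif_flags = {f[6:]: True for f in union_flags if f.startswith("motif:")}
        tf_flags = {f[3:]: True for f in union_flags if f.startswith("tf:")}
        cand = CandidateGene(gene=sym, direction=direction.get(sym), linked_peaks=glinks,
                             stage_flags=dict(stage_flags), motif_flags=motif_flags,
                             tf_flags=tf_flags)
        candidates.append(cand)
        rows.append(dict(gene=sym, direction=direction.get(sym) or "NA",
                         n_linked_peaks=len(glinks),
                         **{f"pass_{k}": v for k, v in stage_flags.items()},
                         final_candidate=cand.is_final and sym in set5,
                         motifs="+".join(sorted(motif_flags)) or "none",
                         tfs="+".join(sorted(tf_flags)) or "none"))
    gene_table = pd.DataFrame(rows, columns=None)
    if gene_table.empty:
        gene_table = pd.DataFrame(columns=["gene", "direction", "n_linked_peaks", "final_candidate"])

    # stratified TF enrichment and gene-level co-occurrence over the
    # human-DE-linked peak subset (the stage the study re-assessed)
    enrichment_df = None
    cooc_df = None
    if inputs.tf_sets:
        up_peaks = [ln.peak for s in surviving3 if direction.get(s) == "up" for ln in links_by_gene[s]]
        down_peaks = [ln.peak for s in surviving3 if direction.get(s) == "down" for ln in links_by_gene[s]]
        subsets = {"all": shared, "up": up_peaks, "down": down_peaks}
        enrichment_df = stratified_enrichment(subsets, inputs.tf_sets, universe=cfg.universe,
                                              max_center_dist=cfg.tf_center_dist)
    if flag_map and any(flag_map.values()):
        de_links = [ln for s in surviving3 for ln in links_by_gene[s]]
        cooc_df = cooccurrence_by_gene(de_links, flag_map,
                                       {s: direction.get(s) or "all" for s in surviving3})

    return ScreenReport(stage_counts=counts, candidates=candidates, pairs=pairs, links=links,
                        score_correlation=correlation, gene_table=gene_table,
                        mouse_table=mouse_df, enrichment_table=enrichment_df,
                        cooccurrence_table=cooc_df)


# ---------------------------------------------------------------------------
# config-file entry point
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise ValueError(f"{path}: config must be a mapping with an 'inputs' section")
    required = ["rep1", "rep2", "annotation", "human_de"]
    missing = [k for k in required if k not in cfg["inputs"]]
    if missing:
        raise ValueError(f"{path}: missing required input path(s) {missing}")
    base = Path(path).parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    for key in required:
        p = resolve(cfg["inputs"][key])
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    cfg["_base"] = str(base)
    return cfg


def screen_config_from_dict(d: Mapping) -> ScreenConfig:
    cfg = ScreenConfig(**dict(d or {}))
    cfg.validate()
    return cfg


def run_screen_from_config(path) -> ScreenReport:
    """Load all inputs named by a YAML config and run the screen."""
    cfg = load_config(path)
    base = Path(cfg["_base"])

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    inp = cfg["inputs"]
    rep1 = read_peaks(resolve(inp["rep1"]), format="narrowPeak")
    rep2 = read_peaks(resolve(inp["rep2"]), format="narrowPeak")
    genes = read_genes_gtf(resolve(inp["annotation"]))
    human_de = read_cuffdiff(resolve(inp["human_de"]))
    panels = None
    if "mouse" in inp:
        m = inp["mouse"]
        panels = build_adenoma_panels(
            read_expression_matrix(resolve(m["model_a"]["matrix"])),
            read_sample_manifest(resolve(m["model_a"]["manifest"])),
            read_expression_matrix(resolve(m["model_b"]["matrix"])),
            read_sample_manifest(resolve(m["model_b"]["manifest"])),
        )
    genome = open_genome(resolve(inp["genome"])) if "genome" in inp else None
    motifs = read_motifs(resolve(inp["motifs"])) if "motifs" in inp else None
    tf_sets = None
    if "tf_sets" in inp:
        screen_cfg = screen_config_from_dict(cfg.get("thresholds"))
        tf_sets = {}
        for name, paths in inp["tf_sets"].items():
            reps = [read_peaks(resolve(p), format="narrowPeak") for p in paths]
            tf_sets[name] = (consolidate_tf_replicates(reps, max_center_dist=screen_cfg.tf_center_dist)
                             if len(reps) > 1 else reps[0])
    screen_cfg = screen_config_from_dict(cfg.get("thresholds"))
    inputs = ScreenInputs(peaks_rep1=rep1, peaks_rep2=rep2, genes=genes, human_de=human_de,
                          panels=panels, genome=genome, motifs=motifs, tf_sets=tf_sets)
    return run_screen(inputs, screen_cfg)
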