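"""Differential-expression ingestion and the screen's expression filters.

Two filters narrow the peak-linked gene list:

* the human filter keeps genes whose knockdown differential-expression
  q-value (Cuffdiff FDR-adjusted) is below 0.05, split by direction;
* the mouse concordance filter keeps genes changed >= 1.5-fold, in the
  human direction, in adenomas of BOTH mouse tumor models (Apc-mutant
  and AOM/DSS carcinogen-induced) relative to normal-colon controls,
  with a one-sample t-test of per-sample log2 fold changes against 0 and
  an FDR cutoff (default 0.1) across tested genes.

Multiple-testing correction is the literal Benjamini-Hochberg arithmetic
(p * N / rank with ranks by ascending p); a conventional step-up variant
(monotone, capped at 1) is also provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DERecord:
    """One row of a knockdown differential-expression table (Cuffdiff dialect)."""

    gene: str
    fpkm_control: float
    fpkm_knockdown: float
    log2fc: float
    p: float
    q: float

    @property
    def direction(self) -> str:
        if self.log2fc > 0:
            return "up"
        if self.log2fc < 0:
            return "down"
        return "none"


CUFFDIFF_COLUMNS = ["gene", "value_1", "value_2", "log2_fold_change", "p_value", "q_value"]


def read_cuffdiff(path) -> list[DERecord]:
    """Read a tab-separated DE table with the Cuffdiff header
    (gene, value_1, value_2, log2_fold_change, p_value, q_value);
    value_1 is the control FPKM, value_2 the knockdown FPKM."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CUFFDIFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE table column(s) {missing}")
    return [
        DERecord(gene=str(r.gene), fpkm_control=float(r.value_1), fpkm_knockdown=float(r.value_2),
                 log2fc=float(r.log2_fold_change), p=float(r.p_value), q=float(r.q_value))
        for r in df.itertuples()
    ]


def write_cuffdiff(records: Sequence[DERecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CUFFDIFF_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.gene}\t{r.fpkm_control:.6g}\t{r.fpkm_knockdown:.6g}\t"
                     f"{r.log2fc:.6g}\t{r.p:.6g}\t{r.q:.6g}\n")


def filter_human_de(records: Sequence[DERecord], q_max: float = 0.05) -> tuple[list[DERecord], list[DERecord]]:
    """Partition records with q strictly below ``q_max`` into (up, down)
    by the sign of the log2 fold change. Records with missing q are
    skipped with a warning."""
    up: list[DERecord] = []
    down: list[DERecord] = []
    n_skipped = 0
    for r in records:
        if r.q is None or np.isnan(r.q):
            n_skipped += 1
            continue
        if r.q < q_max:
            if r.direction == "up":
                up.append(r)
            elif r.direction == "down":
                down.append(r)
    if n_skipped:
        log.warning("%d DE records skipped for missing q-values", n_skipped)
    log.info("human DE filter (q < %g): %d up, %d down of %d records",
             q_max, len(up), len(down), len(records))
    return up, down


def bh_fdr(pvalues, mode: str = "literal") -> np.ndarray:
    """Benjamini-Hochberg adjusted values, in the input order.

    ``literal`` multiplies each p-value by the number of tests and divides
    by its rank (ascending p, stable ties) — the arithmetic exactly as
    commonly stated; the result is not forced to be monotone or <= 1.
    ``step-up`` additionally takes the cumulative minimum from the largest
    p downwards and caps at 1, the conventional BH adjusted q-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size and (np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if mode not in ("literal", "step-up"):
        raise ValueError(f"unknown mode {mode!r}; expected 'literal' or 'step-up'")
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    adj = p * n / ranks
    if mode == "step-up":
        sorted_adj = adj[order]
        sorted_adj = np.minimum.accumulate(sorted_adj[::-1])[::-1]
        adj = np.empty(n, dtype=float)
        adj[order] = np.minimum(sorted_adj, 1.0)
    return adj


@dataclass
class AdenomaPanel:
    """Per-sample adenoma/control fold changes for one gene in both mouse
    tumor models (linear scale, one value per tumor sample; controls are
    folded into the per-model control mean)."""

    gene: str
    model_a_fc: tuple[float, ...]
    model_b_fc: tuple[float, ...]
    t_p: Optional[float] = None
    fdr: Optional[float] = None

    @property
    def mean_fold_a(self) -> float:
        return float(np.mean(self.model_a_fc)) if self.model_a_fc else float("nan")

    @property
    def mean_fold_b(self) -> float:
        return float(np.mean(self.model_b_fc)) if self.model_b_fc else float("nan")


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples tab-separated matrix with a 'gene' first column."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene'")
    return df.set_index("gene")


def read_sample_manifest(path) -> dict[str, str]:
    """Two-column (sample TAB group) manifest; groups are 'tumor'/'control'."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns 'sample' and 'group'")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def build_adenoma_panels(
    expr_a: pd.DataFrame,
    manifest_a: Mapping[str, str],
    expr_b: pd.DataFrame,
    manifest_b: Mapping[str, str],
) -> list[AdenomaPanel]:
    """Per-sample linear fold changes (tumor sample / control mean) for the
    genes shared between the two model matrices. Genes whose control mean
    is not positive in either model are dropped with a warning."""
    panels: list[AdenomaPanel] = []
    n_dropped = 0
    shared = expr_a.index.intersection(expr_b.index)
    for gene in shared:
        fcs = []
        ok = True
        for expr, manifest in ((expr_a, manifest_a), (expr_b, manifest_b)):
            tumor_cols = [s for s, g in manifest.items() if g == "tumor"]
            ctrl_cols = [s for s, g in manifest.items() if g == "control"]
            ctrl_mean = float(expr.loc[gene, ctrl_cols].mean())
            if ctrl_mean <= 0:
                ok = False
                break
            fcs.append(tuple(float(expr.loc[gene, c]) / ctrl_mean for c in tumor_cols))
        if not ok:
            n_dropped += 1
            continue
        panels.append(AdenomaPanel(gene=str(gene), model_a_fc=fcs[0], model_b_fc=fcs[1]))
    if n_dropped:
        log.warning("%d genes dropped (non-positive control mean)", n_dropped)
    return panels


def _one_sample_log2_test(log2fc: np.ndarray) -> tuple[float, bool]:
    """Two-sided one-sample t-test of log2 fold changes against 0.

    Zero-variance vectors are flagged (second return value) and assigned
    p = 0 when the mean differs from 0 and p = 1 otherwise, so that
    noise-free data remain testable.
    """
    if log2fc.size < 2:
        raise ValueError("need >= 2 samples for a one-sample t-test")
    if np.ptp(log2fc) < 1e-9:  # noise-free data up to float rounding
        return (0.0 if abs(float(np.mean(log2fc))) > 1e-9 else 1.0), True
    t = stats.ttest_1samp(log2fc, 0.0)
    return float(t.pvalue), False


def mouse_concordance(
    panels: Sequence[AdenomaPanel],
    human_direction: Mapping[str, str],
    min_fold: float = 1.5,
    fdr_max: float = 0.1,
    pooled: bool = True,
    fdr_mode: str = "literal",
) -> pd.DataFrame:
    """Cross-species concordance filter over adenoma fold-change panels.

    A gene passes iff (i) its mean linear fold change is >= min_fold (for
    a human 'up' call) or <= 1/min_fold ('down') in BOTH models, (ii) the
    direction matches the human direction in both models, and (iii) the
    one-sample t-test of per-sample log2 fold changes against 0 (samples
    pooled across models by default; per-model with ``pooled=False``,
    taking the larger p) survives BH correction at ``fdr_max`` across all
    tested genes. Only genes present in ``human_direction`` are tested.

    Returns a data frame with one row per tested gene and per-clause
    verdict columns; ``passed`` is the conjunction.
    """
    if min_fold <= 1.0:
        raise ValueError("min_fold must exceed 1")
    rows = []
    n_zero_var = 0
    for panel in panels:
        hdir = human_direction.get(panel.gene)
        if hdir not in ("up", "down"):
            continue
        la = np.log2(np.asarray(panel.model_a_fc, dtype=float))
        lb = np.log2(np.asarray(panel.model_b_fc, dtype=float))
        if la.size + lb.size < 2:
            rows.append(dict(gene=panel.gene, human_direction=hdir, testable=False,
                             mean_fold_a=panel.mean_fold_a, mean_fold_b=panel.mean_fold_b,
                             t_p=np.nan, zero_variance=False,
                             fold_ok=False, direction_ok=False))
            continue
        if pooled:
            p, zv = _one_sample_log2_test(np.concatenate([la, lb]))
        else:
            pa, zva = _one_sample_log2_test(la)
            pb, zvb = _one_sample_log2_test(lb)
            p, zv = max(pa, pb), zva or zvb
        n_zero_var += zv
        ma, mb = panel.mean_fold_a, panel.mean_fold_b
        if hdir == "up":
            fold_ok = ma >= min_fold and mb >= min_fold
            direction_ok = ma > 1.0 and mb > 1.0
        else:
            fold_ok = ma <= 1.0 / min_fold and mb <= 1.0 / min_fold
            direction_ok = ma < 1.0 and mb < 1.0
        rows.append(dict(gene=panel.gene, human_direction=hdir, testable=True,
                         mean_fold_a=ma, mean_fold_b=mb, t_p=p, zero_variance=zv,
                         fold_ok=fold_ok, direction_ok=direction_ok))
    if n_zero_var:
        log.warning("%d genes had zero variance in log2 fold changes; assigned "
                    "degenerate p-values (0 for nonzero mean, 1 otherwise)", n_zero_var)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["gene", "human_direction", "testable", "mean_fold_a",
                                     "mean_fold_b", "t_p", "zero_variance", "fold_ok",
                                     "direction_ok", "fdr", "fdr_ok", "passed"])
    df["fdr"] = np.nan
    testable = df["testable"].to_numpy()
    if testable.any():
        df.loc[testable, "fdr"] = bh_fdr(df.loc[testable, "t_p"].to_numpy(), mode=fdr_mode)
    df["fdr_ok"] = df["fdr"] < fdr_max
    df["passed"] = df["testable"] & df["fold_ok"] & df["direction_ok"] & df["fdr_ok"]
    log.info("mouse concordance filter (fold >= %g both models, FDR < %g): %d of %d genes pass",
             min_fold, fdr_max, int(df["passed"].sum()), len(df))
    return df


def map_orthologs(
    human_symbols: Sequence[str],
    mouse_symbols: Sequence[str],
    mapping: Optional[Mapping[str, str]] = None,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pair human and mouse gene symbols.

    An explicit human->mouse mapping (dict or iterable of (human, mouse)
    rows) takes precedence; remaining symbols are matched
    case-insensitively. Returns (pairs, unmapped human symbols).
    Duplicate mapping rows are an error.
    """
    if mapping is not None and not isinstance(mapping, Mapping):
        rows = list(mapping)
        keys = [h for h, _ in rows]
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        if dupes:
            raise ValueError(f"duplicate mapping rows for {dupes}")
        mapping = dict(rows)
    mouse_by_lower = {}
    for m in mouse_symbols:
        mouse_by_lower.setdefault(m.lower(), m)
    mouse_set = set(mouse_symbols)
    pairs: list[tuple[str, str]] = []
    unmapped: list[str] = []
    for h in human_symbols:
        if mapping is not None and h in mapping:
            m = mapping[h]
            if m in mouse_set:
                pairs.append((h, m))
            else:
                unmapped.append(h)
            continue
        m = mouse_by_lower.get(h.lower())
        if m is not None:
            pairs.append((h, m))
        else:
            unmapped.append(h)
    if unmapped:
        log.info("%d human symbols had no mouse counterpart", len(unmapped))
    return pairs, unmapped
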