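"""Dual-luciferase reporter plate normalization and construct statistics.

Each well carries a firefly (construct-driven) and a Renilla
(transfection-control) luminescence reading. The per-well firefly/Renilla
ratio is normalized to the mean ratio over the empty-vector wells of the
same experiment and condition, so empty-vector activity averages to 1 by
construction. Construct responsiveness to a knockdown is assessed with an
equal-variance Student's t-test (default two-tailed; one-tailed
available) against the scrambled-siRNA control, with BH correction
(literal p*N/rank arithmetic) across the constructs of a panel.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr

log = logging.getLogger(__name__)

EMPTY_VECTOR = "empty-vector"
SCRAMBLED = "scrambled"


@dataclass(frozen=True)
class ReporterWell:
    construct: str
    condition: str
    replicate_id: int
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly < 0:
            raise ValueError(f"well {self.construct}/{self.condition}/rep{self.replicate_id}: "
                             f"negative firefly signal")


def read_plate(path) -> list[ReporterWell]:
    """Tab-separated plate table: construct, condition, replicate, firefly, renilla."""
    df = pd.read_csv(path, sep="\t")
    required = ["construct", "condition", "replicate", "firefly", "renilla"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plate column(s) {missing}")
    return [ReporterWell(construct=str(r.construct), condition=str(r.condition),
                         replicate_id=int(r.replicate), firefly=float(r.firefly),
                         renilla=float(r.renilla))
            for r in df.itertuples()]


def write_plate(wells: Sequence[ReporterWell], path) -> None:
    with open(path, "w") as fh:
        fh.write("construct\tcondition\treplicate\tfirefly\trenilla\n")
        for w in wells:
            fh.write(f"{w.construct}\t{w.condition}\t{w.replicate_id}\t"
                     f"{w.firefly:.6g}\t{w.renilla:.6g}\n")


def normalize_plate(wells: Sequence[ReporterWell], empty_construct: str = EMPTY_VECTOR) -> pd.DataFrame:
    """Per-well normalized activity.

    activity = (firefly/renilla) / mean(firefly/renilla over the
    empty-vector wells of the same experiment and condition). Raises if a
    (replicate, condition) group lacks empty-vector wells or any Renilla
    reading is non-positive.
    """
    if not wells:
        raise ValueError("no wells supplied")
    rows = []
    for w in wells:
        if w.renilla <= 0:
            raise ValueError(f"well {w.construct}/{w.condition}/rep{w.replicate_id}: "
                             f"non-positive Renilla signal {w.renilla}")
        rows.append(dict(construct=w.construct, condition=w.condition,
                         replicate=w.replicate_id, firefly=w.firefly, renilla=w.renilla,
                         ratio=w.firefly / w.renilla))
    df = pd.DataFrame(rows)
    activities = np.empty(len(df))
    for (rep, cond), idx in df.groupby(["replicate", "condition"]).groups.items():
        group = df.loc[idx]
        ev = group[group["construct"] == empty_construct]
        if ev.empty:
            raise ValueError(f"no {empty_construct!r} wells in experiment {rep}, condition {cond!r}")
        activities[np.asarray(idx)] = group["ratio"].to_numpy() / ev["ratio"].mean()
    df["activity"] = activities
    return df


def test_construct(
    activities_scrambled: Sequence[float],
    activities_knockdown: Sequence[float],
    tails: int = 2,
    equal_var: bool = True,
    direction: Optional[str] = None,
) -> float:
    """Student's t-test p-value for a knockdown effect on one construct.

    ``tails=2`` (default) is the two-tailed test; ``tails=1`` halves the
    two-tailed p when the observed effect lies in the hypothesized
    direction (``direction`` in {'up','down'} for knockdown vs scrambled;
    the observed direction when not given) and reports 1 - p/2 otherwise.
    Arms that are both constant with equal means give p = 1 by convention.
    """
    x = np.asarray(activities_scrambled, dtype=float)
    y = np.asarray(activities_knockdown, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 activity values per arm")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            log.info("zero variance in both arms with equal means; p = 1 by convention")
            return 1.0
        return 0.0
    p2 = float(stats.ttest_ind(y, x, equal_var=equal_var).pvalue)
    if tails == 2:
        return p2
    observed = "up" if y.mean() >= x.mean() else "down"
    hypothesized = direction or observed
    return p2 / 2 if observed == hypothesized else 1 - p2 / 2


def analyze_constructs(
    normalized: pd.DataFrame,
    control_condition: str = SCRAMBLED,
    tails: int = 2,
    equal_var: bool = True,
    fdr_mode: str = "literal",
    empty_construct: str = EMPTY_VECTOR,
) -> pd.DataFrame:
    """Per-construct activity summary and significance vs the scrambled
    control, with FDR computed within each knockdown-condition panel."""
    conditions = [c for c in normalized["condition"].unique() if c != control_condition]
    constructs = [c for c in normalized["construct"].unique() if c != empty_construct]
    rows = []
    for cond in conditions:
        for construct in constructs:
            ctrl = normalized.query("construct == @construct and condition == @control_condition")
            test = normalized.query("construct == @construct and condition == @cond")
            if ctrl.empty or test.empty:
                continue
            p = test_construct(ctrl["activity"], test["activity"], tails=tails, equal_var=equal_var)
            rows.append(dict(construct=construct, condition=cond,
                             n_control=len(ctrl), n_test=len(test),
                             mean_control=ctrl["activity"].mean(), sd_control=ctrl["activity"].std(ddof=1),
                             mean_test=test["activity"].mean(), sd_test=test["activity"].std(ddof=1),
                             fold=test["activity"].mean() / ctrl["activity"].mean(),
                             p=p))
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["fdr"] = np.nan
    for cond in conditions:
        mask = (df["condition"] == cond).to_numpy()
        if mask.any():
            df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p"].to_numpy(), mode=fdr_mode)
    return df
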