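"""Wet-lab validation arithmetic: ddCt knockdown, RIP fold enrichment,
and the chi-squared goodness-of-fit on biallelic FISH counts.

The ddCt (delta-delta-Ct) convention: technical-replicate Cts are averaged,
dCt = mean target Ct - mean reference Ct per condition, ddCt =
dCt(treatment) - dCt(control), relative expression = 2^(-ddCt), knockdown %
= 100 * (1 - relative expression).  RIP enrichment of an RNA in a protein
immunoprecipitate is 2^(mean IgG Ct - mean target-IP Ct).  FISH scoring is
binary (biallelic vs not); the treatment counts are tested against expected
counts derived from the control proportions (Pearson chi-squared, df = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LikError

CT_COLUMNS = ["sample_id", "condition", "target_gene", "role", "replicate", "ct"]


@dataclass(frozen=True)
class KnockdownResult:
    target_gene: str
    ddct: float
    relative_expression: float
    knockdown_percent: float


def _mean_ct(ct: pd.DataFrame, condition: str, role: str,
             gene: str | None = None) -> float:
    sel = (ct["condition"] == condition) & (ct["role"] == role)
    if gene is not None:
        sel &= ct["target_gene"] == gene
    sub = ct.loc[sel, "ct"]
    if sub.empty:
        raise LikError(f"no Ct rows for condition={condition!r}, role={role!r}")
    return float(sub.mean())


def ddct_relative_expression(
    ct: pd.DataFrame,
    reference_gene: str,
    control_condition: str = "control",
) -> list[KnockdownResult]:
    """Per-target relative expression and knockdown % by the ddCt method.

    ``ct`` is a long table with columns sample_id, condition, target_gene,
    role (target | reference), replicate, ct.  The reference gene must be
    measured in every condition.
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise LikError(f"Ct table missing column(s): {missing}")
    if not (ct.loc[ct["role"] == "reference", "target_gene"] == reference_gene).any():
        raise LikError(f"reference gene {reference_gene!r} not in Ct table")

    targets = sorted(ct.loc[ct["role"] == "target", "target_gene"].unique())
    conditions = [c for c in ct["condition"].unique() if c != control_condition]
    if control_condition not in set(ct["condition"]):
        raise LikError(f"control condition {control_condition!r} absent")

    out = []
    for gene in targets:
        for cond in conditions:
            dct_t = (_mean_ct(ct, cond, "target", gene)
                     - _mean_ct(ct, cond, "reference", reference_gene))
            dct_c = (_mean_ct(ct, control_condition, "target", gene)
                     - _mean_ct(ct, control_condition, "reference", reference_gene))
            ddct = dct_t - dct_c
            rel = float(2.0 ** (-ddct))
            out.append(KnockdownResult(gene, float(ddct), rel, 100.0 * (1.0 - rel)))
    return out


def rip_fold_enrichment(
    ct_target_ip: Sequence[float],
    ct_igg_ip: Sequence[float],
) -> float:
    """Fold enrichment of the RNA in a target immunoprecipitate relative to
    the IgG control: 2^(mean IgG Ct - mean target Ct)."""
    t = np.asarray(ct_target_ip, dtype=float)
    g = np.asarray(ct_igg_ip, dtype=float)
    if t.size == 0 or g.size == 0:
        raise LikError("need at least one Ct per arm")
    return float(2.0 ** (g.mean() - t.mean()))


def is_enriched(fold: float, threshold: float = 10.0) -> bool:
    """Convention for calling a RIP target enriched: fold strictly above
    the threshold (default tenfold)."""
    return fold > threshold


@dataclass(frozen=True)
class GoodnessOfFitResult:
    chi2: float
    df: int
    p_value: float


def fish_goodness_of_fit(
    control: tuple[int, int],
    treatment: tuple[int, int],
) -> GoodnessOfFitResult:
    """Pearson chi-squared goodness of fit of treatment FISH counts against
    control proportions.

    Each argument is (biallelic, not_biallelic) nucleus counts.  Expected
    treatment counts are the control proportions scaled to the treatment
    total; df = 1 (two categories); no continuity correction.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if (c < 0).any() or (t < 0).any():
        raise LikError("counts must be nonnegative")
    if c.sum() <= 0 or t.sum() <= 0:
        raise LikError("each arm needs a positive total count")
    expected = c / c.sum() * t.sum()
    if (expected == 0).any():
        raise LikError("expected count of zero; test undefined")
    chi2 = float(((t - expected) ** 2 / expected).sum())
    df = t.size - 1
    return GoodnessOfFitResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def fish_counts_from_frame(fish: pd.DataFrame, condition: str) -> tuple[int, int]:
    row = fish.loc[fish["condition"] == condition]
    if row.empty:
        raise LikError(f"no FISH counts for condition {condition!r}")
    return int(row["biallelic"].iloc[0]), int(row["not_biallelic"].iloc[0])
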