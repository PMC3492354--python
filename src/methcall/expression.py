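"""Methylation-expression concordance.

Expression matrices are standardized per gene to z-scores; differential
expression follows the combined rule: a permutation t-test (step-down
maxT + BH FDR, mirroring the methylation test) must be significant AND
the z-score must exceed 1 in strictly more than half of the case
samples (symmetric, z < -1, for down-regulation).  Concordance is then
summarized per differentially methylated gene: hypermethylated genes
with reduced expression, hypomethylated genes with increased
expression.  Percentages are exact rational arithmetic truncated to one
decimal, matching how such tables are conventionally printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .stats import bh_fdr, maxt_stepdown

__all__ = [
    "ExpressionZMatrix",
    "ExpressionConfig",
    "zscore_transform",
    "call_differential_expression",
    "concordance_summary",
]


@dataclass
class ExpressionZMatrix:
    """Per-gene standardized expression.

    ``z`` is genes x samples; ``source_stats`` records the mean and SD
    used per gene (computed over the standardization population).
    Zero-variance genes are flagged and their z set missing.
    """

    z: pd.DataFrame
    source_stats: pd.DataFrame
    population: list[str]

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


@dataclass
class ExpressionConfig:
    alpha: float = 0.01
    z_threshold: float = 1.0
    min_case_fraction: float = 0.5  # strictly more than this fraction
    use_adjusted: bool = True       # apply alpha to the BH q-value
    n_perm: int = 10000
    seed: int | None = 0
    exhaustive_limit: int = 20000


def zscore_transform(
    expr: pd.DataFrame,
    population: list[str] | None = None,
    ddof: int = 1,
) -> ExpressionZMatrix:
    """Standardize each gene: z = (x - mean) / SD over ``population``.

    The standardization population defaults to all samples; sample SD
    (ddof=1) is the default convention, ``ddof=0`` selects the
    population SD.  Genes with zero SD are flagged (z -> NaN).
    """
    if population is None:
        population = list(expr.columns)
    missing = [s for s in population if s not in expr.columns]
    if missing:
        raise KeyError(f"population samples not in matrix: {missing[:5]}")
    sub = expr[list(population)]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    flagged = (sd == 0) | sd.isna()
    sd_safe = sd.replace(0, np.nan)
    z = expr.sub(mean, axis=0).div(sd_safe, axis=0)
    stats = pd.DataFrame({"mean": mean, "sd": sd, "zero_sd": flagged})
    return ExpressionZMatrix(z=z, source_stats=stats, population=list(population))


def call_differential_expression(
    zmat: ExpressionZMatrix,
    case_ids,
    ref_ids,
    cfg: ExpressionConfig | None = None,
) -> pd.DataFrame:
    """Per-gene {up, down, none} differential-expression calls.

    up: test significant AND z > z_threshold in > 50% of case samples;
    down: symmetric with z < -z_threshold.
    """
    cfg = cfg or ExpressionConfig()
    case_ids, ref_ids = list(case_ids), list(ref_ids)
    if len(case_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("both groups need >= 2 samples for the test")
    z = zmat.z
    X = z[case_ids + ref_ids].to_numpy(dtype=float)
    labels = np.array([1] * len(case_ids) + [0] * len(ref_ids))
    perm = maxt_stepdown(X, labels, n_perm=cfg.n_perm, seed=cfg.seed,
                         exhaustive_limit=cfg.exhaustive_limit,
                         feature_ids=np.asarray(z.index))
    q = bh_fdr(perm.p_raw)
    sig = (q if cfg.use_adjusted else perm.p_raw) < cfg.alpha

    zc = z[case_ids].to_numpy(dtype=float)
    fin = np.isfinite(zc)
    n_case = fin.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac_up = np.where(fin, zc > cfg.z_threshold, False).sum(axis=1) / n_case
        frac_dn = np.where(fin, zc < -cfg.z_threshold, False).sum(axis=1) / n_case
    frac_up = np.where(n_case > 0, frac_up, 0.0)
    frac_dn = np.where(n_case > 0, frac_dn, 0.0)

    up = sig & (frac_up > cfg.min_case_fraction)
    down = sig & (frac_dn > cfg.min_case_fraction)
    direction = np.where(up, "up", np.where(down, "down", "none"))
    return pd.DataFrame(
        {
            "direction": direction,
            "frac_above": frac_up,
            "frac_below": frac_dn,
            "p_raw": perm.p_raw,
            "q_fdr": q,
        },
        index=z.index,
    )


def _pct_truncated(k: int, n: int) -> float:
    """Exact k/n as a percentage truncated to one decimal (38.46.. -> 38.4)."""
    frac = Fraction(k, n) * 1000  # tenths of a percent
    return float(int(frac)) / 10.0


def concordance_summary(gene_calls: pd.DataFrame, expr_calls: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate methylation direction against expression direction.

    Rows: hyper (concordant = down-regulated) and hypo (concordant =
    up-regulated).  Evaluable = called genes with expression data;
    percentages are NaN when nothing is evaluable.
    """
    rows = []
    for meth_dir, expr_dir in (("hyper", "down"), ("hypo", "up")):
        genes = gene_calls.index[gene_calls["direction"] == meth_dir]
        evaluable = [g for g in genes if g in expr_calls.index]
        concordant = [g for g in evaluable
                      if expr_calls.loc[g, "direction"] == expr_dir]
        pct = (_pct_truncated(len(concordant), len(evaluable))
               if evaluable else float("nan"))
        rows.append(
            {
                "methylation": meth_dir,
                "expression": expr_dir,
                "n_called": len(genes),
                "n_evaluable": len(evaluable),
                "n_concordant": len(concordant),
                "concordant_pct": pct,
            }
        )
    return pd.DataFrame(rows).set_index("methylation")
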