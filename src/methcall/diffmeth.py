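"""Three-criteria consensus differential-methylation calling.

A probe is called differentially methylated in a case-vs-reference
comparison only when three independent criteria agree:

A. **threshold** — hypermethylated when every reference beta is below
   ``low_beta`` (0.25) and at least ``case_fraction`` (10%) of case
   samples exceed ``high_beta`` (0.75); hypomethylated symmetrically.
B. **mean shift** — |mean(case) - mean(reference)| strictly greater
   than ``mean_diff`` (0.25); the sign gives the direction.
C. **test** — an unpaired t-test assessed by step-down maxT permutation
   and Benjamini–Hochberg FDR across all probes jointly (q < 0.05).
   When either group is smaller than ``min_group_for_ttest`` the test is
   not applicable (single-tissue references); the call then rests on
   A and B and carries a ``test_skipped`` flag.

NB-specific genes are the per-direction intersection of gene-level
calls across several independent reference comparisons (normal fetal
brain, adrenal gland, and ganglioneuroma/ganglioneuroblastoma), ranked
by the fraction of case samples shifted and the size of the beta change.

The public model object is :class:`DifferentialMethylation`, whose
``fit()`` returns :class:`DifferentialMethylationResults`; the
functional surface (:func:`call_probes` etc.) delegates to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix
from .stats import bh_fdr, maxt_stepdown

__all__ = [
    "DiffMethConfig",
    "ContrastSpec",
    "DifferentialMethylation",
    "DifferentialMethylationResults",
    "ConsensusResult",
    "criterion_threshold",
    "criterion_meandiff",
    "call_probes",
    "aggregate_to_genes",
    "consensus_across_references",
    "rank_genes",
    "run_subgroup_contrast",
]


@dataclass
class DiffMethConfig:
    """Thresholds and test settings for the consensus caller."""

    low_beta: float = 0.25
    high_beta: float = 0.75
    case_fraction: float = 0.10
    mean_diff: float = 0.25
    fdr_alpha: float = 0.05
    n_perm: int = 10000
    seed: int | None = 0
    min_group_for_ttest: int = 3
    exhaustive_limit: int = 20000
    t_variant: str = "pooled"

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_beta < self.high_beta <= 1.0:
            raise ValueError("need 0 <= low_beta < high_beta <= 1")
        if not 0.0 < self.case_fraction <= 1.0:
            raise ValueError("case_fraction must be in (0, 1]")
        if not 0.0 < self.mean_diff < 1.0:
            raise ValueError("mean_diff must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


# fraction comparisons are inclusive (>=); give float arithmetic 1 ulp of slack
_FRAC_EPS = 1e-12


# ---------------------------------------------------------------------------
# single-probe criteria (scalar reference implementations)
# ---------------------------------------------------------------------------

def criterion_threshold(ref_values, case_values, cfg: DiffMethConfig | None = None) -> str:
    """Direction under the threshold criterion: 'hyper', 'hypo' or 'none'.

    "In the reference samples" is read as *all* reference values beyond
    the threshold (the mean-based view is already the second criterion);
    the case-side fraction is inclusive and computed on non-missing
    values only.
    """
    cfg = cfg or DiffMethConfig()
    ref = np.asarray(ref_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    case = case[np.isfinite(case)]
    if len(ref) == 0 or len(case) == 0:
        return "none"
    frac_high = float(np.mean(case > cfg.high_beta))
    frac_low = float(np.mean(case < cfg.low_beta))
    if np.all(ref < cfg.low_beta) and frac_high >= cfg.case_fraction - _FRAC_EPS:
        return "hyper"
    if np.all(ref > cfg.high_beta) and frac_low >= cfg.case_fraction - _FRAC_EPS:
        return "hypo"
    return "none"


def criterion_meandiff(ref_values, case_values, cfg: DiffMethConfig | None = None
                       ) -> tuple[bool, float]:
    """Mean-shift criterion: (passes, signed delta = mean(case) - mean(ref)).

    The inequality is strict ("greater than"), so delta == mean_diff fails.
    """
    cfg = cfg or DiffMethConfig()
    ref = np.asarray(ref_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    case = case[np.isfinite(case)]
    if len(ref) == 0 or len(case) == 0:
        return False, float("nan")
    delta = float(np.mean(case) - np.mean(ref))
    return abs(delta) > cfg.mean_diff, delta


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class DifferentialMethylation:
    """Consensus differential-methylation model for one comparison.

    Parameters
    ----------
    beta
        BetaMatrix holding both groups.
    case_ids, ref_ids
        Disjoint sample-id sets present in the matrix.
    annotation
        Optional probe annotation used for gene-level aggregation.
    config
        :class:`DiffMethConfig`; defaults follow the stringent
        three-criteria scheme (0.25 / 0.75 / 10% / |delta| > 0.25 /
        q < 0.05).
    """

    def __init__(self, beta: BetaMatrix, case_ids: Sequence[str],
                 ref_ids: Sequence[str], annotation: pd.DataFrame | None = None,
                 config: DiffMethConfig | None = None):
        case_ids = list(case_ids)
        ref_ids = list(ref_ids)
        overlap = set(case_ids) & set(ref_ids)
        if overlap:
            raise ValueError(f"case and reference samples overlap: {sorted(overlap)[:5]}")
        missing = [s for s in case_ids + ref_ids if s not in beta.beta.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        if not case_ids or not ref_ids:
            raise ValueError("case and reference sets must be non-empty")
        self.beta = beta
        self.case_ids = case_ids
        self.ref_ids = ref_ids
        self.annotation = annotation
        self.config = config or DiffMethConfig()

    @classmethod
    def from_dataframe(cls, beta_df: pd.DataFrame, case_ids, ref_ids,
                       annotation=None, config=None) -> "DifferentialMethylation":
        return cls(BetaMatrix(beta_df), case_ids, ref_ids, annotation, config)

    def fit(self) -> "DifferentialMethylationResults":
        cfg = self.config
        C = self.beta.values_for(self.case_ids)
        R = self.beta.values_for(self.ref_ids)
        probe_ids = self.beta.beta.index

        c_fin = np.isfinite(C)
        r_fin = np.isfinite(R)
        n_case = c_fin.sum(axis=1)
        n_ref = r_fin.sum(axis=1)

        with np.errstate(invalid="ignore", divide="ignore"):
            frac_high = np.where(c_fin, C > cfg.high_beta, False).sum(axis=1) / n_case
            frac_low = np.where(c_fin, C < cfg.low_beta, False).sum(axis=1) / n_case
            mean_case = np.where(c_fin, C, 0.0).sum(axis=1) / n_case
            mean_ref = np.where(r_fin, R, 0.0).sum(axis=1) / n_ref
        frac_high = np.where(n_case > 0, frac_high, 0.0)
        frac_low = np.where(n_case > 0, frac_low, 0.0)
        mean_case = np.where(n_case > 0, mean_case, np.nan)
        mean_ref = np.where(n_ref > 0, mean_ref, np.nan)

        ref_all_low = np.where(r_fin, R < cfg.low_beta, True).all(axis=1) & (n_ref >= 1)
        ref_all_high = np.where(r_fin, R > cfg.high_beta, True).all(axis=1) & (n_ref >= 1)

        a_hyper = ref_all_low & (frac_high >= cfg.case_fraction - _FRAC_EPS)
        a_hypo = ref_all_high & (frac_low >= cfg.case_fraction - _FRAC_EPS)

        delta = mean_case - mean_ref
        b_pass = np.abs(delta) > cfg.mean_diff

        test_skipped = (len(self.case_ids) < cfg.min_group_for_ttest
                        or len(self.ref_ids) < cfg.min_group_for_ttest)
        if test_skipped:
            perm = None
            p_raw = np.full(len(probe_ids), np.nan)
            p_adj = np.full(len(probe_ids), np.nan)
            q = np.full(len(probe_ids), np.nan)
            c_pass = np.ones(len(probe_ids), dtype=bool)  # consensus on A & B only
        else:
            X = np.hstack([C, R])
            labels = np.array([1] * len(self.case_ids) + [0] * len(self.ref_ids))
            perm = maxt_stepdown(
                X, labels, n_perm=cfg.n_perm, seed=cfg.seed,
                exhaustive_limit=cfg.exhaustive_limit, variant=cfg.t_variant,
                feature_ids=np.asarray(probe_ids),
            )
            p_raw = perm.p_raw
            p_adj = perm.p_adj
            q = bh_fdr(p_raw)
            c_pass = q < cfg.fdr_alpha

        hyper = a_hyper & b_pass & (delta > 0) & c_pass
        hypo = a_hypo & b_pass & (delta < 0) & c_pass
        direction = np.where(hyper, "hyper", np.where(hypo, "hypo", "none"))
        frac_shift = np.where(
            direction == "hyper", frac_high,
            np.where(direction == "hypo", frac_low,
                     np.where(np.nan_to_num(delta) >= 0, frac_high, frac_low)),
        )

        calls = pd.DataFrame(
            {
                "direction": direction,
                "crit_threshold": a_hyper | a_hypo,
                "crit_meandiff": b_pass,
                "crit_test": pd.array(
                    [pd.NA] * len(probe_ids) if test_skipped else c_pass,
                    dtype="boolean",
                ),
                "test_skipped": test_skipped,
                "fraction_cases_shifted": frac_shift,
                "mean_case": mean_case,
                "mean_ref": mean_ref,
                "delta": delta,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "q_fdr": q,
            },
            index=probe_ids,
        )
        return DifferentialMethylationResults(self, calls, perm)


class DifferentialMethylationResults:
    """Fitted per-probe calls plus gene-level views."""

    def __init__(self, model: DifferentialMethylation, probe_calls: pd.DataFrame,
                 perm_result=None):
        self.model = model
        self.probe_calls = probe_calls
        self.perm_result = perm_result

    @property
    def config(self) -> DiffMethConfig:
        return self.model.config

    def gene_calls(self, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
        ann = annotation if annotation is not None else self.model.annotation
        if ann is None:
            raise ValueError("gene-level aggregation needs a probe annotation")
        return aggregate_to_genes(self.probe_calls, ann)

    def summary(self) -> str:
        pc = self.probe_calls
        n_hyper = int((pc["direction"] == "hyper").sum())
        n_hypo = int((pc["direction"] == "hypo").sum())
        lines = [
            "Consensus differential methylation",
            "==================================",
            f"probes:              {len(pc)}",
            f"case samples:        {len(self.model.case_ids)}",
            f"reference samples:   {len(self.model.ref_ids)}",
            f"t-test:              {'skipped (group too small)' if pc['test_skipped'].any() else 'maxT + BH FDR'}",
            f"threshold criterion: {int(pc['crit_threshold'].sum())} probes",
            f"mean-shift criterion:{int(pc['crit_meandiff'].sum()):>5} probes",
            f"consensus hyperM:    {n_hyper} probes",
            f"consensus hypoM:     {n_hypo} probes",
        ]
        return "\n".join(lines)


def call_probes(beta: BetaMatrix, case_ids, ref_ids,
                cfg: DiffMethConfig | None = None,
                annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-probe consensus calls for one comparison (functional surface)."""
    return DifferentialMethylation(beta, case_ids, ref_ids, annotation, cfg).fit().probe_calls


# ---------------------------------------------------------------------------
# gene-level aggregation, multi-reference consensus, ranking
# ---------------------------------------------------------------------------

def aggregate_to_genes(calls: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Any-probe gene aggregation with a direction-consistency flag.

    A gene is called when at least one of its probes is called; genes
    whose called probes disagree in direction are flagged ambiguous and
    excluded from ranked lists.
    """
    called = calls[calls["direction"] != "none"]
    known = called.index.isin(ann.index)
    if (~known).any():
        warnings.warn(
            f"{int((~known).sum())} called probes lack annotation and were skipped",
            stacklevel=2,
        )
        called = called[known]
    if called.empty:
        return pd.DataFrame(
            columns=["direction", "supporting_probes", "n_supporting",
                     "best_fraction_cases", "max_abs_meandiff", "ambiguous"]
        ).rename_axis("gene_symbol")
    genes = ann.reindex(called.index)["gene_symbol"]
    rows = {}
    for gene, grp in called.groupby(genes.to_numpy()):
        dirs = set(grp["direction"])
        ambiguous = len(dirs) > 1
        rows[gene] = {
            "direction": "ambiguous" if ambiguous else next(iter(dirs)),
            "supporting_probes": ",".join(grp.index),
            "n_supporting": len(grp),
            "best_fraction_cases": float(grp["fraction_cases_shifted"].max()),
            "max_abs_meandiff": float(grp["delta"].abs().max()),
            "ambiguous": ambiguous,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_symbol"
    return out.sort_index()


@dataclass
class ConsensusResult:
    """Per-direction intersection across reference comparisons.

    ``regions`` holds the full Venn membership: one row per
    (gene, direction) observed anywhere, with a boolean column per
    comparison.  ``gene_table`` carries conservative (minimum over
    comparisons) ranking statistics for the intersection genes.
    """

    hyper: list[str]
    hypo: list[str]
    regions: pd.DataFrame
    gene_table: pd.DataFrame

    def exclusive_to(self, name: str) -> pd.DataFrame:
        others = [c for c in self.regions.columns
                  if c not in ("direction",) and c != name]
        mask = self.regions[name] & ~self.regions[others].any(axis=1)
        return self.regions[mask]


def consensus_across_references(
    gene_call_sets: Sequence[pd.DataFrame],
    names: Sequence[str] | None = None,
) -> ConsensusResult:
    """Intersect gene calls (by symbol AND direction) across comparisons.

    Genes whose direction conflicts between comparisons cannot be in
    either intersection; every Venn region is reported.
    """
    if len(gene_call_sets) < 2:
        raise ValueError("consensus needs at least two reference comparisons")
    if names is None:
        names = [f"ref{i + 1}" for i in range(len(gene_call_sets))]
    if len(names) != len(gene_call_sets):
        raise ValueError("names/gene_call_sets length mismatch")

    unambiguous = [gc[~gc["ambiguous"]] if len(gc) else gc for gc in gene_call_sets]
    keys = sorted(
        {(g, d) for gc in unambiguous for g, d in zip(gc.index, gc["direction"])}
    )
    regions = pd.DataFrame(
        {
            name: [((g in gc.index) and gc.loc[g, "direction"] == d) for g, d in keys]
            for name, gc in zip(names, unambiguous)
        },
        index=pd.MultiIndex.from_tuples(keys, names=["gene_symbol", "direction"]),
    ).reset_index(level="direction")

    in_all = regions[list(names)].all(axis=1)
    consensus = regions[in_all]
    hyper = sorted(consensus.index[consensus["direction"] == "hyper"])
    hypo = sorted(consensus.index[consensus["direction"] == "hypo"])

    rows = {}
    for gene in hyper + hypo:
        rows[gene] = {
            "direction": "hyper" if gene in hyper else "hypo",
            # case samples are shared between comparisons, so take the
            # most conservative (minimum) statistics over references
            "best_fraction_cases": min(
                float(gc.loc[gene, "best_fraction_cases"]) for gc in unambiguous
            ),
            "max_abs_meandiff": min(
                float(gc.loc[gene, "max_abs_meandiff"]) for gc in unambiguous
            ),
            "ambiguous": False,
        }
    gene_table = pd.DataFrame.from_dict(rows, orient="index")
    if gene_table.empty:
        gene_table = pd.DataFrame(
            columns=["direction", "best_fraction_cases", "max_abs_meandiff", "ambiguous"]
        )
    gene_table.index.name = "gene_symbol"
    return ConsensusResult(hyper=hyper, hypo=hypo, regions=regions,
                           gene_table=gene_table)


def rank_genes(gene_calls: pd.DataFrame) -> pd.DataFrame:
    """Rank non-ambiguous gene calls.

    Primary key: fraction of case samples shifted (descending);
    secondary: maximum |delta beta| (descending); tertiary: gene symbol
    (ascending) so output order is deterministic.
    """
    gc = gene_calls[~gene_calls["ambiguous"]].copy()
    gc["_sym"] = gc.index
    gc = gc.sort_values(
        by=["best_fraction_cases", "max_abs_meandiff", "_sym"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_sym")
    gc["rank"] = np.arange(1, len(gc) + 1)
    return gc


# ---------------------------------------------------------------------------
# subgroup contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastSpec:
    """Selects two NB sample sets from the sample sheet.

    ``group_by`` is one of the sheet fields (``risk``, ``inss_stage``,
    ``mycn``) or ``"age"``, in which case ``age_cutoff_months`` splits
    the tumors into case = younger (< cutoff) and ref = older (>= cutoff).
    """

    group_by: str
    case_levels: tuple = ()
    ref_levels: tuple = ()
    age_cutoff_months: float | None = None
    name: str = ""

    def select(self, sheet: pd.DataFrame) -> tuple[list[str], list[str]]:
        nb = sheet[sheet["group"] == "NB"]
        if self.group_by == "age":
            if self.age_cutoff_months is None:
                raise ValueError("age contrast needs age_cutoff_months")
            case = nb.index[nb["age_months"] < self.age_cutoff_months]
            ref = nb.index[nb["age_months"] >= self.age_cutoff_months]
        else:
            if self.group_by not in sheet.columns:
                raise KeyError(f"unknown sample-sheet field {self.group_by!r}")
            col = nb[self.group_by].astype(str)
            case = nb.index[col.isin([str(x) for x in self.case_levels])]
            ref = nb.index[col.isin([str(x) for x in self.ref_levels])]
        case, ref = list(case), list(ref)
        if not case or not ref:
            raise ValueError(
                f"contrast {self.name or self.group_by!r}: empty subgroup "
                f"(case={len(case)}, ref={len(ref)})"
            )
        return case, ref


@dataclass
class SubgroupResult:
    contrast: ContrastSpec
    case_ids: list[str]
    ref_ids: list[str]
    probe_calls: pd.DataFrame
    gene_calls: pd.DataFrame | None


def run_subgroup_contrast(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    contrast: ContrastSpec,
    cfg: DiffMethConfig | None = None,
    annotation: pd.DataFrame | None = None,
    reference_ids: Sequence[str] | None = None,
) -> SubgroupResult:
    """Run the consensus caller between two tumor subgroups.

    When ``reference_ids`` (normal/benign tissues) are supplied, each
    called probe additionally gets a ``ref_consistent`` flag: the
    threshold criterion against those external references must agree
    with the subgroup call direction (three-way consistency).
    """
    cfg = cfg or DiffMethConfig()
    case_ids, ref_ids = contrast.select(sheet)
    res = DifferentialMethylation(beta, case_ids, ref_ids, annotation, cfg).fit()
    calls = res.probe_calls
    if reference_ids is not None:
        ext = beta.values_for(list(reference_ids))
        case_vals = beta.values_for(case_ids)
        flags = []
        for i, probe in enumerate(calls.index):
            d = calls["direction"].iloc[i]
            if d == "none":
                flags.append(False)
            else:
                flags.append(criterion_threshold(ext[i], case_vals[i], cfg) == d)
        calls = calls.assign(ref_consistent=flags)
    gene_calls = None
    if annotation is not None:
        gene_calls = aggregate_to_genes(calls, annotation)
    return SubgroupResult(contrast, case_ids, ref_ids, calls, gene_calls)
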