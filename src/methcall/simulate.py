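"""Synthetic Infinium-style beta matrices with planted truth.

The generator emulates the statistical structure of a 27K-style tumor
methylation study: a bimodal per-probe beta landscape (unmethylated
probes around 0.10, methylated around 0.85, a minority intermediate),
shared baselines across samples with beta-distributed measurement
noise, single-tissue and small-group reference sets (fetal brain,
adrenal gland, ganglioneuroma/ganglioneuroblastoma), per-probe
detection p-values with planted failures, planted hyper-/hypomethylated
genes carried by a configurable fraction of case samples,
subgroup-specific signals keyed to the sample sheet, and an expression
matrix whose responsive genes co-/anti-vary with the planted
methylation (hyper -> down, hypo -> up).

Everything is driven by one seed; identical configs give byte-identical
outputs.  The registry of planted signal (:class:`SyntheticTruth`)
enables sensitivity/precision scoring of the calling pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "make_ccnd1_fixture",
    "reference_groups",
]

_AUTOSOMES = [str(i) for i in range(1, 23)]


@dataclass
class SyntheticConfig:
    """Study-scale defaults mirror the emulated design: ~1000 genes at
    1-3 probes each (~2000 probes), 20 tumors, references FB=1, AG=1,
    GN=2 + GNB=1; beta mixture 45% unmethylated (mean 0.10) / 45%
    methylated (mean 0.85) / 10% intermediate at concentration 50;
    planted shifts of 0.6 carried by half the tumors."""

    n_genes: int = 1000
    probes_per_gene: tuple[int, int] = (1, 3)  # uniform inclusive
    n_case: int = 20
    ref_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"FB": 1, "AG": 1, "GN": 2, "GNB": 1}
    )
    frac_unmeth: float = 0.45
    frac_meth: float = 0.45
    unmeth_mean: float = 0.10
    meth_mean: float = 0.85
    concentration: float = 50.0
    n_planted_hyper: int = 10
    n_planted_hypo: int = 30
    effect_delta: float = 0.6
    planted_case_fraction: float = 0.5
    subgroup_specs: tuple = ()  # (field, level, n_genes, direction)
    expression_coupling_fraction: float = 0.5
    expression_coupling_magnitude: float = 2.0  # in units of the gene's SD
    frac_gonosomal: float = 0.04
    bad_sample_count: int = 0
    bad_sample_fail_fraction: float = 0.05
    n_failed_probes: int = 0
    detection_noise_max: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_unmeth", "frac_meth", "planted_case_fraction",
                     "expression_coupling_fraction", "frac_gonosomal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.frac_unmeth + self.frac_meth > 1.0 + 1e-12:
            raise ValueError("mixture fractions exceed 1")
        if self.n_planted_hyper + self.n_planted_hypo > self.n_genes:
            raise ValueError("more planted genes than genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ref_sizes"] = dict(self.ref_sizes)
        return d


@dataclass
class SyntheticTruth:
    """Registry of everything that was planted."""

    hyper_genes: list[str]
    hypo_genes: list[str]
    planted_probes: dict[str, list[str]]       # gene -> probes
    carriers: dict[str, list[str]]             # gene -> carrier case samples
    subgroup_genes: dict[str, list[str]]       # "field=level:direction" -> genes
    bad_samples: list[str]
    failed_probes: list[str]
    expression_responsive_genes: list[str]

    @property
    def planted_genes(self) -> set[str]:
        return set(self.hyper_genes) | set(self.hypo_genes)


@dataclass
class SyntheticDataset:
    beta: BetaMatrix
    annotation: pd.DataFrame
    sheet: pd.DataFrame
    expression: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig


def reference_groups(sheet: pd.DataFrame) -> dict[str, list[str]]:
    """The three reference comparisons used to define tumor-specific
    genes: FB, AG, and GN together with GNB."""
    out: dict[str, list[str]] = {}
    fb = list(sheet.index[sheet["group"] == "FB"])
    ag = list(sheet.index[sheet["group"] == "AG"])
    gn = list(sheet.index[sheet["group"].isin(["GN", "GNB"])])
    if fb:
        out["FB"] = fb
    if ag:
        out["AG"] = ag
    if gn:
        out["GN_GNB"] = gn
    return out


def _beta_noise(rng: np.random.Generator, mean, concentration: float, size) -> np.ndarray:
    mean = np.clip(np.asarray(mean, dtype=float), 0.02, 0.98)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)


def _sample_sheet(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    case_ids = [f"NB{i + 1:02d}" for i in range(cfg.n_case)]
    # INSS stages roughly in the observed clinical proportions
    stage_pool = ["1", "2", "3", "4", "4S"]
    stage_p = [0.17, 0.17, 0.16, 0.32, 0.18]
    stages = rng.choice(stage_pool, size=cfg.n_case, p=stage_p)
    status = ["amplified", "non_amplified"]
    mycn_stage4 = rng.choice(status, size=cfg.n_case, p=[0.6, 0.4])
    mycn_other = rng.choice(status, size=cfg.n_case, p=[0.1, 0.9])
    mycn = np.where(stages == "4", mycn_stage4, mycn_other)
    ages = np.round(np.clip(rng.gamma(1.6, 22.0, size=cfg.n_case), 0, 120), 1)
    rows = {
        sid: {"group": "NB", "inss_stage": st, "mycn": my, "age_months": age}
        for sid, st, my, age in zip(case_ids, stages, mycn, ages)
    }
    for tissue, count in cfg.ref_sizes.items():
        for i in range(count):
            sid = f"{tissue}{i + 1:02d}" if count > 1 else f"{tissue}01"
            rows[sid] = {"group": tissue, "inss_stage": "NA",
                         "mycn": "undetermined", "age_months": 0.0}
    sheet = pd.DataFrame.from_dict(rows, orient="index")
    from .io import derive_risk

    sheet["risk"] = [derive_risk(s, m)
                     for s, m in zip(sheet["inss_stage"], sheet["mycn"])]
    return sheet


def generate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic dataset plus its truth registry."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    sheet = _sample_sheet(cfg, rng)
    case_ids = list(sheet.index[sheet["group"] == "NB"])
    sample_ids = list(sheet.index)
    n_samples = len(sample_ids)

    # --- genes, probes, annotation ---------------------------------------
    genes = [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)]
    ppg = rng.integers(cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1,
                       size=cfg.n_genes)
    probe_gene: list[str] = []
    for g, k in zip(genes, ppg):
        probe_gene.extend([g] * int(k))
    n_probes = len(probe_gene)
    probe_ids = [f"cg{i + 1:07d}" for i in range(n_probes)]

    n_gono_genes = int(round(cfg.frac_gonosomal * cfg.n_genes))
    gene_chrom = {}
    for i, g in enumerate(genes):
        if i < n_gono_genes:
            gene_chrom[g] = "X" if i % 8 else "Y"  # Y genes are rare
        else:
            gene_chrom[g] = _AUTOSOMES[int(rng.integers(0, 22))]
    gene_band = {
        g: f"{gene_chrom[g]}{rng.choice(['p', 'q'])}{rng.integers(11, 36)}"
        for g in genes
    }
    ann = pd.DataFrame(index=probe_ids)
    ann["gene_symbol"] = probe_gene
    ann["chromosome"] = [gene_chrom[g] for g in probe_gene]
    ann["cytoband"] = [gene_band[g] for g in probe_gene]
    ann["position"] = pd.array(rng.integers(10_000, 240_000_000, size=n_probes),
                               dtype="Int64")
    ann["promoter_class"] = rng.choice(
        ["HCP", "ICP", "LCP", "MIXED"], size=n_probes, p=[0.54, 0.12, 0.23, 0.11]
    )
    ann["is_pcg_target"] = rng.random(n_probes) < 0.096
    ann["is_gonosomal"] = ann["chromosome"].isin(["X", "Y"]).to_numpy()

    # --- baseline mixture --------------------------------------------------
    state = rng.choice(
        ["unmeth", "meth", "mid"], size=n_probes,
        p=[cfg.frac_unmeth, cfg.frac_meth, 1.0 - cfg.frac_unmeth - cfg.frac_meth],
    )
    baseline = np.where(
        state == "unmeth", cfg.unmeth_mean,
        np.where(state == "meth", cfg.meth_mean, rng.uniform(0.3, 0.7, size=n_probes)),
    ).astype(float)

    # --- choose planted genes (autosomal only; QC would drop gonosomal) ---
    autosomal_genes = [g for g in genes if gene_chrom[g] not in ("X", "Y")]
    n_planted = cfg.n_planted_hyper + cfg.n_planted_hypo
    picked = list(rng.choice(autosomal_genes, size=n_planted, replace=False))
    hyper_genes = picked[: cfg.n_planted_hyper]
    hypo_genes = picked[cfg.n_planted_hyper:]

    gene_probes: dict[str, list[str]] = {}
    for pid, g in zip(probe_ids, probe_gene):
        gene_probes.setdefault(g, []).append(pid)
    probe_pos = {pid: i for i, pid in enumerate(probe_ids)}

    # force planted baselines to the mode the direction needs
    for g in hyper_genes:
        for pid in gene_probes[g]:
            baseline[probe_pos[pid]] = cfg.unmeth_mean
    for g in hypo_genes:
        for pid in gene_probes[g]:
            baseline[probe_pos[pid]] = cfg.meth_mean

    # --- carrier assignment and per-sample means ---------------------------
    n_carriers = int(round(cfg.planted_case_fraction * cfg.n_case))
    mean_matrix = np.tile(baseline[:, None], (1, n_samples))
    col_of = {sid: j for j, sid in enumerate(sample_ids)}
    carriers: dict[str, list[str]] = {}
    planted_probes: dict[str, list[str]] = {}
    for g in hyper_genes + hypo_genes:
        carr = sorted(rng.choice(case_ids, size=n_carriers, replace=False))
        carriers[g] = carr
        planted_probes[g] = list(gene_probes[g])
        sign = 1.0 if g in hyper_genes else -1.0
        for pid in gene_probes[g]:
            i = probe_pos[pid]
            for sid in carr:
                mean_matrix[i, col_of[sid]] = np.clip(
                    baseline[i] + sign * cfg.effect_delta, 0.02, 0.98
                )

    # --- subgroup-specific signals -----------------------------------------
    subgroup_genes: dict[str, list[str]] = {}
    used = set(picked)
    for spec in cfg.subgroup_specs:
        fld, level, n_sub, direction = spec
        pool = [g for g in autosomal_genes if g not in used]
        chosen = list(rng.choice(pool, size=int(n_sub), replace=False))
        used.update(chosen)
        members = [s for s in case_ids if str(sheet.loc[s, fld]) == str(level)]
        sign = 1.0 if direction == "hyper" else -1.0
        base_mode = cfg.unmeth_mean if direction == "hyper" else cfg.meth_mean
        for g in chosen:
            for pid in gene_probes[g]:
                i = probe_pos[pid]
                baseline[i] = base_mode
                mean_matrix[i, :] = base_mode
                for sid in members:
                    mean_matrix[i, col_of[sid]] = np.clip(
                        base_mode + sign * cfg.effect_delta, 0.02, 0.98
                    )
        subgroup_genes[f"{fld}={level}:{direction}"] = chosen

    beta_vals = _beta_noise(rng, mean_matrix, cfg.concentration,
                            size=mean_matrix.shape)
    beta_df = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)

    # --- detection p-values -------------------------------------------------
    det = rng.uniform(0.0, cfg.detection_noise_max, size=(n_probes, n_samples))
    bad_samples = list(rng.choice(case_ids, size=cfg.bad_sample_count,
                                  replace=False)) if cfg.bad_sample_count else []
    for sid in bad_samples:
        j = col_of[sid]
        n_fail = int(np.ceil(cfg.bad_sample_fail_fraction * n_probes))
        rows_fail = rng.choice(n_probes, size=n_fail, replace=False)
        det[rows_fail, j] = rng.uniform(0.05, 0.9, size=n_fail)
    failed_probes = []
    if cfg.n_failed_probes:
        idx = rng.choice(n_probes, size=cfg.n_failed_probes, replace=False)
        for i in idx:
            cols_fail = rng.choice(n_samples, size=max(1, n_samples // 10),
                                   replace=False)
            det[i, cols_fail] = rng.uniform(0.05, 0.9, size=len(cols_fail))
            failed_probes.append(probe_ids[int(i)])
    det_df = pd.DataFrame(det, index=probe_ids, columns=sample_ids)

    # --- coupled expression ---------------------------------------------------
    gene_mu = rng.normal(8.0, 2.0, size=cfg.n_genes)
    gene_sd = rng.uniform(0.5, 1.5, size=cfg.n_genes)
    expr = rng.normal(gene_mu[:, None], gene_sd[:, None],
                      size=(cfg.n_genes, n_samples))
    n_resp = int(round(cfg.expression_coupling_fraction * n_planted))
    responsive = list(rng.choice(picked, size=n_resp, replace=False))
    gene_row = {g: i for i, g in enumerate(genes)}
    for g in responsive:
        shift = cfg.expression_coupling_magnitude * gene_sd[gene_row[g]]
        sign = -1.0 if g in hyper_genes else 1.0  # hyper -> down, hypo -> up
        for sid in carriers[g]:
            expr[gene_row[g], col_of[sid]] += sign * shift
    expr_df = pd.DataFrame(expr, index=genes, columns=sample_ids)

    truth = SyntheticTruth(
        hyper_genes=hyper_genes,
        hypo_genes=hypo_genes,
        planted_probes=planted_probes,
        carriers=carriers,
        subgroup_genes=subgroup_genes,
        bad_samples=bad_samples,
        failed_probes=failed_probes,
        expression_responsive_genes=responsive,
    )
    return SyntheticDataset(
        beta=BetaMatrix(beta_df, det_df),
        annotation=ann,
        sheet=sheet,
        expression=expr_df,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# CCND1-like fixture
# ---------------------------------------------------------------------------

def make_ccnd1_fixture() -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame]:
    """Deterministic 17-probe single-gene fixture along a CCND1-like locus.

    Synthetic stand-in for a CCND1 probe panel: promoter
    probes unmethylated in every sample, gene-body probes epigenetically
    heterogeneous across the five reference samples (so the strict
    reference-side condition fails), and two 3'-region probes fully
    methylated (beta > 0.90) in all references while 17 of 21 tumors
    lose methylation.  A consensus caller at default thresholds must
    flag exactly those two probes, hypomethylated.

    Returns (beta, annotation, sample sheet).
    """
    rng = np.random.default_rng(20121107)
    case_ids = [f"NB{i + 1:02d}" for i in range(21)]
    ref_ids = ["GN01", "GN02", "GNB01", "FB01", "AG01"]
    samples = case_ids + ref_ids

    probes = [f"ccnd1_pr{i}" for i in range(1, 5)]          # promoter, synthetic
    probes += [f"ccnd1_body{i:02d}" for i in range(1, 12)]  # gene body, synthetic
    probes += ["cg04717045", "cg02723533"]                  # 3' region

    beta = pd.DataFrame(index=probes, columns=samples, dtype=float)
    jitter = lambda size, lo, hi: rng.uniform(lo, hi, size=size)

    for p in probes[:4]:  # promoter: unmethylated everywhere
        beta.loc[p] = jitter(26, 0.03, 0.10)
    # body: heterogeneous references, variably reduced tumors
    ref_patterns = np.array([
        [0.15, 0.85, 0.55, 0.30, 0.78],
        [0.82, 0.20, 0.60, 0.88, 0.35],
        [0.40, 0.72, 0.15, 0.80, 0.55],
    ])
    for i, p in enumerate(probes[4:15]):
        beta.loc[p, case_ids] = jitter(21, 0.05, 0.50)
        beta.loc[p, ref_ids] = ref_patterns[i % 3] + rng.uniform(-0.03, 0.03, 5)
    # 3' region: references consistently methylated, 17/21 tumors hypoM
    for p in probes[15:]:
        vals = np.empty(21)
        vals[:11] = jitter(11, 0.03, 0.09)    # markedly hypomethylated
        vals[11:17] = jitter(6, 0.10, 0.22)   # hypomethylated
        vals[17:] = jitter(4, 0.84, 0.93)     # retain methylation
        beta.loc[p, case_ids] = vals
        beta.loc[p, ref_ids] = np.array([0.92, 0.93, 0.94, 0.95, 0.96])

    ann = pd.DataFrame(index=probes)
    ann["gene_symbol"] = "CCND1"
    ann["chromosome"] = "11"
    ann["cytoband"] = "11q13"
    ann["position"] = pd.array(69455873 + 500 * np.arange(len(probes)), dtype="Int64")
    ann["promoter_class"] = (["HCP"] * 4) + (["UNKNOWN"] * 13)
    ann["is_pcg_target"] = False
    ann["is_gonosomal"] = False

    rows = {}
    for sid in case_ids:
        rows[sid] = {"group": "NB", "inss_stage": "NA", "mycn": "undetermined",
                     "age_months": 24.0, "risk": "other"}
    for sid, grp in zip(ref_ids, ["GN", "GN", "GNB", "FB", "AG"]):
        rows[sid] = {"group": grp, "inss_stage": "NA", "mycn": "undetermined",
                     "age_months": 0.0, "risk": "other"}
    sheet = pd.DataFrame.from_dict(rows, orient="index")
    return BetaMatrix(beta), ann, sheet
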