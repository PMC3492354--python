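"""Annotation-level enrichment of called gene sets.

Chromosome/cytoband distribution, promoter CpG-content classes
(HCP/ICP/LCP), Polycomb-target status and arbitrary term->gene maps
(GO-style) are all tested with the exact upper-tail hypergeometric
probability against a background universe, by default the genes that
survived QC on the array (the printed background percentages of such
studies are platform-relative, not genome-relative).

The sequence-based promoter classifier is an optional convenience: the
annotation table remains the source of truth for promoter class and
PcG status.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import EnrichmentResult, hypergeom_tail, bh_fdr

__all__ = [
    "PromoterClassifierConfig",
    "enrich_category",
    "chromosome_distribution",
    "classify_promoter",
    "classify_promoters_fasta",
    "read_category_map",
]


@dataclass
class PromoterClassifierConfig:
    """Sliding-window CpG-content classification around the TSS.

    The promoter is the window ``tss + window[0] .. tss + window[1]``
    (default -700..+200 bp); within it, 500-bp sliding windows are
    scored for GC fraction and CpG observed/expected ratio
    ``(#CpG * L) / (#C * #G)``.  High-CpG promoters (HCP) have some
    window with GC >= 0.55 and o/e >= 0.75; low-CpG promoters (LCP)
    never reach o/e 0.48; the rest are intermediate (ICP).
    """

    window: tuple[int, int] = (-700, 200)
    sliding_window: int = 500
    gc_high: float = 0.55
    cpg_oe_high: float = 0.75
    cpg_oe_low: float = 0.48
    step: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.cpg_oe_low < self.cpg_oe_high:
            raise ValueError("need 0 < cpg_oe_low < cpg_oe_high")
        if not 0.0 < self.gc_high < 1.0:
            raise ValueError("gc_high must be in (0, 1)")


def enrich_category(
    list_genes: Iterable[str],
    background_genes: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list per category.

    Raw hypergeometric p-values by default (set ``bh_correct`` for an
    additional BH column).  Every list gene must be in the background.
    """
    lst = set(list_genes)
    bg = set(background_genes)
    stray = lst - bg
    if stray:
        raise ValueError(f"list gene(s) absent from background: {sorted(stray)[:5]}")
    n, N = len(lst), len(bg)
    rows = []
    for cat in category_map:
        members = set(category_map[cat]) & bg
        res = EnrichmentResult(
            category=str(cat),
            k=len(lst & members),
            n=n,
            K=len(members),
            N=N,
            p_hyper=hypergeom_tail(len(lst & members), n, len(members), N),
        )
        rows.append(res)
    out = pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "k": [r.k for r in rows],
            "n": [r.n for r in rows],
            "K": [r.K for r in rows],
            "N": [r.N for r in rows],
            "list_pct": [100.0 * r.list_fraction for r in rows],
            "background_pct": [100.0 * r.background_fraction for r in rows],
            "p_hyper": [r.p_hyper for r in rows],
        }
    ).set_index("category")
    if bh_correct and len(out):
        out["q_bh"] = bh_fdr(out["p_hyper"].to_numpy())
    out["significant"] = out["p_hyper"] < alpha
    return out


_BAND_RE = re.compile(r"^([0-9XY]+[pq]\d+)")


def major_band(cytoband: str) -> str:
    """Collapse a cytoband to its major band (e.g. 19p13.2 -> 19p13)."""
    m = _BAND_RE.match(str(cytoband))
    return m.group(1) if m else str(cytoband)


def chromosome_distribution(
    called_genes: Iterable[str],
    ann: pd.DataFrame,
    background_genes: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome enrichment of called genes, plus per-band shares.

    Genes map to the chromosome/cytoband of their first annotated probe;
    called genes without annotation are excluded with a warning.  Because
    every chromosome is tested at once, the significance flag here uses
    the BH-corrected q across chromosomes (raw p is still reported);
    without the correction roughly half of all *random* gene lists would
    flag some chromosome.  For every chromosome enriched at ``alpha``,
    the second frame reports the share of that chromosome's called genes
    per major cytoband.
    """
    gene_info = (
        ann[["gene_symbol", "chromosome", "cytoband"]]
        .drop_duplicates("gene_symbol")
        .set_index("gene_symbol")
    )
    called = list(dict.fromkeys(called_genes))
    bg = (list(dict.fromkeys(background_genes)) if background_genes is not None
          else list(gene_info.index))
    unknown = [g for g in called if g not in gene_info.index]
    if unknown:
        warnings.warn(f"{len(unknown)} called genes lack annotation", stacklevel=2)
        called = [g for g in called if g in gene_info.index]
    bg = [g for g in bg if g in gene_info.index]
    chrom_of = gene_info["chromosome"]
    cat_map = {
        chrom: set(gene_info.index[chrom_of == chrom]) for chrom in chrom_of.unique()
    }
    chrom_df = enrich_category(called, bg, cat_map, alpha=alpha, bh_correct=True)
    if "q_bh" in chrom_df.columns:
        chrom_df["significant"] = chrom_df["q_bh"] < alpha
    chrom_df = chrom_df.sort_index()

    band_rows = []
    for chrom in chrom_df.index[chrom_df["significant"]]:
        genes_here = [g for g in called if chrom_of[g] == chrom]
        bands = pd.Series([major_band(gene_info.loc[g, "cytoband"]) for g in genes_here])
        for band, cnt in bands.value_counts().items():
            band_rows.append(
                (chrom, band, int(cnt), len(genes_here), 100.0 * cnt / len(genes_here))
            )
    band_df = pd.DataFrame(
        band_rows, columns=["chromosome", "band", "k", "chrom_called", "share_pct"]
    )
    return chrom_df, band_df


# ---------------------------------------------------------------------------
# sequence-based promoter classifier
# ---------------------------------------------------------------------------

def _window_stats(seq: np.ndarray, length: int, step: int):
    """Yield (gc_fraction, cpg_oe) for each sliding window of `length`."""
    # seq is a byte array; N bases are excluded from all counts
    s = seq
    for start in range(0, len(s) - length + 1, step):
        win = s[start : start + length]
        c = int(np.count_nonzero(win == ord("C")))
        g = int(np.count_nonzero(win == ord("G")))
        acgt = int(np.count_nonzero(win != ord("N")))
        if acgt == 0:
            yield 0.0, 0.0
            continue
        cg = int(np.count_nonzero((win[:-1] == ord("C")) & (win[1:] == ord("G"))))
        gc = (c + g) / acgt
        oe = (cg * acgt) / (c * g) if c and g else 0.0
        yield gc, oe


def classify_promoter(
    sequence: str,
    cfg: PromoterClassifierConfig | None = None,
    tss: int | None = None,
) -> str:
    """Classify a promoter sequence as HCP, ICP or LCP.

    With ``tss`` (0-based index into ``sequence``) the analysis is
    restricted to the configured window around it, making the result
    invariant to flanking sequence; otherwise the whole sequence is
    treated as the promoter window.
    """
    cfg = cfg or PromoterClassifierConfig()
    seq = sequence.upper()
    if tss is not None:
        lo = max(0, tss + cfg.window[0])
        hi = min(len(seq), tss + cfg.window[1])
        seq = seq[lo:hi]
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence alphabet must be ACGTN")
    if len(seq) < cfg.sliding_window:
        raise ValueError(
            f"sequence ({len(seq)} bp) shorter than sliding window "
            f"({cfg.sliding_window} bp)"
        )
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_hcp = False
    any_reaches_low = False
    for gc, oe in _window_stats(arr, cfg.sliding_window, cfg.step):
        if gc >= cfg.gc_high and oe >= cfg.cpg_oe_high:
            is_hcp = True
        if oe >= cfg.cpg_oe_low:
            any_reaches_low = True
    if is_hcp:
        return "HCP"
    if not any_reaches_low:
        return "LCP"
    return "ICP"


def classify_promoters_fasta(path, cfg: PromoterClassifierConfig | None = None,
                             tss: int | None = None) -> pd.Series:
    """Classify every record of a promoter FASTA (record id = gene symbol)."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = classify_promoter(str(rec.seq), cfg, tss=tss)
    return pd.Series(out, name="promoter_class")


def read_category_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term->genes mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["term", "gene"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(term, set()).add(gene)
    return out
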