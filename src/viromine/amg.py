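"""Core vs auxiliary metabolic gene (AMG) partitioning and profiling.

Viral genes fall into three classes: *core* genes serve viral replication
(VOG category Xr) or virion structure (Xs); *AMGs* are host-metabolism genes
(nutrient transformation, pollutant degradation) recognised by a curated
Pfam-family list; everything else is *other*. Core takes precedence over AMG
when annotations conflict, so structural genes never inflate AMG counts.

A putative AMG is positionally validated in the DRAM-v style: it should be
flanked by viral hallmark genes on both sides, and receives flags
F (near a contig end, where host contamination is likeliest) and
B (inside a run of >=3 consecutive metabolism-flagged genes, suggesting a
bystander host genome fragment). Per-sample AMG diversity and summed TPM are
compared between groups with an exact rank-sum test and a Fisher 2x2 test,
and gene co-occurrence across samples is summarised as a Pearson network
(|r| > 0.6, p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationHit, GeneRecord
from .params import Parameters

__all__ = [
    "GeneClass", "AMGValidation", "AMGGroupComparison",
    "load_amg_families", "default_amg_families",
    "classify_genes", "validate_context", "validate_all",
    "amg_abundance", "cooccurrence_network",
]

AMG_CATEGORIES = ("C", "N", "P", "S", "pesticide", "other")


@dataclass(frozen=True)
class GeneClass:
    gene_id: str
    klass: str                    # core | AMG | other
    basis: str = ""               # VOG category or Pfam family behind the call
    amg_category: str | None = None


@dataclass(frozen=True)
class AMGValidation:
    gene_id: str
    flanked_both_sides: bool
    flags: frozenset[str]
    auxiliary_score: int | None = None


def load_amg_families(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("pfam_family", "amg_category"):
        if col not in df.columns:
            raise ValueError(f"AMG family list: missing column {col}")
    bad = set(df["amg_category"]) - set(AMG_CATEGORIES)
    if bad:
        raise ValueError(f"AMG family list: unknown categories {sorted(bad)}")
    return dict(zip(df["pfam_family"], df["amg_category"]))


def default_amg_families() -> dict[str, str]:
    """The curated Pfam-family -> category list shipped with the package."""
    ref = resources.files("viromine").joinpath("data/amg_families.tsv")
    with resources.as_file(ref) as p:
        return load_amg_families(p)


def classify_genes(genes: Sequence[GeneRecord],
                   hits: Iterable[AnnotationHit],
                   amg_families: Mapping[str, str] | None = None,
                   params: Parameters | None = None) -> list[GeneClass]:
    """Partition genes into core / AMG / other (core precedence)."""
    if amg_families is None:
        amg_families = default_amg_families()
    by_protein: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for g in genes:
        phits = by_protein.get(g.protein_id, [])
        core_basis = next(
            (h.label for h in phits
             if h.database == "VOG" and ("Xr" in h.label or "Xs" in h.label)),
            None)
        amg_hit = next(
            (h for h in phits
             if h.database == "PFAM" and h.accession in amg_families),
            None)
        if core_basis is not None:
            out.append(GeneClass(g.gene_id, "core", core_basis))
        elif amg_hit is not None:
            out.append(GeneClass(g.gene_id, "AMG", amg_hit.accession,
                                 amg_families[amg_hit.accession]))
        else:
            out.append(GeneClass(g.gene_id, "other"))
    return out


def _positional_flags(index: int, n_genes: int, m_indexes: set[int],
                      params: Parameters) -> set[str]:
    flags = set()
    if min(index, n_genes - 1 - index) < params.end_flag_window_genes:
        flags.add("F")
    if index in m_indexes:
        run_lo = index
        while run_lo - 1 in m_indexes:
            run_lo -= 1
        run_hi = index
        while run_hi + 1 in m_indexes:
            run_hi += 1
        if run_hi - run_lo + 1 >= params.consecutive_M_for_B:
            flags.add("B")
    return flags


def validate_context(gene: GeneRecord,
                     contig_genes: Sequence[GeneRecord],
                     hallmark_gene_ids: set[str],
                     params: Parameters,
                     input_flags: Mapping[str, set[str]] | None = None,
                     auxiliary_scores: Mapping[str, int] | None = None) -> AMGValidation:
    """Positional validation of one putative AMG.

    ``flanked_both_sides`` requires a hallmark gene at a strictly lower index
    and another at a strictly higher index on the same contig. Flag F marks a
    gene within ``end_flag_window_genes`` of either contig end; flag B marks
    membership in a run of >= ``consecutive_M_for_B`` consecutive
    metabolism-flagged (M) genes. Other flags are copied from the input
    annotation.
    """
    contig_genes = sorted(contig_genes, key=lambda g: g.index)
    if gene.gene_id not in {g.gene_id for g in contig_genes}:
        raise ValueError(f"gene {gene.gene_id} not on contig {gene.contig_id}")
    input_flags = input_flags or {}
    n = len(contig_genes)
    m_indexes = {g.index for g in contig_genes if "M" in input_flags.get(g.gene_id, set())}
    flags = set(input_flags.get(gene.gene_id, set()))
    flags |= _positional_flags(gene.index, n, m_indexes, params)
    flanked = (
        any(g.index < gene.index for g in contig_genes
            if g.gene_id in hallmark_gene_ids)
        and any(g.index > gene.index for g in contig_genes
                if g.gene_id in hallmark_gene_ids)
    )
    score = (auxiliary_scores or {}).get(gene.gene_id)
    return AMGValidation(gene.gene_id, flanked, frozenset(flags), score)


def validate_all(genes: Sequence[GeneRecord],
                 gene_classes: Sequence[GeneClass],
                 hits: Iterable[AnnotationHit],
                 params: Parameters,
                 hallmark_gene_ids: set[str] | None = None) -> list[AMGValidation]:
    """Validate every AMG-classified gene.

    Hallmark genes default to genes whose protein carries a VPF hit or a VOG
    ``hallmark`` label; flags are read from AMG_FLAG hits (one letter per
    hit label).
    """
    hits = list(hits)
    by_protein: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    if hallmark_gene_ids is None:
        hallmark_gene_ids = {
            g.gene_id for g in genes
            if any(h.database == "VPF" or (h.database == "VOG" and "hallmark" in h.label)
                   for h in by_protein.get(g.protein_id, []))
        }
    input_flags = {
        g.gene_id: {h.label for h in by_protein.get(g.protein_id, [])
                    if h.database == "AMG_FLAG"}
        for g in genes
    }
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    klass_of = {gc.gene_id: gc.klass for gc in gene_classes}
    out = []
    for g in genes:
        if klass_of.get(g.gene_id) != "AMG":
            continue
        out.append(validate_context(g, by_contig[g.contig_id], hallmark_gene_ids,
                                    params, input_flags))
    return out


@dataclass
class AMGGroupComparison:
    """Per-sample AMG profile plus clean-vs-contaminated test statistics."""

    per_sample: pd.DataFrame
    tpm_rank_sum: tuple[float, float] | None        # (statistic, p)
    diversity_rank_sum: tuple[float, float] | None
    detection_fisher: tuple[float, float] | None    # (odds ratio, p)


def amg_abundance(gene_classes: Sequence[GeneClass],
                  tpm: pd.DataFrame,
                  groups: Mapping[str, str],
                  params: Parameters | None = None) -> AMGGroupComparison:
    """Per-sample AMG diversity (distinct categories detected) and summed TPM,
    with clean vs contaminated (light+heavy pooled) comparisons.

    Rank-sum tests (exact where possible) compare summed TPM and category
    diversity; a Fisher exact 2x2 compares AMG gene detection counts.
    ``log10(x + pseudocount)`` columns are provided for display parity.
    """
    params = params or Parameters()
    amg = {gc.gene_id: gc.amg_category for gc in gene_classes if gc.klass == "AMG"}
    amg_cols = [c for c in tpm.columns if c in amg]
    rows = []
    for sample in tpm.index:
        present = [c for c in amg_cols if tpm.loc[sample, c] > 0]
        rows.append({
            "sample_id": sample,
            "group": groups.get(sample, ""),
            "amg_category_diversity": len({amg[c] for c in present}),
            "amg_gene_richness": len(present),
            "amg_tpm_sum": float(tpm.loc[sample, amg_cols].sum()) if amg_cols else 0.0,
        })
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    per_sample["log10_amg_tpm_sum"] = np.log10(
        per_sample["amg_tpm_sum"] + params.amg_pseudocount)

    clean = per_sample[per_sample["group"] == "clean"]
    contam = per_sample[per_sample["group"].isin(["light", "heavy"])]
    if len(clean) < 2 or len(contam) < 2:
        warnings.warn("a group has fewer than 2 samples; tests skipped", stacklevel=2)
        return AMGGroupComparison(per_sample, None, None, None)

    def ranksum(col):
        res = stats.mannwhitneyu(contam[col], clean[col], alternative="two-sided")
        return float(res.statistic), float(res.pvalue)

    tpm_rs = ranksum("amg_tpm_sum")
    div_rs = ranksum("amg_category_diversity")
    detected_clean = sum((tpm.loc[clean.index, c] > 0).any() for c in amg_cols)
    detected_contam = sum((tpm.loc[contam.index, c] > 0).any() for c in amg_cols)
    n_amg = len(amg_cols)
    table = [[detected_contam, n_amg - detected_contam],
             [detected_clean, n_amg - detected_clean]]
    odds, p = stats.fisher_exact(table)
    return AMGGroupComparison(per_sample, tpm_rs, div_rs, (float(odds), float(p)))


def cooccurrence_network(tpm: pd.DataFrame, params: Parameters | None = None) -> pd.DataFrame:
    """Pearson co-occurrence edges between features across samples.

    Edge iff |r| strictly exceeds ``pearson_r_threshold`` and the two-sided
    p-value (t distribution, df = n_samples - 2) is below
    ``pearson_p_threshold``. Constant features are excluded. Returns a
    DataFrame with columns feature_a, feature_b, r, p.
    """
    params = params or Parameters()
    n = len(tpm.index)
    if n < 3:
        raise ValueError("co-occurrence network needs at least 3 samples")
    values = tpm.to_numpy(dtype=float)
    keep = values.std(axis=0) > 0
    feats = [f for f, k in zip(tpm.columns, keep) if k]
    x = values[:, keep]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    rows = []
    m = len(feats)
    iu = np.triu_indices(m, k=1)
    pvals = p[iu]
    if params.cooccurrence_bh_correct and len(pvals):
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(pvals)
        out[order] = np.minimum(adj, 1.0)
        pvals = out
    for (i, j, pv) in zip(iu[0], iu[1], pvals):
        if abs(r[i, j]) > params.pearson_r_threshold and pv < params.pearson_p_threshold:
            rows.append({"feature_a": feats[i], "feature_b": feats[j],
                         "r": float(r[i, j]), "p": float(pv)})
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p"])
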