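"""End-to-end orchestration of the mining pipeline over one dataset."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import amg as amg_mod
from . import io_formats as io
from . import stats as stats_mod
from .cluster import VOTUCluster, greedy_cluster, select_long
from .hostlink import HostLink, LinkTopology, classify_topology, match_spacers, match_trna
from .params import Parameters
from .screen import ScreenDecision, build_profiles, screen
from .synthetic import SyntheticDataset
from .taxonomy import TaxonomyCall, propagate_by_vc, vote_family

__all__ = ["PipelineResult", "run_pipeline", "load_dataset"]


@dataclass
class PipelineResult:
    decisions: list[ScreenDecision]
    votus: list[VOTUCluster]
    long_votus: list[VOTUCluster]
    taxonomy: list[TaxonomyCall]
    links: list[HostLink]
    orphan_links: list[HostLink]
    topology: LinkTopology
    gene_classes: list
    amg_validations: list
    amg_comparison: amg_mod.AMGGroupComparison
    cooccurrence_edges: pd.DataFrame
    gene_tpm: pd.DataFrame
    alpha_bacteria: pd.DataFrame
    alpha_viral: pd.DataFrame
    bray_curtis_viral: pd.DataFrame
    upgma_newick: str
    network: stats_mod.NetworkStats


def load_dataset(indir: str | Path) -> SyntheticDataset:
    """Read a dataset directory written by :meth:`SyntheticDataset.write`."""
    indir = Path(indir)
    meta = io.read_contig_meta(indir / "contig_meta.tsv")
    contigs = io.read_fasta(indir / "contigs.fasta", meta=meta)
    lengths = {c.contig_id: len(c) for c in contigs}
    sample_groups = dict(
        pd.read_csv(indir / "sample_groups.tsv", sep="\t").values)
    gene_lengths = {
        r.gene_id: int(r.length_bp)
        for r in pd.read_csv(indir / "gene_lengths.tsv", sep="\t").itertuples()}
    return SyntheticDataset(
        contigs=contigs,
        genes=io.read_gene_table(indir / "genes.tsv", contig_lengths=lengths),
        hits=io.read_hit_table(indir / "hits.tsv"),
        arrays=io.read_crispr_table(indir / "crispr.tsv"),
        trnas=io.read_trna_table(indir / "trnas.tsv"),
        host_taxonomy=io.read_taxon_table(indir / "host_taxonomy.tsv"),
        vc_membership=io.read_vc_table(indir / "vc_membership.tsv"),
        counts_bacteria=io.read_count_table(indir / "counts_bacteria.tsv"),
        counts_viral=io.read_count_table(indir / "counts_viral.tsv"),
        counts_genes=io.read_count_table(indir / "counts_genes.tsv"),
        gene_lengths=gene_lengths,
        sample_groups=sample_groups,
    )


def run_pipeline(dataset: SyntheticDataset,
                 params: Parameters | None = None) -> PipelineResult:
    params = params or Parameters()
    viral = dataset.viral_contigs
    hosts = dataset.host_contigs

    profiles = build_profiles(viral, dataset.genes, dataset.hits)
    decisions = screen(viral, profiles, params)
    retained_ids = {d.contig_id for d in decisions if d.retained}
    retained = [c for c in viral if c.contig_id in retained_ids]

    votus = greedy_cluster(retained, params)
    long_votus = select_long(votus, retained, params)
    calls = [vote_family(v, dataset.genes, dataset.hits, params) for v in votus]
    calls = propagate_by_vc(calls, votus, dataset.vc_membership, params)

    trna_links = match_trna(dataset.trnas, hosts, dataset.host_taxonomy, params)
    crispr_links, orphans = match_spacers(dataset.arrays, retained, hosts,
                                          dataset.host_taxonomy, params)
    links = trna_links + crispr_links
    topology = classify_topology(links)

    gene_classes = amg_mod.classify_genes(dataset.genes, dataset.hits,
                                          params=params)
    validations = amg_mod.validate_all(dataset.genes, gene_classes,
                                       dataset.hits, params)
    gene_tpm = stats_mod.tpm(dataset.counts_genes, dataset.gene_lengths, params)
    comparison = amg_mod.amg_abundance(gene_classes, gene_tpm,
                                       dataset.sample_groups, params)
    edges_df = amg_mod.cooccurrence_network(gene_tpm, params)

    alpha_b = stats_mod.alpha_diversity(dataset.counts_bacteria, params)
    alpha_v = stats_mod.alpha_diversity(dataset.counts_viral, params)
    bc = stats_mod.bray_curtis(dataset.counts_viral)
    newick = stats_mod.upgma(bc)
    net = stats_mod.network_stats(
        list(zip(edges_df["feature_a"], edges_df["feature_b"])))

    return PipelineResult(
        decisions=decisions, votus=votus, long_votus=long_votus,
        taxonomy=calls, links=links, orphan_links=orphans, topology=topology,
        gene_classes=gene_classes, amg_validations=validations,
        amg_comparison=comparison, cooccurrence_edges=edges_df,
        gene_tpm=gene_tpm, alpha_bacteria=alpha_b, alpha_viral=alpha_v,
        bray_curtis_viral=bc, upgma_newick=newick, network=net,
    )
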