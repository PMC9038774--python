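"""Synthetic soil-community generator with planted ground truth.

The generator emulates the structure of a clean vs pesticide-contaminated
soil study: three clean samples (C1-C3) and six contaminated samples, three
lightly (S1-S3) and three heavily (S4-S6) contaminated. It emits every input
the pipeline consumes — contigs, gene calls, annotation hit tables, CRISPR
arrays, tRNA entries, viral-cluster membership, host taxonomy and per-sample
count tables — together with a :class:`GroundTruth` record of everything that
was planted, so every downstream stage can be tested end to end.

Planted structure:

* viral lineages: a random ancestor plus variants derived by point mutations
  only (no indels), so pairwise identity to the ancestor is exactly
  ``1 - mutations/length`` and the expected vOTU partition is closed-form;
* genomes laid out as hallmark-rich gene maps with core (Xr/Xs) genes and,
  on designated lineages, one AMG flanked by hallmark genes on both sides;
* CRISPR arrays embedded in bacterial host contigs whose spacers copy a
  protospacer from a linked viral contig at 0 or 1 mismatches (2-mismatch
  negative plants are recorded as non-links);
* shared exact tRNA substrings for tRNA-evidence links;
* per-sample counts with multiplicative group effects: bacterial richness
  drop, clean-sample bacterial dominance (evenness contrast), viral richness
  gain and an AMG abundance multiplier increasing with contamination
  severity.

The same seed always produces the identical dataset.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io_formats as io
from .io_formats import AnnotationHit, Contig, CrisprArray, GeneRecord, TrnaEntry
from .params import Parameters

__all__ = ["SynthDesign", "ContaminationEffects", "GroundTruth",
           "SyntheticDataset", "simulate", "perturb"]

_BASES = np.array(list("ACGT"))
_FAMILIES = ("Siphoviridae", "Podoviridae", "Myoviridae", "Microviridae",
             "Inoviridae")
_AMG_PLANT_FAMILIES = (  # (Pfam family, category) drawn from the shipped list
    ("HAD_2", "pesticide"), ("ALDH", "pesticide"), ("GH13", "C"),
    ("NorD", "N"), ("CysH", "S"), ("PhoD", "P"),
)

GENE_LEN_BP = 240
GENE_STRIDE_BP = 250


@dataclass(frozen=True)
class ContaminationEffects:
    """Multiplicative group effects planted into the count tables.

    ``bacterial_richness_drop`` is the fraction of bacterial taxa absent from
    each contaminated sample; ``viral_richness_gain`` multiplies the baseline
    fraction of viral lineages present in a sample; ``amg_tpm_multiplier``
    scales AMG gene counts in heavily contaminated samples (light samples get
    the square root); ``bacterial_dominance_factor`` boosts one taxon in
    clean samples, lowering clean evenness.
    """

    bacterial_richness_drop: float = 0.4
    viral_richness_gain: float = 1.6
    amg_tpm_multiplier: float = 4.0
    bacterial_dominance_factor: float = 8.0

    def __post_init__(self):
        if not 0.0 <= self.bacterial_richness_drop < 1.0:
            raise ValueError("bacterial_richness_drop must lie in [0, 1)")
        for name in ("viral_richness_gain", "amg_tpm_multiplier",
                     "bacterial_dominance_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SynthDesign:
    """Study design of one synthetic dataset (all defaults are the baseline
    study conditions; the same seed yields a byte-identical dataset)."""

    n_samples_per_group: int = 3
    n_viral_lineages: int = 12
    variants_per_lineage: int = 3            # contigs per lineage incl. ancestor
    variant_identity_levels: tuple[float, ...] = (0.97,)
    lineage_len_bp: int = 2000
    n_long_lineages: int = 2                 # lineages above the 5 kb screen gate
    long_lineage_len_bp: int = 6000
    n_bacterial_taxa: int = 8
    host_contig_len_bp: int = 6000
    n_screen_fail_decoys: int = 2            # >5 kb, viral category, criteria fail
    n_category_fail_decoys: int = 2          # VirSorter category 3
    amg_lineage_fraction: float = 0.5        # lineages carrying a planted AMG
    amg_insertion_rate: Mapping[str, float] = field(
        default_factory=lambda: {"clean": 0.4, "light": 0.75, "heavy": 0.9})
    base_viral_presence: float = 0.5
    vc_size: int = 3
    plant_unannotated: bool = True           # one lineage per VC lacks direct hits
    n_trna_links: int = 2
    n_crispr_links: int = 3
    crispr_mismatches: tuple[int, ...] = (0, 1)
    n_crispr_negative: int = 1               # 2-mismatch plants that must NOT link
    spacer_len_nt: int = 32
    repeat_len_nt: int = 28
    trna_len_nt: int = 75
    abundance_mu: float = 3.0
    abundance_sigma: float = 0.5
    contamination_effects: ContaminationEffects = field(
        default_factory=ContaminationEffects)
    rng_seed: int = 0

    def validate(self, params: Parameters) -> None:
        for lvl in self.variant_identity_levels:
            if not 0.0 < lvl <= 1.0:
                raise ValueError(f"identity level {lvl} outside (0, 1]")
            if round((1.0 - lvl) * self.lineage_len_bp) > self.lineage_len_bp:
                raise ValueError("variant identity below mutation budget")
        for L in (self.lineage_len_bp, self.long_lineage_len_bp):
            if L // GENE_STRIDE_BP < 6:
                raise ValueError(f"lineage length {L} too short for a gene layout")
        if self.spacer_len_nt < params.spacer_min_len_nt:
            raise ValueError("planted spacers shorter than spacer_min_len_nt")
        if self.repeat_len_nt < params.min_repeat_len_nt:
            raise ValueError("planted repeats shorter than min_repeat_len_nt")
        if self.trna_len_nt < params.min_trna_len_nt:
            raise ValueError("planted tRNAs shorter than min_trna_len_nt")
        n_slots = self.n_trna_links + self.n_crispr_links + self.n_crispr_negative
        slot = self.trna_len_nt + 3 * self.repeat_len_nt + 2 * self.spacer_len_nt
        if self.host_contig_len_bp < 200 + n_slots * (slot + 50):
            raise ValueError("host contigs too short for the planted arrays")
        if not 0 <= self.amg_lineage_fraction <= 1:
            raise ValueError("amg_lineage_fraction must lie in [0, 1]")
        n_plants = self.n_crispr_links + self.n_crispr_negative
        proto_end = 10 + n_plants * (self.spacer_len_nt + 10)
        if proto_end > self.lineage_len_bp - self.trna_len_nt - 40:
            raise ValueError("too many CRISPR plants for the lineage length")


@dataclass
class GroundTruth:
    """Everything planted, keyed the way the consumer modules report it."""

    votu_partition: dict[str, str]
    taxonomy: dict[str, dict]            # lineage -> {family, tier}
    links: list[dict]
    negative_links: list[dict]
    amg_genes: dict[str, dict]           # gene_id -> {category, flags, flanked}
    screen_truth: dict[str, bool]
    abundance_expectations: dict

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    contigs: list[Contig]
    genes: list[GeneRecord]
    hits: list[AnnotationHit]
    arrays: list[CrisprArray]
    trnas: list[TrnaEntry]
    host_taxonomy: dict[str, str]
    vc_membership: dict[str, str]
    counts_bacteria: pd.DataFrame
    counts_viral: pd.DataFrame
    counts_genes: pd.DataFrame
    gene_lengths: dict[str, int]
    sample_groups: dict[str, str]

    @property
    def viral_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if c.virsorter_category is not None]

    @property
    def host_contigs(self) -> list[Contig]:
        return [c for c in self.contigs if c.contig_id in self.host_taxonomy]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.contigs, outdir / "contigs.fasta")
        io.write_contig_meta(self.contigs, outdir / "contig_meta.tsv")
        io.write_gene_table(self.genes, outdir / "genes.tsv")
        io.write_hit_table(self.hits, outdir / "hits.tsv")
        io.write_crispr_table(self.arrays, outdir / "crispr.tsv")
        io.write_trna_table(self.trnas, outdir / "trnas.tsv")
        io.write_taxon_table(self.host_taxonomy, outdir / "host_taxonomy.tsv")
        io.write_vc_table(self.vc_membership, outdir / "vc_membership.tsv")
        io.write_count_table(self.counts_bacteria, outdir / "counts_bacteria.tsv")
        io.write_count_table(self.counts_viral, outdir / "counts_viral.tsv")
        io.write_count_table(self.counts_genes, outdir / "counts_genes.tsv")
        pd.DataFrame(sorted(self.gene_lengths.items()),
                     columns=["gene_id", "length_bp"]) \
            .to_csv(outdir / "gene_lengths.tsv", sep="\t", index=False)
        pd.DataFrame(sorted(self.sample_groups.items()),
                     columns=["sample_id", "group"]) \
            .to_csv(outdir / "sample_groups.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Exactly ``n_mut`` substitutions at distinct positions, never to the
    same base and never to N, so identity to ``seq`` is 1 - n_mut/len."""
    arr = np.array(list(seq))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _mismatch_copy(rng: np.random.Generator, seq: str, n_mismatch: int) -> str:
    return _mutate(rng, seq, n_mismatch) if n_mismatch else seq


def _gene_layout(n_genes: int, carries_amg: bool) -> list[str]:
    """Hallmark-rich layout: Xr near the start, Xs near the end, optionally
    one AMG in the middle flanked by hallmark genes on both sides."""
    roles = ["hallmark"] * n_genes
    roles[1] = "core_Xr"
    roles[n_genes - 3] = "core_Xs"
    mid = n_genes // 2
    roles[mid] = "amg" if carries_amg else "other"
    return roles


def _annotate_contig(contig_id: str, length: int, roles: Sequence[str],
                     family: str | None, amg_plant: tuple[str, str] | None,
                     genes: list, hits: list, index_offset: int = 0) -> dict:
    """Emit gene records and annotation hits for one viral contig; returns
    the planted-AMG record (or {})."""
    amg_record: dict = {}
    n = len(roles)
    n_family = math.ceil(0.6 * n) if family else 0
    for i, role in enumerate(roles):
        gid = f"{contig_id}_g{i}"
        pid = f"{contig_id}_p{i}"
        start = 1 + i * GENE_STRIDE_BP
        genes.append(GeneRecord(gid, contig_id, i, start,
                                start + GENE_LEN_BP - 1, "+", pid))
        if role == "hallmark":
            hits.append(AnnotationHit(pid, "VPF", f"VPF_{i:05d}", "hallmark"))
            hits.append(AnnotationHit(pid, "VOG", f"VOG{i:05d}", "hallmark"))
        elif role == "core_Xr":
            hits.append(AnnotationHit(pid, "VOG", f"VOG{i:05d}", "Xr"))
        elif role == "core_Xs":
            hits.append(AnnotationHit(pid, "VOG", f"VOG{i:05d}", "Xs"))
        elif role == "amg":
            pfam, category = amg_plant
            hits.append(AnnotationHit(pid, "PFAM", pfam, pfam))
            hits.append(AnnotationHit(pid, "KO", f"K{10000 + i}", "metabolism"))
            hits.append(AnnotationHit(pid, "AMG_FLAG", "M", "M"))
            amg_record = {"gene_id": gid, "contig_id": contig_id,
                          "category": category, "flags": ["M"],
                          "flanked": True}
        if family and i < n_family:
            hits.append(AnnotationHit(pid, "REFSEQ_FAMILY", f"ref_{family}",
                                      family, 80.0))
    return amg_record


# ---------------------------------------------------------------------------
# main generator

def simulate(design: SynthDesign,
             params: Parameters | None = None) -> tuple[SyntheticDataset, GroundTruth]:
    """Generate one complete dataset plus its ground truth."""
    params = params or Parameters()
    design.validate(params)
    rng = np.random.default_rng(design.rng_seed)
    eff = design.contamination_effects

    nspg = design.n_samples_per_group
    samples = ([f"C{i + 1}" for i in range(nspg)]
               + [f"S{i + 1}" for i in range(2 * nspg)])
    sample_groups = {s: "clean" for s in samples[:nspg]}
    sample_groups.update({s: "light" for s in samples[nspg:2 * nspg]})
    sample_groups.update({s: "heavy" for s in samples[2 * nspg:]})

    contigs: list[Contig] = []
    genes: list[GeneRecord] = []
    hits: list[AnnotationHit] = []
    votu_partition: dict[str, str] = {}
    screen_truth: dict[str, bool] = {}
    amg_genes: dict[str, dict] = {}
    taxonomy: dict[str, dict] = {}
    vc_membership: dict[str, str] = {}

    # --- viral lineages -------------------------------------------------
    lineage_ids = [f"L{i:03d}" for i in range(design.n_viral_lineages)]
    # tRNAs are planted into the ancestor BEFORE variants are derived, so the
    # analytic variant identity 1 - mutations/length stays exact
    trna_plants: dict[int, str] = {}
    for t in range(design.n_trna_links):
        li = t % design.n_viral_lineages
        if li not in trna_plants:
            trna_plants[li] = _random_seq(rng, design.trna_len_nt)
    ancestor_seq: dict[str, str] = {}
    lineage_sample: dict[str, str] = {}
    lineage_family: dict[str, str] = {}
    lineage_has_amg: dict[str, bool] = {}
    n_amg_planted = 0  # rank among AMG-carrying lineages, cycles the family list

    for i, lid in enumerate(lineage_ids):
        L = (design.long_lineage_len_bp if i < design.n_long_lineages
             else design.lineage_len_bp)
        seq = _random_seq(rng, L)
        if i in trna_plants:
            pos = L - design.trna_len_nt - 20
            seq = (seq[:pos] + trna_plants[i]
                   + seq[pos + design.trna_len_nt:])
        ancestor_seq[lid] = seq
        sample = samples[i % len(samples)]
        lineage_sample[lid] = sample
        vc = f"VC_{i // design.vc_size:03d}"
        lineage_family[lid] = _FAMILIES[(i // design.vc_size) % len(_FAMILIES)]
        lineage_has_amg[lid] = i % max(1, round(1 / design.amg_lineage_fraction)) == 0 \
            if design.amg_lineage_fraction > 0 else False
        # the last lineage of each full VC is left without direct hits so the
        # VC-propagation tier has planted truth
        is_unannotated = (design.plant_unannotated
                          and i % design.vc_size == design.vc_size - 1)
        n_genes = L // GENE_STRIDE_BP
        roles = _gene_layout(n_genes, lineage_has_amg[lid])
        # cycle the curated family list over AMG-carrying lineages only
        amg_plant = _AMG_PLANT_FAMILIES[n_amg_planted % len(_AMG_PLANT_FAMILIES)]
        if lineage_has_amg[lid]:
            n_amg_planted += 1
        group = sample_groups[sample]
        category = (1, 2, 4, 5)[i % 4]
        for j in range(design.variants_per_lineage):
            cid = f"{lid}_v{j:02d}"
            if j == 0:
                vseq, identity = seq, 1.0
            else:
                lvl = design.variant_identity_levels[
                    (j - 1) % len(design.variant_identity_levels)]
                n_mut = round((1.0 - lvl) * L)
                vseq = _mutate(rng, seq, n_mut)
                identity = 1.0 - n_mut / L
            contigs.append(Contig(cid, vseq, sample, group, category))
            votu_partition[cid] = (lid if identity >= params.votu_min_identity
                                   else cid)
            screen_truth[cid] = True  # viral category; short ones pass the gate,
            # long ones meet criterion 1/2/3 by construction
            rec = _annotate_contig(cid, L, roles,
                                   None if is_unannotated else lineage_family[lid],
                                   amg_plant, genes, hits)
            if rec:
                amg_genes[rec["gene_id"]] = {k: v for k, v in rec.items()
                                             if k != "gene_id"}
        vc_membership[f"{lid}_v00"] = vc
        taxonomy[lid] = {"family": lineage_family[lid],
                         "tier": "propagated" if is_unannotated else "direct"}

    # lineages whose VC has no directly annotated member stay unassigned
    vc_direct = {}
    for lid in lineage_ids:
        if taxonomy[lid]["tier"] == "direct":
            vc_direct.setdefault(vc_membership[f"{lid}_v00"], []).append(lid)
    for lid in lineage_ids:
        if taxonomy[lid]["tier"] == "propagated":
            vc = vc_membership[f"{lid}_v00"]
            if vc not in vc_direct:
                taxonomy[lid] = {"family": "Unassigned", "tier": "unassigned"}

    # --- screening decoys -----------------------------------------------
    for i in range(design.n_screen_fail_decoys):
        cid = f"DF{i:02d}"
        L = design.long_lineage_len_bp
        contigs.append(Contig(cid, _random_seq(rng, L), samples[i % len(samples)],
                              sample_groups[samples[i % len(samples)]], 1))
        n_genes = L // GENE_STRIDE_BP
        for g in range(n_genes):
            gid, pid = f"{cid}_g{g}", f"{cid}_p{g}"
            start = 1 + g * GENE_STRIDE_BP
            genes.append(GeneRecord(gid, cid, g, start, start + GENE_LEN_BP - 1,
                                    "+", pid))
            hits.append(AnnotationHit(pid, "PFAM", f"PF{g:05d}", "housekeeping"))
            if g % 2 == 0:
                hits.append(AnnotationHit(pid, "KO", f"K{g:05d}", "metabolism"))
        votu_partition[cid] = cid
        screen_truth[cid] = False
    for i in range(design.n_category_fail_decoys):
        cid = f"DC{i:02d}"
        contigs.append(Contig(cid, _random_seq(rng, design.lineage_len_bp),
                              samples[i % len(samples)],
                              sample_groups[samples[i % len(samples)]], 3))
        votu_partition[cid] = cid
        screen_truth[cid] = False

    # --- bacterial hosts and planted links -------------------------------
    taxa = [f"Taxon_{i:02d}" for i in range(design.n_bacterial_taxa)]
    host_ids = [f"B{i:02d}" for i in range(design.n_bacterial_taxa)]
    host_taxonomy = dict(zip(host_ids, taxa))
    host_seq = {h: _random_seq(rng, design.host_contig_len_bp) for h in host_ids}
    host_cursor = {h: 100 for h in host_ids}

    def _embed(host: str, fragment: str) -> int:
        """Overwrite a slice of the host contig at the next free slot."""
        pos = host_cursor[host]
        if pos + len(fragment) > len(host_seq[host]) - 50:
            raise ValueError(f"host contig {host} out of planting room")
        s = host_seq[host]
        host_seq[host] = s[:pos] + fragment + s[pos + len(fragment):]
        host_cursor[host] = pos + len(fragment) + 50
        return pos

    links: list[dict] = []
    negative_links: list[dict] = []
    trnas: list[TrnaEntry] = []
    arrays: list[CrisprArray] = []
    link_no = 0

    def _next_pair(k: int) -> tuple[str, str]:
        return (lineage_ids[k % len(lineage_ids)], host_ids[k % len(host_ids)])

    for t in range(design.n_trna_links):
        lid, host = _next_pair(link_no)
        link_no += 1
        virus = f"{lid}_v00"
        trna = trna_plants[lineage_ids.index(lid)]
        _embed(host, trna)
        trnas.append(TrnaEntry(virus, trna))
        links.append({"virus_contig_id": virus, "host_taxon": host_taxonomy[host],
                      "host_contig_id": host, "evidence": "tRNA", "mismatches": 0})

    crispr_plants = ([design.crispr_mismatches[i % len(design.crispr_mismatches)]
                      for i in range(design.n_crispr_links)]
                     + [2] * design.n_crispr_negative)
    for a, mm in enumerate(crispr_plants):
        lid, host = _next_pair(link_no)
        link_no += 1
        virus = f"{lid}_v00"
        vseq = ancestor_seq[lid]
        proto_pos = 10 + a * (design.spacer_len_nt + 10)
        protospacer = vseq[proto_pos:proto_pos + design.spacer_len_nt]
        spacer = _mismatch_copy(rng, protospacer, mm)
        repeat = _random_seq(rng, design.repeat_len_nt)
        decoy_spacer = _random_seq(rng, design.spacer_len_nt)
        _embed(host, repeat + spacer + repeat + decoy_spacer + repeat)
        arrays.append(CrisprArray(host, f"{host}_arr{a}", repeat,
                                  (spacer, decoy_spacer)))
        rec = {"virus_contig_id": virus, "host_taxon": host_taxonomy[host],
               "host_contig_id": host, "evidence": "CRISPR", "mismatches": mm}
        (links if mm <= params.spacer_max_mismatch else negative_links).append(rec)

    for h in host_ids:
        contigs.append(Contig(h, host_seq[h], samples[0], "clean", None))
        votu_partition[h] = h
        screen_truth[h] = False

    # --- abundance tables -------------------------------------------------
    def _lognormal_counts(shape) -> np.ndarray:
        lam = rng.lognormal(design.abundance_mu, design.abundance_sigma, shape)
        return rng.poisson(lam)

    severity = {"clean": 0.0, "light": 0.5, "heavy": 1.0}

    bact = _lognormal_counts((len(samples), len(taxa))).astype(float)
    n_drop = round(eff.bacterial_richness_drop * len(taxa))
    for si, s in enumerate(samples):
        if sample_groups[s] == "clean":
            bact[si, 0] *= eff.bacterial_dominance_factor
        elif n_drop:
            drop = rng.choice(len(taxa), size=n_drop, replace=False)
            bact[si, drop] = 0.0
    counts_bacteria = pd.DataFrame(bact.astype(int), index=samples, columns=taxa)

    vir = _lognormal_counts((len(samples), len(lineage_ids))).astype(float)
    for si, s in enumerate(samples):
        presence = design.base_viral_presence
        if sample_groups[s] != "clean":
            presence = min(1.0, presence * eff.viral_richness_gain)
        n_present = round(presence * len(lineage_ids))
        absent = rng.choice(len(lineage_ids),
                            size=len(lineage_ids) - n_present, replace=False)
        vir[si, absent] = 0.0
    counts_viral = pd.DataFrame(vir.astype(int), index=samples,
                                columns=lineage_ids)

    gene_features = [g.gene_id for g in genes if g.contig_id.endswith("_v00")]
    gene_lengths = {g.gene_id: g.end - g.start + 1 for g in genes}
    amg_feature = {gid: gid in amg_genes for gid in gene_features}
    gmat = _lognormal_counts((len(samples), len(gene_features))).astype(float)
    for si, s in enumerate(samples):
        group = sample_groups[s]
        mult = eff.amg_tpm_multiplier ** severity[group]
        rate = design.amg_insertion_rate[group]
        for gi, gid in enumerate(gene_features):
            if amg_feature[gid]:
                if rng.random() > rate:
                    gmat[si, gi] = 0.0
                else:
                    gmat[si, gi] *= mult
    counts_genes = pd.DataFrame(gmat.astype(int), index=samples,
                                columns=gene_features)

    dataset = SyntheticDataset(
        contigs=contigs, genes=genes, hits=hits, arrays=arrays, trnas=trnas,
        host_taxonomy=host_taxonomy, vc_membership=vc_membership,
        counts_bacteria=counts_bacteria, counts_viral=counts_viral,
        counts_genes=counts_genes, gene_lengths=gene_lengths,
        sample_groups=sample_groups,
    )
    truth = GroundTruth(
        votu_partition=votu_partition,
        taxonomy=taxonomy,
        links=links,
        negative_links=negative_links,
        amg_genes=amg_genes,
        screen_truth=screen_truth,
        abundance_expectations={
            "bacterial_richness": "clean>contaminated",
            "viral_richness": "contaminated>clean",
            "bacterial_pielou": "contaminated>clean",
            "amg_tpm_sum": "contaminated>clean",
            "amg_category_diversity": "contaminated>clean",
            "effects": dataclasses.asdict(eff),
        },
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# negative-control perturbations

PERTURB_OPS = ("shuffle_labels", "scramble_spacers", "strip_hallmarks")


def perturb(dataset: SyntheticDataset, op: str,
            seed: int = 0) -> SyntheticDataset:
    """Destroy one planted structure, leaving everything else unchanged."""
    if op not in PERTURB_OPS:
        raise ValueError(f"unknown perturbation {op!r}; choose from {PERTURB_OPS}")
    rng = np.random.default_rng(seed)
    out = dataclasses.replace(dataset)
    if op == "shuffle_labels":
        sample_ids = list(dataset.sample_groups)
        shuffled = [dataset.sample_groups[s] for s in sample_ids]
        rng.shuffle(shuffled)
        out.sample_groups = dict(zip(sample_ids, shuffled))
    elif op == "scramble_spacers":
        out.arrays = [
            CrisprArray(a.host_contig_id, a.array_id, a.repeat_seq,
                        tuple(_random_seq(rng, len(s)) for s in a.spacers))
            for a in dataset.arrays
        ]
    elif op == "strip_hallmarks":
        out.hits = [
            h for h in dataset.hits
            if h.database != "VPF"
            and not (h.database == "VOG" and "hallmark" in h.label)
        ]
    return out
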