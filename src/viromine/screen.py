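"""Viral contig screening.

A contig is first gated on its VirSorter confidence category (1, 2, 4, 5 are
accepted as viral). Contigs longer than the 5 kb gate are then checked against
three annotation-composition criteria:

* c1 — at least 5 genes with viral-protein-family (VPF) hits, while the
  fraction of KO-annotated genes is strictly below 20% and the fraction of
  Pfam-annotated genes is at most 40%;
* c2 — at least as many VPF-annotated genes as Pfam-annotated genes;
* c3 — VPF-annotated genes reach 60% of all genes.

With the default ``retain_if_any`` polarity a long contig is kept when it
meets at least one criterion; ``discard_if_any`` inverts that reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import AnnotationHit, Contig, GeneRecord
from .params import Parameters

__all__ = ["ScreenProfile", "ScreenDecision", "build_profiles",
           "evaluate_criteria", "screen"]


@dataclass(frozen=True)
class ScreenProfile:
    """Per-contig annotation composition used by the filter criteria."""

    contig_id: str
    n_genes: int
    n_genes_vpf: int
    n_genes_ko: int
    n_genes_pfam: int
    length_bp: int

    def __post_init__(self):
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for f in ("n_genes_vpf", "n_genes_ko", "n_genes_pfam"):
            v = getattr(self, f)
            if not 0 <= v <= self.n_genes:
                raise ValueError(f"{f}={v} outside 0..n_genes={self.n_genes}")


@dataclass(frozen=True)
class ScreenDecision:
    contig_id: str
    category_pass: bool
    c1: bool
    c2: bool
    c3: bool
    retained: bool
    reason: str


def build_profiles(contigs: Iterable[Contig], genes: Iterable[GeneRecord],
                   hits: Iterable[AnnotationHit]) -> dict[str, ScreenProfile]:
    """Assemble ScreenProfiles from gene calls and annotation hits.

    "Hits to viral protein families" are counted as genes with >=1 VPF hit
    (not raw hit rows), matching the gene-covered counting of the KO and Pfam
    quantities.
    """
    hit_dbs: dict[str, set[str]] = {}
    for h in hits:
        hit_dbs.setdefault(h.protein_id, set()).add(h.database)
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    profiles = {}
    for c in contigs:
        gs = by_contig.get(c.contig_id, [])
        dbs = [hit_dbs.get(g.protein_id, set()) for g in gs]
        profiles[c.contig_id] = ScreenProfile(
            contig_id=c.contig_id,
            n_genes=len(gs),
            n_genes_vpf=sum("VPF" in d for d in dbs),
            n_genes_ko=sum("KO" in d for d in dbs),
            n_genes_pfam=sum("PFAM" in d for d in dbs),
            length_bp=len(c),
        )
    return profiles


def evaluate_criteria(profile: ScreenProfile,
                      params: Parameters) -> tuple[bool, bool, bool]:
    """Evaluate the three filter criteria; fractions on a zero-gene contig
    are defined as 0."""
    n = profile.n_genes
    ko_frac = profile.n_genes_ko / n if n else 0.0
    pfam_frac = profile.n_genes_pfam / n if n else 0.0
    c1 = (profile.n_genes_vpf >= params.min_vpf_hits
          and ko_frac < params.max_ko_fraction
          and pfam_frac <= params.max_pfam_fraction)
    c2 = profile.n_genes_vpf >= profile.n_genes_pfam
    c3 = profile.n_genes_vpf >= params.vpf_total_fraction * n
    return c1, c2, c3


def screen(contigs: Sequence[Contig],
           profiles: Mapping[str, ScreenProfile],
           params: Parameters,
           polarity: str | None = None) -> list[ScreenDecision]:
    """Emit a retention decision for every input contig."""
    polarity = polarity or params.screen_polarity
    if polarity not in ("retain_if_any", "discard_if_any"):
        raise ValueError(f"unknown polarity {polarity!r}")
    decisions = []
    for contig in contigs:
        profile = profiles.get(contig.contig_id)
        if profile is None:
            raise KeyError(f"no screen profile for contig {contig.contig_id}")
        c1, c2, c3 = evaluate_criteria(profile, params)
        category_pass = (contig.virsorter_category in params.kept_categories)
        if len(contig) < params.min_contig_len_bp:
            decisions.append(ScreenDecision(contig.contig_id, category_pass,
                                            c1, c2, c3, False, "below_min_length"))
            continue
        if not category_pass:
            retained, reason = False, "category_fail"
        elif len(contig) <= params.screen_len_gate_bp:
            retained, reason = True, "category_pass_short"
        else:
            any_criterion = c1 or c2 or c3
            keep = any_criterion if polarity == "retain_if_any" else not any_criterion
            retained = keep
            reason = ("criteria_pass" if keep else "criteria_fail")
        decisions.append(ScreenDecision(contig.contig_id, category_pass,
                                        c1, c2, c3, retained, reason))
    return decisions
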