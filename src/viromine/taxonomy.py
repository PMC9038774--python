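"""Majority-rules viral family assignment.

Each protein on a vOTU's member contigs casts at most one vote: its
best-bitscore RefSeq family among hits with bitscore >= 50 (a bitscore tie
between different families discards the vote). A family is adopted iff its
votes exceed 50% of the vOTU's proteins — strictly, so an exact 50% split
stays Unassigned. vOTUs left unassigned can adopt the majority family of
their viral cluster (VC), computed over the VC's directly-assigned members
only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .cluster import VOTUCluster
from .io_formats import AnnotationHit, GeneRecord
from .params import Parameters

__all__ = ["TaxonomyCall", "UNASSIGNED", "vote_family", "propagate_by_vc"]

UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class TaxonomyCall:
    votu_id: str
    family: str
    support: float
    tier: str  # direct | propagated | unassigned


def _protein_vote(hits: Sequence[AnnotationHit], min_bitscore: float) -> str | None:
    """Best family by bitscore; None when no qualifying hit or a cross-family tie."""
    best: list[AnnotationHit] = []
    for h in hits:
        if h.database != "REFSEQ_FAMILY" or h.bitscore is None:
            continue
        if h.bitscore < min_bitscore:
            continue
        if not best or h.bitscore > best[0].bitscore:
            best = [h]
        elif h.bitscore == best[0].bitscore:
            best.append(h)
    if not best:
        return None
    families = {h.label for h in best}
    if len(families) > 1:
        return None
    return best[0].label


def vote_family(votu: VOTUCluster,
                genes: Iterable[GeneRecord],
                hits: Iterable[AnnotationHit],
                params: Parameters) -> TaxonomyCall:
    """Majority vote over all proteins encoded on the vOTU's member contigs.

    The denominator includes unannotated proteins by default (configurable
    via ``taxonomy_count_unannotated``).
    """
    member_set = set(votu.member_ids)
    proteins = [g.protein_id for g in genes if g.contig_id in member_set]
    hits_by_protein: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    votes = Counter()
    n_voting = 0
    for pid in proteins:
        fam = _protein_vote(hits_by_protein.get(pid, []), params.taxonomy_min_bitscore)
        if fam is not None:
            votes[fam] += 1
            n_voting += 1
    denominator = len(proteins) if params.taxonomy_count_unannotated else n_voting
    if denominator == 0 or not votes:
        return TaxonomyCall(votu.votu_id, UNASSIGNED, 0.0, "unassigned")
    family, count = votes.most_common(1)[0]
    support = count / denominator
    if support > params.taxonomy_vote_fraction:
        return TaxonomyCall(votu.votu_id, family, support, "direct")
    return TaxonomyCall(votu.votu_id, UNASSIGNED, support, "unassigned")


def propagate_by_vc(calls: Sequence[TaxonomyCall],
                    votus: Sequence[VOTUCluster],
                    vc_membership: Mapping[str, str],
                    params: Parameters) -> list[TaxonomyCall]:
    """Propagate family labels through viral clusters.

    An unassigned vOTU whose representative sits in a VC adopts family F iff
    strictly more than half of that VC's directly-assigned vOTUs carry F.
    Direct calls never change.
    """
    rep_of = {v.votu_id: v.representative_id for v in votus}
    vc_of = {cid: vc_membership.get(rep_of.get(cid, cid)) for cid in rep_of}

    direct_by_vc: dict[str, Counter] = {}
    n_direct_by_vc: Counter = Counter()
    for call in calls:
        vc = vc_of.get(call.votu_id)
        if vc is None or call.tier != "direct":
            continue
        direct_by_vc.setdefault(vc, Counter())[call.family] += 1
        n_direct_by_vc[vc] += 1

    out = []
    for call in calls:
        if call.tier != "unassigned":
            out.append(call)
            continue
        vc = vc_of.get(call.votu_id)
        if vc is None or vc not in direct_by_vc:
            out.append(call)
            continue
        family, count = direct_by_vc[vc].most_common(1)[0]
        total = n_direct_by_vc[vc]
        if count > params.taxonomy_vote_fraction * total:
            out.append(replace(call, family=family, support=count / total,
                               tier="propagated"))
        else:
            out.append(call)
    return out
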