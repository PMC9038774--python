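"""Greedy centroid clustering of viral contigs into vOTUs.

Contigs are clustered at >=95% nucleotide identity over >=80% coverage of the
shorter sequence, the de-facto community standard for defining viral
populations. The clustering is the classic greedy centroid heuristic: contigs
are processed longest-first and each joins the first existing representative
it matches, otherwise founds a new cluster.

Identity and coverage come from an end-gap-free (overlap) pairwise alignment;
both orientations are scored and the better one reported. ``N`` bases never
count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Seq import reverse_complement

from .io_formats import Contig
from .params import Parameters

__all__ = ["AlignmentSummary", "VOTUCluster", "align_pair", "greedy_cluster",
           "select_long"]


@dataclass(frozen=True)
class AlignmentSummary:
    """Identity/coverage summary of the best-orientation pairwise alignment.

    ``identity`` is the fraction of matching bases over aligned columns
    (internal gap columns count against identity); ``coverage`` is the aligned
    length divided by the length of the shorter sequence.
    """

    query_id: str
    target_id: str
    identity: float
    coverage: float
    aligned_len_bp: int
    strand: str = "+"


def _aligner(params: Parameters) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.align_match
    aligner.mismatch_score = params.align_mismatch
    aligner.open_gap_score = params.align_gap_open
    aligner.extend_gap_score = params.align_gap_extend
    # overlap alignment: end gaps are free (set last — the general gap scores
    # above would otherwise overwrite them)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _summarize(alignment, len_a: int, len_b: int) -> tuple[float, float, int]:
    s0 = str(alignment[0])
    s1 = str(alignment[1])
    lo, hi = 0, len(s0)
    while lo < hi and (s0[lo] == "-" or s1[lo] == "-"):
        lo += 1
    while hi > lo and (s0[hi - 1] == "-" or s1[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols <= 0:
        return 0.0, 0.0, 0
    matches = sum(
        1 for i in range(lo, hi)
        if s0[i] == s1[i] and s0[i] not in ("-", "N")
    )
    identity = matches / cols
    coverage = min(1.0, cols / min(len_a, len_b))
    return identity, coverage, cols


def align_pair(a: Contig, b: Contig, params: Parameters) -> AlignmentSummary:
    """Best-orientation overlap alignment of two contigs.

    Raises for sequences beyond ``align_max_len_bp``; at that scale the exact
    dynamic program is no longer appropriate and the k-mer prefilter mode of
    :func:`greedy_cluster` should be used to avoid hopeless pairs entirely.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align empty sequences")
    too_long = max(len(a), len(b))
    if too_long > params.align_max_len_bp:
        raise ValueError(
            f"sequence length {too_long} exceeds align_max_len_bp="
            f"{params.align_max_len_bp}; enable the k-mer prefilter mode and "
            f"raise the cap only if exact alignment is really required")
    aligner = _aligner(params)
    fwd = aligner.align(a.sequence, b.sequence)[0]
    rev = aligner.align(a.sequence, reverse_complement(b.sequence))[0]
    if rev.score > fwd.score:
        identity, coverage, cols = _summarize(rev, len(a), len(b))
        strand = "-"
    else:
        identity, coverage, cols = _summarize(fwd, len(a), len(b))
        strand = "+"
    return AlignmentSummary(a.contig_id, b.contig_id, identity, coverage,
                            cols, strand)


@dataclass(frozen=True)
class VOTUCluster:
    votu_id: str
    representative_id: str
    member_ids: tuple[str, ...]

    def __post_init__(self):
        if self.representative_id not in self.member_ids:
            raise ValueError(f"{self.votu_id}: representative not among members")


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    """Canonical (lexicographic min of forward/revcomp) k-mer set; k-mers
    containing N are skipped."""
    rc = reverse_complement(seq)
    n = len(seq)
    kmers = set()
    for i in range(n - k + 1):
        f = seq[i:i + k]
        if "N" in f:
            continue
        r = rc[n - k - i:n - i]
        kmers.add(min(f, r))
    return frozenset(kmers)


def _qualifying_alignment(a: Contig, b: Contig, params: Parameters,
                          aligner: Align.PairwiseAligner) -> bool:
    """Membership check used by clustering: does the best orientation reach
    both thresholds? The forward orientation is tried first and the reverse
    complement only when forward does not already qualify, which cannot
    change the decision."""
    fwd = aligner.align(a.sequence, b.sequence)[0]
    identity, coverage, _ = _summarize(fwd, len(a), len(b))
    if (identity >= params.votu_min_identity
            and coverage >= params.votu_min_coverage):
        return True
    rev = aligner.align(a.sequence, reverse_complement(b.sequence))[0]
    identity, coverage, _ = _summarize(rev, len(a), len(b))
    return (identity >= params.votu_min_identity
            and coverage >= params.votu_min_coverage)


def greedy_cluster(contigs: Sequence[Contig], params: Parameters,
                   prefilter: bool | None = None,
                   align_cache: dict | None = None) -> list[VOTUCluster]:
    """Greedy longest-first centroid clustering.

    Candidates are compared against representatives in founding order and join
    the first one reaching both the identity and the coverage threshold. With
    the k-mer prefilter (default) pairs sharing no canonical 21-mer are skipped
    without alignment; at the 95% identity threshold true pairs share many
    21-mers unless substitutions are pathologically evenly spaced.

    ``align_cache`` optionally memoizes membership decisions by contig-id pair
    across repeated clusterings of the same contig set (e.g. order-invariance
    checks); callers must not reuse it across different sequence sets.
    """
    if prefilter is None:
        prefilter = params.kmer_prefilter
    ids = [c.contig_id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in clustering input")
    order = sorted(contigs, key=lambda c: (-len(c), c.contig_id))
    k = params.prefilter_k
    aligner = _aligner(params)
    kmers: dict[str, frozenset[str]] = {}
    reps: list[Contig] = []
    members: dict[str, list[str]] = {}
    for contig in order:
        if prefilter:
            kmers[contig.contig_id] = _kmer_set(contig.sequence, k)
        placed = False
        for rep in reps:
            if prefilter and kmers[contig.contig_id].isdisjoint(kmers[rep.contig_id]):
                continue
            key = (rep.contig_id, contig.contig_id)
            if align_cache is not None and key in align_cache:
                ok = align_cache[key]
            else:
                ok = _qualifying_alignment(rep, contig, params, aligner)
                if align_cache is not None:
                    align_cache[key] = ok
            if ok:
                members[rep.contig_id].append(contig.contig_id)
                placed = True
                break
        if not placed:
            reps.append(contig)
            members[contig.contig_id] = [contig.contig_id]
    width = max(4, len(str(len(reps))))
    return [
        VOTUCluster(f"vOTU_{i:0{width}d}", rep.contig_id,
                    tuple(sorted(members[rep.contig_id])))
        for i, rep in enumerate(reps, start=1)
    ]


def select_long(votus: Iterable[VOTUCluster], contigs: Sequence[Contig],
                params: Parameters) -> list[VOTUCluster]:
    """vOTUs whose representative is strictly longer than ``votu_long_len_bp``."""
    lengths = {c.contig_id: len(c) for c in contigs}
    return [v for v in votus if lengths[v.representative_id] > params.votu_long_len_bp]
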