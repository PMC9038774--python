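"""Virus-host linkage from tRNA and CRISPR evidence.

Two complementary signals connect a viral contig to a bacterial host:

* a tRNA carried by the virus that occurs as an exact, full-length copy
  (either strand) in a host contig — temperate phages frequently carry
  host-derived tRNAs;
* a CRISPR spacer matching a viral protospacer with at most one mismatch,
  provided the same array's repeat occurs exactly in a bacterial contig that
  anchors the array to a host taxon.

Unknown bases (``N``) never count as matches. Deduplicated (virus, host)
links are then classified by bipartite degree pattern into specialist /
generalist / polyvalent topologies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .io_formats import Contig, CrisprArray, TrnaEntry
from .params import Parameters

__all__ = ["HostLink", "LinkTopology", "match_trna", "match_spacers",
           "classify_topology", "find_approx_matches"]


@dataclass(frozen=True)
class HostLink:
    virus_contig_id: str
    host_taxon: str
    host_contig_id: str
    evidence: str            # tRNA | CRISPR
    position: int            # 0-based start of the match in the matched contig
    strand: str              # + | -
    mismatches: int

    def __post_init__(self):
        if self.evidence not in ("tRNA", "CRISPR"):
            raise ValueError(f"unknown evidence type {self.evidence!r}")
        if self.evidence == "tRNA" and self.mismatches != 0:
            raise ValueError("tRNA links require exact matches")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


_N = ord("N")


def find_approx_matches(pattern: str, text: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (offset, mismatches) where ``pattern`` matches ``text`` over its
    full length with at most ``max_mismatch`` mismatches; ``N`` on either side
    is always a mismatch."""
    m, n = len(pattern), len(text)
    if m == 0 or m > n:
        return []
    p = _encode(pattern)
    t = _encode(text)
    n_win = n - m + 1
    acc = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        window = t[j:j + n_win]
        mism = (window != p[j]) | (window == _N) | (p[j] == _N)
        acc += mism
    hits = np.nonzero(acc <= max_mismatch)[0]
    return [(int(i), int(acc[i])) for i in hits]


def _best_match_both_strands(pattern: str, text: str,
                             max_mismatch: int) -> tuple[int, str, int] | None:
    """Minimal-mismatch full-length occurrence of pattern in text on either
    strand -> (position, strand, mismatches), or None."""
    best = None
    for strand, pat in (("+", pattern), ("-", reverse_complement(pattern))):
        for pos, mm in find_approx_matches(pat, text, max_mismatch):
            if best is None or mm < best[2]:
                best = (pos, strand, mm)
                if mm == 0:
                    return best
    return best


def match_trna(trnas: Sequence[TrnaEntry],
               host_contigs: Sequence[Contig],
               host_taxonomy: Mapping[str, str],
               params: Parameters) -> list[HostLink]:
    """Exact full-length tRNA occurrence (either strand) in a host contig.

    Self-hits (the host contig is the tRNA's own source contig) are removed
    and duplicate (virus, host contig) pairs collapsed to one link.
    """
    links: dict[tuple[str, str], HostLink] = {}
    for trna in trnas:
        seq = trna.trna_seq
        if len(seq) < params.min_trna_len_nt or "N" in seq:
            continue
        for host in host_contigs:
            if host.contig_id == trna.virus_contig_id:
                continue  # self-hit
            key = (trna.virus_contig_id, host.contig_id)
            if key in links:
                continue
            hit = _best_match_both_strands(seq, host.sequence, 0)
            if hit is None:
                continue
            pos, strand, _ = hit
            links[key] = HostLink(
                trna.virus_contig_id,
                host_taxonomy.get(host.contig_id, "unknown"),
                host.contig_id, "tRNA", pos, strand, 0)
    return list(links.values())


def match_spacers(arrays: Sequence[CrisprArray],
                  virus_contigs: Sequence[Contig],
                  host_contigs: Sequence[Contig],
                  host_taxonomy: Mapping[str, str],
                  params: Parameters) -> tuple[list[HostLink], list[HostLink]]:
    """CRISPR spacer-to-protospacer linkage.

    Step 1: a spacer matches a viral contig over its full length with at most
    ``spacer_max_mismatch`` mismatches (both strands). Step 2: the same
    array's repeat must occur exactly in a bacterial contig, which supplies
    the host taxon. Spacer matches whose repeat anchors nowhere are returned
    separately as orphans, not links.

    Returns ``(links, orphans)``; links are deduplicated per
    (virus, host taxon) keeping the minimal-mismatch detail.
    """
    links: dict[tuple[str, str], HostLink] = {}
    orphans: list[HostLink] = []
    for array in arrays:
        if len(array.repeat_seq) < params.min_repeat_len_nt:
            continue
        # step 2 evidence: anchor the array to host contigs via its repeat
        anchor_hosts = [
            h for h in host_contigs
            if _best_match_both_strands(array.repeat_seq, h.sequence, 0) is not None
        ]
        for spacer in array.spacers:
            if len(spacer) < params.spacer_min_len_nt:
                continue
            for virus in virus_contigs:
                hit = _best_match_both_strands(spacer, virus.sequence,
                                               params.spacer_max_mismatch)
                if hit is None:
                    continue
                pos, strand, mm = hit
                if not anchor_hosts:
                    orphans.append(HostLink(virus.contig_id, "unanchored",
                                            array.host_contig_id, "CRISPR",
                                            pos, strand, mm))
                    continue
                for host in anchor_hosts:
                    taxon = host_taxonomy.get(host.contig_id, "unknown")
                    key = (virus.contig_id, taxon)
                    link = HostLink(virus.contig_id, taxon, host.contig_id,
                                    "CRISPR", pos, strand, mm)
                    if key not in links or mm < links[key].mismatches:
                        links[key] = link
    return list(links.values()), orphans


@dataclass(frozen=True)
class LinkTopology:
    """Degree-pattern classes of the deduplicated virus-host bipartite graph."""

    virus_class: dict[str, str]
    host_class: dict[str, str]
    edge_class: dict[tuple[str, str], tuple[str, str]]  # (virus-side, host-side)


def classify_topology(links: Iterable[HostLink]) -> LinkTopology:
    """Classify each virus, host taxon and edge.

    A virus with several host taxa is *polyvalent*; a host with several
    viruses is a *generalist*; a one-to-one pair is a *specialist* pair. A
    degree-1 node attached to a high-degree partner inherits the partner's
    class for its side of the edge.
    """
    edges = sorted({(l.virus_contig_id, l.host_taxon) for l in links})
    vdeg: dict[str, int] = {}
    hdeg: dict[str, int] = {}
    for v, h in edges:
        vdeg[v] = vdeg.get(v, 0) + 1
        hdeg[h] = hdeg.get(h, 0) + 1
    virus_class = {
        v: ("polyvalent" if d >= 2 else
            "specialist" if all(hdeg[h] == 1 for vv, h in edges if vv == v)
            else "generalist")
        for v, d in vdeg.items()
    }
    host_class = {
        h: ("generalist" if d >= 2 else
            "specialist" if all(vdeg[v] == 1 for v, hh in edges if hh == h)
            else "polyvalent")
        for h, d in hdeg.items()
    }
    edge_class = {
        (v, h): ("polyvalent" if vdeg[v] >= 2 else "specialist",
                 "generalist" if hdeg[h] >= 2 else "specialist")
        for v, h in edges
    }
    return LinkTopology(virus_class, host_class, edge_class)
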