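"""Domain types and readers/writers for every external representation.

Sequences travel as FASTA; everything tabular (gene calls, annotation hits,
CRISPR arrays, tRNA entries, viral-cluster membership, host taxonomy,
abundance counts) travels as tab-separated files with a header row.
Coordinates are 1-based inclusive (GFF convention); the gene ``index`` is the
0-based rank along its contig used by positional AMG rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig", "GeneRecord", "AnnotationHit", "CrisprArray", "TrnaEntry",
    "DATABASES", "GROUPS",
    "read_fasta", "write_fasta",
    "read_gene_table", "write_gene_table",
    "read_hit_table", "write_hit_table",
    "read_crispr_table", "write_crispr_table",
    "read_trna_table", "write_trna_table",
    "read_vc_table", "write_vc_table",
    "read_taxon_table", "write_taxon_table",
    "read_count_table", "write_count_table",
    "read_contig_meta", "write_contig_meta",
]

GROUPS = ("clean", "light", "heavy")
#: annotation databases understood by the pipeline
DATABASES = ("VPF", "KO", "PFAM", "VOG", "REFSEQ_FAMILY", "AMG_FLAG")

_DNA = set("ACGTN")


@dataclass(frozen=True)
class Contig:
    """An assembled nucleotide contig with its provenance and screen metadata."""

    contig_id: str
    sequence: str
    sample_id: str = ""
    group: str = ""
    virsorter_category: int | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"contig {self.contig_id}: empty sequence")
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"contig {self.contig_id}: non-DNA characters {sorted(bad)}")
        if self.group and self.group not in GROUPS:
            raise ValueError(f"contig {self.contig_id}: unknown group {self.group!r}")
        if self.virsorter_category is not None and not 1 <= self.virsorter_category <= 6:
            raise ValueError(f"contig {self.contig_id}: VirSorter category must be 1..6")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """A positional gene call.

    ``index`` is the 0-based rank of the gene along its contig (sorted by
    start); ``start``/``end`` are 1-based inclusive nucleotide coordinates.
    """

    gene_id: str
    contig_id: str
    index: int
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self):
        if self.index < 0:
            raise ValueError(f"gene {self.gene_id}: negative index")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class AnnotationHit:
    """One database assignment of a protein.

    ``label`` carries the human-meaningful part: a viral family name for
    REFSEQ_FAMILY, the VOG functional category string (e.g. ``"Xr"``) for VOG,
    a Pfam family for PFAM, a flag letter for AMG_FLAG.
    """

    protein_id: str
    database: str
    accession: str
    label: str = ""
    bitscore: float | None = None

    def __post_init__(self):
        if self.database not in DATABASES:
            raise ValueError(f"hit {self.protein_id}: unknown database {self.database!r}")
        if self.bitscore is not None and self.bitscore < 0:
            raise ValueError(f"hit {self.protein_id}: negative bitscore")
        if self.database == "REFSEQ_FAMILY" and self.bitscore is None:
            raise ValueError(f"hit {self.protein_id}: REFSEQ_FAMILY hits need a bitscore")


@dataclass(frozen=True)
class CrisprArray:
    """A CRISPR repeat-spacer array recovered from a bacterial contig."""

    host_contig_id: str
    array_id: str
    repeat_seq: str
    spacers: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "repeat_seq", self.repeat_seq.upper())
        object.__setattr__(self, "spacers", tuple(s.upper() for s in self.spacers))
        if not self.spacers:
            raise ValueError(f"array {self.array_id}: needs at least one spacer")
        if len(self.repeat_seq) < 18:
            raise ValueError(f"array {self.array_id}: repeat shorter than 18 nt")


@dataclass(frozen=True)
class TrnaEntry:
    """A tRNA sequence recovered from a viral contig."""

    virus_contig_id: str
    trna_seq: str

    def __post_init__(self):
        object.__setattr__(self, "trna_seq", self.trna_seq.upper())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, meta: dict[str, dict] | None = None) -> list[Contig]:
    """Read contigs from FASTA; ids are headers up to the first whitespace.

    ``meta`` optionally maps contig_id -> dict(sample_id=, group=,
    virsorter_category=) to attach provenance that FASTA cannot carry.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id in {path.name}: {rec.id}")
        seen.add(rec.id)
        m = (meta or {}).get(rec.id, {})
        contigs.append(Contig(rec.id, str(rec.seq), **m))
    if not contigs:
        warnings.warn(f"{path.name}: no FASTA records", stacklevel=2)
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# TSV helpers

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {missing}")
    return df


GENE_COLUMNS = ["gene_id", "contig_id", "index", "start", "end", "strand", "protein_id"]


def read_gene_table(path: str | Path,
                    contig_lengths: dict[str, int] | None = None) -> list[GeneRecord]:
    """Read gene calls; validates index order per contig and, when contig
    lengths are supplied, that coordinates stay in bounds."""
    df = _read_tsv(path, GENE_COLUMNS)
    genes = [
        GeneRecord(r.gene_id, r.contig_id, int(r.index), int(r.start),
                   int(r.end), r.strand, r.protein_id)
        for r in df.itertuples()
    ]
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for cid, gs in by_contig.items():
        gs_sorted = sorted(gs, key=lambda g: g.start)
        if [g.index for g in gs_sorted] != list(range(len(gs))):
            raise ValueError(f"contig {cid}: gene indexes not a gap-free 0-based "
                             f"order sorted by start")
        if contig_lengths is not None and cid in contig_lengths:
            for g in gs:
                if g.end > contig_lengths[cid]:
                    raise ValueError(f"gene {g.gene_id}: end {g.end} beyond contig "
                                     f"{cid} length {contig_lengths[cid]}")
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame([vars(g) for g in genes], columns=GENE_COLUMNS) \
        .to_csv(path, sep="\t", index=False)


HIT_COLUMNS = ["protein_id", "database", "accession", "label", "bitscore"]


def read_hit_table(path: str | Path) -> list[AnnotationHit]:
    df = _read_tsv(path, HIT_COLUMNS)
    hits = []
    seen: set[tuple] = set()
    for r in df.itertuples():
        bits = float(r.bitscore) if r.bitscore != "" else None
        key = (r.protein_id, r.database, r.accession)
        if key in seen:
            raise ValueError(f"duplicate annotation hit {key}")
        seen.add(key)
        hits.append(AnnotationHit(r.protein_id, r.database, r.accession, r.label, bits))
    return hits


def write_hit_table(hits: Iterable[AnnotationHit], path: str | Path) -> None:
    rows = [{**vars(h), "bitscore": "" if h.bitscore is None else h.bitscore}
            for h in hits]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


CRISPR_COLUMNS = ["host_contig_id", "array_id", "repeat_seq", "spacer_rank", "spacer_seq"]


def read_crispr_table(path: str | Path) -> list[CrisprArray]:
    """One row per spacer; rows of an array share host_contig_id/array_id/repeat."""
    df = _read_tsv(path, CRISPR_COLUMNS)
    arrays: list[CrisprArray] = []
    for (host, aid, repeat), sub in df.groupby(
            ["host_contig_id", "array_id", "repeat_seq"], sort=False):
        sub = sub.assign(_rank=sub["spacer_rank"].astype(int)).sort_values("_rank")
        arrays.append(CrisprArray(host, aid, repeat, tuple(sub["spacer_seq"])))
    return arrays


def write_crispr_table(arrays: Iterable[CrisprArray], path: str | Path) -> None:
    rows = [
        {"host_contig_id": a.host_contig_id, "array_id": a.array_id,
         "repeat_seq": a.repeat_seq, "spacer_rank": i, "spacer_seq": s}
        for a in arrays for i, s in enumerate(a.spacers)
    ]
    pd.DataFrame(rows, columns=CRISPR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_trna_table(path: str | Path) -> list[TrnaEntry]:
    df = _read_tsv(path, ["virus_contig_id", "trna_seq"])
    return [TrnaEntry(r.virus_contig_id, r.trna_seq) for r in df.itertuples()]


def write_trna_table(trnas: Iterable[TrnaEntry], path: str | Path) -> None:
    pd.DataFrame([vars(t) for t in trnas], columns=["virus_contig_id", "trna_seq"]) \
        .to_csv(path, sep="\t", index=False)


def read_vc_table(path: str | Path) -> dict[str, str]:
    """Viral-cluster membership: contig_id -> vc_id."""
    df = _read_tsv(path, ["contig_id", "vc_id"])
    if df["contig_id"].duplicated().any():
        dup = df.loc[df["contig_id"].duplicated(), "contig_id"].iloc[0]
        raise ValueError(f"contig {dup} appears in more than one VC")
    return dict(zip(df["contig_id"], df["vc_id"]))


def write_vc_table(membership: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(membership.items()), columns=["contig_id", "vc_id"]) \
        .to_csv(path, sep="\t", index=False)


def read_taxon_table(path: str | Path) -> dict[str, str]:
    """Host taxonomy: host_contig_id -> taxon."""
    df = _read_tsv(path, ["host_contig_id", "taxon"])
    return dict(zip(df["host_contig_id"], df["taxon"]))


def write_taxon_table(taxonomy: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(taxonomy.items()), columns=["host_contig_id", "taxon"]) \
        .to_csv(path, sep="\t", index=False)


META_COLUMNS = ["contig_id", "sample_id", "group", "virsorter_category"]


def read_contig_meta(path: str | Path) -> dict[str, dict]:
    """Per-contig provenance FASTA cannot carry: contig_id -> kwargs for Contig."""
    df = _read_tsv(path, META_COLUMNS)
    meta = {}
    for r in df.itertuples():
        cat = int(r.virsorter_category) if r.virsorter_category != "" else None
        meta[r.contig_id] = {"sample_id": r.sample_id, "group": r.group,
                             "virsorter_category": cat}
    return meta


def write_contig_meta(contigs: Iterable[Contig], path: str | Path) -> None:
    rows = [{"contig_id": c.contig_id, "sample_id": c.sample_id, "group": c.group,
             "virsorter_category": "" if c.virsorter_category is None
             else c.virsorter_category}
            for c in contigs]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Samples x features table; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{Path(path).name}: negative abundance value")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")
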