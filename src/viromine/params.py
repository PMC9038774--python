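"""Global parameter set for the virome mining pipeline.

Every numeric threshold used anywhere in the pipeline lives in one
:class:`Parameters` object so that nothing is hard-coded and every screening /
clustering / linkage rule can be reconfigured from a single YAML or JSON file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Parameters"]


@dataclass
class Parameters:
    """All tunable thresholds of the pipeline.

    Attributes
    ----------
    min_contig_len_bp:
        Minimum assembled contig length considered at all (1 kb).
    screen_len_gate_bp:
        Contigs at or below this length are retained on the VirSorter category
        gate alone; longer contigs are additionally subjected to the three
        annotation-fraction criteria (5 kb).
    kept_categories:
        VirSorter confidence categories accepted as viral (1, 2, 4, 5 —
        sure/somewhat-sure phage and prophage calls).
    min_vpf_hits:
        Criterion 1: minimum number of genes with a viral-protein-family hit.
    max_ko_fraction:
        Criterion 1: fraction of genes with a KEGG Orthology hit must be
        strictly below this value.
    max_pfam_fraction:
        Criterion 1: fraction of genes with a Pfam hit may be at most this
        value (inclusive).
    vpf_total_fraction:
        Criterion 3: VPF-hit genes must reach this fraction of all genes.
    screen_polarity:
        ``retain_if_any`` keeps >5 kb contigs meeting at least one criterion
        (the protocol reading, default); ``discard_if_any`` drops them.
    votu_min_identity, votu_min_coverage:
        Greedy vOTU clustering thresholds (0.95 nucleotide identity over 0.80
        of the shorter sequence).
    votu_long_len_bp:
        Representatives strictly longer than this are "long" vOTUs used for
        protein-sharing analyses (10 kb).
    align_match, align_mismatch, align_gap_open, align_gap_extend:
        Pairwise alignment scoring (end-gap-free / overlap alignment).
    align_max_len_bp:
        Hard cap on sequence length for exact pairwise alignment.
    kmer_prefilter, prefilter_k:
        Skip alignment of pairs sharing no canonical k-mer (k = 21). Pairs at
        >=95% identity share many 21-mers except under pathologically
        evenly-spaced substitutions.
    taxonomy_min_bitscore:
        Minimum BLASTp bitscore for a RefSeq family hit to vote (50).
    taxonomy_vote_fraction:
        A family is adopted iff its votes exceed this fraction of proteins
        (strict >, 0.50).
    taxonomy_count_unannotated:
        Whether unannotated proteins count in the vote denominator.
    spacer_max_mismatch:
        CRISPR spacer-to-protospacer matching tolerance (<=1 mismatch;
        set to 0 for the strict-exact reading).
    spacer_min_len_nt:
        Minimum spacer length accepted for matching; the statistical control
        replacing a BLAST E-value cutoff (20 nt).
    min_trna_len_nt:
        Minimum tRNA sequence length accepted for exact matching.
    min_repeat_len_nt:
        Minimum CRISPR repeat length for a valid array (18 nt).
    pearson_r_threshold, pearson_p_threshold:
        Co-occurrence network edge rule: |r| > 0.6 (strict) and p < 0.05.
    cooccurrence_bh_correct:
        Benjamini-Hochberg correction of network p-values (off by default,
        mirroring common practice for these descriptive networks).
    end_flag_window_genes:
        AMG flag F: gene rank within this many genes of either contig end (2).
    consecutive_M_for_B:
        AMG flag B: minimum run length of consecutive M-flagged genes (3).
    amg_pseudocount:
        Pseudocount for log10 display transforms of AMG abundances.
    shannon_base:
        Logarithm base for the Shannon index (e — natural log).
    tpm_scale:
        Per-sample sum of a TPM row (1e6).
    rng_seed:
        Seed for any stochastic step.
    """

    min_contig_len_bp: int = 1000
    screen_len_gate_bp: int = 5000
    kept_categories: frozenset[int] = frozenset({1, 2, 4, 5})
    min_vpf_hits: int = 5
    max_ko_fraction: float = 0.20
    max_pfam_fraction: float = 0.40
    vpf_total_fraction: float = 0.60
    screen_polarity: str = "retain_if_any"

    votu_min_identity: float = 0.95
    votu_min_coverage: float = 0.80
    votu_long_len_bp: int = 10000
    align_match: float = 1.0
    align_mismatch: float = -1.0
    align_gap_open: float = -5.0
    align_gap_extend: float = -1.0
    align_max_len_bp: int = 200_000
    kmer_prefilter: bool = True
    prefilter_k: int = 21

    taxonomy_min_bitscore: float = 50.0
    taxonomy_vote_fraction: float = 0.50
    taxonomy_count_unannotated: bool = True

    spacer_max_mismatch: int = 1
    spacer_min_len_nt: int = 20
    min_trna_len_nt: int = 50
    min_repeat_len_nt: int = 18

    pearson_r_threshold: float = 0.6
    pearson_p_threshold: float = 0.05
    cooccurrence_bh_correct: bool = False

    end_flag_window_genes: int = 2
    consecutive_M_for_B: int = 3
    amg_pseudocount: float = 1.0

    shannon_base: float | None = None  # None -> natural log
    tpm_scale: float = 1_000_000.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.kept_categories = frozenset(int(c) for c in self.kept_categories)
        for name in ("max_ko_fraction", "max_pfam_fraction", "vpf_total_fraction",
                     "votu_min_identity", "votu_min_coverage",
                     "taxonomy_vote_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("min_contig_len_bp", "screen_len_gate_bp", "min_vpf_hits",
                     "votu_long_len_bp", "spacer_min_len_nt", "min_trna_len_nt",
                     "min_repeat_len_nt", "consecutive_M_for_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.screen_polarity not in ("retain_if_any", "discard_if_any"):
            raise ValueError(f"unknown screen_polarity {self.screen_polarity!r}")
        if self.spacer_max_mismatch < 0:
            raise ValueError("spacer_max_mismatch must be >= 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kept_categories"] = sorted(self.kept_categories)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write the parameter set as YAML (or JSON if the suffix is .json)."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Parameters":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)

    def replace(self, **kw) -> "Parameters":
        return dataclasses.replace(self, **kw)
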