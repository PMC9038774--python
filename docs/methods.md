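# Methods

This note documents the models, rules and numerical choices behind
`viromine`, what the synthetic generator does and does not emulate, and the
decisions taken where the underlying protocols are genuinely open.

## Viral screening

A contig enters the viral set through two gates. The *category gate* keeps
VirSorter confidence categories 1, 2, 4 and 5 (category calling itself is an
input — this package never re-scores HMMs). Contigs longer than the 5 kb
gate must additionally satisfy at least one of three composition criteria
over gene-covered counts:

* **c1** — ≥ 5 genes carry viral-protein-family (VPF) hits, the KO-annotated
  gene fraction is strictly < 0.20, and the Pfam-annotated fraction is
  ≤ 0.40 (the boundary semantics are implemented exactly as stated: strict
  for KO, inclusive for Pfam);
* **c2** — VPF-annotated genes ≥ Pfam-annotated genes;
* **c3** — VPF-annotated genes ≥ 60% of all genes.

"Hits" are counted as genes-with-≥1-hit, not raw hit rows, so all three
criteria compare like quantities. Fractions on zero-gene contigs are defined
as 0, which makes c2 and c3 vacuously true there; such contigs are only ever
retained through the ≤ 5 kb category-only path.

**Polarity.** The source protocols disagree on whether criteria-passing
contigs are kept or removed. The default is `retain_if_any` (passing ≥ 1
criterion keeps the contig), which matches the established screening
protocol and the small fraction of long contigs removed in practice;
`discard_if_any` is available as a flag and is never chosen silently.

## vOTU clustering

Viral populations are defined at ≥ 95% nucleotide identity over ≥ 80%
coverage. Identity and coverage come from an end-gap-free (overlap) pairwise
alignment (match +1, mismatch −1, gap open −5, gap extend −1, end gaps
free); both orientations are scored and the better one used. Identity is
matches / aligned columns after trimming end gaps (internal gap columns
count against identity); coverage is aligned columns / length of the
**shorter** sequence, matching ClusterGenomes behaviour — whether the
original script required coverage of both sequences is unknown, and this
choice is flagged. `N` bases never count as matches in any comparison.

Clustering is the greedy longest-first centroid heuristic: contigs sorted by
(length desc, id asc — the deterministic tie-break), each joining the
*first* representative (founding order) that reaches both thresholds,
otherwise founding a new cluster. First-match rather than best-match is the
standard centroid heuristic; it can differ from best-match near threshold
boundaries, which is why it is documented. Because sorting is internal, the
partition is invariant to input order.

A canonical 21-mer prefilter (on by default) skips alignment for pairs
sharing no k-mer. A true ≥ 95% pair could in principle be missed only if
substitutions were spaced ≤ 21 bp apart throughout the overlap — a
pathological pattern the generator never produces and random mutation makes
vanishingly unlikely; partitions with and without the prefilter are asserted
bit-identical in the tests. Sequences beyond `align_max_len_bp` (200 kb) are
refused by the exact aligner rather than silently truncated.

## Taxonomy voting

Each protein on a vOTU's member contigs casts ≤ 1 vote: its best-bitscore
RefSeq family among hits with bitscore ≥ 50. A bitscore tie across different
families discards the vote (conservative). The vote denominator includes
unannotated proteins — "of the proteins", not "of annotated proteins" — and
is configurable. A family is adopted iff votes > 0.50 × denominator
(strict: an exact 50% split stays Unassigned).

Unassigned vOTUs inside a viral cluster (VC — an input table; VC
construction is out of scope) adopt family *F* iff > 50% of the VC's
*directly assigned* members carry *F*. Restricting the propagation majority
to direct calls avoids self-reinforcing feedback; direct calls never change,
so the assigned fraction is monotone non-decreasing under propagation. The
original two-tier procedure is under-specified; this VC-propagation reading
is a documented reconstruction, not a claim about the original scripts.

## Virus–host linkage

*tRNA evidence*: a viral tRNA (≥ 50 nt) linking to a host contig requires a
full-length exact occurrence on either strand; self-hits are removed and
duplicate (virus, host-contig) pairs collapsed.

*CRISPR evidence*: a spacer (≥ 20 nt) must match a viral contig over its
full length with ≤ 1 mismatch on either strand, and the **same array's**
repeat must occur exactly in a bacterial contig, which supplies the host
taxon. Spacer matches whose repeat anchors nowhere are reported as orphans,
never links. The printed "100% identity, mismatch ≤ 1" rule is internally
contradictory; ≤ 1 mismatch is the default and a strict-exact mode
(`spacer_max_mismatch = 0`) is provided. BLAST E-value cut-offs are replaced
by the minimum-length requirement: for a full-length ≤ 1-mismatch match of
≥ 20 nt against megabase-scale search spaces, the expected false-hit count
is ≪ 1, so length is the operative statistical control.

Deduplicated (virus, host-taxon) edges are classified by degree pattern:
a virus with ≥ 2 host taxa is *polyvalent*, a host with ≥ 2 viruses is a
*generalist*, a 1–1 pair is a *specialist* pair; a degree-1 node attached
to a high-degree partner inherits the partner's class for its side.

## AMG profiling

Genes partition into exactly one of {core, AMG, other}: *core* iff any VOG
hit carries category Xr (replication) or Xs (structure); *AMG* iff any Pfam
hit is in the curated family list; core takes precedence on conflict so
structural genes never inflate AMG counts. The curated list is data, not
code — a versioned TSV mapping Pfam families to categories {C, N, P, S,
pesticide, other}, covering nitrogen (norD, norQ), sulfur (cysD, cysH),
pesticide degradation (HAD-family dehalogenases, ALDH), CAZy (GH/GT/CBM/CE/
PL) and phosphorus families. It is a documented reconstruction; its totals
are not comparable to any particular published list.

Positional validation of a putative AMG requires viral hallmark genes at
both a strictly lower and a strictly higher gene rank on the same contig.
Flags follow DRAM-v semantics: **F** iff the gene rank is within
`end_flag_window_genes` of either contig end (fixed at 2 — the tool does
not export its constant, so this is a configurable package choice); **B**
iff the gene belongs to a run of ≥ 3 consecutive M-flagged genes. Both
rules are rank-based, not coordinate-based, because "near the end" in the
source tooling counts genes.

Group comparisons pool light + heavy as "contaminated": summed AMG TPM and
category diversity via two-sided rank-sum (exact where scipy permits),
detection counts via Fisher's exact 2×2. With 3 clean vs 6 contaminated
samples the exact rank-sum attains p = 2/84 ≈ 0.024 under complete
separation; a 3-vs-3 comparison cannot reach p < 0.05 (minimum 0.1), which
is why the pooled contrast carries the significance claim. Co-occurrence
edges require |r| strictly > 0.6 and two-sided p < 0.05 from the
t-distribution with n − 2 df; constant features are excluded, and p-values
are *not* multiple-testing corrected by default (a Benjamini–Hochberg flag
exists), mirroring common descriptive-network practice.

## Community statistics

TPM_i = 10⁶ · (c_i/L_i) / Σ_j (c_j/L_j) per sample; all-zero samples yield
all-zero rows with a warning. Alpha diversity follows vegan-style defaults,
documented because the originals are unstated: natural-log Shannon (base
configurable), Gini–Simpson 1 − Σp² (so "higher Simpson" means "more
even"), Pielou H/ln(S) (undefined at richness ≤ 1), bias-corrected Chao1
S + F₁(F₁−1)/(2(F₂+1)), and ACE with rare cut-off 10 and γ² floored at 0.
ACE degenerate cases: no rare taxa → observed richness; estimated sample
coverage 0 (every rare individual a singleton) → bias-corrected Chao1 as
the documented fallback. Richness/Chao1/ACE require integer counts.

Bray–Curtis is Σ|x−y| / Σ(x+y) (two all-zero samples → 0 with a warning).
UPGMA is hand-implemented (~40 lines) rather than delegated to scipy
because the output newick needs merge heights (node height = half the merge
dissimilarity) and a deterministic smallest-sample-id tie-break; scipy's
average-linkage serves as the independent oracle in the tests. Network
statistics treat the graph as simple and undirected (self-loops/duplicates
dropped and counted): density 2E/(N(N−1)), average neighbours 2E/N, and the
clustering coefficient averaged over *all* nodes with degree-< 2 nodes
contributing 0 (Cytoscape NetworkAnalyzer convention; excluding them is a
flag).

## Synthetic communities and what passing tests show

The generator emulates a 3 + 3 + 3 design (clean C1–C3; light S1–S3; heavy
S4–S6). Defaults: 12 viral lineages of 2 kb (2 of them 6 kb, above the
screen's length gate), 3 contigs per lineage, variants at 0.97 identity,
8 bacterial taxa, 2 tRNA links, 3 CRISPR links at 0/1 mismatches plus one
2-mismatch negative plant, half the lineages carrying one AMG, lognormal
(μ = 3, σ = 0.5) Poisson-thinned counts. Group effects are multiplicative
and recorded in the ground truth as orderings, not magic numbers: a 0.4
bacterial-richness drop and 1.6× viral presence gain in contaminated
samples, an 8× dominance boost of one taxon in clean samples (the evenness
contrast), AMG abundance × 4^severity (severity 0/0.5/1 for
clean/light/heavy) with per-group AMG detection rates 0.4/0.75/0.9. These
defaults are the baseline study conditions of every end-to-end test and are
not adjusted per test.

Design choices that make ground truth exact: variants are derived by point
substitutions only (never to the same base, never to N), so identity to the
ancestor is exactly 1 − m/L and the expected vOTU partition is closed-form
— indel robustness is a clustering test, not a generator feature; tRNAs are
planted into ancestors *before* variants are derived, preserving that
identity; protospacers are extracted from (not inserted into) ancestors;
CRISPR arrays are physically embedded (repeat–spacer–repeat–decoy–repeat)
in host contigs so repeat anchoring is real; annotation tables are laid out
so designated contigs pass or fail each screening criterion by
construction. AMG categories cycle over the curated family list by rank
among AMG-carrying lineages, so all six categories are represented.

What the generator does **not** emulate — and hence what green tests do not
show about field data: read-level sequencing error and assembly chimerism;
indels and rearrangements between related genomes; annotation noise
(false-positive hits, missing gene calls); compositional correlation
structure in counts beyond the planted effects; uneven sequencing depth.
Recovery rates of 1.0 on planted structure certify the *logic* of each
stage at its thresholds, not expected sensitivity on real soil viromes.

Perturbations provide negative controls: `scramble_spacers` (random spacers
of the same lengths — expected residual matches ≪ 1), `strip_hallmarks`
(removes VPF hits and VOG hallmark labels, voiding flank validation while
AMG classification still fires), `shuffle_labels` (permutes sample→group
assignment for null calibration).

## Statistical calibration and problem sizes

The end-to-end contrast checks run the abundance/diversity/AMG stages on
100 replicate seeds (the alignment-based stages are exercised separately at
a 200-contig scale: 50 lineages × 3 variants at 0.97 plus 50 decoy variants
at 0.90); host-linkage recall uses 100 replicate 4-virus/4-host datasets.
Under the null (all group effects set to 1, equal detection rates) the
clean-vs-contaminated exact rank-sum has attainable two-sided p-values
{2/84, 4/84, 8/84, …}, so rejecting at p < 0.05 has true level 8/84 ≈ 0.095
— calibrated within the ≤ 10% band by construction, with Monte-Carlo
fluctuation around it. All replicate seeds are fixed, so suite results are
reproducible run to run.

## Known limitations

* Exact pairwise alignment is quadratic; very long contigs rely on the
  prefilter and the configurable length cap rather than a banded aligner.
* The greedy first-match rule can split borderline chains that best-match
  assignment would merge (and vice versa); only the documented heuristic is
  implemented.
* Host taxonomy is an input mapping; no k-mer-composition or CRISPR-array
  taxonomy inference is attempted.
* The AMG family list is deliberately small and editable; category totals
  depend entirely on it.
* VC construction (protein-sharing clustering) is out of scope; propagation
  quality is bounded by the supplied membership table.
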