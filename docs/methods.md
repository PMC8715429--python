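# Methods

## Scope and model

The package treats a bacterial genome as a set of contigs with strand-aware
16S rRNA annotations. Each annotated gene copy is extracted in 5′→3′ gene
orientation together with up to U (default 1000) bases immediately upstream
of the gene start ("near-16S"); for minus-strand genes both sequences are
reverse-complemented and the upstream window is taken from the genomically
3′ side. Genes outside 1000–2000 bp are dropped and counted. Sequences with
any non-ACGT letter, genomes without genus or species, and — following the
strict whole-genome rule — every genome in which at least one copy failed a
per-locus filter (wildcards, missing primer, out-of-order primers) are
removed; an audit log records per-step counts so that retained = input −
Σ discards.

Hypervariable regions V1–V9 are delimited by conserved inter-region primer
sites. Each primer is located by infix alignment (end-gaps free on the
gene) with IUPAC degeneracies matching compatible bases at no cost; the
minimum-edit placement is kept (leftmost on ties) and placements needing
more than two edit columns — substitutions and indels share a single budget
— are treated as absent. A locus passes QC only when every primer is found
and the hits are in sequential order; region V_k spans from the end of
primer k−1's hit (gene start for V1) to the start of primer k's hit, so the
default V1–V2 composite runs from the gene start to the start of the
V2-terminating primer (341 bp in the synthetic template).

## Statistics

**Copy identifiability.** Per member of a rank: distinct composites /
total copies; report mean over members. Grouping: strain (intra-strain),
species pooling its strains' copies (inter-strain, species with ≥ 2
strains), genus pooling its species (inter-species). Caps (10 strains per
species; 10 species per genus for inter-species) are applied by uniform
seeded sub-sampling. Pooling keeps the multiset of copies; there is no
within-strain pre-deduplication (switchable by deduplicating the input).
"Unique" means exact string equality — a single-nucleotide variant
separates two copies.

**Conservation.** Column Shannon entropy S = −Σ Pᵢ log₄ Pᵢ with Pᵢ the
fraction of non-gap residues; columns gapped in the designated reference
(default row 0) are dropped, and a column whose non-reference rows are all
gaps is emitted as NaN. Gaps are excluded from the denominator — the
4-symbol log base then keeps S in [0, 1]; treating the gap as a fifth
symbol is the natural alternative and deliberately not mixed in. The
progressive aligner uses +2/−1 substitution scores with affine gaps
(−10/−1); a pre-aligned FASTA can be supplied instead and skips alignment.

**OTU metrics.** Distances are MSA column mismatch fractions (internal
gaps count as differences, end-gaps and both-gap columns are ignored);
clustering is average-neighbour hierarchical, cut at 1 − threshold. MCC is
computed on the pair-level confusion; NMI is normalised by the arithmetic
mean of the two entropies (natural logs); bijection counts species whose
sequences occupy exactly one otherwise-empty cluster. Argmax thresholds
resolve ties to the lowest threshold.

**Classification.** RDP-scheme naive Bayes on distinct 8-mers: word prior
(n_w + 0.5)/(N + 1), per-taxon conditional (m_wt + prior)/(M_t + 1);
bootstrap support = fraction of 100 resamplings of ⌊W/8⌋ words voting for
the winner. Leave-clade-out cross-validation holds out whole strains (the
held-out rank is a parameter) across 5 folds; accuracy counts a prediction
only when correct *and* support strictly exceeds 0.80, over all validation
sequences (including those that fail the cutoff — the ambiguity in "all
predictions" is resolved toward the larger denominator).

## Read pipeline

Pairs are dropped when either read is shorter than 250 nt or contains N,
or when R2 carries the 16S-targeting primer (Hamming ≤ 1) within its first
40 bases (such pairs read back into the gene); the primer is trimmed from
R1 when found at edit distance ≤ 2 starting within the first 50 bases.
Merging takes the best gapless overlap (≥ 20 nt, ≤ 10 % mismatches) between
the R1 suffix and the reverse-complemented R2, with the higher-quality base
winning disagreements; candidate offsets come from exact 16-mer seeds at
three positions of the overlap, so a merge is missed only when all three
seeds carry errors.

Dereplication is exact-match collapse (size-descending, ties lexicographic).
Swarm-style clustering at distance d is single-linkage over Levenshtein
distance ≤ d, computed as connected components with length-bucket pruning
(|Δlength| > d pairs cannot link); cluster order follows total abundance.
The quantification path clusters deduplicated merged reads at d = 1
(b-clusters); the assembly path clusters the first 240 bp of forward reads
at d = 2 (a-clusters); a-clusters holding < 0.001 of the filtered pairs are
flagged not-for-assembly. Abundance per a-cluster is
a_f = (1/j) Σ_b |b ∩ a| / |b|, which sums to 1 whenever the a-clusters
partition the reads.

Contig cleanup follows the two-level rules. Within one read cluster:
keep only the dominant cluster of 5′ 230-bp prefixes (single linkage at
≥ 96 % identity, which subsumes the d = 2 step for 230-mers); drop contigs
shorter than 52 % of the maximum; drop contigs contained in a longer one at
> 98 % identity over ≥ 90 % of their length, excluding the last 20 bp.
Globally: validate each contig against a genus-labelled reference catalog —
best match must cover ≥ 90 % of the contig, start within its first five
bases, and hit a reference region with < 5 Ns; the 3′ overhang beyond the
match is trimmed; per source cluster only the genus with the largest median
contig length survives; the final containment pass removes a contig
contained at ≥ 96 % identity over 99 % of its length *unless* its
3′-terminal 15 bp or 50 bp identity against the container is below 80 %
(diverging gene copies are rescued); equal-length duplicates keep the
higher abundance. "Identity" is matches / alignment columns from aligning
the shorter sequence as an infix of the longer (end-gaps free). Copy number
per organism is the count of retained contigs. The catalog stands in for a
labelled nucleotide database so no external download is needed; assembly
itself is delegated — the cleanup accepts contigs from any assembler, and
simulated runs use ground-truth-derived fragments per cluster. Read-count
abundance from the linkage stands in for TPM quantification.

## Synthetic data: what it emulates, and what it does not

The generator builds one ancestral 16S template of nine variable windows
separated by nine conserved 20-bp primer sites plus a conserved 3′ tail
(gene length 1441; V1+p1+V2 = 341 matching the V1–V2 composite scale).
Mutations are substitutions applied down a genus → species → strain tree;
gene-rate mutations are confined to the variable windows so primer sites
stay exact, upstream-rate mutations cover the whole upstream region.
Upstream structure: the 200 bp adjacent to the gene form a shared leader;
beyond it each gene copy of a species carries its own random distal context
(drawn once per copy slot at the species level and inherited by its
strains), modelling real rRNA operons whose distal upstream flanks are
unrelated neighbouring genes. `copy_context=False` switches to a single
inherited upstream so copies differ only through intragenomic SNPs.

Default rates (substitutions/site): gene 0.02 / 0.005 / 2×10⁻⁴ at
genus / species / strain, upstream five times those values, intragenomic
2×10⁻⁴ per copy. The scale follows typical 16S identity — congeneric
species at roughly 97–99 % gene identity, strains of a species frequently
carrying identical 16S genes — while the 5× upstream excess encodes the
lower conservation of intergenic flanks. Operons are placed at
non-overlapping positions with ≥ 2 kb flanks on random strands in an
i.i.d.-uniform backbone (no GC modelling).

Read simulation mirrors the chain-termination chemistry: operons are
sampled ∝ genome abundance × copy number; a fragment is the priming
primer plus an extension whose length is geometric with termination
probability p per incorporated base (mean 1/p, capped at the template
end — p is the proxy for the terminator:dNTP molar ratio, linear in mole
fraction); R1 is the first read_len bases of the fragment, R2 reads back
from the termination point. Errors are uniform substitutions; qualities
are constant Q30. Not modelled: indel errors, quality decay along the
read, PCR chimeras, GC bias, real mock-community genomes. Tests passing on
this generator therefore demonstrate the correctness and discriminatory
logic of the algorithms under controlled divergence — not performance on
real libraries with indels, chimeras or uneven coverage.

Mock presets (`even8`, `even20`): one genus/species/strain per member,
even abundances, copy numbers drawn from 1..10 with the first member fixed
to a six-copy layout with distinct distal contexts.

## Numerical and design notes

* Edit distances are Levenshtein throughout (edlib); swarm d counts indels.
* Primer-hit selection minimises edit distance (leftmost on ties); within
  the ≤ 2-edit budget this coincides with the +1/−2/−2 maximum-score
  placement, which is still computed and reported per hit.
* The 52 % length rule and the > 98 % / ≥ 96 % identity cutoffs are strict
  as written: a contig at exactly 52 % of the maximum length is kept.
* Degenerate inputs: a single sequence aligns to itself with a warning;
  MCC is NaN when a pair-confusion marginal is empty; a member with no
  sequences is skipped with a log entry rather than failing the run.
* Problem sizes in the test suite — 4 000 read pairs for the mock-community
  recovery run, a 6×3×3 hierarchy with 4 copies per genome for the
  discrimination ordering, 10⁴ fragments for the length calibration — were
  chosen as the smallest sizes at which the checked properties are stable
  across seeds.
* On an exactly even community the copy-number-corrected abundance vector
  is constant in truth, so recovery is scored as the correlation between
  estimated and expected per-member *read shares* (abundance × copy
  number, normalised) — the same comparison up to the constant abundance
  factor — plus closeness of corrected abundances to the even profile.

## Known limitations

* The upstream window is extracted without masking neighbouring annotated
  genes; a window overlapping an adjacent gene is reported as-is.
* The b-cluster/a-cluster abundance a_f weights every b-cluster equally;
  with shallow, error-rich data it is dominated by singleton clusters and
  degrades gracefully but noisily.
* cleanup_global assigns genus by best catalog match only; no LCA logic.
* The internal progressive aligner is adequate for the short composites
  used here; genuinely large alignments should be pre-aligned externally
  and passed through the pre-aligned input path.
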