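# Methods

## Model and procedure

`kmersweep` treats each sample as a sparse vector over the space of canonical
k-mers and computes all pairwise distances between those vectors without ever
materializing them densely. The pipeline has four stages, each persisting its
artifact so runs are idempotent and resumable:

1. **Prefix histograms.** Each sample's reads are decomposed into canonical
   k-mers (every window of length k; windows containing any non-ACGT
   character are skipped, never whole reads, to keep the maximum usable
   signal while staying deterministic). A histogram of the first
   `prefix_len` letters of each *distinct* k-mer approximates the k-mer
   distribution cheaply. Distinct-record counts (not frequency mass) are
   used because the partitioning target is records per partition.
2. **Partitioning.** A greedy cumulative walk over the ascending prefixes of
   the merged histogram cuts the k-mer space into at most n half-open ranges
   with roughly equal record counts. Boundaries live at prefix granularity
   (the histogram cannot see finer structure); ties break deterministically
   at the first prefix whose cumulative count reaches the target quantile.
   When k < prefix_len, prefixes are whole k-mers and partitioning is exact.
3. **Inverted index.** Per-sample count tables (samples staged in byte-size
   groups, 4 GiB cap by default; grouping never affects results and is
   tested not to) are merged into records `kmer → ⟨sample, frequency⟩…`,
   routed to chunks by range. Raw frequencies are stored, never weights, so
   one index serves every weighting scheme. Chunks are sorted plain text
   with a JSON sidecar: bit-exact, diffable, language-neutral.
4. **Sweep.** Each partition is scanned once in k-mer order; a record with m
   postings updates its m(m−1)/2 unordered sample pairs. Per-pair partial
   sums use compensated (Kahan) summation, and partitions merge by exact
   addition in ordinal order, which is why partition- and worker-count
   invariance holds to 1e-12 and better. Workers are separate processes
   with no shared mutable state; the merge is the only synchronization
   point.

## Distances and numerical choices

- **Cosine** (default): d = 1 − D/(M₁M₂). Nonnegative weights make the
  distance fall in [0, 1]; a dot product below −1e-12 or a distance outside
  [−1e-12, 1 + 1e-9] raises an error (it would indicate accumulator
  corruption), and sub-epsilon residues are clamped into [0, 1].
- **Bray-Curtis**: d = 1 − 2Σmin(w₁,w₂)/(Σw₁+Σw₂) on the weighted vectors —
  the standard abundance form.
- **Jensen-Shannon**: the divergence itself (not its square root) on
  probability vectors p = w/Σw, log base 2, so it is bounded in [0, 1]. It
  needs the per-sample weight totals before the sweep, hence a two-pass
  schedule: a vectorized norms pass, then the sweep. K-mers private to one
  sample contribute p/2 per side; these are recovered at finalization as
  half of each side's unshared probability mass (1 − shared mass), which
  the sweep tracks per pair.
- **Logarithm base**: natural log for logarithmic weighting. For cosine the
  base only rescales vectors uniformly and is unobservable; for Bray-Curtis
  and Jensen-Shannon it is observable, so it is documented and fixed here.
- **Empty samples**: distance 1 to any non-empty sample, 0 to another empty
  sample, diagonal exactly 0; a warning is logged.
- Pairwise accumulators are dense upper-triangle arrays over the roster —
  O(S²) memory, acceptable because sample count (not read count) bounds it.

Defaults: k = 21 (the point where k-mer matches become read-representative
while staying resilient to sequencing error; fully configurable),
logarithmic weighting, cosine metric, prefix_len = 6, min_freq = 1 (no
abundance filter by default; `--min-freq 2` reproduces a common
comparison-tool convention).

## Synthetic data: what it emulates and what it does not

The generator emulates *staggered mock communities*: defined genome mixtures
whose relative abundances are log-spaced across several orders of magnitude
(default 6 decades), from which error-bearing reads are drawn (genome chosen
by abundance, start and strand uniform, i.i.d. substitutions at a configured
rate). Genomes are i.i.d. uniform ACGT: at k = 21 the profiles of different
genomes are near-orthogonal, which makes community-separation tests sharp
and download-free; tests that want overlapping profiles use smaller k.
Everything is reproducible from integer seeds, byte-for-byte.

`make_mock_series` builds the four-community evaluation design: mock2
inverts the abundances of three disjoint pairs of *abundant* members, mock3
inverts two further pairs, mock4 spikes in foreign genomes (default 2
genomes carrying 30% of the community). Two design choices matter:

- Inversions are drawn from the 10 most abundant members. The altered
  species in this design are abundant ones; a uniformly random inversion
  would frequently land on members whose expected read count at desk scale
  is ~0 and produce no observable signal — a statistical-power artifact,
  not a property of the method.
- mock3's further inversions are drawn from the abundant members mock2 left
  untouched, so its alterations accumulate on top of mock2's and the total
  abundance displacement from mock1 strictly increases by construction
  (asserted at build time). Without disjoint supports, extra transpositions
  inside an already-permuted set can cancel earlier ones.

What passing the separation test shows: the pipeline resolves ordered
abundance perturbations of the same magnitude structure as the classic
mock designs, at 10,000 reads per sample. What it does not show: behaviour
on real genomes (shared k-mer content between related taxa compresses
distances), platform-specific error profiles (the error model is
substitution-only; no indels, no quality-dependent rates), or performance
at ambitious read depths.

Read-simulation error model: substitutions only. This is sufficient to
exercise k-mer robustness; indel-bearing platform error models are a
non-goal.

## Problem sizes in the tests and acceptance script

The test suite runs randomized pipeline-vs-brute-force equivalence at up to
6 samples × ~900 reads (k ∈ {5, 11, 21}, all nine weighting × metric
combinations, tolerance 1e-9), metric-axiom checks over 100 random
instances, and the mock-series separation over 40 replicates at 10,000 reads
per sample. The acceptance script uses one 50,000-read sample (150 bp, 1%
error) plus its 2× and 10× self-concatenations — sizes chosen so a complete
run finishes in minutes on a laptop core while every k-mer-level effect the
larger designs probe (depth scaling, duplication invariance, stepwise
separation) is still measurable.

## Known limitations

- Ward linkage is applied to the distance matrix directly, as is
  conventional for this kind of heatmap/dendrogram post-processing, although
  cosine or Jensen-Shannon distances are not Euclidean; the dendrogram is a
  visualization aid, not an inferential tree.
- The index is plain text; for very large runs a binary/compressed chunk
  format would cut I/O severalfold (explicitly out of scope).
- Paired-end mates are independent inputs; there is no mate pairing, quality
  filtering, or trimming inside the tool.
- The sweep's inner pair loop is pure Python over CSR arrays; it is the
  dominant cost for many-sample runs and would be the first candidate for
  compilation if scaled up.
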