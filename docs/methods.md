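# Methods

## Model and assumptions

The score treats a bulk expression profile as a state of the
protein-interaction network (PIN). Each gene *i* with neighbor set `J_i`
gets a mass-action neighbor distribution: the probability of interacting
with neighbor *j* is `e_j / Σ_{k∈J_i} e_k`, with `e` the (log2-normalized,
non-negative) expression values. The per-gene divergence between two
samples is the Jensen–Shannon divergence of these distributions; nJSD is
its mean over genes, and

    tITH = NT / (NT + TA),

with NT the nJSD from a normal reference to the tumor and TA the nJSD from
the tumor to the maximally ambiguous state A (constant expression ⇒ uniform
neighbor distributions). The model's assumptions, made explicit:

* interaction propensity scales linearly with the partner's expression
  (no edge weights, no binding constants — confidence scores on edges are
  used only as a load-time filter);
* the PIN is undirected and simple; topology enters only through neighbor
  sets;
* the normal reference is a pooled per-gene mean of normal samples
  (per-cohort, not per-patient);
* probabilities compare expression *within* a gene's neighborhood, so any
  per-sample global rescaling of expression cancels exactly (scaling
  invariance).

## Conventions and numerical choices

* **Log base 2** throughout, so each per-gene JSD ∈ [0, 1]. The tITH ratio
  is base-invariant (a base change rescales NT and TA by the same factor);
  the low-level functions expose a `base` argument used in tests to verify
  this.
* **0·log(0/x) := 0.** The JSD mixture `M = ½(P+Q)` is positive wherever
  either distribution is, so no division by zero arises; a direct KLD call
  with a support violation raises instead of returning infinity.
* **Missing genes**: a neighbor absent from either profile is dropped from
  *both* states' neighbor lists, keeping the two distributions aligned on a
  common support. The averaging universe is network ∩ both profiles.
* **Degenerate genes**: if a gene's neighbor-expression sum is zero in
  either state, its distribution is undefined; the gene is excluded from
  the average and counted (`n_genes_skipped`), never imputed — imputing
  uniform would silently pull divergences toward state A.
* **Identical gene sets for NT and TA**: state A is built on the same
  restricted universe as NT, and a gene enters the averages only if its
  distribution is defined in the normal state, the tumor state and state A,
  so the ratio never mixes averages over different gene sets. This is also
  what makes the pathway partition identity (count-weighted per-set means
  reproduce the global values) hold exactly.
* **NT + TA = 0**: reported as tITH = 0 with a `degenerate` flag rather
  than NaN.
* Per-gene computation is vectorized (CSR-style neighbor index +
  `scipy.special.rel_entr` with segment sums); equality with a literal
  dictionary-and-`log2` loop transcription is asserted to 1e-12 over all
  graphs on ≤5 nodes in the test suite. Tiny negative rounding residues
  (> −1e-12) are clipped to 0.
* Neighbor lists and gene universes are lexicographically sorted, so
  summation order is fixed and nJSD(X, Y) = nJSD(Y, X) holds exactly, not
  just to rounding.

## Pathway scores

Pathway-tITH restricts only the *averaging* step to a gene set's members;
neighborhoods remain full-network. The alternative reading — rebuilding
neighborhoods inside the pathway-induced subgraph — is exposed as an
off-by-default `induced_subgraph` mode; it changes degree structure
substantially (many pathway genes become isolated) and breaks the partition
identity, which is why it is not the default. The covariate screen reports
raw two-sided Pearson p-values by default (callers choose their threshold;
p < 0.001 is a conventional choice at KEGG scale) with optional
Benjamini–Hochberg q-values.

## Synthetic data: what it emulates, what it does not

`generate_synthetic_cohort` emulates a clone-mixing study design: a
baseline profile with log2 values drawn N(`baseline_logmean`,
`baseline_logsd`) clipped at 0 (default 3.0 ± 2.0, a plausible spread for
log2 expression), per-clone profiles obtained by adding independent
N(0, `clone_divergence`) perturbations per gene (default s.d. 1.0 — a
2-fold typical shift, strong but realistic clonal divergence), and a
connected random PIN (Barabási–Albert with 3 attachment edges by default,
matching the heavy-tailed degree distribution of real PINs; Erdős–Rényi
available). Bulk samples are arithmetic means of clone columns on the log2
scale, mirroring how already-log-transformed profiles were averaged in the
mixing design; a linear-scale mode (mixing 2^x − 1 abundances, the way
physical RNA pools) is provided but not the default.

Deliberately **not** modeled: read-count noise, single-cell dropout,
library-size effects, gene–gene correlation in the perturbations, and
stromal/immune admixture. Passing simulation tests therefore demonstrates
the *mechanism* — averaging divergent clones flattens neighbor
distributions toward state A — not calibration on any real cohort.

Desk-scale problem sizes, chosen as the package's standard study
conditions: 200 genes, 128 clones, 100 replicates per mixture size for the
mixing trend; 50 clones and 100 seeded runs for the bulk-vs-cells z-score
power and null calibration. The z statistic uses the sample (n−1) standard
deviation of the single-cell distances and a one-sided lower-tail normal
p-value (the hypothesis is directional: bulk closer to state A). Mixture
members are drawn without replacement within a mixture, independently
across replicates.

## Open design choices taken

* **Combining formula**: tITH = NT/(NT+TA), the simple combination
  consistent with a [0, 1] range and the two-distance construction
  (tITH→0 as tumor→normal, →1 as tumor→state A).
* **Duplicate gene rows** collapse by maximum (configurable to mean);
  negatives are rejected rather than clipped, since the probabilities
  require non-negative expression.
* **Normal aggregation** averages on the log2 scale (a linear-scale option
  exists behind a flag).
* **Upstream normalization** (e.g. upper-quartile before log2) is the
  caller's responsibility; by scaling invariance, per-sample global factors
  have no effect anyway.

## Limitations

* Scores depend on the chosen PIN and its confidence cutoff; comparisons
  are meaningful within one network, not across networks.
* Stromal/immune admixture also flattens bulk profiles and inflates the
  score; on real cohorts tITH should be interpreted alongside purity
  estimates.
* Genes missing from the PIN or unmeasured are silently outside the
  universe (counts are reported); very sparse pathways may have too few
  usable genes for a stable pathway score.
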