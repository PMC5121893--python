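# tith — network-entropy scoring of intratumor heterogeneity from bulk RNA-seq

A heterogeneous tumor is a mixture of transcriptionally divergent subclones.
Bulk RNA-seq averages over them, and on a protein-interaction network (PIN)
that averaging shows up as *ambiguity*: expression differences between a
gene's neighbors get washed out, so every gene's interaction preferences
drift toward uniform. `tith` quantifies that drift and turns it into a
per-sample heterogeneity score, for anyone who has bulk tumor expression,
matched normals, and a PIN edge list — no somatic variant calling required.

## The model

Under a law-of-mass-action assumption, the probability that gene *i*
interacts with neighbor *j* in sample *X* is proportional to *j*'s
expression:

```
p_ij = e_j / Σ_{k ∈ J_i} e_k
```

where `J_i` is *i*'s neighbor set in the PIN. The vector
`PD_i(X) = (p_i1, …, p_in)` is gene *i*'s neighbor distribution. Between two
samples the gene's divergence is the Jensen–Shannon divergence (base-2 logs,
so each gene's JSD ∈ [0, 1]):

```
JSD_i = ½·KLD(PD_i(N) ‖ M) + ½·KLD(PD_i(T) ‖ M),   M = ½(PD_i(N) + PD_i(T))
```

and **nJSD(N, T)** is the mean `JSD_i` over all usable network genes. With

* **NT** = nJSD(normal reference, tumor), and
* **TA** = nJSD(tumor, state **A**) — state A being the maximally ambiguous
  reference in which every gene is expressed equally, so every neighbor
  distribution is uniform —

the transcriptome-based intratumor heterogeneity score is

```
tITH = NT / (NT + TA)  ∈ [0, 1]
```

Tumors transcriptionally close to their normal tissue score near 0; tumors
whose network state has flattened toward state A — the signature of a
many-clone mixture — score near 1. **Pathway-tITH** is the same ratio with
NT and TA averaged only over one gene set's genes, quantifying perturbation
of a single pathway.

## Worked example

Three genes on a star network (`TP53` interacting with `MDM2` and `ATM`),
one normal, two tumors:

```bash
tith score --expr tumors.tsv --normals normals.tsv --network net.tsv --out out/
cat out/tith.tsv
```

```
sample	NT	TA	tITH	n_genes_used
t1	0.06290729184695572	0.0162649802317995	0.7945621641927847	3
t2	0.0162649802317995	0.0	1.0	3
```

The normal has `MDM2=1, ATM=3`, so TP53's neighbor distribution is
(0.25, 0.75). Tumor `t1` reverses it to (0.75, 0.25): a large shift from
normal (NT ≈ 0.063) but still some distance from uniform (TA ≈ 0.016),
giving tITH ≈ 0.79. Tumor `t2` has equal neighbor expression — exactly
state A — so TA = 0 and tITH = 1. The two leaf genes have a single neighbor
each (point-mass distributions), contribute JSD = 0, and dilute both
averages equally; `n_genes_used` reports how many genes entered them.

The same computation as a library, scikit-learn style (frames are
samples × genes; compose with sklearn pipelines and model selection):

```python
from tith import TITHScorer, load_expression, load_network

net = load_network("net.tsv")
normals = load_expression("normals.tsv")   # genes × samples
tumors = load_expression("tumors.tsv")
scores = TITHScorer(network=net).fit(normals.T).transform(tumors.T)
```

Other entry points: `tith pathway` (per-pathway scores from a GMT, plus a
Pearson screen against an external covariate such as a genome-based clone
count), `tith simulate` (synthetic clone cohorts, random PINs, and the
clone-mixing experiment), and `tith mix` (bulk mixtures of expression
columns). Every command writes a JSON run manifest alongside its outputs.

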