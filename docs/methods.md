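# Methods

## Consensus by robust rank aggregation

Each driver-calling strategy k = 1..K emits an ordered list of candidate
genes over a shared universe of n protein-coding genes; real callers emit
only the genes they deem significant, so lists are truncated and mutually
incomplete. A gene found at 1-based position p in a list receives the
normalized rank p/n. The **denominator is the shared universe size**, not
the individual list length: this makes a rank of 5 mean the same thing in a
50-gene list and a 500-gene one, which is what lets truncated lists be
aggregated at all.

Under the null that each strategy ranks genes uniformly at random, the j-th
smallest of a gene's normalized ranks is distributed like the j-th order
statistic of K independent Uniform(0,1) variables, i.e. Beta(j, K−j+1).
The score

    rho = min_{j=1..k} I_{r_(j)}(j, K−j+1)

(I the regularized incomplete beta function, evaluated by
`scipy.special.betainc`) asks, at each order-statistic position, how
surprising it is that the gene's j best ranks are all that small, and keeps
the most surprising answer. Genes absent from a list contribute **no**
order statistic rather than an imputed worst rank — a caller that stayed
silent is treated as uninformative, not negative, which is the source of
the method's robustness to missing predictions. A gene ranked by no list
scores rho = 1.

Because rho takes a minimum over K dependent tests, it is not itself a
p-value; the Bonferroni correction p = min(1, K·rho) over the K positions
restores a conservative p-value (the published default of the rank
aggregation method this implements). The consensus list is ordered by
ascending rho, ties broken by descending number of supporting lists, then
lexicographic gene symbol — deterministic output is a hard requirement for
reproducible pipelines. No simulation is used in the production path; the
Monte-Carlo order-statistic oracle exists only in the tests.

Whether the consensus list is truncated before downstream use (e.g. to its
top 100) is an explicit CLI parameter, never an assumption.

## Exact multi-set intersection significance

The null model treats each strategy's predicted set A_i as an independent
uniform random subset of size n_i from a background of N protein-coding
genes. The distribution of |A_1 ∩ … ∩ A_m| is built by sequential
conditioning: after one set the running intersection is the set itself
(size n_1 with probability 1); intersecting with set i+1, the new overlap z
given the current overlap y is hypergeometric with population N, y
successes and n_{i+1} draws. The recursion is evaluated with
`scipy.stats.hypergeom.logpmf` and log-sum-exp, i.e. entirely in log space:
high-order intersections of large lists produce p-values far below float
underflow, and the −log10 p reported alongside p is computed from the log
value directly. This formulation was chosen over a closed-form product
expression because it reduces *exactly* to the two-set hypergeometric test
and is verifiable against exhaustive enumeration at small N.

`all_subset_intersections` tests every combination of ≥ 2 of the m named
sets (2^m − m − 1 tests; 57 for six strategies), each reported with the
observed overlap, the expectation N·Π(n_i/N), the fold enrichment, and the
exact upper-tail p-value P(X ≥ observed) (1 when the observed overlap
is 0). N is a required input with no default — it must be the user's
protein-coding background — and genes in a predicted set but absent from a
supplied background are a hard error, because silently inflating N would
bias every p-value anticonservatively.

## Evaluation metrics

**Top-N-Precision** against a membership reference is
|top-n ∩ reference| / n. When the predicted list is shorter than n the
denominator is the number of genes actually evaluated, not n: a short list
should not be penalized once for missing genes and again by a fixed
denominator. (Published uses of the metric only evaluate lists longer than
n, so the convention only matters at the margins.)

**Top-N-nDCG** against a weighted reference: reference gene g has weight
w(g) = (count(g)/total_count) · (G − rank(g)), where counts are per-gene
driver-mutation counts, G the reference size, and ranks descend by count
with lexicographic tie-breaks. The formula forces the bottom-ranked
reference gene to weight exactly 0; that is preserved, not smoothed. Genes
outside the reference have weight 0. Then

    CG_n  = Σ_{i=1..n} w_i
    DCG_n = w_1 + Σ_{i=2..n} w_i / log2(i)
    nDCG_n = DCG_n / IDCG_n,

with IDCG_n the DCG of the reference's own descending-weight ordering
truncated at n (including zero-weight tail genes when n exceeds the count
of positive weights). The per-gene discounted form of DCG is used; a
summation of cumulative gains over positions would be non-standard and
inconsistent with a per-position discount factor 1/log2(i). nDCG is defined
as 0 when IDCG_n = 0 (a degenerate, e.g. single-gene, reference), keeping
the metric total and bounded; by the rearrangement inequality it always
lies in [0, 1]. The default evaluation depth is n = 100, the conventional
depth for driver-gene benchmarks; it is configurable everywhere.

Pan-cancer summaries average per-cancer-type precision or nDCG at a fixed
depth; the denominator is the number of cohorts supplied, never a
hard-coded count.

## MAF ingestion

The reader accepts the TCGA MAF column set or a reduced micro-MAF dialect
whose mandatory columns are Hugo_Symbol, Tumor_Sample_Barcode and
Variant_Classification (the minimum the pipeline consumes); positional
columns are optional and sentinel-filled (positions 0, alleles "-").
Column lookup is by header name, `#` comments are skipped, and malformed
integer positions are reported with their line number — the reason this
parser is hand-written rather than delegated to a DataFrame reader. Cohort
summaries count **every** data row, silent mutations included: published
per-cohort means are consistent with raw record counts and no filter is
stated anywhere authoritative. Means are rounded half-up to 2 decimals to
match the printed precision of such tables. Gene symbols are matched
case-sensitively after whitespace stripping; alias resolution would require
an external database and is out of scope. Genomic coordinates are
pass-through, so reference genome builds are irrelevant here.

## Synthetic planted-driver benchmark

The simulator generates what the pipeline assumes but with known truth:

* **Rankings:** gene scores s_{g,k} = β_k·[g is driver] + ε_{g,k},
  ε ~ N(0,1) i.i.d.; each strategy ranks by descending score and truncates
  to its top L. The additive-normal model was chosen over a Mallows
  permutation model because its behaviour has closed-form sanity checks
  (β = 0 is exactly a uniform random ranking; large β pushes every driver
  into every list with computable probability). Defaults: universe 2000
  genes, 30 drivers, K = 6 strategies with β = (2.5, 2.0, 2.0, 1.5, 1.5,
  1.0), lists truncated to L = 200. The heterogeneous β emulate six callers
  of complementary, unequal power; truncation to 10% of the universe
  exercises the incomplete-ranking path that motivates RRA.
* **Cohorts:** exactly M mutation records over exactly S distinct sample
  barcodes (each barcode used at least once), a fixed rounded share of
  records hitting drivers, the rest uniform over passengers.
* **References:** a membership reference sampling 80% of the planted
  drivers (real catalogues are incomplete), and a weighted reference with
  geometric counts (support ≥ 1) whose mean is 8× larger for drivers, so
  reference weight correlates with truth without copying it.

Every generator takes an explicit seed and instantiates its own
`numpy.random.default_rng`; no global state, and identical configuration
gives bitwise-identical output.

What the simulator does **not** emulate: mutational signatures,
trinucleotide context, per-gene covariates (replication timing,
expression), inter-strategy error correlation, or gene-length effects.
Passing the synthetic benchmark therefore shows that the aggregation,
intersection and evaluation machinery behaves correctly under its stated
null and signal models — not that any particular caller combination works
on real tumors.

The benchmark harness (`planted_driver_benchmark`) runs 20 independent
simulations at the defaults, aggregates each into a consensus, and compares
mean Top-50-Precision (against the planted drivers) and Top-50-nDCG
(against the synthetic weighted reference) between the consensus and each
strategy. The problem size — 2000 genes, 20 seeds — keeps the full run in
seconds while leaving the consensus-vs-best-single gap far larger than the
seed-to-seed noise.

## Numerical choices and edge cases

* Beta CDFs via the regularized incomplete beta; intersection recursion in
  log space; pmf normalization verified to 1e−12.
* Fold enrichment is observed/expected, with an infinity sentinel when the
  expectation is 0 but an overlap was observed.
* Report serialization: p-value-like columns in scientific notation
  (p = 1e−300 must survive a TSV round trip), other floats to 4 decimals;
  fixed column order; byte-identical reruns under identical inputs.
* Ties everywhere (reference counts, rho, consensus) break
  deterministically, ending in lexicographic gene symbol.
* Degenerate inputs: empty MAF → empty record list (not an error); empty
  gene-set file → warning + valid empty set; empty rank vector → rho 1;
  observed overlap 0 → p 1; IDCG 0 → nDCG 0.

## Known limitations

* The six external callers themselves are out of scope; the package starts
  from their ranked lists.
* No gene-symbol alias resolution; inputs must share a nomenclature.
* The intersection null assumes independent uniform sets; real callers
  share inputs and biases, so its p-values overstate surprise for
  correlated callers. They are comparative scores, not literal error rates.
* Bonferroni over order-statistic positions makes the aggregation p-values
  conservative (measured null false-positive rate at 0.05 is ≈ 0.04).
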