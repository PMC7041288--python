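# Methods

## Model and assumptions

`hetlink` treats link prediction between two designated *target* node
types of an attributed heterogeneous network (here: ncRNAs and diseases)
as a three-stage procedure: pair scoring by meta-path sequence
similarity, hierarchical overlapping multi-type clustering, and
cluster-cohesiveness prediction. The method is transductive — it scores
only pairs among nodes present at training time — and rests on a network
autocorrelation assumption: nodes that are close in the network, or that
are wired into similar neighbourhoods, tend to carry similar attribute
profiles, and target pairs embedded in mutually similar neighbourhoods
are more likely to interact.

### Stage 1 — pair scoring

Meta-paths are enumerated over the schema from the ncRNA type to the
disease type, bounded at `max_path_len` edges (default 3) and with no
repeated node type. The bound keeps enumeration finite and mirrors the
observation that informative routes in these networks have one or two
intermediate hops; the type-repetition ban removes type-level cycles.

`pathscore(P, n, d)` is 1 when some instance of P runs from n to d —
connectivity along an admissible route is taken as full certainty, with
the direct ncRNA–disease edge as the special case — and otherwise the
maximum attribute-profile similarity between instances starting at n and
instances ending at d. Pair scores compose across meta-paths by maximum
(fuzzy OR): one convincing route suffices, and adding meta-paths can
never lower a score.

Numeric attribute similarity is range-normalised with the **global**
per-(type, attribute) minimum and maximum over the whole network, not
per meta-path: global stats keep the normalisation stable across
meta-paths and folds. Degenerate cases are fixed as follows: a constant
numeric attribute (max = min) compares as 1 when both values are
present; attribute pairs with a missing value are dropped from both the
numerator and the denominator of the sequence-similarity mean (pairwise
deletion — sparse annotation is not evidence of dissimilarity); when no
attribute pair is comparable at all the similarity is 0, with a warning.

Node types that appear on no meta-path are not discarded: their
attributes are aggregated — arithmetic mean for numeric, mode for
categorical, ties resolved to the lexicographically smallest label for
determinism — onto adjacent on-path nodes, following connections through
off-path nodes up to `depth` hops (default 2, which keeps the
aggregation local to the meta-path neighbourhood). Missing aggregates
stay missing; nothing is imputed.

Sequence materialization enumerates all simple instances of each
meta-path in lexicographic node-ID order, capped at `seq_cap` per
starting and per ending node (default 1000). The cap bounds the
worst-case exponential blow-up; lexicographic truncation keeps runs
byte-reproducible. Truncation is flagged with a warning.

### Stage 2 — hierarchy construction

Retained relationships are the pairs with `s ≥ β` (default 0.4; the
companion cohesiveness floor α defaults to 0.2 — both sit in the range
where the method is typically operated, β ∈ {0.3, 0.4}, α ∈ {0.1, 0.2}).
Cluster cohesiveness sums the **retained** pair scores and divides by
*all* possible ncRNA×disease pairs of the cluster, so unretained pairs
dilute h; this is the reading under which the reference worked example
(h = 0.4 for the 2×3 cluster with retained scores 0.7 + 0.8 + 0.9, and
h = 0.3 for the 1×2 cluster with a single 0.6) comes out exactly.

The merge order `C′ < C″ ⟺ h(C′) > h(C″)` is only a strict partial
order; it is refined to a deterministic total order by (fewer possible
pairs, then lexicographically smallest member tuple). Level 1 iterates
greedy merging — each cluster fuses with the first later cluster in the
sorted list whose union is still a biclique over the retained pairs,
re-sorting after every merge — to a fixpoint. Levels 2..k replace the
biclique test with `h(union) > α` and perform **one** pass per level, so
each level corresponds to one round of merging; clusters that find no
partner carry over unchanged (coverage of target nodes never shrinks),
duplicate clusters created by overlapping merges are deduplicated, and
the hierarchy ends at the first pass with no merge. Every produced level
is therefore strictly smaller than its predecessor and every cluster
above level 1 contains at least one cluster of the previous level.

### Stage 3 — prediction

A pair contained in m clusters of level w (ordered by decreasing h as
C₁..C_m) is scored by one of: maximum, minimum, average, or evidence
combination `ec(C₁) = h(C₁)`, `ec(C_i) = ec(C_{i−1}) +
(1 − ec(C_{i−1}))·h(C_i)`. EC dominates the other three and rewards
pairs suggested by several cohesive clusters. Pairs in no cluster at a
level are omitted from the table and treated as score 0 by the
evaluation — ψ is defined only through clusters. By default the ranked
output excludes the training positives, listing only new candidates;
ties are broken lexicographically on (ncRNA, disease) so top-k
evaluation is reproducible.

## Evaluation protocol

Ten-fold cross-validation partitions the known positive **pairs** (not
nodes — node cold-start is out of scope); each training network drops
that fold's direct target edges and keeps all nodes. TPR@k is the
fraction of held-out positives ranked in the top k after appending all
unranked candidates at score 0 in lexicographic order. AUTPR@k is the
area of the right-continuous TPR@k step curve over k ∈ [1, k_max]
(equivalently `Σ_{k=2..k_max} TPR@k / (k_max − 1)`), normalised so a
ranking that places every positive at the very top scores exactly 1;
k_max defaults to 5000. ROC and PR curves treat every non-validated
candidate pair as negative; because genuinely novel links violate that
assumption, the resulting AUROC/AUPR support only relative comparison
between rankings, and the implementation labels them accordingly.

## Synthetic data

The generator plants block structure: each cluster owns a set of
ncRNAs, diseases and genes; direct ncRNA–disease edges appear within a
block with probability 0.9 and across blocks with probability `p_noise`
(default 0); ncRNA–gene and gene–disease wiring is dense (0.9) within a
block; two proteins hang off each gene, reachable by no meta-path, so
they exercise the attribute-propagation path. Attributes are
block-correlated: numeric values are drawn around per-block means spaced
3.0 apart with shared noise SD 0.5; categorical values take a per-block
dominant label flipped with probability 0.1, including a per-block
marker label on every node type so that blocks are separable even when
1-D numeric means force adjacent blocks to look alike. Defaults (3
blocks of 4 ncRNAs × 5 diseases × 3 genes, plus 2 background genes)
keep a single run around a tenth of a second, which is the problem size
used by the repeated-seed test batteries.

What the generator does *not* emulate: the heavy-tailed degree
distributions, annotation sparsity patterns and attribute semantics of
the curated ncRNA–disease resources. Recovery results on planted blocks
therefore show algorithmic correctness (the pipeline finds the structure
it is designed to find, and degrades as noise grows), not expected
performance on real curated networks.

Exact level-1 recovery is asserted under zero noise (`p_noise = 0`,
`categorical_flip = 0`): then cross-block pairs can only score through
numeric similarity, which is bounded well below β = 0.4 once categorical
attributes never match across blocks, while intra-block pairs score 1
through connectivity. With flips enabled, the max over many sequence
pairs has heavy tails and occasional cross-block scores above β are
expected — those configurations are used for the invariant and
degradation tests instead.

## Numerical and design choices

- Scores, cohesiveness and aggregates are plain floats; equality checks
  in tests use exact comparison where the arithmetic is exact (counts,
  0/1 saturation) and 1e-12-level tolerances elsewhere.
- Edges are stored typed but traversed undirected; meta-paths are node
  sequences, not directed walks.
- Edge attributes are loaded and preserved but feed no computation —
  similarity is defined over node attributes only.
- Node IDs are case-sensitive opaque strings, unique per type.
- The evidence-combination recursion consumes clusters in decreasing-h
  order; appending zero-cohesiveness clusters leaves it unchanged.
- All randomness (generator, fold splits) flows through
  `numpy.random.default_rng` seeds; identical inputs and parameters
  give byte-identical outputs.

## Known limitations

- The greedy merge is quadratic-to-cubic in the number of retained
  pairs; the implementation targets curated-network scales (thousands of
  retained pairs), not genome-wide all-vs-all matrices.
- Scores are degrees of certainty, not calibrated probabilities, and
  carry no direction or causality.
- The unknowns-as-negatives ROC/PR numbers are structurally pessimistic
  and must not be read as absolute performance.
- `pathscore` saturates at 1 for any pair connected within
  `max_path_len` edges along an admissible meta-path; in densely
  connected networks the β filter therefore does most of its work
  through connectivity rather than attribute similarity.
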