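# Methods

This note records the model, the numerical and design choices, what the
synthetic-data generator does and does not emulate, and the known
limitations. Notation follows the README: dosages $a_{ik}$, power $p_{ijk}$,
heterozygosity weight $h$, adjacency weights $q_{kl}$, objectives $f(x)$ and
$g(x)$, depth $h(x)$.

## Problem setting and assumptions

Three assumptions define the scope: (1) the maternal parent is known and is
homozygous at every marker used; (2) the candidate paternal population is
closed (the true father is among the candidates); (3) every candidate is
genotyped at all markers under consideration. Under (1) the offspring's
dosage of the non-maternal allele *is* its paternal gamete, which makes both
the power definition and exclusion assignment direction-free with respect to
the mother. Loading recodes genotypes so the maternal allele is the
reference (mother = 0 everywhere); markers where the mother is heterozygous
or missing are discarded because gamete origin is ambiguous there.

## Discriminatory power and the feasibility constraint

$p_{ijk}$ takes values $\{0, h^{-1}, 1, h\}$ only. The constraint
$\sum_k p_{ijk} x_k \ge h$ has a deliberate double role: a single opposing
homozygote ($p = h$) satisfies a pair outright, while pairs without any such
marker — parent–offspring pairs can never have one — must stack $h$ units of
hom–het evidence. $h$ is accepted as any positive real (the $h^{-1}$ branch
makes non-integer values meaningful), though integer $h$ between 8 and 16 is
the practical range: larger $h$ buys redundancy and missing-data tolerance
at the cost of markers.

An important consequence, quantified by the test suite: the constraint
guarantees *deterministic* exclusion only through opposing homozygotes. A
hom–het marker excludes a wrong candidate only when the heterozygote sits on
the true father's side, and then only with probability 1/2 per offspring. A
pair covered by $k$ unit-power markers in the relevant direction is missed
with probability $2^{-k}$, so panels optimized at $h = 8$ leave a few
percent of close-relative comparisons unresolved by pure exclusion, while
$h = 16$ drives the residual toward zero. This is inherent to the
formulation, not to the optimizer: accuracy is monotone in $h$, which is the
intended control.

Pairs whose total power over *all* markers is below $h$ (clones, duplicated
accessions) can never be separated; they are dropped before optimization and
reported, rather than rendering the whole model infeasible.

## Adjacency weights

$q_{kl}$ (populated strictly for $k > l$) is 1 across chromosomes and
$(|B_k - B_l|/D)^{-1}$ within one, with $D$ the shared chromosome length —
a physical-distance proxy for linkage disequilibrium, since downstream
parentage inference assumes independent loci. Weights are kept exact and
uncapped; adjacent markers can receive arbitrarily large penalties, which
only strengthens their avoidance. Coincident same-chromosome positions are
rejected (the weight is undefined). Markers absent from the map are placed
on private pseudo-chromosomes (weight 1 against everything): with no
position, no distance penalty can be claimed, which is the conservative
choice. Genetic-map (cM) distances would be the more principled weight but
are out of scope.

## Exact optimization

Both models run on HiGHS branch-and-bound through `scipy.optimize.milp`
behind a thin adapter whose contract is binary variables, linear
constraints, and a proof of optimality or an explicit status and gap; any
MILP backend meeting it would do. The quadratic objective is linearised
with one binary $y_{kl} = x_k x_l$ per pair with $q_{kl} > 0$ and the
standard linking rows; because the objective minimises non-negative $q$,
the linking rows force $y$ to the product exactly, which is re-checked on
every returned assignment. The reported $g$ is recomputed independently
from $Q$ and must agree with the backend objective within $10^{-6}$.

Numerical choice: with integer $h$ the pair-constraint rows are scaled by
$h$ to the integer coefficient set $\{1, h, h^2\}$ (right-hand side $h^2$),
avoiding solver tolerance issues on the $h^{-1}$ entries. Feasibility
comparisons elsewhere use an absolute slack of $10^{-9}$ on accumulated
power sums. The default time limit is 3600 s; at full germplasm scale the
exact quadratic model is not a desk computation, which is precisely why the
heuristics exist. An optional lexicographic second pass (fix $g^*$,
minimise $f$) is off by default: the adjacency model as defined minimises
$g$ alone.

## Greedy constructor

The residual $r_{ij}$ starts at $h$ and tracks the power each pair still
needs; marker value is $z_k(r) = \sum_{ij} \min(p_{ijk}, r_{ij})$, so
already-covered pairs contribute nothing. The score divides by
$\mathrm{denom}(k) = 1 + \sum_{l \in \text{selected}} q_{kl}[q_{kl} > 1]$,
i.e. one plus the summed same-chromosome adjacency weights between $k$ and
the current selection. Two natural versions of this discount exist — an
indicator count of nearby markers over the whole pool, or a weight sum over
the existing solution; this implementation uses the existing-solution
weight sum (the point of the discount is to penalise proximity to what is
already chosen) with the +1 guaranteeing a well-defined, purely
power-driven first pick. Ties on the
score break to the lowest marker index, making the whole constructor
deterministic. Each iteration strictly reduces $\sum r_{ij}$, so
termination is guaranteed once infeasible pairs have been dropped; a
remaining uncoverable residual is a hard error.

## Neighborhood search

Each round runs a 1-flip pass (drop any marker whose removal keeps all
pairs at $h$; this lowers $f$ and cannot raise $g$) followed by a 2-flip
pass. For each selected $s$, candidate replacements are the top
$\lceil v \cdot |\text{non-selected}| \rceil$ markers by absolute genotypic
correlation with $s$ (pairwise-complete Pearson; zero-variance columns get
correlation 0) — only markers carrying similar information can cover for
$s$, which is what makes the $v$ truncation effective. At least one
candidate is always examined. A swap is accepted when it stays feasible and
strictly lowers $g$, or ties $g$ and strictly raises the depth $h(x)$
(median pair power, midpoint convention for even pair counts); the depth
criterion only ever breaks $g$-ties — it exists to escape early convergence,
and the test suite contains a minimal instance where it is the only way out
of a local optimum. Acceptance is first-improvement in candidate order
(cheaper than best-improvement and order-deterministic). The search stops
after a full round without change or `max_rounds` (default 50; synthetic
runs converge in well under 10). Defaults: $v = 0.2$.

## Dataset-construction filters

`filter_maf` keeps markers with minor-allele frequency (missing excluded
from the denominator) at or above the floor, default 0.05. The spacing/LD
prune scans each chromosome in (position, marker id) order — the id breaks
position ties — removing the later marker of any pair closer than 10 kb,
then the later marker of any pair within a 50-locus window whose squared
dosage correlation exceeds 0.5. This is a single-pass simplification of the
usual PLINK-style windowed prune (kept markers only are compared, making
the pass idempotent); exact PLINK replication is a non-goal.

## Synthetic data: what it emulates, what it does not

`generate_panel` emulates a clonally propagated germplasm panel: founders
drawn from Hardy–Weinberg proportions at per-marker allele frequencies
sampled from a declared distribution (default uniform on [0.05, 0.5],
matching the post-filter frequency floor), optionally extended with
full-sib families (two founder parents) and parent–offspring chains (each
member crossed to a random founder) — the relative classes that make
exclusion hard. Markers sit at distinct uniform positions on a fixed
karyotype (default 17 chromosomes × 35 Mb, an apple-like genome). The
default study population is 40 founders plus a 20-member full-sib family
plus a 5-deep chain, 1,000 markers.

Deliberately *not* modelled: linkage between loci (all gametes are
independent across markers, so the adjacency objective's benefit — robust
downstream likelihood inference — cannot itself be observed on synthetic
offspring); genotyping *errors* (wrong calls) as opposed to missingness;
population structure/admixture among founders; null alleles. Passing tests
therefore demonstrate correctness of the selection machinery and
calibration of the Mendelian/masking model, not field performance on a real
germplasm, where LD, call errors, and pedigree errors all bite.

Masking draws i.i.d. Bernoulli missingness per genotype call at the given
rate (intended range 0–20%; higher warns). All generators run on
`numpy.random.default_rng` with explicit seeds surfaced in outputs.

## Exclusion assignment

A candidate is excluded at a locus when the offspring's paternal gamete is
impossible for him (gamete 1 vs dosage 0, gamete 0 vs dosage 2); missing on
either side skips the locus. Candidates with at most `max_mismatch`
(default 0) incompatible loci survive; a unique survivor is assigned,
anything else is left unassigned — the assigner never guesses among ties.
Under pure missingness the true father can never mismatch, so exclusion at
threshold 0 cannot produce false positives on error-free or masked data;
raising `max_mismatch` is only useful for real data with genotyping errors
(a reasonable starting point there is the expected error count
$\lceil \text{error rate} \times f \rceil$ when errors exceed ~1%), and on
error-free data it merely admits competitors and increases ties. This
assigner is a deliberately simple, deterministic stand-in for
likelihood-based tools; Cervus interop is provided via file export, and
Cervus's LOD/Delta confidence machinery is out of scope.

## Problem sizes used in the checks

The test suite and acceptance script run: exact-vs-enumeration on 50
instances with ≤ 6 fathers and ≤ 15 markers (full $2^m$ enumeration as the
oracle); monotonicity in $h$ on 10 instances of 5 fathers × 30 markers;
the end-to-end study on the 65-individual, 1,000-marker population above
with five offspring per candidate father; and the greedy-vs-search
comparison on 20 instances of 40 individuals × 500 markers. These sizes
were chosen so the entire suite recomputes from scratch in well under a
minute while still exercising every code path at population scales where
the combinatorics are non-trivial.

## Known limitations

* Accuracy targets for pure exclusion must be set via $h$; there is no
  per-pair guarantee below "one opposing homozygote selected".
* The adjacency weight uses physical, not genetic, distance.
* Diploid, biallelic markers only; no imputation or phasing.
* The exact quadratic model grows one binary per marker pair and is only
  practical for small-to-moderate marker pools; the heuristics are the
  intended route at scale.
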