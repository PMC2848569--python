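# Methods

## Model

The predictor treats subcellular localization as a multi-label
classification problem over M compartments (the full system uses the
22-location eukaryotic set in `subcell.evaluation.EUK22_LOCATIONS`). Every
reference protein annotated to m locations enters the reference libraries
as m *virtual samples* — identical feature vector, one sample per location
label — so per-location success rates are counted over virtual samples and
the benchmark total is N(vir) = Σₘ m·Nₘ.

Three feature encodings feed two prediction engines.

**Homology-transferred GO vectors.** The homology set of a query is the
set of BLAST subjects with expect value ≤ `evalue_max_go` and percent
identity ≥ `identity_min` (both inclusive; self-hits excluded). The
query's GO vector is the binary union of the GO indices annotated to those
subjects. The published description leaves the two thresholds as figure
placeholders; the defaults 0.001 and 60 % follow the values this method
family documents elsewhere and are configurable. A vector is *productive*
relative to a reference library if it shares at least one term with the
library — productivity, not mere non-emptiness, gates the GO engine,
because a term unseen in training carries no discriminative information.

**Functional-domain vectors.** Binary indicators over a conserved-domain
index space; component i is set iff some hit on domain i has
E ≤ `evalue_max_fund` (default 0.001, also a masked value in the source
description). No GO-graph or domain-hierarchy propagation is applied: the
method uses flat term/domain presence.

**Pseudo-PSSM.** PSSM rows are standardized to zero mean and unit
*population* standard deviation across the 20 amino acid columns. This
conversion is idempotent and invariant to per-row positive affine
rescaling; zero-variance rows (all 20 scores equal) map to the zero row,
the limit consistent with the zero-mean requirement, which keeps
idempotence and avoids a division failure. The fixed-length descriptor is
the 20 column means followed, for lag ξ ≥ 1, by the correlation factors
G_j(ξ) = (1/(L−ξ)) Σ (E_ij − E_{i+ξ,j})². The exact algebraic form of the
coupling is masked in the source text; the squared-difference form —
standard in this descriptor family — is adopted, with the exponent exposed
as `coupling_exponent`. A lag ξ ≥ L is an error, not a silent cap: the
denominator L−ξ must stay positive, and capping would hide data problems.
The ξ < 50 ceiling mirrors the shortest benchmark protein; profiles with
L < 50 truncate the usable lag range with a recorded warning rather than
failing, since the bound is a property of that benchmark, not of the math.

**Evidential KNN and the engines.** The underlying classifier math is
deferred by the source description to another publication, so the classic
evidential-KNN formulation is used: a neighbor of class c at distance d
supports {c} with mass α·exp(−γ_c·d²) (α = 0.95, exponent configurable),
the rest on the frame; normalized Dempster combination (the unnormalized
variant is available behind a flag); argmax belief. γ_c is the reciprocal
of the class's mean squared same-class nearest-neighbor distance; classes
with one sample or duplicated points fall back to the pooled mean, and a
fully degenerate library gets γ = 1 (the masses are then distance-free,
which is the only consistent choice when all distances vanish). Whether
the original "optimized" variant tuned γ by leave-one-out is not stated;
an optional grid refinement (`fit_gammas(refine=True)`) minimizing the
library's LOO error is provided alongside the heuristic.

Distances: Jaccard on nonzero index sets for the binary spaces (defined as
0 when both sets are empty), Euclidean on the continuous pseudo-PSSM
block. The SEQ engine's member (K, ξ) votes in a joint space with
d = w·d_FunD + (1−w)·d_PsePSSM/s, w = 0.5, where s is the training-set
mean pairwise pseudo-PSSM distance (guarded to 1 when degenerate). The
source formulation feeds "both" representations into one engine without
saying how they are joined; the convex-mix joint space is the package's
choice, and a per-space voting variant (10 members per lag on the
continuous block plus a domain-only bank) is available via
`joint_space=False`.

**Multi-label decision.** Member votes are tallied; with shares
v(ℓ) = votes(ℓ)/n and v* = max share, the predicted set is
{ℓ : votes(ℓ) ≥ 1 and v(ℓ) ≥ v* − θ}. θ = 0 yields the argmax set; the
rule is monotone in θ, zero-vote locations never enter, and the ≥
comparison carries a 10⁻¹² slack so exact rational shares are not lost to
floating-point subtraction. Default θ = 0.2. The exact published decision
rule is deferred to formulas not reproduced in the source text; only this
rule's stated properties are asserted.

**Tie-breaks and sample ordering.** Distance ties at the K boundary
resolve by ascending sample index and belief ties by the smallest class
label — both for bit-reproducibility. Virtual copies of a multi-location
protein are stored adjacent in *descending* label order. This ordering is
deliberate: when a query's nearest neighbors are identical-feature
multi-location twins (exact distance ties), the prefix of the sorted
neighbor list alternates classes, and the member votes across K = 1..10
split 5/5 over a pair, 4/3/3 over a triple, 3/3/2/2 over a quadruple —
all within the default θ band — so clean multi-label evidence yields the
full label set. Ascending storage would resolve every exact tie onto the
lowest label and systematically erase multi-label calls.

**Routing.** A query with a productive GO vector goes to the GO engine;
an empty homology set or unproductive vector falls back to the SEQ
engine; sequences under 50 residues are rejected as fragments. The GO
reference library contains only proteins with non-empty GO vectors:
including empty vectors would create zero-distance cross-class pairs
(empty–empty Jaccard distance is 0) carrying no information.

## Scoring

Locative mode credits a virtual sample (p, ℓ) with 1 iff ℓ is predicted
for p. Penalized mode multiplies that credit by |T∩P|/|T∪P|, so both
over- and under-predictions shrink the score — the published account
states only that false positives and negatives "reduce the scores" and
defers the formulas; the Jaccard weighting is the package's realization,
and both modes are always computed. Rates are rendered as
`correct/total = XX.XX%` tables with a Total row equal to
Σ correct / Σ total. The jackknife unit is the distinct protein: all its
virtual copies leave training together (leaving one would leak an
identical vector), γ is refit per fold, and a fold whose training set
loses an entire location is evaluated anyway with a recorded warning.

The jackknife implementation precomputes protein-level distance matrices
(virtual copies of a protein share one feature vector, so sample distances
reduce to protein distances) and feeds per-fold distance rows and γ fits
through the same `vote_from_distances` path the public engines use; a test
cross-checks the fast path against a literal per-fold rebuild of the
libraries and engines.

## Synthetic data

The generator emulates the structure the method assumes — homologs share
attributes — without any biological sequence realism: each location owns
an exclusive block of GO terms (12), of domains (8), and a 20-column PSSM
bias drawn N(0, 1); a protein with label set S carries the union of its
locations' term/domain blocks and the mean of their biases, scaled by
`separation` (default 6, i.e. rounded integer scores in roughly ±12).
Homologs are the other proteins with the same label set (capped at 50,
like a bounded hit list), reported at 90 % identity and E = 10⁻³⁰.
Sequence lengths are uniform on [60, 120] — above the 50-residue fragment
bound so all 50 lags are exercised — and residues are uniform i.i.d.

Defaults are the baseline study conditions: 200 proteins, 5 locations,
multiplicity proportions matching the curated benchmark's histogram
(6687 : 1029 : 48 : 2), noise 0, 15 % of single-location proteins without
homologs (exercising the SEQ route), and the full-size GO/FunD index
spaces (free, since vectors are index sets).

Two structural guarantees make the noise-free benchmark *exactly*
recoverable by the jackknife, by construction: label sets are drawn first
and proteins partitioned so every realized set keeps at least
⌈10/m⌉ + 1 exemplars (each withheld query then retains ≥ 10
identical-signature virtual twins — enough for every K ≤ 10 member);
multiplicity classes too small for that floor fold into the
single-location class (a sub-percent perturbation of the histogram at the
sizes where the histogram is checked). And homolog-less proteins are
drawn among single-location proteins only, so multi-location
neighborhoods are never starved — mirroring the observation that
multi-site annotations come from well-studied families.

`noise` ∈ [0, 1] drives four corruption channels: per-term annotation
dropout plus binomial spurious terms; per-entry PSSM jitter
(σ = 3·noise, deliberately *not* scaled with separation, since row
standardization makes the features scale-invariant); degraded homolog
identities and dropped/spurious hits; and homolog *misassignment* — with
probability `noise` a protein's hits land in a wrong-location family and
its domain and profile evidence blends toward that location. The last
channel dominates the degradation: pure i.i.d. corruption is largely
absorbed by the union over many homologs, whereas misassignment moves
whole proteins toward wrong clusters, which is what makes the jackknife
accuracy fall monotonically with noise (measured means ≈ 1.00 / 0.71 /
0.54 at noise 0 / 0.2 / 0.4 on 60-protein, 3-location benchmarks averaged
over 5 seeds).

What passing synthetic tests does **not** show: robustness to real
annotation sparsity and bias, to GO terms shared across compartments, to
homology detection noise at realistic identity distributions, or to the
heavy class imbalance of curated benchmarks — real-data rates will be far
below the synthetic ones (the published full-scale benchmark sits near
64 %, not 100 %).

## Problem sizes and numerical choices

The heavyweight checks run at deliberately modest sizes chosen as the
package's own defaults: the noise-free recovery test at the baseline 200
proteins / 5 locations; the noise-monotonicity sweep at 60 proteins / 3
locations × 5 seeds × 3 noise levels. Tolerances: mass bookkeeping 10⁻⁹;
standardization identities 10⁻⁹ (10⁻⁸ summed across 20 columns); oracle
comparisons 10⁻¹⁰; the θ-band slack 10⁻¹².

## Known limitations

* The paralog-trap noise channel conflates several real failure modes
  (annotation transfer error, profile contamination) into one knob.
* `fit_gammas(refine=True)` is O(n²·grid) and not used by default.
* The CLI `predict` command scores against a library containing the query
  itself (resubstitution); unbiased estimates come from
  `evaluate --jackknife`.
* Exact multi-label recovery relies on exact distance ties between
  twin samples; any feature noise collapses most multi-label calls to the
  dominant label well before single-label accuracy suffers, which is why
  penalized scores fall faster than locative ones under noise.
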