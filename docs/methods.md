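# Methods

## The birth-and-death model

The process is a synchronized birth-and-death chain: all lineages
multiply at the same event times *t*₁ < … < *t*ₙ₋₁ with ploidies
*r*ᵢ ≥ 2, and fractionation acts litter by litter — for each parent
gene, the number of surviving progeny *j* ∈ {1, …, *r*ᵢ} is drawn from
the event's survival distribution *u*⁽ⁱ⁾. Two structural assumptions
matter:

1. **No zero-survivor litters.** A lineage whose progeny all die
   leaves no observable trace, so it is excluded by construction
   (*u*₀ ≡ 0). Consequently "unpaired genes" are exactly the genes
   whose litter kept a single copy at *every* event, giving
   **E**(*m*\*) = *m*₁ ∏ᵢ *u*₁⁽ⁱ⁾.
2. **Independence across lineages.** Conditional on the event
   schedule, litters fractionate independently. All expectations
   therefore factor into per-gene products, which is how the closed
   forms avoid the sum over histories (whose cost grows
   combinatorially with *m*ᵢ and *r*ᵢ).

The exhaustive enumeration is retained purely as a test oracle. It
enumerates *labeled* forests (one survivor count per gene per event)
and groups them into aggregate histories {*a*ⱼ⁽ⁱ⁾}. Two bookkeeping
quantities — pair counts at observation time and the unpaired count —
are not functions of the aggregate counts alone (they depend on which
lineages later losses hit), so history records carry their
conditional expectations; expectations over the whole catalogue are
exact either way. Enumeration refuses instances whose maximal
population *m*₁ ∏ *r*ᵢ exceeds a configurable cap (default 12), with
an explicit message rather than silent truncation.

## Similarity components

Pair similarity is the proportion of identical sites, decaying as
*p* = ¼ + ¾ e^(−λt) toward the four-letter saturation value. All
moments are kept on the proportion scale — mean *p*, variance
*p*(1−*p*)/*G* — which is the scale of a percent histogram. (The
count-scale moments *Gp*, *Gp*(1−*p*) describe the identical-site
*count*; mixing the two scales is a notational trap we deliberately
normalize away.) λ and the event times enter the observable model
only through λ(*t*ₙ−*t*ᵢ), so the canonical free parameters are the
*p*ᵢ themselves, with ages recoverable by inverting the decay at
λ = 1.

Binning is integer-percent by default: bin *k* covers
[*k*−0.5, *k*+0.5), masses are normal-CDF differences (not midpoint
densities), and the tails beyond the outermost edges are folded into
the edge bins. Folding makes each component's binned mass exactly 1,
so the predicted vector (*q*, *q*\*) is a probability vector by
construction and refining the bins re-aggregates exactly. The upper
tail fold also absorbs the spill-over the normal approximation
produces when *p* presses against 1; when a component's mean plus two
standard deviations crosses the top edge a warning is emitted (the
approximation is visibly degraded there) but prediction proceeds.
A component with *p* = 1 is a point mass placed in its containing bin.

## Inference

The likelihood is multinomial over histogram bins plus the optional
unpaired count; the additive constant is dropped. Choices that were
genuinely open:

- **Optimizer.** Bounded L-BFGS-B from 50 seeded uniform starts
  (default), followed by a Nelder–Mead polish of the best candidates.
  All randomness flows through one seed; fits are reproducible.
- **Flat ridges are reported, not hidden.** Every local optimum
  within 0.01 log-units of the best is returned, because the
  two-event models are genuinely underdetermined (the likelihood
  depends on the fractionation parameters only through three
  observables) and a single "the" estimate would be misleading.
- **Zero-mass bins.** The public log-likelihood honours the exact
  contract (observed counts in a zero-probability bin ⇒ −∞). Inside
  the optimizer the bin probabilities are floored at 10⁻³⁰⁰ so that a
  start whose components sit far from the data sees a steep but
  finite surface instead of a flat −∞ plateau.
- **Ordering.** *p*₁ < *p*₂ < … is enforced by parametrizing the
  increments, so every reported optimum satisfies it by construction.
- **Missing unpaired counts.** Without *f*\* the pair bins are
  renormalized and the unpaired atom drops out of the likelihood;
  component locations remain identifiable, the absolute fractionation
  level less so.
- **Survival parametrizations.** Each event is either "free" (full
  survival vector; a stick-breaking pair for ploidy 3) or "binomial"
  (one per-copy survival parameter, i.i.d. copy survival conditioned
  on ≥ 1 survivor — for ploidy 3 this is exactly
  *u* = *s*²/(3(1−*s*)+*s*²), *v* = 3*s*(1−*s*)/(3(1−*s*)+*s*²)).
- **Standard errors** come from the observed information matrix
  (central-difference Hessian of the negative log-likelihood at the
  optimum, pushed through the Jacobian of the natural-parameter map).
- Histogram trimming bounds (k_min/k_max) are available — the high
  end is conventionally trimmed to remove heterozygosity artifacts —
  but no bounds are applied by default.

## Two-event algebra

The duplication-first observable triple per ancestral gene is
((2*u*+*v*+1)²*w*, (3*u*+*v*)(1+*w*), (1−*w*)(1−*u*−*v*)); the
triplication-first triple is ((3*p*₃+*p*₂)(1+*z*)²,
*z*(1+2*p*₃+*p*₂), (1−*z*)(1−*p*₃−*p*₂)). Both are validated against
exhaustive paralog-tree catalogues whose probability monomials sum to
one identically. A symbol caveat: the conventional printed form of
the triplication-first equations, (*x*+3*y*)(1+*z*)² and
2*yz*+*xz*+*z*, is consistent with the tree enumeration only when *y*
denotes the probability that all three copies survive and *x* exactly
two — the reverse of how the symbols are usually glossed in prose.
The types here use the unambiguous names *p*₃/*p*₂ and expose the
printed-symbol form under the documented mapping *x* = *p*₂,
*y* = *p*₃; the enumeration is the ground truth.

Equating the triples gives the correspondence system. It is solved by
elimination to a single-variable polynomial — a quartic in *z* going
duplication→triplication, a quintic in *w* in the reverse direction
(the radical introduced by the *t*₁-pair equation is squared out, and
the spurious roots this creates are removed by a residual check on
the original system) — followed by a Newton polish; returned valid
roots have residuals below 10⁻¹⁰, with a boundary epsilon of 10⁻⁶ on
the validity classification. Lattice scans over the valid
(*u*, *v*, *w*) cube label each point by counterpart existence
(default step 0.01, configurable; the acceptance-speed scans use
0.05).

In the constrained one-parameter models, matching both pair
expectations leaves the unpaired expectations free to disagree; that
signed disagreement as a surface over (*s*, *w*), and its zero
contour, is computed on a grid. One limitation found empirically: the
often-stated claim that this matching is a bijection of the open unit
square onto itself does not hold — on part of the square the only
real root has *z* slightly above 1 (e.g. (*s*, *w*) = (0.5, 0.7) ⇒
*z* ≈ 1.003). The implementation returns that analytic continuation
with a `valid` flag instead of failing, which keeps the difference
surface continuous; round-trips hold on the branch to ~10⁻¹⁵.

## Tuple counting

"Triple" defaults to a connected component of exactly three genes in
the graph of pairs at or above the similarity threshold (default
0.81), because a census of "triples not part of a larger tuple" does
not by itself say whether the third edge is required; clique-triples
(all three edges) are always reported alongside. Components are
maximal, so a size-3 component is never part of a larger tuple by
construction. Unpaired genes are computed only against an explicitly
supplied gene roster (pair lists alone cannot define them). Region
and region-tuple memberships are input annotations (a BED-like file
plus gene positions, or a direct gene→region mapping); synteny-block
detection itself is upstream and out of scope. The signature verdict
requires among-tuple pairs to outnumber both within-region and
cross-tuple pairs by a configurable factor (default 10×), with
unlabeled genes counted in an explicit bucket.

## The simulator

The simulator draws litter survivor counts from each event's survival
vector and records full lineage paths, so every surviving same-root
pair has exactly one originating event (the pair-partition identity
∑ᵢ *d*⁽ⁱ⁾ = ∑ᵣₒₒₜₛ C(*k*, 2) is checked in tests). Similarities are
sampled **per pair** as Binomial(*G*, *p*ᵢ)/*G* — the model is a
pair-level model; no nucleotide sequences are emitted and no
alignment is simulated. Synthetic region labels are derived from
lineage paths (genes sharing a full path form a region, regions
sharing all but the last event's slot form a region-tuple), which
yields signature-true toy genomes; real synteny blocks are of course
interrupted by rearrangement, which this emulation does not model.
One RNG (numpy PCG64) drives everything and its identity is recorded
in dataset metadata.

What the simulator does *not* emulate — and hence what passing tests
do not show about real data: lineage-specific or gene-specific loss
biases beyond the per-event survival vectors, codon-aware divergence
or rate variation across genes (a single *G* and λ), synteny-block
geometry and rearrangement, and allelic (heterozygosity) artifacts
near 100% similarity.

## Reference study conditions and problem sizes

The default two-event study design used throughout the examples and
tests is 20,000 ancestral genes, duplication survival *w* = 0.5,
triplication per-copy survival *s* = 0.4, event similarities
*p*₁ = 0.70 and *p*₂ = 0.87, and *G* = 1000 sites — a genome-scale
instance (~46,000 extant genes, ~42,000 pairs) whose mirrored
triplication-first twin uses the same values. Oracle-equivalence
checks run on all schedules with *n* ≤ 3, *r*ᵢ ≤ 3, *m*₁ ≤ 2 over a
0.2-step survival grid (the exhaustive enumeration's comfortable
range); Monte-Carlo checks use 10⁴ replicates of small schedules;
correspondence scans use lattice steps of 0.05–0.1 and the
unpaired-difference surface a step of 0.01.

## Known limitations

- The normal approximation to the binomial degrades for very recent
  events with short genes (*p* → 1, small *G*); the warning contract
  flags it but the fit proceeds.
- Free survival vectors are implemented for ploidies 2 and 3 (the
  cases of practical interest); higher ploidies use the binomial
  parametrization.
- The γ-like earliest events of real plant genomes are simply
  additional mixture components here; nothing special is done for
  pairs older than the modeled events, beyond histogram trimming.
- Fits assume the histogram's pairs are exchangeable given their
  originating event; sibling pairs actually share lineage history, so
  only means and variances of simulated summaries are asserted
  against the closed forms, not joint laws.
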