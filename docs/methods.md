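# Methods

## The pathway model

A trait is controlled by one signaling pathway organized as a tree of
functional genetic units (FGUs): one signal-transduction unit **S** at
the root, transcriptional-regulation units **T** beneath it, and
biosynthesis units **B** at the leaves.  Only B units carry trait
effects (`a_ij` ≥ 0, trait units); a B unit contributes its effect when
its entire chain **S → T → B** is functional.  Within a unit, every
member locus is required (mutual dependency); between levels, function
propagates one way (the principle of hierarchy).

Each locus is biallelic with a functional and a null allele (allele
*weights* 1 and 0; differentiated functional variants may carry any
weights in [0, 1], and a unit may declare per-combination weights to
express co-adapted allele complexes).  A genotype assigns each
segregating locus 0, 1 or 2 copies of the functional allele;
non-segregating loci are the unit's fixed background, either functional
or — when both parents share a crippling mutation — null, which silences
the unit entirely.

**Gene action.**  The per-locus dosage of a genotype is

| state | dominance (D) | additivity (A) |
|---|---|---|
| hom functional | 1 | 1 |
| heterozygote | 1 | 1/2 |
| hom null | 0 | 0 |

with the mixed mode (DA) applying dominance at regulatory S/T loci and
additivity at B loci.  Dosages combine **multiplicatively** within a
unit and down a regulator chain; the trait is the sum over B units of
`a_ij` × chain product.  Multiplicative combination is the unique choice
that (i) yields exactly half the unit effect as the expected main
additive effect of a single segregating locus and (ii) makes mid-parent
heterosis exactly zero in every configuration without functional
dependency; an alternative min-gating rule was rejected because it
creates additional exact-zero heterosis cases that contradict the
expected count of ten.  A repressing regulator inverts its parent's
factor, `f → 1 − f`, the continuous analogue of the dominance inversion
(the additive behaviour of repressors is a modelling choice; nothing in
the framework pins it down).

The canonical instance has 1 S, 2 T and 6 B units with effects
(4, 8, 4) under T1 and (8, 4, 4) under T2 — maximum trait value 32 —
and seven segregation scenarios ranging from two independent regulatory
loci to eight loci spread over three levels.

## Exact population enumeration

Ideal biparental populations are enumerated exhaustively: per locus
(1/4, 1/2, 1/4) genotype frequencies in an F2 and (1/2, 1/2) in an RI
(DH) population, unlinked loci, product-form class frequencies held as
exact rationals (`fractions.Fraction`), trait values fully penetrant.
Moments, conditional means and trait distributions are therefore exact;
there is no sampling error anywhere in the expectation machinery.  The
enumeration cap defaults to 16 loci (3^16 F2 classes); the canonical
scenarios use at most 8.

**Heterosis.**  For r segregating loci there are 2^(r−1) distributions
of the functional alleles between the parents (parent swap removed by
pinning the first locus).  Per configuration: P1 and P2 are the
homozygous parental values, F1 is all-heterozygous, H_MP = F1 −
(P1+P2)/2, and inbreeding depression is defined *signed* as
ID = E[F2] − F1 (the F2 mean does not depend on the configuration, only
on the scenario).  The sign convention makes a large dominance-driven F1
correspond to a large F1→F2 drop, i.e. strongly negative ID.

**The heterosis × depression correlation.**  Two poolings are
implemented: `case` (all per-configuration pairs of scenarios 3–7
pooled, n = 320) and `scenario_mean` (the five per-scenario means).
Exact facts worth recording:

* the mean of H_MP over all configurations of a scenario equals
  F1 − E[RI] identically (averaging the mid-parent over all allele
  distributions reproduces the inbred-population mean);
* under additivity, the trait is multilinear in per-locus dosages whose
  expectation is 1/2 in the F1, the F2 and the RI population alike, so
  F1 = E[F2] = E[RI] exactly — both H̄ and ID vanish identically and the
  additive-mode correlation is **degenerate** (reported as such, and as
  0.0 by the acceptance script).  Any nonzero published value for this
  quantity can only reflect rounding or sampling noise, not expectation.

Computed values: dominance −0.749 (case) / −0.982 (scenario mean);
mixed −0.933 / −0.991.  The scenario-mean pooling is the reported
variant because it is the one under which the dominance-mode value is
reproducible; the mixed-mode correlation is negative under every
definition examined, so a positive published value could not be
reproduced — the discrepancy is documented rather than fitted.

## Expected QTL parameters

Effects are orthogonal contrasts on the enumerated population, not
least-squares fits to samples: code homozygotes ±1 and heterozygotes 0
at each locus of a subset, take φ = Π z and β = E[φX]/E[φ²].  For one
locus this is ½(μ(hom-functional) − μ(hom-null)); for an RI pair the
familiar ¼[μ(++) − μ(+−) − μ(−+) + μ(−−)].  A single closed form covers
every order k:

    effect(subset) = Σ_B a_B (1/2)^k Π_{other segregating chain loci} p

summed over B units whose chain contains the whole subset, with the
functional-genotype frequency p = 1/2 in RI and 3/4 (dominant) or 1/2
(additive) per locus in an F2.  The suite asserts closed form ≡
enumeration contrast exactly (tolerance 10⁻⁹, satisfied at 0) over all
scenarios × populations × modes, orders 1–3.  Consequences that fall
out of the (1/2)/p ratio: in RI, epistasis of any order equals the main
effect of the deepest locus; in an F2 under dominance each added chain
locus scales the effect by 2/3.

Two kinds of statistical epistasis exist: type I (subsets spanning ≥ 2
levels of one regulator chain) and type II (subsets within one unit);
subsets touching two B units or two T subtrees have identically zero
epistasis.  Counting main effects plus all type I/II subsets reproduces
the expected parameter totals (2, 4, 10, 21, 21, 22, 21) for the seven
scenarios.

Variance shares are β²E[φ²]/σ²_G; in RI populations the terms form a
complete orthogonal basis (residual 0), in an F2 under dominance the
dominance deviations stay in the residual by design — only
additive×additive terms are reported.  Pathway effects are recovered by
inverting the closed form given the unit's inferred context
(`a = 2A / Π p`; a co-adapted pair detected only through its
interaction gives `a = 2l`).

## Selection response

Truncation selection is a conditional expectation: retain the classes
passing the threshold, renormalize.  The trajectory ladder is 4, 8, …,
32 trait units for positive selection and 32, 28, …, 4 with the rule
flipped for negative selection, so successive steps are nested and
intensity grows monotonically (a descending negative ladder is the
coherent reading of a threshold list whose late entries would otherwise
retain everything).  An exhausted step truncates the trajectory with a
flag.  Per step: retained fraction, per-locus functional-allele
frequencies, mean, variance, and the full pairwise (D, D′) matrix.
Gamete frequencies are exact: RI classes are their own gametes; F2
classes transmit each allele with probability equal to its dosage
(unlinked loci, random union within the retained set).  This exact
conditional computation is what an iterative approximation of selected-
population disequilibria converges to at enumeration scale, so no
iteration is used.  D′ uses the standard normalization and is undefined
(None) at fixed loci.

## Network detection from QTL effect tables

Pairs (A_i, A_j, l_ij) are classified with an absolute tolerance
(default 5% of the largest |A|): independent (|l| ≤ tol), co-adapted
(both mains ≈ 0, |l| > tol), type II (A_i ≈ A_j ≈ l/c), type I
(l/c ≈ min |A|, clearly unequal mains; the larger-|A| locus upstream),
repressed (l < −tol; the weaker locus expresses in the stronger one's
mutant background — an interpretation, flagged as such), else
*unresolved*, never a silent guess.  c = 1 for RI, 2/3 for F2 under
dominance.  Type II/co-adapted cliques merge into multi-locus units;
type I orientations build a DAG (cycles are an error; transitive
reduction keeps direct regulator edges); pathway effects come from the
closed-form inversion using each unit's inferred upstream locus count.
Round-trip tests plant the canonical scenarios, regenerate their
expected effect tables, and require exact recovery of memberships,
orientations and B-unit effects (tolerance 10⁻⁶), including under
Gaussian noise at 2% of the largest main effect.

## Network detection from selected introgression lines

Against the exact neutral expectation of a k-backcross/m-self scheme
(BC₃F₂: donor allele 1/16; carrier frequency P_i = 3/32 — "carrying at
least one donor allele" is the default reading of introgression, with
the allele-frequency convention available), the pipeline applies:

1. per-locus χ² goodness-of-fit tests of allelic and genotypic
   frequencies, both required at the per-test threshold (default
   P ≤ 10⁻⁴, uncorrected by design; the number of tests is logged);
2. association grouping of the significant loci.  The co-introgression
   probability P_i^m (1−P_i)^(n−m) (m co-carriers of n lines, applied
   per pair, group value = weakest pair) is the significance criterion,
   but it is *not* an association measure — with many lines it is small
   even for unrelated loci — so a pair additionally needs strong
   positive association (carrier-coded D′ ≥ 0.5 by default; 1.0
   reproduces the strict perfect-association behaviour seen in real
   selected ILs, and an explicit mismatch allowance is available).  A
   pair whose carrier sets are in substantial one-sided containment
   (difference ≥ 20% of lines) is treated as an upstream–downstream
   inclusion, not co-membership;
3. network construction: FGUs that are positively associated or in
   carrier containment form groups; within a group, strict containment
   orients regulator → regulated edges (transitive, acyclic by
   construction); strong negative D′ across groups is reported as
   antagonism.  The output is invariant to line and marker order.

## The synthetic cohort generator

The generator emulates the *shape* of a selective-introgression
experiment: 1,900 lines, ~160 markers, BC₃F₂ neutral genotype
frequencies drawn i.i.d. per line × marker (loci unlinked; an optional
bin map clones markers into perfectly linked clusters to exercise
redundancy removal), donor alleles functional for a planted pathway,
survival decided by the fully penetrant genotypic trait value, and a
null mode whose "survivors" are a random line subset.

What it deliberately does not emulate: recombination along
chromosomes, BC-family pedigree structure, genotyping error, or any
residual (environmental) variance in survival.  Passing recovery tests
therefore demonstrate the detection logic under the model's own
assumptions, not robustness to linkage or noise in real data.

A feasibility fact shapes the planted designs: under independent
introgression the probability that one line carries a complete k-locus
unit is (3/32)^k at BC₃F₂, so a 1,900-line cohort whose survival
requires an upstream multi-locus AG would leave ~1–5 survivors — real
selected-IL datasets that show such structure are *stronger* than this
neutral model can produce.  Accordingly, the 1,900-line BC₃F₂ recovery
experiment plants three redundant two-locus branches (any complete
branch survives; ~50–60 survivors; all three units recovered as AGs,
negative associations between branches, no spurious inclusion edges),
and the layered recovery experiment (a required two-locus upstream unit
over redundant downstream units, upstream recovered above downstream)
runs under a BC₁F₂ scheme where the completion arithmetic is feasible.
Null cohorts quantify the false-positive level of the 10⁻⁴ per-test
threshold (~0.1 significant neutral loci per 160-marker cohort).

## Numerical conventions and limitations

* Frequencies and trait values are exact rationals end to end; floats
  appear only at the I/O boundary (6 significant digits in tables).
* Closed-form vs enumeration identities are asserted at 10⁻⁹ absolute,
  network recovery at 10⁻⁶; both hold exactly in practice.
* F2 main-effect contrasts use the homozygote classes only; dominance
  deviations are not reported as separate terms.
* Scenario 1's shared-mutant unit is modelled as one fixed-null locus;
  the number of mutated loci is immaterial to every reported quantity.
* The enumeration treats selection as within-population conditioning;
  there is no recombination between selection steps, no drift, and no
  multi-generation recurrent selection.
* Interval mapping and estimation of effects from finite samples are
  out of scope: the QTL arm consumes effect tables, from whatever
  mapping tool produced them.
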