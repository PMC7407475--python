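# Methods

`scopesim` simulates a recurrent genomic-selection breeding program for
fully inbred crop lines and compares parental selection/mating
strategies by their long-term genetic gain and their ability to keep
favorable QTL alleles segregating. This note records the model, the
numerical choices, and what the synthetic founder generator does and
does not emulate.

## The breeding scheme

Each cycle turns a breeding population of 1000 inbred-ish F3 lines into
the next one:

1. fit the prediction model on the training panel (TP);
2. predict GEBVs for all 1000 lines;
3. select 100 parents and arrange them into 50 couples according to the
   configured strategy;
4. update the TP by the tails rule (phenotype the 75 highest- and 75
   lowest-GEBV lines, evict the 150 oldest TP records);
5. each couple produces 20 F1 offspring (1000 F1);
6. two generations of single-seed descent give the next 1000-line
   breeding population.

Cycle 0 is method-independent: founders are phenotyped, the top 50 lines
of each founder panel by phenotype are paired across panels, and the
full founder set (with those phenotypes) seeds the TP.

## Genetic architecture and genome

A trait is controlled by `L` QTL (default 100) drawn uniformly from the
map; the remaining loci are prediction markers and are never causal.
The k-th QTL carries an additive effect `a^k` with `a = (L-1)/(L+1)`
(a geometric series: a few large, many small effects). The favorable
homozygote scores `+a^k`, the heterozygote 0, the unfavorable homozygote
`-a^k`; dominance and epistasis are absent. Genetic values are reported
as fractions of the maximum `sum_k a^k`, so 1.0 means every favorable
allele fixed.

Meiosis uses the count-location model with no interference (Haldane):
per chromosome, crossover count ~ Poisson(map length in Morgans),
crossover positions uniform over the map span, starting haplotype fair.
There is no mutation, so fixation (allele frequency 1 in the breeding
population) is irreversible and the *maximum reachable genetic value* —
signed effects of fixed QTL plus favorable effects of segregating ones —
can only decrease. The per-replicate QTL sample, favorable orientations
and all stochastic stages are redrawn from independent sub-seeds, so
replicate averages marginalize over architectures.

## Phenotypes

`y_ij = g_i + e_j + eps_ij` over `n_env = 3` environments; the recorded
phenotype is the entry mean. Environment effects are drawn per
phenotyping event with variance `sigma_E^2 = 8 sigma_g^2` (a shared
shift that cannot reorder lines and is absorbed by the model intercept);
residuals have variance `sigma_R^2 = n_env sigma_g^2 (1 - h2)/h2`, which
makes the *entry-mean* heritability equal to the target `h2` (default
0.5). Both variances are calibrated once against the founder genetic
variance and frozen: re-calibrating each cycle would shrink the noise as
genetic variance erodes, changing the selection problem mid-run. The
entry-mean (rather than plot-level) definition of h2 was chosen because
selection only ever consumes the environment-averaged value; the
plot-level alternative would scale `sigma_R^2` by `n_env`.

## Prediction model

RR-BLUP: `y = 1*beta + Z u + eps`, `u ~ N(0, sigma_u^2 I)`,
`eps ~ N(0, sigma_e^2 I)`, with Z the {-1,0,+1} marker codes of the TP
restricted to markers with minor allele frequency >= 0.03 (recomputed on
the current TP each cycle; filtered markers predict with effect zero;
MAF exactly at the threshold is retained). Variance components are
estimated by REML, profiled to a one-dimensional problem in
`delta = sigma_e^2/sigma_u^2` on the spectrum of `ZZ'` after absorbing
the intercept (the spectral/EMMA formulation). The optimizer is a
deterministic 81-point grid on `log delta in [-10, 10]` followed by
bounded Brent refinement to `xatol = 1e-8`; this is exact for a
unimodal profile and cannot depend on starting values. BLUPs are
`u_hat = Z'(K + delta I)^{-1}(y - beta_hat)` with the GLS intercept;
GEBVs are `beta_hat + Z u_hat` (the intercept never affects rankings).
The TP is fixed-size (all founders initially, 764 for the real barley
panels), age-ordered, refit every cycle.

## Selection strategies

* **baseline** — truncation: top 100 by GEBV, random perfect matching.
* **scoping** — pre-select the top `ceil(SR * 1000)` by GEBV
  (`0.1 <= SR <= 1`). Couples are built greedily: P1 = best remaining
  GEBV; P2 = the remaining candidate maximizing
  `F = sum_j var(Z_j, selected+candidate) * p_j` (sample variance,
  n-1 denominator; a single row has variance 0). After each couple,
  `p_j` is set to 0 for every marker whose two alleles are both present
  among the selected parents (a heterozygote contributes both); when all
  `p_j = 0` the mask resets to all ones. At `SR` covering exactly 100
  candidates the selected *set* equals truncation's; only the pairing
  differs.
* **population merit** — merit `B = mean GEBV - c * phi` with `phi` the
  mean off-diagonal VanRaden relationship of the selected set (`c = 20`
  by default). Hill-climbing from the truncation set: best-improvement
  passes in parent order against all non-selected lines, strict
  improvement only, fixed point or a 100-pass cap; then random mating.
* **MVT** — pre-select 300 by truncation; P1 = top 50 by GEBV (fixed),
  P2 = next 50, then best-improvement replacement of P2 members from the
  unused pre-selected pool maximizing
  `(1/n) sum_i ((1 + F_i) - 2 Gbar_p)` with `F_i = G_ii - 1`; each P1
  is paired with a random distinct P2.

VanRaden's G is rebuilt each cycle from the current breeding
population's marker codes and allele frequencies; monomorphic markers
drop out of numerator and denominator identically (an all-monomorphic
matrix is an error). The mean GEBV (not the unobservable true value)
enters the merit, and off-diagonal means exclude the diagonal because
coancestry is a between-individual quantity. Ties anywhere are broken
by higher GEBV, then lower insertion index, making every optimizer
deterministic given its inputs; the accepted-swap criterion value is
non-decreasing by construction.

## Synthetic founders

Two panels of fully homozygous lines share a 7-chromosome x 150 cM map
(uniformly spaced loci in contiguous blocks) and a per-locus allele
frequency spectrum, uniform on [0.05, 0.95] by default; each line draws
one founder allele per locus, and the panels are sampled independently
so they differ by drift only. This mimics the broad shape of two North
American six-row barley panels (764 lines, 1590 SNP loci) but **not**
their linkage disequilibrium, population structure, or realistic allele
frequency spectra — synthetic loci are in linkage equilibrium within
panels. Trajectory-level conclusions (variance preservation, fixation
ordering between methods) transfer; absolute endpoint values do not
necessarily match runs on the real panels, and prediction accuracies
tend to be lower without LD between markers and QTL.

## Problem sizes used in the checks

The long-horizon comparisons are run at desk scale: two synthetic panels
of 250 lines (500 founders, the initial TP), 1590 loci, `L = 100`,
`h2 = 0.5`, 10 replicates x 30 cycles per strategy. The full-scale design this simulator targets is larger
(764 real founders, 250 replicates x 50 cycles);
at desk scale the between-replicate spread of final genetic values is
substantial because every replicate redraws the QTL architecture, so
only strong directional contrasts (e.g., variance-preserving methods
versus truncation on reachable value) are stable, and close method
pairs can reorder between master seeds.

## Known limitations

* No pedigree coancestry: genomic relationships stand in for it
  throughout, as is standard when pedigree records are unavailable.
* No genotype-by-environment interaction, unbalanced designs, or
  spatial field effects in phenotyping.
* No mutation, dominance, epistasis, or sex differences in meiosis.
* Selection candidates are always the full 1000-line population;
  overlapping generations are not modeled.
* REML assumes iid marker effects; no Bayesian alternatives are
  provided.
* Because synthetic loci are unlinked with a uniform frequency
  spectrum, relationship-based criteria (MVT, population merit) are
  stronger proxies for marker-level variance there than on real panels
  with LD and rare alleles; method gaps measured on synthetic founders
  therefore compress, and the scoping-vs-MVT contrast in particular can
  invert relative to runs on real data.
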