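# Methods

`f2qtl` is an in-silico QTL-mapping laboratory for the classical F2
intercross design in poultry-like genomes: it simulates a breeding program
forward in time, maps QTLs in the resulting F2 reference populations (RPs)
with a mixed-model genome scan, and scores detection power across RP sizes
and heritabilities. This note documents the models, the defaults and why,
the numerical choices, and what the scaled-down test runs do and do not
demonstrate.

## Genome and meiosis

The genome is 18 autosomes totalling 2,729.4 cM, handled purely in genetic
map coordinates (cM, 0-based, half-open per chromosome). The full-scale
panel is 33,802 evenly spaced biallelic markers; 35 QTLs with 2-4 alleles
each are placed uniformly at random with expected counts proportional to
chromosome length. Because only the total map length is specified for the
target genome, per-chromosome lengths default to chicken-linkage-map-like
relative weights (one micro-chromosome-like 6-cM element included) rescaled
to the exact total; they are fully configurable.

Markers are allocated to chromosomes by largest-remainder rounding of the
length-proportional quota and placed at `(j + 1/2)·L/n`, so adjacent spacing
within a chromosome is exactly `L/n`. QTL positions within 1e-6 cM of a
marker or another QTL are re-drawn, keeping the marker panel strictly
"neutral positions only".

Meiosis uses the standard no-interference model: crossover counts are
Poisson with mean = map length in Morgans, positions i.i.d. uniform, start
haplotype a fair coin per chromosome. Two-locus recombination fractions
therefore follow Haldane's map function, which the test suite verifies
empirically at 10-100 cM. Recurrent mutation flips marker alleles at
2.5e-4 per locus per gamete and moves QTLs to a uniformly chosen different
allele of their fixed 2-4-allele set at 2.5e-5 (both configurable; the
sources for this design also quote 1e-5 for both, so the rates are explicit
knobs rather than constants).

## Population phases

* **Historical population (HP).** Random union of gametes from randomly
  paired parents, equal sex probability, founders initialized at allele
  frequency 1/2 (markers) / uniform (QTLs). Full scale: 1,000 generations at
  10,000, then 1,050 generations shrinking linearly to 8,000 — the
  bottleneck that generates drift LD. The linear schedule is our choice; the
  design only says the size was gradually reduced.
* **Panel selection.** At the end of the HP, markers with MAF < 0.1 and QTLs
  whose rarest segregating allele has frequency < 0.01 are dropped from the
  analysis panel/architecture. Haplotypes keep all loci so coordinates never
  shift.
* **Pure lines.** 60 males + 600 females selected from the final HP cohort
  per line — top true breeding values (TBV) for the sire line, bottom for
  the dam line — then 20 generations of within-line selection with positive
  assortative mating, realized as TBV-rank matching with contiguous dam
  blocks (10 dams per sire). Replacement ratio is 100%: parents are never
  reused. Selection operates on the *raw* (unscaled) effects; only TBV ranks
  matter at this stage, so the later per-h2 rescaling does not alter the
  breeding trajectory.
* **Reciprocal F1.** Line-1 males x line-2 females give F1a, the reciprocal
  cross F1b (30 males + 300 females, selected by the source line's own TBV
  rule). The F1 populations are bred for 5 generations with random
  within-cohort selection and assortative mating.
* **Reciprocal F2.** 15 males + 150 females drawn at random from each F1
  (males of F1a x females of F1b for F2a, the reciprocal for F2b), then 6
  generations of random selection and random mating, 10 offspring per dam
  (1,500 per generation). Reference populations of 100/500/1,000 are drawn
  uniformly without replacement from the union of generations 5 and 6 of
  both F2 populations.
* Offspring sex is an i.i.d. fair coin throughout (equal probability, not an
  enforced exact ratio). Pedigree export censors each recorded parent id
  independently with probability 0.05; genotypes and phenotypes are
  untouched.

## Trait model

The trait is purely additive and fully QTL-borne; markers are neutral. Raw
allele-effect magnitudes are Gamma(shape 0.4, scale 1) — a heavy-tailed
architecture in which a handful of the 35 QTLs carry most of the genetic
variance — with independent random signs and per-locus centering. One
global constant then rescales all effects so that var(TBV) = h2·Vp (Vp = 1;
h2 ∈ {0.1, 0.3, 0.5}) in the **pooled first F2 generation**, and phenotypes
are y = TBV + N(0, (1-h2)·Vp).

The scaling cohort is a deliberate choice. Scaling on the selected F1
parents of the F2 looks natural but overstates the genetic variance their
hybrid offspring actually carry: the parent set's between-group and
among-selected-family spread does not propagate through random mating, so
realized h2 in the analyzed generations lands well below nominal (we
measured roughly a third low at test scale). Scaling on the first true F2
cohort leaves realized h2 in generations 5-6 within drift distance of the
nominal value, which is what "simulated heritability" should mean for the
mapping population. Genotyping artifacts (5% missing, 0.5% mis-calls;
heterozygote -> random homozygote, homozygote -> heterozygote — the error
model is our symmetric choice) affect only the observed marker matrix.

## Association model

Per marker k: `y = mu + CG + b1·SNP_k + A1 + e`, with contemporary groups
CG = generation x sex (levels with fewer than two members merged into the
nearest level), SNP coded additively 0/1/2 with missing calls mean-imputed
to 2p, `A1 ~ N(0, G·sigma_a2)` and `e ~ N(0, I·sigma_e2)`. G is VanRaden's
method-1 GRM, `W W' / (2 Σ p(1-p))` with column-centered W and a 1e-6
diagonal ridge. Variance components come from exact REML of the null model
(no SNP): after one eigendecomposition of G the profile restricted
likelihood is a 1-D function of the ratio gamma = sigma_a2/sigma_e2,
maximized by a coarse log-grid plus bounded Brent refinement on
log10(gamma) ∈ [-6, 6]; estimates at the bounds carry a boundary flag. The
scan holds the components fixed (EMMAX approximation) and tests each marker
by GLS with a two-sided Wald chi-square (1 df) — exact under the Gaussian
model given V, and verified against a direct V-inverse per-SNP GLS oracle to
1e-8. Markers collinear with the fixed effects return p = 1 with a
degenerate flag. The genome-wide threshold is plain Bonferroni alpha/M over
the M markers actually tested (panel markers polymorphic in the RP); the
"modified" Bonferroni variant the design alludes to is not specified, so
alpha and the definition of M are configuration points.

Treating the SNP effect as fixed (rather than a random SNP-BLUP term) and
the absence of leave-one-chromosome-out GRMs are deliberate scope choices;
the proximal-contamination cost of an all-marker GRM is shared by the
standard EMMAX-style tools this scan mirrors.

## Detection scoring

A QTL is detected when at least one significant marker lies within ±2.5 cM
on its chromosome (default; every report records the window). Each
significant marker is assigned to the nearest in-window QTL, ties toward the
lower index; significant markers with no in-window QTL count as false
signals. Power uses the QTLs segregating in the analyzed RP as denominator,
since fixed QTLs are undetectable in principle. Note that in an F2 design
linkage blocks are long; at the default window a marker 3-6 cM from a true
QTL is scored as a false signal even though it is usually a linked shadow of
a real effect — the false-signal count is therefore an upper bound on
spurious signal.

## Profiles and problem sizes

* `paper`: the full design above (HP 10,000 x 2,050 generations). Provided
  for completeness; hours-to-days of compute.
* `desk`: HP 1,000 x 150 generations + 100 shrinking to 800; lines 12M+120F
  x 10; F1 10M+100F x 3; 10,000 markers. The F2/RP structure is unchanged.
  About half a minute per replicate on one CPU — this is the scale the test
  suite and the acceptance script use for replicated grids (11 replicates,
  medians reported).
* `mini`: HP 500 x 50 + 30 shrinking to 400; lines 8M+80F x 8; F1 10M+100F
  x 3; 5,000 markers; F2/RP structure again unchanged. A few seconds per
  replicate, for exploration and seconds-scale smoke runs.

The scaled profiles preserve the quantities that drive detection power — RP
sizes, heritabilities, the 35-QTL gamma(0.4) architecture, Vp = 1, the
F2 founder numbers and mating scheme, artifact rates, and Bonferroni control
over the realized panel — while shrinking the historical phase and panel.
What they cannot preserve: the longer full-scale line-selection phase drives
larger between-line QTL frequency divergence (hence larger per-QTL F2
variance), and the denser panel shifts both tagging r2 and the threshold.
Scaled detection counts are therefore comparable to full-scale counts only
within a tolerance of a couple of QTLs, and at the strongest-signal cell
(RP 1,000, h2 0.5) the replicated desk runs sit at the low edge of that
band — the replicate median moves between about 2 and 4 with the master
seed: significant peaks concentrate within 0-3 cM of the largest QTLs, but
the third-to-fifth-largest QTLs peak near the plain-Bonferroni line, so
single-count shifts in the median are expected.

## Synthetic data vs real data

The simulator emulates drift/bottleneck LD, divergent selection, reciprocal
crossing, Mendelian segregation, genotyping artifacts and missing pedigree
links. It does not model interference in meiosis, sex chromosomes,
dominance/epistasis, genotype-by-environment interaction, overlapping
generations, or real ascertainment of SNP panels. Passing tests show the
pipeline's internal consistency and calibration (type-I error, parameter
recovery, Mendelian ratios) under this idealized additive world — not that
the power numbers transfer to any particular real chicken population.

## Numerical details and degenerate inputs

Haplotypes are int8 throughout; a replicate at mini scale peaks well under
1 GiB. Eigenvalues of G are clipped at zero before REML. p-values are
floored at 1e-300 for the -log10 transform. Monomorphic-in-RP markers are
excluded from the scan (M follows the tested set); entirely missing marker
columns are dropped with a warning. All randomness flows through named
`numpy` SeedSequence substreams of one master seed — per replicate and
stage — so one seed reproduces every cohort bit for bit and changing one
stage's settings leaves the other stages' draws intact.
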