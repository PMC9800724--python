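# Methods

## Coordinate system and annotation model

All coordinates are 1-based, inclusive, circular on the 16,569 bp rCRS
numbering; intervals crossing the origin of numbering are encoded with
`start > end` (the control region, 16024–576, has circular length
16,569 − 16,024 + 1 + 576 = 1,122 bp). The bundled annotation table
carries the 37 genes (13 OXPHOS proteins with complex membership, 2
rRNAs, 22 tRNAs), the control region, hypervariable segments
HVS1 = 16024–16383, HVS2 = 57–372, HVS3 = 438–574, the replication
origins, and the repeat blacklist {66–71, 303–311, 514–523,
12418–12425, 16184–16193}. With these HVS boundaries the non-HVS
fraction of the control region is 100 × 309/1122 = 27.54%. The HVS
boundaries and origin positions are configurable: they are standard
community coordinates, chosen once, and every lookup goes through the
table rather than hard-coded logic.

Display categories for multi-feature positions use the precedence
tRNA > rRNA > protein > control; blacklist membership is orthogonal
metadata. Overlapping protein genes (ATP8/ATP6 at 8527–8572,
ND4L/ND4 at 10760–10766) are handled per gene; a shared position
contributes to both genes' densities and its reported coding effect is
the most severe across the overlapping frames
(stopgain > nonsynonymous > synonymous).

## The DssH replication-exposure model

Mitochondrial replication is asynchronous strand displacement: the
leading (heavy-strand) fork starts at OriH (position 191) and travels
in the decreasing-coordinate direction; when it passes OriL (interval
5721–5798, midpoint 5759.5), lagging-strand synthesis starts there and
travels in the increasing-coordinate direction. A position x on the
parental heavy strand is displaced (single-stranded) when the leading
fork passes and re-annealed when the lagging fork arrives, so with
equal fork speeds and time in genome-length units:

```
t_lead(x) = dist_dec(OriH → x) / L
t_lag(x)  = [dist_dec(OriH → OriL_mid) + dist_inc(OriL_mid → x)] / L
DssH(x)   = t_lag(x) − t_lead(x)
```

DssH is 0 at the OriL midpoint (and by convention throughout the OriL
interval), rises piecewise-linearly along each replication arc, and is
bounded by 2f, where f is the OriH→OriL leading-path fraction
(f = 11000.5/16569, 2f ≈ 1.328). Control-region positions return NaN:
initiation events there are outside the gradient model, and the model
jumps by one full genome-time across the origin region, so no
continuity claim is made through it. Gene-level exposure is the
unweighted mean of per-position DssH over the gene body; complex-level
exposure is the length-weighted mean over member genes. Under this
model MT-CO1 (5904–7445) is the least exposed protein gene (mean 0.11)
and MT-CYB (14747–15887) the most exposed (1.15); these two decimals
are the package's acceptance anchors.

## Filter cascade

Four pure, order-independent predicates (their conjunction is verified
against a brute-force single-pass oracle in the tests): strand support
(alt reads ≥3 on each strand), coverage (total depth ≥100×), repeat
blacklist (inclusive bounds), and somatic status (tumor VAF ≥ 0.01 and
normal VAF < 0.005, the normal bound strict). Calls lacking a normal
VAF are rejected with a warning and counted in the QC report, whose
per-stage removal counts sum to the input count. Only single-base
substitutions enter the catalog; indels are parsed into a side table
because every downstream statistic is substitution-based. The cohort
denominator `n_samples` must be supplied explicitly since mutation-free
samples belong in every density denominator.

## Annotation choices

*Strand convention.* The rCRS forward sequence is treated as the light
strand (it is guanine-poor; the heavy strand is G-rich), so the
coding-region heavy-strand C>T bias appears as forward G>A. A flag
inverts the labeling for users with the opposite convention.

*Coding effect.* Translation table 2 (TGA=Trp, ATA=Met, AGA/AGG=stop)
is implemented as an explicit codon map and cross-checked in the tests
against Biopython's table-2 definition through an independent CDS-space
extraction route over every protein-gene position. MT-ND6 and the
reverse-sense tRNAs are complemented before codon extraction. Genes
whose length is not a codon multiple end in an incomplete codon
completed by polyadenylation in vivo; substitutions there are
unclassifiable from DNA and are reported as nonsynonymous with an
`uncertain` flag (and counted as nonsynonymous).

*tRNA deleteriousness.* Cloverleaf element labels come from a
length-scaled canonical template (7 bp acceptor stem, 4 bp D stem,
5 bp anticodon and T stems, 7 nt anticodon and T loops; residual
length split between D loop and variable region, which correctly
leaves the shortest mitochondrial tRNAs without a D arm). A stem
substitution is deleterious when it breaks Watson–Crick
complementarity with its partner base; G:U wobble counts as broken
unless configured otherwise; loop/variable/connector substitutions are
benign by default with a configurable pathogenic-position override.
This is a declared structural proxy for the literature's benign/
deleterious tRNA classification, not a reimplementation of any scoring
pipeline.

## Selection statistics

Density is (n/N)/(L/1000) mutations per sample per kb. Spectrum
proportions are class count over regional total (summing to 1).
Two-sample heteroplasmy comparisons use two-sided Kolmogorov–Smirnov
or Mann–Whitney tests; regional count splits use chi-square tests.
P-values are reported raw and two-tailed at the conventional 0.05
level; a Benjamini–Hochberg helper exists but is off by default.

The HVS/non-HVS test restricts the catalog to the control region and
tests the (non-HVS, HVS) counts against (27.54%, 72.46%). The DssH
regression uses Pearson correlation and ordinary least squares of
gene-specific C_H>T_H density on gene-mean DssH across the 13 protein
genes (the relationship is modeled as linear; Spearman is available as
an option). Complex normalization divides each complex's observed
density by `fitted(mean DssH of complex) / fitted(mean DssH of Complex
IV)`; Complex IV's score is 1 by construction, and a non-positive
fitted density triggers a degeneracy warning with raw densities
reported. The tRNA analysis compares stem vs non-stem (loops +
variable + connectors) densities against the length split, per-arm
stem/loop pairs, and deleterious proportions.

## Synthetic cohorts: what they emulate and what they do not

Defaults are the cohort-1 study conditions: 432 samples, 1.4 mutations
per sample (Poisson), mean depth 5,084× (Poisson), and a spectrum
dominated by C_H>T_H (0.50) and T_L>C_L (0.25) with 10% transversions.
Heavy-strand C>T positions are drawn on the replication arc with
intensity a + b·DssH(x) (default a=0.1, b=1.0); other classes are
positionally uniform, and the control region is its own uniform
compartment (its distinct light-strand C>T character emerges through
the base-composition constraint that ref alleles match the reference).
Selection enters as thinning: a proposed mutation survives with its
feature class's multiplier. Heteroplasmy is Beta(0.3, 3) truncated at
0.005 — an illustrative low-VAF-enriched choice, since no quantitative
heteroplasmy distribution is available to copy — and alt reads are
Binomial(depth, VAF) split Binomial(·, 0.5) between strands, with
half-normal paired-normal contamination (σ = 0.001) to exercise the
0.5% somatic bound. All sampling uses one `numpy` Generator seeded
from the config, making outputs byte-reproducible.

The generator does not model read-level errors, FFPE deamination
artifacts, multi-allelic interference, sample contamination or copy-
number variation; passing recovery tests therefore validates the
statistical machinery, not robustness to those artifacts in real data.

### The bundled reference sequence is synthetic

The package ships the real rCRS *coordinates* but a synthetic
*base sequence*: a seeded random sequence matching the rCRS
forward-strand composition (A 0.309, C 0.313, G 0.131, T 0.247) with
tRNA stem pairs forced Watson–Crick complementary
(`rcrs_synthetic.fasta`, regenerable via `scripts/build_fixtures.py`).
Every sequence-dependent computation (codon effects, pair disruption,
class-target counts) is reference-agnostic and tested against oracles
on this stand-in; analyses of real cohorts should construct
`MitoGenomeModel` with a real rCRS FASTA. Coordinate-only quantities —
region lengths, the 27.54% fraction, all DssH values — are independent
of the sequence.

### Estimator note

Raw stem/loop density ratios conflate selection with mutational
opportunity: stems are G/C-balanced by pairing while each substitution
class requires a specific reference base. The recovery tooling
(`replay_analysis`) therefore normalizes observed stem/non-stem counts
by their expected neutral shares given per-class mutable-target
content before estimating the loop multiplier; the Complex V
multiplier is estimated as its normalized density over the mean of the
other complexes. Both carry approximate 95% CIs from Poisson counts on
the log scale.

## Problem sizes and numerical choices

Recovery and calibration tests run at 100 replicates of ~2,000
mutations (100 samples × 20 mutations/sample) for multiplier recovery
and gradient-slope checks, and 500 replicates of 150 control-region
mutations for the type-I-error calibration of the HVS goodness-of-fit
— sizes at which the estimators' CIs are a few tens of percent wide
and the chi-square approximation is accurate. Ties in severity between
overlapping reading frames resolve to the first gene in annotation
order; empty regions and empty catalogs return flagged results rather
than NaN-laden statistics; densities use exact integer position masks,
so wrap-around regions need no special-casing anywhere downstream.

## Known limitations

* The HVS boundaries and origin coordinates are standard but not
  universal; both are configurable, and the 27.54%/0.11/1.15 anchors
  hold only for the bundled values.
* DssH assumes equal fork speeds and a single OriL initiation site;
  alternative replication modes (e.g. strand-coupled) are not modeled.
* The tRNA deleteriousness call is a structural proxy; it ignores
  conservation and known pathogenicity beyond the optional override
  table. External pathogenicity classifications join by exact
  (position, ref, alt) key only.
* Survival analysis, copy-number estimation and expression analyses
  are out of scope; the mutation-load median split utility exists only
  as a convenience for downstream tools.
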