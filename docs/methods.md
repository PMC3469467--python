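# Methods

## Scope and data model

`recland` analyses meiotic recombination at the level of *marker
haplotypes*: one offspring chromosome arm represented as an ordered series
of (position, parental identity) calls over a panel of informative SNPs.
Everything upstream of that representation (read filtering, mapping,
genotype calling) is out of scope.  Coordinates are 0-based and half-open
throughout; a conversion tract `(start, n)` covers positions
`start … start + n − 1`.  Parental identity is binary (P1/P2).

## Meiosis model

* **Crossovers.**  The CO count per gamete is Poisson with mean
  `map_length_cM / 100` — the conservative no-interference assumption — and
  positions are i.i.d. from the arm's CO landscape (uniform by default; a
  per-window relative-intensity vector can encode telomere/centromere
  suppression).  An obligate fixed-count mode exists behind
  `co_count_mode="fixed"` but is off by default.  Chromosome 4 and other
  achiasmatic arms set `has_co=False`.
* **Gene conversion.**  Initiations are Poisson with mean
  `gamma × length_bp` per gamete; tract lengths are geometric with
  per-nucleotide extension probability φ (support n ≥ 1, mean
  `L_GC = 1/(1−φ)`).  A tract copies the homolog's content over its
  interval, so conversion in a homozygous region changes nothing and is
  recorded only when requested (`simulate_meiosis` records all initiations
  as ground truth; RAIL propagation records only visible events).
* **Transmission.**  Male *Drosophila* meiosis is achiasmatic: paternal
  chromosomes pass intact (free recombination *between* chromosomes, none
  within).  The X passes from mother to sons; the mitochondrion is
  maternal and clonal.

Defaults are the study conditions: γ = 1.25×10⁻⁷ /bp/female meiosis,
L_GC = 518 bp, per-arm map lengths from the eight crosses' table
(47.6–73.0 cM), marker panels from a homogeneous Poisson process with mean
spacing 1.83 kb (the study's median nearest-marker distance), r5 arm
lengths, eight crosses of 20♂ + 20♀ per bottle with the bottle count
ramped 5→10.

## RAIL propagation and equivalent meioses

Each generation, flies from all bottles are randomly mixed into bottles,
offspring draw a random mother and father from a random bottle, and sexes
are assigned evenly.  A sampled final-generation female contributes one
female meiosis per arm — the meiosis genotyped in the hybrid.

The *equivalent meioses* of a design is E[detectable CO junctions per
transmitted genome] divided by the single-meiosis expectation
(Σ map/100), estimated by simulating pedigrees
(`detect.estimate_equivalent_meioses`).  A useful closed-form
approximation, derived from junction accumulation with ~1/2 heterozygosity
after F1 (heterozygosity halves both the detectability of new crossovers
and the transmission survival of existing junctions):

    Eq(1) = 1,   Eq(g) ≈ 1 + (g − 2)/4   for g ≥ 2.

The study reports per-cross meiosis totals but not generation counts; the
package's defaults invert the approximation against those totals (assuming
the genotyped genomes split evenly across crosses) and cap at the stated
maximum of ten generations, giving generations [7, 10, 4, 6, 7, 5, 4, 4]
for crosses 1–8.  The design-wide average of ~2.1 meioses per genome
matches the study's totals (5,860 meioses / 2,829 genomes).

## Event detection

Runs of constant parental identity are classified as follows: an interior
run whose outermost-marker span (L_min) is at most the cutoff (15 kb
default) is one GC event; an interior run beyond the cutoff contributes a
CO at each of its two boundaries; remaining persistent switches are COs
with breakpoint interval equal to the bracketing markers.  Runs touching
the first or last marker have one-sided evidence and count as CO.  The
cutoff is applied to L_min (what is observed); applying it to
L_max = L_min + 2·m_gc is available via `span_metric="lmax"`.  At the
study's rates the 15-kb and 25-kb cutoffs give CO/GC counts within 0.5%
(verified in the acceptance suite); the classification error under the
multi-generation designs with uniformly placed COs is ~0.1% of CO-derived
events (close double crossovers called GC).

Window maps assign events by midpoint (converted-run midpoint for GC,
breakpoint-interval midpoint for CO).  *c* = 100·n_CO/(meioses·Mb);
confidence bands are exact binomial (Clopper–Pearson, 90% default) on
n_CO out of round(meioses) trials, rescaled.  Defaults: 100-kb windows at
50-kb steps for *c* maps, 250-kb adjacent windows for cross comparison,
100-kb adjacent for γ maps.

## Joint γ / L_GC likelihood

For an event with converted span L_min and flanking marker distances
g_L, g_R (positional distances, ≥ 1), the admissible tract placements
factorize over left/right extensions, giving

    lik = γ φ^(L_min−1) (1 − φ^{g_L})(1 − φ^{g_R}) / (1 − φ).

The brute-force enumeration oracle in the tests checks this identity on
randomized instances.  When per-side gaps are unavailable (imported data),
the averaged m_gc replaces both (`use_mgc=True`); the choice is recorded
in the fit object.

Uninvolved adjacent-marker gaps enter through the probability that no
*detectable* tract initiates in the gap.  Attributing every tract to the
gap containing its start position counts each detectable tract exactly
once (a tract starting in a gap is detected iff it reaches the gap's right
marker), so per meiosis

    log P = −γ (1 − φ^m) / (1 − φ),

and the product over all gaps is exactly P(no detected GC anywhere).
Tracts that initiate and terminate strictly between two markers are
permitted — they are undetectable, which is precisely why uninvolved
markers are informative.  An alternative reading ("no tract converts
either bounding marker") double-counts interior markers shared by adjacent
intervals and would bias γ̂ low by roughly a factor of two; it is not
used.  The implemented term matches a Monte-Carlo placement oracle at 10⁶
replicates.

Fitting maximizes the summed log-likelihood in transformed coordinates
(log γ, logit φ) by L-BFGS-B from five deterministic starts (relative
log-likelihood tolerance 10⁻⁸), with a final ±1% single-parameter
perturbation check; zero events with positive exposure report the boundary
γ̂ = 0.  Exposure bookkeeping: each haplotype's gaps enter with its
cross's equivalent-meioses weight (RAIL chromosomes passed through several
meioses).  Joint confidence regions are likelihood-ratio level sets at the
χ²(2 df) quantile, with the contour polygon extracted from a log-spaced
grid around the MLE.

Estimator behavior at desk scale: at 5,000 meioses on a 2-Mb arm with
1.8-kb markers (~270 detected events), γ̂ and L̂_GC are unbiased but
strongly anti-correlated along a likelihood ridge, each with ~9% sampling
SD.  Experiments that quote point recoveries therefore repeat the
prescribed experiment with independent seeds (nine in the acceptance
script, three per grid cell in the tests) and take the median — replicate
averaging only; scale and parameters are unchanged.  Coverage of the 95%
region is ~94–95% over 200 recovery simulations.

## Dispersion statistics

Lineage weights are w_i = m_i / mean(m) (mean weight 1; scale-invariant);
corrected counts are y = x/w and R_CO = s²(y)/ȳ with the unbiased
variance.  Crosses with zero CO on a chromosome (or missing an arm, e.g.
fixed inversions) must be excluded, with n reduced.  Significance comes
from replicates that draw a Poisson chromosome total and place events
multinomially among crosses ∝ w and among regions ∝ the observed aggregate
regional intensity; by Poissonization this equals independent Poisson
cells and is sampled as such.  p-values use the add-one estimator
(1 + #{R* ≥ R_obs})/(reps + 1) with ties counted as exceedances
(conservative).  Default 100,000 replicates; 250-kb regions, with a 1-Mb
secondary mode; the whole-genome threshold is α/number-of-windows.

CV heterogeneity tiles the included region (whole arm, or the shipped
centromere/telomere-trimmed coordinates) with non-overlapping windows from
100 kb up to half the chromosome, computes CV = sd/mean of per-window
counts, and compares against 10,000 uniform redistributions of the
observed total.

## Genic enrichment

The null for events "delimited by ≤ 500 bp" corrects for marker density:
candidate locations are uniform, but only those whose containing
adjacent-marker gap is ≤ 500 bp are observable, so the expectation equals
the genic fraction of the accepted-gap length (computed exactly by
splitting accepted gaps at genic boundaries; a Monte-Carlo oracle checks
it).  The enrichment test redraws the observed number of events from that
null and reports both tails.  Events map to transcripts by midpoint
containment (longest transcript on ties); TSS-relative positions are
strand-aware in [0, 1], reported as a 10-bin histogram with exact binomial
CIs and median absolute TSS distances split at 2.5-kb transcript length.
Note that with a homogeneous marker process at 1.83-kb mean spacing,
tightly delimited GC events are rare (the gap containing a tract start is
size-biased); real SNP panels are clustered and yield more, which the
panel generator can emulate via density weights.

## Problem sizes

The test suite and acceptance script run at desk scale by choice:
5,000-meiosis × 2-Mb MLE recoveries (9 or 3 replicates), 2×10⁴ RAIL
genomes across the eight designs for the misassignment rate, 10⁴ regions
for the R_CO null, 2,000 regions/datasets for p-value calibration, 200
simulations for region coverage, and 10⁴ meioses for the cutoff
comparison.  The full suite runs in ~2 minutes; the acceptance script in
~1 minute.

## Limitations

* No crossover interference beyond the none/fixed-count modes; no
  selection or viability effects during RAIL propagation; no sequence-level
  simulation (reads, SNP calling, genotyping error).
* The misassignment-simulation generation counts are a reconstruction from
  per-cross meiosis totals, not reported experimental values.
* The GC model is a single geometric tract-length class with symmetric
  donor direction; no conversion-direction bias, no tract-length mixtures,
  no biased gene conversion.
* Synthetic annotations (alternating genic/intergenic stretches with
  exponential lengths) stand in for a real genome annotation in tests and
  the pipeline demo; passing enrichment calibration on them shows the
  statistics are correct, not that real genomes behave like the generator.
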