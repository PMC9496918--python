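# Methods

## Read-depth karyotyping model

ulcWGS provides no allele-fraction information at useful depth, so copy
number is inferred from read depth alone. The genome (GRCh38 primary
assembly, chr1–22, X, Y) is tiled into fixed-width bins — default 1 Mb,
~3,100 bins — and aligned read starts with mapping quality ≥ 20 are counted
per bin. At 1 Mb resolution and ~2×10⁶ reads per sample each autosomal bin
holds a few hundred reads, enough to resolve single-copy arm-level changes
while keeping Poisson noise per bin near 4% CV; unplaced and alternate
contigs are discarded.

**Panel of normals.** Each of ≥ 2 donor profiles is converted to count
fractions (bin count over the sample's autosomal total). Per bin, the
reference level *m_i* is the median fraction across donors and the
dispersion *d_i* the raw median absolute deviation. Bins are masked when
*m_i* = 0 or *d_i*/*m_i* > 0.3 (tunable); masked bins never enter ratio
computations. X bins are referenced within the matching sex stratum and Y
bins from male donors only. After masking, *m* is rescaled so the usable
autosomal reference sums to exactly 1, which makes the tumor/PON ratio an
exact identity (r ≡ 0, tolerance 10⁻¹²) for any tumor proportional to the
reference.

**Normalization.** For a tumor with counts *c_i* and usable-autosomal total
*C*, the per-bin signal is r_i = log2((c_i/C)/m_i); zero-count bins are
floored at a configurable minimum (default −5). Optional GC correction
subtracts the median r within each GC decile, computed over valid autosomal
bins — a self-normalizing step with no smoother dependency, off by default
because the simulator's GC bias is also optional.

**Segmentation.** Per chromosome, recursive binary splitting: the candidate
breakpoint maximizing the pooled-variance two-sample *t* statistic between
left and right means is accepted when t > 4.0 and both sides keep ≥ 3 valid
bins; recursion continues on accepted halves. A single split is blind to a
short focal event inside a long region (its *t* is diluted by the pooled
variance), so when no split passes, the best interior segment versus the
rest of the region is tested with the same statistic — the circular idea of
CBS — and, if accepted, the region is split into three. Flanks smaller than
the minimum segment size are never created. On ≤ 30-bin instances with one
change point the accepted breakpoint equals the exhaustive-search argmax of
the t statistic, by construction. The threshold 4.0 keeps the per-genome
false-split rate low (~3,000 bins, thousands of implicit candidate tests);
occasional 3-bin telomeric artifacts can still appear and are emitted as
reviewable sub-arm events rather than suppressed.

**State calling.** Continuous CN = baseline·2^r, with baseline the
sex-appropriate germline copy number (2 on autosomes). Integer CN rounds
half-up, floored at 0. Labels from log2 thresholds: neutral |r| < 0.2, loss
r ≤ −0.2, deep loss r ≤ −1.0, gain r ≥ 0.2, amplification r ≥ 1.0. The
±0.2 neutral band sits safely below a clonal single-copy change (|r| =
0.585) yet above bin-level noise at the default depth; at tumor purity p a
single-copy event shows |r| = |log2(1 ± p/2)|, so events remain callable
down to p ≈ 0.5. No purity/ploidy joint inference is attempted: the
reported continuous CN assumes purity 1 and is otherwise an attenuated
(conservative) estimate; purity enters only the simulator. Both
diploid-relative (CN/2) and absolute scales are exposed — panel reports
print the relative scale (a heterozygous loss ≈ 0.62 relative ≈ 1.24
absolute).

**Karyotype estimation.** An arm is called gained/lost when ≥ 60%
(`arm_fraction`) of its valid bins lie in segments of that direction; a
chromosome is whole-gained/lost when both arms agree (on acrocentric
chromosomes 13/14/15/21/22 the q arm alone decides, since p-arm material is
heterochromatic). Non-neutral segments not absorbed by an arm call become
add/del events with Mb coordinates; band-level notation would require a
cytoband table (optional input, not bundled). The rendered total is always
46 + whole gains − whole losses. Flagged segments are emitted for human
review; the dual-reviewer consensus step of the clinical workflow is out of
scope.

## Variant triage

Filter semantics follow the clinical rule set with explicit boundary
conventions: depth strictly > 100×, VAF ≥ 0.05 (the inclusive reading of a
"5%" cutoff), population frequency strictly < 0.05, and a missing
population frequency treated as 0 — absence from population databases is
evidence of rarity. All four choices are config-overridable.
Pathogenicity scoring is a criteria-and-points scheme: the shipped
`vicc_points.yaml` holds default point values and category thresholds
(oncogenic ≥ 10, likely oncogenic 6–9, VUS 0–5, likely benign −6…−1,
benign ≤ −7) that users must review against the published SOP; the package
treats them as configuration, not as a re-derivation of the catalogue.
Evidence matching is exact on gene and alteration string against a local
TSV knowledge base — no live database clients; cross-entity matches are
returned flagged with provenance and their stored tiers, never silently
downgraded, because no formal downgrade rule is defined. Ranking is a
stable total order: ESCAT tier, then DKTK level, then on-label < off-label
< trial, with early-phase trials demoted when timely treatment is required.

## Concordance accounting

A panel CNA is confirmed when ≥ 50% (`min_overlap_fraction`) of its gene
interval overlaps ulcWGS segments of agreeing direction
(gain/amplification vs loss/deep-loss). The confirmation criterion is not
formally defined in the clinical workflow, so both the overlap fraction and
the direction mapping are explicit configuration. Matching is segment-level
because panel calls are gene-granular. Non-neutral ulcWGS segments
unmatched by any panel call are "additional"; off-panel means zero overlap
with the panel target regions. Summary percentages are integer, half-up,
and reported as undefined (not 0) for empty denominators.

## Outcome statistics

PFSr = PFS2/PFS1, reported half-up to one decimal; PFS1 missing or zero
yields "n/a". Benefit classification: progression/death before 3 months on
therapy or a permanent toxicity stop → none; ≥ 6 months to progression →
major; 3–6 months → minor, as is clinical response with < 3 months
follow-up. Both cutoffs are inclusive — a patient progressing exactly at 6
months is a major benefit. A censored record under 3 months without
clinical response is not evaluable and raises rather than guessing.
Patients still on therapy at data cutoff are censored at their follow-up
length.

Kaplan–Meier estimation is delegated to lifelines (median = earliest time
with S(t) ≤ 0.5, undefined if never reached). The log-rank tabulation is
computed in-package so the per-event-time O−E and hypergeometric variance
terms are inspectable; the chi-square statistic (1 df) matches lifelines on
the same data. The Mann–Whitney U counts pairs a > b plus half-ties; with
both n ≤ 8 the two-sided p-value comes from exhaustive permutation
enumeration (tie-safe), otherwise from the tie-corrected normal
approximation with a 0.5 continuity correction (agreeing with
scipy.stats.mannwhitneyu in the respective regimes).

## Synthetic data: what it emulates and what it does not

Bin counts are Poisson around expectations proportional to bin width × GC
factor × sex-appropriate dosage, rescaled to a target total (default 2×10⁶
reads ≈ 0.2× coverage with 2×150 bp reads; the target depth is a package
choice, documented here, since only a < 0.5× bound is specified
clinically). Negative-binomial overdispersion is available but off by
default. Tumor expectations multiply each bin by purity·CN/base +
(1 − purity), overlap-weighted for partially covered bins; optional
renormalization to the target total is recorded as a flag (off by default
so the multiplier is directly interpretable). The default panel has 20
donors, 10 male / 10 female.

Not emulated: fragment-level GC effects, mappability structure, replication
timing waves, germline CNVs in donors, subclonal heterogeneity, and real
centromeric/telomeric artifact structure. Passing recovery tests therefore
shows the estimator is correct under its stated noise model, not that real
tissue artifacts are handled; the PON masking and review-oriented event
output are the mitigations for the latter.

Outcome cohorts draw PFS2 from exponential distributions with arm medians
4.3 (matched) and 1.9 (other) months and PFS1 exponential with median 3
months — only medians are known, so the one-parameter family is the minimal
assumption. Censoring truncates the true time uniformly with a configurable
probability (default 0 — the evaluable clinical cohort consisted almost
entirely of progressors). Response/toxicity flags are drawn at 20%/5% and
never co-occur on a record.

## Validation studies and sizes

The replication studies run at deliberately modest sizes so the whole suite
completes in seconds on one CPU: 20 simulated tumors (two whole-arm events
each, purity uniform on [0.5, 1], 1 Mb bins, 2×10⁶ reads) for arm-event
recovery; one purpose-built sarcoma-like tumor (1p loss, focal 4q12
amplification over PDGFRA/KIT/KDR, partial 4q loss over FBXW7); 1,000
random variants for filter/oracle agreement; 100 replicate cohorts
(n = 30 vs 17) for log-rank power. Note the power study's expected value at
these sample sizes and an exponential data-generating process is ~0.75
(Schoenfeld approximation and Monte Carlo agree), so the replicate fraction
fluctuates around that value from seed to seed; it is reported as measured.

## Known limitations

- No BAF/purity/ploidy inference: a low-purity tumor attenuates toward the
  neutral band and events below ~50% purity are missed by design.
- Focal events smaller than `min_seg_bins` × bin width (3 Mb at defaults)
  are invisible; shrink the bin width for finer resolution at the cost of
  per-bin depth.
- The knowledge base and fusion-rule tables are small curated fixtures, not
  a clinical database; they define the matching contract, not coverage.
- Karyotype strings use Mb coordinates for sub-arm events; ISCN band names
  need an external cytoband table.
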