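# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions a maintainer needs.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Hybridization thermodynamics (`thermo`)

**Model.** Two-state duplex formation only: probes are ≤ 40 nt, where hairpin
or partition-function effects are second order for hydrolysis-probe work.
ΔH/ΔS are summed over nearest-neighbor stacks using the unified DNA/DNA
parameter set, with published single-internal-mismatch and terminal-mismatch
tables for mispaired steps.  The parameter *tables* are imported from
`Bio.SeqUtils.MeltingTemp` (they are published data); all summation logic,
the LNA model, bulges, salt correction and bound-fraction arithmetic are
implemented here.

**LNA parameterization.** Each matched internal locked residue contributes a
base-dependent (ΔΔH, ΔΔS) stabilization worth ≈ −0.9 to −1.3 kcal/mol in
ΔG°₃₇ — a condensed per-base form of published LNA duplex-stabilization data
rather than a full 32-entry locked-dinucleotide table.  The decomposition is
chosen so a locked base raises Tm in every sequence context (the numerator
condition 1000·ΔΔH < Tm·ΔΔS holds for any physical Tm).  A mismatch *at* a
locked position forfeits the stabilization and adds a penalty
(ΔΔG°₃₇ ≈ +2.5 kcal/mol); a mismatch immediately adjacent to a lock adds
≈ +1.2 kcal/mol.  This guarantees the assay-relevant ordering — discrimination
with locks ≥ discrimination without — which is the only property consumed
downstream; absolute LNA Tm values should not be over-interpreted.

**Indels under the probe.** No complete nearest-neighbor table for bulges
exists; each unpaired base costs a fixed ΔΔG°₃₇ ≈ +2.8 kcal/mol
(configurable) and breaks stacking across the bulge.  Only relative
discrimination matters downstream: a > 3 nt deletion under the probe center
drives the annealing-temperature bound fraction below 5% for either probe
chemistry, which is the behaviour the drop-off principle requires.

**Salt.** Owczarzy-style 1/Tm correction with free Mg²⁺ = max(Mg²⁺ − dNTP, 0)
(dNTPs chelate magnesium stoichiometrically), monovalent/divalent regime
selection by √[Mg²⁺]/[mon⁺], at the assay conditions Mg²⁺ = 3.0 mM,
dNTP = 0.8 mM, 50 mM monovalent.  Total strand concentration defaults to
250 nM (conventional hydrolysis-probe usage).

**Bound fraction.** The salt-corrected Tm is converted to an effective entropy
so that the mass-action bound fraction equals exactly ½ at T = Tm for the
reference strand concentration (CT/4 convention, non-self-complementary); this
makes "bound fraction at the annealing temperature" and Tm mutually
consistent by construction.

## Assay design (`assay_design`)

Cut-site convention: blunt double-strand break 3 nt 5′ of the PAM, stored as a
0-based inter-base coordinate.  The locked triplet covers the two bases 5′ and
one base 3′ of the scissile phosphate, shifted minimally away from ≥ 4-long G
runs.  Defaults: amplicon window 110–160 bp with 134 bp preferred (the length
search starts there, so the conventional size is emitted whenever feasible);
primers 18–28 nt; probes 16–32 nt; probes melt 3–6 °C above the hottest primer
(so probes are bound before extension) and within 2 °C of each other; the
reference probe stays ≥ 8 nt from the cut.  Candidates are enumerated in a
fixed order and ranked by a composite penalty (Tm deviations, GC extremes,
homopolymer runs, amplicon-length deviation), so design is deterministic.
`validate_assay` re-measures every invariant independently of the search; the
closed-loop property (every emitted assay validates) is tested on random
references.

Allele-specific probe pairs share one footprint, differ only at the variant,
carry a locked doublet over the discriminating site, and must keep the variant
≥ 2 nt from either probe end (terminal mismatches barely discriminate).

## qPCR quantification (`qpcr_quant`)

Standard ΔΔCq with assumed efficiency 2.0 on both channels; the
calibration-slope check (OLS of ΔCq on log₁₀ input, pass iff |slope| ≤ 0.1,
the conventional cutoff) is the guard on that assumption.  Replicates:
mean/SD/SEM over non-flagged wells; with ≥ 3 replicates a well further than
0.5 cycles from the group median is excluded as an outlier.  SEM of the wt
percentage is first-order: sd(ΔΔCq)² sums the four replicate-mean variances
(sample and calibrator, both channels) and sem(wt%) = wt% · ln 2 · sd(ΔΔCq).
Estimates above 100% are clipped for reporting with the raw value retained;
no-amplification wells are flagged, never imputed to a Cq of 40.  A sample
whose target channel never amplifies is reported 0% with a below-detection
flag.

The drop-off and trans-multiplex configurations differ in where the reference
signal comes from (same wells vs an external assay), not in the estimator;
the mode is recorded and validated but shares the arithmetic.

## dPCR quantification (`dpcr_quant`)

Partition classes: double-positive, reference-only, target-only,
double-negative.  Auto-thresholding finds the valley between the two largest
modes of each channel's (lightly smoothed) fluorescence histogram and demands
the valley be < 30% of the smaller mode's height — a unimodal channel raises
an error instructing manual thresholds rather than guessing.  Target-only
partitions are biologically anomalous (the target site rides inside the
reference amplicon); they are counted toward λ_target but flagged.

Occupancy: λ = −ln(1 − p) per channel; the two probe sites are treated as
perfectly linked (one molecule carries both), so wt% = 100·λ_t/λ_r.  CIs:
Wilson interval on p transformed through −ln(1−·) for single-λ estimates
(well-behaved near p = 0 and 1).  For the ratio, the two positive fractions
share partitions and are strongly positively correlated; the CI therefore
propagates the joint multinomial covariance of (p_t, p_r) to first order
(delta method).  Ignoring that covariance inflates the interval and pushes
empirical coverage above 98%; with it, measured coverage sits near 95%
(computed in the acceptance suite).

## Allele classification (`allele_classify`)

Global pairwise alignment with affine gaps via Biopython's `PairwiseAligner`
(match +1, mismatch −2, gap open −5, gap extend −1 — weights chosen to favor
parsimonious indel calls at amplicon scale), orientation auto-detected by
aligning both strands.  Identity is measured over the shorter sequence, floor
60%: below it a clone is rejected as off-target/vector; a cleanly truncated
clone instead fails the window-coverage check.  Variants are normalized
VCF-style: indel runs are merged and left-shifted through identical context,
substitutions are per-position.  The test suite checks score and
variant-call agreement against an independently coded exhaustive Gotoh DP
that enumerates *all* co-optimal alignments.

Taxonomy inside the analysis window (default 70 nt centered on the cut,
matching the span used for clone tallies in this assay family): zero variants
→ wt; all HDR components and nothing else → HDR; a nonempty subset of
components and nothing else → partial_HDR; otherwise one variant class →
deletion/insertion/point_mutation, two or more → mixed.  HDR-component
presence is read off the aligned bases at the component coordinates, so a
deletion through a component never counts as "present".  Variants outside the
window are recorded separately and never affect the category; both tallies
appear in reports because the field convention for counting them toward
"mixed" is ambiguous.  Distinct alleles are counted by exact variant-set
identity after normalization; an optional mode collapses singleton-clone
alleles that differ from an abundant allele by one substitution (sequencing
error concession, off by default since plasmid clones are high quality).

## Endpoint genotyping (`endpoint_genotype`)

Channels are normalized by NTC-subtracted control maxima (the NTC noise floor
is expressed relative to the control maxima, so calls are invariant to
common-mode gain).  Samples and control centroids live in (signal angle,
amplitude) coordinates; distances are chords (law of cosines), i.e. the exact
discrimination-plane separation expressed in polar coordinates — a naive
Euclidean metric on raw (angle, amplitude) tuples distorts distances when
cluster amplitudes differ.  Calls: nearest control centroid; amplitude below
3 NTC-SDs → indeterminate; distance beyond 3× the widest per-class control
spread (RMS radial) → founder_mosaic_candidate, since mosaic founders carry
non-Mendelian allele ratios and land between the control clusters.  NTC
samples never receive a genotype.  At adjacent-cluster separations of ~5 SD
the Bayes error of any three-class rule on such clusters is already ≈ 0.8%
(the middle cluster faces two 2.5σ boundaries), so the < 1% operating claim is
verified at 6-SD separation, comfortably inside the well-separated regime the
assay is designed to produce.

Dose-response linearity: OLS of the max-normalized mutant-channel signal on
the known mutant fraction, pass iff r² ≥ 0.98.

## Simulator (`simulate`)

The generator emulates the study system: founders carry 1–5 distinct alleles
(uniform count — the true distribution is not recoverable from published
aggregates) with Dirichlet(1) fractions; category probabilities default to
{wt .25, HDR .07, partial_HDR .10, deletion .33, insertion .10,
point_mutation .05, mixed .10}, loosely shaped like published clone tallies
(deletions dominate NHEJ outcomes; full HDR is rare; partial HDR is a sizable
share of HDR-related events).  Alleles are concrete sequences in the analysis
window: deletions of 1–12 nt and insertions of 1–6 nt at the cut, HDR
component subsets, substitutions clear of component coordinates, mixed =
small deletion plus a well-separated substitution.  Edits stay ≥ 3 nt from
window edges so the round trip through the classifier is unambiguous.

qPCR signals: channel signal = binding-weighted allele mass;
Cq = 24 − log₂(signal) + N(0, σ), σ default 0.1 cycles (triplicates).
Binding comes from a per-category table — presets for an ideal LNA probe
(wt-only), an oligo-style probe (single-base changes and 1-nt insertions
half-bound, mimicking the published mismatch-sensitivity panel's structure;
the panel is printed as a figure, so the table is a structured free
parameter), a uniform edited-binding table, or thermodynamic bound-fraction
ratios via `thermo`.  dPCR chips: Poisson copy loading (default λ = 0.6 —
mid-range occupancy, where the estimator is most informative per partition —
over 20,000 partitions), per-copy Bernoulli probe binding, optional Gaussian
fluorescence rendering.  Clone draws are multinomial; endpoint samples are
Gaussian clusters with the HET centroid at the WT/HOMO midpoint and mosaic
centroids interpolated by mutant fraction.

**What the simulator does not emulate** — and hence what passing tests do not
show about real data: per-cycle PCR kinetics and efficiency drift, Sanger
chromatogram/base-calling error, chip loading artifacts and partition-volume
variation, inter-run calibration drift, and any real founder's allele
spectrum.  Recovery results certify the estimators against their own
generative assumptions, not instrument behaviour.

## Problem sizes and numerics

The acceptance suite runs the study-scale conditions: 500 simulated plates per
true-wt level at σ(Cq) = 0.1 on the grid {5, 15, 30, 50, 85, 95}%; 200 chips ×
20,000 partitions per level on {5, 25, 50, 75, 95}%; 500 seeds per arm for the
dPCR-vs-qPCR precision comparison at 5% and 95% wt (qPCR at σ = 0.15); 1,000
classified clones; 100 random references for design soundness; 1,500 genotyped
samples; a 20-animal cohort for byte-level determinism.  Recovery of the ΔΔCq
estimator is assessed as parameter-recovery error (|mean estimate − truth| per
level): the per-plate absolute error at high wt is dominated by the ~8%·wt
relative noise floor that triplicate Cq noise imposes on 2^(−ΔΔCq), which is a
precision statement, not a bias; the bias-direction demonstration for
half-bound probes runs noise-free to isolate the structural effect.  All
randomness flows through `numpy.random.Generator` seeded per operation;
reports round floats at fixed precision so reruns are byte-identical.
Coordinates are 0-based half-open internally, 1-based inclusive in
human-facing reports.

## Known limitations

* Absolute Tm values for LNA probes use condensed per-base increments, not a
  full locked-dinucleotide table; rely on relative discrimination only.
* The ΔΔCq route assumes efficiency 2.0; no Pfaffl-style multi-efficiency
  correction (the slope check is the guard).
* dPCR assumes perfect linkage of the two probe sites and no partition-volume
  variation; target-only partitions are flagged, not modeled.
* The genotyper needs at least one control per class and is control-anchored
  by design; it does not cluster unknowns de novo.
* Mixed-trace deconvolution of heterozygous Sanger traces, chromatogram
  parsing and off-target discovery are out of scope.
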