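# Methods

## Problem and data model

A proximity-labelling experiment tags the neighbours of a lectin bait on
the cell surface with biotin; streptavidin enrichment and label-free
quantification (LFQ) then yield, per labelling experiment ("dataset"),
one intensity per protein for the active bait and one for a non-binding
control. A dataset is the unit of replication: three biological
replicates, each labelled with an in-solution and an on-bead bait
multimer, give six datasets. The pipeline's inputs are a protein-group
quantification table (one LFQ intensity column per sample), the sample
design (which sample is bait/control of which dataset), and a flat
per-protein annotation table (cellular-component class, plasma-membrane
flag, predicted N-glycosylation site count, Ig-like domain count).
Annotation is an input, not a lookup: subcellular classes and predicted
sites come from curated databases upstream.

An LFQ intensity of zero means "not quantified", not "measured zero";
the readers map empty and zero cells to MISSING and preserve the
distinction through round trips.

## The four filtration stages

**Fold changes and imputation.** Per dataset, `x = log2(bait/control)`.
MISSING values are imputed at the sample's noise floor (default the 1st
percentile of its quantified intensities) before the ratio, because
bait-only proteins — present with bait, below detection with control —
are exactly the signal the labelling chemistry produces, and dropping
them would discard the strongest hits. Every ratio computed with an
imputed side carries an `imputed` flag. Flagged ratios are *bounds*, not
measurements (a control dropout bounds the true ratio from below, a bait
dropout from above), so they participate in effect estimation (the
volcano) but are excluded from null-quantile calibration and from
back-mapping judgements by default; both policies are configurable.
Excluding them from calibration matters quantitatively: imputed bait-only
ratios of mid-abundance proteins reach +5 to +7 log2 units and would
otherwise dominate the extreme quantiles of the null.

**Stage 1 — labelling-tail assessment.** The tail is judged per dataset
on the fold-change histogram split by compartment: membrane proteins
develop a high-end excess (the proximity labelling tail), non-membrane
proteins do not. The visual call is operationalised scale-free: the
cutoff is the `tail_quantile` (default 0.99) of the measured non-membrane
ratios; proteins *strictly* above it are counted per class; membrane
enrichment among them is scored with a one-sided hypergeometric test; the
tail is present when ≥ `k_min` (20) membrane proteins are above the
cutoff with p < `p_tail` (0.01). Datasets without a tail are excluded;
fewer than two retained datasets aborts the run.

**Stage 2 — paired-t volcano.** Fold changes are paired within datasets,
so a one-sample t on each protein's per-dataset ratios across all
retained datasets (pooled over multimer formats) is the paired t-test.
Proteins observed in fewer than two retained datasets are skipped and
audited. Zero-variance vectors occur in small-n proteomics and must not
crash: with nonzero mean, p is set to the smallest positive float and
flagged DEGENERATE; with zero mean, t = 0 and p = 1.
Benjamini–Hochberg q values are computed across all tested proteins;
selection uses raw p < 0.05 by default (q by flag) together with mean
log2FC > 1, positive side only. The defaults are consistent with the
printed extrema of the published counter-receptor list (minimum log2FC
1.195, maximum p 0.0194).

**Stage 3 — annotation filter.** A counter-receptor must be a
glycoprotein on the cell surface: candidates are kept when
plasma-membrane-annotated with ≥ 1 predicted N-glycosylation sequon.
Removal reasons are audited (UNANNOTATED / NO_GLYCOSITES /
NOT_PLASMA_MEMBRANE, exactly one per protein).

**Stage 4 — back-mapping.** Candidates are mapped back onto each
retained dataset's histogram and removed if found outside the tail in
any of them. The back-mapping boundary is *not* the detection cutoff:
detection asks whether an extreme excess exists (an extreme-quantile
question), back-mapping asks whether a protein lies within the tail
region, whose base sits at the null distribution's upper shoulder. The
boundary is therefore a separate, lower quantile of the measured
non-membrane ratios (`backmap_quantile`, default 0.85, ≈ 1 sd above the
null centre). Comparison is ≥ (a value on the boundary is retained —
conservative tail calling, permissive retention, deliberately asymmetric
to the strict > of stage 1); proteins are judged only in datasets where
they were measured (flags switch to judging imputed ratios and/or
requiring presence in all retained datasets).

The report records the assessments, the volcano, the nested stage sets,
the final set, and a per-protein audit; identical inputs give
byte-identical reports.

## Synthetic study conditions

The generator emulates the six-dataset design with a known truth.
Defaults: 2000 proteins, 30% membrane-annotated (80% of those
plasma-membrane), 50 spiked counter-receptors drawn from plasma-membrane
glycoproteins with log2 effects ~ Normal(2.5, 0.5) truncated at 0.5;
per-protein log10 baselines ~ Normal(6.5, 0.8); per-dataset bait noise
2^Normal(0, 0.6) applied to the ratio; molecular weights log-normal
around 50 kDa. Under this construction a null protein's fold change is
Normal(0, replicate_sd) exactly, which the tests verify in closed form.

Missingness is missing-not-at-random: the missing probability follows a
logistic censoring curve in log10 intensity (steepness `mnar_strength`,
default 4 per decade) whose *marginal* rate equals `missing_rate_base`
(default 0.1). This matches the intensity-dependent dropout of real LFQ
data — low-abundance values vanish often, high-abundance values almost
never — and it is the regime the noise-floor imputation policy is
designed for. Flags degrade chosen datasets to pure noise (exercising
dataset exclusion) and add "sticky" cytoplasmic contaminants at small
positive effects (exercising the annotation filter).

What the generator does not model: peptide-level quantification and
protein inference, between-run normalization drift, correlated
multimer-format effects beyond a shared effect size, annotation errors
(available separately as an explicit corruption step), and real
biological covariance between abundance, membrane residency and
glycosylation. Passing recovery tests therefore demonstrates that the
statistical logic is sound under realistic noise, missingness and class
structure — not that real acquisitions meet these assumptions.

Under the default conditions the pipeline attains mean sensitivity
≈ 0.95 at a false-discovery proportion ≈ 0.01 (20 seeds), and with zero
spikes the tail fires in < 1% of datasets (100 seeds); the acceptance
tests assert ≥ 0.9, ≤ 0.1 and ≤ 5% respectively, at exactly these
problem sizes (a full 20-seed sweep takes ~15 s on one core).

## Glycan masses and annotation

Masses are monoisotopic, derived at import from elemental formulas of
the permethylated residue increments (Hex C₉H₁₆O₅ = 204.0998 Da, HexNAc
C₁₁H₁₉NO₅ = 245.1263, dHex C₈H₁₄O₄ = 174.0892, NeuAc C₁₆H₂₇NO₈ =
361.1737, NeuGc C₁₇H₂₉NO₉ = 391.1842, Pent C₇H₁₂O₄ = 160.0736) plus the
free-reducing permethylated end group C₂H₆O and the Na⁺ adduct
(22.9892 Da). Formulas are the single source of truth; no mass decimal
is hard-coded. Nominal m/z is the nearest integer of the monoisotopic
[M+Na]⁺ value, matching how spectra are labelled. Glycolipid glycans are
treated with the same free-reducing end group as N-glycans — the
published peak values are reproduced under that convention; the reduced
(alditol) convention (end group C₃H₁₀O, i.e. +CH₄) is available by flag.

Composition enumeration applies biosynthetic constraints: N-glycans need
the trimannosyl-chitobiose core (HexNAc ≥ 2, Hex ≥ 3) and sialic acids
bounded by antennae + 1 (NeuAc + NeuGc ≤ HexNAc − 1); glycolipid glycans
need the lactosyl core (Hex ≥ 2) and exclude fucose by default. Peak
matching uses an absolute tolerance (default 0.5 Da, the MALDI-TOF
reflectron scale; the acquisitions' true calibration is unknown, so the
tolerance is configuration). All candidates within tolerance are
reported sorted by |error|, ties broken lexicographically; compositions
identical in mass (e.g. alternative Hex placements) are inherently
unresolvable and reported as compositions only. NeuAc/NeuGc counterpart
ratios are `I_NeuAc / (I_NeuAc + I_NeuGc)` over peaks whose best
assignment is the composition; pairs must differ exactly by
NeuAc→NeuGc substitutions (CH₂O, 30.0106 Da each).

## Characterization

*Membrane proteome*: union of lysate and surface identifications per
replicate, kept at ≥ 2 distinct replicates of evidence, intersected with
the membrane annotation class. *Fraction*: |counter-receptors ∩
proteome| / |proteome| × 100, one decimal. *Histone ruler*: copies_i =
(I_i / ΣI_histones) · m_DNA · N_A / MW_i, with m_DNA defaulting to the
5.9 pg mouse diploid genome; the histone accession set and DNA mass are
configuration because the upstream acquisition does not fix them; mass
closure over the histone set (Σ copies·MW/N_A = m_DNA) holds to 1e−9
relative by construction and is tested. *Sequons*: the N-X(≠P)-[S/T]
scan, overlapping motifs all reported, 1-based; when no sequence is
supplied the annotation table's database-predicted count is used
directly. *Sequon density*: sites per Ig-like domain, compared between
counter-receptors and other Ig-superfamily proteins as counts above/at
most one site per domain plus medians. *Abundance mapping*: log10-spaced
bins over proteins with abundance strictly above the threshold (default
100 normalized counts); bin membership is exhaustive and disjoint, with
per-bin counter-receptor flags. *Glycogene panel*: per-gene condition
means, log2((mean+1)/(mean+1)) fold change, a plain two-sample t and BH
across the panel only — deliberately a panel summary, not a
differential-expression engine.

## Numerical and policy choices

- Quantiles: numpy's default linear interpolation; cutoffs are floats,
  not data values.
- Tie handling: strictly greater-than for tail counts, ≥ for back-map
  membership (documented asymmetry above).
- Degenerate inputs: empty volcano, empty proteome, zero histone signal,
  all-missing samples and undefined ratio pairs raise typed errors or
  return flagged results; nothing silently coerces.
- BH q values are clipped to ≥ p (the step-up already guarantees it; the
  clip documents the invariant).
- The published-list fixture stores the printed p values verbatim
  without deciding whether they were BH-adjusted upstream; selection
  defaults to raw p accordingly.
- Determinism: every stochastic routine takes an explicit seed; reports
  serialize with sorted keys.

## Known limitations

- The tail call reduces a visual judgement to three numbers (quantile,
  k_min, p_tail); datasets with diffuse enrichment but < k_min extreme
  proteins are excluded by design.
- The paired t pools multimer formats; a per-format stratified test is
  not implemented.
- Back-mapping with `backmap_require_all_datasets` penalizes proteins
  with MNAR dropout in any single dataset; the default
  observed-datasets-only policy is the recommended one.
- Mass annotation is composition-level only: no linkage inference, no
  isotope-pattern or MS/MS fragment modelling.
- The histone ruler inherits its constants; absolute copy numbers are
  only as good as the DNA-mass assumption and the histone set supplied.
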