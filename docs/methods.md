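# Methods

This note documents the models, defaults and design choices behind
`conjnet`, and what the synthetic-data generator does and does not emulate.

## Exact-mass arithmetic (`conjnet.chemmass`)

Monoisotopic masses are hard-coded most-abundant-isotope values (IUPAC/CIAAW
2021 atomic-mass evaluation; C, H, N, O, P, S, Na, K, Cl). Ion m/z is

    m/z = (M(neutral + Δ_ion) − z·m_e) / |z|

with the electron mass m_e = 0.000548580 Da included: omitting it shifts a
singly charged anion by ~0.0005 Da, which is visible at the fourth decimal
of high-resolution theoretical masses (e.g. 392.2073 vs 392.2079 for
C₂₁H₃₀NO₆⁻). Only |z| = 1 species are modelled; isotope envelopes and
in-source fragmentation are out of scope.

Conjugation is pure formula algebra: hormone + amino acid − H₂O, guarded
only by count feasibility (the hormone must contain carbon; subtraction must
not go negative) — no structural check is attempted. The 20 proteinogenic
free amino acids are built in (selenocysteine excluded); Leu and Ile yield
identical conjugate formulas and every equal-formula pair is cross-flagged
as mass-indistinguishable so downstream screens report a joint label.

The default hormone set is dn-iso-OPDA C₁₆H₂₄O₃, OPDA C₁₈H₂₈O₃ and jasmonic
acid C₁₂H₁₈O₃. The dn-iso-OPDA neutral formula is *reconstructed* from its
conjugate ion formulas (subtracting the amino-acid part and restoring the
condensation water); it is not independently tabulated, so treat it as a
derived constant, not a literature value.

## Feature tables, spectra, QC (`conjnet.feature_io`)

Retention time is minutes everywhere (MGF `RTINSECONDS` converted on
read/write). Polarity is a per-feature column (+1/−1) so one table can hold
both electrospray modes. Missing intensities are missing, never zero.

QC filtering computes the relative standard deviation (sample SD, n−1
denominator, over raw intensities) across pooled-QC injections and keeps
features with RSD strictly below the cutoff (default 0.25). A feature with
fewer than two non-missing QC values, or zero QC mean, cannot demonstrate
reproducibility and is removed — the conservative choice. The filter is
idempotent and never increases the feature count.

Weight normalization divides biological-sample intensities by per-sample
tissue weight (mg); QC injections are pooled aliquots and are left
untouched. The source protocol this mirrors described normalizing "to the
weight of seeds" although the organism is a thalloid liverwort — we read
that as a template slip for tissue weight and implement generic per-sample
weight normalization. A `normalized` flag guards against double
application, which would silently square the correction.

## Modified cosine and networks (`conjnet.spectral_network`)

Fragment pairs are candidates when |Δm/z| ≤ tolerance (default 0.02 Da)
either directly or after subtracting the precursor mass difference
(modified cosine; disable the shift for the plain cosine). Intensities are
raised to `intensity_power` (default 0.5, square-root weighting — the
common networking convention) and L2-normalized; the score is the total
product weight of a one-to-one matching of candidate pairs.

The matching is solved exactly as an optimal assignment
(`scipy.optimize.linear_sum_assignment`). We chose the exact matcher over
the traditional greedy descending-score heuristic because it makes the
reported score a well-defined quantity — the maximum over all one-to-one
matchings — instead of an implementation-dependent approximation; greedy
remains available (`CosineParams.matching = "greedy"`) and can only score
lower. On small spectra the two almost always coincide. A score is zeroed
when fewer than `min_matched_peaks` (default 4) pairs match.

Networks connect same-polarity spectra with score ≥ 0.7 (default) and
enough matched peaks; the two electrospray modes are never scored against
each other (they are acquired and networked separately). Clusters are plain
connected components — no top-K edge pruning, since nothing in the source
procedure indicates pruning. Raising the threshold can only refine the
partition. GraphML export is Cytoscape-loadable; an edge-list + node-table
export is also provided.

## Annotation cascade (`conjnet.annotate`)

Step 1 (exact mass / RT): a feature matches a library entry when |Δm/z| ≤
max(0.005 Da, 10 ppm) — the stated "absolute Da or ppm" tolerance is read
permissively as the wider window — and, when the entry carries an RT
standard, |ΔRT| ≤ 0.2 min. Nearest Δm/z wins. RT-gated hits are level 1,
exact-mass-only hits level 2.

Step 2 (MS2 library): best modified-cosine hit with score ≥ 0.8 and ≥ 4
matched peaks, level 2.

Step 3 (propagation): every unannotated node of a cluster containing seeded
annotations receives the cluster's **majority** category at level 3. The
source procedure only says clusters "containing annotated metabolites" are
assigned the same category without resolving mixed clusters; majority vote
with ties broken by the strongest seed (then lexicographically) is our
resolution, and the full seed-category tally plus a conflict flag is kept in
the evidence of every propagated annotation. Seeded nodes are never touched,
so the step is idempotent.

Step 4 (external verification by fragmentation-tree software) is out of
scope; `verification_hook` records which assignments (propagated, conflicted
or Leu/Ile-ambiguous) would be re-checked.

The targeted screen matches feature m/z against conjugate-library ion m/z
of the matching polarity at 10 ppm, labelling hits "putative hormone-aa".

## Redundancy cleaning (`conjnet.dedup`)

Adduct deltas are derived at load time from the element mass table:
positive mode [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺ vs [M+H]⁺; negative mode
[M+Na−2H]⁻, [M+K−2H]⁻, [M+Cl]⁻, [M+HCOO]⁻, [M+NO₃]⁻, [M+CH₃COO]⁻ and a
sodium-formate cluster vs [M−H]⁻. The cluster's stoichiometry is not
specified anywhere authoritative; we implement [M−H+HCOOH+HCOONa]⁻ and the
rule table is user-editable.

Grouping is greedy in descending median intensity: the most intense
unassigned feature is presumed the reference ion (anchored interpretation)
and claims features at reference m/z + delta within 0.006 Da and 0.2 min
(nearest Δm/z on ties). A feature joins at most one group, preventing
chained merges; the cleaned table keeps the reference ion per group plus
all ungrouped features, so the count never grows and the operation is
idempotent. An anchor-free mode (grouping a mutually consistent adduct set
with no reference ion present) is not offered — a known limitation for
metabolites that ionize only as adducts. `audit_groups` reconstructs every
member m/z from the group's neutral mass as a self-consistency check.

Cross-polarity merging infers each cleaned feature's neutral mass (group
neutral mass, else m/z ∓ one proton) and links positive/negative records
agreeing within 0.006 Da and 0.2 min, one-to-one by smallest mass
difference. Nothing is deleted; a `preferred_mode` flag (the more intense
record) tells downstream statistics which record to keep.

## Differential statistics (`conjnet.diffstats`)

Per-feature one-way ANOVA on log10(intensity + 1) — intensities are
approximately log-normal, so the log restores normality; raw-scale analysis
is a flag away. Each genotype:treatment combination is one group (the
one-way-on-composite-groups reading; a per-feature two-way Tukey report is
available for single features). Features with identical values everywhere
are flagged `zero_variance` with p = 1. Benjamini–Hochberg controls the FDR
across features (Bonferroni available); significance is adjusted p < 0.05.
Fold changes are log₂ of pseudo-count-offset raw group means (pseudo = 1,
negligible against typical intensities ~10⁵).

## The simulator (`conjnet.synthdata`)

What it emulates: compound families sharing intense MS2 fragments (the
structural driver of network clusters) plus compound-specific and noise
peaks; exact conjugate/hormone masses from the formula algebra; adduct
series (reference ion always, other adducts with emission probability) and
cross-mode emission; genotype × treatment group means from planted log₂
effects with multiplicative log-normal noise (mean-preserving, default CV
20%); pooled-QC injections at QC CV 10%; Gaussian m/z jitter (0.001 Da),
RT jitter (0.03 min) and fragment m/z jitter (0.003 Da); and pure-noise
features with random spectra. All planted relationships are exact under the
package's own mass arithmetic before jitter, and output is byte-identical
for a fixed seed.

What it does not emulate: chromatographic peak shapes, isotope envelopes,
co-elution interference, missing-value structure, intensity-dependent mass
error, retention-time drift between runs, and in-source fragmentation.
Passing recovery tests on generator data therefore demonstrates the
pipeline's correctness on idealized, well-separated features — not its
robustness to everything real chromatography does.

The `paper_like_config` preset mirrors the study structure qualitatively:
genotypes WT / gh3a / coi1, mock vs wound, 3 replicates, four metabolic
families (oxylipins, terpenoids, phenylpropanoids, flavonoids — the
category vocabulary is configurable), nine planted hormone–amino-acid
conjugates in negative mode that are wound-induced in WT (log₂ = 2.0) and
the receptor mutant (1.5) but not the conjugation-deficient mutant, and a
free hormone that over-accumulates in the conjugation-deficient background.
No quantitative claim from any real experiment is asserted against it.

`truth_score` grades pipeline outputs: pairwise precision/recall of adduct
groups, cross-mode link recovery, network family purity (majority-family
fraction over non-noise members of multi-node components), annotation
category accuracy over non-noise features, and a differential-call
confusion matrix. `truth_libraries` derives annotation libraries from the
truth (every third compound into the exact-mass/RT library; the first
reference spectrum per family and polarity into the spectral library),
emulating partial library coverage so that propagation has real work to do.

## Problem sizes and numerical choices

The test suite runs the preset at ~150 features / ~30 compounds and the
statistics calibration at 1000 null features (2 groups × 3 replicates),
which keeps the whole suite under a minute while leaving Monte-Carlo error
well inside the asserted bands. Planted-effect recovery is asserted on the
mean recovered log₂ fold change across the 20 planted features (the
per-feature estimator at n = 3, CV 20% has SD ≈ 0.23, so only the mean is a
stable ±0.3 quantity) plus a loose per-feature bound. Cosine scores are
clipped to [0, 1] against floating-point overshoot; assignment ties are
broken deterministically; all randomness flows from one `numpy` generator
per simulated run.
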