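# Methods

## Scope and data model

The package analyses bulk TCRβ repertoires given as clonotype count tables.
Counts are consumed as UMI/PID-corrected transcript numbers; read-level
processing (alignment, UMI collapsing) is upstream and out of scope. A
clonotype is identified by its CDR3 amino-acid sequence (the default clonal
definition, used by all diversity and overlap statistics) or by the triple
(TRBV gene, TRBJ gene, CDR3) with allele suffixes stripped (used for
antigen-panel matching, where gene identity carries specificity
information). Gene labels are normalized before comparison — allele
suffixes (`*01`) removed, legacy `TCRBV`/`TCRBJ` prefixes unified with
`TRBV`/`TRBJ` — because public panels use heterogeneous nomenclature.

Filtering retains CDR3s of 8–20 amino acids drawn from the 20 standard
letters. Sequences containing stop (`*`), frameshift (`_`) or ambiguous
(`X`) characters are removed rather than raising, since the amino-acid
clonal definition implies productive-chain analysis; the alphabet filter is
a toggle (`standard_aa_only`) for users who want length filtering only.

## Rarefaction and diversity statistics

Comparisons across samples of different sequencing depths are made on
repertoires down-sampled to the smallest total count of the comparison set.
Rarefaction is a single multivariate-hypergeometric draw (sampling
transcripts without replacement), seeded and recorded; an optional `reps`
mode averages statistics over several draws. Up-sampling is never
performed.

All logarithms are natural. Shannon normalization divides by `ln S`
(Pielou evenness); this orientation is the one consistent with near-unity
values in evenly distributed blood repertoires. A single-clone repertoire
has `H = 0` and normalized Shannon defined as 0, and is flagged degenerate.
The Rényi profile is computed over the conventional order grid
{0, 0.25, 0.5, 1, 2, 4, 8, ∞} with the analytic limits at 0, 1 and ∞.

The Gini statistic is the standard inequality coefficient
`G = Σ_i Σ_j |x_i − x_j| / (2 S² x̄)` (0 = perfectly even). Because figure
conventions in this field sometimes orient "1 = diverse", both `G` and the
evenness complement `1 − G` are always reported under explicit names rather
than silently reinterpreting either convention. `G = 0` by convention for a
single clone.

Rank-abundance masses use deterministic ranking: descending count, ties
broken by lexicographic clonotype key. "Large" clones are those occupying
strictly more than 0.5% of the (rarefied) repertoire.

## Overlap and clone tracking

Morisita-Horn is evaluated in exact integer arithmetic via the equivalent
form `2·Σxy·X·Y / (Σx²·Y² + Σy²·X²)`, which makes the boundary identities
(1 for identical distributions, 0 for disjoint clone sets) hold exactly in
floating point. Pairwise overlap matrices label each unordered pair
within-subject or between-subject and summarize mean ± SD per stratum.
Overlap is computed on rarefied counts by default (MH is invariant to
uniform scaling but not to sampling-depth differences in richness).

A clone is persistent-and-abundant when it ranks in the top 100 at two or
more timepoints of one subject's series. Rank ties at the cutoff are
resolved inclusively — every clone whose count equals the 100th-ranked
count is in the top set — because any other tie rule is arbitrary and
non-deterministic under relabeling. Clones absent at a timepoint carry
frequency 0 and no rank, keeping absence distinguishable from low rank.
Trajectories are reported for the union of top sets; the flow table pairs
consecutive timepoints for circos-style visualization.

## Antigen-panel matching

Matching is exact string equality on the chosen key — never fuzzy — with
`vjcdr3aa` requiring exact V, J and CDR3 agreement and `cdr3aa` matching
the CDR3 alone (so `vjcdr3aa` hits are always a subset of `cdr3aa` hits).
D-gene agreement is not required. Matched mass is the summed frequency of
distinct matched sample clones; per-entry frequencies (0 for absent
entries) feed entry × sample occupancy heatmaps. The packaged
`synthetic_gp70_panel.csv` is a simulator-generated stand-in with the
shape of a public tumor-antigen panel (60 V/J/CDR3 entries); real analyses
must supply their own panel.

## Signature classifier

The repertoire classifier is deliberately transparent: a frequency-weighted
multiple-instance logistic model rather than a neural embedding. Each
sequence in a labeled sample is an instance with its sample's label and a
loss weight equal to its within-sample frequency (a count-weight option
exists; frequency is the default because sample depths vary by orders of
magnitude). Features are position-free CDR3 3-mer counts, one-hot V and J
genes, and CDR3 length; the vocabulary is built from training data only and
frozen, with unseen k-mers/genes dropped at scoring time. Instance weights
are rescaled to mean 1 so the L2 penalty has a consistent meaning across
designs. The estimator is scikit-learn's liblinear logistic regression
(deterministic coordinate descent suited to sparse binary problems).

Sample scores are the frequency-weighted mean of per-sequence label
probabilities — the "weighted proportion of signature" — with argmax
prediction and a 0.5 threshold for high/low classing. A frequency-weighted
mean (rather than a count-weighted vote) is used because it is invariant to
splitting a clone into identical sub-entries. Sequences with no informative
features fall back to the training-set base rate.

Validation is strictly sample-level: Monte-Carlo cross-validation holds out
whole samples (stratified by label, ≥1 training and test sample per label),
rebuilds the vocabulary per split, and reports per-fold AUCs (Mann-Whitney
rank statistic, ties mid-ranked) plus pooled ROC points. The permutation
null shuffles sample labels — preserving each sample's sequences — and
re-runs the identical CV; the p-value is the add-one permutation estimate.
When the L2 strength is not fixed it is chosen by inner CV on training
samples only; permutation refits reuse the already-selected value so large
permutation counts stay affordable. Training can be restricted to chosen
timepoints (e.g. pre-treatment only) and the fitted signature applied to
remaining timepoints. Rank correlation between two fitted models'
per-clone scores uses Spearman's rho; a constant scorer is reported as
degenerate (NaN), not coerced.

## Synthetic study generator

The generator emulates a serial-sampling bilateral-tumor ICT design with a
known truth channel. Defaults are the study conditions: 8 subjects per
response group; timepoints day 0/2/4/6; tumor totals log-uniform in
[10³, 10⁵] with latent tumor richness log-uniform in [10², 10⁴]; blood
near-uniform (3000 clones, lognormal σ = 0.3, giving normalized Shannon
≈ 0.97–0.98 at typical depths); a 50-clone tumor-antigen panel starting at
5% of tumor mass and expanding by fold 2.0 per timepoint step in responders
vs 1.2 in non-responders (≈30% vs ≈8% of the repertoire by day 6, with
renormalization after each step so expansion changes structure, not depth);
half the panel drawn from a shared pool so some entries are public across
subjects; blood carries the panel at a constant 0.2% in both groups.

Background clone sizes follow a rank power law with exponent 0.65, chosen
so pre-treatment top-10 clone mass sits near one fifth of the repertoire —
the magnitude typical of murine tumor repertoires in this design. Within
the panel, clone sizes follow a steeper power law (exponent 1.5) so that
expansion is oligoclonal: a few dominant antigen-specific clones carry most
of the expanded mass, which is what drives the measurable day-6 diversity
drop in responders. An earlier near-even within-panel law was rejected
because spreading the expanded mass over 50 similar clones barely changes
evenness and does not produce the oligoclonal dominance this study design
is about.

Sequences are CDR3-like strings (`C` + random middle + `F`, lengths peaked
at 13–15 within [8, 20]); panel CDR3s carry a planted 3-mer motif at a
random position, which is what the signature classifier can learn. V/J
labels are drawn from fixed gene lists. Bilateral flanks are independent
multinomial draws from the same subject-timepoint latent distribution
(sampling noise is the only within-subject variation); different subjects'
background clones are disjoint by construction apart from rare random CDR3
collisions.

What the generator does *not* emulate: V(D)J recombination statistics or
thymic selection; non-panel clonal expansions (so simulated day-6 top-10
mass reaches ~0.3 rather than the ~0.5 typical of real responding tumors);
treatment-driven growth of total T-cell infiltrate over time; and
sequencing error. Passing tests therefore demonstrate correctness of the
statistics and recovery of planted effects under multinomial sampling — not
robustness to the full messiness of real AIRR-seq data.

`truth_check` verifies a generated study against its own latent state:
depths within configured bounds, empirical panel mass within 3σ (binomial)
of the schedule, and spot-checked clone counts within 3σ of depth × latent
frequency. Each check aggregates across samples and passes when ≥98% of
per-sample comparisons are within tolerance; with ~200 samples a strict
all-within-3σ rule would fail by chance in a large fraction of runs.

## Group statistics and reporting

The stats layer owns the design mapping; the tests themselves are standard
implementations (scipy.stats, statsmodels). Responder-vs-non-responder
comparisons of a metric use two-sided Mann-Whitney per timepoint — exact
when both groups have n ≤ 10 and no ties, normal approximation with tie
correction otherwise — with Holm-Bonferroni adjustment across the
timepoints of a metric. More than two groups use Kruskal-Wallis; repeated
measures within subjects use Friedman on complete blocks.
Benjamini-Hochberg at a stated FDR (default q = 0.1) is the alternative
adjustment family, used for panel-trajectory comparisons. Degenerate
designs (n < 2 in a group, all values tied, incomplete blocks) produce
flagged rows without p-values rather than errors.

`build_report` joins all stages over a study directory: tumor diversity
with tests (right-flank samples only, keeping one observation per subject),
bilateral overlap strata per timepoint, persistent-clone counts from blood
series, panel trajectories, and a signature timecourse trained on the
earliest timepoint. The report's default classifier run uses 5 CV splits
and no permutations (permutations are available via the classifier config
or the `classify` CLI); sections whose inputs are absent are marked absent.
Outputs are CSV tables plus one JSON bundle, deterministic given study and
seed.

## Numerical conventions

Determinism throughout: every stochastic step takes a seed or Generator;
per-sample seeds derive from a root seed via `SeedSequence.spawn`; all
rankings break ties by lexicographic key; vocabulary and panel orders are
sorted. Frequencies sum to 1 within 1e−12 by construction; oracle tests
hold the defining-sum implementations to 1e−10 against brute-force
evaluation. Problem sizes in the test suite (subject counts, depths,
replicate counts) are chosen to exercise the full protocol at desk scale —
20 replicate studies at default design for the study-recovery checks, 10⁴
draws for rarefaction calibration, 50 label permutations for the
classifier null.

## Plotting

The package emits tables (CSV/JSON) shaped for the standard figures of this
analysis style — rank-abundance bands, Rényi profiles, clone-flow (circos)
input, occupancy heatmaps, ROC points — and deliberately contains no
plotting code.
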