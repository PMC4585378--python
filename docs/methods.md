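# Methods

This note records the models the package implements, the assumptions
behind them, the parameters that matter, and the design choices made
where the problem statement left the design open.

## The staging problem

A bulk RNA-seq profile of injured muscle tissue is to be assigned to one
of ten classes: nine post-injury hours (3, 10, 24, 48, 72, 168, 336,
504, 672) or the uninjured control state. The training material is a
time-course study with injured and contralateral-control samples at
every hour, 2–5 biological replicates each; the test material is a set
of blinded single-sample profiles. Classes are ordered in time and
biologically smooth — adjacent hours share much of their expression
program — so errors, when they occur, are expected to land on temporal
neighbors, and the package grades calls both exactly and by coarse
healing period (early 3–24 h, middle 48–168 h, late 336–672 h).

## Preprocessing

**Replicate QC.** Within each (condition, hour) group, pairwise Pearson
correlation is computed over all features on raw FPKM (a log2(FPKM+1)
variant is exposed via `log_space=True`; the default follows the plain
reading of "pairwise Pearson correlation"). "R²" is the square of the
Pearson coefficient. A replicate is excluded when its R² falls below the
cutoff (default 0.95) against a *strict majority* of the other group
members, in a single simultaneous pass. The literal rule "excluded if
below threshold against any other member" was rejected: one corrupt
replicate drags every healthy member below threshold and empties the
group, whereas the majority rule removes exactly the outlier. Groups
emptied anyway raise an error naming the group; singletons pass
untouched.

**Aggregation.** Replicates merge into one profile per group: per
feature, the aggregate is 0 when the replicate median is 0, otherwise
the replicate mean. The median-zero guard prevents a single spurious
nonzero replicate from fabricating expression for a silent gene.

**Fold changes.** `log2fc_t = log2((I_t + ε)/(C_t + ε))` with
pseudocount ε = 0.5 by default, so zero-FPKM cells stay defined. The
pseudocount shrinks fold changes of genes expressed below ~1 FPKM
toward 0; this is intentional (such estimates are unreliable) but means
injected effects are recovered exactly only for adequately expressed
genes. A cell is called `up` when log2fc ≥ log2(min_fold) (`down`
symmetrically), min_fold = 2 — the two-fold rule — optionally gated by a
per-cell q-value threshold (default q < 0.05 when q-values are present).
The package consumes q-values; it never computes differential tests
itself (the upstream engine is out of scope; the synthetic generator
supplies its own q column). A stated "log fold change greater than 2"
variant of the threshold exists in the source analysis's prose; this
package standardizes on |log2fc| ≥ 1 (two-fold) everywhere, with
`min_fold` configurable.

**Feature filters.** Four modes: all significant genes, single-hour
genes, and the same pair for isoform tables (isoform modes operate on
whatever feature table the caller designates; no assembly is done).
A feature is kept when its maximum aggregate FPKM reaches `min_fpkm`
(1.0 for the discovery-style filter, 0.5 for the classification filter)
and at least one cell is significant; significance of a cell couples the
fold rule and the q rule at the *same* hour, which keeps the single-hour
count well defined and makes the single-hour selection a subset of the
full selection.

## The classifiers

**Time point-specific signatures.** Per gene, the up-direction weight is
1/(number of hours called up), likewise down; a gene up at 3 h and 10 h
and down at 504 h carries up-weight ½ and down-weight 1. Scoring a test
call profile against candidate hour *t*: every gene whose test call
equals the training call at *t* adds its directional weight, and a
gene unchanged in both adds 0.5. The 0.5 no-change increment is a fitted
constant of the original analysis; it is exposed as a parameter
(`NO_CHANGE_INCREMENT`) but deliberately not re-optimized here. The
control candidate expects `none` at every gene — controls have no fold
change by construction.

**Time point-weighted signatures.** Weights are
`|log2fc_t| / max_t' |log2fc_t'|` ∈ [0, 1], equal to 1 at the gene's
peak hour; the expected direction is kept separately (normalizing the
magnitude keeps the weight a fraction even when up and down coexist in
one gene's profile). Matches add the weight at the candidate hour;
unchanged/unchanged matches add the same 0.5 increment as the specific
method. All-zero rows are inert rather than errors. The score-matrix
variant restricts to genes significant at exactly one training hour,
encodes training (and thresholded test) profiles as −1/0/+1, and calls
the hour with minimal element-wise L1 distance; an all-zero column
represents the control class. Thresholding is symmetric (+1 above
two-fold up, −1 below two-fold down) even though the source description
is asymmetric about the negative side — a sign convention, not a model
change.

**Confidence tiers.** Margin = winner score − runner-up score. Margin
> 100 → high, 50–100 → medium, else low; thresholds configurable. Ties
(to float precision) break toward the earlier class — control first,
then hours ascending — and are flagged. The tie rule is a determinism
choice; no substantive claim rests on it.

**One-vs-one SVM.** One soft-margin linear SVM (C = 1.0, configurable)
per unordered class pair — C(10,2) = 45 for the full design — trained on
replicate-level profiles z-scored once over the training set. Each model
votes for its predicted side with weight `R = |w·x + b|/‖w‖`, the test
sample's perpendicular distance from the decision hyperplane. The
"distance of the support vectors" phrasing in the source is
operationalized as the distance of the *test sample*: a fixed
margin-width weight would make every vote of a model identical and could
not produce per-sample vote profiles. The one-vs-all cascade first
separates control from pooled injured, then repeatedly trains each
remaining hour against the pooled rest and eliminates the
least-supported hour; the elimination order is recorded.

**PCA nearest sample.** Features are z-scored (ddof = 1; zero-variance
features are dropped first, since their z-score is undefined), a full
PCA is fitted on training samples only, and test samples are
standardized with the *training* means/sds and projected post hoc —
training-only fitting avoids information leakage from the test set.
The call is the label of the Euclidean-nearest training sample over the
first `n_components` (default: all retained components, in which case
the call equals nearest neighbor in z-space by orthogonality; 2 is
useful for visualization). Feature importance is
`Σ_c |loading(f, c)| × λ_c`; magnitudes prevent sign cancellation across
components.

**Pathways.** Pathway activation per sample = arithmetic mean FPKM of
member genes present in the study; members absent from a filtered table
are dropped from the mean rather than counted as zero (absence after
filtering does not mean zero abundance), and duplicate members are
deduplicated at GMT ingest. Significance standardizes each pathway's
activation across the nine injured hours, Z_t = (s_t − mean)/sd
(sample sd, ddof = 1), flagging |Z| > 2 — the two-sided normal 5% level.
The source describes this step as a "two-tailed T test … across the 9
time points", which is not well defined as stated; the within-pathway
standardization above matches the |Z| > 2 ↔ p < 0.05 equivalence it
invokes. A pathway is *selected* when |Z| > 2 and a two-fold
injured/control change co-occur at the same hour. Classifiers re-run at
pathway level by substituting the pathway score matrix for the gene
matrix (q gating disabled — pathway means have no q column); every
pathway-level call also reports its coarse healing period.

## The synthetic generator

The generator emulates the emulated study's design, not its sequences:
no reads, isoform structure or splicing are simulated.

- **Design.** Nine hours; injured replicate counts per hour
  (2, 5, 4, 3, 4, 2, 3, 3, 4) and 4 contralateral controls per hour
  (≈31 injured / ≈36 control training samples), matching a design in
  which several hours retained only 2–3 tissues after RNA quality
  checks. The default blinded set is 6 controls + 2×3 h + 2×10 h +
  2×168 h.
- **Genes.** A fraction respond at exactly one hour (default 0.2), a
  fraction over a contiguous window of 2–4 hours (default 0.3), the rest
  never. Contiguous windows are how temporal smoothness is produced:
  adjacent hours share part of their active set, which is what makes
  adjacent classes confusable and errors land on neighbors. Signed
  effects are uniform in `effect_log2fc_range` (default [1, 4] log2
  units; the recovery experiments use [2, 4]), one sign per gene.
- **Abundance and noise.** Baselines are log-normal across genes
  (ln-mean 1.5, ln-sd 1.5; median ≈ 4.5 FPKM spanning several orders of
  magnitude). Replicate noise is multiplicative log-normal with
  CV = 0.12, chosen so that raw-FPKM replicate pairs typically reach
  R² ≥ 0.95 (measured: ~98 % of pairs) — the reproducibility the
  analysis assumes of real libraries. Injured samples multiply the
  baseline by 2^effect at active hours; controls draw from the baseline
  at every hour.
- **Transition regime (168 h).** When enabled, injured replicates at the
  transition hour get 3× noise variance *and* a per-replicate
  state-mixture: with λ ~ U(0, 0.5) the replicate's effect profile is
  (1−λ)·(168 h program) + λ·(a random adjacent hour's program). Pure
  variance inflation proved unable to reproduce the documented 168 h
  behavior — with two-fold-plus effects, unstructured noise essentially
  never flips thresholded calls — whereas tissue sampled mid-transition
  between healing states shifts profiles *toward neighboring classes*,
  which is both the biologically hypothesized mechanism and the one that
  produces neighbor-directed misclassification. Under the full regime,
  168 h replicate pairs correlate at R² ≈ 0.90–0.93 versus ≥ 0.95
  elsewhere.
- **q-values.** Per gene and hour, a two-sample t-test on log2(FPKM+0.5)
  between injured and control replicates, Benjamini–Hochberg corrected
  across genes within each hour — a stand-in for an upstream
  differential engine so the q-gated filters are exercisable.
- **Blinded studies** re-derive the identical feature-effect model from
  the training seed and draw only replicate noise from their own seed,
  so training and test share gene effects; true labels live in a sealed
  record separate from the study metadata.

**What passing on synthetic data does and does not show.** The generator
captures the design's group structure, abundance spread, replicate
reproducibility, temporal smoothness and the transition-state mechanism,
but not library-preparation batch effects, count-level sampling noise,
isoform complexity, or correlated gene modules beyond shared activity
windows. Perfect recovery on clean synthetic data therefore validates
the pipeline's mechanics and relative method behavior (e.g. one-vs-one
≥ one-vs-all; neighbor-directed errors), not clinical accuracy on real
tissue.

## Numerical choices and degenerate inputs

- Ties in any argmax/argmin break toward the earlier class (control
  first), detected with relative tolerance 1e-9 and flagged.
- Constant features: dropped before PCA z-scoring; given unit sd in SVM
  standardization (they carry no information either way).
- All-zero weighted-signature rows and zero-sd pathways are inert, not
  errors.
- A fold-change computation requires every injured hour to have a
  matched control aggregate; a blinded single sample, which has no
  matched hour, is compared against the mean of the control aggregates.
- Simulation sizes in the test suite (hundreds to 2000 genes, 20 seeds
  for recovery experiments) were chosen as the smallest sizes at which
  the measured quantities are stable.

## Known limitations

- The isoform modes treat any feature table as isoforms; no
  transcript-assembly semantics are implied.
- The q-value stand-in assumes roughly log-normal replicate noise; it is
  not a substitute for a count-based differential engine on real data.
- The one-vs-all cascade's per-class "scores" are elimination ranks, not
  calibrated margins.
- Confidence tiers are defined in absolute score units and therefore
  scale with the number of selected features; the 100/50 defaults assume
  feature-set sizes in the low thousands.
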