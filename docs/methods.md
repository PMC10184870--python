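# Methods

## The scientific question and the analysis it requires

The package asks where in the brain the *topic-level* meaning of a sentence —
the broad semantic category it belongs to, such as *sports* or *religion* —
is represented more strongly than the *word-level* meaning obtained by
treating the sentence as an unordered bag of words.  The comparison is run
with representational similarity analysis (RSA): a model of sentence meaning
induces a representational dissimilarity matrix (RDM) over a stimulus set,
brain activity induces another, and their agreement is measured by the
Pearson correlation of the vectorised upper triangles.

Two primary sentence models are implemented, plus two controls:

1. **Topic classifier final layer.**  A convolutional network (trainable
   embedding layer, two convolution + max-pool blocks over token trigrams,
   two dense layers, softmax over topics) is trained to classify sentences
   into their topic.  The second dense layer, pre-softmax, is the topic-level
   sentence representation.  The network is implemented directly in numpy
   (forward and backward passes, Adam, inverted dropout); the tested contract
   is bit-deterministic single-threaded training under a fixed seed.
2. **Averaged word embeddings.**  The unweighted mean of the word vectors of
   all constituent words, stopwords included, each occurrence counted.  This
   is word-level meaning: blind to order and to the topic objective.
3. **tf-idf control.**  Words get a vector of length `n_topics` with
   component *c* equal to `tf(w, c) · idf(w)`, where tf is the relative
   frequency of *w* in topic *c*'s concatenated training text and
   idf = ln(n_topics / number of topics containing *w*); sentences average
   their words' vectors.  This variant (relative-frequency tf, natural-log
   idf over topic "documents") was chosen because its degeneracies are
   crisply testable: a word present in every topic has an exactly zero
   vector, and components for topics that never contain the word are 0.
4. **MLP control.**  A tanh multilayer perceptron (scikit-learn backend)
   trained on the averaged embeddings — topic-informed but order-blind.  Its
   last hidden layer is the sentence representation; activations are
   recomputed by an explicit forward pass over the fitted coefficients.

Representations are evaluated with nearest-centroid top-k classification:
the centroid is the mean training vector per topic, a test sentence is scored
by Pearson correlation against every centroid, and ties are broken toward
the lowest topic index so reports are deterministic.  Chance level is
`100·k/n` percent.  Displayed accuracies and alphas use half-up decimal
rounding (`display_round`), so 6.25 % prints as 6.3; the exact values are
always retained.

## Brain-side analysis

Subject data enter as sentence × voxel response-amplitude matrices tied to a
3-D grid (brain mask, named ROI masks, per-axis voxel size in mm).  The RSA
configuration defaults are 8 mm searchlight radius, 12 mm FWHM smoothing of
the Fisher-z maps, per-voxel demeaning on, and a minimum of 10 in-mask
sphere voxels.

* **Demeaning** removes each voxel's mean across sentences (the grand
  spatial pattern) before any correlation.  Because this is a per-voxel
  operation it is identical whether applied globally or per sphere, so it is
  applied once.  It is exposed as a flag since "demeaning" admits more than
  one reading.
* **Searchlight.**  For every in-mask center, the sphere of voxels within
  the millimetre radius is gathered (spheres truncated by the mask edge are
  used if they still meet the voxel minimum); the sphere's pattern RDM
  (1 − Pearson) is correlated with the model RDM over vectorised upper
  triangles; the correlation is Fisher-transformed (`atanh`, with |r|
  clipped at 1 − 1e-7 to keep maps finite) and stored at the center.
  Centers with too-small spheres or zero-variance sentence patterns get a
  NaN sentinel rather than propagating undefined correlations.  The z-map is
  then smoothed with a mask-normalised Gaussian (σ = FWHM / (2√(2 ln 2)) per
  axis in voxel units, divided by the smoothed mask) so constant maps stay
  constant inside the mask.  Transform-then-smooth order is fixed.
* **ROI RSA** computes the same statistic once over all ROI voxels and
  returns the raw correlation r (group t-tests operate on r; Fisher z is
  available to callers).
* Internal math is entirely grid-based: voxel indices are 0-based and
  distances come from the per-axis voxel size.  NIfTI affines are honoured
  only at I/O boundaries.

## Group inference

One-tailed one-sample and paired t-tests (sample sd, df = n − 1), Bonferroni
per-test alpha = α/m, and paired Cohen's d = mean(diff)/sd(diff).  The
voxelwise paired contrast excludes sentinel voxels per voxel and needs at
least two valid subjects.  Zero-variance nonzero-mean differences are
reported as a distinct *degenerate-certain* outcome: scalar results carry a
`degenerate` flag, and voxel maps store a large finite sentinel (1e10)
instead of infinity so exported volumes stay representable.

Cluster-level family-wise error control uses sign-flip permutation instead
of random-field theory: observed clusters are face-connected (6-neighbour)
components of voxels above a one-tailed cluster-forming threshold; the null
distribution of the **maximal cluster extent** is built by randomly negating
each subject's difference map (exchangeable under the null), and corrected
p = (1 + #{null max ≥ observed extent}) / (1 + n permutations).  This choice
is self-contained and assumption-light.  One property worth knowing: with
spatially *uncorrelated* noise the max-extent distribution collapses onto a
few small integers and the tie atoms make the test noticeably conservative.
The pipeline always feeds it smoothed maps, where extents are larger and
better spread, so the empirical family-wise error sits near the nominal
level; the null-calibration check therefore uses smoothed noise maps.

## The synthetic-data generator

No raw corpus, embedding set, or imaging data ships with the package;
every study condition is emulated with planted, recoverable structure.

**Corpus.**  Topics own disjoint content-word pools; topics in the same
supra-category additionally share a supra pool (content tokens come from it
with probability `supra_mixture`, default 0.3), and all topics share a
stopword pool (`stopword_fraction`, default 0.4).  Within-pool word
probabilities are Dirichlet with parameter 1/`topic_concentration`, so
larger concentration gives peakier, more separable topics.  Defaults mirror
the study frame — 64 topics, sentence lengths 6–38 — with the per-topic
sentence count scaled to desk size (100) since the full-scale corpus only
changes training time, not the logic under test.  A second generator builds
a two-topic corpus whose topics differ *only* in word co-occurrence
(four word groups; topic 1 pairs A0 with B0 or A1 with B1, topic 2 the
crossed pairings) so the two topics have identical unigram marginals: bag-
of-words representations carry no signal in expectation while co-occurrence-
sensitive models can separate the topics.  This corpus needs on the order of
a thousand sentences per topic before the classifier generalises the
co-occurrence rule instead of memorising training sentences; the defaults
reflect that.

**Embeddings.**  Each word is assigned to the topic (and supra-category)
holding the majority of its occurrences; its vector is
`cluster_strength · (supra centroid + topic centroid) + unit Gaussian
noise`, with spread-out words (stopwords) getting noise only.  Strength 0
plants no structure at all, which the tests exploit as a null.

**Brain patterns.**  For each signal ROI, the planted similarity matrix
S = 1 − RDM (unit diagonal) is projected to the nearest PSD matrix
(eigenvalue clipping at zero, diagonal rescaled to 1 — a repair that leaves
an already-PSD matrix untouched) and factored as L·Lᵀ = S.  The ROI block of
a subject's pattern matrix is `snr · (L @ Z) + noise_sd · E` with Z, E
independent standard normal, so each voxel's response profile has covariance
snr²·S + noise_sd²·I across sentences and the expected pattern RSM tends to
S as snr/noise_sd grows — the generator plants exactly the statistic the
pipeline measures, with a closed-form expectation.  Voxels outside signal
ROIs get pure noise.  Subject s uses sub-seed seed + s.  Voxel loadings are
spatially independent: no smoothness is simulated within ROIs, and no
hemodynamics, trial time series or GLM estimation — patterns live directly
at the per-sentence response level.  The default geometry is a ball mask
inscribed in a 24³ grid at 2 mm isotropic voxels (the acquisition voxel
size, at a desk-scale field of view).

**What passing tests do and do not show.**  Planted-structure recovery shows
the pipeline measures what it claims with correct calibration under the
generator's assumptions (Gaussian noise, exchangeable subjects, spatially
independent voxels).  Real fMRI violates several of these — autocorrelated
noise, inter-subject anatomical variability, hemodynamic confounds — so
passing here validates the *analysis machinery*, not claims about any real
dataset.

## Study-scale choices in tests and the acceptance script

Problem sizes are the package's own desk-scale defaults: recovery runs use
24 subjects (the study's group size), snr/noise_sd = 2, 40 stimulus
sentences, two 552-voxel spherical ROIs placed diagonally in the 24³ ball —
deliberately larger than the 12 mm smoothing kernel, as the atlas ROIs they
stand in for are, so the smoothed contrast peak falls inside the planted
region rather than on its rim.  The embedding cluster strength in the
recovery study is 0.3, which keeps the two model RDMs only moderately
correlated (r ≈ 0.3–0.5), in the regime the contrast logic is meant for.
Null calibration uses 2000 scalar simulations and 200 permutation runs on a
12³ grid with 200 sign-flips each.

## Numerical conventions and degenerate inputs

* RDM validity: symmetry and zero diagonal at 1e-10 absolute tolerance,
  entries in [0, 2]; full square storage (n is at most a few hundred).
* Zero-variance feature rows abort RDM construction with the item named;
  constant vectorised RDMs make comparison an error rather than a NaN.
* `compare_rdms` uses a symmetric centered-dot formulation so that
  compare(a, b) == compare(b, a) exactly, not merely to rounding.
* Ward clustering runs on feature vectors with Euclidean distance (Ward's
  validity condition); clustering on RDM-derived distances is available as
  an option.  Silhouette scores are standard (b − a)/max(a, b), singletons
  scoring 0.  Dendrograms export to Newick with merge heights as branch
  lengths.
* Nearest-centroid ties go to the lowest topic index; constant test vectors
  are counted as errors with a warning.
* Out-of-vocabulary tokens are skipped when averaging embeddings; a sentence
  with no known token is an error naming the sentence.
* Mean lexical frequency for stimulus selection is computed on log10
  relative frequencies.
* Stimulus selection clusters on one representation (caller's choice); the
  half-and-half split across two network layers is possible by calling the
  selection twice but is not the default, since the two layers' RDMs are
  typically too correlated for the distinction to be meaningful.

## Known limitations

* The permutation cluster test controls FWE conservatively for extent-tied
  null distributions (unsmoothed, coarse grids).
* The numpy network is a faithful but small-scale implementation: no GPU
  path, no early stopping, and the two convolution blocks require
  `pad_length` long enough for two rounds of convolution and (ceil) pooling.
* ROI t-tests use raw correlation values; Fisher-z input is available but
  not the default.
* The paired-test form of the two-condition group model holds only for two
  conditions; no extended designs are implemented.
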