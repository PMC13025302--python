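# Methods

## Problem and model

`icseg` implements in-context ("visual prompt") binary segmentation of 2D
grayscale medical slices. A task is defined at inference time by an ordered
prompt of n image–mask pairs of one target class followed by a query image;
the model estimates p(y_q | x_1, y_1, …, x_n, y_n, q). Multi-class problems
are decomposed into one binary sub-task per class, so the *same* query image
has a different correct answer under prompts of different classes — the class
is carried entirely by the prompt, never by an output channel.

The architecture is:

1. **Shared encoder.** A pre-norm ViT over non-overlapping patches encodes
   every episode member — images and masks alike (a mask enters as a {0,1}
   intensity image). At the configured layers, global self-attention is
   replaced by window attention over non-overlapping spatial windows
   (zero-padded to window multiples; pad tokens are masked out of the softmax
   and cropped on exit). When one window covers the whole token grid the
   global code path is used, making the two modes bit-identical in that
   regime.
2. **Information-bottleneck neck.** A 1×1 convolution compresses the encoder
   width to the neck width, followed by layer norm, a 3×3 same-padding
   convolution, and a second layer norm. The norm is applied across channels
   at each spatial position. The prose description of the reference design
   applies norms after *each* convolution, and we follow that reading.
3. **Image-level autoregressive decoder.** Per-image feature maps are
   flattened row-major to s = h·w tokens, concatenated in interleaved order
   [x₁, y₁, …, xₙ, yₙ, q], projected to the decoder width, and summed with
   learned positional embeddings. Every decoder attention layer is
   masked by the image-level visibility matrix M[i,j] = 1 iff
   ⌊j/s⌋ ≤ ⌊i/s⌋ (0-based; equivalently the 1-based rule j ≤ ⌈i/s⌉·s):
   full bidirectional visibility within an image, strict causality across
   images. Masking is additive (−10⁹ before the softmax), since a
   multiplicative zero on logits would not remove attention mass.
4. **Segmentation head.** A per-token linear map expands each of the query's
   s feature vectors to patch_size²×2 logits, reassembled into an H×W×2 map
   and passed through a two-class softmax. The foreground channel is the
   probability map; binarization thresholds at 0.5 with ties going to
   foreground. The head's foreground bias is initialized at the log-odds of
   the expected foreground fraction (`fg_prior`, default 0.1), the standard
   class-imbalance initialization: the untrained model predicts the base rate
   everywhere instead of first collapsing to background and having to escape
   that plateau.

### Positional scheme for variable prompts

Decoder positions are factorized: a per-slot embedding (which of the
2·(n_max+1) images of the sequence a token belongs to) plus a within-image
grid embedding shared across slots. The factorization means the same pixel
location carries the same positional code in every image, so attention can
bind a prompt-image token to its mask token at the same location without
learning a separate correspondence for every (slot, location) pair; both
tables are initialized at a scale comparable to the layer-normed content
(std 0.5) so position-based attention is expressible from the first step.
A k-pair inference sequence uses the leading 2k+1 slots, so the query sits
in the slot of the (k+1)-th training image — exactly a position whose
prediction was supervised during training — which is what makes inference
with any 1 ≤ k ≤ n_max prompt pairs work without retraining.

### Training objective

Training sequences contain n+1 pairs; the outputs at the image positions
x₂ … x_{n+1} are supervised (position 1 has no context and is never
supervised; the final mask y_{n+1} is present in the sequence but invisible
to every supervised position under the mask). The loss per position is
cross-entropy plus soft Dice,

    L = −(1/N) Σᵢ [yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)]
        + 1 − (2 Σ yᵢpᵢ + ε) / (Σ yᵢ + Σ pᵢ + ε),   ε = 10⁻⁵,

averaged over the n supervised positions. Dice uses soft probabilities
(required for differentiability); CE clamps p to [10⁻⁷, 1−10⁻⁷] rather than
shifting ε inside the log — a standard numerical guard.

Optimization is AdamW (decoupled weight decay 0.01, betas (0.9, 0.999),
base lr 2·10⁻⁴ at reference scale) under a cosine schedule with a one-epoch
linear warmup. Episodes and the per-episode augmentation are resampled every
epoch. One master seed fans out to named substreams (init, episode sampling,
augmentation, evaluation), so every subsystem is independently reproducible
and two runs with identical configs are bit-identical.

## Numerical core

No autodiff framework is assumed: the package carries a small reverse-mode
automatic-differentiation engine over numpy arrays (`icseg.autodiff`) with
exactly the primitives the model needs (broadcasted arithmetic, batched
matmul, shape ops, reductions, fused softmax/layer-norm/GELU, a 3×3 unfold
for the neck convolution) plus AdamW and the warmup-cosine schedule. All
primitive gradients and the full end-to-end model gradient are verified
against central finite differences in the test suite. Model parameters are
float32; gradient checks run in float64.

Two numerical choices matter for exactness guarantees:

- Additive −10⁹ attention masking underflows to exactly zero weight after the
  softmax shift, so predictions are *bit*-invariant to the content of masked
  positions (the causality tests assert equality, not closeness).
- The window-attention path switches to the global code path whenever the
  window covers the token grid, so the windowed=global equivalence is exact
  rather than within tolerance.

## Synthetic task generator

Desk-scale training and all tests use generated data. A sample is a 64×64
image containing one deformed shape of its class (families: ellipse,
rectangle, annulus, crescent, blob; the default corpus uses the first
three), drawn with a class-specific intensity distribution over a smooth dim
background. Per-class intensity means are spread over [0.35, 0.9] (default
spread 0.04), background mean 0.12 (spread 0.03), with a smoothed random
elastic deformation (max displacement 1.5 px applied identically to image
and mask, nearest-neighbor for the mask) and additive Gaussian noise
(sd 0.02), clipped to [0, 1]. Defaults: 40 training and 16 evaluation
samples per class, generated from per-sample seeds derived from the master
seed, so datasets are reproducible independently of generation order. A
held-out class list supports the unseen-target protocol (excluded from the
train split, present in the eval split).

An alternative scene layout (`generate_scene_task_dataset`) places one shape
of *every* class in the same image, decomposed into per-class binary
sub-tasks, so a single query image admits several valid tasks — the analogue
of a multi-organ slice. It is strictly harder: a query image alone
underdetermines the task, and only the prompt's masks disambiguate it. At
the miniature scale and step budget this variant does not train to a useful
level (the context-free optimum — segmenting the union of all shapes — is a
strong attractor), so the default corpus is the single-shape layout; the
scene layout is provided for prompt-switching studies at larger budgets.

What the generator does *not* emulate: anatomical texture and
partial-volume effects, inter-slice context, intensity physics of CT/MRI,
class imbalance across slices, or empty-target slices. Passing tests on
this corpus demonstrate the mechanism (in-context segmentation under the
episode protocol, prompt scaling, uncertainty behavior), not clinical
segmentation accuracy.

Augmentation follows the 11-kind table (intensity complement, label
complement, horizontal/vertical flip, Sobel edge labels, affine shift,
brightness/contrast, elastic warp, Gaussian blur/noise, sharpness): one kind
drawn uniformly per episode per epoch, applied with probability 0.5 with the
same sampled parameters to every episode member. Magnitudes are config
fields with documented defaults (shift ±10 % of image size, blur sigma
0.5–1.5, noise sd 0.01–0.05, contrast 0.7–1.3, elastic displacement 1–4 px),
since the reference table names the operations without magnitudes. The two
label-transforming kinds intentionally redefine supervision for the whole
episode — they create new, internally consistent tasks. The Sobel edge label
binarizes at any nonzero filter response.

## Desk-scale (miniature) study conditions

The miniature preset is a 64 px / patch 8 model (s = 64 tokens per image)
with 4 encoder and 4 decoder layers of width 128 (4 heads), neck width 128,
window size 8 at layers {2, 4}, and n_max = 3. Its training harness
(`train_miniature`) runs 700 steps of two n = 3 episodes with lr 10⁻³
(constant), betas (0.9, 0.95), global gradient-norm clip 1.0, and no
augmentation. The rationale for each departure from the reference-scale
defaults:

- β₂ = 0.95 instead of 0.999: small-batch Dice+CE training passes through a
  collapse-to-background plateau whose gradients are orders of magnitude
  smaller than the initial transient; a slowly decaying second moment
  suppresses the escape for roughly 1/(1−β₂) steps.
- A single fixed prompt length (the reference protocol's own scheme): all
  supervised positions — context sizes 1..n — receive equal training. A
  staged short-prompts-first schedule trains faster per step but leaves the
  model systematically more confident at small k, inverting the
  prompt-count/uncertainty relation.
- Augmentation off: at a few hundred steps, the label- and
  intensity-transforming kinds (a quarter of the draws) redefine the task
  often enough that no segmentation circuit forms at all. At reference scale
  the protocol keeps augmentation at p = 0.5 (the TrainConfig default).

Evaluation samples 5 prompt sequences per query by default and averages
Dice; desk-scale checks reduce repeats and query counts where noted in the
scripts themselves. Dice of two empty masks is defined as 1.0 (an absent
structure correctly predicted absent is a perfect outcome).

Prompt-following is measured two ways. Under the episode protocol (prompts
share the query's category — the protocol's own invariant), the rate is the
fraction of queries whose prediction overlaps the prompted class's ground
truth strictly better than any other class's; on a single-structure query
the other classes' ground truths are empty, so this chiefly checks that
predictions land on the true structure. The stricter mismatched-prompt
diagnostic prompts with a class absent from the query, where faithful
following means predicting nothing; the desk-scale model does not acquire
this behavior (it segments the structure present, scoring near chance), and
we report it as such — mismatch robustness is expected to require the
augmentation pressure, the scene corpus, or reference-scale training, all
outside the desk budget.

On uncertainty: the trained miniature is already near-saturated confident at
one prompt (mean pixel entropy ≈ 0.016, two orders of magnitude below ln 2),
so the entropy change from k = 1 to k = 3 prompts converges toward zero and
is assessed as a non-increase within the bootstrap error of the mean — the
same error construction as the Dice prompt-scaling check — rather than as a
raw inequality whose sign is unresolved at saturation.

## Preprocessing

CT slices are windowed to [level − width/2, level + width/2] in Hounsfield
units and min-max mapped to [0, 1] using the *clip bounds* (not the observed
post-clip extrema), making normalization a pure function of the window spec.
MRI slices are clipped at per-sample percentiles (defaults 0.5/99.5) and
min-max mapped with the same convention; a constant slice maps to zeros and
is logged as degenerate. Volumes are reformatted to 2D axial slices along
the first array axis; resizing to the model resolution is bilinear for
images and nearest-neighbor for masks (preserving binarity). The
interpolation scheme is not specified by the reference description; this is
our choice.

## Uncertainty

Per-pixel predictive entropy is H = −Σ_{c∈{0,1}} p_c log(p_c + ε) with
natural log and ε = 10⁻⁸ (so H ∈ [−2ε, ln 2]); the summary statistic is the
mean over all pixels of all query predictions at a given prompt count. The
log base is not fixed by the reference description; natural log is used
throughout.

## Known limitations

- Pure-numpy training limits practical scale to miniature configs; the
  reference-scale configuration (256 px, 12+12 layers, width 768) constructs
  and runs but is not trainable in reasonable time on a CPU.
- The generator's shapes are star-convex or simple composites; no topology
  beyond the annulus hole, no multi-structure classes.
- 2D only; no DICOM, no resampling to isotropic spacing, no orientation
  metadata beyond "axial = first axis".
- KV-cache incremental decoding is not implemented; every prediction is a
  full forward pass.
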