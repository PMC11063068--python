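# Methods

This note records the modelling choices behind `seqarchitect`: the
architecture template and its parameterization, the optimizer, the
training harness, the synthetic data the package is exercised on, and the
numerical conventions that a reimplementation would need to match.

## Architecture template

Networks follow a three-stage template — a convolutional trunk, an
embedding stage (global average pooling for the CNN-GAP family, a
recurrent stack for CNN-RNN), and a dense head.  The trunk is
parameterized only at its ends; intermediate layers are interpolated:

- **Block structure.** Requested layer count `n_c` ∈ [1, 20] and block
  count `n_cb` ∈ [1, 10] reconcile to `N_cb = n_c` if `n_c ≤ n_cb`, else
  `n_cb`; layers per block `s_cb = round(n_c / N_cb)`, realized depth
  `N_c = N_cb · s_cb`.  `round` is half-away-from-zero (so `round(2.5) = 3`);
  this convention is pinned by the oracle tests.
- **Filters.** `f_i = ⌈f_0 (f_end/f_0)^{j(i)}⌉` with `j(i) = ⌊i/s_cb⌋ /
  (N_cb − 1)` under residual blocks (filters constant within a block, a
  requirement of additive shortcuts) and `i/(N_c − 1)` otherwise.  A
  single layer gets `⌈f_0⌉`; a residual trunk with one block keeps all
  layers at `⌈f_0⌉` (the `0/0` exponent is defined as 0).
- **Kernels.** `k_i = ⌈k_0 (k_end/k_0)^{i/(N_c−1)}⌉`, `⌈k_0⌉` when
  `N_c = 1`.
- **Dilation.** Within each block, position `q` gets
  `⌈d_end^{q/(s_cb−1)}⌉`; single-layer blocks use dilation 1 (the growth
  "from 1" has nowhere to go).
- **Pooling.** The total reduction is `2^round(log2 p_end)` halvings.
  One potential pooling site follows each convolutional layer; the
  exponent budget is spread as evenly as possible with the remainder
  assigned to the latest sites, keeping early layers at full resolution
  while the length still shrinks exponentially along the model.
- **GAP taps.** The last `max(1, ⌈(1 − r_s) N_cb⌉)` block outputs are
  average-pooled and concatenated.  With `r_s = 0.72` and `N_cb = 7` this
  taps exactly 2 blocks.  At least one block is always tapped.
- **Receptive-extent constraint.** Every layer requires
  `dilation · (kernel − 1) + 1 ≤` the sequence length remaining at its
  depth after earlier pooling; configurations violating it raise a build
  error naming the layer.  During a search such configurations score 0
  and the run continues.
- **Length-dependent ranges.** The upper bound of `d_end` and `p_end` is
  2^4 for read-scale inputs and 2^7 for contig-scale ones; the cut sits
  at L = 1000 nt.

Choices the template leaves open, resolved here: residual shortcuts are
identity where shapes match, otherwise a width-1 projection convolution,
with the block's pooling applied on the skip path (standard ResNet
practice); batch-norm sits between each convolution and its leaky-ReLU,
with the searched momentum (Keras convention,
`running = m·running + (1−m)·batch`); dropout exists only in the dense
stack; the recurrent stack returns per-position outputs and the last
layer's output is flattened; reverse-complement input runs both strands
through shared trunk weights and concatenates the two embeddings before
the dense stack (keeps the parameter count independent of strand handling
except for the first dense layer's input width).

Parameter accounting is closed-form — conv `(k·C_in + 1)·F` plus `2F`
batch-norm scale/shift, dense `(in + 1)·units`, LSTM/GRU
`gates·((in + units)·units + units)` per direction with 4/3 gates and a
single bias vector — and is cross-checked in tests against the
instantiated backend's trainable count.

## Optimizer

The surrogate is a Gaussian process (scikit-learn, Matérn ν = 3/2, ARD
length scales, small white-noise term, normalized targets) over the
unit-cube encoding of configurations: numeric dimensions affine on their
(log where flagged) scale, booleans as {0, 1}, categoricals one-hot with
ties decoded to the first listed category, integers rounded on decode.
The training budget joins the encoding as one extra coordinate
(`log2(budget)/16`), which lets short-budget observations inform
long-budget predictions without being conflated — the minimal mechanism
consistent with carrying warm-start data inside one surrogate.

Batch proposals maximize the UCB score `mean + λ·sd` with λ drawn
independently per proposal from an exponential distribution with rate 1
(the rate is configurable; nothing in the method fixes it).  Maximization
uses 1000 random candidates followed by coordinate-wise refinement of the
best 10 (steps 0.05 then 0.01, two passes each, one surrogate call per
sweep).  Candidates are first *canonicalized* — snapped to encodings a
decoded configuration can actually realize — because scoring off-grid
integer/categorical coordinates overstates the surrogate's uncertainty
there and degenerates the proposals into noise-chasing.  Duplicate
proposals are re-drawn.

The initial design is a per-dimension stratified (latin-hypercube) sample;
its default size is `max(8, 4 × number of numeric dimensions)`, a common
rule of thumb.  Failed objective evaluations are recorded with objective 0
and a logged diagnostic rather than aborting a long search.  Fidelity
restarts carry every record forward and never re-run the initial design.

## Training harness

Training uses multi-class cross-entropy with the configuration's optimizer
and initial learning rate.  Validation balanced accuracy (mean per-class
recall) is evaluated at a cadence of `budget / target_evals` steps
(~20 evaluations in the short stage, ~100 at full scale; scaled-down runs
here use 10/20).  After each evaluation the learning rate halves if the
last 3 evaluations all failed to beat the *running best* accuracy — the
plateau is judged against the best seen, not the previous value, which is
the standard plateau-scheduler semantics — and the stagnation counter
resets after a halving.  Training stops when 10 consecutive evaluations
fail to improve, which implies at least two halvings have occurred.
Wall-time budgets are converted to step budgets via one timed warm-up
step, so behaviour is hardware-independent.  Batch-capacity search is a
binary search for the largest batch the memory probe accepts, returning
`floor(0.9 × capacity)` (minimum 1).

Stage objectives: short stage — the maximum validation balanced accuracy
anywhere on the trace; long stage — the second-highest value among the
last 20 validation evaluations, so a single noisy outlier cannot win
(a window with fewer than two entries falls back to its maximum).

## Data pipeline

Training and validation batches contain the same number of windows from
every class (minority classes are effectively oversampled).  The search
driver scores validation deterministically over offset-0 windows of the
validation split (an evenly strided subset, capped at 768 windows, when
the split is larger) — random subsampling at small scales adds enough
noise to scramble configuration ranking; the random-batch validation path
remains available.  Each file visit
draws a fresh random start offset and emits consecutive, non-overlapping
L-windows; windows never span record boundaries; re-visits redraw the
offset.  Test iteration is deterministic: files in listed order, windows
from position 0, trailing fragments discarded.  One-hot encoding orders
channels A, C, G, T; ambiguous IUPAC codes become all-zero columns —
length-preserving and inert under convolution (the handling of ambiguous
bases is otherwise an open choice).  Reverse complement commutes with
one-hot encoding: reverse positions and swap A↔T, C↔G.

## Backend

The training backend is a compact numpy implementation with manual
backpropagation: same-padded dilated 1-D convolution (computed on a
zero-copy sliding-window view, contracted with BLAS), batch normalization,
leaky ReLU, non-overlapping max-pooling, global average pooling, LSTM and
GRU (single bias vector, forget-gate bias initialized to 1, optional
bidirectionality), dense layers with inverted dropout, and
Adam/Adagrad/RMSprop/SGD.  Every backward pass is pinned by central
difference gradient checks; the checks use an absolute floor because a
conv bias feeding a batch-norm is exactly absorbed and both gradients are
numerically zero.  Models can train in float32 (about 3× faster; the
search driver's choice) or float64 (the default, used by the gradient
checks).

## Synthetic data

The fixture generator emulates the one property the search loop needs
from a real multi-class genome collection: a planted, learnable class
signal of controllable strength.  Each class has disjoint 8-mer motifs
written over i.i.d. background sequence at Poisson-placed positions;
insertion overwrites (lengths stay exact) and overlaps resolve
last-writer-wins, so realized density is slightly below nominal.  The
default density of 20 insertions/kb was chosen so that over ~95% of
150-nt windows contain at least one intact motif, making the read-level
task learnable by construction; windows without a motif bound the
achievable balanced accuracy at roughly 0.95–0.97.  The generator does
not emulate repeats, GC skew, phylogenetic structure, or sequencing
error, so green tests here demonstrate that the search loop works, not
that any architecture will transfer to real metagenomes.

Profiles: `tiny` is 3 classes × 6 files × 5 kb (seconds to generate; the
quick fixture for unit tests), `small` is 3 × 30 × 50 kb and is the
profile sized for end-to-end search smoke tests.  Files are split
70/20/10 into train/validation/test at the file level, so validation and
test genomes are never seen in training.  The split sizes matter: with
tiny's single validation genome per class, validation balanced accuracy
saturates near 0.83 for every reasonable configuration and cannot rank
the best ones — whole-search demonstrations need the small profile's
6 validation / 3 test genomes per class.

## Desk-scale run sizes

The full-scale method matches its search space to runs of several hundred
evaluations per setting.  The package's end-to-end runs use a few dozen
evaluations, so the demo space is narrowed proportionally
(`DESK_SCALE_OVERRIDES`: depth ≤ 3, kernels 16–32, filters 4–32, dilation
≤ 4, dense stack ≤ 2 × ≤ 48 units, dropout ≤ 0.6, leaky slope ≤ 0.3)
while the dimensions the optimizer must navigate — optimizer choice,
learning rate, pooling total, skip ratio, reverse complement — keep their
full ranges.  Step budgets stand in for wall-time fidelities (300 then
900 steps at batch 30); the winning configuration is retrained at batch
90 for up to 2000 steps with the plateau schedule and early stopping.
These sizes are the package's demonstration defaults; all of them are
constructor parameters.

## Known limitations

- The search loop is sequential; q-wide proposal batches are exposed, but
  scheduling them across workers is the caller's concern.
- The GP surrogate fits in O(n³); fine for hundreds of records, not tens
  of thousands.
- Wall-time fidelity estimation from a single warm-up step is coarse on
  machines with variable load.
- `find_max_batch_size` assumes the memory probe is monotone in batch
  size.
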