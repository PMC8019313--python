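# Methods

## The task

A schema is represented as a directed acyclic graph of story states.
Each state contributes a fixed keyword and an ordered set of role slots
(Subject, Friend, Emcee, Poet, Drink, Dessert); outgoing transitions are
equally likely. A story instantiates one start-to-end traversal with
concrete fillers bound to the roles, one padding token inserted at a
uniformly random body position, tail padding to a fixed length, and a
final query token (`qsubject` … `qdessert`). The supervised target is
the embedding of the filler bound to the queried role.

The coffee-shop schema used throughout has 11 states, 24 distinct
traversals, and 112 answerable (traversal, query-role) pairs, with
per-role counts Subject/Friend/Poet 24, Drink 16, Emcee/Dessert 12. The
longest story body is 23 tokens, so the fixed sequence length is 25
(body + inserted pad + query); the correlation experiments use a fixed
13-token linear frame and length 15. Where a fixed length is needed we
always take the smallest length that fits the longest body plus one
inserted pad and the query.

Words are 50-dimensional vectors: each coordinate N(0, 1), normalized to
unit Euclidean norm. No pretrained embeddings are used anywhere, so
success cannot come from prior lexical knowledge. Retrieval is
nearest-corpus-word by cosine similarity; ties break to the lowest
corpus index. The corpus is the experiment vocabulary plus, in the
unlimited-filler regime, the fresh filler vectors of the evaluation
batch (30 base words + 6 fillers x 16 stories = 126 candidates; chance
1/126 = 0.8%). The 30-word base vocabulary is the 11 state keywords, 6
query tokens, the padding token, and 12 reserved tokens; the full-scale
corpus compositions are not itemized in our sources, so chance rates are
always computed as 1/|corpus| from the corpus actually assembled, never
hard-coded.

## Models

All four architectures share one contract: consume one word vector per
timestep, expose a readout feature after the final (query) step, and
emit a 50-d prediction through a linear readout. All use 50 hidden
units. Layer normalization (epsilon 1e-5, learnable gain and bias)
stabilizes the recurrent pre-activations of the RNN, LSTM, and Fast
Weights cells; the nonlinearity is tanh, chosen so hidden states stay
bounded (which also bounds the fast-weight matrix norm by
eta·max‖h‖²/(1−lambda)).

* RNN: h ← tanh(LN(U x + W h)).
* LSTM: one LN over the joint 4H gate pre-activation; standard
  input/forget/candidate/output gating. (Applying LN once to the sum
  rather than separately per projection halves the parameter count and
  satisfies the same forced-gate identities; this is a deliberate
  simplification.)
* Fast Weights: an auto-associative matrix A ← lambda·A + eta·h hᵀ
  (lambda = 0.95, eta = 0.5, values from the original fast-weights
  work), written with the previous hidden state each step, then S = 1
  settling iteration h ← tanh(LN(z + A h)) against the slow-weight
  drive z. A is batch-local state, reset per story.
* DNC: an LSTM controller reads/writes a 128-slot x 20-word buffer with
  one read and one write head. Content addressing uses cosine keys with
  softplus-sharpened softmax; writing mixes content addressing with
  usage-based allocation; erase/add updates the buffer; temporal links
  (on by default) let the read head follow write order. The readout
  feature is [controller h; read vector]. The allocation weighting is
  computed outside the gradient tape: the slot ordering is a sort and
  hence piecewise constant, and gradients still reach the write path
  through the gates and content addressing. Usage and link updates are
  otherwise fully differentiable.

Training minimizes the mean squared error between the prediction and
the target filler embedding with Adam. MSE is chosen because the output
layer is a 50-node linear map into embedding space and retrieval is by
cosine similarity; a softmax over a fixed vocabulary would be unusable
in the unlimited-filler regime, where targets are fresh vectors. The
reference learning rate is 1e-4 with training batches of 16; early
stopping monitors retrieval accuracy (validation if available, else
training) with patience 10, and a target accuracy can stop training
once a criterion (e.g. >90% train accuracy) is met.

## Study conditions and desk scale

The experiments mirror three regimes:

1. limited fillers, test on new permutations of seen fillers;
2. limited fillers, test on a disjoint filler pool;
3. unlimited fillers — every story gets six freshly drawn vectors, in
   training and test, over the 112 frames.

Full-scale sizes (5,000 stories per path with deduplication, 1,000
violation fillers with 750-per-role training pools) are supported by
the same builders. The bundled experiment builders run desk-scale
versions sized for a single CPU:

* disjoint-pool experiment: 2 paths x 200 stories, 6 fillers per role,
  trained at lr 1e-4 until >90% (stopping at 95%) train accuracy;
* violation design: 100 fillers, per-role pools 75/25, 2,000 training
  stories, fixed linear frame;
* retention: fresh fillers per story from distributions X/Y
  (even-coordinate shift of +0.5 with probability 0.9 or 0.1, one coin
  per vector, 0-based even indices), frame words from Z; five seeds.

At desk scale the networks see far fewer gradient steps than the
original full-scale runs, so the scaled runs use a larger Adam step
(1e-2 for the Fast Weights probes, chosen once from convergence-speed
considerations on the training set) while the architecture and data
conditions are unchanged. The qualitative claims under test —
zero generalization from limited pools, perfect generalization of the
external-memory networks to correlation-violating bindings, retention
biases — are properties of the converged solutions, not of a particular
step size.

## Decoding analyses

For 100 stories sharing one frame (identical frame text, pinned pad
position, distinct fresh fillers) we record activity after every input
word: hidden states (50-d), the fast-weight matrix flattened to
2,500-d, the DNC buffer flattened to 2,560-d, and DNC read/write
weightings. One ridge regression (regularization strength 1.0, the
scikit-learn closed form) is fitted per (role, timestep, component)
from activity to the correct filler vector on 80 sequences; per-
timestep fitting is the only reading consistent with score curves over
time. Held-out predictions for the remaining 20 are scored by
1 − rank/|corpus| of the true filler under cosine ordering (max 1;
uniformly random rank gives 0.5 + 1/(2|corpus|) ≈ 0.5). The default
frame is the unique traversal containing all six roles
(BEGIN→ORDER_DRINK→SIT→INTRO→POETRY→PERFORM→ORDER_DESSERT→END).

The DNC read/write analysis takes, per story, the argmax write-weight
slot at the timestep each role's filler is input and the argmax
read-weight slot at the query timestep (ties to the lowest slot), and
correlates the resulting per-role histograms (Pearson). A location-
based binding strategy appears as a correlation matrix dominated by its
matched (write role = read role) entries.

## Correlation probes

The violation design excludes filler i from varied role i mod 4
(Subject, Friend, Emcee, Poet); training binds each role only to its
750 (desk scale: 75) allowed fillers, the test set binds each role only
to its excluded fillers, and Dessert/Drink stay constant. Every filler
therefore appears in exactly three training pools, and every test
binding contradicts the training statistics.

Retention trains with role-correlated distributions and probes bias two
ways: (a) ambiguous stories — the queried filler's input vector is
replaced by the zero vector (input side only; the zero vector is never
a retrieval candidate) and the prediction's even- vs odd-index values
are compared; (b) all-Z stories — the residual prediction − target is
compared the same way while accuracy is recorded simultaneously. Both
use a two-sample Welch t over the pooled even-index and odd-index
values across a trial's test stories (the pooling is our choice; the
source does not define it). Positive t means elevated even indices,
the signature of distribution X.

## Numerical and engineering choices

The networks are trained with a small reverse-mode autodiff engine
written on numpy (dense float64, tape-based, with fused layer-norm /
softmax / sigmoid kernels). Gradient correctness is tested against
central finite differences for every cell type. Determinism: all
randomness flows through explicitly passed numpy Generators; refitting
with the same seed reproduces parameters bit-identically, and ridge
decoding is closed-form.

Degenerate inputs: a zero prediction vector has no cosine direction and
raises; a missing filler for an on-path role raises; non-finite training
loss aborts with a diagnostic rather than continuing silently.

## What the generator does and does not emulate

The synthetic stories exercise exactly the structural property under
study — an arbitrary, structure-determined binding between roles and
fillers — while removing every semantic cue: word vectors are random,
frames are rigid, and distributional structure is imposed only where
the design calls for it. Passing these tests therefore shows that an
architecture can learn structure-based binding, not that it handles
natural language, referential ambiguity, or schemata that must be
induced from unsegmented experience.

## Known limitations

* Desk-scale runs train far fewer steps than the original full-scale
  experiments; accuracies for the hard regimes are reproduced as
  qualitative patterns (above/below chance, 0%, 100%) rather than exact
  curve shapes.
* At desk scale a small fraction of disjoint-pool test predictions can
  land on out-of-training-vocabulary candidates (near-misses in cosine
  space); the full-scale "predictions are always training fillers"
  observation sharpens with training diversity.
* The DNC allocation weighting is piecewise constant in usage by
  construction; we do not propagate gradients through the sort.
* Wider/deeper LSTM variants are configurable (`hidden`, stacking is
  not implemented) but not part of the test conditions.
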