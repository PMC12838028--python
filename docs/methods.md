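# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not show.

## The SplitFed procedure

A segmentation network is partitioned into FE / SS / BE sub-models with
disjoint, exhaustive parameter sets. One **global round** consists of:

1. every client loads the current global FE and BE weights and its
   server-held SS copy;
2. the client runs `local_epochs` epochs of minibatch training. A step is
   `forward_split` (FE → boundary packet → SS → boundary packet → BE →
   logits), softmax + Soft Dice loss, `backward_relay` (BE, then SS given
   the BE-boundary gradient, then FE given the SS-boundary gradient plus
   the client-side skip/index gradients), and one simultaneous optimizer
   step over all three roles;
3. the server aggregates client FE and BE weight sets with FedAvg
   (elementwise convex combination; weights default to local training-set
   size) and broadcasts. SS copies live at the server, so they are
   aggregated too by default (`aggregate_ss=True`); setting the flag off
   keeps one persistent SS copy per client instead.

All clients participate in every round; partitions are IID by
construction (a seeded uniform permutation). Training runs a fixed budget
with no early stopping. Packet hand-offs are explicit in-process calls,
but the packet type (main tensor + named side tensors + shape/dtype
metadata) is serializable, so a networked deployment would only replace
the transport.

**Privacy partition.** FE consumes only images; BE is the only role that
touches labels; any tensor produced by FE and consumed by BE (UNet's
stage-1 skip, SegNet's stage-1 pooling indices) is retained client-side.
`SplitSpec` rejects FE → SS side routes at construction time.

**Optimizer.** Adam (β₁=0.9, β₂=0.999, ε=1e-8) by default; plain SGD is
available. Optimizer state is reset at each broadcast — aggregated
weights invalidate per-client moment estimates. The centralized loop
accepts `opt_reset_every` so the single-client equivalence (SplitFed with
one client ≡ centralized training, bit for bit) holds under matching
reset policies. Shuffles are seeded per (seed, client, global-epoch), so
the equivalence requires no tolerance at all; the test asserts 1e-6.

## Architectures and pinned split points

All layers are built on a small NumPy module with explicit per-layer
forward/backward passes (BLAS-dispatched convolutions, no im2col buffer).
Explicit layer-wise backprop is what a staged gradient relay needs; a
global autodiff tape would have to be cut artificially. Initialization is
a seeded uniform fan-in scheme, U(−√(1/fan_in), +√(1/fan_in)), applied to
weights *and* biases (random biases avoid starting the network exactly on
a ReLU kink where post-ReLU windows are all zero, which would make
gradient verification ill-posed). No normalization layers are used
anywhere.

- **UNet** — 4 encoder + 4 decoder stages, widths (w, 2w, 4w, 8w, 16w),
  paired 3×3 convolutions, 2×2 max pooling, transpose-conv (k=2, s=2)
  upsampling, 1×1 head. FE = first paired-conv block (+ pooling); BE =
  last transpose conv + last paired-conv block + head; SS = the rest.
  The stage-1 skip routes FE → BE client-side. At w=32 and 2 classes the
  total is exactly 7,760,130 parameters (7.76 M); the additive MAC
  estimator gives 10.61 GMAC at 240×240, within 1% of the published
  10.52 GMAC figure for this configuration.
- **SegNet** — same encoder skeleton without skips; decoders upsample by
  max **unpooling** with the argmax indices recorded by the matching
  encoder pool. Stage-1 indices are a client-side FE → BE side tensor;
  indices produced in SS never leave SS. Indices carry no gradient.
- **Attention UNet** — the UNet skeleton plus additive attention gates
  α = σ(ψ(ReLU(Wx·x + Wg·g))) on each decoder skip (x = skip, g =
  upsampled decoder feature). Gates for the internal skips live in SS;
  the stage-1 gate lives in BE with its skip input routed client-side.
- **CGNet** — a light context-guided net: a 3-conv stem (stride-2 first
  conv) in FE; a stride-2 down-conv plus four context blocks at width 2w
  in SS; a stride-2 down-conv, three context blocks at width 4w, a 1×1
  head and ×8 nearest upsampling in BE. A context block is 1×1 reduce →
  (depthwise 3×3 local ∥ depthwise 3×3 dilated surround) → concat → ReLU
  → residual. Conv-layer counts per role are 3/13/11 and BE holds the
  parameter majority (~67% at the default widths) — the partition is
  intentionally back-heavy, unlike the other nets.

Input sizes must divide the pooling factor (16 for the U-shaped nets, 8
for CGNet); the forward pass rejects other sizes naming the factor rather
than padding silently.

**Correctness oracles.** `assemble` shares parameter storage with the
three sub-models, so split-vs-assembled agreement validates packet
routing and caching. The layer mathematics itself is validated
independently: every convolution variant, the transpose conv, pooling,
unpooling and the gates pass central finite-difference checks in float64,
and full-model directional FD checks pass on the median criterion (the
median tolerates probes that straddle a ReLU/max-pool kink, where
two-sided differences are not a valid derivative estimate).

## Loss and metrics

Soft Dice uses the squared-denominator form with smooth s=1 by default,
classes equally weighted, background included in the loss. Reported IoU
excludes background: the 5-class task averages the four foreground
structures, binary tasks report the foreground class (a flag re-includes
background). A class absent from both masks scores IoU 1.0 (empty-union
convention), keeping per-sample averages defined on small images. On hard
masks with s=0 the identity dice = 2·IoU/(1+IoU) holds per class and is
asserted in the tests.

## Synthetic data

The generator emulates the *structure*, not the appearance, of the three
study datasets: concentric ring/ring/disk/blob geometry for the 5-class
embryo-like task and Fourier-perturbed blobs for the two binary tasks.
Classes render at base intensities spaced ≥ 0.15 with mild RGB tints and
additive Gaussian noise (default sd 0.08 in [0,1] units). Radius ranges
(fractions of image size) are nested strictly by validation, so masks are
nested by construction. Everything is a pure function of (spec, seed).

What passing tests therefore show: the *mechanism* is right — split
training equals monolithic training, aggregation behaves, federation
recovers the data-pooling advantage. What they do not show: performance
on real dermoscopy/endoscopy/microscopy texture, robustness to non-IID
partitions, or the published absolute IoU levels, which require the real
datasets and GPU-scale budgets.

## Reporting arithmetic

The harness reproduces the published summary conventions: IoUs are
reported to 4 decimals, the average-over-models row is the arithmetic
column mean (rounded to 4), and C−L / C−S differences are taken between
average-row entries and expressed in percentage points (rounded to 2).
Rankings sort by IoU descending with lexicographic tie-break. Note that
two of the published narrative differences (blastocyst C−L and the
KVASIR C−S) are inconsistent with the published table's own average row;
recomputing from the table gives 11.87 and 2.31 where the narrative says
10.61 and 2.01. The arithmetic here follows the table.

## Problem sizes and defaults

Tests run at desk scale by design: 64-px images (not the 240-px
production setting), base width 8 (not 32), 3 global rounds × 2 local
epochs against 6 local-only epochs, and 4 clients with 11/9/20/30
samples — the published blastocyst client proportions scaled by ten.
Learning rates are task- and budget-specific; for the 64-px 5-class task
the default 2e-3 with batch size 2 was chosen by a convergence sweep of
plain centralized training (rates ≥ 5e-3 collapse to all-background under
Soft Dice; ≤ 5e-4 underfit a 6-epoch budget). Production-scale defaults
mirror the published protocol: 240×240 inputs, 85/15 train/val split per
client, 120 centralized epochs, 10 global rounds × 12 local epochs.

## Known limitations

- Only the four core architectures are implemented; the `SplitSpec`
  contract (cut indices + typed side-channel routes) is designed so
  further encoder–decoder nets can be added without touching the engine.
- The MAC estimator counts convolution multiplies only; nets dominated by
  elementwise or attention arithmetic would be under-counted.
- CPU-only, single-process simulation; no secure aggregation, encryption,
  differential privacy, client sampling, or asynchronous rounds.
- Binary-task IoU reporting defaults to foreground-only; whether the
  published binary averages include background is not stated, so the
  choice is exposed as a flag rather than guessed.
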