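# Methods

`spikeplex` quantifies how the local synaptic topology of a spiking neural
network shapes its *functional* reconstruction — the directed graph of
statistically significant spike-train correlations. The analysis chain is:
structural network construction → spiking simulation → correlation
estimation (transfer entropy or rate correlation) → per-neuron thresholding
→ multiplex pairing of the two layers → dyadic/triadic transformation
census → Z-scores against two randomised null models.

## Structural networks

Neurons sit on an `r × c` integer grid (default 10×10, 100 neurons) with an
undirected edge between every pair at Euclidean distance ≤ √2 and no
periodic boundaries; the 10×10 grid has exactly 342 undirected edges.
Watts–Strogatz rewiring then moves each undirected edge with probability
`p_rw` (default 0.4): one endpoint, chosen uniformly, is kept and the other
replaced by a uniform vertex, redrawing on self-loops and duplicates. Both
directions of an edge move together, so the network stays fully recurrent
through this stage.

Recurrence is then reduced by making an **exact count** `round(p_r · E)` of
undirected edges unidirectional (selection without replacement), deleting
the canonical lower-index→higher-index direction with probability `p_d`
(default 0.5) and the reverse otherwise. The exact-count reading makes the
headline statement "`p_r = 0.4` leaves 60 % of connections recurrent" hold
deterministically (205 = round(0.6·342) recurrent pairs), and the canonical
orientation makes the `p_r = 1, p_d ∈ {0, 1}` network acyclic by
construction. Finally `round(0.2 n)` neurons are flagged inhibitory at
uniformly random positions; each directed edge from an excitatory source
draws an amplitude from N(3.1, 0.1) mV independently per direction, and
every inhibitory-source edge has amplitude −1.5 mV.

## Spiking model

Excitatory cells follow the regular-spiking quadratic
integrate-and-reset dynamics
`100 v̇ = 0.7 (v+60)(v+40) − u + I`, `u̇ = 0.03(−2(v+60)) − u`, reset at
35 mV to −50 mV with `u ← u + 100`; inhibitory cells follow the
fast-spiking form `20 v̇ = (v+55)(v+40) − u + I`,
`u̇ = 0.2 (U(v) − u)` with `U(v) = 0.025 (v + 55)³` above −55 mV and 0
below, reset at 25 mV to −45 mV. (The `−u` outside the 0.03 factor in the
excitatory adaptation equation is implemented exactly as written; it
differs from the more common form in which the leak sits inside the
`a(b(v−v_r) − u)` bracket, but shares its fixed point at (−60, 0).)

A synaptic event from a spike at `t_k` contributes
`v_X · exp(−(t − t_X − t_k)/τ)` for `t ≥ t_k + t_X`, with τ = 3 ms and
onset delays `t_X` of 5 ms (excitatory) and 1 ms (inhibitory);
contributions superpose linearly. Because all synapses share τ, the
superposition is tracked *exactly* by one exponentially decaying
accumulator per neuron plus a ring buffer of scheduled arrivals — no
per-event bookkeeping or cutoff is needed. The summed trace `S` enters the
current as `I = (C/τ) · S`, i.e. one event delivers total membrane charge
`C · v_X`, so the peak depolarisation of a quiescent cell approximates the
synaptic amplitude `v_X` — the reading of "maximum voltage increase
delivered by the synapse" that keeps 3 mV synapses physiologically
meaningful. (Summing `S` into `I` unscaled would move the membrane by
~0.1 mV per event and leave the network silent; the gain is configurable
per target population.)

External drive is a pooled excitatory Poisson event train per neuron —
events pass through the standard excitatory synapse with amplitudes from
N(3.1, 0.1) mV — standing in for many independent external afferents at a
nominal 10 Hz each. Pooled defaults of 170 Hz (excitatory targets,
≈ 17 afferents) and 700 Hz (inhibitory targets, ≈ 70 afferents, whose
smaller capacitance dilutes charge injection) were chosen once to place
both populations in a fluctuation-driven regime with mean drive near
rheobase and cortical-like irregular firing of 3–8 Hz. Event times are
generated in milliseconds, independent of the integration step, so seeded
runs are comparable across `dt`.

Integration is forward Euler with default `dt = 0.025 ms`. At this step,
halving `dt` changes the spike count of a seeded 10 s network run by ≈ 4 %
(first-order convergence; coarser steps amplify through the recurrent
dynamics — at `dt = 0.1 ms` the halving change is ≈ 10 %).

## Correlation measures

**Higher-order transfer entropy (TE).** For each ordered pair the plug-in
estimate of the transfer entropy from source history words of order
`l = 5` to the target's next bin given its own order-`k = 5` history, on
1 ms binned binary trains, maximised over delays 0–30 ms (ties → smallest
delay). Probabilities are raw word frequencies (no smoothing) with the
`0·log 0 = 0` convention; the estimate is a conditional mutual information
of the empirical distribution and hence non-negative. The all-pairs path
encodes words as integers and visits only time bins where either word is
non-zero, recovering the all-zero cell from the total count — bit-exact
against the naive estimator, ~10× faster on sparse trains.

The estimator's finite-sample bias (a 2·2⁵·2⁵-cell histogram) sets a noise
floor ∝ 1/T. At 60 s it rivals the synaptic signal; at 300 s connected
pairs separate cleanly and at 600 s (the full profile) the reconstruction
recovers ≈ 88 % of synapses at κ = 0.2 with false positives well below the
density-matched chance level. The reduced profile therefore uses 300 s.

**Gaussian-convolution correlation (CC).** Each binned train is convolved
with a normalised Gaussian kernel of σ = 0.2 s sampled at 1 ms and
truncated at ±4σ ("same" alignment), giving a firing-rate signal; the
σ = 0.2 figure is read in seconds — a 0.2 ms kernel would be sub-bin and
inert, and the coarse kernel is consistent with CC's higher false-positive
rate. The delayed Pearson coefficient between target and source signals is
evaluated at delays 1–30 ms with overlap truncation and maximised over the
grid; zero-variance overlaps are flagged undefined (NaN) and excluded from
the maximum. Because the 200 ms kernel wipes out millisecond timing, CC
carries almost no direction information: reciprocal functional edges are
common, which inflates its false positives and washes out
direction-sensitive dyadic cells (2→2 versus 2→3). The direction-resolved
acceptance checks therefore target the TE reconstruction; CC is retained
as the rate-based contrast.

## Thresholding

For each neuron the mean and **population** SD of its n−1 outgoing and,
separately, its n−1 incoming correlation values (zeros and NaN→0 included)
define `γ_out = μ_out + κ σ_out` and `γ_in = μ_in + κ σ_in`. The directed
correlation j→i is retained iff it is ≥ both the source's outward and the
target's inward threshold — a non-strict comparison, so the all-equal
degenerate case keeps every edge. Thresholds are monotone in κ, hence edge
sets are nested over the κ grid {0.2, 0.5, 0.8}.

## Multiplex census

The structural and functional layers share the vertex set; the
supra-adjacency is the 2n×2n block matrix with the layer adjacencies on
the diagonal and identity off-diagonal blocks. Neuron types are ignored in
classification. Dyads have three classes (empty / single / recurrent);
pairing the layers and reducing by the simultaneous vertex swap leaves ten
dyadic transformation classes (three preservations, the reversal 2→2*, six
conversions). Triads fall into the 16 isomorphism classes of 3-vertex
digraphs, implemented as a 64-entry canonical-form lookup (minimum 6-bit
edge code over the vertex permutations) built from explicit class
representatives; the class sizes over the 64 labelled digraphs are
(1,6,3,3,3,6,6,6,6,2,3,3,3,6,6,1). The numbering follows the convention in
which 4 is the out-hub, 5 the in-star, 6 the chain, 9 the feed-forward
triangle, 10 the cycle and 16 the complete triad; the tests pin the table
against networkx's triadic census as an independent oracle. The triadic
census fills the 16×16 table of (structural class, functional class) over
all C(n,3) unordered triples; dyadic counts sum to C(n,2).

## Null models and Z-scores

**Structure randomisation** (for dyadic Z-scores): a uniform vertex
permutation followed by 100 double-edge-swap *attempts*. Each attempt
draws two edge units uniformly from the pooled list of recurrent pairs and
unidirectional edges; attempts mixing the two kinds, sharing a vertex, or
whose proposed positions are occupied in either direction (which would
create a duplicate or a new mutual pair) are discarded. Recurrent pairs
swap as undirected units with randomised orientation; unidirectional edges
swap sources, preserving source/sink roles. In-, out- and
recurrent-degree sequences are preserved exactly; each sample is
independently permuted and paired with the fixed functional layer.

**Discrepancy randomisation** (for triadic Z-scores): a surrogate
functional layer copies the structural one, deletes as many uniform
structural edges as observed false negatives and adds as many uniform
structural non-edges as observed false positives; each sample pairs with
the fixed structural layer.

Per transformation, `Z = (observed − μ)/σ` with μ, σ the ensemble mean and
population SD over N samples (default 100; reduced profile 20). Cells with
σ = 0 are reported as undefined unless the observed count equals μ (then
Z = 0); undefined cells are excluded from cross-trial averages, with the
per-cell denominator reported.

## Experiment profiles and expected signature

The full profile mirrors the source conditions: 10 trials, 600 s trains,
N = 100, κ ∈ {0.2, 0.5, 0.8}, both measures. The reduced profile (tests,
examples, acceptance script) uses 3 trials of 300 s, N = 20, κ = 0.2 —
about 80 s per trial on one CPU. Under it the TE reconstruction
reproduces the expected dyadic signature: preservation transformations
(1→1, 2→2, 3→3) strongly overrepresented (mean Z ≈ +20 to +50),
conversions underrepresented (Z ≈ −3 to −42), and the direction reversal
2→2* and recurrence gain 2→3 small relative to the far-from-zero cells.
"Near zero" is operationalised relatively — their |Z| must stay below half
the mean magnitude of the other cells — because the underlying published
values exist only as figures; in this implementation the weakly negative
cells 3→2 and (at short trains) 1→2 can approach similar magnitudes, so a
strict "smallest |Z|" ordering is not a reliable property.

## What the generator does and does not emulate

The simulation produces irregular, weakly correlated spiking with
physiologic rates, genuine synaptic causation at millisecond delays, and
common-input correlations through shared neighbours — the features the
correlation measures are meant to detect and confound. It does not emulate
synaptic plasticity, conductance-based synapses, axonal delay
distributions, bursting cell classes, or measurement effects
(subsampling, spike-sorting errors). Passing tests therefore show that the
census/null machinery behaves correctly on data with realistic first-order
statistics, not that reconstruction quality transfers to biological
recordings.

## Numerical choices and degenerate inputs

Word histograms use int64 counts; TE marginals are recomputed per delay.
Ties in max-over-delay resolve to the smallest delay for determinism.
Undefined CC entries are NaN end-to-end and treated as 0 by thresholding
(logged). The simulator aborts with a diagnostic on non-finite state or
|v| > 10³ mV and on sustained firing above 150 Hz (buffer overflow guard).
All randomness flows through seeded `numpy` generators; per-trial seeds
derive from the experiment seed via `SeedSequence` and stay below 2³¹.

## Known limitations

- The 1024-neuron configuration is supported through `BuildParams` but not
  exercised by the test suite (quadratic pair and cubic triple costs).
- CC direction recovery is intrinsically poor at σ = 0.2 s (see above).
- The plug-in TE estimator is uncorrected; at 60 s and below its bias
  floor dominates, which is why the reduced profile uses 300 s trains.
- Null model one's 100 swap attempts randomise locally on top of the
  global permutation; attempt (not success) counting follows the stated
  procedure, and the permutation already guarantees global mixing.
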