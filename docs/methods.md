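# Methods

## Data model

One dyad's observation is a pair of equally long categorical sequences at
1 Hz: an infant code (1–8) and a mother code (10–20) per second, one code
per second per stream (half-open `[t, t+1)` intervals, 0-based). The code
book ships as editable YAML (`dyadnet/data/default_codebook.yaml`) and
carries, besides the code lists, the interpretive harmony classes used by
the latency analysis: harmonious combined states `1-11`/`1-12`, smooth
mother codes {11, 12} and infant codes {3, 4}, disharmonious infant codes
{5, 6} and mother codes {13, 14, 15}, neglect codes {infant 6, mother 18}.

Unknown or blank codes are hard errors, never silently dropped: a silent
drop would bias transition counts. Non-contiguous or duplicated seconds
within a dyad are integrity errors naming the dyad and second.

## Transitions and networks

Seconds in which either partner holds an 'other' code (infant 8,
mother 10) carry no specific behavior. They are removed and the remaining
seconds split into maximal contiguous segments; a transition is emitted at
each consecutive pair of seconds within a segment whose combined state
differs (a simultaneous change in both streams is one transition). Stream
boundaries and splice cuts never generate transitions — counting across a
cut would fabricate transitions through omitted states. Per-dyad streams
are processed independently and pooled only as counts.

Edge weights are transition rates, 100 × count / group total, which
normalizes simultaneously for the number of dyads and recording lengths.
Node attributes record total dwell seconds and a per-dyad mean dwell
(dwell ÷ number of dyads observed in the state); the mean is kept for
display scaling in exports, analyses use the total. States with dwell but
no transitions are retained as isolated nodes — their existence is itself
a group feature picked up by the connectivity profile.

Connectivity categories use unweighted degrees over distinct edges (a
reciprocal pair gives each endpoint one in and one out); category 5 is
"no in **or** no out", with fully isolated nodes (no in **and** no out)
additionally sub-counted because the group contrast of interest singles
them out.

## Group comparison

Subtraction is over the union edge set with absent edges as rate 0; dwell
differences are plain seconds, unnormalized. The distinctness threshold
is 0.5 percentage points, **inclusive** at exactly ±0.5 (the boundary
reading is ambiguous in the field's usage; inclusive is chosen and the
threshold is a parameter). Flag lists are ordered by |difference| with a
lexicographic state-order tie-break so output is deterministic.

Flagged edges are tested with a 2×2 Pearson χ² of count vs group total,
df 1, right-tail p, **without** Yates continuity correction — the
uncorrected statistic is the one that reproduces published values computed
this way (e.g. counts 16/1864 vs 5/1729 give 5.00, and 12/1864 vs 2/1729
give 6.45). By default only flagged edges are tested, mirroring standard
practice for this analysis; `test_all=True` tests every union edge, and
no multiplicity correction is applied by default (a faithful-reproduction
default; Benjamini–Hochberg can be applied downstream from the exported
p-values). Edges whose table has a zero marginal are untestable and
skipped.

### Calibration and the Markov caveat

`calibration.null_calibration` simulates both groups from identical
dynamics and measures the fraction of per-edge χ² tests with p < 0.05
among *testable* edges (every expected cell count ≥ 5, Cochran's rule).
On iid multinomial counts the test is correctly sized (≈4.9% in our
checks). On pooled Markov-stream counts the realized rate runs slightly
above nominal (≈5.0–5.7% across seed batches) because successive
transitions are dependent — the next transition's source is the current
one's target — making edge counts mildly overdispersed relative to the
multinomial sampling χ² assumes. This is a property of applying 2×2 χ²
to pooled transition counts from any sequential behavioral record, not of
the implementation; at this data scale the miscalibration is small but
worth remembering when p-values sit near 0.05.

## Randomization null

Surrogate networks are generated by Maslov–Sneppen-style directed edge
swaps: pick two distinct directed edges (a→b), (c→d), propose (a→d),
(c→b), each keeping its weight. Proposals creating an already existing
edge or a self-loop are rejected (self-loops are impossible under the
transition definition, so admitting them would put mass on impossible
networks). This conserves the node set, edge count, every node's in- and
out-degree, and the weight multiset. The swap budget counts **attempts**
(default 20 000), with the accepted-swap count recorded in
`meta["accepted_swaps"]` so the alternative "20 000 accepted" reading can
be checked; on the default synthetic networks (~80–90 edges) roughly a
quarter of attempts are accepted, several dozen times the edge count, so
the chain is well mixed.

The empirical p of a focal transition pairs the i-th rewired group-A
network with the i-th rewired group-B network (default 5 000 replicate
pairs), subtracts focal rates (absent edge → 0), and reports the fraction
of pairs with difference ≥ the observed one. With zero extreme replicates
the p-value is reported as the upper bound 1/n_replicates, never 0. A
single seeded generator drives the run; per-replicate substreams are
spawned deterministically, so identical seed + config gives identical
results.

## Sequence analyses

Backward trees walk the within-segment transition sequence: for each
occurrence of the focal transition, level k collects the source state of
the k-th preceding transition (depth 3 by default); a walk exiting its
segment stops contributing, so level totals are non-increasing in depth.
Rates at each level are percentages of that level's total. The ≥5%
display threshold affects rendering only; full counts are always kept.

Latency runs on real recording seconds: the clock starts at the second
the focal transition completes (the first second in its target state) and
searches the dyad's **full** stream to its end — 'other'-coded gaps count
as elapsed, non-target time, because reported latencies are wall-time.
If the focal transition's own target state is in the target set the
latency is 0. Occurrences never followed by a target state are censored;
mean and sample SD are over reached occurrences only (a censoring-aware
estimator such as Kaplan–Meier is deliberately out of scope; with heavy
censoring the reported mean understates the true latency).

## Time-unit kappa

Second t of coder A agrees when coder B holds the same code at any second
within a symmetric whole-second tolerance window (default ±2 s). An
agreement confusion tally puts agreeing seconds on the diagonal under A's
code and disagreeing seconds in cell (A's code, B's code at t); kappa is
(p_o − p_e)/(1 − p_e) with p_e from the tally's marginals, defined as 1
when p_e = 1 (both coders constant and identical). Tolerant matches are
not consumed — one B-second may justify several A-seconds' agreement. A
one-to-one matching variant would be slightly stricter; which one
established coding software uses is not documented, so the simpler scheme
is used and stated here. Kappa is non-decreasing in the tolerance on
fixed inputs (tolerance can only add agreements).

## Synthetic dyads

The generator is a first-order Markov process over combined states with
explicit per-state persistence: each second the dyad stays with
probability `persistence[s]` (dwell per visit is geometric, mean
1/(1−p)), otherwise jumps by a row-stochastic zero-diagonal between-state
matrix. This is the simplest process consistent with one-code-per-second
streams and geometric-looking dwell — an assumption of the test harness,
not a claim about real dyads.

Defaults are the study conditions: 42 full-term and 30 preterm dyads;
recording lengths drawn from normal(415 s, SD 118 s), truncated by
redraw at ≥ 60 s (avoiding degenerate recordings) and rounded to whole
seconds. Two stock dynamics ship. The *harmonious-centric* configuration
uses 14 states around the harmonious core (`1-11`, `1-12`, `2-11`, …,
`6-13`) with jump-target attractiveness strongly peaked on harmonious
play, persistence 0.85 in the core and 0.70 in the periphery, and
double-code-change jumps down-weighted ×0.01 (behavioral streams mostly
move one partner at a time; this also keeps observed networks at
realistic sparsity, ~80–90 links, instead of near-complete). The
*uniform* configuration is a structureless control. Neither claims to
reproduce any real group's rates — passing tests show the pipeline's
statistics behave correctly on data with this structure, not that any
particular developmental finding is recovered. 'Other' codes are
optionally inserted by overwriting each second independently at
`other_rate` (side drawn uniformly from infant-only / mother-only /
both).

Planted differences adjust group B's matrix so a chosen edge's expected
transition rate (share of all jumps: stationary mass of the source ×
row entry) differs from group A's by a stated number of percentage
points. Because changing a row re-weights the stationary distribution,
the entry is solved by fixed-point iteration rather than a one-shot
first-order adjustment, with the row's remaining mass rebalanced
proportionally; the planted expected offset is exact to numerical
tolerance under the stationary jump chain, and infeasible offsets raise
a configuration error before any simulation. Finite recordings start
from the initial-state distribution rather than the stationary one and
truncate mid-dwell, so measured offsets carry a small transient bias
(≈0.1 pp at the default scale), well inside the recovery band.

## Problem sizes used by the checks

The calibration suite runs at: null calibration, 200 identical-group
replicates at the study sizes (≈11 000 edge tests); planted recovery,
+2.0 pp on the designated low-frequency edge `6-15 → 3-15`, 50 replicates
at 200 dyads per group (the sampling SD of the measured difference is
≈0.15 pp there, comfortably inside the ±0.5 pp recovery band; at 60
dyads per group it is ≈0.45 pp and recovery would be noise-limited);
empirical-p sanity, 2 000 replicate pairs at 20 000 swap attempts;
structural conservation, 100 random networks × 20 000 attempts;
transition-extraction oracle, 1 000 random streams of up to 500 s.

## Known limitations

* First-order dynamics: real interaction streams show longer-range
  dependence; the generator cannot emulate it, so tests say nothing about
  higher-order structure.
* The χ² edge tests inherit the mild overdispersion liberality described
  above on sequential data.
* The latency mean is a complete-case estimator; censoring is reported
  but not modeled.
* Network exports carry attributes only; layout and styling are left to
  the viewer.
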