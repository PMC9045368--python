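# Methods

## TSS calling

The relative read score RRS*ᵢₒ* = (*nᵢₒ*/*N*)·10⁶ normalizes the 5′-end count
at position *i*, orientation *o* by the library size *N* (total mapped reads
across all replicons and strands, which may exceed the counts carried in a
partial-genome profile). Clustering absorbs the few-bp imprecision of TSS
determination: the unconsumed position with the highest RRS becomes a peak,
all unconsumed RRS within ±5 bp is summed into it, and the process repeats.
Ties between equal RRS values are broken toward the smaller forward
coordinate on both strands, making the output byte-identical across runs;
pooled mass is conserved exactly and peaks are pairwise more than one radius
apart.

Quality scores are either the clustered RRS itself (control-free mode, the
default) or the ratio to the control-library RRS pooled with the same radius
around the peak. In ratio mode a zero pooled control is replaced by the
smallest nonzero control RRS in the track, and the call is flagged; this
pseudo-count floor avoids infinities without inventing a global constant.
Cutoffs: RRS ≥ 5 (inclusive), per-replicate score > 5 (strict), and a strict
mean score > 10 across replicates, which must all contain the peak at the
same clustered position (per-replicate jitter is already absorbed by
clustering, so exact-position matching is the correct replicate test).
Clustering runs per replicate, before the consensus intersection.

## Promoter windows

Windows cover relative positions −90..−1, +1..+10 (TSS = +1, no position 0):
100 nt, with the TSS at window index 90. Minus-strand windows are
reverse-complemented so every window reads 5′→3′ with the TSS-proximal end
3′; all downstream coordinates are defined on this oriented window. Windows
that would extend beyond a replicon end raise an error and the TSS is
dropped (no circular wrap-around). N bases are allowed; they emit with
background probability in the HMM and never match a consensus base in
scoring.

## The two-motif promoter HMM

### Architecture

Background states share one homogeneous emission distribution; each of the
two motif sets offers K alternative 10-state chains with position-specific
emissions, entered at most once, or skipped. Switches between alternative
chains are impossible inside a motif — a path commits to one component per
set. Two structural constraints are encoded as mandatory background runs: no
motif may start before window position 40 (with the 100-nt window this
confines the search to −50..+10; when the first set is empty the constraint
binds the second set's motif), and at least 10 background positions separate
the two motifs (a hard minimum, the interpretation adopted for "minimum
distance").

### Transitions

All background decision states share a single stay probability *t*; each
motif set contributes one "move on" event whose outcome is categorical over
(skip, component 1..K). A path's transition cost is therefore
*n*·log *t* + Σ log(1−*t*) + log *a*(choice₁) + log *b*(choice₂), where *n*
counts the background positions after the offset and outside motifs up to the
last motif. Because the cost depends only on the motif placements, Viterbi
decoding reduces to exact maximization over all legal
(component, start, component, start) placements, which vectorizes over
sequences; it is equivalent to running Viterbi on the underlying state graph.
The shared *t* gives a geometric prior that mildly favors earlier motif
placements; skip timing is canonicalized to the earliest opportunity
(placements of the skip jump are likelihood-equivalent). Tie-breaking is
lexicographic and deterministic: skip before use, earlier starts, lower
component indices.

### Training

Viterbi training (segmental k-means): decode all sequences, re-estimate
emissions, the component/skip choice distributions and *t* from path-aligned
counts with a pseudo-count of 0.5 on every count, repeat until no sequence
changes its path, up to 100 iterations. Pseudo-count smoothing maximizes a
penalized rather than the raw path likelihood, so the trainer additionally
verifies the total Viterbi log-probability each iteration and stops —
keeping the previous model — if it would decrease; the recorded training
history is therefore non-decreasing by construction. Each restart *r* draws
its initialization (Dirichlet(1) motif emissions; background from the
empirical base composition; uniform transition choices; *t* = 0.9) from a
generator seeded with `seed + r`, so restarts are individually reproducible
and order-independent; the restart with the highest total Viterbi
log-probability wins, ties to the lowest index.

The reported LLR of a sequence is its Viterbi log-probability minus that of
the all-skip (pure background) path under the same model.

### Two-phase protocol

Phase 1 trains (0, 5) components with 100 restarts, targeting the −10
region; the component matched by the most promoters is the dominant −10
motif. Phase 2 trains (5, 1) components with 500 restarts on the promoters
that used the dominant component, with the single second-set motif
initialized from the dominant component's emissions and the five first-set
components initialized randomly per restart.

### Evaluating recovery

A discovered motif is defined only up to a small register shift (the model
may anchor one or two flanking background bases). Recovery on planted data
is therefore measured register-corrected: the planted hexamer is located in
the learned consensus and that offset is subtracted before comparing start
positions — standard practice in motif-discovery benchmarks. At the
benchmark scale (500 windows, 100/500 restarts) the dominant −10 component
absorbs ~84 % of the motif-bearing windows; with far fewer restarts the
remainder can split over sibling components modeling shifted registers, a
known behavior of Viterbi training that more restarts suppress.

## RpoD consensus score

s35 scores the first 6 nt of the −35 model match against TTGACA with weights
(3, 1.5, 1.5, 1, 1, 1); s10 scores positions 3–8 of the −10 model match
against TATAAT with weights (1, 2, 1, 1, 1, 2) — the leading two bases of
the −10 match belong to the extended −10 "TGn" element and carry no weight.
With spacer = |m35| − 6 − |m10| (nucleotides between the −35 hexamer's 3′
end and the −10 model start),

score = s35 + s10 − |m35 − (−35.6)| − |spacer − 15.8|.

This exact formulation reproduces all 48 bundled housekeeping scores to
their printed precision. Its maximum over integer placements with perfect
hexamers is 16.4 (m35 = −36, spacer = 16), verified by brute force in the
tests. The bundled table's recomputed mean is ≈10.4 ± 3.1; a published
summary figure of 11.2 ± 2.7 for the same promoters stems from an earlier
scoring variant and is deliberately not used as a reference value.

Strength classes use strict lower and inclusive upper bounds:
strong > 6.35 ≥ medium > 3.28 ≥ weak > 0.21 ≥ none. Positional categories
compare the starts with the screening windows −39..−31 (−35) and −18..−10
(−10): both inside → in_window; only the −10 inside → sba; only the −35
inside → ba; both outside, displaced toward the same side by at most 5 bp
each and with spacer in 13..19 → nu; anything else → all_wrong, and absent
motifs → no_motif. The nu spacer band 13..19 operationalizes "correct
−35/−10 distance" so that it covers every published nu geometry; it is
configurable. Tiers: high = in_window∧(strong ∨ medium) ∨ (sba ∨ ba)∧strong;
low = in_window∧weak ∨ (sba ∨ ba ∨ nu)∧medium; none otherwise (strong∧nu
cannot arise from the formula — the displacement penalties that define nu
already push the score below the strong cutoff — but the table is total).

## Gene linkage and responsibility

Each TSS links to the nearest same-strand, same-replicon gene 5′ end at a
non-negative distance up to 5 000 bp (default; observed regulatory distances
reach several kb), ties to the smaller locus tag. A promoter is called
responsible for (or contributing to) a gene's transcript level when its TSS
score lies within a factor of three of the gene's NPKM, the empirical
genome-wide spread between the two quantities. The ratio
log₁₀(NPKM)/log₁₀(score) is reported only when both values exceed 1, since
the ratio changes sign and meaning below that.

## Synthetic data

The generator produces what the pipeline assumes and nothing more: a random
genome at GC 0.635 (high-GC betaproteobacterial background), promoters
planted at TSSs at least 250 bp apart, an enriched library with
Poisson-distributed reads per TSS (per-promoter means lognormal around 500)
jittered by a rounded Gaussian (σ = 1 bp, matching the ±1 bp positional
accuracy of TSS determination, truncated at ±5 bp so clustering can always
re-center), uniform processed-end background at 0.05 reads/bp/strand, and a
control library capturing true starts 100× less efficiently. The library
size used for RRS normalization (10⁷) is configured independently of the
window's reads — the replicon is a window of a larger genome — so the RRS ≥ 5
cutoff removes single background reads exactly as it does in real libraries.

Promoter geometry mirrors the observed statistics with the correct
dependency structure: the −10 model position (−13.7 ± 0.9) and the spacer
(15.8 ± 1.4) are drawn, and the −35 position is derived, which reproduces
its observed ±1.6 spread. Consensus hexamers are mutated per position at
0.35 (−35) and 0.15 (−10), calibrated to the per-position consensus identity
of the bundled housekeeping table. Ground truth records the planted
(post-mutation) hexamers and their TSS-relative starts, so planted RpoD
scores are computable analytically.

What the generator does not emulate: RNA degradation kinetics, sequencing
error, transcription-unit structure (background is uniform genome-wide
rather than confined to transcribed spans), promoter classes of other sigma
factors, and operon context. Passing tests therefore demonstrate correctness
of the algorithms under the stated statistical assumptions, not performance
on real libraries.

## Problem sizes and numerical choices

The validation suite runs the TSS benchmark on a 50-kb replicon with 100
planted promoters and three replicates, and motif discovery on 500 windows
with the full 100/500-restart protocol — sizes at which the benchmarks are
stable while the whole suite stays fast. Emission/transition probabilities
are validated to sum to 1 within 1e−9; score-decomposition identities hold
to 1e−9; clustering and decoding are exactly deterministic (fixed
tie-breaks), and all randomness flows through explicit integer seeds.
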