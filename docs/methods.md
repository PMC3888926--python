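# Methods

## Model summary

The simulator implements a six-area network of graded-response
(firing-rate) units. Each area is a pair of superimposed 25 × 25 grids:
excitatory cells modelling pyramidal-cell clusters and, underneath each,
one inhibitory cell modelling the local interneuron pool. The state of a
cell is its membrane potential `V`, integrating the net synaptic input
(EPSPs positive, IPSPs negative, plus a constant baseline `Vb`) and
uniform white noise on [−0.5, 0.5] scaled by `k2`, with leak time
constant `tau` and explicit Euler steps of `dt = 0.5`. All cells update
synchronously from the previous step's outputs; the update order within
a step is: outputs → net inputs → plasticity → noise → integration of
`V`, the adaptation average `omega`, and the area accumulator `omegaS`.
The paper-level description does not fix an intra-step order; the
synchronous contract was chosen because it makes trajectories
independent of cell enumeration and bit-reproducible.

Excitatory output is `clip(V − alpha·omega, 0, 1)`: `omega` low-pass
filters the cell's own output with time constant `tauA`, so sustained
firing raises the threshold (`phi = alpha·omega`) — spike-frequency
adaptation at the population level. Inhibitory output is `max(V, 0)`,
deliberately unclipped above. Each excitatory cell also receives
`−kS·omegaS` where `omegaS` tracks the area's total excitatory output
with time constant `tauS` (area-global competition). Noise is drawn
independently per cell and step for excitatory and inhibitory cells
alike, from one seeded generator per simulator; whether inhibitory cells
also receive `Vb` is a config flag (default on, since the membrane
equation is stated generically for every cell).

## Connectivity

Projections are sampled once at build time. A source cell at grid
position (i, j) may reach targets inside an `n × n` square centred on
(i, j) in the target grid (`n = 19` for excitatory→excitatory, `n = 5`
for excitatory→inhibitory), with acceptance probability
`p0 · exp(−d²/2σ²)` at grid distance `d` and σ defaulting to `n/4`.
Neighbourhoods are clipped at area borders (no toroidal wrap), so edge
cells have fewer afferents; self-links are excluded within an area. Each
inhibitory cell pools local excitatory output and inhibits only the
excitatory cell at its own position, with fixed gain `w_ie` (the
excitatory→inhibitory weights are scaled by `g_ei`). Between-area
projections exist for chain neighbours plus the four jumping pairs
(full variant) and are sampled independently per direction — reciprocity
holds at area level, not per cell pair. Initial weights are uniform on
]0, 0.1].

## Plasticity

The two-level LTP/LTD rule acts on every excitatory→excitatory link,
within- and between-area, during training only; probe and spontaneous
phases freeze the weights so the CA definition stays fixed. The
postsynaptic variable is the membrane potential, as the rule is written,
not the output. Weights are clipped to `[0, w_max]`: the rule itself is
unbounded, and the ceiling is what lets strongly associated links
saturate into a stable assembly while heterosynaptic LTD prunes
uncorrelated links toward zero.

## Training, probe, and analysis pipeline

Training presents each sensorimotor pattern pair (20 cells in P1, 20 in
M1; overlap: a small fixed block shared with each ring-neighbouring
pattern) 15 000 times in globally shuffled order, driving the pattern
cells with a strong additive input (default 10, saturating their output
within 2–3 steps) for 16 steps, followed by a uniform random
inter-stimulus interval. After training, the probe presents each pattern
to the rested network and averages every excitatory cell's output over
15 steps starting one step after stimulus onset (the stated 15-step
window versus the 16-step stimulus is ambiguous by one step; the window
offset is configurable), over 12 repetitions with noise on. CA
membership per pattern and area uses the threshold γ times the area's
maximal average response (γ = 0.50); the same per-area threshold serves
as the per-step firing criterion during the spontaneous phase. A CA is
active when at least 50 % of its members (pooled over all six areas)
fire above threshold; maximal runs of active steps are ignition events
(no gap-merging by default). ASI traces are means over 40-step trials
aligned 10 steps before onset; normalized traces divide by the per-area
CA size. The critical window starts at the last pre-onset step of the
CA's averaged trace at which all areas are exactly at zero — computed
per CA, since trials of the same CA share dynamics while different CAs
need not be synchronous; CAs with no such baseline step (continuously
flickering recordings) are excluded from the window analysis.

The per-step statistics are two-way fully-within repeated-measures
ANOVAs (centrality: primary/secondary/central × frontality:
posterior/anterior) with the CA as subject, each effect tested against
its own effect-by-subject interaction. Planned comparisons (each
centrality level against the zero baseline; central vs secondary;
secondary vs primary) are computed from per-subject contrast scores and
reported as F(1, n−1): with 11 CAs this yields the F(1, 10) form the
design implies, which is why contrast-score error is used rather than a
pooled error term (df ≈ 50). No sphericity correction or
multiple-testing adjustment is applied, matching the planned-comparison
logic; significance is p < 0.05.

## Parameter calibration

The cellular constants are not uniquely determined by the model's
structural description, and the package therefore exposes every one of
them in the configuration. The shipped defaults were calibrated with
`scripts/calibrate.py` at the reduced scale against four joint
requirements: (i) training must grow CAs spanning all six areas with
more member cells in central than secondary than primary areas; (ii)
trained CAs must be bistable — a rested network must show zero events
without noise, yet tens of noise-triggered ignition episodes per
4000-step recording; (iii) each episode must self-terminate within a few
tens of steps through adaptation plus global inhibition; (iv) the
ignition cascade must propagate outwards from the central areas. The
main tensions are: the LTP threshold `theta_plus` must sit low enough
(≈ 1σ of the noise-driven potential) for feed-forward bootstrap onto
initially weak links, yet high enough that heterosynaptic LTD prunes
noise-only coincidences; the weight ceiling sets the reverberation loop
gain and must clear the ignition threshold while `alpha` (strong) and
`tauA` (slow) guarantee termination regardless of loop gain; and the
global-inhibition gain `kS` sets both the tonic excitability floor and
the termination margin, so it scales inversely with area size (0.22 at
12 × 12, 0.05 at 25 × 25). Calibrated values: `tau 2.5, k1 1, k2 0.6,
Vb 0.02, alpha 5, tauA 25, tauS 7.5`, `delta_w 0.00167, theta_pre 0.05,
theta_plus 0.05, theta_minus 0.025, w_max 0.5`, `g_ei 1.5, w_ie 1`,
`p0_within 0.35, p0_between 0.8` (reduced scale), `kS 0.24`.

Spontaneous recordings begin only after a settling period (default 300
unrecorded steps): starting the integration from the artificial all-zero
state delivers the baseline input to every cell simultaneously — a
coherent kick that can ignite assemblies once in a perfectly
deterministic network and that a continuously running cortex never
experiences. Recording the settled network makes the noise-free control
cleanly silent and the noise-driven statistics stationary.

## Reduced-scale preset

The default acceptance configuration scales the model down to run in
about two minutes per seed on one CPU: 12 × 12 areas, 6 patterns of 10
cells, 1000 presentations per pattern, a 4000-step spontaneous
recording, neighbourhoods 9/3, ISIs uniform on [15, 40] and 8 probe
repetitions. The degree ratios (4 : 3 : 2, serial 2 : 2 : 1), the
pattern-to-area coverage order of magnitude, and the qualitative
bistable dynamics are preserved.

What the reduced synthetic conditions do *not* preserve is statistical
power and cascade resolution: with 6 CAs (subjects) and typically 4–12
usable trials per CA, the per-step planned contrasts of the critical
window are far weaker than in an 11-CA, ~18-trials-per-CA design, and
the first post-baseline step of a trial-averaged trace is carried by
single-cell flickers whose area is not always consistent across CAs. In
the smaller network the ignition sweep also crosses areas faster
relative to the analysis step, compressing the onset spacing. As a
result, single realizations scatter: across seeds, the majority-vote
first-significant step is 1 for the central areas, with secondary areas
reaching significance in the same or the following step and primary
areas consistently last — the outward cascade is reproduced, but the
exact one-step spacing (1, 2, 3) of the reference-scale analysis is not
reliably resolved at this scale. Event counts also vary by seed because
the trained attractor strength feeds back on the ignition rate;
realizations whose recording never settles to an all-quiet baseline are
excluded from the window analysis by construction.

## Numerical and degenerate-input choices

Euler stability requires `dt ≤ tau` (enforced). Membership thresholds
of an all-zero probe profile would classify every cell as a member at
threshold 0; such patterns are instead flagged empty with no members.
ANOVA and contrast computations guard exactly-degenerate designs (zero
error variance) with a scale-aware epsilon instead of dividing rounding
dust. Events whose 40-step window overruns the recording are dropped;
CAs with no usable trial are excluded (only CAs that ignited at least
once enter the analysis). Ignition detection uses ≥ on both the firing
threshold and the 50 % criterion (boundary inclusive). All randomness
derives from one master seed per experiment through independent child
streams (network, patterns, schedule, training noise, probe noise,
recording noise), making event tables and statistics bit-reproducible.

## Limitations

Cells are graded-rate cluster models: no spiking, conductances, or
axonal delays, and the six-area chain abstracts the anatomy rather than
mapping an atlas. The full-scale defaults inherit the reduced-scale
calibration (with `kS` rescaled); the full 25 × 25 / 15 000-presentation
configuration is provided but its defaults have not been separately
tuned. Overlapping patterns can ignite jointly; detection treats each CA
independently and does not arbitrate simultaneous ignitions.
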