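# hebbca

Simulation and analysis of **spontaneous cell-assembly ignition** in a
six-area model of fronto-temporal (perception–action) cortex.

`hebbca` builds a rate-based network of six reciprocally connected
cortical areas — primary sensory (P1), secondary/"higher" sensory (HP),
central association (PA, PF), secondary motor (PM) and primary motor
(M1) — trains it with a discretised Hebbian LTP/LTD rule on paired
sensorimotor patterns, and analyses how the resulting distributed cell
assemblies (CAs) later ignite *spontaneously*, driven by nothing but each
cell's intrinsic noise. The scientific question the pipeline addresses is
*where* in the cortical hierarchy the first traces of such self-generated
activity appear: the model predicts that ignition starts in the central
association areas and cascades outwards to secondary and then primary
areas — the topography of readiness-potential-like activity preceding
self-initiated action.

## Model

Each area holds a 25 × 25 grid of excitatory cells, each paired with an
inhibitory cell at the same position. Every cell is a leaky integrator

    τ · dV(x,t)/dt = −V(x,t) + k₁ · (V_In(x,t) + k₂ · η(x,t)),

with η uniform white noise on [−0.5, 0.5], integrated by an explicit
Euler scheme with Δt = 0.5. Excitatory output is a piecewise-linear
sigmoid of V clipped to [0, 1] above an adaptive threshold
φ = α · ω(x,t), where ω low-pass filters the cell's own output (neuronal
adaptation); inhibitory output is max(V, 0). Each area additionally
subtracts a global-inhibition term k_S · ω_S from its excitatory cells,
with ω_S tracking the area's summed excitatory output. Excitatory
projections (within- and between-area) are sparse, patchy and
topographic: a Gaussian fall-off of connection probability clipped
outside a 19 × 19 (excitatory) or 5 × 5 (inhibitory) neighbourhood, with
weights initialised uniformly in ]0, 0.1]. Between-area links follow the
known anatomy: a chain P1–HP–PA–PF–PM–M1 plus reciprocal "jumping" links
(P1–PA, HP–PF, PA–PM, PF–M1), giving 4 : 3 : 2 partners for central :
secondary : primary areas (2 : 2 : 1 in the serial variant without
jumping links).

Excitatory synapses follow a two-level Artola–Bröcher–Singer rule: with
presynaptic output O(x,t) and postsynaptic potential V(y,t),

    w += Δw   if O ≥ θ_pre and V ≥ θ₊            (LTP)
    w −= Δw   if O ≥ θ_pre and θ₋ ≤ V < θ₊       (homosynaptic LTD)
    w −= Δw   if O < θ_pre and V ≥ θ₊            (heterosynaptic LTD)

with weights clipped to [0, w_max]. Training presents 12 sensorimotor
pattern pairs (20 cells in P1 + 20 in M1, partially overlapping) 15 000
times each in random order; CA membership is then defined per pattern w
and area A by the threshold θ_w(A) = γ · max over A of the time-averaged
probe response (γ = 0.50). A CA is *active* when ≥ 50 % of its member
cells fire above θ; event-aligned 40-step trials averaged per CA give the
**average spontaneous ignition** (ASI), whose normalized per-area traces
enter per-time-step two-way repeated-measures ANOVAs (centrality ×
frontality) with planned comparisons.

## Worked example

The reduced-scale preset (12 × 12 areas, 6 patterns of 10 cells, 1000
presentations per pattern, 4000-step spontaneous recording) runs end to
end in about two minutes:

```python
from hebbca import reduced_preset, run_experiment

rec = run_experiment(reduced_preset("full", seed=4))
print(rec.n_events, "events across", rec.n_igniting_cas, "CAs")
print(rec.mean_ca_size_per_area().round(1))
print(rec.onsets)
```

prints (seed 4):

```
60 events across 6 CAs
P1    11.8
HP    15.8
PA    19.5
PF    23.5
PM    20.3
M1    16.8
{'primary': 2, 'secondary': 2, 'central': 2}
```

i.e. 60 spontaneous ignition episodes in 4000 noise-driven steps, with
CA cells concentrated in the central areas (PA, PF) and sparsest in the
primary ones (P1, M1). The onsets dict gives the first critical-window
step at which each centrality level is significantly above baseline; a
single reduced-scale realization is noisy (here all three levels reach
significance at step 2), so the onset cascade is assessed by majority
vote over several seeds (see below), where central areas lead and
primary areas trail. The same pipeline is available from the shell:

```bash
hebbca run --variant full --scale reduced --seed 4 --outdir out/
hebbca run --variant no_jumping --scale reduced --seed 4 --outdir out_serial/
```

with stage-wise subcommands (`build`, `train`, `record`, `analyze`,
`stats`, `report`) operating on the same run directory.

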