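# locustolf

A model of odor coding in the locust olfactory system, from parametric
odor input to mushroom-body output neurons (MBONs), built to study one
question: **is there an optimal degree of Kenyon-cell (KC) sparseness for
separating similar odors, and does synaptic plasticity destroy it?**

The pipeline mirrors the biology:

1. **Antennal lobe** (`locustolf.al_network`) — 350 projection neurons
   (PNs) and 100 inhibitory local neurons (LNs) with Hodgkin-Huxley-style
   conductances, fast GABAergic and nicotinic synapses.  An odor is a
   Gaussian profile of input amplitudes over the neuron index (peak =
   identity, width σ = concentration; `locustolf.stimulus`).  The driven
   network produces the locust's hallmark ~20 Hz local field potential
   (LFP, the mean PN membrane potential).
2. **Phase gating** (`locustolf.lfp_gating`) — the LFP is filtered at
   40 Hz and its Hilbert phase segments the trial into oscillation
   cycles.  PN spikes later than a threshold phase φ in each cycle are
   deleted.  φ is the *window of integration*: a controllable stand-in
   for the feedback inhibition (giant GABAergic neuron) that enforces KC
   sparseness in vivo.
3. **Mushroom body** (`locustolf.mb_network`) — 15,000 KCs and 100 MBONs
   as two-variable map neurons (fast spiking variable + slow
   excitability variable), cheap enough to simulate at scale.  KC
   responses are sparse and grow with φ and σ.
4. **Plasticity** (`locustolf.plasticity`) — trace-based STDP with soft
   bounds at the KC→MBON synapse: potentiation `Δw = (W_max − w) η₊ x`
   on a postsynaptic spike, depression `Δw = −w η₋ y` on a presynaptic
   spike, so depression dominates near `W_max` and potentiation near 0.
5. **Analysis** (`locustolf.coding_analysis`) — MBON spikes binarised
   per LFP cycle into MBON × cycle 0/1 patterns; the Hamming distance
   between patterns (= squared Euclidean distance on binary vectors)
   measures odor separation.  Sweeping φ gives distance-vs-φ curves
   whose argmax φ* is the optimal integration window; MDS + a linear
   discriminant classify single trials.

The model's headline behaviours: the distance between two similar odors
has an interior maximum in φ at high concentration, φ* shifts to lower
values as concentration (or the uniform KC→MBON weight) increases, and
after STDP training the median synaptic weight converges to the same
value from above and below while φ* stays put and the peak distance
grows.

## Worked example

```python
import numpy as np
from locustolf.al_network import build_al_network
from locustolf.coding_analysis import distance_vs_phi
from locustolf.experiments import ExperimentConfig, prepare_trial, _child_seeds
from locustolf.lfp_gating import dominant_frequency
from locustolf.mb_network import build_mb_connectivity

cfg = ExperimentConfig.preset("ci")          # 100 PN / 30 LN / 1500 KC / 20 MBON
net = build_al_network(cfg.al_config(), seed=101)
conn = build_mb_connectivity(cfg.n_pn, cfg.n_kc, cfg.n_mbon, seed=202)

curves = {}
for sigma in (0.2, 0.35):
    trials = {}
    for name, shift in (("A", 0.0), ("B", 5.0)):    # similar pair: peak shift 5
        odor = cfg.odor(sigma, shift, label=name)
        seeds = _child_seeds(55, 2, salt=int(sigma * 1000) + int(shift))
        trials[name] = [prepare_trial(net, odor, cfg, s) for s in seeds]
    curves[sigma] = distance_vs_phi(
        trials["A"], trials["B"], conn, cfg.phi_grid, sigma=sigma
    )
    print(sigma, np.round(curves[sigma].distances, 1), round(curves[sigma].phi_star, 2))

tr = trials["A"][0]
print("LFP peak:", round(dominant_frequency(tr.lfp, window=(260, 660))[0], 1), "Hz")
```

prints

```
0.2 [  0.    0.    0.   54.  103.2 101.2  97.8  95.5] 3.93
0.35 [ 0.  0.  0. 59.  0.  0.  0.  0.] 3.14
LFP peak: 20.5 Hz
```

Read: the φ grid spans π/4 … 2π.  At low concentration (σ = 0.2) the
inter-odor Hamming distance keeps rising until late windows and peaks at
φ* ≈ 3.9; at high concentration (σ = 0.35) the distance peaks at the
smaller φ* = π and collapses beyond it — wider windows drive so many KC
spikes that every MBON fires in every cycle and the two odors' patterns
saturate into identity.  That is the optimal-sparseness effect: more
concentrated odors need earlier feedback inhibition.

The same experiments run from the shell:

```
locustolf al-demo  --out out/demo  --seed 1 --scale ci
locustolf phi-sweep --out out/sweep --seed 1 --scale ci
locustolf stdp-run  --out out/stdp  --seed 1 --scale ci
```

each writing CSV/JSON artifacts plus a manifest; identical config + seed
reproduce the artifacts byte for byte.

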