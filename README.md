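# soundflow

Directed acoustic-information flow between soundscape monitoring sites.

Passive acoustic monitoring describes a park with eco-acoustic indices —
scalar summaries (acoustic entropy H, acoustic complexity ACI, bioacoustic
index BI, NDSI, …) of each 1-min recording. Those indices are static: they
say how a site sounds, not whether the acoustic activity at one site
carries information about what a neighboring site records next, or in which
direction that information travels. `soundflow` adds that directed layer
for soundscape ecologists working with multi-sensor deployments in parks
and other green areas where birdsong and road-traffic noise compete.

## Method

For every ordered pair of sites, the pipeline estimates the **Shannon
transfer entropy** of their discretized index series (Markov orders
m = n = 1, plug-in estimator, bits):

    STE(X→Y) = Σ p(y_{t+1}, y_t, x_t) · log₂ [ p(y_{t+1}|y_t, x_t) / p(y_{t+1}|y_t) ]

together with the **Rényi transfer entropy** (escort distribution
φ_q = p^q/Σp^q; q = 0.1 and 0.5), which emphasizes rare, tail events such
as dawn-chorus bursts. Each pair is reduced to the net flow
DTEM = TE(X→Y) − TE(Y→X); arrows above the 75th/95th percentile of the
pooled oriented values form a directed flow network summarized by

* per-site emission/reception totals (biophonic "hot"/"cold" sites),
* arrow density per site group (interior vs road-side) or per period
  (dawn/day/night),
* the normalized distance index d_n = (1/n̄)·Σ dᵢ/d_max, the spatial scale
  of the interconnections.

Upstream, the package computes the eight standard eco-acoustic indices
from WAV audio, selects representative indices by PCA (explained-variance
fractions, per-index contributions), and — because the original recordings
are not public — generates synthetic multi-site soundscapes with known
ground truth: dawn-peaking biophony shared across sites with interior
sites leading exterior ones by a configurable lag, and road noise decaying
with distance from a road line. See `docs/methods.md` for the full model
description and design decisions.

## Worked example

The numbered scripts under `analysis/` run the two campaign-style analyses
end to end (synthetic data → indices → PCA → TE → networks → survey
validation), writing tables under `results/`:

```
$ python analysis/01_simulate_soundscapes.py
urban: 16 usable sites, 210 windows/site, protocol=continuous
river: 8 usable sites, 3360 windows/site, protocol=duty_cycle

$ python analysis/02_pca_representatives.py
urban: EV per dimension = (60.8, 30.9, 4.7, 2.1, 0.8, 0.5, 0.2, 0.0)%
urban: first two dimensions carry 91.7% of the variance; representatives:
Dim1=ACI (19%, top_contribution), Dim2=BI (1%, manual)
...

$ python analysis/03_transfer_entropy.py
urban/ACI: mean STE 0.0556 bits; hot (net-emitting) sites: [17, 18, 19, 20, 22]
river/BI: mean STE 0.0266 bits; hot (net-emitting) sites: [1, 2, 3, 4, 6]
...

$ python analysis/04_flow_networks.py
urban_ACI_shannon: 6 arrows, density by group {'external': 0.0, 'internal': 1.2}
river_BI_shannon: 2 arrows, density by group {'internal': 0.4, 'external': 0.0}
  arrows by period: {'dawn': 5, 'day': 0, 'night': 0}
...
```

Reading the output: in both synthetic parks the net-emitting ("hot") sites
are exactly the interior sites where the generator plants the leading
dawn-chorus signal — the road-side sites only receive. The flow networks
tell the same story: every above-threshold arrow originates at an interior
site (internal density 1.2 arrows/site vs 0.0 external), and in the
duty-cycle park the arrows concentrate in the dawn period (5 dawn vs 0 day
and 0 night), when the chorus is active and couplings are strongest.

The same machinery is available as a library:

```python
from soundflow import transfer_entropy as te
from soundflow.synthetic import CouplingSpec, gen_coupled_pair

x, y = gen_coupled_pair(CouplingSpec(coupling_strength=0.8, lag=1, seed=0))
sx, sy = te.discretize(x), te.discretize(y)
print(te.shannon_te(sx, sy).value, te.shannon_te(sy, sx).value)
# 0.09551... 0.00336...   -> information flows X→Y, as constructed
```

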