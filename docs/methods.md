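# Methods

## Problem and approach

Eco-acoustic indices summarize what a soundscape sounds like at one place
and time, but they are static and non-directional: they cannot say whether
the acoustic activity recorded at one monitoring site carries information
about what another site will record next. `soundflow` implements a directed
complement: all-pairs transfer entropy between per-site index time series,
reduced to flow networks whose arrow density and spatial scale summarize
acoustic connectivity across a park.

The pipeline is: (1) eight eco-acoustic indices per 1-min recording window
per site; (2) PCA over the pooled (site, window) observations to find how
many independent axes the indices span and to pick one representative index
per retained axis; (3) plug-in Shannon and Rényi transfer entropy between
every ordered site pair of the representative-index series; (4) net-flow
orientation, percentile thresholding, and network summaries (emission
profiles, arrow density per site group or period, normalized distance
index).

## Transfer entropy

For discretized series with symbols `x_t`, `y_t` and Markov orders
`m = n = 1` (the defaults throughout), the Shannon transfer entropy in bits
is the Kullback–Leibler departure of the target's transitions from its own
Markov model:

    STE(X→Y) = Σ p(y_{t+1}, y_t, x_t) · log2 [ p(y_{t+1}|y_t, x_t) / p(y_{t+1}|y_t) ]

estimated by plugging in empirical transition counts. `STE(X→X) = 0`
*exactly* in this implementation: the log ratio is computed as a ratio of
count products, which is the float `1.0` whenever source and target
coincide. Plug-in STE is a conditional mutual information of empirical
distributions and therefore never negative.

The Rényi variant reweights conditioning contexts with the escort
distribution `φ_q(j) = p(j)^q / Σ p(j)^q`:

    RTE(X→Y) = 1/(1−q) · log2 [ Σ φ_q(y_t) p(y_{t+1}|y_t)^q / Σ φ_q(y_t,x_t) p(y_{t+1}|y_t,x_t)^q ]

`q < 1` emphasizes rare (tail) transitions, `q > 1` frequent ones; the
analysis defaults are `q = 0.1` and `q = 0.5`. RTE converges to STE as
`q → 1` (checked to < 1e-3 at `q = 0.999`) and may legitimately be
negative; it is never clipped. Zero-count contexts contribute nothing and
escort normalization runs over observed contexts only.

### Discretization

The series are symbolized by per-series quantile edges, default the 5th and
95th percentiles — three symbols separating the lower tail, bulk and upper
tail. Tail coding suits series whose information-bearing events are
episodic (dawn-chorus bursts); it makes the symbol sequence invariant under
strictly increasing transforms of the values (values landing exactly on an
edge go to the lower bin), so any monotone re-expression of an index gives
identical TE. The boundaries are configurable and recorded in outputs. The
choice of three tail-coded symbols is this package's own default; the
analyses it reproduces never published their binning. One caveat observed
on ground-truth simulations: for coupled logistic maps, whose invariant
density peaks at the interval edges, equiprobable terciles recover the
coupling direction far more reliably than tail bins, and strong coupling
(≥ 0.6) synchronizes the maps making direction unidentifiable; the
benchmarks document both regimes.

### Contiguity blocks

Transitions are only counted between windows that are truly adjacent under
the recording protocol. Duty-cycle recordings count successive retained
windows (6 min apart) as adjacent; period splits (dawn/day/night) cut a
block at every boundary, so a dawn-to-day step never forms a transition;
missing values split blocks too. No bias correction is applied — reported
TE is the raw plug-in value — and a block-respecting shuffle null
(`shuffle_null`) is available as an opt-in diagnostic.

## Flow networks

Each unordered pair is reduced to `DTEM = TE(X→Y) − TE(Y→X)`; the arrow
points toward the larger value and an exact tie draws no arrow (logged).
Arrows survive if their oriented DTEM strictly exceeds a percentile cutoff
(75th or 95th) of the pooled oriented values of one (index, estimator, q)
configuration. When periods are compared, all period networks share a
cutoff pooled across periods — with per-period pools every period would
keep ~5% of its pairs by construction and period comparisons would be
meaningless; with a shared pool, a period with systematically stronger net
flows (dawn) keeps more arrows.

Summaries:

* **Emission profile** — `emitted(X) = Σ_Y TE(X→Y)` (row sums),
  `received(X) = Σ_Y TE(Y→X)` (column sums); sites with positive net are
  biophonic "hot" (net-emitting) sites. Every pair contributes symmetrically,
  so total net flow is identically zero — computed with exact (`fsum`)
  summation this is a machine-exact zero, used as a self-check.
* **Arrow density** — arrows attributed to a site group divided by group
  size. Attribution is **by source site** (an arrow represents information
  emitted); this is a package convention, the alternative (by target or
  either endpoint) was not published.
* **NDI** — `d_n = (1/n̄) Σ d_i / d_max`, the mean arrow length over a
  normalizing distance. Two readings of `d_max` are offered:
  `"arrows"` (default; longest drawn arrow — the literal reading, giving
  `d_n = 1` for a single-arrow network) and `"all_pairs"` (site diameter).
  Cross-period comparisons use `"all_pairs"`: the literal reading saturates
  at 1.0 for near-empty networks, so a quiet period with one random arrow
  would spuriously "span more space" than a dense dawn network.

Periods are half-open local-time intervals: dawn [05:00, 08:00),
day [08:00, 18:00), night [18:00, 05:00) wrapping midnight.

## Eco-acoustic indices

Computed from a short-time magnitude spectrogram: 512-sample FFT, Hann
window, zero overlap, magnitudes scaled by `2/Σw` so a full-scale sine
peaks at 0 dBFS (BI's and ADI's dB values depend on this reference; it is
stated here for that reason). Bands are half-open `[lo, hi)` on bin-center
frequencies. Defaults follow the reference implementations commonly used in
the field, all configurable:

| index | definition | default parameters |
|---|---|---|
| H | temporal entropy of the Hilbert envelope × spectral entropy of the mean spectrum, each normalized by log-cardinality | — |
| ACI | Σ over bins and clumps of Σ_t\|ΔI\|/Σ_t I | 5 s clumps |
| ADI | natural-log Shannon entropy of per-band occupancy above threshold | 1 kHz bands, 0–10 kHz, −50 dBFS |
| AEI | Gini coefficient of the same occupancy vector | as ADI |
| NDSI | (B−A)/(B+A), band powers | anthrophony 1–2 kHz, biophony 2–8 kHz |
| BI | area under max-referenced mean dB spectrum in-band minus in-band minimum, trapezoid over kHz | 2–8 kHz, −60 dB floor |
| DSC | time-average of per-frame magnitude-weighted spectral centroid | — |
| ZCR | sign changes / (N−1) | — |

Design notes: the Hann window was chosen over Hamming because its fast
sidelobe rolloff keeps a pure tone's centroid within one bin and keeps
leakage out of BI's band; BI additionally caps dynamic range at −60 dB so
leakage wiggles below any real signal cannot register as in-band area (an
out-of-band tone then scores exactly 0). DSC's source definition is not
fully specified in the literature this follows; the per-frame
magnitude-weighted centroid averaged over frames is this package's
documented reading. Whether the original analyses band-limited ACI/ADI
above 10 kHz is unknown; the defaults above are declared, not attributed.

Silence handling: H, NDSI, ADI, AEI and DSC are undefined on silent input
and return NaN (never a numeric 0); BI returns 0 by convention; missing
values propagate flagged and split TE contiguity blocks. There is no
microphone frequency-response correction layer.

## PCA and representatives

Observations are pooled (site, window) rows — one PCA per study area, not
per site. Columns are standardized (sample sd, incomplete rows dropped and
counted; constant columns rejected by name). Explained-variance fractions
`V_i` sum to 1; the contribution of index j to dimension i is the
squared-loading share in percent. Loading signs are fixed so the
largest-magnitude entry of each vector is positive, making results
deterministic. Retention defaults to the top two dimensions (a
`threshold` policy keeping `V_i` above a fraction of the mean variance is
available). Representatives default to the top contributor per dimension
(ties broken by the canonical order H, ACI, ADI, AEI, NDSI, BI, DSC, ZCR);
a manual override exists because interpretability can trump a few
contribution points — the shipped analysis overrides Dim 2 to BI, which
reads directly as biophony level, the quantity the flow networks trace.

## Synthetic soundscapes

No recordings from the original campaigns are public, so the generator
produces inputs with the statistical structure the analysis assumes. The
defaults are the study conditions: a continuous 3.5 h session of 1-min
windows (210 per site) for the urban-park layout (22 sites, 6 faulty,
road along the north edge), and a 14-day 1-min-on/5-min-pause duty cycle
(3360 windows per site) for the river-park layout (9 sites, 1 offline,
highway to the east). Site coordinates are synthetic — only counts, group
membership and the road side matter.

* **Biophony**: a shared latent chorus activity — a circadian bump centered
  at 06:30 (width 1 h) modulated by a smooth AR(1) process (φ = 0.85) —
  reaches interior sites immediately and exterior sites `inter_site_lag`
  windows (default 1) later, so information flows interior → exterior by
  construction. Road noise masks audible birdsong via a per-site monotone
  damping `1/(1 + 0.5·amp·atten)`; being monotone it changes survey label
  fractions but not the symbolized dynamics.
* **Traffic**: road-line distance attenuation `(d/100 m)^(−decay)`,
  decay exponent 1 (geometric-spreading surrogate), times a
  daytime-weighted diurnal profile with substantial multiplicative noise.
  Coupling magnitudes between real sites were never published; these are
  calibration choices fixed once, not field values.
* **Indices (fast path)**: smooth saturating functions of the two drivers
  plus Gaussian noise, with the response directions the indices show on
  real audio (BI grows with biophony and high-frequency traffic leakage,
  NDSI contrasts the bands, H tracks spectral mixing…).
* **Audio path**: Poisson-arriving FM chirps confined to 2–8 kHz at rate
  2·B/s plus low-passed (< 2 kHz) noise with RMS ∝ T; zero drivers give
  exact silence; peak never exceeds full scale. The generator is
  statistical, not physical — no propagation, diffraction, or
  species-realistic song.
* **Coupled-pair benchmarks**: a linear VAR (`x_t = 0.5x_{t−1} + ε`,
  `y_t = a·x_{t−lag} + ε`) and coupled logistic maps
  (`y_{t+1} = f(a·x_{t+1−lag} + (1−a)y_t)`, `f(u) = 4u(1−u)`), both with
  known direction, strength and lag. Both forms ship because the
  estimator's selling point is model-freeness.

All randomness flows from one integer seed through spawned child
generators; identical spec + seed reproduces outputs at bit level.

What passing tests on this generator do **not** show: real recorders have
heterogeneous frequency responses, real biophony is not a single shared
latent process, and real traffic is not a stationary diurnal profile.
The qualitative-structure tests (dawn arrow density > night, interior
density > road-side density, in the majority of 20 seeds) validate that the
pipeline recovers planted structure, not that any particular park behaves
this way.

## Numerical choices

* Base-2 logarithms throughout; TE in bits.
* Self-TE and total-net-flow checks are machine-exact (count-product
  ratios; `fsum` over antisymmetric entries).
* Strict inequality at percentile thresholds (all-equal pools keep zero
  arrows); percentiles use linear interpolation.
* Degenerate discretizations (fewer distinct values than bins) are rejected
  by default or merged to a coarser alphabet on request; series with fewer
  than 20 finite values are rejected; a small-sample warning fires when
  transitions < alphabet^(m+n+1).
* PCA sign fixing and mergesort-stable row ordering make every artifact
  byte-reproducible for a fixed configuration.

## Problem sizes

The shipped analyses and tests run at the study scale (210- and
3360-window series; 16 and 8 sites): the estimator is counting-based, so
an all-pairs matrix costs well under a second. The multi-seed structure
sweep uses 20 seeds of the full river-park configuration.

## Known limitations

Bivariate TE only — no multivariate/conditional correction for common
drivers, so shared diurnal forcing can create spurious symmetric links
(the net-flow orientation cancels much, not all, of this). No kernel or
k-NN continuous estimators; no Granger causality; no significance test on
individual arrows; no map rendering beyond abstract coordinate plots.
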