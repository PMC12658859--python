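# Methods

This note documents the models implemented in `scquant`, the defaults and
their rationale, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter for reproducibility.  No empirical
claim is made here beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Per-cell mass model

Both instrument branches quantify through the same relation,

m_c = η · F · t · I / b,

with all unit handling centralised in `scquant.units` (flow canonicalised to
L/s, concentrations to g/L, masses reported in fg = 10⁻¹⁵ g).  The two modes
differ only in what I and t mean:

- **sequential quadrupole (sc_icpms)** — at a 5 ms dwell a cell transit
  (~0.5 ms) fits inside one dwell, so I is the single-point event intensity
  and t the 5 ms dwell.
- **mass cytometry (cytof)** — at a 13 µs dwell a cell spans 10–150 points;
  I is the per-point Dual Counts summed over the event and t the 13 µs
  per-point dwell.  Summing per-point intensities while keeping the
  per-point t makes the two branches dimensionally identical, because the
  product t·I is then the same "counts × seconds of sampled flow" in both.

Physical constants: N_A = 6.02214076×10²³ mol⁻¹, M(Lu) = 174.97 g/mol, both
in `scquant.constants`.  Receptor counts assume one antibody per receptor
and a fixed metal:antibody ratio (default uncertainty ±2 around 76 is
carried as metadata, not propagated).

## Event extraction (quadrupole)

`detect_events` implements the iterative threshold: compute mean and SD of
the points not yet flagged, flag everything strictly above mean + 3·SD,
repeat until an iteration flags nothing new.  Choices fixed for
reproducibility:

- flagged points are removed from the statistics of later iterations (the
  only reading under which repetition changes anything);
- sample SD (ddof = 1); at ~36,000 points per run the population/sample
  distinction is far below any tolerance in use, but it is pinned down;
- ties at the threshold are background (strict `>`), a conservative and
  deterministic rule;
- iteration cap 100 with a `DegenerateTraceError` on reaching it;
- adjacent above-threshold dwells are separate events by default (one point
  per cell at 5 ms); `merge_adjacent=True` is available for longer transits.

A statistical property of this rule worth stating explicitly: on any
appreciable Poisson background the converged threshold sits ~3σ above the
background mean, so ~0.1–0.3% of background dwells end up flagged no matter
what λ is.  On a heavy-metal channel of washed cells the background is
essentially detector dark counts (defaults below), so these artifacts are
single-count events, orders of magnitude below real cells; `clean_artifacts`
(Tukey 1.5·IQR fences on **log** mass, the natural scale for lognormal
per-cell masses) automates the manual curation such event sets receive in
practice.  Zero-mass entries are always removed.  Dim genuine cells and
cell doublets sit well inside the fences.

For nanoparticle *counting* (transport efficiency), the measurand is the
event number, not the intensities, and the same tail artifacts would bias
the count directly; `transport_efficiency_from_trace` therefore counts
particles with the iterative threshold at 5σ, the stricter criterion common
in single-particle counting work.  The cell pipeline keeps 3σ.

## Event building and gating (mass cytometry)

`build_events` forms an event as a maximal run of contiguous dwells whose
summed trigger-channel signal is ≥ 10 Dual Counts (Dual Counts are treated
as real-valued counts).  The sum over trigger channels is the default so
that a dim antibody channel still contributes on top of the cell marker; a
per-channel mode is available.  Runs shorter than 10 or longer than 150
points are flagged `too_short` / `too_long` and leave the valid set.

`gate_events` then reproduces the clean-up intent of standard mass-cytometry
postprocessing:

- **beads** — integrated DC above a threshold (default 100 DC) in at least
  k = 3 of the bead-exclusive metals {Y, In, Ce, Tb, Bi}.  Lu is never used
  for the bead call because the antibody label shares it.
- **doublets** — a bimodal intra-event pulse shape: the per-dwell
  trigger-channel profile is smoothed with an adaptive boxcar (~1/12 of the
  event duration, odd, clipped to 3–9 points), peaks are accepted at ≥10% of
  the profile maximum in height and prominence, and the event is called a
  doublet when the valley between the two largest peaks drops below 75% of
  the smaller peak.  The 75% figure reflects that the two coincident cells
  are generally of unequal brightness: the brighter pulse's tail floors the
  valley *relative to the dimmer peak*, so a 50% criterion misses a large
  fraction of clearly two-peaked composites.  All parameters are exposed.

Events longer than 150 points (heavily overlapped multiplets) are already
excluded by the duration gate.  Measured on generator ground truth at
defaults: bead recall 1.0, doublet recall ≈ 0.97–1.0, no true cell flagged
as a bead, cell retention ≈ 1.0 (recomputed by the acceptance script).

## Calibration, transport efficiency, detection limit

- Calibration curves are ordinary least squares of mean intensity vs
  concentration (statsmodels OLS behind `fit_calibration`); the "SD of the
  y-intercept" is the OLS standard error of the intercept, the standard
  analytical-chemistry reading.  No weighted or robust variants.
- Transport efficiency: η = detected / (conc · F · duration) from a
  nanoparticle run, with an error raised when η > 1.  η measured on 30 nm
  particles is assumed transferable to dissolved standards; the assumption
  is recorded on the result object (`transferred_to_solutions`).
- Isotope correction rescales the slope by (label abundance / standards
  abundance); with natural-Lu standards (97.4% ¹⁷⁵Lu) and an isotopically
  pure label this is a 1/0.974 sensitivity increase.  The operation
  composes and inverts exactly.
- Detection limit: LOD concentration = 3·SD(intercept)/slope, converted to
  mass through the volume η·F·(min_points·dwell) sampled by a minimal event
  (min_points defaults to 10, the shortest valid CyTOF event).

## Statistical comparison

Replicate medians are compared with a two-sided pooled-variance Student's t
(Welch and paired variants by flag); full per-cell distributions with the
Mann–Whitney U — exact enumeration when both samples have ≤ 8 observations
without ties, tie-corrected continuity-corrected normal approximation
otherwise.  (The worst-case gap between the exact and approximate two-sided
p over all achievable U at n₁ = n₂ = 8 is 0.0109.)  The outlier policy for
the distribution-level test is Tukey 1.5·IQR per sample, chosen because it
is standard and parameter-free; the policy used is recorded in the report.
Cross-replicate central tendency is the mean of per-replicate medians,
robust to the right-skewed per-cell mass distributions.  Tests are two-sided
at α = 0.05 throughout; replicates are treated as unpaired by default.

## Synthetic-data generator

The generator inverts the mass equation: a lognormal per-cell mass draw
(median m̃, geometric SD) becomes an expected intensity I = m·b/(η·F·t),
realised as Poisson shot noise on top of a Poisson count background.

Defaults describe the reference study conditions and are not tuned per
experiment:

| parameter | default | rationale |
|---|---|---|
| SC flow, dwell, duration, η | 10 µL/min, 5 ms, 180 s, 0.48 | quadrupole syringe-pump setup |
| CyTOF flow, dwell, η | 30 µL/min, 13 µs, 0.15 | mass-cytometer loop injection |
| event rate (SC) | 1.7 s⁻¹ | ≈300 events per 3 min run |
| event rate (CyTOF sims) | 100–200 s⁻¹ | typical acquisition rates; duration set by the target event count (≈36,000 for a full run) |
| median Lu mass | 0.18 fg (SC) / 0.17 fg (CyTOF runs) | the per-cell label masses the two modes report |
| geometric SD | 1.6 | ~60% CV, the right-skew scale typical of surface-receptor expression |
| background (SC trace) | 10⁻³ counts/dwell | ≈0.2 cps dark counts on a clean heavy-metal channel; washed cells contribute no dissolved Lu.  A phosphorus-like channel would need a far larger value |
| background (CyTOF) | 0.02 DC/dwell/channel | near-zero inter-event baseline |
| quadrupole calibration slope | 2000 counts/(µg/L) | puts a median cell at ~900 counts/dwell |
| CyTOF slopes | Lu 2.5, Ir 25 DC/(µg/L) | put a median cell at ~430 integrated Lu DC with a bright Ir trigger, matching the DC scales such data display |
| bead signal | 3000 DC expected per bead channel, GSD 1.15 | bright six-metal beads, clearly separated from cells |
| sedimentation | exponential thinning of the arrival rate, true half-life semantics 2^(−t/t½); ∞ = stable | the decline is reported as a phenomenon without a functional form; exponential decay of the suspended concentration is the simplest mechanism |

Cell pulses in the CyTOF stream are discretised Gaussians (σ = duration/6)
of 10–150 dwells.  Doublets are a second cell at 60–80% offset of the first
pulse with comparable width, i.e. merged into one trigger run but
two-peaked.  Events are laid down sequentially with a guaranteed gap:
accidental pile-up would be indistinguishable from a deliberate doublet and
would poison the ground-truth labels.  One-dwell SC events are likewise
placed on distinct dwells.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: plasma/ionisation physics and nebuliser droplet
statistics; spectral interferences; asymmetric (tailed) pulse shapes;
instrument drift and bead-based normalisation over time; correlated
Ir/Lu content within a cell; dead time; split events at the dwell boundary
(available only as an off-by-default flag); and real biological
heterogeneity beyond a single lognormal mode.

## Validation experiments (what the acceptance script recomputes)

- desk conversions: LOD → ≈59 receptors; 800 DC through the
  (100 DC ↔ 1800 molecules) anchor → 14,400 molecules; 0.18 fg at ratio 76
  → ≈8.2×10³ receptors.  The latter two are proportionality arithmetic whose
  inputs (the anchor pair, the concentrations behind the ratio) are printed
  study values; each is reported unrounded.
- detector vs brute-force reference: exact index-level agreement on
  randomized traces.
- median-mass recovery: simulate → detect → quantify recovers the known
  median within 5% (quadrupole, ~300 events/run) and 2% (mass cytometry,
  ~36,000 events/run), averaged over seeds.
- transport-efficiency recovery at true η ∈ {0.15, 0.48} over 50 runs of
  ~2,000 introduced particles (mean within 2% relative).
- gating recall/precision against ground-truth labels.
- cross-mode structure: one population through both simulated instruments
  gives medians within 10% (quadrupole biased slightly high — it keeps the
  doublets the CyTOF gate removes) and a broader quadrupole dispersion,
  measured as (P95−P5)/median on pooled replicates.

Problem sizes (4 replicates per mode, 50 nanoparticle runs, 300 oracle
traces in the script; 20 seeds and 1,000 oracle traces in the test suite)
were chosen so sampling error sits well inside each tolerance.

## Known limitations

- The FCS writer emits $DATATYPE F (float32) list mode only; reading
  supports F and D.  Keyword values are not delimiter-escaped.
- The bead call needs at least `min_bead_channels` bead-exclusive channels
  acquired; with fewer channels the gate must be reconfigured.
- `clean_artifacts` assumes a unimodal, roughly lognormal cell population;
  a strongly bimodal population (e.g. a dim antigen-loss subpopulation)
  could lose its dim mode to the lower fence if it sits orders of magnitude
  below the bright mode.
- Receptor conversion treats the stoichiometric ratio as exact and assumes
  complete, monovalent labelling.
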