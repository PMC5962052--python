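# Methods

## The model

`mtarray` simulates a cellular microtubule (MT) array as a fixed-time-step
Monte Carlo process. The cell is a thin cylinder — radius `R = 25 μm`,
height 0.5 μm — mimicking the basal region of a spread epithelial cell
where MT dynamics are usually measured. `N = 500` nucleation sites sit at
the center; each site carries at most one MT, modeled as a straight,
coarse-grained filament characterized only by its length and its phase
(growing or shortening). Molecular detail (protofilaments, GTP cap,
individual dimers) is deliberately absent; the model is blind to
mechanism and driven entirely by measured phenomenological parameters.

Each step advances the clock by `dt = 1 s` and applies, in order:

1. **Nucleation.** Every empty site nucleates with probability
   `1 − exp(−k_nuc·dt)`. A newborn MT enters the growing phase with a
   first increment of `V_g_mean·dt` — the parameter set's measured mean
   growth velocity — so that growth can start even when the free pool is
   low; from the next step on its velocity is concentration-dependent.
2. **Growth.** Every MT growing at step entry adds `V_g·dt`, with
   `V_g = k_on·[Tub]_free + C1` evaluated once per step from the
   start-of-step free concentration (`k_on = 0.0167 μm·μM⁻¹·s⁻¹`,
   `C1 = 0`). A tip that would meet or exceed the boundary is clamped to
   the boundary and forced into shortening. Tips that stay inside test a
   catastrophe with probability `1 − exp(−k_c·dt)`.
3. **Shortening.** Every MT shortening at step entry loses `V_s·dt`. A
   MT reaching zero length is removed; its remaining dimers return to
   the pool and the site becomes eligible for nucleation at the next
   step. Survivors test a rescue with probability `1 − exp(−k_r·dt)`.
4. **Pool reconciliation.** The free concentration is recomputed once
   from the budget: `[Tub]_free = max(0, [Tub]_total − L_tot·1624 /
   (602.214·V))`, with `L_tot` the summed length over all MTs,
   1624 dimers per μm of lattice, and 602.214 molecules per μM·μm³.

Phase switches act on the *following* step (move-then-test): a MT that
catastrophes in step `t` shortens for the first time in step `t+1`, and
symmetrically for rescues. The published step sequence does not say
whether a freshly switched MT also moves within its switch step;
move-then-test is the simplest reading that treats both transitions
uniformly, and it is applied everywhere.

### Why the free pool is derived, not integrated

Free tubulin is recomputed from the budget each step rather than
integrated as its own state variable. This makes mass conservation
structural (free + polymer ≡ total, to rounding), makes results
independent of the order in which sites are processed (all growth in a
step shares one velocity; the pool is reconciled once), and gives
dilution an unambiguous meaning. The per-step pool drawdown is small by
construction — with all 500 sites growing, uptake is
`N·k_on·1624/(602.214·V) ≈ 2.3 %` of the free pool per step — so the
synchronous update cannot overdraw the pool.

### Tubulin accounting constants

`1 μm of lattice = 1624 dimers` (13 protofilaments × 8 nm/dimer) and
`1 μM·μm³ = 602.214 molecules` (Avogadro × 10⁻²¹). The working volume
defaults to a round 1000 μm³ rather than the geometric π·25²·0.5 ≈
981.7 μm³: the published steady-state partition (411 MTs × 20.3 μm of
polymer vs 12.5 μM free out of 35 μM) back-calculates to V = 1000 within
rounding, and the cylinder is described as "approximately" 1000 μm³.
Volume is overridable independently of radius.

## Parameters

| parameter | default | units | meaning |
| --------- | ------- | ----- | ------- |
| `n_sites` | 500 | — | nucleation sites = max MT count |
| `rate_per_site` | 0.0005 | s⁻¹ | per-site nucleation rate (centrosomal emergence rate / 500) |
| `total_tubulin` | 35 | μM | closed dimer budget |
| `radius` | 25 | μm | cell (boundary) radius |
| `k_on` | 0.0167 | μm·μM⁻¹·s⁻¹ | apparent whole-MT growth constant |
| `c1_intercept` | 0 | μm/s | growth-velocity intercept |
| `dt` | 1 | s | step size (probabilities derive from rates, so other values are well-defined) |

Dynamic-instability presets (mean ± sd measured in LLCPK1 cells):

| | Set A | Set B | NEBD |
|---|---|---|---|
| V_g (μm/s) | 0.192 ± 0.123 | 0.142 ± 0.097 | 0.178 ± 0.153 |
| V_s (μm/s) | 0.218 ± 0.144 | 0.188 ± 0.132 | 0.205 ± 0.087 |
| k_c (s⁻¹) | 0.026 ± 0.024 | 0.053 ± 0.003 | 0.075 ± 0.089 |
| k_r (s⁻¹) | 0.175 ± 0.104 | 0.086 ± 0.005 | 0.023 ± 0.029 |

Only the means drive the baseline model; the sds define noise ranges
when noise is enabled.

### Rate → probability convention

Per-step probabilities use the exponential waiting-time form
`p = 1 − exp(−k·dt)` rather than the linear `k·dt`. At the rates in play
(≤ 0.175 s⁻¹ at dt = 1 s) the two differ by under 1 %, but the
exponential form remains a probability for any rate and step size.
Anyone attempting an exact numerical match against a linear-convention
implementation should expect per-step probabilities up to ~4 % higher
there (for k_r = 0.086: 0.0860 vs 0.0824), which matters only for
extreme-tail statistics such as complete-depolymerization counts.

### Zonal catastrophe

An optional two-zone landscape splits the cell at
`R − peripheral_width`: tips strictly interior see
`k_c × interior_catastrophe_factor` (default 1/16, the reported interior
reduction); tips at or beyond the seam see the measured `k_c`. A
peripheral width equal to `R` reproduces the homogeneous model exactly.
Rescue is kept uniform across zones, since no regional rescue difference
has been reported.

### Noise

When enabled, each MT independently redraws per step: `V_s` uniform on
[mean − sd, mean + sd] (truncated at 0), and `k_c`, `k_r` uniform on
[0, 2·mean] — the widest symmetric range that stays non-negative, chosen
because the measured sds of the frequencies are of the order of the
means. "A range covering one standard deviation" for V_s is read as
± 1 sd; ± 0.5 sd would also fit the phrase, and the choice is recorded
here because it is not disambiguated by the source data. The boundary
jitter is one global draw per step, `R_eff = R − U(0, jitter_max)`
(default max 3 μm), because it models one physical boundary; any MT
longer than the jittered radius is clamped there and forced to
catastrophe.

### Concentration-dependent nucleation

Optionally `k_nuc = slope × [Tub]_free`, with the default slope
calibrated so the measured interphase rate (0.0005 s⁻¹) is recovered at
the measured interphase free concentration (7 μM). The linear law is
supported experimentally up to ~8–10 μM free tubulin; no saturation is
implemented above that, so users probing the high-free regime should
treat the law as an extrapolation and set the slope themselves.

## Staged protocols

`run_stages` starts stage 1 from the empty state (all budget free) and
passes the complete array state into each later stage. At stage entry
the budget is set to that stage's `total_tubulin` and then multiplied by
its `dilution_factor` if present. After a dilution the free pool clamps
at zero while standing polymer exceeds the shrunken budget:
depolymerized tubulin above the budget is discarded, which is the
physical reading of removing cytoplasm, and prevents the spurious
regrowth that returning those dimers to the pool would allow. The
recorded sample at a stage boundary holds the pre-transition state, so
transition half-times measured from it use the correct baseline.

Built-in recipes (module `mtarray.experiments`) package the protocols:
interphase steady states, a 20–35 μM total-tubulin scan,
nucleation shutoff (48 h for Set A, which barely turns over; ~22 h for
Set B, which halves), 10× dilution, the prophase switch (with variants:
5× nucleation, catastrophe or rescue held at interphase values),
single-parameter swaps between Sets A and B, the zone-width scan, and
the noise/boundary-jitter comparison. Default replicate count is 4;
conditions within one experiment share replicate seeds (common random
numbers), which reduces the variance of the paired contrasts these
experiments exist to make. Replicate seeds are base + 0, 1, 2, …, and
are recorded in every output so single replicates can be re-run alone.

## Analysis conventions

* **Steady state** is summarized by time-averaging each output over the
  last 2,000 s of a 10,000 s run, per replicate, then mean ± sample sd
  across replicates. 10,000 s suffices because both the rolling mean
  and the rolling standard deviation plateau by then — the sd being the
  slower and therefore stricter criterion (`plateau_reached` checks
  both, default 5 % relative change between consecutive 2,000 s
  windows).
* **Half-times** are midpoint crossings: baseline = the pre-transition
  sample, asymptote = mean of the last 10 % of the series, crossing
  linearly interpolated. The definition is amplitude-scale invariant
  and returns NaN for series that never cross (including constants).
* **Length histograms** use right-closed 1 μm bins over [0, R], so a
  tip exactly at the boundary counts in the outermost bin (boundary
  accumulation is the signature feature of these distributions). The
  five-fraction radial profile bins length/R into [0,0.2), …, [0.8,1.0]
  for comparison with measured tip distributions.
* **Closed forms.** In the unconfined, constant-tubulin, bounded regime
  (`V_s·k_c > V_g·k_r`) the stationary length distribution is
  exponential with mean `V_g·V_s/(V_s·k_c − V_g·k_r)`;
  `dogterom_leibler_mean` returns it (or ∞ when unbounded) and the test
  suite holds the engine to it within 10 % — a budget covering both
  Monte Carlo error and the O(k·dt) bias of 1 s discretization. A
  second limit — velocities zeroed, no boundary — reduces each MT to a
  two-state Markov chain whose growing-phase occupancy is
  `k_r/(k_c+k_r)`; the engine matches it to the discrete-chain value.

## Numerical choices and degenerate inputs

* Lengths and the pool are continuous reals; no integer dimer rounding.
* Boundary clamps place the tip exactly at `R_eff`; there is no
  sub-step partial movement.
* A MT whose shortening step takes it to length ≤ 0 is removed that
  step; its site re-enters the nucleation pool at the next step.
* With nucleation off and no MTs the empty state is absorbing.
* `transition_probability` saturates at 1.0 in floating point for
  `k·dt ≳ 36`; this is outside any physiological regime.
* Identical seed + config reproduce trajectories and output files
  byte-for-byte.

## What the simulations do and do not show

The generator's default conditions are the published study conditions
(35 μM total tubulin, 500 sites, 25 μm radius, the preset parameter
sets, 10,000 s assembly, 4–10 replicates); passing tests show the
implementation reproduces the behavior of *that model* under *those
conditions*. The model omits, by design: MT bending at the cortex,
minus-end dynamics, severing, pause states, motor transport, explicit
GTP-cap or age-dependent catastrophe (the interior zone is a spatial
proxy), 3-D geometry, and centrosome repositioning (subsumed by the
radius jitter). Real arrays also face measurement selection (e.g.,
plus-end markers label only growing tips), which the simulated length
snapshots do not model.

Two reported outcomes sit at the extreme tail of the model's statistics
and are sensitive to step-ordering conventions that the source
description leaves open: the count of complete depolymerizations of a
long-MT array over 48 h, and the time for a shut-off Set B array to
lose half its MTs. Our implementation reproduces the qualitative
behavior (near-total persistence; decelerating exponential-like decay
with free tubulin recovering to ~21 μM) but loses MTs somewhat more
slowly than originally reported; the conventions above are documented
precisely so that this difference is interpretable.

## Problem sizes

Default runs simulate 500 sites for 10,000 one-second steps (seconds of
wall time); the longest protocol (48 h shutoff) is 183,000 steps per
replicate. The acceptance script runs every staged protocol at 6
replicates in a couple of minutes on one CPU.
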