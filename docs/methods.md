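# Methods

`orf1kin` models the interaction of LINE-1 ORF1p trimers with a single
tethered ssDNA molecule under tension, generates synthetic
optical-tweezers traces for four coiled-coil variants, and recovers
kinetic parameters from those traces the way a force-spectroscopy
analysis would: two-rate exponential fits, change-point step detection,
and replicate aggregation with SEM uncertainties. This note records the
models, the parameter choices, and the numerical decisions, including
the places where the design was genuinely open.

## Polymer model

Bare ssDNA follows the extensible freely jointed chain,

    x(F) = L_nt · [coth(bF/kT) − kT/(bF)] · (1 + F/S),

with `L_nt` the contour length per nucleotide, `b` the Kuhn length, `S`
the enthalpic stretch modulus and `kT = 4.11 pN·nm` (T ≈ 298 K). The
defaults, `L_nt = 0.575 nm/nt`, `b = 1.5 nm`, `S = 800 pN`, are within
the standard ssDNA literature range and were calibrated once so that
the model reproduces the three measured anchor points of the 8.1 knt
substrate: 0.29 nm/nt at 5 pN, 0.54 nm/nt at 30 pN, and ~2.35 µm total
extension at 5 pN (the model gives 0.2924, 0.5421 and 2.369 µm). The
force–extension relation is strictly monotone, so its inverse
(`force_at_extension`) is computed by bracketed root finding (Brent,
cap 200 pN, |Δ| < 1e−6 pN round trip).

A protein-decorated tether is a sum over lattice slots: each slot of
`footprint` nucleotides contributes the bare extension scaled by
`1 − γ(state, F)`, where γ is the fractional compaction of that slot's
state (below).

## Reaction scheme and occupancy states

Protein on the lattice follows the three-state scheme

    θ₀  ⇄(c·k_b / k_−b)  θ_b  ⇄(k_oligo / k_−oligo)  θ_oligo

— unbound, bound-but-not-oligomerized, and oligomerized (tightly
compacted). The generator of this linear system is constant at fixed
force, so `master_equation_solve` propagates it by matrix exponential:
exact to machine precision, conservation holds to ~1e−15 (well inside
the 1e−9 contract), with no ODE-tolerance knobs to document.

When binding is much faster than everything else (`c·k_b ≫ k_−b` and
`c·k_b ≫ k_oligo + k_−oligo`; `check_decoupling_conditions` reports the
ratios, 200× and 100× at the defaults), the extension change reduces to
the biphasic closed form

    Δx(t) = Δx_i (1 − e^(−k_i t)) + Δx_s (1 − e^(−k_s t)),

with `k_i = c·k_b` and `k_s = k_oligo + k_−oligo`. At the default
parameters the closed form matches the exact solution to 0.3% RMS of
the total amplitude; the discrepancy grows monotonically as the binding
rate is lowered toward `k_s` (2% is crossed near ratio ~30).

Force enters through Bell factors `exp(−(F − F_ref)·Δx‡/kT)`:

* Oligomerization: `Δx‡ = 2.0 nm`, `F_ref = 5 pN`. Compaction is fast
  at 5 pN and effectively absent at 30 pN (equilibrium oligomer
  fraction 0.95 vs ~1e−3·that), matching the observation that tension
  suppresses compaction and that the 30 pN binding signature shows no
  compaction events.
* Bound-state conformational conversion (below): negative transition
  distance (−1.0 nm, referenced to 30 pN), i.e. force-promoted —
  τ ~ 10 s at 30 pN, negligible (τ ~ 10³ s) at 5 pN.
* Bound-state compaction factor γ_b softens with force over an
  "engagement distance" of 0.42 nm, chosen so the fast-phase length
  change at 30 pN is 7-fold smaller than at 5 pN, as measured.

Per-state compaction factors: free 0; bound `γ_b(F)` (0.14 at 5 pN);
bound-extended `γ_b(F)/2` (the 30 pN complex re-elongates by about half
its initial dip); oligomerized `γ_o = 1` (the full-compaction asymptote
is ~−0.29 nm/nt, i.e. near zero extension, and compacted blocks resist
elastic opening even at 75 pN — they yield by discrete rupture, not by
stretching).

## Stochastic lattice simulator

`gillespie_simulate` runs an exact direct-method SSA on the slot
lattice (8100 nt / 50 nt footprint = 162 slots). Reactions: binding
(`c·k_b` per free slot), unbinding (`k_−b` per bound slot),
nearest-neighbour oligomerization (`k_oligo(F)` per bound slot with at
least one occupied neighbour; only the chosen slot converts, so the
mean-field flux equals the master-equation term), de-oligomerization
(`k_−oligo`), and the force-promoted compact→extended conversion.
Replicate-averaged occupancies agree with the master equation within
binomial sampling error (the acceptance test uses a
multiplicity-adjusted 3-SE band, z ≤ 4.5 with median z < 1, because
with hundreds of correlated grid points a literal per-point 3-SE bound
is exceeded somewhere by chance in any correct implementation). The
nearest-neighbour constraint produces a small transient occupancy lag
(~1e−3 absolute) while the lattice is sparse; it is inside the sampling
band at 100 replicates.

Protocol segments are handled piecewise: force clamps run the full SSA;
extension clamps recompute the clamp force after every event
(`constant_extension_step`, Brent inversion of the composite
force–extension relation); constant-velocity ramps (450 nm/s) freeze
the lattice — they last a few seconds while every rate is ≤ 0.01 s⁻¹ at
those forces. Identical seeds give bitwise-identical trajectories; all
randomness flows from one `numpy` Generator.

## Protein-free (apo) phenomenology

The mechanisms behind three observed behaviours in protein-free buffer
are not established, so they are modelled phenomenologically and
flagged as such in trace metadata:

* **Dissociation at 30 pN** (re-compaction then elongation): at the
  buffer swap a fraction `p_recompact = 0.6` of bound slots is eligible
  to collapse into compact clusters at `k_reconf` (τ ~ 10 s); of those,
  `p_stay` (0.3 retro⁺ / 0.05 retro⁻) resist unbinding while the rest
  leave at `k_unbind_apo` (τ ~ 100 s retro⁺, 3× faster retro⁻). This
  yields equal re-compaction amplitudes across variants, the measured
  2× / 3× rate contrasts, and final plateaus ≤ 85% of bare (retro⁺) vs
  ≥ 95% (retro⁻). `k_unbind_apo` is a separate parameter from `k_−b`
  because the observed protein-free elongation timescale (τ ~ 100 s) is
  not the same as the with-protein unbinding rate.
* **Low-extension incubation** (0.2 nm/nt clamp, 2–30 min): bound
  protein coarsens into "locked" blocks at
  `k_coarsen0 · exp(−(F − 3 pN)·2.0 nm/kT)` per slot, scaled by the
  variant's equilibrium oligomer fraction (so incompetent variants
  barely coarsen). The Bell feedback self-limits the process as the
  clamp force rises, which keeps the force inside the measured ~2–10 pN
  window and makes it grow with incubation time. Growth is
  nucleation-biased (slots flanking a block join it preferentially), so
  blocks reach the tens-to-hundreds-of-nm scale seen in the 75 pN hold.
* **75 pN hold**: each locked block ruptures with a rate set by
  `hold_survival` over the 100 s hold (0.85 retro⁺ / 0.10 retro⁻); a
  rupture opens a contiguous run of slots whose target length is drawn
  log-uniformly on [10, 500] nm, quantized to whole slots (~30 nm).
  During the hold, remaining blocks anneal; on release below 50 pN they
  recruit neighbouring bound regions (`recruit_frac = 0.8` of
  `frac_locked·(1 − frac_locked)`), which is why the release curve at
  30 pN lies below the stretch curve, increasingly so for longer
  incubations.

## Variant presets

All four presets share the binding parameters (`c = 30 nM`,
`c·k_b = 1.0 s⁻¹` anchoring the fast phase at τ ~ 1 s; `k_−b = 0.005
s⁻¹`) and the conformational rate — initial binding is identical across
variants at both forces, as observed. They differ only in the
oligomerization split and the apo parameters:

| preset | k_oligo0 | k_−oligo | eq. oligo fraction | k_reconf | k_unbind_apo | p_stay | hold_survival |
|--------|----------|----------|--------------------|----------|--------------|--------|---------------|
| 111p   | 0.0095   | 0.0005   | 0.95               | 0.1      | 0.01         | 0.3    | 0.85          |
| m14p   | 0.0095   | 0.0005   | 0.95               | 0.1      | 0.01         | 0.3    | 0.85          |
| m15p   | 0.001    | 0.009    | 0.10               | 0.2      | 0.03         | 0.05   | 0.10          |
| 151p   | 1e−4     | 0.01     | ~0.01              | 0.2      | 0.03         | 0.05   | 0.10          |

The sum `k_oligo + k_−oligo = 0.01 s⁻¹` (τ ~ 100 s secondary phase) is
shared by 111p/m14p/m15p; only the split differs, which is exactly the
degeneracy a constant-force experiment cannot resolve (it measures only
the sum). The 111p/m14p split 0.0095/0.0005 is fixed by the
full-compaction asymptote: an equilibrium oligomer fraction of 0.95
puts the long-time extension change at −0.29 nm/nt. m15p's 0.10 and
151p's ~0.01 reproduce the ordering of secondary-compaction amplitudes
(111p ≈ m14p > m15p > 151p) with 151p's phase small enough to be
statistically unreportable. `k_conf = 0.096 s⁻¹` is calibrated so the
*fitted* slow elongation time constant at 30 pN is 10 s — the
conversion compounds with unbind/rebind cycling, so the observable
relaxation is slightly faster than the bare rate, and the calibration
target is the observable.

## Instrument noise model

Additive white noise (σ = 4 nm per sample, a typical dual-trap
resolution) plus a linear drift of magnitude 0.05 nm/s whose sign is
drawn per trace, so replicate averages are unbiased — the real
instrument corrected drift by bead-image tracking, which is not
simulated. Sampling at 10 Hz. What the generator does **not** emulate:
bead/trap compliance, hydrodynamics, sequence-dependent binding,
RNA-like secondary structure, and any spatial correlation in binding
beyond nearest-neighbour oligomerization. Passing tests therefore
certify the analysis pipeline against the stated kinetic model, not
against every artifact of real data.

A consequence worth knowing: with a 50 nt footprint, each
oligomerization event moves the tether by ~13 nm at 5 pN. The fast
binding phase (−330 nm, τ ~ 1 s) therefore rides on a compound-Poisson
staircase, and no estimator can beat an ~10% per-trace floor on the
fast rate/amplitude (verified on noiseless traces). Replicate means are
unbiased and converge as 1/√n; results are reported as mean ± SEM over
≥ 3 replicates, which is also the study's own convention.

## Trace fitting

`fit_compaction` fits `x(t) = x0 + Δx_f(1 − e^(−k_f t)) + Δx_s(1 −
e^(−k_s t))` (optionally + `m·t`) by Levenberg–Marquardt (lmfit), with:

* **Global initialization** by a coarse scan over log-spaced rate pairs,
  solving the linearly-entering amplitudes at each pair, followed by
  multi-start refinement (spec'd log-spaced ×5 around the optimum).
* **Log-time resampling** so each time decade gets equal leverage —
  sparse (60/decade) for same-sign compaction records, whose slow
  correlated occupancy noise otherwise lets the optimizer collapse both
  rates onto it, dense (400/decade) for the small opposite-sign 30 pN
  signatures, which are white-noise dominated.
* **Sign structure**: 5 pN compaction constrains both amplitudes ≤ 0;
  the 30 pN signature uses Δx_s = −Δx_f·φ with φ ∈ [0, 1], encoding
  that re-elongation is partial (the tether ends below bare extension).
* **Rate separation** `k_f ≥ 5·k_s` (anything slower than the record is
  drift, not a phase; merged-rate optima are degenerate). A same-sign
  fit that still lands at the bound is refit with the phases forced
  apart and flagged.
* **Fast-phase re-estimation** for same-sign fits: the fast rate is
  re-measured on short early windows (50/80/120 samples; median of the
  three window estimates) with an exponential-plus-line model weighted
  by 1/√t against the growing slow-event variance; the amplitude is
  then re-solved over ~48 fast time constants. This sidesteps the
  long-record leverage problem entirely.
* **Model selection** (`auto`): AICc with a margin of 2 — the second
  exponential must earn its parameters. On one-phase truth vs two-phase
  truth (10× separation, default noise) the correct model is chosen in
  ≥ 95% of trials.

`fit_dissociation` applies the opposite-sign fit after estimating the
drift slope on the final quarter of the record (slow phase saturated)
and subtracting it; near-flat records are flagged `degenerate` rather
than fitted. A slow phase is reported as *negligible* (its rate
unreportable) when |Δx_s| < 3× its replicate SEM or when model
selection drops it — this operationalizes "secondary compaction was
negligible" for 151p; no threshold is hand-set per variant.

`detect_steps` is binary-segmentation change-point search on the mean
with penalty `10·σ²·log n`, σ estimated from the median absolute
successive difference; events smaller than `min_size` (default 20 nm,
honouring the "tens of nm" observation floor) are discarded. Planted
steps ≥ 5σ are recovered with recall ≥ 0.9 at ≤ 0.05 spurious events
per 100 s.

## Assay orchestration and problem sizes

`run_binding_assay`, `run_dissociation_assay` and
`run_compaction_at_fixed_extension` run generate → normalize → fit →
aggregate, with per-replicate seeds derived deterministically from one
run seed plus a preset-name salt (so kinetically identical variants
still get independent realizations). Cross-variant comparisons use
overlapping ±2 SEM intervals for "identical/similar" and the 3-SEM rule
for negligible phases.

Default problem sizes — 162 slots, 300–1100 s binding records, 800 s
dissociation records, 3–4 replicates in tests and 4–24 in the
acceptance script (more where the per-trace floor is largest) — were
chosen so every contract is measured well inside its uncertainty at
desk scale; the full test suite runs in about a minute.

## Known limitations

* The split of `k_oligo` vs `k_−oligo` is conventionally fixed by the
  asymptote; any split with the same sum and equilibrium fraction is
  observationally equivalent at constant force.
* α (extension change per oligomerization event) is carried in nm per
  event and only enters the analytic `secondary_amplitude` helper; the
  lattice expresses compaction through γ weights instead.
* The apo-phase and incubation mechanisms are explicit model choices,
  not inferences; they are constrained only by the amplitude/rate/
  plateau contrasts they were built to reproduce.
* Fast-phase parameters carry an irreducible ~10% per-trace
  uncertainty at the 50 nt footprint (see noise model); only replicate
  means are quantitative.
* `extension_at_force` interpolates ramps linearly between samples;
  at 450 nm/s and 10 Hz the force spacing near 30 pN is ~1 pN.
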