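# orf1kin

Kinetics of LINE-1 ORF1p binding and oligomerization-driven compaction
of single-stranded DNA under tension: a simulator, synthetic
optical-tweezers trace generator, and fitting pipeline.

## The problem

The LINE-1 retrotransposon's ORF1 protein binds single-stranded nucleic
acid as a trimer and, when retrotransposition-competent, condenses it
into tightly compacted nucleoprotein structures. In a dual-trap optical
tweezers experiment an 8.1 knt ssDNA tether is held at fixed force (or
fixed extension) while 30 nM ORF1p trimer binds, and the tether's
extension x(t) reports the protein's state. Coiled-coil variants that
differ by as little as one residue (retro⁺ 111p, m14p vs retro⁻ 151p,
m15p) separate cleanly in this assay even though their intrinsic DNA
affinity is identical.

This package is for people analysing (or teaching the analysis of) such
traces: it implements the polymer and kinetic models, generates
realistic synthetic data for all four variants and all three
experimental protocols, and extracts phase amplitudes and rates exactly
the way the experiment is analysed.

## The model

Bare ssDNA elasticity is the extensible freely jointed chain,
x(F) = L_nt[coth(bF/kT) − kT/(bF)](1 + F/S), calibrated to the measured
0.29 nm/nt at 5 pN, 0.54 nm/nt at 30 pN and ~2.35 µm total at 5 pN.

Protein kinetics follow the three-state scheme

    θ₀ ⇄ θ_b ⇄ θ_oligo        (binding: c·k_b, k₋b; oligomerization: k_oligo, k₋oligo)

solved exactly (matrix exponential) and stochastically (Gillespie on a
162-slot lattice, 50 nt trimer footprint). When binding is much faster
than oligomerization — true here at 100–200× — the extension change is
biphasic:

    Δx(t) = Δx₊ⁱ(1 − e^(−k₊ⁱ t)) + Δx₊ˢ(1 − e^(−k₊ˢ t)),
    k₊ⁱ = c·k_b,   k₊ˢ = k_oligo + k₋oligo,
    Δx₊ˢ = α(n−1)·k_oligo/(k_oligo + k₋oligo).

Tension suppresses oligomerization through a Bell factor
exp(−(F−5 pN)·Δx‡/kT), so compaction runs to near zero extension at
5 pN (τ ~ 1 s binding, τ ~ 100 s secondary compaction) but is shut off
at 30 pN, where a force-promoted conformational change produces the
fast-compaction / slow-elongation (τ ~ 10 s) signature instead.
Protein-free dissociation at 30 pN is biphasic the other way:
re-compaction (τ ~ 10 s) then elongation (τ ~ 100 s), with the
incompetent variants 2× faster to re-compact, 3× faster to unbind, and
more complete in their release. See `docs/methods.md` for every
parameter and the design decisions behind the phenomenological parts.

## Worked example

Simulate a 1000 s binding trace of wild-type 111p at 5 pN and fit the
two-rate exponential:

```bash
orf1kin simulate --preset 111p --force 5 --duration 1000 --seed 7 --out trace_111p_5pN.tsv
orf1kin fit trace_111p_5pN.tsv --model 2-exp
```

```json
{
  "model": "2-exp",
  "dx_fast_nm_per_nt": -0.0465,
  "k_fast_per_s": 0.8806,
  "dx_slow_nm_per_nt": -0.2220,
  "k_slow_per_s": 0.00944,
  "residual_rms_nm_per_nt": 0.00472,
  "flags": ["fast_phase_refined"]
}
```

Read: the tether shortens by 0.046 nm/nt in a fast phase with
τ = 1/0.88 ≈ 1.1 s (initial trimer binding, every ~50 nt slot filling at
c·k_b ≈ 1 s⁻¹), then by a further 0.222 nm/nt with τ ≈ 106 s
(oligomerization of neighbouring trimers into tightly compacted
blocks). The total, −0.27 nm/nt on this seed, approaches the bare
extension at 5 pN (0.29 nm/nt): the DNA ends almost fully compacted.
Replicates sharpen this; the same assay run at three seeds,

```python
from orf1kin import run_binding_assay
r = run_binding_assay("111p", 5.0, replicates=3, seed=7)
s = r.summary
print(f"tau_fast = {1/s.k_fast:.2f} s, tau_slow = {1/s.k_slow:.1f} s, "
      f"total = {s.dx_fast + s.dx_slow:.3f} nm/nt")
```

prints `tau_fast = 1.18 s, tau_slow = 102.8 s, total = -0.285 nm/nt`.
Running the same assay with the `151p` preset flags the slow phase as
negligible — the oligomerization-deficient variant never develops
secondary compaction, which is the mechanical correlate of its failure
to retrotranspose.

Other entry points: `orf1kin simulate --assay dissociation|cycle`,
`orf1kin protocol --assay {binding,dissociation,fixed-extension}`
(replicated assays with fit tables), `orf1kin fixture` (the full
four-variant × three-protocol synthetic dataset), `orf1kin report`
(cross-variant comparison table). All randomness flows from `--seed`;
identical seeds give identical files.

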