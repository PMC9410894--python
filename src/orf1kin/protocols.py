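"""End-to-end assays and cross-variant comparison tables.

Each assay runs generate -> normalize -> fit -> aggregate over seeded
replicates of one variant preset, mirroring the three experiments:
constant-force binding (5 or 30 pN), protein-free dissociation at
30 pN, and low-extension incubation followed by stretch / 75 pN hold /
release cycles.  ``compare_variants`` assembles amplitude/rate tables,
fold-change ratios with propagated SEM, and negligible-phase flags.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import (PhaseFit, aggregate_replicates, detect_steps,
                      extension_at_force, fit_compaction, fit_dissociation,
                      normalize_extension)
from .polymer import PolymerParams
from .protocol import ProtocolSpec
from .synthetic import (NoiseModel, VALID_INCUBATIONS_MIN,
                        generate_binding_trace, generate_dissociation_trace,
                        generate_stretch_release_cycle, get_preset)
from .trace import Trace

__all__ = ["AssayResult", "CycleResult", "VariantComparison",
           "run_binding_assay", "run_dissociation_assay",
           "run_compaction_at_fixed_extension", "compare_variants",
           "replicate_seeds"]

#: fixed offset stream deriving replicate seeds from one run seed
_SEED_STRIDE = 1009


def replicate_seeds(seed: int, replicates: int, salt: str = "") -> list:
    """Deterministic per-replicate seeds derived from a single run seed.

    ``salt`` (e.g. the preset name) decorrelates otherwise identical
    parameter sets so that kinetically equivalent variants still produce
    independent noise/lattice realizations.
    """
    offset = zlib.crc32(salt.encode()) % 65521 if salt else 0
    return [(seed + offset + _SEED_STRIDE * i) % (2**31 - 1)
            for i in range(replicates)]


@dataclass
class AssayResult:
    """Replicate fits and their aggregate for one preset x protocol."""

    preset: str
    protocol: str
    force: float
    fits: list
    summary: PhaseFit
    failures: list = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fits):
            rows.append({"preset": self.preset, "protocol": self.protocol,
                         "replicate": i, "model": f.model,
                         "dx_fast_nm_per_nt": f.dx_fast, "k_fast_s": f.k_fast,
                         "dx_slow_nm_per_nt": f.dx_slow, "k_slow_s": f.k_slow,
                         "residual_rms": f.residual_rms})
        return pd.DataFrame(rows)


@dataclass
class CycleResult:
    """Stretch/release observables for one incubation duration."""

    preset: str
    incubation_min: float
    stretch_rel_30pN: float
    release_rel_30pN: float
    steps: list
    incubation_force_final: float
    trace: Trace = None


def run_binding_assay(preset, force: float, replicates: int = 3,
                      seed: int = 0, duration: float = None,
                      noise: NoiseModel = NoiseModel(),
                      polymer: PolymerParams = PolymerParams()) -> AssayResult:
    """Constant-force binding assay with replicate-averaged biphasic fit.

    At 5 pN both phases compact (same sign); at 30 pN the fit allows the
    fast-compaction / slow-elongation signature (opposite signs).
    Default durations: 1000 s at <= 10 pN (to resolve the tau ~100 s
    secondary compaction), 200 s above.
    """
    if replicates < 3:
        raise ValueError("need >= 3 replicates for SEM reporting")
    preset = get_preset(preset)
    if duration is None:
        duration = 1000.0 if force <= 10.0 else 200.0
    sign = "same" if force <= 10.0 else "opposite"
    # the 5 pN signal dwarfs instrument drift; the free baseline slope is
    # only worth its variance cost for the small 30 pN amplitudes
    use_drift = force > 10.0
    fits, failures = [], []
    for s in replicate_seeds(seed, replicates, preset.name):
        trace = generate_binding_trace(preset, force, duration, noise, s,
                                       polymer)
        trace = normalize_extension(trace, polymer)
        try:
            fits.append(fit_compaction(trace, model="auto", sign=sign,
                                       drift=use_drift, polymer=polymer))
        except RuntimeError as exc:
            failures.append(str(exc))
    summary = aggregate_replicates(fits)
    return AssayResult(preset.name, f"binding_{force:g}pN", force, fits,
                       summary, failures)


def run_dissociation_assay(preset, force: float = 30.0, replicates: int = 3,
                           seed: int = 0, duration: float = 800.0,
                           noise: NoiseModel = NoiseModel(),
                           polymer: PolymerParams = PolymerParams()) -> AssayResult:
    """Protein-free dissociation assay (re-compaction then elongation)."""
    if replicates < 3:
        raise ValueError("need >= 3 replicates for SEM reporting")
    preset = get_preset(preset)
    fits, failures = [], []
    for s in replicate_seeds(seed, replicates, preset.name):
        trace = generate_dissociation_trace(preset, force, duration, noise, s,
                                            polymer)
        trace = normalize_extension(trace, polymer)
        try:
            fits.append(fit_dissociation(trace, polymer=polymer))
        except RuntimeError as exc:
            failures.append(str(exc))
    summary = aggregate_replicates(fits)
    return AssayResult(preset.name, "dissociation", force, fits, summary,
                       failures)


def run_compaction_at_fixed_extension(preset, incubation_min=(2, 5, 15, 30),
                                      replicates: int = 3, seed: int = 0,
                                      noise: NoiseModel = NoiseModel(),
                                      polymer: PolymerParams = PolymerParams(),
                                      keep_traces: bool = False) -> list:
    """Incubation / stretch / hold / release cycles over incubation times.

    Returns one :class:`CycleResult` per (incubation, replicate): the
    normalized stretch and release extensions at 30 pN, the detected
    75 pN-hold step events, and the clamp force reached by the end of
    the incubation.
    """
    if not incubation_min:
        raise ValueError("incubation list must be non-empty")
    preset = get_preset(preset)
    results = []
    for inc in incubation_min:
        if inc not in VALID_INCUBATIONS_MIN:
            raise ValueError(f"invalid incubation time {inc} min; "
                             f"choose from {VALID_INCUBATIONS_MIN}")
        for s in replicate_seeds(seed, replicates, preset.name):
            trace = generate_stretch_release_cycle(preset, inc, noise, s,
                                                   polymer)
            trace = normalize_extension(trace, polymer)
            h0, h1 = trace.segment_bounds("hold")
            hold = trace.window(h0, h1)
            steps = detect_steps(hold, min_size=20.0)
            i0, i1 = trace.segment_bounds("incubation")
            f_inc = trace.window(i0, i1).force[-1]
            results.append(CycleResult(
                preset.name, inc,
                extension_at_force(trace, 30.0, "stretch"),
                extension_at_force(trace, 30.0, "release"),
                steps, float(f_inc),
                trace if keep_traces else None))
    return results


@dataclass
class VariantComparison:
    """Cross-variant summary of one protocol: per-preset fits, ratios, flags."""

    protocol: str
    summaries: dict                   # preset -> PhaseFit
    ratios: dict                      # (num, den, param) -> (ratio, sem)
    negligible_slow: dict             # preset -> bool

    def table(self) -> pd.DataFrame:
        rows = []
        for name, f in self.summaries.items():
            rows.append({
                "preset": name, "model": f.model,
                "dx_fast": f.dx_fast, "dx_fast_sem": f.stderr.get("dx_fast"),
                "k_fast": f.k_fast, "k_fast_sem": f.stderr.get("k_fast"),
                "dx_slow": f.dx_slow, "dx_slow_sem": f.stderr.get("dx_slow"),
                "k_slow": f.k_slow, "k_slow_sem": f.stderr.get("k_slow"),
                "n": f.n_replicates,
                "slow_phase_negligible": self.negligible_slow.get(name)})
        return pd.DataFrame(rows)


def _ratio_with_sem(a, a_sem, b, b_sem):
    if not (np.isfinite(a) and np.isfinite(b)) or b == 0:
        return np.nan, np.nan
    r = a / b
    rel = np.sqrt((a_sem / a) ** 2 + (b_sem / b) ** 2) if (
        np.isfinite(a_sem) and np.isfinite(b_sem) and a != 0) else np.nan
    return float(r), float(abs(r) * rel) if np.isfinite(rel) else np.nan


def compare_variants(results: dict) -> VariantComparison:
    """Build the cross-variant comparison from same-protocol assay results.

    A preset's slow phase is flagged negligible when |dx_slow| < 3 x its
    replicate SEM (the rate of an absent phase is not reportable).
    Pairwise fold-change ratios are computed for every parameter with
    SEM propagated in quadrature.
    """
    protocols = {r.protocol for r in results.values()}
    if len(protocols) != 1:
        raise ValueError(f"assay results span mixed protocols: {protocols}")
    summaries = {name: r.summary for name, r in results.items()}
    negligible = {}
    for name, f in summaries.items():
        sem = f.stderr.get("dx_slow", np.nan)
        negligible[name] = bool(
            not np.isfinite(f.dx_slow)
            or (np.isfinite(sem) and abs(f.dx_slow) < 3.0 * sem)
            or f.model in ("1-exp", "mixed"))
    ratios = {}
    names = sorted(summaries)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            fi, fj = summaries[ni], summaries[nj]
            for par in ("dx_fast", "k_fast", "dx_slow", "k_slow"):
                ratios[(ni, nj, par)] = _ratio_with_sem(
                    getattr(fi, par), fi.stderr.get(par, np.nan),
                    getattr(fj, par), fj.stderr.get(par, np.nan))
    return VariantComparison(protocols.pop(), summaries, ratios, negligible)
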