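"""Phase extraction from single-molecule traces.

Constant-force binding and dissociation records are fit with the
two-rate saturating exponential

    x(t) = x0 + dx_fast*(1 - exp(-k_fast t)) + dx_slow*(1 - exp(-k_slow t))

to recover the amplitude and rate of each phase (compaction negative by
convention).  ``auto`` model selection chooses between one and two
exponentials by small-sample-corrected AIC.  Step detection for the
75 pN hold uses binary-segmentation change-point search on the mean with
a penalty calibrated from the noise floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from lmfit import Parameters, minimize

from .polymer import PolymerParams, bare_extension_per_nt
from .trace import Trace

__all__ = ["PhaseFit", "StepEvent", "normalize_extension", "fit_compaction",
           "fit_dissociation", "detect_steps", "extension_at_force",
           "aggregate_replicates"]


@dataclass
class PhaseFit:
    """Amplitudes and rates of the fitted phases of one (or several) traces.

    Amplitudes are in nm/nt and signed (compaction negative); rates in
    s^-1 with ``k_fast > k_slow`` for two-exponential fits.  ``stderr``
    carries per-parameter uncertainties: least-squares standard errors
    for a single fit, SEM over replicates after aggregation.
    """

    dx_fast: float
    k_fast: float
    dx_slow: float = np.nan
    k_slow: float = np.nan
    model: str = "2-exp"
    stderr: dict = field(default_factory=dict)
    residual_rms: float = np.nan
    n_replicates: int = 1
    protocol: str = ""
    flags: tuple = ()

    @property
    def tau_fast(self) -> float:
        return 1.0 / self.k_fast

    @property
    def tau_slow(self) -> float:
        return 1.0 / self.k_slow

    def __post_init__(self) -> None:
        if self.model == "2-exp" and np.isfinite(self.k_slow):
            if not self.k_fast > self.k_slow > 0:
                raise ValueError(
                    f"2-exp fit requires k_fast > k_slow > 0, got "
                    f"{self.k_fast} and {self.k_slow}")


@dataclass(frozen=True)
class StepEvent:
    """A discrete extension change during a constant-force hold."""

    time: float
    size: float          # nm, positive = elongation
    confidence: float    # |step| / (sigma * sqrt(2/window)) z-score

    def __post_init__(self) -> None:
        if self.size == 0:
            raise ValueError("step size must be non-zero")


def normalize_extension(trace: Trace,
                        polymer: PolymerParams = PolymerParams()) -> Trace:
    """Add nm/nt and relative-to-bare channels to a trace.

    ``ext_nm_per_nt`` divides by the substrate length (from metadata);
    ``ext_relative`` divides by the bare-ssDNA extension at each sample's
    force.
    """
    n_nt = trace.metadata.get("substrate_nt")
    if not n_nt:
        raise ValueError("trace metadata lacks substrate_nt; cannot normalize")
    out = trace.copy()
    out.channels["ext_nm_per_nt"] = out.extension / n_nt
    with np.errstate(divide="ignore", invalid="ignore"):
        bare = bare_extension_per_nt(np.maximum(out.force, 0.0), polymer) * n_nt
        out.channels["ext_relative"] = np.where(bare > 0,
                                                out.extension / bare, 0.0)
    return out


# ---------------------------------------------------------------------------
# exponential fitting

def _model_eval(p, t, n_exp, drift):
    y = np.full_like(t, p["x0"].value)
    y = y + p["dx_fast"] * (1.0 - np.exp(-p["k_fast"] * t))
    if n_exp == 2:
        y = y + p["dx_slow"] * (1.0 - np.exp(-p["k_slow"] * t))
    if drift:
        y = y + p["m"] * t
    return y


def _residual(p, t, y, n_exp, drift):
    return _model_eval(p, t, n_exp, drift) - y


def _log_resample(t, y, per_decade: int = 400):
    """Subsample a uniformly sampled record onto a log-spaced time grid.

    Keeps every sample in decades that have fewer than ``per_decade``
    points; later decades are thinned to that density.  The first sample
    (t = 0) is always kept.
    """
    if t.size < 3:
        return t, y
    dt = np.median(np.diff(t))
    span = t[-1]
    if span <= 0 or dt <= 0:
        return t, y
    n_dec = np.log10(span / dt)
    if n_dec <= 1 or t.size <= per_decade * n_dec:
        return t, y
    targets = np.geomspace(dt, span, int(np.ceil(per_decade * n_dec)))
    idx = np.unique(np.searchsorted(t, targets))
    idx = np.clip(idx, 0, t.size - 1)
    idx = np.unique(np.concatenate(([0], idx)))
    return t[idx], y[idx]


def _grid_init(t, y, n_exp, drift):
    """Coarse global search: scan log-spaced rate pairs, solving the
    amplitudes (which enter linearly) by least squares at each pair."""
    span = t[-1] - t[0]
    dt = max(np.median(np.diff(t)), 1e-9)
    kf_grid = np.geomspace(2.0 / span, 1.0 / dt, 14)
    best, best_sse = None, np.inf
    ones = np.ones_like(t)
    for kf in kf_grid:
        ks_grid = ([None] if n_exp == 1
                   else np.geomspace(kf / 500.0, kf / 2.0, 8))
        for ks in ks_grid:
            cols = [ones, 1.0 - np.exp(-kf * t)]
            if ks is not None:
                cols.append(1.0 - np.exp(-ks * t))
            if drift:
                cols.append(t)
            A = np.column_stack(cols)
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            sse = float(np.sum((A @ coef - y) ** 2))
            if sse < best_sse:
                best_sse, best = sse, (kf, ks if ks is not None else kf / 100.0)
    return best


def _fit_once(t, y, n_exp, drift, k_fast0, k_slow0, sign=None,
              min_ratio=5.0):
    p = Parameters()
    y_end = y[-max(t.size // 20, 2):].mean()
    amp = y_end - y[0]
    span = max(t[-1] - t[0], 1e-9)
    rng_y = float(y.max() - y.min()) or 1.0
    p.add("x0", value=float(y[0]))
    if n_exp == 2:
        # the two phases must be kinetically distinct; tying k_fast to
        # k_slow through a bounded ratio prevents the fit from collapsing
        # both rates onto slow correlated fluctuations.  k_slow >= 1/span:
        # anything slower than the record is drift, not a phase.
        p.add("k_slow", value=max(k_slow0, 1.0 / span), min=1.0 / span,
              max=1e4)
        p.add("k_ratio", value=float(max(k_fast0 / k_slow0, min_ratio)),
              min=min_ratio, max=1e7)
        p.add("k_fast", expr="k_slow * k_ratio")
    else:
        p.add("k_fast", value=k_fast0, min=1e-6, max=1e4)
    if n_exp == 2:
        lim = 2.0 * rng_y  # amplitudes cannot exceed the data range
        if sign == "opposite":
            # fast compaction followed by partial slow re-elongation: the
            # recovered amplitude cannot exceed the dip (the tether ends
            # below its bare extension), so dx_slow = -dx_fast * frac
            fast0 = min(y.min() - y[0], -1e-6)
            frac0 = float(np.clip((amp - fast0) / max(-fast0, 1e-9),
                                  0.05, 0.95))
            p.add("dx_fast", value=float(fast0), min=-lim, max=0.0)
            p.add("recovery_frac", value=frac0, min=0.0, max=1.0)
            p.add("dx_slow", expr="-dx_fast * recovery_frac")
        elif sign == "same":
            # compaction: both phases shorten the tether
            half = min(amp / 2.0, -1e-6)
            p.add("dx_fast", value=float(half), min=-lim, max=0.0)
            p.add("dx_slow", value=float(half), min=-lim, max=0.0)
        else:
            p.add("dx_fast", value=float(amp / 2.0 or 1e-4), min=-lim, max=lim)
            p.add("dx_slow", value=float(amp / 2.0 or 1e-4), min=-lim, max=lim)
    else:
        p.add("dx_fast", value=float(amp or 1e-4), min=-2.0 * rng_y,
              max=2.0 * rng_y)
    if drift:
        p.add("m", value=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return minimize(_residual, p, args=(t, y, n_exp, drift),
                        method="leastsq", nan_policy="omit")


def _fit_multistart(t, y, n_exp, drift, sign, min_ratio=5.0):
    k_fast0, k_slow0 = _grid_init(t, y, n_exp, drift)
    best = None
    starts = [(k_fast0, k_slow0)]
    # log-spaced multi-start around the grid optimum for robustness
    for ff in (0.2, 1.0, 5.0):
        for fs in (0.2, 1.0, 5.0):
            if (ff, fs) != (1.0, 1.0):
                starts.append((k_fast0 * ff, k_slow0 * fs))
    for kf, ks in starts:
        if n_exp == 2 and ks >= kf:
            ks = kf / 10.0
        try:
            res = _fit_once(t, y, n_exp, drift, kf, ks, sign, min_ratio)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    return best


def _aicc(res, n):
    k = res.nvarys
    if n - k - 1 <= 0:
        return np.inf
    return res.aic + 2.0 * k * (k + 1) / (n - k - 1)


def _result_to_fit(res, n_exp, trace, drift) -> PhaseFit:
    p = res.params
    n_nt = trace.metadata.get("substrate_nt", 1)
    flags = []
    if n_exp == 2:
        kf, ks = p["k_fast"].value, p["k_slow"].value
        df, ds = p["dx_fast"].value, p["dx_slow"].value
        kf_e, ks_e = p["k_fast"].stderr or np.nan, p["k_slow"].stderr or np.nan
        df_e, ds_e = p["dx_fast"].stderr or np.nan, p["dx_slow"].stderr or np.nan
        if ks > kf:  # reorder so the fast phase is fast
            kf, ks, df, ds = ks, kf, ds, df
            kf_e, ks_e, df_e, ds_e = ks_e, kf_e, ds_e, df_e
        fit = PhaseFit(dx_fast=df / n_nt, k_fast=kf, dx_slow=ds / n_nt,
                       k_slow=ks, model="2-exp",
                       stderr={"dx_fast": df_e / n_nt, "k_fast": kf_e,
                               "dx_slow": ds_e / n_nt, "k_slow": ks_e},
                       residual_rms=float(np.sqrt(np.mean(res.residual**2))) / n_nt,
                       protocol=trace.metadata.get("protocol", ""),
                       flags=tuple(flags))
    else:
        fit = PhaseFit(dx_fast=p["dx_fast"].value / n_nt,
                       k_fast=p["k_fast"].value, model="1-exp",
                       stderr={"dx_fast": (p["dx_fast"].stderr or np.nan) / n_nt,
                               "k_fast": p["k_fast"].stderr or np.nan},
                       residual_rms=float(np.sqrt(np.mean(res.residual**2))) / n_nt,
                       protocol=trace.metadata.get("protocol", ""),
                       flags=tuple(flags))
    return fit


def _refine_fast_phase(t, y, fit: PhaseFit, n_nt: float) -> PhaseFit:
    """Re-estimate the fast phase on its own early window.

    On long records the least-squares fast rate is degraded by slow
    correlated fluctuations (discrete oligomerization events).  When the
    phases are well separated (ratio >= 20) the slow phase is locally
    linear over ~12 fast time constants, so the early window is refit
    with an exponential-plus-line model, weighted by 1/sqrt(t) to track
    the growing variance of the accumulated slow-event noise.
    """
    from scipy.optimize import minimize_scalar

    span = t[-1] - t[0]
    kf = fit.k_fast
    if not np.isfinite(kf) or kf <= 0:
        return fit
    dt = max(float(np.median(np.diff(t))), 1e-9)

    def window_estimate(window, fixed_k=None):
        m = t <= t[0] + window
        if m.sum() < 30:
            return None
        tt, yy = t[m] - t[0], y[m]
        w = 1.0 / np.sqrt(tt + 0.1)
        ones = np.ones_like(tt)

        def wsse(k):
            A = np.column_stack([ones, 1.0 - np.exp(-k * tt), tt]) * w[:, None]
            coef, *_ = np.linalg.lstsq(A, yy * w, rcond=None)
            return float(np.sum((A @ coef - yy * w) ** 2)), coef

        if fixed_k is not None:
            return fixed_k, wsse(fixed_k)[1]
        grid = np.geomspace(0.4 / window, 0.5 / dt, 50)
        sses = [wsse(k)[0] for k in grid]
        i = int(np.argmin(sses))
        k_best = grid[i]
        if 0 < i < grid.size - 1:
            try:
                opt = minimize_scalar(
                    lambda lk: wsse(np.exp(lk))[0],
                    bracket=(np.log(grid[i - 1]), np.log(k_best),
                             np.log(grid[i + 1])))
                k_best = float(np.exp(opt.x))
            except ValueError:
                pass
        return k_best, wsse(k_best)[1]

    # three windows spanning plausible fast-phase durations; the median
    # vote is robust to any single window landing on a slow-phase optimum.
    # Windows scale with the sampling interval (50-120 samples) and widen
    # if the joint fit suggests a slower fast phase.
    scale = max(1.0, 4.0 / (kf * 80.0 * dt)) if kf * 80.0 * dt < 4.0 else 1.0
    estimates = []
    for window in (50.0 * dt * scale, 80.0 * dt * scale, 120.0 * dt * scale):
        out = window_estimate(float(np.clip(window, 30.0 * dt, span / 4.0)))
        if out is not None:
            estimates.append(out)
    if not estimates:
        return fit
    estimates.sort(key=lambda e: e[0])
    kf = estimates[len(estimates) // 2][0]
    if not kf > fit.k_slow:
        return fit
    # re-solve the amplitude at the chosen rate over ~48 time constants:
    # long enough that the saturated fast phase anchors the amplitude
    # against the local linear slow-phase/drift term
    out = window_estimate(float(np.clip(48.0 / kf, 30.0 * dt, span / 4.0)),
                          fixed_k=kf)
    if out is None:
        return fit
    return replace(fit, k_fast=kf, dx_fast=float(out[1][1]) / n_nt,
                   flags=fit.flags + ("fast_phase_refined",))


def fit_compaction(trace: Trace, model: str = "auto", sign: str = None,
                   drift: bool = False,
                   polymer: PolymerParams = PolymerParams()) -> PhaseFit:
    """Fit the biphasic exponential to a constant-force trace.

    Parameters
    ----------
    model : {'1-exp', '2-exp', 'auto'}
        ``auto`` compares the two by small-sample-corrected AIC and keeps
        the extra phase only if it improves AICc by more than 2.
    sign : {None, 'same', 'opposite'}
        Constrain phase amplitudes: ``same`` for 5 pN compaction (both
        negative expected), ``opposite`` for the 30 pN binding signature
        (fast compaction, slow elongation).
    drift : bool
        Include a free linear baseline term (for traces carrying
        uncorrected instrument drift).

    Raises
    ------
    RuntimeError
        If no multi-start attempt converges.
    """
    if len(trace) < 50:
        raise ValueError(f"need >= 50 samples to fit, got {len(trace)}")
    if model not in ("1-exp", "2-exp", "auto"):
        raise ValueError(f"unknown model {model!r}")
    t = trace.time - trace.time[0]
    y = trace.extension.astype(float)
    # log-time resampling: equal leverage per time decade, so a short fast
    # phase is not outvoted by hours of slow-phase samples.  Same-sign
    # compaction records carry slow correlated occupancy noise and are
    # thinned hard (their fast phase is re-estimated separately); the
    # opposite-sign signatures are white-noise dominated and keep density.
    t, y = _log_resample(t, y, per_decade=60 if sign == "same" else 400)
    results = {}
    for n_exp in (1, 2):
        if model == "1-exp" and n_exp == 2:
            continue
        if model == "2-exp" and n_exp == 1:
            continue
        res = _fit_multistart(t, y, n_exp, drift, sign if n_exp == 2 else None)
        if res is not None:
            results[n_exp] = res
    if not results:
        raise RuntimeError(
            "exponential fit failed to converge after multi-start; "
            f"n={len(trace)}, span={t[-1]:.1f}s")
    if len(results) == 2:
        n = t.size
        # parsimony: keep the second phase only if it earns its parameters
        choice = 2 if _aicc(results[2], n) < _aicc(results[1], n) - 2.0 else 1
    else:
        choice = next(iter(results))
    fit = _result_to_fit(results[choice], choice, trace, drift)
    if sign == "same" and fit.model == "2-exp" and (
            fit.k_fast <= 5.5 * fit.k_slow) and t[-1] * fit.k_slow > 3.0:
        # the ratio sits at its lower bound: a degenerate merged-phase
        # optimum.  Refit with the phases forced apart and flag it.
        res = _fit_multistart(t, y, 2, drift, sign, min_ratio=25.0)
        if res is not None:
            fit = _result_to_fit(res, 2, trace, drift)
            fit = replace(fit, flags=fit.flags + ("rate_separation_enforced",))
    if (fit.model == "2-exp"
            and (sign == "same" or fit.k_fast >= 20.0 * fit.k_slow)
            and fit.residual_rms * trace.metadata.get("substrate_nt", 1)
            > 0.01 * abs(fit.dx_fast) * trace.metadata.get("substrate_nt", 1)):
        fit = _refine_fast_phase(trace.time, trace.extension, fit,
                                 trace.metadata.get("substrate_nt", 1))
    if sign == "opposite" and fit.model == "2-exp" and not (
            fit.dx_fast < 0 < fit.dx_slow):
        fit = replace(fit, flags=fit.flags + ("sign_pattern_not_met",))
    return fit


def fit_dissociation(trace: Trace, drift: bool = False, detrend: bool = True,
                     polymer: PolymerParams = PolymerParams()) -> PhaseFit:
    """Fit the two-phase dissociation signature after the buffer swap.

    Expects a fast negative (re-compaction) and a slow positive
    (elongation) amplitude; if that sign pattern cannot be achieved the
    unconstrained fit is returned with a ``sign_pattern_relaxed`` flag.
    A near-flat trace is flagged ``degenerate``.  By default the linear
    instrument drift is estimated on the final quarter of the record
    (where the slow phase has saturated) and subtracted before fitting.
    """
    n_nt = trace.metadata.get("substrate_nt", 1)
    spread = trace.extension.std()
    noise = trace.metadata.get("noise", {}).get("sigma", 0.0)
    if spread <= max(1.5 * noise, 1e-9):
        return PhaseFit(dx_fast=0.0, k_fast=np.nan, dx_slow=0.0,
                        k_slow=np.nan, model="degenerate",
                        protocol=trace.metadata.get("protocol", ""),
                        flags=("degenerate",))
    if detrend and not drift and len(trace) >= 200:
        t, y = trace.time, trace.extension
        m = t >= t[0] + 0.75 * (t[-1] - t[0])
        slope = np.polyfit(t[m], y[m], 1)[0]
        trace = trace.copy()
        trace.extension = y - slope * (t - t[0])
    try:
        fit = fit_compaction(trace, model="2-exp", sign="opposite",
                             drift=drift, polymer=polymer)
    except RuntimeError:
        fit = fit_compaction(trace, model="2-exp", sign=None, drift=drift,
                             polymer=polymer)
        fit = replace(fit, flags=fit.flags + ("sign_pattern_relaxed",))
    return fit


# ---------------------------------------------------------------------------
# step detection

def _robust_sigma(y: np.ndarray) -> float:
    """Noise s.d. from the median absolute successive difference."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (0.6745 * np.sqrt(2.0)))


def _binseg(y, i0, i1, penalty, min_seg, out):
    """Recursive binary segmentation minimizing within-segment SSE."""
    n = i1 - i0
    if n < 2 * min_seg:
        return
    seg = y[i0:i1]
    csum = np.cumsum(seg)
    total = csum[-1]
    k = np.arange(min_seg, n - min_seg + 1)
    left_mean = csum[k - 1] / k
    right_mean = (total - csum[k - 1]) / (n - k)
    # SSE reduction of splitting at k: between-group sum of squares
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    j = int(np.argmax(gain))
    if gain[j] > penalty:
        split = i0 + k[j]
        out.append(split)
        _binseg(y, i0, split, penalty, min_seg, out)
        _binseg(y, split, i1, penalty, min_seg, out)


def detect_steps(trace: Trace, min_size: float = 20.0,
                 min_segment_s: float = 1.0) -> list:
    """Detect discrete extension steps in a constant-force hold.

    Binary-segmentation change-point search on the extension mean; the
    split penalty is calibrated from the robust noise floor, and only
    mean shifts with |size| >= ``min_size`` nm are reported.

    Returns a time-ordered list of :class:`StepEvent`.
    """
    y = trace.extension.astype(float)
    if y.size < 10:
        return []
    dt = np.median(np.diff(trace.time)) if y.size > 1 else 1.0
    min_seg = max(3, int(round(min_segment_s / dt)))
    sigma = _robust_sigma(y)
    penalty = max(10.0 * sigma**2 * np.log(y.size), 1e-12)
    splits: list = []
    _binseg(y, 0, y.size, penalty, min_seg, splits)
    splits = sorted(splits)
    events = []
    bounds = [0] + splits + [y.size]
    means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    for i, s in enumerate(splits):
        size = means[i + 1] - means[i]
        if abs(size) >= min_size:
            w = min(bounds[i + 2] - s, s - bounds[i])
            conf = abs(size) / (sigma * np.sqrt(2.0 / max(w, 1)) + 1e-12)
            events.append(StepEvent(time=float(trace.time[s]),
                                    size=float(size), confidence=float(conf)))
    return events


# ---------------------------------------------------------------------------
# cycle analysis and aggregation

def extension_at_force(trace: Trace, query_force: float,
                       segment: str) -> float:
    """Relative extension at a query force on a stretch or release ramp.

    Linearly interpolates the ``ext_relative`` channel (added by
    :func:`normalize_extension`) against force within the named segment.
    """
    if segment not in ("stretch", "release"):
        raise ValueError("segment must be 'stretch' or 'release'")
    if "ext_relative" not in trace.channels:
        trace = normalize_extension(trace)
    t0, t1 = trace.segment_bounds(segment)
    sub = trace.window(t0, t1)
    f, x = sub.force, sub.channels["ext_relative"]
    if f.size < 2 or not (f.min() <= query_force <= f.max()):
        raise ValueError(
            f"{segment} segment does not cross {query_force} pN "
            f"(range {f.min():.2f}-{f.max():.2f})")
    order = np.argsort(f, kind="stable")
    return float(np.interp(query_force, f[order], x[order]))


def aggregate_replicates(fits: list) -> PhaseFit:
    """Parameter-wise mean and SEM over replicate fits of one protocol."""
    if len(fits) < 2:
        raise ValueError("need >= 2 replicate fits to aggregate")
    protocols = {f.protocol for f in fits}
    if len(protocols) > 1:
        raise ValueError(f"cannot aggregate fits of mixed protocols: {protocols}")
    usable = [f for f in fits if f.model != "degenerate"]
    if not usable:
        raise ValueError("all replicate fits are degenerate")

    def mean_sem(values):
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            return np.nan, np.nan
        sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        return float(v.mean()), float(sem)

    out, err = {}, {}
    for name in ("dx_fast", "k_fast", "dx_slow", "k_slow"):
        out[name], err[name] = mean_sem([getattr(f, name) for f in usable])
    model = "2-exp" if all(f.model == "2-exp" for f in usable) else "mixed"
    flags = tuple(sorted({fl for f in usable for fl in f.flags}))
    return PhaseFit(dx_fast=out["dx_fast"], k_fast=out["k_fast"],
                    dx_slow=out["dx_slow"], k_slow=out["k_slow"],
                    model=model, stderr=err,
                    residual_rms=float(np.nanmean([f.residual_rms
                                                   for f in usable])),
                    n_replicates=len(usable),
                    protocol=fits[0].protocol, flags=flags)
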