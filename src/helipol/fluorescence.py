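"""Stopped-flow FRET traces: averaging, multi-exponential fits, quench curves.

Presteady-state traces report donor-sensitized acceptor emission while the
helicase loads onto and translocates along a fork substrate.  Traces are
acquired on a split time base (dense early sampling for the fast
binding/loading phase, sparse late sampling for the slow translocation
phase) and fit jointly to a sum of exponentials

    v(t) = sum_i a_i * exp(-k_i * t) + C

with signed amplitudes.  Sign convention, fixed throughout the package:
a_i < 0 is a signal INCREASE over time (the exponential relaxes upward to
C), a_i > 0 a decrease.  Phases are reported with rates in descending
order, so phase 0 is the fast (binding) phase and the last phase is the
slow (translocation / dissociation) phase whose direction carries the
orientation information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal, Optional, Sequence

import numpy as np
import lmfit


class FluorescenceError(ValueError):
    pass


class LabelSite(str, Enum):
    N_TERMINUS = "N_terminus"
    C682 = "C682"


class SubstrateClass(str, Enum):
    FORK_3LONG = "fork_3long"
    FORK_5LONG = "fork_5long"
    SSDNA_3TAIL = "ssDNA_3tail"
    SSDNA_5TAIL = "ssDNA_5tail"


@dataclass(frozen=True)
class ConditionDescriptor:
    """One stopped-flow experimental condition."""

    label_site: LabelSite
    block: bool                       # streptavidin roadblock present
    substrate_class: SubstrateClass
    atp: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "label_site", LabelSite(self.label_site))
        object.__setattr__(self, "substrate_class", SubstrateClass(self.substrate_class))

    def key(self) -> str:
        return (
            f"{self.label_site.value}|{'block' if self.block else 'noblock'}|"
            f"{self.substrate_class.value}|{'ATP' if self.atp else 'noATP'}"
        )


@dataclass(frozen=True)
class FluorTrace:
    """One (possibly averaged) stopped-flow fluorescence trace."""

    time: np.ndarray                  # seconds, strictly increasing
    signal: np.ndarray                # arbitrary units
    segment: np.ndarray               # split-time-base segment id per point
    condition: Optional[ConditionDescriptor] = None
    point_variance: Optional[np.ndarray] = None  # set by average_traces

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.signal, dtype=float)
        seg = np.asarray(self.segment, dtype=int)
        if not (t.shape == v.shape == seg.shape):
            raise FluorescenceError("time, signal, segment must have equal length")
        if t.size < 50:
            raise FluorescenceError(f"trace too short ({t.size} points; need >= 50)")
        if np.any(np.diff(t) <= 0):
            raise FluorescenceError("time must be strictly increasing across segments")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", v)
        object.__setattr__(self, "segment", seg)

    def __len__(self) -> int:
        return self.time.size


class PhaseDirection(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    FLAT = "flat"


@dataclass(frozen=True)
class Phase:
    amplitude: float                  # signed; < 0 means signal increase
    rate: float                       # s^-1
    amplitude_se: float
    rate_se: float

    @property
    def direction(self) -> PhaseDirection:
        return PhaseDirection.INCREASE if self.amplitude < 0 else PhaseDirection.DECREASE


@dataclass(frozen=True)
class MultiExpFit:
    n_exp: int
    phases: tuple[Phase, ...]         # rates descending: phases[0] fastest
    offset: float
    offset_se: float
    rss: float                        # weighted residual sum of squares
    n_points: int
    aicc: float
    degenerate: bool = False          # rate collapse (adjacent k ratio < 3)

    @property
    def fast_phase(self) -> Phase:
        return self.phases[0]

    @property
    def slow_phase(self) -> Phase:
        return self.phases[-1]

    def to_dict(self) -> dict:
        return {
            "n_exp": self.n_exp,
            "phases": [
                {
                    "amplitude": p.amplitude, "amplitude_se": p.amplitude_se,
                    "rate_per_s": p.rate, "rate_se_per_s": p.rate_se,
                    "direction": p.direction.value,
                }
                for p in self.phases
            ],
            "offset": self.offset, "offset_se": self.offset_se,
            "rss": self.rss, "aicc": self.aicc, "degenerate": self.degenerate,
        }


def multi_exp_curve(
    t: np.ndarray, amplitudes: Sequence[float], rates: Sequence[float], offset: float
) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    v = np.full_like(t, offset, dtype=float)
    for a, k in zip(amplitudes, rates):
        v += a * np.exp(-k * t)
    return v


def average_traces(traces: Sequence[FluorTrace]) -> FluorTrace:
    """Pointwise mean of replicate traces on identical time grids.

    Per-point variance across replicates is retained as weight metadata for
    downstream fitting.  Conditions (when present) must match.
    """
    if len(traces) < 2:
        raise FluorescenceError("need >= 2 traces to average")
    ref = traces[0]
    for tr in traces[1:]:
        if len(tr) != len(ref) or not np.allclose(tr.time, ref.time):
            raise FluorescenceError("traces are not on identical time grids")
        if tr.condition != ref.condition:
            raise FluorescenceError("traces have mismatched conditions")
    stack = np.vstack([tr.signal for tr in traces])
    return FluorTrace(
        time=ref.time.copy(),
        signal=stack.mean(axis=0),
        segment=ref.segment.copy(),
        condition=ref.condition,
        point_variance=stack.var(axis=0, ddof=1),
    )


def _density_weights(trace: FluorTrace) -> np.ndarray:
    """Per-point weights inversely proportional to local sampling density.

    Each split-time-base segment gets total weight proportional to the time
    span it covers, so a dense early segment cannot dominate the fit of the
    slow phase.  Normalized to mean 1.
    """
    w = np.empty(len(trace))
    for seg_id in np.unique(trace.segment):
        mask = trace.segment == seg_id
        t_seg = trace.time[mask]
        span = float(t_seg[-1] - t_seg[0]) if t_seg.size > 1 else 1.0
        w[mask] = span / max(t_seg.size, 1)
    return w / w.mean()


def _linear_amplitudes(
    t: np.ndarray, v: np.ndarray, w: np.ndarray, rates: Sequence[float]
) -> tuple[np.ndarray, float, float]:
    """Weighted linear LS for amplitudes + offset at fixed rates; returns (a, C, wrss)."""
    cols = [np.exp(-k * t) for k in rates] + [np.ones_like(t)]
    design = np.column_stack(cols)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], v * sw, rcond=None)
    resid = v - design @ coef
    return coef[:-1], float(coef[-1]), float(np.sum(w * resid**2))


def _grid_init(
    t: np.ndarray, v: np.ndarray, w: np.ndarray, n_exp: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Coarse log-grid search over rate combinations, amplitudes by linear LS."""
    t_pos = t[t > 0]
    k_lo = 0.5 / float(t[-1])
    k_hi = 2.0 / float(t_pos[0])
    grid = np.geomspace(k_lo, k_hi, 16)
    candidates = []
    for combo in itertools.combinations(grid, n_exp):
        # near-equal rate pairs can cancel into a degenerate local minimum
        if any(combo[i + 1] / combo[i] < 5.0 for i in range(n_exp - 1)):
            continue
        amps, offset, wrss = _linear_amplitudes(t, v, w, combo)
        candidates.append((wrss, np.asarray(combo, dtype=float), np.append(amps, offset)))
    candidates.sort(key=lambda c: c[0])

    # polish a handful of structurally distinct candidates: the coarse grid
    # can misplace a rate by ~1.5x, which on a long heavily-weighted slow
    # segment costs more than an entire unresolved fast phase, so the raw
    # best combo is not always in the right valley
    kept: list[tuple[float, np.ndarray, np.ndarray]] = []
    for wrss, rates, amps_c in candidates:
        if any(
            np.all(np.maximum(rates / k2, k2 / rates) < 4.0)
            for _, k2, _ in kept
        ):
            continue
        kept.append((wrss, rates, amps_c))
        if len(kept) >= 6:
            break

    def _polish(rates, amps_c, wrss):
        for _ in range(2):
            for i in range(n_exp):
                for k in rates[i] * np.geomspace(1 / 3.0, 3.0, 25):
                    trial = rates.copy()
                    trial[i] = k
                    srt = np.sort(trial)
                    if np.any(srt[1:] / srt[:-1] < 3.0):
                        continue
                    amps_t, off_t, wrss_t = _linear_amplitudes(t, v, w, trial)
                    if wrss_t < wrss:
                        rates, amps_c, wrss = trial, np.append(amps_t, off_t), wrss_t
        return rates, amps_c, wrss

    best = None
    for wrss, rates, amps_c in kept:
        polished = _polish(rates.copy(), amps_c, wrss)
        if best is None or polished[2] < best[2]:
            best = polished
    return best


def fit_multi_exponential(trace: FluorTrace, n_exp: int) -> MultiExpFit:
    """Weighted least-squares fit of 1-3 exponentials across all segments.

    Initialization is a coarse log-spaced grid search over rate
    combinations with amplitudes solved linearly, followed by nonlinear
    refinement.  Rate collapse (adjacent fitted rates within a factor of 3)
    flags the fit degenerate rather than failing.
    """
    if n_exp not in (1, 2, 3):
        raise FluorescenceError("n_exp must be 1, 2, or 3")
    t, v = trace.time, trace.signal
    w = _density_weights(trace)
    k_min_needed = 1.0 / float(t[-1])

    rates0, amps_c0, _ = _grid_init(t, v, w, n_exp)

    def model_fn(t, **p):
        amps = [p[f"a{i}"] for i in range(n_exp)]
        rates = [p[f"k{i}"] for i in range(n_exp)]
        return multi_exp_curve(t, amps, rates, p["c"])

    model = lmfit.Model(model_fn)
    params = lmfit.Parameters()
    order = np.argsort(rates0)[::-1]
    for i in range(n_exp):
        params.add(f"a{i}", value=float(amps_c0[order[i]]))
        params.add(f"k{i}", value=float(rates0[order[i]]), min=k_min_needed * 1e-3)
    params.add("c", value=float(amps_c0[-1]))
    result = model.fit(v, params, t=t, weights=np.sqrt(w))
    if not result.success:
        raise FluorescenceError(f"{n_exp}-exponential fit failed: {result.message}")

    def _se(p):
        return float(p.stderr) if p.stderr is not None else float("nan")

    phases = [
        Phase(
            amplitude=float(result.params[f"a{i}"].value),
            rate=float(result.params[f"k{i}"].value),
            amplitude_se=_se(result.params[f"a{i}"]),
            rate_se=_se(result.params[f"k{i}"]),
        )
        for i in range(n_exp)
    ]
    phases.sort(key=lambda p: p.rate, reverse=True)
    degenerate = any(
        phases[i].rate / max(phases[i + 1].rate, 1e-300) < 3.0
        for i in range(n_exp - 1)
    )
    wrss = float(np.sum(w * result.residual**2))
    n = t.size
    n_par = 2 * n_exp + 1
    aicc = n * np.log(max(wrss, 1e-300) / n) + 2 * n_par
    if n - n_par - 1 > 0:
        aicc += 2 * n_par * (n_par + 1) / (n - n_par - 1)
    return MultiExpFit(
        n_exp=n_exp,
        phases=tuple(phases),
        offset=float(result.params["c"].value),
        offset_se=_se(result.params["c"]),
        rss=wrss,
        n_points=n,
        aicc=float(aicc),
        degenerate=degenerate,
    )


def _phases_supported(fit: MultiExpFit) -> bool:
    """Every phase resolved: rates separated and amplitudes > 2 SE."""
    if fit.degenerate:
        return False
    for p in fit.phases:
        if not np.isfinite(p.amplitude_se) or abs(p.amplitude) <= 2.0 * p.amplitude_se:
            return False
    return True


def select_exponential_order(
    trace: FluorTrace,
    criterion: Literal["aicc", "ftest"] = "aicc",
    max_order: int = 3,
) -> tuple[int, dict[int, MultiExpFit]]:
    """Fit orders 1..max_order and select the supported model.

    A higher order is accepted only if its information criterion (or
    F-test at alpha = 0.01) improves on the current choice AND every phase
    is resolved — rates separated >= 3-fold and each amplitude exceeding
    twice its standard error.  Order 1 is always available as the fallback.
    """
    fits: dict[int, MultiExpFit] = {}
    for order in range(1, max_order + 1):
        try:
            fits[order] = fit_multi_exponential(trace, order)
        except FluorescenceError:
            break
    chosen = 1
    for order in range(2, max_order + 1):
        if order not in fits or not _phases_supported(fits[order]):
            continue
        lo, hi = fits[chosen], fits[order]
        if criterion == "aicc":
            if hi.aicc < lo.aicc:
                chosen = order
        else:
            d_par = 2 * (order - chosen)
            dof = hi.n_points - (2 * order + 1)
            if hi.rss < lo.rss and dof > 0:
                f_stat = ((lo.rss - hi.rss) / d_par) / (hi.rss / dof)
                from scipy import stats
                if stats.f.sf(f_stat, d_par, dof) < 0.01:
                    chosen = order
    return chosen, fits


def normalize_quench(
    concentrations: Sequence[float],
    signal_labelled: Sequence[float],
    signal_unlabelled: Sequence[float],
) -> np.ndarray:
    """Background-corrected normalized quench vs titrant concentration.

    The drift seen on adding unlabelled protein is subtracted from the
    labelled-protein series before normalizing to the zero-protein signal:

        quench(c) = 1 - [S_lab(c) - (S_unlab(c) - S_unlab(0))] / S_lab(0)

    so quench(0) = 0 and a fully quenched reporter gives 1.
    """
    c = np.asarray(concentrations, dtype=float)
    s_lab = np.asarray(signal_labelled, dtype=float)
    s_unlab = np.asarray(signal_unlabelled, dtype=float)
    if not (c.shape == s_lab.shape == s_unlab.shape):
        raise FluorescenceError("quench series must share one concentration grid")
    if s_lab[0] <= 0:
        raise FluorescenceError("zero-concentration labelled signal must be positive")
    background = s_unlab - s_unlab[0]
    return 1.0 - (s_lab - background) / s_lab[0]
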