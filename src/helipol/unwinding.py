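"""Single-turnover unwinding: fraction unwound and single-exponential fits.

In a single-turnover experiment the helicase is prebound, then ATP and a
large excess of unlabelled trap DNA are added simultaneously so each
hexamer gets one chance to unwind.  The single-strand / duplex gel band
intensities are normalized between the zero-time and boiled (fully
denatured) controls,

    F(t) = [r(t) - r(0)] / [r(b) - r(0)],    r = Is / (Is + Id),

and F(t) is fit to a rising single exponential F(t) = Af * (1 - exp(-k t)).
The amplitude Af is the fraction of hexamers bound in a productive,
processive configuration; k is the unwinding rate in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import lmfit

MIN_TO_S = 1.0 / 60.0


def per_min_to_per_s(k_per_min: float) -> float:
    """Convert a rate in 1/min to 1/s (0.07 min^-1 -> 1.1667e-3 s^-1)."""
    return k_per_min * MIN_TO_S


def per_s_to_per_min(k_per_s: float) -> float:
    return k_per_s * 60.0


class UnwindingError(ValueError):
    pass


class NormalizationError(UnwindingError):
    pass


class DegenerateFitError(UnwindingError):
    pass


@dataclass(frozen=True)
class BandTimeCourse:
    """Gel band intensities of one unwinding time course.

    ``times`` in minutes (must include 0 and be strictly increasing);
    ``i_ss`` / ``i_ds`` are single-strand and duplex band intensities at
    each time; the boiled-control row is stored separately.
    """

    substrate: str
    times: np.ndarray
    i_ss: np.ndarray
    i_ds: np.ndarray
    i_ss_boiled: float
    i_ds_boiled: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        i_ss = np.asarray(self.i_ss, dtype=float)
        i_ds = np.asarray(self.i_ds, dtype=float)
        if not (times.shape == i_ss.shape == i_ds.shape):
            raise UnwindingError("times, Is, Id must have equal length")
        if times.size < 2 or times[0] != 0.0:
            raise UnwindingError("time course must start at t = 0")
        if np.any(np.diff(times) <= 0):
            raise UnwindingError("times must be strictly increasing")
        if np.any(i_ss < 0) or np.any(i_ds < 0) or self.i_ss_boiled < 0 or self.i_ds_boiled < 0:
            raise UnwindingError("band intensities must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "i_ss", i_ss)
        object.__setattr__(self, "i_ds", i_ds)


@dataclass(frozen=True)
class UnwindingFit:
    """Result of the single-exponential amplitude/rate fit."""

    amplitude: float          # productive fraction, in [0, 1]
    k: float                  # 1/min
    amplitude_se: float
    k_se: float
    rss: float
    n_points: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "amplitude_se": self.amplitude_se,
            "k_per_min": self.k,
            "k_se_per_min": self.k_se,
            "k_per_s": per_min_to_per_s(self.k),
            "rss": self.rss,
            "n_points": self.n_points,
            "degenerate": self.degenerate,
        }


def _ratio(i_ss: np.ndarray, i_ds: np.ndarray) -> np.ndarray:
    total = i_ss + i_ds
    if np.any(total <= 0):
        raise NormalizationError("Is + Id must be positive in every row")
    return i_ss / total


def fraction_unwound(tc: BandTimeCourse) -> tuple[np.ndarray, np.ndarray]:
    """Normalize band intensities to fraction unwound.

    Returns ``(times, F)`` with F(0) = 0 exactly.  Values may fall slightly
    outside [0, 1] from band noise; they are reported un-clamped so the fit
    sees unbiased residuals.
    """
    r = _ratio(tc.i_ss, tc.i_ds)
    r0 = r[0]
    rb = _ratio(np.array([tc.i_ss_boiled]), np.array([tc.i_ds_boiled]))[0]
    denom = rb - r0
    if denom <= 0:
        raise NormalizationError(
            "boiled-control single-strand ratio must exceed the zero-time ratio "
            f"(r(b)={rb:.4f}, r(0)={r0:.4f})"
        )
    return tc.times.copy(), (r - r0) / denom


def fit_single_exponential(
    times: Sequence[float], f: Sequence[float]
) -> UnwindingFit:
    """Least-squares fit of F(t) = Af * (1 - exp(-k t)).

    This is the C + A*exp(-k t) single-exponential with C = Af and A = -Af,
    so the reported amplitude is directly the productive fraction.  Bounds:
    0 <= Af <= 1, k > 0.  A flat series (max |F| below noise scale) is
    returned flagged degenerate with amplitude ~0 and an unidentifiable k.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.size != f.size or t.size < 4:
        raise UnwindingError("need >= 4 (time, F) points to fit")

    fmax = float(np.max(np.abs(f)))
    if fmax < 1e-6:
        return UnwindingFit(
            amplitude=0.0, k=float("nan"), amplitude_se=0.0, k_se=float("nan"),
            rss=float(np.sum(f**2)), n_points=t.size, degenerate=True,
        )

    # initial guesses: amplitude from the plateau, rate from time of half-max
    af0 = min(max(float(np.max(f)), 1e-3), 1.0)
    above = t[f >= af0 / 2.0]
    t_half = float(above[0]) if above.size else float(t[-1]) / 2.0
    k0 = np.log(2.0) / max(t_half, t[1] if t[1] > 0 else 1.0)

    model = lmfit.Model(lambda t, af, k: af * (1.0 - np.exp(-k * t)))
    params = model.make_params(
        af={"value": af0, "min": 0.0, "max": 1.0},
        k={"value": k0, "min": 1e-8},
    )
    result = model.fit(f, params, t=t)
    if not result.success:
        raise UnwindingError(
            f"single-exponential fit failed ({result.message}); "
            f"initial guesses af={af0:.3g}, k={k0:.3g}"
        )
    af = result.params["af"]
    k = result.params["k"]
    return UnwindingFit(
        amplitude=float(af.value),
        k=float(k.value),
        amplitude_se=float(af.stderr) if af.stderr is not None else float("nan"),
        k_se=float(k.stderr) if k.stderr is not None else float("nan"),
        rss=float(np.sum(result.residual**2)),
        n_points=t.size,
    )


def fit_timecourse(tc: BandTimeCourse) -> UnwindingFit:
    """Normalize a band time course and fit the single exponential."""
    t, f = fraction_unwound(tc)
    return fit_single_exponential(t, f)


def productive_fraction(fit: UnwindingFit) -> tuple[float, float]:
    """The fitted amplitude, labelled as the productive-complex fraction."""
    if fit.degenerate:
        raise DegenerateFitError(
            "fit is degenerate (no unwinding signal); productive fraction undefined"
        )
    return fit.amplitude, fit.amplitude_se
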