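"""Equilibrium binding: Hill fits of fluorescence-anisotropy titrations.

Anisotropy of a dye-labelled DNA substrate rises as helicase binds; the
titration is fit to the cooperative (Hill) isotherm

    Y = Amax * [P]^n / (Kd^n + [P]^n)

with [P] the hexamer-equivalent protein concentration (nM), Amax the
saturating anisotropy amplitude (free-DNA baseline subtracted before the
fit, since the isotherm has no offset term), Kd the half-saturation
concentration and n the Hill cooperativity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit


class BindingError(ValueError):
    pass


class IdentifiabilityError(BindingError):
    """Titration does not bracket the half-saturation region."""


@dataclass(frozen=True)
class TitrationSeries:
    """One anisotropy titration: concentrations (nM) vs baseline-subtracted anisotropy."""

    concentrations: np.ndarray
    anisotropy: np.ndarray
    replicate: str = "r1"

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.anisotropy, dtype=float)
        if conc.size == 0:
            raise BindingError("empty titration")
        if conc.shape != y.shape:
            raise BindingError("concentration and anisotropy vectors differ in length")
        if np.any(conc < 0):
            raise BindingError("concentrations must be non-negative")
        if np.any(np.diff(conc) <= 0):
            raise BindingError("concentrations must be strictly increasing")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "anisotropy", y)


@dataclass(frozen=True)
class HillFit:
    amax: float
    kd: float           # nM
    n: float            # Hill coefficient
    amax_se: float
    kd_se: float
    n_se: float
    rss: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "Amax": self.amax, "Amax_se": self.amax_se,
            "Kd_nM": self.kd, "Kd_se_nM": self.kd_se,
            "hill_n": self.n, "hill_n_se": self.n_se,
            "rss": self.rss, "n_points": self.n_points,
        }


def hill_curve(conc: np.ndarray, amax: float, kd: float, n: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        xn = np.where(conc > 0, conc, 0.0) ** n
    return amax * xn / (kd**n + xn)


def fit_hill(series: TitrationSeries) -> HillFit:
    """Fit the Hill isotherm to a titration.

    n is fitted freely within [0.25, 8] — wide enough for the cooperativity
    a hexamer can show, bounded to keep shallow titrations from diverging.
    A titration lying entirely below 20% or above 80% of its apparent
    saturation cannot pin Kd and is rejected.
    """
    conc, y = series.concentrations, series.anisotropy
    if conc.size < 5:
        raise BindingError("need >= 5 titration points to fit the Hill model")
    y_top = float(np.max(y))
    if y_top <= 0:
        raise BindingError("titration has no positive anisotropy signal")

    # initial guesses: plateau from the top point, Kd from half-saturation crossing
    kd0 = float(np.interp(0.5, y / y_top, conc))
    model = lmfit.Model(hill_curve, independent_vars=["conc"])
    params = model.make_params(
        amax={"value": y_top, "min": 0.0},
        kd={"value": max(kd0, conc[conc > 0].min()), "min": 1e-9},
        n={"value": 1.0, "min": 0.25, "max": 8.0},
    )
    result = model.fit(y, params, conc=conc)
    if not result.success:
        raise BindingError(f"Hill fit failed: {result.message}")

    # identifiability: the data must bracket half-saturation of the fitted plateau
    amax_fit = float(result.params["amax"].value)
    if amax_fit > 0:
        sat = hill_curve(conc[conc > 0], 1.0, float(result.params["kd"].value),
                         float(result.params["n"].value))
        if np.all(sat < 0.2) or np.all(sat > 0.8):
            raise IdentifiabilityError(
                "titration lies entirely below 20% or above 80% saturation of the "
                "fitted isotherm; Kd is unidentifiable"
            )

    def _se(p):
        return float(p.stderr) if p.stderr is not None else float("nan")

    return HillFit(
        amax=float(result.params["amax"].value),
        kd=float(result.params["kd"].value),
        n=float(result.params["n"].value),
        amax_se=_se(result.params["amax"]),
        kd_se=_se(result.params["kd"]),
        n_se=_se(result.params["n"]),
        rss=float(np.sum(result.residual**2)),
        n_points=conc.size,
    )
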