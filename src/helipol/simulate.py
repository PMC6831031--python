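"""Mechanistic synthetic-data generator with known ground truth.

A single binding-population model — probabilities over (arm x orientation)
configurations of a hexameric helicase on a fork substrate — drives all
four simulated data streams:

* footprint lane profiles: a cleavage kernel placed where the C-terminal
  probe of each configuration would cut, mixed by configuration
  probability, over a uniform background, with per-base lognormal lane
  noise;
* single-turnover unwinding time courses: a rising exponential whose true
  amplitude is the probability of the productive configuration under the
  chosen translocation rule;
* anisotropy titrations: a Hill isotherm plus Gaussian noise;
* stopped-flow FRET traces: two-phase exponentials whose slow-phase sign
  follows the label-site / roadblock / translocation-direction decision
  table.

Every generator takes a single integer seed and is bit-reproducible; each
emitted dataset can carry the :class:`TruthRecord` that generated it, so
pipeline stages have a parameter-recovery test surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .substrates import ForkSubstrate, LabelledStrand, RegionMap
from .footprint import LaneProfile
from .unwinding import BandTimeCourse
from .binding import TitrationSeries
from .fluorescence import ConditionDescriptor, FluorTrace, multi_exp_curve


class SimulationError(ValueError):
    pass


class Arm(str, Enum):
    ARM3 = "arm3"
    ARM5 = "arm5"


class Orientation(str, Enum):
    N_AT_DUPLEX = "N_at_duplex"
    C_AT_DUPLEX = "C_at_duplex"


class Direction(str, Enum):
    """Which hexamer face leads during translocation/unwinding."""

    N_FIRST = "N_first"
    C_FIRST = "C_first"


Configuration = tuple[Arm, Orientation]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class BindingPopulation:
    """Probability mixture over (arm x orientation) binding configurations."""

    probabilities: Mapping[Configuration, float]
    unbound: float = 0.0

    def __post_init__(self) -> None:
        probs = {
            (Arm(a), Orientation(o)): float(p)
            for (a, o), p in self.probabilities.items()
        }
        total = sum(probs.values()) + self.unbound
        if any(p < 0 or p > 1 for p in probs.values()) or not 0 <= self.unbound <= 1:
            raise SimulationError("all configuration probabilities must lie in [0, 1]")
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"probabilities + unbound must sum to 1, got {total}")
        object.__setattr__(self, "probabilities", probs)

    def prob(self, arm: Arm, orientation: Orientation) -> float:
        return self.probabilities.get((arm, orientation), 0.0)

    def aggregate_f_n(self, cross_strand_prob: float = 0.0, labelled_arm: Arm = Arm.ARM3) -> float:
        """Expected footprint F_N on the labelled strand (cross-strand cuts included)."""
        w = {Orientation.N_AT_DUPLEX: 0.0, Orientation.C_AT_DUPLEX: 0.0}
        for (arm, orient), p in self.probabilities.items():
            w[orient] += p if arm is labelled_arm else p * cross_strand_prob
        total = w[Orientation.N_AT_DUPLEX] + w[Orientation.C_AT_DUPLEX]
        if total <= 0:
            raise SimulationError("population places no cleavage mass on the labelled strand")
        return w[Orientation.N_AT_DUPLEX] / total

    def productive_fraction(self, rule: Direction) -> float:
        """Probability of the configuration that can unwind under ``rule``.

        The hexamer translocates 3'->5' on the encircled strand, so only
        3'-arm-loaded hexamers lead into the duplex; N_first means the
        N@duplex orientation of those is productive, C_first the C@duplex.
        """
        orient = (
            Orientation.N_AT_DUPLEX if rule is Direction.N_FIRST else Orientation.C_AT_DUPLEX
        )
        return self.prob(Arm.ARM3, orient)

    def to_dict(self) -> dict:
        return {
            "probabilities": {f"{a.value}:{o.value}": p for (a, o), p in self.probabilities.items()},
            "unbound": self.unbound,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BindingPopulation":
        probs = {}
        for key, p in d["probabilities"].items():
            a, o = key.split(":")
            probs[(Arm(a), Orientation(o))] = p
        return cls(probabilities=probs, unbound=d.get("unbound", 0.0))


def orientation_population(
    f_n: float, bound: float = 1.0, arm: Arm = Arm.ARM3
) -> BindingPopulation:
    """Population with all bound mass on one arm and F_N = ``f_n``."""
    if not 0 <= f_n <= 1 or not 0 < bound <= 1:
        raise SimulationError("f_n in [0,1] and bound in (0,1] required")
    return BindingPopulation(
        probabilities={
            (arm, Orientation.N_AT_DUPLEX): f_n * bound,
            (arm, Orientation.C_AT_DUPLEX): (1.0 - f_n) * bound,
        },
        unbound=1.0 - bound,
    )


@dataclass(frozen=True)
class ProbeModel:
    """Generative model of probe-proximal cleavage on the labelled strand.

    The hexamer occupies ``footprint_span`` nt; cleavage from the
    C-terminal probe lands in a discretized Gaussian of spread
    ``cleavage_sd`` centred ``probe_offset`` nt from the midpoint of the
    region its orientation maps to.  Hexamers on the non-labelled arm cut
    the labelled strand with probability ``cross_strand_prob`` (the probe
    domain is flexible enough to reach the other strand at the junction).
    ``signal_mass`` is the total cleavage density a fully-bound
    configuration deposits; ``background_rate`` the uniform per-base floor.
    """

    footprint_span: int = 24
    probe_offset: int = 0
    cleavage_sd: float = 2.5
    cross_strand_prob: float = 0.3
    background_rate: float = 1.0
    signal_mass: float = 200.0

    def __post_init__(self) -> None:
        if self.footprint_span <= 0:
            raise SimulationError("footprint_span must be positive")
        if self.cleavage_sd <= 0:
            raise SimulationError("cleavage_sd must be positive")
        if not 0 <= self.cross_strand_prob <= 1:
            raise SimulationError("cross_strand_prob must lie in [0, 1]")
        if self.background_rate < 0 or self.signal_mass <= 0:
            raise SimulationError("background_rate >= 0 and signal_mass > 0 required")


@dataclass
class TruthRecord:
    """Ground truth attached to every simulated dataset."""

    population: BindingPopulation
    productive_rule: Direction
    kinetics: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "population": self.population.to_dict(),
            "productive_rule": self.productive_rule.value,
            "kinetics": self.kinetics,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            population=BindingPopulation.from_dict(d["population"]),
            productive_rule=Direction(d["productive_rule"]),
            kinetics=d.get("kinetics", {}),
            seed=d.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# footprint lanes
# ---------------------------------------------------------------------------

def _kernel(center: float, sd: float, strand_len: int, window: tuple[int, int]) -> np.ndarray:
    """Discretized Gaussian over bases 1..strand_len, truncated to window, unit mass."""
    bases = np.arange(1, strand_len + 1, dtype=float)
    dens = np.exp(-0.5 * ((bases - center) / sd) ** 2)
    lo, hi = window
    dens[(bases < lo) | (bases > hi)] = 0.0
    total = dens.sum()
    if total <= 0:
        raise SimulationError(
            f"cleavage kernel centred at base {center:.1f} falls entirely outside "
            f"the single-strand window [{lo},{hi}]"
        )
    return dens / total


def simulate_cleavage_profiles(
    substrate: ForkSubstrate,
    regions: RegionMap,
    population: BindingPopulation,
    probe: ProbeModel = ProbeModel(),
    n_replicates: int = 5,
    noise_cv: float = 0.10,
    seed: int = 0,
) -> tuple[list[LaneProfile], LaneProfile, TruthRecord]:
    """Simulate replicate footprint lanes plus a background-only control.

    Returns ``(replicates, control, truth)``.  Lane noise is per-base
    lognormal with coefficient of variation ``noise_cv``; the control lane
    carries the same background and noise but no cleavage signal.
    """
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")
    if noise_cv < 0:
        raise SimulationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    strand_len = regions.strand_len
    window = (regions.n_region[0], regions.c_region[1])
    labelled_arm = (
        Arm.ARM3 if substrate.labelled_strand is LabelledStrand.ENCIRCLED_3ARM else Arm.ARM5
    )
    centers = {
        Orientation.N_AT_DUPLEX: (regions.n_region[0] + regions.n_region[1]) / 2.0
        + probe.probe_offset,
        Orientation.C_AT_DUPLEX: (regions.c_region[0] + regions.c_region[1]) / 2.0
        + probe.probe_offset,
    }

    clean = np.full(strand_len, probe.background_rate, dtype=float)
    for (arm, orient), p in population.probabilities.items():
        weight = p if arm is labelled_arm else p * probe.cross_strand_prob
        if weight <= 0:
            continue
        try:
            kern = _kernel(centers[orient], probe.cleavage_sd, strand_len, window)
        except SimulationError as exc:
            raise SimulationError(f"configuration ({arm.value}, {orient.value}): {exc}") from exc
        clean += probe.signal_mass * weight * kern

    def _noisy(profile: np.ndarray) -> np.ndarray:
        if noise_cv == 0:
            return profile.copy()
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=profile.size)
        return profile * factors

    lanes = [
        LaneProfile(
            substrate=substrate.name, replicate=f"rep{i + 1}", intensities=_noisy(clean)
        )
        for i in range(n_replicates)
    ]
    control = LaneProfile(
        substrate=substrate.name,
        replicate="control",
        intensities=_noisy(np.full(strand_len, probe.background_rate)),
        is_control=True,
    )
    try:
        aggregate = population.aggregate_f_n(probe.cross_strand_prob, labelled_arm)
    except SimulationError:
        aggregate = float("nan")  # nothing bound: no orientation fraction exists
    truth = TruthRecord(
        population=population,
        productive_rule=Direction.N_FIRST,
        kinetics={"aggregate_f_n": aggregate},
        seed=seed,
    )
    return lanes, control, truth


# ---------------------------------------------------------------------------
# single-turnover unwinding
# ---------------------------------------------------------------------------

DEFAULT_UNWINDING_TIMES = tuple(np.linspace(0.0, 240.0, 12))  # minutes


def simulate_unwinding_timecourse(
    population: BindingPopulation,
    productive_rule: Direction,
    k: float,
    times: Sequence[float] = DEFAULT_UNWINDING_TIMES,
    noise_sd: float = 0.02,
    seed: int = 0,
    substrate: str = "fork",
    total_signal: float = 100.0,
    leak: float = 5.0,
) -> tuple[BandTimeCourse, TruthRecord]:
    """Simulate a single-turnover unwinding band time course.

    The true fraction unwound is ``F(t) = p * (1 - exp(-k t))`` with ``p``
    the productive-configuration probability; band intensities are
    ``Is = F*S + leak`` and ``Id = (1-F)*S + leak`` with additive Gaussian
    noise of sd ``noise_sd * S``, so the normalization against the
    zero-time and boiled rows is exercised non-trivially.
    """
    if k <= 0:
        raise SimulationError("rate k must be positive")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    t = np.asarray(times, dtype=float)
    if t.size < 2 or t[0] != 0.0:
        raise SimulationError("times must start at 0")
    if np.any(np.diff(t) <= 0):
        raise SimulationError("times must be strictly increasing")
    rule = Direction(productive_rule)
    p = population.productive_fraction(rule)
    rng = np.random.default_rng(seed)

    f_true = p * (1.0 - np.exp(-k * t))
    i_ss = f_true * total_signal + leak
    i_ds = (1.0 - f_true) * total_signal + leak
    i_ss_b = 1.0 * total_signal + leak
    i_ds_b = 0.0 * total_signal + leak
    if noise_sd > 0:
        scale = noise_sd * total_signal
        i_ss = np.maximum(i_ss + rng.normal(0.0, scale, t.size), 0.0)
        i_ds = np.maximum(i_ds + rng.normal(0.0, scale, t.size), 0.0)
        i_ss_b = max(i_ss_b + rng.normal(0.0, scale), 0.0)
        i_ds_b = max(i_ds_b + rng.normal(0.0, scale), 0.0)

    tc = BandTimeCourse(
        substrate=substrate,
        times=t,
        i_ss=i_ss,
        i_ds=i_ds,
        i_ss_boiled=float(i_ss_b),
        i_ds_boiled=float(i_ds_b),
    )
    truth = TruthRecord(
        population=population,
        productive_rule=rule,
        kinetics={"amplitude": p, "k_per_min": k},
        seed=seed,
    )
    return tc, truth


# ---------------------------------------------------------------------------
# anisotropy titrations
# ---------------------------------------------------------------------------

def simulate_anisotropy_series(
    amax: float,
    kd: float,
    n: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Hill-isotherm anisotropy titration with additive Gaussian noise."""
    if kd <= 0 or n <= 0:
        raise SimulationError("Kd and Hill n must be positive")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise SimulationError("empty concentration list")
    if np.any(conc < 0):
        raise SimulationError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        y = amax * np.where(conc > 0, conc, 0.0) ** n / (kd**n + np.where(conc > 0, conc, 1.0) ** n)
    y = np.where(conc > 0, y, 0.0)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, conc.size)
    return TitrationSeries(concentrations=conc, anisotropy=y)


# ---------------------------------------------------------------------------
# stopped-flow traces
# ---------------------------------------------------------------------------

DEFAULT_TIMEBASE = ((10.0, 500), (300.0, 500))  # (t_end s, n_points) per segment


def make_split_timebase(
    segments: Sequence[tuple[float, int]] = DEFAULT_TIMEBASE,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample times and segment ids for a split time base.

    Each ``(t_end, n_points)`` segment is sampled uniformly from the end of
    the previous segment (time 0 for the first) up to ``t_end``.
    """
    times, seg_ids = [], []
    t_prev = 0.0
    for i, (t_end, n_points) in enumerate(segments):
        if t_end <= t_prev:
            raise SimulationError("timebase segment ends must be strictly increasing")
        if n_points < 2:
            raise SimulationError("each timebase segment needs >= 2 points")
        seg = np.linspace(t_prev, t_end, n_points + 1)[1:]  # open at the left edge
        times.append(seg)
        seg_ids.append(np.full(n_points, i, dtype=int))
        t_prev = t_end
    return np.concatenate(times), np.concatenate(seg_ids)


def emit_two_exp_trace(
    a1: float,
    k1: float,
    a2: float,
    k2: float,
    offset: float,
    timebase: Sequence[tuple[float, int]] = DEFAULT_TIMEBASE,
    noise_sd: float = 0.01,
    seed: int = 0,
    condition: Optional[ConditionDescriptor] = None,
) -> FluorTrace:
    """Generic two-exponential trace emitter (signed amplitudes; a < 0 rises).

    ``noise_sd`` is additive Gaussian noise in signal units (signals are
    generated on an O(1) scale, so 0.01 is 1% of full scale).
    """
    t, seg = make_split_timebase(timebase)
    rng = np.random.default_rng(seed)
    v = multi_exp_curve(t, [a1, a2], [k1, k2], offset)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, t.size)
    return FluorTrace(time=t, signal=v, segment=seg, condition=condition)


def slow_phase_direction(condition: ConditionDescriptor, truth_direction: Direction) -> int:
    """Slow-phase sign for a condition under the true translocation direction.

    Returns +1 (signal increase), -1 (decrease), or 0 (no slow phase).
    With the roadblock in place the helicase stalls near the reporter, so
    the slow phase rises iff the labelled face leads (N label under
    N-first, C682 label under C-first) and otherwise falls (dissociation).
    Without the block the helicase unwinds past the reporter and the slow
    phase falls for either label.  Without ATP there is no slow phase.
    """
    from .fluorescence import LabelSite

    if not condition.atp:
        return 0
    if condition.block:
        label_leads = (
            condition.label_site is LabelSite.N_TERMINUS
            and truth_direction is Direction.N_FIRST
        ) or (
            condition.label_site is LabelSite.C682
            and truth_direction is Direction.C_FIRST
        )
        return 1 if label_leads else -1
    return -1


def simulate_fret_trace(
    condition: ConditionDescriptor,
    truth_direction: Direction,
    fast: tuple[float, float],
    slow_rate: float,
    slow_amp: float = 0.4,
    timebase: Sequence[tuple[float, int]] = DEFAULT_TIMEBASE,
    noise_sd: float = 0.01,
    seed: int = 0,
    baseline: float = 1.0,
) -> tuple[FluorTrace, TruthRecord]:
    """Simulate one translocation/unwinding stopped-flow trace.

    The fast phase (``fast = (amplitude, rate s^-1)``) is always a signal
    increase — helicase binding — and the slow phase follows the
    label-site/block/direction decision table (:func:`slow_phase_direction`),
    with magnitude ``slow_amp``.  The trace starts at ``baseline``.
    """
    fast_amp, fast_rate = fast
    if fast_rate <= 0 or slow_rate <= 0:
        raise SimulationError("phase rates must be positive")
    if fast_amp < 0 or slow_amp < 0:
        raise SimulationError("phase amplitude magnitudes must be >= 0")
    truth_direction = Direction(truth_direction)
    sign = slow_phase_direction(condition, truth_direction)
    a1 = -fast_amp                       # binding: always an increase
    a2 = -sign * slow_amp                # a < 0 is an increase
    offset = baseline - a1 - a2          # v(0) = baseline
    trace = emit_two_exp_trace(
        a1, fast_rate, a2, slow_rate, offset,
        timebase=timebase, noise_sd=noise_sd, seed=seed, condition=condition,
    )
    truth = TruthRecord(
        population=orientation_population(1.0),
        productive_rule=truth_direction,
        kinetics={
            "fast_amp": fast_amp, "fast_rate_per_s": fast_rate,
            "slow_rate_per_s": slow_rate, "slow_sign": sign,
            "slow_amp": slow_amp,
        },
        seed=seed,
    )
    return trace, truth
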