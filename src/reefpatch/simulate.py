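"""Synthetic scored transects with controllable clustering and missingness.

Real *S. spinulosa* reef is clustered along a tow rather than scattered at
random, so presence is simulated as a two-state Markov chain: the
stay-probabilities ``a = P(1 -> 1)`` and ``b = P(0 -> 0)`` control run
lengths (mean presence-run length ``1/(1-a)``) and together set the
stationary prevalence ``pi = (1-b) / ((1-a) + (1-b))``. Obscured-seabed
observations are emulated by marking entries missing, either independently
or in bursts (obscured footage occurs in runs in real video). Cover and
elevation for presence segments are drawn from pluggable distributions.

Defaults describe a 10-minute tow at 5-s segments (120 segments) over
strongly clustered reef (a = 0.9, prevalence 0.3) with 5% missing
observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .patchiness import PresenceSequence
from .status import ReefStatusMatrix
from .transect import Quality, SegmentRecord, TransectSeries

__all__ = ["Distribution", "SimulationConfig", "generate_presence", "generate_transect"]


@dataclass(frozen=True)
class Distribution:
    """A named univariate family for cover or elevation draws.

    ``uniform(low, high)`` draws on the half-open interval (low, high];
    ``constant(value)`` always returns ``value``; ``lognormal(mean, sigma)``
    draws ``exp(N(mean, sigma))``. Draws are truncated to ``bounds`` by
    re-sampling (uniform/constant families are validated against the bounds
    instead).
    """

    family: Literal["uniform", "constant", "lognormal"]
    params: tuple[float, ...]

    @classmethod
    def uniform(cls, low: float, high: float) -> "Distribution":
        if not low < high:
            raise ValueError("uniform requires low < high")
        return cls("uniform", (low, high))

    @classmethod
    def constant(cls, value: float) -> "Distribution":
        return cls("constant", (value,))

    @classmethod
    def lognormal(cls, mean: float, sigma: float) -> "Distribution":
        if sigma <= 0:
            raise ValueError("lognormal requires sigma > 0")
        return cls("lognormal", (mean, sigma))

    @classmethod
    def from_spec(cls, spec: "Distribution | dict | float | int") -> "Distribution":
        """Coerce a config entry: a number means a constant."""
        if isinstance(spec, Distribution):
            return spec
        if isinstance(spec, (int, float)):
            return cls.constant(float(spec))
        family = spec["family"]
        if family == "uniform":
            return cls.uniform(float(spec["low"]), float(spec["high"]))
        if family == "constant":
            return cls.constant(float(spec["value"]))
        if family == "lognormal":
            return cls.lognormal(float(spec["mean"]), float(spec["sigma"]))
        raise ValueError(f"unknown distribution family: {family!r}")

    def sample(
        self, n: int, rng: np.random.Generator, bounds: tuple[float, float]
    ) -> np.ndarray:
        lo, hi = bounds
        if self.family == "constant":
            (value,) = self.params
            if not lo < value <= hi:
                raise ValueError(f"constant {value} outside ({lo}, {hi}]")
            return np.full(n, value)
        if self.family == "uniform":
            low, high = self.params
            if low < lo or high > hi:
                raise ValueError(f"uniform({low}, {high}) outside ({lo}, {hi}]")
            # half-open (low, high]: reflect the generator's [low, high)
            return high + low - rng.uniform(low, high, size=n)
        # lognormal, truncated to (lo, hi] by resampling
        mean, sigma = self.params
        out = rng.lognormal(mean, sigma, size=n)
        bad = (out <= lo) | (out > hi)
        while bad.any():
            out[bad] = rng.lognormal(mean, sigma, size=int(bad.sum()))
            bad = (out <= lo) | (out > hi)
        return out


def _stationary_prevalence(a: float, b: float) -> float:
    return (1.0 - b) / ((1.0 - a) + (1.0 - b))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic tow.

    Attributes
    ----------
    n_segments
        Number of 5-s segments; default 120, a 10-minute tow (the survey
        minimum tow length).
    stay_prob_presence, stay_prob_absence
        Markov stay-probabilities ``a = P(1->1)`` and ``b = P(0->0)``, both
        in [0, 1). Defaults a = 0.9 (mean presence run of 10 segments) with
        b chosen for stationary prevalence 0.3.
    initial_presence_prob
        P(presence) for the first segment; ``None`` uses the stationary
        prevalence so the chain starts in equilibrium.
    missing_rate
        Marginal probability that a segment is unusable (obscured seabed).
    missing_mode
        ``"iid"`` for independent missingness, ``"burst"`` for missing runs
        generated by a second Markov chain with stay-probability
        ``missing_stay_prob`` and the same marginal rate.
    cover_distribution, elevation_distribution
        Distributions of cover (%) and tube elevation (cm) given presence;
        defaults Uniform(0, 100] and Uniform(0, 15].
    seed
        Base RNG seed; the same config and seed reproduce the tow exactly.
    """

    n_segments: int = 120
    stay_prob_presence: float = 0.9
    stay_prob_absence: float = 1.0 - (0.3 * (1.0 - 0.9)) / 0.7  # prevalence 0.3
    initial_presence_prob: float | None = None
    missing_rate: float = 0.05
    missing_mode: Literal["iid", "burst"] = "iid"
    missing_stay_prob: float = 0.7
    cover_distribution: Distribution = field(
        default_factory=lambda: Distribution.uniform(0.0, 100.0)
    )
    elevation_distribution: Distribution = field(
        default_factory=lambda: Distribution.uniform(0.0, 15.0)
    )
    segment_duration_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be positive")
        for name in ("stay_prob_presence", "stay_prob_absence"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1); got {p}")
        if self.initial_presence_prob is not None and not (
            0.0 <= self.initial_presence_prob <= 1.0
        ):
            raise ValueError("initial_presence_prob must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.missing_stay_prob < 1.0:
            raise ValueError("missing_stay_prob must be in [0, 1)")
        if self.missing_mode not in ("iid", "burst"):
            raise ValueError("missing_mode must be 'iid' or 'burst'")
        object.__setattr__(
            self, "cover_distribution", Distribution.from_spec(self.cover_distribution)
        )
        object.__setattr__(
            self,
            "elevation_distribution",
            Distribution.from_spec(self.elevation_distribution),
        )

    @property
    def stationary_prevalence(self) -> float:
        """Long-run fraction of presence segments, pi = (1-b)/((1-a)+(1-b))."""
        return _stationary_prevalence(self.stay_prob_presence, self.stay_prob_absence)

    @classmethod
    def from_prevalence(
        cls, stay_prob_presence: float, prevalence: float, **kwargs
    ) -> "SimulationConfig":
        """Config with ``b`` solved so the stationary prevalence is as given."""
        if not 0.0 < prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        a = stay_prob_presence
        b = 1.0 - prevalence * (1.0 - a) / (1.0 - prevalence)
        if not 0.0 <= b < 1.0:
            raise ValueError(
                f"no valid P(0->0) for a={a}, prevalence={prevalence}"
            )
        return cls(stay_prob_presence=a, stay_prob_absence=b, **kwargs)

    @classmethod
    def from_dict(cls, cfg: dict) -> "SimulationConfig":
        """Build from a plain mapping (e.g. a parsed YAML config)."""
        cfg = dict(cfg)
        prevalence = cfg.pop("prevalence", None)
        if prevalence is not None:
            a = cfg.pop("stay_prob_presence", 0.9)
            cfg.pop("stay_prob_absence", None)
            return cls.from_prevalence(a, float(prevalence), **cfg)
        return cls(**cfg)


def _markov_chain(
    n: int, stay1: float, stay0: float, p_init: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary two-state chain; vectorized via inverse-CDF on uniforms."""
    u = rng.random(n)
    out = np.empty(n, dtype=np.int8)
    state = 1 if u[0] < p_init else 0
    out[0] = state
    for i in range(1, n):
        stay = stay1 if state else stay0
        if u[i] >= stay:
            state = 1 - state
        out[i] = state
    return out


def generate_presence(
    config: SimulationConfig, tow_id: str = "sim"
) -> PresenceSequence:
    """Simulate the presence sequence of one tow.

    A two-state Markov chain of length ``n_segments`` generates clustered
    presence; entries are then masked missing per the config's missingness
    model. With ``a = b = 0.5`` the chain degenerates to an i.i.d. fair
    Bernoulli sequence. Reproducible for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    p_init = (
        config.initial_presence_prob
        if config.initial_presence_prob is not None
        else config.stationary_prevalence
    )
    chain = _markov_chain(
        config.n_segments,
        config.stay_prob_presence,
        config.stay_prob_absence,
        p_init,
        rng,
    )
    missing = _missing_mask(config, rng)
    values = tuple(
        None if missing[i] else int(chain[i]) for i in range(config.n_segments)
    )
    return PresenceSequence(values, tow_id=tow_id)


def _missing_mask(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_segments
    r = config.missing_rate
    if r == 0.0:
        return np.zeros(n, dtype=bool)
    if config.missing_mode == "iid":
        return rng.random(n) < r
    # burst mode: missingness itself is a two-state chain with marginal
    # rate r and stay-probability missing_stay_prob in the missing state
    a = config.missing_stay_prob
    b = 1.0 - r * (1.0 - a) / (1.0 - r)
    if b < 0.0:
        raise ValueError(
            "burst missingness infeasible: lower missing_stay_prob or missing_rate"
        )
    return _markov_chain(n, a, b, r, rng).astype(bool)


def generate_transect(
    config: SimulationConfig,
    tow_id: str = "sim",
    study_area: str = "",
    matrix: ReefStatusMatrix | None = None,
) -> TransectSeries:
    """Simulate a fully scored transect.

    Presence comes from :func:`generate_presence`; presence segments get
    cover and elevation draws from the configured distributions, absence
    segments get cover 0, and missing segments are marked unusable. Status
    is assigned through the reef structure matrix exactly as for real data.
    """
    presence = generate_presence(config, tow_id=tow_id)
    # separate stream for the scores so the chain is invariant to families
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_present = sum(1 for v in presence.values if v == 1)
    covers = config.cover_distribution.sample(n_present, rng, (0.0, 100.0))
    elevations = config.elevation_distribution.sample(n_present, rng, (0.0, np.inf))

    segments = []
    j = 0
    for i, v in enumerate(presence.values):
        start = i * config.segment_duration_s
        if v is None:
            rec = SegmentRecord.score(
                tow_id, i, start, quality=Quality.UNUSABLE, matrix=matrix
            )
        elif v == 0:
            rec = SegmentRecord.score(
                tow_id, i, start, quality=Quality.OK, cover_pct=0.0, matrix=matrix
            )
        else:
            rec = SegmentRecord.score(
                tow_id, i, start,
                quality=Quality.OK,
                cover_pct=float(covers[j]),
                elevation_cm=float(elevations[j]),
                matrix=matrix,
            )
            j += 1
        segments.append(rec)
    return TransectSeries(
        tow_id=tow_id,
        segments=tuple(segments),
        study_area=study_area,
        segment_duration_s=config.segment_duration_s,
    )
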