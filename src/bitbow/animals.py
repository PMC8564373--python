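"""Coupon-collector estimation of how many animals an experiment needs.

Each animal labels every lineage independently with some activation rate;
a labeled lineage draws a barcode, and the observation only counts when
the barcode is in the analysis whitelist (otherwise its lineage identity
cannot be assigned with confidence).  The question is how many animals are
needed until every one of ``L`` lineages has been validly sampled at least
once — a coupon-collector problem with per-animal per-lineage success
probability ``q = activation_rate * whitelist mass``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frequency import CodeDistribution, Whitelist

__all__ = [
    "AnimalSimConfig",
    "AnimalSimResult",
    "simulate_animals_needed",
    "expected_animals_analytic",
]


@dataclass(frozen=True)
class AnimalSimConfig:
    """Configuration for the animals-needed simulation.

    ``dist`` + ``whitelist`` determine the probability a drawn barcode is
    usable; with no whitelist every barcode counts and the distribution is
    irrelevant.  ``trials`` defaults to 500 independent repetitions.
    """

    lineages: int
    activation_rate: float
    dist: CodeDistribution | None = None
    whitelist: Whitelist | None = None
    trials: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lineages < 1:
            raise ValueError("lineages must be >= 1")
        if not 0.0 <= self.activation_rate <= 1.0:
            raise ValueError("activation_rate must lie in [0, 1]")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.whitelist is not None and self.dist is None:
            object.__setattr__(self, "dist", self.whitelist.dist)

    @property
    def whitelist_mass(self) -> float:
        if self.whitelist is None:
            return 1.0
        return self.whitelist.mass

    @property
    def success_rate(self) -> float:
        """Per-animal probability a given lineage is validly sampled."""
        return self.activation_rate * self.whitelist_mass


#: Published activation-rate presets.  The single-color MARCM baseline is
#: quoted both as ~1% (to keep at most one clone per brain) and 0.5% in
#: different contexts; both are kept so the discrepancy stays visible.
ACTIVATION_PRESETS: dict[str, float] = {
    "bitbow": 0.4808,
    "marcm": 0.01,
    "marcm-conservative": 0.005,
}


@dataclass(frozen=True)
class AnimalSimResult:
    mean: float
    sd: float
    per_trial: np.ndarray = field(repr=False)
    config: AnimalSimConfig = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "trials": self.config.trials,
            "lineages": self.config.lineages,
            "activation_rate": self.config.activation_rate,
            "whitelist_mass": self.config.whitelist_mass,
            "seed": self.config.seed,
        }


def simulate_animals_needed(cfg: AnimalSimConfig) -> AnimalSimResult:
    """Monte Carlo animals-needed estimate (mean ± SD over trials).

    Per trial, animals are added until every lineage has been validly
    sampled at least once.  In each animal an unsampled lineage activates
    with ``activation_rate`` and, if activated, its drawn barcode counts
    only when whitelisted.  Already-sampled lineages need not be re-drawn,
    so each lineage's first valid observation is geometric with success
    probability ``q = activation_rate * whitelist_mass`` and a trial's
    animal count is the maximum of ``L`` such geometrics.
    """
    q = cfg.success_rate
    if q <= 0.0:
        raise ValueError(
            "activation_rate x whitelist mass is 0: the simulation would "
            "never terminate"
        )
    rng = np.random.default_rng(cfg.seed)
    draws = rng.geometric(q, size=(cfg.trials, cfg.lineages))
    per_trial = draws.max(axis=1)
    mean = float(per_trial.mean())
    sd = float(per_trial.std(ddof=1)) if cfg.trials > 1 else 0.0
    return AnimalSimResult(mean=mean, sd=sd, per_trial=per_trial, config=cfg)


def expected_animals_analytic(
    cfg: AnimalSimConfig | None = None,
    lineages: int | None = None,
    success_rate: float | None = None,
    tail_tol: float = 1e-12,
) -> float:
    """Exact expected animal count for the coupon-collector model.

    The number of animals is the maximum of ``L`` i.i.d. geometric
    variables with success probability ``q``, whose expectation is
    ``E[A] = sum_{a>=0} [1 - (1 - (1-q)**a)**L]``; the series is summed
    until the tail term drops below ``tail_tol``.
    """
    if cfg is not None:
        lineages = cfg.lineages
        success_rate = cfg.success_rate
    if lineages is None or success_rate is None:
        raise ValueError("provide either cfg or (lineages, success_rate)")
    L, q = int(lineages), float(success_rate)
    if not 0.0 < q <= 1.0:
        raise ValueError("success rate q must lie in (0, 1]")
    if q == 1.0:
        return 1.0
    total = 0.0
    a = 0
    chunk = 1024
    while True:
        ar = np.arange(a, a + chunk, dtype=float)
        terms = 1.0 - (1.0 - (1.0 - q) ** ar) ** L
        total += float(terms.sum())
        a += chunk
        if terms[-1] < tail_tol:
            break
        if a > 10_000_000:  # pragma: no cover - guards pathological q
            raise RuntimeError("series did not converge")
    return total
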