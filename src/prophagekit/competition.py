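"""Repetitive-batch competition under spontaneous prophage induction (SPI).

Strains are co-cultivated, grown to stationary phase, and diluted 1:200
into fresh medium twice a day for a fixed number of cycles. Each cycle the
surviving population regrows by the dilution factor, i.e. runs
``log2(dilution_factor)`` generations. SPI removes a lysing lineage's
doubling, so a strain with per-generation lysis probability ``s`` grows by
``2 * (1 - s)`` per generation — the minimal model consistent with a
continuous loss of lysogenic cells. After ``n`` total generations the
lysogen-free : lysogen ratio changes by ``(1 - s)**(-n)``, which
:func:`estimate_selection` inverts.

The deterministic mode propagates exact fractions; the stochastic mode
draws binomial lysis per generation and a multinomial bottleneck at each
transfer. The model attributes the whole fitness difference to ``s``; it
cannot separate SPI cost from other fitness effects of carrying a prophage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PassageConfig",
    "PassageTrajectory",
    "generations",
    "simulate_passage",
    "estimate_selection",
    "od_to_cdw",
]

#: Cell dry weight per OD600 unit, g/liter.
CDW_PER_OD = 0.27


def generations(od_final: float, od_start: float) -> float:
    """Number of generations n from OD_final / OD_start = 2**n."""
    if od_final <= 0 or od_start <= 0:
        raise ValueError("OD values must be positive")
    if od_final < od_start:
        raise ValueError("OD_final must be at least OD_start")
    return math.log2(od_final / od_start)


def od_to_cdw(od600: float) -> float:
    """Cell dry weight (g/liter) from OD600: CDW = OD600 * 0.27."""
    if od600 < 0:
        raise ValueError("OD600 must be non-negative")
    return od600 * CDW_PER_OD


@dataclass
class PassageConfig:
    """Configuration of a repetitive-batch competition.

    ``spi_rate`` maps strain name to the per-generation lysis probability;
    ``growth_rate`` (per hour) is optional and defaults to equal rates — a
    strain growing at a fraction rho of the fastest rate completes only
    ``rho * log2(dilution_factor)`` generations per cycle.
    """

    spi_rate: dict[str, float]
    growth_rate: dict[str, float] | None = None
    initial_fractions: dict[str, float] | None = None
    dilution_factor: float = 200.0
    cycles: int = 12
    od_start: float = 0.1
    od_final: float | None = None
    stochastic: bool = False
    bottleneck_cells: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.cycles < 1:
            raise ValueError("cycles must be at least 1")
        if not self.spi_rate:
            raise ValueError("at least one strain required")
        for strain, s in self.spi_rate.items():
            if not 0 <= s < 1:
                raise ValueError(f"spi_rate for {strain!r} must be in [0, 1)")
        if self.growth_rate is not None:
            if set(self.growth_rate) != set(self.spi_rate):
                raise ValueError("growth_rate must name the same strains as spi_rate")
            if any(r <= 0 for r in self.growth_rate.values()):
                raise ValueError("growth rates must be positive")
        if self.initial_fractions is not None:
            if set(self.initial_fractions) != set(self.spi_rate):
                raise ValueError("initial_fractions must name the same strains as spi_rate")
            total = sum(self.initial_fractions.values())
            if not math.isclose(total, 1.0, rel_tol=1e-9):
                raise ValueError("initial fractions must sum to 1")
        if self.stochastic and self.bottleneck_cells is None:
            raise ValueError("bottleneck_cells is required in stochastic mode")
        if self.od_start <= 0:
            raise ValueError("od_start must be positive")

    @property
    def strains(self) -> list[str]:
        return sorted(self.spi_rate)

    @property
    def generations_per_cycle(self) -> float:
        return math.log2(self.dilution_factor)


@dataclass
class PassageTrajectory:
    """Per-cycle read-out of a competition run.

    ``fractions[c]`` is the composition of the stationary culture after
    cycle ``c`` (row 0 is the inoculum); fractions sum to 1 every cycle and
    cumulative generations are nondecreasing.
    """

    strains: list[str]
    fractions: np.ndarray  # (cycles + 1, n_strains)
    od_final: np.ndarray  # (cycles,)
    generations_per_cycle: np.ndarray  # (cycles,)
    cumulative_generations: np.ndarray  # (cycles,)

    def fraction(self, strain: str, cycle: int = -1) -> float:
        return float(self.fractions[cycle, self.strains.index(strain)])

    def ratio(self, numerator: str, denominator: str, cycle: int = -1) -> float:
        denom = self.fraction(denominator, cycle)
        if denom == 0:
            raise ZeroDivisionError(f"strain {denominator!r} extinct at cycle {cycle}")
        return self.fraction(numerator, cycle) / denom

    @property
    def total_generations(self) -> float:
        return float(self.cumulative_generations[-1])


def _per_cycle_log_multipliers(config: PassageConfig) -> np.ndarray:
    """log of each strain's per-cycle growth multiplier (2(1-s))**g_i."""
    g = config.generations_per_cycle
    strains = config.strains
    if config.growth_rate is None:
        rho = np.ones(len(strains))
    else:
        rates = np.array([config.growth_rate[s] for s in strains])
        rho = rates / rates.max()
    s = np.array([config.spi_rate[x] for x in strains])
    return g * rho * (np.log(2.0) + np.log1p(-s))


def simulate_passage(config: PassageConfig) -> PassageTrajectory:
    """Simulate the repetitive-batch competition.

    Deterministic mode propagates exact fractions (seed-independent);
    stochastic mode tracks integer cell counts with binomial lysis per
    generation and a multinomial bottleneck of ``bottleneck_cells`` at each
    transfer.
    """
    strains = config.strains
    n = len(strains)
    if config.initial_fractions is None:
        f0 = np.full(n, 1.0 / n)
    else:
        f0 = np.array([config.initial_fractions[s] for s in strains], dtype=float)

    g = config.generations_per_cycle
    od_final = config.od_final if config.od_final is not None else config.od_start * config.dilution_factor
    fractions = [f0]

    if not config.stochastic:
        log_mult = _per_cycle_log_multipliers(config)
        f = f0.copy()
        for _ in range(config.cycles):
            w = np.log(np.where(f > 0, f, 1.0)) + log_mult
            w = np.where(f > 0, w, -np.inf)
            f = np.exp(w - w.max())
            f /= f.sum()
            fractions.append(f)
    else:
        rng = np.random.default_rng(config.seed)
        s = np.array([config.spi_rate[x] for x in strains])
        counts = rng.multinomial(config.bottleneck_cells, f0)
        whole, frac_gen = int(math.floor(g)), g - math.floor(g)
        for _ in range(config.cycles):
            for _ in range(whole):
                lysed = rng.binomial(counts, s)
                counts = 2 * (counts - lysed)
            if frac_gen > 0:
                survivors = rng.binomial(counts, (1.0 - s) ** frac_gen)
                counts = np.rint(survivors * 2.0**frac_gen).astype(np.int64)
            total = counts.sum()
            if total == 0:
                raise RuntimeError("population went extinct in stochastic simulation")
            f = counts / total
            fractions.append(f)
            counts = rng.multinomial(config.bottleneck_cells, f)

    per_cycle = np.full(config.cycles, g)
    return PassageTrajectory(
        strains=strains,
        fractions=np.vstack(fractions),
        od_final=np.full(config.cycles, od_final),
        generations_per_cycle=per_cycle,
        cumulative_generations=np.cumsum(per_cycle),
    )


def estimate_selection(ratio_initial: float, ratio_final: float, n_generations: float) -> float:
    """Per-generation selection coefficient from start/end strain ratios.

    With ``ratio`` the lysogen-free : lysogen ratio, inverts
    ``ratio_final = ratio_initial * (1 - s)**(-n)``:
    ``s = 1 - (ratio_initial / ratio_final)**(1 / n)``. Exact inverse of the
    deterministic passage model; unbiased in expectation for stochastic
    trajectories.
    """
    if ratio_initial <= 0 or ratio_final <= 0:
        raise ValueError("ratios must be positive")
    if n_generations <= 0:
        raise ValueError("n_generations must be positive")
    return 1.0 - (ratio_initial / ratio_final) ** (1.0 / n_generations)
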