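"""Synthetic data with the statistical structure the analysis assumes.

Generates desk-scale stand-ins for the wet-lab inputs of a prophage
induction study: a host chromosome with implanted prophages flanked by att
direct repeats, supernatant-sequencing coverage with prophage regions
enriched proportionally to induced fraction x burst size, qPCR plates with
1:10 dilution standard curves, and repetitive-batch competition read-outs.

A :class:`SyntheticTruth` fully determines every simulator's expectations,
so parameter-recovery tests have closed-form targets. All randomness flows
from explicit seeds. Defaults emulate the study conditions: a 200-kb
chromosome (stand-in for a 3.25-Mb replicon) carrying a 20-kb and a 35-kb
prophage, a mitomycin-C induction scenario with induced fraction 0.9 and
burst sizes 10 and 70 (excess enrichment ratio exactly 7), spontaneous
induction fractions of 0.13% and 0.61%, a residual host-DNA background of
10x, negative-binomial coverage noise (size 10; sequencing is overdispersed
relative to Poisson), and qPCR noise of 0.15 cycles. Read-level simulation,
sequencing error models and library-prep biases are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .competition import PassageConfig, PassageTrajectory, simulate_passage
from .io import CoverageTrack, GenomeRecord, ProphageRegion, QpcrPlate

__all__ = [
    "PhageSpec",
    "SyntheticTruth",
    "default_phage_specs",
    "generate_host_genome",
    "simulate_supernatant_coverage",
    "simulate_qpcr_plate",
    "simulate_competition_experiment",
    "random_dna",
    "mutate_sequence",
    "PERFECT_SLOPE",
]

#: Standard-curve slope (cycles per decade) at 100% amplification efficiency.
PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.3219...

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PhageSpec:
    """Specification of one implanted prophage.

    The region ``[start, end)`` is the full integrated prophage; the att
    core is written as a direct repeat occupying its first and last
    ``len(att_core)`` bases. ``induced_fraction`` and ``burst_size`` drive
    supernatant enrichment (expected fold ``1 + f*b``); ``spi_fraction`` is
    the instantaneous fraction of genomes with the prophage excised, probed
    by the attB-junction qPCR assay.
    """

    name: str
    start: int
    end: int
    att_core: str
    induced_fraction: float = 0.9
    burst_size: float = 10.0
    spi_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end must exceed start")
        if len(self.att_core) < 10:
            raise ValueError(f"{self.name}: att core shorter than the 10 bp minimum")
        if not 0 <= self.induced_fraction <= 1:
            raise ValueError(f"{self.name}: induced_fraction must be in [0, 1]")
        if not 0 <= self.spi_fraction <= 1:
            raise ValueError(f"{self.name}: spi_fraction must be in [0, 1]")
        if self.burst_size <= 0:
            raise ValueError(f"{self.name}: burst_size must be positive")
        if self.end - self.start < 2 * len(self.att_core):
            raise ValueError(f"{self.name}: region shorter than two att-core copies")


def default_phage_specs() -> list[PhageSpec]:
    """The two default prophages of the synthetic chromosome.

    The first carries a 14-bp core and burst size 10, the second a 26-bp
    core and burst size 70, so the excess supernatant enrichment ratio of
    phage 2 over phage 1 is (0.9*70)/(0.9*10) = 7. Spontaneous induction
    fractions are 0.13% and 0.61% (exponential-phase values).
    """
    return [
        PhageSpec(
            name="VNP1",
            start=50_000,
            end=70_000,
            att_core="TAGATTTGTGTGGT",
            induced_fraction=0.9,
            burst_size=10.0,
            spi_fraction=0.0013,
        ),
        PhageSpec(
            name="VNP2",
            start=120_000,
            end=155_000,
            att_core="CAGCCGACATTCTTCTTCTTTGACTA",
            induced_fraction=0.9,
            burst_size=70.0,
            spi_fraction=0.0061,
        ),
    ]


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic data set."""

    genome: GenomeRecord
    regions: list[ProphageRegion]
    induced_fraction: dict[str, float]
    burst_size: dict[str, float]
    spi_fraction: dict[str, float]
    background_depth: float = 10.0
    qpcr_noise_sd: float = 0.15
    spi_rate: dict[str, float] = field(default_factory=lambda: {"wt": 0.006, "dvnp12": 0.0})

    def __post_init__(self) -> None:
        for a in self.regions:
            if not (0 <= a.start < a.end <= len(self.genome)):
                raise ValueError(f"region {a.name} outside the genome")
            for b in self.regions:
                if a is not b and a.overlaps(b):
                    raise ValueError(f"regions {a.name} and {b.name} overlap")
            core = a.att_core
            if core is None:
                raise ValueError(f"region {a.name} lacks an att core")
            seq = self.genome.sequence
            if seq[a.start : a.start + len(core)] != core or seq[a.end - len(core) : a.end] != core:
                raise ValueError(f"att core of {a.name} not duplicated at both region flanks")
        for name, f in self.induced_fraction.items():
            if not 0 <= f <= 1:
                raise ValueError(f"induced_fraction[{name}] must be in [0, 1]")
        if self.background_depth <= 0:
            raise ValueError("background_depth must be positive")

    def expected_fold(self, phage: str) -> float:
        """Closed-form expected coverage fold of a region: 1 + f*b."""
        return 1.0 + self.induced_fraction[phage] * self.burst_size[phage]


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. random DNA at the requested GC content."""
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def mutate_sequence(sequence: str, rate: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute each base independently with probability ``rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.array(list(sequence))
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def generate_host_genome(
    length: int = 200_000,
    regions_spec: list[PhageSpec] | None = None,
    gc: float = 0.45,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate a host chromosome with implanted, att-flanked prophages.

    The background is i.i.d. at the requested GC; each prophage's att core
    is written as an exact direct repeat at the first and last positions of
    its region. Prophages must fit inside the chromosome with at least 1 kb
    margins and must not overlap. Identical seeds give identical genomes.
    """
    specs = default_phage_specs() if regions_spec is None else list(regions_spec)
    margin = 1000
    for spec in specs:
        if spec.start < margin or spec.end > length - margin:
            raise ValueError(f"{spec.name}: region must keep >= {margin} bp margins")
    for i, a in enumerate(specs):
        for b in specs[i + 1 :]:
            if a.start < b.end and b.start < a.end:
                raise ValueError(f"regions {a.name} and {b.name} overlap")

    rng = np.random.default_rng(seed)
    seq = list(random_dna(length, gc, rng))
    regions = []
    for spec in specs:
        core = spec.att_core.upper()
        c = len(core)
        seq[spec.start : spec.start + c] = core
        seq[spec.end - c : spec.end] = core
        # The direct repeat must be *exactly* the core: if the random bases
        # just outside the two copies happen to agree, the repeat would
        # extend past the att site — resample the interior-side neighbour.
        for left_pos, right_pos in (
            (spec.start - 1, spec.end - c - 1),
            (spec.start + c, spec.end),
        ):
            if right_pos < length and seq[left_pos] == seq[right_pos]:
                others = [b for b in "ACGT" if b != seq[left_pos]]
                seq[right_pos] = others[rng.integers(3)]
        regions.append(
            ProphageRegion("chr1", spec.start, spec.end, name=spec.name, att_core=core)
        )
    genome = GenomeRecord("chr1", "".join(seq), "synthetic host chromosome")
    return SyntheticTruth(
        genome=genome,
        regions=regions,
        induced_fraction={s.name: s.induced_fraction for s in specs},
        burst_size={s.name: s.burst_size for s in specs},
        spi_fraction={s.name: s.spi_fraction for s in specs},
    )


def simulate_supernatant_coverage(
    truth: SyntheticTruth,
    mean_depth: float | None = None,
    overdispersion: float = 10.0,
    seed: int = 0,
) -> CoverageTrack:
    """Supernatant-sequencing coverage of the synthetic chromosome.

    Per-base depth is negative-binomial with size ``overdispersion`` and
    mean ``background`` outside prophage regions and
    ``background * (1 + f_i * b_i)`` inside region ``i``, so the expected
    in-region/background ratio is ``1 + f*b``.
    """
    background = truth.background_depth if mean_depth is None else mean_depth
    if background <= 0 or overdispersion <= 0:
        raise ValueError("depth parameters must be positive")
    rng = np.random.default_rng(seed)
    mean = np.full(len(truth.genome), background)
    for region in truth.regions:
        mean[region.start : region.end] = background * truth.expected_fold(region.name)
    r = overdispersion
    p = r / (r + mean)
    depth = rng.negative_binomial(r, p).astype(float)
    return CoverageTrack(truth.genome.id, depth)


def _target_for(phage_name: str) -> str:
    return f"{phage_name.lower()}_attB"


def simulate_qpcr_plate(
    truth: SyntheticTruth,
    curve_params: tuple[float, float] = (PERFECT_SLOPE, 20.0),
    n_standards: int = 5,
    seed: int = 0,
    noise_sd: float | None = None,
    reference_amount: float = 0.1,
    sample_id: str = "wt_exp",
    control_id: str = "dvnp12_ctrl",
    n_replicates: int = 2,
) -> QpcrPlate:
    """Simulate a qPCR plate for the SPI experiment.

    Standards are ``n_standards`` 1:10 serial dilutions from 1 ng/ul (so
    five dilutions reach 1e-5 ng/ul). Each well's Ct is
    ``intercept + slope * log10(true amount) + Normal(0, noise_sd)``; a zero
    true amount yields the no-amplification sentinel (missing Ct), never a
    fake Ct. The sample's attB-target amounts equal
    ``spi_fraction * reference_amount``; the prophage-free control carries
    the attB junction on every genome (amount = reference amount).
    """
    slope, intercept = curve_params
    if slope >= 0:
        raise ValueError("curve slope must be negative")
    if n_standards < 3:
        raise ValueError("at least 3 serial dilutions required")
    sd = truth.qpcr_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)

    def ct_for(amount: float) -> float:
        if amount <= 0:
            return math.nan
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        return intercept + slope * math.log10(amount) + noise

    rows = []
    for level in range(n_standards + 1):
        conc = 10.0 ** (-level)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"std_1e{-level}",
                    "target": "standard",
                    "ct": ct_for(conc),
                    "known_conc": conc,
                    "replicate": rep,
                }
            )

    amounts: dict[tuple[str, str], float] = {}
    for region in truth.regions:
        target = _target_for(region.name)
        amounts[(sample_id, target)] = truth.spi_fraction[region.name] * reference_amount
        amounts[(control_id, target)] = reference_amount
    amounts[(sample_id, "reference_tk")] = reference_amount
    amounts[(control_id, "reference_tk")] = reference_amount

    for (sid, target), amount in amounts.items():
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sid,
                    "target": target,
                    "ct": ct_for(amount),
                    "known_conc": math.nan,
                    "replicate": rep,
                }
            )
    return QpcrPlate(pd.DataFrame(rows))


def simulate_competition_experiment(
    config: PassageConfig,
    seed: int = 0,
    marker_strain: str | None = None,
    marker_target: str = "vnp1_attB",
    noise_sd: float = 0.15,
    curve_params: tuple[float, float] = (PERFECT_SLOPE, 20.0),
    n_standards: int = 5,
    reference_amount: float = 0.1,
) -> tuple[PassageTrajectory, QpcrPlate, QpcrPlate]:
    """Run a competition and report qPCR plates after cycles 1 and 12 (last).

    The marker target is the attB-junction assay that amplifies only in the
    prophage-free (marker) strain; by default the strain with the lowest
    spontaneous-induction rate is the marker. Each plate contains a
    dilution-series, the mixed-culture sample and a pure marker-strain
    control whose normalised marker amount defines 100%.
    """
    trajectory = simulate_passage(config)
    if marker_strain is None:
        marker_strain = min(config.spi_rate, key=lambda s: (config.spi_rate[s], s))
    if marker_strain not in config.spi_rate:
        raise ValueError(f"unknown marker strain {marker_strain!r}")

    slope, intercept = curve_params
    rng = np.random.default_rng(seed)

    def build_plate(cycle: int) -> QpcrPlate:
        frac = trajectory.fraction(marker_strain, cycle)
        rows = []

        def ct_for(amount: float) -> float:
            if amount <= 0:
                return math.nan
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            return intercept + slope * math.log10(amount) + noise

        for level in range(n_standards + 1):
            conc = 10.0 ** (-level)
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"std_1e{-level}",
                        "target": "standard",
                        "ct": ct_for(conc),
                        "known_conc": conc,
                        "replicate": rep,
                    }
                )
        wells = {
            (f"mix_cycle{cycle}", marker_target): frac * reference_amount,
            (f"mix_cycle{cycle}", "reference_tk"): reference_amount,
            ("marker_ctrl", marker_target): reference_amount,
            ("marker_ctrl", "reference_tk"): reference_amount,
        }
        for (sid, target), amount in wells.items():
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": sid,
                        "target": target,
                        "ct": ct_for(amount),
                        "known_conc": math.nan,
                        "replicate": rep,
                    }
                )
        return QpcrPlate(pd.DataFrame(rows))

    return trajectory, build_plate(1), build_plate(config.cycles)
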