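"""Absolute qPCR quantification of prophage excision.

The chain follows standard-curve quantification: a dilution series of a
known template gives an ordinary-least-squares fit of threshold cycle (Ct)
on log10(concentration); amounts of unknowns are read off the inverted
curve; each target amount is normalised to a single-copy genomic reference
gene (a thymidine kinase); and biological quantities are ratios of
normalised amounts:

* SPI fraction (%) = 100 * N(sample) / N(fully-induced control), where the
  control is DNA of the prophage-free strain in which every genome carries
  the attB junction (100% by definition).
* strain ratio (%) = 100 * N(sample) / N(wild-type control).
* phage:genome copy ratio from circular-phage and reference amounts, with
  amounts converted to copy numbers via amplicon length (the mass-per-bp
  constant cancels).

Amplification efficiency derives from the slope as ``10**(-1/slope) - 1``;
a slope of -3.32 cycles per decade corresponds to perfect doubling.
Curves are accepted only when r^2 > 0.95. A missing Ct is the
no-amplification sentinel and quantifies as amount 0. Normalisation is a
division: it must cancel differences in DNA input mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import QpcrPlate

__all__ = [
    "StandardCurve",
    "QuantResult",
    "CurveRejectedError",
    "fit_standard_curve",
    "curve_predict",
    "quantify",
    "normalize",
    "spi_fraction",
    "strain_ratio",
    "phage_to_genome_ratio",
    "predict_amplicon",
    "AmpliconError",
    "fit_plate_curve",
    "quantify_plate",
    "normalized_amounts",
    "spi_from_plate",
    "strain_ratio_from_plate",
]

R2_ACCEPTANCE = 0.95


class CurveRejectedError(ValueError):
    """Standard-curve QC failure; carries the offending fitted curve."""

    def __init__(self, message: str, curve: "StandardCurve"):
        super().__init__(message)
        self.curve = curve


@dataclass(frozen=True)
class StandardCurve:
    """Ct-vs-log10(concentration) regression.

    ``slope`` is in cycles per decade of template (negative), ``intercept``
    the Ct at 1 ng/ul, ``efficiency`` the per-cycle amplification gain minus
    one (1.0 = perfect doubling).
    """

    slope: float
    intercept: float
    r2: float
    efficiency: float
    n_points: int

    @property
    def accepted(self) -> bool:
        return self.slope < 0 and self.r2 > R2_ACCEPTANCE


@dataclass(frozen=True)
class QuantResult:
    """One quantified (sample, target) pair."""

    sample_id: str
    target: str
    amount: float
    normalized: float | None = None
    flags: tuple[str, ...] = ()


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Ct on log10(known concentration) over all replicate points.

    Requires at least three distinct concentrations; rejects (raising
    :class:`CurveRejectedError` carrying the fit) curves with non-negative
    slope or r^2 <= 0.95.
    """
    conc = np.array([c for c, _ in standards], dtype=float)
    ct = np.array([t for _, t in standards], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    if np.unique(conc).size < 3:
        raise ValueError("at least 3 distinct standard concentrations required")
    res = stats.linregress(np.log10(conc), ct)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    efficiency = 10 ** (-1 / slope) - 1 if slope != 0 else math.inf
    curve = StandardCurve(slope, intercept, r2, float(efficiency), len(standards))
    if slope >= 0:
        raise CurveRejectedError(f"standard curve slope must be negative, got {slope:.3f}", curve)
    if r2 <= R2_ACCEPTANCE:
        raise CurveRejectedError(f"standard curve r2 {r2:.4f} <= {R2_ACCEPTANCE}", curve)
    return curve


def curve_predict(concentration: float, curve: StandardCurve) -> float:
    """Expected Ct for a given concentration (ng/ul)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    return curve.intercept + curve.slope * math.log10(concentration)


def quantify(ct: float | Iterable[float] | None, curve: StandardCurve) -> float:
    """Invert the standard curve: Ct -> concentration (ng/ul).

    A missing Ct (``None``/NaN, the no-amplification sentinel) quantifies as
    0. An iterable of replicate Ct values is averaged on the concentration
    scale after per-replicate inversion.
    """
    if not curve.accepted:
        raise ValueError("cannot quantify against a rejected standard curve")
    if ct is None:
        return 0.0
    if np.iterable(ct):
        return float(np.mean([quantify(c, curve) for c in ct]))
    ctf = float(ct)
    if math.isnan(ctf):
        return 0.0
    return float(10 ** ((ctf - curve.intercept) / curve.slope))


def normalize(amount_target: float, amount_reference: float) -> float:
    """Normalised DNA amount N = target amount / reference-gene amount."""
    if amount_reference <= 0:
        raise ValueError("reference amount must be positive")
    if amount_target < 0:
        raise ValueError("target amount must be non-negative")
    return amount_target / amount_reference


def spi_fraction(n_sample: float, n_control: float) -> float:
    """Spontaneous-prophage-induction fraction in percent.

    ``100 * N(sample) / N(fully-induced control)``; the prophage-free
    control, in which every genome carries the attB junction, defines 100%.
    Values above 100% are returned as-is (flag downstream, never clamp).
    """
    if n_control <= 0:
        raise ValueError("control normalised amount must be positive")
    if n_sample < 0:
        raise ValueError("sample normalised amount must be non-negative")
    # grouped so that n_sample == n_control gives exactly 100.0
    return 100.0 * (n_sample / n_control)


def strain_ratio(n_sample: float, n_wt: float) -> float:
    """Strain-to-wild-type ratio in percent; WT control DNA defines 100%."""
    return spi_fraction(n_sample, n_wt)


def phage_to_genome_ratio(
    circle_amount: float,
    circle_amplicon_len: int,
    genome_amount: float,
    ref_amplicon_len: int,
) -> float:
    """Phage genome copies per bacterial genome copy.

    Amounts are converted to copy numbers as ``amount / (amplicon_len *
    mass_per_bp)``; the mass-per-bp constant cancels in the ratio.
    """
    if circle_amplicon_len <= 0 or ref_amplicon_len <= 0:
        raise ValueError("amplicon lengths must be positive")
    if circle_amount < 0 or genome_amount < 0:
        raise ValueError("amounts must be non-negative")
    genome_copies = genome_amount / ref_amplicon_len
    if genome_copies == 0:
        raise ValueError("zero bacterial genome copies")
    return (circle_amount / circle_amplicon_len) / genome_copies


# ---------------------------------------------------------------------------
# In-silico PCR

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AmpliconError(ValueError):
    """No unique in-silico PCR product."""


def predict_amplicon(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_len: int = 5000,
) -> tuple[str, int]:
    """Exact-match in-silico PCR.

    Finds the forward primer on either strand and the reverse complement of
    the reverse primer downstream on the same strand; the product includes
    both primer sites. Requires a unique product of at most ``max_len`` bp;
    ambiguity raises :class:`AmpliconError` listing the loci. Degenerate
    bases and mismatch tolerance are out of scope.
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev = rev_primer.upper()
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be at least 15 nt")

    products: list[tuple[str, int, str]] = []  # (strand, start, product)
    for strand, seq in (("+", template), ("-", _revcomp(template))):
        rev_site = _revcomp(rev)
        i = seq.find(fwd)
        while i >= 0:
            j = seq.find(rev_site, i + 1)
            while j >= 0:
                product = seq[i : j + len(rev_site)]
                if len(product) <= max_len:
                    products.append((strand, i, product))
                j = seq.find(rev_site, j + 1)
            i = seq.find(fwd, i + 1)

    if not products:
        raise AmpliconError("no in-silico PCR product (primer site absent)")
    if len(products) > 1:
        loci = ", ".join(f"{s}:{i}({len(p)} bp)" for s, i, p in products)
        raise AmpliconError(f"multiple in-silico PCR products: {loci}")
    product = products[0][2]
    return product, len(product)


# ---------------------------------------------------------------------------
# Plate-level pipeline helpers


def fit_plate_curve(plate: QpcrPlate) -> StandardCurve:
    """Fit the standard curve from a plate's dilution-series wells."""
    std = plate.standards
    std = std[std["ct"].notna()]
    if std.empty:
        raise ValueError("plate contains no standard wells with measured Ct")
    return fit_standard_curve(list(zip(std["known_conc"], std["ct"])))


def quantify_plate(plate: QpcrPlate, curve: StandardCurve | None = None) -> pd.DataFrame:
    """Quantify every (sample, target) pair on a plate.

    Technical replicates are inverted individually and averaged on the
    concentration scale. Returns a DataFrame with columns ``sample_id``,
    ``target``, ``amount``.
    """
    if curve is None:
        curve = fit_plate_curve(plate)
    rows = []
    for (sample, target), group in plate.unknowns.groupby(["sample_id", "target"], sort=False):
        amount = quantify(group["ct"].tolist(), curve)
        rows.append({"sample_id": sample, "target": target, "amount": amount})
    return pd.DataFrame(rows)


def normalized_amounts(
    plate: QpcrPlate,
    reference_target: str = "reference_tk",
    curve: StandardCurve | None = None,
) -> pd.DataFrame:
    """Per-sample normalised amounts N(target) = amount / reference amount."""
    amounts = quantify_plate(plate, curve)
    ref = amounts[amounts["target"] == reference_target].set_index("sample_id")["amount"]
    rows = []
    for _, row in amounts[amounts["target"] != reference_target].iterrows():
        if row["sample_id"] not in ref.index:
            raise ValueError(f"sample {row['sample_id']!r} lacks the reference target")
        rows.append(
            {
                "sample_id": row["sample_id"],
                "target": row["target"],
                "amount": row["amount"],
                "normalized": normalize(row["amount"], float(ref[row["sample_id"]])),
            }
        )
    return pd.DataFrame(rows)


def _lookup_n(norm: pd.DataFrame, sample_id: str, target: str) -> float:
    sel = norm[(norm["sample_id"] == sample_id) & (norm["target"] == target)]
    if sel.empty:
        raise ValueError(f"no normalised amount for sample {sample_id!r}, target {target!r}")
    return float(sel["normalized"].iloc[0])


def spi_from_plate(
    plate: QpcrPlate,
    sample_id: str,
    control_id: str,
    target: str,
    reference_target: str = "reference_tk",
) -> float:
    """End-to-end SPI fraction (%) from a raw plate.

    ``control_id`` names the fully-induced (prophage-free) control sample.
    """
    norm = normalized_amounts(plate, reference_target)
    return spi_fraction(_lookup_n(norm, sample_id, target), _lookup_n(norm, control_id, target))


def strain_ratio_from_plate(
    plate: QpcrPlate,
    sample_id: str,
    control_id: str,
    target: str,
    reference_target: str = "reference_tk",
) -> float:
    """End-to-end strain ratio (%) from a raw plate; control is WT-level DNA."""
    norm = normalized_amounts(plate, reference_target)
    return strain_ratio(_lookup_n(norm, sample_id, target), _lookup_n(norm, control_id, target))
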