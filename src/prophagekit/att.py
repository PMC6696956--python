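"""Site-specific recombination at prophage attachment (att) sites.

An integrated prophage is delimited by two hybrid attachment sites, attL and
attR, which share a short core sequence as a direct repeat. Excision
recombines attL with attR at a crossover position and reconstitutes the
bacterial site attB on the chromosome while the excised circle carries the
phage site attP. With a crossover after ``k`` leading positions (0-based,
half-open slices):

    attB = attL[:k] + attR[k:]
    attP = attR[:k] + attL[k:]

so at every position ``i`` the multiset ``{attB[i], attP[i]}`` equals
``{attL[i], attR[i]}`` — recombination only redistributes the bases of the
two parental sites. When attL and attR are exact repeats the four sites are
identical and every ``k`` is equivalent; when the repeat is impaired (as for
a site with internal mismatches) the observed attP constrains ``k`` to a
contiguous interval, computed by :func:`infer_crossover_interval`.

The model is a single crossover with exact matching: gene-conversion tracts,
staggered-cut overhangs and mismatch-tolerant core discovery are out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenomeRecord, ProphageRegion

__all__ = [
    "AttSiteSet",
    "CoreNotFoundError",
    "find_att_core",
    "recombine",
    "infer_crossover_interval",
    "excise",
    "integrate",
    "region_length",
]


class CoreNotFoundError(ValueError):
    """Raised when an att core cannot be located where the model expects it."""


@dataclass(frozen=True)
class AttSiteSet:
    """The attL/attR/attB/attP quartet plus crossover information.

    All present sequences have identical length (``core_length``).
    ``crossover_interval`` is ``(kmin, kmax)`` with ``k`` the number of
    leading positions contributed by the donor site, ``0 <= k <= core_length``.
    """

    attL: str
    attR: str
    attB: str | None = None
    attP: str | None = None
    crossover_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        sites = {"attL": self.attL, "attR": self.attR, "attB": self.attB, "attP": self.attP}
        lengths = {name: len(s) for name, s in sites.items() if s is not None}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"att sites must share one length, got {lengths}")
        if self.crossover_interval is not None:
            kmin, kmax = self.crossover_interval
            if not (0 <= kmin <= kmax <= self.core_length):
                raise ValueError(f"crossover interval {self.crossover_interval} out of range")

    @property
    def core_length(self) -> int:
        return len(self.attL)


def region_length(start: int, end: int, convention: str) -> int:
    """Interval length under an explicit coordinate convention.

    ``convention="inclusive"`` treats ``start``/``end`` as 1-based inclusive
    printed positions (length ``end - start + 1``); ``"end_minus_start"``
    returns the plain difference. Published coordinates mix both conventions
    for the same interval, so the caller must choose explicitly.
    """
    if end < start:
        raise ValueError(f"end ({end}) < start ({start})")
    if convention == "inclusive":
        return end - start + 1
    if convention == "end_minus_start":
        return end - start
    raise ValueError(f"unknown convention {convention!r}")


def recombine(attL: str, attR: str, k: int) -> tuple[str, str]:
    """Single-crossover recombination of attL with attR after ``k`` positions.

    Returns ``(attB, attP)``. Raises on length mismatch or ``k`` out of
    ``[0, core_length]``.
    """
    if len(attL) != len(attR):
        raise ValueError(f"attL ({len(attL)} bp) and attR ({len(attR)} bp) differ in length")
    if not 0 <= k <= len(attL):
        raise ValueError(f"crossover k={k} outside [0, {len(attL)}]")
    attB = attL[:k] + attR[k:]
    attP = attR[:k] + attL[k:]
    return attB, attP


def infer_crossover_interval(attL: str, attR: str, attP: str) -> tuple[int, int] | None:
    """All crossover positions consistent with an observed attP.

    Returns ``(kmin, kmax)`` for the set ``{k : attR[:k] + attL[k:] == attP}``
    (always a contiguous interval) or ``None`` when the set is empty, i.e.
    the single-crossover model cannot explain the observed attP.
    """
    if not (len(attL) == len(attR) == len(attP)):
        raise ValueError("attL, attR and attP must share one length")
    ks = [k for k in range(len(attL) + 1) if attR[:k] + attL[k:] == attP]
    if not ks:
        return None
    return ks[0], ks[-1]


# ---------------------------------------------------------------------------
# Core discovery


def _longest_common_substrings(a: str, b: str, min_len: int) -> tuple[int, list[tuple[int, int]]]:
    """Length and occurrence pairs (i_a, i_b) of the longest common substrings.

    Binary search over the candidate length (common-substring existence is
    monotone in length), with a hash-set membership check per length.
    """

    def pairs_at(length: int) -> list[tuple[int, int]]:
        if length == 0 or length > min(len(a), len(b)):
            return []
        kmers: dict[str, list[int]] = {}
        for i in range(len(a) - length + 1):
            kmers.setdefault(a[i : i + length], []).append(i)
        out = []
        for j in range(len(b) - length + 1):
            sub = b[j : j + length]
            for i in kmers.get(sub, ()):
                out.append((i, j))
        return out

    lo, hi = min_len, min(len(a), len(b))
    if not pairs_at(lo):
        return 0, []
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if pairs_at(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo, pairs_at(lo)


def find_att_core(
    genome: GenomeRecord | str,
    region: ProphageRegion,
    window: int = 1000,
    min_len: int = 10,
) -> AttSiteSet | None:
    """Locate the att core as the longest exact direct repeat flanking a region.

    Searches a ``window`` around the region start and a ``window`` around the
    region end for the longest sequence present in both; ties are broken by
    proximity of the two occurrences to the region boundaries, then by the
    leftmost occurrence pair. Returns ``None`` when no repeat of at least
    ``min_len`` bp exists (an explicit no-core result, not an error).

    Because the discovered repeat is exact, the returned set has
    ``attL == attR == attB == attP`` and the whole ``[0, core_length]``
    crossover interval.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    if not (0 <= region.start < region.end <= len(seq)):
        raise ValueError("region must lie inside the genome")
    if window < min_len:
        raise ValueError("window must be at least min_len")

    left_lo = max(0, region.start - window)
    left_hi = min(len(seq), region.start + window)
    right_lo = max(0, region.end - window)
    right_hi = min(len(seq), region.end + window)
    wl = seq[left_lo:left_hi]
    wr = seq[right_lo:right_hi]

    length, pairs = _longest_common_substrings(wl, wr, min_len)
    if length == 0:
        return None

    def score(pair: tuple[int, int]) -> tuple[int, int, int]:
        i, j = pair
        left_end = left_lo + i + length
        right_end = right_lo + j + length
        prox = abs(left_end - region.start) + abs(right_end - region.end)
        return (prox, left_lo + i, right_lo + j)

    i, j = min(pairs, key=score)
    core = wl[i : i + length]
    return AttSiteSet(attL=core, attR=core, attB=core, attP=core, crossover_interval=(0, length))


# ---------------------------------------------------------------------------
# Excision and integration


def _locate_flanking_cores(seq: str, region: ProphageRegion, att: AttSiteSet) -> None:
    c = att.core_length
    if seq[region.start : region.start + c] != att.attL:
        raise CoreNotFoundError(
            f"attL not found at region start {region.start} (expected {att.attL})"
        )
    if seq[region.end - c : region.end] != att.attR:
        raise CoreNotFoundError(f"attR not found at region end {region.end} (expected {att.attR})")


def excise(
    genome: GenomeRecord,
    region: ProphageRegion,
    att: AttSiteSet,
    k: int,
) -> tuple[GenomeRecord, GenomeRecord]:
    """Excise an integrated prophage, returning ``(host_genome, phage_circle)``.

    The region is the full integrated prophage with attL occupying its first
    ``core_length`` bases and attR its last. The host keeps attB at the
    junction; the circle (reported linearly, opened at the recombination
    joint) starts with attP followed by the prophage interior. Sequence
    material is conserved exactly:
    ``len(host) + len(circle) == len(genome)``.
    """
    seq = genome.sequence
    c = att.core_length
    if len(region) < 2 * c:
        raise ValueError("region shorter than two core copies")
    _locate_flanking_cores(seq, region, att)
    attB, attP = recombine(att.attL, att.attR, k)
    host_seq = seq[: region.start] + attB + seq[region.end :]
    circle_seq = attP + seq[region.start + c : region.end - c]
    host = GenomeRecord(f"{genome.id}_host", host_seq, f"host after excision of {region.name}")
    circle = GenomeRecord(
        f"{region.name or 'phage'}_circle", circle_seq, "excised circular phage DNA (linearised at attP)"
    )
    return host, circle


def integrate(
    host_genome: GenomeRecord,
    attB_position: int,
    phage_circle: GenomeRecord,
    att: AttSiteSet,
    k: int,
) -> GenomeRecord:
    """Integrate a phage circle at an attB site; inverse of :func:`excise`.

    ``att`` must carry attB/attP (or they are derived from attL/attR and
    ``k``). The circle may be any rotation; it is rotated so attP leads.
    With identical cores ``integrate`` after ``excise`` is the identity; with
    impaired cores the two resulting junction sites still satisfy per-column
    multiset conservation.
    """
    attB, attP = att.attB, att.attP
    if attB is None or attP is None:
        attB, attP = recombine(att.attL, att.attR, k)
    c = len(attB)
    host_seq = host_genome.sequence
    if host_seq[attB_position : attB_position + c] != attB:
        raise CoreNotFoundError(f"attB not found at position {attB_position}")
    doubled = phage_circle.sequence * 2
    pos = doubled.find(attP)
    if pos < 0 or len(phage_circle.sequence) < c:
        raise CoreNotFoundError("attP not found on the phage circle")
    rotated = doubled[pos : pos + len(phage_circle.sequence)]
    interior = rotated[c:]
    # Reverse of the excision crossover: attL = attB[:k] + attP[k:], attR = attP[:k] + attB[k:]
    attL = attB[:k] + attP[k:]
    attR = attP[:k] + attB[k:]
    new_seq = host_seq[:attB_position] + attL + interior + attR + host_seq[attB_position + c :]
    return GenomeRecord(
        f"{host_genome.id}_integrated", new_seq, f"after integration of {phage_circle.id}"
    )
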