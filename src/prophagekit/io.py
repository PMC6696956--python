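"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are 0-based half-open throughout. Publications usually
print 1-based inclusive positions; :func:`printed_to_internal` and
:func:`internal_to_printed` convert between the two conventions and are
mutually inverse. Supported formats: FASTA (genomes and phage sequences),
BED 3-4 column (prophage region tables), bedGraph (coverage tracks), CSV
(qPCR plates) and a JSON run configuration.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "ProphageRegion",
    "CoverageTrack",
    "QpcrPlate",
    "RunConfig",
    "QPCR_TARGETS",
    "read_fasta",
    "write_fasta",
    "read_regions",
    "write_regions",
    "read_coverage",
    "write_coverage",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "printed_to_internal",
    "internal_to_printed",
    "get_logger",
]

_DNA_ALPHABET = frozenset("ACGTN")

#: Allowed qPCR assay targets. ``*_attB`` assays amplify the reconstituted
#: bacterial attachment-site junction that only exists after prophage
#: excision; ``*_circle`` assays amplify across the circular phage DNA
#: junction; ``reference_tk`` is the single-copy genomic thymidine-kinase
#: control; ``standard`` marks dilution-series wells.
QPCR_TARGETS = frozenset(
    {"vnp1_attB", "vnp2_attB", "vnp1_circle", "vnp2_circle", "reference_tk", "standard"}
)


def get_logger(name: str = "prophagekit") -> logging.Logger:
    """Return the package logger, configured once to log to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def printed_to_internal(start: int, end: int) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to 0-based half-open."""
    if start < 1 or end < start:
        raise ValueError(f"invalid printed coordinates ({start}, {end})")
    return start - 1, end


def internal_to_printed(start: int, end: int) -> tuple[int, int]:
    """Convert 0-based half-open coordinates to 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid internal coordinates ({start}, {end})")
    return start + 1, end


def _validate_dna(sequence: str, *, name: str) -> None:
    bad = set(sequence) - _DNA_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(sequence) if c in bad)
        raise ValueError(
            f"record {name!r}: illegal character {sequence[pos]!r} at position {pos}"
            + (" (RNA input? U is rejected)" if sequence[pos] == "U" else "")
        )


@dataclass(frozen=True)
class GenomeRecord:
    """A replicon or phage sequence over the alphabet ``{A, C, G, T, N}``."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        _validate_dna(self.sequence, name=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProphageRegion:
    """A chromosomal interval (0-based half-open) holding a prophage.

    ``att_core`` optionally carries the attachment-site core, the short
    sequence present as a direct repeat at both flanks of the integrated
    prophage.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    att_core: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.name!r}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.att_core is not None:
            object.__setattr__(self, "att_core", self.att_core.upper())
            _validate_dna(self.att_core, name=f"{self.name or self.chrom}:att_core")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ProphageRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class CoverageTrack:
    """Dense per-base sequencing depth over a single replicon."""

    chrom: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0):
            raise ValueError("negative depth values")

    @property
    def length(self) -> int:
        return int(self.depth.size)

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return CoverageTrack(self.chrom, self.depth * factor)


@dataclass
class QpcrPlate:
    """A typed qPCR plate: one row per well.

    Columns: ``sample_id``, ``target``, ``ct`` (threshold cycle; NaN is the
    no-amplification sentinel), ``known_conc`` (ng/ul, standards only) and
    ``replicate``. Technical replicates are kept as separate rows; averaging
    happens downstream on the concentration scale.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "target", "ct")

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"qPCR plate missing required columns: {missing}")
        if "known_conc" not in df.columns:
            df["known_conc"] = np.nan
        if "replicate" not in df.columns:
            df["replicate"] = 1
        df["ct"] = pd.to_numeric(df["ct"], errors="raise")
        df["known_conc"] = pd.to_numeric(df["known_conc"], errors="raise")
        df["replicate"] = df["replicate"].astype(int)

        bad_targets = set(df["target"]) - QPCR_TARGETS
        if bad_targets:
            raise ValueError(f"unknown qPCR targets: {sorted(bad_targets)}")
        measured = df["ct"].notna()
        if (df.loc[measured, "ct"] <= 0).any():
            raise ValueError("all measured Ct values must be positive")
        std = df["target"] == "standard"
        if std.any() and df.loc[std, "known_conc"].isna().any():
            raise ValueError("standard wells must carry known_conc")
        if std.any() and (df.loc[std, "known_conc"] <= 0).any():
            raise ValueError("standard known_conc must be positive")
        self.data = df.reset_index(drop=True)

    @property
    def standards(self) -> pd.DataFrame:
        return self.data[self.data["target"] == "standard"]

    @property
    def unknowns(self) -> pd.DataFrame:
        return self.data[self.data["target"] != "standard"]


@dataclass
class RunConfig:
    """A JSON-serialisable run configuration: seed, paths, per-module blocks."""

    seed: int = 0
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            seed=doc.get("seed", 0),
            paths=doc.get("paths", {}),
            params=doc.get("params", {}),
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "paths": self.paths, "params": self.params}, fh, indent=2)

    def log_resolved(self, logger: logging.Logger | None = None) -> None:
        (logger or get_logger()).info(
            "resolved config: seed=%d params=%s", self.seed, json.dumps(self.params, sort_keys=True)
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects, in file order.

    Sequences are uppercased; duplicate ids, empty files and characters
    outside ``{A, C, G, T, N}`` (including RNA ``U``) are rejected.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1 :]
        records.append(GenomeRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED regions


def read_regions(path: str | Path) -> list[ProphageRegion]:
    """Read a 3-4 column BED file (0-based half-open) of prophage regions."""
    regions: list[ProphageRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            regions.append(ProphageRegion(chrom, start, end, name))
    return regions


def write_regions(regions: Iterable[ProphageRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name:
                cols.append(r.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# bedGraph coverage


def read_coverage(path: str | Path, bin_size: int = 1) -> CoverageTrack:
    """Read a bedGraph file into a dense per-base :class:`CoverageTrack`.

    Intervals must be sorted and non-overlapping and refer to a single
    replicon; gaps are filled with depth 0. ``bin_size > 1`` averages the
    reconstructed signal into bins at read time (last partial bin kept).
    """
    chroms: list[str] = []
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chroms.append(fields[0])
            start, end = int(fields[1]), int(fields[2])
            depth = float(fields[3])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth")
            rows.append((start, end, depth))
    if not rows:
        raise ValueError(f"no coverage intervals in {path}")
    if len(set(chroms)) != 1:
        raise ValueError("coverage track must cover a single replicon")
    prev_end = 0
    for start, end, _ in rows:
        if start < prev_end:
            raise ValueError("coverage intervals must be sorted and non-overlapping")
        prev_end = end
    length = rows[-1][1]
    depth = np.zeros(length, dtype=float)
    for start, end, d in rows:
        depth[start:end] = d
    track = CoverageTrack(chroms[0], depth)
    if bin_size > 1:
        n_bins = -(-length // bin_size)
        binned = np.array(
            [depth[i * bin_size : (i + 1) * bin_size].mean() for i in range(n_bins)]
        )
        track = CoverageTrack(chroms[0], binned)
    return track


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as run-length-encoded bedGraph (zeros omitted)."""
    depth = track.depth
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [depth.size]))
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            d = depth[s]
            if d == 0:
                continue
            fh.write(f"{track.chrom}\t{s}\t{e}\t{d:g}\n")


# ---------------------------------------------------------------------------
# qPCR CSV


def read_qpcr_csv(path: str | Path) -> QpcrPlate:
    """Read a comma-separated qPCR plate (header mandatory)."""
    df = pd.read_csv(path)
    return QpcrPlate(df)


def write_qpcr_csv(plate: QpcrPlate, path: str | Path) -> None:
    plate.data.to_csv(path, index=False)
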