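"""Cleavage-rate datasets: records, guide grouping, splits, and file I/O.

The on-disk exchange format is a TSV with header columns ``guide_id``,
``guide_seq``, ``pairing`` and ``k``: one row per target variant, with the
pairing column in the run-length dialect of :mod:`piwislice.encoding` and
``k`` the pre-steady-state cleavage rate (positive, inverse-time units of the
source assay). Guide positions are 1-based (g1..gL) in all human-facing I/O;
insertion boundary slots are 0-based 0..L everywhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .encoding import (
    GuideSequence,
    InteractionEncoding,
    PairingError,
    PairingSpec,
    encode_interaction,
    format_pairing_string,
    parse_pairing_string,
)


@dataclass(frozen=True)
class CleavageRecord:
    """One guide-target variant with its measured cleavage rate k > 0."""

    guide: GuideSequence
    spec: PairingSpec
    k: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k <= 0:
            raise ValueError(f"cleavage rate must be finite and positive, got {self.k}")
        if len(self.spec) != len(self.guide):
            raise ValueError(
                f"guide {self.guide.id!r}: spec length {len(self.spec)} != guide length {len(self.guide)}"
            )

    def encode(self) -> InteractionEncoding:
        return encode_interaction(self.guide, self.spec)


@dataclass
class CleavageDataset:
    """A list of records grouped by guide id, with optional split labels."""

    records: list[CleavageRecord]
    split: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split:
            self.split = [None] * len(self.records)
        if len(self.split) != len(self.records):
            raise ValueError("split labels must align with records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CleavageRecord]:
        return iter(self.records)

    @property
    def guide_groups(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(self.records):
            groups.setdefault(rec.guide.id, []).append(i)
        return groups

    @property
    def guide_ids(self) -> list[str]:
        return sorted(self.guide_groups)

    @property
    def rates(self) -> np.ndarray:
        return np.array([rec.k for rec in self.records])

    def subset(self, indices: Sequence[int]) -> "CleavageDataset":
        idx = list(indices)
        return CleavageDataset(
            records=[self.records[i] for i in idx],
            split=[self.split[i] for i in idx],
        )

    def encodings(self) -> list[InteractionEncoding]:
        return [rec.encode() for rec in self.records]

    def merged_with(self, other: "CleavageDataset") -> "CleavageDataset":
        return CleavageDataset(records=self.records + other.records, split=self.split + other.split)


HEADER = ["guide_id", "guide_seq", "pairing", "k"]


def read_cleavage_table(path: str | Path) -> CleavageDataset:
    """Read a cleavage TSV; every row is validated, errors name the row."""
    path = Path(path)
    records: list[CleavageRecord] = []
    guides: dict[str, GuideSequence] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(HEADER) <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header columns {HEADER}, got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            try:
                gid = row["guide_id"].strip()
                guide = guides.get(gid)
                if guide is None:
                    guide = guides[gid] = GuideSequence(id=gid, nucleotides=row["guide_seq"])
                elif guide.nucleotides != row["guide_seq"].strip().upper().replace("T", "U"):
                    raise ValueError(f"guide {gid!r} has inconsistent sequences across rows")
                spec = parse_pairing_string(row["pairing"], L=len(guide))
                records.append(CleavageRecord(guide=guide, spec=spec, k=float(row["k"])))
            except (PairingError, ValueError, KeyError) as exc:
                raise ValueError(f"{path}, row {lineno}: {exc}") from exc
    return CleavageDataset(records=records)


def write_cleavage_table(data: CleavageDataset, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HEADER)
        for rec in data.records:
            writer.writerow(
                [rec.guide.id, rec.guide.nucleotides, format_pairing_string(rec.spec), repr(rec.k)]
            )


def read_guides_fasta(path: str | Path) -> list[GuideSequence]:
    """Read guide RNAs from FASTA; T is normalized to U."""
    return [GuideSequence(id=rec.id, nucleotides=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
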