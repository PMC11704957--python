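"""Sequence and label I/O.

Reads protein FASTA files, assembles the labeled dataset (one real-valued
experimental measure per sequence, e.g. ``k_cat/K_M``) that every downstream
stage consumes, and writes the ranked candidate table.

Two label dialects are supported:

* the last whitespace-separated token of each FASTA header is the measure
  (``>wt some text 4.2``), or
* a plain FASTA plus a two-column TSV sidecar ``id<TAB>value`` with a header
  row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "VALID_RESIDUES",
    "SequenceRecord",
    "FitnessDataset",
    "RankedCandidate",
    "read_fasta",
    "write_fasta",
    "read_fitness_fasta",
    "read_fitness_tsv",
    "write_fitness_fasta",
    "write_ranked_table",
    "read_ranked_table",
]

#: The 20 standard amino acids plus X (unknown). B/Z/U and other ambiguity
#: codes are rejected to keep the embedder contract explicit.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence with a unique identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence for {self.id!r} is empty")
        seq = self.sequence.upper()
        bad = [(i, c) for i, c in enumerate(seq) if c not in VALID_RESIDUES]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"invalid residue {c!r} at position {i + 1} in sequence {self.id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


Transform = Literal["identity", "log10"]


@dataclass
class FitnessDataset:
    """Ordered sequences paired with one real-valued measure each.

    ``values`` holds the raw measurements; ``transformed_values()`` applies
    the configured transform (``log10`` by default for kinetic parameters
    spanning orders of magnitude) at training time.
    """

    records: list[SequenceRecord]
    values: np.ndarray
    measure_name: str = "fitness"
    transform: Transform = "identity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.records):
            raise ValueError(
                f"{len(self.records)} records but {len(self.values)} values"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("fitness values must be finite")
        if self.transform not in ("identity", "log10"):
            raise ValueError(f"unknown transform {self.transform!r}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def transformed_values(self) -> np.ndarray:
        """Values on the training scale (log10 requires all raw values > 0)."""
        if self.transform == "identity":
            return self.values.copy()
        if np.any(self.values <= 0):
            raise ValueError("log10 transform requires all raw values > 0")
        return np.log10(self.values)

    def subset(self, indices: Sequence[int]) -> "FitnessDataset":
        return FitnessDataset(
            records=[self.records[i] for i in indices],
            values=self.values[list(indices)],
            measure_name=self.measure_name,
            transform=self.transform,
        )


@dataclass(frozen=True)
class RankedCandidate:
    """One row of the ranked output: dense 1-based rank, prediction in
    transformed space, optional identity to the query sequence."""

    id: str
    predicted_value: float
    rank: int
    identity_to_query: float | None = None


def _clean_sequence(raw: str) -> str:
    return raw.strip().upper().rstrip("*")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved, lowercase residues are uppercased and terminal stop
    characters (``*``) are stripped. Empty files, duplicate ids and
    non-amino-acid characters raise ``ValueError``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id) :].strip()
        records.append(
            SequenceRecord(
                id=entry.id,
                sequence=_clean_sequence(str(entry.seq)),
                description=desc,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA (id + description on the header line)."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(Path(path)), "fasta")


def _parse_value_token(header_desc: str, rec_id: str) -> float:
    tokens = header_desc.split()
    if not tokens:
        raise ValueError(
            f"header for {rec_id!r} carries no numeric measure "
            "(expected the last whitespace-separated token to be a number)"
        )
    try:
        value = float(tokens[-1])
    except ValueError:
        raise ValueError(
            f"last header token {tokens[-1]!r} for {rec_id!r} is not a number"
        ) from None
    if not math.isfinite(value):
        raise ValueError(f"measure for {rec_id!r} is not finite: {tokens[-1]!r}")
    return value


def read_fitness_fasta(
    path: str | Path,
    measure_name: str = "fitness",
    transform: Transform = "identity",
) -> FitnessDataset:
    """Read a labeled FASTA: the last header token of each entry is the measure.

    Example: ``>wt kynureninase 4.2`` gives id ``wt`` and value ``4.2``.
    """
    records = read_fasta(path)
    values = []
    stripped = []
    for rec in records:
        values.append(_parse_value_token(rec.description, rec.id))
        desc = " ".join(rec.description.split()[:-1])
        stripped.append(SequenceRecord(rec.id, rec.sequence, desc))
    return FitnessDataset(
        records=stripped,
        values=np.asarray(values, dtype=float),
        measure_name=measure_name,
        transform=transform,
    )


def read_fitness_tsv(
    fasta_path: str | Path,
    tsv_path: str | Path,
    measure_name: str = "fitness",
    transform: Transform = "identity",
) -> FitnessDataset:
    """Read a plain FASTA plus a two-column TSV sidecar (``id<TAB>value``,
    header row). Every TSV id must be present in the FASTA; FASTA order wins.
    """
    records = read_fasta(fasta_path)
    by_id: dict[str, float] = {}
    lines = Path(tsv_path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty label file {tsv_path}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{tsv_path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        rec_id, raw = parts
        try:
            by_id[rec_id] = float(raw)
        except ValueError:
            raise ValueError(
                f"{tsv_path}:{lineno}: value {raw!r} is not a number"
            ) from None
    fasta_ids = {r.id for r in records}
    missing = sorted(set(by_id) - fasta_ids)
    if missing:
        raise ValueError(f"label ids absent from FASTA: {missing[:5]}")
    unlabeled = [r.id for r in records if r.id not in by_id]
    if unlabeled:
        raise ValueError(f"sequences without a label: {unlabeled[:5]}")
    return FitnessDataset(
        records=records,
        values=np.asarray([by_id[r.id] for r in records], dtype=float),
        measure_name=measure_name,
        transform=transform,
    )


def write_fitness_fasta(dataset: FitnessDataset, path: str | Path) -> None:
    """Write a labeled FASTA in the last-header-token dialect."""
    with open(path, "w") as fh:
        for rec, value in zip(dataset.records, dataset.values):
            desc = f"{rec.description} {float(value)!r}".strip()
            fh.write(f">{rec.id} {desc}\n{rec.sequence}\n")


_RANKED_COLUMNS = ("rank", "id", "predicted_value", "identity_to_query")


def write_ranked_table(
    candidates: Sequence[RankedCandidate], path: str | Path
) -> None:
    """Write the ranked candidate list as a TSV.

    Columns: rank (1-based, dense), id, predicted_value, identity_to_query
    (empty when unknown). The input must already be sorted by rank.
    """
    ranks = [c.rank for c in candidates]
    if ranks != sorted(ranks) or ranks != list(range(1, len(ranks) + 1)):
        raise ValueError("candidates must be sorted with dense 1-based ranks")
    with open(path, "w") as fh:
        fh.write("\t".join(_RANKED_COLUMNS) + "\n")
        for c in candidates:
            ident = "" if c.identity_to_query is None else f"{c.identity_to_query:.6f}"
            fh.write(f"{c.rank}\t{c.id}\t{c.predicted_value:.6f}\t{ident}\n")


def read_ranked_table(path: str | Path) -> list[RankedCandidate]:
    """Read a TSV written by :func:`write_ranked_table`."""
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != _RANKED_COLUMNS:
        raise ValueError(f"{path} is not a ranked candidate table")
    out = []
    for line in lines[1:]:
        rank, rec_id, pred, ident = line.split("\t")
        out.append(
            RankedCandidate(
                id=rec_id,
                predicted_value=float(pred),
                rank=int(rank),
                identity_to_query=float(ident) if ident else None,
            )
        )
    return out
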