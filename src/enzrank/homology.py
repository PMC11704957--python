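"""Homology-hit filtering, identity computation, redundancy removal and
candidate ranking.

The homology search itself (e.g. MMseqs2 or BLAST against a large protein
database) is consumed as a precomputed tabular result; this module applies
the significance and bidirectional-coverage filters, collapses near-identical
sequences, ranks the surviving candidates by predicted fitness and offers an
identity-vs-prediction diagnostic showing whether the ranker merely tracks
similarity to the query enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .embedders import EmbeddingMatrix
from .regression import TrainedRanker, predict, spearman_rho
from .seqio import RankedCandidate, SequenceRecord

__all__ = [
    "HomologyHit",
    "parse_hits_m8",
    "write_hits_m8",
    "attach_lengths",
    "filter_hits",
    "pairwise_identity",
    "redundancy_filter",
    "rank_candidates",
    "identity_vs_prediction",
    "IdentitySummary",
]


@dataclass
class HomologyHit:
    """One query-target alignment record in BLAST/MMseqs2 tabular form.

    Positions are 1-based inclusive, as in the m8 format. ``q_len``/``t_len``
    come from the extended 14-column dialect or are attached from FASTA.
    """

    query_id: str
    target_id: str
    percent_identity: float
    aln_len: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    evalue: float
    bit_score: float
    q_len: int | None = None
    t_len: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value for {self.target_id!r}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity must be in [0, 100]")
        if not 1 <= self.q_start <= self.q_end:
            raise ValueError(f"bad query span for {self.target_id!r}")
        if not 1 <= self.t_start <= self.t_end:
            raise ValueError(f"bad target span for {self.target_id!r}")
        if self.q_len is not None and self.q_end > self.q_len:
            raise ValueError(f"query span exceeds q_len for {self.target_id!r}")
        if self.t_len is not None and self.t_end > self.t_len:
            raise ValueError(f"target span exceeds t_len for {self.target_id!r}")

    def query_coverage(self) -> float:
        if self.q_len is None:
            raise ValueError(f"q_len unknown for hit {self.query_id}->{self.target_id}")
        return (self.q_end - self.q_start + 1) / self.q_len

    def target_coverage(self) -> float:
        if self.t_len is None:
            raise ValueError(f"t_len unknown for hit {self.query_id}->{self.target_id}")
        return (self.t_end - self.t_start + 1) / self.t_len


def parse_hits_m8(path: str | Path) -> list[HomologyHit]:
    """Parse BLAST outfmt-6 style TSV (12 standard columns, optionally with
    trailing qlen and tlen). Malformed lines raise with their line number."""
    hits: list[HomologyHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) not in (12, 14):
            raise ValueError(
                f"{path}:{lineno}: expected 12 or 14 columns, got {len(cols)}"
            )
        try:
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    target_id=cols[1],
                    percent_identity=float(cols[2]),
                    aln_len=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_openings=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    t_start=int(cols[8]),
                    t_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bit_score=float(cols[11]),
                    q_len=int(cols[12]) if len(cols) == 14 else None,
                    t_len=int(cols[13]) if len(cols) == 14 else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_m8(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back to tabular form (14 columns when lengths are known)."""
    with open(path, "w") as fh:
        for h in hits:
            cols = [
                h.query_id, h.target_id, f"{h.percent_identity:.3f}",
                str(h.aln_len), str(h.mismatches), str(h.gap_openings),
                str(h.q_start), str(h.q_end), str(h.t_start), str(h.t_end),
                f"{h.evalue:.3e}", f"{h.bit_score:.1f}",
            ]
            if h.q_len is not None and h.t_len is not None:
                cols += [str(h.q_len), str(h.t_len)]
            fh.write("\t".join(cols) + "\n")


def attach_lengths(
    hits: Sequence[HomologyHit],
    query_lengths: Mapping[str, int],
    target_lengths: Mapping[str, int],
) -> list[HomologyHit]:
    """Fill in missing q_len/t_len from FASTA-derived length maps."""
    out = []
    for h in hits:
        q_len = h.q_len if h.q_len is not None else query_lengths.get(h.query_id)
        t_len = h.t_len if h.t_len is not None else target_lengths.get(h.target_id)
        if q_len is None or t_len is None:
            raise ValueError(
                f"no length available for hit {h.query_id}->{h.target_id}"
            )
        out.append(
            HomologyHit(
                **{
                    **h.__dict__,
                    "q_len": int(q_len),
                    "t_len": int(t_len),
                }
            )
        )
    return out


def filter_hits(
    hits: Sequence[HomologyHit],
    max_evalue: float = 1e-3,
    min_bidir_cov: float = 0.9,
) -> list[HomologyHit]:
    """Keep hits with E-value strictly below ``max_evalue`` and alignment
    spans covering at least ``min_bidir_cov`` of BOTH query and target.

    Order is preserved; the E-value boundary is strict (an E-value equal to
    the threshold is removed), the coverage boundary is inclusive.
    """
    kept = []
    for h in hits:
        if h.q_len is None or h.t_len is None:
            raise ValueError(
                f"cannot compute coverage for {h.query_id}->{h.target_id}: "
                "lengths unknown (use attach_lengths)"
            )
        if (
            h.evalue < max_evalue
            and h.query_coverage() >= min_bidir_cov
            and h.target_coverage() >= min_bidir_cov
        ):
            kept.append(h)
    return kept


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch with BLOSUM62, affine gaps (open 11, extend 1);
    identity = identical aligned columns / total alignment columns, gaps
    counting in the denominator. Symmetric in its arguments.
    """
    if a.sequence == b.sequence:
        return 1.0
    # fixed argument order so f(a,b) and f(b,a) traverse the same alignment
    first, second = sorted((a.sequence, b.sequence))
    alignment = _aligner().align(first, second)[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    matches = sum(c1 == c2 and c1 != "-" for c1, c2 in zip(s1, s2))
    return matches / len(s1)


def redundancy_filter(
    records: Sequence[SequenceRecord], threshold: float = 0.9
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy identity-based redundancy removal.

    Records are visited sorted by (length descending, id ascending); each
    joins the first existing representative with pairwise identity >=
    ``threshold``, otherwise it founds a new cluster. Returns the
    representatives (in visiting order) and the id -> representative-id map.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        for rep in reps:
            if pairwise_identity(rec, rep) >= threshold:
                assignment[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            assignment[rec.id] = rec.id
    return reps, assignment


def rank_candidates(
    model: TrainedRanker,
    embeddings: EmbeddingMatrix,
    records: Sequence[SequenceRecord],
) -> list[RankedCandidate]:
    """Rank candidates by predicted fitness, descending; ties by id.

    Ranks are dense and 1-based. Every record must have an embedding row.
    """
    ids = [r.id for r in records]
    X = embeddings.rows_for(ids)  # raises KeyError on a missing embedding
    preds = predict(model, X)
    order = sorted(range(len(ids)), key=lambda i: (-preds[i], ids[i]))
    return [
        RankedCandidate(id=ids[i], predicted_value=float(preds[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


@dataclass(frozen=True)
class IdentitySummary:
    """Identity-to-query profile of the top-ranked candidates."""

    identities: tuple[float, ...]
    min_identity: float
    max_identity: float
    rank_identity_rho: float | None  # None when degenerate (all ties)


def identity_vs_prediction(
    ranked: Sequence[RankedCandidate],
    query: SequenceRecord,
    records: Sequence[SequenceRecord],
    top_k: int = 50,
) -> IdentitySummary:
    """Diversity diagnostic: identity to the query among the top-k candidates.

    A ranker blindly tracking similarity to the query would show identity
    decreasing smoothly with rank; a wide identity range among top hits
    indicates the regressor uses features beyond query similarity. The
    Spearman rho between rank and identity is reported, or ``None`` when all
    identities (or ranks) tie.
    """
    if top_k > len(ranked):
        raise ValueError(f"top_k={top_k} exceeds {len(ranked)} candidates")
    by_id = {r.id: r for r in records}
    top = sorted(ranked, key=lambda c: c.rank)[:top_k]
    idents = [pairwise_identity(by_id[c.id], query) for c in top]
    try:
        rho = spearman_rho([c.rank for c in top], idents)
    except ValueError:
        rho = None
    return IdentitySummary(
        identities=tuple(idents),
        min_identity=min(idents),
        max_identity=max(idents),
        rank_identity_rho=rho,
    )
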