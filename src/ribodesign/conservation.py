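"""Per-column conservation of a pre-aligned large-subunit rRNA alignment,
mapped onto reference (E. coli) residue numbering.

Conservation of a column is the frequency of its modal base among non-gap,
unambiguous letters, in percent.  An optional variant measures agreement
with the reference sequence's base instead of the modal base.  The
alignment itself is an input — no alignment construction or phylogenetics
happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .library import RNA_BASES

__all__ = [
    "Alignment",
    "ConservationProfile",
    "read_alignment",
    "map_columns",
    "column_conservation",
    "build_profile",
    "region_summary",
]

GAP_CHARS = {"-", "."}


@dataclass
class Alignment:
    """Equal-length gapped RNA records with a designated reference row."""

    records: list[tuple[str, str]]
    ref_id: str

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no records")
        ncol = len(self.records[0][1])
        for rid, seq in self.records:
            if len(seq) != ncol:
                raise ValueError(
                    f"ragged alignment: record {rid!r} has length {len(seq)}, expected {ncol}"
                )
        if self.ref_id not in {rid for rid, _ in self.records}:
            raise KeyError(f"reference id {self.ref_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def reference(self) -> str:
        return next(seq for rid, seq in self.records if rid == self.ref_id)

    def column(self, j: int) -> list[str]:
        if not 0 <= j < self.n_columns:
            raise IndexError(f"column {j} out of range")
        return [seq[j] for _, seq in self.records]


def _normalize(seq: str) -> str:
    return seq.lower().replace("t", "u")


def read_alignment(path: str | Path, ref_id: str) -> Alignment:
    """Read a pre-aligned multi-FASTA; letters are lowercased and DNA t
    mapped to u so DNA-alphabet alignments normalize to RNA."""
    records = [
        (rec.id, _normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{Path(path).name}: no FASTA records found")
    return Alignment(records=records, ref_id=ref_id)


def map_columns(aln: Alignment, offset: int = 0) -> dict[int, int]:
    """Map alignment columns to reference positions.

    Columns where the reference row is non-gap map to successive reference
    positions (1-based plus ``offset``); reference-gap columns are absent
    from the map.
    """
    ref = aln.reference
    if all(c in GAP_CHARS for c in ref):
        raise ValueError("reference sequence is all gaps")
    mapping: dict[int, int] = {}
    pos = 0
    for j, c in enumerate(ref):
        if c not in GAP_CHARS:
            pos += 1
            mapping[j] = pos + offset
    return mapping


def column_conservation(aln: Alignment, column: int) -> float | None:
    """Conservation of one column: 100 x modal-base count / non-gap count.

    Ambiguity letters are excluded from both numerator and denominator.
    Returns None (missing) when no unambiguous letters remain.
    """
    counts = {b: 0 for b in RNA_BASES}
    for c in aln.column(column):
        if c in counts:
            counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        return None
    return 100.0 * max(counts.values()) / total


def _column_identity(aln: Alignment, column: int, ref_base: str) -> float | None:
    """Reference-base variant: % of unambiguous letters equal to the
    reference base in that column."""
    letters = [c for c in aln.column(column) if c in RNA_BASES]
    if not letters:
        return None
    return 100.0 * sum(c == ref_base for c in letters) / len(letters)


@dataclass
class ConservationProfile:
    """Per-reference-position conservation with column coverage."""

    frame: pd.DataFrame  # index: reference position; columns: ref_base, conservation, coverage

    def __post_init__(self):
        cons = self.frame["conservation"].dropna()
        if ((cons < 0) | (cons > 100)).any():
            raise ValueError("conservation percentages must lie in [0, 100]")
        idx = self.frame.index
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("reference positions must be strictly increasing")

    def __contains__(self, position: int) -> bool:
        return position in self.frame.index

    def at(self, position: int) -> tuple[str, float, float]:
        row = self.frame.loc[position]
        return str(row["ref_base"]), float(row["conservation"]), float(row["coverage"])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="position")


def build_profile(
    aln: Alignment, offset: int = 0, metric: str = "modal"
) -> ConservationProfile:
    """Conservation profile over all reference positions.

    ``metric`` is ``"modal"`` (frequency of the most common base, the
    default) or ``"reference"`` (frequency of the reference row's base).
    Coverage is the fraction of rows that are non-gap in the column.
    """
    if metric not in ("modal", "reference"):
        raise ValueError("metric must be 'modal' or 'reference'")
    mapping = map_columns(aln, offset=offset)
    ref = aln.reference
    rows = []
    for j, pos in mapping.items():
        column = aln.column(j)
        coverage = sum(c not in GAP_CHARS for c in column) / aln.n_rows
        if metric == "modal":
            cons = column_conservation(aln, j)
        else:
            cons = _column_identity(aln, j, ref[j])
        rows.append(
            {"position": pos, "ref_base": ref[j], "conservation": cons, "coverage": coverage}
        )
    frame = pd.DataFrame(rows).set_index("position")
    return ConservationProfile(frame)


def region_summary(
    profile: ConservationProfile,
    positions: Sequence[int],
    thresholds: Iterable[float] = (91.0, 95.0),
) -> dict:
    """Mean conservation over a region's positions plus counts above each
    threshold (strict >)."""
    missing = [p for p in positions if p not in profile]
    if missing:
        raise KeyError(f"positions absent from profile: {missing}")
    values = []
    per_position = []
    for p in positions:
        base, cons, cov = profile.at(p)
        per_position.append({"position": p, "ref_base": base,
                             "conservation": cons, "coverage": cov})
        if not math.isnan(cons):
            values.append(cons)
    mean = float(pd.Series(values).mean()) if values else math.nan
    return {
        "mean": mean,
        "per_position": per_position,
        "n_above": {float(t): sum(v > t for v in values) for t in thresholds},
    }
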