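"""Score-based selection protocols for building screening panels.

Three protocols cover the workflow: span-the-range picks to probe the
score-activity relationship, top-fraction picks once that relationship is
trusted, and fully randomized negative controls emulating randomized
primers (which, unlike designed libraries, may re-draw the wild-type base).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .library import LibraryDefinition, SequenceVariant

__all__ = [
    "RankedSet",
    "select_spanning",
    "select_top_fraction",
    "sample_random_controls",
]


@dataclass
class RankedSet:
    """Scored sequences sorted ascending (best score first)."""

    frame: pd.DataFrame  # columns: tag, bases?, score
    provenance: Literal["campaign", "forward-fold", "external"] = "external"

    def __post_init__(self):
        cols = self.frame.columns
        if "score" not in cols:
            raise ValueError("RankedSet frame needs a 'score' column")
        if "tag" not in cols:
            if "bases" in cols:
                self.frame = self.frame.assign(tag=self.frame["bases"])
            else:
                raise ValueError("RankedSet frame needs a 'tag' or 'bases' column")
        sort_cols = ["score"] + (["bases"] if "bases" in cols else ["tag"])
        self.frame = self.frame.sort_values(
            sort_cols, kind="mergesort", ignore_index=True
        )

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[str, float]], provenance: str = "external"
    ) -> "RankedSet":
        frame = pd.DataFrame(pairs, columns=["tag", "score"])
        return cls(frame, provenance=provenance)  # type: ignore[arg-type]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def select_spanning(ranked: RankedSet, n: int = 50) -> pd.DataFrame:
    """Pick ``n`` sequences at evenly spaced score quantiles.

    Quantiles 0, 1/(n-1), ..., 1 are mapped to ranks by the nearest-rank
    rule (rank = ceil(q*N), floored at 1); a rank already used steps to the
    next unused one so exactly ``n`` distinct rows return.  Both extremes
    of the score range are always included.
    """
    N = len(ranked)
    if N < n:
        raise ValueError(f"ranked set has {N} rows < n={n}; lower n")
    if n < 1:
        raise ValueError("n must be >= 1")
    used: set[int] = set()
    picks: list[int] = []
    qs = [0.0] if n == 1 else [k / (n - 1) for k in range(n)]
    for q in qs:
        rank = max(1, math.ceil(q * N))
        while rank in used and rank <= N:
            rank += 1
        if rank > N:  # walked off the top; step down instead
            rank = max(1, math.ceil(q * N))
            while rank in used:
                rank -= 1
        used.add(rank)
        picks.append(rank - 1)
    return ranked.frame.iloc[sorted(picks)].reset_index(drop=True)


def select_top_fraction(
    ranked: RankedSet, fraction: float = 0.30, n: int = 14
) -> pd.DataFrame:
    """Best ``n`` rows among the top ``fraction`` of the ranking.

    Eligibility is rank-based: the first ceil(fraction * N) rows (best
    scores).  If fewer than ``n`` are eligible, all of them return.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_eligible = math.ceil(fraction * len(ranked))
    eligible = ranked.frame.head(n_eligible)
    return eligible.head(n).reset_index(drop=True)


def sample_random_controls(
    lib: LibraryDefinition,
    n: int = 14,
    seed: int = 0,
    alphabet: str = "n",
) -> list[SequenceVariant]:
    """Draw ``n`` distinct variants from the fully randomized library.

    Emulates randomized mutagenic primers: every position is drawn from the
    full alphabet (IUPAC ``n`` = all four bases by default), so the
    wild-type base can reappear — unlike the designed library's
    anything-but-WT exclusion.  Seeded, without replacement, uniform over
    the space.
    """
    from .library import AMBIGUITY, _index_to_bases

    if n < 1:
        raise ValueError("n must be >= 1")
    letters = sorted(AMBIGUITY[alphabet])
    k = len(lib)
    total = len(letters) ** k
    if n > total:
        raise ValueError(f"cannot draw {n} distinct variants from a space of {total}")
    rng = np.random.default_rng(seed)
    if total <= 50_000_000:
        indices = sorted(rng.choice(total, size=n, replace=False).tolist())
    else:
        chosen: set[int] = set()
        while len(chosen) < n:
            chosen.add(int(rng.integers(total)))
        indices = sorted(chosen)
    alphabets = [letters] * k
    return [
        SequenceVariant(
            region=lib.region,
            variant_id=f"{lib.region}.rand{i}",
            bases=_index_to_bases(idx, alphabets),
            strand_lengths=lib.strand_lengths,
        )
        for i, idx in enumerate(indices, start=1)
    ]
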