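"""Monte Carlo design over nucleotide identity with a pluggable energy model.

The real pipeline scores each candidate with an all-atom energy from a
stepwise Monte Carlo structure calculation; that score function is external
to this toolkit and enters either through :class:`EnergyModel` subclasses
or through score files written by the external application
(:func:`read_scorefile`).  :class:`ToyEnergyModel` is a documented,
configurable stand-in that rewards Watson-Crick-rich helices: it is NOT an
approximation of the all-atom score, only a device with the same contract
(lower = more stable) plus a Gaussian noise channel emulating the
variability of conformational search.

Three sampling operations mirror the production workflow:

* ``design_trajectory`` — one Metropolis walk over variant space;
* ``design_campaign`` — many independent trajectories aggregated into a
  table of best frames with sampling frequencies;
* ``forward_fold`` — fixed sequences re-scored under an equal sampling
  budget so their best scores are directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .library import RNA_BASES, LibraryDefinition, SequenceVariant

__all__ = [
    "PairingMap",
    "EnergyModel",
    "ToyEnergyModel",
    "toy_energy",
    "TrajectoryResult",
    "CampaignTable",
    "ScoreRecord",
    "design_trajectory",
    "design_campaign",
    "forward_fold",
    "read_scorefile",
    "write_scorefile",
]

WC_PAIRS = {("a", "u"), ("u", "a"), ("c", "g"), ("g", "c")}
WOBBLE_PAIRS = {("g", "u"), ("u", "g")}


@dataclass(frozen=True)
class PairingMap:
    """Position-index base pairs plus the strand layout of the positions.

    ``pairs`` holds 0-based index pairs (i, j); ``strands`` groups the flat
    position indices into strands so intra-strand adjacency is defined.
    The position-wise convention pairs the i-th base of the first strand
    with the i-th base of the second.
    """

    pairs: tuple[tuple[int, int], ...]
    strands: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self):
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError(f"position {i} paired with itself")
            for k in (i, j):
                if k in seen:
                    raise ValueError(f"position {k} appears in more than one pair")
                seen.add(k)

    @classmethod
    def from_strands(cls, len1: int, len2: int) -> "PairingMap":
        """Position-wise duplex pairing: strand1[i] with strand2[i]."""
        if len1 != len2:
            raise ValueError("position-wise pairing requires equal strand lengths")
        pairs = tuple((i, len1 + i) for i in range(len1))
        strands = (tuple(range(len1)), tuple(range(len1, len1 + len2)))
        return cls(pairs, strands)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _check_bases(bases: str) -> None:
    bad = [i for i, b in enumerate(bases) if b not in RNA_BASES]
    if bad:
        raise ValueError(f"invalid base at position(s) {bad} in {bases!r}")


def toy_energy(
    bases: str,
    pairing: PairingMap,
    wc: float = -3.0,
    wobble: float = -1.5,
    mismatch: float = 1.0,
    continuity: float = -0.5,
) -> float:
    """Deterministic helix-quality score (arbitrary energy units, lower =
    more stable).

    Per pair in the map: ``wc`` for Watson-Crick (au/ua/cg/gc), ``wobble``
    for gu/ug, ``mismatch`` otherwise.  A helix-continuity bonus
    ``continuity`` is added for every intra-strand adjacent position pair
    whose members both sit in Watson-Crick pairs.  Unpaired positions
    contribute nothing.
    """
    _check_bases(bases)
    for i, j in pairing.pairs:
        if i >= len(bases) or j >= len(bases):
            raise IndexError(f"pair ({i},{j}) out of range for length {len(bases)}")
    score = 0.0
    is_wc: set[int] = set()
    for i, j in pairing.pairs:
        duo = (bases[i], bases[j])
        if duo in WC_PAIRS:
            score += wc
            is_wc.update((i, j))
        elif duo in WOBBLE_PAIRS:
            score += wobble
        else:
            score += mismatch
    # continuity needs an explicit strand layout; without one no two
    # positions are known to be sequence-adjacent
    for strand in pairing.strands:
        for a, b in zip(strand, strand[1:]):
            if a in is_wc and b in is_wc:
                score += continuity
    return score


class EnergyModel:
    """Contract: ``score(bases)`` -> energy (lower = more stable), plus a
    Gaussian noise channel of width ``sigma`` emulating conformational
    search variability.  sigma = 0 means deterministic scoring."""

    sigma: float = 0.0

    def score(self, bases: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def noisy_score(self, bases: str, rng: np.random.Generator) -> float:
        s = self.score(bases)
        if self.sigma > 0:
            s += rng.normal(0.0, self.sigma)
        return s


@dataclass
class ToyEnergyModel(EnergyModel):
    """Watson-Crick-rewarding stand-in energy with configurable terms."""

    pairing: PairingMap = field(default_factory=lambda: PairingMap(()))
    sigma: float = 0.0
    wc: float = -3.0
    wobble: float = -1.5
    mismatch: float = 1.0
    continuity: float = -0.5

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def score(self, bases: str) -> float:
        return toy_energy(
            bases, self.pairing, self.wc, self.wobble, self.mismatch, self.continuity
        )


@dataclass(frozen=True)
class TrajectoryResult:
    """Best frame of one design trajectory."""

    best_bases: str
    best_score: float
    seed: int
    cycles: int


@dataclass
class CampaignTable:
    """Aggregated best frames across trajectories.

    ``frame``: one row per distinct best-frame sequence with the minimum
    score it achieved and the number of trajectories that ended on it.
    Rows sorted by score ascending, ties lexicographic by bases.
    """

    frame: pd.DataFrame  # columns: bases, score, frequency
    n_trajectories: int

    def __post_init__(self):
        if int(self.frame["frequency"].sum()) != self.n_trajectories:
            raise ValueError("sampling frequencies must sum to trajectory count")

    @property
    def best(self) -> tuple[str, float]:
        row = self.frame.iloc[0]
        return str(row["bases"]), float(row["score"])

    def top(self, n: int) -> pd.DataFrame:
        return self.frame.head(n)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _random_variant(lib: LibraryDefinition, rng: np.random.Generator) -> list[str]:
    return [sorted(p.allowed)[rng.integers(len(p.allowed))] for p in lib.positions]


def design_trajectory(
    lib: LibraryDefinition,
    model: EnergyModel,
    n_cycles: int = 1000,
    seed: int = 0,
    temperature: float = 1.0,
) -> TrajectoryResult:
    """One Metropolis walk over a library's variant space.

    Each cycle proposes mutating one uniformly chosen position to a
    uniformly chosen allowed base, scores the proposal (through the model's
    noise channel when sigma > 0), accepts downhill moves always and uphill
    moves with probability exp(-delta/T).  The lowest-scoring frame seen —
    including the initial frame — is recorded.  Deterministic per seed.

    1000 cycles is the working default for simple helices; structurally
    complex regions warrant 2000.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if len(lib) == 0:
        raise ValueError("empty library")
    rng = np.random.default_rng(seed)
    current = _random_variant(lib, rng)
    current_score = model.noisy_score("".join(current), rng)
    best_bases, best_score = "".join(current), current_score
    for _ in range(n_cycles):
        pos = int(rng.integers(len(lib)))
        alphabet = sorted(lib.positions[pos].allowed)
        proposal = current.copy()
        proposal[pos] = alphabet[rng.integers(len(alphabet))]
        prop_bases = "".join(proposal)
        prop_score = model.noisy_score(prop_bases, rng)
        delta = prop_score - current_score
        if delta <= 0 or rng.random() < np.exp(-delta / temperature):
            current, current_score = proposal, prop_score
        if prop_score < best_score or (
            prop_score == best_score and prop_bases < best_bases
        ):
            best_bases, best_score = prop_bases, prop_score
    return TrajectoryResult(best_bases, float(best_score), seed, n_cycles)


def design_campaign(
    lib: LibraryDefinition,
    model: EnergyModel,
    n_trajectories: int = 10_000,
    n_cycles: int = 1000,
    seed: int = 0,
    temperature: float = 1.0,
) -> CampaignTable:
    """Run independent design trajectories and aggregate their best frames.

    Per-trajectory seeds are spawned deterministically from ``seed``.  The
    production scale is at least 10 000 trajectories per library; desk
    studies use hundreds.
    """
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_trajectories) % (2**31)
    best: dict[str, float] = {}
    freq: dict[str, int] = {}
    for t in range(n_trajectories):
        res = design_trajectory(
            lib, model, n_cycles=n_cycles, seed=int(child_seeds[t]), temperature=temperature
        )
        freq[res.best_bases] = freq.get(res.best_bases, 0) + 1
        if res.best_bases not in best or res.best_score < best[res.best_bases]:
            best[res.best_bases] = res.best_score
    frame = pd.DataFrame(
        {
            "bases": list(best.keys()),
            "score": [best[b] for b in best],
            "frequency": [freq[b] for b in best],
        }
    ).sort_values(["score", "bases"], kind="mergesort", ignore_index=True)
    return CampaignTable(frame=frame, n_trajectories=n_trajectories)


def forward_fold(
    variants: Sequence[str] | Sequence[SequenceVariant],
    model: EnergyModel,
    n_cycles: int = 500,
    n_models: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-score fixed sequences under an equal sampling budget.

    For each sequence, ``n_models`` independent models are generated, each
    the best of ``n_cycles`` evaluations through the model's noise channel
    (the sequence itself is fixed); the minimum over models is reported.
    An identical budget per sequence makes best scores comparable — the
    point of forward folding.  In production this is applied to the 200
    top-scoring design-campaign sequences with 500 cycles x 400 models.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    seqs = [v.bases if isinstance(v, SequenceVariant) else str(v) for v in variants]
    tags = [
        v.variant_id if isinstance(v, SequenceVariant) else str(v) for v in variants
    ]
    # per-variant child seeds: a variant's noise stream is independent of
    # how many other variants share the call and of n_models (prefix property)
    child = np.random.SeedSequence(seed).generate_state(max(len(seqs), 1)) % (2**31)
    rows = []
    for k, (tag, bases) in enumerate(zip(tags, seqs)):
        base_score = model.score(bases)
        if model.sigma > 0:
            vrng = np.random.default_rng(int(child[k]))
            noise = vrng.normal(0.0, model.sigma, size=(n_models, n_cycles))
            best = float(base_score + noise.min(axis=1).min())
        else:
            best = float(base_score)
        rows.append({"tag": tag, "bases": bases, "score": best})
    return (
        pd.DataFrame(rows)
        .sort_values(["score", "bases"], kind="mergesort", ignore_index=True)
    )


@dataclass(frozen=True)
class ScoreRecord:
    tag: str
    score: float
    source: str = ""


def read_scorefile(path: str | Path) -> list[ScoreRecord]:
    """Parse an externally computed score table.

    Accepts the whitespace-delimited dialect with a leading ``SCORE:``
    sentinel on header and data lines (as written by the external all-atom
    application) or a plain whitespace/tab-separated table.  The header
    must name a score column (``score`` or ``total_score``) and a tag
    column (``description`` or ``tag``); duplicate tags keep the minimum
    score.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    content = []
    for ln in lines:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("SCORE:"):
            stripped = stripped[len("SCORE:"):].strip()
        if stripped:
            content.append(stripped)
    if not content:
        warnings.warn(f"{path.name}: empty score file", stacklevel=2)
        return []
    header = content[0].split()
    lowered = [h.lower() for h in header]
    score_col = next(
        (i for i, h in enumerate(lowered) if h in ("score", "total_score")), None
    )
    tag_col = next(
        (i for i, h in enumerate(lowered) if h in ("description", "tag")), None
    )
    if score_col is None:
        raise ValueError(f"{path.name}: header has no score column: {header}")
    if tag_col is None:
        raise ValueError(f"{path.name}: header has no tag/description column: {header}")
    best: dict[str, float] = {}
    for lineno, row in enumerate(content[1:], start=2):
        fields = row.split()
        if len(fields) <= max(score_col, tag_col):
            raise ValueError(f"{path.name}:{lineno}: too few columns")
        try:
            score = float(fields[score_col])
        except ValueError:
            raise ValueError(
                f"{path.name}:{lineno}: non-numeric score {fields[score_col]!r}"
            ) from None
        if not np.isfinite(score):
            raise ValueError(f"{path.name}:{lineno}: non-finite score")
        tag = fields[tag_col]
        if tag not in best or score < best[tag]:
            best[tag] = score
    return [ScoreRecord(tag, sc, source=str(path)) for tag, sc in best.items()]


def write_scorefile(records: Sequence[ScoreRecord], path: str | Path) -> None:
    """Write records in the SCORE: dialect (round-trips through
    :func:`read_scorefile`)."""
    with open(path, "w") as fh:
        fh.write("SCORE: score description\n")
        for rec in records:
            fh.write(f"SCORE: {rec.score:.3f} {rec.tag}\n")
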