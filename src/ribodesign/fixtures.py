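"""Synthetic inputs for building and testing the toolkit without downloads.

Three generators mirror the three external data sources of the pipeline:

* :func:`make_ideal_helix` — a coarse-grained ideal A-form RNA duplex
  standing in for a deposited ribosome structure in structural tests;
* :func:`simulate_screen` — a reporter screen whose activities follow a
  stated linear score->activity link with Gaussian noise, emulating the
  observed inverse score-activity relationship;
* :func:`simulate_alignment` — a gapped multi-FASTA with planted
  per-column conservation.

Residues of the helix carry three pseudo-atoms (P, C1', base centroid):
enough for every geometric operation in scope — distance-sphere selection
and pairing geometry — while keeping fixtures tiny.  The A-form constants
(2.81 A rise, 32.7 deg twist per base pair) are standard literature
geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import RNA_BASES
from .scaffold import Atom, Residue, Structure

__all__ = [
    "AFORM_RISE",
    "AFORM_TWIST_DEG",
    "make_ideal_helix",
    "ScreenSimSpec",
    "simulate_screen",
    "screen_score_activity",
    "simulate_viability",
    "simulate_alignment",
    "write_alignment_fasta",
]

AFORM_RISE = 2.81  # A per base pair
AFORM_TWIST_DEG = 32.7  # degrees per base pair

# cylindrical placement of the pseudo-atoms (radius A, phase deg):
# tuned so paired C1'-C1' ~ 10.4 A and consecutive intra-strand P-P ~ 5.9 A
_C1_RADIUS = 9.4
_P_RADIUS = 9.2
_P_PHASE = -14.0
_CEN_RADIUS = 3.5
_CEN_PHASE = 34.0
_STRAND2_PHASE = 67.2  # included angle giving the 10.4 A C1'-C1' chord

_COMPLEMENT = {"a": "u", "u": "a", "c": "g", "g": "c"}


def _cyl(radius: float, angle_deg: float, z: float) -> tuple[float, float, float]:
    t = math.radians(angle_deg)
    return (radius * math.cos(t), radius * math.sin(t), z)


def make_ideal_helix(
    n_bp: int,
    sequence: str | None = None,
    sequence2: str | None = None,
    chains: tuple[str, str] = ("A", "B"),
    start_numbers: tuple[int, int] = (1, 1),
) -> Structure:
    """Build a coarse ideal A-form RNA duplex as a writable Structure.

    ``sequence`` is strand 1 in 5'->3' order; ``sequence2`` defaults to its
    reverse complement (a perfect Watson-Crick duplex).  Each residue gets
    P, C1' and a base-centroid pseudo-atom.  Chains and author-numbering
    offsets are configurable so reference numbering (e.g. 23S positions)
    survives round-trips.
    """
    if not 1 <= n_bp <= 20:
        raise ValueError("n_bp must be between 1 and 20")
    if sequence is None:
        sequence = ("gcau" * ((n_bp + 3) // 4))[:n_bp]
    sequence = sequence.lower()
    if len(sequence) != n_bp:
        raise ValueError(f"sequence length {len(sequence)} != n_bp {n_bp}")
    if any(b not in RNA_BASES for b in sequence):
        raise ValueError(f"non-RNA base in {sequence!r}")
    if sequence2 is None:
        sequence2 = "".join(_COMPLEMENT[b] for b in reversed(sequence))
    sequence2 = sequence2.lower()
    if len(sequence2) != n_bp:
        raise ValueError(f"strand 2 length {len(sequence2)} != n_bp {n_bp}")
    if any(b not in RNA_BASES for b in sequence2):
        raise ValueError(f"non-RNA base in {sequence2!r}")

    residues: list[Residue] = []
    for i, base in enumerate(sequence):
        theta = i * AFORM_TWIST_DEG
        z = i * AFORM_RISE
        atoms = (
            Atom("P", "P", *_cyl(_P_RADIUS, theta + _P_PHASE, z)),
            Atom("C1'", "C", *_cyl(_C1_RADIUS, theta, z)),
            Atom("CEN", "C", *_cyl(_CEN_RADIUS, theta + _CEN_PHASE, z)),
        )
        residues.append(
            Residue(chains[0], start_numbers[0] + i, base.upper(), "rna", atoms)
        )
    # strand 2 runs antiparallel: its k-th residue pairs strand 1's (n-1-k)-th
    for k, base in enumerate(sequence2):
        i = n_bp - 1 - k
        theta = i * AFORM_TWIST_DEG + _STRAND2_PHASE
        z = i * AFORM_RISE
        atoms = (
            Atom("P", "P", *_cyl(_P_RADIUS, theta - _P_PHASE, z)),
            Atom("C1'", "C", *_cyl(_C1_RADIUS, theta, z)),
            Atom("CEN", "C", *_cyl(_CEN_RADIUS, theta - _CEN_PHASE, z)),
        )
        residues.append(
            Residue(chains[1], start_numbers[1] + k, base.upper(), "rna", atoms)
        )
    return Structure(residues, name=f"ideal_helix_{n_bp}bp")


@dataclass(frozen=True)
class ScreenSimSpec:
    """Generating conditions for a simulated reporter screen.

    Activities follow A_rel = max(0, alpha + beta * score + eps) with
    eps ~ Normal(0, sigma) per construct; scores are uniform over
    ``score_range`` unless explicit scores are supplied.  The defaults
    emulate the benchmark helix screen: 50 constructs, a negative link
    (lower energy -> more active) spanning activities ~1.05 down to ~0.05
    over the toy-energy score range, and noise giving an implied
    correlation near -0.6.  Replicates repeat the construct activity with
    optional Gaussian scatter (off by default; the construct-level eps is
    the noise knob that sets the correlation).
    """

    n: int = 50
    score_range: tuple[float, float] = (-15.0, 4.0)
    alpha: float = 0.26
    beta: float = -1.0 / 19.0
    sigma: float = 0.385
    n_replicates: int = 3
    replicate_sigma: float = 0.0
    wt_fluorescence: float = 1000.0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need at least 3 constructs")
        if self.sigma < 0 or self.replicate_sigma < 0:
            raise ValueError("noise widths must be >= 0")
        if self.score_range[1] <= self.score_range[0]:
            raise ValueError("empty score range")

    @property
    def implied_rho(self) -> float:
        """Analytic correlation of the unclipped linear link: for uniform
        scores, rho = sign(beta) * |beta| sd_s / sqrt(beta^2 sd_s^2 + sigma^2)."""
        sd_s = (self.score_range[1] - self.score_range[0]) / math.sqrt(12.0)
        denom = math.hypot(self.beta * sd_s, self.sigma)
        return math.copysign(abs(self.beta) * sd_s / denom, self.beta)

    @classmethod
    def from_target_rho(
        cls, rho: float = -0.6, n: int = 50, n_calibration_seeds: int = 40, **kwargs
    ) -> "ScreenSimSpec":
        """Calibrate sigma so the realized correlation matches ``rho``.

        Zero-clipping of activities makes the analytic no-clip formula
        biased, so sigma is found by bisection against the mean recovered
        Pearson r over a fixed internal set of calibration seeds — a
        deterministic, one-off construction of the generating conditions.
        """
        if not -1 < rho < 0:
            raise ValueError("target rho must be in (-1, 0) for the negative link")

        def mean_r(sigma: float) -> float:
            spec = cls(n=n, sigma=sigma, **kwargs)
            rs = []
            for s in range(10_000, 10_000 + n_calibration_seeds):
                table = simulate_screen(spec, seed=s)
                pairs = screen_score_activity(table)
                rs.append(np.corrcoef(pairs["score"], pairs["a_rel"])[0, 1])
            return float(np.mean(rs))

        lo, hi = 0.0, 3.0
        for _ in range(28):
            mid = 0.5 * (lo + hi)
            if mean_r(mid) <= rho:  # too strong (more negative): need more noise
                lo = mid
            else:
                hi = mid
        return cls(n=n, sigma=0.5 * (lo + hi), **kwargs)


def simulate_screen(
    spec: ScreenSimSpec,
    seed: int = 0,
    scores: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a screen as a long replicate table.

    Returns columns ``construct``, ``score``, ``replicate``, ``value``
    (fluorescence units), including a WT control row set at A_rel = 1
    (score NaN — the control is not part of the scored panel).  When
    ``scores`` is given it fixes the construct set and their energy
    scores; otherwise ``spec.n`` constructs get uniform scores over
    ``spec.score_range``.  Bit-reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    if scores is None:
        lo, hi = spec.score_range
        svals = rng.uniform(lo, hi, size=spec.n)
        scores = {f"S{i + 1}": float(s) for i, s in enumerate(svals)}
    rows = []

    def emit(cid: str, score: float, a_rel: float):
        for rep in range(1, spec.n_replicates + 1):
            value = a_rel * spec.wt_fluorescence
            if spec.replicate_sigma > 0:
                value += rng.normal(0.0, spec.replicate_sigma * spec.wt_fluorescence)
            rows.append(
                {"construct": cid, "score": score, "replicate": rep, "value": value}
            )

    emit("WT", math.nan, 1.0)
    for cid, s in scores.items():
        eps = rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0
        a_rel = max(0.0, spec.alpha + spec.beta * s + eps)
        emit(cid, float(s), a_rel)
    return pd.DataFrame(rows)


def screen_score_activity(table: pd.DataFrame, wt_id: str = "WT") -> pd.DataFrame:
    """Collapse a simulated screen table to (construct, score, a_rel) rows,
    normalizing replicate means to the WT mean; the WT control row itself
    is dropped (it has no score)."""
    from .screen import normalize_activity

    records = normalize_activity(table[["construct", "value"]], wt_id=wt_id)
    score_of = (
        table.drop_duplicates("construct").set_index("construct")["score"].to_dict()
    )
    rows = [
        {"construct": r.construct_id, "score": score_of[r.construct_id], "a_rel": r.a_rel}
        for r in records
        if r.construct_id != wt_id
    ]
    return pd.DataFrame(rows)


def simulate_viability(
    a_rel: Mapping[str, float],
    seed: int = 0,
    threshold: float = 1 / 3,
    p_alive_above: float = 0.85,
    p_alive_below: float = 0.10,
) -> dict[str, str]:
    """Plant viability outcomes consistent with the screen-to-cell
    heuristic: constructs above the activity threshold are alive with
    probability ``p_alive_above``, the rest with ``p_alive_below``."""
    rng = np.random.default_rng(seed)
    out = {}
    for cid, a in a_rel.items():
        p = p_alive_above if a > threshold else p_alive_below
        out[cid] = "alive" if rng.random() < p else "dead"
    return out


def simulate_alignment(
    n_rows: int,
    targets: Sequence[float],
    seed: int = 0,
    gap_fraction: float = 0.0,
    ref_id: str = "ref",
    modal_bases: str | None = None,
) -> list[tuple[str, str]]:
    """Simulate a pre-aligned multi-FASTA with planted conservation.

    Column j's modal base appears with probability ``targets[j]/100``
    among non-gap letters; the remaining mass is uniform over the other
    three bases.  Gaps are drawn independently at ``gap_fraction``.  The
    first record is an ungapped reference row spelling the modal bases, so
    column -> reference-position mapping is the identity.  Targets below
    25 are rejected: with a uniform remainder the planted base would no
    longer be modal.
    """
    if n_rows < 1:
        raise ValueError("need at least one row")
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    for t in targets:
        if not 25 < t <= 100:
            raise ValueError(f"conservation target {t} outside (25, 100]")
    rng = np.random.default_rng(seed)
    ncol = len(targets)
    if modal_bases is None:
        modal = [RNA_BASES[rng.integers(4)] for _ in range(ncol)]
    else:
        if len(modal_bases) != ncol:
            raise ValueError("modal_bases length must match targets")
        modal = list(modal_bases.lower())
    records: list[tuple[str, str]] = [(ref_id, "".join(modal))]
    for i in range(n_rows - 1):
        letters = []
        for j in range(ncol):
            if gap_fraction > 0 and rng.random() < gap_fraction:
                letters.append("-")
                continue
            if rng.random() < targets[j] / 100.0:
                letters.append(modal[j])
            else:
                others = [b for b in RNA_BASES if b != modal[j]]
                letters.append(others[rng.integers(3)])
        records.append((f"row{i + 1}", "".join(letters)))
    return records


def write_alignment_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")
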