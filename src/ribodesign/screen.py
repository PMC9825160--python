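"""Screen analytics: normalized activities, score-activity correlation,
base-pair classification, combinatorial epistasis and viability concordance.

The screen readout is maximum reporter fluorescence per construct over
replicates of an in vitro ribosome synthesis-assembly-translation
reaction; every analysis works on activities normalized to the wild-type
control (A_rel, dimensionless, WT = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .design import WC_PAIRS, WOBBLE_PAIRS, PairingMap

__all__ = [
    "ActivityRecord",
    "CorrelationResult",
    "EpistasisEntry",
    "normalize_activity",
    "correlate_score_activity",
    "classify_pairs",
    "epistasis_table",
    "viability_concordance",
]

Viability = Literal["alive", "dead", "untested"]


@dataclass(frozen=True)
class ActivityRecord:
    """One construct's screen outcome, normalized to the wild-type control."""

    construct_id: str
    replicates: tuple[float, ...]
    a_rel: float
    a_sd: float = 0.0
    viability: Viability = "untested"

    def __post_init__(self):
        if self.a_rel < 0:
            raise ValueError("normalized activity must be >= 0")


def normalize_activity(
    raw: pd.DataFrame | Mapping[str, Sequence[float]],
    wt_id: str = "WT",
    viability: Mapping[str, Viability] | None = None,
) -> list[ActivityRecord]:
    """Normalize replicate fluorescence maxima to the wild-type mean.

    ``raw`` is either a long table with ``construct`` and ``value`` columns
    (one row per replicate) or a mapping construct -> replicate values.
    A_rel = mean(replicates) / mean(WT replicates); the replicate standard
    deviation is propagated on the same scale (sd / WT mean) for reporting.
    Negative raw values are clipped to zero with a warning.
    """
    if isinstance(raw, pd.DataFrame):
        groups = {
            str(cid): [float(v) for v in sub["value"]]
            for cid, sub in raw.groupby("construct", sort=False)
        }
    else:
        groups = {str(k): [float(v) for v in vals] for k, vals in raw.items()}
    if wt_id not in groups or not groups[wt_id]:
        raise KeyError(f"wild-type id {wt_id!r} absent or has no replicates")
    clipped = False
    for cid, vals in groups.items():
        for i, v in enumerate(vals):
            if v < 0:
                vals[i] = 0.0
                clipped = True
    if clipped:
        warnings.warn("negative raw fluorescence values clipped to 0", stacklevel=2)
    wt_mean = float(np.mean(groups[wt_id]))
    if wt_mean == 0:
        raise ValueError("wild-type mean fluorescence is zero; cannot normalize")
    viability = viability or {}
    records = []
    for cid, vals in groups.items():
        records.append(
            ActivityRecord(
                construct_id=cid,
                replicates=tuple(vals),
                a_rel=float(np.mean(vals)) / wt_mean,
                a_sd=float(np.std(vals, ddof=1)) / wt_mean if len(vals) > 1 else 0.0,
                viability=viability.get(cid, "untested"),
            )
        )
    return records


@dataclass
class CorrelationResult:
    """Pearson correlation with an OLS fit line and pointwise 95% CI band."""

    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    x_grid: np.ndarray
    fit_line: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def summary(self) -> str:
        return (
            f"Pearson r = {self.r:.3f} (P = {self.p_value:.2e}, n = {self.n})\n"
            f"OLS fit: activity = {self.intercept:.4f} + {self.slope:.4f} * score"
        )

    def plot(self, pairs=None, ax=None):
        """Scatter + fit line + shaded 95% CI band (the screen-vs-score figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        if pairs is not None:
            xy = np.asarray(pairs, dtype=float)
            ax.scatter(xy[:, 0], xy[:, 1], s=18, color="k", zorder=3)
        ax.plot(self.x_grid, self.fit_line, color="C0")
        ax.fill_between(self.x_grid, self.ci_lower, self.ci_upper,
                        color="gray", alpha=0.35, lw=0)
        ax.set_xlabel("energy score")
        ax.set_ylabel("normalized activity (WT = 1)")
        ax.set_title(f"r = {self.r:.2f}, P = {self.p_value:.1e}")
        return ax


def correlate_score_activity(
    pairs: Sequence[tuple[float, float]], n_grid: int = 100
) -> CorrelationResult:
    """Pearson correlation between energy score and normalized activity,
    with an ordinary-least-squares line and pointwise 95% confidence band.

    The p-value is the two-sided t-distribution test of r = 0.
    """
    xy = np.asarray(pairs, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 3:
        raise ValueError("need at least 3 (score, activity) pairs")
    x, y = xy[:, 0], xy[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    r, p = scipy.stats.pearsonr(x, y)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = fit.get_prediction(sm.add_constant(grid))
    ci = pred.conf_int(alpha=0.05)
    return CorrelationResult(
        r=float(r),
        p_value=float(p),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n=len(x),
        x_grid=grid,
        fit_line=pred.predicted_mean,
        ci_lower=ci[:, 0],
        ci_upper=ci[:, 1],
    )


def classify_pairs(
    strands: Sequence[str] | str, pairing: PairingMap
) -> tuple[dict[str, int], list[tuple[int, int, str, str]]]:
    """Classify each base pair in the map as Watson-Crick, wobble or other.

    ``strands`` may be a flat base string or strand-grouped strings which
    are concatenated in order; the map's indices address the flat string.
    Returns ({'WC': ..., 'wobble': ..., 'other': ...},
    [(i, j, 'xy', label), ...]).
    """
    flat = strands if isinstance(strands, str) else "".join(strands)
    counts = {"WC": 0, "wobble": 0, "other": 0}
    labels = []
    for i, j in pairing.pairs:
        if i >= len(flat) or j >= len(flat):
            raise IndexError(f"pair ({i},{j}) out of range for length {len(flat)}")
        duo = (flat[i], flat[j])
        if duo in WC_PAIRS:
            kind = "WC"
        elif duo in WOBBLE_PAIRS:
            kind = "wobble"
        else:
            kind = "other"
        counts[kind] += 1
        labels.append((i, j, flat[i] + flat[j], kind))
    return counts, labels


@dataclass(frozen=True)
class EpistasisEntry:
    """Observed vs multiplicative-expected activity for one combination.

    D = observed - expected: positive flags synergistic rescue, negative
    flags incompatibility between individually tolerated mutations.  The
    multiplicative expectation (product of constituent single-region
    A_rel) is this toolkit's definition of "no interaction" for
    WT-relative ratios.
    """

    construct_id: str
    observed: float
    expected: float
    constituents: tuple[str, ...] = ()

    @property
    def deviation(self) -> float:
        return self.observed - self.expected


def epistasis_table(
    singles: Mapping[str, float],
    combos: Sequence[tuple[str, Sequence[str], float]],
) -> list[EpistasisEntry]:
    """Compare combined-construct activities with the multiplicative
    expectation from their single-region constituents.

    ``singles`` maps single-variant ids (e.g. region variants) to A_rel;
    ``combos`` is (construct id, constituent variant ids, observed A_rel).
    Combos with a missing constituent are skipped with a warning.  Entries
    return sorted by |D| descending.
    """
    entries = []
    for cid, constituents, observed in combos:
        missing = [c for c in constituents if c not in singles]
        if missing:
            warnings.warn(
                f"construct {cid}: missing single-variant records {missing}; skipped",
                stacklevel=2,
            )
            continue
        expected = float(np.prod([singles[c] for c in constituents])) if constituents else 1.0
        entries.append(
            EpistasisEntry(
                construct_id=cid,
                observed=float(observed),
                expected=expected,
                constituents=tuple(constituents),
            )
        )
    entries.sort(key=lambda e: (-abs(e.deviation), e.construct_id))
    return entries


def viability_concordance(
    records: Iterable[ActivityRecord], threshold: float = 1 / 3
) -> tuple[float, pd.DataFrame]:
    """Fraction of constructs above the activity threshold that support
    life, plus the full 2x2 (above/below x alive/dead) table.

    The default threshold of one third of wild-type activity is the
    screen-to-cell heuristic: in vitro activity above it predicts that the
    construct can serve as a cell's only ribosome.  Untested records are
    excluded.
    """
    tested = [r for r in records if r.viability != "untested"]
    if not tested:
        raise ValueError("no records with a tested viability flag")
    table = pd.DataFrame(
        0,
        index=pd.Index(["above", "below"], name="activity"),
        columns=pd.Index(["alive", "dead"], name="viability"),
    )
    for r in tested:
        row = "above" if r.a_rel > threshold else "below"
        table.loc[row, r.viability] += 1
    n_above = int(table.loc["above"].sum())
    if n_above == 0:
        fraction = math.nan
    else:
        fraction = float(table.loc["above", "alive"]) / n_above
    return fraction, table
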