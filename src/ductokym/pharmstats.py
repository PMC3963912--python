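"""Drug-epoch frequency comparison: paired 2-minute windows, Friedman, Dunn.

The experimental design measures the contractile frequency in paired
2-minute windows around each drug addition: a pre-window ending at the
addition and a post-window starting 10 s after it (the delay lets the drug
reach the tissue).  The "Spont" (spontaneous) baseline is the pre-window
of the *first* addition.  Segments (duct pieces) are the blocks of a
Friedman test on within-block ranks, followed by Dunn's rank-based
pairwise comparisons with multiplicity-adjusted p-values.

Both tests are implemented from their formulas so every intermediate
quantity (rank sums, tie correction, z statistics) is available:

* Friedman:  ``Q = [12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C`` with
  the tie correction ``C = 1 - sum(t^3 - t) / (n (k^3 - k))`` over tie
  groups within blocks; p from chi-square with k-1 df.  Fully tied tables
  give Q = 0, p = 1 by convention.  An exact permutation p-value (all
  within-block rank permutations enumerated) is available for small
  tables.
* Dunn:  ``z = (Rbar_i - Rbar_j) / sqrt(k (k+1) / (6 n))``, two-sided
  normal p, Bonferroni (default) or Holm adjustment over the comparisons
  actually performed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contract import contraction_frequency
from .stackio import DrugSchedule


# ---------------------------------------------------------------------------
# epoch design
# ---------------------------------------------------------------------------

@dataclass
class EpochDesign:
    """Paired pre/post window layout around drug additions.

    Defaults: 120 s windows, post-window starting 10 s after addition.
    """

    schedule: DrugSchedule
    window_length_s: float = 120.0
    post_delay_s: float = 10.0

    def __post_init__(self) -> None:
        if not self.window_length_s > 0:
            raise ValueError("window_length_s must be positive")
        if self.post_delay_s < 0:
            raise ValueError("post_delay_s must be >= 0")
        if len(self.schedule) == 0:
            raise ValueError("schedule must contain at least one addition")

    def windows(self, recording_duration_s: float) -> list[dict]:
        """Validated pre/post windows for every addition.

        Raises ``ValueError`` naming the offending addition when a window
        leaves the recording or overlaps the next addition's windows.
        """
        w = self.window_length_s
        out = []
        additions = list(self.schedule)
        problems = []
        for i, (t, label) in enumerate(additions):
            pre = (t - w, t)
            post = (t + self.post_delay_s, t + self.post_delay_s + w)
            if pre[0] < 0:
                problems.append(
                    f"{label!r} at t={t:g} s: pre-window starts at "
                    f"{pre[0]:g} s, before the recording"
                )
            if post[1] > recording_duration_s:
                problems.append(
                    f"{label!r} at t={t:g} s: post-window ends at "
                    f"{post[1]:g} s, after the recording "
                    f"({recording_duration_s:g} s)"
                )
            if i + 1 < len(additions):
                next_pre_start = additions[i + 1][0] - w
                if post[1] > next_pre_start:
                    problems.append(
                        f"{label!r} at t={t:g} s: post-window overlaps the "
                        f"pre-window of {additions[i + 1][1]!r}"
                    )
            out.append({"time_s": t, "label": label, "pre": pre,
                        "post": post})
        if problems:
            raise ValueError("epoch design violations: "
                             + "; ".join(problems))
        return out


def epoch_frequencies(events, design: EpochDesign,
                      recording_duration_s: float) -> dict[str, float]:
    """One bpm value per condition for a single segment.

    "Spont" is the pre-window of the first addition; each drug condition
    is its post-window.  All windows are half-open, so abutting windows
    never double-count an event.
    """
    windows = design.windows(recording_duration_s)
    row: dict[str, float] = {}
    first = windows[0]
    row["Spont"] = contraction_frequency(events, *first["pre"])
    for wnd in windows:
        label = wnd["label"]
        key = label
        suffix = 2
        while key in row:
            key = f"{label} ({suffix})"
            suffix += 1
        row[key] = contraction_frequency(events, *wnd["post"])
    return row


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def _as_table(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        values = table.to_numpy(dtype=float)
        names = [str(c) for c in table.columns]
    else:
        values = np.asarray(table, dtype=float)
        names = [f"C{j + 1}" for j in range(values.shape[1])]
    if values.ndim != 2:
        raise ValueError("table must be 2-D: segments x conditions")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError(f"need n >= 2 segments and k >= 2 conditions, "
                         f"got {n} x {k}")
    if np.isnan(values).any():
        raise ValueError("table is incomplete; paired tests require every "
                         "cell (no imputation is performed)")
    return values, names


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, values)


def _tie_correction(values: np.ndarray) -> float:
    n, k = values.shape
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    return 1.0 - ties / (n * (k ** 3 - k))


@dataclass
class FriedmanResult:
    Q: float
    df: int
    p_value: float
    rank_sums: np.ndarray
    n: int
    k: int


def friedman_test(table) -> FriedmanResult:
    """Tie-corrected Friedman test on a segments x conditions table.

    Values are ranked within each segment (mid-ranks on ties).  A table in
    which every segment is fully tied carries no ordering information and
    returns Q = 0, p = 1 by convention.
    """
    values, _ = _as_table(table)
    n, k = values.shape
    ranks = _row_ranks(values)
    rank_sums = ranks.sum(axis=0)
    numerator = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums ** 2)) \
        - 3.0 * n * (k + 1)
    correction = _tie_correction(values)
    if correction <= 0:
        # every row fully tied
        q = 0.0
    else:
        q = numerator / correction
    q = max(q, 0.0)
    p = float(stats.chi2.sf(q, k - 1)) if q > 0 else 1.0
    return FriedmanResult(Q=float(q), df=k - 1, p_value=p,
                          rank_sums=rank_sums, n=n, k=k)


def friedman_exact_p(table, max_enumeration: int = 2_000_000) -> float:
    """Exact permutation p-value for the Friedman statistic.

    Enumerates all within-segment permutations of the observed values
    (k!^n arrangements) and reports the fraction with Q at least as large
    as observed.  Only feasible for small tables; raises when the
    enumeration would exceed ``max_enumeration`` arrangements.
    """
    values, _ = _as_table(table)
    n, k = values.shape
    total = math.factorial(k) ** n
    if total > max_enumeration:
        raise ValueError(
            f"exact enumeration needs {total} arrangements "
            f"(> {max_enumeration}); use the chi-square approximation"
        )
    ranks = _row_ranks(values)
    perms = np.array(list(itertools.permutations(range(k))))
    correction = _tie_correction(values)

    colsums = ranks[0][perms]                       # (k!, k)
    for i in range(1, n):
        row_variants = ranks[i][perms]              # (k!, k)
        colsums = (colsums[:, None, :] + row_variants[None, :, :]) \
            .reshape(-1, k)
    numerators = 12.0 / (n * k * (k + 1)) * np.sum(colsums ** 2, axis=1) \
        - 3.0 * n * (k + 1)
    if correction <= 0:
        return 1.0
    q_all = np.maximum(numerators / correction, 0.0)
    q_obs = friedman_test(values).Q
    return float(np.mean(q_all >= q_obs - 1e-9))


# ---------------------------------------------------------------------------
# Dunn's post hoc
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_rank_diff: float
    z: float
    p_unadjusted: float
    p_adjusted: float
    stars: str


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def dunns_posthoc(table, comparisons=None,
                  adjustment: str = "bonferroni") -> list[PairwiseComparison]:
    """Dunn's rank-based pairwise comparisons after a Friedman test.

    ``comparisons`` is a list of (column, column) pairs; the default
    compares every condition against "Spont" when that column exists,
    otherwise against the first column.  ``adjustment`` is "bonferroni"
    (default: adjusted p = min(1, m*p) with m comparisons performed) or
    "holm" (step-down).
    """
    values, names = _as_table(table)
    n, k = values.shape
    mean_ranks = dict(zip(names, _row_ranks(values).mean(axis=0)))

    if comparisons is None:
        baseline = "Spont" if "Spont" in names else names[0]
        comparisons = [(baseline, c) for c in names if c != baseline]
    comparisons = [(str(a), str(b)) for a, b in comparisons]
    for a, b in comparisons:
        for c in (a, b):
            if c not in mean_ranks:
                raise ValueError(f"unknown column {c!r}; columns: {names}")

    se = math.sqrt(k * (k + 1) / (6.0 * n))
    m = len(comparisons)
    raw = []
    for a, b in comparisons:
        diff = mean_ranks[a] - mean_ranks[b]
        z = diff / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        raw.append((a, b, diff, z, min(p, 1.0)))

    if adjustment == "bonferroni":
        adjusted = [min(1.0, m * p) for *_, p in raw]
    elif adjustment == "holm":
        order = np.argsort([p for *_, p in raw], kind="stable")
        adjusted = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            p = raw[idx][4]
            running = max(running, (m - rank) * p)
            adjusted[idx] = min(1.0, running)
    else:
        raise ValueError("adjustment must be 'bonferroni' or 'holm'")

    return [
        PairwiseComparison(pair=(a, b), mean_rank_diff=diff, z=z,
                           p_unadjusted=p, p_adjusted=padj,
                           stars=_stars(padj))
        for (a, b, diff, z, p), padj in zip(raw, adjusted)
    ]


# ---------------------------------------------------------------------------
# assembled comparison
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Friedman omnibus + Dunn pairwise results for a frequency table."""

    friedman_Q: float
    df: int
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "friedman_Q": self.friedman_Q,
            "df": self.df,
            "p_value": self.p_value,
            "pairwise": [
                {
                    "pair": list(c.pair),
                    "mean_rank_diff": c.mean_rank_diff,
                    "z": c.z,
                    "p_unadjusted": c.p_unadjusted,
                    "p_adjusted": c.p_adjusted,
                    "stars": c.stars,
                }
                for c in self.pairwise
            ],
        }


def compare_conditions(event_sets_by_segment, design: EpochDesign,
                       recording_duration_s: float,
                       comparisons=None,
                       adjustment: str = "bonferroni",
                       ) -> tuple[TestResult, pd.DataFrame]:
    """Full epoch comparison across segments.

    ``event_sets_by_segment`` is one event list per duct segment, all
    recorded under the same schedule.  Builds the segments x conditions
    frequency table, runs the Friedman test and Dunn's post hoc, and
    returns (TestResult, table).
    """
    rows = [epoch_frequencies(events, design, recording_duration_s)
            for events in event_sets_by_segment]
    if len(rows) < 2:
        raise ValueError("need >= 2 segments for the paired tests")
    keys = list(rows[0])
    for i, r in enumerate(rows[1:], start=2):
        if list(r) != keys:
            raise ValueError(
                f"segment {i} has conditions {list(r)}, expected {keys}"
            )
    table = pd.DataFrame(rows, columns=keys)
    fr = friedman_test(table)
    pairwise = dunns_posthoc(table, comparisons=comparisons,
                             adjustment=adjustment)
    result = TestResult(friedman_Q=fr.Q, df=fr.df, p_value=fr.p_value,
                        pairwise=pairwise)
    return result, table
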