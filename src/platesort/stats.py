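"""Statistical procedures for summarized plates: the edge-effect
Wilcoxon rank-sum test, trait correlation matrices and dose-response
summarization.

Long-running plate experiments develop position effects — evaporation and
oxygenation gradients hit the outermost wells hardest.  The edge-effect
test splits the 96 wells into the outer ring (36 wells) and the interior
(60 wells) and compares a per-well summary statistic between the two
populations with a two-sided Wilcoxon rank-sum test.  Wells, not raw
objects, are the exchangeable units: pooling thousands of per-object
records across wells would pseudo-replicate and wildly overstate
significance.

The rank-sum test itself is implemented here with an exact small-sample
mode (full enumeration of the null rank-sum distribution by dynamic
programming when n1+n2 <= 20 and there are no ties) and a tie-corrected
normal approximation with continuity correction otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InsufficientDataError, InvalidMetadataError, UnknownTraitError
from .summarize import SUMMARY_TRAITS, SummarizedPlate
from .wells import WellID, edge_center_partition

log = logging.getLogger(__name__)

#: Largest pooled sample size for which the exact null distribution is used.
EXACT_LIMIT = 20


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of one two-sided Wilcoxon rank-sum comparison.

    ``w_statistic`` is the rank-sum of the first sample over the pooled
    midranks; its range is n1(n1+1)/2 .. n1(n1+2*n2+1)/2.
    """

    w_statistic: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" | "normal-approximation"
    tie_corrected: bool


def _null_ranksum_counts(n1: int, n: int) -> np.ndarray:
    """Number of size-``n1`` subsets of ranks 1..n with each possible sum.

    Dynamic programming over ranks; ``counts[s]`` is the number of subsets
    summing to ``s``.  Exact in int64 for n <= 20 (max count C(20,10)).
    """
    max_sum = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        dp[1:, r:] += dp[:-1, :-r or None].copy()
    return dp[n1]


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Missing values are dropped first.  With n1+n2 <= 20 and no ties in the
    pooled sample, the two-sided p-value is exact: both tail probabilities
    of the observed rank-sum under full enumeration of the null, the
    smaller doubled and capped at 1.  Otherwise the normal approximation is
    used with midranks, tie-corrected variance and a 0.5 continuity
    correction.  Two identical samples give p = 1.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    xv = xv[np.isfinite(xv)]
    yv = yv[np.isfinite(yv)]
    n1, n2 = len(xv), len(yv)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError(
            f"both samples must be nonempty after dropping missing values (n1={n1}, n2={n2})"
        )
    pooled = np.concatenate([xv, yv])
    n = n1 + n2
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    if n <= EXACT_LIMIT and not has_ties:
        counts = _null_ranksum_counts(n1, n)
        total = counts.sum()
        wi = int(round(w))
        p_low = counts[: wi + 1].sum() / total
        p_high = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankSumResult(w, n1, n2, float(p), "exact", False)

    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return RankSumResult(w, n1, n2, 1.0, "normal-approximation", bool(has_ties))
    diff = w - mean_w
    cc = 0.5 * math.copysign(1.0, diff) if diff != 0 else 0.0
    z = (diff - cc) / math.sqrt(var_w)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return RankSumResult(w, n1, n2, p, "normal-approximation", bool(has_ties))


@dataclass
class EdgeEffectReport:
    """Per-trait rank-sum comparisons between edge and center wells."""

    results: dict[str, RankSumResult]
    untestable: list[str]
    edge_wells: list[str]
    center_wells: list[str]
    statistic: str
    adjusted_p: dict[str, float] = field(default_factory=dict)

    def p_values(self) -> dict[str, float]:
        return {t: r.p_value for t, r in self.results.items()}


def _bh_adjust(pvals: Mapping[str, float]) -> dict[str, float]:
    """Benjamini-Hochberg step-up adjustment."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj = {}
    running = 1.0
    for rank_i, (name, p) in reversed(list(enumerate(items, start=1))):
        running = min(running, p * m / rank_i)
        adj[name] = running
    return adj


def edge_effect_test(
    summary: SummarizedPlate,
    trait: str = "all",
    statistic: str = "mean",
    edge_depth: int = 1,
    bh_adjust: bool = False,
) -> EdgeEffectReport:
    """Compare edge wells against center wells for one trait or all traits.

    The edge is the outermost ring of the plate (rows A and H plus columns
    1 and 12 of rows B-G: 36 wells; ``edge_depth=2`` adds the second ring);
    the remaining wells are the center.  For each trait the chosen per-well
    summary statistic (default the well mean) is compared between the two
    populations with :func:`wilcoxon_rank_sum`.  When testing all traits,
    traits with too little non-missing data are reported as untestable
    instead of failing the batch.
    """
    edge, center = edge_center_partition(edge_depth)
    edge_labels = {str(w) for w in edge}
    center_labels = {str(w) for w in center}

    if trait == "all":
        traits = [t for t in SUMMARY_TRAITS if f"{statistic}_{t}" in summary.data.columns]
        if not traits:
            raise UnknownTraitError(f"no '{statistic}_<trait>' columns in summary")
    else:
        traits = [trait]

    df = summary.data
    results: dict[str, RankSumResult] = {}
    untestable: list[str] = []
    for t in traits:
        col = t if t in df.columns and t == "n" else f"{statistic}_{t}"
        if col not in df.columns:
            raise UnknownTraitError(f"column {col!r} not in summary")
        vals = df.set_index("well")[col]
        ev = vals[vals.index.isin(edge_labels)].to_numpy(float)
        cv = vals[vals.index.isin(center_labels)].to_numpy(float)
        try:
            results[t] = wilcoxon_rank_sum(ev, cv)
        except InsufficientDataError:
            if trait != "all":
                raise
            untestable.append(t)
            log.info("edge-effect test: trait %s untestable (all missing)", t)

    report = EdgeEffectReport(
        results=results,
        untestable=untestable,
        edge_wells=sorted(edge_labels, key=lambda s: WellID.from_string(s).index),
        center_wells=sorted(center_labels, key=lambda s: WellID.from_string(s).index),
        statistic=statistic,
    )
    if bh_adjust and results:
        report.adjusted_p = _bh_adjust(report.p_values())
    return report


@dataclass
class CorrelationMatrix:
    """Pairwise-complete correlations between trait columns of summaries.

    Within-plate matrices are symmetric with a unit diagonal; between-plate
    matrices have the first plate's traits on the rows and the second's on
    the columns.  Entries backed by fewer than ``min_pairs`` complete well
    pairs are missing.
    """

    values: pd.DataFrame
    pair_counts: pd.DataFrame
    within_plate: bool
    method: str


def _trait_frame(summary: SummarizedPlate, traits: Sequence[str] | None) -> pd.DataFrame:
    df = summary.data.set_index("well")
    numeric = df.select_dtypes(include=[np.number])
    if traits is not None:
        missing = [t for t in traits if t not in numeric.columns]
        if missing:
            raise UnknownTraitError(f"traits not in summary: {', '.join(missing)}")
        numeric = numeric[list(traits)]
    return numeric


def correlation_matrix(
    a: SummarizedPlate,
    b: SummarizedPlate | None = None,
    traits: Sequence[str] | None = None,
    method: str = "pearson",
    min_pairs: int = 3,
) -> CorrelationMatrix:
    """Correlate trait columns over wells, within one plate or between two.

    Pearson by default (Spearman via ``method``), pairwise-complete: each
    trait pair uses exactly the wells where both values are present.  In
    between-plate mode the plates are matched by well and the result pairs
    every trait of ``a`` with every trait of ``b``.  Raises
    :class:`InsufficientDataError` when no pair reaches ``min_pairs``
    complete observations.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported method {method!r}")
    A = _trait_frame(a, traits)
    if b is None:
        vals = A.corr(method=method, min_periods=min_pairs)
        present = A.notna().astype(int)
        counts = present.T @ present
        vals = vals.where(counts >= min_pairs)
        if vals.notna().sum().sum() == 0:
            raise InsufficientDataError(
                f"no trait pair has >= {min_pairs} complete well pairs"
            )
        return CorrelationMatrix(vals, counts, within_plate=True, method=method)

    B = _trait_frame(b, traits)
    wells = A.index.intersection(B.index)
    A2, B2 = A.loc[wells], B.loc[wells]
    la = _plate_tag(a, "a")
    lb = _plate_tag(b, "b")
    A2 = A2.add_suffix(f".{la}")
    B2 = B2.add_suffix(f".{lb}")
    combined = pd.concat([A2, B2], axis=1)
    full = combined.corr(method=method, min_periods=min_pairs)
    present = combined.notna().astype(int)
    full_counts = present.T @ present
    vals = full.loc[A2.columns, B2.columns]
    counts = full_counts.loc[A2.columns, B2.columns]
    vals = vals.where(counts >= min_pairs)
    if vals.notna().sum().sum() == 0:
        raise InsufficientDataError(f"no trait pair has >= {min_pairs} complete well pairs")
    return CorrelationMatrix(vals, counts, within_plate=False, method=method)


def _plate_tag(p: SummarizedPlate, fallback: str) -> str:
    src = p.source or fallback
    stem = src.rsplit("/", 1)[-1]
    return stem if stem and stem != "<memory>" else fallback


@dataclass
class DoseResponseTable:
    """Per-well points and per-(strain, dose) means for one trait.

    ``points`` has one row per well with a non-missing value (well, strain,
    dose, value); ``groups`` one row per (strain, dose) with the mean of
    its wells' values and the contributing well count (0 and missing mean
    when every well of the group is missing).
    """

    trait: str
    statistic: str
    points: pd.DataFrame
    groups: pd.DataFrame


def dose_response_table(
    summary: SummarizedPlate,
    strains: Sequence[str],
    doses: Sequence[float],
    trait: str,
    statistic: str = "mean",
) -> DoseResponseTable:
    """Summarize one trait by strain across increasing doses.

    ``strains`` and ``doses`` are 96-element vectors in row-major well
    order A1..H12, the plate-map convention for dose-response runs.  Each
    well contributes one point (its per-well statistic for the trait);
    wells with a missing value are excluded from their group's mean and
    count but the group itself remains in the table.
    """
    if len(strains) != 96:
        raise InvalidMetadataError(f"strains vector must have 96 entries, got {len(strains)}")
    if len(doses) != 96:
        raise InvalidMetadataError(f"doses vector must have 96 entries, got {len(doses)}")

    col = trait if trait in summary.data.columns else f"{statistic}_{trait}"
    if col not in summary.data.columns:
        raise UnknownTraitError(f"trait column {col!r} not in summary")

    from .wells import ALL_WELL_LABELS

    meta = pd.DataFrame(
        {"well": ALL_WELL_LABELS, "strain": list(strains), "dose": list(doses)}
    )
    merged = meta.merge(summary.data[["well", col]], on="well", how="inner")
    merged = merged.rename(columns={col: "value"})
    groups = (
        merged.groupby(["strain", "dose"], dropna=False)["value"]
        .agg(mean="mean", well_count="count")
        .reset_index()
        .sort_values(["strain", "dose"])
        .reset_index(drop=True)
    )
    points = merged[merged["value"].notna()].reset_index(drop=True)
    return DoseResponseTable(trait=trait, statistic=statistic, points=points, groups=groups)


def dose_response_all_traits(
    summary: SummarizedPlate,
    strains: Sequence[str],
    doses: Sequence[float],
    statistic: str = "mean",
) -> dict[str, DoseResponseTable]:
    """A :func:`dose_response_table` for every summarizable trait.

    Traits whose statistic column is absent or entirely missing are
    skipped with a log entry rather than failing the batch.
    """
    out: dict[str, DoseResponseTable] = {}
    for t in SUMMARY_TRAITS:
        col = f"{statistic}_{t}"
        if col not in summary.data.columns or summary.data[col].isna().all():
            log.info("dose-response: skipping trait %s (no data)", t)
            continue
        out[t] = dose_response_table(summary, strains, doses, t, statistic)
    return out
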