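"""Challenge-style team ranking from per-case metric tables.

Two schemes are provided:

* **rank-then-aggregate** (the challenge's primary scheme): for every
  (case, metric) pair, teams are ranked 1..T in the metric's
  better-direction with ties given averaged ranks; a team's score is the
  mean of its ranks over all (case, metric) pairs, and the final ordering
  sorts ascending mean rank.
* **aggregate-then-rank** (the complementary analysis): per metric, each
  team's values are first averaged over cases, teams are ranked on the
  aggregate, and the final score is the mean of per-metric ranks.

Ranking stability is assessed with a case bootstrap: case ids are resampled
with replacement (the same resample applied across teams and metrics so
re-ranking stays coherent), the scheme's ranking is recomputed per
replicate — a thousand replicates by default — and the per-team
rank-frequency distribution is returned alongside the full-data point
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MetricTable",
    "RankingResult",
    "rank_then_aggregate",
    "aggregate_then_rank",
    "bootstrap_ranking",
    "DEFAULT_DIRECTIONS",
]

#: Better-direction of the four challenge metrics.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "dsc": "higher_better",
    "lesion_f1": "higher_better",
    "avd_ml": "lower_better",
    "ald": "lower_better",
}


@dataclass(frozen=True)
class MetricTable:
    """Long-form (team, case_id, metric, value) table with metric directions.

    Every team must have exactly one value for every (case, metric) pair;
    undefined cells are disallowed rather than imputed.
    """

    data: pd.DataFrame = field(repr=False)
    directions: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))

    def __post_init__(self) -> None:
        df = self.data
        required = {"team", "case_id", "metric", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"metric table needs columns {sorted(required)}")
        if df["value"].isna().any():
            bad = df[df["value"].isna()][["team", "case_id", "metric"]]
            raise ValueError(f"undefined metric cells are not allowed:\n{bad.to_string(index=False)}")
        if df.duplicated(["team", "case_id", "metric"]).any():
            raise ValueError("duplicate (team, case, metric) entries")
        metrics = df["metric"].unique()
        unknown = set(metrics) - set(self.directions)
        if unknown:
            raise ValueError(f"no direction declared for metrics: {sorted(unknown)}")
        # completeness: all teams share the same case set per metric
        counts = df.groupby(["team", "metric"], sort=False)["case_id"].nunique()
        n_cases = df["case_id"].nunique()
        holes = counts[counts != n_cases]
        if len(holes):
            raise ValueError(f"missing (team, case, metric) cells:\n{holes.to_string()}")
        object.__setattr__(self, "data", df.reset_index(drop=True))
        object.__setattr__(self, "directions", dict(self.directions))

    @property
    def teams(self) -> list[str]:
        return sorted(self.data["team"].unique())

    @property
    def case_ids(self) -> list:
        return sorted(self.data["case_id"].unique())

    @classmethod
    def from_csv(cls, path, directions: Mapping[str, str] | None = None) -> "MetricTable":
        df = pd.read_csv(path)
        return cls(df, directions or dict(DEFAULT_DIRECTIONS))


@dataclass(frozen=True)
class RankingResult:
    """Point-estimate ranking, optionally with a bootstrap rank distribution.

    ``mean_rank`` maps team -> mean rank score (lower is better);
    ``final_rank`` maps team -> ordinal rank with ties shared as averaged
    ranks. ``rank_distribution`` (bootstrap only) is a DataFrame indexed by
    team with integer-rank columns 1..T whose rows each sum to
    ``n_bootstrap``.
    """

    scheme: str
    mean_rank: dict[str, float]
    final_rank: dict[str, float]
    rank_distribution: pd.DataFrame | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    def ordering(self) -> list[str]:
        """Teams sorted best-first (ties broken by name for display only)."""
        return sorted(self.mean_rank, key=lambda t: (self.mean_rank[t], t))


def _signed_values(df: pd.DataFrame, directions: Mapping[str, str]) -> pd.Series:
    """Values negated where higher is better, so that smaller is always better."""
    sign = df["metric"].map(lambda m: -1.0 if directions[m] == "higher_better" else 1.0)
    return df["value"] * sign


def _finalize(scheme: str, scores: pd.Series) -> RankingResult:
    final = scores.rank(method="average")
    return RankingResult(
        scheme=scheme,
        mean_rank={t: float(s) for t, s in scores.items()},
        final_rank={t: float(r) for t, r in final.items()},
    )


def _rank_then_aggregate_scores(df: pd.DataFrame, directions: Mapping[str, str]) -> pd.Series:
    work = df.copy()
    work["signed"] = _signed_values(work, directions)
    work["rank"] = work.groupby(["case_id", "metric"], sort=False)["signed"].rank(method="average")
    return work.groupby("team")["rank"].mean()


def _aggregate_then_rank_scores(df: pd.DataFrame, directions: Mapping[str, str]) -> pd.Series:
    work = df.copy()
    work["signed"] = _signed_values(work, directions)
    agg = work.groupby(["metric", "team"], sort=False)["signed"].mean().reset_index()
    agg["rank"] = agg.groupby("metric", sort=False)["signed"].rank(method="average")
    return agg.groupby("team")["rank"].mean()


_SCHEMES = {
    "rank_then_aggregate": _rank_then_aggregate_scores,
    "aggregate_then_rank": _aggregate_then_rank_scores,
}


def rank_then_aggregate(table: MetricTable) -> RankingResult:
    """Primary scheme: rank per (case, metric), then average ranks per team."""
    _require_teams(table)
    return _finalize("rank_then_aggregate", _rank_then_aggregate_scores(table.data, table.directions))


def aggregate_then_rank(table: MetricTable) -> RankingResult:
    """Complementary scheme: average values per metric, rank the aggregates."""
    _require_teams(table)
    return _finalize("aggregate_then_rank", _aggregate_then_rank_scores(table.data, table.directions))


def _require_teams(table: MetricTable) -> None:
    if len(table.teams) < 2:
        raise ValueError("ranking requires at least 2 teams")


def _tally(rank_counts: pd.DataFrame, teams: list[str], scores: np.ndarray) -> None:
    """Count each team's final rank in one replicate.

    Averaged tie ranks can be fractional; they are counted at the floor so
    each team's row still sums to n_bootstrap.
    """
    from scipy.stats import rankdata

    final = rankdata(scores, method="average")
    for t, r in zip(teams, final):
        rank_counts.loc[t, int(np.floor(r))] += 1


def bootstrap_ranking(
    table: MetricTable,
    scheme: str = "rank_then_aggregate",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> RankingResult:
    """Bootstrap the ranking by resampling cases with replacement.

    Returns the full-data point estimate plus, per team, the frequency of
    each final rank over the replicates. Fully reproducible for a fixed
    seed.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(_SCHEMES)}")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    score_fn = _SCHEMES[scheme]
    point = _finalize(scheme, score_fn(table.data, table.directions))

    from scipy.stats import rankdata

    teams = table.teams
    cases = table.case_ids
    metrics = sorted(table.data["metric"].unique())
    n_cases, n_teams = len(cases), len(teams)
    rng = np.random.default_rng(seed)

    # dense value cube (metric, case, team), sign-flipped so smaller is better
    work = table.data.copy()
    work["signed"] = _signed_values(work, table.directions)
    cube = (work.pivot_table(index=["metric", "case_id"], columns="team", values="signed")
            .loc[[(m, c) for m in metrics for c in cases], teams]
            .to_numpy().reshape(len(metrics), n_cases, n_teams))

    rank_counts = pd.DataFrame(0, index=teams, columns=range(1, n_teams + 1))
    if scheme == "rank_then_aggregate":
        # per-(case, metric) team ranks are resample-invariant; a replicate's
        # team score is the mean of precomputed per-case mean ranks over draws
        per_case_rank = rankdata(cube, axis=2, method="average").mean(axis=0)  # (case, team)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_cases, size=n_cases)
            scores = per_case_rank[idx].mean(axis=0)
            _tally(rank_counts, teams, scores)
    else:
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_cases, size=n_cases)
            agg = cube[:, idx, :].mean(axis=1)                      # (metric, team)
            scores = rankdata(agg, axis=1, method="average").mean(axis=0)
            _tally(rank_counts, teams, scores)

    return RankingResult(
        scheme=scheme,
        mean_rank=point.mean_rank,
        final_rank=point.final_rank,
        rank_distribution=rank_counts,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
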