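"""Hospital-type performance ranking: AHP weights, weighted scores,
contingency tables with chi-square tests, ranks and Kendall's W.

The traffic-light composition of each hospital type is scored with
analytic-hierarchy-process (AHP) weights derived from the ordinal category
scores (green=3 best, yellow=2, red=1 worst): the pairwise odds matrix
A_ij = s_i/s_j is column-normalized and row-averaged. For such a consistent
ratio matrix the exact weights reduce to score normalization s_i/sum(s) =
(1/2, 1/3, 1/6); the published analysis uses the one-decimal rounding
(0.5, 0.3, 0.2), which is the default here.

Agreement of the per-drug rankings is tested with Kendall's coefficient of
concordance W = 12S / (m^2 (n^3 - n)) over m drugs ranking n hospital
types, with chi2 = m(n-1)W on n-1 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .growth_share import GrowthShareResult
from .panel_io import HOSPITAL_TYPES, Hospital

COLORS = ("red", "yellow", "green")

#: ordinal category scores: green best (3) down to red worst (1)
DEFAULT_CATEGORY_SCORES = {"red": 1, "yellow": 2, "green": 3}


@dataclass(frozen=True)
class WeightVector:
    """(red, yellow, green) weights from AHP, rounded or exact."""

    red: float
    yellow: float
    green: float
    mode: str = "paper_rounded"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.red, self.yellow, self.green)


def ahp_weights(scores=(3, 2, 1), mode: str = "paper_rounded") -> WeightVector:
    """AHP weights for (green, yellow, red) ordinal scores.

    Builds the pairwise odds matrix A_ij = s_i/s_j, normalizes each column
    by its sum, and averages rows. ``paper_rounded`` mode rounds each
    weight to one decimal and keeps the rounding only if the rounded set
    still sums to 1.0 exactly, otherwise it falls back to exact weights
    with a warning.

    Parameters
    ----------
    scores : sequence of 3 positive numbers
        (green, yellow, red) category scores, best first.
    """
    s = np.asarray(scores, dtype=float)
    if np.any(s <= 0):
        raise ValueError("category scores must be positive")
    a = s[:, None] / s[None, :]
    col_normalized = a / a.sum(axis=0, keepdims=True)
    exact = col_normalized.mean(axis=1)  # == s / s.sum() for a consistent matrix
    if mode == "exact":
        weights = exact
    elif mode == "paper_rounded":
        rounded = np.round(exact, 1)
        if abs(rounded.sum() - 1.0) < 1e-12:
            weights = rounded
        else:
            warnings.warn(
                "rounded AHP weights do not sum to 1.0; using exact weights",
                stacklevel=2,
            )
            weights = exact
            mode = "exact"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    green, yellow, red = (float(w) for w in weights)
    return WeightVector(red=red, yellow=yellow, green=green, mode=mode)


def weighted_score(row_percent, weights: WeightVector) -> float:
    """Weighted performance score of one (red%, yellow%, green%) row.

    score = (red% * w_red + yellow% * w_yellow + green% * w_green) with the
    percentages on the proportion scale and the result scaled by 100 — i.e.
    a plain percent-weight dot product, reported to one decimal. Example:
    (2, 56, 42) with weights (0.2, 0.3, 0.5) gives 38.2.
    """
    pct = np.asarray(row_percent, dtype=float)
    if pct.shape != (3,):
        raise ValueError("expected (red%, yellow%, green%)")
    if np.any(pct < 0):
        raise ValueError("percentages must be non-negative")
    total = pct.sum()
    if not (99.0 <= total <= 101.0):
        warnings.warn(
            f"row percentages sum to {total:g}, outside 100 +/- 1", stacklevel=2
        )
    score = float(pct @ np.asarray(weights.as_tuple()))
    return round(score, 1)


def contingency(
    results: list[GrowthShareResult], hospitals: list[Hospital]
) -> pd.DataFrame:
    """Hospital-type x color counts with integer-rounded row percentages.

    Rows follow the accreditation hierarchy (medical center, regional,
    district); columns are red/yellow/green counts plus ``<color>_pct``.
    """
    htype_by_id = {h.id: h.htype for h in hospitals}
    counts = pd.DataFrame(0, index=list(HOSPITAL_TYPES), columns=list(COLORS))
    for r in results:
        try:
            htype = htype_by_id[r.hospital_id]
        except KeyError:
            raise KeyError(f"no metadata for hospital {r.hospital_id!r}") from None
        counts.loc[htype, r.color] += 1
    totals = counts.sum(axis=1)
    out = counts.copy()
    out["n"] = totals
    for color in COLORS:
        with np.errstate(invalid="ignore"):
            pct = np.where(
                totals > 0, counts[color] / totals.replace(0, np.nan) * 100, 0.0
            )
        out[f"{color}_pct"] = np.round(np.nan_to_num(pct)).astype(int)
    return out


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a count table.

    Zero-margin rows/columns are dropped with a warning and the degrees of
    freedom adjusted accordingly.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row_ok = obs.sum(axis=1) > 0
    col_ok = obs.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        obs = obs[row_ok][:, col_ok]
        if min(obs.shape) < 2:
            raise ValueError("table degenerate after dropping zero margins")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)


def rank_types(scores) -> np.ndarray:
    """Ranks (1 = highest weighted score); ties share the average rank."""
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need >= 2 hospital types to rank")
    return stats.rankdata(-s, method="average")


def kendall_w(ranks) -> tuple[float, float, float, int, float]:
    """Kendall's coefficient of concordance over m rank columns of n subjects.

    Parameters
    ----------
    ranks : (n, m) array
        Each column a permutation of 1..n (ties unsupported).

    Returns
    -------
    (S, W, chi2, df, p) where S = sum over subjects of (R_j - m(n+1)/2)^2,
    W = 12S / (m^2 (n^3 - n)), chi2 = m(n-1)W on df = n-1, p = upper tail.
    """
    r = np.asarray(ranks, dtype=float)
    if r.ndim != 2:
        raise ValueError("expected an (n subjects, m raters) rank matrix")
    n, m = r.shape
    if n < 2 or m < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    expected = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        if not np.array_equal(np.sort(r[:, j]), expected):
            raise ValueError(
                f"rater column {j} is not a permutation of 1..{n} "
                "(tied ranks are unsupported)"
            )
    row_sums = r.sum(axis=1)
    s = float(((row_sums - m * (n + 1) / 2.0) ** 2).sum())
    w = 12.0 * s / (m**2 * (n**3 - n))
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return s, w, chi2, df, p


@dataclass
class RankingResult:
    """Cross-drug ranking bundle."""

    weights: WeightVector
    contingency: dict[str, pd.DataFrame]
    scores: pd.DataFrame  # htype x drug weighted scores
    chi2: dict[str, tuple[float, int, float]]
    ranks: pd.DataFrame  # htype x drug ranks, 1 = best
    kendall: tuple[float, float, float, int, float]  # (S, W, chi2, df, p)

    def to_dict(self) -> dict:
        s, w, chi2, df, p = self.kendall
        return {
            "weights": {
                "red": self.weights.red,
                "yellow": self.weights.yellow,
                "green": self.weights.green,
                "mode": self.weights.mode,
            },
            "contingency": {
                drug: table.to_dict(orient="index")
                for drug, table in self.contingency.items()
            },
            "scores": self.scores.to_dict(orient="index"),
            "chi2_per_drug": {
                drug: {"chi2": c, "df": d, "p": round(pv, 3)}
                for drug, (c, d, pv) in self.chi2.items()
            },
            "ranks": self.ranks.to_dict(orient="index"),
            "kendall": {"S": s, "W": w, "chi2": chi2, "df": df, "p": round(p, 3)},
        }


class PerformanceRankingModel:
    """Rank hospital types across drug categories.

    Parameters
    ----------
    results_by_drug : dict drug -> list of GrowthShareResult
    hospitals_by_drug : dict drug -> list of Hospital
    weights : WeightVector, optional
        Defaults to AHP on (3, 2, 1) in paper_rounded mode, i.e.
        (red, yellow, green) = (0.2, 0.3, 0.5).
    from_counts : bool
        When True, weighted scores use raw count proportions instead of the
        integer-rounded row percentages of the published tables.
    """

    def __init__(self, results_by_drug, hospitals_by_drug, weights=None, from_counts=False):
        self.results_by_drug = results_by_drug
        self.hospitals_by_drug = hospitals_by_drug
        self.weights = weights or ahp_weights()
        self.from_counts = from_counts

    def fit(self) -> "RankingResults":
        tables = {}
        chi2 = {}
        scores = {}
        for drug, results in self.results_by_drug.items():
            table = contingency(results, self.hospitals_by_drug[drug])
            keep = table["n"] > 0
            tables[drug] = table
            chi2[drug] = pearson_chi_square(table.loc[keep, list(COLORS)].to_numpy())
            per_type = {}
            for htype in table.index[keep]:
                if self.from_counts:
                    row = table.loc[htype, list(COLORS)].to_numpy(dtype=float)
                    pct = row / row.sum() * 100
                else:
                    pct = [table.loc[htype, f"{c}_pct"] for c in COLORS]
                per_type[htype] = weighted_score(pct, self.weights)
            scores[drug] = per_type
        score_frame = pd.DataFrame(scores).reindex(list(HOSPITAL_TYPES)).dropna(how="all")
        rank_frame = score_frame.apply(lambda col: rank_types(col.to_numpy()), axis=0)
        kendall = kendall_w(rank_frame.to_numpy())
        result = RankingResult(
            weights=self.weights,
            contingency=tables,
            scores=score_frame,
            chi2=chi2,
            ranks=rank_frame,
            kendall=kendall,
        )
        return RankingResults(result)


class RankingResults:
    """Fitted ranking results with ``summary()`` and JSON export."""

    def __init__(self, result: RankingResult):
        self.result = result

    def __getattr__(self, name):
        return getattr(self.result, name)

    def to_dict(self) -> dict:
        return self.result.to_dict()

    def summary(self) -> str:
        r = self.result
        s, w, chi2, df, p = r.kendall
        lines = [
            "Hospital-type performance ranking",
            "-" * 64,
            f"Weights (red,yellow,green) = ({r.weights.red}, {r.weights.yellow}, "
            f"{r.weights.green}) [{r.weights.mode}]",
            "",
            "Weighted scores (rank):",
        ]
        for htype in r.scores.index:
            cells = []
            for drug in r.scores.columns:
                cells.append(
                    f"{drug}: {r.scores.loc[htype, drug]:.1f} "
                    f"(rank {r.ranks.loc[htype, drug]:g})"
                )
            lines.append(f"  {htype:<15} " + " | ".join(cells))
        for drug, (c, d, pv) in r.chi2.items():
            lines.append(f"Chi-square {drug}: {c:.2f} (df={d}, p={pv:.3g})")
        lines.append(
            f"Kendall W = {w:.3f} (S={s:g}, chi2={chi2:.2f}, df={df}, p={p:.3f})"
        )
        return "\n".join(lines)
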