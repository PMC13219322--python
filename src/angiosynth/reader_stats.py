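"""Reader-study analysis: visual Turing-test confusion matrices, Fleiss'
kappa, weighted Cohen kappa, exact Wilcoxon signed-rank, group tests, and
ordinal rating summaries.

CSV schemas
-----------
turing.csv: item_id, stratum, truth, rater_1..rater_k
    truth and judgments are the labels "real" / "generated".
ratings.csv: item_id, stratum, arm, rater_1..rater_k
    arm is "real" or "generated"; scores are integers 1..5; each item_id
    appears once per arm (the pairing key).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

LABELS = ("real", "generated")

#: per-stratum pair counts of the reader-study harness design
#: (mode x disease strata; the fixture generator replicates this layout)
TURING_DESIGN = {
    "2D-IA": 41,
    "3D-IA": 40,
    "2D-CVS": 30,
    "3D-CVS": 28,
    "2D-AVM": 17,
    "3D-AVM": 14,
    "2D-AVF": 8,
    "3D-AVF": 12,
    "2D-MMD": 4,
    "3D-MMD": 6,
}


@dataclass
class TuringResponses:
    """Items x raters judgments plus per-item truth and stratum."""

    item_id: list
    stratum: list
    truth: np.ndarray  # labels in LABELS
    judgments: pd.DataFrame  # one column per rater, values in LABELS

    def __post_init__(self) -> None:
        n = len(self.item_id)
        if len(self.stratum) != n or len(self.truth) != n or len(self.judgments) != n:
            raise ValueError("inconsistent table lengths")
        if self.judgments.isna().any().any():
            raise ValueError("judgment matrix must be complete")
        bad = set(np.unique(self.truth)) - set(LABELS)
        if bad:
            raise ValueError(f"invalid truth labels: {bad}")

    @property
    def n_items(self) -> int:
        return len(self.item_id)

    @property
    def raters(self) -> list[str]:
        return list(self.judgments.columns)


@dataclass
class RatingTable:
    """Paired ordinal scores (1..5): one row per item per arm."""

    table: pd.DataFrame  # columns: item_id, stratum, arm, rater_*

    def __post_init__(self) -> None:
        t = self.table
        raters = self.raters
        if not raters:
            raise ValueError("no rater columns found")
        scores = t[raters].to_numpy()
        if not np.isin(scores, [1, 2, 3, 4, 5]).all():
            raise ValueError("scores must be integers 1..5")
        for arm in LABELS:
            ids = t.loc[t.arm == arm, "item_id"]
            if ids.duplicated().any():
                raise ValueError(f"duplicate item_id within arm {arm!r}")
        real_ids = set(t.loc[t.arm == "real", "item_id"])
        gen_ids = set(t.loc[t.arm == "generated", "item_id"])
        if real_ids != gen_ids:
            raise ValueError("pairing must be a bijection between arms")

    @property
    def raters(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("rater_")]


def load_turing_csv(path: str | Path) -> TuringResponses:
    df = pd.read_csv(path)
    raters = [c for c in df.columns if c.startswith("rater_")]
    return TuringResponses(
        item_id=df["item_id"].tolist(),
        stratum=df["stratum"].tolist(),
        truth=df["truth"].to_numpy(),
        judgments=df[raters],
    )


def load_ratings_csv(path: str | Path) -> RatingTable:
    return RatingTable(pd.read_csv(path))


def make_turing_design_fixture(
    seed: int = 0,
    n_raters: int = 5,
    design: dict[str, int] | None = None,
    accuracy: float = 0.5,
) -> pd.DataFrame:
    """Simulated Turing-test response table following the design strata.

    Each rater is a biased coin: correct with probability ``accuracy``.
    """
    design = TURING_DESIGN if design is None else design
    rng = np.random.default_rng(seed)
    rows = []
    item = 0
    for stratum, n_pairs in design.items():
        for _ in range(n_pairs):
            truth = LABELS[int(rng.integers(2))]
            row = {"item_id": f"item_{item:04d}", "stratum": stratum, "truth": truth}
            other = LABELS[1 - LABELS.index(truth)]
            for r in range(1, n_raters + 1):
                correct = rng.random() < accuracy
                row[f"rater_{r}"] = truth if correct else other
            rows.append(row)
            item += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Turing confusion


def turing_confusion(resp: TuringResponses, rater: str) -> dict:
    """2x2 judgment-vs-truth counts with accuracy and per-class recalls.

    ``sensitivity`` is the real-class recall (true real sequences judged
    real). Both per-class recalls are reported explicitly because the
    summary convention is ambiguous.
    """
    if rater not in resp.judgments.columns:
        raise ValueError(f"unknown rater {rater!r}")
    judged = resp.judgments[rater].to_numpy()
    counts = {
        (t, j): int(np.sum((resp.truth == t) & (judged == j)))
        for t, j in product(LABELS, LABELS)
    }
    n = resp.n_items
    correct = counts[("real", "real")] + counts[("generated", "generated")]
    n_real = counts[("real", "real")] + counts[("real", "generated")]
    n_gen = counts[("generated", "generated")] + counts[("generated", "real")]
    recall_real = counts[("real", "real")] / n_real if n_real else np.nan
    recall_gen = counts[("generated", "generated")] / n_gen if n_gen else np.nan
    return {
        "counts": counts,
        "n_items": n,
        "accuracy": correct / n,
        "sensitivity": recall_real,
        "recall_real": recall_real,
        "recall_generated": recall_gen,
    }


# ---------------------------------------------------------------------------
# agreement statistics


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa for an items x raters categorical matrix.

    Returns NaN (with the reason discoverable from the inputs) when every
    rating falls in a single category, where expected agreement is 1 and
    the coefficient is undefined.
    """
    ratings = np.asarray(ratings)
    n_items, n_raters = ratings.shape
    if n_items < 2 or n_raters < 2:
        raise ValueError("need at least 2 items and 2 raters")
    cats = np.unique(ratings)
    if cats.size < 2:
        return float("nan")
    counts = np.stack([(ratings == c).sum(axis=1) for c in cats], axis=1).astype(float)
    p_cat = counts.sum(axis=0) / (n_items * n_raters)
    p_item = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_item.mean()
    p_exp = float((p_cat**2).sum())
    if p_exp >= 1.0:
        return float("nan")
    return float((p_bar - p_exp) / (1.0 - p_exp))


def pairwise_kappa(scores_a, scores_b, weighting: str = "quadratic") -> float:
    """Weighted Cohen kappa between two raters on an ordinal scale.

    weighting: "none", "linear", or "quadratic" (ordinal default).
    Categories span the full integer range covered by either rater.
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("score lists must have equal length >= 2")
    if weighting not in ("none", "linear", "quadratic"):
        raise ValueError("weighting must be none, linear or quadratic")
    cats = np.arange(min(a.min(), b.min()), max(a.max(), b.max()) + 1)
    k = cats.size
    if k == 1:
        return 1.0  # total agreement on a single category
    idx_a = np.searchsorted(cats, a)
    idx_b = np.searchsorted(cats, b)
    observed = np.zeros((k, k))
    np.add.at(observed, (idx_a, idx_b), 1.0)
    observed /= a.size
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    d = np.abs(np.subtract.outer(np.arange(k), np.arange(k))).astype(float)
    if weighting == "none":
        w = (d > 0).astype(float)
    elif weighting == "linear":
        w = d / (k - 1)
    else:
        w = (d / (k - 1)) ** 2
    denom = float((w * expected).sum())
    if denom == 0.0:
        return float("nan")
    return float(1.0 - (w * observed).sum() / denom)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample enumeration


EXACT_ENUMERATION_LIMIT = 12


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; (W+ statistic, two-sided p).

    Zero differences are dropped; tied magnitudes are mid-ranked. For n up
    to 12 remaining pairs the p-value is exact, from full enumeration of
    the 2^n sign patterns; beyond that a normal approximation with tie
    correction is used. All-zero differences return (nan, nan).
    """
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    if d.ndim != 1:
        raise ValueError("inputs must be 1-D and paired")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan")
    ranks = _stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= EXACT_ENUMERATION_LIMIT:
        # distribution of W+ over all sign patterns with these tied ranks
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p = float(np.mean(np.abs(sums - mu) >= abs(w_pos - mu) - 1e-12))
        return w_pos, p
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(((ties**3 - ties) / 48.0).sum())
    z = (w_pos - mu) / np.sqrt(var)
    return w_pos, float(2.0 * _stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# group comparisons

GROUP_METHODS = ("paired_t", "mann_whitney", "chi_square", "kruskal_wallis")


def compare_groups(a, b=None, method: str = "mann_whitney") -> tuple[float, float]:
    """Standard two-group / k-group tests. Significance convention: 0.05.

    paired_t and mann_whitney take two samples; chi_square takes a
    contingency table (as ``a``); kruskal_wallis takes a list of groups
    (as ``a``) or two samples.
    """
    if method not in GROUP_METHODS:
        raise ValueError(f"method must be one of {GROUP_METHODS}")
    if method == "paired_t":
        res = _stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        res = _stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if method == "chi_square":
        table = np.asarray(a, dtype=np.float64)
        res = _stats.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    groups = list(a) if b is None else [a, b]
    res = _stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# rating summaries


def summarize_ratings(ratings: RatingTable, strata: list[str] | None = None) -> dict:
    """Per-stratum and overall mean +/- sample sd per arm, with paired
    Wilcoxon tests (real vs generated, rater scores averaged per item)."""
    df = ratings.table
    raters = ratings.raters
    strata = sorted(df["stratum"].unique()) if strata is None else strata
    out: dict = {"per_stratum": {}, "overall": {}}

    def arm_stats(sub: pd.DataFrame) -> dict:
        scores = sub[raters].to_numpy().ravel().astype(float)
        sd = float(np.std(scores, ddof=1)) if scores.size > 1 else 0.0
        return {"mean": float(np.mean(scores)), "sd": sd, "n_scores": int(scores.size)}

    def paired_test(sub: pd.DataFrame) -> tuple[float, float]:
        wide = sub.pivot_table(index="item_id", columns="arm",
                               values=raters, aggfunc="mean")
        real = wide.xs("real", axis=1, level=1).mean(axis=1).to_numpy()
        gen = wide.xs("generated", axis=1, level=1).mean(axis=1).to_numpy()
        return wilcoxon_signed_rank(real, gen)

    for stratum in strata:
        sub = df[df["stratum"] == stratum]
        w, p = paired_test(sub)
        out["per_stratum"][stratum] = {
            "real": arm_stats(sub[sub.arm == "real"]),
            "generated": arm_stats(sub[sub.arm == "generated"]),
            "wilcoxon_w": w,
            "wilcoxon_p": p,
        }
    w, p = paired_test(df)
    out["overall"] = {
        "real": arm_stats(df[df.arm == "real"]),
        "generated": arm_stats(df[df.arm == "generated"]),
        "wilcoxon_w": w,
        "wilcoxon_p": p,
    }
    return out
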