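"""Small-sample nonparametric statistics and study-style summary tables.

At the sample sizes this pipeline targets (n = 8 per group), exact
permutation null distributions are cheap to enumerate, so the
Mann–Whitney U and Wilcoxon signed-rank tests use full enumeration
(ties handled via average ranks over the permutation distribution)
whenever the combined sample size allows it, and fall back to the
scipy asymptotic approximations above the switchover.  Two-sided
p values are tail-doubled: p = min(1, 2·min(P(T ≤ t), P(T ≥ t))).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import config as cfg
from .config import DEFAULTS


@dataclass
class TestResult:
    statistic: float
    p_two_sided: float
    n_x: int
    n_y: int
    method: str                       # "exact" | "approximation"
    note: str = ""

    def __post_init__(self):
        if not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError("p value outside [0, 1]")


# ---------------------------------------------------------------------------
# Exact null distributions (cached; ranks doubled to integers so ties
# introduce no float-key issues)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _mwu_null_counts(ranks2: Tuple[int, ...], n_x: int) -> Tuple[Tuple[int, ...],
                                                                 Tuple[int, ...]]:
    """Distribution of 2·(rank sum of x) over all C(n, n_x) label
    assignments of the pooled ranks.  Returns (values, counts)."""
    n = len(ranks2)
    counts: Dict[int, int] = {}
    for idx in combinations(range(n), n_x):
        s = sum(ranks2[i] for i in idx)
        counts[s] = counts.get(s, 0) + 1
    vals = tuple(sorted(counts))
    return vals, tuple(counts[v] for v in vals)


def _tail_doubled_p(values: np.ndarray, counts: np.ndarray, observed: float) -> float:
    total = counts.sum()
    lo = counts[values <= observed + 1e-9].sum() / total
    hi = counts[values >= observed - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = DEFAULTS.exact_test_max_n) -> TestResult:
    """Unpaired two-sample Mann–Whitney U test, exact by enumeration of
    all rank-label assignments when n_x + n_y <= ``exact_max_n`` (ties
    via average ranks), asymptotic otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)           # average ranks on ties
    r_x = ranks[:n_x].sum()
    u_x = r_x - n_x * (n_x + 1) / 2.0

    if n_x + n_y <= exact_max_n:
        ranks2 = tuple(int(round(2 * r)) for r in ranks)
        vals2, counts = _mwu_null_counts(tuple(sorted(ranks2)), n_x)
        # U is affine in the rank sum; work on the doubled rank-sum scale
        vals = np.asarray(vals2, dtype=float)
        counts = np.asarray(counts, dtype=float)
        p = _tail_doubled_p(vals, counts, 2 * r_x)
        return TestResult(statistic=float(u_x), p_two_sided=p,
                          n_x=n_x, n_y=n_y, method="exact")
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(statistic=float(res.statistic), p_two_sided=float(res.pvalue),
                      n_x=n_x, n_y=n_y, method="approximation")


@lru_cache(maxsize=256)
def _wilcoxon_null_counts(ranks2: Tuple[int, ...]) -> Tuple[Tuple[int, ...],
                                                            Tuple[int, ...]]:
    """Distribution of 2·W⁺ over all 2^n sign patterns, by the
    generating-polynomial (subset-sum) convolution."""
    total = sum(ranks2)
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in ranks2:
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else counts[r:]
    vals = tuple(int(v) for v in np.nonzero(counts)[0])
    return vals, tuple(int(counts[v]) for v in vals)


def wilcoxon_signed_rank(diffs: Sequence[float],
                         exact_max_n: int = DEFAULTS.exact_test_max_n) -> TestResult:
    """Paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped (count noted); exact sign-pattern
    enumeration when the nonzero n <= ``exact_max_n``.  All differences
    zero yields the degenerate p = 1 with a flag.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("no finite differences")
    nz = d[d != 0]
    n_zero = d.size - nz.size
    note = f"{n_zero} zero difference(s) dropped" if n_zero else ""
    if nz.size == 0:
        return TestResult(statistic=0.0, p_two_sided=1.0, n_x=d.size, n_y=d.size,
                          method="exact", note="degenerate: all differences zero")
    ranks = sstats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    if nz.size <= exact_max_n:
        ranks2 = tuple(int(round(2 * r)) for r in ranks)
        vals2, counts = _wilcoxon_null_counts(tuple(sorted(ranks2)))
        vals = np.asarray(vals2, dtype=float)
        counts = np.asarray(counts, dtype=float)
        p = _tail_doubled_p(vals, counts, 2 * w_plus)
        return TestResult(statistic=w_plus, p_two_sided=p,
                          n_x=nz.size, n_y=nz.size, method="exact", note=note)
    res = sstats.wilcoxon(nz, alternative="two-sided", method="approx")
    return TestResult(statistic=float(res.statistic), p_two_sided=float(res.pvalue),
                      n_x=nz.size, n_y=nz.size, method="approximation", note=note)


def spearman_rho(x: Sequence[float], y: Sequence[float],
                 exact_max_n: int = 8,
                 n_resamples: int = 100_000, seed: int = 0) -> TestResult:
    """Spearman rank correlation: Pearson correlation of average ranks.

    p is exact by full permutation for n <= ``exact_max_n``, otherwise the
    t approximation.  Zero rank variance raises (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a @ b) / np.sqrt((a @ a) * (b @ b)))

    rho = corr(rx, ry)
    if n <= exact_max_n:
        hits = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(corr(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        tstat = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho ** 2))
        p = float(2 * sstats.t.sf(abs(tstat), df=n - 2))
        method = "approximation"
    return TestResult(statistic=rho, p_two_sided=min(1.0, p),
                      n_x=n, n_y=n, method=method)


# ---------------------------------------------------------------------------
# Subject records and summary tables
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """All per-subject measures feeding the group statistics."""
    subject_id: str
    group: str
    # per-hemisphere measures, dicts keyed "L"/"R" (NaN when missing)
    rmt: Dict[str, float] = field(default_factory=dict)
    sp: Dict[str, float] = field(default_factory=dict)
    rest_amp_mv: Dict[str, float] = field(default_factory=dict)
    rest_lat: Dict[str, float] = field(default_factory=dict)
    active_lat: Dict[str, float] = field(default_factory=dict)
    area_hand: Dict[str, float] = field(default_factory=dict)
    area_arm: Dict[str, float] = field(default_factory=dict)
    overlap: Dict[str, float] = field(default_factory=dict)
    mean_motor_gm: float = float("nan")
    mean_sensory_gm: float = float("nan")
    bbt: Dict[str, float] = field(default_factory=dict)
    activity: float = float("nan")
    hand_arm_ratio: Dict[str, float] = field(default_factory=dict)
    lr_ratio: Dict[str, float] = field(default_factory=dict)  # "hand"/"arm"

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "group": self.group,
               "mean_motor_gm": self.mean_motor_gm,
               "mean_sensory_gm": self.mean_sensory_gm,
               "activity": self.activity}
        for name in ("rmt", "sp", "rest_amp_mv", "rest_lat", "active_lat",
                     "area_hand", "area_arm", "overlap", "bbt",
                     "hand_arm_ratio"):
            d = getattr(self, name)
            for h in ("L", "R"):
                row[f"{name}_{h}"] = d.get(h, float("nan"))
        for s in ("hand", "arm"):
            row[f"lr_ratio_{s}"] = self.lr_ratio.get(s, float("nan"))
        return row


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])


TABLE2_MEASURES = ("rmt", "sp", "rest_amp_mv", "rest_lat", "active_lat",
                   "area_hand", "area_arm", "overlap")

TABLE2_COLUMNS = ["measure", "hemisphere",
                  "AS_mean", "AS_sd", "AS_within_p",
                  "control_mean", "control_sd", "control_within_p",
                  "between_p", "between_sig"]

TABLE3_COLUMNS = ["subset", "lr_ratio_hand", "lr_ratio_arm",
                  "hand_arm_ratio_L", "hand_arm_ratio_R",
                  "mean_motor_gm", "mean_sensory_gm", "activity"]


def _star(p: float, alpha: float) -> str:
    return "*" if np.isfinite(p) and p <= alpha else ""


def build_summary_tables(records: Sequence[SubjectRecord],
                         alpha: float = DEFAULTS.alpha) -> Dict[str, pd.DataFrame]:
    """Study-style tables: a per-measure group summary with between-group
    (Mann–Whitney) and within-group left-vs-right (Wilcoxon) p values,
    and a correlation table of manual-dexterity (BBT, mean of hands)
    against map ratios, ROI gray-matter means and physical activity
    (Spearman).  Tests run on complete cases; missing cells are NaN.
    """
    df = records_to_frame(records)
    if (df.groupby("group")["subject_id"].count() < 2).any():
        raise ValueError("need at least 2 subjects per group")
    groups = {g: df[df["group"] == g] for g in ("AS", "control")}

    rows = []
    for measure in TABLE2_MEASURES:
        within = {}
        for g, sub in groups.items():
            pairs = sub[[f"{measure}_L", f"{measure}_R"]].dropna()
            if len(pairs) >= 2:
                d = (pairs[f"{measure}_L"] - pairs[f"{measure}_R"]).to_numpy()
                try:
                    within[g] = wilcoxon_signed_rank(d).p_two_sided
                except ValueError:
                    within[g] = float("nan")
            else:
                within[g] = float("nan")
        for hemi in ("L", "R"):
            col = f"{measure}_{hemi}"
            a = groups["AS"][col].dropna().to_numpy()
            c = groups["control"][col].dropna().to_numpy()
            try:
                between = mann_whitney_u(a, c).p_two_sided if a.size and c.size \
                    else float("nan")
            except ValueError:
                between = float("nan")
            rows.append({
                "measure": measure, "hemisphere": hemi,
                "AS_mean": a.mean() if a.size else float("nan"),
                "AS_sd": a.std(ddof=1) if a.size > 1 else float("nan"),
                "AS_within_p": within["AS"],
                "control_mean": c.mean() if c.size else float("nan"),
                "control_sd": c.std(ddof=1) if c.size > 1 else float("nan"),
                "control_within_p": within["control"],
                "between_p": between,
                "between_sig": _star(between, alpha),
            })
    table2 = pd.DataFrame(rows, columns=TABLE2_COLUMNS)

    # correlations vs mean-of-hands BBT
    df = df.assign(bbt_mean=df[["bbt_L", "bbt_R"]].mean(axis=1))
    corr_cols = ["lr_ratio_hand", "lr_ratio_arm", "hand_arm_ratio_L",
                 "hand_arm_ratio_R", "mean_motor_gm", "mean_sensory_gm",
                 "activity"]
    rows3 = []
    subsets = {"all": df, "AS": groups["AS"].assign(
        bbt_mean=lambda s: s[["bbt_L", "bbt_R"]].mean(axis=1)),
        "control": groups["control"].assign(
        bbt_mean=lambda s: s[["bbt_L", "bbt_R"]].mean(axis=1))}
    for name, sub in subsets.items():
        row = {"subset": name}
        for col in corr_cols:
            pair = sub[[col, "bbt_mean"]].dropna()
            if len(pair) >= 3:
                try:
                    res = spearman_rho(pair[col], pair["bbt_mean"])
                    row[col] = f"{res.statistic:.3f} (p={res.p_two_sided:.3f})" \
                               + _star(res.p_two_sided, alpha)
                except ValueError:
                    row[col] = "NA"
            else:
                row[col] = "NA"
        # align key names with TABLE3_COLUMNS
        rows3.append({"subset": row["subset"],
                      "lr_ratio_hand": row["lr_ratio_hand"],
                      "lr_ratio_arm": row["lr_ratio_arm"],
                      "hand_arm_ratio_L": row["hand_arm_ratio_L"],
                      "hand_arm_ratio_R": row["hand_arm_ratio_R"],
                      "mean_motor_gm": row["mean_motor_gm"],
                      "mean_sensory_gm": row["mean_sensory_gm"],
                      "activity": row["activity"]})
    table3 = pd.DataFrame(rows3, columns=TABLE3_COLUMNS)

    # demographic/behavioral table
    rows1 = []
    for measure, cols in (("bbt_right", ["bbt_R"]), ("bbt_left", ["bbt_L"]),
                          ("activity", ["activity"])):
        a = groups["AS"][cols[0]].dropna().to_numpy()
        c = groups["control"][cols[0]].dropna().to_numpy()
        p = mann_whitney_u(a, c).p_two_sided if a.size and c.size else float("nan")
        rows1.append({"measure": measure,
                      "AS_mean": a.mean(), "AS_sd": a.std(ddof=1),
                      "control_mean": c.mean(), "control_sd": c.std(ddof=1),
                      "between_p": p, "between_sig": _star(p, alpha)})
    table1 = pd.DataFrame(rows1, columns=["measure", "AS_mean", "AS_sd",
                                          "control_mean", "control_sd",
                                          "between_p", "between_sig"])
    return {"table1": table1, "table2": table2, "table3": table3}


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (opt-in; the default pipeline reports
    unadjusted p values)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
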