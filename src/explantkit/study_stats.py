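"""Normalization, pooling and nonparametric testing on explant tables.

All statistics operate on a pandas DataFrame with one row per explant
(see :mod:`explantkit.records`). The analysis chain mirrors standard
practice for skewed outgrowth data:

* outcomes are expressed as fold changes relative to the median of the
  relevant untreated control group — a single global control for the
  neurotrophin design (:func:`normalize_nt`), or the unstimulated controls
  on the same culture plate for the stimulation design (:func:`normalize_es`);
* cochlear turns are balanced by subsampling each turn to the smallest
  turn's n before whole-cochlea comparisons (:func:`pool_equal_shares`);
* multi-group comparisons use Kruskal–Wallis with Dunn's post-hoc against
  the control and Bonferroni correction over the performed comparisons only
  (:func:`kruskal_dunn`); pairwise designs use Mann–Whitney with
  Holm–Šídák step-down (:func:`mw_holm_sidak`); monotone association uses
  Spearman's rank correlation (:func:`spearman_matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BoxSummary",
    "TestReport",
    "significance_stars",
    "normalize_nt",
    "normalize_es",
    "pool_equal_shares",
    "kruskal_dunn",
    "mw_holm_sidak",
    "spearman_matrix",
    "box_summary",
    "run_nt_chain",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class BoxSummary:
    """Tukey box-plot summary: quartiles, 1.5×IQR whiskers clipped to the
    most extreme in-range data points, and the out-of-range points."""

    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


@dataclass
class TestReport:
    """Result of a multi-comparison procedure.

    ``comparisons`` has one row per performed comparison with columns
    ``label, n_a, n_b, statistic, p_raw, p_adj, stars``. ``omnibus`` holds
    the Kruskal–Wallis H and p when applicable.
    """

    method: str
    comparisons: pd.DataFrame
    omnibus: Optional[dict] = None
    alpha: float = 0.05

    @property
    def rejected(self) -> bool:
        """Omnibus decision at ``alpha`` (for omnibus-less methods: any
        adjusted p below alpha)."""
        if self.omnibus is not None:
            return bool(self.omnibus["p"] < self.alpha)
        return bool((self.comparisons["p_adj"] < self.alpha).any())


def significance_stars(p: float) -> str:
    """Convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001, else 'ns'."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# normalization and pooling


def normalize_nt(
    df: pd.DataFrame,
    metric: str,
    control: str = "NT CTRL",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Fold change of ``metric`` relative to the global control median.

    Every record (controls included) is divided by the median of the
    control group's metric, so the control group's own fold-change median
    is exactly 1. Returns a copy with a ``fold_change`` column.
    """
    ctrl = df.loc[df[treatment_col] == control, metric].dropna()
    if ctrl.empty:
        raise ValueError(f"no control records with {treatment_col} == {control!r}")
    ctrl_median = float(ctrl.median())
    if ctrl_median <= 0:
        raise ValueError(f"control median of {metric!r} is {ctrl_median}, must be > 0")
    out = df.copy()
    out["fold_change"] = out[metric] / ctrl_median
    return out


def normalize_es(
    df: pd.DataFrame,
    metric: str,
    plate_col: str = "plate",
    control_col: str = "is_control",
) -> pd.DataFrame:
    """Fold change of ``metric`` relative to the same-plate control median.

    Each plate is processed independently; a plate without at least one
    control record is an error naming the plate.
    """
    out = df.copy()
    out["fold_change"] = np.nan
    for plate, sub in df.groupby(plate_col):
        ctrl = sub.loc[sub[control_col].astype(bool), metric].dropna()
        if ctrl.empty:
            raise ValueError(f"plate {plate!r} has no unstimulated control records")
        m = float(ctrl.median())
        if m <= 0:
            raise ValueError(f"plate {plate!r} control median is {m}, must be > 0")
        out.loc[sub.index, "fold_change"] = sub[metric] / m
    return out


def pool_equal_shares(
    df: pd.DataFrame,
    by: str = "turn",
    seed: int | np.random.Generator = 0,
    within: Optional[str] = None,
    expected_levels: Sequence[str] = ("apical", "middle", "basal"),
) -> pd.DataFrame:
    """Balance the ``by`` factor by seeded subsampling without replacement.

    The smallest level's n is used for every level, so pooled cohorts are
    exactly balanced. With ``within`` set (e.g. ``"treatment"``), balancing
    is applied separately inside each of its groups, matching the design
    where every displayed group represents the whole cochlea in equal
    shares.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _balance(sub: pd.DataFrame) -> pd.DataFrame:
        counts = sub[by].value_counts()
        missing = [lv for lv in expected_levels if lv not in counts.index]
        if missing:
            raise ValueError(f"levels absent from {by!r}: {missing}")
        n_min = int(counts.min())
        parts = []
        for lv in expected_levels:
            idx = sub.index[sub[by] == lv].to_numpy()
            take = np.sort(rng.choice(idx, size=n_min, replace=False))
            parts.append(sub.loc[take])
        return pd.concat(parts)

    if within is None:
        return _balance(df)
    pooled = [_balance(sub) for _, sub in df.groupby(within, sort=False)]
    return pd.concat(pooled)


# ---------------------------------------------------------------------------
# tests


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_dunn(
    df: pd.DataFrame,
    value: str,
    group_col: str,
    control: str,
    alpha: float = 0.05,
) -> TestReport:
    """Kruskal–Wallis omnibus plus Dunn's z against the control group.

    Dunn's z uses the pooled mid-ranks with the standard tie correction;
    raw two-sided p-values are Bonferroni-corrected over the performed
    group-vs-control family only. If all values are identical the omnibus
    p is 1 and no post-hoc is run.
    """
    groups = [g for g in df[group_col].unique() if g != control]
    if control not in set(df[group_col]):
        raise ValueError(f"control group {control!r} not present")
    if len(groups) < 1:
        raise ValueError("need at least one non-control group")
    samples = {g: df.loc[df[group_col] == g, value].dropna().to_numpy() for g in [control] + groups}
    for g, x in samples.items():
        if len(x) < 3:
            raise ValueError(f"group {g!r} has n={len(x)} < 3")

    pooled = np.concatenate(list(samples.values()))
    empty = pd.DataFrame(
        columns=["label", "n_a", "n_b", "statistic", "p_raw", "p_adj", "stars"]
    )
    if np.ptp(pooled) == 0:  # all values identical: no evidence, no post-hoc
        return TestReport("kruskal-dunn-bonferroni", empty, {"H": 0.0, "p": 1.0}, alpha)

    h_stat, h_p = stats.kruskal(*samples.values())

    ranks = stats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(samples[g]) for g in [control] + groups])
    mean_rank = {}
    for i, g in enumerate([control] + groups):
        mean_rank[g] = ranks[offsets[i] : offsets[i + 1]].mean()
    n_tot = len(pooled)
    tie = _tie_term(pooled)
    var_base = n_tot * (n_tot + 1) / 12.0 - tie / (12.0 * (n_tot - 1))

    rows = []
    m = len(groups)
    for g in groups:
        n_g, n_c = len(samples[g]), len(samples[control])
        se = np.sqrt(var_base * (1.0 / n_g + 1.0 / n_c))
        z = (mean_rank[g] - mean_rank[control]) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "label": f"{g} vs {control}",
                "n_a": n_g,
                "n_b": n_c,
                "statistic": z,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return TestReport(
        "kruskal-dunn-bonferroni",
        pd.DataFrame(rows),
        {"H": float(h_stat), "p": float(h_p)},
        alpha,
    )


def mw_holm_sidak(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> TestReport:
    """Groupwise two-sided Mann–Whitney U with Holm–Šídák step-down.

    ``pairs`` maps a comparison label to its two samples. The step-down
    adjustment sorts raw p ascending and sets
    ``p_adj_i = 1 - (1 - p_i)**(m - i)`` (0-based i) with a running maximum.
    """
    if not pairs:
        raise ValueError("no pairs given")
    labels, raws, stats_u, sizes = [], [], [], []
    for label, (a, b) in pairs.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"pair {label!r} has a sample with n < 3")
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        labels.append(label)
        raws.append(float(p))
        stats_u.append(float(u))
        sizes.append((len(a), len(b)))
    _, p_adj, _, _ = multipletests(raws, alpha=alpha, method="holm-sidak")
    rows = [
        {
            "label": lab,
            "n_a": na,
            "n_b": nb,
            "statistic": u,
            "p_raw": p,
            "p_adj": pa,
            "stars": significance_stars(pa),
        }
        for lab, (na, nb), u, p, pa in zip(labels, sizes, stats_u, raws, p_adj)
    ]
    return TestReport("mann-whitney-holm-sidak", pd.DataFrame(rows), None, alpha)


def spearman_matrix(
    df: pd.DataFrame, variables: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p over complete cases of each pair.

    Returns ``(rho, p)`` as symmetric DataFrames with unit diagonal. A
    constant variable yields NaN against everything (undefined ranks).
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables, dtype=float)
    pmat = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables, dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            sub = df[[variables[i], variables[j]]].dropna()
            if len(sub) < 4:
                raise ValueError(
                    f"fewer than 4 complete cases for {variables[i]}/{variables[j]}"
                )
            x = sub.iloc[:, 0].to_numpy(dtype=float)
            y = sub.iloc[:, 1].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return rho, pmat


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Quartiles by linear interpolation, Tukey 1.5×IQR whiskers clipped to
    the most extreme in-range data points, points beyond listed as outliers."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 1:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    in_range = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = x[(x < lo_fence) | (x > hi_fence)]
    return BoxSummary(
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        whisker_low=float(in_range.min()),
        whisker_high=float(in_range.max()),
        outliers=sorted(float(v) for v in outliers),
    )


# ---------------------------------------------------------------------------
# chains


def run_nt_chain(
    df: pd.DataFrame,
    metric: str,
    control: str = "NT CTRL",
    seed: int = 0,
    alpha: float = 0.05,
) -> TestReport:
    """The neurotrophin-design chain: global-control fold-change
    normalization, equal-share turn pooling per treatment group, then
    Kruskal–Wallis with Dunn/Bonferroni against the control."""
    normed = normalize_nt(df, metric, control=control)
    pooled = pool_equal_shares(normed, by="turn", seed=seed, within="treatment")
    return kruskal_dunn(pooled, "fold_change", "treatment", control, alpha=alpha)
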