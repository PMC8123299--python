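"""Per-sample aggregation and cohort-level nonparametric statistics.

Per-cell particle counts are assumed Poisson within a sample and subtype;
the subtype summary is therefore the arithmetic mean count (the Poisson
lambda).  Group comparisons use the two-sided Mann-Whitney U test (exact
enumeration for small tie-free samples, normal approximation with tie
correction otherwise) with Shapiro-Wilk normality reported alongside;
associations use Pearson's r^2.  The rank rule "higher lambda means
patient" has ROC AUC equal to U / (n1 * n2).  Binding stratification uses
cutoffs of 5 and 10 particles per cell (low < 5 <= medium < 10 <= high).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import StatsConfig
from .errors import DataError
from .lineage import LINEAGE_CLASSES

ALL_PBMC = "AllPBMC"
SUBTYPE_ORDER = (ALL_PBMC,) + LINEAGE_CLASSES


@dataclass
class SampleSummary:
    """Per-sample lambda estimates and binding stratification."""

    sample_id: str
    group: str
    lambda_by_subtype: Dict[str, float]
    n_cells_by_subtype: Dict[str, int]
    stratification: Dict[str, Dict[str, float]]
    serum_value: Optional[float] = None

    @property
    def lambda_all(self) -> Optional[float]:
        return self.lambda_by_subtype.get(ALL_PBMC)

    def to_row(self) -> Dict:
        row: Dict = {"sample_id": self.sample_id, "group": self.group}
        for k in SUBTYPE_ORDER:
            row[f"lambda_{k}"] = self.lambda_by_subtype.get(k, np.nan)
            row[f"n_{k}"] = self.n_cells_by_subtype.get(k, 0)
        if self.serum_value is not None:
            row["serum"] = self.serum_value
        return row


@dataclass
class CohortResult:
    """Cohort-level statistics, one entry per subtype where computable."""

    mannwhitney: pd.DataFrame
    auc: Dict[str, float]
    shapiro: pd.DataFrame
    correlations: Optional[pd.DataFrame] = None
    boxplots: Optional[pd.DataFrame] = None

    def to_json_dict(self) -> Dict:
        out = {
            "mannwhitney": self.mannwhitney.to_dict(orient="records"),
            "auc": self.auc,
            "shapiro": self.shapiro.to_dict(orient="records"),
        }
        if self.correlations is not None:
            out["correlations"] = self.correlations.to_dict(orient="records")
        if self.boxplots is not None:
            out["boxplots"] = self.boxplots.to_dict(orient="records")
        return out


def summarize_sample(
    cells: pd.DataFrame,
    sample_id: Optional[str] = None,
    group: str = "",
    config: Optional[StatsConfig] = None,
    serum_value: Optional[float] = None,
) -> SampleSummary:
    """Aggregate a cell-level table into per-subtype Poisson means.

    ``cells`` needs columns ``lineage`` and ``pnp_count``.  The all-PBMC
    aggregate covers every CD45-positive cell, i.e. every row whose
    lineage is not ``NotLeukocyte`` (excluded multi-marker cells are still
    leukocytes).  Subtypes with zero cells are recorded as missing, not 0.
    """
    config = config or StatsConfig()
    if sample_id is None:
        sample_id = str(cells["sample_id"].iloc[0]) if len(cells) else "<empty>"
    lam: Dict[str, float] = {}
    ncells: Dict[str, int] = {}
    strat: Dict[str, Dict[str, float]] = {}
    groups = {ALL_PBMC: cells[cells["lineage"] != "NotLeukocyte"]}
    for cls in LINEAGE_CLASSES:
        groups[cls] = cells[cells["lineage"] == cls]
    for name, sub in groups.items():
        n = len(sub)
        ncells[name] = n
        if n == 0:
            continue
        counts = sub["pnp_count"].to_numpy(dtype=float)
        lam[name] = float(counts.mean())
        lo, hi = config.cutoff_low, config.cutoff_high
        strat[name] = {
            "low": float((counts < lo).mean()),
            "medium": float(((counts >= lo) & (counts < hi)).mean()),
            "high": float((counts >= hi).mean()),
        }
    return SampleSummary(
        sample_id=sample_id,
        group=group,
        lambda_by_subtype=lam,
        n_cells_by_subtype=ncells,
        stratification=strat,
        serum_value=serum_value,
    )


def _lambda_vectors(
    summaries: Sequence[SampleSummary], subtype: str
) -> Dict[str, np.ndarray]:
    out: Dict[str, List[float]] = {}
    for s in summaries:
        if subtype in s.lambda_by_subtype:
            out.setdefault(s.group, []).append(s.lambda_by_subtype[subtype])
    return {g: np.asarray(v, dtype=float) for g, v in out.items()}


def mann_whitney_u(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple:
    """U statistic of ``x`` (ties counted half) and two-sided p-value.

    Exact enumeration for n <= 20 per group without ties, otherwise the
    normal approximation with tie correction.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        # fully degenerate: every pairwise comparison ties
        warnings.warn("all observations identical; U test degenerate, p = 1")
        return len(x) * len(y) / 2.0, 1.0
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    summaries: Sequence[SampleSummary],
    config: Optional[StatsConfig] = None,
    group_a: str = "patient",
    group_b: str = "control",
) -> CohortResult:
    """Mann-Whitney U, Shapiro-Wilk and AUC per subtype across two groups."""
    config = config or StatsConfig()
    mw_rows, sw_rows, auc = [], [], {}
    for subtype in SUBTYPE_ORDER:
        vecs = _lambda_vectors(summaries, subtype)
        a, b = vecs.get(group_a, np.array([])), vecs.get(group_b, np.array([]))
        for gname, v in ((group_a, a), (group_b, b)):
            if len(v) >= 3:
                sw = stats.shapiro(v)
                sw_rows.append(
                    {"subtype": subtype, "group": gname,
                     "shapiro_w": float(sw.statistic), "shapiro_p": float(sw.pvalue)}
                )
            elif len(v):
                warnings.warn(
                    f"group {gname} has {len(v)} samples for {subtype}; "
                    "Shapiro-Wilk skipped"
                )
        if len(a) == 0 or len(b) == 0:
            continue
        u, p = mann_whitney_u(a, b, config.alternative)
        mw_rows.append(
            {"subtype": subtype, "U": u, "p": p,
             "n_patient": len(a), "n_control": len(b),
             "lambda_patient_mean": float(a.mean()),
             "lambda_control_mean": float(b.mean())}
        )
        auc[subtype] = u / (len(a) * len(b))
    if not mw_rows:
        raise DataError("need at least one sample in each group")
    return CohortResult(
        mannwhitney=pd.DataFrame(mw_rows),
        auc=auc,
        shapiro=pd.DataFrame(sw_rows),
        boxplots=boxplot_table(summaries, config),
    )


def subtype_auc(
    summaries: Sequence[SampleSummary],
    group_a: str = "patient",
    group_b: str = "control",
) -> Dict[str, float]:
    """ROC AUC of the rank rule "higher lambda implies patient", per subtype."""
    out = {}
    for subtype in SUBTYPE_ORDER:
        vecs = _lambda_vectors(summaries, subtype)
        if not vecs:
            continue  # subtype absent from every sample
        a, b = vecs.get(group_a), vecs.get(group_b)
        if a is None or b is None or len(a) == 0 or len(b) == 0:
            raise DataError(f"both groups required for AUC of {subtype}")
        u, _ = mann_whitney_u(a, b)
        out[subtype] = u / (len(a) * len(b))
    return out


def correlate(
    summaries: Sequence[SampleSummary],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r^2 within each group for every subtype pair and vs serum.

    Samples missing one member of a pair are dropped pairwise; constant
    vectors yield a missing entry with a warning.
    """
    rows = []
    groups = sorted({s.group for s in summaries})
    for g in groups:
        subs = [s for s in summaries if s.group == g]
        variables: Dict[str, np.ndarray] = {}
        for name in SUBTYPE_ORDER:
            variables[name] = np.array(
                [s.lambda_by_subtype.get(name, np.nan) for s in subs]
            )
        serum = np.array(
            [np.nan if s.serum_value is None else s.serum_value for s in subs]
        )
        if np.isfinite(serum).any():
            variables["Serum"] = serum
        for va, vb in itertools.combinations(variables, 2):
            x, y = variables[va], variables[vb]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs:
                continue
            xs, ys = x[ok], y[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                warnings.warn(f"constant vector for {va} or {vb} in group {g}")
                rows.append({"group": g, "a": va, "b": vb, "n": int(ok.sum()),
                             "r2": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(xs, ys)
            rows.append({"group": g, "a": va, "b": vb, "n": int(ok.sum()),
                         "r2": float(r**2), "p": float(p)})
    return pd.DataFrame(rows)


def boxplot_table(
    summaries: Sequence[SampleSummary], config: Optional[StatsConfig] = None
) -> pd.DataFrame:
    """Box-plot summaries per subtype and group.

    Whiskers span the data range after excluding outliers, where outliers
    lie beyond ``outlier_iqr_factor`` times the interquartile range from
    the quartiles.
    """
    config = config or StatsConfig()
    rows = []
    for subtype in SUBTYPE_ORDER:
        vecs = _lambda_vectors(summaries, subtype)
        for g, v in sorted(vecs.items()):
            if len(v) == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - config.outlier_iqr_factor * iqr, q3 + config.outlier_iqr_factor * iqr
            inliers = v[(v >= lo) & (v <= hi)]
            outliers = v[(v < lo) | (v > hi)]
            rows.append(
                {"subtype": subtype, "group": g, "n": len(v),
                 "q1": float(q1), "median": float(med), "q3": float(q3),
                 "whisker_low": float(inliers.min()), "whisker_high": float(inliers.max()),
                 "outliers": [float(o) for o in np.sort(outliers)]}
            )
    return pd.DataFrame(rows)


def summarize_cohort(
    cells: pd.DataFrame,
    metadata: pd.DataFrame,
    config: Optional[StatsConfig] = None,
) -> List[SampleSummary]:
    """Split a pooled cell table by sample and summarize each.

    ``metadata`` columns: ``sample_id``, ``group`` and optionally ``serum``.
    """
    config = config or StatsConfig()
    meta = metadata.set_index("sample_id")
    out = []
    for sid, sub in cells.groupby("sample_id", sort=True):
        if sid not in meta.index:
            raise DataError(f"sample {sid} missing from metadata")
        serum = meta.loc[sid].get("serum", np.nan)
        out.append(
            summarize_sample(
                sub,
                sample_id=str(sid),
                group=str(meta.loc[sid, "group"]),
                config=config,
                serum_value=None if pd.isna(serum) else float(serum),
            )
        )
    return out


def plot_boxplots(
    summaries: Sequence[SampleSummary],
    path: Optional[str] = None,
    config: Optional[StatsConfig] = None,
):
    """Box plots of per-sample lambda by subtype and group.

    Whiskers follow the cohort convention: data range after removing
    points beyond 1.5 interquartile ranges from the quartiles.  Returns
    the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or StatsConfig()
    subtypes = [s for s in SUBTYPE_ORDER
                if any(s in x.lambda_by_subtype for x in summaries)]
    fig, axes = plt.subplots(1, len(subtypes), figsize=(3 * len(subtypes), 4))
    if len(subtypes) == 1:
        axes = [axes]
    for ax, subtype in zip(axes, subtypes):
        vecs = _lambda_vectors(summaries, subtype)
        groups = sorted(vecs)
        ax.boxplot([vecs[g] for g in groups], tick_labels=groups,
                   whis=config.outlier_iqr_factor)
        ax.set_title(subtype)
        ax.set_ylabel("PNPs per cell")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
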