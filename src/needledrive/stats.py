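"""Stage medians, contrasts, and nonparametric tests.

The experimental protocol has three phases per participant (open
baseline, teleoperation, open again).  Performance at four stages —
open1-late, tele-early, tele-late, open2-early — is summarized as the
median of a block of 5 trials (metrics here are mostly non-normal, so
medians are the block statistic).  Three pre-registered contrasts are
formed per participant:

* learning          = tele_late - tele_early
* aftereffect       = open2_early - open1_late
* final_performance = tele_late - open1_late

Each contrast is tested against zero per feedback condition with a
two-sided Wilcoxon signed-rank test, compared across the three
conditions with a Kruskal–Wallis test, and summarized with a
nonparametric bootstrap percentile CI of the median difference.  No
multiple-testing correction is applied by default (a Benjamini–
Hochberg option exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import CONSISTENCY_METRICS, SCALAR_METRICS

__all__ = [
    "STAGES",
    "CONTRASTS",
    "ALL_METRICS",
    "stage_value",
    "build_stage_table",
    "contrast_diffs",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "bootstrap_ci",
    "ContrastTables",
    "run_full_analysis",
]

#: stage -> (phase, which end of the phase the 5-trial block is taken from)
STAGES = {
    "open1_late": ("open1", "last"),
    "tele_early": ("tele", "first"),
    "tele_late": ("tele", "last"),
    "open2_early": ("open2", "first"),
}

#: contrast -> (minuend stage, subtrahend stage)
CONTRASTS = {
    "learning": ("tele_late", "tele_early"),
    "aftereffect": ("open2_early", "open1_late"),
    "final_performance": ("tele_late", "open1_late"),
}

ALL_METRICS = tuple(SCALAR_METRICS) + tuple(CONSISTENCY_METRICS)

DEFAULT_BLOCK_SIZE = 5


def stage_value(values, block_size: int = DEFAULT_BLOCK_SIZE) -> float:
    """Median of one stage's block of per-trial metric values.

    NaN-only blocks yield NaN (metric unavailable at this stage);
    blocks of the wrong length raise.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != block_size:
        raise ValueError(f"stage requires exactly {block_size} trials, got {values.shape[0]}")
    if np.all(np.isnan(values)):
        return float("nan")
    return float(np.nanmedian(values))


def build_stage_table(
    trial_table: pd.DataFrame,
    metrics=None,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """Per-(participant, stage) block medians from a tidy trial table.

    ``trial_table`` needs columns ``participant, condition, phase,
    trial_in_phase`` plus one column per metric.
    """
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in trial_table.columns]
    rows = []
    for (participant, condition), part in trial_table.groupby(
        ["participant", "condition"], sort=True
    ):
        for stage, (phase, end) in STAGES.items():
            sel = part[part["phase"] == phase].sort_values("trial_in_phase")
            row = {"participant": participant, "condition": condition, "stage": stage}
            if len(sel) < block_size:
                # e.g. a quarantined trial left the block short: this
                # participant's stage is unavailable, others unaffected
                for m in metrics:
                    row[m] = float("nan")
            else:
                block = sel.head(block_size) if end == "first" else sel.tail(block_size)
                for m in metrics:
                    row[m] = stage_value(block[m].to_numpy(), block_size)
            rows.append(row)
    return pd.DataFrame(rows)


def contrast_diffs(stage_table: pd.DataFrame, metric: str, contrast: str) -> pd.DataFrame:
    """Per-participant stage differences for one metric and contrast.

    Returns a frame with ``participant, condition, diff``; participants
    whose stages are unavailable (NaN) are kept as NaN diffs so
    missingness stays explicit.
    """
    stage_a, stage_b = CONTRASTS[contrast]
    wide = (
        stage_table.set_index(["participant", "condition", "stage"])[metric]
        .unstack("stage")
    )
    diff = wide[stage_a] - wide[stage_b]
    return diff.rename("diff").reset_index()


def wilcoxon_signed_rank(diffs) -> float:
    """Two-sided signed-rank p-value for median difference = 0.

    Exact zeros are dropped first (classic Wilcoxon); the null
    distribution is exact for small samples without ties and a
    tie-corrected normal approximation otherwise.  Returns NaN when
    fewer than 2 nonzero differences remain (test undefined).
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    diffs = diffs[diffs != 0]
    if diffs.size < 2:
        return float("nan")
    res = sps.wilcoxon(diffs, zero_method="wilcox", correction=False, method="auto")
    return float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    Degenerate all-equal data yields (H=0, p=1).
    """
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
        cleaned.append(g)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    allvals = np.concatenate(cleaned)
    if np.all(allvals == allvals[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*cleaned)
    return float(h), float(p)


def bootstrap_ci(
    values, level: float = 0.95, n_boot: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the median, resampling participants."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.percentile(meds, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in the tables)."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    m = int(ok.sum())
    if m == 0:
        return q
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    tmp = np.empty(m)
    tmp[order] = np.clip(ranked, 0, 1)
    q[ok] = tmp
    return q


@dataclass
class ContrastTables:
    """The two statistical summary tables of a cohort analysis.

    ``signed_rank``: one row per (metric, contrast, condition) with the
    median difference, Wilcoxon p and bootstrap CI.  ``kruskal``: one
    row per (metric, contrast) with the KW model p and chi-squared H,
    plus pairwise condition entries (median-difference location shifts
    with two-sided Mann-Whitney p; the pairwise definition is this
    package's own).  Unavailable cells carry NaN.
    """

    signed_rank: pd.DataFrame
    kruskal: pd.DataFrame
    stage_table: pd.DataFrame

    def to_text(self) -> str:
        lines = ["== Signed-rank contrasts (delta = median difference) =="]
        sr = self.signed_rank.copy()
        with pd.option_context("display.width", 200, "display.max_columns", 50):
            lines.append(sr.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
            lines.append("")
            lines.append("== Kruskal-Wallis across feedback conditions ==")
            lines.append(self.kruskal.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def run_full_analysis(
    trial_table: pd.DataFrame | None = None,
    stage_table: pd.DataFrame | None = None,
    metrics=None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_boot: int = 10000,
    seed: int = 0,
    bootstrap: bool = True,
    pairwise: bool = True,
    adjust: bool = False,
) -> ContrastTables:
    """Full statistical pipeline: stages -> contrasts -> both tables.

    Provide either a tidy per-trial table (stage medians are computed
    here) or a prebuilt stage table (e.g. when consistency metrics were
    scored per stage).  Deterministic under ``seed``.
    """
    if stage_table is None:
        if trial_table is None:
            raise ValueError("provide trial_table or stage_table")
        stage_table = build_stage_table(trial_table, metrics, block_size)
    if metrics is None:
        metrics = [m for m in ALL_METRICS if m in stage_table.columns]

    conditions = sorted(stage_table["condition"].unique())
    ss = np.random.SeedSequence(seed)
    cell_seeds = iter(ss.generate_state(len(metrics) * len(CONTRASTS) * len(conditions) + 16))

    sr_rows = []
    kw_rows = []
    for metric in metrics:
        for contrast in CONTRASTS:
            diffs = contrast_diffs(stage_table, metric, contrast)
            groups = {}
            for cond in conditions:
                d = diffs.loc[diffs["condition"] == cond, "diff"].to_numpy()
                groups[cond] = d[~np.isnan(d)]
                cell_seed = int(next(cell_seeds))
                if groups[cond].size == 0:
                    sr_rows.append(
                        dict(metric=metric, contrast=contrast, condition=cond,
                             delta=np.nan, p=np.nan, ci_lo=np.nan, ci_hi=np.nan, n=0)
                    )
                    continue
                delta = float(np.median(groups[cond]))
                p = wilcoxon_signed_rank(groups[cond])
                ci = (
                    bootstrap_ci(groups[cond], n_boot=n_boot, seed=cell_seed)
                    if bootstrap
                    else (np.nan, np.nan)
                )
                sr_rows.append(
                    dict(metric=metric, contrast=contrast, condition=cond,
                         delta=delta, p=p, ci_lo=ci[0], ci_hi=ci[1],
                         n=int(groups[cond].size))
                )
            # across-condition comparison
            if all(g.size >= 2 for g in groups.values()) and len(groups) >= 2:
                h, p_model = kruskal_wallis(list(groups.values()))
            else:
                h, p_model = np.nan, np.nan
            row = dict(metric=metric, contrast=contrast, h=h, p_model=p_model)
            if pairwise:
                for c1, c2 in combinations(conditions, 2):
                    key = f"{c1}-{c2}"
                    g1, g2 = groups.get(c1, np.array([])), groups.get(c2, np.array([]))
                    if g1.size >= 2 and g2.size >= 2:
                        row[f"delta_{key}"] = float(np.median(g1) - np.median(g2))
                        row[f"p_{key}"] = float(
                            sps.mannwhitneyu(g1, g2, alternative="two-sided").pvalue
                        )
                    else:
                        row[f"delta_{key}"] = np.nan
                        row[f"p_{key}"] = np.nan
            kw_rows.append(row)

    signed_rank = pd.DataFrame(sr_rows)
    kruskal = pd.DataFrame(kw_rows)
    if adjust:
        signed_rank["p_adj"] = benjamini_hochberg(signed_rank["p"].to_numpy())
    return ContrastTables(signed_rank=signed_rank, kruskal=kruskal, stage_table=stage_table)
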