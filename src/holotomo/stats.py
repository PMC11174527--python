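"""Cohort comparison layer: pairwise tests, significance stars, box plots.

Morphometric distributions across cell states are compared pairwise with a
two-sided Mann-Whitney U test by default (Welch's t is available); p-values
are mapped to the conventional star labels with strict thresholds:

    n.s.  p >= 0.05     *  p < 0.05     **  p < 0.01
    ***   p < 0.001     ****  p < 0.0001

No multiple-testing correction is applied by default; Holm-adjusted
p-values can be added as an extra column.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                   (0.05, "*"))


def star_label(p: float) -> str:
    """Map a p-value to its significance stars (strict inequalities)."""
    if not np.isfinite(p):
        return "n.s."
    for thr, label in STAR_THRESHOLDS:
        if p < thr:
            return label
    return "n.s."


def compare_states(table: pd.DataFrame, parameter: str,
                   test: str = "mannwhitney",
                   holm: bool = False) -> pd.DataFrame:
    """Pairwise two-sided tests of one parameter across all state pairs.

    ``table`` needs a ``state`` column and the parameter column.  Groups
    with fewer than 3 records are skipped; constant pooled values are
    flagged degenerate (p = NaN).  Returns one row per state pair with the
    statistic, p-value and star label (plus Holm-adjusted columns when
    requested).
    """
    if parameter not in table.columns:
        raise KeyError(parameter)
    groups = {s: g[parameter].dropna().to_numpy()
              for s, g in table.groupby("state", sort=True)}
    groups = {s: v for s, v in groups.items() if v.size >= 3}
    if len(groups) < 2:
        raise ValueError("need >= 2 states with >= 3 records each")
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        degenerate = np.ptp(np.concatenate([xa, xb])) == 0
        if degenerate:
            stat, p = float("nan"), float("nan")
            log.warning("compare_states: %s %s/%s constant-valued",
                        parameter, a, b)
        elif test == "mannwhitney":
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided",
                                   method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        elif test == "welch":
            res = sps.ttest_ind(xa, xb, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"parameter": parameter, "state_a": a, "state_b": b,
                     "statistic": stat, "pvalue": p,
                     "stars": star_label(p), "degenerate": degenerate})
    report = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests
        ok = report["pvalue"].notna()
        adj = np.full(len(report), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                report.loc[ok, "pvalue"], method="holm")[1]
        report["pvalue_holm"] = adj
        report["stars_holm"] = [star_label(p) for p in adj]
    return report


def full_report(table: pd.DataFrame, parameters=None,
                test: str = "mannwhitney", holm: bool = False) -> pd.DataFrame:
    """Pairwise tests for every parameter; concatenated report."""
    from .morphometry import PARAMETER_NAMES
    parameters = parameters or [p for p in PARAMETER_NAMES
                                if p in table.columns]
    parts = [compare_states(table, p, test=test, holm=holm)
             for p in parameters]
    return pd.concat(parts, ignore_index=True)


STATE_COLORS = {"normal": "#4c72b0", "autophagy": "#dd8452",
                "apoptosis": "#c44e52", "ferroptosis": "#55a868"}


def render_report(table: pd.DataFrame, report: pd.DataFrame,
                  output_dir: str | Path, image_format: str = "png",
                  ) -> list[Path]:
    """Write per-parameter box plots with star annotations plus CSV tables.

    One panel per parameter (16 for a full cohort table); pairs involving
    the first state are annotated with their stars, the complete pairwise
    report goes to ``statistics.csv``.  File naming and CSV bytes are
    deterministic for identical inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    states = sorted(table["state"].unique())
    params = sorted(report["parameter"].unique()) if len(report) else [
        c for c in table.columns if c not in ("state", "cell_id")]
    if len(report) == 0:
        log.warning("render_report: empty report, plots get no annotations")
    written = []
    for param in params:
        fig, ax = plt.subplots(figsize=(4, 3.2))
        data = [table.loc[table["state"] == s, param].dropna() for s in states]
        bp = ax.boxplot(data, tick_labels=states, patch_artist=True)
        for patch, s in zip(bp["boxes"], states):
            patch.set_facecolor(STATE_COLORS.get(s, "#cccccc"))
        ax.set_ylabel(param)
        sub = report[report["parameter"] == param] if len(report) else None
        if sub is not None and len(sub) and len(states) > 1:
            ymax = max((d.max() for d in data if len(d)), default=1.0)
            step = 0.08 * abs(ymax if ymax else 1.0)
            y = ymax + step
            ref = states[0]
            for other in states[1:]:
                row = sub[((sub.state_a == ref) & (sub.state_b == other))
                          | ((sub.state_a == other) & (sub.state_b == ref))]
                if len(row):
                    i, j = 1, states.index(other) + 1
                    ax.plot([i, i, j, j],
                            [y, y + step / 3, y + step / 3, y],
                            lw=0.8, c="k")
                    ax.text((i + j) / 2, y + step / 3,
                            row.iloc[0]["stars"], ha="center", fontsize=8)
                    y += step
        fig.tight_layout()
        path = output_dir / f"boxplot_{param}.{image_format}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    cohort_csv = output_dir / "cohort.csv"
    table.to_csv(cohort_csv, index=False, lineterminator="\n")
    stats_csv = output_dir / "statistics.csv"
    report.to_csv(stats_csv, index=False, lineterminator="\n")
    written += [cohort_csv, stats_csv]
    return written
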