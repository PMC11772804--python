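"""Group statistics, modifier-screen assembly and report rendering.

Group comparisons use the unpaired two-sided Mann–Whitney U test (exact by
enumeration for small tie-free samples, normal approximation with tie and
continuity correction otherwise).  The screen couples each target's egg
chambers to same-replicate sensitized controls: the per-chamber Δ ratio is
the chamber's nuclei/cell minus the mean control nuclei/cell of its
replicate, and the target-level call (enhancer / suppressor / no_effect)
combines the Mann–Whitney p-value against pooled same-replicate controls
with the sign of the median Δ.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

#: combined sample size at or below which the exact null distribution is used
#: (tie-free data only); above it, normal approximation with corrections.
EXACT_MAX_COMBINED_N = 12


@dataclass
class GroupComparison:
    """Two-sided Mann–Whitney comparison of two groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    median_a: float
    median_b: float
    method: str  # "exact" or "normal_approx"


def mann_whitney_u(
    x: Iterable[float],
    y: Iterable[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Unpaired two-sided Mann–Whitney U test.

    ``U`` is the statistic of the first sample computed from midranks.  The
    p-value is exact (full enumeration of the rank distribution) when the
    combined sample size is at most :data:`EXACT_MAX_COMBINED_N` and the data
    carry no ties; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= EXACT_MAX_COMBINED_N and not has_ties:
        method, scipy_method = "exact", "exact"
    else:
        method, scipy_method = "normal_approx", "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=len(x),
        n_b=len(y),
        U=float(res.statistic),
        p_two_sided=min(1.0, float(res.pvalue)),
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        method=method,
    )


def assemble_screen(
    records: pd.DataFrame,
    control_group: str,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Build the modifier-screen table from per-egg-chamber records.

    Parameters
    ----------
    records
        One row per egg chamber with columns ``sample_id, group, replicate,
        nuclei_per_cell`` (extra columns pass through).
    control_group
        Group label of the sensitized controls each replicate must contain.
    alpha
        Call threshold on the (uncorrected, matching the per-experiment
        design) two-sided Mann–Whitney p-value.
    bh_correction
        If true, an additional ``p_bh`` column with Benjamini–Hochberg
        adjusted p-values across targets is appended (off by default).

    Returns
    -------
    DataFrame with per-chamber ``delta_ratio`` and per-target ``p_vs_control``
    and ``call`` (``enhancer`` when p < alpha and median Δ > 0, ``suppressor``
    when p < alpha and median Δ < 0, else ``no_effect``).
    """
    required = {"sample_id", "group", "replicate", "nuclei_per_cell"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.copy()
    controls = df[df["group"] == control_group]
    if controls.empty:
        raise ValueError(f"no rows for control group {control_group!r}")
    control_means = controls.groupby("replicate")["nuclei_per_cell"].mean()

    targets = df[df["group"] != control_group]
    unpaired = targets[~targets["replicate"].isin(control_means.index)]
    if not unpaired.empty:
        rows = ", ".join(unpaired["sample_id"].astype(str))
        raise ValueError(
            f"rows without same-replicate controls ({control_group!r}): {rows}"
        )

    df["delta_ratio"] = df["nuclei_per_cell"] - df["replicate"].map(control_means)
    controls = df[df["group"] == control_group]

    out_rows = []
    for target, sub in df[df["group"] != control_group].groupby("group", sort=True):
        reps = sub["replicate"].unique()
        pooled_controls = controls[controls["replicate"].isin(reps)]["nuclei_per_cell"]
        cmp = mann_whitney_u(
            sub["nuclei_per_cell"], pooled_controls, group_a=str(target),
            group_b=control_group,
        )
        median_delta = float(sub["delta_ratio"].median())
        if cmp.p_two_sided < alpha and median_delta > 0:
            call = "enhancer"
        elif cmp.p_two_sided < alpha and median_delta < 0:
            call = "suppressor"
        else:
            call = "no_effect"
        for _, row in sub.iterrows():
            out_rows.append(
                {
                    "target": target,
                    "replicate": row["replicate"],
                    "egg_chamber_id": row["sample_id"],
                    "ratio": row["nuclei_per_cell"],
                    "delta_ratio": row["delta_ratio"],
                    "p_vs_control": cmp.p_two_sided,
                    "median_delta": median_delta,
                    "call": call,
                }
            )
    for _, row in controls.iterrows():
        out_rows.append(
            {
                "target": control_group,
                "replicate": row["replicate"],
                "egg_chamber_id": row["sample_id"],
                "ratio": row["nuclei_per_cell"],
                "delta_ratio": row["delta_ratio"],
                "p_vs_control": np.nan,
                "median_delta": np.nan,
                "call": "control",
            }
        )
    table = pd.DataFrame(
        out_rows,
        columns=[
            "target", "replicate", "egg_chamber_id", "ratio", "delta_ratio",
            "p_vs_control", "median_delta", "call",
        ],
    )
    if bh_correction:
        per_target = (
            table[table["call"] != "control"]
            .groupby("target")["p_vs_control"].first().sort_index()
        )
        p_bh = _benjamini_hochberg(per_target.to_numpy())
        bh_map = dict(zip(per_target.index, p_bh))
        table["p_bh"] = table["target"].map(bh_map)
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def render_report(
    out_dir: str | Path,
    screen_table: Optional[pd.DataFrame] = None,
    constriction_fits: Optional[pd.DataFrame] = None,
    failure_summary: Optional[pd.DataFrame] = None,
    comparisons: Optional[list[GroupComparison]] = None,
) -> dict[str, Path]:
    """Write the analysis tables as CSV plus a plain-text summary.

    Every table is written with a fixed column order; absent tables produce
    headers-only files so downstream tooling sees a stable layout.  Returns
    the mapping of artifact name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    specs = {
        "screen_table": (
            screen_table,
            ["target", "replicate", "egg_chamber_id", "ratio", "delta_ratio",
             "p_vs_control", "median_delta", "call"],
        ),
        "constriction_fits": (
            constriction_fits,
            ["sample_id", "t0_index", "d_t0_um", "window_start", "alpha_um",
             "beta_um_per_min", "rate_um_per_min", "r2"],
        ),
        "failure_summary": (
            failure_summary,
            ["group", "n_eligible", "n_category_1", "n_category_2", "n_category_3",
             "pct_category_1", "pct_category_2", "pct_category_3", "pct_failure",
             "regression_time_mean_min", "regression_time_sd_min"],
        ),
    }
    summary_lines = []
    for name, (table, columns) in specs.items():
        path = out_dir / f"{name}.csv"
        if table is None or len(table) == 0:
            pd.DataFrame(columns=columns).to_csv(path, index=False)
            summary_lines.append(f"{name}: 0 rows")
        else:
            cols = [c for c in columns if c in table.columns] + [
                c for c in table.columns if c not in columns
            ]
            table[cols].to_csv(path, index=False)
            summary_lines.append(f"{name}: {len(table)} rows")
        paths[name] = path

    if comparisons:
        cmp_df = pd.DataFrame([asdict(c) for c in comparisons])
    else:
        cmp_df = pd.DataFrame(
            columns=["group_a", "group_b", "n_a", "n_b", "U", "p_two_sided",
                     "median_a", "median_b", "method"]
        )
    cmp_path = out_dir / "group_comparisons.csv"
    cmp_df.to_csv(cmp_path, index=False)
    summary_lines.append(f"group_comparisons: {len(cmp_df)} rows")
    paths["group_comparisons"] = cmp_path

    summary_path = out_dir / "summary.txt"
    summary_path.write_text("\n".join(summary_lines) + "\n")
    paths["summary"] = summary_path
    return paths
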