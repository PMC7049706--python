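"""Per-cell summaries and group comparisons of speckle localization.

Per cell and channel: nuclear, cytoplasmic and total speckle counts, the
cytoplasmic ratio x = n_cyto / n_total, and its x**(1/5) transform (a
normalizing transform applied before the distributional tests). Group
comparisons use the Mann-Whitney U and two-sample Kolmogorov-Smirnov tests
on the transformed ratios, Pearson's chi-squared on the proportion of cells
with any cytoplasmic speckle, and Mann-Whitney plus quartile summaries for
speckle-size box plots.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .nuclei import NucleusRecord
from .speckles import CYTOPLASMIC, NUCLEAR, SpeckleRecord

log = logging.getLogger(__name__)


def transform_ratio(x):
    """Normalizing transform x -> x**(1/5) on [0, 1].

    Strictly increasing, fixes 0 and 1; spreads the mass near zero that
    cytoplasmic ratios concentrate at.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    out = arr ** 0.2
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def summarize_cells(
    speckle_records: list[SpeckleRecord],
    nucleus_records: list[NucleusRecord],
    micronuclei_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per non-excluded cell per channel.

    Cells with zero assigned speckles carry an undefined (NaN) ratio — they
    are excluded from ratio tests but kept in proportion tests with
    ``has_cytoplasmic = False``.
    """
    main = [
        r
        for r in nucleus_records
        if not r.is_candidate and not r.is_micronucleus and not r.touches_border
    ]
    channels = sorted({r.channel for r in speckle_records}) or [""]
    micro = {}
    if micronuclei_counts is not None and len(micronuclei_counts):
        micro = dict(
            zip(micronuclei_counts["nucleus_id"], micronuclei_counts["has_micronuclei"])
        )
    by_cell_channel: dict[tuple[int, str], list[SpeckleRecord]] = {}
    for s in speckle_records:
        if s.cell_id > 0 and s.compartment in (NUCLEAR, CYTOPLASMIC):
            by_cell_channel.setdefault((s.cell_id, s.channel), []).append(s)

    rows = []
    for nuc in main:
        for ch in channels:
            recs = by_cell_channel.get((nuc.nucleus_id, ch), [])
            n_nuc = sum(1 for s in recs if s.compartment == NUCLEAR)
            n_cyto = sum(1 for s in recs if s.compartment == CYTOPLASMIC)
            n_total = n_nuc + n_cyto
            ratio = n_cyto / n_total if n_total else np.nan
            sizes_nuc = [s.voxel_count for s in recs if s.compartment == NUCLEAR]
            sizes_cyto = [s.voxel_count for s in recs if s.compartment == CYTOPLASMIC]
            rows.append(
                dict(
                    cell_id=nuc.nucleus_id,
                    phase=nuc.phase,
                    channel=ch,
                    n_nuclear=n_nuc,
                    n_cytoplasmic=n_cyto,
                    n_total=n_total,
                    cytoplasmic_ratio=ratio,
                    transformed_ratio=transform_ratio(ratio) if n_total else np.nan,
                    has_cytoplasmic=n_cyto >= 1,
                    mean_size_nuclear=float(np.mean(sizes_nuc)) if sizes_nuc else np.nan,
                    mean_size_cytoplasmic=float(np.mean(sizes_cyto)) if sizes_cyto else np.nan,
                    has_micronuclei=bool(micro.get(nuc.nucleus_id, False)),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "phase",
            "channel",
            "n_nuclear",
            "n_cytoplasmic",
            "n_total",
            "cytoplasmic_ratio",
            "transformed_ratio",
            "has_cytoplasmic",
            "mean_size_nuclear",
            "mean_size_cytoplasmic",
            "has_micronuclei",
        ],
    )


@dataclass
class DistributionComparison:
    mw_statistic: float
    mw_p: float
    ks_statistic: float
    ks_p: float
    n_a: int
    n_b: int


def mannwhitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for combined n <= 20 without ties; otherwise the
    normal approximation with tie-corrected variance and no continuity
    correction. All-tied data returns p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("Mann-Whitney on all-tied data: p = 1", stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= 20 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def compare_distributions(sample_a, sample_b) -> DistributionComparison:
    """MW and two-sample KS (asymptotic p) on the given samples."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u, p_mw = mannwhitney(a, b)
    ks = sps.ks_2samp(a, b, method="asymp")
    return DistributionComparison(
        mw_statistic=u,
        mw_p=p_mw,
        ks_statistic=float(ks.statistic),
        ks_p=min(float(ks.pvalue), 1.0),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def compare_proportions(table) -> tuple[float, int, float]:
    """Pearson's chi-squared on an r x c contingency table.

    No continuity correction; expected counts from the row/column margins;
    df = (r-1)(c-1). Warns when any expected count is below 5.
    """
    obs = np.asarray(table, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("contingency table has a zero row or column margin")
    expected = row @ col / obs.sum()
    if np.any(expected < 5):
        warnings.warn("chi-squared: some expected counts < 5", stacklevel=2)
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(sps.chi2.sf(stat, df))


def quartile_summary(values) -> dict[str, float]:
    """Median and quartiles (linear interpolation) for box-plot reporting."""
    v = np.asarray(values, dtype=np.float64)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return dict(
        n=int(v.size),
        min=float(v.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        max=float(v.max()),
    )


def compare_speckle_sizes(sizes_a, sizes_b) -> dict:
    """MW two-sided test plus per-group quartiles on speckle sizes.

    Accepts per-speckle sizes or per-cell mean sizes; the caller picks the
    granularity.
    """
    a = np.asarray(sizes_a, dtype=np.float64)
    b = np.asarray(sizes_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both size samples must be non-empty")
    u, p = mannwhitney(a, b)
    return dict(
        mw_statistic=u, mw_p=p, group_a=quartile_summary(a), group_b=quartile_summary(b)
    )


def length_fold(len_a: float, len_b: float) -> int:
    """Fold ratio of two annotation lengths, rounded half away from zero.

    Used for report annotations of deleted-region sizes (e.g. a 1655-bp
    region is 11-fold the size of a 148-bp element).
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("lengths must be positive")
    return int(math.floor(len_a / len_b + 0.5))


def compare_groups(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    group_names: tuple[str, str] = ("a", "b"),
    use_transform: bool = True,
) -> pd.DataFrame:
    """Full comparison table across strata (interphase / mitotic / all).

    Per channel and stratum: MW and KS on the (transformed) cytoplasmic
    ratios of cells with at least one speckle, chi-squared on the
    has-cytoplasmic contingency table, and the raw-ratio MW/KS alongside.
    Strata without enough cells in both groups are skipped.
    """
    rows = []
    channels = sorted(set(summary_a["channel"]) | set(summary_b["channel"]))
    for ch in channels:
        sub_a = summary_a[summary_a["channel"] == ch]
        sub_b = summary_b[summary_b["channel"] == ch]
        for stratum in ("interphase", "mitotic", "all"):
            if stratum == "all":
                sel_a, sel_b = sub_a, sub_b
            else:
                sel_a = sub_a[sub_a["phase"] == stratum]
                sel_b = sub_b[sub_b["phase"] == stratum]
            ratios_a = sel_a["cytoplasmic_ratio"].dropna().to_numpy()
            ratios_b = sel_b["cytoplasmic_ratio"].dropna().to_numpy()
            base = dict(
                group_a=group_names[0],
                group_b=group_names[1],
                stratum=stratum,
                channel=ch,
                n_a=len(sel_a),
                n_b=len(sel_b),
            )
            if ratios_a.size and ratios_b.size:
                for label, ta, tb in (
                    ("transformed", transform_ratio(ratios_a), transform_ratio(ratios_b)),
                    ("raw", ratios_a, ratios_b),
                ):
                    if label == "raw" and not use_transform:
                        continue
                    cmp_ = compare_distributions(ta, tb)
                    rows.append(
                        dict(
                            base,
                            test=f"mw_{label}",
                            statistic=cmp_.mw_statistic,
                            p=cmp_.mw_p,
                        )
                    )
                    rows.append(
                        dict(
                            base,
                            test=f"ks_{label}",
                            statistic=cmp_.ks_statistic,
                            p=cmp_.ks_p,
                        )
                    )
            if len(sel_a) and len(sel_b):
                tab = np.array(
                    [
                        [
                            int(sel_a["has_cytoplasmic"].sum()),
                            int((~sel_a["has_cytoplasmic"]).sum()),
                        ],
                        [
                            int(sel_b["has_cytoplasmic"].sum()),
                            int((~sel_b["has_cytoplasmic"]).sum()),
                        ],
                    ]
                )
                if tab.sum(axis=0).min() > 0 and tab.sum(axis=1).min() > 0:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        stat, df, p = compare_proportions(tab)
                    rows.append(dict(base, test="chi2_has_cytoplasmic", statistic=stat, p=p))
    out = pd.DataFrame(
        rows,
        columns=["group_a", "group_b", "stratum", "channel", "test", "statistic", "p", "n_a", "n_b"],
    )
    if len(out):
        # unadjusted p-values are primary; a Bonferroni column is emitted for
        # transparency across the channel x compartment comparisons
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def cumulative_table(values, n_points: int = 101) -> pd.DataFrame:
    """Empirical CDF of the transformed ratios for plotting."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    grid = np.linspace(0.0, 1.0, n_points)
    cdf = np.searchsorted(v, grid, side="right") / max(v.size, 1)
    return pd.DataFrame({"transformed_ratio": grid, "cumulative_fraction": cdf})
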