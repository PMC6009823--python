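"""Sample-level quality filters for spiked amplicon runs.

Four automated filters, each independent and idempotent:

* low sequencing depth relative to the sample group mean;
* synthetic/microbial read ratio far above the group mean (spike
  over-representation, e.g. from pipetting error);
* abundance estimate an order of magnitude off the other biological
  replicates;
* observed spike share outside the per-1000 acceptance window.

Known contamination is a manual manifest annotation passed through, not
detected.  Removing flagged samples never rescales the survivors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .read_processing import CountTable

DEPTH_FRACTION = 0.4
SPIKE_RATIO_FOLD = 2.5
WINDOW = (200.0, 800.0)
MAGNITUDE_LOG10 = 1.0


def per1000(synthetic_reads: int, total_reads: int) -> float:
    """Synthetic reads per 1000 total reads; raises on zero total."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if not 0 <= synthetic_reads <= total_reads:
        raise ValueError("synthetic_reads must lie in [0, total_reads]")
    return 1000.0 * synthetic_reads / total_reads


def flag_window(
    sr1000_observed: float,
    low: float = WINDOW[0],
    high: float = WINDOW[1],
    strict: bool = True,
) -> bool:
    """True iff the observed spike share is inside the acceptance window
    (strict inequalities by default; set ``strict=False`` for inclusive)."""
    if strict:
        return low < sr1000_observed < high
    return low <= sr1000_observed <= high


def filter_low_depth(
    total_reads: pd.Series,
    groups: pd.Series,
    fraction: float = DEPTH_FRACTION,
    leave_one_out: bool = False,
) -> pd.Series:
    """Flag samples whose depth is below ``fraction`` x their group mean.

    The group mean includes the sample itself by default (so a
    single-sample group is never flagged); ``leave_one_out=True`` excludes
    it.
    """
    total = total_reads.astype(float)
    flags = pd.Series(False, index=total.index)
    for _, idx in total.groupby(groups).groups.items():
        vals = total.loc[idx]
        if leave_one_out and len(vals) > 1:
            means = (vals.sum() - vals) / (len(vals) - 1)
        else:
            means = pd.Series(vals.mean(), index=vals.index)
        flags.loc[idx] = vals < fraction * means
    return flags


def filter_spike_ratio(
    synthetic_reads: pd.Series,
    microbial_reads: pd.Series,
    groups: pd.Series,
    fold: float = SPIKE_RATIO_FOLD,
) -> pd.Series:
    """Flag samples whose synthetic/microbial read ratio is at least
    ``fold`` times their group mean ratio.  Samples with zero microbial
    reads are flagged unconditionally (ratio undefined)."""
    syn = synthetic_reads.astype(float)
    mic = microbial_reads.astype(float)
    degenerate = mic <= 0
    ratio = syn.where(~degenerate) / mic.where(~degenerate)
    flags = degenerate.copy()
    for _, idx in ratio.groupby(groups).groups.items():
        vals = ratio.loc[idx]
        mean = vals.mean()  # NaN-skipping
        if np.isnan(mean):
            continue
        flags.loc[idx] = flags.loc[idx] | (vals >= fold * mean)
    return flags.fillna(True)


def filter_magnitude_outlier(
    estimates: pd.Series,
    groups: pd.Series | None = None,
    threshold_log10: float = MAGNITUDE_LOG10,
) -> pd.Series:
    """Flag biological replicates whose estimate is an order of magnitude
    off: |log10(x) - median(log10 of the other replicates)| >= threshold.

    With fewer than 2 replicates in a group nothing is flagged.
    """
    est = estimates.astype(float)
    if (est <= 0).any():
        raise ValueError("estimates must be > 0 for log10 comparison")
    if groups is None:
        groups = pd.Series("all", index=est.index)
    logs = np.log10(est)
    flags = pd.Series(False, index=est.index)
    for _, idx in logs.groupby(groups).groups.items():
        vals = logs.loc[idx]
        if len(vals) < 2:
            continue
        for i in vals.index:
            others = vals.drop(i)
            flags.loc[i] = abs(vals.loc[i] - others.median()) >= threshold_log10
    return flags


def qc_report(
    count_table: CountTable,
    manifest: pd.DataFrame,
    *,
    depth_fraction: float = DEPTH_FRACTION,
    spike_fold: float = SPIKE_RATIO_FOLD,
    window: tuple[float, float] = WINDOW,
    strict_window: bool = True,
    estimates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (sample, family) with read metrics and all flags.

    ``manifest`` is the long-format sample manifest (columns sample,
    family, group, and optionally contaminated).  ``estimates`` (columns
    sample, family, copies_per_unit), when given, feeds the
    magnitude-outlier filter; otherwise that flag is False.  The ``flagged``
    column is the union of all flags.
    """
    rows = []
    for _, m in manifest.iterrows():
        s, fam = m["sample"], m["family"]
        total = count_table.total_reads(s, fam)
        syn = count_table.synthetic_reads(s, fam)
        rows.append(
            {
                "sample": s,
                "family": fam,
                "group": m.get("group", "all"),
                "total_reads": total,
                "synthetic_reads": syn,
                "microbial_reads": total - syn,
                "sr1000_observed": per1000(syn, total) if total else np.nan,
                "contaminated": bool(m.get("contaminated", False)),
            }
        )
    qc = pd.DataFrame(rows)
    gkey = qc["group"].astype(str) + "|" + qc["family"].astype(str)
    qc["low_depth"] = filter_low_depth(qc["total_reads"], gkey, depth_fraction)
    qc["spike_ratio_high"] = filter_spike_ratio(
        qc["synthetic_reads"], qc["microbial_reads"], gkey, spike_fold
    )
    qc["out_of_window"] = ~qc["sr1000_observed"].map(
        lambda v: flag_window(v, *window, strict=strict_window)
    )
    qc["magnitude_outlier"] = False
    if estimates is not None:
        est = qc.merge(
            estimates[["sample", "family", "copies_per_unit"]],
            on=["sample", "family"],
            how="left",
        )["copies_per_unit"]
        ok = est.notna() & (est > 0)
        if ok.any():
            flags = filter_magnitude_outlier(est[ok], gkey[ok])
            qc.loc[flags.index, "magnitude_outlier"] = flags
    qc["flagged"] = qc[
        [
            "low_depth",
            "spike_ratio_high",
            "out_of_window",
            "magnitude_outlier",
            "contaminated",
        ]
    ].any(axis=1)
    return qc
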