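"""Absolute gene-copy abundance from spike/microbial read ratios.

The core estimator: a sample spiked with S molecule copies that yields m
microbial-origin and s synthetic-origin reads carries

    copies per unit sample = S x m / s

gene copies per gram (or ml).  "Microbial-origin" excludes synthetic and
unassigned reads.  When spikes were added to already-purified DNA rather
than the raw sample, DNA lost during isolation was never seen by the
spikes, and the estimate must be rescaled by (predicted total DNA / DNA
actually used); adding spikes before isolation makes that loss cancel.

Per-taxon absolute profiles distribute a sample's total over taxa by read
fraction, and small helpers cover cross-family summaries, qPCR Ct-based
proportions, and the cell-culture control arithmetic.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_processing import CountTable


def absolute_abundance(
    microbial_reads: float, synthetic_reads: float, spike_copies: float
) -> float:
    """Gene copies per unit sample: spike_copies x microbial / synthetic.

    Raises on zero synthetic reads (quantitation impossible — the spike
    failed) or non-positive spike copies.
    """
    if synthetic_reads <= 0:
        raise ValueError("synthetic_reads must be > 0 (spike failure?)")
    if spike_copies <= 0:
        raise ValueError("spike_copies must be > 0")
    if microbial_reads < 0:
        raise ValueError("microbial_reads must be >= 0")
    return spike_copies * microbial_reads / synthetic_reads


def isolation_correction(
    estimate: float,
    predicted_total_dna_ng: float,
    used_dna_ng: float,
    spike_timing: str = "after",
) -> float:
    """Rescale a spike-after-isolation estimate by predicted/used DNA.

    Only valid when spikes were added after DNA purification
    (``spike_timing == "after"``); raises for spike-before-isolation
    samples, where the loss already cancels in the read ratio.
    """
    if spike_timing != "after":
        raise ValueError(
            "isolation correction applies only to spike-after-isolation "
            f"samples (got timing={spike_timing!r})"
        )
    if used_dna_ng <= 0:
        raise ValueError("used_dna_ng must be > 0")
    if predicted_total_dna_ng < 0:
        raise ValueError("predicted_total_dna_ng must be >= 0")
    return estimate * predicted_total_dna_ng / used_dna_ng


def expected_culture_copies(cells_per_unit: float, operons_per_genome: int) -> float:
    """Expected marker copies per unit of a counted culture:
    cfu x rRNA operons per genome."""
    if cells_per_unit <= 0 or operons_per_genome < 1:
        raise ValueError("inputs must be positive")
    return cells_per_unit * operons_per_genome


def recovery_percent(estimates: Sequence[float], expected: float) -> float:
    """mean(estimates) / expected x 100 — control-culture recovery."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    return float(np.mean(list(estimates))) / expected * 100.0


def taxon_absolute(
    taxon_reads: pd.Series, total_estimate: float
) -> pd.Series:
    """Distribute a sample's total copies over taxa by read fraction.

    ``taxon_reads`` holds microbial (non-synthetic) read counts only; the
    result sums to ``total_estimate`` exactly.
    """
    reads = taxon_reads.astype(float)
    total_reads = reads.sum()
    if total_reads <= 0:
        raise ValueError("no microbial reads to distribute")
    return reads / total_reads * total_estimate


def quantify(
    count_table: CountTable,
    manifest: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    keep_flagged: bool = False,
) -> pd.DataFrame:
    """Per-(sample, family) absolute-abundance estimates from a count table.

    ``manifest`` columns: sample, family, spike_copies, and optionally
    spike_timing ("before"/"after"), predicted_total_dna_ng, used_dna_ng.
    Samples flagged in ``qc`` are dropped unless ``keep_flagged``.
    Returns columns sample, family, microbial_reads, synthetic_reads,
    spike_copies, copies_per_unit, corrected.
    """
    man = manifest.copy()
    if qc is not None and not keep_flagged:
        bad = qc.loc[qc["flagged"], ["sample", "family"]]
        man = man.merge(
            bad.assign(_drop=True), on=["sample", "family"], how="left"
        )
        man = man[man["_drop"].isna()].drop(columns="_drop")
    rows = []
    for _, m in man.iterrows():
        s, fam = m["sample"], m["family"]
        mic = count_table.microbial_reads(s, fam)
        syn = count_table.synthetic_reads(s, fam)
        est = absolute_abundance(mic, syn, float(m["spike_copies"]))
        corrected = False
        timing = m.get("spike_timing", "before")
        if timing == "after":
            predicted = m.get("predicted_total_dna_ng", np.nan)
            used = m.get("used_dna_ng", np.nan)
            if np.isfinite(predicted) and np.isfinite(used):
                est = isolation_correction(est, float(predicted), float(used))
                corrected = True
        rows.append(
            {
                "sample": s,
                "family": fam,
                "microbial_reads": mic,
                "synthetic_reads": syn,
                "spike_copies": float(m["spike_copies"]),
                "copies_per_unit": est,
                "corrected": corrected,
            }
        )
    return pd.DataFrame(rows)


def absolute_profiles(
    count_table: CountTable, estimates: pd.DataFrame, family: str
) -> pd.DataFrame:
    """Samples x taxa absolute profiles (copies per unit) for one family.

    ``estimates`` is the output of :func:`quantify`; only samples present
    there are profiled.  Row sums equal the per-sample totals.
    """
    mic = count_table.microbial_counts(family)
    est = estimates[estimates["family"] == family].set_index("sample")
    out = {}
    for sample, row in est.iterrows():
        out[sample] = taxon_absolute(mic[sample], row["copies_per_unit"])
    return pd.DataFrame(out).T


def relative_profiles(count_table: CountTable, family: str) -> pd.DataFrame:
    """Samples x taxa relative profiles (fractions of microbial reads)."""
    mic = count_table.microbial_counts(family).astype(float)
    return (mic / mic.sum(axis=0)).T


def domain_fractions(totals: Mapping[str, float]) -> Dict[str, float]:
    """Percent contribution of each amplicon family (or grouping) to the
    summed absolute abundance; invariant to a common scale factor."""
    vals = {k: float(v) for k, v in totals.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("totals must be >= 0")
    s = sum(vals.values())
    if s == 0:
        raise ValueError("totals must not all be zero")
    return {k: v / s * 100.0 for k, v in vals.items()}


def qpcr_fractions(
    ct_values: Mapping[str, float], efficiency: float = 2.0
) -> Dict[str, float]:
    """Target proportions from qPCR Ct values: quantity ~ efficiency^(-Ct),
    normalised to 100%.  ``efficiency`` is the per-cycle amplification
    factor (2.0 = perfect doubling)."""
    if efficiency <= 1:
        raise ValueError("efficiency must be > 1")
    q = {k: efficiency ** (-float(ct)) for k, ct in ct_values.items()}
    s = sum(q.values())
    return {k: v / s * 100.0 for k, v in q.items()}
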