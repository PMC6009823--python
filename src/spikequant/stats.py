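"""Group comparisons and community ordination for relative vs absolute profiles.

Per-taxon two-sample t-tests (Welch by default) with Bonferroni correction
and star tiers; Bray-Curtis dissimilarity with the standard
standardise/square-root pre-treatment; and metric (classical) or
non-metric MDS ordination.  The point of running the same comparison on
both scales is that relative and absolute abundance can disagree in sign:
a taxon's read fraction can drop while its copies per gram rise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform


def _tier(p_adj: float) -> str:
    if np.isnan(p_adj):
        return "ns"
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def compare_groups(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    group_names: Tuple[str, str] = ("A", "B"),
    welch: bool = True,
) -> pd.DataFrame:
    """Per-taxon t-tests between two sample groups (samples x taxa frames).

    Returns one row per taxon: group means and SDs, raw p, Bonferroni-
    adjusted p (multiplied by the number of testable taxa, capped at 1),
    direction (name of the higher-mean group), star tier, and an
    ``untestable`` flag for taxa with zero variance in both groups and
    equal means.
    """
    if list(profiles_a.columns) != list(profiles_b.columns):
        raise ValueError("both groups must share the same taxon set")
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need >= 2 samples per group")
    rows = []
    for taxon in profiles_a.columns:
        a = profiles_a[taxon].to_numpy(dtype=float)
        b = profiles_b[taxon].to_numpy(dtype=float)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        untestable = False
        if va == 0 and vb == 0:
            if a.mean() == b.mean():
                p, stat = np.nan, np.nan
                untestable = True
            else:
                p, stat = 0.0, np.inf  # separated point masses
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "taxon": taxon,
                f"mean_{group_names[0]}": a.mean(),
                f"mean_{group_names[1]}": b.mean(),
                f"sd_{group_names[0]}": np.sqrt(va),
                f"sd_{group_names[1]}": np.sqrt(vb),
                "statistic": stat,
                "pvalue": p,
                "direction": group_names[0] if a.mean() > b.mean() else group_names[1],
                "untestable": untestable,
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    m = int((~out["untestable"]).sum())
    out["pvalue_bonferroni"] = np.minimum(out["pvalue"] * max(m, 1), 1.0)
    out["tier"] = out["pvalue_bonferroni"].map(_tier)
    return out


def bray_curtis_matrix(
    profiles: pd.DataFrame,
    standardise: bool = True,
    sqrt_transform: bool = True,
) -> Tuple[pd.DataFrame, List[str]]:
    """Bray-Curtis dissimilarities between samples (rows of ``profiles``).

    With ``standardise`` each sample is first divided by its total
    (proportions), then optionally square-root transformed — the usual
    pre-treatment for community ordination.  All-zero samples have no
    defined distance; they are excluded and returned in the second element.
    """
    if (profiles.to_numpy() < 0).any():
        raise ValueError("profiles must be non-negative")
    totals = profiles.sum(axis=1)
    excluded = list(profiles.index[totals == 0])
    kept = profiles.loc[totals > 0]
    if len(kept) < 2:
        raise ValueError("need >= 2 non-empty samples")
    x = kept.to_numpy(dtype=float)
    if standardise:
        x = x / x.sum(axis=1, keepdims=True)
    if sqrt_transform:
        x = np.sqrt(x)
    dm = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(dm, index=kept.index, columns=kept.index), excluded


def ordinate(
    dissimilarity: pd.DataFrame,
    dimensions: int = 2,
    method: str = "classical",
    seed: int = 0,
) -> pd.DataFrame:
    """Embed samples in ``dimensions`` coordinates from a dissimilarity
    matrix.

    ``method="classical"`` runs metric MDS (principal coordinates), which
    is deterministic and reproduces Euclidean inputs exactly;
    ``method="nonmetric"`` runs stress-minimising non-metric MDS seeded by
    ``seed``.  Columns are MDS1..MDSk.
    """
    ids = [str(i) for i in dissimilarity.index]
    if method == "classical":
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa

        res = pcoa(DistanceMatrix(dissimilarity.to_numpy(), ids))
        coords = res.samples.iloc[:, :dimensions].to_numpy()
    elif method == "nonmetric":
        from sklearn.manifold import MDS

        mds = MDS(
            n_components=dimensions,
            metric=False,
            dissimilarity="precomputed",
            random_state=seed,
            normalized_stress="auto",
        )
        coords = mds.fit_transform(dissimilarity.to_numpy())
    else:
        raise ValueError(f"unknown MDS method {method!r}")
    cols = [f"MDS{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dissimilarity.index, columns=cols)


@dataclass
class NullCalibration:
    """Observed familywise error of the Bonferroni-corrected comparison
    under a no-difference Gaussian null."""

    reps: int
    n_taxa: int
    n_per_group: int
    alpha: float
    familywise_rate: float


def familywise_error_rate(
    n_taxa: int = 20,
    n_per_group: int = 10,
    reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullCalibration:
    """Monte Carlo familywise type-I error of :func:`compare_groups` under
    the null (both groups i.i.d. standard normal)."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(n_taxa)]
    hits = 0
    for _ in range(reps):
        a = pd.DataFrame(rng.normal(size=(n_per_group, n_taxa)), columns=taxa)
        b = pd.DataFrame(rng.normal(size=(n_per_group, n_taxa)), columns=taxa)
        res = compare_groups(a, b)
        if (res["pvalue_bonferroni"] < alpha).any():
            hits += 1
    return NullCalibration(reps, n_taxa, n_per_group, alpha, hits / reps)
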