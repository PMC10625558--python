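"""Region-of-interest differential expression and DEG-set overlap.

Given per-spot region labels (an input — clustering/deconvolution that
produces them is outside this package), expression is compared between the
two conditions within each region using the non-parametric Kruskal-Wallis
rank-sum test on log2(CPM + 1) values, with every spot treated as a
replicate.  P-values are adjusted per region by the Benjamini-Hochberg
("FDR step-up") procedure; a gene is called a region DEG when FDR < 0.001
(strict) and |log2 fold change| >= 0.2, the fold change being the difference
of group medians on the log2 scale (so a gene unexpressed in a region has
median 0 in both groups and log2FC exactly 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegionDEResult",
    "kruskal_wallis_de",
    "kruskal_wallis_h",
    "filter_degs",
    "region_overlap",
]


@dataclass
class RegionDEResult:
    """Per-gene Kruskal-Wallis results within one region."""

    region: str
    table: pd.DataFrame          # gene, H, p, fdr, log2fc, significant


def kruskal_wallis_h(values: np.ndarray, group_b_mask: np.ndarray):
    """Vectorised two-group Kruskal-Wallis H with tie correction, per row.

    ``values`` is genes x spots; ``group_b_mask`` marks the second condition's
    columns.  Returns (H, p) with p from the chi-square distribution with 1
    degree of freedom.  Rows whose values are completely tied give H = 0,
    p = 1.
    """
    values = np.asarray(values, dtype=float)
    group_b_mask = np.asarray(group_b_mask, dtype=bool)
    n = values.shape[1]
    nb = int(group_b_mask.sum())
    na = n - nb
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 spots per condition in the region")

    ranks = stats.rankdata(values, axis=1)
    rb = ranks[:, group_b_mask].sum(axis=1)
    ra = ranks.sum(axis=1) - rb
    h = 12.0 / (n * (n + 1)) * (ra ** 2 / na + rb ** 2 / nb) - 3.0 * (n + 1)

    # tie correction: 1 - sum(t^3 - t) / (n^3 - n) over tie groups per row
    sorted_vals = np.sort(values, axis=1)
    tie_term = np.empty(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(sorted_vals[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    correction = 1.0 - tie_term / (n ** 3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = h / correction
    all_tied = correction == 0
    h = np.where(all_tied, 0.0, h)
    h = np.maximum(h, 0.0)                      # guard tiny negative rounding
    p = stats.chi2.sf(h, df=1)
    p = np.where(all_tied, 1.0, p)
    h = np.where(all_tied, 0.0, h)
    return h, p


def kruskal_wallis_de(values: np.ndarray, genes: np.ndarray,
                      region_labels: np.ndarray, condition_labels: np.ndarray,
                      region: str, condition_order: tuple[str, str] = None,
                      fdr_cut: float = 0.001, lfc_cut: float = 0.2) -> RegionDEResult:
    """Kruskal-Wallis DE between two conditions within one region.

    ``values`` is a genes x spots matrix on the log2(CPM + 1) scale;
    ``region_labels``/``condition_labels`` are per-spot.  log2FC is
    median(second condition) - median(first condition); with the default
    order inferred from sorted labels, pass ``condition_order=("NSD", "SD")``
    to fix the sign convention explicitly.  FDR is Benjamini-Hochberg step-up
    across genes within the region.
    """
    region_labels = np.asarray(region_labels)
    condition_labels = np.asarray(condition_labels)
    in_region = region_labels == region
    if not in_region.any():
        raise ValueError(f"region {region!r} absent from labels")
    vals = np.asarray(values, dtype=float)[:, in_region]
    cond = condition_labels[in_region]
    if condition_order is None:
        condition_order = tuple(sorted(set(cond)))
    if len(condition_order) != 2:
        raise ValueError("exactly two conditions required")
    a, b = condition_order
    mask_b = cond == b
    if (cond == a).sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"need >= 2 spots per condition in region {region!r}")

    h, p = kruskal_wallis_h(vals, mask_b)
    med_a = np.median(vals[:, cond == a], axis=1)
    med_b = np.median(vals[:, mask_b], axis=1)
    log2fc = med_b - med_a
    fdr = multipletests(p, method="fdr_bh")[1]
    sig = (fdr < fdr_cut) & (np.abs(log2fc) >= lfc_cut)
    return RegionDEResult(region, pd.DataFrame({
        "gene": np.asarray(genes, dtype=object),
        "H": h,
        "p": p,
        "fdr": fdr,
        "log2fc": log2fc,
        "significant": sig,
    }))


def filter_degs(result: RegionDEResult, fdr_cut: float = 0.001,
                lfc_cut: float = 0.2) -> set:
    """DEG set for a region: FDR strictly below the cut and |log2FC| >= cut."""
    t = result.table
    keep = (t["fdr"] < fdr_cut) & (t["log2fc"].abs() >= lfc_cut)
    return set(t.loc[keep, "gene"])


def region_overlap(deg_sets: dict) -> pd.DataFrame:
    """Exclusive-intersection (UpSet-style) counts over DEG sets by region.

    For every non-empty combination of regions, counts genes belonging to
    exactly that combination.  Rows with zero genes are omitted.
    """
    if not deg_sets:
        raise ValueError("at least one DEG set required")
    regions = list(deg_sets)
    membership: dict = {}
    for g in set().union(*deg_sets.values()):
        key = frozenset(r for r in regions if g in deg_sets[r])
        membership[key] = membership.get(key, 0) + 1
    rows = []
    for r in range(1, len(regions) + 1):
        for combo in combinations(regions, r):
            n = membership.get(frozenset(combo), 0)
            if n:
                rows.append(("&".join(combo), len(combo), n))
    return pd.DataFrame(rows, columns=["combination", "degree", "n_genes"])
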