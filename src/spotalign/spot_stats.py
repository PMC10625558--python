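"""Per-digital-spot two-sample testing with family-wise correction.

At every kept digital spot, each gene's pooled group-A values are compared to
its pooled group-B values with a two-tailed two-sample t-test (Student pooled
variance by default, Welch optional).  The family of tests is the set of
genes: the per-test threshold is Sidak-corrected, alpha_s = 1 - (1 -
alpha)^(1/m) with m the number of genes in the tested universe (Bonferroni
alpha/m and Benjamini-Hochberg step-up are provided as alternatives).  A gene
is called differentially expressed if at least one kept digital spot passes
the corrected threshold; its direction class is "up" if every significant
spot has t > 0 (second group above first), "down" if all t < 0, "mixed"
otherwise.

The pooled spots are treated as independent replicates within a group — the
rank/t-test convention of spot-level transcriptomics.  This is a deliberate
pseudoreplication: per-animal correlation is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .digital_grid import PooledExpression

__all__ = [
    "MultipleTestingConfig",
    "SpotTestResult",
    "corrected_threshold",
    "spot_ttest",
    "spot_ttest_all",
    "summarize_genes",
    "masked_subregion_test",
]


@dataclass(frozen=True)
class MultipleTestingConfig:
    """Family-wise correction settings: level alpha, method, family size m."""

    alpha: float = 0.05
    method: str = "sidak"       # sidak | bonferroni | bh
    m: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.method not in ("sidak", "bonferroni", "bh"):
            raise ValueError(f"unknown correction method {self.method!r}")


@dataclass
class SpotTestResult:
    """t and p per (gene, kept digital spot) plus per-gene summary calls."""

    genes: np.ndarray
    spot_ids: np.ndarray          # kept digital spot ids
    t: np.ndarray                 # genes x spots
    p: np.ndarray                 # genes x spots
    group_a: str
    group_b: str
    summary: pd.DataFrame | None = None
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        gi, si = np.meshgrid(np.arange(len(self.genes)),
                             np.arange(len(self.spot_ids)), indexing="ij")
        return pd.DataFrame({
            "gene": self.genes[gi.ravel()],
            "spot_id": self.spot_ids[si.ravel()],
            "t": self.t.ravel(),
            "p": self.p.ravel(),
        })


def corrected_threshold(cfg: MultipleTestingConfig) -> float:
    """Per-test p threshold under the configured family-wise correction.

    Sidak: 1 - (1 - alpha)^(1/m).  Bonferroni: alpha/m.  BH has no fixed
    per-test threshold (it is data dependent); requesting it here raises.
    """
    if cfg.m < 1:
        raise ValueError("m must be >= 1")
    if cfg.method == "sidak":
        return 1.0 - (1.0 - cfg.alpha) ** (1.0 / cfg.m)
    if cfg.method == "bonferroni":
        return cfg.alpha / cfg.m
    raise ValueError(
        "BH threshold is data-dependent; apply it via summarize_genes")


def _ttest_arrays(a: np.ndarray, b: np.ndarray, equal_var: bool = True):
    """Vectorised two-sample t over the last axis with the degenerate-variance
    convention: zero pooled variance with equal means -> t = 0, p = 1."""
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 values per gene")
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va = a.var(axis=-1, ddof=1)
    vb = b.var(axis=-1, ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, na + nb - 2, dtype=float)
    else:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    diff = mb - ma                       # positive t <=> group B above group A
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    zero_se = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    return t, p


def spot_ttest(values_a: np.ndarray, values_b: np.ndarray,
               equal_var: bool = True):
    """Two-tailed two-sample t per gene at one digital spot.

    ``values_a``/``values_b`` are genes x pooled-width matrices.  The sign
    convention is t > 0 when group B's mean exceeds group A's (call with
    A=control, B=treatment for "treatment > control" t maps).
    """
    return _ttest_arrays(np.asarray(values_a, float),
                         np.asarray(values_b, float), equal_var)


def spot_ttest_all(pooled: PooledExpression, group_a: str, group_b: str,
                   equal_var: bool = True) -> SpotTestResult:
    """t and p for every gene at every kept digital spot (vectorised).

    Requires equal pooled widths across kept spots within each group (the
    default grid filter guarantees this); spots are processed in blocks.
    """
    stacked_a, cols_a = pooled.group_stack(group_a)
    stacked_b, cols_b = pooled.group_stack(group_b)
    n_spots = len(pooled.kept_indices)
    n_genes = len(pooled.genes)
    t = np.empty((n_genes, n_spots))
    p = np.empty((n_genes, n_spots))
    widths_a = {len(c) for c in cols_a}
    widths_b = {len(c) for c in cols_b}
    if len(widths_a) == 1 and len(widths_b) == 1:
        # uniform widths: one 3-D vectorised pass
        ia = np.stack(cols_a)                      # spots x widthA
        ib = np.stack(cols_b)
        a = stacked_a[:, ia]                       # genes x spots x widthA
        b = stacked_b[:, ib]
        t, p = _ttest_arrays(a, b, equal_var)
    else:
        for j in range(n_spots):
            t[:, j], p[:, j] = _ttest_arrays(
                stacked_a[:, cols_a[j]], stacked_b[:, cols_b[j]], equal_var)
    return SpotTestResult(
        genes=pooled.genes, spot_ids=pooled.kept_indices,
        t=t, p=p, group_a=group_a, group_b=group_b,
    )


def summarize_genes(result: SpotTestResult,
                    cfg: MultipleTestingConfig) -> SpotTestResult:
    """Call DEGs and direction classes from the per-spot t/p matrices.

    Family size m = number of genes; a gene is significant iff >= 1 kept spot
    passes.  For sidak/bonferroni a fixed per-test threshold is used; for BH
    the step-up procedure runs over the same family the fixed corrections
    use — the genes at each digital spot, column by column — so BH rejects a
    superset of the Bonferroni calls at every spot.
    """
    if cfg.method == "bh":
        sig = np.empty_like(result.p, dtype=bool)
        for j in range(result.p.shape[1]):
            sig[:, j] = multipletests(result.p[:, j], alpha=cfg.alpha,
                                      method="fdr_bh")[0]
        threshold = float("nan")
    else:
        threshold = corrected_threshold(
            MultipleTestingConfig(cfg.alpha, cfg.method, m=len(result.genes)))
        sig = result.p < threshold

    n_sig = sig.sum(axis=1)
    up = np.array([bool(s.any()) and bool((result.t[i][s] > 0).all())
                   for i, s in enumerate(sig)])
    down = np.array([bool(s.any()) and bool((result.t[i][s] < 0).all())
                     for i, s in enumerate(sig)])
    cls = np.where(n_sig == 0, "ns",
                   np.where(up, "up", np.where(down, "down", "mixed")))
    result.summary = pd.DataFrame({
        "gene": result.genes,
        "n_sig_spots": n_sig,
        "class": cls,
    })
    result.threshold = threshold
    return result


def masked_subregion_test(result: SpotTestResult, spot_mask: np.ndarray,
                          gene: str, alpha: float = 0.1) -> dict:
    """Single-gene test restricted to a subset of digital spots.

    The correction family is the number of masked kept spots m (not the gene
    universe): threshold = 1 - (1 - alpha)^(1/m).  Returns the threshold and
    per-masked-spot significance calls.
    """
    spot_mask = np.asarray(spot_mask, dtype=bool)
    if spot_mask.shape != result.spot_ids.shape:
        raise ValueError("spot mask must align with kept digital spots")
    if not spot_mask.any():
        raise ValueError("empty digital-spot mask")
    gi = np.nonzero(result.genes == gene)[0]
    if gi.size == 0:
        raise KeyError(f"gene {gene!r} not in tested universe")
    m = int(spot_mask.sum())
    thr = corrected_threshold(MultipleTestingConfig(alpha, "sidak", m=m))
    p = result.p[gi[0], spot_mask]
    t = result.t[gi[0], spot_mask]
    return {
        "gene": gene,
        "m": m,
        "threshold": thr,
        "spot_ids": result.spot_ids[spot_mask],
        "t": t,
        "p": p,
        "significant": p < thr,
    }
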