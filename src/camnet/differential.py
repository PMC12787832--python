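"""Differential-feature statistics and the per-layer calling rules.

Calling rules, per pairwise contrast (test vs reference):

- transcript:  |log2FC| >= 1  and  BH-adjusted p (FDR) < 0.05
- protein:     |log2FC| >= 1  and  unadjusted p < 0.05
- metabolite:  VIP > 1 (strict) and p < 0.05, direction by sign of log2FC

The fold-change boundary is inclusive ("at least"), the VIP boundary strict.
The transcript layer runs a configurable two-sample test on log2(count+1)
in place of a negative-binomial GLM; the calling thresholds are unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SampleDesign
from .matrix import OmicsMatrix, Stage

logger = logging.getLogger(__name__)

LOG10_2 = np.log10(2.0)


@dataclass
class Thresholds:
    log2fc: float = 1.0
    fdr: float = 0.05
    p: float = 0.05
    vip: float = 1.0


@dataclass
class DifferentialTable:
    """Per-feature statistics and call status for one contrast of one layer.

    ``table`` columns: log2fc, p, and (layer-dependent) fdr, vip, call.
    """

    contrast: tuple[str, str]
    layer: str
    table: pd.DataFrame

    @property
    def up(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "up"])

    @property
    def down(self) -> set[str]:
        return set(self.table.index[self.table["call"] == "down"])

    @property
    def significant(self) -> set[str]:
        return self.up | self.down

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def _group_arrays(
    m: OmicsMatrix, design: SampleDesign, contrast: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    test, ref = contrast
    a = m.values[design.samples_in_group(test)].to_numpy(dtype=float)
    b = m.values[design.samples_in_group(ref)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both contrast groups need >= 2 replicates")
    return a, b


def log2_fold_change(
    m: OmicsMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    pseudocount: float = 0.0,
) -> pd.Series:
    """log2((mean_test + c) / (mean_ref + c)) per feature.

    On a logged metabolite matrix (stage ``logged``, base-10) the fold change
    is the difference of group means divided by log10(2) — the same ratio on
    the raw scale.
    """
    a, b = _group_arrays(m, design, contrast)
    if m.stage == Stage.LOGGED:
        fc = (a.mean(axis=1) - b.mean(axis=1)) / LOG10_2
    else:
        num = a.mean(axis=1) + pseudocount
        den = b.mean(axis=1) + pseudocount
        if np.any(den == 0) or np.any(num == 0):
            raise ValueError(
                "zero group mean with pseudocount 0; supply a positive pseudocount"
            )
        fc = np.log2(num / den)
    return pd.Series(fc, index=m.feature_ids, name="log2fc")


def welch_t(
    m: OmicsMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    equal_var: bool = False,
) -> pd.Series:
    """Two-sided two-sample t-test p-values per feature (Welch by default,
    pooled-variance Student with ``equal_var=True``).

    Degenerate features (zero variance in both groups) get p = 1 when the
    means are equal, and the smallest positive float when they differ.
    """
    import warnings

    a, b = _group_arrays(m, design, contrast)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # zero-variance features trigger a precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    var0 = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if var0.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        n_eq = int((var0 & same).sum())
        if n_eq:
            logger.warning("welch_t: %d zero-variance feature(s), p set to 1", n_eq)
        p[var0 & same] = 1.0
        p[var0 & ~same] = np.finfo(float).tiny
    return pd.Series(p, index=m.feature_ids, name="p")


def bh_adjust(pvals: pd.Series) -> pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (FDR).

    fdr_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; stable under
    input reordering.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return pd.Series(p, index=pvals.index, name="fdr")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(n)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return pd.Series(fdr, index=pvals.index, name="fdr")


def call_features(
    table: DifferentialTable, thresholds: Thresholds | None = None
) -> DifferentialTable:
    """Apply the layer's calling rule, writing the ``call`` column
    (up / down / ns)."""
    thr = thresholds or Thresholds()
    t = table.table
    layer = table.layer

    required = {
        "transcript": ("log2fc", "fdr"),
        "protein": ("log2fc", "p"),
        "metabolite": ("log2fc", "p", "vip"),
    }[layer]
    for col in required:
        if col not in t.columns or t[col].isna().all():
            raise ValueError(f"layer {layer!r} requires statistic {col!r}")

    fc = t["log2fc"]
    if layer == "transcript":
        sig = t["fdr"] < thr.fdr
        up = sig & (fc >= thr.log2fc)
        down = sig & (fc <= -thr.log2fc)
    elif layer == "protein":
        sig = t["p"] < thr.p
        up = sig & (fc >= thr.log2fc)
        down = sig & (fc <= -thr.log2fc)
    else:  # metabolite: no fold threshold, direction by sign
        sig = (t["vip"] > thr.vip) & (t["p"] < thr.p)
        up = sig & (fc > 0)
        down = sig & (fc < 0)

    call = pd.Series("ns", index=t.index, name="call")
    call[up] = "up"
    call[down] = "down"
    out = t.copy()
    out["call"] = call
    return DifferentialTable(table.contrast, layer, out)


def differential_table(
    m: OmicsMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    pseudocount: float | None = None,
    equal_var: bool = False,
    vip: pd.Series | None = None,
    thresholds: Thresholds | None = None,
) -> DifferentialTable:
    """Build a fully called differential table for one contrast.

    Transcript counts are tested on the log2(x+1) scale with a default
    pseudocount of 1 for the fold change; protein and metabolite layers use
    pseudocount 0 (their intensities are strictly positive after
    preprocessing). The metabolite rule needs a ``vip`` series from
    :func:`camnet.preprocess.pls_vip`.
    """
    layer = m.layer
    if pseudocount is None:
        pseudocount = 1.0 if layer == "transcript" else 0.0

    fc = log2_fold_change(m, design, contrast, pseudocount=pseudocount)

    if layer == "transcript" and m.stage == Stage.RAW:
        test_m = OmicsMatrix(np.log2(m.values + 1.0), layer=layer, stage=m.stage)
    else:
        test_m = m
    p = welch_t(test_m, design, contrast, equal_var=equal_var)

    cols = {"log2fc": fc, "p": p}
    if layer == "transcript":
        cols["fdr"] = bh_adjust(p)
    if layer == "metabolite":
        if vip is None:
            raise ValueError("metabolite layer requires a VIP series")
        cols["vip"] = vip.reindex(m.feature_ids)
    t = pd.DataFrame(cols, index=m.feature_ids)
    return call_features(DifferentialTable(contrast, layer, t), thresholds)
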