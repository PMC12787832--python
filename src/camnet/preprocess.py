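"""Metabolomics preprocessing cascade and PLS-DA variable importance.

The cascade is applied in a fixed, contract-enforced order on a raw peak
table:

1. presence filter   — keep features detected in >= 80 % of samples
2. minimum imputation — replace missing entries by the minimum observed value
3. sum normalization — scale each sample column to unit total
4. QC-RSD filter     — drop features with RSD > 30 % across pooled-QC columns
5. log10 transform   — final matrix for statistics

"Detected" means non-missing and strictly positive. The RSD uses the sample
standard deviation (n-1 denominator), the metabolomics-QC convention, and is
computed after sum normalization and before the log, matching the narrated
order of the protocol.

Metabolite significance combines a two-sample t-test with a variable
importance in projection (VIP) score from a partial-least-squares
discriminant model; ``pls_vip`` implements PLS1-NIPALS on autoscaled data
with the standard VIP formula, whose mean squared value over fitted
features is 1 by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleDesign
from .matrix import OmicsMatrix, Stage

logger = logging.getLogger(__name__)


def presence_filter(m: OmicsMatrix, min_frac: float = 0.8) -> OmicsMatrix:
    """Retain features detected (non-missing and > 0) in at least
    ``min_frac`` of samples; the boundary is inclusive."""
    m.require_stage(Stage.RAW)
    if m.n_features == 0 or m.n_samples == 0:
        logger.warning("presence_filter: empty matrix")
        return m.advanced(m.values, Stage.FILTERED)
    detected = m.values.notna() & (m.values > 0)
    frac = detected.sum(axis=1) / m.n_samples
    keep = frac >= min_frac
    return m.advanced(m.values.loc[keep], Stage.FILTERED)


def impute_min(m: OmicsMatrix, scope: str = "per_feature") -> OmicsMatrix:
    """Replace every missing entry by the minimum observed value, either per
    feature row or globally over the whole matrix."""
    m.require_stage(Stage.FILTERED)
    if scope not in ("per_feature", "global"):
        raise ValueError(f"unknown imputation scope {scope!r}")
    values = m.values.copy()
    if scope == "per_feature":
        mins = values.min(axis=1, skipna=True)
        empty = mins.isna()
        if empty.any():
            raise ValueError(
                "features with no observed values cannot be imputed per-feature: "
                f"{list(values.index[empty])}"
            )
        values = values.apply(lambda row: row.fillna(mins[row.name]), axis=1)
    else:
        gmin = np.nanmin(values.to_numpy()) if values.size else np.nan
        values = values.fillna(gmin)
    return m.advanced(values, Stage.IMPUTED)


def sum_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Divide each sample column by its total so every column sums to 1."""
    m.require_stage(Stage.IMPUTED)
    if (m.values.to_numpy() < 0).any():
        raise ValueError("sum normalization requires nonnegative intensities")
    totals = m.values.sum(axis=0)
    zero = totals == 0
    if zero.any():
        raise ValueError(f"sample(s) with zero total intensity: {list(totals.index[zero])}")
    return m.advanced(m.values / totals, Stage.NORMALIZED)


def qc_rsd_filter(
    m: OmicsMatrix, design: SampleDesign, max_rsd: float = 0.30
) -> OmicsMatrix:
    """Drop features whose relative standard deviation over the pooled-QC
    columns exceeds ``max_rsd`` (strict: RSD exactly at the threshold is
    retained). RSD = sample sd / mean."""
    m.require_stage(Stage.NORMALIZED)
    qc = [s for s in design.qc_samples if s in m.values.columns]
    if len(qc) < 2:
        raise ValueError(f"QC-RSD filter needs >= 2 QC samples, found {len(qc)}")
    sub = m.values[qc]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    zero_mean = mean == 0
    if zero_mean.any():
        logger.warning(
            "qc_rsd_filter: zero QC mean, excluding %s", list(mean.index[zero_mean])
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    keep = (~zero_mean) & (rsd <= max_rsd)
    return m.advanced(m.values.loc[keep], Stage.QC_FILTERED)


def log10_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log10; all values must be strictly positive."""
    m.require_stage(Stage.QC_FILTERED)
    bad = (m.values <= 0) | m.values.isna()
    if bad.to_numpy().any():
        rows = m.values.index[bad.any(axis=1)].tolist()
        cols = m.values.columns[bad.any(axis=0)].tolist()
        raise ValueError(f"nonpositive values (features {rows[:5]}, samples {cols[:5]})")
    return m.advanced(np.log10(m.values), Stage.LOGGED)


def run_cascade(
    m: OmicsMatrix,
    design: SampleDesign,
    min_frac: float = 0.8,
    max_rsd: float = 0.30,
    impute_scope: str = "per_feature",
) -> tuple[OmicsMatrix, list[dict]]:
    """Run the full cascade in order, recording a provenance entry (operation,
    parameters, features in/out, removed feature ids) per stage."""
    prov: list[dict] = []

    def _step(name: str, params: dict, before: OmicsMatrix, after: OmicsMatrix) -> None:
        removed = sorted(set(before.feature_ids) - set(after.feature_ids))
        prov.append(
            {
                "operation": name,
                "params": params,
                "n_features_in": before.n_features,
                "n_features_out": after.n_features,
                "removed_features": removed,
            }
        )

    cur = m
    nxt = presence_filter(cur, min_frac)
    _step("presence_filter", {"min_frac": min_frac}, cur, nxt)
    cur, nxt = nxt, impute_min(nxt, impute_scope)
    _step("impute_min", {"scope": impute_scope}, cur, nxt)
    cur, nxt = nxt, sum_normalize(nxt)
    _step("sum_normalize", {}, cur, nxt)
    cur, nxt = nxt, qc_rsd_filter(nxt, design, max_rsd)
    _step("qc_rsd_filter", {"max_rsd": max_rsd}, cur, nxt)
    cur, nxt = nxt, log10_transform(nxt)
    _step("log10_transform", {}, cur, nxt)
    return nxt, prov


# ---------------------------------------------------------------------------
# PLS-DA VIP


@dataclass
class VipResult:
    """Per-feature VIP scores from a PLS1 discriminant fit.

    The invariant mean(VIP^2) = 1 holds over the fitted (non-constant)
    features; constant features are excluded from autoscaling and carry
    VIP = 0.
    """

    vip: pd.Series
    n_components: int
    y_contrast: tuple[str, str]

    def selected(self, threshold: float = 1.0) -> set[str]:
        """Features with VIP strictly above ``threshold``."""
        return set(self.vip.index[self.vip > threshold])


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """PLS1 via NIPALS: returns (weights W [p x A], per-component explained
    response sum of squares SSY [A]). X and y must be centered."""
    Xc = X.copy()
    yc = y.astype(float).copy()
    p = X.shape[1]
    W = np.zeros((p, n_components))
    ssy = np.zeros(n_components)
    a_used = 0
    for a in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pload = Xc.T @ t / tt
        q = float(yc @ t) / tt
        Xc -= np.outer(t, pload)
        yc -= q * t
        W[:, a] = w
        ssy[a] = q * q * tt
        a_used += 1
    return W[:, :a_used], ssy[:a_used]


def pls_vip(
    m: OmicsMatrix,
    design: SampleDesign,
    contrast: tuple[str, str],
    n_components: int = 2,
) -> VipResult:
    """Variable importance in projection for a two-group contrast.

    Fits PLS1-NIPALS on mean-centered, unit-variance features against a
    centered +/-1 group code and evaluates

        VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

    where p is the number of fitted features and SSY_a the response sum of
    squares explained by component a.
    """
    m.require_stage(Stage.LOGGED)
    test, ref = contrast
    s_test = design.samples_in_group(test)
    s_ref = design.samples_in_group(ref)
    if len(s_test) < 2 or len(s_ref) < 2:
        raise ValueError("both groups need >= 2 non-QC samples")
    samples = s_test + s_ref
    n, p_all = len(samples), m.n_features
    if not 1 <= n_components < min(n - 1, p_all):
        raise ValueError(
            f"n_components {n_components} outside [1, min(samples-1, features)) "
            f"= [1, {min(n - 1, p_all)})"
        )

    X = m.values[samples].T.to_numpy(dtype=float)  # samples x features
    y = np.array([1.0] * len(s_test) + [-1.0] * len(s_ref))
    y = y - y.mean()

    sd = X.std(axis=0, ddof=1)
    fitted = sd > 0
    if not fitted.all():
        warnings.warn(
            f"{int((~fitted).sum())} constant feature(s) excluded from PLS scaling; VIP set to 0",
            stacklevel=2,
        )
    Xf = X[:, fitted]
    Xf = (Xf - Xf.mean(axis=0)) / sd[fitted]

    W, ssy = _nipals_pls1(Xf, y, n_components)
    if W.shape[1] == 0 or ssy.sum() <= 0:
        raise ValueError("PLS fit degenerate: no response variance explained")
    p_fit = Xf.shape[1]
    # columns of W are unit norm by construction
    vip_fit = np.sqrt(p_fit * (W**2 @ ssy) / ssy.sum())

    vip = np.zeros(p_all)
    vip[np.flatnonzero(fitted)] = vip_fit
    series = pd.Series(vip, index=m.feature_ids, name="vip")
    return VipResult(vip=series, n_components=W.shape[1], y_contrast=(test, ref))
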