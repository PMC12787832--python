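"""Enrichment statistics: hypergeometric over-representation and pre-ranked
GSEA enrichment scores with a permutation p-value."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .gmt import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeom_enrich(
    selected: set[str],
    universe: set[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    Population N = |universe|, successes K = |set ∩ universe|, draws
    n = |selected|, observed overlap k; p = P(X >= k). Sets are intersected
    with the universe before testing and BH adjustment is applied across
    all tested sets. ``selected`` must be a subset of ``universe``.
    """
    from scipy.stats import hypergeom

    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")
    cols = ["pathway", "description", "k", "K", "n", "N", "p", "fdr"]
    if not selected:
        logger.warning("hypergeom_enrich: empty selected set")
        return pd.DataFrame(columns=cols)

    restricted = collection.restricted_to(universe)
    N, n = len(universe), len(selected)
    rows = []
    for pid in sorted(restricted.sets):
        members = restricted.members(pid)
        K = len(members)
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, restricted.description(pid), k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=cols[:-1])
    out["fdr"] = bh_adjust(out.set_index("pathway")["p"]).to_numpy()
    return out


def gsea_es(
    ranked: pd.Series,
    members: set[str],
    weight_exponent: float = 1.0,
) -> float:
    """Weighted Kolmogorov–Smirnov-like enrichment score.

    ``ranked`` maps feature -> ranking score, ordered from best to worst.
    The running sum increments by |score|^w / sum(|score|^w over members)
    at member positions and decrements by 1/(N-K) elsewhere; ES is the
    running sum's signed maximum deviation from zero, in [-1, 1].
    """
    if ranked.index.has_duplicates:
        raise ValueError("ranked list contains duplicate features")
    ismem = ranked.index.isin(members)
    K = int(ismem.sum())
    N = len(ranked)
    if K == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    hit_w = np.where(ismem, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        raise ValueError("all member scores are zero under this weight exponent")
    miss = 0.0 if K == N else 1.0 / (N - K)
    run = np.cumsum(hit_w / denom - np.where(ismem, 0.0, miss))
    es = float(run[np.argmax(np.abs(run))])
    return es


def gsea_permutation_p(
    ranked: pd.Series,
    members: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> tuple[float, float]:
    """Gene-label permutation p-value for the enrichment score.

    Member labels are reassigned to uniformly random positions of the
    ranked list ``n_perm`` times; p = (1 + #{|ES*| >= |ES|}) / (1 + n_perm).
    Returns (es, perm_p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es = gsea_es(ranked, members, weight_exponent)
    ismem = ranked.index.isin(members)
    K, N = int(ismem.sum()), len(ranked)
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    miss = 0.0 if K == N else 1.0 / (N - K)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.choice(N, size=K, replace=False)
        mem = np.zeros(N, dtype=bool)
        mem[idx] = True
        hit_w = np.where(mem, w, 0.0)
        denom = hit_w.sum()
        if denom == 0:
            perm_es = 0.0
        else:
            run = np.cumsum(hit_w / denom - np.where(mem, 0.0, miss))
            perm_es = float(run[np.argmax(np.abs(run))])
        if abs(perm_es) >= abs(es) - 1e-12:
            exceed += 1
    return es, (1 + exceed) / (1 + n_perm)


def gsea_table(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 200,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Pre-ranked GSEA over every set with >= ``min_overlap`` features in
    the ranked list. No multiple-testing correction is applied across sets."""
    rows = []
    universe = set(ranked.index)
    for pid in sorted(collection.sets):
        members = set(collection.members(pid)) & universe
        if len(members) < min_overlap:
            continue
        es, p = gsea_permutation_p(ranked, members, n_perm, seed, weight_exponent)
        rows.append((pid, collection.description(pid), len(members), es, p))
    return pd.DataFrame(rows, columns=["pathway", "description", "k", "es", "perm_p"])
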