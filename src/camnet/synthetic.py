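"""Synthetic multi-omics data with planted ground truth.

The study's raw omics deposit is access-restricted, so every downstream
stage is exercised on generated data that emulates the study design: a
three-group calcium gradient (T0/T2/T4 analog), n = 3 replicates for the
transcript and protein layers, n = 6 for metabolites plus pooled-QC
injections, planted log2 differential effects, pathway-module structure in
the interaction network, and intensity-dependent metabolite missingness.

Noise models per layer follow the field's conventions: overdispersed
(negative-binomial) counts for transcripts, multiplicative log-normal noise
for protein and metabolite intensities. QC injections are technical
replicates of the pooled grand mean with a small CV.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .design import SampleDesign
from .gmt import GeneSetCollection
from .matrix import OmicsMatrix, Stage

Contrast = tuple[str, str]


def feature_names(n: int, prefix: str = "F") -> list[str]:
    return [f"{prefix}{i + 1:05d}" for i in range(n)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests.

    de_features maps a contrast (test, reference) to per-feature signed
    log2 effects; module_membership assigns features to pathway modules;
    edge densities control the planted network; planted_hub_module receives
    elevated inter-module connectivity (its incident inter-module edge
    probability is multiplied by hub_factor); unstable_features are
    metabolite features planted with a high QC coefficient of variation.
    """

    de_features: dict[Contrast, dict[str, float]] = field(default_factory=dict)
    module_membership: dict[str, frozenset[str]] = field(default_factory=dict)
    intra_density: float = 0.3
    inter_density: float = 0.05
    planted_hub_module: str | None = None
    hub_factor: float = 3.0
    unstable_features: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for contrast, effects in self.de_features.items():
            zero = [f for f, e in effects.items() if e == 0]
            if zero:
                raise ValueError(f"zero effect sizes for {contrast}: {zero}")
        for d, name in ((self.intra_density, "intra"), (self.inter_density, "inter")):
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"{name}-module edge density {d} outside [0, 1]")
        if self.planted_hub_module is not None:
            pathways = set().union(*self.module_membership.values()) if self.module_membership else set()
            if self.planted_hub_module not in pathways:
                raise ValueError(
                    f"planted hub module {self.planted_hub_module!r} is not among "
                    "the pathways in module_membership"
                )
        self.module_membership = {f: frozenset(p) for f, p in self.module_membership.items()}
        self.unstable_features = frozenset(self.unstable_features)

    @property
    def all_de_features(self) -> set[str]:
        out: set[str] = set()
        for effects in self.de_features.values():
            out |= set(effects)
        return out

    def de_set(self, contrast: Contrast) -> set[str]:
        return set(self.de_features.get(contrast, {}))


def simulate_truth(
    n_features: int,
    contrasts: list[Contrast],
    n_de: int,
    effect_size: float = 2.0,
    frac_down: float = 0.5,
    n_modules: int = 8,
    module_size: int = 12,
    intra_density: float = 0.3,
    inter_density: float = 0.05,
    hub_factor: float = 3.0,
    plant_hub: bool = True,
    n_unstable: int = 0,
    de_module_weight: float = 3.0,
    prefix: str = "F",
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a ground-truth configuration: planted DE features per contrast,
    disjoint pathway modules over the first ``n_modules * module_size``
    features, and (optionally) one hub module with elevated inter-module
    connectivity.

    Hub-module members are always part of every contrast's DE set, and the
    remaining DE features are sampled with weight ``de_module_weight`` on
    module members — this is what makes the differential subnetwork carry
    the planted module structure (and the hub's extra edges) downstream.
    """
    if n_modules * module_size > n_features:
        raise ValueError("module structure does not fit into n_features")
    rng = np.random.default_rng(seed)
    feats = feature_names(n_features, prefix)

    pathways = [f"Map{i + 1:05d}" for i in range(n_modules)]
    membership: dict[str, frozenset[str]] = {}
    in_module = np.zeros(n_features, dtype=bool)
    for m, pid in enumerate(pathways):
        for i in range(m * module_size, (m + 1) * module_size):
            membership[feats[i]] = frozenset({pid})
            in_module[i] = True
    hub = pathways[int(rng.integers(n_modules))] if (plant_hub and pathways) else None
    hub_idx = (
        [i for i, f in enumerate(feats) if hub in membership.get(f, frozenset())]
        if hub
        else []
    )

    de: dict[Contrast, dict[str, float]] = {}
    for contrast in contrasts:
        size = min(n_de, n_features)
        seed_idx = hub_idx[:size]
        rest = np.setdiff1d(np.arange(n_features), seed_idx)
        weights = np.where(in_module[rest], de_module_weight, 1.0)
        weights /= weights.sum()
        fill = rng.choice(rest, size=size - len(seed_idx), replace=False, p=weights)
        chosen = np.concatenate([seed_idx, fill]).astype(int)
        signs = np.where(rng.random(len(chosen)) < frac_down, -1.0, 1.0)
        de[contrast] = {feats[i]: s * effect_size for i, s in zip(chosen, signs)}

    unstable = frozenset(
        feats[i] for i in rng.choice(n_features, size=min(n_unstable, n_features), replace=False)
    )
    return SyntheticTruth(
        de_features=de,
        module_membership=membership,
        intra_density=intra_density,
        inter_density=inter_density,
        planted_hub_module=hub,
        hub_factor=hub_factor,
        unstable_features=unstable,
    )


# ---------------------------------------------------------------------------
# design


def simulate_design(
    groups: list[str],
    reps_per_group: int,
    n_qc: int,
    layer: str,
    seed: int = 0,
) -> SampleDesign:
    """Lay out a balanced design: ``reps_per_group`` biological replicates per
    group plus ``n_qc`` pooled-QC injections (metabolite layer only)."""
    if reps_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    if n_qc < 0:
        raise ValueError("n_qc must be nonnegative")
    if n_qc > 0 and layer != "metabolite":
        raise ValueError(
            f"QC injections are pooled metabolite samples; they cannot be placed "
            f"on the {layer!r} layer"
        )
    rows = []
    for g in groups:
        for r in range(1, reps_per_group + 1):
            rows.append((f"{g}_r{r}", g, False))
    for q in range(1, n_qc + 1):
        rows.append((f"QC_{q}", "", True))
    table = pd.DataFrame(rows, columns=["sample_id", "group", "is_qc"]).set_index("sample_id")
    return SampleDesign(table, layer=layer)


# ---------------------------------------------------------------------------
# expression / intensity layers


@dataclass
class NoiseParams:
    """Layer noise settings.

    dispersion: negative-binomial dispersion a (var = mu + a mu^2), transcripts.
    cv: multiplicative log-normal coefficient of variation, protein/metabolite.
    missing_rate: overall metabolite missingness rate in [0, 1).
    qc_cv / qc_cv_unstable: CV of pooled-QC technical replicates for stable
    and planted-unstable features.
    base_log_mean, base_log_sigma: log-normal draw of per-feature baseline
    abundance.
    """

    dispersion: float = 0.1
    cv: float = 0.2
    missing_rate: float = 0.0
    qc_cv: float = 0.05
    qc_cv_unstable: float = 0.8
    base_log_mean: float = math.log(1000.0)
    base_log_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate {self.missing_rate} outside [0, 1)")


def _lognormal_noise(rng: np.random.Generator, mean: np.ndarray, cv: float | np.ndarray) -> np.ndarray:
    """Multiplicative noise with E[X] = mean and CV(X) = cv (cv = 0 is exact)."""
    cv = np.asarray(cv, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    z = rng.standard_normal(mean.shape)
    return mean * np.exp(sigma * z - sigma**2 / 2.0)


def simulate_layer(
    design: SampleDesign,
    truth: SyntheticTruth,
    n_features: int,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    prefix: str | None = None,
) -> OmicsMatrix:
    """Simulate one feature-by-sample matrix under the planted truth.

    Planted DE features differ between the contrast's test and reference
    groups by their stated log2 effect in expectation (the multiplier
    ``2**effect`` is applied to the test group's mean). QC columns are draws
    around the pooled grand mean. Metabolite matrices receive missing
    entries at ``missing_rate`` overall, preferentially at low intensity.
    """
    params = noise_params or NoiseParams()
    if n_features < len(truth.all_de_features):
        raise ValueError("n_features smaller than the number of planted DE features")
    if prefix is None:
        prefix = "M" if design.layer == "metabolite" else "F"
    rng = np.random.default_rng(seed)
    feats = feature_names(n_features, prefix)
    fidx = {f: i for i, f in enumerate(feats)}

    base = np.exp(rng.normal(params.base_log_mean, params.base_log_sigma, n_features))

    # per-group expected abundance: baseline times 2^effect for test groups
    group_means: dict[str, np.ndarray] = {g: base.copy() for g in design.groups}
    for (test, _ref), effects in truth.de_features.items():
        if test not in group_means:
            continue
        for f, eff in effects.items():
            if f in fidx:
                group_means[test][fidx[f]] *= 2.0**eff

    cols: dict[str, np.ndarray] = {}
    for g in design.groups:
        mu = group_means[g]
        for s in design.samples_in_group(g):
            if design.layer == "transcript":
                if params.dispersion > 0:
                    a = params.dispersion
                    cols[s] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mu)).astype(float)
                else:
                    cols[s] = rng.poisson(mu).astype(float)
            else:
                cols[s] = _lognormal_noise(rng, mu, params.cv)

    qc_ids = design.qc_samples
    if qc_ids:
        grand = np.mean([group_means[g] for g in design.groups], axis=0)
        cv_vec = np.full(n_features, params.qc_cv)
        unstable_idx = [fidx[f] for f in truth.unstable_features if f in fidx]
        cv_vec[unstable_idx] = params.qc_cv_unstable
        for s in qc_ids:
            cols[s] = _lognormal_noise(rng, grand, cv_vec)

    values = pd.DataFrame(cols, index=feats, columns=design.sample_ids, dtype=float)

    if design.layer == "metabolite" and params.missing_rate > 0:
        # intensity-dependent dropout: probability decreases linearly with the
        # entry's fractional rank so overall rate ~= missing_rate
        flat = values.to_numpy().ravel()
        frac_rank = (rankdata(flat) - 0.5) / flat.size
        p_miss = np.clip(2.0 * params.missing_rate * (1.0 - frac_rank), 0.0, 0.95)
        drop = rng.random(flat.size) < p_miss
        arr = flat.copy()
        arr[drop] = np.nan
        values = pd.DataFrame(
            arr.reshape(values.shape), index=values.index, columns=values.columns
        )

    return OmicsMatrix(values, layer=design.layer, stage=Stage.RAW)


# ---------------------------------------------------------------------------
# interaction network


def simulate_network(
    truth: SyntheticTruth,
    n_features: int,
    seed: int = 0,
    prefix: str = "F",
) -> tuple[nx.Graph, GeneSetCollection]:
    """Draw an undirected interaction network plus its pathway annotation.

    Each unordered feature pair receives an edge independently with
    probability ``intra_density`` if the two features share a pathway and
    ``inter_density`` otherwise; inter-module probabilities for pairs
    touching the planted hub module are multiplied by ``hub_factor``
    (capped at 1). No self-edges, no parallel edges. Edge scores mimic a
    confidence column in [0, 1].
    """
    rng = np.random.default_rng(seed)
    feats = feature_names(n_features, prefix)
    membership = {f: truth.module_membership.get(f, frozenset()) for f in feats}
    hub = truth.planted_hub_module

    g = nx.Graph()
    g.add_nodes_from(feats)
    pairs = list(itertools.combinations(feats, 2))
    draws = rng.random(len(pairs))
    scores = rng.uniform(0.15, 1.0, len(pairs))
    for (u, v), r, sc in zip(pairs, draws, scores):
        shared = bool(membership[u] & membership[v])
        if shared:
            p = truth.intra_density
        else:
            p = truth.inter_density
            if hub is not None and (hub in membership[u] or hub in membership[v]):
                p = min(1.0, p * truth.hub_factor)
        if r < p:
            g.add_edge(u, v, score=round(float(sc), 6))

    pathways: dict[str, set[str]] = {}
    for f, mods in membership.items():
        for pid in mods:
            pathways.setdefault(pid, set()).add(f)
    annotation = GeneSetCollection(
        {pid: frozenset(m) for pid, m in pathways.items()},
        {pid: f"synthetic module {pid}" for pid in pathways},
    )
    return g, annotation
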