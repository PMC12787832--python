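"""End-to-end orchestration: simulate -> preprocess -> differential ->
enrich -> network -> contract, as a configured, logged, reproducible run.

Every stage writes plain-text artifacts (TSV/GMT/JSON) plus a provenance
sidecar; a rerun with the same config and seed is byte-identical. Default
thresholds are the study's stated calling rules (|log2FC| >= 1, FDR < 0.05
for transcripts; raw p < 0.05 for proteins; VIP > 1 and p < 0.05 for
metabolites; 80 % presence; QC RSD > 30 % exclusion).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import enrichment, modules, network, preprocess, synthetic
from .design import SampleDesign
from .matrix import OmicsMatrix, Stage

logger = logging.getLogger(__name__)

Contrast = tuple[str, str]


@dataclass
class RunConfig:
    seed: int = 42
    groups: list[str] = field(default_factory=lambda: ["T0", "T2", "T4"])
    contrasts: list[Contrast] = field(
        default_factory=lambda: [("T2", "T0"), ("T4", "T0")]
    )
    # calling thresholds (the study's defaults)
    log2fc: float = 1.0
    fdr: float = 0.05
    p: float = 0.05
    vip: float = 1.0
    min_frac: float = 0.8
    max_rsd: float = 0.30
    min_score: float = 0.4
    # policies
    assignment_policy: str = "unique_lexicographic"
    equal_var: bool = False  # False = Welch, True = pooled-variance Student
    impute_scope: str = "per_feature"
    rank_by: str = "degree"
    run_gsea: bool = True
    gsea_n_perm: int = 200
    # synthetic design (desk-scale analog of the study: 3 groups, n=3
    # transcript/protein replicates, n=6 metabolite replicates + pooled QC)
    n_transcripts: int = 1200
    n_proteins: int = 600
    n_metabolites: int = 400
    reps_transcript: int = 3
    reps_protein: int = 3
    reps_metabolite: int = 6
    n_qc: int = 4
    n_de_genes: int = 120
    n_de_metabolites: int = 40
    effect_size: float = 2.0
    # NB dispersion 0.04 ~= 20 % biological CV at high abundance, matching
    # the multiplicative CV used for the protein/metabolite layers
    dispersion: float = 0.04
    cv: float = 0.2
    metabolite_cv: float = 0.2
    missing_rate: float = 0.15
    qc_cv: float = 0.05
    qc_cv_unstable: float = 0.8
    unstable_frac: float = 0.10
    n_modules: int = 8
    module_size: int = 12
    intra_density: float = 0.3
    inter_density: float = 0.05
    hub_factor: float = 3.0

    def validate(self) -> None:
        known = set(self.groups)
        for test, ref in self.contrasts:
            if test not in known or ref not in known:
                raise ValueError(
                    f"contrast {test}:{ref} references a group outside {sorted(known)}"
                )
        for name in ("log2fc", "fdr", "p", "vip", "min_frac", "max_rsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be nonnegative")
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("module structure must fit into the protein feature space")

    @property
    def thresholds(self) -> diff.Thresholds:
        return diff.Thresholds(self.log2fc, self.fdr, self.p, self.vip)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrasts" in raw:
            raw["contrasts"] = [tuple(c) for c in raw["contrasts"]]
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _contrast_tag(c: Contrast) -> str:
    return f"{c[0]}_vs_{c[1]}"


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full chain and return the run report (also written to
    ``outdir/report.json``)."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    report: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "stages": {},
        "warnings": [],
    }

    # -- 1. simulate -------------------------------------------------------
    truth_genes = synthetic.simulate_truth(
        n_features=config.n_transcripts,
        contrasts=config.contrasts,
        n_de=config.n_de_genes,
        effect_size=config.effect_size,
        n_modules=config.n_modules,
        module_size=config.module_size,
        intra_density=config.intra_density,
        inter_density=config.inter_density,
        hub_factor=config.hub_factor,
        seed=int(seeds[0]),
    )
    truth_metab = synthetic.simulate_truth(
        n_features=config.n_metabolites,
        contrasts=config.contrasts,
        n_de=config.n_de_metabolites,
        effect_size=config.effect_size,
        n_modules=0,
        module_size=0,
        plant_hub=False,
        n_unstable=int(round(config.unstable_frac * config.n_metabolites)),
        prefix="M",
        seed=int(seeds[1]),
    )

    designs = {
        "transcript": synthetic.simulate_design(
            config.groups, config.reps_transcript, 0, "transcript"
        ),
        "protein": synthetic.simulate_design(
            config.groups, config.reps_protein, 0, "protein"
        ),
        "metabolite": synthetic.simulate_design(
            config.groups, config.reps_metabolite, config.n_qc, "metabolite"
        ),
    }
    mats = {
        "transcript": synthetic.simulate_layer(
            designs["transcript"],
            truth_genes,
            config.n_transcripts,
            synthetic.NoiseParams(dispersion=config.dispersion),
            seed=int(seeds[2]),
        ),
        "protein": synthetic.simulate_layer(
            designs["protein"],
            truth_genes,
            config.n_proteins,
            synthetic.NoiseParams(cv=config.cv),
            seed=int(seeds[3]),
            prefix="F",
        ),
        "metabolite": synthetic.simulate_layer(
            designs["metabolite"],
            truth_metab,
            config.n_metabolites,
            synthetic.NoiseParams(
                cv=config.metabolite_cv,
                missing_rate=config.missing_rate,
                qc_cv=config.qc_cv,
                qc_cv_unstable=config.qc_cv_unstable,
            ),
            seed=int(seeds[4]),
        ),
    }
    net, annotation = synthetic.simulate_network(
        truth_genes, config.n_proteins, seed=int(seeds[5])
    )

    sim = out / "simulate"
    sim.mkdir(exist_ok=True)
    for layer in designs:
        designs[layer].to_tsv(sim / f"design_{layer}.tsv")
        mats[layer].to_tsv(sim / f"matrix_{layer}.tsv")
    network.write_edge_list(net, sim / "edges.tsv")
    annotation.to_gmt(sim / "kegg.gmt")
    _write_json(
        sim / "provenance.json",
        {
            "stage": "simulate",
            "planted_hub_module": truth_genes.planted_hub_module,
            "n_de": {
                _contrast_tag(c): len(v) for c, v in truth_genes.de_features.items()
            },
            "n_unstable_metabolites": len(truth_metab.unstable_features),
        },
    )
    report["stages"]["simulate"] = {
        "n_features": {layer: mats[layer].n_features for layer in mats},
        "n_samples": {layer: mats[layer].n_samples for layer in mats},
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
        "planted_hub_module": truth_genes.planted_hub_module,
    }

    # -- 2. metabolomics preprocessing --------------------------------------
    processed, prov = preprocess.run_cascade(
        mats["metabolite"],
        designs["metabolite"],
        min_frac=config.min_frac,
        max_rsd=config.max_rsd,
        impute_scope=config.impute_scope,
    )
    pre = out / "preprocess"
    pre.mkdir(exist_ok=True)
    processed.to_tsv(pre / "matrix_metabolite_logged.tsv")
    _write_json(pre / "provenance.json", {"stage": "preprocess", "cascade": prov})
    report["stages"]["preprocess"] = {
        "n_features_in": mats["metabolite"].n_features,
        "n_features_out": processed.n_features,
        "per_step": [
            {k: p[k] for k in ("operation", "n_features_in", "n_features_out")}
            for p in prov
        ],
    }

    # -- 3. differential ----------------------------------------------------
    dif = out / "differential"
    dif.mkdir(exist_ok=True)
    tables: dict[tuple[str, Contrast], diff.DifferentialTable] = {}
    for contrast in config.contrasts:
        tag = _contrast_tag(contrast)
        for layer in ("transcript", "protein"):
            t = diff.differential_table(
                mats[layer],
                designs[layer],
                contrast,
                equal_var=config.equal_var,
                thresholds=config.thresholds,
            )
            tables[(layer, contrast)] = t
            t.to_tsv(dif / f"{layer}_{tag}.tsv")
        vip = preprocess.pls_vip(processed, designs["metabolite"], contrast)
        t = diff.differential_table(
            processed,
            designs["metabolite"],
            contrast,
            vip=vip.vip,
            thresholds=config.thresholds,
        )
        tables[("metabolite", contrast)] = t
        t.to_tsv(dif / f"metabolite_{tag}.tsv")
    report["stages"]["differential"] = {
        _contrast_tag(c): {
            layer: {
                "up": len(tables[(layer, c)].up),
                "down": len(tables[(layer, c)].down),
                "total": len(tables[(layer, c)].table),
            }
            for layer in ("transcript", "protein", "metabolite")
        }
        for c in config.contrasts
    }
    _write_json(
        dif / "provenance.json",
        {"stage": "differential", "thresholds": asdict(config.thresholds)},
    )

    # -- 4. enrichment ------------------------------------------------------
    enr = out / "enrich"
    enr.mkdir(exist_ok=True)
    enrich_counts = {}
    for contrast in config.contrasts:
        tag = _contrast_tag(contrast)
        t = tables[("transcript", contrast)]
        universe = set(t.table.index)
        ora = enrichment.hypergeom_enrich(t.significant, universe, annotation)
        ora.to_csv(enr / f"ora_transcript_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
        row = {"ora_sets_tested": len(ora)}
        if config.run_gsea:
            ranked = t.table["log2fc"].sort_values(ascending=False)
            gsea = enrichment.gsea_table(
                ranked, annotation, n_perm=config.gsea_n_perm, seed=int(seeds[6])
            )
            gsea.to_csv(enr / f"gsea_transcript_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
            row["gsea_sets_tested"] = len(gsea)
        enrich_counts[tag] = row
    report["stages"]["enrich"] = enrich_counts
    _write_json(enr / "provenance.json", {"stage": "enrich", "n_perm": config.gsea_n_perm})

    # -- 5 & 6. PPI subnetwork and module contraction -----------------------
    netdir = out / "network"
    netdir.mkdir(exist_ok=True)
    moddir = out / "contract"
    moddir.mkdir(exist_ok=True)
    net_counts, mod_counts = {}, {}
    for contrast in config.contrasts:
        tag = _contrast_tag(contrast)
        deg = tables[("transcript", contrast)].significant
        dep = tables[("protein", contrast)].significant
        concordant, unmapped = network.concordant_nodes(deg, dep)
        sub = network.differential_subnetwork(net, deg, dep, config.min_score)
        network.write_edge_list(sub, netdir / f"subnet_{tag}.tsv")
        pd.DataFrame(
            sorted(network.node_degree(sub).items()), columns=["node", "degree"]
        ).to_csv(netdir / f"degree_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame({"node": sorted(concordant)}).to_csv(
            netdir / f"concordant_{tag}.tsv", sep="\t", index=False
        )
        net_counts[tag] = {
            "nodes": sub.number_of_nodes(),
            "edges": sub.number_of_edges(),
            "concordant": len(concordant),
            "unmapped": len(unmapped),
        }

        assignment = modules.assign_modules(
            set(sub.nodes), annotation, config.assignment_policy
        )
        mn = modules.contract(sub, assignment)
        pd.DataFrame(
            [(a, b, w) for (a, b), w in sorted(mn.edges.items())],
            columns=["module_a", "module_b", "weight"],
        ).to_csv(moddir / f"module_edges_{tag}.tsv", sep="\t", index=False)
        mn.degree_table().to_csv(moddir / f"module_degree_{tag}.tsv", sep="\t", index=False)
        ranking = modules.rank_modules(mn, by=config.rank_by)
        mod_counts[tag] = {
            "modules": len(mn.modules),
            "module_edges": len(mn.edges),
            "dropped_edges": mn.dropped_edges,
            "unassigned_nodes": len(assignment.unassigned),
            "top_modules": [list(r) for r in ranking[:5]],
        }
    report["stages"]["network"] = net_counts
    report["stages"]["contract"] = mod_counts
    _write_json(netdir / "provenance.json", {"stage": "network", "min_score": config.min_score})
    _write_json(
        moddir / "provenance.json",
        {"stage": "contract", "policy": config.assignment_policy, "rank_by": config.rank_by},
    )

    _write_json(out / "report.json", report)
    return report
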