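"""The end-to-end repositioning run: simulate → signatures → connectivity →
concordance → percentile ranking → GSEA validation (→ regulators).

A run is a pure function of its :class:`RunConfig`: every stochastic stage
receives an explicit seed derived from the run seed, the config is serialized
verbatim into the output directory, and the manifest records row counts and
content digests of every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import concordant_inverse, percentile_rank, score_library
from .errors import ConfigurationError, PipelineError
from .gsea import signature_direction_panel
from .io import (
    read_edge_list,
    read_gene_set_library,
    write_gene_set_pair,
    write_ground_truth,
    write_rnk,
)
from .regulators import expression_to_kinases
from .signatures import (
    differential_signature,
    ranked_list,
    signature_gene_sets,
)
from .synthetic import (
    SyntheticStudyConfig,
    generate_compound_library,
    generate_disease_library,
    ground_truth,
)

DEFAULT_N_PERM = 100_000


@dataclass
class RunConfig:
    """Configuration for one reproducible pipeline run.

    ``n_perm`` is the connectivity permutation depth; with the shared null
    the attainable BH q floor over m pairs with k top hits is
    ``m / (k · (n_perm + 1))``, so calling FDR < 0.01 over thousands of pairs
    needs a deep null (the 100,000 default).
    """

    seed: int
    synthetic: SyntheticStudyConfig
    n_top: int | None = 100
    q_cutoff: float | None = None
    n_perm: int = DEFAULT_N_PERM
    q_connectivity: float = 0.01
    q_gsea: float = 0.05
    deg_q: float = 0.1
    expected_conditions: int = 4
    gsea_exponent: float = 1.0
    gsea_n_perm: int = 1000
    tf_library: str | None = None
    ppi_edges: str | None = None
    kinase_library: str | None = None
    write_signature_tables: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ConfigurationError("config must state an explicit seed")
        synth = dict(raw.pop("synthetic", {}))
        synth.setdefault("seed", raw["seed"])
        return cls(synthetic=SyntheticStudyConfig(**synth), **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "synthetic"}
        out["synthetic"] = self.synthetic.to_dict()
        return out


@dataclass
class RunResult:
    truth: object
    connectivity: pd.DataFrame
    concordance: pd.DataFrame
    percentiles: pd.DataFrame
    gsea: pd.DataFrame
    regulators: dict | None
    manifest: dict
    outdir: Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> RunResult:
    """Execute every stage and write results + provenance manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # --- simulate
    truth = ground_truth(config.synthetic)
    write_ground_truth(outdir / "ground_truth.tsv", truth)

    # --- drug signatures and tag sets
    drug_sets = {}
    drug_signatures = {}
    try:
        for key, treated, control in generate_compound_library(config.synthetic):
            sig = differential_signature(treated, control, origin=key.label())
            drug_signatures[key] = sig
            drug_sets[key] = signature_gene_sets(
                sig, n_top=config.n_top, q_cutoff=config.q_cutoff
            )
    except Exception as exc:
        raise PipelineError("signature", str(exc)) from exc
    gmt_dir = outdir / "tag_sets"
    gmt_dir.mkdir(exist_ok=True)
    for key, pair in drug_sets.items():
        write_gene_set_pair(gmt_dir / f"{key.label().replace('|', '_')}.gmt", pair)

    # --- disease ranked lists
    disease_ranked = {}
    rnk_dir = outdir / "disease_rnk"
    rnk_dir.mkdir(exist_ok=True)
    try:
        for did, case, control in generate_disease_library(config.synthetic, truth):
            sig = differential_signature(case, control, origin=did)
            disease_ranked[did] = ranked_list(sig)
            write_rnk(rnk_dir / f"{did}.rnk", disease_ranked[did])
    except Exception as exc:
        raise PipelineError("disease", str(exc)) from exc

    # --- connectivity + FDR
    try:
        conn = score_library(
            drug_sets, disease_ranked, n_perm=config.n_perm, seed=config.seed
        )
    except Exception as exc:
        raise PipelineError("connect", str(exc)) from exc
    conn.to_csv(outdir / "connectivity.csv", index=False)

    # --- cross-condition concordance
    calls = []
    scored = conn[conn["flag"] == ""]
    for (compound, disease), sub in scored.groupby(["compound", "disease"]):
        if len(sub) < config.expected_conditions:
            continue
        call = concordant_inverse(
            sub,
            q_threshold=config.q_connectivity,
            expected_conditions=config.expected_conditions,
        )
        calls.append(
            {
                "compound": compound,
                "disease": disease,
                "inverse_concordant": call.inverse_concordant,
                "max_q": sub["q"].max(),
                "max_score": sub["score"].max(),
            }
        )
    concordance = pd.DataFrame(calls)
    concordance.to_csv(outdir / "concordance.csv", index=False)

    # --- percentile ranking (compound-level score = mean across conditions)
    pct_rows = []
    for disease, sub in scored.groupby("disease"):
        means = sub.groupby("compound")["score"].mean()
        for compound, value in means.items():
            pct_rows.append(
                {
                    "disease": disease,
                    "compound": compound,
                    "mean_score": value,
                    "percentile": percentile_rank(value, means.to_numpy()),
                }
            )
    percentiles = pd.DataFrame(pct_rows)
    percentiles.to_csv(outdir / "percentiles.csv", index=False)

    # --- GSEA validation panels for inverse-concordant compounds
    panels = []
    hits = (
        concordance[concordance["inverse_concordant"]]["compound"].unique()
        if len(concordance)
        else []
    )
    for i, compound in enumerate(sorted(hits)):
        for key, pair in drug_sets.items():
            if key.compound != compound:
                continue
            panel = signature_direction_panel(
                pair,
                disease_ranked,
                exponent=config.gsea_exponent,
                n_perm=config.gsea_n_perm,
                seed=config.seed + 1000 + i,
                q_threshold=config.q_gsea,
            )
            panel.insert(0, "condition", key.label())
            panels.append(panel)
    gsea_table = pd.concat(panels, ignore_index=True) if panels else pd.DataFrame()
    gsea_table.to_csv(outdir / "gsea_panel.csv", index=False)

    # --- regulators (only when libraries are configured)
    reg_result = None
    if config.tf_library and config.ppi_edges and config.kinase_library:
        planted_key = next(
            k
            for k in drug_sets
            if k.compound == truth.planted_compound_id and k.dose == "high"
        )
        sig = drug_signatures[planted_key]
        degs = list(sig.significant_genes(config.deg_q))
        try:
            reg_result = expression_to_kinases(
                degs,
                read_gene_set_library(config.tf_library),
                read_edge_list(config.ppi_edges),
                read_gene_set_library(config.kinase_library),
            )
        except Exception as exc:
            raise PipelineError("regulators", str(exc)) from exc
        reg_result["tf"].to_csv(outdir / "regulators_tf.csv", index=False)
        reg_result["kinase"].to_csv(outdir / "regulators_kinase.csv", index=False)

    # --- manifest
    outputs = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": {"name": "sigreverse", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config.to_dict(),
        "planted_compound": truth.planted_compound_id,
        "target_disease": truth.target_disease_id,
        "row_counts": {
            "connectivity": int(len(conn)),
            "concordance": int(len(concordance)),
            "percentiles": int(len(percentiles)),
            "gsea_panel": int(len(gsea_table)),
        },
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return RunResult(
        truth=truth,
        connectivity=conn,
        concordance=concordance,
        percentiles=percentiles,
        gsea=gsea_table,
        regulators=reg_result,
        manifest=manifest,
        outdir=outdir,
    )
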