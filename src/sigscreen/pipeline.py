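"""End-to-end screen orchestration with config, seeding and a run manifest.

Stages run in a fixed order: QC -> quantile normalization -> variance filter
-> module detection -> module-trait association -> differential expression /
signature -> connectivity scoring -> compound ranking.  Every stage writes
its output under the run directory and the manifest records the config hash,
derived seeds and a checksum per artifact, so identical (config, seed) pairs
produce bit-identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import connectivity as conn
from . import expression as expr
from . import network as net
from . import signature as sigmod
from . import simulate as sim
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full screen run needs, serializable as YAML."""

    seed: int = 0
    simulate: bool = True
    expression_path: str | None = None
    annotation_path: str | None = None
    compendium_ranks_path: str | None = None
    compendium_meta_path: str | None = None
    qc_k: float = 3.0
    quantile_normalize: bool = True
    top_n_genes: int = 10000
    network: net.NetworkParams = field(default_factory=net.NetworkParams)
    alpha: float = 0.005
    permutations: int = 1000
    expression_cfg: sim.SyntheticExpressionConfig = field(
        default_factory=sim.SyntheticExpressionConfig
    )
    compendium_cfg: sim.SyntheticCompendiumConfig = field(
        default_factory=sim.SyntheticCompendiumConfig
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(klass, payload, where):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(payload) - names
            if unknown:
                raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
            return payload

        payload = build(cls, dict(data), "pipeline config")
        for key, klass in (
            ("network", net.NetworkParams),
            ("expression_cfg", sim.SyntheticExpressionConfig),
            ("compendium_cfg", sim.SyntheticCompendiumConfig),
        ):
            if key in payload and isinstance(payload[key], dict):
                sub = build(klass, payload[key], key)
                payload[key] = klass(**sub)
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one by stage-name hashing."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_screen(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full screen; returns the manifest (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        # --- input ---------------------------------------------------------
        stage = "input"
        if cfg.simulate:
            ecfg = dataclasses.replace(
                cfg.expression_cfg, seed=stage_seed(cfg.seed, "expression")
            )
            ds, truth = sim.generate_expression_dataset(ecfg)
        else:
            if not cfg.expression_path or not cfg.annotation_path:
                raise ConfigError("expression_path and annotation_path required "
                                  "when simulate is false")
            ds = expr.read_expression_matrix(cfg.expression_path, cfg.annotation_path)
            truth = None
        expr.write_expression_matrix(ds, out / "expression.tsv", out / "annotation.tsv")
        artifacts["expression"] = out / "expression.tsv"
        artifacts["annotation"] = out / "annotation.tsv"
        if truth is not None:
            (out / "ground_truth.json").write_text(truth.to_json())
            artifacts["ground_truth"] = out / "ground_truth.json"

        # --- QC ------------------------------------------------------------
        stage = "qc"
        qc = expr.sample_qc(ds, k=cfg.qc_k)
        (out / "qc_report.json").write_text(qc.to_json())
        artifacts["qc_report"] = out / "qc_report.json"
        if qc.outliers:
            logger.info("dropping QC outliers: %s", sorted(qc.outliers))
            ds = ds.drop_samples(qc.outliers)

        # --- normalize + filter --------------------------------------------
        stage = "normalize"
        if cfg.quantile_normalize:
            ds = expr.quantile_normalize(ds)
        stage = "filter"
        ds = expr.select_most_variable_genes(ds, n=cfg.top_n_genes)

        # --- modules --------------------------------------------------------
        stage = "modules"
        decomp = net.detect_modules(ds, cfg.network)
        assign = "\n".join(f"{g}\t{m}" for g, m in
                           sorted(decomp.assignment.items())) + "\n"
        (out / "modules.tsv").write_text("gene\tmodule\n" + assign)
        artifacts["modules"] = out / "modules.tsv"
        decomp.eigengene_frame().to_csv(out / "eigengenes.tsv", sep="\t",
                                        index_label="module")
        artifacts["eigengenes"] = out / "eigengenes.tsv"

        stage = "module_trait"
        trait = (ds.group_vector() != "vehicle").astype(float).to_numpy()
        if decomp.modules:
            mt = net.module_trait_relationships(decomp, trait)
            mt.to_csv(out / "module_trait.tsv", sep="\t")
            artifacts["module_trait"] = out / "module_trait.tsv"

        # --- signature ------------------------------------------------------
        stage = "signature"
        de = sigmod.differential_expression(ds)
        de.with_direction(cfg.alpha).to_csv(out / "differential_expression.tsv",
                                            sep="\t", index_label="gene")
        artifacts["differential_expression"] = out / "differential_expression.tsv"
        sig = sigmod.build_query_signature(de, alpha=cfg.alpha)
        sigmod.write_signature(sig, out / "signature_up.grp", out / "signature_down.grp")
        artifacts["signature_up"] = out / "signature_up.grp"
        artifacts["signature_down"] = out / "signature_down.grp"

        # --- compendium -----------------------------------------------------
        stage = "compendium"
        if cfg.simulate:
            ccfg = dataclasses.replace(
                cfg.compendium_cfg,
                universe=cfg.compendium_cfg.universe or list(ds.genes),
                seed=stage_seed(cfg.seed, "compendium"),
            )
            compendium = sim.generate_reference_compendium(ccfg, truth or sim.GroundTruth())
        else:
            if not cfg.compendium_ranks_path or not cfg.compendium_meta_path:
                raise ConfigError("compendium paths required when simulate is false")
            compendium = conn.read_compendium(cfg.compendium_ranks_path,
                                              cfg.compendium_meta_path)

        # --- connectivity ---------------------------------------------------
        stage = "connectivity"
        report = conn.score_compendium(
            sig, compendium, B=cfg.permutations,
            seed=stage_seed(cfg.seed, "permutation"),
        )
        report.instances.to_csv(out / "instances.tsv", sep="\t", index=False)
        artifacts["instances"] = out / "instances.tsv"
        report.compounds.to_csv(out / "compounds.tsv", sep="\t")
        artifacts["compounds"] = out / "compounds.tsv"
        (out / "report.json").write_text(report.to_json())
        artifacts["report"] = out / "report.json"
    except Exception as e:
        raise type(e)(f"[stage: {stage}] {e}") from e

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("expression", "compendium", "permutation")},
        "artifacts": {k: {"path": str(v), "sha256": _checksum(v)}
                      for k, v in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
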