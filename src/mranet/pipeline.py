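"""Config-driven orchestration of the full master-regulator workflow.

One run takes a reference cohort (full cohort -> network ``tn1``; a sample
subset -> network ``tn2``), two case-control cohorts (-> signatures
``sig1`` and ``sig2``), infers relevance and DPI networks, extracts signed
regulons, runs one-tailed and two-tailed enrichment for every
network x signature combination, and calls consensus master regulators.
All intermediate artifacts are written as plain-text tables and a JSON
manifest records every parameter, seed, stage count and output checksum,
so a run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from ._seeds import child_seed
from .enrich import (
    ConsensusReport,
    consensus,
    mra,
    two_tailed_mra,
    write_records_tsv,
)
from .exceptions import InvalidParameterError, PipelineStageError
from .expression import ExpressionMatrix, read_expression, read_tf_list
from .mi import MIEstimatorConfig
from .network import (
    apply_dpi,
    bootstrap_consensus,
    filter_probes_cv,
    permutation_threshold,
)
from .regulons import (
    build_association_map,
    extract_regulons,
    write_regulons_gmt,
    write_regulons_tsv,
)
from .signature import compute_signature
from .simulate import (
    PerturbationSpec,
    make_truth_network,
    simulate_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All parameters of one pipeline run.

    ``mode`` is ``"simulate"`` (cohorts drawn from the synthetic generator)
    or ``"paths"`` (user-supplied TSV matrices).  Defaults follow the
    reference analysis where it states values (1000 bootstraps, DPI
    tolerance 0, 1000 enrichment permutations) and this package's
    documented decisions elsewhere.
    """

    mode: str = "simulate"
    seed: int = 0
    out_dir: str = "mranet_run"

    # simulation-mode parameters
    sim: dict = field(
        default_factory=lambda: {
            "n_tf": 10,
            "targets_per_tf": 20,
            "frac_negative": 0.4,
            "n_decoys": 400,
            "shared_target_rate": 0.0,
            "effect_weight": 1.0,
            "noise_sd": 0.5,
            "n_reference": 269,
            "subsample_size": 180,
            "perturbed_tf": "TF000",
            "direction": "repressed",
            "activity_shift": 1.5,
            "cohort1": {"n_case": 5, "n_control": 6},
            "cohort2": {"n_case": 30, "n_control": 31},
        }
    )

    # path-mode inputs
    paths: dict = field(
        default_factory=lambda: {
            "reference_expr": "",
            "tf_list": "",
            "subsample_ids": "",
            "cohort1_expr": "",
            "cohort1_labels": "",
            "cohort2_expr": "",
            "cohort2_labels": "",
        }
    )

    # network inference
    network: dict = field(
        default_factory=lambda: {
            "keep_fraction": 1.0,
            "n_bins": "auto",
            "n_perm": 1000,
            "alpha": 0.01,
            "n_boot": 1000,
            "consensus_fraction": 0.95,
            "tolerance": 0.0,
        }
    )

    # regulon extraction
    regulon: dict = field(default_factory=lambda: {"min_size": 15})

    # enrichment
    enrichment: dict = field(
        default_factory=lambda: {
            "n_perm": 1000,
            "alpha": 0.05,
            "alpha_strict": 0.001,
            "min_tail": 5,
            "exponent": 1.0,
            "two_tailed_on_significant": True,
        }
    )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Fail fast before any stage runs."""
        if self.mode not in ("simulate", "paths"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.mode == "paths":
            for key in ("reference_expr", "tf_list", "cohort1_expr",
                        "cohort1_labels", "cohort2_expr", "cohort2_labels"):
                p = self.paths.get(key, "")
                if not p or not Path(p).exists():
                    raise InvalidParameterError(
                        f"input file for {key!r} missing: {p!r}"
                    )
            sub = self.paths.get("subsample_ids", "")
            if sub and not Path(sub).exists():
                raise InvalidParameterError(f"subsample id file missing: {sub!r}")
        net = self.network
        if not (0.0 < net["keep_fraction"] <= 1.0):
            raise InvalidParameterError("network.keep_fraction must lie in (0, 1]")
        if net["n_perm"] < 100:
            raise InvalidParameterError("network.n_perm must be >= 100")
        if not (0.0 < net["alpha"] < 1.0):
            raise InvalidParameterError("network.alpha must lie in (0, 1)")
        if net["n_boot"] < 1:
            raise InvalidParameterError("network.n_boot must be >= 1")
        if not (0.0 < net["consensus_fraction"] <= 1.0):
            raise InvalidParameterError("network.consensus_fraction must lie in (0, 1]")
        if net["tolerance"] < 0:
            raise InvalidParameterError("network.tolerance must be >= 0")
        if self.enrichment["n_perm"] < 100:
            raise InvalidParameterError("enrichment.n_perm must be >= 100")
        if self.regulon["min_size"] < 1:
            raise InvalidParameterError("regulon.min_size must be >= 1")
        MIEstimatorConfig(net["n_bins"])  # raises on bad bin spec

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise InvalidParameterError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                merged = dict(current)
                for k, v in value.items():
                    if isinstance(merged.get(k), dict) and isinstance(v, dict):
                        merged[k] = {**merged[k], **v}
                    else:
                        merged[k] = v
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass
class PipelineResult:
    consensus: ConsensusReport
    manifest: dict
    out_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulated_inputs(cfg: RunConfig, out: Path):
    s = cfg.sim
    truth = make_truth_network(
        n_tf=s["n_tf"],
        targets_per_tf=s["targets_per_tf"],
        frac_negative=s["frac_negative"],
        n_decoys=s["n_decoys"],
        shared_target_rate=s["shared_target_rate"],
        effect_weight=s["effect_weight"],
        seed=child_seed(cfg.seed, "truth"),
    )
    truth.write_tsv(out / "truth.tsv", out / "truth.json")
    reference = simulate_cohort(
        truth, s["n_reference"], s["noise_sd"], seed=child_seed(cfg.seed, "reference")
    )
    reference.write_tsv(out / "reference_expr.tsv")
    perturb = PerturbationSpec(s["perturbed_tf"], s["direction"], s["activity_shift"])
    cohorts = {}
    for name in ("cohort1", "cohort2"):
        cc = s[name]
        n_case, n_ctrl = cc["n_case"], cc["n_control"]
        cohorts[name] = simulate_cohort(
            truth,
            n_case + n_ctrl,
            s["noise_sd"],
            perturbation=perturb,
            n_case=n_case,
            seed=child_seed(cfg.seed, name),
        )
        cohorts[name].write_tsv(
            out / f"{name}_expr.tsv", out / f"{name}_labels.tsv"
        )
    if s["subsample_size"] >= s["n_reference"]:
        raise InvalidParameterError("subsample_size must be < n_reference")
    # subsample analog of the "adult only" network: the tail of the cohort
    sub_ids = reference.sample_ids[-s["subsample_size"]:]
    return truth.tf_ids, reference, sub_ids, cohorts["cohort1"], cohorts["cohort2"]


def _loaded_inputs(cfg: RunConfig):
    p = cfg.paths
    reference = read_expression(p["reference_expr"])
    tf_ids = read_tf_list(p["tf_list"])
    if p.get("subsample_ids"):
        sub_ids = [
            s.strip()
            for s in Path(p["subsample_ids"]).read_text().splitlines()
            if s.strip()
        ]
    else:
        sub_ids = reference.sample_ids[len(reference.sample_ids) // 3 :]
    c1 = read_expression(p["cohort1_expr"], p["cohort1_labels"])
    c2 = read_expression(p["cohort2_expr"], p["cohort2_labels"])
    return tf_ids, reference, sub_ids, c1, c2


def _infer_network(
    cfg: RunConfig, expr: ExpressionMatrix, tf_ids: list[str], net_id: str, out: Path
):
    netp = cfg.network
    mi_cfg = MIEstimatorConfig(netp["n_bins"])
    filtered = filter_probes_cv(expr, netp["keep_fraction"], tf_ids)
    thr = permutation_threshold(
        filtered,
        tf_ids,
        mi_cfg,
        n_perm=netp["n_perm"],
        alpha=netp["alpha"],
        seed=child_seed(cfg.seed, "threshold", net_id),
    )
    relevance = bootstrap_consensus(
        filtered,
        tf_ids,
        mi_cfg,
        threshold=thr,
        n_boot=netp["n_boot"],
        consensus_fraction=netp["consensus_fraction"],
        seed=child_seed(cfg.seed, "bootstrap", net_id),
        null_alpha=netp["alpha"],
    )
    dpi = apply_dpi(relevance, netp["tolerance"])
    relevance.write_tsv(out / f"{net_id}_relevance.tsv")
    dpi.write_tsv(out / f"{net_id}_dpi.tsv")
    regs = extract_regulons(dpi, filtered, cfg.regulon["min_size"])
    write_regulons_tsv(regs, out / f"{net_id}_regulons.tsv")
    write_regulons_gmt(regs, out / f"{net_id}_regulons.gmt")
    if regs:
        build_association_map(regs).write_tsv(out / f"{net_id}_association_map.tsv")
    counts = {
        "genes_after_cv": filtered.n_genes,
        "mi_threshold": thr,
        "relevance_edges": relevance.n_edges,
        "dpi_edges": dpi.n_edges,
        "regulons": len(regs),
    }
    logger.info("network %s: %s", net_id, counts)
    return regs, counts


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow and write all artifacts to ``out_dir``.

    Any stage failure aborts with the stage name; partial outputs are kept
    alongside a ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    stage_counts: dict[str, Any] = {}
    try:
        stage = "inputs"
        if config.mode == "simulate":
            tf_ids, reference, sub_ids, c1, c2 = _simulated_inputs(config, out)
        else:
            tf_ids, reference, sub_ids, c1, c2 = _loaded_inputs(config)
        (out / "tn2_sample_ids.txt").write_text("".join(f"{s}\n" for s in sub_ids))

        stage = "networks"
        regulon_sets = {}
        regulon_sets["tn1"], stage_counts["tn1"] = _infer_network(
            config, reference, tf_ids, "tn1", out
        )
        regulon_sets["tn2"], stage_counts["tn2"] = _infer_network(
            config, reference.subset_samples(sub_ids), tf_ids, "tn2", out
        )

        stage = "signatures"
        signatures = {"sig1": compute_signature(c1), "sig2": compute_signature(c2)}
        for sid, sig in signatures.items():
            sig.write_tsv(out / f"{sid}.tsv")

        stage = "enrichment"
        enr = config.enrichment
        all_records = []
        for net_id in ("tn1", "tn2"):
            for sig_id in ("sig1", "sig2"):
                recs = mra(
                    regulon_sets[net_id],
                    signatures[sig_id],
                    n_perm=enr["n_perm"],
                    alpha=enr["alpha"],
                    seed=child_seed(config.seed, "mra", net_id, sig_id),
                    network_id=net_id,
                    signature_id=sig_id,
                    exponent=enr["exponent"],
                )
                write_records_tsv(recs, out / f"mra_{net_id}_{sig_id}.tsv")
                all_records.extend(recs)
                if enr["two_tailed_on_significant"]:
                    chosen = {
                        r.tf for r in recs if r.p_adj <= enr["alpha"]
                    }
                    regs2 = [r for r in regulon_sets[net_id] if r.tf in chosen]
                else:
                    regs2 = list(regulon_sets[net_id])
                recs2 = two_tailed_mra(
                    regs2,
                    signatures[sig_id],
                    n_perm=enr["n_perm"],
                    alpha=enr["alpha"],
                    min_tail=enr["min_tail"],
                    seed=child_seed(config.seed, "gsea2", net_id, sig_id),
                    network_id=net_id,
                    signature_id=sig_id,
                    exponent=enr["exponent"],
                )
                write_records_tsv(recs2, out / f"gsea2_{net_id}_{sig_id}.tsv")
                stage_counts[f"records_{net_id}_{sig_id}"] = {
                    "mra": len(recs),
                    "two_tailed": len(recs2),
                }

        stage = "consensus"
        report = consensus(all_records, enr["alpha"], enr["alpha_strict"])
        report.write_tsv(out / "consensus.tsv")
        report.write_json(out / "consensus.json")
    except Exception as exc:  # noqa: BLE001 - annotate stage, keep partial output
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "manifest"
    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "package": "mranet",
        "version": __version__,
        "config": config.to_dict(),
        "stage_counts": stage_counts,
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(report, manifest, out)


def run_from_manifest(
    manifest_path: str | Path, out_dir: str | Path | None = None
) -> PipelineResult:
    """Re-execute a run exactly as recorded in its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg = RunConfig.from_dict(manifest["config"])
    if out_dir is not None:
        cfg.out_dir = str(out_dir)
    return run_pipeline(cfg)
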