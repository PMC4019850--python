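"""End-to-end orchestration: enrichment -> interactome -> pathway labels ->
complex evidence -> substrate inference, with a JSON run manifest and a
human-readable report.

Outputs are deterministic: two runs of the same configuration on the same
inputs produce byte-identical files (the manifest records a configuration
hash, not timestamps).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .inference import (
    InferenceConfig,
    infer_substrates,
    write_accepted_graphml,
    write_hypotheses_tsv,
)
from .interactome import (
    assemble_interactome,
    literature_overlap_fraction,
    prey_complex_components,
    write_network_graphml,
    write_network_tsv,
)
from .io import InputBundle, read_bundle
from .pathways import (
    assign_bait_label,
    enrich_pathways,
    write_enrichment_results_tsv,
)
from .silac import call_enrichment, write_enrichment_tsv
from .types import EnrichmentThresholds, ValidationError

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serializable to/from YAML."""

    input_dir: str
    output_dir: str
    min_unique_peptides: int = 2
    min_ratio: float = 1.9
    max_sig_b: float = 0.1
    bin_size: int = 300
    alpha: float = 0.005
    mode: str = "permissive"
    max_pathway_depth: int = 4
    require_all_readouts: bool = True
    include_experimental_in_complexes: bool = False
    seed: int = 0
    dialect: dict[str, str] = field(default_factory=dict)

    @property
    def thresholds(self) -> EnrichmentThresholds:
        return EnrichmentThresholds(
            min_unique_peptides=self.min_unique_peptides,
            min_ratio=self.min_ratio,
            max_sig_b=self.max_sig_b,
            bin_size=self.bin_size,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    def content_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


_REQUIRED_FILES = {
    "silac_enrichment": ["protein_groups"],
    "interactome": ["literature_ppi.tsv"],
    "substrate_inference": [
        "pathway_edges.tsv", "pathway_roles.tsv", "readouts.txt",
        "phosphosites.tsv", "phosphatases.tsv",
        # rule 5 cannot be evaluated without the siRNA phenotype table
        "phenotypes.tsv",
    ],
}


def _validate_inputs(input_dir: Path) -> None:
    for stage, names in _REQUIRED_FILES.items():
        for name in names:
            if not (input_dir / name).exists():
                hint = (" (filter rule 5, phenotype consistency, needs it)"
                        if name == "phenotypes.tsv" else "")
                raise PipelineError(
                    f"stage {stage}: missing required input "
                    f"{input_dir / name}{hint}"
                )


def run_pipeline(cfg: RunConfig,
                 bundle: Optional[InputBundle] = None) -> Path:
    """Run all stages; returns the artifact directory.

    Stage outputs: ``enrichment/<bait>.tsv``, ``network.tsv`` +
    ``network.graphml``, ``pathways/<bait>.tsv`` + ``pathway_labels.tsv``,
    ``complexes.tsv``, ``hypotheses.tsv`` + ``accepted.graphml`` and
    ``manifest.json``. A failing stage renames its partial outputs to
    ``*.partial`` and aborts with the stage name.
    """
    input_dir, out = Path(cfg.input_dir), Path(cfg.output_dir)
    _validate_inputs(input_dir)
    if bundle is None:
        bundle = read_bundle(input_dir, cfg.dialect or None)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage 1: SILAC enrichment ---------------------------------------
    stage_files: list[Path] = []
    try:
        per_bait_calls = {}
        enr_dir = out / "enrichment"
        enr_dir.mkdir(exist_ok=True)
        for bait, groups in sorted(bundle.protein_groups.items()):
            calls = call_enrichment(groups, cfg.thresholds)
            per_bait_calls[bait] = calls
            path = enr_dir / f"{bait}.tsv"
            stage_files.append(path)
            write_enrichment_tsv(calls, path)
            counts[f"enriched:{bait}"] = sum(c.enriched for c in calls)
        counts["baits"] = len(per_bait_calls)
    except Exception as exc:
        _mark_partial(stage_files)
        raise PipelineError(f"stage silac_enrichment: {exc}") from exc

    # --- stage 2: interactome assembly ------------------------------------
    stage_files = [out / "network.tsv", out / "network.graphml"]
    try:
        net = assemble_interactome(per_bait_calls, bundle.literature)
        write_network_tsv(net, stage_files[0])
        write_network_graphml(net, stage_files[1])
        counts["network_nodes"] = len(net.nodes)
        counts["network_edges"] = net.graph.number_of_edges()
        try:
            overlap = literature_overlap_fraction(net)
        except ValidationError:
            overlap = float("nan")
        counts["literature_overlap_pct"] = round(100 * overlap, 3)
    except PipelineError:
        raise
    except Exception as exc:
        _mark_partial(stage_files)
        raise PipelineError(f"stage interactome: {exc}") from exc

    # --- stage 3: pathway enrichment --------------------------------------
    stage_files = []
    labels: dict[str, Optional[str]] = {}
    try:
        pw_dir = out / "pathways"
        pw_dir.mkdir(exist_ok=True)
        background = set(net.nodes)
        for aset in bundle.annotation_sets:
            background |= set(aset.members)
        for bait in sorted(bundle.protein_groups):
            preys = net.preys_of(bait)
            results = enrich_pathways(preys, bundle.annotation_sets,
                                      background, bait=bait)
            path = pw_dir / f"{bait}.tsv"
            stage_files.append(path)
            write_enrichment_results_tsv(results, path)
            labels[bait] = assign_bait_label(results, cfg.alpha)
        label_path = out / "pathway_labels.tsv"
        stage_files.append(label_path)
        with open(label_path, "w", newline="") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            w.writerow(["bait", "label"])
            for bait in sorted(labels):
                w.writerow([bait, labels[bait] or ""])
        counts["labeled_baits"] = sum(1 for v in labels.values() if v)
    except Exception as exc:
        _mark_partial(stage_files)
        raise PipelineError(f"stage pathway_enrichment: {exc}") from exc

    # --- stage 4: complex evidence among preys -----------------------------
    stage_files = [out / "complexes.tsv"]
    try:
        with open(stage_files[0], "w", newline="") as handle:
            w = csv.writer(handle, delimiter="\t", lineterminator="\n")
            w.writerow(["bait", "component_size", "members"])
            n_with = 0
            for bait in sorted(bundle.protein_groups):
                comps = prey_complex_components(
                    net, bait, bundle.literature,
                    include_experimental=cfg.include_experimental_in_complexes,
                )
                n_with += bool(comps)
                for comp in comps:
                    w.writerow([bait, len(comp), ";".join(sorted(comp))])
        counts["baits_with_prey_complexes"] = n_with
    except Exception as exc:
        _mark_partial(stage_files)
        raise PipelineError(f"stage complex_evidence: {exc}") from exc

    # --- stage 5: substrate inference --------------------------------------
    stage_files = [out / "hypotheses.tsv", out / "accepted.graphml"]
    try:
        inf_cfg = InferenceConfig(
            mode=cfg.mode,
            max_pathway_depth=cfg.max_pathway_depth,
            require_all_readouts=cfg.require_all_readouts,
            sequences=bundle.sequences,
        )
        hypotheses = []
        for pid in sorted(bundle.phosphatases):
            info = bundle.phosphatases[pid]
            if info.id not in net.nodes:
                logger.warning("phosphatase %s absent from network; skipped",
                               info.id)
                continue
            hypotheses.extend(
                infer_substrates(net, info, bundle.pathway, bundle.sites,
                                 bundle.phenotypes, inf_cfg)
            )
        write_hypotheses_tsv(hypotheses, stage_files[0])
        write_accepted_graphml(hypotheses, stage_files[1])
        counts["hypotheses"] = len(hypotheses)
        counts["accepted_hypotheses"] = sum(h.accepted for h in hypotheses)
    except PipelineError:
        raise
    except Exception as exc:
        _mark_partial(stage_files)
        raise PipelineError(f"stage substrate_inference: {exc}") from exc

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.content_hash(),
        "version": __version__,
        "seed": cfg.seed,
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return out


def _mark_partial(paths: list[Path]) -> None:
    for path in paths:
        if path.exists():
            path.rename(path.with_suffix(path.suffix + ".partial"))


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

def write_report(artifact_dir, report_name: str = "report.md") -> Path:
    """Render a per-bait summary of a completed run as Markdown.

    Reads only the stage outputs, so regeneration is idempotent; missing
    stage outputs raise an error listing them.
    """
    out = Path(artifact_dir)
    required = ["manifest.json", "network.tsv", "pathway_labels.tsv",
                "complexes.tsv", "hypotheses.tsv"]
    missing = [name for name in required if not (out / name).exists()]
    if missing:
        raise PipelineError(
            "incomplete run; missing stage outputs: " + ", ".join(missing)
        )
    manifest = json.loads((out / "manifest.json").read_text())
    counts = manifest["row_counts"]

    labels = _read_tsv(out / "pathway_labels.tsv")
    complexes = _read_tsv(out / "complexes.tsv")
    hypotheses = _read_tsv(out / "hypotheses.tsv")

    baits = sorted({row["bait"] for row in labels})
    lines = ["# Pipeline report", ""]
    lines.append(f"Configuration hash: `{manifest['config_hash']}` "
                 f"(phosbridge {manifest['version']}, seed {manifest['seed']})")
    lines.append("")
    overlap = counts.get("literature_overlap_pct")
    lines.append(f"Network: {counts.get('network_nodes', 0)} nodes, "
                 f"{counts.get('network_edges', 0)} edges; "
                 f"{overlap}% of bait-prey interactions literature-supported.")
    lines.append("")

    for bait in baits:
        lines.append(f"## {bait}")
        enr = _read_tsv(out / "enrichment" / f"{bait}.tsv")
        enriched = [row for row in enr if row["enriched"] == "1"]
        reg = {}
        for row in enriched:
            reg[row["regulation"] or "tnf_independent"] = (
                reg.get(row["regulation"] or "tnf_independent", 0) + 1
            )
        reg_txt = ", ".join(f"{k}: {v}" for k, v in sorted(reg.items())) or "-"
        lines.append(f"- enriched preys: {len(enriched)} ({reg_txt})")
        label = next((row["label"] for row in labels if row["bait"] == bait),
                     "")
        lines.append(f"- pathway label: {label or 'none'}")
        comps = [row for row in complexes if row["bait"] == bait]
        if comps:
            for row in comps:
                lines.append(f"- prey complex ({row['component_size']}): "
                             f"{row['members']}")
        else:
            lines.append("- prey complexes: none")
        accepted = {
            (row["path"], row["substrate"])
            for row in hypotheses
            if row["phosphatase"] == bait and row["accepted"] == "1"
        }
        if accepted:
            for path, substrate in sorted(accepted):
                flags = next(row for row in hypotheses
                             if row["phosphatase"] == bait
                             and row["path"] == path)
                passed = [k for k in ("max_steps", "substrate_role",
                                      "functional_sites",
                                      "residue_compatibility",
                                      "phenotype_consistency")
                          if flags[k] == "1"]
                lines.append(f"- accepted substrate hypothesis: {path} "
                             f"(substrate {substrate}; rules passed: "
                             f"{', '.join(passed)})")
        else:
            lines.append("- accepted substrate hypotheses: none")
        lines.append("")

    report = out / report_name
    report.write_text("\n".join(lines))
    return report


def _read_tsv(path) -> list[dict[str, str]]:
    with open(path, newline="") as handle:
        return list(csv.DictReader(handle, delimiter="\t"))
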