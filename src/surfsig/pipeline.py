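"""End-to-end pipeline: DEA -> protein/category quantification -> signature.

``run_pipeline`` sequences the stages over a loaded input bundle, writes
every stage output as TSV/JSON under the output directory, and records a
run manifest (configuration snapshot, tool version, input and output
checksums, seed, per-stage status).  Identical inputs, configuration and
seed reproduce byte-identical stage outputs; a stage failure aborts the
run with downstream stages marked ``not_run`` in the manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dea import differential_expression
from .errors import ConfigError, StageError
from .io import Bundle, load_bundle, sha256_file
from .signature import (
    build_signature,
    consolidate_core,
    cross_identification,
    deg_specific,
    exclusive_to,
    itraq_confirm,
    membrane_filter,
)
from .wspp import category_report, category_stats, protein_pipeline

log = logging.getLogger(__name__)

STAGES = ("dea", "quant", "signature", "report")


@dataclass
class PipelineConfig:
    """Paths, thresholds and bookkeeping for one pipeline run."""

    bundle_dir: str
    outdir: str
    alpha_deg: float = 0.05
    alpha_membrane: float = 0.02
    min_peptides: int = 4
    min_category_size: int = 5
    confirm_rule: str = "positive"
    confirm_threshold: float | None = None
    target_group: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_deg", "alpha_membrane"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.min_peptides < 1:
            raise ConfigError("min_peptides must be >= 1")
        if self.min_category_size < 1:
            raise ConfigError("min_category_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Audit trail of one pipeline run."""

    config: dict
    version: str
    seed: int
    input_checksums: dict = field(default_factory=dict)
    output_checksums: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _stage_dea(bundle: Bundle, cfg: PipelineConfig, outdir: Path) -> dict:
    cm = bundle.count_matrix
    groups = cm.groups
    target = cfg.target_group if cfg.target_group in groups else groups[0]
    others = [g for g in groups if g != target]
    tables = {}
    outputs = {}
    for other in others:
        table = differential_expression(cm, (target, other))
        label = f"{target}_vs_{other}"
        tables[label] = table
        rel = f"deg_{label}.tsv"
        _write_tsv(table.drop(columns=["t"]), outdir / rel)
        outputs[rel] = None
        log.info(
            "%s: %d genes tested, %d with padj < %.3g",
            label,
            len(table),
            int((table["padj"] < cfg.alpha_deg).sum()),
            cfg.alpha_deg,
        )
    return {"tables": tables, "target": target, "others": others, "outputs": list(outputs)}


def _stage_quant(bundle: Bundle, cfg: PipelineConfig, outdir: Path) -> dict:
    pq = protein_pipeline(bundle.spectra, min_peptides=cfg.min_peptides)
    cats = category_stats(pq.table, bundle.categories, min_size=cfg.min_category_size)
    _write_tsv(pq.table, outdir / "proteins.tsv")
    _write_tsv(cats, outdir / "categories.tsv")
    outputs = ["proteins.tsv", "categories.tsv"]
    reports = {}
    for cmp_label, sub in cats.groupby("comparison", sort=True):
        reports[cmp_label] = category_report(sub.reset_index(drop=True))
    return {"protein_quant": pq, "category_stats": cats, "category_reports": reports, "outputs": outputs}


def _stage_signature(
    bundle: Bundle, cfg: PipelineConfig, outdir: Path, dea_res: dict, quant_res: dict
) -> dict:
    target = dea_res["target"]
    others = dea_res["others"]
    comps = bundle.compartments

    we = {k: set(v) for k, v in bundle.whole_extract.items()}
    mf = {k: set(v) for k, v in bundle.membrane_fraction.items()}
    we_exclusive = exclusive_to(we, target)
    we_excl_membrane = membrane_filter(we_exclusive, comps)
    mf_exclusive = exclusive_to(mf, target)
    mf_excl_membrane = membrane_filter(mf_exclusive, comps)
    seen_whole_extract = set().union(*we.values())
    additional = mf_excl_membrane - seen_whole_extract
    core, core_prov = consolidate_core(we_excl_membrane, additional)

    tables = dea_res["tables"]
    labels = [f"{target}_vs_{o}" for o in others]
    deg_a, deg_b = tables[labels[0]], tables[labels[1 % len(labels)]]
    deg_specific_both = deg_specific(deg_a, deg_b, cfg.alpha_deg, direction="both")
    deg_up_strict = deg_specific(deg_a, deg_b, cfg.alpha_membrane, direction="up")
    rna_core = membrane_filter(deg_up_strict, comps)

    pq_table = quant_res["protein_quant"].table
    primary = pq_table[pq_table["comparison"] == labels[0]]
    confirmed, confirmed_pct = itraq_confirm(
        core, primary, rule=cfg.confirm_rule, threshold=cfg.confirm_threshold
    )

    report = build_signature(core, rna_core, core_prov, confirmed)
    transcriptome = set(bundle.count_matrix.counts.index[bundle.count_matrix.counts.sum(axis=1) > 0])
    proteome = we[target]
    cross = cross_identification(proteome, transcriptome)

    stages = {
        "target_group": target,
        "comparisons": labels,
        "whole_extract_exclusive": sorted(we_exclusive),
        "whole_extract_exclusive_membrane": sorted(we_excl_membrane),
        "membrane_fraction_exclusive_membrane": sorted(mf_excl_membrane),
        "membrane_fraction_additional": sorted(additional),
        "core": sorted(core),
        "deg_specific": sorted(deg_specific_both),
        "deg_specific_up_strict": sorted(deg_up_strict),
        "rna_membrane_core": sorted(report.rna_core),
        "verified": sorted(report.verified),
        "combined_signature": sorted(report.combined),
        "itraq_confirmed": sorted(confirmed),
        "counts": {
            "whole_extract_exclusive": len(we_exclusive),
            "whole_extract_exclusive_membrane": len(we_excl_membrane),
            "membrane_fraction_additional": len(additional),
            "core": len(core),
            "deg_specific": len(deg_specific_both),
            "rna_membrane_core": len(report.rna_core),
            "verified": len(report.verified),
            "combined_signature": len(report.combined),
        },
        "percentages": {
            "itraq_confirmed_pct": confirmed_pct,
            "rna_core_overlap_pct": report.overlap_pct,
            **{k: v for k, v in cross.items()},
        },
    }
    _write_tsv(report.provenance, outdir / "signature.tsv", index=True)
    with open(outdir / "stages.json", "w") as fh:
        json.dump(stages, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"report": report, "stages": stages, "outputs": ["signature.tsv", "stages.json"]}


def render_report(outdir: str | Path) -> str:
    """Deterministic human-readable report from serialized stage outputs.

    Every number shown is recomputed from the stage files; a missing
    stage output is an error naming the stage.
    """
    outdir = Path(outdir)
    needed = {
        "signature": outdir / "stages.json",
        "quant": outdir / "proteins.tsv",
    }
    for stage, path in needed.items():
        if not path.exists():
            raise StageError(f"missing output of stage {stage!r}: {path.name}")
    with open(needed["signature"]) as fh:
        stages = json.load(fh)
    proteins = pd.read_csv(needed["quant"], sep="\t")
    categories = pd.read_csv(outdir / "categories.tsv", sep="\t")

    lines = []
    lines.append("surface signature pipeline report")
    lines.append("=" * 40)
    lines.append(f"target population: {stages['target_group']}")
    lines.append(f"comparisons: {', '.join(stages['comparisons'])}")
    lines.append("")
    lines.append("evidence-set counts")
    for k, v in sorted(stages["counts"].items()):
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("percentages (report rounding conventions)")
    for k, v in sorted(stages["percentages"].items()):
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("top proteins by |Zq|")
    top = proteins.dropna(subset=["Zq"]).copy()
    top["absZq"] = top["Zq"].abs()
    top = top.sort_values(["absZq", "protein"], ascending=[False, True]).head(10)
    for _, row in top.iterrows():
        lines.append(
            f"  {row['protein']} ({row['comparison']}): Zq={row['Zq']:.2f}, "
            f"Xq={row['Xq']:.3f}, peptides={row['n_peptides']}"
        )
    for direction, ascending in (("Zc+ (up)", False), ("Zc- (down)", True)):
        lines.append("")
        lines.append(f"top categories {direction}")
        ranked = categories.sort_values(["Zc", "category"], ascending=[ascending, True]).head(10)
        for _, row in ranked.iterrows():
            lines.append(
                f"  {row['category']} ({row['comparison']}): Zc={row['Zc']:.2f}, "
                f"nc={row['nc']}, Xc={row['Xc']:.3f}"
            )
    lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute dea -> quant -> signature -> report over a bundle."""
    from . import __version__

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle_dir = Path(cfg.bundle_dir)
    manifest = RunManifest(
        config=cfg.to_dict(),
        version=__version__,
        seed=cfg.seed,
        started=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    for rel in sorted(p for p in bundle_dir.rglob("*") if p.is_file()):
        manifest.input_checksums[str(rel.relative_to(bundle_dir))] = sha256_file(rel)

    results: dict = {}
    outputs: list[str] = []
    pending = list(STAGES)
    try:
        bundle = load_bundle(bundle_dir)
    except Exception as exc:  # noqa: BLE001 - recorded in the manifest
        manifest.stages["load"] = {"status": "failed", "error": str(exc)}
        for stage in pending:
            manifest.stages[stage] = {"status": "not_run"}
        _finalize(manifest, outdir)
        raise StageError(f"stage load: {exc}") from exc
    manifest.stages["load"] = {"status": "complete"}

    for stage in STAGES:
        pending.remove(stage)
        try:
            if stage == "dea":
                results["dea"] = _stage_dea(bundle, cfg, outdir)
                outputs += results["dea"]["outputs"]
            elif stage == "quant":
                results["quant"] = _stage_quant(bundle, cfg, outdir)
                outputs += results["quant"]["outputs"]
            elif stage == "signature":
                results["signature"] = _stage_signature(
                    bundle, cfg, outdir, results["dea"], results["quant"]
                )
                outputs += results["signature"]["outputs"]
            elif stage == "report":
                text = render_report(outdir)
                (outdir / "report.txt").write_text(text)
                outputs.append("report.txt")
            manifest.stages[stage] = {"status": "complete"}
        except Exception as exc:  # noqa: BLE001 - recorded in the manifest
            manifest.stages[stage] = {"status": "failed", "error": str(exc)}
            for s in pending:
                manifest.stages[s] = {"status": "not_run"}
            for rel in outputs:
                manifest.output_checksums[rel] = sha256_file(outdir / rel)
            _finalize(manifest, outdir)
            raise StageError(f"stage {stage}: {exc}") from exc

    for rel in outputs:
        manifest.output_checksums[rel] = sha256_file(outdir / rel)
    _finalize(manifest, outdir)
    return manifest


def _finalize(manifest: RunManifest, outdir: Path) -> None:
    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
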