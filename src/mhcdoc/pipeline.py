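"""End-to-end orchestration: simulate/load -> preprocess -> correct ->
genotype -> name -> compare, with per-stage artifacts and a run manifest.

Configuration is a nested mapping (usually loaded from YAML) with optional
sections ``simulate``, ``preprocess``, ``correct``, ``genotype``,
``compare`` and ``report``; a single ``seed`` governs every source of
randomness.  Each stage writes its outputs under the run directory so any
stage can be re-run from its serialized inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from . import comparison, correction, genotyping, naming, preprocess, simdata
from ._util import spawn_seed


@dataclass
class PlatformResult:
    """Artifacts of one platform's pass through the pipeline."""

    platform: str
    table_raw: preprocess.VariantTable
    table_corrected: preprocess.VariantTable
    decisions: list
    calls: dict[str, genotyping.GenotypeCall]
    profiles: dict[str, genotyping.DocProfile]
    paths: dict[str, Path] = field(default_factory=dict)


@dataclass
class PipelineResult:
    out_dir: Path
    platforms: dict[str, PlatformResult]
    report: Optional[comparison.ComparisonReport] = None
    truth: Optional[dict[str, frozenset[str]]] = None
    replicate_pairs: list = field(default_factory=list)
    pedigree_rows: list = field(default_factory=list)
    manifest_path: Optional[Path] = None


class StageError(RuntimeError):
    """Raised when a named pipeline stage fails."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _simulate_platform(
    cfg: Mapping[str, Any],
    platform: str,
    pool: simdata.AllelePool,
    genotypes: dict[str, frozenset[str]],
    replicate_pairs: list[tuple[str, str]],
    seed: int,
    out_dir: Path,
) -> dict[str, Path]:
    profile = simdata.ErrorProfile.default(
        platform, **cfg.get(f"profile_{platform}", {})
    )
    amplicon_ids = sorted(genotypes)
    design = simdata.make_run_design(amplicon_ids, platform, seed)
    amplicons = simdata.simulate_run(design, pool, genotypes, profile)
    return simdata.emit_run(design, amplicons, out_dir / f"sim_{platform}", profile)


def run_pipeline(
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run the configured stages in order; any stage failure is re-raised
    as a :class:`StageError` naming the stage.  Deterministic given the
    config and seed (identical runs produce byte-identical artifacts)."""
    cfg = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    manifest: dict[str, Any] = {"seed": seed, "stages": []}

    sim_cfg = cfg.get("simulate")
    truth: Optional[dict[str, frozenset[str]]] = None
    replicate_pairs: list[tuple[str, str]] = []
    pedigree_rows: list[tuple[str, str, str, str]] = []
    platform_inputs: dict[str, dict] = {}

    if sim_cfg:
        try:
            pool = simdata.make_allele_pool(
                n_classical=int(sim_cfg.get("n_classical", 21)),
                n_nonclassical=int(sim_cfg.get("n_nonclassical", 4)),
                min_pairwise_substitutions=int(
                    sim_cfg.get("min_pairwise_substitutions", 3)
                ),
                seed=spawn_seed(seed, 1),
            )
            a_i_range = tuple(sim_cfg.get("a_i_range", (3, 9)))
            if sim_cfg.get("pedigree"):
                ped_cfg = sim_cfg["pedigree"]
                pedigree = simdata.make_pedigree(
                    n_families=int(ped_cfg.get("n_families", 3)),
                    chicks_per_family=tuple(ped_cfg.get("chicks_per_family", (3, 5))),
                    pool=pool,
                    haplotype_size_range=tuple(
                        ped_cfg.get("haplotype_size_range", (2, 4))
                    ),
                    a_i_range=a_i_range,
                    seed=spawn_seed(seed, 2),
                )
                truth = {ind: pedigree.genotype(ind) for ind in pedigree.individuals}
                pedigree_rows = pedigree.to_rows()
            else:
                truth = simdata.sample_genotypes(
                    pool,
                    int(sim_cfg.get("n_samples", 12)),
                    a_i_range,
                    seed=spawn_seed(seed, 2),
                )
            n_rep = int(sim_cfg.get("n_replicates", 0))
            for sample in sorted(truth)[:n_rep]:
                rep_id = f"{sample}rep"
                truth[rep_id] = truth[sample]
                replicate_pairs.append((sample, rep_id))

            platforms = sim_cfg.get("platforms") or [sim_cfg.get("platform", "miseq")]
            for platform in platforms:
                paths = _simulate_platform(
                    sim_cfg, platform, pool, truth, replicate_pairs,
                    spawn_seed(seed, 10 + len(platform)), out_dir,
                )
                platform_inputs[platform] = {
                    "reads": paths.get("reads") or (paths["r1"], paths["r2"]),
                    "tags": paths["tags"],
                }
            manifest["stages"].append("simulate")
        except Exception as exc:  # noqa: BLE001
            raise StageError("simulate", exc) from exc
    else:
        for platform, section in (cfg.get("reads") or {}).items():
            platform_inputs[platform] = {
                "reads": (
                    (section["r1"], section["r2"])
                    if "r1" in section
                    else section["reads"]
                ),
                "tags": section["tags"],
            }

    if not platform_inputs:
        raise StageError("input", ValueError("no simulated or provided reads"))

    pre_cfg = cfg.get("preprocess", {})
    corr_cfg = cfg.get("correct", {})
    geno_cfg = cfg.get("genotype", {})
    results: dict[str, PlatformResult] = {}
    for platform, inputs in platform_inputs.items():
        try:
            table = preprocess.preprocess_run(
                platform,
                inputs["reads"],
                inputs["tags"],
                min_overlap=int(pre_cfg.get("min_overlap", 100)),
                min_mean_phred=float(pre_cfg.get("min_mean_phred", 30.0)),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("preprocess", exc) from exc
        try:
            corrected, decisions = correction.correct_table(
                table,
                top_k=int(corr_cfg.get("top_k", 50)),
                run_min=int(corr_cfg.get("run_min", 3)),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("correct", exc) from exc
        try:
            calls, profiles = genotyping.genotype_table(
                corrected,
                n_max=int(geno_cfg.get("n_max", genotyping.DEFAULT_N_MAX)),
                mode=geno_cfg.get("mode", "adjacent_ratio"),
                tau=float(geno_cfg.get("tau", genotyping.DEFAULT_TAU)),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("genotype", exc) from exc

        pdir = out_dir / platform
        pdir.mkdir(exist_ok=True)
        table.to_tsv(pdir / "variants_raw.tsv")
        table.write_stage_log(pdir / "stage_ledger.tsv")
        corrected.to_tsv(pdir / "variants_corrected.tsv")
        correction.write_decision_log(decisions, pdir / "correction_decisions.tsv")
        genotyping.write_genotypes(calls, pdir / "genotypes.tsv")
        if geno_cfg.get("curves", False):
            genotyping.export_curves(profiles, pdir / "curves")
        results[platform] = PlatformResult(
            platform, table, corrected, decisions, calls, profiles,
            {"dir": pdir},
        )
        manifest["stages"].append(f"genotype:{platform}")

    report_cfg = cfg.get("report", {})
    try:
        reference = (
            naming.read_reference_fasta(report_cfg["reference_fasta"])
            if report_cfg.get("reference_fasta")
            else []
        )
        for platform, res in results.items():
            seqs = {
                seq for c in res.calls.values() if c.quality == "good"
                for seq in c.alleles
            }
            names = naming.name_alleles(
                seqs, reference, prefix=report_cfg.get("prefix", "Pado-UA*")
            )
            naming.write_outputs(res.calls, names, out_dir / platform)
        manifest["stages"].append("name")
    except Exception as exc:  # noqa: BLE001
        raise StageError("name", exc) from exc

    report = None
    if len(results) == 2:
        try:
            pa, pb = sorted(results)
            a_i_bins = (
                {s: len(g) for s, g in truth.items()} if truth is not None else None
            )
            report = comparison.compare_platforms(
                results[pa].calls,
                results[pb].calls,
                depths_a={
                    s: results[pa].table_corrected.total_depth(s)
                    for s in results[pa].table_corrected.entries
                },
                depths_b={
                    s: results[pb].table_corrected.total_depth(s)
                    for s in results[pb].table_corrected.entries
                },
                replicate_pairs=replicate_pairs,
                pedigree_rows=pedigree_rows,
                a_i_bins=a_i_bins,
                platform_a=pa,
                platform_b=pb,
            )
            report.to_json(out_dir / "comparison_report.json")
            manifest["stages"].append("compare")
        except Exception as exc:  # noqa: BLE001
            raise StageError("compare", exc) from exc

    manifest_path = out_dir / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(
        out_dir, results, report, truth, replicate_pairs, pedigree_rows,
        manifest_path,
    )
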