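"""One-call orchestration of the full analysis.

quantify (NSAF) -> technical-replicate averaging -> zero replacement -> log2
-> PCA -> ASCA + permutation validation -> loadings selection per effect ->
clade clustering -> clade profiles -> optional GO enrichment, with every
intermediate written as TSV and a machine-readable JSON report (percent
variation and p per factor, selection sizes, clade counts, enrichment
summaries). Given the same config and seed the report is byte-identical;
timestamps live in the separate run-record file so the report stays
deterministic.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import cluster as _cluster
from . import enrich as _enrich
from . import select as _select
from .decompose import PermutationSpec, decompose_asca, run_pca, run_permutation_tests
from .io import (
    AbundanceMatrix,
    ProtascaError,
    RunRecord,
    SampleDesign,
    SpectralCountTable,
    read_abundance_table,
    read_design,
    read_ontology,
    write_abundance_table,
    write_design,
)
from .preprocess import (
    PreprocessParams,
    autoscale_rows,
    average_technical_replicates,
    compute_nsaf,
    log2_transform,
    replace_zeros,
)
from .simulate import generate_dataset, score_recovery

log = logging.getLogger("protasca")


@dataclass
class PipelineConfig:
    """Declarative configuration; unknown keys are rejected on load."""

    output_dir: str = "protasca_out"
    # inputs: either file paths or a synthetic-generator parameter block
    counts: str | None = None
    abundance: str | None = None
    dialect: str = "plain"
    design: str | None = None
    simulate: dict | None = None
    annotations: str | None = None
    obo: str | None = None
    slim: str | None = None
    go_aspect: str | None = "biological_process"
    # preprocessing
    zero_fraction: float = 0.125
    autoscale_ddof: int = 0
    # decomposition
    include_interaction: bool = True
    exclude_unbalanced: bool = True
    n_permutations: int = 1000
    seed: int = 0
    # selection: "elbow" or a PAPER_PRESETS name
    selection_mode: str = "elbow"
    components: dict = field(default_factory=dict)  # factor -> list of PCs
    min_cumulative_variance: float = 0.9
    # clustering
    time_cut_height: float | None = 1.8
    time_n_clades: int | None = None
    temperature_cut_height: float | None = 1.5
    temperature_n_clades: int | None = None
    # enrichment
    alpha: float = 0.05
    min_background_count: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ProtascaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        sources = [s is not None for s in (self.counts, self.abundance, self.simulate)]
        if sum(sources) != 1:
            raise ProtascaError(
                "exactly one of counts / abundance / simulate must be given")
        if self.simulate is None and self.design is None:
            raise ProtascaError("a design table is required with file inputs")
        for factor in ("time", "temperature"):
            ch = getattr(self, f"{factor}_cut_height")
            nc = getattr(self, f"{factor}_n_clades")
            if (ch is None) == (nc is None):
                raise ProtascaError(
                    f"give exactly one of {factor}_cut_height / {factor}_n_clades")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the JSON-serializable report.

    Writes intermediates (TSV), ``report.json`` and ``run_record.json`` to
    ``config.output_dir``. Fully deterministic given ``config.seed``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = RunRecord(run_id=uuid.uuid4().hex[:12], config=asdict(config),
                       seed=config.seed)
    report: dict = {"stages": []}

    def stage(name: str):
        log.info("stage: %s", name)
        report["stages"].append(name)

    try:
        # ------------------------------------------------------------------ load
        stage("load")
        truth = None
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            table, design, truth = generate_dataset(**sim_kwargs)
        else:
            src = config.counts or config.abundance
            table = read_abundance_table(src, dialect=config.dialect)
            design = read_design(config.design, run_record=record)

        # -------------------------------------------------------------- quantify
        stage("quantify")
        params = PreprocessParams(zero_replacement_fraction=config.zero_fraction,
                                  autoscale_ddof=config.autoscale_ddof)
        if isinstance(table, SpectralCountTable):
            nsaf = compute_nsaf(table)
        else:
            nsaf = table
        keep = [s for s in design.sample_ids if s in nsaf.values.columns]
        extra = [s for s in design.sample_ids if s not in keep]
        if extra:
            record.log(f"design samples missing from matrix, dropped: {extra}")
            design = design.subset(keep)
        nsaf = AbundanceMatrix(values=nsaf.values[design.sample_ids],
                               scale_tag=nsaf.scale_tag)
        write_abundance_table(nsaf, out / "nsaf.tsv", record)

        stage("average_replicates")
        averaged, bio_design = average_technical_replicates(nsaf, design, record)
        write_abundance_table(averaged, out / "nsaf_averaged.tsv", record)
        write_design(bio_design, out / "design_biological.tsv", record)

        stage("preprocess")
        replaced = replace_zeros(averaged, params, record)
        logged = log2_transform(replaced)
        write_abundance_table(logged, out / "log2_nsaf.tsv", record)
        autoscaled = autoscale_rows(logged, params)

        # ------------------------------------------------------------ decompose
        stage("pca")
        pca = run_pca(logged)
        report["pca"] = {
            "explained_variance_fraction":
                [float(v) for v in pca.explained_variance_fraction[:10]],
        }
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")

        stage("asca")
        asca_design = bio_design
        if config.exclude_unbalanced and bio_design.unbalanced_samples:
            dropped = bio_design.unbalanced_samples
            record.log(f"asca: excluding unbalanced samples {dropped}")
            asca_design = bio_design.subset(
                [s for s in bio_design.sample_ids if s not in dropped])
        asca = decompose_asca(logged, asca_design,
                              include_interaction=config.include_interaction,
                              run_record=record)
        spec = PermutationSpec(n_permutations=config.n_permutations,
                               seed=config.seed)
        run_permutation_tests(logged, asca_design, asca, spec)
        report["asca"] = {
            "percent_variation": {f: round(v, 2)
                                  for f, v in asca.percent_variation.items()},
            "residual_percent": round(asca.residual_percent, 2),
            "permutation_p": {f: round(p, 6)
                              for f, p in asca.permutation_p.items()},
            "n_permutations": config.n_permutations,
            "balanced": asca.balanced,
            "saturated": asca.saturated,
        }
        for f, E in asca.effects.items():
            E.to_csv(out / f"asca_effect_{f}.tsv", sep="\t")
            asca.sca[f].loadings.to_csv(out / f"asca_{f}_loadings.tsv", sep="\t")

        # ------------------------------------------------ selection + clustering
        report["selection"] = {}
        report["clades"] = {}
        clade_assignments = {}
        for factor in ("time", "temperature"):
            stage(f"select_{factor}")
            sca = asca.sca[factor]
            comps = config.components.get(factor)
            if comps is None:
                comps = _select.select_components_by_variance(
                    sca, min_cumulative=config.min_cumulative_variance)
            ranked = _select.rank_loadings(sca, comps)
            if config.selection_mode == "elbow":
                sels = [_select.select_by_elbow(ranked[c], component_id=c)
                        for c in comps]
            elif config.selection_mode in _select.PAPER_PRESETS:
                preset = _select.PAPER_PRESETS[config.selection_mode]
                sels = [_select.select_by_threshold(
                            ranked[c], *preset[c], component_id=c)
                        for c in comps if c in preset]
            else:
                raise ProtascaError(
                    f"unknown selection_mode {config.selection_mode!r}")
            selected = _select.union_selections(sels)
            report["selection"][factor] = {
                "components": comps,
                "n_selected": len(selected),
                "thresholds": {s.component_id: [s.upper_threshold,
                                                s.lower_threshold] for s in sels},
            }
            (out / f"selected_{factor}.txt").write_text(
                "\n".join(sorted(selected)) + "\n")
            if len(selected) < 3:
                record.log(f"{factor}: fewer than 3 proteins selected; "
                           "skipping clustering")
                continue

            stage(f"cluster_{factor}")
            auto_sel = AbundanceMatrix(
                values=autoscaled.values.loc[sorted(selected)],
                scale_tag="autoscaled")
            dist = _cluster.pearson_distance_matrix(auto_sel,
                                                    drop_zero_variance=True)
            clades = _cluster.hierarchical_clades(
                dist,
                cut_height=getattr(config, f"{factor}_cut_height"),
                n_clades=getattr(config, f"{factor}_n_clades"))
            clade_assignments[factor] = clades
            clades.labels.to_csv(out / f"clades_{factor}.tsv", sep="\t")
            (out / f"dendrogram_{factor}.nwk").write_text(clades.to_newick() + "\n")
            profiles = _cluster.clade_profiles(auto_sel, clades, bio_design)
            profiles.to_csv(out / f"clade_profiles_{factor}.tsv", sep="\t",
                            index=False)
            report["clades"][factor] = {
                "n_clades": clades.n_clades,
                "sizes": {int(k): int(v)
                          for k, v in clades.clade_sizes.items()},
            }

        # ------------------------------------------------------------ enrichment
        if config.annotations is not None and config.obo is not None:
            stage("enrichment")
            ann = read_ontology(config.obo, config.annotations,
                                slim_path=config.slim, run_record=record)
            background = _enrich.build_background(
                ann, set(logged.protein_ids), aspect=config.go_aspect)
            report["enrichment"] = {}
            for factor, clades in clade_assignments.items():
                table_e = _enrich.enrich_clades(
                    clades, background, alpha=config.alpha,
                    min_background_count=config.min_background_count)
                filtered = _enrich.apply_significance_filters(
                    table_e, alpha=config.alpha,
                    min_background_count=config.min_background_count)
                filtered.to_csv(out / f"enrichment_{factor}.tsv", sep="\t",
                                index=False)
                summary = {
                    "background_size": background.size,
                    "n_significant": int(len(filtered)),
                    "per_clade": {int(c): int(n) for c, n in
                                  filtered.groupby("clade").size().items()},
                }
                if ann.slim_subset:
                    slim_m = _enrich.slim_count_matrix(filtered, ann)
                    if not slim_m.empty:
                        slim_m.to_csv(out / f"enrichment_{factor}_slim.tsv",
                                      sep="\t")
                        summary["n_slim_terms"] = int(slim_m.shape[1])
                report["enrichment"][factor] = summary

        # -------------------------------------------------------------- recovery
        if truth is not None:
            stage("recovery")
            from .simulate import TEMP_ARCHETYPES, TIME_ARCHETYPES

            report["recovery"] = {}
            for factor, names in (("time", TIME_ARCHETYPES),
                                  ("temperature", TEMP_ARCHETYPES)):
                sel_path = out / f"selected_{factor}.txt"
                sel = frozenset(sel_path.read_text().split())
                metrics = score_recovery(
                    truth, selection=sel,
                    clades=clade_assignments.get(factor),
                    planted_names=names)
                metrics.pop("per_archetype_recall", None)
                report["recovery"][factor] = {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in metrics.items()}
    except Exception as exc:
        record.log(f"FAILED at stage {report['stages'][-1]}: {exc}")
        record.to_json(out / "run_record.json")
        raise

    report["n_proteins"] = len(logged.protein_ids)
    report["n_samples"] = len(design.sample_ids)
    report["seed"] = config.seed
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    record.record_file(out / "report.json")
    record.to_json(out / "run_record.json")
    return report


def compare_protein_sets(set_a: set[str], set_b: set[str]) -> dict:
    """Overlap statistics between two protein id sets.

    Reports both overlap conventions: shared over the union, and shared over
    the mean of the two set sizes (the per-pair convention used when quoting
    average overlap between paired proteomes).
    """
    a, b = set(set_a), set(set_b)
    shared = a & b
    union = a | b
    mean_size = (len(a) + len(b)) / 2
    return {
        "unique_to_a": len(a - b),
        "unique_to_b": len(b - a),
        "shared": len(shared),
        "union_overlap_pct": 100.0 * len(shared) / len(union) if union else 100.0,
        "mean_size_overlap_pct": (100.0 * len(shared) / mean_size
                                  if mean_size else 100.0),
    }
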