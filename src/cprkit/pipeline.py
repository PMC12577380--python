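"""End-to-end orchestration: one config, one reproducible output bundle.

A pipeline run executes (optionally) simulation, normalization, qPCR
anchoring, growth and enrichment estimation, primer-coverage
assessment, oxygen-metabolism profiling, co-occurrence analysis and
community statistics, writing one TSV per stage plus a JSON manifest
(config hash, seed, version, per-file checksums). Identical
configurations produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import absolute_abundance, fold_enrichment, total_sum_scale
from .community_stats import (
    ingest_differential_abundance,
    merge_association_reports,
    shannon_cpr,
    supplement_association,
)
from .cooccurrence import count_order_links, estimate_network, filter_cpr_edges
from .errors import ConfigError, CprkitError, ValidationError
from .growth import estimates_frame, fit_all_growth_rates, summarize_growth
from .io_formats import (
    DEFAULT_CPR_CLASSES,
    metadata_frame,
    read_annotations,
    read_count_table,
    read_fasta_with_taxonomy,
    read_metadata,
    read_qpcr,
    read_reaction_classes,
    read_taxonomy,
    write_abs_abundance,
    write_annotations,
    write_count_table,
    write_fasta,
    write_metadata,
    write_qpcr,
    write_reaction_classes,
    write_rel_abundance,
    write_taxonomy,
)
from .oxynet import (
    DEFAULT_OXYGEN_ENZYMES,
    compare_function_prevalence,
    profile_mags,
    profiles_frame,
)
from .primer_silico import BAKT341F, BAKT785R, PrimerSpec, coverage_by_class
from .synthetic import (
    SynthConfig,
    simulate_experiment,
    simulate_mag_annotations,
    simulate_reference_db,
)

logger = logging.getLogger(__name__)


class StageError(CprkitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    output_dir: str
    seed: int = 0
    simulate: SynthConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    cpr_classes: tuple[str, ...] = DEFAULT_CPR_CLASSES
    mismatch_budget: int = 2
    amplicon_bounds: tuple[int, int] = (50, 2000)
    edge_min_weight: float = 0.1
    network_method: str = "rank"
    prevalence_floor: float = 0.2
    top_n_edges: int = 200
    min_order_links: int = 3
    alpha_spearman: float = 0.001
    alpha_enrichment: float = 0.05
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    focal_classes: tuple[str, ...] = ("Saccharimonadia", "Berkelbacteria")

    def __post_init__(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ConfigError("config needs input paths or a simulate block")
        if not 0 < self.edge_min_weight < 1:
            raise ConfigError("edge_min_weight must lie in (0, 1)")
        if self.simulate is None:
            missing = [p for p in self.inputs.values() if not Path(p).exists()]
            if missing:
                raise ConfigError(f"input files not found: {missing}")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    simulate = None
    if sim is not None:
        if "time_points" in sim:
            sim["time_points"] = tuple(float(t) for t in sim["time_points"])
        simulate = SynthConfig(**sim)
    for key in ("cpr_classes", "focal_classes", "amplicon_bounds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PipelineConfig(simulate=simulate, **raw)


def _config_hash(config: PipelineConfig) -> str:
    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    payload = dataclasses.asdict(config)
    payload.pop("output_dir", None)  # bundle content does not depend on location
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the output bundle.

    Returns the mapping of output name to written path. Any stage
    failure is re-raised as :class:`StageError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        written[name] = path

    sim = config.simulate
    stage = "load-inputs"
    try:
        if sim is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
            stage = "simulate"
            counts, records, qpcr, taxonomy, truth = simulate_experiment(sim)
            ref_seqs, ref_tax, ref_truth = simulate_reference_db(sim)
            mags, reaction_classes, mag_truth = simulate_mag_annotations(sim)
            write_count_table(counts, out / "counts.tsv")
            write_metadata(records, out / "metadata.tsv")
            write_taxonomy(taxonomy, out / "taxonomy.tsv")
            write_qpcr(qpcr, out / "qpcr.tsv")
            write_fasta(ref_seqs, out / "reference.fasta")
            write_taxonomy(ref_tax, out / "reference_taxonomy.tsv")
            write_annotations(mags, out / "annotations.tsv")
            write_reaction_classes(reaction_classes, out / "reaction_classes.tsv")
            truth_df = pd.DataFrame(
                {"true_k_per_day": truth.true_k, "true_n0": truth.true_n0}
            )
            _write(truth_df.rename_axis("asv_id").reset_index(), out / "truth_asv.tsv")
            _write(
                mag_truth.mag_truth.rename_axis("mag_id").reset_index(),
                out / "truth_mags.tsv",
            )
            diff_table = None
        else:
            inp = config.inputs
            counts = read_count_table(inp["counts"])
            records = read_metadata(inp["metadata"])
            taxonomy = read_taxonomy(inp["taxonomy"], config.cpr_classes)
            qpcr = read_qpcr(inp["qpcr"]) if "qpcr" in inp else None
            ref_seqs = ref_tax = None
            if "reference_fasta" in inp and "reference_taxonomy" in inp:
                ref_seqs, ref_tax = read_fasta_with_taxonomy(
                    inp["reference_fasta"], inp["reference_taxonomy"], config.cpr_classes
                )
            mags = read_annotations(inp["annotations"]) if "annotations" in inp else None
            reaction_classes = (
                read_reaction_classes(inp["reaction_classes"])
                if "reaction_classes" in inp
                else None
            )
            diff_table = (
                ingest_differential_abundance(inp["differential_abundance"])
                if "differential_abundance" in inp
                else None
            )

        stage = "normalize"
        rel = total_sum_scale(counts)
        write_rel_abundance(rel, out / "relative_abundance.tsv")
        emit("relative_abundance", out / "relative_abundance.tsv")

        stage = "growth"
        if qpcr is None:
            raise ValidationError("qPCR totals are required for absolute abundances")
        abs_table = absolute_abundance(rel, qpcr)
        write_abs_abundance(abs_table, out / "absolute_abundance.tsv")
        emit("absolute_abundance", out / "absolute_abundance.tsv")
        estimates = fit_all_growth_rates(abs_table, records)
        _write(estimates_frame(estimates), out / "growth_estimates.tsv")
        emit("growth_estimates", out / "growth_estimates.tsv")
        _write(summarize_growth(estimates, taxonomy), out / "growth_summary.tsv")
        emit("growth_summary", out / "growth_summary.tsv")

        stage = "enrichment"
        _write(fold_enrichment(abs_table, records), out / "fold_enrichment.tsv")
        emit("fold_enrichment", out / "fold_enrichment.tsv")

        if ref_seqs is not None:
            stage = "primer-coverage"
            cov = coverage_by_class(
                ref_seqs,
                ref_tax,
                BAKT341F,
                BAKT785R,
                budget=config.mismatch_budget,
                amplicon_bounds=config.amplicon_bounds,
            )
            _write(cov, out / "primer_coverage.tsv")
            emit("primer_coverage", out / "primer_coverage.tsv")

        if mags is not None and reaction_classes is not None:
            stage = "oxynet"
            profiles = profile_mags(
                mags,
                reaction_classes,
                min_completeness=config.min_completeness,
                max_contamination=config.max_contamination,
            )
            pf = profiles_frame(profiles)
            _write(pf.reset_index(), out / "mag_oxygen_profiles.tsv")
            emit("mag_oxygen_profiles", out / "mag_oxygen_profiles.tsv")
            presence = pd.DataFrame(
                {
                    label: [
                        int(any(l == label for l, _ in p.oxygen_enzyme_hits))
                        for p in profiles
                    ]
                    for label in DEFAULT_OXYGEN_ENZYMES
                },
                index=pd.Index([p.mag_id for p in profiles], name="mag_id"),
            )
            classes = pd.Series(
                [p.taxon_class for p in profiles], index=presence.index
            )
            focal = [c for c in config.focal_classes if (classes == c).any()]
            if focal and classes.isin(focal).sum() >= 2 and (~classes.isin(focal)).sum() >= 2:
                enrich = compare_function_prevalence(
                    presence, classes, focal, alpha=config.alpha_enrichment
                )
                _write(enrich, out / "function_enrichment.tsv")
                emit("function_enrichment", out / "function_enrichment.tsv")

        stage = "coocc"
        meta = metadata_frame(records)
        for treatment, sub in meta.groupby("treatment_group", sort=True):
            if treatment in ("Start", "InSitu"):
                continue
            sample_ids = sub.index.intersection(counts.data.index)
            if len(sample_ids) < 4:
                logger.info("treatment %s: too few samples for networks", treatment)
                continue
            net = estimate_network(
                counts.data.loc[sample_ids],
                treatment_group=str(treatment),
                method=config.network_method,
                prevalence_floor=config.prevalence_floor,
            )
            filtered = filter_cpr_edges(net, taxonomy, min_weight=config.edge_min_weight)
            _write(filtered.edges, out / f"edges_{treatment}.tsv")
            emit(f"edges_{treatment}", out / f"edges_{treatment}.tsv")
            chord = count_order_links(
                filtered,
                taxonomy,
                top_n=config.top_n_edges,
                min_links=config.min_order_links,
            )
            _write(chord.rows, out / f"order_links_{treatment}.tsv")
            emit(f"order_links_{treatment}", out / f"order_links_{treatment}.tsv")

        stage = "diversity"
        div = shannon_cpr(rel, taxonomy)
        _write(div.rename_axis("sample_id").reset_index(), out / "diversity.tsv")
        emit("diversity", out / "diversity.tsv")

        stage = "associate"
        assoc = supplement_association(
            rel, records, taxonomy=taxonomy, alpha=config.alpha_spearman
        )
        merged = merge_association_reports(assoc, diff_table)
        _write(merged, out / "associations.tsv")
        emit("associations", out / "associations.tsv")
    except CprkitError as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    manifest = {
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "cprkit_version": __version__,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = out / "manifest.json"
    return written
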