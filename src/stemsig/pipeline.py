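"""End-to-end orchestration: QC -> DEG -> enrichment -> selection ->
clustering -> derived gene sets -> term enrichment.

``run_pipeline`` is the in-memory engine; ``run_all`` wraps it with file
I/O (manifest + GMT in, TSV tables + run manifest out).  A single master
seed governs all stochastic stages; per-stage sub-seeds are derived by
stage index, so re-running with the same config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import GenotypeAssignment, two_way_cluster
from .derive import (DerivedGeneSet, SignatureConsistencySets, extract_cgs,
                     rank_and_threshold_signatures, select_urg_drg)
from .diffexp import compute_contrast, deg_overlap_matrix, select_degs
from .io import (ExpressionDataset, Manifest, SignatureCollection,
                 load_manifest_datasets, read_gmt, read_manifest, write_table)
from .profiles import (build_profile, filter_signatures_by_overlap,
                       select_signatures_gsea)
from .qc import SeparationReport, gate_datasets, pca_separation_score
from .scoring import profile_dataset
from .terms import compare_enrichment_profiles, fisher_enrichment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the whole pipeline; the defaults are the
    reference analysis settings (PCA gate 0.75, FDR<0.05 & FC>2 for DEGs,
    signature overlap 10-200, nominal p<0.05 in >=10/18 of the datasets,
    top 5% rules, 3x3 two-way clusters)."""

    manifest: str = ""
    signatures_gmt: str = ""
    terms_gmt: str = ""
    outdir: str = "stemsig_out"
    pca_min: float = 0.75
    fdr_max: float = 0.05
    fc_min: float = 2.0
    sig_min_overlap: int = 10
    sig_max_overlap: int = 200
    p_nominal: float = 0.05
    min_datasets: int | None = None  # default: ceil(10/18 of accepted datasets)
    top_frac: float = 0.05
    k_dataset_clusters: int = 3
    k_feature_clusters: int = 3
    method: str = "gsea"
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0.5 <= self.pca_min <= 1.0):
            raise ValueError("pca_min must be in [0.5, 1]")
        if not (0 < self.top_frac <= 1):
            raise ValueError("top_frac must be in (0, 1]")
        if self.sig_min_overlap > self.sig_max_overlap:
            raise ValueError("sig_min_overlap > sig_max_overlap")
        if self.method not in {"gsea", "page", "gage"}:
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """Everything the stages produced, keyed for inspection and export."""

    qc_reports: list[SeparationReport]
    accepted: list[str]
    deg_sets: dict[str, frozenset[str]]
    deg_overlap: pd.DataFrame
    filtered_signatures: SignatureCollection
    profiles: dict[str, pd.DataFrame]
    selected_signatures: list[str]
    assignment: GenotypeAssignment
    genotype_datasets: dict[str, list[str]]
    cgs: dict[str, DerivedGeneSet]
    consistency: dict[str, SignatureConsistencySets]
    urg: dict[str, DerivedGeneSet]
    drg: dict[str, DerivedGeneSet]
    term_results: dict[str, pd.DataFrame]
    term_profile: pd.DataFrame | None


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(
    datasets: Sequence[ExpressionDataset],
    collection: SignatureCollection,
    terms: SignatureCollection | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage in memory and return the assembled results."""
    config = config or PipelineConfig()
    config.validate()

    # stage 1: PCA quality gate
    reports = [pca_separation_score(ds) for ds in datasets]
    accepted_reports, rejected = gate_datasets(reports, min_score=config.pca_min)
    accepted_names = [r.name for r in accepted_reports]
    for r in rejected:
        logger.info("qc: rejected %s (pca_score=%.3f)", r.name, r.pca_score)
    kept = [ds for ds in datasets if ds.name in set(accepted_names)]
    if not kept:
        raise RuntimeError("qc: no dataset passed the PCA gate")

    # stage 2: differential expression
    contrasts = {ds.name: compute_contrast(ds, config.fdr_max, config.fc_min) for ds in kept}
    deg_sets = {name: select_degs(res, config.fdr_max, config.fc_min)
                for name, res in contrasts.items()}
    overlap = deg_overlap_matrix(deg_sets)

    # stage 3: signature size filter against every platform universe
    universes = {ds.name: ds.genes for ds in kept}
    filtered = filter_signatures_by_overlap(
        collection, universes, config.sig_min_overlap, config.sig_max_overlap
    )
    logger.info("select: %d of %d signatures pass the %d-%d overlap filter",
                len(filtered), len(collection), config.sig_min_overlap, config.sig_max_overlap)

    # stage 4: per-dataset enrichment profiles
    enrich_seed = _stage_seed(config.seed, 4)
    profiles = {
        ds.name: profile_dataset(
            ds, filtered, method=config.method, n_perm=config.n_perm,
            seed=enrich_seed + i,
        )
        for i, ds in enumerate(kept)
    }

    # stage 5: cross-dataset signature selection and the profile matrix
    min_datasets = config.min_datasets
    if min_datasets is None:
        min_datasets = max(1, math.ceil(len(kept) * 10 / 18))
    selected = select_signatures_gsea(profiles, p_max=config.p_nominal,
                                      min_datasets=min_datasets)
    if not selected:
        raise RuntimeError("select: no signature passed the cross-dataset rule")
    profile = build_profile(selected, profiles, mode="gsa")

    # stage 6: two-way clustering into genotypes and signature clusters
    k_rows = min(config.k_dataset_clusters, profile.values.shape[0])
    k_cols = min(config.k_feature_clusters, profile.values.shape[1])
    if (k_rows, k_cols) != (config.k_dataset_clusters, config.k_feature_clusters):
        logger.warning("cluster: clamped (k_rows, k_cols) to (%d, %d)", k_rows, k_cols)
    assignment = two_way_cluster(profile, k_rows, k_cols)
    genotype_datasets = {
        f"T{label}": list(assignment.dataset_labels.index[assignment.dataset_labels == label])
        for label in sorted(assignment.dataset_labels.unique())
    }

    # stage 7: derived gene sets
    cgs = {}
    for label in sorted(assignment.feature_labels.unique()):
        members = list(assignment.feature_labels.index[assignment.feature_labels == label])
        cgs[f"CGS-{label}"] = extract_cgs(members, profiles, config.top_frac,
                                          label=f"CGS-{label}")
    consistency, urg, drg = {}, {}, {}
    for genotype, members in genotype_datasets.items():
        type_profiles = {name: profiles[name] for name in members}
        cons = rank_and_threshold_signatures(type_profiles, top_frac=config.top_frac)
        consistency[genotype] = cons
        up, down = select_urg_drg(cons, type_profiles, top_frac=config.top_frac,
                                  label=genotype)
        urg[genotype], drg[genotype] = up, down

    # stage 8: term enrichment of every derived set
    term_results: dict[str, pd.DataFrame] = {}
    term_profile = None
    if terms is not None and len(terms):
        universe = set.intersection(*[set(ds.genes) for ds in kept])
        derived_all = {**cgs,
                       **{s.label: s for s in urg.values()},
                       **{s.label: s for s in drg.values()}}
        for label, dset in derived_all.items():
            if dset.genes:
                term_results[label] = fisher_enrichment(dset.genes, terms, universe)
        if term_results:
            term_profile = compare_enrichment_profiles(term_results)

    return PipelineResult(
        qc_reports=reports,
        accepted=accepted_names,
        deg_sets=deg_sets,
        deg_overlap=overlap,
        filtered_signatures=filtered,
        profiles=profiles,
        selected_signatures=selected,
        assignment=assignment,
        genotype_datasets=genotype_datasets,
        cgs=cgs,
        consistency=consistency,
        urg=urg,
        drg=drg,
        term_results=term_results,
        term_profile=term_profile,
    )


def _export_profiles(profiles: Mapping[str, pd.DataFrame], outdir: Path) -> None:
    for name, frame in profiles.items():
        out = frame.copy()
        out["leading_edge"] = out["leading_edge"].map(
            lambda s: ";".join(sorted(s)) if isinstance(s, frozenset) else ""
        )
        write_table(out.reset_index(), outdir / f"enrichment_{name}.tsv")


def _export_derived(sets: Mapping[str, DerivedGeneSet], outdir: Path) -> None:
    for label, dset in sets.items():
        rows = [
            {"gene": g, "frequency": dset.frequency.get(g, 0),
             "n_contributing_signatures": len(dset.provenance)}
            for g in sorted(dset.genes)
        ]
        write_table(rows, outdir / f"genes_{label}.tsv",
                    columns=["gene", "frequency", "n_contributing_signatures"])


def run_all(config: PipelineConfig) -> PipelineResult:
    """File-level entry point: read manifest and GMTs, run every stage and
    write all result tables plus a machine-readable run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(config.manifest)
    datasets = load_manifest_datasets(manifest, root=Path(config.manifest).parent)
    collection = read_gmt(config.signatures_gmt)
    terms = read_gmt(config.terms_gmt) if config.terms_gmt else None

    result = run_pipeline(datasets, collection, terms, config)

    write_table(
        [
            {"name": r.name, "pca_score": r.pca_score, "n_misplaced": r.n_misplaced,
             "accepted": r.pca_score >= config.pca_min}
            for r in result.qc_reports
        ],
        outdir / "qc_scores.tsv",
    )
    write_table(
        [{"dataset": name, "n_degs": len(degs)} for name, degs in result.deg_sets.items()],
        outdir / "deg_counts.tsv",
    )
    result.deg_overlap.rename_axis("dataset").reset_index().pipe(
        write_table, outdir / "deg_overlap.tsv"
    )
    _export_profiles(result.profiles, outdir)
    write_table([{"signature": s} for s in result.selected_signatures],
                outdir / "selected_signatures.tsv", columns=["signature"])
    prof = build_profile(result.selected_signatures, result.profiles, mode="gsa")
    prof.values.rename_axis("dataset").reset_index().pipe(
        write_table, outdir / "profile_matrix.tsv"
    )
    result.assignment.dataset_labels.rename_axis("dataset").reset_index().pipe(
        write_table, outdir / "dataset_clusters.tsv"
    )
    result.assignment.feature_labels.rename_axis("signature").reset_index().pipe(
        write_table, outdir / "signature_clusters.tsv"
    )
    result.assignment.reordered.rename_axis("dataset").reset_index().pipe(
        write_table, outdir / "heatmap_matrix.tsv"
    )
    _export_derived(result.cgs, outdir)
    _export_derived(result.urg, outdir)
    _export_derived(result.drg, outdir)
    for genotype, cons in result.consistency.items():
        rows = [
            {"signature": s, "summed_neglogp": cons.summed_neglogp[s],
             "set": "PNS" if s in set(cons.pns) else ("NNS" if s in set(cons.nns) else "mixed")}
            for s in cons.top_signatures
        ]
        write_table(rows, outdir / f"pns_nns_{genotype}.tsv",
                    columns=["signature", "summed_neglogp", "set"])
    for label, frame in result.term_results.items():
        write_table(frame.reset_index(), outdir / f"term_enrichment_{label}.tsv")
    if result.term_profile is not None:
        result.term_profile.rename_axis("derived_set").reset_index().pipe(
            write_table, outdir / "term_profile.tsv"
        )

    run_manifest = {
        "package": "stemsig",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "n_datasets": len(datasets),
        "n_accepted": len(result.accepted),
        "n_signatures_filtered": len(result.filtered_signatures),
        "n_signatures_selected": len(result.selected_signatures),
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return result
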