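"""Synthetic multi-dataset expression collections with planted genotype
structure.

The generator emulates the statistical shape of a public-repository
meta-analysis: several matched test-vs-control contrasts per genotype, small
arms (3-15 samples each), Gaussian noise on the log2 scale, and directional
gene modules (e.g. a proliferation module up and an EMT module down in one
genotype, EMT up in another, both down in a third) planted into the test
samples.  The accompanying signature collection contains the planted modules
among random decoy signatures, so every pipeline stage - quality gating,
differential expression, enrichment scoring, clustering, derived gene sets -
can be exercised against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import ExpressionDataset, Manifest, ManifestEntry, SignatureCollection
from .qc import pca_separation_score

#: Study-condition defaults: three genotypes of three datasets each, 2,000
#: genes, 6v6 arms, module shift of 3x the noise standard deviation.
DEFAULT_GENOTYPES: tuple[tuple[str, int, dict[str, float]], ...] = (
    ("T1", 3, {"proliferation": +1.5, "emt": -1.5}),
    ("T2", 3, {"emt": +1.5}),
    ("T3", 3, {"proliferation": -1.5, "emt": -1.5}),
)


@dataclass
class SimulationConfig:
    """Parameters of the planted-module generator.

    ``genotypes`` maps each genotype label to a number of datasets and a
    dict of signed module effects (log2 units, applied to test samples
    only).  ``noise_sd``, ``baseline_mean`` and ``baseline_sd`` are log2
    units.  Defaults are the reference study conditions: 2,000 genes, three
    genotypes x three datasets, 6v6 arms, two 80-gene modules, effect size
    1.5 = 3 x noise_sd, 100 decoy signatures of 10-200 genes.
    """

    n_genes: int = 2000
    genotypes: Sequence[tuple[str, int, dict[str, float]]] = DEFAULT_GENOTYPES
    n_control: int = 6
    n_test: int = 6
    noise_sd: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    modules: Mapping[str, int] = field(
        default_factory=lambda: {"proliferation": 80, "emt": 80}
    )
    n_decoy_signatures: int = 500
    n_related_per_module: int = 10
    related_dilution_range: tuple[float, float] = (1.0, 2.0)
    signature_size_range: tuple[int, int] = (10, 200)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_control <= 0 or self.n_test <= 0:
            raise ValueError("counts must be positive")
        if sum(self.modules.values()) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        lo, hi = self.signature_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("signature_size_range must lie within [1, n_genes]")
        for label, n_ds, effects in self.genotypes:
            if n_ds <= 0:
                raise ValueError(f"genotype {label}: n_datasets must be positive")
            unknown = set(effects) - set(self.modules)
            if unknown:
                raise ValueError(f"genotype {label}: unknown modules {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What was planted: dataset genotype labels, module membership and the
    signed per-genotype effect of each module."""

    dataset_genotype: dict[str, str]
    module_genes: dict[str, frozenset[str]]
    effects: dict[str, dict[str, float]]  # genotype -> module -> delta


def _subrng(seed: int, *indices: int) -> np.random.Generator:
    """Deterministic sub-stream: master seed plus indexed offsets."""
    return np.random.default_rng(np.random.SeedSequence([seed, *indices]))


def generate_collection(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], SignatureCollection, GroundTruth]:
    """Generate datasets, a signature collection and the ground truth.

    Per gene g and sample s the value is ``baseline_g + delta_m * [g in
    module m and s in test] + Normal(0, noise_sd)`` with ``baseline_g ~
    Normal(baseline_mean, baseline_sd)`` drawn once and shared across
    datasets.  The signature collection holds the planted modules, a number
    of module-related signatures per module (the module diluted with a
    random amount of off-module padding, emulating the redundancy of curated
    collections where many gene sets describe the same process at varying
    specificity), and ``n_decoy_signatures`` sets drawn uniformly from
    non-module genes.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = _subrng(config.seed, 0)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    shuffled = list(rng.permutation(genes))
    module_genes: dict[str, frozenset[str]] = {}
    cursor = 0
    for module, size in config.modules.items():
        module_genes[module] = frozenset(shuffled[cursor : cursor + size])
        cursor += size
    non_module = np.array(sorted(set(genes) - set().union(*module_genes.values())
                                 if module_genes else set(genes)))

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    datasets: list[ExpressionDataset] = []
    dataset_genotype: dict[str, str] = {}
    effects: dict[str, dict[str, float]] = {}
    ds_counter = 0
    for label, n_ds, module_effects in config.genotypes:
        effects[label] = dict(module_effects)
        for rep in range(n_ds):
            ds_counter += 1
            name = f"{label}_ds{rep + 1}"
            ds_rng = _subrng(config.seed, 1, ds_counter)
            n_s = config.n_control + config.n_test
            values = baseline[:, None] + ds_rng.normal(
                0.0, config.noise_sd, size=(config.n_genes, n_s)
            )
            for module, delta in module_effects.items():
                rows = [gene_index[g] for g in module_genes[module]]
                values[np.ix_(rows, range(config.n_control, n_s))] += delta
            samples = [f"{name}_c{i + 1}" for i in range(config.n_control)] + [
                f"{name}_t{i + 1}" for i in range(config.n_test)
            ]
            datasets.append(
                ExpressionDataset(
                    name=name,
                    genes=list(genes),
                    samples=samples,
                    values=values,
                    control_ids=samples[: config.n_control],
                    test_ids=samples[config.n_control :],
                )
            )
            dataset_genotype[name] = label

    sig_rng = _subrng(config.seed, 2)
    signatures: dict[str, frozenset[str]] = {
        f"MODULE_{m.upper()}": gs for m, gs in module_genes.items()
    }
    dil_lo, dil_hi = config.related_dilution_range
    for module, genes_m in module_genes.items():
        for i in range(config.n_related_per_module):
            dilution = sig_rng.uniform(dil_lo, dil_hi)
            n_pad = int(round((dilution - 1.0) * len(genes_m)))
            pad = sig_rng.choice(non_module, size=min(n_pad, len(non_module)), replace=False)
            signatures[f"SIG_{module.upper()}_R{i:02d}"] = genes_m | frozenset(pad)
    lo, hi = config.signature_size_range
    hi_eff = min(hi, len(non_module))
    for i in range(config.n_decoy_signatures):
        size = int(sig_rng.integers(lo, hi_eff + 1))
        members = sig_rng.choice(non_module, size=size, replace=False)
        signatures[f"DECOY_{i:04d}"] = frozenset(members)
    collection = SignatureCollection(signatures, source_description="synthetic")

    truth = GroundTruth(
        dataset_genotype=dataset_genotype,
        module_genes=module_genes,
        effects=effects,
    )
    return datasets, collection, truth


def degrade_separation(
    dataset: ExpressionDataset,
    k_misplaced: int,
    seed: int,
    max_retries: int = 200,
) -> ExpressionDataset:
    """Return a copy of ``dataset`` in which exactly ``k_misplaced`` samples'
    expression vectors are replaced by draws from the opposite group's
    generating distribution, so the best principal-component bipartition
    misclassifies exactly ``k_misplaced`` of them.

    The opposite group's distribution is estimated from the data (per-gene
    group mean, pooled within-group standard deviation).  The result is
    verified by re-scoring; when the scored misplaced count differs the draw
    is repeated with a fresh sub-seed, up to ``max_retries`` times.  Beyond
    half the samples the best-assignment convention flips, so a fully
    swapped dataset scores 1.0 again.
    """
    n = dataset.n_samples
    if not 0 <= k_misplaced <= n:
        raise ValueError(f"k_misplaced must be in [0, {n}]")
    expected = min(k_misplaced, n - k_misplaced)
    if k_misplaced == 0:
        report = pca_separation_score(dataset)
        if report.n_misplaced != 0:
            raise ValueError(
                f"{dataset.name}: not cleanly separated to begin with "
                f"(n_misplaced={report.n_misplaced}); increase the effect size"
            )
        return dataset

    is_control = dataset.is_control()
    ctrl_mean = dataset.values[:, is_control].mean(axis=1)
    test_mean = dataset.values[:, ~is_control].mean(axis=1)
    pooled_sd = np.sqrt(
        0.5
        * (
            dataset.values[:, is_control].var(axis=1, ddof=1)
            + dataset.values[:, ~is_control].var(axis=1, ddof=1)
        )
    )

    for attempt in range(max_retries):
        rng = _subrng(seed, 3, attempt)
        chosen = rng.choice(n, size=k_misplaced, replace=False)
        values = dataset.values.copy()
        for j in chosen:
            opposite_mean = test_mean if is_control[j] else ctrl_mean
            values[:, j] = rng.normal(opposite_mean, pooled_sd)
        candidate = ExpressionDataset(
            name=dataset.name,
            genes=list(dataset.genes),
            samples=list(dataset.samples),
            values=values,
            control_ids=list(dataset.control_ids),
            test_ids=list(dataset.test_ids),
        )
        if pca_separation_score(candidate).n_misplaced == expected:
            return candidate
    raise RuntimeError(
        f"{dataset.name}: could not realize exactly {k_misplaced} misplaced samples "
        f"in {max_retries} attempts; use a larger planted effect size"
    )


def generate_term_collection(
    truth: GroundTruth,
    n_terms: int,
    seed: int,
    jaccard_levels: Sequence[float] = (1.0, 0.5, 0.25),
    universe: Sequence[str] | None = None,
) -> SignatureCollection:
    """Build a GO/KEGG-style term collection around the planted modules.

    For each module and each requested Jaccard level a term is created that
    overlaps the module at that level (the module genes padded with
    off-module genes); the remaining terms are random decoys disjoint from
    the modules when possible.
    """
    rng = _subrng(seed, 4)
    module_union = set().union(*truth.module_genes.values())
    if universe is None:
        universe = sorted(module_union)
        # fall back to padding names when no wider universe is supplied
        universe += [f"PAD{i:05d}" for i in range(2000)]
    pool = np.array(sorted(set(universe) - module_union))
    terms: dict[str, frozenset[str]] = {}
    for module, genes in truth.module_genes.items():
        size = len(genes)
        for level in jaccard_levels:
            extra = int(round(size * (1.0 / level - 1.0)))
            extra = min(extra, len(pool))
            padding = rng.choice(pool, size=extra, replace=False) if extra else []
            terms[f"TERM_{module.upper()}_J{int(level * 100):03d}"] = frozenset(genes) | frozenset(
                padding
            )
    i = 0
    while len(terms) < n_terms:
        size = int(rng.integers(10, min(200, len(pool)) + 1))
        terms[f"TERM_DECOY_{i:04d}"] = frozenset(rng.choice(pool, size=size, replace=False))
        i += 1
    return SignatureCollection(terms, source_description="synthetic terms")
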