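"""Readers and writers for the formats the pipeline touches.

GMT signature files (the MSigDB distribution format), expression matrices as
TSV (first column ``gene``, remaining columns sample identifiers, values on
the log2 scale), dataset manifests, and generic result tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to its expected format."""


@dataclass
class ExpressionDataset:
    """One matched contrast: a log2 expression matrix with a control/test
    partition of its samples.

    Parameters
    ----------
    name : str
        Dataset identifier.
    genes : list of str
        Row labels; unique gene symbols (case-sensitive, no aliasing).
    samples : list of str
        Column labels.
    values : ndarray of shape (n_genes, n_samples)
        log2 expression, no missing values.
    control_ids, test_ids : list of str
        Disjoint, non-empty subsets of ``samples`` that together cover it.
    """

    name: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    control_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"{self.name}: matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.name}: duplicate gene symbols")
        control, test = set(self.control_ids), set(self.test_ids)
        if not control or not test:
            raise ValueError(f"{self.name}: control and test groups must be non-empty")
        if control & test:
            raise ValueError(f"{self.name}: control/test overlap: {sorted(control & test)}")
        if control | test != set(self.samples):
            raise ValueError(f"{self.name}: control+test must cover all samples")
        if np.isnan(self.values).any():
            raise ValueError(f"{self.name}: matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def _cols(self, ids: Sequence[str]) -> np.ndarray:
        index = {s: j for j, s in enumerate(self.samples)}
        return np.array([index[s] for s in ids], dtype=int)

    @property
    def control_values(self) -> np.ndarray:
        return self.values[:, self._cols(self.control_ids)]

    @property
    def test_values(self) -> np.ndarray:
        return self.values[:, self._cols(self.test_ids)]

    def is_control(self) -> np.ndarray:
        """Boolean mask over ``samples``: True for control columns."""
        control = set(self.control_ids)
        return np.array([s in control for s in self.samples], dtype=bool)


@dataclass
class SignatureCollection:
    """Named gene sets, e.g. molecular signatures or GO/KEGG-style terms."""

    signatures: dict[str, frozenset[str]]
    source_description: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.signatures.items():
            fs = frozenset(genes)
            if not fs:
                raise ValueError(f"signature {name!r} is empty")
            clean[name] = fs
        self.signatures = clean

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.signatures[name]

    def subset(self, names: Iterable[str]) -> "SignatureCollection":
        names = list(names)
        return SignatureCollection(
            {n: self.signatures[n] for n in names}, self.source_description
        )


@dataclass
class ManifestEntry:
    name: str
    path: str
    control_ids: list[str]
    test_ids: list[str]


@dataclass
class Manifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate dataset names in manifest")


def read_gmt(path: str | Path) -> SignatureCollection:
    """Parse a GMT file: one signature per line, tab-separated
    ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are collapsed; empty gene fields dropped.
    A line with fewer than three fields, or a repeated signature name, is an
    error.
    """
    path = Path(path)
    signatures: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in signatures:
                raise FormatError(f"{path}:{lineno}: duplicate signature name {name!r}")
            genes = frozenset(g for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: signature {name!r} has no genes")
            signatures[name] = genes
    return SignatureCollection(signatures, source_description=str(path))


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes within a line sorted for stability."""
    with Path(path).open("w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source_description or "na", *sorted(genes)]))
            fh.write("\n")


def read_expression(
    path: str | Path,
    control_ids: Sequence[str],
    test_ids: Sequence[str],
    name: str | None = None,
    apply_log2: bool = False,
) -> ExpressionDataset:
    """Load an expression TSV as an :class:`ExpressionDataset`.

    Rows sharing a gene symbol are collapsed by mean (probe-to-gene
    stand-in); rows containing any missing value are dropped, since every
    downstream statistic assumes complete rows.  Values are assumed to be on
    the log2 scale already; pass ``apply_log2=True`` to transform raw
    intensities as log2(x + 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    header = list(frame.columns)
    missing = [s for s in [*control_ids, *test_ids] if s not in header]
    if missing:
        raise FormatError(f"{path}: sample ids not in header: {missing}")
    frame = frame[[*control_ids, *test_ids]]
    frame = frame.dropna(axis=0, how="any")
    frame.index = frame.index.astype(str)
    frame = frame.groupby(level=0, sort=False).mean()
    values = frame.to_numpy(dtype=float)
    if apply_log2:
        values = np.log2(values + 1.0)
    return ExpressionDataset(
        name=name or path.stem,
        genes=list(frame.index),
        samples=list(frame.columns),
        values=values,
        control_ids=list(control_ids),
        test_ids=list(test_ids),
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    frame = pd.DataFrame(dataset.values, index=dataset.genes, columns=dataset.samples)
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t", float_format="%.8g")


def read_manifest(path: str | Path) -> Manifest:
    """Manifest TSV with columns name, file, control, test; sample ids
    within the control/test fields joined by commas."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "file", "control", "test"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    entries = [
        ManifestEntry(
            name=row["name"],
            path=row["file"],
            control_ids=row["control"].split(","),
            test_ids=row["test"].split(","),
        )
        for _, row in frame.iterrows()
    ]
    return Manifest(entries)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    rows = [
        {
            "name": e.name,
            "file": e.path,
            "control": ",".join(e.control_ids),
            "test": ",".join(e.test_ids),
        }
        for e in manifest.entries
    ]
    pd.DataFrame(rows, columns=["name", "file", "control", "test"]).to_csv(
        path, sep="\t", index=False
    )


def load_manifest_datasets(manifest: Manifest, root: str | Path = ".") -> list[ExpressionDataset]:
    root = Path(root)
    return [
        read_expression(root / e.path, e.control_ids, e.test_ids, name=e.name)
        for e in manifest.entries
    ]


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (a DataFrame or an iterable of dicts sharing a schema)
    as a TSV with header.  Numbers are serialized with 8 significant digits
    so tables round-trip through :func:`read_table` without loss of keys.
    An empty record list yields a header-only file (pass ``columns`` to name
    the header when no record carries it)."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        frame = pd.DataFrame(records, columns=columns)
        if not records and columns is None:
            raise ValueError("cannot infer a header from an empty record list; pass columns=")
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
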