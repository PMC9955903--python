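"""Synthetic microarray generation and CuMiDa-dialect CSV I/O.

The on-disk dialect mirrors the curated microarray benchmarks (CuMiDa):
samples as rows, a sample-identifier column, a class column named ``type``,
and one column per gene/probe accession holding continuous log-scale
expression values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "SyntheticSpec",
    "generate_dataset",
    "read_cumida_csv",
    "write_cumida_csv",
]


@dataclass
class ExpressionDataset:
    """A sample x gene expression matrix with binary class labels.

    Labels use the encoding 0 = normal, 1 = primary tumor. All values must
    be finite; gene identifiers must be unique (duplicates are deduplicated
    at ingest, see :func:`read_cumida_csv`).
    """

    sample_ids: list
    gene_ids: list
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, g = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for a {n}-row matrix"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for a {g}-column matrix"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if self.labels.shape != (n,):
            raise ValueError("labels must be one code per sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must take values in {0, 1}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must all be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict:
        """Number of samples per class code, e.g. ``{0: 10, 1: 176}``."""
        return {int(c): int((self.labels == c).sum()) for c in (0, 1)}

    def gene_index(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def select_genes(self, gene_ids) -> "ExpressionDataset":
        idx = self.gene_index(gene_ids)
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
            labels=self.labels.copy(),
        )

    def subset_samples(self, indices) -> "ExpressionDataset":
        indices = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in indices],
            gene_ids=list(self.gene_ids),
            values=self.values[indices].copy(),
            labels=self.labels[indices].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.gene_ids)
        frame.insert(0, "type", self.labels)
        frame.insert(0, "samples", self.sample_ids)
        return frame


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic two-class microarray generator.

    Defaults emulate the curated breast-cancer benchmark the pipeline was
    designed around: a heavily imbalanced two-class cohort (176 tumor vs 10
    normal samples), many more genes than samples, log-scale expression with
    per-gene base means in [4, 13] and SDs in [0.1, 1.3], and a small planted
    set of genes whose class means differ by ``effect_sizes`` expression
    units (positive shifts raise the tumor-class mean).
    """

    n_tumor: int = 176
    n_normal: int = 10
    n_genes: int = 500
    n_informative: int = 6
    effect_sizes: tuple = None
    base_mean_range: tuple = (4.0, 13.0)
    base_sd_range: tuple = (0.1, 1.3)
    seed: int = 0

    def __post_init__(self):
        if self.effect_sizes is None:
            self.effect_sizes = tuple([0.8] * self.n_informative)
        self.effect_sizes = tuple(float(e) for e in self.effect_sizes)
        if min(self.n_tumor, self.n_normal, self.n_genes, self.n_informative) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if len(self.effect_sizes) != self.n_informative:
            raise ValueError("effect_sizes must have length n_informative")
        if not (0 < self.base_sd_range[0] <= self.base_sd_range[1]):
            raise ValueError("base_sd_range must be strictly positive")


def generate_dataset(spec: SyntheticSpec) -> ExpressionDataset:
    """Generate a synthetic two-class expression dataset.

    Every gene g is drawn i.i.d. Normal(mu_g, sd_g) with mu_g ~ U(base mean
    range) and sd_g ~ U(base SD range). For the ``n_informative`` planted
    genes the tumor-class mean is shifted by the corresponding effect size.
    Bit-reproducible for a fixed seed: the RNG is consumed in the order
    base means, base SDs, informative gene choice, noise matrix.
    """
    if spec.n_genes == 0:
        raise ValueError("cannot generate a dataset with zero genes")
    n_total = spec.n_tumor + spec.n_normal
    if n_total == 0:
        raise ValueError("cannot generate a dataset with zero samples")

    rng = np.random.default_rng(spec.seed)
    means = rng.uniform(*spec.base_mean_range, size=spec.n_genes)
    sds = rng.uniform(*spec.base_sd_range, size=spec.n_genes)
    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )

    labels = np.concatenate(
        [np.ones(spec.n_tumor, dtype=int), np.zeros(spec.n_normal, dtype=int)]
    )
    values = means + sds * rng.standard_normal((n_total, spec.n_genes))
    for g, effect in zip(informative, spec.effect_sizes):
        values[labels == 1, g] += effect

    return ExpressionDataset(
        sample_ids=[f"sample_{i + 1}" for i in range(n_total)],
        gene_ids=[f"G{i + 1:06d}" for i in range(spec.n_genes)],
        values=values,
        labels=labels,
    )


def informative_gene_ids(spec: SyntheticSpec) -> list:
    """Gene ids of the planted informative genes for ``spec``.

    Replays the generator's RNG stream, so it is exact for any seed.
    """
    rng = np.random.default_rng(spec.seed)
    rng.uniform(*spec.base_mean_range, size=spec.n_genes)
    rng.uniform(*spec.base_sd_range, size=spec.n_genes)
    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    return [f"G{i + 1:06d}" for i in informative]


def _dedupe_gene_ids(names):
    """Suffix repeated gene ids with an occurrence index (a_2, a_3, ...)."""
    seen: dict = {}
    out = []
    for name in names:
        count = seen.get(name, 0) + 1
        seen[name] = count
        out.append(name if count == 1 else f"{name}_{count}")
    return out


def default_label_map(value) -> int:
    """Map a class string to {0, 1}: 'normal' (case-insensitive) is 0,
    anything else is tumor (1). Numeric 0/1 pass through."""
    text = str(value).strip()
    if text in ("0", "1"):
        return int(text)
    return 0 if text.lower() == "normal" else 1


def read_cumida_csv(path, label_map=None, sample_column: str = "samples") -> ExpressionDataset:
    """Read a CuMiDa-dialect CSV into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path : path-like
        CSV with a header row, a class column named ``type``, an optional
        sample-identifier column, and gene columns.
    label_map : dict or callable, optional
        Class-string mapping. A dict must cover every label present;
        the default maps "normal" to 0 and anything else to 1.
    sample_column : str
        Name of the sample-identifier column (preserved as ``sample_ids``
        and excluded from the matrix). Row numbers are used if absent.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n\r").split(",")
    if "type" not in header:
        raise ValueError(f"{path}: missing mandatory class column 'type'")

    names = _dedupe_gene_ids(header)
    frame = pd.read_csv(path, skiprows=1, names=names, dtype=str)

    labels_raw = frame.pop("type")
    if sample_column in frame.columns:
        sample_ids = frame.pop(sample_column).tolist()
    else:
        sample_ids = [f"row_{i + 1}" for i in range(len(frame))]
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found")

    if label_map is None:
        mapper = default_label_map
    elif callable(label_map):
        mapper = label_map
    else:
        def mapper(value, _table=dict(label_map)):
            if value not in _table:
                raise KeyError(value)
            return _table[value]
    try:
        labels = np.array([int(mapper(v)) for v in labels_raw])
    except KeyError as exc:
        raise ValueError(
            f"{path}: class label {exc.args[0]!r} has no mapping to {{0, 1}}"
        ) from None

    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric gene expression cell ({exc})") from None

    return ExpressionDataset(
        sample_ids=sample_ids,
        gene_ids=list(frame.columns),
        values=values,
        labels=labels,
    )


def write_cumida_csv(dataset: ExpressionDataset, path, float_format: str = "%.12g") -> None:
    """Write ``dataset`` in the dialect :func:`read_cumida_csv` accepts.

    Class codes are written back as the strings "normal" / "tumor" so the
    round trip through the default label map is the identity.
    """
    if dataset.n_genes == 0:
        raise ValueError("refusing to write a dataset with no genes")
    frame = dataset.to_frame()
    frame["type"] = np.where(dataset.labels == 0, "normal", "tumor")
    frame.to_csv(path, index=False, float_format=float_format)
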