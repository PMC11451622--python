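"""Core data model and tabular I/O for deconvolved tumor-expression cohorts.

The central object is the :class:`DeconvolvedCohort`: one expression matrix
per cell type (all sharing the same samples), a per-gene × per-cell-type
deconvolution confidence matrix in [0, 1], and a sample × cell-type fraction
matrix whose rows sum to one.  Everything is plain-text (TSV/CSV) on disk;
a cohort is persisted as a directory with a YAML manifest naming its parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The nine-cell-type reference set used for breast tumor deconvolution.
REFERENCE_CELL_TYPES = (
    "B-cells",
    "CAFs",
    "malignant",
    "endothelial",
    "myeloid",
    "normal-epithelial",
    "plasmablasts",
    "PVL",
    "T-cells",
)

VALID_SCALE_TAGS = ("tpm", "log2tpm1")


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected layout."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep)


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    scale_tag
        ``"tpm"`` for linear non-negative values, ``"log2tpm1"`` for
        log2(TPM + 1)-scaled values.
    """

    values: pd.DataFrame
    scale_tag: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale_tag not in VALID_SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.values = self.values.astype(float)
        if self.scale_tag == "tpm" and (self.values.values < 0).any():
            raise ValueError("TPM-scaled expression must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(x + 1) view; identity if already log-scaled."""
        if self.scale_tag == "log2tpm1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), "log2tpm1")

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale_tag)

    def write(self, path: str | Path) -> None:
        _write_table(self.values, path)


@dataclass
class ResponseLabels:
    """Binary per-sample outcome labels (1 = responder)."""

    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.labels.index.is_unique:
            raise ValueError("duplicate sample ids in labels")
        vals = set(pd.unique(self.labels))
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(vals)}")
        self.labels = self.labels.astype(np.int8)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def values(self) -> np.ndarray:
        return self.labels.to_numpy()

    def require_both_classes(self) -> None:
        if self.labels.nunique() < 2:
            raise ValueError(
                "supervised operation requires both classes; "
                f"got a single class ({int(self.labels.iloc[0])})"
            )

    def align_to(self, sample_ids: Sequence[str]) -> "ResponseLabels":
        """Restrict to samples present in a companion matrix, warning on drops."""
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        dropped = len(self.labels) - len(keep)
        if dropped:
            logger.warning(
                "dropping %d labeled sample(s) absent from expression data", dropped
            )
        return ResponseLabels(self.labels.loc[keep])

    def write(self, path: str | Path) -> None:
        self.labels.rename("label").to_frame().to_csv(path, sep="\t")


@dataclass
class DeconvolvedCohort:
    """Deconvolution output for one cohort.

    ``expression`` maps each cell type to a genes × samples
    :class:`ExpressionMatrix` (same sample set across cell types unless
    ``strict=False``, as for single-cell-harmonized cohorts in which a
    patient may lack cells of some type).  ``confidence`` is a gene ×
    cell-type matrix of deconvolution confidence scores in [0, 1];
    ``fractions`` is a sample × cell-type matrix whose rows sum to one.
    """

    cell_types: list[str]
    expression: dict[str, ExpressionMatrix]
    confidence: pd.DataFrame
    fractions: pd.DataFrame
    strict: bool = True

    def __post_init__(self) -> None:
        missing = [ct for ct in self.cell_types if ct not in self.expression]
        if missing:
            raise ValueError(f"no expression matrix for cell type(s) {missing}")
        sample_sets = {ct: tuple(self.expression[ct].sample_ids) for ct in self.cell_types}
        if self.strict and len(set(sample_sets.values())) > 1:
            raise ValueError("per-cell-type matrices must share the same sample set")
        conf = self.confidence.astype(float)
        if ((conf.values < 0) | (conf.values > 1)).any():
            raise ValueError("confidence scores must lie in [0, 1]")
        self.confidence = conf
        frac = self.fractions.astype(float)
        sums = frac.sum(axis=1)
        if (np.abs(sums - 1.0) > 1e-3).any():
            bad = sums[np.abs(sums - 1.0) > 1e-3]
            raise ValueError(
                f"fraction rows must sum to 1 within 1e-3; offenders: {list(bad.index)[:5]}"
            )
        # renormalize small drift; rows already summing to 1 are left
        # untouched so exact ties between samples survive
        drift = np.abs(sums - 1.0) > 1e-12
        if drift.any():
            frac.loc[drift] = frac.loc[drift].div(sums[drift], axis=0)
        self.fractions = frac

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression[self.cell_types[0]].sample_ids)

    def confidence_column(self, cell_type: str) -> pd.Series:
        if cell_type not in self.confidence.columns:
            raise KeyError(f"no confidence column for cell type {cell_type!r}")
        return self.confidence[cell_type]


@dataclass
class SingleCellCohort:
    """Single-cell expression with per-cell patient and cell-type annotations.

    ``expression`` is cells × genes (non-negative, linear scale);
    ``patient_ids`` and ``cell_types`` are per-cell Series sharing the cell
    index; ``patient_labels`` optionally carries per-patient outcomes.
    """

    expression: pd.DataFrame
    patient_ids: pd.Series
    cell_types: pd.Series
    patient_labels: ResponseLabels | None = None

    def __post_init__(self) -> None:
        if not (
            self.expression.index.equals(self.patient_ids.index)
            and self.expression.index.equals(self.cell_types.index)
        ):
            raise ValueError("per-cell annotations must share the cell index")
        if self.patient_ids.isna().any() or self.cell_types.isna().any():
            raise ValueError("every cell needs a patient and a cell-type annotation")
        if (self.expression.values < 0).any():
            raise ValueError("single-cell expression must be non-negative")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def patients(self) -> list[str]:
        return list(pd.unique(self.patient_ids))

    @property
    def cell_type_set(self) -> list[str]:
        return list(pd.unique(self.cell_types))


@dataclass(frozen=True)
class LRPairList:
    """Ordered, de-duplicated list of (ligand_gene, receptor_gene) pairs."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("L-R pairs must be unique")
        for lg, rg in self.pairs:
            if not lg or not rg:
                raise ValueError("gene symbols must be non-empty")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for lg, rg in self.pairs:
            seen.setdefault(lg)
            seen.setdefault(rg)
        return list(seen)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_expression_table(path: str | Path, scale_tag: str = "tpm") -> ExpressionMatrix:
    """Read a delimited genes × samples table.

    The first column holds gene ids and the header row sample ids.
    Duplicate gene rows are collapsed by their mean (logged); any
    non-numeric or missing cell is a :class:`FormatError`.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    header = path.read_text().splitlines()[0].rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise FormatError(f"{path}: duplicate sample ids in header")
    df = _read_table(path)
    if df.columns.isna().any() or any(str(c).startswith("Unnamed") for c in df.columns):
        raise FormatError(f"{path}: missing or malformed header row")
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell in expression table") from exc
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression table")
    if not df.index.is_unique:
        n_dup = len(df.index) - df.index.nunique()
        logger.info("collapsing %d duplicate gene row(s) by mean in %s", n_dup, path)
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df, scale_tag)


def counts_to_tpm(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert read counts to TPM given per-gene lengths in bases.

    For each sample, TPM_g = 1e6 · (count_g / len_g) / Σ_j (count_j / len_j).
    """
    lengths = pd.Series(
        {g: float(gene_lengths[g]) for g in counts.gene_ids}, dtype=float
    )
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise ValueError(f"gene lengths must be positive; offenders: {bad}")
    rate = counts.values.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum <= 0).any():
        bad = list(colsum.index[colsum <= 0])[:5]
        raise ValueError(f"all-zero sample column(s): {bad}")
    tpm = rate.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, "tpm")


def load_response_labels(path: str | Path, positive_token: str) -> ResponseLabels:
    """Read a two-column (sample, outcome token) table into binary labels."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] != 1:
        raise FormatError(f"{path}: expected exactly one outcome column")
    tokens = df.iloc[:, 0]
    labels = (tokens == positive_token).astype(np.int8)
    logger.info(
        "mapped outcome tokens %s -> 1 for %r, 0 otherwise (%d/%d positive)",
        sorted(set(tokens)), positive_token, int(labels.sum()), len(labels),
    )
    return ResponseLabels(labels)


def load_lr_pairs(path: str | Path) -> LRPairList:
    """Read a two-column ligand/receptor table into a de-duplicated pair list."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty ligand-receptor list")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (ligand, receptor)")
    seen: dict[tuple[str, str], None] = {}
    for lg, rg in zip(df.iloc[:, 0], df.iloc[:, 1]):
        seen.setdefault((str(lg), str(rg)))
    return LRPairList(tuple(seen))


def write_lr_pairs(lr: LRPairList, path: str | Path) -> None:
    pd.DataFrame(list(lr.pairs), columns=["ligand", "receptor"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cohort bundles (directory + YAML manifest)
# ---------------------------------------------------------------------------

def write_cohort_bundle(
    cohort: DeconvolvedCohort,
    path: str | Path,
    labels: ResponseLabels | None = None,
    bulk: ExpressionMatrix | None = None,
) -> None:
    """Persist a deconvolved cohort as a directory of TSVs with a manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cell_types": list(cohort.cell_types),
        "expression": {},
        "confidence": "confidence.tsv",
        "fractions": "fractions.tsv",
        "scale_tag": cohort.expression[cohort.cell_types[0]].scale_tag,
    }
    for ct in cohort.cell_types:
        fname = f"expression_{ct.replace('/', '_').replace(' ', '_')}.tsv"
        cohort.expression[ct].write(path / fname)
        manifest["expression"][ct] = fname
    _write_table(cohort.confidence, path / "confidence.tsv")
    _write_table(cohort.fractions, path / "fractions.tsv")
    if labels is not None:
        labels.write(path / "labels.tsv")
        manifest["labels"] = "labels.tsv"
    if bulk is not None:
        bulk.write(path / "bulk.tsv")
        manifest["bulk"] = "bulk.tsv"
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_cohort_bundle(
    path: str | Path,
) -> tuple[DeconvolvedCohort, ResponseLabels | None, ExpressionMatrix | None]:
    """Load a cohort bundle written by :func:`write_cohort_bundle`."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    scale_tag = manifest.get("scale_tag", "tpm")
    expression = {
        ct: load_expression_table(path / fname, scale_tag)
        for ct, fname in manifest["expression"].items()
    }
    confidence = _read_table(path / manifest["confidence"])
    fractions = _read_table(path / manifest["fractions"])
    cohort = DeconvolvedCohort(
        cell_types=list(manifest["cell_types"]),
        expression=expression,
        confidence=confidence,
        fractions=fractions,
    )
    labels = None
    if "labels" in manifest:
        lab = pd.read_csv(path / manifest["labels"], sep="\t", index_col=0)
        labels = ResponseLabels(lab.iloc[:, 0])
    bulk = None
    if "bulk" in manifest:
        bulk = load_expression_table(path / manifest["bulk"], scale_tag)
    return cohort, labels, bulk
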