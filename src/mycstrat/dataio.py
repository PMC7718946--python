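"""Readers and writers for the tabular formats the pipeline touches.

Supported formats:

* tab-delimited expression matrix (header row = sample IDs, column 1 = gene ID)
* GCT version ``#1.2``
* GMT gene-set collections
* CLS binary phenotype labels
* tab-delimited drug-response tables (drug x cell line, % of control viability,
  optionally replicated rows)

All writers emit UTF-8, LF line endings and ``repr``-exact floats so that a
write/read round trip reproduces values bit-exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "PhenotypeLabels",
    "DrugResponseTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_phenotype",
    "write_phenotype",
    "read_drug_table",
    "write_drug_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _fmt(x: float) -> str:
    """repr-exact float formatting (ints without trailing .0 are kept as float repr)."""
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    return repr(float(x))


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes x samples.

    ``values[i, j]`` is the expression of ``gene_ids[i]`` in ``sample_ids[j]``.
    ``metadata`` is a free-form string map (e.g. per-sample subtype labels
    serialized elsewhere); it travels with the matrix but is not written by
    the TSV/GCT writers.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample IDs")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: "set[str] | list[str]", case_fold: bool = False) -> "ExpressionMatrix":
        """Rows restricted to ``genes`` (file order preserved); missing genes dropped.

        With ``case_fold`` gene symbols are matched case-insensitively, which
        aligns murine symbols (``Myc``) with human ones (``MYC``).
        """
        if case_fold:
            wanted = {g.casefold() for g in genes}
            keep = [i for i, g in enumerate(self.gene_ids) if g.casefold() in wanted]
        else:
            wanted = set(genes)
            keep = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        missing = len(set(genes)) - len(keep)
        if missing:
            logger.info("subset_genes: %d requested genes absent from matrix", missing)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.values[keep, :],
            dict(self.metadata),
        )


@dataclass
class GeneSet:
    """A named gene list (e.g. one MYC target signature)."""

    name: str
    genes: set[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set with empty name")
        self.genes = set(self.genes)
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PhenotypeLabels:
    """Binary class labels per sample; ``class_names[0]`` is the positive class."""

    sample_ids: list[str]
    labels: list[str]
    class_names: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise FormatError("label count does not match sample count")
        classes = set(self.labels)
        if classes != set(self.class_names) or len(self.class_names) != 2:
            raise FormatError(
                f"expected exactly the two classes {self.class_names}, got labels {sorted(classes)}"
            )

    def mask(self) -> np.ndarray:
        """Boolean array, True for the positive (first-named) class."""
        return np.array([lab == self.class_names[0] for lab in self.labels])

    def aligned_to(self, sample_ids: list[str]) -> "PhenotypeLabels":
        """Re-order labels to ``sample_ids``, joining by ID."""
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise FormatError(f"samples without phenotype label: {missing[:5]}")
        return PhenotypeLabels(list(sample_ids), [lookup[s] for s in sample_ids], self.class_names)


@dataclass
class DrugResponseTable:
    """Viability (% of control) for drugs x cell lines, with optional replicates.

    ``viability`` has shape (n_drugs, n_lines, n_replicates); missing wells are
    NaN. ``dose`` is the per-drug concentration in nM (a single screen dose is
    one value repeated).
    """

    drug_ids: list[str]
    cell_line_ids: list[str]
    viability: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.ndim == 2:
            self.viability = self.viability[:, :, None]
        self.dose = np.atleast_1d(np.asarray(self.dose, dtype=float))
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise FormatError("duplicate drug IDs")
        if len(set(self.cell_line_ids)) != len(self.cell_line_ids):
            raise FormatError("duplicate cell line IDs")
        if self.viability.shape[:2] != (len(self.drug_ids), len(self.cell_line_ids)):
            raise FormatError("viability shape does not match drug/line IDs")
        if np.nanmin(self.viability, initial=0.0) < 0:
            raise FormatError("negative viability")
        if np.any(self.dose <= 0):
            raise FormatError("doses must be positive")

    @property
    def n_replicates(self) -> int:
        return self.viability.shape[2]

    def mean_viability(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate means and effective n per (drug, line), NaN wells excluded."""
        n_eff = np.sum(~np.isnan(self.viability), axis=2)
        if np.any(n_eff < self.viability.shape[2]):
            logger.info(
                "mean_viability: %d wells missing, excluded from means",
                int(np.isnan(self.viability).sum()),
            )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message="Mean of empty slice")
            means = np.nanmean(self.viability, axis=2)
        return means, n_eff


# ---------------------------------------------------------------------------
# expression matrices


def _collapse_duplicate_genes(genes: list[str], rows: list[list[float]]) -> tuple[list[str], list[list[float]]]:
    """Collapse duplicated gene rows by element-wise max, keeping first-seen order."""
    seen: dict[str, int] = {}
    out_genes: list[str] = []
    out_rows: list[list[float]] = []
    n_dups = 0
    for g, row in zip(genes, rows):
        if g in seen:
            n_dups += 1
            prev = out_rows[seen[g]]
            out_rows[seen[g]] = [max(a, b) for a, b in zip(prev, row)]
        else:
            seen[g] = len(out_genes)
            out_genes.append(g)
            out_rows.append(row)
    if n_dups:
        logger.warning("collapsed %d duplicate gene rows by max", n_dups)
    return out_genes, out_rows


def _parse_float(tok: str, where: str) -> float:
    tok = tok.strip()
    if tok in ("", "NA", "NaN", "nan"):
        return math.nan
    try:
        return float(tok)
    except ValueError:
        raise FormatError(f"non-numeric value {tok!r} at {where}") from None


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    ``dialect='tsv'``: header row of sample IDs (first field is the gene-ID
    column name), one row per gene. ``dialect='gct'``: GCT #1.2 with a
    Description column that is discarded. Duplicate gene rows are collapsed by
    element-wise max (logged); duplicate sample IDs are a hard error.
    """
    path = Path(path)
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = path.read_text(encoding="utf-8").splitlines()
    if dialect == "gct":
        if len(lines) < 3:
            raise FormatError(f"{path}: GCT needs at least 3 lines")
        if lines[0].strip() != "#1.2":
            raise FormatError(f"{path}: unsupported GCT version line {lines[0]!r} (only #1.2)")
        try:
            n_genes, n_samples = (int(tok) for tok in lines[1].split("\t")[:2])
        except ValueError:
            raise FormatError(f"{path}: malformed GCT dimension line {lines[1]!r}") from None
        header = lines[2].split("\t")
        if len(header) < 3 or header[0].lower() != "name":
            raise FormatError(f"{path}: malformed GCT header line: {lines[2]!r}")
        samples = header[2:]
        if len(samples) != n_samples:
            raise FormatError(
                f"{path}: header declares {len(samples)} samples, dimension line says {n_samples}"
            )
        body = [ln for ln in lines[3:] if ln.strip()]
        if len(body) != n_genes:
            raise FormatError(f"{path}: GCT declares {n_genes} data rows but file has {len(body)}")
        data_start, value_col = body, 2
    else:
        if not lines or not lines[0].strip():
            raise FormatError(f"{path}: empty or missing header line")
        header = lines[0].split("\t")
        samples = header[1:]
        if not samples:
            raise FormatError(f"{path}: header has no sample columns: {lines[0]!r}")
        data_start, value_col = [ln for ln in lines[1:] if ln.strip()], 1

    if len(set(samples)) != len(samples):
        raise FormatError(f"{path}: duplicate sample ID in header")

    genes: list[str] = []
    rows: list[list[float]] = []
    for i, ln in enumerate(data_start):
        fields = ln.split("\t")
        if len(fields) != len(samples) + value_col:
            raise FormatError(
                f"{path}: row {i + 1} has {len(fields)} fields, expected {len(samples) + value_col}"
            )
        genes.append(fields[0])
        rows.append([_parse_float(tok, f"row {i + 1}, column {j + value_col + 1}")
                     for j, tok in enumerate(fields[value_col:])])
    genes, rows = _collapse_duplicate_genes(genes, rows)
    return ExpressionMatrix(genes, samples, np.array(rows, dtype=float).reshape(len(genes), len(samples)))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    path = Path(path)
    out: list[str] = []
    if dialect == "gct":
        out.append("#1.2")
        out.append(f"{matrix.n_genes}\t{matrix.n_samples}")
        out.append("Name\tDescription\t" + "\t".join(matrix.sample_ids))
        for g, row in zip(matrix.gene_ids, matrix.values):
            out.append(g + "\tna\t" + "\t".join(_fmt(v) for v in row))
    elif dialect == "tsv":
        out.append("gene_id\t" + "\t".join(matrix.sample_ids))
        for g, row in zip(matrix.gene_ids, matrix.values):
            out.append(g + "\t" + "\t".join(_fmt(v) for v in row))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT collection: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets: list[GeneSet] = []
    for i, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {i + 1} has {len(fields)} fields, GMT needs >= 3")
        genes = {g for g in fields[2:] if g.strip()}
        if not genes:
            raise FormatError(f"{path}: line {i + 1}: gene set {fields[0]!r} has no genes")
        sets.append(GeneSet(fields[0], genes, fields[1]))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description or "na", *sorted(s.genes)])
        for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# phenotypes (CLS)


def read_phenotype(path: str | Path) -> PhenotypeLabels:
    """Read a CLS file (counts line / ``#`` class-name line / space-separated labels).

    CLS carries no sample IDs: labels are positional, so ``sample_ids`` is
    filled with ``s1..sn`` placeholders and alignment to a matrix is by
    position (use :meth:`PhenotypeLabels.aligned_to` for ID-joined TSVs).
    """
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) != 3:
        raise FormatError(f"{path}: CLS must have exactly 3 non-empty lines, got {len(lines)}")
    head = lines[0].split()
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: malformed CLS counts line {lines[0]!r}") from None
    if n_classes != 2:
        raise FormatError(f"{path}: exactly two classes required, declared {n_classes}")
    name_line = lines[1].split()
    if not name_line or name_line[0] != "#":
        raise FormatError(f"{path}: CLS class-name line must start with '#'")
    class_names = tuple(name_line[1:])
    if len(class_names) != 2:
        raise FormatError(f"{path}: expected 2 class names, got {len(class_names)}")
    raw = lines[2].split()
    if len(raw) != n_samples:
        raise FormatError(f"{path}: declared {n_samples} labels, found {len(raw)}")
    # CLS allows numeric labels (0/1 by order of first appearance) or the names
    if set(raw) <= {"0", "1"}:
        labels = [class_names[int(tok)] for tok in raw]
    else:
        labels = raw
    if set(labels) != set(class_names):
        raise FormatError(f"{path}: labels {sorted(set(labels))} do not match classes {class_names}")
    return PhenotypeLabels([f"s{i + 1}" for i in range(n_samples)], labels, class_names)  # type: ignore[arg-type]


def write_phenotype(labels: PhenotypeLabels, path: str | Path) -> None:
    lines = [
        f"{len(labels.labels)} 2 1",
        "# " + " ".join(labels.class_names),
        " ".join(labels.labels),
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# drug tables


def read_drug_table(path: str | Path, dose: float = 600.0) -> DrugResponseTable:
    """Read a drug x cell-line viability TSV.

    Header row is ``drug_id`` then cell-line IDs; repeated drug rows become the
    replicate dimension; ``NA``/empty cells become missing values. ``dose`` is
    the screen concentration in nM (600 nM is the single-dose screen default).
    """
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty drug table")
    header = lines[0].split("\t")
    cell_lines = header[1:]
    if not cell_lines:
        raise FormatError(f"{path}: header has no cell-line columns")
    per_drug: dict[str, list[list[float]]] = {}
    order: list[str] = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}: line {i} has {len(fields)} fields, expected {len(header)}")
        drug = fields[0]
        row = [_parse_float(tok, f"line {i}, column {j + 2}") for j, tok in enumerate(fields[1:])]
        for j, v in enumerate(row):
            if not math.isnan(v) and v < 0:
                raise FormatError(f"{path}: negative viability at line {i}, column {j + 2}")
        if drug not in per_drug:
            per_drug[drug] = []
            order.append(drug)
        per_drug[drug].append(row)
    n_rep = max(len(rows) for rows in per_drug.values())
    cube = np.full((len(order), len(cell_lines), n_rep), np.nan)
    for d, drug in enumerate(order):
        for r, row in enumerate(per_drug[drug]):
            cube[d, :, r] = row
    return DrugResponseTable(order, cell_lines, cube, np.full(len(order), float(dose)))


def write_drug_table(table: DrugResponseTable, path: str | Path) -> None:
    out = ["drug_id\t" + "\t".join(table.cell_line_ids)]
    for d, drug in enumerate(table.drug_ids):
        for r in range(table.n_replicates):
            row = table.viability[d, :, r]
            if np.all(np.isnan(row)) and r > 0:
                continue  # padding replicate for drugs with fewer rows
            out.append(drug + "\t" + "\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8", newline="\n")
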