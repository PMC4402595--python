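"""Reading, writing, validation and pre-filtering of binary somatic mutation matrices.

The central container is :class:`MutationMatrix`: an ordered ``m`` patients ×
``n`` genes 0/1 incidence matrix.  Entry ``(i, j) = 1`` means gene *j* carries
a somatic mutation in patient *i*.  Two plain-text input formats are
supported: a headered TSV matrix and a two-column patient/gene pair list
(one mutation event per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MutationMatrix",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix_tsv",
    "read_pair_list",
    "write_matrix_tsv",
    "filter_by_frequency",
]


class MatrixParseError(ValueError):
    """A cell or line in an input file could not be parsed."""


class MatrixValidationError(ValueError):
    """The parsed content violates a structural invariant."""


@dataclass(frozen=True)
class MutationMatrix:
    """Binary patients × genes somatic mutation incidence matrix.

    Parameters
    ----------
    patients
        Ordered unique patient identifiers (rows).
    genes
        Ordered unique gene symbols (columns).
    entries
        ``(m, n)`` array of 0/1 values, row *i* = patient ``patients[i]``.
    """

    patients: tuple[str, ...]
    genes: tuple[str, ...]
    entries: np.ndarray
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        patients = tuple(self.patients)
        genes = tuple(self.genes)
        object.__setattr__(self, "patients", patients)
        object.__setattr__(self, "genes", genes)
        if len(patients) == 0 or len(genes) == 0:
            raise MatrixValidationError("matrix must have at least one patient and one gene")
        if len(set(patients)) != len(patients):
            raise MatrixValidationError("duplicate patient identifiers")
        if len(set(genes)) != len(genes):
            raise MatrixValidationError("duplicate gene symbols")
        entries = np.asarray(self.entries, dtype=np.int8)
        if entries.shape != (len(patients), len(genes)):
            raise MatrixValidationError(
                f"entries shape {entries.shape} does not match "
                f"{len(patients)} patients x {len(genes)} genes"
            )
        if not np.isin(entries, (0, 1)).all():
            raise MatrixValidationError("entries must be 0 or 1")
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "_gene_index", {g: j for j, g in enumerate(genes)})

    # -- basic shape ---------------------------------------------------

    @property
    def m(self) -> int:
        """Number of patients."""
        return len(self.patients)

    @property
    def n(self) -> int:
        """Number of genes."""
        return len(self.genes)

    # -- lookups -------------------------------------------------------

    def gene_column(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene symbol: {gene!r}") from None

    def coverage(self, gene: str) -> frozenset[str]:
        """Γ(g): the set of patients in which ``gene`` is mutated."""
        col = self.entries[:, self.gene_column(gene)]
        return frozenset(self.patients[i] for i in np.flatnonzero(col))

    def coverage_count(self, gene: str) -> int:
        """|Γ(g)|: number of patients carrying a mutation in ``gene``."""
        return int(self.entries[:, self.gene_column(gene)].sum())

    def coverage_counts(self) -> dict[str, int]:
        sums = self.entries.sum(axis=0)
        return {g: int(sums[j]) for j, g in enumerate(self.genes)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return (
            self.patients == other.patients
            and self.genes == other.genes
            and np.array_equal(self.entries, other.entries)
        )

    def __hash__(self) -> int:  # pragma: no cover - rarely needed
        return hash((self.patients, self.genes, self.entries.tobytes()))


def _parse_cell(text: str, row_label: str, col_label: str) -> int:
    text = text.strip()
    if text == "0":
        return 0
    if text == "1":
        return 1
    raise MatrixParseError(
        f"cell for patient {row_label!r}, gene {col_label!r} is {text!r}; expected 0 or 1"
    )


def read_matrix_tsv(path: str | Path) -> MutationMatrix:
    """Read a headered TSV mutation matrix.

    First row: tab-separated gene symbols (a leading corner label is
    permitted).  Each body row: patient ID followed by 0/1 cells.  Row and
    column order of the file is preserved.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 2:
        raise MatrixValidationError(f"{path}: need a header row and at least one patient row")
    header = lines[0].split("\t")
    body_width = len(lines[1].split("\t"))
    # header may or may not carry a corner cell above the patient-ID column
    genes = header[1:] if len(header) == body_width else header
    if len(genes) != body_width - 1:
        raise MatrixParseError(
            f"{path}: header has {len(genes)} genes but rows have {body_width - 1} cells"
        )
    patients: list[str] = []
    rows: list[list[int]] = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != body_width:
            raise MatrixParseError(
                f"{path}: row {fields[0]!r} has {len(fields) - 1} cells, expected {body_width - 1}"
            )
        patients.append(fields[0])
        rows.append([_parse_cell(c, fields[0], g) for c, g in zip(fields[1:], genes)])
    return MutationMatrix(tuple(patients), tuple(genes), np.array(rows, dtype=np.int8))


def read_pair_list(path: str | Path) -> MutationMatrix:
    """Read a two-column ``patient<TAB>gene`` mutation event list.

    Lines starting with ``#`` and blank lines are ignored; duplicate pairs
    collapse to a single 1.  Patients and genes are sorted lexicographically
    so the result is independent of line order.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    for lineno, ln in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise MatrixParseError(
                f"{path}:{lineno}: expected 'patient<TAB>gene', got {ln!r}"
            )
        pairs.add((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise MatrixValidationError(f"{path}: no mutation events found")
    patients = tuple(sorted({p for p, _ in pairs}))
    genes = tuple(sorted({g for _, g in pairs}))
    p_idx = {p: i for i, p in enumerate(patients)}
    g_idx = {g: j for j, g in enumerate(genes)}
    entries = np.zeros((len(patients), len(genes)), dtype=np.int8)
    for p, g in pairs:
        entries[p_idx[p], g_idx[g]] = 1
    return MutationMatrix(patients, genes, entries)


def write_matrix_tsv(matrix: MutationMatrix, path: str | Path) -> None:
    """Write ``matrix`` in the headered TSV format (exact round trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("patient\t" + "\t".join(matrix.genes) + "\n")
        for i, p in enumerate(matrix.patients):
            fh.write(p + "\t" + "\t".join(str(int(v)) for v in matrix.entries[i]) + "\n")


def filter_by_frequency(matrix: MutationMatrix, min_fraction: float = 0.05) -> MutationMatrix:
    """Drop genes mutated in fewer than ``min_fraction`` of all patients.

    A gene g is retained iff ``|Γ(g)| >= min_fraction * m`` (the boundary
    count is kept; the comparison uses the exact product, no rounding).
    Patients are never removed, so the coverage-degree denominator ``m``
    is unchanged.  The operation is idempotent.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    counts = matrix.entries.sum(axis=0)
    keep = [j for j in range(matrix.n) if counts[j] >= min_fraction * matrix.m]
    if not keep:
        raise MatrixValidationError(
            f"all {matrix.n} genes fall below the frequency threshold "
            f"{min_fraction}; lower min_fraction"
        )
    if len(keep) == matrix.n:
        return matrix
    return MutationMatrix(
        matrix.patients,
        tuple(matrix.genes[j] for j in keep),
        matrix.entries[:, keep],
    )
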