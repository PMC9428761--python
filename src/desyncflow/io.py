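"""Shared data model and file I/O for forced-desynchrony study data.

The pipeline works on three kinds of tabular inputs: a log2 expression
matrix (probes x samples, tab-delimited), a sample sheet annotating each
array column (participant, sleep condition, clock time), and per-participant
hormone time series (melatonin, cortisol). Gene sets are read from GMT
files. Expression values are assumed to be already log2-normalised;
no preprocessing is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Sleep-condition labels: sleep aligned with the central circadian clock
# (melatonin rhythm) vs scheduled 12 h against it.
IN_PHASE = "in_phase"
OUT_OF_PHASE = "out_of_phase"
CONDITIONS = (IN_PHASE, OUT_OF_PHASE)

MELATONIN = "melatonin"
CORTISOL = "cortisol"

#: Columns required in a sample sheet.
SAMPLESHEET_COLUMNS = ("sample_id", "participant_id", "condition", "clock_time_h")

#: Circadian period used for all periodic arithmetic, in hours.
PERIOD_H = 24.0


class DataFormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def wrap_hours(x, half: float = PERIOD_H / 2):
    """Wrap hour differences into ``(-half, half]`` (default ``(-12, 12]``)."""
    x = np.asarray(x, dtype=float)
    w = x % (2 * half)
    w = np.where(w > half, w - 2 * half, w)
    return float(w) if w.ndim == 0 else w


@dataclass(frozen=True)
class HormoneSeries:
    """One analyte time series for one participant in one condition."""

    participant_id: str
    condition: str
    analyte: str
    times_h: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-normalised to upper case)."""

    name: str
    description: str
    members: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "members", frozenset(str(m).upper() for m in self.members)
        )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionDataset:
    """Probes x samples log2 expression with per-sample annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Expression matrix, index = probe ids, columns = sample ids.
        Missing cells are NaN.
    gene_symbols : pandas.Series
        Probe id -> gene symbol (upper case). Many probes may map to the
        same gene; the mapping is never inverted implicitly.
    samples : pandas.DataFrame
        One row per array column, aligned with ``values.columns``. Columns:
        sample_id, participant_id, condition, clock_time_h and, after
        phase alignment, aligned_time_h and time_bin.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DataFormatError(f"duplicate probe ids: {list(dups)[:5]}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise DataFormatError("matrix columns do not match sample sheet order")
        if self.samples["sample_id"].duplicated().any():
            raise DataFormatError("duplicate sample ids in sample sheet")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise DataFormatError(f"unknown condition labels: {sorted(bad)}")
        sizes = self.samples.groupby(["participant_id", "condition"]).size()
        if (sizes > 7).any():
            raise DataFormatError(
                "more than 7 samples for a (participant, condition) pair"
            )
        self.gene_symbols = self.gene_symbols.reindex(self.values.index).fillna("")
        self.gene_symbols = self.gene_symbols.str.upper()

    @property
    def probe_ids(self):
        return list(self.values.index)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def platform_genes(self) -> set:
        """All non-empty gene symbols represented on the platform."""
        return set(self.gene_symbols[self.gene_symbols != ""].unique())

    def probes_for_gene(self, symbol: str) -> list:
        symbol = symbol.upper()
        return list(self.gene_symbols.index[self.gene_symbols == symbol])

    def subset_condition(self, condition: str) -> "ExpressionDataset":
        mask = self.samples["condition"] == condition
        samples = self.samples.loc[mask].reset_index(drop=True)
        return ExpressionDataset(
            values=self.values[samples["sample_id"]],
            gene_symbols=self.gene_symbols.copy(),
            samples=samples,
        )


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet
# ---------------------------------------------------------------------------

def read_expression(matrix_path, samplesheet_path) -> ExpressionDataset:
    """Read a tab-delimited expression matrix plus its CSV sample sheet.

    The matrix has a ``probe_id`` first column, an optional ``gene_symbol``
    second column, and one column per sample. Empty cells become NaN.
    Columns are re-ordered to follow the sample sheet; a matrix column with
    no sample-sheet row is an error, as is a sheet row with no column.
    """
    mat = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    if mat.columns[0] != "probe_id":
        raise DataFormatError("first matrix column must be 'probe_id'")
    mat = mat.set_index("probe_id")
    if len(mat.columns) and mat.columns[0] == "gene_symbol":
        symbols = mat["gene_symbol"].astype(str)
        mat = mat.drop(columns="gene_symbol")
    else:
        symbols = pd.Series("", index=mat.index)
    try:
        values = mat.astype(float)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric expression cell: {exc}") from exc

    sheet = pd.read_csv(samplesheet_path, dtype={"sample_id": str, "participant_id": str})
    missing = set(SAMPLESHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise DataFormatError(f"sample sheet missing columns: {sorted(missing)}")

    matrix_samples = set(values.columns)
    sheet_samples = set(sheet["sample_id"])
    if matrix_samples - sheet_samples:
        raise DataFormatError(
            f"unannotated sample(s) in matrix: {sorted(matrix_samples - sheet_samples)[:5]}"
        )
    if sheet_samples - matrix_samples:
        raise DataFormatError(
            f"sample sheet rows without matrix column: {sorted(sheet_samples - matrix_samples)[:5]}"
        )
    values = values[list(sheet["sample_id"])]
    return ExpressionDataset(values=values, gene_symbols=symbols, samples=sheet)


def write_expression(data: ExpressionDataset, matrix_path, samplesheet_path,
                     float_format: str = "%.10g") -> None:
    """Write the matrix (TSV, with gene_symbol column) and sample sheet (CSV)."""
    out = data.values.copy()
    out.insert(0, "gene_symbol", data.gene_symbols)
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", float_format=float_format)
    data.samples.to_csv(samplesheet_path, index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Hormone series
# ---------------------------------------------------------------------------

def read_hormones(path) -> list:
    """Read a long-format hormone TSV into a list of :class:`HormoneSeries`.

    Expected columns: participant_id, condition, analyte, time_h, concentration.
    """
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str})
    required = {"participant_id", "condition", "analyte", "time_h", "concentration"}
    if missing := required - set(df.columns):
        raise DataFormatError(f"hormone table missing columns: {sorted(missing)}")
    series = []
    for (pid, cond, analyte), grp in df.groupby(
        ["participant_id", "condition", "analyte"], sort=True
    ):
        grp = grp.sort_values("time_h")
        series.append(
            HormoneSeries(
                participant_id=pid,
                condition=cond,
                analyte=analyte,
                times_h=grp["time_h"].to_numpy(),
                concentrations=grp["concentration"].to_numpy(),
            )
        )
    return series


def write_hormones(series, path, float_format: str = "%.10g") -> None:
    rows = []
    for s in series:
        for t, c in zip(s.times_h, s.concentrations):
            rows.append((s.participant_id, s.condition, s.analyte, t, c))
    pd.DataFrame(
        rows, columns=["participant_id", "condition", "analyte", "time_h", "concentration"]
    ).to_csv(path, sep="\t", index=False, float_format=float_format)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> list:
    """Read GMT: one set per line, ``name TAB description TAB member...``."""
    sets = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"GMT line {i}: expected at least 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise DataFormatError(f"GMT line {i}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gene_sets(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def restrict_to_platform(gene_set: GeneSet, data: ExpressionDataset) -> GeneSet:
    """Intersect a gene set with the genes represented on the platform.

    Mirrors the standard enrichment practice of refining target lists to the
    measured background. Empty intersections are allowed but warned about.
    """
    members = gene_set.members & data.platform_genes()
    if not members:
        warnings.warn(
            f"gene set {gene_set.name!r} shares no genes with the platform",
            stacklevel=2,
        )
    return GeneSet(name=gene_set.name, description=gene_set.description,
                   members=frozenset(members))
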