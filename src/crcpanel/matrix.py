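"""Expression-matrix and clinical-table containers and their text formats.

The interchange format for expression data is a plain TSV/CSV dialect:

* row 1 — header: ``symbol``, ``transcript_id``, ``is_housekeeping``,
  then one column per sample ID;
* row 2 — class row: first three cells ``#class``, ``''``, ``''``, then the
  per-sample class label (``tumour`` or ``normal``);
* remaining rows — one per transcript: gene symbol, RefSeq transcript
  accession, housekeeping flag (0/1), then numeric values per sample.

Clinical tables are ordinary CSVs with one row per patient; see
:data:`CLINICAL_COLUMNS` for the column dictionary.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
NORMALIZED_LOG2 = "normalized_log2"

TUMOUR = "tumour"
NORMAL = "normal"

#: Column dictionary for the clinical CSV. Times are months, CEA ng/mL,
#: tumour size cm; event flags are 0/1 with 1 = death (OS) or relapse/death
#: (DFS).
CLINICAL_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "tumour_size",
    "site",
    "cea",
    "grade",
    "lymphovascular_invasion",
    "pT",
    "pN",
    "M",
    "tnm_stage",
    "os_time",
    "os_event",
    "dfs_time",
    "dfs_event",
]


class MatrixFormatError(ValueError):
    """Raised when an expression-matrix file violates the dialect."""


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """One panel transcript: gene symbol, RefSeq accession, housekeeping flag."""

    symbol: str
    transcript_id: str
    is_housekeeping: bool = False


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes × samples expression values with annotations.

    ``values`` has one row per entry of ``genes`` and one column per entry of
    ``samples``; ``sample_class`` labels each sample ``tumour`` or ``normal``;
    ``scale`` records whether values are raw counts or normalized log2 units.
    """

    values: np.ndarray
    genes: list[GeneAnnotation]
    samples: list[str]
    sample_class: list[str]
    scale: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.genes):
            raise MatrixFormatError(
                f"{len(self.genes)} gene annotations for {n_genes} value rows"
            )
        if n_samples != len(self.samples) or n_samples != len(self.sample_class):
            raise MatrixFormatError(
                f"{len(self.samples)} sample IDs / {len(self.sample_class)} class "
                f"labels for {n_samples} value columns"
            )
        if len(set(self.samples)) != len(self.samples):
            raise MatrixFormatError("sample IDs are not unique")
        tids = [g.transcript_id for g in self.genes]
        if len(set(tids)) != len(tids):
            dupes = sorted({t for t in tids if tids.count(t) > 1})
            raise MatrixFormatError(f"duplicate transcript_id(s): {dupes}")
        bad = set(self.sample_class) - {TUMOUR, NORMAL}
        if bad:
            raise MatrixFormatError(f"unknown sample class label(s): {sorted(bad)}")
        if self.scale not in (RAW_COUNTS, NORMALIZED_LOG2):
            raise MatrixFormatError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise MatrixFormatError("non-finite expression values")
        if self.scale == RAW_COUNTS and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise MatrixFormatError(
                f"negative count at gene {self.genes[i].transcript_id!r}, "
                f"sample {self.samples[j]!r} (raw counts must be >= 0)"
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def housekeeping_index(self) -> np.ndarray:
        return np.array([g.is_housekeeping for g in self.genes], dtype=bool)

    @property
    def class_array(self) -> np.ndarray:
        return np.asarray(self.sample_class)

    def gene_row(self, transcript_id: str) -> np.ndarray:
        """Per-sample values for one transcript (by RefSeq accession)."""
        for i, g in enumerate(self.genes):
            if g.transcript_id == transcript_id:
                return self.values[i]
        raise KeyError(f"transcript_id {transcript_id!r} not in panel")

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            values=self.values[:, mask].copy(),
            genes=list(self.genes),
            samples=[s for s, m in zip(self.samples, mask) if m],
            sample_class=[c for c, m in zip(self.sample_class, mask) if m],
            scale=self.scale,
        )

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by transcript_id, columns = samples."""
        return pd.DataFrame(
            self.values,
            index=[g.transcript_id for g in self.genes],
            columns=self.samples,
        )


_DELIMS = {"tsv": "\t", "csv": ","}


def read_expression_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read the plain-text matrix dialect into an :class:`ExpressionMatrix`.

    The file carries raw counts (``scale=raw_counts``); row and column order
    are preserved. Malformed numeric cells raise :class:`MatrixFormatError`
    naming the offending row and column.
    """
    if format not in _DELIMS:
        raise ValueError(f"format must be one of {sorted(_DELIMS)}, got {format!r}")
    sep = _DELIMS[format]
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise MatrixFormatError(f"{path}: expected header, class row and >=1 gene row")
    header = lines[0].split(sep)
    if len(header) < 4 or header[:3] != ["symbol", "transcript_id", "is_housekeeping"]:
        raise MatrixFormatError(
            f"{path}: header must start with symbol/transcript_id/is_housekeeping"
        )
    samples = header[3:]
    class_row = lines[1].split(sep)
    if class_row[0] != "#class" or len(class_row) != len(header):
        raise MatrixFormatError(f"{path}: second row must be the #class row")
    sample_class = class_row[3:]

    genes: list[GeneAnnotation] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[2:], start=3):
        cells = line.split(sep)
        if len(cells) != len(header):
            raise MatrixFormatError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
            )
        genes.append(
            GeneAnnotation(
                symbol=cells[0],
                transcript_id=cells[1],
                is_housekeeping=_parse_flag(cells[2], path, lineno),
            )
        )
        row = []
        for j, cell in enumerate(cells[3:]):
            try:
                row.append(float(cell))
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}:{lineno}: malformed numeric cell {cell!r} "
                    f"in sample column {samples[j]!r}"
                ) from exc
        rows.append(row)

    return ExpressionMatrix(
        values=np.array(rows, dtype=float),
        genes=genes,
        samples=samples,
        sample_class=sample_class,
        scale=RAW_COUNTS,
    )


def _parse_flag(cell: str, path: Path, lineno: int) -> bool:
    if cell in ("0", "1"):
        return cell == "1"
    if cell.lower() in ("true", "false"):
        return cell.lower() == "true"
    raise MatrixFormatError(f"{path}:{lineno}: housekeeping flag {cell!r} not 0/1")


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write the matrix dialect; bit-identical output for identical inputs."""
    if format not in _DELIMS:
        raise ValueError(f"format must be one of {sorted(_DELIMS)}, got {format!r}")
    sep = _DELIMS[format]
    buf = io.StringIO()
    buf.write(sep.join(["symbol", "transcript_id", "is_housekeeping", *m.samples]))
    buf.write("\n")
    buf.write(sep.join(["#class", "", "", *m.sample_class]))
    buf.write("\n")
    for g, row in zip(m.genes, m.values):
        cells = [g.symbol, g.transcript_id, "1" if g.is_housekeeping else "0"]
        cells += [format_value(v) for v in row]
        buf.write(sep.join(cells))
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def format_value(v: float) -> str:
    """Render a value losslessly but without float noise on round numbers."""
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a per-patient clinical CSV and validate it.

    Requires the full :data:`CLINICAL_COLUMNS` set; checks non-negative,
    finite survival times and 0/1 event flags.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"clinical table missing column(s): {missing}")
    if df["patient_id"].duplicated().any():
        raise MatrixFormatError("duplicate patient_id in clinical table")
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    for tcol in ("os_time", "dfs_time"):
        t = df[tcol].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise MatrixFormatError(f"{tcol} must be finite and >= 0")
    for ecol in ("os_event", "dfs_event", "lymphovascular_invasion"):
        e = df[ecol].to_numpy()
        if not np.isin(e, [0, 1, True, False]).all():
            raise MatrixFormatError(f"{ecol} must be boolean 0/1")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in df.columns])


def endpoints_from_clinical(
    clinical: pd.DataFrame, endpoint: str = "OS"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (time, event) arrays for ``endpoint`` in {"OS", "DFS"}."""
    key = endpoint.upper()
    if key not in ("OS", "DFS"):
        raise ValueError("endpoint must be 'OS' or 'DFS'")
    prefix = "os" if key == "OS" else "dfs"
    time = clinical[f"{prefix}_time"].to_numpy(dtype=float)
    event = clinical[f"{prefix}_event"].to_numpy(dtype=bool)
    return time, event


def align_samples(
    m: ExpressionMatrix, clinical: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Restrict to tumour samples with a clinical row, in matrix order."""
    ids = set(clinical["patient_id"].astype(str))
    mask = np.array(
        [c == TUMOUR and s in ids for s, c in zip(m.samples, m.sample_class)]
    )
    sub = m.subset_samples(mask)
    cl = clinical.set_index(clinical["patient_id"].astype(str)).loc[sub.samples]
    return sub, cl.reset_index(drop=True)
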