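"""Readers and writers for PSI matrices, clinical tables and expression tables.

All tables are plain delimited text; the delimiter is sniffed from the file
extension (``.csv`` -> comma, anything else -> tab).  PSI values are stored as
fractions in [0, 1]; inputs on a 0-100 percent scale must be pre-divided —
there is no auto-detection, to avoid silent scale bugs.  Missing markers
accepted on read: the empty cell, ``NA``, ``NaN`` and ``null``
(case-insensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import SpliceEvent, parse_event_id

log = logging.getLogger(__name__)

MISSING_MARKERS = ("", "NA", "NaN", "null")

#: Categorical clinical annotations; blanks become the explicit "unknown".
CLINICAL_CATEGORICALS = (
    "grade",
    "histology",
    "idh_status",
    "codel_1p19q",
    "mgmt_status",
    "tert_status",
    "atrx_status",
    "chr7gain_chr10loss",
    "chr19_20_gain",
    "transcriptome_cluster",
)


class TableFormatError(ValueError):
    """Malformed header or missing required columns."""


class TableValidationError(ValueError):
    """Parsed values violate a domain invariant (e.g. PSI outside [0, 1])."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _is_missing(cell: object) -> bool:
    return str(cell).strip().lower() in {m.lower() for m in MISSING_MARKERS}


# ---------------------------------------------------------------------------
# PSI matrices
# ---------------------------------------------------------------------------

@dataclass
class PsiMatrix:
    """Events x samples matrix of Percent-Spliced-In fractions.

    ``data`` is a float DataFrame indexed by canonical event-id strings with
    one column per sample; missing PSI is ``NaN``.  ``events`` holds the
    parsed identities in the same order as ``data.index``.
    """

    events: list[SpliceEvent]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.events) != self.data.shape[0]:
            raise TableValidationError("event list does not match matrix rows")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        keys = [(e.symbol, e.as_id, e.splice_type) for e in self.events]
        if len(set(keys)) != len(keys):
            raise TableValidationError("duplicate (symbol, as_id, splice_type) events")
        vals = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)  # NaN compares False
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise TableValidationError(
                f"PSI outside [0, 1] for event {self.data.index[i]!r} "
                f"sample {self.data.columns[j]!r}: {vals[i, j]}"
            )

    # -- basic views --------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def event_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def splice_types(self) -> pd.Series:
        """Series mapping event id -> splice category."""
        return pd.Series([e.splice_type for e in self.events],
                         index=self.data.index, name="splice_type")

    @classmethod
    def from_frame(cls, data: pd.DataFrame) -> "PsiMatrix":
        """Build from a DataFrame whose index holds event-id strings."""
        events = [parse_event_id(i) for i in data.index]
        frame = data.astype(float).copy()
        frame.index = [e.event_id for e in events]
        return cls(events=events, data=frame)

    def subset_events(self, event_ids: Sequence[str]) -> "PsiMatrix":
        keep = [i for i, eid in enumerate(self.data.index) if eid in set(event_ids)]
        return PsiMatrix(events=[self.events[i] for i in keep],
                         data=self.data.iloc[keep])


def read_psi_table(path: str | Path, dialect: str = "simple") -> PsiMatrix:
    """Read a PSI table.

    ``dialect="simple"``: first column is the event id
    (``SYMBOL|as_id|TYPE[|exon]``), remaining columns are samples.
    ``dialect="tcgaspliceseq"``: leading columns ``symbol``, ``as_id``,
    ``splice_type``, ``exons``, then one column per sample.

    Unparseable numeric cells become missing; values outside [0, 1] raise
    :class:`TableValidationError` naming the offending event and sample.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise TableValidationError(f"{path}: duplicate sample ids: {dupes}")
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str,
                      keep_default_na=False)
    if dialect == "simple":
        if raw.shape[1] < 2:
            raise TableFormatError(
                f"{path}: expected an event-id column plus sample columns"
            )
        events = [parse_event_id(v) for v in raw.iloc[:, 0]]
        body = raw.iloc[:, 1:]
    elif dialect == "tcgaspliceseq":
        need = ["symbol", "as_id", "splice_type", "exons"]
        cols = {c.lower(): c for c in raw.columns}
        if not all(c in cols for c in need):
            raise TableFormatError(
                f"{path}: tcgaspliceseq dialect requires columns {need}; "
                f"found {list(raw.columns)[:6]}"
            )
        events = [
            SpliceEvent(symbol=s, as_id=int(a), splice_type=t,
                        exon_label="" if _is_missing(x) else str(x))
            for s, a, t, x in zip(raw[cols["symbol"]], raw[cols["as_id"]],
                                  raw[cols["splice_type"]], raw[cols["exons"]])
        ]
        body = raw[[c for c in raw.columns
                    if c.lower() not in set(need)]]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    numeric = body.apply(
        lambda col: pd.to_numeric(col.map(lambda v: np.nan if _is_missing(v) else v),
                                  errors="coerce"))
    n_unparseable = int((numeric.isna() & ~body.map(_is_missing)).to_numpy().sum())
    if n_unparseable:
        log.warning("%s: %d unparseable PSI cells treated as missing",
                    path, n_unparseable)
    numeric.index = [e.event_id for e in events]
    return PsiMatrix(events=events, data=numeric)


def write_psi_table(psi: PsiMatrix, path: str | Path,
                    dialect: str = "simple") -> None:
    """Write a PSI table in the given dialect (inverse of :func:`read_psi_table`)."""
    path = Path(path)
    if dialect == "simple":
        out = psi.data.copy()
        out.insert(0, "event_id", psi.data.index)
        out.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")
    elif dialect == "tcgaspliceseq":
        out = psi.data.copy()
        out.insert(0, "exons", [e.exon_label for e in psi.events])
        out.insert(0, "splice_type", [e.splice_type for e in psi.events])
        out.insert(0, "as_id", [e.as_id for e in psi.events])
        out.insert(0, "symbol", [e.symbol for e in psi.events])
        out.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

@dataclass
class ClinicalTable:
    """Per-sample survival and categorical annotations.

    ``data`` is indexed by sample id.  Required columns: ``os_months``
    (non-negative, NaN allowed) and ``os_event`` (0/1, NaN allowed); samples
    with missing survival are excluded from survival operations but retained
    elsewhere.  Categorical annotations use the explicit string ``"unknown"``
    for blanks; ``standard_therapy`` is 0/1/NaN (concurrent chemoradiotherapy
    flag).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("os_months", "os_event"):
            if col not in self.data.columns:
                raise TableFormatError(f"clinical table lacks column {col!r}")
        if self.data.index.duplicated().any():
            raise TableValidationError("duplicate sample ids in clinical table")
        osm = pd.to_numeric(self.data["os_months"], errors="coerce")
        if (osm.dropna() < 0).any():
            bad = self.data.index[osm < 0][0]
            raise TableValidationError(f"negative os_months for sample {bad!r}")
        ose = pd.to_numeric(self.data["os_event"], errors="coerce").dropna()
        if not ose.isin([0, 1]).all():
            raise TableValidationError("os_event must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def survival(self) -> pd.DataFrame:
        """Rows with usable survival: both os_months and os_event present."""
        osm = pd.to_numeric(self.data["os_months"], errors="coerce")
        ose = pd.to_numeric(self.data["os_event"], errors="coerce")
        ok = osm.notna() & ose.notna()
        n_drop = int((~ok).sum())
        if n_drop:
            log.info("dropping %d samples with missing survival", n_drop)
        out = pd.DataFrame({"os_months": osm[ok], "os_event": ose[ok].astype(int)})
        return out


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical table (first column = sample id)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.shape[1] < 3 or raw.columns[0].lower() not in ("sample_id", "sample"):
        raise TableFormatError(
            f"{path}: first column must be sample_id, then clinical columns"
        )
    raw = raw.set_index(raw.columns[0])
    missing = [c for c in ("os_months", "os_event") if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required columns {missing}")
    data = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if col in ("os_months", "os_event", "age", "karnofsky", "standard_therapy"):
            data[col] = pd.to_numeric(
                raw[col].map(lambda v: np.nan if _is_missing(v) else v),
                errors="coerce")
        else:
            data[col] = raw[col].map(
                lambda v: "unknown" if _is_missing(v) else str(v))
    return ClinicalTable(data=data)


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    out = clin.data.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise TableValidationError("duplicate gene symbols")
        vals = self.data.to_numpy(dtype=float)
        if np.nan_to_num(vals, nan=0.0).min() < 0:
            raise TableValidationError("expression values must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples expression table (first column = gene symbol)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: expected gene column plus sample columns")
    raw = raw.set_index(raw.columns[0])
    numeric = raw.apply(
        lambda col: pd.to_numeric(col.map(lambda v: np.nan if _is_missing(v) else v),
                                  errors="coerce"))
    return ExpressionMatrix(data=numeric)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    out = expr.data.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")
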