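"""RSEM normalized_results readers and TCGA barcode handling.

Expression input follows the RNA-Seq-V2 ``rsem.genes.normalized_results``
and ``rsem.isoforms.normalized_results`` dialect: one tab-delimited file
per sample with a header row and two columns (``gene_id`` or
``isoform_id``, then ``normalized_count``). The sample's TCGA barcode is
the filename prefix up to ``.rsem``.

Barcodes follow the hierarchical grammar
Project-TSS-Participant-SampleType/Vial-Portion/Analyte-Plate-Center,
e.g. ``TCGA-AB-2842-03A-01T-0734-13``. Both the concatenated form
(``03A``) and the slash form (``03/A``) are accepted; the canonical
emitted form is concatenated. Sample-type code 03 is primary blood-derived
cancer / peripheral blood, 09 is bone marrow.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "BarcodeError",
    "TcgaBarcode",
    "SurvivalRecord",
    "DEFAULT_ISOFORM_ALIASES",
    "parse_barcode",
    "read_rsem_table",
    "read_clinical",
    "select_peripheral_blood",
    "dedupe_participants",
]

#: Default mapping of isoform feature ids to the three NKp44 splice
#: variants (RefSeq accessions of the NCR2 transcripts). Override when the
#: isoform files use other identifier schemes (e.g. UCSC ids).
DEFAULT_ISOFORM_ALIASES: dict[str, str] = {
    "NM_004828.3": "NKp44-1",
    "NM_001199509": "NKp44-2",
    "NM_001199510.1": "NKp44-3",
}

_VALID_ANALYTES = frozenset("TD")


class BarcodeError(ValueError):
    """Raised for text that does not follow the TCGA barcode grammar."""


@dataclass(frozen=True, order=True)
class TcgaBarcode:
    """The nine components of a TCGA aliquot barcode."""

    project: str
    tissue_source_site: str
    participant: str
    sample_type: str
    vial: str
    portion: str
    analyte: str
    plate: str
    center: str

    def __post_init__(self):
        if not (len(self.sample_type) == 2 and self.sample_type.isdigit()):
            raise BarcodeError(
                f"sample_type must be two decimal digits, got {self.sample_type!r}"
            )
        if self.analyte not in _VALID_ANALYTES:
            raise BarcodeError(
                f"analyte must be T (total RNA) or D (DNA), got {self.analyte!r}"
            )

    def __str__(self) -> str:
        return (
            f"{self.project}-{self.tissue_source_site}-{self.participant}"
            f"-{self.sample_type}{self.vial}-{self.portion}{self.analyte}"
            f"-{self.plate}-{self.center}"
        )


_BARCODE_RE = re.compile(
    r"^(?P<project>[A-Z0-9]+)"
    r"-(?P<tss>[A-Z0-9]{2})"
    r"-(?P<participant>[A-Z0-9]{4})"
    r"-(?P<sample_type>\d{2})/?(?P<vial>[A-Z])"
    r"-(?P<portion>\d{2})/?(?P<analyte>[A-Z])"
    r"-(?P<plate>[A-Z0-9]{4})"
    r"-(?P<center>[A-Z0-9]{2})$"
)

_FIELD_NAMES = (
    "project", "tissue source site", "participant", "sample type/vial",
    "portion/analyte", "plate", "center",
)


def parse_barcode(text: str) -> TcgaBarcode:
    """Parse a TCGA aliquot barcode into its nine components.

    Accepts both ``TCGA-AB-2842-03A-01T-0734-13`` and the slash notation
    ``TCGA-AB-2842-03/A-01/T-0734-13``; formatting the result always
    yields the concatenated form.
    """
    m = _BARCODE_RE.match(text.strip())
    if m is None:
        # locate the first offending hyphen-delimited field for the message
        parts = text.strip().split("-")
        if len(parts) != 7:
            raise BarcodeError(
                f"barcode {text!r}: expected 7 hyphen-delimited fields, got {len(parts)}"
            )
        pats = (
            r"[A-Z0-9]+", r"[A-Z0-9]{2}", r"[A-Z0-9]{4}", r"\d{2}/?[A-Z]",
            r"\d{2}/?[A-Z]", r"[A-Z0-9]{4}", r"[A-Z0-9]{2}",
        )
        for i, (part, pat) in enumerate(zip(parts, pats)):
            if not re.fullmatch(pat, part):
                raise BarcodeError(
                    f"barcode {text!r}: field {i + 1} ({_FIELD_NAMES[i]}) "
                    f"is malformed: {part!r}"
                )
        raise BarcodeError(f"malformed barcode {text!r}")
    g = m.groupdict()
    if g["analyte"] not in _VALID_ANALYTES:
        raise BarcodeError(
            f"barcode {text!r}: field 5 (portion/analyte) has invalid analyte "
            f"{g['analyte']!r} (must be T or D)"
        )
    return TcgaBarcode(
        project=g["project"],
        tissue_source_site=g["tss"],
        participant=g["participant"],
        sample_type=g["sample_type"],
        vial=g["vial"],
        portion=g["portion"],
        analyte=g["analyte"],
        plate=g["plate"],
        center=g["center"],
    )


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-event (days) with an event flag, keyed by barcode."""

    barcode: str
    time_days: float
    event: bool
    risk_group: str | None = None

    def __post_init__(self):
        if not (self.time_days >= 0):
            raise ValueError(f"time_days must be >= 0, got {self.time_days}")


_ID_COLUMN = {"gene": "gene_id", "isoform": "isoform_id"}


def _barcode_from_path(path: Path) -> str:
    name = path.name
    return name.split(".rsem", 1)[0] if ".rsem" in name else path.stem


def read_rsem_table(paths: Iterable[str | Path], level: str = "gene") -> pd.DataFrame:
    """Read per-sample RSEM normalized_results files into a sample x feature matrix.

    Parameters
    ----------
    paths : iterable of paths
        One normalized_results file per sample; the barcode is taken from
        the filename prefix (up to ``.rsem``).
    level : {"gene", "isoform"}
        Selects the expected id column (``gene_id`` / ``isoform_id``).

    Returns
    -------
    pandas.DataFrame
        Indexed by barcode string, one column per feature id. Features
        absent from a file are NaN (explicitly missing), never 0.
    """
    if level not in _ID_COLUMN:
        raise ValueError(f"level must be 'gene' or 'isoform', got {level!r}")
    id_col = _ID_COLUMN[level]
    rows: dict[str, pd.Series] = {}
    for path in sorted(Path(p) for p in paths):
        barcode = _barcode_from_path(path)
        tab = pd.read_csv(path, sep="\t")
        if id_col not in tab.columns or "normalized_count" not in tab.columns:
            raise ValueError(
                f"{path}: expected columns [{id_col}, normalized_count], "
                f"got {list(tab.columns)}"
            )
        values = pd.to_numeric(tab["normalized_count"], errors="raise")
        if (values < 0).any():
            bad = tab.loc[values < 0, id_col].iloc[0]
            raise ValueError(f"{path}: negative normalized_count for {bad}")
        if tab[id_col].duplicated().any():
            dup = tab.loc[tab[id_col].duplicated(), id_col].iloc[0]
            raise ValueError(f"{path}: duplicate feature id {dup}")
        if barcode in rows:
            raise ValueError(f"duplicate barcode {barcode} (second file: {path})")
        rows[barcode] = pd.Series(values.to_numpy(), index=tab[id_col].to_numpy())
    frame = pd.DataFrame(rows).T
    frame.index.name = "barcode"
    return frame


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV (barcode, days_to_event, event, optional risk_group)."""
    tab = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    required = {"barcode", "days_to_event", "event"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    if (tab["days_to_event"] < 0).any():
        raise ValueError(f"{path}: negative days_to_event")
    tab["event"] = tab["event"].astype(int).astype(bool)
    if "risk_group" not in tab.columns:
        tab["risk_group"] = None
    if tab["barcode"].duplicated().any():
        dup = tab.loc[tab["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"{path}: duplicate barcode {dup}")
    return tab.set_index("barcode")


def select_peripheral_blood(barcodes: Sequence[str]) -> list[str]:
    """Keep barcodes with sample-type code 03 (peripheral blood), order preserved.

    Bone-marrow aliquots (09) and every other sample type are dropped.
    Idempotent; duplicate vials of one participant are retained
    (de-duplication is a separate step, :func:`dedupe_participants`).
    """
    return [b for b in barcodes if parse_barcode(b).sample_type == "03"]


def dedupe_participants(barcodes: Sequence[str], keep: str = "first") -> list[str]:
    """One aliquot per participant, default keep-first by lexicographic barcode."""
    if keep not in {"first", "last"}:
        raise ValueError("keep must be 'first' or 'last'")
    by_participant: dict[tuple[str, str], str] = {}
    for b in barcodes:
        parsed = parse_barcode(b)
        key = (parsed.tissue_source_site, parsed.participant)
        if key not in by_participant:
            by_participant[key] = b
        else:
            best = by_participant[key]
            if (keep == "first" and b < best) or (keep == "last" and b > best):
                by_participant[key] = b
    chosen = set(by_participant.values())
    return [b for b in barcodes if b in chosen]
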