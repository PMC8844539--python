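"""Domain types and tabular I/O.

The pipeline consumes protein-group quantification tables shaped like a
MaxQuant ``proteinGroups`` export (one row per protein group, one label-free
quantification intensity column per sample), a per-protein annotation table
(cellular-component class, plasma-membrane flag, predicted N-glycosylation
site count, Ig-like domain count), and centroided MALDI peak lists
(two-column m/z / intensity TSV).  All formats are tab-separated UTF-8 with a
header row and ``.`` as decimal separator.

Intensity cells that are empty or exactly ``0`` are treated as MISSING
(``None``) by default: an LFQ zero is absence of evidence, not a measured
zero.  MISSING survives a write/read round trip as an empty cell.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, FixtureIntegrityError, TableFormatError

REPORT_SCHEMA_VERSION = "1.0"

MISSING = None  # sentinel alias; intensities use Optional[float]


class Bait(str, Enum):
    """Which member of a labelling pair a sample is."""

    ACTIVE_SN = "ACTIVE_SN"  # sialic-acid-binding Siglec-1 multimer
    CONTROL_R97A = "CONTROL_R97A"  # non-binding R97A mutant control


class Multimer(str, Enum):
    IN_SOLUTION = "IN_SOLUTION"
    ON_BEAD = "ON_BEAD"


class CCClass(str, Enum):
    """Flat Gene Ontology cellular-component class assignment."""

    MEMBRANE = "MEMBRANE"
    CYTOPLASM = "CYTOPLASM"
    NUCLEUS = "NUCLEUS"
    OTHER = "OTHER"


@dataclass(frozen=True)
class SampleDesign:
    """One MS sample: which experiment (dataset) it belongs to and its role.

    A *dataset* is one labelling experiment: exactly one active-bait sample
    and one R97A-control sample sharing a ``dataset_id``.  ``(multimer,
    replicate)`` identifies a dataset uniquely.
    """

    sample_id: str
    dataset_id: str
    bait: Bait
    multimer: Multimer
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ConfigurationError(
                f"replicate must be a positive integer, got {self.replicate}"
            )


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check the bait/control pairing and dataset-identity invariants."""
    by_dataset: dict[str, list[SampleDesign]] = {}
    seen_samples: set[str] = set()
    for s in design:
        if s.sample_id in seen_samples:
            raise ConfigurationError(f"duplicate sample_id {s.sample_id!r}")
        seen_samples.add(s.sample_id)
        by_dataset.setdefault(s.dataset_id, []).append(s)
    keys: dict[tuple[Multimer, int], str] = {}
    for ds_id, members in by_dataset.items():
        baits = sorted(m.bait.value for m in members)
        if baits != [Bait.ACTIVE_SN.value, Bait.CONTROL_R97A.value]:
            raise ConfigurationError(
                f"dataset {ds_id!r} must have exactly one ACTIVE_SN and one "
                f"CONTROL_R97A sample, got {baits}"
            )
        key = (members[0].multimer, members[0].replicate)
        if any((m.multimer, m.replicate) != key for m in members):
            raise ConfigurationError(
                f"samples of dataset {ds_id!r} disagree on (multimer, replicate)"
            )
        if key in keys:
            raise ConfigurationError(
                f"datasets {keys[key]!r} and {ds_id!r} share (multimer, replicate) {key}"
            )
        keys[key] = ds_id


@dataclass
class ProteinQuantRecord:
    """Per-protein LFQ intensities keyed by sample id.

    ``intensity_by_sample`` values are finite non-negative floats or ``None``
    for not-quantified (MISSING).
    """

    protein_id: str
    gene_name: str = ""
    molecular_weight_kda: float | None = None  # kilodaltons
    intensity_by_sample: dict[str, float | None] = field(default_factory=dict)


@dataclass
class ProteinQuantTable:
    """An ordered collection of :class:`ProteinQuantRecord` with unique ids."""

    records: list[ProteinQuantRecord]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        ids = [r.protein_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise TableFormatError(f"duplicate protein_id {dup!r}")
        self._by_id = {r.protein_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, protein_id: str) -> ProteinQuantRecord:
        return self._by_id[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-protein membrane / glycosylation / Ig-domain metadata.

    ``n_sequons`` is the number of predicted N-glycosylation sequons
    (database-predicted sites, or the N-X(!=P)-[S/T] scan when a sequence is
    supplied).
    """

    protein_id: str
    cc_class: CCClass
    plasma_membrane: bool
    n_sequons: int
    n_ig_domains: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.plasma_membrane and self.cc_class is not CCClass.MEMBRANE:
            raise ConfigurationError(
                f"{self.protein_id}: plasma_membrane=True requires cc_class=MEMBRANE"
            )
        if self.n_sequons < 0 or self.n_ig_domains < 0:
            raise ConfigurationError(
                f"{self.protein_id}: negative sequon or Ig-domain count"
            )


@dataclass(frozen=True)
class CounterReceptorTableRow:
    """One row of the published counter-receptor list."""

    gene_name: str
    log2_fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value < 1.0):
            raise FixtureIntegrityError(
                f"{self.gene_name}: p value {self.p_value} outside (0, 1)"
            )


@dataclass
class PeakList:
    """A centroided spectrum: (m/z, intensity) pairs sorted by m/z."""

    peaks: list[tuple[float, float]]
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        for mz, inten in self.peaks:
            if not (mz > 0 and math.isfinite(mz)):
                raise TableFormatError(f"non-positive or non-finite m/z {mz}")
            if not (inten >= 0 and math.isfinite(inten)):
                raise TableFormatError(f"negative or non-finite intensity {inten}")

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# quant tables


def _parse_intensity(cell: str, zero_as_missing: bool, where: str) -> float | None:
    cell = cell.strip()
    if cell == "" or cell.upper() in {"NA", "NAN"}:
        return None
    try:
        value = float(cell)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric intensity {cell!r} at {where}") from exc
    if not math.isfinite(value) or value < 0:
        raise TableFormatError(f"invalid intensity {value} at {where}")
    if value == 0.0 and zero_as_missing:
        return None
    return value


def read_quant_table(
    path: str | Path,
    design: Sequence[SampleDesign],
    *,
    zero_as_missing: bool = True,
) -> ProteinQuantTable:
    """Read a protein-group quantification TSV.

    The header must contain ``protein_id`` and one intensity column per
    ``sample_id`` in *design*; ``gene_name`` and ``molecular_weight_kda``
    are optional.  Unknown columns are ignored.  Empty (and by default zero)
    intensity cells become MISSING.
    """
    path = Path(path)
    sample_ids = [s.sample_id for s in design]
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        col = {name: i for i, name in enumerate(header)}
        if "protein_id" not in col:
            raise TableFormatError(f"{path}: missing required column 'protein_id'")
        for sid in sample_ids:
            if sid not in col:
                raise TableFormatError(f"{path}: missing sample column {sid!r}")
        records: list[ProteinQuantRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            pid = row[col["protein_id"]].strip()
            if pid in seen:
                raise TableFormatError(f"{path}: duplicate protein_id {pid!r}")
            seen.add(pid)
            gene = row[col["gene_name"]].strip() if "gene_name" in col else ""
            mw: float | None = None
            if "molecular_weight_kda" in col:
                cell = row[col["molecular_weight_kda"]].strip()
                if cell:
                    try:
                        mw = float(cell)
                    except ValueError as exc:
                        raise TableFormatError(
                            f"{path}: non-numeric molecular weight {cell!r} "
                            f"at line {lineno}"
                        ) from exc
                    if mw <= 0:
                        raise TableFormatError(
                            f"{path}: molecular weight must be > 0 at line {lineno}"
                        )
            intens = {
                sid: _parse_intensity(
                    row[col[sid]], zero_as_missing, f"{path}:{lineno} column {sid!r}"
                )
                for sid in sample_ids
            }
            records.append(
                ProteinQuantRecord(
                    protein_id=pid,
                    gene_name=gene,
                    molecular_weight_kda=mw,
                    intensity_by_sample=intens,
                )
            )
    return ProteinQuantTable(records=records, sample_ids=list(sample_ids))


def write_quant_table(table: ProteinQuantTable, path: str | Path) -> None:
    """Write a quant table as TSV; MISSING intensities become empty cells."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["protein_id", "gene_name", "molecular_weight_kda", *table.sample_ids]
        )
        for rec in table.records:
            mw = "" if rec.molecular_weight_kda is None else repr(rec.molecular_weight_kda)
            cells = [
                "" if rec.intensity_by_sample.get(sid) is None
                else repr(rec.intensity_by_sample[sid])
                for sid in table.sample_ids
            ]
            writer.writerow([rec.protein_id, rec.gene_name, mw, *cells])


# ---------------------------------------------------------------------------
# design and annotation tables


def write_design_table(design: Sequence[SampleDesign], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "dataset_id", "bait", "multimer", "replicate"])
        for s in design:
            writer.writerow(
                [s.sample_id, s.dataset_id, s.bait.value, s.multimer.value, s.replicate]
            )


def read_design_table(path: str | Path) -> list[SampleDesign]:
    path = Path(path)
    design: list[SampleDesign] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "dataset_id", "bait", "multimer", "replicate"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TableFormatError(
                f"{path}: design table needs columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                design.append(
                    SampleDesign(
                        sample_id=row["sample_id"],
                        dataset_id=row["dataset_id"],
                        bait=Bait(row["bait"]),
                        multimer=Multimer(row["multimer"]),
                        replicate=int(row["replicate"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise TableFormatError(f"{path}: bad design row at line {lineno}") from exc
    validate_design(design)
    return design


def write_annotation_table(
    ann: Sequence[AnnotationRecord], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["protein_id", "cc_class", "plasma_membrane", "n_sequons",
             "n_ig_domains", "sequence"]
        )
        for a in ann:
            writer.writerow(
                [a.protein_id, a.cc_class.value, int(a.plasma_membrane),
                 a.n_sequons, a.n_ig_domains, a.sequence or ""]
            )


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    out: list[AnnotationRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"protein_id", "cc_class", "plasma_membrane", "n_sequons",
                    "n_ig_domains"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise TableFormatError(
                f"{path}: annotation table needs columns {sorted(required)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    AnnotationRecord(
                        protein_id=row["protein_id"],
                        cc_class=CCClass(row["cc_class"]),
                        plasma_membrane=bool(int(row["plasma_membrane"])),
                        n_sequons=int(row["n_sequons"]),
                        n_ig_domains=int(row["n_ig_domains"]),
                        sequence=row.get("sequence") or None,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise TableFormatError(
                    f"{path}: bad annotation row at line {lineno}"
                ) from exc
    return out


# ---------------------------------------------------------------------------
# published counter-receptor table fixture

_TABLE1_RESOURCE = "table1_counter_receptors.tsv"
_TABLE1_EXPECTED_ROWS = 49


def read_table1_fixture() -> list[CounterReceptorTableRow]:
    """Load the packaged published counter-receptor list.

    Returns all 49 rows (gene name, log2 fold change over the R97A control,
    p value) with the printed decimal values preserved.
    """
    try:
        text = (
            resources.files("proxiglyc.data").joinpath(_TABLE1_RESOURCE).read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise FixtureIntegrityError("counter-receptor table fixture missing") from exc
    rows: list[CounterReceptorTableRow] = []
    seen: set[str] = set()
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        try:
            parsed = CounterReceptorTableRow(
                gene_name=row["gene_name"],
                log2_fold_change=float(row["log2_fold_change"]),
                p_value=float(row["p_value"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FixtureIntegrityError(f"corrupt fixture row: {row!r}") from exc
        if parsed.gene_name in seen:
            raise FixtureIntegrityError(f"duplicate gene name {parsed.gene_name!r}")
        seen.add(parsed.gene_name)
        rows.append(parsed)
    if len(rows) != _TABLE1_EXPECTED_ROWS:
        raise FixtureIntegrityError(
            f"expected {_TABLE1_EXPECTED_ROWS} rows, found {len(rows)}"
        )
    return rows


# ---------------------------------------------------------------------------
# peak lists


def read_peaklist(path: str | Path, condition_label: str = "") -> PeakList:
    """Read a two-column (m/z, intensity) TSV into a sorted :class:`PeakList`.

    A header line is optional and detected by non-numeric first field.
    """
    path = Path(path)
    peaks: list[tuple[float, float]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TableFormatError(f"{path}:{lineno}: expected two columns")
            if lineno == 1:
                try:
                    float(parts[0])
                except ValueError:
                    continue  # header
            try:
                mz, inten = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise TableFormatError(
                    f"{path}:{lineno}: non-numeric cell in {parts[:2]!r}"
                ) from exc
            if inten < 0:
                raise TableFormatError(f"{path}:{lineno}: negative intensity {inten}")
            if mz <= 0:
                raise TableFormatError(f"{path}:{lineno}: non-positive m/z {mz}")
            peaks.append((mz, inten))
    return PeakList(peaks=peaks, condition_label=condition_label or path.stem)


def write_peaklist(peaklist: PeakList, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        fh.write("mz\tintensity\n")
        for mz, inten in peaklist.peaks:
            fh.write(f"{mz!r}\t{inten!r}\n")


# ---------------------------------------------------------------------------
# JSON reports


def write_report(report: Mapping | Sequence, path: str | Path) -> None:
    """Serialize a report object as versioned JSON (sorted keys, so the
    output is byte-stable for identical inputs)."""
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "report": report}
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path):
    with Path(path).open(encoding="utf-8") as fh:
        payload = json.load(fh)
    if "schema_version" not in payload or "report" not in payload:
        raise TableFormatError(f"{path}: not a versioned report")
    return payload["report"]


def annotation_by_id(
    ann: Iterable[AnnotationRecord],
) -> dict[str, AnnotationRecord]:
    return {a.protein_id: a for a in ann}
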