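"""Reading, validating and writing the pipeline's on-disk formats.

Measurement tables and sample metadata are comma-delimited UTF-8 text with a
header row; missing measurements are empty cells.  Sequences are plain FASTA
(aligned, equal length) joined to a region via a metadata CSV.  Results
tables are written back as CSV at a fixed documented precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: canonical measure codes, in anatomical order (Table order 1-18)
MEASURE_CODES = (
    "IW", "ZW", "CW", "CBL", "NL", "RW", "ONL", "NOc",
    "TLC", "TLS", "TC", "TDAP", "TDML",
    "ML", "MH", "MD", "MT", "MW",
)

#: measures recorded on both sides (tusk and mandible, measures 9-17)
BILATERAL_CODES = ("TLC", "TLS", "TC", "TDAP", "TDML", "ML", "MH", "MD", "MT")

#: skull-vault measures standardized by cranial (mastoid) width
SKULL_CODES = ("IW", "ZW", "CBL", "NL", "RW", "ONL", "NOc")
#: tusk measures, also standardized by cranial width
TUSK_CODES = ("TLC", "TLS", "TC", "TDAP", "TDML")
#: mandible measures standardized by mandible width
MANDIBLE_CODES = ("ML", "MH", "MD", "MT")

REGIONS = ("MAR", "ATL", "PAC")
SEXES = ("M", "F", "unknown")

#: IUPAC nucleotide one-letter codes accepted on input (plus alignment gap)
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: decimal places used when writing results tables
RESULTS_PRECISION = 6


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass
class MorphoSpecimen:
    """One specimen: metadata plus a (measure, side) -> millimetres map.

    ``side`` is ``"L"``/``"R"`` for the bilateral tusk/mandible measures and
    ``None`` for midline cranial measures.
    """

    specimen_id: str
    region: str
    sex: str = "unknown"
    age_years: float | None = None
    measures: dict[tuple[str, str | None], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DataError(
                f"specimen {self.specimen_id!r}: unknown region {self.region!r}"
                f" (expected one of {REGIONS})"
            )
        if self.sex not in SEXES:
            raise DataError(f"specimen {self.specimen_id!r}: unknown sex {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise DataError(f"specimen {self.specimen_id!r}: negative age")
        for (code, side), value in self.measures.items():
            if code not in MEASURE_CODES:
                raise DataError(f"specimen {self.specimen_id!r}: unknown measure {code!r}")
            bilateral = code in BILATERAL_CODES
            if bilateral and side not in ("L", "R"):
                raise DataError(
                    f"specimen {self.specimen_id!r}: bilateral measure {code} needs a side"
                )
            if not bilateral and side is not None:
                raise DataError(
                    f"specimen {self.specimen_id!r}: midline measure {code} cannot have a side"
                )
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise DataError(
                    f"specimen {self.specimen_id!r}: non-positive value {value!r} for {code}"
                )

    def get(self, code: str, side: str | None = None) -> float | None:
        return self.measures.get((code, side))


@dataclass
class MorphoDataset:
    """A collection of specimens with unique ids."""

    specimens: list[MorphoSpecimen]

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DataError(f"duplicate specimen ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.specimens)

    def __iter__(self):
        return iter(self.specimens)

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for s in self.specimens:
            if s.region not in seen:
                seen.append(s.region)
        return seen

    def subset(self, region: str) -> "MorphoDataset":
        return MorphoDataset([s for s in self.specimens if s.region == region])


@dataclass
class RegionAlignment:
    """Aligned control-region sequences with per-sample region labels."""

    records: list[tuple[str, str, str]]  # (sample_id, region, sequence)
    length: int

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample ids in alignment")
        for sid, region, seq in self.records:
            if region not in REGIONS:
                raise DataError(f"sample {sid!r}: unknown region {region!r}")
            if len(seq) != self.length:
                raise DataError("unequal alignment lengths")
            bad = set(seq.upper()) - IUPAC_DNA
            if bad:
                raise DataError(f"sample {sid!r}: non-IUPAC characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for _, region, _ in self.records:
            if region not in seen:
                seen.append(region)
        return seen


# ---------------------------------------------------------------------------
# morphometric tables


def _column_key(column: str) -> tuple[str, str | None]:
    """Map a header column like ``TLC_L`` or ``CBL`` to a (code, side) key."""
    if "_" in column:
        code, side = column.rsplit("_", 1)
        if code in BILATERAL_CODES and side in ("L", "R"):
            return code, side
    return column, None


def morpho_columns() -> list[str]:
    """Canonical measurement column order for morphometric CSVs."""
    cols: list[str] = []
    for code in MEASURE_CODES:
        if code in BILATERAL_CODES:
            cols.extend([f"{code}_L", f"{code}_R"])
        else:
            cols.append(code)
    return cols


def read_morpho_table(path: str | Path) -> MorphoDataset:
    """Read a measurement CSV into a validated :class:`MorphoDataset`.

    Expected header: ``specimen_id, region, sex, age`` followed by one column
    per measure (bilateral measures as ``CODE_L`` / ``CODE_R``).  Empty cells
    are missing values and are simply absent from the measure map.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"specimen_id", "region", "sex", "age"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing required columns {sorted(missing)}")
    specimens = []
    for idx, row in df.iterrows():
        sid = row["specimen_id"]
        if pd.isna(sid) or not str(sid).strip():
            raise DataError(f"{path}: row {idx + 2}: empty specimen_id")
        measures: dict[tuple[str, str | None], float] = {}
        for col in df.columns:
            if col in required:
                continue
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            code, side = _column_key(col)
            if code not in MEASURE_CODES:
                raise DataError(f"{path}: unknown measure column {col!r}")
            try:
                value = float(raw)
            except ValueError:
                raise DataError(
                    f"{path}: row {idx + 2} ({sid}): non-numeric value {raw!r} in {col}"
                ) from None
            if value <= 0:
                raise DataError(
                    f"{path}: row {idx + 2} ({sid}): non-positive value {value} in {col}"
                )
            measures[(code, side)] = value
        sex = row["sex"]
        age = row["age"]
        try:
            spec = MorphoSpecimen(
                specimen_id=str(sid),
                region=str(row["region"]),
                sex="unknown" if pd.isna(sex) or not str(sex).strip() else str(sex),
                age_years=None if pd.isna(age) or str(age).strip() == "" else float(age),
                measures=measures,
            )
        except DataError as exc:
            raise DataError(f"{path}: row {idx + 2}: {exc}") from None
        specimens.append(spec)
    return MorphoDataset(specimens)


def write_morpho_table(ds: MorphoDataset, path: str | Path) -> None:
    """Write a dataset back to the CSV layout :func:`read_morpho_table` expects."""
    cols = morpho_columns()
    rows = []
    for s in ds:
        row: dict[str, object] = {
            "specimen_id": s.specimen_id,
            "region": s.region,
            "sex": s.sex,
            "age": "" if s.age_years is None else s.age_years,
        }
        for col in cols:
            key = _column_key(col)
            value = s.measures.get(key)
            row[col] = "" if value is None else round(value, RESULTS_PRECISION)
        rows.append(row)
    pd.DataFrame(rows, columns=["specimen_id", "region", "sex", "age"] + cols).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# sequence alignments


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> RegionAlignment:
    """Read aligned FASTA plus a (sample_id, region) metadata CSV.

    Sequences are upper-cased; every FASTA record must have a metadata row
    and vice versa, and all sequences must share one alignment length.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise DataError(f"{fasta_path}: no FASTA records")
    meta = pd.read_csv(metadata_path, dtype=str)
    if not {"sample_id", "region"} <= set(meta.columns):
        raise DataError(f"{metadata_path}: needs columns sample_id, region")
    region_of = dict(zip(meta["sample_id"], meta["region"]))
    if len(region_of) != len(meta):
        raise DataError(f"{metadata_path}: duplicate sample ids")

    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise DataError(f"{fasta_path}: unequal alignment lengths {sorted(lengths)}")
    fasta_ids = [r.id for r in records]
    orphans = [i for i in fasta_ids if i not in region_of]
    if orphans:
        raise DataError(f"FASTA ids missing from metadata: {orphans}")
    unmatched = sorted(set(region_of) - set(fasta_ids))
    if unmatched:
        raise DataError(f"metadata ids missing from FASTA: {unmatched}")
    rows = [(r.id, region_of[r.id], str(r.seq).upper()) for r in records]
    return RegionAlignment(records=rows, length=lengths.pop())


def write_alignment(aln: RegionAlignment, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write an alignment as FASTA plus region-metadata CSV (inverse of read)."""
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, _, seq in aln.records
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(
        [(sid, region) for sid, region, _ in aln.records],
        columns=["sample_id", "region"],
    ).to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# results tables


def write_results_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write homogeneous result records as CSV, floats at fixed precision."""
    if rows:
        keys = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != keys:
                raise DataError("heterogeneous result records")
        df = pd.DataFrame(list(rows), columns=keys)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False, float_format=f"%.{RESULTS_PRECISION}g")


# ---------------------------------------------------------------------------
# validation report


def validate_dataset(ds: MorphoDataset) -> dict:
    """Report per-region/per-measure availability and complete-case counts.

    ``counts`` maps region -> measure -> {"L": n, "R": n} (or {"value": n}
    for midline measures); ``standardizable`` counts specimens carrying the
    relevant standardizer; ``complete_cases`` counts specimens with every
    measure of each analysis block present (left side for bilateral codes).
    """
    counts: dict[str, dict[str, dict[str, int]]] = {}
    for region in ds.regions:
        per_measure: dict[str, dict[str, int]] = {}
        for code in MEASURE_CODES:
            if code in BILATERAL_CODES:
                entry = {"L": 0, "R": 0}
            else:
                entry = {"value": 0}
            per_measure[code] = entry
        counts[region] = per_measure
    for s in ds:
        for (code, side), _ in s.measures.items():
            key = side if code in BILATERAL_CODES else "value"
            counts[s.region][code][key] += 1

    standardizable = {
        "skull_tusk": sum(1 for s in ds if s.get("CW") is not None),
        "mandible": sum(1 for s in ds if s.get("MW") is not None),
    }

    def _block_complete(s: MorphoSpecimen, codes: Iterable[str], standardizer: str) -> bool:
        if s.get(standardizer) is None:
            return False
        for code in codes:
            side = "L" if code in BILATERAL_CODES else None
            if s.get(code, side) is None:
                return False
        return True

    complete_cases = {
        "skull": sum(1 for s in ds if _block_complete(s, SKULL_CODES, "CW")),
        "tusk": sum(1 for s in ds if _block_complete(s, TUSK_CODES, "CW")),
        "mandible": sum(1 for s in ds if _block_complete(s, MANDIBLE_CODES, "MW")),
    }
    return {
        "n_specimens": len(ds),
        "regions": ds.regions,
        "counts": counts,
        "standardizable": standardizable,
        "complete_cases": complete_cases,
    }
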