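"""Reading and writing per-specimen morphometric tables.

The on-disk dialect is a flat CSV with one row per worker: a specimen
identifier, the nest sample code, an optional species label and the 22
trait columns in μm.  Trait headers are matched case-insensitively and
tolerate the spelling variants that occur in print (PoOc/PoOC/POC,
NOdL/NodL).  Unknown columns are passed through untouched.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    TRAIT_NAMES,
    Region,
    SpecimenRecord,
    TraitVector,
    ValidationError,
    canonical_trait,
)

__all__ = ["ParseReport", "read_dataset", "write_dataset"]

log = logging.getLogger(__name__)

_ID_CANDIDATES = ("specimen_id", "specimen", "id", "worker_id")
_NEST_CANDIDATES = ("nest_id", "nest", "sample", "sample_code", "sample_id")
_SPECIES_CANDIDATES = ("species", "taxon", "label")
_META_OPTIONAL = ("country", "antennomere_count", "spine_angle_deg", "region")


@dataclass
class ParseReport:
    """Accounting of a dataset read: what was kept, dropped and why."""

    path: str
    rows_read: int = 0
    rows_accepted: int = 0
    rejected: list[dict] = field(default_factory=list)
    unknown_columns: list[str] = field(default_factory=list)

    @property
    def rows_rejected(self) -> int:
        return len(self.rejected)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _resolve_column(columns: Sequence[str], candidates: Sequence[str]) -> str | None:
    lower = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    return None


def read_dataset(
    path: str | Path,
    *,
    check_window: bool = True,
) -> tuple[list[SpecimenRecord], ParseReport]:
    """Read an S3-dialect CSV into validated specimen records.

    A missing trait column is fatal.  A row with a non-numeric or
    invariant-violating trait cell is rejected, logged, and recorded in
    the parse report; all other rows are preserved in file order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    report = ParseReport(path=str(path), rows_read=len(df))

    trait_cols: dict[str, str] = {}
    other_cols: list[str] = []
    for col in df.columns:
        try:
            trait_cols[canonical_trait(col)] = col
        except KeyError:
            other_cols.append(col)
    missing = [t for t in TRAIT_NAMES if t not in trait_cols]
    if missing:
        raise ValidationError(f"missing trait column(s): {', '.join(missing)}")

    id_col = _resolve_column(other_cols, _ID_CANDIDATES)
    nest_col = _resolve_column(other_cols, _NEST_CANDIDATES)
    if nest_col is None:
        raise ValidationError("no nest/sample-code column found")
    species_col = _resolve_column(other_cols, _SPECIES_CANDIDATES)
    meta_cols = {m: _resolve_column(other_cols, (m,)) for m in _META_OPTIONAL}
    claimed = {id_col, nest_col, species_col, *meta_cols.values()}
    report.unknown_columns = [c for c in other_cols if c not in claimed]

    records: list[SpecimenRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            values = {}
            for trait, col in trait_cols.items():
                cell = rowd[col].strip()
                try:
                    values[trait] = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"non-numeric value {cell!r} in column {col}"
                    ) from None
            traits = TraitVector(values, check_window=check_window)
            ant = rowd.get(meta_cols["antennomere_count"] or "", "").strip()
            angle = rowd.get(meta_cols["spine_angle_deg"] or "", "").strip()
            rec = SpecimenRecord(
                specimen_id=rowd[id_col].strip() if id_col else f"{path.stem}-{i}",
                nest_id=rowd[nest_col].strip(),
                traits=traits,
                species=(rowd[species_col].strip() or None) if species_col else None,
                country=(rowd.get(meta_cols["country"] or "", "").strip() or None),
                antennomere_count=int(float(ant)) if ant else None,
                spine_angle_deg=float(angle) if angle else None,
                region=Region.coerce(
                    rowd.get(meta_cols["region"] or "", "").strip() or None
                ),
                extras={c: rowd[c] for c in report.unknown_columns},
            )
        except (ValidationError, ValueError) as exc:
            log.warning("row %d rejected: %s", i, exc)
            report.rejected.append({"row": i, "reason": str(exc)})
            continue
        records.append(rec)
    report.rows_accepted = len(records)
    return records, report


def write_dataset(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write specimen records back to the CSV dialect read_dataset reads.

    Numeric trait cells are written with full double precision so a
    read → write → read cycle reproduces every value bit-identically.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "specimen_id": rec.specimen_id,
            "nest_id": rec.nest_id,
            "species": rec.species or "",
        }
        row.update({t: repr(rec.traits[t]) for t in TRAIT_NAMES})
        if rec.country:
            row["country"] = rec.country
        if rec.antennomere_count is not None:
            row["antennomere_count"] = rec.antennomere_count
        if rec.spine_angle_deg is not None:
            row["spine_angle_deg"] = repr(rec.spine_angle_deg)
        if rec.region is not Region.UNKNOWN:
            row["region"] = rec.region.value
        row.update(rec.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
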