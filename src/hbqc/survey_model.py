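"""Record-level data model, CSV ingestion, validity and inclusion rules.

A survey is a set of individual hemoglobin (Hb) measurements taken with a
point-of-care photometer (HemoCue Hb 301 class device, reporting range
0-25.6 g/dL) on one demographic group at one site: children aged 6-59
months or non-pregnant women of reproductive age (WRA, 15-49 y). This
module turns delimited text into :class:`HbRecord` / :class:`Survey`
objects, marks device-range validity, removes exact duplicate rows, drops
pregnant-women records, and applies the survey inclusion rule (at least
30% of sampled individuals with a valid Hb value).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Device reporting range, g/dL; values outside are invalid, bounds inclusive.
DEVICE_RANGE = (0.0, 25.6)


class Group(str, Enum):
    """Demographic group of a survey or record."""

    CHILD = "child"  # children 6-59 months
    WRA = "wra"      # non-pregnant women 15-49 years

    @classmethod
    def parse(cls, raw: str) -> "Group":
        token = str(raw).strip().lower()
        aliases = {
            "child": cls.CHILD, "children": cls.CHILD, "c": cls.CHILD,
            "wra": cls.WRA, "women": cls.WRA, "woman": cls.WRA, "w": cls.WRA,
        }
        try:
            return aliases[token]
        except KeyError:
            raise ValueError(f"unknown demographic group: {raw!r}") from None


class SchemaError(ValueError):
    """Raised when an input file lacks a mandatory column."""


@dataclass(frozen=True, slots=True)
class HbRecord:
    """One individual's Hb measurement with survey metadata.

    ``hb_gdl`` is ``None`` when the field was empty or unparseable; such
    records are retained (row counts must reconcile) but can never be valid.
    """

    record_id: str
    survey_id: str
    group: Group
    hb_gdl: float | None
    altitude_m: float | None = None
    pregnant: bool | None = None
    altitude_adjusted: bool = True
    country: str = ""
    site: str = ""
    year: int | None = None
    valid: bool | None = None  # set by mark_validity

    def __post_init__(self) -> None:
        if self.group is Group.CHILD and self.pregnant:
            raise ValueError(f"child record {self.record_id!r} marked pregnant")


@dataclass(frozen=True, slots=True)
class InclusionPolicy:
    """Survey-level inclusion rule: minimum fraction of valid Hb values.

    A survey enters the analysis only if at least ``min_valid_fraction`` of
    the individuals sampled for Hb have a value inside the device range.
    """

    min_valid_fraction: float = 0.30
    min_n_valid: int = 1
    validity_range: tuple[float, float] = DEVICE_RANGE

    def __post_init__(self) -> None:
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must be in (0, 1]")
        lo, hi = self.validity_range
        if not lo < hi:
            raise ValueError("validity_range must satisfy low < high")


@dataclass(slots=True)
class Survey:
    """A single survey: its records plus sampling metadata.

    ``n_sampled`` is the number of individuals approached for Hb; when the
    input carries no subsampling metadata it defaults to the number of rows,
    which makes the 30%-valid rule vacuous (documented in the CLI help).
    """

    survey_id: str
    group: Group
    records: list[HbRecord] = field(default_factory=list)
    country: str = ""
    site: str = ""
    year: int | None = None
    n_sampled: int | None = None

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def n_valid(self) -> int:
        return sum(1 for r in self.records if r.valid)

    def effective_n_sampled(self) -> int:
        return self.n_sampled if self.n_sampled is not None else len(self.records)

    def valid_values(self) -> np.ndarray:
        """Hb values of valid records, as a float array (g/dL)."""
        return np.array([r.hb_gdl for r in self.records if r.valid], dtype=float)


#: Default column map for CSV ingestion; keys are logical names, values
#: the column headers looked up in the file.
DEFAULT_SCHEMA: dict[str, str] = {
    "survey_id": "survey_id",
    "group": "group",
    "hb_gdl": "hb_gdl",
    "record_id": "record_id",
    "country": "country",
    "site": "site",
    "year": "year",
    "pregnant": "pregnant",
    "altitude_m": "altitude_m",
    "altitude_adjusted": "altitude_adjusted",
}

_MANDATORY = ("survey_id", "group", "hb_gdl")
_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", ""}


def _parse_float(raw: str | None) -> float | None:
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    try:
        return float(raw)
    except ValueError:
        return None


def _parse_bool(raw: str | None) -> bool | None:
    if raw is None or raw.strip() == "":
        return None
    token = raw.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    return None


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
) -> list[HbRecord]:
    """Read one :class:`HbRecord` per CSV row.

    Unparseable Hb values become missing (the row is retained, it can never
    be marked valid), so the output row count always equals the input row
    count. Missing mandatory columns raise :class:`SchemaError` naming the
    column; an empty file yields an empty list.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    path = Path(path)
    records: list[HbRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return []
        header = set(reader.fieldnames)
        for logical in _MANDATORY:
            if colmap[logical] not in header:
                raise SchemaError(
                    f"mandatory column {colmap[logical]!r} (for {logical}) "
                    f"not found in {path.name}; available: {sorted(header)}"
                )

        def get(row: dict, logical: str) -> str | None:
            col = colmap.get(logical)
            return row.get(col) if col else None

        for i, row in enumerate(reader):
            rid = get(row, "record_id") or f"{path.name}:{i}"
            year_raw = _parse_float(get(row, "year"))
            adj = _parse_bool(get(row, "altitude_adjusted"))
            records.append(
                HbRecord(
                    record_id=str(rid),
                    survey_id=str(get(row, "survey_id")),
                    group=Group.parse(get(row, "group") or ""),
                    hb_gdl=_parse_float(get(row, "hb_gdl")),
                    altitude_m=_parse_float(get(row, "altitude_m")),
                    pregnant=_parse_bool(get(row, "pregnant")),
                    altitude_adjusted=True if adj is None else adj,
                    country=(get(row, "country") or "").strip(),
                    site=(get(row, "site") or "").strip(),
                    year=int(year_raw) if year_raw is not None else None,
                )
            )
    return records


def mark_validity(
    records: Iterable[HbRecord],
    policy: InclusionPolicy | None = None,
) -> list[HbRecord]:
    """Flag each record valid iff its Hb lies inside the device range.

    Missing Hb is invalid. No records are dropped; the operation is
    idempotent. Bounds are inclusive (the device reports 0 and 25.6).
    """
    policy = policy or InclusionPolicy()
    lo, hi = policy.validity_range
    out = []
    for r in records:
        ok = r.hb_gdl is not None and lo <= r.hb_gdl <= hi
        out.append(r if r.valid == ok else replace(r, valid=ok))
    return out


def dedupe(records: Sequence[HbRecord]) -> list[HbRecord]:
    """Drop exact duplicate rows (every field equal), keeping first occurrence.

    Rows sharing a record_id but differing in any field are both kept with a
    logged warning: silently dropping measurements would distort the
    distribution shape the QC statistics describe.
    """
    seen: set[HbRecord] = set()
    out: list[HbRecord] = []
    id_counts: Counter[tuple[str, str]] = Counter()
    n_dropped = 0
    for r in records:
        if r in seen:
            n_dropped += 1
            continue
        seen.add(r)
        id_counts[(r.survey_id, r.record_id)] += 1
        out.append(r)
    if n_dropped:
        logger.info("dedupe: removed %d exact-duplicate rows", n_dropped)
    n_clash = sum(1 for c in id_counts.values() if c > 1)
    if n_clash:
        logger.warning(
            "dedupe: %d record_ids repeat with differing fields; all kept", n_clash
        )
    return out


def include_survey(
    survey: Survey, policy: InclusionPolicy | None = None
) -> tuple[bool, str]:
    """Apply the >=30%-valid inclusion rule; returns (included, reason)."""
    policy = policy or InclusionPolicy()
    n_sampled = survey.effective_n_sampled()
    if n_sampled == 0:
        return False, "no sample"
    n_valid = survey.n_valid
    frac = n_valid / n_sampled
    if n_valid < policy.min_n_valid:
        return False, f"only {n_valid} valid Hb values"
    if frac < policy.min_valid_fraction:
        return False, (
            f"valid fraction {frac:.1%} below "
            f"{policy.min_valid_fraction:.0%} threshold"
        )
    return True, "included"


def assemble_surveys(
    records: Sequence[HbRecord],
    policy: InclusionPolicy | None = None,
    *,
    n_sampled: Mapping[tuple[str, str], int] | None = None,
) -> list[Survey]:
    """Group records into surveys, applying the full ingestion pipeline.

    Steps: dedupe -> drop pregnant WRA (the analysis covers non-pregnant
    women only; a missing pregnancy flag is treated as non-pregnant and
    logged) -> mark validity -> group by (survey_id, group). ``n_sampled``
    optionally maps (survey_id, group value) to the number approached.
    """
    policy = policy or InclusionPolicy()
    records = dedupe(records)
    kept: list[HbRecord] = []
    n_pregnant = n_unflagged = 0
    for r in records:
        if r.group is Group.WRA and r.pregnant:
            n_pregnant += 1
            continue
        if r.group is Group.WRA and r.pregnant is None:
            n_unflagged += 1
        kept.append(r)
    if n_pregnant:
        logger.info("assemble_surveys: dropped %d pregnant WRA records", n_pregnant)
    if n_unflagged:
        logger.info(
            "assemble_surveys: %d WRA records lacked a pregnancy flag; "
            "treated as non-pregnant", n_unflagged,
        )
    kept = mark_validity(kept, policy)

    by_key: dict[tuple[str, Group], Survey] = {}
    for r in kept:
        key = (r.survey_id, r.group)
        if key not in by_key:
            ns = None
            if n_sampled is not None:
                ns = n_sampled.get((r.survey_id, r.group.value))
            by_key[key] = Survey(
                survey_id=r.survey_id, group=r.group, country=r.country,
                site=r.site, year=r.year, n_sampled=ns,
            )
        by_key[key].records.append(r)
    return list(by_key.values())


def read_surveys(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    policy: InclusionPolicy | None = None,
    *,
    delimiter: str = ",",
) -> list[Survey]:
    """Convenience: :func:`read_records` then :func:`assemble_surveys`."""
    return assemble_surveys(
        read_records(path, schema, delimiter=delimiter), policy
    )
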