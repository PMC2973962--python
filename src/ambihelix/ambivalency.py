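"""Conformational-shift quantification, binning and helix classification.

For each mapped occurrence of a fully helical query segment, the
*conformational shift* is the percentage of occurrence positions annotated
non-helical in the target chain.  A helix with several occurrences is placed
in the decade bin of its *maximum* shift: bins are left-open/right-closed
decades, so 0 stays in the 0% bin, shifts in (0, 10] go to the 10% bin,
(10, 20] to 20%, and so on.  Classes: CONSERVED (all occurrences fully
helical), VARIABLE (at least one occurrence with 100% shift), PARTIAL
(anything in between), UNMAPPED (no occurrence at all).

When SCOP labels are present on both sides, per-helix fold/domain
concordance is the fraction of occurrences whose target chain shares the
query chain's label.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .helix_ops import HelixSegment
from .io_model import ChainDatabase, ChainRecord
from .mapping import MappingOccurrence

__all__ = [
    "HelixClass",
    "HelixAmbivalencyRecord",
    "percent_shift",
    "assign_bin",
    "classify",
    "concordance",
    "aggregate_records",
    "length_shift_table",
    "write_records_tsv",
]

#: Default length-class boundaries (upper edges, inclusive) for the
#: length-vs-shift table; the last class is open-ended.
DEFAULT_LENGTH_BREAKS = (9, 14, 19, 29)


class HelixClass(str, Enum):
    CONSERVED = "CONSERVED"
    PARTIAL = "PARTIAL"
    VARIABLE = "VARIABLE"
    UNMAPPED = "UNMAPPED"


@dataclass
class HelixAmbivalencyRecord:
    """Per-helix aggregate over all of its mapped occurrences."""

    helix: HelixSegment
    shifts: list[float] = field(default_factory=list)
    same_fold_fraction: Optional[float] = None
    same_domain_fraction: Optional[float] = None

    @property
    def n_occurrences(self) -> int:
        return len(self.shifts)

    @property
    def max_shift(self) -> Optional[float]:
        return max(self.shifts) if self.shifts else None

    @property
    def bin(self) -> Optional[int]:
        return assign_bin(self.shifts) if self.shifts else None

    @property
    def klass(self) -> HelixClass:
        return classify(self.shifts)


def percent_shift(occurrence: MappingOccurrence) -> float:
    """Percentage of occurrence positions annotated non-helical."""
    flags = occurrence.per_position_helical
    n = len(flags)
    if n == 0:
        raise ValueError("empty occurrence")
    return 100.0 * sum(1 for f in flags if not f) / n


def assign_bin(shifts: Sequence[float]) -> int:
    """Decade bin of the maximum shift: 0 iff max == 0, else 10*ceil(max/10)."""
    if not shifts:
        raise ValueError("cannot bin a helix with no occurrences")
    mx = max(shifts)
    if not (0.0 <= mx <= 100.0):
        raise ValueError(f"shift {mx} outside [0, 100]")
    if mx == 0.0:
        return 0
    return 10 * math.ceil(mx / 10.0)


def classify(shifts: Sequence[float]) -> HelixClass:
    """CONSERVED / PARTIAL / VARIABLE / UNMAPPED from an occurrence shift list."""
    if not shifts:
        return HelixClass.UNMAPPED
    mx = max(shifts)
    if mx == 0.0:
        return HelixClass.CONSERVED
    if mx == 100.0:
        return HelixClass.VARIABLE
    return HelixClass.PARTIAL


def concordance(
    occurrences: Sequence[MappingOccurrence],
    query_chain: ChainRecord,
    target_db: ChainDatabase,
) -> tuple[Optional[float], Optional[float]]:
    """Fractions of occurrences sharing the query chain's SCOP fold / domain.

    Returns (None, None) components wherever labels are missing on the query
    side or on every target side.
    """
    def frac(attr: str) -> Optional[float]:
        q = getattr(query_chain, attr)
        if q is None or not occurrences:
            return None
        labels = [
            getattr(target_db[o.target_chain_key], attr) for o in occurrences
        ]
        labelled = [lab for lab in labels if lab is not None]
        if not labelled:
            return None
        return sum(1 for lab in labelled if lab == q) / len(labelled)

    return frac("scop_fold"), frac("scop_domain")


def aggregate_records(
    helices: Sequence[HelixSegment],
    occurrences: Sequence[MappingOccurrence],
    query_db: Optional[ChainDatabase] = None,
    target_db: Optional[ChainDatabase] = None,
) -> list[HelixAmbivalencyRecord]:
    """Group occurrences by helix and build one record per query helix.

    Helices with no occurrence get an UNMAPPED record.  Concordance is
    filled only when both databases (with SCOP labels) are supplied.
    """
    by_helix: dict[tuple, list[MappingOccurrence]] = defaultdict(list)
    for occ in occurrences:
        by_helix[occ.helix.key].append(occ)
    records = []
    for h in helices:
        occs = by_helix.get(h.key, [])
        rec = HelixAmbivalencyRecord(helix=h, shifts=[percent_shift(o) for o in occs])
        if query_db is not None and target_db is not None and occs:
            qchain = query_db.get(h.chain_key)
            if qchain is not None:
                rec.same_fold_fraction, rec.same_domain_fraction = concordance(
                    occs, qchain, target_db
                )
        records.append(rec)
    return records


def length_shift_table(
    records: Sequence[HelixAmbivalencyRecord],
    length_breaks: Sequence[int] = DEFAULT_LENGTH_BREAKS,
) -> pd.DataFrame:
    """Length-class counts, helix fractions and maximum lengths per shift bin.

    One row per occupied bin; columns hold the count of mapped helices per
    length class (classes are ``<=b`` ranges from ``length_breaks`` plus an
    open-ended last class), the fraction of all mapped helices falling in the
    bin, and the longest helix in the bin.  Fractions sum to 1 over bins.
    """
    mapped = [r for r in records if r.klass is not HelixClass.UNMAPPED]
    breaks = sorted(length_breaks)
    labels = []
    lo = 1
    for b in breaks:
        labels.append(f"{lo}-{b}")
        lo = b + 1
    labels.append(f">={lo}")

    def length_class(n: int) -> str:
        for b, lab in zip(breaks, labels):
            if n <= b:
                return lab
        return labels[-1]

    rows: dict[int, dict] = {}
    for r in mapped:
        b = r.bin
        row = rows.setdefault(
            b, {lab: 0 for lab in labels} | {"n_helices": 0, "max_length": 0}
        )
        row[length_class(r.helix.length)] += 1
        row["n_helices"] += 1
        row["max_length"] = max(row["max_length"], r.helix.length)
    total = len(mapped)
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "bin"
    if total:
        table["fraction"] = table["n_helices"] / total
    return table


def write_records_tsv(
    records: Iterable[HelixAmbivalencyRecord], path: str | Path
) -> None:
    """Per-helix record writer: span, occurrence count, max shift, bin, class,
    concordance fractions."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "structure_id\tchain_id\tstart\tend\tlength\tn_occurrences\t"
            "max_shift\tbin\tclass\tsame_fold_fraction\tsame_domain_fraction\n"
        )
        for r in records:
            h = r.helix
            mx = "NA" if r.max_shift is None else repr(float(r.max_shift))
            bn = "NA" if r.bin is None else str(r.bin)
            ff = "NA" if r.same_fold_fraction is None else repr(r.same_fold_fraction)
            df_ = (
                "NA"
                if r.same_domain_fraction is None
                else repr(r.same_domain_fraction)
            )
            fh.write(
                f"{h.chain_key[0]}\t{h.chain_key[1]}\t{h.start}\t{h.end}\t"
                f"{h.length}\t{r.n_occurrences}\t{mx}\t{bn}\t{r.klass.value}\t"
                f"{ff}\t{df_}\n"
            )
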