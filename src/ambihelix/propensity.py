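"""Normalized conformational parameter (CP) and flanking-sequence statistics.

For amino acid i in residue group j,

    CP_ij = f_ij / f_i = (n_ij / sum_i n_ij) / (N_i / sum_i N_i)

where n_ij counts residue i within the group and N_i counts it in the whole
background database.  CP > 1 marks a preference of residue i for the group.
The background is the composition of the entire query (non-redundant)
database, not just its helical residues.

Flanking sequences are the up-to-four residues immediately preceding
(N-terminal) or following (C-terminal) a helix or one of its mapped
occurrences; they are analysed separately per terminus and per source class
(helical conformation of variable helices, their non-helical occurrences, or
conserved helices), which exposes the N/C anisotropy of flank composition.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .ambivalency import HelixAmbivalencyRecord, HelixClass
from .helix_ops import HelixSegment
from .io_model import STANDARD_AA, ChainDatabase, ChainRecord, ResidueCounts
from .mapping import MappingOccurrence

__all__ = [
    "Terminus",
    "FlankClass",
    "PropensityTable",
    "FlankSet",
    "FlankWindow",
    "compute_cp",
    "cp_by_bin",
    "extract_flanks",
    "collect_flank_windows",
    "collect_flank_sets",
    "conformation_groups",
    "flank_cp",
    "write_cp_tables_tsv",
]


class Terminus(str, Enum):
    N = "N"
    C = "C"


class FlankClass(str, Enum):
    """Which population a flank belongs to."""

    HELICAL_CONF = "HELICAL_CONF"        # query helices of variable helices
    NONHELICAL_CONF = "NONHELICAL_CONF"  # their mapped (non-helical) occurrences
    CONSERVED = "CONSERVED"              # conserved helices


@dataclass
class PropensityTable:
    """Per-amino-acid CP values for a residue group against a background.

    ``cp[i]`` is None (absent) when residue i has zero background count.
    """

    group_name: str
    cp: dict[str, Optional[float]]
    group_counts: ResidueCounts
    background: ResidueCounts

    def as_series(self) -> pd.Series:
        return pd.Series(
            {aa: self.cp.get(aa) for aa in STANDARD_AA}, name=self.group_name,
            dtype=float,
        )


@dataclass
class FlankSet:
    """Flank strings of one terminus for one source class."""

    terminus: Terminus
    source_class: FlankClass
    per_flank_sequences: list[str] = field(default_factory=list)
    flank_width: int = 4

    def __post_init__(self) -> None:
        for s in self.per_flank_sequences:
            if len(s) > self.flank_width:
                raise ValueError(
                    f"flank {s!r} longer than flank_width {self.flank_width}"
                )

    @property
    def residues(self) -> ResidueCounts:
        return ResidueCounts.from_sequences(self.per_flank_sequences)


def compute_cp(
    group: ResidueCounts, background: ResidueCounts, group_name: str = ""
) -> PropensityTable:
    """Evaluate CP_ij for every standard amino acid.

    Residues absent from the background get an absent (None) CP rather than
    a division by zero — relevant for small synthetic databases.
    """
    if group.total == 0:
        raise ValueError("empty residue group")
    if background.total == 0:
        raise ValueError("empty background")
    cp: dict[str, Optional[float]] = {}
    for aa in STANDARD_AA:
        n_bg = background.counts.get(aa, 0)
        if n_bg == 0:
            cp[aa] = None
            continue
        f_group = group.counts.get(aa, 0) / group.total
        f_bg = n_bg / background.total
        cp[aa] = f_group / f_bg
    return PropensityTable(
        group_name=group_name, cp=cp, group_counts=group, background=background
    )


def cp_by_bin(
    records: Sequence[HelixAmbivalencyRecord],
    background: ResidueCounts,
) -> dict[int, PropensityTable]:
    """Per-bin CP tables, pooling the query-helix residues of each bin.

    Only mapped helices contribute; empty bins are simply absent.  Helices
    with non-standard residues are excluded, matching the mapping stage.
    """
    seqs_per_bin: dict[int, list[str]] = defaultdict(list)
    for r in records:
        if r.klass is HelixClass.UNMAPPED or r.helix.contains_x:
            continue
        seqs_per_bin[r.bin].append(r.helix.sequence)
    return {
        b: compute_cp(
            ResidueCounts.from_sequences(seqs), background, group_name=f"bin{b}"
        )
        for b, seqs in sorted(seqs_per_bin.items())
    }


def extract_flanks(
    segment: Union[HelixSegment, MappingOccurrence],
    chain: ChainRecord,
    flank_width: int = 4,
    terminus: Terminus = Terminus.N,
) -> str:
    """Residues adjacent to a helix or occurrence, truncated at chain ends.

    N-terminal flank: up to ``flank_width`` residues immediately preceding
    the segment start, in chain order; C-terminal flank: the residues
    immediately following the end.  'X' residues are retained in the string
    (count exclusion happens in :class:`ResidueCounts`).
    """
    if isinstance(segment, MappingOccurrence):
        start, end = segment.target_start, segment.target_end
        if segment.target_chain_key != chain.key:
            raise ValueError("occurrence does not belong to the given chain")
    else:
        start, end = segment.start, segment.end
        if segment.chain_key != chain.key:
            raise ValueError("helix does not belong to the given chain")
    if not (1 <= start <= end <= len(chain)):
        raise ValueError("segment coordinates outside chain")
    terminus = Terminus(terminus)
    if terminus is Terminus.N:
        i0 = max(0, start - 1 - flank_width)
        return chain.sequence[i0 : start - 1]
    return chain.sequence[end : end + flank_width]


@dataclass(frozen=True)
class FlankWindow:
    """One flank with its chain and 1-based residue positions (for RSA)."""

    terminus: Terminus
    source_class: FlankClass
    chain: ChainRecord
    positions: tuple[int, ...]

    @property
    def sequence(self) -> str:
        return "".join(self.chain.sequence[p - 1] for p in self.positions)


def collect_flank_windows(
    records: Sequence[HelixAmbivalencyRecord],
    occurrences: Sequence[MappingOccurrence],
    query_db: ChainDatabase,
    target_db: ChainDatabase,
    flank_width: int = 4,
) -> list[FlankWindow]:
    """Locate the six flank populations: {N, C} x {helical conformation of
    variable helices, their non-helical occurrences, conserved helices}.

    Helical-conformation flanks come from the query chains around each
    variable helix; non-helical-conformation flanks from the target chains
    around each 100%-shift occurrence (one flank per occurrence); conserved
    flanks from the query chains around conserved helices.  Empty (fully
    truncated) flanks are dropped.
    """
    occ_by_helix: dict[tuple, list[MappingOccurrence]] = defaultdict(list)
    for o in occurrences:
        occ_by_helix[o.helix.key].append(o)
    windows: list[FlankWindow] = []

    def add(t: Terminus, c: FlankClass, chain: ChainRecord, start: int, end: int) -> None:
        if t is Terminus.N:
            pos = tuple(range(max(1, start - flank_width), start))
        else:
            pos = tuple(range(end + 1, min(len(chain), end + flank_width) + 1))
        if pos:
            windows.append(
                FlankWindow(terminus=t, source_class=c, chain=chain, positions=pos)
            )

    for r in records:
        if r.klass is HelixClass.VARIABLE:
            qchain = query_db[r.helix.chain_key]
            for t in Terminus:
                add(t, FlankClass.HELICAL_CONF, qchain, r.helix.start, r.helix.end)
            for o in occ_by_helix.get(r.helix.key, []):
                if not any(o.per_position_helical):  # the 100%-shift occurrences
                    tchain = target_db[o.target_chain_key]
                    for t in Terminus:
                        add(t, FlankClass.NONHELICAL_CONF, tchain,
                            o.target_start, o.target_end)
        elif r.klass is HelixClass.CONSERVED:
            qchain = query_db[r.helix.chain_key]
            for t in Terminus:
                add(t, FlankClass.CONSERVED, qchain, r.helix.start, r.helix.end)
    return windows


def collect_flank_sets(
    records: Sequence[HelixAmbivalencyRecord],
    occurrences: Sequence[MappingOccurrence],
    query_db: ChainDatabase,
    target_db: ChainDatabase,
    flank_width: int = 4,
) -> list[FlankSet]:
    """Flank strings per (terminus, source class); see
    :func:`collect_flank_windows` for the population definitions."""
    sets: dict[tuple[Terminus, FlankClass], FlankSet] = {
        (t, c): FlankSet(terminus=t, source_class=c, flank_width=flank_width)
        for t in Terminus
        for c in FlankClass
    }
    for w in collect_flank_windows(
        records, occurrences, query_db, target_db, flank_width
    ):
        sets[(w.terminus, w.source_class)].per_flank_sequences.append(w.sequence)
    return list(sets.values())


def conformation_groups(
    records: Sequence[HelixAmbivalencyRecord],
    occurrences: Sequence[MappingOccurrence],
    per_occurrence: bool = True,
) -> dict[str, ResidueCounts]:
    """Residue groups for conformation-class CP tables.

    ``CONSERVED``: residues of conserved helices; ``VARIABLE_HELICAL``:
    residues of variable helices in their helical (query) conformation;
    ``VARIABLE_NONHELICAL``: residues of their fully non-helical occurrences,
    counted once per occurrence by default (set ``per_occurrence=False`` to
    count each unique helix sequence once).  Helices with non-standard
    residues and empty groups are omitted.
    """
    occ_by_helix: dict[tuple, list[MappingOccurrence]] = defaultdict(list)
    for o in occurrences:
        occ_by_helix[o.helix.key].append(o)
    conserved: list[str] = []
    var_hel: list[str] = []
    var_non: list[str] = []
    for r in records:
        if r.helix.contains_x:
            continue
        if r.klass is HelixClass.CONSERVED:
            conserved.append(r.helix.sequence)
        elif r.klass is HelixClass.VARIABLE:
            var_hel.append(r.helix.sequence)
            n_full = sum(
                1
                for o in occ_by_helix.get(r.helix.key, [])
                if not any(o.per_position_helical)
            )
            var_non.extend([r.helix.sequence] * (n_full if per_occurrence else 1))
    groups = {
        "CONSERVED": conserved,
        "VARIABLE_HELICAL": var_hel,
        "VARIABLE_NONHELICAL": var_non,
    }
    return {
        name: ResidueCounts.from_sequences(seqs)
        for name, seqs in groups.items()
        if seqs
    }


def flank_cp(
    flank_sets: Sequence[FlankSet], background: ResidueCounts
) -> dict[tuple[Terminus, FlankClass], PropensityTable]:
    """CP tables per (terminus, source class); empty flank sets are absent."""
    out = {}
    for fs in flank_sets:
        counts = fs.residues
        if counts.total == 0:
            continue
        out[(fs.terminus, fs.source_class)] = compute_cp(
            counts,
            background,
            group_name=f"{fs.source_class.value}_{fs.terminus.value}flank",
        )
    return out


def write_cp_tables_tsv(
    tables: Mapping[object, PropensityTable] | Sequence[PropensityTable],
    path: str | Path,
    long_format: bool = False,
) -> None:
    """Write CP tables as TSV: wide (rows = amino acids, columns = groups) or
    long format (group, amino_acid, cp) for plotting."""
    if isinstance(tables, Mapping):
        tables = list(tables.values())
    df = pd.DataFrame({t.group_name: t.as_series() for t in tables})
    df.index.name = "amino_acid"
    if long_format:
        long = df.reset_index().melt(
            id_vars="amino_acid", var_name="group", value_name="cp"
        )
        long.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        df.to_csv(path, sep="\t", na_rep="NA")
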