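"""Exact-sequence mapping of query helices into a target chain database.

The reference algorithm builds, for a helix of length N and a target chain of
length M, an N x M match matrix A with A(i, j) = 1 iff helix position i and
chain position j carry the same residue; the helix maps at target position l
(1-based) whenever the diagonal sum from A(1, l) equals N, i.e. the helix
sequence occurs verbatim at l .. l+N-1.  Every occurrence is reported,
including overlapping ones — nothing is deduplicated.

:func:`map_helix_fast` is an equivalent k-mer-indexed search used for whole
databases; its contract is exact-match completeness, with the matrix
algorithm as the oracle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .helix_ops import HELICAL_CODES, HelixSegment
from .io_model import ChainDatabase, ChainRecord

__all__ = ["MappingOccurrence", "TargetIndex", "map_helix_naive",
           "map_helix_fast", "map_all", "write_occurrences_tsv",
           "read_occurrences_tsv"]


@dataclass(frozen=True)
class MappingOccurrence:
    """One exact occurrence of a query helix in a target chain.

    ``target_start``/``target_end`` are 1-based inclusive;
    ``per_position_helical`` applies the H/G binarization to the target's
    secondary structure over the occurrence window.
    """

    helix: HelixSegment
    target_chain_key: tuple[str, str]
    target_start: int
    target_end: int
    target_ss_slice: str
    per_position_helical: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.helix.sequence)
        if self.target_end - self.target_start + 1 != n:
            raise ValueError("occurrence window does not match helix length")
        if len(self.per_position_helical) != n:
            raise ValueError("per_position_helical length mismatch")


def _occurrence(helix: HelixSegment, target: ChainRecord, j0: int) -> MappingOccurrence:
    n = len(helix.sequence)
    ss_slice = target.ss[j0 : j0 + n]
    return MappingOccurrence(
        helix=helix,
        target_chain_key=target.key,
        target_start=j0 + 1,
        target_end=j0 + n,
        target_ss_slice=ss_slice,
        per_position_helical=tuple(c in HELICAL_CODES for c in ss_slice),
    )


def map_helix_naive(helix: HelixSegment, target: ChainRecord) -> list[MappingOccurrence]:
    """Find all exact occurrences via the N x M match-matrix algorithm."""
    if not helix.sequence:
        raise ValueError("empty helix sequence")
    if helix.contains_x:
        raise ValueError(
            f"helix {helix.key} contains non-standard residues; pre-filter 'X' "
            "helices before mapping"
        )
    n, m = len(helix.sequence), len(target.sequence)
    if m < n:
        return []
    h = np.frombuffer(helix.sequence.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(target.sequence.encode("ascii"), dtype=np.uint8)
    # 'X' in the target matches nothing (the helix carries no 'X').
    a = h[:, None] == t[None, :]
    out = []
    for j0 in range(m - n + 1):
        if a[0, j0] and all(a[i, j0 + i] for i in range(1, n)):
            out.append(_occurrence(helix, target, j0))
    return out


class TargetIndex:
    """k-mer index over a target database for exact substring search.

    Seeds of length ``k`` (default 5, the minimum helix length) anchor
    candidate positions which are then verified by direct comparison;
    helices shorter than ``k`` fall back to a linear scan.  Output is
    identical to running the match-matrix algorithm on every chain.
    """

    def __init__(self, db: ChainDatabase, k: int = 5):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.db = db
        self.k = k
        self._kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ci, chain in enumerate(db):
            s = chain.sequence
            for j in range(len(s) - k + 1):
                kmer = s[j : j + k]
                if "X" not in kmer:
                    self._kmers[kmer].append((ci, j))

    def find(self, sequence: str) -> list[tuple[ChainRecord, int]]:
        """All (chain, 0-based start) positions where ``sequence`` occurs."""
        n = len(sequence)
        hits: list[tuple[ChainRecord, int]] = []
        if n >= self.k:
            seed = sequence[: self.k]
            for ci, j in self._kmers.get(seed, ()):
                chain = self.db.chains[ci]
                if chain.sequence[j : j + n] == sequence:
                    hits.append((chain, j))
        else:
            for chain in self.db:
                s = chain.sequence
                j = s.find(sequence)
                while j != -1:
                    hits.append((chain, j))
                    j = s.find(sequence, j + 1)
        return hits


def map_helix_fast(helix: HelixSegment, index: TargetIndex) -> list[MappingOccurrence]:
    """Index-accelerated mapping over every chain of the indexed database."""
    if not helix.sequence:
        raise ValueError("empty helix sequence")
    if helix.contains_x:
        raise ValueError(
            f"helix {helix.key} contains non-standard residues; pre-filter 'X' "
            "helices before mapping"
        )
    occs = [
        _occurrence(helix, chain, j) for chain, j in index.find(helix.sequence)
    ]
    order = {c.key: i for i, c in enumerate(index.db.chains)}
    occs.sort(key=lambda o: (order[o.target_chain_key], o.target_start))
    return occs


def map_all(
    query_helices: Sequence[HelixSegment],
    target_db: ChainDatabase,
    exclude_self: bool = True,
    *,
    index: Optional[TargetIndex] = None,
) -> list[MappingOccurrence]:
    """Map every query helix into every target chain.

    With ``exclude_self`` (default), occurrences in target chains whose
    structure_id equals the helix's source structure_id are removed, so a
    helix is never scored against its own structure.  Helices containing
    'X' are skipped (they can never match).
    """
    if index is None:
        index = TargetIndex(target_db)
    out: list[MappingOccurrence] = []
    for helix in query_helices:
        if helix.contains_x:
            continue
        for occ in map_helix_fast(helix, index):
            if exclude_self and occ.target_chain_key[0] == helix.chain_key[0]:
                continue
            out.append(occ)
    return out


def write_occurrences_tsv(
    occurrences: Iterable[MappingOccurrence],
    path: str | Path,
    shifts: Optional[Sequence[float]] = None,
) -> None:
    """Write occurrences as TSV; ``shifts`` optionally fills a percent-shift
    column (computed by the ambivalency stage)."""
    occurrences = list(occurrences)
    if shifts is not None and len(shifts) != len(occurrences):
        raise ValueError("shifts length must match occurrences")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "helix_structure_id\thelix_chain_id\thelix_start\thelix_end\t"
            "helix_sequence\ttarget_structure_id\ttarget_chain_id\t"
            "target_start\ttarget_end\ttarget_ss\tpercent_shift\n"
        )
        for i, o in enumerate(occurrences):
            shift = "NA" if shifts is None else repr(float(shifts[i]))
            fh.write(
                f"{o.helix.chain_key[0]}\t{o.helix.chain_key[1]}\t"
                f"{o.helix.start}\t{o.helix.end}\t{o.helix.sequence}\t"
                f"{o.target_chain_key[0]}\t{o.target_chain_key[1]}\t"
                f"{o.target_start}\t{o.target_end}\t{o.target_ss_slice}\t"
                f"{shift}\n"
            )


def read_occurrences_tsv(
    path: str | Path, source_db: str = ""
) -> list[MappingOccurrence]:
    """Read an occurrence TSV written by :func:`write_occurrences_tsv`.

    The file is self-contained: each row reconstructs both the helix segment
    and its occurrence (the percent-shift column, if present, is ignored —
    it is recomputed by the ambivalency stage).
    """
    out = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        (hsid, hcid, hstart, hend, hseq, tsid, tcid, tstart, tend, tss,
         _shift) = line.split("\t")
        helix = HelixSegment(
            chain_key=(hsid, hcid),
            start=int(hstart),
            end=int(hend),
            sequence=hseq,
            source_db=source_db,
        )
        out.append(
            MappingOccurrence(
                helix=helix,
                target_chain_key=(tsid, tcid),
                target_start=int(tstart),
                target_end=int(tend),
                target_ss_slice=tss,
                per_position_helical=tuple(c in HELICAL_CODES for c in tss),
            )
        )
    return out
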