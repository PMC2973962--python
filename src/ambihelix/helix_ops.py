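"""Binarization of secondary structure and helix-segment extraction.

Following the standard coarse definition, DSSP codes H (alpha-helix) and
G (3-10 helix) are helical; B, E, I, S, T and '-' are non-helical.  A helix
segment is a maximal run of helical codes; runs shorter than ``min_length``
(default 5) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_model import DSSP_ALPHABET, ChainRecord

__all__ = ["HELICAL_CODES", "HelixSegment", "is_helical", "extract_helices",
           "write_helices_tsv", "read_helices_tsv"]

HELICAL_CODES = frozenset("HG")


@dataclass(frozen=True)
class HelixSegment:
    """A maximal helical run within one chain.

    ``start``/``end`` are 1-based inclusive positions in the source chain;
    ``sequence`` is the corresponding slice of the chain sequence.
    """

    chain_key: tuple[str, str]
    start: int
    end: int
    sequence: str
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"helix {self.key}: span {self.start}-{self.end} does not match "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (*self.chain_key, self.start, self.end)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def contains_x(self) -> bool:
        """True for helices with non-standard residues; such helices are
        excluded from mapping (they can never match) and from propensity
        counts."""
        return "X" in self.sequence


def is_helical(ss_code: str) -> bool:
    """True iff the DSSP code is H or G."""
    if ss_code not in DSSP_ALPHABET:
        raise ValueError(f"unknown secondary-structure code {ss_code!r}")
    return ss_code in HELICAL_CODES


def extract_helices(
    chain: ChainRecord, min_length: int = 5, *, source_db: str = ""
) -> list[HelixSegment]:
    """Extract maximal helical runs of length >= ``min_length``, sorted by start.

    Binarization (H/G vs the rest) happens first, so one run may mix H and G
    codes and still count as a single helix.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    segments: list[HelixSegment] = []
    run_start: int | None = None
    for i, code in enumerate(chain.ss):
        if is_helical(code):
            if run_start is None:
                run_start = i
        elif run_start is not None:
            if i - run_start >= min_length:
                segments.append(_segment(chain, run_start, i, source_db))
            run_start = None
    if run_start is not None and len(chain.ss) - run_start >= min_length:
        segments.append(_segment(chain, run_start, len(chain.ss), source_db))
    return segments


def _segment(chain: ChainRecord, i0: int, i1: int, source_db: str) -> HelixSegment:
    return HelixSegment(
        chain_key=chain.key,
        start=i0 + 1,
        end=i1,
        sequence=chain.sequence[i0:i1],
        source_db=source_db,
    )


def write_helices_tsv(helices: Iterable[HelixSegment], path: str | Path) -> None:
    """Write helix segments as TSV: chain key, 1-based span, length, sequence."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("structure_id\tchain_id\tstart\tend\tlength\tsequence\n")
        for h in helices:
            fh.write(
                f"{h.chain_key[0]}\t{h.chain_key[1]}\t{h.start}\t{h.end}\t"
                f"{h.length}\t{h.sequence}\n"
            )


def read_helices_tsv(path: str | Path, source_db: str = "") -> list[HelixSegment]:
    """Read a helix TSV written by :func:`write_helices_tsv`."""
    helices = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        sid, cid, start, end, _length, seq = line.split("\t")
        helices.append(
            HelixSegment(
                chain_key=(sid, cid),
                start=int(start),
                end=int(end),
                sequence=seq,
                source_db=source_db,
            )
        )
    return helices
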