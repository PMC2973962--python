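"""Domain types and I/O for protein-chain secondary-structure databases.

The central object is the :class:`ChainRecord`: one protein chain with its
one-letter sequence, a per-residue 8-state secondary-structure string (DSSP
alphabet ``H G I B E S T -``), an optional absolute solvent-accessibility
vector (A^2), and structure-level metadata (experimental method, resolution,
crystallographic R-factor, optional SCOP labels).  Collections of chains are
held in a :class:`ChainDatabase`, which enforces unique (structure_id,
chain_id) keys.

Two on-disk representations are supported: classic DSSP text output
(:func:`read_dssp`) and a flat tab-separated "chain table" with one row per
chain (:func:`read_chain_table` / :func:`write_chain_table`), which is the
format the synthetic generator emits.

Conventions
-----------
* Internal coordinates are 0-based half-open; every report and on-disk
  format uses 1-based inclusive positions.
* Non-standard residues are stored as ``'X'``; ``'X'`` never matches during
  sequence mapping and is excluded from all residue counts.
* Chains are independent units; no inter-chain merging within a structure.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "STANDARD_AA",
    "DSSP_ALPHABET",
    "Method",
    "ChainRecord",
    "ChainDatabase",
    "ResidueCounts",
    "ChainTableError",
    "DSSPParseError",
    "read_dssp",
    "read_chain_table",
    "write_chain_table",
    "filter_chains",
    "background_counts",
    "write_helix_fasta",
    "read_helix_fasta",
]

#: The 20 standard amino acids, one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: DSSP 8-state alphabet; '-' marks "no assignment".
DSSP_ALPHABET = frozenset("HGIBEST-")


class Method(str, Enum):
    """Experimental method of the source structure."""

    XRAY = "XRAY"
    OTHER = "OTHER"


class ChainTableError(ValueError):
    """Raised for malformed or inconsistent chain-table rows."""


class DSSPParseError(ValueError):
    """Raised for malformed DSSP files; carries the offending line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ChainRecord:
    """One protein chain with per-residue annotation and metadata.

    Parameters
    ----------
    structure_id : str
        PDB-style 4-character code or synthetic identifier.
    chain_id : str
        Chain identifier (1+ characters; split segments carry ``/n`` suffixes).
    sequence : str
        One-letter amino-acid sequence over the 20 standard codes plus 'X'.
    ss : str
        Secondary-structure string over ``H G I B E S T -``; same length as
        ``sequence``.
    acc : numpy.ndarray or None
        Absolute solvent accessibility per residue (A^2), or None if unknown.
    """

    structure_id: str
    chain_id: str
    sequence: str
    ss: str
    acc: Optional[np.ndarray] = None
    method: Method = Method.OTHER
    resolution: Optional[float] = None
    r_factor: Optional[float] = None
    scop_class: Optional[str] = None
    scop_fold: Optional[str] = None
    scop_domain: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != len(self.ss):
            raise ChainTableError(
                f"chain {self.key}: sequence length {len(self.sequence)} != "
                f"ss length {len(self.ss)}"
            )
        bad = set(self.ss) - DSSP_ALPHABET
        if bad:
            raise ChainTableError(
                f"chain {self.key}: invalid secondary-structure codes {sorted(bad)}"
            )
        bad_aa = set(self.sequence) - _STANDARD_SET - {"X"}
        if bad_aa:
            raise ChainTableError(
                f"chain {self.key}: invalid residue letters {sorted(bad_aa)}"
            )
        if self.acc is not None:
            self.acc = np.asarray(self.acc, dtype=float)
            if len(self.acc) != len(self.sequence):
                raise ChainTableError(
                    f"chain {self.key}: acc length {len(self.acc)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if np.any(self.acc < 0):
                raise ChainTableError(f"chain {self.key}: negative accessibility")
        if isinstance(self.method, str):
            self.method = Method(self.method)
        if self.r_factor is not None and not (0.0 <= self.r_factor <= 1.0):
            raise ChainTableError(f"chain {self.key}: r_factor outside [0, 1]")
        if self.resolution is not None and self.resolution <= 0:
            raise ChainTableError(f"chain {self.key}: non-positive resolution")

    @property
    def key(self) -> tuple[str, str]:
        return (self.structure_id, self.chain_id)

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChainRecord):
            return NotImplemented
        if (self.acc is None) != (other.acc is None):
            return False
        acc_ok = self.acc is None or np.array_equal(self.acc, other.acc)
        return acc_ok and all(
            getattr(self, f) == getattr(other, f)
            for f in (
                "structure_id",
                "chain_id",
                "sequence",
                "ss",
                "method",
                "resolution",
                "r_factor",
                "scop_class",
                "scop_fold",
                "scop_domain",
            )
        )


class Role(str, Enum):
    """Whether a database supplies query helices or mapping targets."""

    QUERY = "QUERY"
    TARGET = "TARGET"


@dataclass
class ChainDatabase:
    """Ordered collection of :class:`ChainRecord` with unique chain keys."""

    chains: list[ChainRecord] = field(default_factory=list)
    name: str = ""
    role: Role = Role.QUERY

    def __post_init__(self) -> None:
        if isinstance(self.role, str):
            self.role = Role(self.role)
        seen: set[tuple[str, str]] = set()
        for c in self.chains:
            if c.key in seen:
                raise ChainTableError(f"duplicate chain key {c.key} in database")
            seen.add(c.key)
        self._by_key = {c.key: c for c in self.chains}

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self) -> Iterator[ChainRecord]:
        return iter(self.chains)

    def __getitem__(self, key: tuple[str, str]) -> ChainRecord:
        return self._by_key[key]

    def get(self, key: tuple[str, str]) -> Optional[ChainRecord]:
        return self._by_key.get(key)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._by_key


@dataclass
class ResidueCounts:
    """Amino-acid occurrence counts restricted to the 20 standard letters.

    ``counts`` holds per-letter tallies and ``total`` their sum; these are the
    n_ij / N_i numerator-denominator pairs of the normalized conformational
    parameter.
    """

    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def __post_init__(self) -> None:
        bad = set(self.counts) - _STANDARD_SET
        if bad:
            raise ValueError(f"non-standard letters in counts: {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative residue count")
        if self.total != sum(self.counts.values()):
            raise ValueError("total does not equal sum of counts")

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "ResidueCounts":
        """Count residues over sequences, silently dropping 'X'."""
        c = Counter()
        for s in sequences:
            c.update(s.upper())
        counts = {aa: n for aa, n in c.items() if aa in _STANDARD_SET}
        return cls(counts=counts, total=sum(counts.values()))

    def fraction(self, aa: str) -> float:
        if self.total == 0:
            raise ZeroDivisionError("empty residue counts")
        return self.counts.get(aa, 0) / self.total

    def __add__(self, other: "ResidueCounts") -> "ResidueCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ResidueCounts(counts=dict(merged), total=self.total + other.total)

    def scaled(self, k: int) -> "ResidueCounts":
        return ResidueCounts(
            counts={aa: n * k for aa, n in self.counts.items()},
            total=self.total * k,
        )


# ---------------------------------------------------------------------------
# DSSP reader
# ---------------------------------------------------------------------------

# Fixed columns of the classic DSSP per-residue table (0-based, half-open):
_DSSP_CHAIN_COL = 11
_DSSP_AA_COL = 13
_DSSP_SS_COL = 16
_DSSP_ACC_SLICE = slice(34, 38)


def read_dssp(
    path: str | Path,
    *,
    structure_id: Optional[str] = None,
    method: Method = Method.OTHER,
    resolution: Optional[float] = None,
    r_factor: Optional[float] = None,
    split_on_breaks: bool = True,
) -> list[ChainRecord]:
    """Parse classic DSSP text output into :class:`ChainRecord` objects.

    DSSP files carry no resolution/R-factor/method metadata, so those fields
    default to absent/OTHER unless supplied by the caller.  Chain-break rows
    (``'!'`` in the amino-acid column) split a chain into separate records
    when ``split_on_breaks`` is true (split segments get ``/2``, ``/3`` ...
    appended to the chain id); ``'!*'`` rows always terminate the current
    chain.  DSSP's lowercase letters (SS-bonded half-cystines) map to ``'C'``
    and a blank structure code maps to ``'-'``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    sid = structure_id
    header_end = None
    for i, line in enumerate(lines):
        if line.startswith("  #  RESIDUE"):
            header_end = i
            break
        if sid is None and line.startswith("HEADER"):
            tokens = line.rstrip(" .").split()
            if tokens and len(tokens[-1]) == 4:
                sid = tokens[-1]
    if header_end is None:
        raise DSSPParseError(f"{path}: no residue-table header ('  #  RESIDUE') found")
    if sid is None:
        sid = path.stem[:4].upper() or "UNK0"

    records: list[ChainRecord] = []
    segments_per_chain: Counter = Counter()
    cur_chain: Optional[str] = None
    seq: list[str] = []
    ss: list[str] = []
    acc: list[float] = []

    def flush() -> None:
        nonlocal seq, ss, acc
        if not seq:
            return
        segments_per_chain[cur_chain] += 1
        n = segments_per_chain[cur_chain]
        cid = cur_chain if n == 1 else f"{cur_chain}/{n}"
        records.append(
            ChainRecord(
                structure_id=sid,
                chain_id=cid,
                sequence="".join(seq),
                ss="".join(ss),
                acc=np.array(acc, dtype=float),
                method=method,
                resolution=resolution,
                r_factor=r_factor,
            )
        )
        seq, ss, acc = [], [], []

    for lineno, line in enumerate(lines[header_end + 1 :], start=header_end + 2):
        if not line.strip():
            continue
        if len(line) <= _DSSP_AA_COL:
            raise DSSPParseError(f"{path}:{lineno}: residue line too short")
        aa = line[_DSSP_AA_COL]
        if aa == "!":
            # '!*' ends a chain; plain '!' is a break within one chain.
            if line[_DSSP_AA_COL + 1 : _DSSP_AA_COL + 2] == "*" or split_on_breaks:
                flush()
            continue
        chain = line[_DSSP_CHAIN_COL].strip() or "_"
        if cur_chain is not None and chain != cur_chain:
            flush()
        cur_chain = chain
        if aa.islower():
            aa = "C"  # DSSP labels SS-bonded cystines a, b, c, ...
        elif aa not in _STANDARD_SET:
            aa = "X"
        code = line[_DSSP_SS_COL] if len(line) > _DSSP_SS_COL else " "
        code = "-" if code == " " else code
        if code not in DSSP_ALPHABET:
            raise DSSPParseError(
                f"{path}:{lineno}: unknown structure code {code!r}"
            )
        try:
            acc_val = float(line[_DSSP_ACC_SLICE])
        except ValueError as exc:
            raise DSSPParseError(f"{path}:{lineno}: bad ACC field") from exc
        seq.append(aa)
        ss.append(code)
        acc.append(acc_val)
    flush()
    return records


# ---------------------------------------------------------------------------
# Chain-table format
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = [
    "structure_id",
    "chain_id",
    "method",
    "resolution",
    "r_factor",
    "scop_class",
    "scop_fold",
    "scop_domain",
    "sequence",
    "ss",
    "acc",
]


def _fmt_opt(x: Optional[float | str]) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _parse_opt_float(tok: str, what: str, key: str) -> Optional[float]:
    if tok == "NA":
        return None
    try:
        return float(tok)
    except ValueError as exc:
        raise ChainTableError(f"chain {key}: bad {what} value {tok!r}") from exc


def read_chain_table(
    path: str | Path, *, name: str = "", role: Role = Role.QUERY
) -> ChainDatabase:
    """Read the tab-separated one-row-per-chain flat format.

    Columns: structure_id, chain_id, method, resolution, r_factor,
    scop_class, scop_fold, scop_domain, sequence, ss, acc.  ``acc`` is a
    comma-separated list of reals or ``NA``; optional scalar fields use
    ``NA``.  Lines starting with ``#`` are comments.
    """
    path = Path(path)
    chains: list[ChainRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_TABLE_COLUMNS):
                raise ChainTableError(
                    f"{path}:{lineno}: expected {len(_TABLE_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_TABLE_COLUMNS, fields))
            key = f"{row['structure_id']}_{row['chain_id']}"
            if row["acc"] == "NA":
                acc = None
            else:
                try:
                    acc = np.array(
                        [float(t) for t in row["acc"].split(",")], dtype=float
                    )
                except ValueError as exc:
                    raise ChainTableError(
                        f"chain {key}: malformed acc vector"
                    ) from exc
            try:
                rec = ChainRecord(
                    structure_id=row["structure_id"],
                    chain_id=row["chain_id"],
                    sequence=row["sequence"],
                    ss=row["ss"],
                    acc=acc,
                    method=Method(row["method"]),
                    resolution=_parse_opt_float(row["resolution"], "resolution", key),
                    r_factor=_parse_opt_float(row["r_factor"], "r_factor", key),
                    scop_class=None if row["scop_class"] == "NA" else row["scop_class"],
                    scop_fold=None if row["scop_fold"] == "NA" else row["scop_fold"],
                    scop_domain=None
                    if row["scop_domain"] == "NA"
                    else row["scop_domain"],
                )
            except ValueError as exc:
                raise ChainTableError(f"{path}:{lineno} ({key}): {exc}") from exc
            chains.append(rec)
    return ChainDatabase(chains=chains, name=name or path.stem, role=role)


def write_chain_table(db: ChainDatabase, path: str | Path) -> None:
    """Write a database in the flat chain-table format (lossless round trip)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_TABLE_COLUMNS) + "\n")
        for c in db:
            acc = (
                "NA"
                if c.acc is None
                else ",".join(repr(float(v)) for v in c.acc)
            )
            fh.write(
                "\t".join(
                    [
                        c.structure_id,
                        c.chain_id,
                        c.method.value,
                        _fmt_opt(c.resolution),
                        _fmt_opt(c.r_factor),
                        _fmt_opt(c.scop_class),
                        _fmt_opt(c.scop_fold),
                        _fmt_opt(c.scop_domain),
                        c.sequence,
                        c.ss,
                        acc,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Structure-quality filter and background composition
# ---------------------------------------------------------------------------


def filter_chains(
    db: ChainDatabase,
    max_resolution: float = 3.0,
    max_r: float = 0.3,
    xray_only: bool = True,
) -> ChainDatabase:
    """Apply the structure-quality filter: X-ray, resolution <= 3 A, R <= 0.3.

    Both thresholds are inclusive.  Chains lacking resolution or R-factor are
    dropped while the corresponding filter is active (pass ``math.inf`` to
    disable a numeric filter).
    """
    kept = []
    for c in db:
        if xray_only and c.method is not Method.XRAY:
            continue
        if math.isfinite(max_resolution):
            if c.resolution is None or c.resolution > max_resolution:
                continue
        if math.isfinite(max_r):
            if c.r_factor is None or c.r_factor > max_r:
                continue
        kept.append(c)
    return ChainDatabase(chains=kept, name=db.name, role=db.role)


def background_counts(db: ChainDatabase) -> ResidueCounts:
    """Residue composition over every chain of the database ('X' excluded)."""
    if len(db) == 0:
        raise ValueError("cannot compute background composition of an empty database")
    return ResidueCounts.from_sequences(c.sequence for c in db)


# ---------------------------------------------------------------------------
# FASTA for extracted helices
# ---------------------------------------------------------------------------


def write_helix_fasta(helices: Sequence, path: str | Path) -> None:
    """Write helix sequences as FASTA, headers ``structure_id_chain|start-end``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(h.sequence),
            id=f"{h.chain_key[0]}_{h.chain_key[1]}|{h.start}-{h.end}",
            description="",
        )
        for h in helices
    ]
    SeqIO.write(records, str(path), "fasta")


def read_helix_fasta(path: str | Path) -> list[tuple[tuple[str, str], int, int, str]]:
    """Read a helix FASTA back as (chain_key, start, end, sequence) tuples."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ident, _, span = rec.id.partition("|")
        sid, _, cid = ident.rpartition("_")
        start_s, _, end_s = span.partition("-")
        out.append(((sid, cid), int(start_s), int(end_s), str(rec.seq)))
    return out
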