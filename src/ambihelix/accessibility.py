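"""Relative solvent accessibility normalized by Gly-X-Gly maxima.

Absolute per-residue accessibility (DSSP's ACC column, A^2) is divided by
the maximum accessibility of that residue type in an extended Gly-X-Gly
tripeptide, giving a relative solvent accessibility (RSA) in [0, 1].  The
default maxima are the theoretical Gly-X-Gly values of Tien et al. (2013,
PLoS ONE 8:e80635); a user table can be supplied as two-column TSV
(letter, A^2).  DSSP occasionally reports ACC above the tripeptide maximum;
such values are capped at 1.0 and the cap is counted.

The flank-environment analysis averages RSA over the residues of each
flanking sequence and histograms those means per terminus and source class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import STANDARD_AA, ChainRecord

__all__ = [
    "TIEN_2013_THEORETICAL",
    "MaxAccTable",
    "normalize_acc",
    "flank_mean_rsa",
    "rsa_distribution",
    "write_histograms_tsv",
]

logger = logging.getLogger(__name__)

#: Theoretical maximum solvent accessibility (A^2) in extended Gly-X-Gly,
#: Tien et al. 2013.
TIEN_2013_THEORETICAL: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass(frozen=True)
class MaxAccTable:
    """Per-residue maximum accessibility (A^2) in Gly-X-Gly."""

    max_acc: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(STANDARD_AA) - set(self.max_acc)
        if missing:
            raise ValueError(f"max-acc table missing residues {sorted(missing)}")
        if any(v <= 0 for v in self.max_acc.values()):
            raise ValueError("max-acc values must be positive")

    @classmethod
    def default(cls) -> "MaxAccTable":
        return cls(max_acc=dict(TIEN_2013_THEORETICAL))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MaxAccTable":
        """Read a two-column TSV (one-letter code, maximum A^2)."""
        table: dict[str, float] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                aa, val = line.split("\t")
                table[aa.strip().upper()] = float(val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row") from exc
        return cls(max_acc=table)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("#amino_acid\tmax_acc\n")
            for aa in STANDARD_AA:
                fh.write(f"{aa}\t{self.max_acc[aa]}\n")


def normalize_acc(
    residue: str, acc: float, table: Optional[MaxAccTable] = None
) -> Optional[float]:
    """RSA of one residue: acc / max_acc, capped at 1.0; 'X' gives None."""
    if residue == "X":
        return None
    if table is None:
        table = MaxAccTable.default()
    if residue not in table.max_acc:
        raise ValueError(f"unknown residue {residue!r}")
    if acc < 0:
        raise ValueError("negative accessibility")
    rsa = acc / table.max_acc[residue]
    if rsa > 1.0:
        logger.debug("capping RSA %.3f for residue %s", rsa, residue)
        return 1.0
    return rsa


def count_capped(chain: ChainRecord, table: Optional[MaxAccTable] = None) -> int:
    """Number of residues whose absolute accessibility exceeds the tripeptide
    maximum (i.e. would be capped during normalization)."""
    if chain.acc is None:
        return 0
    if table is None:
        table = MaxAccTable.default()
    n = 0
    for aa, a in zip(chain.sequence, chain.acc):
        if aa != "X" and a > table.max_acc[aa]:
            n += 1
    return n


def flank_mean_rsa(
    positions: Sequence[int],
    chain: ChainRecord,
    table: Optional[MaxAccTable] = None,
) -> Optional[float]:
    """Mean RSA over 1-based flank positions; None if no usable residue.

    'X' residues are skipped; requires the chain's accessibility vector.
    """
    if chain.acc is None:
        raise ValueError(f"chain {chain.key} has no accessibility data")
    values = []
    for p in positions:
        if not (1 <= p <= len(chain)):
            raise ValueError(f"position {p} outside chain {chain.key}")
        rsa = normalize_acc(chain.sequence[p - 1], float(chain.acc[p - 1]), table)
        if rsa is not None:
            values.append(rsa)
    return float(np.mean(values)) if values else None


def rsa_distribution(
    means_by_class: Mapping[object, Sequence[float]],
    bin_width: float = 0.1,
) -> dict[object, pd.Series]:
    """Histogram of flank-mean RSA values per class, as fractions over [0, 1].

    Fractions sum to 1 within each class; classes with no usable flank are
    absent from the result.  Bin labels are left edges; the closed top edge
    1.0 falls into the last bin.
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must lie in (0, 1]")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out: dict[object, pd.Series] = {}
    for klass, means in means_by_class.items():
        means = [m for m in means if m is not None]
        if not means:
            continue
        counts, _ = np.histogram(means, bins=edges)
        out[klass] = pd.Series(
            counts / counts.sum(), index=np.round(edges[:-1], 9), name=str(klass)
        )
    return out


def write_histograms_tsv(
    histograms: Mapping[object, pd.Series], path: str | Path
) -> None:
    """Write RSA histograms as TSV: rows = bin left edges, columns = classes."""
    df = pd.DataFrame({str(k): v for k, v in histograms.items()})
    df.index.name = "rsa_bin"
    df.to_csv(path, sep="\t", na_rep="NA")
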