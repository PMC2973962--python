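"""Shared fixtures: synthetic chain databases and a miniature DSSP file.

All fixture data is generated programmatically; the DSSP text below is a
synthetic miniature following the classic fixed-column layout (it does not
describe any real structure).
"""

from __future__ import annotations

import pytest

from ambihelix import GeneratorConfig, PlantSpec, generate


def dssp_line(i: int, resnum: int, chain: str, aa: str, ss: str,
              acc: float) -> str:
    """One residue row of a classic DSSP table (fixed columns)."""
    line = f"{i:5d}{resnum:5d} {chain} {aa}  {ss}"
    return line.ljust(34) + f"{acc:4.0f}"


def dssp_break_line(i: int, star: bool = False) -> str:
    mark = "!*" if star else "! "
    return f"{i:5d}      " + " " * 2 + mark


DSSP_TABLE_HEADER = (
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA"
)


def make_dssp_text(rows: list[str], structure_id: str = "1ABC") -> str:
    """Assemble a synthetic DSSP file from pre-formatted residue rows."""
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        f"HEADER    SYNTHETIC FIXTURE                       01-JAN-00   {structure_id}",
        "  128  2  0  0  0 TOTAL NUMBER OF RESIDUES",
        DSSP_TABLE_HEADER,
    ]
    return "\n".join(header + rows) + "\n"


@pytest.fixture(scope="session")
def standard_plants() -> list[PlantSpec]:
    """Small design spanning all classes: conserved, partial, variable,
    unmapped, plus a Gly-enriched variable group."""
    gly_rich = {aa: (5.0 if aa == "G" else 1.0) for aa in "ACDEFGHIKLMNPQRSTVWY"}
    return [
        PlantSpec(helix_length=12, n_target_occurrences=1,
                  occurrence_shifts=[0], group_label="conserved"),
        PlantSpec(helix_length=15, n_target_occurrences=2,
                  occurrence_shifts=[0, 0], group_label="conserved"),
        PlantSpec(helix_length=12, n_target_occurrences=1,
                  occurrence_shifts=[75], group_label="partial"),
        PlantSpec(helix_length=10, n_target_occurrences=3,
                  occurrence_shifts=[50, 60, 70], group_label="partial",
                  scop_fold_match=[True, False, False],
                  scop_domain_match=[True, True, False]),
        PlantSpec(helix_length=12, n_target_occurrences=2,
                  occurrence_shifts=[100, 100], group_label="variable",
                  residue_bias=gly_rich),
        PlantSpec(helix_length=8, n_target_occurrences=0,
                  occurrence_shifts=[], group_label="unmapped"),
    ]


@pytest.fixture(scope="session")
def small_dbs(standard_plants):
    """(query, target, ground truth) for the standard small design."""
    return generate(standard_plants, seed=11, config=GeneratorConfig())
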