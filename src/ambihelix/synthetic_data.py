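"""Seeded generator of chain databases with planted ambivalent helices.

The generator emulates the structure of a query/target database pair: each
:class:`PlantSpec` places one fully helical segment in a query chain and a
configurable number of sequence-identical occurrences in target chains, each
occurrence carrying a prescribed conformational shift (fraction of positions
re-annotated with non-helical codes).  Residue composition of the planted
helices and of their four-residue flanks can be biased per group, giving
known ground truth for the propensity and flank-anisotropy statistics, and
per-region Beta-distributed accessibilities give ground truth for the
solvent-accessibility analysis.

The number of non-helical positions for a requested shift s and helix length
N is round-half-up(s*N/100); a positive shift that rounds to zero positions
(or a sub-100% shift that rounds to all N) is rejected as infeasible because
it would change the planted class.  Ground truth records the *realized*
shift 100*k/N.

Everything is driven by one ``numpy`` generator seeded from the config, so
identical seeds give byte-identical databases.  After generation every
planted sequence is scanned against both databases; accidental extra
occurrences trigger bounded regeneration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .accessibility import MaxAccTable
from .ambivalency import assign_bin, classify
from .io_model import STANDARD_AA, ChainDatabase, ChainRecord, Method, Role

__all__ = ["PlantSpec", "GeneratorConfig", "GroundTruth", "generate",
           "verify_no_collisions", "CollisionError"]

_NONHELICAL_CODES = "BEIST-"


class CollisionError(RuntimeError):
    """Planted sequences kept colliding with random context after all retries."""


@dataclass
class PlantSpec:
    """One planted helix and its target occurrences.

    ``occurrence_shifts`` are requested percentage shifts (one per
    occurrence); ``residue_bias`` and the flank biases are sampling weights
    over the 20 standard letters (uniform when None).  ``scop_fold_match`` /
    ``scop_domain_match`` say, per occurrence, whether the target chain gets
    the query chain's SCOP label (a single bool applies to all occurrences).
    """

    helix_length: int
    n_target_occurrences: int
    occurrence_shifts: Sequence[float] = ()
    group_label: str = ""
    residue_bias: Optional[Mapping[str, float]] = None
    n_flank_bias: Optional[Mapping[str, float]] = None
    c_flank_bias: Optional[Mapping[str, float]] = None
    scop_fold_match: bool | Sequence[bool] = True
    scop_domain_match: Optional[bool | Sequence[bool]] = None

    def __post_init__(self) -> None:
        if self.helix_length < 5:
            raise ValueError("helix_length must be >= 5")
        self.occurrence_shifts = list(self.occurrence_shifts)
        if len(self.occurrence_shifts) != self.n_target_occurrences:
            raise ValueError("occurrence_shifts length != n_target_occurrences")
        for s in self.occurrence_shifts:
            if not (0.0 <= s <= 100.0):
                raise ValueError(f"shift {s} outside [0, 100]")
            k = _n_nonhelical(s, self.helix_length)
            if s > 0 and k == 0:
                raise ValueError(
                    f"shift {s}% infeasible for length {self.helix_length}: "
                    "rounds to zero non-helical positions"
                )
            if s < 100 and k == self.helix_length:
                raise ValueError(
                    f"shift {s}% infeasible for length {self.helix_length}: "
                    "rounds to a fully non-helical occurrence"
                )
        if self.scop_domain_match is None:
            self.scop_domain_match = self.scop_fold_match

    def fold_matches(self) -> list[bool]:
        return _as_bool_list(self.scop_fold_match, self.n_target_occurrences)

    def domain_matches(self) -> list[bool]:
        return _as_bool_list(self.scop_domain_match, self.n_target_occurrences)


def _as_bool_list(v: bool | Sequence[bool], n: int) -> list[bool]:
    if isinstance(v, bool):
        return [v] * n
    v = list(v)
    if len(v) != n:
        raise ValueError("per-occurrence flag list length mismatch")
    return [bool(x) for x in v]


def _n_nonhelical(shift: float, length: int) -> int:
    """Round-half-up count of non-helical positions for a requested shift."""
    return int(np.floor(shift * length / 100.0 + 0.5))


@dataclass
class GeneratorConfig:
    """Global knobs of the generator.

    ``context_length`` is the number of random residues on each side of a
    planted segment (its innermost ``flank_width`` residues are the flank,
    drawn from the plant's flank bias).  ``shift_placement`` controls where
    the non-helical positions of an occurrence sit: a contiguous block at
    the C-terminal end ("cterm", mimicking fraying; default), at the
    N-terminal end ("nterm"), or "scattered" random positions.  ``acc_beta``
    maps region names (helix, occurrence, context, query_n_flank,
    query_c_flank, target_n_flank, target_c_flank) to Beta(a, b) parameters;
    absolute accessibility is Beta-sampled and scaled by the residue's
    Gly-X-Gly maximum.
    """

    context_length: int = 15
    flank_width: int = 4
    shift_placement: str = "cterm"
    n_decoy_target_chains: int = 2
    decoy_length: int = 60
    max_retries: int = 20
    acc_beta: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "helix": (1.5, 6.0),
            "occurrence": (2.0, 3.0),
            "context": (2.0, 2.5),
            "query_n_flank": (2.0, 5.0),
            "query_c_flank": (2.0, 5.0),
            "target_n_flank": (2.0, 5.0),
            "target_c_flank": (2.0, 5.0),
        }
    )

    def __post_init__(self) -> None:
        if self.context_length < self.flank_width:
            raise ValueError("context_length must be >= flank_width")
        if self.shift_placement not in ("cterm", "nterm", "scattered"):
            raise ValueError(f"unknown shift_placement {self.shift_placement!r}")


@dataclass
class GroundTruth:
    """Planted truth: per-helix shifts/bins/classes, per-group composition."""

    seed: int
    helices: list[dict] = field(default_factory=list)
    group_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    flank_composition: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "helices": self.helices,
                    "group_composition": self.group_composition,
                    "flank_composition": self.flank_composition,
                },
                indent=1,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            helices=d["helices"],
            group_composition=d["group_composition"],
            flank_composition=d["flank_composition"],
        )


def _weights(bias: Optional[Mapping[str, float]]) -> np.ndarray:
    if bias is None:
        return np.full(20, 1.0 / 20.0)
    w = np.array([float(bias.get(aa, 0.0)) for aa in STANDARD_AA])
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("residue bias weights must be non-negative, not all zero")
    return w / w.sum()


def _sample_seq(rng: np.random.Generator, n: int, p: np.ndarray) -> str:
    letters = rng.choice(list(STANDARD_AA), size=n, p=p)
    return "".join(letters)


def _sample_acc(
    rng: np.random.Generator,
    sequence: str,
    ab: tuple[float, float],
    max_table: Mapping[str, float],
) -> np.ndarray:
    frac = rng.beta(ab[0], ab[1], size=len(sequence))
    scale = np.array([max_table[aa] for aa in sequence])
    return frac * scale


def _occurrence_ss(
    rng: np.random.Generator, n: int, k: int, placement: str
) -> str:
    """Secondary structure of one target occurrence: k non-helical positions."""
    helical = rng.choice(list("HG"), size=n, p=[0.9, 0.1])
    codes = list(helical)
    if k == 0:
        return "".join(codes)
    if placement == "cterm":
        idx = range(n - k, n)
    elif placement == "nterm":
        idx = range(k)
    else:
        idx = rng.choice(n, size=k, replace=False)
    for i in idx:
        codes[i] = rng.choice(list(_NONHELICAL_CODES))
    return "".join(codes)


def generate(
    plants: Sequence[PlantSpec],
    seed: int,
    config: Optional[GeneratorConfig] = None,
) -> tuple[ChainDatabase, ChainDatabase, GroundTruth]:
    """Build a (query, target) database pair with planted ground truth.

    Each plant yields one query chain whose planted segment is fully helical
    and ``n_target_occurrences`` target chains each carrying one occurrence
    at the requested shift.  Contexts are re-sampled (up to
    ``config.max_retries`` full regenerations) until no planted sequence has
    accidental extra occurrences anywhere.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    for attempt in range(config.max_retries):
        query, target, truth = _generate_once(plants, rng, config, seed)
        planted: dict[str, int] = {}
        in_query: dict[str, int] = {}
        for h, spec in zip(truth.helices, plants):
            seq = h["sequence"]
            planted[seq] = planted.get(seq, 0) + spec.n_target_occurrences
            in_query[seq] = in_query.get(seq, 0) + 1
        report = verify_no_collisions(query, target, planted, in_query)
        if all(r["ok"] for r in report.values()):
            return query, target, truth
    raise CollisionError(
        f"could not avoid accidental occurrences after {config.max_retries} tries"
    )


def _generate_once(
    plants: Sequence[PlantSpec],
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    seed: int,
) -> tuple[ChainDatabase, ChainDatabase, GroundTruth]:
    max_table = MaxAccTable.default().max_acc
    fw = cfg.flank_width
    ctx = cfg.context_length - fw
    truth = GroundTruth(seed=seed)
    qchains: list[ChainRecord] = []
    tchains: list[ChainRecord] = []

    for k, spec in enumerate(plants):
        p_helix = _weights(spec.residue_bias)
        p_nfl = _weights(spec.n_flank_bias)
        p_cfl = _weights(spec.c_flank_bias)
        helix_seq = _sample_seq(rng, spec.helix_length, p_helix)
        fold = f"FOLD{k:03d}"
        domain = f"DOM{k:03d}"

        # --- query chain: context | n-flank | helix (all H/G) | c-flank | context
        left = _sample_seq(rng, ctx, _weights(None)) + _sample_seq(rng, fw, p_nfl)
        right = _sample_seq(rng, fw, p_cfl) + _sample_seq(rng, ctx, _weights(None))
        qseq = left + helix_seq + right
        helix_ss = "".join(rng.choice(list("HG"), size=spec.helix_length, p=[0.9, 0.1]))
        qss = (
            "".join(rng.choice(list(_NONHELICAL_CODES), size=len(left)))
            + helix_ss
            + "".join(rng.choice(list(_NONHELICAL_CODES), size=len(right)))
        )
        acc = np.concatenate(
            [
                _sample_acc(rng, left[:ctx], cfg.acc_beta["context"], max_table),
                _sample_acc(rng, left[ctx:], cfg.acc_beta["query_n_flank"], max_table),
                _sample_acc(rng, helix_seq, cfg.acc_beta["helix"], max_table),
                _sample_acc(rng, right[:fw], cfg.acc_beta["query_c_flank"], max_table),
                _sample_acc(rng, right[fw:], cfg.acc_beta["context"], max_table),
            ]
        )
        qchains.append(
            ChainRecord(
                structure_id=f"Q{k:03d}",
                chain_id="A",
                sequence=qseq,
                ss=qss,
                acc=acc,
                method=Method.XRAY,
                resolution=round(float(rng.uniform(1.2, 2.8)), 2),
                r_factor=round(float(rng.uniform(0.15, 0.25)), 3),
                scop_class="SYN",
                scop_fold=fold,
                scop_domain=domain,
            )
        )
        start = len(left) + 1
        realized = []
        fold_flags = spec.fold_matches()
        dom_flags = spec.domain_matches()

        # --- one target chain per occurrence
        for o, shift in enumerate(spec.occurrence_shifts):
            n_non = _n_nonhelical(shift, spec.helix_length)
            realized.append(100.0 * n_non / spec.helix_length)
            tleft = _sample_seq(rng, ctx, _weights(None)) + _sample_seq(rng, fw, p_nfl)
            tright = _sample_seq(rng, fw, p_cfl) + _sample_seq(rng, ctx, _weights(None))
            tseq = tleft + helix_seq + tright
            occ_ss = _occurrence_ss(
                rng, spec.helix_length, n_non, cfg.shift_placement
            )
            tss = (
                "".join(rng.choice(list(_NONHELICAL_CODES), size=len(tleft)))
                + occ_ss
                + "".join(rng.choice(list(_NONHELICAL_CODES), size=len(tright)))
            )
            tacc = np.concatenate(
                [
                    _sample_acc(rng, tleft[:ctx], cfg.acc_beta["context"], max_table),
                    _sample_acc(
                        rng, tleft[ctx:], cfg.acc_beta["target_n_flank"], max_table
                    ),
                    _sample_acc(rng, helix_seq, cfg.acc_beta["occurrence"], max_table),
                    _sample_acc(
                        rng, tright[:fw], cfg.acc_beta["target_c_flank"], max_table
                    ),
                    _sample_acc(rng, tright[fw:], cfg.acc_beta["context"], max_table),
                ]
            )
            tchains.append(
                ChainRecord(
                    structure_id=f"T{k:03d}{chr(ord('a') + o)}",
                    chain_id="A",
                    sequence=tseq,
                    ss=tss,
                    acc=tacc,
                    method=Method.XRAY,
                    resolution=round(float(rng.uniform(1.2, 2.8)), 2),
                    r_factor=round(float(rng.uniform(0.15, 0.25)), 3),
                    scop_class="SYN",
                    scop_fold=fold if fold_flags[o] else f"{fold}.alt",
                    scop_domain=domain if dom_flags[o] else f"{domain}.alt",
                )
            )

        shifts_sorted = sorted(realized)
        truth.helices.append(
            {
                "plant_index": k,
                "group_label": spec.group_label,
                "structure_id": f"Q{k:03d}",
                "chain_id": "A",
                "start": start,
                "end": start + spec.helix_length - 1,
                "sequence": helix_seq,
                "requested_shifts": list(spec.occurrence_shifts),
                "realized_shifts": realized,
                "bin": assign_bin(realized) if realized else None,
                "klass": classify(realized).value,
                "fold_matches": fold_flags,
                "domain_matches": dom_flags,
            }
        )
        if spec.group_label:
            truth.group_composition.setdefault(
                spec.group_label,
                {aa: float(w) for aa, w in zip(STANDARD_AA, p_helix)},
            )
            truth.flank_composition.setdefault(
                spec.group_label,
                {
                    "N": {aa: float(w) for aa, w in zip(STANDARD_AA, p_nfl)},
                    "C": {aa: float(w) for aa, w in zip(STANDARD_AA, p_cfl)},
                },
            )

    for d in range(cfg.n_decoy_target_chains):
        dseq = _sample_seq(rng, cfg.decoy_length, _weights(None))
        dss = "".join(rng.choice(list(_NONHELICAL_CODES), size=cfg.decoy_length))
        dacc = _sample_acc(rng, dseq, cfg.acc_beta["context"], max_table)
        tchains.append(
            ChainRecord(
                structure_id=f"D{d:03d}",
                chain_id="A",
                sequence=dseq,
                ss=dss,
                acc=dacc,
                method=Method.XRAY,
                resolution=round(float(rng.uniform(1.2, 2.8)), 2),
                r_factor=round(float(rng.uniform(0.15, 0.25)), 3),
                scop_class="SYN",
                scop_fold="FOLD.decoy",
                scop_domain="DOM.decoy",
            )
        )

    query = ChainDatabase(chains=qchains, name="synthetic_query", role=Role.QUERY)
    target = ChainDatabase(chains=tchains, name="synthetic_target", role=Role.TARGET)
    return query, target, truth


def _count_overlapping(haystack: str, needle: str) -> int:
    n, j = 0, haystack.find(needle)
    while j != -1:
        n += 1
        j = haystack.find(needle, j + 1)
    return n


def verify_no_collisions(
    query_db: ChainDatabase,
    target_db: ChainDatabase,
    planted: Mapping[str, int],
    expected_query: Optional[Mapping[str, int]] = None,
) -> dict[str, dict]:
    """Check each planted sequence occurs exactly as specified.

    ``planted`` maps each planted helix sequence to its expected number of
    target occurrences; each sequence must additionally occur in the query
    database exactly ``expected_query[seq]`` times (default once — plants
    sharing one sequence should pass their summed expectations).  Returns a
    per-sequence report with an ``ok`` flag.
    """
    report: dict[str, dict] = {}
    for seq, expected in planted.items():
        q_exp = 1 if expected_query is None else expected_query.get(seq, 1)
        t_obs = sum(_count_overlapping(c.sequence, seq) for c in target_db)
        q_obs = sum(_count_overlapping(c.sequence, seq) for c in query_db)
        report[seq] = {
            "expected_target": expected,
            "observed_target": t_obs,
            "expected_query": q_exp,
            "observed_query": q_obs,
            "ok": t_obs == expected and q_obs == q_exp,
        }
    return report
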