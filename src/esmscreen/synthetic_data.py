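"""Synthetic membrane-protein cohorts with known topology and planted motifs.

Because the screen's real inputs are externally curated sequences and
topology predictions, the test bed here is generative: multi-pass membrane
proteins with alternating cytoplasmic/exoplasmic loops, ground-truth
topology (emitted, not predicted), optional planted polybasic clusters with
a nearby serine, and an analytic null model for how often a qualifying
window arises by chance.

Defaults emulate human P-type ATPase catalytic subunits: ~800–1300 residues,
8–10 transmembrane helices of 19–23 residues, terminal tails of 30–120
residues, background per-residue K/R probability 0.11 and S/T/Y probability
0.15 (approximate human proteome composition). An even helix count places
both termini in the cytoplasm, as in the real family.

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    ProteinRecord,
    TopologyAnnotation,
    write_fasta,
    write_topology_threeline,
)

__all__ = [
    "PlantSpec",
    "SyntheticSpec",
    "GroundTruth",
    "SpecError",
    "generate_protein",
    "generate_cohort",
    "write_cohort",
    "null_window_probability",
]

# residues drawn inside TM helices: hydrophobic, never basic or phospho-acceptor
_TM_ALPHABET = "AFGILMVW"
# background alphabet outside the K/R and S/T/Y draws
_OTHER_RESIDUES = "ACDEFGHILMNPQVW"
_BASIC = "KR"
_PHOSPHO = "STY"


class SpecError(ValueError):
    """A synthetic spec is internally inconsistent or cannot be realised."""


@dataclass(frozen=True)
class PlantSpec:
    """One planted polybasic cluster.

    ``n_basic`` K/R residues are written into a ``span_len``-residue span of
    the chosen terminal tail (span endpoints are always basic, interior
    non-basic positions are alanine); when ``include_phospho`` a serine is
    written ``phospho_offset`` residues past the span end.
    """

    terminus: str  # "N" or "C"
    n_basic: int = 9
    span_len: int = 9
    phospho_offset: int = 2
    include_phospho: bool = True

    def __post_init__(self) -> None:
        if self.terminus not in {"N", "C"}:
            raise SpecError("plant terminus must be 'N' or 'C'")
        if self.span_len < self.n_basic:
            raise SpecError("plant span_len must be >= n_basic")
        if self.n_basic < 1:
            raise SpecError("plant n_basic must be >= 1")
        if self.phospho_offset < 1:
            raise SpecError("phospho_offset must be >= 1 (past the span end)")
        if self.span_len > 1 and self.n_basic < 2:
            raise SpecError(
                "a multi-residue span needs n_basic >= 2 (endpoints are basic)"
            )


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-level generation parameters (the study conditions)."""

    n_proteins: int = 20
    length_range: tuple[int, int] = (800, 1300)
    n_tm_range: tuple[int, int] = (8, 10)
    tail_length_range: tuple[int, int] = (30, 120)
    background_basic_prob: float = 0.11
    background_phospho_prob: float = 0.15
    plants: dict[int, PlantSpec] = field(default_factory=dict)
    search_depth: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise SpecError("n_proteins must be >= 0")
        p, q = self.background_basic_prob, self.background_phospho_prob
        if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0 and p + q <= 1.0):
            raise SpecError("background probabilities must lie in [0,1], p+q <= 1")
        if self.n_tm_range[0] < 2:
            raise SpecError("need at least 2 TM helices for two terminal tails")
        for index in self.plants:
            if not 0 <= index < self.n_proteins:
                raise SpecError(f"plant index {index} outside the cohort")
        if self.tail_length_range[0] < 1:
            raise SpecError("tails must have length >= 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, for use as a test oracle."""

    protein_id: str
    n_tail_span: tuple[int, int]
    c_tail_span: tuple[int, int]
    planted_terminus: Optional[str] = None
    planted_span: Optional[tuple[int, int]] = None  # protein coordinates
    planted_n_basic: int = 0
    planted_phosphosite: Optional[int] = None
    expected_candidate: bool = False


def _draw_background(rng: np.random.Generator, length: int, p: float, q: float) -> list[str]:
    draws = rng.random(length)
    out = []
    for u in draws:
        if u < p:
            out.append(_BASIC[rng.integers(0, 2)])
        elif u < p + q:
            out.append(_PHOSPHO[rng.integers(0, 3)])
        else:
            out.append(_OTHER_RESIDUES[rng.integers(0, len(_OTHER_RESIDUES))])
    return out


def generate_protein(
    index: int,
    spec: SyntheticSpec,
    seed: int,
) -> tuple[ProteinRecord, TopologyAnnotation, GroundTruth]:
    """Generate one synthetic membrane protein.

    Architecture: cytoplasmic N-tail, an even number of TM helices with
    alternating exoplasmic/cytoplasmic loops, cytoplasmic C-tail. The plant
    for this index (if any) is written into the designated tail inside the
    search depth. Identical (index, spec, seed) give identical output.
    """
    rng = np.random.default_rng((seed, index))
    p, q = spec.background_basic_prob, spec.background_phospho_prob

    lo_tm, hi_tm = spec.n_tm_range
    evens = [k for k in range(lo_tm, hi_tm + 1) if k % 2 == 0]
    if not evens:
        raise SpecError("n_tm_range contains no even helix count")
    n_tm = int(evens[rng.integers(0, len(evens))])
    tail_n = int(rng.integers(spec.tail_length_range[0], spec.tail_length_range[1] + 1))
    tail_c = int(rng.integers(spec.tail_length_range[0], spec.tail_length_range[1] + 1))
    tm_lens = [int(rng.integers(19, 24)) for _ in range(n_tm)]
    n_loops = n_tm - 1
    min_loop = 3
    fixed = tail_n + tail_c + sum(tm_lens) + min_loop * n_loops
    target = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    if fixed > spec.length_range[1]:
        raise SpecError(
            f"protein {index}: minimum architecture ({fixed} aa) exceeds "
            f"length_range upper bound {spec.length_range[1]}"
        )
    extra = max(target - fixed, 0)
    loop_extra = rng.multinomial(extra, [1.0 / n_loops] * n_loops) if n_loops else []
    loop_lens = [min_loop + int(e) for e in loop_extra]

    # assemble sequence and per-residue topology
    seq: list[str] = []
    topo: list[str] = []
    seq += _draw_background(rng, tail_n, p, q)
    topo += ["I"] * tail_n
    for t in range(n_tm):
        seq += [_TM_ALPHABET[rng.integers(0, len(_TM_ALPHABET))] for _ in range(tm_lens[t])]
        topo += ["M"] * tm_lens[t]
        if t < n_loops:
            # loops alternate: after TM1 -> outside, after TM2 -> inside, ...
            side = "O" if t % 2 == 0 else "I"
            seq += _draw_background(rng, loop_lens[t], p, q)
            topo += [side] * loop_lens[t]
    seq += _draw_background(rng, tail_c, p, q)
    topo += ["I"] * tail_c
    total_len = len(seq)
    c_tail_start = total_len - tail_c + 1

    protein_id = f"SYN{index:04d}"
    truth = GroundTruth(
        protein_id=protein_id,
        n_tail_span=(1, tail_n),
        c_tail_span=(c_tail_start, total_len),
    )

    plant = spec.plants.get(index)
    if plant is not None:
        tail_len = tail_n if plant.terminus == "N" else tail_c
        w = plant.span_len
        reach = plant.phospho_offset if plant.include_phospho else 0
        # the span must sit inside the searched region (prefix of an N-tail,
        # suffix of a C-tail) and the phosphosite inside the tail
        if plant.terminus == "N":
            min_local_start = 1
            max_local_start = min(spec.search_depth, tail_len - reach) - w + 1
        else:
            min_local_start = max(1, tail_len - spec.search_depth + 1)
            max_local_start = tail_len - reach - w + 1
        if max_local_start < min_local_start:
            raise SpecError(
                f"protein {protein_id}: planted span ({w} aa + offset {reach}) "
                f"does not fit in its {tail_len}-residue tail within the "
                f"search depth"
            )
        local_start = int(rng.integers(min_local_start, max_local_start + 1))
        if plant.terminus == "N":
            span_start = local_start
        else:
            span_start = c_tail_start + local_start - 1
        span_end = span_start + w - 1
        # choose which positions in the span are basic: endpoints always
        interior = list(range(span_start + 1, span_end))
        rng.shuffle(interior)
        basic_positions = sorted(
            ([span_start, span_end] if w > 1 else [span_start])
            + interior[: plant.n_basic - min(2, w)]
        )
        for pos in range(span_start, span_end + 1):
            seq[pos - 1] = "A"
        for pos in basic_positions:
            seq[pos - 1] = _BASIC[rng.integers(0, 2)]
        phospho_pos = None
        if plant.include_phospho:
            phospho_pos = span_end + plant.phospho_offset
            seq[phospho_pos - 1] = "S"
        truth.planted_terminus = plant.terminus
        truth.planted_span = (span_start, span_end)
        truth.planted_n_basic = plant.n_basic
        truth.planted_phosphosite = phospho_pos

    record = ProteinRecord(protein_id, "".join(seq), description=f"synthetic index={index}")
    annotation = _topology_from_string(protein_id, "".join(topo))
    return record, annotation, truth


def _topology_from_string(protein_id: str, topo: str) -> TopologyAnnotation:
    regions: list[tuple[str, int, int]] = []
    label_map = {"I": "inside", "O": "outside", "M": "TMhelix"}
    start = 0
    for i in range(1, len(topo) + 1):
        if i == len(topo) or topo[i] != topo[start]:
            regions.append((label_map[topo[start]], start + 1, i))
            start = i
    return TopologyAnnotation(protein_id=protein_id, regions=regions)


def generate_cohort(
    spec: SyntheticSpec,
    min_basic: int = 9,
) -> tuple[list[ProteinRecord], dict[str, TopologyAnnotation], list[GroundTruth]]:
    """Generate the whole cohort in memory.

    ``expected_candidate`` on each ground truth is filled in against the
    given detection threshold: a plant is expected to be found iff it has at
    least ``min_basic`` basics and an included phosphosite (both terminal
    tails are cytoplasmic by construction).
    """
    records: list[ProteinRecord] = []
    topologies: dict[str, TopologyAnnotation] = {}
    truths: list[GroundTruth] = []
    for index in range(spec.n_proteins):
        record, annotation, truth = generate_protein(index, spec, spec.seed)
        plant = spec.plants.get(index)
        truth.expected_candidate = bool(
            plant and plant.n_basic >= min_basic and plant.include_phospho
        )
        records.append(record)
        topologies[record.id] = annotation
        truths.append(truth)
    return records, topologies, truths


def write_cohort(
    spec: SyntheticSpec,
    outdir: str | Path,
    min_basic: int = 9,
    config_hash: str | None = None,
) -> dict[str, Path]:
    """Generate a cohort and write FASTA, threeline topology and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, topologies, truths = generate_cohort(spec, min_basic=min_basic)
    fasta = outdir / "cohort.fasta"
    topo = outdir / "cohort.topology.txt"
    truth_tsv = outdir / "cohort.truth.tsv"
    write_fasta(records, fasta, config_hash=config_hash)
    write_topology_threeline(
        [(r, topologies[r.id]) for r in records], topo, config_hash=config_hash
    )
    with open(truth_tsv, "w", encoding="utf-8", newline="\n") as out:
        out.write(
            "#protein_id\tn_tail\tc_tail\tplanted_terminus\tplanted_span\t"
            "planted_n_basic\tplanted_phosphosite\texpected_candidate\n"
        )
        for t in truths:
            span = (
                f"{t.planted_span[0]}-{t.planted_span[1]}" if t.planted_span else "-"
            )
            out.write(
                f"{t.protein_id}\t{t.n_tail_span[0]}-{t.n_tail_span[1]}\t"
                f"{t.c_tail_span[0]}-{t.c_tail_span[1]}\t"
                f"{t.planted_terminus or '-'}\t{span}\t{t.planted_n_basic}\t"
                f"{t.planted_phosphosite or '-'}\t{int(t.expected_candidate)}\n"
            )
    return {"fasta": fasta, "topology": topo, "truth": truth_tsv}


def null_window_probability(window_len: int, min_basic: int, basic_prob: float) -> float:
    """P[at least ``min_basic`` basics in one window of ``window_len``].

    Exact binomial upper tail: sum_{j=B}^{W} C(W,j) p^j (1-p)^(W-j) — the
    chance a single window of i.i.d. residues qualifies, the building block
    of the screen's false-positive calibration.
    """
    if not 0.0 <= basic_prob <= 1.0:
        raise ValueError("basic_prob must lie in [0, 1]")
    if not 1 <= min_basic <= window_len:
        raise ValueError("require 1 <= min_basic <= window_len")
    p = basic_prob
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    total = 0.0
    for j in range(min_basic, window_len + 1):
        total += math.comb(window_len, j) * p**j * (1.0 - p) ** (window_len - j)
    return min(total, 1.0)
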