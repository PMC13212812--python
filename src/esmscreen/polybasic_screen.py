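"""Sliding-window screen for electrostatic-switch hallmarks in terminal tails.

The screen looks for three things on a cytoplasmic terminal tail:

1. a *polybasic cluster* — at least ``min_basic`` lysine/arginine residues
   within a ``window_len``-residue window (defaults 9 within 30), scanned at
   step 1 over the ``search_depth`` residues nearest the terminus;
2. a potential *phosphosite* — an S, T or Y inside the qualifying window
   union or within ``phospho_flank`` residues of it (default 5), clipped to
   the tail so a site buried in the membrane never counts;
3. overall basic enrichment — the K+R density of the whole tail and a
   Henderson–Hasselbalch net side-chain charge at the reporting pH.

A terminus is an electrostatic-switch candidate when it is cytoplasmic and
carries at least one cluster with an attached phosphosite. Tails shorter than
``min_tail_len`` (default: one window) are excluded, not errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import ProteinRecord, TopologyAnnotation
from .tail_extraction import NotMembraneProteinError, TerminalTail, extract_tails

__all__ = [
    "ScreenConfig",
    "PolybasicCluster",
    "TerminusScreenResult",
    "ScreenTable",
    "scan_windows",
    "merge_windows",
    "attach_phosphosites",
    "kr_density",
    "net_tail_charge",
    "screen_protein",
    "screen_proteome",
]

#: Side-chain pKa values used by the net-charge summary. This scalar proxy is
#: a sequence-only convenience, not a substitute for a structure-based
#: electrostatic-surface calculation.
SIDE_CHAIN_PKA_BASIC = {"K": 10.5, "R": 12.5, "H": 6.0}
SIDE_CHAIN_PKA_ACIDIC = {"D": 3.9, "E": 4.1, "C": 8.3, "Y": 10.1}


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the polybasic screen.

    Defaults encode the published screen: >=9 K/R in a 30-residue window,
    phosphosites within the window or 5 flanking residues, scanning only the
    100 residues nearest each terminus, shorter-than-window tails excluded.
    """

    window_len: int = 30
    min_basic: int = 9
    phospho_flank: int = 5
    search_depth: int = 100
    phospho_residues: frozenset[str] = frozenset({"S", "T", "Y"})
    basic_residues: frozenset[str] = frozenset({"K", "R"})
    min_tail_len: Optional[int] = None  # None -> window_len
    report_pH: float = 7.0

    def __post_init__(self) -> None:
        if not (1 <= self.min_basic <= self.window_len):
            raise ValueError("require 1 <= min_basic <= window_len")
        if self.phospho_flank < 0:
            raise ValueError("phospho_flank must be >= 0")
        if self.search_depth < self.window_len:
            raise ValueError("search_depth must be >= window_len")
        if self.basic_residues != frozenset({"K", "R"}):
            raise ValueError("basic_residues is fixed to {K, R}")
        if self.min_tail_len is None:
            object.__setattr__(self, "min_tail_len", self.window_len)

    @property
    def effective_min_tail_len(self) -> int:
        return self.min_tail_len  # type: ignore[return-value]


@dataclass
class PolybasicCluster:
    """A merged run of qualifying windows, in 1-based protein coordinates."""

    protein_id: str
    terminus: str
    window_union_start: int
    window_union_end: int
    basic_span_start: int
    basic_span_end: int
    n_basic: int
    phosphosites: list[tuple[str, int]] = field(default_factory=list)
    qualifies_esm: bool = False


@dataclass
class TerminusScreenResult:
    """Screen outcome for one terminus of one protein."""

    tail: TerminalTail
    clusters: list[PolybasicCluster]
    kr_density: float
    net_charge: float
    is_candidate: bool
    exclusion_reason: Optional[str] = None


@dataclass
class ScreenTable:
    """Per-terminus screen rows plus cohort-level candidate summary."""

    table: pd.DataFrame
    summary: dict
    unscreened: list[str]


# ---------------------------------------------------------------------------
# Window scanning

def _scan_region(tail: TerminalTail, config: ScreenConfig) -> tuple[int, int]:
    """Tail-local 1-based bounds of the region scanned for windows."""
    length = tail.tail_length
    if tail.terminus == "N":
        return 1, min(length, config.search_depth)
    return max(1, length - config.search_depth + 1), length


def scan_windows(tail: TerminalTail, config: ScreenConfig) -> list[int]:
    """Return tail-local 1-based start positions of qualifying windows.

    A start ``s`` qualifies when the window ``[s, s + window_len - 1]`` lies
    fully inside the scanned region (the ``search_depth`` residues nearest
    the terminus) and contains at least ``min_basic`` K/R residues. Tails
    shorter than ``min_tail_len`` yield an empty result.
    """
    if tail.tail_length < config.effective_min_tail_len:
        return []
    lo, hi = _scan_region(tail, config)
    w = config.window_len
    seq = tail.sequence
    # prefix sums of basic-residue counts over the tail
    prefix = [0] * (len(seq) + 1)
    for i, ch in enumerate(seq):
        prefix[i + 1] = prefix[i] + (ch in config.basic_residues)
    starts = []
    for s in range(lo, hi - w + 2):
        if prefix[s + w - 1] - prefix[s - 1] >= config.min_basic:
            starts.append(s)
    return starts


def merge_windows(
    window_starts: Sequence[int], tail: TerminalTail, config: ScreenConfig
) -> list[PolybasicCluster]:
    """Merge overlapping or abutting qualifying windows into clusters.

    Each cluster's ``window_union`` is the union of a maximal run of
    qualifying windows; its ``basic_span`` is the first-to-last K/R within
    that union, and ``n_basic`` counts K/R over the union. Output is in
    protein coordinates.
    """
    if not window_starts:
        return []
    w = config.window_len
    runs: list[tuple[int, int]] = []  # tail-local (union_start, union_end)
    run_start = window_starts[0]
    run_end = window_starts[0] + w - 1
    for s in window_starts[1:]:
        if s <= run_end + 1:  # overlap or abut
            run_end = s + w - 1
        else:
            runs.append((run_start, run_end))
            run_start, run_end = s, s + w - 1
    runs.append((run_start, run_end))

    clusters = []
    offset = tail.start - 1  # tail-local -> protein coordinates
    for lo, hi in runs:
        segment = tail.sequence[lo - 1 : hi]
        basic_positions = [
            lo + i for i, ch in enumerate(segment) if ch in config.basic_residues
        ]
        clusters.append(
            PolybasicCluster(
                protein_id=tail.protein_id,
                terminus=tail.terminus,
                window_union_start=lo + offset,
                window_union_end=hi + offset,
                basic_span_start=basic_positions[0] + offset,
                basic_span_end=basic_positions[-1] + offset,
                n_basic=len(basic_positions),
            )
        )
    return clusters


def attach_phosphosites(
    cluster: PolybasicCluster,
    tail: TerminalTail,
    config: ScreenConfig,
    curated_sites: Optional[set[int]] = None,
) -> PolybasicCluster:
    """Attach S/T/Y residues in or near the cluster's window union.

    Candidate positions span the window union widened by ``phospho_flank`` on
    each side, clipped to the tail: a residue inside a TM helix is never
    kinase-accessible. When a curated site set is given (protein coordinates)
    the sequence-predicted sites are intersected with it, so curation narrows
    but never invents sites.
    """
    lo = max(cluster.window_union_start - config.phospho_flank, tail.start)
    hi = min(cluster.window_union_end + config.phospho_flank, tail.end)
    sites: list[tuple[str, int]] = []
    for pos in range(lo, hi + 1):
        residue = tail.sequence[pos - tail.start]
        if residue in config.phospho_residues:
            if curated_sites is not None and pos not in curated_sites:
                continue
            sites.append((residue, pos))
    return replace(cluster, phosphosites=sites, qualifies_esm=bool(sites))


# ---------------------------------------------------------------------------
# Tail-level metrics

def kr_density(tail: TerminalTail) -> float:
    """Fraction of the whole tail that is lysine or arginine."""
    basics = sum(1 for ch in tail.sequence if ch in {"K", "R"})
    return basics / tail.tail_length


def net_tail_charge(tail_sequence: str, pH: float = 7.0) -> float:
    """Net side-chain charge of a tail at a given pH.

    Sums Henderson–Hasselbalch fractional charges over titratable side chains
    (K, R, H positive; D, E, C, Y negative). Free termini are excluded: the
    tail is part of a longer chain.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    charge = 0.0
    for ch in tail_sequence:
        if ch in SIDE_CHAIN_PKA_BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (pH - SIDE_CHAIN_PKA_BASIC[ch]))
        elif ch in SIDE_CHAIN_PKA_ACIDIC:
            charge -= 1.0 / (1.0 + 10.0 ** (SIDE_CHAIN_PKA_ACIDIC[ch] - pH))
    return charge


# ---------------------------------------------------------------------------
# Protein- and cohort-level screening

def _screen_tail(
    tail: TerminalTail,
    config: ScreenConfig,
    curated_sites: Optional[set[int]],
) -> TerminusScreenResult:
    density = kr_density(tail)
    charge = net_tail_charge(tail.sequence, config.report_pH)
    if tail.tail_length < config.effective_min_tail_len:
        return TerminusScreenResult(
            tail=tail,
            clusters=[],
            kr_density=density,
            net_charge=charge,
            is_candidate=False,
            exclusion_reason="excluded: tail shorter than window",
        )
    if not tail.cytoplasmic:
        return TerminusScreenResult(
            tail=tail,
            clusters=[],
            kr_density=density,
            net_charge=charge,
            is_candidate=False,
            exclusion_reason="excluded: tail not cytoplasmic",
        )
    starts = scan_windows(tail, config)
    clusters = [
        attach_phosphosites(c, tail, config, curated_sites)
        for c in merge_windows(starts, tail, config)
    ]
    return TerminusScreenResult(
        tail=tail,
        clusters=clusters,
        kr_density=density,
        net_charge=charge,
        is_candidate=any(c.qualifies_esm for c in clusters),
        exclusion_reason="needs_review: beta/re-entrant region in tail"
        if tail.needs_review
        else None,
    )


def screen_protein(
    record: ProteinRecord,
    topology: TopologyAnnotation,
    config: ScreenConfig = ScreenConfig(),
    curated_sites: Optional[set[int]] = None,
) -> tuple[Optional[TerminusScreenResult], Optional[TerminusScreenResult]]:
    """Screen both termini of one protein; absent tails yield ``None``."""
    n_tail, c_tail = extract_tails(record, topology)
    n_res = _screen_tail(n_tail, config, curated_sites) if n_tail else None
    c_res = _screen_tail(c_tail, config, curated_sites) if c_tail else None
    return n_res, c_res


def _result_row(
    record: ProteinRecord,
    terminus: str,
    result: Optional[TerminusScreenResult],
) -> dict:
    if result is None:
        return {
            "protein_id": record.id,
            "family": record.family,
            "terminus": terminus,
            "tail_start": None,
            "tail_end": None,
            "tail_length": 0,
            "cytoplasmic": False,
            "kr_density": None,
            "net_charge_pH7": None,
            "cluster_window_union": "",
            "cluster_basic_span": "",
            "n_basic": 0,
            "phosphosites": "",
            "is_candidate": False,
            "exclusion_reason": "tail absent",
        }
    tail = result.tail
    return {
        "protein_id": record.id,
        "family": record.family,
        "terminus": terminus,
        "tail_start": tail.start,
        "tail_end": tail.end,
        "tail_length": tail.tail_length,
        "cytoplasmic": tail.cytoplasmic,
        "kr_density": round(result.kr_density, 6),
        "net_charge_pH7": round(result.net_charge, 3),
        "cluster_window_union": ";".join(
            f"{c.window_union_start}-{c.window_union_end}" for c in result.clusters
        ),
        "cluster_basic_span": ";".join(
            f"{c.basic_span_start}-{c.basic_span_end}" for c in result.clusters
        ),
        "n_basic": max((c.n_basic for c in result.clusters), default=0),
        "phosphosites": ";".join(
            f"{res}{pos}" for c in result.clusters for res, pos in c.phosphosites
        ),
        "is_candidate": result.is_candidate,
        "exclusion_reason": result.exclusion_reason or "",
    }


def screen_proteome(
    records: Sequence[ProteinRecord],
    topologies: Mapping[str, TopologyAnnotation],
    config: ScreenConfig = ScreenConfig(),
    known_candidates: Iterable[str] = (),
    curated_sites: Optional[Mapping[str, set[int]]] = None,
) -> ScreenTable:
    """Screen a cohort and tabulate per-terminus rows plus summary counts.

    Rows follow input order with the N terminus before the C terminus.
    Summary counts classify candidate proteins as N-only, C-only or both
    (one protein with clusters at both ends counts once in the unique total),
    and report how many candidates are new relative to ``known_candidates``.
    Records lacking a topology are listed under ``unscreened``, not fatal.
    """
    known = set(known_candidates)
    rows: list[dict] = []
    unscreened: list[str] = []
    n_set: set[str] = set()
    c_set: set[str] = set()
    for record in records:
        topo = topologies.get(record.id)
        if topo is None:
            unscreened.append(record.id)
            continue
        curated = curated_sites.get(record.id) if curated_sites else None
        n_res, c_res = screen_protein(record, topo, config, curated)
        rows.append(_result_row(record, "N", n_res))
        rows.append(_result_row(record, "C", c_res))
        if n_res is not None and n_res.is_candidate:
            n_set.add(record.id)
        if c_res is not None and c_res.is_candidate:
            c_set.add(record.id)
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "family", "terminus", "tail_start", "tail_end",
            "tail_length", "cytoplasmic", "kr_density", "net_charge_pH7",
            "cluster_window_union", "cluster_basic_span", "n_basic",
            "phosphosites", "is_candidate", "exclusion_reason",
        ],
    )
    unique = n_set | c_set
    summary = {
        "n_only": len(n_set - c_set),
        "c_only": len(c_set - n_set),
        "both": len(n_set & c_set),
        "unique_candidates": len(unique),
        "additional_candidates": len(unique - known),
        "n_screened": len(records) - len(unscreened),
        "n_unscreened": len(unscreened),
    }
    return ScreenTable(table=table, summary=summary, unscreened=unscreened)
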