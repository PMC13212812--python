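"""Derive N- and C-terminal tails from transmembrane topology.

The terminal tails — the stretches before the first and after the last
transmembrane helix — are the unit of analysis for the electrostatic-switch
screen: only a terminus protruding into the cytoplasm can engage the
negatively charged inner membrane leaflet. A tail is *cytoplasmic* when every
non-membrane region it spans is annotated ``inside``; tails facing the
extracellular/luminal side are still reported but marked ineligible, and a
cleaved signal peptide at the N-terminus means there is no N-tail at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io_formats import ProteinRecord, TopologyAnnotation

__all__ = ["TerminalTail", "NotMembraneProteinError", "extract_tails"]


class NotMembraneProteinError(ValueError):
    """Raised when a topology contains no transmembrane helix."""


@dataclass
class TerminalTail:
    """One terminal tail in 1-based inclusive protein coordinates.

    ``needs_review`` flags tails overlapping beta/re-entrant regions, which
    are unexpected for an alpha-helical P-type ATPase and suggest a suspect
    topology prediction.
    """

    protein_id: str
    terminus: str  # "N" or "C"
    start: int
    end: int
    sequence: str
    cytoplasmic: bool
    needs_review: bool = False

    def __post_init__(self) -> None:
        if self.terminus not in {"N", "C"}:
            raise ValueError(f"terminus must be 'N' or 'C', got {self.terminus!r}")
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: tail start > end")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(f"{self.protein_id}: tail sequence/span mismatch")

    @property
    def tail_length(self) -> int:
        return self.end - self.start + 1


def _span_flags(
    topology: TopologyAnnotation, span_start: int, span_end: int
) -> tuple[bool, bool, bool]:
    """(all inside, contains signal, contains beta) over regions in the span."""
    all_inside = True
    has_signal = False
    has_beta = False
    for label, start, end in topology.regions:
        if end < span_start or start > span_end:
            continue
        if label == "signal":
            has_signal = True
        if label == "beta":
            has_beta = True
        if label not in {"inside", "TMhelix"}:
            all_inside = False
    return all_inside, has_signal, has_beta


def extract_tails(
    record: ProteinRecord, topology: TopologyAnnotation
) -> tuple[Optional[TerminalTail], Optional[TerminalTail]]:
    """Extract the (N, C) terminal tails of a membrane protein.

    The N-tail spans position 1 up to the residue before the first TM helix;
    the C-tail spans the residue after the last TM helix to the protein's end.
    A zero-length tail (helix at the very terminus) is returned as ``None``,
    as is an N-tail preceded by a signal peptide.

    Raises
    ------
    NotMembraneProteinError
        If the topology has no TM helix: the electrostatic switch requires an
        integral membrane protein.
    ValueError
        If topology and sequence lengths disagree.
    """
    if topology.length != len(record):
        raise ValueError(
            f"{record.id}: topology covers {topology.length} residues but the "
            f"sequence has {len(record)}"
        )
    tm_regions = [r for r in topology.regions if r[0] == "TMhelix"]
    if not tm_regions:
        raise NotMembraneProteinError(
            f"{record.id}: no transmembrane helix in topology"
        )
    first_tm_start = tm_regions[0][1]
    last_tm_end = tm_regions[-1][2]

    n_tail: Optional[TerminalTail] = None
    if first_tm_start > 1:
        span = (1, first_tm_start - 1)
        all_inside, has_signal, has_beta = _span_flags(topology, *span)
        if not has_signal:
            n_tail = TerminalTail(
                protein_id=record.id,
                terminus="N",
                start=span[0],
                end=span[1],
                sequence=record.sequence[span[0] - 1 : span[1]],
                cytoplasmic=all_inside,
                needs_review=has_beta,
            )

    c_tail: Optional[TerminalTail] = None
    if last_tm_end < len(record):
        span = (last_tm_end + 1, len(record))
        all_inside, _, has_beta = _span_flags(topology, *span)
        c_tail = TerminalTail(
            protein_id=record.id,
            terminus="C",
            start=span[0],
            end=span[1],
            sequence=record.sequence[span[0] - 1 : span[1]],
            cytoplasmic=all_inside,
            needs_review=has_beta,
        )
    return n_tail, c_tail
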