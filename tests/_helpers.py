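"""Shared test helpers: tail builders and independent brute-force oracles."""

from __future__ import annotations

from esmscreen import ScreenConfig, TerminalTail


def make_tail(
    sequence: str,
    terminus: str = "N",
    start: int = 1,
    protein_id: str = "p1",
    cytoplasmic: bool = True,
) -> TerminalTail:
    return TerminalTail(
        protein_id=protein_id,
        terminus=terminus,
        start=start,
        end=start + len(sequence) - 1,
        sequence=sequence,
        cytoplasmic=cytoplasmic,
    )


def naive_scan(tail: TerminalTail, config: ScreenConfig) -> list[int]:
    """Enumerate every window position; independent of the implementation."""
    length = len(tail.sequence)
    if length < config.effective_min_tail_len:
        return []
    if tail.terminus == "N":
        lo, hi = 1, min(length, config.search_depth)
    else:
        lo, hi = max(1, length - config.search_depth + 1), length
    starts = []
    for s in range(1, length - config.window_len + 2):
        if s < lo or s + config.window_len - 1 > hi:
            continue
        window = tail.sequence[s - 1 : s - 1 + config.window_len]
        if sum(ch in "KR" for ch in window) >= config.min_basic:
            starts.append(s)
    return starts


def naive_clusters(
    tail: TerminalTail, config: ScreenConfig
) -> list[tuple[int, int, int, int, int]]:
    """From-scratch cluster spans: (union_start, union_end, basic_start,
    basic_end, n_basic) in protein coordinates."""
    starts = naive_scan(tail, config)
    if not starts:
        return []
    w = config.window_len
    covered = set()
    for s in starts:
        covered.update(range(s, s + w))
    runs: list[list[int]] = []
    for pos in sorted(covered):
        if runs and pos == runs[-1][-1] + 1:
            runs[-1].append(pos)
        else:
            runs.append([pos])
    out = []
    offset = tail.start - 1
    for run in runs:
        basics = [p for p in run if tail.sequence[p - 1] in "KR"]
        out.append(
            (
                run[0] + offset,
                run[-1] + offset,
                basics[0] + offset,
                basics[-1] + offset,
                len(basics),
            )
        )
    return out
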