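"""Sliding-window scan for insertion-free regions within genes.

A gene whose termini tolerate insertions can hide an indispensable core
and be miscalled non-essential by the whole-gene insertion index.  A
fixed window (default 300 bp) slides along the gene in steps (default
150 bp); any window containing zero unique insertions flags the gene as
carrying a candidate essential domain.  Only genes currently called
non-essential or unclear are scanned, and flagged genes are (by
default) promoted to essential.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .essentiality import GeneCall
from .io_formats import GeneModel, GenomeAnnotation, InsertionSiteTable

__all__ = [
    "WINDOW_BP",
    "STEP_BP",
    "Window",
    "WindowScanResult",
    "place_windows",
    "scan_gene",
    "domain_correction",
]

log = logging.getLogger(__name__)

WINDOW_BP = 300
STEP_BP = 150

DEFAULT_SCOPE = ("non_essential", "unclear")


@dataclass(frozen=True)
class Window:
    offset_bp: int
    span_bp: int
    insertion_count: int

    @property
    def essential_window(self) -> bool:
        return self.insertion_count == 0


@dataclass
class WindowScanResult:
    gene_id: str
    windows: list[Window]

    @property
    def flagged(self) -> bool:
        return any(w.essential_window for w in self.windows)

    @property
    def n_zero_windows(self) -> int:
        return sum(1 for w in self.windows if w.essential_window)

    @property
    def first_zero_offset(self) -> int | None:
        for w in self.windows:
            if w.essential_window:
                return w.offset_bp
        return None


def place_windows(
    length: int,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    terminal_window: bool = True,
) -> list[tuple[int, int]]:
    """Gene-relative (offset, span) pairs for the sliding scan.

    Windows start at offsets 0, step, 2*step, ... while they fit inside
    the gene.  A gene shorter than the window gets a single window
    spanning its whole length.  When the length is not step-aligned an
    extra window anchored at the 3' end guarantees every base is covered;
    ``terminal_window=False`` reproduces the strict full-windows-only
    placement (possibly leaving a 3' tail unscanned).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0 < step <= window:
        raise ValueError("step must satisfy 0 < step <= window")
    if length < window:
        return [(0, length)]
    offsets = list(range(0, length - window + 1, step))
    placed = [(o, window) for o in offsets]
    if terminal_window and offsets[-1] + window < length:
        placed.append((length - window, window))
    return placed


def scan_gene(
    gene: GeneModel,
    sites: InsertionSiteTable,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    terminal_window: bool = True,
) -> WindowScanResult:
    """Count unique insertions in every placed window of one gene."""
    positions = sites.positions(gene.contig)
    lo = bisect_left(positions, gene.start)
    hi = bisect_left(positions, gene.end)
    rel = [positions[i] - gene.start for i in range(lo, hi)]
    windows = []
    for offset, span in place_windows(
        gene.length_bp, window=window, step=step, terminal_window=terminal_window
    ):
        count = bisect_left(rel, offset + span) - bisect_left(rel, offset)
        windows.append(Window(offset_bp=offset, span_bp=span, insertion_count=count))
    return WindowScanResult(gene_id=gene.gene_id, windows=windows)


def domain_correction(
    calls: Sequence[GeneCall],
    annotation: GenomeAnnotation,
    sites: InsertionSiteTable,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    terminal_window: bool = True,
    promote: bool = True,
    scope: Iterable[str] = DEFAULT_SCOPE,
) -> tuple[list[GeneCall], list[WindowScanResult]]:
    """Scan non-essential/unclear genes and promote flagged ones.

    Returns the (possibly updated) call list plus the scan results of
    every flagged gene.  ``promote=False`` is a report-only mode that
    sets ``domain_flag`` without touching the calls.
    """
    scope = set(scope)
    genes = {g.gene_id: g for g in annotation.genes}
    updated: list[GeneCall] = []
    flagged: list[WindowScanResult] = []
    for call in calls:
        if call.call not in scope:
            updated.append(call)
            continue
        gene = genes.get(call.gene_id)
        if gene is None:
            raise ValueError(f"call for unknown gene {call.gene_id!r}")
        result = scan_gene(
            gene, sites, window=window, step=step, terminal_window=terminal_window
        )
        if result.flagged:
            flagged.append(result)
            new_call = call.call
            if promote:
                new_call = "essential"
            updated.append(replace(call, call=new_call, domain_flag=True))
        else:
            updated.append(call)
    log.info("domain scan flagged %d gene(s)", len(flagged))
    return updated, flagged
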