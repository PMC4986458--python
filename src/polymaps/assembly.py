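"""Scaffold ordering/orientation along linkage maps and synteny-run counts.

Scaffolds are placed whole unless anchors on the same scaffold map to
different linkage groups (or to distant map positions), in which case the
scaffold is split at the midpoint between the conflicting anchors.  Ordering
within a pseudochromosome follows the median centimorgan position of a
scaffold's anchors (ties broken by prior-assembly rank); orientation flips
when within-scaffold anchor order anticorrelates with map position; scaffolds
with a single anchor keep their prior orientation.  Placed scaffolds are
separated by fixed 10-kb N gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np

GAP_BP = 10_000


@dataclass(frozen=True)
class ScaffoldAnchor:
    scaffold: str
    scaffold_position: int   # 1-based coordinate on the scaffold
    linkage_group: str
    cm: float


@dataclass
class PlacedScaffold:
    scaffold: str            # scaffold id (split parts get :part suffixes)
    source_scaffold: str
    source_start: int        # 1-based slice of the source scaffold
    source_end: int
    orientation: int         # +1 forward, -1 reverse-complemented
    start: int               # 1-based position on the pseudochromosome
    end: int


def _split_conflicting(
    anchors: Sequence[ScaffoldAnchor], length: int
) -> list[tuple[int, int, list[ScaffoldAnchor]]]:
    """Split a scaffold at midpoints between anchors on different groups.

    Returns (source_start, source_end, part_anchors) slices covering the
    scaffold; a scaffold without conflicts returns one full-length slice.
    """
    ordered = sorted(anchors, key=lambda a: a.scaffold_position)
    cuts: list[int] = []
    for a, b in zip(ordered, ordered[1:]):
        if a.linkage_group != b.linkage_group:
            cuts.append((a.scaffold_position + b.scaffold_position) // 2)
    bounds = [1] + [c + 1 for c in cuts] + [length + 1]
    parts = []
    for s, e in zip(bounds, bounds[1:]):
        part_anchors = [x for x in ordered if s <= x.scaffold_position < e]
        parts.append((s, e - 1, part_anchors))
    return parts


def order_scaffolds(
    scaffold_lengths: Mapping[str, int],
    anchors: Sequence[ScaffoldAnchor],
    prior_order: Sequence[str],
    gap: int = GAP_BP,
) -> dict[str, list[PlacedScaffold]]:
    """Lay scaffolds out into per-linkage-group pseudochromosomes.

    Unanchored scaffolds are not placed (callers keep their prior layout for
    those).  Returns a layout per linkage group.
    """
    for a in anchors:
        if a.scaffold not in scaffold_lengths:
            raise ValueError(f"anchor references unknown scaffold {a.scaffold!r}")
    prior_rank = {s: i for i, s in enumerate(prior_order)}
    by_scaffold: dict[str, list[ScaffoldAnchor]] = {}
    for a in anchors:
        by_scaffold.setdefault(a.scaffold, []).append(a)

    # candidate placements: (group, median_cm, prior_rank, part descriptor)
    candidates: list[tuple[str, float, int, str, str, int, int, int]] = []
    for scaffold in sorted(by_scaffold, key=lambda s: prior_rank.get(s, 1 << 30)):
        sc_anchors = by_scaffold[scaffold]
        parts = _split_conflicting(sc_anchors, scaffold_lengths[scaffold])
        multi = len(parts) > 1
        for pi, (s, e, part_anchors) in enumerate(parts):
            if not part_anchors:
                continue
            group = part_anchors[0].linkage_group
            med = float(median(a.cm for a in part_anchors))
            orientation = 1
            if len(part_anchors) >= 2:
                pos = [a.scaffold_position for a in part_anchors]
                cms = [a.cm for a in part_anchors]
                if len(set(cms)) > 1 and np.corrcoef(pos, cms)[0, 1] < 0:
                    orientation = -1
            name = f"{scaffold}:{pi + 1}" if multi else scaffold
            candidates.append(
                (group, med, prior_rank.get(scaffold, 1 << 30), name,
                 scaffold, s, e, orientation)
            )

    layout: dict[str, list[PlacedScaffold]] = {}
    for group in sorted({c[0] for c in candidates}):
        rows = sorted(
            (c for c in candidates if c[0] == group), key=lambda c: (c[1], c[2], c[3])
        )
        placed: list[PlacedScaffold] = []
        cursor = 1
        for _, _, _, name, src, s, e, orientation in rows:
            length = e - s + 1
            if placed:
                cursor += gap
            placed.append(
                PlacedScaffold(name, src, s, e, orientation, cursor, cursor + length - 1)
            )
            cursor += length
        layout[group] = placed
    return layout


def pseudochromosome_length(placed: Sequence[PlacedScaffold], gap: int = GAP_BP) -> int:
    if not placed:
        return 0
    return placed[-1].end


def render_pseudochromosome(
    placed: Sequence[PlacedScaffold],
    sequences: Mapping[str, str],
    gap: int = GAP_BP,
) -> str:
    """Concatenate placed scaffold slices with N gaps (reverse-complementing
    flipped scaffolds)."""
    from .rearrange import reverse_complement

    parts = []
    for p in placed:
        seq = sequences[p.source_scaffold][p.source_start - 1 : p.source_end]
        parts.append(reverse_complement(seq) if p.orientation < 0 else seq)
    return ("N" * gap).join(parts)


def count_synteny_stretches(chromosome_labels: Sequence[object]) -> int:
    """Count maximal runs of identical partner-genome chromosome labels in a
    positionally ordered ortholog list (within-run order is irrelevant)."""
    count = 0
    prev = object()
    for lab in chromosome_labels:
        if lab != prev:
            count += 1
            prev = lab
    return count
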