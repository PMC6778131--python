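"""Screen-coverage arithmetic.

Planning helpers for pooled CRISPR screens: how many cells must be harvested
to maintain a target guide representation given a partial transduction, and
how much genomic DNA (and how many PCR reactions) the readout requires.

All arithmetic is exact (rational) before the final ceiling to whole cells /
whole reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

#: genomic DNA content of one million diploid human cells, in micrograms
UG_DNA_PER_MILLION_CELLS = Fraction(66, 10)

#: default cap on genomic DNA input per 50 ul PCR reaction, in micrograms
DEFAULT_MAX_UG_PER_REACTION = 10.0


@dataclass(frozen=True)
class CoveragePlan:
    """A complete harvest-and-PCR plan for one screen timepoint."""

    n_guides: int
    coverage: float
    transduced_fraction: float
    cells_required: int
    dna_mass_ug: float
    n_pcr_reactions: int


def cells_required(n_guides: int, coverage: float, transduced_fraction: float) -> int:
    """Cells to harvest so the transduced subpopulation holds ``coverage``
    cells per guide.

    Computed as ``n_guides * coverage / transduced_fraction`` with exact
    rational arithmetic, rounded up to a whole cell.

    Parameters
    ----------
    n_guides:
        Number of guides in the library.
    coverage:
        Target representation (cells per guide), e.g. 1000 for 1000x.
    transduced_fraction:
        Fraction of harvested cells carrying both Cas9 and a guide, in (0, 1].
    """
    if not 0 < transduced_fraction <= 1:
        raise ValueError(
            f"transduced_fraction must be in (0, 1], got {transduced_fraction}"
        )
    if coverage < 1:
        raise ValueError(f"coverage must be >= 1, got {coverage}")
    if n_guides < 1:
        raise ValueError(f"n_guides must be >= 1, got {n_guides}")
    exact = (
        Fraction(n_guides)
        * Fraction(str(coverage))
        / Fraction(str(transduced_fraction))
    )
    return math.ceil(exact)


def dna_plan(
    cells: int, max_ug_per_reaction: float = DEFAULT_MAX_UG_PER_REACTION
) -> tuple[float, int]:
    """Genomic DNA mass (ug) covering ``cells`` cells, and the PCR reaction
    count under a strict per-reaction mass cap.

    One million human cells carry ~6.6 ug of genomic DNA, so
    ``mass = cells / 1e6 * 6.6``; the reaction count is the strict ceiling
    ``ceil(mass / max_ug_per_reaction)`` — the cap is a maximum, so any
    overflow, however small, opens a new reaction.
    """
    if cells <= 0:
        raise ValueError(f"cells must be positive, got {cells}")
    if max_ug_per_reaction <= 0:
        raise ValueError("max_ug_per_reaction must be positive")
    mass = Fraction(cells, 10**6) * UG_DNA_PER_MILLION_CELLS
    n_reactions = math.ceil(mass / Fraction(str(max_ug_per_reaction)))
    return float(mass), n_reactions


def coverage_plan(
    n_guides: int,
    coverage: float,
    transduced_fraction: float,
    max_ug_per_reaction: float = DEFAULT_MAX_UG_PER_REACTION,
) -> CoveragePlan:
    """Full plan: cells to harvest, DNA mass, and PCR reaction count."""
    cells = cells_required(n_guides, coverage, transduced_fraction)
    mass, n_reactions = dna_plan(cells, max_ug_per_reaction)
    return CoveragePlan(
        n_guides=n_guides,
        coverage=coverage,
        transduced_fraction=transduced_fraction,
        cells_required=cells,
        dna_mass_ug=mass,
        n_pcr_reactions=n_reactions,
    )
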