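"""Barcoded-construct competition abundance.

In a pooled competitive culture, clones carrying barcoded overexpression
constructs are sequenced at intervals. Per sample, clone counts N_ictr
(clone i, construct c, timepoint t, replicate r) normalize to relative
abundances F_ictr = N_ictr / sum_i N_ictr; the per-construct readout is
M_ct, the mean of F over the construct's clones and the replicates at each
timepoint. Replicates in which a clone dropped out entirely contribute
zeros, not missing values — absence is informative in a dropout competition.

Timepoint labels are ordinal strings; their order is taken from the sample
sheet (first appearance) or supplied explicitly, never parsed as dates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class BarcodeCounts:
    """Clone x sample counts, a clone -> construct map, and sample metadata.

    ``counts`` indexed by clone_id, one column per sample_id; ``clone_map``
    a Series clone_id -> construct; ``samples`` indexed by sample_id with
    columns timepoint, replicate.
    """

    counts: pd.DataFrame
    clone_map: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("counts columns and sample sheet ids disagree")
        unmapped = self.counts.index.difference(self.clone_map.index)
        if len(unmapped):
            raise ValueError(f"unmapped clones: {list(unmapped[:3])}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ConstructAbundance:
    """Mean relative abundance per construct and timepoint.

    ``M``: construct x timepoint matrix (NaN where a construct has no clones
    at a timepoint — reported missing, not zero); ``L``: matching clone
    counts; ``n_replicates``: R.
    """

    M: pd.DataFrame
    L: pd.DataFrame
    n_replicates: int


def clone_relative_abundance(counts: BarcodeCounts | pd.DataFrame) -> pd.DataFrame:
    """Per-sample clone frequencies F = N / sum(N); columns sum to 1."""
    matrix = counts.counts if isinstance(counts, BarcodeCounts) else counts
    totals = matrix.sum(axis=0)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"sample(s) with zero total counts: {list(empty.index)}")
    return matrix / totals


def construct_mean_abundance(
    F: pd.DataFrame,
    clone_map: pd.Series,
    samples: pd.DataFrame,
    timepoint_order: list[str] | None = None,
) -> ConstructAbundance:
    """Average clone abundance per construct and timepoint.

    M_ct is the mean of F_ictr over the L_ct clones of construct c and the R
    replicates available at timepoint t (one grand mean over the clone x
    replicate grid).
    """
    unmapped = F.index.difference(clone_map.index)
    if len(unmapped):
        raise ValueError(f"unmapped clones: {list(unmapped[:3])}")
    if timepoint_order is None:
        timepoint_order = list(dict.fromkeys(samples["timepoint"]))
    constructs = sorted(clone_map.loc[F.index].unique())
    construct_of = clone_map.loc[F.index]
    n_replicates = samples["replicate"].nunique()

    M = pd.DataFrame(index=constructs, columns=timepoint_order, dtype=float)
    L = pd.DataFrame(0, index=constructs, columns=timepoint_order, dtype=int)
    for timepoint in timepoint_order:
        sample_ids = samples.index[samples["timepoint"] == timepoint]
        block = F[list(sample_ids)]
        for construct in constructs:
            clones = construct_of.index[construct_of == construct]
            if len(clones) == 0 or block.empty:
                continue  # missing, stays NaN
            M.loc[construct, timepoint] = float(block.loc[clones].to_numpy().mean())
            L.loc[construct, timepoint] = len(clones)
    M.index.name = "construct"
    M.columns.name = "timepoint"
    return ConstructAbundance(M=M, L=L, n_replicates=n_replicates)


def abundance_trajectory(abundance: ConstructAbundance) -> pd.DataFrame:
    """Tidy (construct, timepoint, M, L, R) rows, sorted by timepoint (in
    the abundance matrix's column order) then construct."""
    if abundance.M.columns.empty:
        raise ValueError("no timepoints")
    rows = []
    for timepoint in abundance.M.columns:
        for construct in sorted(abundance.M.index):
            rows.append(
                {
                    "construct": construct,
                    "timepoint": timepoint,
                    "M": abundance.M.loc[construct, timepoint],
                    "L": int(abundance.L.loc[construct, timepoint]),
                    "R": abundance.n_replicates,
                }
            )
    return pd.DataFrame.from_records(rows)
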