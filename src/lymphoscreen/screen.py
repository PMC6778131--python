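"""Pooled CRISPR screen scoring.

The readout of a pooled knockout screen is a guide x sample matrix of
sequencing read counts N_igtr (guide i, gene g, timepoint t, replicate r).
Scoring proceeds in four steps:

1. per-sample normalization to relative frequencies
   F_igtr = N_igtr / sum_i N_igtr;
2. per-guide log2 fold change between the plasmid library (P) and a late
   culture sample (L), lfc_igr = log2(F_igrL / F_igrP), with an optional
   pseudofrequency inside the ratio to keep zero-count guides finite;
3. per-replicate standardization over all guides of the library (NTCs
   included, population standard deviation) giving Z_igr;
4. the CRISPR gene score: the mean of Z_igr over all guides of a gene and
   all replicates. Positive scores mean enrichment of the gene's guides over
   the culture (tumor-suppressor-like), negative scores depletion
   (oncogene-like). Non-targeting controls are pooled as one pseudo-gene.

A single plasmid reference sample is shared by all replicates; multi-
timepoint screens are scored once per late timepoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel gene symbol for pooled non-targeting controls
NTC_GENE = "NTC"


@dataclass(frozen=True)
class GuideLibrary:
    """The screen's design object: one row per guide.

    ``table`` columns: guide_id (unique), gene (symbol, or ``NTC_GENE``),
    spacer (19-20 nt, leading G), is_ntc (bool, iff gene == ``NTC_GENE``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"guide_id", "gene", "spacer", "is_ntc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"guide library missing columns: {sorted(missing)}")
        if self.table["guide_id"].duplicated().any():
            raise ValueError("guide_id values must be unique")
        mismatch = self.table["is_ntc"] != (self.table["gene"] == NTC_GENE)
        if mismatch.any():
            raise ValueError(
                "is_ntc flag must hold exactly for guides with gene == "
                f"{NTC_GENE!r}"
            )

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def genes(self) -> pd.Series:
        """guide_id -> gene symbol (NTCs mapped to the pooled pseudo-gene)."""
        return self.table.set_index("guide_id")["gene"]

    @property
    def n_guides(self) -> int:
        return len(self.table)

    @property
    def n_target_genes(self) -> int:
        return self.table.loc[~self.table["is_ntc"], "gene"].nunique()

    @property
    def n_ntc(self) -> int:
        return int(self.table["is_ntc"].sum())


@dataclass(frozen=True)
class ScreenCounts:
    """Guide x sample read counts plus sample metadata.

    ``counts`` is indexed by guide_id with one column per sample_id;
    ``samples`` is indexed by sample_id with columns timepoint, replicate,
    is_plasmid. Exactly one plasmid sample is shared across replicates.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("counts columns and sample sheet ids disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        n_plasmid = int(self.samples["is_plasmid"].sum())
        if n_plasmid != 1:
            raise ValueError(
                f"exactly one plasmid reference sample required, got {n_plasmid}"
            )

    @property
    def plasmid_sample(self) -> str:
        return str(self.samples.index[self.samples["is_plasmid"]][0])

    def check_library(self, library: GuideLibrary) -> None:
        """Every library guide must be present as a row; absence is a hard
        error, never a silent zero-fill."""
        missing = library.guide_ids.difference(self.counts.index)
        if len(missing):
            raise ValueError(
                f"{len(missing)} library guides absent from counts, e.g. "
                f"{list(missing[:3])}"
            )


@dataclass
class GeneScoreTable:
    """Per-gene CRISPR scores with provenance.

    ``table`` columns: gene, crispr_score, n_guides, n_replicates.
    ``guide_z`` holds the underlying per-guide z-scores (guides x replicates),
    reported alongside the pooled scores (NTC guides appear individually here
    and as one pseudo-gene row in ``table``).
    """

    table: pd.DataFrame
    guide_z: pd.DataFrame = field(repr=False, default=None)

    def score_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene"] == gene, "crispr_score"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])


# ---------------------------------------------------------------------------
# step 1: relative frequencies


def relative_frequency(counts: ScreenCounts | pd.DataFrame) -> pd.DataFrame:
    """Column-wise relative frequencies F = N / sum(N); no pseudocount here.

    Each column of the result sums to 1; a zero column total raises an error
    naming the sample.
    """
    matrix = counts.counts if isinstance(counts, ScreenCounts) else counts
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total reads: {list(zero.index)}")
    return matrix / totals


# ---------------------------------------------------------------------------
# step 2: log2 fold change vs the plasmid library


def default_pseudofreq(counts: ScreenCounts) -> float:
    """Half a read at the median sample depth, expressed as a frequency."""
    return 0.5 / float(counts.counts.sum(axis=0).median())


def guide_log2fc(
    F: pd.DataFrame,
    samples: pd.DataFrame,
    late_timepoint: str,
    pseudofreq: float = 0.0,
) -> pd.DataFrame:
    """Per-guide log2 fold change of the late sample over the plasmid library.

    lfc_igr = log2((F_igrL + pseudofreq) / (F_igrP + pseudofreq)), one column
    per replicate present at ``late_timepoint``. With ``pseudofreq == 0``,
    guides at zero plasmid frequency are dropped with a warning (their ratio
    is undefined); zero late frequencies yield -inf and are likewise dropped.
    """
    plasmid_ids = samples.index[samples["is_plasmid"]]
    if len(plasmid_ids) != 1:
        raise ValueError("exactly one plasmid sample required")
    late = samples[(samples["timepoint"] == late_timepoint) & ~samples["is_plasmid"]]
    if late.empty:
        raise ValueError(f"no samples at timepoint {late_timepoint!r}")
    f_plasmid = F[plasmid_ids[0]]
    lfc = pd.DataFrame(index=F.index)
    for sample_id, row in late.iterrows():
        ratio = (F[sample_id] + pseudofreq) / (f_plasmid + pseudofreq)
        lfc[str(row["replicate"])] = np.log2(ratio)
    if pseudofreq == 0:
        finite = np.isfinite(lfc).all(axis=1)
        if not finite.all():
            warnings.warn(
                f"dropping {int((~finite).sum())} guides with zero frequency "
                "(pseudofreq=0)",
                stacklevel=2,
            )
            lfc = lfc.loc[finite]
    return lfc


# ---------------------------------------------------------------------------
# step 3: per-replicate z-standardization


def guide_zscore(lfc: pd.DataFrame) -> pd.DataFrame:
    """Standardize each replicate's fold changes over the whole library.

    z = (lfc - mean) / sd, where mean and sd range over ALL guides of the
    replicate (non-targeting controls included) and sd is the population
    standard deviation (divisor n). Raises if any replicate has zero spread.
    """
    if len(lfc) < 2:
        raise ValueError("z-standardization needs >=2 guides per replicate")
    mean = lfc.mean(axis=0)
    sd = lfc.std(axis=0, ddof=0)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(
            f"replicate(s) with zero fold-change spread: {list(flat.index)}"
        )
    return (lfc - mean) / sd


# ---------------------------------------------------------------------------
# step 4: gene scores


def gene_crispr_score(z: pd.DataFrame, library: GuideLibrary) -> GeneScoreTable:
    """CRISPR score per gene: the mean z over the gene's guide x replicate grid.

    NTC guides are pooled into one pseudo-gene row; genes whose guides were
    all filtered out upstream are omitted with a warning.
    """
    genes = library.genes
    unknown = z.index.difference(genes.index)
    if len(unknown):
        raise ValueError(f"guides absent from library: {list(unknown[:3])}")
    gene_of = genes.loc[z.index]
    n_replicates = z.shape[1]
    grouped = z.groupby(gene_of.to_numpy())
    records = [
        {
            "gene": gene,
            "crispr_score": float(block.to_numpy().mean()),
            "n_guides": len(block),
            "n_replicates": n_replicates,
        }
        for gene, block in grouped
    ]
    table = pd.DataFrame.from_records(records)
    lost = set(genes.unique()) - set(table["gene"])
    if lost:
        warnings.warn(
            f"{len(lost)} gene(s) had no guides left after filtering and were "
            f"omitted: {sorted(lost)[:5]}",
            stacklevel=2,
        )
    return GeneScoreTable(table=table, guide_z=z)


def rank_genes(scores: GeneScoreTable) -> list[str]:
    """Genes in descending score order; ties broken alphabetically."""
    if scores.table.empty:
        raise ValueError("empty gene score table")
    ordered = scores.table.sort_values(
        ["crispr_score", "gene"], ascending=[False, True], kind="stable"
    )
    return list(ordered["gene"])


# ---------------------------------------------------------------------------
# QC


def library_uniformity(f_plasmid: pd.Series | np.ndarray, fold: float = 4.0) -> float:
    """Fraction of guides whose plasmid frequency lies within ``fold`` of the
    mean, i.e. inside [mean/fold, mean*fold] with mean = 1/m."""
    if fold <= 1:
        raise ValueError(f"fold must be > 1, got {fold}")
    freqs = np.asarray(f_plasmid, dtype=float)
    mean = 1.0 / len(freqs)
    in_band = (freqs >= mean / fold) & (freqs <= mean * fold)
    return float(in_band.mean())


# ---------------------------------------------------------------------------
# one-call pipeline


def score_screen(
    library: GuideLibrary,
    counts: ScreenCounts,
    late_timepoint: str,
    pseudofreq: float | None = None,
) -> GeneScoreTable:
    """Run the full scoring chain for one late timepoint.

    ``pseudofreq=None`` selects the default (half a read at median depth);
    pass 0.0 to disable it (zero-frequency guides are then dropped).
    """
    counts.check_library(library)
    if pseudofreq is None:
        pseudofreq = default_pseudofreq(counts)
    F = relative_frequency(counts)
    lfc = guide_log2fc(F, counts.samples, late_timepoint, pseudofreq)
    z = guide_zscore(lfc)
    return gene_crispr_score(z, library)
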