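"""IgHV gene replacement detection.

IgHV replacement is a secondary rearrangement that swaps the V gene of an
existing VDJ join while retaining the downstream junction. Its footprint in
a repertoire is a pair of unique BCR sequences that share an identical
"stem" — the N-D-N-J region starting 3 bp downstream of the V gene boundary
— but use clearly different V genes and differ in the 5' part of the
junction (the last 3 bp of V plus the N-D-N-J region).

The detector consumes AIRR-style annotations (it never computes V/D/J calls
itself): for each record the stem is extracted from the annotated V-region
end coordinate, records whose N-D-N-J span is shorter than 8 nt are excluded
(such short joins can arise germline-encoded, without replacement), unique
sequences are grouped by exact stem string, and within each group a pair is
called a replacement event when the V calls differ, the pairwise global
V-region identity falls below a threshold (default 95%), and the 5'
junction strings differ. The reported percentage is the fraction of
post-exclusion unique BCRs participating in at least one event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

DEFAULT_IDENTITY_THRESHOLD = 95.0
DEFAULT_MIN_JUNCTION = 8

#: stem starts this many bases downstream of the V boundary, skipping the
#: junction bases whose origin (V trimming vs N addition) is ambiguous
STEM_OFFSET = 3


@dataclass(frozen=True)
class ReplacementPair:
    id_a: str
    id_b: str
    stem: str
    v_call_a: str
    v_call_b: str
    v_identity: float


@dataclass
class ReplacementReport:
    """Outcome of replacement detection on one repertoire.

    ``pct_replacement`` is None (not applicable) when no unique BCRs survive
    the junction-length exclusion.
    """

    n_unique_bcrs: int
    n_excluded_short_junction: int
    replacement_pairs: list[ReplacementPair] = field(default_factory=list)
    pct_replacement: float | None = None

    @property
    def n_events(self) -> int:
        return len(self.replacement_pairs)

    def as_dict(self) -> dict:
        return {
            "n_unique_bcrs": self.n_unique_bcrs,
            "n_excluded_short_junction": self.n_excluded_short_junction,
            "n_replacement_pairs": self.n_events,
            "pct_replacement": self.pct_replacement,
        }

    def pairs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(p) for p in self.replacement_pairs],
            columns=["id_a", "id_b", "stem", "v_call_a", "v_call_b", "v_identity"],
        )


# ---------------------------------------------------------------------------
# per-record coordinate helpers (v_end is 0-based half-open)


def extract_stem(sequence: str, v_end: int) -> str:
    """N-D-N-J stem: the suffix starting ``STEM_OFFSET`` bases past the V
    boundary. Empty when the sequence ends at or before that point."""
    if not 0 < v_end <= len(sequence):
        raise ValueError(f"v_end {v_end} outside sequence of length {len(sequence)}")
    return sequence[v_end + STEM_OFFSET :]


def ndnj_span(sequence: str, v_end: int) -> str:
    """The full N-D-N-J region: everything downstream of the V boundary."""
    return sequence[v_end:]


def five_prime_junction(sequence: str, v_end: int) -> str:
    """Last 3 bp of the V gene plus the N-D-N-J region."""
    return sequence[max(v_end - STEM_OFFSET, 0) :]


def filter_short_junctions(
    table: pd.DataFrame, min_junction: int = DEFAULT_MIN_JUNCTION
) -> tuple[pd.DataFrame, int]:
    """Drop records whose N-D-N-J span is shorter than ``min_junction`` nt.

    Returns (retained table, number excluded)."""
    spans = table.apply(
        lambda row: len(ndnj_span(row["sequence"], int(row["v_end"]))), axis=1
    )
    keep = spans >= min_junction
    return table.loc[keep], int((~keep).sum())


# ---------------------------------------------------------------------------
# V-region identity


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def v_region_identity(a: str, b: str) -> float:
    """Percent identity of a unit-cost global alignment: matched columns
    over all alignment columns x 100. Symmetric in its arguments."""
    if not a or not b:
        raise ValueError("empty sequence")
    if b < a:  # canonical order so identity(a, b) == identity(b, a)
        a, b = b, a
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


# ---------------------------------------------------------------------------
# detection


def detect_replacements(
    table: pd.DataFrame,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    min_junction: int = DEFAULT_MIN_JUNCTION,
) -> ReplacementReport:
    """Find IgHV replacement events in an AIRR-style annotation table.

    Identical full-length sequences are collapsed first (a read never pairs
    with its own duplicates); ``identity_threshold`` is the percent V-region
    identity below which two V genes count as different.
    """
    required = {"sequence_id", "sequence", "v_call", "v_end"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")

    unique = table.drop_duplicates(subset="sequence", keep="first")
    retained, n_short = filter_short_junctions(unique, min_junction)

    records = []
    for _, row in retained.iterrows():
        sequence = row["sequence"]
        v_end = int(row["v_end"])
        v_region = sequence[:v_end]
        if not v_region:
            warnings.warn(
                f"record {row['sequence_id']!r} has no V-region sequence; skipped",
                stacklevel=2,
            )
            continue
        stem = extract_stem(sequence, v_end)
        if not stem:
            continue  # degenerate: sequence ends within the stem offset
        records.append(
            {
                "sequence_id": str(row["sequence_id"]),
                "v_call": str(row["v_call"]),
                "v_region": v_region,
                "stem": stem,
                "junction5": five_prime_junction(sequence, v_end),
            }
        )

    groups: dict[str, list[dict]] = {}
    for rec in records:
        groups.setdefault(rec["stem"], []).append(rec)

    pairs: list[ReplacementPair] = []
    involved: set[str] = set()
    for stem in sorted(groups):
        members = groups[stem]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if a["v_call"] == b["v_call"]:
                    continue
                if a["junction5"] == b["junction5"]:
                    continue
                identity = v_region_identity(a["v_region"], b["v_region"])
                if identity >= identity_threshold:
                    continue
                pairs.append(
                    ReplacementPair(
                        id_a=a["sequence_id"],
                        id_b=b["sequence_id"],
                        stem=stem,
                        v_call_a=a["v_call"],
                        v_call_b=b["v_call"],
                        v_identity=identity,
                    )
                )
                involved.update((a["sequence_id"], b["sequence_id"]))

    n_unique = len(retained)
    pct = 100.0 * len(involved) / n_unique if n_unique else None
    return ReplacementReport(
        n_unique_bcrs=n_unique,
        n_excluded_short_junction=n_short,
        replacement_pairs=pairs,
        pct_replacement=pct,
    )
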