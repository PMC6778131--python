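"""Screen scoring: normalization, fold change, z-scores, gene scores."""

import math
import statistics
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lymphoscreen as ls
from tests.conftest import make_screen_counts


def frame(values: dict[str, list[float]], guides: list[str]) -> pd.DataFrame:
    return pd.DataFrame(values, index=pd.Index(guides, name="guide_id"))


# ---------------------------------------------------------------------------
# relative frequencies


def test_relative_frequency_single_sample():
    F = ls.relative_frequency(frame({"s1": [2, 3, 5]}, ["a", "b", "c"]))
    assert list(F["s1"]) == [0.2, 0.3, 0.5]


def test_relative_frequency_uniform_and_zeros():
    F = ls.relative_frequency(frame({"s1": [1, 1, 1, 1]}, list("abcd")))
    assert np.allclose(F["s1"], 0.25)
    F = ls.relative_frequency(frame({"s1": [0, 1, 3]}, list("abc")))
    assert list(F["s1"]) == [0.0, 0.25, 0.75]


def test_relative_frequency_names_empty_sample():
    with pytest.raises(ValueError, match="s2"):
        ls.relative_frequency(frame({"s1": [1, 2], "s2": [0, 0]}, ["a", "b"]))


@given(
    st.lists(st.integers(min_value=0, max_value=10**6), min_size=2, max_size=30).filter(
        lambda xs: sum(xs) > 0
    )
)
@settings(max_examples=50, derandomize=True)
def test_relative_frequency_conserves_mass(counts):
    guides = [f"g{i}" for i in range(len(counts))]
    F = ls.relative_frequency(frame({"s1": counts}, guides))
    assert F["s1"].sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# log2 fold change


def _samples(ids):
    rows = []
    for sid in ids:
        if sid == "plasmid":
            rows.append({"sample_id": sid, "timepoint": "plasmid",
                         "replicate": "0", "is_plasmid": True})
        else:
            tp, rep = sid.rsplit("_r", 1)
            rows.append({"sample_id": sid, "timepoint": tp,
                         "replicate": rep, "is_plasmid": False})
    return pd.DataFrame.from_records(rows).set_index("sample_id", drop=False)


def test_log2fc_identity_and_doubling():
    F = frame({"plasmid": [0.25, 0.25], "d70_r1": [0.25, 0.5]}, ["a", "b"])
    lfc = ls.guide_log2fc(F, _samples(F.columns), "d70", pseudofreq=0.0)
    assert lfc.loc["a", "1"] == pytest.approx(0.0)
    assert lfc.loc["b", "1"] == pytest.approx(1.0)


def test_log2fc_pseudofreq_keeps_zero_guides():
    F = frame({"plasmid": [1e-4, 0.9999], "d70_r1": [0.0, 1.0]}, ["a", "b"])
    lfc = ls.guide_log2fc(F, _samples(F.columns), "d70", pseudofreq=1e-5)
    assert lfc.loc["a", "1"] == pytest.approx(math.log2(1e-5 / 1.1e-4))


def test_log2fc_zero_pseudofreq_drops_zero_guides():
    F = frame({"plasmid": [0.0, 1.0], "d70_r1": [0.5, 0.5]}, ["a", "b"])
    with pytest.warns(UserWarning, match="dropping 1 guides"):
        lfc = ls.guide_log2fc(F, _samples(F.columns), "d70", pseudofreq=0.0)
    assert list(lfc.index) == ["b"]


def test_log2fc_missing_late_sample_errors():
    F = frame({"plasmid": [0.5, 0.5]}, ["a", "b"])
    with pytest.raises(ValueError, match="d70"):
        ls.guide_log2fc(F, _samples(F.columns), "d70")


# ---------------------------------------------------------------------------
# z-standardization


def test_zscore_two_point_example():
    lfc = frame({"1": [1.0, -1.0]}, ["a", "b"])
    z = ls.guide_zscore(lfc)
    assert list(z["1"]) == pytest.approx([1.0, -1.0])


def test_zscore_population_sd():
    lfc = frame({"1": [0.0, 1.0, 2.0, 3.0]}, list("abcd"))
    z = ls.guide_zscore(lfc)
    expected = [-1.3416407865, -0.4472135955, 0.4472135955, 1.3416407865]
    assert list(z["1"]) == pytest.approx(expected, abs=1e-9)


def test_zscore_standardizes_each_replicate():
    rng = np.random.default_rng(0)
    lfc = frame({"1": rng.normal(2, 3, 40), "2": rng.normal(-1, 0.5, 40)},
                [f"g{i}" for i in range(40)])
    z = ls.guide_zscore(lfc)
    for rep in z.columns:
        assert z[rep].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[rep].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_zscore_idempotent():
    rng = np.random.default_rng(1)
    lfc = frame({"1": rng.normal(size=25)}, [f"g{i}" for i in range(25)])
    once = ls.guide_zscore(lfc)
    twice = ls.guide_zscore(once)
    assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_zscore_rejects_flat_replicate():
    lfc = frame({"1": [2.0, 2.0, 2.0]}, list("abc"))
    with pytest.raises(ValueError, match="zero fold-change spread"):
        ls.guide_zscore(lfc)


# ---------------------------------------------------------------------------
# gene scores and ranking


def test_gene_score_is_mean_of_guide_z(tiny_library):
    z = frame({"1": [1.0, 2.0, 0.5, -0.5, 0.0, 0.0, 1.0, -1.0]},
              list(tiny_library.guide_ids))
    scores = ls.gene_crispr_score(z, tiny_library)
    assert scores.score_of("ALPHA") == pytest.approx(1.5)
    assert scores.score_of("BETA") == pytest.approx(0.0)
    assert scores.score_of(ls.NTC_GENE) == pytest.approx(0.0)


def test_gene_score_constant_z_is_exact(tiny_library):
    z = frame({"1": [0.7] * 8, "2": [0.7] * 8}, list(tiny_library.guide_ids))
    scores = ls.gene_crispr_score(z, tiny_library)
    assert scores.score_of("GAMMA") == 0.7


def test_identical_counts_refuse_standardization(tiny_library):
    """Identical counts at both timepoints give zero fold change for every
    guide, hence zero spread: standardization must refuse rather than emit
    0/0 scores."""
    counts = make_screen_counts(
        {"plasmid": [10, 20, 30, 40, 50, 60, 70, 80],
         "d70_r1": [10, 20, 30, 40, 50, 60, 70, 80]},
        list(tiny_library.guide_ids),
    )
    with pytest.raises(ValueError, match="zero fold-change spread"):
        ls.score_screen(tiny_library, counts, "d70", pseudofreq=0.0)


def test_rank_genes_tie_break():
    table = ls.GeneScoreTable(
        table=pd.DataFrame(
            {"gene": ["B", "A", "C"], "crispr_score": [-1.0, 2.0, 2.0],
             "n_guides": [2, 2, 2], "n_replicates": [1, 1, 1]}
        )
    )
    assert ls.rank_genes(table) == ["A", "C", "B"]


def test_score_invariant_to_sample_depth_rescaling(tiny_library):
    base = {"plasmid": [10, 20, 30, 40, 50, 60, 70, 80],
            "d70_r1": [80, 70, 60, 50, 40, 30, 20, 10]}
    counts = make_screen_counts(base, list(tiny_library.guide_ids))
    scaled = make_screen_counts(
        {"plasmid": base["plasmid"], "d70_r1": [5 * c for c in base["d70_r1"]]},
        list(tiny_library.guide_ids),
    )
    s1 = ls.score_screen(tiny_library, counts, "d70", pseudofreq=0.0)
    s2 = ls.score_screen(tiny_library, scaled, "d70", pseudofreq=0.0)
    for gene in ["ALPHA", "BETA", "GAMMA", ls.NTC_GENE]:
        assert s1.score_of(gene) == pytest.approx(s2.score_of(gene), abs=1e-9)


def test_missing_library_guide_is_hard_error(tiny_library):
    counts = make_screen_counts(
        {"plasmid": [1] * 7, "d70_r1": [1] * 7}, list(tiny_library.guide_ids[:-1])
    )
    with pytest.raises(ValueError, match="absent from counts"):
        ls.score_screen(tiny_library, counts, "d70")


# ---------------------------------------------------------------------------
# arbitrary-precision oracle for the full chain (pseudofreq 0)


def oracle_scores(
    counts: dict[str, list[int]], genes: list[str], late: str
) -> dict[str, float]:
    """Naive re-implementation with exact rational frequencies: normalize,
    log2 ratio, population-sd standardize per replicate, average per gene."""
    replicates = [s for s in counts if s != "plasmid" and s.startswith(late)]
    f_plasmid = [Fraction(c, sum(counts["plasmid"])) for c in counts["plasmid"]]
    z_by_rep = []
    for rep in replicates:
        f_late = [Fraction(c, sum(counts[rep])) for c in counts[rep]]
        lfc = [math.log2(fl / fp) for fl, fp in zip(f_late, f_plasmid)]
        mu = statistics.fmean(lfc)
        sd = statistics.pstdev(lfc)
        z_by_rep.append([(x - mu) / sd for x in lfc])
    out: dict[str, float] = {}
    for gene in set(genes):
        zs = [z[i] for z in z_by_rep for i, g in enumerate(genes) if g == gene]
        out[gene] = statistics.fmean(zs)
    return out


def test_pipeline_matches_rational_oracle(tiny_library):
    counts_dict = {
        "plasmid": [13, 7, 41, 5, 23, 11, 17, 3],
        "d70_r1": [2, 29, 6, 31, 19, 8, 12, 44],
        "d70_r2": [9, 9, 15, 27, 4, 33, 21, 10],
    }
    guides = list(tiny_library.guide_ids)
    genes = list(tiny_library.genes.loc[guides])
    counts = make_screen_counts(counts_dict, guides)
    scores = ls.score_screen(tiny_library, counts, "d70", pseudofreq=0.0)
    expected = oracle_scores(counts_dict, genes, "d70")
    for gene, value in expected.items():
        assert scores.score_of(gene) == pytest.approx(value, abs=1e-12)


# ---------------------------------------------------------------------------
# QC


def test_uniformity_perfect_library():
    assert ls.library_uniformity(np.full(100, 0.01), fold=4) == 1.0


def test_uniformity_band_membership():
    # mean 0.25, band [0.125, 0.5]: 0.7 above, the 0.1s below -> none in band
    assert ls.library_uniformity([0.7, 0.1, 0.1, 0.1], fold=2) == 0.0


def test_uniformity_wide_band_captures_all():
    rng = np.random.default_rng(3)
    freqs = rng.dirichlet(np.ones(50))
    assert ls.library_uniformity(freqs, fold=1e9) == 1.0
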