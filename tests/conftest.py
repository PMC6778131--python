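import pandas as pd
import pytest

import lymphoscreen as ls


@pytest.fixture(scope="session")
def tiny_library() -> ls.GuideLibrary:
    """Three target genes x two guides plus two NTCs."""
    rows = []
    for gi, gene in enumerate(["ALPHA", "BETA", "GAMMA"]):
        for k in range(2):
            rows.append(
                {
                    "guide_id": f"{gene}_g{k + 1}",
                    "gene": gene,
                    "spacer": "G" + "ACGT" * 4 + "ACG"[: 2 + gi] + "AT"[:k],
                    "is_ntc": False,
                }
            )
    for k in range(2):
        rows.append(
            {
                "guide_id": f"NTC_g{k + 1}",
                "gene": ls.NTC_GENE,
                "spacer": "G" + "TTTT" * 4 + "AC"[:k],
                "is_ntc": True,
            }
        )
    return ls.GuideLibrary(table=pd.DataFrame.from_records(rows))


def make_screen_counts(counts: dict[str, list[int]], guides: list[str]) -> ls.ScreenCounts:
    """ScreenCounts from a sample -> counts dict; sample ids follow the
    plasmid / '<tp>_r<rep>' naming."""
    sheet = []
    for sample_id in counts:
        if sample_id == "plasmid":
            sheet.append(
                {"sample_id": sample_id, "timepoint": "plasmid",
                 "replicate": "0", "is_plasmid": True}
            )
        else:
            timepoint, rep = sample_id.rsplit("_r", 1)
            sheet.append(
                {"sample_id": sample_id, "timepoint": timepoint,
                 "replicate": rep, "is_plasmid": False}
            )
    return ls.ScreenCounts(
        counts=pd.DataFrame(counts, index=pd.Index(guides, name="guide_id")),
        samples=pd.DataFrame.from_records(sheet).set_index("sample_id", drop=False),
    )


@pytest.fixture(scope="session")
def small_repertoire():
    """A seeded clonally expanded repertoire with planted replacements."""
    config = ls.RepertoireSimConfig(
        n_clones=30, clone_size_distribution=1.8, shm_rate=0.004,
        replacement_rate=0.2, seed=11,
    )
    return ls.simulate_repertoire(config)
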