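"""Seeded generators for every input the pipeline consumes.

Three families of synthetic data, each mirroring the structure of the real
experiments:

- a guide-library designer and a pooled-screen count simulator (guide-level
  fitness effects with Beta-distributed guide efficacy, neutral
  non-targeting controls, Dirichlet-multinomial sequencing noise);
- a barcoded-construct competition simulator (exponential competition in
  frequency space plus sampling noise);
- a BCR repertoire simulator (power-law clonal expansion, per-read somatic
  hypermutation of the V region, and planted IgHV-replacement events whose
  partners share an identical N-D-N-J stem but a discordant V gene and an
  altered 5' junction).

Every generator takes an explicit integer seed; identical seeds give
byte-identical outputs. Defaults mirror the screen design the package
targets: 6000 guides over 692 target genes plus 250 non-targeting controls,
at most nine guides per gene, spacers 19-20 nt with a leading G.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode import BarcodeCounts
from .screen import NTC_GENE, GuideLibrary, ScreenCounts

BASES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """An infeasible or inconsistent generator configuration."""


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def parse_time(label: str) -> float:
    """Numeric time from an ordinal label like 'd70' or 'day14'."""
    digits = re.sub(r"[^0-9.]", "", str(label))
    if not digits:
        raise ConfigurationError(f"timepoint label {label!r} has no numeric part")
    return float(digits)


# ===========================================================================
# guide library


@dataclass(frozen=True)
class LibraryDesignConfig:
    """Design of a pooled guide library; defaults are the lymphoma-focused
    library (6000 guides, 692 genes, 250 NTCs, <=9 guides/gene)."""

    n_target_genes: int = 692
    max_guides_per_gene: int = 9
    n_ntc: int = 250
    total_guides: int = 6000
    seed: int = 0

    def __post_init__(self) -> None:
        n_targeting = self.total_guides - self.n_ntc
        if self.n_target_genes < 0 or self.n_ntc < 0 or self.total_guides < 1:
            raise ConfigurationError("counts must be non-negative, >=1 total guide")
        if self.n_target_genes > 0 and not (
            self.n_target_genes
            <= n_targeting
            <= self.n_target_genes * self.max_guides_per_gene
        ):
            raise ConfigurationError(
                f"cannot place {n_targeting} targeting guides on "
                f"{self.n_target_genes} genes with 1..{self.max_guides_per_gene} "
                "guides each"
            )
        if self.n_target_genes == 0 and n_targeting != 0:
            raise ConfigurationError("targeting guides require target genes")


def generate_library(config: LibraryDesignConfig) -> GuideLibrary:
    """Draw a guide library satisfying the design: every target gene gets
    between 1 and ``max_guides_per_gene`` guides (as even a split as the
    totals allow, remainder genes chosen at random), plus ``n_ntc``
    non-targeting controls. Spacers are unique 19-20 nt sequences starting
    with G. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_targeting = config.total_guides - config.n_ntc

    guides_per_gene = np.zeros(config.n_target_genes, dtype=int)
    if config.n_target_genes:
        base, remainder = divmod(n_targeting, config.n_target_genes)
        guides_per_gene[:] = base
        if remainder:
            extra = rng.choice(config.n_target_genes, size=remainder, replace=False)
            guides_per_gene[extra] += 1

    spacers: set[str] = set()

    def new_spacer() -> str:
        while True:
            length = int(rng.integers(19, 21))
            spacer = "G" + _random_seq(rng, length - 1)
            if spacer not in spacers:
                spacers.add(spacer)
                return spacer

    width = max(4, len(str(config.n_target_genes)))
    rows = []
    for gi in range(config.n_target_genes):
        gene = f"GENE{gi + 1:0{width}d}"
        for k in range(guides_per_gene[gi]):
            rows.append(
                {
                    "guide_id": f"{gene}_g{k + 1}",
                    "gene": gene,
                    "spacer": new_spacer(),
                    "is_ntc": False,
                }
            )
    for k in range(config.n_ntc):
        rows.append(
            {
                "guide_id": f"NTC_g{k + 1}",
                "gene": NTC_GENE,
                "spacer": new_spacer(),
                "is_ntc": True,
            }
        )
    return GuideLibrary(table=pd.DataFrame.from_records(rows))


# ===========================================================================
# pooled screen counts


@dataclass(frozen=True)
class ScreenSimConfig:
    """Selection-and-sequencing model for a pooled screen.

    Guides of gene g grow as exp(efficacy_i * s_g * t) in frequency space,
    with per-guide efficacy drawn once from Beta(*guide_efficacy*) and time
    parsed from the timepoint labels. ``plasmid_dispersion`` is the single
    Dirichlet-multinomial overdispersion knob (0 = pure multinomial).
    The NTC pseudo-gene is always neutral.
    """

    fitness_map: dict[str, float] = field(default_factory=dict)
    guide_efficacy: tuple[float, float] = (6.0, 2.0)
    plasmid_dispersion: float = 0.01
    depth_per_sample: int = 5_000_000
    timepoints: tuple[str, ...] = ("d14", "d28")
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fitness_map.get(NTC_GENE, 0.0) != 0.0:
            raise ConfigurationError("the NTC pseudo-gene must stay neutral (s=0)")
        if self.depth_per_sample <= 0:
            raise ConfigurationError("depth_per_sample must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.plasmid_dispersion < 0:
            raise ConfigurationError("plasmid_dispersion must be >= 0")


def _sample_counts(
    rng: np.random.Generator, freqs: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    """Dirichlet-multinomial draw (multinomial when dispersion == 0).

    ``dispersion`` is the reciprocal of the mean per-category Dirichlet
    concentration: alpha_i = p_i * m / dispersion for m categories, so a
    uniform p at dispersion 0.01 gets alpha_i = 100 (mild overdispersion)
    and dispersion -> 0 recovers the multinomial."""
    p = freqs / freqs.sum()
    if dispersion > 0:
        alpha = np.maximum(p * len(p) / dispersion, 1e-9)
        p = rng.dirichlet(alpha)
    return rng.multinomial(depth, p)


def simulate_screen(library: GuideLibrary, config: ScreenSimConfig) -> ScreenCounts:
    """Simulate plasmid + timepoint x replicate read counts for a library.

    The plasmid pool is a Dirichlet perturbation of the uniform design; each
    replicate then evolves deterministically under exponential selection and
    is sequenced with Dirichlet-multinomial noise at ``depth_per_sample``.
    """
    genes = library.table["gene"].to_numpy()
    known = set(genes) | {NTC_GENE}
    unknown = set(config.fitness_map) - known
    if unknown:
        raise ConfigurationError(
            f"fitness_map genes absent from library: {sorted(unknown)[:5]}"
        )
    rng = np.random.default_rng(config.seed)
    m = library.n_guides

    design = np.full(m, 1.0 / m)
    if config.plasmid_dispersion > 0:
        plasmid_freq = rng.dirichlet(
            np.full(m, 1.0 / config.plasmid_dispersion)
        )
    else:
        plasmid_freq = design
    efficacy = rng.beta(*config.guide_efficacy, size=m)
    s = np.array([config.fitness_map.get(g, 0.0) for g in genes])
    s[library.table["is_ntc"].to_numpy()] = 0.0

    columns: dict[str, np.ndarray] = {
        "plasmid": rng.multinomial(config.depth_per_sample, plasmid_freq)
    }
    sheet = [
        {
            "sample_id": "plasmid",
            "timepoint": "plasmid",
            "replicate": "0",
            "is_plasmid": True,
        }
    ]
    for rep in range(1, config.n_replicates + 1):
        for label in config.timepoints:
            t = parse_time(label)
            freqs = plasmid_freq * np.exp(efficacy * s * t)
            sample_id = f"{label}_r{rep}"
            columns[sample_id] = _sample_counts(
                rng, freqs, config.depth_per_sample, config.plasmid_dispersion
            )
            sheet.append(
                {
                    "sample_id": sample_id,
                    "timepoint": label,
                    "replicate": str(rep),
                    "is_plasmid": False,
                }
            )
    counts = pd.DataFrame(columns, index=library.guide_ids)
    counts.index.name = "guide_id"
    samples = pd.DataFrame.from_records(sheet).set_index("sample_id", drop=False)
    return ScreenCounts(counts=counts, samples=samples)


def planted_screen(
    seed: int = 0,
    n_positive: int = 10,
    n_negative: int = 10,
    effect: float = 0.3,
    n_target_genes: int = 700,
    guides_per_gene: int = 8,
    n_ntc: int = 250,
    depth: int = 2_000_000,
) -> tuple[GuideLibrary, ScreenSimConfig, list[str], list[str]]:
    """Benchmark screen with planted fitness effects.

    Returns (library, config, positive genes, negative genes): the first
    ``n_positive`` genes get selection coefficient +``effect`` per day, the
    next ``n_negative`` get -``effect``, all others are neutral.
    """
    lib_config = LibraryDesignConfig(
        n_target_genes=n_target_genes,
        max_guides_per_gene=guides_per_gene,
        n_ntc=n_ntc,
        total_guides=n_target_genes * guides_per_gene + n_ntc,
        seed=seed,
    )
    library = generate_library(lib_config)
    gene_names = sorted(set(library.table["gene"]) - {NTC_GENE})
    positives = gene_names[:n_positive]
    negatives = gene_names[n_positive : n_positive + n_negative]
    fitness = {g: effect for g in positives}
    fitness.update({g: -effect for g in negatives})
    config = ScreenSimConfig(fitness_map=fitness, depth_per_sample=depth, seed=seed)
    return library, config, positives, negatives


# ===========================================================================
# barcode competition


def simulate_barcodes(
    constructs: list[str],
    clones_per_construct: int,
    growth_advantages: dict[str, float] | None = None,
    timepoints: tuple[str, ...] = ("d4", "d18", "d32", "d46"),
    n_replicates: int = 2,
    depth: int = 200_000,
    dispersion: float = 0.005,
    seed: int = 0,
    sampling: str = "dirichlet-multinomial",
) -> BarcodeCounts:
    """Simulate a pooled competitive culture of barcoded clones.

    Clone frequencies follow exponential competition,
    f_i(t) ∝ f_i(0) * exp(g_c * t) for a clone of construct c, read out
    with Dirichlet-multinomial noise. ``sampling="exact"`` emits noise-free
    expected counts (depth * frequency; the closed-form logistic dynamics),
    useful for validating the abundance estimator.
    """
    if not constructs:
        raise ConfigurationError("need >=1 construct")
    if clones_per_construct < 1:
        raise ConfigurationError("clones_per_construct must be >= 1")
    if sampling not in ("dirichlet-multinomial", "exact"):
        raise ConfigurationError(f"unknown sampling mode {sampling!r}")
    growth = growth_advantages or {}
    unknown = set(growth) - set(constructs)
    if unknown:
        raise ConfigurationError(f"growth advantages for unknown constructs: {unknown}")

    rng = np.random.default_rng(seed)
    clones = [
        (f"{construct}_c{k + 1}", construct)
        for construct in constructs
        for k in range(clones_per_construct)
    ]
    clone_ids = [c for c, _ in clones]
    g = np.array([growth.get(construct, 0.0) for _, construct in clones])
    x0 = np.full(len(clones), 1.0 / len(clones))

    columns: dict[str, np.ndarray] = {}
    sheet = []
    for rep in range(1, n_replicates + 1):
        for label in timepoints:
            t = parse_time(label)
            freqs = x0 * np.exp(g * t)
            freqs = freqs / freqs.sum()
            sample_id = f"{label}_r{rep}"
            if sampling == "exact":
                columns[sample_id] = freqs * depth
            else:
                columns[sample_id] = _sample_counts(rng, freqs, depth, dispersion)
            sheet.append(
                {"sample_id": sample_id, "timepoint": label, "replicate": str(rep)}
            )
    counts = pd.DataFrame(columns, index=pd.Index(clone_ids, name="clone_id"))
    clone_map = pd.Series(
        {cid: construct for cid, construct in clones}, name="construct"
    )
    clone_map.index.name = "clone_id"
    samples = pd.DataFrame.from_records(sheet).set_index("sample_id", drop=False)
    return BarcodeCounts(counts=counts, clone_map=clone_map, samples=samples)


# ===========================================================================
# BCR repertoire


@dataclass(frozen=True)
class RepertoireSimConfig:
    """Clonally expanded, SHM-diversified heavy-chain repertoire.

    Clone sizes follow a Zipf law with exponent ``clone_size_distribution``
    (smaller exponent = heavier tail = stronger clonal expansion). Each read
    receives independent per-base substitutions at ``shm_rate`` in the V
    region; the N-D-N-J stem is left untouched so planted replacement
    partners share byte-identical stems. With probability
    ``replacement_rate`` a clone carries a planted IgHV replacement: a
    partner clone with the same stem, a different germline V (pairwise
    identity well below the detection threshold) and an altered 5'
    junction.
    """

    n_clones: int = 50
    clone_size_distribution: float = 2.0
    germline_v_set: tuple[tuple[str, str], ...] = ()
    shm_rate: float = 0.002
    replacement_rate: float = 0.0
    junction_length_range: tuple[int, int] = (40, 60)
    seed: int = 0
    max_clone_size: int = 200

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")
        if not 0 <= self.shm_rate <= 0.1:
            raise ConfigurationError("shm_rate must lie in [0, 0.1]")
        if not 0 <= self.replacement_rate <= 1:
            raise ConfigurationError("replacement_rate must lie in [0, 1]")
        if self.clone_size_distribution <= 1:
            raise ConfigurationError("clone size power-law exponent must be > 1")
        lo, hi = self.junction_length_range
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid junction_length_range")


def default_germline_v_set(
    n: int = 8, length: int = 150, seed: int = 12345
) -> tuple[tuple[str, str], ...]:
    """Synthetic stand-in for a germline IGHV gene set: ``n`` independent
    random sequences (pairwise identity far below 95%), labelled
    IGHV1-SYN..IGHVn-SYN. Not a real germline database."""
    rng = np.random.default_rng(seed)
    return tuple(
        (f"IGHV{k + 1}-SYN", _random_seq(rng, length)) for k in range(n)
    )


def _mutate_v_region(
    rng: np.random.Generator, sequence: str, v_end: int, rate: float
) -> str:
    if rate <= 0:
        return sequence
    chars = list(sequence)
    hits = np.nonzero(rng.random(v_end) < rate)[0]
    for pos in hits:
        current = chars[pos]
        chars[pos] = rng.choice(BASES[BASES != current])
    return "".join(chars)


def simulate_repertoire(
    config: RepertoireSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame, pd.DataFrame]:
    """Generate (reads, AIRR-style annotations, truth table).

    Reads are (read_id, sequence) pairs; annotations carry one row per read
    with 0-based half-open ``v_end``; the truth table has one row per
    generated clone (replacement partners included) recording the planted
    stem, clone size and replacement pairing.
    """
    rng = np.random.default_rng(config.seed)
    v_set = config.germline_v_set or default_germline_v_set()
    d_set = [(f"IGHD{k + 1}-SYN", _random_seq(rng, int(rng.integers(10, 16))))
             for k in range(4)]
    j_set = [(f"IGHJ{k + 1}-SYN", _random_seq(rng, int(rng.integers(15, 21))))
             for k in range(3)]

    reads: list[tuple[str, str]] = []
    airr_rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit_clone(
        clone_id: str,
        v_name: str,
        v_seq: str,
        junction_seq: str,
        size: int,
        partner_of: str | None,
    ) -> None:
        sequence = v_seq + junction_seq
        v_end = len(v_seq)
        d_call = airr_d_call
        j_call = airr_j_call
        for k in range(size):
            mutated = _mutate_v_region(rng, sequence, v_end, config.shm_rate)
            read_id = f"{clone_id}_r{k + 1}"
            reads.append((read_id, mutated))
            airr_rows.append(
                {
                    "sequence_id": read_id,
                    "sequence": mutated,
                    "v_call": v_name,
                    "d_call": d_call,
                    "j_call": j_call,
                    "v_end": v_end,
                    "junction": junction_seq,
                    "junction_length": len(junction_seq),
                }
            )
        truth_rows.append(
            {
                "clone_id": clone_id,
                "v_call": v_name,
                "stem": sequence[v_end + 3 :],
                "size": size,
                "is_replacement_partner": partner_of is not None,
                "partner_of": partner_of if partner_of is not None else "",
            }
        )

    lo, hi = config.junction_length_range
    for ci in range(config.n_clones):
        clone_id = f"clone{ci + 1:04d}"
        v_idx = int(rng.integers(len(v_set)))
        v_name, v_seq = v_set[v_idx]
        airr_d_call, d_seq = d_set[int(rng.integers(len(d_set)))]
        airr_j_call, j_seq = j_set[int(rng.integers(len(j_set)))]
        span_target = int(rng.integers(lo, hi + 1))
        n_total = max(span_target - len(d_seq) - len(j_seq), 6)
        n1_len = int(rng.integers(3, n_total - 3 + 1)) if n_total > 6 else 3
        n2_len = n_total - n1_len
        n1 = _random_seq(rng, n1_len)
        n2 = _random_seq(rng, n2_len)
        junction_seq = n1 + d_seq + n2 + j_seq
        size = min(int(rng.zipf(config.clone_size_distribution)),
                   config.max_clone_size)
        emit_clone(clone_id, v_name, v_seq, junction_seq, size, None)

        if rng.random() < config.replacement_rate and len(v_set) > 1:
            other_idx = int(rng.integers(len(v_set) - 1))
            if other_idx >= v_idx:
                other_idx += 1
            v2_name, v2_seq = v_set[other_idx]
            # altered 5' junction: the 3 bases past the V boundary change,
            # everything downstream (the stem) is retained verbatim
            while True:
                head = _random_seq(rng, 3)
                if head != n1[:3]:
                    break
            partner_junction = head + junction_seq[3:]
            partner_size = min(int(rng.zipf(config.clone_size_distribution)),
                               config.max_clone_size)
            emit_clone(
                f"{clone_id}R", v2_name, v2_seq, partner_junction,
                partner_size, clone_id,
            )

    airr = pd.DataFrame.from_records(airr_rows)
    truth = pd.DataFrame.from_records(truth_rows)
    return reads, airr, truth


def planted_replacement_events(truth: pd.DataFrame) -> int:
    """Number of planted replacement events (partner clones) in a truth
    table."""
    return int(truth["is_replacement_partner"].sum())
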