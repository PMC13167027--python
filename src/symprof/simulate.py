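"""Truth-labelled synthetic data emulating the study's statistical structure.

Two generators:

* a **metagenome cohort**: a reference genome with genes laid head-to-tail,
  a planted set of lineage-specific genes, and per-sample error-free read
  placements (all-M truth alignments — the analysis begins at the alignment
  stage, so mapping fidelity is out of scope).  Group A (luna-dominant)
  samples cover core and specific genes at a high depth regime; group B
  (lotti-dominant) samples cover core genes at a low regime and specific
  genes at (normally) zero depth.

* an **amplicon dataset**: gill ASV tables for a host cohort with the focal
  symbiont trio drawn per co-occurrence category, low-abundance background
  ASVs, organelle contaminants, and four seagrass-habitat compartments with
  two planted host-environment shared ASVs.

Everything is deterministic given (params, seed), byte-level for file
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from symprof.community import (
    COMPARTMENTS_ENV,
    FOCAL_TYPES,
    ASVTable,
    CooccurrenceCategory,
)
from symprof.coverage import depth_from_segments
from symprof.io import (
    GROUP_LOTTI,
    GROUP_LUNA,
    GROUPS,
    AlignmentRecord,
    GeneInterval,
    ParameterError,
    ReferenceGenome,
    write_bed,
    write_fasta,
    write_sam,
)

ASV_LOTTI = "ASV_7xh_i9e"
ASV_LUNA1 = "ASV_imh_tqk"
ASV_LUNA2 = "ASV_ey3_jh5"
ASV_SHARED2 = "ASV_1n2_n6n"  # the second host/environment shared ASV

_THIO_LINEAGE = (
    "Bacteria;Pseudomonadota;Gammaproteobacteria;Chromatiales;"
    "Sedimenticolaceae;Ca_Thiodiazotropha"
)
_MITO_LINEAGE = "Bacteria;Pseudomonadota;Alphaproteobacteria;Rickettsiales;Mitochondria"
_CHLORO_LINEAGE = "Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast"
_BACKGROUND_LINEAGES = (
    "Bacteria;Bacteroidota;Bacteroidia;Flavobacteriales;Flavobacteriaceae",
    "Bacteria;Pseudomonadota;Gammaproteobacteria;Cellvibrionales;Halieaceae",
    "Bacteria;Campylobacterota;Campylobacteria;Campylobacterales;Sulfurovaceae",
    "Bacteria;Desulfobacterota;Desulfobulbia;Desulfobulbales;Desulfocapsaceae",
    "Bacteria;Spirochaetota;Spirochaetia;Spirochaetales;Spirochaetaceae",
    "Bacteria;Planctomycetota;Planctomycetes;Pirellulales;Pirellulaceae",
)


@dataclass
class SimulationTruth:
    """Planted labels: what the pipeline should recover."""

    specific_genes: set[str] = field(default_factory=set)
    sample_groups: dict[str, str] = field(default_factory=dict)
    sample_categories: dict[str, str] = field(default_factory=dict)
    shared_asv_ids: set[str] = field(default_factory=set)

    def write(self, path: str | Path) -> None:
        payload = {
            "specific_genes": sorted(self.specific_genes),
            "sample_groups": dict(sorted(self.sample_groups.items())),
            "sample_categories": dict(sorted(self.sample_categories.items())),
            "shared_asv_ids": sorted(self.shared_asv_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            specific_genes=set(payload["specific_genes"]),
            sample_groups=dict(payload["sample_groups"]),
            sample_categories=dict(payload["sample_categories"]),
            shared_asv_ids=set(payload["shared_asv_ids"]),
        )


# ---------------------------------------------------------------------------
# metagenome cohort
# ---------------------------------------------------------------------------


@dataclass
class ReadSimParams:
    """Depth regimes of the read simulator (all depths in x, fold coverage).

    Defaults mirror the classification regimes the pipeline thresholds
    against: group A (luna-dominant) maps its own genome at high depth
    (core and lineage-specific genes alike); group B (lotti-dominant) maps
    shared core genes at low depth and lineage-A-specific genes at zero.
    Per-gene read counts are Poisson with mean depth*gene_length/read_length.
    """

    read_length: int = 100
    depth_core_group_a: float = 50.0
    depth_core_group_b: float = 5.0
    depth_specific_group_a: float = 50.0
    depth_specific_group_b: float = 0.0
    intergenic_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ParameterError("read_length must be >= 1")
        for name in (
            "depth_core_group_a", "depth_core_group_b",
            "depth_specific_group_a", "depth_specific_group_b", "intergenic_depth",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    def expected_depth(self, specific: bool, group: str) -> float:
        if group == GROUP_LUNA:
            return self.depth_specific_group_a if specific else self.depth_core_group_a
        if group == GROUP_LOTTI:
            return self.depth_specific_group_b if specific else self.depth_core_group_b
        raise ParameterError(f"unknown group {group!r}; expected one of {GROUPS}")


def simulate_reference(
    n_genes: int,
    n_specific: int,
    gene_length: int = 300,
    intergenic_length: int = 50,
    seed: int = 0,
    ref_id: str = "sim_luna_mag",
) -> tuple[ReferenceGenome, list[GeneInterval], SimulationTruth]:
    """Reference with genes laid head-to-tail between intergenic spacers.

    Total length is n_genes*gene_length + (n_genes+1)*intergenic_length.
    ``n_specific`` gene ids are sampled without replacement as the planted
    lineage-A-specific set and recorded in the returned truth.
    """
    if n_specific > n_genes:
        raise ParameterError(f"n_specific ({n_specific}) > n_genes ({n_genes})")
    if n_genes < 1 or gene_length < 1 or intergenic_length < 0:
        raise ParameterError("n_genes, gene_length must be >= 1; intergenic_length >= 0")
    rng = np.random.default_rng(seed)
    total = n_genes * gene_length + (n_genes + 1) * intergenic_length
    sequence = "".join(rng.choice(list("ACGT"), size=total))
    width = max(4, len(str(n_genes)))
    genes = []
    pos = intergenic_length
    for i in range(n_genes):
        genes.append(
            GeneInterval(
                gene_id=f"gene_{i + 1:0{width}d}",
                ref_id=ref_id,
                start=pos,
                end=pos + gene_length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        pos += gene_length + intergenic_length
    specific = set(rng.choice([g.gene_id for g in genes], size=n_specific, replace=False))
    truth = SimulationTruth(specific_genes=specific)
    return ReferenceGenome(id=ref_id, sequence=sequence), genes, truth


def _read_starts(
    genes: Sequence[GeneInterval],
    specific: set[str],
    group: str,
    params: ReadSimParams,
    reference_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sorted 0-based start positions of all reads of one sample.

    Reads never straddle gene boundaries: starts are uniform over
    [gene_start, gene_end - read_length], which makes per-gene expected
    depth exact.  Intergenic reads (if enabled) are a separate stream over
    spacers long enough to hold a read.
    """
    L = params.read_length
    starts: list[np.ndarray] = []
    for g in genes:
        if L > g.length:
            raise ParameterError(
                f"read_length {L} exceeds gene {g.gene_id!r} length {g.length}"
            )
        depth = params.expected_depth(g.gene_id in specific, group)
        n = rng.poisson(depth * g.length / L)
        if n:
            starts.append(rng.integers(g.start, g.end - L + 1, size=n))
    if params.intergenic_depth > 0:
        bounds = [0] + [x for g in genes for x in (g.start, g.end)] + [reference_length]
        for lo, hi in zip(bounds[::2], bounds[1::2]):
            if hi - lo < L:
                continue
            n = rng.poisson(params.intergenic_depth * (hi - lo) / L)
            if n:
                starts.append(rng.integers(lo, hi - L + 1, size=n))
    if not starts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(starts))


def simulate_sample_depth(
    genes: Sequence[GeneInterval],
    truth: SimulationTruth,
    group: str,
    params: ReadSimParams,
    reference_length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-base depth profile of one simulated sample (no record objects).

    Identical in distribution (and, for a shared generator state, in value)
    to computing per-base depth from :func:`simulate_sample_alignments`.
    """
    starts = _read_starts(genes, truth.specific_genes, group, params, reference_length, rng)
    return depth_from_segments(starts, starts + params.read_length, reference_length)


def simulate_sample_alignments(
    reference: ReferenceGenome,
    genes: Sequence[GeneInterval],
    truth: SimulationTruth,
    group: str,
    params: ReadSimParams,
    rng: np.random.Generator,
    sample_id: str = "sample",
) -> list[AlignmentRecord]:
    """Error-free truth alignments (all-M CIGARs) for one sample, pos-sorted."""
    starts = _read_starts(
        genes, truth.specific_genes, group, params, reference.length, rng
    )
    cigar = ((params.read_length, "M"),)
    return [
        AlignmentRecord(
            read_id=f"{sample_id}_r{i + 1:07d}",
            ref_id=reference.id,
            pos0=int(s),
            cigar=cigar,
            flags=0,
            mapq=60,
        )
        for i, s in enumerate(starts)
    ]


def _cohort_sample_ids(n_group_a: int, n_group_b: int) -> tuple[list[str], dict[str, str]]:
    width = max(3, len(str(n_group_a + n_group_b)))
    ids = [f"S{i + 1:0{width}d}" for i in range(n_group_a + n_group_b)]
    groups = {
        s: (GROUP_LUNA if i < n_group_a else GROUP_LOTTI) for i, s in enumerate(ids)
    }
    return ids, groups


def simulate_cohort_depths(
    n_group_a: int,
    n_group_b: int,
    genes: Sequence[GeneInterval],
    truth: SimulationTruth,
    params: ReadSimParams,
    reference_length: int,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], SimulationTruth]:
    """In-memory cohort: per-sample depth profiles plus truth with groups."""
    if n_group_a + n_group_b < 2:
        raise ParameterError("cohort needs at least 2 samples")
    ids, groups = _cohort_sample_ids(n_group_a, n_group_b)
    rng = np.random.default_rng(seed)
    profiles = {
        s: simulate_sample_depth(genes, truth, groups[s], params, reference_length, rng)
        for s in ids
    }
    out_truth = dataclasses.replace(truth, sample_groups=groups)
    return profiles, out_truth


def simulate_cohort(
    n_group_a: int,
    n_group_b: int,
    reference: ReferenceGenome,
    genes: Sequence[GeneInterval],
    truth: SimulationTruth,
    params: ReadSimParams,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[AlignmentRecord]], pd.DataFrame, SimulationTruth]:
    """Full cohort with alignment records; optionally written to disk.

    With ``out_dir`` set, writes reference.fasta, genes.bed, one
    ``<sample>.sam`` per sample, ``samples.tsv`` (sample_id, group) and
    ``truth.json``.
    """
    if n_group_a + n_group_b < 2:
        raise ParameterError("cohort needs at least 2 samples")
    if n_group_a == 0 or n_group_b == 0:
        import logging
        logging.getLogger("symprof").warning(
            "simulate_cohort: one group is empty; differential testing will refuse"
        )
    ids, groups = _cohort_sample_ids(n_group_a, n_group_b)
    rng = np.random.default_rng(seed)
    cohort = {
        s: simulate_sample_alignments(reference, genes, truth, groups[s], params, rng, s)
        for s in ids
    }
    metadata = pd.DataFrame({"sample_id": ids, "group": [groups[s] for s in ids]})
    out_truth = dataclasses.replace(truth, sample_groups=groups)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta([reference], out_dir / "reference.fasta")
        write_bed(genes, out_dir / "genes.bed")
        for s, records in cohort.items():
            write_sam(records, {reference.id: reference.length}, out_dir / f"{s}.sam")
        metadata.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
        out_truth.write(out_dir / "truth.json")
    return cohort, metadata, out_truth


# ---------------------------------------------------------------------------
# amplicon dataset
# ---------------------------------------------------------------------------


def _renormalized(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or p.sum() <= 0:
        raise ParameterError("category probabilities must be nonnegative with positive sum")
    return p / p.sum()


@dataclass
class ASVSimParams:
    """Parameters of the amplicon generator.

    ``category_probabilities`` follow the observed host co-occurrence split
    (LOTTI_ONLY 23.8%, LOTTI_PLUS_ONE_VARIANT 14.6%, ALL_THREE ~25%,
    VARIANTS_ONLY 36.9%; renormalized since the printed values sum to
    1.003).  Dominant-abundance ranges are the observed ranges: lotti
    68.3-98.7%, luna variants 48.4-98.1% relative abundance.

    The minor-variant floor is 5e-4 rather than the lowest observed 6e-5 so
    that every planted co-occurrence pattern stays detectable at the default
    library size (expected count ~10 rather than ~1).
    """

    n_hosts: int = 130
    category_probabilities: tuple[float, float, float, float] = (0.238, 0.146, 0.25, 0.369)
    lotti_dominant_range: tuple[float, float] = (0.683, 0.987)
    luna_dominant_range: tuple[float, float] = (0.484, 0.981)
    minor_variant_range: tuple[float, float] = (0.0005, 0.019)
    n_background_asvs: int = 60
    background_concentration: float = 0.3
    n_thio_background_asvs: int = 8
    gill_shared2_probability: float = 0.6
    gill_shared2_range: tuple[float, float] = (0.0005, 0.01)
    library_size_median: float = 20000.0
    library_size_sigma: float = 0.35
    low_quality_fraction: float = 0.0
    n_env_samples_per_compartment: int = 12
    n_env_background_asvs: int = 80
    # per-compartment mean relative abundance of the two shared ASVs;
    # ASV_1n2_n6n is planted only on blades and the root/rhizome
    env_focal_abundance: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "blade": {ASV_LUNA1: 1e-4, ASV_SHARED2: 2e-4},
            "root_rhizome": {ASV_LUNA1: 2e-4, ASV_SHARED2: 4e-4},
            "sediment": {ASV_LUNA1: 5e-5},
            "seawater": {ASV_LUNA1: 5e-5},
        }
    )
    blade_chloroplast_range: tuple[float, float] = (0.1, 0.4)

    def __post_init__(self) -> None:
        _renormalized(self.category_probabilities)
        for lo, hi in (
            self.lotti_dominant_range, self.luna_dominant_range,
            self.minor_variant_range, self.gill_shared2_range,
        ):
            if not (0 < lo < hi < 1):
                raise ParameterError(f"abundance range ({lo}, {hi}) outside (0, 1)")
        if self.n_hosts < 1 or self.library_size_median < 1:
            raise ParameterError("n_hosts and library_size_median must be >= 1")
        if self.background_concentration < 0:
            raise ParameterError("background concentration must be >= 0")


_CATEGORY_ORDER = (
    CooccurrenceCategory.LOTTI_ONLY,
    CooccurrenceCategory.LOTTI_PLUS_ONE_VARIANT,
    CooccurrenceCategory.ALL_THREE,
    CooccurrenceCategory.VARIANTS_ONLY,
)


def _host_focal_fractions(
    category: CooccurrenceCategory, p: ASVSimParams, rng: np.random.Generator
) -> dict[str, float]:
    """Relative abundances of the focal trio for one host, per its category."""
    u = rng.uniform
    if category is CooccurrenceCategory.LOTTI_ONLY:
        return {ASV_LOTTI: u(*p.lotti_dominant_range)}
    if category is CooccurrenceCategory.LOTTI_PLUS_ONE_VARIANT:
        dom = u(*p.lotti_dominant_range)
        variant = ASV_LUNA1 if rng.random() < 0.5 else ASV_LUNA2
        minor = min(u(*p.minor_variant_range), 0.8 * (1 - dom))
        return {ASV_LOTTI: dom, variant: minor}
    if category is CooccurrenceCategory.ALL_THREE:
        dominant = (ASV_LOTTI, ASV_LUNA1, ASV_LUNA2)[rng.integers(3)]
        rng_range = p.lotti_dominant_range if dominant == ASV_LOTTI else p.luna_dominant_range
        dom = u(*rng_range)
        rest = 1 - dom
        out = {dominant: dom}
        for asv in (ASV_LOTTI, ASV_LUNA1, ASV_LUNA2):
            if asv != dominant:
                out[asv] = u(0.05, 0.4) * rest
        return out
    if category is CooccurrenceCategory.VARIANTS_ONLY:
        dominant = ASV_LUNA1 if rng.random() < 0.5 else ASV_LUNA2
        other = ASV_LUNA2 if dominant == ASV_LUNA1 else ASV_LUNA1
        dom = u(*p.luna_dominant_range)
        return {dominant: dom, other: u(0.05, 0.8) * (1 - dom)}
    raise ParameterError(f"generator does not plant category {category}")


def _library_size(p: ASVSimParams, rng: np.random.Generator) -> int:
    if p.low_quality_fraction > 0 and rng.random() < p.low_quality_fraction:
        return int(rng.integers(100, 1000))
    size = int(round(rng.lognormal(math.log(p.library_size_median), p.library_size_sigma)))
    return max(size, 1)


def simulate_asv_dataset(
    params: ASVSimParams | None = None, seed: int = 0
) -> tuple[ASVTable, ASVTable, SimulationTruth]:
    """Gill and environment ASV tables plus planted truth.

    Gill: ``n_hosts`` samples; each host gets a co-occurrence category, focal
    abundances within the observed dominance ranges (both luna variants are
    always co-planted in VARIANTS_ONLY hosts), the shared ASV_1n2_n6n in
    ~60% of hosts at <1%, a host-mitochondrial contaminant ASV, and the
    remaining mass over background ASVs via a symmetric Dirichlet.

    Environment: four compartments; *Ca.* T. luna variant 1 planted in all
    compartments at low abundance (higher on the root/rhizome), ASV_1n2_n6n
    only on blades and root/rhizome at about twice variant 1's rhizome
    abundance; blade samples carry a large chloroplast fraction that the
    taxon filter must remove.
    """
    p = params or ASVSimParams()
    rng = np.random.default_rng(seed)
    probs = _renormalized(p.category_probabilities)

    # --- column universe, gill ---------------------------------------------
    bg_ids = [f"ASV_bg_g{i + 1:03d}" for i in range(p.n_background_asvs)]
    gill_cols = [ASV_LOTTI, ASV_LUNA1, ASV_LUNA2, ASV_SHARED2, "ASV_mt_host"] + bg_ids
    taxonomy = {
        ASV_LOTTI: _THIO_LINEAGE,
        ASV_LUNA1: _THIO_LINEAGE,
        ASV_LUNA2: _THIO_LINEAGE,
        ASV_SHARED2: _THIO_LINEAGE,
        "ASV_mt_host": _MITO_LINEAGE,
    }
    for i, asv in enumerate(bg_ids):
        taxonomy[asv] = (
            _THIO_LINEAGE
            if i < p.n_thio_background_asvs
            else _BACKGROUND_LINEAGES[i % len(_BACKGROUND_LINEAGES)]
        )

    width = max(3, len(str(p.n_hosts)))
    host_ids = [f"G{i + 1:0{width}d}" for i in range(p.n_hosts)]
    counts = np.zeros((p.n_hosts, len(gill_cols)), dtype=np.int64)
    categories: dict[str, str] = {}
    sites = ("bay_east", "bay_west")
    dates = ("2023-05-10", "2023-07-12")
    meta_rows = []
    col_index = {a: j for j, a in enumerate(gill_cols)}
    for i, host in enumerate(host_ids):
        category = _CATEGORY_ORDER[rng.choice(4, p=probs)]
        categories[host] = category.value
        fractions = dict(_host_focal_fractions(category, p, rng))
        if rng.random() < p.gill_shared2_probability:
            fractions[ASV_SHARED2] = rng.uniform(*p.gill_shared2_range)
        fractions["ASV_mt_host"] = rng.uniform(0.002, 0.02)
        remaining = max(1.0 - sum(fractions.values()), 0.005)
        if p.background_concentration > 0 and p.n_background_asvs > 0:
            bg = rng.dirichlet(np.full(p.n_background_asvs, p.background_concentration))
            for asv, frac in zip(bg_ids, bg * remaining):
                fractions[asv] = frac
        vec = np.zeros(len(gill_cols))
        for asv, frac in fractions.items():
            vec[col_index[asv]] = frac
        counts[i] = rng.multinomial(_library_size(p, rng), vec / vec.sum())
        meta_rows.append(
            {"sample_id": host, "site": sites[i % 2], "date": dates[(i // 2) % 2],
             "compartment": "gill"}
        )
    gill = ASVTable(
        counts=pd.DataFrame(counts, index=host_ids, columns=gill_cols),
        taxonomy=pd.Series({a: taxonomy[a] for a in gill_cols}),
        metadata=pd.DataFrame(meta_rows).set_index("sample_id"),
    )

    # --- environment --------------------------------------------------------
    env_bg_ids = [f"ASV_env_{i + 1:03d}" for i in range(p.n_env_background_asvs)]
    env_cols = [ASV_LUNA1, ASV_SHARED2, "ASV_cp_zostera"] + env_bg_ids
    env_taxonomy = {
        ASV_LUNA1: _THIO_LINEAGE,
        ASV_SHARED2: _THIO_LINEAGE,
        "ASV_cp_zostera": _CHLORO_LINEAGE,
    }
    for i, asv in enumerate(env_bg_ids):
        env_taxonomy[asv] = (
            _THIO_LINEAGE if i < 6 else _BACKGROUND_LINEAGES[i % len(_BACKGROUND_LINEAGES)]
        )
    env_ids = []
    env_meta = []
    env_counts = []
    env_col_index = {a: j for j, a in enumerate(env_cols)}
    for comp in COMPARTMENTS_ENV:
        focal_means = p.env_focal_abundance.get(comp, {})
        for i in range(p.n_env_samples_per_compartment):
            sid = f"E_{comp}_{i + 1:02d}"
            env_ids.append(sid)
            vec = np.zeros(len(env_cols))
            for asv, mean_frac in focal_means.items():
                vec[env_col_index[asv]] = mean_frac * rng.uniform(0.5, 1.5)
            if comp == "blade":
                vec[env_col_index["ASV_cp_zostera"]] = rng.uniform(*p.blade_chloroplast_range)
            remaining = max(1.0 - vec.sum(), 0.1)
            bg = rng.dirichlet(np.full(p.n_env_background_asvs, 0.5))
            vec[3:] = bg * remaining
            env_counts.append(rng.multinomial(_library_size(p, rng), vec / vec.sum()))
            env_meta.append(
                {"sample_id": sid, "site": sites[i % 2], "date": dates[(i // 2) % 2],
                 "compartment": comp}
            )
    environment = ASVTable(
        counts=pd.DataFrame(np.array(env_counts), index=env_ids, columns=env_cols),
        taxonomy=pd.Series(env_taxonomy),
        metadata=pd.DataFrame(env_meta).set_index("sample_id"),
    )

    truth = SimulationTruth(
        sample_categories=categories,
        shared_asv_ids={ASV_LUNA1, ASV_SHARED2},
    )
    return gill, environment, truth
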