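"""ASV-table processing: filtering, CSS normalization, dominance,
co-occurrence categories, richness, and host-environment shared ASVs.

The focal unit is the trio of dominant *Ca.* Thiodiazotropha sequence types
found in lucinid gills — *Ca.* T. lotti and two *Ca.* T. luna variants —
plus any ASV detected both in gill tissue and in a seagrass-habitat
compartment (blade, root/rhizome, sediment, seawater).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from symprof.io import ParameterError, SymprofError

logger = logging.getLogger("symprof")

COMPARTMENTS_ENV = ("blade", "root_rhizome", "sediment", "seawater")
COMPARTMENT_GILL = "gill"

#: Default focal-ASV identities: the three dominant symbiont sequence types.
FOCAL_TYPES = {
    "ASV_7xh_i9e": "T_lotti",
    "ASV_imh_tqk": "T_luna_var1",
    "ASV_ey3_jh5": "T_luna_var2",
}

_ORGANELLE_MARKERS = ("mitochondria", "chloroplast", "eukaryota")


class CooccurrenceCategory(str, Enum):
    """Which combination of the three focal symbiont types a host carries.

    The six values partition the 8 detection patterns of the trio: two
    patterns collapse to LOTTI_PLUS_ONE_VARIANT and two to
    SINGLE_VARIANT_ONLY.
    """

    LOTTI_ONLY = "LOTTI_ONLY"
    LOTTI_PLUS_ONE_VARIANT = "LOTTI_PLUS_ONE_VARIANT"
    ALL_THREE = "ALL_THREE"
    VARIANTS_ONLY = "VARIANTS_ONLY"
    SINGLE_VARIANT_ONLY = "SINGLE_VARIANT_ONLY"
    NONE_DETECTED = "NONE_DETECTED"


@dataclass
class ASVTable:
    """Samples x ASVs count table with taxonomy and sample metadata.

    ``counts``: integer DataFrame, samples as rows, ASV ids as columns.
    ``taxonomy``: Series mapping ASV id -> semicolon-separated lineage.
    ``metadata``: DataFrame indexed by sample_id with at least
    site, date and compartment columns.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ParameterError("ASV counts must be nonnegative")
        missing_meta = set(self.counts.index) - set(self.metadata.index)
        if missing_meta:
            raise ParameterError(f"samples without metadata: {sorted(missing_meta)[:5]}")
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ParameterError(f"ASVs without taxonomy: {sorted(missing_tax)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, samples=None, asvs=None) -> "ASVTable":
        counts = self.counts
        if samples is not None:
            counts = counts.loc[list(samples)]
        if asvs is not None:
            counts = counts[list(asvs)]
        return ASVTable(
            counts=counts,
            taxonomy=self.taxonomy.loc[list(counts.columns)],
            metadata=self.metadata.loc[list(counts.index)],
        )

    # -- TSV round trip ----------------------------------------------------

    def write(self, out_dir: str | Path, prefix: str = "asv") -> None:
        out_dir = Path(out_dir)
        self.counts.rename_axis("sample_id").to_csv(out_dir / f"{prefix}_counts.tsv", sep="\t")
        self.taxonomy.rename_axis("asv_id").rename("lineage").to_csv(
            out_dir / f"{prefix}_taxonomy.tsv", sep="\t"
        )
        self.metadata.rename_axis("sample_id").to_csv(
            out_dir / f"{prefix}_sample_metadata.tsv", sep="\t", na_rep="."
        )

    @classmethod
    def read(cls, out_dir: str | Path, prefix: str = "asv") -> "ASVTable":
        out_dir = Path(out_dir)
        counts = pd.read_csv(out_dir / f"{prefix}_counts.tsv", sep="\t", index_col="sample_id")
        taxonomy = pd.read_csv(
            out_dir / f"{prefix}_taxonomy.tsv", sep="\t", index_col="asv_id"
        )["lineage"]
        metadata = pd.read_csv(
            out_dir / f"{prefix}_sample_metadata.tsv", sep="\t", index_col="sample_id",
            na_values=["."], keep_default_na=True,
        )
        return cls(counts=counts, taxonomy=taxonomy, metadata=metadata)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_samples(table: ASVTable, min_library_size: int) -> ASVTable:
    """Drop samples with total counts below ``min_library_size`` (strict <)."""
    if min_library_size < 0:
        raise ParameterError("min_library_size must be >= 0")
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= min_library_size].index
    n_removed = len(table.counts) - len(keep)
    if n_removed:
        logger.info(
            "filter_samples: removed=%d kept=%d (threshold=%d)",
            n_removed, len(keep), min_library_size,
        )
    if len(keep) == 0:
        raise SymprofError("filter_samples removed every sample")
    return table.subset(samples=keep)


def filter_taxa(table: ASVTable) -> ASVTable:
    """Remove mitochondrial, chloroplast and eukaryotic ASVs (case-insensitive).

    ASVs with an "unclassified" lineage are kept: no organelle evidence.
    """
    lineages = table.taxonomy.loc[table.asv_ids].fillna("").str.lower()
    organelle = lineages.apply(lambda s: any(m in s for m in _ORGANELLE_MARKERS))
    keep = [a for a, bad in organelle.items() if not bad]
    n_removed = len(table.asv_ids) - len(keep)
    if n_removed:
        logger.info("filter_taxa: removed=%d organelle/eukaryote ASVs", n_removed)
    return table.subset(asvs=keep)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def css_scaling_factor(counts: np.ndarray, quantile: float) -> float:
    """Cumulative-sum-scaling factor s_j of one sample.

    The quantile is taken nearest-rank over the sample's positive counts
    (value at 1-based index ceil(l * k) of the k sorted positive counts);
    s_j is the sum of all counts <= that quantile value.
    """
    if not 0 < quantile < 1:
        raise ParameterError(f"css quantile {quantile} outside (0, 1)")
    positive = np.sort(counts[counts > 0])
    if positive.size == 0:
        raise ParameterError("CSS undefined for a sample with no positive counts")
    k = positive.size
    q = positive[int(np.ceil(quantile * k)) - 1]
    s = float(counts[counts <= q].sum())
    if s <= 0:  # unreachable given a positive count exists, kept defensively
        raise SymprofError("CSS scaling factor is zero")
    return s


def css_normalize(
    table: ASVTable, css_quantile: float = 0.5, css_scale: float = 1000.0
) -> tuple[pd.DataFrame, pd.Series]:
    """CSS-normalize counts: raw * scale / s_j per sample.

    Returns the normalized table and the per-sample scaling factors s_j.
    Normalization is invariant to multiplying a sample's counts by any
    positive constant, which is the property that removes sequencing-depth
    differences.
    """
    factors = pd.Series(
        {
            sample: css_scaling_factor(row.to_numpy(), css_quantile)
            for sample, row in table.counts.iterrows()
        },
        name="css_factor",
    )
    normalized = table.counts.div(factors, axis=0) * css_scale
    return normalized, factors


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances; every row sums to 1."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals[totals <= 0].index)[:5]
        raise ParameterError(f"zero-total samples (filter first): {bad}")
    return counts.div(totals, axis=0)


# ---------------------------------------------------------------------------
# dominance & co-occurrence
# ---------------------------------------------------------------------------


def dominant_symbiont(
    table: ASVTable,
    focal: Mapping[str, str] = FOCAL_TYPES,
    detection_min_count: int = 1,
) -> pd.DataFrame:
    """Per-sample dominant focal symbiont sequence type.

    The dominant is the *detected* focal ASV (raw count >=
    ``detection_min_count``) with the largest relative abundance; exact ties
    break to the lexicographically smallest ASV id.  Samples with no focal
    ASV detected get dominant_type "none".
    """
    if not focal:
        raise ParameterError("focal mapping must be nonempty")
    focal_ids = sorted(a for a in focal if a in table.counts.columns)
    rel = relative_abundance(table.counts)
    rows = []
    for sample in table.sample_ids:
        detected = [a for a in focal_ids if table.counts.at[sample, a] >= detection_min_count]
        if not detected:
            rows.append(
                {"sample_id": sample, "dominant_asv": ".", "dominant_type": "none",
                 "dominant_rel_abundance": 0.0}
            )
            continue
        # detected is id-sorted: keeping the first maximum breaks ties to the
        # lexicographically smallest ASV id
        best = detected[0]
        for a in detected[1:]:
            if rel.at[sample, a] > rel.at[sample, best]:
                best = a
        rows.append(
            {
                "sample_id": sample,
                "dominant_asv": best,
                "dominant_type": focal[best],
                "dominant_rel_abundance": float(rel.at[sample, best]),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def cooccurrence_category(
    lotti_detected: bool, var1_detected: bool, var2_detected: bool
) -> CooccurrenceCategory:
    """Map the focal trio's detection flags to a co-occurrence category."""
    n_variants = int(var1_detected) + int(var2_detected)
    if lotti_detected:
        if n_variants == 0:
            return CooccurrenceCategory.LOTTI_ONLY
        if n_variants == 1:
            return CooccurrenceCategory.LOTTI_PLUS_ONE_VARIANT
        return CooccurrenceCategory.ALL_THREE
    if n_variants == 2:
        return CooccurrenceCategory.VARIANTS_ONLY
    if n_variants == 1:
        return CooccurrenceCategory.SINGLE_VARIANT_ONLY
    return CooccurrenceCategory.NONE_DETECTED


def categorize_samples(
    table: ASVTable,
    focal: Mapping[str, str] = FOCAL_TYPES,
    detection_min_count: int = 1,
) -> pd.Series:
    """Co-occurrence category of every sample in the table."""
    by_type = {t: a for a, t in focal.items()}
    def detected(sample: str, asv: str) -> bool:
        return asv in table.counts.columns and bool(
            table.counts.at[sample, asv] >= detection_min_count
        )
    return pd.Series(
        {
            s: cooccurrence_category(
                detected(s, by_type["T_lotti"]),
                detected(s, by_type["T_luna_var1"]),
                detected(s, by_type["T_luna_var2"]),
            ).value
            for s in table.sample_ids
        },
        name="category",
    )


def cooccurrence_summary(categories: Iterable[str | CooccurrenceCategory]) -> pd.DataFrame:
    """Counts and percentages (1 decimal) per co-occurrence category."""
    values = [c.value if isinstance(c, CooccurrenceCategory) else str(c) for c in categories]
    if not values:
        raise ParameterError("cooccurrence_summary requires at least one sample")
    order = [c.value for c in CooccurrenceCategory]
    counts = pd.Series(values).value_counts().reindex(order, fill_value=0)
    pct = (100.0 * counts / counts.sum()).round(1)
    return pd.DataFrame({"count": counts, "percent": pct}).rename_axis("category")


# ---------------------------------------------------------------------------
# richness & shared ASVs
# ---------------------------------------------------------------------------


def richness(
    table: ASVTable, detection_min_count: int = 1, taxon_prefix: str | None = None
) -> pd.Series:
    """Observed ASV count per sample (counts >= detection_min_count).

    ``taxon_prefix`` restricts to ASVs whose lineage contains the given
    substring (case-insensitive), e.g. a genus name.
    """
    counts = table.counts
    if taxon_prefix is not None:
        lineages = table.taxonomy.loc[table.asv_ids].fillna("").str.lower()
        keep = [a for a in table.asv_ids if taxon_prefix.lower() in lineages[a]]
        counts = counts[keep]
    return (counts >= detection_min_count).sum(axis=1).rename("richness")


def shared_asvs(
    gill: ASVTable, environment: ASVTable, detection_min_count: int = 1
) -> pd.DataFrame:
    """ASVs detected in at least one gill sample AND one environment sample.

    For each shared ASV the report gives gill prevalence plus, per
    environment compartment, the fraction of samples in which it is detected
    and its mean relative abundance; sorted by overall environment
    prevalence (descending), ties by ASV id.
    """
    common = sorted(set(gill.asv_ids) & set(environment.asv_ids))
    if not common:
        raise SymprofError(
            "gill and environment tables share no ASV ids; shared-ASV detection "
            "requires a common id space (identical sequences, identical ids)"
        )
    gill_det = (gill.counts[common] >= detection_min_count)
    env_det = (environment.counts[common] >= detection_min_count)
    shared = [a for a in common if gill_det[a].any() and env_det[a].any()]
    env_rel = relative_abundance(environment.counts)
    compartments = environment.metadata["compartment"]
    rows = []
    for asv in shared:
        row = {
            "asv_id": asv,
            "gill_prevalence": float(gill_det[asv].mean()),
            "env_prevalence": float(env_det[asv].mean()),
        }
        for comp in COMPARTMENTS_ENV:
            comp_samples = compartments[compartments == comp].index
            if len(comp_samples) == 0:
                row[f"{comp}_prevalence"] = float("nan")
                row[f"{comp}_mean_rel_abundance"] = float("nan")
            else:
                row[f"{comp}_prevalence"] = float(env_det.loc[comp_samples, asv].mean())
                row[f"{comp}_mean_rel_abundance"] = float(env_rel.loc[comp_samples, asv].mean())
        rows.append(row)
    report = pd.DataFrame(
        rows,
        columns=["asv_id", "gill_prevalence", "env_prevalence"]
        + [f"{c}_{m}" for c in COMPARTMENTS_ENV for m in ("prevalence", "mean_rel_abundance")],
    )
    return report.sort_values(
        ["env_prevalence", "asv_id"], ascending=[False, True]
    ).reset_index(drop=True)
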