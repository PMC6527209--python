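"""Data model and I/O for OTU abundance tables and sample metadata.

The on-disk formats are the classic tab-delimited OTU table (a leading
``#OTU ID`` header cell is tolerated, an optional trailing ``taxonomy``
column holds semicolon-delimited lineage strings) and a flat tab-delimited
metadata table with one row per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical body-site vocabulary used throughout the package.
LUNG = "lung"
OROPHARYNX = "oropharynx"
GASTRIC = "gastric"
STOOL = "stool"
SITES = (LUNG, OROPHARYNX, GASTRIC, STOOL)
AERODIGESTIVE_SITES = (LUNG, OROPHARYNX, GASTRIC)

#: Aliases normalised at parse time; the literature uses specimen names
#: (BAL, oropharyngeal swab, gastric fluid) and site names interchangeably.
SITE_ALIASES: dict[str, str] = {
    "lung": LUNG,
    "bal": LUNG,
    "oropharynx": OROPHARYNX,
    "oropharyngeal swab": OROPHARYNX,
    "oropharyngeal": OROPHARYNX,
    "throat": OROPHARYNX,
    "gastric": GASTRIC,
    "gastric fluid": GASTRIC,
    "stomach": GASTRIC,
    "stool": STOOL,
}

ASPIRATION_STATUSES = ("aspirator", "non_aspirator", "untested")

#: Taxonomic ranks, in lineage order, addressable by collapse_to_rank.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

METADATA_COLUMNS = ("patient_id", "site", "batch", "aspiration_status")


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


def normalize_site(label: str, aliases: dict[str, str] | None = None) -> str:
    """Map a free-form body-site label onto the canonical vocabulary."""
    table = SITE_ALIASES if aliases is None else {**SITE_ALIASES, **aliases}
    key = str(label).strip().lower()
    if key not in table:
        raise ParseError(f"unrecognised body-site label: {label!r}")
    return table[key]


@dataclass
class AbundanceTable:
    """An OTU-by-sample abundance matrix with per-OTU taxonomy lineages.

    Parameters
    ----------
    data
        DataFrame with OTU IDs as the index and sample IDs as columns.
        Values are non-negative counts or relative abundances.
    taxonomy
        One semicolon-delimited lineage string per OTU (kingdom through
        genus); an empty string at a rank means unannotated there.
    mode
        ``"counts"`` or ``"relative"``. In relative mode every sample
        column sums to 1 (within 1e-9).
    """

    data: pd.DataFrame
    taxonomy: list[str] = field(default_factory=list)
    mode: str = "counts"

    def __post_init__(self) -> None:
        if not self.taxonomy:
            self.taxonomy = [""] * self.data.shape[0]
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> np.ndarray:
        """Abundance vector (over OTUs) for one sample."""
        return self.data[sample_id].to_numpy(dtype=float)

    def validate(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate OTU IDs: {list(dupes)}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dupes)}")
        if len(self.taxonomy) != self.data.shape[0]:
            raise ValueError(
                "taxonomy length does not match number of OTUs: "
                f"{len(self.taxonomy)} vs {self.data.shape[0]}"
            )
        vals = self.data.to_numpy(dtype=float)
        if vals.size and (vals < 0).any():
            bad = self.data.columns[np.where(vals < 0)[1][0]]
            raise ValueError(f"negative abundance in sample {bad!r}")
        if self.mode == "relative" and vals.size:
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.columns[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValueError(
                    f"relative-mode column {bad!r} sums to {sums.max():.6g}, not 1"
                )

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), list(self.taxonomy), self.mode)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.mode == other.mode
            and self.taxonomy == other.taxonomy
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.allclose(self.values, other.values, atol=1e-12, rtol=0)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: patient, body site, batch, aspiration status.

    ``data`` is indexed by sample ID with at least the columns
    ``patient_id``, ``site``, ``batch``, ``aspiration_status``; any further
    columns are free covariates (PPI use, reflux measures, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs in metadata: {list(dupes)}")
        pairs = self.data[["patient_id", "site"]]
        if pairs.duplicated().any():
            bad = pairs[pairs.duplicated()].iloc[0]
            raise ValueError(
                f"patient {bad['patient_id']!r} has multiple {bad['site']!r} samples"
            )
        bad_sites = set(self.data["site"]) - set(SITES)
        if bad_sites:
            raise ValueError(f"unknown body sites in metadata: {sorted(bad_sites)}")
        bad_status = set(self.data["aspiration_status"]) - set(ASPIRATION_STATUSES)
        if bad_status:
            raise ValueError(f"unknown aspiration statuses: {sorted(bad_status)}")

    def samples_of_site(self, site: str) -> pd.DataFrame:
        return self.data[self.data["site"] == site]

    def sample_for(self, patient_id: str, site: str) -> str | None:
        """Sample ID of a patient's sample at a site, or None if absent."""
        rows = self.data[
            (self.data["patient_id"] == patient_id) & (self.data["site"] == site)
        ]
        return None if rows.empty else rows.index[0]

    def patients_with_sites(self, sites) -> list[str]:
        """Patients that have a sample at every site in ``sites``."""
        by_patient = self.data.groupby("patient_id")["site"].agg(set)
        want = set(sites)
        return sorted(p for p, have in by_patient.items() if want <= have)

    def patient_status(self, patient_id: str) -> str:
        statuses = set(
            self.data.loc[self.data["patient_id"] == patient_id, "aspiration_status"]
        )
        if len(statuses) != 1:
            raise ValueError(
                f"inconsistent aspiration status for patient {patient_id!r}"
            )
        return statuses.pop()

    def copy(self) -> "SampleMetadata":
        return SampleMetadata(self.data.copy())


@dataclass(frozen=True)
class SitePair:
    """An unordered pair of body sites, plus the site used for partialling.

    When both members are aerodigestive sites the third aerodigestive site
    is the default conditioning site for partial-correlation analyses.
    """

    site_a: str
    site_b: str
    partial_site: str | None = None

    def __post_init__(self) -> None:
        if self.site_a == self.site_b:
            raise ValueError("site_a and site_b must differ")
        partial = self.partial_site
        if partial is None and {self.site_a, self.site_b} <= set(AERODIGESTIVE_SITES):
            (partial,) = set(AERODIGESTIVE_SITES) - {self.site_a, self.site_b}
            object.__setattr__(self, "partial_site", partial)
        if self.partial_site in (self.site_a, self.site_b):
            raise ValueError("partial_site must differ from the pair sites")

    @property
    def sites(self) -> tuple[str, str]:
        return (self.site_a, self.site_b)

    def __str__(self) -> str:
        return f"{self.site_a}-{self.site_b}"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path) -> AbundanceTable:
    """Read a tab-delimited OTU table (counts mode).

    First column is the OTU ID (a leading ``#OTU ID`` header cell is
    tolerated); an optional final ``taxonomy`` column carries lineages.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ParseError(f"{path}: empty file")
    raw_cols = header.split("\t")
    sample_cols = raw_cols[1:]
    if sample_cols and sample_cols[-1].lower() == "taxonomy":
        sample_cols = sample_cols[:-1]
    dupes = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate sample IDs: {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no columns found")
    df = df.rename(columns={df.columns[0]: "_otu_id"})
    has_tax = df.columns[-1].lower() == "taxonomy"
    taxonomy_col = df.pop(df.columns[-1]) if has_tax else None
    otu_ids = df.pop("_otu_id").astype(str)
    if otu_ids.duplicated().any():
        dupes = sorted(otu_ids[otu_ids.duplicated()].unique())
        raise ParseError(f"{path}: duplicate OTU IDs: {dupes}")
    if pd.Index(df.columns).has_duplicates:
        dupes = sorted(pd.Index(df.columns)[pd.Index(df.columns).duplicated()])
        raise ParseError(f"{path}: duplicate sample IDs: {dupes}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance value ({exc})") from exc
    values.index = otu_ids
    if values.size and (values.to_numpy() < 0).any():
        col = values.columns[np.where(values.to_numpy() < 0)[1][0]]
        raise ParseError(f"{path}: negative value in sample column {col!r}")
    taxonomy = (
        taxonomy_col.fillna("").astype(str).tolist()
        if taxonomy_col is not None
        else [""] * len(otu_ids)
    )
    return AbundanceTable(values, taxonomy, mode="counts")


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table in the tab-delimited OTU-table format read back by
    :func:`read_abundance_table` (round-trip identity within 1e-12)."""
    out = table.data.copy()
    out.insert(0, "#OTU ID", table.otu_ids)
    out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t", index=False)


def read_sample_metadata(path, site_aliases: dict[str, str] | None = None) -> SampleMetadata:
    """Read tab-delimited sample metadata, normalising body-site labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    if "site" in df.columns:
        df["site"] = [normalize_site(s, site_aliases) for s in df["site"]]
    for col in df.columns:
        if col not in METADATA_COLUMNS:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                pass
    return SampleMetadata(df)


def write_sample_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total; idempotent on relative tables."""
    if table.mode == "relative":
        return table.copy()
    sums = table.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total abundance: {list(zero.index)}")
    return AbundanceTable(table.data / sums, list(table.taxonomy), mode="relative")


def _lineage_key(lineage: str, depth: int) -> str:
    """Collapse key: lineage prefix through ``depth`` ranks, with a sentinel
    for OTUs unannotated at the target rank."""
    parts = [p.strip() for p in lineage.split(";")]
    parts += [""] * (depth - len(parts))
    prefix = parts[:depth]
    if prefix[-1] == "":
        parent = ";".join(p for p in prefix[:-1] if p != "")
        rank_name = RANKS[depth - 1]
        sentinel = f"unclassified at {rank_name}"
        return f"{parent};{sentinel}" if parent else sentinel
    return ";".join(prefix)


def collapse_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum OTUs sharing a lineage prefix through ``rank``.

    OTUs unannotated at ``rank`` are grouped under an
    ``unclassified at <rank>`` sentinel per parent lineage. Per-sample
    totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank) + 1
    keys = [_lineage_key(lineage, depth) for lineage in table.taxonomy]
    grouped = table.data.groupby(pd.Index(keys, name="lineage"), sort=True).sum()
    return AbundanceTable(grouped, list(grouped.index), mode=table.mode)


def align(table: AbundanceTable, metadata: SampleMetadata) -> tuple[AbundanceTable, SampleMetadata]:
    """Restrict the table and metadata to their shared sample IDs.

    Samples present in only one input are dropped (and logged). Order
    follows the table's sample order.
    """
    shared = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    if not shared:
        raise ValueError("no sample IDs shared between table and metadata")
    dropped_t = sorted(set(table.sample_ids) - set(shared))
    dropped_m = sorted(set(metadata.sample_ids) - set(shared))
    if dropped_t:
        logger.info("align: dropping %d table samples without metadata: %s",
                    len(dropped_t), dropped_t)
    if dropped_m:
        logger.info("align: dropping %d metadata rows without abundances: %s",
                    len(dropped_m), dropped_m)
    new_table = AbundanceTable(table.data[shared], list(table.taxonomy), table.mode)
    new_meta = SampleMetadata(metadata.data.loc[shared])
    return new_table, new_meta
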