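"""Detection of OTUs exchanged between two aerodigestive body sites.

The operational definition of microbial exchange: an OTU is "exchanged"
between two sites when its non-zero abundances in those sites are
positively partially correlated across patients, conditioning on the third
aerodigestive site. The statistic is the first-order partial Spearman
correlation

    (r_xy - r_xz r_zy) / sqrt((1 - r_xz^2)(1 - r_zy^2)),

its null distribution is obtained by shuffling the site-b abundances
across patients (2000 times by default, keeping x and z paired), and
Benjamini-Hochberg correction is applied within each site-pair family;
OTUs with q < 0.1 are flagged as exchanged. Only OTUs present in both
sites in at least 10 patients are tested, using patients with all three
aerodigestive sites sampled. A patient-ID shuffling calibration estimates
how many exchanged OTUs such a procedure finds when no exchange exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from aerodx.core_io import (
    AERODIGESTIVE_SITES,
    AbundanceTable,
    SampleMetadata,
    SitePair,
)

__all__ = [
    "ExchangeResult",
    "NullCalibration",
    "PrevalenceResult",
    "DifferentialPrevalence",
    "spearman_partial",
    "permutation_p",
    "detect_exchanged",
    "null_calibration",
    "cooccurrence_prevalence",
    "differential_prevalence",
    "results_table",
]


# ---------------------------------------------------------------------------
# Partial Spearman correlation and its permutation test
# ---------------------------------------------------------------------------

def _rank_unit(v: np.ndarray) -> np.ndarray | None:
    """Average ranks, centred and scaled to unit norm; None if constant."""
    r = stats.rankdata(v)
    r = r - r.mean()
    norm = np.sqrt((r**2).sum())
    if norm == 0:
        return None
    return r / norm


def spearman_partial(x, y, z) -> float:
    """First-order partial Spearman correlation of x and y given z.

    Ranks use average ranks on ties. A constant z is treated as carrying
    no information (its correlations are taken as 0, so the statistic
    reduces to the plain Spearman correlation of x and y). Returns NaN
    (the not-computable sentinel) when x or y is constant or when a
    denominator factor vanishes (|r_xz| = 1 or |r_zy| = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y, z must have equal lengths")
    if x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("need at least 3 paired observations")
    ux, uy, uz = _rank_unit(x), _rank_unit(y), _rank_unit(z)
    if ux is None or uy is None:
        return float("nan")
    r_xy = float(ux @ uy)
    if uz is None:
        r_xz = r_zy = 0.0
    else:
        r_xz = float(ux @ uz)
        r_zy = float(uz @ uy)
    denom = (1.0 - r_xz**2) * (1.0 - r_zy**2)
    if denom <= 0:
        return float("nan")
    return float((r_xy - r_xz * r_zy) / np.sqrt(denom))


def _null_partials(x, y, z, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """Partial correlations after permuting y, vectorised over permutations.

    x and z stay paired; rows where a denominator factor vanishes are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.shape[0]
    ux = _rank_unit(x)
    uz = _rank_unit(z)
    perms = rng.permuted(np.broadcast_to(y, (n_permutations, n)).copy(), axis=1)
    ranks = stats.rankdata(perms, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    uy = ranks / norms  # y constant is excluded upstream
    r_xy = uy @ ux
    if uz is None:
        r_xz = 0.0
        r_zy = np.zeros(n_permutations)
    else:
        r_xz = float(ux @ uz)
        r_zy = uy @ uz
    denom = (1.0 - r_xz**2) * (1.0 - r_zy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (r_xy - r_xz * r_zy) / np.sqrt(denom), np.nan)
    return out


def permutation_p(x, y, z, n_permutations: int = 2000, seed=None) -> float:
    """Permutation p-value for the partial Spearman statistic.

    y is permuted uniformly at random ``n_permutations`` times while x and
    z stay paired; the p-value is the fraction of null statistics strictly
    larger than the observed one (signed, upper tail), so p = 0 is
    attainable.
    """
    obs = spearman_partial(x, y, z)
    if np.isnan(obs):
        raise ValueError("observed partial correlation is not computable")
    rng = np.random.default_rng(seed)
    null = _null_partials(x, y, z, n_permutations, rng)
    return float(np.sum(null > obs) / n_permutations)


# ---------------------------------------------------------------------------
# Exchanged-OTU detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExchangeResult:
    """Per-OTU exchange test result for one site pair."""

    otu_id: str
    site_pair: SitePair
    n_patients: int
    partial_rho: float
    perm_p: float
    q_value: float
    exchanged: bool


@dataclass(frozen=True)
class NullCalibration:
    """Exchanged-OTU counts under patient-ID shuffling."""

    n_rounds: int
    counts: tuple[int, ...]

    @property
    def max_count(self) -> int:
        return max(self.counts)

    @property
    def median_count(self) -> float:
        return float(np.median(self.counts))


def _site_matrices(
    table: AbundanceTable, metadata: SampleMetadata, sites, patients
) -> dict[str, pd.DataFrame]:
    """Per-site patient x OTU abundance matrices over a fixed patient set."""
    mats = {}
    for site in sites:
        samples = [metadata.sample_for(p, site) for p in patients]
        mats[site] = pd.DataFrame(
            table.data[samples].to_numpy(dtype=float).T,
            index=patients,
            columns=table.otu_ids,
        )
    return mats


def _detect_core(
    mats: dict[str, pd.DataFrame],
    site_pair: SitePair,
    min_patients: int,
    n_permutations: int,
    q_threshold: float,
    seed,
) -> list[ExchangeResult]:
    A = mats[site_pair.site_a].to_numpy()
    B = mats[site_pair.site_b].to_numpy()
    Z = mats[site_pair.partial_site].to_numpy()
    otu_ids = list(mats[site_pair.site_a].columns)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(otu_ids))
    tested: list[tuple[str, int, float, float]] = []
    for k, otu in enumerate(otu_ids):
        xa, xb = A[:, k], B[:, k]
        mask = (xa > 0) & (xb > 0)
        n_pat = int(mask.sum())
        if n_pat < min_patients:
            continue
        x, y, z = xa[mask], xb[mask], Z[mask, k]
        rho = spearman_partial(x, y, z)
        if np.isnan(rho):
            continue  # not computable; excluded from the BH family
        rng = np.random.default_rng(children[k])
        null = _null_partials(x, y, z, n_permutations, rng)
        p = float(np.sum(null > rho) / n_permutations)
        tested.append((otu, n_pat, rho, p))
    if not tested:
        return []
    pvals = np.array([t[3] for t in tested])
    reject, qvals, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    return [
        ExchangeResult(otu, site_pair, n_pat, rho, p, float(q), bool(q < q_threshold))
        for (otu, n_pat, rho, p), q in zip(tested, qvals)
    ]


def detect_exchanged(
    table: AbundanceTable,
    metadata: SampleMetadata,
    site_pair: SitePair,
    min_patients: int = 10,
    n_permutations: int = 2000,
    q_threshold: float = 0.1,
    seed=None,
) -> list[ExchangeResult]:
    """Detect OTUs exchanged between the two sites of ``site_pair``.

    Uses patients with all three aerodigestive sites sampled. For each
    OTU, patients with non-zero relative abundance in both pair sites form
    the test set (their third-site abundances, zeros retained, are the
    conditioning vector); OTUs with fewer than ``min_patients`` such
    patients are excluded from testing and from the BH family, which is
    corrected within this site pair only.

    Returns one :class:`ExchangeResult` per tested OTU (empty list when no
    OTU meets the prevalence filter).
    """
    if table.mode != "relative":
        raise ValueError("detect_exchanged requires a relative-mode table")
    patients = metadata.patients_with_sites(AERODIGESTIVE_SITES)
    patients = [
        p
        for p in patients
        if all(
            metadata.sample_for(p, s) in set(table.sample_ids)
            for s in AERODIGESTIVE_SITES
        )
    ]
    if len(patients) < min_patients:
        raise ValueError(
            f"only {len(patients)} patients have all three aerodigestive "
            f"sites; need at least {min_patients}"
        )
    mats = _site_matrices(table, metadata, AERODIGESTIVE_SITES, patients)
    return _detect_core(mats, site_pair, min_patients, n_permutations, q_threshold, seed)


def null_calibration(
    table: AbundanceTable,
    metadata: SampleMetadata,
    site_pair: SitePair,
    n_rounds: int = 10,
    min_patients: int = 10,
    n_permutations: int = 2000,
    q_threshold: float = 0.1,
    seed=None,
) -> NullCalibration:
    """Exchanged-OTU counts after shuffling patient IDs per OTU per site.

    Each round independently permutes every OTU's abundances across
    patients within each site (destroying all within-patient structure)
    and re-runs the full detection; the per-round exchanged counts and
    their maximum calibrate how many detections arise by chance.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if table.mode != "relative":
        raise ValueError("null_calibration requires a relative-mode table")
    patients = metadata.patients_with_sites(AERODIGESTIVE_SITES)
    patients = [
        p
        for p in patients
        if all(
            metadata.sample_for(p, s) in set(table.sample_ids)
            for s in AERODIGESTIVE_SITES
        )
    ]
    if len(patients) < min_patients:
        raise ValueError("too few triple-site patients for null calibration")
    mats = _site_matrices(table, metadata, AERODIGESTIVE_SITES, patients)
    top = np.random.SeedSequence(seed)
    shuffle_ss, detect_ss = top.spawn(2)
    shuffle_rngs = [np.random.default_rng(s) for s in shuffle_ss.spawn(n_rounds)]
    detect_seeds = detect_ss.spawn(n_rounds)
    counts = []
    for r in range(n_rounds):
        rng = shuffle_rngs[r]
        shuffled = {
            site: pd.DataFrame(
                rng.permuted(df.to_numpy(), axis=0),
                index=df.index,
                columns=df.columns,
            )
            for site, df in mats.items()
        }
        results = _detect_core(
            shuffled, site_pair, min_patients, n_permutations, q_threshold,
            detect_seeds[r],
        )
        counts.append(sum(res.exchanged for res in results))
    return NullCalibration(n_rounds=n_rounds, counts=tuple(counts))


# ---------------------------------------------------------------------------
# Co-occurrence prevalence of exchanged OTUs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrevalenceResult:
    """Per-OTU co-occurrence prevalence (%) within one patient group.

    Prevalence of an OTU is the percentage of the group's patients (those
    with both pair sites sampled) harbouring it in both sites.
    """

    prevalence: pd.Series  # index: OTU ID, values: percent
    n_patients: int
    group: str
    site_pair: SitePair


@dataclass(frozen=True)
class DifferentialPrevalence:
    """Per-OTU prevalence difference between two groups plus a paired test.

    The paired t-test is computed on log10 prevalences, with any zero
    prevalence replaced by the half-patient pseudo-prevalence
    100 * 0.5 / n_group.
    """

    per_otu: pd.DataFrame  # columns: group1, group2, difference
    t_statistic: float
    p_value: float


def cooccurrence_prevalence(
    table: AbundanceTable,
    metadata: SampleMetadata,
    exchanged_otus,
    site_pair: SitePair,
    group: str,
) -> PrevalenceResult:
    """Co-occurrence prevalence of each exchanged OTU in one group.

    100 x (# group patients with abundance > 0 in both sites) /
    (# group patients with both sites sampled).
    """
    otus = list(exchanged_otus)
    missing = [o for o in otus if o not in set(table.otu_ids)]
    if missing:
        raise ValueError(f"OTUs absent from table: {missing}")
    sample_set = set(table.sample_ids)
    patients = [
        p
        for p in metadata.patients_with_sites(site_pair.sites)
        if metadata.patient_status(p) == group
        and all(metadata.sample_for(p, s) in sample_set for s in site_pair.sites)
    ]
    if not patients:
        raise ValueError(f"no patients with both sites in group {group!r}")
    mats = _site_matrices(table, metadata, site_pair.sites, patients)
    a = mats[site_pair.site_a][otus].to_numpy() > 0
    b = mats[site_pair.site_b][otus].to_numpy() > 0
    co = (a & b).sum(axis=0)
    prev = pd.Series(100.0 * co / len(patients), index=otus)
    return PrevalenceResult(prev, len(patients), group, site_pair)


def differential_prevalence(
    prev_group1: PrevalenceResult, prev_group2: PrevalenceResult
) -> DifferentialPrevalence:
    """Per-OTU prevalence difference (group2 - group1, percentage points)
    and a paired t-test on log10 prevalences."""
    p1, p2 = prev_group1.prevalence, prev_group2.prevalence
    if list(p1.index) != list(p2.index):
        raise ValueError("prevalence results cover different OTU sets")
    diff = p2 - p1
    floor1 = 100.0 * 0.5 / prev_group1.n_patients
    floor2 = 100.0 * 0.5 / prev_group2.n_patients
    l1 = np.log10(p1.replace(0.0, floor1).to_numpy())
    l2 = np.log10(p2.replace(0.0, floor2).to_numpy())
    if np.allclose(l1, l2):
        t_stat, p_val = 0.0, 1.0  # degenerate: no paired differences
    else:
        t_stat, p_val = stats.ttest_rel(l2, l1)
    per_otu = pd.DataFrame(
        {
            prev_group1.group: p1,
            prev_group2.group: p2,
            "difference": diff,
        }
    )
    return DifferentialPrevalence(per_otu, float(t_stat), float(p_val))


def results_table(results: list[ExchangeResult], table: AbundanceTable | None = None) -> pd.DataFrame:
    """Tabulate exchange results, appending family/genus taxonomy when the
    source table is given (family = rank 5, genus = rank 6 of the lineage)."""
    rows = []
    tax = {}
    if table is not None:
        tax = dict(zip(table.otu_ids, table.taxonomy))
    for r in results:
        row = {
            "otu_id": r.otu_id,
            "site_pair": str(r.site_pair),
            "n_patients": r.n_patients,
            "partial_rho": r.partial_rho,
            "perm_p": r.perm_p,
            "q_value": r.q_value,
            "exchanged": r.exchanged,
        }
        if tax:
            parts = [p.strip() for p in tax.get(r.otu_id, "").split(";")]
            parts += [""] * (6 - len(parts))
            row["family"] = parts[4]
            row["genus"] = parts[5]
        rows.append(row)
    return pd.DataFrame(rows)
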