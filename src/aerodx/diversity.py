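"""Alpha and beta diversity, PERMANOVA, and within- vs. across-patient
community comparisons.

Beta diversity centres on the Jensen-Shannon distance (JSD): the square
root of the Jensen-Shannon divergence with base-2 logarithms, so that the
distance is a metric bounded in [0, 1] — values near 1 mean two
communities are very different. Bray-Curtis is provided as an alternative
metric. Cross-patient comparisons are restricted to samples sequenced in
the same batch; within-patient comparisons are not batch-restricted
because each patient's samples share a batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import rel_entr
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova

from aerodx.core_io import AbundanceTable, SampleMetadata, SitePair

_LN2 = np.log(2.0)


def _check_prob_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector")
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} does not sum to 1 (sum={p.sum():.8g})")
    return p


def jensen_shannon_distance(p, q) -> float:
    """Jensen-Shannon distance between two relative-abundance profiles.

    sqrt(0.5 KL(p || m) + 0.5 KL(q || m)) with m = (p + q)/2 and base-2
    logarithms; 0 log 0 is treated as 0. The result lies in [0, 1].
    """
    p = _check_prob_vector(p, "p")
    q = _check_prob_vector(q, "q")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    m = 0.5 * (p + q)
    # rel_entr(x, y) = x ln(x/y) with the 0 log 0 = 0 convention
    div = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / _LN2
    return float(np.sqrt(max(div, 0.0)))


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity: sum|p_i - q_i| / sum(p_i + q_i)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    total = (p + q).sum()
    if total == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(p - q).sum() / total)


def pairwise_distances(table: AbundanceTable, metric: str = "jsd") -> DistanceMatrix:
    """All-pairs beta-diversity matrix over the table's samples.

    Requires a relative-mode table; returns a scikit-bio DistanceMatrix
    keyed by sample ID.
    """
    if table.mode != "relative":
        raise ValueError(
            "pairwise_distances requires a relative-mode table; "
            "call to_relative_abundance first"
        )
    if metric not in ("jsd", "braycurtis"):
        raise ValueError(f"unknown metric {metric!r}")
    X = table.values  # OTUs x samples
    n = X.shape[1]
    out = np.zeros((n, n))
    if metric == "jsd":
        # JS divergence via entropies: D(p,q) = H(m) - (H(p)+H(q))/2 (bits)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(X > 0, X * np.log2(X), 0.0), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            for i in range(n):
                for j in range(i + 1, n):
                    m = 0.5 * (X[:, i] + X[:, j])
                    hm = -np.sum(np.where(m > 0, m * np.log2(m), 0.0))
                    div = hm - 0.5 * (ent[i] + ent[j])
                    out[i, j] = out[j, i] = np.sqrt(max(div, 0.0))
    else:
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis(X[:, i], X[:, j])
    return DistanceMatrix(out, ids=table.sample_ids)


def alpha_diversity(counts, metric: str = "shannon") -> float:
    """Alpha diversity of one sample's raw OTU counts.

    shannon: -sum f_i log2 f_i (bits); chao1: S_obs + F1^2 / (2 F2), with
    the F1(F1-1)/2 correction when F2 = 0; simpson: 1 - sum f_i^2
    (Gini-Simpson).
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.allclose(c, np.round(c)):
        raise ValueError("counts must be integers")
    total = c.sum()
    if total == 0:
        raise ValueError("zero total count")
    f = c[c > 0] / total
    if metric == "shannon":
        return float(-(f * np.log2(f)).sum())
    if metric == "simpson":
        return float(1.0 - (f**2).sum())
    if metric == "chao1":
        s_obs = int((c > 0).sum())
        f1 = int((c == 1).sum())
        f2 = int((c == 2).sum())
        if f2 > 0:
            return float(s_obs + f1**2 / (2 * f2))
        return float(s_obs + f1 * (f1 - 1) / 2)
    raise ValueError(f"unknown alpha-diversity metric {metric!r}")


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999, seed=None):
    """PERMANOVA pseudo-F and permutation p-value on a distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_permutations).
    Requires at least two groups, each with at least two samples.
    """
    labels = pd.Series(list(grouping), index=dm.ids)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    singletons = counts[counts < 2]
    if len(singletons):
        raise ValueError(f"singleton group(s): {list(singletons.index)}")
    res = _skbio_permanova(
        dm, labels.to_numpy(), permutations=n_permutations, seed=seed
    )
    return float(res["test statistic"]), float(res["p-value"])


# ---------------------------------------------------------------------------
# Within- vs. across-patient machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedDistanceRecord:
    """Per-patient within-pair distance and same-site across-patient means.

    ``across_mean_a`` (resp. ``_b``) is the mean distance from this
    patient's site-a (site-b) sample to all other patients' samples of the
    same site within the same sequencing batch.
    """

    patient_id: str
    site_pair: SitePair
    within: float
    across_mean_a: float
    across_mean_b: float


def within_patient_distances(
    dm: DistanceMatrix, metadata: SampleMetadata, site_pair: SitePair
) -> list[tuple[str, float]]:
    """Distance between each patient's two site samples.

    Patients missing either site (or either sample from the distance
    matrix) are skipped.
    """
    ids = set(dm.ids)
    out = []
    for patient in metadata.patients_with_sites(site_pair.sites):
        sa = metadata.sample_for(patient, site_pair.site_a)
        sb = metadata.sample_for(patient, site_pair.site_b)
        if sa in ids and sb in ids:
            out.append((patient, float(dm[sa, sb])))
    return out


def across_patient_distances(
    dm: DistanceMatrix, metadata: SampleMetadata, site: str
) -> list[float]:
    """Distances between distinct patients' samples of one site,
    restricted to pairs sequenced in the same batch."""
    rows = metadata.samples_of_site(site)
    rows = rows[rows.index.isin(set(dm.ids))]
    samples = list(rows.index)
    out = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            ri, rj = rows.loc[samples[i]], rows.loc[samples[j]]
            if ri["patient_id"] == rj["patient_id"]:
                continue
            if ri["batch"] != rj["batch"]:
                continue
            out.append(float(dm[samples[i], samples[j]]))
    return out


def _across_mean(dm, metadata, patient, site):
    """Mean distance from one patient's site sample to all other patients'
    same-site, same-batch samples; NaN if no eligible peer exists."""
    own = metadata.sample_for(patient, site)
    rows = metadata.samples_of_site(site)
    rows = rows[rows.index.isin(set(dm.ids))]
    batch = metadata.data.loc[own, "batch"]
    peers = rows[(rows["patient_id"] != patient) & (rows["batch"] == batch)]
    if peers.empty or own not in set(dm.ids):
        return float("nan")
    return float(np.mean([dm[own, s] for s in peers.index]))


def within_vs_across(
    dm: DistanceMatrix, metadata: SampleMetadata, site_pair: SitePair
) -> tuple[list[PairedDistanceRecord], float, float]:
    """Compare within-patient cross-site distances with each patient's
    average same-site across-patient distance.

    Returns one record per patient having both sites, plus the two
    Wilcoxon signed-rank p-values (within vs. across site-a means, and
    within vs. across site-b means), paired over patients. When every
    paired difference is zero the test is degenerate and NaN is returned
    for that p-value.
    """
    within = within_patient_distances(dm, metadata, site_pair)
    records = []
    for patient, w in within:
        ma = _across_mean(dm, metadata, patient, site_pair.site_a)
        mb = _across_mean(dm, metadata, patient, site_pair.site_b)
        if np.isnan(ma) or np.isnan(mb):
            continue
        records.append(PairedDistanceRecord(patient, site_pair, w, ma, mb))
    if len(records) < 6:
        raise ValueError(
            f"within_vs_across needs >= 6 patients with both sites; "
            f"got {len(records)}"
        )
    w = np.array([r.within for r in records])
    a = np.array([r.across_mean_a for r in records])
    b = np.array([r.across_mean_b for r in records])

    def _signed_rank(x, y):
        if np.allclose(x, y):
            return float("nan")  # tie-degenerate
        return float(stats.wilcoxon(x, y).pvalue)

    return records, _signed_rank(w, a), _signed_rank(w, b)
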