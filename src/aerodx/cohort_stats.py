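"""Group-level statistics: aspirator vs. non-aspirator contrasts of
within-patient beta diversity, alpha-diversity comparisons, Kruskal-Wallis
differential abundance with BH correction, and reflux-distance Spearman
correlations.

Aspiration grouping merges aspiration and penetration into a single
"aspirator" class; patients with untested status are excluded from
aspiration contrasts, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from aerodx.core_io import AbundanceTable, SampleMetadata, SitePair, collapse_to_rank
from aerodx.diversity import alpha_diversity, within_patient_distances


@dataclass
class GroupComparison:
    """One statistical comparison between (or across) patient groups."""

    unit: str  # site, site pair, taxon, or covariate name
    statistic_name: str
    statistic_value: float
    p_value: float
    q_value: float | None = None
    group_summaries: dict = field(default_factory=dict)  # group -> {median, n}


def _grouped_patients(metadata: SampleMetadata, patients, grouping: str):
    """Split patients by group label, dropping untested aspiration status."""
    groups: dict[str, list[str]] = {}
    for p in patients:
        if grouping == "aspiration_status":
            label = metadata.patient_status(p)
            if label == "untested":
                continue
        else:
            vals = set(metadata.data.loc[metadata.data["patient_id"] == p, grouping])
            if len(vals) != 1:
                raise ValueError(f"inconsistent {grouping!r} for patient {p!r}")
            label = vals.pop()
        groups.setdefault(str(label), []).append(p)
    return groups


def compare_within_patient_jsd(
    dm,
    metadata: SampleMetadata,
    site_pair: SitePair,
    grouping: str = "aspiration_status",
) -> GroupComparison:
    """Wilcoxon rank-sum on within-patient cross-site distances by group."""
    within = dict(within_patient_distances(dm, metadata, site_pair))
    groups = _grouped_patients(metadata, list(within), grouping)
    groups = {g: [within[p] for p in ps] for g, ps in groups.items()}
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(groups)}")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 eligible patients: {small}")
    (ga, va), (gb, vb) = sorted(groups.items())
    stat, p = stats.ranksums(va, vb)
    return GroupComparison(
        unit=str(site_pair),
        statistic_name="wilcoxon_ranksum",
        statistic_value=float(stat),
        p_value=float(p),
        group_summaries={
            ga: {"median": float(np.median(va)), "n": len(va)},
            gb: {"median": float(np.median(vb)), "n": len(vb)},
        },
    )


def compare_alpha(
    table: AbundanceTable,
    metadata: SampleMetadata,
    site: str,
    metric: str = "shannon",
    grouping: str = "aspiration_status",
) -> GroupComparison:
    """Rank-sum comparison of per-sample alpha diversity within one site."""
    if table.mode != "counts":
        raise ValueError("alpha diversity is computed on raw counts")
    rows = metadata.samples_of_site(site)
    rows = rows[rows.index.isin(set(table.sample_ids))]
    if rows.empty:
        raise ValueError(f"no samples for site {site!r}")
    values: dict[str, list[float]] = {}
    for sample_id, row in rows.iterrows():
        if grouping == "aspiration_status":
            label = row["aspiration_status"]
            if label == "untested":
                continue
        else:
            label = row[grouping]
        values.setdefault(str(label), []).append(
            alpha_diversity(table.sample(sample_id), metric)
        )
    if len(values) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(values)}")
    small = [g for g, v in values.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 samples: {small}")
    (ga, va), (gb, vb) = sorted(values.items())
    stat, p = stats.ranksums(va, vb)
    return GroupComparison(
        unit=f"{site}:{metric}",
        statistic_name="wilcoxon_ranksum",
        statistic_value=float(stat),
        p_value=float(p),
        group_summaries={
            ga: {"median": float(np.median(va)), "n": len(va)},
            gb: {"median": float(np.median(vb)), "n": len(vb)},
        },
    )


def differential_abundance(
    table: AbundanceTable,
    metadata: SampleMetadata,
    site: str,
    rank: str | None = None,
    grouping: str = "aspiration_status",
    q_threshold: float = 0.1,
) -> list[GroupComparison]:
    """Per-taxon Kruskal-Wallis tests on relative abundances within a site.

    Optionally collapses to a taxonomic rank first. Taxa constant across
    all of the site's samples are excluded. BH q-values are computed
    within this (site, rank) family only, mirroring per-site, per-level
    correction.
    """
    if table.mode != "relative":
        raise ValueError("differential abundance uses relative abundances")
    if rank is not None:
        table = collapse_to_rank(table, rank)
    rows = metadata.samples_of_site(site)
    rows = rows[rows.index.isin(set(table.sample_ids))]
    sample_groups: dict[str, list[str]] = {}
    for sample_id, row in rows.iterrows():
        if grouping == "aspiration_status":
            label = row["aspiration_status"]
            if label == "untested":
                continue
        else:
            label = row[grouping]
        sample_groups.setdefault(str(label), []).append(sample_id)
    if len(sample_groups) < 2:
        raise ValueError("differential abundance needs at least 2 groups")
    group_names = sorted(sample_groups)
    sub = {g: table.data[sample_groups[g]].to_numpy() for g in group_names}
    comparisons = []
    pvals = []
    for i, taxon in enumerate(table.otu_ids):
        vectors = [sub[g][i] for g in group_names]
        pooled = np.concatenate(vectors)
        if np.all(pooled == pooled[0]):
            continue  # constant taxon: excluded
        stat, p = stats.kruskal(*vectors)
        comparisons.append(
            GroupComparison(
                unit=taxon,
                statistic_name="kruskal_wallis",
                statistic_value=float(stat),
                p_value=float(p),
                group_summaries={
                    g: {"median": float(np.median(sub[g][i])), "n": sub[g].shape[1]}
                    for g in group_names
                },
            )
        )
        pvals.append(p)
    if comparisons:
        _, qvals, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
        for comp, q in zip(comparisons, qvals):
            comp.q_value = float(q)
    return comparisons


def reflux_correlation(
    dm,
    metadata: SampleMetadata,
    covariate: str,
    site_pair: SitePair | None = None,
) -> GroupComparison:
    """Spearman correlation between a per-patient covariate (e.g. a reflux
    measure) and the within-patient distance for a site pair
    (lung-gastric by default)."""
    if site_pair is None:
        site_pair = SitePair("lung", "gastric")
    if covariate not in metadata.data.columns:
        raise ValueError(f"covariate {covariate!r} not in metadata")
    within = dict(within_patient_distances(dm, metadata, site_pair))
    xs, ys = [], []
    for patient, d in within.items():
        vals = metadata.data.loc[
            metadata.data["patient_id"] == patient, covariate
        ].dropna()
        if vals.empty:
            continue
        xs.append(float(vals.iloc[0]))
        ys.append(d)
    if len(xs) < 5:
        raise ValueError(
            f"reflux correlation needs >= 5 patients with both sites and "
            f"a {covariate!r} value; got {len(xs)}"
        )
    rho, p = stats.spearmanr(xs, ys)
    return GroupComparison(
        unit=f"{covariate} vs {site_pair}",
        statistic_name="spearman",
        statistic_value=float(rho),
        p_value=float(p),
        group_summaries={"all": {"median": float(np.median(ys)), "n": len(ys)}},
    )
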