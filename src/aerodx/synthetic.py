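"""Synthetic multi-site cohort generator with planted ground truth.

The generator emulates the statistical structure the analyses assume,
without attempting realistic taxonomies or read sequences:

- a single shared, sparse "core" oropharyngeal community: every patient's
  oropharynx is a Dirichlet draw around the same base, so oropharyngeal
  communities are conserved across people;
- person-specific lung and gastric communities: each patient has an
  independent sparse personal base per site, so lungs (and stomachs)
  differ strongly across people, and — outside the planted exchange and
  the aspiration effect — the sites are mutually independent given their
  bases (the property the null calibration of the exchange detector
  relies on);
- planted exchanged OTUs: for designated OTUs and site pairs, the two
  sites' latent abundances follow a shared lognormal with the recipient
  site's log-abundance equal to the source site's plus Gaussian noise;
  the noise variance is set from the bivariate-normal identity
  rho_s = (6/pi) arcsin(r/2) so the within-patient Spearman correlation
  targets ``exchange_strength``. The recipient site (the first of the
  pair: lung for lung-oropharynx and lung-gastric, gastric for
  gastric-oropharynx, matching the aspiration/reflux/swallowing
  directions) carries a reduced share of the source's abundance, so its
  presence is partial — the substrate of the co-occurrence contrasts;
- an aspiration effect: each aspirator's lung latent composition is a
  convex mixture of their own oropharynx (weight ``aspiration_mixing``)
  and their lung latent;
- multinomial read sampling at ``sequencing_depth`` with an extra
  per-entry dropout probability, and round-robin batch assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from aerodx.core_io import (
    AERODIGESTIVE_SITES,
    AbundanceTable,
    SampleMetadata,
)

#: Canonical aerodigestive site pairs, in reporting order.
SITE_PAIRS: tuple[tuple[str, str], ...] = (
    ("lung", "oropharynx"),
    ("lung", "gastric"),
    ("gastric", "oropharynx"),
)

_EPS = 1e-12


@dataclass
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the study scale: 66 patients with all three
    aerodigestive sites, ~25 aspirators and ~23 non-aspirators among
    labelled patients (the rest untested), 200 OTUs, 10,000 reads per
    sample, two sequencing batches.
    """

    n_patients: int = 66
    fraction_aspirators: float = 25 / 66
    fraction_untested: float = 18 / 66
    n_otus: int = 200
    #: planted exchanged OTUs per site pair; an int applies to every pair
    n_exchanged: int | dict = 20
    #: Dirichlet concentration around the shared oropharyngeal core
    #: (high -> conserved across people)
    core_concentration: float = 100.0
    #: total concentration of the sparse patient-specific base
    #: (low -> bases very different across people)
    person_concentration: float = 15.0
    #: concentration of a patient's lung/gastric draws around their base
    within_person_concentration: float = 50.0
    #: Dirichlet shape of the shared core base (low -> sparse core)
    base_sparsity: float = 0.5
    #: target within-patient Spearman correlation of planted OTUs
    exchange_strength: float = 0.8
    #: median latent relative abundance of a planted OTU in its source site
    exchange_abundance: float = 1e-3
    #: recipient-site share of the source abundance (partial carryover)
    exchange_carryover: float = 0.15
    #: lognormal sigma of planted OTU abundances across patients
    exchange_spread: float = 1.2
    #: fraction of an aspirator's lung drawn from their oropharynx
    aspiration_mixing: float = 0.6
    sequencing_depth: int = 10_000
    #: probability that a sampled entry is zeroed beyond multinomial noise
    dropout: float = 0.05
    n_batches: int = 2
    seed: int | None = None

    def exchanged_per_pair(self) -> dict[tuple[str, str], int]:
        if isinstance(self.n_exchanged, dict):
            out = {tuple(k): int(v) for k, v in self.n_exchanged.items()}
            bad = set(out) - set(SITE_PAIRS)
            if bad:
                raise ValueError(f"n_exchanged: unknown site pair(s) {sorted(bad)}")
            return {pair: out.get(pair, 0) for pair in SITE_PAIRS}
        return {pair: int(self.n_exchanged) for pair in SITE_PAIRS}

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if self.n_otus < 1:
            raise ValueError("n_otus must be positive")
        for name in ("fraction_aspirators", "fraction_untested", "exchange_strength",
                     "aspiration_mixing", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fraction_aspirators + self.fraction_untested > 1.0:
            raise ValueError("fraction_aspirators + fraction_untested exceeds 1")
        total_exchanged = sum(self.exchanged_per_pair().values())
        if total_exchanged > self.n_otus:
            raise ValueError(
                f"n_exchanged totals {total_exchanged} > n_otus {self.n_otus}"
            )
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        if not 0.0 < self.exchange_carryover <= 1.0:
            raise ValueError("exchange_carryover must lie in (0, 1]")
        for name in ("core_concentration", "person_concentration",
                     "within_person_concentration", "base_sparsity",
                     "exchange_abundance", "exchange_spread"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    spec: SyntheticCohortSpec
    exchanged_otu_ids: dict[tuple[str, str], tuple[str, ...]]
    mixing: dict[str, float]  # patient -> lung<-oropharynx mixing weight
    latent: dict[str, pd.DataFrame] = field(repr=False)  # site -> patients x OTUs


def _normalize_rows(w: np.ndarray) -> np.ndarray:
    sums = w.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return w / sums


def _synthetic_taxonomy(n_otus: int, rng: np.random.Generator) -> list[str]:
    """Simple nested lineages; ~10% of OTUs unannotated at genus."""
    lineages = []
    for j in range(n_otus):
        phylum = f"Phylum{j % 5}"
        family = f"Family{j % 20}"
        genus = "" if rng.random() < 0.1 else f"Genus{j % 40}"
        lineages.append(
            f"Bacteria;{phylum};Class{j % 8};Order{j % 12};{family};{genus}"
        )
    return lineages


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Generate a counts table, metadata, and ground truth from ``spec``.

    Every patient has all three aerodigestive sites sampled. All
    randomness flows from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_patients, spec.n_otus
    patients = [f"P{i + 1:03d}" for i in range(n)]
    otu_ids = [f"OTU_{j + 1:04d}" for j in range(k)]
    taxonomy = _synthetic_taxonomy(k, rng)

    # Latent compositions -------------------------------------------------
    core_base = rng.dirichlet(np.full(k, spec.base_sparsity)) + _EPS
    oroph = rng.dirichlet(spec.core_concentration * core_base, size=n)
    weights = {"oropharynx": oroph}
    for site in ("lung", "gastric"):
        # independent sparse personal base per patient and site
        base = _normalize_rows(
            rng.gamma(np.full((n, k), spec.person_concentration / k) + _EPS)
        )
        weights[site] = _normalize_rows(
            rng.gamma(spec.within_person_concentration * base + _EPS)
        )

    # Planted exchanged OTUs ----------------------------------------------
    per_pair = spec.exchanged_per_pair()
    order = rng.permutation(k)
    exchanged_ids: dict[tuple[str, str], tuple[str, ...]] = {}
    cursor = 0
    rho = spec.exchange_strength
    for pair in SITE_PAIRS:
        m = per_pair[pair]
        idx = order[cursor : cursor + m]
        cursor += m
        exchanged_ids[pair] = tuple(otu_ids[j] for j in idx) if rho > 0 else ()
        recipient, source = pair
        for j in idx:
            u = rng.normal(0.0, spec.exchange_spread, size=n)
            if rho > 0:
                r = 2.0 * np.sin(np.pi * rho / 6.0)
                sigma = spec.exchange_spread * np.sqrt(max(1.0 / r**2 - 1.0, 0.0))
                v = u + rng.normal(0.0, sigma, size=n)
            else:
                v = rng.normal(0.0, spec.exchange_spread, size=n)
            weights[source][:, j] = spec.exchange_abundance * np.exp(u)
            weights[recipient][:, j] = (
                spec.exchange_carryover * spec.exchange_abundance * np.exp(v)
            )
    compositions = {s: _normalize_rows(w) for s, w in weights.items()}

    # Aspiration statuses and lung<-oropharynx mixing ----------------------
    n_asp = int(round(spec.fraction_aspirators * n))
    n_unt = int(round(spec.fraction_untested * n))
    statuses = (
        ["aspirator"] * n_asp
        + ["untested"] * n_unt
        + ["non_aspirator"] * (n - n_asp - n_unt)
    )
    statuses = list(rng.permutation(statuses))
    mixing = {
        p: (spec.aspiration_mixing if s == "aspirator" else 0.0)
        for p, s in zip(patients, statuses)
    }
    m_vec = np.array([mixing[p] for p in patients])[:, None]
    compositions["lung"] = (
        (1.0 - m_vec) * compositions["lung"] + m_vec * compositions["oropharynx"]
    )

    # Read sampling --------------------------------------------------------
    columns = {}
    meta_rows = []
    for i, patient in enumerate(patients):
        batch = f"B{i % spec.n_batches + 1}"
        for site in AERODIGESTIVE_SITES:
            sample_id = f"{patient}-{site}"
            counts = rng.multinomial(spec.sequencing_depth, compositions[site][i])
            if spec.dropout > 0:
                counts = np.where(rng.random(k) < spec.dropout, 0, counts)
            columns[sample_id] = counts
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "patient_id": patient,
                    "site": site,
                    "batch": batch,
                    "aspiration_status": statuses[i],
                }
            )
    table = AbundanceTable(
        pd.DataFrame(columns, index=otu_ids), taxonomy, mode="counts"
    )
    metadata = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = SyntheticTruth(
        spec=spec,
        exchanged_otu_ids=exchanged_ids,
        mixing=mixing,
        latent={
            s: pd.DataFrame(c, index=patients, columns=otu_ids)
            for s, c in compositions.items()
        },
    )
    return table, metadata, truth


def null_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Generate a cohort with no exchange and no aspiration effect.

    All sites are independent given the per-site bases; used for null
    calibration of the exchange detector and type-I-error suites.
    """
    import dataclasses

    null_spec = dataclasses.replace(spec, exchange_strength=0.0, aspiration_mixing=0.0)
    return generate_cohort(null_spec)


ASPIRATION_ORDER = ("non_aspirator", "aspirator", "untested")


def summarize_cohort(table: AbundanceTable | None, metadata: SampleMetadata) -> pd.DataFrame:
    """Patients per body-site combination, split by aspiration status.

    When a table is given, only samples present in it count. Mirrors the
    usual cohort-description layout (one row per site combination).
    """
    df = metadata.data
    if table is not None:
        df = df[df.index.isin(set(table.sample_ids))]
    if df.empty:
        return pd.DataFrame(
            columns=["site_combination", *ASPIRATION_ORDER, "total"]
        ).set_index("site_combination")
    combos = df.groupby("patient_id").agg(
        sites=("site", lambda s: " + ".join(sorted(set(s)))),
        status=("aspiration_status", "first"),
    )
    counts = (
        combos.groupby(["sites", "status"]).size().unstack(fill_value=0)
    )
    for status in ASPIRATION_ORDER:
        if status not in counts.columns:
            counts[status] = 0
    counts = counts[list(ASPIRATION_ORDER)]
    counts["total"] = counts.sum(axis=1)
    counts.index.name = "site_combination"
    return counts
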