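"""Synthetic multiplex-family cohorts with the structure the method assumes.

The generator emulates the study design the screen was built for: ~25
multi-generational families ascertained for multiple breast cancer cases,
~210 members with methylation data, and per-site M-values that are bimodal
conditional on carrier status.  Site presets mirror the methylation modes
seen on the 450K array — hypomethylated (β ≈ 0.1, M ≈ −3), hemimethylated
(β ≈ 0.5, M ≈ 0) and hypermethylated (β ≈ 0.9, M ≈ 3) — with a
carrier/non-carrier mean separation of 3 M-units and within-group SD 0.3.

Three site kinds are contrasted:

* ``mendelian`` — group membership is a variant dropped through the
  pedigree (one carrier founder at most, transmission probability 1/2);
* ``mixture``   — membership iid Bernoulli(α₁), ignoring family structure,
  with the same marginal frequency;
* ``gaussian``  — a single component.

Separate random streams drive pedigree structure, variant drops,
methylation noise, and phenotypes, so each can be varied with the others
held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .methylation import MethylationMatrix
from .pedigree import Individual, Pedigree, PhenotypeRecord, write_pedigrees
from .segregation import enumerate_founder_configs

__all__ = [
    "SiteSpec",
    "HazardConfig",
    "SimulationConfig",
    "SimulatedCohort",
    "default_sites",
    "simulate_pedigree_set",
    "drop_variant",
    "simulate_site",
    "simulate_phenotypes",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SiteSpec:
    """Generative description of one probe."""

    kind: str  # mendelian | mixture | gaussian
    mu0: float = -3.0
    mu1: float = 0.0
    sigma0: float = 0.3
    sigma1: float = 0.3

    def __post_init__(self) -> None:
        if self.kind not in ("mendelian", "mixture", "gaussian"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigmas must be positive")


@dataclass(frozen=True)
class HazardConfig:
    """Weibull baseline hazard for age at onset plus a carrier hazard ratio.

    Defaults give a cumulative female risk of ~16% by age 80 — high for a
    general population but appropriate for the familial setting the
    rejection sampler must reach (multiple affected members per family).
    """

    weibull_shape: float = 4.5
    weibull_scale: float = 120.0
    hazard_ratio: float = 3.0
    censor_age_low: float = 40.0
    censor_age_high: float = 80.0


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 25
    generations: int = 3
    mean_offspring: float = 2.5
    max_offspring: int = 4
    marry_prob: float = 0.7
    min_females: int = 4
    typed_fraction: float = 0.8
    max_typed_per_family: int = 12
    alpha1: float = 0.01  # screening prior used downstream by the fitted models
    # carrier frequency at which simulated variants actually segregate; the
    # heritable marks such screens detect show minor-mode fractions well
    # above the analysis prior (often 10-50% of families), so the
    # generative frequency is higher
    site_alpha1: float = 0.20
    sites: tuple[SiteSpec, ...] = ()
    hazard: HazardConfig = field(default_factory=HazardConfig)
    min_affected: int = 2
    ascertainment_policy: str = "redraw"  # redraw | discard
    retry_budget: int = 1000
    near_snp_fraction: float = 0.1
    seed: int = 0


@dataclass
class SimulatedCohort:
    """A full synthetic study: inputs plus ground truth for assertions."""

    config: SimulationConfig
    pedigrees: list[Pedigree]
    matrix: MethylationMatrix
    annotations: pd.DataFrame
    phenotypes: list[PhenotypeRecord]
    site_kinds: dict[str, str]
    carriers: dict[str, dict[str, int]]  # probe_id -> individual -> 0/1
    manifest: dict = field(default_factory=dict)


def default_sites(
    n_mendelian: int = 20, n_mixture: int = 90, n_gaussian: int = 90
) -> tuple[SiteSpec, ...]:
    """The default 200-probe contrast: a minority of truly Mendelian sites
    among independent-mixture and unimodal sites with matched components."""
    hypo_hemi = dict(mu0=-3.0, mu1=0.0, sigma0=0.3, sigma1=0.3)
    return (
        tuple(SiteSpec("mendelian", **hypo_hemi) for _ in range(n_mendelian))
        + tuple(SiteSpec("mixture", **hypo_hemi) for _ in range(n_mixture))
        + tuple(SiteSpec("gaussian", mu0=-3.0, mu1=-3.0) for _ in range(n_gaussian))
    )


def _streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_pedigree_set(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Pedigree]:
    """Loop-free multi-generational pedigrees with marry-in founders.

    Each family starts from a founder couple; children marry in new
    founders with probability ``marry_prob`` and reproduce until
    ``generations`` is reached.  Typed members are a random subset of size
    ≈ ``typed_fraction`` × family size (capped so prior tables stay small).
    """
    if config.generations < 1 or config.n_families < 1:
        raise ValueError("need at least one generation and one family")
    if rng is None:
        rng = _streams(config.seed)[0]
    pedigrees = []
    for fi in range(config.n_families):
        fam = f"F{fi + 1:03d}"
        for _ in range(1000):  # redraw until the family has enough females
            members = _grow_family(fam, config, rng)
            n_females = sum(m.sex == "female" for m in members)
            if n_females >= min(config.min_females, 1 + config.generations):
                break
        ped = Pedigree(family_id=fam, members=tuple(members))
        n_typed = min(
            max(2, int(round(config.typed_fraction * len(members)))),
            config.max_typed_per_family,
            len(members),
        )
        chosen = sorted(
            rng.choice(len(members), size=n_typed, replace=False).tolist()
        )
        ped = ped.with_typed(tuple(members[i].individual_id for i in chosen))
        pedigrees.append(ped)
    return pedigrees


def _grow_family(
    fam: str, config: SimulationConfig, rng: np.random.Generator
) -> list[Individual]:
    members: list[Individual] = []
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{fam}_{counter[0]:02d}"

    def add(father=None, mother=None, sex=None) -> Individual:
        if sex is None:
            sex = "female" if rng.random() < 0.5 else "male"
        ind = Individual(
            individual_id=new_id(),
            family_id=fam,
            father_id=father,
            mother_id=mother,
            sex=sex,
        )
        members.append(ind)
        return ind

    pa = add(sex="male")
    ma = add(sex="female")
    couples = [(pa, ma)]
    for gen in range(1, config.generations):
        next_couples = []
        for father, mother in couples:
            n_kids = int(
                np.clip(rng.poisson(config.mean_offspring), 1, config.max_offspring)
            )
            for _ in range(n_kids):
                child = add(father=father.individual_id, mother=mother.individual_id)
                if gen < config.generations - 1 and rng.random() < config.marry_prob:
                    spouse = add(sex="female" if child.sex == "male" else "male")
                    next_couples.append(
                        (child, spouse) if child.sex == "male" else (spouse, child)
                    )
        couples = next_couples
    return members


def drop_variant(
    pedigree: Pedigree, alpha1: float, rng: np.random.Generator
) -> dict[str, int]:
    """Sample carrier statuses for all members: founder origin from the
    truncated-binomial prior, then Mendelian transmission (probability 1/2
    from a heterozygous parent)."""
    configs = enumerate_founder_configs(pedigree, alpha1)
    weights = np.array([w for _, w in configs])
    origin = configs[rng.choice(len(configs), p=weights / weights.sum())][0]
    carriers = {m.individual_id: 0 for m in pedigree.members}
    if origin is None:
        return carriers
    carriers[origin] = 1
    for m in pedigree.members:  # input order is parents-before-children
        if m.father_id is None:
            continue
        n_carrier_parents = carriers[m.father_id] + carriers[m.mother_id]
        if n_carrier_parents >= 1:
            # at most one under the single-origin, loop-free model
            carriers[m.individual_id] = int(rng.random() < 0.5)
    return carriers


def simulate_site(
    pedigrees: Sequence[Pedigree],
    carriers: dict[str, int] | None,
    spec: SiteSpec,
    rng: np.random.Generator,
    alpha1: float = 0.01,
) -> dict[str, float]:
    """M-values for all typed members under one site's generative regime."""
    values: dict[str, float] = {}
    for ped in pedigrees:
        for t in ped.typed_members:
            if spec.kind == "mendelian":
                if carriers is None:
                    raise ValueError("mendelian site requires carrier assignments")
                y = carriers[t]
            elif spec.kind == "mixture":
                y = int(rng.random() < alpha1)
            else:
                y = 0
            mu = spec.mu1 if y else spec.mu0
            sd = spec.sigma1 if y else spec.sigma0
            values[t] = float(rng.normal(mu, sd))
    return values


def _draw_ages(
    ped: Pedigree,
    carriers: dict[str, int],
    hz: HazardConfig,
    rng: np.random.Generator,
) -> tuple[list[PhenotypeRecord], int]:
    records = []
    n_affected_f = 0
    for m in ped.members:
        censor = float(rng.uniform(hz.censor_age_low, hz.censor_age_high))
        if m.sex == "female":
            hr = hz.hazard_ratio if carriers.get(m.individual_id, 0) else 1.0
            onset = hz.weibull_scale * (rng.exponential() / hr) ** (1.0 / hz.weibull_shape)
            affected = onset <= censor
            age = min(onset, censor)
            n_affected_f += int(affected)
        else:
            affected, age = False, censor
        records.append(
            PhenotypeRecord(
                individual_id=m.individual_id,
                affected=bool(affected),
                event_or_censor_age=float(age),
                sex=m.sex,
            )
        )
    return records, n_affected_f


def simulate_phenotypes(
    pedigrees: Sequence[Pedigree],
    carriers_by_family: dict[str, dict[str, int]],
    hazard: HazardConfig,
    min_affected: int,
    rng: np.random.Generator,
    policy: str = "redraw",
    retry_budget: int = 1000,
) -> tuple[list[PhenotypeRecord], list[str]]:
    """Carrier-dependent Weibull onset ages for females, censoring at a
    follow-up age, under multiple-case ascertainment.

    Families with fewer than ``min_affected`` affected females are redrawn
    (phenotypes resampled, up to ``retry_budget`` attempts) or discarded.
    Returns the phenotype records and the retained family ids.
    """
    if hazard.hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if policy not in ("redraw", "discard"):
        raise ValueError(f"unknown ascertainment policy {policy!r}")
    records: list[PhenotypeRecord] = []
    retained: list[str] = []
    for ped in pedigrees:
        carriers = carriers_by_family.get(ped.family_id, {})
        for attempt in range(max(retry_budget, 1)):
            fam_records, n_affected = _draw_ages(ped, carriers, hazard, rng)
            if n_affected >= min_affected:
                records.extend(fam_records)
                retained.append(ped.family_id)
                break
            if policy == "discard":
                break
        else:
            raise RuntimeError(
                f"family {ped.family_id!r}: ascertainment (≥{min_affected} affected "
                f"females) not reached within {retry_budget} redraws"
            )
    return records, retained


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a complete study: pedigrees, per-site M-values, synthetic
    probe annotation, ascertained phenotypes, and ground truth."""
    sites = config.sites or default_sites()
    rng_ped, rng_var, rng_meth, rng_pheno = _streams(config.seed)
    pedigrees = simulate_pedigree_set(config, rng_ped)

    probe_ids = [f"cg{j:08d}" for j in range(len(sites))]
    site_kinds = {}
    carriers_by_probe: dict[str, dict[str, int]] = {}
    columns = [t for ped in pedigrees for t in ped.typed_members]
    data = np.empty((len(sites), len(columns)))
    # the first mendelian site's variant also drives the disease phenotype
    causal_carriers: dict[str, dict[str, int]] = {}
    for j, (probe, spec) in enumerate(zip(probe_ids, sites)):
        site_kinds[probe] = spec.kind
        carriers: dict[str, int] = {}
        if spec.kind == "mendelian":
            for ped in pedigrees:
                carriers.update(drop_variant(ped, config.site_alpha1, rng_var))
            carriers_by_probe[probe] = carriers
            if not causal_carriers:
                causal_carriers = {
                    ped.family_id: {
                        m.individual_id: carriers[m.individual_id] for m in ped.members
                    }
                    for ped in pedigrees
                }
        vals = simulate_site(
            pedigrees, carriers or None, spec, rng_meth, alpha1=config.site_alpha1
        )
        data[j] = [vals[c] for c in columns]
    matrix = MethylationMatrix(
        values=pd.DataFrame(data, index=probe_ids, columns=columns), scale="m"
    )

    snp_distance = np.where(
        rng_meth.random(len(sites)) < config.near_snp_fraction,
        rng_meth.integers(0, 11, size=len(sites)),
        rng_meth.integers(11, 5000, size=len(sites)),
    )
    annotations = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chr": rng_meth.integers(1, 23, size=len(sites)).astype(str),
            "pos": rng_meth.integers(1, 2_000_000, size=len(sites)),
            "snp_distance": snp_distance,
        }
    ).set_index("probe_id")

    phenotypes, retained = simulate_phenotypes(
        pedigrees,
        causal_carriers,
        config.hazard,
        config.min_affected,
        rng_pheno,
        policy=config.ascertainment_policy,
        retry_budget=config.retry_budget,
    )
    if config.ascertainment_policy == "discard":
        pedigrees = [p for p in pedigrees if p.family_id in retained]

    return SimulatedCohort(
        config=config,
        pedigrees=pedigrees,
        matrix=matrix,
        annotations=annotations,
        phenotypes=phenotypes,
        site_kinds=site_kinds,
        carriers=carriers_by_probe,
        manifest={
            "seed": config.seed,
            "n_families": len(pedigrees),
            "n_typed": len(columns),
            "n_sites": len(sites),
            "ascertainment_policy": config.ascertainment_policy,
            "retained_families": retained,
        },
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the TSV inputs the pipeline consumes, plus truth
    tables for assertions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.tsv",
        "m_values": out / "m_values.tsv",
        "annotation": out / "annotation.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth_sites": out / "truth_sites.tsv",
        "truth_carriers": out / "truth_carriers.tsv",
    }
    write_pedigrees(cohort.pedigrees, paths["pedigree"])
    cohort.matrix.values.to_csv(paths["m_values"], sep="\t", index_label="probe_id")
    cohort.annotations.to_csv(paths["annotation"], sep="\t")
    pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "affected": int(r.affected),
                "age": round(r.event_or_censor_age, 4),
                "sex": r.sex,
            }
            for r in cohort.phenotypes
        ]
    ).to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        [{"probe_id": p, "kind": k} for p, k in cohort.site_kinds.items()]
    ).to_csv(paths["truth_sites"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"probe_id": p, "individual_id": i, "carrier": c}
            for p, members in cohort.carriers.items()
            for i, c in members.items()
        ]
    ).to_csv(paths["truth_carriers"], sep="\t", index=False)
    return paths
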