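"""Genome-wide Δl screening, SNP-proximity trend validation, and Cox
proportional-hazards association of carrier probabilities with disease.

The screen ranks probes by Δl = l_Mendel − l_mix using only pedigree
structure and M-values (phenotypes are not an argument, by construction).
The top-k sites' carrier probabilities are then tested for association with
disease by a Cox model on the age time-scale; inference uses the
likelihood-ratio test because multiple-case ascertainment biases the hazard
ratio estimates but leaves the LRT valid under the null.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .carrier import CarrierPosterior, carrier_posteriors
from .methylation import MethylationMatrix, filter_probes, load_annotation, load_matrix
from .models import MendelianModel, MixtureModel
from .pedigree import (
    Pedigree,
    PhenotypeRecord,
    attach_typed_members,
    parse_pedigrees,
    parse_phenotypes,
)
from .segregation import precompute_family_priors

__all__ = [
    "ScreenResult",
    "AssociationResult",
    "screen_sites",
    "snp_trend_test",
    "cox_lrt",
    "bonferroni_alpha",
    "run_pipeline",
]


@dataclass
class ScreenResult:
    """Δl ranking over the screened probes (descending; ties broken by
    probe id)."""

    table: pd.DataFrame  # probe_id, delta_l, l_mendel, l_mix, + fit details
    top_k: int
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def top(self) -> pd.DataFrame:
        return self.table.head(self.top_k)


@dataclass
class AssociationResult:
    """Cox LRT for one probe's carrier probabilities vs disease."""

    probe_id: str
    lrt_statistic: float
    p_value: float
    n_events: int
    n_at_risk: int
    significant: bool
    log_hazard_ratio: float  # ascertainment-biased; not for reporting
    note: str = "hazard ratio is ascertainment-biased; use the p-value only"


def bonferroni_alpha(family_wise_alpha: float, m: int) -> float:
    """Per-test significance threshold α/m."""
    if m < 1:
        raise ValueError("m must be a positive integer")
    return family_wise_alpha / m


def screen_sites(
    matrix: MethylationMatrix,
    pedigrees: Sequence[Pedigree],
    annotations: pd.DataFrame | None = None,
    k: int = 1000,
    alpha1: float = 0.01,
    prior_tables=None,
    **fit_options,
) -> ScreenResult:
    """Rank all probes by Δl; phenotype data never enters.

    ``matrix`` is assumed probe-filtered already and on the M scale (β
    matrices are converted).  Family prior tables are computed once and
    reused across probes.  Probes with fewer than 4 distinct values are
    skipped with a recorded reason.
    """
    matrix = matrix.to_m()
    if prior_tables is None:
        prior_tables = precompute_family_priors(pedigrees, alpha1)
    typed_order = [t for ped in pedigrees for t in ped.typed_members]
    rows = []
    skipped: dict[str, str] = {}
    for probe in matrix.probe_ids:
        x = matrix.site(probe, typed_order)
        if np.unique(x).size < 4:
            skipped[probe] = "fewer than 4 distinct values"
            continue
        mix = MixtureModel(alpha1=alpha1, **fit_options).fit(x)
        mendel = MendelianModel(
            pedigrees=pedigrees,
            prior_tables=prior_tables,
            alpha1=alpha1,
            **fit_options,
        ).fit(x)
        t = mendel.theta_
        rows.append(
            {
                "probe_id": probe,
                "delta_l": mendel.loglik_ - mix.loglik_,
                "l_mendel": mendel.loglik_,
                "l_mix": mix.loglik_,
                "mu0": t.mu0,
                "mu1": t.mu1,
                "sigma0": t.sigma0,
                "sigma1": t.sigma1,
                "orientation": mendel.orientation_,
                "iterations": mendel.n_iter_,
                "converged": mendel.converged_,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["delta_l", "probe_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    if k > len(table):
        warnings.warn(
            f"requested top {k} but only {len(table)} probes were fitted; returning all"
        )
        k = len(table)
    return ScreenResult(table=table, top_k=k, skipped=skipped)


def snp_trend_test(
    delta_ls: np.ndarray,
    near_snp: np.ndarray,
    degree: int = 3,
    n_bins: int = 10,
) -> dict:
    """Does the fraction of SNP-adjacent probes rise with Δl?

    Logistic regression of the near-SNP indicator on an orthogonalised
    polynomial in Δl, compared to the intercept-only model by a likelihood
    ratio test on ``degree`` degrees of freedom.  Probes near SNPs behave
    like genotypes, so a positive trend validates Δl as a heritability
    screen.  Also returns decile-binned proportions with binomial 95% CIs
    for plotting.
    """
    import statsmodels.api as sm
    from statsmodels.stats.proportion import proportion_confint

    dl = np.asarray(delta_ls, dtype=float)
    y = np.asarray(near_snp, dtype=float)
    if dl.size != y.size:
        raise ValueError("delta_ls and near_snp must have equal length")
    if np.unique(dl).size < 2:
        raise ValueError("need at least 2 distinct delta_l values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("near_snp must contain both classes")

    # orthonormal polynomial basis (QR of the centred Vandermonde matrix)
    z = (dl - dl.mean()) / (dl.std() or 1.0)
    V = np.column_stack([z**p for p in range(degree + 1)])
    Q, _ = np.linalg.qr(V)
    X = np.column_stack([np.ones_like(z), Q[:, 1:]])

    null = sm.Logit(y, np.ones((y.size, 1))).fit(disp=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.Logit(y, X).fit(disp=0, maxiter=200)
    lrt = 2.0 * (full.llf - null.llf)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=degree))

    edges = np.quantile(dl, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    which = np.searchsorted(edges, dl, side="right") - 1
    which = np.clip(which, 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        mask = which == b
        n = int(mask.sum())
        if n == 0:
            continue
        hits = int(y[mask].sum())
        lo, hi = proportion_confint(hits, n, alpha=0.05, method="wilson")
        bins.append(
            {
                "bin": b,
                "n": n,
                "mean_delta_l": float(dl[mask].mean()),
                "prop_near_snp": hits / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return {
        "lrt_statistic": float(max(lrt, 0.0)),
        "p_value": p,
        "degree": degree,
        "coefficients": full.params.tolist(),
        "bins": pd.DataFrame(bins),
    }


def _breslow_loglik(beta: float, t, e, x) -> float:
    """Breslow partial log-likelihood for one covariate (events share the
    full risk set at tied times)."""
    order = np.argsort(-t, kind="mergesort")  # decreasing time
    t, e, x = t[order], e[order], x[order]
    eta = beta * x
    ll = 0.0
    run = -np.inf
    i = 0
    n = t.size
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        run = np.logaddexp.reduce(np.append(eta[i:j], run))
        d = e[i:j].astype(bool)
        ll += float(eta[i:j][d].sum() - d.sum() * run)
        i = j
    return ll


def cox_lrt(
    carriers: CarrierPosterior | Mapping[str, float],
    phenotypes: Sequence[PhenotypeRecord],
    significance_threshold: float = 5e-5,
    female_only: bool = True,
    ties: str = "efron",
    strata: Mapping[str, str] | None = None,
) -> AssociationResult:
    """Cox proportional-hazards LRT of carrier probability vs disease.

    Age is the time scale (event age for affected, censoring age
    otherwise); the single covariate is q₁.  The risk set defaults to
    females (the transmission model still uses males, but breast cancer
    risk sets do not).  ``ties``: ``"efron"`` uses lifelines' fitter;
    ``"breslow"`` uses an internal one-covariate partial-likelihood
    optimiser.  Hazard ratios are computed but ascertainment-biased —
    only the p-value is meaningful.
    """
    q1 = carriers.q1 if isinstance(carriers, CarrierPosterior) else dict(carriers)
    probe_id = carriers.probe_id if isinstance(carriers, CarrierPosterior) else ""
    rows = []
    for rec in phenotypes:
        if female_only and rec.sex == "male":
            continue
        if rec.individual_id not in q1:
            continue
        rows.append(
            {
                "individual_id": rec.individual_id,
                "duration": rec.event_or_censor_age,
                "event": int(rec.affected),
                "q1": q1[rec.individual_id],
            }
        )
    if not rows:
        raise ValueError("risk set is empty")
    df = pd.DataFrame(rows)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the risk set; LRT undefined")

    if float(df["q1"].max() - df["q1"].min()) < 1e-12:
        return AssociationResult(
            probe_id=probe_id,
            lrt_statistic=0.0,
            p_value=1.0,
            n_events=n_events,
            n_at_risk=len(df),
            significant=False,
            log_hazard_ratio=0.0,
        )

    if strata is not None:
        df["_stratum"] = [strata[i] for i in df["individual_id"]]

    if ties == "efron":
        from lifelines import CoxPHFitter

        cph = CoxPHFitter()
        fit_cols = ["duration", "event", "q1"] + (["_stratum"] if strata else [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[fit_cols],
                duration_col="duration",
                event_col="event",
                strata=["_stratum"] if strata else None,
            )
        res = cph.log_likelihood_ratio_test()
        stat = float(res.test_statistic)
        p = float(res.p_value)
        log_hr = float(cph.params_["q1"])
    elif ties == "breslow":
        groups = (
            df.groupby("_stratum") if strata is not None else [(None, df)]
        )
        def negll(beta):
            return -sum(
                _breslow_loglik(
                    beta,
                    g["duration"].to_numpy(float),
                    g["event"].to_numpy(float),
                    g["q1"].to_numpy(float),
                )
                for _, g in groups
            )
        opt = optimize.minimize_scalar(negll, bounds=(-50, 50), method="bounded")
        stat = 2.0 * (negll(0.0) - opt.fun)
        stat = float(max(stat, 0.0))
        p = float(stats.chi2.sf(stat, df=1))
        log_hr = float(opt.x)
    else:
        raise ValueError(f"unknown tie-handling method {ties!r}")

    return AssociationResult(
        probe_id=probe_id,
        lrt_statistic=max(stat, 0.0),
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        n_events=n_events,
        n_at_risk=len(df),
        significant=p < significance_threshold,
        log_hazard_ratio=log_hr,
    )


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """End-to-end run: filter → screen → carrier posteriors → associate.

    ``config`` keys: ``m_values`` (TSV path), ``values_scale`` ("beta"/"m"),
    ``pedigree``, ``annotation``, ``phenotypes`` (optional), ``top_k``,
    ``alpha_carrier``, ``familywise_alpha``, ``snp_bp``, ``drop_sex``,
    ``female_only``.  Writes TSV outputs and a JSON run manifest; returns
    the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)

    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Stage()

    manifest: dict = {
        "parameters": {
            k: cfg.get(k)
            for k in (
                "top_k",
                "alpha_carrier",
                "familywise_alpha",
                "snp_bp",
                "drop_sex",
                "female_only",
                "values_scale",
                "seed",
            )
        },
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }

    with stage("load"):
        matrix = load_matrix(cfg["m_values"], scale=cfg.get("values_scale", "m"))
        annotations = load_annotation(cfg["annotation"]) if cfg.get("annotation") else None
        pedigrees = parse_pedigrees(cfg["pedigree"])
        pedigrees = attach_typed_members(pedigrees, matrix.sample_ids)
    manifest["stages"].append("load")

    with stage("filter"):
        if annotations is not None:
            matrix, report = filter_probes(
                matrix,
                annotations,
                snp_bp=int(cfg.get("snp_bp", 10)),
                drop_sex=bool(cfg.get("drop_sex", True)),
            )
            pd.DataFrame(
                [{"reason": r, "n_removed": n} for r, n in report.removed.items()]
                + [{"reason": "retained", "n_removed": report.n_retained}]
            ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
            manifest["filter"] = {
                "n_input": report.n_input,
                "n_retained": report.n_retained,
                "removed": report.removed,
            }
    manifest["stages"].append("filter")

    alpha1 = float(cfg.get("alpha_carrier", 0.01))
    with stage("screen"):
        prior_tables = precompute_family_priors(pedigrees, alpha1)
        screen = screen_sites(
            matrix,
            pedigrees,
            k=int(cfg.get("top_k", 1000)),
            alpha1=alpha1,
            prior_tables=prior_tables,
        )
        screen.table.to_csv(out / "delta_l.tsv", sep="\t", index=False)
        screen.top.to_csv(out / "top_probes.tsv", sep="\t", index=False)
        manifest["screen"] = {
            "n_probes": len(screen.table),
            "top_k": screen.top_k,
            "n_skipped": len(screen.skipped),
        }
    manifest["stages"].append("screen")

    with stage("carriers"):
        matrix_m = matrix.to_m()
        typed_order = [t for ped in pedigrees for t in ped.typed_members]
        from .models import Theta

        ext_cache: dict = {}
        carrier_frames = []
        posteriors: dict[str, CarrierPosterior] = {}
        for row in screen.top.itertuples(index=False):
            theta = Theta(1 - alpha1, alpha1, row.mu0, row.mu1, row.sigma0, row.sigma1)
            cp = carrier_posteriors(
                matrix_m.site(row.probe_id, typed_order),
                pedigrees,
                theta,
                prior_tables=prior_tables,
                probe_id=row.probe_id,
                extended_tables=ext_cache,
            )
            posteriors[row.probe_id] = cp
            carrier_frames.append(cp.to_frame(pedigrees))
        if carrier_frames:
            pd.concat(carrier_frames).to_csv(out / "carriers.tsv", sep="\t", index=False)
    manifest["stages"].append("carriers")

    if cfg.get("phenotypes"):
        with stage("associate"):
            phenos = parse_phenotypes(cfg["phenotypes"])
            fw_alpha = float(cfg.get("familywise_alpha", 0.05))
            threshold = bonferroni_alpha(fw_alpha, max(screen.top_k, 1))
            assoc_rows = []
            for probe, cp in posteriors.items():
                res = cox_lrt(
                    cp,
                    phenos,
                    significance_threshold=threshold,
                    female_only=bool(cfg.get("female_only", True)),
                )
                assoc_rows.append(
                    {
                        "probe_id": probe,
                        "lrt_statistic": res.lrt_statistic,
                        "p_value": res.p_value,
                        "n_events": res.n_events,
                        "significant": res.significant,
                    }
                )
            pd.DataFrame(assoc_rows).to_csv(out / "associations.tsv", sep="\t", index=False)
            manifest["associate"] = {
                "threshold": threshold,
                "n_significant": int(sum(r["significant"] for r in assoc_rows)),
            }
        manifest["stages"].append("associate")
    elif cfg.get("require_phenotypes") or "associate" in cfg.get("stages", ()):
        raise RuntimeError("pipeline stage 'associate' failed: no phenotype file configured")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
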