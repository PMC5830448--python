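"""Posterior carrier probabilities — the covariate for association testing.

Given a fitted Mendelian model for one site, each individual's probability
of carrying the hypothetical variant is computed by segregation analysis
with the site's Gaussian densities playing the role of the penetrance
function.  Only pedigree structure and M-values enter: no phenotype data.

Typed members get the exact E-step quantity

    q_{i1} = Σ_{y^f : y_i = 1} P(y^f | x^f, θ̂).

Untyped members (scope ``all_members``, the default used for association)
are handled by extending the family's configuration sum with that member
and marginalising every other untyped member; an untyped member of a family
with no methylation data at all falls back to the structural prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Theta, _FamilyBlock, _mendelian_estep
from .pedigree import Pedigree
from .segregation import (
    FamilyPriorTable,
    joint_carrier_distribution,
    precompute_family_priors,
)

__all__ = ["CarrierPosterior", "carrier_posteriors"]


@dataclass
class CarrierPosterior:
    """Per-individual carrier probabilities for one site."""

    probe_id: str
    q1: dict[str, float]
    basis: str  # "typed_only" | "all_members"
    typed: frozenset[str] = field(default_factory=frozenset)

    def to_frame(self, pedigrees: Sequence[Pedigree]) -> pd.DataFrame:
        family_of = {
            m.individual_id: ped.family_id for ped in pedigrees for m in ped.members
        }
        rows = [
            {
                "probe_id": self.probe_id,
                "family_id": family_of.get(ind, ""),
                "individual_id": ind,
                "typed": int(ind in self.typed),
                "q1": q,
            }
            for ind, q in self.q1.items()
        ]
        return pd.DataFrame(rows)


def carrier_posteriors(
    x,
    pedigrees: Sequence[Pedigree],
    theta: Theta,
    scope: str = "all_members",
    prior_tables: Mapping[str, FamilyPriorTable] | None = None,
    probe_id: str = "",
    extended_tables: dict | None = None,
) -> CarrierPosterior:
    """Carrier probabilities at the plug-in MLE θ̂ for every individual.

    Parameters
    ----------
    x : site M-values aligned to the concatenated typed members (array,
        Series, or id → value mapping).
    scope : ``"typed_only"`` restricts to the E-step quantities;
        ``"all_members"`` additionally infers untyped relatives.
    extended_tables : optional cache, reused across probes, of the
        structural joint distributions over (typed members + one untyped
        member); these depend only on pedigree structure and α₁.
    """
    if scope not in ("typed_only", "all_members"):
        raise ValueError(f"unknown scope {scope!r}")
    if prior_tables is None:
        prior_tables = precompute_family_priors(pedigrees, theta.alpha1)

    # align x to typed order, family by family
    order: list[str] = [t for ped in pedigrees for t in ped.typed_members]
    if hasattr(x, "reindex"):
        xv = x.reindex(order).to_numpy(dtype=float)
    elif isinstance(x, dict):
        xv = np.array([x[o] for o in order], dtype=float)
    else:
        xv = np.asarray(x, dtype=float).ravel()
        if xv.size != len(order):
            raise ValueError(f"expected {len(order)} values, got {xv.size}")
    if not np.all(np.isfinite(xv)):
        raise ValueError("M-values must be finite")

    q1: dict[str, float] = {}
    pos = 0
    for ped in pedigrees:
        k = len(ped.typed_members)
        idx = np.arange(pos, pos + k)
        pos += k
        table = prior_tables[ped.family_id]
        if k:
            blk = _FamilyBlock(table, np.arange(k))
            _, q_typed = _mendelian_estep([blk], xv[idx], theta)
            # family posterior over typed vectors, needed for untyped members
            for j, t in enumerate(ped.typed_members):
                q1[t] = float(q_typed[j])
        if scope == "typed_only":
            continue
        untyped = [m.individual_id for m in ped.members if m.individual_id not in ped.typed_members]
        if not untyped:
            continue
        if k == 0:
            # no data in this family: posterior = structural prior marginal
            for u in untyped:
                dist = _extended(ped, (), u, theta.alpha1, extended_tables)
                q1[u] = float(dist[1])
            continue
        post = _family_posterior(table, xv[idx], theta)
        for u in untyped:
            ext = _extended(ped, ped.typed_members, u, theta.alpha1, extended_tables)
            # P(y_u = 1 | y_typed = v) = ext[v with u-bit set] / prior[v]
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = np.where(
                    table.probs > 0, ext[(1 << k):] / table.probs, 0.0
                )
            q1[u] = float(post @ cond)
    typed = frozenset(t for ped in pedigrees for t in ped.typed_members)
    return CarrierPosterior(probe_id=probe_id, q1=q1, basis=scope, typed=typed)


def _family_posterior(
    table: FamilyPriorTable, x_f: np.ndarray, theta: Theta
) -> np.ndarray:
    """Posterior over the 2^k typed carrier vectors of one family."""
    from .models import _bits_matrix, _norm_logpdf
    from scipy.special import logsumexp

    k = len(table.typed_members)
    bits = _bits_matrix(k)
    lp0 = _norm_logpdf(x_f, theta.mu0, theta.sigma0)
    lp1 = _norm_logpdf(x_f, theta.mu1, theta.sigma1)
    logjoint = table.log_probs + lp0.sum() + bits @ (lp1 - lp0)
    return np.exp(logjoint - logsumexp(logjoint))


def _extended(
    ped: Pedigree,
    typed: tuple[str, ...],
    member: str,
    alpha1: float,
    cache: dict | None,
) -> np.ndarray:
    """Joint structural distribution over (typed…, member); member is the
    highest bit.  Cached across probes when a cache dict is supplied."""
    key = (ped.family_id, typed, member, alpha1)
    if cache is not None and key in cache:
        return cache[key]
    dist = joint_carrier_distribution(ped, list(typed) + [member], alpha1)
    if cache is not None:
        cache[key] = dist
    return dist
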