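"""Exact carrier-vector probabilities in pedigrees under a rare-variant model.

The latent genetic model behind the pedigree-coupled mixture: a rare
autosomal variant enters each family through at most one founder (never as
a homozygote), and a heterozygous parent transmits it to each child
independently with probability 1/2.  Founder configurations are weighted by
the truncated binomial

    P(no carrier founder)      ∝ (1 − α₁)^F
    P(founder j heterozygous)  ∝ α₁ (1 − α₁)^(F−1)

renormalised over the F + 1 admissible configurations, which keeps the
marginal founder carrier probability ≈ α₁ for small α₁.

``joint_carrier_distribution`` computes the exact joint distribution of
carrier indicators over any ordered subset of members (marginalising the
rest) by a single downward pass over each founder's descent tree;
``brute_force_prior`` is a deliberately naive re-derivation by full
enumeration, kept independent as an oracle.

Consanguinity (a child whose two parents descend from the same founder) is
rejected: under the single-origin assumption such a child could be a
homozygote, which the model excludes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pedigree import Pedigree

__all__ = [
    "UnsupportedPedigreeError",
    "FamilyPriorTable",
    "enumerate_founder_configs",
    "joint_carrier_distribution",
    "config_prior",
    "brute_force_prior",
    "precompute_family_priors",
]


class UnsupportedPedigreeError(ValueError):
    """Pedigree structure outside the model's assumptions (consanguinity loop)."""


def enumerate_founder_configs(
    pedigree: Pedigree, alpha1: float
) -> list[tuple[str | None, float]]:
    """Admissible founder-origin configurations with normalised weights.

    Returns ``[(None, w0), (founder_1, w1), ...]`` where ``None`` is the
    no-carrier configuration and each other entry names the single
    heterozygous founder.
    """
    if not 0.0 < alpha1 < 1.0:
        raise ValueError("alpha1 must be in (0, 1)")
    founders = pedigree.founders
    F = len(founders)
    w_none = (1.0 - alpha1) ** F
    w_one = alpha1 * (1.0 - alpha1) ** (F - 1)
    z = w_none + F * w_one
    configs: list[tuple[str | None, float]] = [(None, w_none / z)]
    configs.extend((f, w_one / z) for f in founders)
    return configs


class _DescentIndex:
    """Per-founder descent sets and children links; validates the
    no-consanguinity assumption once per pedigree."""

    def __init__(self, pedigree: Pedigree) -> None:
        self.pedigree = pedigree
        self.children: dict[str, tuple[str, ...]] = {
            m.individual_id: pedigree.children_of(m.individual_id)
            for m in pedigree.members
        }
        self.descent: dict[str, frozenset[str]] = {}
        for f in pedigree.founders:
            seen: set[str] = set()
            stack = [f]
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                stack.extend(self.children[node])
            self.descent[f] = frozenset(seen)
        for m in pedigree.members:
            if m.father_id is None:
                continue
            for f, desc in self.descent.items():
                if m.father_id in desc and m.mother_id in desc:
                    raise UnsupportedPedigreeError(
                        f"family {pedigree.family_id!r}: parents of "
                        f"{m.individual_id!r} both descend from founder {f!r} "
                        "(consanguinity loop; single-origin model undefined)"
                    )


def _subtree_joint(
    index: _DescentIndex,
    node: str,
    carrier: int,
    positions: Mapping[str, int],
) -> tuple[np.ndarray, list[str]]:
    """Joint probability vector over the tracked members in ``node``'s
    subtree, given ``node``'s carrier state.  Bit j of the returned array's
    index corresponds to the j-th entry of the returned member list."""
    vec = np.array([1.0])
    tracked: list[str] = []
    for child in index.children[node]:
        a0, members0 = _subtree_joint(index, child, 0, positions)
        if carrier == 1:
            a1, _ = _subtree_joint(index, child, 1, positions)
            child_vec = 0.5 * a0 + 0.5 * a1
        else:
            child_vec = a0
        vec = np.multiply.outer(child_vec, vec).ravel()
        tracked = tracked + members0
    if node in positions:
        full = np.zeros(2 * vec.size)
        # node's bit is the new highest bit; fixed to its carrier state
        if carrier == 1:
            full[vec.size :] = vec
        else:
            full[: vec.size] = vec
        return full, tracked + [node]
    return vec, tracked


def joint_carrier_distribution(
    pedigree: Pedigree,
    subset: Sequence[str],
    alpha1: float,
    _index: _DescentIndex | None = None,
) -> np.ndarray:
    """Exact joint distribution of carrier indicators over ``subset``.

    Returns an array of length 2^k; entry ``b`` is the probability that
    member ``subset[j]`` is a carrier iff bit ``j`` of ``b`` is set, with
    all members outside the subset marginalised out.  Sums to 1.
    """
    subset = list(subset)
    for s in subset:
        if s not in pedigree:
            raise ValueError(f"{s!r} is not a member of family {pedigree.family_id!r}")
    if len(set(subset)) != len(subset):
        raise ValueError("subset contains duplicate ids")
    index = _index or _DescentIndex(pedigree)
    positions = {s: j for j, s in enumerate(subset)}
    k = len(subset)
    out = np.zeros(1 << k)
    for origin, weight in enumerate_founder_configs(pedigree, alpha1):
        if origin is None:
            out[0] += weight  # nobody carries
            continue
        vec, tracked = _subtree_joint(index, origin, 1, positions)
        # scatter subtree-local bit order into the requested bit order;
        # subset members outside the descent tree are non-carriers (bit 0)
        local_bits = [positions[m] for m in tracked]
        contrib = np.zeros(1 << k)
        for local_idx, p in enumerate(vec):
            if p == 0.0:
                continue
            global_idx = 0
            for j, bit in enumerate(local_bits):
                if (local_idx >> j) & 1:
                    global_idx |= 1 << bit
            contrib[global_idx] += p
        out += weight * contrib
    return out


def config_prior(
    pedigree: Pedigree,
    assignment: Mapping[str, int],
    alpha1: float,
    _index: _DescentIndex | None = None,
) -> float:
    """P(carrier indicators = ``assignment`` over its keys), exactly.

    Members not named in ``assignment`` are marginalised out.  An empty
    assignment has probability 1.
    """
    subset = list(assignment)
    dist = joint_carrier_distribution(pedigree, subset, alpha1, _index=_index)
    idx = 0
    for j, s in enumerate(subset):
        if assignment[s]:
            idx |= 1 << j
    return float(dist[idx])


def brute_force_prior(
    pedigree: Pedigree, assignment: Mapping[str, int], alpha1: float
) -> float:
    """Oracle: same probability by enumerating all 2^n full carrier vectors.

    Naive by design (plain Python loops, no descent-tree recursion) so that
    it stays independent of :func:`config_prior`.
    """
    members = list(pedigree.member_ids)
    n = len(members)
    if n > 20:
        raise ValueError("brute force limited to pedigrees of ≤ 20 members")
    founders = set(pedigree.founders)
    F = len(founders)
    a = alpha1
    z = (1.0 - a) ** F + F * a * (1.0 - a) ** (F - 1)
    w_none = (1.0 - a) ** F / z
    w_one = a * (1.0 - a) ** (F - 1) / z

    total = 0.0
    for bits in range(1 << n):
        y = {members[i]: (bits >> i) & 1 for i in range(n)}
        if any(y[s] != v for s, v in assignment.items()):
            continue
        n_carrier_founders = sum(y[f] for f in founders)
        if n_carrier_founders == 0:
            p = w_none
        elif n_carrier_founders == 1:
            p = w_one
        else:
            continue  # inadmissible under the ≤1-carrier-founder model
        for m in pedigree.members:
            if m.father_id is None:
                continue
            carrier_parents = y[m.father_id] + y[m.mother_id]
            child = y[m.individual_id]
            if carrier_parents == 0:
                t = 0.0 if child else 1.0
            elif carrier_parents == 1:
                t = 0.5
            else:
                # unreachable in loop-free pedigrees with one founder origin;
                # independent-transmission fallback kept for completeness
                t = 0.75 if child else 0.25
            p *= t
            if p == 0.0:
                break
        total += p
    return total


@dataclass
class FamilyPriorTable:
    """Cached prior P(y^f) over all carrier vectors of one family's typed
    members.  The table depends only on pedigree structure and the carrier
    frequency α₁ — not on the methylation values or the Gaussian
    parameters — so it is computed once and shared by every probe and every
    EM iteration."""

    family_id: str
    typed_members: tuple[str, ...]
    alpha1: float
    probs: np.ndarray  # length 2^k, bit j ↔ typed_members[j]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.size != 1 << len(self.typed_members):
            raise ValueError("table size does not match typed member count")

    @property
    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)

    def prob(self, assignment: Mapping[str, int]) -> float:
        idx = 0
        for j, s in enumerate(self.typed_members):
            if assignment[s]:
                idx |= 1 << j
        return float(self.probs[idx])


def precompute_family_priors(
    pedigrees: Sequence[Pedigree],
    alpha1: float,
    max_typed: int = 16,
) -> dict[str, FamilyPriorTable]:
    """Build a :class:`FamilyPriorTable` per family (keyed by family id)."""
    tables: dict[str, FamilyPriorTable] = {}
    for ped in pedigrees:
        k = len(ped.typed_members)
        if k > max_typed:
            raise ValueError(
                f"family {ped.family_id!r} has {k} typed members; the "
                f"2^{k}-entry prior table exceeds the budget of 2^{max_typed} "
                "(raise max_typed or evaluate priors per call)"
            )
        index = _DescentIndex(ped)
        probs = joint_carrier_distribution(
            ped, ped.typed_members, alpha1, _index=index
        )
        tables[ped.family_id] = FamilyPriorTable(
            family_id=ped.family_id,
            typed_members=ped.typed_members,
            alpha1=alpha1,
            probs=probs,
        )
    return tables
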