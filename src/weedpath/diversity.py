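"""Hill-series (Rényi) diversity metrics for weed communities.

The Hill number of order ``a`` is the effective number of species

.. math::

    {}^{a}D = \\Bigl(\\sum_{i=1}^{S} p_i^{a}\\Bigr)^{1/(1-a)},

where :math:`p_i` is the proportional abundance of species *i*.  The
series interpolates familiar indices: species richness at ``a = 0``,
the exponential of the Shannon entropy ("equivalent species richness",
or true diversity) at ``a = 1``, the inverse Simpson index at ``a = 2``
and the reciprocal Berger–Parker dominance index at ``a = inf``.

Abundances may be plant counts per area (autumn surveys) or dry
biomass per area (early-summer harvest).  All metrics depend on the
data only through proportions, so both bases share the formulas, but
the two bases must never be pooled within one community, and the
module enforces this for alpha/gamma partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Default grid of Hill orders used throughout the package.
HILL_ORDERS: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, np.inf)

#: Orders closer to 1 than this are evaluated with the analytic a=1 limit.
_UNIT_ORDER_TOL = 1e-9


class EmptyCommunityError(ValueError):
    """Raised when a community has no positive abundance at all."""


@dataclass(frozen=True)
class Community:
    """A single weed community: species codes with nonnegative quantities.

    Parameters
    ----------
    species
        EPPO-style species codes (e.g. ``"VIOAR"``).
    quantity
        Nonnegative abundances, plants m⁻² for ``basis="counts"`` or
        g m⁻² dry mass for ``basis="biomass"``.
    basis
        Measurement basis, ``"counts"`` or ``"biomass"``.  Uniform
        within one community by construction.
    """

    species: tuple[str, ...]
    quantity: tuple[float, ...]
    basis: str = "counts"

    def __post_init__(self) -> None:
        if self.basis not in ("counts", "biomass"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if len(self.species) != len(self.quantity):
            raise ValueError("species and quantity have different lengths")
        q = np.asarray(self.quantity, dtype=float)
        if q.size and (q < 0).any():
            bad = self.species[int(np.argmin(q))]
            raise ValueError(f"negative abundance for species {bad!r}")

    @classmethod
    def from_mapping(cls, data: Mapping[str, float], basis: str = "counts") -> "Community":
        return cls(tuple(data.keys()), tuple(float(v) for v in data.values()), basis)

    def quantities(self) -> np.ndarray:
        return np.asarray(self.quantity, dtype=float)


def _as_quantities(community) -> np.ndarray:
    """Coerce a Community, mapping or array-like to a quantity vector."""
    if isinstance(community, Community):
        return community.quantities()
    if isinstance(community, Mapping):
        return np.asarray(list(community.values()), dtype=float)
    return np.asarray(community, dtype=float)


def proportions(community) -> np.ndarray:
    """Proportional abundances with zero-abundance species dropped.

    Returns the vector :math:`p` with :math:`p_i > 0` and
    :math:`\\sum_i p_i = 1`.

    Raises
    ------
    EmptyCommunityError
        If no species has positive abundance.
    ValueError
        If any abundance is negative.
    """
    q = _as_quantities(community)
    if q.size and (q < 0).any():
        raise ValueError("abundances must be nonnegative")
    q = q[q > 0]
    if q.size == 0:
        raise EmptyCommunityError("community has no positive abundances")
    return q / q.sum()


def hill_diversity(p, a: float) -> float:
    """Hill diversity (effective species number) of order ``a``.

    ``p`` may be a proportion vector or any community accepted by
    :func:`proportions`.  Orders within 1e-9 of 1 use the analytic
    limit ``exp(-sum p log p)``; ``a = inf`` uses ``1 / max(p)``.
    """
    p = np.asarray(p, dtype=float)
    if not (p.size and abs(p.sum() - 1.0) < 1e-9 and (p > 0).all()):
        p = proportions(p)
    if a < 0:
        raise ValueError(f"Hill order must be nonnegative, got {a}")
    if np.isinf(a):
        return float(1.0 / p.max())
    if abs(a - 1.0) < _UNIT_ORDER_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**a) ** (1.0 / (1.0 - a)))


def shannon_index(p) -> float:
    """Shannon entropy H' in nats; equals ``log(hill_diversity(p, 1))``."""
    return float(np.log(hill_diversity(p, 1.0)))


@dataclass(frozen=True)
class DiversityProfile:
    """Hill diversity evaluated along a grid of orders for one community."""

    orders: tuple[float, ...]
    values: tuple[float, ...]

    def __getitem__(self, a: float) -> float:
        return dict(zip(self.orders, self.values))[a]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.orders), name="diversity")


def diversity_profile(community, orders: Sequence[float] = HILL_ORDERS) -> DiversityProfile:
    """Evaluate the Hill series of one community on a grid of orders."""
    p = proportions(community)
    values = tuple(hill_diversity(p, float(a)) for a in orders)
    return DiversityProfile(tuple(float(a) for a in orders), values)


def alpha_gamma(communities: Iterable[Community], a: float) -> tuple[float, float]:
    """Whittaker partition: (gamma, alpha) diversity of order ``a``.

    gamma is the Hill diversity of the pooled (summed) abundances over
    all fields; alpha is the unweighted arithmetic mean of the
    per-field Hill diversities.

    Raises
    ------
    ValueError
        If the communities mix counts and biomass, or the list is empty.
    """
    communities = list(communities)
    if not communities:
        raise ValueError("need at least one community")
    bases = {c.basis for c in communities}
    if len(bases) > 1:
        raise ValueError(f"mixed abundance bases {sorted(bases)}; cannot pool")
    pooled: dict[str, float] = {}
    per_field = []
    for c in communities:
        for s, q in zip(c.species, c.quantity):
            pooled[s] = pooled.get(s, 0.0) + float(q)
        per_field.append(hill_diversity(proportions(c), a))
    gamma = hill_diversity(proportions(pooled), a)
    alpha = float(np.mean(per_field))
    return gamma, alpha


# ---------------------------------------------------------------------------
# tabular interface

def communities_from_long(df: pd.DataFrame, group_cols: Sequence[str],
                          species_col: str = "species",
                          quantity_col: str = "quantity",
                          basis: str = "counts") -> dict[tuple, Community]:
    """Aggregate a long survey table into one Community per group key.

    Quantities of the same species within a group are summed (pooling
    across blocks/plots before normalisation).
    """
    out: dict[tuple, Community] = {}
    for key, sub in df.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        agg = sub.groupby(species_col, sort=True)[quantity_col].sum()
        out[key] = Community(tuple(agg.index), tuple(float(v) for v in agg.values), basis)
    return out


def profile_table(communities: Mapping[tuple, Community],
                  group_cols: Sequence[str],
                  orders: Sequence[float] = HILL_ORDERS) -> pd.DataFrame:
    """Tidy table of Hill profiles: one row per group key x order."""
    rows = []
    for key, comm in communities.items():
        prof = diversity_profile(comm, orders)
        for a, v in zip(prof.orders, prof.values):
            rows.append(dict(zip(group_cols, key)) | {"order_a": a, "diversity": v})
    return pd.DataFrame(rows)
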