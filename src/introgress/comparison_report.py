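"""Pedigree expectations, the -log agreement metric, and group summaries.

Pedigree breed fractions propagate through a crossing scheme as exact
rational parental means: a composite such as Canchim is 5/8 Charolais + 3/8
Zebu by design, and the MA genetic group (Charolais bull x (1/2 Canchim +
1/2 Zebu) dam) is 21/32 = 65.625% Charolais.

Agreement between two per-sample composition vectors is summarized as

    D = -log_base( aggregate_i (a_i - b_i)^2 )

with a floor of 1e-12 inside the log; larger D means closer agreement, and
a conventional empirical threshold of 2 (mean squared difference 0.01 at
base 10) marks "highly similar" analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .errors import CyclicPedigreeError, ParameterError

DISTANCE_FLOOR = 1e-12
SIMILARITY_THRESHOLD = 2.0


@dataclass
class PedigreeNode:
    """A named animal/group with exact rational breed fractions."""

    name: str
    breed_fractions: dict  # breed -> Fraction, sums to 1
    parents: tuple | None = None

    def fraction(self, breed: str) -> Fraction:
        return self.breed_fractions.get(breed, Fraction(0))


def pedigree_expected_fraction(scheme: dict) -> dict[str, PedigreeNode]:
    """Exact expected breed fractions for every node of a mating graph.

    ``scheme`` maps node names to either a founder breed name (string) or a
    pair of parent node names.  Non-founder fractions are the exact rational
    mean of the parents'.  Cycles and missing parents raise structural
    errors.
    """
    nodes: dict[str, PedigreeNode] = {}
    state: dict[str, int] = {}

    def build(name: str) -> PedigreeNode:
        if state.get(name) == 1:
            raise CyclicPedigreeError(f"cycle through node {name!r}")
        if name in nodes:
            return nodes[name]
        if name not in scheme:
            raise ParameterError(f"node {name!r} missing from the scheme")
        state[name] = 1
        spec = scheme[name]
        if isinstance(spec, str):
            node = PedigreeNode(name, {spec: Fraction(1)}, None)
        else:
            p1, p2 = (build(p) for p in spec)
            breeds = set(p1.breed_fractions) | set(p2.breed_fractions)
            fracs = {
                b: (p1.fraction(b) + p2.fraction(b)) / 2 for b in sorted(breeds)
            }
            node = PedigreeNode(name, fracs, tuple(spec))
        state[name] = 2
        nodes[name] = node
        return node

    for name in scheme:
        build(name)
    return nodes


#: design breed fractions of the Canchim crossing schemes (exact rationals):
#: CA = 5/8 Charolais, MA = 21/32, C2 (CA x MA) = 41/64, C3 (MA x MA) = 21/32
CANCHIM_DESIGN = {
    "CA": Fraction(5, 8),
    "MA": Fraction(21, 32),
    "C2": Fraction(41, 64),
    "C3": Fraction(21, 32),
}


def composition_distance(
    comp_a,
    comp_b,
    base: float = 10.0,
    aggregate: str = "mean",
    eps: float = DISTANCE_FLOOR,
) -> float:
    """-log_base of the aggregated squared per-sample differences.

    ``aggregate`` is ``"mean"`` (default) or ``"sum"``.  Identical inputs
    hit the floor ``eps`` and return the capped maximum -log_base(eps).
    Symmetric; strictly decreasing as discrepancies grow (above the floor).
    """
    a = np.asarray(comp_a, dtype=float).ravel()
    b = np.asarray(comp_b, dtype=float).ravel()
    if a.size == 0 or a.shape != b.shape:
        raise ParameterError("need two equal-length, non-empty vectors")
    sq = (a - b) ** 2
    agg = sq.mean() if aggregate == "mean" else sq.sum()
    if aggregate not in ("mean", "sum"):
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    return -math.log(max(agg, eps)) / math.log(base)


def summarize_group_means(
    comp, groups, expected: dict | None = None
) -> pd.DataFrame:
    """Per-group mean, SD, min, max of a composition component.

    ``comp`` is a per-sample vector of one component (e.g. the taurine
    fraction); ``expected`` optionally maps group labels to their pedigree
    expectation, adding ``expected`` and signed ``deviation`` (mean -
    expectation) columns.  Unknown expected labels raise an error.
    """
    comp = np.asarray(comp, dtype=float).ravel()
    groups = np.asarray(groups)
    if comp.shape[0] != groups.shape[0]:
        raise ParameterError("comp and groups must have equal length")
    present = list(dict.fromkeys(groups))
    if expected is not None:
        unknown = set(expected) - set(str(g) for g in present)
        if unknown:
            raise ParameterError(f"unknown group label(s): {sorted(unknown)}")
    rows = []
    for grp in present:
        vals = comp[groups == grp]
        row = {
            "group": str(grp),
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": float(vals.std()),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
        if expected is not None and str(grp) in expected:
            exp = float(expected[str(grp)])
            row["expected"] = exp
            row["deviation"] = row["mean"] - exp
        rows.append(row)
    return pd.DataFrame(rows)


def method_agreement_table(
    compositions: dict, base: float = 10.0, aggregate: str = "mean"
) -> pd.DataFrame:
    """Pairwise -log agreement among named per-sample composition vectors.

    ``compositions`` maps a method name (e.g. "pedigree", "ml", "bayes",
    "regression") to its per-sample vector of the reference component.
    """
    names = list(compositions)
    out = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i == j:
                continue
            out.loc[a, b] = composition_distance(
                compositions[a], compositions[b], base=base, aggregate=aggregate
            )
    return out
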