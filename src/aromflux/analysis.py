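"""Post-FBA analytics.

Split-ratio analysis resolves, for one metabolite at steady state, which
reactions produce it and which consume it, and in what fractions of the total
turnover.  Activity tables classify reactions as active/inactive per
condition from their flux-variability ranges.  Flux-variation shares
attribute the across-condition spread of fluxes to reaction groups, and
hierarchical clustering of per-condition flux vectors exposes the oxic/anoxic
divide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .fba import FLUX_EPS, FluxRange, FluxSolution
from .model import MetabolicModel


@dataclass
class SplitRatioTable:
    """Producer/consumer flux ledger at one metabolite node.

    Each entry is (reaction id, flux contribution in mmol·gDW⁻¹·h⁻¹,
    fraction of turnover in percent).  At steady state total production
    equals total consumption (= turnover).
    """

    metabolite_id: str
    producers: list[tuple[str, float, float]]
    consumers: list[tuple[str, float, float]]
    turnover: float


def split_ratios(
    model: MetabolicModel,
    solution: FluxSolution,
    metabolite_id: str,
    threshold: float = FLUX_EPS,
) -> SplitRatioTable:
    """Fractional contributions of each reaction to a metabolite's turnover.

    A reaction produces the node when coefficient × flux > 0 (so reversible
    reactions contribute according to the sign of their flux, not their
    declared direction).  Zero turnover yields an empty table, not an error.
    """
    if not solution.optimal:
        raise ValueError("solution is not optimal")
    model.metabolite(metabolite_id)  # raises KeyError if absent
    produced: list[tuple[str, float]] = []
    consumed: list[tuple[str, float]] = []
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(metabolite_id)
        if coeff is None:
            continue
        contribution = coeff * solution.fluxes.get(rxn.id, 0.0)
        if contribution > threshold:
            produced.append((rxn.id, contribution))
        elif contribution < -threshold:
            consumed.append((rxn.id, -contribution))
    turnover = sum(c for _, c in produced)
    if turnover <= 0.0:
        return SplitRatioTable(metabolite_id, [], [], 0.0)
    consumption = sum(c for _, c in consumed)
    producers = [(rid, c, 100.0 * c / turnover) for rid, c in
                 sorted(produced, key=lambda t: -t[1])]
    consumers = [(rid, c, 100.0 * c / consumption) for rid, c in
                 sorted(consumed, key=lambda t: -t[1])]
    return SplitRatioTable(metabolite_id, producers, consumers, turnover)


@dataclass
class ActivityMatrix:
    """Boolean reactions × conditions table of flux-range activity."""

    table: pd.DataFrame  # index: reaction ids, columns: condition labels
    always_active: pd.Series  # boolean per reaction

    @property
    def n_always_active(self) -> int:
        return int(self.always_active.sum())


def activity_table(
    ranges: list[FluxRange],
    threshold: float = FLUX_EPS,
) -> ActivityMatrix:
    """A reaction is active under a condition when its FVA range is not
    identically zero beyond *threshold*."""
    if not ranges:
        raise ValueError("need at least one FluxRange")
    ref = set(ranges[0].ranges)
    for fr in ranges[1:]:
        if set(fr.ranges) != ref:
            diff = sorted(set(fr.ranges) ^ ref)
            raise ValueError(f"mismatched reaction sets; symmetric difference: {diff}")
    rids = sorted(ref)
    labels = []
    cols = {}
    for i, fr in enumerate(ranges):
        label = fr.condition_label or f"condition_{i}"
        labels.append(label)
        cols[label] = [
            abs(fr.ranges[rid][0]) > threshold or abs(fr.ranges[rid][1]) > threshold
            for rid in rids
        ]
    table = pd.DataFrame(cols, index=rids)
    return ActivityMatrix(table=table, always_active=table.all(axis=1))


def flux_variation_shares(
    matrix: pd.DataFrame,
    groups: dict[str, list[str]],
) -> tuple[dict[str, float], float]:
    """Share of total across-condition flux variation carried by each group.

    ``matrix`` is reactions × conditions.  Variation of a reaction is its
    max minus min flux across conditions; a group's share is its summed
    variation over the total across *all* reactions in the matrix.  Groups
    must not overlap.  If nothing varies, shares are NaN (flagged by the
    returned total of 0).
    """
    seen: set[str] = set()
    for name, rids in groups.items():
        overlap = seen & set(rids)
        if overlap:
            raise ValueError(f"group {name!r} overlaps previous groups: {sorted(overlap)}")
        missing = set(rids) - set(matrix.index)
        if missing:
            raise ValueError(f"group {name!r} references unknown reactions: {sorted(missing)}")
        seen |= set(rids)
    variation = matrix.max(axis=1) - matrix.min(axis=1)
    total = float(variation.sum())
    if total == 0.0:
        return {name: float("nan") for name in groups}, 0.0
    shares = {name: float(variation.loc[rids].sum()) / total for name, rids in groups.items()}
    return shares, total


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy linkage encoding of the merges
    labels: list[str]
    two_group_cut: dict[str, int]  # condition label -> 1 or 2

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_conditions(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "ward",
    column_scale: dict[str, float] | None = None,
) -> Dendrogram:
    """Hierarchically cluster conditions (columns) by their flux vectors.

    ``column_scale`` optionally divides each condition's fluxes by a
    normalizer (e.g. substrate carbon uptake) so uptake magnitude does not
    dominate the distances.  Deterministic given metric/method and column
    order; the flat cut at two groups separates the top-level split.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 conditions to cluster")
    data = matrix.copy()
    if column_scale is not None:
        for label in data.columns:
            scale = column_scale.get(label)
            if not scale:
                raise ValueError(f"missing/zero scale for condition {label!r}")
            data[label] = data[label] / scale
    values = data.to_numpy().T  # conditions as observations
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(data.to_numpy()))
        r, c = bad[0]
        raise ValueError(
            f"non-finite flux for reaction {data.index[r]!r} under {data.columns[c]!r}"
        )
    dists = pdist(values, metric=metric)
    Z = hierarchy.linkage(dists, method=method)
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    labels = list(data.columns)
    return Dendrogram(
        linkage_matrix=Z,
        labels=labels,
        two_group_cut=dict(zip(labels, (int(x) for x in flat))),
    )


def carbon_uptake_scale(
    solutions: dict[str, tuple["MetabolicModel", FluxSolution]],
) -> dict[str, float]:
    """Per-condition substrate carbon uptake (mmol C·gDW⁻¹·h⁻¹).

    The recommended ``column_scale`` for :func:`cluster_conditions`: dividing
    each condition's fluxes by its carbon uptake stops substrates of
    different carbon content (or uptake magnitude) from dominating the
    distances.  ``solutions`` maps condition label -> (bounded model,
    optimal solution with its condition attached).
    """
    scale: dict[str, float] = {}
    for label, (model, sol) in solutions.items():
        if sol.condition is None:
            raise ValueError(f"solution {label!r} carries no condition")
        exchange = model.reaction(sol.condition.substrate_exchange)
        (mid,) = exchange.stoichiometry
        met = model.metabolite(mid)
        n_c = met.formula.get("C", 0.0) if met.formula else 0.0
        if n_c <= 0:
            raise ValueError(f"substrate of {label!r} has no carbon formula")
        scale[label] = abs(sol.fluxes[exchange.id]) * n_c
    return scale


def newick(dendrogram: Dendrogram) -> str:
    """Serialize the merge tree in nested-pair (newick) format with heights."""
    Z = dendrogram.linkage_matrix
    labels = dendrogram.labels
    n = len(labels)

    def _node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        return f"({_node(int(a))},{_node(int(b))}):{h:.6g}"

    return _node(n + len(Z) - 1) + ";"
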