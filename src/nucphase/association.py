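"""Association between phasing clusters and genomic factors.

A factor (Pol II occupancy, NDR length, AT ratio, ...) is binarized into
equal halves at its median (-1 = low, +1 = high); the two phasing clusters
are balanced to equal size beforehand. A zero-hidden-layer perceptron with a
Hebbian weight then measures the interdependence: for a single factor the
weight is exactly the agreement rate minus the disagreement rate between
factor group and cluster, and the prediction-accuracy ratio against the 0.5
chance line is the association readout. This is a descriptive correlation
measure computed on the training genes, not a predictive model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BinarizedFactor:
    groups: pd.Series  # gene -> -1 or +1
    name: str
    rule: str


@dataclass
class AssociationResult:
    factors: list[str]
    weights: np.ndarray
    accuracy: float
    n_genes: int


def binarize_factor(
    values: pd.Series,
    rule: str | dict = "median",
    name: str | None = None,
) -> BinarizedFactor:
    """Split a factor into two groups of (as near as ties allow) equal size.

    Numeric rule 'median': values <= median go to -1, values above to +1;
    if ties at the median leave the groups more than 10% apart in size a
    warning is emitted. A dict rule maps categories explicitly to -1/+1.
    """
    values = pd.Series(values)
    name = name or str(values.name or "factor")
    if isinstance(rule, dict):
        unknown = set(values.dropna().unique()) - set(rule)
        if unknown:
            raise ValueError(f"{name}: categories without a mapping: {sorted(unknown)}")
        groups = values.map(rule).astype(float)
        if not groups.dropna().isin([-1, 1]).all():
            raise ValueError(f"{name}: category map must assign -1 or +1")
        return BinarizedFactor(groups=groups, name=name, rule="categorical")
    if rule != "median":
        raise ValueError(f"unknown binarization rule {rule!r}")
    numeric = pd.to_numeric(values)
    if numeric.nunique() < 2:
        raise ValueError(f"{name}: all values identical, cannot binarize")
    med = numeric.median()
    groups = pd.Series(np.where(numeric <= med, -1.0, 1.0), index=values.index)
    n_low, n_high = int((groups == -1).sum()), int((groups == 1).sum())
    if abs(n_low - n_high) > 0.1 * len(groups):
        warnings.warn(
            f"{name}: median ties leave groups of size {n_low}/{n_high}"
        )
    return BinarizedFactor(groups=groups, name=name, rule="median")


def hebbian_association(
    cluster_labels: np.ndarray,
    factors: BinarizedFactor | list[BinarizedFactor],
    zero_activation_class: int = 0,
) -> AssociationResult:
    """Hebbian-trained perceptron association between clusters and factors.

    Per factor j the weight is w_j = (N_agree - N_disagree)/N, where a gene
    agrees when factor group and cluster are both low (-1, 0) or both high
    (+1, 1). The output neuron fires 1 when sum_j w_j x_j is positive; an
    activation of exactly zero maps to ``zero_activation_class`` (default 0,
    i.e. zero counts as non-positive). Accuracy is the fraction of genes
    whose output matches their cluster.
    """
    labels = np.asarray(cluster_labels)
    if not np.isin(labels, [0, 1]).all():
        raise ValueError("cluster labels must be 0/1")
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if abs(n0 - n1) > 1:
        raise ValueError(
            f"clusters are unbalanced ({n0} vs {n1}); run balance_clusters first"
        )
    if isinstance(factors, BinarizedFactor):
        factors = [factors]
    X = np.column_stack([np.asarray(f.groups, dtype=float) for f in factors])
    if np.isnan(X).any():
        raise ValueError("factor groups contain missing values; drop those genes")
    y = 2.0 * labels - 1.0  # cluster 0 -> low (-1), cluster 1 -> high (+1)
    weights = (X * y[:, None]).mean(axis=0)
    activation = X @ weights
    output = np.where(
        activation > 0, 1, np.where(activation < 0, 0, zero_activation_class)
    )
    accuracy = float((output == labels).mean())
    return AssociationResult(
        factors=[f.name for f in factors],
        weights=weights,
        accuracy=accuracy,
        n_genes=labels.size,
    )


def association_report(
    cluster_labels: np.ndarray,
    factor_table: pd.DataFrame,
    factor_names: list[str] | None = None,
    combinations: list[tuple[str, str]] = (),
    category_maps: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Accuracy table for single factors and requested factor pairs.

    Numeric factors are median-binarized; categorical factors need an entry
    in ``category_maps`` (name -> {category: -1 or +1}).
    """
    if factor_names is None:
        factor_names = list(factor_table.columns)
    unknown = set(factor_names) - set(factor_table.columns)
    for pair in combinations:
        unknown |= set(pair) - set(factor_table.columns)
    if unknown:
        raise KeyError(f"unknown factor name(s): {sorted(unknown)}")
    category_maps = category_maps or {}
    binarized = {}
    for name in set(factor_names) | {f for pair in combinations for f in pair}:
        col = factor_table[name]
        rule = category_maps.get(name, "median")
        if not pd.api.types.is_numeric_dtype(col) and not isinstance(rule, dict):
            raise ValueError(f"{name}: categorical factor needs a category map")
        binarized[name] = binarize_factor(col, rule=rule, name=name)
    rows = []
    for name in factor_names:
        res = hebbian_association(cluster_labels, binarized[name])
        rows.append(
            {"factors": name, "weights": res.weights[0],
             "accuracy": res.accuracy, "n_genes": res.n_genes}
        )
    for pair in combinations:
        res = hebbian_association(cluster_labels, [binarized[f] for f in pair])
        rows.append(
            {"factors": "+".join(pair), "weights": tuple(res.weights),
             "accuracy": res.accuracy, "n_genes": res.n_genes}
        )
    return pd.DataFrame(rows)
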