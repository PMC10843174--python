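"""End-to-end orchestration: profiles -> clusters -> fPCA -> boundary -> report.

A strain is analysed from two replicate coverage tracks sharing one +1
annotation set. Per replicate the pipeline restricts to large genes
(> 1000 bp) by default, clusters the profiles by correlation distance,
checks cluster significance, fits the functional model and the SVM boundary.
Strains are then compared to a reference through the replicate-calibrated
s statistic of the boundary slopes.

All randomness flows from one master seed, expanded deterministically per
stage, so a rerun with the same configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nucphase.boundary import BoundaryFit, fit_boundary, s_statistic
from nucphase.clustering import (
    ClusterResult,
    SignificanceResult,
    cluster_significance,
    kmeans_correlation,
    pearson_matrix,
    select_k_silhouette,
)
from nucphase.fpca import BasisConfig, FunctionalModel, fit_functional_representation, fpca_decompose
from nucphase.profile_io import ProfileSet, extract_windows, read_coverage


@dataclass(frozen=True)
class PipelineConfig:
    subset: str = "large"  # all | small | large | very_large
    k: int = 2
    select_k: bool = False
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_init: int = 25
    basis: BasisConfig = field(default_factory=BasisConfig)
    n_components: int = 2
    run_significance: bool = True
    n_random: int = 500
    subsample: int = 500
    alpha: float = 0.05
    svm_regularization: float = 1.0
    seed: int = 0


@dataclass
class StrainRun:
    strain: str
    replicate: str
    profiles: ProfileSet
    clusters: ClusterResult
    model: FunctionalModel
    boundary: BoundaryFit
    significance: SignificanceResult | None


def _stage_seeds(master_seed: int, n: int) -> list[int]:
    """Expand the master seed into per-stage integer seeds (< 2^31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n)]


def _subset_profiles(profiles: ProfileSet, subset: str) -> ProfileSet:
    if subset == "all":
        return profiles
    classes = profiles.size_classes()
    if subset == "small":
        mask = (classes["size_class"] == "small").to_numpy()
    elif subset == "large":
        mask = (classes["size_class"] == "large").to_numpy()
    elif subset == "very_large":
        mask = classes["very_large"].to_numpy()
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not mask.any():
        raise ValueError(f"no genes in subset {subset!r}")
    return profiles.subset(mask)


def run_replicate(
    profiles: ProfileSet,
    config: PipelineConfig = PipelineConfig(),
    strain: str = "strain",
    replicate: str = "A",
) -> StrainRun:
    """Full single-replicate pipeline on the configured gene subset."""
    sub = _subset_profiles(profiles, config.subset)
    seeds = _stage_seeds(config.seed, 3)
    if config.select_k:
        k, _ = select_k_silhouette(sub, config.k_range, n_init=config.n_init, seed=seeds[0])
    else:
        k = config.k
    clusters = kmeans_correlation(sub, k=k, n_init=config.n_init, seed=seeds[0])
    significance = None
    if config.run_significance and k == 2:
        corr = pearson_matrix(sub)
        significance = cluster_significance(
            corr,
            clusters.labels,
            n_random=config.n_random,
            subsample=config.subsample,
            seed=seeds[1],
            alpha=config.alpha,
        )
    smoothed = fit_functional_representation(sub, config.basis)
    model = fpca_decompose(smoothed, K=config.n_components)
    bd = fit_boundary(
        model.scores[:, :2], clusters.labels, regularization=config.svm_regularization
    )
    return StrainRun(
        strain=strain,
        replicate=replicate,
        profiles=sub,
        clusters=clusters,
        model=model,
        boundary=bd,
        significance=significance,
    )


def run_strain(
    replicate_a,
    replicate_b,
    annotations=None,
    config: PipelineConfig = PipelineConfig(),
    strain: str = "strain",
    one_based: bool = False,
) -> tuple[StrainRun, StrainRun]:
    """Run both replicates of a strain.

    ``replicate_a``/``replicate_b`` may be coverage file paths (annotations
    required) or ready ProfileSets. Both replicates are mandatory: the
    s statistic needs two slopes per strain.
    """
    if replicate_a is None or replicate_b is None:
        raise ValueError("both replicates are required (the s statistic needs two slopes)")
    runs = []
    for rep_name, rep in (("A", replicate_a), ("B", replicate_b)):
        if isinstance(rep, ProfileSet):
            profiles = rep
        else:
            if annotations is None:
                raise ValueError("annotations are required when passing coverage paths")
            coverage = rep if hasattr(rep, "values") and not isinstance(rep, str) else read_coverage(rep)
            profiles = extract_windows(coverage, annotations, one_based=one_based)
        runs.append(run_replicate(profiles, config, strain=strain, replicate=rep_name))
    return runs[0], runs[1]


def comparison_table(
    slopes: dict[str, tuple[float, float]],
    reference: str,
    absolute_denominator: bool = True,
) -> pd.DataFrame:
    """Boundary-slope comparison report from per-strain replicate slopes.

    One row per strain: replicate slopes, mean absolute slope, the s
    statistic against the reference strain (0 for the reference itself by
    construction) and the s > 1 notability flag. Means and s are rounded to
    4 decimals for reporting.
    """
    if reference not in slopes:
        raise KeyError(f"reference strain {reference!r} missing from slopes")
    ref = slopes[reference]
    rows = []
    for strain, (a, b) in slopes.items():
        st = s_statistic((a, b), ref, absolute_denominator=absolute_denominator)
        rows.append(
            {
                "strain": strain,
                "slope_A": a,
                "slope_B": b,
                "mean_mu": round(st.mean_mutant, 4),
                "s": round(st.s, 4) if np.isfinite(st.s) else st.s,
                "notable": st.notable,
            }
        )
    return pd.DataFrame(rows).set_index("strain")


def compare_strains(
    runs: dict[str, tuple[StrainRun, StrainRun]],
    reference: str,
    absolute_denominator: bool = True,
) -> pd.DataFrame:
    """Comparison report from full strain runs (slopes from the SVM fits)."""
    if reference not in runs:
        raise KeyError(f"reference strain {reference!r} missing")
    slopes = {
        strain: (pair[0].boundary.slope, pair[1].boundary.slope)
        for strain, pair in runs.items()
    }
    table = comparison_table(slopes, reference, absolute_denominator=absolute_denominator)
    table["mean_p_A"] = [
        runs[s][0].significance.mean_p if runs[s][0].significance else np.nan
        for s in table.index
    ]
    table["mean_p_B"] = [
        runs[s][1].significance.mean_p if runs[s][1].significance else np.nan
        for s in table.index
    ]
    return table
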