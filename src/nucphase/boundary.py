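"""Cluster-boundary quantification in fPC score space.

The two correlation clusters are linearly separable in the (zeta1, zeta2)
score plane; the dividing line is fitted with a linear SVM. Only the slope m
of that line carries meaning here (eigenfunction signs are arbitrary, so only
|m| is compared): it states how much each eigenfunction contributes to the
discrimination. Replicate-to-replicate slope variability calibrates the
s statistic

    s(i) = (mean_i - mean_ref)^2 / |(|mA|-|mB|)_i * (|mA|-|mB|)_ref|

where mean is the average absolute slope of the two replicates; s > 1 flags a
notable boundary change, meaning the strain-vs-reference difference exceeds
the within-replicate variability. The slope also defines the combined
discriminator function phi' = (m*phi1 + phi2)/(m+1), whose band around the
mean shows which profile positions drive the classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class BoundaryFit:
    slope: float
    intercept: float
    angle_degrees: float  # 0 = pure fPC2 discrimination, 90 = pure fPC1
    svm_regularization: float
    training_accuracy: float

    @property
    def abs_slope(self) -> float:
        return abs(self.slope)


@dataclass
class SStat:
    s: float
    mean_mutant: float
    mean_reference: float

    @property
    def notable(self) -> bool:
        return self.s > 1.0


@dataclass
class DiscriminatorFunction:
    phi_prime: np.ndarray
    band_scale: float
    band_upper: np.ndarray
    band_lower: np.ndarray


@dataclass
class JSSeparability:
    js_fpc1: float
    js_fpc2: float
    n_bins: int


def fit_boundary(
    scores: np.ndarray, labels: np.ndarray, regularization: float = 1.0
) -> BoundaryFit:
    """Linear SVM boundary in (zeta1, zeta2) space.

    The slope is d(zeta2)/d(zeta1) along the decision line; a near-vertical
    boundary (separation almost purely along zeta1) yields a very large
    slope, which is why the angle parameterization is reported alongside.
    No feature scaling is applied: the two score axes are already in the same
    units.
    """
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2 or min((labels == u).sum() for u in uniq) < 2:
        raise ValueError("need two clusters with at least 2 genes each")
    if np.allclose(scores, scores[0]):
        raise ValueError("degenerate scores: all genes identical in score space")
    svm = SVC(kernel="linear", C=regularization)
    svm.fit(scores, labels)
    w1, w2 = svm.coef_[0]
    b = svm.intercept_[0]
    if w2 == 0:
        slope = np.inf
        intercept = np.nan
        logger.warning("fit_boundary: vertical boundary, slope reported as inf")
    else:
        slope = -w1 / w2
        intercept = -b / w2
    angle = float(np.degrees(np.arctan2(abs(w1), abs(w2))))
    return BoundaryFit(
        slope=float(slope),
        intercept=float(intercept),
        angle_degrees=angle,
        svm_regularization=regularization,
        training_accuracy=float(svm.score(scores, labels)),
    )


def s_statistic(
    mutant_slopes: tuple[float, float],
    reference_slopes: tuple[float, float],
    absolute_denominator: bool = True,
) -> SStat:
    """Replicate-calibrated boundary-change statistic.

    Means are taken over absolute slopes. By default the denominator (the
    product of within-strain replicate differences) enters as an absolute
    value so that s is non-negative; set ``absolute_denominator=False`` for
    the literal signed product.
    """
    ma, mb = (abs(float(v)) for v in mutant_slopes)
    ra, rb = (abs(float(v)) for v in reference_slopes)
    if not all(np.isfinite([ma, mb, ra, rb])):
        raise ValueError("all four slopes must be finite")
    mean_mut = (ma + mb) / 2.0
    mean_ref = (ra + rb) / 2.0
    numerator = (mean_mut - mean_ref) ** 2
    denominator = (ma - mb) * (ra - rb)
    if absolute_denominator:
        denominator = abs(denominator)
    if denominator == 0:
        if numerator == 0:
            s = 0.0
        else:
            warnings.warn("s_statistic: zero replicate variability, s is infinite")
            s = np.inf
    else:
        s = numerator / denominator
    return SStat(s=float(s), mean_mutant=mean_mut, mean_reference=mean_ref)


def combined_discriminator(
    model, m: float, band_scale: float = 5.0
) -> DiscriminatorFunction:
    """Combine the two leading eigenfunctions as implied by the boundary slope:
    phi' = (m*phi1 + phi2)/(m+1); the band mean +/- band_scale*phi' shows the
    position-specific impact of the discriminator."""
    if model.K < 2:
        raise ValueError("model must have at least 2 components")
    if m == -1:
        raise ValueError("m = -1 makes the combination singular; use |m| instead")
    phi1, phi2 = model.components[0], model.components[1]
    phi_prime = (m * phi1 + phi2) / (m + 1.0)
    mu = model.mean_function
    return DiscriminatorFunction(
        phi_prime=phi_prime,
        band_scale=band_scale,
        band_upper=mu + band_scale * phi_prime,
        band_lower=mu - band_scale * phi_prime,
    )


def js_separability(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 50
) -> JSSeparability:
    """Jensen-Shannon distance between the cluster score distributions.

    Per axis, both clusters are histogrammed on shared equal-width bins over
    the pooled range; the base-2 JS distance (square root of the divergence)
    lies in [0, 1]: 0 for identical distributions, 1 for disjoint supports.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=float)[:, :2]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2 or min((labels == u).sum() for u in uniq) < 2:
        raise ValueError("need two clusters with at least 2 genes each")
    out = []
    for axis in range(2):
        col = scores[:, axis]
        edges = np.linspace(col.min(), col.max(), n_bins + 1)
        p, _ = np.histogram(col[labels == uniq[0]], bins=edges)
        q, _ = np.histogram(col[labels == uniq[1]], bins=edges)
        out.append(float(jensenshannon(p, q, base=2)))
    return JSSeparability(js_fpc1=out[0], js_fpc2=out[1], n_bins=n_bins)


def cluster_median_curves(model, labels: np.ndarray) -> dict:
    """Per-cluster median profile: the K=2 reconstruction evaluated at the
    cluster's median (zeta1, zeta2)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("expected exactly 2 clusters")
    curves = {}
    for lab in uniq:
        med = np.median(model.scores[labels == lab, :2], axis=0)
        curves[lab] = (
            model.mean_function
            + med[0] * model.components[0]
            + med[1] * model.components[1]
        )
    return curves
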