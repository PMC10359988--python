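"""Cluster-based copy-number genotyping of a CNV region.

Per region, every sample contributes one delta value (median target LRR
minus median flank LRR). Carriers of deletion or duplication alleles form
satellite clusters left or right of the diploid reference cluster. A
one-dimensional Gaussian mixture over delta, with the number of components
selected by BIC, reproduces that visual cluster separation deterministically
and without hard cut-offs. Components are mapped to copy-number states 0-4
by proximity to canonical LRR shifts, and every call can be confirmed or
contradicted by the BAF pattern inside the target (deletions have no
di-allelic heterozygotes; single-copy duplications show heterozygotes at
1/3 and 2/3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .datatypes import CNVGenotype, RegionSummary

__all__ = [
    "DeltaMixtureGenotyper",
    "ClusterModel",
    "NoReferenceClusterError",
    "CANONICAL_SHIFTS",
    "fit_clusters",
    "assign_genotype",
    "confirm_with_baf",
    "delta_vs_het_table",
    "genotype_cohort",
]

#: canonical delta shift per copy-number state: CN1/CN3 anchored on observed
#: cluster centers near -0.5 and +0.25; CN0/CN4 from standard LRR theory.
CANONICAL_SHIFTS: dict[int, float] = {0: -2.0, 1: -0.50, 2: 0.0, 3: 0.25, 4: 0.45}


class NoReferenceClusterError(ValueError):
    """No mixture component centers near delta = 0: the region has no
    identifiable diploid reference cluster and is unusable."""


def _label_components(centers: np.ndarray, shifts: dict[int, float],
                      tolerance: float) -> list[int | None]:
    """CN label per component center: the nearest canonical shift, provided
    the center lies within ``tolerance`` of it (otherwise None, producing
    no-calls). Several components may share a label — a cluster split by the
    mixture fit merges back into one copy-number state. Distance ties break
    toward the label nearer the diploid state."""
    labels: list[int | None] = []
    for c in centers:
        best = min(shifts, key=lambda cn: (abs(c - shifts[cn]), abs(cn - 2)))
        labels.append(best if abs(c - shifts[best]) <= tolerance else None)
    return labels


class DeltaMixtureGenotyper(BaseEstimator):
    """1-D Gaussian-mixture genotyper over per-sample delta values.

    Parameters
    ----------
    max_components : int, default=5
        BIC model selection runs over 1..max_components mixture components.
    canonical_shifts : dict or None
        Copy-number state -> expected delta shift (LRR units). None uses
        ``CANONICAL_SHIFTS``.
    reference_tolerance : float, default=0.1
        The component nearest zero must lie within +/- this value of zero,
        otherwise fitting raises :class:`NoReferenceClusterError`.
    label_tolerance : float, default=0.1
        A satellite component receives a CN label only when its center lies
        within this distance of a canonical shift; unlabelled components
        yield no-calls (ambiguous clusters are not forced into a state).
    membership_threshold : float, default=0.95
        Samples whose maximum posterior membership falls below this value
        are reported as no-calls by :func:`assign_genotype`.
    n_init : int, default=10
        Restarts per mixture fit.
    random_state : int or None
        Seed; fits are deterministic given a fixed value.

    Attributes
    ----------
    gmm_ : fitted ``sklearn.mixture.GaussianMixture`` (components sorted by mean)
    n_components_ : selected number of components
    means_ : 1-d array of component centers, ascending
    weights_ : component weights
    cn_labels_ : list mapping component index -> CN state (None = unlabelled)
    reference_component_ : index of the CN=2 component
    """

    def __init__(self, max_components: int = 5, canonical_shifts: dict | None = None,
                 reference_tolerance: float = 0.1, label_tolerance: float = 0.1,
                 membership_threshold: float = 0.95,
                 n_init: int = 10, random_state: int | None = None):
        self.max_components = max_components
        self.canonical_shifts = canonical_shifts
        self.reference_tolerance = reference_tolerance
        self.label_tolerance = label_tolerance
        self.membership_threshold = membership_threshold
        self.n_init = n_init
        self.random_state = random_state

    def _shifts(self) -> dict[int, float]:
        return dict(CANONICAL_SHIFTS if self.canonical_shifts is None
                    else self.canonical_shifts)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of delta values")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite delta values; drop them first")
        if X.shape[0] < 20:
            raise ValueError(f"need >= 20 samples to fit clusters, got {X.shape[0]}")

        best, best_bic = None, np.inf
        for k in range(1, self.max_components + 1):
            gmm = GaussianMixture(n_components=k, n_init=self.n_init,
                                  covariance_type="full",
                                  random_state=self.random_state)
            gmm.fit(X)
            bic = gmm.bic(X)
            if bic < best_bic:
                best, best_bic = gmm, bic
        # sort components by center so labels are monotone in CN
        order = np.argsort(best.means_[:, 0])
        best.means_ = best.means_[order]
        best.covariances_ = best.covariances_[order]
        best.weights_ = best.weights_[order]
        best.precisions_ = best.precisions_[order]
        best.precisions_cholesky_ = best.precisions_cholesky_[order]

        means = best.means_[:, 0]
        ref = int(np.argmin(np.abs(means)))
        if abs(means[ref]) > self.reference_tolerance:
            raise NoReferenceClusterError(
                f"no component center within +/-{self.reference_tolerance} of 0 "
                f"(nearest: {means[ref]:.3f}); region unusable")

        shifts = self._shifts()
        labels = _label_components(means, shifts, self.label_tolerance)
        labels[ref] = 2

        self.gmm_ = best
        self.n_components_ = best.n_components
        self.means_ = means
        self.weights_ = best.weights_
        self.cn_labels_ = labels
        self.reference_component_ = ref
        self.bic_ = float(best_bic)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "gmm_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.gmm_.predict_proba(X)

    def predict_components(self, X) -> np.ndarray:
        check_is_fitted(self, "gmm_")
        return np.argmax(self.predict_proba(X), axis=1)

    def predict(self, X) -> np.ndarray:
        """Copy-number state per sample; -1 for an unlabelled component."""
        comps = self.predict_components(X)
        lab = np.array([-1 if l is None else l for l in self.cn_labels_])
        return lab[comps]


@dataclass
class ClusterModel:
    """Fitted cluster model of one region and one flank."""

    region_id: str
    flank: str  # '5prime' or '3prime'
    estimator: DeltaMixtureGenotyper
    cluster_centers: list[float] = field(init=False)
    cn_labels: dict[int, int | None] = field(init=False)
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.cluster_centers = [float(m) for m in self.estimator.means_]
        self.cn_labels = dict(enumerate(self.estimator.cn_labels_))
        self.n_clusters = self.estimator.n_components_


_FLANK_ATTR = {"5prime": "delta5", "3prime": "delta3"}


def fit_clusters(summaries: list[RegionSummary], flank: str,
                 random_state: int | None = 0, **params) -> ClusterModel:
    """Fit the delta mixture of one region from its per-sample summaries."""
    if flank not in _FLANK_ATTR:
        raise ValueError("flank must be '5prime' or '3prime'")
    region_ids = {s.region_id for s in summaries}
    if len(region_ids) != 1:
        raise ValueError(f"summaries span several regions: {sorted(region_ids)}")
    deltas = np.array([getattr(s, _FLANK_ATTR[flank]) for s in summaries])
    deltas = deltas[np.isfinite(deltas)]
    est = DeltaMixtureGenotyper(random_state=random_state, **params)
    est.fit(deltas[:, None])
    return ClusterModel(region_id=region_ids.pop(), flank=flank, estimator=est)


def _flank_call(model: ClusterModel, delta: float) -> tuple[int | None, float]:
    """(cn, membership probability) for one flank; cn None when the delta is
    missing, the component unlabelled, or the membership below threshold."""
    if not np.isfinite(delta):
        return None, float("nan")
    probs = model.estimator.predict_proba([[delta]])[0]
    comp = int(np.argmax(probs))
    prob = float(probs[comp])
    cn = model.cn_labels[comp]
    if cn is None or prob < model.estimator.membership_threshold:
        return None, prob
    return cn, prob


def assign_genotype(sample_summary: RegionSummary, model5: ClusterModel,
                    model3: ClusterModel) -> CNVGenotype:
    """Combine the two per-flank cluster assignments into one genotype.

    When both flanks call the same CN the genotype is confident
    (flank_agreement True); on disagreement the flank with higher membership
    probability wins and the genotype is flagged. A sample with no usable
    flank becomes a no-call."""
    cn5, p5 = _flank_call(model5, sample_summary.delta5)
    cn3, p3 = _flank_call(model3, sample_summary.delta3)
    d5, d3 = sample_summary.delta5, sample_summary.delta3

    if cn5 is None and cn3 is None:
        probs = [p for p in (p5, p3) if np.isfinite(p)]
        return CNVGenotype(sample_summary.sample_id, sample_summary.region_id,
                           cn=None, delta_used=d5 if np.isfinite(d5) else d3,
                           flank_agreement=None,
                           membership_prob=max(probs) if probs else float("nan"))
    if cn5 is not None and cn3 is not None:
        if cn5 == cn3:
            use5 = p5 >= p3
            return CNVGenotype(sample_summary.sample_id, sample_summary.region_id,
                               cn=cn5, delta_used=d5 if use5 else d3,
                               flank_agreement=True,
                               membership_prob=max(p5, p3))
        use5 = p5 >= p3
        return CNVGenotype(sample_summary.sample_id, sample_summary.region_id,
                           cn=cn5 if use5 else cn3,
                           delta_used=d5 if use5 else d3,
                           flank_agreement=False,
                           membership_prob=max(p5, p3))
    if cn5 is not None:
        return CNVGenotype(sample_summary.sample_id, sample_summary.region_id,
                           cn=cn5, delta_used=d5, flank_agreement=None,
                           membership_prob=p5)
    return CNVGenotype(sample_summary.sample_id, sample_summary.region_id,
                       cn=cn3, delta_used=d3, flank_agreement=None,
                       membership_prob=p3)


def confirm_with_baf(genotype: CNVGenotype, summary: RegionSummary) -> CNVGenotype:
    """Confirm or contradict a called genotype from the target BAF pattern.

    Hemizygous deletions (CN 1) must show no di-allelic heterozygote; CN 3
    must show tri-allelic heterozygotes dominating di-allelic ones; the
    diploid state must show at least one di-allelic heterozygote. Two states
    are uninformative: CN 4 (balanced duplication heterozygotes sit at BAF
    0.5, indistinguishable from diploid) and CN 0 (no alleles remain to
    genotype, so the reported BAF is pure noise and supports no category
    counts either way)."""
    if genotype.cn is None:
        raise ValueError("cannot BAF-confirm a no-call genotype")
    cn = genotype.cn
    di, tri = summary.n_di_het, summary.n_tri_het
    if cn in (0, 4):
        status = "uninformative"
    elif cn == 1:
        status = "confirmed" if di == 0 else "contradicted"
    elif cn == 2:
        status = "confirmed" if di >= 1 else "contradicted"
    elif cn == 3:
        status = "confirmed" if (tri >= 1 and tri > di) else "contradicted"
    else:
        raise ValueError(f"unknown copy-number state {cn}")
    genotype.baf_confirmed = status
    return genotype


def delta_vs_het_table(summaries: list[RegionSummary],
                       model: ClusterModel) -> pd.DataFrame:
    """Validation table: delta against heterozygous-SNP counts, one row per
    sample, with the model's CN assignment. Deletion clusters should show
    n_di_het = 0 and duplication clusters n_tri_het > 0."""
    attr = _FLANK_ATTR[model.flank]
    rows = []
    for s in summaries:
        delta = getattr(s, attr)
        cn, _ = _flank_call(model, delta)
        rows.append({"sample_id": s.sample_id, "delta": delta,
                     "n_di_het": s.n_di_het, "n_tri_het": s.n_tri_het,
                     "cn": cn})
    return pd.DataFrame(rows)


def genotype_cohort(summaries: pd.DataFrame, random_state: int = 0,
                    **params) -> tuple[pd.DataFrame, dict]:
    """Fit both flank models per region and genotype every sample.

    Parameters
    ----------
    summaries : DataFrame in the layout of ``summarize_cohort``.

    Returns
    -------
    genotypes : DataFrame with one row per (sample, region).
    models : dict mapping (region_id, flank) -> ClusterModel.
    """
    genotypes, models = [], {}
    for region_id, group in summaries.groupby("region_id", sort=True):
        rs = [RegionSummary(**row) for row in group.to_dict("records")]
        m5 = fit_clusters(rs, "5prime", random_state=random_state, **params)
        m3 = fit_clusters(rs, "3prime", random_state=random_state, **params)
        models[(region_id, "5prime")] = m5
        models[(region_id, "3prime")] = m3
        for s in rs:
            g = assign_genotype(s, m5, m3)
            if g.cn is not None:
                g = confirm_with_baf(g, s)
            genotypes.append({
                "sample_id": g.sample_id, "region_id": g.region_id,
                "cn": g.cn, "delta_used": g.delta_used,
                "baf_confirmed": g.baf_confirmed,
                "flank_agreement": g.flank_agreement,
                "membership_prob": g.membership_prob,
            })
    return pd.DataFrame(genotypes), models
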