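"""SVD-based spatiotemporal taxonomy of retained introns.

The PIR matrix of each compartment is (optionally row-centred and) thin-SVD
decomposed; each intron is scored against each right singular vector by
Pearson correlation and by projection; introns at the positive and negative
extremes of the (correlation, projection) plane are selected per component
with k-means (extreme clusters kept); selections are assembled into group
labels — introns selected on cytoplasmic components become C-groups,
introns selected only on nuclear components become N-groups, one group per
(component, polarity) cell, conflicts resolved by the largest projection
(standardised within each component).

Row-centring makes the components capture retention *dynamics* rather than
baseline level; a consequence is that archetypes with a flat profile carry
no signal and remain unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .types import PIRMatrix


class TaxonomyError(ValueError):
    pass


@dataclass
class SVDResult:
    intron_ids: list
    sample_ids: list
    left_vectors: np.ndarray  # introns x k
    singular_values: np.ndarray  # k, non-increasing
    right_vectors: np.ndarray  # samples x k
    centering: str
    row_means: np.ndarray
    variance_explained: np.ndarray
    n_imputed: int

    @property
    def k(self) -> int:
        return len(self.singular_values)

    def reconstruct(self) -> np.ndarray:
        rec = self.left_vectors @ np.diag(self.singular_values) @ self.right_vectors.T
        if self.centering == "row_center":
            rec = rec + self.row_means[:, None]
        return rec


def svd_pir(pir: PIRMatrix, centering: str = "row_center") -> SVDResult:
    """Thin SVD of the PIR matrix, sign-fixed for determinism.

    Missing values are imputed by the row mean for the decomposition only
    (count logged in ``n_imputed``).  Signs are fixed so each right singular
    vector's largest-magnitude entry is positive.
    """
    if centering not in ("none", "row_center"):
        raise TaxonomyError(f"unknown centering {centering!r}")
    X = pir.values.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise TaxonomyError(f"matrix too small for SVD: {X.shape}")
    row_means = np.nanmean(X, axis=1)
    nan_mask = np.isnan(X)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        X = np.where(nan_mask, row_means[:, None], X)
    if np.isnan(X).any():
        raise TaxonomyError("introns with all-missing values cannot be decomposed")
    if centering == "row_center":
        X = X - row_means[:, None]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    # sign fix: largest-|entry| of each right vector positive
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    total = float((s**2).sum())
    ve = s**2 / total if total > 0 else np.zeros_like(s)
    return SVDResult(
        pir.intron_ids,
        pir.sample_ids,
        U,
        s,
        V,
        centering,
        row_means,
        ve,
        n_imputed,
    )


@dataclass
class ComponentScores:
    intron_id: str
    component_index: int
    correlation: float  # NaN for zero-variance profiles
    projection: float


def score_introns(pir: PIRMatrix, svd: SVDResult, component: int) -> list:
    """Pearson r and inner product of each intron's profile with right vector k.

    Profiles are row-mean imputed and, under row centring, centred before
    projection (matching the decomposition).  Zero-variance profiles get
    correlation NaN and are excluded from extreme selection downstream.
    """
    if component >= svd.k:
        raise TaxonomyError(f"component {component} >= k={svd.k}")
    X = pir.values.to_numpy(dtype=float)
    row_means = np.nanmean(X, axis=1)
    X = np.where(np.isnan(X), row_means[:, None], X)
    v = svd.right_vectors[:, component]
    Xc = X - X.mean(axis=1, keepdims=True)
    sd_x = Xc.std(axis=1)
    vc = v - v.mean()
    sd_v = vc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ vc) / (len(v) * sd_x * sd_v)
    corr = np.where(sd_x == 0, np.nan, corr)
    proj = (X - row_means[:, None]) @ v if svd.centering == "row_center" else X @ v
    return [
        ComponentScores(iid, component, float(c), float(p))
        for iid, c, p in zip(pir.intron_ids, corr, proj)
    ]


def select_extremes(scores, k_clusters: int = 3, seed: int = 0):
    """k-means on standardised (correlation, projection); keep the extreme clusters.

    Returns (positive ids, negative ids): the clusters whose standardised
    centroid coordinate sum is largest / smallest.  Introns with undefined
    correlation are excluded beforehand.
    """
    usable = [s for s in scores if np.isfinite(s.correlation) and np.isfinite(s.projection)]
    # canonical order: k-means initialisation must not depend on input row order
    usable.sort(key=lambda s: (s.correlation, s.projection, s.intron_id))
    if len(usable) < k_clusters:
        raise TaxonomyError(f"only {len(usable)} scored introns for k={k_clusters}")
    pts = np.array([[s.correlation, s.projection] for s in usable])
    if len(np.unique(pts, axis=0)) < k_clusters:
        raise TaxonomyError("fewer distinct score points than clusters")
    mu, sd = pts.mean(axis=0), pts.std(axis=0)
    sd[sd == 0] = 1.0
    z = (pts - mu) / sd
    km = KMeans(n_clusters=k_clusters, n_init=20, random_state=seed).fit(z)
    sums = km.cluster_centers_.sum(axis=1)
    pos_c, neg_c = int(np.argmax(sums)), int(np.argmin(sums))
    pos = {usable[i].intron_id for i in range(len(usable)) if km.labels_[i] == pos_c}
    neg = {usable[i].intron_id for i in range(len(usable)) if km.labels_[i] == neg_c}
    return pos, neg


@dataclass
class TaxonomyAssignment:
    intron_id: str
    group: str  # N1..N3, C1..C6 or unassigned
    compartment: str  # nucleus / cytoplasm / ""
    component_index: int
    polarity: str  # positive / negative / ""
    projection: float


def default_group_map(n_components: int) -> dict:
    """(compartment, component, polarity) -> group label.

    Cytoplasmic cells map to C1..C6 and nuclear cells to N1..N3, enumerated
    (comp 0 +, comp 0 -, comp 1 +, ...).  Config-exposed: pass your own map
    to :func:`assign_taxonomy` to pin labels to known dynamics.
    """
    mapping = {}
    c = n = 0
    for k in range(n_components):
        for pol in ("positive", "negative"):
            if c < 6:
                c += 1
                mapping[("cytoplasm", k, pol)] = f"C{c}"
            if n < 3:
                n += 1
                mapping[("nucleus", k, pol)] = f"N{n}"
    return mapping


def choose_n_components(svd: SVDResult, min_variance: float = 0.6, cap: int = 5) -> int:
    cum = np.cumsum(svd.variance_explained)
    k = int(np.searchsorted(cum, min_variance) + 1)
    return max(1, min(k, cap, svd.k))


def assign_taxonomy(
    pir_nuc: PIRMatrix,
    pir_cyt: PIRMatrix,
    n_components: int | None = 3,
    seed: int = 0,
    k_clusters: int = 5,
    centering: str = "row_center",
    group_map: dict | None = None,
) -> list:
    """Assemble the nine-group taxonomy from per-compartment decompositions.

    Introns selected on any cytoplasmic component get a C label; introns
    selected only on nuclear components get an N label; everything else is
    unassigned.  Within a compartment, an intron selected on several
    (component, polarity) cells goes to the one with largest |projection|.
    """
    if list(pir_nuc.intron_ids) != list(pir_cyt.intron_ids):
        raise TaxonomyError("nuclear and cytoplasmic matrices must share intron ids")
    selections = {}  # compartment -> intron -> (|z-proj|, component, polarity, proj)
    for comp_name, mat in (("nucleus", pir_nuc), ("cytoplasm", pir_cyt)):
        svd = svd_pir(mat, centering=centering)
        k = n_components if n_components is not None else choose_n_components(svd)
        if k > svd.k:
            raise TaxonomyError(f"{k} components requested, rank is {svd.k}")
        best = {}
        for c in range(k):
            scores = score_introns(mat, svd, c)
            proj = {s.intron_id: s.projection for s in scores}
            # projections standardised within the component, so "largest
            # projection" is comparable across components of unequal scale
            scale = np.std([p for p in proj.values() if np.isfinite(p)])
            scale = scale if scale > 0 else 1.0
            pos, neg = select_extremes(scores, k_clusters=k_clusters, seed=seed)
            for ids, pol in ((pos, "positive"), (neg, "negative")):
                for iid in ids:
                    cand = (abs(proj[iid]) / scale, c, pol, proj[iid])
                    if iid not in best or cand[0] > best[iid][0]:
                        best[iid] = cand
        selections[comp_name] = best
    gmap = group_map or default_group_map(n_components if n_components is not None else 5)
    out = []
    for iid in pir_nuc.intron_ids:
        if iid in selections["cytoplasm"]:
            compartment = "cytoplasm"
        elif iid in selections["nucleus"]:
            compartment = "nucleus"
        else:
            out.append(TaxonomyAssignment(iid, "unassigned", "", -1, "", 0.0))
            continue
        _, c, pol, proj = selections[compartment][iid]
        group = gmap.get((compartment, c, pol), "unassigned")
        out.append(TaxonomyAssignment(iid, group, compartment, c, pol, proj))
    return out


class SpatiotemporalTaxonomy(BaseEstimator):
    """sklearn-style wrapper: fit on (nuclear, cytoplasmic) PIR matrices.

    Fitted attributes: ``assignments_`` (list of TaxonomyAssignment),
    ``labels_`` (pd.Series intron -> group), ``svd_nucleus_``,
    ``svd_cytoplasm_``.
    """

    def __init__(
        self,
        n_components: int | None = 3,
        k_clusters: int = 5,
        centering: str = "row_center",
        seed: int = 0,
        group_map: dict | None = None,
    ):
        self.n_components = n_components
        self.k_clusters = k_clusters
        self.centering = centering
        self.seed = seed
        self.group_map = group_map

    def fit(self, pir_nuc: PIRMatrix, pir_cyt: PIRMatrix):
        self.svd_nucleus_ = svd_pir(pir_nuc, centering=self.centering)
        self.svd_cytoplasm_ = svd_pir(pir_cyt, centering=self.centering)
        self.assignments_ = assign_taxonomy(
            pir_nuc,
            pir_cyt,
            n_components=self.n_components,
            seed=self.seed,
            k_clusters=self.k_clusters,
            centering=self.centering,
            group_map=self.group_map,
        )
        self.labels_ = pd.Series(
            {a.intron_id: a.group for a in self.assignments_}, name="group"
        ).loc[pir_nuc.intron_ids]
        return self


def assignments_frame(assignments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intron_id": a.intron_id,
                "group": a.group,
                "compartment": a.compartment,
                "component": a.component_index,
                "polarity": a.polarity,
                "projection": a.projection,
            }
            for a in assignments
        ]
    )
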