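"""Semi-supervised cluster explainability metrics for gait embeddings.

Given K-means clusters over 18x3 gait embeddings and the identity of the
"regular" cluster *r* (the only supervision used), three metrics describe
each abnormal cluster *a*:

* **DimWise importance** — for each joint feature *f* (an embedding
  3-vector),

      I_fa = (1 / sigma_f^2) * (1 + O_far) * (1 + ||mu_fr - mu_fa||),

  where ``sigma_f^2`` is the within-cluster-*a* variance of feature *f*
  (trace of its 3x3 covariance), ``O_far`` penalizes inter-cluster overlap
  and the last factor rewards centroid separation along *f*.  Low variance,
  low overlap and a large centroid gap all mark a joint as characteristic
  of the abnormality.

* **Overlap** ``O_far`` — one minus the fraction of instances of the two
  clusters that lie closer (Mahalanobis, under each cluster's own
  per-feature covariance) to the *other* cluster's centroid along *f*;
  1 means perfectly separated, 0 means fully interleaved.

* **Confidence** — per instance, ``max(d_ri, d_ai) / Dist(M_r, M_a)`` with
  Euclidean distances in the full 54-dim embedding space: near 1 at a
  centroid, 0.5 at the inter-centroid midpoint, above 1 beyond either
  centroid (reported unclamped).

* **Severity** — per abnormal instance, its distance to the regular
  centroid normalized by the mean such distance of the other abnormal
  instances; values above 1 mark instances deviating more than their peers.

Joint-level DimWise scores are aggregated into six body regions, scaled by
user weights (clinically, leg joints matter more than the nose) and
softmax-normalized into percentages ranked 1-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, REGIONS, JointSchema

N_JOINTS = 18

#: absolute floor on a feature variance when a cluster is degenerate
#: (single instance or identical points); keeps 1/sigma^2 finite.
VARIANCE_FLOOR = 1e-12

#: default region weights: locomotion-bearing regions up-weighted, the head
#: (nose/eyes/ears, nearly rigid in gait) down-weighted.  Fully overridable.
DEFAULT_REGION_WEIGHTS = {
    "head": 0.5, "torso": 1.0,
    "left_arm": 1.0, "right_arm": 1.0,
    "left_leg": 1.5, "right_leg": 1.5,
}


def _as_features(vectors: np.ndarray) -> np.ndarray:
    """Accept (n, 54) or (n, 18, 3); return (n, 18, 3)."""
    x = np.asarray(vectors, dtype=float)
    if x.ndim == 2 and x.shape[1] == 54:
        return x.reshape(-1, N_JOINTS, 3)
    if x.ndim == 3 and x.shape[1:] == (N_JOINTS, 3):
        return x
    raise ValueError(f"vectors must be (n, 54) or (n, 18, 3), got {x.shape}")


@dataclass
class ClusterFeatureStats:
    """Per-joint sample statistics of one cluster's embeddings."""

    cluster_id: int
    n: int
    means: np.ndarray       # (18, 3)
    covs: np.ndarray        # (18, 3, 3), regularized
    inv_covs: np.ndarray    # (18, 3, 3)
    variances: np.ndarray   # (18,) trace of the unregularized covariance, floored
    degenerate: bool = False


def cluster_feature_stats(vectors: np.ndarray, assignments: np.ndarray,
                          cluster_id: int) -> ClusterFeatureStats:
    """Sample mean, covariance and trace-variance per joint feature.

    Covariances use denominator ``n - 1`` and are regularized by
    ``eps * I`` with ``eps = 1e-6 *`` (mean diagonal) so Mahalanobis
    distances stay defined; degenerate clusters (one instance, or identical
    points) fall back to :data:`VARIANCE_FLOOR` with a warning.
    """
    x = _as_features(vectors)[np.asarray(assignments) == cluster_id]
    n = len(x)
    if n == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    means = x.mean(axis=0)
    covs = np.zeros((N_JOINTS, 3, 3))
    variances = np.zeros(N_JOINTS)
    degenerate = False
    for j in range(N_JOINTS):
        if n > 1:
            c = np.cov(x[:, j, :], rowvar=False, ddof=1)
        else:
            c = np.zeros((3, 3))
        tr = float(np.trace(c))
        if tr <= VARIANCE_FLOOR:
            degenerate = True
            variances[j] = VARIANCE_FLOOR
        else:
            variances[j] = tr
        eps = 1e-6 * max(tr / 3.0, VARIANCE_FLOOR)
        covs[j] = c + eps * np.eye(3)
    if degenerate:
        warnings.warn(
            f"cluster {cluster_id} has (near-)zero variance in some joint "
            "features; inverse-variance importance uses the floor "
            f"{VARIANCE_FLOOR:g} and is not meaningful there", stacklevel=2)
    inv_covs = np.linalg.inv(covs)
    return ClusterFeatureStats(cluster_id=cluster_id, n=n, means=means,
                               covs=covs, inv_covs=inv_covs,
                               variances=variances, degenerate=degenerate)


def _sq_mahalanobis(points: np.ndarray, mean: np.ndarray,
                    inv_cov: np.ndarray) -> np.ndarray:
    d = points - mean
    return np.einsum("ni,ij,nj->n", d, inv_cov, d)


def overlap(f: int, stats_a: ClusterFeatureStats, points_a: np.ndarray,
            stats_r: ClusterFeatureStats, points_r: np.ndarray) -> float:
    """Inverse overlap ``O_far`` of clusters *a* and *r* along joint feature *f*.

    An instance of either cluster counts as overlapping when it is strictly
    Mahalanobis-closer to the other cluster's centroid (each centroid's own
    covariance); ``O = 1 - overlapping / (n1 + n2)``.  Exact distance ties
    never satisfy the strict inequality, so two *identical* clusters score
    O = 1 — flagged with a warning since importance is meaningless there.
    """
    if (np.allclose(stats_a.means[f], stats_r.means[f])
            and np.allclose(stats_a.covs[f], stats_r.covs[f])):
        warnings.warn(
            f"feature {f}: the two clusters have identical statistics; the "
            "tie-free overlap O=1 does not indicate separation", stacklevel=2)
    xa = _as_features(points_a)[:, f, :]
    xr = _as_features(points_r)[:, f, :]
    a_to_a = _sq_mahalanobis(xa, stats_a.means[f], stats_a.inv_covs[f])
    a_to_r = _sq_mahalanobis(xa, stats_r.means[f], stats_r.inv_covs[f])
    r_to_r = _sq_mahalanobis(xr, stats_r.means[f], stats_r.inv_covs[f])
    r_to_a = _sq_mahalanobis(xr, stats_a.means[f], stats_a.inv_covs[f])
    crossed = int((a_to_r < a_to_a).sum()) + int((r_to_a < r_to_r).sum())
    return 1.0 - crossed / (len(xa) + len(xr))


def dimwise(f: int, stats_a: ClusterFeatureStats, stats_r: ClusterFeatureStats,
            o_far: float) -> float:
    """DimWise importance of joint feature *f* for abnormal cluster *a*."""
    gap = float(np.linalg.norm(stats_r.means[f] - stats_a.means[f]))
    return (1.0 / stats_a.variances[f]) * (1.0 + o_far) * (1.0 + gap)


def region_scores(importances: np.ndarray,
                  schema: JointSchema = DEFAULT_SCHEMA,
                  weights: dict[str, float] | None = None,
                  ) -> tuple[dict[str, float], dict[str, int]]:
    """Aggregate 18 joint importances into 6 weighted softmax percentages.

    Per region the member-joint scores are summed and multiplied by the
    region's weight; a softmax over the six weighted sums yields percentages
    (summing to 1).  Rank 1 is the largest percentage; exact ties break by
    the canonical region order, with a warning.
    """
    importances = np.asarray(importances, dtype=float)
    if importances.shape != (N_JOINTS,):
        raise ValueError(f"expected 18 joint scores, got {importances.shape}")
    weights = dict(DEFAULT_REGION_WEIGHTS if weights is None else weights)
    for r in REGIONS:
        if weights.get(r, 0.0) <= 0:
            raise ValueError(f"region weight for {r!r} must be positive")
    sums = np.array([
        weights[r] * importances[schema.region_joints(r)].sum() for r in REGIONS])
    z = sums - sums.max()
    soft = np.exp(z) / np.exp(z).sum()
    percentages = {r: float(s) for r, s in zip(REGIONS, soft)}
    order = np.argsort(-soft, kind="stable")  # stable: ties keep region order
    if len(np.unique(np.round(soft, 15))) < len(soft):
        warnings.warn("tied region scores; ranks broken by canonical region "
                      "order", stacklevel=2)
    ranks = {REGIONS[i]: int(pos + 1) for pos, i in enumerate(order)}
    return percentages, ranks


def confidence(point: np.ndarray, m_a: np.ndarray, m_r: np.ndarray) -> float:
    """Assignment confidence of one instance between centroids ``m_a``/``m_r``.

    ``max(d_ri, d_ai) / Dist(M_r, M_a)`` with Euclidean distances in the
    embedding space.  Values can exceed 1 for instances lying beyond a
    centroid; they are reported unclamped.
    """
    m_a = np.asarray(m_a, float).ravel()
    m_r = np.asarray(m_r, float).ravel()
    dist = float(np.linalg.norm(m_a - m_r))
    if dist <= 1e-12:
        raise ValueError("coincident centroids: confidence is undefined")
    p = np.asarray(point, float).ravel()
    return float(max(np.linalg.norm(p - m_r), np.linalg.norm(p - m_a)) / dist)


def severity(d_ri: float, d_rj_others: np.ndarray) -> float:
    """Severity of one abnormal instance given the other instances' regular
    distances: ``d_ri / mean_j(d_rj)``."""
    others = np.asarray(d_rj_others, dtype=float)
    if others.size < 1:
        raise ValueError("severity needs at least one other abnormal instance")
    denom = float(others.mean())
    if denom <= 1e-15:
        raise ValueError("all other abnormal instances coincide with the "
                         "regular centroid; severity is undefined")
    return float(d_ri / denom)


def severity_scores(distances_to_regular: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out severity for a set of abnormal instances."""
    d = np.asarray(distances_to_regular, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("severity needs at least 2 abnormal instances")
    loo_mean = (d.sum() - d) / (k - 1)
    if (loo_mean <= 1e-15).any():
        raise ValueError("degenerate abnormal distances; severity undefined")
    return d / loo_mean


@dataclass
class DimWiseResult:
    """DimWise output for one abnormal cluster."""

    cluster_id: int
    importances: np.ndarray          # (18,)
    overlaps: np.ndarray             # (18,)
    region_percentages: dict[str, float]
    region_ranks: dict[str, int]
    region_weights: dict[str, float]


@dataclass
class ExplainReport:
    """All three metrics for every abnormal cluster against the regular one."""

    regular_cluster_id: int
    dimwise: dict[int, DimWiseResult]
    mean_confidence: dict[int, float]
    mean_severity: dict[int, float]
    instance_scores: pd.DataFrame    # per instance: cluster, confidence, severity
    regular_mean_severity: float = float("nan")

    def region_table(self) -> pd.DataFrame:
        """One row of 6 region ranks per abnormal cluster."""
        rows = []
        for cid, res in sorted(self.dimwise.items()):
            row = {"cluster": cid}
            row.update({r: res.region_ranks[r] for r in REGIONS})
            rows.append(row)
        return pd.DataFrame(rows)


def explain_clusters(vectors: np.ndarray, assignments: np.ndarray,
                     regular_cluster_id: int,
                     schema: JointSchema = DEFAULT_SCHEMA,
                     region_weights: dict[str, float] | None = None,
                     feature_mode: str = "vector",
                     feature_scaling: str = "population") -> ExplainReport:
    """Compute DimWise, confidence and severity for every abnormal cluster.

    ``feature_mode='vector'`` (default) treats each joint's embedding
    3-vector as one feature (trace variance, 3x3 Mahalanobis, Euclidean
    centroid gap).  ``'scalar'`` scores each of the 54 scalars separately
    and sums the three per-axis importances back into a joint score — a
    sensitivity-analysis variant.

    ``feature_scaling='population'`` (default) z-scores every embedding
    dimension over the whole population first.  Inverse-variance importance
    compares features against each other, which is only meaningful on a
    common scale: raw first-component scores differ in scale by orders of
    magnitude across joints, and without scaling the lowest-variance joints
    win regardless of whether they carry any between-cluster signal.  Pass
    ``'none'`` to score raw values.
    """
    if feature_mode not in ("vector", "scalar"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    if feature_scaling not in ("population", "none"):
        raise ValueError(f"unknown feature_scaling {feature_scaling!r}")
    feats = _as_features(vectors)
    if feature_scaling == "population":
        sd = feats.std(axis=0)
        feats = (feats - feats.mean(axis=0)) / np.where(sd > 1e-12, sd, 1.0)
    flat = feats.reshape(len(feats), -1)
    assignments = np.asarray(assignments, dtype=int)
    cluster_ids = sorted(set(assignments.tolist()))
    if regular_cluster_id not in cluster_ids:
        raise ValueError(f"regular cluster {regular_cluster_id} not present")

    stats = {cid: cluster_feature_stats(feats, assignments, cid)
             for cid in cluster_ids}
    r_stats = stats[regular_cluster_id]
    r_points = feats[assignments == regular_cluster_id]
    r_centroid = flat[assignments == regular_cluster_id].mean(axis=0)

    abnormal_ids = [c for c in cluster_ids if c != regular_cluster_id]
    dim_results: dict[int, DimWiseResult] = {}
    mean_conf: dict[int, float] = {}
    rows = []

    # severity normalizes over *all* abnormal instances
    abnormal_mask = assignments != regular_cluster_id
    d_regular_all = np.linalg.norm(flat - r_centroid, axis=1)
    sev_all = np.full(len(flat), np.nan)
    if abnormal_mask.sum() >= 2:
        sev_all[abnormal_mask] = severity_scores(d_regular_all[abnormal_mask])
    else:
        warnings.warn("fewer than two abnormal instances; severity is "
                      "undefined and reported as NaN", stacklevel=2)

    for cid in abnormal_ids:
        a_stats = stats[cid]
        a_points = feats[assignments == cid]
        a_centroid = flat[assignments == cid].mean(axis=0)

        if feature_mode == "vector":
            overlaps = np.array([
                overlap(f, a_stats, a_points, r_stats, r_points)
                for f in range(N_JOINTS)])
            importances = np.array([
                dimwise(f, a_stats, r_stats, overlaps[f])
                for f in range(N_JOINTS)])
        else:
            overlaps, importances = _scalar_mode_scores(
                a_points, r_points, a_stats, r_stats)

        pct, ranks = region_scores(importances, schema, region_weights)
        dim_results[cid] = DimWiseResult(
            cluster_id=cid, importances=importances, overlaps=overlaps,
            region_percentages=pct, region_ranks=ranks,
            region_weights=dict(DEFAULT_REGION_WEIGHTS
                                if region_weights is None else region_weights))

        idx = np.flatnonzero(assignments == cid)
        confs = [confidence(flat[i], a_centroid, r_centroid) for i in idx]
        mean_conf[cid] = float(np.mean(confs))
        for i, cf in zip(idx, confs):
            rows.append({"index": int(i), "cluster": cid,
                         "confidence": cf, "severity": float(sev_all[i]),
                         "d_regular": float(d_regular_all[i])})

    # regular instances: severity against the abnormal normalization, as a
    # baseline the abnormal clusters should exceed
    reg_idx = np.flatnonzero(~abnormal_mask)
    reg_sev = np.nan
    if abnormal_mask.sum() >= 1:
        denom = d_regular_all[abnormal_mask].mean()
        if denom > 1e-15:
            reg_sev_vals = d_regular_all[reg_idx] / denom
            reg_sev = float(reg_sev_vals.mean())
            for i, s in zip(reg_idx, reg_sev_vals):
                rows.append({"index": int(i), "cluster": regular_cluster_id,
                             "confidence": np.nan, "severity": float(s),
                             "d_regular": float(d_regular_all[i])})

    mean_sev = {cid: float(np.nanmean(sev_all[assignments == cid]))
                for cid in abnormal_ids}
    return ExplainReport(
        regular_cluster_id=regular_cluster_id, dimwise=dim_results,
        mean_confidence=mean_conf, mean_severity=mean_sev,
        instance_scores=pd.DataFrame(rows).sort_values("index").reset_index(drop=True),
        regular_mean_severity=reg_sev)


def _scalar_mode_scores(a_points: np.ndarray, r_points: np.ndarray,
                        a_stats: ClusterFeatureStats,
                        r_stats: ClusterFeatureStats,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """54-scalar-feature variant, summed back to 18 joint scores."""
    xa = a_points.reshape(len(a_points), N_JOINTS, 3)
    xr = r_points.reshape(len(r_points), N_JOINTS, 3)
    overlaps = np.zeros(N_JOINTS)
    importances = np.zeros(N_JOINTS)
    for j in range(N_JOINTS):
        for c in range(3):
            mu_a, mu_r = a_stats.means[j, c], r_stats.means[j, c]
            var_a = max(float(np.var(xa[:, j, c], ddof=1)) if len(xa) > 1 else 0.0,
                        VARIANCE_FLOOR)
            var_r = max(float(np.var(xr[:, j, c], ddof=1)) if len(xr) > 1 else 0.0,
                        VARIANCE_FLOOR)
            za = np.abs(xa[:, j, c] - mu_a) / np.sqrt(var_a)
            za_r = np.abs(xa[:, j, c] - mu_r) / np.sqrt(var_r)
            zr = np.abs(xr[:, j, c] - mu_r) / np.sqrt(var_r)
            zr_a = np.abs(xr[:, j, c] - mu_a) / np.sqrt(var_a)
            crossed = int((za_r < za).sum()) + int((zr_a < zr).sum())
            o = 1.0 - crossed / (len(xa) + len(xr))
            imp = (1.0 / var_a) * (1.0 + o) * (1.0 + abs(mu_r - mu_a))
            overlaps[j] += o / 3.0
            importances[j] += imp
    return overlaps, importances
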