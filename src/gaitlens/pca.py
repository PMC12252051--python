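"""Per-joint PCA: compress 18x7x3 latent gait-cycle arrays to 18x3
single-frame embeddings.

For each of the 18 joints and each of the 3 channels, the 7 temporal values
form the feature axis and the instances the sample axis; a population PCA is
fitted per (joint, channel) and only the first principal component kept, so
each joint's whole-cycle behavior collapses to one scalar per channel.  The
fit population should be the training split only, to keep downstream
clustering evaluation leakage-free.

A per-instance mode ("instance"), which instead treats each instance's own
7 time points as the PCA sample axis, is available for comparison; the
population mode is the default because explained-variance ratios are then a
property of the dataset rather than of single instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .types import CYCLE_FRAMES, EmbeddingVector, GaitCycleInstance

N_JOINTS = 18
N_CHANNELS = 3


@dataclass
class JointPCAModel:
    """First-component loadings per (joint, channel).

    ``loadings``: (18, 3, 7) unit-norm vectors, sign-fixed so that each
    vector's largest-magnitude element is positive.
    ``means``: (18, 3, 7) temporal means of the fit population.
    ``explained_variance_ratio``: (18, 3) fraction of per-(joint, channel)
    variance captured by the first component.
    """

    loadings: np.ndarray
    means: np.ndarray
    explained_variance_ratio: np.ndarray
    n_fit: int

    def __post_init__(self) -> None:
        assert self.loadings.shape == (N_JOINTS, N_CHANNELS, CYCLE_FRAMES)
        norms = np.linalg.norm(self.loadings, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading vectors must be unit-norm")
        evr = self.explained_variance_ratio
        if ((evr < -1e-12) | (evr > 1 + 1e-12)).any():
            raise ValueError("explained-variance ratios must lie in [0, 1]")


def _fix_sign(vec: np.ndarray) -> np.ndarray:
    """Flip so the largest-magnitude element is positive (deterministic)."""
    i = int(np.argmax(np.abs(vec)))
    return -vec if vec[i] < 0 else vec


def fit_joint_pca(latents: np.ndarray | list[np.ndarray]) -> JointPCAModel:
    """Fit the per-(joint, channel) first principal component.

    ``latents`` is an (n, 18, 7, 3) stack (or list of 18x7x3 arrays); at
    least 8 instances are required so that samples outnumber the 7 temporal
    features.
    """
    arr = np.stack(list(latents)) if isinstance(latents, list) else np.asarray(latents)
    if arr.ndim != 4 or arr.shape[1:] != (N_JOINTS, CYCLE_FRAMES, N_CHANNELS):
        raise ValueError(f"latents must be (n, 18, 7, 3), got {arr.shape}")
    n = arr.shape[0]
    if n <= CYCLE_FRAMES:
        raise ValueError(
            f"need more instances ({n}) than temporal dimensions "
            f"({CYCLE_FRAMES}) to fit a population PCA; provide more data")
    loadings = np.empty((N_JOINTS, N_CHANNELS, CYCLE_FRAMES))
    means = np.empty((N_JOINTS, N_CHANNELS, CYCLE_FRAMES))
    evr = np.empty((N_JOINTS, N_CHANNELS))
    for j in range(N_JOINTS):
        for c in range(N_CHANNELS):
            data = arr[:, j, :, c]  # (n, 7)
            pca = PCA(n_components=1).fit(data)
            loadings[j, c] = _fix_sign(pca.components_[0])
            means[j, c] = pca.mean_
            evr[j, c] = pca.explained_variance_ratio_[0]
    return JointPCAModel(loadings, means, evr, n_fit=n)


def transform(latents: np.ndarray | list[np.ndarray], model: JointPCAModel,
              instances: list[GaitCycleInstance] | None = None,
              ) -> list[EmbeddingVector]:
    """Project latents onto the fitted first components -> 18x3 embeddings.

    If ``instances`` is given, ids/labels/subjects are carried over;
    otherwise embeddings get positional ids.
    """
    arr = np.stack(list(latents)) if isinstance(latents, list) else np.asarray(latents)
    if arr.ndim != 4 or arr.shape[1:] != (N_JOINTS, CYCLE_FRAMES, N_CHANNELS):
        raise ValueError(f"latents must be (n, 18, 7, 3), got {arr.shape}")
    scores = transform_array(arr, model)
    out = []
    for i in range(arr.shape[0]):
        if instances is not None:
            inst = instances[i]
            out.append(EmbeddingVector(scores[i], instance_id=inst.instance_id,
                                       class_label=inst.class_label,
                                       subject_id=inst.subject_id))
        else:
            out.append(EmbeddingVector(scores[i], instance_id=str(i)))
    return out


def transform_array(arr: np.ndarray, model: JointPCAModel) -> np.ndarray:
    """Vectorized projection: (n, 18, 7, 3) -> (n, 18, 3) scores."""
    centered = arr.transpose(0, 1, 3, 2) - model.means  # (n, 18, 3, 7)
    return np.einsum("njct,jct->njc", centered, model.loadings)


def inverse_transform(scores: np.ndarray, model: JointPCAModel) -> np.ndarray:
    """Reconstruct (n, 18, 7, 3) latents from (n, 18, 3) first-component scores."""
    rec = model.means + scores[..., None] * model.loadings  # (n, 18, 3, 7)
    return rec.transpose(0, 1, 3, 2)


def variance_report(model: JointPCAModel, threshold: float = 0.5) -> pd.DataFrame:
    """Explained-variance table with a low-variance flag per (joint, channel).

    Rows where the first component captures less than ``threshold`` of the
    variance are flagged — the diagnostic for deciding whether a single
    component adequately summarizes each joint's temporal profile.
    """
    rows = []
    for j in range(N_JOINTS):
        for c in range(N_CHANNELS):
            r = float(model.explained_variance_ratio[j, c])
            rows.append({"joint": j, "channel": "xyz"[c],
                         "explained_variance_ratio": r,
                         "flagged": r < threshold})
    return pd.DataFrame(rows)


def fit_joint_pca_instance_mode(latent: np.ndarray) -> np.ndarray:
    """Per-instance variant: PCA over one instance's 7 time points.

    For a single 18x7x3 latent array, treats the 7 temporal samples of each
    joint as observations of a 3-vector and returns the (18, 3) first
    principal axis scaled by the component's standard deviation.  Provided
    for comparison with the population fit; ratios computed this way vary
    instance by instance.
    """
    if latent.shape != (N_JOINTS, CYCLE_FRAMES, N_CHANNELS):
        raise ValueError(f"latent must be (18, 7, 3), got {latent.shape}")
    out = np.empty((N_JOINTS, N_CHANNELS))
    for j in range(N_JOINTS):
        data = latent[j]  # (7, 3)
        pca = PCA(n_components=1).fit(data)
        axis = _fix_sign(pca.components_[0])
        out[j] = axis * np.sqrt(pca.explained_variance_[0])
    return out
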