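"""PCA of measured exchange-flux data.

The measured dataset (experiments × species) is auto-scaled column-wise to
zero mean and unit variance and decomposed by SVD,

    scaled data = Scores · Coeffᵀ,

so that each retained principal component encodes a direction of correlated
variation of the exchange fluxes.  The loadings matrix ``Coeff`` together
with the scaling vectors (mu, sigma) later parameterise the empirical
constraint block of the hybrid LP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FluxDataset", "PCAModel", "autoscale", "fit_pca", "select_npc"]


@dataclass
class FluxDataset:
    """Experiments × species matrix of exchange rates (mmol·gDW⁻¹·h⁻¹).

    Column order defines the species alignment used throughout; growth (h⁻¹)
    is carried as an ordinary column.
    """

    data: pd.DataFrame

    def __post_init__(self):
        self.data = pd.DataFrame(self.data).astype(float)
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate species labels")
        if self.data.isna().all(axis=0).any():
            bad = list(self.data.columns[self.data.isna().all(axis=0)])
            raise ValueError(f"all-missing columns: {bad}")
        if self.data.isna().any().any():
            raise ValueError("missing values are not supported")

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def experiment_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_experiments(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path) -> "FluxDataset":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


@dataclass
class PCAModel:
    """Scaling vectors, loadings and training-score statistics.

    ``coeff`` has orthonormal columns (species × components); ``explained``
    is the per-component explained-variance fraction, non-increasing;
    ``score_stats`` holds the min/max/SD of the training scores per component
    and provides the default score bounds of the hybrid LP.
    """

    mu: pd.Series                 # per-species autoscaling mean
    sigma: pd.Series              # per-species autoscaling SD (sample, n−1)
    coeff: pd.DataFrame           # loadings, species × PC
    explained: np.ndarray
    score_stats: pd.DataFrame     # PC × [min, max, sd]
    scores: pd.DataFrame = field(repr=False, default=None)  # training scores

    @property
    def species(self) -> list[str]:
        return list(self.mu.index)

    @property
    def n_components(self) -> int:
        return self.coeff.shape[1]

    def reconstruct(self, scores: np.ndarray, npc: int | None = None) -> np.ndarray:
        """Map scores back to the original (unscaled) rate space."""
        npc = self.n_components if npc is None else npc
        scaled = np.atleast_2d(scores)[:, :npc] @ self.coeff.to_numpy()[:, :npc].T
        return self.mu.to_numpy() + self.sigma.to_numpy() * scaled

    def to_json(self, path) -> None:
        payload = {
            "species": self.species,
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "coeff": self.coeff.to_numpy().tolist(),
            "explained": np.asarray(self.explained).tolist(),
            "score_stats": self.score_stats.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        payload = json.loads(Path(path).read_text())
        species = payload["species"]
        coeff = pd.DataFrame(payload["coeff"], index=species,
                             columns=[f"PC{i+1}" for i in
                                      range(len(payload["explained"]))])
        stats = pd.DataFrame(payload["score_stats"], index=coeff.columns)
        return cls(mu=pd.Series(payload["mu"], index=species, name="mu"),
                   sigma=pd.Series(payload["sigma"], index=species, name="sigma"),
                   coeff=coeff, explained=np.asarray(payload["explained"]),
                   score_stats=stats)


def autoscale(ds: FluxDataset):
    """Column-wise scale to zero mean and unit (sample, n−1) variance.

    Returns ``(scaled DataFrame, mu, sigma)``.  A zero-variance column cannot
    be scaled and raises, naming the species.
    """
    if ds.n_experiments < 2:
        raise ValueError("autoscaling needs at least 2 experiments")
    mu = ds.data.mean(axis=0)
    sigma = ds.data.std(axis=0, ddof=1)
    dead = sigma[sigma == 0]
    if len(dead):
        raise ValueError(f"zero-variance columns cannot be autoscaled: "
                         f"{list(dead.index)}")
    scaled = (ds.data - mu) / sigma
    return scaled, mu.rename("mu"), sigma.rename("sigma")


def fit_pca(ds: FluxDataset) -> PCAModel:
    """Autoscale and decompose by SVD.

    All ``min(n−1, p)`` components are retained in the model; truncation to
    NPC happens downstream.  Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is positive.
    """
    scaled, mu, sigma = autoscale(ds)
    X = scaled.to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in scaled data")
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, X.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]

    # deterministic sign fix
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0

    var = s**2 / (n - 1)
    explained = var / X.var(axis=0, ddof=1).sum()
    scores = U * s
    cols = [f"PC{i+1}" for i in range(k)]
    coeff = pd.DataFrame(Vt.T, index=ds.species, columns=cols)
    score_df = pd.DataFrame(scores, index=ds.experiment_ids, columns=cols)
    stats = pd.DataFrame({"min": scores.min(axis=0),
                          "max": scores.max(axis=0),
                          "sd": scores.std(axis=0, ddof=1)}, index=cols)
    return PCAModel(mu=mu, sigma=sigma, coeff=coeff, explained=explained,
                    score_stats=stats, scores=score_df)


def select_npc(pca: PCAModel, threshold: float = 0.90) -> int:
    """Smallest number of components with cumulative explained variance
    ≥ ``threshold`` (default 90%)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cum = np.cumsum(pca.explained)
    hits = np.where(cum >= threshold - 1e-12)[0]
    return int(hits[0]) + 1 if len(hits) else pca.n_components
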