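"""Extreme Pseudo-Samples (EPS): generative gene ranking via a VAE.

The pipeline trains a VAE on the balanced training set, embeds the
samples, fits a linear (logistic) separator between the two classes in
latent space, identifies the *extreme regions* -- the correct-side class
members whose absolute signed distance to the separator lies in the top
q fraction -- and draws new latent points from the posteriors of those
extreme members (rejecting wrong-side draws).  Decoding the points yields
equal-sized sets of case-like and control-like pseudo-samples that are
linearly separable in feature space; the absolute coefficients of a
regularized logistic model fitted on them, with features standardized
across pseudo-samples, rank the genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data import CASE, FeatureMatrix, GeneRanking, SampleMetadata, SplitSpec
from .vae import VAE, LatentRepresentation, TrainingHistory, VAEArchitecture, embed, train_vae

DEFAULT_QUANTILE = 0.10
DEFAULT_N_PSEUDO = 400
#: L2 penalty strength of the logistic fits (lambda; sklearn C = 1/lambda).
LOGISTIC_L2 = 1e-3
MAX_REJECTION_ATTEMPTS = 100


@dataclass
class Separator:
    """Linear class separator in latent space (case side positive)."""

    weight: np.ndarray
    intercept: float
    training_accuracy: float

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float).ravel()
        norm = np.linalg.norm(self.weight)
        if norm == 0:
            raise ValueError("separator weight vector must be nonzero")

    def signed_distance(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return (Z @ self.weight + self.intercept) / np.linalg.norm(self.weight)


@dataclass
class ExtremeRegions:
    """Per class: the extreme correct-side members and their threshold."""

    members: dict[int, np.ndarray]  # class label -> latent sample indices
    thresholds: dict[int, float]  # min |signed distance| among members
    side_signs: dict[int, int]  # class label -> sign of its side
    separator: Separator

    def __post_init__(self) -> None:
        if set(self.members) != {0, 1} or self.side_signs[0] == self.side_signs[1]:
            raise ValueError("extreme regions require both classes on distinct sides")
        for c, idx in self.members.items():
            if len(idx) == 0:
                raise ValueError(f"extreme region for class {c} is empty")


@dataclass
class PseudoSampleSet:
    """Decoded virtual samples with labels and generating latent points."""

    values: np.ndarray  # (n_pseudo, n_features) decoded feature-space vectors
    labels: np.ndarray  # 1 = case-like, 0 = control-like
    latent_points: np.ndarray
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=2)
        if counts[0] != counts[1]:
            raise ValueError("pseudo-sample classes must have equal counts")

    @property
    def n_per_class(self) -> int:
        return int(np.sum(self.labels == 1))


def fit_separator(latent: LatentRepresentation) -> Separator:
    """Regularized logistic separator on the sampled latent points z."""
    y = latent.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a separator")
    if np.allclose(latent.z, latent.z[0]):
        raise ValueError("latent points are all identical; separator undefined")
    clf = LogisticRegression(C=1.0 / LOGISTIC_L2, max_iter=5000)
    clf.fit(latent.z, y)
    accuracy = float(np.mean(clf.predict(latent.z) == y))
    return Separator(clf.coef_[0], float(clf.intercept_[0]), accuracy)


def find_extreme_regions(
    latent: LatentRepresentation,
    separator: Separator,
    quantile_q: float = DEFAULT_QUANTILE,
) -> ExtremeRegions:
    """Top-q |signed distance| correct-side members of each class."""
    if not (0 < quantile_q <= 1):
        raise ValueError("quantile_q must lie in (0, 1]")
    dist = separator.signed_distance(latent.z)
    members: dict[int, np.ndarray] = {}
    thresholds: dict[int, float] = {}
    side_signs = {1: 1, 0: -1}
    for c, sign in side_signs.items():
        cls_idx = np.flatnonzero(latent.labels == c)
        correct = cls_idx[np.sign(dist[cls_idx]) == sign]
        if len(correct) == 0:
            raise ValueError(
                f"class {c} has no samples on its own side of the separator"
            )
        k = int(np.ceil(quantile_q * len(correct)))
        order = correct[np.argsort(-np.abs(dist[correct]), kind="stable")]
        members[c] = np.sort(order[:k])
        thresholds[c] = float(np.min(np.abs(dist[members[c]])))
    return ExtremeRegions(members, thresholds, side_signs, separator)


def draw_pseudo_samples(
    regions: ExtremeRegions,
    latent: LatentRepresentation,
    model: VAE,
    n_per_class: int = DEFAULT_N_PSEUDO,
    seed: int = 0,
) -> PseudoSampleSet:
    """Sample latent points from extreme members' posteriors and decode.

    Each draw picks a region member uniformly and samples
    z ~ N(mu_member, sigma_member); draws landing on the wrong side of the
    separator are rejected and redrawn (at most 100 attempts per draw).
    Decoding is deterministic, so the pseudo-sample set is a pure function
    of the seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    sep = regions.separator
    zs, labels = [], []
    for c in (0, 1):
        sign = regions.side_signs[c]
        members = regions.members[c]
        for _ in range(n_per_class):
            for attempt in range(MAX_REJECTION_ATTEMPTS):
                m = members[rng.integers(len(members))]
                z = latent.mu[m] + latent.sigma[m] * rng.standard_normal(
                    latent.mu.shape[1]
                )
                if np.sign(sep.signed_distance(z)[0]) == sign:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a class-{c} latent point on the correct side "
                    f"in {MAX_REJECTION_ATTEMPTS} attempts; increase quantile_q or "
                    "train the VAE longer"
                )
            zs.append(z)
            labels.append(c)
    Z = np.vstack(zs)
    X = model.decode(Z)
    return PseudoSampleSet(
        values=X,
        labels=np.asarray(labels, dtype=int),
        latent_points=Z,
        gene_ids=list(model.feature_names) if model.feature_names else None,
    )


def rank_by_eps(pseudo: PseudoSampleSet, gene_ids: list[str] | None = None) -> GeneRanking:
    """Rank genes by |logistic coefficient| on the pseudo-samples.

    Features are standardized across pseudo-samples first (constant
    features map to 0 and therefore receive coefficient 0).
    """
    if pseudo.n_per_class < 2:
        raise ValueError("need at least 2 pseudo-samples per class")
    names = gene_ids if gene_ids is not None else pseudo.gene_ids
    if names is None:
        raise ValueError("gene identifiers are required to build a ranking")
    X = pseudo.values
    # exact constancy check (a numerical std of a constant column can be
    # a nonzero rounding artifact, which would explode after scaling)
    constant = X.max(axis=0) == X.min(axis=0)
    center = np.where(constant, X[0], X.mean(axis=0))
    scale = np.where(constant, 1.0, X.std(axis=0))
    Xs = (X - center) / scale
    clf = LogisticRegression(C=1.0 / LOGISTIC_L2, max_iter=5000)
    clf.fit(Xs, pseudo.labels)
    score = np.abs(clf.coef_[0])
    df = pd.DataFrame({"gene_id": names, "score": score})
    df = df.sort_values(["score", "gene_id"], ascending=[False, True])
    return GeneRanking("EPS", list(df["gene_id"]), df["score"].to_numpy())


@dataclass
class EPSResult:
    """Everything the pipeline produced, for inspection and testing."""

    ranking: GeneRanking
    model: VAE
    history: TrainingHistory
    latent: LatentRepresentation
    separator: Separator
    regions: ExtremeRegions
    pseudo: PseudoSampleSet


def eps_ranking(
    features: FeatureMatrix,
    labels: SampleMetadata,
    split: SplitSpec,
    arch: VAEArchitecture | None = None,
    epochs: int = 300,
    kl_weight: float = 0.2,
    quantile_q: float = DEFAULT_QUANTILE,
    n_per_class: int = DEFAULT_N_PSEUDO,
    seed: int = 0,
    batch_size: int = 32,
    learning_rate: float = 2e-3,
) -> EPSResult:
    """Run the full EPS pipeline on the training samples of a split."""
    train_ids = list(split.training_ids)
    X = features.rows(train_ids)
    y = (labels.table.loc[train_ids, "condition"] == CASE).to_numpy(dtype=int)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 training samples per class")
    if arch is None:
        arch = VAEArchitecture.desk(X.shape[1])
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31 - 1)
    model, history = train_vae(
        X, arch, epochs=epochs, kl_weight=kl_weight, seed=int(seeds[0]),
        batch_size=batch_size, learning_rate=learning_rate,
        feature_names=list(features.gene_ids),
    )
    latent = embed(model, X, train_ids, y, seed=int(seeds[1]))
    separator = fit_separator(latent)
    regions = find_extreme_regions(latent, separator, quantile_q)
    pseudo = draw_pseudo_samples(
        regions, latent, model, n_per_class=n_per_class, seed=int(seeds[2])
    )
    ranking = rank_by_eps(pseudo)
    return EPSResult(ranking, model, history, latent, separator, regions, pseudo)
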