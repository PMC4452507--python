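"""Cross-validation protocol: negative sampling, folds, AUC, and the CV driver.

Three prediction settings are supported:

* ``pair``    — samples are split at random into folds (warm associations).
* ``drug``    — the *drugs* are partitioned; each fold's test set is every
                sample touching that fold's drugs, so test drugs have no
                training associations (cold-start drugs).
* ``disease`` — symmetric over diseases (cold-start / orphan diseases).

Three model modes mirror the ablation design:

* ``full`` — warm-start A, B from genomic-space features, then train.
* ``fv``   — no training at all: score by the (sigmoid of the) dot product
             of the warm-start feature vectors.
* ``mf``   — random initialization, then train (no genomic space).

Negatives are drawn uniformly from non-positive pairs at ``neg_ratio`` per
positive, once per repeat so all folds of a repeat share one sample universe.
Features derive only from the gene network and the entity-gene maps — never
from association labels — so they are computed once outside the folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from . import mf as mf_mod
from .features import BipartiteInteractions, aggregate_features, init_missing
from .mf import DEFAULT_ETA, DEFAULT_LAMBDA, LabeledPairSet, MatrixFactorization
from .network import DEFAULT_A_PRIME, DEFAULT_B_PRIME, GeneNetwork, gene_feature_space

SETTINGS = ("pair", "drug", "disease")
MODES = ("full", "fv", "mf")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and model hyperparameters (defaults mirror the method's)."""

    n_folds: int = 10
    n_repeats: int = 5
    neg_ratio: float = 2.0
    setting: str = "pair"
    mode: str = "full"
    seed: int = 0
    k: int = 32
    lambda_reg: float = DEFAULT_LAMBDA
    eta: float = DEFAULT_ETA
    max_epochs: int = 500
    tol: float = 1e-5
    a_prime: float = DEFAULT_A_PRIME
    b_prime: float = DEFAULT_B_PRIME
    init_scale: float = 0.1

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be positive")
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class CVResult:
    """Per-repeat, per-fold AUCs and their grand mean."""

    aucs: np.ndarray = field(repr=False)  # shape (n_repeats, n_folds)
    config: CVConfig = None

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def repeat_means(self) -> np.ndarray:
        return self.aucs.mean(axis=1)

    @property
    def sem(self) -> float:
        """Standard error of the mean over repeat-level means."""
        reps = self.repeat_means
        return float(reps.std(ddof=1) / np.sqrt(len(reps)))


def sample_negatives(
    positives: LabeledPairSet,
    n_drugs: int,
    n_diseases: int,
    ratio: float = 2.0,
    seed: int = 0,
) -> LabeledPairSet:
    """Uniform sample of non-positive pairs, ``round(ratio * n_pos)`` of them.

    Sampling is without replacement from the (drug x disease) grid minus the
    positives, so negatives never collide with positives or each other.
    """
    n_pos = len(positives)
    n_neg = int(round(ratio * n_pos))
    grid = n_drugs * n_diseases
    pos_flat = positives.drug_idx * n_diseases + positives.disease_idx
    n_avail = grid - n_pos
    if n_neg > n_avail:
        raise ValueError(
            f"cannot draw {n_neg} negatives from a {n_drugs}x{n_diseases} grid "
            f"with {n_pos} positives; at most {n_avail} available"
        )
    mask = np.ones(grid, dtype=bool)
    mask[pos_flat] = False
    candidates = np.flatnonzero(mask)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_neg, replace=False)
    return LabeledPairSet(
        drug_idx=chosen // n_diseases,
        disease_idx=chosen % n_diseases,
        labels=np.zeros(n_neg),
    )


def split_folds(
    samples: LabeledPairSet,
    config: CVConfig,
    n_drugs: int,
    n_diseases: int,
    seed: int = 0,
) -> list[tuple[LabeledPairSet, LabeledPairSet]]:
    """Per-fold (train, test) splits for the configured prediction setting.

    Pair setting: the samples are shuffled and cut into ``n_folds`` near-equal
    parts. Drug/disease setting: the *entities* are shuffled and cut; a fold's
    test set is every sample touching that fold's entities. Test folds are
    disjoint and cover all samples in every setting.
    """
    rng = np.random.default_rng(seed)
    n = len(samples)
    folds = []
    if config.setting == "pair":
        parts = np.array_split(rng.permutation(n), config.n_folds)
        for part in parts:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[part] = True
            folds.append((samples.subset(~test_mask), samples.subset(test_mask)))
        return folds
    n_entities = n_drugs if config.setting == "drug" else n_diseases
    if n_entities < config.n_folds:
        raise ValueError(
            f"{config.setting} setting needs at least {config.n_folds} "
            f"{config.setting}s, got {n_entities}"
        )
    entity_idx = samples.drug_idx if config.setting == "drug" else samples.disease_idx
    parts = np.array_split(rng.permutation(n_entities), config.n_folds)
    for part in parts:
        test_mask = np.isin(entity_idx, part)
        folds.append((samples.subset(~test_mask), samples.subset(test_mask)))
    return folds


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties counted 1/2)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs at least one positive and one negative label")
    return float(roc_auc_score(labels, scores))


def _child_seed(*parts: int) -> int:
    """Deterministic 31-bit seed derived from integer components."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def build_feature_spaces(
    network: GeneNetwork,
    drug_genes: BipartiteInteractions,
    disease_genes: BipartiteInteractions,
    config: CVConfig,
):
    """Gene -> drug/disease feature spaces for the given data (label-free).

    The gene space covers the genes of interest: every gene occurring in a
    drug-gene or disease-gene pair. Entities without interactors get seeded
    random vectors.
    """
    goi = sorted({g for _, g in drug_genes.pairs} | {g for _, g in disease_genes.pairs})
    gene_space = gene_feature_space(
        network, goi, config.k, a_prime=config.a_prime, b_prime=config.b_prime
    )
    drug_space = init_missing(
        aggregate_features(drug_genes, gene_space),
        scale=config.init_scale, seed=_child_seed(config.seed, 101),
    )
    disease_space = init_missing(
        aggregate_features(disease_genes, gene_space),
        scale=config.init_scale, seed=_child_seed(config.seed, 102),
    )
    return gene_space, drug_space, disease_space


def _fit_fold(
    mode: str,
    A0: np.ndarray,
    B0: np.ndarray,
    train_set: LabeledPairSet,
    config: CVConfig,
    seed: int,
) -> MatrixFactorization:
    """Train (or not, for fv) one fold's model from the appropriate start."""
    if mode == "fv":
        model = MatrixFactorization(k=A0.shape[1], init="warm")
        return model.warm_start(A0, B0)
    if mode == "full":
        model = MatrixFactorization(
            k=A0.shape[1], lambda_reg=config.lambda_reg, eta=config.eta,
            max_epochs=config.max_epochs, tol=config.tol, init="warm",
        )
        model.warm_start(A0, B0)
    else:  # mf: random init, genomic space unused
        model = mf_mod.init_model_random(
            n_drugs=A0.shape[0], n_diseases=B0.shape[0], k=config.k,
            lambda_reg=config.lambda_reg, eta=config.eta,
            init_scale=config.init_scale, seed=_child_seed(seed, 1),
            max_epochs=config.max_epochs, tol=config.tol,
        )
    model._train(train_set, seed=_child_seed(seed, 2))
    return model


def cross_validate(
    network: GeneNetwork,
    drug_genes: BipartiteInteractions,
    disease_genes: BipartiteInteractions,
    positives: LabeledPairSet,
    config: CVConfig,
) -> CVResult:
    """Repeated k-fold cross-validation of one mode in one setting.

    Each repeat draws a fresh negative set (``neg_ratio`` per positive) from
    a repeat-specific seed, splits into folds per the setting, fits per the
    mode and records the test-fold AUC of the association scores.
    """
    n_drugs, n_diseases = drug_genes.n_rows, disease_genes.n_rows
    _, drug_space, disease_space = build_feature_spaces(
        network, drug_genes, disease_genes, config
    )
    A0, B0 = drug_space.X, disease_space.X
    aucs = np.empty((config.n_repeats, config.n_folds))
    for rep in range(config.n_repeats):
        rep_seed = _child_seed(config.seed, 7, rep)
        negatives = sample_negatives(
            positives, n_drugs, n_diseases, config.neg_ratio,
            seed=_child_seed(rep_seed, 11),
        )
        samples = positives.concat(negatives)
        folds = split_folds(
            samples, config, n_drugs, n_diseases, seed=_child_seed(rep_seed, 13)
        )
        for f, (train_set, test_set) in enumerate(folds):
            model = _fit_fold(
                config.mode, A0, B0, train_set, config, seed=_child_seed(rep_seed, 17, f)
            )
            X_test = np.column_stack([test_set.drug_idx, test_set.disease_idx])
            scores = model.predict_proba(X_test)
            aucs[rep, f] = roc_auc(test_set.labels, scores)
    return CVResult(aucs=aucs, config=config)


def compare_modes(
    network, drug_genes, disease_genes, positives, config: CVConfig,
    modes=MODES,
) -> dict[str, CVResult]:
    """Run cross_validate for several modes under one config."""
    return {
        m: cross_validate(
            network, drug_genes, disease_genes, positives, replace(config, mode=m)
        )
        for m in modes
    }
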