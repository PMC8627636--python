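"""scikit-learn estimator wrapping the full selection pipeline.

``MaPSOGSSelector`` is a feature selector in the sklearn sense: ``fit(X, y)``
runs Fisher filtering, graph construction, Louvain clustering and the
many-objective swarm search on the training data, after which ``transform``
restricts any matrix to the selected genes. It composes with ``Pipeline``
and ``clone`` like any other ``SelectorMixin`` estimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .data import ExpressionDataset, RunConfig
from .swarm import run_mapsogs

__all__ = ["MaPSOGSSelector"]


class MaPSOGSSelector(SelectorMixin, BaseEstimator):
    """Graph-based many-objective PSO gene selector.

    Parameters mirror the pipeline configuration: the Fisher filter
    (``filter_mode``, ``lambda_threshold``, ``top_m``), the similarity graph
    (``theta``), the repair operator (``omega``) and the swarm
    (``swarm_size``, ``max_iterations``, ``inertia_w``, ``c1``, ``c2``,
    ``v_max``, ``archive_capacity``). ``classifier_spec`` names the wrapped
    evaluator ("svm", "dt" or "knn:k=5") scored with ``cv_folds``-fold
    stratified cross-validation inside the fitness function.

    Attributes (after fit)
    ----------------------
    support_ : bool ndarray of shape (n_features,)
        Mask of the selected genes over the original feature axis.
    selected_features_ : int ndarray
        Indices of the selected genes.
    result_ : SelectionResult
        Full pipeline output (archive, clustering, trace, scores).
    n_features_in_ : int
    """

    def __init__(
        self,
        filter_mode: str = "top-m",
        lambda_threshold: float = 0.0,
        top_m: int = 300,
        theta: float = 0.6,
        omega: int = 1,
        swarm_size: int = 30,
        max_iterations: int = 100,
        inertia_w: float = 0.7,
        c1: float = 2.0,
        c2: float = 2.0,
        v_max: float = 4.0,
        archive_capacity: int = 50,
        cv_folds: int = 5,
        classifier_spec: str = "svm",
        node_centrality_measure: str = "eigenvector",
        edge_centrality_measure: str = "direct-weight",
        use_repair: bool = True,
        epsilon: float = 1e-6,
        random_state: int = 0,
    ):
        self.filter_mode = filter_mode
        self.lambda_threshold = lambda_threshold
        self.top_m = top_m
        self.theta = theta
        self.omega = omega
        self.swarm_size = swarm_size
        self.max_iterations = max_iterations
        self.inertia_w = inertia_w
        self.c1 = c1
        self.c2 = c2
        self.v_max = v_max
        self.archive_capacity = archive_capacity
        self.cv_folds = cv_folds
        self.classifier_spec = classifier_spec
        self.node_centrality_measure = node_centrality_measure
        self.edge_centrality_measure = edge_centrality_measure
        self.use_repair = use_repair
        self.epsilon = epsilon
        self.random_state = random_state

    def _to_config(self) -> RunConfig:
        return RunConfig(
            filter_mode=self.filter_mode,
            lambda_threshold=self.lambda_threshold,
            top_m=self.top_m,
            theta=self.theta,
            omega=self.omega,
            swarm_size=self.swarm_size,
            max_iterations=self.max_iterations,
            inertia_w=self.inertia_w,
            c1=self.c1,
            c2=self.c2,
            v_max=self.v_max,
            archive_capacity=self.archive_capacity,
            cv_folds=self.cv_folds,
            classifier_spec=self.classifier_spec,
            node_centrality_measure=self.node_centrality_measure,
            edge_centrality_measure=self.edge_centrality_measure,
            use_repair=self.use_repair,
            epsilon=self.epsilon,
            seed=self.random_state,
        )

    def fit(self, X, y, gene_ids=None):
        """Run the selection pipeline on labeled training data.

        ``X`` is (n_samples, n_genes), ``y`` the class label per sample;
        ``gene_ids`` optionally names the columns (defaults to G1..Gn).
        """
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        if gene_ids is None:
            gene_ids = tuple(f"G{j + 1}" for j in range(X.shape[1]))
        dataset = ExpressionDataset(X, gene_ids, tuple(y))
        result = run_mapsogs(dataset, self._to_config())
        self.n_features_in_ = X.shape[1]
        self.gene_ids_ = tuple(gene_ids)
        self.result_ = result
        self.support_ = result.subset.mask(gene_ids)
        self.selected_features_ = np.flatnonzero(self.support_)
        self.selected_gene_ids_ = tuple(result.subset.gene_ids)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
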