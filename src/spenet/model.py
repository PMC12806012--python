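"""High-level model object tying data, encodings and the transformer together.

`ComorbidityModel` is the statsmodels-style entry point: construct it from
an interactome + disease map + scored pairs (or from the three TSV tables),
then `fit()` for a single trained model or `cross_validate()` for the full
k-fold protocol; both return results objects with `summary()`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import encoding as enc
from . import evaluation as ev
from . import training as tr
from .graph_data import (
    DiseaseMap,
    Interactome,
    RawPair,
    adjacency_matrix,
    label_pairs,
    load_disease_associations,
    load_edge_list,
    load_pair_table,
)
from .node_embedding import WalkConfig, node2vec_embedding
from .transformer import ModelConfig


class ComorbidityModel:
    """Disease-pair comorbidity classifier over an interactome.

    Parameters
    ----------
    graph, disease_map, raw_pairs
        The interactome, the disease modules on its index space, and the
        RR-scored disease pairs.
    mode
        Label convention: "RR0" (positive iff rr > 0) or "RR1"
        (positive iff rr >= 1).
    variant
        Positional-encoding variant: "NoPE", "LPE" or "SPE".
    gpe_d
        Width of the label-aware GPE block (SPE only).
    """

    def __init__(
        self,
        graph: Interactome,
        disease_map: DiseaseMap,
        raw_pairs: list[RawPair],
        mode: str = "RR1",
        variant: str = "SPE",
        walk_config: WalkConfig | None = None,
        model_config: ModelConfig | None = None,
        gpe_d: int = 8,
        node_embedding: np.ndarray | None = None,
    ):
        self.graph = graph
        self.disease_map = disease_map
        self.raw_pairs = raw_pairs
        self.dataset = label_pairs(raw_pairs, mode)
        self.variant = variant
        self.walk_config = walk_config or WalkConfig()
        self.gpe_d = gpe_d
        self._M = node_embedding
        self._bundle: enc.EncodingBundle | None = None
        d_model = self.walk_config.dim + (gpe_d if variant == "SPE" else 0)
        self.model_config = model_config or ModelConfig(d_model=d_model)

    @classmethod
    def from_tables(
        cls, edge_path, assoc_path, pair_path, **kwargs
    ) -> "ComorbidityModel":
        g = load_edge_list(edge_path)
        dm = load_disease_associations(assoc_path, g)
        pairs = load_pair_table(pair_path, dm)
        return cls(g, dm, pairs, **kwargs)

    # -- encodings ---------------------------------------------------------

    def node_embedding_matrix(self) -> np.ndarray:
        if self._M is None:
            self._M = node2vec_embedding(self.graph, self.walk_config)
        return self._M

    def encodings(self) -> enc.EncodingBundle:
        """Assemble (and cache) the per-node encoding for this variant."""
        if self._bundle is not None:
            return self._bundle
        M = self.node_embedding_matrix()
        lpe_m = gpe_m = None
        if self.variant in ("LPE", "SPE"):
            A = adjacency_matrix(self.graph)
            L = enc.normalized_laplacian(A)
            lpe_m = enc.laplacian_pe(L, k=M.shape[1])
            if self.variant == "SPE":
                W = enc.gee_weight_matrix(self.disease_map, self.graph.n_nodes)
                Z = enc.gee_embedding(A, W)
                gpe_m = enc.gpe(Z, d=self.gpe_d)
        self._bundle = enc.assemble_encoding(M, lpe_m, gpe_m, variant=self.variant)
        if self._bundle.d_model != self.model_config.d_model:
            raise ValueError(
                f"encoding width {self._bundle.d_model} != model d_model "
                f"{self.model_config.d_model}"
            )
        return self._bundle

    def disease_tokens(self) -> list[np.ndarray]:
        return tr.disease_tokens(self.encodings(), self.disease_map)

    # -- fitting -----------------------------------------------------------

    def fit(self, run: tr.TrainRun | None = None) -> tr.FitResult:
        """Train one transformer on all pairs (validation split held out)."""
        run = run or tr.TrainRun()
        return tr.fit_pair_transformer(
            list(self.dataset.pairs), self.disease_tokens(), self.model_config, run
        )

    def cross_validate(
        self,
        k: int = 10,
        run: tr.TrainRun | None = None,
        plan: ev.FoldPlan | None = None,
    ) -> ev.MetricsReport:
        """Stratified k-fold cross-validation; returns the metrics report."""
        run = run or tr.TrainRun()
        if plan is None:
            plan = ev.stratified_folds(self.dataset.labels, k=k, seed=run.seed)
        return tr.cross_validate(
            self.dataset, self.disease_tokens(), self.model_config, run, plan,
            variant=self.variant,
        )

    def with_variant(self, variant: str) -> "ComorbidityModel":
        """Same data and node embedding under a different PE variant
        (shares the cached embedding so ablations isolate the PE)."""
        d_model = self.walk_config.dim + (self.gpe_d if variant == "SPE" else 0)
        return ComorbidityModel(
            self.graph,
            self.disease_map,
            self.raw_pairs,
            mode=self.dataset.mode,
            variant=variant,
            walk_config=self.walk_config,
            model_config=replace(self.model_config, d_model=d_model),
            gpe_d=self.gpe_d,
            node_embedding=self.node_embedding_matrix(),
        )
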