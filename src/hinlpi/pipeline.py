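"""End-to-end orchestration: sequences -> similarity -> heterogeneous
network -> embeddings -> pair classification under cross-validation.

Each stage is the corresponding module's public surface; this file only
wires them together and threads the seed through every stochastic step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .autoencoder import ae_encode, ae_train
from .classify_eval import MetricReport, PairDataset, cross_validate, make_pairs
from .hetnet import (
    LNCRNA_FILTER,
    PROTEIN_FILTER,
    EdgeFilter,
    HeteroNetwork,
    build_network,
    filter_similarity_edges,
)
from .hin2vec import ModelParams, TrainConfig, node_embeddings, train
from .io_formats import BlastHitTable, EmbeddingTable, InteractionList, SequenceRecord
from .metapath import enumerate_relations, random_walks, walks_to_tuples
from .similarity import pairwise_similarity, toy_blast_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with the defaults used throughout."""

    k_rna: int = 4
    k_protein: int = 3
    lncrna_filter: EdgeFilter = field(default_factory=lambda: LNCRNA_FILTER)
    protein_filter: EdgeFilter = field(default_factory=lambda: PROTEIN_FILTER)
    max_metapath_len: int = 2
    walks_per_node: int = 10
    walk_length: int = 80
    neg_per_pos: int = 5
    train: TrainConfig = field(default_factory=TrainConfig)
    use_autoencoder: bool = False
    ae_rho: float = 0.05
    ae_beta: float = 0.1
    ae_epochs: int = 500
    ae_lr: float = 0.5
    classifier: str = "SVM"
    neg_ratio: float = 1.0
    combiner: str = "concat"
    cv_folds: int = 5
    seed: int = 0


@dataclass
class PipelineResult:
    network: HeteroNetwork
    edge_counts: dict[str, int]
    embeddings: EmbeddingTable
    params: ModelParams
    trace: list[float]
    dataset: PairDataset
    report: MetricReport


def build_hetnet_from_sequences(
    lncrnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    interactions: InteractionList,
    config: PipelineConfig,
    lncrna_blast: BlastHitTable | None = None,
    protein_blast: BlastHitTable | None = None,
) -> tuple[HeteroNetwork, dict[str, int]]:
    """Similarity computation + edge filtering + network assembly. When no
    BLAST tables are supplied, the internal local-alignment pseudo-e-values
    stand in so the thresholds stay meaningful."""
    if lncrna_blast is None:
        lncrna_blast = toy_blast_table(lncrnas)
    if protein_blast is None:
        protein_blast = toy_blast_table(proteins)
    l_table = pairwise_similarity(lncrnas, config.k_rna, lncrna_blast)
    p_table = pairwise_similarity(proteins, config.k_protein, protein_blast)
    l_edges = filter_similarity_edges(l_table, config.lncrna_filter)
    p_edges = filter_similarity_edges(p_table, config.protein_filter)
    net, counts = build_network(
        l_edges,
        p_edges,
        interactions,
        [r.id for r in lncrnas],
        [r.id for r in proteins],
    )
    logger.info("network: %d nodes, edge counts %s", net.num_nodes, counts)
    return net, counts


def embed_network(
    network: HeteroNetwork, config: PipelineConfig
) -> tuple[ModelParams, list[float], EmbeddingTable]:
    """Walk generation, tuple preparation and embedding training."""
    relations = enumerate_relations(
        ("L", "P"),
        config.max_metapath_len,
        network.present_edge_types(),
    )
    walks = random_walks(
        network, config.walks_per_node, config.walk_length, config.seed
    )
    tuples = walks_to_tuples(
        walks,
        network,
        relations,
        config.max_metapath_len,
        config.neg_per_pos,
        config.seed,
    )
    logger.info("prepared %d training tuples over %d relations",
                len(tuples), len(relations))
    train_cfg = config.train
    if train_cfg.seed != config.seed:
        train_cfg = TrainConfig(
            d=train_cfg.d, lr=train_cfg.lr, epochs=train_cfg.epochs,
            seed=config.seed, init_scale=train_cfg.init_scale,
            export=train_cfg.export,
        )
    params, trace = train(network, relations, tuples, train_cfg)
    return params, trace, node_embeddings(params, train_cfg.export)


def run_pipeline(
    lncrnas: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    interactions: InteractionList,
    config: PipelineConfig | None = None,
    lncrna_blast: BlastHitTable | None = None,
    protein_blast: BlastHitTable | None = None,
) -> PipelineResult:
    """The full method: similarity networks, heterogeneous network,
    embedding training, optional sparse-autoencoder lift, pair assembly
    and cross-validated classification."""
    config = config or PipelineConfig()
    network, counts = build_hetnet_from_sequences(
        lncrnas, proteins, interactions, config, lncrna_blast, protein_blast
    )
    params, trace, embeddings = embed_network(network, config)
    if config.use_autoencoder:
        ae = ae_train(
            embeddings,
            rho=config.ae_rho,
            beta=config.ae_beta,
            epochs=config.ae_epochs,
            lr=config.ae_lr,
            seed=config.seed,
        )
        embeddings = ae_encode(ae, embeddings)
    dataset = make_pairs(
        embeddings,
        interactions,
        neg_ratio=config.neg_ratio,
        seed=config.seed,
        combiner=config.combiner,
        lncrna_ids=[r.id for r in lncrnas],
        protein_ids=[r.id for r in proteins],
    )
    report = cross_validate(
        dataset, config.classifier, k=config.cv_folds, seed=config.seed
    )
    return PipelineResult(network, counts, embeddings, params, trace, dataset, report)
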