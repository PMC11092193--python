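"""End-to-end pipeline: similarity -> fusion -> SAE -> pair features -> CV.

``run_pipeline`` chains the stages for one fusion weight and persists every
intermediate artifact (similarity matrices, embeddings, the cross-validation
report and per-fold ROC points) plus a log of all resolved parameters, so a
run is a pure function of (inputs, config, seed).

By default the similarity matrices are computed on the full network,
including pairs later held out as CV test examples — matching the protocol
the method was described with.  ``mask_test_edges`` enables a
leakage-controlled mode that recomputes the network similarity per fold with
the test fold's positive edges removed (retraining the SAE per fold).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import data_io
from .data_io import InteractionNetwork, PairDataset, ProteinSet
from .embedding import SAEConfig, encode, train_sae
from .evaluate import (
    ClassifierSpec,
    CVReport,
    _aggregate,
    build_pair_features,
    cv_splitter,
    evaluate_fold,
    make_classifier,
    run_cv,
)
from .similarity import fuse, gip_similarity, sequence_similarity_matrix


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    fasta: str
    pairs: str
    out_dir: str
    alpha: float = 0.5
    seq_normalization: str = "max"
    sae: SAEConfig = field(default_factory=SAEConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k: int = 5
    seed: int = 0
    stratify: bool = True
    mask_test_edges: bool = False
    per_fold_sae: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        # out_dir does not influence the computation, only where it lands
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _mask_positives(network: InteractionNetwork, pairs: np.ndarray) -> InteractionNetwork:
    adjacency = network.adjacency.copy()
    adjacency[pairs[:, 0], pairs[:, 1]] = 0
    adjacency[pairs[:, 1], pairs[:, 0]] = 0
    return InteractionNetwork(adjacency=adjacency)


def run_cv_per_fold(
    proteins: ProteinSet,
    network: InteractionNetwork,
    dataset: PairDataset,
    alpha: float,
    sae_config: SAEConfig,
    spec: ClassifierSpec,
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
    mask_test_edges: bool = False,
    seq_normalization: str = "max",
) -> CVReport:
    """Cross-validation with the SAE retrained per fold.

    With ``mask_test_edges`` the network similarity is recomputed per fold
    from an adjacency with the test fold's positive edges removed, so no test
    interaction leaks into the features.
    """
    s_seq = sequence_similarity_matrix(proteins, normalization=seq_normalization)
    x, y = dataset.pairs, dataset.labels
    folds = []
    for train_idx, test_idx in cv_splitter(k, seed, stratify).split(x, y):
        fold_network = network
        if mask_test_edges:
            test_pos = x[test_idx][y[test_idx] == 1]
            fold_network = _mask_positives(network, test_pos)
        s_net = gip_similarity(fold_network)
        fused = fuse(s_net, s_seq, alpha)
        encoder, _ = train_sae(fused, sae_config)
        embeddings = encode(encoder, fused.values)
        feats = build_pair_features(embeddings, dataset)
        model = make_classifier(spec)
        model.fit(feats.features[train_idx], y[train_idx])
        folds.append(evaluate_fold(model, feats.features[test_idx], y[test_idx]))
    report = _aggregate(folds, k, spec, alpha=float(alpha))
    return report


def run_pipeline(config: RunConfig) -> CVReport:
    """Execute the full pipeline and persist all artifacts under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    proteins = data_io.read_fasta(config.fasta)
    dataset = data_io.read_pairs_tsv(config.pairs, proteins)
    network = data_io.build_network(dataset, len(proteins))

    s_net = gip_similarity(network)
    s_seq = sequence_similarity_matrix(proteins, normalization=config.seq_normalization)
    fused = fuse(s_net, s_seq, config.alpha)
    data_io.write_matrix_tsv(out / "s_network.tsv", proteins.ids, s_net.values)
    data_io.write_matrix_tsv(out / "s_seq.tsv", proteins.ids, s_seq.values)
    data_io.write_matrix_tsv(out / "fused.tsv", proteins.ids, fused.values)

    encoder, history = train_sae(fused, config.sae)
    embeddings = encode(encoder, fused.values)
    data_io.write_embeddings(out / "embeddings.tsv", proteins.ids, embeddings)
    (out / "training_history.json").write_text(
        json.dumps(history.to_dict(), indent=1)
    )

    if config.mask_test_edges or config.per_fold_sae:
        report = run_cv_per_fold(
            proteins, network, dataset, config.alpha, config.sae,
            config.classifier, k=config.k, seed=config.seed,
            stratify=config.stratify, mask_test_edges=config.mask_test_edges,
            seq_normalization=config.seq_normalization,
        )
    else:
        features = build_pair_features(embeddings, dataset)
        report = run_cv(
            features, config.classifier, k=config.k, seed=config.seed,
            stratify=config.stratify,
        )
        report.alpha = float(config.alpha)

    payload = report.to_dict()
    payload["seed"] = config.seed
    payload["config_digest"] = config.digest()
    (out / "report.json").write_text(json.dumps(payload, indent=1))
    for i, fold in enumerate(report.folds, start=1):
        if fold.roc_points is not None:
            np.savetxt(
                out / f"roc_fold{i}.tsv", fold.roc_points, delimiter="\t",
                header="fpr\ttpr", comments="",
            )
    (out / "run_log.json").write_text(
        json.dumps(
            {"config": config.to_dict(), "config_digest": config.digest(),
             "n_proteins": len(proteins), "n_pairs": len(dataset),
             "n_edges": network.n_edges},
            indent=1, default=str,
        )
    )
    return report
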