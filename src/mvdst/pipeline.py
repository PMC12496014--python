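"""End-to-end convenience wrapper: views -> training -> latent/denoised.

Used by the CLI, the benchmark driver, and the acceptance checks so they
all exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import SRTDataset
from .model import ModelConfig, TrainedModel, denoise, encode, train
from .multiview import AffinityGraph, FilteredExpression, build_knn_affinity, laplacian_filter

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    Z: np.ndarray
    denoised: np.ndarray
    filtered: FilteredExpression
    model: TrainedModel
    spatial_graph: AffinityGraph
    morphology_graph: AffinityGraph | None


def run_pipeline(
    ds: SRTDataset,
    config: ModelConfig | None = None,
    features: np.ndarray | None = None,
    use_morphology: bool = True,
) -> PipelineResult:
    """Build graphs, filter expression, train, and produce Z and denoised X.

    ``features`` overrides the matrix fed to the filter/autoencoder (e.g. a
    neighbourhood-augmented matrix); it defaults to the dataset expression.
    """
    config = config or ModelConfig()
    X = ds.dense_expression() if features is None else np.asarray(features, float)
    As = build_knn_affinity(ds.coords, config.k_spatial, view="spatial")
    Am = None
    if use_morphology and ds.morphology is not None:
        Am = build_knn_affinity(
            ds.morphology, config.k_morph, view="morphology"
        )
    Xf = laplacian_filter(X, As, t=config.filter_order)
    model = train(Xf, As, Am, config)
    latent = encode(Xf, model, perturb=False)
    return PipelineResult(
        Z=latent.Z,
        denoised=denoise(model, Xf),
        filtered=Xf,
        model=model,
        spatial_graph=As,
        morphology_graph=Am,
    )
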