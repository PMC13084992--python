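"""Population structure via PCA of the (LD-pruned) genotype matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix


def pca(
    gm: GenotypeMatrix,
    n_components: int = 2,
    scaling: str = "unit-variance",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal component analysis of alt-allele dosages across individuals.

    Each site is centred; with ``scaling="unit-variance"`` (the default,
    matching the common population-genetic practice of standardising
    genotypes) it is additionally divided by its standard deviation, with
    monomorphic sites left at zero. Returns per-individual coordinates and
    the fraction of total variance explained by each component. The sign of
    each component is fixed so that its largest-magnitude loading is
    positive.
    """
    if (gm.genotypes == MISSING).any():
        raise ValueError("PCA requires a matrix without missing genotypes")
    n, s = gm.genotypes.shape
    if n < 2:
        raise ValueError("PCA requires at least two individuals")
    max_rank = min(n - 1, s)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank bound {max_rank}")
    if scaling not in ("unit-variance", "center-only"):
        raise ValueError(f"unknown scaling {scaling!r}")
    x = gm.genotypes.astype(float)
    x -= x.mean(axis=0)
    if scaling == "unit-variance":
        sd = x.std(axis=0)
        nonzero = sd > 0
        x[:, nonzero] /= sd[nonzero]
    # economy SVD: components are eigenvectors of the individual covariance
    u, singular, _vt = np.linalg.svd(x, full_matrices=False)
    coords = u * singular
    total_var = (singular**2).sum()
    fractions = (singular[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    coords = coords[:, :n_components]
    for k in range(coords.shape[1]):
        if np.abs(coords[:, k]).size and coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1
    frame = pd.DataFrame(
        coords,
        index=gm.individuals,
        columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
    )
    return frame, fractions
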