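"""Functional trait space: mixed-type dissimilarity, principal coordinates,
axis retention.

The pipeline's default trait space keeps the first five principal-coordinate
axes of the Gower dissimilarity matrix (equal trait weights; ordered
categorical traits contribute range-normalized rank differences) and measures
all downstream functional distances in that retained-axis Euclidean space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TraitTable
from .errors import ValidationError

logger = logging.getLogger("riverdiv")

__all__ = ["TraitSpace", "PcoaResult", "gower_dissimilarity", "pcoa", "build_trait_space"]


def gower_dissimilarity(traits: TraitTable, weights: dict | None = None) -> pd.DataFrame:
    """Pairwise Gower dissimilarity over all traits, in [0, 1].

    Continuous traits contribute ``|x_i - x_j| / range``; nominal categorical
    traits contribute a 0/1 mismatch; ordinal categorical traits contribute the
    range-normalized rank difference. A trait with zero range contributes 0 and
    logs a warning. Weights default to 1 per trait.
    """
    schema = traits.schema
    names = schema.columns
    if len(traits.species) < 2:
        raise ValidationError("need at least 2 species for a dissimilarity matrix")
    w = np.array([1.0 if weights is None else float(weights.get(c, 1.0)) for c in names])
    if np.any(w < 0) or w.sum() == 0:
        raise ValidationError("weights must be non-negative and not all zero")

    n = len(traits.species)
    num = np.zeros((n, n))
    wsum = 0.0
    for col, wt in zip(names, w):
        if wt == 0:
            continue
        if col in schema.continuous:
            x = traits.table[col].to_numpy(float)
        elif col in schema.ordinal:
            x = traits.ordinal_ranks(col).to_numpy(float)
        else:
            lab = traits.table[col].to_numpy()
            contrib = (lab[:, None] != lab[None, :]).astype(float)
            num += wt * contrib
            wsum += wt
            continue
        rng = np.ptp(x)
        if rng == 0:
            logger.warning("trait %r has zero range; contributes 0 to Gower", col)
            wsum += wt
            continue
        num += wt * np.abs(x[:, None] - x[None, :]) / rng
        wsum += wt
    d = num / wsum
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=traits.species, columns=traits.species)


@dataclass
class PcoaResult:
    """Full principal-coordinate decomposition of a dissimilarity matrix."""

    species: list
    coordinates: np.ndarray       # n x n_positive, ordered by descending eigenvalue
    eigenvalues: np.ndarray       # full (post-correction) spectrum, descending
    cumulative_variance: np.ndarray  # prefix fractions over positive eigenvalues
    correction: str

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dissimilarity, correction: str = "lingoes", _tol: float = 1e-9) -> PcoaResult:
    """Principal coordinates of a symmetric zero-diagonal dissimilarity matrix.

    ``lingoes`` adds the smallest constant to squared off-diagonal distances
    that removes negative eigenvalues; ``cailliez`` adds a constant to the
    distances themselves; ``none`` keeps negative eigenvalues and normalizes
    variance by the positive part only. Axis signs are fixed by making each
    axis's largest-magnitude loading positive.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        species = list(dissimilarity.index)
        d = dissimilarity.to_numpy(float)
    else:
        d = np.asarray(dissimilarity, float)
        species = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("dissimilarity must be symmetric")
    if correction not in ("none", "lingoes", "cailliez"):
        raise ValueError(f"unknown correction {correction!r}")

    n = d.shape[0]
    evals = np.linalg.eigvalsh(_double_center(d ** 2))
    min_eig = evals.min()
    off = ~np.eye(n, dtype=bool)
    if correction == "lingoes" and min_eig < -_tol * max(1.0, abs(evals).max()):
        c1 = -min_eig
        d = d.copy()
        d[off] = np.sqrt(d[off] ** 2 + 2.0 * c1)
    elif correction == "cailliez" and min_eig < -_tol * max(1.0, abs(evals).max()):
        # smallest additive constant: largest eigenvalue of the 2n x 2n block matrix
        b1 = _double_center(d ** 2)
        b2 = _double_center(d)
        block = np.block([
            [np.zeros((n, n)), 2.0 * b1],
            [-np.eye(n), -4.0 * b2],
        ])
        c2 = float(np.max(np.linalg.eigvals(block).real))
        d = d.copy()
        d[off] = d[off] + c2

    evals, evecs = np.linalg.eigh(_double_center(d ** 2))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = abs(evals).max() if evals.size else 1.0
    pos = evals > _tol * max(1.0, scale)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    # deterministic axis orientation
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = evals[pos].sum()
    cumvar = np.cumsum(evals[pos]) / pos_sum if pos_sum > 0 else np.array([])
    return PcoaResult(species=species, coordinates=coords, eigenvalues=evals,
                      cumulative_variance=cumvar, correction=correction)


@dataclass
class TraitSpace:
    """Species coordinates on the retained axes plus eigenvalue diagnostics."""

    species: list
    coordinates: pd.DataFrame      # species x n_axes
    eigenvalues: np.ndarray
    cumulative_variance: np.ndarray
    distance_matrix: pd.DataFrame  # Euclidean distances on retained axes
    correction: str

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def points(self, species) -> np.ndarray:
        return self.coordinates.loc[list(species)].to_numpy(float)

    def distances(self, species) -> np.ndarray:
        sp = list(species)
        return self.distance_matrix.loc[sp, sp].to_numpy(float)


def build_trait_space(traits: TraitTable, n_axes: int = 5, correction: str = "lingoes",
                      weights: dict | None = None) -> TraitSpace:
    """Gower -> PCoA -> retain ``n_axes`` axes -> Euclidean distances."""
    gower = gower_dissimilarity(traits, weights)
    res = pcoa(gower, correction=correction)
    if n_axes > res.n_positive:
        raise ValidationError(
            f"requested {n_axes} axes but only {res.n_positive} positive axes available"
        )
    coords = pd.DataFrame(res.coordinates[:, :n_axes], index=res.species,
                          columns=[f"axis{i+1}" for i in range(n_axes)])
    pts = coords.to_numpy()
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return TraitSpace(
        species=res.species,
        coordinates=coords,
        eigenvalues=res.eigenvalues,
        cumulative_variance=res.cumulative_variance,
        distance_matrix=pd.DataFrame(dist, index=res.species, columns=res.species),
        correction=correction,
    )
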