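"""Point Distribution Model: PCA of aligned, corresponded landmark sets.

The model follows the classic construction: stack each shape's landmarks
into a 3n-vector, take the arithmetic mean, and eigen-decompose the sample
covariance (divisor ``n_samples - 1``) of the centered data.  Because the
number of specimens is far smaller than 3n, the decomposition is done by
SVD of the centered data matrix, which is rank-revealing and numerically
safe.  Shape variation is summarized by the number of modes needed to reach
an explained-variance threshold (95% by convention).

The API is organized as a model/results pair: build a
:class:`PointDistributionModel` from shapes, call :meth:`fit`, and work with
the returned :class:`PDMResults` (projection, synthesis, per-mode deviation
shapes, sampling, summary table).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correspond import CorrespondedShape

__all__ = ["PointDistributionModel", "PDMResults", "build_pdm", "num_modes"]


def _as_matrix(shapes) -> tuple[np.ndarray, int]:
    rows = []
    n_landmarks = None
    for s in shapes:
        pts = s.points if isinstance(s, CorrespondedShape) else np.asarray(s, float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("each shape must be an (n, 3) landmark array")
        if n_landmarks is None:
            n_landmarks = len(pts)
        elif len(pts) != n_landmarks:
            raise ValueError("all shapes must have the same landmark count")
        rows.append(pts.reshape(-1))
    data = np.asarray(rows, dtype=float)
    if not np.isfinite(data).all():
        raise ValueError("shapes contain non-finite coordinates")
    return data, int(n_landmarks)


class PointDistributionModel:
    """Shape model over a population of corresponded, aligned landmark sets.

    Parameters
    ----------
    shapes :
        Sequence of :class:`CorrespondedShape` or (n, 3) arrays, all with the
        same landmark count, already brought into a common frame.
    ids :
        Optional specimen identifiers, carried through to the results.
    """

    def __init__(self, shapes, ids: list[str] | None = None):
        self.data, self.n_landmarks = _as_matrix(shapes)
        if len(self.data) < 2:
            raise ValueError("a shape model needs at least two shapes")
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(self.data))]
        if len(self.ids) != len(self.data):
            raise ValueError("ids length does not match the number of shapes")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def fit(self) -> "PDMResults":
        mean = self.data.mean(axis=0)
        centered = self.data - mean
        # economy SVD of the (n_samples x 3n) centered matrix
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigenvalues = s**2 / (self.n_samples - 1)
        modes = vt.T  # columns orthonormal, ordered by descending eigenvalue
        # cut numerically null space (rank <= n_samples - 1)
        keep = min(len(eigenvalues), self.n_samples - 1)
        eigenvalues = eigenvalues[:keep]
        modes = modes[:, :keep]
        # flush numerically-null variance (e.g. identical shapes) to exact zero
        floor = (1.0 + np.abs(self.data).max()) ** 2 * 1e-20
        eigenvalues = np.where(eigenvalues <= floor, 0.0, eigenvalues)
        # deterministic sign: largest-magnitude entry of each mode positive
        flip = np.sign(modes[np.abs(modes).argmax(axis=0), np.arange(modes.shape[1])])
        flip[flip == 0] = 1.0
        modes = modes * flip
        return PDMResults(
            mean=mean, modes=modes, eigenvalues=eigenvalues,
            n_samples=self.n_samples, n_landmarks=self.n_landmarks, ids=self.ids,
        )


def num_modes(eigenvalues: np.ndarray, threshold: float = 0.95) -> int:
    """Smallest m with cumulative explained variance >= threshold.

    A zero-variance spectrum has zero modes.  The boundary is inclusive:
    eigenvalues [19, 1] reach 0.95 with a single mode.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        return 0
    frac = np.cumsum(ev) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


@dataclass
class PDMResults:
    """Fitted point distribution model.

    Attributes
    ----------
    mean : (3n,) mean shape vector (mm)
    modes : (3n, m) orthonormal eigenmodes, columns by descending eigenvalue
    eigenvalues : (m,) descending variances along the modes (mm^2)
    """

    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    n_samples: int
    n_landmarks: int
    ids: list[str]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def mean_shape(self) -> np.ndarray:
        return self.mean.reshape(-1, 3)

    def num_modes(self, threshold: float = 0.95) -> int:
        return num_modes(self.eigenvalues, threshold)

    def _vector(self, shape) -> np.ndarray:
        pts = shape.points if isinstance(shape, CorrespondedShape) else np.asarray(shape, float)
        return pts.reshape(-1)

    def project(self, shape) -> np.ndarray:
        """Coefficients b = modes^T (x - mean)."""
        v = self._vector(shape)
        if v.shape != self.mean.shape:
            raise ValueError("shape has the wrong landmark count")
        return self.modes.T @ (v - self.mean)

    def synthesize(self, coefficients: np.ndarray) -> np.ndarray:
        """Shape (n, 3) for the given mode coefficients (missing ones zero)."""
        c = np.asarray(coefficients, dtype=float)
        if c.ndim != 1 or len(c) > self.modes.shape[1]:
            raise ValueError("coefficient vector longer than the mode count")
        full = np.zeros(self.modes.shape[1])
        full[: len(c)] = c
        return (self.mean + self.modes @ full).reshape(-1, 3)

    def mode_deviation(self, mode: int, k: float) -> np.ndarray:
        """Mean shape displaced k standard deviations along one mode (0-based)."""
        if not 0 <= mode < self.modes.shape[1]:
            raise ValueError(f"mode index {mode} out of range")
        vec = self.mean + k * np.sqrt(self.eigenvalues[mode]) * self.modes[:, mode]
        return vec.reshape(-1, 3)

    def sample(self, n: int, rng: np.random.Generator | None = None,
               n_modes: int | None = None) -> list[np.ndarray]:
        """Draw new shapes from N(mean, diag(eigenvalues)) in mode space."""
        rng = rng if rng is not None else np.random.default_rng(0)
        m = self.modes.shape[1] if n_modes is None else min(n_modes, self.modes.shape[1])
        coeffs = rng.normal(size=(n, m)) * np.sqrt(self.eigenvalues[:m])
        return [self.synthesize(c) for c in coeffs]

    def coefficients_table(self, shapes, ids: list[str] | None = None) -> pd.DataFrame:
        rows = np.asarray([self.project(s) for s in shapes])
        cols = [f"mode_{i + 1}" for i in range(rows.shape[1])]
        return pd.DataFrame(rows, columns=cols, index=ids)

    def summary(self, threshold: float = 0.95) -> pd.DataFrame:
        """Per-mode eigenvalue / explained-variance table."""
        ratio = self.explained_variance_ratio
        table = pd.DataFrame({
            "mode": np.arange(1, len(self.eigenvalues) + 1),
            "eigenvalue_mm2": self.eigenvalues,
            "explained_variance": ratio,
            "cumulative": np.cumsum(ratio),
        })
        table.attrs["n_samples"] = self.n_samples
        table.attrs["n_landmarks"] = self.n_landmarks
        table.attrs["num_modes"] = self.num_modes(threshold)
        table.attrs["threshold"] = threshold
        return table

    def save(self, path) -> None:
        """Serialize to .npz with a JSON-compatible header."""
        np.savez_compressed(
            path, mean=self.mean, modes=self.modes, eigenvalues=self.eigenvalues,
            n_samples=self.n_samples, n_landmarks=self.n_landmarks,
            ids=np.asarray(self.ids, dtype=object),
        )

    @classmethod
    def load(cls, path) -> "PDMResults":
        with np.load(path, allow_pickle=True) as f:
            return cls(
                mean=f["mean"], modes=f["modes"], eigenvalues=f["eigenvalues"],
                n_samples=int(f["n_samples"]), n_landmarks=int(f["n_landmarks"]),
                ids=list(f["ids"]),
            )


def build_pdm(shapes, ids: list[str] | None = None) -> PDMResults:
    """Convenience wrapper: fit a point distribution model in one call."""
    return PointDistributionModel(shapes, ids=ids).fit()
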