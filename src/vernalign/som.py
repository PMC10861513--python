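"""Toroidal self-organising map (SOM) expression landscapes.

Gene expression profiles (replicate-collapsed, per-gene z-scaled so that
clustering is by profile shape, not level) are mapped onto a rectangular
grid of prototype profiles ("codebooks").  The grid wraps around at both
edges — a torus — so that clusters on opposite boundaries are adjacent and
no unit suffers a boundary effect.  Training is the classic online
Kohonen rule: each presented profile pulls its best-matching unit (BMU)
and, with Gaussian-decaying strength over torus grid distance, the BMU's
neighbours, with learning rate and neighbourhood radius decaying linearly
over the run.  The grid aspect ratio follows the ratio of the first two
principal-component eigenvalues of the data; the total unit count comes
from an elbow scan of the quantization error over candidate sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .expression import TimePointProfile
from .simulate import archetype_profile

GRID_CANDIDATES = (25, 36, 49, 64, 81, 100, 121)


@dataclass
class SOMModel:
    rows: int
    cols: int
    toroidal: bool
    codebooks: np.ndarray  # (rows*cols, n_features)
    days: list[int]
    training_meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_coords(self) -> np.ndarray:
        """(n_units, 2) array of (row, col) grid coordinates; unit index is
        row-major."""
        r, c = np.divmod(np.arange(self.n_units), self.cols)
        return np.column_stack([r, c])


@dataclass
class ClusterAssignment:
    """Gene-to-unit mapping of one trained SOM."""

    gene_unit: pd.Series  # index gene, value unit index
    n_units: int

    @property
    def counts(self) -> pd.Series:
        return self.gene_unit.value_counts().reindex(range(self.n_units), fill_value=0)

    @property
    def proportions(self) -> pd.Series:
        n = len(self.gene_unit)
        return self.counts / n if n else self.counts.astype(float)


def scale_profiles(profile: TimePointProfile, genes: list[str]) -> pd.DataFrame:
    """Per-gene z-scaling (mean 0, population SD 1) of selected genes.

    Zero-variance genes cannot be scaled and are dropped; the drop count
    is recorded on the returned frame's ``attrs['n_dropped']``.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    missing = [g for g in genes if g not in profile.values.index]
    if missing:
        raise ValueError(f"genes absent from profile: {missing[:10]}")
    sub = profile.values.loc[genes]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    scaled = sub[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    scaled.attrs["n_dropped"] = int((~keep).sum())
    return scaled


def grid_distance_sq(rows: int, cols: int, toroidal: bool) -> np.ndarray:
    """(n_units, n_units) squared grid distances, torus-wrapped if toroidal."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    dr = np.abs(r[:, None] - r[None, :])
    dc = np.abs(c[:, None] - c[None, :])
    if toroidal:
        dr = np.minimum(dr, rows - dr)
        dc = np.minimum(dc, cols - dc)
    return (dr ** 2 + dc ** 2).astype(float)


def quantization_error(codebooks: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance of each profile to its best-matching unit."""
    d = cdist(data, codebooks)
    return float(d.min(axis=1).mean())


def som_grid_shape(
    scaled: pd.DataFrame | np.ndarray,
    target_units: int | None = None,
    toroidal: bool = True,
    seed: int = 0,
) -> tuple[int, int]:
    """Grid dimensions: aspect ratio from PCA eigenvalues, size from an
    elbow scan.

    The rows:cols ratio approximates lambda1/lambda2 of the feature
    covariance of the scaled data (rows >= cols, both >= 2).  When
    ``target_units`` is omitted the candidate sizes
    ``(25, 36, ..., 121)`` are each trained briefly (10 epochs) and the
    smallest size whose relative quantization-error improvement over the
    previous candidate falls below 5% is chosen.
    """
    data = np.asarray(scaled, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError("need at least 2 genes and 2 features")
    cov = np.cov(data, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    if eigvals[1] <= 1e-12:
        raise ValueError(
            "degenerate covariance (second eigenvalue ~ 0); pass an explicit shape"
        )
    ratio = float(eigvals[0] / eigvals[1])

    def shape_for(n_units: int) -> tuple[int, int]:
        rows = max(2, round(np.sqrt(n_units * ratio)))
        cols = max(2, round(n_units / rows))
        if rows < cols:
            rows, cols = cols, rows
        return int(rows), int(cols)

    if target_units is not None:
        return shape_for(target_units)

    prev_qe = None
    chosen = GRID_CANDIDATES[-1]
    for cand in GRID_CANDIDATES:
        model = train_som(data, shape_for(cand), toroidal=toroidal, seed=seed, epochs=10)
        qe = model.training_meta["qe_final"]
        if prev_qe is not None and (prev_qe - qe) / prev_qe < 0.05:
            chosen = cand
            break
        prev_qe = qe
    return shape_for(chosen)


def train_som(
    scaled: pd.DataFrame | np.ndarray,
    shape: tuple[int, int],
    toroidal: bool = True,
    seed: int = 0,
    epochs: int = 30,
    alpha: tuple[float, float] = (0.5, 0.01),
    radius: tuple[float, float] | None = None,
    days: list[int] | None = None,
) -> SOMModel:
    """Online SOM training, deterministic for a given seed.

    Codebooks initialise from a random sample of the data.  Per
    presentation the BMU is found by Euclidean distance and every unit w
    is updated as ``w += a * h * (x - w)`` with Gaussian neighbourhood
    ``h = exp(-grid_dist^2 / (2 r^2))`` over (torus) grid distance; the
    learning rate a and radius r decay linearly from their initial to
    final values over all presentations.
    """
    if isinstance(scaled, pd.DataFrame):
        if days is None:
            days = [int(c) for c in scaled.columns]
        data = scaled.to_numpy(dtype=float)
    else:
        data = np.asarray(scaled, dtype=float)
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 1 or cols < 1 or epochs < 1:
        raise ValueError("shape dims and epochs must be >= 1")
    n_units = rows * cols
    n_samples, n_features = data.shape
    if n_samples < n_units:
        import warnings

        warnings.warn(
            f"fewer profiles ({n_samples}) than units ({n_units}); "
            "training proceeds but some units will stay empty"
        )
    rng = np.random.default_rng(seed)

    init_idx = rng.choice(n_samples, size=n_units, replace=n_samples < n_units)
    codebooks = data[init_idx].copy()
    qe_init = quantization_error(codebooks, data)

    gd2 = grid_distance_sq(rows, cols, toroidal)
    if radius is None:
        # finish in a fine-tuning regime (near-BMU-only updates) so the
        # trained map converges below its sample-initialisation error
        radius = (max(rows, cols) / 2.0, 0.1)
    a0, a1 = alpha
    r0, r1 = radius
    total = epochs * n_samples
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_samples)
        for i in order:
            frac = step / max(total - 1, 1)
            a = a0 + (a1 - a0) * frac
            r = r0 + (r1 - r0) * frac
            x = data[i]
            bmu = int(np.argmin(((codebooks - x) ** 2).sum(axis=1)))
            h = np.exp(-gd2[bmu] / (2.0 * r * r))
            codebooks += (a * h)[:, None] * (x - codebooks)
            step += 1

    qe_final = quantization_error(codebooks, data)
    return SOMModel(
        rows=rows,
        cols=cols,
        toroidal=toroidal,
        codebooks=codebooks,
        days=days if days is not None else list(range(n_features)),
        training_meta={
            "epochs": epochs,
            "alpha": (a0, a1),
            "radius": (r0, r1),
            "seed": seed,
            "qe_initial": qe_init,
            "qe_final": qe_final,
        },
    )


def assign_genes(model: SOMModel, scaled: pd.DataFrame) -> ClusterAssignment:
    """Assign each scaled gene profile to its nearest codebook.

    Ties go to the lowest unit index.
    """
    if scaled.shape[1] != model.codebooks.shape[1]:
        raise ValueError(
            f"feature mismatch: data has {scaled.shape[1]}, "
            f"model has {model.codebooks.shape[1]}"
        )
    if scaled.shape[0] == 0:
        return ClusterAssignment(
            gene_unit=pd.Series([], dtype=int, name="unit"), n_units=model.n_units
        )
    d = cdist(scaled.to_numpy(dtype=float), model.codebooks)
    units = d.argmin(axis=1)  # argmin returns the first (lowest) index on ties
    return ClusterAssignment(
        gene_unit=pd.Series(units, index=scaled.index, name="unit"),
        n_units=model.n_units,
    )


def top_populated_clusters(
    assignment: ClusterAssignment, k: int
) -> list[tuple[int, int, float]]:
    """The k units with the most genes: (unit, count, proportion of mapped
    genes), descending by count with ties towards the lower unit index."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = assignment.counts
    props = assignment.proportions
    order = sorted(counts.index, key=lambda u: (-counts[u], u))
    return [(int(u), int(counts[u]), float(props[u])) for u in order[:k]]


def label_codebooks(model: SOMModel, cold_window: tuple[int, int]) -> list[str]:
    """Descriptive archetype label per codebook.

    Each codebook is correlated against the unit-amplitude archetype
    shapes evaluated on the model's day grid; the best-correlated
    archetype names the unit.  Labels are descriptive only.
    """
    days = model.days
    candidates = {}
    for arch in ("early_vern", "treatment", "late", "treatment_late"):
        prof = archetype_profile(arch, days, cold_window, 1.0)
        candidates[arch] = (prof - prof.mean()) / prof.std()
    labels = []
    for cb in model.codebooks:
        sd = cb.std()
        if sd <= 1e-12:
            labels.append("flat")
            continue
        z = (cb - cb.mean()) / sd
        best = max(candidates, key=lambda a: float(np.dot(z, candidates[a])))
        labels.append(best)
    return labels


def codebook_archetype_correlations(
    model: SOMModel, cold_window: tuple[int, int]
) -> pd.DataFrame:
    """Pearson r between each codebook and each archetype shape."""
    days = model.days
    out = {}
    for arch in ("early_vern", "treatment", "late", "treatment_late"):
        prof = archetype_profile(arch, days, cold_window, 1.0)
        out[arch] = [
            float(np.corrcoef(cb, prof)[0, 1]) if cb.std() > 1e-12 else np.nan
            for cb in model.codebooks
        ]
    return pd.DataFrame(out)
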