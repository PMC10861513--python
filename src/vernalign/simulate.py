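"""Synthetic two-variety, two-tissue expression time courses.

The generator emulates the processed quantities of a vernalisation
time-course experiment on an amphidiploid crop: FPKM-scale expression for
genes organised into homologue families of 1-6 copies (biased towards even
copy counts, as expected from an A/C-genome hybrid), sampled for two
varieties and two tissues over the study's day grid, with two time points
falling inside a cold (vernalisation) window.  Gene temporal behaviour is
drawn from a small set of archetypes:

``early_vern``
    high at the start, decaying through and after the cold window
    ("early / vernalisation responsive");
``treatment``
    a peak inside the cold window ("treatment responsive");
``late``
    monotone rise peaking at the final time point;
``treatment_late``
    both a cold-window peak and a final-day peak;
``flat``
    constant.

Noise is multiplicative log-normal (Gaussian on the natural-log scale),
the simplest model consistent with strictly positive FPKM.  A configurable
fraction of genes is variety-specific — in the other variety their values
are drawn uniformly below the 2.0-FPKM expression threshold, zero-inflated
to emulate undetected genes — and a fraction is tissue-preferential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import EXPRESSION_THRESHOLD, ExpressionSeries

ARCHETYPES = ("early_vern", "treatment", "late", "treatment_late", "flat")

#: Sampling design of the study: days post-sowing per (variety, tissue).
#: The second variety lacks the final day, and only its apex was sampled
#: on day 69; days 43 and 64 fall inside the cold window.
DEFAULT_SAMPLING_DAYS: dict[tuple[str, str], tuple[int, ...]] = {
    ("Tapidor", "apex"): (22, 43, 64, 65, 67, 72, 83),
    ("Tapidor", "leaf"): (22, 43, 64, 65, 67, 72, 83),
    ("Westar", "apex"): (22, 43, 64, 65, 67, 69, 72),
    ("Westar", "leaf"): (22, 43, 64, 65, 67, 72),
}

#: Replicate pools per sampling point: two pools everywhere except day 65
#: (one pool) and the day-69 apex-only point (one pool).
def default_n_pools(variety: str, tissue: str, day: int) -> int:
    if day in (65, 69):
        return 1
    return 2


def _normalised(vec: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(vec, dtype=float)
    if arr.ndim != 1 or (arr < 0).any():
        raise ValueError(f"{name} must be a non-negative 1-D probability vector")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {arr.sum():.12f})")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults reproduce the study conditions: the full two-variety,
    two-tissue day grid with its missing points, a cold window spanning
    days 23-64, even-biased family copy numbers, and log-normal
    multiplicative noise with sigma 0.2 on the natural-log scale.
    """

    n_families: int = 1350
    copy_number_weights: tuple[float, ...] = (0.05, 0.30, 0.10, 0.35, 0.08, 0.12)
    archetype_mix: tuple[float, ...] = (0.20, 0.20, 0.20, 0.10, 0.30)
    varieties: tuple[str, str] = ("Tapidor", "Westar")
    tissues: tuple[str, str] = ("apex", "leaf")
    sampling_days: Mapping[tuple[str, str], tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLING_DAYS)
    )
    cold_window: tuple[int, int] = (23, 64)
    n_pools: Mapping[tuple[str, str, int], int] | None = None  # None -> study design
    baseline_fpkm: float = 10.0
    amplitude_sigma: float = 0.8  # log-normal spread of per-gene amplitudes
    noise_sigma: float = 0.2
    frac_variety_specific: float = 0.10
    specific_variety_prob: float = 0.5  # P(a specific gene belongs to variety 1)
    frac_tissue_preferential: float = 0.10
    frac_no_homologue: float = 0.05
    specific_archetype: str | None = None  # force this archetype on specific genes
    late_shift_variety: str | None = None  # variety whose "late" genes run delayed
    late_shift: int = 1  # delay in sampling positions
    seed: int = 0

    def pools_for(self, variety: str, tissue: str, day: int) -> int:
        if self.n_pools is not None:
            return int(self.n_pools.get((variety, tissue, day), 1))
        return default_n_pools(variety, tissue, day)

    def validate(self) -> list[str]:
        """Return a list of problems; empty means valid."""
        problems: list[str] = []
        if self.n_families < 1:
            problems.append("n_families must be >= 1")
        for name, vec, expect_len in (
            ("copy_number_weights", self.copy_number_weights, 6),
            ("archetype_mix", self.archetype_mix, len(ARCHETYPES)),
        ):
            arr = np.asarray(vec, dtype=float)
            if len(arr) != expect_len:
                problems.append(f"{name} must have length {expect_len}")
            elif (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                problems.append(f"{name} must be a probability vector summing to 1")
        if len(self.varieties) != 2 or len(self.tissues) != 2:
            problems.append("exactly 2 varieties and 2 tissues are required")
        all_days: list[int] = []
        for v in self.varieties:
            for t in self.tissues:
                days = self.sampling_days.get((v, t))
                if not days:
                    problems.append(f"no sampling days for ({v}, {t})")
                    continue
                if any(b <= a for a, b in zip(days, days[1:])):
                    problems.append(f"sampling days for ({v}, {t}) not strictly increasing")
                all_days.extend(days)
        if all_days:
            lo, hi = self.cold_window
            if lo > hi or lo < min(all_days) or hi > max(all_days):
                problems.append("cold_window must lie within the sampling-day range")
        if self.baseline_fpkm <= 0:
            problems.append("baseline_fpkm must be positive")
        if self.noise_sigma < 0:
            problems.append("noise_sigma must be non-negative")
        for name in (
            "frac_variety_specific",
            "specific_variety_prob",
            "frac_tissue_preferential",
            "frac_no_homologue",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1]")
        if self.late_shift_variety is not None and self.late_shift_variety not in self.varieties:
            problems.append("late_shift_variety must be one of the configured varieties")
        if self.specific_archetype is not None and self.specific_archetype not in ARCHETYPES:
            problems.append(f"specific_archetype must be one of {ARCHETYPES}")
        return problems


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth.

    ``expression`` maps (variety, tissue) to an :class:`ExpressionSeries`;
    ``noiseless`` holds the corresponding noise-free gene-by-day profiles;
    ``homology`` is the crop-gene / model-gene / bitscore table (genes
    without a homologue are absent from it); ``truth`` records, per gene,
    its family, archetype, amplitude, variety-specific and
    tissue-preferential flags; ``flowering_genes`` is a planted gene-set
    list usable as an analysis subset.
    """

    config: SimulationConfig
    expression: dict[tuple[str, str], ExpressionSeries]
    noiseless: dict[tuple[str, str], pd.DataFrame]
    homology: pd.DataFrame
    truth: pd.DataFrame
    flowering_genes: list[str]


def archetype_profile(
    archetype: str,
    days: Sequence[int],
    cold_window: tuple[int, int],
    amplitude: float,
) -> np.ndarray:
    """Noise-free FPKM profile of one archetype over the given days.

    The shapes are fixed, smooth functions of the day grid and cold
    window: ``early_vern`` starts at ``amplitude`` and decays to <= 45%
    from the start of the cold window onwards; ``treatment`` is a Gaussian
    bump centred mid-window; ``late`` is a quadratic rise peaking at the
    final day; ``treatment_late`` sums a window bump and a cubic rise;
    ``flat`` is constant at ``amplitude``.
    """
    if len(days) == 0:
        raise ValueError("days must be non-empty")
    if amplitude <= 0:
        raise ValueError(f"amplitude must be positive, got {amplitude}")
    d = np.asarray(days, dtype=float)
    d0, dn = d[0], d[-1]
    lo, hi = float(cold_window[0]), float(cold_window[1])
    mu = 0.5 * (lo + hi)
    s = max((hi - lo) / 5.0, 1.0)
    span = max(dn - d0, 1.0)

    if archetype == "early_vern":
        # linear drop to 45% at the window start, then linear decay to 8%
        rel = np.empty_like(d)
        pre = d <= lo
        rel[pre] = 1.0 - 0.55 * (d[pre] - d0) / max(lo - d0, 1.0)
        rel[~pre] = 0.45 - 0.37 * (d[~pre] - lo) / max(dn - lo, 1.0)
        rel = np.clip(rel, 0.05, 1.0)
        rel[0] = 1.0
    elif archetype == "treatment":
        rel = 0.1 + 0.9 * np.exp(-(((d - mu) / s) ** 2))
    elif archetype == "late":
        rel = 0.1 + 0.9 * ((d - d0) / span) ** 2
    elif archetype == "treatment_late":
        rel = 0.08 + 0.55 * np.exp(-(((d - mu) / s) ** 2)) + 0.75 * ((d - d0) / span) ** 3
    elif archetype == "flat":
        rel = np.ones_like(d)
    else:
        raise ValueError(f"unknown archetype label: {archetype!r}")
    return amplitude * rel


def _delay_profile(profile: np.ndarray, shift: int) -> np.ndarray:
    """Delay a profile by ``shift`` sampling positions: position i takes the
    value of position i - shift (clamped at the first position), so the
    delayed series runs behind the original on the same day grid."""
    idx = np.maximum(np.arange(len(profile)) - shift, 0)
    return profile[idx]


def noiseless_profile(
    truth_row: pd.Series,
    variety: str,
    tissue: str,
    days: Sequence[int],
    config: SimulationConfig,
) -> np.ndarray | None:
    """Noise-free profile of one gene for a variety/tissue, or None if the
    gene is specific to the other variety (its values are random draws)."""
    specific = truth_row["specific_variety"]
    if specific and specific != variety:
        return None
    prof = archetype_profile(
        truth_row["archetype"], days, config.cold_window, truth_row["amplitude"]
    )
    if (
        truth_row["archetype"] == "late"
        and config.late_shift_variety == variety
        and config.late_shift > 0
    ):
        prof = _delay_profile(prof, config.late_shift)
    preferred = truth_row["preferred_tissue"]
    if preferred and preferred != tissue:
        prof = prof * 0.15
    return prof


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset under ``config``.

    Deterministic for a given seed.  Expressed values are
    ``profile * exp(N(0, noise_sigma))`` per sample; the off-variety values
    of variety-specific genes are per-day draws below 1.0 FPKM (about one
    third exactly zero), replicated across pools without noise, so the
    truth flag always agrees with the 2.0-FPKM rule.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid simulation config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)

    copies = rng.choice(
        np.arange(1, 7), size=config.n_families,
        p=_normalised(config.copy_number_weights, "copy_number_weights"),
    )
    gene_ids: list[str] = []
    families: list[str] = []
    for f, n_copies in enumerate(copies):
        fam = f"AT{f + 1:05d}"
        for c in range(n_copies):
            gene_ids.append(f"Bna{f + 1:05d}c{c + 1}")
            families.append(fam)
    n_genes = len(gene_ids)

    archetypes = rng.choice(
        ARCHETYPES, size=n_genes, p=_normalised(config.archetype_mix, "archetype_mix")
    )
    amplitude = config.baseline_fpkm * np.exp(
        rng.normal(0.0, config.amplitude_sigma, size=n_genes)
    )
    amplitude = np.clip(amplitude, 0.5, None)

    specific = np.array([""] * n_genes, dtype=object)
    mask = rng.random(n_genes) < config.frac_variety_specific
    specific[mask] = rng.choice(
        list(config.varieties),
        size=int(mask.sum()),
        p=[config.specific_variety_prob, 1.0 - config.specific_variety_prob],
    )
    if config.specific_archetype is not None:
        archetypes[mask] = config.specific_archetype
    preferred = np.array([""] * n_genes, dtype=object)
    mask = rng.random(n_genes) < config.frac_tissue_preferential
    preferred[mask] = rng.choice(list(config.tissues), size=int(mask.sum()))
    has_homologue = rng.random(n_genes) >= config.frac_no_homologue

    truth = pd.DataFrame(
        {
            "family": families,
            "archetype": archetypes,
            "amplitude": amplitude,
            "specific_variety": specific,
            "preferred_tissue": preferred,
            "has_homologue": has_homologue,
        },
        index=pd.Index(gene_ids, name="gene"),
    )

    homology = pd.DataFrame(
        {
            "crop_gene": [g for g, h in zip(gene_ids, has_homologue) if h],
            "model_gene": [f for f, h in zip(families, has_homologue) if h],
            "bitscore": np.round(rng.uniform(100.0, 1000.0, size=int(has_homologue.sum())), 1),
        }
    )

    expression: dict[tuple[str, str], ExpressionSeries] = {}
    noiseless: dict[tuple[str, str], pd.DataFrame] = {}
    for variety in config.varieties:
        for tissue in config.tissues:
            days = list(config.sampling_days[(variety, tissue)])
            # unit-amplitude shape per archetype; "late" may run delayed
            shapes: dict[str, np.ndarray] = {}
            for arch in ARCHETYPES:
                shape = archetype_profile(arch, days, config.cold_window, 1.0)
                if (
                    arch == "late"
                    and config.late_shift_variety == variety
                    and config.late_shift > 0
                ):
                    shape = _delay_profile(shape, config.late_shift)
                shapes[arch] = shape
            shape_matrix = np.stack([shapes[a] for a in archetypes])
            tissue_factor = np.where(
                (preferred != "") & (preferred != tissue), 0.15, 1.0
            )
            base = shape_matrix * (amplitude * tissue_factor)[:, None]
            # off-variety values: uniform below threshold, zero-inflated
            off_variety = np.array([bool(s) and s != variety for s in specific])
            n_off = int(off_variety.sum())
            if n_off:
                base[off_variety] = np.maximum(
                    0.0, rng.uniform(-0.5, 1.0, size=(n_off, len(days)))
                )
            noiseless[(variety, tissue)] = pd.DataFrame(
                base, index=truth.index, columns=days
            )

            cols: dict[str, np.ndarray] = {}
            meta_rows: list[dict] = []
            for j, day in enumerate(days):
                for pool in range(1, config.pools_for(variety, tissue, day) + 1):
                    sid = f"{variety}_{tissue}_D{day}_P{pool}"
                    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=n_genes))
                    vals = base[:, j] * noise
                    # below-threshold draws carry no multiplicative noise so
                    # they stay strictly under the expression threshold
                    vals[off_variety] = base[off_variety, j]
                    cols[sid] = vals
                    meta_rows.append(
                        {"sample_id": sid, "variety": variety, "tissue": tissue,
                         "day": day, "pool": pool}
                    )
            values = pd.DataFrame(cols, index=truth.index)
            meta = pd.DataFrame(meta_rows).set_index("sample_id")
            expression[(variety, tissue)] = ExpressionSeries(values=values, sample_meta=meta)

    # planted "flowering" gene set: all members of a random 5% of families
    n_flower_fams = max(1, config.n_families // 20)
    flower_fams = set(
        rng.choice(np.unique(families), size=n_flower_fams, replace=False)
    )
    flowering = [g for g, f in zip(gene_ids, families) if f in flower_fams]

    return SyntheticDataset(
        config=config,
        expression=expression,
        noiseless=noiseless,
        homology=homology,
        truth=truth,
        flowering_genes=flowering,
    )


def write_fixtures(dataset: SyntheticDataset, directory: str | Path) -> pd.DataFrame:
    """Write the dataset as TSV fixtures; returns a manifest DataFrame.

    Files: ``expression_<variety>_<tissue>.tsv`` (one per combination, all
    sharing one ``samples.tsv``), ``homology.tsv``, ``flowering_genes.txt``
    and ``truth.tsv``.  Output is byte-deterministic for a given dataset.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    meta_frames = []
    for (variety, tissue), series in dataset.expression.items():
        fname = f"expression_{variety}_{tissue}.tsv"
        series.values.rename_axis("gene").to_csv(
            directory / fname, sep="\t", float_format="%.6g"
        )
        manifest.append({"file": fname, "rows": int(series.values.shape[0])})
        meta_frames.append(series.sample_meta)

    meta = pd.concat(meta_frames)
    meta.rename_axis("sample_id").to_csv(directory / "samples.tsv", sep="\t")
    manifest.append({"file": "samples.tsv", "rows": int(meta.shape[0])})

    dataset.homology.to_csv(directory / "homology.tsv", sep="\t", index=False)
    manifest.append({"file": "homology.tsv", "rows": int(dataset.homology.shape[0])})

    (directory / "flowering_genes.txt").write_text(
        "\n".join(dataset.flowering_genes) + "\n"
    )
    manifest.append({"file": "flowering_genes.txt", "rows": len(dataset.flowering_genes)})

    dataset.truth.to_csv(directory / "truth.tsv", sep="\t", float_format="%.6g")
    manifest.append({"file": "truth.tsv", "rows": int(dataset.truth.shape[0])})

    return pd.DataFrame(manifest)
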