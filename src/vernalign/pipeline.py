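"""End-to-end orchestration of the vernalisation time-course analysis.

One configuration drives the full chain — simulate (or load) expression
tables, collapse replicates, classify expressed genes and apply the SOM
prefilter, align transcriptomes by Euclidean distance, quantify
homologue-family copy-number bias, train one toroidal SOM per
variety/tissue, test clusters for variety-specific-gene enrichment, and
rank clusters by distance-correlation AUC.  All outputs are TSV/JSON and
the whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alignment, copy_number, correlation, enrichment, expression, simulate, som

logger = logging.getLogger("vernalign")


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    ``mode`` is ``"simulate"`` (generate inputs from ``simulation``) or
    ``"load"`` (read TSVs from ``input_dir``).  Analysis parameters carry
    the pipeline defaults: 2.0-FPKM expression threshold, zero detection
    floor, 10x10 toroidal SOM trained for 30 epochs, enrichment alpha
    1e-5, top-3 reporting, survival-form correlation curves.
    """

    mode: str = "simulate"
    simulation: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    input_dir: str | None = None
    out_dir: str = "vernalign_out"
    threshold: float = expression.EXPRESSION_THRESHOLD
    detection_floor: float = 0.0
    som_shape: tuple[int, int] | None = (10, 10)
    som_epochs: int = 30
    toroidal: bool = True
    alpha: float = 1e-5
    top_k: int = 3
    curve_form: str = "above"
    seed: int = 0


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems with a config (empty = valid)."""
    problems: list[str] = []
    if config.mode not in ("simulate", "load"):
        problems.append(f"mode must be 'simulate' or 'load', got {config.mode!r}")
    if config.mode == "simulate":
        problems.extend(config.simulation.validate())
    elif config.input_dir is None:
        problems.append("load mode requires input_dir")
    else:
        base = Path(config.input_dir)
        needed = ["samples.tsv", "homology.tsv"]
        needed += [
            f"expression_{v}_{t}.tsv"
            for v in config.simulation.varieties
            for t in config.simulation.tissues
        ]
        for f in needed:
            if not (base / f).exists():
                problems.append(f"missing input file: {base / f}")
    if config.threshold < 0:
        problems.append("threshold must be non-negative")
    if config.detection_floor < 0:
        problems.append("detection_floor must be non-negative")
    if config.som_epochs < 1:
        problems.append("som_epochs must be >= 1")
    if not 0 < config.alpha <= 1:
        problems.append("alpha must be in (0, 1]")
    if config.top_k < 1:
        problems.append("top_k must be >= 1")
    if config.curve_form not in ("above", "below"):
        problems.append("curve_form must be 'above' or 'below'")
    return problems


def config_from_yaml(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys plus a nested
    ``simulation`` section mirroring SimulationConfig fields)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("simulation", {}) or {}
    sim_fields = {f.name for f in dataclasses.fields(simulate.SimulationConfig)}
    unknown = set(sim_raw) - sim_fields
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    if "sampling_days" in sim_raw:
        sim_raw["sampling_days"] = {
            tuple(k.split("/")): tuple(v) for k, v in sim_raw["sampling_days"].items()
        }
    for key in ("varieties", "tissues", "cold_window", "copy_number_weights", "archetype_mix"):
        if key in sim_raw:
            sim_raw[key] = tuple(sim_raw[key])
    sim = simulate.SimulationConfig(**sim_raw)
    run_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - run_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "som_shape" in raw and raw["som_shape"] is not None:
        raw["som_shape"] = tuple(raw["som_shape"])
    return RunConfig(simulation=sim, **raw)


def _load_series(config: RunConfig) -> dict[tuple[str, str], expression.ExpressionSeries]:
    base = Path(config.input_dir)
    out = {}
    for v in config.simulation.varieties:
        for t in config.simulation.tissues:
            out[(v, t)] = expression.read_expression_table(
                base / f"expression_{v}_{t}.tsv", base / "samples.tsv"
            )
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the run report (also written as ``report.json``): per-stage
    gene counts, expressed-gene overlaps, copy-number bias summaries and
    binomial tests per tissue, SOM metadata with top-populated clusters,
    enrichment hits, and top-AUC clusters, plus the seed and output
    paths.  Raises with the failing stage named if any stage errors.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "mode": config.mode,
        "outputs": [],
        "stages": {},
    }
    written: list[str] = []

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", float_format="%.6g", index=index)
        written.append(name)

    stage = "input"
    try:
        t0 = time.time()
        varieties = list(config.simulation.varieties)
        tissues = list(config.simulation.tissues)
        if config.mode == "simulate":
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            dataset = simulate.generate_dataset(sim_cfg)
            manifest = simulate.write_fixtures(dataset, out_dir / "input")
            written.extend("input/" + f for f in manifest["file"])
            series = dataset.expression
            homology = dataset.homology
            gene_sets = {"flowering": dataset.flowering_genes}
        else:
            series = _load_series(config)
            homology = pd.read_csv(Path(config.input_dir) / "homology.tsv", sep="\t")
            gene_sets = {}
            flw = Path(config.input_dir) / "flowering_genes.txt"
            if flw.exists():
                gene_sets["flowering"] = [
                    line for line in flw.read_text().splitlines() if line
                ]
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "collapse"
        profiles = {
            key: expression.collapse_replicates(s, *key) for key, s in series.items()
        }
        report["stages"]["collapse"] = {
            f"{v}/{t}": {"genes": len(profiles[(v, t)].gene_ids),
                         "days": profiles[(v, t)].days}
            for (v, t) in profiles
        }

        stage = "filter"
        homology_genes = set(homology["crop_gene"])
        filtered: dict[tuple[str, str], list[str]] = {}
        filter_counts = {}
        for key, prof in profiles.items():
            survivors, counts = expression.som_prefilter(
                prof, homology_genes,
                detection_floor=config.detection_floor,
                threshold=config.threshold,
            )
            filtered[key] = survivors
            filter_counts["/".join(key)] = counts
        report["stages"]["filter"] = filter_counts
        emit("filter_counts.tsv", pd.DataFrame(filter_counts).T.rename_axis("series"))

        stage = "overlap"
        va, vb = varieties
        overlaps = {}
        for t in tissues:
            ov = expression.variety_specific_sets(
                profiles[(va, t)], profiles[(vb, t)], threshold=config.threshold
            )
            overlaps[t] = ov
            report["stages"].setdefault("overlap", {})[t] = {
                f"only_{va}": len(ov.only_a),
                f"only_{vb}": len(ov.only_b),
                "shared": len(ov.shared),
                "percentages": [round(p, 2) for p in ov.percentages],
            }

        stage = "align"
        for t in tissues:
            for label, subset in [("all", None)] + (
                [("flowering", gene_sets["flowering"])] if "flowering" in gene_sets else []
            ):
                d = alignment.distance_matrix(
                    profiles[(va, t)], profiles[(vb, t)], gene_subset=subset, label=label
                )
                emit(f"distance_{t}_{label}.tsv", d.values.rename_axis("day"))
                emit(f"trace_{t}_{label}.tsv", alignment.trace_table(d), index=False)
                report["stages"].setdefault("align", {})[f"{t}/{label}"] = {
                    "row_min": alignment.min_traces(d).row_min,
                    "col_min": alignment.min_traces(d).col_min,
                }

        stage = "bias"
        families = copy_number.build_families(homology)
        for t in tissues:
            exp_a = expression.expressed_set(profiles[(va, t)], config.threshold)
            exp_b = expression.expressed_set(profiles[(vb, t)], config.threshold)
            records = copy_number.family_expression_counts(families, exp_a, exp_b)
            summary = copy_number.bias_summary(records)
            emit(f"family_counts_{t}.tsv", copy_number.records_table(records), index=False)
            try:
                n, k, p = copy_number.bias_binomial_test(records)
                binom = {"n_biased": n, "k_toward_a": k, "p_value": p}
            except ValueError:
                binom = {"n_biased": 0, "k_toward_a": 0, "p_value": None}
            report["stages"].setdefault("bias", {})[t] = {
                "pct_biased_a": round(summary["pct_biased_a"], 2),
                "pct_biased_b": round(summary["pct_biased_b"], 2),
                "pct_compensatory": round(summary["pct_compensatory"], 2),
                "n_families": summary["n_families"],
                "binomial": binom,
            }

        stage = "som"
        seed_seq = np.random.SeedSequence(config.seed)
        som_seeds = {
            key: int(s.generate_state(1)[0] % (2**31))
            for key, s in zip(sorted(profiles), seed_seq.spawn(len(profiles)))
        }
        models: dict[tuple[str, str], som.SOMModel] = {}
        assignments: dict[tuple[str, str], som.ClusterAssignment] = {}
        scaled_all: dict[tuple[str, str], pd.DataFrame] = {}
        for key in sorted(profiles):
            genes = filtered[key]
            if not genes:
                raise ValueError(f"no genes survive the prefilter for {key}")
            scaled = som.scale_profiles(profiles[key], genes)
            shape = config.som_shape or som.som_grid_shape(
                scaled, toroidal=config.toroidal, seed=som_seeds[key]
            )
            model = som.train_som(
                scaled, shape, toroidal=config.toroidal,
                seed=som_seeds[key], epochs=config.som_epochs,
            )
            assign = som.assign_genes(model, scaled)
            models[key], assignments[key], scaled_all[key] = model, assign, scaled
            v, t = key
            cb = pd.DataFrame(
                model.codebooks, columns=[f"day_{d}" for d in model.days]
            ).rename_axis("unit")
            coords = model.unit_coords()
            cb.insert(0, "row", coords[:, 0])
            cb.insert(1, "col", coords[:, 1])
            emit(f"som_codebooks_{v}_{t}.tsv", cb)
            emit(f"som_assignments_{v}_{t}.tsv", assign.gene_unit.rename_axis("gene").to_frame())
            report["stages"].setdefault("som", {})[f"{v}/{t}"] = {
                "shape": [model.rows, model.cols],
                "n_genes": int(len(assign.gene_unit)),
                "n_dropped_zero_variance": int(scaled.attrs.get("n_dropped", 0)),
                "qe_initial": round(model.training_meta["qe_initial"], 4),
                "qe_final": round(model.training_meta["qe_final"], 4),
                "top_populated": [
                    {"unit": u, "count": c, "proportion": round(p, 4)}
                    for u, c, p in som.top_populated_clusters(assign, config.top_k)
                ],
            }

        stage = "enrich"
        for key in sorted(profiles):
            v, t = key
            ov = overlaps[t]
            specific = ov.only_a if v == va else ov.only_b
            mapped = set(assignments[key].gene_unit.index)
            special = frozenset(specific) & mapped
            table = enrichment.fisher_enrichment(assignments[key], special)
            emit(f"enrichment_{v}_{t}.tsv", table)
            report["stages"].setdefault("enrich", {})[f"{v}/{t}"] = {
                "n_special_mapped": len(special),
                "top_enriched": enrichment.top_enriched_clusters(
                    table, alpha=config.alpha, k=config.top_k
                ),
                "min_q": float(table["q_value"].min()) if len(table) else None,
            }

        stage = "correlate"
        for key in sorted(profiles):
            v, t = key
            d = alignment.distance_matrix(profiles[(va, t)], profiles[(vb, t)])
            genes = list(assignments[key].gene_unit.index)
            recs = correlation.gene_correlation_table(
                profiles[(va, t)], profiles[(vb, t)], d, genes
            )
            emit(f"gene_correlations_{v}_{t}.tsv", recs)
            curves = correlation.cluster_threshold_curve(
                recs, assignments[key], form=config.curve_form
            )
            emit(
                f"cluster_auc_{v}_{t}.tsv",
                pd.DataFrame(
                    [{"cluster": c.cluster, "auc": c.auc, "n_genes": c.n_genes}
                     for c in curves]
                ),
                index=False,
            )
            report["stages"].setdefault("correlate", {})[f"{v}/{t}"] = {
                "top_auc_clusters": correlation.rank_clusters_by_auc(curves, config.top_k),
                "n_defined": int(recs["defined"].sum()),
            }
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} "
            f"(outputs so far: {written}): {err}"
        ) from err

    report["outputs"] = written
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("run complete: %d outputs under %s", len(written), out_dir)
    return report
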