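"""End-to-end benchmark runs: obtain, standardize, compare, validate.

The workflow mirrors how heterogeneous chromatin models are actually
benchmarked: every model file is read, spline-resampled to a common bead
count, reduced to one distance matrix (final structure for annealing
trajectories, mean heatmap for equilibrium ensembles, medoid as a
deterministic single-representative rule), and then scored pairwise
(compare) or against inverted experimental contact maps (validate).

Runs are a pure function of (config, input files): every stochastic stage
is seeded from the config, and each output directory contains a
machine-readable provenance file echoing the config, package version and
seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .matrixio import read_cooler_region, read_dense_matrix, read_sparse_text, write_matrix
from .matrixops import (
    PowerLawMap,
    SquareMatrix,
    coarsen,
    contact_to_pseudodistance,
    default_eps,
    distance_to_contact,
    ensemble_reduce,
    mask_sparse_bins,
)
from .metrics import (
    ComparisonResult,
    StrataSpec,
    kl_divergence,
    pairwise_table,
    spearman_compare,
    stratified_spearman,
    table_to_square,
)
from .regions import GenomicRegion, bead_count, parse_region
from .standardize import SplineSpec, resample_ensemble
from .structures import read_structure, write_structure
from .synthetic import make_benchmark_scene

__all__ = ["InputSpec", "RunConfig", "run_compare", "run_validate", "run_simulate"]

logger = logging.getLogger("chrombench")

DEFAULT_BP_PER_BEAD = 5000


@dataclass(frozen=True)
class InputSpec:
    """One labeled input file: a model structure or an experimental map."""

    label: str
    path: str
    role: Literal["model", "experiment"] = "model"
    format: str = "auto"
    bp_per_bead: float | None = None  # native model resolution, if known


@dataclass
class RunConfig:
    """Configuration of one benchmark run (YAML-loadable).

    n_beads defaults to the bin count of *region* at 5 kb/bead — the
    standardization resolution of the reference workflow.
    """

    region: GenomicRegion
    inputs: list[InputSpec]
    output_dir: str = "chrombench_out"
    n_beads: int | None = None
    spline: SplineSpec = field(default_factory=SplineSpec)
    power_law: PowerLawMap | None = None  # None -> a=1, per-matrix default eps
    strata: StrataSpec = field(default_factory=StrataSpec)
    metrics: tuple[str, ...] = ("spearman",)
    ensemble_mode: dict[str, str] = field(default_factory=dict)
    default_ensemble_mode: str = "mean"
    mask_min_fraction: float = 0.0
    kl_smoothing: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_beads is None:
            self.n_beads = bead_count(self.region, DEFAULT_BP_PER_BEAD)
        labels = [i.label for i in self.inputs]
        if len(set(labels)) != len(labels):
            raise ValueError("input labels must be unique")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        region = raw["region"]
        if isinstance(region, str):
            region = parse_region(region)
        inputs = [
            i if isinstance(i, InputSpec) else InputSpec(**i) for i in raw["inputs"]
        ]
        spline = raw.get("spline", {})
        if isinstance(spline, dict):
            spline = SplineSpec(**spline)
        strata = raw.get("strata", {})
        if isinstance(strata, dict):
            if "edges" in strata and strata["edges"] is not None:
                strata["edges"] = tuple(strata["edges"])
            strata = StrataSpec(**strata)
        power_law = raw.get("power_law")
        if isinstance(power_law, dict):
            power_law = PowerLawMap(**power_law)
        return cls(
            region=region,
            inputs=inputs,
            output_dir=raw.get("output_dir", "chrombench_out"),
            n_beads=raw.get("n_beads"),
            spline=spline,
            power_law=power_law,
            strata=strata,
            metrics=tuple(raw.get("metrics", ("spearman",))),
            ensemble_mode=dict(raw.get("ensemble_mode", {})),
            default_ensemble_mode=raw.get("default_ensemble_mode", "mean"),
            mask_min_fraction=float(raw.get("mask_min_fraction", 0.0)),
            kl_smoothing=float(raw.get("kl_smoothing", 1e-9)),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = str(self.region)
        d["spline"] = dataclasses.asdict(self.spline)
        d["strata"] = dataclasses.asdict(self.strata)
        d["power_law"] = (
            None if self.power_law is None else dataclasses.asdict(self.power_law)
        )
        return d


# ---------------------------------------------------------------------------
# loading helpers

def _load_model_matrix(config: RunConfig, inp: InputSpec) -> SquareMatrix:
    """model file -> resample to n_beads -> one distance matrix."""
    bp = inp.bp_per_bead or DEFAULT_BP_PER_BEAD
    ensemble = read_structure(
        inp.path, config.region, bp, format=inp.format, label=inp.label
    )
    ensemble = resample_ensemble(ensemble, config.n_beads, config.spline)
    mode = config.ensemble_mode.get(inp.label, config.default_ensemble_mode)
    logger.info(
        "model %s: %d structures x %d beads, reduce mode=%s",
        inp.label, len(ensemble), ensemble.n_beads, mode,
    )
    return ensemble_reduce(ensemble, mode=mode, label=inp.label)


def _read_experiment(config: RunConfig, inp: InputSpec) -> SquareMatrix:
    path = Path(inp.path)
    suffix = path.suffix.lower()
    fmt = inp.format
    if fmt == "auto":
        fmt = {
            ".cool": "cooler", ".mcool": "cooler", ".h5": "cooler", ".hdf5": "cooler",
        }.get(suffix, "dense")
        if suffix in (".tsv", ".bed", ".pairs", ".txt"):
            # 3-column sparse if the first data line has 3 fields
            with path.open() as fh:
                for line in fh:
                    if line.strip() and not line.startswith("#"):
                        if len(line.split()) == 3:
                            fmt = "sparse"
                        break
    if fmt == "cooler":
        return _relabel(read_cooler_region(path, config.region), inp.label)
    bin_bp = config.region.length() / config.n_beads
    if fmt == "sparse":
        return _relabel(read_sparse_text(path, config.region, bin_bp), inp.label)
    if path.with_name(path.name + ".json").exists():
        # sidecar carries the native region/bin size; don't override it
        return _relabel(read_dense_matrix(path), inp.label)
    return _relabel(
        read_dense_matrix(path, region=config.region, bp_per_bin=bin_bp), inp.label
    )


def _relabel(m: SquareMatrix, label: str) -> SquareMatrix:
    m.label = label
    return m


def _align_experiment(config: RunConfig, contacts: SquareMatrix) -> SquareMatrix:
    """Coarsen an experimental map to the run's n_beads, then mask."""
    n_target = config.n_beads
    if contacts.n != n_target:
        factor = max(1, round(contacts.n / n_target))
        if -(-contacts.n // factor) != n_target:
            near = sorted({-(-contacts.n // f) for f in range(1, contacts.n + 1)},
                          key=lambda v: abs(v - n_target))[:3]
            raise ValueError(
                f"cannot coarsen {contacts.n} bins to {n_target} by an integer "
                f"factor; nearest achievable bead counts: {near}"
            )
        contacts = coarsen(contacts, factor)
        logger.info("coarsened %s by factor %d -> %d bins",
                    contacts.label, factor, contacts.n)
    if config.mask_min_fraction > 0:
        contacts = mask_sparse_bins(contacts, config.mask_min_fraction)
        logger.info("%s: %d of %d bins masked as sparse",
                    contacts.label, int((~contacts.mask).sum()), contacts.n)
    return contacts


def _power_law_for(config: RunConfig, contacts: SquareMatrix) -> PowerLawMap:
    if config.power_law is not None:
        return config.power_law
    return PowerLawMap(a=1.0, eps=default_eps(contacts.values))


# ---------------------------------------------------------------------------
# output helpers

def _tidy_rows(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "label_a": r.label_a, "label_b": r.label_b, "metric": r.metric,
            "stratum": "global", "value": r.global_value, "n_pairs": r.n_pairs,
            "reason": r.reason,
        })
        for key, v in r.per_stratum.items():
            rows.append({
                "label_a": r.label_a, "label_b": r.label_b, "metric": r.metric,
                "stratum": key, "value": v,
                "n_pairs": r.stratum_n_pairs.get(key, 0), "reason": None,
            })
    return pd.DataFrame(rows)


def _write_provenance(config: RunConfig, out: Path, extra: dict | None = None) -> None:
    prov = {
        "chrombench_version": __version__,
        "config": config.to_dict(),
    }
    if extra:
        prov.update(extra)
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))


# ---------------------------------------------------------------------------
# top-level runs

def run_compare(config: RunConfig) -> dict[str, Path]:
    """All-pairs model comparison; writes tidy and square CSV tables.

    Returns a mapping metric -> square-table path.
    """
    model_inputs = [i for i in config.inputs if i.role == "model"]
    if len(model_inputs) < 2:
        raise ValueError("compare needs at least 2 model inputs")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices = [_load_model_matrix(config, i) for i in model_inputs]
    written: dict[str, Path] = {}
    all_results: list[ComparisonResult] = []
    for metric in config.metrics:
        kwargs = {"smoothing": config.kl_smoothing} if metric == "kl" else {}
        results = pairwise_table(matrices, metric=metric, **kwargs)
        all_results.extend(results)
        square = table_to_square(results, labels=[m.label for m in matrices])
        path = out / f"compare_{metric}.csv"
        square.to_csv(path)
        written[metric] = path
    _tidy_rows(all_results).to_csv(out / "compare_tidy.csv", index=False)
    _write_provenance(config, out)
    return written


def run_validate(config: RunConfig) -> dict[str, Path]:
    """Model-vs-experiment validation grids.

    Experiments are coarsened to n_beads, sparse bins masked, and inverted
    to pseudodistances through the power-law map.  For each model x
    experiment pair: Spearman in pseudodistance space, KL in contact space
    (model distances mapped through the power law), and stratified
    Spearman.  Writes one model x experiment grid CSV per metric plus a
    tidy CSV with all strata.
    """
    model_inputs = [i for i in config.inputs if i.role == "model"]
    expt_inputs = [i for i in config.inputs if i.role == "experiment"]
    if not model_inputs or not expt_inputs:
        raise ValueError("validate needs at least 1 model and 1 experiment input")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    model_mats = [_load_model_matrix(config, i) for i in model_inputs]
    expt_contacts = [
        _align_experiment(config, _read_experiment(config, i)) for i in expt_inputs
    ]
    model_labels = [m.label for m in model_mats]
    expt_labels = [e.label for e in expt_contacts]
    grids = {
        metric: pd.DataFrame(np.nan, index=model_labels, columns=expt_labels)
        for metric in ("spearman", "kl", "stratified_spearman")
    }
    all_results: list[ComparisonResult] = []
    for expt in expt_contacts:
        plaw = _power_law_for(config, expt)
        pseudo = contact_to_pseudodistance(expt, plaw)
        for model in model_mats:
            sp = spearman_compare(model, pseudo)
            kl = kl_divergence(
                model, expt, smoothing=config.kl_smoothing, power_law=plaw
            )
            strat = stratified_spearman(model, pseudo, config.strata)
            grids["spearman"].loc[model.label, expt.label] = sp.global_value
            grids["kl"].loc[model.label, expt.label] = kl.global_value
            grids["stratified_spearman"].loc[model.label, expt.label] = (
                strat.global_value
            )
            all_results.extend([sp, kl, strat])
            logger.info(
                "%s vs %s: spearman=%.4f kl=%.4f (a=%.3g eps=%.3g)",
                model.label, expt.label,
                -1 if sp.global_value is None else sp.global_value,
                kl.global_value, plaw.a, plaw.eps,
            )
    written: dict[str, Path] = {}
    for metric, grid in grids.items():
        path = out / f"validate_{metric}.csv"
        grid.to_csv(path)
        written[metric] = path
    _tidy_rows(all_results).to_csv(out / "validate_tidy.csv", index=False)
    _write_provenance(config, out)
    return written


def run_simulate(
    output_dir: str | Path,
    seed: int = 0,
    n_beads: int = 214,
    n_structures: int = 200,
    region: GenomicRegion | None = None,
) -> dict[str, Path]:
    """Generate a benchmark scene and write structures, maps and metadata."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = make_benchmark_scene(
        seed=seed, n_beads=n_beads, n_structures=n_structures, region=region
    )
    paths = {
        "truth": out / "truth.xyz",
        "hic_like": out / "hic_like.csv",
        "chia_like": out / "chia_like.csv",
        "metadata": out / "scene.json",
    }
    write_structure(scene.truth, paths["truth"])
    write_matrix(scene.hic_like, paths["hic_like"])
    write_matrix(scene.chia_like, paths["chia_like"])
    meta = dict(scene.metadata)
    meta["region"] = str(scene.truth.region)
    paths["metadata"].write_text(json.dumps(meta, indent=1))
    return paths
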