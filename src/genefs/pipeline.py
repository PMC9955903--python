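"""End-to-end orchestration: preprocess -> mRMR -> t-test screen ->
metaheuristic subset search -> multi-classifier evaluation -> report.

A run is driven by one :class:`PipelineConfig` and one master seed; every
stage derives its own seed from the master via a stable hash, so stages
are individually re-runnable and two runs with the same configuration
produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datasets import ExpressionDataset, SyntheticSpec, generate_dataset, read_cumida_csv
from .evaluation import DEFAULT_CLASSIFIERS, cross_validate_models
from .filter_stats import mrmr_select_fcq, ttest_rows_to_frame, ttest_screen
from .fitness import FitnessConfig
from .metaheuristics import ALGORITHMS, OptimizerConfig, optimize
from .preprocessing import quasi_constant_filter, smote_balance, stratified_split

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "derive_seed"]


class PipelineError(RuntimeError):
    """A stage failure with context and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"[{stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Exactly one of ``synthetic`` / ``input_csv`` provides the data. By
    default the stage order follows the published protocol: variance
    filter, SMOTE balancing, feature selection on the full balanced data,
    then the 80/20 split for evaluation. Selecting features on balanced
    (partly synthetic) data before splitting leaks information into the
    test partition; set ``split_before_selection`` to split first and run
    all selection stages on the training partition only.
    """

    synthetic: SyntheticSpec = None
    input_csv: str = None
    variance_threshold: float = 0.01
    smote_k: int = 5
    test_fraction: float = 0.2
    split_before_selection: bool = False
    mrmr_k: int = 20
    alpha: float = 0.05
    t_variant: str = "student"
    fitness_weight: float = 0.9
    fitness_cv: int = 5
    algorithms: tuple = tuple(ALGORITHMS)
    n_agents: int = 20
    max_iter: int = 100
    classifiers: tuple = DEFAULT_CLASSIFIERS
    folds: int = 10
    seed: int = 0
    outdir: str = "genefs_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("synthetic"), dict):
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        for key in ("algorithms", "classifiers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.synthetic is not None:
            out["synthetic"] = dataclasses.asdict(self.synthetic)
            out["synthetic"]["effect_sizes"] = list(self.synthetic.effect_sizes)
            out["synthetic"]["base_mean_range"] = list(self.synthetic.base_mean_range)
            out["synthetic"]["base_sd_range"] = list(self.synthetic.base_sd_range)
        out["algorithms"] = list(self.algorithms)
        out["classifiers"] = list(self.classifiers)
        # the output location is not part of the scientific configuration
        out.pop("outdir", None)
        return out


def _write_json(path: Path, payload):
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages, persisting one artifact per stage under
    ``cfg.outdir``. Returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_records = []
    log_lines = []

    def log(stage: str, **details):
        log_records.append({"stage": stage, **details})
        log_lines.append(f"{stage}: " + ", ".join(f"{k}={v}" for k, v in details.items()))

    def fail(stage, message, hint=""):
        raise PipelineError(stage, message, hint)

    import sklearn  # noqa: local import: version provenance only
    log("start", genefs=__version__, numpy=np.__version__, sklearn=sklearn.__version__,
        master_seed=cfg.seed)
    _write_json(outdir / "run_config.json", cfg.to_dict())

    # --- load / generate ---------------------------------------------------
    try:
        if cfg.input_csv is not None:
            dataset = read_cumida_csv(cfg.input_csv)
            source = cfg.input_csv
        elif cfg.synthetic is not None:
            spec = dataclasses.replace(
                cfg.synthetic, seed=derive_seed(cfg.seed, "generate"))
            dataset = generate_dataset(spec)
            source = "synthetic"
        else:
            fail("load", "no input configured",
                 "set either 'synthetic' or 'input_csv' in the config")
    except PipelineError:
        raise
    except Exception as exc:
        fail("load", str(exc), "check the input CSV dialect")
    log("load", source=source, n_samples=dataset.n_samples,
        n_genes=dataset.n_genes, class_counts=dataset.class_counts())

    # --- preprocessing -----------------------------------------------------
    try:
        filtered, removed = quasi_constant_filter(dataset, cfg.variance_threshold)
        balanced = smote_balance(filtered, k_neighbors=cfg.smote_k,
                                 seed=derive_seed(cfg.seed, "smote"))
        split = stratified_split(balanced, test_fraction=cfg.test_fraction,
                                 seed=derive_seed(cfg.seed, "split"))
    except Exception as exc:
        fail("preprocess", str(exc),
             "lower the variance threshold or check class sizes")
    counts = {
        "input": dataset.class_counts(),
        "after_filter_genes": filtered.n_genes,
        "removed_genes": len(removed),
        "after_smote": balanced.class_counts(),
        "train": split.train.class_counts(),
        "test": split.test.class_counts(),
        "train_total": split.train.n_samples,
        "test_total": split.test.n_samples,
    }
    _write_json(outdir / "preprocessing.json",
                {"counts": counts, "removed_gene_ids": removed})
    log("preprocess", **{k: v for k, v in counts.items() if k != "removed_genes"},
        removed_genes=len(removed))

    selection_data = split.train if cfg.split_before_selection else balanced

    # --- mRMR ---------------------------------------------------------------
    try:
        mrmr = mrmr_select_fcq(selection_data, k=cfg.mrmr_k)
    except Exception as exc:
        fail("mrmr", str(exc), "check that both classes survived preprocessing")
    _write_json(outdir / "mrmr.json", {
        "selected": mrmr.selected,
        "relevance": [float(v) for v in mrmr.relevance],
        "step_scores": [float(v) for v in mrmr.step_scores],
    })
    log("mrmr", k=len(mrmr.selected), top=mrmr.selected[0])

    # --- t-test screen ------------------------------------------------------
    try:
        rows, candidates = ttest_screen(selection_data, mrmr.selected,
                                        alpha=cfg.alpha, variant=cfg.t_variant)
    except Exception as exc:
        fail("ttest_screen", str(exc), "check group sizes")
    ttest_rows_to_frame(rows).to_csv(outdir / "ttest.csv", index=False,
                                     float_format="%.6g")
    _write_json(outdir / "ttest.json",
                {"alpha": cfg.alpha, "variant": cfg.t_variant,
                 "selected": candidates})
    log("ttest_screen", alpha=cfg.alpha, candidates=len(candidates))

    # --- metaheuristic subset search ---------------------------------------
    if not candidates:
        fail("metaheuristics", "empty candidate pool",
             "raise alpha or plant stronger effects; the screen selected no genes")
    pool = selection_data.select_genes(candidates)
    fitness_cfg = FitnessConfig(weight=cfg.fitness_weight, cv=cfg.fitness_cv)
    shared_cache: dict = {}
    masks = {}
    for algo in cfg.algorithms:
        opt_cfg = OptimizerConfig(n_agents=cfg.n_agents, max_iter=cfg.max_iter,
                                  seed=derive_seed(cfg.seed, f"optimize:{algo}"))
        try:
            mask, trace = optimize(pool, algo, fitness_cfg, opt_cfg,
                                   cache=shared_cache)
        except Exception as exc:
            fail(f"optimize:{algo}", str(exc),
                 "reduce fitness_cv if the balanced classes are very small")
        genes = mask.gene_ids(pool.gene_ids)
        masks[algo] = genes
        _write_json(outdir / f"optimizer_{algo}.json", {
            "algorithm": algo,
            "params": {"n_agents": opt_cfg.n_agents, "max_iter": opt_cfg.max_iter,
                       "seed": opt_cfg.seed, "fitness_weight": cfg.fitness_weight,
                       "fitness_cv": cfg.fitness_cv},
            "best_mask": genes,
            "best_fitness": trace.best_fitness[-1],
            "trace": trace.best_fitness,
        })
        log(f"optimize:{algo}", n_selected=len(genes),
            best_fitness=round(trace.best_fitness[-1], 6))

    # --- evaluation ---------------------------------------------------------
    try:
        report = cross_validate_models(split, masks, specs=cfg.classifiers,
                                       folds=cfg.folds,
                                       seed=derive_seed(cfg.seed, "evaluate"))
    except Exception as exc:
        fail("evaluate", str(exc), "check fold count against class sizes")
    _write_json(outdir / "evaluation.json", report.to_json_dict())
    report.to_frame().to_csv(outdir / "evaluation.csv", index=False,
                             float_format="%.6g")
    best = report.best_row()
    log("evaluate", pairs=len(report.rows), folds=cfg.folds,
        best=f"{best.subset}/{best.classifier}",
        best_test_cv_accuracy=round(best.test_cv["accuracy_mean"], 4))

    _write_json(outdir / "log.json", log_records)
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return outdir
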