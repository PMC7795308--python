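"""End-to-end pipeline: generate -> train -> select -> combine -> search -> evaluate.

One :class:`RunConfig` plus a root seed fully determines a run.  Per-stage
and per-descriptor seeds are derived from the root seed with counter-based
``SeedSequence`` keys, so changing one stage's settings does not perturb
another stage's randomness.  Every artifact (dataset, model checkpoints,
selections, combined matrix, recall table, concordance report, log) is
written under the run directory and is bit-reproducible from config + seed.

The screening representation for the reweighted method is, by default, the
continuous Tanimoto over the combined descriptor built from reconstructed
feature weights at the selected columns; ``representation="binary"``
switches to the original binary bits at those columns.  Single-descriptor
binary Tanimoto columns serve as in-run baselines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dbn import DBNModel, iterative_feature_learning
from .evaluation import build_recall_table, class_recall, gains, kendall_w
from .feature_select import (
    SelectedFeatureSet,
    build_error_pca,
    combine_descriptors,
    select_features,
)
from .fingerprint_io import (
    ActivityClassSpec,
    FingerprintMatrix,
    binarize,
    read_fingerprints,
    write_matrix,
)
from .rbm import RBMParameters, TrainConfig
from .synthetic_data import SyntheticSpec, generate, write_dataset

__all__ = ["RunConfig", "run", "save_model", "load_model", "derive_seed"]

logger = logging.getLogger("dbnscreen")

CHECKPOINT_VERSION = 1


def derive_seed(root: int, *key: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([int(root), *map(int, key)])
               .generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything a full pipeline run needs besides the root seed.

    ``descriptor_paths`` (dense matrix files) and ``synthetic`` are
    alternatives; exactly one must be provided.  ``hidden_sizes`` applies to
    every descriptor's DBN.
    """

    synthetic: SyntheticSpec | None = None
    descriptor_paths: tuple[str, ...] = ()
    hidden_sizes: tuple[int, ...] = (32, 16)
    epochs: int = 10
    fine_tune_epochs: int = 30
    learning_rate: float = 0.05
    batch_size: int = 32
    gibbs_steps: int = 1
    weight_init: str = "uniform"
    convergence_tolerance: float = 1e-3
    outlier_fraction: float = 0.0
    max_rounds: int = 2
    threshold: float = float("inf")
    top_k: int = 300
    combine_subset: tuple[str, ...] = ()   # empty = all descriptors
    representation: str = "continuous"
    cutoffs: tuple[float, ...] = (0.01, 0.05)
    n_refs: int = 10
    seed: int = 0

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            gibbs_steps=self.gibbs_steps,
            seed=seed,
            convergence_tolerance=self.convergence_tolerance,
            weight_init=self.weight_init,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"]["class_specs"] = [
                [c.class_id, c.class_size] for c in self.synthetic.class_specs
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            syn["class_specs"] = tuple(
                ActivityClassSpec(str(c), int(s)) for c, s in syn["class_specs"]
            )
            if syn.get("outlier_features") is not None:
                syn["outlier_features"] = tuple(syn["outlier_features"])
            syn = SyntheticSpec(**syn)
        for k in ("descriptor_paths", "hidden_sizes", "combine_subset",
                  "cutoffs"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(synthetic=syn, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def save_model(model: DBNModel, path: str | Path,
               removed_features: list[int] | None = None) -> None:
    """Serialize a DBN checkpoint as versioned JSON."""
    doc = {
        "format": "dbnscreen-checkpoint",
        "version": CHECKPOINT_VERSION,
        "layer_sizes": [int(s) for s in model.layer_sizes],
        "layers": [
            {"W": l.W.tolist(), "a": l.a.tolist(), "b": l.b.tolist()}
            for l in model.layers
        ],
        "decoder": [
            {"W": W.tolist(), "c": c.tolist()} for W, c in model.decoder
        ],
        "fine_tuned": model.fine_tuned,
        "training_log": [float(x) for x in model.training_log],
        "removed_features": list(removed_features or []),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> tuple[DBNModel, list[int]]:
    """Load a checkpoint; returns the model and the removed-feature list."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "dbnscreen-checkpoint":
        raise ValueError(f"{path}: not a model checkpoint")
    if doc.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"{path}: unsupported checkpoint version")
    layers = [RBMParameters(np.array(l["W"]), np.array(l["a"]),
                            np.array(l["b"])) for l in doc["layers"]]
    model = DBNModel(
        layers=layers,
        layer_sizes=list(doc["layer_sizes"]),
        decoder=[(np.array(d["W"]), np.array(d["c"]))
                 for d in doc["decoder"]],
        fine_tuned=bool(doc["fine_tuned"]),
        training_log=list(doc["training_log"]),
    )
    return model, list(doc.get("removed_features", []))


def _surviving(n_features: int, removed: list[int]) -> list[int]:
    removed_set = set(removed)
    return [i for i in range(n_features) if i not in removed_set]


@dataclass
class DescriptorRun:
    """Per-descriptor artifacts of the training/selection stages."""

    matrix: FingerprintMatrix          # binarized input
    model: DBNModel
    removed_features: list[int]
    surviving: list[int]               # original coordinates, ascending
    reconstruction: object
    selection: SelectedFeatureSet      # indices local to surviving columns
    selection_original: list[int]      # same selection, original coordinates


def _train_descriptor(fp: FingerprintMatrix, cfg: RunConfig,
                      seed: int) -> DescriptorRun:
    tc = cfg.train_config(seed)
    ft = tc.with_(epochs=cfg.fine_tune_epochs)
    model, result, removed = iterative_feature_learning(
        fp, [fp.n_features] + list(cfg.hidden_sizes), tc,
        cfg.outlier_fraction, max_rounds=cfg.max_rounds, fine_tune_cfg=ft,
    )
    surviving = _surviving(fp.n_features, removed)
    pca = build_error_pca(result.E, k=min(3, len(surviving)))
    sel = select_features(pca, threshold=cfg.threshold,
                          top_k=min(cfg.top_k, len(surviving)),
                          descriptor_name=fp.descriptor_name)
    sel_orig = [surviving[i] for i in sel.selected_indices]
    return DescriptorRun(
        matrix=fp, model=model, removed_features=removed,
        surviving=surviving, reconstruction=result, selection=sel,
        selection_original=sel_orig,
    )


def _combined_matrix(runs: list[DescriptorRun], cfg: RunConfig
                     ) -> FingerprintMatrix:
    sets, mats = [], []
    for r in runs:
        sets.append(r.selection)
        if cfg.representation == "continuous":
            # reconstructed feature weights over the surviving columns
            base = r.matrix.select_columns(r.surviving).with_values(
                r.reconstruction.Y)
        elif cfg.representation == "binary":
            base = r.matrix.select_columns(r.surviving)
        else:
            raise ValueError("representation must be 'continuous' or 'binary'")
        mats.append(base)
    _, combined = combine_descriptors(sets, mats)
    return combined


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns a summary dict.

    Artifacts written under ``outdir``: ``config.yaml``, the dataset (for
    synthetic input), one ``model_<desc>.json`` checkpoint and selection
    entry per descriptor, ``combined.csv``, ``recall_table_<cutoff>.csv``,
    ``concordance_<cutoff>.json`` and ``run.log``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        config.save(outdir / "config.yaml")

        # --- stage 1: inputs -------------------------------------------------
        if (config.synthetic is None) == (len(config.descriptor_paths) == 0):
            raise ValueError("provide exactly one of synthetic | descriptor_paths")
        if config.synthetic is not None:
            spec = dataclasses.replace(
                config.synthetic, seed=derive_seed(config.seed, 0))
            matrices, manifest = generate(spec)
            write_dataset(matrices, manifest, outdir / "dataset")
            logger.info("generated %d descriptors, %d molecules, M=%d",
                        len(matrices), spec.n_molecules, spec.n_features)
        else:
            matrices = [read_fingerprints(p) for p in config.descriptor_paths]
            manifest = None
            logger.info("loaded %d descriptor files", len(matrices))
        matrices = [binarize(m) for m in matrices]
        names = [m.descriptor_name for m in matrices]

        # --- stage 2+3: train, select ---------------------------------------
        subset = config.combine_subset or tuple(names)
        runs: list[DescriptorRun] = []
        for di, fp in enumerate(matrices):
            if fp.descriptor_name not in subset:
                continue
            seed = derive_seed(config.seed, 1, di)
            t = time.time()
            dr = _train_descriptor(fp, config, seed)
            logger.info(
                "descriptor %s: removed %d features, selected %d, %.1fs",
                fp.descriptor_name, len(dr.removed_features),
                len(dr.selection_original), time.time() - t)
            save_model(dr.model, outdir / f"model_{fp.descriptor_name}.json",
                       dr.removed_features)
            runs.append(dr)
        selections = {
            r.matrix.descriptor_name: {
                "selected_original_indices": r.selection_original,
                "scores": r.selection.scores,
                "threshold": r.selection.threshold_used,
                "top_k": r.selection.top_k_used,
                "removed_features": r.removed_features,
            }
            for r in runs
        }
        (outdir / "selections.json").write_text(json.dumps(selections, indent=2))

        # --- stage 4: combine ------------------------------------------------
        combined = _combined_matrix(runs, config)
        write_matrix(combined, outdir / "combined.csv")
        logger.info("combined descriptor width: %d", combined.n_features)

        # --- stage 5+6: search & evaluate ------------------------------------
        class_ids = sorted(set(combined.activity_labels.values()))
        summary: dict = {"tables": {}, "concordance": {}}
        for cutoff in config.cutoffs:
            per_method: dict[str, dict[str, float]] = {}
            eval_seed = derive_seed(config.seed, 2)
            mode = "continuous" if config.representation == "continuous" else "binary"
            per_method["SDBN"] = {
                c: class_recall(combined, c, n_refs=config.n_refs,
                                cutoff=cutoff, seed=eval_seed, mode=mode)
                for c in class_ids
            }
            for r in runs:
                per_method[f"TAN_{r.matrix.descriptor_name}"] = {
                    c: class_recall(r.matrix, c, n_refs=config.n_refs,
                                    cutoff=cutoff, seed=eval_seed,
                                    mode="binary")
                    for c in class_ids
                }
            table = build_recall_table(per_method, dataset_name="synthetic"
                                       if manifest else "files",
                                       cutoff_fraction=cutoff)
            table.to_frame().to_csv(outdir / f"recall_table_{cutoff}.csv")
            conc = kendall_w(table.rows)
            (outdir / f"concordance_{cutoff}.json").write_text(json.dumps({
                "W": conc.W, "p_value": conc.p_value,
                "mean_ranks": dict(zip(table.rows.columns,
                                       conc.mean_ranks.tolist())),
            }, indent=2))
            summary["tables"][cutoff] = table
            summary["concordance"][cutoff] = conc
            summary.setdefault("gains", {})[cutoff] = gains(table, "SDBN")
            logger.info("cutoff %.2f: means %s, W=%.3f", cutoff,
                        {k: round(v, 2) for k, v in table.column_means.items()},
                        conc.W)
        summary["manifest"] = manifest
        summary["runs"] = runs
        summary["combined"] = combined
        logger.info("run complete in %.1fs", time.time() - t0)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
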