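"""End-to-end orchestration: simulate/load -> distances -> diversity ->
entropy -> analyze, with a machine-readable run manifest.

A run is governed by a single config document (JSON or YAML)::

    {
      "seed": 1,
      "source": {"kind": "simulate", "config": {"n_groups": 3, ...}},
      "stages": {"distances": true, "diversity": true,
                 "entropy": true, "analyze": true},
      "analyze": {"svm": false, "posthoc": true},
      "export_matrix": false
    }

or ``{"source": {"kind": "csv", "path": "corpus.csv"}}`` to analyze an
existing corpus.  Every stage writes its table next to the manifest; the
manifest records the config digest, seeds, output checksums and per-stage
status, so a re-run with identical inputs reproduces identical checksums
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .corpus import Corpus, read_corpus_csv, write_corpus_csv
from .diversity import diversity_table, group_covariation
from .inference import (
    entropy_group_tests,
    fit_distance_lmm,
    fit_diversity_lmm,
    svm_classify_categories,
)
from .jaro import build_dyad_dataset, pairwise_jaro_matrix
from .markov import entropy_table
from .simulate import SyntheticConfig, generate_corpus

__all__ = ["RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger("indriflex")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclasses.dataclass
class RunManifest:
    config_digest: str
    package_version: str
    seed: int
    started: str
    finished: str
    stages: dict[str, str]  # stage -> "ok" | "skipped" | "failed: ..."
    outputs: dict[str, str]  # relative path -> sha256
    notes: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML pipeline config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _build_corpus(source: Mapping[str, Any], seed: int) -> Corpus:
    kind = source.get("kind", "simulate")
    if kind == "simulate":
        cfg_dict = dict(source.get("config", {}))
        cfg_dict.setdefault("seed", seed)
        cfg = SyntheticConfig(**cfg_dict)
        return generate_corpus(cfg)
    if kind == "csv":
        return read_corpus_csv(source["path"])
    raise PipelineError(f"source: unknown kind {kind!r}")


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Run the full analysis chain and write all stage outputs to ``out_dir``.

    ``seed`` overrides the config's seed.  Stage errors abort the run with a
    stage-named :class:`PipelineError`; outputs written before the failure
    remain on disk and the manifest (also written on failure) marks the
    failed stage.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    seed = int(config.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stages_cfg = dict(config.get("stages", {}))
    stage_on = lambda name: bool(stages_cfg.get(name, True))
    analyze_cfg = dict(config.get("analyze", {}))

    stages: dict[str, str] = {}
    outputs: dict[str, str] = {}
    notes: dict[str, str] = {"seed": str(seed)}

    def record(path: Path) -> None:
        outputs[path.name] = _sha256(path)

    def finish() -> RunManifest:
        manifest = RunManifest(
            config_digest=digest,
            package_version=__version__,
            seed=seed,
            started=started,
            finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
            stages=stages,
            outputs=outputs,
            notes=notes,
        )
        (out / "manifest.json").write_text(manifest.to_json())
        return manifest

    def run_stage(name: str, fn) -> Any:
        if not stage_on(name):
            logger.info("stage %s: skipped (disabled in config)", name)
            stages[name] = "skipped"
            return None
        logger.info("stage %s: running", name)
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            stages[name] = f"failed: {exc}"
            finish()
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        stages[name] = "ok"
        logger.info("stage %s: done in %.1fs", name, time.time() - t0)
        return result

    # --- source ---------------------------------------------------------
    def _source() -> Corpus:
        corpus = _build_corpus(config.get("source", {"kind": "simulate"}), seed)
        write_corpus_csv(corpus, out / "corpus.csv")
        record(out / "corpus.csv")
        return corpus

    corpus = run_stage("source", _source)
    if corpus is None:
        raise PipelineError("the source stage cannot be disabled")

    # --- distances ------------------------------------------------------
    dyads = None

    def _distances():
        matrix = pairwise_jaro_matrix(corpus.contributions)
        table = build_dyad_dataset(matrix, corpus.contributions, corpus)
        table.to_csv(out / "dyads.csv", index=False)
        record(out / "dyads.csv")
        if config.get("export_matrix", False):
            pd.DataFrame(matrix).to_csv(out / "jaro_matrix.csv", index=False)
            record(out / "jaro_matrix.csv")
        return matrix, table

    dist = run_stage("distances", _distances)
    matrix = dist[0] if dist else None
    dyads = dist[1] if dist else None

    # --- diversity ------------------------------------------------------
    def _diversity():
        table = diversity_table(corpus)
        table.to_csv(out / "diversity.csv", index=False)
        record(out / "diversity.csv")
        cov = group_covariation(table)
        cov.to_csv(out / "covariation.csv", index=False)
        record(out / "covariation.csv")
        return table, cov

    divr = run_stage("diversity", _diversity)
    div_table = divr[0] if divr else None

    # --- entropy --------------------------------------------------------
    def _entropy():
        table = entropy_table(corpus, seed=seed)
        table.to_csv(out / "entropy.csv", index=False)
        record(out / "entropy.csv")
        return table

    ent_table = run_stage("entropy", _entropy)

    # --- analyze --------------------------------------------------------
    def _analyze():
        report: dict[str, Any] = {"seed": seed}
        posthoc = bool(analyze_cfg.get("posthoc", True))
        if dyads is not None:
            fit = fit_distance_lmm(dyads, posthoc=posthoc)
            notes["distance_df_method"] = fit.df_method
            report["distance_lmm"] = {
                "levels": list(fit.levels),
                "lrt_chi2": fit.lrt_chi2,
                "lrt_df": fit.lrt_df,
                "p_value": fit.p_value,
                "converged": fit.converged,
                "posthoc": fit.posthoc.to_dict(orient="records")
                if fit.posthoc is not None
                else None,
            }
        if div_table is not None:
            fit = fit_diversity_lmm(div_table, posthoc=posthoc)
            notes["diversity_df_method"] = fit.df_method
            report["diversity_lmm"] = {
                "levels": list(fit.levels),
                "lrt_chi2": fit.lrt_chi2,
                "lrt_df": fit.lrt_df,
                "p_value": fit.p_value,
                "converged": fit.converged,
                "posthoc": fit.posthoc.to_dict(orient="records")
                if fit.posthoc is not None
                else None,
            }
        if ent_table is not None:
            try:
                ent = entropy_group_tests(ent_table)
                report["entropy_tests"] = dataclasses.asdict(ent)
            except ValueError as exc:
                report["entropy_tests"] = {"untested": str(exc)}
        if analyze_cfg.get("svm", False) and matrix is not None:
            labels = np.array(
                [corpus.category_of(c.singer_id) for c in corpus.contributions]
            )
            cls = svm_classify_categories(matrix, labels, seed=seed)
            report["svm"] = {
                "classes": list(cls.classes),
                "best_C": cls.best_C,
                "best_sigma": cls.best_sigma,
                "cv_accuracy": cls.cv_accuracy,
                "train_accuracy": cls.train_accuracy,
                "test_accuracy": cls.test_accuracy,
                "per_class_recall": cls.per_class_recall,
                "confusion": cls.confusion.to_dict(),
            }
        (out / "analysis.json").write_text(json.dumps(report, indent=2))
        record(out / "analysis.json")
        return report

    run_stage("analyze", _analyze)

    return finish()
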