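"""End-to-end orchestration of the surveillance pipeline.

Canonical stage order: generate -> select -> preprocess -> split -> train
-> evaluate.  Every stage reads its inputs from, and writes its artifacts
to, the configured run directory, so stages can be run together or one at a
time across invocations.  A JSON run report records configs, seeds, stage
durations and the final metric summary; rerunning with the same config and
seed reproduces identical artifacts (apart from wall-clock fields).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .classes import OtitisClass, read_corpus_jsonl, write_corpus_jsonl
from .corpus import GeneratorConfig, generate_corpus, corpus_summary
from .embeddings import (
    EmbeddingConfig,
    load_embedding_text,
    save_embedding_text,
    train_embeddings,
)
from .evaluation import confusion_matrix, error_report, metrics_report
from .lexicon import Lexicon
from .nn import (
    default_grid,
    default_spec,
    ensemble_predict,
    predict_logits,
    two_stage_develop,
    TrainingConfig,
)
from .preprocessing import PreprocessConfig, build_vocabulary, encode_corpus, merge_fields
from .selection import compile_search_pattern, default_search_pattern, load_pattern_yaml, select_records
from .split import SplitAssignment, SplitConfig, stratified_split

STAGES = ("generate", "select", "preprocess", "split", "train", "evaluate")

#: Architectures whose logits enter the ensemble (simple embedding excluded).
ENSEMBLE_ARCH_IDS = (1, 2, 3, 4)


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing; the message names the stage."""


@dataclass
class TrainStageConfig:
    architectures: tuple[int, ...] = (0, 1, 2, 3, 4)
    filters: int = 64
    batch_sizes: tuple[int, ...] = (8, 16)
    hidden_dropouts: tuple[float, ...] = (0.5, 0.7)
    embedding_dropout: float = 0.2
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 5
    n_transfer: int = 300


@dataclass
class RunConfig:
    outdir: Path = Path("otitext_run")
    seed: int = 0
    verbosity: int = 1
    lexicon_path: Path | None = None
    pattern_path: Path | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    train: TrainStageConfig = field(default_factory=TrainStageConfig)

    def lexicon(self) -> Lexicon:
        return Lexicon.from_yaml(self.lexicon_path) if self.lexicon_path else Lexicon()

    def pattern(self):
        return load_pattern_yaml(self.pattern_path) if self.pattern_path else default_search_pattern()


def _parse_date(v) -> _dt.date:
    return v if isinstance(v, _dt.date) else _dt.date.fromisoformat(str(v))


def config_from_dict(obj: dict, base_dir: Path | None = None) -> RunConfig:
    """Build a RunConfig from a parsed YAML mapping; raises on first error."""
    errors = validate_config_dict(obj)
    if errors:
        raise ValueError("invalid run config:\n" + "\n".join(errors))
    base = Path(base_dir) if base_dir else Path(".")
    cfg = RunConfig()
    cfg.outdir = base / obj.get("outdir", "otitext_run")
    cfg.seed = int(obj.get("seed", 0))
    cfg.verbosity = int(obj.get("verbosity", 1))
    if obj.get("lexicon_path"):
        cfg.lexicon_path = base / obj["lexicon_path"]
    if obj.get("pattern_path"):
        cfg.pattern_path = base / obj["pattern_path"]

    g = dict(obj.get("generator", {}))
    if "date_range" in g:
        g["date_range"] = tuple(_parse_date(d) for d in g["date_range"])
    if "class_proportions" in g:
        g["class_proportions"] = tuple(float(x) for x in g["class_proportions"])
    g.setdefault("seed", cfg.seed)
    cfg.generator = GeneratorConfig(**g)
    cfg.generator.validate()

    p = dict(obj.get("preprocess", {}))
    cfg.preprocess = PreprocessConfig(**p)

    e = dict(obj.get("embedding", {}))
    e.setdefault("seed", cfg.seed)
    cfg.embedding = EmbeddingConfig(**e)

    s = dict(obj.get("split", {}))
    if "historical_cutoff" in s:
        s["historical_cutoff"] = _parse_date(s["historical_cutoff"])
    if "set_sizes" in s:
        s["set_sizes"] = {k: int(v) for k, v in s["set_sizes"].items()}
    s.setdefault("seed", cfg.seed)
    cfg.split = SplitConfig(**s)
    cfg.split.validate()

    t = dict(obj.get("train", {}))
    for key in ("architectures", "batch_sizes", "hidden_dropouts"):
        if key in t:
            t[key] = tuple(t[key])
    cfg.train = TrainStageConfig(**t)
    return cfg


def validate_config_dict(obj: dict) -> list[str]:
    """Collect constraint violations with their field paths (empty if valid)."""
    errors: list[str] = []
    if not isinstance(obj, dict):
        return ["config root must be a mapping"]
    g = obj.get("generator", {})
    if "n_visits" in g and int(g["n_visits"]) < 0:
        errors.append("generator.n_visits: must be nonnegative")
    if "class_proportions" in g:
        p = [float(x) for x in g["class_proportions"]]
        if len(p) != 6:
            errors.append("generator.class_proportions: must have 6 entries")
        elif abs(sum(p) - 1.0) > 1e-9:
            errors.append(
                f"generator.class_proportions: must sum to 1 (got {sum(p)})"
            )
        if any(x < 0 for x in p):
            errors.append("generator.class_proportions: entries must be nonnegative")
    for rate in ("male_fraction", "negation_rate", "other_doctor_rate",
                 "atypical_term_rate", "typo_rate"):
        if rate in g and not 0 <= float(g[rate]) <= 1:
            errors.append(f"generator.{rate}: must be in [0, 1]")
    pp = obj.get("preprocess", {})
    if "max_length" in pp and int(pp["max_length"]) < 1:
        errors.append("preprocess.max_length: must be >= 1")
    emb = obj.get("embedding", {})
    if "dimension" in emb and int(emb["dimension"]) < 1:
        errors.append("embedding.dimension: must be >= 1")
    sp = obj.get("split", {})
    if "min_records_per_set" in sp and int(sp["min_records_per_set"]) < 1:
        errors.append("split.min_records_per_set: must be >= 1")
    tr = obj.get("train", {})
    if "architectures" in tr and not set(tr["architectures"]) <= {0, 1, 2, 3, 4}:
        errors.append("train.architectures: entries must be in 0-4")
    return errors


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; raises with all field errors."""
    with open(path, encoding="utf-8") as fh:
        obj = yaml.safe_load(fh)
    return config_from_dict(obj, base_dir=Path(path).parent)


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if isinstance(o, (_dt.date, Path)):
            return str(o)
        return repr(o)

    blob = json.dumps(asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage {stage!r} requires {path.name} (produced by stage {produced_by!r})"
        )
    return path


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages in canonical order and write artifacts."""
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    log = print if config.verbosity else (lambda *a, **k: None)

    for stage in requested:
        t0 = time.perf_counter()
        log(f"[otitext] stage {stage} ...")
        info = _STAGE_FUNCS[stage](config, out)
        info["seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = info
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


# -- individual stages ------------------------------------------------------


def _stage_generate(cfg: RunConfig, out: Path) -> dict:
    corpus = generate_corpus(cfg.generator, cfg.lexicon())
    write_corpus_jsonl(corpus, out / "corpus.jsonl")
    summ = corpus_summary(corpus)
    return {
        "n_records": summ["n_records"],
        "class_counts": summ["class_counts"].to_dict(),
    }


def _stage_select(cfg: RunConfig, out: Path) -> dict:
    corpus = read_corpus_jsonl(_require(out / "corpus.jsonl", "select", "generate"))
    selected = select_records(corpus, cfg.pattern())
    write_corpus_jsonl(selected, out / "selected.jsonl")
    return {"n_input": len(corpus), "n_selected": len(selected)}


def _stage_preprocess(cfg: RunConfig, out: Path) -> dict:
    corpus = read_corpus_jsonl(_require(out / "selected.jsonl", "preprocess", "select"))
    streams = [merge_fields(r, cfg.preprocess) for r in corpus]
    vocab = build_vocabulary(streams, cfg.embedding.min_count)
    table = train_embeddings(streams, cfg.embedding, vocab)
    save_embedding_text(table, out / "embeddings.txt")
    return {"vocabulary_size": vocab.size, "dimension": table.dimension}


def _stage_split(cfg: RunConfig, out: Path) -> dict:
    corpus = read_corpus_jsonl(_require(out / "selected.jsonl", "split", "select"))
    assignment = stratified_split(corpus, cfg.split)
    assignment.save(out / "splits.tsv")
    return {"sizes": assignment.sizes()}


def _stage_train(cfg: RunConfig, out: Path) -> dict:
    corpus = read_corpus_jsonl(_require(out / "selected.jsonl", "train", "select"))
    assignment = SplitAssignment.load(_require(out / "splits.tsv", "train", "split"))
    table = load_embedding_text(_require(out / "embeddings.txt", "train", "preprocess"))
    sets = {
        name: encode_corpus(assignment.subset(corpus, name), table.vocab, cfg.preprocess)
        for name in ("train", "validation", "test")
    }
    specs = [default_spec(a, cfg.train.filters) for a in cfg.train.architectures]
    base = TrainingConfig(
        embedding_dropout=cfg.train.embedding_dropout,
        learning_rate=cfg.train.learning_rate,
        max_epochs=cfg.train.max_epochs,
        patience=cfg.train.patience,
    )
    grid = default_grid(cfg.train.batch_sizes, cfg.train.hidden_dropouts)
    results = two_stage_develop(
        specs,
        table,
        sets["train"],
        sets["validation"],
        grid=grid,
        n_transfer=cfg.train.n_transfer,
        base_config=base,
        seed=cfg.seed,
    )
    info: dict = {"validation_accuracy": {}, "test_sets": len(sets["test"])}
    test_ids = [r.record_id for r in sets["test"]]
    for arch_id, res in results.items():
        model = res["model"]
        model.save_metadata(out / f"model_arch{arch_id}.json")
        logits = predict_logits(model, sets["test"])
        np.savetxt(
            out / f"logits_arch{arch_id}.tsv", logits, delimiter="\t", fmt="%.8g"
        )
        info["validation_accuracy"][str(arch_id)] = res["validation_accuracy"]
    with open(out / "test_ids.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(test_ids) + "\n")
    return info


def _stage_evaluate(cfg: RunConfig, out: Path) -> dict:
    corpus = read_corpus_jsonl(_require(out / "selected.jsonl", "evaluate", "select"))
    _require(out / "splits.tsv", "evaluate", "split")
    with open(_require(out / "test_ids.txt", "evaluate", "train"), encoding="utf-8") as fh:
        test_ids = [line.strip() for line in fh if line.strip()]
    logit_matrices = []
    for arch_id in ENSEMBLE_ARCH_IDS:
        path = _require(out / f"logits_arch{arch_id}.tsv", "evaluate", "train")
        logit_matrices.append(np.loadtxt(path, delimiter="\t", ndmin=2))
    preds, probs = ensemble_predict(logit_matrices)
    by_id = {r.visit_id: r for r in corpus}
    records = [by_id[i] for i in test_ids]
    gold = [r.gold_label for r in records]
    cm = confusion_matrix(preds, gold)
    cm.save_tsv(out / "confusion_matrix.tsv")
    rep = metrics_report(cm)
    rep.to_json(out / "metrics.json")
    err = error_report(records, preds, gold)
    err.to_jsonl(out / "misclassified.jsonl")
    with open(out / "predictions.tsv", "w", encoding="utf-8") as fh:
        for rid, p, prow in zip(test_ids, preds, probs):
            fh.write(rid + "\t" + p.label + "\t" + "\t".join(f"{x:.6f}" for x in prow) + "\n")
    return {"metrics": rep.rounded(), "n_misclassified": err.n_misclassified}


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "select": _stage_select,
    "preprocess": _stage_preprocess,
    "split": _stage_split,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}
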