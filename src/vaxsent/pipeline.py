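"""End-to-end orchestration: filter -> preprocess -> classify -> analytics.

Each stage writes its artifacts under the configured output directory so
stages can also be re-run independently (per-period re-analyses). The run
report reconciles counts at every stage (retained + dropped = input) and
echoes the config and seed; report CSVs carry the seed in a leading
``# seed=`` comment line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
import yaml

from . import mining, trends, validation
from .corpus import (
    GeoFilterResult,
    KeywordFilterSpec,
    PostRecord,
    UsageError,
    default_filter_spec,
    dedupe_exact,
    filter_geo,
    filter_thematic,
    load_keywords,
    posts_to_frame,
    read_posts,
    write_posts,
)
from .ensemble import (
    Backends,
    ClassifierOutput,
    EnsembleConfig,
    KeywordClassifier,
    LexiconScorer,
    Sentiment,
    classify_corpus,
    default_backends,
    load_lexicon,
)
from .preprocess import clean_corpus, load_stopwords
from .synthetic import CorpusConfig, corpus_config_from_dict, generate_corpus, write_truth_csv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    output_dir: Path = Path("vaxsent_out")
    # exactly one of corpus_path / synthetic must be set
    corpus_path: Path | None = None
    corpus_format: str | None = None
    synthetic: CorpusConfig | None = None
    stage1_file: Path | None = None
    stage2_file: Path | None = None
    match_mode: str = "word_boundary"
    case_sensitive: bool = False
    countries: tuple[str, ...] = ("GB", "US")
    stopword_file: Path | None = None
    lexicon_a_file: Path | None = None
    lexicon_b_file: Path | None = None
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    dedupe: bool = False
    annotation_fraction: float = 0.10
    ngram_orders: tuple[int, ...] = (1, 2)
    top_k: int = 25
    min_posts_per_region: int = 10
    tau_geo: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if (self.corpus_path is None) == (self.synthetic is None):
            raise UsageError("set exactly one of corpus_path or synthetic")
        for p in (self.corpus_path, self.stage1_file, self.stage2_file,
                  self.stopword_file, self.lexicon_a_file, self.lexicon_b_file):
            if p is not None and not Path(p).exists():
                raise UsageError(f"configured file does not exist: {p}")
        if not self.countries:
            raise UsageError("countries must be non-empty")
        if not 0 < self.annotation_fraction <= 1:
            raise UsageError("annotation_fraction must be in (0, 1]")

    def filter_spec(self) -> KeywordFilterSpec:
        default = default_filter_spec()
        return KeywordFilterSpec(
            stage1_terms=tuple(load_keywords(self.stage1_file))
            if self.stage1_file else default.stage1_terms,
            stage2_terms=tuple(load_keywords(self.stage2_file))
            if self.stage2_file else default.stage2_terms,
            match_mode=self.match_mode,
            case_sensitive=self.case_sensitive,
        )

    def backends(self, classifier: Callable[[str], ClassifierOutput] | None = None) -> Backends:
        if classifier is None:
            classifier = KeywordClassifier()
        default = default_backends(classifier)
        lex_a = (LexiconScorer(load_lexicon(self.lexicon_a_file), "lexicon_a")
                 if self.lexicon_a_file else default.lexicon_a)
        lex_b = (LexiconScorer(load_lexicon(self.lexicon_b_file), "lexicon_b")
                 if self.lexicon_b_file else default.lexicon_b)
        return Backends(lex_a, lex_b, classifier)


def pipeline_config_from_yaml(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return pipeline_config_from_dict(raw)


def pipeline_config_from_dict(raw: Mapping) -> PipelineConfig:
    kwargs: dict = {}
    paths = ("output_dir", "corpus_path", "stage1_file", "stage2_file",
             "stopword_file", "lexicon_a_file", "lexicon_b_file")
    for key in paths:
        if key in raw and raw[key] is not None:
            kwargs[key] = Path(raw[key])
    simple = ("corpus_format", "match_mode", "case_sensitive", "dedupe",
              "annotation_fraction", "top_k", "min_posts_per_region",
              "tau_geo", "seed")
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    if "countries" in raw:
        kwargs["countries"] = tuple(raw["countries"])
    if "ngram_orders" in raw:
        kwargs["ngram_orders"] = tuple(int(n) for n in raw["ngram_orders"])
    if "synthetic" in raw and raw["synthetic"] is not None:
        kwargs["synthetic"] = corpus_config_from_dict(raw["synthetic"])
    if "ensemble" in raw and raw["ensemble"] is not None:
        ens = raw["ensemble"]
        ekw: dict = {}
        if "lexicon_weights" in ens:
            ekw["lexicon_weights"] = tuple(float(w) for w in ens["lexicon_weights"])
        if "neutral_band" in ens:
            ekw["neutral_band"] = float(ens["neutral_band"])
        if "rule_table" in ens:
            # YAML form: list of {lexicon: L, classifier: C, final: F}
            table = {
                (Sentiment(int(e["lexicon"])), Sentiment(int(e["classifier"]))):
                    Sentiment(int(e["final"]))
                for e in ens["rule_table"]
            }
            ekw["rule_table"] = table
        kwargs["ensemble"] = EnsembleConfig(**ekw)
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    cfg: PipelineConfig,
    classifier: Callable[[str], ClassifierOutput] | None = None,
) -> dict:
    """Execute the full pipeline; returns the machine-readable run report.

    Identical config + seed give identical artifacts. Per-post backend
    failures are counted, not fatal; an invalid config raises before any
    work is done.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "artifacts": []}

    # -- acquire ----------------------------------------------------------
    truth: dict[str, int] | None = None
    if cfg.synthetic is not None:
        records, labels = generate_corpus(cfg.synthetic)
        truth = {t.post_id: int(t.label) for t in labels}
        write_posts(records, out / "corpus.jsonl")
        write_truth_csv(labels, out / "truth_labels.csv")
        report["artifacts"] += ["corpus.jsonl", "truth_labels.csv"]
        n_skipped = 0
    else:
        result = read_posts(cfg.corpus_path, cfg.corpus_format)
        records, n_skipped = result.records, result.n_skipped
    report["stages"]["input"] = {"n": len(records), "n_skipped_rows": n_skipped}

    # -- filters ----------------------------------------------------------
    spec = cfg.filter_spec()
    thematic = filter_thematic(records, spec)
    report["stages"]["thematic_filter"] = {
        "kept": len(thematic), "dropped": len(records) - len(thematic),
    }
    geo: GeoFilterResult = filter_geo(thematic, cfg.countries)
    report["stages"]["geo_filter"] = {
        "kept": len(geo.records), "dropped": geo.n_dropped,
        "no_location": geo.n_no_location,
    }
    kept = geo.records
    if cfg.dedupe:
        kept = dedupe_exact(kept)
        report["stages"]["dedupe"] = {
            "kept": len(kept), "dropped": len(geo.records) - len(kept),
        }
    write_posts(kept, out / "filtered.jsonl")
    report["artifacts"].append("filtered.jsonl")

    # -- preprocess + classify -------------------------------------------
    stopwords = load_stopwords(cfg.stopword_file)
    cleaned = clean_corpus(kept, stopwords)
    n_empty = sum(1 for c in cleaned if len(c) == 0)
    report["stages"]["preprocess"] = {"n": len(cleaned), "n_empty_after_cleaning": n_empty}

    backends = cfg.backends(classifier)
    audit, n_errors = classify_corpus(kept, cleaned, backends, cfg.ensemble)
    _write_csv(audit, out / "classified.csv", cfg.seed)
    report["artifacts"].append("classified.csv")
    report["stages"]["classify"] = {
        "n": len(audit), "labeled": int(audit["final"].notna().sum()), "errors": n_errors,
    }

    labeled = posts_to_frame(kept).merge(
        audit[["id", "combined", "final"]], on="id", how="left"
    ).rename(columns={"final": "label"})

    # -- validation -------------------------------------------------------
    sample = validation.sample_for_annotation(kept, cfg.annotation_fraction, cfg.seed)
    validation.export_annotation_sheet(sample, out / "annotation_sample.csv")
    report["artifacts"].append("annotation_sample.csv")
    report["stages"]["annotation_sample"] = {"n": len(sample)}
    if truth is not None and sample:
        sample_ids = [r.id for r in sample]
        pred = labeled.set_index("id")["label"]
        pairs = [
            (truth[i], int(pred.loc[i])) for i in sample_ids
            if i in truth and pd.notna(pred.loc[i])
        ]
        if pairs:
            cm = validation.confusion_matrix([t for t, _ in pairs], [p for _, p in pairs])
            (out / "validation_report.txt").write_text(
                f"# seed={cfg.seed}\n" + validation.metrics_report(cm) + "\n",
                encoding="utf-8",
            )
            _write_csv(
                cm.to_frame(normalized=True).reset_index(), out / "confusion_normalized.csv",
                cfg.seed,
            )
            report["artifacts"] += ["validation_report.txt", "confusion_normalized.csv"]
            m = validation.class_metrics(cm)
            report["stages"]["validation"] = {
                "n": len(pairs), "accuracy": m.accuracy,
            }

    # -- trends -----------------------------------------------------------
    weekly = trends.weekly_proportions(labeled)
    _write_csv(weekly, out / "weekly_trends.csv", cfg.seed)
    overall = trends.overall_proportions(labeled, by="platform")
    _write_csv(overall, out / "overall_by_platform.csv", cfg.seed)
    report["artifacts"] += ["weekly_trends.csv", "overall_by_platform.csv"]

    strength_rows = []
    for (country, platform, cls), grp in weekly.groupby(["country", "platform", "class"]):
        if grp["proportion"].notna().sum() >= 3 and grp["proportion"].nunique() > 1:
            strength_rows.append(
                {"country": country, "platform": platform, "class": cls,
                 "trend_r": trends.trend_strength(grp)}
            )
    if strength_rows:
        _write_csv(pd.DataFrame(strength_rows), out / "trend_strength.csv", cfg.seed)
        report["artifacts"].append("trend_strength.csv")

    cross = {}
    for country in sorted({c for c in labeled["country"].dropna()}):
        sub = labeled[labeled["country"] == country]
        per_platform = trends.overall_proportions(sub, by="platform")
        if per_platform["platform"].nunique() == 2:
            d = {
                p: dict(zip(g["class"], g["percent"]))
                for p, g in per_platform.groupby("platform")
            }
            cross[country] = trends.cross_platform_average(d)
    if cross:
        rows = [
            {"country": c, "class": cls, "percent": pct}
            for c, d in cross.items() for cls, pct in d.items()
        ]
        _write_csv(pd.DataFrame(rows), out / "cross_platform_overall.csv", cfg.seed)
        report["artifacts"].append("cross_platform_overall.csv")

    # -- mining -----------------------------------------------------------
    by_id = {c.post_id: c for c in cleaned}
    for n in cfg.ngram_orders:
        table = mining.ngram_counts(cleaned, n)
        mining.write_ngram_csv(mining.top_terms(table, cfg.top_k), out / f"top_{n}grams.csv")
        report["artifacts"].append(f"top_{n}grams.csv")
        for cls_value, cls_name in ((-1, "negative"), (1, "positive")):
            ids = set(labeled.loc[labeled["label"] == cls_value, "id"])
            texts = [by_id[i] for i in by_id if i in ids]
            cls_table = mining.ngram_counts(texts, n, scope=cls_name)
            mining.write_ngram_csv(
                mining.top_terms(cls_table, cfg.top_k) if cls_table.rows else cls_table,
                out / f"top_{n}grams_{cls_name}.csv",
            )
            report["artifacts"].append(f"top_{n}grams_{cls_name}.csv")

    region = mining.region_sentiment(
        labeled, min_posts=cfg.min_posts_per_region, tau_geo=cfg.tau_geo
    )
    _write_csv(region.table, out / "region_sentiment.csv", cfg.seed)
    _write_csv(region.low_coverage, out / "region_low_coverage.csv", cfg.seed)
    report["artifacts"] += ["region_sentiment.csv", "region_low_coverage.csv"]
    report["stages"]["geo_aggregate"] = {
        "regions_mapped": len(region.table), "regions_low_coverage": len(region.low_coverage),
    }

    # -- report -----------------------------------------------------------
    report["config"] = _config_echo(cfg)
    with open(out / "run_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    report["artifacts"].append("run_report.json")
    return report


def _config_echo(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if isinstance(obj, EnsembleConfig):
            return {
                "lexicon_weights": list(obj.lexicon_weights),
                "neutral_band": obj.neutral_band,
                "rule_table": [
                    {"lexicon": int(l), "classifier": int(c), "final": int(f)}
                    for (l, c), f in sorted(obj.rule_table.items())
                ],
            }
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, Mapping):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (Path,)):
            return str(obj)
        if isinstance(obj, Sentiment):
            return int(obj)
        return obj

    return convert(cfg)
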