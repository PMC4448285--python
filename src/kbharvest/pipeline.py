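"""End-to-end pipeline: recognize -> gather -> analyze -> reason -> export.

Every stage is a pure function of its inputs and the configuration; the
runner wires them together, writes intermediates (so runs can resume and
ablations stay comparable) and produces a machine-readable run report.

Ablation flags mirror the method's component study: ``no_dom`` drops
document-structure patterns, ``no_pattern_stats`` skips the confidence
statistics (every mined subsequence that co-occurs with a relation's
seeds becomes a seed pattern with confidence 1), and ``no_reasoning``
accepts all fact candidates without type checking or Max-Sat reasoning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import analysis, gathering, kb, reasoning
from .analysis import PatternOccurrence, SeedPattern
from .corpus import parse_dom_document, read_dictionary, read_parsed_corpus
from .recognition import (
    MatchIndex,
    MatchIndexParams,
    SemanticTypeHierarchy,
    recognize_mentions,
    resolve_overlaps,
)
from .relations import (
    DEFAULT_EXCLUSIONS,
    DEFAULT_SIGNATURES,
    load_exclusions,
    load_signatures,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    dictionary: Path
    hierarchy: Path
    seeds: Path
    corpus: Path
    outdir: Path
    html_dir: Path | None = None
    signatures_file: Path | None = None
    exclusions_file: Path | None = None
    ngram_size: int = 3
    signature_length: int = 256
    band_count: int = 64
    threshold: float = 0.7
    max_window: int = 6
    hash_seed: int = 42
    min_support: int = 2
    confidence_threshold: float = 0.3
    no_dom: bool = False
    no_pattern_stats: bool = False
    no_reasoning: bool = False
    resume: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold < 1.0):
            raise ValueError("confidence_threshold must be in [0, 1)")
        for name in ("dictionary", "hierarchy", "seeds", "corpus", "outdir",
                     "html_dir", "signatures_file", "exclusions_file"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    def matcher_params(self) -> MatchIndexParams:
        return MatchIndexParams(
            self.ngram_size,
            self.signature_length,
            self.band_count,
            self.threshold,
            self.max_window,
            self.hash_seed,
        )


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["pipeline run report", "-" * 32]
        lines += [f"{k:32s} {v}" for k, v in self.counts.items()]
        return "\n".join(lines) + "\n"

    def write(self, outdir: Path) -> None:
        pd.DataFrame(
            [{"counter": k, "value": v} for k, v in self.counts.items()],
            columns=["counter", "value"],
        ).to_csv(outdir / "report.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(self.to_text(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Occurrence cache (JSONL)
# ---------------------------------------------------------------------------

def write_occurrences(occurrences: list[PatternOccurrence], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for o in occurrences:
            fh.write(json.dumps(dataclasses.asdict(o), ensure_ascii=False) + "\n")


def read_occurrences(path: Path) -> list[PatternOccurrence]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                d["pattern"] = tuple(d["pattern"])
                out.append(PatternOccurrence(**d))
    return out


def write_seed_patterns(seed_patterns: list[SeedPattern], path: Path) -> None:
    rows = [
        {"pattern": " ".join(sp.tokens), "relation": sp.relation,
         "confidence": f"{sp.confidence:.6f}"}
        for sp in seed_patterns
    ]
    pd.DataFrame(rows, columns=["pattern", "relation", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def write_candidates(candidates: list, path: Path) -> None:
    rows = [
        {"relation": c.relation, "left_entity": c.left_entity,
         "right_entity": c.right_entity, "weight": f"{c.weight:.6f}",
         "support_count": len(c.support)}
        for c in candidates
    ]
    pd.DataFrame(
        rows, columns=["relation", "left_entity", "right_entity", "weight", "support_count"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def gather_occurrences(
    cfg: PipelineConfig, index: MatchIndex, hierarchy: SemanticTypeHierarchy
) -> tuple[list[PatternOccurrence], gathering.GatherDiagnostics, dict[str, int]]:
    diag = gathering.GatherDiagnostics()
    occurrences: list[PatternOccurrence] = []
    counters = {"sentences": 0, "mentions": 0, "sentence_patterns": 0, "dom_patterns": 0}
    for meta, sent in read_parsed_corpus(cfg.corpus):
        counters["sentences"] += 1
        mentions = resolve_overlaps(recognize_mentions(sent, index), hierarchy)
        counters["mentions"] += len(mentions)
        if len(mentions) < 2:
            continue
        for sp in gathering.gather_sentence_patterns(sent, mentions, diag):
            counters["sentence_patterns"] += 1
            occurrences.append(analysis.occurrence_from_sentence_pattern(sp, meta))
    if cfg.html_dir is not None and not cfg.no_dom and cfg.html_dir.is_dir():
        for html_path in sorted(cfg.html_dir.glob("*.html")):
            tree = parse_dom_document(
                html_path.read_text(encoding="utf-8"), html_path.stem
            )
            for dp in gathering.extract_dom_patterns(tree, index, html_path.stem):
                occ = analysis.occurrence_from_dom_pattern(dp, source=html_path.stem)
                if occ is not None:
                    counters["dom_patterns"] += 1
                    occurrences.append(occ)
    return occurrences, diag, counters


def analyze_occurrences(
    cfg: PipelineConfig,
    occurrences: list[PatternOccurrence],
    seed_index: analysis.RelationSeedIndex,
) -> tuple[list[SeedPattern], list[analysis.FactCandidate]]:
    mined = analysis.mine_frequent_subsequences(occurrences, cfg.min_support)
    confidences = analysis.compute_all_confidences(mined, occurrences, seed_index)
    if cfg.no_pattern_stats:
        seed_patterns = [
            SeedPattern(q, rel, 1.0) for (q, rel), c in sorted(confidences.items()) if c > 0
        ]
    else:
        seed_patterns = analysis.select_seed_patterns(confidences, cfg.confidence_threshold)
    if not seed_patterns:
        return [], []
    candidates = analysis.build_fact_candidates(occurrences, seed_patterns)
    return seed_patterns, candidates


def run_pipeline(cfg: PipelineConfig, stop_after: str | None = None) -> RunReport:
    """Run all stages (or stop after "gather"/"analyze"); returns the report."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    entries = read_dictionary(cfg.dictionary)
    hierarchy = SemanticTypeHierarchy.from_tsv(cfg.hierarchy)
    seeds = analysis.read_seed_facts(cfg.seeds)
    signatures = (
        load_signatures(cfg.signatures_file) if cfg.signatures_file else dict(DEFAULT_SIGNATURES)
    )
    exclusions = (
        load_exclusions(cfg.exclusions_file) if cfg.exclusions_file else DEFAULT_EXCLUSIONS
    )
    report.counts["dictionary_entries"] = len(entries)
    report.counts["seed_facts"] = len(seeds)

    occ_path = cfg.outdir / "occurrences.jsonl"
    if cfg.resume and occ_path.exists():
        log.info("resuming: loading cached occurrences from %s", occ_path)
        occurrences = read_occurrences(occ_path)
        diag = gathering.GatherDiagnostics()
        counters = {}
    else:
        if not entries:
            log.warning("empty dictionary; pipeline will extract nothing")
        index = MatchIndex(entries, cfg.matcher_params()) if entries else None
        if index is None:
            occurrences, diag, counters = [], gathering.GatherDiagnostics(), {}
        else:
            occurrences, diag, counters = gather_occurrences(cfg, index, hierarchy)
        write_occurrences(occurrences, occ_path)
    report.counts.update(counters)
    report.counts["pattern_occurrences"] = len(occurrences)
    pd.DataFrame(diag.as_rows(), columns=["counter", "value"]).to_csv(
        cfg.outdir / "diagnostics.tsv", sep="\t", index=False
    )
    if stop_after == "gather":
        report.write(cfg.outdir)
        return report

    if occurrences and seeds:
        seed_index = analysis.build_seed_index(seeds, signatures.keys())
        seed_patterns, candidates = analyze_occurrences(cfg, occurrences, seed_index)
    else:
        if not occurrences:
            log.warning("no pattern occurrences; empty knowledge base")
        seed_patterns, candidates = [], []
    write_seed_patterns(seed_patterns, cfg.outdir / "seed_patterns.tsv")
    write_candidates(candidates, cfg.outdir / "candidates.tsv")
    report.counts["seed_patterns"] = len(seed_patterns)
    report.counts["fact_candidates"] = len(candidates)
    if stop_after == "analyze":
        report.write(cfg.outdir)
        return report

    entity_types: dict[str, frozenset[str]] = {}
    for e in entries:
        entity_types[e.entity_id] = entity_types.get(e.entity_id, frozenset()) | e.semantic_types
    if cfg.no_reasoning:
        accepted = frozenset(c.key for c in candidates)
        result = reasoning.ReasonerResult(accepted, frozenset(), 0.0)
        kept = candidates
        pruned: list = []
    else:
        seed_keys = [(s.relation, s.left_entity, s.right_entity) for s in seeds]
        result, kept, pruned = reasoning.run_reasoner(
            candidates, signatures, entity_types, hierarchy, exclusions, seed_keys
        )
    report.counts["type_pruned"] = len(pruned)
    report.counts["accepted_facts"] = len(result.accepted)
    report.counts["rejected_facts"] = len(result.rejected)

    facts = kb.assemble_kb(result, kept)
    n_facts, n_occ = kb.kb_counts(facts)
    report.counts["kb_facts"] = n_facts
    report.counts["kb_fact_occurrences"] = n_occ
    kb.export_kb_tsv(facts, cfg.outdir / "kb.tsv")
    kb.export_kb_ntriples(facts, cfg.outdir / "kb.nt", cfg.outdir / "kb_provenance.tsv")
    report.write(cfg.outdir)
    return report
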