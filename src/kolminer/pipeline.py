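"""End-to-end orchestration: tag -> filter -> normalize -> network -> rank.

Stages communicate only through documented on-disk artifacts (TSV/JSONL),
so any stage can be inspected or replaced, and a run manifest records the
configuration, stage counts and artifact digests.  A rerun with the same
configuration and seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import comention_sna, expert_filter, name_normalizer, ner_crf
from .corpus_io import Document
from .synthetic_corpus import GeneratorConfig, SyntheticCorpus, generate_corpus

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All thresholds and switches of the pipeline, serialized verbatim
    into the run manifest."""

    out_dir: str = "run"
    seed: int = 42
    keyword_window: int = 100
    min_publications: int = 10
    theta_name: float = 0.85
    require_context: bool | str = True
    top_k: int = 20
    use_global_n: bool = False
    crf_max_iter: int = 150
    crf_l2_variance: float = 10.0
    log_level: str = "INFO"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.keyword_window <= 0:
            raise PipelineError("keyword window must be positive")
        if self.min_publications < 0:
            raise PipelineError("publication threshold must be >= 0")
        if self.top_k <= 0:
            raise PipelineError("top_k must be positive")
        if not 0.0 <= self.theta_name <= 1.0:
            raise PipelineError("theta_name must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    mentions: list
    experts: list
    clusters: list
    graph: object
    table: object
    ranking: object
    truth: SyntheticCorpus | None = None
    model: ner_crf.CrfModel | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_mentions_tsv(mentions, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("doc_id\ttype\tchar_start\tchar_end\ttext\n")
        for m in mentions:
            fh.write(f"{m.doc_id}\t{m.type}\t{m.char_start}\t{m.char_end}\t{m.text}\n")


def run_pipeline(
    config: PipelineConfig,
    documents: list[Document] | None = None,
    truth: SyntheticCorpus | None = None,
) -> PipelineResult:
    """Run the full discovery pipeline and emit per-stage artifacts.

    Without explicit ``documents``, the synthetic generator supplies the
    corpus, training split, lexicons and publication table (the
    self-contained reproducible mode); a trained CRF tags the articles, the
    three rules keep subject experts, the normalizer maps mentions to
    individuals, and the co-mention network is ranked by mention frequency
    plus the four centralities.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if documents is None:
        gen_cfg = dataclasses.replace(config.generator, seed=config.seed)
        truth = generate_corpus(gen_cfg)
        documents = truth.documents
    if truth is None:
        raise PipelineError(
            "external corpora need an accompanying SyntheticCorpus-style "
            "bundle providing lexicons, training data and publication counts"
        )
    lexicons = truth.lexicons
    provider = truth.pub_provider

    stage = "train"
    try:
        model, stats = ner_crf.train_crf(
            truth.train_sentences,
            lexicons=lexicons,
            l2_variance=config.crf_l2_variance,
            max_iter=config.crf_max_iter,
        )
        model.save(out / "model.crf")

        stage = "tag"
        mentions = []
        for doc in documents:
            mentions.extend(ner_crf.tag_document(doc, model, lexicons))
        _write_mentions_tsv(mentions, out / "mentions.tsv")

        stage = "filter"
        by_doc: dict[str, list] = {}
        for m in mentions:
            by_doc.setdefault(m.doc_id, []).append(m)
        doc_text = {d.doc_id: d.text for d in documents}
        experts = []
        for doc_id in sorted(by_doc):
            experts.extend(
                expert_filter.filter_experts(
                    by_doc[doc_id],
                    doc_text[doc_id],
                    provider,
                    window=config.keyword_window,
                    min_count=config.min_publications,
                )
            )
        with open(out / "experts.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("doc_id\tchar_start\tchar_end\ttext\tkeyword\tgap\tpubs\n")
            for em in experts:
                fh.write(
                    f"{em.doc_id}\t{em.char_start}\t{em.char_end}\t{em.text}\t"
                    f"{em.keyword}\t{em.keyword_gap}\t{em.publication_count}\n"
                )

        stage = "normalize"
        records = name_normalizer.build_records(
            experts, by_doc, documents={d.doc_id: d for d in documents}
        )
        clusters = name_normalizer.cluster_mentions(
            records,
            theta_name=config.theta_name,
            require_context=config.require_context,
        )
        with open(out / "persons.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write("person_id\tcanonical_name\taliases\tmention_count\tdoc_ids\n")
            for c in clusters:
                fh.write(
                    f"{c.person_id}\t{c.canonical_name}\t{'|'.join(c.aliases)}\t"
                    f"{c.mention_count}\t{'|'.join(c.doc_ids)}\n"
                )

        stage = "network"
        article_persons: dict[str, set] = {}
        for c in clusters:
            for rec in c.members:
                article_persons.setdefault(rec.doc_id, set()).add(c.person_id)
        graph = comention_sna.build_graph(article_persons)
        with open(out / "edges.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"{u}\t{v}\n")
        counts = {c.person_id: c.mention_count for c in clusters}
        table = comention_sna.centrality_table(
            graph, counts, use_global_n=config.use_global_n
        )

        stage = "rank"
        ranking = comention_sna.rank_experts(table, k=config.top_k)
        with open(out / "ranking.tsv", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(
                "person_id\tmentions\tc_deg\tc_btw\tc_clo\tc_eig\t"
                "qualifying_metrics\n"
            )
            for pid, row in ranking.table.iterrows():
                quals = ",".join(ranking.qualifying.get(pid, []))
                fh.write(
                    f"{pid}\t{int(row['mentions'])}\t{row['c_deg']:.10g}\t"
                    f"{row['c_btw']:.10g}\t{row['c_clo']:.10g}\t"
                    f"{row['c_eig']:.10g}\t{quals}\n"
                )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    components = comention_sna.connected_components(graph)
    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k != "generator"},
            "generator": dataclasses.asdict(config.generator),
        },
        "counts": {
            "documents": len(documents),
            "person_mentions": sum(1 for m in mentions if m.type == "person"),
            "organization_mentions": sum(
                1 for m in mentions if m.type == "organization"),
            "location_mentions": sum(
                1 for m in mentions if m.type == "location"),
            "expert_mentions": len(experts),
            "unique_individuals": len(clusters),
            "edges": graph.number_of_edges(),
            "components": len(components),
            "largest_component": len(components[0]) if components else 0,
        },
        "training": {"iterations": stats.iterations,
                     "final_objective": stats.final_objective},
        "digests": {},
    }
    for name in ("model.crf", "mentions.tsv", "experts.tsv", "persons.tsv",
                 "edges.tsv", "ranking.tsv"):
        manifest["digests"][name] = _sha256(out / name)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return PipelineResult(
        out_dir=out, manifest=manifest, mentions=mentions, experts=experts,
        clusters=clusters, graph=graph, table=table, ranking=ranking,
        truth=truth, model=model,
    )
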