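"""End-to-end pipeline orchestration.

Stages run in a fixed order, each computing over the annotations of the
previous ones: zoning → tokenisation → POS tagging → lemmatisation →
entity recognition → chunking → noun-group negation → hedge negation →
verbal negation → relation extraction → labelling.  The pipeline is a
pure function of (text, config): repeated runs produce byte-identical
output.  In batch mode a report that violates a stage contract is
logged and skipped; the rest of the batch continues.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import chunk_negation, labeller, linguistic, ner, zoner
from .model import ReportDocument, read_report, validate_document
from .relations import apply_verbal_negation, extract_relations

__all__ = ["PipelineConfig", "PipelineError", "annotate", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage contract violation while annotating one report."""


@dataclass
class PipelineConfig:
    """Declarative configuration: every resource defaults to the shipped one."""

    obs_lexicon: Optional[Path] = None
    mod_lexicon: Optional[Path] = None
    cue_file: Optional[Path] = None
    header_file: Optional[Path] = None
    label_rules_file: Optional[Path] = None

    _loaded: dict = field(default_factory=dict, repr=False)

    def resources(self) -> dict:
        """Load (and cache) lexicons, cues, headers and the rule table."""
        if not self._loaded:
            obs, mods = ner.load_lexicons(self.obs_lexicon, self.mod_lexicon)
            negation_cues, hedge_patterns = chunk_negation.load_cues(self.cue_file)
            headers = (zoner.load_header_config(self.header_file)
                       if self.header_file else None)
            rules = labeller.load_label_rules(self.label_rules_file)
            self._loaded = {
                "observations": obs,
                "modifiers": mods,
                "negation_cues": negation_cues,
                "hedge_patterns": hedge_patterns,
                "headers": headers,
                "label_rules": rules,
            }
        return self._loaded


_STAGES = (
    "zone", "tokenize", "pos_tag", "lemmatise", "ner", "chunk",
    "ng_negation", "hedge_negation", "verbal_negation", "relations",
    "labels",
)


def annotate(text: str, report_id: str = "report",
             config: Optional[PipelineConfig] = None) -> ReportDocument:
    """Run the full pipeline over one report text."""
    config = config or PipelineConfig()
    res = config.resources()
    doc = read_report(text, report_id=report_id)
    timings: dict[str, float] = {}

    def run(stage: str, fn) -> None:
        t0 = time.perf_counter()
        fn()
        timings[stage] = time.perf_counter() - t0

    run("zone", lambda: zoner.zone(doc, res["headers"]))
    run("tokenize", lambda: linguistic.tokenize(doc))
    run("pos_tag", lambda: linguistic.pos_tag(doc))
    run("lemmatise", lambda: linguistic.lemmatise(doc))
    run("ner", lambda: ner.match_entities(doc, res["observations"],
                                          res["modifiers"]))
    run("chunk", lambda: chunk_negation.chunk(doc))
    run("ng_negation", lambda: chunk_negation.apply_noun_group_negation(
        doc, res["negation_cues"]))
    run("hedge_negation", lambda: chunk_negation.apply_hedge_negation(
        doc, res["hedge_patterns"]))
    run("verbal_negation", lambda: apply_verbal_negation(doc))
    run("relations", lambda: extract_relations(doc))
    run("labels", lambda: labeller.assign_labels(doc, res["label_rules"]))
    validate_document(doc)
    logger.debug("report %s: stage timings %s", report_id,
                 {k: f"{v * 1e3:.2f}ms" for k, v in timings.items()})
    return doc


def run_pipeline(
    texts: Iterable[tuple[str, str]] | Sequence[str],
    config: Optional[PipelineConfig] = None,
) -> list[ReportDocument]:
    """Annotate a batch, preserving input order.

    ``texts`` is an iterable of (report_id, text) pairs, or of bare
    strings (ids are then assigned positionally).  A report that fails a
    stage is logged and skipped.
    """
    config = config or PipelineConfig()
    docs: list[ReportDocument] = []
    for i, item in enumerate(texts):
        if isinstance(item, str):
            report_id, text = f"report-{i:04d}", item
        else:
            report_id, text = item
        try:
            docs.append(annotate(text, report_id=report_id, config=config))
        except Exception as exc:  # contract violation: skip, keep the batch
            logger.error("report %s aborted: %s", report_id, exc)
    return docs
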