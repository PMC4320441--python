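"""End-to-end funnel orchestration and the recorded-annotation replay mode.

Stages, in order: build inclusion/exclusion pairs -> translate and diff ->
domain impact -> GO/domain token-overlap filter -> pathway enrichment over
the genes that pass the filter.  Per-event failures are logged with reason
codes and excluded from downstream counts, never fatal.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from . import domains as dom
from . import enrichment as enr
from . import io as sio
from . import isoforms, proteins, textmatch
from .models import (
    AltExonEvent,
    DomainHit,
    EnrichmentResult,
    FunnelReport,
    GeneAnnotationSet,
    ImpactRecord,
    PathwayCollection,
    TranscriptModel,
    normalize_symbol,
)

log = logging.getLogger(__name__)


def _domain_index(hits: Sequence[DomainHit]) -> Dict[str, List[DomainHit]]:
    index: Dict[str, List[DomainHit]] = {}
    for h in hits:
        index.setdefault(normalize_symbol(h.protein_key), []).append(h)
    return index


def annotate_event(
    event: AltExonEvent,
    transcripts: Sequence[TranscriptModel],
    transcripts_by_id: Dict[str, TranscriptModel],
    genome,
    domain_index: Dict[str, List[DomainHit]],
) -> ImpactRecord:
    """Run one event through pair building, translation, diff and domain calls."""
    host = isoforms.pick_host(event, transcripts)
    pair = isoforms.build_pair(event, host, transcripts_by_id)
    record = ImpactRecord(event=event)
    record.region_class = isoforms.classify_region(event, pair)

    p_incl = proteins.translate(pair.inclusion, genome)
    p_excl = proteins.translate(pair.exclusion, genome)
    record.coding_status_incl = p_incl.coding_status
    record.coding_status_excl = p_excl.coding_status
    diff = proteins.diff(p_incl, p_excl)
    record.diff = diff
    record.protein_changed = diff.protein_changed

    hits = (
        domain_index.get(normalize_symbol(event.gene_symbol), [])
        + domain_index.get(normalize_symbol(pair.inclusion.transcript_id), [])
    )
    if hits and len(p_incl):
        statuses, changed, affected = dom.classify_impact(hits, diff)
        record.domain_statuses = statuses
        record.domain_changed = changed
        record.affected_region = affected
    elif diff.protein_changed:
        _, _, affected = dom.classify_impact([], diff)
        record.affected_region = affected
    return record


def apply_overlap_filter(
    records: Iterable[ImpactRecord],
    annotations: GeneAnnotationSet,
    stopwords=None,
) -> None:
    """Fill overlap tokens / pass flag on every domain-changed record in place."""
    stopwords = textmatch.load_stopwords() if stopwords is None else stopwords
    for record in records:
        if not record.domain_changed:
            continue
        descriptions = [
            s.domain.description
            for s in record.domain_statuses
            if s.status != "intact"
        ]
        terms = annotations.terms_for(record.event.gene_symbol)
        if not terms:
            log.warning(
                "%s: gene %s absent from GO annotations; overlap filter fails",
                record.event.probeset_id,
                record.event.gene_symbol,
            )
            record.overlap_tokens, record.passes_overlap_filter = set(), False
            continue
        shared, passes = textmatch.overlap_filter(descriptions, terms, stopwords)
        record.overlap_tokens = shared
        record.passes_overlap_filter = passes


def summarize(
    records: Sequence[ImpactRecord],
    n_failed: int = 0,
    failure_reasons: Optional[Dict[str, int]] = None,
    top_pathway: Optional[EnrichmentResult] = None,
) -> FunnelReport:
    breakdown: Dict[str, int] = {}
    for r in records:
        breakdown[r.region_class] = breakdown.get(r.region_class, 0) + 1
    passing = [r for r in records if r.passes_overlap_filter]
    return FunnelReport(
        n_events=len(records) + n_failed,
        n_failed=n_failed,
        n_protein_changed=sum(r.protein_changed for r in records),
        n_domain_changed=sum(r.domain_changed for r in records),
        n_overlap_probesets=len(passing),
        n_overlap_genes=len(
            {normalize_symbol(r.event.gene_symbol) for r in passing}
        ),
        region_class_breakdown=breakdown,
        top_pathway=top_pathway,
        failure_reasons=failure_reasons or {},
    )


def run(config) -> Tuple[FunnelReport, List[ImpactRecord], List[EnrichmentResult]]:
    """Execute the full funnel from a config mapping or YAML path.

    Config keys: genome, gtf, events, domains, go, gmt (paths); out_dir
    (optional: write impact.tsv / enrichment.tsv / funnel.tsv there);
    stopwords (optional path), p_threshold (default 0.01), bh (default off).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    genome = sio.read_genome(config["genome"])
    transcripts = sio.read_transcripts(config["gtf"])
    events = sio.read_events(config["events"])
    domain_hits = sio.read_domains(config["domains"])
    annotations = sio.read_go(config["go"])
    pathways = sio.read_gmt(config["gmt"]) if config.get("gmt") else None
    stopwords = (
        textmatch.load_stopwords(config["stopwords"])
        if config.get("stopwords")
        else textmatch.load_stopwords()
    )
    p_threshold = float(config.get("p_threshold", enr.DEFAULT_P_THRESHOLD))
    bh = bool(config.get("bh", False))

    by_id = {t.transcript_id: t for t in transcripts}
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(normalize_symbol(t.gene_symbol), []).append(t)
    domain_index = _domain_index(domain_hits)

    records: List[ImpactRecord] = []
    failures: Dict[str, int] = {}
    for event in events:
        try:
            records.append(
                annotate_event(event, transcripts, by_id, genome, domain_index)
            )
        except isoforms.PairBuildError as exc:
            log.warning("%s: %s", event.probeset_id, exc)
            failures["PAIR_BUILD_ERROR"] = failures.get("PAIR_BUILD_ERROR", 0) + 1
        except ValueError as exc:
            log.warning("%s: %s", event.probeset_id, exc)
            failures["ANNOTATION_ERROR"] = failures.get("ANNOTATION_ERROR", 0) + 1
    log.info("annotated %d/%d events", len(records), len(events))

    apply_overlap_filter(records, annotations, stopwords)
    passing_genes = {
        normalize_symbol(r.event.gene_symbol)
        for r in records
        if r.passes_overlap_filter
    }

    results: List[EnrichmentResult] = []
    if pathways is not None and passing_genes:
        universe = annotations.genes() or {
            normalize_symbol(t.gene_symbol) for t in transcripts
        }
        results = enr.enrich(
            passing_genes, pathways, universe, p_threshold=p_threshold, bh_correct=bh
        )
    report = summarize(
        records,
        n_failed=sum(failures.values()),
        failure_reasons=failures,
        top_pathway=results[0] if results else None,
    )

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_impact_table(out / "impact.tsv", records)
        write_enrichment_table(out / "enrichment.tsv", results)
        write_funnel(out / "funnel.tsv", report)
    return report, records, results


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------


def impact_frame(records: Sequence[ImpactRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = r.diff
        rows.append(
            {
                "probeset_id": r.event.probeset_id,
                "gene_symbol": r.event.gene_symbol,
                "event_class": r.event.event_class,
                "region_class": r.region_class,
                "protein_changed": r.protein_changed,
                "domain_changed": r.domain_changed,
                "affected_region": r.affected_region,
                "n_altered": d.n_altered if d else 0,
                "frac_altered": round(d.frac_altered, 6) if d else 0.0,
                "len_incl": d.len_incl if d else 0,
                "len_excl": d.len_excl if d else 0,
                "coding_status_incl": r.coding_status_incl,
                "coding_status_excl": r.coding_status_excl,
                "domain_statuses": ";".join(
                    f"{s.domain.accession}:{s.status}" for s in r.domain_statuses
                ),
                "overlap_tokens": ",".join(sorted(r.overlap_tokens)),
                "passes_overlap_filter": r.passes_overlap_filter,
                "SI": r.event.SI,
                "FC": r.event.FC,
            }
        )
    return pd.DataFrame(rows)


def write_impact_table(path, records: Sequence[ImpactRecord]) -> None:
    impact_frame(records).to_csv(path, sep="\t", index=False)


def write_enrichment_table(path, results: Sequence[EnrichmentResult]) -> None:
    rows = [
        {
            "pathway_id": r.pathway_id,
            "name": r.name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p_value": f"{r.p_value:.6g}",
            "significant": r.significant,
            "members": ",".join(r.members),
        }
        for r in results
    ]
    pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "name",
            "k",
            "K",
            "n",
            "N",
            "p_value",
            "significant",
            "members",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_funnel(path, report: FunnelReport) -> None:
    rows = [
        ("events", report.n_events),
        ("failed", report.n_failed),
        ("protein_changed", report.n_protein_changed),
        ("domain_changed", report.n_domain_changed),
        ("overlap_probesets", report.n_overlap_probesets),
        ("overlap_genes", report.n_overlap_genes),
    ]
    for cls in sorted(report.region_class_breakdown):
        rows.append((f"region_{cls}", report.region_class_breakdown[cls]))
    if report.top_pathway is not None:
        rows.append(("top_pathway", report.top_pathway.pathway_id))
        rows.append(("top_pathway_p", f"{report.top_pathway.p_value:.6g}"))
    pd.DataFrame(rows, columns=["stage", "count"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# replay of a recorded annotation table
# ---------------------------------------------------------------------------

_REPLAY_ALIASES = {
    "probeset_id": ("probeset_id", "probeset", "probeset_seq", "probe_set"),
    "gene_symbol": ("gene_symbol", "gene", "symbol", "gene_name"),
    "protein_changed": (
        "protein_changed",
        "aa_change",
        "amino_acid_change",
        "protein_change",
    ),
    "domain_changed": ("domain_changed", "domain_change", "domain_altered"),
    "passes_overlap_filter": (
        "passes_overlap_filter",
        "overlap",
        "overlap_pass",
        "filter",
        "selected",
    ),
}

_TRUTHY = {"yes", "y", "true", "1", "changed", "pass", "selected"}


def _truthy(value) -> bool:
    return str(value).strip().lower() in _TRUTHY


def replay_table_s2(path) -> FunnelReport:
    """Reproduce funnel counts from a table of recorded per-row annotations.

    Nothing is recomputed: the table's own flags (did the event change the
    protein / a domain / pass the description-GO overlap filter) are simply
    aggregated, which is how published funnel counts tied to a specific
    annotation snapshot are reproduced.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower().strip(): c for c in df.columns}
    resolved = {}
    for logical, aliases in _REPLAY_ALIASES.items():
        col = next((lower[a] for a in aliases if a in lower), None)
        if col is None:
            raise sio.FormatError(
                f"{path}: no column for {logical!r} "
                f"(aliases: {', '.join(aliases)}); found: {', '.join(df.columns)}"
            )
        resolved[logical] = col

    protein = df[resolved["protein_changed"]].map(_truthy)
    domain = df[resolved["domain_changed"]].map(_truthy)
    passes = df[resolved["passes_overlap_filter"]].map(_truthy)
    genes = df[resolved["gene_symbol"]].map(normalize_symbol)

    breakdown: Dict[str, int] = {}
    if "region_class" in lower:
        breakdown = (
            df[lower["region_class"]].str.strip().str.lower().value_counts().to_dict()
        )
    return FunnelReport(
        n_events=len(df),
        n_protein_changed=int(protein.sum()),
        n_domain_changed=int(domain.sum()),
        n_overlap_probesets=int(passes.sum()),
        n_overlap_genes=int(genes[passes].nunique()),
        region_class_breakdown=breakdown,
    )
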