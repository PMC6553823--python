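"""End-to-end run orchestration, editability summaries, and output writers.

Every input request ends up in exactly one of two places: the guide library
(>= 1 candidate designed) or the unreachable report (with a reason code).
Identical (inputs, config, seed) produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import GuideCandidate, UnreachableRequest, design_guides_for_request
from .genome import CoordinateError, GenomeBundle, ValidationError, load_genome
from .mutations import MutationRequest, parse_mutation_table, validate_request
from .offtarget import find_alignments
from .registry import RunConfig
from .scoring import PenaltyModel, ScoreBreakdown, default_penalty_model, score_guide

__all__ = [
    "PipelineResult",
    "EditabilitySummary",
    "run_pipeline",
    "summarize_editability",
    "write_outputs",
    "library_to_frame",
]

LIBRARY_COLUMNS = [
    "guide_id",
    "request_id",
    "editor",
    "pam",
    "chromosome",
    "protospacer_start",
    "protospacer_end",
    "strand",
    "spacer",
    "pam_observed",
    "edited_offset",
    "in_window",
    "bystander_offsets",
    "polyT_length",
]
SCORING_COLUMNS = ["n_offtargets", "guide_score", "A_applied", "min_Pa", "worst_region"]

STAGES = ("parse", "design", "offtarget", "score")


@dataclass
class EditabilitySummary:
    """Per-substitution and overall editability statistics.

    ``pct_editability`` is 100 x (requests with >= 1 designed guide) /
    (requests submitted); ``strands_covered`` marks whether guides exist on
    +, -, or both strands for the substitution.
    """

    table: pd.DataFrame
    n_requests: int
    n_editable: int
    pct_editability: float
    guides_per_mutation: float


@dataclass
class PipelineResult:
    config: RunConfig
    requests: list[MutationRequest]
    rejects: pd.DataFrame
    unreachable: list[UnreachableRequest]
    guides: list[GuideCandidate]
    alignments: dict[str, list] = field(default_factory=dict)
    breakdowns: dict[str, ScoreBreakdown] = field(default_factory=dict)
    summary: EditabilitySummary | None = None
    log: list[str] = field(default_factory=list)
    stopped_after: str | None = None


def _config_hash(cfg: RunConfig) -> str:
    # hash covers the design parameters, not where the input files live
    d = cfg.to_yaml_dict()
    for key in ("genome_fasta", "annotation_gff", "mutation_table"):
        d.pop(key, None)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(
    cfg: RunConfig,
    genome: GenomeBundle | None = None,
    stop_after: str | None = None,
) -> PipelineResult:
    """parse -> validate -> design -> off-target -> score -> summarize.

    ``stop_after`` truncates the run after the named stage (partial-step
    execution).  A pre-loaded genome bundle may be passed to skip file I/O.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(f"unknown stage {stop_after!r}")
    if genome is None:
        genome = load_genome(cfg.genome_fasta, cfg.annotation_gff)
    model = cfg.penalty_model or default_penalty_model()

    result = PipelineResult(cfg, [], pd.DataFrame(), [], [])
    log = result.log
    log.append(f"version={__version__}")
    log.append(f"seed={cfg.random_seed}")
    log.append(f"config_hash={_config_hash(cfg)}")

    requests, rejects = parse_mutation_table(cfg.mutation_table, cfg)
    result.requests, result.rejects = requests, rejects
    log.append(f"stage=parse requests={len(requests)} rejects={len(rejects)}")
    if stop_after == "parse":
        result.stopped_after = "parse"
        return result

    validated: list[MutationRequest] = []
    for req in requests:
        try:
            validated.append(validate_request(req, genome))
        except (ValidationError, CoordinateError) as exc:
            result.unreachable.append(UnreachableRequest(req.request_id, str(exc)))
    log.append(f"stage=validate ok={len(validated)} failed={len(result.unreachable)}")

    guides: list[GuideCandidate] = []
    for req in validated:
        designed = design_guides_for_request(req, genome, cfg)
        if isinstance(designed, UnreachableRequest):
            result.unreachable.append(designed)
        else:
            guides.extend(designed)
    result.guides = guides
    log.append(f"stage=design guides={len(guides)} unreachable={len(result.unreachable)}")
    if stop_after == "design":
        result.guides = _ordered(guides)
        result.stopped_after = "design"
        result.summary = summarize_editability(requests, result.guides)
        return result

    pam_by_name = {p.name: p for p in cfg.pams}
    for g in guides:
        result.alignments[g.guide_id] = find_alignments(
            genome, g, pam_by_name[g.pam_name], cfg.max_mismatches
        )
    n_aln = sum(len(a) for a in result.alignments.values())
    log.append(f"stage=offtarget alignments={n_aln}")
    if stop_after == "offtarget":
        result.guides = _ordered(guides)
        result.stopped_after = "offtarget"
        result.summary = summarize_editability(requests, result.guides)
        return result

    scored: list[GuideCandidate] = []
    for g in guides:
        pam = pam_by_name[g.pam_name]
        bd = score_guide(g, result.alignments[g.guide_id], model, cfg.guide_length, pam.side)
        result.breakdowns[g.guide_id] = bd
        scored.append(_with_score(g, bd.B))
    result.guides = _ordered(scored)
    log.append("stage=score done")

    result.summary = summarize_editability(requests, result.guides)
    result.stopped_after = stop_after
    return result


def _with_score(g: GuideCandidate, score: float) -> GuideCandidate:
    from dataclasses import replace

    return replace(g, guide_score=score)


def _ordered(guides: list[GuideCandidate]) -> list[GuideCandidate]:
    """Deterministic library order: request, score desc, coordinate, + first."""
    return sorted(
        guides,
        key=lambda g: (
            g.request_id,
            -(g.guide_score if g.guide_score is not None else 0.0),
            g.chromosome,
            g.protospacer_start,
            0 if g.strand == "+" else 1,
            g.guide_id,
        ),
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_editability(
    requests: list[MutationRequest], library: list[GuideCandidate]
) -> EditabilitySummary:
    """Editability per substitution pair and overall.

    A request is editable iff at least one guide was designed for it.
    Substitutions absent from the input do not appear in the table (they
    would be the grey cells of a substitution map).
    """
    by_request: dict[str, list[GuideCandidate]] = {}
    for g in library:
        by_request.setdefault(g.request_id, []).append(g)

    rows = []
    pairs: dict[tuple[str, str], dict] = {}
    for req in requests:
        key = req.substitution
        rec = pairs.setdefault(
            key, {"n_requested": 0, "n_editable": 0, "strands": set()}
        )
        rec["n_requested"] += 1
        guides = by_request.get(req.request_id, [])
        if guides:
            rec["n_editable"] += 1
            rec["strands"].update(g.strand for g in guides)
    for (frm, to), rec in sorted(pairs.items()):
        strands = rec["strands"]
        mark = "±" if strands == {"+", "-"} else ("+" if strands == {"+"} else ("-" if strands else ""))
        rows.append(
            {
                "from_symbol": frm,
                "to_symbol": to,
                "n_requested": rec["n_requested"],
                "n_editable": rec["n_editable"],
                "pct_editability": round(100.0 * rec["n_editable"] / rec["n_requested"], 4),
                "strands_covered": mark,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "from_symbol",
            "to_symbol",
            "n_requested",
            "n_editable",
            "pct_editability",
            "strands_covered",
        ],
    )
    n_requests = len(requests)
    n_editable = sum(1 for r in requests if by_request.get(r.request_id))
    counts = [len(by_request[r.request_id]) for r in requests if by_request.get(r.request_id)]
    return EditabilitySummary(
        table=table,
        n_requests=n_requests,
        n_editable=n_editable,
        pct_editability=(100.0 * n_editable / n_requests) if n_requests else 0.0,
        guides_per_mutation=(sum(counts) / len(counts)) if counts else 0.0,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def library_to_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    with_scores = result.stopped_after in (None, "score")
    for g in result.guides:
        row = {
            "guide_id": g.guide_id,
            "request_id": g.request_id,
            "editor": g.editor_name,
            "pam": g.pam_name,
            "chromosome": g.chromosome,
            "protospacer_start": g.protospacer_start,
            "protospacer_end": g.protospacer_end,
            "strand": g.strand,
            "spacer": g.spacer,
            "pam_observed": g.pam_observed,
            "edited_offset": g.edited_offset,
            "in_window": g.in_window,
            "bystander_offsets": ",".join(map(str, g.bystander_offsets)),
            "polyT_length": g.polyT_length,
        }
        if with_scores and g.guide_id in result.breakdowns:
            bd = result.breakdowns[g.guide_id]
            pas = [pa for _, pa, _ in bd.per_alignment]
            regions = [a.region for a, _, _ in bd.per_alignment]
            row.update(
                {
                    "n_offtargets": bd.n_alignments,
                    "guide_score": bd.B,
                    "A_applied": bd.A_applied,
                    "min_Pa": min(pas) if pas else 1.0,
                    "worst_region": "genic" if "genic" in regions else (
                        "intergenic" if regions else ""
                    ),
                }
            )
        rows.append(row)
    cols = LIBRARY_COLUMNS + (SCORING_COLUMNS if with_scores else [])
    return pd.DataFrame(rows, columns=cols)


def _provenance(result: PipelineResult) -> str:
    return (
        f"#tool=bedesign {__version__}\n"
        f"#seed={result.config.random_seed}\n"
        f"#config_hash={_config_hash(result.config)}\n"
    )


def write_outputs(
    result: PipelineResult,
    outdir: str | Path,
    write_bed: bool = False,
    write_alignments: bool = False,
) -> dict[str, Path]:
    """Write library, summary, unreachable, rejects (+ optional BED6 and
    alignment dump) under ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    lib = library_to_frame(result)
    paths["library"] = outdir / "library.tsv"
    with open(paths["library"], "w") as fh:
        fh.write(_provenance(result))
        lib.to_csv(fh, sep="\t", index=False)

    if result.summary is not None:
        s = result.summary
        paths["summary"] = outdir / "summary.tsv"
        with open(paths["summary"], "w") as fh:
            fh.write(_provenance(result))
            s.table.to_csv(fh, sep="\t", index=False)
            fh.write(
                f"overall\t\t{s.n_requests}\t{s.n_editable}\t"
                f"{round(s.pct_editability, 4)}\t\n"
            )
            fh.write(f"#guides_per_mutation={round(s.guides_per_mutation, 4)}\n")

    paths["unreachable"] = outdir / "unreachable.tsv"
    with open(paths["unreachable"], "w") as fh:
        fh.write(_provenance(result))
        pd.DataFrame(
            [{"request_id": u.request_id, "reason": u.reason} for u in result.unreachable],
            columns=["request_id", "reason"],
        ).to_csv(fh, sep="\t", index=False)

    paths["rejects"] = outdir / "rejects.tsv"
    with open(paths["rejects"], "w") as fh:
        fh.write(_provenance(result))
        result.rejects.to_csv(fh, sep="\t", index=False)

    paths["log"] = outdir / "run.log"
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(result.log) + "\n")

    if write_bed:
        paths["bed"] = outdir / "protospacers.bed"
        with open(paths["bed"], "w") as fh:
            for g in result.guides:
                score = int(round(1000 * (g.guide_score or 0.0)))
                fh.write(
                    f"{g.chromosome}\t{g.protospacer_start - 1}\t{g.protospacer_end}\t"
                    f"{g.guide_id}\t{score}\t{g.strand}\n"
                )
    if write_alignments and result.alignments:
        paths["alignments"] = outdir / "alignments.tsv"
        rows = []
        for gid in sorted(result.alignments):
            for a in result.alignments[gid]:
                rows.append(
                    {
                        "guide_id": gid,
                        "chromosome": a.chromosome,
                        "start": a.start,
                        "end": a.end,
                        "strand": a.strand,
                        "mismatch_offsets": ",".join(map(str, a.mismatch_offsets)),
                        "region": a.region,
                        "is_intended_target": a.is_intended_target,
                    }
                )
        with open(paths["alignments"], "w") as fh:
            fh.write(_provenance(result))
            pd.DataFrame(
                rows,
                columns=[
                    "guide_id",
                    "chromosome",
                    "start",
                    "end",
                    "strand",
                    "mismatch_offsets",
                    "region",
                    "is_intended_target",
                ],
            ).to_csv(fh, sep="\t", index=False)
    return paths
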