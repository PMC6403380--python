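"""End-to-end orchestration: load -> convert -> control -> average -> ANOVA
-> foldability -> critical call -> mutation mapping -> reports.

:func:`run_pipeline` consumes a :class:`PipelineConfig` (buildable from a
YAML file), validates that matrix ids, AFASTA ids and domain annotations
agree, runs the screen and writes every artifact (averaged matrix TSV,
foldability profile TSV, per-domain Chimera attribute files, mutation and
conservation reports, a JSON run summary). Each stage logs one structured
line with its input/output counts so report numbers remain auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .core import (
    DdgMatrix,
    FoldabilityParams,
    TransformConfig,
    UnfoldingMatrix,
    convert_matrix,
)
from .ensemble import AlignedDomainSet, MultidomainScreen, read_afasta
from .exceptions import AlignmentError, MdumsError, ValidationError
from .mutations import (
    annotate_critical,
    assessments_frame,
    classify_conservation,
    conservation_foldability_report,
    map_mutation,
    parse_mutations,
    summarize_protein,
)

logger = logging.getLogger("mdums.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``matrices`` maps domain_id -> matrix TSV path (propensity or ΔΔG
    units; ΔΔG inputs are converted with ``transform`` at load).
    """

    domains_tsv: str
    afasta: str
    matrices: dict[str, str]
    out_dir: str
    mutations: str | None = None
    transform: TransformConfig = field(default_factory=TransformConfig)
    params: FoldabilityParams = field(default_factory=FoldabilityParams)
    min_domains: int = 2
    multiple_testing: str | None = None
    attribute_name: str = "foldability"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        base = Path(path).parent
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))

        def _p(v):  # resolve paths relative to the config file
            return str((base / v)) if v and not Path(v).is_absolute() else v

        return cls(
            domains_tsv=_p(raw["domains_tsv"]),
            afasta=_p(raw["afasta"]),
            matrices={k: _p(v) for k, v in raw["matrices"].items()},
            out_dir=_p(raw.get("out_dir", "mdums_out")),
            mutations=_p(raw.get("mutations")),
            transform=TransformConfig(scale=float(raw.get("transform_scale", 0.593))),
            params=FoldabilityParams(
                severe_threshold=float(raw.get("severe_threshold", 0.9)),
                critical_foldability_threshold=float(
                    raw.get("critical_foldability_threshold", 10.0)
                ),
                critical_p_threshold=float(raw.get("critical_p_threshold", 0.05)),
            ),
            min_domains=int(raw.get("min_domains", 2)),
            multiple_testing=raw.get("multiple_testing"),
            attribute_name=str(raw.get("attribute_name", "foldability")),
        )


@dataclass
class PipelineResult:
    """Artifacts of a completed run (in-memory results plus file paths)."""

    results: object  # ScreenResults
    aligned: AlignedDomainSet
    paths: dict[str, str]
    summary: dict


def _load_matrices(cfg: PipelineConfig, domains) -> dict[str, UnfoldingMatrix]:
    by_id = {d.domain_id: d for d in domains}
    out = {}
    for did, mpath in cfg.matrices.items():
        if did not in by_id:
            raise AlignmentError(f"matrix id {did!r} has no domain annotation")
        m = mio.read_matrix_tsv(mpath, domain=by_id[did])
        if isinstance(m, DdgMatrix):
            m = convert_matrix(m, cfg.transform)
        out[did] = m
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage and write all artifacts under ``cfg.out_dir``.

    Deterministic given inputs and config. Raises a stage-labelled
    :class:`MdumsError` subclass on any validation failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    domains = mio.read_domains_tsv(cfg.domains_tsv)
    logger.info("load: %d domain annotations from %s", len(domains), cfg.domains_tsv)
    afasta = read_afasta(cfg.afasta)
    logger.info("load: %d AFASTA rows (length %d)", len(afasta), len(next(iter(afasta.values()))))
    missing = set(afasta) - set(cfg.matrices)
    if missing:
        raise AlignmentError(f"AFASTA ids without a matrix: {sorted(missing)}")
    matrices = _load_matrices(cfg, domains)
    n_conv = sum(m.provenance == "converted-from-ddg" for m in matrices.values())
    logger.info("convert: %d/%d matrices converted from ΔΔG", n_conv, len(matrices))

    aligned = AlignedDomainSet.from_afasta(afasta, domains, matrices)
    screen = MultidomainScreen(aligned, cfg.params)
    results = screen.fit(min_domains=cfg.min_domains, multiple_testing=cfg.multiple_testing)

    controls = results.internal_controls
    n_pass = sum(1 for c in controls.values() if c is not None and c.passed)
    logger.info("internal-control: %d/%d domains pass", n_pass, len(controls))
    ctl_rows = []
    for did, c in controls.items():
        ctl_rows.append(
            {"domain_id": did}
            | (
                {
                    "n": c.n, "mean": c.mean, "sd": c.sd,
                    "ci_low": c.ci_low, "ci_high": c.ci_high,
                    "p_value": c.p_value, "passed": c.passed,
                }
                if c is not None
                else {"n": 0, "passed": False}
            )
        )
    import pandas as pd

    paths["internal_control"] = str(out / "internal_control.tsv")
    pd.DataFrame(ctl_rows).to_csv(paths["internal_control"], sep="\t", index=False, float_format="%.10g")

    paths["averaged_matrix"] = str(out / "averaged_matrix.tsv")
    results.averaged.to_frame().to_csv(
        paths["averaged_matrix"], sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
    logger.info("average: %d alignment positions", results.averaged.alignment_length)

    prof = results.profile
    paths["profile"] = str(out / "foldability_profile.tsv")
    prof.to_frame().to_csv(paths["profile"], sep="\t", index=False, na_rep="NA", float_format="%.10g")
    crit = prof.critical_positions
    logger.info("critical: %d positions called", len(crit))
    paths["critical_positions"] = str(out / "critical_positions.txt")
    Path(paths["critical_positions"]).write_text(
        "\n".join(str(p) for p in crit) + ("\n" if crit else ""), encoding="utf-8"
    )

    # per-domain Chimera attribute files in protein coordinates
    attr_dir = out / "attributes"
    attr_dir.mkdir(exist_ok=True)
    from .ensemble import map_row_to_positions

    for dom, row in zip(aligned.domains, aligned.rows):
        pos_map = map_row_to_positions(row)
        values = {}
        for a in range(1, prof.alignment_length + 1):
            rpos = pos_map[a - 1]
            if rpos > 0 and not np.isnan(prof.foldability[a - 1]):
                values[dom.residue_number(int(rpos))] = float(prof.foldability[a - 1])
        apath = attr_dir / f"{dom.domain_id}.defattr"
        try:
            mio.write_attribute_file(cfg.attribute_name, values, apath)
            paths[f"attribute:{dom.domain_id}"] = str(apath)
        except ValidationError as exc:
            logger.warning("attribute: skipped %s (%s)", dom.domain_id, exc)

    # conservation vs foldability
    cons = classify_conservation(aligned.rows)
    report = conservation_foldability_report(cons, prof)
    paths["conservation_report"] = str(out / "conservation_report.tsv")
    report.by_class.to_csv(paths["conservation_report"], sep="\t", na_rep="NA", float_format="%.10g")
    paths["conservation_positions"] = str(out / "conservation_positions.tsv")
    report.per_position.to_csv(
        paths["conservation_positions"], sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
    logger.info(
        "conservation: %d conserved / %d nonconserved positions",
        int(cons.conserved_mask().sum()),
        sum(c == "nonconserved" for c in cons.classes),
    )

    summary: dict = {
        "n_domains": aligned.n_domains,
        "alignment_length": prof.alignment_length,
        "n_critical": len(crit),
        "critical_positions": crit,
        "internal_control_pass": n_pass,
    }

    # mutation mapping (optional)
    if cfg.mutations:
        records, errors = parse_mutations(cfg.mutations)
        logger.info("mutations: %d parsed, %d malformed lines", len(records), len(errors))
        if errors:
            paths["mutation_errors"] = str(out / "mutation_errors.txt")
            Path(paths["mutation_errors"]).write_text(
                "\n".join(str(e) for e in errors) + "\n", encoding="utf-8"
            )
        assessments = [map_mutation(r, domains, matrices, cfg.params) for r in records]
        annotate_critical(assessments, prof, aligned)
        paths["mutation_assessments"] = str(out / "mutation_assessments.tsv")
        assessments_frame(assessments).to_csv(
            paths["mutation_assessments"], sep="\t", index=False, na_rep="NA", float_format="%.10g"
        )
        proteins = sorted({r.protein_id for r in records})
        rows = [summarize_protein(assessments, protein_id=p).to_row() for p in proteins]
        paths["protein_summary"] = str(out / "protein_summary.tsv")
        pd.DataFrame(rows).to_csv(
            paths["protein_summary"], sep="\t", index=False, na_rep="NA"
        )
        n_severe = sum(a.severity == "severe" for a in assessments)
        logger.info("mutations: %d/%d severe", n_severe, len(assessments))
        summary["n_mutations"] = len(records)
        summary["n_severe"] = int(n_severe)

    paths["run_summary"] = str(out / "run_summary.json")
    Path(paths["run_summary"]).write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return PipelineResult(results=results, aligned=aligned, paths=paths, summary=summary)
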