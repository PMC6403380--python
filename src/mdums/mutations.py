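"""Missense-variant parsing, domain mapping, severity and conservation.

Variants arrive as plain-text lists ("G123R" or "p.Gly123Arg", one per
line, optionally prefixed by a protein id and a tab). Each variant is
mapped onto the domain covering its protein coordinate, its unfolding
propensity is looked up in that domain's matrix, and a severity class is
assigned: *severe* above 0.9, *medium* in [0.5, 0.9], *low* below 0.5
(the medium/low boundary is configurable). Variants outside every domain
are *unmapped*; mapped variants whose matrix cell is missing are
*unscored*.

The module also classifies alignment columns by conservation (identical /
similar / nonconserved / gap-dominated, using fixed physicochemical
similarity groups) and relates conservation to foldability and critical
calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AA_INDEX, GAP, DomainRecord, FoldabilityParams, UnfoldingMatrix
from .ensemble import AlignedDomainSet, FoldabilityProfile, map_row_to_positions
from .exceptions import ParseError, ValidationError

__all__ = [
    "MutationRecord",
    "MutationAssessment",
    "ProteinSummary",
    "ConservationProfile",
    "SIMILARITY_GROUPS",
    "parse_mutations",
    "map_mutation",
    "summarize_protein",
    "classify_conservation",
    "conservation_foldability_report",
]

#: Physicochemical similarity groups used for the "similarly conserved"
#: class: aliphatic/hydrophobic, aromatic, hydroxyl, basic, acidic, amide,
#: and the three singletons whose substitution is rarely neutral.
SIMILARITY_GROUPS: tuple[str, ...] = ("AVLIM", "FWY", "ST", "KRH", "DE", "NQ", "C", "G", "P")

_GROUP_OF = {aa: grp for grp in SIMILARITY_GROUPS for aa in grp}

_THREE_TO_ONE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F", "Gly": "G",
    "His": "H", "Ile": "I", "Lys": "K", "Leu": "L", "Met": "M", "Asn": "N",
    "Pro": "P", "Gln": "Q", "Arg": "R", "Ser": "S", "Thr": "T", "Val": "V",
    "Trp": "W", "Tyr": "Y",
}

_SHORT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_HGVS_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


@dataclass(frozen=True)
class MutationRecord:
    """One missense variant in protein coordinates (1-based)."""

    protein_id: str
    position: int
    wt_aa: str
    mut_aa: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_INDEX or self.mut_aa not in AA_INDEX:
            raise ValidationError(f"unknown residue code in {self.wt_aa}{self.position}{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise ValidationError(f"identity substitution {self.wt_aa}{self.position}{self.mut_aa}")
        if self.position < 1:
            raise ValidationError("mutation position must be >= 1")

    @property
    def short(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def _parse_variant(token: str) -> tuple[str, int, str]:
    m = _SHORT_RE.match(token)
    if m:
        return m.group(1), int(m.group(2)), m.group(3)
    m = _HGVS_RE.match(token)
    if m:
        wt3, pos, mut3 = m.group(1), int(m.group(2)), m.group(3)
        if wt3 not in _THREE_TO_ONE or mut3 not in _THREE_TO_ONE:
            raise ValueError(f"unknown three-letter residue code in {token!r}")
        return _THREE_TO_ONE[wt3], pos, _THREE_TO_ONE[mut3]
    raise ValueError(f"unrecognised variant syntax {token!r}")


def parse_mutations(
    source, default_protein: str = "", label: str = ""
) -> tuple[list[MutationRecord], list[ParseError]]:
    """Parse a variant list into records plus an error report.

    ``source`` is a path or an iterable of lines. Each non-empty,
    non-comment line is either ``<variant>`` or ``<protein_id>\t<variant>``
    with the variant in short ("G123R") or HGVS-protein ("p.Gly123Arg")
    form. Malformed lines (bad syntax, unknown residue codes, identity
    substitutions) are collected as :class:`ParseError` entries with their
    line numbers — never silently dropped.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)

    records: list[MutationRecord] = []
    errors: list[ParseError] = []
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            protein, token = default_protein, parts[0].strip()
        elif len(parts) == 2:
            protein, token = parts[0].strip(), parts[1].strip()
        else:
            errors.append(ParseError(f"expected 1 or 2 tab-separated fields, got {len(parts)}", i))
            continue
        try:
            wt, pos, mut = _parse_variant(token)
            records.append(MutationRecord(protein, pos, wt, mut, source=label))
        except (ValueError, ValidationError) as exc:
            errors.append(ParseError(str(exc), i))
    return records, errors


@dataclass
class MutationAssessment:
    """A variant mapped (or not) to a domain matrix cell.

    ``severity`` partitions every assessed variant into exactly one of
    severe / medium / low / unmapped / unscored; ``valid`` is False when
    the annotated wild type disagrees with the domain sequence (a
    coordinate error, reported but kept for auditing).
    """

    record: MutationRecord
    mapped_domain: DomainRecord | None
    domain_position: int | None
    propensity: float
    severity: str
    in_critical: bool | None = None
    valid: bool = True
    note: str = ""


def _severity(prop: float, severe_threshold: float, medium_floor: float) -> str:
    if np.isnan(prop):
        return "unscored"
    if prop > severe_threshold:
        return "severe"
    if prop >= medium_floor:
        return "medium"
    return "low"


def map_mutation(
    rec: MutationRecord,
    domains: list[DomainRecord],
    matrices: dict[str, UnfoldingMatrix],
    params: FoldabilityParams = FoldabilityParams(),
    medium_floor: float = 0.5,
) -> MutationAssessment:
    """Map one variant onto its covering domain and classify severity.

    Domains of other proteins are ignored; overlapping domain annotations
    for one protein are rejected. A variant whose position falls outside
    every domain is *unmapped* (excluded from stability statistics). The
    annotated wild type is cross-checked against the domain sequence; a
    mismatch marks the assessment invalid.
    """
    mine = sorted(
        (d for d in domains if d.protein_id == rec.protein_id), key=lambda d: d.start
    )
    for d1, d2 in zip(mine, mine[1:]):
        if d2.start <= d1.end:
            raise ValidationError(
                f"overlapping domain annotations for {rec.protein_id}: "
                f"{d1.domain_id} and {d2.domain_id}"
            )
    covering = next((d for d in mine if d.start <= rec.position <= d.end), None)
    if covering is None:
        return MutationAssessment(rec, None, None, float("nan"), "unmapped")

    dpos = rec.position - covering.start + 1
    expected_wt = covering.sequence[dpos - 1]
    if expected_wt != rec.wt_aa:
        return MutationAssessment(
            rec,
            covering,
            dpos,
            float("nan"),
            "unscored",
            valid=False,
            note=f"wild type mismatch: annotation says {rec.wt_aa}, domain sequence has {expected_wt}",
        )
    m = matrices.get(covering.domain_id)
    if m is None:
        return MutationAssessment(rec, covering, dpos, float("nan"), "unscored", note="no matrix")
    prop = float(m.values[dpos - 1, AA_INDEX[rec.mut_aa]])
    return MutationAssessment(
        rec, covering, dpos, prop, _severity(prop, params.severe_threshold, medium_floor)
    )


def _alignment_position(aligned: AlignedDomainSet, domain_id: str, domain_position: int) -> int | None:
    """Alignment column (1-based) of a residue of one domain, or None."""
    for dom, row in zip(aligned.domains, aligned.rows):
        if dom.domain_id == domain_id:
            pos_map = map_row_to_positions(row)
            hits = np.flatnonzero(pos_map == domain_position)
            return int(hits[0]) + 1 if hits.size else None
    return None


def annotate_critical(
    assessments: list[MutationAssessment],
    profile: FoldabilityProfile,
    aligned: AlignedDomainSet,
) -> None:
    """Fill ``in_critical`` on mapped assessments from the fitted profile."""
    critical = set(profile.critical_positions)
    for a in assessments:
        if a.mapped_domain is None or a.domain_position is None:
            continue
        col = _alignment_position(aligned, a.mapped_domain.domain_id, a.domain_position)
        a.in_critical = (col in critical) if col is not None else None


@dataclass(frozen=True)
class ProteinSummary:
    """Per-protein roll-up of mutation assessments (mirrors a per-protein
    row of the screen's mutation report)."""

    protein_id: str
    n_retrieved: int
    n_mapped: int
    mean_propensity: float
    sd_propensity: float
    n_severe: int
    percent_severe: float
    n_severe_in_critical: int
    percent_severe_in_critical: float
    empty: bool = False

    def to_row(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "n_retrieved": self.n_retrieved,
            "n_mapped": self.n_mapped,
            "mean_unfolding": round(self.mean_propensity, 4) if not self.empty else float("nan"),
            "sd_unfolding": round(self.sd_propensity, 4) if not self.empty else float("nan"),
            "n_severe": self.n_severe,
            "percent_severe": round(self.percent_severe, 1),
            "n_severe_in_critical": self.n_severe_in_critical,
            "percent_severe_in_critical": round(self.percent_severe_in_critical, 1),
        }


def summarize_protein(
    assessments: list[MutationAssessment], protein_id: str | None = None
) -> ProteinSummary:
    """Aggregate assessments of one protein into a summary row.

    Mean ± sd run over mapped, scored propensities; the severe percentage
    is relative to those; the severe-in-critical percentage is relative to
    the severe variants with a known critical flag.
    """
    if protein_id is not None:
        assessments = [a for a in assessments if a.record.protein_id == protein_id]
    else:
        ids = {a.record.protein_id for a in assessments}
        protein_id = ids.pop() if len(ids) == 1 else "all"
    n_retrieved = len(assessments)
    scored = [a for a in assessments if a.valid and not np.isnan(a.propensity)]
    if not scored:
        return ProteinSummary(protein_id, n_retrieved, 0, float("nan"), float("nan"),
                              0, float("nan"), 0, float("nan"), empty=True)
    props = np.array([a.propensity for a in scored])
    severe = [a for a in scored if a.severity == "severe"]
    flagged = [a for a in severe if a.in_critical is not None]
    n_sic = sum(a.in_critical for a in flagged)
    return ProteinSummary(
        protein_id=protein_id,
        n_retrieved=n_retrieved,
        n_mapped=len(scored),
        mean_propensity=float(props.mean()),
        sd_propensity=float(props.std(ddof=1)) if props.size > 1 else 0.0,
        n_severe=len(severe),
        percent_severe=100.0 * len(severe) / len(scored),
        n_severe_in_critical=int(n_sic),
        percent_severe_in_critical=(100.0 * n_sic / len(flagged)) if flagged else float("nan"),
    )


def assessments_frame(assessments: list[MutationAssessment]) -> pd.DataFrame:
    rows = []
    for a in assessments:
        rows.append(
            {
                "protein_id": a.record.protein_id,
                "variant": a.record.short,
                "domain_id": a.mapped_domain.domain_id if a.mapped_domain else "",
                "domain_position": a.domain_position if a.domain_position else "",
                "unfolding": a.propensity,
                "severity": a.severity,
                "in_critical": "" if a.in_critical is None else bool(a.in_critical),
                "valid": a.valid,
                "note": a.note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationProfile:
    """Per-alignment-column conservation class.

    Classes: ``identical`` (all non-gap residues equal, no gaps),
    ``similar`` (all within one similarity group, no gaps),
    ``gap-dominated`` (gap fraction above the configured threshold),
    otherwise ``nonconserved``.
    """

    classes: list[str]

    @property
    def alignment_length(self) -> int:
        return len(self.classes)

    def conserved_mask(self) -> np.ndarray:
        """identical ∪ similar."""
        return np.array([c in ("identical", "similar") for c in self.classes])


def classify_conservation(
    rows: list[str],
    gap_dominated_fraction: float = 0.5,
    ignore_gap_fraction: float = 0.0,
) -> ConservationProfile:
    """Classify each alignment column by residue conservation.

    Strict by default: a column with any gap can be at best nonconserved.
    ``ignore_gap_fraction > 0`` enables the tolerant mode, where columns
    with up to that fraction of gaps are classified from their non-gap
    residues. Row order never matters.
    """
    if len(rows) < 2:
        raise ValidationError("conservation needs >= 2 alignment rows")
    if len({len(r) for r in rows}) != 1:
        raise ValidationError("alignment rows have unequal lengths")
    n = len(rows)
    classes = []
    for a in range(len(rows[0])):
        col = [r[a] for r in rows]
        n_gap = col.count(GAP)
        gap_frac = n_gap / n
        residues = set(col) - {GAP}
        if gap_frac > gap_dominated_fraction:
            classes.append("gap-dominated")
            continue
        gaps_ok = n_gap == 0 or gap_frac <= ignore_gap_fraction
        if gaps_ok and residues and len(residues) == 1:
            classes.append("identical")
        elif gaps_ok and residues and len({_GROUP_OF[r] for r in residues}) == 1:
            classes.append("similar")
        else:
            classes.append("nonconserved")
    return ConservationProfile(classes)


@dataclass
class ConservationFoldabilityReport:
    """Conservation vs foldability: class-level means and per-position detail."""

    by_class: pd.DataFrame
    per_position: pd.DataFrame

    @property
    def mean_foldability_conserved(self) -> float:
        return float(self.by_class.loc["conserved", "mean_foldability"])

    @property
    def mean_foldability_nonconserved(self) -> float:
        return float(self.by_class.loc["nonconserved", "mean_foldability"])


def conservation_foldability_report(
    cons: ConservationProfile, prof: FoldabilityProfile
) -> ConservationFoldabilityReport:
    """Compare foldability and critical calls between conserved (identical ∪
    similar) and nonconserved alignment positions.

    Returns class-level mean foldability and percent-critical (nan, never
    0, when a class has no scored positions) plus a per-position table of
    class, foldability and critical flag for column-by-column plots.
    """
    if cons.alignment_length != prof.alignment_length:
        raise ValidationError(
            f"conservation profile length {cons.alignment_length} != "
            f"foldability profile length {prof.alignment_length}"
        )
    per_position = pd.DataFrame(
        {
            "position": np.arange(1, prof.alignment_length + 1),
            "conservation": cons.classes,
            "foldability": prof.foldability,
            "critical": prof.critical,
        }
    )
    conserved = cons.conserved_mask()
    noncons = np.array([c == "nonconserved" for c in cons.classes])

    def _stats(mask: np.ndarray) -> dict:
        fold = prof.foldability[mask]
        scored = fold[~np.isnan(fold)]
        n = int(mask.sum())
        return {
            "n_positions": n,
            "mean_foldability": float(scored.mean()) if scored.size else float("nan"),
            "n_critical": int(prof.critical[mask].sum()),
            "percent_critical": (100.0 * prof.critical[mask].sum() / n) if n else float("nan"),
        }

    by_class = pd.DataFrame(
        {"conserved": _stats(conserved), "nonconserved": _stats(noncons)}
    ).T
    by_class[["n_positions", "n_critical"]] = by_class[["n_positions", "n_critical"]].astype(int)
    return ConservationFoldabilityReport(by_class=by_class, per_position=per_position)
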