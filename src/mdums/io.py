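"""On-disk formats: matrix/domain TSVs, AFASTA, attribute files, truth JSON.

All tabular formats are UTF-8, tab-separated, with ``#`` comment lines and
1-based inclusive coordinates. Matrix files carry a mandatory units header
(``#units=propensity`` or ``#units=kcal/mol``) and share one layout:

    #units=propensity
    position  wildtype  A  C  D  ...  Y
    1         M         0.41  NA  ...

Missing cells are written as ``NA``. Floats are written with 10 significant
digits, so a write/read round trip reproduces values to ~1e-9.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AMINO_ACIDS,
    DomainRecord,
    DdgMatrix,
    UnfoldingMatrix,
)
from .exceptions import ParseError, UnitsError, ValidationError

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_domains_tsv",
    "write_domains_tsv",
    "write_afasta",
    "write_attribute_file",
    "write_truth_json",
    "read_truth_json",
]

_FLOAT_FMT = "%.10g"
_UNITS_PROP = "propensity"
_UNITS_DDG = "kcal/mol"


def write_matrix_tsv(matrix: UnfoldingMatrix | DdgMatrix, path) -> None:
    """Write a matrix with its units header; NA marks missing cells."""
    units = _UNITS_PROP if isinstance(matrix, UnfoldingMatrix) else _UNITS_DDG
    df = pd.DataFrame(matrix.values, columns=list(AMINO_ACIDS))
    df.insert(0, "position", np.arange(1, matrix.domain.length + 1))
    df.insert(1, "wildtype", list(matrix.domain.sequence))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#units={units}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_matrix_tsv(path, domain: DomainRecord | None = None) -> UnfoldingMatrix | DdgMatrix:
    """Read a matrix TSV, returning the class its units header declares.

    When ``domain`` is given, the wildtype column and row count are checked
    against it; otherwise a stand-alone :class:`DomainRecord` (protein id =
    file stem, 1-based from 1, type "other") is built from the file.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#units="):
        raise ParseError(f"{path.name}: missing '#units=' header line", line=1)
    units = lines[0].split("=", 1)[1].strip()
    if units not in (_UNITS_PROP, _UNITS_DDG):
        raise UnitsError(f"{path.name}: unknown units {units!r}")
    df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#", na_values=["NA"])
    expected = ["position", "wildtype", *AMINO_ACIDS]
    if list(df.columns) != expected:
        raise ParseError(f"{path.name}: columns must be {expected}")
    wt = "".join(df["wildtype"])
    if not (df["position"].to_numpy() == np.arange(1, len(df) + 1)).all():
        raise ParseError(f"{path.name}: positions must run 1..L without holes")
    if domain is None:
        domain = DomainRecord(
            protein_id=path.stem, domain_type="other", ordinal=1,
            start=1, end=len(wt), sequence=wt,
        )
    elif domain.sequence != wt:
        raise ValidationError(
            f"{path.name}: wildtype column does not match domain {domain.domain_id} sequence"
        )
    values = df[list(AMINO_ACIDS)].to_numpy(dtype=float)
    if units == _UNITS_PROP:
        return UnfoldingMatrix(domain=domain, values=values, provenance="supplied")
    return DdgMatrix(domain=domain, values=values)


_DOMAIN_COLS = ["protein_id", "domain_type", "ordinal", "start", "end", "sequence"]


def write_domains_tsv(domains: list[DomainRecord], path) -> None:
    rows = [
        {
            "protein_id": d.protein_id,
            "domain_type": d.domain_type,
            "ordinal": d.ordinal,
            "start": d.start,
            "end": d.end,
            "sequence": d.sequence,
        }
        for d in domains
    ]
    pd.DataFrame(rows, columns=_DOMAIN_COLS).to_csv(path, sep="\t", index=False)


def read_domains_tsv(path) -> list[DomainRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != _DOMAIN_COLS:
        raise ParseError(f"{Path(path).name}: columns must be {_DOMAIN_COLS}")
    return [
        DomainRecord(
            protein_id=str(r.protein_id),
            domain_type=str(r.domain_type),
            ordinal=int(r.ordinal),
            start=int(r.start),
            end=int(r.end),
            sequence=str(r.sequence),
        )
        for r in df.itertuples()
    ]


def write_afasta(rows: dict[str, str], path) -> None:
    """Write an id -> gapped-row mapping as aligned FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid, row in rows.items():
            fh.write(f">{rid}\n{row}\n")


def write_attribute_file(
    name: str, values_by_residue: dict[int, float], path
) -> None:
    """Write a UCSF-Chimera residue attribute file.

    ``values_by_residue`` keys are protein residue numbers. The attribute
    name must contain no whitespace (dialect constraint); an empty value
    map is refused.
    """
    if not name or any(c.isspace() for c in name):
        raise ValidationError(f"attribute name {name!r} must be non-empty without whitespace")
    scored = {k: v for k, v in values_by_residue.items() if not np.isnan(v)}
    if not scored:
        raise ValidationError("no scored residues: refusing to write an empty attribute file")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"attribute: {name}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for resnum in sorted(scored):
            fh.write(f"\t:{resnum}\t{scored[resnum]:g}\n")


def write_truth_json(truth, path) -> None:
    """Persist a SyntheticTruth's ground truth and config for replay."""
    cfg = truth.config
    payload = {
        "critical_positions": sorted(truth.critical_positions),
        "config": {
            "n_domains": cfg.n_domains,
            "length": cfg.length,
            "fraction_critical": cfg.fraction_critical,
            "critical_beta": list(cfg.critical_beta),
            "background_beta": list(cfg.background_beta),
            "domain_noise_sd": cfg.domain_noise_sd,
            "gap_rate": cfg.gap_rate,
            "identity_sd": cfg.identity_sd,
            "gaps_anywhere": cfg.gaps_anywhere,
            "seed": cfg.seed,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
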