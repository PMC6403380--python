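"""Synthetic homologous-domain ensembles with planted critical positions.

The generator emulates the inputs of the multidomain screen — a set of
homologous domains, their gapped alignment, and per-domain unfolding
matrices — with a known ground truth. A chosen fraction of alignment
positions is *planted* as critical: every non-identity cell there is
drawn from a high-propensity Beta distribution (default Beta(50, 2),
mass above 0.9, the severe regime), while background cells come from a
low-propensity Beta (default Beta(2, 8)). Identity cells scatter around
0.5 as a well-behaved internal control. Each domain additionally carries
a small additive offset (the per-domain noise), emulating systematic
model-quality differences between homology models; the offset is what
gives the between-domain ANOVA its signal. Gaps are planted only at
non-critical positions by default so recovery targets stay unambiguous.

Beta distributions are used because propensities live in [0, 1].
:func:`recovery_metrics` scores a critical-position call against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np

from .core import AMINO_ACIDS, DomainRecord, TransformConfig, UnfoldingMatrix
from .ensemble import AlignedDomainSet
from .exceptions import ValidationError

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "RecoveryMetrics",
    "generate",
    "recovery_metrics",
    "write_fixture_set",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic ensemble.

    Defaults are the reference conditions used throughout the test suite:
    10 homologous domains of 100 residues, 20% of positions planted
    critical, Beta(50, 2) critical vs Beta(2, 8) background cells, a 0.05
    per-domain offset sd, 5% gaps and a tight (0.02 sd) identity control.
    """

    n_domains: int = 10
    length: int = 100
    fraction_critical: float = 0.2
    critical_beta: tuple[float, float] = (50.0, 2.0)
    background_beta: tuple[float, float] = (2.0, 8.0)
    domain_noise_sd: float = 0.05
    gap_rate: float = 0.05
    identity_sd: float = 0.02
    gaps_anywhere: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_domains < 2:
            raise ValidationError("need >= 2 domains")
        if self.length < 1:
            raise ValidationError("domain length must be positive")
        if not 0.0 <= self.fraction_critical <= 1.0:
            raise ValidationError("fraction_critical must lie in [0, 1]")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValidationError("gap_rate must lie in [0, 1)")
        for pair in (self.critical_beta, self.background_beta):
            if min(pair) <= 0:
                raise ValidationError("Beta parameters must be positive")
        if self.domain_noise_sd < 0 or self.identity_sd < 0:
            raise ValidationError("noise standard deviations must be non-negative")


@dataclass
class SyntheticTruth:
    """Generated ensemble plus its ground truth.

    ``critical_positions`` are 1-based alignment positions; the seed is
    echoed for replay.
    """

    config: SyntheticConfig
    critical_positions: set[int]
    aligned: AlignedDomainSet

    @property
    def seed(self) -> int | None:
        return self.config.seed


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Generate a seeded synthetic ensemble with planted critical positions.

    Deterministic given ``config.seed``: one RNG stream drives position
    selection, gaps, sequences, matrix cells and per-domain offsets. The
    number of planted positions is ``round(fraction_critical * length)``.
    """
    rng = np.random.default_rng(config.seed)
    A = config.length
    n_planted = round(config.fraction_critical * A)
    if config.fraction_critical > 0 and n_planted < 1:
        warnings.warn("fraction_critical * length < 1: no positions planted")
    planted = set(
        int(p) + 1 for p in rng.choice(A, size=n_planted, replace=False)
    ) if n_planted else set()

    aa = np.array(list(AMINO_ACIDS))
    domains: list[DomainRecord] = []
    rows: list[str] = []
    matrices: list[UnfoldingMatrix] = []
    offset_sd = config.domain_noise_sd
    spacing = A + 10  # disjoint domain ranges on one synthetic protein
    for d in range(config.n_domains):
        offset = rng.normal(0.0, offset_sd) if offset_sd > 0 else 0.0
        gap_mask = np.zeros(A, dtype=bool)
        if config.gap_rate > 0:
            candidates = (
                np.arange(1, A + 1)
                if config.gaps_anywhere
                else np.array([p for p in range(1, A + 1) if p not in planted])
            )
            gap_mask[candidates[rng.random(candidates.size) < config.gap_rate] - 1] = True
        res_cols = np.flatnonzero(~gap_mask)  # 0-based alignment columns with residues
        L = res_cols.size
        seq = aa[rng.integers(0, 20, size=L)]
        row = np.full(A, "-", dtype="<U1")
        row[res_cols] = seq
        values = np.empty((L, 20))
        for i, col in enumerate(res_cols):
            apos = int(col) + 1
            a_, b_ = config.critical_beta if apos in planted else config.background_beta
            cells = rng.beta(a_, b_, size=20) + offset
            cells[AMINO_ACIDS.index(seq[i])] = 0.5 + (
                rng.normal(0.0, config.identity_sd) if config.identity_sd > 0 else 0.0
            )
            values[i] = np.clip(cells, 0.0, 1.0)
        start = 1 + d * spacing
        dom = DomainRecord(
            protein_id="SYNP",
            domain_type="other",
            ordinal=d + 1,
            start=start,
            end=start + L - 1,
            sequence="".join(seq),
        )
        domains.append(dom)
        rows.append("".join(row))
        matrices.append(UnfoldingMatrix(domain=dom, values=values, provenance="supplied"))

    aligned = AlignedDomainSet(domains=domains, rows=rows, matrices=matrices)
    return SyntheticTruth(config=config, critical_positions=planted, aligned=aligned)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Precision/recall/F1 of a called position set against the truth."""

    precision: float
    recall: float
    f1: float
    n_called: int
    n_true: int
    n_hit: int


def recovery_metrics(called: set[int], truth: set[int]) -> RecoveryMetrics:
    """Score called critical positions against planted ones.

    Empty ``called`` leaves precision (and F1) undefined (nan) with recall
    0; empty ``truth`` leaves recall undefined.
    """
    called, truth = set(called), set(truth)
    hit = len(called & truth)
    precision = hit / len(called) if called else float("nan")
    recall = hit / len(truth) if truth else float("nan")
    if called and truth and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif called and truth:
        f1 = 0.0
    else:
        f1 = float("nan")
    return RecoveryMetrics(precision, recall, f1, len(called), len(truth), hit)


def write_fixture_set(
    truth: SyntheticTruth,
    out_dir,
    as_ddg: bool = False,
    transform: TransformConfig = TransformConfig(),
) -> dict[str, str]:
    """Emit the full on-disk fixture set for a generated ensemble.

    Writes ``domains.tsv``, ``alignment.afasta``, one matrix TSV per domain
    under ``matrices/``, ``truth.json`` and a ready-to-run ``config.yaml``
    for ``mdums run``. With ``as_ddg=True`` matrices are written in
    kcal/mol via the inverse of the logistic transform (propensities
    clipped away from 0/1 first), for conversion round-trip tests.
    """
    from scipy.special import logit

    from . import io as mio
    from .core import DdgMatrix

    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    aligned = truth.aligned
    mio.write_domains_tsv(aligned.domains, out / "domains.tsv")
    paths["domains_tsv"] = str(out / "domains.tsv")
    rows = {d.domain_id: r for d, r in zip(aligned.domains, aligned.rows)}
    mio.write_afasta(rows, out / "alignment.afasta")
    paths["afasta"] = str(out / "alignment.afasta")

    matrix_paths: dict[str, str] = {}
    for dom, m in zip(aligned.domains, aligned.matrices):
        mpath = out / "matrices" / f"{dom.domain_id}.tsv"
        if as_ddg:
            p = np.clip(m.values, 1e-12, 1 - 1e-12)
            ddg = np.where(np.isnan(m.values), np.nan, logit(p) * transform.scale)
            mio.write_matrix_tsv(DdgMatrix(domain=dom, values=ddg), mpath)
        else:
            mio.write_matrix_tsv(m, mpath)
        matrix_paths[dom.domain_id] = f"matrices/{dom.domain_id}.tsv"
    mio.write_truth_json(truth, out / "truth.json")
    paths["truth_json"] = str(out / "truth.json")

    config_lines = [
        "domains_tsv: domains.tsv",
        "afasta: alignment.afasta",
        "out_dir: results",
        f"transform_scale: {transform.scale}",
        "matrices:",
    ]
    for did, rel in sorted(matrix_paths.items()):
        config_lines.append(f"  {did}: {rel}")
    (out / "config.yaml").write_text("\n".join(config_lines) + "\n", encoding="utf-8")
    paths["config"] = str(out / "config.yaml")
    return paths
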