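"""Averaging homologous-domain matrices over an alignment and calling
critical residues.

The coordinate system is the gapped alignment (AFASTA) of a set of
homologous domains. Each domain brings its own L x 20 unfolding matrix;
per alignment column the package averages the non-identity substitution
propensities across contributing domains, runs a one-way ANOVA with
domains as groups, computes the foldability of the averaged vector, and
flags *critical* positions: foldability > 10 together with ANOVA
p < 0.05.

The statsmodels-style entry point is :class:`MultidomainScreen` — a model
built from an :class:`AlignedDomainSet` whose :meth:`~MultidomainScreen.fit`
returns a :class:`ScreenResults` with the averaged matrix, the per-position
profile, internal controls and a ``summary()`` table. The standalone
functions (:func:`average_matrices`, :func:`anova_position`,
:func:`foldability_profile`, ...) expose the same computations piecemeal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AMINO_ACIDS,
    AA_INDEX,
    GAP,
    DomainRecord,
    FoldabilityParams,
    InternalControlResult,
    UnfoldingMatrix,
    foldability,
    identity_control,
)
from .exceptions import AlignmentError, InsufficientDataError, UnitsError, ValidationError

__all__ = [
    "AlignedDomainSet",
    "AveragedMatrix",
    "FoldabilityProfile",
    "MultidomainScreen",
    "ScreenResults",
    "read_afasta",
    "map_row_to_positions",
    "average_matrices",
    "anova_position",
    "anova_profile",
    "foldability_profile",
]


def read_afasta(path) -> dict[str, str]:
    """Read a gapped (aligned) FASTA file into an ordered id -> row mapping.

    Requires at least two records, all of equal gapped length, with unique
    ids. Rows are upper-cased; ``-`` is the gap symbol.
    """
    from Bio import SeqIO

    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise AlignmentError(f"duplicate AFASTA record id {rec.id!r}")
        rows[rec.id] = str(rec.seq).upper()
    if len(rows) < 2:
        raise AlignmentError(f"AFASTA must contain >= 2 records, found {len(rows)}")
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"AFASTA rows have unequal lengths {sorted(lengths)}")
    return rows


def map_row_to_positions(row: str) -> np.ndarray:
    """Map alignment columns of one gapped row to 1-based residue indices.

    Returns an int array of length A where gaps are -1 and non-gap columns
    carry strictly increasing residue indices starting at 1.
    """
    if not row:
        raise ValidationError("gapped row must be non-empty")
    out = np.full(len(row), -1, dtype=int)
    k = 0
    for a, ch in enumerate(row):
        if ch != GAP:
            k += 1
            out[a] = k
    return out


@dataclass
class AlignedDomainSet:
    """Homologous domains, their gapped alignment rows, and their matrices.

    ``rows[i]`` degapped must equal ``domains[i].sequence``; matrices are
    in propensity units (a ΔΔG matrix must be converted before attaching).
    """

    domains: list[DomainRecord]
    rows: list[str]
    matrices: list[UnfoldingMatrix]

    def __post_init__(self) -> None:
        if len(self.domains) < 2:
            raise AlignmentError("need at least 2 aligned domains")
        if not (len(self.domains) == len(self.rows) == len(self.matrices)):
            raise AlignmentError("domains, rows and matrices must have equal counts")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"alignment rows have unequal lengths {sorted(lengths)}")
        for dom, row, m in zip(self.domains, self.rows, self.matrices):
            if row.replace(GAP, "") != dom.sequence:
                raise AlignmentError(
                    f"degapped alignment row for {dom.domain_id} does not match its sequence"
                )
            if not isinstance(m, UnfoldingMatrix):
                raise UnitsError(
                    f"matrix for {dom.domain_id} is not in propensity units; convert ΔΔG first"
                )
            if m.domain is not dom and m.domain != dom:
                raise ValidationError(f"matrix attached to {dom.domain_id} belongs to another domain")

    @classmethod
    def from_afasta(
        cls,
        afasta_rows: dict[str, str],
        domains: list[DomainRecord],
        matrices: dict[str, UnfoldingMatrix],
    ) -> "AlignedDomainSet":
        """Pair AFASTA rows with domains and matrices by ``domain_id``."""
        by_id = {d.domain_id: d for d in domains}
        missing = set(afasta_rows) - set(by_id)
        if missing:
            raise AlignmentError(f"AFASTA ids without a domain record: {sorted(missing)}")
        ordered = [by_id[i] for i in afasta_rows]
        mats = []
        for i in afasta_rows:
            if i not in matrices:
                raise AlignmentError(f"AFASTA id {i!r} has no unfolding matrix")
            mats.append(matrices[i])
        return cls(domains=ordered, rows=list(afasta_rows.values()), matrices=mats)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def alignment_length(self) -> int:
        return len(self.rows[0])

    def position_maps(self) -> np.ndarray:
        """(n_domains, A) array of 1-based residue indices, -1 at gaps."""
        return np.vstack([map_row_to_positions(r) for r in self.rows])

    def consensus_residues(self) -> list[str]:
        """Modal non-gap residue per column (ties broken by alphabet order);
        '-' for all-gap columns."""
        out = []
        for a in range(self.alignment_length):
            col = [r[a] for r in self.rows if r[a] != GAP]
            if not col:
                out.append(GAP)
                continue
            counts = Counter(col)
            # deterministic tie-break: highest count, then earliest in alphabet
            top = max(counts.values())
            tied = sorted(aa for aa, c in counts.items() if c == top)
            out.append(tied[0])
        return out

    def gap_fractions(self) -> np.ndarray:
        rows = np.array([list(r) for r in self.rows])
        return (rows == GAP).mean(axis=0)

    def substitution_cube(self) -> np.ndarray:
        """(n_domains, A, 20) propensities with nan at gaps, missing cells
        and each domain's own identity cell."""
        D, A = self.n_domains, self.alignment_length
        cube = np.full((D, A, 20), np.nan)
        maps = self.position_maps()
        for d, (dom, m) in enumerate(zip(self.domains, self.matrices)):
            pos = maps[d]
            nz = pos > 0
            cube[d, nz, :] = m.values[pos[nz] - 1, :]
            wt_cols = m.wt_indices[pos[nz] - 1]
            cube[d, np.flatnonzero(nz), wt_cols] = np.nan  # exclude identity cells
        return cube


@dataclass
class AveragedMatrix:
    """Per-alignment-position averaged substitution propensities.

    ``means`` and ``n_contributing`` are (A, 20) arrays: each cell averages
    the domains that have a residue at that column, a non-missing matrix
    cell, and a wild type different from the substitution. ``n_positions``
    counts domains contributing any data per column; ``consensus`` is the
    modal residue per column.
    """

    means: np.ndarray
    n_contributing: np.ndarray
    n_positions: np.ndarray
    consensus: list[str]
    gap_fraction: np.ndarray

    @property
    def alignment_length(self) -> int:
        return self.means.shape[0]

    def substitution_vector(self, a: int) -> np.ndarray:
        """Averaged non-consensus substitution vector at 1-based column ``a``.

        The consensus wild-type column is dropped so the vector has at most
        19 entries, keeping foldability on its 0-19 scale.
        """
        row = self.means[a - 1]
        cons = self.consensus[a - 1]
        if cons == GAP:
            return row[np.isnan(row)][:0]
        keep = np.arange(20) != AA_INDEX[cons]
        return row[keep]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.means, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(1, self.alignment_length + 1))
        df.insert(1, "consensus", self.consensus)
        df.insert(2, "n_domains", self.n_positions)
        return df


def average_matrices(aligned: AlignedDomainSet) -> AveragedMatrix:
    """Average homologous-domain propensities per alignment cell.

    A domain contributes to cell (column a, substitution aa) iff it has a
    residue (not a gap) at a, the matrix cell is non-missing, and aa is not
    that domain's wild type there. Cells with zero contributors are missing.
    """
    cube = aligned.substitution_cube()
    n = (~np.isnan(cube)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
        means = np.nanmean(cube, axis=0)
    means[n == 0] = np.nan
    maps = aligned.position_maps()
    n_positions = (maps > 0).sum(axis=0)
    return AveragedMatrix(
        means=means,
        n_contributing=n,
        n_positions=n_positions,
        consensus=aligned.consensus_residues(),
        gap_fraction=aligned.gap_fractions(),
    )


def _position_groups(aligned: AlignedDomainSet, a: int, cube: np.ndarray | None = None):
    if cube is None:
        cube = aligned.substitution_cube()
    groups = []
    for d in range(aligned.n_domains):
        obs = cube[d, a - 1, :]
        obs = obs[~np.isnan(obs)]
        if obs.size >= 2:
            groups.append(obs)
    return groups


def anova_position(aligned: AlignedDomainSet, a: int, _cube: np.ndarray | None = None) -> float:
    """One-way ANOVA p-value at 1-based alignment column ``a``.

    Groups are domains; observations are each domain's non-identity,
    non-missing substitution propensities at that column. Degenerate
    conventions: all observations equal -> p = 1; zero within-group
    variance with unequal group means -> p = 0; fewer than two usable
    groups -> nan.
    """
    groups = _position_groups(aligned, a, _cube)
    if len(groups) < 2:
        return float("nan")
    allobs = np.concatenate(groups)
    if np.all(allobs == allobs[0]):
        return 1.0
    if all(np.all(g == g[0]) for g in groups):
        return 0.0  # distinct constant groups: F diverges
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.f_oneway(*groups).pvalue
    return float(p)


def anova_profile(aligned: AlignedDomainSet) -> np.ndarray:
    """Vector of per-column ANOVA p-values over the whole alignment."""
    cube = aligned.substitution_cube()
    return np.array(
        [anova_position(aligned, a, cube) for a in range(1, aligned.alignment_length + 1)]
    )


@dataclass
class FoldabilityProfile:
    """Per-alignment-position foldability, ANOVA p, coverage and critical flag."""

    foldability: np.ndarray
    p_value: np.ndarray
    n_domains: np.ndarray
    critical: np.ndarray
    consensus: list[str]
    gap_flag: np.ndarray
    params: FoldabilityParams = field(default_factory=FoldabilityParams)

    @property
    def alignment_length(self) -> int:
        return self.foldability.size

    @property
    def critical_positions(self) -> list[int]:
        """Sorted 1-based alignment positions flagged critical."""
        return [int(i) + 1 for i in np.flatnonzero(self.critical)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.alignment_length + 1),
                "consensus": self.consensus,
                "n_domains": self.n_domains,
                "foldability": self.foldability,
                "p_value": self.p_value,
                "critical": self.critical,
                "gap_majority": self.gap_flag,
            }
        )


def foldability_profile(
    avg: AveragedMatrix,
    pvals: np.ndarray,
    params: FoldabilityParams = FoldabilityParams(),
    min_domains: int = 2,
    multiple_testing: str | None = None,
    count_based: bool = False,
) -> FoldabilityProfile:
    """Compute per-position foldability and call critical positions.

    Foldability uses the averaged substitution vector with the consensus
    wild-type column removed. Positions backed by fewer than
    ``min_domains`` domains, or with missing foldability or p-value, are
    never critical. ``multiple_testing="bh"`` applies Benjamini-Hochberg to
    the p-values before thresholding (off by default; raw p < 0.05 is the
    standard rule).
    """
    A = avg.alignment_length
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size != A:
        raise ValidationError("p-value vector length does not match alignment length")
    fold = np.full(A, np.nan)
    for a in range(1, A + 1):
        if avg.n_positions[a - 1] < min_domains:
            continue
        vec = avg.substitution_vector(a)
        if vec.size and not np.all(np.isnan(vec)):
            fold[a - 1] = foldability(vec, params, count_based=count_based)

    p_eff = pvals.copy()
    if multiple_testing == "bh":
        ok = ~np.isnan(p_eff)
        p_eff[ok] = stats.false_discovery_control(p_eff[ok], method="bh")
    elif multiple_testing is not None:
        raise ValidationError(f"unknown multiple-testing mode {multiple_testing!r}")

    with np.errstate(invalid="ignore"):
        critical = (
            ~np.isnan(fold)
            & ~np.isnan(p_eff)
            & (fold > params.critical_foldability_threshold)
            & (p_eff < params.critical_p_threshold)
        )
    return FoldabilityProfile(
        foldability=fold,
        p_value=pvals,
        n_domains=avg.n_positions.copy(),
        critical=critical,
        consensus=list(avg.consensus),
        gap_flag=avg.gap_fraction > 0.5,
        params=params,
    )


class MultidomainScreen:
    """Multidomain unfolding screen over a set of aligned homologous domains.

    Parameters
    ----------
    aligned : AlignedDomainSet
        Domains, gapped rows and propensity matrices sharing one alignment.
    params : FoldabilityParams, optional
        Severity and critical-call thresholds.

    ``fit()`` averages the matrices, computes per-position ANOVA p-values
    and foldability, calls critical positions and runs the per-domain
    internal control, returning a :class:`ScreenResults`.
    """

    def __init__(self, aligned: AlignedDomainSet, params: FoldabilityParams | None = None):
        self.aligned = aligned
        self.params = params or FoldabilityParams()

    def fit(
        self,
        min_domains: int = 2,
        multiple_testing: str | None = None,
        count_based: bool = False,
    ) -> "ScreenResults":
        avg = average_matrices(self.aligned)
        pvals = anova_profile(self.aligned)
        profile = foldability_profile(
            avg,
            pvals,
            self.params,
            min_domains=min_domains,
            multiple_testing=multiple_testing,
            count_based=count_based,
        )
        controls = {}
        for dom, m in zip(self.aligned.domains, self.aligned.matrices):
            try:
                controls[dom.domain_id] = identity_control(m)
            except InsufficientDataError:
                controls[dom.domain_id] = None
        return ScreenResults(self, avg, profile, controls)


class ScreenResults:
    """Fitted results of a :class:`MultidomainScreen`.

    Attributes
    ----------
    averaged : AveragedMatrix
    profile : FoldabilityProfile
    internal_controls : dict mapping domain_id -> InternalControlResult
    """

    def __init__(
        self,
        model: MultidomainScreen,
        averaged: AveragedMatrix,
        profile: FoldabilityProfile,
        internal_controls: dict[str, InternalControlResult | None],
    ):
        self.model = model
        self.averaged = averaged
        self.profile = profile
        self.internal_controls = internal_controls

    @property
    def critical_positions(self) -> list[int]:
        return self.profile.critical_positions

    def summary(self) -> str:
        """Plain-text summary table of the fitted screen."""
        prof = self.profile
        n_crit = int(prof.critical.sum())
        scored = ~np.isnan(prof.foldability)
        lines = [
            "Multidomain Unfolding Screen Results",
            "=" * 52,
            f"domains:              {self.model.aligned.n_domains}",
            f"alignment length:     {prof.alignment_length}",
            f"scored positions:     {int(scored.sum())}",
            f"critical positions:   {n_crit} "
            f"(foldability > {prof.params.critical_foldability_threshold:g}, "
            f"p < {prof.params.critical_p_threshold:g})",
        ]
        if scored.any():
            lines.append(
                f"mean foldability:     {np.nanmean(prof.foldability):.3f}"
            )
        controls = [c for c in self.internal_controls.values() if c is not None]
        if controls:
            n_pass = sum(c.passed for c in controls)
            lines.append(f"internal control:     {n_pass}/{len(controls)} domains pass (CI ∋ 0.5)")
        lines.append("-" * 52)
        df = prof.to_frame()
        crit = df[df["critical"]]
        if len(crit):
            lines.append("critical positions (position, consensus, foldability, p):")
            for _, r in crit.iterrows():
                lines.append(
                    f"  {int(r.position):4d}  {r.consensus}  "
                    f"{r.foldability:6.2f}  {r.p_value:.3g}"
                )
        return "\n".join(lines)

    def plot_foldability(self, ax=None):
        """Bar plot of per-position foldability, critical positions in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        prof = self.profile
        x = np.arange(1, prof.alignment_length + 1)
        colors = np.where(prof.critical, "crimson", "steelblue")
        ax.bar(x, np.nan_to_num(prof.foldability), color=colors, width=0.9)
        ax.axhline(prof.params.critical_foldability_threshold, ls="--", c="gray", lw=1)
        ax.set_xlabel("alignment position")
        ax.set_ylabel("foldability")
        ax.set_ylim(0, 19.5)
        return ax
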