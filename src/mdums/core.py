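"""Single-domain data model and statistics.

This module holds the per-domain building blocks of the unfolding mutation
screen (UMS):

* :data:`AMINO_ACIDS` — the fixed 20-letter residue alphabet that orders
  every matrix column in the package;
* :class:`DomainRecord` / :class:`UnfoldingMatrix` / :class:`DdgMatrix` —
  a globular domain, its L x 20 grid of unfolding propensities in [0, 1],
  and the corresponding grid of free-energy changes (kcal/mol);
* :func:`ddg_to_propensity` / :func:`convert_matrix` — the two-state
  logistic map from a folding free-energy change to an unfolding
  propensity;
* :func:`identity_control` — the self-mutation internal control used to
  judge model quality (identity propensities should center on 0.5);
* :func:`foldability` — the 0-19 per-position statistic obtained by
  summing substitution propensities above the severe threshold.

Propensity matrices use ``numpy.nan`` for missing cells throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .exceptions import InsufficientDataError, ValidationError

#: The 20 canonical residues, alphabetical by one-letter code. Every matrix
#: in the package uses this column order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue one-letter code -> column index into :data:`AMINO_ACIDS`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Domain folds recognised in annotations. "other" is a catch-all for
#: domain types outside the seven studied fold groups.
DOMAIN_TYPES: frozenset[str] = frozenset(
    {
        "EGF-like",
        "laminin-G",
        "cadherin",
        "TB",
        "sushi",
        "Ig-like C2-type",
        "fibronectin type-III",
        "other",
    }
)

GAP = "-"


def _check_sequence(seq: str) -> None:
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(f"sequence contains non-canonical residues: {sorted(bad)}")


@dataclass(frozen=True)
class DomainRecord:
    """One globular domain of a multidomain protein.

    Coordinates are 1-based inclusive positions on the full-length protein,
    matching UniProt domain ranges.
    """

    protein_id: str
    domain_type: str
    ordinal: int
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.domain_type not in DOMAIN_TYPES:
            raise ValidationError(
                f"unknown domain type {self.domain_type!r}; expected one of {sorted(DOMAIN_TYPES)}"
            )
        if self.ordinal < 1:
            raise ValidationError("ordinal must be a positive integer")
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad domain range {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"sequence length {len(self.sequence)} does not match range "
                f"{self.start}..{self.end}"
            )
        _check_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def domain_id(self) -> str:
        """Stable identifier used to pair the domain with AFASTA records."""
        slug = self.domain_type.replace(" ", "")
        return f"{self.protein_id}_{slug}_{self.ordinal}"

    def residue_number(self, domain_position: int) -> int:
        """Protein coordinate of a 1-based position within the domain."""
        if not 1 <= domain_position <= self.length:
            raise ValidationError(f"domain position {domain_position} outside 1..{self.length}")
        return self.start + domain_position - 1


def _check_grid(domain: DomainRecord, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (domain.length, len(AMINO_ACIDS)):
        raise ValidationError(
            f"matrix shape {values.shape} does not match domain length {domain.length} x 20"
        )
    return values


@dataclass
class DdgMatrix:
    """L x 20 grid of folding free-energy changes, in kcal/mol.

    Identity cells (column equal to the wild-type residue of the row) are
    nominally 0. ``nan`` marks a missing cell; infinities are rejected.
    """

    domain: DomainRecord
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_grid(self.domain, self.values)
        if np.isinf(self.values).any():
            raise ValidationError("ΔΔG matrix contains non-finite (inf) entries")


@dataclass
class UnfoldingMatrix:
    """L x 20 grid of unfolding propensities in [0, 1] for one domain.

    Rows follow the domain sequence; columns follow :data:`AMINO_ACIDS`.
    ``nan`` marks a missing cell. ``provenance`` records whether the grid
    was supplied directly or converted from a ΔΔG matrix.
    """

    domain: DomainRecord
    values: np.ndarray
    provenance: str = "supplied"

    def __post_init__(self) -> None:
        self.values = _check_grid(self.domain, self.values)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("unfolding propensities must lie in [0, 1]")

    @property
    def wt_indices(self) -> np.ndarray:
        """Column index of the wild-type residue for each row."""
        return np.array([AA_INDEX[aa] for aa in self.domain.sequence])

    def identity_values(self) -> np.ndarray:
        """Identity-cell propensities (wild type mutated to itself), with nan
        where the cell is missing."""
        return self.values[np.arange(self.domain.length), self.wt_indices]

    def substitution_values(self, row: int) -> np.ndarray:
        """The 19 non-identity propensities of 1-based row ``row``."""
        wt = AA_INDEX[self.domain.sequence[row - 1]]
        keep = np.arange(len(AMINO_ACIDS)) != wt
        return self.values[row - 1, keep]


@dataclass(frozen=True)
class TransformConfig:
    """Parameters of the ΔΔG → propensity logistic transform.

    ``scale`` is the energy scale in kcal/mol; the default is RT at 298 K,
    so a 1 RT destabilisation maps to a propensity of ~0.73.
    """

    scale: float = 0.593

    def __post_init__(self) -> None:
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise ValidationError("transform scale must be a positive, finite energy")


@dataclass(frozen=True)
class FoldabilityParams:
    """Thresholds for severity and critical-residue calling.

    All comparisons are strict: a propensity of exactly 0.9 is not severe,
    a foldability of exactly 10 is not critical, p exactly 0.05 fails.
    """

    severe_threshold: float = 0.9
    critical_foldability_threshold: float = 10.0
    critical_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.severe_threshold < 1.0:
            raise ValidationError("severe_threshold must lie strictly inside (0, 1)")
        if self.critical_foldability_threshold <= 0 or self.critical_p_threshold <= 0:
            raise ValidationError("critical thresholds must be positive")


@dataclass(frozen=True)
class InternalControlResult:
    """Outcome of the self-mutation internal control for one domain.

    ``p_value`` is a Welch two-sample comparison of identity versus
    non-identity propensities: a matrix that genuinely distinguishes real
    mutations from self-mutations yields a small p. ``passed`` is the
    complementary location check — the 95% CI of the identity mean
    contains 0.5.
    """

    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    p_value: float
    passed: bool


def ddg_to_propensity(ddg, cfg: TransformConfig = TransformConfig()):
    """Map a folding free-energy change to an unfolding propensity.

    Uses the two-state logistic ``1 / (1 + exp(-ΔΔG / s))``: a neutral
    mutation (ΔΔG = 0) maps to 0.5, strong destabilisation saturates at 1,
    strong stabilisation at 0. Accepts scalars or arrays (kcal/mol).
    """
    arr = np.asarray(ddg, dtype=float)
    if np.isinf(arr).any() or (np.isnan(arr).any() and arr.ndim == 0):
        raise ValidationError("ΔΔG must be finite")
    out = special.expit(arr / cfg.scale)
    return float(out) if np.ndim(ddg) == 0 else out


def convert_matrix(ddg: DdgMatrix, cfg: TransformConfig = TransformConfig()) -> UnfoldingMatrix:
    """Convert a ΔΔG matrix to an unfolding-propensity matrix cell-wise.

    Missing (nan) cells stay missing; provenance records the conversion.
    """
    vals = np.where(np.isnan(ddg.values), np.nan, special.expit(ddg.values / cfg.scale))
    return UnfoldingMatrix(domain=ddg.domain, values=vals, provenance="converted-from-ddg")


def identity_control(m: UnfoldingMatrix, confidence: float = 0.95) -> InternalControlResult:
    """Self-mutation internal control for one domain matrix.

    Collects the identity-cell propensities, reports their mean, sample sd
    and t-based confidence interval, and a Welch two-sample p-value against
    all non-identity cells. The quality flag passes when the CI contains
    0.5 (identity mutations should leave stability unchanged).
    """
    ident = m.identity_values()
    ident = ident[~np.isnan(ident)]
    n = ident.size
    if n < 2:
        raise InsufficientDataError(
            f"internal control needs >= 2 identity cells, found {n}"
        )
    mean = float(ident.mean())
    sd = float(ident.std(ddof=1))
    if sd == 0.0:
        ci_low = ci_high = mean
    else:
        half = stats.t.ppf(0.5 + confidence / 2, n - 1) * sd / math.sqrt(n)
        ci_low, ci_high = mean - half, mean + half

    mask = np.ones_like(m.values, dtype=bool)
    mask[np.arange(m.domain.length), m.wt_indices] = False
    other = m.values[mask]
    other = other[~np.isnan(other)]
    if other.size < 2:
        p = float("nan")
    elif sd == 0.0 and other.std(ddof=1) == 0.0:
        p = 1.0 if mean == other.mean() else 0.0
    else:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # near-constant samples
            p = float(stats.ttest_ind(ident, other, equal_var=False).pvalue)

    return InternalControlResult(
        n=n,
        mean=mean,
        sd=sd,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p,
        passed=bool(ci_low <= 0.5 <= ci_high),
    )


def foldability(
    props,
    params: FoldabilityParams = FoldabilityParams(),
    count_based: bool = False,
) -> float:
    """Per-position foldability from the non-identity substitution vector.

    Sums the propensities strictly greater than ``params.severe_threshold``
    (missing entries contribute nothing), giving a value in [0, 19] for a
    fully observed 19-substitution vector. ``count_based=True`` counts the
    qualifying substitutions instead of summing them, for sensitivity
    analysis. A vector with every entry missing has undefined foldability
    (returned as nan, never 0).
    """
    arr = np.asarray(props, dtype=float)
    if arr.ndim != 1 or not 1 <= arr.size <= 19:
        raise ValidationError("expected a 1-d vector of at most 19 substitution propensities")
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        return float("nan")
    if finite.min() < 0.0 or finite.max() > 1.0:
        raise ValidationError("substitution propensities must lie in [0, 1]")
    qualifying = finite[finite > params.severe_threshold]
    return float(qualifying.size) if count_based else float(qualifying.sum())
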