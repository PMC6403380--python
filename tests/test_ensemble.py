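"""Alignment mapping, matrix averaging, per-position ANOVA and critical calls."""

import math

import numpy as np
import pytest
from scipy import stats

from mdums.core import AA_INDEX, AMINO_ACIDS, FoldabilityParams, UnfoldingMatrix
from mdums.ensemble import (
    AlignedDomainSet,
    AveragedMatrix,
    MultidomainScreen,
    anova_position,
    anova_profile,
    average_matrices,
    foldability_profile,
    map_row_to_positions,
    read_afasta,
)
from mdums.exceptions import AlignmentError, UnitsError, ValidationError
from mdums.simulate import SyntheticConfig, generate

from conftest import make_domain, make_matrix


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadAfasta:
    def test_two_records(self, tmp_path):
        rows = read_afasta(write(tmp_path, "a.afasta", ">a\nAC-D\n>b\nACED\n"))
        assert rows == {"a": "AC-D", "b": "ACED"}

    def test_unequal_lengths_rejected(self, tmp_path):
        with pytest.raises(AlignmentError):
            read_afasta(write(tmp_path, "b.afasta", ">a\nACDE\n>b\nACDEF\n"))

    def test_duplicate_ids_rejected(self, tmp_path):
        with pytest.raises(AlignmentError):
            read_afasta(write(tmp_path, "c.afasta", ">a\nAC\n>a\nGG\n"))

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(AlignmentError):
            read_afasta(write(tmp_path, "d.afasta", ""))


class TestRowMapping:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ("ACD", [1, 2, 3]),
            ("A-CD", [1, -1, 2, 3]),
            ("---", [-1, -1, -1]),
        ],
    )
    def test_examples(self, row, expected):
        assert map_row_to_positions(row).tolist() == expected

    def test_empty_row_rejected(self):
        with pytest.raises(ValidationError):
            map_row_to_positions("")


def two_domain_set(values1, values2, seqs=("ACDE", "ACDE"), rows=None):
    doms, mats = [], []
    for i, (seq, vals) in enumerate(zip(seqs, (values1, values2))):
        d = make_domain(seq, protein_id=f"P{i}", ordinal=1)
        doms.append(d)
        mats.append(UnfoldingMatrix(d, vals))
    return AlignedDomainSet(doms, list(rows or seqs), mats)


class TestAveraging:
    def test_identical_inputs_average_to_themselves(self):
        vals = np.random.default_rng(0).uniform(0.1, 0.9, (4, 20))
        ads = two_domain_set(vals.copy(), vals.copy())
        avg = average_matrices(ads)
        wt_cols = [AA_INDEX[a] for a in "ACDE"]
        for i in range(4):
            for j in range(20):
                if j == wt_cols[i]:
                    assert np.isnan(avg.means[i, j])  # both domains exclude identity
                else:
                    assert avg.means[i, j] == pytest.approx(vals[i, j])

    def test_simple_two_value_mean(self):
        v1, v2 = np.full((4, 20), 0.2), np.full((4, 20), 0.6)
        avg = average_matrices(two_domain_set(v1, v2))
        j = AA_INDEX["W"]  # not a wild type in ACDE
        assert avg.means[0, j] == pytest.approx(0.4)
        assert avg.n_contributing[0, j] == 2

    def test_gapped_domain_drops_out_of_the_mean(self):
        doms, mats = [], []
        fills = [0.2, 0.4, 0.9]
        rows = ["ACDE", "ACDE", "A-DE"]
        for i, (fill, row) in enumerate(zip(fills, rows)):
            seq = row.replace("-", "")
            d = make_domain(seq, protein_id=f"P{i}")
            doms.append(d)
            mats.append(make_matrix(d, fill=fill, identity=None))
        ads = AlignedDomainSet(doms, rows, mats)
        avg = average_matrices(ads)
        j = AA_INDEX["W"]
        assert avg.means[1, j] == pytest.approx((0.2 + 0.4) / 2)  # column 2: P2 gapped
        assert avg.n_contributing[1, j] == 2
        assert avg.n_positions[1] == 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        v1 = rng.uniform(0, 1, (4, 20))
        v2 = rng.uniform(0, 1, (4, 20))
        a = average_matrices(two_domain_set(v1, v2))
        b = average_matrices(two_domain_set(v2, v1, seqs=("ACDE", "ACDE")))
        np.testing.assert_allclose(a.means, b.means, equal_nan=True)

    def test_means_bounded_by_contributing_cells(self):
        truth = generate(SyntheticConfig(n_domains=4, length=12, seed=5))
        avg = average_matrices(truth.aligned)
        cube = truth.aligned.substitution_cube()
        lo = np.nanmin(cube, axis=0, initial=np.inf, where=~np.isnan(cube))
        hi = np.nanmax(cube, axis=0, initial=-np.inf, where=~np.isnan(cube))
        ok = ~np.isnan(avg.means)
        assert np.all(avg.means[ok] >= lo[ok] - 1e-12)
        assert np.all(avg.means[ok] <= hi[ok] + 1e-12)

    def test_ddg_matrix_rejected_at_attach(self):
        from mdums.core import DdgMatrix

        d1 = make_domain("ACDE", protein_id="P0")
        d2 = make_domain("ACDE", protein_id="P1")
        m1 = make_matrix(d1)
        ddg = DdgMatrix(d2, np.zeros((4, 20)))
        with pytest.raises(UnitsError):
            AlignedDomainSet([d1, d2], ["ACDE", "ACDE"], [m1, ddg])

    def test_degapped_row_must_match_sequence(self):
        d1 = make_domain("ACDE", protein_id="P0")
        d2 = make_domain("ACDE", protein_id="P1")
        with pytest.raises(AlignmentError):
            AlignedDomainSet([d1, d2], ["ACDE", "ACED"], [make_matrix(d1), make_matrix(d2)])


def _anova_set(cells1, cells2):
    """Two single-residue domains (wt A) with given non-nan cells at C, D, ..."""
    doms, mats = [], []
    for i, cells in enumerate((cells1, cells2)):
        d = make_domain("A", protein_id=f"P{i}")
        vals = np.full((1, 20), np.nan)
        for aa, v in cells.items():
            vals[0, AA_INDEX[aa]] = v
        doms.append(d)
        mats.append(UnfoldingMatrix(d, vals))
    return AlignedDomainSet(doms, ["A", "A"], mats)


class TestAnova:
    def test_two_group_f_statistic_hand_checked(self):
        # groups {0.1, 0.2} vs {0.3, 0.4}: SSB/SSW give F = 8 (scale-free),
        # p = F(1,2) survival at 8, evaluated by an independent oracle
        ads = _anova_set({"C": 0.1, "D": 0.2}, {"C": 0.3, "D": 0.4})
        p = anova_position(ads, 1)
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2), abs=1e-12)
        assert p == pytest.approx(0.10557280900008413)

    def test_identical_constant_groups_give_p_one(self):
        ads = _anova_set({"C": 0.5, "D": 0.5}, {"C": 0.5, "D": 0.5})
        assert anova_position(ads, 1) == 1.0

    def test_distinct_constant_groups_give_p_zero(self):
        ads = _anova_set({"C": 0.2, "D": 0.2}, {"C": 0.8, "D": 0.8})
        assert anova_position(ads, 1) == 0.0

    def test_single_contributing_group_is_undefined(self):
        d1 = make_domain("AC", protein_id="P0")
        d2 = make_domain("C", protein_id="P1")
        ads = AlignedDomainSet(
            [d1, d2], ["AC", "-C"], [make_matrix(d1, 0.4, None), make_matrix(d2, 0.6, None)]
        )
        assert math.isnan(anova_position(ads, 1))

    def test_matches_brute_force_on_random_ensembles(self):
        rng = np.random.default_rng(99)
        for seed in range(5):
            truth = generate(SyntheticConfig(n_domains=4, length=8, gap_rate=0.1, seed=seed))
            pvals = anova_profile(truth.aligned)
            for a in range(1, truth.aligned.alignment_length + 1):
                groups = _extract_groups(truth.aligned, a)
                p_brute = _brute_force_anova_p(groups)
                if math.isnan(p_brute):
                    assert math.isnan(pvals[a - 1])
                else:
                    assert pvals[a - 1] == pytest.approx(p_brute, abs=1e-10)


def _extract_groups(aligned, a):
    """Independent group extraction: count non-gaps, drop wt cell and nans."""
    groups = []
    for dom, row, m in zip(aligned.domains, aligned.rows, aligned.matrices):
        if row[a - 1] == "-":
            continue
        res_idx = sum(1 for c in row[: a] if c != "-")  # 1-based residue index
        obs = []
        for j, aa in enumerate(AMINO_ACIDS):
            if aa == dom.sequence[res_idx - 1]:
                continue
            v = m.values[res_idx - 1, j]
            if not np.isnan(v):
                obs.append(v)
        if len(obs) >= 2:
            groups.append(np.array(obs))
    return groups


def _brute_force_anova_p(groups):
    if len(groups) < 2:
        return float("nan")
    allobs = np.concatenate(groups)
    if np.all(allobs == allobs[0]):
        return 1.0
    if all(np.all(g == g[0]) for g in groups):
        return 0.0
    grand = allobs.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(allobs) - len(groups)
    f = (ssb / df1) / (ssw / df2)
    return float(stats.f.sf(f, df1, df2))


def _avg_from_vector(vec19, p):
    """AveragedMatrix with one position: consensus A, substitutions = vec19."""
    means = np.full((1, 20), np.nan)
    means[0, 1:] = vec19
    return (
        AveragedMatrix(
            means=means,
            n_contributing=(~np.isnan(means)).astype(int) * 2,
            n_positions=np.array([2]),
            consensus=["A"],
            gap_fraction=np.array([0.0]),
        ),
        np.array([p]),
    )


class TestFoldabilityProfile:
    def test_fully_destabilized_position_is_critical(self):
        avg, p = _avg_from_vector(np.ones(19), 0.001)
        prof = foldability_profile(avg, p)
        assert prof.foldability[0] == 19.0
        assert prof.critical[0]
        assert prof.critical_positions == [1]

    def test_foldability_exactly_ten_is_not_critical(self):
        vec = np.full(19, 0.5)
        vec[:10] = 1.0  # sum of qualifying cells = 10.0 exactly
        avg, p = _avg_from_vector(vec, 0.001)
        prof = foldability_profile(avg, p)
        assert prof.foldability[0] == 10.0
        assert not prof.critical[0]

    def test_large_p_blocks_critical_call(self):
        vec = np.full(19, 0.5)
        vec[:15] = 1.0
        avg, p = _avg_from_vector(vec, 0.2)
        prof = foldability_profile(avg, p)
        assert prof.foldability[0] == 15.0
        assert not prof.critical[0]

    def test_missing_p_or_foldability_never_critical(self):
        avg, p = _avg_from_vector(np.ones(19), float("nan"))
        assert not foldability_profile(avg, p).critical[0]
        avg2, p2 = _avg_from_vector(np.full(19, np.nan), 0.001)
        prof2 = foldability_profile(avg2, p2)
        assert math.isnan(prof2.foldability[0]) and not prof2.critical[0]

    def test_min_domain_floor_suppresses_thin_positions(self):
        avg, p = _avg_from_vector(np.ones(19), 0.001)
        avg.n_positions[0] = 1
        prof = foldability_profile(avg, p)
        assert math.isnan(prof.foldability[0]) and not prof.critical[0]

    def test_raising_foldability_threshold_shrinks_critical_set(self):
        truth = generate(SyntheticConfig(seed=2))
        sets = []
        for thr in (5.0, 10.0, 15.0):
            params = FoldabilityParams(critical_foldability_threshold=thr)
            res = MultidomainScreen(truth.aligned, params).fit()
            sets.append(set(res.critical_positions))
        assert sets[2] <= sets[1] <= sets[0]

    def test_bh_mode_never_grows_the_critical_set(self):
        truth = generate(SyntheticConfig(seed=3))
        raw = MultidomainScreen(truth.aligned).fit()
        bh = MultidomainScreen(truth.aligned).fit(multiple_testing="bh")
        assert set(bh.critical_positions) <= set(raw.critical_positions)


class TestScreenResults:
    def test_summary_reports_critical_count(self):
        truth = generate(SyntheticConfig(seed=4))
        res = MultidomainScreen(truth.aligned).fit()
        text = res.summary()
        assert f"critical positions:   {len(res.critical_positions)}" in text
        assert "internal control" in text

    def test_profile_frame_has_documented_columns(self):
        truth = generate(SyntheticConfig(n_domains=3, length=10, seed=6))
        res = MultidomainScreen(truth.aligned).fit()
        df = res.profile.to_frame()
        assert list(df.columns) == [
            "position", "consensus", "n_domains", "foldability",
            "p_value", "critical", "gap_majority",
        ]
        assert len(df) == 10
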