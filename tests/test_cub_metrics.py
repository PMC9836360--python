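import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocub.codon_core import FamilyPolicy, build_genetic_code
from mitocub.cub_metrics import (
    deviation,
    enc,
    enc_from_class_means,
    expected_enc,
    gc_content,
    neutral_fit,
    rscu,
)

from conftest import make_counts, random_counts

# --------------------------------------------------------------------------
# Independent oracle: hand-listed standard-code families and naive formulas.
# Kept deliberately separate from the package's family construction.
# --------------------------------------------------------------------------
ORACLE_FAMILIES = [
    ("UUU", "UUC"),                                     # Phe
    ("UUA", "UUG", "CUU", "CUC", "CUA", "CUG"),         # Leu
    ("AUU", "AUC", "AUA"),                              # Ile
    ("AUG",),                                           # Met
    ("GUU", "GUC", "GUA", "GUG"),                       # Val
    ("UCU", "UCC", "UCA", "UCG", "AGU", "AGC"),         # Ser
    ("CCU", "CCC", "CCA", "CCG"),                       # Pro
    ("ACU", "ACC", "ACA", "ACG"),                       # Thr
    ("GCU", "GCC", "GCA", "GCG"),                       # Ala
    ("UAU", "UAC"),                                     # Tyr
    ("CAU", "CAC"),                                     # His
    ("CAA", "CAG"),                                     # Gln
    ("AAU", "AAC"),                                     # Asn
    ("AAA", "AAG"),                                     # Lys
    ("GAU", "GAC"),                                     # Asp
    ("GAA", "GAG"),                                     # Glu
    ("UGU", "UGC"),                                     # Cys
    ("UGG",),                                           # Trp
    ("CGU", "CGC", "CGA", "CGG", "AGA", "AGG"),         # Arg
    ("GGU", "GGC", "GGA", "GGG"),                       # Gly
]

# sixfold families split into fourfold + twofold sub-families by shared prefix
ORACLE_FAMILIES_SPLIT = [
    fam for fam in ORACLE_FAMILIES if len(fam) <= 4
] + [
    ("CUU", "CUC", "CUA", "CUG"), ("UUA", "UUG"),
    ("UCU", "UCC", "UCA", "UCG"), ("AGU", "AGC"),
    ("CGU", "CGC", "CGA", "CGG"), ("AGA", "AGG"),
]


def naive_rscu(counts: dict, split: bool) -> dict:
    fams = ORACLE_FAMILIES_SPLIT if split else ORACLE_FAMILIES
    out = {}
    for fam in fams:
        if len(fam) == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = None if n == 0 else counts.get(c, 0) * len(fam) / n
    return out


def naive_enc(counts: dict):
    """Wright's ENc, recomputed naively; None if any class lacks a valid F."""
    by_class = {}
    for fam in ORACLE_FAMILIES:
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        f = (n * sum((counts.get(c, 0) / n) ** 2 for c in fam) - 1) / (n - 1)
        if f > 0:
            by_class.setdefault(k, []).append(f)
    if set(by_class) != {2, 3, 4, 6}:
        return None
    fbar = {k: sum(v) / len(v) for k, v in by_class.items()}
    return 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]


class TestRSCU:
    def test_uniform_usage_is_one(self, standard_code):
        counts = make_counts({"GCU": 1, "GCC": 1, "GCA": 1, "GCG": 1})
        v = rscu(counts, standard_code)
        assert all(v.values[c] == pytest.approx(1.0) for c in ("GCU", "GCC", "GCA", "GCG"))

    def test_sole_fourfold_codon_is_four(self, standard_code):
        v = rscu(make_counts({"ACC": 1}), standard_code)
        assert v.values["ACC"] == pytest.approx(4.0)
        assert v.values["ACU"] == 0.0

    def test_one_of_three_is_four_thirds(self, standard_code):
        v = rscu(make_counts({"CCG": 1, "CCU": 2}), standard_code)
        assert v.values["CCG"] == pytest.approx(4.0 / 3.0)
        assert round(v.values["CCG"], 2) == 1.33

    def test_split_serine_subfamily(self, standard_code):
        v = rscu(make_counts({"UCC": 2}), standard_code, FamilyPolicy(split_sixfold=True))
        assert v.values["UCC"] == pytest.approx(4.0)

    def test_unsplit_serine(self, standard_code):
        v = rscu(make_counts({"UCC": 2}), standard_code, FamilyPolicy(split_sixfold=False))
        assert v.values["UCC"] == pytest.approx(6.0)

    def test_absent_family_is_na(self, standard_code):
        v = rscu(make_counts({"GCA": 1}), standard_code)
        assert v.values["CCU"] is None

    def test_nondegenerate_excluded_by_default(self, standard_code):
        v = rscu(make_counts({"AUG": 3, "GCA": 1}), standard_code)
        assert "AUG" not in v.values
        v2 = rscu(
            make_counts({"AUG": 3, "GCA": 1}),
            standard_code,
            FamilyPolicy(exclude_nondegenerate=False),
        )
        assert v2.values["AUG"] == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.booleans())
    def test_matches_naive_oracle(self, seed, split):
        code = build_genetic_code("standard")
        rng = np.random.default_rng(seed)
        counts = random_counts(rng, code, n_codons=int(rng.integers(5, 400)))
        got = rscu(counts, code, FamilyPolicy(split_sixfold=split)).values
        expected = naive_rscu(counts.counts, split)
        assert set(got) == set(expected)
        for c in got:
            if expected[c] is None:
                assert got[c] is None
            else:
                assert got[c] == pytest.approx(expected[c], abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_family_sums_equal_family_size(self, seed):
        code = build_genetic_code("standard")
        rng = np.random.default_rng(seed)
        counts = random_counts(rng, code, n_codons=200)
        policy = FamilyPolicy(split_sixfold=True)
        v = rscu(counts, code, policy)
        for fam in code.families(policy).values():
            if len(fam) == 1:
                continue
            vals = [v.values[c] for c in fam]
            if all(x is not None for x in vals):
                assert sum(vals) == pytest.approx(len(fam), abs=1e-9)

    def test_scale_invariance(self, standard_code):
        base = {"GCA": 3, "GCC": 1, "CCU": 2, "CCG": 5}
        v1 = rscu(make_counts(base), standard_code)
        v2 = rscu(make_counts({k: 7 * n for k, n in base.items()}), standard_code)
        for c in v1.values:
            if v1.values[c] is not None:
                assert v1.values[c] == pytest.approx(v2.values[c])


class TestGCContent:
    def test_gc3_zero(self, standard_code):
        assert gc_content(make_counts({"GCA": 2}), standard_code).gc3 == 0.0

    def test_gc3_one(self, standard_code):
        assert gc_content(make_counts({"GCC": 1, "GCG": 1}), standard_code).gc3 == 1.0

    def test_gc3_half(self, standard_code):
        assert gc_content(make_counts({"GCC": 1, "GCA": 1}), standard_code).gc3 == 0.5

    def test_gc_overall(self, standard_code):
        # GCA = 2 GC of 3 positions
        assert gc_content(make_counts({"GCA": 2}), standard_code).gc == pytest.approx(2 / 3)

    def test_nondegenerate_excluded_from_gc3s(self, standard_code):
        # AUG ends G but is a single-codon family: not a synonymous site
        stats = gc_content(make_counts({"AUG": 5, "GCA": 1}), standard_code)
        assert stats.gc3 == 0.0
        assert stats.gc3_all == pytest.approx(5 / 6)

    def test_no_eligible_codons_is_nan(self, standard_code):
        assert math.isnan(gc_content(make_counts({"AUG": 2}), standard_code).gc3)

    def test_accepts_sequence(self, standard_code):
        assert gc_content("ATGGCAGCA", standard_code).gc3 == 0.0


class TestENc:
    def test_extreme_bias_is_twenty(self, standard_code):
        counts = {fam[0]: 10 for fam in standard_code.families().values()}
        p = enc(make_counts(counts), standard_code)
        assert p.enc == pytest.approx(20.0)

    def test_equal_usage_limit_is_sixty_one(self, standard_code):
        val = enc_from_class_means({2: 1 / 2, 3: 1 / 3, 4: 1 / 4, 6: 1 / 6}, standard_code)
        assert val == pytest.approx(61.0)

    def test_equal_usage_limit_mold_mito(self, mold_code):
        val = enc_from_class_means({2: 1 / 2, 3: 1 / 3, 4: 1 / 4, 6: 1 / 6}, mold_code)
        assert val == pytest.approx(62.0)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_naive_oracle(self, seed):
        code = build_genetic_code("standard")
        rng = np.random.default_rng(seed)
        counts = random_counts(rng, code, n_codons=300)
        expected = naive_enc(counts.counts)
        if expected is None:
            return  # oracle declines imputation cases
        p = enc(counts, code)
        assert p.enc_raw == pytest.approx(expected, abs=1e-9)

    def test_enc_capped_at_max(self, standard_code):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = enc(random_counts(rng, standard_code, n_codons=500), standard_code)
            assert 1.0 <= p.enc <= standard_code.enc_max

    def test_self_concatenation_limit(self, standard_code):
        """F-hat depends on n only via (n F0 - 1)/(n - 1); doubling counts
        moves ENc toward its large-n limit, shrinking the gap."""
        base = {"GCA": 3, "GCC": 1, "CCU": 2, "CCG": 1, "UUU": 2, "UUC": 1,
                "AUU": 2, "AUA": 1, "CUU": 2, "CUG": 2, "CAU": 1, "CAC": 2}
        p1 = enc(make_counts(base), standard_code)
        p2 = enc(make_counts({k: 2 * v for k, v in base.items()}), standard_code)
        p8 = enc(make_counts({k: 8 * v for k, v in base.items()}), standard_code)
        assert abs(p8.enc_raw - p2.enc_raw) < abs(p2.enc_raw - p1.enc_raw)
        # the analytic class-mean path is exactly scale-free
        assert enc_from_class_means(
            {k: v for k, v in p2.class_fs.items()}, standard_code
        ) == pytest.approx(p2.enc_raw)

    def test_no_degenerate_family_errors(self, standard_code):
        from mitocub.codon_core import CodonUsageError

        with pytest.raises(CodonUsageError, match="no degenerate family"):
            enc(make_counts({"AUG": 5}), standard_code)

    def test_imputation_flags(self, standard_code):
        # only twofold families observed: classes 3, 4, 6 all imputed
        counts = make_counts({"UUU": 3, "UUC": 2, "CAU": 2, "CAC": 2, "AAA": 4, "AAG": 1})
        p = enc(counts, standard_code)
        assert set(p.imputed_classes) == {3, 4, 6}
        assert "low_confidence" in p.flags


class TestExpectedEnc:
    @pytest.mark.parametrize("gc3,expected", [(0.0, 31.0), (1.0, 32.0), (0.5, 60.5)])
    def test_known_values(self, gc3, expected):
        assert expected_enc(gc3) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)

    def test_bounded_and_peaked_near_half(self):
        grid = np.linspace(0, 1, 201)
        vals = [expected_enc(s) for s in grid]
        assert max(vals) <= 61.0
        assert abs(grid[int(np.argmax(vals))] - 0.5) < 0.01


class TestNeutralFit:
    def _point(self, gene_id, enc_val, gc3):
        from mitocub.cub_metrics import EncPoint

        exp = expected_enc(gc3)
        return EncPoint(gene_id, enc_val, gc3, exp, (exp - enc_val) / exp)

    def test_points_on_curve_give_r2_one(self):
        pts = [self._point(f"g{i}", expected_enc(s), s) for i, s in enumerate((0.2, 0.4, 0.6, 0.8))]
        assert neutral_fit(pts).r2 == pytest.approx(1.0)

    def test_constant_enc_is_na(self):
        pts = [self._point(f"g{i}", 50.0, s) for i, s in enumerate((0.2, 0.5, 0.8))]
        fit = neutral_fit(pts)
        assert math.isnan(fit.r2)
        assert "SS_tot" in fit.reason

    def test_negative_r2_hand_computed(self):
        # four fixed points; oracle worked out by hand below
        gc3s = [0.0, 0.5, 0.5, 1.0]
        encs = [61.0, 31.0, 33.0, 60.0]
        exps = [expected_enc(s) for s in gc3s]  # 31.0, 60.5, 60.5, 32.0
        mean_enc = sum(encs) / 4  # 46.25
        ss_tot = sum((e - mean_enc) ** 2 for e in encs)
        ss_res = sum((e - x) ** 2 for e, x in zip(encs, exps))
        expected_r2 = 1 - ss_res / ss_tot
        assert expected_r2 < 0
        pts = [self._point(f"g{i}", e, s) for i, (e, s) in enumerate(zip(encs, gc3s))]
        assert neutral_fit(pts).r2 == pytest.approx(expected_r2)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">=3"):
            neutral_fit([self._point("g", 50, 0.5)])


class TestDeviation:
    def test_zero_when_on_curve(self):
        from mitocub.cub_metrics import EncPoint

        p = EncPoint("g", 50.0, 0.5, 50.0, 0.0)
        assert deviation(p) == 0.0

    def test_half(self):
        from mitocub.cub_metrics import EncPoint

        p = EncPoint("g", 30.0, 0.5, 60.0, 0.5)
        assert deviation(p) == pytest.approx(0.5)

    def test_negative_when_above(self):
        from mitocub.cub_metrics import EncPoint

        p = EncPoint("g", 61.0, 0.5, 60.5, 0.0)
        assert deviation(p) < 0
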