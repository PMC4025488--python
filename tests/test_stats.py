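import numpy as np
import pytest

from gbsdiv import (
    GenotypeMatrix,
    GroupAssignment,
    allele_freqs,
    amova_phi,
    het_stats,
)
from gbsdiv.io import MISSING
from .conftest import random_matrix
from .oracles import brute_force_amova


def _one_locus(column):
    codes = np.asarray(column, dtype=np.int8).reshape(-1, 1)
    return GenotypeMatrix([f"l{i}" for i in range(len(column))], ["m1"], codes)


def test_allele_freqs_hand_count():
    p, n_valid = allele_freqs(_one_locus([1, 1, 2, 3]))
    assert p[0] == pytest.approx(5 / 8)
    assert n_valid[0] == 4


def test_allele_freqs_all_missing_flagged():
    p, n_valid = allele_freqs(_one_locus([MISSING, MISSING]))
    assert np.isnan(p[0]) and n_valid[0] == 0


def test_allele_freqs_all_het():
    p, _ = allele_freqs(_one_locus([2, 2, 2]))
    assert p[0] == 0.5


def test_het_stats_hand_computation():
    """One locus [1,1,2,3]: Ho = 1/4, He = 1 − 0.625² − 0.375², F = (He−Ho)/He = 7/15."""
    d = het_stats(_one_locus([1, 1, 2, 3]))
    assert d.ho == pytest.approx(0.25)
    assert d.he == pytest.approx(0.46875)
    assert d.f == pytest.approx(7 / 15)


def test_het_stats_max_heterozygosity():
    d = het_stats(_one_locus([2, 2, 2, 2]))
    assert d.ho == 1.0 and d.he == 0.5 and d.f == -1.0


def test_het_stats_monomorphic():
    with pytest.warns(UserWarning, match="F undefined"):
        d = het_stats(_one_locus([1, 1, 1]))
    assert d.ho == 0.0 and d.he == 0.0 and np.isnan(d.f)


def test_het_stats_ignores_missing_only_cells(tiny_matrix):
    """Adding masked cells at level 0 changes nothing."""
    from gbsdiv import apply_random_missing

    out, _ = apply_random_missing(tiny_matrix, 0.0, np.random.default_rng(0))
    a, b = het_stats(tiny_matrix), het_stats(out)
    assert a.ho == b.ho and a.he == b.he and a.f == b.f


def test_label_swap_invariance():
    """Swapping allele labels (1 ↔ 3) at a locus leaves Ho, He, F unchanged."""
    col = [1, 1, 2, 3, 3, 1, 2]
    swapped = [{1: 3, 2: 2, 3: 1}[c] for c in col]
    a, b = het_stats(_one_locus(col)), het_stats(_one_locus(swapped))
    assert a.ho == pytest.approx(b.ho)
    assert a.he == pytest.approx(b.he)
    assert a.f == pytest.approx(b.f)


def test_amova_complete_fixation():
    """Two fixed groups at one locus: Φst = 1 with the stated arithmetic."""
    g = GenotypeMatrix(
        ["a1", "a2", "b1", "b2"], ["m1"],
        np.array([[1], [1], [3], [3]], dtype=np.int8),
    )
    grp = GroupAssignment({"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2"})
    am = amova_phi(g, grp)
    assert am.ss_total == pytest.approx(4.0)
    assert am.ss_within == pytest.approx(0.0)
    assert am.n0 == pytest.approx(2.0)
    assert am.va == pytest.approx(2.0)
    assert am.phi_st == pytest.approx(1.0)
    assert am.df_among == 1 and am.df_within == 2


def test_amova_matches_brute_force():
    """Vectorized AMOVA equals the loop-based oracle on random grouped instances."""
    rng = np.random.default_rng(1)
    for trial in range(30):
        n = int(rng.integers(6, 13))
        L = int(rng.integers(3, 9))
        K = int(rng.integers(2, 4))
        g = random_matrix(rng, n, L, missing=0.15)
        labels = [f"g{i % K}" for i in range(n)]
        grp = GroupAssignment(dict(zip(g.line_ids, labels)))
        try:
            am = amova_phi(g, grp)
        except ValueError:
            continue  # a pair without co-observed loci; covered elsewhere
        oracle = brute_force_amova(g.codes, labels)
        for key in ("ss_total", "ss_among", "ss_within", "va", "vw", "phi_st"):
            assert getattr(am, key) == pytest.approx(oracle[key], abs=1e-9), key


def test_amova_permutation_null(inbred_population):
    """Randomly permuted group labels give mean Φst ≈ 0 on structured data."""
    g, grp = inbred_population
    sub = g.take(np.arange(80), np.arange(300))
    labels = grp.labels_for(sub.line_ids)
    rng = np.random.default_rng(2)
    phis = []
    for _ in range(100):
        perm = rng.permutation(labels)
        ga = GroupAssignment(dict(zip(sub.line_ids, perm)))
        phis.append(amova_phi(sub, ga).phi_st)
    assert abs(float(np.mean(phis))) < 0.01


def test_amova_ss_additivity_and_df(inbred_population):
    g, grp = inbred_population
    sub = g.take(np.arange(0, 200, 5), np.arange(200))
    am = amova_phi(sub, grp.subset(sub.line_ids))
    assert am.ss_total == pytest.approx(am.ss_among + am.ss_within, rel=1e-9)
    assert am.df_among == 3 and am.df_within == 36


def test_amova_undefined_pair():
    codes = np.array([[1, MISSING], [MISSING, 3], [1, 1], [3, 3]], dtype=np.int8)
    g = GenotypeMatrix(["a", "b", "c", "d"], ["m1", "m2"], codes)
    grp = GroupAssignment({"a": "x", "b": "x", "c": "y", "d": "y"})
    with pytest.raises(ValueError, match="co-observed"):
        amova_phi(g, grp)
    with pytest.warns(UserWarning):
        am = amova_phi(g, grp, undefined_pair_fallback=True)
    assert np.isfinite(am.phi_st)


def test_small_sample_he_bias_closed_form():
    """With F=1 and known q, E[Ĥe] from n observed lines is (1 − 1/n)·2q(1−q)."""
    import warnings as _w

    rng = np.random.default_rng(3)
    q, n_obs, reps = 0.3, 5, 4000
    he = []
    for _ in range(reps):
        draws = np.where(rng.random(n_obs) < q, 1, 3).astype(np.int8)
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # monomorphic draws legitimately occur
            he.append(het_stats(_one_locus(draws)).he)
    expected = (1 - 1 / n_obs) * 2 * q * (1 - q)
    assert float(np.mean(he)) == pytest.approx(expected, abs=0.01)


def test_he_downward_bias_with_missingness(inbred_population):
    """Heavy missingness shrinks mean He below the complete-data value."""
    from gbsdiv import apply_random_missing

    g, _ = inbred_population
    sub = g.take(np.arange(60), np.arange(400))
    he_full = het_stats(sub).he
    he_mask = het_stats(apply_random_missing(sub, 0.9, np.random.default_rng(4))[0]).he
    assert he_mask < he_full
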