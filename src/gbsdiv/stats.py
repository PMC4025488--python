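"""Missing-aware diversity statistics: allele frequencies, Ho/He/F, AMOVA Φst.

All estimators use only non-missing genotypes.  Per biallelic locus with
N1/N2/N3 the counts of codes 1/2/3 among observed cells and
n = N1 + N2 + N3:

    p  = (2·N1 + N2) / (2n)            frequency of allele A
    Ho = N2 / n                        observed heterozygosity
    He = 1 − p² − (1−p)²               expected heterozygosity
    F  = (He − Ho) / He                inbreeding coefficient (He > 0 only)

Summaries pool all lines (no group stratification): Ho and He average over
loci with at least one observed genotype; F averages per-locus F over loci
with He > 0 (monomorphic loci contribute He = 0 to the He mean but are
excluded from F).  The alternative ratio-of-pooled-means summary
1 − mean(Ho)/mean(He) is also reported, but the per-locus mean is primary.

AMOVA partitions pairwise squared genotypic distances on the allele-count
scale (codes 1/2/3 → 2/1/0 copies of allele A, per-locus squared differences
0/1/4).  Missing observations are handled by rescaling each pair's distance
by L / L_valid(i, j), the ratio of total loci to co-observed loci, so pairs
with fewer shared observations are not artificially close.  Φst =
Va / (Va + Vw) is reported as computed, never clipped at zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, GroupAssignment, allele_count_view

logger = logging.getLogger(__name__)

__all__ = ["DiversitySummary", "AmovaResult", "allele_freqs", "het_stats", "amova_phi"]


@dataclass
class DiversitySummary:
    ho: float
    he: float
    f: float                       # NaN when no informative locus
    f_from_means: float            # 1 − mean(Ho)/mean(He); secondary summary
    ho_per_locus: np.ndarray
    he_per_locus: np.ndarray
    f_per_locus: np.ndarray        # NaN where He == 0
    n_valid_per_locus: np.ndarray
    n_loci_used: int


@dataclass
class AmovaResult:
    ss_total: float
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    n0: float
    va: float
    vw: float
    phi_st: float
    n_undefined_pairs: int = 0


def allele_freqs(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus frequency of allele A and valid-genotype count.

    Loci with zero observed genotypes get p = NaN (flagged, not an error).
    """
    codes = g.codes
    n1 = (codes == 1).sum(axis=0)
    n2 = (codes == 2).sum(axis=0)
    n3 = (codes == 3).sum(axis=0)
    n_valid = n1 + n2 + n3
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_valid > 0, (2.0 * n1 + n2) / (2.0 * np.maximum(n_valid, 1)), np.nan)
    return p, n_valid


def het_stats(g: GenotypeMatrix) -> DiversitySummary:
    """Pooled observed/expected heterozygosity and inbreeding coefficient."""
    p, n_valid = allele_freqs(g)
    n2 = (g.codes == 2).sum(axis=0)
    used = n_valid > 0
    if not used.any():
        raise ValueError("no locus has an observed genotype")
    with np.errstate(divide="ignore", invalid="ignore"):
        ho_l = np.where(used, n2 / np.maximum(n_valid, 1), np.nan)
        he_l = np.where(used, 1.0 - p**2 - (1.0 - p) ** 2, np.nan)
        f_l = np.where(used & (he_l > 0), (he_l - ho_l) / he_l, np.nan)
    ho = float(np.nanmean(ho_l[used]))
    he = float(np.nanmean(he_l[used]))
    informative = used & (he_l > 0)
    if informative.any():
        f = float(np.nanmean(f_l[informative]))
    else:
        warnings.warn("no informative locus (He > 0); F undefined", stacklevel=2)
        f = float("nan")
    f_means = 1.0 - ho / he if he > 0 else float("nan")
    return DiversitySummary(
        ho=ho,
        he=he,
        f=f,
        f_from_means=f_means,
        ho_per_locus=ho_l,
        he_per_locus=he_l,
        f_per_locus=f_l,
        n_valid_per_locus=n_valid,
        n_loci_used=int(used.sum()),
    )


def _pairwise_sq_dist(codes: np.ndarray, rescale: bool) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Σ (x_i − x_j)² over co-observed loci, allele-count scale.

    Returns (d², L_valid); d² is NaN for pairs with no co-observed locus.
    """
    x = allele_count_view(codes)
    obs = ~np.isnan(x)
    a = np.where(obs, x, 0.0)
    m = obs.astype(float)
    a2 = a * a
    # Σ_co (a_i − a_j)² = Σ a_i² m_j + Σ m_i a_j² − 2 Σ a_i a_j  (zeros at missing)
    d2 = a2 @ m.T + m @ a2.T - 2.0 * (a @ a.T)
    d2 = np.maximum(d2, 0.0)  # clip numerical negatives
    l_valid = m @ m.T
    L = codes.shape[1]
    if rescale:
        with np.errstate(divide="ignore", invalid="ignore"):
            d2 = np.where(l_valid > 0, d2 * (L / np.maximum(l_valid, 1)), np.nan)
    else:
        d2 = np.where(l_valid > 0, d2, np.nan)
    np.fill_diagonal(d2, 0.0)
    return d2, l_valid


def amova_phi(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    rescale_missing: bool = True,
    undefined_pair_fallback: bool = False,
) -> AmovaResult:
    """One-level AMOVA (among/within groups) on squared genotypic distances.

    A pair of lines with zero co-observed loci has no defined distance; this
    raises unless ``undefined_pair_fallback`` substitutes the mean of the
    defined distances (with a warning).
    """
    labels = groups.labels_for(g.line_ids)
    uniq = list(dict.fromkeys(labels.tolist()))
    K = len(uniq)
    N = g.n_lines
    if K < 2:
        raise ValueError("AMOVA requires at least 2 groups")
    sizes = np.array([(labels == u).sum() for u in uniq], dtype=float)

    d2, _ = _pairwise_sq_dist(g.codes, rescale_missing)
    iu = np.triu_indices(N, k=1)
    undef = np.isnan(d2[iu])
    n_undef = int(undef.sum())
    if n_undef:
        if not undefined_pair_fallback:
            raise ValueError(
                f"{n_undef} line pair(s) share no co-observed locus; enable "
                "undefined_pair_fallback to substitute the mean distance"
            )
        fill = float(np.nanmean(d2[iu]))
        warnings.warn(
            f"{n_undef} pair(s) with no co-observed locus set to the mean distance",
            stacklevel=2,
        )
        d2 = np.where(np.isnan(d2), fill, d2)

    ss_total = float(d2[iu].sum() / N)
    ss_within = 0.0
    for u, n_g in zip(uniq, sizes):
        idx = np.flatnonzero(labels == u)
        sub = d2[np.ix_(idx, idx)]
        ss_within += float(np.triu(sub, k=1).sum() / n_g)
    ss_among = ss_total - ss_within

    df_among = K - 1
    df_within = N - K
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    n0 = (N - float((sizes**2).sum()) / N) / (K - 1)
    va = (ms_among - ms_within) / n0
    vw = ms_within
    phi = va / (va + vw) if (va + vw) != 0 else float("nan")
    return AmovaResult(
        ss_total=ss_total,
        ss_among=ss_among,
        ss_within=ss_within,
        df_among=df_among,
        df_within=df_within,
        ms_among=ms_among,
        ms_within=ms_within,
        n0=n0,
        va=va,
        vw=vw,
        phi_st=phi,
        n_undefined_pairs=n_undef,
    )
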