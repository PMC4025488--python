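"""The empirical-assessment loop: mask → subsample → impute → statistics → topology.

For each missing level m and simulation run r the harness (1) masks the
whole genotype matrix at level m, (2) draws a random subsample of lines and
markers and extracts the aligned original cells, (3) imputes the masked
subsample with each requested method, (4) computes pooled Ho/He/F and AMOVA
Φst on the original, missing, and imputed subsets, (5) draws one
representative line per group and scores whether the missing/imputed
neighbor-joining quartet matches the original one, and (6) scores
cell-level imputation accuracy, overall and by the original genotype's
class (major homozygote, heterozygote, minor homozygote).

Per-run estimates are aggregated into means and SDs per (level, method);
relative biases are computed per run against that run's own original-data
estimate and averaged.  Run-level RNG streams derive deterministically from
(master seed, level index, run), so a sweep is reproducible bit for bit.
Heterozygosity values are kept as fractions; multiply Ho by 100 where a
percentage display is wanted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .impute import impute
from .io import MISSING, GenotypeMatrix, GroupAssignment
from .missing import MissingMask, apply_random_missing, subsample
from .stats import allele_freqs, amova_phi, het_stats
from .tree import nj_tree, same_topology, smc_distance

logger = logging.getLogger(__name__)

__all__ = [
    "AssessmentConfig",
    "AccuracyBreakdown",
    "AssessmentResult",
    "relative_bias",
    "imputation_accuracy",
    "run_assessment",
]

DEFAULT_LEVELS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class AssessmentConfig:
    missing_levels: tuple[float, ...] = DEFAULT_LEVELS
    n_runs: int = 100
    n_lines: int = 130
    n_markers: int = 1000
    methods: tuple[str, ...] = ("NONE",)
    seed: int = 0
    imputer_params: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not (0.0 <= m <= 1.0) for m in self.missing_levels):
            raise ValueError("missing levels must lie in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        self.methods = tuple(m.upper() for m in self.methods)


@dataclass
class AccuracyBreakdown:
    """Percent of masked cells recovered, overall and by original class."""

    m_pct: float
    aa_pct: float   # matched and original is the minor homozygote
    het_pct: float  # matched and original is the heterozygote
    maj_pct: float  # matched and original is the major homozygote
    denominator: int


@dataclass
class AssessmentResult:
    summary: pd.DataFrame
    per_run: pd.DataFrame
    failures: list[tuple[float, int, str, str]]


def relative_bias(est: float, ref: float) -> float:
    """Signed percent difference 100·(est − ref)/ref; NaN when ref = 0."""
    if ref == 0:
        warnings.warn("reference estimate is zero; relative bias undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (est - ref) / ref


def imputation_accuracy(
    original: GenotypeMatrix, mask: MissingMask, imputed: GenotypeMatrix
) -> AccuracyBreakdown:
    """Fraction of masked cells whose imputed genotype matches the original.

    Only masked cells whose original genotype is known enter the
    denominator.  A cell's class is its ORIGINAL genotype's class at that
    locus; the major/minor homozygote is decided from allele frequencies on
    the original data, ties counting the code-1 homozygote as major.
    """
    if len(mask) == 0:
        raise ValueError("empty mask")
    li, mj = mask.line_idx, mask.marker_idx
    orig = original.codes[li, mj]
    known = orig != MISSING
    denom = int(known.sum())
    if denom == 0:
        warnings.warn("no masked cell has a known original genotype", stacklevel=2)
        return AccuracyBreakdown(float("nan"), float("nan"), float("nan"), float("nan"), 0)
    p, _ = allele_freqs(original)
    major_code = np.where(p >= 0.5, 1, 3)  # ties: code-1 homozygote is major

    orig_k = orig[known]
    imp_k = imputed.codes[li[known], mj[known]]
    match = imp_k == orig_k
    maj_of_cell = major_code[mj[known]]
    is_het = orig_k == 2
    is_maj = (~is_het) & (orig_k == maj_of_cell)
    is_min = (~is_het) & ~is_maj
    pct = lambda x: 100.0 * float(np.sum(x)) / denom
    return AccuracyBreakdown(
        m_pct=pct(match),
        aa_pct=pct(match & is_min),
        het_pct=pct(match & is_het),
        maj_pct=pct(match & is_maj),
        denominator=denom,
    )


def _quartet(g: GenotypeMatrix, rep_idx: np.ndarray):
    sub = g.take(rep_idx, np.arange(g.n_markers))
    return nj_tree(smc_distance(sub, undefined_pair_fallback=True))


def _stat_row(g: GenotypeMatrix, groups: GroupAssignment) -> dict[str, float]:
    div = het_stats(g)
    am = amova_phi(g, groups, undefined_pair_fallback=True)
    return {"ho": div.ho, "he": div.he, "f": div.f, "phi_st": am.phi_st}


def run_assessment(
    g: GenotypeMatrix, groups: GroupAssignment, cfg: AssessmentConfig
) -> AssessmentResult:
    """Run the full sweep and aggregate per-(level, method) summaries.

    Any stage error is caught, logged with (level, run, method), and the
    affected entry is excluded from the aggregates; failure counts appear in
    the summary.
    """
    records: list[dict[str, Any]] = []
    failures: list[tuple[float, int, str, str]] = []

    for lvl_idx, m in enumerate(cfg.missing_levels):
        for run in range(cfg.n_runs):
            ss = np.random.SeedSequence([int(cfg.seed), lvl_idx, run])
            kids = ss.spawn(4 + len(cfg.methods))
            rng_mask, rng_sub, rng_rep = (np.random.default_rng(k) for k in kids[:3])
            try:
                masked_full, _ = apply_random_missing(g, m, rng_mask)
                sub_miss, sub_groups, idx = subsample(
                    masked_full, groups, cfg.n_lines, cfg.n_markers, rng_sub
                )
                sub_orig = idx.apply(g)
            except Exception as exc:  # setup failure voids the whole run
                logger.error("level %.2f run %d setup failed: %s", m, run, exc)
                failures.append((m, run, "SETUP", str(exc)))
                continue

            # newly masked cells of the subset whose original value is known
            new_miss = sub_miss.missing_mask & ~sub_orig.missing_mask
            li, mj = np.nonzero(new_miss)
            sub_mask = MissingMask(li, mj, m)

            imputed: dict[str, GenotypeMatrix] = {}
            accs: dict[str, AccuracyBreakdown | None] = {}
            for k, method in enumerate(cfg.methods):
                rng_m = np.random.default_rng(kids[3 + k])
                try:
                    res = impute(sub_miss, method, rng=rng_m,
                                 **cfg.imputer_params.get(method, {}))
                    imputed[method] = res.imputed
                    accs[method] = (
                        imputation_accuracy(sub_orig, sub_mask, res.imputed)
                        if method != "NONE" and len(sub_mask)
                        else None
                    )
                except Exception as exc:
                    logger.error("level %.2f run %d %s imputation failed: %s", m, run, method, exc)
                    failures.append((m, run, method, str(exc)))

            # same four representatives for original, missing, and all methods
            labels = sub_groups.labels_for(sub_miss.line_ids)
            rep_idx = np.array(
                [rng_rep.choice(np.flatnonzero(labels == u)) for u in dict.fromkeys(labels)]
            )
            try:
                ref_stats = _stat_row(sub_orig, sub_groups)
                ref_tree = _quartet(sub_orig, rep_idx)
            except Exception as exc:
                logger.error("level %.2f run %d original-data analysis failed: %s", m, run, exc)
                failures.append((m, run, "ORIGINAL", str(exc)))
                continue
            records.append(
                {"level": m, "run": run, "method": "ORIGINAL", **ref_stats,
                 "topo_match": np.nan, "acc_m": np.nan, "acc_aa": np.nan,
                 "acc_het": np.nan, "acc_maj": np.nan,
                 "bias_ho": 0.0, "bias_he": 0.0, "bias_f": 0.0, "bias_phi": 0.0}
            )

            for method, mat in imputed.items():
                try:
                    st = _stat_row(mat, sub_groups)
                    topo = same_topology(_quartet(mat, rep_idx), ref_tree)
                except Exception as exc:
                    logger.error("level %.2f run %d %s analysis failed: %s", m, run, method, exc)
                    failures.append((m, run, method, str(exc)))
                    continue
                acc = accs.get(method)
                records.append(
                    {
                        "level": m, "run": run, "method": method, **st,
                        "topo_match": float(topo),
                        "acc_m": acc.m_pct if acc else np.nan,
                        "acc_aa": acc.aa_pct if acc else np.nan,
                        "acc_het": acc.het_pct if acc else np.nan,
                        "acc_maj": acc.maj_pct if acc else np.nan,
                        "bias_ho": relative_bias(st["ho"], ref_stats["ho"])
                        if ref_stats["ho"] else np.nan,
                        "bias_he": relative_bias(st["he"], ref_stats["he"])
                        if ref_stats["he"] else np.nan,
                        "bias_f": relative_bias(st["f"], ref_stats["f"])
                        if ref_stats["f"] else np.nan,
                        "bias_phi": relative_bias(st["phi_st"], ref_stats["phi_st"])
                        if ref_stats["phi_st"] else np.nan,
                    }
                )

    per_run = pd.DataFrame.from_records(records)
    if per_run.empty:
        raise RuntimeError("all assessment runs failed")

    stat_cols = ["ho", "he", "f", "phi_st", "acc_m", "acc_aa", "acc_het", "acc_maj"]
    bias_cols = ["bias_ho", "bias_he", "bias_f", "bias_phi"]
    grouped = per_run.groupby(["level", "method"], sort=True)
    agg = grouped[stat_cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    agg[[f"{c}_mean" for c in bias_cols]] = grouped[bias_cols].mean()
    agg["topo_accuracy"] = 100.0 * grouped["topo_match"].mean()
    agg["n_runs"] = grouped.size()
    fail_counts: dict[tuple[float, str], int] = {}
    for lvl, run, method, _ in failures:
        fail_counts[(lvl, method)] = fail_counts.get((lvl, method), 0) + 1
    agg["n_failed"] = [fail_counts.get(k, 0) for k in agg.index]
    summary = agg.reset_index()
    return AssessmentResult(summary=summary, per_run=per_run, failures=failures)
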