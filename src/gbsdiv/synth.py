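"""Synthetic genotype generator with controlled MAF regime, inbreeding, and structure.

The generator emulates the statistical features of real crop SNP panels:
three minor-allele-frequency regimes (roughly uniform; an excess of high
MAF; a strong excess of MAF < 0.1), very high inbreeding (selfing crops have
observed heterozygosity well below 10%), and a handful of weakly
differentiated groups (Φst on the order of 1.5–5%).  Differentiation uses
the Balding–Nichols model: group allele frequencies are Beta-distributed
around an ancestral frequency with dispersion set by ``fst_target``.
Within-group genotypes follow an F-model: with q the frequency of allele A,

    P(AA) = q² + f·q(1−q),  P(Aa) = 2q(1−q)(1−f),  P(aa) = (1−q)² + f·q(1−q).

Markers are generated independently (no linkage), matching the unordered-
marker setting the assessment targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix, GroupAssignment

__all__ = ["SyntheticConfig", "sample_maf", "generate_population", "MAF_REGIMES"]

MAF_REGIMES = ("uniform", "high_skew", "low_skew")


@dataclass
class SyntheticConfig:
    """Parameters of the stated synthetic world.

    Defaults correspond to a selfing crop panel with four weakly
    differentiated groups: K=4 groups of 100 lines, 2000 markers, a uniform
    MAF regime, Φst target 3%, inbreeding F = 0.98, no baseline missingness.
    """

    n_groups: int = 4
    lines_per_group: int = 100
    n_markers: int = 2000
    maf_regime: str = "uniform"
    fst_target: float = 0.03
    f_is: float = 0.98
    baseline_missing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maf_regime not in MAF_REGIMES:
            raise ValueError(f"maf_regime must be one of {MAF_REGIMES}")
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        if not (0 <= self.f_is <= 1):
            raise ValueError("f_is must be in [0, 1]")
        if not (0 <= self.baseline_missing < 1):
            raise ValueError("baseline_missing must be in [0, 1)")
        if min(self.n_groups, self.lines_per_group, self.n_markers) < 1:
            raise ValueError("counts must be >= 1")


def sample_maf(regime: str, n_markers: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-marker ancestral minor-allele frequencies for a regime.

    uniform   → Uniform(0.05, 0.5)           (flat MAF spectrum)
    high_skew → Beta(3, 2) rescaled to (0.05, 0.5)   (excess of high MAF)
    low_skew  → Beta(0.6, 3) rescaled to (0.01, 0.5) (strong excess of MAF < 0.1)
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if regime == "uniform":
        return rng.uniform(0.05, 0.5, size=n_markers)
    if regime == "high_skew":
        return 0.05 + 0.45 * rng.beta(3.0, 2.0, size=n_markers)
    if regime == "low_skew":
        return 0.01 + 0.49 * rng.beta(0.6, 3.0, size=n_markers)
    raise ValueError(f"unknown maf_regime {regime!r}")


def generate_population(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, GroupAssignment]:
    """Generate a structured, inbred genotype matrix and its group table.

    Deterministic under (cfg, cfg.seed) when ``rng`` is not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    K, n, L = cfg.n_groups, cfg.lines_per_group, cfg.n_markers
    p_anc = sample_maf(cfg.maf_regime, L, rng)

    theta = cfg.fst_target
    if theta > 0:
        scale = (1.0 - theta) / theta
        # Balding–Nichols: group frequency ~ Beta(p*scale, (1-p)*scale)
        p_grp = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(K, L))
    else:
        p_grp = np.broadcast_to(p_anc, (K, L)).copy()

    f = cfg.f_is
    q = p_grp  # frequency of allele A within each group
    p_aa_hom = q * q + f * q * (1.0 - q)          # code 1
    p_het = 2.0 * q * (1.0 - q) * (1.0 - f)       # code 2
    # code 3 takes the remaining mass

    codes = np.empty((K * n, L), dtype=np.int8)
    line_ids: list[str] = []
    mapping: dict[str, str] = {}
    for g in range(K):
        u = rng.random(size=(n, L))
        block = np.full((n, L), 3, dtype=np.int8)
        block[u < p_aa_hom[g] + p_het[g]] = 2
        block[u < p_aa_hom[g]] = 1
        codes[g * n : (g + 1) * n] = block
        for i in range(n):
            lid = f"G{g + 1}_L{i + 1:03d}"
            line_ids.append(lid)
            mapping[lid] = f"group{g + 1}"

    if cfg.baseline_missing > 0:
        n_cells = codes.size
        n_miss = int(round(cfg.baseline_missing * n_cells))
        flat = rng.choice(n_cells, size=n_miss, replace=False)
        codes.flat[flat] = MISSING

    marker_ids = [f"M{j + 1:05d}" for j in range(L)]
    return GenotypeMatrix(line_ids, marker_ids, codes), GroupAssignment(mapping)
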