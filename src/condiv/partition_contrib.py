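"""Diversity partitioning and per-breed leave-one-out contributions.

Gene diversity is partitioned per locus as

    HT = HS + DG,       HS = 1 - f_bar,

where HS is the unweighted mean of within-breed gene diversities
``2 p_i (1 - p_i)``, HT the gene diversity ``2 p_bar (1 - p_bar)`` at the
unweighted mean frequency, f_bar the mean within-breed expected identity,
and DG = HT - HS the divergence component.  DG also equals the average of
all n^2 pairwise Nei minimum distances (diagonal zeros included) — an
algebraic identity used as an internal cross-check in the test suite.

Allelic diversity is partitioned as

    AT = AS + DA,
    AS = (1/n) sum_i k_i,
    DA = 1/(n (n-1)) sum_{i != j} (k_i - k_ij),

with ``k_i`` the number of distinct alleles in breed i at a locus and
``k_ij`` the number shared by breeds i and j.  Rarefaction replaces the
observed counts by their hypergeometric expectations in a subsample of
``g`` gene copies (``g`` = the smallest number of called copies across
breeds at the locus), removing sample-size bias; shared counts use the
product of per-breed presence probabilities (independent subsamples).

The leave-one-out contribution of breed k to a component X is

    c_k(X) = 100 (X_all - X_without_k) / T_all,

with the *total* (HT or AT) of the full panel as common denominator for
every column, which makes each row exactly additive:
``c(total) = c(within) + c(between)``.  A positive contribution means
removing the breed lowers that component.

Breeds are treated as units (unweighted means regardless of sample size).
Loci where any included breed has zero called copies are skipped for the
whole partition; leave-one-out runs reuse the full-panel locus mask so that
contributions reflect breed removal only, never a change of locus set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import GenotypePanel, genotype_counts

logger = logging.getLogger(__name__)


@dataclass
class GeneDiversityPartition:
    HT: float
    HS: float
    DG: float
    f_bar: float
    n_subpops: int
    breed_codes: list[str] = field(default_factory=list)
    loci_used: np.ndarray | None = None


@dataclass
class AllelicPartition:
    AT: float
    AS: float
    DA: float
    k_i: dict[str, float] = field(default_factory=dict)
    k_ij: pd.DataFrame | None = None
    rarefaction_g: str = "none"
    n_subpops: int = 0
    breed_codes: list[str] = field(default_factory=list)
    loci_used: np.ndarray | None = None


@dataclass
class ContributionTable:
    """Signed percentage contributions of each breed to a partition.

    ``which`` is "gene" (columns c_HT, c_HS, c_DG) or "allelic" (columns
    c_AT, c_AS, c_DA); ``data`` uses the generic column names ``c_total``,
    ``c_within``, ``c_between``.  Rows satisfy
    ``c_total == c_within + c_between`` exactly.
    """

    which: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.which not in ("gene", "allelic"):
            raise ValueError("which must be 'gene' or 'allelic'")
        got = set(self.data.columns)
        need = {"breed_code", "c_total", "c_within", "c_between"}
        if not need <= got:
            raise ValueError(f"contribution table needs columns {sorted(need)}")

    @property
    def component_names(self) -> tuple[str, str, str]:
        return ("HT", "HS", "DG") if self.which == "gene" else ("AT", "AS", "DA")


def _allele_copy_counts(panel: GenotypePanel, breeds: list[str]):
    """Copy counts of allele a and b per breed per locus."""
    ca, cb = [], []
    for b in breeds:
        n_aa, n_ab, n_bb, _ = genotype_counts(panel.breed_calls(b))
        ca.append(2 * n_aa + n_ab)
        cb.append(2 * n_bb + n_ab)
    return np.vstack(ca).astype(float), np.vstack(cb).astype(float)


def partition_locus_mask(panel: GenotypePanel, breeds: list[str] | None = None) -> np.ndarray:
    """Variant indices where every breed has at least one called genotype."""
    breeds = breeds or panel.breed_codes
    ca, cb = _allele_copy_counts(panel, breeds)
    ok = ((ca + cb) >= 1).all(axis=0)
    return np.flatnonzero(ok)


def gene_diversity_partition(
    panel: GenotypePanel, breeds: list[str] | None = None, loci: np.ndarray | None = None
) -> GeneDiversityPartition:
    """HT/HS/DG partition over the given breeds (>= 2 required)."""
    breeds = breeds or panel.breed_codes
    if len(breeds) < 2:
        raise ValueError("gene-diversity partition needs at least 2 breeds")
    ca, cb = _allele_copy_counts(panel, breeds)
    n_copies = ca + cb
    if loci is None:
        loci = np.flatnonzero((n_copies >= 1).all(axis=0))
    if loci.size == 0:
        raise ValueError("no locus with calls in every breed")
    skipped = panel.n_variants - loci.size
    if skipped:
        logger.info("gene partition: %d loci skipped (no calls in some breed)", skipped)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = cb[:, loci] / n_copies[:, loci]
    hs_loc = np.mean(2 * p * (1 - p), axis=0)
    p_bar = p.mean(axis=0)
    ht_loc = 2 * p_bar * (1 - p_bar)
    HS = float(hs_loc.mean())
    HT = float(ht_loc.mean())
    return GeneDiversityPartition(
        HT=HT,
        HS=HS,
        DG=HT - HS,
        f_bar=1 - HS,
        n_subpops=len(breeds),
        breed_codes=list(breeds),
        loci_used=loci,
    )


def _presence_probability(c: np.ndarray, n_copies: np.ndarray, g: np.ndarray) -> np.ndarray:
    """P(an allele with c copies out of N appears in a subsample of g copies).

    ``1 - C(N - c, g) / C(N, g)``, computed through log-gamma for stability;
    exactly 1 when fewer than g copies of the other alleles exist.
    """
    absent_possible = (n_copies - c) >= g
    with np.errstate(invalid="ignore", divide="ignore"):
        log_p_absent = (
            gammaln(n_copies - c + 1)
            - gammaln(n_copies - c - g + 1)
            + gammaln(n_copies - g + 1)
            - gammaln(n_copies + 1)
        )
    p_absent = np.where(absent_possible, np.exp(log_p_absent), 0.0)
    return 1.0 - p_absent


def allelic_partition(
    panel: GenotypePanel,
    breeds: list[str] | None = None,
    rarefaction: str = "min",
    loci: np.ndarray | None = None,
) -> AllelicPartition:
    """AT/AS/DA partition over the given breeds (>= 2 required).

    ``rarefaction="min"`` rarefies per locus to the smallest called
    gene-copy count across breeds; ``rarefaction="none"`` uses raw observed
    allele counts (the two modes coincide when sample sizes are equal and
    complete).
    """
    breeds = breeds or panel.breed_codes
    if len(breeds) < 2:
        raise ValueError("allelic partition needs at least 2 breeds")
    if rarefaction not in ("min", "none"):
        raise ValueError("rarefaction must be 'min' or 'none'")
    ca, cb = _allele_copy_counts(panel, breeds)
    n_copies = ca + cb
    if loci is None:
        loci = np.flatnonzero((n_copies >= 1).all(axis=0))
    if loci.size == 0:
        raise ValueError("no locus with calls in every breed")
    skipped = panel.n_variants - loci.size
    if skipped:
        logger.info("allelic partition: %d loci skipped (no calls in some breed)", skipped)
    ca, cb, n_copies = ca[:, loci], cb[:, loci], n_copies[:, loci]
    B, L = ca.shape

    if rarefaction == "min":
        g = n_copies.min(axis=0)  # (L,)
        pa = _presence_probability(ca, n_copies, g)
        pb = _presence_probability(cb, n_copies, g)
    else:
        pa = (ca > 0).astype(float)
        pb = (cb > 0).astype(float)

    k_i = pa + pb  # (B, L)
    sum_ki = k_i.sum(axis=0)  # (L,)
    # sum over ordered pairs i != j of k_ij, via Gram sums minus diagonals
    sum_kij_all = (pa.sum(axis=0)) ** 2 - (pa**2).sum(axis=0)
    sum_kij_all += (pb.sum(axis=0)) ** 2 - (pb**2).sum(axis=0)
    da_loc = ((B - 1) * sum_ki - sum_kij_all) / (B * (B - 1))
    as_loc = sum_ki / B

    AS = float(as_loc.mean())
    DA = float(da_loc.mean())
    kij_mean = (pa @ pa.T + pb @ pb.T) / L
    return AllelicPartition(
        AT=AS + DA,
        AS=AS,
        DA=DA,
        k_i={b: float(k_i[i].mean()) for i, b in enumerate(breeds)},
        k_ij=pd.DataFrame(kij_mean, index=breeds, columns=breeds),
        rarefaction_g=rarefaction,
        n_subpops=B,
        breed_codes=list(breeds),
        loci_used=loci,
    )


def loo_contribution(
    panel: GenotypePanel,
    breeds: list[str] | None = None,
    which: str = "gene",
    rarefaction: str = "min",
) -> ContributionTable:
    """Leave-one-out contribution of every breed to each partition component.

    Requires >= 3 breeds (removing one must leave a valid partition).
    ``c_between`` is reported as ``c_total - c_within`` so each row is
    additive to machine exactness.
    """
    breeds = breeds or panel.breed_codes
    if len(breeds) < 3:
        raise ValueError("leave-one-out contributions need at least 3 breeds")
    if which not in ("gene", "allelic"):
        raise ValueError("which must be 'gene' or 'allelic'")

    mask = partition_locus_mask(panel, breeds)

    def parts(sub: list[str]) -> tuple[float, float, float]:
        if which == "gene":
            p = gene_diversity_partition(panel, sub, loci=mask)
            return p.HT, p.HS, p.DG
        p = allelic_partition(panel, sub, rarefaction=rarefaction, loci=mask)
        return p.AT, p.AS, p.DA

    total_all, within_all, between_all = parts(list(breeds))
    rows = []
    for k in breeds:
        rest = [b for b in breeds if b != k]
        _, within_wo, between_wo = parts(rest)
        c_within = 100.0 * (within_all - within_wo) / total_all
        c_between = 100.0 * (between_all - between_wo) / total_all
        rows.append(
            {
                "breed_code": k,
                # the sum, so each row is additive to machine exactness
                "c_total": c_within + c_between,
                "c_within": c_within,
                "c_between": c_between,
            }
        )
    return ContributionTable(which=which, data=pd.DataFrame(rows))
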