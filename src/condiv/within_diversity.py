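"""Within-breed diversity: Ho, He, MAF, FHOM and molecular coancestry.

All per-locus statistics use called genotypes only; loci with no calls in a
breed are skipped for that breed.  Every statistic here is invariant under
the arbitrary allele-coding orientation of the panel.

The coancestry indices follow the molecular (identity-by-state) definition:
the coancestry of two individuals at a locus is the mean of the four
allele-identity indicators between them, and an individual's raw
self-coancestry is ``s = 1 - h/2`` with ``h`` its heterozygous fraction.
Both are reported as deviations from the value expected under within-breed
Hardy-Weinberg proportions, scaled by the maximum possible deviation, and
*signed so that positive values mean an excess of homozygosity* (a deficit
of pairwise allele sharing) and negative values an excess of
heterozygosity.  This makes the sign of ``fii`` track ``He - Ho``: an
outbred breed with Ho > He has fii < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, genotype_counts


@dataclass
class BreedDiversitySummary:
    """One row of a per-breed diversity table."""

    breed_code: str
    n_samples: int
    Ho: float
    He: float
    MAF: float
    FHOM: float
    fii: float
    si: float


def _breed_counts(panel: GenotypePanel, breed: str):
    calls = panel.breed_calls(breed)
    n_aa, n_ab, n_bb, _ = genotype_counts(calls)
    n_called = n_aa + n_ab + n_bb
    return calls, n_aa, n_ab, n_bb, n_called


def breed_allele_freqs(panel: GenotypePanel, breed: str) -> np.ndarray:
    """Per-variant frequency of ``allele_b`` in one breed.

    Variants with no called genotype in the breed are NaN.
    """
    _, n_aa, n_ab, n_bb, n_called = _breed_counts(panel, breed)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_bb + n_ab) / (2 * n_called)
    return np.where(n_called > 0, p, np.nan)


def pooled_allele_freqs(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Pooled allele-b frequency and called-individual count per variant."""
    n_aa, n_ab, n_bb, _ = genotype_counts(panel.calls)
    n_called = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_bb + n_ab) / (2 * n_called)
    return np.where(n_called > 0, p, np.nan), n_called


def observed_heterozygosity(panel: GenotypePanel, breed: str) -> float:
    """Mean over variants of the heterozygote fraction among called genotypes."""
    _, _, n_ab, _, n_called = _breed_counts(panel, breed)
    ok = n_called > 0
    if not ok.any():
        raise ValueError(f"breed {breed!r} has no called genotypes")
    return float(np.mean(n_ab[ok] / n_called[ok]))


def expected_heterozygosity(panel: GenotypePanel, breed: str, unbiased: bool = False) -> float:
    """Mean over variants of ``2p(1-p)``.

    With ``unbiased=True`` each per-variant term is multiplied by
    ``2n/(2n-1)`` (Nei's small-sample correction, ``n`` = called genotypes).
    """
    _, _, _, _, n_called = _breed_counts(panel, breed)
    p = breed_allele_freqs(panel, breed)
    ok = n_called > 0
    if not ok.any():
        raise ValueError(f"breed {breed!r} has no called genotypes")
    he = 2 * p[ok] * (1 - p[ok])
    if unbiased:
        n2 = 2 * n_called[ok]
        he = he * np.where(n2 > 1, n2 / (n2 - 1), np.nan)
    return float(np.nanmean(he))


def breed_maf(panel: GenotypePanel, breed: str) -> float:
    """Mean over variants of the within-breed minor-allele frequency."""
    p = breed_allele_freqs(panel, breed)
    ok = ~np.isnan(p)
    if not ok.any():
        raise ValueError(f"breed {breed!r} has no called genotypes")
    return float(np.mean(np.minimum(p[ok], 1 - p[ok])))


# ----------------------------------------------------------------------
# FHOM
# ----------------------------------------------------------------------

def _reference_freqs(
    panel: GenotypePanel, breed: str | None, source: str
) -> tuple[np.ndarray, np.ndarray]:
    if source == "pooled":
        return pooled_allele_freqs(panel)
    if source == "within":
        if breed is None:
            raise ValueError("within-breed reference requires a breed")
        _, _, _, _, n_called = _breed_counts(panel, breed)
        return breed_allele_freqs(panel, breed), n_called
    raise ValueError(f"ref_freq_source must be 'pooled' or 'within', got {source!r}")


def f_hom(
    panel: GenotypePanel,
    sample_id: str,
    ref_freq_source: str = "pooled",
) -> float:
    """Method-of-moments inbreeding coefficient of one individual.

    ``FHOM = (O_hom - E_hom) / (L - E_hom)`` where ``O_hom`` is the
    individual's observed homozygote count over its called loci, ``L`` the
    number of those loci, and ``E_hom`` the homozygote count expected under
    Hardy-Weinberg at reference allele frequencies with the ``2n/(2n-1)``
    small-sample correction.  Reference frequencies come from the pooled
    panel (default, the single-run convention of chip-QC tooling) or from
    the individual's own breed (``ref_freq_source="within"``).

    Returns NaN when the denominator degenerates (e.g. all reference
    frequencies fixed).
    """
    idx = [i for i, s in enumerate(panel.samples) if s.sample_id == sample_id]
    if not idx:
        raise KeyError(f"unknown sample {sample_id!r}")
    i = idx[0]
    breed = panel.samples[i].breed_code
    p, n_called = _reference_freqs(panel, breed, ref_freq_source)
    g = panel.calls[i]
    called = (g >= 0) & ~np.isnan(p) & (n_called > 0)
    if not called.any():
        return math.nan
    pj = p[called]
    n2 = 2 * n_called[called]
    corr = np.where(n2 > 1, n2 / (n2 - 1), 1.0)
    e_hom = float(np.sum(1 - 2 * pj * (1 - pj) * corr))
    L = int(called.sum())
    o_hom = int(np.sum((g[called] == 0) | (g[called] == 2)))
    denom = L - e_hom
    if abs(denom) < 1e-12:
        return math.nan
    return (o_hom - e_hom) / denom


def breed_f_hom(panel: GenotypePanel, breed: str, ref_freq_source: str = "pooled") -> float:
    """Breed-level FHOM: mean of the per-individual coefficients."""
    vals = [
        f_hom(panel, s.sample_id, ref_freq_source)
        for s in panel.samples
        if s.breed_code == breed
    ]
    if not vals:
        raise KeyError(f"unknown breed code {breed!r}")
    return float(np.nanmean(vals))


# ----------------------------------------------------------------------
# molecular coancestry
# ----------------------------------------------------------------------

def coancestry_indices(panel: GenotypePanel, breed: str) -> tuple[float, float]:
    """Deviation-scaled mean coancestry ``fii`` and self-coancestry ``si``.

    Per locus with ``n >= 2`` called individuals, the mean molecular
    coancestry over distinct pairs satisfies the closed form

        f_obs = [n (1 - He) - 1 + Ho/2] / (n - 1),

    (He at sample frequencies, Ho the called heterozygote fraction), with
    Hardy-Weinberg expectation ``f_exp`` obtained by substituting He for
    Ho.  The reported index is ``fii = (f_exp - f_obs) / (1 - f_exp)``
    averaged over loci, positive when pairwise allele sharing falls short
    of the random-mating expectation (homozygote excess) and negative under
    heterozygote excess — so ``sign(fii) = sign(He - Ho)``.

    ``si`` is the analogous deviation of the mean raw self-coancestry
    ``s = 1 - h/2`` from its expectation ``1 - He/2``.

    ``fii`` is NaN for a breed with fewer than two samples (``si`` is still
    computed).  Both are NaN when every usable locus is monomorphic.
    """
    calls, n_aa, n_ab, n_bb, n_called = _breed_counts(panel, breed)
    n_ind = calls.shape[0]
    p = breed_allele_freqs(panel, breed)

    ok1 = n_called >= 1
    if not ok1.any():
        raise ValueError(f"breed {breed!r} has no called genotypes")
    he = 2 * p * (1 - p)
    ho = np.where(ok1, n_ab / np.maximum(n_called, 1), np.nan)

    # self-coancestry deviation
    s_obs = np.nanmean(1 - ho[ok1] / 2)
    s_exp = np.nanmean(1 - he[ok1] / 2)
    si = (s_obs - s_exp) / (1 - s_exp) if (1 - s_exp) > 1e-12 else math.nan

    if n_ind < 2:
        return math.nan, si

    ok2 = n_called >= 2
    if not ok2.any():
        return math.nan, si
    n = n_called[ok2].astype(float)
    f_obs = (n * (1 - he[ok2]) - 1 + ho[ok2] / 2) / (n - 1)
    f_exp = (n * (1 - he[ok2]) - 1 + he[ok2] / 2) / (n - 1)
    f_obs_bar = float(np.mean(f_obs))
    f_exp_bar = float(np.mean(f_exp))
    if (1 - f_exp_bar) <= 1e-12:
        return math.nan, si
    fii = (f_exp_bar - f_obs_bar) / (1 - f_exp_bar)
    return fii, si


def diversity_summary(
    panel: GenotypePanel, ref_freq_source: str = "pooled"
) -> pd.DataFrame:
    """Per-breed table of Ho, He, MAF, FHOM, fii and si."""
    rows = []
    for code in panel.breed_codes:
        fii, si = coancestry_indices(panel, code)
        rows.append(
            BreedDiversitySummary(
                breed_code=code,
                n_samples=len(panel.sample_indices(code)),
                Ho=observed_heterozygosity(panel, code),
                He=expected_heterozygosity(panel, code),
                MAF=breed_maf(panel, code),
                FHOM=breed_f_hom(panel, code, ref_freq_source),
                fii=fii,
                si=si,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
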